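"""Small reporting helpers: dataset-composition percentages.

Percentages are rounded half away from zero (so 60.5% reports as 61%), the
convention used in the tabulated summaries this package reproduces.
"""

from __future__ import annotations

import math


def percent(part: float, whole: float) -> float:
    """``100 * part / whole``; whole must be positive."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent_rounded(part: float, whole: float) -> int:
    """Integer percentage with half-up rounding."""
    return round_half_up(percent(part, whole))


def composition_summary(counts: dict[str, int]) -> dict[str, int]:
    """Integer percentages describing a screening-library overlap.

    ``counts`` must provide: ``database`` (labeled database size),
    ``overlap`` (chemicals also in the screening library), ``toxic``,
    ``hepatocellular``, ``hepatobiliary`` and ``both_mechanisms`` counts
    within the overlap.
    """
    return {
        "pct_in_library": percent_rounded(counts["overlap"], counts["database"]),
        "pct_toxic": percent_rounded(counts["toxic"], counts["overlap"]),
        "pct_hepatocellular": percent_rounded(counts["hepatocellular"], counts["toxic"]),
        "pct_hepatobiliary": percent_rounded(counts["hepatobiliary"], counts["toxic"]),
        "pct_both_mechanisms": percent_rounded(counts["both_mechanisms"], counts["toxic"]),
    }


def ke_multiplicity_percent(n_multi_assay_kes: int, n_kes: int) -> int:
    """Integer percentage of KEs backed by more than one assay."""
    return percent_rounded(n_multi_assay_kes, n_kes)
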