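"""Selection of assays associated with hepatotoxicity endpoints.

Per assay and per endpoint (hepatocellular, hepatobiliary), hit calls are
cross-tabulated against labels, tested with the two-sided Fisher exact
test, and controlled with the Benjamini-Hochberg step-up procedure at an
FDR of 0.15 within each endpoint.  Only positively associated assays
(odds ratio > 1) are retained; the two endpoint sets are reported together
with their union and intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FDR = 0.15

ENDPOINTS = ("hepatocellular", "hepatobiliary")


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one assay x endpoint association test."""

    assay_id: str
    endpoint: str
    table: np.ndarray  # [[active&toxic, active&nontoxic], [inactive&toxic, inactive&nontoxic]]
    odds_ratio: float
    p_value: float
    degenerate: bool
    selected: bool = False


@dataclass
class AssaySelection:
    """Per-endpoint selected assay sets plus their union and intersection."""

    results: list[AssociationResult]
    by_endpoint: dict[str, set[str]]

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.by_endpoint.values():
            out |= s
        return out

    @property
    def intersection(self) -> set[str]:
        sets = list(self.by_endpoint.values())
        if not sets:
            return set()
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            (a, b), (c, d) = r.table
            rows.append(
                {
                    "assay_id": r.assay_id,
                    "endpoint": r.endpoint,
                    "a": int(a),
                    "b": int(b),
                    "c": int(c),
                    "d": int(d),
                    "odds_ratio": r.odds_ratio,
                    "p_value": r.p_value,
                    "selected": int(r.selected),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["assay_id", "endpoint", "a", "b", "c", "d", "odds_ratio", "p_value", "selected"],
        )


def _as_unique_mapping(values, what: str) -> dict[str, int]:
    if isinstance(values, pd.Series):
        if not values.index.is_unique:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated chem_id rows in {what}: {dupes}")
        return {str(k): int(v) for k, v in values.items()}
    return {str(k): int(v) for k, v in dict(values).items()}


def contingency(hit_calls, labels) -> np.ndarray:
    """2x2 table of (active/inactive) x (toxic/nontoxic) counts.

    Both arguments are chem_id-keyed binary mappings (or Series); only
    chemicals present in both contribute.
    """
    hits = _as_unique_mapping(hit_calls, "hit_calls")
    labs = _as_unique_mapping(labels, "labels")
    table = np.zeros((2, 2), dtype=int)
    for chem, hit in hits.items():
        lab = labs.get(chem)
        if lab is None:
            continue
        table[1 - hit, 1 - lab] += 1
    return table


def fisher_exact(table: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p_value, degenerate)``.  The odds ratio is the
    sample ratio ``(a*d)/(b*c)``, infinity when ``b*c == 0`` and
    ``a*d > 0``.  A table with any zero margin carries no information: it is
    flagged degenerate and reported as ``(1.0, 1.0, True)``.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative integers")
    (a, b), (c, d) = t
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0, 1.0, True
    _, p = stats.fisher_exact(t, alternative="two-sided")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else 0.0
    else:
        odds = ad / bc
    return float(odds), float(p), False


def bh_select(p_values, fdr: float = DEFAULT_FDR) -> np.ndarray:
    """Benjamini-Hochberg step-up selection flags.

    Sorts ascending, finds the largest rank i with ``p_(i) <= i * fdr / m``,
    selects all hypotheses of rank <= i.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, m + 1) * fdr) / m
    passing = np.nonzero(p[order] <= thresholds)[0]
    selected = np.zeros(m, dtype=bool)
    if passing.size:
        selected[order[: passing[-1] + 1]] = True
    return selected


def endpoint_labels(labels: pd.DataFrame, endpoint: str) -> pd.Series:
    """Binary endpoint labels per chemical, excluding unknowables.

    Nontoxic chemicals count as endpoint-negative.  Hepatotoxicants whose
    mechanism for this endpoint is unrecorded are excluded from this
    endpoint's tables only.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    col = labels[endpoint]
    out = col.where(labels["hepatotoxic"] == 1, other=0)
    return out.dropna().astype(int)


def select_relevant_assays(
    hit_table: pd.DataFrame, labels: pd.DataFrame, fdr: float = DEFAULT_FDR
) -> AssaySelection:
    """Run the full association screen.

    ``hit_table`` is a chem_id x assay_id frame of binary hit calls (NaN =
    untested).  ``labels`` is the frame from :func:`ketox.io.labels_frame`.
    BH control is applied within each endpoint separately; an assay is
    selected for an endpoint when it passes BH and its odds ratio exceeds 1.
    """
    results: list[AssociationResult] = []
    by_endpoint: dict[str, set[str]] = {}
    assay_ids = list(hit_table.columns)
    for endpoint in ENDPOINTS:
        labs = endpoint_labels(labels, endpoint)
        partial: list[AssociationResult] = []
        for assay in assay_ids:
            hits = hit_table[assay].dropna().astype(int)
            tab = contingency(hits, labs)
            odds, p, degenerate = fisher_exact(tab)
            partial.append(
                AssociationResult(
                    assay_id=assay,
                    endpoint=endpoint,
                    table=tab,
                    odds_ratio=odds,
                    p_value=p,
                    degenerate=degenerate,
                )
            )
        flags = bh_select([r.p_value for r in partial], fdr=fdr)
        chosen: set[str] = set()
        for r, flag in zip(partial, flags):
            picked = bool(flag) and not r.degenerate and r.odds_ratio > 1.0
            results.append(
                AssociationResult(
                    assay_id=r.assay_id,
                    endpoint=r.endpoint,
                    table=r.table,
                    odds_ratio=r.odds_ratio,
                    p_value=r.p_value,
                    degenerate=r.degenerate,
                    selected=picked,
                )
            )
            if picked:
                chosen.add(r.assay_id)
        by_endpoint[endpoint] = chosen
    return AssaySelection(results=results, by_endpoint=by_endpoint)


def hit_call_table(fits: Mapping[tuple[str, str], "object"]) -> pd.DataFrame:
    """Pivot best fits into a chem_id x assay_id hit-call frame (NaN = untested)."""
    rows: dict[str, dict[str, int]] = {}
    for (chem, assay), fit in fits.items():
        rows.setdefault(chem, {})[assay] = fit.hit_call
    return pd.DataFrame.from_dict(rows, orient="index").sort_index().sort_index(axis=1)
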