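"""Toxicokinetic overlay: bioavailable ("realized") portion of KE activity.

Steady-state plasma concentration (Css, 95th percentile at 1 mg/kg/day oral
dosing) bounds the concentrations a chemical plausibly reaches in vivo.
The realized KE score integrates the KE curve only over grid concentrations
at or below Css, so activity occurring entirely above systemic exposure
contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ketox.curves import ConcentrationGrid
from ketox.ke_model import ke_score

DEFAULT_UNREALIZABLE_THRESHOLD = 0.05


@dataclass(frozen=True)
class RealizedActivity:
    chem_id: str
    ke_id: str
    css_95: float  # uM
    raw_auc: float
    realized_auc: float

    @property
    def realized_fraction(self) -> float:
        """Share of the raw score within reach of systemic exposure (0 if inert)."""
        if self.raw_auc <= 0:
            return 0.0
        return self.realized_auc / self.raw_auc


def restricted_auc(curve_values: np.ndarray, grid: ConcentrationGrid, css: float) -> float:
    """Trapezoidal AUC of the curve over concentrations <= css.

    Computed in the log10 domain and normalized by the full grid width, so
    the result is directly comparable to the raw KE score.  The cut point is
    linearly interpolated inside the straddling grid segment.
    """
    if css <= 0:
        raise ValueError("css must be positive")
    values = np.asarray(curve_values, dtype=float)
    if values.shape != grid.log10_points.shape:
        raise ValueError("curve length must match the grid")
    x = grid.log10_points
    x_css = np.log10(css)
    if x_css >= x[-1]:
        return ke_score(values, grid)
    if x_css <= x[0]:
        return 0.0
    i = int(np.searchsorted(x, x_css, side="right"))  # segment (i-1, i) straddles the cut
    area = np.trapezoid(values[:i], x=x[:i])
    frac = (x_css - x[i - 1]) / (x[i] - x[i - 1])
    v_cut = values[i - 1] + frac * (values[i] - values[i - 1])
    area += 0.5 * (values[i - 1] + v_cut) * (x_css - x[i - 1])
    return float(area / grid.width)


def realized_ke_score(
    chem_id: str, ke_id: str, curve_values: np.ndarray, grid: ConcentrationGrid, css: float
) -> RealizedActivity:
    """Realized activity of one chemical's KE curve given its Css."""
    raw = ke_score(np.asarray(curve_values, dtype=float), grid)
    realized = restricted_auc(curve_values, grid, css)
    # guard the invariant against quadrature round-off at the cut point
    realized = min(realized, raw)
    return RealizedActivity(chem_id=chem_id, ke_id=ke_id, css_95=css, raw_auc=raw, realized_auc=realized)


def flag_unrealizable(
    activities: Iterable[RealizedActivity],
    threshold: float = DEFAULT_UNREALIZABLE_THRESHOLD,
) -> list[str]:
    """Chemicals whose every active KE is essentially out of bioavailable range.

    A chemical is flagged when it has at least one KE with ``raw_auc > 0``
    and every such KE has ``realized_fraction < threshold``.  Chemicals with
    zero activity everywhere are never flagged (inertness is not a
    toxicokinetic limitation).
    """
    by_chem: dict[str, list[RealizedActivity]] = {}
    for act in activities:
        by_chem.setdefault(act.chem_id, []).append(act)
    flagged = []
    for chem, acts in by_chem.items():
        active = [a for a in acts if a.raw_auc > 0]
        if active and all(a.realized_fraction < threshold for a in active):
            flagged.append(chem)
    return sorted(flagged)


def overlay_table(activities: Sequence[RealizedActivity]) -> pd.DataFrame:
    """Long export: ``chem_id,ke_id,css95_uM,raw_auc,realized_auc,realized_fraction``."""
    return pd.DataFrame(
        {
            "chem_id": [a.chem_id for a in activities],
            "ke_id": [a.ke_id for a in activities],
            "css95_uM": [a.css_95 for a in activities],
            "raw_auc": [a.raw_auc for a in activities],
            "realized_auc": [a.realized_auc for a in activities],
            "realized_fraction": [a.realized_fraction for a in activities],
        }
    )
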