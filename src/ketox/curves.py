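"""Concentration-response curve reconstruction and per-assay normalization.

Curves are evaluated on a shared log10-spaced grid spanning 1 pM to 100 mM
(1e-6 to 1e5 uM, eleven decades).  Each assay's reconstructed responses are
normalized to [0, 1] by the assay-wide maximum so that assays reported in
different native units (percent response, fold change, ...) become
comparable before composition into key-event curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ketox.io import CurveFit

GRID_LOG10_MIN = -6.0  # 1 pM in uM
GRID_LOG10_MAX = 5.0  # 100 mM in uM


@dataclass(frozen=True)
class ConcentrationGrid:
    """Shared log-spaced concentration axis, 1 pM to 100 mM (in uM)."""

    log10_points: np.ndarray

    @property
    def points(self) -> np.ndarray:
        """Concentrations in uM."""
        p = np.power(10.0, self.log10_points)
        # pin the endpoints so grid extremes compare exactly against 1e-6/1e5
        p[0] = float(f"1e{int(round(self.log10_points[0]))}")
        p[-1] = float(f"1e{int(round(self.log10_points[-1]))}")
        return p

    @property
    def width(self) -> float:
        """Total span in log10 units (eleven decades for the default grid)."""
        return float(self.log10_points[-1] - self.log10_points[0])

    def __len__(self) -> int:
        return len(self.log10_points)


def build_grid(points_per_decade: int = 10) -> ConcentrationGrid:
    """Build the shared grid covering eleven decades.

    Length is ``11 * points_per_decade + 1``; log10 spacing is uniform at
    ``1 / points_per_decade``.
    """
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    n = int(round(GRID_LOG10_MAX - GRID_LOG10_MIN)) * points_per_decade + 1
    return ConcentrationGrid(log10_points=np.linspace(GRID_LOG10_MIN, GRID_LOG10_MAX, n))


def hill_response(top: float, slope: float, ac50: float, conc) -> np.ndarray | float:
    """Three-parameter Hill response ``top / (1 + (ac50/conc)**slope)``.

    Monotone nondecreasing in ``conc`` for ``top >= 0``; equals ``top/2`` at
    ``conc == ac50``.  ``conc`` may be a scalar or array of concentrations in
    uM.  Evaluated in log space to avoid overflow for steep slopes at
    concentrations far below AC50.
    """
    if ac50 <= 0:
        raise ValueError("ac50 must be positive")
    if slope <= 0:
        raise ValueError("slope must be positive")
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr <= 0):
        raise ValueError("conc must be positive")
    with np.errstate(over="ignore"):
        ratio = np.power(10.0, slope * (np.log10(ac50) - np.log10(conc_arr)))
        out = top / (1.0 + ratio)
    if np.isscalar(conc) or conc_arr.ndim == 0:
        return float(out)
    return out


def flat_curve(grid: ConcentrationGrid) -> np.ndarray:
    """All-zero response row (no response at any concentration)."""
    return np.zeros(len(grid))


def raw_response_row(fit: Optional[CurveFit], grid: ConcentrationGrid) -> np.ndarray:
    """Evaluate a fit on the grid; missing fits or parameters give a flat curve."""
    if fit is None or not fit.responsive:
        return flat_curve(grid)
    return np.asarray(hill_response(fit.top, fit.slope, fit.ac50, grid.points))


@dataclass
class ResponseSurface:
    """Normalized responses for one assay: chemicals x grid points in [0, 1]."""

    assay_id: str
    chem_ids: list[str]
    grid: ConcentrationGrid
    values: np.ndarray  # shape (n_chem, len(grid))
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {c: i for i, c in enumerate(self.chem_ids)}

    def row(self, chem_id: str) -> np.ndarray:
        """Normalized response row for one chemical; zeros if untested."""
        i = self._index.get(chem_id)
        if i is None:
            return flat_curve(self.grid)
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        """Wide export: chem_id index, columns named by log10 uM."""
        cols = [f"{lg:.3f}" for lg in self.grid.log10_points]
        return pd.DataFrame(self.values, index=pd.Index(self.chem_ids, name="chem_id"), columns=cols)


def normalize_assay(
    assay_id: str, raw_rows: Mapping[str, np.ndarray], grid: ConcentrationGrid
) -> ResponseSurface:
    """Normalize an assay's raw responses to [0, 1].

    Negative raw values are clipped to 0 (conservative zeroing of
    loss-of-signal directions), then every entry is divided by the assay-wide
    maximum.  If the maximum is <= 0 everything is 0, so no-response rows are
    preserved exactly and any positive surface attains 1 somewhere.
    """
    chem_ids = list(raw_rows)
    if chem_ids:
        values = np.clip(np.stack([raw_rows[c] for c in chem_ids]), 0.0, None)
        peak = values.max()
        if peak > 0:
            values = values / peak
    else:
        values = np.zeros((0, len(grid)))
    return ResponseSurface(assay_id=assay_id, chem_ids=chem_ids, grid=grid, values=values)


def build_surfaces(
    fits: Mapping[tuple[str, str], CurveFit],
    grid: ConcentrationGrid,
    chem_ids: Sequence[str],
    assay_ids: Iterable[str],
) -> dict[str, ResponseSurface]:
    """Reconstruct and normalize one ResponseSurface per assay.

    Every chemical in ``chem_ids`` gets a row in every assay; untested or
    no-response chemicals get flat rows, which survive normalization as
    exact zeros.
    """
    surfaces: dict[str, ResponseSurface] = {}
    for assay in assay_ids:
        raw = {c: raw_response_row(fits.get((c, assay)), grid) for c in chem_ids}
        surfaces[assay] = normalize_assay(assay, raw, grid)
    return surfaces
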