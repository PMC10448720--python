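"""Tabular input/output for the pipeline.

All files are plain CSV (RFC-4180, UTF-8, header row required).  Expected
column names:

* curve fits   ``chem_id,assay_id,top,slope,ac50_uM,curve_error,hit_call``
* labels       ``chem_id,hepatotoxic,hepatocellular,hepatobiliary``
* KE map       ``assay_id,ke_id,ke_name``
* Css          ``chem_id,css95_uM``
* structures   ``chem_id,smiles``

Concentrations are carried internally in micromolar.  A unit suffix on the
``ac50``/``css95`` column header (``_pM``, ``_nM``, ``_uM``, ``_mM``, ``_M``)
is honoured and converted once at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: multiplicative factor to micromolar, by column-header unit suffix
_UNIT_TO_UM = {"pM": 1e-6, "nM": 1e-3, "uM": 1.0, "mM": 1e3, "M": 1e6}


class FormatError(ValueError):
    """A file does not conform to the documented CSV contract."""


@dataclass(frozen=True)
class CurveFit:
    """One chemical x assay concentration-response parameter set.

    ``top``/``slope``/``ac50`` of ``None`` mean the chemical showed no
    response in the assay (flat-curve semantics downstream).
    """

    chem_id: str
    assay_id: str
    top: Optional[float]
    slope: Optional[float]
    ac50: Optional[float]  # uM
    curve_error: Optional[float]
    hit_call: int

    @property
    def responsive(self) -> bool:
        """True when all three Hill parameters are present."""
        return self.top is not None and self.slope is not None and self.ac50 is not None


@dataclass(frozen=True)
class HepatotoxLabel:
    chem_id: str
    hepatotoxic: int
    hepatocellular: Optional[int]
    hepatobiliary: Optional[int]


@dataclass(frozen=True)
class KEAssignment:
    assay_id: str
    ke_id: str
    ke_name: str


@dataclass(frozen=True)
class CssRecord:
    chem_id: str
    css_95: float  # uM, 95th-percentile steady-state plasma concentration


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header row")
    _require_columns(df, required, path)
    return df


def _opt_float(raw: str) -> Optional[float]:
    raw = raw.strip()
    if not raw:
        return None
    try:
        value = float(raw)
    except ValueError:
        return None
    if math.isnan(value):
        return None
    return value


def _conc_column(df: pd.DataFrame, prefix: str, path) -> tuple[str, float]:
    """Locate the concentration column ``<prefix>_<unit>`` and its uM factor."""
    for col in df.columns:
        if col == prefix or col.startswith(prefix + "_"):
            suffix = col[len(prefix) + 1 :] if col != prefix else "uM"
            if suffix in _UNIT_TO_UM:
                return col, _UNIT_TO_UM[suffix]
    raise FormatError(f"{path}: missing required column {prefix}_uM (or unit variant)")


def read_curve_fits(path) -> list[CurveFit]:
    """Read a curve-fit summary table.

    Rows whose ``top``/``slope``/``ac50`` cells are blank or unparseable are
    loaded with those parameters absent (no-response semantics) and logged.
    A nonpositive AC50 is likewise demoted to no-response.  An unparseable
    ``hit_call`` is a format error: hit calls are a distinct data channel and
    have no conservative default.
    """
    df = _read_csv(path, ["chem_id", "assay_id", "top", "slope", "curve_error", "hit_call"])
    ac50_col, factor = _conc_column(df, "ac50", path)

    fits: list[CurveFit] = []
    for idx, row in df.iterrows():
        top = _opt_float(row["top"])
        slope = _opt_float(row["slope"])
        ac50 = _opt_float(row[ac50_col])
        if ac50 is not None:
            ac50 *= factor
            if ac50 <= 0:
                logger.warning("%s row %d: nonpositive ac50, treated as no response", path, idx)
                ac50 = None
        if top is None or slope is None or ac50 is None:
            if any(v is not None for v in (top, slope, ac50)):
                logger.warning("%s row %d: incomplete curve parameters, treated as no response", path, idx)
            top = slope = ac50 = None
        try:
            hit = int(float(row["hit_call"]))
        except ValueError:
            raise FormatError(f"{path} row {idx}: unparseable hit_call {row['hit_call']!r}")
        if hit not in (0, 1):
            raise FormatError(f"{path} row {idx}: hit_call must be 0 or 1, got {hit}")
        fits.append(
            CurveFit(
                chem_id=row["chem_id"],
                assay_id=row["assay_id"],
                top=top,
                slope=slope,
                ac50=ac50,
                curve_error=_opt_float(row["curve_error"]),
                hit_call=hit,
            )
        )
    return fits


def write_curve_fits(fits: Iterable[CurveFit], path) -> None:
    df = pd.DataFrame(
        {
            "chem_id": [f.chem_id for f in fits],
            "assay_id": [f.assay_id for f in fits],
            "top": [f.top for f in fits],
            "slope": [f.slope for f in fits],
            "ac50_uM": [f.ac50 for f in fits],
            "curve_error": [f.curve_error for f in fits],
            "hit_call": [f.hit_call for f in fits],
        }
    )
    df.to_csv(path, index=False)


def select_best_fit(fits: Sequence[CurveFit]) -> CurveFit:
    """Pick the single fit with the lowest curve error from a chem x assay group.

    Ties break on smaller AC50, then on input order; a missing curve error
    ranks worst, a missing AC50 ranks after any present one.
    """
    if not fits:
        raise ValueError("select_best_fit: empty group")
    first = fits[0]
    for f in fits[1:]:
        if f.chem_id != first.chem_id or f.assay_id != first.assay_id:
            raise ValueError("select_best_fit: fits must share chem_id and assay_id")

    def key(item: tuple[int, CurveFit]):
        i, f = item
        err = f.curve_error if f.curve_error is not None else math.inf
        ac50 = f.ac50 if f.ac50 is not None else math.inf
        return (err, ac50, i)

    return min(enumerate(fits), key=key)[1]


def best_fits(fits: Iterable[CurveFit]) -> dict[tuple[str, str], CurveFit]:
    """Resolve multiple fits per chemical x assay to the single best fit each."""
    groups: dict[tuple[str, str], list[CurveFit]] = {}
    for f in fits:
        groups.setdefault((f.chem_id, f.assay_id), []).append(f)
    return {k: select_best_fit(v) for k, v in groups.items()}


def _opt_binary(raw: str, path, idx: int, col: str) -> Optional[int]:
    raw = raw.strip()
    if not raw:
        return None
    try:
        v = int(float(raw))
    except ValueError:
        raise FormatError(f"{path} row {idx}: unparseable {col} {raw!r}")
    if v not in (0, 1):
        raise FormatError(f"{path} row {idx}: {col} must be 0 or 1, got {v}")
    return v


def read_labels(path) -> list[HepatotoxLabel]:
    """Read hepatotoxicity labels; mechanism columns may be blank (unknown).

    Enforces the consistency invariant that a hepatocellular or hepatobiliary
    toxicant is a hepatotoxicant.
    """
    df = _read_csv(path, ["chem_id", "hepatotoxic", "hepatocellular", "hepatobiliary"])
    out: list[HepatotoxLabel] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        chem = row["chem_id"]
        if chem in seen:
            raise FormatError(f"{path} row {idx}: duplicate chem_id {chem!r}")
        seen.add(chem)
        tox = _opt_binary(row["hepatotoxic"], path, idx, "hepatotoxic")
        if tox is None:
            raise FormatError(f"{path} row {idx}: hepatotoxic is required")
        hc = _opt_binary(row["hepatocellular"], path, idx, "hepatocellular")
        hb = _opt_binary(row["hepatobiliary"], path, idx, "hepatobiliary")
        if tox == 0 and (hc == 1 or hb == 1):
            raise FormatError(
                f"{path} row {idx}: chemical {chem!r} has a mechanism label but hepatotoxic=0"
            )
        out.append(HepatotoxLabel(chem_id=chem, hepatotoxic=tox, hepatocellular=hc, hepatobiliary=hb))
    return out


def write_labels(labels: Iterable[HepatotoxLabel], path) -> None:
    df = pd.DataFrame(
        {
            "chem_id": [l.chem_id for l in labels],
            "hepatotoxic": [l.hepatotoxic for l in labels],
            "hepatocellular": [l.hepatocellular for l in labels],
            "hepatobiliary": [l.hepatobiliary for l in labels],
        }
    )
    df["hepatocellular"] = df["hepatocellular"].astype("Int64")
    df["hepatobiliary"] = df["hepatobiliary"].astype("Int64")
    df.to_csv(path, index=False)


def read_ke_assignments(path) -> list[KEAssignment]:
    """Read the assay -> key-event map; each assay maps to exactly one KE."""
    df = _read_csv(path, ["assay_id", "ke_id", "ke_name"])
    seen: dict[str, str] = {}
    out: list[KEAssignment] = []
    for idx, row in df.iterrows():
        assay, ke = row["assay_id"], row["ke_id"]
        if assay in seen:
            if seen[assay] != ke:
                raise FormatError(
                    f"{path} row {idx}: assay {assay!r} mapped to both {seen[assay]!r} and {ke!r}"
                )
            continue  # duplicate but consistent: dedupe
        seen[assay] = ke
        out.append(KEAssignment(assay_id=assay, ke_id=ke, ke_name=row["ke_name"]))
    return out


def write_ke_assignments(assignments: Iterable[KEAssignment], path) -> None:
    pd.DataFrame(
        {
            "assay_id": [a.assay_id for a in assignments],
            "ke_id": [a.ke_id for a in assignments],
            "ke_name": [a.ke_name for a in assignments],
        }
    ).to_csv(path, index=False)


def ke_groups(assignments: Iterable[KEAssignment]) -> dict[str, list[str]]:
    """Group assay ids by KE id, preserving input order."""
    groups: dict[str, list[str]] = {}
    for a in assignments:
        groups.setdefault(a.ke_id, []).append(a.assay_id)
    return groups


def read_css(path) -> list[CssRecord]:
    """Read 95th-percentile steady-state plasma concentrations (uM)."""
    df = _read_csv(path, ["chem_id"])
    col, factor = _conc_column(df, "css95", path)
    out: list[CssRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        chem = row["chem_id"]
        if chem in seen:
            raise FormatError(f"{path} row {idx}: duplicate chem_id {chem!r}")
        seen.add(chem)
        css = _opt_float(row[col])
        if css is None or css <= 0:
            raise FormatError(f"{path} row {idx}: chemical {chem!r} has invalid css95 {row[col]!r}")
        out.append(CssRecord(chem_id=chem, css_95=css * factor))
    return out


def write_css(records: Iterable[CssRecord], path) -> None:
    pd.DataFrame(
        {"chem_id": [r.chem_id for r in records], "css95_uM": [r.css_95 for r in records]}
    ).to_csv(path, index=False)


def read_smiles(path) -> dict[str, str]:
    """Read chemical structures as a chem_id -> SMILES mapping."""
    df = _read_csv(path, ["chem_id", "smiles"])
    out: dict[str, str] = {}
    for idx, row in df.iterrows():
        chem = row["chem_id"]
        if chem in out:
            raise FormatError(f"{path} row {idx}: duplicate chem_id {chem!r}")
        out[chem] = row["smiles"]
    return out


def write_smiles(smiles: dict[str, str], path) -> None:
    pd.DataFrame({"chem_id": list(smiles), "smiles": list(smiles.values())}).to_csv(path, index=False)


def labels_frame(labels: Iterable[HepatotoxLabel]) -> pd.DataFrame:
    """Labels as a chem_id-indexed frame with nullable mechanism columns."""
    df = pd.DataFrame(
        {
            "chem_id": [l.chem_id for l in labels],
            "hepatotoxic": [l.hepatotoxic for l in labels],
            "hepatocellular": [l.hepatocellular for l in labels],
            "hepatobiliary": [l.hepatobiliary for l in labels],
        }
    ).set_index("chem_id")
    df["hepatocellular"] = df["hepatocellular"].astype("Int64")
    df["hepatobiliary"] = df["hepatobiliary"].astype("Int64")
    return df
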