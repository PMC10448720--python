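"""Synthetic dataset generation with known ground truth.

Produces the full input bundle the pipeline consumes — curve fits with hit
calls, hepatotoxicity labels, a KE assignment map, Css values and SMILES —
plus machine-readable truth tables (which assays are truly associated with
which endpoint, and which chemicals are "TK-rescued": structurally active
but nontoxic because systemic exposure never reaches their active range).

Generation logic, per chemical x assay:

* a latent toxicant flag drives elevated activation probability in
  endpoint-associated assays (baseline + effect size vs baseline);
* active pairs get Hill parameters (log-uniform AC50, uniform top and
  slope) and hit_call=1; inactive tested pairs get blank parameters and
  hit_call=0; a fraction of pairs is left untested entirely;
* with ``tk_modulation`` on, a random subset of active latent toxicants is
  assigned a Css far below their lowest active AC50 and relabeled
  nontoxic, while remaining active toxicants get Css above their activity
  onset — encoding the contrast between a bioavailable and a
  non-bioavailable chemical with similar in vitro profiles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ketox import io

_SCAFFOLDS = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCOC1", "c1ccc2ccccc2c1", "C1CCNCC1"]
_SUBSTITUENTS = [
    "", "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC", "NCC",
    "Cl", "ClC", "FC", "OC(=O)", "NC(=O)", "S", "SC", "C(C)C", "OCCC",
]


def smiles_library(n: int) -> list[str]:
    """First ``n`` entries of the built-in valid-SMILES library.

    Scaffold x substituent enumeration, padded with alcohol chains; all
    entries parse and are unique.
    """
    lib: list[str] = []
    seen: set[str] = set()
    for sub in _SUBSTITUENTS:
        for scaffold in _SCAFFOLDS:
            smi = sub + scaffold
            if smi not in seen:
                seen.add(smi)
                lib.append(smi)
    k = 1
    while len(lib) < n:
        smi = "C" * k + "O"
        if smi not in seen:
            seen.add(smi)
            lib.append(smi)
        k += 1
    return lib[:n]


@dataclass
class GeneratorConfig:
    n_chemicals: int = 200
    n_assays: int = 40
    n_kes: int = 8
    frac_associated: float = 0.1  # fraction of assays truly endpoint-associated
    effect_size: float = 0.4  # activation probability lift for labeled toxicants
    baseline_hit_rate: float = 0.05
    toxicant_fraction: float = 0.5
    untested_rate: float = 0.1
    p_hepatocellular: float = 0.8
    p_hepatobiliary: float = 0.6
    ac50_log10_range: tuple[float, float] = (-3.0, 2.0)  # uM decades
    top_max: float = 100.0
    slope_range: tuple[float, float] = (0.5, 4.0)
    css_log10_mean: float = 1.0  # log10 uM
    css_log10_sd: float = 1.0
    tk_modulation: bool = False
    tk_rescue_fraction: float = 0.3
    extra_fit_rate: float = 0.5  # chance of inferior duplicate fits per tested pair
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chemicals", "n_assays", "n_kes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "frac_associated", "baseline_hit_rate", "toxicant_fraction", "untested_rate",
            "p_hepatocellular", "p_hepatobiliary", "tk_rescue_fraction", "extra_fit_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.effect_size <= 1.0 - self.baseline_hit_rate:
            raise ValueError("effect_size must keep activation probability in [0, 1]")
        if self.n_kes > self.n_assays:
            raise ValueError("n_kes cannot exceed n_assays")


@dataclass
class DatasetBundle:
    """Generated inputs plus the ground truth used to score recovery."""

    config: GeneratorConfig
    curve_fits: list[io.CurveFit]
    labels: list[io.HepatotoxLabel]
    ke_assignments: list[io.KEAssignment]
    css: list[io.CssRecord]
    smiles: dict[str, str]
    truth: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "curve_fits": out_dir / "curve_fits.csv",
            "labels": out_dir / "labels.csv",
            "ke_map": out_dir / "ke_map.csv",
            "css": out_dir / "css.csv",
            "smiles": out_dir / "smiles.csv",
            "truth": out_dir / "truth.json",
        }
        io.write_curve_fits(self.curve_fits, paths["curve_fits"])
        io.write_labels(self.labels, paths["labels"])
        io.write_ke_assignments(self.ke_assignments, paths["ke_map"])
        io.write_css(self.css, paths["css"])
        io.write_smiles(self.smiles, paths["smiles"])
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return paths


def generate(config: GeneratorConfig) -> DatasetBundle:
    """Generate a full dataset bundle; byte-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    chem_ids = [f"C{i + 1:05d}" for i in range(config.n_chemicals)]
    assay_ids = [f"A{i + 1:04d}" for i in range(config.n_assays)]
    ke_ids = [f"KE{i + 1:03d}" for i in range(config.n_kes)]

    # round-robin assay -> KE assignment: deterministic, gives multi-assay KEs
    assignments = [
        io.KEAssignment(assay_id=a, ke_id=ke_ids[i % config.n_kes], ke_name=f"key event {i % config.n_kes + 1}")
        for i, a in enumerate(assay_ids)
    ]

    # truly associated assays, each tagged to one or both endpoints
    n_assoc = int(round(config.frac_associated * config.n_assays))
    assoc_assays = sorted(rng.choice(assay_ids, size=n_assoc, replace=False).tolist())
    endpoint_of: dict[str, list[str]] = {}
    for a in assoc_assays:
        tag = rng.choice(["hepatocellular", "hepatobiliary", "both"], p=[0.4, 0.4, 0.2])
        endpoint_of[a] = ["hepatocellular", "hepatobiliary"] if tag == "both" else [str(tag)]

    latent_toxic = rng.random(config.n_chemicals) < config.toxicant_fraction
    hepatocellular = np.zeros(config.n_chemicals, dtype=int)
    hepatobiliary = np.zeros(config.n_chemicals, dtype=int)
    for i in range(config.n_chemicals):
        if latent_toxic[i]:
            hc = rng.random() < config.p_hepatocellular
            hb = rng.random() < config.p_hepatobiliary
            if not hc and not hb:
                hc = True
            hepatocellular[i], hepatobiliary[i] = int(hc), int(hb)

    mech = {"hepatocellular": hepatocellular, "hepatobiliary": hepatobiliary}
    fits: list[io.CurveFit] = []
    active_ac50: dict[str, list[float]] = {c: [] for c in chem_ids}
    lo, hi = config.ac50_log10_range
    for ci, chem in enumerate(chem_ids):
        for assay in assay_ids:
            if rng.random() < config.untested_rate:
                continue
            p = config.baseline_hit_rate
            if assay in endpoint_of and any(mech[e][ci] for e in endpoint_of[assay]):
                p += config.effect_size
            active = rng.random() < p
            if active:
                ac50 = float(10.0 ** rng.uniform(lo, hi))
                top = float(rng.uniform(0.05, 1.0) * config.top_max)
                slope = float(rng.uniform(*config.slope_range))
                err = float(rng.uniform(0.02, 0.2))
                fits.append(io.CurveFit(chem, assay, top, slope, ac50, err, 1))
                active_ac50[chem].append(ac50)
                # inferior duplicate fits exercise best-fit resolution downstream
                if rng.random() < config.extra_fit_rate:
                    for _ in range(int(rng.integers(1, 3))):
                        fits.append(
                            io.CurveFit(
                                chem,
                                assay,
                                top * float(rng.uniform(0.5, 1.5)),
                                float(np.clip(slope * rng.uniform(0.5, 1.5), 0.1, 10.0)),
                                float(ac50 * 10.0 ** rng.uniform(-0.5, 0.5)),
                                err + float(rng.uniform(0.05, 0.8)),
                                1,
                            )
                        )
            else:
                fits.append(io.CurveFit(chem, assay, None, None, None, float(rng.uniform(0.2, 1.0)), 0))

    css_log10 = rng.normal(config.css_log10_mean, config.css_log10_sd, size=config.n_chemicals)
    css_values = {c: float(10.0 ** lg) for c, lg in zip(chem_ids, css_log10)}

    final_toxic = latent_toxic.copy()
    rescued: list[str] = []
    if config.tk_modulation:
        candidates = [
            (i, c) for i, c in enumerate(chem_ids) if latent_toxic[i] and active_ac50[c]
        ]
        n_rescue = int(round(config.tk_rescue_fraction * len(candidates)))
        order = rng.permutation(len(candidates))
        for j in order[:n_rescue]:
            i, chem = candidates[j]
            onset = min(active_ac50[chem])
            # exposure far below the lowest active AC50: activity unreachable
            css_values[chem] = float(min(css_values[chem], onset * 10.0 ** (-rng.uniform(1.5, 3.0))))
            final_toxic[i] = False
            hepatocellular[i] = hepatobiliary[i] = 0
            rescued.append(chem)
        rescued_set = set(rescued)
        for i, chem in candidates:
            if chem not in rescued_set:
                # bioavailable toxicants stay at (at least) their onset concentration
                onset = min(active_ac50[chem])
                css_values[chem] = float(max(css_values[chem], onset * 10.0 ** rng.uniform(0.5, 1.0)))
        rescued.sort()

    labels = [
        io.HepatotoxLabel(
            chem_id=c,
            hepatotoxic=int(final_toxic[i]),
            hepatocellular=int(hepatocellular[i]) if final_toxic[i] else 0,
            hepatobiliary=int(hepatobiliary[i]) if final_toxic[i] else 0,
        )
        for i, c in enumerate(chem_ids)
    ]
    css = [io.CssRecord(chem_id=c, css_95=css_values[c]) for c in chem_ids]
    smiles = dict(zip(chem_ids, smiles_library(config.n_chemicals)))

    truth = {
        "associated_assays": assoc_assays,
        "associated_endpoints": endpoint_of,
        "tk_rescued": rescued,
        "latent_toxicants": [c for i, c in enumerate(chem_ids) if latent_toxic[i]],
        "config": asdict(config),
    }
    return DatasetBundle(
        config=config,
        curve_fits=fits,
        labels=labels,
        ke_assignments=assignments,
        css=css,
        smiles=smiles,
        truth=truth,
    )


def ground_truth(bundle: DatasetBundle) -> dict:
    """Machine-readable truth tables for recovery scoring."""
    return bundle.truth


def recovery_score(selected: set[str], truth: dict) -> dict:
    """Sensitivity and empirical FDR of an assay selection against the truth."""
    true_set = set(truth["associated_assays"])
    tp = len(selected & true_set)
    sensitivity = tp / len(true_set) if true_set else float("nan")
    fdr = (len(selected) - tp) / len(selected) if selected else 0.0
    return {"sensitivity": sensitivity, "fdr": fdr, "n_selected": len(selected), "n_true": len(true_set)}
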