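"""Structure handling: fingerprints, Tanimoto similarity, Butina clustering,
hepatotoxicant-enriched cluster detection, and Lipinski-type descriptors.

Fingerprints are 2048-bit circular (radius 2, ECFP4-equivalent) Morgan bit
vectors.  Clustering follows the classic sphere-exclusion scheme: neighbor
lists at the similarity cutoff (Tanimoto >= cutoff, default 0.70), then
iteratively the unassigned chemical with the most unassigned neighbors
becomes a centroid and claims them; ties break on the lexicographically
smallest chem_id so the partition is deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit.DataStructs import ExplicitBitVect, TanimotoSimilarity

DEFAULT_SIMILARITY_CUTOFF = 0.70
ENRICHMENT_FRACTION = 2.0 / 3.0

_FP_GENERATORS: dict[tuple[int, int], object] = {}


class StructureError(ValueError):
    """A SMILES string could not be parsed into a molecule."""


def _mol_from_smiles(smiles: str, chem_id: Optional[str] = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for chemical {chem_id!r}" if chem_id else ""
        raise StructureError(f"unparseable SMILES{who}: {smiles!r}")
    return mol


def fingerprint(smiles: str, chem_id: Optional[str] = None, n_bits: int = 2048, radius: int = 2) -> ExplicitBitVect:
    """Circular substructure fingerprint; identical molecules give identical bits."""
    key = (n_bits, radius)
    gen = _FP_GENERATORS.get(key)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        _FP_GENERATORS[key] = gen
    return gen.GetFingerprint(_mol_from_smiles(smiles, chem_id))


def tanimoto(a: ExplicitBitVect, b: ExplicitBitVect) -> float:
    """Intersection-over-union of fingerprint bits; 1.0 when both are empty."""
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 1.0
    return float(TanimotoSimilarity(a, b))


@dataclass
class ClusterAssignment:
    cluster_id: int
    centroid: str
    members: list[str]  # sorted chem_ids, centroid included


def butina_cluster(
    fingerprints: Mapping[str, ExplicitBitVect],
    similarity_cutoff: float = DEFAULT_SIMILARITY_CUTOFF,
) -> list[ClusterAssignment]:
    """Sphere-exclusion clustering over a Tanimoto cutoff.

    Returns a partition of the input chemicals; singletons are allowed.
    Neighborhoods are closed (each chemical neighbors itself) and membership
    uses ``tanimoto >= similarity_cutoff``, so every member of a cluster has
    similarity at least the cutoff to its centroid.
    """
    if not fingerprints:
        raise ValueError("butina_cluster: need at least one fingerprint")
    ids = sorted(fingerprints)
    neighbors: dict[str, set[str]] = {}
    for i, a in enumerate(ids):
        neighbors.setdefault(a, set()).add(a)
        for b in ids[i + 1 :]:
            if tanimoto(fingerprints[a], fingerprints[b]) >= similarity_cutoff:
                neighbors[a].add(b)
                neighbors.setdefault(b, set()).add(b)
                neighbors[b].add(a)
    unassigned = set(ids)
    clusters: list[ClusterAssignment] = []
    while unassigned:
        centroid = min(unassigned, key=lambda c: (-len(neighbors[c] & unassigned), c))
        members = sorted(neighbors[centroid] & unassigned)
        clusters.append(ClusterAssignment(cluster_id=len(clusters), centroid=centroid, members=members))
        unassigned.difference_update(members)
    return clusters


def enriched_clusters(
    clusters: Iterable[ClusterAssignment],
    labels: pd.DataFrame,
    scaled_scores: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-cluster hepatotoxicant enrichment with optional mean KE scores.

    ``hepatotoxicant_fraction`` is computed over cluster members that have a
    liver label; a cluster is ``enriched`` when that fraction strictly
    exceeds 2/3.  Clusters with no labeled member get a NaN fraction and are
    not enriched.  When ``scaled_scores`` (chem_id x ke_id) is given, each
    KE's mean scaled score over cluster members is attached (untested
    members count as zero, mirroring heat-map semantics of inactivity).
    """
    hepatotoxic = labels["hepatotoxic"]
    rows = []
    for cl in clusters:
        labeled = [c for c in cl.members if c in hepatotoxic.index]
        n_labeled = len(labeled)
        if n_labeled:
            fraction = float(hepatotoxic.loc[labeled].astype(int).mean())
            enriched = fraction > ENRICHMENT_FRACTION
        else:
            fraction = float("nan")
            enriched = False
        row = {
            "cluster_id": cl.cluster_id,
            "centroid": cl.centroid,
            "n_members": len(cl.members),
            "n_with_liver_data": n_labeled,
            "hepatotoxicant_fraction": fraction,
            "enriched": enriched,
        }
        if scaled_scores is not None and not scaled_scores.empty:
            member_scores = scaled_scores.reindex(cl.members).fillna(0.0)
            for ke_id in scaled_scores.columns:
                row[f"mean_score_{ke_id}"] = float(member_scores[ke_id].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_members_table(clusters: Iterable[ClusterAssignment], enrichment: pd.DataFrame) -> pd.DataFrame:
    """Long export: ``cluster_id,chem_id,centroid,hepatotoxicant_fraction,enriched``."""
    enr = enrichment.set_index("cluster_id")
    rows = []
    for cl in clusters:
        for chem in cl.members:
            rows.append(
                {
                    "cluster_id": cl.cluster_id,
                    "chem_id": chem,
                    "centroid": cl.centroid,
                    "hepatotoxicant_fraction": enr.loc[cl.cluster_id, "hepatotoxicant_fraction"],
                    "enriched": int(bool(enr.loc[cl.cluster_id, "enriched"])),
                }
            )
    return pd.DataFrame(rows, columns=["cluster_id", "chem_id", "centroid", "hepatotoxicant_fraction", "enriched"])


@dataclass(frozen=True)
class LipinskiDescriptors:
    """Oral-bioavailability-related descriptors of one structure."""

    chem_id: str
    mol_weight: float
    log_p: float
    h_donors: int
    h_acceptors: int
    rotatable_bonds: int
    ring_count: int
    heavy_atoms: int


def lipinski_descriptors(smiles: str, chem_id: str = "") -> LipinskiDescriptors:
    """Deterministic descriptor vector from the canonicalized structure."""
    mol = _mol_from_smiles(smiles, chem_id)
    return LipinskiDescriptors(
        chem_id=chem_id,
        mol_weight=float(Descriptors.MolWt(mol)),
        log_p=float(Crippen.MolLogP(mol)),
        h_donors=int(Lipinski.NumHDonors(mol)),
        h_acceptors=int(Lipinski.NumHAcceptors(mol)),
        rotatable_bonds=int(Lipinski.NumRotatableBonds(mol)),
        ring_count=int(Lipinski.RingCount(mol)),
        heavy_atoms=int(mol.GetNumHeavyAtoms()),
    )


def descriptor_table(smiles_by_chem: Mapping[str, str]) -> pd.DataFrame:
    """One descriptor row per chemical, indexed by chem_id."""
    rows = [lipinski_descriptors(smi, chem) for chem, smi in smiles_by_chem.items()]
    return pd.DataFrame(
        {
            "chem_id": [r.chem_id for r in rows],
            "mol_weight": [r.mol_weight for r in rows],
            "log_p": [r.log_p for r in rows],
            "h_donors": [r.h_donors for r in rows],
            "h_acceptors": [r.h_acceptors for r in rows],
            "rotatable_bonds": [r.rotatable_bonds for r in rows],
            "ring_count": [r.ring_count for r in rows],
            "heavy_atoms": [r.heavy_atoms for r in rows],
        }
    ).set_index("chem_id")
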