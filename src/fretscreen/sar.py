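"""Structure-activity clustering of screened compounds.

Compounds are binary fingerprints compared by Tanimoto dissimilarity.
Cluster representatives are chosen from the ACTIVE compounds (normalized ER
calcium response < 0.9) by OptiSim — iterative dissimilarity-based selection
with a bounded random subsample per round — then every compound is assigned
to its nearest representative (inactives only within an assignment radius),
near-duplicate representatives are merged single-link, and each cluster is
annotated: a "star" cluster has > 50% active members, and is "highlighted"
if it additionally holds more than four actives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FingerprintSet",
    "CompoundCluster",
    "tanimoto_dissimilarity",
    "dissimilarity_matrix",
    "optisim_select",
    "cluster_compounds",
    "annotate_clusters",
    "fingerprints_from_smiles",
]

DEFAULT_SUBSAMPLE_K = 10
DEFAULT_RADIUS = 0.4
ACTIVITY_CUTOFF = 0.9


@dataclass
class FingerprintSet:
    """Compound ids, a (compounds x bits) binary matrix and activity flags."""

    compound_ids: list
    fingerprints: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        fps = np.asarray(self.fingerprints)
        if fps.ndim != 2 or not np.isin(fps, (0, 1)).all():
            raise ValueError("fingerprints must be a binary matrix")
        if np.any(fps.sum(axis=1) == 0):
            raise ValueError("every compound needs at least one set bit")
        if len(self.compound_ids) != fps.shape[0]:
            raise ValueError("compound_ids and fingerprint rows differ")
        self.fingerprints = fps.astype(np.uint8)
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != (fps.shape[0],):
            raise ValueError("activity flags must match compound count")

    @classmethod
    def from_scores(cls, compound_ids, fingerprints, normalized_responses,
                    cutoff: float = ACTIVITY_CUTOFF) -> "FingerprintSet":
        scores = np.asarray(normalized_responses, dtype=float)
        return cls(list(compound_ids), fingerprints, scores < cutoff)

    def canonical_order(self) -> "FingerprintSet":
        """Sorted by compound_id, the ordering under which selection is
        defined (makes clustering invariant to input permutation)."""
        order = np.argsort(np.asarray(self.compound_ids, dtype=object))
        return FingerprintSet(
            [self.compound_ids[i] for i in order],
            self.fingerprints[order],
            self.active[order],
        )


@dataclass
class CompoundCluster:
    cluster_id: int
    representative: str
    members: list = field(default_factory=list)
    n_active: int = 0

    @property
    def n_total(self) -> int:
        return len(self.members)

    @property
    def star(self) -> bool:
        return self.n_total > 0 and self.n_active / self.n_total > 0.5

    @property
    def highlighted(self) -> bool:
        return self.star and self.n_active > 4


def tanimoto_dissimilarity(fp_a, fp_b) -> float:
    """1 − |a ∧ b| / |a ∨ b| for binary fingerprints of equal length."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal bit-length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    return 1.0 - np.logical_and(a, b).sum() / union


def dissimilarity_matrix(fingerprints) -> np.ndarray:
    """All-pairs Tanimoto dissimilarity (compounds x compounds)."""
    fps = np.asarray(fingerprints, dtype=float)
    inter = fps @ fps.T
    counts = fps.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore"):
        d = 1.0 - inter / union
    return np.nan_to_num(d, nan=0.0)


def optisim_select(
    fingerprints,
    subsample_k: int = DEFAULT_SUBSAMPLE_K,
    radius_r: float = DEFAULT_RADIUS,
    seed: int = 0,
) -> list:
    """OptiSim representative selection; returns indices in selection order.

    Each round, compounds farther than ``radius_r`` from every selected
    compound are eligible; a random subsample of at most ``subsample_k``
    eligible compounds is drawn (the first ``k`` positions of a seeded
    permutation of the eligible list in input order) and the candidate with
    the greatest minimum dissimilarity to the selected set joins it (lowest
    input index on ties; the very first pick is the first subsample entry).
    Rounds repeat until nothing is eligible.
    """
    fps = np.asarray(fingerprints)
    n = fps.shape[0]
    if n == 0:
        return []
    if subsample_k < 1:
        raise ValueError("subsample_k must be >= 1")
    if not 0.0 <= radius_r <= 1.0:
        raise ValueError("radius_r must be in [0, 1]")
    d = dissimilarity_matrix(fps)
    rng = np.random.default_rng(seed)
    selected: list = []
    min_d = np.full(n, np.inf)
    while True:
        eligible = np.flatnonzero(min_d > radius_r)
        eligible = eligible[~np.isin(eligible, selected)] if selected else eligible
        if len(eligible) == 0:
            break
        perm = rng.permutation(len(eligible))
        sub = eligible[perm[: min(subsample_k, len(eligible))]]
        if not selected:
            pick = int(sub[0])
        else:
            scores = min_d[sub]
            best = np.max(scores)
            pick = int(sub[scores == best].min())
        selected.append(pick)
        min_d = np.minimum(min_d, d[:, pick])
    return selected


def _merge_representatives(rep_indices, d, merge_radius) -> list:
    """Single-link components among representatives within merge_radius."""
    groups = [{i} for i in range(len(rep_indices))]
    merged = True
    while merged:
        merged = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(
                    d[rep_indices[i], rep_indices[j]] <= merge_radius
                    for i in groups[a]
                    for j in groups[b]
                ):
                    groups[a] |= groups[b]
                    del groups[b]
                    merged = True
                    break
            if merged:
                break
    return groups


def cluster_compounds(
    fpset: FingerprintSet,
    subsample_k: int = DEFAULT_SUBSAMPLE_K,
    radius_r: float = DEFAULT_RADIUS,
    assignment_radius: float | None = None,
    merge_radius: float | None = None,
    seed: int = 0,
) -> tuple:
    """Full SAR clustering; returns ``(clusters, unclustered_ids)``.

    1. OptiSim representatives are selected among active compounds;
    2. every active joins its nearest representative;
    3. every inactive joins its nearest representative if within
       ``assignment_radius``, else the unclustered pool;
    4. clusters whose representatives sit within ``merge_radius`` of each
       other merge (single link). Both radii default to ``radius_r``.
    """
    assignment_radius = radius_r if assignment_radius is None else assignment_radius
    merge_radius = radius_r if merge_radius is None else merge_radius
    fpset = fpset.canonical_order()
    ids = fpset.compound_ids
    active_idx = np.flatnonzero(fpset.active)
    if len(active_idx) == 0:
        return [], list(ids)

    reps_local = optisim_select(
        fpset.fingerprints[active_idx], subsample_k, radius_r, seed
    )
    reps = [int(active_idx[i]) for i in reps_local]
    d = dissimilarity_matrix(fpset.fingerprints)

    assignment: dict = {}
    unclustered: list = []
    d_to_reps = d[:, reps]                      # (n, n_reps)
    for i in range(len(ids)):
        nearest = int(np.argmin(d_to_reps[i]))
        if fpset.active[i]:
            assignment[i] = nearest
        elif d_to_reps[i, nearest] <= assignment_radius:
            assignment[i] = nearest
        else:
            unclustered.append(ids[i])

    groups = _merge_representatives(reps, d, merge_radius)
    clusters = []
    for cid, group in enumerate(sorted(groups, key=min), start=1):
        rep_first = reps[min(group)]
        members = [i for i, r in assignment.items() if r in group]
        clusters.append(
            CompoundCluster(
                cluster_id=cid,
                representative=ids[rep_first],
                members=[ids[i] for i in sorted(members)],
                n_active=int(fpset.active[sorted(members)].sum()),
            )
        )
    return clusters, unclustered


def annotate_clusters(clusters) -> pd.DataFrame:
    """Annotation table with the star/highlight activity rules."""
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "representative": c.representative,
                "n_total": c.n_total,
                "n_active": c.n_active,
                "active_fraction": c.n_active / c.n_total if c.n_total else 0.0,
                "star": c.star,
                "highlighted": c.highlighted,
            }
            for c in clusters
        ],
        columns=[
            "cluster_id",
            "representative",
            "n_total",
            "n_active",
            "active_fraction",
            "star",
            "highlighted",
        ],
    )


def fingerprints_from_smiles(smiles_list, n_bits: int = 1024) -> np.ndarray:
    """Optional convenience: Morgan fingerprints from SMILES via RDKit.
    The core clustering never requires this path."""
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "fingerprints_from_smiles needs the optional rdkit dependency"
        ) from exc
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fps = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        fps.append(np.array(gen.GetFingerprint(mol), dtype=np.uint8))
    return np.vstack(fps)
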