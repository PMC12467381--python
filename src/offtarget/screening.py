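"""Latent-space off-target screening.

Per-entity model embeddings (the projection-stack outputs) are projected to
two dimensions with a neighbour-graph manifold method (UMAP; small inputs
fall back to a principal-axes projection), and compound-target interaction
strength is read off as the Euclidean distance between projected points —
smaller distance, stronger predicted interaction.  Targets are ranked per
compound, compared against a randomly sampled control proteome with a
one-sided Welch t-test, and aggregated by organ group over repeated
projections.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import InteractionModel

__all__ = [
    "LatentEmbedding",
    "ProjectedPoint",
    "InteractionScore",
    "OrganAggregate",
    "extract_entity_embeddings",
    "manifold_project_2d",
    "interaction_distance",
    "rank_targets",
    "sample_control_proteins",
    "compare_to_controls",
    "aggregate_by_organ",
]

ENTITY_KINDS = ("compound", "ae_target", "control_protein")

# Below this many points the neighbour-graph embedding is unreliable and the
# projection falls back to centred principal axes.
MIN_POINTS_FOR_UMAP = 30


@dataclasses.dataclass
class LatentEmbedding:
    entity_id: str
    entity_kind: str
    vector: np.ndarray

    def __post_init__(self):
        if self.entity_kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {self.entity_kind!r}")
        self.vector = np.asarray(self.vector, float)
        if not np.isfinite(self.vector).all():
            raise ValueError(f"non-finite latent vector for {self.entity_id!r}")


@dataclasses.dataclass
class ProjectedPoint:
    entity_id: str
    x: float
    y: float
    projection_seed: int
    entity_kind: str = "compound"


@dataclasses.dataclass
class InteractionScore:
    compound_id: str
    target_id: str
    distance: float
    rank: int


@dataclasses.dataclass
class OrganAggregate:
    compound_id: str
    target_id: str
    organ_group: str
    mean_distance: float
    se_distance: float
    n_repetitions: int


def extract_entity_embeddings(
    model: InteractionModel,
    compounds: Mapping[str, np.ndarray],
    proteins: Mapping[str, np.ndarray],
    protein_kinds: Mapping[str, str] | None = None,
) -> list[LatentEmbedding]:
    """Latent (projection-stack output) vectors for every entity.

    ``compounds`` maps compound_id -> fingerprint; ``proteins`` maps
    protein_id -> raw embedding.  ``protein_kinds`` optionally labels each
    protein as "ae_target" or "control_protein" (default "ae_target").
    """
    out: list[LatentEmbedding] = []
    if compounds:
        ids = sorted(compounds)
        L = model.project_compound(np.stack([compounds[i] for i in ids]))
        out.extend(
            LatentEmbedding(i, "compound", v) for i, v in zip(ids, L)
        )
    if proteins:
        ids = sorted(proteins)
        L = model.project_target(np.stack([proteins[i] for i in ids]))
        for i, v in zip(ids, L):
            kind = protein_kinds.get(i, "ae_target") if protein_kinds else "ae_target"
            out.append(LatentEmbedding(i, kind, v))
    return out


def _principal_axes_2d(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    axes = Vt[:2]
    # sign convention: largest-magnitude loading of each axis is positive
    for i in range(axes.shape[0]):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    Y = Xc @ axes.T
    if Y.shape[1] < 2:  # rank-deficient or 1-D input
        Y = np.hstack([Y, np.zeros((Y.shape[0], 2 - Y.shape[1]))])
    return Y


def manifold_project_2d(
    embeddings: Sequence[LatentEmbedding],
    seed: int,
    n_neighbors: int = 100,
    min_dist: float = 0.1,
) -> list[ProjectedPoint]:
    """Project latent vectors to 2-D, preserving local and global structure.

    Uses the UMAP neighbour-graph embedding with a fixed random state.  The
    default neighbourhood is deliberately large (100): the screening stage
    reads *inter-cluster* distances out of this plane, and small
    neighbourhoods are known to scramble the global arrangement of clusters;
    a wide neighbourhood makes the embedding honour global geometry, which
    is the property the distance comparison relies on.  With fewer than
    ``MIN_POINTS_FOR_UMAP`` points it falls back to centred principal axes
    (deterministic, seed-independent coordinates, still recorded under the
    given seed).  Same inputs + seed give identical coordinates.
    """
    if len(embeddings) < 2:
        raise ValueError("need at least 2 points to project")
    X = np.stack([e.vector for e in embeddings])
    if len(embeddings) < MIN_POINTS_FOR_UMAP:
        Y = _principal_axes_2d(X)
    else:
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_components=2,
                n_neighbors=min(n_neighbors, len(embeddings) - 1),
                min_dist=min_dist,
                random_state=int(seed) % (2**31 - 1),
            )
            Y = reducer.fit_transform(X)
    Y = np.asarray(Y, float)
    if not np.isfinite(Y).all():
        raise RuntimeError("projection produced non-finite coordinates")
    return [
        ProjectedPoint(e.entity_id, float(x), float(y), int(seed), e.entity_kind)
        for e, (x, y) in zip(embeddings, Y)
    ]


def interaction_distance(a: ProjectedPoint, b: ProjectedPoint) -> float:
    """Euclidean distance between two points of the same projection run."""
    if a.projection_seed != b.projection_seed:
        raise ValueError(
            f"points come from different projection runs "
            f"({a.projection_seed} vs {b.projection_seed}); distances across "
            f"runs are meaningless"
        )
    return float(np.hypot(a.x - b.x, a.y - b.y))


def rank_targets(
    compound: ProjectedPoint, targets: Sequence[ProjectedPoint]
) -> list[InteractionScore]:
    """Rank targets by ascending distance to the compound (rank 1 closest).

    Ties are broken by entity_id lexicographic order, so the ranking is a
    deterministic permutation of 1..N.
    """
    if not targets:
        raise ValueError("empty target list")
    scored = sorted(
        ((interaction_distance(compound, t), t.entity_id) for t in targets),
    )
    return [
        InteractionScore(compound.entity_id, tid, dist, rank)
        for rank, (dist, tid) in enumerate(scored, start=1)
    ]


def sample_control_proteins(
    proteome_ids: Sequence[str],
    exclude: Iterable[str],
    n: int,
    seed: int,
) -> list[str]:
    """Sample ``n`` control proteins uniformly, excluding AE-dataset accessions.

    Exclusion matches the base accession, so isoform suffixes ("P00742-2")
    are removed whenever "P00742" is excluded.
    """
    excluded_bases = {str(e).split("-")[0] for e in exclude}
    eligible = sorted(
        pid for pid in set(proteome_ids) if str(pid).split("-")[0] not in excluded_bases
    )
    if len(eligible) < n:
        raise ValueError(
            f"control pool has {len(eligible)} eligible proteins, {n} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(chosen)]


def compare_to_controls(
    compound_id: str,
    ae_distances: Sequence[float],
    control_distances: Sequence[float],
) -> tuple[float, float]:
    """One-sided Welch t-test of H1: AE-target distances < control distances.

    A small p-value means the compound sits significantly closer to the
    adverse-effect-associated targets than to the control proteome.
    """
    ae = np.asarray(ae_distances, float)
    ctl = np.asarray(control_distances, float)
    if len(ae) < 2 or len(ctl) < 2:
        raise ValueError("both distance lists need length >= 2")
    if ae.var() == 0 and ctl.var() == 0:
        if ae.mean() == ctl.mean():
            return 0.0, 0.5
        return (-np.inf, 0.0) if ae.mean() < ctl.mean() else (np.inf, 1.0)
    res = stats.ttest_ind(ae, ctl, equal_var=False, alternative="less")
    return float(res.statistic), float(res.pvalue)


def aggregate_by_organ(
    embeddings: Sequence[LatentEmbedding],
    organ_map: Mapping[str, Sequence[str]],
    n_repetitions: int = 5,
    master_seed: int = 0,
) -> list[OrganAggregate]:
    """Mean and standard error of distances over repeated 2-D projections.

    The stochastic stage is the projection, so repetition r re-projects with
    seed ``master_seed + r`` and re-measures every compound-target distance;
    per (compound, target) the mean and SE = sd/sqrt(n) are reported once per
    organ group of the target (a target annotated "Lung/Heart" contributes to
    both groups).  Targets absent from ``organ_map`` go to "unmapped" with a
    warning.
    """
    if n_repetitions < 2:
        raise ValueError("n_repetitions must be >= 2 for a defined standard error")
    compounds = [e for e in embeddings if e.entity_kind == "compound"]
    targets = [e for e in embeddings if e.entity_kind == "ae_target"]
    dists: dict[tuple[str, str], list[float]] = {
        (c.entity_id, t.entity_id): [] for c in compounds for t in targets
    }
    for r in range(n_repetitions):
        pts = manifold_project_2d(embeddings, seed=master_seed + r)
        by_id = {p.entity_id: p for p in pts}
        for c in compounds:
            for t in targets:
                dists[(c.entity_id, t.entity_id)].append(
                    interaction_distance(by_id[c.entity_id], by_id[t.entity_id])
                )
    out: list[OrganAggregate] = []
    warned: set[str] = set()
    for (cid, tid), values in sorted(dists.items()):
        groups = organ_map.get(tid)
        if not groups:
            if tid not in warned:
                warnings.warn(f"target {tid!r} missing from organ map; using 'unmapped'")
                warned.add(tid)
            groups = ["unmapped"]
        arr = np.asarray(values)
        mean = float(arr.mean())
        se = float(arr.std(ddof=1) / np.sqrt(len(arr)))
        for g in groups:
            out.append(OrganAggregate(cid, tid, g, mean, se, n_repetitions))
    return out


def scores_to_frame(scores: Sequence[InteractionScore], projection_seed: int,
                    kinds: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Tabulate a screen as the standard output CSV columns."""
    return pd.DataFrame(
        {
            "compound_id": [s.compound_id for s in scores],
            "target_id": [s.target_id for s in scores],
            "entity_kind": [
                (kinds or {}).get(s.target_id, "ae_target") for s in scores
            ],
            "distance": [s.distance for s in scores],
            "rank": [s.rank for s in scores],
            "projection_seed": projection_seed,
        }
    )
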