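"""Pre-training on labelled interaction pairs and contrastive fine-tuning.

The model is first pre-trained by minimising sigmoid-BCE over shuffled
mini-batches of (compound, target, label) pairs.  It is then fine-tuned with
a triplet objective: every positive pair becomes an anchor (target) and
positive (compound), contrasted against ``n_decoys`` compounds sampled
uniformly from the pool, excluding the active compound and anything
positively paired with that target.  Decoys are re-sampled every epoch from
an epoch-derived seed, acting as a fresh negative-sample augmentation; a
loss-mix weight lambda blends the triplet term with BCE on the same
anchor/positive/decoy pairs.  Everything is deterministic under one master
seed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import InteractionModel

__all__ = [
    "InteractionDataset",
    "DecoySet",
    "TrainingConfig",
    "AdamOptimizer",
    "pretrain",
    "sample_decoys",
    "contrastive_finetune",
    "train_validation_split",
    "read_pair_table",
    "write_pair_table",
]


@dataclasses.dataclass
class TrainingConfig:
    """Hyper-parameters for both training phases."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    margin: float = 1.0
    n_decoys: int = 50
    loss_mix: float = 0.5  # lambda: weight of the triplet term during fine-tuning
    finetune_epochs: int = 10
    # fine-tuning nudges an already-converged model, so it runs at a tenth of
    # the pre-training rate by default
    finetune_learning_rate: float = 1e-4
    # symmetric contrastive term: besides compound decoys, sample target-side
    # decoys (non-interacting proteins) per anchor so the latent geometry
    # separates a compound from non-binding targets, not only from decoy
    # compounds — required for the control-proteome screening comparison
    bidirectional: bool = True
    debug_checks: bool = False

    def __post_init__(self):
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be >= 1")
        if not 0.0 <= self.loss_mix <= 1.0:
            raise ValueError("loss_mix must lie in [0, 1]")


class InteractionDataset:
    """Labelled (compound, target) pairs resolved against feature stores.

    ``compound_features`` and ``protein_features`` map ids to the raw
    embedding vectors (fingerprint / k-mer embedding).  Duplicate pairs and
    unresolvable ids are rejected at construction.
    """

    def __init__(
        self,
        pairs: pd.DataFrame,
        compound_features: Mapping[str, np.ndarray],
        protein_features: Mapping[str, np.ndarray],
    ):
        required = {"compound_id", "target_id", "label"}
        if not required.issubset(pairs.columns):
            raise ValueError(f"pair table needs columns {sorted(required)}")
        dup = pairs.duplicated(subset=["compound_id", "target_id"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (compound, target) rows")
        labels = set(pairs["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {sorted(labels)}")
        missing_c = set(pairs["compound_id"]) - set(compound_features)
        missing_t = set(pairs["target_id"]) - set(protein_features)
        if missing_c or missing_t:
            raise ValueError(
                f"unresolvable ids: compounds {sorted(missing_c)[:5]}, "
                f"targets {sorted(missing_t)[:5]}"
            )
        self.pairs = pairs.reset_index(drop=True)
        self.compound_features = compound_features
        self.protein_features = protein_features
        self.E1 = np.stack([protein_features[t] for t in pairs["target_id"]])
        self.E2 = np.stack([compound_features[c] for c in pairs["compound_id"]])
        self.labels = pairs["label"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def positive_pairs(self) -> list[tuple[str, str]]:
        """(target_id, compound_id) for every label-1 row."""
        pos = self.pairs[self.pairs["label"] == 1]
        return list(zip(pos["target_id"], pos["compound_id"]))


@dataclasses.dataclass
class DecoySet:
    """Decoys sampled for one anchor (target, active-compound) pair."""

    target_id: str
    compound_id: str
    decoy_ids: list[str]


class AdamOptimizer:
    """Standard Adam with bias correction, one state slot per parameter."""

    def __init__(self, params: Mapping[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def pretrain(
    model: InteractionModel,
    data: InteractionDataset,
    config: TrainingConfig,
    optimizer: AdamOptimizer | None = None,
) -> tuple[InteractionModel, list[float]]:
    """Minimise sigmoid-BCE over shuffled mini-batches; returns the loss trace.

    The trace holds one mean-batch-loss entry per epoch.  A single-class
    dataset is legal (the loss is still defined) but warned about.
    """
    n_classes = len(set(data.labels.tolist()))
    if n_classes < 2:
        import warnings

        warnings.warn("pretraining dataset contains a single label class")
    if optimizer is None:
        optimizer = AdamOptimizer(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    trace: list[float] = []
    n = len(data)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            loss, grads = model.bce_loss_and_grads(
                data.E1[sel], data.E2[sel], data.labels[sel]
            )
            optimizer.step(model.params, grads)
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    return model, trace


def sample_decoys(
    anchor: tuple[str, str],
    pool: Sequence[str],
    positives: Iterable[tuple[str, str]],
    n: int,
    seed: int,
) -> DecoySet:
    """Sample ``n`` distinct decoy compounds uniformly without replacement.

    The active compound itself and every compound positively paired with the
    anchor target are excluded.
    """
    target_id, compound_id = anchor
    positive_set = set(positives)
    eligible = sorted(
        c for c in set(pool)
        if c != compound_id and (target_id, c) not in positive_set
    )
    if len(eligible) < n:
        raise ValueError(
            f"decoy pool for target {target_id!r} has only {len(eligible)} "
            f"eligible compounds, {n} requested (short by {n - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n, replace=False)
    return DecoySet(target_id=target_id, compound_id=compound_id,
                    decoy_ids=[eligible[i] for i in chosen])


def contrastive_finetune(
    model: InteractionModel,
    positives: Sequence[tuple[str, str]],
    pool: Sequence[str],
    config: TrainingConfig,
    compound_features: Mapping[str, np.ndarray],
    protein_features: Mapping[str, np.ndarray],
    optimizer: AdamOptimizer | None = None,
    target_pool: Sequence[str] | None = None,
) -> tuple[InteractionModel, list[float]]:
    """Triplet fine-tuning with per-epoch decoy re-sampling.

    ``positives`` are (target_id, compound_id) anchors.  Each epoch draws a
    fresh compound-decoy set per anchor from seed
    ``config.seed + 1000 * (epoch + 1)`` plus the anchor index, then minimises
    lambda * triplet + (1 - lambda) * BCE(anchor-positive = 1, anchor-decoy = 0).

    With ``config.bidirectional`` (the default) the triplet term is the mean
    of two symmetric directions: the usual target-anchor vs compound decoys,
    plus compound-anchor vs target-side decoys drawn from ``target_pool``
    (every target id in ``protein_features`` appearing in ``positives`` plus
    any ids passed explicitly), excluding targets positively paired with the
    anchor compound.  The second direction teaches the latent space to keep a
    compound away from proteins it does not bind — the geometry the
    control-proteome screening comparison reads out.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    if optimizer is None:
        optimizer = AdamOptimizer(model.params, lr=config.finetune_learning_rate)
    rng = np.random.default_rng(config.seed)
    positive_set = set(positives)
    transposed = {(c, t) for t, c in positive_set}
    if target_pool is None:
        target_pool = sorted({t for t, _ in positives})
    # every anchor batch needs a rectangular decoy block, so the target-decoy
    # count is capped by the least-eligible anchor
    targets_by_compound: dict[str, set[str]] = {}
    for t, c in positive_set:
        targets_by_compound.setdefault(c, set()).add(t)
    pool_set = set(target_pool)
    min_eligible = min(
        (len(pool_set - targets_by_compound[c] - {t}) for t, c in positives),
        default=0,
    )
    n_target_decoys = min(config.n_decoys, min_eligible)
    bidir = config.bidirectional and n_target_decoys >= 1
    trace: list[float] = []
    n = len(positives)
    lam = config.loss_mix
    for epoch in range(config.finetune_epochs):
        epoch_seed = (config.seed + 1000 * (epoch + 1)) % (2**31 - 1)
        decoy_sets = [
            sample_decoys(anchor, pool, positive_set, config.n_decoys,
                          seed=epoch_seed + i)
            for i, anchor in enumerate(positives)
        ]
        target_decoy_sets = None
        if bidir:
            target_decoy_sets = [
                sample_decoys((c, t), target_pool, transposed, n_target_decoys,
                              seed=(epoch_seed + 500_000 + i) % (2**31 - 1))
                for i, (t, c) in enumerate(positives)
            ]
        if config.debug_checks:
            for ds in decoy_sets:
                assert ds.compound_id not in ds.decoy_ids
                assert all((ds.target_id, d) not in positive_set for d in ds.decoy_ids)
            for tds in target_decoy_sets or []:
                assert tds.compound_id not in tds.decoy_ids
                assert all((d, tds.target_id) not in positive_set for d in tds.decoy_ids)
        order = rng.permutation(n)
        # anchor mini-batches kept small: each anchor carries n_decoys rows
        batch = max(1, config.batch_size // max(1, config.n_decoys // 8))
        epoch_losses = []
        for start in range(0, n, batch):
            sel = order[start : start + batch]
            E1a = np.stack([protein_features[positives[i][0]] for i in sel])
            E2p = np.stack([compound_features[positives[i][1]] for i in sel])
            E2n = np.stack(
                [np.stack([compound_features[d] for d in decoy_sets[i].decoy_ids])
                 for i in sel]
            )
            loss_t, grads_t = model.triplet_loss_and_grads(
                E1a, E2p, E2n, margin=config.margin
            )
            if bidir:
                E1n = np.stack(
                    [np.stack([protein_features[d]
                               for d in target_decoy_sets[i].decoy_ids])
                     for i in sel]
                )
                loss_t2, grads_t2 = model.triplet_loss_and_grads(
                    E2p, E1a, E1n, margin=config.margin, anchor="c"
                )
                loss_t = 0.5 * (loss_t + loss_t2)
                grads_t = {k: 0.5 * (grads_t[k] + grads_t2[k]) for k in grads_t}
            total = lam * loss_t
            grads = {k: lam * v for k, v in grads_t.items()}
            if lam < 1.0:
                B, N, d2 = E2n.shape
                E1_all = np.repeat(E1a, N + 1, axis=0)
                E2_all = np.concatenate([E2p[:, None, :], E2n], axis=1).reshape(
                    B * (N + 1), d2
                )
                y = np.tile(np.r_[1.0, np.zeros(N)], B)
                loss_b, grads_b = model.bce_loss_and_grads(E1_all, E2_all, y)
                total += (1 - lam) * loss_b
                for k in grads:
                    grads[k] += (1 - lam) * grads_b[k]
            optimizer.step(model.params, grads)
            epoch_losses.append(total)
        trace.append(float(np.mean(epoch_losses)))
    return model, trace


def separation_statistic(
    model: InteractionModel,
    positives: Sequence[tuple[str, str]],
    decoys: Sequence[str],
    compound_features: Mapping[str, np.ndarray],
    protein_features: Mapping[str, np.ndarray],
) -> float:
    """Mean latent anchor-positive distance minus mean anchor-decoy distance.

    Distances are Euclidean between the target and compound projection-stack
    outputs; a more negative value means the contrastive objective has pushed
    active compounds closer to their targets than the decoys are.
    """
    Pa = model.project_target(np.stack([protein_features[t] for t, _ in positives]))
    Pp = model.project_compound(np.stack([compound_features[c] for _, c in positives]))
    Pd = model.project_compound(np.stack([compound_features[d] for d in decoys]))
    d_ap = np.linalg.norm(Pa - Pp, axis=1).mean()
    d_an = np.linalg.norm(Pa[:, None, :] - Pd[None, :, :], axis=2).mean()
    return float(d_ap - d_an)


def train_validation_split(
    pairs: pd.DataFrame, validation_fraction: float = 0.15, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-label split into train / validation pair tables."""
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for label, grp in pairs.groupby("label"):
        k = int(round(len(grp) * validation_fraction))
        val_idx.extend(rng.choice(grp.index.to_numpy(), size=k, replace=False))
    val_mask = pairs.index.isin(val_idx)
    return pairs[~val_mask].reset_index(drop=True), pairs[val_mask].reset_index(drop=True)


def read_pair_table(path) -> pd.DataFrame:
    """CSV/TSV with header compound_id,target_id,label; '#' lines skipped."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    need = {"compound_id", "target_id", "label"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    df["label"] = df["label"].astype(int)
    return df


def write_pair_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
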