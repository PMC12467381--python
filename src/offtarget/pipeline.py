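"""End-to-end orchestration: simulate -> featurize -> train -> finetune ->
screen -> aggregate -> evaluate.

Each stage reads the stage parameters from one :class:`~offtarget.config.RunConfig`,
derives its randomness from the master seed, logs its timing, and writes its
outputs as CSV/JSON files whose leading ``#`` metadata lines record the tool
version, the configuration hash and the master seed.  Re-running with the
same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .evaluation import (
    EditDistanceNormalizer,
    normalize_term_set,
    precision_recall,
    predict_adverse_effect_terms,
)
from .featurization import morgan_fingerprint, protein_embed, train_kmer_embeddings
from .model import InteractionModel, ModelConfig
from .screening import (
    aggregate_by_organ,
    compare_to_controls,
    extract_entity_embeddings,
    manifold_project_2d,
    rank_targets,
    scores_to_frame,
)
from .synthetic import generate_world, world_to_files
from .training import (
    InteractionDataset,
    TrainingConfig,
    contrastive_finetune,
    pretrain,
    train_validation_split,
)

__all__ = ["run_pipeline", "write_csv_with_metadata"]

log = logging.getLogger("offtarget")


def write_csv_with_metadata(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    """CSV with a leading '#' metadata block (version, config hash, seed)."""
    with open(path, "w") as fh:
        fh.write(f"# tool_version: {__version__}\n")
        fh.write(f"# config_hash: {config.config_hash()}\n")
        fh.write(f"# master_seed: {config.master_seed}\n")
        df.to_csv(fh, index=False)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # stop the chain with a stage-named error
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


@_stage("featurize")
def _featurize(world, config: RunConfig):
    f = config.featurization
    compound_features = {
        c.compound_id: morgan_fingerprint(c.smiles, radius=f.radius, n_bits=f.n_bits)
        for c in world.compounds
    }
    table = train_kmer_embeddings(
        [p.sequence for p in world.all_proteins],
        k=f.k, dimension=f.dimension, window=f.window, epochs=f.epochs,
        seed=config.master_seed, frames=f.frames,
    )
    protein_features = {
        p.protein_id: protein_embed(p.sequence, table, frames=f.frames,
                                    aggregate=f.aggregate)
        for p in world.all_proteins
    }
    return compound_features, protein_features, table


@_stage("train")
def _train(world, compound_features, protein_features, config: RunConfig):
    t = config.training
    m = config.model
    f = config.featurization
    model = InteractionModel(
        ModelConfig(
            d_protein=f.dimension, d_compound=f.n_bits, p=m.p,
            hidden=tuple(m.hidden) if m.hidden else None,
            attention_mode=m.attention_mode, n_tokens=m.n_tokens, eps=m.eps,
            seed=config.master_seed,
        )
    )
    tc = TrainingConfig(
        learning_rate=t.learning_rate, batch_size=t.batch_size, epochs=t.epochs,
        seed=config.master_seed, margin=t.margin, n_decoys=t.n_decoys,
        loss_mix=t.loss_mix, finetune_epochs=t.finetune_epochs,
        finetune_learning_rate=t.finetune_learning_rate,
        bidirectional=t.bidirectional,
    )
    train_pairs, val_pairs = train_validation_split(
        world.pairs, t.validation_fraction, seed=config.master_seed
    )
    dataset = InteractionDataset(train_pairs, compound_features, protein_features)
    model, pre_trace = pretrain(model, dataset, tc)
    positives = dataset.positive_pairs
    pool = [c.compound_id for c in world.compounds]
    model, ft_trace = contrastive_finetune(
        model, positives, pool, tc, compound_features, protein_features,
        target_pool=[p.protein_id for p in world.targets],
    )
    traces = pd.DataFrame(
        {
            "phase": ["pretrain"] * len(pre_trace) + ["finetune"] * len(ft_trace),
            "epoch": list(range(1, len(pre_trace) + 1)) + list(range(1, len(ft_trace) + 1)),
            "mean_loss": pre_trace + ft_trace,
        }
    )
    return model, traces, val_pairs


@_stage("screen")
def _screen(world, model, compound_features, protein_features, config: RunConfig):
    s = config.screening
    screened = sorted(world.ground_truth)
    if s.max_compounds is not None:
        screened = screened[: s.max_compounds]
    kinds = {t.protein_id: "ae_target" for t in world.targets
             if t.protein_id in set(world.ae_target_ids)}
    kinds.update({c.protein_id: "control_protein" for c in world.controls})
    proteins = {
        pid: protein_features[pid]
        for pid in list(kinds)
    }
    embeddings = extract_entity_embeddings(
        model,
        {cid: compound_features[cid] for cid in screened},
        proteins,
        protein_kinds=kinds,
    )
    points = manifold_project_2d(embeddings, seed=config.master_seed)
    by_id = {p.entity_id: p for p in points}
    protein_points = [by_id[pid] for pid in sorted(kinds)]
    frames, stats_rows = [], []
    for cid in screened:
        scores = rank_targets(by_id[cid], protein_points)
        frames.append(scores_to_frame(scores, config.master_seed, kinds))
        ae = [s_.distance for s_ in scores if kinds[s_.target_id] == "ae_target"]
        ctl = [s_.distance for s_ in scores if kinds[s_.target_id] == "control_protein"]
        tstat, pval = compare_to_controls(cid, ae, ctl)
        stats_rows.append(dict(compound_id=cid, t_statistic=tstat, p_value=pval,
                               n_ae_targets=len(ae), n_controls=len(ctl)))
    screen_df = pd.concat(frames, ignore_index=True)
    stats_df = pd.DataFrame(stats_rows)
    return screen_df, stats_df, embeddings, kinds


@_stage("aggregate")
def _aggregate(embeddings, world, config: RunConfig):
    aggs = aggregate_by_organ(
        [e for e in embeddings if e.entity_kind in ("compound", "ae_target")],
        world.organ_map,
        n_repetitions=config.screening.n_repetitions,
        master_seed=config.master_seed,
    )
    return pd.DataFrame(
        {
            "compound_id": [a.compound_id for a in aggs],
            "target_id": [a.target_id for a in aggs],
            "organ_group": [a.organ_group for a in aggs],
            "mean_distance": [a.mean_distance for a in aggs],
            "se_distance": [a.se_distance for a in aggs],
            "n_repetitions": [a.n_repetitions for a in aggs],
        }
    )


@_stage("evaluate")
def _evaluate(world, screen_df, kinds, config: RunConfig):
    from .screening import InteractionScore

    e = config.evaluation
    normalizer = EditDistanceNormalizer(world.dictionary, e.max_edit_fraction)
    rows, detail = [], {}
    for cid, grp in screen_df.groupby("compound_id", sort=True):
        if cid not in world.ground_truth:
            continue
        scores = [
            InteractionScore(cid, r.target_id, r.distance, r.rank)
            for r in grp.itertuples(index=False)
            if kinds.get(r.target_id) == "ae_target"
        ]
        controls = [
            r.distance for r in grp.itertuples(index=False)
            if kinds.get(r.target_id) == "control_protein"
        ]
        raw_pred = predict_adverse_effect_terms(
            cid, scores, world.annotations, controls, e.threshold_quantile
        )
        pred = normalize_term_set(cid, sorted(raw_pred.preferred), normalizer)
        truth = normalize_term_set(cid, world.ground_truth[cid], normalizer)
        res = precision_recall(pred, truth)
        rows.append(
            dict(
                compound_id=cid,
                precision=res.precision if res.precision is not None else np.nan,
                recall=res.recall if res.recall is not None else np.nan,
                n_tp=len(res.true_positives), n_fp=len(res.false_positives),
                n_fn=len(res.false_negatives),
            )
        )
        detail[cid] = dict(
            predicted=sorted(pred.preferred),
            truth=sorted(truth.preferred),
            true_positives=sorted(res.true_positives),
            false_positives=sorted(res.false_positives),
            false_negatives=sorted(res.false_negatives),
            unmapped_truth=[list(u) for u in truth.unmapped],
            threshold_quantile=e.threshold_quantile,
        )
    return pd.DataFrame(rows), detail


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute the full chain and return the paths of every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    log.addHandler(fh)
    try:
        config.to_json(outdir / "effective_config.json")
        w = config.world
        world = generate_world(
            n_compounds=w.n_compounds, n_targets=w.n_targets,
            n_positive_per_target=w.n_positive_per_target,
            motif_smiles_fragment=w.motif_smiles_fragment,
            motif_sequence=w.motif_sequence, ae_vocab_size=w.ae_vocab_size,
            variant_rate=w.variant_rate, seed=config.master_seed,
            n_controls=w.n_controls, null_world=w.null_world,
        )
        world_dir = outdir / "world"
        world_to_files(world, world_dir)

        compound_features, protein_features, table = _featurize(world, config)
        table.save(outdir / "kmer_embeddings.w2v.txt")

        model, traces, val_pairs = _train(
            world, compound_features, protein_features, config
        )
        model.save(outdir / "checkpoint.npz")
        write_csv_with_metadata(traces, outdir / "loss_trace.csv", config)
        write_csv_with_metadata(val_pairs, outdir / "validation_pairs.csv", config)

        screen_df, stats_df, embeddings, kinds = _screen(
            world, model, compound_features, protein_features, config
        )
        write_csv_with_metadata(screen_df, outdir / "screen.csv", config)
        write_csv_with_metadata(stats_df, outdir / "screen_stats.csv", config)

        organ_df = _aggregate(embeddings, world, config)
        write_csv_with_metadata(organ_df, outdir / "organ_aggregate.csv", config)

        eval_df, detail = _evaluate(world, screen_df, kinds, config)
        write_csv_with_metadata(eval_df, outdir / "evaluation.csv", config)
        (outdir / "evaluation.json").write_text(
            json.dumps(detail, indent=2, sort_keys=True) + "\n"
        )
    finally:
        log.removeHandler(fh)
        fh.close()
    return {
        "world": outdir / "world",
        "checkpoint": outdir / "checkpoint.npz",
        "loss_trace": outdir / "loss_trace.csv",
        "screen": outdir / "screen.csv",
        "screen_stats": outdir / "screen_stats.csv",
        "organ_aggregate": outdir / "organ_aggregate.csv",
        "evaluation": outdir / "evaluation.csv",
        "evaluation_detail": outdir / "evaluation.json",
        "config": outdir / "effective_config.json",
    }
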