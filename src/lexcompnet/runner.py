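"""End-to-end run orchestration: train n seeds, evaluate, simulate VWP."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, save_config
from .evaluation import TrainingMonitor, learning_snapshot, recognize_all
from .grunet import GRUWordRecognizer
from .io import load_checkpoint, save_checkpoint
from .phonology import PhoneInventory, load_vocabulary, save_vocabulary
from .pipeline import Dataset, build_dataset
from .representations import load_matrix, pairwise_jaccard_table
from .synth import gen_phone_inventory, gen_semvis, gen_vocabulary
from .vwp import RelatednessTables, grand_average, results_frame, run_trial, select_trials

log = logging.getLogger("lexcompnet")


class DataError(ValueError):
    """Input files are malformed or mutually inconsistent."""


def load_dataset(cfg: RunConfig) -> tuple[Dataset, float | None]:
    """Load the four inputs, or generate a synthetic dataset when paths are unset."""
    if cfg.vocab is None:
        log.info("no input paths given; generating synthetic dataset (seed %d)",
                 cfg.synth.seed)
        inv = gen_phone_inventory(cfg.synth)
        vocab = gen_vocabulary(cfg.synth, inv)
        sem, vis = gen_semvis(cfg.synth, vocab)
        ds, var = build_dataset(vocab, inv, sem, vis, vis_k=cfg.synth.vis_dims,
                                z_cut=cfg.z_cut, n_slots=cfg.synth.n_slots)
        return ds, var
    vocab = load_vocabulary(cfg.vocab)
    inv = PhoneInventory.from_csv(cfg.features)
    sem_ids, sem = load_matrix(cfg.semantic)
    vis_ids, vis = load_matrix(cfg.visual)
    item_ids = [v.item_id for v in vocab]
    if sem_ids != item_ids or vis_ids != item_ids:
        raise DataError("representation matrices do not match the vocabulary item order")
    ds, var = build_dataset(vocab, inv, sem, vis, vis_k=cfg.vis_k,
                            z_cut=cfg.z_cut, n_slots=cfg.n_slots)
    return ds, var


def train_one(cfg: RunConfig, ds: Dataset, seed: int, out: Path):
    """Train a single model (or reload its finished checkpoint) and write logs."""
    ckpt = out / f"model_seed{seed}.h5"
    log_path = out / f"train_log_seed{seed}.tsv"
    if ckpt.exists():
        log.info("seed %d: checkpoint exists, resuming from %s", seed, ckpt)
        params, spec, meta = load_checkpoint(ckpt)
        return params, pd.read_csv(log_path, sep="\t"), None
    t = cfg.train
    model = GRUWordRecognizer(
        hidden_dim=ds.spec.total_dim,
        learning_rate=t.learning_rate,
        momentum=t.momentum,
        nesterov=t.nesterov,
        epochs=t.epochs,
        eval_every=t.eval_every,
        batch_size=t.batch_size,
        loss=t.loss,
        convergence_patience=t.convergence_patience,
        random_state=seed,
    )
    monitor = TrainingMonitor(
        X=ds.X, offsets=ds.offsets, semvis_targets=ds.semvis_targets,
        lexical_targets=ds.lexical_targets, item_ids=ds.item_ids, spec=ds.spec,
        threshold=cfg.vwp.threshold,
    )
    model.fit(ds.X, ds.Y, eval_fn=monitor)
    log_df = pd.DataFrame(model.log_)[
        ["epoch", "loss", "pct_both", "pct_semvis_only", "pct_lex_only", "pct_neither"]
    ]
    log_df.to_csv(log_path, sep="\t", index=False)
    monitor.per_item_frame().to_csv(out / f"per_item_seed{seed}.tsv", sep="\t", index=False)
    save_checkpoint(ckpt, model.params_, ds.spec, epoch=model.n_epochs_,
                    config=dataclasses.asdict(cfg.train))
    log.info("seed %d: trained %d epochs, final both=%.1f%%", seed,
             model.n_epochs_, model.log_[-1]["pct_both"] if model.log_ else float("nan"))
    return model.params_, log_df, monitor


def evaluate_model(cfg: RunConfig, ds: Dataset, params, seed: int, out: Path) -> dict:
    results = recognize_all(params, ds.X, ds.offsets, ds.semvis_targets,
                            ds.lexical_targets, ds.item_ids, ds.spec,
                            cfg.vwp.threshold)
    rows = [
        (r.item_id, r.best_semvis_item, r.best_lexical_item,
         r.semvis_correct, r.lexical_correct,
         float(r.semvis_activations.max()), float(r.lexical_activations.max()))
        for r in results
    ]
    pd.DataFrame(rows, columns=["item_id", "best_semvis", "best_lexical",
                                "semvis_correct", "lexical_correct",
                                "semvis_activation", "lexical_activation"]
                 ).to_csv(out / f"eval_seed{seed}.tsv", sep="\t", index=False)
    snap = learning_snapshot(results)
    return {f"pct_{k}": 100.0 * v for k, v in snap.items()}


def simulate_vwp(cfg: RunConfig, ds: Dataset, models: dict[int, object], out: Path):
    tables = RelatednessTables.from_binary(
        ds.item_ids, ds.sem_binary, ds.vis_binary, cfg.vwp.pct_hi, cfg.vwp.pct_lo
    )
    trials = select_trials(ds.vocab, tables, ds.inventory, cfg.vwp.rhyme)
    if not trials:
        log.warning("no valid target-absent trials in this vocabulary")
        return [], None, 0
    pd.DataFrame([dataclasses.asdict(t) for t in trials]).to_csv(
        out / "trial_specs.tsv", sep="\t", index=False
    )
    semvis = {i: ds.semvis_targets[k] for k, i in enumerate(ds.item_ids)}
    x_by_id = {i: ds.X[k] for k, i in enumerate(ds.item_ids)}
    frames = []
    for seed, params in models.items():
        results = [
            run_trial(params, t, x_by_id[t.target_id], semvis, ds.spec,
                      cfg.vwp.threshold)
            for t in trials
        ]
        frames.append(results_frame(results, model_seed=seed))
    pd.concat(frames, ignore_index=True).to_csv(out / "vwp_trials.tsv", sep="\t",
                                                index=False)
    table, crossover = grand_average(frames, seed=cfg.train.seed)
    table.to_csv(out / "vwp_grand_average.tsv", sep="\t", index=False)
    return frames, crossover, len(trials)


def run_experiment(cfg: RunConfig) -> Path:
    """Train ``n_seeds`` models, evaluate them, and simulate the VWP trials.

    The run is resumable: finished checkpoints are reloaded rather than
    retrained, and a rerun with the same seeds reproduces the same summary.
    """
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    ds, var = load_dataset(cfg)
    save_vocabulary(ds.vocab, out / "vocabulary.csv")
    for kind, mat in (("semantic", ds.sem_binary), ("visual", ds.vis_binary),
                      ("lexical", ds.lexical)):
        pairwise_jaccard_table(mat, ds.item_ids, kind).to_csv(
            out / f"pairwise_{kind}.tsv", sep="\t", index=False
        )
    seeds = [cfg.train.seed + i for i in range(cfg.n_seeds)]
    models = {}
    summaries = {}
    for seed in seeds:
        params, _, _ = train_one(cfg, ds, seed, out)
        models[seed] = params
        summaries[seed] = evaluate_model(cfg, ds, params, seed, out)
    _, crossover, n_trials = simulate_vwp(cfg, ds, models, out)
    summary = {
        "seeds": seeds,
        "per_seed": summaries,
        "vis_variance_explained": var,
        "n_vwp_trials": n_trials,
        "vwp_crossover_timestep": crossover,
    }
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    with open(out / "provenance.json", "w") as f:
        json.dump(
            {
                "package_version": __version__,
                "python": sys.version,
                "platform": platform.platform(),
                "numpy": np.__version__,
                "seeds": seeds,
                "timestamp": datetime.now(timezone.utc).isoformat(),
            },
            f,
            indent=2,
        )
    return out
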