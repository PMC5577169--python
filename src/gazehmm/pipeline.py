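"""End-to-end orchestration of the scanpath-classification pipeline.

Each stage is a plain function reading and writing text artifacts (TSV/JSON)
in an output directory, so any stage can be inspected or replaced; ``run``
chains them. Every artifact records the seed and a hash of the configuration
that produced it; existing artifacts are never silently overwritten.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as gio
from .baselines import LogisticBaseline, SvmBaseline
from .evaluation import DEFAULT_GRID, confusion, cross_validate, select_states
from .features import extract_sequence
from .hmm import (
    DhmmClassifier,
    StateSpec,
    classify_batch,
    conditional_log_likelihood,
    discriminative_train,
    fit_generative,
)
from .simulate import GeneratorConfig, simulate_corpus

logger = logging.getLogger("gazehmm")

__all__ = ["RunConfig", "run", "simulate_stage", "extract_stage", "train_stage",
           "classify_stage", "select_stage", "evaluate_stage", "report_stage"]


@dataclass
class RunConfig:
    """Configuration shared by the pipeline stages."""

    out_dir: str = "gazehmm_out"
    seed: int = 0
    states: StateSpec = field(default_factory=lambda: StateSpec(3, 3))
    grid: tuple[StateSpec, ...] = DEFAULT_GRID
    folds: int = 5
    repeats: int = 10
    restarts: int = 10
    n_per_class: int = 840
    overwrite: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed, "states": str(self.states),
                "grid": [str(s) for s in self.grid], "folds": self.folds,
                "repeats": self.repeats, "restarts": self.restarts,
                "n_per_class": self.n_per_class,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _out(cfg: RunConfig, name: str) -> Path:
    d = Path(cfg.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    p = d / name
    if p.exists() and not cfg.overwrite:
        raise FileExistsError(f"{p} exists; pass overwrite=True (or --overwrite)")
    return p


def _write_json(cfg: RunConfig, name: str, obj: dict) -> Path:
    p = _out(cfg, name)
    obj = {"_seed": cfg.seed, "_config_hash": cfg.config_hash(), **obj}
    p.write_text(json.dumps(obj, indent=2))
    logger.info("wrote %s", p)
    return p


def simulate_stage(cfg: RunConfig) -> Path:
    """Generate a synthetic corpus; write raw fixation table, coded
    sequences, the AOI layout, the generating parameters and the split."""
    gen = GeneratorConfig(seed=cfg.seed, n_per_class=cfg.n_per_class)
    corpus, raw = simulate_corpus(gen, with_raw=True)
    gio.write_fixation_table(raw, _out(cfg, "fixations.tsv"))
    gio.write_sequences(corpus.sequences, _out(cfg, "sequences.tsv"))
    gio.write_layout(gen.layout, _out(cfg, "layout.json"))
    gio.write_params(gen.params, _out(cfg, "generating_params.json"))
    _write_json(cfg, "split.json", {
        "train": corpus.train_idx.tolist(), "test": corpus.test_idx.tolist(),
        "n_sequences": len(corpus.sequences),
    })
    return Path(cfg.out_dir)


def extract_stage(cfg: RunConfig, fixation_table, layout_file) -> Path:
    """Code a raw fixation table into observation sequences and features."""
    layout = gio.read_layout(layout_file)
    trials = gio.read_fixation_table(fixation_table)
    seqs = [extract_sequence(fixes, layout) for fixes in trials.values()]
    gio.write_sequences(seqs, _out(cfg, "extracted_sequences.tsv"))
    gio.write_feature_matrix(seqs, _out(cfg, "features.tsv"))
    return Path(cfg.out_dir)


def _load_train(cfg: RunConfig, sequences_file, split_file=None):
    seqs = gio.read_sequences(sequences_file)
    if split_file is None:
        return seqs, None
    split = json.loads(Path(split_file).read_text())
    train = [seqs[i] for i in split["train"]]
    test = [seqs[i] for i in split["test"]]
    return train, test


def train_stage(cfg: RunConfig, sequences_file, split_file=None) -> Path:
    """Baum-Welch then discriminative refinement; writes both parameter sets."""
    train, _ = _load_train(cfg, sequences_file, split_file)
    gen = fit_generative(train, cfg.states, restarts=cfg.restarts, seed=cfg.seed)
    gio.write_params(gen.params, _out(cfg, "params_generative.json"))
    disc = discriminative_train(train, gen.params)
    gio.write_params(disc.params, _out(cfg, "params_dhmm.json"))
    _write_json(cfg, "train_summary.json", {
        "log_likelihood": gen.final_objective,
        "conditional_log_likelihood": disc.final_objective,
        "cll_before_refinement": conditional_log_likelihood(train, gen.params),
    })
    return Path(cfg.out_dir)


def classify_stage(cfg: RunConfig, sequences_file, params_file) -> Path:
    """Posterior strategy probabilities for every sequence in a file."""
    seqs = gio.read_sequences(sequences_file)
    params = gio.read_params(params_file)
    labels, probs = classify_batch(seqs, params)
    rows = [
        {
            "subject_id": s.subject_id, "trial_id": s.trial_id,
            "actual": s.strategy, "predicted": lab,
            "p_lfrr": float(p[0]), "p_rflr": float(p[1]),
        }
        for s, lab, p in zip(seqs, labels, probs)
    ]
    import pandas as pd

    p = _out(cfg, "posteriors.tsv")
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    return Path(cfg.out_dir)


def select_stage(cfg: RunConfig, sequences_file, split_file=None) -> Path:
    """Hidden-state-count selection over the configured grid."""
    train, _ = _load_train(cfg, sequences_file, split_file)
    labels = [s.strategy for s in train]
    spec, curve = select_states(
        train, labels,
        lambda spec: DhmmClassifier(spec, restarts=max(1, cfg.restarts // 5),
                                    seed=cfg.seed, bw_max_iter=30, disc_max_iter=30),
        grid=cfg.grid, k=cfg.folds, seed=cfg.seed,
    )
    _write_json(cfg, "selected_states.json", {"selected": str(spec), "curve": curve})
    return Path(cfg.out_dir)


def evaluate_stage(cfg: RunConfig, sequences_file, split_file=None) -> Path:
    """Cross-validated comparison of the three classifiers plus held-out
    confusion matrices."""
    train, test = _load_train(cfg, sequences_file, split_file)
    labels = [s.strategy for s in train]
    factories = {
        "logistic": lambda: LogisticBaseline(),
        "svm": lambda: SvmBaseline(),
        "dhmm": lambda: DhmmClassifier(cfg.states, restarts=max(1, cfg.restarts // 5),
                                       seed=cfg.seed, bw_max_iter=30, disc_max_iter=30),
    }
    cv_results = {}
    for name, fac in factories.items():
        res = cross_validate(fac, train, labels, k=cfg.folds,
                             repeats=cfg.repeats, seed=cfg.seed, name=name)
        cv_results[name] = {"mean": res.mean, "sd": res.sd,
                            "per_repeat": res.per_repeat.tolist()}
    out = {"cv": cv_results}
    if test is not None:
        confusions = {}
        actual = [s.strategy for s in test]
        for name, fac in factories.items():
            model = fac()
            model.fit(train, labels)
            cm = confusion(model.predict(test), actual)
            confusions[name] = {
                "counts": cm.counts.tolist(),
                "total_accuracy": cm.total_accuracy,
                "row_accuracies": cm.row_accuracies.tolist(),
                "col_accuracies": cm.col_accuracies.tolist(),
            }
        out["test_confusion"] = confusions
    _write_json(cfg, "evaluation.json", out)
    return Path(cfg.out_dir)


def report_stage(cfg: RunConfig, evaluation_file, params_file=None) -> Path:
    """Plain-text report mirroring the confusion-matrix and parameter tables."""
    ev = json.loads(Path(evaluation_file).read_text())
    lines = ["Strategy-classification report", "=" * 32, ""]
    for name, res in ev.get("cv", {}).items():
        lines.append(f"{name:10s} CV accuracy: {res['mean'] * 100:.1f}% (sd {res['sd'] * 100:.1f})")
    for name, cm in ev.get("test_confusion", {}).items():
        c = np.array(cm["counts"])
        r = np.array(cm["row_accuracies"]) * 100
        lines += [
            "",
            f"{name}: held-out confusion matrix (rows actual LFRR/RFLR, cols predicted)",
            f"  LFRR ({r[0]:.1f}%)  {c[0, 0]:5d} {c[0, 1]:5d}",
            f"  RFLR ({r[1]:.1f}%)  {c[1, 0]:5d} {c[1, 1]:5d}",
            f"  total accuracy {cm['total_accuracy'] * 100:.1f}%",
        ]
    if params_file is not None:
        params = gio.read_params(params_file)
        lines += ["", "Fitted dHMM parameters", "-" * 24]
        for i, em in enumerate(params.emissions):
            cls = params.class_of_state[i]
            lines.append(
                f"state {i} [{cls}] pi={params.pi[i]:.3f} "
                f"FD~{np.exp(em.mu_fd):.0f}ms SL~{np.exp(em.mu_sl):.0f}px "
                f"p_aoi={np.round(em.p_aoi, 2).tolist()} "
                f"p_sd={np.round(em.p_sd, 2).tolist()}"
            )
    p = _out(cfg, "report.txt")
    p.write_text("\n".join(lines) + "\n")
    return p


def run(command: str, cfg: RunConfig, **paths) -> Path:
    """Dispatch one pipeline stage by name (see the stage functions)."""
    stages = {
        "simulate": simulate_stage,
        "extract": extract_stage,
        "train": train_stage,
        "classify": classify_stage,
        "select": select_stage,
        "evaluate": evaluate_stage,
        "report": report_stage,
    }
    if command not in stages:
        raise ValueError(f"unknown stage {command!r}; choose from {sorted(stages)}")
    logger.info("stage %s (seed=%d, config=%s)", command, cfg.seed, cfg.config_hash())
    return stages[command](cfg, **paths)
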