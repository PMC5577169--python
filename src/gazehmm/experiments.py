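"""Reproducible end-to-end experiments on synthetic corpora.

These functions bundle the package's standard study protocols — model
recovery against the published parameter tables, behavioural slope recovery,
classifier comparison, and hidden-state-count selection — so that a single
seeded call reruns a whole experiment. They are what the example scripts and
the reproduction script drive.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .baselines import LogisticBaseline, SvmBaseline
from .evaluation import angle_effect_slope, cross_validate, select_states
from .hmm import (
    BlockHMMParams,
    DhmmClassifier,
    StateSpec,
    discriminative_train,
    fit_generative,
)
from .simulate import GeneratorConfig, default_params, simulate_corpus, simulate_rt

__all__ = [
    "match_states",
    "recover_default_model",
    "rt_slope_recovery",
    "classifier_comparison",
    "state_selection_experiment",
]


def match_states(reference: BlockHMMParams, fitted: BlockHMMParams, cls: str):
    """Match fitted states of one block to reference states by emission profile.

    The cost couples the log-duration mean with the saccade-direction row
    (L1 distance), which separates the three processing states cleanly.
    Returns ``{reference_state_index: fitted_state_index}`` (joint indices).
    """
    ridx = reference.states_of(cls)
    fidx = fitted.states_of(cls)
    D = np.zeros((len(ridx), len(fidx)))
    for a, i in enumerate(ridx):
        for b, j in enumerate(fidx):
            D[a, b] = abs(reference.emissions[i].mu_fd - fitted.emissions[j].mu_fd) + \
                np.abs(reference.emissions[i].p_sd - fitted.emissions[j].p_sd).sum()
    rows, cols = linear_sum_assignment(D)
    return {int(ridx[a]): int(fidx[b]) for a, b in zip(rows, cols)}


def recover_default_model(
    seed: int,
    *,
    n_per_class: int = 1000,
    restarts: int = 10,
    bw_max_iter: int = 100,
    polish_max_iter: int = 1500,
    disc_max_iter: int = 100,
) -> dict:
    """Simulate from the published-parameter model and re-estimate it.

    Draws ``n_per_class`` labelled trials per strategy from the default
    generating model, fits the 3-3 block HMM by restarted Baum-Welch with a
    convergence polish, refines it discriminatively, matches the fitted LFRR
    states to the generating ones by emission profile, and reports the
    re-estimated quantities on the percent scale:

    - ``sd1_encoding_lfrr``: SD-1 probability of the encoding-and-searching
      state (generating value 89),
    - ``sd3_comparison_lfrr``: SD-3 probability of the comparison state
      (generating value 68),
    - ``pi_searching_lfrr``: joint initial probability of the
      searching-on-one-side state (generating value 35).
    """
    cfg = GeneratorConfig(n_per_class=n_per_class, seed=seed)
    corpus = simulate_corpus(cfg)
    gen = fit_generative(
        corpus.sequences, StateSpec(3, 3), restarts=restarts, seed=seed,
        max_iter=bw_max_iter, polish_max_iter=polish_max_iter,
    )
    disc = discriminative_train(corpus.sequences, gen.params,
                                max_iter=disc_max_iter)
    fitted = disc.params
    truth = cfg.params
    mapping = match_states(truth, fitted, "LFRR")
    # generating LFRR block order: 0 = encoding/searching, 1 = comparison,
    # 2 = searching on one side
    e, c, s = mapping[0], mapping[1], mapping[2]
    return {
        "sd1_encoding_lfrr": 100.0 * float(fitted.emissions[e].p_sd[0]),
        "sd3_comparison_lfrr": 100.0 * float(fitted.emissions[c].p_sd[2]),
        "pi_searching_lfrr": 100.0 * float(fitted.pi[s]),
        "n_sequences": 2 * n_per_class,
        "params": fitted,
    }


def rt_slope_recovery(
    seed: int,
    *,
    slope: float = 13.340,
    intercept: float = 1500.0,
    noise_sd: float = 300.0,
    n_subjects: int = 15,
    n_trials_per_angle: int = 8,
) -> dict:
    """Generate reaction times with a linear angle effect and re-fit the slope."""
    rng = np.random.default_rng(seed)
    table = simulate_rt(slope=slope, intercept=intercept, noise_sd=noise_sd,
                        n_subjects=n_subjects,
                        n_trials_per_angle=n_trials_per_angle, rng=rng)
    est, est_intercept = angle_effect_slope(table)
    return {"slope": est, "intercept": est_intercept, "n_trials": len(table)}


def classifier_comparison(
    seed: int,
    *,
    n_per_class: int = 150,
    k: int = 5,
    restarts: int = 2,
    bw_max_iter: int = 40,
    polish_max_iter: int = 100,
    disc_max_iter: int = 40,
) -> dict:
    """Mean k-fold CV accuracy of the three classifiers on one seeded corpus."""
    corpus = simulate_corpus(GeneratorConfig(n_per_class=n_per_class, seed=seed))
    seqs = corpus.sequences
    labels = [s.strategy for s in seqs]
    dhmm = lambda: DhmmClassifier(  # noqa: E731
        StateSpec(3, 3), restarts=restarts, seed=seed, bw_max_iter=bw_max_iter,
        polish_max_iter=polish_max_iter, disc_max_iter=disc_max_iter,
    )
    return {
        "logistic": cross_validate(LogisticBaseline, seqs, labels, k=k,
                                   repeats=1, seed=seed).mean,
        "svm": cross_validate(SvmBaseline, seqs, labels, k=k,
                              repeats=1, seed=seed).mean,
        "dhmm": cross_validate(dhmm, seqs, labels, k=k, repeats=1, seed=seed).mean,
    }


def state_selection_experiment(
    seed: int,
    *,
    n_per_class: int = 150,
    grid=(StateSpec(2, 2), StateSpec(3, 3), StateSpec(4, 4)),
    k: int = 5,
    restarts: int = 2,
    bw_max_iter: int = 40,
    polish_max_iter: int = 100,
    disc_max_iter: int = 40,
    margin: float = 0.01,
):
    """Run the level-off state-count selection on one seeded 3-3 corpus."""
    corpus = simulate_corpus(GeneratorConfig(n_per_class=n_per_class, seed=seed))
    seqs = corpus.sequences
    labels = [s.strategy for s in seqs]
    factory = lambda spec: DhmmClassifier(  # noqa: E731
        spec, restarts=restarts, seed=seed, bw_max_iter=bw_max_iter,
        polish_max_iter=polish_max_iter, disc_max_iter=disc_max_iter,
    )
    return select_states(seqs, labels, factory, grid=list(grid), k=k,
                         seed=seed, margin=margin)
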