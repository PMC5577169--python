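"""Block-structured discriminative hidden Markov model over scanpaths.

The model is a single joint HMM whose hidden states are partitioned into two
blocks, one per mental-rotation strategy (LFRR / RFLR). The transition matrix
is block-diagonal — a state path never crosses blocks — and the initial
distribution spans both blocks, so its per-block mass encodes the class prior.
Classifying a trial is Bayes' rule on the terminal forward mass of each block:

    P(C | X, lambda) = P(X, paths in block C | lambda) / P(X | lambda)

Each state emits, conditionally independently given the state: the log
fixation duration and log outgoing saccade length (Gaussians) and the
4-category saccade direction (categorical). The final fixation of a trial has
no outgoing saccade, so its emission density drops the saccade factors. The
per-state AOI occupancy is estimated alongside (it is what the parameter
tables report) but is not part of the default likelihood: the AOI chain is
already determined by the first AOI and the saccade-direction stream, so a
fourth AOI factor would double-count that information and lets the hidden
states latch onto the arm-parity of the scanpath instead of the processing
states; ``include_aoi=True`` restores the four-factor density.

Training is two-stage: per-block Baum–Welch on labelled sequences (maximum
likelihood; responsibilities of a labelled trial are confined to its block),
then discriminative refinement by gradient ascent on the conditional
log-likelihood sum_n log P(c_n | X_n, lambda) in an unconstrained
reparameterization (softmax logits for all categorical parameters, log sigmas
for the Gaussians), with backtracking line search so accepted steps never
decrease the objective.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .features import ObservationEvent, ObservationSequence, target_aoi

__all__ = [
    "CLASSES",
    "ValidationError",
    "EmissionParams",
    "StateSpec",
    "BlockHMMParams",
    "ClassPosterior",
    "FitResult",
    "SequenceBatch",
    "log_forward",
    "forward_batch",
    "viterbi",
    "random_init",
    "baum_welch",
    "fit_generative",
    "conditional_log_likelihood",
    "discriminative_train",
    "fit_dhmm",
    "classify",
    "classify_batch",
    "sample_sequence",
    "DhmmClassifier",
]

CLASSES = ("LFRR", "RFLR")

_PROB_FLOOR = 1e-12  # floor on categorical probabilities, keeps logs finite
_SIGMA_FLOOR = 1e-3
_LOG2PI = math.log(2.0 * math.pi)


class ValidationError(ValueError):
    """Model parameters violate a structural constraint."""


@dataclass
class EmissionParams:
    """Per-state emission parameters.

    ``mu_fd``/``sigma_fd`` parameterize the Gaussian over log fixation
    duration (log ms); ``mu_sl``/``sigma_sl`` the Gaussian over log saccade
    length (log px). ``p_aoi`` and ``p_sd`` are 4-vectors over the AOI and
    saccade-direction categories.
    """

    mu_fd: float
    sigma_fd: float
    mu_sl: float
    sigma_sl: float
    p_aoi: np.ndarray
    p_sd: np.ndarray

    def __post_init__(self) -> None:
        self.p_aoi = np.asarray(self.p_aoi, dtype=float)
        self.p_sd = np.asarray(self.p_sd, dtype=float)

    def validate(self) -> None:
        if self.sigma_fd <= 0 or self.sigma_sl <= 0:
            raise ValidationError("emission sigmas must be > 0")
        for name, p in (("p_aoi", self.p_aoi), ("p_sd", self.p_sd)):
            if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
                raise ValidationError(f"{name} must be a 4-vector summing to 1")


@dataclass(frozen=True)
class StateSpec:
    """Number of hidden states in each strategy block."""

    n_lfrr: int
    n_rflr: int

    def __post_init__(self) -> None:
        if self.n_lfrr < 1 or self.n_rflr < 1:
            raise ValidationError("each block needs at least one state")

    @property
    def n_states(self) -> int:
        return self.n_lfrr + self.n_rflr

    def __str__(self) -> str:
        return f"{self.n_lfrr}-{self.n_rflr}"


@dataclass
class BlockHMMParams:
    """Joint parameters lambda of the block HMM.

    ``pi`` is the initial distribution over all states (its per-block mass is
    the class prior); ``A`` is block-diagonal by ``class_of_state``.
    """

    pi: np.ndarray
    A: np.ndarray
    emissions: list[EmissionParams]
    class_of_state: tuple[str, ...]

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.class_of_state = tuple(self.class_of_state)

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def states_of(self, cls: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.class_of_state) if c == cls])

    @property
    def spec(self) -> StateSpec:
        return StateSpec(
            n_lfrr=int(np.sum([c == "LFRR" for c in self.class_of_state])),
            n_rflr=int(np.sum([c == "RFLR" for c in self.class_of_state])),
        )

    def validate(self) -> None:
        n = self.n_states
        if self.A.shape != (n, n) or len(self.emissions) != n or len(self.class_of_state) != n:
            raise ValidationError("inconsistent parameter dimensions")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-6:
            raise ValidationError("pi must be a distribution over all states")
        if np.any(self.A < 0) or np.max(np.abs(self.A.sum(axis=1) - 1.0)) > 1e-6:
            raise ValidationError("every row of A must sum to 1")
        for i in range(n):
            for j in range(n):
                if self.class_of_state[i] != self.class_of_state[j] and self.A[i, j] > 1e-12:
                    raise ValidationError("A must have zero mass between class blocks")
        for cls in CLASSES:
            idx = self.states_of(cls)
            if len(idx) == 0:
                raise ValidationError(f"class {cls} owns no state")
            if self.pi[idx].sum() <= 0:
                raise ValidationError(f"class {cls} has zero initial mass")
        for em in self.emissions:
            em.validate()

    def copy(self) -> "BlockHMMParams":
        return BlockHMMParams(
            pi=self.pi.copy(),
            A=self.A.copy(),
            emissions=[
                EmissionParams(
                    em.mu_fd, em.sigma_fd, em.mu_sl, em.sigma_sl,
                    em.p_aoi.copy(), em.p_sd.copy(),
                )
                for em in self.emissions
            ],
            class_of_state=self.class_of_state,
        )

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "class_of_state": list(self.class_of_state),
            "emissions": [
                {
                    "mu_fd": em.mu_fd,
                    "sigma_fd": em.sigma_fd,
                    "mu_sl": em.mu_sl,
                    "sigma_sl": em.sigma_sl,
                    "p_aoi": em.p_aoi.tolist(),
                    "p_sd": em.p_sd.tolist(),
                }
                for em in self.emissions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockHMMParams":
        return cls(
            pi=np.array(d["pi"], dtype=float),
            A=np.array(d["A"], dtype=float),
            emissions=[
                EmissionParams(
                    e["mu_fd"], e["sigma_fd"], e["mu_sl"], e["sigma_sl"],
                    np.array(e["p_aoi"], dtype=float), np.array(e["p_sd"], dtype=float),
                )
                for e in d["emissions"]
            ],
            class_of_state=tuple(d["class_of_state"]),
        )


@dataclass(frozen=True)
class ClassPosterior:
    """P(C | X, lambda) for one trial; ties go to LFRR."""

    p_lfrr: float
    p_rflr: float

    @property
    def predicted(self) -> str:
        return "LFRR" if self.p_lfrr >= self.p_rflr else "RFLR"


@dataclass
class FitResult:
    params: BlockHMMParams
    history: list[float]

    @property
    def final_objective(self) -> float:
        return self.history[-1]


# ---------------------------------------------------------------------------
# batched sequence representation


class SequenceBatch:
    """Padded array view of a set of observation sequences."""

    def __init__(self, seqs: Sequence[ObservationSequence]):
        if len(seqs) == 0:
            raise ValueError("empty batch")
        self.seqs = list(seqs)
        N = len(seqs)
        self.lengths = np.array([len(s) for s in seqs], dtype=int)
        T = int(self.lengths.max())
        self.log_fd = np.zeros((N, T))
        self.log_sl = np.zeros((N, T))
        self.aoi = np.zeros((N, T), dtype=int)
        self.sd = np.zeros((N, T), dtype=int)
        for i, s in enumerate(seqs):
            L = len(s)
            self.log_fd[i, :L] = s.log_fd
            self.aoi[i, :L] = s.aoi - 1
            if L > 1:
                self.log_sl[i, : L - 1] = s.log_sl
                self.sd[i, : L - 1] = s.sd - 1
        t_idx = np.arange(T)[None, :]
        self.mask = t_idx < self.lengths[:, None]
        self.sacc_mask = t_idx < (self.lengths - 1)[:, None]
        self.labels = [s.strategy for s in seqs]

    def subset(self, idx: Iterable[int]) -> "SequenceBatch":
        return SequenceBatch([self.seqs[i] for i in idx])


def _emission_arrays(params: BlockHMMParams):
    mu_fd = np.array([e.mu_fd for e in params.emissions])
    sig_fd = np.array([e.sigma_fd for e in params.emissions])
    mu_sl = np.array([e.mu_sl for e in params.emissions])
    sig_sl = np.array([e.sigma_sl for e in params.emissions])
    lp_aoi = np.log(np.clip(np.stack([e.p_aoi for e in params.emissions]), _PROB_FLOOR, None))
    lp_sd = np.log(np.clip(np.stack([e.p_sd for e in params.emissions]), _PROB_FLOOR, None))
    return mu_fd, sig_fd, mu_sl, sig_sl, lp_aoi, lp_sd


def _log_emissions(batch: SequenceBatch, params: BlockHMMParams,
                   include_aoi: bool = False) -> np.ndarray:
    """log P(X_t | S_t = k) as an (N, T, n) array; 0 at padded positions.

    By default the density factors over the three per-fixation features
    (log FD always; log SL and SD for non-final fixations). With
    ``include_aoi`` the AOI category is a fourth categorical factor.
    """
    mu_fd, sig_fd, mu_sl, sig_sl, lp_aoi, lp_sd = _emission_arrays(params)
    x = batch.log_fd[..., None]
    logB = (
        -0.5 * ((x - mu_fd) / sig_fd) ** 2
        - np.log(sig_fd)
        - 0.5 * _LOG2PI
    )
    if include_aoi:
        logB = logB + lp_aoi.T[batch.aoi]
    y = batch.log_sl[..., None]
    sacc = (
        -0.5 * ((y - mu_sl) / sig_sl) ** 2
        - np.log(sig_sl)
        - 0.5 * _LOG2PI
        + lp_sd.T[batch.sd]
    )
    logB = logB + np.where(batch.sacc_mask[..., None], sacc, 0.0)
    return np.where(batch.mask[..., None], logB, 0.0)


def _forward_pass(batch: SequenceBatch, params: BlockHMMParams, pi: np.ndarray,
                  keep: bool = False, include_aoi: bool = False):
    """Scaled forward pass.

    Returns (loglik (N,), alpha_final (N, n)) and, with ``keep``, the per-step
    scaled alphas, scale factors and scaled emission matrices needed by the
    backward pass. ``pi`` may be an unnormalized restriction of the joint
    initial distribution (class-masked), in which case loglik is the log mass
    of the surviving paths.
    """
    logB = _log_emissions(batch, params, include_aoi)
    N, T, n = logB.shape
    bmax = logB.max(axis=2)
    Bt = np.exp(logB - bmax[..., None])
    A = params.A
    alphas = np.empty((N, T, n)) if keep else None
    cs = np.empty((N, T)) if keep else None

    alpha = pi[None, :] * Bt[:, 0]
    c = alpha.sum(axis=1)
    dead = c <= 0.0
    c_safe = np.where(dead, 1.0, c)
    alpha = alpha / c_safe[:, None]
    loglik = np.where(dead, -np.inf, np.log(c_safe) + bmax[:, 0])
    if keep:
        alphas[:, 0] = alpha
        cs[:, 0] = c_safe
    for t in range(1, T):
        new = (alpha @ A) * Bt[:, t]
        c = new.sum(axis=1)
        c_safe = np.where(c <= 0.0, 1.0, c)
        upd = batch.mask[:, t]
        alpha = np.where(upd[:, None], new / c_safe[:, None], alpha)
        loglik = loglik + np.where(upd, np.log(c_safe) + bmax[:, t], 0.0)
        if keep:
            alphas[:, t] = alpha
            cs[:, t] = c_safe
    if keep:
        return loglik, alpha, alphas, cs, Bt
    return loglik, alpha


def forward_batch(seqs: Sequence[ObservationSequence] | SequenceBatch,
                  params: BlockHMMParams, *, include_aoi: bool = False):
    """Total log-likelihood and per-class terminal log mass for each trial.

    Returns ``(loglik (N,), class_log_mass (N, 2))`` with columns ordered as
    :data:`CLASSES`. Because the transition matrix is block-diagonal, the
    terminal forward mass inside a block equals the likelihood of all paths
    of that class.
    """
    batch = seqs if isinstance(seqs, SequenceBatch) else SequenceBatch(seqs)
    loglik, alpha = _forward_pass(batch, params, params.pi, include_aoi=include_aoi)
    out = np.full((len(batch.seqs), len(CLASSES)), -np.inf)
    with np.errstate(divide="ignore"):
        for j, cls in enumerate(CLASSES):
            idx = params.states_of(cls)
            share = alpha[:, idx].sum(axis=1)
            out[:, j] = np.where(share > 0, np.log(np.clip(share, 1e-300, None)) + loglik, -np.inf)
    return loglik, out


def log_forward(seq: ObservationSequence, params: BlockHMMParams,
                *, include_aoi: bool = False):
    """log P(X | lambda) and the per-class terminal log mass for one trial."""
    params.validate()
    loglik, mass = forward_batch([seq], params, include_aoi=include_aoi)
    return float(loglik[0]), {cls: float(mass[0, j]) for j, cls in enumerate(CLASSES)}


def viterbi(seq: ObservationSequence, params: BlockHMMParams,
            *, include_aoi: bool = False):
    """Most probable state path and its log joint probability.

    Ties are broken toward the lowest state index. The path never crosses
    class blocks because cross-block transitions have zero probability.
    """
    params.validate()
    batch = SequenceBatch([seq])
    logB = _log_emissions(batch, params, include_aoi)[0]
    T, n = logB.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.clip(params.pi, 1e-300, None))
        log_pi[params.pi <= 0] = -np.inf
        logA = np.where(params.A > 0, np.log(np.clip(params.A, 1e-300, None)), -np.inf)
    T = len(seq)
    delta = log_pi + logB[0]
    back = np.zeros((T, n), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(n)] + logB[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path.tolist(), float(delta[path[-1]])


# ---------------------------------------------------------------------------
# expected sufficient statistics (forward-backward)


def _expected_counts(batch: SequenceBatch, params: BlockHMMParams, pi: np.ndarray,
                     include_aoi: bool = False):
    """Posterior expected sufficient statistics under ``pi`` (possibly a
    class-masked restriction of the joint initial distribution).

    Returns (total loglik, counts dict). Count arrays: ``init`` (n,),
    ``trans`` (n, n), ``occ_fd``/``sum_fd``/``sum_fd2`` (n,),
    ``aoi`` (n, 4), ``occ_sl``/``sum_sl``/``sum_sl2`` (n,), ``sd`` (n, 4).
    """
    loglik, _, alphas, cs, Bt = _forward_pass(batch, params, pi, keep=True,
                                              include_aoi=include_aoi)
    N, T, n = alphas.shape
    A = params.A
    beta = np.ones((N, n))
    gammas = np.empty((N, T, n))
    gammas[:, T - 1] = alphas[:, T - 1] * beta
    trans = np.zeros((n, n))
    for t in range(T - 2, -1, -1):
        valid = batch.mask[:, t + 1]
        w = Bt[:, t + 1] * beta / cs[:, t + 1][:, None]
        trans += A * ((alphas[:, t] * valid[:, None]).T @ w)
        beta = np.where(valid[:, None], w @ A.T, beta)
        gammas[:, t] = alphas[:, t] * beta

    gm = gammas * batch.mask[..., None]
    gs = gammas * batch.sacc_mask[..., None]
    counts = {
        "init": gammas[:, 0].sum(axis=0),
        "trans": trans,
        "occ_fd": gm.sum(axis=(0, 1)),
        "sum_fd": np.einsum("ntk,nt->k", gm, batch.log_fd),
        "sum_fd2": np.einsum("ntk,nt->k", gm, batch.log_fd**2),
        "occ_sl": gs.sum(axis=(0, 1)),
        "sum_sl": np.einsum("ntk,nt->k", gs, batch.log_sl),
        "sum_sl2": np.einsum("ntk,nt->k", gs, batch.log_sl**2),
        "aoi": np.stack(
            [gm[(batch.aoi == k) & batch.mask].sum(axis=0) for k in range(4)], axis=1
        ),
        "sd": np.stack(
            [gs[(batch.sd == k) & batch.sacc_mask].sum(axis=0) for k in range(4)], axis=1
        ),
    }
    return float(loglik.sum()), counts


# ---------------------------------------------------------------------------
# generative training (Baum-Welch)


def _moment_init_emission(batch: SequenceBatch, rng: np.random.Generator) -> EmissionParams:
    """Seeded perturbation of the pooled moment estimates (restart init)."""
    fd = batch.log_fd[batch.mask]
    sl = batch.log_sl[batch.sacc_mask]
    mu_fd = float(fd.mean()) + rng.normal(0, max(fd.std(), 0.1))
    mu_sl = (float(sl.mean()) if sl.size else 3.5) + rng.normal(0, 0.5)
    return EmissionParams(
        mu_fd=mu_fd,
        sigma_fd=max(float(fd.std()), 0.2),
        mu_sl=mu_sl,
        sigma_sl=max(float(sl.std()) if sl.size else 0.5, 0.2),
        p_aoi=rng.dirichlet(np.full(4, 5.0)),
        p_sd=rng.dirichlet(np.full(4, 2.0)),
    )


def random_init(seqs: Sequence[ObservationSequence], spec: StateSpec,
                rng: np.random.Generator) -> BlockHMMParams:
    """Random starting point: perturbed global moments, sticky transitions."""
    batch = seqs if isinstance(seqs, SequenceBatch) else SequenceBatch(seqs)
    class_of_state = ("LFRR",) * spec.n_lfrr + ("RFLR",) * spec.n_rflr
    n = spec.n_states
    pi = rng.dirichlet(np.full(n, 2.0))
    A = np.zeros((n, n))
    offsets = {"LFRR": (0, spec.n_lfrr), "RFLR": (spec.n_lfrr, n)}
    for lo, hi in offsets.values():
        k = hi - lo
        for i in range(lo, hi):
            row = rng.dirichlet(np.full(k, 2.0))
            row = 0.5 * row + 0.5 * np.eye(k)[i - lo]  # sticky bias
            A[i, lo:hi] = row / row.sum()
    emissions = [_moment_init_emission(batch, rng) for _ in range(n)]
    return BlockHMMParams(pi=pi, A=A, emissions=emissions, class_of_state=class_of_state)


@dataclass
class _BlockView:
    """One class block seen as a stand-alone HMM (duck-typed for the
    forward/backward helpers, which only touch ``A`` and ``emissions``)."""

    A: np.ndarray
    emissions: list[EmissionParams]


def _mstep_block(counts: dict, old, idx: np.ndarray,
                 batch: SequenceBatch, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, list[EmissionParams]]:
    """Closed-form M-step for the states ``idx`` of one block view."""
    init = counts["init"][idx]
    trans = counts["trans"][np.ix_(idx, idx)]
    pi_block = init / init.sum() if init.sum() > 0 else np.full(len(idx), 1.0 / len(idx))
    rows = trans.sum(axis=1, keepdims=True)
    A_block = np.where(rows > 0, trans / np.where(rows > 0, rows, 1.0),
                       np.full_like(trans, 1.0 / len(idx)))
    emissions = []
    for j, i in enumerate(idx):
        occ = counts["occ_fd"][i]
        if occ < 1e-8:
            warnings.warn(f"state {i} starved during Baum-Welch; re-seeding its emissions")
            emissions.append(_moment_init_emission(batch, rng))
            continue
        mu_fd = counts["sum_fd"][i] / occ
        var_fd = max(counts["sum_fd2"][i] / occ - mu_fd**2, _SIGMA_FLOOR**2)
        p_aoi = counts["aoi"][i] / occ
        occ_sl = counts["occ_sl"][i]
        old_em = old.emissions[i]
        if occ_sl > 1e-8:
            mu_sl = counts["sum_sl"][i] / occ_sl
            var_sl = max(counts["sum_sl2"][i] / occ_sl - mu_sl**2, _SIGMA_FLOOR**2)
            p_sd = counts["sd"][i] / occ_sl
        else:  # state saw only final fixations; keep previous saccade params
            mu_sl, var_sl, p_sd = old_em.mu_sl, old_em.sigma_sl**2, old_em.p_sd
        p_aoi = np.clip(p_aoi, _PROB_FLOOR, None)
        p_sd = np.clip(p_sd, _PROB_FLOOR, None)
        emissions.append(
            EmissionParams(
                mu_fd=float(mu_fd), sigma_fd=float(np.sqrt(var_fd)),
                mu_sl=float(mu_sl), sigma_sl=float(np.sqrt(var_sl)),
                p_aoi=p_aoi / p_aoi.sum(), p_sd=p_sd / p_sd.sum(),
            )
        )
    return pi_block, A_block, emissions


def baum_welch(
    seqs: Sequence[ObservationSequence],
    init: BlockHMMParams,
    *,
    tol: float = 1e-3,
    max_iter: int = 100,
    rng: np.random.Generator | None = None,
    include_aoi: bool = False,
) -> FitResult:
    """Labelled Baum-Welch: per-block EM with jointly normalized pi.

    Each sequence's responsibilities are confined to the block of its label,
    so this is per-class Baum-Welch; the joint initial distribution assigns
    each block its empirical class frequency times the within-block initial
    distribution, and therefore encodes the class prior. The per-iteration
    total log-likelihood (recorded in ``history``) is non-decreasing.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    params = init.copy()
    labels = np.array([s.strategy for s in seqs])
    batches = {}
    for cls in CLASSES:
        sel = [s for s, lab in zip(seqs, labels) if lab == cls]
        if sel:
            batches[cls] = SequenceBatch(sel)
    if not batches:
        raise ValueError("no labelled sequences")
    n_total = sum(len(b.seqs) for b in batches.values())

    n = params.n_states
    new_pi = params.pi.copy()
    new_A = params.A.copy()
    new_emissions = list(params.emissions)
    histories: list[list[float]] = []
    for cls, batch in batches.items():
        idx = params.states_of(cls)
        k = len(idx)
        # each block is an independent reduced HMM; fit it on its own batch
        sub = _BlockView(
            A=params.A[np.ix_(idx, idx)].copy(),
            emissions=[params.emissions[i] for i in idx],
        )
        pi_b = params.pi[idx] / params.pi[idx].sum()
        hist: list[float] = []
        for _ in range(max_iter):
            ll, counts = _expected_counts(batch, sub, pi_b, include_aoi)
            hist.append(ll)
            pi_b, sub.A, sub.emissions = _mstep_block(
                counts, sub, np.arange(k), batch, rng
            )
            if len(hist) >= 2 and abs(hist[-1] - hist[-2]) < tol:
                break
        ll, _ = _forward_pass(batch, sub, pi_b, include_aoi=include_aoi)
        hist.append(float(ll.sum()))
        histories.append(hist)
        new_pi[idx] = (len(batch.seqs) / n_total) * pi_b
        new_A[np.ix_(idx, idx)] = sub.A
        for j, i in enumerate(idx):
            new_emissions[i] = sub.emissions[j]
    params = BlockHMMParams(
        pi=new_pi / new_pi.sum(), A=new_A, emissions=new_emissions,
        class_of_state=params.class_of_state,
    )
    # total-likelihood trace: pad each block's trace with its final value
    L = max(len(h) for h in histories)
    history = [
        sum(h[min(t, len(h) - 1)] for h in histories) for t in range(L)
    ]
    return FitResult(params=params, history=history)


def fit_generative(
    seqs: Sequence[ObservationSequence],
    spec: StateSpec,
    *,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 100,
    polish_max_iter: int = 1500,
    polish_tol: float = 1e-5,
    include_aoi: bool = False,
) -> FitResult:
    """Best-of-``restarts`` Baum-Welch from seeded moment-perturbation inits.

    Each restart runs a moderate number of EM iterations, enough to rank the
    basins of attraction; the best restart is then polished to a much tighter
    tolerance. EM creeps slowly near the optimum when emission distributions
    overlap, so the polish phase is what makes low-occupancy states converge.
    """
    best: FitResult | None = None
    master = np.random.default_rng(seed)
    for _ in range(restarts):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        init = random_init(seqs, spec, rng)
        res = baum_welch(seqs, init, tol=tol, max_iter=max_iter, rng=rng,
                         include_aoi=include_aoi)
        if best is None or res.final_objective > best.final_objective:
            best = res
    if polish_max_iter > 0:
        polished = baum_welch(seqs, best.params.copy(), tol=polish_tol,
                              max_iter=polish_max_iter, include_aoi=include_aoi)
        return FitResult(params=polished.params,
                         history=best.history + polished.history)
    return best


# ---------------------------------------------------------------------------
# discriminative training


def conditional_log_likelihood(seqs: Sequence[ObservationSequence],
                               params: BlockHMMParams,
                               *, include_aoi: bool = False) -> float:
    """sum_n log P(c_n | X_n, lambda) over labelled sequences."""
    batch = seqs if isinstance(seqs, SequenceBatch) else SequenceBatch(seqs)
    loglik, mass = forward_batch(batch, params, include_aoi=include_aoi)
    cls_idx = np.array([CLASSES.index(lab) for lab in batch.labels])
    own = mass[np.arange(len(cls_idx)), cls_idx]
    if not np.all(np.isfinite(loglik)):
        warnings.warn("zero total likelihood for some sequence; returning -inf")
        return float("-inf")
    return float(np.sum(own - loglik))


@dataclass
class _Unconstrained:
    """Log-odds / log-sigma reparameterization of BlockHMMParams.

    ``u_pi`` is a joint softmax over all states; each block row of ``u_A`` is
    a softmax within its block; categorical emissions are row softmaxes;
    sigmas are exponentials. Gradients of the conditional log-likelihood in
    this space are the difference between block-restricted and full-model
    expected counts, pushed through the softmax Jacobian.
    """

    u_pi: np.ndarray
    u_A: np.ndarray  # (n, n), only within-block entries meaningful
    mu_fd: np.ndarray
    ls_fd: np.ndarray
    mu_sl: np.ndarray
    ls_sl: np.ndarray
    u_aoi: np.ndarray
    u_sd: np.ndarray
    class_of_state: tuple[str, ...]

    @staticmethod
    def _softmax(u: np.ndarray, axis=-1) -> np.ndarray:
        z = u - u.max(axis=axis, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=axis, keepdims=True)

    @classmethod
    def from_params(cls, params: BlockHMMParams) -> "_Unconstrained":
        n = params.n_states
        u_A = np.zeros((n, n))
        for c in CLASSES:
            idx = params.states_of(c)
            block = np.log(np.clip(params.A[np.ix_(idx, idx)], _PROB_FLOOR, None))
            u_A[np.ix_(idx, idx)] = block
        return cls(
            u_pi=np.log(np.clip(params.pi, _PROB_FLOOR, None)),
            u_A=u_A,
            mu_fd=np.array([e.mu_fd for e in params.emissions]),
            ls_fd=np.log([e.sigma_fd for e in params.emissions]),
            mu_sl=np.array([e.mu_sl for e in params.emissions]),
            ls_sl=np.log([e.sigma_sl for e in params.emissions]),
            u_aoi=np.log(np.clip(np.stack([e.p_aoi for e in params.emissions]), _PROB_FLOOR, None)),
            u_sd=np.log(np.clip(np.stack([e.p_sd for e in params.emissions]), _PROB_FLOOR, None)),
            class_of_state=params.class_of_state,
        )

    def to_params(self) -> BlockHMMParams:
        n = len(self.u_pi)
        pi = self._softmax(self.u_pi)
        A = np.zeros((n, n))
        blocks = {}
        for c in CLASSES:
            idx = np.array([i for i, cc in enumerate(self.class_of_state) if cc == c])
            blocks[c] = idx
            A[np.ix_(idx, idx)] = self._softmax(self.u_A[np.ix_(idx, idx)], axis=1)
        p_aoi = self._softmax(self.u_aoi, axis=1)
        p_sd = self._softmax(self.u_sd, axis=1)
        sig_fd = np.maximum(np.exp(self.ls_fd), _SIGMA_FLOOR)
        sig_sl = np.maximum(np.exp(self.ls_sl), _SIGMA_FLOOR)
        emissions = [
            EmissionParams(
                mu_fd=float(self.mu_fd[i]), sigma_fd=float(sig_fd[i]),
                mu_sl=float(self.mu_sl[i]), sigma_sl=float(sig_sl[i]),
                p_aoi=p_aoi[i], p_sd=p_sd[i],
            )
            for i in range(n)
        ]
        return BlockHMMParams(pi=pi, A=A, emissions=emissions,
                              class_of_state=self.class_of_state)

    def vector(self) -> np.ndarray:
        return np.concatenate([
            self.u_pi, self.u_A.ravel(), self.mu_fd, self.ls_fd,
            self.mu_sl, self.ls_sl, self.u_aoi.ravel(), self.u_sd.ravel(),
        ])

    def with_vector(self, v: np.ndarray) -> "_Unconstrained":
        n = len(self.u_pi)
        parts = np.split(v, np.cumsum([n, n * n, n, n, n, n, 4 * n]))
        return _Unconstrained(
            u_pi=parts[0], u_A=parts[1].reshape(n, n),
            mu_fd=parts[2], ls_fd=parts[3], mu_sl=parts[4], ls_sl=parts[5],
            u_aoi=parts[6].reshape(n, 4), u_sd=parts[7].reshape(n, 4),
            class_of_state=self.class_of_state,
        )


def _cll_and_grad(batches: dict[str, SequenceBatch], u: _Unconstrained,
                  include_aoi: bool = False):
    """Conditional log-likelihood and its gradient in unconstrained space."""
    params = u.to_params()
    n = params.n_states
    diff = {
        k: 0.0
        for k in ("init", "trans", "occ_fd", "sum_fd", "sum_fd2",
                  "occ_sl", "sum_sl", "sum_sl2", "aoi", "sd")
    }
    cll = 0.0
    for cls, batch in batches.items():
        idx = params.states_of(cls)
        pi_masked = np.zeros(n)
        pi_masked[idx] = params.pi[idx]  # unnormalized block restriction
        ll_block, counts_block = _expected_counts(batch, params, pi_masked, include_aoi)
        ll_full, counts_full = _expected_counts(batch, params, params.pi, include_aoi)
        cll += ll_block - ll_full
        for k in diff:
            diff[k] = diff[k] + counts_block[k] - counts_full[k]

    sig_fd = np.maximum(np.exp(u.ls_fd), _SIGMA_FLOOR)
    sig_sl = np.maximum(np.exp(u.ls_sl), _SIGMA_FLOOR)
    g = _Unconstrained(
        u_pi=diff["init"] - params.pi * diff["init"].sum(),
        u_A=np.zeros((n, n)),
        mu_fd=(diff["sum_fd"] - u.mu_fd * diff["occ_fd"]) / sig_fd**2,
        ls_fd=(diff["sum_fd2"] - 2 * u.mu_fd * diff["sum_fd"] + u.mu_fd**2 * diff["occ_fd"])
        / sig_fd**2 - diff["occ_fd"],
        mu_sl=(diff["sum_sl"] - u.mu_sl * diff["occ_sl"]) / sig_sl**2,
        ls_sl=(diff["sum_sl2"] - 2 * u.mu_sl * diff["sum_sl"] + u.mu_sl**2 * diff["occ_sl"])
        / sig_sl**2 - diff["occ_sl"],
        u_aoi=diff["aoi"] - params.pi[:, None] * 0.0,  # placeholder, set below
        u_sd=np.zeros((n, 4)),
        class_of_state=u.class_of_state,
    )
    p_aoi = np.stack([e.p_aoi for e in params.emissions])
    p_sd = np.stack([e.p_sd for e in params.emissions])
    # p_aoi enters the objective only when the AOI factor is in the density
    if include_aoi:
        g.u_aoi = diff["aoi"] - p_aoi * diff["aoi"].sum(axis=1, keepdims=True)
    else:
        g.u_aoi = np.zeros((n, 4))
    g.u_sd = diff["sd"] - p_sd * diff["sd"].sum(axis=1, keepdims=True)
    for c in CLASSES:
        idx = params.states_of(c)
        t = diff["trans"][np.ix_(idx, idx)]
        Ab = params.A[np.ix_(idx, idx)]
        g.u_A[np.ix_(idx, idx)] = t - Ab * t.sum(axis=1, keepdims=True)
    return cll, g


def discriminative_train(
    seqs: Sequence[ObservationSequence],
    init: BlockHMMParams,
    *,
    tol: float = 1e-4,
    max_iter: int = 100,
    lr: float = 1e-3,
    include_aoi: bool = False,
) -> FitResult:
    """Gradient ascent on the conditional log-likelihood.

    Parameters stay valid throughout (softmax / log-sigma reparameterization);
    steps are accepted only if the objective does not decrease, with the
    learning rate halved on rejection, so the recorded history is
    non-decreasing. Stops when the improvement falls below ``tol`` (absolute,
    per call) or after ``max_iter`` accepted iterations.
    """
    batches: dict[str, SequenceBatch] = {}
    for cls in CLASSES:
        sel = [s for s in seqs if s.strategy == cls]
        if sel:
            batches[cls] = SequenceBatch(sel)
    u = _Unconstrained.from_params(init)
    cll, grad = _cll_and_grad(batches, u, include_aoi)
    history = [cll]
    n_seq = sum(len(b.seqs) for b in batches.values())
    step = lr
    for _ in range(max_iter):
        gvec = grad.vector() / max(n_seq, 1)
        if not np.all(np.isfinite(gvec)):
            warnings.warn("non-finite gradient; halving step and retrying")
            step /= 2.0
            if step < 1e-12:
                break
            continue
        accepted = False
        for _try in range(30):
            cand = u.with_vector(u.vector() + step * gvec)
            cand_cll, cand_grad = _cll_and_grad(batches, cand, include_aoi)
            if np.isfinite(cand_cll) and cand_cll >= cll - 1e-12:
                improved = cand_cll - cll
                u, cll, grad = cand, cand_cll, cand_grad
                history.append(cll)
                step = min(step * 1.2, 1.0)
                accepted = True
                break
            step /= 2.0
            if step < 1e-12:
                break
        if not accepted:
            warnings.warn("discriminative training: no acceptable step found; "
                          "returning best parameters so far")
            break
        if improved < tol:
            break
    return FitResult(params=u.to_params(), history=history)


def fit_dhmm(
    seqs: Sequence[ObservationSequence],
    spec: StateSpec,
    *,
    restarts: int = 10,
    seed: int = 0,
    bw_tol: float = 1e-3,
    bw_max_iter: int = 100,
    polish_max_iter: int = 300,
    disc_tol: float = 1e-4,
    disc_max_iter: int = 100,
    discriminative: bool = True,
    include_aoi: bool = False,
) -> FitResult:
    """Full training protocol: restarted Baum-Welch, then discriminative refinement."""
    gen = fit_generative(seqs, spec, restarts=restarts, seed=seed,
                         tol=bw_tol, max_iter=bw_max_iter,
                         polish_max_iter=polish_max_iter, include_aoi=include_aoi)
    if not discriminative:
        return gen
    return discriminative_train(seqs, gen.params, tol=disc_tol,
                                max_iter=disc_max_iter, include_aoi=include_aoi)


# ---------------------------------------------------------------------------
# classification and sampling


def classify(seq: ObservationSequence, params: BlockHMMParams,
             *, include_aoi: bool = False) -> ClassPosterior:
    """Posterior strategy probabilities for one trial (Bayes on block masses)."""
    _, mass = forward_batch([seq], params, include_aoi=include_aoi)
    m = mass[0]
    z = m - m.max()
    p = np.exp(z)
    p = p / p.sum()
    return ClassPosterior(p_lfrr=float(p[0]), p_rflr=float(p[1]))


def classify_batch(seqs: Sequence[ObservationSequence] | SequenceBatch,
                   params: BlockHMMParams, *, include_aoi: bool = False):
    """Predicted labels and posterior matrix (N, 2) for a set of trials."""
    _, mass = forward_batch(seqs, params, include_aoi=include_aoi)
    z = mass - mass.max(axis=1, keepdims=True)
    p = np.exp(z)
    p = p / p.sum(axis=1, keepdims=True)
    labels = [CLASSES[0] if row[0] >= row[1] else CLASSES[1] for row in p]
    return labels, p


def sample_sequence(
    params: BlockHMMParams,
    cls: str,
    length: int,
    rng: np.random.Generator,
    *,
    subject_id: str = "sim",
    trial_id: str = "t0",
) -> ObservationSequence:
    """Draw one trial of the given class from the generative model.

    The state path is drawn from the block-renormalized initial distribution
    and the class's transition block. The first AOI is drawn from the first
    state's AOI distribution; each saccade direction is drawn from the current
    state's SD distribution and the next AOI is the one the SD code implies,
    so the emitted scanpath is self-consistent (coding the generated AOI
    stream back through the SD map reproduces the SD stream exactly).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    idx = params.states_of(cls)
    pi_block = params.pi[idx] / params.pi[idx].sum()
    A_block = params.A[np.ix_(idx, idx)]
    k = len(idx)
    states = np.zeros(length, dtype=int)
    states[0] = rng.choice(k, p=pi_block)
    for t in range(1, length):
        states[t] = rng.choice(k, p=A_block[states[t - 1]])
    events: list[ObservationEvent] = []
    aoi = int(rng.choice(4, p=params.emissions[idx[states[0]]].p_aoi)) + 1
    for t in range(length):
        em = params.emissions[idx[states[t]]]
        log_fd = float(rng.normal(em.mu_fd, em.sigma_fd))
        if t < length - 1:
            sd = int(rng.choice(4, p=em.p_sd)) + 1
            log_sl = float(rng.normal(em.mu_sl, em.sigma_sl))
            events.append(ObservationEvent(log_fd=log_fd, aoi=aoi, log_sl=log_sl, sd=sd))
            aoi = target_aoi(aoi, sd)
        else:
            events.append(ObservationEvent(log_fd=log_fd, aoi=aoi))
    return ObservationSequence(subject_id=subject_id, strategy=cls,
                               trial_id=trial_id, events=events)


class DhmmClassifier:
    """Estimator-style wrapper around the dHMM training protocol.

    ``fit`` takes observation sequences and labels; ``predict`` ignores the
    sequences' own strategy attribute so held-out evaluation cannot leak.
    """

    def __init__(self, spec: StateSpec = StateSpec(3, 3), *, restarts: int = 10,
                 seed: int = 0, discriminative: bool = True,
                 bw_max_iter: int = 100, polish_max_iter: int = 300,
                 disc_max_iter: int = 100):
        self.spec = spec
        self.restarts = restarts
        self.seed = seed
        self.discriminative = discriminative
        self.bw_max_iter = bw_max_iter
        self.polish_max_iter = polish_max_iter
        self.disc_max_iter = disc_max_iter
        self.params_: BlockHMMParams | None = None

    def fit(self, seqs: Sequence[ObservationSequence], labels: Sequence[str] | None = None):
        if labels is not None:
            seqs = [
                ObservationSequence(s.subject_id, lab, s.trial_id, s.events)
                for s, lab in zip(seqs, labels)
            ]
        res = fit_dhmm(
            seqs, self.spec, restarts=self.restarts, seed=self.seed,
            discriminative=self.discriminative,
            bw_max_iter=self.bw_max_iter, polish_max_iter=self.polish_max_iter,
            disc_max_iter=self.disc_max_iter,
        )
        self.params_ = res.params
        return self

    def predict(self, seqs: Sequence[ObservationSequence]) -> list[str]:
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        labels, _ = classify_batch(seqs, self.params_)
        return labels

    def predict_proba(self, seqs: Sequence[ObservationSequence]) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        _, p = classify_batch(seqs, self.params_)
        return p
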