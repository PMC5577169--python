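"""Synthetic labelled scanpath corpora, raw fixation tables and behavioural RTs.

The generator mirrors the generative reading of the fitted block HMM: its
default parameters are the published values of the three-state-per-strategy
model (initial probabilities, per-state emission marginals, and the four
text-reported leave probabilities of the transition structure), so every stage
of the analysis pipeline can be exercised and checked against those values
without any raw recordings.

Defaults that the model tables do not pin down are fixed here once: log-space
sigma 0.5 for the log-normal fixation-duration and saccade-length emissions
(the printed values are treated as back-transformed medians), equal splits for
transition mass the text does not enumerate, a negative-binomial sequence
length (mean 20, dispersion 5, minimum 1), and a 1e-3 floor on zero
categorical cells so generated corpora are not degenerate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .features import AOI_NAMES, AOILayout, Fixation, ObservationSequence
from .hmm import CLASSES, BlockHMMParams, EmissionParams, sample_sequence

__all__ = [
    "GeneratorConfig",
    "StimulusDesign",
    "Corpus",
    "default_layout",
    "default_params",
    "simulate_trial",
    "simulate_corpus",
    "simulate_rt",
    "enumerate_stimuli",
]

#: names of the three per-strategy processing states, in model order
STATE_NAMES = ("encoding_searching", "comparison", "searching_one_side")

_CAT_FLOOR = 1e-3  # floor on zero categorical cells in the generating model

# published per-strategy parameter tables: initial probabilities, FD / SL
# medians (ms / px), AOI occupancy and saccade-direction rows per state
_TABLE = {
    "LFRR": {
        "pi": [0.09, 0.05, 0.35],
        "fd": [96.0, 170.0, 179.0],
        "sl": [37.0, 67.0, 52.0],
        "p_aoi": [
            [0.44, 0.14, 0.29, 0.13],
            [0.28, 0.21, 0.31, 0.20],
            [0.18, 0.18, 0.39, 0.26],
        ],
        "p_sd": [
            [0.89, 0.04, 0.05, 0.02],
            [0.00, 0.01, 0.68, 0.31],
            [0.56, 0.43, 0.00, 0.01],
        ],
        "leave_e": 0.68,
        "leave_s": 0.71,
    },
    "RFLR": {
        "pi": [0.15, 0.04, 0.31],
        "fd": [108.0, 162.0, 172.0],
        "sl": [33.0, 69.0, 59.0],
        "p_aoi": [
            [0.57, 0.14, 0.21, 0.08],
            [0.32, 0.21, 0.30, 0.17],
            [0.46, 0.22, 0.18, 0.14],
        ],
        "p_sd": [
            [0.94, 0.03, 0.02, 0.01],
            [0.02, 0.01, 0.66, 0.31],
            [0.43, 0.49, 0.05, 0.03],
        ],
        "leave_e": 0.60,
        "leave_s": 0.78,
    },
}


def _floored(v) -> np.ndarray:
    p = np.clip(np.asarray(v, dtype=float), _CAT_FLOOR, None)
    return p / p.sum()


def _block_transitions(leave_e: float, leave_s: float) -> np.ndarray:
    """3x3 block for states (e, c, s): text-reported leave probabilities from
    e and s split equally between the two other states; uniform from c."""
    A = np.zeros((3, 3))
    A[0] = [1.0 - leave_e, leave_e / 2.0, leave_e / 2.0]
    A[1] = [1.0 / 3.0] * 3
    A[2] = [leave_s / 2.0, leave_s / 2.0, 1.0 - leave_s]
    return A


def default_params(*, log_sigma_fd: float = 0.5, log_sigma_sl: float = 0.5) -> BlockHMMParams:
    """The default generating model built from the published parameter tables.

    The printed FD / SL values are taken as back-transformed medians, so the
    Gaussian means on the log scale are their logs; the log-space sigma is a
    configurable convention (default 0.5). The joint initial distribution is
    the concatenated per-strategy columns renormalized to exactly 1.
    """
    pi = np.array(_TABLE["LFRR"]["pi"] + _TABLE["RFLR"]["pi"], dtype=float)
    pi = pi / pi.sum()
    A = np.zeros((6, 6))
    emissions: list[EmissionParams] = []
    for b, cls in enumerate(CLASSES):
        tab = _TABLE[cls]
        A[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = _block_transitions(
            tab["leave_e"], tab["leave_s"]
        )
        for s in range(3):
            emissions.append(
                EmissionParams(
                    mu_fd=float(np.log(tab["fd"][s])),
                    sigma_fd=log_sigma_fd,
                    mu_sl=float(np.log(tab["sl"][s])),
                    sigma_sl=log_sigma_sl,
                    p_aoi=_floored(tab["p_aoi"][s]),
                    p_sd=_floored(tab["p_sd"][s]),
                )
            )
    params = BlockHMMParams(
        pi=pi, A=A, emissions=emissions,
        class_of_state=("LFRR",) * 3 + ("RFLR",) * 3,
    )
    params.validate()
    return params


def default_layout() -> AOILayout:
    """Four rectangular AOIs on a 1920x1080 screen: upper/lower arm of the
    left and right figure, separated by small gaps so regions are disjoint."""
    return AOILayout(
        {
            "L1": {"x0": 330, "y0": 340, "x1": 630, "y1": 536},
            "L2": {"x0": 330, "y0": 544, "x1": 630, "y1": 740},
            "R1": {"x0": 1290, "y0": 340, "x1": 1590, "y1": 536},
            "R2": {"x0": 1290, "y0": 544, "x1": 1590, "y1": 740},
        }
    )


@dataclass(frozen=True)
class StimulusDesign:
    """Factorial stimulus design: angles x axes x identities x symmetries."""

    angles: tuple[int, ...] = (0, 30, 60, 90, 120, 150, 180)
    axes: tuple[str, ...] = ("x", "z")
    identities: tuple[str, ...] = ("identical", "mirrored")
    symmetries: tuple[str, ...] = ("left-shift", "right-shift")


def enumerate_stimuli(design: StimulusDesign = StimulusDesign()) -> pd.DataFrame:
    """All cells of the factorial design, in stable lexicographic order."""
    rows = [
        {"angle": a, "axis": ax, "identity": ident, "symmetry": sym}
        for a, ax, ident, sym in itertools.product(
            design.angles, design.axes, design.identities, design.symmetries
        )
    ]
    return pd.DataFrame(rows)


@dataclass
class GeneratorConfig:
    """Study-level configuration of the synthetic corpus.

    The defaults emulate the published study scale: 15 retained subjects,
    two strategy sessions of 56 trials each -> 1680 sequences, split 80/20
    into 1344 training and 336 test trials.
    """

    params: BlockHMMParams = field(default_factory=default_params)
    n_per_class: int = 840
    n_subjects: int = 15
    length_mean: float = 20.0
    length_dispersion: float = 5.0
    seed: int = 0
    layout: AOILayout = field(default_factory=default_layout)
    train_fraction: float = 0.8
    rt_intercept: float = 1500.0
    rt_slope_lfrr: float = 13.340
    rt_slope_rflr: float = 11.377
    rt_noise_sd: float = 300.0
    saccade_gap_ms: float = 30.0

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "layout": self.layout.to_dict(),
        }
        for k in (
            "n_per_class", "n_subjects", "length_mean", "length_dispersion",
            "seed", "train_fraction", "rt_intercept", "rt_slope_lfrr",
            "rt_slope_rflr", "rt_noise_sd", "saccade_gap_ms",
        ):
            d[k] = getattr(self, k)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["params"] = BlockHMMParams.from_dict(d["params"])
        d["layout"] = AOILayout.from_dict(d["layout"])
        return cls(**d)


def _sample_length(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    """Negative-binomial trial length (mean, dispersion) with a floor of 1."""
    r = cfg.length_dispersion
    p = r / (r + cfg.length_mean)
    return max(1, int(rng.negative_binomial(r, p)))


def simulate_trial(
    cfg: GeneratorConfig,
    cls: str,
    rng: np.random.Generator,
    *,
    subject_id: str = "sim",
    trial_id: str = "t0",
    with_raw: bool = False,
):
    """One labelled trial; optionally also its raw fixation-table rows.

    Raw rows place each fixation uniformly inside its AOI rectangle with
    onsets accumulated from the drawn durations, so re-coding them through
    the feature extractor reproduces the generated AOI and SD streams
    exactly (the saccade lengths are then the distances between the placed
    points rather than the drawn log-normal values).
    """
    length = _sample_length(cfg, rng)
    seq = sample_sequence(
        cfg.params, cls, length, rng, subject_id=subject_id, trial_id=trial_id
    )
    if not with_raw:
        return seq
    fixations = []
    onset = 0.0
    for i, ev in enumerate(seq.events):
        poly = cfg.layout.polygons[AOI_NAMES[ev.aoi - 1]]
        x0, y0, x1, y1 = poly.bounds
        while True:  # rejection sampling handles polygonal regions too
            x = rng.uniform(x0, x1)
            y = rng.uniform(y0, y1)
            if poly.covers(Point(x, y)):
                break
        duration = float(np.exp(ev.log_fd))
        fixations.append(
            Fixation(
                subject_id=subject_id, strategy=cls, trial_id=trial_id,
                index=i, onset=onset, duration=duration, x=x, y=y,
            )
        )
        onset += duration + cfg.saccade_gap_ms
    return seq, fixations


@dataclass
class Corpus:
    """A labelled synthetic corpus with a fixed train/test split."""

    sequences: list[ObservationSequence]
    train_idx: np.ndarray
    test_idx: np.ndarray
    config: GeneratorConfig

    @property
    def train(self) -> list[ObservationSequence]:
        return [self.sequences[i] for i in self.train_idx]

    @property
    def test(self) -> list[ObservationSequence]:
        return [self.sequences[i] for i in self.test_idx]


def simulate_corpus(cfg: GeneratorConfig | None = None, *, with_raw: bool = False):
    """Balanced labelled corpus with a seeded stratified train/test split.

    With defaults: 840 trials per strategy (1680 total), subject identifiers
    assigned round-robin over 15 subjects, and an 80/20 split (1344 / 336)
    stratified by strategy. With ``with_raw`` the matching raw fixation rows
    are returned as well.
    """
    cfg = cfg if cfg is not None else GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    sequences: list[ObservationSequence] = []
    raw_rows: list[Fixation] = []
    for cls in CLASSES:
        for i in range(cfg.n_per_class):
            subject = f"s{(i % cfg.n_subjects) + 1:02d}"
            trial = f"{cls}_{i:04d}"
            out = simulate_trial(
                cfg, cls, rng, subject_id=subject, trial_id=trial, with_raw=with_raw
            )
            if with_raw:
                seq, fixes = out
                raw_rows.extend(fixes)
            else:
                seq = out
            sequences.append(seq)
    # stratified split: permute within each class, take the first 80%
    split_rng = np.random.default_rng(cfg.seed + 1)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in CLASSES:
        idx = np.array([i for i, s in enumerate(sequences) if s.strategy == cls])
        idx = split_rng.permutation(idx)
        n_train = int(round(cfg.train_fraction * len(idx)))
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    corpus = Corpus(
        sequences=sequences,
        train_idx=np.array(sorted(train_idx)),
        test_idx=np.array(sorted(test_idx)),
        config=cfg,
    )
    if with_raw:
        return corpus, raw_rows
    return corpus


def simulate_rt(
    design: StimulusDesign = StimulusDesign(),
    *,
    slope: float,
    intercept: float,
    noise_sd: float,
    n_subjects: int = 15,
    n_trials_per_angle: int = 8,
    rng: np.random.Generator,
    rt_cap: float = 8000.0,
) -> pd.DataFrame:
    """Reaction times with a linear angle effect, truncated at the response cap.

    RT = intercept + slope * angle + Gaussian(0, noise_sd), clipped to
    [0, rt_cap] (trials hitting the presentation limit are recorded at the
    cap). One row per subject x angle x trial.
    """
    if slope < 0 or noise_sd < 0:
        raise ValueError("slope and noise_sd must be >= 0")
    rows = []
    for subj in range(1, n_subjects + 1):
        for angle in design.angles:
            rts = intercept + slope * angle + rng.normal(0.0, noise_sd, n_trials_per_angle)
            rts = np.clip(rts, 0.0, rt_cap)
            for j, rt in enumerate(rts):
                rows.append(
                    {"subject": f"s{subj:02d}", "angle": angle, "trial": j, "rt": float(rt)}
                )
    return pd.DataFrame(rows)
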