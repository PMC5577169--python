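"""Plain-text readers and writers for the pipeline's interchange formats.

Fixation tables and coded sequences are tab-separated with headers; AOI
layouts, model parameters and generator configs are JSON. All formats
round-trip through their reader/writer pair.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import (
    AOILayout,
    Fixation,
    ObservationEvent,
    ObservationSequence,
    summary_features,
)
from .hmm import BlockHMMParams

__all__ = [
    "FIXATION_COLUMNS",
    "read_fixation_table",
    "write_fixation_table",
    "read_layout",
    "write_layout",
    "read_params",
    "write_params",
    "write_sequences",
    "read_sequences",
    "write_feature_matrix",
    "read_feature_matrix",
]

FIXATION_COLUMNS = [
    "subject_id", "strategy", "trial_id", "fixation_index",
    "onset_ms", "duration_ms", "x_px", "y_px",
]


def write_fixation_table(fixations: Iterable[Fixation], path) -> None:
    rows = [
        {
            "subject_id": f.subject_id, "strategy": f.strategy,
            "trial_id": f.trial_id, "fixation_index": f.index,
            "onset_ms": f.onset, "duration_ms": f.duration,
            "x_px": f.x, "y_px": f.y,
        }
        for f in fixations
    ]
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fixation_table(path) -> dict[tuple[str, str], list[Fixation]]:
    """Fixations grouped per (subject_id, trial_id), ordered by onset."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "trial_id": str},
                     float_precision="round_trip")
    missing = set(FIXATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation table missing columns: {sorted(missing)}")
    trials: dict[tuple[str, str], list[Fixation]] = {}
    for row in df.itertuples(index=False):
        fx = Fixation(
            subject_id=row.subject_id, strategy=row.strategy, trial_id=row.trial_id,
            index=int(row.fixation_index), onset=float(row.onset_ms),
            duration=float(row.duration_ms), x=float(row.x_px), y=float(row.y_px),
        )
        trials.setdefault((fx.subject_id, fx.trial_id), []).append(fx)
    for key in trials:
        trials[key].sort(key=lambda f: f.onset)
    return trials


def write_layout(layout: AOILayout, path) -> None:
    Path(path).write_text(json.dumps(layout.to_dict(), indent=2))


def read_layout(path) -> AOILayout:
    return AOILayout.from_dict(json.loads(Path(path).read_text()))


def write_params(params: BlockHMMParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


def read_params(path) -> BlockHMMParams:
    return BlockHMMParams.from_dict(json.loads(Path(path).read_text()))


def write_sequences(seqs: Sequence[ObservationSequence], path) -> None:
    """One row per retained fixation with its coded features; the final
    fixation of each trial has empty sd / log_sl cells."""
    rows = []
    for s in seqs:
        for i, ev in enumerate(s.events):
            rows.append(
                {
                    "subject_id": s.subject_id, "strategy": s.strategy,
                    "trial_id": s.trial_id, "fixation_index": i,
                    "aoi": ev.aoi,
                    "sd": ev.sd if ev.sd is not None else "",
                    "log_fd": repr(ev.log_fd),
                    "log_sl": repr(ev.log_sl) if ev.log_sl is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sequences(path) -> list[ObservationSequence]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "trial_id": str},
                     float_precision="round_trip")
    seqs: list[ObservationSequence] = []
    for (subj, trial), g in df.groupby(["subject_id", "trial_id"], sort=False):
        g = g.sort_values("fixation_index")
        events = []
        for row in g.itertuples(index=False):
            has_sacc = not (pd.isna(row.sd) or row.sd == "")
            events.append(
                ObservationEvent(
                    log_fd=float(row.log_fd),
                    aoi=int(row.aoi),
                    log_sl=float(row.log_sl) if has_sacc else None,
                    sd=int(row.sd) if has_sacc else None,
                )
            )
        seqs.append(
            ObservationSequence(
                subject_id=subj, strategy=g["strategy"].iloc[0],
                trial_id=trial, events=events,
            )
        )
    return seqs


def write_feature_matrix(seqs: Sequence[ObservationSequence], path) -> None:
    from .baselines import FEATURE_NAMES

    rows = []
    for s in seqs:
        sf = summary_features(s)
        row = dict(zip(FEATURE_NAMES, sf.as_array().tolist()))
        row["strategy"] = s.strategy
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_feature_matrix(path) -> tuple[np.ndarray, list[str]]:
    from .baselines import FEATURE_NAMES

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df[list(FEATURE_NAMES)].to_numpy(dtype=float), df["strategy"].tolist()
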