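"""Per-fixation feature coding for mental-rotation scanpaths.

Raw fixation tables are turned into the observation sequences consumed by the
block HMM: each retained fixation carries the log of its duration, the area of
interest (AOI) it falls in, and — for every fixation but the last of a trial —
the log length and 4-category direction code of its outgoing saccade.

The four AOIs are the upper and lower arm of the left-side figure (L1, L2) and
of the right-side figure (R1, R2), numbered 1..4 in that order. Saccade
directions are coded relative to the AOI pair they connect:

    SD-1  within the identical AOI
    SD-2  to the other AOI of the same figure        (L1<->L2, R1<->R2)
    SD-3  to the corresponding AOI of the other figure (L1<->R1, L2<->R2)
    SD-4  to the transformed AOI of the other figure   (L1<->R2, L2<->R1)

For a fixed source AOI this map is a bijection between target AOIs and SD
codes, so the AOI chain of a trial can be reconstructed from its first AOI and
its SD string.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box

__all__ = [
    "AOI_NAMES",
    "OUTSIDE",
    "Fixation",
    "AOILayout",
    "ObservationEvent",
    "ObservationSequence",
    "SummaryFeatures",
    "assign_aoi",
    "code_saccade_direction",
    "target_aoi",
    "extract_sequence",
    "summary_features",
    "pooled_distributions",
]

#: canonical AOI order; category k (1-based) is AOI_NAMES[k-1]
AOI_NAMES = ("L1", "L2", "R1", "R2")

#: sentinel returned by :func:`assign_aoi` for points in no region
OUTSIDE = 0

STRATEGIES = ("LFRR", "RFLR")


class LayoutError(ValueError):
    """Malformed AOI layout (wrong region set, overlap, bad geometry)."""


class CodingError(ValueError):
    """Invalid input to a feature-coding operation."""


@dataclass(frozen=True)
class Fixation:
    """One fixation event of one trial.

    Coordinates are screen pixels with the origin at the top-left corner and
    y increasing downwards; onset and duration are milliseconds.
    """

    subject_id: str
    strategy: str
    trial_id: str
    index: int
    onset: float
    duration: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"fixation duration must be > 0, got {self.duration}")


class AOILayout:
    """Geometry of the four areas of interest.

    Parameters
    ----------
    regions
        Mapping from AOI name (``L1``, ``L2``, ``R1``, ``R2``) to either a
        rectangle dict ``{x0, y0, x1, y1}`` or a list of ``(x, y)`` polygon
        vertices, in screen px.
    """

    def __init__(self, regions: Mapping[str, object]) -> None:
        if set(regions) != set(AOI_NAMES):
            raise LayoutError(
                f"layout must define exactly the regions {AOI_NAMES}, got {sorted(regions)}"
            )
        polys: dict[str, Polygon] = {}
        for name, spec in regions.items():
            polys[name] = _as_polygon(spec)
        names = list(AOI_NAMES)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                inter = polys[a].intersection(polys[b])
                if inter.area > 1e-9:
                    raise LayoutError(f"regions {a} and {b} overlap (area {inter.area:.3g})")
        self.polygons: dict[str, Polygon] = polys

    def figure_of(self, name: str) -> str:
        return "left" if name.startswith("L") else "right"

    def arm_of(self, name: str) -> str:
        return "upper" if name.endswith("1") else "lower"

    def to_dict(self) -> dict:
        return {
            name: [list(xy) for xy in poly.exterior.coords[:-1]]
            for name, poly in self.polygons.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "AOILayout":
        return cls(d)


def _as_polygon(spec: object) -> Polygon:
    if isinstance(spec, Mapping):
        try:
            poly = box(spec["x0"], spec["y0"], spec["x1"], spec["y1"])
        except KeyError as exc:
            raise LayoutError(f"rectangle spec missing key {exc}") from exc
    else:
        poly = Polygon([tuple(p) for p in spec])  # type: ignore[arg-type]
    if not poly.is_valid or poly.area <= 0:
        raise LayoutError("region polygon is degenerate or self-intersecting")
    return poly


def assign_aoi(fixation_or_point, layout: AOILayout) -> int:
    """Return the AOI category (1..4) containing a fixation, or ``OUTSIDE``.

    Containment is inclusive of region edges; because regions are pairwise
    disjoint a point can belong to at most one region.
    """
    if isinstance(fixation_or_point, Fixation):
        x, y = fixation_or_point.x, fixation_or_point.y
    else:
        x, y = fixation_or_point
    p = Point(float(x), float(y))
    for k, name in enumerate(AOI_NAMES, start=1):
        if layout.polygons[name].covers(p):
            return k
    return OUTSIDE


def code_saccade_direction(aoi_from: int, aoi_to: int) -> int:
    """4-category direction code of a saccade between two AOIs (1..4 each)."""
    for a in (aoi_from, aoi_to):
        if a not in (1, 2, 3, 4):
            raise CodingError(f"AOI category must be in 1..4, got {a}")
    if aoi_from == aoi_to:
        return 1
    same_figure = (aoi_from <= 2) == (aoi_to <= 2)
    if same_figure:
        return 2
    # other figure: corresponding arm keeps the arm index, transformed flips it
    return 3 if abs(aoi_from - aoi_to) == 2 else 4


# target_aoi(a, sd) is the inverse of code_saccade_direction for fixed source
_SD_OFFSETS = {  # (figure half, arm) arithmetic, precomputed for clarity
    1: lambda a: a,
    2: lambda a: a + 1 if a % 2 == 1 else a - 1,
    3: lambda a: a + 2 if a <= 2 else a - 2,
    4: lambda a: {1: 4, 2: 3, 3: 2, 4: 1}[a],
}


def target_aoi(aoi_from: int, sd: int) -> int:
    """Target AOI implied by a source AOI and an SD code (inverse coding map)."""
    if aoi_from not in (1, 2, 3, 4):
        raise CodingError(f"AOI category must be in 1..4, got {aoi_from}")
    if sd not in (1, 2, 3, 4):
        raise CodingError(f"SD code must be in 1..4, got {sd}")
    return _SD_OFFSETS[sd](aoi_from)


@dataclass(frozen=True)
class ObservationEvent:
    """Feature vector of one retained fixation.

    ``log_sl`` and ``sd`` describe the outgoing saccade and are ``None`` for
    the final fixation of a trial.
    """

    log_fd: float
    aoi: int
    log_sl: float | None = None
    sd: int | None = None

    def __post_init__(self) -> None:
        if (self.log_sl is None) != (self.sd is None):
            raise ValueError("log_sl and sd must be both present or both absent")


@dataclass
class ObservationSequence:
    """One trial's ordered observation events plus its strategy label."""

    subject_id: str
    strategy: str
    trial_id: str
    events: list[ObservationEvent]

    def __post_init__(self) -> None:
        if len(self.events) < 1:
            raise ValueError("an observation sequence needs at least one event")
        for ev in self.events[:-1]:
            if ev.sd is None:
                raise ValueError("only the final event may lack an outgoing saccade")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def log_fd(self) -> np.ndarray:
        return np.array([ev.log_fd for ev in self.events])

    @property
    def aoi(self) -> np.ndarray:
        return np.array([ev.aoi for ev in self.events], dtype=int)

    @property
    def log_sl(self) -> np.ndarray:
        return np.array([ev.log_sl for ev in self.events[:-1]], dtype=float)

    @property
    def sd(self) -> np.ndarray:
        return np.array([ev.sd for ev in self.events[:-1]], dtype=int)


@dataclass(frozen=True)
class SummaryFeatures:
    """The five per-trial aggregates used by the logistic and SVM baselines."""

    n_fix: int
    mean_fd: float
    sd_fd: float
    mean_sl: float
    sd_sl: float

    FEATURE_NAMES = ("n_fix", "mean_fd", "sd_fd", "mean_sl", "sd_sl")

    def as_array(self) -> np.ndarray:
        return np.array([self.n_fix, self.mean_fd, self.sd_fd, self.mean_sl, self.sd_sl])


def extract_sequence(
    fixations: Sequence[Fixation],
    layout: AOILayout,
    *,
    snap_px: float | None = None,
) -> ObservationSequence:
    """Code one trial's fixations into an observation sequence.

    Fixations outside every AOI are dropped before saccades are formed, so a
    saccade connects consecutive *retained* fixations; its length is the
    Euclidean distance between their coordinates. With ``snap_px`` set,
    outside fixations within that distance of a region are snapped to the
    nearest region instead of dropped.

    Raises
    ------
    CodingError
        If no fixation falls inside (or snaps to) any AOI.
    """
    fixations = sorted(fixations, key=lambda f: f.onset)
    retained: list[tuple[Fixation, int]] = []
    for fx in fixations:
        k = assign_aoi(fx, layout)
        if k == OUTSIDE and snap_px is not None:
            p = Point(fx.x, fx.y)
            dists = {
                name: layout.polygons[name].distance(p) for name in AOI_NAMES
            }
            name = min(dists, key=dists.get)
            if dists[name] <= snap_px:
                k = AOI_NAMES.index(name) + 1
        if k != OUTSIDE:
            retained.append((fx, k))
    if not retained:
        raise CodingError("all fixations of the trial fall outside every AOI")

    events: list[ObservationEvent] = []
    for i, (fx, k) in enumerate(retained):
        log_fd = float(np.log(fx.duration))
        if i < len(retained) - 1:
            nxt, k_next = retained[i + 1]
            dist = float(np.hypot(nxt.x - fx.x, nxt.y - fx.y))
            # coincident consecutive fixations get a floor of 1 px so the log
            # stays finite; they are still SD-1 within-AOI saccades
            dist = max(dist, 1.0)
            events.append(
                ObservationEvent(
                    log_fd=log_fd,
                    aoi=k,
                    log_sl=float(np.log(dist)),
                    sd=code_saccade_direction(k, k_next),
                )
            )
        else:
            events.append(ObservationEvent(log_fd=log_fd, aoi=k))
    first = retained[0][0]
    return ObservationSequence(
        subject_id=first.subject_id,
        strategy=first.strategy,
        trial_id=first.trial_id,
        events=events,
    )


def summary_features(seq: ObservationSequence) -> SummaryFeatures:
    """Per-trial aggregates on the untransformed ms / px scales.

    Standard deviations are sample SDs (ddof=1) and are 0 by convention when
    fewer than two values exist; with no saccades the mean saccade length is
    also 0.
    """
    fd = np.exp(seq.log_fd)
    sl = np.exp(seq.log_sl) if len(seq) > 1 else np.array([])
    return SummaryFeatures(
        n_fix=len(seq),
        mean_fd=float(fd.mean()),
        sd_fd=float(fd.std(ddof=1)) if len(fd) > 1 else 0.0,
        mean_sl=float(sl.mean()) if sl.size else 0.0,
        sd_sl=float(sl.std(ddof=1)) if sl.size > 1 else 0.0,
    )


def pooled_distributions(
    seqs: Iterable[ObservationSequence],
) -> dict[str, dict[str, np.ndarray]]:
    """Pooled AOI-occupancy and SD-usage frequencies per strategy.

    Returns ``{strategy: {"aoi": 4-vector, "sd": 4-vector}}``; each vector is
    a relative frequency over all fixations (resp. saccades) of that class
    and sums to 1.
    """
    aoi_counts: dict[str, Counter] = {}
    sd_counts: dict[str, Counter] = {}
    for seq in seqs:
        aoi_counts.setdefault(seq.strategy, Counter()).update(seq.aoi.tolist())
        sd_counts.setdefault(seq.strategy, Counter()).update(seq.sd.tolist())
    if not aoi_counts:
        raise CodingError("no sequences supplied")
    out: dict[str, dict[str, np.ndarray]] = {}
    for strat, counts in aoi_counts.items():
        aoi_vec = np.array([counts.get(k, 0) for k in (1, 2, 3, 4)], dtype=float)
        sd_vec = np.array([sd_counts[strat].get(k, 0) for k in (1, 2, 3, 4)], dtype=float)
        total_aoi = aoi_vec.sum()
        if total_aoi == 0:
            raise CodingError(f"strategy {strat} has no fixations")
        aoi_vec /= total_aoi
        if sd_vec.sum() > 0:
            sd_vec /= sd_vec.sum()
        out[strat] = {"aoi": aoi_vec, "sd": sd_vec}
    return out
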