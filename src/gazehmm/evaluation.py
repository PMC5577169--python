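"""Cross-validation, confusion accounting, state-count selection and the
statistical comparisons used to evaluate the strategy classifiers.

Accuracies are reported on [0, 1]; the formatted report rounds to 0.1%. The
hidden-state grid is searched with repeated stratified k-fold CV and the
"level off" rule made explicit: the smallest configuration whose mean
validation accuracy is within a configurable margin of the grid maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .hmm import CLASSES, StateSpec

__all__ = [
    "ConfusionMatrix",
    "CVResult",
    "confusion",
    "kfold",
    "cross_validate",
    "select_states",
    "majority_vote_selection",
    "wilcoxon_rank_sum",
    "oneway_anova",
    "angle_effect_slope",
]


@dataclass
class ConfusionMatrix:
    """2x2 strategy confusion counts with the derived accuracies.

    Rows are actual classes, columns predicted, both ordered (LFRR, RFLR).
    Row-wise accuracy is the fraction of trials of a given actual strategy
    that were predicted correctly; column-wise accuracy conditions on the
    prediction; total accuracy is trace over grand total.
    """

    counts: np.ndarray
    labels: tuple[str, str] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 2x2 matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def total_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def row_accuracies(self) -> np.ndarray:
        return np.diag(self.counts) / self.counts.sum(axis=1)

    @property
    def col_accuracies(self) -> np.ndarray:
        return np.diag(self.counts) / self.counts.sum(axis=0)

    def report(self) -> str:
        """Plain-text table mirroring the confusion-matrix layout."""
        r = self.row_accuracies * 100
        c = self.col_accuracies * 100
        lines = [
            f"{'':>16}  Pred {self.labels[0]} ({c[0]:.1f}%)  Pred {self.labels[1]} ({c[1]:.1f}%)",
        ]
        for i, lab in enumerate(self.labels):
            lines.append(
                f"Actual {lab} ({r[i]:.1f}%)".ljust(24)
                + f"{self.counts[i, 0]:>8d}{self.counts[i, 1]:>20d}"
            )
        lines.append(f"Total accuracy: {self.total_accuracy * 100:.1f}%")
        return "\n".join(lines)


def confusion(pred: Sequence[str], actual: Sequence[str],
              labels: tuple[str, str] = CLASSES) -> ConfusionMatrix:
    """Confusion matrix of predicted vs actual strategy labels."""
    if len(pred) != len(actual) or len(pred) == 0:
        raise ValueError("pred and actual must be equal-length, non-empty")
    counts = np.zeros((2, 2), dtype=int)
    for p, a in zip(pred, actual):
        counts[labels.index(a), labels.index(p)] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


def kfold(n: int, k: int, seed: int, stratify_labels: Sequence[str] | None = None):
    """Seeded (stratified) k-fold partition of ``range(n)``.

    Returns a list of k disjoint index arrays covering all indices, with
    sizes differing by at most one; with labels given, each fold preserves
    the class balance to within one item per class.
    """
    if k > n:
        raise ValueError(f"cannot split {n} items into {k} folds")
    if stratify_labels is None:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return [np.sort(f) for f in np.array_split(perm, k)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [np.sort(test) for _, test in skf.split(np.zeros(n), list(stratify_labels))]


@dataclass
class CVResult:
    """Accuracies of a repeated k-fold cross-validation."""

    accuracies: np.ndarray  # (repeats, k)
    model: str = ""

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.accuracies.size > 1 else 0.0

    @property
    def per_repeat(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)


def cross_validate(
    model_factory: Callable[[], object],
    items: Sequence,
    labels: Sequence[str],
    *,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    name: str = "",
) -> CVResult:
    """Repeated stratified k-fold CV of any fit/predict classifier.

    ``model_factory`` returns a fresh estimator with ``fit(items, labels)``
    and ``predict(items)``. Folds are reshuffled every repeat with seeds
    derived from ``seed``. With ``repeats=1, k=n`` this is leave-one-out.
    """
    items = list(items)
    labels = list(labels)
    accs = np.zeros((repeats, k))
    for r in range(repeats):
        folds = kfold(len(items), k, seed + 1000 * r,
                      stratify_labels=labels if k <= min(
                          sum(1 for l in labels if l == c) for c in set(labels)
                      ) else None)
        for fi, test_idx in enumerate(folds):
            test_set = set(test_idx.tolist())
            train_idx = [i for i in range(len(items)) if i not in test_set]
            model = model_factory()
            try:
                model.fit([items[i] for i in train_idx], [labels[i] for i in train_idx])
                pred = model.predict([items[i] for i in test_idx])
            except Exception as exc:  # pragma: no cover - propagated with context
                raise RuntimeError(f"model failed on repeat {r}, fold {fi}") from exc
            actual = [labels[i] for i in test_idx]
            accs[r, fi] = np.mean([p == a for p, a in zip(pred, actual)])
    return CVResult(accuracies=accs, model=name)


DEFAULT_GRID = (
    StateSpec(2, 2), StateSpec(2, 3), StateSpec(3, 3), StateSpec(3, 4),
    StateSpec(4, 4), StateSpec(4, 5), StateSpec(5, 5),
)


def select_states(
    items: Sequence,
    labels: Sequence[str],
    model_factory: Callable[[StateSpec], object],
    *,
    grid: Sequence[StateSpec] = DEFAULT_GRID,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    margin: float = 0.01,
):
    """Hidden-state-count selection by the explicit "level off" rule.

    Every grid configuration is scored by mean (repeated) k-fold validation
    accuracy; the selected configuration is the smallest one — by total state
    count, then by block imbalance — whose mean accuracy is within ``margin``
    of the grid maximum. Returns ``(spec, curve)`` where ``curve`` maps the
    spec string to its mean accuracy. Configurations whose training fails are
    skipped with a warning.
    """
    if len(grid) == 0:
        raise ValueError("empty state grid")
    curve: dict[str, float] = {}
    scored: list[tuple[StateSpec, float]] = []
    for spec in grid:
        try:
            res = cross_validate(
                lambda spec=spec: model_factory(spec), items, labels,
                k=k, repeats=repeats, seed=seed, name=str(spec),
            )
        except RuntimeError as exc:
            warnings.warn(f"state spec {spec} skipped: {exc}")
            continue
        curve[str(spec)] = res.mean
        scored.append((spec, res.mean))
    if not scored:
        raise RuntimeError("every state configuration failed to train")
    best_acc = max(acc for _, acc in scored)
    eligible = [(s, a) for s, a in scored if a >= best_acc - margin]
    eligible.sort(key=lambda sa: (sa[0].n_states, abs(sa[0].n_lfrr - sa[0].n_rflr)))
    return eligible[0][0], curve


def majority_vote_selection(
    acc_a: Sequence[float],
    acc_b: Sequence[float],
    spec_a: StateSpec,
    spec_b: StateSpec,
    *,
    alpha: float = 0.05,
):
    """Majority-vote model selection between two configurations.

    ``acc_a`` / ``acc_b`` are per-participant accuracies under each spec.
    Counts how many participants favour each; a Wilcoxon signed-rank test on
    the paired accuracies decides whether the data overrule simplicity: the
    simpler spec (fewer total states, ties by balance) is kept unless the
    test is significant at ``alpha`` *and* the majority favours the larger.
    Returns ``(selected_spec, n_favour_a, n_favour_b, p_value)``.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("need >= 5 participants with paired accuracies")
    diffs = a - b
    n_favour_a = int(np.sum(diffs > 0))
    n_favour_b = int(np.sum(diffs < 0))
    simpler, larger = sorted(
        [spec_a, spec_b], key=lambda s: (s.n_states, abs(s.n_lfrr - s.n_rflr))
    )
    if np.all(diffs == 0):
        return simpler, n_favour_a, n_favour_b, 1.0
    try:
        stat_res = stats.wilcoxon(a, b, alternative="two-sided", method="auto")
        p = float(stat_res.pvalue)
    except ValueError:
        p = 1.0
    mean_larger = float(np.mean(a)) if larger == spec_a else float(np.mean(b))
    mean_simpler = float(np.mean(b)) if larger == spec_a else float(np.mean(a))
    selected = larger if (p < alpha and mean_larger > mean_simpler) else simpler
    return selected, n_favour_a, n_favour_b, p


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]):
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank sum of ``x``. The p-value is the
    exact permutation distribution for small samples without ties (both
    n <= 25), otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[: len(x)].sum())
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return w, float(res.pvalue)


def oneway_anova(*groups: Sequence[float]):
    """Classical one-way ANOVA; returns (F, p).

    Raises if the F statistic is undefined (no variance anywhere).
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arrs)
    if np.all(grand == grand[0]):
        raise ValueError("F undefined: zero variance within and between groups")
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def angle_effect_slope(rt_table) -> tuple[float, float]:
    """OLS slope (ms/degree) and intercept of reaction time on angle.

    ``rt_table`` is a DataFrame with columns ``angle`` and ``rt`` (or any
    two-column array-like ordered that way).
    """
    if hasattr(rt_table, "columns"):
        angle = np.asarray(rt_table["angle"], dtype=float)
        rt = np.asarray(rt_table["rt"], dtype=float)
    else:
        arr = np.asarray(rt_table, dtype=float)
        angle, rt = arr[:, 0], arr[:, 1]
    if len(np.unique(angle)) < 2:
        raise ValueError("need at least two distinct angles")
    res = stats.linregress(angle, rt)
    return float(res.slope), float(res.intercept)
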