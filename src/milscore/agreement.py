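"""Rater-agreement and association statistics.

Implements the statistics used to compare a model, a central reader and an
independent pathologist panel: confusion matrices with accuracy and Cohen's
kappa, Fleiss' kappa for multi-rater panels, modal panel scores with an
upward tie-break, the pooled two-proportion Z-test, odds ratios with Woolf
(log) confidence intervals and Fisher's exact association p-value, and
Wilson score intervals for accuracies.

All statistics are computed from their closed forms; ``scipy`` supplies only
the normal/Fisher reference distributions.  Kappas that are undefined
(chance agreement equal to 1, or a single category ever used) are reported
as ``math.nan`` sentinels rather than silently coerced to 0 or 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "AgreementReport",
    "PanelScores",
    "confusion_and_kappa",
    "cohen_kappa",
    "fleiss_kappa",
    "modal_score",
    "two_proportion_z",
    "odds_ratio_ci",
    "wilson_interval",
    "compare_model_vs_panel",
]

#: sentinel for kappa statistics with a degenerate chance-agreement term
UNDEFINED = math.nan


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows = reference (central reader), columns = prediction."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label count must match matrix dimension")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.n)


@dataclass(frozen=True)
class AgreementReport:
    confusion: ConfusionMatrix
    accuracy: float
    kappa: float
    n: int


@dataclass(frozen=True)
class PanelScores:
    """Items x raters integer score matrix; NaN marks a missing rating."""

    ratings: np.ndarray
    score_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        ratings = np.asarray(self.ratings, dtype=float)
        if ratings.ndim != 2:
            raise ValueError("ratings must be a 2-D items x raters array")
        if self.score_range is not None:
            lo, hi = self.score_range
            present = ratings[~np.isnan(ratings)]
            if present.size and ((present < lo) | (present > hi)).any():
                raise ValueError(f"rating outside declared range [{lo}, {hi}]")
        object.__setattr__(self, "ratings", ratings)


def _as_labels(reference: Sequence, predicted: Sequence) -> tuple:
    labels = sorted(set(reference) | set(predicted))
    return tuple(labels)


def cohen_kappa(reference: Sequence, predicted: Sequence, weighted: str | None = None) -> float:
    """Cohen's kappa; unweighted by default, ``weighted="linear"`` optional.

    Returns the :data:`UNDEFINED` NaN sentinel when expected agreement is 1
    (both raters constant on one class).
    """
    reference = list(reference)
    predicted = list(predicted)
    if len(reference) != len(predicted) or not reference:
        raise ValueError("reference and predicted must be equal-length, non-empty")
    labels = _as_labels(reference, predicted)
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for r, p in zip(reference, predicted):
        counts[index[r], index[p]] += 1
    n = counts.sum()
    prop = counts / n
    if weighted is None:
        weight = 1.0 - np.eye(k)
    elif weighted == "linear":
        grid = np.arange(k, dtype=float)
        weight = np.abs(grid[:, None] - grid[None, :]) / max(k - 1, 1)
    else:
        raise ValueError(f"unknown weighting {weighted!r}")
    row = prop.sum(axis=1)
    col = prop.sum(axis=0)
    expected = np.outer(row, col)
    disagree_o = float((weight * prop).sum())
    disagree_e = float((weight * expected).sum())
    if disagree_e == 0.0:
        return UNDEFINED
    return 1.0 - disagree_o / disagree_e


def confusion_and_kappa(
    reference: Sequence, predicted: Sequence, weighted: str | None = None
) -> AgreementReport:
    """Confusion matrix, accuracy and Cohen's kappa for two label sequences."""
    reference = list(reference)
    predicted = list(predicted)
    if len(reference) != len(predicted) or not reference:
        raise ValueError("reference and predicted must be equal-length, non-empty")
    labels = _as_labels(reference, predicted)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for r, p in zip(reference, predicted):
        counts[index[r], index[p]] += 1
    confusion = ConfusionMatrix(counts=counts, labels=labels)
    kappa = cohen_kappa(reference, predicted, weighted=weighted)
    return AgreementReport(
        confusion=confusion,
        accuracy=confusion.accuracy,
        kappa=kappa,
        n=confusion.n,
    )


def fleiss_kappa(panel: PanelScores) -> float:
    """Fleiss' kappa over a panel with a possibly varying number of raters.

    Items rated by fewer than two raters are dropped with a warning.  The
    standard fixed-rater form requires equal rater counts; with varying
    counts the per-item agreement generalises to pair counts
    ``sum_j n_ij (n_ij - 1) / (n_i (n_i - 1))``.
    """
    ratings = panel.ratings
    rater_counts = (~np.isnan(ratings)).sum(axis=1)
    usable = rater_counts >= 2
    if (~usable).any():
        warnings.warn(
            f"dropping {int((~usable).sum())} item(s) with fewer than 2 raters",
            stacklevel=2,
        )
    ratings = ratings[usable]
    if ratings.shape[0] == 0:
        raise ValueError("no items with at least two raters")
    present = ratings[~np.isnan(ratings)]
    categories = np.unique(present)
    if categories.size < 2:
        return UNDEFINED
    counts = np.zeros((ratings.shape[0], categories.size), dtype=np.int64)
    for j, cat in enumerate(categories):
        counts[:, j] = np.nansum(ratings == cat, axis=1)
    n_i = counts.sum(axis=1)
    p_i = (np.sum(counts * (counts - 1), axis=1)) / (n_i * (n_i - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / counts.sum()
    p_e = float(np.sum(p_j**2))
    if p_e == 1.0:
        return UNDEFINED
    return (p_bar - p_e) / (1.0 - p_e)


def modal_score(scores: Sequence[int]) -> int:
    """Most frequent score; non-unique modes resolve to the highest."""
    scores = [int(s) for s in scores]
    if not scores:
        raise ValueError("modal_score requires at least one score")
    values, counts = np.unique(scores, return_counts=True)
    best = counts.max()
    return int(values[counts == best].max())


@dataclass(frozen=True)
class TwoProportionResult:
    z: float
    p_value: float
    significant: bool
    alpha: float
    degenerate: bool = False


def two_proportion_z(
    successes1: int, n1: int, successes2: int, n2: int, alpha: float = 0.05
) -> TwoProportionResult:
    """Two-sided pooled-variance Z-test for a difference in proportions.

    A pooled proportion of exactly 0 or 1 has zero pooled variance; by
    convention the result is z = 0, p = 1 and flagged degenerate.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= successes1 <= n1 and 0 <= successes2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = successes1 / n1, successes2 / n2
    pooled = (successes1 + successes2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TwoProportionResult(0.0, 1.0, False, alpha, degenerate=True)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TwoProportionResult(float(z), float(p), bool(p < alpha), alpha)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False


def odds_ratio_ci(
    table: Sequence[Sequence[int]], confidence: float = 0.95
) -> OddsRatioResult:
    """Odds ratio of a 2x2 table with Woolf CI and Fisher's exact p.

    OR = ad/bc; whenever any cell is zero, the Haldane-Anscombe +0.5
    correction is applied to every cell (for both the point estimate and
    the interval) and the result is flagged ``corrected``.  The confidence
    interval is the Woolf log-interval ``exp(ln OR +/- z * SE)`` with
    ``SE = sqrt(1/a + 1/b + 1/c + 1/d)``.  The association p-value is from
    Fisher's exact test on the uncorrected table.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.sum() == 0:
        raise ValueError("empty table")
    corrected = bool((t == 0).any())
    tc = t + 0.5 if corrected else t
    a, b, c, d = tc.ravel()
    odds = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    log_or = math.log(odds)
    ci = (math.exp(log_or - z * se), math.exp(log_or + z * se))
    p = float(stats.fisher_exact(np.asarray(table, dtype=np.int64))[1])
    return OddsRatioResult(float(odds), ci[0], ci[1], p, corrected)


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if successes == 0 else max(0.0, centre - half)
    hi = 1.0 if successes == n else min(1.0, centre + half)
    return (lo, hi)


@dataclass(frozen=True)
class ModelVsPanelReport:
    n: int
    model_accuracy: float
    model_ci: tuple[float, float]
    panel_accuracy: float
    panel_ci: tuple[float, float]
    test: TwoProportionResult
    modal_panel: dict


def compare_model_vs_panel(
    reference: dict,
    model: dict,
    panel: dict,
    alpha: float = 0.05,
) -> ModelVsPanelReport:
    """Accuracy of model vs modal-panel predictions against one reference.

    All three arguments map item id -> score(s): ``reference`` and
    ``model`` to a single (binary or ordinal) score, ``panel`` to a
    sequence of rater scores summarised by :func:`modal_score`.  Item sets
    must coincide; accuracies carry Wilson intervals and are compared with
    the pooled two-proportion Z-test.
    """
    ids = sorted(reference)
    missing = sorted(
        set(ids) ^ set(model) | set(ids) ^ set(panel)
    )
    if set(model) != set(ids) or set(panel) != set(ids):
        raise KeyError(f"item sets differ; mismatched ids: {missing}")
    if not ids:
        raise ValueError("empty item set")
    modal_panel = {i: modal_score(panel[i]) for i in ids}
    n = len(ids)
    model_hits = sum(model[i] == reference[i] for i in ids)
    panel_hits = sum(modal_panel[i] == reference[i] for i in ids)
    test = two_proportion_z(model_hits, n, panel_hits, n, alpha=alpha)
    return ModelVsPanelReport(
        n=n,
        model_accuracy=model_hits / n,
        model_ci=wilson_interval(model_hits, n),
        panel_accuracy=panel_hits / n,
        panel_ci=wilson_interval(panel_hits, n),
        test=test,
        modal_panel=modal_panel,
    )
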