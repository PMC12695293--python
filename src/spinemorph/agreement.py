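"""Agreement statistics between two raters' masks or measurement series.

Covers the standard evaluation suite for a two-annotator segmentation study:

* per-structure Dice similarity coefficient (DSC) and Intersection over
  Union (IoU), aggregated as mean +/- SE across structures;
* Bland-Altman analysis of paired measurements (bias, SD of differences,
  1.96-SD limits of agreement) with a two-sided paired t-test;
* squared Pearson correlation (R^2) with a percentile bootstrap 95% CI
  (1000 resamples by default), overall or per spinal level.

Differences are oriented first-argument-minus-second (A - B) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DimensionError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from .mask_io import LEVELS, STRUCTURES, LabelMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapScores:
    """Per-structure overlap scores plus mean +/- SE over defined structures.

    A structure empty in both masks has an undefined score (None) and is
    excluded from the aggregate.
    """

    per_structure: dict[str, float | None]
    mean: float
    se: float
    metric: str

    def __str__(self) -> str:
        return f"{self.metric.upper()} {self.mean:.4f} ± {self.se:.4f}"


@dataclass(frozen=True)
class PairedSeries:
    """Two equal-length measurement series with (subject, level) labels."""

    labels: tuple[tuple[str, str], ...]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        labels = tuple((str(s), str(l)) for s, l in self.labels)
        if not (len(labels) == a.size == b.size):
            raise InsufficientDataError("labels, a and b must have equal length")
        if a.size < 2:
            raise InsufficientDataError("need at least 2 pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired series must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.a.size

    def restrict_level(self, level: str) -> "PairedSeries":
        keep = [i for i, (_, lvl) in enumerate(self.labels) if lvl == level]
        if len(keep) < 2:
            raise InsufficientDataError(f"level {level}: fewer than 2 pairs")
        return PairedSeries(
            tuple(self.labels[i] for i in keep), self.a[keep], self.b[keep]
        )


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_stat: float  # NaN when sd_diff == 0
    df: int
    p_two_sided: float  # NaN when sd_diff == 0
    degenerate: bool  # True when all differences are identical


@dataclass(frozen=True)
class BootstrapCI:
    r2: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def _structure_sets(mask_a: LabelMask, mask_b: LabelMask, structure: str):
    if mask_a.shape != mask_b.shape:
        raise DimensionError(
            f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}"
        )
    return mask_a.structure_pixels(structure), mask_b.structure_pixels(structure)


def dice(mask_a: LabelMask, mask_b: LabelMask, structure: str) -> float | None:
    """Dice coefficient 2|A∩B|/(|A|+|B|); None when both sets are empty."""
    a, b = _structure_sets(mask_a, mask_b, structure)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return None
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def iou(mask_a: LabelMask, mask_b: LabelMask, structure: str) -> float | None:
    """Jaccard index |A∩B|/|A∪B|; None when both sets are empty."""
    a, b = _structure_sets(mask_a, mask_b, structure)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return None
    inter = int(np.count_nonzero(a & b))
    return inter / union


def overlap_report(mask_a: LabelMask, mask_b: LabelMask, metric: str = "dsc") -> OverlapScores:
    """Per-structure overlap for all 11 structures, aggregated mean +/- SE
    over structures with a defined score."""
    if metric not in ("dsc", "iou"):
        raise ValueError(f"metric must be 'dsc' or 'iou', got {metric!r}")
    fn = dice if metric == "dsc" else iou
    per = {s: fn(mask_a, mask_b, s) for s in STRUCTURES}
    defined = np.array([v for v in per.values() if v is not None], dtype=np.float64)
    if defined.size == 0:
        raise DimensionError("no structure has a defined overlap score")
    mean = float(defined.mean())
    se = float(defined.std(ddof=1) / np.sqrt(defined.size)) if defined.size > 1 else 0.0
    return OverlapScores(per, mean, se, metric)


def bland_altman(series: PairedSeries) -> BlandAltmanResult:
    """Bland-Altman summary of paired differences a - b.

    Limits of agreement are bias +/- 1.96 SD; the paired t-test is two-sided
    Student t with n-1 degrees of freedom. When the differences have zero
    spread the t statistic is undefined: the result carries the bias with
    ``degenerate=True`` and NaN t/p.
    """
    d = series.a - series.b
    n = d.size
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    if sd_diff == 0.0:
        return BlandAltmanResult(
            n, mean_diff, 0.0, loa_low, loa_high, float("nan"), n - 1, float("nan"), True
        )
    t = mean_diff / (sd_diff / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return BlandAltmanResult(n, mean_diff, sd_diff, loa_low, loa_high, float(t), n - 1, float(p), False)


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    am = a - a.mean()
    bm = b - b.mean()
    denom = np.sqrt((am @ am) * (bm @ bm))
    if denom == 0.0:
        raise UndefinedCorrelationError("a constant series has no defined correlation")
    r = float(am @ bm) / float(denom)
    return r * r


def _bootstrap_r2_from_rng(
    a: np.ndarray, b: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Percentile 2.5/97.5 bounds of resampled r^2, vectorised.

    Resamples where either series is constant (zero variance) are skipped.
    """
    n = a.size
    idx = rng.integers(0, n, size=(n_boot, n))
    A, B = a[idx], b[idx]
    Am = A - A.mean(axis=1, keepdims=True)
    Bm = B - B.mean(axis=1, keepdims=True)
    va = np.einsum("ij,ij->i", Am, Am)
    vb = np.einsum("ij,ij->i", Bm, Bm)
    cov = np.einsum("ij,ij->i", Am, Bm)
    ok = (va > 0) & (vb > 0)
    if not np.all(ok):
        logger.info("skipping %d zero-variance bootstrap resamples", int((~ok).sum()))
    r2 = (cov[ok] ** 2) / (va[ok] * vb[ok])
    if r2.size == 0:
        raise UndefinedCorrelationError("all bootstrap resamples were constant")
    lo, hi = np.percentile(r2, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_r2(series: PairedSeries, n_boot: int = 1000, seed: int = 0) -> BootstrapCI:
    """R^2 (squared Pearson correlation) with a percentile bootstrap 95% CI.

    Pairs are resampled with replacement ``n_boot`` times; the CI spans the
    2.5th to the 97.5th percentile of resampled R^2. Fully reproducible for a
    fixed seed.
    """
    if series.n < 3:
        raise InsufficientDataError("need at least 3 pairs for bootstrap R^2")
    r2 = _pearson_r2(series.a, series.b)
    rng = np.random.default_rng(seed)
    lo, hi = _bootstrap_r2_from_rng(series.a, series.b, n_boot, rng)
    return BootstrapCI(r2, lo, hi, n_boot, seed)


def grouped_r2(
    series: PairedSeries, n_boot: int = 1000, seed: int = 0,
    levels: Sequence[str] = tuple(lvl for lvl, _, _ in LEVELS),
) -> dict[str, BootstrapCI]:
    """Per-level bootstrap R^2 under one deterministic seeding rule.

    Every level draws its resamples from a fresh generator seeded with the
    same integer, so restricting the input to one level and calling
    :func:`bootstrap_r2` with that seed reproduces the grouped result exactly.
    """
    out: dict[str, BootstrapCI] = {}
    for lvl in levels:
        sub = series.restrict_level(lvl)
        if sub.n < 3:
            raise InsufficientDataError(f"level {lvl}: fewer than 3 pairs")
        out[lvl] = bootstrap_r2(sub, n_boot=n_boot, seed=seed)
    return out


def bland_altman_plot(series: PairedSeries, result: BlandAltmanResult, path) -> None:
    """Write a Bland-Altman scatter (mean vs. difference) with bias and
    limits-of-agreement lines to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = (series.a + series.b) / 2.0
    diffs = series.a - series.b
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=12, alpha=0.6)
    ax.axhline(result.mean_diff, color="k", lw=1.2, label=f"bias {result.mean_diff:.3f}")
    for y, lab in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="r", ls="--", lw=1.0, label=f"{lab} {y:.3f}")
    ax.set_xlabel("mean of raters")
    ax.set_ylabel("difference (A - B)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
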