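"""Absolute integer copy number from segmented ratios, and resolution analysis.

A segmented ratio profile is only defined up to scale: the mean ratio of a
segment is (segment copy number) / (genome average copy number).  The ploidy
scale is recovered by a grid search for the multiplier m that minimizes the
bin-count-weighted least-squares distance of scaled segment ratios to the
nearest integers,

    m* = argmin_m  sum_s  w_s * (r_s * m - round(r_s * m))^2 ,

after which each segment's copy number is round(r_s * m*).  A flat profile
(every ratio 1) leaves the ploidy unidentifiable — every integer multiplier
fits exactly — and is flagged; by default the diploid scale m = 2 is then
reported, the sensible prior for a normal karyotype.

Also here: hypergeometric read-count downsampling (the in-silico equivalent
of sequencing fewer molecules), spurious/missed breakpoint accounting against
a known truth, the width x bin-size event-resolution arithmetic, and Pearson
concordance between ratio profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bins import BinProfile
from .segment import CBSParams, segment as _segment

__all__ = [
    "CNProfile",
    "IntegerCopyCaller",
    "fit_absolute",
    "downsample",
    "spurious_segments",
    "BoundaryComparison",
    "resolution",
    "profile_pearson",
    "call_pipeline",
]


@dataclass
class CNProfile:
    """Integer copy-number call: segments with CN, per-bin CN, and the scale."""

    segments: pd.DataFrame
    multiplier: float
    cn_per_bin: np.ndarray
    fit_error: float
    ploidy_unresolvable: bool = False

    def to_frame(self) -> pd.DataFrame:
        return self.segments


class IntegerCopyCaller(BaseEstimator):
    """Least-squares integer copy-number scaling as an estimator.

    Fit on a segment table (``n_bins``, ``mean_ratio`` columns); attributes
    ``multiplier_``, ``fit_error_`` and ``ploidy_unresolvable_`` describe the
    optimum; ``predict`` maps ratios to integer copy numbers at that scale.

    Parameters
    ----------
    grid_min, grid_max, grid_step : float
        Multiplier search grid over (grid_min, grid_max]; ties in the
        objective break toward the smallest multiplier.
    diploid_default : bool, default True
        When the fit is degenerate (a flat, all-ratio-1 profile fits every
        integer multiplier exactly) report the diploid scale m = 2 instead of
        the smallest tied grid point, and set ``ploidy_unresolvable_``.
    """

    def __init__(self, grid_min: float = 0.5, grid_max: float = 8.0,
                 grid_step: float = 0.05, diploid_default: bool = True):
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.grid_step = grid_step
        self.diploid_default = diploid_default

    def _grid(self) -> np.ndarray:
        if not (0 < self.grid_min < self.grid_max):
            raise ValueError("need 0 < grid_min < grid_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        n = int(round((self.grid_max - self.grid_min) / self.grid_step))
        return np.round(self.grid_min + self.grid_step * np.arange(1, n + 1), 10)

    def fit(self, X, y=None):
        seg = X
        if isinstance(seg, CNProfile):
            seg = seg.segments
        if len(seg) == 0:
            raise ValueError("empty segment set")
        r = np.asarray(seg["mean_ratio"], dtype=float)
        w = np.asarray(seg["n_bins"], dtype=float)
        grid = self._grid()
        scaled = r[None, :] * grid[:, None]
        err = (w[None, :] * (scaled - np.round(scaled)) ** 2).sum(axis=1)
        best = float(err.min())
        # smallest multiplier within numerical tolerance of the optimum
        tol = max(1e-12, 1e-9 * (1 + best))
        m_star = float(grid[np.flatnonzero(err <= best + tol)[0]])
        self.objective_ = pd.DataFrame({"multiplier": grid, "error": err})
        self.ploidy_unresolvable_ = bool(np.allclose(r, 1.0, atol=1e-9))
        if self.ploidy_unresolvable_ and self.diploid_default:
            m_star = 2.0
        self.multiplier_ = m_star
        self.fit_error_ = float(
            (w * (r * m_star - np.round(r * m_star)) ** 2).sum()
        )
        return self

    def predict(self, ratios) -> np.ndarray:
        """Integer copy number for each ratio at the fitted scale."""
        r = np.asarray(ratios, dtype=float)
        return np.clip(np.round(r * self.multiplier_), 0, None).astype(int)


def fit_absolute(
    segments: pd.DataFrame,
    grid: tuple[float, float, float] = (0.5, 8.0, 0.05),
    diploid_default: bool = True,
) -> CNProfile:
    """Scale segment ratios to absolute integer copy numbers.

    ``grid`` is (min, max, step) for the multiplier search.  Returns a
    :class:`CNProfile` whose segment table gains a ``cn`` column and whose
    ``cn_per_bin`` expands segment calls to bins.
    """
    caller = IntegerCopyCaller(*grid, diploid_default=diploid_default).fit(segments)
    seg = segments.copy()
    seg["cn"] = caller.predict(seg["mean_ratio"])
    cn_per_bin = np.repeat(seg["cn"].to_numpy(), seg["n_bins"].to_numpy())
    return CNProfile(
        segments=seg,
        multiplier=caller.multiplier_,
        cn_per_bin=cn_per_bin,
        fit_error=caller.fit_error_,
        ploidy_unresolvable=caller.ploidy_unresolvable_,
    )


def downsample(profile, n: int, seed: int | None = None):
    """Subsample bin counts to exactly ``n`` total reads without replacement.

    Multivariate hypergeometric draw over bins — equivalent in distribution
    to subsampling the underlying reads.  Accepts and returns either a
    :class:`BinProfile` or a plain count vector.
    """
    counts = profile.count if isinstance(profile, BinProfile) else np.asarray(profile)
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if n > total:
        raise ValueError(f"cannot downsample {total} reads to {n}")
    if n == total:
        sub = counts.copy()
    else:
        rng = np.random.default_rng(seed)
        sub = rng.multivariate_hypergeometric(counts, n, method="marginals")
    if isinstance(profile, BinProfile):
        return BinProfile(scheme=profile.scheme, count=sub, outside=profile.outside)
    return sub


class BoundaryComparison(NamedTuple):
    spurious: int
    missed: int
    n_called: int
    n_true: int

    @property
    def recall(self) -> float:
        return 1.0 if self.n_true == 0 else 1.0 - self.missed / self.n_true


def _called_boundaries(segments: pd.DataFrame) -> np.ndarray:
    """Interior segment starts: chromosome-initial starts are not transitions."""
    starts = segments["start_bin"].to_numpy()
    chrom = segments["chrom"].to_numpy()
    chrom_first = np.ones(len(segments), dtype=bool)
    chrom_first[1:] = chrom[1:] != chrom[:-1]
    return starts[~chrom_first]


def spurious_segments(called: pd.DataFrame, truth, tol: int = 2) -> BoundaryComparison:
    """Count called breakpoints without nearby truth, and missed true ones.

    A called boundary is spurious when no true copy-number transition lies
    within ``tol`` bins of it; a true boundary is missed when no called
    boundary lies within ``tol``.  Chromosome starts never count as
    boundaries on either side.
    """
    called_b = _called_boundaries(called)
    true_b = np.asarray(truth.true_boundaries() if hasattr(truth, "true_boundaries")
                        else truth, dtype=int)
    if len(true_b) == 0:
        spurious = len(called_b)
        missed = 0
    else:
        spurious = int(sum(np.abs(true_b - c).min() > tol for c in called_b))
        if len(called_b) == 0:
            missed = len(true_b)
        else:
            missed = int(sum(np.abs(called_b - t).min() > tol for t in true_b))
    return BoundaryComparison(spurious, missed, len(called_b), len(true_b))


def resolution(min_width: int, median_bin_bp: int) -> int:
    """Smallest detectable event size: minimum segment width x median bin length.

    With the five-bin transition rule, 600 kb bins (5000-bin resolution on a
    human genome) resolve 3 Mb events and 150 kb bins (20000-bin) 0.75 Mb.
    """
    if min_width < 1 or median_bin_bp < 1:
        raise ValueError("min_width and median_bin_bp must be >= 1")
    return min_width * median_bin_bp


def profile_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two aligned ratio profiles.

    Returns NaN (undefined) when either profile has zero variance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("profiles must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    from scipy.stats import pearsonr

    return float(pearsonr(a, b).statistic)


def call_pipeline(
    counts: np.ndarray,
    chrom: np.ndarray | None = None,
    gc: np.ndarray | None = None,
    cbs: CBSParams | None = None,
    grid: tuple[float, float, float] = (0.5, 8.0, 0.05),
) -> tuple[np.ndarray, pd.DataFrame, CNProfile]:
    """Counts -> ratios -> segments -> integer CN, in one call.

    Convenience composition of the normalization, segmentation and scaling
    steps; returns (ratios, segment table, CNProfile).
    """
    from .bins import GCNormalizer

    ratios = GCNormalizer(gc_correct=gc is not None).fit_transform(
        np.asarray(counts, dtype=float), gc=gc
    )
    segs = _segment(ratios, cbs or CBSParams(), chrom=chrom)
    prof = fit_absolute(segs, grid=grid)
    return ratios, segs, prof
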