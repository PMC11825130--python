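"""Sweep-region calling from scan tracks.

Tracks are smoothed with a cubic smoothing spline whose penalty is chosen
by generalized cross-validation, outliers are defined against a quantile
of fitted values pooled over neutral coalescent simulations matched to
each population's demography, and outlier runs within a merge distance
are collapsed into regions. Hyperparameters are selected by maximizing
sweep-region concordance between replicate samples of the same
population.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .scan import HaplotypeMatrix, MuTrack, QualityMask, maf_filter, mu_scan
from .synth import Demography, simulate_neutral_haplotypes

logger = logging.getLogger(__name__)

#: Maximum number of points used when choosing the spline penalty by GCV.
#: Larger tracks are thinned for the fit and evaluated at every center.
GCV_MAX_POINTS = 4000

DEFAULT_W_GRID = (10, 24, 50, 100, 200, 500)
DEFAULT_QUANTILE_GRID = (0.8, 0.9, 0.95, 0.99, 0.999)
DEFAULT_MERGE_GRID = (50_000, 100_000, 200_000, 500_000)


@dataclass
class SplineFit:
    """Cubic-spline smoothing of a scan track at its window centers."""

    chrom: str
    positions: np.ndarray
    fitted: np.ndarray
    lam: float  # np.nan when chosen internally by GCV

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.fitted = np.asarray(self.fitted, dtype=float)
        if self.positions.shape != self.fitted.shape:
            raise ValueError("positions/fitted length mismatch")
        if not np.all(np.isfinite(self.fitted)):
            raise ValueError("fitted values must be finite")


@dataclass
class SweepRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    peak_bp: float
    peak_fitted_value: float
    population: str = ""
    subspecies: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must be < end")

    def overlaps(self, other: "SweepRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class SweepRegionSet:
    regions: list[SweepRegion]
    population: str = ""
    subspecies: str = ""

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start))
        for a, b in zip(self.regions, self.regions[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("regions within a set must be non-overlapping")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "peak_bp": [r.peak_bp for r in self.regions],
                "peak_fitted_value": [r.peak_fitted_value for r in self.regions],
                "population": self.population,
                "subspecies": self.subspecies,
            }
        )


@dataclass
class HyperParams:
    W: int = 24
    quantile: float = 0.999
    merge_dist: int = 50_000


@dataclass
class ThresholdResult:
    """Outlier threshold plus the pooled neutral fitted values behind it."""

    value: float
    quantile: float
    pooled: np.ndarray
    n_reps: int
    n_failed: int


# ---------------------------------------------------------------------------
# spline smoothing
# ---------------------------------------------------------------------------


def fit_spline(track: MuTrack, max_gcv_points: int = GCV_MAX_POINTS) -> SplineFit:
    """Smooth mu against window center with a GCV-penalized cubic spline.

    For tracks longer than ``max_gcv_points`` the penalty search runs on an
    evenly thinned subset (the full solve is linear-time but the GCV
    search is not); fitted values are evaluated at every window center.
    """
    if len(track) < 10:
        raise ValueError(f"need >= 10 windows on {track.chrom}, got {len(track)}")
    x = np.asarray(track.center_bp, dtype=float)
    y = np.asarray(track.mu, dtype=float)
    if len(track) > max_gcv_points:
        step = int(np.ceil(len(track) / max_gcv_points))
        spl = make_smoothing_spline(x[::step], y[::step])
    else:
        spl = make_smoothing_spline(x, y)
    fitted = spl(x)
    return SplineFit(chrom=track.chrom, positions=x, fitted=fitted, lam=float("nan"))


# ---------------------------------------------------------------------------
# neutral thresholds
# ---------------------------------------------------------------------------


def neutral_fitted_pool(
    demog: Demography,
    n_hap: int,
    L: int,
    W: int,
    reps: int,
    seed: int,
    maf_min: float = 0.05,
    mask: QualityMask | None = None,
) -> tuple[np.ndarray, int]:
    """Pooled spline-fitted values over neutral simulation replicates.

    Returns (pooled values, number of failed replicates). Replicates fail
    when too few SNPs survive filtering to scan or smooth.
    """
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    n_failed = 0
    for _ in range(reps):
        rep_seed = int(rng.integers(1, 2**31 - 1))
        try:
            hap = simulate_neutral_haplotypes(demog, n_hap, L, rep_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                track = mu_scan(hap, W, maf_min=maf_min, mask=mask)
            fit = fit_spline(track)
        except ValueError:
            n_failed += 1
            continue
        pooled.append(fit.fitted)
    if n_failed > reps // 2:
        raise RuntimeError(
            f"{n_failed}/{reps} neutral replicates failed; cannot form a threshold"
        )
    if n_failed:
        logger.warning("%d/%d neutral replicates failed", n_failed, reps)
    return np.concatenate(pooled), n_failed


def neutral_threshold(
    demog: Demography,
    n_hap: int,
    L: int,
    W: int,
    reps: int,
    quantile: float,
    seed: int,
    maf_min: float = 0.05,
    mask: QualityMask | None = None,
) -> ThresholdResult:
    """Quantile of pooled neutral spline-fitted values."""
    if reps < 20:
        raise ValueError("reps must be >= 20")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    pooled, n_failed = neutral_fitted_pool(
        demog, n_hap, L, W, reps, seed, maf_min=maf_min, mask=mask
    )
    return ThresholdResult(
        value=float(np.quantile(pooled, quantile)),
        quantile=quantile,
        pooled=pooled,
        n_reps=reps,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------


def call_regions(
    fit: SplineFit,
    threshold: float,
    merge_dist: int,
    population: str = "",
    subspecies: str = "",
) -> SweepRegionSet:
    """Runs of fitted values above threshold, merged within ``merge_dist``.

    A run over evaluation positions [p_first .. p_last] becomes the
    interval [p_first, p_last + 1); intervals whose gap is at most
    ``merge_dist`` bp are merged, and the peak is the argmax fitted value
    inside the merged span.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if merge_dist < 0:
        raise ValueError("merge_dist must be >= 0")
    above = fit.fitted > threshold
    if not above.any():
        return SweepRegionSet([], population=population, subspecies=subspecies)
    # run boundaries
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1  # inclusive index
    intervals = [
        (int(fit.positions[s]), int(fit.positions[e]) + 1, s, e)
        for s, e in zip(starts, ends)
    ]
    merged: list[list[int]] = []
    for lo, hi, s, e in intervals:
        if merged and lo - merged[-1][1] <= merge_dist:
            merged[-1][1] = hi
            merged[-1][3] = e
        else:
            merged.append([lo, hi, s, e])
    regions = []
    for lo, hi, s, e in merged:
        seg = slice(s, e + 1)
        peak_idx = s + int(np.argmax(fit.fitted[seg]))
        regions.append(
            SweepRegion(
                chrom=fit.chrom,
                start=lo,
                end=hi,
                peak_bp=float(fit.positions[peak_idx]),
                peak_fitted_value=float(fit.fitted[peak_idx]),
                population=population,
                subspecies=subspecies,
            )
        )
    return SweepRegionSet(regions, population=population, subspecies=subspecies)


def replicate_concordance(
    set_a: SweepRegionSet, set_b: SweepRegionSet
) -> tuple[float, float, float]:
    """Proportion of each set's regions overlapping the other, and the mean.

    Overlap is >= 1 bp. An empty set yields NaN for its side (and for the
    mean), with a warning.
    """

    def _shared(xs: SweepRegionSet, ys: SweepRegionSet) -> float:
        if len(xs) == 0:
            warnings.warn("empty region set: concordance undefined for this side")
            return float("nan")
        return sum(any(r.overlaps(o) for o in ys) for r in xs) / len(xs)

    s_a = _shared(set_a, set_b)
    s_b = _shared(set_b, set_a)
    return s_a, s_b, (s_a + s_b) / 2


# ---------------------------------------------------------------------------
# hyperparameter grid search
# ---------------------------------------------------------------------------


@dataclass
class ReplicatePair:
    """Two disjoint samples of one population plus its demography."""

    label: str
    hap_a: HaplotypeMatrix
    hap_b: HaplotypeMatrix
    demography: Demography


@dataclass
class GridSearchResult:
    best: HyperParams
    table: pd.DataFrame


def grid_search(
    pairs: list[ReplicatePair],
    seed: int,
    W_grid=DEFAULT_W_GRID,
    quantile_grid=DEFAULT_QUANTILE_GRID,
    merge_grid=DEFAULT_MERGE_GRID,
    threshold_reps: int = 100,
    maf_min: float = 0.05,
) -> GridSearchResult:
    """Exhaustive search over (W, quantile, merge distance).

    Each combination runs scan -> spline -> threshold -> call on both
    replicates of every pair; the score is mean replicate concordance
    across pairs. Neutral pools are cached per (pair, W) so all quantiles
    reuse the same simulations. Ties break toward smaller W, then larger
    quantile, then smaller merge distance.
    """
    if not pairs:
        raise ValueError("at least one replicate pair required")
    rng = np.random.default_rng(seed)
    pool_seed = {p.label: int(rng.integers(1, 2**31 - 1)) for p in pairs}

    # cache per (pair, W): spline fits of both replicates + neutral pool
    cache: dict[tuple[str, int], tuple[SplineFit, SplineFit, np.ndarray] | None] = {}

    def _get(pair: ReplicatePair, W: int):
        key = (pair.label, W)
        if key not in cache:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit_a = fit_spline(mu_scan(pair.hap_a, W, maf_min=maf_min))
                    fit_b = fit_spline(mu_scan(pair.hap_b, W, maf_min=maf_min))
                pooled, _ = neutral_fitted_pool(
                    pair.demography,
                    pair.hap_a.n_hap,
                    pair.hap_a.L,
                    W,
                    threshold_reps,
                    pool_seed[pair.label],
                    maf_min=maf_min,
                )
            except (ValueError, RuntimeError) as exc:
                logger.info("pair %s W=%d unusable: %s", pair.label, W, exc)
                cache[key] = None
                return None
            cache[key] = (fit_a, fit_b, pooled)
        return cache[key]

    records = []
    for W, quantile, merge_dist in itertools.product(W_grid, quantile_grid, merge_grid):
        scores = []
        failed = False
        for pair in pairs:
            entry = _get(pair, W)
            if entry is None:
                failed = True
                break
            fit_a, fit_b, pooled = entry
            thr = float(np.quantile(pooled, quantile))
            set_a = call_regions(fit_a, thr, merge_dist)
            set_b = call_regions(fit_b, thr, merge_dist)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, mean = replicate_concordance(set_a, set_b)
            scores.append(mean)
        score = float("nan") if failed else float(np.mean(scores))
        records.append(
            {"W": W, "quantile": quantile, "merge_dist": merge_dist, "score": score}
        )
    table = pd.DataFrame(records)
    valid = table.dropna(subset=["score"])
    if valid.empty:
        raise RuntimeError("no grid combination produced a usable score")
    # argmax with parsimony tie-break: smaller W, larger quantile, smaller merge
    best_score = valid["score"].max()
    ties = valid[valid["score"] == best_score].sort_values(
        by=["W", "quantile", "merge_dist"], ascending=[True, False, True]
    )
    row = ties.iloc[0]
    best = HyperParams(
        W=int(row["W"]), quantile=float(row["quantile"]), merge_dist=int(row["merge_dist"])
    )
    logger.info("grid search best: %s (score %.4f)", best, best_score)
    return GridSearchResult(best=best, table=table)
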