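"""Composite windowed sweep statistic and supporting diversity statistics.

The scan statistic ``mu`` is a product of three self-normalizing
sub-statistics computed in sliding windows of a fixed number of SNPs:

* ``mu_var`` — window-span deficit, rescaled by per-window callable-base
  quality;
* ``mu_sfs`` — excess of extreme-frequency (singleton / (n-1)-ton) derived
  alleles relative to the chromosome-wide proportion;
* ``mu_ld`` — contrast of linkage disequilibrium within the two window
  halves against LD between them.

Each sub-statistic is approximately 1 under neutrality, so the composite
product is as well; sweeps inflate all three.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Regularizer in the mu_ld denominator.
LD_EPS = 1e-6
#: Hard cap on mu_ld so the epsilon-regularized ratio cannot blow up.
LD_CAP = 100.0


class MonomorphicSiteError(ValueError):
    """Raised when an LD computation receives a monomorphic column."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeMatrix:
    """Binary ancestral(0)/derived(1) haplotypes at polymorphic sites.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    L : int
        Chromosome length in bp.
    positions : ndarray of int
        Strictly increasing 1-based bp positions, one per site.
    derived : ndarray, shape (n_hap, S)
        0/1 derived-state matrix.
    """

    chrom: str
    L: int
    positions: np.ndarray
    derived: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.derived = np.asarray(self.derived, dtype=np.int8)
        if self.derived.ndim != 2:
            raise ValueError("derived must be 2-D (n_hap x S)")
        if self.positions.shape[0] != self.derived.shape[1]:
            raise ValueError("positions and derived disagree on site count")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < 1 or self.positions[-1] > self.L:
                raise ValueError("positions must lie in [1, L]")
            counts = self.derived.sum(axis=0)
            if np.any((counts <= 0) | (counts >= self.n_hap)):
                raise ValueError("every site must be polymorphic in the sample")

    @property
    def n_hap(self) -> int:
        return self.derived.shape[0]

    @property
    def n_sites(self) -> int:
        return self.derived.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.derived.sum(axis=0).astype(np.int64)

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            chrom=self.chrom,
            L=self.L,
            positions=self.positions[index],
            derived=self.derived[:, index],
        )

    def take_haplotypes(self, index: np.ndarray) -> "HaplotypeMatrix":
        """Subset haplotypes, dropping sites monomorphic in the subset."""
        sub = self.derived[np.asarray(index), :]
        counts = sub.sum(axis=0)
        keep = (counts > 0) & (counts < sub.shape[0])
        return HaplotypeMatrix(
            chrom=self.chrom,
            L=self.L,
            positions=self.positions[keep],
            derived=sub[:, keep],
        )


@dataclass
class QualityMask:
    """Callable intervals on one chromosome, 0-based half-open (BED-style)."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts/ends length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must be non-empty")
        if self.starts.size > 1:
            if np.any(np.diff(self.starts) < 0):
                raise ValueError("intervals must be sorted")
            if np.any(self.starts[1:] < self.ends[:-1]):
                raise ValueError("intervals must be non-overlapping")

    def callable_fraction(self, first_bp: np.ndarray, last_bp: np.ndarray) -> np.ndarray:
        """Proportion of callable bases in inclusive 1-based spans."""
        first_bp = np.atleast_1d(np.asarray(first_bp, dtype=np.int64))
        last_bp = np.atleast_1d(np.asarray(last_bp, dtype=np.int64))
        # prefix sum of callable bases over interval boundaries
        lo = first_bp - 1  # 0-based inclusive start
        hi = last_bp  # 0-based exclusive end
        q = self._coverage(hi) - self._coverage(lo)
        return q / (hi - lo)

    def _coverage(self, pos: np.ndarray) -> np.ndarray:
        """Number of callable bases in [0, pos)."""
        cum = np.concatenate([[0], np.cumsum(self.ends - self.starts)])
        idx = np.searchsorted(self.starts, pos, side="right")
        full = cum[idx]
        # subtract the part of the last interval beyond pos
        prev = idx - 1
        overhang = np.where(
            (prev >= 0) & (pos < self.ends[np.clip(prev, 0, None)]),
            self.ends[np.clip(prev, 0, None)] - pos,
            0,
        )
        return full - overhang


@dataclass
class MuTrack:
    """Per-window scan records along one chromosome."""

    chrom: str
    first_bp: np.ndarray
    last_bp: np.ndarray
    center_bp: np.ndarray
    W: int
    mu_var: np.ndarray
    mu_sfs: np.ndarray
    mu_ld: np.ndarray
    mu: np.ndarray
    n_skipped: int = 0

    def __len__(self) -> int:
        return self.center_bp.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "first_bp": self.first_bp,
                "last_bp": self.last_bp,
                "center_bp": self.center_bp,
                "W": self.W,
                "mu_var": self.mu_var,
                "mu_sfs": self.mu_sfs,
                "mu_ld": self.mu_ld,
                "mu": self.mu,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MuTrack":
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("MuTrack holds exactly one chromosome")
        return cls(
            chrom=str(chroms[0]),
            first_bp=df["first_bp"].to_numpy(np.int64),
            last_bp=df["last_bp"].to_numpy(np.int64),
            center_bp=df["center_bp"].to_numpy(float),
            W=int(df["W"].iloc[0]),
            mu_var=df["mu_var"].to_numpy(float),
            mu_sfs=df["mu_sfs"].to_numpy(float),
            mu_ld=df["mu_ld"].to_numpy(float),
            mu=df["mu"].to_numpy(float),
        )


# ---------------------------------------------------------------------------
# filters and scalar sub-statistics
# ---------------------------------------------------------------------------


def maf_filter(hap: HaplotypeMatrix, maf_min: float) -> HaplotypeMatrix:
    """Remove sites with minor allele frequency below ``maf_min``.

    Sites exactly at the threshold are kept (>= convention).
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    counts = hap.derived_counts()
    maf = np.minimum(counts, hap.n_hap - counts) / hap.n_hap
    return hap.take_sites(np.flatnonzero(maf >= maf_min))


def r2(site_a: np.ndarray, site_b: np.ndarray) -> float:
    """Squared haplotype correlation between two binary columns."""
    a = np.asarray(site_a, dtype=float)
    b = np.asarray(site_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicSiteError("r2 undefined for monomorphic columns")
    pab = (a * b).mean()
    return (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))


def mu_var(first_bp: int, last_bp: int, W: int, L: int, S_chrom: int, q_w: float) -> float:
    """Window-span sub-statistic: (span * q_w * S_chrom) / (L * W)."""
    if W < 2:
        raise ValueError("window must contain at least 2 SNPs")
    if not 0 < q_w <= 1:
        raise ValueError("q_w must be in (0, 1]; q_w == 0 windows are unusable")
    span = last_bp - first_bp
    return span * q_w * S_chrom / (L * W)


def mu_sfs(extreme_in_window: int, W: int, chrom_extreme_proportion: float) -> float:
    """Extreme-frequency excess relative to the chromosome-wide proportion."""
    if chrom_extreme_proportion <= 0:
        raise ValueError("chromosome-wide extreme proportion must be > 0")
    return (extreme_in_window / W) / chrom_extreme_proportion


def mu_ld(window: np.ndarray) -> float:
    """Flank-LD contrast for one window of haplotype columns.

    ``window`` is (n_hap, W); the window is split at the middle SNP and the
    ratio of mean within-half r2 to mean between-half r2 is returned,
    regularized by ``LD_EPS`` and capped at ``LD_CAP``.
    """
    window = np.asarray(window, dtype=float)
    W = window.shape[1]
    if W < 4:
        raise ValueError("mu_ld requires at least 4 SNPs")
    h = W // 2
    left, right = window[:, :h], window[:, h:]
    if left.shape[1] < 2 or right.shape[1] < 2:
        raise ValueError("each half needs >= 2 sites")
    mean_left = _mean_pairwise_r2(left)
    mean_right = _mean_pairwise_r2(right)
    mean_between = _mean_cross_r2(left, right)
    val = (mean_left + mean_right) / (2 * mean_between + LD_EPS)
    return min(val, LD_CAP)


def _mean_pairwise_r2(block: np.ndarray) -> float:
    vals = []
    for i in range(block.shape[1]):
        for j in range(i + 1, block.shape[1]):
            vals.append(r2(block[:, i], block[:, j]))
    return float(np.mean(vals))


def _mean_cross_r2(left: np.ndarray, right: np.ndarray) -> float:
    vals = []
    for i in range(left.shape[1]):
        for j in range(right.shape[1]):
            vals.append(r2(left[:, i], right[:, j]))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# vectorized scan
# ---------------------------------------------------------------------------


def _banded_r2(X: np.ndarray, max_lag: int) -> np.ndarray:
    """r2 for all site pairs (i, i+k), k = 1..max_lag.

    Returns R with shape (max_lag, S); R[k-1, i] = r2(site i, site i+k),
    NaN where i+k is out of range.
    """
    n, S = X.shape
    p = X.mean(axis=0)
    denom_var = p * (1 - p)
    R = np.full((max_lag, S), np.nan)
    Xf = X.astype(np.float64)
    for k in range(1, max_lag + 1):
        if S - k <= 0:
            break
        pab = (Xf[:, : S - k] * Xf[:, k:]).mean(axis=0)
        num = (pab - p[: S - k] * p[k:]) ** 2
        R[k - 1, : S - k] = num / (denom_var[: S - k] * denom_var[k:])
    return R


def _sliding_sum(x: np.ndarray, width: int) -> np.ndarray:
    """Sum of x over each window of `width` consecutive entries."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[width:] - c[:-width]


def mu_scan(
    hap: HaplotypeMatrix,
    W: int,
    maf_min: float = 0.05,
    mask: QualityMask | None = None,
) -> MuTrack:
    """Sliding-window composite scan.

    Windows contain ``W`` consecutive post-filter SNPs and advance one SNP
    per step. Windows whose span has zero callable bases under ``mask``
    are dropped (counted in ``n_skipped``).
    """
    if W < 4:
        raise ValueError("W must be >= 4")
    filtered = maf_filter(hap, maf_min)
    S = filtered.n_sites
    if S < W:
        warnings.warn(
            f"only {S} SNPs after MAF filter on {hap.chrom}; need >= {W}: empty track"
        )
        empty = np.empty(0)
        return MuTrack(hap.chrom, empty.astype(np.int64), empty.astype(np.int64),
                       empty, W, empty, empty, empty, empty)

    pos = filtered.positions
    X = filtered.derived.astype(np.float64)
    n = filtered.n_hap
    counts = filtered.derived_counts()
    n_windows = S - W + 1

    first_bp = pos[:n_windows]
    last_bp = pos[W - 1:]
    center_bp = (first_bp + last_bp) / 2.0

    # --- mu_var -----------------------------------------------------------
    if mask is not None:
        q_w = mask.callable_fraction(first_bp, last_bp)
    else:
        q_w = np.ones(n_windows)
    span = (last_bp - first_bp).astype(float)
    m_var = span * q_w * S / (float(filtered.L) * W)

    # --- mu_sfs -----------------------------------------------------------
    extreme = ((counts == 1) | (counts == n - 1)).astype(float)
    chrom_prop = extreme.mean()
    if chrom_prop == 0:
        logger.warning("no extreme-frequency sites on %s; mu_sfs set to 1", hap.chrom)
        m_sfs = np.ones(n_windows)
    else:
        m_sfs = (_sliding_sum(extreme, W) / W) / chrom_prop

    # --- mu_ld ------------------------------------------------------------
    h = W // 2
    R = _banded_r2(X, W - 1)
    # within-left: pairs (i, i+k), both in [w, w+h-1]  -> k <= h-1, i in [w, w+h-1-k]
    # within-right: both in [w+h, w+W-1]               -> k <= W-h-1, i in [w+h, w+W-1-k]
    # between: i in left, j in right                   -> i in [w, w+h-1], j in [w+h, w+W-1]
    sum_left = np.zeros(n_windows)
    sum_right = np.zeros(n_windows)
    n_left_pairs = h * (h - 1) // 2
    n_right = W - h
    n_right_pairs = n_right * (n_right - 1) // 2
    for k in range(1, h):
        # i from w .. w+h-1-k : width h-k starting at w
        sum_left += _sliding_sum(np.nan_to_num(R[k - 1]), h - k)[:n_windows]
    for k in range(1, n_right):
        # i from w+h .. w+W-1-k : width n_right-k starting at w+h
        s = _sliding_sum(np.nan_to_num(R[k - 1]), n_right - k)
        sum_right += s[h: h + n_windows]
    # between-half pairs have lags k = j - i with i in left, j in right
    sum_between = np.zeros(n_windows)
    for k in range(1, W):
        lo = max(0, h - k)  # offsets within window for i such that j=i+k is in right
        hi = min(h - 1, W - 1 - k)
        if hi < lo:
            continue
        width = hi - lo + 1
        s = _sliding_sum(np.nan_to_num(R[k - 1]), width)
        sum_between += s[lo: lo + n_windows]
    n_between_pairs = h * n_right
    mean_within = (sum_left / n_left_pairs + sum_right / n_right_pairs)
    mean_between = sum_between / n_between_pairs
    m_ld = np.minimum(mean_within / (2 * mean_between + LD_EPS), LD_CAP)

    # --- compose ----------------------------------------------------------
    usable = q_w > 0
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("%d windows with q_w == 0 dropped on %s", n_skipped, hap.chrom)
    mu = m_var * m_sfs * m_ld
    return MuTrack(
        chrom=hap.chrom,
        first_bp=first_bp[usable],
        last_bp=last_bp[usable],
        center_bp=center_bp[usable],
        W=W,
        mu_var=m_var[usable],
        mu_sfs=m_sfs[usable],
        mu_ld=m_ld[usable],
        mu=mu[usable],
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------


def _window_edges(L: int, window_bp: int) -> np.ndarray:
    edges = np.arange(0, L, window_bp, dtype=np.int64)
    return np.append(edges, L)


def diversity_pi(hap: HaplotypeMatrix, window_bp: int) -> pd.DataFrame:
    """Per-window nucleotide diversity per bp in non-overlapping windows.

    Windows with no segregating sites get NaN.
    """
    n = hap.n_hap
    counts = hap.derived_counts()
    per_site = 2.0 * counts * (n - counts) / (n * (n - 1))
    edges = _window_edges(hap.L, window_bp)
    idx = np.searchsorted(edges, hap.positions - 1, side="right") - 1
    sums = np.bincount(idx, weights=per_site, minlength=len(edges) - 1)
    nsites = np.bincount(idx, minlength=len(edges) - 1)
    widths = np.diff(edges)
    pi = np.where(nsites > 0, sums / widths, np.nan)
    return pd.DataFrame(
        {"chrom": hap.chrom, "start": edges[:-1], "end": edges[1:],
         "n_sites": nsites, "pi": pi}
    )


def tajimas_d(hap: HaplotypeMatrix, window_bp: int) -> pd.DataFrame:
    """Tajima's D in non-overlapping windows (NaN below 3 segregating sites)."""
    n = hap.n_hap
    counts = hap.derived_counts()
    per_site = 2.0 * counts * (n - counts) / (n * (n - 1))
    edges = _window_edges(hap.L, window_bp)
    idx = np.searchsorted(edges, hap.positions - 1, side="right") - 1
    pi_sum = np.bincount(idx, weights=per_site, minlength=len(edges) - 1)
    S = np.bincount(idx, minlength=len(edges) - 1).astype(float)

    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = e1 * S + e2 * S * (S - 1)
        d = (pi_sum - S / a1) / np.sqrt(var)
    d = np.where(S >= 3, d, np.nan)
    return pd.DataFrame(
        {"chrom": hap.chrom, "start": edges[:-1], "end": edges[1:],
         "n_sites": S.astype(int), "tajimas_d": d}
    )
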