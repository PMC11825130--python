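"""Private/shared sweep bookkeeping and accuracy-adjusted sharing tests.

Regions from all populations are clustered by single-linkage >=1-bp
overlap; clusters spanning one population are private. Sweep-calling
accuracy is estimated from replicate samples as
P = 1 - (nS/nP1 + nS/nP2)/2, and population pairs are tested for excess
sharing with an exact hypergeometric upper-tail test on P-adjusted
counts, corrected across pairs with the Benjamini-Yekutieli method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .regions import SweepRegion, SweepRegionSet


@dataclass
class SharingCluster:
    members: list[tuple[str, SweepRegion]]  # (population, region)
    chrom: str
    start: int
    end: int
    populations: frozenset[str]
    n_maize: int
    n_teosinte: int

    @property
    def is_private(self) -> bool:
        return len(self.populations) == 1


@dataclass
class AccuracyEstimate:
    nS: int
    nP1: int
    nP2: int
    P: float
    group: str = ""


@dataclass
class SharingTestResult:
    pop1: str
    pop2: str
    N: int
    n1: int
    n2: int
    x: int
    N_adj: int
    n1_adj: int
    n2_adj: int
    x_adj: int
    p_raw: float
    p_adj: float = float("nan")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_regions(sets: list[SweepRegionSet]) -> list[SharingCluster]:
    """Connected components of the >=1-bp overlap graph across populations.

    Single linkage: intervals A-B and B-C overlapping joins A, B, C even
    when A and C are disjoint. Implemented as a per-chromosome sweep over
    start-sorted intervals.
    """
    tagged: list[tuple[str, SweepRegion]] = []
    for s in sets:
        for r in s:
            pop = r.population or s.population
            ssp = r.subspecies or s.subspecies
            tagged.append((pop, SweepRegion(
                chrom=r.chrom, start=r.start, end=r.end, peak_bp=r.peak_bp,
                peak_fitted_value=r.peak_fitted_value, population=pop, subspecies=ssp,
            )))
    clusters: list[SharingCluster] = []
    by_chrom: dict[str, list[tuple[str, SweepRegion]]] = {}
    for pop, r in tagged:
        by_chrom.setdefault(r.chrom, []).append((pop, r))
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[1].start, t[1].end))
        current: list[tuple[str, SweepRegion]] = []
        cur_end = -1
        for pop, r in items:
            if current and r.start < cur_end:  # half-open overlap with the chain
                current.append((pop, r))
                cur_end = max(cur_end, r.end)
            else:
                if current:
                    clusters.append(_finalize(chrom, current))
                current = [(pop, r)]
                cur_end = r.end
        if current:
            clusters.append(_finalize(chrom, current))
    return clusters


def _finalize(chrom: str, members: list[tuple[str, SweepRegion]]) -> SharingCluster:
    pops = frozenset(pop for pop, _ in members)
    ssp_of = {pop: r.subspecies for pop, r in members}
    n_maize = sum(1 for p in pops if ssp_of[p] == "maize")
    n_teosinte = sum(1 for p in pops if ssp_of[p] == "teosinte")
    return SharingCluster(
        members=members,
        chrom=chrom,
        start=min(r.start for _, r in members),
        end=max(r.end for _, r in members),
        populations=pops,
        n_maize=n_maize,
        n_teosinte=n_teosinte,
    )


def sharing_summary(clusters: list[SharingCluster]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts by (n_maize, n_teosinte) and per-population private proportion."""
    contingency = (
        pd.DataFrame(
            {"n_maize": [c.n_maize for c in clusters],
             "n_teosinte": [c.n_teosinte for c in clusters]}
        )
        .value_counts()
        .rename("n_clusters")
        .reset_index()
        .sort_values(["n_maize", "n_teosinte"])
        .reset_index(drop=True)
    )
    pops = sorted({p for c in clusters for p in c.populations})
    rows = []
    for pop in pops:
        containing = [c for c in clusters if pop in c.populations]
        private = sum(1 for c in containing if c.is_private)
        rows.append(
            {"population": pop, "n_clusters": len(containing), "n_private": private,
             "private_proportion": private / len(containing)}
        )
    return contingency, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------


def accuracy_P(nS: int, nP1: int, nP2: int, group: str = "") -> AccuracyEstimate:
    """P = 1 - (nS/nP1 + nS/nP2)/2 from replicate region counts."""
    if nP1 <= 0 or nP2 <= 0:
        raise ValueError("replicate region counts must be > 0")
    if nS > min(nP1, nP2):
        raise ValueError("shared count cannot exceed either replicate total")
    P = 1.0 - (nS / nP1 + nS / nP2) / 2.0
    return AccuracyEstimate(nS=nS, nP1=nP1, nP2=nP2, P=P, group=group)


# ---------------------------------------------------------------------------
# hypergeometric sharing test
# ---------------------------------------------------------------------------


def _hypergeom_sf_exact(x: int, N: int, n1: int, n2: int) -> float:
    """Pr(X >= x) for X ~ Hypergeometric(N total, n1 successes, n2 draws).

    Exact rational summation of the pmf.
    """
    if x <= 0:
        return 1.0
    hi = min(n1, n2)
    if x > hi:
        return 0.0
    total = Fraction(0)
    denom = math.comb(N, n2)
    for k in range(x, hi + 1):
        total += Fraction(math.comb(n1, k) * math.comb(N - n1, n2 - k), denom)
    return float(total)


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def shared_sweep_test(N: int, n1: int, n2: int, x: int, P: float = 1.0,
                      pop1: str = "", pop2: str = "") -> SharingTestResult:
    """Upper-tail hypergeometric test of shared sweep counts.

    The population with more regions is designated first (reordered
    internally). All four counts are scaled by the accuracy P, rounded
    half-up, and clamped to keep x' <= n2' <= n1' <= N' before the exact
    tail sum.
    """
    if n1 < n2:
        n1, n2 = n2, n1
        pop1, pop2 = pop2, pop1
    if not (0 <= x <= n2 <= n1 <= N):
        raise ValueError("counts must satisfy 0 <= x <= n2 <= n1 <= N")
    if not 0 < P <= 1:
        raise ValueError("P must be in (0, 1]")
    N_adj = _round_half_up(P * N)
    n1_adj = _round_half_up(P * n1)
    n2_adj = _round_half_up(P * n2)
    x_adj = _round_half_up(P * x)
    # consistency clamps: x' <= n2' <= n1' <= N'
    n1_adj = min(n1_adj, N_adj)
    n2_adj = min(n2_adj, n1_adj)
    x_adj = min(x_adj, n2_adj)
    p = _hypergeom_sf_exact(x_adj, N_adj, n1_adj, n2_adj)
    return SharingTestResult(
        pop1=pop1, pop2=pop2, N=N, n1=n1, n2=n2, x=x,
        N_adj=N_adj, n1_adj=n1_adj, n2_adj=n2_adj, x_adj=x_adj, p_raw=p,
    )


def default_locus_count(total_genome_bp: int, mean_region_bp: float, merge_dist: int) -> int:
    """Number of non-overlapping slots a sweep region could occupy.

    Serves as the test's total-locus count N: floor(total scanned length /
    (mean called region length + merge distance)).
    """
    slot = mean_region_bp + merge_dist
    if slot <= 0:
        raise ValueError("slot size must be positive")
    return int(total_genome_bp // slot)


# ---------------------------------------------------------------------------
# multiple-testing correction
# ---------------------------------------------------------------------------


def adjust_pvalues_by(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (any-dependence FDR)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def pairwise_sharing_tests(
    region_sets: dict[str, SweepRegionSet],
    N: int,
    P: float = 1.0,
) -> pd.DataFrame:
    """Pairwise sharing tests over all populations, BY-corrected.

    x is counted at the cluster level: the number of clusters containing
    regions from both populations of the pair.
    """
    pops = sorted(region_sets)
    clusters = cluster_regions(list(region_sets.values()))
    results: list[SharingTestResult] = []
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            x = sum(1 for c in clusters if {p1, p2} <= c.populations)
            results.append(
                shared_sweep_test(
                    N, len(region_sets[p1]), len(region_sets[p2]), x, P,
                    pop1=p1, pop2=p2,
                )
            )
    adj = adjust_pvalues_by([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    columns = ["pop1", "pop2", "N", "n1", "n2", "x", "N_adj", "n1_adj", "n2_adj",
               "x_adj", "p_raw", "p_adj"]
    return pd.DataFrame([r.__dict__ for r in results], columns=columns)
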