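"""Degeneracy annotation, uSFS construction, and asymptotic-MK alpha fits.

Coding positions are classified by how many of the four nucleotides
preserve the amino acid (0-fold: none besides the observed base; 4-fold:
all). Polymorphism and fixed-difference counts at 0-fold (selected) and
4-fold (neutral) sites, polarized against two outgroups, form an unfolded
site frequency spectrum; per-bin alpha = 1 - (d0/d) * (p_i/p0_i) with
subscript 0 denoting the neutral class, and the asymptote of
a + b*exp(-c*x) fitted to the bins estimates the adaptive proportion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synth import UsfsCounts, alpha_curve

logger = logging.getLogger(__name__)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codon_fold_classes(codon: str) -> list[int]:
    """Fold class at each of the three positions of a sense codon.

    The class is the number of nucleotides coding the same amino acid at
    that position, with the 1-nucleotide case named 0-fold by convention.
    """
    codon = codon.upper()
    aa = CODON_TABLE.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"not a sense codon: {codon!r}")
    classes = []
    for pos in range(3):
        same = 0
        for base in BASES:
            alt = codon[:pos] + base + codon[pos + 1:]
            if CODON_TABLE[alt] == aa:
                same += 1
        classes.append(0 if same == 1 else same)
    return classes


@dataclass
class DegeneracyAnnotation:
    """Fold class per genomic CDS position.

    ``table`` has columns chrom, pos (1-based), fold, strand, codon_pos
    (0..2 within codon), transcript.
    """

    table: pd.DataFrame
    n_skipped: int = 0
    n_conflicts: int = 0

    def fold_lookup(self) -> dict[tuple[str, int], int]:
        return {
            (c, int(p)): int(f)
            for c, p, f in zip(self.table["chrom"], self.table["pos"], self.table["fold"])
        }

    def to_bed(self) -> pd.DataFrame:
        """0-based BED representation (chrom, start, end, fold)."""
        t = self.table
        return pd.DataFrame(
            {"chrom": t["chrom"], "start": t["pos"] - 1, "end": t["pos"],
             "name": "fold" + t["fold"].astype(str), "score": t["fold"],
             "strand": t["strand"]}
        )


def classify_degeneracy(
    cds_records: list[dict],
    on_conflict: str = "most_constrained",
) -> DegeneracyAnnotation:
    """Annotate fold classes for a set of spliced CDS records.

    Each record is a dict with keys ``transcript``, ``chrom``, ``strand``
    ('+'/'-'), ``seq`` (spliced CDS in transcription order, phase-trimmed,
    length divisible by 3) and ``genomic_positions`` (1-based positions of
    each base of ``seq``, 5'->3' in transcript orientation). Codons with
    ambiguous bases or internal stops are skipped and counted. Positions
    annotated by multiple transcripts with conflicting classes are
    resolved to the most constrained (smallest) class, or dropped when
    ``on_conflict='drop'``.
    """
    if on_conflict not in ("most_constrained", "drop"):
        raise ValueError("on_conflict must be 'most_constrained' or 'drop'")
    rows = []
    n_skipped = 0
    for rec in cds_records:
        seq = rec["seq"].upper()
        gpos = np.asarray(rec["genomic_positions"], dtype=np.int64)
        if len(seq) != len(gpos):
            raise ValueError(f"{rec['transcript']}: seq/position length mismatch")
        if len(seq) % 3:
            raise ValueError(f"{rec['transcript']}: CDS length not divisible by 3")
        n_codons = len(seq) // 3
        for ci in range(n_codons):
            codon = seq[3 * ci: 3 * ci + 3]
            if any(b not in BASES for b in codon):
                n_skipped += 3
                continue
            aa = CODON_TABLE[codon]
            if aa == "*":
                if ci != n_codons - 1:
                    logger.warning(
                        "%s: internal stop at codon %d skipped", rec["transcript"], ci
                    )
                n_skipped += 3
                continue
            folds = codon_fold_classes(codon)
            for k in range(3):
                rows.append(
                    (rec["chrom"], int(gpos[3 * ci + k]), folds[k], rec["strand"], k,
                     rec["transcript"])
                )
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "fold", "strand", "codon_pos", "transcript"]
    )
    # resolve transcripts annotating the same genomic position
    n_conflicts = 0
    if not table.empty:
        grouped = table.groupby(["chrom", "pos"])["fold"].nunique()
        conflict_keys = set(grouped[grouped > 1].index)
        n_conflicts = len(conflict_keys)
        if conflict_keys:
            logger.info("%d positions with conflicting fold classes", n_conflicts)
        if on_conflict == "drop" and conflict_keys:
            mask = ~table.set_index(["chrom", "pos"]).index.isin(conflict_keys)
            table = table[mask]
        table = (
            table.sort_values(["chrom", "pos", "fold"])
            .drop_duplicates(["chrom", "pos"], keep="first")
            .reset_index(drop=True)
        )
    return DegeneracyAnnotation(table=table, n_skipped=n_skipped, n_conflicts=n_conflicts)


# ---------------------------------------------------------------------------
# outgroup polarization
# ---------------------------------------------------------------------------

HET_MAF_MAX = 0.001


def polarize_sites(
    og1_allele: np.ndarray,
    og1_maf: np.ndarray,
    og2_allele: np.ndarray,
    og2_maf: np.ndarray,
) -> tuple[np.ndarray, dict[str, int]]:
    """Ancestral-state calls from two outgroups.

    Outgroup states with minor allele frequency above 0.001 are treated as
    heterozygous, i.e. missing. The ancestral allele is the shared
    homozygous state of both outgroups; a state homozygous in outgroup 1
    but missing in outgroup 2 is accepted; sites missing in outgroup 1 are
    excluded, as are sites where the two homozygous states disagree.

    Returns (ancestral alleles as object array with None for excluded,
    exclusion-reason counts).
    """
    og1_allele = np.asarray(og1_allele, dtype=object)
    og2_allele = np.asarray(og2_allele, dtype=object)
    og1_maf = np.asarray(og1_maf, dtype=float)
    og2_maf = np.asarray(og2_maf, dtype=float)
    n = og1_allele.size
    anc = np.full(n, None, dtype=object)
    report = {"called": 0, "og1_missing": 0, "og1_het": 0, "disagree": 0}
    for i in range(n):
        a1 = og1_allele[i]
        a2 = og2_allele[i]
        if a1 is not None and og1_maf[i] > HET_MAF_MAX:
            a1 = None
            report["og1_het"] += 1
            continue
        if a2 is not None and og2_maf[i] > HET_MAF_MAX:
            a2 = None
        if a1 is None:
            report["og1_missing"] += 1
            continue
        if a2 is None:
            anc[i] = a1
            report["called"] += 1
        elif a1 == a2:
            anc[i] = a1
            report["called"] += 1
        else:
            report["disagree"] += 1
    return anc, report


# ---------------------------------------------------------------------------
# uSFS construction
# ---------------------------------------------------------------------------

MUTATION_CLASSES = {"AT2GC": ({"A", "T"}, {"G", "C"}), "GC2AT": ({"G", "C"}, {"A", "T"})}


def mutation_class(anc: str, der: str) -> str:
    for name, (src, dst) in MUTATION_CLASSES.items():
        if anc in src and der in dst:
            return name
    return "other"


def build_usfs(
    sites: pd.DataFrame,
    degeneracy: DegeneracyAnnotation,
    n: int,
    by_mutation_type: bool = False,
    labels: dict | None = None,
) -> UsfsCounts | dict[str, UsfsCounts]:
    """Tally selected/neutral uSFS counts from polarized site calls.

    ``sites`` columns: chrom, pos (1-based), derived_count (0..n; n means
    a fixed derived difference), anc, der. Sites lacking a fold class, an
    ancestral call (derived_count is NaN), or falling in 2-/3-fold classes
    are excluded and counted in the metadata report.
    """
    fold = degeneracy.fold_lookup()
    report = {"no_fold": 0, "midfold": 0, "no_ancestral": 0, "used": 0}

    def _empty() -> dict:
        return {"p": np.zeros(n - 1), "p0": np.zeros(n - 1), "d": 0.0, "d0": 0.0}

    strata: dict[str, dict] = {}
    for row in sites.itertuples(index=False):
        key = (row.chrom, int(row.pos))
        if pd.isna(row.derived_count):
            report["no_ancestral"] += 1
            continue
        f = fold.get(key)
        if f is None:
            report["no_fold"] += 1
            continue
        if f not in (0, 4):
            report["midfold"] += 1
            continue
        stratum = mutation_class(row.anc, row.der) if by_mutation_type else "all"
        bucket = strata.setdefault(stratum, _empty())
        dc = int(row.derived_count)
        if not 0 <= dc <= n:
            raise ValueError(f"derived_count {dc} outside [0, {n}] at {key}")
        if dc == 0:
            continue  # ancestral-fixed: contributes nothing
        report["used"] += 1
        if dc == n:  # fixed derived difference
            if f == 0:
                bucket["d"] += 1
            else:
                bucket["d0"] += 1
        else:
            if f == 0:
                bucket["p"][dc - 1] += 1
            else:
                bucket["p0"][dc - 1] += 1

    def _make(stratum: str, b: dict) -> UsfsCounts:
        lab = dict(labels or {})
        if by_mutation_type:
            lab["mutation_type"] = stratum
        return UsfsCounts(
            n=n, p=b["p"], p0=b["p0"], d=b["d"], d0=b["d0"], labels=lab,
            metadata={"report": dict(report)},
        )

    if by_mutation_type:
        return {s: _make(s, b) for s, b in strata.items()}
    bucket = strata.get("all", _empty())
    return _make("all", bucket)


# ---------------------------------------------------------------------------
# per-bin alpha and asymptotic fit
# ---------------------------------------------------------------------------


def alpha_per_bin(u: UsfsCounts) -> pd.DataFrame:
    """alpha_i = 1 - (d0/d) * (p_i/p0_i); NaN where p0_i = 0."""
    if u.d <= 0:
        raise ValueError("d = 0: every bin is undefined")
    if u.d0 <= 0:
        raise ValueError("d0 = 0: ratio undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = 1.0 - (u.d0 / u.d) * (u.p / u.p0)
    alpha = np.where(u.p0 > 0, alpha, np.nan)
    n_undef = int(np.isnan(alpha).sum())
    if n_undef:
        logger.info("%d/%d bins undefined (p0 = 0)", n_undef, u.n - 1)
    return pd.DataFrame({"bin": np.arange(1, u.n), "x": u.x, "alpha": alpha})


@dataclass
class AlphaFit:
    a: float
    b: float
    c: float
    alpha_inf: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    group: str = ""
    converged: bool = True
    c_identifiable: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.a + self.b * np.exp(-self.c)
        if np.isfinite(expected) and abs(expected - self.alpha_inf) > 1e-12:
            raise ValueError("alpha_inf inconsistent with (a, b, c)")


_C_STARTS = (0.5, 2.0, 8.0)
_BOUNDS = ([-10.0, -10.0, 1e-8], [10.0, 10.0, 100.0])


def _fit_curve(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Bounded NLS with multi-start over c; returns (params, cost, ok)."""

    def resid(theta):
        return alpha_curve(x, *theta) - y

    best = None
    for c0 in _C_STARTS:
        a0 = float(y[-1])
        b0 = float(y[0] - y[-1])
        try:
            sol = least_squares(resid, x0=[a0, b0, c0], bounds=_BOUNDS, method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return np.array([np.nan] * 3), np.inf, False
    return best.x, float(best.cost), bool(best.success)


def _fit_one_group(
    x: np.ndarray,
    y: np.ndarray,
    group: str,
    n_boot: int,
    ci_level: float,
    seed: int,
) -> AlphaFit:
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError(f"group {group!r}: need >= 5 defined bins, got {x.size}")
    if np.allclose(y, y[0], atol=1e-12):
        # constant curve: b = 0, c unidentifiable
        a = float(y[0])
        return AlphaFit(
            a=a, b=0.0, c=1.0, alpha_inf=a, ci_lower=a, ci_upper=a,
            ci_level=ci_level, group=group, converged=True, c_identifiable=False,
            diagnostics={"note": "constant alpha; c unidentifiable"},
        )
    theta, cost, ok_fit = _fit_curve(x, y)
    if not ok_fit:
        return AlphaFit(
            a=np.nan, b=np.nan, c=np.nan, alpha_inf=np.nan,
            ci_lower=np.nan, ci_upper=np.nan, ci_level=ci_level, group=group,
            converged=False, diagnostics={"cost": cost},
        )
    a, b, c = theta
    alpha_inf = float(a + b * np.exp(-c))
    lo = hi = alpha_inf
    boots = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, x.size, x.size)
            xb, yb = x[idx], y[idx]
            if np.unique(xb).size < 5:
                continue
            tb, _, okb = _fit_curve(xb, yb)
            if okb:
                vals.append(tb[0] + tb[1] * np.exp(-tb[2]))
        if vals:
            boots = np.asarray(vals)
            tail = (1 - ci_level) / 2
            lo = float(np.quantile(boots, tail))
            hi = float(np.quantile(boots, 1 - tail))
            lo = min(lo, alpha_inf)
            hi = max(hi, alpha_inf)
    return AlphaFit(
        a=float(a), b=float(b), c=float(c), alpha_inf=alpha_inf,
        ci_lower=lo, ci_upper=hi, ci_level=ci_level, group=group,
        converged=True,
        diagnostics={"cost": cost, "n_boot_ok": 0 if boots is None else len(boots)},
    )


def fit_asymptotic(
    curves: pd.DataFrame,
    mode: str = "per-group",
    n_boot: int = 100,
    ci_level: float = 0.95,
    seed: int = 0,
    subspecies_offset: bool = False,
) -> list[AlphaFit]:
    """Fit a + b*exp(-c*x) to per-bin alpha values.

    ``curves`` columns: x, alpha, and (optionally) group / subspecies.
    Modes: ``pooled`` ignores groups; ``per-group`` fits each group
    independently; ``partial-pooling`` fits per group and then shrinks
    each group's asymptote toward the across-group mean with an
    empirical-Bayes weight (between-group variance over total), adjusting
    the intercept a to keep (a, b, c) consistent with the asymptote. With
    ``subspecies_offset`` the shrinkage target is per-subspecies, which
    realizes a fixed subspecies effect on the asymptote level.
    """
    if mode not in ("pooled", "per-group", "partial-pooling"):
        raise ValueError(f"unknown mode {mode!r}")
    df = curves.copy()
    if "group" not in df.columns or mode == "pooled":
        df["group"] = "all"
    fits = []
    for i, (group, sub) in enumerate(df.groupby("group", sort=True)):
        fit = _fit_one_group(
            sub["x"].to_numpy(float), sub["alpha"].to_numpy(float),
            str(group), n_boot, ci_level, seed + i,
        )
        if subspecies_offset and "subspecies" in sub.columns:
            fit.diagnostics["subspecies"] = str(sub["subspecies"].iloc[0])
        fits.append(fit)
    if mode != "partial-pooling" or len(fits) < 3:
        return fits

    # empirical-Bayes shrinkage of asymptotes toward the (per-subspecies) mean
    ok = [f for f in fits if f.converged and np.isfinite(f.alpha_inf)]
    if len(ok) < 3:
        return fits

    def _target_groups():
        if subspecies_offset:
            by_ssp: dict[str, list[AlphaFit]] = {}
            for f in ok:
                by_ssp.setdefault(f.diagnostics.get("subspecies", "all"), []).append(f)
            return by_ssp.values()
        return [ok]

    for members in _target_groups():
        vals = np.array([f.alpha_inf for f in members])
        if vals.size < 3:
            continue
        grand = float(vals.mean())
        var_between = float(vals.var(ddof=1))
        # within-group noise from bootstrap spread when available
        noises = []
        for f in members:
            if f.ci_upper > f.ci_lower:
                z = 3.92  # 2 * 1.96 for the default 95% interval
                noises.append(((f.ci_upper - f.ci_lower) / z) ** 2)
        s2 = float(np.mean(noises)) if noises else var_between / 2
        tau2 = max(var_between - s2, 0.0)
        w = tau2 / (tau2 + s2) if (tau2 + s2) > 0 else 1.0
        for f in members:
            shrunk = w * f.alpha_inf + (1 - w) * grand
            f.a += shrunk - f.alpha_inf
            delta = shrunk - f.alpha_inf
            f.ci_lower += delta
            f.ci_upper += delta
            f.alpha_inf = f.a + f.b * float(np.exp(-f.c))
            f.diagnostics["shrinkage_weight"] = w
    return fits


def fits_to_dataframe(fits: list[AlphaFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": f.group, "a": f.a, "b": f.b, "c": f.c,
                "alpha_inf": f.alpha_inf, "ci_lower": f.ci_lower,
                "ci_upper": f.ci_upper, "ci_level": f.ci_level,
                "converged": f.converged, "c_identifiable": f.c_identifiable,
            }
            for f in fits
        ]
    )
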