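import numpy as np
import pandas as pd
import pytest

from sweepshare.mk import (
    BASES,
    CODON_TABLE,
    alpha_per_bin,
    build_usfs,
    classify_degeneracy,
    codon_fold_classes,
    fit_asymptotic,
    mutation_class,
    polarize_sites,
    reverse_complement,
)
from sweepshare.synth import UsfsCounts, alpha_curve, generate_usfs_counts

SENSE_CODONS = [c for c, aa in CODON_TABLE.items() if aa != "*"]


def oracle_fold(codon: str, pos: int) -> int:
    """Brute-force translate-all-substitutions oracle via Biopython."""
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    same = sum(
        1
        for b in BASES
        if str(Seq(codon[:pos] + b + codon[pos + 1:]).translate()) == aa
    )
    return 0 if same == 1 else same


class TestCodonFoldClasses:
    def test_atg_all_zero_fold(self):
        assert codon_fold_classes("ATG") == [0, 0, 0]

    def test_gga_third_position_four_fold(self):
        assert codon_fold_classes("GGA")[2] == 4

    def test_all_sense_codons_match_translation_oracle(self):
        for codon in SENSE_CODONS:
            got = codon_fold_classes(codon)
            expect = [oracle_fold(codon, p) for p in range(3)]
            assert got == expect, codon

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_fold_classes("TAA")


def _record(seq, positions=None, chrom="1", strand="+", transcript="t1"):
    if positions is None:
        positions = np.arange(1, len(seq) + 1)
    return {"transcript": transcript, "chrom": chrom, "strand": strand,
            "seq": seq, "genomic_positions": np.asarray(positions)}


class TestClassifyDegeneracy:
    def test_exhaustive_on_concatenated_codons(self):
        seq = "".join(SENSE_CODONS)
        ann = classify_degeneracy([_record(seq)])
        lookup = ann.fold_lookup()
        for ci, codon in enumerate(SENSE_CODONS):
            for k in range(3):
                assert lookup[("1", 3 * ci + k + 1)] == oracle_fold(codon, k)

    def test_strand_symmetry(self):
        # the same coding sequence annotated as a minus-strand feature
        # mirrors the genomic fold map of its plus-strand representation
        seq = "ATGGGATTTCTG"
        n = len(seq)
        plus = classify_degeneracy([_record(seq)]).fold_lookup()
        minus = classify_degeneracy(
            [_record(seq, positions=np.arange(n, 0, -1), strand="-")]
        ).fold_lookup()
        for p in range(1, n + 1):
            assert plus[("1", p)] == minus[("1", n + 1 - p)]

    def test_internal_stop_skipped(self, caplog):
        seq = "ATG" + "TAA" + "GGA"
        ann = classify_degeneracy([_record(seq)])
        assert ("1", 4) not in ann.fold_lookup()
        assert ann.n_skipped == 3

    def test_ambiguous_base_skipped(self):
        ann = classify_degeneracy([_record("ATGGNA")])
        assert set(ann.table["pos"]) == {1, 2, 3}

    def test_conflicting_transcripts_most_constrained_wins(self):
        # GGA pos 3 is 4-fold; ATG pos 3 is 0-fold at the same genomic spot
        r1 = _record("GGA", positions=[10, 11, 12], transcript="t1")
        r2 = _record("ATG", positions=[14, 13, 12], transcript="t2")
        ann = classify_degeneracy([r1, r2])
        assert ann.fold_lookup()[("1", 12)] == 0
        assert ann.n_conflicts == 1

    def test_conflicting_transcripts_drop_mode(self):
        r1 = _record("GGA", positions=[10, 11, 12], transcript="t1")
        r2 = _record("ATG", positions=[14, 13, 12], transcript="t2")
        ann = classify_degeneracy([r1, r2], on_conflict="drop")
        assert ("1", 12) not in ann.fold_lookup()

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            classify_degeneracy([_record("ATGG")])


class TestPolarizeSites:
    def test_both_homozygous_agreeing(self):
        anc, rep = polarize_sites(["A"], [0.0], ["A"], [0.0])
        assert anc[0] == "A" and rep["called"] == 1

    def test_og1_homozygous_og2_missing(self):
        anc, _ = polarize_sites(["A"], [0.0], [None], [0.0])
        assert anc[0] == "A"

    def test_og1_missing_excluded(self):
        anc, rep = polarize_sites([None], [0.0], ["A"], [0.0])
        assert anc[0] is None and rep["og1_missing"] == 1

    def test_heterozygous_outgroup_treated_missing(self):
        # MAF 0.002 > 0.001 -> og1 missing -> site excluded
        anc, rep = polarize_sites(["A"], [0.002], ["A"], [0.0])
        assert anc[0] is None and rep["og1_het"] == 1

    def test_og2_heterozygous_falls_back_to_og1(self):
        anc, _ = polarize_sites(["A"], [0.0], ["G"], [0.5])
        assert anc[0] == "A"

    def test_disagreement_excluded_and_counted(self):
        anc, rep = polarize_sites(["A"], [0.0], ["G"], [0.0])
        assert anc[0] is None and rep["disagree"] == 1


def _ann_from_rows(rows):
    from sweepshare.mk import DegeneracyAnnotation

    return DegeneracyAnnotation(
        table=pd.DataFrame(
            rows, columns=["chrom", "pos", "fold", "strand", "codon_pos", "transcript"]
        )
    )


class TestBuildUsfs:
    def test_only_fourfold_singletons(self):
        sites = pd.DataFrame(
            {"chrom": "1", "pos": [10, 20, 30], "derived_count": 1.0,
             "anc": "A", "der": "T"}
        )
        ann = _ann_from_rows([("1", p, 4, "+", 0, "t") for p in (10, 20, 30)])
        u = build_usfs(sites, ann, n=10)
        assert u.p0[0] == 3 and u.p0[1:].sum() == 0 and u.p.sum() == 0

    def test_pre_binned_counts_round_trip(self):
        src = generate_usfs_counts(0.2, -0.3, 4.0, d0=50, d=40, theta0=100, n=6, seed=5)
        rows = []
        pos = 1
        for i in range(1, 6):
            for _ in range(int(src.p[i - 1])):
                rows.append(("1", pos, i, 0)); pos += 1
            for _ in range(int(src.p0[i - 1])):
                rows.append(("1", pos, i, 4)); pos += 1
        for _ in range(int(src.d)):
            rows.append(("1", pos, 6, 0)); pos += 1
        for _ in range(int(src.d0)):
            rows.append(("1", pos, 6, 4)); pos += 1
        sites = pd.DataFrame(
            [{"chrom": c, "pos": p, "derived_count": float(dc), "anc": "A", "der": "T"}
             for c, p, dc, _ in rows]
        )
        ann = _ann_from_rows([(c, p, f, "+", 0, "t") for c, p, _, f in rows])
        u = build_usfs(sites, ann, n=6)
        assert np.array_equal(u.p, src.p) and np.array_equal(u.p0, src.p0)
        assert (u.d, u.d0) == (src.d, src.d0)

    def test_hand_tally_six_sites(self):
        # 0-fold: singleton, doubleton, fixed; 4-fold: singleton, fixed, excluded
        sites = pd.DataFrame(
            [
                {"chrom": "1", "pos": 1, "derived_count": 1.0, "anc": "A", "der": "G"},
                {"chrom": "1", "pos": 2, "derived_count": 2.0, "anc": "A", "der": "G"},
                {"chrom": "1", "pos": 3, "derived_count": 4.0, "anc": "C", "der": "T"},
                {"chrom": "1", "pos": 4, "derived_count": 1.0, "anc": "G", "der": "C"},
                {"chrom": "1", "pos": 5, "derived_count": 4.0, "anc": "T", "der": "A"},
                {"chrom": "1", "pos": 6, "derived_count": np.nan, "anc": "A", "der": "G"},
            ]
        )
        ann = _ann_from_rows(
            [("1", 1, 0, "+", 0, "t"), ("1", 2, 0, "+", 0, "t"), ("1", 3, 0, "+", 0, "t"),
             ("1", 4, 4, "+", 0, "t"), ("1", 5, 4, "+", 0, "t"), ("1", 6, 4, "+", 0, "t")]
        )
        u = build_usfs(sites, ann, n=4)
        assert list(u.p) == [1, 1, 0]
        assert list(u.p0) == [1, 0, 0]
        assert (u.d, u.d0) == (1, 1)
        assert u.metadata["report"]["no_ancestral"] == 1

    def test_midfold_and_unannotated_excluded(self):
        sites = pd.DataFrame(
            [{"chrom": "1", "pos": 1, "derived_count": 1.0, "anc": "A", "der": "G"},
             {"chrom": "1", "pos": 99, "derived_count": 1.0, "anc": "A", "der": "G"}]
        )
        ann = _ann_from_rows([("1", 1, 2, "+", 0, "t")])
        u = build_usfs(sites, ann, n=4)
        assert u.p.sum() == 0 and u.p0.sum() == 0
        assert u.metadata["report"]["midfold"] == 1
        assert u.metadata["report"]["no_fold"] == 1

    def test_mutation_type_stratification(self):
        assert mutation_class("A", "G") == "AT2GC"
        assert mutation_class("C", "T") == "GC2AT"
        assert mutation_class("A", "T") == "other"
        sites = pd.DataFrame(
            [{"chrom": "1", "pos": 1, "derived_count": 1.0, "anc": "A", "der": "G"},
             {"chrom": "1", "pos": 2, "derived_count": 1.0, "anc": "A", "der": "T"}]
        )
        ann = _ann_from_rows([("1", 1, 0, "+", 0, "t"), ("1", 2, 0, "+", 0, "t")])
        strata = build_usfs(sites, ann, n=4, by_mutation_type=True)
        assert set(strata) == {"AT2GC", "other"}


class TestAlphaPerBin:
    def test_zero_selected_polymorphism_gives_one(self):
        u = UsfsCounts(n=4, p=[0, 0, 0], p0=[5, 5, 5], d=10, d0=10)
        assert np.allclose(alpha_per_bin(u)["alpha"], 1.0)

    def test_balanced_ratio_gives_zero(self):
        u = UsfsCounts(n=4, p=[5, 5, 5], p0=[5, 5, 5], d=10, d0=10)
        assert np.allclose(alpha_per_bin(u)["alpha"], 0.0)

    def test_worked_arithmetic(self):
        u = UsfsCounts(n=4, p=[40, 40, 40], p0=[100, 100, 100], d=100, d0=200)
        assert np.allclose(alpha_per_bin(u)["alpha"], 1 - 2 * 0.4)

    def test_undefined_bins_flagged(self):
        u = UsfsCounts(n=4, p=[1, 1, 1], p0=[5, 0, 5], d=10, d0=10)
        alpha = alpha_per_bin(u)["alpha"]
        assert np.isnan(alpha[1]) and np.isfinite(alpha[0])

    def test_scale_invariance(self):
        u1 = UsfsCounts(n=6, p=[3, 4, 5, 6, 7], p0=[9, 8, 7, 6, 5], d=10, d0=20)
        u2 = UsfsCounts(n=6, p=np.array([3, 4, 5, 6, 7]) * 7,
                        p0=np.array([9, 8, 7, 6, 5]) * 7, d=10, d0=20)
        u3 = UsfsCounts(n=6, p=[3, 4, 5, 6, 7], p0=[9, 8, 7, 6, 5], d=30, d0=60)
        a1 = alpha_per_bin(u1)["alpha"]
        assert np.allclose(a1, alpha_per_bin(u2)["alpha"])
        assert np.allclose(a1, alpha_per_bin(u3)["alpha"])

    def test_zero_divergence_signalled(self):
        u = UsfsCounts(n=4, p=[1, 1, 1], p0=[5, 5, 5], d=0, d0=10)
        with pytest.raises(ValueError):
            alpha_per_bin(u)


def _curve_df(a, b, c, n=20, group=None, noise=0.0, seed=0):
    x = np.arange(1, n) / n
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"x": x, "alpha": alpha_curve(x, a, b, c)
                       + noise * rng.standard_normal(n - 1)})
    if group is not None:
        df["group"] = group
    return df


class TestFitAsymptotic:
    def test_exact_recovery_without_noise(self):
        fits = fit_asymptotic(_curve_df(0.3, -0.4, 5.0), mode="pooled", n_boot=0)
        (fit,) = fits
        assert fit.a == pytest.approx(0.3, abs=1e-4)
        assert fit.b == pytest.approx(-0.4, abs=1e-4)
        assert fit.c == pytest.approx(5.0, abs=1e-3)
        assert fit.alpha_inf == pytest.approx(0.3 - 0.4 * np.exp(-5), abs=1e-4)

    def test_constant_curve_contract(self):
        fits = fit_asymptotic(_curve_df(0.25, 0.0, 3.0), mode="pooled", n_boot=0)
        (fit,) = fits
        assert fit.alpha_inf == pytest.approx(0.25)
        assert not fit.c_identifiable

    def test_per_group_equals_pooled_on_single_group(self):
        df = _curve_df(0.2, -0.5, 3.0, noise=0.05, seed=3, group="g1")
        per_group = fit_asymptotic(df, mode="per-group", n_boot=0)
        pooled = fit_asymptotic(df.drop(columns="group"), mode="pooled", n_boot=0)
        assert per_group[0].alpha_inf == pytest.approx(pooled[0].alpha_inf, abs=1e-6)

    def test_insufficient_bins_rejected(self):
        df = _curve_df(0.3, -0.4, 5.0).iloc[:4]
        with pytest.raises(ValueError):
            fit_asymptotic(df, mode="pooled", n_boot=0)

    def test_interval_contains_point_estimate(self):
        df = _curve_df(0.3, -0.4, 5.0, noise=0.05, seed=11)
        (fit,) = fit_asymptotic(df, mode="pooled", n_boot=50, seed=2)
        assert fit.ci_lower <= fit.alpha_inf <= fit.ci_upper

    def test_simulation_recovery_rate(self):
        a, b, c = 0.3, -0.4, 5.0
        truth = a + b * np.exp(-c)
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            u = generate_usfs_counts(a, b, c, d0=200, d=100, theta0=1e4, n=20, seed=s)
            df = alpha_per_bin(u).dropna(subset=["alpha"])
            (fit,) = fit_asymptotic(df, mode="pooled", n_boot=0)
            hits += abs(fit.alpha_inf - truth) < 0.05
        assert hits / n_seeds >= 0.9

    def test_partial_pooling_reduces_mse_with_shared_hyperparameters(self):
        a, b, c = 0.3, -0.4, 5.0
        truth = a + b * np.exp(-c)
        err_pg, err_pp = [], []
        for s in range(50):
            frames = []
            for g in range(8):
                u = generate_usfs_counts(a, b, c, d0=200, d=100, theta0=300,
                                         n=20, seed=1000 * s + g)
                df = alpha_per_bin(u).dropna(subset=["alpha"])
                df["group"] = f"g{g}"
                frames.append(df)
            curves = pd.concat(frames)
            pg = fit_asymptotic(curves, mode="per-group", n_boot=0)
            pp = fit_asymptotic(curves, mode="partial-pooling", n_boot=0)
            err_pg.append(np.mean([(f.alpha_inf - truth) ** 2 for f in pg]))
            err_pp.append(np.mean([(f.alpha_inf - truth) ** 2 for f in pp]))
        assert np.mean(err_pp) < np.mean(err_pg)

    def test_consistency_invariant(self):
        df = _curve_df(0.3, -0.4, 5.0, noise=0.02, seed=7)
        (fit,) = fit_asymptotic(df, mode="pooled", n_boot=0)
        assert abs(fit.alpha_inf - (fit.a + fit.b * np.exp(-fit.c))) < 1e-12
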