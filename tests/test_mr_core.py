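import numpy as np
import pandas as pd
import pytest

from reprotri.mr_core import (
    HarmonizedInstrumentSet,
    SummaryStatRecord,
    harmonize,
    instrument_strength,
    ivw,
    mr_egger,
    mvmr_ivw,
    negative_control_outcome_mr,
    wald_ratio,
    weighted_median,
)
from reprotri.studies import two_sample_mr_replicate


def _wls_oracle(X, y, w):
    """Independent weighted-least-squares solution via lstsq on the
    sqrt-weight-scaled system."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def _random_set(rng, k=None, second=False):
    k = k or int(rng.integers(5, 60))
    bx = rng.normal(0.05, 0.03, k)
    sex = rng.uniform(0.002, 0.01, k)
    by = rng.normal(0.0, 0.05, k)
    sey = rng.uniform(0.005, 0.03, k)
    if second:
        bx2 = rng.normal(0.02, 0.04, k)
        sex2 = rng.uniform(0.002, 0.01, k)
        return HarmonizedInstrumentSet.from_arrays(bx, sex, by, sey, bx2=bx2, sex2=sex2)
    return HarmonizedInstrumentSet.from_arrays(bx, sex, by, sey)


class TestHarmonize:
    def _exp(self):
        return pd.DataFrame(
            {
                "snp": ["rs1", "rs2", "rs3", "rs4"],
                "ea": ["A", "C", "A", "G"],
                "oa": ["G", "T", "T", "A"],
                "eaf": [0.3, 0.4, 0.2, 0.6],
                "beta": [0.10, 0.20, 0.15, 0.05],
                "se": [0.01, 0.01, 0.01, 0.01],
            }
        )

    def test_swapped_alleles_flip_outcome_beta(self):
        out = self._exp().assign(beta=[0.2, 0.1, 0.3, 0.1])
        out.loc[0, ["ea", "oa"]] = ["G", "A"]
        out.loc[0, "eaf"] = 0.7
        h = harmonize(self._exp(), out)
        row = h.data.set_index("snp").loc["rs1"]
        assert row["by"] == pytest.approx(-0.2)
        assert bool(row["flipped"])

    def test_strand_complement_recognised(self):
        out = self._exp().assign(beta=[0.2, 0.1, 0.3, 0.1])
        out.loc[1, ["ea", "oa"]] = ["G", "A"]  # complement of C/T
        h = harmonize(self._exp(), out)
        row = h.data.set_index("snp").loc["rs2"]
        assert row["by"] == pytest.approx(0.1)
        assert not bool(row["flipped"])

    def test_palindrome_at_half_frequency_dropped(self):
        exp = self._exp()
        exp.loc[2, "eaf"] = 0.50  # A/T palindrome, uninformative EAF
        out = exp.assign(beta=[0.2, 0.1, 0.3, 0.1])
        h = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert "rs3" not in set(h.data["snp"])
        reasons = {e["snp"]: e["reason"] for e in h.log if e["action"] == "dropped"}
        assert reasons["rs3"] == "palindromic_ambiguous"

    def test_palindrome_resolved_by_eaf_concordance(self):
        exp = self._exp()  # rs3 A/T with eaf 0.2
        out = exp.assign(beta=[0.2, 0.1, 0.3, 0.1])
        out.loc[2, "eaf"] = 0.8  # discordant side: outcome oriented to T
        h = harmonize(exp, out)
        row = h.data.set_index("snp").loc["rs3"]
        assert row["by"] == pytest.approx(-0.3)
        assert bool(row["inferred_by_eaf"])

    def test_strand_complement_of_swapped_alleles_flips(self):
        out = self._exp().assign(beta=[0.2, 0.1, 0.3, 0.1])
        # exposure rs4 is G/A; C/T is its direct strand complement
        out.loc[3, ["ea", "oa"]] = ["C", "T"]
        h = harmonize(self._exp(), out)
        row = h.data.set_index("snp").loc["rs4"]
        assert row["by"] == pytest.approx(0.1) and not bool(row["flipped"])

    def test_irreconcilable_alleles_dropped(self):
        out = self._exp().assign(beta=[0.2, 0.1, 0.3, 0.1])
        out.loc[3, ["ea", "oa"]] = ["C", "G"]  # exposure has G/A: no match
        h = harmonize(self._exp(), out)
        assert "rs4" not in set(h.data["snp"])
        reasons = {e["snp"]: e["reason"] for e in h.log if e["action"] == "dropped"}
        assert reasons["rs4"] == "allele_mismatch"

    def test_empty_intersection_rejected(self):
        out = self._exp().assign(snp=["x1", "x2", "x3", "x4"])
        with pytest.raises(ValueError, match="no shared SNP"):
            harmonize(self._exp(), out)

    def test_relabelling_leaves_ivw_invariant(self, rng):
        """Randomly flipping outcome allele labels (with matching beta/eaf
        changes) must not change the IVW estimate."""
        exp = self._exp()
        out = self._exp().assign(beta=[0.21, 0.12, 0.31, 0.14], se=[0.02] * 4)
        base = ivw(harmonize(exp, out))
        flip = out.copy()
        for i in [0, 3]:
            flip.loc[i, ["ea", "oa"]] = out.loc[i, ["oa", "ea"]].to_numpy()
            flip.loc[i, "beta"] = -out.loc[i, "beta"]
            flip.loc[i, "eaf"] = 1 - out.loc[i, "eaf"]
        relabelled = ivw(harmonize(exp, flip))
        assert relabelled.beta == pytest.approx(base.beta, rel=1e-12)


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.5, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(0.1)
        assert est.se == pytest.approx(0.04)

    def test_zero_outcome_beta(self):
        est = wald_ratio(0.5, 0.01, 0.0, 0.02)
        assert est.beta == 0.0 and est.se == pytest.approx(0.04)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)

    def test_first_order_se_close_to_second_order_for_strong_instrument(self):
        bx, sex, by, sey = 0.5, 0.01, 0.2, 0.02  # |bx/sex| = 50
        est = wald_ratio(bx, sex, by, sey)
        second = np.sqrt(sey**2 / bx**2 + by**2 * sex**2 / bx**4)
        assert abs(est.se - second) / second < 0.10


class TestIVW:
    def test_collinear_points_recover_exact_slope(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = HarmonizedInstrumentSet.from_arrays(bx, bx * 0 + 0.01, 0.3 * bx, bx * 0 + 0.02)
        est = ivw(h)
        assert est.beta == pytest.approx(0.3, rel=1e-12)
        assert est.cochran_q == pytest.approx(0.0, abs=1e-20)

    def test_single_snp_directed_to_wald(self):
        h = HarmonizedInstrumentSet.from_arrays([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(h)
        w = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert w.beta == pytest.approx(0.5)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(100):
            h = _random_set(rng)
            est = ivw(h, mode="fixed")
            coef = _wls_oracle(h.bx[:, None], h.by, h.sey**-2.0)
            assert abs(est.beta - coef[0]) <= 1e-10 * max(1.0, abs(coef[0]))

    def test_mre_se_never_below_fixed(self, rng):
        h = _random_set(rng)
        assert ivw(h).se >= ivw(h, mode="fixed").se


class TestEgger:
    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        by = 0.02 + 0.3 * bx
        h = HarmonizedInstrumentSet.from_arrays(bx, bx * 0 + 0.01, by, bx * 0 + 0.02)
        slope, intercept = mr_egger(h)
        assert slope.beta == pytest.approx(0.3, rel=1e-12)
        assert intercept.beta == pytest.approx(0.02, rel=1e-12)

    def test_bx_orientation_makes_fit_sign_invariant(self, rng):
        h = _random_set(rng, k=20)
        flipped = HarmonizedInstrumentSet.from_arrays(-h.bx, h.sex, -h.by, h.sey)
        s1, i1 = mr_egger(h)
        s2, i2 = mr_egger(flipped)
        assert s1.beta == pytest.approx(s2.beta, rel=1e-12)
        assert i1.beta == pytest.approx(i2.beta, rel=1e-12)

    def test_constant_bx_unidentified(self):
        h = HarmonizedInstrumentSet.from_arrays(
            [0.1, 0.1, 0.1], [0.01] * 3, [0.1, 0.2, 0.3], [0.02] * 3
        )
        with pytest.raises(ValueError, match="unidentified"):
            mr_egger(h)

    def test_matches_wls_with_intercept_oracle(self, rng):
        for _ in range(100):
            h = _random_set(rng)
            sign = np.where(h.bx < 0, -1.0, 1.0)
            X = np.column_stack([np.ones(h.k), sign * h.bx])
            coef = _wls_oracle(X, sign * h.by, h.sey**-2.0)
            slope, intercept = mr_egger(h)
            assert abs(slope.beta - coef[1]) <= 1e-10 * max(1.0, abs(coef[1]))
            assert abs(intercept.beta - coef[0]) <= 1e-10 * max(1.0, abs(coef[0]))

    def test_recovers_truth_under_directional_pleiotropy_with_inside(self):
        h, truth = two_sample_mr_replicate(
            n=100_000, k=100, theta=0.1, prop_invalid=1.0,
            pleiotropy_mean=0.02, pleiotropy_sd=0.005, rng=3, mode="summary",
        )
        slope, intercept = mr_egger(h)
        est_ivw = ivw(h)
        assert abs(slope.beta - 0.1) < abs(est_ivw.beta - 0.1)
        assert intercept.beta == pytest.approx(0.02, abs=3 * intercept.se)


class TestWeightedMedian:
    def test_identical_ratios_degenerate(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = HarmonizedInstrumentSet.from_arrays(bx, bx * 0 + 0.01, 0.25 * bx, [0.01, 0.05, 0.2])
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.25, rel=1e-9)

    def test_hand_evaluated_interpolation(self):
        """Three ratios (0.1, 0.2, 0.9) with equal weights: midpoints are
        (1/6, 1/2, 5/6) so the CDF hits 0.5 exactly at the middle ratio."""
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        h = HarmonizedInstrumentSet.from_arrays(bx, bx * 0 + 0.1, by, bx * 0 + 0.05)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2, rel=1e-12)

    def test_small_bootstrap_warns(self):
        h = _random_set(np.random.default_rng(0), k=10)
        with pytest.warns(RuntimeWarning, match="n_boot"):
            weighted_median(h, n_boot=50, seed=0)

    def test_zero_bx_dropped(self):
        h = HarmonizedInstrumentSet.from_arrays(
            [0.0, 0.2, 0.3, 0.4], [0.01] * 4, [0.1, 0.04, 0.06, 0.08], [0.02] * 4
        )
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.k_snps == 3
        assert est.diagnostics["dropped_zero_bx"] == 1

    def test_seeded_bootstrap_reproducible(self, rng):
        h = _random_set(rng, k=15)
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        assert a.se == b.se


class TestMVMR:
    def test_zero_second_exposure_reduces_to_univariable(self, rng):
        h2 = _random_set(rng, k=20, second=True)
        data = h2.data.copy()
        data["bx2"] = 0.0
        h2 = HarmonizedInstrumentSet(data=data, exposure_names=("e1", "e2"))
        uni = ivw(HarmonizedInstrumentSet.from_arrays(h2.bx, h2.sex, h2.by, h2.sey), mode="fixed")
        direct = mvmr_ivw(h2, mode="fixed")
        assert direct["e1"].beta == pytest.approx(uni.beta, rel=1e-12)
        assert np.isnan(direct["e2"].beta)

    def test_matches_two_column_wls_oracle(self, rng):
        for _ in range(100):
            h = _random_set(rng, second=True)
            X = np.column_stack([h.bx, h.data["bx2"].to_numpy()])
            coef = _wls_oracle(X, h.by, h.sey**-2.0)
            est = mvmr_ivw(h)
            assert abs(est["exposure"].beta - coef[0]) <= 1e-10 * max(1.0, abs(coef[0]))
            assert abs(est["exposure2"].beta - coef[1]) <= 1e-10 * max(1.0, abs(coef[1]))

    def test_rank_deficient_design_rejected(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = HarmonizedInstrumentSet.from_arrays(
            bx, bx * 0 + 0.01, 0.2 * bx, bx * 0 + 0.02, bx2=2 * bx, sex2=bx * 0 + 0.01
        )
        with pytest.raises(ValueError, match="rank"):
            mvmr_ivw(h)


class TestInstrumentStrength:
    def test_plug_in_single_snp(self):
        frame = pd.DataFrame(
            {"snp": ["rs1"], "ea": ["A"], "oa": ["G"], "eaf": [0.5],
             "beta": [0.1], "se": [0.01], "n": [10_000]}
        )
        res = instrument_strength(frame, trait_variance=1.0)
        assert res.r2_total == pytest.approx(0.005)
        expected_f = 0.005 * 9998 / 0.995
        assert res.mean_f == pytest.approx(expected_f)

    def test_null_snp_contributes_nothing(self):
        frame = pd.DataFrame(
            {"snp": ["rs1"], "ea": ["A"], "oa": ["G"], "eaf": [0.3],
             "beta": [0.0], "se": [0.01], "n": [1000]}
        )
        res = instrument_strength(frame, trait_variance=2.0)
        assert res.r2_total == 0.0 and res.mean_f == 0.0

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            instrument_strength(pd.DataFrame(), trait_variance=0.0)


class TestProperties:
    def test_outcome_rescaling_equivariance(self, rng):
        h = _random_set(rng, k=25)
        c = 3.7
        scaled = HarmonizedInstrumentSet.from_arrays(h.bx, h.sex, c * h.by, c * h.sey)
        for mode in ("fixed", "multiplicative_random"):
            a, b = ivw(h, mode=mode), ivw(scaled, mode=mode)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-12)
            assert b.se == pytest.approx(c * a.se, rel=1e-12)
        sa, ia = mr_egger(h)
        sb, ib = mr_egger(scaled)
        assert sb.beta == pytest.approx(c * sa.beta, rel=1e-12)
        assert ib.se == pytest.approx(c * ia.se, rel=1e-12)
        wa = weighted_median(h, n_boot=300, seed=3)
        wb = weighted_median(scaled, n_boot=300, seed=3)
        assert wb.beta == pytest.approx(c * wa.beta, rel=1e-12)

    def test_snp_order_permutation_leaves_estimates_identical(self, rng):
        h = _random_set(rng, k=30)
        perm = rng.permutation(30)
        hp = HarmonizedInstrumentSet.from_arrays(
            h.bx[perm], h.sex[perm], h.by[perm], h.sey[perm]
        )
        assert ivw(hp).beta == pytest.approx(ivw(h).beta, rel=1e-12)
        assert mr_egger(hp)[0].beta == pytest.approx(mr_egger(h)[0].beta, rel=1e-12)
        # the weighted median point estimate is order-free; its bootstrap SE
        # requires identical seeding plus identical draw-to-SNP assignment
        assert weighted_median(hp, 200, seed=1).beta == pytest.approx(
            weighted_median(h, 200, seed=1).beta, rel=1e-12
        )


class TestNegativeControlOutcome:
    def test_null_outcome_rarely_flagged(self, rng):
        flags = 0
        n_reps = 60
        for rep in range(n_reps):
            h, _ = two_sample_mr_replicate(
                n=20_000, k=30, theta=0.0, rng=np.random.default_rng(rep), mode="summary"
            )
            _, flag = negative_control_outcome_mr(h, alpha=0.05)
            flags += flag
        assert flags / n_reps <= 0.05 * 2.5

    def test_confounded_outcome_flagged(self):
        # outcome sharing the instruments' aggregate signal: strong flag
        h, _ = two_sample_mr_replicate(n=50_000, k=30, theta=0.3, rng=5, mode="summary")
        est, flag = negative_control_outcome_mr(h, alpha=0.05)
        assert flag and est.p < 1e-6

    def test_empty_set_rejected(self):
        h = HarmonizedInstrumentSet(data=pd.DataFrame(columns=["bx", "sex", "by", "sey"]))
        with pytest.raises(ValueError):
            negative_control_outcome_mr(h)


def test_summary_stat_record_validation():
    with pytest.raises(ValueError, match="se"):
        SummaryStatRecord("rs1", "A", "G", 0.3, 0.1, 0.0)
    with pytest.raises(ValueError, match="eaf"):
        SummaryStatRecord("rs1", "A", "G", 1.2, 0.1, 0.01)
    with pytest.raises(ValueError, match="allele"):
        SummaryStatRecord("rs1", "A", "A", 0.3, 0.1, 0.01)
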