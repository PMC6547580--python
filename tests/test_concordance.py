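import numpy as np
import pandas as pd
import pytest

import pam50kit as pk
from pam50kit.concordance import (
    BlandAltmanStats,
    bin_correlations,
    crosstab_calls,
)
from pam50kit.errors import ConcordanceError, ValidationError
from conftest import make_call
from test_pam50 import brute_force_spearman


class TestSpearman:
    def test_perfect_agreement(self):
        rho, _ = pk.spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_perfect_inversion(self):
        rho, _ = pk.spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_brute_force_ranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 5.0]
        rho, _ = pk.spearman_rho(x, y)
        assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConcordanceError):
            pk.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestIcc:
    def test_identity_is_one(self):
        x = np.arange(10.0)
        res = pk.icc_single_measures(x, x)
        assert res.icc == pytest.approx(1.0)

    def test_constant_shift_distinguishes_variants(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        cons = pk.icc_single_measures(x, x + 2.0, variant="consistency")
        agree = pk.icc_single_measures(x, x + 2.0, variant="absolute_agreement")
        assert cons.icc == pytest.approx(1.0)
        assert agree.icc < 1.0

    def test_six_pair_anova_table_oracle(self):
        x = np.array([9.0, 10.0, 12.0, 6.0, 8.0, 11.0])
        y = np.array([10.0, 12.0, 14.0, 7.0, 7.0, 13.0])
        data = np.column_stack([x, y])
        n, k = data.shape
        grand = data.mean()
        ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
        ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
        ss_total = ((data - grand) ** 2).sum()
        ss_err = ss_total - ss_rows - ss_cols
        msr = ss_rows / (n - 1)
        msc = ss_cols / (k - 1)
        mse = ss_err / ((n - 1) * (k - 1))
        expect_c = (msr - mse) / (msr + mse)
        expect_a = (msr - mse) / (msr + mse + (2 / n) * (msc - mse))
        got_c = pk.icc_single_measures(x, y, variant="consistency")
        got_a = pk.icc_single_measures(x, y, variant="absolute_agreement")
        assert got_c.icc == pytest.approx(expect_c, abs=1e-10)
        assert got_a.icc == pytest.approx(expect_a, abs=1e-10)
        assert got_c.ci_low < got_c.icc < got_c.ci_high

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(31)
        x = rng.normal(size=30)
        y = 0.8 * x + rng.normal(scale=0.4, size=30) + 0.3
        frame = pd.DataFrame(
            {
                "target": np.repeat(np.arange(30), 2),
                "rater": np.tile(["a", "b"], 30),
                "score": np.column_stack([x, y]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            frame, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
        got_c = pk.icc_single_measures(x, y, variant="consistency")
        got_a = pk.icc_single_measures(x, y, variant="absolute_agreement")
        assert got_c.icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert got_a.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        ci_c = ref.loc["ICC(C,1)", "CI95"]
        ci_a = ref.loc["ICC(A,1)", "CI95"]
        assert got_c.ci_low == pytest.approx(ci_c[0], abs=1e-2)
        assert got_c.ci_high == pytest.approx(ci_c[1], abs=1e-2)
        assert got_a.ci_low == pytest.approx(ci_a[0], abs=1e-2)
        assert got_a.ci_high == pytest.approx(ci_a[1], abs=1e-2)

    def test_zero_between_subject_variance_warns_and_zeroes(self):
        x = np.full(6, 3.0)
        y = np.full(6, 5.0)  # rows identical: no between-subject variance
        with pytest.warns(UserWarning, match="between-subject"):
            res = pk.icc_single_measures(x, y)
        assert res.icc == 0.0


class TestKappa:
    def test_identical_vectors(self):
        assert pk.cohen_kappa(list("ababab"), list("ababab")) == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        a = ["x"] * 50 + ["y"] * 50
        b = ["x"] * 45 + ["y"] * 5 + ["x"] * 5 + ["y"] * 45
        # p_obs = 0.9, marginals 0.5/0.5 so p_exp = 0.5
        assert pk.cohen_kappa(a, b) == pytest.approx((0.9 - 0.5) / 0.5, abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(37)
        a = rng.choice(list("abcde"), size=10_000)
        b = rng.choice(list("abcde"), size=10_000)
        assert abs(pk.cohen_kappa(a, b)) < 0.05

    def test_kappa_never_exceeds_raw_agreement(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            a = rng.choice(list("abc"), size=60)
            b = np.where(rng.random(60) < 0.6, a, rng.choice(list("abc"), size=60))
            raw = np.mean(a == b)
            assert pk.cohen_kappa(a, b) <= raw + 1e-12


class TestBlandAltman:
    def test_identical_inputs(self):
        ba = pk.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_difference == 0.0
        assert ba.lower_limit == 0.0 and ba.upper_limit == 0.0

    def test_three_pair_hand_computation(self):
        x = np.array([10.0, 12.0, 11.0])
        y = np.array([9.0, 13.0, 10.0])
        d = x - y  # [1, -1, 1]
        ba = pk.bland_altman(x, y)
        mean_d = d.sum() / 3.0
        sd_d = np.sqrt(((d - mean_d) ** 2).sum() / 2.0)
        assert ba.mean_difference == pytest.approx(mean_d, abs=1e-12)
        assert ba.sd_difference == pytest.approx(sd_d, abs=1e-12)
        assert ba.lower_limit == pytest.approx(mean_d - 1.96 * sd_d, abs=1e-12)
        assert ba.upper_limit == pytest.approx(mean_d + 1.96 * sd_d, abs=1e-12)

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(43)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pk.bland_altman(x, y).mean_difference == pytest.approx(
            -pk.bland_altman(y, x).mean_difference, abs=1e-12
        )

    def test_limits_bracket_mean(self):
        rng = np.random.default_rng(44)
        ba = pk.bland_altman(rng.normal(size=50), rng.normal(size=50))
        assert ba.lower_limit <= ba.mean_difference <= ba.upper_limit


def paired_from_corrs(corr_pairs):
    """Build PairedCalls from a list of (corrs_a, corrs_b) dicts."""
    calls_a = [make_call(f"S{i}", ca) for i, (ca, _) in enumerate(corr_pairs)]
    calls_b = [make_call(f"S{i}", cb) for i, (_, cb) in enumerate(corr_pairs)]
    return pk.PairedCalls.from_call_lists(calls_a, calls_b, "ns", "rs")


def corrs(top, second=None, top_val=0.8, second_val=0.3):
    c = dict.fromkeys(pk.SUBTYPES, -0.5)
    c[top] = top_val
    if second:
        c[second] = second_val
    return c


class TestCallConcordance:
    def test_identical_calls_fully_concordant(self):
        paired = paired_from_corrs([(corrs("Basal"), corrs("Basal"))] * 4)
        raw, adjusted, records = pk.raw_and_adjusted_concordance(paired)
        assert raw == 1.0 and adjusted == 1.0 and records == []

    def test_near_tie_with_matching_second_call_is_rescued(self):
        a = corrs("Basal", "Her2", top_val=0.50, second_val=0.45)
        b = corrs("Her2")
        paired = paired_from_corrs([(a, b)])
        raw, adjusted, records = pk.raw_and_adjusted_concordance(paired, 0.10)
        assert raw == 0.0 and adjusted == 1.0
        assert records[0].reason == "second_call_match"
        assert records[0].gap_a == pytest.approx(0.05)

    def test_unresolved_near_tie_flag_controls_adjustment(self):
        a = corrs("Basal", "LumA", top_val=0.50, second_val=0.45)
        b = corrs("Her2")
        paired = paired_from_corrs([(a, b)])
        _, adj_on, rec_on = pk.raw_and_adjusted_concordance(
            paired, count_any_near_tie=True
        )
        _, adj_off, rec_off = pk.raw_and_adjusted_concordance(
            paired, count_any_near_tie=False
        )
        assert adj_on == 1.0 and adj_off == 0.0
        assert rec_on[0].reason == rec_off[0].reason == "near_tie_unresolved"

    def test_cohort_arithmetic_89_raw_92_adjusted_of_96(self):
        pairs = [(corrs("Basal"), corrs("Basal"))] * 89
        # 3 rescuable near-ties: second call matches the other platform
        pairs += [
            (corrs("Basal", "Her2", 0.50, 0.45), corrs("Her2")),
            (corrs("Her2", "LumA", 0.60, 0.59), corrs("LumA")),
            (corrs("Basal"), corrs("Her2", "Basal", 0.40, 0.31)),
        ]
        # 4 real discordances
        pairs += [(corrs("Basal"), corrs("Her2"))] * 3
        pairs += [(corrs("Her2"), corrs("LumA"))]
        paired = paired_from_corrs(pairs)
        raw, adjusted, records = pk.raw_and_adjusted_concordance(paired, 0.10)
        assert raw == pytest.approx(89 / 96)
        assert adjusted == pytest.approx(92 / 96)
        assert round(100 * adjusted) == 96
        assert sum(r.reason == "real_discordance" for r in records) == 4

    def test_adjusted_at_least_raw_and_monotone_in_threshold(self, paired_pipeline):
        cfg = pk.SimulationConfig(n_samples=60, seed=47, nanostring_noise_sd=0.6,
                                  rnaseq_noise_sd=0.6)
        _, _, _, calls_ns, calls_rs = paired_pipeline(cfg)
        paired = pk.PairedCalls.from_call_lists(calls_ns, calls_rs)
        prev_raw, prev_adj = None, None
        for thr in (0.0, 0.05, 0.10, 0.25, 0.5):
            raw, adj, _ = pk.raw_and_adjusted_concordance(paired, thr)
            assert adj >= raw
            if prev_adj is not None:
                assert adj >= prev_adj and raw == prev_raw
            prev_raw, prev_adj = raw, adj

    def test_crosstab_totals_match_n(self):
        paired = paired_from_corrs(
            [(corrs("Basal"), corrs("Basal"))] * 5
            + [(corrs("Her2"), corrs("LumA"))] * 2
        )
        table = crosstab_calls(paired)
        assert table.to_numpy().sum() == 7
        assert table.loc["Basal", "Basal"] == 5
        assert table.loc["Her2", "LumA"] == 2


class TestRiskGroupDiscordance:
    def test_identical_groups_give_zero(self):
        calls = [make_call(f"S{i}", corrs("Basal")) for i in range(5)]
        paired = pk.PairedCalls.from_call_lists(calls, calls)
        n_s, n_ps, _ = pk.risk_group_discordance(paired)
        assert n_s == 0 and n_ps == 0

    def test_injected_flips_counted_exactly(self):
        rng = np.random.default_rng(53)
        n, k = 40, 6
        calls_a = [make_call(f"S{i}", corrs("Basal")) for i in range(n)]
        calls_b = [make_call(f"S{i}", corrs("Basal")) for i in range(n)]
        flip = rng.choice(n, size=k, replace=False)
        for i in flip:
            calls_b[i].ror_s_group = "high"
        paired = pk.PairedCalls.from_call_lists(calls_a, calls_b)
        n_s, n_ps, records = pk.risk_group_discordance(paired)
        assert n_s == k and n_ps == 0
        assert records["ror_s_discordant"].sum() == k


class TestPerGeneAgreement:
    def _matrix(self, arr, genes=None):
        arr = np.asarray(arr, dtype=float)
        values = pd.DataFrame(
            arr, index=genes or [f"G{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        )
        return pk.ExpressionMatrix(values=values, platform="other",
                                   scale="log2_normalized")

    def test_identical_matrices(self):
        rng = np.random.default_rng(59)
        m = self._matrix(rng.normal(size=(10, 8)))
        res = pk.per_gene_agreement(m, m)
        assert np.allclose(res.table["rho"], 1.0)
        assert np.allclose(res.table["icc"], 1.0)
        assert res.median_icc == pytest.approx(1.0)

    def test_gene_wise_shifts_leave_rho_at_one(self):
        rng = np.random.default_rng(61)
        arr = rng.normal(size=(10, 8))
        shifted = arr + rng.normal(size=(10, 1))
        res = pk.per_gene_agreement(self._matrix(arr), self._matrix(shifted))
        assert np.allclose(res.table["rho"], 1.0)

    def test_constant_gene_reported_not_crashed(self):
        arr = np.vstack([np.ones(8), np.arange(8.0)])
        res = pk.per_gene_agreement(
            self._matrix(arr), self._matrix(np.vstack([np.arange(8.0)] * 2))
        )
        row = res.table.set_index("gene").loc["G0"]
        assert np.isnan(row["rho"]) and row["note"] != ""

    def test_binning_of_constructed_rho_vector(self):
        rhos = [0.95] * 23 + [0.85] * 18 + [0.75] * 7 + [0.65] * 2
        bins = bin_correlations(rhos)
        assert bins == {">0.9": 23, "0.8-0.9": 18, "0.7-0.8": 7, "<0.7": 2}
        assert (bins[">0.9"] + bins["0.8-0.9"]) / len(rhos) == pytest.approx(0.82)


class TestSummaryStats:
    def test_constant_vector_has_zero_width_ci(self):
        s = pk.summary_stats([2.0] * 6)
        assert s["ci95_low"] == s["ci95_high"] == s["mean"] == 2.0

    def test_ten_value_t_interval_oracle(self):
        from scipy import stats as sps

        v = [1.1, 1.4, 2.0, 2.2, 1.8, 1.9, 2.4, 1.6, 2.1, 1.7]
        s = pk.summary_stats(v)
        mean = sum(v) / 10
        sd = (sum((x - mean) ** 2 for x in v) / 9) ** 0.5
        half = sps.t.ppf(0.975, 9) * sd / 10**0.5
        assert s["mean"] == pytest.approx(mean, abs=1e-12)
        assert s["ci95_low"] == pytest.approx(mean - half, abs=1e-10)
        assert s["ci95_high"] == pytest.approx(mean + half, abs=1e-10)

    def test_mean_between_extrema(self):
        rng = np.random.default_rng(67)
        s = pk.summary_stats(rng.normal(size=25))
        assert s["min"] <= s["mean"] <= s["max"]

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            pk.summary_stats([1.0])


def test_full_report_assembles_and_writes(tmp_path, paired_pipeline):
    cfg = pk.SimulationConfig(n_samples=24, seed=71)
    _, matrix_ns, matrix_rs, calls_ns, calls_rs = paired_pipeline(cfg)
    paired = pk.PairedCalls.from_call_lists(calls_ns, calls_rs, "nanostring",
                                            "rnaseq")
    report = pk.build_concordance_report(paired, matrix_ns, matrix_rs)
    assert report.crosstab.to_numpy().sum() == 24
    assert 0.0 <= report.raw_concordance <= report.adjusted_concordance <= 1.0
    ba = report.ror_agreement["ror_s"]["bland_altman"]
    assert isinstance(ba, BlandAltmanStats)
    files = pk.write_report(report, tmp_path / "report")
    for name in files:
        assert (tmp_path / "report" / name).exists()
    assert "summary.json" in files and "per_gene.tsv" in files
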