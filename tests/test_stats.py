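"""The statistical battery against hand computations and oracle libraries."""

import numpy as np
import pingouin as pg
import pandas as pd
import pytest
from scipy.stats import spearmanr, studentized_range
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss_kappa

from tessella import (
    DegeneratePairError,
    EyeRecord,
    Grade,
    TFISet,
    UndefinedStatisticError,
    fleiss_kappa,
    group_summary,
    icc_absolute_single,
    pooled_mean,
    run_study,
    spearman,
    steel_dwass,
    studentized_range_sf,
)

from oracles import pearson_on_midranks, spearman_exact_p, wilcoxon_normal_p


class TestStudentizedRange:
    def test_matches_scipy_infinite_df(self):
        qs = np.array([0.1, 0.5, 1.0, 2.0, 2.7775, 3.5, 4.5, 6.0])
        for k in (2, 3, 4, 6):
            mine = studentized_range_sf(qs, k)
            ref = studentized_range.sf(qs, k, np.inf)
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_boundary_values(self):
        assert studentized_range_sf(0.0, 3) == 1.0
        assert studentized_range_sf(50.0, 3) == pytest.approx(0.0, abs=1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.rho == 1.0
        assert 0 < res.p_value < 1e-300  # sub-machine-floor, not NaN

    def test_perfect_reversal(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == -1.0

    def test_tied_data_matches_midrank_oracle(self, rng):
        x = np.round(rng.normal(size=20), 1)
        y = np.round(0.6 * x + rng.normal(size=20), 1)
        res = spearman(x, y)
        assert res.rho == pytest.approx(pearson_on_midranks(x, y), abs=1e-12)

    def test_matches_scipy_with_p(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 60))
            x = np.round(rng.normal(size=n), 1)
            y = np.round(0.3 * x + rng.normal(size=n), 1)
            res = spearman(x, y)
            ref = spearmanr(x, y)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_t_approximation_close_to_exact_permutation_small_n(self, rng):
        # the t approximation is the n=100 regime's tool; at n=7 it should
        # still track the exact permutation p within a few percent
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([2.1, 1.0, 4.3, 3.2, 6.6, 5.0, 6.0])
        res = spearman(x, y)
        assert res.p_value == pytest.approx(spearman_exact_p(x, y), abs=0.05)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSteelDwass:
    def test_hand_computed_three_group_example(self):
        # pair {1,2,3} vs {4,5,6}: untied ranks 1..6, R1 = 6, E = 10.5,
        # V = 3*3/(6*5) * (91 - 6*49/4) = 5.25, t = -4.5/sqrt(5.25)
        values = np.array([1, 2, 3, 4, 5, 6, 10, 11, 12.0])
        groups = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        res = steel_dwass(values, groups)
        first = res[0]
        t_hand = -4.5 / np.sqrt(5.25)
        assert first.t_statistic == pytest.approx(t_hand, abs=1e-12)
        q = abs(t_hand) * np.sqrt(2)
        assert first.p_value == pytest.approx(
            float(studentized_range.sf(q, 3, np.inf)), abs=1e-10
        )
        assert first.p_value == pytest.approx(0.121229, abs=1e-5)

    def test_two_group_reduction_to_wilcoxon(self, rng):
        for _ in range(20):
            a = rng.normal(size=8)
            b = np.round(rng.normal(size=11), 1)  # introduces ties sometimes
            res = steel_dwass(
                np.concatenate([a, b]), np.array([0] * 8 + [1] * 11)
            )
            assert res[0].p_value == pytest.approx(
                wilcoxon_normal_p(a, b), abs=1e-10
            )

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat([0, 1, 2], 10)
        res1 = steel_dwass(values, groups)
        res2 = steel_dwass(np.exp(3 * values), groups)
        for c1, c2 in zip(res1, res2):
            assert c1.t_statistic == pytest.approx(c2.t_statistic, abs=1e-12)
            assert c1.p_value == pytest.approx(c2.p_value, abs=1e-12)

    def test_all_identical_values_degenerate(self):
        with pytest.raises(DegeneratePairError):
            steel_dwass([5.0] * 6, [0, 0, 0, 1, 1, 1])

    def test_symmetry_up_to_sign(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=7)
        r_ab = steel_dwass(np.concatenate([a, b]), [0] * 6 + [1] * 7)[0]
        r_ba = steel_dwass(np.concatenate([b, a]), [1] * 7 + [0] * 6)[0]
        assert r_ab.t_statistic == pytest.approx(-r_ba.t_statistic, abs=1e-12)
        assert r_ab.p_value == pytest.approx(r_ba.p_value, abs=1e-12)


class TestFleissKappa:
    def test_unanimous_raters_give_kappa_one(self):
        counts = np.zeros((10, 3), dtype=int)
        counts[:5, 0] = 3
        counts[5:, 2] = 3
        assert fleiss_kappa(counts).kappa == pytest.approx(1.0, abs=1e-15)

    def test_two_item_crossed_example_by_hand(self):
        # items (A,B) and (B,A): every P_i = 0, p = (0.5, 0.5), Pe = 0.5
        counts = np.array([[1, 1], [1, 1]])
        res = fleiss_kappa(counts)
        assert res.observed_agreement == 0.0
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.5 / (0.5 - 1.0), abs=1e-15)

    def test_matches_statsmodels_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 51))
            counts = rng.multinomial(3, rng.dirichlet(np.ones(3)), size=n)
            try:
                mine = fleiss_kappa(counts).kappa
            except UndefinedStatisticError:
                continue
            assert mine == pytest.approx(float(sm_fleiss_kappa(counts)), abs=1e-12)

    def test_invariant_under_category_relabeling_and_item_order(self, rng):
        counts = rng.multinomial(3, [0.5, 0.3, 0.2], size=30)
        k0 = fleiss_kappa(counts).kappa
        assert fleiss_kappa(counts[:, [2, 0, 1]]).kappa == pytest.approx(k0, abs=1e-15)
        assert fleiss_kappa(counts[rng.permutation(30)]).kappa == pytest.approx(
            k0, abs=1e-15
        )

    def test_single_category_undefined(self):
        counts = np.zeros((5, 3), dtype=int)
        counts[:, 1] = 3
        with pytest.raises(UndefinedStatisticError):
            fleiss_kappa(counts)

    def test_unequal_row_sums_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[2, 1, 0], [1, 1, 0]]))


class TestICC:
    def test_identical_sessions_give_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc_absolute_single(x).icc == pytest.approx(1.0, abs=1e-15)

    def test_hand_decomposed_2x2(self):
        # subjects (1,2),(3,4): grand 2.5, SS_rows = 4, SS_cols = 1,
        # SS_err = 0 -> ICC = (4-0)/(4 + 0 + (2/2)*(1-0)) = 0.8
        res = icc_absolute_single(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert res.ms_rows == pytest.approx(4.0, abs=1e-15)
        assert res.ms_cols == pytest.approx(1.0, abs=1e-15)
        assert res.ms_error == pytest.approx(0.0, abs=1e-15)
        assert res.icc == pytest.approx(0.8, abs=1e-15)

    def test_crossed_2x2_has_zero_denominator(self):
        # subjects (1,2),(2,1): MS_R = MS_C = 0, MS_E = 1; the absolute-
        # agreement denominator vanishes, so the coefficient is undefined
        with pytest.raises(UndefinedStatisticError):
            icc_absolute_single(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_matches_pingouin_on_random_matrices(self, rng):
        for _ in range(20):
            x = rng.normal(size=(30, 2)) + rng.normal(size=(30, 1))
            mine = icc_absolute_single(x).icc
            df = pd.DataFrame(
                {
                    "subj": np.repeat(np.arange(30), 2),
                    "sess": np.tile([0, 1], 30),
                    "y": x.ravel(),
                }
            )
            table = pg.intraclass_corr(df, targets="subj", raters="sess", ratings="y")
            ref = float(table.loc[table.Type == "ICC(A,1)", "ICC"].iloc[0])
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_constant_matrix_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_absolute_single(np.full((4, 2), 3.0))


def _record(eye_id, tfi3, grade, sfct=260.0, nct=240.0, al=25.0):
    g = (grade, grade, grade)
    # tfi1/tfi2 derived from tfi3 so each index varies across the cohort
    return EyeRecord(
        eye_id=eye_id, age=25.0, axial_length=al, spherical_equivalent=-4.0,
        sfct=sfct, nct=nct, rater_grades=g, consensus=grade,
        tfi=TFISet(tfi1=2 * tfi3, tfi2=0.45 + tfi3 / 4, tfi3=tfi3),
    )


class TestGroupSummaryAndPooledMean:
    def test_two_eyes_per_group_by_hand(self):
        recs = [
            _record("a", 0.10, Grade.NT), _record("b", 0.12, Grade.NT),
            _record("c", 0.18, Grade.WT), _record("d", 0.20, Grade.WT),
            _record("e", 0.26, Grade.ST), _record("f", 0.30, Grade.ST),
        ]
        gs = group_summary(recs)
        assert gs.grades == (Grade.NT, Grade.WT, Grade.ST)
        assert gs.sizes == (2, 2, 2)
        assert gs.means["tfi3"] == pytest.approx((0.11, 0.19, 0.28))
        assert gs.sds["tfi3"][0] == pytest.approx(np.std([0.10, 0.12], ddof=1))

    def test_pooled_mean_examples(self):
        assert pooled_mean([1.0, 2.0], [1, 1]) == 1.5
        assert pooled_mean([0.7], [13]) == pytest.approx(0.7)
        got = pooled_mean([0.332, 0.363, 0.413], [57, 27, 16])
        assert got == pytest.approx(0.35333, abs=1e-5)

    def test_pooled_mean_reproduces_sizeweighted_group_means(self, rng):
        recs = [
            _record(f"e{i}", float(v), g)
            for i, (v, g) in enumerate(
                zip(rng.uniform(0.1, 0.3, size=12),
                    [Grade.NT] * 5 + [Grade.WT] * 4 + [Grade.ST] * 3)
            )
        ]
        gs = group_summary(recs)
        overall = np.mean([r.tfi.tfi3 for r in recs])
        assert pooled_mean(gs.means["tfi3"], gs.sizes) == pytest.approx(
            overall, abs=1e-12
        )


class TestRunStudy:
    def _cohort(self, rng, n_per=8, grade_effect=0.05):
        recs = []
        for gi, grade in enumerate((Grade.NT, Grade.WT, Grade.ST)):
            for i in range(n_per):
                sfct = float(rng.uniform(100, 400))
                tfi3 = 0.30 - 0.0004 * sfct + gi * grade_effect
                recs.append(
                    _record(f"g{gi}e{i}", tfi3, grade, sfct=sfct,
                            nct=sfct - 18.0, al=float(rng.uniform(23, 28)))
                )
        return recs

    def test_monotone_tfi_of_sfct_gives_rho_minus_one(self, rng):
        recs = self._cohort(rng)
        report = run_study(recs)
        for name in ("tfi1", "tfi2", "tfi3"):
            res = report.correlations[(name, "sfct")]
            # tfi decreases in sfct apart from grade steps, so the rank
            # correlation must be clearly negative
            assert res.rho < -0.5 and res.p_value < 0.05
        # raters are unanimous in this synthetic cohort
        assert report.kappa.kappa == pytest.approx(1.0)

    def test_strictly_monotone_limit(self):
        recs = [
            _record(f"e{i}", 0.4 - 0.0005 * s, Grade.NT if i < 4 else Grade.WT,
                    sfct=s, nct=s, al=23.0 + 0.01 * i)
            for i, s in enumerate([100.0, 150.0, 200.0, 250.0, 300.0, 350.0])
        ]
        report = run_study(recs)
        assert report.correlations[("tfi3", "sfct")].rho == pytest.approx(-1.0)

    def test_absent_grade_warns_and_skips_its_pairs(self, rng):
        recs = [r for r in self._cohort(rng) if r.consensus != Grade.ST]
        report = run_study(recs)
        assert any("ST" in w for w in report.warnings)
        pairs = {(c.group_a, c.group_b) for c in report.pairwise["tfi3"]}
        assert pairs == {(Grade.NT, Grade.WT)}

    def test_report_csvs_deterministic(self, rng, tmp_path):
        recs = self._cohort(rng)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_study(recs).write(out1)
        run_study(recs).write(out2)
        for name in ("report_groups.csv", "report_pairwise.csv",
                     "report_correlations.csv", "report_summary.txt"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_group_sizes_sum_to_cohort(self, rng):
        recs = self._cohort(rng)
        report = run_study(recs)
        assert sum(report.groups.sizes) == report.n_eyes
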