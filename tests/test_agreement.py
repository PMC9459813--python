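import numpy as np
import pytest
from scipy import stats

from stairpower.agreement import (
    PairedMeasurements,
    agreement_report,
    bland_altman,
    icc_2_1,
    pearson_correlation,
    welch_t_test,
)

# six-subject paired fixture (watts); hand-checkable magnitudes
FIX_A = np.array([150.0, 180.0, 120.0, 200.0, 160.0, 140.0])
FIX_B = np.array([145.0, 186.0, 118.0, 190.0, 165.0, 133.0])


def pairs(a=FIX_A, b=FIX_B, **groups):
    return PairedMeasurements(np.asarray(a, float), np.asarray(b, float),
                              groups={k: np.asarray(v) for k, v in groups.items()})


class TestPearson:
    def test_identity_and_negation(self):
        assert pearson_correlation(pairs(FIX_A, FIX_A)).r == pytest.approx(1.0)
        assert pearson_correlation(pairs(FIX_A, -FIX_A)).r == pytest.approx(-1.0)

    def test_fixture_matches_sum_formula_oracle(self):
        n = len(FIX_A)
        sx, sy = FIX_A.sum(), FIX_B.sum()
        sxx, syy = (FIX_A**2).sum(), (FIX_B**2).sum()
        sxy = (FIX_A * FIX_B).sum()
        r_oracle = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx**2) * (n * syy - sy**2)
        )
        assert pearson_correlation(pairs()).r == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation(pairs(FIX_A, np.full(6, 3.0)))


def icc_oracle(a, b):
    """Two-way ANOVA mean squares written out with explicit loops."""
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    msr = sum(k * (data[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identity_data_is_perfect_agreement(self):
        res = icc_2_1(pairs(FIX_A, FIX_A))
        assert res == (1.0, 1.0, 1.0)

    def test_fixture_matches_hand_anova_oracle(self):
        res = icc_2_1(pairs())
        assert res.icc == pytest.approx(icc_oracle(FIX_A, FIX_B), abs=1e-9)
        assert res.lower <= res.icc <= res.upper

    def test_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        a = rng.normal(150, 30, 24)
        b = a + rng.normal(-4, 12, 24)
        mine = icc_2_1(pairs(a, b))
        df = pd.DataFrame(
            {
                "s": np.r_[np.arange(24), np.arange(24)],
                "rater": ["A"] * 24 + ["B"] * 24,
                "y": np.r_[a, b],
            }
        )
        tab = pg.intraclass_corr(df, targets="s", raters="rater", ratings="y")
        ref = tab[tab["Type"] == "ICC(A,1)"]
        if ref.empty:
            ref = tab[tab["Type"] == "ICC2"]
        assert mine.icc == pytest.approx(float(ref["ICC"].iloc[0]), abs=1e-9)

    def test_dominant_noise_drives_icc_to_zero(self):
        rng = np.random.default_rng(3)
        iccs = []
        for _ in range(500):
            a = rng.normal(150, 5, 30)  # small between-subject spread
            b = a + rng.normal(0, 60, 30)  # huge independent noise
            iccs.append(icc_2_1(pairs(a, b)).icc)
        assert np.mean(iccs) < 0.1

    def test_variance_component_recovery_at_large_n(self):
        # A = s + e1, B = s + e2 with var(s)=400, var(e)=100
        # -> analytic ICC = 400 / 500 = 0.8
        rng = np.random.default_rng(8)
        s = rng.normal(150, 20, 500)
        a = s + rng.normal(0, 10, 500)
        b = s + rng.normal(0, 10, 500)
        assert icc_2_1(pairs(a, b)).icc == pytest.approx(0.8, abs=0.03)


class TestBlandAltman:
    def test_constant_offset(self):
        res = bland_altman(pairs([10, 20, 30], [12, 22, 32]))
        assert res.bias == pytest.approx(-2.0)
        assert res.sd == pytest.approx(0.0)
        assert (res.loa_low, res.loa_high) == (pytest.approx(-2.0), pytest.approx(-2.0))

    def test_identical_methods(self):
        res = bland_altman(pairs(FIX_A, FIX_A))
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_fixture_matches_direct_formulas(self):
        d = FIX_A - FIX_B
        res = bland_altman(pairs())
        assert res.bias == pytest.approx(d.mean(), abs=1e-12)
        assert res.sd == pytest.approx(d.std(ddof=1), abs=1e-12)
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd)

    def test_antisymmetry_of_bias(self):
        f = bland_altman(pairs(FIX_A, FIX_B))
        r = bland_altman(pairs(FIX_B, FIX_A))
        assert f.bias == -r.bias

    def test_parameter_recovery_of_known_offset(self):
        # study-scale simulation: n=64 pairs, true offset -4.11 W, sd 10.6 W
        rng = np.random.default_rng(0)
        a = rng.normal(160, 40, 64)
        b = a - (-4.11) + rng.normal(0, 10.6, 64)
        res = bland_altman(pairs(a, b))
        two_se = 2 * 10.6 / np.sqrt(64)
        assert abs(res.bias - (-4.11)) <= two_se


class TestWelch:
    def test_identical_groups(self):
        v = np.r_[FIX_A, FIX_A]
        g = np.r_[np.zeros(6), np.ones(6)]
        res = welch_t_test(v, g)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(4)
        v = np.r_[rng.normal(0, 0.01, 4), rng.normal(1, 0.01, 4)]
        g = np.r_[np.zeros(4), np.ones(4)]
        assert welch_t_test(v, g).p < 0.01

    def test_fixture_matches_textbook_formula(self):
        a = np.array([150.0, 180.0, 120.0, 200.0])
        b = np.array([145.0, 186.0, 118.0, 190.0, 165.0, 133.0])
        v, g = np.r_[a, b], np.r_["0", np.zeros(4), np.ones(6)]
        res = welch_t_test(v, g)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 4 + vb / 6
        t_oracle = (a.mean() - b.mean()) / np.sqrt(se2)
        df_oracle = se2**2 / ((va / 4) ** 2 / 3 + (vb / 6) ** 2 / 5)
        assert res.t == pytest.approx(t_oracle, abs=1e-12)
        assert res.df == pytest.approx(df_oracle, abs=1e-12)
        # cross-check p against scipy's implementation
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            welch_t_test(FIX_A, np.zeros(6))


def test_agreement_report_bundles_everything():
    rep = agreement_report(pairs(age=[0, 0, 0, 1, 1, 1], sex=[0, 1, 0, 1, 0, 1]))
    d = rep.to_dict()
    assert set(d) == {"n", "pearson", "icc", "bland_altman", "t_tests"}
    assert set(d["t_tests"]) == {"age", "sex"}
    assert -1 <= d["pearson"]["r"] <= 1
    assert d["icc"]["lower"] <= d["icc"]["icc"] <= d["icc"]["upper"]
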