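"""ICC, response binarization, Box-Cox, mixed-model contrasts, agreement."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from equisym import (
    SidednessAssociationModel,
    ThresholdConfig,
    binarize_response,
    boxcox_transform,
    correlate_li_asymmetry,
    cramers_v,
    fit_lmm_contrast,
    icc_absolute_average,
    side_specific_agreement,
)


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.tile(np.arange(10.0), (3, 1)).T
        assert icc_absolute_average(x).icc == pytest.approx(1.0)

    def test_matches_pingouin_icc2k_on_random_matrices(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(0, 1, (5, 3)) + rng.normal(0, 2, (5, 1))
            res = icc_absolute_average(x)
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(5), 3),
                    "visit": np.tile(np.arange(3), 5),
                    "y": x.ravel(),
                }
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = pingouin.intraclass_corr(
                    long, targets="subject", raters="visit", ratings="y"
                ).set_index("Type")
            assert res.icc == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-10)
            assert res.f_stat == pytest.approx(ref.loc["ICC(A,k)", "F"], rel=1e-9)

    def test_variance_components_recovery(self):
        # subject SD 4, residual SD 2, k = 3: ICC(A,k) -> 16/(16 + 4/3)
        rng = np.random.default_rng(42)
        n, k = 200, 3
        x = rng.normal(0, 4, (n, 1)) + rng.normal(0, 2, (n, k))
        assert icc_absolute_average(x).icc == pytest.approx(16 / (16 + 4 / 3), abs=0.03)

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 2, (500, 3))
        assert abs(icc_absolute_average(x).icc) < 0.05

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            icc_absolute_average(x)


class TestBinarize:
    @pytest.mark.parametrize(
        "token, expected",
        [("left", "YES"), ("RIGHT", "YES"), ("none", "NO"), ("no", "NO"),
         ("no perception", None), ("no perception/did not answer", None)],
    )
    def test_tokens(self, token, expected):
        assert binarize_response(token) == expected

    def test_unknown_token_named_in_error(self):
        with pytest.raises(ValueError, match="sideways"):
            binarize_response("sideways")


class TestBoxCox:
    def test_transform_follows_power_formula(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0.5, 4.0, 200)
        yt, lam = boxcox_transform(y)
        np.testing.assert_allclose(yt, (y ** lam - 1) / lam, atol=1e-10)

    def test_lognormal_gives_lambda_near_zero(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.normal(0, 1.5, 5000))
        _, lam = boxcox_transform(y)
        assert abs(lam) < 0.2

    def test_normal_gives_lambda_near_one(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10, 1, 5000)
        _, lam = boxcox_transform(y)
        assert abs(lam - 1) < 0.2

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox_transform([0.0, 1.0])


def _linked_records(rng, n_horses=200, n_visits=3, effect=0.0):
    """Visit records where YES-horses have |pdmin| elevated by `effect` mm."""
    horse = np.repeat(np.arange(n_horses), n_visits)
    yes = np.repeat(rng.random(n_horses) < 0.5, n_visits)
    base = np.repeat(np.abs(rng.uniform(-8, 8, n_horses)), n_visits)
    pdmin = base + effect * yes + rng.normal(0, 0.45, n_horses * n_visits)
    return pd.DataFrame(
        {
            "horse_id": [f"H{i}" for i in horse],
            "visit": np.tile(np.arange(n_visits), n_horses),
            "pdmin": pdmin,
            "surface": rng.choice(["soft", "hard"], n_horses * n_visits),
            "stride_duration": rng.normal(0.72, 0.04, n_horses * n_visits),
            "q2a": np.where(yes, "left", "no"),
        }
    )


class TestMixedModelContrast:
    def test_pairing_restricted_to_question_map(self, visit_records):
        with pytest.raises(ValueError, match="not modelled against"):
            fit_lmm_contrast(visit_records, "hdmin", "q2a")

    def test_identical_response_flagged_degenerate(self, visit_records):
        df = visit_records.copy()
        df["pdmin"] = 2.0
        res = fit_lmm_contrast(df, "pdmin", "q2a")
        assert res.degenerate and res.estimate == 0.0

    def test_injected_effect_recovered(self):
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 20
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_rep):
                res = fit_lmm_contrast(_linked_records(rng, effect=2.0), "pdmin", "q2a")
                if res.estimate > 0 and res.p_value < 0.05:
                    hits += 1
        assert hits >= int(0.8 * n_rep)

    def test_ordinal_question_returns_joint_test(self, visit_records):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_lmm_contrast(visit_records, "tas", "q1")
        assert res.kind == "anova"
        assert 0.0 <= res.p_value <= 1.0
        assert np.isnan(res.estimate)


class TestAgreement:
    def test_cramers_v_closed_form_2x2(self):
        # V = |ad - bc| / sqrt(row and column margins)
        assert cramers_v([[20, 10], [10, 20]]) == pytest.approx(1 / 3)
        assert cramers_v([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_cramers_v_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, 4)
            expected = abs(a * d - b * c) / np.sqrt(
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert cramers_v([[a, b], [c, d]]) == pytest.approx(expected)

    def _records(self, answers, pdmin, pdmin_sd=0.0):
        n = len(answers)
        return pd.DataFrame(
            {
                "horse_id": [f"H{i}" for i in range(n)],
                "q2a": answers,
                "pdmin": pdmin,
                "pdmin_sd": np.full(n, pdmin_sd),
                "pdmax": np.zeros(n),
                "pdmax_sd": np.zeros(n),
            }
        )

    def test_perfect_agreement(self):
        answers = ["right"] * 10 + ["no"] * 10
        pdmin = [5.0] * 10 + [0.0] * 10
        res = side_specific_agreement(self._records(answers, pdmin), "q2a")
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.cramers_v == pytest.approx(1.0)
        assert res.fisher_p < 0.001

    def test_independent_answers_give_near_zero_v(self):
        rng = np.random.default_rng(5)
        n = 10 ** 4
        answers = rng.choice(["no", "left", "right"], n)
        pdmin = rng.choice([0.0, 5.0, -5.0], n)
        res = side_specific_agreement(self._records(answers, pdmin), "q2a")
        assert abs(res.cramers_v) < 0.03

    def test_empty_margin_yields_nan_not_exception(self):
        res = side_specific_agreement(
            self._records(["no", "no", "no"], [0.0, 0.0, 0.0]), "q2a"
        )
        assert np.isnan(res.sensitivity)
        assert res.p_method == "undefined"


class TestLICorrelation:
    def test_perfect_correlation(self):
        df = pd.DataFrame(
            {
                "li": np.linspace(-100, 100, 20),
                "hdmin": np.linspace(-10, 10, 20),
                "hdmax": np.linspace(-10, 10, 20),
                "pdmin": np.linspace(-10, 10, 20),
                "pdmax": np.linspace(-10, 10, 20),
                "tas": np.abs(np.linspace(-100, 100, 20)),
            }
        )
        res = correlate_li_asymmetry(df).set_index("parameter")
        assert res.loc["HDMIN", "r_signed"] == pytest.approx(1.0)
        assert res.loc["HDMIN", "r_abs"] == pytest.approx(1.0)
        assert res.loc["TAS", "r_abs"] == pytest.approx(1.0)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(9)
        n = 10 ** 4
        df = pd.DataFrame(
            {
                "li": rng.uniform(-100, 100, n),
                **{p: rng.normal(0, 5, n) for p in ("hdmin", "hdmax", "pdmin", "pdmax")},
            }
        )
        df["tas"] = df[["pdmin", "pdmax"]].abs().sum(axis=1)
        res = correlate_li_asymmetry(df)
        assert (res["r_abs"].abs() < 0.03).all()
        assert (res["r_signed"].abs() < 0.03).all()

    def test_negating_parameters_negates_signed_r_only(self):
        rng = np.random.default_rng(4)
        n = 50
        df = pd.DataFrame(
            {
                "li": rng.uniform(-100, 100, n),
                **{p: rng.normal(0, 5, n) for p in ("hdmin", "hdmax", "pdmin", "pdmax")},
            }
        )
        df["tas"] = df[["pdmin", "pdmax"]].abs().sum(axis=1)
        neg = df.copy()
        for p in ("hdmin", "hdmax", "pdmin", "pdmax", "tas"):
            neg[p] = -neg[p]
        a = correlate_li_asymmetry(df).set_index("parameter")
        b = correlate_li_asymmetry(neg).set_index("parameter")
        np.testing.assert_allclose(b["r_signed"], -a["r_signed"], atol=1e-12)
        np.testing.assert_allclose(b["r_abs"], a["r_abs"], atol=1e-12)

    def test_zero_variance_flagged(self):
        df = pd.DataFrame(
            {
                "li": [10.0, 20.0, 30.0],
                "hdmin": [1.0, 1.0, 1.0],
                "hdmax": [1.0, 2.0, 3.0],
                "pdmin": [1.0, 2.0, 3.0],
                "pdmax": [1.0, 2.0, 3.0],
                "tas": [1.0, 2.0, 3.0],
            }
        )
        res = correlate_li_asymmetry(df).set_index("parameter")
        assert np.isnan(res.loc["HDMIN", "r_signed"])


def test_association_model_facade(visit_records):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = SidednessAssociationModel(visit_records, thresholds=ThresholdConfig()).fit(
            questions=["q2a"]
        )
    assert set(res.icc["parameter"]) == {"HDMIN", "HDMAX", "PDMIN", "PDMAX"}
    assert (res.icc["icc"] <= 1.0).all()
    assert len(res.contrasts) == 2
    assert "ICC" in res.summary()
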