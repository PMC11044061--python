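import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msnpipe.errors import EstimabilityError, ValidationError
from msnpipe.stats import (
    DesignSpec,
    partial_eta_squared,
    pearson_chi_square,
    pooled_t_test,
    rm_ancova,
    welch_t_test,
)
from oracles import balanced_two_way_anova_oracle

DENSITIES = (0.25, 0.30, 0.35, 0.40, 0.45)


def make_design_data(rng, n_per_cell: int, response=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balanced 2x2 cohort plus a metric table constant across densities."""
    rows = []
    for diag in ("DAT", "bvFTD"):
        for dis in (False, True):
            for _ in range(n_per_cell):
                rows.append({"diagnosis": diag, "disinhibition_present": dis})
    cohort = pd.DataFrame(rows)
    cohort.insert(0, "subject_id", [f"s{i:03d}" for i in range(len(cohort))])
    if response is None:
        response = rng.normal(size=len(cohort))
    metrics = pd.DataFrame(
        [
            {"subject_id": sid, "density": d, "value": v}
            for sid, v in zip(cohort.subject_id, response)
            for d in DENSITIES
        ]
    )
    return metrics, cohort


class TestSummaryTests:
    def test_pooled_t_reproduces_cohort_age_row(self):
        t, df, p = pooled_t_test(74.15, 7.53, 111, 64.46, 7.03, 75)
        assert t == pytest.approx(8.84, abs=0.005)
        assert df == 184
        assert p < 0.001

    def test_pooled_t_identical_groups_is_zero(self):
        t, _, p = pooled_t_test(5.0, 1.0, 30, 5.0, 1.0, 30)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_pooled_t_matches_raw_sample_computation(self, rng):
        x = rng.normal(2.0, 1.5, 40)
        y = rng.normal(1.0, 1.0, 25)
        t_raw, p_raw = sps.ttest_ind(x, y, equal_var=True)
        t, df, p = pooled_t_test(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert t == pytest.approx(t_raw, abs=1e-8)
        assert p == pytest.approx(p_raw, abs=1e-8)

    def test_welch_reduces_to_pooled_for_equal_variances(self):
        tw, dfw, _ = welch_t_test(1.0, 2.0, 30, 0.0, 2.0, 30)
        tp, dfp, _ = pooled_t_test(1.0, 2.0, 30, 0.0, 2.0, 30)
        assert tw == pytest.approx(tp)
        assert dfw == pytest.approx(dfp)

    def test_welch_df_shrinks_under_variance_imbalance(self):
        _, df, _ = welch_t_test(0.0, 1.0, 50, 0.0, 4.0, 50)
        assert df < 98

    def test_welch_df_for_mri_interval_row(self):
        _, df, _ = welch_t_test(14.01, 55.81, 111, 4.03, 25.47, 75)
        assert df == pytest.approx(165.0, abs=0.1)

    def test_invalid_summary_inputs_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test(0, 1, 1, 0, 1, 30)
        with pytest.raises(ValueError):
            welch_t_test(0, 0.0, 10, 0, 1, 10)


class TestChiSquare:
    def test_reproduces_cohort_categorical_rows(self):
        chi2, df, _ = pearson_chi_square([[27, 84], [62, 13]])
        assert chi2 == pytest.approx(61.05, abs=0.005)
        assert df == 1
        chi2, df, _ = pearson_chi_square([[84, 12, 13, 2], [13, 15, 27, 20]])
        assert chi2 == pytest.approx(67.49, abs=0.005)
        assert df == 3

    def test_zero_when_observed_equals_expected(self):
        chi2, _, p = pearson_chi_square([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_under_permutation(self, rng):
        tab = rng.integers(1, 40, size=(3, 4))
        chi2, _, _ = pearson_chi_square(tab)
        chi2_p, _, _ = pearson_chi_square(tab[::-1, ::-1])
        assert chi2_p == pytest.approx(chi2, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[0, 0], [3, 4]])


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "ss_effect, ss_error, expected", [(0.0, 5.0, 0.0), (1.0, 3.0, 0.25), (3.0, 1.0, 0.75)]
    )
    def test_arithmetic(self, ss_effect, ss_error, expected):
        assert partial_eta_squared(ss_effect, ss_error) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            partial_eta_squared(1.0, 0.0)
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1.0)


class TestRmAncova:
    def test_matches_textbook_anova_oracle_without_covariates(self, rng):
        metrics, cohort = make_design_data(rng, n_per_cell=5)
        results = {
            r.effect: r for r in rm_ancova(metrics, cohort, DesignSpec(covariates=()))
        }
        y = (
            metrics.groupby("subject_id")["value"].mean().reindex(cohort.subject_id).to_numpy()
        )
        oracle = balanced_two_way_anova_oracle(
            y, cohort.diagnosis.to_numpy(), cohort.disinhibition_present.to_numpy()
        )
        for effect, (f_exp, df_num, df_den) in oracle.items():
            r = results[effect]
            assert r.F == pytest.approx(f_exp, abs=1e-8)
            assert (r.df_num, r.df_den) == (df_num, df_den)
            # p consistent with F and dfs; partial eta in range
            assert r.p == pytest.approx(sps.f.sf(r.F, r.df_num, r.df_den), abs=1e-10)
            assert 0 <= r.partial_eta_sq <= 1

    def test_orthogonal_covariate_leaves_effect_ss_unchanged(self, rng):
        metrics, cohort = make_design_data(rng, n_per_cell=6)
        base = {r.effect: r for r in rm_ancova(metrics, cohort, DesignSpec(covariates=()))}
        # residualize a random covariate against the effect-coded design,
        # so it is exactly orthogonal to every tested term
        a = np.where(cohort.diagnosis == "DAT", 1.0, -1.0)
        b = np.where(cohort.disinhibition_present, 1.0, -1.0)
        design = np.column_stack([np.ones(len(cohort)), a, b, a * b])
        z = rng.normal(size=len(cohort))
        z -= design @ np.linalg.lstsq(design, z, rcond=None)[0]
        with_cov = {
            r.effect: r
            for r in rm_ancova(metrics, cohort.assign(age=z), DesignSpec(covariates=("age",)))
        }
        for effect in ("diagnosis", "disinhibition", "diagnosis:disinhibition"):
            assert with_cov[effect].ss == pytest.approx(base[effect].ss, abs=1e-8)
            assert with_cov[effect].df_den == base[effect].df_den - 1
            assert 0 <= with_cov[effect].partial_eta_sq <= 1

    def test_null_interaction_rejection_rate_is_nominal(self, rng):
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            metrics, cohort = make_design_data(rng, n_per_cell=10)
            res = rm_ancova(metrics, cohort, DesignSpec(covariates=()))
            p = next(r.p for r in res if r.effect == "diagnosis:disinhibition")
            hits += p < 0.05
        assert 0.02 <= hits / n_rep <= 0.08

    def test_empty_cell_raises_estimability_error(self, rng):
        metrics, cohort = make_design_data(rng, n_per_cell=4)
        cohort = cohort[~((cohort.diagnosis == "DAT") & cohort.disinhibition_present)]
        metrics = metrics[metrics.subject_id.isin(cohort.subject_id)]
        with pytest.raises(EstimabilityError, match="DAT"):
            rm_ancova(metrics, cohort, DesignSpec(covariates=()))

    def test_unbalanced_densities_rejected(self, rng):
        metrics, cohort = make_design_data(rng, n_per_cell=4)
        metrics = metrics.iloc[:-1]
        with pytest.raises(ValidationError, match="density"):
            rm_ancova(metrics, cohort, DesignSpec(covariates=()))

    def test_estimate_sign_tracks_group_difference(self, rng):
        metrics, cohort = make_design_data(rng, n_per_cell=8)
        shift = np.where(cohort.disinhibition_present, -1.0, 0.0) + rng.normal(
            0, 0.1, len(cohort)
        )
        metrics = metrics.merge(cohort[["subject_id"]], on="subject_id")
        metrics["value"] = np.repeat(shift, len(DENSITIES))
        res = {r.effect: r for r in rm_ancova(metrics, cohort, DesignSpec(covariates=()))}
        assert res["disinhibition"].estimate < 0
        assert res["disinhibition"].p < 0.001
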