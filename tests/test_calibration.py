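"""Tests for the background-calibration pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import _oracle as oracle
from imvt.calibration import test_probes as run_probe_tests
from imvt import (
    ExpressionStudy,
    FixtureSpec,
    bh_fdr,
    bonferroni_threshold,
    calibrate_study,
    generate_fixture,
    genomic_inflation_factor,
    pca_sample_scores,
    qq_band,
    residualize,
    screen_pcs,
    select_robust_probes,
)
from imvt.calibration import CalibrationModel


def _study(matrix, condition, covariates=None):
    m, n = matrix.shape
    return ExpressionStudy(
        matrix=matrix,
        probe_ids=[f"p{i}" for i in range(m)],
        sample_ids=[f"s{j}" for j in range(n)],
        condition=condition,
        covariates=covariates,
    )


def test_study_validation(rng):
    mat = rng.normal(size=(5, 6))
    with pytest.raises(ValueError, match="2 levels"):
        _study(mat, [0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError, match="at least 2"):
        _study(mat, [0, 1, 1, 1, 1, 1])
    mat[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        _study(mat, [0, 0, 0, 1, 1, 1])


# --- PCA -------------------------------------------------------------------


def test_pca_variance_proportions_are_a_distribution(rng):
    study = _study(rng.normal(size=(30, 12)), [0] * 6 + [1] * 6)
    model = pca_sample_scores(study, n_components="all")
    props = model.variance_proportions
    assert props.sum() == pytest.approx(1.0, abs=1e-10)
    assert (np.diff(props) <= 1e-12).all()
    assert model.pc_scores.shape == (12, 11)  # at most n_samples - 1


def test_pca_rank_one_matrix_concentrates_on_pc1(rng):
    loadings = rng.normal(size=50)
    scores = rng.normal(size=16)
    mat = np.outer(loadings, scores) + 1e-4 * rng.normal(size=(50, 16))
    model = pca_sample_scores(_study(mat, [0] * 8 + [1] * 8), n_components="all")
    assert model.variance_proportions[0] > 0.99


def test_pca_sample_duplication_preserves_leading_proportions(rng):
    mat = np.outer(rng.normal(size=10), rng.normal(size=25)) + 0.3 * rng.normal(size=(10, 25))
    cond = [0] * 12 + [1] * 13
    base = pca_sample_scores(_study(mat, cond), n_components="all")
    dup = pca_sample_scores(
        _study(np.hstack([mat, mat]), cond + cond), n_components="all"
    )
    assert dup.variance_proportions[:3] == pytest.approx(
        base.variance_proportions[:3], rel=1e-8
    )


def test_pca_requires_probes(rng):
    study = _study(rng.normal(size=(4, 6)), [0] * 3 + [1] * 3)
    with pytest.raises(ValueError, match="empty"):
        pca_sample_scores(study, probe_subset=[])


# --- PC screening ----------------------------------------------------------


def _model_from_scores(scores):
    k = scores.shape[1]
    return CalibrationModel(
        pc_scores=scores, variance_proportions=np.full(k, 1.0 / k), n_structure=k
    )


def test_screen_pcs_flags_constructed_condition_pcs():
    cond = np.r_[np.zeros(40, int), np.ones(40, int)]
    base = np.linspace(-1.0, 1.0, 40)
    flat = np.r_[base, base]                # identical score sets per condition
    shifted = np.r_[base, base + 2.0]       # mean heterogeneity
    inflated = np.r_[base, 3.0 * base]      # variance heterogeneity
    model = _model_from_scores(np.column_stack([flat, shifted, inflated]))
    sig = screen_pcs(model, cond)
    assert sig == [1, 2]
    assert model.pc_tests.loc[1, "p_WT"] < 0.05
    assert model.pc_tests.loc[2, "p_LF"] < 0.05


def test_screen_pcs_identical_scores_not_significant():
    cond = np.r_[np.zeros(5, int), np.ones(5, int)]
    scores = np.tile(np.arange(5.0), 2)[:, None]
    model = _model_from_scores(scores)
    assert screen_pcs(model, cond) == []


# --- residualization -------------------------------------------------------


def test_residuals_orthogonal_to_design(small_study):
    study, _ = small_study
    model = select_robust_probes(study)
    resid = residualize(study, model)
    design_cols = [np.ones(study.n_samples)]
    design_cols.append(study.covariates.to_numpy(dtype=float))
    design_cols.append(model.pc_scores[:, model.significant_pcs])
    d = np.column_stack(design_cols)
    assert np.abs(resid @ d).max() < 1e-6


def test_residualizing_a_design_column_gives_zero(rng):
    cond = [0] * 5 + [1] * 5
    cov = pd.DataFrame({"age": rng.normal(50, 5, size=10)})
    age_row = cov["age"].to_numpy()
    mat = np.vstack([age_row, rng.normal(size=(4, 10))])
    study = _study(mat, cond, covariates=cov)
    resid = residualize(study, None)
    assert np.abs(resid[0]).max() < 1e-8


def test_collinear_design_rejected(rng):
    cond = [0] * 5 + [1] * 5
    cov = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
    study = _study(rng.normal(size=(3, 10)), cond, covariates=cov)
    with pytest.raises(ValueError, match="collinear"):
        residualize(study, None)


def test_residualization_removes_covariate_confounding(rng):
    """A probe driven by a condition-shifted covariate plus a real condition
    effect keeps its condition signal but loses the covariate inflation."""
    n = 80
    cond = np.r_[np.zeros(40, int), np.ones(40, int)]
    cov = rng.normal(size=n) + 0.5 * cond  # mildly confounded covariate
    probes = []
    for _ in range(200):
        probes.append(2.0 * cov + rng.normal(size=n))  # covariate-driven only
    mat = np.array(probes)
    study = _study(mat, cond, covariates=pd.DataFrame({"c": cov}))
    raw = run_probe_tests(study, tests=("WT",))
    lam_raw = genomic_inflation_factor(raw["p_WT"])
    resid = residualize(study, None)
    cal = run_probe_tests(study, matrix=resid, tests=("WT",))
    lam_cal = genomic_inflation_factor(cal["p_WT"])
    assert lam_raw > 1.5
    assert 0.7 < lam_cal < 1.4


# --- robust probes ---------------------------------------------------------


def test_robust_selection_on_null_study_retains_most(rng):
    mat = rng.normal(size=(1000, 40))
    study = _study(mat, [0] * 20 + [1] * 20)
    model = select_robust_probes(study, tau=0.05)
    assert len(model.robust_probe_ids) >= 0.85 * 1000


def test_robust_selection_excludes_planted_probes(small_study):
    study, truth = small_study
    model = select_robust_probes(study)
    planted = set(truth["probe_id"])
    kept = set(model.robust_probe_ids)
    assert len(planted & kept) <= 0.2 * len(planted)


def test_tau_zero_retains_everything(rng):
    mat = rng.normal(size=(50, 20))
    study = _study(mat, [0] * 10 + [1] * 10)
    model = select_robust_probes(study, tau=0.0)
    assert len(model.robust_probe_ids) == 50


# --- genomic inflation, QQ band, multiple testing --------------------------


def test_lambda_of_uniform_p_values(rng):
    p = rng.uniform(size=22_283)
    assert genomic_inflation_factor(p) == pytest.approx(1.0, abs=0.02)


def test_lambda_monotone_under_inflation(rng):
    p = rng.uniform(size=5000)
    assert genomic_inflation_factor(p / 2) > genomic_inflation_factor(p)


def test_lambda_of_single_median_p():
    assert genomic_inflation_factor([0.5]) == pytest.approx(1.0)


def test_lambda_rejects_invalid():
    with pytest.raises(ValueError):
        genomic_inflation_factor([0.5, 0.0])


def test_qq_band_edge_cases(rng):
    band = qq_band(1)
    assert band.lower[0] == pytest.approx(0.025)
    assert band.upper[0] == pytest.approx(0.975)
    band = qq_band(500)
    # band widens (log scale) toward the smallest ranks
    width = band.neglog10_upper - band.neglog10_lower
    assert width.iloc[0] > width.iloc[250] > width.iloc[-1]
    # uniform p-values fall inside for the vast majority of ranks on
    # average (order statistics are strongly correlated, so the per-draw
    # inside fraction is highly variable; averaging over draws recovers
    # the ~95% pointwise coverage)
    fractions = []
    for _ in range(50):
        p = np.sort(rng.uniform(size=500))
        inside = (p >= band.lower.to_numpy()) & (p <= band.upper.to_numpy())
        fractions.append(inside.mean())
    assert np.mean(fractions) >= 0.93


def test_bh_fdr_worked_example_and_oracle(rng):
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)
    for _ in range(100):
        p = rng.uniform(size=rng.integers(1, 40))
        assert bh_fdr(p) == pytest.approx(oracle.bh_stepup(list(p)), rel=1e-12)
    q = bh_fdr(np.sort(rng.uniform(size=50)))
    assert (np.diff(q) >= -1e-15).all()
    assert (bh_fdr(p) >= p).all()


def test_bonferroni_threshold_values():
    assert bonferroni_threshold(0.05, 22_283) == pytest.approx(2.2438e-6, rel=1e-4)
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.1, 10) == pytest.approx(0.01)


# --- over-adjustment pathology --------------------------------------------


def test_global_pc_adjustment_absorbs_dense_signal():
    """Adjusting for significant PCs of *all* probes on signal-dense data
    deflates the tests and loses power relative to the robust-probe pipeline
    (the PCs, computed with the signal probes included, align with the
    condition and soak up true effects)."""
    spec = FixtureSpec(n_probes=2000, n_planted=400, seed=0)
    study, truth = generate_fixture(spec)
    planted = set(truth["probe_id"])

    def recovery(results):
        top = results.sort_values("p_IMVT").head(len(planted))
        return len(set(top["probe_id"]) & planted) / len(planted)

    # naive: PCA over all probes, screen, residualize
    global_model = pca_sample_scores(study)
    screen_pcs(global_model, study.condition)
    naive = run_probe_tests(study, matrix=residualize(study, global_model))
    # robust pipeline
    report = calibrate_study(study)

    lam_naive = genomic_inflation_factor(naive["p_IMVT"])
    assert lam_naive < 1.0
    assert recovery(report.results) > recovery(naive) + 0.05


# --- end-to-end ------------------------------------------------------------


def test_calibrate_study_report_shape(small_study):
    study, _ = small_study
    report = calibrate_study(study)
    assert report.lambda_uncalibrated > report.lambda_calibrated
    assert {"probe_id", "p_IMVT", "q_BH_IMVT", "bonferroni_IMVT"} <= set(
        report.results.columns
    )
    assert len(report.results) == study.n_probes
    assert report.model.residual_matrix.shape == study.matrix.shape
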