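import numpy as np
import pandas as pd
import pytest

from dentasym.reliability import (
    SampleSizeSpec,
    combine_sds,
    estimate_true_positions,
    fit_random_intercept,
    inter_rater_sds,
    intra_rater_sds,
    landmark_variability,
    magnitude_3d,
    parameter_variability,
    profiles_table,
    required_sample_size,
    true_position_records,
)
from dentasym.io import Point3, RatingRecord
from dentasym.simulate import SyntheticConfig, generate, template_face, zero_noise


def cohort(n_subjects=4, seed=0, **overrides):
    return generate(SyntheticConfig(n_subjects=n_subjects, seed=seed, **overrides))


# --- random-intercept REML ---------------------------------------------------


def test_identical_ratings_zero_variance():
    groups = [[2.0, 2.0, 2.0]] * 4
    fit = fit_random_intercept(groups)
    assert fit.intercept == pytest.approx(2.0)
    assert fit.intercept_se == pytest.approx(0.0)
    assert fit.group_variance == pytest.approx(0.0)
    assert fit.residual_variance == pytest.approx(0.0)


def test_balanced_intercept_is_grand_mean():
    rng = np.random.default_rng(17)
    data = rng.normal(5.0, 1.0, size=(4, 3))
    fit = fit_random_intercept(list(data))
    assert fit.intercept == pytest.approx(data.mean(), abs=1e-12)


def test_reml_matches_statsmodels_mixedlm():
    """Balanced and unbalanced fits agree with an independent REML engine."""
    statsmodels = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(23)
    layouts = [[3, 3, 3, 3], [2, 4, 3, 5, 2]]
    for sizes in layouts:
        groups = [
            rng.normal(0.0, 0.4) + rng.normal(1.0, 0.25, size=k) for k in sizes
        ]
        fit = fit_random_intercept(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(np.arange(len(sizes)), sizes),
            }
        )
        sm_fit = statsmodels.MixedLM.from_formula("y ~ 1", groups="g", data=df).fit(reml=True)
        assert fit.intercept == pytest.approx(sm_fit.params["Intercept"], abs=1e-5)
        assert fit.intercept_se == pytest.approx(sm_fit.bse["Intercept"], abs=1e-4)
        assert fit.group_variance == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), abs=1e-4
        )
        assert fit.residual_variance == pytest.approx(sm_fit.scale, abs=1e-4)


def test_variance_component_recovery():
    """Averaged over many subjects, REML recovers the generating components."""
    rng = np.random.default_rng(31)
    sd_rater, sd_resid = 0.4, 0.2
    rater_vars, resid_vars = [], []
    for _ in range(1000):
        groups = [
            rng.normal(0.0, sd_rater) + rng.normal(0.0, sd_resid, size=3)
            for _ in range(4)
        ]
        fit = fit_random_intercept(groups)
        rater_vars.append(fit.group_variance)
        resid_vars.append(fit.residual_variance)
    assert np.mean(rater_vars) == pytest.approx(sd_rater**2, rel=0.15)
    assert np.mean(resid_vars) == pytest.approx(sd_resid**2, rel=0.15)


def test_estimate_true_positions_balanced_identity():
    records, _ = cohort(n_subjects=2, seed=5)
    estimates = estimate_true_positions(records)
    by_key = {(e.subject_id, e.landmark): e for e in estimates}
    subjects = {r.subject_id for r in records}
    for subject in subjects:
        recs = [r for r in records if r.subject_id == subject]
        for name in recs[0].landmarks:
            grand = np.mean([r.landmarks[name].as_array() for r in recs], axis=0)
            est = by_key[(subject, name)]
            assert np.allclose(est.position.as_array(), grand, atol=1e-6)


def test_estimate_true_positions_needs_replication():
    records, _ = cohort(n_subjects=1, n_raters=1, n_repeats=3, seed=6)
    with pytest.raises(ValueError, match="insufficient replication"):
        estimate_true_positions(records)


def test_true_position_records_roundtrip():
    records, truth = cohort(n_subjects=2, seed=8)
    recs = true_position_records(estimate_true_positions(records))
    assert [r.subject_id for r in recs] == ["S01", "S02"]
    assert set(recs[0].landmarks) == set(template_face())


# --- cell SDs and combination ------------------------------------------------


def long_table(cells):
    rows = []
    for (subject, rater, repeat), value in cells:
        rows.append({"subject": subject, "rater": rater, "repeat": repeat, "value": value})
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "repeats, expected",
    [([1.0, 1.0, 1.0], 0.0), ([0.0, 0.3, 0.6], 0.3), ([0.0, 1.0], 0.7071)],
)
def test_cell_sd_values(repeats, expected):
    df = long_table([(("S1", "R1", i + 1), v) for i, v in enumerate(repeats)])
    sds = intra_rater_sds(df)
    assert sds.iloc[0] == pytest.approx(expected, abs=5e-5)
    # same values laid out across raters for the inter-rater scheme
    df2 = long_table([(("S1", f"R{i+1}", 1), v) for i, v in enumerate(repeats)])
    assert inter_rater_sds(df2).iloc[0] == pytest.approx(expected, abs=5e-5)


def test_cells_below_replication_skipped_with_warning():
    df = long_table(
        [(("S1", "R1", 1), 0.0), (("S1", "R1", 2), 1.0), (("S1", "R2", 1), 5.0)]
    )
    with pytest.warns(UserWarning, match="skipped 1"):
        sds = intra_rater_sds(df)
    assert len(sds) == 1


def test_combine_sds_values():
    est = combine_sds([0.5, 0.5, 0.5, 0.5])
    assert est.mean_sd == pytest.approx(0.5)
    assert est.ci95_half_width == pytest.approx(0.0)
    assert combine_sds([0.2, 0.4]).mean_sd == pytest.approx(0.3)
    with pytest.raises(ValueError):
        combine_sds([0.2])


def test_combine_sds_permutation_and_scaling():
    rng = np.random.default_rng(3)
    sds = rng.uniform(0.1, 1.0, size=20)
    a = combine_sds(sds)
    b = combine_sds(sds[::-1])
    assert a.mean_sd == pytest.approx(b.mean_sd)
    scaled = combine_sds(2.5 * sds)
    assert scaled.mean_sd == pytest.approx(2.5 * a.mean_sd)
    assert scaled.ci95_half_width == pytest.approx(2.5 * a.ci95_half_width)


def test_combine_sds_ci_coverage():
    """The 95% CI for the mean cell SD covers the true mean ~95% of the time."""
    rng = np.random.default_rng(55)
    true_mean = np.sqrt(2.0 / np.pi)  # E|N(0,1)| folded-normal mean
    hits = 0
    n_rep = 500
    for _ in range(n_rep):
        cells = np.abs(rng.normal(0.0, 1.0, size=400))
        est = combine_sds(cells)
        if abs(est.mean_sd - true_mean) <= est.ci95_half_width:
            hits += 1
    assert hits / n_rep == pytest.approx(0.95, abs=0.02)


@pytest.mark.parametrize(
    "sds, expected", [((3, 4, 0), 5.0), ((0, 0, 0), 0.0), ((0.5, 0.1, 0.7), 0.8660)]
)
def test_magnitude_3d(sds, expected):
    assert magnitude_3d(*sds) == pytest.approx(expected, abs=5e-5)
    with pytest.raises(ValueError):
        magnitude_3d(-0.1, 0.0, 0.0)


# --- pipeline-level variability ----------------------------------------------


def test_zero_noise_cohort_all_sds_zero():
    records, _ = generate(zero_noise(SyntheticConfig(n_subjects=3, seed=10)))
    for est in parameter_variability(records):
        assert est.mean_sd == pytest.approx(0.0, abs=1e-9)
    for est in landmark_variability(records):
        assert est.mean_sd == pytest.approx(0.0, abs=1e-9)


def test_landmark_noise_recovered():
    """Uniform 0.3 mm placement noise is recovered by the intra-rater pipeline."""
    records, _ = cohort(
        n_subjects=20, seed=12, rater_bias_sd=0.0, repeat_noise_sd=0.3
    )
    ests = {
        (e.target, e.axis): e
        for e in landmark_variability(records)
        if e.mode == "intra"
    }
    per_axis = [ests[("N", ax)].mean_sd for ax in ("x", "y", "z")]
    # sample SD of 3 draws has mean c4(3)*sigma = 0.8862*sigma
    expected = 0.8862 * 0.3
    for value in per_axis:
        assert value == pytest.approx(expected, rel=0.15)


def test_noise_monotonicity_matched_seeds():
    base = dict(n_subjects=4, seed=21, rater_bias_sd=0.0)
    r1, _ = cohort(repeat_noise_sd=0.3, **base)
    r2, _ = cohort(repeat_noise_sd=0.6, **base)
    v1 = {(e.target, e.mode): e.mean_sd for e in parameter_variability(r1)}
    v2 = {(e.target, e.mode): e.mean_sd for e in parameter_variability(r2)}
    assert all(v2[k] > v1[k] for k in v1)


def test_parameter_sd_matches_monte_carlo_oracle():
    """Combined intra-rater SD of the dental-midline deviation agrees with a
    larger brute-force Monte-Carlo of the same generator."""
    kwargs = dict(rater_bias_sd=0.0, repeat_noise_sd=0.3)
    records, _ = cohort(n_subjects=8, seed=30, **kwargs)
    est = {
        (e.target, e.mode): e.mean_sd for e in parameter_variability(records)
    }[("dentMid_facMP", "intra")]
    big, _ = cohort(n_subjects=80, seed=31, **kwargs)
    oracle = {
        (e.target, e.mode): e.mean_sd for e in parameter_variability(big)
    }[("dentMid_facMP", "intra")]
    assert est == pytest.approx(oracle, rel=0.25)


# --- sample size -------------------------------------------------------------


def test_required_sample_size_values():
    assert required_sample_size(SampleSizeSpec(sigma2=0.0, w=0.25)) == 1
    assert required_sample_size(SampleSizeSpec(sigma2=0.25, w=0.25, alpha=0.05)) == 62


def test_required_sample_size_quadratic_scaling():
    from scipy.stats import norm

    z = norm.ppf(0.975)
    for sigma in (0.3, 0.5, 1.1):
        n1 = 4 * z**2 * sigma**2 / 0.25**2
        n2 = 4 * z**2 * (2 * sigma) ** 2 / 0.25**2
        assert n2 == pytest.approx(4 * n1, rel=1e-12)
        assert required_sample_size(SampleSizeSpec(sigma2=sigma**2, w=0.25)) == int(
            np.ceil(n1 - 1e-9)
        )


def test_required_sample_size_monotonicity():
    specs = [SampleSizeSpec(sigma2=s, w=0.25) for s in (0.1, 0.2, 0.4)]
    ns = [required_sample_size(s) for s in specs]
    assert ns == sorted(ns)
    ws = [required_sample_size(SampleSizeSpec(sigma2=0.25, w=w)) for w in (0.1, 0.25, 0.5)]
    assert ws == sorted(ws, reverse=True)


def test_sample_size_achieves_target_ci_width():
    """Monte-Carlo: n=62 gives mean 95% CI width <= 0.25 for sigma=0.5."""
    from scipy.stats import norm

    rng = np.random.default_rng(77)
    n = required_sample_size(SampleSizeSpec(sigma2=0.25, w=0.25, alpha=0.05))
    widths = []
    for _ in range(2000):
        sample = rng.normal(0.0, 0.5, size=n)
        se = sample.std(ddof=1) / np.sqrt(n)
        widths.append(2 * norm.ppf(0.975) * se)
    assert np.mean(widths) <= 0.25


def test_invalid_sample_size_specs():
    with pytest.raises(ValueError):
        SampleSizeSpec(sigma2=-1.0, w=0.25)
    with pytest.raises(ValueError):
        SampleSizeSpec(sigma2=0.25, w=0.0)
    with pytest.raises(ValueError):
        SampleSizeSpec(sigma2=0.25, w=0.25, alpha=1.5)
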