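import numpy as np
import pytest
from scipy import ndimage

import strokeconn as sc
from strokeconn.simulate import (
    _subject_damage,
    _target_correlation,
    subject_lesion_volume,
)


def _toy_config(**kw):
    """Two disjoint 3-region networks; no damping unless asked."""
    reg = sc.NetworkRegistry(
        {"P": ["A", "B", "C"], "Q": ["D", "E", "F"]},
        hemisphere_scopes=("left", "right", "both"),
    )
    defaults = dict(
        registry=reg,
        n_subjects=5,
        n_timepoints=2000,
        within_network_r=0.6,
        between_network_r=0.0,
        connectivity_damping_slope=0.0,
        affected_networks=(),
        outcome_coefficients={"intercept": 0.0},
        noise_sd=0.0,
        seed=0,
    )
    defaults.update(kw)
    return sc.SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# time-series generator


def test_block_correlations_match_configuration():
    """Sample-correlation oracle at large T: empirical within-block r near
    the configured 0.6, cross-block near 0."""
    cfg = _toy_config()
    ts = sc.simulate_roi_timeseries(cfg, 0)
    corr = sc.correlation_matrix(ts).to_numpy()
    members = cfg.registry.lateralized_members("P", "both")
    idx = [ts.region_names.index(m) for m in members]
    within = [
        corr[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]
    ]
    assert abs(np.mean(within) - 0.6) < 0.05
    other = [ts.region_names.index(m)
             for m in cfg.registry.lateralized_members("Q", "both")]
    cross = np.abs(corr[np.ix_(idx, other)])
    assert cross.mean() < 0.05


def test_covariance_fidelity_at_large_t_with_damping():
    """Empirical correlations converge entrywise to the damped target."""
    cfg = sc.SimulationConfig(seed=5, n_timepoints=5000)
    lat, atten = _subject_damage(cfg, 2)
    target = _target_correlation(cfg, atten, lat)
    ts = sc.simulate_roi_timeseries(cfg, 2)
    emp = sc.correlation_matrix(ts).to_numpy()
    off = ~np.eye(len(target), dtype=bool)
    assert np.abs(emp - target)[off].mean() < 0.03


def test_generator_is_deterministic_and_seed_stable():
    cfg = sc.SimulationConfig(seed=9, n_timepoints=80)
    a = sc.simulate_roi_timeseries(cfg, 3)
    b = sc.simulate_roi_timeseries(cfg, 3)
    assert np.array_equal(a.data, b.data)
    # growing the cohort must not reshuffle earlier subjects
    bigger = sc.SimulationConfig(seed=9, n_timepoints=80, n_subjects=60)
    c = sc.simulate_roi_timeseries(bigger, 3)
    assert np.array_equal(a.data, c.data)
    assert subject_lesion_volume(cfg, 3) == subject_lesion_volume(bigger, 3)


def test_ar1_preserves_marginal_correlations():
    cfg = _toy_config(ar1_phi=0.5, n_timepoints=4000)
    ts = sc.simulate_roi_timeseries(cfg, 1)
    corr = sc.correlation_matrix(ts).to_numpy()
    members = [ts.region_names.index(m)
               for m in cfg.registry.lateralized_members("P", "left")]
    within = [corr[i, j] for a, i in enumerate(members)
              for j in members[a + 1:]]
    assert abs(np.mean(within) - 0.6) < 0.07
    # and introduces the requested autocorrelation
    x = ts.data[:, 0]
    lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert 0.35 < lag1 < 0.65


def test_non_positive_definite_configuration_rejected():
    with pytest.raises(ValueError, match="positive definite"):
        sc.SimulationConfig(within_network_r=0.9, between_network_r=0.0)


def test_excessive_damping_rejected():
    with pytest.raises(ValueError, match="damping"):
        sc.SimulationConfig(connectivity_damping_slope=1e-3)


def test_subject_index_bounds():
    cfg = sc.SimulationConfig(n_subjects=6, n_timepoints=50)
    with pytest.raises(ValueError, match="subject_index"):
        sc.simulate_roi_timeseries(cfg, 6)


# ---------------------------------------------------------------------------
# cohort and outcome model


def test_noiseless_outcome_identifiable():
    """With noise_sd = 0 OLS on the true predictors recovers the generating
    coefficients and R-squared 1."""
    cfg = sc.SimulationConfig(seed=2, noise_sd=0.0, n_timepoints=120)
    cohort = sc.simulate_cohort(cfg)
    truth = cohort.truth.coefficients
    predictors = [p for p in truth if p != "intercept"]
    fit = sc.fit_linear_model(cohort.table, predictors)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
    assert fit.coefficients["intercept"] == pytest.approx(
        truth["intercept"], abs=1e-8
    )
    for p in predictors:
        assert fit.coefficients[p] == pytest.approx(truth[p], abs=1e-8)
    assert cohort.truth.design_r2 == 1.0
    # truth recomputes the outcome exactly
    assert np.allclose(
        cohort.truth.linear_predictor, cohort.table["nihss"], atol=1e-12
    )


def test_design_r2_calibration_matches_realized_r2():
    """Monte-Carlo oracle: noise calibrated for design R2 0.70 yields mean
    in-sample R2 of the true model near 0.70."""
    r2s = []
    for seed in range(100):
        cfg = sc.SimulationConfig(seed=seed, target_design_r2=0.70)
        cohort = sc.simulate_cohort(cfg)
        predictors = [
            p for p in cohort.truth.coefficients if p != "intercept"
        ]
        r2s.append(sc.fit_linear_model(cohort.table, predictors).r_squared)
    assert abs(np.mean(r2s) - 0.70) < 0.05


def test_null_cohort_has_no_predictor_outcome_correlation():
    """With all slopes zero the NIHSS-predictor correlation behaves like a
    sampling null: |r| <= 0.35 in at least ~95% of seeds at n=44."""
    within = 0
    n_seeds = 100
    for seed in range(n_seeds):
        cfg = sc.SimulationConfig(
            seed=seed,
            n_timepoints=120,
            outcome_coefficients={"intercept": 4.0},
            noise_sd=2.0,
        )
        tab = sc.simulate_cohort(cfg).table
        r = np.corrcoef(tab["lesion_volume"], tab["nihss"])[0, 1]
        within += abs(r) <= 0.35
    assert within >= 0.90 * n_seeds


def test_unknown_outcome_predictor_rejected():
    with pytest.raises(ValueError, match="unknown predictors"):
        sc.simulate_cohort(
            sc.SimulationConfig(
                n_timepoints=50,
                outcome_coefficients={"intercept": 1.0, "not_a_feature": 2.0},
            )
        )


def test_integer_outcome_mode_clips_to_scale():
    cfg = sc.SimulationConfig(seed=4, n_timepoints=80, integer_outcome=True)
    tab = sc.simulate_cohort(cfg).table
    assert np.array_equal(tab["nihss"], np.round(tab["nihss"]))
    assert tab["nihss"].between(0, 14).all()


def test_cohort_masks_match_tabulated_volumes():
    cfg = sc.SimulationConfig(
        n_subjects=5, n_timepoints=50, seed=8,
        lesion_volume_range=(50.0, 400.0),
    )
    cohort = sc.simulate_cohort(cfg, include_masks=True)
    assert len(cohort.lesion_masks) == 5
    for mask, volume in zip(cohort.lesion_masks, cohort.table["lesion_volume"]):
        assert sc.compute_lesion_volume(mask).volume_mm3 == volume


def test_cohort_is_reproducible():
    cfg = sc.SimulationConfig(seed=12, n_timepoints=60)
    a = sc.simulate_cohort(cfg).table
    b = sc.simulate_cohort(sc.SimulationConfig(seed=12, n_timepoints=60)).table
    assert a.equals(b)


# ---------------------------------------------------------------------------
# lesion masks


@pytest.mark.parametrize(
    "volume, dims, expected_voxels",
    [(1000.0, (1.0, 1.0, 1.0), 1000), (0.0, (1.0, 1.0, 1.0), 0),
     (40.0, (2.0, 2.0, 2.0), 5)],
)
def test_mask_voxel_counts_forced_by_volume(volume, dims, expected_voxels):
    mask = sc.make_lesion_mask(volume, (16, 16, 16), dims, seed=1)
    assert int(mask.grid.sum()) == expected_voxels
    assert sc.compute_lesion_volume(mask).volume_mm3 == volume


def test_mask_is_single_connected_component():
    mask = sc.make_lesion_mask(500.0, (16, 16, 16), (1.0, 1.0, 1.0), seed=2)
    _, n_components = ndimage.label(mask.grid)
    assert n_components == 1


def test_unachievable_volume_reports_nearest():
    with pytest.raises(ValueError, match="nearest achievable"):
        sc.make_lesion_mask(10.0, (8, 8, 8), (2.0, 2.0, 2.0), seed=0)
    with pytest.raises(ValueError, match="nearest achievable"):
        sc.make_lesion_mask(1000.0, (4, 4, 4), (1.0, 1.0, 1.0), seed=0)


# ---------------------------------------------------------------------------
# toy volumetric rendering


def _small_cohort():
    return sc.simulate_cohort(_toy_config(n_timepoints=40, n_subjects=5))


def test_render_round_trip_recovers_series_exactly():
    cohort = _small_cohort()
    toy = sc.render_toy_dataset(cohort, voxel_noise_sd=0.0)
    img = np.asanyarray(toy.images[0].dataobj)
    labels = np.asanyarray(toy.label_volume.dataobj)
    ts = sc.extract_roi_timeseries(
        img, labels, {v: k for k, v in toy.region_labels.items()}, 1.78
    )
    src = cohort.timeseries[0]
    col = [ts.region_names.index(r) for r in src.region_names]
    assert np.allclose(ts.data[:, col], src.data, atol=1e-5)  # float32 store


def test_render_voxel_noise_attenuated_by_averaging():
    """CLT oracle: mean over k voxels shrinks noise sd by sqrt(k)."""
    cohort = _small_cohort()
    sigma, k = 0.5, 8  # 2x2x2 blocks
    toy = sc.render_toy_dataset(cohort, voxel_noise_sd=sigma, seed=3)
    img = np.asanyarray(toy.images[0].dataobj)
    labels = np.asanyarray(toy.label_volume.dataobj)
    ts = sc.extract_roi_timeseries(
        img, labels, {v: k_ for k_, v in toy.region_labels.items()}, 1.78
    )
    src = cohort.timeseries[0]
    col = [ts.region_names.index(r) for r in src.region_names]
    resid = ts.data[:, col] - src.data
    assert resid.std() == pytest.approx(sigma / np.sqrt(k), rel=0.15)


def test_render_single_voxel_regions_verbatim():
    cohort = _small_cohort()
    names = cohort.timeseries[0].region_names
    layout = sc.simulate.default_atlas_layout(names, block_shape=(1, 1, 1))
    toy = sc.render_toy_dataset(cohort, atlas_layout=layout)
    img = np.asanyarray(toy.images[1].dataobj)
    labels = np.asanyarray(toy.label_volume.dataobj)
    ts = sc.extract_roi_timeseries(
        img, labels, {v: k for k, v in toy.region_labels.items()}, 1.78
    )
    src = cohort.timeseries[1]
    col = [ts.region_names.index(r) for r in src.region_names]
    assert np.allclose(ts.data[:, col], src.data, atol=1e-5)


def test_render_rejects_overlapping_blocks():
    cohort = _small_cohort()
    names = cohort.timeseries[0].region_names
    layout = {n: (slice(0, 2), slice(0, 2), slice(0, 2)) for n in names}
    with pytest.raises(ValueError, match="overlap"):
        sc.render_toy_dataset(cohort, atlas_layout=layout)
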