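"""Orientation statistics, division-angle weights, daughter-separation
dynamics, diffusion fits, and orientation-weighted averages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epivertex import analysis as ana
from epivertex import interface as iface
from epivertex import tissue_geometry as tg


# -- division-angle weights -------------------------------------------------

def test_stage_fraction_passthrough():
    w14 = ana.division_angle_weights(ana.STAGE_FRACTIONS["E14"])
    np.testing.assert_allclose(w14.weights, [0.20, 0.25, 0.55])
    w16 = ana.division_angle_weights(ana.STAGE_FRACTIONS["E16"])
    np.testing.assert_allclose(w16.weights, [0.60, 0.25, 0.15])


def test_weight_normalization():
    w = ana.division_angle_weights((2, 3, 5))
    np.testing.assert_allclose(w.weights, [0.2, 0.3, 0.5])


@given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=3, max_size=3)
       .filter(lambda f: sum(f) > 1e-9))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_weights_always_sum_to_one(fracs):
    w = ana.division_angle_weights(fracs)
    assert w.weights.sum() == pytest.approx(1.0)


def test_weights_reject_degenerate():
    with pytest.raises(ValueError):
        ana.division_angle_weights((0, 0, 0))
    with pytest.raises(ValueError):
        ana.division_angle_weights((-1, 1, 1))


@pytest.mark.parametrize("theta,label", [
    (0.0, "planar"),
    (np.pi / 6, "planar"),          # boundary belongs to the closed interval
    (np.pi / 4, "oblique"),
    (np.pi / 3, "oblique"),
    (np.pi / 3 + 0.01, "perpendicular"),
    (np.pi / 2, "perpendicular"),
])
def test_classify_division_angle(theta, label):
    assert ana.classify_division_angle(theta) == label


def test_classify_rejects_out_of_range():
    with pytest.raises(ValueError):
        ana.classify_division_angle(-0.1)
    with pytest.raises(ValueError):
        ana.classify_division_angle(2.0)


# -- long-axis distribution -------------------------------------------------

def test_isotropic_samples_give_flat_ratio():
    # Monte-Carlo oracle: under the 3D uniform orientation measure the folded
    # polar angle arccos|u_z| has density sin(theta) on [0, pi/2], which is
    # exactly the reference measure -- the normalized ratio must be ~1
    rng = np.random.default_rng(3)
    u = rng.standard_normal((100000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    theta = np.arccos(np.abs(u[:, 2]))
    dist = ana.long_axis_distribution(theta, n_bins=9)
    np.testing.assert_allclose(dist.ratio, 1.0, atol=0.06)
    assert dist.anisotropy_ratio < 1.15


def test_delta_peak_limit():
    dist = ana.long_axis_distribution(np.full(1000, np.pi / 2), n_bins=18)
    centers = dist.centers
    assert centers[np.argmax(dist.ratio)] == pytest.approx(np.pi / 2, abs=0.1)
    width = dist.edges[1] - dist.edges[0]
    assert dist.fwhm <= 2.5 * width


def test_distribution_mirrored_and_normalized():
    rng = np.random.default_rng(4)
    samples = rng.uniform(0, np.pi / 2, 5000)
    dist = ana.long_axis_distribution(samples, n_bins=12)
    width = dist.edges[1] - dist.edges[0]
    assert (dist.density * width).sum() == pytest.approx(1.0)
    np.testing.assert_allclose(dist.density, dist.density[::-1], atol=1e-12)


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        ana.long_axis_distribution([])


# -- daughter separation ----------------------------------------------------

def _brownian_fixture(D0=0.01, n_pairs=200, seed=0):
    t, pos = iface.generate_fixture(
        "synthetic_separation_trace",
        {"D0": D0, "n_pairs": n_pairs, "n_t": 81, "dt": 1.0}, seed=seed)
    rows = []
    events = []
    for pair in range(n_pairs):
        events.append({"t0": 0.0, "d1": 2 * pair, "d2": 2 * pair + 1})
        for d in range(2):
            cell = 2 * pair + d
            p = pos[pair, d]
            rows.append(pd.DataFrame({
                "time": t, "cell": cell, "x": p[:, 0], "y": p[:, 1],
                "z": p[:, 2], "type": tg.BASAL}))
    return pd.DataFrame(events), pd.concat(rows, ignore_index=True)


def test_dd2_zero_at_division_time():
    events, traj = _brownian_fixture(n_pairs=10)
    box = tg.PeriodicBox(Lx=1e6, Ly=1e6, z_min=-1e6, z_max=1e6)
    trace = ana.daughter_separation(events, traj, box)
    assert trace.mean()[0] == 0.0
    assert (trace.dd2[:, 0] == 0.0).all()


def test_rigid_translation_filtered():
    t = np.arange(20.0)
    drift = np.outer(t, [0.3, -0.2, 0.1])
    rows = []
    for cell, offset in ((0, np.zeros(3)), (1, np.array([1.0, 0, 0]))):
        p = drift + offset
        rows.append(pd.DataFrame({"time": t, "cell": cell, "x": p[:, 0],
                                  "y": p[:, 1], "z": p[:, 2], "type": tg.BASAL}))
    events = pd.DataFrame([{"t0": 0.0, "d1": 0, "d2": 1}])
    box = tg.PeriodicBox(Lx=1e6, Ly=1e6, z_min=-1e6, z_max=1e6)
    trace = ana.daughter_separation(events, pd.concat(rows), box)
    np.testing.assert_allclose(trace.mean(), 0.0, atol=1e-12)


def test_brownian_pairs_recover_relative_diffusion():
    # two independent walkers with diffusivity D0 each: Dd2(t) = 12 D0 t
    D0 = 0.02
    events, traj = _brownian_fixture(D0=D0, n_pairs=1000, seed=2)
    box = tg.PeriodicBox(Lx=1e6, Ly=1e6, z_min=-1e6, z_max=1e6)
    trace = ana.daughter_separation(events, traj, box)
    slope = np.polyfit(trace.times, trace.mean(), 1)[0]
    assert slope == pytest.approx(12 * D0, rel=0.05)


def test_censoring_on_type_change():
    events, traj = _brownian_fixture(n_pairs=4)
    # daughter 0 of pair 0 leaves the basal layer from t = 40
    mask = (traj["cell"] == 0) & (traj["time"] >= 40)
    traj.loc[mask, "type"] = tg.SUPRABASAL
    box = tg.PeriodicBox(Lx=1e6, Ly=1e6, z_min=-1e6, z_max=1e6)
    trace = ana.daughter_separation(events, traj, box)
    row = trace.dd2[list(trace.event_ids).index(0)]
    assert np.isfinite(row[:40]).all()
    assert np.isnan(row[40:]).all()


def test_minimal_image_separation_across_boundary():
    box = tg.PeriodicBox(Lx=10.0, Ly=10.0, z_min=0.0, z_max=5.0)
    t = np.arange(3.0)
    rows = [
        pd.DataFrame({"time": t, "cell": 0, "x": [0.5, 0.4, 0.3],
                      "y": 1.0, "z": 1.0, "type": tg.BASAL}),
        pd.DataFrame({"time": t, "cell": 1, "x": [9.5, 9.4, 9.3],
                      "y": 1.0, "z": 1.0, "type": tg.BASAL}),
    ]
    events = pd.DataFrame([{"t0": 0.0, "d1": 0, "d2": 1}])
    trace = ana.daughter_separation(events, pd.concat(rows), box)
    # separation is constant (1.0 across the boundary): Dd2 stays 0
    np.testing.assert_allclose(trace.dd2[0], 0.0, atol=1e-12)


# -- binning, bootstrap, diffusion fits --------------------------------------

def _line_trace(slope=0.02, n_events=40, n_t=100, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(float(n_t))
    base = slope * t
    dd2 = np.tile(base, (n_events, 1))
    if noise:
        dd2 = dd2 * (1 + noise * rng.standard_normal(dd2.shape))
    return ana.SeparationTrace(times=t, dd2=dd2,
                               event_ids=np.arange(n_events))


def test_bootstrap_partition_forty_into_five():
    trace = _line_trace(n_events=40)
    binned, groups = ana.bin_with_bootstrap(trace, bin_width=5.0, n_subgroups=5)
    assert groups.shape == (5, 8)
    assert sorted(groups.ravel()) == list(range(40))


def test_bootstrap_identical_subgroups_zero_error():
    trace = _line_trace(n_events=40, noise=0.0)
    binned, _ = ana.bin_with_bootstrap(trace, bin_width=5.0, n_subgroups=5)
    np.testing.assert_allclose(binned["err"], 0.0, atol=1e-12)


def test_bootstrap_rejects_uneven_partition():
    trace = _line_trace(n_events=41)
    with pytest.raises(ValueError):
        ana.bin_with_bootstrap(trace, 5.0, n_subgroups=5)


def test_bootstrap_error_scale_on_gaussian_data():
    # error estimate within 2x of sigma/sqrt(N) over repetitions
    rng = np.random.default_rng(7)
    sigma = 1.0
    ratios = []
    for _ in range(20):
        dd2 = 5.0 + sigma * rng.standard_normal((40, 10))
        trace = ana.SeparationTrace(times=np.arange(10.0), dd2=dd2,
                                    event_ids=np.arange(40))
        binned, _ = ana.bin_with_bootstrap(trace, bin_width=10.0,
                                           n_subgroups=5, rng=rng)
        # one bin holding all 10 samples per event
        expected = sigma / np.sqrt(40 * 10)
        ratios.append(binned["err"].iloc[0] / expected)
    assert 0.5 < np.median(ratios) < 2.0


def test_fit_diffusion_exact_line():
    trace = _line_trace(slope=0.02)
    binned, groups = ana.bin_with_bootstrap(trace, 5.0, 5)
    D, _ = ana.fit_diffusion(binned, (0, 100))
    assert D == pytest.approx(0.02, rel=1e-9)


def test_fit_diffusion_constant_trace():
    trace = _line_trace(slope=0.0)
    trace.dd2 += 3.0
    binned, _ = ana.bin_with_bootstrap(trace, 5.0, 5)
    D, _ = ana.fit_diffusion(binned, (0, 100))
    assert D == pytest.approx(0.0, abs=1e-12)


def test_fit_diffusion_recovers_noisy_slope_within_errors():
    hits = 0
    for rep in range(50):
        trace = _line_trace(slope=0.02, noise=0.05, seed=rep)
        binned, groups = ana.bin_with_bootstrap(trace, 5.0, 5)
        D, D_err = ana.fit_diffusion(binned, (0, 100), trace, groups)
        if abs(D - 0.02) < 2 * max(D_err, 1e-9):
            hits += 1
    assert hits >= 40  # ~95% nominal coverage at 2 sigma
    assert D == pytest.approx(0.02, rel=0.05)


def test_fit_diffusion_needs_three_bins():
    trace = _line_trace()
    binned, _ = ana.bin_with_bootstrap(trace, 5.0, 5)
    with pytest.raises(ValueError):
        ana.fit_diffusion(binned, (0, 6))


@pytest.mark.parametrize("power", [1.0, 0.5])
def test_msd_exponent_power_laws(power):
    t = np.arange(1.0, 101.0)
    binned = pd.DataFrame({"t": t, "mean": 0.03 * t ** power})
    expo, _ = ana.msd_exponent(binned, (1, 100))
    assert expo == pytest.approx(power, abs=1e-6)


def test_msd_exponent_caged_plateau():
    t = np.arange(1.0, 101.0)
    binned = pd.DataFrame({"t": t, "mean": 0.5 * (1 - np.exp(-t / 3.0))})
    expo, label = ana.msd_exponent(binned, (50, 100))
    assert expo < 0.3
    assert label == "subdiffusive"


def test_msd_exponent_classification_bands():
    t = np.arange(1.0, 101.0)
    binned = pd.DataFrame({"t": t, "mean": 0.01 * t})
    _, label = ana.msd_exponent(binned, (1, 100))
    assert label == "diffusive"


# -- orientation-weighted averages -------------------------------------------

def test_weighted_average_hand_arithmetic():
    w = ana.DivisionAngleWeights.for_stage("E14")
    mean, spread = ana.orientation_weighted_average(
        {"planar": 1.0, "oblique": 2.0, "perpendicular": 3.0}, w)
    assert mean == pytest.approx(0.20 * 1 + 0.25 * 2 + 0.55 * 3)  # = 2.35
    assert mean == pytest.approx(2.35)


def test_weighted_average_constant_and_degenerate():
    wc = ana.division_angle_weights((1, 1, 1))
    mean, spread = ana.orientation_weighted_average(
        {"planar": 4.2, "oblique": 4.2, "perpendicular": 4.2}, wc)
    assert mean == pytest.approx(4.2)
    assert spread == pytest.approx(0.0)
    wd = ana.division_angle_weights((1, 0, 0))
    mean, _ = ana.orientation_weighted_average(
        {"planar": 1.5, "oblique": 9.9, "perpendicular": -3}, wd)
    assert mean == pytest.approx(1.5)


def test_weighted_average_missing_bin_rejected():
    w = ana.DivisionAngleWeights.for_stage("E16")
    with pytest.raises(ValueError):
        ana.orientation_weighted_average({"planar": 1.0, "oblique": 2.0}, w)
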