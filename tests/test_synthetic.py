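"""Generator contracts: determinism, Poisson scaling, staining chains,
photon conservation, bleaching, two-plex cross-reactivity."""

import dataclasses
import math

import numpy as np
import pytest

from evquant import synthetic as syn


def test_zero_density_gives_empty_field():
    cfg = syn.FieldConfig(ev_density=0.0, nsb_density=0.0)
    field = syn.sample_field(cfg, 0)
    assert len(field) == 0


def test_same_seed_reproduces_field_and_image(optics, tsa):
    cfg = syn.FieldConfig(fov_shape=(64, 64), ev_density=20 / 4096)
    f1, f2 = syn.sample_field(cfg, 7), syn.sample_field(cfg, 7)
    assert f1.to_dataframe().equals(f2.to_dataframe())
    r1 = syn.simulate_staining(f1, tsa, "CD63", 3)
    r2 = syn.simulate_staining(f2, tsa, "CD63", 3)
    np.testing.assert_array_equal(r1, r2)
    i1 = syn.render_image(f1, r1, optics, 5)
    i2 = syn.render_image(f2, r2, optics, 5)
    np.testing.assert_array_equal(i1, i2)


def test_concentration_scaling_poisson_means():
    """E[count] scales with the plating factor: 8x/1x mean ratio near 8."""
    base = syn.FieldConfig(
        fov_shape=(64, 64), ev_density=100 / 4096, nsb_density=0.0
    )
    high = dataclasses.replace(base, concentration_scale=8.0)
    n1 = [len(syn.sample_field(base, 1000 + s)) for s in range(200)]
    n8 = [len(syn.sample_field(high, 2000 + s)) for s in range(200)]
    ratio = np.mean(n8) / np.mean(n1)
    assert 7.2 <= ratio <= 8.8


def test_zero_copies_zero_specific_rate():
    cfg = syn.FieldConfig(
        fov_shape=(32, 32),
        ev_density=30 / 1024,
        nsb_density=0.0,
        markers=(syn.MarkerModel("CD63", fixed_copies=0),),
    )
    # fixed_copies=0 is floored to 1 by the positive-marker model, so build
    # zero-copy particles directly
    field = syn.sample_field(cfg, 0)
    for p in field.particles:
        p.copies["CD63"] = 0
    for stain in (syn.ds_default(), syn.pss_default(), syn.tsa_default()):
        rates = syn.simulate_staining(field, stain, "CD63", 1)
        assert np.all(rates == 0.0)


def test_ds_degenerate_rate_exactly_proportional_to_copies():
    """label_efficiency 1 and one fluor per primary: rate = copies * unit."""
    stain = syn.StainMethod(
        name="DS", fluors_per_primary=1.0, label_efficiency=1.0,
        brightness_sigma_log=0.0,
    )
    cfg = syn.FieldConfig(
        fov_shape=(32, 32), ev_density=50 / 1024, nsb_density=0.0,
        markers=(syn.MarkerModel("CD63", mean_copies=40),),
    )
    field = syn.sample_field(cfg, 2)
    rates = syn.simulate_staining(field, stain, "CD63", 3)
    copies = np.array([p.copies["CD63"] for p in field.particles])
    np.testing.assert_allclose(rates, copies * stain.photon_rate_per_fluor)


def test_tsa_to_ds_mean_ratio_matches_product_model():
    """Law of large numbers: TSA/DS mean rate -> tyramide_mean x secondaries
    per primary (with one fluor per primary) within 5%."""
    c = 10
    cfg = syn.FieldConfig(
        fov_shape=(320, 320), ev_density=10_000 / 320**2, nsb_density=0.0,
        markers=(syn.MarkerModel("M", fixed_copies=c),),
    )
    field = syn.sample_field(cfg, 4)
    assert len(field) > 8000
    ds = syn.StainMethod(name="DS", fluors_per_primary=1.0, label_efficiency=0.8)
    tsa = syn.StainMethod(
        name="TSA", tyramide_mean=12.0, secondaries_per_primary=1.5,
        label_efficiency=0.8,
    )
    r_ds = syn.simulate_staining(field, ds, "M", 5)
    r_tsa = syn.simulate_staining(field, tsa, "M", 6)
    ratio = r_tsa.mean() / r_ds.mean()
    expect = tsa.tyramide_mean * tsa.secondaries_per_primary
    assert abs(ratio - expect) / expect < 0.05


def test_default_method_ordering_ds_pss_tsa():
    """Calibrated defaults keep mean DS < mean PSS < mean TSA and the
    TSA/DS population ratio near the printed 6.4x amplification."""
    cfg = syn.FieldConfig(
        fov_shape=(256, 256), ev_density=4000 / 65536, nsb_density=0.0
    )
    field = syn.sample_field(cfg, 8)
    means = {}
    for k, stain in enumerate(
        (syn.ds_default(), syn.pss_default(), syn.tsa_default())
    ):
        means[stain.name] = syn.simulate_staining(field, stain, "CD63", 20 + k).mean()
    assert means["DS"] < means["PSS"] < means["TSA"]
    assert abs(means["TSA"] / means["DS"] - 6.4) < 0.5


def test_unknown_marker_error_names_marker(tsa):
    field = syn.sample_field(syn.FieldConfig(fov_shape=(32, 32), ev_density=10 / 1024), 0)
    with pytest.raises(KeyError, match="EGFRv3"):
        syn.simulate_staining(field, tsa, "EGFRv3", 0)


def test_render_all_zero_rates_gives_offset_image(noiseless_optics):
    cfg = syn.FieldConfig(fov_shape=(48, 48), ev_density=10 / 2304, nsb_density=0.0)
    field = syn.sample_field(cfg, 1)
    img = syn.render_image(field, np.zeros(len(field)), noiseless_optics, 0)
    np.testing.assert_array_equal(img, np.full((48, 48), noiseless_optics.offset))


def test_photon_conservation_point_source(noiseless_optics):
    """Total above-offset intensity ~ gain * rate * exposure (3 sigma)."""
    cfg = syn.FieldConfig(fov_shape=(128, 128), ev_density=0.0, nsb_density=0.0)
    field = syn.sample_field(cfg, 0)
    field.particles.append(
        syn.GroundTruthParticle(id=0, kind="EV", x=64.0, y=64.0, diameter_nm=0.0)
    )
    rate = 40.0  # photons/ms
    img = syn.render_image(field, np.array([rate]), noiseless_optics, 123)
    total = img.sum() - noiseless_optics.offset * img.size
    expect = noiseless_optics.gain * rate * noiseless_optics.exposure_ms
    sigma = noiseless_optics.gain * math.sqrt(rate * noiseless_optics.exposure_ms)
    assert abs(total - expect) < 3 * sigma


def test_doubling_exposure_doubles_signal(noiseless_optics):
    cfg = syn.FieldConfig(fov_shape=(96, 96), ev_density=0.0, nsb_density=0.0)
    field = syn.sample_field(cfg, 0)
    for k in range(5):
        field.particles.append(
            syn.GroundTruthParticle(id=k, kind="EV", x=20.0 + 14 * k, y=48.0)
        )
    rates = np.full(5, 30.0)
    long = dataclasses.replace(noiseless_optics, exposure_ms=2 * noiseless_optics.exposure_ms)
    s1 = syn.render_image(field, rates, noiseless_optics, 1).sum() - noiseless_optics.offset * 96**2
    s2 = syn.render_image(field, rates, long, 2).sum() - long.offset * 96**2
    assert abs(s2 / s1 - 2.0) < 0.05


def test_timeseries_bleaching_follows_exponential(tsa, noiseless_optics):
    """Mean above-offset signal at t over t=0 ~ exp(-k t) for >= 100 spots."""
    k = 0.7
    stain = dataclasses.replace(tsa, bleach_rate=k)
    cfg = syn.FieldConfig(fov_shape=(256, 256), ev_density=150 / 65536, nsb_density=0.0)
    field = syn.sample_field(cfg, 3)
    assert len(field) >= 100
    rates = syn.simulate_staining(field, stain, "CD63", 4)
    stack = syn.render_timeseries(field, rates, noiseless_optics, stain, (0, 1, 3, 5), 5)
    total0 = stack.frame(0).sum() - noiseless_optics.offset * 256**2
    for ti, t in enumerate(stack.timepoints_min):
        tot = stack.frame(ti).sum() - noiseless_optics.offset * 256**2
        assert abs(tot / total0 - math.exp(-k * t)) < 0.05
    # zero bleaching: all frames statistically identical in expectation
    stable = dataclasses.replace(stain, bleach_rate=0.0)
    stack0 = syn.render_timeseries(field, rates, noiseless_optics, stable, (0, 1, 3, 5), 6)
    totals = [stack0.frame(i).sum() for i in range(4)]
    assert np.ptp(totals) / np.mean(totals) < 0.02


def test_ds_signal_drops_within_first_minute(noiseless_optics):
    """Direct staining of EVs loses most signal after 1 min of excitation."""
    ds = syn.ds_default()
    cfg = syn.FieldConfig(fov_shape=(128, 128), ev_density=60 / 16384, nsb_density=0.0)
    field = syn.sample_field(cfg, 9)
    rates = syn.simulate_staining(field, ds, "CD63", 10)
    stack = syn.render_timeseries(field, rates, noiseless_optics, ds, (0, 1), 11)
    s0 = stack.frame(0).sum() - noiseless_optics.offset * 128**2
    s1 = stack.frame(1).sum() - noiseless_optics.offset * 128**2
    assert s1 < 0.5 * s0


def test_timeseries_rejects_unsorted_timepoints(tsa, optics):
    field = syn.sample_field(syn.FieldConfig(fov_shape=(32, 32), ev_density=5 / 1024), 0)
    rates = np.zeros(len(field))
    with pytest.raises(ValueError):
        syn.render_timeseries(field, rates, optics, tsa, (0, 3, 1), 0)
    with pytest.raises(ValueError):
        syn.render_timeseries(field, rates, optics, tsa, (1, 3, 5), 0)


def test_expected_signal_monotone_in_parameters():
    """Mean emission is non-decreasing in copies, label efficiency and
    tyramide yield (checked on the analytic per-copy mean)."""
    base = syn.tsa_default()
    assert (
        dataclasses.replace(base, label_efficiency=0.9).mean_fluors_per_copy
        > base.mean_fluors_per_copy
    )
    assert (
        dataclasses.replace(base, tyramide_mean=base.tyramide_mean * 2).mean_fluors_per_copy
        > base.mean_fluors_per_copy
    )
    cfg10 = syn.FieldConfig(
        fov_shape=(128, 128), ev_density=2000 / 16384, nsb_density=0.0,
        markers=(syn.MarkerModel("M", fixed_copies=10),),
    )
    cfg50 = dataclasses.replace(cfg10, markers=(syn.MarkerModel("M", fixed_copies=50),))
    r10 = syn.simulate_staining(syn.sample_field(cfg10, 1), base, "M", 2).mean()
    r50 = syn.simulate_staining(syn.sample_field(cfg50, 1), base, "M", 2).mean()
    assert r50 > r10


# ---------------------------------------------------------------------------
# two-plex
# ---------------------------------------------------------------------------


def _twoplex_field(n=10_000, seed=0):
    side = int(math.sqrt(n / (150 / 65536)))
    cfg = syn.FieldConfig(
        fov_shape=(side, side),
        ev_density=n / side**2,
        nsb_density=0.0,
        n_channels=2,
        class_probs=(1.0, 0.0, 0.0),  # all A-only
        markers=(syn.MarkerModel("STEAM"), syn.MarkerModel("CD9-CD81")),
    )
    return syn.sample_field(cfg, seed)


@pytest.mark.parametrize(
    "cross,quench,quench_eff,expect",
    [(0.0, False, 0.0, 0.0), (0.2, True, 1.0, 0.0)],
)
def test_twoplex_no_effective_cross_reaction_no_spurious(
    tsa, optics, cross, quench, quench_eff, expect
):
    field = _twoplex_field(n=2000, seed=1)
    tp = syn.TwoPlexConfig(
        cross_react_fraction=cross, quench_applied=quench, quench_efficiency=quench_eff
    )
    _, truth = syn.simulate_twoplex(field, tsa, tsa, tp, optics, 2, render=False)
    assert truth["b_spurious"].sum() == expect


def test_twoplex_spurious_fraction_binomial(tsa, optics):
    """cross_react_fraction 0.2, no quench: spurious fraction 0.2 +- 0.02
    among A-stained particles (10^4 A-only EVs)."""
    field = _twoplex_field(n=10_000, seed=3)
    tp = syn.TwoPlexConfig(cross_react_fraction=0.2, quench_applied=False)
    _, truth = syn.simulate_twoplex(field, tsa, tsa, tp, optics, 4, render=False)
    stained = truth[truth["a_stained"]]
    frac = stained["b_spurious"].mean()
    assert abs(frac - 0.2) <= 0.02


def test_twoplex_rejects_same_marker():
    with pytest.raises(syn.ConfigurationError):
        syn.TwoPlexConfig(channel_a_marker="CD63", channel_b_marker="CD63")


def test_calibration_substrate_empty_and_mode(tsa, noiseless_optics, optics):
    stack, truth = syn.make_calibration_substrate(
        noiseless_optics, tsa, 0, fov_shape=(64, 64), seed=0
    )
    np.testing.assert_array_equal(
        stack.frame(), np.full((64, 64), noiseless_optics.offset)
    )
    assert len(truth) == 0
    # distinct isolated spots whose intensity mode sits near one secondary's
    # amplified output
    import dataclasses as dc

    from evquant.detection import DetectionParams, calibrate_threshold, detect_particles
    from evquant.lod import find_first_peak
    from evquant.quantify import measure_particles

    lod_optics = dc.replace(optics, exposure_ms=4000.0)
    stack, truth = syn.make_calibration_substrate(
        lod_optics, tsa, 250, fov_shape=(512, 512), seed=1
    )
    img = stack.frame()
    bg = syn.render_image(
        syn.sample_field(syn.FieldConfig(ev_density=0.0, nsb_density=0.0), 0),
        np.zeros(0), lod_optics, 2,
    )
    params = DetectionParams()
    thr = calibrate_threshold([bg], params)
    parts = detect_particles(img, dc.replace(params, threshold=thr))
    assert len(parts) > 150  # most events resolved as distinct spots
    vals = measure_particles(parts, img, params)["integrated"].to_numpy()
    peak = find_first_peak(vals)
    expect = (
        lod_optics.gain * lod_optics.exposure_ms * tsa.tyramide_mean
        * tsa.photon_rate_per_fluor
    )
    assert abs(peak - expect) / expect < 0.25
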