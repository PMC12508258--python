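"""Shared fixtures: default configurations and one rendered EV field with a
calibrated threshold, reused by detection/quantify/property tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from evquant import synthetic as syn
from evquant._utils import derive_seed
from evquant.detection import DetectionParams, calibrate_threshold, detect_particles


@pytest.fixture(scope="session")
def optics():
    return syn.OpticsCameraConfig()


@pytest.fixture(scope="session")
def tsa():
    return syn.tsa_default()


@pytest.fixture(scope="session")
def noiseless_optics():
    """Deterministic camera: no background, no read noise (shot noise only)."""
    return syn.OpticsCameraConfig(read_noise_sd=0.0, background_rate=0.0)


@pytest.fixture(scope="session")
def field_config():
    return syn.FieldConfig()


def render_controls(field_config, stain, optics, master_seed, n=4, channel_index=0):
    """EV-free control FOVs under the given configuration."""
    imgs = []
    for k in range(n):
        cf = syn.control_field(field_config, derive_seed(master_seed, "control", k))
        rates = syn.simulate_staining(
            cf, stain, None, derive_seed(master_seed, "control", 100 + k),
            specific=False, channel_index=channel_index,
        )
        imgs.append(
            syn.render_image(cf, rates, optics, derive_seed(master_seed, "control", 200 + k))
        )
    return imgs


@pytest.fixture(scope="session")
def tsa_scene(field_config, tsa, optics):
    """One rendered TSA EV field with its ground truth and calibrated params."""
    controls = render_controls(field_config, tsa, optics, master_seed=11, n=3)
    params = DetectionParams()
    thr = calibrate_threshold(controls, params)
    params = dataclasses.replace(params, threshold=thr)
    field = syn.sample_field(field_config, derive_seed(11, "field"))
    rates = syn.simulate_staining(field, tsa, "CD63", derive_seed(11, "staining"))
    image = syn.render_image(field, rates, optics, derive_seed(11, "render"))
    particles = detect_particles(image, params)
    return {
        "field": field,
        "rates": rates,
        "image": image,
        "controls": controls,
        "params": params,
        "particles": particles,
    }


def random_test_images(n=8, shape=(64, 64), levels=9, seed=5):
    """Small integer-valued images: random fields plus structured blobs."""
    rng = np.random.default_rng(seed)
    imgs = [rng.integers(0, levels, size=shape).astype(float) for _ in range(n)]
    # structured: disjoint blobs, a ring with a hole, touching shapes
    a = np.zeros(shape)
    a[5:9, 5:8] = 7.0
    a[20:24, 30:33] = 6.0
    a[40:41, 40:45] = 8.0  # 5-px line, below min size
    imgs.append(a)
    b = np.zeros(shape)
    b[10:13, 10:14] = 5.0
    b[11, 11:13] = 0.0  # ring with interior hole
    imgs.append(b)
    c = np.zeros(shape)
    c[30:36, 30:36] = 4.0
    c[33:39, 33:39] = 4.0  # overlapping squares
    imgs.append(c)
    return imgs
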