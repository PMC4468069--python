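import numpy as np
import pytest

import meamap as m


@pytest.fixture(scope="session")
def layout():
    return m.standard_layout()


@pytest.fixture(scope="session")
def planar_sim():
    """Noise-free planar wave, 200 mm/s at 30 deg, with ground truth."""
    spec = m.WaveSpec.planar(200.0, 30.0, seed=11)
    rec, truth = m.generate_recording(spec)
    return spec, rec, truth


@pytest.fixture(scope="session")
def planar_map(planar_sim, layout):
    _, rec, _ = planar_sim
    window = m.AnalysisWindow(0.0, rec.duration_ms)
    return m.detect_activation_map(rec, window)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quadratic_truth_map(layout):
    """Activation map whose times follow a known quadratic surface exactly."""
    coeffs = (1e-6, -2e-6, 5e-7, 5e-3, -1e-3, 10.0)
    xy = layout.coords()
    a, b, c, d, e, f = coeffs
    x, y = xy[:, 0], xy[:, 1]
    t = a * x * x + b * y * y + c * x * y + d * x + e * y + f
    window = m.AnalysisWindow(float(t.min()) - 1.0, float(np.ptp(t)) + 2.0)
    amap = m.ActivationMap(
        times={lab: float(ti) for lab, ti in zip(layout.labels, t)},
        min_gradient={lab: -100.0 for lab in layout.labels},
        window=window,
    )
    return coeffs, amap
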