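import numpy as np
import pytest

from fdmech import AcquisitionParams, ForceCurve, build_scene
from fdmech.synthetic import simulate_curve


@pytest.fixture
def acq():
    return AcquisitionParams()


def make_scene(e_pm=5.3, e_cortex=37.5, noise_sd=0.0, drift=(0.0, 0.0, 0.0),
               coverage=0.0, p_bind=1.0, seed=0, rows=1, cols=1, e_pm_out=None):
    """Single-purpose scene: homogeneous fields unless a coverage is given."""
    return build_scene(rows, cols, coverage=coverage,
                       e_pm_in=e_pm, e_pm_out=e_pm if e_pm_out is None else e_pm_out,
                       e_cortex=e_cortex, p_bind=p_bind,
                       noise_sd=noise_sd, drift_coeffs=drift, seed=seed)


def make_curve(e_pm=5.3, e_cortex=37.5, noise_sd=0.0, drift=(0.0, 0.0, 0.0),
               with_event=False, seed=0, acq=None):
    """One synthetic curve; the scene ground truth rides on `.scene`."""
    scene = make_scene(e_pm=e_pm, e_cortex=e_cortex, noise_sd=noise_sd,
                       drift=drift, coverage=0.95 if with_event else 0.0,
                       seed=seed)
    scene.height_true = np.full((1, 1), np.nan)
    curve = simulate_curve(scene, 0, 0, acq or AcquisitionParams(), seed=seed)
    curve.scene = scene
    return curve


def flat_noise_curve(sigma=15.0, n=512, z_turn=370.0, seed=0,
                     drift=(0.0, 0.0, 0.0), acq=None):
    """No contact anywhere: baseline drift plus white noise."""
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, z_turn, n)
    c0, c1, c2 = drift
    base = c0 + c1 * z + c2 * z ** 2
    f_app = base + (rng.normal(0, sigma, n) if sigma > 0 else 0.0)
    f_ret = base + (rng.normal(0, sigma, n) if sigma > 0 else 0.0)
    return ForceCurve(approach_z=z, approach_f=f_app,
                      retract_z=z[::-1].copy(), retract_f=f_ret[::-1].copy(),
                      acquisition=acq or AcquisitionParams())
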