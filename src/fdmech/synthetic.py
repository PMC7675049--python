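"""Synthetic force-volume generator with full ground truth.

The generator emulates the statistical structure the analysis assumes so
that every pipeline stage is testable without instrument data:

* a two-layer elastic response -- a soft membrane-dominated layer over a
  stiffer cortex, force-continuous at the 50 nm boundary (incremental
  stiffness switches, force accumulates);
* spatially clustered binding domains: random blobs with sizes drawn from a
  truncated power law (small domains most abundant, heavy tail), grown until
  a target area coverage is reached;
* specific adhesion events on domain pixels with probability ``p_bind``:
  a worm-like-chain pull (PEG linker, Lp = 0.38 nm, Lc uniform in
  [10, 40] nm) rupturing at a force drawn from a normal distribution
  (default 130 +/- 35 pN, truncated positive);
* second-degree baseline drift and white Gaussian force noise (default
  sigma = 15 pN, under the instrument's typical 20 pN).

Determinism: the scene uses ``SeedSequence([seed])``; each pixel's curve
uses ``SeedSequence([seed, row, col])``, so pixel streams are reproducible
and independent of traversal order.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .errors import ParameterError
from .model import AcquisitionParams, ForceCurve, ForceVolumeMap, SyntheticScene
from .units import modulus_kpa_to_internal, spring_constant_internal, thermal_energy

DEFAULT_NOISE_SD_PN = 15.0
DEFAULT_RUPTURE_MEAN_PN = 130.0
DEFAULT_RUPTURE_SD_PN = 35.0
DEFAULT_DRIFT_COEFFS = (2.0, 0.01, 2e-5)
DEFAULT_LC_RANGE_NM = (10.0, 40.0)
DEFAULT_LP_NM = 0.38
DEFAULT_SAMPLES_PER_SEGMENT = 512
DEFAULT_BASE_HEIGHT_NM = 220.0
DEFAULT_HEIGHT_JITTER_NM = 10.0
LAYER_BOUNDARY_NM = 50.0
BLOB_SIZE_EXPONENT = 1.8
MAX_COVERAGE = 0.95


def _pixel_rng(seed: int, row: int, col: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, row, col]))


def _power_law_sizes(rng: np.random.Generator, s_max: int,
                     tau: float = BLOB_SIZE_EXPONENT) -> int:
    sizes = np.arange(1, s_max + 1, dtype=float)
    w = sizes ** (-tau)
    w /= w.sum()
    return int(rng.choice(sizes, p=w))


def _grow_blob(rng: np.random.Generator, mask: np.ndarray, size: int) -> None:
    """Grow one 8-connected blob of ``size`` pixels onto the mask in place."""
    rows, cols = mask.shape
    r0 = int(rng.integers(rows))
    c0 = int(rng.integers(cols))
    blob = {(r0, c0)}
    frontier = [(r0, c0)]
    while len(blob) < size and frontier:
        r, c = frontier[int(rng.integers(len(frontier)))]
        nbrs = [(r + dr, c + dc)
                for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if not (dr == 0 and dc == 0)
                and 0 <= r + dr < rows and 0 <= c + dc < cols
                and (r + dr, c + dc) not in blob]
        if not nbrs:
            frontier.remove((r, c))
            continue
        nxt = nbrs[int(rng.integers(len(nbrs)))]
        blob.add(nxt)
        frontier.append(nxt)
    for r, c in blob:
        mask[r, c] = True


def build_scene(rows: int, cols: int, coverage: float = 0.275,
                e_pm_in: float = 13.1, e_pm_out: float = 9.0,
                e_cortex: float = 15.9, p_bind: float = 1.0,
                rupture_mean: float = DEFAULT_RUPTURE_MEAN_PN,
                rupture_sd: float = DEFAULT_RUPTURE_SD_PN,
                noise_sd: float = DEFAULT_NOISE_SD_PN,
                drift_coeffs: tuple = DEFAULT_DRIFT_COEFFS,
                seed: int = 0) -> SyntheticScene:
    """Build ground truth: clustered domain mask + two-value elasticity field.

    The membrane modulus takes ``e_pm_in`` (kPa) on domain pixels and
    ``e_pm_out`` elsewhere; the cortex field is uniform. Blobs are placed
    until the realized coverage reaches the target. Coverage above 0.95 is
    rejected as unreachable by the blob process.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ParameterError("coverage must be in [0, 1]")
    if coverage > MAX_COVERAGE:
        raise ParameterError(
            f"coverage {coverage} unreachable (maximum {MAX_COVERAGE})")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    mask = np.zeros((rows, cols), dtype=bool)
    n_target = int(round(coverage * rows * cols))
    s_max = max(1, min(400, rows * cols // 4))
    guard = 0
    while mask.sum() < n_target:
        remaining = n_target - int(mask.sum())
        _grow_blob(rng, mask, min(_power_law_sizes(rng, s_max), remaining + 8))
        guard += 1
        if guard > 100 * rows * cols:
            raise ParameterError("coverage target unreachable")
    e_pm = np.where(mask, e_pm_in, e_pm_out).astype(float)
    e_cx = np.full((rows, cols), float(e_cortex))
    return SyntheticScene(
        e_pm_true=e_pm, e_cortex_true=e_cx, domain_mask=mask,
        p_bind=p_bind, rupture_mean=rupture_mean, rupture_sd=rupture_sd,
        noise_sd=noise_sd, drift_coeffs=tuple(drift_coeffs), seed=seed)


# --- forward contact model -------------------------------------------------

_CONTACT_CACHE: dict = {}


def _contact_tables(e_pm: float, e_cortex: float, acq: AcquisitionParams,
                    boundary: float = LAYER_BOUNDARY_NM):
    """Cached (u, F) tables for the piecewise two-layer response, where
    u = delta + F/k is piezo travel past contact including deflection."""
    key = (round(e_pm, 9), round(e_cortex, 9), acq.tip_radius,
           acq.poisson_ratio, acq.spring_constant, acq.setpoint_force, boundary)
    hit = _CONTACT_CACHE.get(key)
    if hit is not None:
        return hit
    pre = (4.0 / 3.0) / (1.0 - acq.poisson_ratio ** 2) * np.sqrt(acq.tip_radius)
    c_pm = modulus_kpa_to_internal(e_pm) * pre
    c_cx = modulus_kpa_to_internal(e_cortex) * pre
    big_b = boundary ** 1.5
    # depth reaching ~5% beyond the setpoint force
    f_stop = 1.05 * acq.setpoint_force
    d_deep = ((f_stop + c_pm * big_b) / c_cx + big_b) ** (2.0 / 3.0) \
        if c_cx > 0 else boundary
    d_max = max(boundary * 1.5, d_deep)
    delta = np.linspace(0.0, d_max, 4096)
    force = np.where(delta <= boundary, c_pm * delta ** 1.5,
                     c_pm * big_b + c_cx * (np.maximum(delta, boundary) ** 1.5
                                            - big_b))
    k_int = spring_constant_internal(acq.spring_constant)
    u = delta + force / k_int
    _CONTACT_CACHE[key] = (u, force)
    return u, force


def _wlc_tether_tables(f_rup: float, lc: float, lp: float, kbt: float,
                       k_int: float):
    """(z0 - z, force) table for the tether pull up to rupture."""
    t = np.linspace(0.0, 0.999, 2048)
    f_wlc = (kbt / lp) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)
    f_rup = min(f_rup, f_wlc[-1] * 0.999)
    s_rup = float(np.interp(f_rup, f_wlc, t)) * lc
    s = np.linspace(0.0, s_rup, 512)
    ts = np.clip(s / lc, 0.0, 0.999)
    f = (kbt / lp) * (0.25 / (1.0 - ts) ** 2 - 0.25 + ts)
    # piezo coordinate: z = z0 - s - F/k  =>  z0 - z = s + F/k
    dz = s + f / k_int
    return dz, f, s_rup


def simulate_curve(scene: SyntheticScene, row: int, col: int,
                   acquisition: Optional[AcquisitionParams] = None,
                   seed: Optional[int] = None,
                   n_samples: int = DEFAULT_SAMPLES_PER_SEGMENT,
                   rng: Optional[np.random.Generator] = None,
                   record_truth: bool = True) -> ForceCurve:
    """Simulate one pixel's approach/retract record from scene ground truth.

    The approach ramps until the contact force reaches the setpoint (the
    curve maximum is the setpoint to within one sample); the retract mirrors
    the contact response and, with probability ``p_bind`` on domain pixels,
    carries a WLC tether pull. The injected event's truth (rupture force,
    rupture separation, Lc, Lp) is recorded on ``scene.events``.
    """
    acq = acquisition or AcquisitionParams()
    if rng is None:
        rng = _pixel_rng(scene.seed if seed is None else seed, row, col)
    k_int = spring_constant_internal(acq.spring_constant)
    u_tab, f_tab = _contact_tables(scene.e_pm_true[row, col],
                                   scene.e_cortex_true[row, col], acq)
    z0 = DEFAULT_BASE_HEIGHT_NM + float(
        rng.uniform(-DEFAULT_HEIGHT_JITTER_NM, DEFAULT_HEIGHT_JITTER_NM))
    if record_truth and scene.height_true is not None:
        scene.height_true[row, col] = z0
    u_turn = float(np.interp(acq.setpoint_force, f_tab, u_tab))
    z_turn = z0 + u_turn
    z_app = np.linspace(0.0, z_turn, n_samples)
    contact_app = np.where(z_app > z0,
                           np.interp(z_app - z0, u_tab, f_tab), 0.0)
    z_ret = z_app[::-1].copy()
    contact_ret = contact_app[::-1].copy()

    # tether pull on the retract
    has_event = bool(scene.domain_mask[row, col]) \
        and float(rng.uniform()) < scene.p_bind
    if has_event:
        f_rup = -1.0
        while f_rup <= 0.0:
            f_rup = float(rng.normal(scene.rupture_mean, scene.rupture_sd))
        lc = float(rng.uniform(*DEFAULT_LC_RANGE_NM))
        lp = DEFAULT_LP_NM
        dz_tab, f_pull_tab, s_rup = _wlc_tether_tables(
            f_rup, lc, lp, thermal_energy(acq.temperature), k_int)
        f_rup = float(f_pull_tab[-1])
        sel = (z_ret < z0) & (z0 - z_ret <= dz_tab[-1])
        contact_ret[sel] = contact_ret[sel] - np.interp(
            z0 - z_ret[sel], dz_tab, f_pull_tab)
        if record_truth:
            scene.events[(row, col)] = (f_rup, s_rup, lc, lp)

    c0, c1, c2 = scene.drift_coeffs
    drift_app = c0 + c1 * z_app + c2 * z_app ** 2
    drift_ret = c0 + c1 * z_ret + c2 * z_ret ** 2
    f_app = contact_app + drift_app
    f_ret = contact_ret + drift_ret
    if scene.noise_sd > 0:
        f_app = f_app + rng.normal(0.0, scene.noise_sd, n_samples)
        f_ret = f_ret + rng.normal(0.0, scene.noise_sd, n_samples)
    return ForceCurve(approach_z=z_app, approach_f=f_app,
                      retract_z=z_ret, retract_f=f_ret,
                      row=row, col=col, acquisition=acq)


def simulate_map(scene: SyntheticScene,
                 acquisition: Optional[AcquisitionParams] = None,
                 seed: Optional[int] = None,
                 n_samples: int = DEFAULT_SAMPLES_PER_SEGMENT
                 ) -> ForceVolumeMap:
    """Simulate the whole grid; ground truth rides along on the map."""
    acq = acquisition or AcquisitionParams()
    rows, cols = scene.shape
    base_seed = scene.seed if seed is None else seed
    scene.events.clear()
    scene.height_true = np.full((rows, cols), np.nan)
    az = np.empty((rows, cols, n_samples))
    af = np.empty_like(az)
    rz = np.empty_like(az)
    rf = np.empty_like(az)
    for r in range(rows):
        for c in range(cols):
            curve = simulate_curve(scene, r, c, acq, seed=base_seed,
                                   n_samples=n_samples)
            az[r, c] = curve.approach_z
            af[r, c] = curve.approach_f
            rz[r, c] = curve.retract_z
            rf[r, c] = curve.retract_f
    return ForceVolumeMap(acquisition=acq, approach_z=az, approach_f=af,
                          retract_z=rz, retract_f=rf, scene=scene)
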