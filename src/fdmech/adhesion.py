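"""Rupture-event detection, worm-like-chain validation and specificity.

On retraction, a tip-borne probe bound to its target stretches the PEG
linker until the bond ruptures: the force dips increasingly negative along
the tether's entropic-elasticity profile and snaps back to the baseline.
Candidates are runs of at least two consecutive samples below -3 sigma
outside the contact region (single samples qualify when very deep or when a
ramp precedes them and baseline follows -- steep tethers may put only one
sample below threshold), merged across gaps of up to two samples, that
return above -3 sigma within five samples after the run. The run
requirement keeps the false-alarm rate of the 3-sigma rule negligible on
white noise.

Each candidate's extension profile is validated against the Marko-Siggia
worm-like chain,

    F(x) = (kBT/Lp) * [ 1/4 (1 - x/Lc)^{-2} - 1/4 + x/Lc ],

with the persistence length constrained to the PEG-linker scale. An event is
*specific* when the rupture force exceeds 80 pN, the rupture distance
exceeds 5 nm, and the WLC fit was accepted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError
from .model import (AdhesionEvent, ForceCurve, WLCParams,
                    STRATUM_CHOLESTEROL, STRATUM_INDETERMINATE,
                    STRATUM_NON_ADHESIVE)
from .preprocess import NoiseEstimate
from .units import spring_constant_internal, thermal_energy

DEFAULT_SPECIFIC_MIN_FORCE_PN = 80.0
DEFAULT_SPECIFIC_MIN_DISTANCE_NM = 5.0
DEFAULT_CHOLESTEROL_MIN_FORCE_PN = 100.0
DEFAULT_NONADHESIVE_MAX_FORCE_PN = 30.0
DEFAULT_WLC_LC_BOUNDS_NM = (5.0, 60.0)
DEFAULT_WLC_LP_BOUNDS_NM = (0.1, 1.5)
MIN_WLC_SAMPLES = 10        # raw samples between crossing and rupture
MIN_WLC_FIT_SAMPLES = 5     # usable samples after the extension filter

THRESHOLD_SIGMA = 3.0
SINGLE_SAMPLE_SIGMA = 4.2
RUN_MERGE_GAP = 2
RETURN_WINDOW = 5


def wlc_force(x, params: WLCParams):
    """Marko-Siggia interpolation force (pN) at extension x (nm)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any() or (x >= params.contour_length).any():
        raise DomainError("extension must satisfy 0 <= x < Lc")
    t = x / params.contour_length
    out = (params.thermal_energy / params.persistence_length) \
        * (0.25 / (1.0 - t) ** 2 - 0.25 + t)
    return float(out) if out.ndim == 0 else out


def wlc_extension_at_force(force: float, params: WLCParams,
                           n_grid: int = 4000) -> float:
    """Extension (nm) at which the WLC reaches a given force (monotone inverse)."""
    t = np.linspace(0.0, 0.999, n_grid)
    f = (params.thermal_energy / params.persistence_length) \
        * (0.25 / (1.0 - t) ** 2 - 0.25 + t)
    return float(np.interp(force, f, t)) * params.contour_length


@dataclass(frozen=True)
class WLCRejection:
    """Why a candidate's extension profile failed tether validation."""

    reason: str
    rms: Optional[float] = None
    contour_length: Optional[float] = None


@dataclass
class RuptureCandidate:
    """A detected rupture before WLC validation/classification."""

    rupture_force: float        # pN, magnitude of the minimum
    rupture_distance: float     # nm, tip-sample separation at the minimum
    index: int                  # sample index of the minimum (time order)
    start_index: int            # first sample of the pulling segment


def _separation(z: np.ndarray, f: np.ndarray, z0: float,
                k_int: float) -> np.ndarray:
    """Tip-sample separation (nm): piezo retraction past contact minus the
    (negative) deflection pulling the tip back toward the surface."""
    return (z0 - z) + f / k_int


def detect_ruptures(curve: ForceCurve, noise: NoiseEstimate, z0: float,
                    threshold_sigma: float = THRESHOLD_SIGMA
                    ) -> list[RuptureCandidate]:
    """Rupture candidates on the retract segment, ordered by distance.

    The retract segment must be baseline-corrected and the contact point
    located. An empty list is a valid result.
    """
    z, f = curve.retract_z, curve.retract_f
    # time order = stored order (z decreasing on retraction)
    k_int = spring_constant_internal(curve.acquisition.spring_constant)
    sigma = max(noise.sigma, 1e-9)
    off = z < z0
    below = (f < -threshold_sigma * sigma) & off
    idx = np.flatnonzero(below)
    out: list[RuptureCandidate] = []
    if idx.size == 0:
        return out
    splits = np.flatnonzero(np.diff(idx) > RUN_MERGE_GAP + 1)
    for run in np.split(idx, splits + 1):
        seg = f[run[0]:run[-1] + 1]
        deep_enough = (len(run) >= 2) or (seg.min() < -SINGLE_SAMPLE_SIGMA * sigma)
        if not deep_enough and run[0] >= 2:
            # a steep tether can put only one sample below threshold: accept
            # it when the two preceding samples already pull below -1 sigma
            # AND the force stays at baseline afterwards (terminal rupture,
            # not a noise dip on a shallow ramp)
            ramp = (f[run[0] - 1] < -sigma) and (f[run[0] - 2] < -sigma)
            post_stable = f[run[-1] + 1:run[-1] + 7]
            deep_enough = ramp and post_stable.size >= 4 \
                and float(post_stable.mean()) > -sigma
        if not deep_enough:
            continue
        j_min = int(run[0] + np.argmin(seg))
        end = int(run[-1])
        post = f[end + 1:end + 1 + RETURN_WINDOW]
        if post.size == 0 or not (post > -threshold_sigma * sigma).any():
            continue
        s = float(_separation(z[j_min:j_min + 1], f[j_min:j_min + 1],
                              z0, k_int)[0])
        if s < 0:
            continue
        # the true rupture lies within one sample past the minimum: linear
        # half-sample extrapolation along the pull removes the shortfall
        force = float(-f[j_min])
        if j_min > 0 and f[j_min - 1] > f[j_min]:
            force += 0.5 * float(f[j_min - 1] - f[j_min])
        out.append(RuptureCandidate(
            rupture_force=force,
            rupture_distance=s,
            index=j_min,
            start_index=int(run[0])))
    out.sort(key=lambda c: c.rupture_distance)
    # a shallow pull split by noise yields several runs for one event:
    # merge candidates closer than 8 nm, keeping the deepest
    merged: list[RuptureCandidate] = []
    for cand in out:
        if merged and cand.rupture_distance - merged[-1].rupture_distance < 8.0:
            if cand.rupture_force > merged[-1].rupture_force:
                cand.start_index = merged[-1].start_index
                merged[-1] = cand
            continue
        merged.append(cand)
    return merged


def _profiled_wlc_ls(x: np.ndarray, f_pull: np.ndarray, kbt: float,
                     lc_bounds: tuple[float, float],
                     lp_bounds: tuple[float, float],
                     n_grid: int = 96) -> tuple[float, float, float]:
    """Least squares over (Lp, Lc) by profiling: for each Lc on a grid the
    amplitude kBT/Lp is closed-form (clipped to the Lp bounds); the best Lc
    is refined parabolically. Returns (Lp, Lc, rms)."""
    lcs = np.linspace(lc_bounds[0], lc_bounds[1], n_grid)
    t = np.clip(x[None, :] / lcs[:, None], 0.0, 0.999)
    g = 0.25 / (1.0 - t) ** 2 - 0.25 + t
    gg = (g * g).sum(1)
    gf = (g * f_pull[None, :]).sum(1)
    a = gf / np.maximum(gg, 1e-300)
    a = np.clip(a, kbt / lp_bounds[1], kbt / lp_bounds[0])
    rss = float(f_pull @ f_pull) - 2 * a * gf + a * a * gg
    j = int(np.argmin(rss))
    # parabolic refinement between grid neighbours
    lc = float(lcs[j])
    if 0 < j < n_grid - 1:
        y0, y1, y2 = rss[j - 1], rss[j], rss[j + 1]
        denom = (y0 - 2 * y1 + y2)
        if denom > 0:
            lc += 0.5 * (y0 - y2) / denom * (lcs[1] - lcs[0])
            tt = np.clip(x / lc, 0.0, 0.999)
            gr = 0.25 / (1.0 - tt) ** 2 - 0.25 + tt
            ar = float((gr @ f_pull) / max(gr @ gr, 1e-300))
            ar = float(np.clip(ar, kbt / lp_bounds[1], kbt / lp_bounds[0]))
            rss_r = float(((f_pull - ar * gr) ** 2).sum())
            if rss_r <= rss[j]:
                return kbt / ar, lc, float(np.sqrt(rss_r / x.size))
    return float(kbt / a[j]), float(lcs[j]), float(np.sqrt(rss[j] / x.size))


def validate_wlc(curve: ForceCurve, candidate: RuptureCandidate,
                 noise: NoiseEstimate, z0: float,
                 lc_bounds: tuple[float, float] = DEFAULT_WLC_LC_BOUNDS_NM,
                 lp_bounds: tuple[float, float] = DEFAULT_WLC_LP_BOUNDS_NM,
                 prev_index: Optional[int] = None):
    """Fit the tether extension profile; return WLCParams or WLCRejection.

    The profile runs from the contact point (or from just past the
    preceding event, ``prev_index``) to the rupture minimum; acceptance
    needs >= 10 samples, fit RMS below 2 sigma and a contour length on the
    linker+protein scale.
    """
    z, f = curve.retract_z, curve.retract_f
    k_int = spring_constant_internal(curve.acquisition.spring_constant)
    kbt = thermal_energy(curve.acquisition.temperature)
    # pulling segment in stored order (pull deepens with index); a small
    # guard past the estimated contact absorbs contact-point error
    off = np.flatnonzero(z < z0 + 4.0)
    start = int(off[0]) if off.size else candidate.index
    if prev_index is not None:
        start = max(start, prev_index + 2)
    start = min(start, candidate.index)
    if candidate.index + 1 - start < MIN_WLC_SAMPLES:
        return WLCRejection("too short")
    seg = slice(start, candidate.index + 1)
    x = _separation(z[seg], f[seg], z0, k_int)
    pull = -f[seg]
    keep = (x > 0.2) & (pull > -2 * noise.sigma)
    if int(keep.sum()) < MIN_WLC_FIT_SAMPLES:
        return WLCRejection("too short")
    x, pull = x[keep], pull[keep]
    if (x >= lc_bounds[1]).any():
        return WLCRejection("extension beyond contour-length bound")
    lp, lc, rms = _profiled_wlc_ls(x, pull, kbt, lc_bounds, lp_bounds)
    if not np.isfinite(rms):
        return WLCRejection("fit did not converge")
    if rms >= 2.0 * noise.sigma:
        return WLCRejection("rms above 2 sigma", rms=rms, contour_length=lc)
    if not lc_bounds[0] <= lc <= lc_bounds[1]:
        return WLCRejection("contour length out of range",
                            rms=rms, contour_length=lc)
    if x.max() >= lc:
        return WLCRejection("extension exceeds contour length",
                            rms=rms, contour_length=lc)
    return WLCParams(persistence_length=lp, contour_length=lc,
                     thermal_energy=kbt, rms=rms)


def refine_rupture_force(curve: ForceCurve, candidate: RuptureCandidate,
                         wlc: WLCParams, z0: float) -> float:
    """Rupture-force estimate combining the sampled minimum with the tether
    model.

    The true rupture lies between the last sampled point of the pull and the
    next (post-rupture) sample; the accepted WLC fit evaluated half a sample
    beyond the minimum is averaged with the half-sample extrapolation of the
    raw samples, roughly halving the flip rate at classification thresholds.
    """
    z, f = curve.retract_z, curve.retract_f
    k_int = spring_constant_internal(curve.acquisition.spring_constant)
    dz = abs(float(np.median(np.diff(z))))
    z_r = z[candidate.index] - 0.5 * dz
    s = max(z0 - z_r, 0.0)
    cap = 0.985 * wlc.contour_length
    for _ in range(40):
        f_m = wlc_force(min(s, cap), wlc)
        s = 0.5 * s + 0.5 * max((z0 - z_r) - f_m / k_int, 0.0)
    f_model = float(wlc_force(min(s, cap), wlc))
    return 0.5 * (candidate.rupture_force + f_model)


def classify_specific(event: AdhesionEvent,
                      min_force: float = DEFAULT_SPECIFIC_MIN_FORCE_PN,
                      min_distance: float = DEFAULT_SPECIFIC_MIN_DISTANCE_NM
                      ) -> bool:
    """Specific iff force > min_force, distance > min_distance, WLC present."""
    return (event.rupture_force > min_force
            and event.rupture_distance > min_distance
            and event.wlc is not None)


def stratify_pixel(events: Sequence[AdhesionEvent],
                   cholesterol_min_force: float = DEFAULT_CHOLESTEROL_MIN_FORCE_PN,
                   nonadhesive_max_force: float = DEFAULT_NONADHESIVE_MAX_FORCE_PN
                   ) -> int:
    """Pixel stratum for the domain comparison.

    cholesterol: a specific event above 100 pN; non_adhesive: no candidate
    reaches 30 pN (or none at all); indeterminate otherwise (excluded from
    stratified statistics).
    """
    if not events:
        return STRATUM_NON_ADHESIVE
    specific_forces = [e.rupture_force for e in events if e.specific]
    if specific_forces and max(specific_forces) > cholesterol_min_force:
        return STRATUM_CHOLESTEROL
    if max(e.rupture_force for e in events) < nonadhesive_max_force:
        return STRATUM_NON_ADHESIVE
    return STRATUM_INDETERMINATE
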