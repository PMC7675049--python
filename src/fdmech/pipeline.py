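"""Per-curve and per-map orchestration.

``process_curve`` runs the full per-pixel chain: baseline correction, noise
estimation, contact-point location (iterated with a baseline refit on the
re-identified off-contact region, leaving a tether guard below contact),
depth-segmented elasticity, rupture detection, WLC validation, specificity
and stratum. ``process_map`` applies it across a grid and assembles the
derived channels; ``run_pipeline`` wraps a whole container-to-report run
with embedded provenance.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import __version__ as _pkg_version
from .adhesion import (classify_specific, detect_ruptures,
                       refine_rupture_force, stratify_pixel, validate_wlc)
from .contact import segmented_moduli
from .errors import ConfigError, InsufficientDataError
from .mapstats import assemble_maps, map_report
from .model import AdhesionEvent, ForceCurve, ForceVolumeMap
from .preprocess import (NoiseEstimate, fit_baseline, linefit_sigma,
                         locate_contact_array, to_indentation)
from .units import spring_constant_internal


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Defaults are the package's study conditions; every report embeds the
    full resolved config plus the package version.
    """

    # preprocess
    off_contact_fraction: float = 0.30
    contact_min_snr: float = 5.0
    fit_segment: str = "retract"
    contact_segments: str = "both"        # segments pooled for the z0 scan
    baseline_margin_nm: float = 15.0      # guard below contact for refits
    baseline_iterations: int = 1
    # contact mechanics
    pm_window_nm: float = 50.0
    cortex_window_nm: tuple = (50.0, 200.0)
    fit_method: str = "force"             # or "f23"
    bottom_effect: bool = False
    layer_thickness_nm: float = 50.0
    # adhesion events
    specific_min_force_pN: float = 80.0
    specific_min_distance_nm: float = 5.0
    cholesterol_min_force_pN: float = 100.0
    nonadhesive_max_force_pN: float = 30.0
    wlc_lc_bounds_nm: tuple = (5.0, 60.0)
    wlc_lp_bounds_nm: tuple = (0.1, 1.5)
    # map analysis
    connectivity: int = 8
    # stage toggles
    mechanics: bool = True
    events: bool = True
    # bookkeeping
    input: Optional[str] = None
    output: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.off_contact_fraction <= 0.9:
            raise ConfigError("off_contact_fraction must be in (0, 0.9]")
        if self.fit_segment not in ("retract", "approach"):
            raise ConfigError("fit_segment must be 'retract' or 'approach'")
        if self.contact_segments not in ("both", "retract", "approach"):
            raise ConfigError(
                "contact_segments must be 'both', 'retract' or 'approach'")
        if self.fit_method not in ("force", "f23"):
            raise ConfigError("fit_method must be 'force' or 'f23'")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in data:
            if key not in known:
                raise ConfigError(f"unknown config key {key!r}")
        data = dict(data)
        for key in ("cortex_window_nm", "wlc_lc_bounds_nm", "wlc_lp_bounds_nm"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a flat key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, val in out.items():
            if isinstance(val, tuple):
                out[key] = list(val)
        return out


def _refit_segment(z, f_raw, f_corr, k_int, z0, margin, frac):
    """Refit the drift polynomial on the off-contact region implied by the
    current contact estimate, rejecting tether pulls (strongly negative
    excursions) from the fit. Returns (f_corr, mask) or None."""
    w = z - f_corr / k_int
    mask = w < z0 - margin
    if int(mask.sum()) < 16:
        return None
    bl = fit_baseline(z, f_raw, frac, mask=mask)
    resid = f_raw[mask] - bl(z[mask])
    sigma_rob = max(
        1.4826 * float(np.median(np.abs(resid - np.median(resid)))), 1e-9)
    # a tether pull sits just below contact: push the baseline region below
    # its full extent (runs of >=2 below-threshold samples within 80 nm of
    # contact), then reject any remaining negative outliers
    dip = np.flatnonzero((f_corr < -3.0 * sigma_rob)
                         & (w < z0) & (w > z0 - 80.0))
    dip = dip[np.isin(dip, np.concatenate([dip + 1, dip - 1]))]
    if dip.size:
        cut = float(w[dip].min()) - 8.0
        shrunk = mask & (w < cut)
        if int(shrunk.sum()) >= 16:
            mask = shrunk
            bl = fit_baseline(z, f_raw, frac, mask=mask)
            resid = f_raw[mask] - bl(z[mask])
    keep = np.zeros_like(mask)
    keep[mask] = resid > -3.0 * sigma_rob
    n_keep = int(keep.sum())
    if n_keep >= 16 and n_keep < int(mask.sum()):
        bl = fit_baseline(z, f_raw, frac, mask=keep)
        mask = keep
    return f_raw - bl(z), mask


def _iterated_contact(curve: ForceCurve, config: RunConfig):
    """Baseline-corrected fit-segment force, noise and contact point.

    Returns (f_corrected, noise, z0) with z0 None on a no-contact pixel.
    The baseline is refit on the full off-contact region identified by the
    current contact estimate, because the initial fractional region
    under-spans the drift polynomial. With ``contact_segments="both"`` the
    approach and retract are pooled in the contact scan (they share the
    contact point; the approach carries no adhesion features).
    """
    frac = config.off_contact_fraction
    k_int = spring_constant_internal(curve.acquisition.spring_constant)
    if config.contact_segments == "both":
        scan_names = ["retract", "approach"]
    else:
        scan_names = [config.contact_segments]
    corr_names = list(dict.fromkeys([config.fit_segment] + scan_names))
    segs = {}
    for name in corr_names:
        z, f_raw = curve.segment(name)
        bl = fit_baseline(z, f_raw, frac)
        segs[name] = [z, f_raw, f_raw - bl(z)]
    fit_name = config.fit_segment

    def _noise() -> NoiseEstimate:
        z, _, f = segs[fit_name]
        n_off = int(round(len(z) * frac))
        mask = z <= np.partition(z, n_off - 1)[n_off - 1]
        return NoiseEstimate(linefit_sigma(z[mask], f[mask]), int(mask.sum()))

    def _scan(sigma: float, window=None):
        z_all = np.concatenate([segs[n][0] for n in scan_names])
        f_all = np.concatenate([segs[n][2] for n in scan_names])
        step = 2.0
        return locate_contact_array(z_all, f_all, sigma, k_int,
                                    min_snr=config.contact_min_snr,
                                    coarse_step=step, window=window)

    noise = _noise()
    z0 = _scan(noise.sigma)
    if z0 is None:
        return segs[fit_name][2], noise, None
    for _ in range(config.baseline_iterations):
        n_mask = None
        for name in corr_names:
            z, f_raw, f_corr = segs[name]
            out = _refit_segment(z, f_raw, f_corr, k_int, z0,
                                 config.baseline_margin_nm, frac)
            if out is None:
                continue
            segs[name][2] = out[0]
            if name == fit_name:
                n_mask = out[1]
        if n_mask is None:
            break
        z, _, f = segs[fit_name]
        sigma = float(np.std(f[n_mask], ddof=3))
        noise = NoiseEstimate(sigma, int(n_mask.sum()))
        z0_new = _scan(sigma, window=(z0 - 60.0, z0 + 60.0))
        if z0_new is None:
            return segs[fit_name][2], noise, None
        converged = abs(z0_new - z0) < 0.5
        z0 = z0_new
        if converged:
            break
    return segs[fit_name][2], noise, z0


def process_curve(curve: ForceCurve, config: Optional[RunConfig] = None) -> dict:
    """Full per-pixel analysis; returns a result mapping for assembly."""
    config = config or RunConfig()
    f_corr, noise, z0 = _iterated_contact(curve, config)
    result: dict = {"noise_sigma": noise.sigma}
    if z0 is None:
        result["status"] = "no_contact"
        return result
    result["status"] = "ok"
    result["height"] = z0
    corrected = curve.with_retract_force(f_corr) \
        if config.fit_segment == "retract" else curve.with_approach_force(f_corr)
    acq = curve.acquisition
    if config.mechanics:
        ind = to_indentation(corrected, z0, acq.spring_constant,
                             segment=config.fit_segment)
        try:
            fit = segmented_moduli(
                ind, acq.tip_radius, acq.poisson_ratio,
                pm_window=(0.0, config.pm_window_nm),
                cortex_window=tuple(config.cortex_window_nm),
                method=config.fit_method,
                bottom_effect=config.bottom_effect,
                layer_thickness=config.layer_thickness_nm)
            result["e_pm"] = fit.e_pm
            result["e_cortex"] = fit.e_cortex
            result["mechanics_fit"] = fit
        except InsufficientDataError:
            pass
    if config.events:
        cands = detect_ruptures(corrected, noise, z0)
        events = []
        prev_index = None
        for cand in cands:
            wlc = validate_wlc(corrected, cand, noise, z0,
                               lc_bounds=tuple(config.wlc_lc_bounds_nm),
                               lp_bounds=tuple(config.wlc_lp_bounds_nm),
                               prev_index=prev_index)
            prev_index = cand.index
            ok = not hasattr(wlc, "reason")
            force = refine_rupture_force(corrected, cand, wlc, z0) \
                if ok else cand.rupture_force
            ev = AdhesionEvent(
                rupture_force=force,
                rupture_distance=cand.rupture_distance,
                wlc=wlc if ok else None,
                specific=False, row=curve.row, col=curve.col)
            ev.specific = classify_specific(
                ev, min_force=config.specific_min_force_pN,
                min_distance=config.specific_min_distance_nm)
            events.append(ev)
        result["events"] = events
        specific = [e for e in events if e.specific]
        if specific:
            # the last rupture (largest distance) defines the adhesion channel
            result["adhesion_force"] = specific[-1].rupture_force
        result["stratum"] = stratify_pixel(
            events,
            cholesterol_min_force=config.cholesterol_min_force_pN,
            nonadhesive_max_force=config.nonadhesive_max_force_pN)
    return result


def process_map(fv: ForceVolumeMap,
                config: Optional[RunConfig] = None) -> ForceVolumeMap:
    """Run :func:`process_curve` on every pixel and assemble channels."""
    config = config or RunConfig()
    results = {}
    for r, c in fv.iter_pixels():
        res = process_curve(fv.curve(r, c), config)
        if res.get("status") == "ok":
            results[(r, c)] = res
    return assemble_maps(fv, results)


def run_pipeline(config: RunConfig) -> dict:
    """Container in, report out; raises on any stage error.

    The report embeds the resolved config and the package version so a run
    can be regenerated bit-identically from the report plus the input
    container.
    """
    from .io import read_dataset, write_dataset
    if config.input is None:
        raise ConfigError("config key 'input' is required")
    fv = read_dataset(config.input)
    fv = process_map(fv, config)
    report = {
        "package": {"name": "fdmech", "version": _pkg_version},
        "config": config.to_dict(),
        "mapstats": map_report(fv, connectivity=config.connectivity),
        "warnings": [],
    }
    if config.output:
        write_dataset(fv, config.output)
        report["output"] = config.output
    return report


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
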