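"""Map-level assembly and statistics.

Once every pixel has been processed, the per-pixel results are assembled
into co-registered channels (height, membrane and cortex moduli, adhesion
force, specificity, stratum). The map-level quantities mirror the adhesion
analysis of toxin-derivatized-tip experiments: binding probability as the
percentage of analyzed pixels carrying a specific unbinding event, domain
sizes as connected components of the specific mask, and the membrane
modulus stratified by cholesterol vs non-adhesive pixels.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats as sstats
from skimage import measure

from .errors import DomainError, ParameterError
from .model import (ForceVolumeMap, STRATUM_CHOLESTEROL, STRATUM_NON_ADHESIVE,
                    STRATUM_UNASSIGNED)

#: fraction trimmed from EACH tail when summarising a modulus channel;
#: per-pixel membrane fits have a heavy right tail from contact-point
#: misses, so the trimmed mean is the map-level location estimate.
DEFAULT_TRIM_FRACTION = 0.10


@dataclass
class DomainSet:
    """Connected components of the specific mask."""

    sizes_px: np.ndarray          # pixels per component, descending
    areas_nm2: np.ndarray         # sizes * pixel_size^2
    labels: np.ndarray            # 0 = background
    connectivity: int             # 4 or 8

    @property
    def n_domains(self) -> int:
        return int(self.sizes_px.size)


def binding_probability(fv: ForceVolumeMap) -> float:
    """Percentage of analyzed pixels covered by specific unbinding events.

    Analyzed pixels are those with a usable curve (contact found); they form
    the denominator. Raises :class:`DomainError` when nothing was analyzed.
    """
    if fv.specific_mask is None:
        raise DomainError("specific mask not computed")
    analyzed = _analyzed_mask(fv)
    n = int(analyzed.sum())
    if n == 0:
        raise DomainError("no analyzed pixels: binding probability undefined")
    return 100.0 * float(fv.specific_mask[analyzed].sum()) / n


def _analyzed_mask(fv: ForceVolumeMap) -> np.ndarray:
    if "height" in fv.channels:
        return np.isfinite(fv.channels["height"])
    return np.ones(fv.shape, dtype=bool)


def domain_sizes(fv: ForceVolumeMap, connectivity: int = 8) -> DomainSet:
    """Connected components of the specific mask (8-connectivity default:
    irregular domains should not be split at diagonal contacts)."""
    if fv.specific_mask is None:
        raise DomainError("specific mask not computed")
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    conn = 2 if connectivity == 8 else 1
    labels = measure.label(fv.specific_mask, connectivity=conn)
    sizes = np.bincount(labels.ravel())[1:] if labels.max() > 0 \
        else np.array([], dtype=int)
    order = np.argsort(sizes)[::-1]
    sizes = sizes[order]
    px = fv.acquisition.pixel_size
    return DomainSet(sizes_px=sizes.astype(int),
                     areas_nm2=sizes.astype(float) * px * px,
                     labels=labels, connectivity=connectivity)


def stratified_pm_elasticity(fv: ForceVolumeMap
                             ) -> dict[str, np.ndarray]:
    """Membrane-modulus values grouped by pixel stratum.

    Returns {"cholesterol": values, "non_adhesive": values}; indeterminate
    pixels are excluded. Either set may be empty (comparison then skipped
    downstream).
    """
    if fv.stratum is None:
        raise DomainError("strata not computed")
    if "e_pm" not in fv.channels:
        raise DomainError("e_pm channel not computed")
    e = fv.channels["e_pm"]
    out = {}
    for name, code in (("cholesterol", STRATUM_CHOLESTEROL),
                       ("non_adhesive", STRATUM_NON_ADHESIVE)):
        vals = e[(fv.stratum == code) & np.isfinite(e)]
        out[name] = np.sort(vals)
    return out


def channel_summary(fv: ForceVolumeMap, name: str,
                    trim: float = DEFAULT_TRIM_FRACTION) -> dict:
    """Robust location/scale summary of a channel over analyzed pixels."""
    vals = fv.channel(name)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return {"n": 0, "mean": None, "sd": None}
    return {"n": int(vals.size),
            "mean": float(sstats.trim_mean(vals, trim)),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "median": float(np.median(vals))}


def percent_change(before: float, after: float) -> float:
    """Percentage decrease from before to after: 100*(before-after)/before."""
    if before <= 0:
        raise DomainError(f"before must be > 0, got {before}")
    return 100.0 * (before - after) / before


def fold_change(a: float, b: float) -> float:
    """Ratio a/b."""
    if b <= 0:
        raise DomainError(f"denominator must be > 0, got {b}")
    return a / b


def assemble_maps(fv: ForceVolumeMap, pixel_results: dict) -> ForceVolumeMap:
    """Populate channels/masks/events from per-pixel results.

    ``pixel_results`` maps (row, col) to a mapping with optional keys
    ``height`` (contact z0), ``e_pm``, ``e_cortex``, ``adhesion_force``,
    ``events`` (list of AdhesionEvent), ``stratum``. Pixels without contact
    stay NaN/unassigned in every derived channel.
    """
    rows, cols = fv.shape
    for k in ("height", "e_pm", "e_cortex", "adhesion_force"):
        fv.channels.setdefault(k, np.full((rows, cols), np.nan))
    fv.specific_mask = np.zeros((rows, cols), dtype=bool)
    fv.stratum = np.full((rows, cols), STRATUM_UNASSIGNED, dtype=np.int8)
    fv.events = []
    for (r, c), res in pixel_results.items():
        if not (0 <= r < rows and 0 <= c < cols):
            raise ParameterError(f"pixel {(r, c)} outside grid {fv.shape}")
        for key in ("height", "e_pm", "e_cortex", "adhesion_force"):
            val = res.get(key)
            if val is not None:
                fv.channels[key][r, c] = val
        for ev in res.get("events", ()):
            fv.events.append(ev)
            if ev.specific:
                fv.specific_mask[r, c] = True
        if res.get("stratum") is not None:
            fv.stratum[r, c] = res["stratum"]
    return fv


def map_report(fv: ForceVolumeMap, connectivity: int = 8) -> dict:
    """JSON-ready map statistics: binding probability, domain-size
    histogram, stratum summaries."""
    report: dict = {"grid": list(fv.shape)}
    analyzed = _analyzed_mask(fv)
    report["n_analyzed"] = int(analyzed.sum())
    if fv.specific_mask is not None:
        report["binding_probability_pct"] = binding_probability(fv)
        ds = domain_sizes(fv, connectivity=connectivity)
        report["n_domains"] = ds.n_domains
        report["domain_sizes_px"] = ds.sizes_px.tolist()
        report["connectivity"] = connectivity
    for name in ("e_pm", "e_cortex", "adhesion_force"):
        if name in fv.channels:
            report[f"{name}_summary"] = channel_summary(fv, name)
    if fv.stratum is not None and "e_pm" in fv.channels:
        strata = stratified_pm_elasticity(fv)
        report["strata"] = {
            name: {"n": int(v.size),
                   "mean": float(sstats.trim_mean(v, DEFAULT_TRIM_FRACTION))
                   if v.size else None,
                   "sd": float(v.std(ddof=1)) if v.size > 1 else None}
            for name, v in strata.items()}
    return report
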