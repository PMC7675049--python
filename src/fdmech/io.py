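"""Container I/O for force-volume maps.

One map = one HDF5 file (see ``docs/format.md``):

    /                     attrs: format_version
    /acquisition          attrs: spring_constant, tip_radius, poisson_ratio,
                                 setpoint_force, pixel_size, temperature
    /curves/approach_z    float64 (rows, cols, n)   [nm]
    /curves/approach_f    float64 (rows, cols, n)   [pN]
    /curves/retract_z     float64 (rows, cols, n)
    /curves/retract_f     float64 (rows, cols, n)
    /channels/<name>      float64 (rows, cols), NaN = absent pixel
    /masks/specific       uint8   (rows, cols)      optional
    /masks/stratum        int8    (rows, cols)      optional
    /events/<column>      per-event columns         optional
    /truth/...            synthetic ground truth    optional

Writes are byte-deterministic: attributes are written in sorted order,
datasets carry no timestamps, and dataset creation order is fixed.
"""
from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelError, SchemaError
from .model import (AcquisitionParams, AdhesionEvent, ForceVolumeMap,
                    SyntheticScene, WLCParams)

FORMAT_VERSION = "1.0"

_ACQ_FIELDS = ("pixel_size", "poisson_ratio", "setpoint_force",
               "spring_constant", "temperature", "tip_radius")
_CURVE_SETS = ("approach_f", "approach_z", "retract_f", "retract_z")
_EVENT_COLUMNS = ("row", "col", "rupture_force_pN", "rupture_distance_nm",
                  "Lc_nm", "Lp_nm", "rms_pN", "specific")


def _h5py():
    import h5py
    return h5py


def _dset(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def _events_frame(events: list) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "row": ev.row, "col": ev.col,
            "rupture_force_pN": ev.rupture_force,
            "rupture_distance_nm": ev.rupture_distance,
            "Lc_nm": ev.wlc.contour_length if ev.wlc else np.nan,
            "Lp_nm": ev.wlc.persistence_length if ev.wlc else np.nan,
            "rms_pN": ev.wlc.rms if ev.wlc else np.nan,
            "specific": bool(ev.specific),
        })
    return pd.DataFrame(rows, columns=list(_EVENT_COLUMNS))


def _events_from_frame(df: pd.DataFrame, thermal_energy: float) -> list:
    out = []
    for rec in df.itertuples(index=False):
        wlc = None
        if np.isfinite(rec.Lc_nm):
            wlc = WLCParams(persistence_length=float(rec.Lp_nm),
                            contour_length=float(rec.Lc_nm),
                            thermal_energy=thermal_energy,
                            rms=float(rec.rms_pN))
        out.append(AdhesionEvent(
            rupture_force=float(rec.rupture_force_pN),
            rupture_distance=float(rec.rupture_distance_nm),
            wlc=wlc, specific=bool(rec.specific),
            row=int(rec.row), col=int(rec.col)))
    return out


def write_dataset(fv: ForceVolumeMap, path: str) -> None:
    """Write a map (curves, metadata, channels, events, ground truth)."""
    h5py = _h5py()
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        acq = f.create_group("acquisition")
        for name in _ACQ_FIELDS:
            acq.attrs[name] = float(getattr(fv.acquisition, name))
        curves = f.create_group("curves")
        for name in _CURVE_SETS:
            _dset(curves, name, getattr(fv, name))
        if fv.channels:
            ch = f.create_group("channels")
            for name in sorted(fv.channels):
                _dset(ch, name, fv.channels[name])
        if fv.specific_mask is not None or fv.stratum is not None:
            masks = f.create_group("masks")
            if fv.specific_mask is not None:
                _dset(masks, "specific", fv.specific_mask.astype(np.uint8))
            if fv.stratum is not None:
                _dset(masks, "stratum", fv.stratum.astype(np.int8))
        if fv.events:
            ev = f.create_group("events")
            df = _events_frame(fv.events)
            for colname in _EVENT_COLUMNS:
                col = df[colname].to_numpy()
                if colname in ("row", "col"):
                    col = col.astype(np.int64)
                elif colname == "specific":
                    col = col.astype(np.uint8)
                else:
                    col = col.astype(np.float64)
                _dset(ev, colname, col)
        if fv.scene is not None:
            sc = fv.scene
            tr = f.create_group("truth")
            _dset(tr, "e_pm_true", sc.e_pm_true)
            _dset(tr, "e_cortex_true", sc.e_cortex_true)
            _dset(tr, "domain_mask", sc.domain_mask.astype(np.uint8))
            if sc.height_true is not None:
                _dset(tr, "height_true", sc.height_true)
            for name, val in sorted({
                    "p_bind": sc.p_bind, "rupture_mean": sc.rupture_mean,
                    "rupture_sd": sc.rupture_sd, "noise_sd": sc.noise_sd,
                    "drift_c0": sc.drift_coeffs[0],
                    "drift_c1": sc.drift_coeffs[1],
                    "drift_c2": sc.drift_coeffs[2],
                    "seed": sc.seed}.items()):
                tr.attrs[name] = val
            if sc.events:
                keys = sorted(sc.events)
                arr = np.array(
                    [[r, c, *sc.events[(r, c)]] for r, c in keys], dtype=float)
                _dset(tr, "events", arr)


def read_dataset(path: str) -> ForceVolumeMap:
    """Read a container written by :func:`write_dataset`.

    Raises :class:`SchemaError` naming the offending field on malformed
    input; curves round-trip bit-exactly.
    """
    h5py = _h5py()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "format_version" not in f.attrs:
            raise SchemaError("missing root attribute 'format_version'")
        if "acquisition" not in f:
            raise SchemaError("missing group '/acquisition'")
        acq_kwargs = {}
        for name in _ACQ_FIELDS:
            if name not in f["acquisition"].attrs:
                raise SchemaError(f"missing acquisition attribute {name!r}")
            acq_kwargs[name] = float(f["acquisition"].attrs[name])
        acq = AcquisitionParams(**acq_kwargs)
        if "curves" not in f:
            raise SchemaError("missing group '/curves'")
        curve_arrays = {}
        for name in _CURVE_SETS:
            if name not in f["curves"]:
                raise SchemaError(f"missing dataset '/curves/{name}'")
            arr = f["curves"][name][...]
            if arr.ndim != 3:
                raise SchemaError(f"'/curves/{name}' must be 3-D (rows, cols, n)")
            curve_arrays[name] = arr
        channels = {}
        if "channels" in f:
            for name in f["channels"]:
                channels[name] = f["channels"][name][...]
        specific = stratum = None
        if "masks" in f:
            if "specific" in f["masks"]:
                specific = f["masks"]["specific"][...].astype(bool)
            if "stratum" in f["masks"]:
                stratum = f["masks"]["stratum"][...].astype(np.int8)
        events: list = []
        if "events" in f:
            data = {}
            for colname in _EVENT_COLUMNS:
                if colname not in f["events"]:
                    raise SchemaError(f"missing dataset '/events/{colname}'")
                data[colname] = f["events"][colname][...]
            from .units import thermal_energy
            events = _events_from_frame(pd.DataFrame(data),
                                        thermal_energy(acq.temperature))
        scene: Optional[SyntheticScene] = None
        if "truth" in f:
            tr = f["truth"]
            for name in ("e_pm_true", "e_cortex_true", "domain_mask"):
                if name not in tr:
                    raise SchemaError(f"missing dataset '/truth/{name}'")
            ev_dict = {}
            if "events" in tr:
                for rec in tr["events"][...]:
                    ev_dict[(int(rec[0]), int(rec[1]))] = tuple(rec[2:])
            scene = SyntheticScene(
                e_pm_true=tr["e_pm_true"][...],
                e_cortex_true=tr["e_cortex_true"][...],
                domain_mask=tr["domain_mask"][...].astype(bool),
                p_bind=float(tr.attrs["p_bind"]),
                rupture_mean=float(tr.attrs["rupture_mean"]),
                rupture_sd=float(tr.attrs["rupture_sd"]),
                noise_sd=float(tr.attrs["noise_sd"]),
                drift_coeffs=(float(tr.attrs["drift_c0"]),
                              float(tr.attrs["drift_c1"]),
                              float(tr.attrs["drift_c2"])),
                seed=int(tr.attrs["seed"]),
                events=ev_dict,
                height_true=tr["height_true"][...]
                if "height_true" in tr else None)
    return ForceVolumeMap(acquisition=acq, channels=channels,
                          specific_mask=specific, stratum=stratum,
                          events=events, scene=scene, **curve_arrays)


def export_channels(fv: ForceVolumeMap, directory: str,
                    channels: Optional[list] = None) -> dict:
    """Export derived channels as 32-bit float TIFF + CSV, events as CSV.

    Returns a dict of written paths. Raises :class:`ChannelError` if a
    requested channel has not been computed.
    """
    os.makedirs(directory, exist_ok=True)
    written = {}
    names = channels if channels is not None else sorted(fv.channels)
    for name in names:
        if name == "specific":
            if fv.specific_mask is None:
                raise ChannelError("channel 'specific' not computed")
            grid = fv.specific_mask.astype(np.float64)
        elif name in fv.channels:
            grid = fv.channels[name]
        else:
            raise ChannelError(f"channel {name!r} not computed")
        tiff_path = os.path.join(directory, f"{name}.tiff")
        csv_path = os.path.join(directory, f"{name}.csv")
        tifffile.imwrite(tiff_path, grid.astype(np.float32))
        np.savetxt(csv_path, grid, delimiter=",", fmt="%.17g")
        written[name] = (tiff_path, csv_path)
    events_path = os.path.join(directory, "events.csv")
    _events_frame(fv.events).to_csv(events_path, index=False)
    written["events"] = events_path
    return written
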