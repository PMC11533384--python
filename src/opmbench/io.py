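"""Raw-recording container (HDF5) and stat-image / table exports.

Container layout::

    /data      (n_channels, n_samples) float64, tesla
    /fs        scalar
    /triggers  (n_events,) compound: sample (i8), code (i8)
    /trigger_labels  variable-length strings
    /channels  positions, orientations, names (sensor-major, x/y/z)
    /meta      JSON blob: sensor state, geometry parameters, provenance

Stat images are exported as 4-mm isotropic NIfTI volumes (head frame in
mm, origin at the sphere centre) plus a JSON peak report; optional export
of raw data to the standard FIF MEG format goes through ``mne``.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .array_geometry import Sensor, SensorArray
from .opm_sensor import SensorState
from .synthetic_data import RawRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_stat_image",
    "to_mne_raw",
]


def write_recording(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f["fs"] = float(rec.fs)
        f.create_dataset("triggers", data=rec.triggers)
        str_dt = h5py.string_dtype()
        f.create_dataset("trigger_labels", data=rec.trigger_labels, dtype=str_dt)
        ch = f.create_group("channels")
        ch.create_dataset("positions", data=rec.array.positions)
        ch.create_dataset("orientations", data=rec.array.axes)
        ch.create_dataset("names", data=rec.array.channel_names(), dtype=str_dt)
        meta = {
            "sensor_state": vars(rec.sensor_state).copy(),
            "head_radius": rec.array.head_radius,
            "standoff": rec.array.standoff,
            "array_seed": rec.array.seed,
            "provenance": rec.provenance,
        }
        f["meta"] = json.dumps(meta)
        if rec.saturated is not None:
            f.create_dataset("saturated", data=rec.saturated)


def read_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f["fs"][()])
        triggers = f["triggers"][()]
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["trigger_labels"][()]]
        pos = f["channels/positions"][()]
        ori = f["channels/orientations"][()]
        meta = json.loads(f["meta"][()])
        saturated = f["saturated"][()] if "saturated" in f else None
    sensors = tuple(
        Sensor(id=k, position=pos[k], axes=ori[k]) for k in range(len(pos))
    )
    array = SensorArray(
        sensors=sensors,
        head_radius=meta["head_radius"],
        standoff=meta["standoff"],
        seed=meta["array_seed"],
    )
    return RawRecording(
        data=data,
        fs=fs,
        triggers=triggers,
        trigger_labels=labels,
        array=array,
        sensor_state=SensorState(**meta["sensor_state"]),
        provenance=meta["provenance"],
        saturated=saturated,
    )


def write_stat_image(image, path, json_path=None) -> None:
    """Export a StatImage to NIfTI on its regular grid (mm, origin-centred).

    Off-grid (invalid) voxels are written as NaN.
    """
    import nibabel as nib

    grid = image.grid
    spacing_mm = grid.spacing * 1000.0
    pts_mm = grid.points * 1000.0
    mins = pts_mm.min(axis=0)
    idx = np.round((pts_mm - mins) / spacing_mm).astype(int)
    shape = idx.max(axis=0) + 1
    vol = np.full(shape, np.nan)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = image.values
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[:3, 3] = mins
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    if json_path is not None:
        loc, val = image.peak
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "kind": image.kind,
                    "peak_location_mm": (np.asarray(loc) * 1000.0).tolist(),
                    "peak_value": float(val),
                },
                fh,
                indent=2,
            )


def to_mne_raw(rec: RawRecording):
    """Convert to an ``mne.io.Raw`` for FIF interoperability.

    Channels are exported as magnetometers with their head-frame positions
    and sensitive orientations; triggers become a stim channel.
    """
    import mne

    names = rec.array.channel_names()
    info = mne.create_info(names + ["STI101"], sfreq=rec.fs, ch_types=["mag"] * len(names) + ["stim"])
    orient = rec.array.axes.reshape(rec.n_channels, 3)
    pos = rec.array.channel_positions()
    for k, ch in enumerate(info["chs"][:-1]):
        loc = np.zeros(12)
        loc[:3] = pos[k]
        # columns of the coil frame: ex, ey, ez with ez = sensitive axis
        ez = orient[k]
        ref = np.array([0.0, 0.0, 1.0]) if abs(ez[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        ex = np.cross(ref, ez)
        ex /= np.linalg.norm(ex)
        loc[3:6], loc[6:9], loc[9:12] = ex, np.cross(ez, ex), ez
        ch["loc"] = loc
    stim = np.zeros((1, rec.n_samples))
    stim[0, rec.triggers["sample"]] = rec.triggers["code"]
    return mne.io.RawArray(np.vstack([rec.data, stim]), info, verbose="error")
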