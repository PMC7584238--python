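"""Container I/O: HDF5 RF volumes with masks, CSV feature tables, map exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from qustex.glcm_texture import FeatureVector, feature_names
from qustex.parametric_maps import ParametricMap
from qustex.phantom_sim import ReferencePhantom, RFVolume
from qustex.response_model import CohortTable


def write_rf_h5(
    path: str | Path, rf: RFVolume, masks: list[np.ndarray] | None = None,
    label: str | None = None,
) -> None:
    """Write an RF volume (and optional per-frame ROI masks) to HDF5.

    Layout: /frames (n_frames, n_samples, n_lines) float64, /masks bool with
    the same shape, acquisition geometry as root attributes.
    """
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=np.stack(rf.frames))
        if masks is not None:
            h5.create_dataset("masks", data=np.stack(masks).astype(bool))
        h5.attrs["sampling_frequency"] = rf.sampling_frequency
        h5.attrs["line_spacing"] = rf.line_spacing
        h5.attrs["speed_of_sound"] = rf.speed_of_sound
        h5.attrs["frame_spacing"] = rf.frame_spacing
        if label is not None:
            h5.attrs["label"] = label


def read_rf_h5(path: str | Path) -> tuple[RFVolume, list[np.ndarray] | None, str | None]:
    try:
        with h5py.File(path, "r") as h5:
            frames = [np.asarray(f) for f in h5["frames"]]
            masks = None
            if "masks" in h5:
                masks = [np.asarray(m, dtype=bool) for m in h5["masks"]]
            rf = RFVolume(
                frames=frames,
                sampling_frequency=float(h5.attrs["sampling_frequency"]),
                line_spacing=float(h5.attrs["line_spacing"]),
                speed_of_sound=float(h5.attrs["speed_of_sound"]),
                frame_spacing=float(h5.attrs["frame_spacing"]),
            )
            label = str(h5.attrs["label"]) if "label" in h5.attrs else None
        return rf, masks, label
    except (OSError, KeyError) as exc:
        raise ValueError(f"unreadable RF container {path}: {exc}") from exc


def write_reference_h5(path: str | Path, reference: ReferencePhantom) -> None:
    write_rf_h5(path, reference.rf)
    with h5py.File(path, "a") as h5:
        h5.create_dataset("bsc_frequencies", data=reference.bsc_frequencies)
        h5.create_dataset("bsc_values", data=reference.bsc_values)
        h5.attrs["attenuation"] = reference.attenuation


def read_reference_h5(path: str | Path) -> ReferencePhantom:
    rf, _, _ = read_rf_h5(path)
    with h5py.File(path, "r") as h5:
        freqs = np.asarray(h5["bsc_frequencies"])
        bsc = np.asarray(h5["bsc_values"])
        att = float(h5.attrs.get("attenuation", 0.0))
    return ReferencePhantom(rf=rf, bsc_frequencies=freqs, bsc_values=bsc, attenuation=att)


def write_feature_table(
    path: str | Path, rows: list[tuple[str, str, FeatureVector]]
) -> pd.DataFrame:
    """One row per patient: id, label, then the 105 canonical feature columns.

    Comma-separated, UTF-8, '.' decimal, missing values as empty cells.
    """
    records = []
    for pid, label, fv in rows:
        rec = {"id": pid, "label": label}
        rec.update(fv.values)
        records.append(rec)
    df = pd.DataFrame(records, columns=["id", "label"] + feature_names())
    df.to_csv(path, index=False)
    return df


def read_feature_table(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path))


def export_map_csv(path: str | Path, pmap: ParametricMap) -> None:
    """Per-frame map matrix as CSV plus a JSON sidecar with geometry/units."""
    path = Path(path)
    np.savetxt(path, pmap.values, delimiter=",", fmt="%.8g")
    sidecar = {
        "name": pmap.name,
        "units": pmap.units,
        "pixel_spacing_mm": {"axial": pmap.geometry[0], "lateral": pmap.geometry[1]},
        "shape": list(pmap.values.shape),
        "missing": "nan",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
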