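"""Tactile recording containers and standard-format IO.

A :class:`TactileRecording` is a time-ordered stack of 2D pressure frames
(time x rows x cols, ADC counts) with a boolean sensor mask marking the
physically present taxels, a sampling rate, and free-form string metadata.

Canonical on-disk format is HDF5 (datasets ``frames`` and ``sensor_mask``;
root attributes ``sampling_rate`` and ``bit_depth``; metadata under the
``metadata`` group's attributes).  MAT containers are accepted because the
source grasping dataset ships in that form; ``npz`` and a CSV stack with a
JSON sidecar are provided as plain-array alternatives.

Conventions: 0-based indices, time is always the first axis, frames are
row-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import scipy.io

from .errors import ValidationError

FORMATS = ("hdf5", "mat", "npz", "csv-stack")

_EXTENSIONS = {
    ".h5": "hdf5",
    ".hdf5": "hdf5",
    ".mat": "mat",
    ".npz": "npz",
    ".csv": "csv-stack",
}


@dataclass
class TactileRecording:
    """One tactile recording: pressure frames plus sensor mask and metadata.

    Parameters
    ----------
    frames
        3D array, shape (time, rows, cols), pressure in ADC counts.
        Integer dtype for raw sensor data; float after denoising.
    sensor_mask
        Boolean (rows, cols) array; True where a physical sensor exists.
    sampling_rate
        Frame rate in Hz.
    bit_depth
        ADC resolution in bits; raw integer data must lie in
        [0, 2**bit_depth - 1].
    metadata
        Free-form string-to-string map (object label, trial id, provenance).
    """

    frames: np.ndarray
    sensor_mask: np.ndarray
    sampling_rate: float
    bit_depth: int = 10
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.sensor_mask = np.asarray(self.sensor_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.frames.ndim != 3 or self.frames.size == 0:
            raise ValidationError(
                f"frames: expected non-empty 3D (time, rows, cols) array, "
                f"got shape {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("frames: contains non-finite values")
        if self.sensor_mask.shape != self.frames.shape[1:]:
            raise ValidationError(
                f"sensor_mask: shape {self.sensor_mask.shape} does not match "
                f"frame shape {self.frames.shape[1:]}"
            )
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate: must be positive")
        if not 1 <= int(self.bit_depth) <= 32:
            raise ValidationError("bit_depth: must be in [1, 32]")
        if np.issubdtype(self.frames.dtype, np.integer):
            lo, hi = self.frames.min(), self.frames.max()
            if lo < 0 or hi > 2**self.bit_depth - 1:
                raise ValidationError(
                    f"frames: raw integer values [{lo}, {hi}] exceed the "
                    f"{self.bit_depth}-bit range [0, {2**self.bit_depth - 1}]"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sampling_rate

    def copy_with(self, **changes) -> "TactileRecording":
        fields = dict(
            frames=self.frames,
            sensor_mask=self.sensor_mask,
            sampling_rate=self.sampling_rate,
            bit_depth=self.bit_depth,
            metadata=dict(self.metadata),
        )
        fields.update(changes)
        return TactileRecording(**fields)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in FORMATS:
            raise ValidationError(f"format: unknown format {format!r}; expected one of {FORMATS}")
        return format
    try:
        return _EXTENSIONS[path.suffix.lower()]
    except KeyError:
        raise ValidationError(
            f"format: cannot infer container format from suffix {path.suffix!r}"
        ) from None


def write_recording(rec: TactileRecording, path, format: str | None = None) -> None:
    """Write a recording to ``path`` in one of the supported containers."""
    path = Path(path)
    fmt = _infer_format(path, format)
    rec.validate()
    meta_json = json.dumps(rec.metadata, sort_keys=True)
    if fmt == "hdf5":
        with h5py.File(path, "w", track_order=True) as f:
            # track_times=False keeps identical inputs byte-identical on disk
            f.create_dataset("frames", data=rec.frames, track_times=False)
            f.create_dataset("sensor_mask", data=rec.sensor_mask, track_times=False)
            f.attrs["sampling_rate"] = float(rec.sampling_rate)
            f.attrs["bit_depth"] = int(rec.bit_depth)
            g = f.create_group("metadata")
            for k, v in sorted(rec.metadata.items()):
                g.attrs[k] = str(v)
    elif fmt == "mat":
        scipy.io.savemat(
            path,
            {
                "frames": rec.frames,
                "sensor_mask": rec.sensor_mask.astype(np.uint8),
                "sampling_rate": float(rec.sampling_rate),
                "bit_depth": int(rec.bit_depth),
                "metadata_json": meta_json,
            },
        )
    elif fmt == "npz":
        np.savez(
            path,
            frames=rec.frames,
            sensor_mask=rec.sensor_mask,
            sampling_rate=float(rec.sampling_rate),
            bit_depth=int(rec.bit_depth),
            metadata_json=meta_json,
        )
    else:  # csv-stack: frames flattened to (time, rows*cols) + JSON sidecar
        t, r, c = rec.frames.shape
        flat = rec.frames.reshape(t, r * c)
        if np.issubdtype(rec.frames.dtype, np.integer):
            np.savetxt(path, flat, fmt="%d", delimiter=",")
        else:
            np.savetxt(path, flat, fmt="%.17g", delimiter=",")
        sidecar = {
            "shape": [t, r, c],
            "dtype": rec.frames.dtype.name,
            "sensor_mask": rec.sensor_mask.astype(int).ravel().tolist(),
            "sampling_rate": float(rec.sampling_rate),
            "bit_depth": int(rec.bit_depth),
            "metadata": rec.metadata,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, sort_keys=True))


def read_recording(path, format: str | None = None) -> TactileRecording:
    """Read a recording written by :func:`write_recording` (or a compatible
    MAT container with ``frames``/``sensor_mask`` variables)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            try:
                frames = f["frames"][()]
                mask = f["sensor_mask"][()]
                fs = float(f.attrs["sampling_rate"])
                bits = int(f.attrs["bit_depth"])
            except KeyError as e:
                raise ValidationError(f"hdf5 container missing field: {e}") from e
            metadata = {k: str(v) for k, v in f["metadata"].attrs.items()} if "metadata" in f else {}
    elif fmt == "mat":
        raw = scipy.io.loadmat(path, squeeze_me=True)
        try:
            frames = np.asarray(raw["frames"])
            mask = np.asarray(raw["sensor_mask"]).astype(bool)
            fs = float(raw["sampling_rate"])
            bits = int(raw["bit_depth"])
        except KeyError as e:
            raise ValidationError(f"mat container missing field: {e}") from e
        metadata = json.loads(str(raw.get("metadata_json", "{}")))
    elif fmt == "npz":
        with np.load(path) as raw:
            try:
                frames = raw["frames"]
                mask = raw["sensor_mask"].astype(bool)
                fs = float(raw["sampling_rate"])
                bits = int(raw["bit_depth"])
            except KeyError as e:
                raise ValidationError(f"npz container missing field: {e}") from e
            metadata = json.loads(str(raw["metadata_json"])) if "metadata_json" in raw else {}
    else:
        sidecar_path = Path(str(path) + ".meta.json")
        if not sidecar_path.exists():
            raise FileNotFoundError(sidecar_path)
        sidecar = json.loads(sidecar_path.read_text())
        t, r, c = sidecar["shape"]
        flat = np.loadtxt(path, delimiter=",", dtype=np.dtype(sidecar["dtype"]), ndmin=2)
        frames = flat.reshape(t, r, c)
        mask = np.asarray(sidecar["sensor_mask"], dtype=bool).reshape(r, c)
        fs = sidecar["sampling_rate"]
        bits = sidecar["bit_depth"]
        metadata = dict(sidecar["metadata"])
    return TactileRecording(
        frames=frames,
        sensor_mask=mask,
        sampling_rate=fs,
        bit_depth=bits,
        metadata={str(k): str(v) for k, v in metadata.items()},
    )


def write_dataset(recordings, path) -> None:
    """Write a sequence of recordings into one HDF5 file, one group per trial."""
    recordings = list(recordings)
    if not recordings:
        raise ValidationError("dataset: empty recording collection")
    with h5py.File(Path(path), "w", track_order=True) as f:
        f.attrs["n_recordings"] = len(recordings)
        for i, rec in enumerate(recordings):
            rec.validate()
            g = f.create_group(f"recording_{i:04d}")
            g.create_dataset("frames", data=rec.frames, track_times=False)
            g.create_dataset("sensor_mask", data=rec.sensor_mask, track_times=False)
            g.attrs["sampling_rate"] = float(rec.sampling_rate)
            g.attrs["bit_depth"] = int(rec.bit_depth)
            m = g.create_group("metadata")
            for k, v in sorted(rec.metadata.items()):
                m.attrs[k] = str(v)


def read_dataset(path) -> list[TactileRecording]:
    """Read a multi-recording HDF5 file written by :func:`write_dataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            out.append(
                TactileRecording(
                    frames=g["frames"][()],
                    sensor_mask=g["sensor_mask"][()],
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    bit_depth=int(g.attrs["bit_depth"]),
                    metadata={k: str(v) for k, v in g["metadata"].attrs.items()},
                )
            )
    if not out:
        raise ValidationError("dataset: file contains no recordings")
    return out


#: Stable column order of survey CSVs (one row per sparsification result).
TABLE_COLUMNS = [
    "wavelet",
    "transform",
    "dimensionality",
    "target_nmse",
    "achieved_nmse",
    "Q",
    "sparsity",
    "bits_per_pixel",
    "energy_ratio",
    "iterations",
    "n_recordings",
    "status",
]


def write_table(table, path, header_lines: Mapping[str, str] | None = None) -> None:
    """Serialize a survey table to CSV with a stable column order.

    ``header_lines`` (run metadata such as config hash and seed) are written
    as leading ``#``-comment lines so the CSV body stays machine-readable.
    """
    df = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table, columns=TABLE_COLUMNS)
    df = df.reindex(columns=TABLE_COLUMNS)
    path = Path(path)
    with open(path, "w") as f:
        for k, v in (header_lines or {}).items():
            f.write(f"# {k}: {v}\n")
        df.to_csv(f, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    """Read a survey CSV written by :func:`write_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, comment="#")
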