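"""Sweep-bundle containers and lossless on-disk formats (CSV+JSON dir, HDF5)."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .trace import Trace

__all__ = ["SweepBundle", "read_bundle", "write_bundle", "BundleFormatError"]

_REQUIRED_META = ("id", "units", "sampling_rate_hz", "protocol", "condition")


class BundleFormatError(ValueError):
    """Raised on malformed bundle files; names the offending field."""


@dataclass
class SweepBundle:
    """An ordered set of sweeps sharing units and sampling rate.

    ``meta`` must contain: id, units, sampling_rate_hz, protocol (a dict
    describing the stimulus), condition.  Per-sweep stimulus annotations
    live on each Trace's ``meta``.
    """

    meta: dict
    sweeps: list[Trace] = field(default_factory=list)

    def __post_init__(self) -> None:
        for key in _REQUIRED_META:
            if key not in self.meta:
                raise BundleFormatError(f"bundle metadata missing required field {key!r}")
        units = self.meta["units"]
        rate = self.meta["sampling_rate_hz"]
        if not (isinstance(rate, (int, float)) and rate > 0):
            raise BundleFormatError("sampling_rate_hz must be a positive number")
        for i, sw in enumerate(self.sweeps):
            if sw.units != units:
                raise BundleFormatError(
                    f"sweep {i} units {sw.units!r} differ from bundle units {units!r}"
                )
            if abs(sw.sampling_rate_hz - rate) > 1e-9 * rate:
                raise BundleFormatError(f"sweep {i} sampling rate differs from bundle")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.meta["sampling_rate_hz"]

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


def write_bundle(bundle: SweepBundle, path, fmt: str = "dir") -> None:
    """Write a bundle as a directory (meta.json + sweeps.csv) or HDF5 file.

    The CSV stores samples with 17 significant digits, so write->read
    round-trips are bit-identical.
    """
    path = Path(path)
    if fmt == "dir":
        path.mkdir(parents=True, exist_ok=True)
        doc = dict(bundle.meta)
        doc["sweep_meta"] = [sw.meta for sw in bundle.sweeps]
        doc["n_sweeps"] = len(bundle.sweeps)
        with open(path / "meta.json", "w") as fh:
            json.dump(doc, fh, indent=1, default=_json_default)
        if bundle.sweeps:
            mat = np.column_stack([sw.data for sw in bundle.sweeps])
            header = ",".join(f"sweep_{i:03d}" for i in range(len(bundle.sweeps)))
            np.savetxt(path / "sweeps.csv", mat, delimiter=",", fmt="%.17g", header=header,
                       comments="")
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["meta"] = json.dumps(bundle.meta, default=_json_default)
            for i, sw in enumerate(bundle.sweeps):
                ds = fh.create_dataset(f"sweep_{i:03d}", data=sw.data)
                ds.attrs["meta"] = json.dumps(sw.meta, default=_json_default)
    else:
        raise ValueError(f"unknown bundle format {fmt!r}")


def read_bundle(path, fmt: str | None = None) -> SweepBundle:
    """Read a bundle written by :func:`write_bundle`."""
    path = Path(path)
    if fmt is None:
        fmt = "dir" if path.is_dir() else "hdf5"
    if fmt == "dir":
        meta_path = path / "meta.json"
        if not meta_path.exists():
            raise BundleFormatError("missing meta.json")
        with open(meta_path) as fh:
            doc = json.load(fh)
        for key in _REQUIRED_META:
            if key not in doc:
                raise BundleFormatError(f"bundle metadata missing required field {key!r}")
        sweep_meta = doc.pop("sweep_meta", [])
        n = doc.pop("n_sweeps", len(sweep_meta))
        dt = 1000.0 / doc["sampling_rate_hz"]
        sweeps: list[Trace] = []
        if n:
            csv_path = path / "sweeps.csv"
            if not csv_path.exists():
                raise BundleFormatError("missing sweeps.csv for non-empty bundle")
            mat = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
            if mat.shape[1] != n:
                raise BundleFormatError(
                    f"sweeps.csv has {mat.shape[1]} columns, metadata says {n} sweeps"
                )
            for i in range(n):
                m = sweep_meta[i] if i < len(sweep_meta) else {}
                sweeps.append(Trace(mat[:, i], dt_ms=dt, units=doc["units"], meta=m))
        return SweepBundle(meta=doc, sweeps=sweeps)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            doc = json.loads(fh.attrs["meta"])
            dt = 1000.0 / doc["sampling_rate_hz"]
            sweeps = []
            for key in sorted(k for k in fh.keys() if k.startswith("sweep_")):
                ds = fh[key]
                m = json.loads(ds.attrs.get("meta", "{}"))
                sweeps.append(Trace(ds[()], dt_ms=dt, units=doc["units"], meta=m))
        return SweepBundle(meta=doc, sweeps=sweeps)
    raise ValueError(f"unknown bundle format {fmt!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
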