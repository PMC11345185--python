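"""Reading and writing patient epochs as channel files.

Two on-disk layouts are supported and round-trip losslessly (float64
timestamps/values, NaNs preserved):

``csv-dir``
    One ``<CHANNEL>.csv`` per channel inside a directory.  The first line is
    a comment header ``# units=<u> rate=<r>``, followed by a normal CSV with
    columns ``t_seconds,value``.  Epoch metadata lives in ``meta.json`` and
    intervention markers, if any, in ``events.csv``.

``hdf5``
    One group per channel holding ``t`` and ``v`` datasets with ``units`` and
    ``rate`` attributes; ``patient_id``/``epoch_id`` as root attributes.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .channels import ChannelFormatError, ChannelSeries, PatientEpoch

FORMATS = ("csv-dir", "hdf5")


def write_epoch(epoch: PatientEpoch, path, format: str = "csv-dir") -> Path:
    """Serialize an epoch; returns the path written."""
    path = Path(path)
    if format == "csv-dir":
        return _write_csv_dir(epoch, path)
    if format == "hdf5":
        return _write_hdf5(epoch, path)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def read_epoch(path, format: str | None = None) -> PatientEpoch:
    """Load an epoch written by :func:`write_epoch`.

    ``format`` is inferred from the path when omitted (directory -> csv-dir,
    file -> hdf5).
    """
    path = Path(path)
    if format is None:
        format = "csv-dir" if path.is_dir() else "hdf5"
    if format == "csv-dir":
        return _read_csv_dir(path)
    if format == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def _write_csv_dir(epoch: PatientEpoch, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    for name, ch in sorted(epoch.channels.items()):
        f = path / f"{name}.csv"
        with open(f, "w") as fh:
            fh.write(f"# units={ch.units} rate={ch.nominal_rate!r}\n")
            pd.DataFrame({"t_seconds": ch.t, "value": ch.v}).to_csv(
                fh, index=False, na_rep="nan"
            )
    (path / "meta.json").write_text(
        json.dumps({"patient_id": epoch.patient_id, "epoch_id": epoch.epoch_id})
    )
    if epoch.events:
        pd.DataFrame(epoch.events, columns=["t_seconds", "category"]).to_csv(
            path / "events.csv", index=False
        )
    return path


_HEADER_RE = re.compile(r"#\s*units=(\S+)\s+rate=(\S+)")


def _read_csv_dir(path: Path) -> PatientEpoch:
    if not path.is_dir():
        raise ChannelFormatError(f"{path} is not a csv-dir epoch")
    meta = {"patient_id": "unknown", "epoch_id": "unknown"}
    meta_file = path / "meta.json"
    if meta_file.exists():
        meta.update(json.loads(meta_file.read_text()))
    epoch = PatientEpoch(meta["patient_id"], meta["epoch_id"])
    for f in sorted(path.glob("*.csv")):
        if f.name == "events.csv":
            df = pd.read_csv(f)
            epoch.events = list(df.itertuples(index=False, name=None))
            continue
        name = f.stem
        with open(f) as fh:
            header = fh.readline()
            m = _HEADER_RE.match(header)
            if not m:
                raise ChannelFormatError(
                    f"{f}: missing '# units=... rate=...' header"
                )
            units, rate = m.group(1), float(m.group(2))
            df = pd.read_csv(fh, float_precision="round_trip")
        if list(df.columns) != ["t_seconds", "value"]:
            raise ChannelFormatError(f"{f}: expected columns t_seconds,value")
        epoch.add(ChannelSeries(name, df["t_seconds"].to_numpy(float),
                                df["value"].to_numpy(float), units, rate))
    return epoch


def _write_hdf5(epoch: PatientEpoch, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.attrs["patient_id"] = epoch.patient_id
        h5.attrs["epoch_id"] = epoch.epoch_id
        for name, ch in epoch.channels.items():
            g = h5.create_group(name)
            g.create_dataset("t", data=ch.t)
            g.create_dataset("v", data=ch.v)
            g.attrs["units"] = ch.units
            g.attrs["rate"] = ch.nominal_rate
        if epoch.events:
            g = h5.create_group("_events")
            g.create_dataset("t", data=[t for t, _ in epoch.events])
            g.create_dataset(
                "category",
                data=np.array([c for _, c in epoch.events], dtype="S64"),
            )
    return path


def _read_hdf5(path: Path) -> PatientEpoch:
    with h5py.File(path, "r") as h5:
        epoch = PatientEpoch(str(h5.attrs.get("patient_id", "unknown")),
                             str(h5.attrs.get("epoch_id", "unknown")))
        for name, g in h5.items():
            if name == "_events":
                epoch.events = [
                    (float(t), c.decode())
                    for t, c in zip(g["t"][:], g["category"][:])
                ]
                continue
            epoch.add(ChannelSeries(name, g["t"][:], g["v"][:],
                                    str(g.attrs["units"]),
                                    float(g.attrs["rate"])))
    return epoch
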