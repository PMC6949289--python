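"""Read/write the published session and spike-sort file layouts.

Two on-disk containers are supported, both using the published element
names:

* MAT v7 structures (elements ``Data``, ``Channels``, ``Movements``, ``fs``
  and, for spike-sort files, ``samples``, ``times``, ``template``, ``fs``),
  written with :mod:`scipy.io` — the native format of the deposited files.
* A plain HDF5 layout with identical element names for non-MATLAB consumers,
  written with :mod:`h5py`.  MATLAB v7.3 session files (which are HDF5
  underneath) are read through the same code path, dereferencing cell arrays
  and decoding uint16 strings.

Spike-sort files store 1-based sample indices (MATLAB provenance); the
in-memory API is 0-based and the shift happens here.
"""

from __future__ import annotations

import os
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
import scipy.io as sio

from .errors import FormatError
from .records import SessionRecord, SpikeSortResult

__all__ = [
    "load_session",
    "save_session",
    "load_spikesort",
    "save_spikesort",
    "export_pairing_table",
]

_SESSION_ELEMENTS = ("Data", "Channels", "Movements", "fs")
_SPIKESORT_ELEMENTS = ("samples", "times", "template", "fs")


def _is_hdf5(path) -> bool:
    try:
        return h5py.is_hdf5(os.fspath(path))
    except OSError:
        return False


def _wants_hdf5(path) -> bool:
    return os.fspath(path).lower().endswith((".h5", ".hdf5"))


# ---------------------------------------------------------------------------
# session records
# ---------------------------------------------------------------------------


def save_session(rec: SessionRecord, path) -> None:
    """Write a validated SessionRecord in the published element layout.

    ``.mat`` paths get a MAT v7 structure; ``.h5``/``.hdf5`` paths get the
    plain HDF5 layout with the same element names.
    """
    rec.validate()
    if _wants_hdf5(path):
        with h5py.File(path, "w") as f:
            f.create_dataset("Data", data=rec.data)
            f.create_dataset(
                "Channels", data=np.array(rec.channels, dtype=object),
                dtype=h5py.string_dtype(),
            )
            g = f.create_group("Movements")
            g.create_dataset("code", data=rec.movements["code"].to_numpy(float))
            g.create_dataset(
                "description",
                data=np.array(rec.movements["description"], dtype=object),
                dtype=h5py.string_dtype(),
            )
            f.create_dataset("fs", data=float(rec.fs))
    else:
        movements = np.empty((len(rec.movements), 2), dtype=object)
        movements[:, 0] = rec.movements["code"].to_numpy(float)
        movements[:, 1] = list(rec.movements["description"])
        sio.savemat(
            os.fspath(path),
            {
                "Data": rec.data,
                "Channels": np.array(rec.channels, dtype=object).reshape(-1, 1),
                "Movements": movements,
                "fs": float(rec.fs),
            },
        )


def load_session(path) -> SessionRecord:
    """Load a session container (MAT v7, MAT v7.3 or plain HDF5)."""
    if _is_hdf5(path):
        raw = _load_session_hdf5(path)
    else:
        raw = _load_session_mat(path)
    rec = SessionRecord(**raw)
    return rec.validate()


def _require(mapping, names: Iterable[str], path) -> None:
    for name in names:
        if name not in mapping:
            raise FormatError(
                f"{os.fspath(path)}: missing element {name!r}", element=name
            )


def _load_session_mat(path) -> dict:
    try:
        mat = sio.loadmat(os.fspath(path), squeeze_me=False)
    except NotImplementedError as exc:  # pragma: no cover - v7.3 goes via h5py
        raise FormatError(f"{path}: unreadable MAT file: {exc}") from exc
    _require(mat, _SESSION_ELEMENTS, path)
    data = np.asarray(mat["Data"], dtype=float)
    channels = [str(np.squeeze(c)) for c in np.ravel(mat["Channels"])]
    movements = _movements_from_cell(np.asarray(mat["Movements"], dtype=object))
    fs = float(np.squeeze(mat["fs"]))
    return dict(data=data, channels=channels, movements=movements, fs=fs)


def _movements_from_cell(cell: np.ndarray) -> pd.DataFrame:
    if cell.ndim != 2 or cell.shape[1] != 2:
        cell = cell.reshape(-1, 2)
    codes = [float(np.squeeze(c)) for c in cell[:, 0]]
    descs = [str(np.squeeze(d)) for d in cell[:, 1]]
    return pd.DataFrame({"code": codes, "description": descs})


def _h5_string(ds, f) -> list[str]:
    """Decode an HDF5 string/cell dataset to a list of python strings."""
    arr = ds[()]
    if isinstance(arr, np.ndarray) and arr.dtype == object:
        out = []
        for item in arr.ravel():
            if isinstance(item, h5py.Reference):
                out.append(_decode_matlab_string(f[item][()]))
            elif isinstance(item, bytes):
                out.append(item.decode())
            else:
                out.append(str(item))
        return out
    if isinstance(arr, bytes):
        return [arr.decode()]
    if arr.dtype.kind in "SU":
        return [x.decode() if isinstance(x, bytes) else str(x) for x in arr.ravel()]
    return [_decode_matlab_string(arr)]


def _decode_matlab_string(arr) -> str:
    # MATLAB v7.3 stores char arrays as uint16 column vectors
    a = np.atleast_1d(np.squeeze(np.asarray(arr)))
    return "".join(chr(int(c)) for c in a)


def _load_session_hdf5(path) -> dict:
    with h5py.File(path, "r") as f:
        _require(f, _SESSION_ELEMENTS, path)
        data = np.asarray(f["Data"][()], dtype=float)
        # MATLAB is column-major: v7.3 stores Data transposed
        if data.ndim == 2 and "Channels" in f:
            n_labels = _h5_len(f["Channels"], f)
            if data.shape[0] == n_labels and data.shape[1] != n_labels:
                data = data.T
        channels = _h5_channels(f)
        movements = _h5_movements(f)
        fs = float(np.squeeze(f["fs"][()]))
    return dict(data=data, channels=channels, movements=movements, fs=fs)


def _h5_len(node, f) -> int:
    arr = node[()]
    return int(np.asarray(arr).size) if not isinstance(arr, bytes) else 1


def _h5_channels(f) -> list[str]:
    node = f["Channels"]
    if isinstance(node, h5py.Group):  # not expected, but tolerate
        return [_decode_matlab_string(node[k][()]) for k in sorted(node)]
    return _h5_string(node, f)


def _h5_movements(f) -> pd.DataFrame:
    node = f["Movements"]
    if isinstance(node, h5py.Group):
        codes = np.atleast_1d(np.squeeze(node["code"][()])).astype(float)
        descs = _h5_string(node["description"], f)
        return pd.DataFrame({"code": codes, "description": descs})
    # v7.3 cell array of references, shape (2, n) or (n, 2)
    refs = np.asarray(node[()])
    if refs.ndim == 1:
        refs = refs.reshape(-1, 2)
    if refs.shape[0] == 2 and refs.shape[1] != 2:
        refs = refs.T
    codes, descs = [], []
    for row in refs:
        codes.append(float(np.squeeze(f[row[0]][()])))
        descs.append(_decode_matlab_string(f[row[1]][()]))
    return pd.DataFrame({"code": codes, "description": descs})


# ---------------------------------------------------------------------------
# spike-sort metadata
# ---------------------------------------------------------------------------


def save_spikesort(res: SpikeSortResult, path) -> None:
    """Write spike-sort metadata (.samples/.times/.template/.fs layout).

    Sample indices are shifted to 1-based on disk; ``times`` is written as
    the 1-based samples divided by ``fs``, matching the published files.
    """
    res.validate()
    samples_1b = [s + 1 for s in res.samples]
    times = [s / res.fs for s in samples_1b]
    if _wants_hdf5(path):
        with h5py.File(path, "w") as f:
            gs = f.create_group("samples")
            gt = f.create_group("times")
            gw = f.create_group("template")
            for i, (s, t, w) in enumerate(zip(samples_1b, times, res.templates)):
                gs.create_dataset(f"u{i:03d}", data=s)
                gt.create_dataset(f"u{i:03d}", data=t)
                gw.create_dataset(f"u{i:03d}", data=w)
            f.create_dataset("fs", data=float(res.fs))
            f.create_dataset("unknown", data=res.unknown + 1)
    else:
        def cell(items):
            out = np.empty((len(items), 1), dtype=object)
            for i, x in enumerate(items):
                out[i, 0] = np.asarray(x).reshape(1, -1)
            return out

        sio.savemat(
            os.fspath(path),
            {
                "samples": cell(samples_1b),
                "times": cell(times),
                "template": cell(res.templates),
                "fs": float(res.fs),
                "unknown": np.asarray(res.unknown + 1).reshape(1, -1),
            },
        )


def load_spikesort(path) -> SpikeSortResult:
    """Load spike-sort metadata; indices are shifted back to 0-based."""
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            _require(f, ("samples", "template", "fs"), path)
            gs, gw = f["samples"], f["template"]
            keys = sorted(gs.keys())
            samples = [np.atleast_1d(np.squeeze(gs[k][()])).astype(np.int64) - 1
                       for k in keys]
            templates = [np.atleast_1d(np.squeeze(gw[k][()])).astype(float)
                         for k in keys]
            fs = float(np.squeeze(f["fs"][()]))
            unknown = (
                np.atleast_1d(np.squeeze(f["unknown"][()])).astype(np.int64) - 1
                if "unknown" in f and f["unknown"].size
                else np.empty(0, dtype=np.int64)
            )
    else:
        mat = sio.loadmat(os.fspath(path), squeeze_me=False)
        _require(mat, ("samples", "template", "fs"), path)
        samples = [
            np.atleast_1d(np.squeeze(c)).astype(np.int64) - 1
            for c in np.ravel(np.asarray(mat["samples"], dtype=object))
        ]
        templates = [
            np.atleast_1d(np.squeeze(c)).astype(float)
            for c in np.ravel(np.asarray(mat["template"], dtype=object))
        ]
        fs = float(np.squeeze(mat["fs"]))
        if "unknown" in mat and np.asarray(mat["unknown"]).size:
            unknown = np.atleast_1d(
                np.squeeze(np.asarray(mat["unknown"]))
            ).astype(np.int64) - 1
        else:
            unknown = np.empty(0, dtype=np.int64)
    res = SpikeSortResult(samples=samples, templates=templates, fs=fs,
                          unknown=unknown)
    return res.validate()


# ---------------------------------------------------------------------------
# pairing-table export
# ---------------------------------------------------------------------------


def export_pairing_table(entries, path) -> None:
    """Write channel/force pairing entries as tab-separated text.

    Columns: emg_channel, force_channel, movement_code, sign, quality.
    ``entries`` is an iterable of :class:`iemgkit.features.PairingEntry`.
    """
    rows = [
        {
            "emg_channel": e.emg_channel,
            "force_channel": e.force_channel if e.paired else "",
            "movement_code": e.movement_code if e.paired else "",
            "sign": e.sign if e.paired else 0,
            "quality": f"{e.score:.3f}",
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
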