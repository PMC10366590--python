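"""Deterministic on-disk archive for model parameters.

A plain ZIP container holding one ``.npy`` member per array plus a JSON
metadata member.  All member timestamps are pinned to the ZIP epoch and the
container is stored uncompressed, so saving the same arrays twice yields
byte-identical files (``np.savez`` embeds wall-clock timestamps and does
not).
"""

from __future__ import annotations

import io
import json
import zipfile

import numpy as np

_EPOCH = (1980, 1, 1, 0, 0, 0)
_META = "__meta__.json"


def save_arrays(path, arrays: dict, meta: dict | None = None) -> None:
    """Write ``arrays`` (name -> ndarray) and ``meta`` to ``path``."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        info = zipfile.ZipInfo(_META, date_time=_EPOCH)
        zf.writestr(info, json.dumps(meta or {}, sort_keys=True))
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, np.asarray(arrays[name]))
            zf.writestr(zipfile.ZipInfo(name + ".npy", date_time=_EPOCH), buf.getvalue())


def load_arrays(path) -> tuple[dict, dict]:
    """Read back ``(arrays, meta)`` written by :func:`save_arrays`."""
    arrays: dict = {}
    meta: dict = {}
    with zipfile.ZipFile(path, "r") as zf:
        for name in zf.namelist():
            payload = zf.read(name)
            if name == _META:
                meta = json.loads(payload.decode())
            else:
                arrays[name[: -len(".npy")]] = np.load(io.BytesIO(payload), allow_pickle=False)
    return arrays, meta
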