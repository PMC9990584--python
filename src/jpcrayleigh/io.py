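"""File formats: lifetime vectors and JPC sample records.

Lifetimes travel as plain text, one value per line, or as a single-column
CSV with header ``time``.  A JPC record travels either as

* a CSV with columns ``lambda,h,s,t`` (r rows) plus a JSON sidecar
  ``<stem>.scheme.json`` carrying ``{"m": .., "n": .., "r": .., "R": [..]}``, or
* one self-contained JSON object with the same scheme keys plus the
  arrays ``lam``, ``h``, ``s``, ``t``.

Reading applies the same counting-identity checks as
:func:`jpcrayleigh.jpc_scheme.validate`; violations are returned alongside
the data (loaded with warnings, never silently repaired).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .jpc_scheme import CensoringScheme, JPCSample, Violation, validate

__all__ = [
    "read_lifetimes",
    "write_lifetimes",
    "read_jpc_sample",
    "write_jpc_sample",
]


def read_lifetimes(path) -> np.ndarray:
    """Read a lifetime vector from plain text or single-column CSV."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()
    if first and first[0].strip().lower() == "time":
        values = pd.read_csv(path)["time"].to_numpy(dtype=float)
    else:
        values = np.loadtxt(path, dtype=float, ndmin=1)
    if values.size == 0:
        raise ValueError(f"{path}: no lifetimes found")
    return values


def write_lifetimes(path, values, *, csv: bool = True) -> None:
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if csv:
        pd.DataFrame({"time": values}).to_csv(path, index=False)
    else:
        np.savetxt(path, values, fmt="%.10g")


def _scheme_sidecar(path: Path) -> Path:
    return path.with_suffix(".scheme.json")


def _build_scheme(meta: dict, source: str) -> CensoringScheme | object:
    try:
        return CensoringScheme(m=int(meta["m"]), n=int(meta["n"]),
                               r=int(meta["r"]), R=tuple(meta["R"]))
    except ValueError:
        # Keep inconsistent published schemes loadable; validate() reports.
        scheme = object.__new__(CensoringScheme)
        object.__setattr__(scheme, "m", int(meta["m"]))
        object.__setattr__(scheme, "n", int(meta["n"]))
        object.__setattr__(scheme, "r", int(meta["r"]))
        object.__setattr__(scheme, "R", tuple(int(v) for v in meta["R"]))
        return scheme


def read_jpc_sample(path) -> tuple[JPCSample, CensoringScheme, list[Violation]]:
    """Read a JPC record (CSV + sidecar, or single JSON).

    Returns the sample, the scheme, and the list of counting-identity
    violations (empty for a consistent record).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        meta = obj
        arrays = {k: obj[k] for k in ("lam", "h", "s", "t")}
    else:
        df = pd.read_csv(path)
        required = ["lambda", "h", "s", "t"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for i, v in enumerate(df["h"]):
            if v not in (0, 1):
                raise ValueError(f"{path}: row {i + 1}: h={v!r} is not 0/1")
        sidecar = _scheme_sidecar(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"scheme sidecar {sidecar} not found")
        meta = json.loads(sidecar.read_text())
        arrays = {"lam": df["lambda"], "h": df["h"], "s": df["s"], "t": df["t"]}
    if any(int(v) not in (0, 1) for v in np.atleast_1d(arrays["h"])):
        raise ValueError(f"{path}: population indicator h must be 0/1")
    sample = JPCSample(lam=np.asarray(arrays["lam"], dtype=float),
                       h=np.asarray(arrays["h"], dtype=int),
                       s=np.asarray(arrays["s"], dtype=int),
                       t=np.asarray(arrays["t"], dtype=int))
    scheme = _build_scheme(meta, str(path))
    return sample, scheme, validate(sample, scheme)


def write_jpc_sample(path, sample: JPCSample, scheme: CensoringScheme) -> None:
    """Write a JPC record; format chosen by extension (.csv or .json)."""
    path = Path(path)
    meta = {"m": scheme.m, "n": scheme.n, "r": scheme.r, "R": list(scheme.R)}
    if path.suffix.lower() == ".json":
        obj = dict(meta)
        obj.update(lam=[float(v) for v in sample.lam],
                   h=[int(v) for v in sample.h],
                   s=[int(v) for v in sample.s],
                   t=[int(v) for v in sample.t])
        path.write_text(json.dumps(obj, indent=1) + "\n")
    else:
        pd.DataFrame({"lambda": sample.lam, "h": sample.h,
                      "s": sample.s, "t": sample.t}).to_csv(path, index=False)
        _scheme_sidecar(path).write_text(json.dumps(meta) + "\n")
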