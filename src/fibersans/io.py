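"""Reading and writing reduced SAS data files and run configuration.

The reader accepts the plain-text columnar dialects reduced SANS data are
deposited in: 2-4 numeric columns (q, I[, sigma_I[, sigma_q]]), comment or
free-text header lines, whitespace or comma delimiters. q is assumed to be
in 1/Angstrom unless a header line declares 1/nm.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import IO, Any

import numpy as np
import yaml

from .curves import ScatteringCurve

__all__ = ["read_sas_ascii", "write_sas_ascii", "read_config", "ParseError"]


class ParseError(ValueError):
    """The file contained no usable numeric data."""


_NM_TOKENS = ("nm-1", "nm^-1", "1/nm", "nm**-1")


def _float_or_none(token: str) -> float | None:
    try:
        return float(token)
    except ValueError:
        return None


def read_sas_ascii(source: "str | Path | IO[str]") -> ScatteringCurve:
    """Read a columnar reduced SAS file into a :class:`ScatteringCurve`.

    Rows with non-positive q or non-finite entries are dropped (counted in
    ``metadata["n_dropped"]``). Two-column input gets a synthesized
    sigma_I of 1% of |I|, flagged in ``metadata["sigma_synthesized"]``.
    Non-monotone q is sorted with a warning.
    """
    if hasattr(source, "read"):
        name = getattr(source, "name", "<stream>")
        lines = source.read().splitlines()
    else:
        name = str(source)
        lines = Path(source).read_text().splitlines()

    metadata: dict[str, Any] = {"source": name}
    q_scale = 1.0
    rows: list[list[float]] = []
    n_dropped = 0
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        body = stripped.lstrip("#").strip()
        lowered = stripped.lower()
        if any(tok in lowered for tok in _NM_TOKENS):
            q_scale = 0.1
        tokens = body.replace(",", " ").split()
        values = [_float_or_none(t) for t in tokens]
        if len(values) >= 2 and all(v is not None for v in values[:2]) \
                and not stripped.startswith("#"):
            row = [v for v in values if v is not None]
            if len(row) != len(values):
                continue  # mixed text/number line: header
            rows.append(row[:4])
        elif stripped.startswith("#") and ":" in body:
            key, _, val = body.partition(":")
            if key.strip() and not key.strip()[0].isdigit():
                metadata.setdefault(key.strip(), val.strip())

    if not rows:
        raise ParseError(f"no numeric data rows in {name}")
    ncols = min(len(r) for r in rows)
    arr = np.array([r[:ncols] for r in rows], dtype=float)

    finite = np.all(np.isfinite(arr), axis=1)
    positive_q = arr[:, 0] > 0
    keep = finite & positive_q
    n_dropped = int((~keep).sum())
    arr = arr[keep]
    if arr.shape[0] == 0:
        raise ParseError(f"no valid data rows in {name}")

    q = arr[:, 0] * q_scale
    if np.any(np.diff(q) <= 0):
        warnings.warn(f"non-monotone q in {name}; sorting", stacklevel=2)
        order = np.argsort(q, kind="stable")
        arr = arr[order]
        q = q[order]
        dup = np.concatenate([[True], np.diff(q) > 0])
        arr, q = arr[dup], q[dup]
        metadata["sorted"] = True

    intensity = arr[:, 1]
    if ncols >= 3:
        sigma_i = arr[:, 2]
        bad = sigma_i <= 0
        if bad.any():
            sigma_i = np.where(bad, 0.01 * np.maximum(np.abs(intensity),
                                                      1e-12), sigma_i)
            metadata["sigma_synthesized_rows"] = int(bad.sum())
    else:
        sigma_i = 0.01 * np.maximum(np.abs(intensity), 1e-12)
        metadata["sigma_synthesized"] = True
    sigma_q = arr[:, 3] * q_scale if ncols >= 4 else None
    metadata["n_dropped"] = n_dropped
    if q_scale != 1.0:
        metadata["q_unit_converted"] = "nm^-1 -> A^-1"
    return ScatteringCurve(q=q, intensity=intensity, sigma_i=sigma_i,
                           sigma_q=sigma_q, metadata=metadata)


def write_sas_ascii(curve: ScatteringCurve, path: "str | Path") -> None:
    """Write a curve as 3- or 4-column ASCII with a metadata header."""
    if len(curve) == 0:
        raise ValueError("refusing to write an empty curve")
    cols = [curve.q, curve.intensity, curve.sigma_i]
    names = ["q(A^-1)", "I(cm^-1)", "sigma_I(cm^-1)"]
    if curve.sigma_q is not None:
        cols.append(curve.sigma_q)
        names.append("sigma_q(A^-1)")
    lines = ["# reduced SAS data written by fibersans"]
    for key, val in curve.metadata.items():
        lines.append(f"# {key}: {val}")
    lines.append("# columns: " + " ".join(names))
    data = np.column_stack(cols)
    for row in data:
        lines.append(" ".join(f"{v:.17e}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: "str | Path") -> dict:
    """Load a declarative YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"configuration in {path} is not a mapping")
    return cfg
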