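"""Delimited-matrix reading/writing, fit serialization and atomic output.

Matrices travel as CSV or TSV with an optional header row and an
optional leading row-identifier column; the decimal separator is always
'.'.  Missing values are rejected with their coordinates, never
imputed.  All writers go through a write-to-temp + atomic-rename path
so a failure never leaves a partial output file behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ActiveSet, SPLSFit
from .pls import PLSFit

__all__ = [
    "Matrix",
    "load_matrix",
    "save_matrix",
    "atomic_write_text",
    "save_fit",
    "load_fit",
    "load_config",
]


@dataclass
class Matrix:
    values: np.ndarray
    col_labels: list[str] | None = None
    row_labels: list[str] | None = None


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def load_matrix(path, has_header: bool = True, has_rownames: bool = False) -> Matrix:
    """Read a rectangular numeric CSV/TSV matrix.

    Raises ``ValueError`` naming the (row, column) of the first missing
    or non-numeric cell, and on ragged rows.
    """
    sep = _sep_for(path)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            header=0 if has_header else None,
            index_col=0 if has_rownames else None,
        )
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: ragged or malformed delimited file: {e}") from e
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at row "
            f"{body.index[r]!r}, column {body.columns[c]!r}"
        )
    return Matrix(
        values=body.to_numpy(dtype=float),
        col_labels=[str(c) for c in df.columns] if has_header else None,
        row_labels=[str(r) for r in df.index] if has_rownames else None,
    )


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` atomically (temp file + rename)."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_matrix(path, M: Matrix) -> None:
    sep = _sep_for(path)
    df = pd.DataFrame(M.values, columns=M.col_labels, index=M.row_labels)
    text = df.to_csv(
        sep=sep,
        header=M.col_labels is not None,
        index=M.row_labels is not None,
        float_format="%.17g",
    )
    atomic_write_text(path, text)


def _mat_to_lines(name: str, A: np.ndarray) -> list[str]:
    A = np.atleast_2d(A)
    lines = [f"@matrix {name} {A.shape[0]} {A.shape[1]}"]
    for row in A:
        lines.append(" ".join(v.hex() for v in map(float, row)))
    return lines


def _parse_matrices(lines: list[str]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        head = lines[i].split()
        assert head[0] == "@matrix", f"bad fit file near line {i}"
        name, r, c = head[1], int(head[2]), int(head[3])
        rows = [
            [float.fromhex(tok) for tok in lines[i + 1 + j].split()]
            for j in range(r)
        ]
        out[name] = np.array(rows).reshape(r, c)
        i += 1 + r
    return out


def save_fit(path, fit: SPLSFit, transform) -> None:
    """Serialize an SPLS fit plus its training transform.

    Floats are stored as C99 hex literals, so the round trip is
    bit-exact and `fit` and `predict` can run in separate processes.
    """
    header = {
        "format": "splsreg-fit-v1",
        "eta": fit.eta,
        "kappa": fit.kappa,
        "K": fit.K,
        "variant": fit.variant,
        "p": int(fit.coef_full.shape[0]),
        "q": int(fit.coef_full.shape[1]),
        "active": fit.active.indices.tolist(),
        "history": [h.tolist() for h in fit.active.history],
        "inner_K": fit.inner_fit.K,
    }
    lines = [json.dumps(header)]
    lines += _mat_to_lines("coef_full", fit.coef_full)
    lines += _mat_to_lines("inner_W", fit.inner_fit.W)
    lines += _mat_to_lines("inner_Q", fit.inner_fit.Q)
    lines += _mat_to_lines("x_center", transform.x_center)
    lines += _mat_to_lines("x_scale", transform.x_scale)
    lines += _mat_to_lines("y_center", transform.y_center)
    lines += _mat_to_lines("y_scale", transform.y_scale)
    atomic_write_text(path, "\n".join(lines) + "\n")


def load_fit(path):
    """Inverse of :func:`save_fit`; returns (SPLSFit, transform-record).

    The transform record carries only the centers/scales needed for
    prediction (a lightweight stand-in for the full training data).
    """
    from .data import CenteredData

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = json.loads(lines[0])
    if header.get("format") != "splsreg-fit-v1":
        raise ValueError(f"{path}: not a splsreg fit file")
    mats = _parse_matrices(lines[1:])
    p, q = header["p"], header["q"]
    transform = CenteredData(
        X=np.zeros((3, p)),
        Y=np.zeros((3, q)),
        x_center=mats["x_center"].ravel(),
        x_scale=mats["x_scale"].ravel(),
        y_center=mats["y_center"].ravel(),
        y_scale=mats["y_scale"].ravel(),
    )
    inner = PLSFit(
        W=mats["inner_W"],
        T=np.zeros((0, header["inner_K"])),
        Q=mats["inner_Q"],
        coef=mats["coef_full"][np.array(header["active"], dtype=int), :],
        K=header["inner_K"],
        variant=header["variant"],
    )
    fit = SPLSFit(
        active=ActiveSet(
            indices=np.array(header["active"], dtype=int),
            history=[np.array(h, dtype=int) for h in header["history"]],
        ),
        inner_fit=inner,
        coef_full=mats["coef_full"],
        eta=header["eta"],
        kappa=header["kappa"],
        K=header["K"],
        variant=header["variant"],
    )
    return fit, transform


def load_config(path) -> dict:
    """Flat key-value config: JSON object, or `key = value` lines."""
    with open(path) as fh:
        text = fh.read()
    try:
        obj = json.loads(text)
        if not isinstance(obj, dict):
            raise ValueError(f"{path}: config must be a flat object")
        return obj
    except json.JSONDecodeError:
        pass
    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        val = val.strip("\"'")
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = val
    return out
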