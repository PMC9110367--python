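"""Delimited-text and .npy I/O plus sidecar run configs.

Matrices are plain tab-separated text with '.' decimals and no header
(nodes x frames for BOLD, square for correlation/eFC); ``.npy`` is accepted
as a simple binary container for large eFC matrices.  Every artefact can
carry a JSON sidecar (same path + ``.json``) recording the full generating
configuration including seeds, so any pipeline invocation is reproducible
from its sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .bold import BoldMatrix
from .correlation import CorrelationModel, CorrelationSpec
from .errors import InvalidInputError
from .surrogate import SurrogateSpec

ORIENTATIONS = ("nodes_by_frames", "frames_by_nodes")


def _parse_delimited(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    n_cols: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if n_cols is None:
                n_cols = len(fields)
            elif len(fields) != n_cols:
                raise InvalidInputError(
                    f"{path}: row {lineno} has {len(fields)} fields, expected {n_cols}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError:
                for col, v in enumerate(fields, start=1):
                    try:
                        float(v)
                    except ValueError:
                        raise InvalidInputError(
                            f"{path}: non-numeric value {v!r} at row {lineno}, column {col}"
                        ) from None
    if not rows:
        raise InvalidInputError(f"{path}: no numeric data found")
    return np.asarray(rows, dtype=float)


def read_array(path) -> np.ndarray:
    """Read a numeric matrix from delimited text or ``.npy``."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"input file {path} does not exist")
    if path.suffix == ".npy":
        return np.load(path)
    return _parse_delimited(path)


def read_bold(path, orientation: str = "nodes_by_frames") -> BoldMatrix:
    """Read a BOLD matrix, transposing for frames-by-nodes layouts."""
    if orientation not in ORIENTATIONS:
        raise InvalidInputError(f"orientation must be one of {ORIENTATIONS}")
    arr = read_array(path)
    if orientation == "frames_by_nodes":
        arr = arr.T
    return BoldMatrix(arr)


def read_correlation(path) -> CorrelationModel:
    """Read a correlation matrix, enforcing symmetry and unit diagonal (1e-6)."""
    arr = read_array(path)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InvalidInputError(f"{path}: correlation matrix must be square, got {arr.shape}")
    if not np.allclose(arr, arr.T, atol=1e-6, rtol=0.0):
        raise InvalidInputError(f"{path}: correlation matrix is not symmetric within 1e-6")
    if not np.allclose(np.diag(arr), 1.0, atol=1e-6, rtol=0.0):
        bad = int(np.argmax(np.abs(np.diag(arr) - 1.0)))
        raise InvalidInputError(
            f"{path}: correlation diagonal must be 1 (row {bad + 1} has {arr[bad, bad]:g})"
        )
    return CorrelationModel(arr)


def write_matrix(path, values, fmt: str = "%.17g") -> Path:
    """Write a matrix as tab-separated text (or ``.npy`` by extension).

    The default float format round-trips IEEE doubles bit-exactly.
    """
    path = Path(path)
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if path.suffix == ".npy":
        np.save(path, arr)
    else:
        np.savetxt(path, arr, fmt=fmt, delimiter="\t")
    return path


def write_vector(path, values, fmt: str = "%.17g") -> Path:
    """Write a 1-D series, one value per line."""
    path = Path(path)
    np.savetxt(path, np.asarray(values, dtype=float), fmt=fmt)
    return path


def read_vector(path) -> np.ndarray:
    arr = read_array(path)
    return arr.ravel()


def _jsonable(obj):
    if isinstance(obj, CorrelationModel):
        return {"kind": "explicit_model", "n_nodes": obj.n_nodes}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.name + ".json")


def write_sidecar(data_path, config: dict) -> Path:
    """Record the generating configuration next to a data file."""
    out = sidecar_path(data_path)
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def read_sidecar(data_path) -> dict:
    with open(sidecar_path(data_path), "r", encoding="utf-8") as fh:
        return json.load(fh)


def surrogate_spec_from_sidecar(config: dict) -> SurrogateSpec:
    """Rebuild a SurrogateSpec from its on-disk sidecar form."""
    corr = config["correlation"]
    if corr.get("matrix") is not None:
        corr = dict(corr, matrix=np.asarray(corr["matrix"], dtype=float))
    if corr.get("module_sizes") is not None:
        corr = dict(corr, module_sizes=tuple(corr["module_sizes"]))
    cspec = CorrelationSpec(**corr)
    return SurrogateSpec(
        correlation=cspec,
        n_frames=config["n_frames"],
        temporal_model=config["temporal_model"],
        ar_coefficient=config["ar_coefficient"],
        seed=config["seed"],
    )


def write_labels(path, labels) -> Path:
    """Write community labels as (i, j, label) triples with 1-based nodes."""
    from .edges import EdgeSet

    path = Path(path)
    es = EdgeSet(labels.n_nodes)
    table = np.column_stack([es.i_idx + 1, es.j_idx + 1, labels.labels])
    np.savetxt(path, table, fmt="%d", delimiter="\t")
    return path
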