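"""Readers, writers and the end-to-end pipeline report.

File formats (all plain CSV):

* activity table — header ``id,activity``, one molecule per line;
* similarity matrix — square, first row and first column hold molecule ids
  in the same order;
* fingerprints — header ``id,bits`` with ``bits`` a fixed-length string
  over {0,1}; hex encoding is supported via a leading comment line
  ``# encoding=hex length=<L>``.

Readers reject malformed input naming the file and line; nothing is
silently coerced.  Molecules are aligned across files by id with one
canonical sort, so row order never affects results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    ActivityVector,
    FingerprintSet,
    SimilarityMatrix,
    TestConfig,
    mean_fusion,
)

logger = logging.getLogger("landsig")

__all__ = [
    "read_activity_table",
    "write_activity_table",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_fingerprints",
    "write_fingerprints",
    "RunReport",
    "run_pipeline",
]

_FLOAT_FMT = "%.17g"  # lossless round trip for float64


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def read_activity_table(path) -> ActivityVector:
    """Read an ``id,activity`` CSV into an ActivityVector."""
    path = Path(path)
    ids: list[str] = []
    vals: list[float] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        if cols[:2] != ["id", "activity"]:
            raise ParseError(f"{path}:1: expected header 'id,activity', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            mol, raw = parts[0].strip(), parts[1].strip()
            if mol in seen:
                raise ParseError(f"{path}:{lineno}: duplicate id {mol!r} (first seen on line {seen[mol]})")
            seen[mol] = lineno
            try:
                val = float(raw)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric activity {raw!r}") from None
            ids.append(mol)
            vals.append(val)
    if len(ids) < 2:
        raise ParseError(f"{path}: need at least 2 molecules, found {len(ids)}")
    return ActivityVector(ids, np.array(vals))


def write_activity_table(acts: ActivityVector, path) -> None:
    with open(path, "w") as fh:
        fh.write("id,activity\n")
        for mol, val in zip(acts.molecule_ids, acts.values):
            fh.write(f"{mol},{val:.17g}\n")


def read_similarity_matrix(path, representation_name: str | None = None) -> SimilarityMatrix:
    """Read a square similarity CSV (ids in first row and first column)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: unreadable CSV ({exc})") from exc
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if df.shape[0] != df.shape[1]:
        raise ParseError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    if row_ids != col_ids:
        raise ParseError(f"{path}: row ids and column ids differ or are ordered differently")
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise ParseError(f"{path}: non-finite entry at row {row_ids[bad[0]]!r}, column {col_ids[bad[1]]!r}")
    if vals.min() < -1e-8 or vals.max() > 1 + 1e-8:
        raise ParseError(f"{path}: similarity entries outside [0, 1] (range {vals.min():g}..{vals.max():g})")
    name = representation_name or path.stem
    try:
        return SimilarityMatrix(row_ids, vals, name)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.values, index=list(sim.molecule_ids), columns=list(sim.molecule_ids))
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_fingerprints(path, representation_name: str | None = None) -> FingerprintSet:
    """Read an ``id,bits`` CSV; bits are 0/1 strings, or hex when a leading
    ``# encoding=hex length=<L>`` comment declares the bit length."""
    path = Path(path)
    encoding, declared_len = "binary", None
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lineno = 0
        line = fh.readline()
        lineno += 1
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("encoding="):
                    encoding = tok.split("=", 1)[1]
                elif tok.startswith("length="):
                    declared_len = int(tok.split("=", 1)[1])
            if encoding == "hex" and declared_len is None:
                raise ParseError(f"{path}:1: hex encoding requires 'length=<L>' in the header comment")
            line = fh.readline()
            lineno += 1
        header = [c.strip() for c in line.strip().split(",")]
        if header[:2] != ["id", "bits"]:
            raise ParseError(f"{path}:{lineno}: expected header 'id,bits', got {line.strip()!r}")
        for line in fh:
            lineno += 1
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            mol, raw = parts[0].strip(), parts[1].strip()
            if encoding == "hex":
                try:
                    as_int = int(raw, 16)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: invalid hex record {raw!r}") from None
                bitstr = bin(as_int)[2:].zfill(declared_len)
                if len(bitstr) > declared_len:
                    raise ParseError(f"{path}:{lineno}: hex record {raw!r} exceeds declared length {declared_len}")
            else:
                bitstr = raw
                if set(bitstr) - {"0", "1"}:
                    raise ParseError(f"{path}:{lineno}: invalid characters in bitstring {raw!r}")
            row = np.frombuffer(bitstr.encode(), dtype=np.uint8) - ord("0")
            if rows and len(row) != len(rows[0]):
                raise ParseError(f"{path}:{lineno}: fingerprint length {len(row)} differs from {len(rows[0])}")
            ids.append(mol)
            rows.append(row)
    if len(ids) < 2:
        raise ParseError(f"{path}: need at least 2 molecules, found {len(ids)}")
    try:
        return FingerprintSet(ids, np.vstack(rows), representation_name or path.stem)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fingerprints(fps: FingerprintSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("id,bits\n")
        for mol, row in zip(fps.molecule_ids, fps.bits):
            fh.write(f"{mol},{''.join('1' if b else '0' for b in row)}\n")


# ---------------------------------------------------------------------------
# pipeline report


@dataclasses.dataclass
class RunReport:
    """Structured record of one full pipeline run; JSON round-trippable."""

    config: dict
    representations: list  # one dict per representation (+ fusion)
    version: str = __version__
    timestamp: str = ""

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        return cls(**d)


def _align(acts: ActivityVector, reps: list, allow_subset: bool):
    """Canonically sort molecules by id across all inputs."""
    id_sets = [set(acts.molecule_ids)] + [set(r.molecule_ids) for r in reps]
    common = set.intersection(*id_sets)
    union = set.union(*id_sets)
    if common != union and not allow_subset:
        diff = sorted(union - common)
        raise ValueError(f"molecule id sets differ across inputs; symmetric difference: {diff}")
    if len(common) < 2:
        raise ValueError("fewer than 2 molecules shared across inputs")
    order = sorted(common)
    a_pos = {mol: k for k, mol in enumerate(acts.molecule_ids)}
    acts2 = ActivityVector(order, acts.values[[a_pos[mol] for mol in order]], acts.unit_label)
    reps2 = []
    for r in reps:
        pos = {mol: k for k, mol in enumerate(r.molecule_ids)}
        idx = [pos[mol] for mol in order]
        if isinstance(r, SimilarityMatrix):
            reps2.append(SimilarityMatrix(order, r.values[np.ix_(idx, idx)], r.representation_name))
        else:
            reps2.append(FingerprintSet(order, r.bits[idx], r.representation_name))
    return acts2, reps2


def run_pipeline(activity_path, representation_paths, cfg: TestConfig,
                 fingerprint_paths=(), fuse: bool = False,
                 iteration_check: bool = False,
                 allow_subset: bool = False) -> RunReport:
    """Run the full validity + cliff-significance analysis from files.

    ``representation_paths`` are similarity-matrix CSVs; ``fingerprint_paths``
    are fingerprint CSVs (similarities computed by Tanimoto).  With ``fuse``
    the mean-fusion consensus of all representations is analysed as well.
    """
    from .model import ActivityLandscape  # local import to avoid a cycle

    acts = read_activity_table(activity_path)
    reps: list = [read_similarity_matrix(p) for p in representation_paths]
    reps += [read_fingerprints(p) for p in fingerprint_paths]
    if not reps:
        raise ValueError("at least one representation input is required")
    acts, reps = _align(acts, reps, allow_subset)

    from .core import similarity_matrix as _simmat

    sims = [r if isinstance(r, SimilarityMatrix) else _simmat(r) for r in reps]
    if fuse and len(sims) > 1:
        sims.append(mean_fusion(sims))

    entries = []
    for sim in sims:
        model = ActivityLandscape(acts, similarity=sim, config=cfg)
        res = model.fit(iteration_check=iteration_check)
        entries.append(res.to_dict())
    import datetime

    return RunReport(config=dataclasses.asdict(cfg), representations=entries,
                     timestamp=datetime.datetime.now().isoformat(timespec="seconds"))
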