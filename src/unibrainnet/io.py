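"""Delimited-text readers/writers and the cohort manifest.

All matrices travel as plain delimited text (comma or tab, auto-detected on
read; comma on write, full double precision) — ROI-level connectivity has no
binary container worth the dependency, and text keeps runs diffable.  A
cohort is described by a manifest CSV with one row per subject:
``subject_id,x_path,g_path,label``, paths resolved relative to the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import MatrixParseError, ValidationError
from .simulate import SubjectSample

__all__ = [
    "read_matrix",
    "write_matrix",
    "CohortManifest",
    "ManifestRow",
    "read_manifest",
    "write_cohort",
]


def read_matrix(
    path: str | Path, expected_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Read a rectangular delimited numeric text matrix.

    The delimiter (tab or comma) is auto-detected from the first data line.
    Ragged rows and non-numeric cells raise ``MatrixParseError`` naming the
    offending line / cell.
    """
    path = Path(path)
    if not path.exists():
        raise MatrixParseError(f"no such file: {path}")
    rows: list[list[float]] = []
    delim: str | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if delim is None:
                delim = "\t" if "\t" in line else ","
            cells = line.split(delim)
            parsed = []
            for colno, cell in enumerate(cells, start=1):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise MatrixParseError(
                        f"{path}: non-numeric cell at line {lineno}, column {colno}: "
                        f"{cell!r}"
                    ) from None
            if rows and len(parsed) != len(rows[0]):
                raise MatrixParseError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parsed)} cells, expected {len(rows[0])})"
                )
            rows.append(parsed)
    if not rows:
        raise MatrixParseError(f"{path}: empty matrix file")
    mat = np.asarray(rows, dtype=float)
    if expected_shape is not None and mat.shape != tuple(expected_shape):
        raise MatrixParseError(
            f"{path}: shape {mat.shape} does not match expected {tuple(expected_shape)}"
        )
    return mat


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a matrix as comma-delimited text at full double precision.

    Byte output is deterministic for identical input; non-finite entries are
    refused with their coordinates.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    bad = np.argwhere(~np.isfinite(matrix))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"refusing to write non-finite entry at ({i}, {j}): {matrix[i, j]}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for row in matrix:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


@dataclass(frozen=True)
class ManifestRow:
    subject_id: str
    x_path: Path
    g_path: Path
    label: str


@dataclass
class CohortManifest:
    """Ordered list of subjects with unique ids and on-disk matrices."""

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")

    def load(self) -> list[SubjectSample]:
        samples = []
        for row in self.rows:
            for p in (row.x_path, row.g_path):
                if not p.exists():
                    raise ValidationError(
                        f"subject {row.subject_id!r}: missing file {p}"
                    )
            samples.append(
                SubjectSample(
                    X=read_matrix(row.x_path),
                    G=read_matrix(row.g_path),
                    label=row.label,
                )
            )
        return samples


def read_manifest(path: str | Path) -> CohortManifest:
    """Parse a ``subject_id,x_path,g_path,label`` CSV (header optional);
    relative paths are resolved against the manifest's directory."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such manifest: {path}")
    base = path.parent
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(",")]
            if lineno == 1 and cells[:1] == ["subject_id"]:
                continue
            if len(cells) != 4:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(cells)} fields, expected 4 "
                    "(subject_id,x_path,g_path,label)"
                )
            sid, xp, gp, label = cells
            rows.append(
                ManifestRow(
                    subject_id=sid,
                    x_path=(base / xp) if not Path(xp).is_absolute() else Path(xp),
                    g_path=(base / gp) if not Path(gp).is_absolute() else Path(gp),
                    label=label,
                )
            )
    return CohortManifest(rows=rows)


def write_cohort(
    samples: Sequence[SubjectSample], out_dir: str | Path
) -> Path:
    """Write each subject's X and G matrices plus a manifest CSV; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with manifest.open("w") as fh:
        fh.write("subject_id,x_path,g_path,label\n")
        for i, s in enumerate(samples):
            sid = f"sub-{i:03d}"
            xname, gname = f"{sid}_timeseries.csv", f"{sid}_fibers.csv"
            write_matrix(s.X, out_dir / xname)
            write_matrix(s.G, out_dir / gname)
            fh.write(f"{sid},{xname},{gname},{s.label}\n")
    return manifest
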