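"""Labeled symmetric intergenomic distance matrices.

Distances are unitless values in [0, 1] of the kind produced by
whole-genome comparison tools (e.g. blast-based genome-to-genome
distances).  They are not assumed to be metric or ultrametric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["DistanceMatrix", "read_distance_matrix", "write_distance_matrix"]

_SYMMETRY_TOL = 1e-9


class DistanceMatrixError(ValueError):
    """Raised when a matrix violates the distance-matrix contract."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Square labeled matrix of pairwise intergenomic distances.

    Parameters
    ----------
    labels
        Ordered genome identifiers, one per row/column. Must be unique.
    values
        ``(n, n)`` array; symmetric within 1e-9, zero diagonal,
        non-negative, no NaN.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DistanceMatrixError(f"matrix must be square, got shape {d.shape}")
        if d.shape[0] != len(labels):
            raise DistanceMatrixError(
                f"{len(labels)} labels but matrix of size {d.shape[0]}"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise DistanceMatrixError(f"duplicate genome labels: {dupes}")
        if np.isnan(d).any():
            raise DistanceMatrixError("matrix contains NaN entries")
        if (d < 0).any():
            raise DistanceMatrixError("matrix contains negative distances")
        if np.abs(d - d.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise DistanceMatrixError("matrix is not symmetric within 1e-9")
        if np.abs(np.diag(d)).max(initial=0.0) > _SYMMETRY_TOL:
            raise DistanceMatrixError("matrix diagonal is not zero")
        # canonical symmetric copy so downstream comparisons are exact
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        d.setflags(write=False)
        object.__setattr__(self, "values", d)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown genome label: {label!r}") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.index(a), self.index(b)])

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle distances as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    @classmethod
    def from_condensed(cls, labels: Sequence[str], condensed: Iterable[float]) -> "DistanceMatrix":
        labels = tuple(labels)
        n = len(labels)
        d = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        d[iu] = np.fromiter(condensed, dtype=float, count=len(iu[0]))
        d = d + d.T
        return cls(labels, d)


def _read_tsv(lines: list[str], path: str) -> DistanceMatrix:
    header = lines[0].rstrip("\n").split("\t")
    labels = header[1:]
    n = len(labels)
    d = np.full((n, n), np.nan)
    rows = [ln for ln in lines[1:] if ln.strip()]
    if len(rows) != n:
        raise DistanceMatrixError(
            f"{path}: header lists {n} genomes but found {len(rows)} data rows"
        )
    for i, ln in enumerate(rows):
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != n + 1:
            raise DistanceMatrixError(
                f"{path}: row {i + 2} has {len(parts) - 1} values, expected {n}"
            )
        if parts[0] != labels[i]:
            raise DistanceMatrixError(
                f"{path}: row label {parts[0]!r} does not match header {labels[i]!r}"
            )
        d[i] = [float(x) for x in parts[1:]]
    return DistanceMatrix(tuple(labels), d)


def _read_phylip(lines: list[str], path: str) -> DistanceMatrix:
    n = int(lines[0].split()[0])
    rows = [ln for ln in lines[1:] if ln.strip()]
    if len(rows) != n:
        raise DistanceMatrixError(
            f"{path}: header declares {n} taxa but found {len(rows)} rows"
        )
    labels: list[str] = []
    d = np.full((n, n), np.nan)
    for i, ln in enumerate(rows):
        parts = ln.split()
        if len(parts) != n + 1:
            raise DistanceMatrixError(
                f"{path}: row {i + 2} has {len(parts) - 1} values, expected {n}"
            )
        labels.append(parts[0])
        d[i] = [float(x) for x in parts[1:]]
    return DistanceMatrix(tuple(labels), d)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a distance matrix, auto-detecting PHYLIP square vs TSV dialect.

    A first line that is a bare integer (optionally padded) marks PHYLIP
    square format; a tab-separated header row of labels marks TSV.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise DistanceMatrixError(f"{path}: empty file")
    first = lines[0].strip()
    if first and all(tok.isdigit() for tok in first.split()) and len(first.split()) == 1:
        return _read_phylip(lines, str(path))
    return _read_tsv(lines, str(path))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write ``dm`` to ``path`` as ``tsv`` or ``phylip`` square format."""
    path = Path(path)
    if fmt == "tsv":
        with path.open("w") as fh:
            fh.write("\t".join(("", *dm.labels)) + "\n")
            for lab, row in zip(dm.labels, dm.values):
                # repr gives the shortest digit string that round-trips exactly
                fh.write(lab + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    elif fmt == "phylip":
        with path.open("w") as fh:
            fh.write(f"{dm.n}\n")
            for lab, row in zip(dm.labels, dm.values):
                fh.write(lab + "  " + "  ".join(repr(float(x)) for x in row) + "\n")
    else:
        raise ValueError(f"unknown distance matrix format: {fmt!r}")
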