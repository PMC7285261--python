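"""Core/soft-core/pangenome partitioning and accumulation curves.

An orthogroup (OG) count matrix — genomes by orthogroups, entries the
number of genes of that genome in the OG — is queried for:

* the *hard core*: OGs present (count >= 1) in every genome;
* a *soft core*: OGs present in at least ``k_min`` genomes;
* the *single-copy core*: OGs with exactly one gene in every genome,
  the usual input to concatenated marker phylogenies;
* resampled accumulation curves: over random genome orderings, the
  running core size, pangenome size and number of newly contributed OGs
  as genomes are added one at a time, summarized by mean and quartiles.

A scaffold-count filter screens fragmented assemblies before pangenome
analysis, since draft genomes in many pieces under-represent gene content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrthoMatrix",
    "GenomeMeta",
    "ScaffoldFilterResult",
    "FractionCurves",
    "filter_by_scaffolds",
    "hard_core",
    "soft_core",
    "single_copy_core",
    "unique_to_one",
    "percent_of_genomes",
    "accumulation_curves",
    "read_orthogroups",
    "write_ortho_counts",
]

#: Genomes split into more scaffolds than this are dropped before
#: pangenome analysis.
DEFAULT_MAX_SCAFFOLDS = 75


@dataclass(frozen=True)
class OrthoMatrix:
    """Genome x orthogroup gene-count matrix.

    ``counts[i, j]`` is the number of genes genome ``genomes[i]``
    contributes to orthogroup ``ogs[j]``; presence means count >= 1.
    Every orthogroup must be present in at least one genome.
    """

    genomes: tuple[str, ...]
    ogs: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        genomes = tuple(str(g) for g in self.genomes)
        ogs = tuple(str(o) for o in self.ogs)
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.mod(c, 1) == 0):
                raise ValueError("orthogroup counts must be integers")
            c = c.astype(np.int64)
        if c.ndim != 2 or c.shape != (len(genomes), len(ogs)):
            raise ValueError(
                f"counts shape {c.shape} does not match "
                f"{len(genomes)} genomes x {len(ogs)} orthogroups"
            )
        if (c < 0).any():
            raise ValueError("orthogroup counts must be non-negative")
        if len(set(genomes)) != len(genomes):
            raise ValueError("duplicate genome labels")
        if len(set(ogs)) != len(ogs):
            raise ValueError("duplicate orthogroup ids")
        empty = [ogs[j] for j in np.flatnonzero(c.sum(axis=0) == 0)]
        if empty:
            raise ValueError(f"orthogroups present in no genome: {empty[:5]}")
        c = c.copy()
        c.setflags(write=False)
        object.__setattr__(self, "genomes", genomes)
        object.__setattr__(self, "ogs", ogs)
        object.__setattr__(self, "counts", c)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_ogs(self) -> int:
        return len(self.ogs)

    def presence(self) -> np.ndarray:
        """Boolean presence matrix (count >= 1)."""
        return self.counts >= 1

    def subset_genomes(self, labels: Sequence[str]) -> "OrthoMatrix":
        """Restrict to ``labels`` (in the given order), dropping now-empty OGs."""
        idx = [self.genomes.index(l) for l in labels]
        sub = self.counts[idx]
        keep = np.flatnonzero(sub.sum(axis=0) > 0)
        return OrthoMatrix(tuple(labels), tuple(self.ogs[j] for j in keep), sub[:, keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.genomes), columns=list(self.ogs))


@dataclass(frozen=True)
class GenomeMeta:
    """Assembly metadata used by the scaffold filter."""

    label: str
    scaffold_count: int

    def __post_init__(self) -> None:
        if self.scaffold_count < 1:
            raise ValueError(f"{self.label}: scaffold_count must be >= 1")


@dataclass(frozen=True)
class ScaffoldFilterResult:
    retained: tuple[str, ...]
    removed: tuple[str, ...]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_by_scaffolds(
    meta: Iterable[GenomeMeta], max_scaffolds: int = DEFAULT_MAX_SCAFFOLDS
) -> ScaffoldFilterResult:
    """Drop genomes assembled into more than ``max_scaffolds`` scaffolds."""
    if max_scaffolds < 1:
        raise ValueError("max_scaffolds must be >= 1")
    retained, removed = [], []
    for m in meta:
        (retained if m.scaffold_count <= max_scaffolds else removed).append(m.label)
    return ScaffoldFilterResult(tuple(retained), tuple(removed))


def _require_nonempty(m: OrthoMatrix) -> None:
    if m.n_genomes == 0:
        raise ValueError("orthogroup matrix has no genomes")


def hard_core(m: OrthoMatrix) -> set[str]:
    """Orthogroups present in every genome."""
    _require_nonempty(m)
    mask = m.presence().all(axis=0)
    return {m.ogs[j] for j in np.flatnonzero(mask)}


def soft_core(m: OrthoMatrix, k_min: int) -> set[str]:
    """Orthogroups present in at least ``k_min`` genomes."""
    _require_nonempty(m)
    if not 1 <= k_min <= m.n_genomes:
        raise ValueError(f"k_min must lie in [1, {m.n_genomes}], got {k_min}")
    mask = m.presence().sum(axis=0) >= k_min
    return {m.ogs[j] for j in np.flatnonzero(mask)}


def single_copy_core(m: OrthoMatrix) -> set[str]:
    """Orthogroups with exactly one gene in every genome."""
    _require_nonempty(m)
    mask = (m.counts == 1).all(axis=0)
    return {m.ogs[j] for j in np.flatnonzero(mask)}


def unique_to_one(m: OrthoMatrix) -> set[str]:
    """Orthogroups present in exactly one genome of the full collection.

    This is the static reading of "strain specific"; the sequential
    reading (new OGs per added genome) is what
    :func:`accumulation_curves` reports as ``new``.
    """
    _require_nonempty(m)
    mask = m.presence().sum(axis=0) == 1
    return {m.ogs[j] for j in np.flatnonzero(mask)}


def percent_of_genomes(k: int, n: int) -> float:
    """Share of ``n`` genomes that ``k`` represents, in percent.

    Rounded half-up to two decimals so printed thresholds such as
    235/237 -> 99.16 and 234/237 -> 98.73 come out exactly.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    frac = Decimal(100 * k) / Decimal(n)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FractionCurves:
    """Genome-fraction accumulation curves over random genome orderings.

    For each replicate ordering and each prefix length ``k``:
    ``core[r, k-1]`` is the intersection size of the first ``k`` OG sets,
    ``pan[r, k-1]`` the union size, and ``new[r, k-1]`` the OGs the k-th
    genome adds to the union.  ``mean``/``q1``/``q3`` summarize the
    replicates at each ``k`` (quartiles by linear interpolation).
    """

    core: np.ndarray = field(repr=False)
    pan: np.ndarray = field(repr=False)
    new: np.ndarray = field(repr=False)
    seed: int | None

    def __post_init__(self) -> None:
        for arr in (self.core, self.pan, self.new):
            arr.setflags(write=False)

    @property
    def n_replicates(self) -> int:
        return self.core.shape[0]

    @property
    def n_genomes(self) -> int:
        return self.core.shape[1]

    def summary(self, fraction: str) -> pd.DataFrame:
        """Per-k mean/q1/q3 for ``fraction`` in {'core', 'pan', 'new'}."""
        arr = {"core": self.core, "pan": self.pan, "new": self.new}[fraction]
        return pd.DataFrame(
            {
                "k": np.arange(1, arr.shape[1] + 1),
                "mean": arr.mean(axis=0),
                "q1": np.quantile(arr, 0.25, axis=0),
                "q3": np.quantile(arr, 0.75, axis=0),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-form table with columns k, fraction, statistic, value."""
        frames = []
        for fraction in ("core", "pan", "new"):
            wide = self.summary(fraction)
            long = wide.melt(id_vars="k", var_name="statistic", value_name="value")
            long.insert(1, "fraction", fraction)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


def accumulation_curves(
    m: OrthoMatrix, n_replicates: int = 300, seed: int | None = None
) -> FractionCurves:
    """Resample genome orderings and trace core/pan/new trajectories.

    Each replicate is a uniform random permutation of the genomes
    (sampling without replacement, so the curves terminate at the full
    collection).  Deterministic under ``seed``.
    """
    _require_nonempty(m)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    pres = m.presence()
    n = m.n_genomes
    core = np.empty((n_replicates, n), dtype=np.int64)
    pan = np.empty((n_replicates, n), dtype=np.int64)
    for r in range(n_replicates):
        perm = rng.permutation(n)
        ordered = pres[perm]
        core[r] = np.logical_and.accumulate(ordered, axis=0).sum(axis=1)
        pan[r] = np.logical_or.accumulate(ordered, axis=0).sum(axis=1)
    new = np.diff(pan, axis=1, prepend=0)
    return FractionCurves(core=core, pan=pan, new=new, seed=seed)


def _looks_numeric(values: Iterable[str]) -> bool:
    for v in values:
        v = v.strip()
        if not v:
            continue
        try:
            float(v)
        except ValueError:
            return False
    return True


def read_orthogroups(path: str | Path) -> OrthoMatrix:
    """Read an orthogroup table, auto-detecting its dialect.

    Two dialects are supported:

    * a numeric count matrix, genomes as rows, orthogroup ids as columns;
    * an OrthoFinder-style membership table, orthogroups as rows, genomes
      as columns, each cell a comma-separated list of gene ids (empty
      cell = absent); counts are the number of gene ids per cell.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    width = len(header)
    cells: list[list[str]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        row = ln.split("\t")
        if len(row) != width:
            raise ValueError(
                f"{path}: line {lineno} has {len(row)} columns, expected {width}"
            )
        cells.append(row)
    if not cells:
        raise ValueError(f"{path}: no data rows")
    body = [c for row in cells for c in row[1:]]
    if _looks_numeric(body):
        genomes = [row[0] for row in cells]
        ogs = header[1:]
        counts = np.array(
            [[int(float(c)) if c.strip() else 0 for c in row[1:]] for row in cells],
            dtype=np.int64,
        )
        return OrthoMatrix(tuple(genomes), tuple(ogs), counts)
    # OrthoFinder-style: orthogroup rows, genome columns, gene-id lists
    ogs = [row[0] for row in cells]
    genomes = header[1:]
    counts = np.zeros((len(genomes), len(ogs)), dtype=np.int64)
    for j, row in enumerate(cells):
        for i, cell in enumerate(row[1:]):
            cell = cell.strip()
            counts[i, j] = len([g for g in cell.split(",") if g.strip()]) if cell else 0
    return OrthoMatrix(tuple(genomes), tuple(ogs), counts)


def write_ortho_counts(m: OrthoMatrix, path: str | Path) -> None:
    """Write the numeric count-matrix dialect (genomes as rows)."""
    m.to_frame().to_csv(path, sep="\t", index_label="genome")
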