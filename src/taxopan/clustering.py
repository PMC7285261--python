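"""Threshold clustering of intergenomic distances and partition agreement.

Genomes are clustered agglomeratively: two clusters merge when at least a
fraction ``f`` of their cross pairs lie within distance ``t``.  With
``f = 0.5`` the criterion behaves like average linkage; ``f = 1`` is
complete linkage and ``f`` approaching 0 single linkage.  Species are
delineated at the distance corresponding to the conventional 70% digital
DNA-DNA hybridization (dDDH) boundary, and phylogenomic groups at a
threshold chosen by sweeping ``t`` against a reference partition and
maximizing a chance-corrected Rand agreement score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .distmat import DistanceMatrix

__all__ = [
    "Partition",
    "SweepResult",
    "DdhRecord",
    "FlaggedPair",
    "SPECIES_DISTANCE_THRESHOLD",
    "DDH_SPECIES_CUTOFF",
    "DEFAULT_LINKAGE_FRACTION",
    "cluster_at_threshold",
    "mri",
    "sweep_thresholds",
    "species_partition",
    "flag_synonyms",
    "read_partition",
    "write_partition",
    "read_ddh_table",
]

#: Intergenomic distance equivalent to 70% dDDH, the conventional
#: prokaryotic species boundary.
SPECIES_DISTANCE_THRESHOLD = 0.036

#: Conventional dDDH species cutoff in percent.
DDH_SPECIES_CUTOFF = 70.0

#: Cross-pair fraction giving average-linkage behaviour.
DEFAULT_LINKAGE_FRACTION = 0.5


@dataclass(frozen=True)
class Partition:
    """Assignment of each genome label to exactly one cluster.

    Cluster ids are canonicalized to 0..k-1 in order of first appearance
    over the sorted label list, so partitions that differ only by cluster
    relabeling compare equal.
    """

    assignment: Mapping[str, int]
    t_used: float | None = None
    f_used: float | None = None

    def __post_init__(self) -> None:
        raw = dict(self.assignment)
        remap: dict[object, int] = {}
        canon: dict[str, int] = {}
        for label in sorted(raw):
            cid = raw[label]
            if cid not in remap:
                remap[cid] = len(remap)
            canon[label] = remap[cid]
        object.__setattr__(self, "assignment", canon)

    @classmethod
    def from_clusters(
        cls,
        clusters: Iterable[Iterable[str]],
        t_used: float | None = None,
        f_used: float | None = None,
    ) -> "Partition":
        assignment: dict[str, int] = {}
        for cid, members in enumerate(clusters):
            for label in members:
                if label in assignment:
                    raise ValueError(f"label {label!r} assigned to more than one cluster")
                assignment[label] = cid
        return cls(assignment, t_used=t_used, f_used=f_used)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.assignment))

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> list[frozenset[str]]:
        """Clusters as frozensets, ordered by canonical cluster id."""
        out: dict[int, set[str]] = {}
        for label, cid in self.assignment.items():
            out.setdefault(cid, set()).add(label)
        return [frozenset(out[cid]) for cid in sorted(out)]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters()]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.assignment == other.assignment

    def __hash__(self) -> int:
        return hash(frozenset(self.assignment.items()))

    def refines(self, other: "Partition") -> bool:
        """True when every cluster of ``self`` lies inside one cluster of ``other``."""
        if set(self.assignment) != set(other.assignment):
            return False
        parent: dict[int, int] = {}
        for label, cid in self.assignment.items():
            oid = other.assignment[label]
            if parent.setdefault(cid, oid) != oid:
                return False
        return True


@dataclass(frozen=True)
class SweepResult:
    """Result of sweeping the clustering threshold against a reference."""

    grid: np.ndarray = field(repr=False)
    mri: np.ndarray = field(repr=False)
    n_clusters: np.ndarray = field(repr=False)
    optimal_range: tuple[float, float]
    optimal_mri: float

    def optimal_thresholds(self) -> np.ndarray:
        """Grid points attaining the maximum agreement."""
        return self.grid[self.mri >= self.optimal_mri]


@dataclass(frozen=True)
class DdhRecord:
    """One pairwise dDDH estimate with its confidence interval (percent)."""

    genome_a: str
    genome_b: str
    ddh_percent: float
    ci_lo: float
    ci_hi: float
    prob_same_species: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lo <= self.ddh_percent <= self.ci_hi <= 100.0):
            raise ValueError(
                f"{self.genome_a}/{self.genome_b}: inconsistent dDDH bounds "
                f"{self.ci_lo} <= {self.ddh_percent} <= {self.ci_hi}"
            )
        if not (0.0 <= self.prob_same_species <= 100.0):
            raise ValueError("prob_same_species must lie in [0, 100]")


@dataclass(frozen=True)
class FlaggedPair:
    """A genome pair whose dDDH exceeds the species cutoff."""

    record: DdhRecord
    ci_entirely_above: bool


def _validate_tf(t: float, f: float) -> None:
    if t < 0:
        raise ValueError(f"threshold t must be non-negative, got {t}")
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"linkage fraction f must lie in [0, 1], got {f}")


def cluster_at_threshold(dm: DistanceMatrix, t: float, f: float = DEFAULT_LINKAGE_FRACTION) -> Partition:
    """Agglomerative threshold clustering with cross-pair fraction linkage.

    Starting from singletons, a pair of clusters (A, B) is mergeable when
    the fraction of cross pairs with d(a, b) <= ``t`` is at least ``f``.
    Among mergeable pairs the one with the smallest mean cross distance is
    merged first; exact ties are broken by the lexicographically smallest
    member label of the two clusters.  Merging repeats until no pair is
    mergeable, which makes the result deterministic.
    """
    _validate_tf(t, f)
    n = dm.n
    d = dm.values
    if n == 1:
        return Partition({dm.labels[0]: 0}, t_used=t, f_used=f)

    # incremental cross-pair statistics per live cluster pair
    cnt = (d <= t).astype(float)
    np.fill_diagonal(cnt, 0.0)
    tot = d.copy()
    size = np.ones(n)
    alive = np.ones(n, dtype=bool)
    minlab: list[str] = list(dm.labels)
    members: list[list[int]] = [[i] for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)

    while alive.sum() > 1:
        pair_alive = alive[iu] & alive[ju]
        npairs = size[iu] * size[ju]
        with np.errstate(invalid="ignore"):
            frac = cnt[iu, ju] / npairs
        mergeable = pair_alive & (frac >= f)
        if not mergeable.any():
            break
        mean = np.where(mergeable, tot[iu, ju] / npairs, np.inf)
        best = mean.min()
        cand = np.flatnonzero(mean == best)
        # lexicographic tie-break on the smallest member labels of each pair
        key = min(
            cand,
            key=lambda k: tuple(sorted((minlab[iu[k]], minlab[ju[k]]))),
        )
        a, b = int(iu[key]), int(ju[key])
        cnt[a, :] += cnt[b, :]
        cnt[:, a] = cnt[a, :]
        tot[a, :] += tot[b, :]
        tot[:, a] = tot[a, :]
        cnt[a, a] = tot[a, a] = 0.0
        size[a] += size[b]
        alive[b] = False
        minlab[a] = min(minlab[a], minlab[b])
        members[a].extend(members[b])

    assignment: dict[str, int] = {}
    for cid, root in enumerate(np.flatnonzero(alive)):
        for idx in members[root]:
            assignment[dm.labels[idx]] = cid
    return Partition(assignment, t_used=t, f_used=f)


def _pair_sum(counts: Iterable[int]) -> int:
    return sum(c * (c - 1) // 2 for c in counts)


def mri(p: Partition, q: Partition) -> float:
    """Chance-corrected Rand agreement between two partitions.

    Uses the Hubert-Arabie adjustment computed from the pairwise
    contingency table: 1 means identical partitions up to relabeling, 0
    is the expectation under random independent partitions, and negative
    values indicate less agreement than chance.  Symmetric in its
    arguments.
    """
    lp, lq = set(p.assignment), set(q.assignment)
    if lp != lq:
        missing = sorted(lp ^ lq)
        raise ValueError(f"partitions cover different label sets; mismatched: {missing}")
    n = len(lp)
    contingency: dict[tuple[int, int], int] = {}
    for label in lp:
        key = (p.assignment[label], q.assignment[label])
        contingency[key] = contingency.get(key, 0) + 1
    a = _pair_sum(contingency.values())
    row: dict[int, int] = {}
    col: dict[int, int] = {}
    for (i, j), c in contingency.items():
        row[i] = row.get(i, 0) + c
        col[j] = col.get(j, 0) + c
    sum_row = _pair_sum(row.values())
    sum_col = _pair_sum(col.values())
    total = n * (n - 1) // 2
    if total == 0:
        return 1.0
    expected = sum_row * sum_col / total
    maximum = (sum_row + sum_col) / 2.0
    if maximum == expected:
        # both partitions are all-singletons or a single cluster: identical
        return 1.0
    return (a - expected) / (maximum - expected)


def sweep_thresholds(
    dm: DistanceMatrix,
    ref: Partition,
    t_min: float = 0.0,
    t_max: float = 0.2,
    step: float = 0.0005,
    f: float = DEFAULT_LINKAGE_FRACTION,
) -> SweepResult:
    """Sweep the clustering threshold and score agreement with ``ref``.

    The grid runs from ``t_min`` to ``t_max`` inclusive (when ``t_max``
    lies on the grid), built as integer index times ``step`` to avoid
    floating-point drift; the defaults give 401 points.  ``optimal_range``
    is the [min, max] of the thresholds attaining the maximal agreement.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not t_min < t_max:
        raise ValueError("t_min must be below t_max")
    n_steps = int(math.floor((t_max - t_min) / step + 1e-9))
    grid = t_min + step * np.arange(n_steps + 1)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    scores = np.empty(grid.size)
    ncl = np.empty(grid.size, dtype=int)
    for k, t in enumerate(grid):
        part = cluster_at_threshold(dm, float(t), f)
        scores[k] = mri(part, ref)
        ncl[k] = part.n_clusters
    best = scores.max()
    at_best = grid[scores == best]
    return SweepResult(
        grid=grid,
        mri=scores,
        n_clusters=ncl,
        optimal_range=(float(at_best.min()), float(at_best.max())),
        optimal_mri=float(best),
    )


def species_partition(dm: DistanceMatrix, f: float = DEFAULT_LINKAGE_FRACTION) -> Partition:
    """Delineate species-level clusters at the 70% dDDH distance (0.036)."""
    return cluster_at_threshold(dm, SPECIES_DISTANCE_THRESHOLD, f)


def flag_synonyms(
    records: Sequence[DdhRecord], cutoff: float = DDH_SPECIES_CUTOFF
) -> list[FlaggedPair]:
    """Flag genome pairs whose dDDH exceeds the species cutoff.

    Pairs above the cutoff indicate candidate synonymous species; each
    flag also records whether the whole confidence interval clears the
    cutoff (a stronger signal than a straddling interval).
    """
    if not (0.0 <= cutoff <= 100.0):
        raise ValueError(f"cutoff must lie in [0, 100], got {cutoff}")
    return [
        FlaggedPair(record=r, ci_entirely_above=r.ci_lo > cutoff)
        for r in records
        if r.ddh_percent > cutoff
    ]


def write_partition(p: Partition, path: str | Path) -> None:
    """Write a two-column TSV ``genome<TAB>cluster_id``."""
    with Path(path).open("w") as fh:
        fh.write("genome\tcluster\n")
        for label in p.labels:
            fh.write(f"{label}\t{p.assignment[label]}\n")


def read_partition(path: str | Path) -> Partition:
    """Read a two-column TSV partition, skipping an optional header."""
    raw: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        if lineno == 1 and parts[0].lower() in {"genome", "label"}:
            continue
        label, cid = parts
        if label in raw:
            raise ValueError(f"{path}:{lineno}: duplicate genome label {label!r}")
        raw[label] = cid
    ids = {cid: k for k, cid in enumerate(dict.fromkeys(raw.values()))}
    assignment = {label: ids[cid] for label, cid in raw.items()}
    if not assignment:
        raise ValueError(f"{path}: no partition rows found")
    return Partition(assignment)


def read_ddh_table(path: str | Path) -> list[DdhRecord]:
    """Read a dDDH table TSV with columns genome_a, genome_b, ddh, ci_lo, ci_hi, prob_same_species."""
    records: list[DdhRecord] = []
    lines = Path(path).read_text().splitlines()
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if lineno == 1 and parts[0].lower() in {"genome_a", "a"}:
            continue
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        records.append(
            DdhRecord(
                genome_a=parts[0],
                genome_b=parts[1],
                ddh_percent=float(parts[2]),
                ci_lo=float(parts[3]),
                ci_hi=float(parts[4]),
                prob_same_species=float(parts[5]),
            )
        )
    return records
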