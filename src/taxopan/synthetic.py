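"""Synthetic genome collections with known cluster and pangenome structure.

Generates everything the analysis pipeline consumes — a pairwise
intergenomic distance matrix, an orthogroup count matrix, trait
orthogroups and the ground-truth species/group partitions — for a
hierarchical collection: genomes nested in species nested in
phylogenomic groups.

Distances are drawn i.i.d. uniform from three strictly separated
ranges (within species < within group < between groups) and
symmetrized; no metricity is enforced, since real whole-genome blast
distances are not guaranteed metric either.  The separation means
threshold clustering at any value inside a gap recovers the generating
partition exactly, which is what the downstream recovery tests exploit.

Orthogroup content has three compartments: a hard core present in every
genome, a per-group shell sampled per genome with a fixed presence
probability and absent outside its group, and a per-genome cloud of
unique orthogroups (Poisson-distributed count), so that
hard core << soft core << pangenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .clustering import Partition, write_partition
from .distmat import DistanceMatrix, write_distance_matrix
from .pangenome import OrthoMatrix, write_ortho_counts
from .traits import write_trait_map

__all__ = ["CollectionParams", "SyntheticCollection", "simulate_collection", "write_collection"]

Range = tuple[float, float]


def _as_range(v) -> tuple[int, int]:
    if isinstance(v, int):
        return (v, v)
    lo, hi = int(v[0]), int(v[1])
    return (lo, hi)


@dataclass(frozen=True)
class CollectionParams:
    """Parameters of a synthetic genome collection.

    Counts may be a single int or an inclusive ``(lo, hi)`` range drawn
    per group/species.  The three distance ranges must be strictly
    ordered and non-overlapping so that ground-truth partitions are
    recoverable by thresholding.
    """

    n_groups: int = 10
    species_per_group: int | tuple[int, int] = 2
    genomes_per_species: int | tuple[int, int] = 3
    d_within_species: Range = (0.005, 0.03)
    d_within_group: Range = (0.05, 0.12)
    d_between_group: Range = (0.17, 0.40)
    n_core_ogs: int = 300
    shell_ogs_per_group: int = 40
    shell_presence_prob: float = 0.7
    cloud_rate: float = 30.0
    trait_ogs: Mapping[str, frozenset[int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        for name in ("species_per_group", "genomes_per_species"):
            lo, hi = _as_range(getattr(self, name))
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be >= 1 (or a valid range)")
        for name in ("d_within_species", "d_within_group", "d_between_group"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo < hi:
                raise ValueError(f"{name} must satisfy 0 <= lo < hi, got ({lo}, {hi})")
        if not self.d_within_species[1] < self.d_within_group[0]:
            raise ValueError(
                "distance ranges overlap: within-species "
                f"{self.d_within_species} must lie strictly below within-group "
                f"{self.d_within_group}"
            )
        if not self.d_within_group[1] < self.d_between_group[0]:
            raise ValueError(
                "distance ranges overlap: within-group "
                f"{self.d_within_group} must lie strictly below between-group "
                f"{self.d_between_group}"
            )
        if self.n_core_ogs < 1:
            raise ValueError("n_core_ogs must be >= 1")
        if self.shell_ogs_per_group < 0:
            raise ValueError("shell_ogs_per_group must be >= 0")
        if not 0.0 <= self.shell_presence_prob <= 1.0:
            raise ValueError("shell_presence_prob must lie in [0, 1]")
        if self.cloud_rate < 0:
            raise ValueError("cloud_rate must be >= 0")
        bad = [
            t
            for t, gs in self.trait_ogs.items()
            if not gs or any(not 0 <= g < self.n_groups for g in gs)
        ]
        if bad:
            raise ValueError(f"trait groups out of range [0, {self.n_groups}): {bad}")


@dataclass(frozen=True)
class SyntheticCollection:
    """A simulated genome collection plus its generating ground truth."""

    distances: DistanceMatrix
    ortho: OrthoMatrix
    truth_species: Partition
    truth_groups: Partition
    trait_map: dict[str, list[str]]
    params: CollectionParams

    def __post_init__(self) -> None:
        if not self.truth_species.refines(self.truth_groups):
            raise ValueError("truth_species must refine truth_groups")
        if set(self.distances.labels) != set(self.ortho.genomes):
            raise ValueError("distance and orthogroup labels differ")


def _draw_count(rng: np.random.Generator, spec: int | tuple[int, int]) -> int:
    lo, hi = _as_range(spec)
    return int(rng.integers(lo, hi + 1)) if hi > lo else lo


def simulate_collection(params: CollectionParams) -> SyntheticCollection:
    """Simulate a genome collection under ``params``; deterministic per seed."""
    ss = np.random.SeedSequence(params.seed)
    rng_layout, rng_dist, rng_shell, rng_cloud = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # --- layout: genome labels and their species / group ids -------------
    labels: list[str] = []
    species_of: list[int] = []
    group_of: list[int] = []
    species_counter = 0
    for g in range(params.n_groups):
        n_species = _draw_count(rng_layout, params.species_per_group)
        for s in range(n_species):
            n_genomes = _draw_count(rng_layout, params.genomes_per_species)
            for r in range(n_genomes):
                labels.append(f"g{g + 1:02d}s{s + 1:02d}r{r + 1:02d}")
                species_of.append(species_counter)
                group_of.append(g)
            species_counter += 1
    n = len(labels)
    if n == 0:
        raise ValueError("collection has zero genomes")
    sp = np.array(species_of)
    gr = np.array(group_of)

    # --- distances: one uniform draw per unordered pair -------------------
    d = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    same_species = sp[iu] == sp[ju]
    same_group = gr[iu] == gr[ju]
    vals = np.empty(iu.size)
    for mask, (lo, hi) in (
        (same_species, params.d_within_species),
        (~same_species & same_group, params.d_within_group),
        (~same_group, params.d_between_group),
    ):
        vals[mask] = rng_dist.uniform(lo, hi, size=int(mask.sum()))
    d[iu, ju] = vals
    d = d + d.T
    distances = DistanceMatrix(tuple(labels), d)

    # --- orthogroup content -----------------------------------------------
    og_ids: list[str] = []
    columns: list[np.ndarray] = []

    for k in range(params.n_core_ogs):
        og_ids.append(f"core{k + 1:05d}")
        columns.append(np.ones(n, dtype=np.int64))

    def _shell_column(group_members: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        col = np.zeros(n, dtype=np.int64)
        hit = rng.random(group_members.size) < params.shell_presence_prob
        if not hit.any():  # keep the column non-empty
            hit[rng.integers(group_members.size)] = True
        col[group_members[hit]] = 1
        return col

    for g in range(params.n_groups):
        members = np.flatnonzero(gr == g)
        for k in range(params.shell_ogs_per_group):
            og_ids.append(f"shell_g{g + 1:02d}_{k + 1:04d}")
            columns.append(_shell_column(members, rng_shell))

    trait_map: dict[str, list[str]] = {}
    for trait in sorted(params.trait_ogs):
        og = f"trait_{trait}"
        col = np.zeros(n, dtype=np.int64)
        for g in sorted(params.trait_ogs[trait]):
            col += _shell_column(np.flatnonzero(gr == g), rng_shell)
        og_ids.append(og)
        columns.append(col)
        trait_map[trait] = [og]

    for i, label in enumerate(labels):
        n_cloud = int(rng_cloud.poisson(params.cloud_rate))
        for k in range(n_cloud):
            og_ids.append(f"cloud_{label}_{k + 1:04d}")
            col = np.zeros(n, dtype=np.int64)
            col[i] = 1
            columns.append(col)

    ortho = OrthoMatrix(tuple(labels), tuple(og_ids), np.column_stack(columns))

    truth_species = Partition({lab: int(s) for lab, s in zip(labels, sp)})
    truth_groups = Partition({lab: int(g) for lab, g in zip(labels, gr)})
    return SyntheticCollection(
        distances=distances,
        ortho=ortho,
        truth_species=truth_species,
        truth_groups=truth_groups,
        trait_map=trait_map,
        params=params,
    )


def write_collection(coll: SyntheticCollection, directory: str | Path) -> dict[str, Path]:
    """Write the collection as plain-text files; returns a file manifest.

    Emits the distance matrix in both PHYLIP square and TSV form, the
    orthogroup count matrix, the two truth partitions and the trait map;
    each file round-trips through the corresponding reader.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "distances_phylip": directory / "distances.phy",
        "distances_tsv": directory / "distances.tsv",
        "ortho_counts": directory / "ortho_counts.tsv",
        "truth_species": directory / "truth_species.tsv",
        "truth_groups": directory / "truth_groups.tsv",
        "trait_map": directory / "trait_map.tsv",
    }
    write_distance_matrix(coll.distances, manifest["distances_phylip"], fmt="phylip")
    write_distance_matrix(coll.distances, manifest["distances_tsv"], fmt="tsv")
    write_ortho_counts(coll.ortho, manifest["ortho_counts"])
    write_partition(coll.truth_species, manifest["truth_species"])
    write_partition(coll.truth_groups, manifest["truth_groups"])
    write_trait_map(coll.trait_map, manifest["trait_map"])
    return manifest
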