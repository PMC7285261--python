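"""Trait-distribution profiling across phylogenomic groups.

Given an orthogroup count matrix, a group partition and a list of
trait-associated orthogroups (e.g. ring-hydroxylating dioxygenase
subunits, alkane monooxygenases), computes the fraction of genomes in
each group carrying each orthogroup — the heatmap cells of a
trait-distribution figure — orders heatmap rows and columns by
average-linkage hierarchical clustering, counts orthologs of a gene
family per genome, and deduplicates identical protein sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .clustering import Partition
from .pangenome import OrthoMatrix

__all__ = [
    "TraitProfile",
    "trait_fractions",
    "ortholog_counts",
    "heatmap_order",
    "dedupe_sequences",
    "read_trait_map",
    "write_trait_map",
]


@dataclass(frozen=True)
class TraitProfile:
    """Groups x traits matrix of presence fractions in [0, 1].

    ``fraction[i, j]`` is the share of genomes in group ``groups[i]``
    that carry orthogroup ``traits[j]`` (count >= 1); 1 means present in
    every genome of the group, 0 absent from all.
    """

    groups: tuple[int, ...]
    traits: tuple[str, ...]
    fraction: np.ndarray = field(repr=False)
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        self.fraction.setflags(write=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fraction,
            index=pd.Index(list(self.groups), name="group"),
            columns=list(self.traits),
        )


def trait_fractions(
    m: OrthoMatrix, groups: Partition, trait_ogs: Sequence[str]
) -> TraitProfile:
    """Per-group presence fraction of each trait orthogroup."""
    if not trait_ogs:
        raise ValueError("trait_ogs is empty")
    unknown = [og for og in trait_ogs if og not in m.ogs]
    if unknown:
        raise KeyError(f"orthogroups not in matrix: {unknown}")
    missing = sorted(set(groups.assignment) ^ set(m.genomes))
    if missing:
        raise KeyError(f"partition and matrix disagree on genomes: {missing}")
    og_idx = [m.ogs.index(og) for og in trait_ogs]
    pres = m.presence()[:, og_idx]
    gen_idx = {g: i for i, g in enumerate(m.genomes)}
    clusters = groups.clusters()
    frac = np.empty((len(clusters), len(trait_ogs)))
    sizes = []
    for gi, members in enumerate(clusters):
        rows = [gen_idx[g] for g in members]
        frac[gi] = pres[rows].mean(axis=0)
        sizes.append(len(rows))
    return TraitProfile(
        groups=tuple(range(len(clusters))),
        traits=tuple(trait_ogs),
        fraction=frac,
        group_sizes=tuple(sizes),
    )


def ortholog_counts(m: OrthoMatrix, og_family: Sequence[str]) -> pd.Series:
    """Total gene count per genome over a family of orthogroups.

    The per-genome totals of e.g. all Rieske 2Fe-2S dioxygenase
    orthogroups are the heights of a per-genome ortholog barplot.
    """
    if not og_family:
        raise ValueError("og_family is empty")
    unknown = [og for og in og_family if og not in m.ogs]
    if unknown:
        raise KeyError(f"orthogroups not in matrix: {unknown}")
    idx = [m.ogs.index(og) for og in og_family]
    totals = m.counts[:, idx].sum(axis=1)
    return pd.Series(totals, index=list(m.genomes), name="orthologs")


def _leaf_order(values: np.ndarray, names: Sequence) -> list:
    if len(names) <= 1:
        return list(names)
    order = np.argsort(np.asarray(names, dtype=object))  # lexicographic tie-break
    values = values[order]
    names = [names[i] for i in order]
    z = linkage(pdist(values, metric="euclidean"), method="average")
    return [names[i] for i in leaves_list(z)]


def heatmap_order(profile: TraitProfile) -> tuple[list[int], list[str]]:
    """Row (group) and column (trait) orderings for a clustered heatmap.

    Average-linkage agglomerative clustering on Euclidean distances,
    rows and columns independently; the ordering is the left-to-right
    dendrogram leaf order, with inputs pre-sorted lexicographically so
    ties resolve deterministically.
    """
    rows = _leaf_order(profile.fraction, list(profile.groups))
    cols = _leaf_order(profile.fraction.T, list(profile.traits))
    return rows, cols


def dedupe_sequences(
    records: Iterable[SeqRecord],
) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Collapse identical protein sequences, keeping the first-seen record.

    Identity is exact string match on residues, case-insensitive; gaps
    and stop characters are compared literally.  Returns the unique
    records and a map from each retained id to all original ids sharing
    its sequence, so the sum of multiplicities equals the input count.
    """
    unique: list[SeqRecord] = []
    by_seq: dict[str, str] = {}
    multiplicity: dict[str, list[str]] = {}
    seen_ids: set[str] = set()
    count = 0
    for rec in records:
        count += 1
        if rec.id in seen_ids:
            warnings.warn(f"duplicate sequence header {rec.id!r}", stacklevel=2)
        seen_ids.add(rec.id)
        key = str(rec.seq).upper()
        if key in by_seq:
            multiplicity[by_seq[key]].append(rec.id)
        else:
            by_seq[key] = rec.id
            multiplicity[rec.id] = [rec.id]
            unique.append(rec)
    if count == 0:
        raise ValueError("no sequences to deduplicate")
    return unique, multiplicity


def dedupe_fasta(path: str | Path, out: str | Path | None = None):
    """Deduplicate a FASTA file; optionally write the unique records."""
    unique, multiplicity = dedupe_sequences(SeqIO.parse(str(path), "fasta"))
    if out is not None:
        SeqIO.write(unique, str(out), "fasta")
    return unique, multiplicity


def read_trait_map(path: str | Path) -> dict[str, list[str]]:
    """Read a TSV ``trait<TAB>orthogroup_id`` into trait -> OG ids."""
    out: dict[str, list[str]] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        if lineno == 1 and parts[0].lower() == "trait":
            continue
        out.setdefault(parts[0], []).append(parts[1])
    return out


def write_trait_map(trait_map: dict[str, Sequence[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("trait\torthogroup\n")
        for trait in sorted(trait_map):
            for og in trait_map[trait]:
                fh.write(f"{trait}\t{og}\n")
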