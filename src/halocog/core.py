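"""Shared domain types: protein records, genome sets, clusters, alignments,
phyletic matrices, and the BLOSUM62 scoring table used throughout.

Conventions
-----------
* Protein headers are ``<genome>|<protein-id>``; protein ids are unique
  across a :class:`GenomeSet`.
* Alignments use ``-`` as the gap character; degapping an MSA row must
  reproduce the member sequence exactly.
* Phyletic matrices are pandas DataFrames with family ids as the index and
  genome ids as columns; presence means copy count >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from biotite.sequence.align import SubstitutionMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_BIOTITE_B62 = SubstitutionMatrix.std_protein_matrix()


def _build_blosum62() -> np.ndarray:
    m = np.zeros((20, 20), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = _BIOTITE_B62.get_score(a, b)
    return m


#: BLOSUM62 over the 20 canonical residues, ordered as AMINO_ACIDS.
BLOSUM62 = _build_blosum62()


def blosum62_score(a: str, b: str) -> float:
    """BLOSUM62 score between two residues (``X`` etc. fall back to the
    full biotite table)."""
    try:
        return BLOSUM62[_AA_INDEX[a], _AA_INDEX[b]]
    except KeyError:
        return float(_BIOTITE_B62.get_score(a, b))


def aa_index(residue: str) -> int:
    return _AA_INDEX[residue]


@dataclass(frozen=True, order=True)
class ProteinRecord:
    """A single protein sequence tagged with its source genome."""

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")

    @property
    def header(self) -> str:
        return f"{self.genome_id}|{self.protein_id}"


class GenomeSet:
    """Proteins grouped by genome; the raw material for clustering."""

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records: list[ProteinRecord] = sorted(
            records, key=lambda r: r.protein_id
        )
        self.by_id: dict[str, ProteinRecord] = {}
        self.by_genome: dict[str, list[ProteinRecord]] = {}
        for r in self.records:
            if r.protein_id in self.by_id:
                raise ValueError(f"duplicate protein id {r.protein_id!r}")
            self.by_id[r.protein_id] = r
            self.by_genome.setdefault(r.genome_id, []).append(r)

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.by_genome)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genome_of(self, protein_id: str) -> str:
        return self.by_id[protein_id].genome_id


@dataclass
class MSA:
    """A gapped multiple alignment: ordered ids plus equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("MSA rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def to_array(self) -> np.ndarray:
        """(n_rows, n_columns) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def take_columns(self, keep: Iterable[int]) -> "MSA":
        keep = list(keep)
        return MSA(
            ids=list(self.ids),
            rows=["".join(r[j] for j in keep) for r in self.rows],
        )


@dataclass
class Cluster:
    """An orthologous group: member proteins plus an optional alignment."""

    cluster_id: str
    members: tuple[ProteinRecord, ...]
    alignment: MSA | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        self.members = tuple(sorted(self.members, key=lambda r: r.protein_id))

    @property
    def member_ids(self) -> list[str]:
        return [m.protein_id for m in self.members]

    @property
    def genome_ids(self) -> set[str]:
        return {m.genome_id for m in self.members}

    @property
    def copy_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            counts[m.genome_id] = counts.get(m.genome_id, 0) + 1
        return counts

    @property
    def size(self) -> int:
        return len(self.members)

    def with_alignment(self, msa: MSA) -> "Cluster":
        return replace(self, alignment=msa)

    def member_key(self) -> tuple[str, ...]:
        return tuple(self.member_ids)


@dataclass
class ClusterSet:
    """All non-singleton clusters plus the excluded singleton proteins."""

    clusters: list[Cluster] = field(default_factory=list)
    singletons: list[ProteinRecord] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    def relabel(self) -> "ClusterSet":
        """Assign deterministic ids C00001... ordered by smallest member id."""
        ordered = sorted(self.clusters, key=lambda c: c.member_ids[0])
        clusters = [
            replace(c, cluster_id=f"C{i + 1:05d}") for i, c in enumerate(ordered)
        ]
        return ClusterSet(
            clusters=clusters,
            singletons=sorted(self.singletons, key=lambda r: r.protein_id),
        )

    def by_id(self) -> dict[str, Cluster]:
        return {c.cluster_id: c for c in self.clusters}


class PhyleticMatrix:
    """Clusters-by-genomes copy-count matrix with a binarised view."""

    def __init__(self, df: pd.DataFrame):
        if (df.values < 0).any():
            raise ValueError("phyletic matrix contains negative counts")
        self.df = df.astype(int)

    @property
    def family_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_families(self) -> int:
        return self.df.shape[0]

    def binarized(self) -> pd.DataFrame:
        return (self.df >= 1).astype(int)

    def presence(self, family_id: str) -> pd.Series:
        return (self.df.loc[family_id] >= 1).astype(int)

    @classmethod
    def from_clusters(
        cls, clusters: ClusterSet, genome_ids: Iterable[str]
    ) -> "PhyleticMatrix":
        genome_ids = sorted(genome_ids)
        rows = {}
        for c in clusters.clusters:
            counts = c.copy_counts
            rows[c.cluster_id] = [counts.get(g, 0) for g in genome_ids]
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=genome_ids, dtype=int
        )
        df = df.sort_index()
        return cls(df)

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, str], int], families, genomes
    ) -> "PhyleticMatrix":
        df = pd.DataFrame(0, index=list(families), columns=list(genomes))
        for (f, g), c in counts.items():
            df.loc[f, g] = c
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, PhyleticMatrix) and self.df.equals(other.df)
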