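"""Universal-marker selection and supermatrix construction.

Selects clusters present in every genome with a bounded number of extra
paralogs, picks one index ortholog per genome by BLOSUM62 score against
the alignment consensus, filters alignment columns by gap fraction and
homogeneity, and concatenates the surviving columns into a partitioned
supermatrix suitable for species-tree inference with external ML tools.

Homogeneity of a column with consensus residue ``c`` is the mean over its
non-gap residues ``r`` of ``BLOSUM62(r, c) / BLOSUM62(c, c)`` — a score of
1 means the column is pure consensus, values near 0 mean the average
residue is unrelated to the consensus. The default threshold 0.05 removes
columns with essentially no conservation signal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .core import GAP, MSA, Cluster, PhyleticMatrix, blosum62_score


@dataclass
class MarkerSelection:
    cluster_ids: list[str]
    n_genomes_required: int
    max_extra_paralogs: int


@dataclass
class FilterReport:
    kept: int
    removed: int


@dataclass
class Supermatrix:
    """Concatenated marker alignment, one row per genome."""

    genome_ids: list[str]
    rows: dict[str, str]  # genome -> concatenated gapped sequence
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)
    # partitions: cluster_id -> half-open, 0-based column interval

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def select_markers(
    matrix: PhyleticMatrix,
    n_genomes: int | None = None,
    max_extra_paralogs: int = 4,
    per_genome: bool = False,
) -> MarkerSelection:
    """Clusters with the full genome complement and few extra paralogs.

    With ``per_genome=False`` (default) a cluster qualifies when every
    genome has >= 1 copy and the total copy count exceeds the genome count
    by at most ``max_extra_paralogs``; with ``per_genome=True`` the bound
    applies to each genome's own extra copies instead.
    """
    genomes = matrix.genome_ids
    if n_genomes is None:
        n_genomes = len(genomes)
    if n_genomes != len(genomes):
        raise ValueError(
            f"matrix has {len(genomes)} genomes, full complement requires "
            f"{n_genomes}"
        )
    df = matrix.df
    full = (df >= 1).all(axis=1)
    if per_genome:
        ok = (df - 1).max(axis=1) <= max_extra_paralogs
    else:
        ok = (df.sum(axis=1) - n_genomes) <= max_extra_paralogs
    selected = sorted(df.index[full & ok])
    return MarkerSelection(selected, n_genomes, max_extra_paralogs)


def consensus(msa: MSA) -> str:
    """Per-column majority residue; ties alphabetical; all-gap gives gap."""
    if msa.n_rows == 0:
        raise ValueError("empty MSA")
    out = []
    for j in range(msa.n_columns):
        residues = [c for c in msa.column(j) if c != GAP]
        if not residues:
            out.append(GAP)
            continue
        counts = Counter(residues)
        top = max(counts.values())
        out.append(min(r for r, c in counts.items() if c == top))
    return "".join(out)


def consensus_score(row: str, cons: str) -> float:
    """Sum of BLOSUM62(residue, consensus) over columns where neither is
    a gap; gap columns contribute 0."""
    s = 0.0
    for r, c in zip(row, cons):
        if r != GAP and c != GAP:
            s += blosum62_score(r, c)
    return s


def select_index_ortholog(cluster: Cluster, genome_id: str) -> str:
    """The genome's member scoring highest against the cluster consensus.

    Ties go to the lexicographically smallest protein id.
    """
    if cluster.alignment is None:
        raise ValueError(f"cluster {cluster.cluster_id} is not aligned")
    members = [m for m in cluster.members if m.genome_id == genome_id]
    if not members:
        raise ValueError(
            f"genome {genome_id!r} absent from cluster {cluster.cluster_id}"
        )
    if len(members) == 1:
        return members[0].protein_id
    cons = consensus(cluster.alignment)
    scored = [
        (-consensus_score(cluster.alignment.row(m.protein_id), cons),
         m.protein_id)
        for m in members
    ]
    return min(scored)[1]


def column_homogeneity(column: str, consensus_residue: str) -> float:
    """Consensus-normalised mean BLOSUM62 score of a column; <= 1."""
    residues = [c for c in column if c != GAP]
    if not residues or consensus_residue == GAP:
        return 0.0
    denom = blosum62_score(consensus_residue, consensus_residue)
    return sum(
        blosum62_score(r, consensus_residue) for r in residues
    ) / (denom * len(residues))


def filter_columns(
    msa: MSA,
    max_gap_fraction: float = 0.667,
    min_homogeneity: float = 0.05,
) -> tuple[MSA, FilterReport]:
    """Keep columns with gap fraction <= ``max_gap_fraction`` and
    homogeneity >= ``min_homogeneity``; column order preserved."""
    if msa.n_rows == 0:
        raise ValueError("empty MSA")
    cons = consensus(msa)
    keep = []
    for j in range(msa.n_columns):
        col = msa.column(j)
        gap_fraction = col.count(GAP) / len(col)
        if gap_fraction > max_gap_fraction:
            continue
        if column_homogeneity(col, cons[j]) < min_homogeneity:
            continue
        keep.append(j)
    report = FilterReport(kept=len(keep), removed=msa.n_columns - len(keep))
    if not keep:
        warnings.warn("all columns removed by filtering", stacklevel=2)
    return msa.take_columns(keep), report


def concatenate(
    selection: MarkerSelection,
    msas: dict[str, MSA],
    index_map: dict[tuple[str, str], str],
    genome_ids: list[str],
) -> Supermatrix:
    """Concatenate index-ortholog rows of filtered marker MSAs.

    ``index_map`` maps (cluster_id, genome_id) to the chosen protein id.
    Clusters are concatenated in sorted cluster-id order; the partition
    map records each cluster's half-open column interval.
    """
    genome_ids = sorted(genome_ids)
    parts: dict[str, list[str]] = {g: [] for g in genome_ids}
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for cid in sorted(selection.cluster_ids):
        msa = msas[cid]
        for g in genome_ids:
            key = (cid, g)
            if key not in index_map:
                raise ValueError(
                    f"no index ortholog for genome {g!r} in cluster {cid!r}"
                )
            pid = index_map[key]
            parts[g].append(msa.row(pid))
        width = msa.n_columns
        partitions[cid] = (offset, offset + width)
        offset += width
    rows = {g: "".join(parts[g]) for g in genome_ids}
    return Supermatrix(genome_ids=genome_ids, rows=rows, partitions=partitions)


def build_supermatrix(
    clusters,
    matrix: PhyleticMatrix,
    max_extra_paralogs: int = 4,
    per_genome: bool = False,
    max_gap_fraction: float = 0.667,
    min_homogeneity: float = 0.05,
) -> tuple[Supermatrix, MarkerSelection, dict[str, FilterReport]]:
    """End-to-end marker pipeline: select, pick index orthologs, filter,
    concatenate. ``clusters`` is a ClusterSet whose clusters are aligned."""
    selection = select_markers(
        matrix, max_extra_paralogs=max_extra_paralogs, per_genome=per_genome
    )
    by_id = clusters.by_id()
    genome_ids = matrix.genome_ids
    index_map: dict[tuple[str, str], str] = {}
    filtered: dict[str, MSA] = {}
    reports: dict[str, FilterReport] = {}
    for cid in selection.cluster_ids:
        cluster = by_id[cid]
        for g in genome_ids:
            index_map[(cid, g)] = select_index_ortholog(cluster, g)
        sub = MSA(
            ids=[index_map[(cid, g)] for g in genome_ids],
            rows=[
                cluster.alignment.row(index_map[(cid, g)])
                for g in genome_ids
            ],
        )
        filtered[cid], reports[cid] = filter_columns(
            sub, max_gap_fraction, min_homogeneity
        )
    sm = concatenate(selection, filtered, index_map, genome_ids)
    return sm, selection, reports
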