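"""Clade-level phyletic-pattern queries.

Given a clusters-by-genomes matrix and a clade (a subset of genomes with
its complement as the default outgroup), these pure set queries extract
the clade core (families present in every clade member), clade-specific
gains (core families absent from the whole outgroup), clade-specific
absences of otherwise-common families, and per-genome ortholog coverage
against a reference genome set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import PhyleticMatrix, ProteinRecord


@dataclass(frozen=True)
class CladeDefinition:
    clade_genomes: frozenset[str]
    outgroup_genomes: frozenset[str]

    @classmethod
    def from_matrix(
        cls, matrix: PhyleticMatrix, clade: Iterable[str],
        outgroup: Iterable[str] | None = None,
    ) -> "CladeDefinition":
        clade = frozenset(clade)
        genomes = set(matrix.genome_ids)
        if not clade:
            raise ValueError("clade must be non-empty")
        if not clade <= genomes:
            raise ValueError(
                f"unknown clade genomes: {sorted(clade - genomes)}"
            )
        if outgroup is None:
            outgroup = genomes - clade
        outgroup = frozenset(outgroup)
        if outgroup & clade:
            raise ValueError("clade and outgroup overlap")
        if not outgroup <= genomes:
            raise ValueError("outgroup contains unknown genomes")
        return cls(clade, outgroup)


def _validate(matrix: PhyleticMatrix, clade: CladeDefinition) -> None:
    if not clade.clade_genomes:
        raise ValueError("clade must be non-empty")


def clade_core(matrix: PhyleticMatrix, clade: CladeDefinition) -> set[str]:
    """Families present (count >= 1) in every clade genome."""
    _validate(matrix, clade)
    b = matrix.binarized()
    mask = b[sorted(clade.clade_genomes)].all(axis=1)
    return set(b.index[mask])


def clade_specific_gains(
    matrix: PhyleticMatrix, clade: CladeDefinition
) -> set[str]:
    """Families present in every clade genome and absent everywhere
    outside it."""
    _validate(matrix, clade)
    if not clade.outgroup_genomes:
        raise ValueError("outgroup must be non-empty")
    b = matrix.binarized()
    inside = b[sorted(clade.clade_genomes)].all(axis=1)
    outside = b[sorted(clade.outgroup_genomes)].sum(axis=1) == 0
    return set(b.index[inside & outside])


def clade_absent_common(
    matrix: PhyleticMatrix,
    clade: CladeDefinition,
    common_fraction: float = 0.667,
) -> set[str]:
    """Families absent from every clade genome yet present in at least
    ``common_fraction`` of the outgroup genomes."""
    _validate(matrix, clade)
    if not clade.outgroup_genomes:
        raise ValueError("outgroup must be non-empty")
    b = matrix.binarized()
    absent = b[sorted(clade.clade_genomes)].sum(axis=1) == 0
    out_cols = sorted(clade.outgroup_genomes)
    frac = b[out_cols].sum(axis=1) / len(out_cols)
    return set(b.index[absent & (frac >= common_fraction)])


def ortholog_coverage(
    matrix: PhyleticMatrix,
    genome: str,
    singletons: Sequence[ProteinRecord],
    reference_genomes: Iterable[str],
) -> tuple[int, int]:
    """(proteins with an ortholog in the reference set, total proteins).

    The total counts the genome's clustered members plus its singletons;
    a clustered member has an ortholog when its cluster also contains at
    least one reference genome.
    """
    if genome not in matrix.genome_ids:
        raise ValueError(f"unknown genome {genome!r}")
    reference = [g for g in reference_genomes if g != genome]
    df = matrix.df
    n_single = sum(1 for s in singletons if s.genome_id == genome)
    n_total = int(df[genome].sum()) + n_single
    if reference:
        has_ref = (df[reference] >= 1).any(axis=1)
    else:
        has_ref = df[genome] < 0  # empty reference set: nothing qualifies
    n_with = int(df.loc[has_ref, genome].sum())
    return n_with, n_total


def signature_summary(
    matrix: PhyleticMatrix,
    clade: CladeDefinition,
    common_fraction: float = 0.667,
) -> dict:
    """Counts for the three clade queries, for reporting."""
    return {
        "clade_size": len(clade.clade_genomes),
        "outgroup_size": len(clade.outgroup_genomes),
        "core": len(clade_core(matrix, clade)),
        "specific_gains": len(clade_specific_gains(matrix, clade)),
        "absent_common": len(
            clade_absent_common(matrix, clade, common_fraction)
        ),
    }
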