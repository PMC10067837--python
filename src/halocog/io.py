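"""Standard-format readers and writers.

FASTA goes through Biopython (headers ``<genome>|<protein-id>``, wrap
60), Newick through scikit-bio. Tabular outputs (phyletic matrices,
event calls, posteriors, marker lists, logs) are tab-separated with
``#``-prefixed metadata headers recording the tool version, config hash
and seed; FASTA and Newick files are written without such headers so
external tools can consume them directly.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from . import __version__
from .core import GenomeSet, PhyleticMatrix, ProteinRecord
from .supermatrix import Supermatrix


def metadata_header(config_hash: str = "-", seed: int | str = "-") -> str:
    return (
        f"# halocog {__version__}\n"
        f"# config_hash={config_hash}\n"
        f"# seed={seed}\n"
    )


# ---------------------------------------------------------------------------
# FASTA


def _parse_header(header: str, line_no: int | None = None) -> tuple[str, str]:
    if "|" not in header:
        where = f" at record {line_no}" if line_no else ""
        raise ValueError(
            f"FASTA header {header!r}{where} is not '<genome>|<protein-id>'"
        )
    genome, protein = header.split("|", 1)
    return genome, protein


def read_fasta(path) -> list[ProteinRecord]:
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        genome, protein = _parse_header(rec.id, i)
        records.append(ProteinRecord(protein, genome, str(rec.seq)))
    return records


def read_fasta_dir(directory) -> GenomeSet:
    records: list[ProteinRecord] = []
    for path in sorted(Path(directory).glob("*.faa")):
        records.extend(read_fasta(path))
    if not records:
        raise ValueError(f"no .faa files with records under {directory}")
    return GenomeSet(records)


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.header, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def write_genome_fastas(genomes: GenomeSet, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome_id in genomes.genome_ids:
        path = directory / f"{genome_id}.faa"
        write_fasta(genomes.by_genome[genome_id], path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Newick


def read_newick(path) -> TreeNode:
    text = Path(path).read_text()
    payload = "\n".join(
        line for line in text.splitlines() if not line.startswith("#")
    )
    return TreeNode.read(_io.StringIO(payload))


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        tree.write(fh)


# ---------------------------------------------------------------------------
# phyletic matrix TSV


def write_matrix(
    matrix: PhyleticMatrix, path, config_hash: str = "-", seed="-"
) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(config_hash, seed))
        df = matrix.df.copy()
        df.index.name = "family"
        df.to_csv(fh, sep="\t")


def read_matrix(path) -> PhyleticMatrix:
    lines = Path(path).read_text().splitlines()
    n_comments = 0
    for line in lines:
        if line.startswith("#"):
            n_comments += 1
        else:
            break
    df = pd.read_csv(path, sep="\t", comment="#", index_col="family")
    values = df.to_numpy()
    bad = (values < 0).nonzero()
    if len(bad[0]):
        row = int(bad[0][0])
        line_no = n_comments + 1 + row + 1  # comments + header + data row
        raise ValueError(
            f"negative count at line {line_no} of {path} "
            f"(family {df.index[row]!r})"
        )
    return PhyleticMatrix(df)


# ---------------------------------------------------------------------------
# cluster membership / events / posteriors / misc tables


def write_membership(
    clusters, path, config_hash: str = "-", seed="-"
) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(config_hash, seed))
        fh.write("cluster_id\tprotein_id\tgenome_id\n")
        for c in clusters.clusters:
            for m in c.members:
                fh.write(f"{c.cluster_id}\t{m.protein_id}\t{m.genome_id}\n")
        for s in clusters.singletons:
            fh.write(f"singleton\t{s.protein_id}\t{s.genome_id}\n")


def write_events(events, path, config_hash: str = "-", seed="-") -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(config_hash, seed))
        fh.write("family\tparent\tchild\ttype\tdelta\n")
        for e in events:
            fh.write(
                f"{e.family}\t{e.parent}\t{e.child}\t{e.kind}\t{e.delta:.6f}\n"
            )


def write_posteriors(
    posteriors: pd.DataFrame, path, config_hash: str = "-", seed="-"
) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(config_hash, seed))
        df = posteriors.copy()
        df.index.name = "family"
        df.round(6).to_csv(fh, sep="\t")


def write_ancestral_content(
    content: pd.Series, path, config_hash: str = "-", seed="-"
) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(config_hash, seed))
        fh.write("node\texpected_families\trounded\n")
        for node, value in content.items():
            fh.write(f"{node}\t{value:.4f}\t{round(value)}\n")


def write_model(model, path, config_hash: str = "-", seed="-") -> None:
    payload = {
        "tool": f"halocog {__version__}",
        "config_hash": config_hash,
        "seed": seed,
        "gain_rate": model.gain_rate,
        "loss_rate": model.loss_rate,
        "root_prior": model.root_prior,
        "log_likelihood": model.log_likelihood,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_truth_events(events, path, config_hash: str = "-", seed="-") -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(config_hash, seed))
        fh.write("edge_child_node\tfamily\tevent_type\n")
        for e in sorted(events, key=lambda e: (e.family, e.child, e.kind)):
            fh.write(f"{e.child}\t{e.family}\t{e.kind}\n")


def write_iteration_log(log: Sequence[dict], path, config_hash: str = "-",
                        seed="-") -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(config_hash, seed))
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# supermatrix formats


def write_supermatrix_fasta(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for g in sm.genome_ids:
            fh.write(f">{g}\n")
            row = sm.rows[g]
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def write_supermatrix_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: name, whitespace, full sequence on one line."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.genome_ids)} {sm.n_columns}\n")
        for g in sm.genome_ids:
            fh.write(f"{g}  {sm.rows[g]}\n")


def write_partitions(sm: Supermatrix, path, config_hash: str = "-",
                     seed="-") -> None:
    """RAxML-style partition file; intervals are 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(metadata_header(config_hash, seed))
        for cid in sorted(sm.partitions):
            start, stop = sm.partitions[cid]
            fh.write(f"PROT, {cid} = {start + 1}-{stop}\n")


def write_marker_list(selection, path, config_hash: str = "-", seed="-"):
    with open(path, "w") as fh:
        fh.write(metadata_header(config_hash, seed))
        fh.write("cluster_id\n")
        for cid in sorted(selection.cluster_ids):
            fh.write(cid + "\n")


def write_signature_sets(sets: dict[str, set[str]], directory,
                         config_hash: str = "-", seed="-") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, families in sets.items():
        with open(directory / f"{name}.tsv", "w") as fh:
            fh.write(metadata_header(config_hash, seed))
            fh.write("family\n")
            for fam in sorted(families):
                fh.write(fam + "\n")
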