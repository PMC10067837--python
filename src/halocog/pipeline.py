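"""End-to-end orchestration: simulate/load -> cluster -> supermatrix ->
gain/loss -> signatures, with deterministic outputs under a fixed seed.

All stage outputs are pure functions of the configuration and inputs;
timing lives only in ``report.json`` so reruns are byte-identical on
every data file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, io as hio
from .clustering import (
    all_vs_all_similarity,
    compute_aai,
    greedy_cluster,
    midpoint_root,
    refine_clusters,
)
from .core import ClusterSet, GenomeSet, PhyleticMatrix
from .gainloss import reconstruct
from .signatures import CladeDefinition, signature_summary
from .simulate import SimulationConfig, simulate_all
from .supermatrix import build_supermatrix


@dataclass
class PipelineConfig:
    """All stage parameters plus I/O locations.

    Either ``simulate=True`` (synthetic inputs generated under ``seed``)
    or ``proteins_dir``/``species_tree`` must be provided.
    """

    outdir: str = "halocog_out"
    seed: int = 0
    # inputs
    simulate: bool = True
    proteins_dir: str | None = None
    species_tree: str | None = None
    # simulation
    n_genomes: int = 20
    n_families: int = 50
    gain_rate: float = 0.3
    loss_rate: float = 0.3
    dup_rate: float = 0.1
    root_presence_prob: float = 0.8
    seq_length: int = 120
    within_family_divergence: float = 0.2
    # clustering
    min_identity: float = 0.5
    min_coverage: float = 0.5
    kmer_size: int = 5
    max_iterations: int = 5
    merge_min_span: float = 0.8
    merge_min_score_per_column: float = 0.5
    # supermatrix
    max_extra_paralogs: int = 4
    per_genome_paralogs: bool = False
    max_gap_fraction: float = 0.667
    min_homogeneity: float = 0.05
    # gain/loss
    event_threshold: float = 0.5
    ascertainment: bool = True
    # signatures
    clade: list[str] = field(default_factory=list)
    common_fraction: float = 0.667

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (I/O locations excluded, so
        the same analysis written elsewhere reproduces identical files)."""
        params = {
            k: v for k, v in self.to_dict().items() if k != "outdir"
        }
        payload = json.dumps(params, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _adjusted_rand(labels_true, labels_pred) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_true, labels_pred))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write standard outputs under ``config.outdir``
    and return the run report (also saved as ``report.json``)."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.seed
    report: dict = {
        "tool": f"halocog {__version__}",
        "config_hash": chash,
        "seed": seed,
        "parameters": config.to_dict(),
        "stages": {},
    }

    # stage 1: inputs -------------------------------------------------------
    truth = None
    if config.simulate:
        sim_cfg = SimulationConfig(
            n_genomes=config.n_genomes,
            n_families=config.n_families,
            gain_rate=config.gain_rate,
            loss_rate=config.loss_rate,
            dup_rate=config.dup_rate,
            root_presence_prob=config.root_presence_prob,
            seq_length=config.seq_length,
            within_family_divergence=config.within_family_divergence,
            seed=seed,
        )
        tree, true_matrix, truth, genomes = simulate_all(sim_cfg)
        fasta_dir = outdir / "proteins"
        hio.write_genome_fastas(genomes, fasta_dir)
        hio.write_newick(tree, outdir / "species_tree.nwk")
        hio.write_matrix(true_matrix, outdir / "true_matrix.tsv", chash, seed)
        hio.write_truth_events(
            truth.events, outdir / "true_events.tsv", chash, seed
        )
        report["stages"]["simulate"] = {
            "n_genomes": config.n_genomes,
            "n_families_observed": true_matrix.n_families,
            "n_families_dropped": truth.n_dropped,
            "n_proteins": len(genomes),
        }
    else:
        if not config.proteins_dir or not config.species_tree:
            raise ValueError(
                "need proteins_dir and species_tree when simulate=False"
            )
        genomes = hio.read_fasta_dir(config.proteins_dir)
        tree = hio.read_newick(config.species_tree)
        if len(tree.children) > 2:
            import warnings

            warnings.warn(
                "species tree is unrooted; applying midpoint rooting",
                stacklevel=2,
            )
            tree = midpoint_root(tree)
        report["stages"]["inputs"] = {
            "proteins_dir": str(config.proteins_dir),
            "species_tree": str(config.species_tree),
            "input_hashes": {
                p.name: _hash_file(p)
                for p in sorted(Path(config.proteins_dir).glob("*.faa"))
            },
            "n_proteins": len(genomes),
        }

    # stage 2: clustering ---------------------------------------------------
    hits = all_vs_all_similarity(
        genomes.records,
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
        kmer_size=config.kmer_size,
    )
    initial = greedy_cluster(hits, genomes.records)
    clusters, log = refine_clusters(
        initial,
        max_iterations=config.max_iterations,
        min_span=config.merge_min_span,
        min_score_per_column=config.merge_min_score_per_column,
    )
    hio.write_membership(clusters, outdir / "clusters.tsv", chash, seed)
    hio.write_iteration_log(log, outdir / "refine_log.jsonl", chash, seed)
    stage2 = {
        "n_hits": len(hits) // 2,
        "n_initial_clusters": initial.n_clusters,
        "n_clusters": clusters.n_clusters,
        "n_singletons": clusters.n_singletons,
        "iterations": log,
    }
    if truth is not None:
        labels_true, labels_pred = [], []
        for c in clusters.clusters:
            for m in c.members:
                labels_true.append(truth.family_membership[m.protein_id])
                labels_pred.append(c.cluster_id)
        stage2["adjusted_rand_vs_truth"] = _adjusted_rand(
            labels_true, labels_pred
        )
    report["stages"]["clustering"] = stage2

    # stage 3: phyletic matrix ---------------------------------------------
    matrix = PhyleticMatrix.from_clusters(clusters, genomes.genome_ids)
    hio.write_matrix(matrix, outdir / "phyletic_matrix.tsv", chash, seed)

    # stage 4: supermatrix --------------------------------------------------
    sm, selection, reports = build_supermatrix(
        clusters,
        matrix,
        max_extra_paralogs=config.max_extra_paralogs,
        per_genome=config.per_genome_paralogs,
        max_gap_fraction=config.max_gap_fraction,
        min_homogeneity=config.min_homogeneity,
    )
    hio.write_supermatrix_fasta(sm, outdir / "supermatrix.faa")
    hio.write_supermatrix_phylip(sm, outdir / "supermatrix.phy")
    hio.write_partitions(sm, outdir / "partitions.txt", chash, seed)
    hio.write_marker_list(selection, outdir / "markers.tsv", chash, seed)
    report["stages"]["supermatrix"] = {
        "n_markers": len(selection.cluster_ids),
        "n_columns": sm.n_columns,
        "columns_removed": sum(r.removed for r in reports.values()),
    }

    # stage 5: gain/loss ----------------------------------------------------
    gl = reconstruct(
        matrix,
        tree,
        threshold=config.event_threshold,
        ascertainment=config.ascertainment,
    )
    hio.write_model(gl.model, outdir / "gainloss_model.json", chash, seed)
    hio.write_posteriors(
        gl.posteriors, outdir / "posteriors.tsv", chash, seed
    )
    hio.write_events(gl.events, outdir / "events.tsv", chash, seed)
    hio.write_ancestral_content(
        gl.ancestral_content, outdir / "ancestral_content.tsv", chash, seed
    )
    report["stages"]["gainloss"] = {
        "gain_rate": gl.model.gain_rate,
        "loss_rate": gl.model.loss_rate,
        "log_likelihood": gl.model.log_likelihood,
        "n_events": len(gl.events),
        "n_gains": sum(1 for e in gl.events if e.kind == "gain"),
        "n_losses": sum(1 for e in gl.events if e.kind == "loss"),
    }

    # stage 6: signatures ---------------------------------------------------
    if config.clade:
        clade = CladeDefinition.from_matrix(matrix, config.clade)
        from .signatures import (
            clade_absent_common,
            clade_core,
            clade_specific_gains,
        )

        sets = {
            "clade_core": clade_core(matrix, clade),
            "clade_specific_gains": clade_specific_gains(matrix, clade),
            "clade_absent_common": clade_absent_common(
                matrix, clade, config.common_fraction
            ),
        }
        hio.write_signature_sets(sets, outdir / "signatures", chash, seed)
        report["stages"]["signatures"] = signature_summary(
            matrix, clade, config.common_fraction
        )

    report["wall_time_seconds"] = round(time.time() - t_start, 3)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
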