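"""Synthetic genome evolution with known ground truth.

Generates (i) a random species tree, (ii) gene-family content evolving
along it under a two-state gain/loss process with terminal-branch
duplications, and (iii) protein sequences diverging within families far
more slowly than between families. Every realised event is recorded, so
clustering, marker selection and gain/loss inference can all be validated
against the truth at desk scale.

Model summary
-------------
* Species tree: Yule splitting (a uniformly chosen lineage splits at each
  step) with every branch length drawn Exponential(mean 0.1).
* Content: a family present at the top of a branch of length ``t`` is lost
  with probability ``1 - exp(-loss_rate*t)``; an absent family is gained
  with probability ``(g/(g+l)) * (1 - exp(-(g+l)*t))`` (the two-state
  chain's 0->1 entry). Families absent from every leaf are unobservable
  and dropped (counted in ``SimulationTruth.n_dropped``).
* Duplications: Poisson(dup_rate*t) extra copies, applied on terminal
  branches only so that each duplication event corresponds to exactly one
  extra leaf copy (the per-leaf copy count minus one equals the number of
  duplication events affecting that leaf).
* Sequences: one random root sequence per family (uniform over the 20
  amino acids); per site, along a branch of length ``t`` a residue is
  replaced with probability ``1 - exp(-d*t)`` by a uniformly chosen
  different residue (``d`` = within_family_divergence). Every family
  carries a latent sequence at every node; a lineage that regains the
  family emits that latent sequence, keeping within-family divergence a
  function of tree distance alone.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import AMINO_ACIDS, GenomeSet, PhyleticMatrix, ProteinRecord


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic evolution model (rates are per unit
    branch length)."""

    n_genomes: int = 20
    n_families: int = 50
    gain_rate: float = 0.3
    loss_rate: float = 0.3
    dup_rate: float = 0.1
    root_presence_prob: float = 0.8
    seq_length: int = 120
    within_family_divergence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("gain_rate", "loss_rate", "dup_rate",
                     "within_family_divergence"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 <= self.root_presence_prob <= 1.0:
            raise ValueError("root_presence_prob must be in [0, 1]")
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")


@dataclass
class Event:
    """One realised change on a tree edge, identified by the child node."""

    child: str
    family: str
    kind: str  # "gain" | "loss" | "duplication"


@dataclass
class SimulationTruth:
    """Ground truth of one simulation run."""

    tree: TreeNode
    events: list[Event]
    true_matrix: PhyleticMatrix
    family_membership: dict[str, str] = field(default_factory=dict)
    node_presence: pd.DataFrame | None = None  # families x node labels (0/1)
    root_present: pd.Series | None = None
    n_dropped: int = 0

    def events_of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_genomes: int, seed: int) -> TreeNode:
    """Yule tree with ``n_genomes`` leaves, Exponential(0.1) branch lengths.

    Leaves are labelled ``G0001``..., internal nodes ``N1``... (preorder);
    identical (n_genomes, seed) give byte-identical Newick.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    root.children = []
    leaves = []
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        leaves.append(child)
    while len(leaves) < n_genomes:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            leaves.append(child)
    # label and assign branch lengths in deterministic preorder
    leaf_counter = 0
    internal_counter = 0
    for node in root.preorder():
        if node.is_tip():
            leaf_counter += 1
            node.name = f"G{leaf_counter:04d}"
        else:
            internal_counter += 1
            node.name = f"N{internal_counter}"
        if node.parent is not None:
            node.length = max(float(rng.exponential(0.1)), 1e-9)
    root.length = None
    return root


def _edges_preorder(tree: TreeNode) -> list[TreeNode]:
    """Non-root nodes in preorder; each node stands for the edge above it."""
    return [n for n in tree.preorder() if n.parent is not None]


# ---------------------------------------------------------------------------
# gene content


def simulate_gene_content(
    tree: TreeNode, config: SimulationConfig
) -> tuple[PhyleticMatrix, SimulationTruth]:
    """Evolve family presence/copy number along ``tree``.

    Returns the observed phyletic matrix (all-absent families dropped) and
    the full ground truth, including per-node presence states.
    """
    for node in _edges_preorder(tree):
        if node.length is None:
            raise ValueError("tree must have branch lengths on all edges")

    rng = np.random.default_rng([config.seed, 1])
    g, l, dup = config.gain_rate, config.loss_rate, config.dup_rate
    n_fam = config.n_families
    families = [f"F{i + 1:04d}" for i in range(n_fam)]

    present_at = {}  # node id -> bool array over families
    root_present = rng.random(n_fam) < config.root_presence_prob
    present_at[id(tree)] = root_present
    events: list[Event] = []
    copy_counts: dict[str, np.ndarray] = {}  # leaf label -> int array

    r = g + l
    for node in _edges_preorder(tree):
        t = float(node.length)
        parent_state = present_at[id(node.parent)]
        p_loss = 1.0 - np.exp(-l * t)
        p_gain = 0.0 if r == 0 else (g / r) * (1.0 - np.exp(-r * t))
        u = rng.random(n_fam)
        lost = parent_state & (u < p_loss)
        gained = (~parent_state) & (u < p_gain)
        state = (parent_state & ~lost) | gained
        present_at[id(node)] = state
        for i in np.flatnonzero(lost):
            events.append(Event(node.name, families[i], "loss"))
        for i in np.flatnonzero(gained):
            events.append(Event(node.name, families[i], "gain"))
        if node.is_tip():
            counts = state.astype(int)
            if dup > 0:
                # duplications only where the family survived the whole branch
                survived = parent_state & state
                extra = rng.poisson(dup * t, size=n_fam) * survived
                counts = counts + extra
                for i in np.flatnonzero(extra):
                    for _ in range(int(extra[i])):
                        events.append(
                            Event(node.name, families[i], "duplication")
                        )
            copy_counts[node.name] = counts

    leaf_labels = sorted(copy_counts)
    mat = pd.DataFrame(
        {leaf: copy_counts[leaf] for leaf in leaf_labels}, index=families
    )
    observed = mat.sum(axis=1) > 0
    n_dropped = int((~observed).sum())
    mat = mat.loc[observed]
    kept = set(mat.index)
    events = [e for e in events if e.family in kept]

    node_labels = [n.name for n in tree.preorder()]
    pres = pd.DataFrame(
        {n.name: present_at[id(n)].astype(int) for n in tree.preorder()},
        index=families,
    )[node_labels].loc[list(mat.index)]

    truth = SimulationTruth(
        tree=tree,
        events=events,
        true_matrix=PhyleticMatrix(mat),
        node_presence=pres,
        root_present=pd.Series(root_present, index=families)[list(mat.index)],
        n_dropped=n_dropped,
    )
    return truth.true_matrix, truth


# ---------------------------------------------------------------------------
# sequences


def _mutate(seqs: np.ndarray, t: float, d: float, rng) -> np.ndarray:
    """Per-site substitution to a uniformly chosen different residue."""
    if d == 0 or t == 0:
        return seqs.copy()
    p = 1.0 - np.exp(-d * t)
    hit = rng.random(seqs.shape) < p
    offset = rng.integers(1, 20, size=seqs.shape)
    return np.where(hit, (seqs + offset) % 20, seqs)


def simulate_sequences(
    truth: SimulationTruth, config: SimulationConfig
) -> GenomeSet:
    """Emit protein sequences for every leaf copy in ``truth``.

    Protein ids are ``<genome>.<family>.<copy>``; family assignments are
    recorded in ``truth.family_membership``.
    """
    rng = np.random.default_rng([config.seed, 2])
    d = config.within_family_divergence
    L = config.seq_length
    tree = truth.tree
    mat = truth.true_matrix.df
    families = list(mat.index)
    n_fam = len(families)

    # latent per-node sequences for every family
    seq_at: dict[int, np.ndarray] = {}
    seq_at[id(tree)] = rng.integers(0, 20, size=(n_fam, L))
    for node in _edges_preorder(tree):
        seq_at[id(node)] = _mutate(
            seq_at[id(node.parent)], float(node.length), d, rng
        )

    aa = np.array(list(AMINO_ACIDS))
    records: list[ProteinRecord] = []
    for node in _edges_preorder(tree):
        if not node.is_tip():
            continue
        genome = node.name
        leaf_seqs = seq_at[id(node)]
        parent_seqs = seq_at[id(node.parent)]
        for fi, fam in enumerate(families):
            copies = int(mat.loc[fam, genome])
            if copies == 0:
                continue
            for k in range(1, copies + 1):
                if k == 1:
                    arr = leaf_seqs[fi]
                else:
                    # paralog re-evolves from the duplication point at the
                    # top of the terminal branch
                    arr = _mutate(
                        parent_seqs[fi][None, :], float(node.length), d, rng
                    )[0]
                pid = f"{genome}.{fam}.{k}"
                records.append(
                    ProteinRecord(pid, genome, "".join(aa[arr]))
                )
                truth.family_membership[pid] = fam
    return GenomeSet(records)


def simulate_all(
    config: SimulationConfig,
) -> tuple[TreeNode, PhyleticMatrix, SimulationTruth, GenomeSet]:
    """Convenience wrapper: tree -> content -> sequences, one seed."""
    tree = simulate_species_tree(config.n_genomes, config.seed)
    matrix, truth = simulate_gene_content(tree, config)
    genomes = simulate_sequences(truth, config)
    return tree, matrix, truth, genomes


def tree_to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue()
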