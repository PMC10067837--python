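"""Construction and iterative refinement of orthologous clusters.

The pipeline mirrors how cluster-of-orthologous-genes (COG) sets are built
for prokaryotic genome collections: an all-vs-all similarity search seeds
greedy clusters; clusters are then refined over several rounds in which
(i) cluster profiles displaying full-length similarity are merged,
(ii) a gene tree is built for each multi-member cluster and midpoint
rooted, and (iii) the tree is parsed into subtrees that maximise the
ratio of taxonomic coverage (distinct genomes) to the paralogy index
(average sequences per genome) — separating paralogous subfamilies while
keeping orthologous sets together.

Similarity search is exact pairwise local alignment (BLOSUM62, gap
open/extend 11/1) behind a shared-k-mer prefilter; gene trees come from
neighbour joining on a log-corrected identity distance. Hooks allow an
external aligner or tree builder to be substituted.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .core import (
    BLOSUM62,
    GAP,
    MSA,
    AMINO_ACIDS,
    Cluster,
    ClusterSet,
    ProteinRecord,
    aa_index,
)
from .supermatrix import consensus, select_index_ortholog

_B62 = SubstitutionMatrix.std_protein_matrix()
_GAP_PENALTY = (-11, -1)

AlignerHook = Callable[[Sequence[ProteinRecord]], MSA]
TreeBuilderHook = Callable[[MSA], TreeNode]


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    target_id: str
    identity: float
    query_coverage: float
    target_coverage: float
    score: float


# ---------------------------------------------------------------------------
# all-vs-all similarity search


def _kmer_candidates(
    proteins: Sequence[ProteinRecord], k: int, min_shared: int
) -> list[tuple[int, int]]:
    """Index pairs (i < j) sharing at least ``min_shared`` k-mers."""
    buckets: dict[str, list[int]] = defaultdict(list)
    for i, p in enumerate(proteins):
        seq = p.sequence
        for kmer in {seq[s : s + k] for s in range(len(seq) - k + 1)}:
            buckets[kmer].append(i)
    shared: Counter[tuple[int, int]] = Counter()
    for idxs in buckets.values():
        if len(idxs) < 2:
            continue
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                shared[(idxs[a], idxs[b])] += 1
    return sorted(p for p, c in shared.items() if c >= min_shared)


def _pair_alignment_stats(seq_a: str, seq_b: str, pa, pb):
    """Local alignment statistics: (identity, cov_a, cov_b, score)."""
    alns = align_optimal(
        pa, pb, _B62, gap_penalty=_GAP_PENALTY, local=True, max_number=1
    )
    aln = alns[0]
    trace = aln.trace
    if len(trace) == 0:
        return 0.0, 0.0, 0.0, 0.0
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    ia = trace[both, 0]
    ib = trace[both, 1]
    arr_a = np.frombuffer(seq_a.encode(), dtype="S1")
    arr_b = np.frombuffer(seq_b.encode(), dtype="S1")
    matches = int((arr_a[ia] == arr_b[ib]).sum())
    identity = matches / len(trace)
    a_idx = trace[trace[:, 0] >= 0, 0]
    b_idx = trace[trace[:, 1] >= 0, 1]
    cov_a = (a_idx.max() - a_idx.min() + 1) / len(seq_a)
    cov_b = (b_idx.max() - b_idx.min() + 1) / len(seq_b)
    return identity, float(cov_a), float(cov_b), float(aln.score)


def all_vs_all_similarity(
    proteins: Sequence[ProteinRecord],
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
    kmer_size: int = 5,
    min_shared_kmers: int = 1,
    prefilter: bool = True,
) -> list[SimilarityHit]:
    """Symmetric local-alignment hits above identity/coverage thresholds.

    A shared-k-mer prefilter restricts which pairs are aligned; with
    ``prefilter=False`` every pair is aligned exhaustively (the oracle
    mode used in tests).
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    proteins = sorted(proteins, key=lambda p: p.protein_id)
    if prefilter:
        pairs = _kmer_candidates(proteins, kmer_size, min_shared_kmers)
    else:
        n = len(proteins)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pseqs = [ProteinSequence(p.sequence) for p in proteins]
    hits: list[SimilarityHit] = []
    for i, j in pairs:
        a, b = proteins[i], proteins[j]
        identity, cov_a, cov_b, score = _pair_alignment_stats(
            a.sequence, b.sequence, pseqs[i], pseqs[j]
        )
        if identity >= min_identity and min(cov_a, cov_b) >= min_coverage:
            hits.append(
                SimilarityHit(a.protein_id, b.protein_id, identity,
                              cov_a, cov_b, score)
            )
            hits.append(
                SimilarityHit(b.protein_id, a.protein_id, identity,
                              cov_b, cov_a, score)
            )
    hits.sort(key=lambda h: (h.query_id, h.target_id))
    return hits


# ---------------------------------------------------------------------------
# greedy clustering


def greedy_cluster(
    hits: Iterable[SimilarityHit], proteins: Sequence[ProteinRecord]
) -> ClusterSet:
    """Longest-centroid greedy clustering; singletons are excluded from
    the ClusterSet and kept in its ``singletons`` list."""
    neighbours: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        neighbours[h.query_id].add(h.target_id)
    by_id = {p.protein_id: p for p in proteins}
    order = sorted(proteins, key=lambda p: (-len(p.sequence), p.protein_id))
    assigned: set[str] = set()
    clusters: list[Cluster] = []
    singles: list[ProteinRecord] = []
    for centroid in order:
        if centroid.protein_id in assigned:
            continue
        member_ids = [centroid.protein_id] + sorted(
            q for q in neighbours[centroid.protein_id] if q not in assigned
        )
        assigned.update(member_ids)
        members = tuple(by_id[m] for m in member_ids)
        if len(members) == 1:
            singles.append(members[0])
        else:
            clusters.append(Cluster("", members))
    return ClusterSet(clusters, singles).relabel()


# ---------------------------------------------------------------------------
# cluster alignment (center star, pluggable)


def _global_align(pa, pb):
    return align_optimal(
        pa, pb, _B62, gap_penalty=_GAP_PENALTY, local=False,
        terminal_penalty=True, max_number=1
    )[0]


def _gapped_strings(aln, seq_a: str, seq_b: str) -> tuple[str, str]:
    ga, gb = [], []
    for ia, ib in aln.trace:
        ga.append(seq_a[ia] if ia >= 0 else GAP)
        gb.append(seq_b[ib] if ib >= 0 else GAP)
    return "".join(ga), "".join(gb)


def align_cluster(
    cluster: Cluster, aligner: AlignerHook | None = None
) -> MSA:
    """Center-star progressive alignment of the cluster members.

    The center is the member with the highest summed pairwise global
    alignment score (ties to the smallest protein id); every other member
    is aligned to the center and the pairwise alignments are merged under
    the once-a-gap-always-a-gap rule. Pass ``aligner`` to delegate to an
    external MSA tool instead.
    """
    if aligner is not None:
        return aligner(cluster.members)
    members = cluster.members
    ids = [m.protein_id for m in members]
    if len(members) == 1:
        return MSA(ids=ids, rows=[members[0].sequence])
    pseqs = [ProteinSequence(m.sequence) for m in members]
    n = len(members)
    scores = np.zeros(n)
    pair_aln: dict[tuple[int, int], object] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = _global_align(pseqs[i], pseqs[j])
            pair_aln[(i, j)] = aln
            scores[i] += aln.score
            scores[j] += aln.score
    center = min(range(n), key=lambda i: (-scores[i], ids[i]))
    c_seq = members[center].sequence
    L = len(c_seq)
    # per-member gapped pair against the center
    pair_rows: dict[int, tuple[str, str]] = {}
    for i in range(n):
        if i == center:
            continue
        key = (min(i, center), max(i, center))
        aln = pair_aln[key]
        if key[0] == center:
            gc, gm = _gapped_strings(aln, c_seq, members[i].sequence)
        else:
            gm, gc = _gapped_strings(aln, members[i].sequence, c_seq)
        pair_rows[i] = (gc, gm)
    # insertion slots: ins[s] = max gap run before center residue s
    ins = [0] * (L + 1)
    member_slots: dict[int, list[str]] = {}
    for i, (gc, gm) in pair_rows.items():
        slots: list[str] = ["" for _ in range(L + 1)]
        s = 0
        for cc, mc in zip(gc, gm):
            if cc == GAP:
                slots[s] += mc
            else:
                slots[s] += "\x00" + mc  # sentinel separates insert/match
                s += 1
        member_slots[i] = slots
        run = 0
        s = 0
        for cc in gc:
            if cc == GAP:
                run += 1
            else:
                ins[s] = max(ins[s], run)
                run = 0
                s += 1
        ins[L] = max(ins[L], run)
    rows: dict[int, str] = {}
    center_row = []
    for s in range(L + 1):
        center_row.append(GAP * ins[s])
        if s < L:
            center_row.append(c_seq[s])
    rows[center] = "".join(center_row)
    for i, slots in member_slots.items():
        out = []
        for s in range(L + 1):
            chunk = slots[s] if s < len(slots) else ""
            if s < L:
                insert, _, match = chunk.partition("\x00")
            else:
                insert, match = chunk, ""
            out.append(insert + GAP * (ins[s] - len(insert)))
            out.append(match)
        rows[i] = "".join(out)
    return MSA(ids=ids, rows=[rows[i] for i in range(n)])


# ---------------------------------------------------------------------------
# profile-profile comparison and full-length merging


def _profile(msa: MSA) -> np.ndarray:
    """(n_columns, 20) residue frequencies over non-gap characters."""
    arr = msa.to_array()
    n_col = arr.shape[1]
    freq = np.zeros((n_col, 20))
    for j in range(n_col):
        col = arr[:, j]
        total = 0
        for c in col:
            if c != GAP and c in AMINO_ACIDS:
                freq[j, aa_index(str(c))] += 1
                total += 1
        if total:
            freq[j] /= total
    return freq


def profile_similarity(
    msa_a: MSA, msa_b: MSA, gap_penalty: float = 5.0
) -> tuple[float, float]:
    """Global alignment of two frequency profiles under BLOSUM62.

    Column-pair score is sum_xy f_a(x) f_b(y) B62(x, y); gaps cost
    ``gap_penalty`` per column, terminal gaps included. Returns the total
    score and the mutual span coverage: aligned columns divided by the
    longer profile's length (equivalently min over the two profiles of
    aligned/length).
    """
    if msa_a.n_rows == 0 or msa_b.n_rows == 0:
        raise ValueError("profiles must be non-empty")
    fa, fb = _profile(msa_a), _profile(msa_b)
    La, Lb = fa.shape[0], fb.shape[0]
    S = fa @ BLOSUM62 @ fb.T
    g = gap_penalty
    H = np.empty((La + 1, Lb + 1))
    H[0, :] = -g * np.arange(Lb + 1)
    H[:, 0] = -g * np.arange(La + 1)
    jj = np.arange(1, Lb + 1)
    for i in range(1, La + 1):
        # candidates reachable from the previous row
        M = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] - g)
        # H[i, j] = max(M[j-1], H[i, j-1] - g); closed form via prefix max
        acc = np.maximum.accumulate(np.concatenate(([H[i, 0]], M + g * jj)))
        H[i, 1:] = acc[1:] - g * jj
    # traceback to count aligned (diagonal) columns
    i, j = La, Lb
    aligned = 0
    while i > 0 and j > 0:
        h = H[i, j]
        if math.isclose(h, H[i - 1, j - 1] + S[i - 1, j - 1],
                        rel_tol=0.0, abs_tol=1e-9):
            aligned += 1
            i -= 1
            j -= 1
        elif math.isclose(h, H[i - 1, j] - g, rel_tol=0.0, abs_tol=1e-9):
            i -= 1
        else:
            j -= 1
    score = float(H[La, Lb])
    mutual = aligned / max(La, Lb)
    return score, mutual


def _consensus_kmer_pairs(
    clusters: list[Cluster], k: int = 4
) -> list[tuple[int, int]]:
    consensi = [consensus(c.alignment).replace(GAP, "") for c in clusters]
    records = [
        ProteinRecord(f"c{i}", "x", s if s else "A")
        for i, s in enumerate(consensi)
    ]
    return _kmer_candidates(records, k, 1)


def merge_full_length(
    clusters: ClusterSet,
    min_span: float = 0.8,
    min_score_per_column: float = 0.5,
    aligner: AlignerHook | None = None,
    candidate_kmer: int = 4,
) -> ClusterSet:
    """Merge connected components of the full-length-similarity graph.

    An edge joins two clusters whose profile alignment covers >=
    ``min_span`` of both profiles with a mean aligned-column score >=
    ``min_score_per_column``. Candidate pairs are limited to clusters
    whose consensus sequences share a k-mer. Merged clusters are
    re-aligned.
    """
    cl = list(clusters.clusters)
    if not cl:
        return ClusterSet([], list(clusters.singletons))
    for i, c in enumerate(cl):
        if c.alignment is None:
            cl[i] = c.with_alignment(align_cluster(c, aligner))
    n = len(cl)
    edges_i, edges_j = [], []
    for i, j in _consensus_kmer_pairs(cl, candidate_kmer):
        score, mutual = profile_similarity(cl[i].alignment, cl[j].alignment)
        la = cl[i].alignment.n_columns
        lb = cl[j].alignment.n_columns
        aligned = mutual * max(la, lb)
        if mutual >= min_span and aligned > 0 and (
            score / aligned >= min_score_per_column
        ):
            edges_i.append(i)
            edges_j.append(j)
    adj = coo_matrix(
        (np.ones(len(edges_i)), (edges_i, edges_j)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[Cluster]] = defaultdict(list)
    for i, lab in enumerate(labels):
        groups[int(lab)].append(cl[i])
    merged: list[Cluster] = []
    for lab in sorted(groups):
        group = groups[lab]
        if len(group) == 1:
            merged.append(group[0])
        else:
            members = tuple(m for c in group for m in c.members)
            newc = Cluster("", members)
            merged.append(newc.with_alignment(align_cluster(newc, aligner)))
    return ClusterSet(merged, list(clusters.singletons)).relabel()


# ---------------------------------------------------------------------------
# gene trees


def msa_identity_distances(msa: MSA) -> np.ndarray:
    """Pairwise d = -ln(max(identity, 0.01)) over shared non-gap columns."""
    arr = msa.to_array()
    n = arr.shape[0]
    nongap = arr != GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            total = int(shared.sum())
            if total == 0:
                ident = 0.0
            else:
                ident = float((arr[i][shared] == arr[j][shared]).sum()) / total
            d[i, j] = d[j, i] = -math.log(max(ident, 0.01))
    return d


def build_gene_tree(
    msa: MSA, tree_builder: TreeBuilderHook | None = None
) -> TreeNode:
    """Neighbour-joining tree on the log-identity distance (unrooted).

    Pass ``tree_builder`` to delegate to an external program (e.g. an
    approximate-ML tool) instead.
    """
    if msa.n_rows < 2:
        raise ValueError("need at least 2 rows to build a tree")
    if tree_builder is not None:
        return tree_builder(msa)
    d = msa_identity_distances(msa)
    if msa.n_rows == 2:
        half = d[0, 1] / 2.0
        t = TreeNode.read(
            _io.StringIO(f"({msa.ids[0]}:{half},{msa.ids[1]}:{half});")
        )
        return t
    dm = DistanceMatrix(d, ids=list(msa.ids))
    tree = nj(dm)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# midpoint rooting


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths go to the lexicographically smallest
    (endpoint, endpoint) label pair. If every branch length is zero the
    tree is rooted at its first internal node with a warning.
    """
    tree = tree.copy()
    tips = sorted(t.name for t in tree.tips())
    if len(tips) < 2:
        raise ValueError("need at least 2 leaves")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    total = sum(n.length for n in tree.traverse(include_self=False))
    if total == 0:
        warnings.warn(
            "all branch lengths are zero; rooting at first internal node",
            stacklevel=2,
        )
        first_internal = next(
            n for n in tree.preorder() if not n.is_tip()
        )
        return tree.root_at(first_internal, reset=True)
    dm = tree.tip_tip_distances()
    best = None
    for a_i in range(len(tips)):
        for b_i in range(a_i + 1, len(tips)):
            dist = dm[tips[a_i], tips[b_i]]
            if best is None or dist > best[0] + 1e-12:
                best = (dist, tips[a_i], tips[b_i])
    total_dist, label_a, label_b = best
    node_a = tree.find(label_a)
    node_b = tree.find(label_b)
    lca = tree.lowest_common_ancestor([node_a, node_b])
    path_a = []
    n = node_a
    while n is not lca:
        path_a.append(n)
        n = n.parent
    path_b = []
    n = node_b
    while n is not lca:
        path_b.append(n)
        n = n.parent
    # walk from label_a towards label_b; each element of path_a/path_b is
    # the child end of one edge on the path
    edges = [(n, n.length, "up") for n in path_a] + [
        (n, n.length, "down") for n in reversed(path_b)
    ]
    target = total_dist / 2.0
    cum = 0.0
    for node, length, direction in edges:
        if cum + length >= target - 1e-12:
            within = target - cum
            # distance above the child node of this edge
            above = within if direction == "up" else length - within
            above = min(max(above, 0.0), length)
            return tree.root_at(node, above=above, reset=True)
        cum += length
    # numerical fallback: root on the last edge
    node, length, direction = edges[-1]
    return tree.root_at(node, above=length / 2.0, reset=True)


# ---------------------------------------------------------------------------
# paralogy-aware subtree parsing


def paralogy_index(members: Iterable[ProteinRecord] | Cluster) -> float:
    """Average number of member sequences per distinct genome; >= 1."""
    if isinstance(members, Cluster):
        members = members.members
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    genomes = {m.genome_id for m in members}
    return len(members) / len(genomes)


def coverage_paralogy_ratio(members: Iterable[ProteinRecord]) -> float:
    """coverage / paralogy index = |genomes|^2 / |members|."""
    members = list(members)
    genomes = {m.genome_id for m in members}
    return len(genomes) ** 2 / len(members)


def parse_subtrees(
    rooted_tree: TreeNode, members: Sequence[ProteinRecord]
) -> list[Cluster]:
    """Recursively split a rooted gene tree into low-paralogy subtrees.

    A clade is split off when both it and its complement improve the
    coverage/paralogy ratio of the current tree; among admissible cuts
    the one maximising the smaller part ratio wins (ties: larger clade,
    then smallest leaf label). Every input leaf lands in exactly one
    output cluster.
    """
    by_id = {m.protein_id: m for m in members}

    def recurse(subtree: TreeNode) -> list[list[ProteinRecord]]:
        leaf_names = sorted(t.name for t in subtree.tips()) or (
            [subtree.name] if subtree.name in by_id else []
        )
        leaf_records = [by_id[n] for n in leaf_names]
        if len(leaf_records) <= 1:
            return [leaf_records]
        current = coverage_paralogy_ratio(leaf_records)
        all_names = set(leaf_names)
        best = None
        for node in subtree.preorder(include_self=False):
            clade = sorted(
                t.name for t in (node.tips() if not node.is_tip() else [node])
            )
            if len(clade) == len(all_names):
                continue
            comp = sorted(all_names.difference(clade))
            r_clade = coverage_paralogy_ratio([by_id[n] for n in clade])
            r_comp = coverage_paralogy_ratio([by_id[n] for n in comp])
            if r_clade > current and r_comp > current:
                key = (min(r_clade, r_comp), len(clade), clade[0])
                if best is None:
                    better = True
                elif key[0] > best[0][0] + 1e-12:
                    better = True
                elif key[0] < best[0][0] - 1e-12:
                    better = False
                elif key[1] != best[0][1]:
                    better = key[1] > best[0][1]
                else:
                    better = key[2] < best[0][2]
                if better:
                    best = (key, clade, comp)
        if best is None:
            return [leaf_records]
        _, clade, comp = best
        parts = []
        for names in (clade, comp):
            if len(names) == 1:
                parts.append([by_id[names[0]]])
            else:
                parts.extend(recurse(subtree.shear(names)))
        return parts

    part_lists = recurse(rooted_tree)
    part_lists.sort(key=lambda ms: ms[0].protein_id if ms else "")
    return [
        Cluster(f"S{i + 1:03d}", tuple(ms))
        for i, ms in enumerate(part_lists)
        if ms
    ]


# ---------------------------------------------------------------------------
# refinement loop


def refine_clusters(
    clusters: ClusterSet,
    max_iterations: int = 5,
    min_span: float = 0.8,
    min_score_per_column: float = 0.5,
    aligner: AlignerHook | None = None,
    tree_builder: TreeBuilderHook | None = None,
) -> tuple[ClusterSet, list[dict]]:
    """Iterate merge -> tree -> parse until a fixed point (or the
    iteration cap); returns the refined set and a per-round log."""
    log: list[dict] = []
    cache: dict[tuple[str, ...], MSA] = {}

    def aligned(c: Cluster) -> Cluster:
        key = c.member_key()
        if key not in cache:
            cache[key] = (
                c.alignment
                if c.alignment is not None
                else align_cluster(c, aligner)
            )
        return c.with_alignment(cache[key])

    current = ClusterSet(
        [aligned(c) for c in clusters.clusters], list(clusters.singletons)
    ).relabel()
    for iteration in range(max_iterations):
        before = current.n_clusters
        merged = merge_full_length(
            ClusterSet(
                [aligned(c) for c in current.clusters],
                list(current.singletons),
            ),
            min_span=min_span,
            min_score_per_column=min_score_per_column,
            aligner=aligner,
        )
        for c in merged.clusters:
            cache.setdefault(c.member_key(), c.alignment)
        n_merges = before - merged.n_clusters
        new_clusters: list[Cluster] = []
        new_singletons = list(merged.singletons)
        n_splits = 0
        for c in merged.clusters:
            c = aligned(c)
            tree = build_gene_tree(c.alignment, tree_builder)
            rooted = midpoint_root(tree)
            parts = parse_subtrees(rooted, c.members)
            if len(parts) > 1:
                n_splits += len(parts) - 1
                for p in parts:
                    if p.size == 1:
                        new_singletons.append(p.members[0])
                    else:
                        new_clusters.append(aligned(p))
            else:
                new_clusters.append(c)
        current = ClusterSet(new_clusters, new_singletons).relabel()
        current = ClusterSet(
            [aligned(c) for c in current.clusters], list(current.singletons)
        )
        log.append(
            {
                "iteration": iteration + 1,
                "merges": n_merges,
                "splits": n_splits,
                "n_clusters": current.n_clusters,
                "n_singletons": current.n_singletons,
            }
        )
        if n_merges == 0 and n_splits == 0:
            break
    return current, log


# ---------------------------------------------------------------------------
# average amino-acid identity


def compute_aai(
    genome_a: str, genome_b: str, clusters: ClusterSet
) -> float:
    """Mean percent identity between two genomes' index orthologs across
    all shared clusters (identity over mutually non-gap MSA columns)."""
    identities: list[float] = []
    for c in clusters.clusters:
        genomes = c.genome_ids
        if genome_a not in genomes or genome_b not in genomes:
            continue
        cl = c if c.alignment is not None else c.with_alignment(
            align_cluster(c)
        )
        pid_a = select_index_ortholog(cl, genome_a)
        pid_b = select_index_ortholog(cl, genome_b)
        row_a = cl.alignment.row(pid_a)
        row_b = cl.alignment.row(pid_b)
        shared = matches = 0
        for x, y in zip(row_a, row_b):
            if x != GAP and y != GAP:
                shared += 1
                if x == y:
                    matches += 1
        if shared:
            identities.append(matches / shared)
    if not identities:
        raise ValueError(
            f"no shared clusters between {genome_a!r} and {genome_b!r}"
        )
    return 100.0 * float(np.mean(identities))
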