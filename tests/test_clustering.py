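"""Clustering: similarity search, greedy clustering, alignment, profile
merging, gene trees, midpoint rooting, subtree parsing, refinement, AAI."""

from collections import defaultdict
from itertools import combinations

import numpy as np
import pytest

from halocog.clustering import (
    SimilarityHit,
    all_vs_all_similarity,
    align_cluster,
    build_gene_tree,
    compute_aai,
    coverage_paralogy_ratio,
    greedy_cluster,
    merge_full_length,
    midpoint_root,
    msa_identity_distances,
    paralogy_index,
    parse_subtrees,
    profile_similarity,
    refine_clusters,
)
from halocog.core import (
    BLOSUM62,
    GAP,
    MSA,
    AMINO_ACIDS,
    Cluster,
    ClusterSet,
    ProteinRecord,
    aa_index,
)
from halocog.simulate import (
    SimulationConfig,
    simulate_gene_content,
    simulate_sequences,
    simulate_species_tree,
)

from conftest import read_tree


def _random_protein(rng, length, pid="p", genome="G"):
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinRecord(pid, genome, seq)


class TestAllVsAll:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        a = _random_protein(rng, 100, "a", "G1")
        b = ProteinRecord("b", "G2", a.sequence)
        hits = all_vs_all_similarity([a, b])
        assert len(hits) == 2  # symmetric pair
        assert {h.query_id for h in hits} == {"a", "b"}
        for h in hits:
            assert h.identity == 1.0
            assert h.query_coverage == 1.0
            assert h.target_coverage == 1.0

    def test_unrelated_sequences_produce_no_hit(self):
        rng = np.random.default_rng(1)
        a = _random_protein(rng, 100, "a", "G1")
        b = _random_protein(rng, 100, "b", "G2")
        assert all_vs_all_similarity([a, b], prefilter=False) == []

    def test_half_sequence_coverage_threshold(self):
        rng = np.random.default_rng(2)
        a = _random_protein(rng, 100, "a", "G1")
        half = ProteinRecord("h", "G2", a.sequence[:50])
        kept = all_vs_all_similarity([a, half], min_coverage=0.5,
                                     prefilter=False)
        assert len(kept) == 2
        h = next(x for x in kept if x.query_id == "a")
        assert h.query_coverage == pytest.approx(0.5)
        assert h.target_coverage == pytest.approx(1.0)
        dropped = all_vs_all_similarity([a, half], min_coverage=0.6,
                                        prefilter=False)
        assert dropped == []

    def test_prefilter_matches_exhaustive_search(self, small_sim):
        """The k-mer prefilter is a pure speedup: identical hit list."""
        _, _, _, _, genomes = small_sim
        subset = genomes.records[:60]
        fast = all_vs_all_similarity(subset, prefilter=True)
        slow = all_vs_all_similarity(subset, prefilter=False)
        assert fast == slow

    def test_requires_two_proteins(self):
        with pytest.raises(ValueError):
            all_vs_all_similarity([ProteinRecord("a", "G1", "MKV")])


def _hit(a, b):
    return [
        SimilarityHit(a, b, 0.9, 0.9, 0.9, 100.0),
        SimilarityHit(b, a, 0.9, 0.9, 0.9, 100.0),
    ]


class TestGreedyCluster:
    def test_mutual_trio_forms_one_cluster(self):
        prots = [
            ProteinRecord("a", "G1", "M" * 30),
            ProteinRecord("b", "G2", "M" * 25),
            ProteinRecord("c", "G3", "M" * 20),
        ]
        hits = _hit("a", "b") + _hit("b", "c") + _hit("a", "c")
        cs = greedy_cluster(hits, prots)
        assert cs.n_clusters == 1
        assert cs.clusters[0].size == 3
        assert cs.n_singletons == 0

    def test_chain_leaves_far_end_as_singleton(self):
        # a-b and b-c hit, no a-c; longest (a) seeds the cluster, takes b;
        # c has no unassigned neighbour left
        prots = [
            ProteinRecord("a", "G1", "M" * 30),
            ProteinRecord("b", "G2", "M" * 25),
            ProteinRecord("c", "G3", "M" * 20),
        ]
        hits = _hit("a", "b") + _hit("b", "c")
        cs = greedy_cluster(hits, prots)
        assert cs.n_clusters == 1
        assert cs.clusters[0].member_ids == ["a", "b"]
        assert [s.protein_id for s in cs.singletons] == ["c"]

    def test_no_hits_all_singletons(self):
        prots = [
            ProteinRecord(f"p{i}", f"G{i}", "MKVL" + "A" * i)
            for i in range(5)
        ]
        cs = greedy_cluster([], prots)
        assert cs.n_clusters == 0
        assert cs.n_singletons == 5


class TestAlignCluster:
    def test_single_member(self):
        c = Cluster("c", (ProteinRecord("a", "G1", "MKVLW"),))
        msa = align_cluster(c)
        assert msa.rows == ["MKVLW"]

    def test_identical_pair_gap_free(self):
        c = Cluster("c", (
            ProteinRecord("a", "G1", "MKVLW" * 4),
            ProteinRecord("b", "G2", "MKVLW" * 4),
        ))
        msa = align_cluster(c)
        assert msa.rows[0] == msa.rows[1]
        assert GAP not in msa.rows[0]

    def test_indel_example(self):
        c = Cluster("c", (
            ProteinRecord("p1", "G1", "ACDE"),
            ProteinRecord("p2", "G2", "ACE"),
        ))
        msa = align_cluster(c)
        assert msa.n_columns == 4
        assert msa.row("p2").count(GAP) == 1
        assert msa.degapped("p1") == "ACDE"
        assert msa.degapped("p2") == "ACE"

    def test_degap_invariant_on_simulated_family(self, small_refined):
        refined, _ = small_refined
        cluster = max(refined.clusters, key=lambda c: c.size)
        msa = align_cluster(cluster)
        for m in cluster.members:
            assert msa.degapped(m.protein_id) == m.sequence


class TestProfileSimilarity:
    def test_profile_against_itself(self):
        msa = MSA(ids=["a", "b"], rows=["ACDE", "ACDE"])
        score, mutual = profile_similarity(msa, msa)
        assert mutual == 1.0
        expected = sum(
            BLOSUM62[aa_index(c), aa_index(c)] for c in "ACDE"
        )
        assert score == pytest.approx(expected)

    def test_profile_against_its_half(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        full = MSA(ids=["a"], rows=[seq])
        half = MSA(ids=["a"], rows=[seq[:20]])
        _, mutual = profile_similarity(full, half)
        assert mutual == pytest.approx(0.5)

    def test_unrelated_profiles_score_nonpositive_per_column(self):
        rng = np.random.default_rng(4)
        a = MSA(ids=["a"], rows=["".join(rng.choice(list(AMINO_ACIDS), 80))])
        b = MSA(ids=["b"], rows=["".join(rng.choice(list(AMINO_ACIDS), 80))])
        score, mutual = profile_similarity(a, b)
        aligned = mutual * 80
        assert score / max(aligned, 1.0) <= 0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_similarity(MSA([], []), MSA(["a"], ["AC"]))


def _family_clusters(truth, genomes, families=None):
    by_family = defaultdict(list)
    for rec in genomes:
        by_family[truth.family_membership[rec.protein_id]].append(rec)
    items = sorted(by_family.items())
    if families is not None:
        items = [kv for kv in items if kv[0] in families]
    return [Cluster(fam, tuple(ms)) for fam, ms in items]


class TestMergeFullLength:
    def test_split_family_is_remerged(self, small_sim):
        _, _, _, truth, genomes = small_sim
        fam = max(
            _family_clusters(truth, genomes), key=lambda c: c.size
        )
        half = fam.size // 2
        a = Cluster("a", fam.members[:half])
        b = Cluster("b", fam.members[half:])
        merged = merge_full_length(ClusterSet([a, b], []))
        assert merged.n_clusters == 1
        assert set(merged.clusters[0].member_ids) == set(fam.member_ids)

    def test_unrelated_families_stay_apart(self, small_sim):
        _, _, _, truth, genomes = small_sim
        fams = _family_clusters(truth, genomes)
        two = [c for c in fams if c.size >= 3][:2]
        merged = merge_full_length(ClusterSet(list(two), []))
        assert merged.n_clusters == 2

    def test_empty_set(self):
        merged = merge_full_length(ClusterSet([], []))
        assert merged.n_clusters == 0


class TestGeneTree:
    def test_two_rows_single_edge(self):
        msa = MSA(ids=["a", "b"], rows=["AAAA", "AAAC"])
        tree = build_gene_tree(msa)
        tips = {t.name: t for t in tree.tips()}
        d = -np.log(0.75)
        total = tips["a"].length + tips["b"].length
        assert total == pytest.approx(d)

    def test_identical_rows_zero_lengths(self):
        msa = MSA(ids=["a", "b", "c"], rows=["ACDE"] * 3)
        tree = build_gene_tree(msa)
        assert all(
            (n.length or 0) == pytest.approx(0.0)
            for n in tree.traverse(include_self=False)
        )

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            build_gene_tree(MSA(ids=["a"], rows=["ACDE"]))

    def test_topology_matches_least_squares_oracle(self):
        """NJ vs exhaustive least-squares fit over the 3 quartet
        topologies, on sequences evolved along a known quartet."""
        rng = np.random.default_rng(5)
        L = 400
        root = rng.integers(0, 20, L)

        def mutate(seq, p):
            hit = rng.random(L) < p
            return np.where(hit, (seq + rng.integers(1, 20, L)) % 20, seq)

        internal_a = mutate(root, 0.05)
        internal_b = mutate(root, 0.05)
        leaves = {
            "a": mutate(internal_a, 0.08),
            "b": mutate(internal_a, 0.12),
            "c": mutate(internal_b, 0.10),
            "d": mutate(internal_b, 0.09),
        }
        aa = np.array(list(AMINO_ACIDS))
        ids = sorted(leaves)
        msa = MSA(ids=ids, rows=["".join(aa[leaves[i]]) for i in ids])
        # oracle: independent distance computation + least squares
        dist = {}
        for x, y in combinations(ids, 2):
            ident = np.mean(
                [p == q for p, q in zip(msa.row(x), msa.row(y))]
            )
            dist[(x, y)] = -np.log(max(ident, 0.01))
        topologies = [
            (("a", "b"), ("c", "d")),
            (("a", "c"), ("b", "d")),
            (("a", "d"), ("b", "c")),
        ]
        pairs = list(combinations(ids, 2))

        def residual(topology):
            (p1, p2), (q1, q2) = topology
            # 5 edges: 4 terminal + 1 internal
            edge_of = {p1: 0, p2: 1, q1: 2, q2: 3}
            rows = []
            for x, y in pairs:
                r = [0.0] * 5
                r[edge_of[x]] = 1
                r[edge_of[y]] = 1
                same = {x, y} in ({p1, p2}, {q1, q2})
                if not same:
                    r[4] = 1
                rows.append(r)
            A = np.array(rows)
            b = np.array([dist[p] for p in pairs])
            _, res, _, _ = np.linalg.lstsq(A, b, rcond=None)
            fit = A @ np.linalg.lstsq(A, b, rcond=None)[0]
            return float(((fit - b) ** 2).sum())

        best = min(topologies, key=residual)
        tree = build_gene_tree(msa)
        # extract the cherry split from the NJ tree
        splits = set()
        for node in tree.non_tips():
            names = frozenset(t.name for t in node.tips())
            if len(names) == 2:
                splits.add(names)
        assert frozenset(best[0]) in splits or frozenset(best[1]) in splits


class TestMidpointRoot:
    def test_two_leaf_symmetry(self):
        rooted = midpoint_root(read_tree("(A:2,B:0);"))
        lengths = sorted(c.length for c in rooted.children)
        assert lengths == pytest.approx([1.0, 1.0])

    def test_caterpillar_known_edge(self):
        tree = read_tree("(((A:5,B:1)X:1,C:1)Y:1,D:1)root;")
        rooted = midpoint_root(tree)
        # longest path A-D has length 8; midpoint sits on A's branch,
        # 4 from A
        depths = {t.name: rooted.distance(t) for t in rooted.tips()}
        assert depths["A"] == pytest.approx(4.0)
        assert depths["D"] == pytest.approx(4.0)

    def test_halves_balanced_invariant(self):
        tree = simulate_species_tree(12, 13)
        rooted = midpoint_root(tree)
        depths = sorted(
            rooted.distance(t) for t in rooted.tips()
        )
        dm = rooted.tip_tip_distances()
        longest = max(
            dm[a, b]
            for a, b in combinations([t.name for t in rooted.tips()], 2)
        )
        assert abs(depths[-1] - longest / 2) < 1e-9

    def test_idempotent_topology(self):
        tree = simulate_species_tree(8, 21)
        once = midpoint_root(tree)
        twice = midpoint_root(once)

        def splitset(t):
            return {
                frozenset(x.name for x in n.tips())
                for n in t.non_tips()
            }

        assert splitset(once) == splitset(twice)

    def test_zero_lengths_warn(self):
        tree = read_tree("((A:0,B:0)I:0,C:0);")
        with pytest.warns(UserWarning):
            rooted = midpoint_root(tree)
        assert {t.name for t in rooted.tips()} == {"A", "B", "C"}


class TestParalogyIndex:
    def test_definition(self):
        single = [ProteinRecord(f"p{i}", f"G{i}", "MK") for i in range(5)]
        assert paralogy_index(single) == 1.0
        paralogs = [
            ProteinRecord(f"p{i}", f"G{i % 3}", "MK") for i in range(6)
        ]
        assert paralogy_index(paralogs) == 2.0
        assert paralogy_index(single[:1]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            paralogy_index([])


def _mixed_members(leaf_genomes):
    return [
        ProteinRecord(pid, genome, "M")
        for pid, genome in leaf_genomes.items()
    ]


def _relabelled_tree(n_leaves, seed, n_genomes):
    """Random tree whose leaves are proteins from a few genomes."""
    rng = np.random.default_rng(seed)
    tree = simulate_species_tree(n_leaves, seed)
    leaf_genomes = {}
    for i, tip in enumerate(tree.tips()):
        pid = f"x{i:02d}"
        tip.name = pid
        leaf_genomes[pid] = f"g{rng.integers(n_genomes)}"
    return tree, leaf_genomes


def _best_single_cut(tree, members):
    """Independent exhaustive search over all single edge cuts."""
    by_id = {m.protein_id: m for m in members}
    all_names = sorted(by_id)
    current = coverage_paralogy_ratio(members)
    best = None
    for node in tree.preorder(include_self=False):
        names = sorted(
            t.name for t in (node.tips() if not node.is_tip() else [node])
        )
        if len(names) == len(all_names):
            continue
        comp = sorted(set(all_names) - set(names))
        rc = coverage_paralogy_ratio([by_id[n] for n in names])
        rm = coverage_paralogy_ratio([by_id[n] for n in comp])
        if rc > current and rm > current:
            cand = (min(rc, rm), len(names), names)
            if best is None or (
                cand[0] > best[0] + 1e-12
                or (abs(cand[0] - best[0]) <= 1e-12
                    and (cand[1] > best[1]
                         or (cand[1] == best[1] and cand[2][0] < best[2][0])))
            ):
                best = cand
    return None if best is None else (set(best[2]),
                                      set(all_names) - set(best[2]))


class TestParseSubtrees:
    def test_single_copy_tree_unsplit(self):
        tree, leaf_genomes = _relabelled_tree(6, 1, n_genomes=100)
        # force distinct genomes
        for i, pid in enumerate(leaf_genomes):
            leaf_genomes[pid] = f"g{i}"
        members = _mixed_members(leaf_genomes)
        parts = parse_subtrees(tree, members)
        assert len(parts) == 1
        assert parts[0].size == 6

    def test_two_clean_duplicate_clades_split(self):
        g = 4
        clade1 = ",".join(f"a{i}:1" for i in range(g))
        clade2 = ",".join(f"b{i}:1" for i in range(g))
        tree = read_tree(f"(({clade1}):1,({clade2}):1);")
        members = [
            ProteinRecord(f"a{i}", f"g{i}", "M") for i in range(g)
        ] + [
            ProteinRecord(f"b{i}", f"g{i}", "M") for i in range(g)
        ]
        parts = parse_subtrees(tree, members)
        assert len(parts) == 2
        part_ids = sorted(tuple(p.member_ids) for p in parts)
        assert part_ids[0] == tuple(f"a{i}" for i in range(g))
        assert part_ids[1] == tuple(f"b{i}" for i in range(g))

    @pytest.mark.parametrize("seed", range(12))
    def test_consistent_with_single_cut_oracle(self, seed):
        n_leaves = 4 + seed % 5  # 4..8 leaves
        tree, leaf_genomes = _relabelled_tree(n_leaves, seed, n_genomes=3)
        members = _mixed_members(leaf_genomes)
        parts = parse_subtrees(tree, members)
        # partition property
        out_ids = sorted(pid for p in parts for pid in p.member_ids)
        assert out_ids == sorted(leaf_genomes)
        # oracle agreement on the first cut
        cut = _best_single_cut(tree, members)
        if cut is None:
            assert len(parts) == 1
        else:
            side_a, side_b = cut
            for p in parts:
                ids = set(p.member_ids)
                assert ids <= side_a or ids <= side_b
        # the minimum part ratio never decreases
        whole = coverage_paralogy_ratio(members)
        assert min(
            coverage_paralogy_ratio(p.members) for p in parts
        ) >= whole - 1e-12


class TestRefine:
    def test_fixpoint_converges_immediately(self, small_refined):
        refined, _ = small_refined
        again, log = refine_clusters(refined)
        assert log[0]["merges"] == 0
        assert log[0]["splits"] == 0
        assert len(log) == 1

    def test_repairs_oversplit_and_fused_clusters(self, small_sim):
        # fuse two full-complement single-copy families: for those the
        # clean unfusing cut strictly dominates any impure cut under the
        # coverage/paralogy objective
        _, _, _, truth, genomes = small_sim
        n_genomes = len(genomes.genome_ids)
        fams = [
            c for c in _family_clusters(truth, genomes)
            if c.size == n_genomes and len(c.genome_ids) == n_genomes
        ]
        target = fams[0]
        half = target.size // 2
        damaged = [
            Cluster("x1", target.members[:half]),
            Cluster("x2", target.members[half:]),
        ]
        fused = Cluster(
            "x3", fams[1].members + fams[2].members
        )
        rest = [
            Cluster(f"r{i}", c.members)
            for i, c in enumerate(_family_clusters(truth, genomes))
            if c.cluster_id not in
            (target.cluster_id, fams[1].cluster_id, fams[2].cluster_id)
            and c.size >= 2
        ]
        refined, log = refine_clusters(
            ClusterSet(damaged + [fused] + rest, [])
        )
        from sklearn.metrics import adjusted_rand_score

        lt, lp = [], []
        for c in refined.clusters:
            for m in c.members:
                lt.append(truth.family_membership[m.protein_id])
                lp.append(c.cluster_id)
        assert adjusted_rand_score(lt, lp) == 1.0

    def test_zero_iterations_returns_input(self, small_refined):
        refined, _ = small_refined
        out, log = refine_clusters(refined, max_iterations=0)
        assert log == []
        assert [c.member_ids for c in out.clusters] == [
            c.member_ids for c in refined.clusters
        ]

    def test_partition_property(self, small_refined, small_sim):
        _, _, _, _, genomes = small_sim
        refined, _ = small_refined
        clustered = [pid for c in refined.clusters for pid in c.member_ids]
        assert len(clustered) == len(set(clustered))
        singles = {s.protein_id for s in refined.singletons}
        assert set(clustered).isdisjoint(singles)
        assert set(clustered) | singles == {
            r.protein_id for r in genomes
        }


class TestAAI:
    def test_self_identity_is_100(self, small_refined):
        refined, _ = small_refined
        genome = next(iter(refined.clusters[0].genome_ids))
        assert compute_aai(genome, genome, refined) == pytest.approx(100.0)

    def test_symmetry(self, small_refined):
        refined, _ = small_refined
        genomes = sorted(
            set.union(*[c.genome_ids for c in refined.clusters])
        )
        a, b = genomes[0], genomes[1]
        assert compute_aai(a, b, refined) == pytest.approx(
            compute_aai(b, a, refined)
        )

    def test_known_divergence_closed_form(self):
        # two genomes at fixed tree distance; per-branch substitution
        # matrices have the form aI + bJ and compose in closed form
        d, t, n_fam, L = 0.25, 0.4, 60, 150
        tree = read_tree(f"(G0001:{t},G0002:{t});")
        cfg = SimulationConfig(
            n_genomes=2, n_families=n_fam, gain_rate=0.0, loss_rate=0.0,
            dup_rate=0.0, root_presence_prob=1.0, seq_length=L,
            within_family_divergence=d, seed=17,
        )
        _, truth = simulate_gene_content(tree, cfg)
        genomes = simulate_sequences(truth, cfg)
        clusters = ClusterSet(
            [
                c.with_alignment(align_cluster(c))
                for c in _family_clusters(truth, genomes)
            ],
            [],
        ).relabel()
        p = 1.0 - np.exp(-d * t)
        a1, b1 = 1.0 - p - p / 19.0, p / 19.0
        # compose the two branch matrices (a1*I + b1*J)^2, J = ones(20)
        a2 = a1 * a1
        b2 = 2 * a1 * b1 + 20 * b1 * b1
        expected = 100.0 * (a2 + b2)
        observed = compute_aai("G0001", "G0002", clusters)
        sigma = 100.0 * np.sqrt(
            (expected / 100) * (1 - expected / 100) / (n_fam * L)
        )
        assert abs(observed - expected) < 3 * sigma

    def test_no_shared_clusters_error(self):
        c = Cluster("c", (
            ProteinRecord("a", "G1", "MKVL"),
            ProteinRecord("b", "G2", "MKVL"),
        ))
        with pytest.raises(ValueError):
            compute_aai("G1", "G9", ClusterSet([c], []))
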