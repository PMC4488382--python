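import hashlib
from pathlib import Path

import numpy as np
import pytest

from luciscreen.phylo import monophyly_check
from luciscreen.selection import STOPS, ng86_pair
from luciscreen.seqio import MultipleAlignment, read_fasta, read_phenotype_table
from luciscreen.simulate import (
    EvolutionParams,
    StudyConfig,
    _random_cds,
    evolve_codons,
    generate_study,
    simulate_tree,
)


def two_taxon_tree(divergence: float):
    tree = simulate_tree(2, seed=1, labels=["A", "B"])
    for lf in tree.leaf_node_iter():
        lf.edge.length = divergence / 2
    return tree


class TestSimulateTree:
    def test_deterministic_under_seed(self):
        from luciscreen.phylo import newick_string

        t1 = simulate_tree(10, seed=4)
        t2 = simulate_tree(10, seed=4)
        assert newick_string(t1) == newick_string(t2)

    def test_binary_topology_and_leaf_count(self):
        tree = simulate_tree(22, seed=9)
        leaves = tree.leaf_nodes()
        internals = [n for n in tree if not n.is_leaf()]
        assert len(leaves) == 22
        assert len(internals) == 21  # seed node + 20 further binary splits

    def test_branch_lengths_positive_unit_depth(self):
        tree = simulate_tree(8, seed=2)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length > 0
        for lf in tree.leaf_nodes():
            assert lf.distance_from_root() == pytest.approx(1.0)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)


class TestEvolveCodons:
    def test_zero_branch_lengths_copy_root(self):
        tree = two_taxon_tree(0.0)
        root = _random_cds(np.random.default_rng(0), 50, {})
        res = evolve_codons(tree, root, EvolutionParams(), seed=1)
        assert res.leaf_cds["A"] == res.leaf_cds["B"] == root
        assert res.events == []

    def test_omega_zero_log_contains_no_nonsynonymous_events(self):
        tree = two_taxon_tree(0.5)
        root = _random_cds(np.random.default_rng(1), 200, {})
        res = evolve_codons(tree, root, EvolutionParams(omega=0.0), seed=2)
        assert res.events  # something happened
        assert all(e.synonymous for e in res.events)

    def test_omega_zero_dn_zero_without_codon_double_hits(self):
        """dN = 0 holds exactly whenever no codon took events at more than
        one position (the multiple-hit pathway artifact cannot arise)."""
        tree = two_taxon_tree(0.5)
        for s in range(5):
            root = _random_cds(np.random.default_rng(100 + s), 200, {})
            res = evolve_codons(tree, root, EvolutionParams(omega=0.0), seed=s)
            positions = {}
            for e in res.events:
                positions.setdefault(e.codon_index, set()).add(e.position)
            r = ng86_pair(res.leaf_cds["A"], res.leaf_cds["B"])
            if all(len(p) <= 1 for p in positions.values()):
                assert r.dN == 0.0
            assert r.Nd <= sum(len(p) > 1 for p in positions.values())

    def test_no_stops_ever(self):
        tree = simulate_tree(6, seed=3)
        root = _random_cds(np.random.default_rng(2), 100, {})
        res = evolve_codons(tree, root, EvolutionParams(omega=0.5), seed=3)
        for seq in res.leaf_cds.values():
            for k in range(0, len(seq), 3):
                assert seq[k : k + 3] not in STOPS

    def test_invariant_sites_never_substituted(self):
        tree = two_taxon_tree(2.0)
        root = _random_cds(np.random.default_rng(3), 60, {})
        locked = frozenset({0, 10, 59})
        res = evolve_codons(
            tree, root, EvolutionParams(invariant_sites=locked), seed=4
        )
        assert all(e.codon_index not in locked for e in res.events)
        for seq in res.leaf_cds.values():
            for i in locked:
                assert seq[3 * i : 3 * i + 3] == root[3 * i : 3 * i + 3]

    def test_counting_underestimates_only_through_multiple_hits(self):
        """Sd + Nd <= true event count between root and a leaf, with
        equality when every codon took at most one event."""
        root = _random_cds(np.random.default_rng(4), 300, {})
        tree = two_taxon_tree(0.3)
        res = evolve_codons(tree, root, EvolutionParams(omega=0.5), seed=5)
        # compare each leaf against the root directly
        for leaf, seq in res.leaf_cds.items():
            n_events = sum(
                1 for e in res.events if _leaf_branch(tree, leaf) == e.branch
            )
            r = ng86_pair(root, seq)
            assert r.Sd + r.Nd <= n_events + 1e-9
            per_codon = {}
            for e in res.events:
                if _leaf_branch(tree, leaf) == e.branch:
                    per_codon[e.codon_index] = per_codon.get(e.codon_index, 0) + 1
            if per_codon and max(per_codon.values()) <= 1:
                assert r.Sd + r.Nd == pytest.approx(n_events)

    def test_event_log_reconstructs_leaves(self):
        tree = two_taxon_tree(0.4)
        root = _random_cds(np.random.default_rng(6), 100, {})
        res = evolve_codons(tree, root, EvolutionParams(omega=0.3), seed=7)
        for leaf, seq in res.leaf_cds.items():
            cur = [root[3 * i : 3 * i + 3] for i in range(100)]
            for e in res.events:
                if e.branch == _leaf_branch(tree, leaf):
                    assert cur[e.codon_index] == e.from_codon
                    cur[e.codon_index] = e.to_codon
            assert "".join(cur) == seq


def _leaf_branch(tree, label):
    from luciscreen.simulate import _branch_key

    for lf in tree.leaf_node_iter():
        if lf.taxon.label == label:
            return _branch_key(lf)
    raise KeyError(label)


class TestGenerateStudy:
    def test_candidate_only_in_luminous_decoys_everywhere(self, small_study):
        study_dir, truth = small_study
        phen = read_phenotype_table(study_dir / "phenotypes.tsv")
        for sp in phen.species:
            recs = read_fasta(study_dir / f"{sp}.proteome.fasta", moltype="protein")
            has_fyy_gene = any("_FYY" in r.id for r in recs)
            assert has_fyy_gene == phen.luminous(sp)
            assert any("_dec" in r.id for r in recs)

    def test_c_terminal_screen_separates_phenotypes(self, small_study):
        from luciscreen.motif_screen import MotifSpec, scan_proteome
        from luciscreen.simulate import load_study_proteomes

        study_dir, truth = small_study
        proteomes = load_study_proteomes(study_dir)
        phen = truth.phenotypes
        for sp, prot in proteomes.items():
            ct = scan_proteome(prot, MotifSpec("FYY", "c_terminal"))
            anym = scan_proteome(prot, MotifSpec("FYY", "any"))
            assert (ct.n_records_with_hit > 0) == phen[sp]
            assert anym.n_records_with_hit > 0  # decoys fire everywhere

    def test_three_families_monophyletic_in_nj_tree(self, small_study):
        from luciscreen.align import identity_matrix
        from luciscreen.phylo import DistanceMatrix, nj_tree
        from luciscreen.simulate import load_study_proteomes

        study_dir, truth = small_study
        proteomes = load_study_proteomes(study_dir)
        fam_members = {f: set(d["members"]) for f, d in truth.families.items()}
        pool = [
            r
            for prot in proteomes.values()
            for r in prot.records
            if any(r.id in m for m in fam_members.values())
        ]
        m = identity_matrix(pool, "ignore_gaps")
        d = 1.0 - m.values / 100.0
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(labels=m.labels, values=d))
        for fam, members in fam_members.items():
            assert monophyly_check(tree, members), fam

    def test_purifying_family_is_most_conserved(self, small_study):
        from luciscreen.align import identity_matrix, summarize_identity_matrix
        from luciscreen.simulate import load_study_proteomes

        study_dir, truth = small_study
        proteomes = load_study_proteomes(study_dir)
        by_id = {r.id: r for p in proteomes.values() for r in p.records}
        mins = {}
        for fam, d in truth.families.items():
            recs = [by_id[m] for m in d["members"]]
            msa = MultipleAlignment([(r.id, r.seq) for r in recs])
            mins[fam] = summarize_identity_matrix(identity_matrix(msa))["min"]
        assert mins["FYY"] >= mins["2OGFe1"]
        assert mins["FYY"] >= mins["2OGFe2"]

    def test_byte_identical_regeneration(self, tmp_path):
        cfg = StudyConfig(n_luminous=4, n_nonluminous=1, n_codons=60, n_decoys=1, decoy_codons=50,
                          anchors={10: ("H", "iron_his1"), 12: ("D", "iron_asp"),
                                   20: ("H", "iron_his2"), 25: ("R", "rxs_arg"),
                                   27: ("S", "rxs_ser")})
        h = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            generate_study(cfg, seed=3, out_dir=out)
            digest = hashlib.sha256()
            for f in sorted(Path(out).iterdir()):
                digest.update(f.name.encode())
                digest.update(f.read_bytes())
            h.append(digest.hexdigest())
        assert h[0] == h[1]

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(n_luminous=0)

    def test_config_file_round_trip(self, tmp_path):
        f = tmp_path / "study.cfg"
        f.write_text("n_luminous = 6\ncandidate_omega = 0.2\nparalog_omegas = 0.4,0.6\n")
        cfg = StudyConfig.from_file(f)
        assert cfg.n_luminous == 6
        assert cfg.candidate_omega == 0.2
        assert cfg.paralog_omegas == (0.4, 0.6)
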