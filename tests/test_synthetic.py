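import json
from dataclasses import dataclass

import numpy as np
import pytest

from xenoscan.homology import compute_ahs, filter_hits, hit_table_from_records
from xenoscan.phylo import read_fasta_alignment
from xenoscan.synthetic import (ScenarioConfig, generate_scenario,
                                simulate_alignment, truth_evaluation)
from xenoscan.taxonomy import taxonomy_from_rows
from xenoscan.trees import Node, Tree, read_newick


SMALL = dict(n_genes=40, n_planted_hgt={"bacteria": 2, "fungi": 1, "viridiplantae": 1},
             contamination_injections=1, n_scaffolds=4, n_sites=120)


@pytest.fixture(scope="module")
def dataset():
    return generate_scenario(ScenarioConfig(seed=7, **SMALL))


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path):
        d1 = generate_scenario(ScenarioConfig(seed=3, **SMALL))
        d2 = generate_scenario(ScenarioConfig(seed=3, **SMALL))
        p1, p2 = tmp_path / "a", tmp_path / "b"
        d1.write(p1)
        d2.write(p2)
        files1 = sorted(f.relative_to(p1) for f in p1.rglob("*") if f.is_file())
        files2 = sorted(f.relative_to(p2) for f in p2.rglob("*") if f.is_file())
        assert files1 == files2
        for f in files1:
            assert (p1 / f).read_bytes() == (p2 / f).read_bytes()

    def test_different_seed_differs(self):
        d1 = generate_scenario(ScenarioConfig(seed=3, **SMALL))
        d2 = generate_scenario(ScenarioConfig(seed=4, **SMALL))
        assert d1.truth != d2.truth


class TestBookkeeping:
    def test_truth_counts_match_config(self, dataset):
        genes = dataset.truth["genes"]
        hgt = [g for g, t in genes.items() if t["label"] == "hgt"]
        assert len(dataset.truth["events"]) == 4
        assert sum(1 for t in genes.values() if t["label"] == "contaminant") == 1
        # every species gene is labeled
        for sp, prot in dataset.proteomes.items():
            for g in prot:
                assert g in genes

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            generate_scenario(ScenarioConfig(
                seed=1, n_genes=3,
                n_planted_hgt={"bacteria": 5, "fungi": 0, "viridiplantae": 0}))

    def test_contaminants_lack_cryptic_homolog_and_are_high_identity(self, dataset):
        for g in dataset.truth["contaminants"]:
            assert dataset.cryptic_homologs[g] is False
            sp = g.split("_")[0]
            hits = dataset.hits[sp]
            sub = hits[hits["query_id"] == g]
            donors = sub[sub["subject_id"].str.startswith("P")]
            assert donors["pct_identity"].max() > 70

    def test_planted_best_nonself_hit_in_donor_kingdom(self, dataset):
        tax = taxonomy_from_rows(dataset.taxonomy_rows)
        base = {"bacteria": 3, "fungi": 4, "viridiplantae": 5}
        for g, t in dataset.truth["genes"].items():
            if t["label"] != "hgt":
                continue
            sp = g.split("_")[0]
            hits = dataset.hits[sp]
            sub = hits[hits["query_id"] == g].copy()
            nonself = sub[sub["subject_taxids"].map(
                lambda ts: not any(tax.is_descendant(x, 20) for x in ts))]
            top = nonself.sort_values("bitscore", ascending=False).iloc[0]
            assert all(tax.is_descendant(x, base[t["kingdom"]])
                       for x in top["subject_taxids"])


class TestAhsSelfConsistency:
    def test_planted_transfers_score_positive(self, dataset):
        tax = taxonomy_from_rows(dataset.taxonomy_rows)
        kingdoms = {"bacteria": 3, "fungi": 4, "viridiplantae": 5}
        for sp, df in dataset.hits.items():
            table = filter_hits(hit_table_from_records(df.to_dict("records")))
            for g, t in dataset.truth["genes"].items():
                if not g.startswith(sp):
                    continue
                if g not in set(table.df["query_id"]):
                    continue
                r = compute_ahs(table, g, tax, 2, 20, kingdoms)
                if t["label"] == "hgt":
                    assert r.ahs > 0, g
                elif t["label"] == "vertical":
                    assert r.ahs <= 0, g


class TestRoundTrip:
    def test_emitted_files_load_through_readers(self, dataset, tmp_path):
        from xenoscan.enrichment import read_annotations, read_go_dag
        from xenoscan.genome_context import read_gene_map
        from xenoscan.grouping import read_domains, read_orthogroups
        from xenoscan.homology import read_hit_table
        from xenoscan.taxonomy import load_taxonomy

        out = dataset.write(tmp_path / "ds")
        tax = load_taxonomy(out / "taxonomy.tsv")
        assert tax.is_descendant(21, 2)
        for sp in dataset.hits:
            t = read_hit_table(out / f"hits_{sp}.tsv")
            assert len(t) == len(dataset.hits[sp])
            gm = read_gene_map(out / f"genemap_{sp}.tsv")
            assert sorted(gm.genes()) == sorted(dataset.proteomes[sp])
        assert read_orthogroups(out / "orthogroups.tsv") == dataset.orthogroups
        assert read_domains(out / "domains.tsv") == dataset.domains
        dag = read_go_dag(out / "go_dag.tsv")
        assert dag.parents == dataset.go_parents
        ann = read_annotations(out / "go_annotations.tsv")
        assert ann == dataset.go_annotations
        for fam, aln in dataset.alignments.items():
            back = read_fasta_alignment(out / "alignments" / f"{fam}.fasta")
            assert back.ids == aln.ids and back.rows == aln.rows
        truth = json.loads((out / "truth.json").read_text())
        assert truth["genes"] == dataset.truth["genes"]


class TestSimulateAlignment:
    def test_zero_length_star_identical_rows(self):
        root = Node(None)
        for name in "ABC":
            root.add(Node(name, 0.0))
        aln = simulate_alignment(Tree(root), 50, seed=1)
        assert len(set(aln.rows)) == 1

    def test_long_branches_reach_stationary_identity(self):
        t = read_newick("(A:50.0,B:50.0);")
        aln = simulate_alignment(t, 10_000, seed=2)
        ident = np.mean([a == b for a, b in zip(aln.rows[0], aln.rows[1])])
        assert ident == pytest.approx(0.05, abs=0.01)

    def test_seeded_reproducibility(self):
        t = read_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        a1 = simulate_alignment(t, 100, seed=9)
        a2 = simulate_alignment(t, 100, seed=9)
        assert a1.rows == a2.rows


@dataclass
class FakeResult:
    validated_genes: set
    rejected_genes: set
    origin_by_gene: dict
    n_events: int
    sharing_by_genes: dict


class TestTruthEvaluation:
    def truth(self):
        return {
            "genes": {
                "A_h1": {"label": "hgt", "kingdom": "bacteria", "event": "E0"},
                "A_h2": {"label": "hgt", "kingdom": "fungi", "event": "E1"},
                "A_v1": {"label": "vertical"},
                "A_v2": {"label": "vertical"},
                "A_c1": {"label": "contaminant", "kingdom": "bacteria"},
                "A_c2": {"label": "contaminant", "kingdom": "fungi"},
            },
            "events": {
                "E0": {"kingdom": "bacteria", "sharing": "single",
                       "n_acquisitions": 1, "genes": ["A_h1"]},
                "E1": {"kingdom": "fungi", "sharing": "single",
                       "n_acquisitions": 1, "genes": ["A_h2"]},
            },
            "contaminants": ["A_c1", "A_c2"],
        }

    def test_perfect_calls(self):
        res = FakeResult({"A_h1", "A_h2"}, {"A_c1", "A_c2"},
                         {"A_h1": "bacteria", "A_h2": "fungi"}, 2, {})
        m = truth_evaluation(res, self.truth())
        assert m["sensitivity"] == 1.0
        assert m["false_positive_rate"] == 0.0
        assert m["origin_accuracy"] == 1.0
        assert m["contaminant_rejection_rate"] == 1.0
        assert m["event_count_error"] == 0.0

    def test_empty_call_set(self):
        res = FakeResult(set(), set(), {}, 0, {})
        assert truth_evaluation(res, self.truth())["sensitivity"] == 0.0

    def test_one_of_two_contaminants_validated(self):
        res = FakeResult({"A_c1"}, {"A_c2"}, {"A_c1": "bacteria"}, 1, {})
        m = truth_evaluation(res, self.truth())
        assert m["contaminant_rejection_rate"] == 0.5

    def test_unknown_gene_rejected(self):
        res = FakeResult({"nope"}, set(), {}, 0, {})
        with pytest.raises(ValueError):
            truth_evaluation(res, self.truth())
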