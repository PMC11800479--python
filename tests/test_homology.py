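import math

import numpy as np
import pytest

from xenoscan.homology import (NoInformativeHits, compute_ahs, donor_hit_stats,
                               filter_hits, hit_category, read_hit_table)
from xenoscan.taxonomy import RECIPIENT, SELF

from conftest import KINGDOMS, make_hits


def brute_force_ahs(bits_and_cats):
    """Independent oracle: plain signed sum of max-normalized bitscores."""
    informative = [(b, c) for b, c in bits_and_cats if c != "SELF"]
    best = max(b for b, _ in informative)
    return sum((b / best) * (+1 if c == "DONOR" else -1) for b, c in informative)


class TestReadAndFilter:
    def test_per_query_descending_bitscore(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "qseqid\tsseqid\tpident\tlength\tevalue\tbitscore\tstaxids\tqcovhsp\n"
            "q1\ts1\t40\t100\t1e-10\t50\t101\t80\n"
            "q1\ts2\t45\t100\t1e-20\t80\t102\t80\n")
        t = read_hit_table(p)
        assert list(t.hits_for("q1")["bitscore"]) == [80.0, 50.0]

    def test_multi_taxid_cell_split(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("qseqid\tsseqid\tpident\tlength\tevalue\tbitscore\tstaxids\tqcovhsp\n"
                     "q1\ts1\t40\t100\t1e-10\t50\t562;620\t80\n")
        assert list(read_hit_table(p).df["subject_taxids"][0]) == [562, 620]

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("qseqid\tsseqid\tpident\tlength\tevalue\tbitscore\tstaxids\tqcovhsp\n")
        assert len(read_hit_table(p)) == 0

    def test_non_numeric_bitscore_strict_vs_lenient(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("qseqid\tsseqid\tpident\tlength\tevalue\tbitscore\tstaxids\tqcovhsp\n"
                     "q1\ts1\t40\t100\t1e-10\toops\t101\t80\n")
        with pytest.raises(ValueError):
            read_hit_table(p)
        assert len(read_hit_table(p, lenient=True)) == 0

    def test_evalue_threshold_and_truncation(self):
        rows = [("q1", f"s{i}", [101], 1000 - i) for i in range(600)]
        rows.append(("q1", "s_bad", [101], 999.5, 50.0, 200, 1e-2))
        t = make_hits(rows)
        f = filter_hits(t, max_evalue=1e-3, max_targets=500)
        assert len(f.hits_for("q1")) == 500
        assert "s_bad" not in f.subject_ids("q1")
        # identity case: everything already passes
        small = make_hits([("q1", "s1", [101], 100.0)])
        assert len(filter_hits(small, 1e-3, 500)) == 1


class TestHitCategory:
    def test_any_self_taxid_dominates(self, taxonomy):
        assert hit_category([21, 201], taxonomy, 2, 20, KINGDOMS) == SELF

    def test_all_donor_required_for_donor(self, taxonomy):
        assert hit_category([201, 101], taxonomy, 2, 20, KINGDOMS) == RECIPIENT
        assert hit_category([201, 301], taxonomy, 2, 20, KINGDOMS) == "DONOR:bacteria"


class TestAhs:
    def test_hand_summed_example(self, taxonomy):
        # donors 200 and 150 bits, recipient 100 -> 1.0 + 0.75 - 0.5 = 1.25
        t = make_hits([
            ("q1", "d1", [201], 200.0),
            ("q1", "d2", [301], 150.0),
            ("q1", "a1", [101], 100.0),
        ])
        r = compute_ahs(t, "q1", taxonomy, 2, 20, KINGDOMS)
        assert r.ahs == pytest.approx(1.25)
        assert r.is_candidate and r.n_donor_hits == 2 and r.n_recipient_hits == 1

    def test_only_recipient_hits(self, taxonomy):
        t = make_hits([("q1", "a1", [101], 100.0)])
        r = compute_ahs(t, "q1", taxonomy, 2, 20, KINGDOMS)
        assert r.ahs == pytest.approx(-1.0) and not r.is_candidate

    def test_zero_is_not_a_candidate(self, taxonomy):
        t = make_hits([("q1", "d1", [201], 100.0), ("q1", "a1", [101], 100.0)])
        r = compute_ahs(t, "q1", taxonomy, 2, 20, KINGDOMS)
        assert r.ahs == pytest.approx(0.0) and not r.is_candidate

    def test_self_hits_excluded_and_all_self_raises(self, taxonomy):
        t = make_hits([("q1", "self", [21], 500.0), ("q1", "d1", [201], 100.0)])
        r = compute_ahs(t, "q1", taxonomy, 2, 20, KINGDOMS)
        assert r.ahs == pytest.approx(1.0)  # self hit does not set the max
        only_self = make_hits([("q1", "self", [21], 500.0)])
        with pytest.raises(NoInformativeHits):
            compute_ahs(only_self, "q1", taxonomy, 2, 20, KINGDOMS)

    def _random_table(self, rng, n):
        taxid_for = {"DONOR": 201, "RECIPIENT": 101, "SELF": 21}
        cats = [str(rng.choice(["DONOR", "RECIPIENT", "SELF"])) for _ in range(n)]
        if all(c == "SELF" for c in cats):
            cats[0] = "DONOR"
        bits = rng.uniform(30, 400, size=n)
        rows = [(f"q", f"s{i}", [taxid_for[c]], float(b))
                for i, (c, b) in enumerate(zip(cats, bits))]
        return rows, list(zip(bits, cats))

    def test_oracle_equivalence_on_random_tables(self, taxonomy, rng):
        for _ in range(200):
            n = int(rng.integers(1, 11))
            rows, bc = self._random_table(rng, n)
            r = compute_ahs(make_hits(rows), "q", taxonomy, 2, 20, KINGDOMS)
            assert r.ahs == pytest.approx(brute_force_ahs(bc), abs=1e-12)
            # bound: each normalized score is in (0, 1]
            assert abs(r.ahs) <= r.n_donor_hits + r.n_recipient_hits + 1e-12

    def test_antisymmetry_under_label_swap(self, taxonomy, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            rows, _ = self._random_table(rng, n)
            swapped = [(q, s, [101 if t == [201] else (201 if t == [101] else 21)], b)
                       for q, s, t, b in rows]
            a1 = compute_ahs(make_hits(rows), "q", taxonomy, 2, 20, KINGDOMS).ahs
            a2 = compute_ahs(make_hits(swapped), "q", taxonomy, 2, 20, KINGDOMS).ahs
            assert a1 == pytest.approx(-a2, abs=1e-12)

    def test_monotone_in_hit_deletion(self, taxonomy):
        rows = [("q", "d1", [201], 300.0), ("q", "d2", [201], 150.0),
                ("q", "a1", [101], 250.0), ("q", "a2", [101], 90.0)]
        base = compute_ahs(make_hits(rows), "q", taxonomy, 2, 20, KINGDOMS).ahs
        no_recip = compute_ahs(make_hits(rows[:2] + rows[3:]), "q", taxonomy, 2, 20,
                               KINGDOMS).ahs
        no_donor = compute_ahs(make_hits(rows[1:]), "q", taxonomy, 2, 20, KINGDOMS).ahs
        assert no_recip >= base - 1e-12
        assert no_donor <= base + 1e-12


class TestDonorStats:
    def test_means_and_max(self, taxonomy):
        t = make_hits([
            ("q", "d1", [201], 100.0, 20.0, 90, 1e-30, 45.0),
            ("q", "d2", [201], 90.0, 30.0, 110, 1e-30, 40.0),
            ("q", "a1", [101], 80.0, 75.0, 300, 1e-30, 99.0),
        ])
        s = donor_hit_stats(t, "q", {"d1", "d2"})
        assert s.mean_pct_identity == pytest.approx(25.0)
        assert s.max_pct_identity == pytest.approx(30.0)
        assert s.mean_aln_length == pytest.approx(100.0)
        assert s.mean_query_coverage == pytest.approx(42.5)
        assert s.count == 2

    def test_single_hit_max(self, taxonomy):
        t = make_hits([("q", "d1", [201], 100.0, 75.0)])
        assert donor_hit_stats(t, "q", {"d1"}).max_pct_identity == pytest.approx(75.0)

    def test_empty_intersection_counts_zero(self):
        t = make_hits([("q", "a1", [101], 80.0)])
        s = donor_hit_stats(t, "q", {"dX"})
        assert s.count == 0 and math.isnan(s.mean_pct_identity)
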