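"""Duplication detection, Nei-Gojobori estimation and dating."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gstfam import duplication as dup
from gstfam.catalog import AnalysisConfig, CatalogTable, GeneRecord
from gstfam.duplication import (
    CODON_TABLE,
    SENSE_CODONS,
    STOP_CODONS,
    classify_pair,
    codon_sites,
    count_sites,
    divergence_time,
    find_clusters,
    jukes_cantor,
    nei_gojobori,
)
from gstfam.io_formats import SeqCollection


def brute_codon_sites(codon):
    """Independent enumeration of all 9 single-nt changes."""
    syn = nonsyn = 0.0
    for pos, nt in itertools.product(range(3), "ACGT"):
        if nt == codon[pos]:
            continue
        mutant = codon[:pos] + nt + codon[pos + 1:]
        if mutant in STOP_CODONS:
            continue
        if CODON_TABLE[mutant] == CODON_TABLE[codon]:
            syn += 1 / 3
        else:
            nonsyn += 1 / 3
    return syn, nonsyn


def brute_pathways(ca, cb):
    """Average syn/nonsyn steps over all stop-free orderings."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, syn, nonsyn, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            syn += CODON_TABLE[nxt] == CODON_TABLE[cur]
            nonsyn += CODON_TABLE[nxt] != CODON_TABLE[cur]
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    if not results:
        return None
    n = len(results)
    return sum(r[0] for r in results) / n, sum(r[1] for r in results) / n


class TestCountSites:
    def test_phenylalanine(self):
        assert codon_sites("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_methionine(self):
        assert codon_sites("ATG") == (0.0, 3.0)

    def test_all_61_sense_codons_match_bruteforce(self):
        for codon in SENSE_CODONS:
            assert codon_sites(codon) == pytest.approx(brute_codon_sites(codon)), codon

    def test_conservation_without_stop_neighbors(self):
        # TTT and ATG have no stop-adjacent changes: S + N = 3 * codons
        s, n = count_sites("TTTATG")
        assert s + n == pytest.approx(6.0)
        # TGG (Trp) reaches TGA and TAG by one change: paths excluded
        s2, n2 = count_sites("TGG")
        assert s2 + n2 == pytest.approx(3.0 - 2 / 3)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            count_sites("TTTA")
        with pytest.raises(ValueError):
            count_sites("TAATTT")  # internal stop


class TestNeiGojobori:
    def test_identical(self):
        r = nei_gojobori("TTTATGGCT", "TTTATGGCT")
        assert r.dn == 0 and r.ds == 0 and r.omega is None

    def test_hand_worked_synonymous(self):
        a = "TTT" * 11
        b = "TTC" + "TTT" * 10
        r = nei_gojobori(a, b)
        assert r.syn_sites == pytest.approx(11 / 3)
        assert r.syn_diffs == 1
        assert r.ds == pytest.approx(-0.75 * math.log(1 - 4 / 11), abs=1e-4)
        assert r.dn == 0

    def test_two_pathway_codon_matches_oracle(self):
        # TTT <-> GTA differs at two positions; both orderings are stop-free
        want = brute_pathways("TTT", "GTA")
        r = nei_gojobori("GGG" * 4 + "TTT", "GGG" * 4 + "GTA")
        assert (r.syn_diffs, r.nonsyn_diffs) == pytest.approx(want)

    def test_all_two_diff_pairs_match_oracle(self):
        for ca in SENSE_CODONS[::5]:
            for cb in SENSE_CODONS[::7]:
                if sum(x != y for x, y in zip(ca, cb)) == 0:
                    continue
                want = brute_pathways(ca, cb)
                if want is None:
                    continue
                pad = "GGG" * 4
                r = nei_gojobori(pad + ca, pad + cb)
                assert (r.syn_diffs, r.nonsyn_diffs) == pytest.approx(want), (ca, cb)

    def test_symmetric(self):
        a, b = "TTTGCTAGAGGGAAACCC", "TTCGCTAGGGGGAAACCC"
        r1, r2 = nei_gojobori(a, b), nei_gojobori(b, a)
        assert r1.dn == pytest.approx(r2.dn)
        assert r1.ds == pytest.approx(r2.ds)

    def test_gap_codons_stripped(self):
        r = nei_gojobori("TTT---GCT", "TTTGGGGCT".replace("GGG", "---"))
        full = nei_gojobori("TTTGCT", "TTTGCT")
        assert r.ds == full.ds == 0

    def test_saturation_error(self):
        with pytest.raises(ValueError, match="saturat"):
            jukes_cantor(0.8)

    def test_jc_monotone(self):
        ps = [0.0, 0.1, 0.2, 0.4, 0.6, 0.7]
        ds = [jukes_cantor(p) for p in ps]
        assert ds == sorted(ds)
        assert all(d >= p for d, p in zip(ds, ps))


class TestDivergenceTime:
    def test_zero(self):
        assert divergence_time(0.0) == 0.0

    def test_one_mya(self):
        assert divergence_time(0.03, 1.5e-8) == pytest.approx(1.0)

    def test_printed_range_endpoint(self):
        assert divergence_time(0.5352, 1.5e-8) == pytest.approx(17.84)

    def test_linear_and_inverse(self):
        assert divergence_time(0.06) == pytest.approx(2 * divergence_time(0.03))
        assert divergence_time(0.03, 3e-8) == pytest.approx(divergence_time(0.03) / 2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)


def _rec(name, chrom, start, end):
    return GeneRecord(
        name=name, locus_id=f"Capana{chrom:02d}g000001", cds_start=start,
        cds_end=end, strand="+", class_label="tau", chromosome=chrom,
    )


class TestClassifyPair:
    def test_close_same_chromosome_tandem(self):
        a = _rec("a", 1, 1000, 2000)
        b = _rec("b", 1, 52000, 53000)
        assert classify_pair(a, b) == "tandem"

    def test_cross_chromosome_segmental(self):
        assert classify_pair(_rec("a", 1, 1, 10), _rec("b", 2, 1, 10)) == "segmental"

    def test_boundary_inclusive(self):
        a = _rec("a", 1, 1000, 2000)
        b = _rec("b", 1, 102000, 103000)  # gap exactly 100000
        assert classify_pair(a, b) == "tandem"
        c = _rec("c", 1, 102001, 103000)
        assert classify_pair(a, c) == "segmental"

    def test_tandem_implies_same_chromosome(self, dataset):
        for p in dataset.truth["pairs"]:
            rec_a = dataset.catalog.get(p["gene_a"])
            rec_b = dataset.catalog.get(p["gene_b"])
            if classify_pair(rec_a, rec_b) == "tandem":
                assert rec_a.chromosome == rec_b.chromosome


class TestFindPairs:
    def test_identical_proteins_pair(self):
        cat = CatalogTable([_rec("a", 1, 1, 9), _rec("b", 2, 1, 9)])
        seq = "MKVLITGAGSGLGQELAKQFAKEGAKVIVTDINEEKLQSL"
        prots = SeqCollection([("a", "", seq), ("b", "", seq)])
        pairs = dup.find_duplicate_pairs(cat, prots)
        assert len(pairs) == 1 and pairs[0].identity_pct == 100.0

    def test_threshold_above_100_empty(self):
        cat = CatalogTable([_rec("a", 1, 1, 9), _rec("b", 2, 1, 9)])
        seq = "MKVLITGAGSGLGQELAKQFAKEGAKVIVTDINEEKLQSL"
        prots = SeqCollection([("a", "", seq), ("b", "", seq)])
        cfg = AnalysisConfig(identity_threshold_pct=101)
        assert dup.find_duplicate_pairs(cat, prots, cfg) == []

    def test_missing_protein_rejected(self):
        cat = CatalogTable([_rec("a", 1, 1, 9), _rec("b", 2, 1, 9)])
        prots = SeqCollection([("a", "", "MKV")])
        with pytest.raises(ValueError, match="missing"):
            dup.find_duplicate_pairs(cat, prots)

    def test_planted_pairs_recovered_exactly(self, dataset):
        pairs = dup.find_duplicate_pairs(dataset.catalog, dataset.proteins)
        got = {frozenset((p.gene_a, p.gene_b)) for p in pairs}
        want = {
            frozenset((p["gene_a"], p["gene_b"])) for p in dataset.truth["pairs"]
        }
        assert got == want


class TestClusters:
    def test_chained_cluster(self):
        cat = CatalogTable(
            [_rec("a", 1, 1000, 2000), _rec("b", 1, 12000, 13000),
             _rec("c", 1, 23000, 24000)]
        )
        clusters = find_clusters(cat, window=100_000)
        assert len(clusters) == 1 and clusters[0].members == ("a", "b", "c")

    def test_gap_beyond_window_no_cluster(self):
        cat = CatalogTable([_rec("a", 1, 1000, 2000), _rec("b", 1, 160_000, 161_000)])
        assert find_clusters(cat, window=100_000) == []

    def test_fixture_clusters_reported(self, table1):
        clusters = find_clusters(table1, window=100_000)
        # own single-linkage rule; compared against the printed count in docs only
        assert all(len(c.members) >= 2 for c in clusters)
        assert all(
            table1.get(m).chromosome == c.chromosome
            for c in clusters for m in c.members
        )


@given(st.floats(min_value=0.0, max_value=0.7))
@settings(max_examples=50, deadline=None)
def test_jc_at_least_p(p):
    assert jukes_cantor(p) >= p - 1e-12
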