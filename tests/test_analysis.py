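"""Dataset analytics: composition, heptads, unique domains, histograms."""
import random
from collections import Counter

import pytest

from sahscan import (
    MYO10_SAH,
    AnalysisError,
    InputError,
    RelationFlag,
    composition,
    cross_gene_identity,
    heptad_frequency,
    length_histogram,
    multi_domain_counts,
    presence_histogram,
    unique_domains,
)

from conftest import make_domain, make_record, random_protein


class TestComposition:
    def test_perfect_repeat_fractions(self):
        table = composition([make_domain("EEEEKKK")])
        assert table.fractions["E"] == pytest.approx(4 / 7)
        assert table.fractions["K"] == pytest.approx(3 / 7)
        assert table.charged_polar_fraction == pytest.approx(1.0)
        assert table.heptad_equivalent == pytest.approx(7.0)

    def test_ek_alternation(self):
        table = composition([make_domain("EK" * 7)])
        assert table.fractions["E"] == pytest.approx(0.5)
        assert table.fractions["K"] == pytest.approx(0.5)

    def test_matches_independent_tally_on_random_domains(self):
        rng = random.Random(17)
        domains = [
            make_domain(random_protein(rng, rng.randint(14, 60)), seq_id=f"s{i}")
            for i in range(100)
        ]
        table = composition(domains)
        tally = Counter()
        for d in domains:
            tally.update(d.subsequence)
        total = sum(tally.values())
        for aa, frac in table.fractions.items():
            assert frac == pytest.approx(tally[aa] / total)
        assert sum(table.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_domain_order(self):
        rng = random.Random(4)
        domains = [make_domain(random_protein(rng, 20), seq_id=f"s{i}") for i in range(10)]
        a = composition(domains)
        b = composition(list(reversed(domains)))
        assert a.fractions == b.fractions

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            composition([])


class TestHeptadFrequency:
    def test_myo10_region_contains_rererer(self):
        heptads = heptad_frequency([make_domain(MYO10_SAH)], top_n=1000)
        assert any(h.heptad == "RERERER" and h.count >= 1 for h in heptads)

    def test_eight_residue_domain_has_two_sliding_positions(self):
        heptads = heptad_frequency([make_domain("EEEEEEEE")], top_n=5)
        assert heptads[0].heptad == "EEEEEEE"
        assert heptads[0].count == 2

    def test_matches_bruteforce_substring_tally(self):
        rng = random.Random(23)
        domains = [
            make_domain(random_protein(rng, rng.randint(14, 40)), seq_id=f"s{i}")
            for i in range(30)
        ]
        tally = Counter()
        for d in domains:
            s = d.subsequence
            for i in range(len(s) - 6):
                tally[s[i : i + 7]] += 1
        ranked = heptad_frequency(domains, top_n=10 ** 6)
        assert {h.heptad: h.count for h in ranked} == dict(tally)
        # total heptad occurrences equal sum over domains of max(0, len - 6)
        assert sum(h.count for h in ranked) == sum(
            max(0, len(d.subsequence) - 6) for d in domains
        )

    def test_ties_break_lexicographically_and_top_n_respected(self):
        domains = [make_domain("KEKEKEK"), make_domain("EKEKEKE")]
        ranked = heptad_frequency(domains, top_n=1)
        assert ranked == [type(ranked[0])(heptad="EKEKEKE", count=1)]


class TestUniqueDomains:
    gene_map = {"t1": "G1", "t2": "G1", "t3": "G1", "t4": "G1"}
    counts = {"G1": 4}

    def test_identical_domains_collapse_with_presence_fraction(self):
        doms = [make_domain("E" * 20, seq_id="t1"), make_domain("E" * 20, seq_id="t2")]
        uniques = unique_domains(doms, self.gene_map, self.counts)
        assert len(uniques) == 1
        assert uniques[0].presence_fraction == pytest.approx(0.5)
        assert uniques[0].carrier_transcripts == {"t1", "t2"}

    def test_substring_flags_included_and_including(self):
        a = make_domain("EEEEKKK" * 2, seq_id="t1")
        b = make_domain("EEEEKKK" * 3, seq_id="t2")
        uniques = unique_domains([a, b], self.gene_map, self.counts)
        by_seq = {u.sequence: u for u in uniques}
        assert by_seq["EEEEKKK" * 2].relation_flags == {RelationFlag.INCLUDED}
        assert by_seq["EEEEKKK" * 3].relation_flags == {RelationFlag.INCLUDING}

    @pytest.mark.parametrize("overlap,flagged", [(5, True), (4, False)])
    def test_minimum_terminal_overlap(self, overlap, flagged):
        # suffix of a == prefix of b, of exactly `overlap` residues
        a = make_domain("KKKKKKKKKK" + "ERKRD"[:overlap], seq_id="t1")
        b = make_domain("ERKRD"[:overlap] + "EEEEEEEEEE", seq_id="t2")
        uniques = unique_domains([a, b], self.gene_map, self.counts)
        for u in uniques:
            if flagged:
                assert u.relation_flags == {RelationFlag.OVERLAPPING}
            else:
                assert u.relation_flags == set()

    def test_flags_are_paired_within_genes(self):
        rng = random.Random(31)
        doms = []
        for g in range(5):
            base = random_protein(rng, 30)
            doms.append(make_domain(base, seq_id=f"g{g}t1"))
            doms.append(make_domain(base[5:25], seq_id=f"g{g}t2"))
        gene_map = {d.seq_id: d.seq_id[:2] for d in doms}
        counts = {g: 2 for g in gene_map.values()}
        uniques = unique_domains(doms, gene_map, counts)
        for gene in counts:
            members = [u for u in uniques if u.gene_id == gene]
            has_inc = any(RelationFlag.INCLUDED in u.relation_flags for u in members)
            has_ing = any(RelationFlag.INCLUDING in u.relation_flags for u in members)
            assert has_inc == has_ing

    def test_unmapped_transcript_is_named_in_error(self):
        with pytest.raises(InputError, match="orphan"):
            unique_domains([make_domain("E" * 20, seq_id="orphan")], {}, {})


class TestPresenceHistogram:
    def make_unique(self, fraction, total=20):
        from sahscan import UniqueDomain

        carriers = frozenset(f"t{i}" for i in range(round(fraction * total)))
        return UniqueDomain(
            gene_id="G",
            sequence="E" * 14,
            carrier_transcripts=carriers,
            gene_transcript_count=total,
        )

    def test_all_present_fills_top_bin(self):
        hist = presence_histogram([self.make_unique(1.0)] * 3)
        assert hist["count"].iloc[-1] == 3
        assert hist["count"].iloc[:-1].sum() == 0

    def test_halves_land_in_their_half_open_bin(self):
        hist = presence_histogram(
            [self.make_unique(0.5), self.make_unique(0.5), self.make_unique(1.0)]
        )
        row = hist[(hist.bin_lo.round(10) == 0.45)].iloc[0]
        assert row["count"] == 2
        assert hist["count"].iloc[-1] == 1

    def test_matches_direct_binning_oracle(self):
        rng = random.Random(8)
        uniques = [self.make_unique(rng.randint(1, 20) / 20) for _ in range(500)]
        hist = presence_histogram(uniques)
        import math

        oracle = [0] * 20
        for u in uniques:
            oracle[min(19, math.ceil(u.presence_fraction * 20 - 1e-9) - 1)] += 1
        assert list(hist["count"]) == oracle


class TestCrossGeneIdentity:
    def make_unique(self, gene, seq):
        from sahscan import UniqueDomain

        return UniqueDomain(
            gene_id=gene,
            sequence=seq,
            carrier_transcripts=frozenset({f"{gene}_t"}),
            gene_transcript_count=1,
        )

    def test_identical_sequence_across_two_genes(self):
        uniques = [self.make_unique("G1", "E" * 20), self.make_unique("G2", "E" * 20)]
        groups, inclusions = cross_gene_identity(uniques)
        assert len(groups) == 1 and groups[0]["genes"] == ["G1", "G2"]
        assert inclusions == []

    def test_cross_gene_inclusion_pair(self):
        short = self.make_unique("G1", "EEEEKKK" * 2)
        long = self.make_unique("G2", "EEEEKKK" * 3)
        groups, inclusions = cross_gene_identity([short, long])
        assert groups == []
        assert inclusions == [(short, long)]

    def test_disjoint_sequences_yield_nothing(self):
        uniques = [self.make_unique("G1", "EEEEKKKEEEEKKE"), self.make_unique("G2", "KRKRKRKRKRKRKR")]
        assert cross_gene_identity(uniques) == ([], [])


class TestLengthHistogram:
    def test_bin_arithmetic_and_max_length_cut(self):
        records = [
            make_record("A" * 120, seq_id="a"),
            make_record("A" * 3001, seq_id="b"),
            make_record("A" * 50, seq_id="c"),
        ]
        doms = [make_domain("E" * 14, seq_id="a")]
        hist = length_histogram(records, doms)
        row_120 = hist[(hist.bin_lo == 101)].iloc[0]
        assert row_120.n_proteins == 1 and row_120.n_sah_proteins == 1
        assert hist.n_proteins.sum() == 2  # the 3001-mer is omitted
        row_50 = hist[(hist.bin_lo == 1)].iloc[0]
        assert row_50.n_proteins == 1 and row_50.n_sah_proteins == 0

    def test_matches_direct_binning_oracle(self):
        rng = random.Random(12)
        records = [
            make_record("A" * rng.randint(20, 3200), seq_id=f"s{i}") for i in range(200)
        ]
        doms = [make_domain("E" * 14, seq_id=f"s{i}") for i in range(0, 200, 3)]
        hist = length_histogram(records, doms)
        oracle_all = [0] * 60
        oracle_sah = [0] * 60
        with_dom = {d.seq_id for d in doms}
        for r in records:
            if r.length > 3000:
                continue
            oracle_all[(r.length - 1) // 50] += 1
            if r.seq_id in with_dom:
                oracle_sah[(r.length - 1) // 50] += 1
        assert list(hist.n_proteins) == oracle_all
        assert list(hist.n_sah_proteins) == oracle_sah


class TestMultiDomainCounts:
    def test_three_domains_on_two_sequences(self):
        doms = [
            make_domain("E" * 14, seq_id="a"),
            make_domain("K" * 14, seq_id="a", start=40),
            make_domain("E" * 14, seq_id="b"),
        ]
        assert multi_domain_counts(doms) == (3, 2, 1)

    def test_empty(self):
        assert multi_domain_counts([]) == (0, 0, 0)
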