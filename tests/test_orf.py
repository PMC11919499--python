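"""Sequence handling: ORF parsing, rate tables, window variants and siRNA
site scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from slowcodon.orf import (
    ElongationRateTable,
    Orf,
    SENSE_CODONS,
    SlowWindowVariant,
    check_variant_seed_safety,
    default_rate_table,
    generate_slow_window_variants,
    load_orf,
    map_sirna_sites,
    scan_seed_matches,
    seed_quartile_counts,
    slowest_synonym,
)

revcomp = lambda s: s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestLoadOrf:
    def test_simple_parse(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nATGAAA\n")
        orf = load_orf(p)
        assert orf.codons == ("ATG", "AAA")
        assert not orf.stop_trimmed

    def test_egfp_fixture_has_239_codons_after_stop_trim(self, egfp):
        assert egfp.length == 239
        assert egfp.stop_trimmed
        assert egfp.protein.startswith("MVSK")

    def test_internal_stop_rejected_with_position(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nATGTAAAAA\n")
        with pytest.raises(ValueError, match="internal stop at codon 2"):
            load_orf(p)

    def test_length_not_divisible_by_three(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nATGAA\n")
        with pytest.raises(ValueError, match="divisible by 3"):
            load_orf(p)

    def test_rna_alphabet_normalized(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\naugaaa\n")
        assert load_orf(p).codons == ("ATG", "AAA")

    def test_missing_record(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nATGAAA\n")
        with pytest.raises(ValueError, match="not found"):
            load_orf(p, record_id="y")


class TestRateTable:
    def test_default_has_61_codons_mean_one(self, rate_table):
        assert len(rate_table.rates) == 61
        assert np.isclose(np.mean(list(rate_table.rates.values())), 1.0)

    def test_missing_codon_rejected(self, rate_table):
        rates = dict(rate_table.rates)
        rates.pop("AAA")
        with pytest.raises(ValueError, match="missing"):
            ElongationRateTable(rates=rates)

    def test_nonpositive_rate_rejected(self, rate_table):
        rates = dict(rate_table.rates)
        rates["AAA"] = 0.0
        with pytest.raises(ValueError, match="> 0"):
            ElongationRateTable(rates=rates)

    def test_tsv_round_trip(self, rate_table, tmp_path):
        p = tmp_path / "rates.tsv"
        rate_table.to_tsv(p)
        again = ElongationRateTable.from_tsv(p)
        assert again.rates == pytest.approx(rate_table.rates)


class TestSlowestSynonym:
    def test_single_codon_families_unchanged(self, rate_table):
        assert slowest_synonym("ATG", rate_table) == "ATG"
        assert slowest_synonym("TGG", rate_table) == "TGG"

    def test_minimal_rate_rule(self):
        rates = {c: 1.0 for c in SENSE_CODONS}
        rates["AAA"] = 0.5
        table = ElongationRateTable(rates=rates)
        assert slowest_synonym("AAG", table) == "AAA"

    def test_leucine_minimum_in_default_table(self, rate_table):
        # brute-force minimum over the six Leu codons
        leu = ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"]
        expected = min(leu, key=lambda c: (rate_table[c], c))
        assert slowest_synonym("CTG", rate_table) == expected

    def test_tie_breaks_lexicographically(self):
        rates = {c: 1.0 for c in SENSE_CODONS}
        table = ElongationRateTable(rates=rates)  # all tied
        assert slowest_synonym("AAG", table) == "AAA"

    def test_stop_codon_rejected(self, rate_table):
        with pytest.raises(ValueError):
            slowest_synonym("TAA", rate_table)


class TestWindowVariants:
    def test_egfp_yields_230_variants(self, egfp, rate_table):
        variants = generate_slow_window_variants(egfp, rate_table)
        assert len(variants) == 230
        assert [v.window_start for v in variants] == list(range(1, 231))

    def test_window_equal_to_length_single_variant(self, rate_table):
        orf = Orf("t", tuple(["ATG"] + ["AAA"] * 11))
        assert len(generate_slow_window_variants(orf, rate_table, 12)) == 1

    def test_12_codon_orf_window_10_gives_3(self, rate_table):
        orf = Orf("t", tuple(["ATG"] + ["AAA"] * 11))
        variants = generate_slow_window_variants(orf, rate_table, 10)
        assert [v.window_start for v in variants] == [1, 2, 3]

    def test_window_longer_than_orf_rejected(self, rate_table):
        orf = Orf("t", ("ATG", "AAA"))
        with pytest.raises(ValueError):
            generate_slow_window_variants(orf, rate_table, 3)

    def test_translation_invariance_and_locality(self, egfp, rate_table):
        """Every variant is synonymous and differs from the parent only
        inside its window."""
        for v in generate_slow_window_variants(egfp, rate_table):
            assert v.to_orf().protein == egfp.protein
            diff = [
                i + 1
                for i, (a, b) in enumerate(zip(v.codons, egfp.codons))
                if a != b
            ]
            assert len(diff) <= v.window_len
            assert all(v.window_start <= d <= v.window_end for d in diff)


class TestSirnaSites:
    def test_constructed_toy_match(self):
        orf = Orf("t", ("ATG", "AAA", "CCC", "GGG", "AAA"))
        # plant a site covering nt 4..13
        guide = revcomp(orf.nt[3:13])
        sites = map_sirna_sites(orf, guide)
        assert [s.start_nt for s in sites] == [4]

    def test_egfp_guides_hit_122_and_433(self, egfp, guides):
        starts = {
            gid: [s.start_nt for s in map_sirna_sites(egfp, g, gid)]
            for gid, g in guides.items()
        }
        assert starts == {"siRNA1": [122], "siRNA2": [433]}

    def test_short_guide_rejected(self, egfp):
        with pytest.raises(ValueError, match="too short"):
            map_sirna_sites(egfp, "ACGTACGT")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(data=st_.data())
    def test_planted_guide_round_trip(self, data):
        """Planting the reverse complement of a guide at position p always
        recovers p."""
        codons = data.draw(
            st_.lists(st_.sampled_from(SENSE_CODONS), min_size=12, max_size=40)
        )
        orf = Orf("rand", tuple(codons))
        n = 3 * orf.length
        glen = data.draw(st_.integers(19, 21))
        p = data.draw(st_.integers(1, n - glen + 1))
        guide = revcomp(orf.nt[p - 1 : p - 1 + glen])
        hits = [s.start_nt for s in map_sirna_sites(orf, guide)]
        assert p in hits

    def test_seed_hits_superset_of_full_sites(self, egfp, guides):
        for gid, g in guides.items():
            full = map_sirna_sites(egfp, g, gid)
            seeds = scan_seed_matches(egfp, g, gid)
            seed_starts = {s.start_nt for s in seeds}
            for site in full:
                assert site.start_nt + len(g) - 8 in seed_starts
            # sites coinciding with full matches carry the "full" flag
            assert {s.start_nt for s in seeds if s.kind == "full"} == {
                site.start_nt + len(g) - 8 for site in full
            }

    def test_seed_absent_from_toy_orf(self):
        orf = Orf("t", ("ATG",) + ("AAA",) * 10)
        guide = "G" * 19
        assert scan_seed_matches(orf, guide) == []

    def test_planted_double_seed(self):
        # seed complement CCCCGGG planted twice in an ORF of sense codons
        orf = Orf("t", ("ATG", "CCC", "CGG", "GAA", "AAA", "CCC", "CGG",
                        "GAA", "AAA"))
        guide = "A" + revcomp("CCCCGGG") + "ACGTACGTACG"  # seed = pos 2..8
        sites = scan_seed_matches(orf, guide)
        assert [s.start_nt for s in sites] == [4, 16]

    def test_quartile_counts_cover_all_hits(self, egfp, guides):
        counts = seed_quartile_counts(egfp, guides)
        total = sum(
            len(scan_seed_matches(egfp, g, gid)) for gid, g in guides.items()
        )
        assert sum(counts) == total


class TestSeedSafety:
    def test_identity_variant_reports_nothing(self, egfp, guides):
        v = SlowWindowVariant(parent=egfp.id, window_start=1, window_len=10,
                              codons=egfp.codons)
        report = check_variant_seed_safety(v, egfp, guides)
        assert report.gained == [] and report.lost == []
        assert report.no_full_site_gained

    def test_window_destroying_site_reported_lost(self, egfp, guides):
        # siRNA1 full site covers nt 122..140 -> codons 41..47; mutate there
        from slowcodon.orf import generate_slow_window_variants, default_rate_table

        variants = generate_slow_window_variants(egfp, default_rate_table())
        v41 = variants[40]  # window at codons 41..50
        report = check_variant_seed_safety(v41, egfp, guides)
        lost_full = [s for s in report.lost if s.match_len == 19]
        assert any(s.start_nt == 122 for s in lost_full)
        assert report.no_full_site_gained

    def test_created_full_site_flagged(self):
        # parent without the site; synonymous swap creates it
        parent = Orf("p", ("ATG", "TTA", "AAA", "CCC", "GGG", "TTT", "AAA"))
        guide = revcomp(parent.nt.replace("TTA", "CTA", 1)[3:13])
        mutated = list(parent.codons)
        mutated[1] = "CTA"  # synonymous Leu swap creating the site
        v = SlowWindowVariant(parent="p", window_start=2, window_len=1,
                              codons=tuple(mutated))
        report = check_variant_seed_safety(v, parent, {"g": guide})
        assert not report.no_full_site_gained
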