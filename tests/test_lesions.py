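"""Lesion scanner: indels, stop scan masking, splice sites, labels, tallies."""

import numpy as np
import pytest

from molechron.genetic_code import STANDARD_CODE, translate
from molechron.io import load_bundled_lesion_table
from molechron.lesions import (
    check_site_table,
    check_splice_sites,
    classify_gene_status,
    detect_boundary_deletions,
    detect_indels,
    detect_premature_stops,
    detect_terminal_codon_mutations,
    format_lesion_label,
    mask_for_stop_scan,
    scan_gene,
    tally_inactivated_genes,
    tally_lesions,
)
from molechron.models import (
    CodingAlignment,
    GeneModel,
    LesionRecord,
    LesionTable,
    SiteEntry,
    SiteTable,
)
from molechron.simulate import inject_lesions, simulate_gene_alignment


def tiny_alignment(ref, other, exon_lengths, gene="G"):
    gm = GeneModel(gene, exon_lengths)
    aln = CodingAlignment.from_rows(gene, {"ref": ref, "tx": other}, "ref", gm)
    return gm, aln


class TestIndels:
    def test_two_bp_deletion_is_frameshift(self):
        # deletion of columns 471-472 scaled down: columns 4-5 of 9
        _, aln = tiny_alignment("ATGAAATGA", "ATG--ATGA", [9])
        recs = detect_indels(aln, "tx")
        assert len(recs) == 1
        assert (recs[0].kind, recs[0].start, recs[0].end) == ("D", 4, 5)
        assert recs[0].frameshift

    def test_in_frame_deletion_not_a_lesion(self):
        _, aln = tiny_alignment("ATGAAACCCTGA", "ATG---CCCTGA", [12])
        assert detect_indels(aln, "tx") == []

    def test_insertion_run_detected(self):
        gm = GeneModel("G", [9])
        aln = CodingAlignment.from_rows(
            "G", {"ref": "ATG--AAATGA", "tx": "ATGCCAAATGA"}, "ref", gm
        )
        recs = detect_indels(aln, "tx")
        assert [(r.kind, r.start, r.end) for r in recs] == [("I", 4, 5)]

    def test_all_gap_row_gives_whole_gene_deletion_and_warning(self):
        gm = GeneModel("G", [9])
        aln = CodingAlignment.from_rows(
            "G", {"ref": "ATGAAATGA", "tx": "---------"}, "ref", gm
        )
        with pytest.warns(UserWarning):
            recs = detect_indels(aln, "tx")
        assert len(recs) == 1
        assert (recs[0].start, recs[0].end) == (1, 9)


class TestStopScanMask:
    def test_lesion_free_taxon_unchanged(self, clean_alignment):
        masked = mask_for_stop_scan(clean_alignment, "tx2")
        assert masked == clean_alignment.rows["tx2"]

    def test_mask_rule_deletes_insertions_and_fills_deletions(self):
        gm = GeneModel("G", [9])
        aln = CodingAlignment.from_rows(
            "G", {"ref": "ATG--AAATGA", "tx": "ATGCCAAA-GA"}, "ref", gm
        )
        assert mask_for_stop_scan(aln, "tx") == "ATGAAANGA"

    def test_mask_length_and_translatability_after_random_injection(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            gm = GeneModel("G", [120, 150, 90, 141])
            aln = simulate_gene_alignment(gm, ["ref", "tx"], seed=200 + trial)
            aln2, gm2, _, _ = inject_lesions(
                aln, gm, "tx", [("D", 2), ("I", 2), ("S", 1)],
                seed=int(rng.integers(1 << 30)),
            )
            masked = mask_for_stop_scan(aln2, "tx")
            assert len(masked) == gm2.cds_length
            assert len(translate(masked)) == gm2.cds_length // 3


class TestStopAndTerminalCodons:
    def test_premature_stop_called(self):
        _, aln = tiny_alignment("ATGTAAAAATGA", "ATGTAAAAATGA", [12])
        recs = detect_premature_stops("ATGTAAAAATGA", aln, "tx")
        assert [(r.kind, r.start, r.end) for r in recs] == [("S", 4, 6)]

    def test_n_containing_codon_never_called(self):
        _, aln = tiny_alignment("ATGNAAAAATGA", "ATGNAAAAATGA", [12])
        assert detect_premature_stops("ATGNAAAAATGA", aln, "tx") == []

    def test_stop_near_end_flagged_possibly_tolerated(self):
        seq = "ATG" + "AAA" * 5 + "TAA" + "TGA"
        _, aln = tiny_alignment(seq, seq, [len(seq)])
        recs = detect_premature_stops(seq, aln, "tx")
        assert len(recs) == 1 and recs[0].possibly_tolerated

    @pytest.mark.parametrize(
        "seq,kinds",
        [
            ("GTGAAATGA", ["SCM"]),
            ("ATGAAAAAA", ["TCM"]),
            ("ATGAAATAG", []),
            ("NTGAAAAAN", []),
        ],
    )
    def test_terminal_codon_mutations(self, seq, kinds):
        _, aln = tiny_alignment(seq, seq, [9])
        recs = detect_terminal_codon_mutations(seq, aln, "tx")
        assert [r.kind for r in recs] == kinds


class TestSpliceSites:
    @pytest.mark.parametrize(
        "donor,acceptor,expected",
        [
            ("AT", "AG", [("Do", "AT")]),
            ("GC", "AG", []),
            ("GT", "GG", [("Ac", "GG")]),
            ("NN", "A-", []),
        ],
    )
    def test_canonical_rules(self, donor, acceptor, expected):
        gm = GeneModel("G", [9, 9])
        from molechron.models import IntronSites

        gm.intron_sites = {"tx": [IntronSites(1, donor, acceptor)]}
        recs = check_splice_sites(gm, "tx")
        assert [(r.kind, r.detail) for r in recs] == expected


class TestBoundaryDeletions:
    def test_acceptor_side_bd(self):
        # exon 2 leading deletion plus flagged intronic extent
        ref = "ATGAAACCC" + "GGGTTTAAATGA"
        tx = "ATGAAACCC" + "----TTAAATGA"
        gm, aln = tiny_alignment(ref, tx, [9, 12])
        recs = detect_boundary_deletions(aln, gm, "tx", {(1, "acceptor"): 12})
        assert len(recs) == 1
        assert recs[0].feature_label == "In1E2"

    def test_zero_intronic_extent_stays_plain_deletion(self):
        ref = "ATGAAACCC" + "GGGTTTAAATGA"
        tx = "ATGAAACCC" + "----TTAAATGA"
        gm, aln = tiny_alignment(ref, tx, [9, 12])
        assert detect_boundary_deletions(aln, gm, "tx", {}) == []
        recs = scan_gene(aln, gm, "tx")
        assert any(r.kind == "D" for r in recs)


class TestSiteTable:
    def test_deleted_tuning_site_gives_stsd(self):
        ref = "ATG" + "TGGGCTACT" + "TGA"
        tx = "ATG" + "---------" + "TGA"
        gm, aln = tiny_alignment(ref, tx, [15])
        sites = SiteTable([SiteEntry(2, "spectral_tuning", frozenset("W"))])
        masked = mask_for_stop_scan(aln, "tx")
        recs = check_site_table(masked, sites, aln, "tx")
        assert [r.kind for r in recs] == ["STSD"]

    def test_all_sites_matching_is_empty(self):
        seq = "ATG" + "TGGGCTACT" + "TGA"
        gm, aln = tiny_alignment(seq, seq, [15])
        sites = SiteTable(
            [
                SiteEntry(2, "spectral_tuning", frozenset("W")),
                SiteEntry(3, "chromophore_binding", frozenset("A")),
                SiteEntry(4, "schiff_base_counterion", frozenset("T")),
            ]
        )
        assert check_site_table(seq, sites, aln, "tx") == []

    def test_mismatches_against_brute_force_residue_check(self):
        rng = np.random.default_rng(17)
        gm = GeneModel("G", [120, 150, 90, 141])
        aln = simulate_gene_alignment(gm, ["ref", "tx"], seed=31,
                                      substitution_prob=0.2)
        masked = mask_for_stop_scan(aln, "tx")
        protein = translate(masked)
        entries = []
        for pos in rng.choice(len(protein) - 2, size=20, replace=False):
            allowed = frozenset(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=3)
            )
            role = ["chromophore_binding", "schiff_base_counterion"][pos % 2]
            entries.append(SiteEntry(int(pos) + 1, role, allowed))
        recs = check_site_table(masked, SiteTable(entries), aln, "tx")
        expected = {
            e.protein_position
            for e in entries
            if protein[e.protein_position - 1] not in e.allowed_residues
            and protein[e.protein_position - 1] != "X"
        }
        got = {(r.start - 1) // 3 + 1 for r in recs}
        assert got == expected


class TestLabels:
    @pytest.mark.parametrize(
        "rec,label",
        [
            (LesionRecord("t", "g", "D", 1478, 1575, feature_label="E13"),
             "1478–1575D (E13)"),
            (LesionRecord("t", "g", "S", 412, 414, feature_label="E5"),
             "412–414S (E5)"),
            (LesionRecord("t", "g", "Do", intron_index=6, feature_label="In6",
                          detail="AT"), "In6Do (AT)"),
            (LesionRecord("t", "g", "D", 1000, 1000, feature_label="E9"),
             "1000D (E9)"),
            (LesionRecord("t", "g", "INV", feature_label="E2"), "E2INV"),
        ],
    )
    def test_table_notation(self, rec, label):
        assert format_lesion_label(rec) == label

    def test_injective_over_distinct_locations(self):
        recs = [
            LesionRecord("t", "g", k, s, e, feature_label=f"E{x}")
            for k in ("D", "I", "S")
            for s, e, x in ((1, 2, 1), (1, 3, 1), (4, 6, 2))
        ]
        labels = {format_lesion_label(r) for r in recs}
        assert len(labels) == len(recs)


class TestTallies:
    def test_gene_status_classification(self):
        table = load_bundled_lesion_table()
        chryso = ("Chrysochloris_asiatica", "Amblysomus_hottentotus")
        assert classify_gene_status(table, "LIM2", chryso) == "lesioned_one"
        assert classify_gene_status(table, "CRYAB", chryso) == "intact_both"
        assert classify_gene_status(table, "KRT12", chryso) == "lesioned_both"

    def test_empty_table_tallies_zero(self):
        table = LesionTable([], {"G": "lens_cornea"}, set())
        assert tally_lesions(table, "x")[0] == 0
        assert tally_inactivated_genes(table, "x", "lens_cornea") == 0

    def test_shared_records_count_once_per_member(self):
        recs = [
            LesionRecord("a", "G", "S", 4, 6, feature_label="E1",
                         sharing="shared"),
            LesionRecord("b", "G", "S", 4, 6, feature_label="E1",
                         sharing="shared"),
        ]
        table = LesionTable(recs, {"G": "lens_cornea"}, set())
        assert tally_lesions(table, "a")[0] == 1
        assert tally_lesions(table, "b")[0] == 1

    def test_adding_a_record_never_decreases_tallies(self):
        table = load_bundled_lesion_table()
        base, _ = tally_lesions(table, "Chrysochloris_asiatica")
        bigger = LesionTable(
            table.records
            + [LesionRecord("Chrysochloris_asiatica", "MIP", "S", 900, 902,
                            feature_label="E4")],
            table.group_map, table.pleiotropic_set,
        )
        after, _ = tally_lesions(bigger, "Chrysochloris_asiatica")
        assert after == base + 1

    def test_pleiotropic_genes_excluded(self):
        recs = [LesionRecord("a", "RHO", "S", 4, 6, feature_label="E1")]
        table = LesionTable(recs, {"RHO": "rod_activation"}, {"RHO"})
        assert tally_lesions(table, "a")[0] == 0
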