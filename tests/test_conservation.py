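import math

import numpy as np
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

from splicedas.annotation import GenomeAnnotation, GeneModel, Transcript
from splicedas.conservation import (
    ConservedEventCall,
    HomologyMap,
    VennCounts,
    alignment_identity,
    call_psi_consistency,
    extract_isoform_sequences,
    match_isoforms,
    overlap_enrichment,
    shared_gene_sets,
    summarize_conserved,
)
from splicedas.events import enumerate_events
from splicedas.table1 import table1_fixture

from conftest import make_annotation, make_gene


def fisher_greater_oracle(a, b, c, d):
    """One-sided Fisher p by direct hypergeometric summation."""
    M, n, N = a + b + c + d, a + b, a + c
    return float(hypergeom.sf(a - 1, M, n, N))


class TestOverlapEnrichment:
    def test_no_overlap_small_margins_is_null(self):
        _, p = overlap_enrichment(VennCounts(0, 2, 2, 100))
        assert p > 0.9

    def test_diagonal_table_enumeration(self):
        """Table [[5,0],[0,5]]: only one of C(10,5) arrangements is as
        extreme, so p = 1/C(10,5)."""
        _, p = overlap_enrichment(VennCounts(5, 0, 0, 10))
        assert p == pytest.approx(1 / comb(10, 5, exact=True), rel=1e-9)

    def test_matches_hypergeometric_oracle_on_random_tables(self, rng):
        for _ in range(50):
            bg = int(rng.integers(20, 200))
            a = int(rng.integers(0, bg // 4))
            b = int(rng.integers(0, bg // 4))
            c = int(rng.integers(0, bg // 4))
            venn = VennCounts(a, b, c, bg)
            _, p = overlap_enrichment(venn)
            oracle = fisher_greater_oracle(a, b, c, bg - a - b - c)
            assert p == pytest.approx(oracle, rel=1e-6)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(VennCounts(50, 40, 40, 100))


class TestSharedGeneSets:
    @pytest.fixture
    def homology(self):
        return HomologyMap.from_pairs([(f"a{i}", f"b{i}") for i in range(20)])

    def test_disjoint_lists_share_nothing(self, homology):
        expressed_a = {f"a{i}" for i in range(20)}
        expressed_b = {f"b{i}" for i in range(20)}
        venn = shared_gene_sets(
            {"a0", "a1"}, {"b5", "b6"}, homology, expressed_a, expressed_b
        )
        assert (venn.both, venn.a_only, venn.b_only) == (0, 2, 2)
        assert venn.background_total == 20

    def test_identical_lists_fully_shared(self, homology):
        das_a = {f"a{i}" for i in range(5)}
        das_b = {f"b{i}" for i in range(5)}
        venn = shared_gene_sets(
            das_a, das_b, homology,
            {f"a{i}" for i in range(20)}, {f"b{i}" for i in range(20)},
        )
        assert (venn.both, venn.a_only, venn.b_only) == (5, 0, 0)

    def test_planted_overlap_recovered_exactly(self, homology, rng):
        k = 3
        das_a = {f"a{i}" for i in range(8)}
        das_b = {f"b{i}" for i in range(k)} | {f"b{i}" for i in range(10, 15)}
        venn = shared_gene_sets(
            das_a, das_b, homology,
            {f"a{i}" for i in range(20)}, {f"b{i}" for i in range(20)},
        )
        assert venn.both == k

    def test_das_gene_missing_from_expressed_warns_and_is_added(self, homology):
        with pytest.warns(UserWarning):
            venn = shared_gene_sets(
                {"a0"}, set(), homology, set(), {f"b{i}" for i in range(20)}
            )
        assert venn.background_total >= 1


class TestExtractIsoformSequences:
    def _toy(self, strand, cds=None):
        u, v, d = (0, 3), (10, 13), (20, 23)
        ann = make_annotation(
            make_gene(
                "g", "c", strand, [[u, v, d], [u, d]],
                cds=None if cds is None else [cds, cds],
            )
        )
        (event,) = enumerate_events(ann)
        return ann, event

    def test_plus_strand_concatenation(self):
        ann, event = self._toy("+")
        genome = {"c": "ATG" + "N" * 7 + "AAA" + "N" * 7 + "TGA"}
        inc, exc, alphabet = extract_isoform_sequences(event, genome, ann)
        assert (inc, exc, alphabet) == ("ATGAAATGA", "ATGTGA", "nucleotide")

    def test_minus_strand_is_reverse_complement(self):
        ann, event = self._toy("-")
        genome = {"c": "ATG" + "N" * 7 + "AAA" + "N" * 7 + "TGA"}
        inc, exc, _ = extract_isoform_sequences(event, genome, ann)
        assert inc == "TCATTTCAT"  # revcomp of ATGAAATGA
        assert exc == "TCACAT"

    def test_coding_event_translates_with_extra_residue(self):
        """CDS covering the whole event with a 3-base variable exon: the
        inclusion protein carries exactly one extra residue."""
        ann, event = self._toy("+", cds=(0, 23))
        genome = {"c": "ATG" + "N" * 7 + "AAA" + "N" * 7 + "TGA"}
        inc, exc, alphabet = extract_isoform_sequences(event, genome, ann)
        assert alphabet == "protein"
        assert len(inc) == len(exc) + 1
        assert inc == "MK" and exc == "M"

    def test_internal_stop_falls_back_to_nucleotide(self):
        ann, event = self._toy("+", cds=(0, 23))
        genome = {"c": "ATG" + "N" * 7 + "TAA" + "N" * 7 + "TGA"}
        with pytest.warns(UserWarning):
            inc, exc, alphabet = extract_isoform_sequences(event, genome, ann)
        assert alphabet == "nucleotide"

    def test_event_outside_contig_rejected(self):
        ann, event = self._toy("+")
        with pytest.raises(ValueError):
            extract_isoform_sequences(event, {"c": "ATG"}, ann)


class TestMatchIsoforms:
    def test_identical_pairs_label_both_with_unit_identity(self):
        a = ("ACGTACGTACGTAAAACGT", "ACGTACGTCGT")
        res = match_isoforms(a, a)
        assert res.label == "both"
        assert res.identities["inc_inc"] == 1.0
        assert res.identities["exc_exc"] == 1.0

    def test_swapped_pair_labels_cross_matched(self):
        inc = "ACGTACGTACGTAAAACGTTTTGGGCCC"
        exc = "ACGTACGTCGTAACCGGTT"
        res = match_isoforms((inc, exc), (exc, inc))
        assert res.label == "cross_matched"

    def test_species_order_symmetry(self, rng):
        for _ in range(5):
            a = tuple(
                "".join(rng.choice(list("ACGT"), 60)) for _ in range(2)
            )
            b = tuple(
                "".join(rng.choice(list("ACGT"), 60)) for _ in range(2)
            )
            assert match_isoforms(a, b).label == match_isoforms(b, a).label

    def test_divergence_simulation_keeps_straight_pairing(self, rng):
        """Planted straight pairing at 10% substitution: label 'both' in at
        least 24 of 25 seeded replicates."""
        hits = 0
        for _ in range(25):
            u = "".join(rng.choice(list("ACGT"), 120))
            v = "".join(rng.choice(list("ACGT"), 80))
            d = "".join(rng.choice(list("ACGT"), 120))

            def mutate(s):
                out = list(s)
                for i in range(len(out)):
                    if rng.random() < 0.1:
                        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
                return "".join(out)

            a = (u + v + d, u + d)
            b = (mutate(u + v + d), mutate(u + d))
            hits += match_isoforms(a, b, 0.5).label == "both"
        assert hits >= 24

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            match_isoforms(("", "ACGT"), ("ACGT", "ACGT"))

    def test_alignment_identity_excludes_terminal_gaps(self):
        # 'CGT' aligns inside 'ACGTA': 3 matches over 3 aligned columns
        assert alignment_identity("CGT", "ACGTA") == 1.0


class TestPsiConsistency:
    @pytest.mark.parametrize(
        "dpsi_a,dpsi_b,label,expected",
        [
            (0.186, 0.198, "both", "Y"),  # EXOC1-like: same sign, conserved
            (-0.060, 0.091, "both", "N"),  # AXL-like: opposite signs
            (-0.180, -0.078, "cross_matched", "N"),  # DMKN-like: crossed
            (0.0, 0.1, "both", "N"),  # zero is sign-indeterminate
        ],
    )
    def test_rule(self, dpsi_a, dpsi_b, label, expected):
        assert call_psi_consistency(dpsi_a, dpsi_b, label) == expected

    def test_reference_table_reproduced(self):
        calls = table1_fixture()
        assert len(calls) == 24
        assert sum(c.psi_consistent == "Y" for c in calls) == 18

    def test_summary_counts_large_events_strictly(self):
        calls = table1_fixture()
        n_consistent, n_large = summarize_conserved(calls, large_dpsi=0.10)
        assert (n_consistent, n_large) == (18, 8)
        # the |dPSI| = 0.100 row must not pass the strict threshold
        spag9 = next(c for c in calls if c.gene_a == "SPAG9")
        assert abs(spag9.dpsi_a) == pytest.approx(0.100)
        assert spag9.psi_consistent == "Y"

    def test_empty_input(self):
        assert summarize_conserved([]) == (0, 0)


class TestHomologyMap:
    def test_homologene_format_round_trip(self, tmp_path):
        path = tmp_path / "homologene.tsv"
        path.write_text(
            "3\t10090\t101\tTnip1\n3\t9606\t102\tTNIP1\n"
            "7\t10090\t201\tExoc1\n7\t9606\t202\tEXOC1\n"
        )
        hm = HomologyMap.read_homologene(path, taxid_a="10090", taxid_b="9606")
        assert hm.b_for_a("Tnip1") == "TNIP1"
        assert hm.a_for_b("EXOC1") == "Exoc1"

    def test_gene_in_two_groups_rejected(self):
        with pytest.raises(ValueError):
            HomologyMap.from_pairs([("a", "b"), ("a", "c")])
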