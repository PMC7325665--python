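"""UTR extraction, both scanners (vs independent oracles) and conservation."""

import itertools
import math
import re

import numpy as np
import pytest

from pufsf.io_formats import GeneFeature, MotifHit
from pufsf.rna_targets import (
    PWM,
    UTRRecord,
    conservation_profile,
    count_target_genes,
    estimate_background,
    exact_pvalues,
    extract_utrs,
    reverse_complement,
    scan_iupac,
    scan_pwm,
)


def make_contig(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestExtractUtrs:
    def test_plus_strand_window(self):
        contig = make_contig(400)
        gene = GeneFeature("g", "c", 50, 100, "+", 100)
        (utr,) = extract_utrs({"c": contig}, [gene])
        # 1-based positions 101..150 == 0-based slice [100:150]
        assert utr.sequence == contig[100:150]
        assert len(utr) == 50 and not utr.truncated

    def test_minus_strand_window(self):
        contig = make_contig(400)
        gene = GeneFeature("g", "c", 301, 350, "-", 301)
        (utr,) = extract_utrs({"c": contig}, [gene])
        # revcomp of 1-based 251..300 == 0-based slice [250:300]
        assert utr.sequence == reverse_complement(contig[250:300])

    def test_truncation_at_contig_end(self):
        contig = make_contig(400)
        gene = GeneFeature("g", "c", 300, 395, "+", 395)
        (utr,) = extract_utrs({"c": contig}, [gene])
        assert len(utr) == 5 and utr.truncated

    def test_terminal_cds_gives_empty_utr_not_error(self):
        contig = make_contig(400)
        gene = GeneFeature("g", "c", 300, 400, "+", 400)
        (utr,) = extract_utrs({"c": contig}, [gene])
        assert utr.sequence == "" and utr.truncated

    def test_missing_contig_error(self):
        gene = GeneFeature("g", "nope", 1, 9, "+", 9)
        with pytest.raises(KeyError):
            extract_utrs({"c": "ACGT"}, [gene])

    def test_strand_symmetry(self):
        # reverse-complementing the contig and flipping strands leaves every
        # UTR sequence unchanged
        contig = make_contig(500, seed=3)
        genes = [
            GeneFeature("g1", "c", 100, 220, "+", 220),
            GeneFeature("g2", "c", 300, 410, "-", 300),
        ]
        utrs = extract_utrs({"c": contig}, genes)
        n = len(contig)
        flipped = [
            GeneFeature(
                g.gene_id, "c", n - g.end + 1, n - g.start + 1,
                "-" if g.strand == "+" else "+",
                n - g.cds_end_most_3prime + 1,
            )
            for g in genes
        ]
        utrs2 = extract_utrs({"c": reverse_complement(contig)}, flipped)
        assert [u.sequence for u in utrs] == [u.sequence for u in utrs2]


def regex_oracle(motif, utrs, motif_id="motif"):
    """Brute-force IUPAC scan via regular expressions."""
    pattern = re.compile(
        "".join("[ACGT]" if b == "N" else b for b in motif.upper().replace("U", "T"))
    )
    hits = []
    for u in utrs:
        for s in range(len(u.sequence)):
            m = pattern.match(u.sequence, s)
            if m and m.end() <= len(u.sequence):
                hits.append((motif_id, u.gene_id, s))
    return set(hits)


class TestScanIupac:
    def test_direct_match(self):
        utr = UTRRecord("g1", "CCCCCTGTATTTAGGGCCCC")
        (hit,) = scan_iupac("UGUAUUUA", [utr])
        assert (hit.gene_id, hit.offset, hit.matched_sequence) == ("g1", 5, "TGTATTTA")

    def test_wildcard_hits_every_offset(self):
        utr = UTRRecord("g1", "ACGTACGT")
        hits = scan_iupac("NN", [utr])
        assert [h.offset for h in hits] == list(range(7))

    def test_no_match(self):
        assert scan_iupac("AAAA", [UTRRecord("g", "CGCGCG")]) == []

    def test_motif_longer_than_utrs(self):
        assert scan_iupac("ACGUACGU", [UTRRecord("g", "ACG")]) == []

    def test_utr_n_matches_only_motif_n(self):
        utr = UTRRecord("g", "ANG")
        assert scan_iupac("ANG", [utr])[0].offset == 0
        assert scan_iupac("AAG", [utr]) == []

    def test_matches_regex_oracle_on_random_utrs(self):
        rng = np.random.default_rng(42)
        utrs = [
            UTRRecord(f"g{i}", "".join(rng.choice(list("ACGT"), size=50)))
            for i in range(200)
        ]
        for motif in ["UGUAUUUA", "NNGU", "ANNNU", "GG"]:
            got = {(h.motif_id, h.gene_id, h.offset) for h in scan_iupac(motif, utrs)}
            assert got == regex_oracle(motif, utrs)


def enumerate_pvalues(pwm, scale=1000):
    """Exhaustive 4^w oracle for the integer-score survival function."""
    ints = pwm.int_scores(scale)
    scores = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(ints[i, b] for i, b in enumerate(word)))
        p = math.prod(pwm.background[b] for b in word)
        scores[s] = scores.get(s, 0.0) + p
    return scores


class TestScanPwm:
    def test_width_one_best_pvalue_is_quarter(self):
        rows = np.array([[0.97, 0.01, 0.01, 0.01]])
        pwm = PWM(rows=rows, background=np.full(4, 0.25))
        sf, lo = exact_pvalues(pwm)
        ints = pwm.int_scores()
        best = int(ints.max())
        assert sf[best - lo] == pytest.approx(0.25)

    @pytest.mark.parametrize("width", [2, 4])
    def test_dp_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        rows = rng.dirichlet(np.ones(4), size=width)
        bg = rng.dirichlet(np.ones(4) * 5)
        pwm = PWM(rows=rows, background=bg)
        sf, lo = exact_pvalues(pwm)
        oracle = enumerate_pvalues(pwm)
        for s in oracle:
            expected = sum(p for t, p in oracle.items() if t >= s)
            assert sf[s - lo] == pytest.approx(expected, abs=1e-9)

    def test_planted_consensus_found_at_threshold(self):
        rng = np.random.default_rng(8)
        utrs = [
            UTRRecord(f"g{i}", "".join(rng.choice(list("ACGT"), size=50)))
            for i in range(60)
        ]
        planted = "TGTATTTA"
        seq = utrs[7].sequence
        utrs[7] = UTRRecord("g7", seq[:20] + planted + seq[28:])
        # guard: no other UTR contains a full match
        assert sum(planted in u.sequence for u in utrs) == 1
        from pufsf.motif_prediction import motif_to_pwm

        pwm = PWM(rows=motif_to_pwm("UGUAUUUA"), background=np.full(4, 0.25))
        hits = scan_pwm(pwm, utrs, p_threshold=1e-4)
        assert {h.gene_id for h in hits} == {"g7"}
        assert hits[0].offset == 20
        assert 0 < hits[0].p_value <= 1e-4

    def test_windows_with_n_skipped(self):
        pwm = PWM(rows=np.array([[0.97, 0.01, 0.01, 0.01]] * 2),
                  background=np.full(4, 0.25))
        hits = scan_pwm(pwm, [UTRRecord("g", "AANAA")], p_threshold=1.0,
                        background=np.full(4, 0.25))
        assert [h.offset for h in hits] == [0, 3]

    def test_background_estimated_from_utrs(self):
        utrs = [UTRRecord("g", "AAAC")]
        bg = estimate_background(utrs)
        assert bg == pytest.approx([0.75, 0.25, 0.0, 0.0])
        assert estimate_background([UTRRecord("g", "NN")]) == pytest.approx(
            np.full(4, 0.25)
        )


class TestCountTargetGenes:
    def test_distinct_genes_counted_once(self):
        hits = [
            MotifHit("m1", "g1", 3, "AC"),
            MotifHit("m1", "g1", 20, "AC"),
            MotifHit("m1", "g2", 0, "AC"),
        ]
        assert count_target_genes(hits) == {"m1": 2}

    def test_empty(self):
        assert count_target_genes([]) == {}

    def test_gene_shared_by_two_motifs_counts_for_both(self):
        hits = [MotifHit("m1", "g1", 0, "A"), MotifHit("m2", "g1", 0, "A")]
        assert count_target_genes(hits) == {"m1": 1, "m2": 1}


class TestConservationProfile:
    def test_column_fractions_and_bins(self):
        aln = ["AAGA", "AAC-", "ACG-", "AAT-"]
        prof = conservation_profile(aln)
        assert prof.fractions == pytest.approx([1.0, 0.75, 0.5, 0.25])
        assert prof.bins == [">80%", ">60%", ">40%", "<40%"]

    def test_gaps_count_in_denominator(self):
        prof = conservation_profile(["A", "-", "-", "-"])
        assert prof.fractions[0] == pytest.approx(0.25)
        assert prof.bins == ["<40%"]

    def test_ambiguous_symbols_excluded_from_modal_count(self):
        prof = conservation_profile(["N", "N", "N", "A"])
        assert prof.fractions[0] == pytest.approx(0.25)

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            conservation_profile(["AC", "A"])

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            conservation_profile(["ACGT"])
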