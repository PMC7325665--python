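"""Signature/architecture typing rules and the survey statistics."""

import math

import pandas as pd
import pytest

from pufsf.classification import (
    Label,
    aggregate_by_taxon,
    classify,
    classify_by_architecture,
    classify_by_signature,
    dedupe_isoforms,
    length_filter,
    survey,
)
from pufsf.io_formats import DomainAnnotation, ProteinRecord
from pufsf.repeat_detection import PufRepeat
from pufsf.synthetic_data import SimConfig, simulate_proteome


def ann(sig, pid="p"):
    return DomainAnnotation(protein_id=pid, signature_id=sig, start=1, end=36)


def reps(n):
    return [PufRepeat("p", 36 * k, 36 * (k + 1), 50.0, index=k + 1) for k in range(n)]


class TestSignatureRules:
    @pytest.mark.parametrize(
        "sigs,label",
        [
            (["IPR040000"], Label.NOP9),
            (["PTHR13102"], Label.NOP9),
            (["IPR040059"], Label.PUM3),
            (["PTHR13389"], Label.PUM3),
            (["IPR001313"] * 8, Label.PUF),
            (["SM00025"], Label.PUF),
            ([], Label.UNCLASSIFIED),
        ],
    )
    def test_signature_mapping(self, sigs, label):
        assert classify_by_signature([ann(s) for s in sigs]).label is label

    def test_precedence_nop9_over_pum3_over_puf(self):
        # family proteins also carry generic repeat signatures in real data
        got = classify_by_signature([ann("IPR001313"), ann("IPR040000")])
        assert got.label is Label.NOP9
        got = classify_by_signature([ann("IPR001313"), ann("IPR040059")])
        assert got.label is Label.PUM3

    def test_evidence_recorded(self):
        got = classify_by_signature([ann("IPR040000")])
        assert "IPR040000" in got.evidence["signature"]


class TestArchitectureRules:
    @pytest.mark.parametrize(
        "n,label",
        [
            (8, Label.PUF),
            (6, Label.PUF),
            (9, Label.PUF),
            (11, Label.ELEVEN_REPEAT_UNRESOLVED),
            (10, Label.ELEVEN_REPEAT_UNRESOLVED),
            (2, Label.UNCLASSIFIED),
            (0, Label.UNCLASSIFIED),
        ],
    )
    def test_repeat_count_mapping(self, n, label):
        assert classify_by_architecture(reps(n)).label is label

    def test_signature_overrides_architecture(self):
        got = classify([ann("IPR040000")], reps(8))
        assert got.label is Label.NOP9

    def test_architecture_fallback_when_no_signature(self):
        assert classify([], reps(8)).label is Label.PUF


class TestDedupeAndFilter:
    def test_longest_isoform_kept(self):
        recs = [
            ProteinRecord("p1", "A" * 300),
            ProteinRecord("p2", "A" * 500),
        ]
        kept = dedupe_isoforms(recs, {"p1": "g1", "p2": "g1"})
        assert [r.id for r in kept] == ["p2"]

    def test_length_tie_smallest_id(self):
        recs = [
            ProteinRecord("p2", "A" * 300),
            ProteinRecord("p1", "A" * 300),
        ]
        kept = dedupe_isoforms(recs, {"p1": "g1", "p2": "g1"})
        assert [r.id for r in kept] == ["p1"]

    def test_identity_mapping_is_noop(self):
        recs = [ProteinRecord("a", "MK"), ProteinRecord("b", "MKT")]
        assert dedupe_isoforms(recs) == recs

    def test_length_filter_boundary(self):
        recs = [ProteinRecord("short", "A" * 499), ProteinRecord("ok", "A" * 500)]
        assert [r.id for r in length_filter(recs)] == ["ok"]
        assert length_filter(recs, min_len=0) == recs


def make_meta(rows):
    return pd.DataFrame(
        rows, columns=["species", "taxon_path", "n_protein_coding_genes"]
    )


def puf_calls(n):
    return [classify_by_signature([ann("IPR001313")]) for _ in range(n)]


class TestSurvey:
    def test_ratio_arithmetic(self):
        meta = make_meta([("sp1", "Opisthokonta/Metazoa", 17350)])
        rows, summary = survey({"sp1": puf_calls(5)}, meta)
        assert rows[0].puf_per_gene == pytest.approx(5 / 17350)
        assert rows[0].puf_per_gene == pytest.approx(2.882e-4, rel=1e-3)
        assert summary.genes_per_puf_mean == pytest.approx(3470)
        assert summary.genes_per_puf_pooled == pytest.approx(3470)

    def test_zero_pufs(self):
        meta = make_meta([("sp1", "A/B", 1000)])
        rows, _ = survey({"sp1": []}, meta)
        assert rows[0].puf_per_gene == 0

    def test_species_duplication_leaves_mean_of_ratios_unchanged(self):
        meta = make_meta([("sp1", "A/B", 10000), ("sp2", "A/C", 20000),
                          ("sp1b", "A/B", 10000), ("sp2b", "A/C", 20000)])
        single = {"sp1": puf_calls(3), "sp2": puf_calls(8)}
        doubled = dict(single, sp1b=puf_calls(3), sp2b=puf_calls(8))
        _, s1 = survey(single, meta)
        _, s2 = survey(doubled, meta)
        assert s1.mean_of_ratios == pytest.approx(s2.mean_of_ratios)

    def test_missing_species_error_lists_them(self):
        meta = make_meta([("sp1", "A/B", 1000)])
        with pytest.raises(KeyError, match="sp2"):
            survey({"sp1": [], "sp2": []}, meta)

    def test_count_conservation(self):
        # classes partition: per-species class counts sum to the number of calls
        sim = simulate_proteome(SimConfig(seed=5, n_species=3))
        calls = {}
        for rec in sim.records:
            calls.setdefault(rec.species, []).append(
                classify(sim.domain_table.get(rec.id, []))
            )
        rows, _ = survey(calls, sim.metadata)
        for r in rows:
            n_calls = len(calls[r.species])
            n_uncls = sum(1 for c in calls[r.species] if not c.classified)
            assert r.n_nop9 + r.n_puf + r.n_pum3 + r.n_unresolved_11 + n_uncls == n_calls


class TestAggregateByTaxon:
    def test_single_species_group_has_zero_sd(self):
        meta = make_meta([("sp1", "A/B", 1000)])
        rows, _ = survey({"sp1": puf_calls(4)}, meta)
        (summary,) = aggregate_by_taxon(rows, level=0)
        assert summary.mean_puf == 4 and summary.sd_puf == 0.0

    def test_sample_sd_closed_form(self):
        meta = make_meta([("sp1", "A/B", 1000), ("sp2", "A/C", 1000)])
        rows, _ = survey({"sp1": puf_calls(2), "sp2": puf_calls(4)}, meta)
        (summary,) = aggregate_by_taxon(rows, level=0)
        assert summary.mean_puf == pytest.approx(3.0)
        assert summary.sd_puf == pytest.approx(math.sqrt(2))

    def test_identical_counts_have_zero_sd(self):
        meta = make_meta([(f"sp{i}", "A/B", 1000) for i in range(3)])
        rows, _ = survey({f"sp{i}": puf_calls(1) for i in range(3)}, meta)
        (summary,) = aggregate_by_taxon(rows, level=0)
        assert summary.mean_puf == 1.0 and summary.sd_puf == 0.0

    def test_grouping_level(self):
        meta = make_meta([("sp1", "A/B", 1000), ("sp2", "A/C", 1000)])
        rows, _ = survey({"sp1": puf_calls(1), "sp2": puf_calls(2)}, meta)
        assert len(aggregate_by_taxon(rows, level=0)) == 1
        assert len(aggregate_by_taxon(rows, level=1)) == 2


class TestSignatureArchitectureConcordance:
    def test_noise_free_synthetic_concordance(self, profile):
        from pufsf.repeat_detection import scan_repeats

        sim = simulate_proteome(SimConfig(seed=11, n_species=2, n_decoys=1))
        for rec in sim.records:
            truth = sim.truth.proteins[rec.id]
            by_sig = classify_by_signature(sim.domain_table.get(rec.id, []))
            by_arch = classify_by_architecture(
                scan_repeats(rec.sequence, profile, protein_id=rec.id)
            )
            if truth.label == "PUF":
                assert by_sig.label is Label.PUF and by_arch.label is Label.PUF
            elif truth.label in ("NOP9", "PUM3"):
                assert by_arch.label is Label.ELEVEN_REPEAT_UNRESOLVED
                assert by_sig.label.value == truth.label
            else:
                assert not by_sig.classified and not by_arch.classified
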