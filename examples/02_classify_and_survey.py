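"""Classify a synthetic multi-species proteome and compute survey statistics.

Simulates proteomes for five species (one Nop9, one PUM3, a variable
number of classical Pufs, plus decoys per species), classifies every
protein by its precomputed signatures, and prints the per-species counts
with the Puf-per-gene normalization that relates Puf copy number to
transcriptome size.
"""

from pufsf import (
    SimConfig,
    aggregate_by_taxon,
    classify,
    simulate_proteome,
    survey,
    survey_to_frame,
)

cfg = SimConfig(seed=7, n_species=5)
sim = simulate_proteome(cfg)

calls = {}
for rec in sim.records:
    calls.setdefault(rec.species, []).append(
        classify(sim.domain_table.get(rec.id, []))
    )

rows, summary = survey(calls, sim.metadata)
print(survey_to_frame(rows).to_string(index=False))
print(f"\nmean of per-species ratios: {summary.mean_of_ratios:.3e} "
      f"(one Puf per {summary.genes_per_puf_mean:,.0f} protein-coding genes)")
print(f"pooled ratio:               {summary.pooled_ratio:.3e} "
      f"(one Puf per {summary.genes_per_puf_pooled:,.0f} protein-coding genes)")
print("\nPer-taxon means +/- sample SD:")
for t in aggregate_by_taxon(rows, level=0):
    print(f"  {t.taxon}: Puf {t.mean_puf:.1f}+/-{t.sd_puf:.1f}, "
          f"Nop9 {t.mean_nop9:.1f}, PUM3 {t.mean_pum3:.1f} (n={t.n_species})")
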