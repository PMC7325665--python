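"""Scan conceptual 3'-UTRs of a simulated compact genome for a Puf motif.

Simulates an intronless genome in which the 8-mer UGUAUUUA is planted in
half of the 50-nt UTR windows, extracts every UTR in transcription
orientation, and scans with both the exact consensus matcher and the
PWM scanner with exact p-values.  Target counts are distinct genes.
"""

from pufsf import (
    PWM,
    SimConfig,
    count_target_genes,
    estimate_background,
    extract_utrs,
    motif_to_pwm,
    scan_iupac,
    scan_pwm,
    simulate_genome,
)

MOTIF = "UGUAUUUA"
cfg = SimConfig(seed=11, plant_rate=0.5, n_genome_genes=20)
sim = simulate_genome(cfg, {"Puf3_type": MOTIF})
utrs = extract_utrs(sim.contigs, sim.genes, utr_len=cfg.utr_len)
planted = sorted(t.gene_id for t in sim.truth.genes.values() if t.motif_id)
print(f"{len(utrs)} UTRs of {cfg.utr_len} nt; motif planted in {len(planted)} genes")

hits = scan_iupac(MOTIF, utrs, motif_id="Puf3_type")
print(f"consensus scan: {count_target_genes(hits)} target genes")
for h in hits:
    mark = "planted" if h.gene_id in planted else "chance"
    print(f"  {h.gene_id} @ {h.offset:2d}  {h.matched_sequence}  ({mark})")

pwm = PWM(rows=motif_to_pwm(MOTIF), background=estimate_background(utrs))
pwm_hits = scan_pwm(pwm, utrs, p_threshold=1e-4, motif_id="Puf3_type")
print(f"PWM scan (p<=1e-4): {count_target_genes(pwm_hits)} target genes; "
      f"best p-value {min(h.p_value for h in pwm_hits):.2e}")
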