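# pufsf

Survey and binding-motif prediction for the **Puf superfamily (PufSF)** of
eukaryotic RNA-binding proteins — classical Pufs, Nop9 and PUM3.

PufSF proteins are built from ~36-aa α-helical **Puf repeats**, each of
which reads a single RNA base.  Classical Pufs carry eight repeats and bind
mRNA 3′-UTRs; Nop9 and PUM3 carry eleven repeats and act on rRNA
precursors.  Within each repeat, the **tripartite recognition motif (TRM)**
— the residues at positions 1, 2 and 5 of the five-residue stretch
1‑2‑X‑X‑5 in the second helix — determines the base read: positions 1 and 5
hydrogen-bond the base edge, position 2 stacks.  Because the repeat array
runs antiparallel to the RNA, the N-terminal-most repeat binds the 3′-most
base.

The package is a library (plus a thin `pufsf` CLI) for people doing
comparative surveys of repeat proteins and sequence-specific RBP target
prediction.  It covers:

- **Repeat detection** — per-column log₂-odds profile
  `S_i(a) = log₂ f_i(a)/b(a)` built from a packaged seed alignment, glocally
  aligned at every start with ≤ 4 net indels, followed by colinear chaining
  (maximum-weight non-overlapping selection) and N→C numbering.
- **Classification** — Nop9 / PUM3 / Puf by precomputed signatures
  (Nop9: IPR040000/PTHR13102; PUM3: IPR040059/PTHR13389; Puf:
  IPR001313/SM00025, in that precedence), with repeat-count architecture
  (8 vs 11) as fallback; isoform dedup (longest per gene) and a ≥500-aa
  length filter.
- **Survey statistics** — per-species class counts, per-taxon mean ± sample
  SD, and the Puf-per-gene ratio `n_Puf / n_protein-coding genes` (both the
  mean of per-species ratios and the pooled ratio are reported).
- **Motif prediction** — TRM extraction from detected windows, a
  replaceable (pos1, pos5) → base code table, and 5′→3′ motif assembly with
  `N` at experimentally unassigned pairs.
- **Target scanning** — conceptual 50-nt 3′-UTRs extracted downstream of
  each CDS end in transcription orientation, scanned either by exact
  consensus matching (`N` = any base) or by PWM log-odds with p-values
  computed *exactly* by dynamic programming over integer-discretized scores
  (the FIMO construction); distinct-gene target counts; per-column
  alignment conservation profiles (>80/>60/>40% bins).
- **Synthetic data** — a seeded generator for proteomes (planted repeat
  architectures + TRMs + decoys, with matching domain tables and gene
  counts) and compact intronless genomes with motifs planted in UTR windows
  at a controlled rate, so every stage is testable end to end offline.

## Worked example

Assemble the canonical Puf3-type motif from its TRMs
(`examples/03_predict_binding_motif.py`):

```
TRMs (N->C): ['CR..Q', 'NY..Q', 'NY..Q', 'NY..Q', 'CR..Q', 'NY..Q', 'SN..E', 'NY..Q']
assembled motif: 5'-UGUAUUUA-3' (completeness 100%)
repeat contributing each position (5'->3'): (8, 7, 6, 5, 4, 3, 2, 1)
```

The eight TRMs, read N→C, map to bases A,U,U,U,A,U,G,U; written 5′→3′
under the antiparallel convention that is `UGUAUUUA`, with repeat 8
contributing the 5′ base and repeat 1 the 3′ base.  Completeness 100%
means every (pos1, pos5) pair was present in the code table.

Detect repeats in a simulated classical Puf
(`examples/01_detect_repeats.py`):

```
protein species_001_puf_1: 473 aa
  repeat 1:  179- 215   139.1 bits  window SVVIQ
  ...
  repeat 8:  431- 467   139.1 bits  window SLVIQ
```

Eight ~139-bit repeats in tandem after a long N-terminal extension — the
classical Puf architecture; each `window` column is the 1‑2‑X‑X‑5 stretch
whose TRM feeds motif assembly.  The other examples cover the survey
statistics, UTR scanning (consensus and PWM with exact p-values) and
conservation profiles; each prints its results with a line of
interpretation.

The same operations are scriptable from the shell:

```sh
pufsf simulate --preset survey --seed 1 -o sim/
pufsf detect --fasta sim/proteins.fasta -o repeats.tsv
pufsf classify --domains sim/domains.tsv --fasta sim/proteins.fasta -o classes.tsv
pufsf survey --classes classes.tsv --meta sim/species.tsv -o survey.tsv
pufsf motif --repeats repeats.tsv -o motifs.meme
pufsf scan --genome g.fasta --gff genes.gff3 --motif m=UGUAUUUA -o hits.tsv
```

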