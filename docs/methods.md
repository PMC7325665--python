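# Methods

## The model

Puf-superfamily proteins are tandem arrays of ~36-aa α-helical repeats.
The package models one repeat as a 36-column position-specific scoring
profile and a repeat array as a colinear chain of profile matches:

- **Profile.** For column *i* and residue *a*,
  `S_i(a) = log₂( (c_i(a) + λ·b(a)) / (n_i + λ) / b(a) )` in bits, where
  `c_i(a)` are residue counts from the seed alignment, `n_i` the counted
  residues in the column, `b` the background (uniform 1/20 by default) and
  `λ` the pseudocount weight (default 1).  Columns with >50% gaps are
  dropped before counting; frequencies are floored at 1e-9 so rows stay
  finite in the λ→0 limit.  Five consecutive columns (13–17 of the packaged
  model, its second helix) are marked as the recognition window; they are
  stored in the profile and never hard-coded downstream, because the
  register of the window relative to the repeat boundary is genuinely
  adjustable in divergent proteins.
- **Matching.** The full profile is aligned glocally (every column
  consumed, by match or deletion) at every query start, with at most
  `max_indel` net insertions/deletions at a linear `gap_cost` per residue.
  The scan over starts is a vectorized DP over (column, net-offset) states;
  the alignment path (and hence the window residues) is recovered by a
  scalar traceback only for candidates above threshold.
- **Chaining.** Candidates with score ≥ `min_score` enter a
  maximum-total-score non-overlapping selection (weighted interval
  scheduling).  On exact score ties the leftmost-start solution is kept.
  Selected repeats are numbered 1..k from the N terminus; a gap >
  `max_gap` residues between adjacent repeats starts a new array, and all
  arrays are reported rather than only the best one.
- **Window reading.** The window is read off the alignment path.  A
  deletion that consumes a window column flags the repeat
  `window_incomplete`; such repeats are excluded from motif assembly
  (their base cannot be read) but still count toward architecture.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| `min_score` | 8 | bits | a consensus repeat scores ~140 bits; 8 bits rejects random 36-mers (whose expected score is strongly negative) while tolerating heavy divergence |
| `max_gap` | 30 | aa | repeats are near-contiguous in known structures; 30 aa allows inter-repeat linkers without merging separate arrays |
| `max_indel` | 4 | aa | repeat length varies by a few residues across the family |
| `gap_cost` | 3 | bits/residue | an indel should cost about as much as a poor substitution |
| `pseudocount_weight` | 1 | — | one pseudo-observation per column on a 12-row seed |

All are overridable per call and from the CLI.

## Classification and survey

Signature classification uses the precomputed family signatures
(Nop9 IPR040000/PTHR13102, PUM3 IPR040059/PTHR13389, Puf repeat
IPR001313/SM00025) with precedence NOP9 > PUM3 > PUF, because Nop9/PUM3
proteins also carry generic Puf-repeat signatures.  Architecture
classification maps 6–9 detected repeats to PUF and ≥10 to an
`ELEVEN_REPEAT_UNRESOLVED` class — repeat count alone cannot split Nop9
from PUM3 — and is only consulted when no signature evidence exists.

Isoform deduplication keeps the longest protein per gene (ties: smallest
id).  The source data do not fix a selection rule, so the rule is a
package choice and is configurable.  The ≥500-aa length filter is off by
default in the survey (it belongs to clustering-style input preparation)
and available behind a flag.

The survey reports, per species, class counts and
`puf_per_gene = n_puf / n_protein_coding_genes`, and two overall
summaries: the mean of per-species ratios and the pooled ratio
Σn_puf/Σn_genes.  Both are computed because a single "one Puf per N genes"
figure is ambiguous between the two; neither is privileged.  Per-taxon
aggregation uses the sample standard deviation (n−1; 0 for singleton
groups).

## Motif prediction

TRMs are the residues at window offsets 1, 2, 5.  The base lookup is keyed
on (pos1, pos5) only — those two residues read the base edge, while pos2
stacks and is recorded as provenance.  The packaged code table carries the
canonical literature pairs (N,Q)→U, (C,Q)→A, (S,Q)→A, (S,E)→G, (S,R)→C and
is deliberately *data*, not code: a versioned TSV the user can replace.
Pairs absent from the table yield `N`, leaving the motif incomplete at
that position, and `completeness` records the non-N fraction.

Assembly defaults to the antiparallel convention (N-terminal repeat ↔
3′-most base), with `orientation="parallel"` available since the
convention is a modelling choice, not an observable of the sequence alone.
The packaged table and antiparallel default jointly reproduce the complete
Puf3-type motif 5′-UGUAUUUA-3′ from its TRM list, which is the table's
consistency anchor in the test suite.

## UTR extraction and scanning

Conceptual 3′-UTRs are the `utr_len` (default 50) bases immediately
downstream of the 3′-most CDS base, in transcription orientation.  The
default length models compact genomes with extremely short UTRs.  GFF3
CDS features are assumed to include the stop codon, so the window starts
at the next base.  Windows are truncated (and flagged) at contig ends;
overlaps with downstream genes are not trimmed.  All genomic coordinates
are 1-based inclusive internally; `extract_utrs` is the single place a
0-based half-open conversion occurs.

The consensus scanner matches exactly with motif `N` as wildcard, sense
strand only (targets are mRNAs; both-strand scanning is deliberately not
replicated).  The PWM scanner scores `Σ log₂ p_i(base)/b(base)` against a
0-order background estimated by maximum likelihood from the scanned UTR
set (uniform fallback), and computes p-values exactly: scores are
discretized to integers at scale 1000, the score distribution under the
background is built by position-wise convolution, and the survival
function gives `P(score ≥ observed)`.  The discretization error bound
(≤ width · 5·10⁻⁴ bits) is far below threshold granularity.  Windows
containing `N` are skipped and logged.  The default threshold p ≤ 1e-4 is
exposed as a flag; no multiple-testing correction is applied because
target sets are reported raw.  Target counts are distinct genes per motif;
a gene hit by two motifs counts for both.

Conservation profiles divide the modal non-gap, non-ambiguous symbol count
by the number of rows (gaps count in the denominator) and bin at
>80/>60/>40% — the deterministic version of the usual alignment-colouring
convention.

## The synthetic generator

The generator defines the study conditions under which the pipeline is
validated.  Per species it emits one Nop9 and one PUM3 protein (11
repeats), a classical-Puf count uniform on {2..10} (spanning the observed
range from insect/nematode minima to plant expansions), and decoys of
background composition; proteins are consensus-repeat concatenations with
TRMs planted in the windows, substitution noise ε applied only *outside*
windows, and N-terminal extensions of 20–200 aa for classical Pufs.
Domain tables are noise-free signature annotations; metadata carries
per-species gene counts uniform on [5000, 40000].  The genome preset
places single-CDS intronless genes on both strands with ≥ 2·utr_len
spacing (so neighbouring UTR windows cannot collide) and plants one motif
instance per gene with probability ρ at a random admissible UTR offset.

Randomness is a single integer seed expanded through keyed
`SeedSequence(seed, spawn_key=...)` streams — one per species, protein,
contig and gene — so outputs are byte-identical across runs and platforms
and insensitive to generation order.

What the generator does **not** emulate: realistic amino-acid composition
outside repeats, repeat-length variation and indels (noise is
substitution-only), correlated taxon structure, codon usage, introns, and
genuine divergence of the repeat family from the packaged profile.
Passing the recovery suite therefore demonstrates the pipeline's internal
consistency and its noise tolerance under these conditions, not
performance on real divergent proteomes — on real data the seed alignment
and thresholds matter and may need tuning.

The packaged seed alignment is a constructed stand-in (marked synthetic in
its filename): twelve 36-column rows around a designed consensus whose
window column variants cover the code-table pairs.  Real structurally
characterized repeat alignments can be dropped in via `build_profile` on
any aligned FASTA with a `WINDOW_MASK` row.

## Numerical and design notes

- Profile scores are in bits (log₂) throughout.
- `X` residues score 0 bits (uninformative) at every column.
- The chaining objective is total score; the max-gap rule only partitions
  the selected repeats into arrays, so near-optimal alternative registers
  are visible as competing candidates rather than silently resolved.
- Degenerate inputs: empty FASTA → empty list; a sequence shorter than
  `profile.length − max_indel` → no repeats; zero-length UTR at a contig
  terminus → flagged record, not an error; empty hit list → header-only
  TSV.
- Duplicate FASTA ids are an error (survey counts depend on unique ids);
  letters outside the 20 canonical residues + X are rejected rather than
  coerced, because TRM lookup is residue-exact.

## Running on real data

The package never downloads.  To run the real survey: fetch eukaryotic
reference proteomes (UniProtKB) and the protein2ipr annotation dump,
filter rows to the signatures above, and feed FASTA + TSV to
`pufsf classify` / `pufsf survey` with a species metadata table of
protein-coding gene counts.  For target prediction in a compact genome:
fetch the genome FASTA and GFF3 annotation (e.g. a GiardiaDB release),
then `pufsf detect` → `pufsf motif` → `pufsf scan`.  Published absolute
numbers from such surveys depend on the database snapshot used; record
the annotation file's path and checksum alongside outputs.

## Problem sizes

The shipped validation uses desk-scale sizes chosen to exercise every code
path: 200-seed end-to-end recovery with ~5 proteins per seed, oracle
comparisons on 1000 UTRs × 50 motifs, exhaustive PWM enumeration to width
6, and chaining enumeration to 12 candidates.
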