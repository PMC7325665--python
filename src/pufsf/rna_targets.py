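"""Conceptual 3'-UTR extraction and motif scanning.

The scan target is the "conceptual 3'-UTR": the fixed-length genomic
window (default 50 nt, reflecting the extremely short UTRs of compact
genomes such as *Giardia*) immediately downstream of each gene's CDS end,
taken in transcription orientation.  Two scanners are provided:

* :func:`scan_iupac` — exact consensus matching where ``N`` in the motif
  matches any base (sense strand only, since targets are mRNAs);
* :func:`scan_pwm` — log-odds scoring against a 0-order background with
  per-position p-values computed *exactly* by dynamic programming over
  integer-discretized scores (scale 1000), the FIMO approach.

This module is also the only place genomic coordinates are converted from
1-based inclusive (GFF3) to 0-based half-open (Python slices): see
:func:`extract_utrs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneFeature, MotifHit

logger = logging.getLogger(__name__)

DNA_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(DNA_BASES)}
_N_CODE = 4
_PAD_CODE = 5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_UTR_LEN = 50
DEFAULT_P_THRESHOLD = 1e-4
PVALUE_SCALE = 1000


@dataclass
class UTRRecord:
    """A conceptual 3'-UTR in transcription orientation (sense strand)."""

    gene_id: str
    sequence: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_utrs(
    genome: Mapping[str, str],
    genes: Sequence[GeneFeature],
    utr_len: int = DEFAULT_UTR_LEN,
) -> list[UTRRecord]:
    """Extract the *utr_len* bases downstream of each gene's CDS end.

    '+' strand: contig positions [cds_end+1, cds_end+utr_len] (1-based
    inclusive); '-' strand: reverse complement of [cds_end-utr_len,
    cds_end-1].  Windows are truncated (flagged) at contig boundaries —
    a CDS ending at the contig terminus yields a zero-length record, not an
    error.  Overlaps with downstream genes are deliberately not trimmed.

    This function owns the package's single 1-based -> 0-based half-open
    coordinate conversion.
    """
    out: list[UTRRecord] = []
    for g in genes:
        if g.contig not in genome:
            raise KeyError(f"gene {g.gene_id}: contig {g.contig!r} not in genome")
        contig = genome[g.contig]
        if g.strand == "+":
            lo = g.cds_end_most_3prime           # 0-based start = (cds_end+1) - 1
            hi = min(g.cds_end_most_3prime + utr_len, len(contig))
            seq = contig[lo:hi]
        else:
            hi = g.cds_end_most_3prime - 1       # 0-based end (exclusive) = (cds_end-1)
            lo = max(hi - utr_len, 0)
            seq = reverse_complement(contig[lo:hi])
        out.append(UTRRecord(gene_id=g.gene_id, sequence=seq, truncated=len(seq) < utr_len))
    return out


# ---------------------------------------------------------------------------
# IUPAC (consensus) scanning
# ---------------------------------------------------------------------------

def _encode_utrs(utrs: Sequence[UTRRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Pack UTRs into a padded code matrix (A,C,G,T -> 0..3, N -> 4, pad -> 5)."""
    max_len = max((len(u) for u in utrs), default=0)
    codes = np.full((len(utrs), max_len), _PAD_CODE, dtype=np.int8)
    lengths = np.empty(len(utrs), dtype=np.int64)
    lut = np.full(128, _PAD_CODE, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
    lut[ord("N")] = _N_CODE
    for i, u in enumerate(utrs):
        arr = np.frombuffer(u.sequence.encode(), dtype=np.uint8)
        codes[i, : len(arr)] = lut[arr]
        lengths[i] = len(arr)
    return codes, lengths


def motif_as_dna(motif: str) -> str:
    """Map an RNA-alphabet motif ({A,C,G,U,N}) onto DNA for matching."""
    motif = motif.upper()
    bad = set(motif) - set("ACGUN")
    if bad:
        raise ValueError(f"motif {motif!r}: letters {sorted(bad)} not in A/C/G/U/N")
    return motif.replace("U", "T")


def scan_iupac(
    motif: str, utrs: Sequence[UTRRecord], motif_id: str = "motif"
) -> list[MotifHit]:
    """All exact occurrences of *motif* (N = any base) on the sense strand.

    ``N`` in a UTR matches only a motif ``N``.  Scores and p-values are
    left unset (this is consensus matching, not statistical scoring).
    """
    dna = motif_as_dna(motif)
    w = len(dna)
    if not utrs or w == 0:
        return []
    codes, _ = _encode_utrs(utrs)
    n, max_len = codes.shape
    if w > max_len:
        return []
    hits: list[MotifHit] = []
    for s in range(max_len - w + 1):
        ok = np.ones(n, dtype=bool)
        for p, base in enumerate(dna):
            col = codes[:, s + p]
            if base == "N":
                ok &= col <= _N_CODE
            else:
                ok &= col == _BASE_CODE[base]
            if not ok.any():
                break
        for i in np.nonzero(ok)[0]:
            hits.append(
                MotifHit(
                    motif_id=motif_id,
                    gene_id=utrs[i].gene_id,
                    offset=s,
                    matched_sequence=utrs[i].sequence[s : s + w],
                )
            )
    hits.sort(key=lambda h: (h.motif_id, h.gene_id, h.offset))
    return hits


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position weight matrix over A, C, G, T with a 0-order background."""

    rows: np.ndarray                     # (width, 4) probabilities
    background: np.ndarray               # (4,)
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != 4 or self.rows.shape[0] < 1:
            raise ValueError("PWM rows must be (width, 4) with width >= 1")
        if np.any(np.abs(self.rows.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PWM rows must each sum to 1")

    @property
    def width(self) -> int:
        return self.rows.shape[0]

    def log_odds(self, pseudo: float = 1e-9) -> np.ndarray:
        """Per-position log2-odds against the background (tiny floor keeps
        zero-probability entries finite rather than -inf)."""
        p = np.maximum(self.rows, pseudo)
        return np.log2(p / self.background)

    def int_scores(self, scale: int = PVALUE_SCALE) -> np.ndarray:
        return np.rint(self.log_odds() * scale).astype(np.int64)


def pwm_from_probabilities(
    rows: np.ndarray, background: Sequence[float] | None = None, name: str = "pwm"
) -> PWM:
    if background is None:
        background = np.full(4, 0.25)
    return PWM(rows=np.asarray(rows), background=np.asarray(background), name=name)


def estimate_background(utrs: Sequence[UTRRecord]) -> np.ndarray:
    """0-order maximum-likelihood base frequencies of a UTR set (N ignored);
    uniform fallback when the set holds no unambiguous bases."""
    counts = np.zeros(4)
    for u in utrs:
        for b, c in _BASE_CODE.items():
            counts[c] += u.sequence.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def score_distribution(pwm: PWM, scale: int = PVALUE_SCALE) -> tuple[np.ndarray, int]:
    """Exact pmf of the integer-discretized score under the background.

    Returns ``(pmf, minimum_score)``: ``pmf[k]`` is the probability that a
    random width-w word drawn from the 0-order background scores exactly
    ``minimum_score + k``.  Computed by position-wise convolution, the
    standard exact-p-value dynamic programme.
    """
    ints = pwm.int_scores(scale)
    lo = int(ints.min(axis=1).sum())
    hi = int(ints.max(axis=1).sum())
    # pmf index k corresponds to score lo + k: each row contributes its
    # score shifted by that row's minimum, and lo is the sum of the minima
    pmf = np.zeros(hi - lo + 1)
    pmf[0] = 1.0
    for i in range(pwm.width):
        row = ints[i]
        nxt = np.zeros_like(pmf)
        rlo = int(row.min())
        for b in range(4):
            shift = int(row[b]) - rlo
            contrib = pmf * pwm.background[b]
            if shift == 0:
                nxt += contrib
            else:
                nxt[shift:] += contrib[: len(pmf) - shift]
        pmf = nxt
    return pmf, lo


def exact_pvalues(pwm: PWM, scale: int = PVALUE_SCALE) -> tuple[np.ndarray, int]:
    """Survival function of the integer score: ``sf[k] = P(score >= lo + k)``."""
    pmf, lo = score_distribution(pwm, scale)
    sf = np.cumsum(pmf[::-1])[::-1]
    return sf, lo


def scan_pwm(
    pwm: PWM,
    utrs: Sequence[UTRRecord],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    background: Sequence[float] | None = None,
    motif_id: str | None = None,
    scale: int = PVALUE_SCALE,
) -> list[MotifHit]:
    """Score every sense-strand window and report hits with p <= threshold.

    The background defaults to the 0-order ML estimate from the scanned UTR
    set.  Windows overlapping an ``N`` are skipped (logged).  No multiple-
    testing correction is applied; p-values are exact under the background.
    """
    if motif_id is None:
        motif_id = pwm.name
    if background is None:
        bg = estimate_background(utrs)
    else:
        bg = np.asarray(background, dtype=float)
    pwm = PWM(rows=pwm.rows, background=bg, name=pwm.name)
    w = pwm.width
    ints = pwm.int_scores(scale)
    lodds = pwm.log_odds()
    sf, lo = exact_pvalues(pwm, scale)
    hi = lo + len(sf) - 1

    hits: list[MotifHit] = []
    n_skipped = 0
    for u in utrs:
        if len(u) < w:
            continue
        seq = u.sequence
        for s in range(len(seq) - w + 1):
            window = seq[s : s + w]
            if "N" in window:
                n_skipped += 1
                continue
            cols = [_BASE_CODE[b] for b in window]
            iscore = int(sum(ints[p, c] for p, c in zip(range(w), cols)))
            pval = float(sf[min(max(iscore, lo), hi) - lo]) if iscore <= hi else 0.0
            pval = min(max(pval, np.nextafter(0, 1)), 1.0)
            if pval <= p_threshold:
                score = float(sum(lodds[p, c] for p, c in zip(range(w), cols)))
                hits.append(
                    MotifHit(
                        motif_id=motif_id, gene_id=u.gene_id, offset=s,
                        matched_sequence=window, score=score, p_value=pval,
                    )
                )
    if n_skipped:
        logger.info("scan_pwm(%s): skipped %d windows overlapping N", motif_id, n_skipped)
    hits.sort(key=lambda h: (h.motif_id, h.gene_id, h.offset))
    return hits


def count_target_genes(hits: Iterable[MotifHit]) -> dict[str, int]:
    """Distinct target genes per motif (a gene with several hits counts once;
    a gene hit by two motifs counts for both)."""
    genes: dict[str, set[str]] = {}
    for h in hits:
        genes.setdefault(h.motif_id, set()).add(h.gene_id)
    return {m: len(g) for m, g in genes.items()}


# ---------------------------------------------------------------------------
# Alignment conservation profiles
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    """Per-column identity fraction of an alignment, with display bins."""

    fractions: np.ndarray
    bins: list[str]

    THRESHOLDS = (0.8, 0.6, 0.4)
    LABELS = (">80%", ">60%", ">40%", "<40%")


def conservation_profile(
    alignment: Sequence[str],
    ambiguous: frozenset[str] = frozenset("N"),
) -> ConservationProfile:
    """Column-wise conservation of an alignment (>= 2 equal-length rows).

    The fraction is the count of the modal non-gap, non-ambiguous symbol
    divided by the number of rows — gaps stay in the denominator, so a
    column that is mostly gaps scores low.  Bins follow the >80/>60/>40
    display convention.
    """
    if len(alignment) < 2:
        raise ValueError("alignment needs >= 2 rows")
    width = len(alignment[0])
    for row in alignment:
        if len(row) != width:
            raise ValueError("alignment rows have unequal lengths")
    rows = [r.upper() for r in alignment]
    skip = {"-", "."} | set(ambiguous)
    fractions = np.zeros(width)
    for c in range(width):
        counts: dict[str, int] = {}
        for r in rows:
            sym = r[c]
            if sym not in skip:
                counts[sym] = counts.get(sym, 0) + 1
        fractions[c] = max(counts.values(), default=0) / len(rows)
    bins = []
    for f in fractions:
        for t, label in zip(ConservationProfile.THRESHOLDS, ConservationProfile.LABELS):
            if f > t:
                bins.append(label)
                break
        else:
            bins.append(ConservationProfile.LABELS[-1])
    return ConservationProfile(fractions=fractions, bins=bins)
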