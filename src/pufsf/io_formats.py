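"""Readers and writers for the external formats the pipeline touches.

Dialects, fixed once here so nothing downstream re-parses text:

* FASTA — wrapped at 60 columns on output; sequences uppercased on input.
* GFF3 — ``gene``/``mRNA``/``CDS`` features with ``ID``/``Parent``
  attributes; coordinates stay 1-based inclusive everywhere inside the
  package.  The single place a 0-based half-open conversion happens is
  :func:`pufsf.rna_targets.extract_utrs`.
* protein2ipr-style domain tables — tab-separated, six columns:
  protein accession, signature accession, description, member-DB
  accession, start, end (1-based inclusive protein coordinates).
* species metadata — TSV with columns ``species``, ``taxon_path``
  (slash-separated, supergroup first), ``n_protein_coding_genes``.
* MEME minimal motif format and a hits TSV for scan results.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")
DNA_ALPHABET = frozenset("ACGTN")
RNA_MOTIF_ALPHABET = frozenset("ACGUN")

HITS_COLUMNS = ["motif_id", "gene_id", "offset", "matched_sequence", "score", "p_value"]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class ProteinRecord:
    """A protein (or nucleotide) sequence with optional survey metadata."""

    id: str
    sequence: str
    species: str = ""
    taxon_path: tuple[str, ...] = ()
    is_representative: bool = True

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A protein-coding gene model reduced to what 3'-UTR extraction needs.

    ``cds_end_most_3prime`` is the 1-based position of the last CDS base in
    transcription order: max CDS end on '+', min CDS start on '-'.  Per GFF3
    convention the CDS includes the stop codon, so the conceptual 3'-UTR
    starts at the next base downstream.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cds_end_most_3prime: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.gene_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.start <= self.cds_end_most_3prime <= self.end:
            raise ValueError(f"{self.gene_id}: CDS end {self.cds_end_most_3prime} outside gene")


@dataclass
class DomainAnnotation:
    """One precomputed signature match on a protein (protein2ipr row)."""

    protein_id: str
    signature_id: str
    source: str = ""
    start: int = 1
    end: int = 1
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}/{self.signature_id}: start {self.start} > end {self.end}"
            )
        if not self.signature_id:
            raise ValueError(f"{self.protein_id}: empty signature id")


@dataclass
class MotifHit:
    """A motif occurrence inside a conceptual 3'-UTR (sense strand)."""

    motif_id: str
    gene_id: str
    offset: int  # 0-based within the UTR
    matched_sequence: str
    score: float = float("nan")
    p_value: float = float("nan")


def read_fasta(path: str | Path, alphabet: frozenset[str] | None = PROTEIN_ALPHABET) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are whitespace-stripped and uppercased; record order is
    preserved.  Duplicate ids and letters outside *alphabet* are errors
    (pass ``alphabet=None`` to skip the letter check, e.g. for alignments
    containing gap characters).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet is not None:
            bad = set(seq) - alphabet
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r} contains non-sequence characters "
                    f"{sorted(bad)} (line {_find_offending_line(path, bad)})"
                )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def _find_offending_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return lineno
    return -1


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA wrapped at *wrap* columns (round-trip safe)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a contig -> uppercase sequence mapping."""
    return {r.id: r.sequence for r in read_fasta(path, alphabet=DNA_ALPHABET)}


def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read gene models from GFF3, one :class:`GeneFeature` per gene.

    CDS features are attached to their gene through the ``Parent`` chain
    (CDS -> mRNA -> gene, or CDS -> gene directly).  A CDS whose parent
    cannot be resolved to a gene, or a gene with strand '.', is an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features: list[GeneFeature] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.strand not in "+-":
            raise FormatError(f"gene {gene.id}: strand {gene.strand!r} is not + or -")
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            raise FormatError(f"gene {gene.id}: no CDS features resolvable to this gene")
        if gene.strand == "+":
            cds_end = max(c.end for c in cds)
        else:
            cds_end = min(c.start for c in cds)
        features.append(
            GeneFeature(
                gene_id=gene.id,
                contig=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds_end_most_3prime=cds_end,
            )
        )
    # orphan CDS check: every CDS must reach a gene via Parent links
    gene_ids = {f.gene_id for f in features}
    for c in db.features_of_type("CDS"):
        parents = [p.id for p in db.parents(c, featuretype="gene")]
        if not parents or not set(parents) & gene_ids:
            raise FormatError(f"CDS at {c.seqid}:{c.start}-{c.end} has no resolvable gene parent")
    return features


def read_domain_table(path: str | Path) -> dict[str, list[DomainAnnotation]]:
    """Read a protein2ipr-style TSV grouped by protein accession.

    Expects >= 6 tab-separated columns: protein, signature (IPR), description,
    member-DB accession, start, end.  File order is preserved within each
    protein.  Malformed rows raise with their line number.
    """
    path = Path(path)
    table: dict[str, list[DomainAnnotation]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 tab-separated columns")
            protein, ipr, desc, member, start_s, end_s = cols[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}")
            try:
                ann = DomainAnnotation(
                    protein_id=protein, signature_id=ipr, source=member,
                    start=start, end=end, description=desc,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}")
            table.setdefault(protein, []).append(ann)
    return table


def write_domain_table(table: Mapping[str, Sequence[DomainAnnotation]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for protein_id in table:
            for a in table[protein_id]:
                fh.write(
                    f"{a.protein_id}\t{a.signature_id}\t{a.description}\t"
                    f"{a.source}\t{a.start}\t{a.end}\n"
                )


def read_species_metadata(path: str | Path) -> pd.DataFrame:
    """Read the species metadata TSV.

    Columns: ``species``, ``taxon_path`` (slash-separated, supergroup first),
    ``n_protein_coding_genes``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "taxon_path": str})
    required = {"species", "taxon_path", "n_protein_coding_genes"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_species_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_motif_meme(
    motifs: Mapping[str, str],
    background: Mapping[str, float] | None = None,
    rna: bool = True,
) -> str:
    """Render predicted consensus motifs as MEME minimal-format text.

    Each motif is a string over {A,C,G,U,N}; a specified base gets the full
    probability mass in its letter-probability row and ``N`` gets the
    background row (the wildcard convention of
    :func:`pufsf.motif_prediction.motif_to_pwm` with mass 1).  With
    ``rna=False`` the alphabet is ACGT and U is mapped to T.
    """
    if not motifs:
        raise ValueError("no motifs to write")
    letters = "ACGU" if rna else "ACGT"
    if background is None:
        background = {b: 0.25 for b in letters}
    bg = {(b if rna else b.replace("U", "T")): f for b, f in background.items()}
    lines = ["MEME version 4", "", f"ALPHABET= {letters}", "", "Background letter frequencies"]
    lines.append(" ".join(f"{b} {bg[b]:.6g}" for b in letters))
    for name, motif in motifs.items():
        if not motif:
            raise ValueError(f"motif {name!r} is empty")
        motif = motif.upper()
        if not set(motif) <= RNA_MOTIF_ALPHABET:
            raise ValueError(f"motif {name!r} not over A/C/G/U/N")
        lines += ["", f"MOTIF {name}",
                  f"letter-probability matrix: alength= 4 w= {len(motif)} nsites= 1 E= 0"]
        for base in motif:
            if base == "N":
                row = [bg[b] for b in letters]
            else:
                b = base if rna else base.replace("U", "T")
                row = [1.0 if x == b else 0.0 for x in letters]
            total = sum(row)
            lines.append(" ".join(f"{v / total:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Write motif hits as TSV, sorted by (motif_id, gene_id, offset)."""
    rows = sorted(hits, key=lambda h: (h.motif_id, h.gene_id, h.offset))
    df = pd.DataFrame(
        [
            {
                "motif_id": h.motif_id,
                "gene_id": h.gene_id,
                "offset": h.offset,
                "matched_sequence": h.matched_sequence,
                "score": h.score,
                "p_value": h.p_value,
            }
            for h in rows
        ],
        columns=HITS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t", dtype={"motif_id": str, "gene_id": str})
    return [
        MotifHit(
            motif_id=r.motif_id,
            gene_id=r.gene_id,
            offset=int(r.offset),
            matched_sequence=str(r.matched_sequence),
            score=float(r.score),
            p_value=float(r.p_value),
        )
        for r in df.itertuples(index=False)
    ]
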