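"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the two data regimes the survey
works on: (a) multi-species proteomes containing 8-repeat classical-Puf
and 11-repeat Nop9/PUM3 architectures plus unrelated decoys, with matching
precomputed domain tables and per-species gene counts; and (b) a compact
intronless genome whose genes carry short conceptual 3'-UTRs into which
RNA motifs are planted at a controlled rate.

Reproducibility contract: one integer seed, expanded through keyed
:class:`numpy.random.SeedSequence` streams (one substream per species /
protein / gene), so identical configs give byte-identical outputs and the
output of one entity never depends on how many others were generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AMINO_ACIDS,
    DomainAnnotation,
    GeneFeature,
    ProteinRecord,
    write_domain_table,
    write_fasta,
    write_species_metadata,
)
from .motif_prediction import TRM, TRMCodeTable, assemble_motif, default_code_table
from .repeat_detection import RepeatProfile, default_profile
from .rna_targets import DEFAULT_UTR_LEN, reverse_complement

HYDROPHOBIC = "AILMFVWY"  # plausible fillers for the stacking position
DNA = "ACGT"

# canonical architectures: 8 repeats for classical Pufs, 11 for Nop9/PUM3
CLASSICAL_PUF_REPEATS = 8
ELEVEN_REPEATS = 11

TAXON_PATHS = (
    "Opisthokonta/Metazoa",
    "Archaeplastida/Streptophyta",
    "Metamonada/Diplomonadida",
    "Discoba/Euglenozoa",
    "TSAR/Alveolata",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic survey and genome.

    Defaults follow the surveyed biology: one Nop9 and one PUM3 per
    species, a classical-Puf count uniform on 2..10 (the observed span from
    insect/nematode minima to plant expansions), 50-nt conceptual UTRs, and
    substitution noise ``epsilon`` applied outside recognition windows.
    """

    seed: int = 0
    # proteome preset
    n_species: int = 3
    n_nop9: int = 1
    n_pum3: int = 1
    n_puf_range: tuple[int, int] = (2, 10)     # uniform inclusive
    n_decoys: int = 2
    epsilon: float = 0.0
    n_genes_range: tuple[int, int] = (5_000, 40_000)
    # genome preset
    n_contigs: int = 2
    contig_length: int = 4_000
    n_genome_genes: int = 20
    utr_len: int = DEFAULT_UTR_LEN
    plant_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 0.2:
            raise ValueError("epsilon must be in [0, 0.2]")
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be in [0, 1]")
        for name in ("n_species", "n_nop9", "n_pum3", "n_decoys", "n_contigs",
                     "n_genome_genes", "utr_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ProteinTruth:
    protein_id: str
    species: str
    label: str                      # NOP9 / PUM3 / PUF / DECOY
    n_repeats: int
    trms: list[tuple[str, str, str]]
    motif: str | None               # planted 5'->3' motif (classical Pufs)


@dataclass
class GeneTruth:
    gene_id: str
    strand: str
    motif_id: str | None = None
    offset: int | None = None       # 0-based within the UTR
    instance: str | None = None     # planted DNA word


@dataclass
class TruthTable:
    proteins: dict[str, ProteinTruth] = field(default_factory=dict)
    genes: dict[str, GeneTruth] = field(default_factory=dict)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _random_residues(n: int, background: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n, p=background))


def random_trm(table: TRMCodeTable, rng: np.random.Generator) -> TRM:
    """A TRM whose (pos1, pos5) pair is drawn from the code table."""
    keys = sorted(table.entries)
    p1, p5 = keys[rng.integers(len(keys))]
    return TRM(pos1=p1, pos2=str(rng.choice(list(HYDROPHOBIC))), pos5=p5)


def random_window_trm(rng: np.random.Generator) -> TRM:
    """An arbitrary-residue TRM (Nop9/PUM3-style: no defined base code)."""
    aas = list(AMINO_ACIDS)
    return TRM(
        pos1=str(rng.choice(aas)),
        pos2=str(rng.choice(list(HYDROPHOBIC))),
        pos5=str(rng.choice(aas)),
    )


def simulate_repeat_protein(
    trms: Sequence[TRM],
    n_repeats: int,
    epsilon: float,
    rng: np.random.Generator,
    profile: RepeatProfile | None = None,
    nterm_range: tuple[int, int] = (0, 0),
    cterm_range: tuple[int, int] = (0, 0),
) -> str:
    """One repeat-array protein: consensus repeats carrying the given TRMs.

    Each repeat is the profile consensus with window positions 1, 2 and 5
    replaced by the TRM residues; every residue outside the 5-residue
    window is substituted with probability *epsilon* by a draw from the
    profile background.  Optional N-terminal extension mimics the long
    low-complexity N termini of classical Pufs.
    """
    if len(trms) != n_repeats:
        raise ValueError(f"got {len(trms)} TRMs for {n_repeats} repeats")
    if profile is None:
        profile = default_profile()
    consensus = profile.consensus()
    w0 = profile.window_cols[0] - 1
    window_positions = set(range(w0, w0 + 5))
    aas = list(AMINO_ACIDS)
    parts: list[str] = []
    nt = int(rng.integers(nterm_range[0], nterm_range[1] + 1)) if nterm_range[1] else 0
    parts.append(_random_residues(nt, profile.background, rng))
    for trm in trms:
        repeat = list(consensus)
        repeat[w0] = trm.pos1
        repeat[w0 + 1] = trm.pos2
        repeat[w0 + 4] = trm.pos5
        if epsilon > 0:
            for i in range(len(repeat)):
                if i not in window_positions and rng.random() < epsilon:
                    repeat[i] = aas[rng.choice(20, p=profile.background)]
        parts.append("".join(repeat))
    ct = int(rng.integers(cterm_range[0], cterm_range[1] + 1)) if cterm_range[1] else 0
    parts.append(_random_residues(ct, profile.background, rng))
    return "".join(parts)


@dataclass
class SimulatedProteome:
    records: list[ProteinRecord]
    domain_table: dict[str, list[DomainAnnotation]]
    metadata: pd.DataFrame
    truth: TruthTable


def _family_annotations(
    protein_id: str, label: str, repeat_start: int, n_repeats: int, repeat_len: int
) -> list[DomainAnnotation]:
    """Noise-free protein2ipr-style rows for one simulated protein."""
    anns: list[DomainAnnotation] = []
    span_end = repeat_start + n_repeats * repeat_len
    if label == "NOP9":
        anns.append(DomainAnnotation(protein_id, "IPR040000", "PTHR13102",
                                     repeat_start + 1, span_end, "Nop9 family"))
    elif label == "PUM3":
        anns.append(DomainAnnotation(protein_id, "IPR040059", "PTHR13389",
                                     repeat_start + 1, span_end, "PUM3 family"))
    for k in range(n_repeats):
        s = repeat_start + k * repeat_len
        anns.append(DomainAnnotation(protein_id, "IPR001313", "SM00025",
                                     s + 1, s + repeat_len, "Pumilio RNA-binding repeat"))
    return anns


def simulate_proteome(
    config: SimConfig,
    profile: RepeatProfile | None = None,
    table: TRMCodeTable | None = None,
) -> SimulatedProteome:
    """Synthetic multi-species proteome + domain table + metadata + truth.

    Per species: ``n_nop9`` and ``n_pum3`` 11-repeat proteins tagged with
    their family signatures, ``n_puf`` (uniform on ``n_puf_range``)
    classical 8-repeat Pufs whose TRMs are drawn from the code table, and
    ``n_decoys`` unrelated background-composition sequences with no
    signature.
    """
    if profile is None:
        profile = default_profile()
    if table is None:
        table = default_code_table()
    L = profile.length
    records: list[ProteinRecord] = []
    domain_table: dict[str, list[DomainAnnotation]] = {}
    truth = TruthTable()
    meta_rows = []
    for si in range(config.n_species):
        species = f"species_{si + 1:03d}"
        srng = _rng(config.seed, 0, si)
        n_puf = int(srng.integers(config.n_puf_range[0], config.n_puf_range[1] + 1))
        n_genes = int(srng.integers(config.n_genes_range[0], config.n_genes_range[1] + 1))
        meta_rows.append(
            {
                "species": species,
                "taxon_path": TAXON_PATHS[si % len(TAXON_PATHS)],
                "n_protein_coding_genes": n_genes,
            }
        )
        members: list[tuple[str, str]] = (
            [("NOP9", f"{species}_nop9_{k + 1}") for k in range(config.n_nop9)]
            + [("PUM3", f"{species}_pum3_{k + 1}") for k in range(config.n_pum3)]
            + [("PUF", f"{species}_puf_{k + 1}") for k in range(n_puf)]
            + [("DECOY", f"{species}_decoy_{k + 1}") for k in range(config.n_decoys)]
        )
        for pi, (label, pid) in enumerate(members):
            prng = _rng(config.seed, 0, si, pi)
            if label == "DECOY":
                length = int(prng.integers(200, 601))
                seq = _random_residues(length, profile.background, prng)
                records.append(ProteinRecord(id=pid, sequence=seq, species=species))
                truth.proteins[pid] = ProteinTruth(pid, species, label, 0, [], None)
                continue
            if label == "PUF":
                n_rep = CLASSICAL_PUF_REPEATS
                trms = [random_trm(table, prng) for _ in range(n_rep)]
                motif = assemble_motif(trms, table=table).motif
                nterm = (20, 200)
            else:
                n_rep = ELEVEN_REPEATS
                trms = [random_window_trm(prng) for _ in range(n_rep)]
                motif = None
                nterm = (5, 50)
            seq = simulate_repeat_protein(
                trms, n_rep, config.epsilon, prng, profile=profile,
                nterm_range=nterm, cterm_range=(5, 30),
            )
            records.append(ProteinRecord(id=pid, sequence=seq, species=species))
            truth.proteins[pid] = ProteinTruth(
                pid, species, label, n_rep,
                [(t.pos1, t.pos2, t.pos5) for t in trms], motif,
            )
    # annotate second pass: the repeat region is located from the truth TRMs
    # (window residues are exact even under epsilon noise)
    for rec in records:
        t = truth.proteins[rec.id]
        if t.label == "DECOY":
            continue
        start = _locate_repeat_start(rec.sequence, t, profile)
        domain_table[rec.id] = _family_annotations(
            rec.id, t.label, start, t.n_repeats, L
        )
    domain_table = {pid: anns for pid, anns in domain_table.items() if anns}
    metadata = pd.DataFrame(meta_rows)
    return SimulatedProteome(records, domain_table, metadata, truth)


def _locate_repeat_start(sequence: str, t: ProteinTruth, profile: RepeatProfile) -> int:
    """Find where the repeat array begins (the window residues are exact)."""
    L = profile.length
    w0 = profile.window_cols[0] - 1
    first = t.trms[0]
    pattern_positions = {w0: first[0], w0 + 1: first[1], w0 + 4: first[2]}
    for s in range(len(sequence) - t.n_repeats * L + 1):
        if all(sequence[s + off] == res for off, res in pattern_positions.items()):
            # confirm every repeat's window to avoid chance matches
            ok = True
            for k, trm in enumerate(t.trms):
                base = s + k * L + w0
                if (
                    sequence[base] != trm[0]
                    or sequence[base + 1] != trm[1]
                    or sequence[base + 4] != trm[2]
                ):
                    ok = False
                    break
            if ok:
                return s
    raise RuntimeError(f"repeat array not found in {t.protein_id}")


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    contigs: dict[str, str]
    genes: list[GeneFeature]
    truth: TruthTable


def _fill_motif_instance(motif_dna: str, rng: np.random.Generator) -> str:
    return "".join(
        b if b != "N" else DNA[rng.integers(4)] for b in motif_dna
    )


def simulate_genome(config: SimConfig, motifs: Mapping[str, str]) -> SimulatedGenome:
    """Compact intronless genome with motifs planted in conceptual 3'-UTRs.

    Contigs are uniform-random DNA; genes (single-CDS, both strands) are
    placed with at least ``2 * utr_len`` spacing so neighbouring UTR
    windows cannot collide.  For a fraction ``plant_rate`` of genes one
    motif instance (N positions filled uniformly) is written into the UTR
    window at a random admissible offset.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    motif_ids = sorted(motifs)
    motif_dna = {m: motifs[m].upper().replace("U", "T") for m in motif_ids}
    utr = config.utr_len
    contigs = {}
    for ci in range(config.n_contigs):
        crng = _rng(config.seed, 1, ci)
        contigs[f"contig_{ci + 1}"] = list(
            crng.choice(list(DNA), size=config.contig_length)
        )
    names = sorted(contigs)
    truth = TruthTable()
    genes: list[GeneFeature] = []
    ci = 0
    cursor = utr + 10  # leave room for a '-' strand UTR on the first gene
    for gi in range(config.n_genome_genes):
        grng = _rng(config.seed, 2, gi)
        gene_len = int(grng.integers(150, 301))
        strand = "+" if grng.random() < 0.5 else "-"
        placed = False
        while ci < len(names):
            contig = names[ci]
            start0 = cursor  # 0-based
            end0 = start0 + gene_len  # exclusive
            if end0 + utr + 10 <= len(contigs[contig]):
                placed = True
                break
            ci += 1
            cursor = utr + 10
        if not placed:
            raise ValueError(
                "genes do not fit on the configured contigs; "
                "increase contig_length or n_contigs"
            )
        gene_id = f"gene_{gi + 1:04d}"
        cds_end = end0 if strand == "+" else start0 + 1  # 1-based transcription-order end
        genes.append(
            GeneFeature(
                gene_id=gene_id, contig=contig, start=start0 + 1, end=end0,
                strand=strand, cds_end_most_3prime=cds_end,
            )
        )
        gt = GeneTruth(gene_id=gene_id, strand=strand)
        if grng.random() < config.plant_rate:
            mid = motif_ids[int(grng.integers(len(motif_ids)))]
            instance = _fill_motif_instance(motif_dna[mid], grng)
            w = len(instance)
            if w <= utr:
                offset = int(grng.integers(0, utr - w + 1))
                seq = contigs[contig]
                if strand == "+":
                    lo = cds_end + offset  # 0-based genomic start of instance
                    seq[lo : lo + w] = list(instance)
                else:
                    hi = (cds_end - 1) - offset  # 0-based exclusive end
                    seq[hi - w : hi] = list(reverse_complement(instance))
                gt = GeneTruth(gene_id, strand, motif_id=mid, offset=offset,
                               instance=instance)
        truth.genes[gene_id] = gt
        cursor = end0 + 2 * utr + int(grng.integers(10, 40))
    return SimulatedGenome(
        contigs={name: "".join(seq) for name, seq in contigs.items()},
        genes=genes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Writers (the formats the rest of the package consumes)
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig}\tpufsf_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.contig}\tpufsf_sim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.contig}\tpufsf_sim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )


def write_proteome(sim: SimulatedProteome, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "domains": outdir / "domains.tsv",
        "metadata": outdir / "species.tsv",
        "truth": outdir / "proteome_truth.json",
    }
    write_fasta(sim.records, paths["fasta"])
    write_domain_table(sim.domain_table, paths["domains"])
    write_species_metadata(sim.metadata, paths["metadata"])
    paths["truth"].write_text(
        json.dumps({pid: asdict(t) for pid, t in sim.truth.proteins.items()}, indent=1)
    )
    return paths


def write_genome(sim: SimulatedGenome, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "genes.gff3",
        "truth": outdir / "genome_truth.json",
    }
    write_fasta(
        [ProteinRecord(id=n, sequence=s) for n, s in sim.contigs.items()],
        paths["fasta"],
    )
    write_gff3(sim.genes, paths["gff3"])
    paths["truth"].write_text(
        json.dumps({gid: asdict(t) for gid, t in sim.truth.genes.items()}, indent=1)
    )
    return paths
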