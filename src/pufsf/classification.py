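"""Classify PufSF proteins and compute the comparative survey statistics.

Proteins are assigned to one of three types — Nop9 (11 repeats, 18S rRNA
processing), PUM3 (11 repeats, 7S rRNA processing) or classical Puf
(8 repeats, mRNA 3'-UTR binding) — primarily by precomputed family
signatures, with repeat architecture as a fallback.  Signature precedence
is NOP9 > PUM3 > PUF: Nop9/PUM3 proteins also carry generic Puf-repeat
signatures, so the family-specific call must win.

The survey normalizes classical-Puf copy number by the species'
protein-coding gene count (the Puf-per-gene ratio), the comparison that
links Puf expansion to transcriptome size.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DomainAnnotation, ProteinRecord
from .repeat_detection import PufRepeat

NOP9_SIGNATURES = frozenset({"IPR040000", "PTHR13102"})
PUM3_SIGNATURES = frozenset({"IPR040059", "PTHR13389"})
PUF_SIGNATURES = frozenset({"IPR001313", "SM00025"})


class Label(str, enum.Enum):
    NOP9 = "NOP9"
    PUM3 = "PUM3"
    PUF = "PUF"
    # 11-repeat architecture without a family signature: Nop9 and PUM3
    # cannot be told apart from repeat count alone
    ELEVEN_REPEAT_UNRESOLVED = "ELEVEN_REPEAT_UNRESOLVED"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class PufSFClass:
    label: Label
    evidence: dict[str, str]

    @property
    def classified(self) -> bool:
        return self.label is not Label.UNCLASSIFIED


def classify_by_signature(annotations: Sequence[DomainAnnotation]) -> PufSFClass:
    """Type a protein from its precomputed signatures (NOP9 > PUM3 > PUF)."""
    sigs = {a.signature_id for a in annotations}
    for label, family in (
        (Label.NOP9, NOP9_SIGNATURES),
        (Label.PUM3, PUM3_SIGNATURES),
        (Label.PUF, PUF_SIGNATURES),
    ):
        found = sigs & family
        if found:
            return PufSFClass(label, {"signature": ",".join(sorted(found))})
    return PufSFClass(Label.UNCLASSIFIED, {})


def classify_by_architecture(repeats: Sequence[PufRepeat]) -> PufSFClass:
    """Type a protein from its detected repeat count alone.

    6-9 repeats look like a classical Puf; >= 10 is the 11-repeat
    architecture shared by Nop9 and PUM3, which repeat count cannot split.
    """
    n = len(repeats)
    if 6 <= n <= 9:
        return PufSFClass(Label.PUF, {"architecture": f"{n} repeats"})
    if n >= 10:
        return PufSFClass(Label.ELEVEN_REPEAT_UNRESOLVED, {"architecture": f"{n} repeats"})
    return PufSFClass(Label.UNCLASSIFIED, {})


def classify(
    annotations: Sequence[DomainAnnotation] = (),
    repeats: Sequence[PufRepeat] = (),
) -> PufSFClass:
    """Combined call: signature evidence, when present, overrides architecture."""
    by_sig = classify_by_signature(annotations)
    if by_sig.classified:
        return by_sig
    return classify_by_architecture(repeats)


def dedupe_isoforms(
    records: Sequence[ProteinRecord],
    gene_of: Mapping[str, str] | None = None,
) -> list[ProteinRecord]:
    """Keep one representative protein per gene: the longest sequence,
    ties broken by lexicographically smallest id.  Input order of the
    surviving genes is preserved."""
    if gene_of is None:
        gene_of = {}
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        gene = gene_of.get(rec.id, rec.id)
        cur = best.get(gene)
        if cur is None:
            best[gene] = rec
            order.append(gene)
        elif (len(rec.sequence), ) > (len(cur.sequence), ) or (
            len(rec.sequence) == len(cur.sequence) and rec.id < cur.id
        ):
            best[gene] = rec
    return [best[g] for g in order]


def length_filter(records: Sequence[ProteinRecord], min_len: int = 500) -> list[ProteinRecord]:
    """Drop sequences shorter than *min_len* residues (>= min_len kept)."""
    return [r for r in records if len(r.sequence) >= min_len]


@dataclass
class SurveyRow:
    species: str
    taxon_path: tuple[str, ...]
    n_nop9: int
    n_puf: int
    n_pum3: int
    n_unresolved_11: int
    n_genes: int

    @property
    def puf_per_gene(self) -> float:
        return self.n_puf / self.n_genes


@dataclass
class TaxonSummary:
    taxon: str
    mean_nop9: float
    mean_puf: float
    mean_pum3: float
    sd_nop9: float
    sd_puf: float
    sd_pum3: float
    n_species: int


@dataclass
class SurveySummary:
    """Overall Puf-to-gene normalization, reported both ways.

    ``mean_of_ratios`` averages per-species puf_per_gene; ``pooled_ratio``
    is total Pufs over total genes.  ``genes_per_puf_*`` are their inverses
    (the 'one Puf for every N protein-coding genes' form).
    """

    mean_of_ratios: float
    pooled_ratio: float

    @property
    def genes_per_puf_mean(self) -> float:
        return 1.0 / self.mean_of_ratios if self.mean_of_ratios else float("inf")

    @property
    def genes_per_puf_pooled(self) -> float:
        return 1.0 / self.pooled_ratio if self.pooled_ratio else float("inf")


def survey(
    classes_by_species: Mapping[str, Sequence[PufSFClass]],
    metadata: pd.DataFrame,
) -> tuple[list[SurveyRow], SurveySummary]:
    """Per-species PufSF counts plus the overall Puf-per-gene summary.

    *metadata* is the species metadata table (columns ``species``,
    ``taxon_path``, ``n_protein_coding_genes``); every surveyed species
    must appear there with a positive gene count.
    """
    meta = metadata.set_index("species")
    missing = sorted(set(classes_by_species) - set(meta.index))
    if missing:
        raise KeyError(f"species missing from metadata: {missing}")
    rows: list[SurveyRow] = []
    for species, classes in classes_by_species.items():
        m = meta.loc[species]
        counts = {label: 0 for label in Label}
        for c in classes:
            counts[c.label] += 1
        n_genes = int(m["n_protein_coding_genes"])
        if n_genes <= 0:
            raise ValueError(f"species {species}: non-positive gene count {n_genes}")
        rows.append(
            SurveyRow(
                species=species,
                taxon_path=tuple(str(m["taxon_path"]).split("/")),
                n_nop9=counts[Label.NOP9],
                n_puf=counts[Label.PUF],
                n_pum3=counts[Label.PUM3],
                n_unresolved_11=counts[Label.ELEVEN_REPEAT_UNRESOLVED],
                n_genes=n_genes,
            )
        )
    ratios = [r.puf_per_gene for r in rows]
    total_puf = sum(r.n_puf for r in rows)
    total_genes = sum(r.n_genes for r in rows)
    summary = SurveySummary(
        mean_of_ratios=float(np.mean(ratios)) if ratios else 0.0,
        pooled_ratio=total_puf / total_genes if total_genes else 0.0,
    )
    return rows, summary


def aggregate_by_taxon(rows: Sequence[SurveyRow], level: int = 0) -> list[TaxonSummary]:
    """Mean and sample SD of per-class counts grouped by taxon_path[level]."""
    groups: dict[str, list[SurveyRow]] = {}
    for r in rows:
        if level >= len(r.taxon_path):
            raise IndexError(f"species {r.species}: taxon_path has no level {level}")
        groups.setdefault(r.taxon_path[level], []).append(r)

    def _sd(values: list[int]) -> float:
        return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0

    out = []
    for taxon in sorted(groups):
        g = groups[taxon]
        nop9 = [r.n_nop9 for r in g]
        puf = [r.n_puf for r in g]
        pum3 = [r.n_pum3 for r in g]
        out.append(
            TaxonSummary(
                taxon=taxon,
                mean_nop9=float(np.mean(nop9)),
                mean_puf=float(np.mean(puf)),
                mean_pum3=float(np.mean(pum3)),
                sd_nop9=_sd(nop9),
                sd_puf=_sd(puf),
                sd_pum3=_sd(pum3),
                n_species=len(g),
            )
        )
    return out


def survey_to_frame(rows: Sequence[SurveyRow]) -> pd.DataFrame:
    """Survey rows as a DataFrame with stable column order (TSV output)."""
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "taxon_path": "/".join(r.taxon_path),
                "n_nop9": r.n_nop9,
                "n_puf": r.n_puf,
                "n_pum3": r.n_pum3,
                "n_unresolved_11": r.n_unresolved_11,
                "n_genes": r.n_genes,
                "puf_per_gene": r.puf_per_gene,
            }
            for r in rows
        ],
        columns=[
            "species", "taxon_path", "n_nop9", "n_puf", "n_pum3",
            "n_unresolved_11", "n_genes", "puf_per_gene",
        ],
    )
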