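"""From recognition windows to a predicted RNA-binding motif.

Each Puf repeat reads one RNA base through its tripartite recognition
motif (TRM): the residues at positions 1, 2 and 5 of the five-residue
window (pattern 1-2-X-X-5).  Positions 1 and 5 hydrogen-bond the base
edge and determine specificity; position 2 stacks between bases and is
recorded but not used for the base lookup.  Known (pos1, pos5) pairs map
to bases via a replaceable code table; unknown pairs yield ``N``, leaving
the motif incomplete at that position.

Because the repeat array runs antiparallel to the RNA, the N-terminal-most
repeat binds the 3'-most base: assembling a motif written 5'->3' reverses
the N->C repeat order (the default; ``orientation="parallel"`` disables
the reversal).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import PROTEIN_ALPHABET
from .repeat_detection import PufRepeat

RNA_BASES = "ACGU"
UNKNOWN_BASE = "N"

CODE_TABLE_RESOURCE = "trm_code.tsv"


@dataclass(frozen=True)
class TRM:
    """The three recognition residues of one repeat (window offsets 1, 2, 5)."""

    pos1: str
    pos2: str
    pos5: str

    def __post_init__(self) -> None:
        for r in (self.pos1, self.pos2, self.pos5):
            if r not in PROTEIN_ALPHABET:
                raise ValueError(f"non-canonical TRM residue {r!r}")


@dataclass
class TRMCodeTable:
    """Replaceable (pos1, pos5) -> base code; absent pairs read as ``N``."""

    entries: dict[tuple[str, str], str]
    name: str = "trm_code"
    version: str = "1"
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, base in self.entries.items():
            if base not in RNA_BASES:
                raise ValueError(f"code table entry {key} -> {base!r} not in RNA alphabet")

    def lookup(self, trm: TRM) -> str:
        """Base read by *trm*, or ``N`` when the pair is not in the table."""
        return self.entries.get((trm.pos1, trm.pos5), UNKNOWN_BASE)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TRMCodeTable":
        entries: dict[tuple[str, str], str] = {}
        provenance: dict[tuple[str, str], str] = {}
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                key = (row["pos1"].strip(), row["pos5"].strip())
                if key in entries:
                    raise ValueError(f"{path}: duplicate code table key {key}")
                entries[key] = row["base"].strip()
                provenance[key] = row.get("provenance", "")
        return cls(entries=entries, provenance=provenance)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pos1\tpos5\tbase\tprovenance\n")
            for (p1, p5), base in self.entries.items():
                fh.write(f"{p1}\t{p5}\t{base}\t{self.provenance.get((p1, p5), '')}\n")


_DEFAULT_TABLE: TRMCodeTable | None = None


def default_code_table() -> TRMCodeTable:
    """The packaged code table (canonical literature pairs; data, not code)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.as_file(
            resources.files("pufsf.data").joinpath(CODE_TABLE_RESOURCE)
        ) as path:
            _DEFAULT_TABLE = TRMCodeTable.from_tsv(path)
    return _DEFAULT_TABLE


@dataclass
class BindingMotif:
    """An assembled 5'->3' RNA consensus over {A,C,G,U,N}.

    ``source_repeats[i]`` is the repeat index (1 = N-terminal-most) that
    contributes motif position ``i``; ``completeness`` is the fraction of
    non-N positions.
    """

    motif: str
    source_repeats: tuple[int, ...]
    completeness: float

    def __len__(self) -> int:
        return len(self.motif)


def extract_trm(window5: str) -> TRM:
    """Residues at window offsets 1, 2, 5 (1-based) of a 5-residue window."""
    if len(window5) != 5:
        raise ValueError(f"recognition window must have 5 residues, got {window5!r}")
    return TRM(pos1=window5[0], pos2=window5[1], pos5=window5[4])


def map_trm(trm: TRM, table: TRMCodeTable | None = None) -> str:
    """Base read by a TRM under *table* (default packaged table), or ``N``."""
    if table is None:
        table = default_code_table()
    return table.lookup(trm)


def assemble_motif(
    trms: Sequence[TRM],
    table: TRMCodeTable | None = None,
    orientation: str = "antiparallel",
    repeat_indices: Sequence[int] | None = None,
) -> BindingMotif:
    """Assemble the 5'->3' binding motif from TRMs given in N->C repeat order."""
    if not trms:
        raise ValueError("need at least one TRM")
    if orientation not in ("antiparallel", "parallel"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if table is None:
        table = default_code_table()
    if repeat_indices is None:
        repeat_indices = list(range(1, len(trms) + 1))
    bases = [table.lookup(t) for t in trms]
    order = list(zip(bases, repeat_indices))
    if orientation == "antiparallel":
        order.reverse()
    motif = "".join(b for b, _ in order)
    sources = tuple(i for _, i in order)
    completeness = sum(b != UNKNOWN_BASE for b in motif) / len(motif)
    return BindingMotif(motif=motif, source_repeats=sources, completeness=completeness)


def motif_from_repeats(
    repeats: Sequence[PufRepeat],
    table: TRMCodeTable | None = None,
    orientation: str = "antiparallel",
) -> BindingMotif:
    """Assemble a motif from detected repeats, skipping window-incomplete ones."""
    usable = [r for r in sorted(repeats, key=lambda r: r.index) if not r.window_incomplete]
    if not usable:
        raise ValueError("no repeats with complete recognition windows")
    return assemble_motif(
        [extract_trm(r.window5) for r in usable],
        table=table,
        orientation=orientation,
        repeat_indices=[r.index for r in usable],
    )


def motif_to_pwm(
    motif: str,
    background: Mapping[str, float] | None = None,
    specified_mass: float = 0.99,
) -> np.ndarray:
    """Turn a consensus motif into per-position base probabilities.

    A specified position gets ``specified_mass`` on its base and spreads the
    remainder over the other three bases in background proportion; an ``N``
    position is exactly the background row.  Rows are over A, C, G, U in
    that order and sum to 1.
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("empty motif")
    if not set(motif) <= set(RNA_BASES + UNKNOWN_BASE):
        raise ValueError(f"motif {motif!r} not over A/C/G/U/N")
    if background is None:
        background = {b: 0.25 for b in RNA_BASES}
    bg = np.array([background[b] for b in RNA_BASES], dtype=float)
    bg = bg / bg.sum()
    rows = np.empty((len(motif), 4))
    for i, base in enumerate(motif):
        if base == UNKNOWN_BASE:
            rows[i] = bg
        else:
            k = RNA_BASES.index(base)
            others = bg.copy()
            others[k] = 0.0
            rows[i] = (1.0 - specified_mass) * others / others.sum()
            rows[i, k] = specified_mass
    return rows
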