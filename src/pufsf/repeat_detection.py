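"""Puf-repeat detection with a packaged log-odds profile.

The Pumilio homology domain is an array of ~36-aa alpha-helical repeats,
each of which contacts one RNA base through a five-residue stretch in its
second helix (the 1-2-X-X-5 recognition window).  Classical Pufs carry
eight repeats, Nop9 and PUM3 proteins eleven.

Detection is profile matching plus colinear chaining:

1. A :class:`RepeatProfile` (per-column log2-odds over the 20 residues,
   built from a seed alignment) is glocally aligned against every start
   position of the query, allowing at most ``max_indel`` net
   insertions/deletions at a linear per-residue gap cost.
2. Every alignment scoring at least ``min_score`` bits becomes a
   candidate; the final call is the non-overlapping candidate set of
   maximum total score (weighted interval scheduling; ties resolved in
   favour of leftmost starts).
3. Selected repeats are numbered N- to C-terminal; consecutive repeats
   separated by more than ``max_gap`` residues are split into separate
   arrays, all of which are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import AMINO_ACIDS, ProteinRecord, read_fasta

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_X_CODE = 20      # unknown residue: scores 0 bits everywhere
_PAD_CODE = 21    # past-the-end sentinel: forbidden
_NEG = -1e9

SEED_ALIGNMENT_RESOURCE = "puf_repeat_seed.synthetic.fasta"
WINDOW_MASK_ID = "WINDOW_MASK"

DEFAULT_MIN_SCORE = 8.0   # bits
DEFAULT_MAX_GAP = 30      # residues between adjacent repeats of one array
DEFAULT_MAX_INDEL = 4     # net insertions/deletions per repeat
DEFAULT_GAP_COST = 3.0    # bits per inserted/deleted residue


@dataclass
class RepeatProfile:
    """Per-column log-odds profile for one Puf repeat.

    ``scores[i, a]`` is the log2-odds (bits) of residue ``a`` at model
    column ``i``; ``window_cols`` are the five consecutive 1-based model
    columns of the recognition stretch.
    """

    scores: np.ndarray                 # (length, 20) bits
    background: np.ndarray             # (20,) frequencies, sums to 1
    window_cols: tuple[int, int, int, int, int]
    name: str = "puf_repeat"
    version: str = "1"

    def __post_init__(self) -> None:
        if len(self.window_cols) != 5:
            raise ValueError("window_cols must list 5 model columns")
        w = list(self.window_cols)
        if w != list(range(w[0], w[0] + 5)):
            raise ValueError(f"window_cols must be consecutive, got {w}")
        if not (1 <= w[0] and w[-1] <= self.length):
            raise ValueError(f"window_cols {w} outside model 1..{self.length}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def consensus(self) -> str:
        """Highest-scoring residue per model column."""
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.scores, axis=1))

    def consensus_score(self) -> float:
        """Score of the consensus sequence (the best possible ungapped match)."""
        return float(np.max(self.scores, axis=1).sum())

    # -- TSV round trip (versioned matrix fixture dialect) ------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#name\t{self.name}\n#version\t{self.version}\n")
            fh.write(f"#window_cols\t{','.join(map(str, self.window_cols))}\n")
            fh.write("#background\t" + ",".join(f"{x:.10g}" for x in self.background) + "\n")
            fh.write("col\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, row in enumerate(self.scores, 1):
                fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RepeatProfile":
        meta: dict[str, str] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, value = line[1:].partition("\t")
                    meta[key] = value
                elif line.startswith("col\t") or not line.strip():
                    continue
                else:
                    rows.append([float(x) for x in line.split("\t")[1:]])
        return cls(
            scores=np.array(rows),
            background=np.array([float(x) for x in meta["background"].split(",")]),
            window_cols=tuple(int(x) for x in meta["window_cols"].split(",")),  # type: ignore[arg-type]
            name=meta.get("name", "puf_repeat"),
            version=meta.get("version", "1"),
        )


@dataclass
class PufRepeat:
    """One detected repeat: 0-based half-open protein coordinates."""

    protein_id: str
    start: int
    end: int
    score: float
    index: int = 0              # ordinal within the protein, 1 = N-terminal-most
    window5: str = ""           # residues at the profile's window columns
    window_incomplete: bool = False
    array: int = 1              # repeat-array ordinal (gaps > max_gap split arrays)


def build_profile(
    seed_records: Sequence[ProteinRecord] | str | Path,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> RepeatProfile:
    """Build a :class:`RepeatProfile` from an aligned repeat seed.

    The seed is aligned FASTA; one record with id ``WINDOW_MASK`` marks the
    five recognition-window columns with ``*``.  Columns with more than 50%
    gap characters are dropped before counting.  Per column,

        score(a) = log2( (count(a) + pc * bg(a)) / (n + pc) / bg(a) )

    with ``pc = pseudocount_weight`` and ``n`` the residues counted in the
    column.  Background defaults to uniform (1/20).
    """
    if isinstance(seed_records, (str, Path)):
        seed_records = read_fasta(seed_records, alphabet=None)
    mask_rows = [r for r in seed_records if r.id == WINDOW_MASK_ID]
    seq_rows = [r for r in seed_records if r.id != WINDOW_MASK_ID]
    if not mask_rows:
        raise ValueError(f"seed alignment lacks a {WINDOW_MASK_ID} annotation row")
    if len(seq_rows) < 1:
        raise ValueError("seed alignment has no sequence rows")
    mask = mask_rows[0].sequence
    width = len(mask)
    for r in seq_rows:
        if len(r.sequence) != width:
            raise ValueError(f"seed row {r.id} length {len(r.sequence)} != mask length {width}")

    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)

    gapchars = {"-", "."}
    keep = [
        c for c in range(width)
        if sum(r.sequence[c] in gapchars for r in seq_rows) <= len(seq_rows) / 2
    ]
    window = [i for i, c in enumerate(keep) if mask[c] == "*"]
    if len(window) != 5:
        raise ValueError(f"window mask marks {len(window)} kept columns, need 5")

    pc = float(pseudocount_weight)
    scores = np.zeros((len(keep), 20))
    for i, c in enumerate(keep):
        counts = np.zeros(20)
        for r in seq_rows:
            aa = r.sequence[c]
            if aa in AA_INDEX:
                counts[AA_INDEX[aa]] += 1
        n = counts.sum()
        freq = (counts + pc * background) / (n + pc)
        # floor keeps rows finite in the pc -> 0 limit (unseen residues
        # score a large negative value instead of -inf)
        scores[i] = np.log2(np.maximum(freq, 1e-9) / background)

    return RepeatProfile(
        scores=scores,
        background=background,
        window_cols=tuple(w + 1 for w in window),  # type: ignore[arg-type]
    )


_DEFAULT_PROFILE: RepeatProfile | None = None


def default_profile() -> RepeatProfile:
    """The packaged 36-column Puf-repeat profile (built once, cached)."""
    global _DEFAULT_PROFILE
    if _DEFAULT_PROFILE is None:
        with resources.as_file(
            resources.files("pufsf.data").joinpath(SEED_ALIGNMENT_RESOURCE)
        ) as path:
            _DEFAULT_PROFILE = build_profile(path)
    return _DEFAULT_PROFILE


def _encode(sequence: str) -> np.ndarray:
    codes = np.full(len(sequence), _X_CODE, dtype=np.int64)
    for i, aa in enumerate(sequence):
        if aa in AA_INDEX:
            codes[i] = AA_INDEX[aa]
        elif aa != "X":
            raise ValueError(f"non-canonical residue {aa!r} at position {i}")
    return codes


def _extended_scores(profile: RepeatProfile) -> np.ndarray:
    """Profile scores with extra columns for X (0 bits) and padding (-inf)."""
    L = profile.length
    ext = np.full((L, 22), 0.0)
    ext[:, :20] = profile.scores
    ext[:, _PAD_CODE] = _NEG
    return ext


def _candidate_scan(
    codes: np.ndarray, profile: RepeatProfile, max_indel: int, gap_cost: float
) -> tuple[np.ndarray, np.ndarray]:
    """Best glocal alignment score of the full profile at every query start.

    Returns ``(scores, net_offsets)`` indexed by start position: the best
    achievable score when all profile columns are consumed starting at that
    query position with at most ``max_indel`` net indels, and the net
    offset (alignment end = start + length + offset).  Vectorized over all
    starts at once; state is (profile column, net offset).
    """
    L = profile.length
    n = len(codes)
    sx = _extended_scores(profile)
    padded = np.concatenate([codes, np.full(L + max_indel + 1, _PAD_CODE, dtype=np.int64)])
    b = max_indel
    width = 2 * b + 1  # offsets -b..b, stored at index d + b

    cur = np.full((width, n), _NEG)
    all_starts = np.arange(n)
    for i in range(L):
        if i == 0:
            # column 0 is matched at the start position itself (offset 0)
            cur[b] = sx[0, padded[:n]]
        else:
            nxt = np.full((width, n), _NEG)
            for d in range(-b, b + 1):
                # match: consume column i and the residue at start + i + d
                idx = all_starts + i + d
                valid = idx >= 0
                match = np.where(valid, cur[d + b] + sx[i, padded[np.clip(idx, 0, None)]], _NEG)
                best = match
                # deletion: column i consumed without a residue (offset shrinks)
                if d + 1 <= b:
                    best = np.maximum(best, cur[d + 1 + b] - gap_cost)
                nxt[d + b] = best
            cur = nxt
        # insertions: extra residues consumed without a column (offset grows)
        for d in range(-b + 1, b + 1):
            cur[d + b] = np.maximum(cur[d + b], cur[d - 1 + b] - gap_cost)

    best_d = np.argmax(cur, axis=0)
    best = cur[best_d, np.arange(n)]
    return best, best_d - b


def _traceback_alignment(
    codes: np.ndarray, start: int, profile: RepeatProfile, max_indel: int, gap_cost: float
) -> tuple[float, int, dict[int, int | None]]:
    """Scalar glocal alignment at one start; returns (score, end, col->residue map).

    ``col_map`` maps each 1-based model column to the 0-based query index of
    the residue aligned to it, or None for a deleted column.
    """
    L = profile.length
    sx = _extended_scores(profile)
    padded = np.concatenate(
        [codes, np.full(L + max_indel + 1, _PAD_CODE, dtype=np.int64)]
    )
    b = max_indel
    NEG = _NEG
    # dp[i][d] over states as in _candidate_scan, with parent pointers
    dp = [[NEG] * (2 * b + 1) for _ in range(L)]
    parent: dict[tuple[int, int], tuple[tuple[int, int] | None, str]] = {}
    dp[0][b] = float(sx[0, padded[start]])
    parent[(0, 0)] = (None, "match")
    for d in range(-b + 1, b + 1):
        cand = dp[0][d - 1 + b] - gap_cost
        if cand > dp[0][d + b]:
            dp[0][d + b] = cand
            parent[(0, d)] = ((0, d - 1), "ins")
    for i in range(1, L):
        for d in range(-b, b + 1):
            j = start + i + d
            match = dp[i - 1][d + b] + float(sx[i, padded[j]]) if j >= 0 else NEG
            dele = dp[i - 1][d + 1 + b] - gap_cost if d + 1 <= b else NEG
            if match >= dele:
                dp[i][d + b] = match
                parent[(i, d)] = ((i - 1, d), "match")
            else:
                dp[i][d + b] = dele
                parent[(i, d)] = ((i - 1, d + 1), "del")
        for d in range(-b + 1, b + 1):
            cand = dp[i][d - 1 + b] - gap_cost
            if cand > dp[i][d + b]:
                dp[i][d + b] = cand
                parent[(i, d)] = ((i, d - 1), "ins")
    d_best = int(np.argmax(dp[L - 1])) - b
    score = dp[L - 1][d_best + b]
    col_map: dict[int, int | None] = {}
    state: tuple[int, int] | None = (L - 1, d_best)
    while state is not None:
        prev, move = parent[state]
        i, d = state
        if move == "match":
            col_map[i + 1] = start + i + d
        elif move == "del":
            col_map[i + 1] = None
        state = prev
    return float(score), start + L + d_best, col_map


def locate_window(
    col_map: dict[int, int | None], sequence: str, profile: RepeatProfile
) -> tuple[str, bool]:
    """Read the 5-residue recognition window off a repeat alignment.

    Returns ``(window5, window_incomplete)``; a deletion spanning any window
    column makes the repeat window-incomplete (excluded from motif
    prediction downstream).
    """
    residues = []
    for col in profile.window_cols:
        pos = col_map.get(col)
        if pos is None or pos >= len(sequence):
            return "", True
        residues.append(sequence[pos])
    return "".join(residues), False


def _chain(candidates: list[tuple[int, int, float]]) -> list[int]:
    """Maximum-total-score set of non-overlapping intervals.

    Standard weighted interval scheduling on (start, end, score); on exact
    score ties the leftmost-start solution is kept.  Returns indices into
    *candidates* in start order.
    """
    order = sorted(range(len(candidates)), key=lambda k: (candidates[k][1], candidates[k][0]))
    ends = [candidates[k][1] for k in order]
    import bisect

    dp: list[float] = [0.0] * (len(order) + 1)
    take: list[bool] = [False] * (len(order) + 1)
    pred: list[int] = [0] * (len(order) + 1)
    for t, k in enumerate(order, 1):
        s, e, sc = candidates[k]
        p = bisect.bisect_right(ends, s, 0, t - 1)
        pred[t] = p
        with_k = dp[p] + sc
        if with_k > dp[t - 1]:
            dp[t] = with_k
            take[t] = True
        else:
            dp[t] = dp[t - 1]
    chosen: list[int] = []
    t = len(order)
    while t > 0:
        if take[t]:
            chosen.append(order[t - 1])
            t = pred[t]
        else:
            t -= 1
    chosen.sort(key=lambda k: candidates[k][0])
    return chosen


def scan_repeats(
    sequence: str,
    profile: RepeatProfile | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    max_gap: int = DEFAULT_MAX_GAP,
    max_indel: int = DEFAULT_MAX_INDEL,
    gap_cost: float = DEFAULT_GAP_COST,
    protein_id: str = "",
) -> list[PufRepeat]:
    """Detect the repeat array(s) of a protein sequence.

    Returns repeats numbered 1..k from the N terminus, with their
    recognition windows; an empty list when nothing scores above
    ``min_score``.
    """
    if profile is None:
        profile = default_profile()
    if len(sequence) < profile.length - max_indel:
        return []
    codes = _encode(sequence.upper())
    scores, _ = _candidate_scan(codes, profile, max_indel, gap_cost)
    starts = np.nonzero(scores >= min_score)[0]
    if starts.size == 0:
        return []
    candidates: list[tuple[int, int, float]] = []
    col_maps: list[dict[int, int | None]] = []
    for s in starts.tolist():
        sc, end, col_map = _traceback_alignment(codes, s, profile, max_indel, gap_cost)
        if sc < min_score or end > len(sequence):
            continue
        candidates.append((s, end, sc))
        col_maps.append(col_map)
    if not candidates:
        return []
    chosen = _chain(candidates)
    repeats: list[PufRepeat] = []
    array = 1
    prev_end: int | None = None
    for idx, k in enumerate(chosen, 1):
        s, e, sc = candidates[k]
        if prev_end is not None and s - prev_end > max_gap:
            array += 1
        window5, incomplete = locate_window(col_maps[k], sequence, profile)
        repeats.append(
            PufRepeat(
                protein_id=protein_id, start=s, end=e, score=sc, index=idx,
                window5=window5, window_incomplete=incomplete, array=array,
            )
        )
        prev_end = e
    return repeats


def repeats_to_tsv(repeats: Sequence[PufRepeat], path: str | Path) -> None:
    """Write detected repeats as TSV (the detect CLI output dialect)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tindex\tstart\tend\tscore\twindow5\twindow_incomplete\tarray\n")
        for r in repeats:
            fh.write(
                f"{r.protein_id}\t{r.index}\t{r.start}\t{r.end}\t{r.score:.3f}\t"
                f"{r.window5}\t{int(r.window_incomplete)}\t{r.array}\n"
            )


def repeats_from_tsv(path: str | Path) -> list[PufRepeat]:
    """Read repeat calls from TSV (the escape hatch for curated coordinates)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "window5": str})
    df["window5"] = df["window5"].fillna("")
    return [
        PufRepeat(
            protein_id=r.protein_id, start=int(r.start), end=int(r.end),
            score=float(r.score), index=int(r.index), window5=str(r.window5),
            window_incomplete=bool(getattr(r, "window_incomplete", False)),
            array=int(getattr(r, "array", 1)),
        )
        for r in df.itertuples(index=False)
    ]
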