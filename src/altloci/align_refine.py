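"""Refinement of reference/alt-scaffold pairwise alignments.

The NCBI alignment descriptors (``Gap=`` M/I/D block lists) are often
suboptimal: alignable stretches are fragmented into many small blocks.
The refinement strategy keeps the long M blocks as trusted anchors
("seeds"), discards their noisy ends, and re-aligns everything between
the anchors with a banded chain alignment:

1. large I/D blocks (inversion-scale events) split the descriptor into
   independently aligned chunks;
2. each M block is trimmed by 5% of its length (at most 50 nt) on both
   ends and kept as a seed iff the trimmed core is longer than 50 nt;
3. seeds spanning long runs of N in the alt scaffold (>10 nt) are split
   at the run;
4. a global affine-gap alignment is computed over the union of a
   Chebyshev band around each seed diagonal and the full rectangles
   connecting consecutive seed endpoints (and the alignment ends);
5. the result is trimmed to the segment between the first and last
   differing column, since the alignments begin and end with identical
   anchors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io_formats import GapBlock, gap_blocks_span

__all__ = [
    "Seed",
    "AlignParams",
    "PairwiseAlignment",
    "AlignmentError",
    "extract_seeds",
    "split_alignment_at_large_indels",
    "split_alignment_chunks",
    "split_seed_at_N",
    "banded_chain_align",
    "trim_to_variable_region",
    "refine_alignment",
    "MIN_SEED_LENGTH",
    "SEED_TRIM_FRACTION",
    "SEED_TRIM_CAP",
    "N_SPLIT_RUN",
]

GAP = None  # gap symbol in an alignment column

#: a trimmed M block is kept as a seed iff strictly longer than this
MIN_SEED_LENGTH = 50
#: fraction of an M block trimmed from each end
SEED_TRIM_FRACTION = 0.05
#: trim at most this many nt per end
SEED_TRIM_CAP = 50
#: alt-scaffold N runs strictly longer than this split a seed
N_SPLIT_RUN = 10

_NEG = -(10**9)


class AlignmentError(ValueError):
    """Raised for inconsistent descriptors or unchainable seeds."""


@dataclass(frozen=True)
class Seed:
    """A gapless anchor interval pair, 0-based half-open on both sequences."""

    ref_begin: int
    ref_end: int
    alt_begin: int
    alt_end: int

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_begin != self.alt_end - self.alt_begin:
            raise AlignmentError("seed is not gapless")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_begin

    def shifted(self, ref_delta: int, alt_delta: int) -> "Seed":
        return Seed(
            self.ref_begin + ref_delta,
            self.ref_end + ref_delta,
            self.alt_begin + alt_delta,
            self.alt_end + alt_delta,
        )


@dataclass(frozen=True)
class AlignParams:
    """Scoring and band parameters of the chain alignment.

    With ``gap_extend = 0`` a gap of any length costs exactly
    ``gap_open``. ``band`` is the Chebyshev half-width around each seed
    diagonal; ``max_unbanded`` bounds the fallback full DP when no seeds
    are available.
    """

    match: int = 5
    mismatch: int = -2
    gap_open: int = -20
    gap_extend: int = 0
    band: int = 10
    max_unbanded: int = 20000

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0:
            raise ValueError("invalid alignment scoring parameters")


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment as a list of (ref, alt) symbol columns.

    Gaps are ``None``; no column is gap/gap. ``ref_offset``/``alt_offset``
    give the 0-based start of the aligned interval on each sequence.
    """

    columns: list[tuple[str | None, str | None]]
    ref_offset: int = 0
    alt_offset: int = 0
    score: int = 0

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def ref_span(self) -> int:
        return sum(1 for r, _ in self.columns if r is not None)

    @property
    def alt_span(self) -> int:
        return sum(1 for _, a in self.columns if a is not None)

    def ref_text(self, gap_char: str = "-") -> str:
        return "".join(r if r is not None else gap_char for r, _ in self.columns)

    def alt_text(self, gap_char: str = "-") -> str:
        return "".join(a if a is not None else gap_char for _, a in self.columns)

    def ungapped_ref(self) -> str:
        return "".join(r for r, _ in self.columns if r is not None)

    def ungapped_alt(self) -> str:
        return "".join(a for _, a in self.columns if a is not None)

    def to_gap_descriptor(self) -> str:
        """The alignment as a Gap= M/I/D block string (mismatches inside M)."""
        ops: list[str] = []
        for r, a in self.columns:
            ops.append("M" if (r is not None and a is not None) else ("I" if r is None else "D"))
        blocks: list[GapBlock] = []
        for op in ops:
            if blocks and blocks[-1].op == op:
                blocks[-1] = GapBlock(op, blocks[-1].length + 1)
            else:
                blocks.append(GapBlock(op, 1))
        return "Gap=" + " ".join(str(b) for b in blocks)


# ---------------------------------------------------------------------------
# Seed preprocessing


def extract_seeds(blocks: list[GapBlock], ref_len: int, alt_len: int) -> list[Seed]:
    """Turn the M blocks of a descriptor into trimmed, ordered seeds.

    Each M block of length L is trimmed by ``min(floor(0.05 L), 50)`` nt
    on both ends and kept iff the remaining core is strictly longer than
    50 nt. Seed coordinates come from walking the cumulative M/I/D
    offsets, so seeds are non-overlapping and ordered on both sequences.
    """
    ref_pos = alt_pos = 0
    seeds: list[Seed] = []
    for block in blocks:
        if block.op == "M":
            L = block.length
            t = min(int(SEED_TRIM_FRACTION * L), SEED_TRIM_CAP)
            if L - 2 * t > MIN_SEED_LENGTH:
                seeds.append(
                    Seed(ref_pos + t, ref_pos + L - t, alt_pos + t, alt_pos + L - t)
                )
            ref_pos += L
            alt_pos += L
        elif block.op == "D":
            ref_pos += block.length
        else:
            alt_pos += block.length
        if ref_pos > ref_len or alt_pos > alt_len:
            raise AlignmentError(
                f"descriptor overruns sequence (ref {ref_pos}/{ref_len}, "
                f"alt {alt_pos}/{alt_len})"
            )
    return seeds


def split_alignment_at_large_indels(
    blocks: list[GapBlock], threshold: int
) -> list[list[GapBlock]]:
    """Split a descriptor at I/D blocks of length >= ``threshold``.

    Large paired insertions/deletions mark inversion-scale events; each
    returned sublist is aligned independently downstream and the boundary
    blocks themselves are excluded.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    chunks: list[list[GapBlock]] = []
    current: list[GapBlock] = []
    for block in blocks:
        if block.op in ("I", "D") and block.length >= threshold:
            if current:
                chunks.append(current)
            current = []
        else:
            current.append(block)
    if current:
        chunks.append(current)
    return chunks


def split_alignment_chunks(
    blocks: list[GapBlock], threshold: int
) -> list[tuple[int, int, list[GapBlock]]]:
    """Like :func:`split_alignment_at_large_indels`, with sequence offsets.

    Returns ``(ref_offset, alt_offset, blocks)`` per chunk so each chunk
    can be aligned against the right subsequences.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out: list[tuple[int, int, list[GapBlock]]] = []
    ref_pos = alt_pos = 0
    current: list[GapBlock] = []
    cur_ref = cur_alt = 0
    for block in blocks:
        if block.op in ("I", "D") and block.length >= threshold:
            if current:
                out.append((cur_ref, cur_alt, current))
            current = []
        else:
            if not current:
                cur_ref, cur_alt = ref_pos, alt_pos
            current.append(block)
        if block.op in ("M", "D"):
            ref_pos += block.length
        if block.op in ("M", "I"):
            alt_pos += block.length
    if current:
        out.append((cur_ref, cur_alt, current))
    return out


_N_RUN = re.compile(r"N{%d,}" % (N_SPLIT_RUN + 1))


def split_seed_at_N(seed: Seed, alt_seq: str) -> list[Seed]:
    """Split a seed at alt-scaffold N runs strictly longer than 10 nt.

    The NCBI alignments treat N stretches as matches; long runs carry no
    anchoring information, so the seed is broken into the flanks on
    either side of each run. Flanks that no longer satisfy the >50 nt
    retention rule are dropped.
    """
    if seed.alt_end > len(alt_seq):
        raise AlignmentError("seed extends past alt sequence")
    segment = alt_seq[seed.alt_begin : seed.alt_end].upper()
    pieces: list[Seed] = []
    prev = 0
    for m in _N_RUN.finditer(segment):
        if m.start() > prev:
            pieces.append(
                Seed(
                    seed.ref_begin + prev,
                    seed.ref_begin + m.start(),
                    seed.alt_begin + prev,
                    seed.alt_begin + m.start(),
                )
            )
        prev = m.end()
    if prev == 0:
        return [seed]
    if prev < len(segment):
        pieces.append(
            Seed(
                seed.ref_begin + prev,
                seed.ref_end,
                seed.alt_begin + prev,
                seed.alt_end,
            )
        )
    return [s for s in pieces if s.length > MIN_SEED_LENGTH]


# ---------------------------------------------------------------------------
# Banded chain alignment


def _band_envelope(
    seeds: list[Seed], n: int, m: int, band: int
) -> tuple[list[int], list[int]]:
    """Per-row [lo, hi] column bounds of the allowed DP cells.

    The allowed region is the union of a Chebyshev band of half-width
    ``band`` around each seed diagonal and the rectangles connecting
    consecutive seed endpoints (including (0,0) and (n,m)), each grown by
    ``band``. The union is stored as one interval per row (its convex
    row-wise hull), which can only add cells and never excludes the
    intended search space.
    """
    lo = [m + 1] * (n + 1)
    hi = [-1] * (n + 1)

    def widen(i: int, jlo: int, jhi: int) -> None:
        if 0 <= i <= n:
            lo[i] = min(lo[i], max(0, jlo))
            hi[i] = max(hi[i], min(m, jhi))

    def rect(i1: int, j1: int, i2: int, j2: int) -> None:
        for i in range(max(0, i1 - band), min(n, i2 + band) + 1):
            widen(i, j1 - band, j2 + band)

    prev = (0, 0)
    for seed in seeds:
        rect(prev[0], prev[1], seed.ref_begin, seed.alt_begin)
        diag = seed.alt_begin - seed.ref_begin
        for i in range(max(0, seed.ref_begin - band), min(n, seed.ref_end + band) + 1):
            widen(i, i + diag - band, i + diag + band)
        prev = (seed.ref_end, seed.alt_end)
    rect(prev[0], prev[1], n, m)
    # row-wise hull must be monotone for the DP to stay connected
    for i in range(1, n + 1):
        lo[i] = min(lo[i], hi[i])
        hi[i] = max(hi[i], hi[i - 1])
    for i in range(n - 1, -1, -1):
        lo[i] = min(lo[i], lo[i + 1])
    return lo, hi


def _check_chainable(seeds: list[Seed]) -> None:
    prev_ref = prev_alt = 0
    for seed in seeds:
        if seed.ref_begin < prev_ref or seed.alt_begin < prev_alt:
            raise AlignmentError("seeds are not chainable (coordinates cross)")
        prev_ref, prev_alt = seed.ref_end, seed.alt_end


# DP states; tie preference is M (diagonal) > Y (gap on REF row) > X (gap on ALT row)
_M, _Y, _X = 0, 1, 2


def banded_chain_align(
    seeds: list[Seed],
    ref_seq: str,
    alt_seq: str,
    params: AlignParams = AlignParams(),
) -> PairwiseAlignment:
    """Global affine-gap alignment constrained to the seed-chain band.

    Scores are maximal within the banded search space; whenever the
    unrestricted optimum lies inside the band the result equals the full
    global affine DP. With no seeds the full DP is run, provided both
    sequences are at most ``params.max_unbanded`` nt.
    """
    if not ref_seq or not alt_seq:
        raise AlignmentError("empty sequence")
    _check_chainable(seeds)
    n, m = len(ref_seq), len(alt_seq)
    if seeds:
        if seeds[-1].ref_end > n or seeds[-1].alt_end > m:
            raise AlignmentError("seed extends past sequence end")
        lo, hi = _band_envelope(seeds, n, m, params.band)
    else:
        if max(n, m) > params.max_unbanded:
            raise AlignmentError(
                f"no seeds and sequences exceed the unbanded limit "
                f"({params.max_unbanded} nt)"
            )
        lo, hi = [0] * (n + 1), [m] * (n + 1)

    match, mismatch = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend
    ref_u, alt_u = ref_seq.upper(), alt_seq.upper()

    # score[state][row as list over j-lo[i]]; ptr stores predecessor state
    score_rows: list[list[list[int]]] = []
    ptr_rows: list[list[list[int]]] = []

    for i in range(n + 1):
        w = hi[i] - lo[i] + 1
        srow = [[_NEG] * w for _ in range(3)]
        prow = [[-1] * w for _ in range(3)]
        if i > 0:
            plo, phi = lo[i - 1], hi[i - 1]
            ps = score_rows[i - 1]
            rc = ref_u[i - 1]
        for k, j in enumerate(range(lo[i], hi[i] + 1)):
            if i == 0:
                if j == 0:
                    srow[_M][k] = 0
                elif k > 0 or lo[0] == 0:
                    # leading gap on the REF row
                    prev_k = j - 1 - lo[0]
                    if 0 <= prev_k:
                        best = max(srow[_M][prev_k] + go + ge, srow[_Y][prev_k] + ge)
                        if best > _NEG // 2:
                            srow[_Y][k] = best
                            srow_choice = (
                                _M
                                if srow[_M][prev_k] + go + ge >= srow[_Y][prev_k] + ge
                                else _Y
                            )
                            prow[_Y][k] = srow_choice
                continue
            # state M: consume ref[i-1], alt[j-1]
            if j >= 1 and plo <= j - 1 <= phi:
                pk = j - 1 - plo
                s = match if rc == alt_u[j - 1] else mismatch
                cand = (ps[_M][pk], ps[_Y][pk], ps[_X][pk])
                best_state = 0 if cand[0] >= cand[1] and cand[0] >= cand[2] else (
                    1 if cand[1] >= cand[2] else 2
                )
                if cand[best_state] > _NEG // 2:
                    srow[_M][k] = cand[best_state] + s
                    prow[_M][k] = best_state
            # state X: consume ref[i-1], gap on ALT row
            if plo <= j <= phi:
                pk = j - plo
                cands = (
                    ps[_M][pk] + go + ge,
                    ps[_Y][pk] + go + ge,
                    ps[_X][pk] + ge,
                )
                order = (_M, _Y, _X)
                bi = 0
                for t in range(1, 3):
                    if cands[t] > cands[bi]:
                        bi = t
                if cands[bi] > _NEG // 2:
                    srow[_X][k] = cands[bi]
                    prow[_X][k] = order[bi]
            # state Y: consume alt[j-1], gap on REF row
            if k > 0:
                pk = k - 1
                cands = (
                    srow[_M][pk] + go + ge,
                    srow[_Y][pk] + ge,
                    srow[_X][pk] + go + ge,
                )
                order = (_M, _Y, _X)
                bi = 0
                for t in range(1, 3):
                    if cands[t] > cands[bi]:
                        bi = t
                if cands[bi] > _NEG // 2:
                    srow[_Y][k] = cands[bi]
                    prow[_Y][k] = order[bi]
        score_rows.append(srow)
        ptr_rows.append(prow)

    if not (lo[n] <= m <= hi[n]):
        raise AlignmentError("band does not reach the end of the alignment")
    kf = m - lo[n]
    finals = [score_rows[n][s][kf] for s in (_M, _Y, _X)]
    state = (_M, _Y, _X)[max(range(3), key=lambda t: (finals[t], -t))]
    total = finals[state]
    if total <= _NEG // 2:
        raise AlignmentError("no path through the band")

    # traceback
    columns: list[tuple[str | None, str | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        k = j - lo[i]
        prev_state = ptr_rows[i][state][k]
        if state == _M:
            columns.append((ref_seq[i - 1], alt_seq[j - 1]))
            i, j = i - 1, j - 1
        elif state == _X:
            columns.append((ref_seq[i - 1], GAP))
            i -= 1
        else:
            columns.append((GAP, alt_seq[j - 1]))
            j -= 1
        if i == 0 and j == 0:
            break
        state = prev_state
    columns.reverse()
    return PairwiseAlignment(columns=columns, ref_offset=0, alt_offset=0, score=total)


def alignment_score(aln: PairwiseAlignment, params: AlignParams) -> int:
    """Recompute the affine score of an explicit alignment."""
    score = 0
    prev = "M"
    for r, a in aln.columns:
        if r is not None and a is not None:
            score += params.match if r.upper() == a.upper() else params.mismatch
            prev = "M"
        else:
            side = "X" if a is None else "Y"
            if prev != side:
                score += params.gap_open
            score += params.gap_extend
            prev = side
    return score


def trim_to_variable_region(
    aln: PairwiseAlignment, params: AlignParams = AlignParams()
) -> PairwiseAlignment:
    """Keep only the columns between the first and last difference.

    The alignments begin and end with identical anchors, so the analysis
    is limited to the variable portion. Identical sequences give a
    zero-column alignment.
    """
    diffs = [
        idx
        for idx, (r, a) in enumerate(aln.columns)
        if r is None or a is None or r.upper() != a.upper()
    ]
    if not diffs:
        return PairwiseAlignment(
            columns=[], ref_offset=aln.ref_offset, alt_offset=aln.alt_offset, score=0
        )
    first, last = diffs[0], diffs[-1]
    head = aln.columns[:first]
    ref_skip = sum(1 for r, _ in head if r is not None)
    alt_skip = sum(1 for _, a in head if a is not None)
    sub = PairwiseAlignment(
        columns=aln.columns[first : last + 1],
        ref_offset=aln.ref_offset + ref_skip,
        alt_offset=aln.alt_offset + alt_skip,
    )
    sub.score = alignment_score(sub, params)
    return sub


# ---------------------------------------------------------------------------
# Pipeline


def refine_alignment(
    ref_seq: str,
    alt_seq: str,
    blocks: list[GapBlock],
    params: AlignParams = AlignParams(),
    large_indel_threshold: int = 1000,
) -> list[PairwiseAlignment]:
    """Descriptor + sequences -> refined alignments, one per chunk.

    Splits at large indels, extracts and N-splits seeds per chunk, and
    runs the banded chain alignment on each chunk's subsequences. The
    returned alignments carry offsets into the full input sequences and
    are NOT yet trimmed to the variable region.
    """
    ref_total, alt_total = gap_blocks_span(blocks)
    if ref_total > len(ref_seq) or alt_total > len(alt_seq):
        raise AlignmentError("descriptor spans exceed the supplied sequences")
    alignments: list[PairwiseAlignment] = []
    for ref_off, alt_off, chunk in split_alignment_chunks(blocks, large_indel_threshold):
        ref_span, alt_span = gap_blocks_span(chunk)
        if ref_span == 0 or alt_span == 0:
            continue
        ref_sub = ref_seq[ref_off : ref_off + ref_span]
        alt_sub = alt_seq[alt_off : alt_off + alt_span]
        seeds = extract_seeds(chunk, ref_span, alt_span)
        seeds = [s for seed in seeds for s in split_seed_at_N(seed, alt_sub)]
        aln = banded_chain_align(seeds, ref_sub, alt_sub, params)
        aln.ref_offset = ref_off
        aln.alt_offset = alt_off
        alignments.append(aln)
    return alignments
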