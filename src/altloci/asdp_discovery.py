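"""Discovery of alignable scaffold-discrepant positions (ASDPs).

An ASDP is a divergent position or event in the refined alignment
between a primary-assembly region and an alternate-locus scaffold,
lying within an otherwise well-aligned stretch. Candidate events are
maximal runs of discrepant alignment columns; high-confidence ASDPs are
the candidates that survive a sliding-window density filter (no window
of 50 alignment columns covering the event may contain more than ten
discrepant columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .align_refine import (
    AlignParams,
    PairwiseAlignment,
    refine_alignment,
    trim_to_variable_region,
)
from .io_formats import RegionInfo, VariantCall, make_vcf_header, write_vcf

__all__ = [
    "Asdp",
    "SNV",
    "DELETION",
    "INSERTION",
    "BLOCK_SUBSTITUTION",
    "SMALL",
    "SV",
    "DEFAULT_WINDOW",
    "DEFAULT_MAX_DISCREPANCIES",
    "DEFAULT_SV_CUTOFF",
    "call_candidate_asdps",
    "high_confidence_filter",
    "asdps_to_vcf",
    "read_asdp_vcf",
    "discover_asdps",
    "ASDP_INFO_HEADER_LINES",
]

SNV = "SNV"
DELETION = "DELETION"
INSERTION = "INSERTION"
BLOCK_SUBSTITUTION = "BLOCK_SUBSTITUTION"
SMALL = "SMALL"
SV = "SV"

DEFAULT_WINDOW = 50
DEFAULT_MAX_DISCREPANCIES = 10
#: events of this size or larger are classed as structural variants
DEFAULT_SV_CUTOFF = 50


@dataclass
class Asdp:
    """One divergent event between a region and an alt-locus scaffold.

    ``pos`` is the 1-based chromosome position (anchor base included for
    indels); ``columns`` records the half-open alignment-column span of
    the underlying discrepant run, used by the window filter.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    category: str
    event_size: int
    size_class: str
    alt_locus: str
    region_id: str = ""
    high_confidence: bool = True
    columns: tuple[int, int] | None = None

    @property
    def end(self) -> int:
        """1-based inclusive end of the REF-side footprint."""
        return self.pos + len(self.ref_allele) - 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def classify_event(ref_allele: str, alt_allele: str, sv_cutoff: int = DEFAULT_SV_CUTOFF):
    """(category, event_size, size_class) from the two event alleles."""
    lr, la = len(ref_allele), len(alt_allele)
    if lr == la == 1:
        category, size = SNV, 1
    elif lr == la:
        category, size = BLOCK_SUBSTITUTION, lr
    elif lr > la:
        category, size = DELETION, lr - 1
    else:
        category, size = INSERTION, la - 1
    return category, size, (SV if size >= sv_cutoff else SMALL)


def _is_discrepant(column: tuple[str | None, str | None]) -> bool:
    r, a = column
    return r is None or a is None or r.upper() != a.upper()


def call_candidate_asdps(
    aln: PairwiseAlignment,
    region: RegionInfo,
    alt_locus: str,
    sv_cutoff: int = DEFAULT_SV_CUTOFF,
) -> list[Asdp]:
    """Merge discrepant alignment columns into candidate ASDP events.

    ``aln`` must already be trimmed to the variable region; its
    ``ref_offset`` is the 0-based offset into the region sequence.
    Maximal runs of consecutive discrepant columns form one event each;
    when either allele of a run would be empty (a pure indel) the
    preceding REF base is prepended per the VCF anchoring convention (the
    following base at the alignment start). Positions are reported in
    chromosome coordinates via ``region.ref_start``.
    """
    cols = aln.columns
    n = len(cols)
    # ref-consumed prefix counts: ref position of column c is ref_offset + pref[c]
    pref = [0] * (n + 1)
    for c, (r, _) in enumerate(cols):
        pref[c + 1] = pref[c] + (1 if r is not None else 0)
    if region.ref_start + aln.ref_offset + pref[n] - 1 > region.ref_stop:
        raise ValueError("alignment extends past the region's reference span")

    asdps: list[Asdp] = []
    c = 0
    while c < n:
        if not _is_discrepant(cols[c]):
            c += 1
            continue
        start = c
        while c < n and _is_discrepant(cols[c]):
            c += 1
        end = c  # half-open run [start, end)
        ref_run = "".join(r for r, _ in cols[start:end] if r is not None)
        alt_run = "".join(a for _, a in cols[start:end] if a is not None)
        ref_pos0 = aln.ref_offset + pref[start]  # 0-based region offset of run start
        if ref_run and alt_run:
            pos = region.ref_start + ref_pos0
            ref_allele, alt_allele = ref_run, alt_run
        elif start > 0:
            anchor = cols[start - 1][0]
            pos = region.ref_start + ref_pos0 - 1
            ref_allele, alt_allele = anchor + ref_run, anchor + alt_run
        elif end < n:
            anchor = cols[end][0]
            pos = region.ref_start + ref_pos0
            ref_allele, alt_allele = ref_run + anchor, alt_run + anchor
        else:
            raise ValueError(
                "alignment consists of a single unanchored indel; no flanking "
                "reference base available for the VCF representation"
            )
        category, size, size_class = classify_event(ref_allele, alt_allele, sv_cutoff)
        asdps.append(
            Asdp(
                chrom=region.chrom,
                pos=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                category=category,
                event_size=size,
                size_class=size_class,
                alt_locus=alt_locus,
                region_id=region.region_id,
                columns=(start, end),
            )
        )
    return asdps


def high_confidence_filter(
    candidates: Sequence[Asdp],
    aln: PairwiseAlignment,
    window: int = DEFAULT_WINDOW,
    max_disc: int = DEFAULT_MAX_DISCREPANCIES,
) -> list[Asdp]:
    """Apply the sliding-window discrepancy filter to candidate ASDPs.

    The window advances one column at a time over the alignment; a
    candidate is excluded iff any window of ``window`` columns containing
    at least one column of the candidate's run has more than ``max_disc``
    discrepant columns. Only fully contained windows are evaluated;
    alignments shorter than ``window`` are treated as a single window.
    Excluded candidates get ``high_confidence = False`` in place; the
    survivors are returned.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(aln.columns)
    disc = [1 if _is_discrepant(col) else 0 for col in aln.columns]
    prefix = [0]
    for d in disc:
        prefix.append(prefix[-1] + d)

    # bad[c] == True iff some over-dense window covers column c
    bad = [False] * n
    if n <= window:
        if prefix[n] > max_disc:
            bad = [True] * n
    else:
        delta = [0] * (n + 1)
        for w0 in range(0, n - window + 1):
            if prefix[w0 + window] - prefix[w0] > max_disc:
                delta[w0] += 1
                delta[w0 + window] -= 1
        cover = 0
        for c in range(n):
            cover += delta[c]
            bad[c] = cover > 0

    kept: list[Asdp] = []
    for asdp in candidates:
        if asdp.columns is None:
            raise ValueError("candidate lacks its alignment-column span")
        s, e = asdp.columns
        excluded = any(bad[c] for c in range(s, e))
        asdp.high_confidence = not excluded
        if not excluded:
            kept.append(asdp)
    return kept


# ---------------------------------------------------------------------------
# VCF serialization

ASDP_INFO_HEADER_LINES = (
    '##INFO=<ID=ALTLOCUS,Number=1,Type=String,Description='
    '"Alternate locus scaffold the ASDP derives from">',
    '##INFO=<ID=REGION,Number=1,Type=String,Description='
    '"Structurally variable region identifier">',
    '##INFO=<ID=CATEGORY,Number=1,Type=String,Description='
    '"ASDP category: SNV, DELETION, INSERTION or BLOCK_SUBSTITUTION">',
    '##INFO=<ID=SIZECLASS,Number=1,Type=String,Description='
    '"SMALL (<50 nt) or SV (>=50 nt)">',
    '##INFO=<ID=HC,Number=0,Type=Flag,Description='
    '"High-confidence ASDP (passes the sliding-window filter)">',
)


def asdps_to_vcf(
    asdps: Sequence[Asdp],
    ref_seqs: Mapping[str, str],
    path,
    region_starts: Mapping[str, int] | None = None,
) -> None:
    """Write ASDPs as a VCF with ALTLOCUS/REGION/CATEGORY/SIZECLASS/HC INFO.

    ``ref_seqs`` maps chromosome name to its sequence (``region_starts``
    gives the 1-based position of each sequence's first base, default 1);
    every record's REF allele is checked against it. Records are sorted
    by (chrom, pos); the same reference position may appear once per alt
    locus.
    """
    starts = region_starts or {}
    for asdp in asdps:
        seq = ref_seqs.get(asdp.chrom)
        if seq is None:
            raise ValueError(f"no reference sequence for contig {asdp.chrom}")
        offset = asdp.pos - starts.get(asdp.chrom, 1)
        expected = seq[offset : offset + len(asdp.ref_allele)].upper()
        if expected != asdp.ref_allele.upper():
            raise ValueError(
                f"REF allele mismatch at {asdp.chrom}:{asdp.pos}: "
                f"ASDP {asdp.ref_allele!r} vs reference {expected!r}"
            )
    contigs = {
        chrom: starts.get(chrom, 1) + len(seq) - 1 for chrom, seq in ref_seqs.items()
    }
    header = make_vcf_header(contigs, ASDP_INFO_HEADER_LINES, sample=None)
    records = [
        VariantCall(a.chrom, a.pos, a.ref_allele, a.alt_allele) for a in asdps
    ]
    info = [
        {
            "ALTLOCUS": a.alt_locus,
            "REGION": a.region_id or ".",
            "CATEGORY": a.category,
            "SIZECLASS": a.size_class,
            **({"HC": True} if a.high_confidence else {}),
        }
        for a in asdps
    ]
    write_vcf(records, header, path, info=info)


def read_asdp_vcf(path) -> list[Asdp]:
    """Read a VCF written by :func:`asdps_to_vcf` back into Asdp records."""
    import pysam

    asdps: list[Asdp] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                category = rec.info.get("CATEGORY", ".")
                size_class = rec.info.get("SIZECLASS", SMALL)
                _, size, _ = classify_event(rec.ref, alt)
                asdps.append(
                    Asdp(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=alt.upper(),
                        category=category,
                        event_size=size,
                        size_class=size_class,
                        alt_locus=rec.info.get("ALTLOCUS", "."),
                        region_id=rec.info.get("REGION", "."),
                        high_confidence=bool(rec.info.get("HC", False)),
                    )
                )
    return asdps


# ---------------------------------------------------------------------------
# Region-level pipeline


def discover_asdps(
    ref_seq: str,
    alt_seq: str,
    blocks,
    region: RegionInfo,
    alt_locus: str,
    params: AlignParams = AlignParams(),
    window: int = DEFAULT_WINDOW,
    max_disc: int = DEFAULT_MAX_DISCREPANCIES,
    sv_cutoff: int = DEFAULT_SV_CUTOFF,
    large_indel_threshold: int = 1000,
) -> list[Asdp]:
    """Full discovery for one region/alt-locus pair.

    Refines the descriptor-based alignment, trims each chunk to its
    variable portion, calls candidate events and applies the window
    filter. Returns ALL candidates; survivors carry
    ``high_confidence=True``.
    """
    candidates: list[Asdp] = []
    for aln in refine_alignment(
        ref_seq, alt_seq, blocks, params, large_indel_threshold
    ):
        trimmed = trim_to_variable_region(aln, params)
        if not trimmed.columns:
            continue
        chunk_candidates = call_candidate_asdps(trimmed, region, alt_locus, sv_cutoff)
        high_confidence_filter(chunk_candidates, trimmed, window, max_disc)
        candidates.extend(chunk_candidates)
    return candidates
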