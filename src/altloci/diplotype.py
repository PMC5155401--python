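"""Per-region diplotype inference from called variants and ASDPs.

For each structurally variable region the algorithm compares the set R
of variants called against the primary assembly with the set A of
high-confidence ASDPs of each associated alternate locus. Treating an
ASDP-associated variant as equivalent to its ASDP, the residual-variant
set is the symmetric set difference

    RV = R triangle A = (R \\ A) union (A \\ R),   |RV| = |R| + |A| - 2|R inter A|.

If the smallest |RV| over the region's loci is strictly below |R|,
assuming the alternate locus reduces the variant burden and the locus is
inferred present; the fraction of matched variants called homozygous
then separates the homozygous (> 90% by default) from the heterozygous
state. Otherwise the region is called homozygous primary assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import intervaltree
import pandas as pd
import pysam

from .asdp_discovery import SMALL, Asdp
from .io_formats import HOM_ALT, MISSING, RegionInfo, VariantCall

__all__ = [
    "InferenceConfig",
    "RegionGenotype",
    "RvResult",
    "REF_HOM",
    "ALT_HET",
    "ALT_HOM",
    "normalize_variant",
    "match_variants_to_asdps",
    "residual_variants",
    "infer_region_genotype",
    "annotate_sample_vcf",
]

REF_HOM = "REF_HOM"
ALT_HET = "ALT_HET"
ALT_HOM = "ALT_HOM"

ASDP_REGION_FILTER = "ASDP_REGION"

_ANNOTATE_HEADER_LINES = (
    '##INFO=<ID=ASDPALT,Number=1,Type=String,Description='
    '"Alternate locus whose ASDP this variant corresponds to">',
    '##INFO=<ID=REGIONGT,Number=1,Type=String,Description='
    '"Inferred diplotype of the enclosing structurally variable region">',
    f'##FILTER=<ID={ASDP_REGION_FILTER},Description='
    '"ASDP-associated variant in a region inferred to carry an alternate locus">',
)


@dataclass(frozen=True)
class InferenceConfig:
    """Tunables of the diplotype inference.

    ``hom_threshold``: fraction of matched variants that must be
    homozygous for an ALT_HOM call (strictly greater than). ``include_sv``
    keeps SV-class ASDPs in the inference set A (off by default, since
    typical small-variant callers do not call events of 50 nt and more,
    so unmatched SV ASDPs would only inflate |A \\ R|).
    """

    hom_threshold: float = 0.90
    include_sv: bool = False
    match_mode: str = "allele_exact"

    def __post_init__(self) -> None:
        if not 0 < self.hom_threshold < 1:
            raise ValueError("hom_threshold must be in (0, 1)")
        if self.match_mode not in ("allele_exact", "position_only"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")


@dataclass
class RegionGenotype:
    """Inference result for one region."""

    region_id: str
    chosen_alt: str | None
    call: str
    n_R: int
    n_A: int
    n_shared: int
    n_RV: int
    hom_fraction: float | None = None
    low_evidence: bool = False


@dataclass
class RvResult:
    """The residual-variant set and its bookkeeping for one locus."""

    residual_calls: list[VariantCall]
    residual_asdps: list[Asdp]
    matched: list[tuple[VariantCall, Asdp]]
    n_R: int
    n_A: int

    @property
    def n_shared(self) -> int:
        return len(self.matched)

    @property
    def n_RV(self) -> int:
        return len(self.residual_calls) + len(self.residual_asdps)


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    seq: str | None = None,
    seq_start: int = 1,
) -> tuple[str, int, str, str]:
    """Left-align and trim a variant to its canonical representation.

    Shared suffix bases are removed (keeping at least one base per
    allele); when ``seq`` (the reference sequence whose first base sits
    at 1-based ``seq_start``) is supplied, indels are shifted left
    through repeat tracts; finally shared prefix bases are trimmed.
    Matching two representations of the same event then reduces to tuple
    equality.
    """
    ref, alt = ref.upper(), alt.upper()
    changed = True
    while changed:
        changed = False
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
            continue
        if (
            ref[-1] == alt[-1]
            and (len(ref) == 1 or len(alt) == 1)
            and seq is not None
            and pos > seq_start
        ):
            prev = seq[pos - 1 - seq_start].upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def match_variants_to_asdps(
    R: Sequence[VariantCall],
    A: Sequence[Asdp],
    mode: str = "allele_exact",
    seq: str | None = None,
    seq_start: int = 1,
) -> list[tuple[VariantCall, Asdp]]:
    """One-to-one matching between called variants and ASDPs.

    In ``allele_exact`` mode a pair matches iff chromosome, position and
    both alleles agree after normalization; ``position_only`` matches on
    (chrom, normalized pos) alone. Each variant matches at most one ASDP
    and vice versa (first-come within input order).
    """
    if mode not in ("allele_exact", "position_only"):
        raise ValueError(f"unknown match mode {mode!r}")

    def vkey(chrom, pos, ref, alt):
        norm = normalize_variant(chrom, pos, ref, alt, seq, seq_start)
        return norm if mode == "allele_exact" else norm[:2]

    available: dict[tuple, list[int]] = {}
    for idx, asdp in enumerate(A):
        key = vkey(asdp.chrom, asdp.pos, asdp.ref_allele, asdp.alt_allele)
        available.setdefault(key, []).append(idx)
    matched: list[tuple[VariantCall, Asdp]] = []
    for call in R:
        key = vkey(call.chrom, call.pos, call.ref_allele, call.alt_allele)
        bucket = available.get(key)
        if bucket:
            matched.append((call, A[bucket.pop(0)]))
    return matched


def residual_variants(
    R: Sequence[VariantCall],
    A: Sequence[Asdp],
    mode: str = "allele_exact",
    seq: str | None = None,
    seq_start: int = 1,
) -> RvResult:
    """The symmetric set difference RV = R triangle A.

    Residual calls are the non-ASDP-associated variants; residual ASDPs
    are alternate-locus differences not observed in the sample. The
    identity |RV| = |R| + |A| - 2|R inter A| holds exactly.
    """
    matched = match_variants_to_asdps(R, A, mode, seq, seq_start)
    matched_calls = {id(c) for c, _ in matched}
    matched_asdps = {id(a) for _, a in matched}
    return RvResult(
        residual_calls=[c for c in R if id(c) not in matched_calls],
        residual_asdps=[a for a in A if id(a) not in matched_asdps],
        matched=matched,
        n_R=len(R),
        n_A=len(A),
    )


def _locus_rank(item: tuple[str, RvResult]) -> tuple[int, int, str]:
    acc, rv = item
    # smallest |RV|; ties broken by larger overlap, then accession name
    return (rv.n_RV, -rv.n_shared, acc)


def infer_region_genotype(
    R: Sequence[VariantCall],
    A_by_locus: Mapping[str, Sequence[Asdp]],
    cfg: InferenceConfig = InferenceConfig(),
    seq: str | None = None,
    seq_start: int = 1,
) -> RegionGenotype:
    """Infer the diplotype of one region from R and its per-locus ASDP sets.

    The locus with the smallest |RV| is the best candidate and only it is
    considered. The alternate locus is inferred present iff |RV| < |R|;
    the homozygous state requires the homozygous fraction of matched
    variants (those with a defined genotype) to exceed the threshold.
    Regions with no variant calls are reported REF_HOM with
    ``low_evidence`` set, since the decision rule is applied without
    observations.
    """
    if not A_by_locus:
        raise ValueError("region has no alternate loci; nothing to infer")
    results: dict[str, RvResult] = {}
    for acc, asdps in A_by_locus.items():
        filtered = [
            a for a in asdps if cfg.include_sv or a.size_class == SMALL
        ]
        results[acc] = residual_variants(R, filtered, cfg.match_mode, seq, seq_start)
    best_acc, best = min(results.items(), key=_locus_rank)
    region_id = ""
    for asdps in A_by_locus.values():
        for a in asdps:
            region_id = a.region_id
            break
        if region_id:
            break

    if best.n_R == 0:
        return RegionGenotype(
            region_id=region_id,
            chosen_alt=None,
            call=REF_HOM,
            n_R=0,
            n_A=best.n_A,
            n_shared=0,
            n_RV=best.n_RV,
            low_evidence=True,
        )
    if best.n_RV < best.n_R:
        defined = [c for c, _ in best.matched if c.genotype != MISSING]
        hom_fraction: float | None
        if defined:
            hom_fraction = sum(1 for c in defined if c.genotype == HOM_ALT) / len(
                defined
            )
            call = ALT_HOM if hom_fraction > cfg.hom_threshold else ALT_HET
        else:
            hom_fraction = None
            call = ALT_HET
        return RegionGenotype(
            region_id=region_id,
            chosen_alt=best_acc,
            call=call,
            n_R=best.n_R,
            n_A=best.n_A,
            n_shared=best.n_shared,
            n_RV=best.n_RV,
            hom_fraction=hom_fraction,
        )
    return RegionGenotype(
        region_id=region_id,
        chosen_alt=None,
        call=REF_HOM,
        n_R=best.n_R,
        n_A=best.n_A,
        n_shared=best.n_shared,
        n_RV=best.n_RV,
    )


# ---------------------------------------------------------------------------
# VCF annotation pipeline


def _asdp_span(
    asdps: Iterable[Asdp], seq: str | None = None, seq_start: int = 1
) -> tuple[int, int] | None:
    """REF-side interval covered by the ASDPs, on left-normalized positions."""
    lo = hi = None
    for a in asdps:
        _, pos, ref_allele, _ = normalize_variant(
            a.chrom, a.pos, a.ref_allele, a.alt_allele, seq, seq_start
        )
        end = pos + len(ref_allele) - 1
        lo = pos if lo is None else min(lo, pos)
        hi = end if hi is None else max(hi, end)
    return None if lo is None else (lo, hi)


def annotate_sample_vcf(
    vcf_in,
    vcf_out,
    regions: Sequence[RegionInfo],
    asdps: Sequence[Asdp],
    cfg: InferenceConfig = InferenceConfig(),
    ref_seqs: Mapping[str, str] | None = None,
    region_starts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Annotate a whole-genome VCF with per-region diplotype calls.

    For every region whose best alternate locus is inferred present,
    ASDP-associated variants receive FILTER ``ASDP_REGION`` plus INFO
    ``ASDPALT``/``REGIONGT``; every other variant inside a region gets
    ``REGIONGT``. Variants outside the regions pass through unchanged
    apart from the added header lines. Returns the per-region summary
    table (region_id, chosen_alt, call, n_R, n_A, n_shared, n_RV,
    hom_fraction, low_evidence).

    The set R of each region is restricted to the interval between the
    first and the last recorded alignment difference, reconstructed as
    the span of the region's candidate ASDP records.
    """
    by_region: dict[str, dict[str, list[Asdp]]] = {}
    for asdp in asdps:
        by_region.setdefault(asdp.region_id, {}).setdefault(asdp.alt_locus, []).append(
            asdp
        )

    with pysam.VariantFile(str(vcf_in)) as vin:
        header = vin.header.copy()
        for line in _ANNOTATE_HEADER_LINES:
            header.add_line(line)
        header_contigs = set(vin.header.contigs)
        if header_contigs:
            missing = [r.chrom for r in regions if r.chrom not in header_contigs]
            if missing:
                raise ValueError(
                    "VCF header lacks contigs for region chromosome(s): "
                    + ", ".join(sorted(set(missing)))
                )
        records = list(vin)

    # split records into per-ALT calls once, keeping the record index
    calls: list[tuple[int, VariantCall]] = []
    for idx, rec in enumerate(records):
        gt = rec.samples[0].get("GT") if rec.samples else None
        for i, alt in enumerate(rec.alts or (), start=1):
            if alt is None or alt in (".", "*"):
                continue
            from .io_formats import _genotype_from_gt

            genotype = _genotype_from_gt(gt, i) if gt is not None else MISSING
            calls.append(
                (
                    idx,
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=alt.upper(),
                        genotype=genotype,
                        qual=rec.qual,
                    ),
                )
            )

    trees: dict[str, intervaltree.IntervalTree] = {}
    region_by_id = {r.region_id: r for r in regions}
    for region in regions:
        trees.setdefault(region.chrom, intervaltree.IntervalTree()).addi(
            region.ref_start, region.ref_stop + 1, region.region_id
        )

    summary_rows = []
    record_filter: dict[int, str] = {}
    record_info: dict[int, dict[str, str]] = {}
    for region in regions:
        loci = by_region.get(region.region_id, {})
        if not loci:
            continue
        seq = ref_seqs.get(region.chrom) if ref_seqs else None
        seq_start = (region_starts or {}).get(region.chrom, 1)
        span = _asdp_span(
            (a for acc in loci.values() for a in acc), seq, seq_start
        )
        region_calls = [
            (idx, c)
            for idx, c in calls
            if c.chrom == region.chrom
            and span
            and span[0]
            <= normalize_variant(c.chrom, c.pos, c.ref_allele, c.alt_allele, seq, seq_start)[1]
            <= span[1]
        ]
        R = [c for _, c in region_calls]
        A_by_locus = {
            acc: [a for a in locus_asdps if a.high_confidence]
            for acc, locus_asdps in loci.items()
        }
        genotype = infer_region_genotype(R, A_by_locus, cfg, seq, seq_start)
        summary_rows.append(
            {
                "region_id": region.region_id,
                "chosen_alt": genotype.chosen_alt or ".",
                "call": genotype.call,
                "n_R": genotype.n_R,
                "n_A": genotype.n_A,
                "n_shared": genotype.n_shared,
                "n_RV": genotype.n_RV,
                "hom_fraction": (
                    round(genotype.hom_fraction, 4)
                    if genotype.hom_fraction is not None
                    else "."
                ),
                "low_evidence": genotype.low_evidence,
            }
        )
        # region-level INFO for all region-overlapping records
        for idx, rec in enumerate(records):
            if rec.chrom == region.chrom and region.ref_start <= rec.pos <= region.ref_stop:
                record_info.setdefault(idx, {})["REGIONGT"] = genotype.call
        if genotype.call in (ALT_HET, ALT_HOM) and genotype.chosen_alt is not None:
            filtered_A = [
                a
                for a in A_by_locus[genotype.chosen_alt]
                if cfg.include_sv or a.size_class == SMALL
            ]
            matched = match_variants_to_asdps(
                R, filtered_A, cfg.match_mode, seq, seq_start
            )
            matched_keys = {id(c) for c, _ in matched}
            for idx, c in region_calls:
                if id(c) in matched_keys:
                    record_filter[idx] = ASDP_REGION_FILTER
                    record_info.setdefault(idx, {})["ASDPALT"] = genotype.chosen_alt

    with pysam.VariantFile(str(vcf_out), "w", header=header) as vout:
        for idx, rec in enumerate(records):
            rec.translate(header)
            out = rec
            info = record_info.get(idx)
            if info:
                for key, value in info.items():
                    out.info[key] = value
            if idx in record_filter:
                out.filter.add(record_filter[idx])
            vout.write(out)

    return pd.DataFrame(
        summary_rows,
        columns=[
            "region_id",
            "chosen_alt",
            "call",
            "n_R",
            "n_A",
            "n_shared",
            "n_RV",
            "hom_fraction",
            "low_evidence",
        ],
    )
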