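"""Readers and writers for the external formats the pipeline touches.

Covers FASTA sequences, GFF3 alignment records carrying a ``Gap=``
attribute (the NCBI encoding of a gapped alignment as space-separated
M/I/D blocks), the alt-scaffold placement table, and VCF.

Coordinate convention: everything in memory is 0-based half-open;
1-based inclusive coordinates appear only at the VCF/TSV/GFF boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "GapBlock",
    "RegionInfo",
    "VariantCall",
    "AlignmentRecord",
    "GapParseError",
    "PlacementError",
    "VcfParseError",
    "parse_gap_attribute",
    "serialize_gap_blocks",
    "gap_blocks_span",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "load_alt_sequence",
    "read_alignment_gff",
    "write_alignment_gff",
    "read_region_placements",
    "write_region_placements",
    "read_vcf",
    "write_vcf",
    "HOM_ALT",
    "HET",
    "HOM_REF",
    "MISSING",
]


class GapParseError(ValueError):
    """Raised for a malformed Gap= alignment descriptor."""


class PlacementError(ValueError):
    """Raised for an invalid region placement table."""


class VcfParseError(ValueError):
    """Raised for a malformed VCF record."""


# genotype states of a variant call
HOM_ALT = "HOM_ALT"
HET = "HET"
HOM_REF = "HOM_REF"
MISSING = "MISSING"


@dataclass(frozen=True)
class GapBlock:
    """One M/I/D unit of an NCBI alignment descriptor.

    M spans both sequences (matches, possibly with mismatches, but no
    gaps); I is sequence present only in the alt scaffold; D is sequence
    present only in the reference.
    """

    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in ("M", "I", "D"):
            raise GapParseError(f"invalid alignment op {self.op!r}")
        if self.length < 1:
            raise GapParseError(f"non-positive block length {self.length}")

    def __str__(self) -> str:  # e.g. "M23343"
        return f"{self.op}{self.length}"


@dataclass
class RegionInfo:
    """Placement of one structurally variable region on the primary assembly.

    Coordinates are 1-based inclusive chromosome positions, as in the
    placement table. ``orientation`` maps each alt accession to '+' or '-'.
    """

    region_id: str
    chrom: str
    ref_start: int
    ref_stop: int
    alt_accessions: list[str] = field(default_factory=list)
    orientation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_stop:
            raise PlacementError(
                f"region {self.region_id}: ref_stop {self.ref_stop} < "
                f"ref_start {self.ref_start}"
            )
        if not self.alt_accessions:
            raise PlacementError(f"region {self.region_id}: no alt accessions")
        if len(set(self.alt_accessions)) != len(self.alt_accessions):
            raise PlacementError(
                f"region {self.region_id}: duplicate alt accession"
            )


@dataclass(frozen=True)
class VariantCall:
    """One called variant (one ALT allele) against the primary assembly."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotype: str = MISSING
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfParseError(f"position {self.pos} < 1")
        if not self.ref_allele or not self.alt_allele:
            raise VcfParseError("empty allele")
        if self.ref_allele == self.alt_allele:
            raise VcfParseError(
                f"REF and ALT alleles identical at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class AlignmentRecord:
    """One GFF3 alignment line between a chromosome segment and an alt scaffold.

    ``ref_start``/``ref_end`` and ``alt_start``/``alt_end`` are 0-based
    half-open after parsing. A target may have several alignment lines
    (a second line encodes an inversion); the reader preserves file order
    and leaves interpretation to the alignment-refinement stage.
    """

    ref_name: str
    ref_start: int
    ref_end: int
    alt_acc: str
    alt_start: int
    alt_end: int
    strand: str
    blocks: list[GapBlock]


# ---------------------------------------------------------------------------
# Gap= descriptors

_GAP_TOKEN = re.compile(r"^([A-Za-z])(\d+)$")


def parse_gap_attribute(text: str) -> list[GapBlock]:
    """Parse a ``Gap=`` alignment descriptor into an ordered block list.

    ``text`` must start with ``Gap=`` followed by whitespace-separated
    tokens, each a letter in {M, I, D} and a positive length, e.g.
    ``Gap=M23343 D19 M5``. A bare token list (without the prefix) is
    rejected.
    """
    if not text.startswith("Gap="):
        raise GapParseError(f"descriptor does not start with 'Gap=': {text[:20]!r}")
    body = text[len("Gap="):].strip()
    if not body:
        raise GapParseError("empty Gap= descriptor")
    blocks: list[GapBlock] = []
    for token in body.split():
        m = _GAP_TOKEN.match(token)
        if m is None:
            raise GapParseError(f"malformed Gap= token {token!r}")
        op, length = m.group(1), int(m.group(2))
        if op not in ("M", "I", "D"):
            raise GapParseError(f"invalid op letter in Gap= token {token!r}")
        if length < 1:
            raise GapParseError(f"non-positive length in Gap= token {token!r}")
        blocks.append(GapBlock(op, length))
    return blocks


def serialize_gap_blocks(blocks: Iterable[GapBlock]) -> str:
    """Inverse of :func:`parse_gap_attribute`."""
    return "Gap=" + " ".join(str(b) for b in blocks)


def gap_blocks_span(blocks: Iterable[GapBlock]) -> tuple[int, int]:
    """(reference span, alt span) in nucleotides covered by a block list.

    M advances both sequences, D the reference only, I the alt only.
    """
    ref = alt = 0
    for b in blocks:
        if b.op == "M":
            ref += b.length
            alt += b.length
        elif b.op == "D":
            ref += b.length
        else:
            alt += b.length
    return ref, alt


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA file into {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def load_alt_sequence(sequences: Mapping[str, str], acc: str, orientation: str) -> str:
    """Fetch an alt scaffold, reverse-complementing '-' placements.

    Downstream code then only ever sees forward-forward alignments.
    """
    seq = sequences[acc]
    if orientation == "-":
        return reverse_complement(seq)
    if orientation != "+":
        raise PlacementError(f"invalid orientation {orientation!r} for {acc}")
    return seq


# ---------------------------------------------------------------------------
# GFF3 alignment records

def read_alignment_gff(path) -> list[AlignmentRecord]:
    """Read GFF3 alignment lines with Target= and Gap= attributes.

    Column 1 is the chromosome (reference side), columns 4-5 its 1-based
    inclusive span; ``Target=<alt_acc> <start> <stop> [strand]`` gives the
    alt-scaffold span and ``Gap=`` the block descriptor. All alignment
    lines are returned in file order, one record per line.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise GapParseError(f"{path}:{lineno}: unparseable GFF line ({exc})")
            target = feat.attributes.get("Target")
            gap = feat.attributes.get("Gap")
            if not target:
                raise GapParseError(f"{path}:{lineno}: missing Target= attribute")
            tparts = target[0].split()
            if len(tparts) < 3:
                raise GapParseError(f"{path}:{lineno}: malformed Target= attribute")
            alt_acc, alt_start, alt_stop = tparts[0], int(tparts[1]), int(tparts[2])
            strand = tparts[3] if len(tparts) > 3 else (feat.strand or "+")
            if gap:
                blocks = parse_gap_attribute("Gap=" + " ".join(gap))
            else:
                # gapless alignment line: a single M block
                blocks = [GapBlock("M", feat.end - feat.start + 1)]
            records.append(
                AlignmentRecord(
                    ref_name=feat.seqid,
                    ref_start=feat.start - 1,
                    ref_end=feat.end,
                    alt_acc=alt_acc,
                    alt_start=alt_start - 1,
                    alt_end=alt_stop,
                    strand=strand,
                    blocks=blocks,
                )
            )
    return records


def write_alignment_gff(records: Sequence[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, rec in enumerate(records, start=1):
            gap = " ".join(str(b) for b in rec.blocks)
            attrs = (
                f"ID=aln{i};Target={rec.alt_acc} {rec.alt_start + 1} "
                f"{rec.alt_end} {rec.strand};Gap={gap}"
            )
            fh.write(
                "\t".join(
                    [
                        rec.ref_name,
                        "altloci",
                        "match",
                        str(rec.ref_start + 1),
                        str(rec.ref_end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Region placements

#: Default column mapping, modeled on the NCBI alt_scaffold_placement.txt
#: header names. Override any entry via the ``columns`` argument of
#: :func:`read_region_placements` to accommodate other layouts.
DEFAULT_PLACEMENT_COLUMNS = {
    "region_id": "region_name",
    "alt_acc": "alt_scaf_acc",
    "chrom": "parent_name",
    "ref_start": "parent_start",
    "ref_stop": "parent_stop",
    "orientation": "ori",
}


def read_region_placements(
    path, columns: Mapping[str, str] | None = None
) -> list[RegionInfo]:
    """Read the alt-scaffold placement table, grouping rows by region.

    One input row per alt scaffold; all rows of a region must agree on
    chromosome and reference span. Duplicate accessions within a region
    are an error.
    """
    colmap = dict(DEFAULT_PLACEMENT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    # NCBI headers start with '#'; normalise
    df.columns = [c.lstrip("#").strip() for c in df.columns]
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise PlacementError(f"placement table missing columns: {missing}")
    regions: dict[str, RegionInfo] = {}
    for _, row in df.iterrows():
        rid = row[colmap["region_id"]]
        acc = row[colmap["alt_acc"]]
        chrom = row[colmap["chrom"]]
        start = int(row[colmap["ref_start"]])
        stop = int(row[colmap["ref_stop"]])
        ori = row[colmap["orientation"]]
        if stop < start:
            raise PlacementError(
                f"region {rid}: parent_stop {stop} < parent_start {start}"
            )
        if rid in regions:
            info = regions[rid]
            if acc in info.alt_accessions:
                raise PlacementError(f"region {rid}: duplicate accession {acc}")
            if (info.chrom, info.ref_start, info.ref_stop) != (chrom, start, stop):
                raise PlacementError(
                    f"region {rid}: inconsistent placement across rows"
                )
            info.alt_accessions.append(acc)
            info.orientation[acc] = ori
        else:
            regions[rid] = RegionInfo(
                region_id=rid,
                chrom=chrom,
                ref_start=start,
                ref_stop=stop,
                alt_accessions=[acc],
                orientation={acc: ori},
            )
    return list(regions.values())


def write_region_placements(regions: Sequence[RegionInfo], path) -> None:
    rows = []
    for info in regions:
        for acc in info.alt_accessions:
            rows.append(
                {
                    "region_name": info.region_id,
                    "alt_scaf_acc": acc,
                    "parent_name": info.chrom,
                    "parent_start": info.ref_start,
                    "parent_stop": info.ref_stop,
                    "ori": info.orientation.get(acc, "+"),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

def _genotype_from_gt(gt: tuple, allele_index: int) -> str:
    called = [a for a in gt if a is not None]
    if not called:
        return MISSING
    hits = sum(1 for a in called if a == allele_index)
    if hits == len(called) and hits > 0:
        return HOM_ALT
    if hits > 0:
        return HET
    return HOM_REF


def read_vcf(path) -> list[VariantCall]:
    """Read a VCF into VariantCall records.

    Multi-allelic rows are split into one record per ALT allele before
    any downstream set logic; the GT subfield of the first sample (when
    present) supplies the genotype, interpreted per ALT allele.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None:
                continue
            gt = None
            if rec.samples:
                sample = rec.samples[0]
                gt = sample.get("GT")
            for i, alt in enumerate(rec.alts, start=1):
                if alt is None or alt in (".", "*"):
                    continue
                genotype = _genotype_from_gt(gt, i) if gt is not None else MISSING
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=alt.upper(),
                        genotype=genotype,
                        qual=rec.qual,
                    )
                )
    return calls


_GT_FIELDS = {HOM_ALT: "1/1", HET: "0/1", HOM_REF: "0/0", MISSING: "./."}


def make_vcf_header(
    contigs: Mapping[str, int] | Iterable[str],
    extra_lines: Iterable[str] = (),
    sample: str | None = "SAMPLE",
) -> pysam.VariantHeader:
    """Build a minimal VCF header declaring contigs, GT, and extra lines."""
    header = pysam.VariantHeader()
    if isinstance(contigs, Mapping):
        items = contigs.items()
    else:
        items = ((c, None) for c in contigs)
    for name, length in items:
        if length:
            header.add_line(f"##contig=<ID={name},length={length}>")
        else:
            header.add_line(f"##contig=<ID={name}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for line in extra_lines:
        header.add_line(line)
    if sample is not None:
        header.add_sample(sample)
    return header


def write_vcf(
    records: Sequence[VariantCall],
    header: pysam.VariantHeader,
    path,
    info: Sequence[Mapping[str, object]] | None = None,
) -> None:
    """Write VariantCall records as uncompressed VCF.

    ``info``, when given, supplies one INFO dict per record (parallel
    list). Records are written in (chrom, pos) sorted order.
    """
    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            call = records[i]
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref_allele),
                alleles=(call.ref_allele, call.alt_allele),
            )
            rec.qual = call.qual
            if info is not None:
                for key, value in info[i].items():
                    rec.info[key] = value
            if header.samples:
                gt = _GT_FIELDS[call.genotype]
                sep = "/"
                alleles = tuple(None if a == "." else int(a) for a in gt.split(sep))
                rec.samples[header.samples[0]]["GT"] = alleles
            out.write(rec)
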