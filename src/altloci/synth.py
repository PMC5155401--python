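"""Synthetic region pairs, alignment descriptors and sample VCFs.

Generates everything the pipeline consumes so it runs with no external
downloads: a primary-assembly region sequence, an alternate-locus
scaffold differing from it at planted events of known category and
size, the NCBI-style ``Gap=`` descriptor consistent with the pair, the
placement metadata, and a simulated whole-genome-style VCF under a
chosen diplotype with controllable false-negative and false-positive
noise.

Default event mix per region (9 SNVs, 1 insertion + 1 deletion of 1-8
nt, 1 block substitution of 2-5 nt over 5 kb, i.e. about 2.4 events/kb
and three quarters SNVs) emulates the divergence density and category
composition observed between GRCh38 primary-assembly regions and their
alternate loci.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .asdp_discovery import Asdp, classify_event
from .diplotype import ALT_HET, ALT_HOM, REF_HOM
from .io_formats import (
    HET,
    HOM_ALT,
    AlignmentRecord,
    GapBlock,
    RegionInfo,
    VariantCall,
    make_vcf_header,
    serialize_gap_blocks,
    write_alignment_gff,
    write_fasta,
    write_region_placements,
    write_vcf,
)

__all__ = ["SimSpec", "SyntheticRegion", "generate_region_pair", "simulate_sample_vcf", "write_bundle"]

_BASES = "ACGT"
_HOMOPOLYMER = re.compile(r"(.)\1{7,}")

#: identical anchor flank kept at each region end, nt
ANCHOR_FLANK = 200


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic region.

    ``min_event_spacing`` separates planted event start positions so
    each 50-column window of the refined alignment covers at most one
    event. ``fn_rate`` is the per-ASDP probability that the simulated
    caller misses the corresponding variant; ``fp_count`` is the exact
    number of spurious non-ASDP variants added inside the region.
    """

    rng_seed: int = 0
    region_length: int = 5000
    n_snv: int = 9
    n_small_indel: int = 2
    n_block_sub: int = 1
    n_sv: int = 0
    min_event_spacing: int = 60
    diplotype: str = ALT_HOM
    fn_rate: float = 0.0
    fp_count: int = 0
    anchor_flank: int = ANCHOR_FLANK
    region_id: str | None = None
    chrom: str | None = None
    alt_acc: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fn_rate <= 1:
            raise ValueError("fn_rate must be in [0, 1]")
        if self.diplotype not in (REF_HOM, ALT_HET, ALT_HOM):
            raise ValueError(f"unknown diplotype {self.diplotype!r}")


@dataclass
class SyntheticRegion:
    """Output bundle of :func:`generate_region_pair`."""

    ref_seq: str
    alt_seq: str
    blocks: list[GapBlock]
    region: RegionInfo
    truth: list[Asdp]

    @property
    def gap_descriptor(self) -> str:
        return serialize_gap_blocks(self.blocks)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform ACGT, rejecting long homopolymers and repeated 13-mers.

    The rejection step keeps the banded alignment optimum unique, which
    synthetic truth comparisons rely on.
    """
    for _ in range(50):
        seq = "".join(rng.choice(list(_BASES), size=length))
        if _HOMOPOLYMER.search(seq):
            continue
        kmers = {seq[i : i + 13] for i in range(length - 12)}
        if length >= 13 and len(kmers) < length - 12:
            continue
        return seq
    raise RuntimeError("could not generate a repeat-free background sequence")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(len(choices)))]


def _event_plan(spec: SimSpec, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Shuffled list of (kind, REF-side footprint, payload length) to plant.

    Small indels alternate insertion/deletion of 1-8 nt; block
    substitutions span 2-5 nt; SVs are indels of 60-120 nt.
    """
    plan: list[tuple[str, int, int]] = [("snv", 1, 1)] * spec.n_snv
    for i in range(spec.n_small_indel):
        length = int(rng.integers(1, 9))
        plan.append(("ins", 0, length) if i % 2 == 0 else ("del", length, length))
    for _ in range(spec.n_block_sub):
        length = int(rng.integers(2, 6))
        plan.append(("block", length, length))
    for i in range(spec.n_sv):
        length = int(rng.integers(60, 121))
        plan.append(("ins", 0, length) if i % 2 == 0 else ("del", length, length))
    order = rng.permutation(len(plan))
    return [plan[i] for i in order]


def generate_region_pair(spec: SimSpec) -> SyntheticRegion:
    """Build a REF/ALT region pair with planted, well-separated events.

    The alt sequence differs from the reference at exactly the planted
    events; the returned descriptor is a valid ``Gap=`` block list for
    the pair, and the truth list carries the left-aligned VCF
    representation, category and size class of every event. Everything
    is deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng([spec.rng_seed, 0])
    L = spec.region_length
    events = _event_plan(spec, rng)
    n = len(events)
    region_id = spec.region_id or f"REGION_{spec.rng_seed}"
    chrom = spec.chrom or f"chrS{spec.rng_seed}"
    alt_acc = spec.alt_acc or f"ALT_{spec.rng_seed}.1"

    ref_seq = _random_sequence(rng, L)
    region = RegionInfo(
        region_id=region_id,
        chrom=chrom,
        ref_start=1,
        ref_stop=L,
        alt_accessions=[alt_acc],
        orientation={alt_acc: "+"},
    )

    if n == 0:
        return SyntheticRegion(ref_seq, ref_seq, [GapBlock("M", L)], region, [])

    flank = spec.anchor_flank
    ref_footprint = sum(rl for _, rl, _ in events)
    slack = (L - 2 * flank) - n * spec.min_event_spacing - ref_footprint
    if slack < 0:
        raise ValueError(
            "events cannot be placed at the requested spacing within "
            f"region_length={L}"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    positions: list[int] = []
    consumed = 0
    for i, (_, ref_len, _) in enumerate(events):
        positions.append(flank + int(offsets[i]) + i * spec.min_event_spacing + consumed)
        consumed += ref_len

    alt_parts: list[str] = []
    blocks: list[GapBlock] = []
    truth: list[Asdp] = []
    cursor = 0

    def push_block(op: str, length: int) -> None:
        if length == 0:
            return
        if blocks and blocks[-1].op == op:
            blocks[-1] = GapBlock(op, blocks[-1].length + length)
        else:
            blocks.append(GapBlock(op, length))

    def add_truth(pos: int, ref_allele: str, alt_allele: str) -> None:
        category, size, size_class = classify_event(ref_allele, alt_allele)
        truth.append(
            Asdp(
                chrom=chrom,
                pos=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                category=category,
                event_size=size,
                size_class=size_class,
                alt_locus=alt_acc,
                region_id=region_id,
                high_confidence=size <= 10,
            )
        )

    for (kind, ref_len, payload), p in zip(events, positions):
        alt_parts.append(ref_seq[cursor:p])
        push_block("M", p - cursor)
        if kind == "snv":
            sub = _other_base(rng, ref_seq[p])
            alt_parts.append(sub)
            push_block("M", 1)
            add_truth(p + 1, ref_seq[p], sub)
            cursor = p + 1
        elif kind == "block":
            sub = "".join(_other_base(rng, b) for b in ref_seq[p : p + ref_len])
            alt_parts.append(sub)
            push_block("M", ref_len)
            add_truth(p + 1, ref_seq[p : p + ref_len], sub)
            cursor = p + ref_len
        elif kind == "ins":
            # insert after the anchor base at p; forbid end bases that would
            # let the event shift, so the planted representation is already
            # left-aligned
            anchor = ref_seq[p]
            following = ref_seq[p + 1]
            while True:
                ins = "".join(rng.choice(list(_BASES), size=payload))
                if ins[-1] != anchor and ins[0] != following:
                    break
            alt_parts.append(anchor)
            push_block("M", 1)
            alt_parts.append(ins)
            push_block("I", payload)
            add_truth(p + 1, anchor, anchor + ins)
            cursor = p + 1
        else:  # deletion of ref[p+1 : p+1+payload]
            anchor = ref_seq[p]
            deleted = ref_seq[p + 1 : p + 1 + payload]
            alt_parts.append(anchor)
            push_block("M", 1)
            push_block("D", payload)
            add_truth(p + 1, anchor + deleted, anchor)
            cursor = p + 1 + payload
    alt_parts.append(ref_seq[cursor:])
    push_block("M", L - cursor)
    alt_seq = "".join(alt_parts)

    # left-align indel truth records through any repeat context
    from .diplotype import normalize_variant

    for t in truth:
        _, pos, ref_allele, alt_allele = normalize_variant(
            t.chrom, t.pos, t.ref_allele, t.alt_allele, seq=ref_seq, seq_start=1
        )
        t.pos, t.ref_allele, t.alt_allele = pos, ref_allele, alt_allele
    truth.sort(key=lambda a: a.pos)
    return SyntheticRegion(ref_seq, alt_seq, blocks, region, truth)


def simulate_sample_vcf(
    truth: list[Asdp],
    region: RegionInfo,
    spec: SimSpec,
    ref_seq: str | None = None,
) -> tuple[list[VariantCall], str]:
    """Simulate the variant calls of one sample at one region.

    Under ALT_HOM every small truth ASDP becomes a homozygous call with
    probability ``1 - fn_rate`` (heterozygous under ALT_HET); REF_HOM
    samples carry no ASDP-associated calls. ``fp_count`` spurious
    heterozygous SNVs are added at positions away from any truth event.
    Deterministic given ``spec.rng_seed``; returns (calls, diplotype).
    """
    rng = np.random.default_rng([spec.rng_seed, 1])
    calls: list[VariantCall] = []
    if spec.diplotype in (ALT_HOM, ALT_HET):
        gt = HOM_ALT if spec.diplotype == ALT_HOM else HET
        for asdp in truth:
            if asdp.size_class != "SMALL":
                continue
            if rng.random() < spec.fn_rate:
                continue
            calls.append(
                VariantCall(
                    chrom=asdp.chrom,
                    pos=asdp.pos,
                    ref_allele=asdp.ref_allele,
                    alt_allele=asdp.alt_allele,
                    genotype=gt,
                    qual=100.0,
                )
            )
    taken = {c.pos for c in calls} | {a.pos for a in truth}
    guard = spec.min_event_spacing // 2
    placed = 0
    attempts = 0
    while placed < spec.fp_count and attempts < 10000:
        attempts += 1
        pos = int(rng.integers(region.ref_start + 1, region.ref_stop))
        if any(abs(pos - t) <= guard for t in taken):
            continue
        if ref_seq is not None:
            base = ref_seq[pos - region.ref_start]
        else:
            base = _BASES[int(rng.integers(4))]
        alt = _other_base(rng, base)
        calls.append(
            VariantCall(
                chrom=region.chrom,
                pos=pos,
                ref_allele=base,
                alt_allele=alt,
                genotype=HET,
                qual=60.0,
            )
        )
        taken.add(pos)
        placed += 1
    if placed < spec.fp_count:
        raise RuntimeError("could not place the requested spurious variants")
    calls.sort(key=lambda c: c.pos)
    return calls, spec.diplotype


def write_bundle(spec: SimSpec, outdir) -> dict[str, Path]:
    """Generate a region and write the full file bundle for the CLI.

    Writes reference + alt FASTA, the GFF3 alignment record, the
    placement TSV, the simulated sample VCF and a truth JSON, and
    returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = generate_region_pair(spec)
    region = sim.region
    acc = region.alt_accessions[0]
    paths = {
        "fasta": outdir / "sequences.fa",
        "gff": outdir / "alignments.gff3",
        "placements": outdir / "placements.tsv",
        "vcf": outdir / "sample.vcf",
        "truth": outdir / "truth.json",
    }
    write_fasta({region.chrom: sim.ref_seq, acc: sim.alt_seq}, paths["fasta"])
    write_alignment_gff(
        [
            AlignmentRecord(
                ref_name=region.chrom,
                ref_start=region.ref_start - 1,
                ref_end=region.ref_stop,
                alt_acc=acc,
                alt_start=0,
                alt_end=len(sim.alt_seq),
                strand="+",
                blocks=sim.blocks,
            )
        ],
        paths["gff"],
    )
    write_region_placements([region], paths["placements"])
    calls, diplotype = simulate_sample_vcf(sim.truth, region, spec, ref_seq=sim.ref_seq)
    header = make_vcf_header({region.chrom: region.ref_stop})
    write_vcf(calls, header, paths["vcf"])
    truth_payload = {
        "diplotype": diplotype,
        "region_id": region.region_id,
        "asdps": [
            {
                "chrom": a.chrom,
                "pos": a.pos,
                "ref": a.ref_allele,
                "alt": a.alt_allele,
                "category": a.category,
                "event_size": a.event_size,
                "size_class": a.size_class,
                "alt_locus": a.alt_locus,
            }
            for a in sim.truth
        ],
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=2) + "\n")
    return paths
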