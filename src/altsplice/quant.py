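"""Read counting, Ψ (percent spliced in) estimation and RPKM.

Ψ is the ratio of the density of inclusion reads to the sum of the densities
of inclusion and exclusion reads, where a density is reads per distinct
mappable read-start position.  A junction segment offers
``read_length - 2*min_overhang + 1`` start positions; an exon-body segment of
length L offers ``max(L - read_length + 1, 1)``.  This makes the long
(inclusion) and short (exclusion) signatures comparable.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .models import (
    EventReadCounts,
    ExpressionRecord,
    PsiEstimate,
    ReadPlacement,
    SpliceEvent,
)

__all__ = [
    "segment_positions",
    "count_event_reads",
    "estimate_psi",
    "tandem_utr_psi",
    "quantify_events",
    "compute_rpkm",
    "count_gene_reads",
    "expression_table",
]


def segment_positions(seg, read_length: int, min_overhang: int) -> int:
    """Distinct mappable read-start positions supporting one segment."""
    if seg.kind == "junction":
        return max(read_length - 2 * min_overhang + 1, 1)
    return max(seg.length - read_length + 1, 1)


def _side_positions(segments, read_length, min_overhang):
    return sum(segment_positions(s, read_length, min_overhang) for s in segments)


def count_event_reads(
    events: Sequence[SpliceEvent],
    placements: Iterable[ReadPlacement],
    read_length: int = 39,
    min_overhang: int = 4,
) -> dict[str, EventReadCounts]:
    """Assign read placements to event segments.

    A read supports an exon-body (or UTR-extension) segment when it is
    unspliced and lies entirely within the segment; it supports a junction
    when two consecutive blocks end/start exactly at the donor/acceptor with
    at least ``min_overhang`` aligned bases on each side.  A read is counted
    at most once per event side.  Reads on chromosomes without events are
    silently ignored.

    Containment of the whole read (rather than of any single block) keeps
    the density model self-consistent: an exon body of length L then offers
    exactly L - read_length + 1 observable start positions, and
    junction-spanning reads are credited through the junction rule alone.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")

    junction_index: dict[tuple[str, int, int], list[tuple[int, int]]] = defaultdict(list)
    body_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for ei, ev in enumerate(events):
        for side, segs in ((0, ev.iso1_segments), (1, ev.iso2_segments)):
            for seg in segs:
                if seg.kind == "junction":
                    junction_index[(ev.chrom, seg.start, seg.end)].append((ei, side))
                else:
                    body_trees[ev.chrom][seg.start:seg.end] = (ei, side, seg.start, seg.end)

    reads = [[0, 0] for _ in events]
    for r in placements:
        hits: set[tuple[int, int]] = set()
        blocks = r.blocks
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if (e1 - s1) >= min_overhang and (e2 - s2) >= min_overhang:
                hits.update(junction_index.get((r.chrom, e1, s2), ()))
        if len(blocks) == 1:
            tree = body_trees.get(r.chrom)
            if tree is not None:
                bs, be = blocks[0]
                for iv in tree.overlap(bs, be):
                    ei, side, ss, se = iv.data
                    if ss <= bs and be <= se:
                        hits.add((ei, side))
        for ei, side in hits:
            reads[ei][side] += 1

    out = {}
    for ei, ev in enumerate(events):
        out[ev.event_id] = EventReadCounts(
            event_id=ev.event_id,
            inc_reads=reads[ei][0],
            exc_reads=reads[ei][1],
            inc_positions=_side_positions(ev.iso1_segments, read_length, min_overhang),
            exc_positions=_side_positions(ev.iso2_segments, read_length, min_overhang),
        )
    return out


def estimate_psi(counts: EventReadCounts) -> PsiEstimate:
    """Ψ from inclusion/exclusion read densities.

    Ψ is undefined (None) — not 0 — when no read supports either isoform.
    """
    if counts.inc_positions <= 0 or counts.exc_positions <= 0:
        raise ValueError(f"event {counts.event_id} has a zero position count")
    inc_d = counts.inc_reads / counts.inc_positions
    exc_d = counts.exc_reads / counts.exc_positions
    if counts.inc_reads + counts.exc_reads == 0:
        psi = None
    else:
        psi = inc_d / (inc_d + exc_d)
    return PsiEstimate(counts.event_id, psi, inc_d, exc_d)


def tandem_utr_psi(
    core: tuple[int, int], extension: tuple[int, int], event_id: str = ""
) -> PsiEstimate:
    """Ψ for tandem 3' UTR events: density(extension) / density(core).

    ``core``/``extension`` are (reads, positions) pairs.  The ratio is the
    fraction of transcripts reading through to the distal site, clamped to
    [0, 1]; undefined when the core region has zero density.
    """
    core_reads, core_pos = core
    ext_reads, ext_pos = extension
    if core_pos <= 0 or ext_pos <= 0:
        raise ValueError("position counts must be positive")
    core_d = core_reads / core_pos
    ext_d = ext_reads / ext_pos
    if core_d == 0:
        return PsiEstimate(event_id, None, ext_d, core_d)
    return PsiEstimate(event_id, min(max(ext_d / core_d, 0.0), 1.0), ext_d, core_d)


def quantify_events(
    events: Sequence[SpliceEvent],
    placements: Iterable[ReadPlacement],
    read_length: int = 39,
    min_overhang: int = 4,
) -> tuple[dict[str, EventReadCounts], dict[str, PsiEstimate]]:
    """Count reads and estimate Ψ for a catalog in one pass.

    Tandem-UTR events use the core/extension density-ratio variant; all other
    types use the inclusion/exclusion density ratio.
    """
    counts = count_event_reads(events, placements, read_length, min_overhang)
    by_id = {ev.event_id: ev for ev in events}
    psis = {}
    for eid, c in counts.items():
        if by_id[eid].event_type == "TandemUTR":
            psis[eid] = tandem_utr_psi(
                core=(c.exc_reads, c.exc_positions),
                extension=(c.inc_reads, c.inc_positions),
                event_id=eid,
            )
        else:
            psis[eid] = estimate_psi(c)
    return counts, psis


# ---------------------------------------------------------------------------
# gene expression

def compute_rpkm(read_count: int, constitutive_length: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of (constitutive) exon model per million mapped reads."""
    if constitutive_length <= 0:
        raise ValueError("constitutive_length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return read_count / (constitutive_length / 1e3) / (total_mapped_reads / 1e6)


def count_gene_reads(
    constitutive: Mapping[str, tuple[str, Sequence[tuple[int, int]]]],
    placements: Iterable[ReadPlacement],
) -> dict[str, int]:
    """Count reads mapped to the constitutive exons of each gene.

    ``constitutive`` maps gene_id -> (chrom, intervals).  A read counts for a
    gene when any of its blocks lies entirely within one of the gene's
    constitutive exons; it is counted once per gene.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gid, (chrom, ivs) in constitutive.items():
        for (s, e) in ivs:
            trees[chrom][s:e] = (gid, s, e)
    counts: dict[str, int] = {g: 0 for g in constitutive}
    for r in placements:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        genes = set()
        for (bs, be) in r.blocks:
            for iv in tree.overlap(bs, be):
                gid, s, e = iv.data
                if s <= bs and be <= e:
                    genes.add(gid)
        for g in genes:
            counts[g] += 1
    return counts


def expression_table(
    gene_counts: Mapping[str, int],
    constitutive_lengths: Mapping[str, int],
    total_mapped_reads: int,
) -> dict[str, ExpressionRecord]:
    out = {}
    for gid, c in gene_counts.items():
        L = constitutive_lengths[gid]
        out[gid] = ExpressionRecord(
            gene_id=gid,
            constitutive_length=L,
            read_count=c,
            rpkm=compute_rpkm(c, L, total_mapped_reads),
        )
    return out
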