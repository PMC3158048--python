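"""Readers and writers for the standard formats the pipeline touches.

GTF writing uses the 1-based inclusive convention; BED uses 0-based
half-open, matching the internal coordinate system.  SAM placements are read
through pysam (split reads from N CIGAR operations; secondary and
supplementary alignments skipped).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .models import ReadPlacement, Segment, SpliceEvent, TranscriptModel

__all__ = [
    "write_gtf",
    "write_fasta",
    "read_bed12",
    "write_bed12",
    "read_sam",
    "read_bed6",
    "write_event_catalog",
    "read_event_catalog",
    "write_events_gff3",
]


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "altsplice") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            s, e = t.span
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for (es, ee) in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{es + 1}\t{ee}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# read placements

def read_bed12(path: str | Path) -> list[ReadPlacement]:
    """Read BED12 read placements; blocks give the aligned intervals."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {ln} is not BED12")
            chrom, start = f[0], int(f[1])
            strand = f[5] if f[5] in "+-" else None
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            out.append(ReadPlacement(chrom=chrom, blocks=blocks, strand=strand))
    return out


def write_bed12(placements: Iterable[ReadPlacement], path: str | Path,
                name_prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(placements):
            start, end = r.blocks[0][0], r.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            offs = ",".join(str(s - start) for s, _ in r.blocks)
            strand = r.strand or "+"
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{name_prefix}{i}\t0\t{strand}\t"
                f"{start}\t{end}\t0\t{len(r.blocks)}\t{sizes}\t{offs}\n"
            )


def read_sam(path: str | Path) -> list[ReadPlacement]:
    """Read placements from SAM/BAM; split reads from N CIGAR operations."""
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            blocks = []
            pos = aln.reference_start
            for op, length in aln.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X consume both
                    if blocks and blocks[-1][1] == pos:
                        blocks[-1] = (blocks[-1][0], pos + length)
                    else:
                        blocks.append((pos, pos + length))
                    pos += length
                elif op in (2, 3):  # D, N consume reference
                    pos += length
                # I, S, H, P consume no reference
            if blocks:
                strand = "-" if aln.is_reverse else "+"
                out.append(ReadPlacement(chrom=aln.reference_name,
                                         blocks=tuple(blocks), strand=strand))
    return out


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals (e.g. CLIP clusters): (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            out.append((f[0], int(f[1]), int(f[2]), name))
    return out


# ---------------------------------------------------------------------------
# event catalog

def _segments_to_str(segs: frozenset[Segment]) -> str:
    return ";".join(f"{s.kind}:{s.start}-{s.end}" for s in sorted(segs))


def _segments_from_str(text: str) -> frozenset[Segment]:
    out = []
    for part in text.split(";"):
        kind, iv = part.split(":")
        s, e = iv.split("-")
        out.append(Segment(kind, int(s), int(e)))
    return frozenset(out)


def write_event_catalog(events: Iterable[SpliceEvent], path: str | Path) -> None:
    """Write the event catalog as TSV with BED12-like block notation."""
    cols = ["event_id", "event_type", "gene_id", "chrom", "strand",
            "iso1_segments", "iso2_segments", "flanking_exons"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ev in events:
            flanks = ";".join(f"{s}-{e}" for s, e in ev.flanking_exons)
            fh.write("\t".join([
                ev.event_id, ev.event_type, ev.gene_id, ev.chrom, ev.strand,
                _segments_to_str(ev.iso1_segments),
                _segments_to_str(ev.iso2_segments),
                flanks,
            ]) + "\n")


def read_event_catalog(path: str | Path) -> list[SpliceEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            flanks = tuple(
                tuple(int(x) for x in part.split("-"))
                for part in f[idx["flanking_exons"]].split(";") if part
            )
            events.append(SpliceEvent(
                event_id=f[idx["event_id"]],
                event_type=f[idx["event_type"]],
                gene_id=f[idx["gene_id"]],
                chrom=f[idx["chrom"]],
                strand=f[idx["strand"]],
                iso1_segments=_segments_from_str(f[idx["iso1_segments"]]),
                iso2_segments=_segments_from_str(f[idx["iso2_segments"]]),
                flanking_exons=flanks,
            ))
    return events


def write_events_gff3(events: Iterable[SpliceEvent], path: str | Path) -> None:
    """Browser-friendly GFF3 rendering of an event catalog."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ev in events:
            s, e = ev.span
            fh.write(
                f"{ev.chrom}\taltsplice\tsplice_event\t{s + 1}\t{e}\t.\t{ev.strand}\t.\t"
                f"ID={ev.event_id};event_type={ev.event_type};gene_id={ev.gene_id}\n"
            )
            for iso, segs in (("iso1", ev.iso1_segments), ("iso2", ev.iso2_segments)):
                for seg in sorted(segs):
                    fh.write(
                        f"{ev.chrom}\taltsplice\t{seg.kind}\t{seg.start + 1}\t{seg.end}\t.\t"
                        f"{ev.strand}\t.\tParent={ev.event_id};isoform={iso}\n"
                    )
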