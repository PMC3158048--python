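"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open throughout the package; GTF/GFF I/O
converts from/to the 1-based inclusive convention at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS", "AFE", "ALE", "TandemUTR")

#: segment kinds used to unify "inclusion reads" / "exclusion reads" across
#: all eight event types
SEGMENT_KINDS = ("exon_body", "junction", "utr_extension")


@dataclass(frozen=True, order=True)
class Segment:
    """A countable piece of isoform evidence.

    For ``exon_body`` / ``utr_extension`` the (start, end) interval is genomic
    exonic sequence; for ``junction`` start is the donor coordinate (end of the
    left exon) and end is the acceptor (start of the right exon) on the
    genomic axis, so start < end always.
    """

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.start >= self.end:
            raise ValueError(
                f"{self.kind} segment requires start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One annotated transcript: an ordered chain of exons on one strand."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s, e) in exons:
            if s >= e:
                raise ValueError(f"empty exon [{s}, {e}) in {self.transcript_id}")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {self.transcript_id}")
        self.exons = exons

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junctions(self) -> set[tuple[int, int]]:
        return {(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])}


@dataclass(frozen=True)
class SpliceEvent:
    """An alternative-isoform event with two disjoint segment signatures.

    ``iso1_segments`` is the inclusion signature (the longer / included form:
    for a skipped exon, the exon body plus its two flanking junctions);
    ``iso2_segments`` is the exclusion signature (the skipping junction).
    """

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    iso1_segments: frozenset[Segment]
    iso2_segments: frozenset[Segment]
    flanking_exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.iso1_segments & self.iso2_segments:
            raise ValueError(f"iso1/iso2 signatures share a segment in {self.event_id}")

    @property
    def span(self) -> tuple[int, int]:
        segs = self.iso1_segments | self.iso2_segments
        return min(s.start for s in segs), max(s.end for s in segs)


@dataclass
class ReadPlacement:
    """An aligned read as a chain of genomic blocks (split reads have >= 2)."""

    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        blocks = tuple(tuple(b) for b in self.blocks)
        for (s, e) in blocks:
            if s >= e:
                raise ValueError("empty read block")
        for (_, e1), (s2, _) in zip(blocks, blocks[1:]):
            if s2 <= e1:
                raise ValueError("read blocks must be ordered and non-overlapping")
        self.blocks = blocks

    @property
    def read_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class EventReadCounts:
    """Inclusion/exclusion read counts and mappable start-position counts."""

    event_id: str
    inc_reads: int
    exc_reads: int
    inc_positions: int
    exc_positions: int

    def __post_init__(self) -> None:
        if min(self.inc_reads, self.exc_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if min(self.inc_positions, self.exc_positions) < 1:
            raise ValueError("position counts must be >= 1")


@dataclass
class PsiEstimate:
    """Percent-spliced-in estimate from inclusion/exclusion read densities.

    ``psi`` is None (undefined) when neither isoform is supported by any
    read; undefined events are excluded from downstream testing.
    """

    event_id: str
    psi: Optional[float]
    inc_density: float
    exc_density: float


@dataclass
class ExpressionRecord:
    gene_id: str
    constitutive_length: int
    read_count: int
    rpkm: float


@dataclass
class DiffExprRecord:
    gene_id: str
    count_1: int
    count_2: int
    n1: int
    n2: int
    fold_change: float  # RPKM ratio, condition2 / condition1
    p_ac: float
    fdr: float = float("nan")
    significant: bool = False

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1 else "down"


@dataclass
class DiffSpliceRecord:
    event_id: str
    psi_1: float
    psi_2: float
    delta_psi: float  # psi_2 - psi_1 (mesenchymal minus epithelial)
    p: float
    fdr: float = float("nan")

    @property
    def direction(self) -> str:
        """Inclusion direction label: which condition favours inclusion."""
        return "condition1-inclusion" if self.delta_psi < 0 else "condition2-inclusion"


#: region keys of the four 250-nt intronic flanks of a skipped exon,
#: transcript-oriented: I5 abuts the donor, I3 the acceptor of its intron
FLANK_KEYS = (
    ("upstream_intron", "I5"),
    ("upstream_intron", "I3"),
    ("downstream_intron", "I5"),
    ("downstream_intron", "I3"),
)


@dataclass
class FlankRegionSet:
    """The four flanking intronic sequences of one skipped-exon event (RNA)."""

    event_id: str
    regions: Mapping[tuple[str, str], str]


@dataclass
class PentamerEnrichment:
    region: tuple[str, str]
    pentamer: str
    fg_count: int
    fg_rate: float
    bg_rate: float
    expected_fg: float
    p_hyper: float
    fdr: float
    family: str


@dataclass
class SignaturePanel:
    """Events x samples inclusion-measure matrix with optional class labels."""

    values: pd.DataFrame  # rows = events, columns = samples, NaN = missing
    labels: Optional[Mapping[str, str]] = None  # sample -> class label
    measure: str = "psi"  # psi | splicing_index | qpcr_ratio
    normalization: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().all(axis=1).any():
            raise ValueError("panel contains an all-missing event row")


@dataclass
class ClusterReport:
    linkage: "object"  # scipy linkage matrix
    assignments: Mapping[str, int]  # sample -> cluster (1 or 2) at the top split
    misclassified: Optional[int] = None
    p_value: Optional[float] = None


@dataclass
class CoherenceResult:
    n_compared: int
    n_coherent: int

    @property
    def fraction(self) -> float:
        return self.n_coherent / self.n_compared
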