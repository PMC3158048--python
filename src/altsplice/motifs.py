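"""Pentamer enrichment in the intronic flanks of regulated skipped exons,
motif-family annotation, and overlap enrichment against CLIP clusters.

Each skipped exon contributes four flanking intronic regions of up to 250 nt,
keyed (upstream_intron|downstream_intron, I5|I3) in transcript orientation:
I5 abuts the donor and I3 the acceptor of its intron.  Enrichment of each
5-mer in a foreground (regulated) set over a background (unchanged) set is
assessed with a hypergeometric upper tail where the population is the pooled
foreground+background window count, followed by BH FDR within each region
class.  All overlapping occurrences count (sliding window, step 1).
"""
from __future__ import annotations

import re
from collections import Counter
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .diff import benjamini_hochberg
from .models import FLANK_KEYS, FlankRegionSet, PentamerEnrichment, SpliceEvent

__all__ = [
    "extract_flanks",
    "pentamer_enrichment",
    "annotate_family",
    "load_family_table",
    "overlap_enrichment",
    "events_overlapping_clusters",
    "select_foreground",
    "select_background",
]

_COMP = str.maketrans("ACGTUN", "TGCAAN")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _se_geometry(event: SpliceEvent) -> tuple[tuple[int, int], tuple[int, int]]:
    """Genomic (left_intron, right_intron) of a skipped-exon event."""
    if event.event_type != "SE":
        raise ValueError(f"flank extraction requires an SE event, got {event.event_type}")
    alt = next(s for s in event.iso1_segments if s.kind == "exon_body")
    skip = next(s for s in event.iso2_segments if s.kind == "junction")
    return (skip.start, alt.start), (alt.end, skip.end)


def extract_flanks(event: SpliceEvent, genome, width: int = 250) -> FlankRegionSet:
    """The four flanking intronic sequences of a skipped exon, as RNA.

    ``genome`` is a mapping from chromosome name to sequence (e.g. a
    ``pyfaidx.Fasta``).  Regions are clipped to intron boundaries; when an
    intron is shorter than 2*width, I5 and I3 are truncated at the midpoint
    (I5 takes the extra base of an odd-length intron) so they never overlap.
    Minus-strand sequences are reverse-complemented.
    """
    try:
        chrom_seq = genome[event.chrom]
    except KeyError as exc:
        raise ValueError(f"chromosome {event.chrom} not in genome") from exc
    left, right = _se_geometry(event)
    if event.strand == "+":
        up_intron, down_intron = left, right
    else:
        up_intron, down_intron = right, left

    def fetch(s, e):
        seq = chrom_seq[s:e]
        return str(getattr(seq, "seq", seq)).upper()

    regions = {}
    for label, (s, e) in (("upstream_intron", up_intron), ("downstream_intron", down_intron)):
        L = e - s
        w5 = min(width, (L + 1) // 2)
        w3 = min(width, L - w5) if L < 2 * width else width
        if event.strand == "+":
            i5 = fetch(s, s + w5)
            i3 = fetch(e - w3, e)
        else:
            i5 = _revcomp_dna(fetch(e - w5, e))
            i3 = _revcomp_dna(fetch(s, s + w3))
        regions[(label, "I5")] = _rna(i5)
        regions[(label, "I3")] = _rna(i3)
    return FlankRegionSet(event_id=event.event_id, regions=regions)


# ---------------------------------------------------------------------------
# pentamer counting and enrichment

def _count_kmers(seqs: Iterable[str], k: int = 5) -> tuple[Counter, int]:
    """All overlapping k-mer occurrences and the total window count.

    Windows containing non-ACGU characters (e.g. N) are skipped and do not
    count towards the window total.
    """
    counts: Counter = Counter()
    windows = 0
    valid = frozenset("ACGU")
    for seq in seqs:
        for i in range(max(len(seq) - k + 1, 0)):
            w = seq[i:i + k]
            if set(w) <= valid:
                counts[w] += 1
                windows += 1
    return counts, windows


def pentamer_enrichment(
    fg: Sequence[FlankRegionSet],
    bg: Sequence[FlankRegionSet],
    k: int = 5,
    family_table: Optional[Sequence[tuple[str, "re.Pattern"]]] = None,
) -> list[PentamerEnrichment]:
    """Hypergeometric pentamer enrichment of foreground over background.

    Per region class and per k-mer: population = all fg+bg windows, successes
    = fg+bg occurrences of the k-mer, draws = fg windows, observed = fg
    occurrences; p is the upper tail P(X >= observed).  BH FDR is applied
    within each region class over the k-mers observed in either set.
    """
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    overlap_ids = {f.event_id for f in fg} & {b.event_id for b in bg}
    if overlap_ids:
        raise ValueError(f"foreground and background share events: {sorted(overlap_ids)[:3]}")
    if family_table is None:
        family_table = load_family_table()

    results: list[PentamerEnrichment] = []
    for region in FLANK_KEYS:
        fg_counts, fg_windows = _count_kmers(
            (f.regions[region] for f in fg if region in f.regions), k)
        bg_counts, bg_windows = _count_kmers(
            (b.regions[region] for b in bg if region in b.regions), k)
        if fg_windows == 0 or bg_windows == 0:
            continue
        words = sorted(set(fg_counts) | set(bg_counts))
        M = fg_windows + bg_windows
        block = []
        for w in words:
            kf = fg_counts.get(w, 0)
            kt = kf + bg_counts.get(w, 0)
            p = float(hypergeom.sf(kf - 1, M, kt, fg_windows))
            bg_rate = bg_counts.get(w, 0) / bg_windows
            block.append(PentamerEnrichment(
                region=region, pentamer=w,
                fg_count=kf, fg_rate=kf / fg_windows,
                bg_rate=bg_rate, expected_fg=bg_rate * fg_windows,
                p_hyper=min(p, 1.0), fdr=float("nan"),
                family=annotate_family(w, family_table),
            ))
        fdr = benjamini_hochberg([b.p_hyper for b in block])
        for rec, q in zip(block, fdr):
            rec.fdr = float(q)
        results.extend(block)
    return results


def load_family_table() -> list[tuple[str, "re.Pattern"]]:
    """The versioned motif-family pattern table shipped as package data."""
    text = resources.files("altsplice").joinpath("data/motif_families.tsv").read_text()
    table = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("family\t"):
            continue
        family, pattern = line.split("\t")
        table.append((family, re.compile(pattern)))
    return table


def annotate_family(pentamer: str, family_table=None) -> str:
    """Label a pentamer with its splicing-factor motif family ('Other' if none).

    Matching follows the precedence order of the family table (first match
    wins), e.g. GCAUG -> RBFOX, GGGGA -> hnRNP F/H.
    """
    if not set(pentamer) <= set("ACGU"):
        raise ValueError(f"pentamer must be RNA (ACGU), got {pentamer!r}")
    if family_table is None:
        family_table = load_family_table()
    for family, pattern in family_table:
        if pattern.search(pentamer):
            return family
    return "Other"


# ---------------------------------------------------------------------------
# CLIP-cluster overlap

def overlap_enrichment(
    fg_ids: Iterable[str],
    flagged_ids: Iterable[str],
    universe_ids: Iterable[str],
) -> float:
    """Hypergeometric upper-tail p for the overlap of a foreground event set
    with a flagged (e.g. CLIP-cluster-bearing) event set within a universe."""
    universe = set(universe_ids)
    fg = set(fg_ids)
    flagged = set(flagged_ids)
    if not fg <= universe:
        raise ValueError("foreground must be a subset of the universe")
    if not flagged <= universe:
        raise ValueError("flagged set must be a subset of the universe")
    k = len(fg & flagged)
    return float(hypergeom.sf(k - 1, len(universe), len(flagged), len(fg)))


def events_overlapping_clusters(
    events: Sequence[SpliceEvent],
    clusters: Sequence[tuple[str, int, int, str]],
    window: int = 0,
) -> set[str]:
    """Event ids whose span (introns + alternative exon, +/- window) overlaps
    any cluster interval (e.g. BED6 CLIP clusters from ``io.read_bed6``)."""
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, _name in clusters:
        trees.setdefault(chrom, IntervalTree())[s:e] = True
    hit = set()
    for ev in events:
        tree = trees.get(ev.chrom)
        if tree is None:
            continue
        s, e = ev.span
        if tree.overlap(s - window, e + window):
            hit.add(ev.event_id)
    return hit


# ---------------------------------------------------------------------------
# foreground/background selection from differential-splicing records

def select_foreground(records, direction: str = "both",
                      min_dpsi: float = 0.10, max_fdr: float = 0.05) -> list:
    """Regulated events: FDR <= max_fdr and ΔΨ passing the directional cut.

    direction 'up' keeps ΔΨ >= min_dpsi, 'down' keeps ΔΨ <= -min_dpsi,
    'both' keeps |ΔΨ| >= min_dpsi.
    """
    out = []
    for r in records:
        if r.fdr > max_fdr:
            continue
        if direction == "up" and r.delta_psi >= min_dpsi:
            out.append(r)
        elif direction == "down" and r.delta_psi <= -min_dpsi:
            out.append(r)
        elif direction == "both" and abs(r.delta_psi) >= min_dpsi:
            out.append(r)
    return out


def select_background(records, min_fdr: float = 0.5,
                      max_abs_dpsi: float = 0.05) -> list:
    """Unchanged events: FDR > min_fdr and |ΔΨ| < max_abs_dpsi, both
    isoforms detected (records exist only for such events)."""
    return [r for r in records
            if r.fdr > min_fdr and abs(r.delta_psi) < max_abs_dpsi]
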