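"""Derive alternative-isoform events from transcript annotation.

Eight event types are recognised: skipped exons (SE), retained introns (RI),
mutually exclusive exons (MXE), alternative 5'/3' splice sites (A5SS/A3SS),
alternative first/last exons (AFE/ALE) and tandem 3' UTRs.  Each event
carries two disjoint segment signatures (inclusion = iso1, exclusion = iso2)
that unify read counting across types.

Classification precedence within a transcript pair is
RI > MXE > SE > A5SS/A3SS > AFE/ALE > TandemUTR; a lower-precedence candidate
that would re-claim a segment already assigned within the same pair is
suppressed.  "Upstream/downstream" and "5'/3'" are transcript-oriented, so
minus-strand events mirror genomic order.
"""
from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .models import Segment, SpliceEvent, TranscriptModel

__all__ = [
    "load_annotation",
    "derive_events",
    "constitutive_exons",
    "group_by_gene",
]


# ---------------------------------------------------------------------------
# annotation loading

def load_annotation(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF or GFF3 file into transcript models.

    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention.  Exons must carry gene and transcript identifiers
    (GTF attributes, or GFF3 Parent chains).  Transcript features without
    exons are rejected with a warning.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"failed to parse annotation {path.name}: {exc}") from exc

    def _attr(feat, key):
        vals = feat.attributes.get(key)
        return vals[0] if vals else None

    exons: dict[str, list] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    for f in db.features_of_type("exon"):
        tid = _attr(f, "transcript_id")
        gid = _attr(f, "gene_id")
        if tid is None:  # GFF3: resolve through Parent transcript
            parent = _attr(f, "Parent")
            if parent is None:
                raise ValueError(f"exon without transcript identifier at {f.seqid}:{f.start}")
            tid = parent
            if gid is None:
                try:
                    tfeat = db[parent]
                    gid = _attr(tfeat, "gene_id") or _attr(tfeat, "Parent")
                except gffutils.FeatureNotFoundError:
                    gid = None
        if gid is None:
            gid = tid
        exons[tid].append((f.start - 1, f.end))
        meta[tid] = (gid, f.seqid, f.strand)

    # transcript features with no exon children -> rejected with warning
    for f in itertools.chain(
        db.features_of_type("transcript"), db.features_of_type("mRNA")
    ):
        tid = _attr(f, "transcript_id") or f.id
        if tid not in exons:
            warnings.warn(f"transcript {tid} has zero exons; skipped")

    models = []
    for tid, ex in exons.items():
        gid, chrom, strand = meta[tid]
        models.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(ex)),
            )
        )
    models.sort(key=lambda t: (t.chrom, t.span[0], t.transcript_id))
    return models


def group_by_gene(transcripts: Iterable[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        genes[t.gene_id].append(t)
    return dict(genes)


# ---------------------------------------------------------------------------
# event derivation

def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _event_id(etype: str, chrom: str, strand: str, segments: Iterable[Segment]) -> str:
    coords = ",".join(
        f"{s.kind[0]}{s.start}-{s.end}" for s in sorted(segments)
    )
    return f"{etype}:{chrom}:{strand}:{coords}"


def _make_event(etype, gene_id, chrom, strand, iso1, iso2, flanks=()):
    iso1 = frozenset(iso1)
    iso2 = frozenset(iso2)
    return SpliceEvent(
        event_id=_event_id(etype, chrom, strand, iso1 | iso2),
        event_type=etype,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        iso1_segments=iso1,
        iso2_segments=iso2,
        flanking_exons=tuple(flanks),
    )


def _pair_events(gene_id: str, chrom: str, strand: str,
                 A: Sequence[tuple[int, int]], B: Sequence[tuple[int, int]]):
    """Yield events induced by one transcript pair, applying precedence."""
    out: list[SpliceEvent] = []
    claimed: set[Segment] = set()

    def emit(ev: SpliceEvent) -> None:
        segs = ev.iso1_segments | ev.iso2_segments
        if segs & claimed:
            return
        claimed.update(segs)
        out.append(ev)

    Aset, Bset = set(A), set(B)
    Ajunc = {(a[1], b[0]) for a, b in zip(A, A[1:])}
    Bjunc = {(a[1], b[0]) for a, b in zip(B, B[1:])}
    body = lambda iv: Segment("exon_body", iv[0], iv[1])
    junc = lambda d, a: Segment("junction", d, a)

    # --- RI: one transcript retains a single intron spliced in the other
    for X, Y in ((A, B), (B, A)):
        Xset = set(X)
        for i in range(len(Y) - 1):
            u, v = Y[i], Y[i + 1]
            if (u[0], v[1]) in Xset:
                intron = (u[1], v[0])
                emit(_make_event("RI", gene_id, chrom, strand,
                                 iso1=[body(intron)],
                                 iso2=[junc(*intron)],
                                 flanks=(u, v)))

    # --- MXE: two internal exons each included exclusively with shared flanks
    for i in range(1, len(A) - 1):
        for j in range(1, len(B) - 1):
            x, y = A[i], B[j]
            if x == y or x in Bset or y in Aset or _overlap(x, y):
                continue
            if A[i - 1][1] == B[j - 1][1] and A[i + 1][0] == B[j + 1][0]:
                d, a = A[i - 1][1], A[i + 1][0]
                # exon1 = transcript-upstream alternative exon
                first, second = sorted((x, y))
                if strand == "-":
                    first, second = second, first
                emit(_make_event("MXE", gene_id, chrom, strand,
                                 iso1=[body(first), junc(d, first[0]), junc(first[1], a)],
                                 iso2=[body(second), junc(d, second[0]), junc(second[1], a)],
                                 flanks=(A[i - 1], A[i + 1])))

    # --- SE: internal exon present in one transcript, flanks joined in the other
    for X, Y, Yj in ((A, B, Bjunc), (B, A, Ajunc)):
        Yset = set(Y)
        for i in range(1, len(X) - 1):
            x = X[i]
            if x in Yset:
                continue
            d, a = X[i - 1][1], X[i + 1][0]
            if (d, a) in Yj:
                emit(_make_event("SE", gene_id, chrom, strand,
                                 iso1=[body(x), junc(d, x[0]), junc(x[1], a)],
                                 iso2=[junc(d, a)],
                                 flanks=(X[i - 1], X[i + 1])))

    # --- A5SS / A3SS: overlapping exons sharing a splice partner on one side
    nextjA = {a[1]: b[0] for a, b in zip(A, A[1:])}
    nextjB = {a[1]: b[0] for a, b in zip(B, B[1:])}
    prevjA = {b[0]: a[1] for a, b in zip(A, A[1:])}
    prevjB = {b[0]: a[1] for a, b in zip(B, B[1:])}
    for a_ex in A:
        for b_ex in B:
            if a_ex == b_ex or not _overlap(a_ex, b_ex):
                continue
            # donor side (genomic right) differs, shared acceptor downstream
            ca, cb = nextjA.get(a_ex[1]), nextjB.get(b_ex[1])
            if ca is not None and ca == cb and a_ex[1] != b_ex[1]:
                lo, hi = sorted((a_ex[1], b_ex[1]))
                etype = "A5SS" if strand == "+" else "A3SS"
                emit(_make_event(etype, gene_id, chrom, strand,
                                 iso1=[body((lo, hi)), junc(hi, ca)],
                                 iso2=[junc(lo, ca)],
                                 flanks=(a_ex, b_ex)))
            # acceptor side (genomic left) differs, shared donor upstream
            da, db_ = prevjA.get(a_ex[0]), prevjB.get(b_ex[0])
            if da is not None and da == db_ and a_ex[0] != b_ex[0]:
                lo, hi = sorted((a_ex[0], b_ex[0]))
                etype = "A3SS" if strand == "+" else "A5SS"
                emit(_make_event(etype, gene_id, chrom, strand,
                                 iso1=[body((lo, hi)), junc(da, lo)],
                                 iso2=[junc(da, hi)],
                                 flanks=(a_ex, b_ex)))

    # --- AFE / ALE: non-overlapping terminal exons splicing to a shared exon
    if len(A) >= 2 and len(B) >= 2:
        for etype, take in (("AFE", "first"), ("ALE", "last")):
            if strand == "+":
                term = (lambda t: t[0]) if take == "first" else (lambda t: t[-1])
            else:
                term = (lambda t: t[-1]) if take == "first" else (lambda t: t[0])
            fa, fb = term(A), term(B)
            if fa == fb or _overlap(fa, fb):
                continue
            # shared-splice-partner test on the internal side of the terminal exon
            internal_right = (strand == "+") == (take == "first")
            if internal_right:
                # terminal exon splices rightward; require shared acceptor
                ca, cb = nextjA.get(fa[1]), nextjB.get(fb[1])
                if ca is None or ca != cb:
                    continue
                seg1 = [body(fa), junc(fa[1], ca)]
                seg2 = [body(fb), junc(fb[1], ca)]
            else:
                da, db_ = prevjA.get(fa[0]), prevjB.get(fb[0])
                if da is None or da != db_:
                    continue
                seg1 = [body(fa), junc(da, fa[0])]
                seg2 = [body(fb), junc(da, fb[0])]
            # iso1 = the transcript-distal terminal exon (deterministic tie-break)
            distal_first = (fa < fb) if internal_right else (fa > fb)
            if not distal_first:
                seg1, seg2 = seg2, seg1
            emit(_make_event(etype, gene_id, chrom, strand,
                             iso1=seg1, iso2=seg2))

    # --- TandemUTR: terminal exons sharing a 5' boundary, differing at 3' end
    la = A[-1] if strand == "+" else A[0]
    lb = B[-1] if strand == "+" else B[0]
    if la != lb:
        if strand == "+" and la[0] == lb[0]:
            mid = min(la[1], lb[1])
            core, ext = (la[0], mid), (mid, max(la[1], lb[1]))
        elif strand == "-" and la[1] == lb[1]:
            mid = max(la[0], lb[0])
            core, ext = (mid, la[1]), (min(la[0], lb[0]), mid)
        else:
            core = ext = None
        if core is not None:
            emit(_make_event("TandemUTR", gene_id, chrom, strand,
                             iso1=[Segment("utr_extension", *ext)],
                             iso2=[Segment("exon_body", *core)]))
    return out


def derive_events(transcripts: Iterable[TranscriptModel]) -> list[SpliceEvent]:
    """Derive all alternative-isoform events from pairwise transcript
    comparison within each gene.

    Duplicate events arising from multiple transcript pairs are merged by
    their (type, chrom, strand, sorted segment coordinates) key, which is
    encoded in the event_id.
    """
    seen: dict[str, SpliceEvent] = {}
    for gene_id, ts in group_by_gene(transcripts).items():
        for t1, t2 in itertools.combinations(ts, 2):
            if t1.chrom != t2.chrom or t1.strand != t2.strand:
                continue
            for ev in _pair_events(gene_id, t1.chrom, t1.strand, t1.exons, t2.exons):
                seen.setdefault(ev.event_id, ev)
    return sorted(seen.values(), key=lambda e: e.event_id)


# ---------------------------------------------------------------------------
# constitutive exons

def _intersect(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]):
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s, e = max(a[i][0], b[j][0]), min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def constitutive_exons(transcripts: Sequence[TranscriptModel]) -> list[tuple[int, int]]:
    """Maximal intervals fully covered by every transcript of one gene.

    Computed as the per-base intersection of transcript exon footprints,
    merged into maximal intervals.  For a single-transcript gene this is the
    exon list itself.
    """
    if not transcripts:
        raise ValueError("gene must have at least one transcript")
    cur = list(transcripts[0].exons)
    for t in transcripts[1:]:
        cur = _intersect(cur, list(t.exons))
        if not cur:
            return []
    merged = [cur[0]]
    for s, e in cur[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
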