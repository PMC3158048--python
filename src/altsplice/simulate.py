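"""Synthetic-data generation with planted ground truth.

Emulates the study design the pipeline targets: two conditions, single-end
39-bp reads over annotated genes, with planted per-event Ψ values, planted
expression fold changes, planted flank motifs and planted two-class Ψ
panels.  Every generator is a pure function of its arguments plus a seed;
re-running with the same seed reproduces output bit-identically.

Counts are Poisson (single library per condition, no biological replication
to estimate overdispersion from); an optional negative-binomial mode exists
for robustness testing.  Positional coverage is uniform (no fragmentation
bias).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as asio
from .models import (
    EVENT_TYPES,
    EventReadCounts,
    FLANK_KEYS,
    FlankRegionSet,
    ReadPlacement,
    SignaturePanel,
    TranscriptModel,
)

__all__ = [
    "SimAnnotation",
    "SimExperiment",
    "simulate_annotation",
    "simulate_reads",
    "simulate_experiment",
    "simulate_panel",
    "simulate_flank_sets",
    "simulate_event_counts",
    "simulate_delta_pairs",
    "STANDARD_EVENTS_PER_TYPE",
]

CHROM = "chrS"
STANDARD_EVENTS_PER_TYPE = {t: 10 for t in EVENT_TYPES}

_RC = str.maketrans("ACGT", "TGCA")


@dataclass
class SimEventGene:
    """Truth for one event-bearing gene (one event per gene)."""

    gene_id: str
    event_type: str
    inclusion_transcript: str  # transcript carrying the iso1 (inclusion) form
    strand: str


@dataclass
class SimAnnotation:
    transcripts: list[TranscriptModel]
    chrom: str
    sequence: str
    event_genes: list[SimEventGene]
    seed: int

    @property
    def counts_per_type(self) -> dict[str, int]:
        out = {t: 0 for t in EVENT_TYPES}
        for eg in self.event_genes:
            out[eg.event_type] += 1
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "annotation.gtf",
            "fasta": outdir / "genome.fa",
            "truth": outdir / "event_truth.tsv",
        }
        asio.write_gtf(self.transcripts, paths["gtf"])
        asio.write_fasta({self.chrom: self.sequence}, paths["fasta"])
        rows = [
            {"gene_id": eg.gene_id, "event_type": eg.event_type,
             "inclusion_transcript": eg.inclusion_transcript, "strand": eg.strand}
            for eg in self.event_genes
        ]
        pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _ilen(rng, lo_hi) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def _gene_structure(etype: Optional[str], rng, exon_lr, intron_lr):
    """Local exon chains (transcript-oriented, plus-strand layout) for one
    gene realising one event of ``etype`` (None -> single-isoform gene).

    Returns (transcript exon lists, index of the inclusion transcript or None).
    """
    el = lambda: _ilen(rng, exon_lr)
    il = lambda: _ilen(rng, intron_lr)

    def chain(lens):  # alternate exon/intron lengths -> exon intervals
        exons, pos = [], 0
        for i, L in enumerate(lens):
            if i % 2 == 0:
                exons.append((pos, pos + L))
            pos += L
        return exons

    if etype is None:
        n = int(rng.integers(2, 5))
        lens = []
        for i in range(2 * n - 1):
            lens.append(el() if i % 2 == 0 else il())
        return [chain(lens)], None
    if etype == "SE":
        exons = chain([el(), il(), el(), il(), el()])
        return [exons, [exons[0], exons[2]]], 0
    if etype == "RI":
        exons = chain([el(), il(), el()])
        retained = [(exons[0][0], exons[1][1])]
        return [exons, retained], 1
    if etype == "MXE":
        exons = chain([el(), il(), el(), il(), el(), il(), el()])
        f1, x, y, f2 = exons
        return [[f1, x, f2], [f1, y, f2]], 0
    if etype == "A5SS":
        l1, ext, i, l2 = el(), int(rng.integers(30, 81)), il(), el()
        long = [(0, l1 + ext), (l1 + ext + i, l1 + ext + i + l2)]
        short = [(0, l1), (l1 + ext + i, l1 + ext + i + l2)]
        return [long, short], 0
    if etype == "A3SS":
        l1, i, ext, l2 = el(), il(), int(rng.integers(30, 81)), el()
        long = [(0, l1), (l1 + i, l1 + i + ext + l2)]
        short = [(0, l1), (l1 + i + ext, l1 + i + ext + l2)]
        return [long, short], 0
    if etype == "AFE":
        la, gap, lb, i, ls = el(), il(), el(), il(), el()
        fa = (0, la)
        fb = (la + gap, la + gap + lb)
        shared = (fb[1] + i, fb[1] + i + ls)
        return [[fa, shared], [fb, shared]], 0
    if etype == "ALE":
        l1, i1, la, gap, lb = el(), il(), el(), il(), el()
        e1 = (0, l1)
        xa = (l1 + i1, l1 + i1 + la)
        xb = (xa[1] + gap, xa[1] + gap + lb)
        return [[e1, xa], [e1, xb]], 1  # distal last exon (xb) is iso1
    if etype == "TandemUTR":
        l1, i, core, ext = el(), il(), max(el(), 60), int(rng.integers(60, 161))
        e1 = (0, l1)
        s = l1 + i
        return [[e1, (s, s + core + ext)], [e1, (s, s + core)]], 0
    raise ValueError(f"unknown event type {etype!r}")


def simulate_annotation(
    n_genes: int = 90,
    events_per_type: Optional[Mapping[str, int]] = None,
    intron_len_range: tuple[int, int] = (300, 1000),
    exon_len_range: tuple[int, int] = (80, 200),
    seed: int = 0,
    gene_gap: int = 300,
    planted_motif: Optional[tuple[str, tuple[str, str], int]] = None,
    flank_width: int = 250,
) -> SimAnnotation:
    """Non-overlapping genes on one synthetic chromosome, each requested
    event type realised by a transcript pair; remaining genes single-isoform.

    ``planted_motif`` = (RNA motif, region key such as
    ("downstream_intron", "I5"), copies per region) plants the motif into the
    corresponding flank of every SE event gene (reverse-complemented on the
    minus strand).
    """
    events_per_type = dict(events_per_type or {})
    for t in events_per_type:
        if t not in EVENT_TYPES:
            raise ValueError(f"unknown event type {t!r}")
    total_events = sum(events_per_type.values())
    if n_genes < total_events:
        raise ValueError(f"n_genes={n_genes} < requested events {total_events}")
    if intron_len_range[0] < 50:
        raise ValueError("introns shorter than 50 bp leave no room for flanks")
    if planted_motif is not None:
        motif, region, copies = planted_motif
        if region not in FLANK_KEYS:
            raise ValueError(f"unknown flank region {region!r}")
        room = min(intron_len_range[0] // 2, flank_width)
        if copies * (len(motif) + 1) > room:
            raise ValueError("intron too short for requested planted motif copies")

    rng = np.random.default_rng(seed)
    plan: list[Optional[str]] = []
    for t in EVENT_TYPES:
        plan.extend([t] * events_per_type.get(t, 0))
    plan.extend([None] * (n_genes - total_events))

    transcripts: list[TranscriptModel] = []
    event_genes: list[SimEventGene] = []
    seq_chunks: list[str] = []
    cursor = 0
    bases = np.array(list("ACGT"))
    plant_jobs: list[tuple[int, str]] = []  # (genomic offset, DNA string)

    for gi, etype in enumerate(plan):
        gene_id = f"g{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        chains, inc_idx = _gene_structure(etype, rng, exon_len_range, intron_len_range)
        span = max(e for ch in chains for (_, e) in ch)
        if strand == "-":
            chains = [sorted((span - e, span - s) for (s, e) in ch) for ch in chains]
        tids = []
        for ti, ch in enumerate(chains):
            tid = f"{gene_id}.t{ti}"
            tids.append(tid)
            transcripts.append(TranscriptModel(
                gene_id=gene_id, transcript_id=tid, chrom=CHROM, strand=strand,
                exons=tuple((cursor + s, cursor + e) for (s, e) in ch),
            ))
        if etype is not None:
            event_genes.append(SimEventGene(
                gene_id=gene_id, event_type=etype,
                inclusion_transcript=tids[inc_idx], strand=strand,
            ))
        if etype == "SE" and planted_motif is not None:
            motif, (which_intron, end5or3), copies = planted_motif
            dna = motif.replace("U", "T")
            inc_exons = [ (s,e) for (s,e) in transcripts[-2].exons ]  # full transcript
            up_i = (inc_exons[0][1], inc_exons[1][0])
            down_i = (inc_exons[1][1], inc_exons[2][0])
            if strand == "-":
                up_i, down_i = down_i, up_i
            s, e = up_i if which_intron == "upstream_intron" else down_i
            L = e - s
            w = min(flank_width, L // 2)
            # transcript-oriented window within the intron
            if (end5or3 == "I5") == (strand == "+"):
                win = (s, s + w)
            else:
                win = (e - w, e)
            step = (w - len(dna)) // max(copies, 1)
            for c in range(copies):
                off = win[0] + c * step + int(rng.integers(0, max(step - len(dna), 1)))
                plant_jobs.append((off, dna if strand == "+" else dna.translate(_RC)[::-1]))
        cursor += span + gene_gap

    genome = rng.choice(bases, size=cursor + gene_gap)
    for off, dna in plant_jobs:
        genome[off:off + len(dna)] = list(dna)
    return SimAnnotation(
        transcripts=transcripts, chrom=CHROM, sequence="".join(genome),
        event_genes=event_genes, seed=seed,
    )


# ---------------------------------------------------------------------------
# read simulation

def _transcript_blocks(exons, start, length):
    """Map a transcript-coordinate interval to genomic blocks."""
    blocks = []
    pos = 0
    for (s, e) in exons:
        elen = e - s
        lo = max(start - pos, 0)
        hi = min(start + length - pos, elen)
        if lo < hi:
            blocks.append((s + lo, s + hi))
        pos += elen
    return tuple(blocks)


def simulate_reads(
    ann: SimAnnotation,
    gene_expression: Mapping[str, float],
    psi: Mapping[str, float],
    depth: int,
    read_length: int = 39,
    seed: int = 0,
    dispersion: Optional[float] = None,
) -> list[ReadPlacement]:
    """Draw reads uniformly over transcript coordinates.

    Transcript weights are expression x isoform fraction (the planted Ψ for
    the inclusion transcript of each event gene) x number of start positions.
    Per-transcript totals are Poisson (or negative binomial when a
    ``dispersion`` > 0 is given); split reads are emitted across junctions.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    if depth == 0:
        return []
    inc_by_gene = {eg.gene_id: eg.inclusion_transcript for eg in ann.event_genes}

    txs, weights = [], []
    for t in ann.transcripts:
        L = t.length
        if L < read_length:
            warnings.warn(f"transcript {t.transcript_id} shorter than read length; skipped")
            continue
        expr = gene_expression.get(t.gene_id, 0.0)
        inc_tid = inc_by_gene.get(t.gene_id)
        if inc_tid is None:
            frac = 1.0
        else:
            p = psi.get(t.gene_id, 0.5)
            frac = p if t.transcript_id == inc_tid else 1.0 - p
        w = expr * frac * (L - read_length + 1)
        if w > 0:
            txs.append(t)
            weights.append(w)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        return []
    lam = depth * weights / weights.sum()
    if dispersion and dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + lam))
    else:
        counts = rng.poisson(lam)

    reads: list[ReadPlacement] = []
    for t, n in zip(txs, counts):
        if n == 0:
            continue
        starts = rng.integers(0, t.length - read_length + 1, size=int(n))
        for s in starts:
            reads.append(ReadPlacement(
                chrom=t.chrom,
                blocks=_transcript_blocks(t.exons, int(s), read_length),
                strand=t.strand,
            ))
    return reads


@dataclass
class SimExperiment:
    """Two-condition experiment with planted Ψ and expression truth."""

    annotation: SimAnnotation
    psi: dict[str, dict[str, float]]  # condition -> gene -> true Ψ
    expression: dict[str, dict[str, float]]  # condition -> gene -> level
    changed_events: dict[str, float]  # event gene -> planted ΔΨ (cond2-cond1)
    de_genes: dict[str, float]  # gene -> planted fold change (cond2/cond1)
    reads: dict[str, list[ReadPlacement]]
    read_length: int
    seed: int


def simulate_experiment(
    n_genes: int = 90,
    events_per_type: Optional[Mapping[str, int]] = None,
    depth: int = 200_000,
    frac_changed: float = 0.3,
    effect_dpsi: float = 0.4,
    n_de_genes: int = 10,
    de_fold: float = 5.0,
    read_length: int = 39,
    seed: int = 0,
    **annotation_kwargs,
) -> SimExperiment:
    """Full planted two-condition experiment: annotation, truth and reads.

    A fraction ``frac_changed`` of event genes receive a ΔΨ of
    ±``effect_dpsi`` (sign randomised); ``n_de_genes`` single-isoform genes
    receive a ``de_fold`` expression change (direction randomised).
    """
    if events_per_type is None:
        events_per_type = STANDARD_EVENTS_PER_TYPE
    rng = np.random.default_rng(seed)
    ann = simulate_annotation(
        n_genes=n_genes, events_per_type=events_per_type,
        seed=int(rng.integers(0, 2**31 - 1)), **annotation_kwargs,
    )
    gene_ids = sorted({t.gene_id for t in ann.transcripts})
    event_gids = [eg.gene_id for eg in ann.event_genes]
    plain_gids = [g for g in gene_ids if g not in set(event_gids)]

    base_expr = {g: float(np.exp(rng.normal(0.0, 0.5))) for g in gene_ids}
    de_pool = plain_gids if len(plain_gids) >= n_de_genes else gene_ids
    de_pick = list(rng.choice(de_pool, size=min(n_de_genes, len(de_pool)), replace=False))
    de_genes = {}
    expr2 = dict(base_expr)
    for g in de_pick:
        fold = de_fold if rng.random() < 0.5 else 1.0 / de_fold
        de_genes[g] = fold
        expr2[g] = base_expr[g] * fold

    psi1 = {g: float(rng.uniform(0.25, 0.75)) for g in event_gids}
    psi2 = dict(psi1)
    n_changed = int(round(frac_changed * len(event_gids)))
    changed = list(rng.choice(event_gids, size=n_changed, replace=False))
    changed_events = {}
    for g in changed:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        target = min(max(psi1[g] + sign * effect_dpsi, 0.02), 0.98)
        psi2[g] = target
        changed_events[g] = target - psi1[g]

    reads = {
        "cond1": simulate_reads(ann, base_expr, psi1, depth, read_length,
                                seed=int(rng.integers(0, 2**31 - 1))),
        "cond2": simulate_reads(ann, expr2, psi2, depth, read_length,
                                seed=int(rng.integers(0, 2**31 - 1))),
    }
    return SimExperiment(
        annotation=ann,
        psi={"cond1": psi1, "cond2": psi2},
        expression={"cond1": base_expr, "cond2": expr2},
        changed_events=changed_events,
        de_genes=de_genes,
        reads=reads,
        read_length=read_length,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# direct count / panel / flank generators

def simulate_event_counts(
    true_psi: float,
    n_reads: int,
    inc_positions: int = 150,
    exc_positions: int = 32,
    seed: int = 0,
) -> EventReadCounts:
    """Informative read counts for one event at a given true Ψ.

    Each informative read supports inclusion with probability
    Ψ·P_inc / (Ψ·P_inc + (1−Ψ)·P_exc), the density model the estimator
    inverts.
    """
    if not 0.0 <= true_psi <= 1.0:
        raise ValueError("true_psi must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w_inc = true_psi * inc_positions
    w_exc = (1.0 - true_psi) * exc_positions
    p = w_inc / (w_inc + w_exc)
    inc = int(rng.binomial(n_reads, p))
    return EventReadCounts(
        event_id="sim", inc_reads=inc, exc_reads=n_reads - inc,
        inc_positions=inc_positions, exc_positions=exc_positions,
    )


def simulate_panel(
    n_class1: int = 12,
    n_class2: int = 12,
    n_events: int = 200,
    effect_dpsi: float = 0.3,
    noise_sd: float = 0.1,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[SignaturePanel, dict]:
    """Two-class Ψ sample panel with a planted separating event subset.

    Class means differ by ``effect_dpsi`` on a random half of events (sign
    randomised); Gaussian noise is added, values are clamped to [0, 1] and
    entries are masked missing at ``missing_rate``.
    """
    if min(n_class1, n_class2, n_events) <= 0:
        raise ValueError("panel dimensions must be positive")
    rng = np.random.default_rng(seed)
    events = [f"ev{i:04d}" for i in range(n_events)]
    samples = [f"A{i:02d}" for i in range(n_class1)] + [f"B{i:02d}" for i in range(n_class2)]
    labels = {s: ("class1" if s.startswith("A") else "class2") for s in samples}

    base = rng.uniform(0.2, 0.8, size=n_events)
    affected_idx = rng.choice(n_events, size=n_events // 2, replace=False)
    signs = rng.choice([-1.0, 1.0], size=affected_idx.size)
    mean1 = np.tile(base[:, None], (1, len(samples)))
    for idx, sg in zip(affected_idx, signs):
        mean1[idx, :n_class1] = base[idx] - sg * effect_dpsi / 2
        mean1[idx, n_class1:] = base[idx] + sg * effect_dpsi / 2
    values = np.clip(mean1 + rng.normal(0.0, noise_sd, size=mean1.shape), 0.0, 1.0)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)
    df = pd.DataFrame(values, index=events, columns=samples)
    truth = {
        "affected_events": [events[i] for i in sorted(affected_idx)],
        "signs": {events[i]: float(s) for i, s in zip(affected_idx, signs)},
        "labels": labels,
    }
    return SignaturePanel(values=df, labels=labels, measure="psi"), truth


def simulate_flank_sets(
    n_fg: int,
    n_bg: int,
    width: int = 250,
    planted: Optional[tuple[str, tuple[str, str], int]] = None,
    seed: int = 0,
) -> tuple[list[FlankRegionSet], list[FlankRegionSet]]:
    """Random RNA flank-region sets, with an optional motif planted into one
    region of every foreground set: planted = (motif, region key, copies)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))

    def one(eid, plant):
        regions = {}
        for key in FLANK_KEYS:
            seq = rng.choice(bases, size=width)
            if plant is not None and key == plant[1]:
                motif = np.array(list(plant[0]))
                step = width // plant[2]
                for c in range(plant[2]):
                    off = c * step + int(rng.integers(0, max(step - motif.size, 1)))
                    seq[off:off + motif.size] = motif
            regions[key] = "".join(seq)
        return FlankRegionSet(event_id=eid, regions=regions)

    fg = [one(f"fg{i:04d}", planted) for i in range(n_fg)]
    bg = [one(f"bg{i:04d}", None) for i in range(n_bg)]
    return fg, bg


def simulate_delta_pairs(
    n: int, flip_prob: float, seed: int = 0, scale: float = 0.3
) -> tuple[dict[str, float], dict[str, float]]:
    """Paired ΔΨ maps where dataset B flips the sign of dataset A's delta
    independently with probability ``flip_prob`` (for coherence checks)."""
    rng = np.random.default_rng(seed)
    da, db = {}, {}
    for i in range(n):
        eid = f"ev{i:04d}"
        d = float(rng.uniform(0.05, scale)) * (1 if rng.random() < 0.5 else -1)
        da[eid] = d
        db[eid] = -d if rng.random() < flip_prob else d
    return da, db
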