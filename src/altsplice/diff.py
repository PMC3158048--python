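"""Differential expression and differential splicing between two conditions.

Expression uses the Audic–Claverie exact test for read counts from two
libraries combined with a fold-change filter on RPKM ratios.  Splicing uses
a per-event two-sided Fisher exact test on inclusion/exclusion read counts
(reads as sampling units — anti-conservative for biological inference with
one library per condition), ΔΨ from density-based Ψ estimates, and
Benjamini–Hochberg FDR across all tested events.
"""
from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact

from .models import DiffExprRecord, DiffSpliceRecord, EventReadCounts, PsiEstimate

__all__ = [
    "audic_claverie_pvalue",
    "benjamini_hochberg",
    "diff_expression",
    "diff_splicing",
    "filter_events",
    "gene_level_fraction",
]

#: cap for reporting infinite fold changes (zero count in one condition)
FOLD_CAP = 2.0 ** 15


def audic_claverie_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-tailed Audic–Claverie p-value for counts from two libraries.

    Under the null that a transcript is equally represented in libraries of
    sizes n1 and n2, the count y in library 2 given x in library 1 follows

        P(y | x) = r^y * (x + y)! / (x! * y! * (1 + r)^(x + y + 1)),  r = n2/n1,

    a negative-binomial law.  The reported p doubles the smaller of the two
    cumulative tails (capped at 1).  Computed in log space, stable for counts
    up to 1e6.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    r = n2 / n1
    log_r = math.log(r)
    log_1pr = math.log1p(r)
    mean = (x + 1) * r
    sd = math.sqrt((x + 1) * r * (1 + r))
    kmax = int(max(y, mean) + 20 * sd + 50)
    k = np.arange(0, kmax + 1)
    logpmf = (
        k * log_r
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * log_1pr
    )
    lower = math.exp(logsumexp(logpmf[: y + 1]))
    upper = math.exp(logsumexp(logpmf[y:]))
    return min(1.0, 2.0 * min(lower, upper))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (order-invariant; ties share)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def diff_expression(
    counts_1: Mapping[str, int],
    counts_2: Mapping[str, int],
    n1: int,
    n2: int,
    fold_cutoff: float = 3.0,
    alpha: float = 0.05,
) -> list[DiffExprRecord]:
    """Audic–Claverie test + fold-change filter over matched gene lists.

    A gene present in only one mapping is treated as count 0 in the other.
    Significance requires BH-adjusted p <= alpha AND an RPKM fold change
    >= fold_cutoff in either direction (length cancels within a gene, so the
    ratio reduces to depth-normalised counts).
    """
    genes = sorted(set(counts_1) | set(counts_2))
    recs = []
    for g in genes:
        x = int(counts_1.get(g, 0))
        y = int(counts_2.get(g, 0))
        r1 = x / n1
        r2 = y / n2
        if r1 == 0 and r2 == 0:
            fc = 1.0
        elif r1 == 0:
            fc = FOLD_CAP
        else:
            fc = min(r2 / r1, FOLD_CAP)
        recs.append(DiffExprRecord(
            gene_id=g, count_1=x, count_2=y, n1=n1, n2=n2,
            fold_change=fc, p_ac=audic_claverie_pvalue(x, y, n1, n2),
        ))
    fdr = benjamini_hochberg([r.p_ac for r in recs])
    for rec, q in zip(recs, fdr):
        rec.fdr = float(q)
        rec.significant = bool(
            q <= alpha and (rec.fold_change >= fold_cutoff
                            or rec.fold_change <= 1.0 / fold_cutoff)
        )
    return recs


def diff_splicing(
    counts_1: Mapping[str, EventReadCounts],
    counts_2: Mapping[str, EventReadCounts],
    psi_1: Optional[Mapping[str, PsiEstimate]] = None,
    psi_2: Optional[Mapping[str, PsiEstimate]] = None,
) -> list[DiffSpliceRecord]:
    """Per-event differential splicing between condition 1 and condition 2.

    Each event is tested with a two-sided Fisher exact test on the 2x2 table
    (inclusion reads, exclusion reads) x (condition 1, condition 2); BH FDR
    is computed over all tested events.  Events with Ψ undefined in either
    condition (no supporting reads) are dropped; all-zero tables are skipped.
    ΔΨ = Ψ(condition 2) − Ψ(condition 1).
    """
    from .quant import estimate_psi

    shared = sorted(set(counts_1) & set(counts_2))
    recs = []
    for eid in shared:
        c1, c2 = counts_1[eid], counts_2[eid]
        e1 = psi_1[eid] if psi_1 is not None else estimate_psi(c1)
        e2 = psi_2[eid] if psi_2 is not None else estimate_psi(c2)
        if e1.psi is None or e2.psi is None:
            continue
        table = [[c1.inc_reads, c1.exc_reads], [c2.inc_reads, c2.exc_reads]]
        if sum(table[0]) + sum(table[1]) == 0:
            continue
        _, p = fisher_exact(table, alternative="two-sided")
        recs.append(DiffSpliceRecord(
            event_id=eid, psi_1=e1.psi, psi_2=e2.psi,
            delta_psi=e2.psi - e1.psi, p=float(p),
        ))
    fdr = benjamini_hochberg([r.p for r in recs])
    for rec, q in zip(recs, fdr):
        rec.fdr = float(q)
    return recs


def filter_events(
    records: Sequence[DiffSpliceRecord],
    min_abs_dpsi: float = 0.10,
    max_fdr: float = 0.05,
) -> list[DiffSpliceRecord]:
    """Keep events with |ΔΨ| >= min_abs_dpsi and FDR <= max_fdr (inclusive)."""
    return [r for r in records
            if abs(r.delta_psi) >= min_abs_dpsi and r.fdr <= max_fdr]


def gene_level_fraction(
    records: Sequence[DiffSpliceRecord],
    gene_map: Mapping[str, str],
    min_abs_dpsi: float = 0.10,
    max_fdr: float = 0.05,
) -> float:
    """Fraction of tested genes with at least one passing event.

    The denominator is the number of distinct genes with >= 1 tested event
    (both isoforms detected); the numerator counts genes with >= 1 event
    passing the ΔΨ/FDR filter.
    """
    missing = [r.event_id for r in records if r.event_id not in gene_map]
    if missing:
        raise ValueError(f"events not mapped to a gene: {missing[:5]}")
    tested = {gene_map[r.event_id] for r in records}
    if not tested:
        return 0.0
    passing = {gene_map[r.event_id]
               for r in filter_events(records, min_abs_dpsi, max_fdr)}
    return len(passing) / len(tested)
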