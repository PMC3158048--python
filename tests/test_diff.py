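"""Differential expression (Audic–Claverie) and differential splicing."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import altsplice as alt
from altsplice.models import EventReadCounts
from altsplice.simulate import simulate_event_counts


# ---------------------------------------------------------------------------
# Audic–Claverie

def ac_exact(x, y, n1, n2):
    """Exact-rational tail summation oracle for the Audic–Claverie test."""
    r = Fraction(n2) / Fraction(n1)
    pmf = lambda k: r**k * comb(x + k, k) / (1 + r) ** (x + k + 1)
    lower = sum(pmf(k) for k in range(y + 1))
    upper = 1 - sum(pmf(k) for k in range(y))
    return float(min(Fraction(1), 2 * min(lower, upper)))


def test_ac_no_evidence_gives_p_one():
    assert alt.audic_claverie_pvalue(0, 0, 1_000_000, 1_000_000) == 1.0


def test_ac_exchange_symmetry():
    """The conditional law is exchange-symmetric pointwise at equal library
    sizes (P(y|x) = P(x|y)); the doubled-tail p-value conditions on
    different observed counts under exchange and agrees only approximately."""
    r = Fraction(1)
    pmf = lambda x, y: r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)
    assert pmf(5, 20) == pmf(20, 5)
    a = alt.audic_claverie_pvalue(5, 20, 1_000_000, 1_000_000)
    b = alt.audic_claverie_pvalue(20, 5, 1_000_000, 1_000_000)
    assert b / 2 < a < b * 2


@pytest.mark.parametrize("x,y,ratio", [(5, 20, 1), (0, 7, 2), (30, 3, Fraction(10, 7))])
def test_ac_matches_brute_force_summation(x, y, ratio):
    n1 = 1_000_000
    got = alt.audic_claverie_pvalue(x, y, n1, float(n1 * ratio))
    assert got == pytest.approx(ac_exact(x, y, n1, n1 * ratio), rel=1e-10)


def test_ac_large_counts_are_stable():
    p = alt.audic_claverie_pvalue(1_000_000, 1_000_000, 2e7, 2e7)
    assert 0.9 < p <= 1.0
    p = alt.audic_claverie_pvalue(1_000_000, 1_010_000, 2e7, 2e7)
    assert 0.0 < p < 1.0


def test_ac_rejects_bad_arguments():
    with pytest.raises(ValueError):
        alt.audic_claverie_pvalue(-1, 0, 1e6, 1e6)
    with pytest.raises(ValueError):
        alt.audic_claverie_pvalue(0, 0, 0, 1e6)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg

def test_bh_identity_and_ties():
    assert alt.benjamini_hochberg([0.03]) == pytest.approx([0.03])
    assert alt.benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    with pytest.raises(ValueError):
        alt.benjamini_hochberg([0.5, 1.2])


def test_bh_matches_independent_reference():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(5)
    p = rng.uniform(size=20)
    got = alt.benjamini_hochberg(p)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    assert got == pytest.approx(ref)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_is_order_invariant_and_monotone(p):
    fwd = alt.benjamini_hochberg(p)
    rev = alt.benjamini_hochberg(p[::-1])
    assert fwd == pytest.approx(rev[::-1])
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(np.asarray(fwd)[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# differential expression

def test_identical_samples_yield_no_significant_genes():
    counts = {f"g{i}": 50 + i for i in range(100)}
    recs = alt.diff_expression(counts, counts, 10**6, 10**6)
    assert not any(r.significant for r in recs)


def test_fold_filter_dominates_significance():
    # 2.5-fold change: however small the p-value, a 3-fold cutoff excludes it
    recs = alt.diff_expression({"g": 100}, {"g": 250}, 10**6, 10**6, fold_cutoff=3)
    (r,) = recs
    assert r.fold_change == pytest.approx(2.5)
    assert not r.significant


def test_missing_gene_treated_as_zero_count():
    recs = alt.diff_expression({"g": 40}, {}, 10**6, 10**6)
    (r,) = recs
    assert r.count_2 == 0
    assert r.fold_change < 1


def test_planted_fold_changes_are_recovered():
    """100 planted 5-fold genes among 2,000 nulls at library size 1e6:
    sensitivity >= 0.9 with false-discovery proportion <= 2x nominal."""
    rng = np.random.default_rng(17)
    c1, c2, planted = {}, {}, set()
    for i in range(2000):
        g = f"null{i}"
        lam = rng.uniform(20, 200)
        c1[g], c2[g] = rng.poisson(lam), rng.poisson(lam)
    for i in range(100):
        g = f"de{i}"
        planted.add(g)
        lam = rng.uniform(20, 200)
        up = rng.random() < 0.5
        c1[g] = rng.poisson(lam)
        c2[g] = rng.poisson(lam * 5 if up else lam / 5)
    recs = alt.diff_expression(c1, c2, 10**6, 10**6, fold_cutoff=3, alpha=0.05)
    sig = {r.gene_id for r in recs if r.significant}
    assert len(sig & planted) / len(planted) >= 0.9
    fdp = len(sig - planted) / max(len(sig), 1)
    assert fdp <= 2 * 0.05


# ---------------------------------------------------------------------------
# differential splicing

def _counts(inc, exc, eid="e0"):
    return {eid: EventReadCounts(eid, inc, exc, 150, 32)}


def test_identical_count_tables_give_null_results():
    c = {f"e{i}": EventReadCounts(f"e{i}", 40 + i, 60, 150, 32) for i in range(5)}
    recs = alt.diff_splicing(c, c)
    assert len(recs) == 5
    for r in recs:
        assert r.delta_psi == 0.0
        assert r.p == 1.0


def test_mutually_exclusive_switch_gives_delta_minus_one():
    # complete switch from inclusion to exclusion between the two conditions,
    # dPsi = psi2 - psi1 = -1, condition-1 (epithelial-like) inclusion
    r1 = alt.diff_splicing(_counts(200, 0), _counts(0, 200))
    (rec,) = r1
    assert rec.psi_1 == 1.0 and rec.psi_2 == 0.0
    assert rec.delta_psi == -1.0
    assert rec.direction == "condition1-inclusion"


def test_fisher_p_matches_table_enumeration_oracle():
    """2x2 table (30,5 | 10,25): two-sided p as the sum of probabilities of
    all tables (fixed margins) no more likely than the observed one."""
    a, b, c, d = 30, 5, 10, 25
    r1, r2, col1 = a + b, c + d, a + c
    n = r1 + r2

    def hyp(k):  # P(X=k) for k in column 1 of row 1
        return Fraction(comb(r1, k) * comb(r2, col1 - k), comb(n, col1))

    p_obs = hyp(a)
    p_exact = sum(hyp(k) for k in range(max(0, col1 - r2), min(r1, col1) + 1)
                  if hyp(k) <= p_obs)
    recs = alt.diff_splicing(_counts(a, b), _counts(c, d))
    assert recs[0].p == pytest.approx(float(p_exact), rel=1e-9)


def test_direction_labels_are_antisymmetric():
    c1 = {f"e{i}": simulate_event_counts(0.3 + 0.05 * i, 500, seed=i) for i in range(6)}
    c2 = {f"e{i}": simulate_event_counts(0.6, 500, seed=100 + i) for i in range(6)}
    for eid in list(c1):
        c1[eid].event_id = c2[eid].event_id = eid
    fwd = {r.event_id: r for r in alt.diff_splicing(c1, c2)}
    rev = {r.event_id: r for r in alt.diff_splicing(c2, c1)}
    for eid in fwd:
        assert fwd[eid].delta_psi == pytest.approx(-rev[eid].delta_psi)
        assert fwd[eid].p == pytest.approx(rev[eid].p)


def test_undefined_psi_events_are_dropped():
    c1 = _counts(0, 0)
    c2 = _counts(10, 10)
    assert alt.diff_splicing(c1, c2) == []


def test_filter_events_boundaries_are_inclusive():
    from altsplice.models import DiffSpliceRecord
    recs = [
        DiffSpliceRecord("a", 0.5, 0.6, 0.10, 0.01, fdr=0.05),
        DiffSpliceRecord("b", 0.5, 0.59, 0.09, 0.01, fdr=0.05),
        DiffSpliceRecord("c", 0.5, 0.8, 0.30, 0.2, fdr=0.051),
    ]
    kept = alt.filter_events(recs, min_abs_dpsi=0.10, max_fdr=0.05)
    assert [r.event_id for r in kept] == ["a"]
    assert alt.filter_events([]) == []


def test_filtering_matches_planted_pass_labels():
    from altsplice.models import DiffSpliceRecord
    rng = np.random.default_rng(23)
    recs, want = [], set()
    for i in range(1000):
        d = float(rng.uniform(-0.5, 0.5))
        q = float(rng.uniform(0, 0.2))
        recs.append(DiffSpliceRecord(f"e{i}", 0.5, 0.5 + d, d, q, fdr=q))
        if abs(d) >= 0.10 and q <= 0.05:
            want.add(f"e{i}")
    got = {r.event_id for r in alt.filter_events(recs, 0.10, 0.05)}
    assert got == want


def test_gene_level_fraction():
    from altsplice.models import DiffSpliceRecord
    recs = [
        DiffSpliceRecord("e1", 0.2, 0.6, 0.4, 0.001, fdr=0.001),  # passes
        DiffSpliceRecord("e2", 0.5, 0.52, 0.02, 0.8, fdr=0.9),
        DiffSpliceRecord("e3", 0.5, 0.45, -0.05, 0.6, fdr=0.9),
    ]
    gmap = {"e1": "gA", "e2": "gA", "e3": "gB"}
    assert alt.gene_level_fraction(recs, gmap) == pytest.approx(0.5)
    assert alt.gene_level_fraction(recs[1:], gmap) == 0.0
    assert alt.gene_level_fraction([recs[0]], gmap) == 1.0
    with pytest.raises(ValueError):
        alt.gene_level_fraction(recs, {"e1": "gA"})
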