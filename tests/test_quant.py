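"""Read counting, Ψ estimation and RPKM."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import altsplice as alt
from altsplice import io as asio
from altsplice.models import EventReadCounts, ReadPlacement
from altsplice.simulate import (
    SimEventGene,
    simulate_annotation,
    simulate_event_counts,
    simulate_reads,
)

from conftest import tm


@pytest.fixture()
def se_event():
    evs = alt.derive_events([
        tm("g", "t1", "+", [(0, 100), (200, 300), (400, 500)]),
        tm("g", "t2", "+", [(0, 100), (400, 500)]),
    ])
    return evs


def _r(*blocks):
    return ReadPlacement(chrom="chrT", blocks=tuple(blocks))


def test_junction_read_counting_rules(se_event):
    reads = [
        _r((80, 100), (400, 419)),    # 20/19 split across the skip junction
        _r((220, 259)),               # unspliced read inside the alternative exon
        _r((90, 100), (200, 229)),    # inclusion junction, 10/29 split
        _r((298, 300), (400, 437)),   # 2-bp overhang: below min_overhang, uncounted
        _r((180, 219)),               # spans the intron boundary: in no segment
        _r((95, 100), (205, 239)),    # 5-bp donor block but acceptor NOT at exon start
    ]
    counts = alt.count_event_reads(se_event, reads, read_length=39, min_overhang=4)
    c = counts[se_event[0].event_id]
    assert c.exc_reads == 1
    assert c.inc_reads == 2
    # positions: alt exon 100 nt -> 62 starts, two junctions at 39-2*4+1=32 each
    assert c.inc_positions == 62 + 2 * 32
    assert c.exc_positions == 32


def test_reads_on_other_chromosomes_are_ignored(se_event):
    reads = [ReadPlacement(chrom="chrZ", blocks=((220, 259),))]
    counts = alt.count_event_reads(se_event, reads)
    c = counts[se_event[0].event_id]
    assert c.inc_reads == 0 and c.exc_reads == 0


def test_negative_overhang_rejected(se_event):
    with pytest.raises(ValueError):
        alt.count_event_reads(se_event, [], min_overhang=0)


def test_read_order_permutation_leaves_counts_unchanged(se_event):
    rng = np.random.default_rng(0)
    reads = [_r((int(s), int(s) + 39)) for s in rng.integers(150, 350, size=50)]
    reads += [_r((80, 100), (400, 419))] * 3
    a = alt.count_event_reads(se_event, reads)
    b = alt.count_event_reads(se_event, list(reversed(reads)))
    assert a == b


def test_psi_definition_cases():
    e = alt.estimate_psi(EventReadCounts("x", 50, 0, 100, 36))
    assert e.psi == 1.0
    e = alt.estimate_psi(EventReadCounts("x", 50, 18, 100, 36))  # equal densities
    assert e.psi == pytest.approx(0.5)
    e = alt.estimate_psi(EventReadCounts("x", 0, 0, 100, 36))
    assert e.psi is None  # undefined, not 0
    from types import SimpleNamespace
    degenerate = SimpleNamespace(event_id="x", inc_reads=1, exc_reads=1,
                                 inc_positions=0, exc_positions=36)
    with pytest.raises(ValueError):
        alt.estimate_psi(degenerate)
    with pytest.raises(ValueError):
        EventReadCounts("x", 1, 1, 0, 36)


def test_psi_binomial_recovery():
    c = simulate_event_counts(0.70, 5000, seed=1)
    assert alt.estimate_psi(c).psi == pytest.approx(0.70, abs=0.02)


def test_psi_rmse_decreases_with_depth():
    rng = np.random.default_rng(3)
    rmses = []
    for depth in (100, 1000, 10_000):
        errs = []
        for i in range(200):
            true = 0.1 + 0.8 * (i % 9) / 8
            c = simulate_event_counts(true, depth, seed=int(rng.integers(2**31)))
            errs.append(alt.estimate_psi(c).psi - true)
        rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
    assert rmses[0] > rmses[1] > rmses[2]
    assert rmses[2] < 0.02


def test_tandem_utr_psi_cases():
    assert alt.tandem_utr_psi((100, 50), (100, 50)).psi == 1.0  # equal densities
    assert alt.tandem_utr_psi((100, 50), (0, 50)).psi == 0.0    # all proximal
    assert alt.tandem_utr_psi((0, 50), (5, 50)).psi is None     # zero core density
    # clamping: extension density can exceed core density by sampling noise
    assert alt.tandem_utr_psi((10, 50), (100, 50)).psi == 1.0


def test_tandem_utr_mixture_recovery():
    t_long = tm("g", "g.t0", "+", [(0, 200), (500, 950)], chrom="chrS")
    t_short = tm("g", "g.t1", "+", [(0, 200), (500, 800)], chrom="chrS")

    class Ann:
        transcripts = [t_long, t_short]
        event_genes = [SimEventGene("g", "TandemUTR", "g.t0", "+")]

    reads = simulate_reads(Ann(), {"g": 1.0}, {"g": 0.6}, depth=100_000, seed=4)
    evs = alt.derive_events(Ann.transcripts)
    _, psis = alt.quantify_events(evs, reads)
    (est,) = psis.values()
    assert est.psi == pytest.approx(0.6, abs=0.03)


def test_event_counts_match_poisson_expectation():
    """Monte-Carlo oracle: inclusion/exclusion read counts fall within 4 sigma
    of their analytic Poisson means for a single deep SE gene."""
    ann = simulate_annotation(n_genes=1, events_per_type={"SE": 1}, seed=9,
                              intron_len_range=(300, 300), exon_len_range=(150, 150))
    gene = ann.event_genes[0].gene_id
    depth, psi = 50_000, 0.5
    reads = simulate_reads(ann, {gene: 1.0}, {gene: psi}, depth=depth, seed=10)
    evs = alt.derive_events(ann.transcripts)
    counts = alt.count_event_reads(evs, reads)[evs[0].event_id]
    # reads per transcript position, split psi/(1-psi) between isoforms
    L_inc = sum(e - s for t in ann.transcripts for s, e in t.exons
                if t.transcript_id == ann.event_genes[0].inclusion_transcript)
    tx = {t.transcript_id: t.length for t in ann.transcripts}
    inc_t = ann.event_genes[0].inclusion_transcript
    (exc_t,) = [k for k in tx if k != inc_t]
    w_inc = psi * (tx[inc_t] - 38)
    w_exc = (1 - psi) * (tx[exc_t] - 38)
    rate_inc = depth * w_inc / (w_inc + w_exc) / (tx[inc_t] - 38)
    rate_exc = depth * w_exc / (w_inc + w_exc) / (tx[exc_t] - 38)
    mu_inc = rate_inc * counts.inc_positions
    mu_exc = rate_exc * counts.exc_positions
    assert abs(counts.inc_reads - mu_inc) < 4 * np.sqrt(mu_inc)
    assert abs(counts.exc_reads - mu_exc) < 4 * np.sqrt(mu_exc)


def test_rpkm_definition_and_invariance():
    assert alt.compute_rpkm(1000, 1000, 1_000_000) == pytest.approx(1000.0)
    assert alt.compute_rpkm(0, 1000, 1_000_000) == 0.0
    # frozen hand computation: 437 / (2.5 kb) / (27.3 M reads)
    assert alt.compute_rpkm(437, 2500, 27_300_000) == pytest.approx(6.402930402930402)
    # duplicating every read while doubling the library leaves RPKM unchanged
    assert alt.compute_rpkm(874, 2500, 54_600_000) == pytest.approx(
        alt.compute_rpkm(437, 2500, 27_300_000))
    with pytest.raises(ValueError):
        alt.compute_rpkm(1, 0, 100)
    with pytest.raises(ValueError):
        alt.compute_rpkm(1, 100, 0)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.integers(0, 10_000),
       st.integers(100, 10_000), st.integers(10, 1000))
def test_psi_always_within_unit_interval(inc, exc, ip, ep):
    est = alt.estimate_psi(EventReadCounts("x", inc, exc, ip, ep))
    if est.psi is not None:
        assert 0.0 <= est.psi <= 1.0


def test_sam_split_read_parsing(tmp_path):
    sam = tmp_path / "reads.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chrT\tLN:1000\n"
        "r1\t0\tchrT\t81\t60\t20M100N19M\t*\t0\t0\t" + "A" * 39 + "\t*\n"
        "r2\t256\tchrT\t1\t60\t39M\t*\t0\t0\t" + "A" * 39 + "\t*\n"  # secondary
        "r3\t0\tchrT\t201\t60\t39M\t*\t0\t0\t" + "A" * 39 + "\t*\n"
    )
    reads = asio.read_sam(sam)
    assert len(reads) == 2
    assert reads[0].blocks == ((80, 100), (200, 219))
    assert reads[1].blocks == ((200, 239),)


def test_bed12_round_trip(tmp_path):
    reads = [
        ReadPlacement("chrT", ((80, 100), (200, 219)), "+"),
        ReadPlacement("chrT", ((5, 44),), "-"),
    ]
    path = tmp_path / "reads.bed"
    asio.write_bed12(reads, path)
    back = asio.read_bed12(path)
    assert [r.blocks for r in back] == [r.blocks for r in reads]
    assert [r.strand for r in back] == ["+", "-"]


def test_gene_read_counting_and_expression(experiment, catalog):
    from altsplice.events import group_by_gene
    genes = group_by_gene(experiment.annotation.transcripts)
    const = {g: (ts[0].chrom, alt.constitutive_exons(ts)) for g, ts in genes.items()}
    const = {g: v for g, v in const.items() if v[1]}
    reads = experiment.reads["cond1"]
    counts = alt.count_gene_reads(const, reads)
    lengths = {g: sum(e - s for s, e in ivs) for g, (_, ivs) in const.items()}
    table = alt.expression_table(counts, lengths, total_mapped_reads=len(reads))
    # deeper-expressed genes get higher RPKM: expression rank correlation
    expr = experiment.expression["cond1"]
    got = [table[g].rpkm for g in table]
    want = [expr[g] for g in table]
    assert np.corrcoef(np.argsort(np.argsort(got)), np.argsort(np.argsort(want)))[0, 1] > 0.8
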