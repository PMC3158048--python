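import pytest

import altsplice as alt
from altsplice import simulate as sim
from altsplice.models import TranscriptModel


def tm(gene, tid, strand, exons, chrom="chrT"):
    return TranscriptModel(gene_id=gene, transcript_id=tid, chrom=chrom,
                           strand=strand, exons=tuple(exons))


@pytest.fixture(scope="session")
def experiment():
    """Standard planted two-condition experiment (90 genes, 10 events/type,
    2e5 reads per condition)."""
    return sim.simulate_experiment(seed=20, depth=200_000)


@pytest.fixture(scope="session")
def catalog(experiment):
    return alt.derive_events(experiment.annotation.transcripts)


@pytest.fixture(scope="session")
def quantified(experiment, catalog):
    out = {}
    for cond in ("cond1", "cond2"):
        out[cond] = alt.quantify_events(catalog, experiment.reads[cond])
    return out
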