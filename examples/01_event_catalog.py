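"""Derive an alternative-isoform event catalog from gene annotation.

Generates a synthetic annotation with ten planted events of each of the
eight types, derives the catalog from transcript pairs, and writes it as
TSV and GFF3.
"""
import collections
import tempfile
from pathlib import Path

import altsplice as alt
from altsplice import io as asio
from altsplice.simulate import STANDARD_EVENTS_PER_TYPE, simulate_annotation

ann = simulate_annotation(n_genes=90, events_per_type=STANDARD_EVENTS_PER_TYPE, seed=1)
events = alt.derive_events(ann.transcripts)

counts = collections.Counter(e.event_type for e in events)
print("derived events per type (planted: 10 of each):")
for etype in alt.EVENT_TYPES:
    print(f"  {etype:<10} {counts.get(etype, 0)}")

ex = next(e for e in events if e.event_type == "SE")
print(f"\nexample skipped exon {ex.event_id}")
print(f"  inclusion signature: {sorted(ex.iso1_segments)}")
print(f"  exclusion signature: {sorted(ex.iso2_segments)}")
print("  (inclusion = alternative exon body + its two junctions;")
print("   exclusion = the single skipping junction)")

out = Path(tempfile.mkdtemp())
asio.write_event_catalog(events, out / "catalog.tsv")
asio.write_events_gff3(events, out / "catalog.gff3")
print(f"\ncatalog written to {out}/catalog.tsv and .gff3")
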