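"""Quantify percent-spliced-in (Ψ) from simulated 39-bp read placements.

Ψ is the ratio of inclusion-read density to the sum of inclusion and
exclusion densities, where density = reads per distinct mappable start
position.  The simulation plants a true Ψ per event, so the printout shows
estimate vs truth.
"""
import numpy as np

import altsplice as alt
from altsplice.simulate import simulate_experiment

exp = simulate_experiment(seed=2, depth=200_000)
events = alt.derive_events(exp.annotation.transcripts)
counts, psis = alt.quantify_events(events, exp.reads["cond1"])

print(f"{len(exp.reads['cond1'])} reads quantified over {len(events)} events\n")
print("event type   true Ψ   est Ψ   inc/exc reads")
shown = set()
errs = []
for ev in events:
    est = psis[ev.event_id]
    true = exp.psi["cond1"].get(ev.gene_id)
    if est.psi is None or true is None:
        continue
    errs.append(abs(est.psi - true))
    if ev.event_type not in shown:
        shown.add(ev.event_type)
        c = counts[ev.event_id]
        print(f"{ev.event_type:<10}   {true:.3f}    {est.psi:.3f}   "
              f"{c.inc_reads}/{c.exc_reads}")

print(f"\nmean |Ψ̂ - Ψ| over {len(errs)} events: {np.mean(errs):.4f}")
print("(sampling error ≈ 0.02-0.03 at the fixture depth of ~800 "
      "informative reads per event)")
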