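"""Simulate digestion and overlap assembly, including the LoxP failure mode.

Three scenarios: (1) a unique-site plasmid is digested with AgeI and
re-assembled, restoring the original circle; (2) three fragments with
unique 30-bp overlaps assemble into one product regardless of input order;
(3) fragments whose termini all carry the 34-bp LoxP site are refused with
a hazard report -- repeated overlaps make the junctioning ambiguous, which
is why removable selectable markers break one-step assembly.
"""

import numpy as np

from donorforge import (
    DEFAULT_ENZYMES, LOXP, Fragment, HazardReport, circular_equal,
    detect_hazards, digest, gibson_assemble, plan_assembly,
)

rng = np.random.default_rng(7)
rand = lambda n: "".join(rng.choice(list("ACGT"), size=n))
AgeI = DEFAULT_ENZYMES["AgeI"]

# 1. digest + re-assemble round trip
plasmid = AgeI.site + rand(1200).replace(AgeI.site, "ATATAT")
frag = digest(plasmid, AgeI, circular=True)[0]
print(f"digest: 1 fragment of {len(frag.seq)} bp, "
      f"{frag.end5.kind} overhang {frag.end5.seq!r} on both ends")
product = gibson_assemble([frag])
print(f"re-assembled == original plasmid: {circular_equal(product.seq, plasmid)}\n")

# 2. unique 30-bp overlaps -> one product
o = [rand(30) for _ in range(3)]
frags = [Fragment(o[i] + rand(150) + o[(i + 1) % 3], label=f"F{i}") for i in range(3)]
product = gibson_assemble(frags)
print(f"unique overlaps: circular product of {len(product.seq)} bp, "
      f"junctions {[j['overlap'] for j in product.junctions]} bp\n")

# 3. LoxP-flanked marker -> ambiguous
loxp_frags = [Fragment(LOXP + rand(120) + LOXP, label=n) for n in ("SM", "FP", "vec")]
report = gibson_assemble(loxp_frags)
assert isinstance(report, HazardReport)
print(f"LoxP-terminal fragments: {len(report.ambiguous_junctions)} ambiguous "
      f"junctions, {report.alternative_products} alternative products")
print(f"quick terminal scan agrees: "
      f"{not detect_hazards(loxp_frags, k=15).is_empty}\n")

# choose a route for a hard target: skewed arms + removable marker
plan = plan_assembly(arm5_gc=72.8, arm3_gc=60.5, if_has_loxp_sm=True)
print(f"assembly plan: {plan.mode}, triggered by {plan.rationale}")
for step in plan.steps:
    print(f"  {step.op:<7}{step.enzyme or ''}  {', '.join(step.fragments)}")
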