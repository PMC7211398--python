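"""Build an sgRNA recognition site and insert it on both sides of the IF.

The recognition site is the 20-nt sgRNA target plus its 3' NGG PAM (23 nt
total).  Flanking the inserted fragment with two copies -- placed just
inside the AgeI and XhoI loci so both restriction sites stay intact --
lets Cas9 release the repair template in the cell, which raises HDR
efficiency.
"""

import numpy as np

from donorforge import DEFAULT_ENZYMES, insert_flanking_sites, make_sgrna_site

site = make_sgrna_site("AAGCTGGCTGACATGTACGG", "AGG")  # the CDH1 target
print(f"sgRNA recognition site ({len(site)} nt): {site}")

rng = np.random.default_rng(3)
def rand(n):
    while True:
        s = "".join(rng.choice(list("ACGT"), size=n))
        if "ACCGGT" not in s and "CTCGAG" not in s:
            return s

donor = "ACCGGT" + rand(40) + rand(700) + rand(40) + "CTCGAG" + rand(1200)
product = insert_flanking_sites(
    donor, site, DEFAULT_ENZYMES["AgeI"], DEFAULT_ENZYMES["XhoI"]
)
print(f"donor {len(donor)} bp -> {len(product)} bp "
      f"(+{len(product) - len(donor)} = 2 x {len(site)} nt)")
print(f"both copies present: {product.count(site) == 2}; "
      f"AgeI/XhoI loci preserved: "
      f"{product.count('ACCGGT') == 1 and product.count('CTCGAG') == 1}")
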