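"""Design ranked linker pairs against a (synthetic) reference genome.

Generates a seeded 100-kb reference, enumerates 30-bp linker-pair
candidates for the default eight-enzyme layout, screens them, ranks
survivors by longest exact substring shared with the genome (lower is
better: the linker is less likely to misprime or misassemble), and prints
the top pairs plus the 60-bp arm-amplification primers for the best pair.
"""

import numpy as np

from donorforge import build_index, design_primers, run_pipeline, salt_adjusted_tm

rng = np.random.default_rng(17)
genome = "".join(rng.choice(list("ACGT"), size=100_000))
index = build_index([("ref", genome)], k=8)

result = run_pipeline(index, mode="sampled", seed=17, max_candidates=2000, top=5)
print(f"candidates emitted: {result.stats['emitted']}, "
      f"passed screening: {result.stats['passed']}\n")
print("rank  identity  linker_a                        linker_b")
for p in result.pairs:
    print(f"{p.rank:>4}  {p.identity.longest_shared_substring:>8}  "
          f"{p.linker_a}  {p.linker_b}")

best = result.pairs[0]
annealing = genome[2000:2030]  # stand-in for a homology-arm annealing segment
print(f"\nbest pair Tm: a={salt_adjusted_tm(best.linker_a):.1f} C, "
      f"b={salt_adjusted_tm(best.linker_b):.1f} C")
print("5' arm forward primer (linker tail + annealing, 60 bp):")
print(" ", design_primers(annealing, best.linker_a, "5p"))
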