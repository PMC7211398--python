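"""Screen single oligos against the six PCR adverse factors.

Builds one clean linker and one deliberately bad oligo, runs the full
screen, and prints what failed.  A report that "passed" means the oligo has
no hairpin stem, no self-dimer run, a Tm inside the window, balanced GC, no
repeats and no GC clamp at either terminus.
"""

from donorforge import FilterThresholds, screen_sequence, salt_adjusted_tm, gc_percent

good = "ACCGGTAGGCTAGCAAGTCGACCTGGATCC"   # a surviving default-layout linker a
bad = "GCGCAAAAAGCGCATATATATGGGGGGCGC"     # hairpin + repeats + clamp by construction

for name, seq in (("good", good), ("bad", bad)):
    report = screen_sequence(seq, FilterThresholds())
    print(f"{name}: {seq}")
    print(f"  GC = {gc_percent(seq):.1f}%  Tm = {salt_adjusted_tm(seq):.2f} C")
    if report.passed:
        print("  PASSED all six filters")
    else:
        for f in report.failures:
            print(f"  FAILED {f.filter_name}: span {f.offending_span}, "
                  f"measured {f.measured_value}")
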