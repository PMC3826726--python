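"""Simulate a ground-truthed strain pair and scan it for integrative elements.

Builds two synthetic strains from a common ancestor (seven implanted
elements each: prophage, ICEs, an IME and several genomic islands), runs
the integrase-anchored scanner on strain A and prints the element table
next to the simulator's ground truth.
"""

from mgescan import default_config, simulate_strain_pair
from mgescan.pipeline import scan_genome

pair = simulate_strain_pair(default_config(seed=1))
elements, report = scan_genome(pair.genome_a)

print(report[["MGE_ID", "type", "start", "end", "size_bp", "orf_count",
              "gc_percent", "att", "dr"]].to_string(index=False))
print()
truth = sorted(pair.truth_for("A"), key=lambda t: t.start)
exact = sum((t.start, t.end) in {(e.start, e.end) for e in elements}
            for t in truth)
print(f"{len(elements)} elements called; {exact}/{len(truth)} truth extents "
      "matched exactly.")
print("Each row is one called element: its class (from cargo modules), "
      "genomic extent, ORF count, G+C% (cargo is ~57% vs a 61% chromosome), "
      "the att target tRNA and the detected direct-repeat lengths.")
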