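"""Composite recipes: hierarchical removal and merge-and-refine.

Hierarchical removal runs one motif library at a time, least important
first: removing one site type can create sites of another, so the most
important library goes last and is guaranteed clean. Merge-and-refine
concatenates independently designed pieces and refines the whole, removing
sites created at the junctions.
"""

import numpy as np

import sitefree as sf

cfg = sf.OptimizerConfig(seed=5)
lib_minor = sf.MotifLibrary(exact_sets=(sf.ExactSiteSet("minor", ("GACTTC",)),))
lib_major = sf.MotifLibrary(exact_sets=(sf.ExactSiteSet("major", ("GAATTC",)),))

seq = ("GAATTC" + "ACG" * 5 + "GACTTC" + "CGT" * 5) * 2
result = sf.hierarchical_removal(seq, [("minor", lib_minor), ("major", lib_major)], cfg)
print("hierarchical removal:")
for name, hits in result.residual_by_library.items():
    print(f"  residual {name} sites : {len(hits)}")

# merge-and-refine: two individually clean pieces whose junction spells a
# site of the major library
a, b = "ACCGGCACCGGAA", "TTCGGCACCGGC"
merged = sf.merge_and_refine([a, b], lib_major, sf.OptimizerConfig(seed=2))
print("merge and refine:")
print(f"  junction sites before : {merged.initial_n}")
print(f"  junction sites after  : {merged.final_n}  (converged={merged.converged})")

# The major library ends with zero residual sites because its pass runs
# last; the minor library's count is reported but not guaranteed to be zero.
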