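"""Enumerate the full factorial design over the packaged hyperparameter space.

The space holds scDblFinder's three tuned hyperparameters — nf (highly
variable genes), pc (principal components), depth (maximum tree depth) —
each at five levels centered on the method default.
"""

import dbltune as dt

space = dt.scdblfinder_space()
design = dt.full_factorial(space)

print(f"factors: {space.factor_names}")
print(f"defaults: {dt.default_point(space)}")
print(f"design size: {len(design)} points (5 x 5 x 5)")
print(f"first point: {design[0]}")
print(f"last point:  {design[-1]}")
# Every combination of the 5-level grids appears exactly once; the design is
# the experiment plan on which detection accuracy is collected.
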