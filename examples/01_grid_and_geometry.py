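"""Cell geometry on the common grid.

Builds the global 0.05-degree grid, computes spherical cell areas and the
land available for cropping after excluding non-croppable cover classes.
"""
import numpy as np

from cropfuse import GridSpec, cell_area, compute_LA

spec = GridSpec(resolution=0.05)
GA = cell_area(spec)
print(f"grid: {spec.n_rows} x {spec.n_cols} cells")
print(f"cell area at the equator: {GA[spec.n_rows // 2, 0]:,.0f} ha")
print(f"cell area at 60N: {GA[int((90 - 60) / 0.05), 0]:,.0f} ha")
# a third of each cell is water/urban/barren -> land available for cropping
LA = compute_LA(GA, np.full(spec.shape, 1 / 3))
print(f"LA/GA ratio: {LA.sum() / GA.sum():.3f}")
# The equatorial cell is ~3,000 ha and shrinks with the cosine of latitude;
# LA is the per-cell ceiling later enforced on total physical crop area.
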