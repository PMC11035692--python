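"""Harmonizing the four input variable conventions.

Generates a synthetic world and shows how a binary-presence layer at 4x
finer resolution and a coarse harvested-area layer both become (HA, CA)
pairs on the common grid.
"""
from cropfuse import gen_world
from cropfuse.pipeline import harmonize_all

world = gen_world()
harmonized = harmonize_all(world)
truth = world.truth["wheat"].HA.sum()
print(f"truth national+global wheat HA: {truth:,.0f} ha")
for rec in world.datasets:
    kind = rec.layers["wheat"].kind
    got = harmonized[rec.acronym]["wheat"].HA.sum()
    print(f"{rec.acronym:8s} (kind={kind:5s}, countries={rec.countries}): "
          f"harmonized wheat HA = {got:,.0f} ha")
# The noise-free full-convention dataset reproduces truth exactly over its
# covered countries; fraction/binary datasets impute HA = CA (one harvest),
# and the coarse legacy layer is conservatively regridded.
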