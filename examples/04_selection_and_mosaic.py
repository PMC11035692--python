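"""Multi-criteria selection and the per-crop mosaic.

Runs the scoring and selection stages on a synthetic world and prints the
winner per (crop, country) with its combined score.
"""
from cropfuse import gen_world
from cropfuse.pipeline import run_pipeline

world = gen_world()
result = run_pipeline(world, adjust=False)
print(result.mosaic.table.to_string(index=False))
# "selected" rows copy the winning dataset's layers for that country;
# "gapfill" rows mark legacy-only pairs resolved from subnational
# statistics in the next stage.  Q combines seven metadata indicators
# (weight 1/3 jointly) with map agreement and statistics agreement
# (1/3 each).
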