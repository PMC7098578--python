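"""The whole chain in one call, plus where every product lands on disk.

simulate -> grain metrics -> spatial adjustment -> descriptive stats ->
LOCO mixed-model scan -> QTL intervals -> driven/specific classification
-> report.json.  Identical seeds give byte-identical reports.
"""

import json

from grainvar import RunConfig, run_all

cfg = RunConfig(outdir="scratch/example_full", seed=1)
report = run_all(cfg)

print(json.dumps(report["stages"], indent=1, sort_keys=True))
print("\nproducts in", cfg.outdir)
# Key numbers to look at in the stage summary: n_significant (GWAS hits at
# LOD>3 across traits), n_qtl (merged GSV intervals), n_specific vs
# n_driven (the split of GSV QTL by yield-component colocalisation).
# The same chain is available from the shell:
#   grainvar all --seed 1 --out scratch/example_full_cli
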