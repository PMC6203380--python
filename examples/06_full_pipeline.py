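"""Run the whole chain on one coherent synthetic study and print the report.

The planted fly modifiers map to the human genes carrying the planted
tumor-downregulation, which annotate a dedicated term and drive the planted
survival split — so every stage should rediscover the same gene set.
"""

import tempfile

from crosstum import PipelineConfig, SimConfig, report, run_pipeline

cfg = PipelineConfig(
    seed=11,
    n_samplings=10_000,
    sim=SimConfig(seed=11, n_lines=619, n_genes=619, hit_fraction=0.08),
)
with tempfile.TemporaryDirectory() as tmp:
    run_pipeline(cfg, tmp)
    print(report(tmp, make_plots=False))
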