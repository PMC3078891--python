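"""Shared configuration for the analysis drivers.

One two-tissue synthetic experiment at the study design (6 hibernating vs
5 summer bears, 3,200-spot arrays, ~5% truly changed genes), analysed in
place under results/pipeline by the numbered scripts.
"""

from pathlib import Path

from hibexpr import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def config() -> PipelineConfig:
    return PipelineConfig(outdir=str(RESULTS / "pipeline"), seed=1)
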