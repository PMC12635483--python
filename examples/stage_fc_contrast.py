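"""Sliding-window network FC by sleep stage, and the REM-vs-Wake
intra-thalamic contrast with mixed-effects inference.

Run:  python examples/stage_fc_contrast.py      (about a minute)
"""

import warnings

from somnidyn.pipeline import PipelineConfig, run_pipeline
from somnidyn.synthetic import scaled_config

cfg = PipelineConfig(K=6, seed=7, generator=scaled_config(4, 1200, 7))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_pipeline(cfg)

print("Per-participant intra-thalamic connection (Fisher-z) by stage:")
print(report.intra_thalamic.round(3).to_string())
print(
    "\nHigher values during REM reflect the generating covariances, where"
    "\nthalamic subnetworks couple more strongly to each other in REM."
)

rem = report.lme_table[report.lme_table["stage"] == "REM"]
intra = rem[
    rem["network_a"].str.startswith("THAL")
    & rem["network_b"].str.startswith("THAL")
    & (rem["network_a"] != rem["network_b"])
]
print(
    f"\nLME REM-vs-Wake contrast over the 10 thalamic-subnetwork pairs:"
    f"\n  mean estimate {intra['estimate'].mean():+.3f} z"
    f" | FWE-significant (Bonferroni/190): "
    f"{int(intra['fwe_significant'].sum())}/10 pairs"
)
print(
    "A positive, significant contrast means windows scored as REM carry"
    "\nreliably stronger intra-thalamic coupling than Wake windows."
)
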