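"""Generate one synthetic night and extract the sleep episodes eligible
for dynamic-FC analysis.

Run:  python examples/simulate_and_segment.py
"""

import collections

from somnidyn import load_atlas
from somnidyn.segmentation import episodes_to_table, segment_episodes
from somnidyn.synthetic import GeneratorConfig, simulate_night

atlas = load_atlas("bundled")
cfg = GeneratorConfig(n_participants=1, night_trs=3200, seed=42)
night = simulate_night(cfg, atlas, 0)

counts = collections.Counter(night.hypnogram.epoch_stages)
print("Night of", night.hypnogram.n_epochs, "30-s epochs; stage occupancy:")
for stage, n in counts.most_common():
    print(f"  {stage:5s} {n:4d} epochs ({n / night.hypnogram.n_epochs:.0%})")

episodes = segment_episodes(night.hypnogram, min_epochs=3)
print(f"\n{len(episodes)} episodes of >= 3 consecutive same-stage epochs")
print("(only these, 90 s or longer, admit stage-pure 30-TR FC windows):")
print(episodes_to_table(episodes).to_string(index=False))
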