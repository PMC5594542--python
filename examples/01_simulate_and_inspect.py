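"""Generate one synthetic subject and inspect the graded ERD it carries.

Builds the five-session recordings for one simulated subject, then
measures the mu-band (8-13 Hz) power at C3 during motor imagery relative
to the pre-cue baseline, split by imagined force load. The power ratio
should fall with the load: high-load imagery attenuates the sensorimotor
rhythm the most, relaxed trials not at all.
"""

import numpy as np
from scipy import signal

from mfload import GeneratorConfig, plan_sessions, synthesize_recording
from mfload.preprocess import select_channels

cfg = GeneratorConfig()
plans = plan_sessions(seed=0)

ratios = {"high": [], "low": [], "relaxed": []}
for plan in plans[:4]:  # sessions 1-4 cover all three loads
    rec = synthesize_recording(plan, cfg, seed=0)
    eeg = select_channels(rec)
    c3 = eeg.data[eeg.labels.index("C3")]

    def mu_power(i0, i1):
        f, p = signal.welch(c3[i0:i1], fs=cfg.fs, nperseg=512)
        return p[(f >= 8) & (f <= 13)].mean()

    for _, ev in rec.events[rec.events["segment"] == "MI"].iterrows():
        i_on = int(ev["onset_s"] * cfg.fs)
        task = mu_power(i_on, i_on + int(6 * cfg.fs))
        base = mu_power(i_on - int(2 * cfg.fs), i_on)
        ratios[ev["label"]].append(task / base)

print("C3 mu-band power, motor imagery / baseline:")
for load in ("high", "low", "relaxed"):
    r = np.mean(ratios[load])
    print(f"  {load:8s} ratio = {r:.2f}  ({len(ratios[load])} trials)")
print()
print("A ratio of ~0.25 for 'high' matches the configured 50% amplitude")
print("attenuation ((1-0.5)^2); 'relaxed' stays near 1 (no ERD).")
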