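"""Signal conditioning and the two motion-scrubbing rules.

Shows drift removal (Savitzky-Golay + 0.01 Hz high-pass) on a corrupted
series, and compares ordinary (union) scrubbing with percentage-based
scrubbing across 30 sessions.
"""

import numpy as np

from densefc import clean, synth

rng = np.random.default_rng(23)
tr = 0.594
t = np.arange(1000) * tr

signal = np.sin(2 * np.pi * 0.08 * t)                     # physiological band
drift = 0.004 * t + 0.5 * np.sin(2 * np.pi * 0.002 * t)   # scanner drift
noisy = signal + drift + 0.1 * rng.standard_normal(1000)

cleaned = clean.clean_session(noisy[:, None], tr)[:, 0]
resid_drift = np.corrcoef(cleaned, drift)[0, 1]
kept_signal = np.corrcoef(cleaned, signal)[0, 1]
print(f"correlation with drift after cleaning:  {resid_drift:+.3f}")
print(f"correlation with signal after cleaning: {kept_signal:+.3f}")

cfg = synth.SynthConfig(n_sessions=30, n_days=133, n_time=1000, seed=23)
fd = np.stack(synth.gen_fd(cfg, spike_prob=0.05))
flags = np.stack([clean.flag_volumes(v, 0.2) for v in fd])
union = clean.scrub_union(flags)
pct10 = clean.scrub_percentage(flags, 0.10)
pct05 = clean.scrub_percentage(flags, 0.05)
print(f"volumes censored of 1000 - union: {union.n_censored}, "
      f"pct 5%: {pct05.n_censored}, pct 10%: {pct10.n_censored}")
print("-> union scrubbing censors a volume flagged (FD > 0.2 mm) in ANY of")
print("   the 30 sessions; the percentage rules need >= 2 (5%) or >= 3 (10%)")
print("   flagged sessions, trading strictness for retained volumes")
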