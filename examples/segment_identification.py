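"""Between-days time-segment identification on movie-like runs.

Every session shares a stimulus-locked response plus day-specific noise;
the leave-one-session-out classifier matches held-out 25-TR segments to
their position by correlation with cross-session average templates.
"""

import numpy as np

from densefc import segclass

rng = np.random.default_rng(17)
n_vol, n_rois, n_sessions = 970, 3, 6

stimulus = rng.standard_normal((n_vol, n_rois))
snrs = [2.0, 1.0, 0.5]
for snr in snrs:
    sessions = [
        snr * stimulus + rng.standard_normal((n_vol, n_rois))
        for _ in range(n_sessions)
    ]
    sets = [segclass.make_segments(s, window=25, step=1) for s in sessions]
    acc = segclass.loo_identify(sets)
    chance = segclass.chance_level(sets[0].n_segments)
    print(f"SNR {snr:3.1f}: {sets[0].n_segments} segments, "
          f"accuracy {acc.mean():.3f} (chance {chance:.5f})")
print("-> a 970-volume run gives 946 overlapping 25-TR segments (14.85 s at")
print("   TR 0.594 s); identification accuracy far above 1/946 means the")
print("   day's response reliably re-expresses the shared stimulus pattern")
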