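"""Lagged cross-correlation with phase-randomized surrogate significance.

A coupling at lag 7 is injected between restless sleep and one link's
generating correlation; the surrogate test should place the strongest,
most significant correlation at exactly that lag.
"""

import numpy as np
import pandas as pd

from densefc import lagcorr, synth

TRUE_LAG = 7

cfg = synth.SynthConfig(n_sessions=30, n_days=133, n_rois=8, n_networks=2,
                        n_time=800, missing_fraction=0.0, seed=9)
atlas = synth.gen_atlas(8, 2, seed=9)
behav = synth.gen_behavior(cfg)
effect = synth.EffectSpec(target_links=[(0, 2)], factor_name="restless",
                          lag_days=TRUE_LAG, slope=0.5, base_corr=0.2)
sessions, _ = synth.gen_sessions(cfg, atlas, behav, [effect])

link_z = [
    np.arctanh(np.corrcoef(s.data[:, 0], s.data[:, 2])[0, 1]) for s in sessions
]
metric = pd.Series(link_z, index=cfg.session_days)

result = lagcorr.surrogate_test(metric, behav.truth["restless"],
                                n_surr=2000, seed=9)
print(result[["lag", "rho", "p"]].to_string(index=False,
                                            float_format=lambda v: f"{v:.4f}"))
best = result.loc[result["rho"].abs().idxmax()]
print(f"strongest correlation at lag {int(best['lag'])} "
      f"(rho={best['rho']:.3f}, p={best['p']:.4f}); injected lag: {TRUE_LAG}")
print("-> surrogates keep each factor's spectrum (and autocorrelation) but")
print("   destroy its coupling to the brain series, so p reflects the lag-")
print("   specific association only")
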