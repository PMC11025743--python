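"""Compare the three OPS wavelength-selection strategies on a known signal.

100 predictor variables, of which only columns 40-49 carry the response;
all three searches use windows of 10, increments of 5 and a fixed seeded
10%-segment cross-validation partition.  A good selection finds (most of)
the informative block and never cross-validates worse than the full
spectrum on the same partition.
"""

import numpy as np

import silcal as sc
from silcal.opsselect import OPSConfig
from silcal.plsmodel import make_segments

rng = np.random.default_rng(0)
n, p = 60, 100
X = rng.normal(size=(n, p))
informative = np.arange(40, 50)
beta = np.zeros(p)
beta[informative] = 1.0
y = X @ beta + rng.normal(0, 0.05, n)

cfg = OPSConfig(seed=1)
segments = make_segments(n, cfg.seed)
for name, search in [("autoOPS", sc.ops_auto), ("feedOPS", sc.ops_feed),
                     ("iOPS", lambda X, y, c, segments: sc.ops_intervals(
                         X, y, sc.OPSConfig(seed=1, interval_min_vars=50), segments=segments))]:
    res = search(X, y, cfg, segments=segments)
    hits = np.intersect1d(res.selected_vars, informative).size
    print(f"{name:8s} selected {res.selected_vars.size:3d} vars "
          f"({hits}/10 informative), RMSECV {res.rmsecv:.4f} "
          f"(full spectrum {res.rmsecv_full:.4f}), nlv {res.chosen_nlv}")
# RMSECV(selected) <= RMSECV(full) always: the full spectrum is a candidate
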