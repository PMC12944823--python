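#!/usr/bin/env python
"""Calibrate the ESOL normalization window from the reference component rows.

The composite score maps the raw ESOL estimate (log10 mol/L) onto [0, 1]
with an affine clamp.  The window endpoints are not published; this script
back-solves them.  For each reference row the published composite and the
published confidence/SA/QED components pin down what the normalized ESOL
term must have been:

    esol_norm = (composite - w_conf*conf - w_sa*sa_norm - w_qed*qed) / w_esol

(with SA below the threshold, sa_norm = 1).  A least-squares affine fit of
esol_norm against the raw ESOL values over the three rows yields the window
frozen as ``DEFAULT_ESOL_WINDOW`` in mclig.scoring.

Run:  python scripts/calibrate_normalization.py
"""

import numpy as np

from mclig.fixtures import REFERENCE_COMPONENT_ROWS
from mclig.scoring import CompositeWeights, normalize_sa

w = CompositeWeights()
x, y = [], []
for row in REFERENCE_COMPONENT_ROWS:
    sa_norm = normalize_sa(row.sa_raw)
    needed = (
        row.composite - w.w_conf * row.confidence - w.w_sa * sa_norm
        - w.w_qed * row.qed
    ) / w.w_esol
    x.append(row.esol_raw)
    y.append(needed)
    print(f"esol_raw {row.esol_raw:8.3f}  implied esol_norm {needed:.4f}")

A = np.vstack([x, np.ones(len(x))]).T
(slope, intercept), *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
lo = -intercept / slope
hi = lo + 1.0 / slope
print(f"\naffine fit: esol_norm = {slope:.5f} * esol + {intercept:.5f}")
print(f"window: lo = {lo:.3f}, hi = {hi:.3f}")

for row in REFERENCE_COMPONENT_ROWS:
    esol_norm = min(1.0, max(0.0, (row.esol_raw - lo) / (hi - lo)))
    pred = (
        w.w_conf * row.confidence + w.w_sa * normalize_sa(row.sa_raw)
        + w.w_esol * esol_norm + w.w_qed * row.qed
    )
    print(
        f"composite: predicted {pred:.4f}  published {row.composite:.3f}  "
        f"|err| {abs(pred - row.composite):.4f}"
    )
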