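"""Simulate both cine acquisitions on the dynamic phantom.

Renders the ground-truth cine, acquires it with the segmented reference
sequence under a regular and an irregular rhythm, and with the single-shot
real-time compressed-sensing sequence, then prints frame RMSE against truth.
With a regular rhythm the segmented arm is exact; under arrhythmia it
degrades, while the real-time arm is unaffected by RR variability.
"""

import numpy as np

from arrcine import (
    AcquisitionParams,
    ArrhythmiaSpec,
    PhantomSpec,
    RRSeries,
    generate_rr,
    simulate_realtime,
    simulate_segmented,
    temporal_interpolate,
    truth_stack,
)

phantom = PhantomSpec()  # 168-px matrix, bright blood / dark myocardium
truth = truth_stack(phantom, 20)
ref = AcquisitionParams.reference()  # 20 phases x 41.2 ms, 13 views/frame

regular = RRSeries(np.full(16, 824.0))  # 824 ms = 20 x 41.2 ms exactly
afib = generate_rr(ArrhythmiaSpec(824.0, "afib", 25.0, 64, seed=3))

for name, rr in [("regular", regular), ("afib CV 25%", afib)]:
    seg = simulate_segmented(phantom, AcquisitionParams.reference(seed=1), rr)
    n = seg.n_frames
    rmse = np.sqrt(np.mean((seg.frames - truth.frames[:n]) ** 2))
    print(f"segmented, {name:12s}: {n:2d} frames, RMSE vs truth {rmse:.2e}")

rt = simulate_realtime(phantom, AcquisitionParams.realtime(seed=1), afib)
rt20 = temporal_interpolate(rt, 20)
rmse = np.sqrt(np.mean((rt20.frames - truth.frames) ** 2))
print(f"real-time, afib CV 25%  : {rt.n_frames:2d} measured frames "
      f"-> 20 interpolated, RMSE vs truth {rmse:.2e}")
# The segmented RMSE jumps by orders of magnitude under arrhythmia (phase
# mixing across heartbeats); the real-time error reflects only the 11-fold
# undersampled reconstruction and does not depend on the rhythm.
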