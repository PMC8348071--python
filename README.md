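# arrcine

**Why does segmented cardiac cine MRI fall apart in arrhythmia, and why is
single-shot real-time compressed-sensing cine immune?**  `arrcine` answers
this at the k-space level, with a tested simulation and analysis pipeline
for the paired comparison of the two sequences: RR-interval variability and
the irregularity criterion, a dynamic bright-blood phantom, both
acquisition schemes simulated mechanistically, the edge-spread-function
sharpness metric, the modified EuroCMR artifact score, and the paired
statistical battery.  It is written for MRI physicists and image-analysis
researchers who want the artifact mechanism and the quality metrics as
runnable, seedable code rather than scanner-bound observations.

## The science in brief

- **Irregularity**: a rhythm is irregular when the coefficient of variation
  of its RR intervals, CV_RR = 100·SD/mean (%), strictly exceeds 10%.
  Synthetic generators mimic atrial fibrillation (log-normal cycles),
  ectopy (short-coupled beats with compensatory pauses) and conduction
  pauses (dropped-beat doubling), moment-matched to a target CV_RR.
- **Segmented cine** splits each frame's k-space across many heartbeats
  (13 views/frame, interleaved segments, 41.2 ms/frame, 20 phases).  A
  frame is a fixed delay after the R peak, so under RR variability its
  segments come from different cardiac phases and — via the Frank–Starling
  preload response — from beats of different contraction amplitude.  The
  merged k-space then mixes inconsistent anatomies: ghosting and
  wall-border blurring (arrhythmia-related artifacts, ARA) emerge without
  being put in by hand.  With a regular rhythm the simulation reproduces
  the ground truth to machine precision.
- **Real-time CS cine** acquires every frame inside one heartbeat
  (49 ms/frame, 11× random variable-density undersampling, 12 centre
  lines), reconstructed by 40 iterations of temporal-Fourier
  soft-thresholding with data consistency.  No data cross heartbeats, so
  RR variability cannot mix phases — its error is undersampling-driven and
  flat in CV_RR.
- **Edge sharpness** ε = 1/d, where d is the distance between the 20% and
  80% crossings of the edge-spread function between local plateau extrema
  (pixel⁻¹; higher = sharper).  Exact on a linear ramp (ε = 1/6 over a
  10-px ramp) and within 1% of the closed form 1/(1.6832σ) on
  Gaussian-blurred steps.
- **Modified EuroCMR score** (items 1–8, max 10, higher = worse) and the
  **ARA rate** (percent of slices with blurring/ARA) score artifact burden;
  **Wilcoxon signed-rank** (exact under ties), **paired t**, **ICC(2,1)**
  and **Cohen's kappa** form the statistical layer.

## Worked example

```python
import numpy as np
from arrcine import (AcquisitionParams, ArrhythmiaSpec, PhantomSpec,
                     RRSeries, generate_rr, cv_rr, simulate_realtime,
                     simulate_segmented, truth_stack, wall_sharpness)
from arrcine.metrics import end_systole_index

phantom = PhantomSpec()                      # 168-px bright-blood annulus
truth   = truth_stack(phantom, 20)

afib = generate_rr(ArrhythmiaSpec(mean_rr=824, pattern="afib",
                                  target_cv=25, n_beats=64, seed=3))
print(f"CV_RR = {cv_rr(afib):.1f}%")         # CV_RR = 23.1%

seg = simulate_segmented(phantom, AcquisitionParams.reference(seed=1), afib)
rt  = simulate_realtime(phantom, AcquisitionParams.realtime(seed=1), afib)

es  = end_systole_index(truth)
tf  = truth.frames[es]
for name, stack in [("truth", truth), ("segmented", seg), ("real-time", rt)]:
    frame = stack.frame_at_phase(float(truth.phases[es]))
    print(f"{name:10s} end-systolic wall sharpness "
          f"{wall_sharpness(frame, reference=tf):.3f} px^-1")
```

prints (exact values depend on the seed):

```
CV_RR = 27.5%
truth      end-systolic wall sharpness 0.653 px^-1
segmented  end-systolic wall sharpness 0.274 px^-1
real-time  end-systolic wall sharpness 0.576 px^-1
```

Under a 27% CV_RR rhythm the segmented wall loses more than half its
sharpness to
cross-beat mixing while the single-shot arm stays close to its
undersampling-limited ceiling — the simulated counterpart of the clinical
finding that real-time CS cine suppresses arrhythmia-related artifacts.
The `examples/` directory walks through each capability: rhythm generation
(`01`), artifact simulation (`02`), sharpness measurement (`03`), scoring
and paired statistics (`04`), and the cohort runner plus the published
score-table reproduction (`05`).

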