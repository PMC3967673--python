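# gimotion

Quantitative gastrointestinal motility analysis for free-breathing
cine MRI.

Rapid abdominal MRI (≈0.7 s per frame) visualizes gastric emptying and
duodenal peristalsis without contrast agents or ionizing radiation, but
turning the image series into numbers requires dealing with respiratory
motion, converting sparse manual wall outlines into well-defined
contours, and summarizing wall motion in indices that survive
simultaneous extension and contraction. `gimotion` implements that
pipeline for researchers studying gastroduodenal physiology (e.g. the
effect of a meal additive or a prokinetic agent on emptying and
duodenal motility), together with digital motion phantoms that make
every stage testable against analytic ground truth.

## What it computes

* **Respiratory stabilization** — the whole-field translation `b_n`
  between successive frames minimizes the SSD energy
  `E(n, n+1) = (1/|χ|) Σ_{x∈χ} [I_n(x) − I_{n+1}(x + b)]²` over a region
  of interest χ by exhaustive integer search; cumulative shifts align
  every frame to frame 0.
* **Wall contours** — a periodic cubic spline through the manual seed
  points (20 for the gastric fundus, 30 for the duodenum), resampled at
  n = 100 equal arc-length points P(k), counterclockwise.
* **Gastric residual volume** — per scan, the sum over the
  meal-containing coronal planes of the frame-mean fundus area,
  normalized to the first scan (MS1 = 100%).
* **Motility indices** per structure and scan:
  * `DM(A)` = 100·SD(A)/mean(A) — percent area variability;
  * `DM(G)` — path length of the area centroid (mm), with the per-frame
    Y-shift trace `DG_Y(t)`;
  * `DM(V_N)`, `DM(V_T)` — mean absolute wall velocity (mm/s): the
    frame-to-frame displacement of P(k) divided by Δt, projected on the
    unit inward normal and counterclockwise tangent of the later
    frame's contour (inward and counterclockwise positive).
* **Paired condition contrasts** — classical two-sided paired t-tests
  across subjects.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

A duodenal phantom with a travelling contraction ring (depth 50%,
σ = 8 mm, 8 mm/s), rendered at 1.7 mm/px and analysed by the same code
path used for real data:

```python
from gimotion import DuodenumSpec, RespirationSpec, make_duodenum_phantom
from gimotion.pipeline import AnalysisConfig, analyze_stack

spec = DuodenumSpec(ring_depth=0.5,
                    respiration=RespirationSpec(amplitude_px=0.0),
                    noise_sigma=0.0, seed=7)
stack, seeds, truth = make_duodenum_phantom(spec)
result = analyze_stack(stack, seeds, AnalysisConfig(stabilize=False))

ix = result.indices
print(f"DM(A)   = {ix.dm_area:.2f} %")
print(f"DM(G)   = {ix.dm_gravity:.2f} mm")
print(f"DM(V_N) = {ix.dm_vn:.3f} mm/s   (ground truth {truth.dm_vn():.3f})")
print(f"DM(V_T) = {ix.dm_vt:.3f} mm/s   (ground truth {truth.dm_vt():.3f})")
```

prints

```
DM(A)   = 3.74 %
DM(G)   = 11.97 mm
DM(V_N) = 0.307 mm/s   (ground truth 0.310)
DM(V_T) = 0.309 mm/s   (ground truth 0.000)
```

The ring makes the enclosed area fluctuate by ~3.7%, drags the centroid
along a ~12 mm path over the 40 frames, and produces a mean absolute
normal wall speed of 0.31 mm/s that matches the analytic ground truth
from the phantom's radius field within 1%. `DM(V_T)` illustrates a
documented caveat: equal-arc resampling slides points tangentially, so
the tangential index is an upper bound (truth is 0 here because the
deformation is purely radial).

A full synthetic study (subjects × conditions × scans × planes) is one
call each way:

```sh
gimotion simulate --seed 1 --out study/
gimotion study --layout study/ --out results/
```

which writes `metrics.csv`, `residual.csv`, `paired_tests.csv` and
figure-parity plots (residual-volume lines per subject, `DG_Y(t)`
traces). `stabilize` and `metrics` subcommands expose the individual
stages.

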