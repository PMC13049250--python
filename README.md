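# ispgr — blood- and fat-suppressed variable-flip-angle relaxometry

`ispgr` is a toolbox for simultaneous volumetric T1 and T2 mapping with an
interleaved spoiled-gradient-echo (I-SPGR) acquisition: a 3D variable-flip-angle
(VFA) SPGR readout interleaved, shot by shot, with fat suppression (SPIR),
iMSDE blood suppression and spoiling.  It is aimed at quantitative-MRI
researchers who want to model, fit, and stress-test such protocols without
scanner data — e.g. for vessel-wall imaging of abdominal aortic aneurysms,
where bright blood and perivascular fat make conventional VFA mapping
impossible.

## The model

With perfect spoiling, steady-state SPGR follows the Ernst equation

    S = M0 sin(α) (1 − E1) / (1 − cos(α) E1),   E1 = exp(−TR/T1).

Preparation modules break the steady state.  Each I-SPGR shot is: a temporal
gap plus SPIR fat suppression (duration T_FS, pure T1 relaxation for
on-resonance spins), an iMSDE block holding the magnetization transverse for
T_BS (pure T2 decay), spoiling for T_Sp (T1 relaxation), then k excitations at
flip angle α and repetition time TR.  After a few shots the signal reaches a
*semi* steady state — identical from shot to shot, evolving within the shot.
With C = E1 cos(α) and E_FS, E_BS, E_Sp the per-interval relaxation factors,
the signal after pulse n is

    S_n = sin(α) M0 [ (1 − E1)(1 − C^(n−1))/(1 − C)
          + ((1 − E_Sp) + (1 − E_FS) E_Sp E_BS
             + E_Sp E_BS E_FS (1 − E1)(1 − C^k)/(1 − C))
            / (1 − E_Sp E_BS E_FS C^k) · C^(n−1) ].

Varying α (T1 weighting) and T_BS (T2 weighting) across measurements and
fitting S_1 — the readout that samples central k-space under the package's
golden-angle pseudo-spiral phase-encode ordering — gives a joint voxel-wise
(T1, T2, M0) estimate.  An event-driven Bloch simulator (perfect-spoiling and
RF/gradient-spoiling isochromat-ensemble modes) serves as an independent
oracle for the closed form, and a digital 8-vial phantom (T1 236–2013 ms,
T2 15–328 ms) with a forward acquisition simulator closes the loop from
ground truth to fitted maps.

## Worked example

Simulate the 8-vial phantom through the in-vivo protocol preset (TR 3.5 ms,
30 readouts/shot, flip angles 25/20/10/4° at T_BS 13 ms plus 10° at 20 and
35 ms), add noise at SNR 60, fit every vial voxel, and tabulate accuracy:

```python
import numpy as np
from ispgr import *

proto = get_protocol("invivo_ispgr")
phantom = make_phantom("standard_8vial", shape=(40, 40, 1))
stack = simulate_stack(phantom, proto, noise=NoiseModel(snr=60, seed=1))
bounds = FitBounds(t1=(50, 4000), t2=(5, 500))   # enclose the phantom range
maps = fit_volume(stack, proto, bounds=bounds, b1_sigma=0.0)
print(bias_table({"ispgr": maps}, stack.mask, phantom).round(1).to_string(index=False))
```

```
model region  ref_t1  fit_t1  err_t1  ref_t2  fit_t2  err_t2
ispgr      1   236.0   243.5     7.5    15.0    14.7    -0.3
ispgr      2   320.6   323.0     2.4    23.3    22.9    -0.4
ispgr      3   435.4   442.8     7.4    36.2    35.8    -0.4
ispgr      4   591.4   585.5    -5.9    56.3    56.7     0.4
ispgr      5   803.3   790.5   -12.8    87.4    89.2     1.7
ispgr      6  1091.1  1105.1    14.0   135.9   135.8    -0.0
ispgr      7  1482.0  1484.8     2.7   211.1   217.3     6.2
ispgr      8  2013.0  1986.1   -26.9   328.0   353.0    25.0
ispgr   mean     NaN     NaN    -1.4     NaN     NaN     4.0
```

Each row compares one vial's fitted region mean against its ground truth;
`err_*` is fitted − reference in ms, and the `mean` row is the grand mean
bias.  Even at SNR 60 the joint fit recovers T1 across 236–2013 ms to within
a few tens of ms; refitting the same stack with `model="spgr"` (Ernst
equation, ignoring the preparation) underestimates T1 on every vial by
hundreds of ms — the bias the semi-steady-state model exists to remove.

A single voxel is a statsmodels-style model/results pair:

```python
res = fit_voxel(stack.voxel_signals((7, 29, 0)), proto, bounds=bounds)
print(res.summary())
```

```
Prepared SPGR least-squares fit
measurements: 6   converged: True   flag: 0
residual norm: 0.00263632   nfev: 27
param           estimate       std err
T1 (ms)          566.653          44.5
T2 (ms)          56.7206          4.37
M0 (a.u.)       0.969397        0.0679
```

The same functionality is scriptable from the shell (`ispgr simulate`,
`ispgr fit`, `ispgr bloch`, `ispgr trajectory`, `ispgr sensitivity`).

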