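# mocolge

Motion-compensated reconstruction for free-breathing, isotropic
high-resolution **3D Dixon late-gadolinium-enhancement (LGE)** cardiac
MRI — with a digital moving phantom so the whole chain runs and is
verified without any scanner data.

In free-breathing 3D LGE the heart moves throughout the several-minute
acquisition.  A low-resolution 2D image navigator (iNAV) acquired every
heartbeat measures the heart's foot–head (FH) and right–left (RL)
position, enabling two reconstructions of the *same* undersampled
dual-echo k-space:

* **TC** — beat-to-beat translational correction: each k-space line is
  modulated by a linear phase `exp(+2πi f·Δ)` toward the average
  breathing position, followed by iterative SENSE (conjugate gradients
  on the normal equations of `E = M·F·S`).
* **NRC** — translational *plus* non-rigid correction: lines are sorted
  into five respiratory bins by FH position, half-resolution bin images
  are reconstructed, histogram-equalized and registered to the central
  bin to estimate per-bin deformation fields `W_b`, which enter a
  generalized encoding operator solved jointly over all bins:

  ```
  min_x  Σ_b || M_b F S W_b x − y_b ||²_w
  ```

Both echoes are then combined by two-point Dixon water–fat separation
(`W = |IP+OP|/2`, `F = |IP−OP|/2`, optional smooth-phasor B0
correction), and the water images are quantified: LGE-to-myocardium and
blood-to-myocardium contrast ratios, and scar mass by the
full-width-half-maximum rule (threshold = half of the maximum signal
within the myocardial shell; mass = voxel count × voxel volume ×
1.05 g/mL).

The package is aimed at MR-reconstruction researchers who want a fully
self-contained, testable reference implementation of this pipeline: a
water/fat thorax–heart phantom with pseudo-periodic breathing (dominant
FH translation plus a smooth non-rigid component), a variable-density
golden-step Cartesian trajectory with spiral profile ordering
(VD-CASPR, centric in-out, 3.3× undersampled), multi-coil dual-echo
simulation with per-beat navigators, and truth-referenced metrics.

See `docs/methods.md` for the model, parameter and design details.

## Worked example

```python
from mocolge import ExperimentConfig, run_experiment

report, _ = run_experiment(ExperimentConfig(seed=0))
tc, nrc = report["tc"], report["nrc"]
print(f"image RMSE (heart):  TC {tc['rmse_op']:.4f}   NRC {nrc['rmse_op']:.4f}")
print(f"border sharpness:    TC {tc['sharpness']:.3f}    NRC {nrc['sharpness']:.3f}")
print(f"LGE/myo contrast:    TC {tc['cr_lge_myo']:.2f}     NRC {nrc['cr_lge_myo']:.2f}")
print(f"FWHM scar mass (g):  TC {tc['mass_g']:.2f}     NRC {nrc['mass_g']:.2f}"
      f"   (truth {report['truth_scar_mass_g']:.2f})")
```

This simulates a desk-scale free-breathing exam (64×64×32 grid, 2 mm
voxels, 8 coils, 100 heartbeats, 10 mm FH breathing with a non-rigid
component, 3.3× VD-CASPR), reconstructs it with both pipelines on the
same raw data, and prints paired metrics, e.g.:

```
image RMSE (heart):  TC 0.0621   NRC 0.0598
border sharpness:    TC 0.262    NRC 0.270
LGE/myo contrast:    TC 3.98     NRC 4.23
FWHM scar mass (g):  TC 4.32     NRC 4.34   (truth 2.50)
```

The non-rigidly corrected reconstruction has lower image error against
the motion-free reference, a sharper blood–myocardium border and higher
LGE-to-myocardium contrast.  Both reconstructions overestimate the
FWHM scar mass (blur and blood partial volume spill signal past the
half-max threshold); the mass difference between them is a one-to-two
voxel effect at this desk resolution — in this run a statistical tie,
across seeds usually lower (less overestimated) for NRC.  Exact numbers
vary with the seed.

A command-line interface exposes each stage:

```bash
mocolge simulate --seed 0 --out scan.h5
mocolge recon --method nrc --raw scan.h5 --out out/
mocolge dixon --op out/nrc_echo0.nii --ip out/nrc_echo1.nii \
        --out-water water.nii --out-fat fat.nii
mocolge traj --ny 240 --nz 240 --accel 3.3 --beats 722
mocolge experiment --seed 0 --out results/
```

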