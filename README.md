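# tdcsmap

Concurrent mapping of tDCS current-induced magnetic fields and BOLD
responses from dual-echo EPI data.

## The problem

Transcranial direct current stimulation (tDCS) passes a weak constant
current (~1–2 mA) through scalp electrodes, but where that current actually
flows in an individual head — and how the brain responds — is hard to
observe. During stimulation inside an MR scanner, the current induces a
static magnetic field whose component along the scanner's main field, Bz,
leaves a signature in the phase of the MR signal:

    φ = (γ · ΔBz · TE) mod 2π

with γ the proton gyromagnetic ratio and TE the echo time. A dual-echo EPI
acquisition (TE₁/TE₂ = 11/26 ms) captures this field in the phase while the
echo-2 magnitude simultaneously carries BOLD contrast — markers of the
electromagnetic cause and the neurophysiological effect in one scan.

`tdcsmap` implements the full analysis chain for this technique, for
methods researchers who want to simulate, process and validate such
acquisitions without scanner data:

* **Forward simulation** — Bz per mA from an explicit current path via the
  exact finite-segment Biot–Savart closed form (the wire-phantom gold
  standard).
* **Synthetic acquisition** — dual-echo magnitude+phase time series that
  encode a known field map in the phase under a block-design current
  waveform, with complex noise, drifts, between-scan level shifts and an
  injectable BOLD-like effect.
* **4D phase unwrapping** — quality-guided spatial region growth, a
  TE₂/TE₁ bootstrap from the short echo, and per-voxel temporal continuity;
  series with excessive wraps are rejected.
* **Field estimation** — per-voxel GLM of the unwrapped phase on the
  applied current with nuisance regressors (per-scan trends, motion, global
  signal, level-shift steps); the current slope in rad/mA converts to the
  induced field per mA: `Bz [nT/mA] = slope / (γ·TE₂) × 10⁹`.
* **Confound models** — closed-form bounds on how much BOLD-like magnitude
  change intravoxel dephasing by the current-induced field gradient could
  produce: `fS = 1 − cos(φ/2)` (worst case) and `fS = 1 − sin(φ/2)/(φ/2)`
  (linear spread).
* **Validation statistics** — spatial Pearson correlation, regression over
  progressively weaker field ranges, paired t-tests of mean field
  strengths, voxelwise test–retest ICC(2,1), cluster-thresholded masks and
  DICE overlap, and a two-stage (dual-regression-style) group test of
  component timecourses against the current waveform.

## Worked example

Run the complete wire-phantom validation — a straight insulated wire in a
water cylinder, three sessions (Active, −Active with the current reversed,
Sham with the stimulator off), each simulated as dual-echo EPI at complex
SNR 50, unwrapped and fitted:

```bash
tdcsmap demo-phantom --out-dir demo --seed 1 --shape 16,16,8
```

which prints (abridged):

```
          comparison  bound  n_voxels     slope  pearson_r
       active_vs_sim    inf       896  1.000257   0.999884
   neg_active_vs_sim    inf       896 -0.998988  -0.999884
active_vs_neg_active    inf       896 -1.001025  -0.999755
         sham_vs_sim    inf       896 -0.000393  -0.024947
```

Reading the rows: the Active session recovers the Biot–Savart simulation
with slope ≈ 1 (accuracy), reversing the current direction flips the sign
of every estimate (slope ≈ −1 between the two sessions, reliability), and
the Sham session is unrelated to the simulated field (slope ≈ 0,
specificity). The `bound` column repeats each regression restricted to
voxels with progressively weaker reference fields, probing sensitivity.

The dephasing-confound table for a worst-case across-voxel field difference
of 1 nT at TE₂ = 26 ms against observed per-mA BOLD changes:

```python
>>> import tdcsmap as tm
>>> rows = tm.confound_table(1.0, [("Experiment 1", -0.15),
...                                ("Experiment 2 (test)", -0.11)])
>>> print(tm.confound_frame(rows).to_string(index=False))
            dataset  observed_per_mA  ratio_model1  ratio_model2  phi_rad  flagged
       Experiment 1            -0.15      0.000040      0.000013 0.006956    False
Experiment 2 (test)            -0.11      0.000055      0.000018 0.006956    False
```

Both models put the dephasing confound four to five orders of magnitude
below the observed effects: a current-locked BOLD decrease of −0.11 to
−0.15 per mA cannot be explained by the current's own field gradient.

## Command-line interface

`tdcsmap` exposes the pipeline as subcommands: `simulate-field`,
`simulate-acq`, `unwrap`, `fit`, `confound`, `validate`, `group-bold` and
`demo-phantom`. Volumes are NIfTI-1 (phase in float32 radians), waveforms
and reports are TSV, and parameters/paths/configs are JSON. See
`docs/methods.md` for the model details, parameter defaults and known
limitations.
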