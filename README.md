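# trunkgait

Trunk-acceleration gait indexes from a single lumbar inertial sensor, with a
ground-truth synthetic walk generator and a rank-based statistical layer for
three-group (healthy / immunocompetent stroke / immunosuppressed stroke)
comparisons.

The pipeline takes tri-axial trunk acceleration (AP/ML/V, 100 Hz) recorded
during straight overground walking and computes, per walk:

- **Gait events** — initial contacts from the detrended, 3.2 Hz FIR
  low-passed vertical axis, numerically integrated and differentiated with a
  Gaussian first-derivative wavelet (scale 9): one contact per
  zero-crossing-bounded segment, sub-sample refined. Final contacts are the
  toe-off troughs of a lightly filtered vertical signal between contacts
  (documented heuristic; the event band cannot resolve them). Steps are
  assigned left/right from medio-lateral polarity, the first/last two
  strides are trimmed, and at least 20 strides must remain.
- **Harmonic ratio (HR)** — per-stride DFT locked to the stride window;
  sum of the first ten even over the first ten odd stride harmonics (AP/V),
  odd over even for ML; averaged over the walk.
- **Short-term largest Lyapunov exponent (sLLE)** — 20 strides
  time-normalized to 100 points each (2000 samples, unfiltered),
  delay-embedded (AMI first minimum in 7..18; FNN dimension, max 10), and
  the slope of Rosenstein's mean log divergence over 0–0.5 stride,
  expressed per stride.
- **Log-dimensionless jerk (LDLJ)** — −ln[(t₂−t₁)/a_peak² · ∫(da/dt)² dt]
  on the 20 Hz low-passed signal over the retained-stride span.
- **Temporal symmetry indexes (SI)** — paretic vs non-paretic stance,
  swing, double- and single-support times, in percent of their mean.
- **Gait speed** — corridor distance over the contact span.

The statistical layer mirrors the study design: Kruskal–Wallis with
eta-squared, Dunn post-hoc with Holm correction, chi-square / Mann–Whitney
baseline tests, and a nonparametric two-group × two-timepoint
repeated-measures analysis (rank-based ANOVA-type statistics with Box-type
degrees of freedom, post-hoc gated on the interaction).

Because the sLLE of real gait has no closed form, the synthetic generator is
a first-class component: stride-locked harmonic templates with exact
(closed-form) harmonic ratios, programmable contact times and stance
fractions, and a within-stride phase-noise knob that drives the stability
exponent monotonically. Group presets reproduce the published cohort
structure (group sizes 42/32/14, NLR ≥ 5 defining the immunosuppressed
group, per-group HR/sLLE/speed levels).

## Command line

```
trunkgait simulate --n-hs 42 --n-ic 32 --n-sii 14 --seed 1 --out cohort/
trunkgait events cohort/hs001_T0.csv --out events.csv
trunkgait indexes --traces cohort/ --out indexes.csv
trunkgait compare --indexes indexes.csv --design t0 --out report.csv
trunkgait run --seed 1 --out results/        # simulate + analyze + compare
```

`trunkgait run` writes `indexes.csv`, `report_t0.csv` (and
`report_longitudinal.csv` when T1 walks exist), the ground-truth table and a
`run_manifest.json` with the config hash, seed, output hashes and exclusion
bookkeeping. Every stage is deterministic under a fixed seed. `--config`
accepts a YAML file overriding any `RunConfig` field (cutoffs, stride
minimum, units `g` vs `mps2`, strict vs tolerant sampling, ...).

### Trace CSV schema

```
time,acc_ap,acc_ml,acc_v
0.00,0.123,-0.045,0.987
0.01,...
```

Time in seconds (uniform, monotone), accelerations in m/s² (or g with
`units: g`). Cohort manifests are CSVs with `subject_id, nlr, paretic_side,
timepoint, trace_path` and optional clinical scores; group labels are always
derived from the NLR ≥ 5 rule and any declared group must agree.

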