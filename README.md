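# coordgait

Intersegmental coordination analysis of running gait by **modified vector
coding** and **circular statistics**, with the 2×2 mixed-design inference
used in pre/post training studies.

Athletes with a recent ankle sprain — even when asymptomatic — can carry
subtle compensations in how the hip and knee coordinate with the ankle
during high-speed running. This package implements the full analysis chain
used to quantify that: from raw sagittal joint-angle time series and a
vertical ground reaction force (GRF) channel, through gait-event detection
and stride normalization, to coupling angles, coordination variability,
pattern classification, and group×time statistics. It is aimed at movement
scientists who have joint-angle exports (or want fully synthetic gait with
known ground truth) rather than raw marker data.

## The measures

For a joint pair (proximal hip or knee, distal ankle) plotted in the
angle-angle plane (ankle on X), the **coupling angle** at step *t* of a
101-point gait cycle is

> θ(t) = atan2(Δθ_prox(t), Δθ_dist(t)) mod 360°

— the direction of travel between consecutive cycle points. Angles are
classified into in-phase/anti-phase, proximal-/ankle-dominant patterns in
45° sectors. Averages use circular statistics: with mean resultant length
R = |(1/n) Σ e^{iθ_k}|, **coordination variability** across strides is the
circular SD

> var_coord = sqrt(−2 ln R) · 180/π.

Coordination angles per subphase (first/second half stance 0–20%/21–40%,
first/second half swing 41–70%/71–100%) come from the ensemble-mean
trajectories; variability comes from per-stride coupling series. Group
inference is a 2×2 (group × time) mixed ANOVA per outcome with partial
eta-squared and noncentral-F 95% CIs. Details: `docs/methods.md`.

## Worked example

`examples/` contains one short script per capability. End to end
(`python examples/05_full_cohort_study.py`): a synthetic 12 + 12 pre/post
cohort where only the sprain-history (RASH) group's second-half-stance
coupling centre moves from 212.7° (in-phase hip-dominant) to 235.5°
(in-phase ankle-dominant), controls fixed at 268.7°:

```
RASH     pre   second-half-stance angle =  211.1 deg
RASH     post  second-half-stance angle =  233.7 deg
nonRASH  pre   second-half-stance angle =  268.1 deg
nonRASH  post  second-half-stance angle =  267.7 deg

group x time interaction on the coordination angle:
  first_half_stance  F(1,22) =    0.02  eta_p2 = 0.001 (negligible)
  second_half_stance F(1,22) = 1091.55  eta_p2 = 0.980 (large)
  first_half_swing   F(1,22) =    0.16  eta_p2 = 0.007 (negligible)
  second_half_swing  F(1,22) =    0.11  eta_p2 = 0.005 (negligible)
```

The recovered group means match the prescribed coupling centres to ~2°
(stride noise, 12 subjects), the pattern label flips from in-phase
proximal to in-phase distal for the shifted group, and the interaction
effect is huge exactly where the shift was injected and null-sized
elsewhere.

The library is the primary interface
(`generate_trial`, `detect_gait_events`, `coupling_angles`,
`coordination_variability`, `mixed_anova_2x2`, `run_pipeline`, ...); a thin
CLI covers the file-based entry points:

```sh
coordgait simulate --seed 7 --out trial_dir
coordgait analyze --trial trial_dir
coordgait run --config study.yaml --out results/
```

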