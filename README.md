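# limbpoint

Analysis pipeline for **sagittal-plane lower-limb pointing**: a standing
participant points with the toe to a target scaled to their own joint
mobility and returns in one smooth motion.  The task probes intersegmental
coordination — keeping one joint still while another moves requires active
muscle torque to cancel the passive torques that the moving segments induce —
and is aimed at quantifying disordered motor strategies in motor-incomplete
spinal cord injury (SCI) and their relation to proprioceptive impairment.
The intended users are movement-science and neurorehabilitation researchers.

From marker trajectories of a planar three-segment limb (thigh, shank, foot;
frictionless hip, knee, ankle; fixed hip anchor) the package computes:

* **joint-torque decomposition** (Newton–Euler, per joint j):

      T_net(j) = T_mus(j) + T_grav(j) + T_int(j)

  with the interaction torque parsed by kinematic source — the ω²
  (centripetal) and α (inertial) terms of each other segment — and the
  muscle torque as the residual, i.e. the physically applied joint torque
  (active + passive tissue).  Muscle power is P(j) = T_mus(j)·φ̇(j),
  flexion-positive, generative when positive.
* **movement segmentation**: the reversal phase spans the two dominant
  toe-speed peaks; the reversal point is the speed minimum between them;
  motor strategies are summarized as the signed mean muscle torque over the
  first half of the reversal phase, end-point errors (h, v in cm) at the
  reversal point, and the foot-path area enclosed between the outbound and
  return toe paths (trapezoid rule).
* **proprioception scores**: joint position sense (JPS, mean absolute
  reproduction error in degrees) and movement detection sense
  (MDS = excursion/10 + direction error, averaged over trials, 0–2).
* **statistics**: random-intercept linear mixed models with a fixed
  interaction-selection rule (group×target, group×vision, three-way only if
  both are significant), ROM and movement-time covariates, target-wise
  group contrasts with Cohen's d, marginal R² and Cohen's
  f² = R²/(1 − R²), and crude torque–performance / torque–proprioception
  associations.
* **a synthetic cohort generator** (12 controls + 16 SCI by default):
  minimum-jerk plans, an independent energy-based inverse model, distorted
  and noise-corrupted torque commands tied to a per-participant
  proprioceptive-noise parameter, RK4 forward dynamics, and simulated
  JPS/MDS sessions — so the whole pipeline runs with no external data.

See `docs/methods.md` for the model, conventions, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from limbpoint.limb_model import Anthropometrics, LimbModel
from limbpoint.protocol import make_target
from limbpoint.synthetic import ParticipantProfile, simulate_trial
from limbpoint.pipeline import process_trial

anthro = Anthropometrics.from_body(body_mass=71.0, height=1.70)
model = LimbModel(anthropometrics=anthro)
rom = {"hip": 64.7, "knee": 103.1, "ankle": 17.1}       # active ROM, deg
profile = ParticipantProfile("C01", "control", anthro, rom, rho=0.0,
                             distortions={})
target = make_target(model, np.zeros(3), rom, {"knee", "ankle"})  # KA target
trial = simulate_trial(profile, target, seed=1234, out_duration=1.0,
                       marker_noise_sd=0.0)
m = process_trial(model, trial.markers, trial.fs, target.target_point)
print(f"h={m.h_error:+.2f} cm  v={m.v_error:+.2f} cm  "
      f"area={m.area*1e4:.1f} cm^2  mt={m.movement_time:.2f} s")
print("mean muscle torque (hip, knee, ankle) N m:",
      np.round(m.mean_torque, 2))
```

prints

```
h=-0.02 cm  v=+0.01 cm  area=0.0 cm^2  mt=0.52 s
mean muscle torque (hip, knee, ankle) N m: [-3.98  5.47  1.11]
```

A noise-free participant lands within a fraction of a millimetre of the
target and retraces the outbound path, so the enclosed foot-path area is
essentially zero.  The knee–ankle target is driven by knee flexor torque
(positive knee value) while the hip produces extensor torque (negative) to
hold the thigh vertical against the interaction torque from the swinging
shank — exactly the strategy signature the task is designed to expose.

## The analysis

Numbered drivers under `analysis/` rebuild the full study on synthetic data
(raw trials land under `scratch/`, tables under `results/`):

```bash
python analysis/01_simulate_cohort.py      # forward-simulate the cohort
python analysis/02_trial_metrics.py        # filter, segment, decompose, measure
python analysis/03_proprioception_scores.py
python analysis/04_group_models.py         # mixed models + contrasts
python analysis/05_associations.py         # torque vs performance / MDS / JPS
```

On the default cohort (seed 20250925) the simulated proprioception scores
span the intended severity range (MDS mean 0.24, range 0.05–0.45 in
controls vs 1.00, range 0.13–2.00 in SCI; JPS 6.9° vs 12.6°), the group
models detect group×target interactions for all three joint torques
(e.g. hip: marginal R² = 0.838, f² = 5.19, p < 1e−9) and for horizontal
error and log foot-path area, and the crude association recovers the
severity link at the knee–ankle target: hip muscle torque vs MDS slope
+1.12 N m per a.u. (p = 0.0096, f² = 0.22) — worse movement sense, less
hip extensor torque.  Contrast directions are emergent properties of the
simulated closed-loop movements, not copies of the injected coefficients;
see `docs/methods.md`.

The same stages are scriptable via the `limbpoint` CLI
(`simulate`, `analyze`, `score-proprio`, `stats`, `report`).

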