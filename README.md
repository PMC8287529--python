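# atsasim

Desk-scale musculoskeletal simulation of an **anatomic total shoulder
arthroplasty (ATSA)** under rotator-cuff deficiencies.

After an ATSA — a 48 mm metal humeral head articulating on a
polyethylene glenoid insert with an 8 mm diametral mismatch — secondary
rotator cuff tears are a common complication. Losing a cuff muscle
changes how the remaining muscles share the abduction load and how hard
the head is pressed into the insert, which bears on patient effort,
joint stability and polyethylene survival. `atsasim` is a compact,
fully synthetic simulator for exploring those effects: it is aimed at
biomechanics students and researchers who want a transparent,
inspectable implementation of the coupled mechanisms rather than a
patient-specific prediction tool.

## Model

Three pieces are coupled at every driven abduction angle
(0–90° over 90 s):

* **Elastic-foundation contact.** Each insert-mesh vertex *i*
  penetrating the head by depth *dᵢ* contributes a normal force
  `Fᵢ = P_V · Vᵢ` with `Vᵢ = dᵢ·Aᵢ` (vertex tributary area `Aᵢ`,
  contact pressure module `P_V = 2.74·10¹¹ N/m³`).
* **Polynomial muscle recruitment.** Muscle forces solve
  `min Σ (fᵢ/Nᵢ)^p` subject to the three GH moment equations
  `R f = −M_ext` and `0 ≤ fᵢ ≤ Nᵢ`, with `p = 2` and strengths
  `Nᵢ = PCSA × 27 N/cm²`.
* **Force-dependent kinematics (FDK).** The three GH translations are
  released: a damped-Newton search finds the translation at which the
  net force on the humerus (muscles + gravity + contact + a 1.74·10⁴
  N/m capsule spring) falls below a 20 N tolerance, with recruitment
  re-solved inside every residual evaluation.

The intact cuff is compared against five deficiency scenarios:
Q1 infraspinatus, Q2 supraspinatus, Q3 supraspinatus+infraspinatus,
Q4 subscapularis, Q5 the whole cuff. A torn muscle keeps its row in
every output with an explicit 0 N force.

All geometry and muscle data are generated procedurally (spherical-cap
implant meshes, a documented muscle attachment fixture); nothing is
downloaded. See `docs/methods.md` for assumptions, parameters and
limitations.

## Worked example

One FDK step on the default model at 45° of abduction:

```python
import numpy as np, atsasim as a

model = a.assemble_model()                 # default 48 mm / 8 mm implant
res = a.fdk_solve_step(model, 45.0)
print("converged:", res.converged, " residual: %.2f N" % res.residual_norm)
print("GH translation (mm):", np.round(res.state.translation * 1e3, 3))
print("GH contact force (N): %.1f" % np.linalg.norm(res.contact.force_on_master))
for name, f in zip(model.muscle_names, res.recruitment.forces):
    if f > 1.0:
        print(f"  {name:24s} {f:7.1f} N")
```

prints

```
converged: True  residual: 19.10 N
GH translation (mm): [0.099 1.017 0.087]
GH contact force (N): 271.9
  deltoideus_clavicular       42.7 N
  deltoideus_scapular        189.0 N
  supraspinatus               28.5 N
  infraspinatus               57.8 N
  subscapularis               49.6 N
```

The head has settled 1.0 mm superiorly and is pressed into the insert
with 272 N; the scapular deltoid carries most of the abduction moment,
the cuff muscles contribute smaller forces that mainly compress and
steer the joint. The residual is the remaining net force on the
humerus, inside the 20 N equilibrium tolerance.

Full sweeps run from the command line:

```sh
atsasim simulate --scenario all --out results/   # 6 scenarios x 91 steps
atsasim summarize --traces results/ --angles 78
atsasim sensitivity                              # P_V, criterion order, steps
atsasim make-fixtures                            # export STLs + muscle CSV
```

`summarize` reports, per scenario, peak muscle forces and the GH
contact force at the query angle, each as percent change versus INTACT.
On the default model the directional effects are: deltoid demand rises
when the subscapularis (Q4) or the whole cuff (Q5) is lost; the GH
contact force falls under supero-posterior cuff loss (Q3) and rises at
its peak under subscapularis loss (Q4).

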