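# flapsim

Coupled flexible-wing / compliant-thorax dynamics of flapping insect flight.

Most flying insects drive their wings *indirectly*: antagonistic flight
muscles deform the elastic thorax, and a hinge linkage amplifies the small
thorax deflection into large wing rotation. The thorax stores and returns
elastic energy every wingbeat, and the wings themselves bend passively under
inertial and aerodynamic loads. `flapsim` is a minimal system-level simulator
of this drivetrain, aimed at people studying insect flight energetics or
designing flapping-wing micro air vehicles (FWMAVs), where the actuator plays
the role of the thorax and a mechanical transmission the role of the hinge.
Its central question: **how much input energy does passive wing flexibility
save, compared with an otherwise identical rigid-wing system?**

## Model

A sprung thorax mass `m` with stiffness `k` moves vertically with
displacement `x` under a harmonic muscle force `F(t) = F0 sin(2πft)`. A
linear transmission maps thorax travel to rigid-body wing rotation,
`x = Γθ`. Two wings flap and deform symmetrically; each wing is a uniform
Euler–Bernoulli cantilever whose bending deflection is expanded in
mass-normalized vibration modes, `W(y,t) = Σ_k φ_k(y) q_k(t)` with
`∫ μ φ_k φ_r dy = δ_kr`. Lagrange's equations give the coupled dynamics

    (m + 2 I_O/Γ²) ẍ + (2/Γ) Σ_k λ_k q̈_k + k x = F_NC
    (λ_k/Γ) ẍ + q̈_k + (ω_k² − ẋ²/Γ²) q_k      = Q_NC,k

where `I_O = m_w L²/3` is the wing's rotational inertia, `λ_k = ∫ μ y φ_k dy`
couples bending to stroke motion, and the `−ẋ²/Γ²` term is centrifugal spin
softening. Quasi-steady blade-element drag (coefficient `C_D`, fluid density
`ρ_f`) supplies the non-conservative forces; even powers of velocity in the
drag law are implemented sign-correctly as `|v|v` so drag opposes the motion
on both half-strokes. Modes with natural frequencies below ten times the
flapping frequency are retained (one bending mode for the defaults); zero
retained modes is the rigid-wing system (RWS), one or more the flexible-wing
system (FWS).

Default parameters are hawkmoth-like (*Manduca sexta* scale): 50 mg, 5 cm
wings tuned to a 60 Hz first bending frequency, a 0.7 g / 2850 N/m thorax,
0.8 mm/rad transmission, 1.5 N muscle amplitude at 25 Hz, `C_D = 3`,
`ρ_f = 1.25 kg/m³`.

## Worked example

```sh
$ flapsim modes
wing bending rigidity EI = 7.185231e-05 N m^2
retained modes at 25 Hz flapping: K=1
  mode 1:    60.000 Hz  lambda=2.011103e-04  [retained]
  mode 2:   376.014 Hz  lambda=-3.209091e-05  [dropped]
linearized RWS natural frequency: 23.483 Hz
linearized FWS natural frequencies: 21.912, 346.185 Hz

$ flapsim baseline
energy ratio (FWS/RWS) = 0.7841; amplitude ratio = 0.7720
wrote baseline_comparison.csv
```

Both systems are driven just above their resonance (23.5 Hz rigid, 21.9 Hz
flexible, vs. the 25 Hz drive). The flexible-wing system needs **~22% less
input energy per wingbeat** (2.14 mJ vs 2.73 mJ) and flaps with a ~23%
smaller thorax stroke (0.46 mm vs 0.59 mm), while the peak two-wing drag
stays in the tens of millinewtons (36 mN rigid; 26 mN rigid-rotation plus
12 mN elastic-deformation components in the flexible system): passive
bending keeps the wingtip moving fast even though the wing base rotates
less. The same library calls are available in Python:

```python
import flapsim as fs

config, _ = fs.default_config()            # hawkmoth-like defaults, K=1
result = fs.integrate(config)              # 50 wingbeats from rest
metrics = fs.summarize(result)             # steady-state summary
print(metrics.input_energy_per_wingbeat_j) # 0.0021385...
```

Single-parameter sweeps over a 15–35 Hz flapping grid
(`flapsim sweep --param force_amplitude`, `transmission_ratio`,
`thorax_stiffness`, `wing_mass`) tabulate thorax amplitude, mean rectified
drag, input energy and the FWS/RWS energy ratio into a long-format CSV.

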