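# Methods

## Model

The simulator couples three elements:

1. **Thorax.** A linear sprung mass: effective mass `m`, stiffness `k`,
   vertical displacement `x(t)`, driven by the indirect-flight-muscle force
   `F(t) = F0 sin(2πft)`. No structural damping is modeled; all dissipation
   is aerodynamic.
2. **Transmission.** A static linear hinge, `x = Γθ`, tying thorax travel to
   the rigid-body stroke angle `θ` of both wings. The phase between thorax
   and stroke is therefore fixed by construction.
3. **Wings.** Two identical uniform cantilevers (span `L`, constant chord
   `w`, thickness `t_w`, mass `m_w` uniformly distributed) flapping and
   deforming symmetrically. Out-of-plane bending is expanded in
   mass-normalized clamped-free modes; with `∫ μ φ_k φ_r dy = δ_kr` the
   modal stiffness is `ω_k²` and the wing's elastic energy is
   `½ Σ_k ω_k² q_k²` per wing, which is how the strain-energy functional is
   evaluated throughout (never volumetrically).

Lagrange's equations with the blade-element generalized forces give the
coupled system quoted in the README. Conventions worth stating:

* **Two-wing bookkeeping.** Modal coordinates describe one wing; symmetric
  deformation lets a single set serve both. The thorax row of the mass
  matrix carries the factor 2 of two wings ( `m + 2I_O/Γ²`, `2λ_k/Γ` ), the
  modal rows are per-wing ( `λ_k/Γ`, identity ), so the constant mass matrix
  is deliberately non-symmetric. It is inverted once per configuration.
  Wing-related energies and reported aerodynamic forces are doubled.
* **Drag sign convention.** The quasi-steady drag density scales with the
  square of the local normal velocity. Even powers cannot reverse sign
  across stroke reversal, so the implementation uses `|θ̇|θ̇`, `|ẋ|ẋ` and
  `|ẋ|q̇` forms. Under this reading the generalized drag power,
  `−C_Dρ_f|θ̇| (θ̇²J3 + 2θ̇ Σq̇_k J2_k + 4 Σ q̇ᵀJ1q̇)`, is a non-positive
  quadratic form at every state (pointwise `(θ̇y+Ẇ)² + 3Ẇ² ≥ 0` under the
  surface integral) — this is property-tested.
* **Spin softening.** The modal stiffness `ω_k² − ẋ²/Γ²` is kept exactly as
  the dynamics state it, treated as a state-dependent right-hand-side term.
  Any parameter set that drives the instantaneous modal stiffness negative
  is reported, not suppressed.

## Energy ledger and a non-conservation caveat

Applied power is `P_F = F ẋ`; the per-wingbeat input energy is the
rectified integral `E_in = ∫|P_F|dt` over the last complete steady wingbeat
(trapezoid on the uniform grid). Kinetic energy uses the full wing quadratic
form including the centrifugal `(ẋ/Γ)² Σq_k²` term.

The governing equations retain the spin-softening term in the modal
equations **without** its conjugate convective terms in the thorax equation.
A consequence discovered while validating the energy ledger: the truncated
system is *not conservative* when undamped. The exact residual power is

    P_soft = 4 (ẋ²/Γ²) Σ q_k q̇_k + 2 (ẋ ẍ/Γ²) Σ q_k²

and `d(T+U)/dt = P_F + P_aero + P_soft` is an identity of the truncated
dynamics. With aerodynamic drag active the residual is small (the softening
channel moves ~1% of `E_in` per wingbeat at baseline and the ledger closes
to <1e-4·E_in); with `C_D = 0` the flexible system is parametrically pumped
and a free release from 1 mm amplitude grows without bound. Undamped
conservation therefore holds exactly only for the rigid configuration
(verified to <1e-6 relative over 50 cycles at tight tolerances); for the
flexible configuration the tests verify the closed ledger instead. This is
a property of the model equations, not of the integrator.

## Numerics

* **Wing FEM.** Two-node Euler–Bernoulli elements, cubic Hermite
  interpolation, consistent mass matrix, uniform element length, root clamp
  imposed by eliminating the two root DOFs; 50 elements by default (first
  two frequencies within 0.01% of the closed-form cantilever; the suite
  checks monotone convergence at 10/20/50 elements). The symmetric
  generalized eigensolver returns mass-normalized shapes directly; signs are
  fixed by `φ_k(L) > 0` so that `λ_1 > 0` and phases are reproducible.
* **Stiffness tuning.** The measured first bending frequency (60 Hz for the
  defaults) is the binding input. Frequency scales as `√EI`, so one
  eigensolve at `EI = 1` fixes `EI = (f_target/f_ref)²` in closed form. For
  the uniform rectangular section this implies a Young's modulus near
  380 GPa — far above cuticle moduli, which simply says a bare uniform
  50 µm membrane is not how a real (vein-stiffened) wing reaches 60 Hz. The
  modulus is reported for reference only; all dynamics depend on `EI`.
* **Mode retention.** Modes with `f_k < 10 f_flap` are kept: one mode at the
  25 Hz default (60 Hz kept, 376 Hz dropped), zero modes below 6 Hz
  flapping (the system degenerates to the rigid wing), two modes above
  37.6 Hz.
* **Modal/aerodynamic integrals.** `λ_k`, `J2_k = w∫y²φ_k dy`,
  `J1_kr = w∫yφ_kφ_r dy` by element-wise 4-point Gauss quadrature on the
  Hermite interpolants (exact for the polynomial integrands);
  `J3 = wL⁴/4` analytically. Scaling sanity: `λ ∝ √m_w`, `J2 ∝ 1/√m_w`,
  `J1 ∝ 1/m_w` when only the wing mass changes.
* **Integration.** Adaptive Dormand–Prince 4(5) (`scipy.integrate.solve_ivp`)
  with `rtol 1e-8`, `atol 1e-11`, dense output evaluated on an exactly
  uniform grid of 100 samples per wingbeat over 50 wingbeats from zero
  initial conditions. Reported amplitudes move by <0.01% when tolerances
  tighten 100×. Artificially stiffened wings (rigid-limit studies, first
  frequency scaled ×100) make the explicit scheme step-limited; those runs
  use the Radau option of the same API. Conservation audits run at
  `rtol 1e-10 / atol 1e-13`.
* **Steady state.** Reported quantities come from the final 10 wingbeats.
  A steadiness diagnostic (relative spread of per-wingbeat amplitudes over
  the window) warns above 1%; the baseline settles to ~1e-9. Amplitude is
  half the peak-to-peak excursion; peak quantities are maxima of absolute
  values; phases come from the fundamental Fourier coefficient at the drive
  frequency (robust to the harmonic distortion the quadratic drag
  introduces) and are wrapped into (−π, π].
* **Energy-balance checks** re-sample the dense solution at 1000 samples
  per wingbeat (5000 for the free-vibration audit) so that quadrature error
  sits well below the tested thresholds; residuals converge as h².
* **Potential-energy split.** The thorax/wing storage fractions are defined
  from each component's *peak* stored energy over a wingbeat, normalized by
  the sum of the peaks (the components peak at different phases, so the
  instantaneous split at the total-PE maximum is also available from the
  series). At baseline the peak-based split is ≈54/46 thorax/wing.

## Experiments

`run_baseline` integrates the same parameter set with the retained-mode
basis (FWS) and with all modes dropped (RWS) and emits per-system
time-series/summary CSVs plus a comparison record (amplitude, peak-force,
power and energy ratios, phase lags). `run_sweep` varies one of force
amplitude {1.0, 1.5, 2.0 N}, transmission ratio {0.6, 0.8, 1.0 mm/rad},
thorax stiffness {2280, 2850, 3420 N/m} or wing mass {35, 50, 65 mg} across
a 15–35 Hz grid (0.5 Hz step by default; the test suite uses a 1 Hz grid
and two parameter values per claim, which resolves the peak locations and
peak energies it checks). When wing mass changes the modal basis is rebuilt
— coupling constants and surface integrals scale with the mass — holding
the measured first frequency fixed by default (`hold_f1`); a switch holds
`EI` instead, since which of the two the source observations pin is not
knowable. Sweeps are resumable (rows keyed on value/frequency/system) and
individual failures are flagged rather than fatal. The entire pipeline is
deterministic: identical configurations produce bit-identical CSVs.

## What the defaults do and do not represent

The defaults emulate a hawkmoth-scale drivetrain driven post-resonance.
They reproduce the scale of measured thorax deformation (~0.5 mm), wingtip
deformation (~1 cm) and peak aerodynamic force (~35 mN), and they predict
that wing flexibility cuts per-wingbeat input energy by ~20% at essentially
unchanged drag production. They do **not** represent: lift or
angle-of-attack variation (single-degree-of-freedom stroke rotation means
the quasi-steady force is pure drag), wing twisting or chordwise modes,
tapered or vein-reinforced planforms (the uniform-beam mode shape slightly
over-weights the tip: wingtip deflection and the quantities that inherit
its amplitude/phase — the deformation phase lag, the elastic-energy floor —
come out 10–20% away from plate/FEM-based values), thorax damping or
hardening, series elasticity in the hinge, or any wake/unsteady
aerodynamics. Passing tests certify the stated model, not insect flight in
general.

## Known limitations

* One elastic degree of freedom per wing at the default drive; conclusions
  near the second-mode band (>370 Hz) are outside the validated range.
* The quasi-steady drag model has no stroke-reversal memory; mean lift is
  identically zero by construction.
* The spin-softening term makes the *undamped* flexible system unstable
  (see the energy-ledger section); conservative-limit studies should use
  the rigid configuration or track the softening channel.
* At extreme parameters (`ẋ/Γ` approaching `ω_1`) the instantaneous modal
  stiffness can turn negative; the integrator reports rather than prevents
  the resulting growth.
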