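# Methods

## Physical model

The cell is a hemisphere of radius R adhering to a filter, coated by a
lipid membrane (entropic tension σ_m, area-expansion modulus K_m) over
a contractile actomyosin cortex (tension σ_c); the resting surface
tension is σ₀ = σ_m + σ_c and the resting Laplace balance sets the
intracellular gauge pressure P = 2σ₀/R₀. Perfusion at a pressure drop
Δp across the basal pore (half-width a) nucleates an inverse bleb — a
spherical-cap invagination of radius r, opening angle θ ∈ [π/2, π]
pinned by r sin θ = a — whose growth the model follows with three
coupled ingredients:

1. **Overdamped radius dynamic.** dr/dt = r/(4μ)[Δp − P − 2Σ/r].
   Inertia is dropped (cellular Reynolds numbers are vanishingly
   small) and μ lumps every resistive contribution of the cell interior
   into one effective viscosity. Confined-geometry corrections to this
   balance are neglected, which is justified while r/R stays small
   (≈ 0.1–0.4 over the regimes simulated here); there is no explicit
   elastic response of the cell body.
2. **Fast pressure equilibration.** P = 2σ/R at every instant; only
   pressure differences matter, so all pressures are gauge relative to
   the bath (P_e ≡ 0) and Δp is the full driving term.
3. **Exact volume conservation.** No material leaks, so the
   hemispherical cell absorbs every cap volume:
   (2π/3)R³ = (2π/3)R₀³ + Σᵢ (4π/3) rᵢ³(2 + cos θᵢ) sin⁴(θᵢ/2).
   The basal pore's own volume is neglected. This relation closes the
   system: R, θ and the areas below are all slaved to the radii.

**Two-regime tension law.** Tension is a function of the relative area
strain of the membrane actually available to the bleb: tension
equilibrates only over a basal patch of radius d on the timescale of a
vacuole lifetime, so the bleb strain is ε_B = (S − S₀)/S₀ with
S₀ = πd² and S = 2πr²(1 − cos θ) + π(d² − a²); the cell strain is
ε_C = (A − A₀)/A₀ with A = 3πR² − πd². Below the reservoir threshold
ε\* (caveolae, wrinkles, microvilli, exocytosis flattening out), area
is buffered at constant target tension σ₀ and the bleb's rebuilt
contractile shell relaxes exponentially, dΣ/dt = (σ₀ − Σ)/τ_c; above
ε\*, the taut membrane responds effectively instantaneously and
Σ = Σ̄(S) = σ₀ + K_m[e^((S−S\*)/S\*) − 1] with S\* = S₀(1 + ε\*),
continuous at S\*. Nucleation locally destroys the cortex, so a new
bleb starts at r = a with Σ = σ_m.

**Steady states.** Δp = 2Σ̄(r)/r + 2σ̄(r)/R(r). With the plateau on
the cortex branch the residual is strictly decreasing in r; on the
membrane branch the exponential makes it strictly increasing. The
branches merge at the reservoir-exhaustion radius (S = S\*): a
saddle-node at Δp\* = 2σ₀(R + r)/(R r) evaluated there. The upper
threshold Δp† is where the cortex root exits the admissible domain at
r = a, i.e. 2σ₀/a + 2σ₀/R(a) (neither threshold has a standard
operational definition, so these closed-form readings define them in
this package). Stability is classified by the sign of the
derivative of the tension-slaved radius rate (fast-tension reduction of
the full system): cortex-branch roots are unstable — they are the
threshold nucleation radii — and membrane-branch roots stable.

**Multiple vacuoles.** Blebs nucleated farther apart than d own
independent patches and evolve as independent copies (coupled only
weakly through the shared cell volume). Blebs closer than d share one
patch: one S = Σᵢ 2πrᵢ²(1 − cos θᵢ) + π(d² − n a²), hence one membrane
target tension, which is the only interaction in the model (steric
contact is ignored). Sharing halves each bleb's effective reservoir, so
the nucleation threshold rises and the symmetric equilibrium shrinks;
past reservoir exhaustion the symmetric state is unstable to size
fluctuations and the system coarsens, Ostwald-ripening-like, to a
single survivor. A bleb deflating to r = a is frozen there — the model
is not valid below the pore radius — its cap removed from the shared
area and the conserved volume while its pore footprint (−πa²) remains.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| R0 | resting cell radius (from spindle-cell surface area ≈ 3πR₀²) | 10 | µm |
| a | basal pore half-width (pore width 2a = 0.5 µm) | 0.25 | µm |
| sigma_m | membrane entropic tension | 40 | pN/µm |
| sigma_c | cortical tension | 374 | pN/µm |
| K_m | membrane area-expansion modulus | 1e5 | pN/µm |
| d | tension-equilibration patch radius (≈ √(2Dt) for membrane-tension diffusion over a GV lifetime) | 10 | µm |
| eps_star | membrane-reservoir threshold strain | 0.5 | — |
| tau_c | actin turnover / myosin recruitment time | 1 | s |
| mu | effective interior viscosity | 2.5e4 | pN·s/µm² |

Internally everything is µm/s/pN (pressures in pN/µm² = Pa); mmHg is
converted only at the CLI/config boundary (1 mmHg = 133.322387415
pN/µm²). ε\* is admitted up to 3.0 for exploring super-stretched
endothelial states, although the target-tension law then ignores the
active strain softening such states involve (see limitations). The
taut-membrane equilibration time is taken as exactly zero, so it has no
runtime parameter.

## Numerics

* Stiff integration with `scipy.integrate.solve_ivp` (Radau),
  rtol 1e−8 / atol 1e−10, dense output. The membrane-regime
  exponential makes the system stiff near steady state.
* Collapse (r − a ↓ 0) and regime switches (ε_B − ε\* crossings) are
  integration events, not step-wise checks, to avoid
  tolerance-dependent chatter; collapse is terminal per bleb, and a
  bleb starting exactly at r = a with a negative rate collapses at
  t = 0 rather than rooting a degenerate event.
* The relaxing cortical tension is integrated at all times; the
  effective tension above ε\* is max(relaxing value, membrane target).
  The max preserves continuity if the threshold were crossed before
  cortical relaxation completes; at the defaults relaxation finishes in
  seconds while exhaustion takes minutes, so it never binds.
* Equilibria: per-branch Brent root finding on analytically monotone
  brackets [a, r(S = S\*)] and [r(S = S\*), r_overflow]; every record
  re-substitutes into the balance to ≤ 1e−9 relative residual. Δp\* is
  refined by bisection on solution-set emptiness to 1e−3 mmHg.
* A guard caps the stretch exponent at 50 (far beyond any lytic
  tension) for both the bleb patch and the cell; the membrane-branch
  bracket ends at whichever guard binds first. Where the lytic line
  itself should sit is left configurable rather than asserted, since
  "lytic" strain levels are not sharply defined.
* Stability uses a central difference with step 1e−6·r_eq on the
  slaved rate; derivatives within 1e−6 of the characteristic rate
  gradient are flagged marginal rather than classified.
* `simulate(..., _frozen_cell=True)` pins the cell at (R₀, σ₀), making
  the cortex-regime radius equation exactly linear
  (dr/dt = αr − β, α = (Δp − 2σ₀/R₀)/(4μ), β = σ₀/(2μ)); this
  diagnostic mode exists so the integrator can be benchmarked against
  the closed form and is not part of the physical model.
* Growth time is reported as first passage into a ±1% band around the
  steady radius, collapse time as first passage to r = a: the
  literature gives only "within about N minutes", so a formal criterion
  had to be chosen here. Times are minutes at the interface, seconds
  internally.

## Ensembles and what the synthetic variability does (not) show

`ensemble` perturbs each listed parameter independently and
multiplicatively, uniform on [1 − f, 1 + f] with f = 0.20 by default —
a minimal reading of "up to 20% physiological variability"; no
correlations between parameters are imposed, and the distribution is
pluggable in code. Draws violating the parameter invariants are
rejected and redrawn; draws are bitwise reproducible given the seed.
The shipped study conditions are 100 draws over {τ_c, μ} for the
dynamics scenarios and 500 draws over all nine parameters for the
branch structure (0/2/1 equilibria below Δp\*, between the thresholds,
and above Δp†). These ensembles probe *parametric* robustness only:
they contain no shape fluctuations, no measurement noise, no
pore-size dynamics, and no cell-to-cell coupling, so passing them
shows the model's qualitative picture is insensitive to tabulated
parameter uncertainty — not that real tissue behaves this way.

## Design choices made where the design was open

* Bleb positions are not modelled; the nucleated-closer-than-d
  dichotomy is an explicit shared/independent patch assignment.
* The two-bleb shared-patch area uses the per-bleb cap-area form
  Σᵢ 2πrᵢ²(1 − cos θᵢ) + π(d² − 2a²), the unique expression that is
  dimensionally consistent and reduces to the single-bleb S.
* With k independent patches the cell strain area subtracts πd² per
  patch: A₀ = 3πR₀² − kπd² (only k = 1 is defined in the source
  literature).
* The cell's tension follows the same two-regime law as the bleb's but
  in the single-vacuole scenarios it provably stays on the plateau
  (its strain never reaches ε\* up to at least 30 mmHg, asserted in
  tests), so σ = σ₀ throughout those runs.
* Post-collapse bookkeeping on a shared patch (cap removed, pore
  footprint kept) is this package's convention; the literature is
  silent.

## Limitations

Spherical-cap vacuoles (real GVs are ellipsoidal); constant pore
half-width a and patch radius d (no pore tearing/pinching, no
tension-diffusion growth of the patch); no membrane bending rigidity;
no super-elastic strain softening above ~100% strain; no nucleation
kinetics (nucleation is an initial condition); no steric interaction
between blebs; single-cell only. The model addresses timescales up to
a few tens of minutes — beyond that, slow lipid flow between cell and
bleb would equilibrate tensions globally and the patch picture breaks
down.
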