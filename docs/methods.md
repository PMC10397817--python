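# Methods

This note documents the model, the parameter choices and their
provenance, the numerical scheme, and known limitations.

## 1. Model

### 1.1 Geometry

The nuclear neighborhood is a 2D disk of radius `R` with no-flux
boundaries. Two chromatin loci are modeled as unit-amplitude Gaussian
profiles

```
g_i(r) = exp(-|r - r_i|^2 / sigma^2),    i in {BL, RL},
```

with the BL (protein-binding locus) at `(-LP/2, 0)` and the RL (lncRNA
locus) at `(+LP/2, 0)`; `LP` is the center-to-center distance and
`sigma` the common locus width (the unit of length).

### 1.2 Free energy

Volume fractions `phiP` (transcriptional protein), `phiR` (lncRNA),
`phiM` (mRNA) and solvent `phiS = 1 - phiP - phiR - phiM` share the
Flory–Huggins free-energy density (thermal units, lattice-site volume
= 1):

```
f(phiP, phiR, phiM) =
    (phiP/nP) ln phiP + (phiR/nR) ln phiR + (phiM/nM) ln phiM
  + phiS ln phiS
  + chiP phiP^2 + chiR (phiR + phiM)^2 + chiPR phiP (phiR + phiM)
```

with polymerization numbers `nP = nR = nM = 10`. Negative χ means
attraction: `chiP < 0` is the protein self-attraction (IDR/charge
mediated), `chiR > 0` the electrostatic self-repulsion of RNA, and
`chiPR < 0` the protein–RNA cross attraction. Both RNA species carry the
same charge-dominated interactions, hence enter through their sum.

The total free energy adds a square-gradient penalty on the protein
field only and the locus wells:

```
F = Int [ f + (kappa/2) |grad phiP|^2
          - cP g_BL(r) phiP - cR g_RL(r) phiR ] dA .
```

Chemical potentials are exact partials of `f`; the protein potential
additionally carries `-kappa lap(phiP) - cP g_BL`, the lncRNA potential
`-cR g_RL` (formation model only).

The reentrance mechanism is visible in the protein potential: the cross
term contributes `chiPR * phiRNA` (attraction, promotes condensation)
while the solvent entropy contributes `-ln phiS` which grows as RNA
crowds out solvent. RNA switches from recruiting to expelling protein
when `phiS < 1/|chiPR|`.

### 1.3 Condensate-formation model (equilibrium)

Protein and tethered lncRNA follow conserved model-B dynamics,

```
d(phiP)/dt = div( DP phiP grad muP )
d(phiR)/dt = div( DR phiR grad muR )
```

from a uniform protein field `phiPavg` and the dilute-limit equilibrium
lncRNA profile `phiR(r) = Z exp(nR cR g_RL(r))` normalized to mean
`phiRavg` (a configuration error is raised if this profile saturates).
Accepted steps conserve both species exactly and never raise `F`.

### 1.4 Transcription model (nonequilibrium)

The protein stays model-B; the two RNA species are produced locally,
diffuse Fickianly and decay:

```
d(phiM)/dt = DM lap(phiM) + kM g_BL(r) phiP - kdM phiM
d(phiR)/dt = DR lap(phiR) + kR g_RL(r)      - kdR phiR
```

mRNA production is proportional to the local protein fraction
(transcription needs the machinery), lncRNA production is constitutive.
Here the lncRNA is localized by where it is made — the RL well depth is
zero — and both RNA fields start at zero, so the `kR = 0` baseline
contains no lncRNA at all. The feedback loop is: protein condenses at
the BL → more mRNA is produced → locus RNA modifies the protein's local
free energy (recruiting at low RNA, dissolving at high RNA).

### 1.5 Readouts

- `phiP_BL`: mean protein fraction within one `sigma` of the BL center;
  `phiP_out`: mean beyond `3 sigma` of both loci; `partition` is their
  ratio.
- Condensate detection: `phiP_BL >= phi_light`, the dilute-branch
  binodal of the protein–solvent binary (common-tangent construction).
- Condensate lifetime: total time with `phiP_BL > 0.15`, in `kd*t`
  units.
- mRNA fold change: steady-state `phiM_BL` divided by its `kR = 0`
  baseline at the same `kM`.

## 2. Parameters and provenance

The model is qualitative; interaction parameters are fixed by
`lncphase.calibrate.calibrate()`, which enforces four regime constraints
at the working concentration `phiPavg = 0.04`:

(a) the uniform bulk is outside the spinodal (metastable, not unstable);
(b) with no lncRNA the BL alone nucleates no condensate;
(c) `phiRavg = 0.01` at `LP = 0.8 sigma` does nucleate one;
(d) the partition ratio is reentrant in `phiRavg` within
    `phiRavg <= 0.2`.

A calibrated preset reproduces itself (`calibrate()` verifies it and
returns it unchanged). The shipped preset:

| symbol | value | role / provenance |
|---|---|---|
| `nP, nR, nM` | 10 | polymer lengths (fixed) |
| `chiP` | −0.93 | protein self-attraction; just below the critical value χc = −(1+√nP)²/(2nP) ≈ −0.8662 so the bulk is metastable, giving dilute binodal `phi_light = 0.0826` |
| `chiR` | +0.5 | RNA self-repulsion (fixed) |
| `chiPR` | −3.5 | protein–RNA attraction; calibrated — strong enough for (c) and for crossover discrimination at `phiRavg = 0.001`, weak enough that solvent crowding reverses it within (d)'s dose range |
| `kappa` | 0.5 | protein gradient penalty (fixed) |
| `cP` | 0.12 | BL well depth; calibrated: deep enough to localize the metastable protein without nucleating alone |
| `cR` | 0.18 | RL well depth; calibrated and capped by feasibility: the Boltzmann initializer requires `nR*cR < ~1.96` for (d)'s `phiRavg = 0.15` run to be constructible |
| `phiPavg` | 0.04 | working protein concentration |
| `DP` | 1 | protein diffusivity (time unit) |
| `DR, DM` | 0.03, 0.005 | RNA diffusivities (transcription model); calibrated (see below) |
| `kdM = kdR` | 0.005 | RNA decay rates; calibrated |
| `kM` regimes | 0.0003 / 0.01 / 0.1 | low / moderate / high expression presets |
| `kR` sweep | 0 … 0.02 | lncRNA transcription rates |

Kinetic calibration rationale: the steady RNA cloud of a point-like
source has decay length `ell = sqrt(D/kd)`. With `D = 1, kd = 0.01`,
`ell = 10 sigma` — the transcribed RNA is spread far beyond the locus
scale, cannot act locally, and none of the expression regimes appear.
The calibrated values give `ell = 1 sigma` (mRNA) and `2.4 sigma`
(lncRNA), localizing the feedback. With them:

- `kM = 0.0003`, `kR = 0`: no condensate (locus protein stays below
  `phi_light`);
- `kM = 0.01`: stable dense condensate (`phiP_BL ≈ 0.44`, lifetime
  ≈ 9.1 `kd*t`);
- `kM = 0.1`: transient condensate — it assembles, its own transcripts
  crowd out solvent, and it dissolves (lifetime ≈ 1.2 `kd*t`);
- fold changes vs `kR`: rise above 1 (peak ≈ 4.4) at `kM = 0.001`,
  stay near 1 at `kM = 0.01`, drop below 1 at `kM = 0.1`.

The low-expression preset uses `kM = 0.0003` rather than `0.001`
because at the calibrated `kd` the `kM = 0.001` feedback already crosses
the detection threshold marginally (0.0878 vs 0.0826); the fold-change
sweeps keep `kM = 0.001` as their low row.

## 3. Numerics

### 3.1 Discretization

Masked-Cartesian finite-volume mesh: square cells of spacing `dr` whose
centers lie inside the disk. The 5-point Laplacian with missing
neighbors dropped implements no-flux boundaries exactly (symmetric,
negative-semidefinite, annihilates constants, second-order accurate).
The model-B flux `div(D phi grad mu)` uses arithmetic-mean face
mobilities, giving exact (telescoping) mass conservation.

Two profiles: `full` (R = 15, dr = 0.1) and `fast` (R = 7.5, dr = 0.15).
All qualitative orderings used by the tests hold on the fast profile;
headline numbers are computed there.

### 3.2 Time stepping

The model-B updates use a linearly stabilized IMEX scheme: the true
variable-mobility flux is explicit, and a constant-coefficient operator
`K = Mbar(-S L + kappa L^2)` is applied implicitly to the increment,

```
(I + dt K) phi_new = phi_old + dt div(D phi grad mu)|_old + dt K phi_old,
```

with `S` chosen to dominate the concave bulk curvature
(`S = 2(|chiP| + |chiPR|)`) and `Mbar` tracking the current maximum
mobility. Every term of `K` has zero column sums, so the update
conserves mass exactly for any `dt` while removing the explicit
stability limits of the fourth-order `kappa` term. RNA species use
implicit diffusion + decay (an M-matrix, hence positivity-preserving)
with explicit production.

An adaptive controller keeps `dt` on a binary ladder
`dt = dt_max 2^-k`: a step is rejected and `dt` halved when it produces
non-finite values, fractions outside [0, 1], a per-cell change above
`delta_max = 0.01`, or (formation model) a free-energy increase; after
4 consecutive accepts `dt` doubles. Keeping `dt` on a small discrete set
lets the sparse LU factorizations of the implicit operators be cached
(LRU-bounded). Runs terminate at steady state
(`max|dphi|/dt < 1e-7`), at `t_max`, or at the step cap.

### 3.3 Phase boundaries

The protein–solvent binary has spinodal roots of
`1/(nP phi) + 1/(1-phi) + 2 chiP = 0` (Brent bracketing) and a binodal
from the common-tangent construction (equal chemical potential and
grand potential; nested Brent solves). Both are verified in the tests
against the closed-form critical point and a brute-force lower-convex-
hull search.

## 4. Limitations

- 2D and mean-field: no fluctuations, no nucleation barriers (kinetics
  from a uniform state are deterministic), no hydrodynamics.
- Qualitative calibration: parameters satisfy regime constraints, not a
  fit to measured concentrations; absolute numbers (partition ratios,
  fold changes) are preset-dependent.
- Condensate detection at `phiRavg = 0.001` is marginal — the locus
  concentration sits near the binodal threshold — so the crossover
  location is resolution/domain sensitive; it is defined on the fast
  profile used throughout.
- The gradient penalty applies to the protein only and `kappa` does not
  scale with `sigma`, so locus-size doubling preserves locus
  concentrations only approximately (≈ 8% at the reference point).
- RNA transport is linear (no RNA chemical-potential coupling in the
  transcription model): RNA affects protein thermodynamics, but protein
  gradients do not advect RNA.
- The dilute-limit Boltzmann initializer caps the feasible
  `nR * cR`; very deep RNA tethering would need a different initial
  condition.
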