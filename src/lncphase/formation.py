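"""Condensate-formation dynamics: conserved model-B evolution of the
protein and lncRNA fields under the chromatin wells.

Both species evolve down chemical-potential gradients,

    d(phiP)/dt = div( DP phiP grad muP ),
    d(phiR)/dt = div( DR phiR grad muR ),

with muP the bulk protein potential minus kappa lap(phiP) plus the BL
well, and muR the bulk lncRNA potential plus the RL well (the gradient
penalty applies to the protein field only).  mRNA is absent from this
model (phiM = 0).

The run starts from a uniform protein field at ``phiPavg`` and the
equilibrium-localized lncRNA profile of :func:`equilibrium_lncrna_profile`,
and integrates to steady state with the adaptive semi-implicit scheme of
:mod:`lncphase.stepping`.  Accepted steps conserve both species exactly
and never raise the total free energy (the controller rejects any step
that would).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import free_energy as fe
from .grid import DiskMesh, build_mesh, div_mobility_flux, integrate
from .params import InteractionParams, LocusWell
from .stepping import (ImplicitSolverCache, StepControls, run_adaptive)
from .trajectory import Recorder, Trajectory


@dataclass(frozen=True)
class FormationConfig:
    """Configuration of a condensate-formation run.

    The BL sits at (-LP/2, 0) and the RL at (+LP/2, 0) by default, with
    LP the center-to-center distance between loci.
    """

    params: InteractionParams = field(default_factory=InteractionParams)
    bl_well: LocusWell = field(default_factory=lambda: LocusWell(
        center=(-0.4, 0.0), sigma=1.0, depth=0.12))
    rl_well: LocusWell = field(default_factory=lambda: LocusWell(
        center=(0.4, 0.0), sigma=1.0, depth=0.18))
    DP: float = 1.0
    DR: float = 1.0
    phiPavg: float = 0.04
    phiRavg: float = 0.0
    radius: float = 15.0
    spacing: float = 0.1
    controls: StepControls = field(default_factory=StepControls)

    def __post_init__(self):
        if self.phiPavg < 0 or self.phiRavg < 0:
            raise ValueError("mean fractions must be >= 0")
        if self.phiPavg + self.phiRavg >= 1:
            raise ValueError("phiPavg + phiRavg must be < 1")

    @property
    def LP(self) -> float:
        bx, by = self.bl_well.center
        rx, ry = self.rl_well.center
        return float(np.hypot(rx - bx, ry - by))

    def with_loci(self, LP: float, sigma: float | None = None
                  ) -> "FormationConfig":
        """Place the loci symmetrically about the origin at distance LP."""
        s_bl = sigma if sigma is not None else self.bl_well.sigma
        s_rl = sigma if sigma is not None else self.rl_well.sigma
        return replace(
            self,
            bl_well=replace(self.bl_well, center=(-LP / 2, 0.0), sigma=s_bl),
            rl_well=replace(self.rl_well, center=(LP / 2, 0.0), sigma=s_rl))


def equilibrium_lncrna_profile(mesh: DiskMesh, rl_well: LocusWell,
                               nR: float, phiRavg: float) -> np.ndarray:
    """Dilute-limit equilibrium lncRNA profile localized at the RL.

    phiR(r) = Z exp(nR cR g(r)) with g the unit Gaussian of the well and
    Z set so the domain mean equals ``phiRavg``.  This is the stationary
    profile of the lncRNA model-B equation in the dilute, protein-
    decoupled limit: muR ~ (ln phiR)/nR - cR g(r) is then spatially
    constant.
    """
    if phiRavg < 0:
        raise ValueError("phiRavg must be >= 0")
    if phiRavg == 0:
        return mesh.zeros()
    boltz = np.exp(nR * rl_well.depth * rl_well.gaussian(mesh.x, mesh.y))
    profile = phiRavg * boltz / boltz.mean()
    if profile.max() >= 1.0 - fe.EPS:
        raise ValueError(
            f"equilibrium lncRNA profile peaks at {profile.max():.3f} "
            ">= 1; reduce phiRavg or the RL well depth")
    return profile


def _energy_fn(mesh, params, bl_well, rl_well):
    def energy(fields):
        return fe.total_free_energy(
            mesh, fields["phiP"], fields["phiR"], mesh.zeros(),
            params, bl_well=bl_well, rl_well=rl_well)
    return energy


def make_formation_stepper(mesh: DiskMesh, config: FormationConfig):
    """Build the semi-implicit model-B stepper for the formation model."""
    p = config.params
    w_bl = fe.locus_field(mesh, config.bl_well)
    w_rl = fe.locus_field(mesh, config.rl_well)
    zero = mesh.zeros()
    # stabilization constants dominate the concave bulk curvature
    S_P = 2.0 * (abs(p.chiP) + abs(p.chiPR))
    S_R = 2.0 * (abs(p.chiR) + abs(p.chiPR))
    cache_P = ImplicitSolverCache(mesh, S=S_P, kappa=p.kappa)
    cache_R = ImplicitSolverCache(mesh, S=S_R, kappa=0.0)

    def stepper(fields, dt):
        phiP, phiR = fields["phiP"], fields["phiR"]
        muP = fe.protein_mu_field(mesh, phiP, phiR, zero, p) + w_bl
        rhs_P = div_mobility_flux(mesh, phiP, muP, config.DP)
        new = {"phiP": cache_P.stabilized_step(
            phiP, rhs_P, dt, config.DP * float(phiP.max()))}
        if config.phiRavg > 0:
            muR = fe.lncrna_mu_field(mesh, phiP, phiR, zero, p) + w_rl
            rhs_R = div_mobility_flux(mesh, phiR, muR, config.DR)
            new["phiR"] = cache_R.stabilized_step(
                phiR, rhs_R, dt, config.DR * float(phiR.max()))
        else:
            new["phiR"] = phiR
        return new

    return stepper


def condensate_threshold(params: InteractionParams) -> float:
    """Dilute-branch binodal of the protein-solvent binary, or inf when
    no two-phase coexistence exists at the given parameters."""
    bnd = fe.spinodal(params)
    if not bnd.exists:
        return np.inf
    return fe.binodal(params).phi_light


def simulate_formation(config: FormationConfig,
                       mesh: DiskMesh | None = None) -> Trajectory:
    """Run the formation model from the standard initial condition."""
    if mesh is None:
        mesh = build_mesh(config.radius, config.spacing)
    fields = {
        "phiP": mesh.full(config.phiPavg),
        "phiR": equilibrium_lncrna_profile(
            mesh, config.rl_well, config.params.nR, config.phiRavg),
    }
    if float(fields["phiP"].max() + fields["phiR"].max()) >= 1.0:
        raise ValueError("initial fields leave no solvent")
    energy = _energy_fn(mesh, config.params, config.bl_well, config.rl_well)
    rec = Recorder(mesh, config.bl_well, config.rl_well,
                   phi_light=condensate_threshold(config.params),
                   DP=config.DP,
                   snapshot_stride=config.controls.snapshot_stride,
                   energy=energy)
    rec.record(0.0, fields)
    stepper = make_formation_stepper(mesh, config)
    t_holder = [0.0]

    def on_accept(t, dt, flds):
        t_holder[0] = t
        rec.record(t, flds)

    fields, result = run_adaptive(fields, stepper, config.controls,
                                  on_accept, energy=energy)
    if rec.snapshots[-1][0] != t_holder[0]:
        rec.take_snapshot(t_holder[0], fields)
    return rec.build(result.termination, config=config)
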