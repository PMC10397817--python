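"""Nonequilibrium transcription dynamics: model-B protein coupled to
reaction-diffusion RNA fields.

The protein remains conserved and moves down its chemical-potential
gradient (its free energy now sees both RNA species through chiPR and
chiR), while the two RNA fields follow Fickian diffusion with localized
production and first-order decay:

    d(phiP)/dt = div( DP phiP grad muP )
    d(phiM)/dt = DM lap(phiM) + kM g_BL(r) phiP - kdM phiM
    d(phiR)/dt = DR lap(phiR) + kR g_RL(r)      - kdR phiR

where g_BL and g_RL are the unit Gaussians of the two loci.  mRNA
production is proportional to the local protein fraction (transcription
requires the machinery); lncRNA production is constitutive at the RL.
In this model the lncRNA is localized by where it is made, not by
tethering: the RL well depth is forced to zero.

Both RNA fields start at zero; lncRNA builds up only by transcription,
so the kR=0 baseline has no lncRNA anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import free_energy as fe
from .grid import DiskMesh, build_mesh, div_mobility_flux
from .params import InteractionParams, LocusWell
from .stepping import (DiffusionSolverCache, ImplicitSolverCache,
                       StepControls, run_adaptive)
from .trajectory import Recorder, Trajectory
from .formation import condensate_threshold


@dataclass(frozen=True)
class TranscriptionConfig:
    """Configuration of a transcription run.

    ``bl_well.sigma`` doubles as the width of the mRNA production profile
    kM(r); ``rl_sigma``/``rl_center`` give the lncRNA production profile.
    """

    params: InteractionParams = field(default_factory=InteractionParams)
    bl_well: LocusWell = field(default_factory=lambda: LocusWell(
        center=(-0.4, 0.0), sigma=1.0, depth=0.12))
    rl_center: tuple = (0.4, 0.0)
    rl_sigma: float = 1.0
    DP: float = 1.0
    DR: float = 0.03
    DM: float = 0.005
    kM: float = 0.01
    kR: float = 0.0
    kdM: float = 0.005
    kdR: float = 0.005
    phiPavg: float = 0.04
    radius: float = 15.0
    spacing: float = 0.1
    controls: StepControls = field(default_factory=lambda: StepControls(
        t_max=2000.0, n_steps=8000))

    def __post_init__(self):
        for name in ("kM", "kR", "kdM", "kdR"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kM > 0 and self.kdM <= 0:
            raise ValueError("kdM must be > 0 when mRNA is produced")
        if self.kR > 0 and self.kdR <= 0:
            raise ValueError("kdR must be > 0 when lncRNA is produced")
        if not 0 <= self.phiPavg < 1:
            raise ValueError("phiPavg must be in [0, 1)")

    @property
    def rl_production_well(self) -> LocusWell:
        """Geometry-only well describing the lncRNA production profile
        (depth 0: no tethering in this model)."""
        return LocusWell(center=self.rl_center, sigma=self.rl_sigma,
                         depth=0.0)


def reaction_rates(mesh: DiskMesh, phiP, phiM, phiR,
                   config: TranscriptionConfig):
    """Per-cell net reaction rates (d phiM, d phiR) of the RNA species."""
    g_bl = config.bl_well.gaussian(mesh.x, mesh.y)
    g_rl = config.rl_production_well.gaussian(mesh.x, mesh.y)
    d_phiM = config.kM * g_bl * phiP - config.kdM * phiM
    d_phiR = config.kR * g_rl - config.kdR * phiR
    return d_phiM, d_phiR


def make_transcription_stepper(mesh: DiskMesh,
                               config: TranscriptionConfig):
    """Semi-implicit stepper: model-B protein, implicit-diffusion RNAs."""
    p = config.params
    w_bl = fe.locus_field(mesh, config.bl_well)
    g_bl = config.bl_well.gaussian(mesh.x, mesh.y)
    g_rl = config.rl_production_well.gaussian(mesh.x, mesh.y)
    S_P = 2.0 * (abs(p.chiP) + abs(p.chiPR))
    cache_P = ImplicitSolverCache(mesh, S=S_P, kappa=p.kappa)
    diff_M = DiffusionSolverCache(mesh, D=config.DM, kd=config.kdM)
    diff_R = DiffusionSolverCache(mesh, D=config.DR, kd=config.kdR)

    def stepper(fields, dt):
        phiP, phiM, phiR = fields["phiP"], fields["phiM"], fields["phiR"]
        muP = fe.protein_mu_field(mesh, phiP, phiR, phiM, p) + w_bl
        rhs_P = div_mobility_flux(mesh, phiP, muP, config.DP)
        new_P = cache_P.stabilized_step(
            phiP, rhs_P, dt, config.DP * float(phiP.max()))
        new_M = diff_M.step(phiM, config.kM * g_bl * phiP, dt)
        new_R = diff_R.step(phiR, config.kR * g_rl, dt)
        return {"phiP": new_P, "phiM": new_M, "phiR": new_R}

    return stepper


def simulate_transcription(config: TranscriptionConfig,
                           mesh: DiskMesh | None = None) -> Trajectory:
    """Run the transcription model from uniform protein and zero RNA."""
    if mesh is None:
        mesh = build_mesh(config.radius, config.spacing)
    fields = {"phiP": mesh.full(config.phiPavg),
              "phiM": mesh.zeros(), "phiR": mesh.zeros()}
    rec = Recorder(mesh, config.bl_well, config.rl_production_well,
                   phi_light=condensate_threshold(config.params),
                   DP=config.DP, kd=config.kdM,
                   snapshot_stride=config.controls.snapshot_stride)
    rec.record(0.0, fields)
    stepper = make_transcription_stepper(mesh, config)
    t_holder = [0.0]

    def on_accept(t, dt, flds):
        t_holder[0] = t
        rec.record(t, flds)

    # nonequilibrium model: no Lyapunov function, so no energy check
    fields, result = run_adaptive(fields, stepper, config.controls,
                                  on_accept, energy=None)
    if rec.snapshots[-1][0] != t_holder[0]:
        rec.take_snapshot(t_holder[0], fields)
    return rec.build(result.termination, config=config)


def steady_rna_fields(mesh: DiskMesh, config: TranscriptionConfig,
                      phiP: np.ndarray | None = None):
    """Direct steady-state solve of the linear RNA equations.

    With the protein field frozen (e.g. decoupled via chiPR=0, cP=0) the
    RNA equations are linear; their steady states solve

        (kd I - D L) phi = production.

    Used as an independent oracle against the time stepper.
    """
    import scipy.sparse as sp
    from scipy.sparse.linalg import spsolve

    if phiP is None:
        phiP = mesh.full(config.phiPavg)
    n = mesh.n_cells
    g_bl = config.bl_well.gaussian(mesh.x, mesh.y)
    g_rl = config.rl_production_well.gaussian(mesh.x, mesh.y)
    A_M = config.kdM * sp.eye(n, format="csr") \
        - config.DM * mesh.laplacian_matrix
    A_R = config.kdR * sp.eye(n, format="csr") \
        - config.DR * mesh.laplacian_matrix
    phiM = spsolve(A_M.tocsc(), config.kM * g_bl * phiP)
    phiR = spsolve(A_R.tocsc(), config.kR * g_rl)
    return phiM, phiR
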