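"""Locus-centered readouts of simulation trajectories.

The condensation readouts mirror the standard droplet-partitioning
quantities: the mean protein fraction over the binding locus (BL), the
mean far from both loci, their ratio (the partition ratio), condensate
detection against the dilute-branch binodal threshold, condensate
lifetime against the fixed cutoff ``LIFETIME_CUTOFF``, and the steady-
state mRNA fold change between two transcription runs.

Region conventions: the "BL region" is the disk of radius sigma_BL about
the BL center; "outside" excludes the 3-sigma neighborhoods of both
loci.  Sensitivity of the partitioning metrics to the region radius is
mild (see docs) because the locus fields are sigma-localized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .free_energy import lncrna_mu_field, protein_mu_field
from .grid import DiskMesh, radial_profile
from .params import InteractionParams, LocusWell

#: phiP_BL cutoff defining an "appreciable" condensate for lifetimes
LIFETIME_CUTOFF = 0.15

#: multiples of sigma excluded around each locus for the background mean
OUTSIDE_EXCLUSION = 3.0


@dataclass(frozen=True)
class LocusMetrics:
    """Per-timepoint locus readouts."""

    time: float
    time_nondim_DP: float     # t * DP / R^2
    time_nondim_kd: float     # kd * t
    phiP_BL: float
    phiP_out: float
    partition_ratio: float
    phiR_BL: float
    phiM_BL: float
    condensate_present: bool


def bl_region_mask(mesh: DiskMesh, well: LocusWell) -> np.ndarray:
    """Cells within one sigma of the well center."""
    mask = mesh.r(well.center) <= well.sigma
    if not mask.any():
        raise ValueError(
            f"no mesh cells within sigma={well.sigma} of {well.center}")
    return mask


def outside_mask(mesh: DiskMesh, bl_well: LocusWell,
                 rl_well: LocusWell | None = None) -> np.ndarray:
    """Cells farther than 3 sigma from every locus."""
    mask = mesh.r(bl_well.center) > OUTSIDE_EXCLUSION * bl_well.sigma
    if rl_well is not None:
        mask &= mesh.r(rl_well.center) > OUTSIDE_EXCLUSION * rl_well.sigma
    if not mask.any():
        raise ValueError("no mesh cells outside the locus neighborhoods")
    return mask


def locus_mean(mesh: DiskMesh, field: np.ndarray,
               well: LocusWell) -> float:
    """Area-weighted mean of a field over the BL region of ``well``."""
    field = mesh.check_field(field)
    return float(field[bl_region_mask(mesh, well)].mean())


def partition_ratio(mesh: DiskMesh, field: np.ndarray,
                    bl_well: LocusWell,
                    rl_well: LocusWell | None = None) -> float:
    """Locus mean over background mean; inf when the background is empty."""
    field = mesh.check_field(field)
    inside = float(field[bl_region_mask(mesh, bl_well)].mean())
    out = float(field[outside_mask(mesh, bl_well, rl_well)].mean())
    if out <= 1e-300:
        return np.inf
    return inside / out


def compute_metrics(mesh: DiskMesh, phiP, phiR, phiM,
                    bl_well: LocusWell, rl_well: LocusWell | None,
                    phi_light: float, t: float,
                    DP: float = 1.0, kd: float = np.nan) -> LocusMetrics:
    """Evaluate all locus readouts for one snapshot."""
    bl = bl_region_mask(mesh, bl_well)
    out = outside_mask(mesh, bl_well, rl_well)
    phiP_BL = float(phiP[bl].mean())
    phiP_out = float(phiP[out].mean())
    ratio = phiP_BL / phiP_out if phiP_out > 1e-300 else np.inf
    return LocusMetrics(
        time=t,
        time_nondim_DP=t * DP / mesh.radius ** 2,
        time_nondim_kd=kd * t,
        phiP_BL=phiP_BL, phiP_out=phiP_out, partition_ratio=ratio,
        phiR_BL=float(phiR[bl].mean()), phiM_BL=float(phiM[bl].mean()),
        condensate_present=bool(phiP_BL >= phi_light))


# ---------------------------------------------------------------------------
# trajectory-level readouts (operate on the metrics table of a Trajectory)
# ---------------------------------------------------------------------------

def initial_recruitment_rate(trajectory) -> float:
    """Slope of phiP_BL(t) at t=0 by forward finite difference."""
    m = trajectory.metrics
    if len(m) < 3:
        raise ValueError("need at least 3 snapshots for an initial rate")
    t = m["t"].to_numpy()
    y = m["phiP_BL"].to_numpy()
    return float((y[1] - y[0]) / (t[1] - t[0]))


def relative_rate(trajectory, baseline) -> float:
    """Initial recruitment rate relative to a no-lncRNA baseline run."""
    base = initial_recruitment_rate(baseline)
    if base <= 0:
        raise ValueError(f"baseline recruitment rate is not positive: {base}")
    return initial_recruitment_rate(trajectory) / base


def condensate_lifetime(trajectory, kd: float,
                        cutoff: float = LIFETIME_CUTOFF) -> float:
    """Total duration with phiP_BL above ``cutoff``, in kd*t units.

    All crossings contribute; a trajectory that never reaches the cutoff
    has lifetime 0.
    """
    m = trajectory.metrics
    t = m["t"].to_numpy()
    above = m["phiP_BL"].to_numpy() > cutoff
    if len(t) < 2:
        return 0.0
    dt = np.diff(t)
    return float(kd * np.sum(dt * above[:-1]))


def steady_window_mean(trajectory, column: str,
                       window_frac: float = 0.05,
                       rel_change_tol: float = 1e-4) -> float:
    """Mean of a metrics column over the last ``window_frac`` of the run.

    Emits the value together with a steadiness check: the maximum
    relative change within the window must be below ``rel_change_tol``
    or a warning is attached via ``RuntimeWarning``.
    """
    import warnings

    m = trajectory.metrics
    t = m["t"].to_numpy()
    y = m[column].to_numpy()
    t_lo = t[-1] - window_frac * (t[-1] - t[0])
    win = y[t >= t_lo]
    scale = max(abs(float(np.mean(win))), 1e-300)
    rel = (win.max() - win.min()) / scale
    if rel > rel_change_tol:
        warnings.warn(
            f"{column} not steady in final window: relative span {rel:.2e}",
            RuntimeWarning, stacklevel=2)
    return float(np.mean(win))


def fold_change_mRNA(trajectory_kR, trajectory_kR0) -> float:
    """Steady-state phiM_BL ratio between an active-lncRNA run and its
    kR=0 baseline (both at the same mRNA rate constant kM)."""
    num = steady_window_mean(trajectory_kR, "phiM_BL")
    den = steady_window_mean(trajectory_kR0, "phiM_BL")
    if den <= 1e-300:
        raise ValueError("baseline steady phiM_BL is zero; fold change "
                         "undefined")
    return num / den


def mu_profile(mesh: DiskMesh, phiP, phiR, phiM,
               params: InteractionParams,
               bl_well: LocusWell | None = None,
               rl_well: LocusWell | None = None,
               origin=(0.0, 0.0), species: str = "protein",
               n_bins: int = 60, r_max: float | None = None) -> pd.DataFrame:
    """Radial profile of a species' chemical potential about ``origin``."""
    if species == "protein":
        mu = protein_mu_field(mesh, phiP, phiR, phiM, params, bl_well)
    elif species == "lncRNA":
        mu = lncrna_mu_field(mesh, phiP, phiR, phiM, params, rl_well)
    else:
        raise ValueError(f"unsupported species {species!r}")
    r, vals = radial_profile(mesh, mu, origin=origin, n_bins=n_bins,
                             r_max=r_max)
    return pd.DataFrame({"r": r, "mu": vals})
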