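"""Flory-Huggins free energy, chemical potentials and phase boundaries.

The bulk mixing free energy per lattice site of the four-component
(protein P, lncRNA R, mRNA M, solvent S) incompressible mixture is

    f = (phiP/nP) ln phiP + (phiR/nR) ln phiR + (phiM/nM) ln phiM
        + phiS ln phiS
        + chiP phiP^2 + chiR (phiR + phiM)^2 + chiPR phiP (phiR + phiM)

with phiS = 1 - phiP - phiR - phiM.  The two RNA species carry separate
entropy lengths but share their interaction parameters: both are treated
as like-charged polyanions (chiR > 0 repulsion among RNAs, chiPR < 0
attraction to protein).

The total free energy of a spatial state adds a gradient penalty on the
protein field and the two Gaussian chromatin wells:

    F = Int [ f + (kappa/2)|grad phiP|^2
              + w_BL(r) phiP + w_RL(r) phiR ] dV

where w(r) = -c exp(-|r - r0|^2 / sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, fsolve

from .grid import DiskMesh, gradient_energy, laplacian
from .params import InteractionParams, LocusWell

#: fractions are clipped to [EPS, 1 - EPS] before logarithms
EPS = 1e-9

SPECIES = ("protein", "lncRNA", "mRNA")


class CompositionError(ValueError):
    """Volume fractions outside the physical simplex."""


def _validate(phiP, phiR, phiM):
    phiP = np.asarray(phiP, dtype=float)
    phiR = np.asarray(phiR, dtype=float)
    phiM = np.asarray(phiM, dtype=float)
    for name, phi in (("phiP", phiP), ("phiR", phiR), ("phiM", phiM)):
        if np.any(phi < 0):
            raise CompositionError(f"{name} has negative values")
    phiS = 1.0 - phiP - phiR - phiM
    if np.any(phiS <= 0):
        raise CompositionError(
            "phiP + phiR + phiM >= 1: no solvent left (phiS <= 0)")
    return phiP, phiR, phiM, phiS


def _xlogx(x):
    """x * ln(x) with the x -> 0 limit evaluated as 0."""
    xc = np.clip(x, EPS, None)
    return np.where(x > 0, x * np.log(xc), 0.0)


def _safe_log(x):
    return np.log(np.clip(x, EPS, None))


def bulk_free_energy_density(phiP, phiR, phiM,
                             params: InteractionParams):
    """Bulk Flory-Huggins free energy density (dimensionless, per site)."""
    phiP, phiR, phiM, phiS = _validate(phiP, phiR, phiM)
    rna = phiR + phiM
    f = (_xlogx(phiP) / params.nP + _xlogx(phiR) / params.nR
         + _xlogx(phiM) / params.nM + _xlogx(phiS)
         + params.chiP * phiP ** 2 + params.chiR * rna ** 2
         + params.chiPR * phiP * rna)
    return f if f.ndim else float(f)


def bulk_chemical_potential(species: str, phiP, phiR, phiM,
                            params: InteractionParams):
    """Exact partial derivative of the bulk density w.r.t. one species.

    Fractions at exactly 0 are clipped to EPS inside the logarithm, so the
    dilute divergence of the entropy term is capped rather than -inf.
    """
    phiP, phiR, phiM, phiS = _validate(phiP, phiR, phiM)
    rna = phiR + phiM
    solvent = -(_safe_log(phiS) + 1.0)
    if species == "protein":
        mu = ((_safe_log(phiP) + 1.0) / params.nP + solvent
              + 2.0 * params.chiP * phiP + params.chiPR * rna)
    elif species == "lncRNA":
        mu = ((_safe_log(phiR) + 1.0) / params.nR + solvent
              + 2.0 * params.chiR * rna + params.chiPR * phiP)
    elif species == "mRNA":
        mu = ((_safe_log(phiM) + 1.0) / params.nM + solvent
              + 2.0 * params.chiR * rna + params.chiPR * phiP)
    else:
        raise ValueError(f"unknown species {species!r}; expected {SPECIES}")
    return mu if mu.ndim else float(mu)


def composition_hessian(phiP, phiR, phiM, params: InteractionParams):
    """3x3 Hessian of the bulk density in (phiP, phiR, phiM).

    Its minimum eigenvalue diagnoses local thermodynamic stability of a
    composition; along an RNA ramp at fixed protein it is non-monotonic
    for the reentrant presets (destabilized by a little RNA, restabilized
    by a lot).
    """
    phiP, phiR, phiM, phiS = _validate(phiP, phiR, phiM)
    phiPc = np.clip(phiP, EPS, None)
    phiRc = np.clip(phiR, EPS, None)
    phiMc = np.clip(phiM, EPS, None)
    invS = 1.0 / phiS
    H = np.empty((3, 3))
    H[0, 0] = 1.0 / (params.nP * phiPc) + invS + 2.0 * params.chiP
    H[1, 1] = 1.0 / (params.nR * phiRc) + invS + 2.0 * params.chiR
    H[2, 2] = 1.0 / (params.nM * phiMc) + invS + 2.0 * params.chiR
    H[0, 1] = H[1, 0] = invS + params.chiPR
    H[0, 2] = H[2, 0] = invS + params.chiPR
    H[1, 2] = H[2, 1] = invS + 2.0 * params.chiR
    return H


def locus_field(mesh: DiskMesh, well: LocusWell) -> np.ndarray:
    """Per-cell well potential -c exp(-|r - center|^2 / sigma^2)."""
    return well.potential(mesh.x, mesh.y)


def total_free_energy(mesh: DiskMesh, phiP, phiR, phiM,
                      params: InteractionParams,
                      bl_well: LocusWell | None = None,
                      rl_well: LocusWell | None = None) -> float:
    """Total free energy of a spatial state by mesh quadrature."""
    phiP = mesh.check_field(np.asarray(phiP, dtype=float))
    phiR = mesh.check_field(np.asarray(phiR, dtype=float))
    phiM = mesh.check_field(np.asarray(phiM, dtype=float))
    f = bulk_free_energy_density(phiP, phiR, phiM, params)
    total = np.sum(f) * mesh.cell_area
    total += 0.5 * params.kappa * gradient_energy(mesh, phiP)
    if bl_well is not None:
        total += np.sum(locus_field(mesh, bl_well) * phiP) * mesh.cell_area
    if rl_well is not None:
        total += np.sum(locus_field(mesh, rl_well) * phiR) * mesh.cell_area
    return float(total)


def protein_mu_field(mesh: DiskMesh, phiP, phiR, phiM,
                     params: InteractionParams,
                     bl_well: LocusWell | None = None) -> np.ndarray:
    """Protein chemical potential field: bulk - kappa lap(phiP) + BL well."""
    mu = bulk_chemical_potential("protein", phiP, phiR, phiM, params)
    mu = mu - params.kappa * laplacian(mesh, phiP)
    if bl_well is not None:
        mu = mu + locus_field(mesh, bl_well)
    return mu


def lncrna_mu_field(mesh: DiskMesh, phiP, phiR, phiM,
                    params: InteractionParams,
                    rl_well: LocusWell | None = None) -> np.ndarray:
    """lncRNA chemical potential field: bulk + RL well.

    The surface term penalizes only protein gradients, so there is no
    kappa contribution here.
    """
    mu = bulk_chemical_potential("lncRNA", phiP, phiR, phiM, params)
    if rl_well is not None:
        mu = mu + locus_field(mesh, rl_well)
    return np.asarray(mu)


# ---------------------------------------------------------------------------
# protein-solvent binary phase boundaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseBoundary:
    """Binodal and spinodal of the protein-solvent binary mixture.

    ``phi_light`` (the dilute coexistence branch) is the concentration
    threshold above which a region counts as a condensate.
    """

    exists: bool
    phi_light: float = np.nan
    phi_dense: float = np.nan
    phi_spin_lo: float = np.nan
    phi_spin_hi: float = np.nan

    def __post_init__(self):
        vals = (self.phi_light, self.phi_spin_lo,
                self.phi_spin_hi, self.phi_dense)
        if self.exists and np.all(np.isfinite(vals)):
            if not (0 < vals[0] < vals[1] <= vals[2] < vals[3] < 1):
                raise ValueError(
                    f"phase-boundary ordering violated: {vals}")


def _binary_f(phi, nP, chiP):
    return (_xlogx(phi) / nP + _xlogx(1.0 - phi) + chiP * phi ** 2)


def _binary_mu(phi, nP, chiP):
    return ((_safe_log(phi) + 1.0) / nP - (_safe_log(1.0 - phi) + 1.0)
            + 2.0 * chiP * phi)


def critical_chi(nP: float) -> float:
    """chiP below which the protein-solvent binary demixes."""
    return -((1.0 + np.sqrt(nP)) ** 2) / (2.0 * nP)


def spinodal(params: InteractionParams) -> PhaseBoundary:
    """Spinodal bounds of the protein-solvent binary.

    Roots of f''(phi) = 1/(nP phi) + 1/(1 - phi) + 2 chiP = 0.  Returns
    ``exists=False`` above the critical point.
    """
    nP, chiP = params.nP, params.chiP
    chic = critical_chi(nP)
    phic = 1.0 / (1.0 + np.sqrt(nP))
    if chiP >= chic:
        return PhaseBoundary(exists=False)

    def fpp(phi):
        return 1.0 / (nP * phi) + 1.0 / (1.0 - phi) + 2.0 * chiP

    lo = brentq(fpp, 1e-12, phic)
    hi = brentq(fpp, phic, 1.0 - 1e-12)
    # binodal branches are filled in by binodal(); NaN here means unset
    return PhaseBoundary(exists=True, phi_spin_lo=lo, phi_spin_hi=hi)


def binodal(params: InteractionParams) -> PhaseBoundary:
    """Coexistence fractions of the protein-solvent binary.

    Common-tangent construction on
    f(phi) = (phi/nP) ln phi + (1-phi) ln(1-phi) + chiP phi^2:
    equal chemical potential and equal exchange grand potential
    (f - phi f') on the two branches.
    """
    sp = spinodal(params)
    if not sp.exists:
        return PhaseBoundary(exists=False)
    nP, chiP = params.nP, params.chiP

    def grand(phi):
        return _binary_f(phi, nP, chiP) - phi * _binary_mu(phi, nP, chiP)

    lo_cap = sp.phi_spin_lo * (1.0 - 1e-12)
    hi_cap = sp.phi_spin_hi * (1.0 + 1e-12)

    def dilute_partner(p2):
        """phi on the dilute branch with the same chemical potential.

        mu is strictly increasing on (0, spin_lo) (f'' > 0 there), so the
        match is found by bisection; mu -> -inf as phi -> 0 guarantees a
        bracket whenever mu(p2) < mu(spin_lo).
        """
        target = _binary_mu(p2, nP, chiP)
        if target >= _binary_mu(lo_cap, nP, chiP):
            return lo_cap
        return brentq(lambda q: _binary_mu(q, nP, chiP) - target,
                      1e-300, lo_cap, xtol=1e-15)

    def tangent_gap(p2):
        return grand(dilute_partner(p2)) - grand(p2)

    # bracket the dense branch: the grand-potential gap changes sign
    # between the spinodal and phi -> 1
    grid = np.linspace(hi_cap + 1e-9, 1.0 - 1e-9, 400)
    gaps = np.array([tangent_gap(g) for g in grid])
    sign_change = np.nonzero(np.diff(np.sign(gaps)) != 0)[0]
    if sign_change.size == 0:
        raise RuntimeError(
            f"binodal solve failed (nP={nP}, chiP={chiP}): no "
            "common-tangent bracket found on the dense branch")
    k = sign_change[-1]
    p2 = brentq(tangent_gap, grid[k], grid[k + 1], xtol=1e-14)
    p1 = dilute_partner(p2)
    if not (0 < p1 < sp.phi_spin_lo and sp.phi_spin_hi < p2 < 1):
        raise RuntimeError(
            f"binodal solve failed (nP={nP}, chiP={chiP}): solution "
            f"({p1}, {p2}) violates ordering")
    return PhaseBoundary(exists=True, phi_light=p1, phi_dense=p2,
                         phi_spin_lo=sp.phi_spin_lo,
                         phi_spin_hi=sp.phi_spin_hi)
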