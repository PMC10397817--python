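"""Free-energy, chemical-potential and phase-boundary unit tests."""

import numpy as np
import pytest

from lncphase import (InteractionParams, binodal, bulk_chemical_potential,
                      composition_hessian, critical_chi, spinodal)
from lncphase.free_energy import (CompositionError, _binary_f,
                                  bulk_free_energy_density)

PARAMS = InteractionParams()


def test_pure_solvent_has_zero_energy():
    assert bulk_free_energy_density(0.0, 0.0, 0.0, PARAMS) == 0.0


def test_known_binary_value():
    # f = (phi/n) ln phi + (1-phi) ln(1-phi) + chiP phi^2 at phi=0.5
    p = InteractionParams(chiP=-1.0, chiR=0.5, chiPR=-1.0, nP=1.0)
    expected = 0.5 * np.log(0.5) + 0.5 * np.log(0.5) - 1.0 * 0.25
    assert bulk_free_energy_density(0.5, 0.0, 0.0, p) == pytest.approx(
        expected, rel=1e-12)


def test_interaction_terms_additive():
    # the chi terms are read off by subtracting the entropy-only value
    p0 = InteractionParams(chiP=-1e-12, chiR=1e-12, chiPR=-1e-12)
    f0 = bulk_free_energy_density(0.1, 0.05, 0.02, p0)
    f1 = bulk_free_energy_density(0.1, 0.05, 0.02, PARAMS)
    rna = 0.05 + 0.02
    expected = (PARAMS.chiP * 0.1 ** 2 + PARAMS.chiR * rna ** 2
                + PARAMS.chiPR * 0.1 * rna)
    assert f1 - f0 == pytest.approx(expected, abs=1e-9)


def test_composition_errors():
    with pytest.raises(CompositionError):
        bulk_free_energy_density(-0.01, 0.0, 0.0, PARAMS)
    with pytest.raises(CompositionError):
        bulk_free_energy_density(0.5, 0.4, 0.2, PARAMS)


@pytest.mark.parametrize("species,index", [("protein", 0),
                                           ("lncRNA", 1), ("mRNA", 2)])
def test_chemical_potential_is_exact_partial(species, index):
    point = np.array([0.08, 0.03, 0.015])
    h = 1e-6
    plus, minus = point.copy(), point.copy()
    plus[index] += h
    minus[index] -= h
    fd = (bulk_free_energy_density(*plus, PARAMS)
          - bulk_free_energy_density(*minus, PARAMS)) / (2 * h)
    mu = bulk_chemical_potential(species, *point, PARAMS)
    assert mu == pytest.approx(fd, rel=1e-6)


def test_hessian_matches_finite_differences():
    point = np.array([0.08, 0.03, 0.015])
    H = composition_hessian(*point, PARAMS)
    h = 1e-5
    species = ("protein", "lncRNA", "mRNA")
    for i in range(3):
        for j in range(3):
            plus, minus = point.copy(), point.copy()
            plus[j] += h
            minus[j] -= h
            fd = (bulk_chemical_potential(species[i], *plus, PARAMS)
                  - bulk_chemical_potential(species[i], *minus, PARAMS)
                  ) / (2 * h)
            assert H[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_stability_nonmonotonic_along_rna_ramp():
    # reentrance signature: adding a little RNA destabilizes the mixture,
    # a lot restabilizes it
    lam = []
    for phiR in np.linspace(0.0, 0.6, 25):
        H = composition_hessian(0.1, phiR, 0.0, PARAMS)
        lam.append(np.linalg.eigvalsh(H)[0])
    lam = np.array(lam)
    k = int(np.argmin(lam))
    assert 0 < k < len(lam) - 1
    assert lam[-1] > lam[k] and lam[0] > lam[k]


def test_critical_chi_closed_form():
    nP = PARAMS.nP
    assert critical_chi(nP) == pytest.approx(
        -((1 + np.sqrt(nP)) ** 2) / (2 * nP), rel=1e-14)
    assert critical_chi(10.0) == pytest.approx(-0.8662277660168379)


def test_spinodal_roots_satisfy_curvature_equation():
    sp = spinodal(PARAMS)
    assert sp.exists
    for phi in (sp.phi_spin_lo, sp.phi_spin_hi):
        assert (1 / (PARAMS.nP * phi) + 1 / (1 - phi)
                + 2 * PARAMS.chiP) == pytest.approx(0.0, abs=1e-10)
    assert not spinodal(InteractionParams(chiP=-0.5)).exists


def test_binodal_symmetric_oracle():
    # for nP=1 the binary is symmetric about 1/2: branches are mirror
    # images and solve ln(phi/(1-phi)) + chi(1-2 phi) ... known values
    # for chi=-3 (in this sign convention): 0.07071, 0.92929
    b = binodal(InteractionParams(chiP=-3.0, nP=1.0))
    assert b.phi_light == pytest.approx(0.07071, abs=2e-5)
    assert b.phi_dense == pytest.approx(1 - b.phi_light, rel=1e-10)


@pytest.mark.parametrize("chiP", [-0.90, -0.93, -1.2, -2.0])
def test_binodal_vs_bruteforce_common_tangent(chiP):
    """Compare against a grid search for the common tangent line."""
    p = InteractionParams(chiP=chiP)
    b = binodal(p)
    phis = np.linspace(1e-6, 1 - 1e-6, 60001)
    f = _binary_f(phis, p.nP, p.chiP)
    # lower convex hull via Andrew monotone chain on (phi, f)
    hull = []
    for x, y in zip(phis, f):
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1) <= 0:
                hull.pop()
            else:
                break
        hull.append((x, y))
    hx = np.array([h[0] for h in hull])
    gaps = np.diff(hx)
    k = int(np.argmax(gaps))
    assert gaps[k] > 0.01, "no coexistence gap found by brute force"
    assert b.phi_light == pytest.approx(hx[k], abs=1e-3)
    assert b.phi_dense == pytest.approx(hx[k + 1], abs=1e-3)


def test_boundary_ordering_invariant():
    b = binodal(PARAMS)
    assert (0 < b.phi_light < b.phi_spin_lo
            <= b.phi_spin_hi < b.phi_dense < 1)


def test_params_validation():
    with pytest.raises(ValueError):
        InteractionParams(nP=0.5)
    with pytest.raises(ValueError):
        InteractionParams(kappa=-0.1)
    with pytest.warns(UserWarning):
        InteractionParams(chiP=0.3)
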