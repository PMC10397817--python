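"""Condensate-formation model tests: invariants, oracles and the
qualitative locus-distance / lncRNA-dose behaviors."""

from dataclasses import replace

import numpy as np
import pytest

from lncphase import (InteractionParams, LocusWell, build_mesh,
                      formation_preset, simulate_formation)
from lncphase.analysis import relative_rate
from lncphase.formation import (FormationConfig, condensate_threshold,
                                equilibrium_lncrna_profile)
from lncphase.free_energy import locus_field, protein_mu_field
from lncphase.stepping import StepControls


def test_config_validation_and_locus_geometry():
    with pytest.raises(ValueError):
        FormationConfig(phiPavg=0.7, phiRavg=0.4)
    with pytest.raises(ValueError):
        FormationConfig(phiRavg=-0.1)
    cfg = FormationConfig().with_loci(2.4, sigma=1.5)
    assert cfg.LP == pytest.approx(2.4)
    assert cfg.bl_well.center == (-1.2, 0.0)
    assert cfg.rl_well.center == (1.2, 0.0)
    assert cfg.bl_well.sigma == 1.5


def test_lncrna_profile_mean_and_saturation(fast_mesh):
    well = LocusWell(center=(0.0, 0.0), sigma=1.0, depth=0.18)
    prof = equilibrium_lncrna_profile(fast_mesh, well, nR=10.0,
                                      phiRavg=0.01)
    assert prof.mean() == pytest.approx(0.01, rel=1e-12)
    assert prof.argmax() == fast_mesh.r().argmin()  # peaks at the well
    with pytest.raises(ValueError):
        # deep well + high dose saturates the Boltzmann profile
        equilibrium_lncrna_profile(fast_mesh, replace(well, depth=2.0),
                                   nR=10.0, phiRavg=0.2)
    assert equilibrium_lncrna_profile(fast_mesh, well, 10.0, 0.0).max() == 0


def test_uniform_state_persists_without_wells(fast_mesh):
    cfg = FormationConfig(
        bl_well=LocusWell(center=(-0.4, 0.0), sigma=1.0, depth=0.0),
        rl_well=LocusWell(center=(0.4, 0.0), sigma=1.0, depth=0.0),
        phiPavg=0.04, phiRavg=0.0, radius=7.5, spacing=0.15,
        controls=StepControls(n_steps=100, t_max=1e9))
    traj = simulate_formation(cfg, mesh=fast_mesh)
    assert traj.termination == "steady"
    assert np.max(np.abs(traj.final_fields["phiP"] - 0.04)) < 1e-12


def test_dilute_lncrna_profile_is_stationary(fast_mesh):
    # with the protein decoupled (chiPR ~ 0, cP = 0) and a dilute dose,
    # the Boltzmann profile is the stationary state of the lncRNA
    # equation; 200 steps must leave it essentially unchanged
    params = InteractionParams(chiP=-0.5, chiR=0.5, chiPR=-1e-12)
    cfg = FormationConfig(
        params=params,
        bl_well=LocusWell(center=(-0.4, 0.0), sigma=1.0, depth=0.0),
        rl_well=LocusWell(center=(0.4, 0.0), sigma=1.0, depth=0.18),
        phiPavg=0.04, phiRavg=1e-4, radius=7.5, spacing=0.15,
        controls=StepControls(n_steps=200, t_max=1e9, steady_tol=0.0))
    traj = simulate_formation(cfg, mesh=fast_mesh)
    ref = equilibrium_lncrna_profile(fast_mesh, cfg.rl_well, params.nR,
                                     1e-4)
    dev = np.max(np.abs(traj.final_fields["phiR"] - ref)) / ref.max()
    assert dev < 0.03


def test_mass_conservation(formation_with_rna):
    assert formation_with_rna.conservation_drift("phiP") < 1e-8
    assert formation_with_rna.conservation_drift("phiR") < 1e-8


def test_free_energy_never_increases(formation_with_rna):
    F = formation_with_rna.metrics["F_total"].to_numpy()
    scale = abs(F[0]) + 1e-300
    assert np.all(np.diff(F) <= 1e-12 * scale)
    assert F[-1] < F[0]  # and it actually relaxes


def test_rotation_symmetry_of_locus_pair(fast_mesh, formation_with_rna):
    # the masked Cartesian mesh is symmetric under 90-degree rotation,
    # so rotating the locus pair must reproduce the metrics exactly
    cfg = formation_preset(phiRavg=0.01, LP=0.8, profile="fast")
    cfg = replace(cfg,
                  bl_well=replace(cfg.bl_well, center=(0.0, -0.4)),
                  rl_well=replace(cfg.rl_well, center=(0.0, 0.4)))
    rotated = simulate_formation(cfg, mesh=fast_mesh)
    assert rotated.metrics["partition"].iloc[-1] == pytest.approx(
        formation_with_rna.metrics["partition"].iloc[-1], rel=1e-9)


def test_mu_flattens_toward_equilibrium(fast_mesh, formation_with_rna):
    # model-B dynamics drive the (well-augmented) chemical potential
    # toward a spatial constant; its spread must contract substantially
    cfg = formation_with_rna.config
    w = locus_field(fast_mesh, cfg.bl_well)

    def spread(fields):
        mu = protein_mu_field(fast_mesh, fields["phiP"], fields["phiR"],
                              fast_mesh.zeros(), cfg.params) + w
        return float(mu.max() - mu.min())

    s0 = spread(formation_with_rna.snapshots[0][1])
    s1 = spread(formation_with_rna.final_fields)
    assert s1 < s0 / 3.0


def test_condensate_only_with_lncrna(formation_no_rna, formation_with_rna):
    thr = condensate_threshold(formation_no_rna.config.params)
    assert np.isfinite(thr)
    assert formation_no_rna.metrics["phiP_BL"].iloc[-1] < thr
    assert formation_with_rna.metrics["phiP_BL"].iloc[-1] >= thr
    assert not bool(formation_no_rna.metrics["condensate"].iloc[-1])
    assert bool(formation_with_rna.metrics["condensate"].iloc[-1])


def test_partition_decreases_with_locus_distance(lp_sweep):
    lps = sorted(lp_sweep)
    parts = [lp_sweep[lp].metrics["partition"].iloc[-1] for lp in lps]
    # enrichment weakens as the loci separate (small numerical wiggle
    # allowed once the condensate is gone and ratios are near-flat)
    for a, b in zip(parts, parts[1:]):
        assert b <= a * 1.02
    assert parts[-1] < parts[0]


def test_condensate_crossover_is_single_flip(lp_sweep):
    lps = sorted(lp_sweep)
    flags = [bool(lp_sweep[lp].metrics["condensate"].iloc[-1])
             for lp in lps]
    assert flags[0] and not flags[-1]
    flips = sum(a != b for a, b in zip(flags, flags[1:]))
    assert flips == 1


def test_partition_reentrant_in_lncrna_dose(reentrance_runs):
    doses = sorted(reentrance_runs)
    parts = [reentrance_runs[d].metrics["partition"].iloc[-1]
             for d in doses]
    k = int(np.argmax(parts))
    assert 0 < k < len(parts) - 1
    assert parts[-1] < parts[k]
    assert parts[0] < parts[k]


def test_lncrna_accelerates_initial_recruitment(formation_no_rna,
                                                formation_with_rna):
    assert relative_rate(formation_with_rna, formation_no_rna) > 1.0
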