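"""Transcription-model tests: reaction kinetics, steady-state oracles,
the equilibrium reduction and the qualitative expression regimes."""

import numpy as np
import pytest

from lncphase import (TranscriptionConfig, condensate_lifetime,
                      formation_preset, integrate, reaction_rates,
                      simulate_formation, simulate_transcription,
                      steady_rna_fields, steady_window_mean,
                      transcription_preset)
from lncphase.analysis import LIFETIME_CUTOFF


def test_config_validation():
    with pytest.raises(ValueError):
        TranscriptionConfig(kM=-0.01)
    with pytest.raises(ValueError):
        TranscriptionConfig(kM=0.01, kdM=0.0)
    with pytest.raises(ValueError):
        TranscriptionConfig(kR=0.01, kdR=0.0)
    with pytest.raises(ValueError):
        TranscriptionConfig(phiPavg=1.0)
    assert TranscriptionConfig().rl_production_well.depth == 0.0


def test_reaction_rates_oracle(fast_mesh):
    cfg = transcription_preset(kM=0.01, kR=0.002, profile="fast")
    phiP = fast_mesh.full(0.04)
    phiM = fast_mesh.full(0.001)
    phiR = fast_mesh.zeros()
    d_phiM, d_phiR = reaction_rates(fast_mesh, phiP, phiM, phiR, cfg)
    g_bl = cfg.bl_well.gaussian(fast_mesh.x, fast_mesh.y)
    g_rl = cfg.rl_production_well.gaussian(fast_mesh.x, fast_mesh.y)
    assert np.allclose(d_phiM, cfg.kM * g_bl * 0.04 - cfg.kdM * 0.001,
                       rtol=0, atol=1e-15)
    assert np.allclose(d_phiR, cfg.kR * g_rl, rtol=0, atol=1e-15)


def test_direct_steady_solve_balances_exactly(fast_mesh):
    # discrete production-decay balance of the steady solve: summing the
    # linear system over cells kills the diffusion term identically
    cfg = transcription_preset(kM=0.001, kR=0.005, profile="fast")
    phiM, phiR = steady_rna_fields(fast_mesh, cfg)
    g_rl = cfg.rl_production_well.gaussian(fast_mesh.x, fast_mesh.y)
    g_bl = cfg.bl_well.gaussian(fast_mesh.x, fast_mesh.y)
    assert cfg.kdR * phiR.sum() == pytest.approx(
        cfg.kR * g_rl.sum(), rel=1e-12)
    assert cfg.kdM * phiM.sum() == pytest.approx(
        cfg.kM * 0.04 * g_bl.sum(), rel=1e-12)
    assert phiM.min() >= 0 and phiR.min() >= 0


def test_steady_lncrna_is_linear_in_kR(fast_mesh):
    # the lncRNA equation is linear with constitutive production, so its
    # steady profile scales exactly with kR
    cfg1 = transcription_preset(kM=0.001, kR=0.005, profile="fast")
    cfg2 = transcription_preset(kM=0.001, kR=0.010, profile="fast")
    _, phiR1 = steady_rna_fields(fast_mesh, cfg1)
    _, phiR2 = steady_rna_fields(fast_mesh, cfg2)
    assert np.max(np.abs(phiR2 - 2.0 * phiR1)) < 1e-12 * phiR2.max()


def test_trajectory_reaches_production_decay_balance(fast_mesh,
                                                     low_km_runs):
    traj = low_km_runs[0.005]
    cfg = traj.config
    f = traj.final_fields
    g_rl = cfg.rl_production_well.gaussian(fast_mesh.x, fast_mesh.y)
    g_bl = cfg.bl_well.gaussian(fast_mesh.x, fast_mesh.y)
    prodR = cfg.kR * integrate(fast_mesh, g_rl)
    decayR = cfg.kdR * integrate(fast_mesh, f["phiR"])
    assert decayR == pytest.approx(prodR, rel=0.01)
    prodM = cfg.kM * integrate(fast_mesh, g_bl * f["phiP"])
    decayM = cfg.kdM * integrate(fast_mesh, f["phiM"])
    assert decayM == pytest.approx(prodM, rel=0.01)


def test_protein_conserved_and_rna_nonnegative(low_km_runs):
    traj = low_km_runs[0.005]
    assert traj.conservation_drift("phiP") < 1e-8
    assert traj.final_fields["phiM"].min() >= 0
    assert traj.final_fields["phiR"].min() >= 0


def test_zero_rate_reduction_matches_formation(fast_mesh,
                                               formation_no_rna):
    # with kM = kR = 0 the transcription model is the formation model
    # without lncRNA: the protein fields must agree
    cfg = transcription_preset(kM=0.0, kR=0.0, profile="fast")
    traj = simulate_transcription(cfg, mesh=fast_mesh)
    assert np.max(np.abs(traj.final_fields["phiM"])) == 0
    assert np.max(np.abs(traj.final_fields["phiR"])) == 0
    diff = np.max(np.abs(traj.final_fields["phiP"]
                         - formation_no_rna.final_fields["phiP"]))
    assert diff < 5e-4


def test_three_expression_regimes(regime_runs):
    low, mod, high = (regime_runs[k] for k in ("low", "moderate", "high"))
    # low expression: never condenses
    assert not low.metrics["condensate"].any()
    # moderate expression: a condensate forms and persists to the end
    assert bool(mod.metrics["condensate"].iloc[-1])
    # high expression: transient -- the condensate assembles above the
    # lifetime cutoff, then dissolves below it
    peaks = high.metrics["phiP_BL"].max()
    assert peaks > LIFETIME_CUTOFF
    assert high.metrics["phiP_BL"].iloc[-1] < LIFETIME_CUTOFF


def test_lifetime_ordering_across_regimes(regime_runs):
    lives = {k: condensate_lifetime(t, t.config.kdM)
             for k, t in regime_runs.items()}
    assert lives["low"] == 0.0
    assert lives["high"] > 0.0
    assert lives["moderate"] > 2 * lives["high"]


def test_lncrna_dose_raises_local_lncrna(low_km_runs):
    krs = sorted(low_km_runs)
    phiR = [steady_window_mean(low_km_runs[k], "phiR_BL") for k in krs]
    assert phiR[0] == 0.0  # no production, no lncRNA
    assert all(b > a for a, b in zip(phiR, phiR[1:]))


def test_lncrna_enhances_mrna_at_low_expression(low_km_runs):
    base = steady_window_mean(low_km_runs[0.0], "phiM_BL")
    boosted = steady_window_mean(low_km_runs[0.01], "phiM_BL")
    assert boosted > base


def test_lncrna_shortens_lifetime_at_high_expression(high_km_runs):
    base = condensate_lifetime(high_km_runs[0.0],
                               high_km_runs[0.0].config.kdM)
    dosed = condensate_lifetime(high_km_runs[0.02],
                                high_km_runs[0.02].config.kdM)
    assert dosed < base
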