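"""Shared fixtures: expensive simulation runs are computed once per
session on the reduced-cost numerical profile and reused across the
property and acceptance tests."""

from __future__ import annotations

import pytest

from lncphase import (LP_SWEEP, build_mesh, formation_preset,
                      simulate_formation, simulate_transcription,
                      transcription_preset)

#: kR grid used by the fold-change fixtures (spans [0.001, 0.02])
KR_GRID = (0.001, 0.002, 0.005, 0.01, 0.02)


@pytest.fixture(scope="session")
def fast_mesh():
    return build_mesh(7.5, 0.15)


@pytest.fixture(scope="session")
def formation_no_rna(fast_mesh):
    """Calibrated formation run with no lncRNA (phiRavg = 0)."""
    cfg = formation_preset(phiRavg=0.0, LP=0.8, profile="fast")
    return simulate_formation(cfg, mesh=fast_mesh)


@pytest.fixture(scope="session")
def formation_with_rna(fast_mesh):
    """Calibrated formation run with phiRavg = 0.01 at LP = 0.8 sigma."""
    cfg = formation_preset(phiRavg=0.01, LP=0.8, profile="fast")
    return simulate_formation(cfg, mesh=fast_mesh)


@pytest.fixture(scope="session")
def lp_sweep(fast_mesh):
    """Locus-distance sweep at phiRavg = 0.001 (one run per LP/sigma)."""
    out = {}
    for lp in LP_SWEEP:
        cfg = formation_preset(phiRavg=0.001, LP=lp, profile="fast")
        out[lp] = simulate_formation(cfg, mesh=fast_mesh)
    return out


@pytest.fixture(scope="session")
def reentrance_runs(fast_mesh, formation_no_rna):
    """Partition ratio vs phiRavg at LP = 0.8 sigma."""
    out = {0.0: formation_no_rna}
    for phiR in (0.005, 0.01, 0.05, 0.15):
        cfg = formation_preset(phiRavg=phiR, LP=0.8, profile="fast")
        out[phiR] = simulate_formation(cfg, mesh=fast_mesh)
    return out


@pytest.fixture(scope="session")
def low_km_runs(fast_mesh):
    """Transcription runs at kM = 0.001 over the kR sweep (incl. kR=0)."""
    out = {}
    for kR in (0.0,) + KR_GRID:
        cfg = transcription_preset(kM=0.001, kR=kR, profile="fast")
        out[kR] = simulate_transcription(cfg, mesh=fast_mesh)
    return out


@pytest.fixture(scope="session")
def high_km_runs(fast_mesh):
    """Transcription runs at kM = 0.1 at kR = 0 and the top of the sweep."""
    out = {}
    for kR in (0.0, KR_GRID[-1]):
        cfg = transcription_preset(kM=0.1, kR=kR, profile="fast")
        out[kR] = simulate_transcription(cfg, mesh=fast_mesh)
    return out


@pytest.fixture(scope="session")
def regime_runs(fast_mesh, high_km_runs):
    """mRNA-only (kR = 0) runs for the three expression regimes."""
    out = {"high": high_km_runs[0.0]}
    for name in ("low", "moderate"):
        cfg = transcription_preset(kM=name, kR=0.0, profile="fast")
        out[name] = simulate_transcription(cfg, mesh=fast_mesh)
    return out
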