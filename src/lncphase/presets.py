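"""Calibrated parameter preset and the standard sweep definitions.

The interaction parameters and well depths below are the output of
:func:`lncphase.calibrate.calibrate` (see that module for the four regime
constraints); the kinetic constants are calibrated against the
qualitative transcription regimes (see docs/methods.md).  All sweeps in
:mod:`lncphase.cli` start from this preset.

Two numerical profiles are provided: ``full`` matches the reference scale
(disk radius 15, spacing 0.1) and ``fast`` (radius 7.5, spacing 0.15) is
a reduced-cost profile validated to preserve all qualitative orderings
used by the test suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .formation import FormationConfig
from .params import InteractionParams, LocusWell
from .stepping import StepControls
from .transcription import TranscriptionConfig

#: numerical profiles: (disk radius, grid spacing)
PROFILES = {"full": (15.0, 0.1), "fast": (7.5, 0.15)}

#: calibrated interaction parameters (see lncphase.calibrate)
CALIBRATED_PARAMS = InteractionParams(
    chiP=-0.93, chiR=0.5, chiPR=-3.5,
    nP=10.0, nR=10.0, nM=10.0, kappa=0.5)

#: calibrated locus-well depths
CP_DEPTH = 0.12      # BL well depth acting on the protein
CR_DEPTH = 0.18      # RL well depth acting on the lncRNA (formation model)

#: calibrated kinetic constants of the transcription model
KD_RNA = 0.005       # decay constant shared by mRNA and lncRNA
DM_RNA = 0.005       # mRNA diffusivity
DR_RNA = 0.03        # lncRNA diffusivity (transcription model)

#: kM presets: the three expression regimes of the mRNA-only reduction
KM_REGIMES = {"low": 0.0003, "moderate": 0.01, "high": 0.1}

#: kM rows of the fold-change sweep and the kR grid it scans
KM_SWEEP_ROWS = (0.001, 0.01, 0.1)
KR_SWEEP = (0.0, 0.001, 0.002, 0.005, 0.01, 0.02)

#: LP/sigma grid of the locus-distance sweep
LP_SWEEP = (0.8, 1.2, 1.6, 2.0, 2.4, 2.8)

#: (phiPavg, phiRavg) grids of the phase-behavior sweep
PHIP_SWEEP = (0.02, 0.03, 0.04, 0.05, 0.06)
PHIR_SWEEP = (0.0, 0.005, 0.01, 0.05, 0.15)


def _grid(profile: str) -> tuple[float, float]:
    try:
        return PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; expected one of {set(PROFILES)}")


def formation_preset(phiRavg: float = 0.01, LP: float = 0.8,
                     phiPavg: float = 0.04, sigma: float = 1.0,
                     profile: str = "full") -> FormationConfig:
    """Calibrated formation configuration with loci at distance ``LP*sigma``."""
    radius, spacing = _grid(profile)
    cfg = FormationConfig(
        params=CALIBRATED_PARAMS,
        bl_well=LocusWell(center=(0.0, 0.0), sigma=sigma, depth=CP_DEPTH),
        rl_well=LocusWell(center=(0.0, 0.0), sigma=sigma, depth=CR_DEPTH),
        phiPavg=phiPavg, phiRavg=phiRavg,
        radius=radius, spacing=spacing,
        controls=StepControls(t_max=400.0, n_steps=2000))
    return cfg.with_loci(LP * sigma, sigma)


def transcription_preset(kM: float = 0.01, kR: float = 0.0,
                         LP: float = 0.8, sigma: float = 1.0,
                         phiPavg: float = 0.04,
                         profile: str = "full") -> TranscriptionConfig:
    """Calibrated transcription configuration.

    ``kM`` may also be one of the regime names in :data:`KM_REGIMES`.
    """
    if isinstance(kM, str):
        kM = KM_REGIMES[kM]
    radius, spacing = _grid(profile)
    return TranscriptionConfig(
        params=CALIBRATED_PARAMS,
        bl_well=LocusWell(center=(-LP * sigma / 2, 0.0), sigma=sigma,
                          depth=CP_DEPTH),
        rl_center=(LP * sigma / 2, 0.0), rl_sigma=sigma,
        DM=DM_RNA, DR=DR_RNA, kM=kM, kR=kR, kdM=KD_RNA, kdR=KD_RNA,
        phiPavg=phiPavg, radius=radius, spacing=spacing,
        controls=StepControls(t_max=2000.0, n_steps=8000))


def sweep_points(preset: str, profile: str = "full") -> list[dict]:
    """Grid points of a named sweep; each row configures one run.

    ``fig2``: phiPavg x phiRavg formation grid at LP=0.8 sigma.
    ``fig3``: LP/sigma formation sweep at phiRavg=0.001, phiPavg=0.04.
    ``fig4``: kM x kR transcription grid.
    """
    if preset == "fig2":
        return [{"kind": "formation",
                 "config": formation_preset(phiRavg=phiR, LP=0.8,
                                            phiPavg=phiP, profile=profile),
                 "phiPavg": phiP, "phiRavg": phiR}
                for phiP in PHIP_SWEEP for phiR in PHIR_SWEEP]
    if preset == "fig3":
        return [{"kind": "formation",
                 "config": formation_preset(phiRavg=0.001, LP=lp,
                                            phiPavg=0.04, profile=profile),
                 "LP_over_sigma": lp}
                for lp in LP_SWEEP]
    if preset == "fig4":
        return [{"kind": "transcription",
                 "config": transcription_preset(kM=kM, kR=kR,
                                                profile=profile),
                 "kM": kM, "kR": kR}
                for kM in KM_SWEEP_ROWS for kR in KR_SWEEP]
    raise ValueError(
        f"unknown sweep preset {preset!r}; expected fig2, fig3 or fig4")


def preset_dict() -> dict:
    """The calibrated preset as a flat serializable mapping."""
    p = CALIBRATED_PARAMS
    return {
        "chiP": p.chiP, "chiR": p.chiR, "chiPR": p.chiPR,
        "nP": p.nP, "nR": p.nR, "nM": p.nM, "kappa": p.kappa,
        "cP": CP_DEPTH, "cR": CR_DEPTH, "sigma": 1.0,
        "DP": 1.0, "DR": DR_RNA, "DM": DM_RNA,
        "kdM": KD_RNA, "kdR": KD_RNA,
        "kM_low": KM_REGIMES["low"], "kM_moderate": KM_REGIMES["moderate"],
        "kM_high": KM_REGIMES["high"],
        "phiPavg": 0.04,
    }
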