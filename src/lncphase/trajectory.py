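"""Trajectory container and the per-step recorder used by both dynamics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import bl_region_mask, outside_mask
from .grid import DiskMesh
from .params import LocusWell

METRIC_COLUMNS = ["t", "t_DP_R2", "kd_t", "phiP_BL", "phiP_out",
                  "partition", "phiR_BL", "phiM_BL", "condensate",
                  "F_total"]


@dataclass
class Trajectory:
    """Recorded output of one simulation run.

    Attributes
    ----------
    mesh : DiskMesh
    metrics : pandas.DataFrame
        One row per accepted step with columns ``METRIC_COLUMNS``
        (``F_total`` is NaN for the nonequilibrium transcription model).
    snapshots : list of (t, dict) pairs
        Full concentration fields at the snapshot stride, always
        including the initial and final states.
    phi_light : float
        Condensate-detection threshold (dilute binodal branch) used for
        the ``condensate`` column; inf when no coexistence exists.
    termination : str
        One of ``steady``, ``t_max``, ``step_cap``.
    """

    mesh: DiskMesh
    metrics: pd.DataFrame
    snapshots: list
    phi_light: float
    termination: str
    config: object = None

    @property
    def times(self) -> np.ndarray:
        return self.metrics["t"].to_numpy()

    @property
    def final_fields(self) -> dict:
        return self.snapshots[-1][1]

    def conservation_drift(self, name: str) -> float:
        """Relative drift of a species total between first and last
        snapshot (meaningful for conserved species only)."""
        first = self.snapshots[0][1][name]
        last = self.snapshots[-1][1][name]
        total0 = first.sum()
        if total0 == 0:
            return abs(last.sum())
        return abs(last.sum() - total0) / abs(total0)


class Recorder:
    """Accumulates metrics every accepted step and snapshots at a stride."""

    def __init__(self, mesh: DiskMesh, bl_well: LocusWell,
                 rl_well: LocusWell | None, phi_light: float,
                 DP: float, kd: float = np.nan,
                 snapshot_stride: int = 50,
                 energy=None):
        self.mesh = mesh
        self.phi_light = phi_light
        self.DP = DP
        self.kd = kd
        self.snapshot_stride = max(int(snapshot_stride), 1)
        self.energy = energy
        self._bl = bl_region_mask(mesh, bl_well)
        self._out = outside_mask(mesh, bl_well, rl_well)
        self._rows = []
        self.snapshots = []
        self._n = 0

    def _mean(self, x, mask):
        return float(x[mask].mean())

    def record(self, t: float, fields: dict) -> None:
        phiP = fields["phiP"]
        phiR = fields.get("phiR")
        phiM = fields.get("phiM")
        phiP_BL = self._mean(phiP, self._bl)
        phiP_out = self._mean(phiP, self._out)
        row = (t, t * self.DP / self.mesh.radius ** 2, self.kd * t,
               phiP_BL, phiP_out,
               phiP_BL / phiP_out if phiP_out > 1e-300 else np.inf,
               self._mean(phiR, self._bl) if phiR is not None else 0.0,
               self._mean(phiM, self._bl) if phiM is not None else 0.0,
               float(phiP_BL >= self.phi_light),
               self.energy(fields) if self.energy is not None else np.nan)
        self._rows.append(row)
        if self._n % self.snapshot_stride == 0:
            self.take_snapshot(t, fields)
        self._n += 1

    def take_snapshot(self, t: float, fields: dict) -> None:
        self.snapshots.append(
            (t, {k: v.copy() for k, v in fields.items()}))

    def build(self, termination: str, config=None) -> Trajectory:
        metrics = pd.DataFrame(self._rows, columns=METRIC_COLUMNS)
        return Trajectory(mesh=self.mesh, metrics=metrics,
                          snapshots=self.snapshots,
                          phi_light=self.phi_light,
                          termination=termination, config=config)
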