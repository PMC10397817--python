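"""Parameter containers for the condensate model.

All quantities are in the dimensionless simulation units of the model:
lengths in units of the locus width scale, energies in units of kT per
lattice site, concentrations as volume fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class InteractionParams:
    """Thermodynamic constants of the bulk Flory-Huggins free energy.

    Parameters
    ----------
    chiP : float
        Protein-protein Flory interaction parameter.  Negative values are
        attractive in this sign convention; transcriptional proteins with
        interacting disordered domains have ``chiP < 0``.
    chiR : float
        RNA-RNA interaction parameter, applied within and between the
        lncRNA and mRNA species.  Positive (repulsive) for like-charged
        polyanions.
    chiPR : float
        Protein-RNA interaction parameter, shared by lncRNA and mRNA.
        Negative (attractive) for positively charged RNA-binding regions.
    nP, nR, nM : float
        Effective polymer lengths entering the mixing-entropy terms,
        each >= 1.
    kappa : float
        Surface-penalty coefficient on protein concentration gradients
        (energy * length^2, >= 0).
    """

    chiP: float = -0.93
    chiR: float = 0.5
    chiPR: float = -3.5
    nP: float = 10.0
    nR: float = 10.0
    nM: float = 10.0
    kappa: float = 0.5

    def __post_init__(self) -> None:
        if self.nP < 1 or self.nR < 1 or self.nM < 1:
            raise ValueError("polymer lengths nP, nR, nM must be >= 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        # the biological regime has attractive P-P and P-RNA, repulsive R-R;
        # other signs are legal parameter space but outside that regime
        if self.chiP >= 0:
            warnings.warn("chiP >= 0: protein-protein interactions not attractive",
                          stacklevel=2)
        if self.chiR <= 0:
            warnings.warn("chiR <= 0: RNA-RNA interactions not repulsive",
                          stacklevel=2)
        if self.chiPR >= 0:
            warnings.warn("chiPR >= 0: protein-RNA interactions not attractive",
                          stacklevel=2)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionParams":
        return cls(**d)


@dataclass(frozen=True)
class LocusWell:
    """A Gaussian chromatin attraction well.

    The well contributes ``-depth * exp(-|r - center|^2 / sigma^2)`` to the
    chemical potential of the species it couples to (protein for the
    binding locus, lncRNA for the lncRNA locus).  Note the exponent uses
    ``sigma**2``, not ``2 sigma**2``.
    """

    center: tuple = (0.0, 0.0)
    sigma: float = 1.0
    depth: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if len(self.center) != 2:
            raise ValueError("center must be a 2D position")

    def gaussian(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian profile of the well at (x, y)."""
        cx, cy = self.center
        return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / self.sigma ** 2)

    def potential(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Well potential -c * exp(-|r - r0|^2 / sigma^2) at (x, y)."""
        return -self.depth * self.gaussian(x, y)

    def to_dict(self) -> dict:
        return {"center": list(self.center), "sigma": self.sigma,
                "depth": self.depth}

    @classmethod
    def from_dict(cls, d: dict) -> "LocusWell":
        return cls(center=tuple(d["center"]), sigma=d["sigma"],
                   depth=d["depth"])
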