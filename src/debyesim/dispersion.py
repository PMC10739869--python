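"""Multipole Debye and Cole–Cole dielectric dispersion models.

Biological tissue is strongly dispersive from DC to GHz: its effective
conductivity rises and its relative permittivity falls with frequency as the
alpha (counterion) and beta (Maxwell–Wagner, cell-membrane) relaxation bands
are crossed.  This module represents such a medium as a sum of first-order
Debye poles on top of a static conductivity ``sigma_s`` and a high-frequency
permittivity ``eps_inf``::

    eps*_r(w) = sigma_s / (j w eps0) + eps_inf + sum_k d_eps_k / (1 + (j w tau_k)^(1 - lambda_k))

with ``lambda_k = 0`` for the pure Debye case.  The Cole–Cole broadening
exponent ``lambda_k`` is supported for evaluation only; the time-domain
machinery requires first-order (Debye) poles.

All frequencies are plain Hz; the angular frequency ``w = 2*pi*f`` is formed
internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Vacuum permittivity, F/m (CODATA 2018).  Single shared value package-wide.
EPS0: float = 8.8541878128e-12


class DispersionError(ValueError):
    """Invalid dispersion parameters or evaluation outside the model domain."""


def _check_freq(freq):
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0.0):
        raise DispersionError("frequency must be strictly positive (Hz)")
    return f


@dataclass(frozen=True)
class DebyePole:
    """One first-order relaxation pole.

    Parameters
    ----------
    delta_eps : float
        Relative-permittivity increment of the pole (dimensionless, > 0).
    tau : float
        Relaxation time in seconds (> 0).
    lam : float, optional
        Cole–Cole broadening exponent in [0, 1); 0 gives a pure Debye pole.
    """

    delta_eps: float
    tau: float
    lam: float = 0.0

    def __post_init__(self):
        if not self.delta_eps > 0:
            raise DispersionError(f"delta_eps must be > 0, got {self.delta_eps}")
        if not self.tau > 0:
            raise DispersionError(f"tau must be > 0, got {self.tau}")
        if not (0.0 <= self.lam < 1.0):
            raise DispersionError(f"lambda must be in [0, 1), got {self.lam}")


@dataclass(frozen=True)
class DebyeMultipole:
    """Multipole Debye (or Cole–Cole) dispersion of a bulk medium.

    Poles are stored sorted by relaxation time, longest first; the pole
    labelling is a gauge freedom, so a canonical order makes models
    comparable.

    Parameters
    ----------
    sigma_s : float
        Static (DC) conductivity, S/m (> 0).
    eps_inf : float
        High-frequency relative permittivity (>= 1).
    poles : sequence of DebyePole
        Zero or more relaxation poles.
    """

    sigma_s: float
    eps_inf: float
    poles: tuple[DebyePole, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.sigma_s > 0:
            raise DispersionError(f"sigma_s must be > 0, got {self.sigma_s}")
        if not self.eps_inf >= 1:
            raise DispersionError(f"eps_inf must be >= 1, got {self.eps_inf}")
        poles = tuple(sorted(self.poles, key=lambda p: -p.tau))
        object.__setattr__(self, "poles", poles)

    @property
    def n_poles(self) -> int:
        return len(self.poles)

    @property
    def is_cole_cole(self) -> bool:
        return any(p.lam != 0.0 for p in self.poles)

    # ---- evaluation -----------------------------------------------------

    def complex_permittivity(self, freq) -> np.ndarray | complex:
        """Complex relative permittivity eps*_r at frequency ``freq`` (Hz).

        Includes the conduction term ``sigma_s/(j w eps0)``, so the imaginary
        part is negative and diverges as f -> 0.
        """
        f = _check_freq(freq)
        w = 2.0 * np.pi * f
        jw = 1j * w
        out = self.sigma_s / (jw * EPS0) + self.eps_inf
        for p in self.poles:
            if p.lam == 0.0:
                out = out + p.delta_eps / (1.0 + jw * p.tau)
            else:
                out = out + p.delta_eps / (1.0 + (jw * p.tau) ** (1.0 - p.lam))
        if np.ndim(freq) == 0:
            return complex(out)
        return out

    def effective_properties(self, freq):
        """Effective conductivity (S/m) and real relative permittivity.

        ``sigma_eff = -w eps0 Im(eps*_r)`` and ``eps_r_eff = Re(eps*_r)``.
        For a valid model both are strictly positive, sigma_eff is
        non-decreasing and eps_r_eff non-increasing in frequency.
        """
        f = _check_freq(freq)
        w = 2.0 * np.pi * f
        e = self.complex_permittivity(freq)
        e = np.asarray(e, dtype=complex)
        sigma_eff = -w * EPS0 * e.imag
        eps_r_eff = e.real
        if np.ndim(freq) == 0:
            return float(sigma_eff), float(eps_r_eff)
        return sigma_eff, eps_r_eff

    def terminal_admittance(self, geometry: "SampleGeometry", freq):
        """Complex terminal admittance Y = G + jB (siemens) of a sample.

        The bulk properties scale by the cell constant S/l; for an applied
        voltage V the complex terminal current is ``V * Y``.
        """
        f = _check_freq(freq)
        w = 2.0 * np.pi * f
        sigma_eff, eps_r_eff = self.effective_properties(freq)
        Y = (geometry.area / geometry.length) * (sigma_eff + 1j * w * EPS0 * eps_r_eff)
        if np.ndim(freq) == 0:
            return complex(Y)
        return Y

    # ---- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "sigma_s": self.sigma_s,
            "eps_inf": self.eps_inf,
            "poles": [{"delta_eps": p.delta_eps, "tau": p.tau} for p in self.poles],
        }
        if self.is_cole_cole:
            for p, pd in zip(self.poles, d["poles"]):
                pd["lambda"] = p.lam
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DebyeMultipole":
        poles = tuple(
            DebyePole(p["delta_eps"], p["tau"], p.get("lambda", 0.0))
            for p in d.get("poles", [])
        )
        return cls(sigma_s=d["sigma_s"], eps_inf=d["eps_inf"], poles=poles)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "DebyeMultipole":
        return cls.from_dict(json.loads(Path(path).read_text()))


def cole_cole(sigma_s: float, eps_inf: float,
              poles: Sequence[tuple[float, float, float]]) -> DebyeMultipole:
    """Build a Cole–Cole model from (delta_eps, tau, lambda) triples."""
    return DebyeMultipole(
        sigma_s, eps_inf, tuple(DebyePole(d, t, lam) for d, t, lam in poles)
    )


@dataclass(frozen=True)
class SampleGeometry:
    """Plate-electrode sample geometry: electrode gap ``length`` (m) and
    electrode contact ``area`` (m^2).

    The cell constant S/l converts bulk conductivity/permittivity to terminal
    conductance/susceptance.
    """

    length: float
    area: float

    def __post_init__(self):
        if not self.length > 0:
            raise DispersionError(f"length must be > 0, got {self.length}")
        if not self.area > 0:
            raise DispersionError(f"area must be > 0, got {self.area}")

    @classmethod
    def cylinder(cls, radius: float, height: float) -> "SampleGeometry":
        """Cylindrical sample contacted on its flat faces."""
        if not (radius > 0 and height > 0):
            raise DispersionError("cylinder radius and height must be > 0")
        return cls(length=height, area=math.pi * radius * radius)

    @property
    def cell_constant(self) -> float:
        """S/l in metres."""
        return self.area / self.length


#: The study sample: a cylinder 18.50 mm in diameter and 5 mm high.
STUDY_CYLINDER = SampleGeometry.cylinder(radius=9.25e-3, height=5e-3)
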