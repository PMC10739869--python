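"""Synthetic admittance spectra emulating a plate-electrode impedance sweep.

The measurement being emulated: a cylindrical tissue sample (18.50 mm
diameter, 5 mm high) between plate electrodes, swept from 40 Hz to 10 MHz at
20 points per decade, with ~10 replicate samples.  Synthetic spectra are
drawn from a known multipole Debye ground truth with independent
multiplicative lognormal noise on conductance and susceptance, so every
downstream stage (conversion, fitting, simulation) is testable against a
known answer.

``fixture_models()`` returns the published potato-tuber (Solanum tuberosum)
parameterisations with 2, 4 and 6 Debye poles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dispersion import DebyeMultipole, DebyePole, SampleGeometry, STUDY_CYLINDER
from .spectra import AdmittanceSpectrum


def default_frequency_grid(f_start: float = 40.0, f_stop: float = 1e7,
                           points_per_decade: int = 20) -> np.ndarray:
    """Log-spaced sweep grid: f_i = f_start * 10**(i/ppd) for f_i < f_stop,
    with f_stop appended as the final point.

    Defaults give the 40 Hz – 10 MHz, 20 points/decade sweep: 108 anchored
    points plus the 10 MHz endpoint, 109 in total.
    """
    n = int(np.floor(np.log10(f_stop / f_start) * points_per_decade)) + 1
    f = f_start * 10.0 ** (np.arange(n) / points_per_decade)
    f = f[f < f_stop * (1 - 1e-12)]
    return np.append(f, f_stop)


# ---------------------------------------------------------------------------
# Published multipole parameterisations of potato tissue (2, 4 and 6 poles).

_FIXTURES = {
    2: dict(sigma_s=2.508e-2, eps_inf=3.463e2,
            poles=[(1.104e6, 1.932e-3), (3.308e4, 4.181e-7)]),
    4: dict(sigma_s=2.159e-2, eps_inf=1.747e2,
            poles=[(2.251e6, 3.783e-3), (2.918e4, 2.309e-5),
                   (1.836e4, 1.005e-6), (1.053e4, 1.658e-7)]),
    6: dict(sigma_s=2.087e-2, eps_inf=1.621e2,
            poles=[(3.198e6, 5.067e-3), (3.321e4, 3.563e-4),
                   (1.968e4, 2.495e-5), (1.048e4, 3.775e-6),
                   (1.548e4, 6.013e-7), (7.628e3, 1.403e-7)]),
}


def fixture_models() -> dict[str, DebyeMultipole]:
    """Named published potato-dispersion models, keyed ``"n2"``, ``"n4"``, ``"n6"``."""
    out = {}
    for n, d in _FIXTURES.items():
        out[f"n{n}"] = DebyeMultipole(
            sigma_s=d["sigma_s"], eps_inf=d["eps_inf"],
            poles=tuple(DebyePole(de, tau) for de, tau in d["poles"]))
    return out


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic measurement.

    noise_cv is the coefficient of variation of the multiplicative lognormal
    noise applied independently to every G and B sample; 0.02 mimics the
    few-percent replicate spread of plate-electrode tissue measurements.
    """

    truth: DebyeMultipole
    freqs: np.ndarray = field(default_factory=default_frequency_grid)
    noise_cv: float = 0.02
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_spectrum(spec: SynthSpec,
                      geometry: SampleGeometry = STUDY_CYLINDER) -> AdmittanceSpectrum:
    """Draw a replicated noisy admittance spectrum from the ground truth.

    Each replicate's G and B are the truth values times independent
    lognormal factors with unit mean and coefficient of variation
    ``noise_cv``.  Reproducible for a fixed seed.
    """
    freqs = np.asarray(spec.freqs, float)
    Y = spec.truth.terminal_admittance(geometry, freqs)
    G0, B0 = Y.real, Y.imag
    if spec.noise_cv == 0.0:
        G = np.tile(G0, (spec.n_replicates, 1))
        B = np.tile(B0, (spec.n_replicates, 1))
    else:
        rng = np.random.default_rng(spec.seed)
        # lognormal with E[X]=1, CV=noise_cv
        s2 = np.log1p(spec.noise_cv ** 2)
        mu = -0.5 * s2
        shape = (spec.n_replicates, freqs.size)
        G = G0 * rng.lognormal(mu, np.sqrt(s2), size=shape)
        B = B0 * rng.lognormal(mu, np.sqrt(s2), size=shape)
    if spec.n_replicates == 1:
        G, B = G[0], B[0]
    return AdmittanceSpectrum(freqs, G, B, geometry=geometry)
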