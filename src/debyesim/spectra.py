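"""Admittance spectra: containers, terminal <-> bulk conversion, CSV I/O.

An impedance analyser sweeping a plate-electrode sample records the terminal
admittance Y(f) = G(f) + jB(f).  With the sample's cell constant S/l these
convert to the bulk quantities a dispersion model predicts:

    eps_r(w) = B(w) / (w eps0) * l/S        (susceptance -> permittivity)
    sigma(w) = G(w) * l/S                   (conductance -> conductivity)

Files are plain CSV with a header; a ``column_map`` names the frequency
column and either (G, B), (Re Y, Im Y) or (|Z|, phase) columns, so deposits
with arbitrary headers load without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dispersion import EPS0, DebyeMultipole, SampleGeometry


class SpectrumError(ValueError):
    pass


def _as_ascending(freqs, *arrays):
    freqs = np.asarray(freqs, dtype=float)
    order = np.argsort(freqs, kind="stable")
    freqs = freqs[order]
    if np.any(np.diff(freqs) <= 0):
        dup = freqs[np.where(np.diff(freqs) <= 0)[0][0]]
        raise SpectrumError(f"duplicate frequency {dup!r} in spectrum")
    return (freqs,) + tuple(np.asarray(a, dtype=float)[..., order] for a in arrays)


@dataclass(frozen=True)
class AdmittanceSpectrum:
    """Terminal admittance vs frequency, optionally with replicates.

    ``conductance`` and ``susceptance`` have shape (n_freqs,) or
    (n_replicates, n_freqs).  Frequencies are stored strictly ascending.
    """

    freqs: np.ndarray
    conductance: np.ndarray
    susceptance: np.ndarray
    geometry: SampleGeometry | None = None

    def __post_init__(self):
        freqs, G, B = _as_ascending(self.freqs, self.conductance, self.susceptance)
        if G.shape != B.shape or G.shape[-1] != freqs.shape[0]:
            raise SpectrumError("conductance/susceptance shapes do not match freqs")
        if np.any(G <= 0):
            raise SpectrumError("conductance must be positive (passive sample)")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "conductance", G)
        object.__setattr__(self, "susceptance", B)

    @property
    def n_replicates(self) -> int:
        return 1 if self.conductance.ndim == 1 else self.conductance.shape[0]

    @property
    def admittance(self) -> np.ndarray:
        return self.conductance + 1j * self.susceptance

    def mean(self) -> "AdmittanceSpectrum":
        """Average replicates per frequency (identity for single-replicate)."""
        if self.conductance.ndim == 1:
            return self
        return AdmittanceSpectrum(
            self.freqs,
            self.conductance.mean(axis=0),
            self.susceptance.mean(axis=0),
            geometry=self.geometry,
        )

    def to_dielectric(self, geometry: SampleGeometry | None = None) -> "DielectricSpectrum":
        """Convert terminal G, B to bulk sigma (S/m) and eps_r via l/S.

        Replicates are averaged first.  Raises if no geometry is available.
        """
        geometry = geometry or self.geometry
        if geometry is None:
            raise SpectrumError("geometry required to convert admittance to bulk properties")
        m = self.mean()
        l_over_s = geometry.length / geometry.area
        w = 2.0 * np.pi * m.freqs
        sigma = m.conductance * l_over_s
        eps_r = m.susceptance / (w * EPS0) * l_over_s
        return DielectricSpectrum(m.freqs, eps_r, sigma)

    @classmethod
    def from_model(cls, model: DebyeMultipole, geometry: SampleGeometry,
                   freqs) -> "AdmittanceSpectrum":
        """Noiseless spectrum predicted by a dispersion model."""
        Y = model.terminal_admittance(geometry, freqs)
        return cls(np.asarray(freqs, float), Y.real, Y.imag, geometry=geometry)


@dataclass(frozen=True)
class DielectricSpectrum:
    """Bulk relative permittivity and conductivity vs frequency."""

    freqs: np.ndarray
    eps_r: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        freqs, eps_r, sigma = _as_ascending(self.freqs, self.eps_r, self.sigma)
        if eps_r.shape != freqs.shape or sigma.shape != freqs.shape:
            raise SpectrumError("eps_r/sigma must be 1-D, same length as freqs")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "eps_r", eps_r)
        object.__setattr__(self, "sigma", sigma)

    def complex_eps(self) -> np.ndarray:
        """eps*_r = eps_r - j sigma/(w eps0)."""
        w = 2.0 * np.pi * self.freqs
        return self.eps_r - 1j * self.sigma / (w * EPS0)

    def to_admittance(self, geometry: SampleGeometry) -> AdmittanceSpectrum:
        """Inverse of :meth:`AdmittanceSpectrum.to_dielectric`."""
        w = 2.0 * np.pi * self.freqs
        s_over_l = geometry.area / geometry.length
        G = self.sigma * s_over_l
        B = self.eps_r * w * EPS0 * s_over_l
        return AdmittanceSpectrum(self.freqs, G, B, geometry=geometry)

    @classmethod
    def from_model(cls, model: DebyeMultipole, freqs) -> "DielectricSpectrum":
        sigma, eps_r = model.effective_properties(np.asarray(freqs, float))
        return cls(np.asarray(freqs, float), eps_r, sigma)


# ---------------------------------------------------------------------------
# CSV I/O

#: default column names written by :func:`write_spectrum`
_DEFAULT_COLUMNS = {"freq": "frequency_hz", "G": "conductance_s", "B": "susceptance_s"}


def read_spectrum(path, column_map: Mapping[str, str] | None = None,
                  geometry: SampleGeometry | None = None) -> AdmittanceSpectrum:
    """Read an admittance spectrum from CSV.

    ``column_map`` maps roles to header names.  Role ``"freq"`` is required;
    the admittance may be given as ``("G", "B")``, as ``("re_y", "im_y")``,
    or as impedance magnitude/phase ``("z_abs", "z_phase_deg")`` which is
    inverted to Y = 1/Z.  Rows are re-ordered to ascending frequency.
    Replicated files (several rows per frequency with a ``"replicate"``
    column) are stacked on a leading replicate axis.
    """
    cmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    if cmap["freq"] not in df.columns:
        raise SpectrumError(f"missing column {cmap['freq']!r} in {path}")

    numeric_roles = [r for r in ("freq", "G", "B", "re_y", "im_y", "z_abs", "z_phase_deg")
                     if cmap.get(r) in df.columns]
    for role in numeric_roles:
        vals = pd.to_numeric(df[cmap[role]], errors="coerce")
        if vals.isna().any():
            row = int(np.where(vals.isna())[0][0])
            raise SpectrumError(
                f"non-numeric cell in column {cmap[role]!r}, row {row} of {path}")
        df[cmap[role]] = vals

    def _col(role):
        name = cmap.get(role)
        return df[name].to_numpy(float) if name in df.columns else None

    freqs = df[cmap["freq"]].to_numpy(float)
    G, B = _col("G"), _col("B")
    if G is None or B is None:
        re_y, im_y = _col("re_y"), _col("im_y")
        if re_y is not None and im_y is not None:
            G, B = re_y, im_y
        else:
            z_abs, z_phase = _col("z_abs"), _col("z_phase_deg")
            if z_abs is None or z_phase is None:
                raise SpectrumError(
                    "column_map must name (G,B), (re_y,im_y) or (z_abs,z_phase_deg) columns"
                )
            phi = np.deg2rad(z_phase)
            # Y = 1/Z: |Y| = 1/|Z|, arg Y = -arg Z
            G = np.cos(phi) / z_abs
            B = -np.sin(phi) / z_abs

    rep_col = cmap.get("replicate", "replicate")
    if rep_col in df.columns:
        reps = df[rep_col].to_numpy()
        uniq = pd.unique(reps)
        f0 = None
        G2, B2 = [], []
        for r in uniq:
            m = reps == r
            fr, Gr, Br = _as_ascending(freqs[m], G[m], B[m])
            if f0 is None:
                f0 = fr
            elif not np.array_equal(f0, fr):
                raise SpectrumError("replicates have inconsistent frequency grids")
            G2.append(Gr)
            B2.append(Br)
        return AdmittanceSpectrum(f0, np.vstack(G2), np.vstack(B2), geometry=geometry)
    return AdmittanceSpectrum(freqs, G, B, geometry=geometry)


def write_spectrum(spec: AdmittanceSpectrum, path) -> None:
    """Write a spectrum as CSV (roles named as in ``_DEFAULT_COLUMNS``);
    replicated spectra gain a ``replicate`` column."""
    c = _DEFAULT_COLUMNS
    if spec.conductance.ndim == 1:
        df = pd.DataFrame({c["freq"]: spec.freqs,
                           c["G"]: spec.conductance,
                           c["B"]: spec.susceptance})
    else:
        frames = []
        for r in range(spec.n_replicates):
            frames.append(pd.DataFrame({
                "replicate": r,
                c["freq"]: spec.freqs,
                c["G"]: spec.conductance[r],
                c["B"]: spec.susceptance[r]}))
        df = pd.concat(frames, ignore_index=True)
    # default float formatting is shortest-round-trip: lossless write->read
    df.to_csv(path, index=False)


def read_geometry(path) -> SampleGeometry:
    """JSON sidecar: {"radius_m", "height_m"} or {"length_m", "area_m2"}."""
    d = json.loads(Path(path).read_text())
    if "radius_m" in d:
        return SampleGeometry.cylinder(d["radius_m"], d["height_m"])
    return SampleGeometry(length=d["length_m"], area=d["area_m2"])


def write_geometry(geometry: SampleGeometry, path) -> None:
    Path(path).write_text(json.dumps(
        {"length_m": geometry.length, "area_m2": geometry.area}, indent=2) + "\n")
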