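"""Terminal <-> bulk conversions and spectrum CSV round trips."""

import numpy as np
import pytest

import debyesim as ds
from debyesim import EPS0
from debyesim.spectra import read_spectrum, write_spectrum


@pytest.fixture
def n4_spectrum(n4_model, cylinder, sweep_grid):
    return ds.AdmittanceSpectrum.from_model(n4_model, cylinder, sweep_grid)


class TestConversions:
    def test_pure_conductance_maps_to_sigma(self, cylinder, sweep_grid):
        sigma_s = 0.04
        G = np.full(sweep_grid.size, sigma_s * cylinder.cell_constant)
        # susceptance must stay positive for a passive dielectric; use a tiny
        # value and check eps_r ~ 0
        B = 1e-30 * np.ones_like(G)
        spec = ds.AdmittanceSpectrum(sweep_grid, G, B, geometry=cylinder)
        diel = spec.to_dielectric()
        np.testing.assert_allclose(diel.sigma, sigma_s, rtol=1e-12)
        assert np.all(diel.eps_r < 1e-10)

    def test_round_trip_to_effective_properties(self, n4_model, cylinder,
                                                sweep_grid, n4_spectrum):
        diel = n4_spectrum.to_dielectric()
        sigma, eps_r = n4_model.effective_properties(sweep_grid)
        np.testing.assert_allclose(diel.sigma, sigma, rtol=1e-12)
        np.testing.assert_allclose(diel.eps_r, eps_r, rtol=1e-12)

    def test_single_point_hand_computation(self, cylinder):
        # G,B of a 1.468 mS admittance at 7.2 degrees, 1 kHz
        y, phi = 1.468e-3, np.deg2rad(7.2)
        spec = ds.AdmittanceSpectrum(np.array([1e3]),
                                     np.array([y * np.cos(phi)]),
                                     np.array([y * np.sin(phi)]),
                                     geometry=cylinder)
        diel = spec.to_dielectric()
        assert diel.sigma[0] == pytest.approx(2.71e-2, rel=2e-3)

    def test_complex_eps_direct_substitution(self):
        f = 1.0 / (2 * np.pi * EPS0) * 1e-6   # makes w*eps0 = 1e-6
        diel = ds.DielectricSpectrum(np.array([f]), np.array([100.0]),
                                     np.array([0.01]))
        e = diel.complex_eps()[0]
        assert e == pytest.approx(100.0 - 1e4 * 1j)

    def test_admittance_round_trip_identity(self, cylinder, n4_spectrum):
        back = n4_spectrum.to_dielectric().to_admittance(cylinder)
        np.testing.assert_allclose(back.conductance, n4_spectrum.conductance,
                                   rtol=1e-12)
        np.testing.assert_allclose(back.susceptance, n4_spectrum.susceptance,
                                   rtol=1e-12)

    def test_complex_eps_matches_model(self, n4_model, sweep_grid, n4_spectrum):
        diel = n4_spectrum.to_dielectric()
        np.testing.assert_allclose(diel.complex_eps(),
                                   n4_model.complex_permittivity(sweep_grid),
                                   rtol=1e-12)

    def test_missing_geometry_raises(self, n4_spectrum):
        bare = ds.AdmittanceSpectrum(n4_spectrum.freqs, n4_spectrum.conductance,
                                     n4_spectrum.susceptance)
        with pytest.raises(ds.SpectrumError):
            bare.to_dielectric()

    def test_conversion_is_frequency_local(self, cylinder, n4_spectrum):
        # dropping rows does not change the values at the remaining rows
        keep = slice(None, None, 3)
        sub = ds.AdmittanceSpectrum(n4_spectrum.freqs[keep],
                                    n4_spectrum.conductance[keep],
                                    n4_spectrum.susceptance[keep],
                                    geometry=cylinder)
        full = n4_spectrum.to_dielectric()
        np.testing.assert_allclose(sub.to_dielectric().sigma,
                                   full.sigma[keep], rtol=1e-14)


class TestCsvIO:
    def test_write_read_round_trip(self, n4_spectrum, tmp_path):
        path = tmp_path / "spec.csv"
        write_spectrum(n4_spectrum, path)
        back = read_spectrum(path)
        np.testing.assert_allclose(back.freqs, n4_spectrum.freqs, rtol=1e-15)
        np.testing.assert_allclose(back.conductance, n4_spectrum.conductance,
                                   rtol=1e-15)
        np.testing.assert_allclose(back.susceptance, n4_spectrum.susceptance,
                                   rtol=1e-15)

    def test_replicated_round_trip(self, n4_model, cylinder, tmp_path):
        spec = ds.generate_spectrum(
            ds.SynthSpec(truth=n4_model, n_replicates=3, seed=1), cylinder)
        path = tmp_path / "rep.csv"
        write_spectrum(spec, path)
        back = read_spectrum(path)
        assert back.n_replicates == 3
        np.testing.assert_allclose(back.conductance, spec.conductance, rtol=1e-15)

    def test_impedance_magnitude_phase_input(self, tmp_path):
        # |Z| = 1000 ohm at impedance phase -30 deg -> Y = (1/1000) e^{+j30}
        path = tmp_path / "z.csv"
        path.write_text("f,zabs,zphi\n1000,1000,-30\n2000,500,-45\n")
        spec = read_spectrum(path, column_map={"freq": "f", "z_abs": "zabs",
                                               "z_phase_deg": "zphi"})
        y = spec.admittance
        np.testing.assert_allclose(y[0], (1 / 1000) * np.exp(1j * np.pi / 6),
                                   rtol=1e-12)
        np.testing.assert_allclose(y[1], (1 / 500) * np.exp(1j * np.pi / 4),
                                   rtol=1e-12)

    def test_descending_frequencies_reordered(self, tmp_path):
        path = tmp_path / "desc.csv"
        path.write_text("frequency_hz,conductance_s,susceptance_s\n"
                        "100,3.0,0.3\n10,1.0,0.1\n1000,5.0,0.5\n")
        spec = read_spectrum(path)
        np.testing.assert_array_equal(spec.freqs, [10, 100, 1000])
        np.testing.assert_array_equal(spec.conductance, [1.0, 3.0, 5.0])

    def test_parse_errors_name_the_problem(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("frequency_hz,conductance_s,susceptance_s\n10,oops,0.1\n")
        with pytest.raises(ds.SpectrumError, match="row 0"):
            read_spectrum(bad)
        dup = tmp_path / "dup.csv"
        dup.write_text("frequency_hz,conductance_s,susceptance_s\n"
                       "10,1,0.1\n10,2,0.2\n")
        with pytest.raises(ds.SpectrumError, match="duplicate"):
            read_spectrum(dup)
        missing = tmp_path / "missing.csv"
        missing.write_text("a,b\n1,2\n")
        with pytest.raises(ds.SpectrumError, match="missing column"):
            read_spectrum(missing)

    def test_geometry_sidecar_round_trip(self, cylinder, tmp_path):
        path = tmp_path / "geom.json"
        ds.write_geometry(cylinder, path)
        back = ds.read_geometry(path)
        assert back.length == pytest.approx(cylinder.length)
        assert back.area == pytest.approx(cylinder.area)
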