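"""Genetic-algorithm fit of a multipole Debye dispersion to a measured spectrum.

Dispersion parameters span many decades (tau from picoseconds to
milliseconds, delta_eps from units to millions), so both the genome and the
cost live in log10 space.  The genome of an N-pole model is

    g = [log10 sigma_s, log10 eps_inf, log10 d_eps_1, log10 tau_1, ...]

and the cost compares model and data complex permittivity point-wise on the
measured grid:

    CF = sum_f (log10 E_r - log10 D_r)^2 + (log10 |E_i| - log10 |D_i|)^2

where E is the (replicate-averaged) measured complex relative permittivity
and D the model's.  Imaginary parts are negative for a passive medium, so
their magnitudes are compared.

The optimiser is a generational GA with tournament selection, uniform
crossover, per-gene mutation, and one-individual elitism, which makes the
best-cost history monotone.  Two details matter for convergence on
multi-pole problems.  First, genomes are kept in canonical pole order (tau
descending): pole labelling is a gauge freedom, and without canonicalisation
uniform crossover between differently-ordered parents scrambles otherwise
good solutions.  Second, mutation mixes global redraws (uniform inside the
bounds) with local Gaussian creep whose width anneals over the run; redraws
alone locate the right basin but cannot refine within it.  The default
settings (population 1000, tournament 20, 10% mutation, up to 2000
generations) are sized for a 4-to-6-pole fit of a 109-point spectrum.

The user-facing surface follows the statsmodels model/results idiom:
``MultipoleDebyeFit(data, n_poles).fit(seed)`` returns a
:class:`DebyeFitResults` carrying the fitted :class:`DebyeMultipole`, the
attained cost and its per-generation history, plus ``summary()`` and
``plot_fit()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dispersion import EPS0, DebyeMultipole, DebyePole
from .spectra import AdmittanceSpectrum, DielectricSpectrum, SampleGeometry


class FitError(ValueError):
    pass


# log10 bounds per parameter kind
LOG_BOUNDS = {
    "sigma_s": (-4.0, 0.0),
    "eps_inf": (0.0, 8.0),
    "delta_eps": (-3.0, 8.0),
    "tau": (-12.0, 1.0),
}


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    The stagnation stop (no improvement beyond 1e-12 for
    ``stagnation_window`` generations) bounds runtime without affecting the
    monotone history guarantee.
    """

    population_size: int = 1000
    tournament_size: int = 20
    mutation_prob: float = 0.10
    max_generations: int = 2000
    crossover_prob: float = 0.9
    elitism: int = 1
    stagnation_window: int = 200
    #: fraction of mutations that are local Gaussian creep (rest: uniform redraw)
    creep_fraction: float = 0.5
    #: creep standard deviation in decades, annealed geometrically hi -> lo
    creep_sigma_hi: float = 0.3
    creep_sigma_lo: float = 0.05
    bounds: dict = field(default_factory=lambda: dict(LOG_BOUNDS))

    def __post_init__(self):
        if not (0 < self.tournament_size <= self.population_size):
            raise FitError("require 0 < tournament_size <= population_size")
        for p in (self.mutation_prob, self.crossover_prob, self.creep_fraction):
            if not (0.0 <= p <= 1.0):
                raise FitError("probabilities must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise FitError("elitism must be in [0, population_size)")
        for k in LOG_BOUNDS:
            lo, hi = self.bounds[k]
            if not lo < hi:
                raise FitError(f"empty bound interval for {k}")


def genome_bounds(n_poles: int, bounds: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper log10 bound vectors for an n-pole genome."""
    b = bounds or LOG_BOUNDS
    lo = [b["sigma_s"][0], b["eps_inf"][0]]
    hi = [b["sigma_s"][1], b["eps_inf"][1]]
    for _ in range(n_poles):
        lo += [b["delta_eps"][0], b["tau"][0]]
        hi += [b["delta_eps"][1], b["tau"][1]]
    return np.asarray(lo), np.asarray(hi)


def genome_to_model(g: np.ndarray) -> DebyeMultipole:
    g = np.asarray(g, float)
    n = (g.size - 2) // 2
    poles = tuple(DebyePole(10.0 ** g[2 + 2 * k], 10.0 ** g[3 + 2 * k])
                  for k in range(n))
    return DebyeMultipole(sigma_s=10.0 ** g[0], eps_inf=10.0 ** g[1], poles=poles)


def canonicalise_genomes(P: np.ndarray) -> np.ndarray:
    """Sort each genome's (delta_eps, tau) blocks by tau descending.

    Removes the pole-permutation gauge freedom so that crossover mixes
    like-for-like genes between parents.
    """
    n = (P.shape[1] - 2) // 2
    if n < 2:
        return P
    blocks = P[:, 2:].reshape(P.shape[0], n, 2)
    order = np.argsort(-blocks[:, :, 1], axis=1, kind="stable")
    blocks = np.take_along_axis(blocks, order[:, :, None], axis=1)
    return np.concatenate([P[:, :2], blocks.reshape(P.shape[0], 2 * n)], axis=1)


def model_to_genome(model: DebyeMultipole) -> np.ndarray:
    g = [np.log10(model.sigma_s), np.log10(model.eps_inf)]
    for p in model.poles:
        g += [np.log10(p.delta_eps), np.log10(p.tau)]
    return np.asarray(g)


# ---------------------------------------------------------------------------
# Cost function


def _prepare_data(data) -> tuple[np.ndarray, np.ndarray]:
    """Coerce input to (freqs, complex eps*_r) with replicates averaged."""
    if isinstance(data, AdmittanceSpectrum):
        data = data.to_dielectric()
    if isinstance(data, DielectricSpectrum):
        return data.freqs, data.complex_eps()
    freqs, eps = data
    return np.asarray(freqs, float), np.asarray(eps, complex)


def cost_function(model: DebyeMultipole, data) -> float:
    """Log-space squared misfit of a model against a complex-eps spectrum."""
    freqs, eps = _prepare_data(data)
    if np.any(eps.real <= 0):
        raise FitError("data has non-positive real permittivity; cannot fit in log space")
    d = np.asarray(model.complex_permittivity(freqs))
    cf = np.sum((np.log10(eps.real) - np.log10(d.real)) ** 2
                + (np.log10(np.abs(eps.imag)) - np.log10(np.abs(d.imag))) ** 2)
    return float(cf)


def _population_cost(P: np.ndarray, freqs: np.ndarray,
                     log_er: np.ndarray, log_ei: np.ndarray) -> np.ndarray:
    """Vectorised CF for a (pop, genes) log10-genome matrix."""
    w = 2.0 * np.pi * freqs[None, :]
    sigma = 10.0 ** P[:, 0:1]
    eps_inf = 10.0 ** P[:, 1:2]
    n = (P.shape[1] - 2) // 2
    d = np.broadcast_to(eps_inf + 0j, (P.shape[0], freqs.size)).copy()
    for k in range(n):
        de = 10.0 ** P[:, 2 + 2 * k: 3 + 2 * k]
        tau = 10.0 ** P[:, 3 + 2 * k: 4 + 2 * k]
        d += de / (1.0 + 1j * w * tau)
    # conduction term only affects the imaginary part
    d_im = d.imag - sigma / (w * EPS0)
    return np.sum((np.log10(d.real) - log_er[None, :]) ** 2
                  + (np.log10(np.abs(d_im)) - log_ei[None, :]) ** 2, axis=1)


# ---------------------------------------------------------------------------
# Results object


@dataclass(frozen=True)
class DebyeFitResults:
    """Outcome of one GA run: fitted model, attained cost, history."""

    params: DebyeMultipole
    cf: float
    history: np.ndarray
    evaluations: int
    seed: int
    n_poles: int
    config: GAConfig
    data_freqs: np.ndarray
    data_eps: np.ndarray

    @property
    def model(self) -> DebyeMultipole:  # alias used by downstream solvers
        return self.params

    def predict(self, freqs) -> np.ndarray:
        """Model complex permittivity on an arbitrary frequency grid."""
        return np.asarray(self.params.complex_permittivity(freqs))

    def summary(self) -> str:
        m = self.params
        lines = [
            f"Multipole Debye dispersion fit ({self.n_poles} poles)",
            "=" * 52,
            f"cost function (CF)   {self.cf:.4e}",
            f"generations run      {len(self.history)}",
            f"cost evaluations     {self.evaluations}",
            f"seed                 {self.seed}",
            "-" * 52,
            f"sigma_s   {m.sigma_s:.4e} S/m",
            f"eps_inf   {m.eps_inf:.4e}",
        ]
        for i, p in enumerate(m.poles, 1):
            lines.append(f"pole {i}:   delta_eps = {p.delta_eps:.4e}   tau = {p.tau:.4e} s")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Measured vs fitted conductivity and permittivity spectra."""
        import matplotlib.pyplot as plt

        freqs = self.data_freqs
        w = 2.0 * np.pi * freqs
        d = self.predict(freqs)
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
        ax[0].loglog(freqs, self.data_eps.real, ".", label="data")
        ax[0].loglog(freqs, d.real, "-", label="fit")
        ax[0].set(xlabel="frequency (Hz)", ylabel=r"$\varepsilon_r$")
        ax[1].loglog(freqs, -w * EPS0 * self.data_eps.imag, ".", label="data")
        ax[1].loglog(freqs, -w * EPS0 * d.imag, "-", label="fit")
        ax[1].set(xlabel="frequency (Hz)", ylabel=r"$\sigma$ (S/m)")
        ax[0].legend()
        return ax


# ---------------------------------------------------------------------------
# Model object


class MultipoleDebyeFit:
    """GA fit of an N-pole Debye dispersion to a complex-permittivity spectrum.

    Parameters
    ----------
    data : DielectricSpectrum, AdmittanceSpectrum or (freqs, complex_eps)
        The measured spectrum.  Admittance input requires an attached
        geometry; replicates are averaged.
    n_poles : int
        Number of Debye poles N to fit.
    config : GAConfig, optional
        GA settings; defaults follow the standard configuration.
    """

    def __init__(self, data, n_poles: int, config: GAConfig | None = None):
        self.freqs, self.eps = _prepare_data(data)
        if np.any(self.eps.real <= 0):
            raise FitError("data has non-positive real permittivity")
        self.n_poles = int(n_poles)
        if self.n_poles < 0:
            raise FitError("n_poles must be >= 0")
        if self.freqs.size < 2 * (self.n_poles + 1):
            raise FitError(
                f"need >= {2 * (self.n_poles + 1)} frequency points for "
                f"{self.n_poles} poles, got {self.freqs.size}")
        self.config = config or GAConfig()

    @classmethod
    def from_admittance(cls, spectrum: AdmittanceSpectrum, geometry: SampleGeometry,
                        n_poles: int, config: GAConfig | None = None):
        return cls(spectrum.to_dielectric(geometry), n_poles, config)

    @classmethod
    def from_dataframe(cls, df, n_poles: int, config: GAConfig | None = None,
                       freq_col: str = "frequency_hz",
                       eps_col: str = "eps_r", sigma_col: str = "sigma_sm"):
        spec = DielectricSpectrum(df[freq_col].to_numpy(float),
                                  df[eps_col].to_numpy(float),
                                  df[sigma_col].to_numpy(float))
        return cls(spec, n_poles, config)

    def fit(self, seed: int = 0,
            initial_models: list[DebyeMultipole] | None = None) -> DebyeFitResults:
        """Run the GA; bit-identical results for identical seed and data.

        ``initial_models`` are injected into the initial population (useful
        for warm starts); elitism then guarantees their cost is never lost.
        """
        cfg = self.config
        rng = np.random.default_rng(seed)
        lo, hi = genome_bounds(self.n_poles, cfg.bounds)
        ng = lo.size
        pop = cfg.population_size
        log_er = np.log10(self.eps.real)
        log_ei = np.log10(np.abs(self.eps.imag))

        P = rng.uniform(lo, hi, size=(pop, ng))
        if initial_models:
            for i, m in enumerate(initial_models[:pop]):
                P[i] = np.clip(model_to_genome(m), lo, hi)
        P = canonicalise_genomes(P)
        cf = _population_cost(P, self.freqs, log_er, log_ei)
        evaluations = pop
        best_idx = int(np.argmin(cf))
        best_g, best_cf = P[best_idx].copy(), float(cf[best_idx])
        history = [best_cf]
        since_improve = 0

        n_off = pop - cfg.elitism
        for _gen in range(cfg.max_generations):
            # tournament selection (lowest CF wins; earliest index on ties)
            cand = rng.integers(0, pop, size=(2 * n_off, cfg.tournament_size))
            cand.sort(axis=1)
            winners = cand[np.arange(2 * n_off), np.argmin(cf[cand], axis=1)]
            pa, pb = P[winners[:n_off]], P[winners[n_off:]]
            # uniform crossover per couple
            do_x = rng.random(n_off) < cfg.crossover_prob
            take_b = (rng.random((n_off, ng)) < 0.5) & do_x[:, None]
            child = np.where(take_b, pb, pa)
            # per-gene mutation: global uniform redraw or annealed local creep
            sigma = cfg.creep_sigma_hi * (
                cfg.creep_sigma_lo / cfg.creep_sigma_hi
            ) ** (_gen / max(cfg.max_generations, 1))
            mut = rng.random((n_off, ng)) < cfg.mutation_prob
            use_creep = rng.random((n_off, ng)) < cfg.creep_fraction
            draws = rng.uniform(lo, hi, size=(n_off, ng))
            crept = child + rng.normal(0.0, sigma, size=(n_off, ng))
            child = np.where(mut, np.where(use_creep, crept, draws), child)
            np.clip(child, lo, hi, out=child)
            child = canonicalise_genomes(child)

            child_cf = _population_cost(child, self.freqs, log_er, log_ei)
            evaluations += n_off
            if cfg.elitism:
                elite_order = np.argsort(cf, kind="stable")[: cfg.elitism]
                P = np.vstack([P[elite_order], child])
                cf = np.concatenate([cf[elite_order], child_cf])
            else:
                P, cf = child, child_cf

            i = int(np.argmin(cf))
            if cf[i] < best_cf - 1e-12:
                best_cf, best_g = float(cf[i]), P[i].copy()
                since_improve = 0
            else:
                since_improve += 1
                if cf[i] < best_cf:
                    best_cf, best_g = float(cf[i]), P[i].copy()
            history.append(best_cf)
            if since_improve >= cfg.stagnation_window:
                break

        model = genome_to_model(best_g)
        return DebyeFitResults(
            params=model,
            cf=cost_function(model, (self.freqs, self.eps)),
            history=np.asarray(history),
            evaluations=evaluations,
            seed=seed,
            n_poles=self.n_poles,
            config=cfg,
            data_freqs=self.freqs,
            data_eps=self.eps,
        )


# ---------------------------------------------------------------------------
# Functional wrappers


def fit(data, n_poles: int, config: GAConfig | None = None,
        seed: int = 0) -> DebyeFitResults:
    """One GA fit (functional form of ``MultipoleDebyeFit(...).fit(seed)``)."""
    return MultipoleDebyeFit(data, n_poles, config).fit(seed=seed)


def multi_start_fit(data, n_poles_list, config: GAConfig | None = None,
                    seed: int = 0) -> dict[int, DebyeFitResults]:
    """Fit each requested pole count; returns ``{N: DebyeFitResults}``.

    Supports model selection: pick the smallest N whose CF meets a user
    tolerance (fit quality plateaus once N reaches the number of resolvable
    relaxation processes in the band).
    """
    out: dict[int, DebyeFitResults] = {}
    for i, n in enumerate(n_poles_list):
        out[int(n)] = MultipoleDebyeFit(data, int(n), config).fit(seed=seed + i)
    return out


def best_of_seeds(data, n_poles: int, config: GAConfig | None = None,
                  seeds=(0, 1, 2)) -> DebyeFitResults:
    """Run the GA once per seed and keep the lowest-cost result."""
    results = [MultipoleDebyeFit(data, n_poles, config).fit(seed=s) for s in seeds]
    return min(results, key=lambda r: r.cf)
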