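"""Synthetic study generator.

Emulates the data-generating process the model assumes: stage-structured
Poisson/Binomial latent dynamics across four wintering subpopulation groups
with pairwise adult (and focal-juvenile) movement, lognormal count
observation, Poisson juvenile-count observation, and multistate detection of
marked individuals.  Default magnitudes follow the study system: 39 winters,
fecundity ≈ 0.1–0.15, adult survival ≈ 0.8–0.9, resighting ≈ 0.9 at focal
groups and ≈ 0.3 Elsewhere, movement means below the 0.2 prior cap, and a
few tens of new marks per focal group-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CovariateSet, standardize
from .model import (
    E_INDEX, N_FOCAL, N_GROUPS,
    DemographicRates, HyperParams, LatentState, MArray, ObservedData,
    adult_flows, build_rates, juvenile_flows,
)

__all__ = [
    "SimulationConfig", "SimTruth", "History",
    "default_hyper", "default_config", "gen_covariates",
    "draw_rates", "simulate_states", "simulate_observations",
    "simulate_histories", "marray_from_histories", "simulate",
]


@dataclass
class History:
    """One marked individual: release and all subsequent resightings."""

    mark_year: int              # 0-based occasion of marking
    mark_group: int
    mark_age: str               # 'juv' | 'adult'
    resightings: list = field(default_factory=list)  # [(year, group), ...]


@dataclass
class SimulationConfig:
    n_groups: int = N_GROUPS
    n_years: int = 39
    hyper: HyperParams = None
    init_A: np.ndarray = None
    #: new marks per (age 0=juv/1=adult, group, release occasion 0..T-2)
    releases: np.ndarray = None
    seed: int = 0
    process_noise: bool = True
    first_year: int = 1983

    def __post_init__(self):
        if self.hyper is None:
            self.hyper = default_hyper(self.n_years)
        if self.init_A is None:
            self.init_A = np.array([3000, 2200, 140, 3600])
        self.init_A = np.asarray(self.init_A, dtype=np.int64)
        if self.releases is None:
            rel = np.zeros((2, self.n_groups, self.n_years - 1), dtype=np.int64)
            rel[0, :N_FOCAL, :] = 30     # juveniles, focal groups only
            rel[1, :N_FOCAL, :] = 30
            self.releases = rel
        self.releases = np.asarray(self.releases, dtype=np.int64)
        if np.any(self.releases < 0):
            raise ValueError("releases must be nonnegative")
        if np.any(self.releases[0, N_FOCAL:, :] > 0):
            raise ValueError("juvenile releases allowed only in focal groups")


@dataclass
class SimTruth:
    """Ground truth of one synthetic study."""

    config: SimulationConfig
    covs: CovariateSet
    rates: DemographicRates
    latent: LatentState
    histories: list
    flags: np.ndarray   # True where Ntot = 0 forced the y = 0 sentinel


def default_hyper(n_years: int = 39) -> HyperParams:
    """True hyperparameters of the default synthetic scenario.

    Intercepts sit at the point estimates typical of the study system;
    covariate and hunting effects are modest; year-effect scales give
    realistic annual spread without destabilizing the metapopulation.
    """
    T, Ti = n_years, n_years - 1
    h = HyperParams.constant(n_years)
    h.alpha_gamma = np.array([0.11, 0.15, 0.10, 0.14])
    h.beta_fec = np.array([
        [0.16, -0.10, 0.02, -0.05],
        [0.05, -0.19, 0.02, -0.05],
        [-0.26, -0.27, 0.02, -0.10],
        [0.05, -0.21, 0.02, -0.15],
    ])
    h.sigma_gamma = 0.30
    h.alpha_phiJ = np.array([0.74, 0.84, 0.76])
    h.beta_storm_J = np.array([-0.14, -0.05, 0.05])
    h.hunt_J = np.array([[0.0, 0.16], [0.0, -0.38], [0.0, 0.0]])
    h.sigma_phiJ = 0.20
    h.alpha_phiA = np.array([0.79, 0.86, 0.86, 0.89])
    h.beta_storm_A = np.array([0.07, -0.05, 0.12, 0.0])
    h.hunt_A = np.array([[0.43, 0.10], [0.0, -0.29], [0.0, -0.34], [0.27, -0.60]])
    h.sigma_phiA = 0.15
    h.mu_beta_J = h.mu_beta_A = 0.0
    h.lam_beta_J = h.lam_beta_A = 2.0
    h.mu_hunt_J = np.zeros(2)
    h.lam_hunt_J = np.full(2, 2.0)
    h.mu_hunt_A = np.zeros(2)
    h.lam_hunt_A = np.full(2, 2.0)
    # movement means: most flows are rare; Elsewhere→Wexford is the largest
    aJ = {f: 0.02 for f in juvenile_flows()}
    aJ[(1, 0)] = 0.03
    h.alpha_psiJ = np.array([aJ[f] for f in juvenile_flows()])
    aA = {f: 0.01 for f in adult_flows()}
    aA.update({(3, 0): 0.04, (3, 1): 0.02, (1, 0): 0.02, (0, 3): 0.015,
               (1, 3): 0.015, (2, 0): 0.02})
    h.alpha_psiA = np.array([aA[f] for f in adult_flows()])
    h.sigma_psi = 0.30
    h.alpha_p = np.array([0.90, 0.89, 0.92, 0.28])
    h.sigma_p = 0.30
    h.eps_gamma = np.zeros((N_GROUPS, T))
    h.eps_phiJ = np.zeros((N_FOCAL, Ti))
    h.eps_phiA = np.zeros((N_GROUPS, Ti))
    h.eps_psiJ = np.zeros((9, Ti))
    h.eps_psiA = np.zeros((12, Ti))
    h.eps_p = np.zeros((N_GROUPS, T))
    h.tau_y = 0.002
    return h


def default_config(seed: int = 0, n_years: int = 39) -> SimulationConfig:
    return SimulationConfig(n_years=n_years, seed=seed)


def gen_covariates(n_groups: int, n_years: int, rng: np.random.Generator,
                   first_year: int = 1983) -> CovariateSet:
    """Standardized environmental covariates for a synthetic study.

    GDD and snowfall series are smooth-ish annual anomalies; storm counts
    are Poisson before standardization.  Each series is standardized per
    group across years, as the real covariates are before entering the
    linear predictors.
    """
    def std_rows(x):
        return np.vstack([standardize(row) for row in x])

    shape = (n_groups, n_years)
    gddw = std_rows(rng.normal(size=shape))
    gdds = std_rows(rng.normal(size=shape))
    gddb = std_rows(rng.normal(size=shape))
    snow = std_rows(rng.gamma(3.0, 1.0, size=shape))
    storms = std_rows(rng.poisson(2.0, size=shape).astype(float))
    years = np.arange(first_year, first_year + n_years)
    return CovariateSet(gddw, gdds, gddb, snow, storms, years=years)


def draw_rates(hyper: HyperParams, covs: CovariateSet,
               seed: int | np.random.Generator = 0) -> DemographicRates:
    """Draw a realized rate trajectory: year effects from their Normal laws,
    then the link functions.  Redraws movement year effects for any interval
    whose total outflow would reach 1 (rejected region of the model)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h = hyper.copy()
    T = h.n_years
    Ti = T - 1
    h.eps_gamma = rng.normal(0, h.sigma_gamma, size=(N_GROUPS, T))
    h.eps_phiJ = rng.normal(0, h.sigma_phiJ, size=(N_FOCAL, Ti))
    h.eps_phiA = rng.normal(0, h.sigma_phiA, size=(N_GROUPS, Ti))
    h.eps_p = rng.normal(0, h.sigma_p, size=(N_GROUPS, T))
    for _ in range(1000):
        h.eps_psiJ = rng.normal(0, h.sigma_psi, size=(9, Ti))
        h.eps_psiA = rng.normal(0, h.sigma_psi, size=(12, Ti))
        try:
            return build_rates(h, covs)
        except ValueError:
            continue
    raise RuntimeError("could not draw movement rates with outflow < 1")


def simulate_states(rates: DemographicRates, init_A, seed=0, *,
                    process_noise: bool = True) -> LatentState:
    """Forward-simulate the latent stage abundances.

    With ``process_noise=False`` every draw is replaced by its (rounded)
    expectation, giving the deterministic projection limit.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    init_A = np.asarray(init_A, dtype=np.int64)
    if np.any(init_A < 0):
        raise ValueError("init_A must be nonnegative")
    G, T = rates.gamma.shape
    J = np.zeros((G, T), dtype=np.int64)
    N1 = np.zeros((G, T), dtype=np.int64)
    Nad = np.zeros((G, T), dtype=np.int64)
    I = np.zeros((G, T), dtype=np.int64)
    A = np.zeros((G, T), dtype=np.int64)
    A[:, 0] = init_A

    def pois(lam):
        return rng.poisson(lam) if process_noise else np.round(lam).astype(np.int64)

    def binom(n, q):
        return rng.binomial(n, q) if process_noise \
            else np.round(n * q).astype(np.int64)

    J[:, 0] = pois(A[:, 0] * rates.gamma[:, 0])
    fidJ, fidA = rates.fidelityJ, rates.fidelityA
    for t in range(1, T):
        N1[:, t] = binom(J[:, t - 1], rates.phiJ[:, t - 1] * fidJ[:, t - 1])
        Nad[:, t] = binom(A[:, t - 1], rates.phiA[:, t - 1] * fidA[:, t - 1])
        inflow = ((rates.phiJ[:, t - 1] * J[:, t - 1]) @ rates.psiJ[:, :, t - 1]
                  + (rates.phiA[:, t - 1] * A[:, t - 1]) @ rates.psiA[:, :, t - 1])
        I[:, t] = pois(inflow)
        A[:, t] = N1[:, t] + Nad[:, t] + I[:, t]
        J[:, t] = pois(A[:, t] * rates.gamma[:, t])
    return LatentState(J=J, N1=N1, Nad=Nad, I=I, A1=init_A)


def simulate_observations(latent: LatentState, tau_y: float, seed=0):
    """Observe the latent states: lognormal counts and Poisson juvenile counts.

    Returns (y, Jobs, flags); cells with Ntot = 0 get the y = 0 sentinel and
    are flagged (a lognormal observation is undefined there).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    Ntot = latent.Ntot
    flags = Ntot == 0
    y = np.zeros(Ntot.shape)
    ok = ~flags
    y[ok] = np.round(np.exp(rng.normal(np.log(Ntot[ok]), np.sqrt(tau_y))))
    y[ok] = np.maximum(y[ok], 1)
    Jobs = rng.poisson(latent.J).astype(float)
    return y, Jobs, flags


def simulate_histories(rates: DemographicRates, releases, seed=0) -> list:
    """Individual-based multistate capture-resighting simulation.

    Each newly marked individual survives and moves with its age-specific
    rates (juvenile rates only for the first interval after a juvenile
    release) and is resighted at its current group with that group-year's
    detection probability.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    releases = np.asarray(releases, dtype=np.int64)
    G, T = rates.gamma.shape
    if releases.shape != (2, G, T - 1):
        raise ValueError(f"releases must have shape (2, {G}, {T - 1})")
    if np.any(releases[0, N_FOCAL:, :] > 0):
        raise ValueError("juvenile releases allowed only in focal groups")
    histories = []
    fidJ, fidA = rates.fidelityJ, rates.fidelityA
    for a, age in enumerate(("juv", "adult")):
        for g in range(G):
            for y in range(T - 1):
                for _ in range(releases[a, g, y]):
                    hist = History(y, g, age)
                    s = g
                    for t in range(y, T - 1):
                        juv = (age == "juv" and t == y)
                        phi = rates.phiJ[s, t] if juv else rates.phiA[s, t]
                        if rng.random() >= phi:
                            break
                        psi = rates.psiJ[s, :, t] if juv else rates.psiA[s, :, t]
                        fid = fidJ[s, t] if juv else fidA[s, t]
                        u = rng.random()
                        if u >= fid:
                            # moved: pick destination by cumulative ψ
                            c = fid
                            for j in range(G):
                                c += psi[j]
                                if u < c:
                                    s = j
                                    break
                        if rng.random() < rates.p[s, t + 1]:
                            hist.resightings.append((t + 1, s))
                    histories.append(hist)
    return histories


def marray_from_histories(histories, n_years: int) -> MArray:
    """Summarize individual histories into the multistate m-array.

    Each individual contributes one release row per capture/resighting
    event: first resightings are tallied by (group, occasion), and every
    resighting re-enters the individual as an adult release at that group
    and occasion (the standard decomposition that makes the rows independent
    multinomials).
    """
    m = MArray.empty(n_years)
    counts = m.counts
    for h in histories:
        prev_year, prev_group, prev_age = h.mark_year, h.mark_group, h.mark_age
        for (u, j) in h.resightings:
            if u <= prev_year:
                raise ValueError("resighting at or before release occasion")
            r = m.row_index(prev_group, prev_age, prev_year)
            counts[r, m.cell_index(u, j)] += 1
            prev_year, prev_group, prev_age = u, j, "adult"
        if prev_year <= n_years - 2:
            r = m.row_index(prev_group, prev_age, prev_year)
            counts[r, -1] += 1
    return MArray(counts, n_years)


def simulate(config: SimulationConfig):
    """Run the full generator.  Returns (ObservedData, SimTruth)."""
    rng = np.random.default_rng(config.seed)
    covs = gen_covariates(config.n_groups, config.n_years, rng,
                          first_year=config.first_year)
    rates = draw_rates(config.hyper, covs, rng)
    latent = simulate_states(rates, config.init_A, rng,
                             process_noise=config.process_noise)
    y, Jobs, flags = simulate_observations(latent, config.hyper.tau_y, rng)
    y = np.where(flags, np.nan, y)
    histories = simulate_histories(rates, config.releases, rng)
    marray = marray_from_histories(histories, config.n_years)
    data = ObservedData(y=y, Jobs=Jobs, marray=marray, covs=covs)
    truth = SimTruth(config, covs, rates, latent, histories, flags)
    return data, truth
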