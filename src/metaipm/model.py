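"""Integrated metapopulation model: states, rates, likelihoods and priors.

The model tracks four wintering subpopulation groups of a migratory goose
population (Wexford, Islay, Loch Ken, and a pooled "Elsewhere" group) over T
winters.  Female abundance in group ``i`` and winter ``t`` is

    Ntot[i,t] = J[i,t] + A[i,t],      A[i,t] = N1[i,t] + Nad[i,t] + I[i,t]

where J are juveniles produced locally (Poisson with mean A·γ), N1 are
last year's juveniles that survived and stayed (Binomial), Nad are older
adults that survived and stayed (Binomial), and I are adult-aged immigrants
from the other groups (Poisson around the expected inflow).  Juvenile
movement out of Elsewhere is structurally zero and Elsewhere juvenile
survival is not separately estimable; it is tied to the focal-group mean on
the logit scale.

Three data sets inform the posterior: site counts (lognormal around log
Ntot), juvenile counts (Poisson around J), and a multistate mark-resighting
m-array (multinomial per release cohort).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .data_io import CovariateSet

__all__ = [
    "N_GROUPS", "N_FOCAL", "E_INDEX", "GROUP_LABELS",
    "juvenile_flows", "adult_flows",
    "HyperParams", "DemographicRates", "LatentState", "MArray", "ObservedData",
    "fecundity_linpred", "survival_linpred", "movement_detection", "build_rates",
    "process_expectation", "process_loglik",
    "loglik_counts", "loglik_juveniles",
    "marray_cell_probs", "loglik_marray",
    "log_prior", "joint_log_posterior",
]

N_GROUPS = 4
N_FOCAL = 3
E_INDEX = 3
GROUP_LABELS = ("W", "Is", "LK", "E")

#: Movement-prior upper bound: ψ means are a-priori Uniform(0, PSI_CAP).
PSI_CAP = 0.2


def juvenile_flows(n_groups: int = N_GROUPS, n_focal: int = N_FOCAL):
    """Ordered (origin, destination) pairs with a juvenile movement rate.

    Juveniles can move from any focal group to any other group; there is no
    juvenile flow out of Elsewhere.
    """
    return [(s, j) for s in range(n_focal) for j in range(n_groups) if j != s]


def adult_flows(n_groups: int = N_GROUPS):
    """Ordered (origin, destination) pairs with an adult movement rate."""
    return [(s, j) for s in range(n_groups) for j in range(n_groups) if j != s]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class HyperParams:
    """All top-level parameters, on their natural scales.

    Shapes use G = 4 groups, Gf = 3 focal groups, T years, Ti = T − 1
    between-winter intervals; flows are ordered per :func:`juvenile_flows` /
    :func:`adult_flows` (9 juvenile, 12 adult).
    """

    # fecundity: log γ = log α^γ + Σ β_k x_k + ε
    alpha_gamma: np.ndarray          # (G,) in (0,1)
    beta_fec: np.ndarray             # (G, 4)
    sigma_gamma: float
    eps_gamma: np.ndarray            # (G, T)

    # juvenile survival (focal only): logit φJ = logit α + β5·storms + hunt1 + ε
    alpha_phiJ: np.ndarray           # (Gf,) in (0,1)
    beta_storm_J: np.ndarray         # (Gf,)
    hunt_J: np.ndarray               # (Gf, 2) protection levels h = 1, 2
    sigma_phiJ: float
    eps_phiJ: np.ndarray             # (Gf, Ti)

    # adult survival (all groups)
    alpha_phiA: np.ndarray           # (G,)
    beta_storm_A: np.ndarray         # (G,)
    hunt_A: np.ndarray               # (G, 2)
    sigma_phiA: float
    eps_phiA: np.ndarray             # (G, Ti)

    # Laplace shrinkage of storm/hunting effects toward among-group means
    mu_beta_J: float = 0.0
    lam_beta_J: float = 1.0
    mu_beta_A: float = 0.0
    lam_beta_A: float = 1.0
    mu_hunt_J: np.ndarray = field(default_factory=lambda: np.zeros(2))
    lam_hunt_J: np.ndarray = field(default_factory=lambda: np.ones(2))
    mu_hunt_A: np.ndarray = field(default_factory=lambda: np.zeros(2))
    lam_hunt_A: np.ndarray = field(default_factory=lambda: np.ones(2))

    # movement: logit ψ_t = logit α^ψ + ε_t, per flow
    alpha_psiJ: np.ndarray = None    # (9,) in [0, 0.2)
    eps_psiJ: np.ndarray = None      # (9, Ti)
    alpha_psiA: np.ndarray = None    # (12,)
    eps_psiA: np.ndarray = None      # (12, Ti)
    sigma_psi: float = 0.1

    # detection
    alpha_p: np.ndarray = None       # (G,) in (0,1)
    sigma_p: float = 0.1
    eps_p: np.ndarray = None         # (G, T)

    # count observation: log-scale variance of the lognormal count model
    tau_y: float = 0.01

    @property
    def n_years(self) -> int:
        return self.eps_gamma.shape[1]

    def copy(self) -> "HyperParams":
        kw = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            kw[name] = v.copy() if isinstance(v, np.ndarray) else v
        return HyperParams(**kw)

    @classmethod
    def constant(cls, n_years: int, *, alpha_gamma=0.12, alpha_phiJ=0.75,
                 alpha_phiA=0.85, alpha_psi=0.03, alpha_p=0.9, tau_y=0.01,
                 sigma_gamma=0.0, sigma_phiJ=0.0, sigma_phiA=0.0,
                 sigma_psi=0.0, sigma_p=0.0) -> "HyperParams":
        """Intercept-only parameter set with no covariate or year effects."""
        T, Ti = n_years, n_years - 1
        g = np.full(N_GROUPS, float(alpha_gamma)) if np.isscalar(alpha_gamma) \
            else np.asarray(alpha_gamma, float)
        return cls(
            alpha_gamma=g,
            beta_fec=np.zeros((N_GROUPS, 4)),
            sigma_gamma=sigma_gamma,
            eps_gamma=np.zeros((N_GROUPS, T)),
            alpha_phiJ=np.full(N_FOCAL, alpha_phiJ) if np.isscalar(alpha_phiJ)
            else np.asarray(alpha_phiJ, float),
            beta_storm_J=np.zeros(N_FOCAL),
            hunt_J=np.zeros((N_FOCAL, 2)),
            sigma_phiJ=sigma_phiJ,
            eps_phiJ=np.zeros((N_FOCAL, Ti)),
            alpha_phiA=np.full(N_GROUPS, alpha_phiA) if np.isscalar(alpha_phiA)
            else np.asarray(alpha_phiA, float),
            beta_storm_A=np.zeros(N_GROUPS),
            hunt_A=np.zeros((N_GROUPS, 2)),
            sigma_phiA=sigma_phiA,
            eps_phiA=np.zeros((N_GROUPS, Ti)),
            alpha_psiJ=np.full(9, alpha_psi) if np.isscalar(alpha_psi)
            else np.asarray(alpha_psi, float),
            eps_psiJ=np.zeros((9, Ti)),
            alpha_psiA=np.full(12, alpha_psi) if np.isscalar(alpha_psi)
            else np.asarray(alpha_psi, float)[:12] if np.size(alpha_psi) > 9
            else np.full(12, np.mean(alpha_psi)),
            eps_psiA=np.zeros((12, Ti)),
            sigma_psi=sigma_psi,
            alpha_p=np.full(N_GROUPS, alpha_p) if np.isscalar(alpha_p)
            else np.asarray(alpha_p, float),
            sigma_p=sigma_p,
            eps_p=np.zeros((N_GROUPS, T)),
            tau_y=tau_y,
        )


@dataclass
class DemographicRates:
    """Realized per-year rates.  Movement is stored as (G × G × Ti) matrices
    with zero diagonals; ``fidelity* = 1 − Σ_j ψ[i, j]``."""

    gamma: np.ndarray    # (G, T) > 0
    phiJ: np.ndarray     # (G, Ti); Elsewhere row is the derived tied value
    phiA: np.ndarray     # (G, Ti)
    psiJ: np.ndarray     # (G, G, Ti), row E structurally zero
    psiA: np.ndarray     # (G, G, Ti)
    p: np.ndarray        # (G, T)

    def __post_init__(self):
        # boundary values (φ = 1, p = 0, γ = 0) are legal in the container so
        # deterministic-limit checks can be expressed; the prior keeps the
        # posterior in the open intervals.
        if np.any(self.gamma < 0):
            raise ValueError("gamma must be nonnegative")
        for nm in ("phiJ", "phiA", "p"):
            v = getattr(self, nm)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{nm} must lie in [0,1]")
        for nm in ("psiJ", "psiA"):
            v = getattr(self, nm)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{nm} must lie in [0,1]")
            if np.any(np.einsum("iit->it", v) != 0):
                raise ValueError(f"{nm} diagonal must be zero")
            if np.any(v.sum(axis=1) > 1 + 1e-12):
                raise ValueError(f"{nm} outflow must not exceed 1")
        if np.any(self.psiJ[E_INDEX] != 0):
            raise ValueError("no juvenile movement out of Elsewhere")

    @property
    def n_years(self) -> int:
        return self.gamma.shape[1]

    @property
    def fidelityJ(self) -> np.ndarray:
        return 1.0 - self.psiJ.sum(axis=1)

    @property
    def fidelityA(self) -> np.ndarray:
        return 1.0 - self.psiA.sum(axis=1)


@dataclass
class LatentState:
    """Integer stage abundances per group-year.

    ``N1``, ``Nad`` and ``I`` are zero in year 1 by convention (the year-1
    state is summarized by initial adults ``A[:, 0]`` and juveniles
    ``J[:, 0]``); ``A`` and ``Ntot`` are derived.
    """

    J: np.ndarray      # (G, T)
    N1: np.ndarray
    Nad: np.ndarray
    I: np.ndarray
    A1: np.ndarray     # (G,) initial adults

    def __post_init__(self):
        for nm in ("J", "N1", "Nad", "I"):
            v = np.asarray(getattr(self, nm))
            if np.any(v < 0):
                raise ValueError(f"{nm} must be nonnegative")
            setattr(self, nm, v.astype(np.int64))
        self.A1 = np.asarray(self.A1, dtype=np.int64)

    @property
    def A(self) -> np.ndarray:
        A = self.N1 + self.Nad + self.I
        A[:, 0] = self.A1
        return A

    @property
    def Ntot(self) -> np.ndarray:
        return self.J + self.A


@dataclass
class MArray:
    """Multistate m-array.

    One row per release cohort (age class, group, release occasion); columns
    are first-resighting cells (occasion u ≥ release + 1, group j) plus a
    final never-seen-again cell.  Row enumeration is fixed: juvenile rows
    (focal groups × release occasions 0..T−2) then adult rows (all groups ×
    occasions 0..T−2); cell index c = u_idx·G + j with u_idx = u − 1, and the
    last column is never-seen.
    """

    counts: np.ndarray          # (R, C) int
    n_years: int
    n_groups: int = N_GROUPS
    n_focal: int = N_FOCAL

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("m-array counts must be nonnegative")
        R, C = self.expected_shape(self.n_years, self.n_groups, self.n_focal)
        if self.counts.shape != (R, C):
            raise ValueError(
                f"m-array shape {self.counts.shape} != expected {(R, C)}")

    @staticmethod
    def expected_shape(T: int, G: int = N_GROUPS, Gf: int = N_FOCAL):
        return ((Gf + G) * (T - 1), (T - 1) * G + 1)

    @classmethod
    def empty(cls, n_years: int) -> "MArray":
        R, C = cls.expected_shape(n_years)
        return cls(np.zeros((R, C), dtype=np.int64), n_years)

    def row_index(self, group: int, age: str, year: int) -> int:
        """Row for a release of ``age`` ('juv'|'adult') in ``group`` at
        0-based occasion ``year`` (must be ≤ T−2)."""
        T = self.n_years
        if not 0 <= year <= T - 2:
            raise ValueError(f"release occasion {year} out of range")
        if age == "juv":
            if group >= self.n_focal:
                raise ValueError("juvenile releases only in focal groups")
            return group * (T - 1) + year
        if age == "adult":
            return self.n_focal * (T - 1) + group * (T - 1) + year
        raise ValueError(f"unknown age class {age!r}")

    def row_meta(self):
        """(age_is_juv, group, occasion) per row, in row order."""
        T = self.n_years
        meta = [(True, g, y) for g in range(self.n_focal) for y in range(T - 1)]
        meta += [(False, g, y) for g in range(self.n_groups) for y in range(T - 1)]
        return meta

    def cell_index(self, resight_year: int, group: int) -> int:
        if resight_year < 1:
            raise ValueError("resightings start at occasion 1")
        return (resight_year - 1) * self.n_groups + group

    @property
    def releases(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ObservedData:
    """Everything the joint posterior conditions on."""

    y: np.ndarray            # (G, T) female counts; NaN = unobserved cell
    Jobs: np.ndarray         # (G, T) juvenile counts; NaN = unobserved
    marray: MArray
    covs: CovariateSet

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.Jobs = np.asarray(self.Jobs, dtype=float)
        if self.y.shape != self.Jobs.shape:
            raise ValueError("y and Jobs shapes differ")
        if self.y.shape[1] != self.marray.n_years:
            raise ValueError("count years and m-array years differ")

    @property
    def n_years(self) -> int:
        return self.y.shape[1]


# ---------------------------------------------------------------------------
# rate construction
# ---------------------------------------------------------------------------

def _logit(x):
    return np.log(x) - np.log1p(-x)


def fecundity_linpred(hyper: HyperParams, covs: CovariateSet, i: int, t: int) -> float:
    """Per-capita production of young γ[i,t] from the log-link predictor.

    The (0,1) fecundity intercept is the natural-scale among-year mean and
    enters as log(α^γ): log γ = log α + β1·GDDwinter + β2·GDDstage +
    β3·GDDbreed + β4·snowbreed + ε.
    """
    a = hyper.alpha_gamma[i]
    if not 0 < a < 1:
        raise ValueError(f"alpha_gamma[{i}]={a} outside (0,1)")
    x = covs.fecundity_design()[:, i, t]
    lp = math.log(a) + float(hyper.beta_fec[i] @ x) + hyper.eps_gamma[i, t]
    return math.exp(lp)


def survival_linpred(hyper: HyperParams, covs: CovariateSet, i: int, t: int,
                     age: str) -> float:
    """Apparent survival over interval t → t+1 from the logit-link predictor.

    Hunting-protection intercepts are deviations from the baseline period
    (h = 0 contributes nothing).  ``age`` is 'juv' or 'adult'; the Elsewhere
    juvenile rate is the derived focal-mean value.
    """
    h = covs.hunt_level[t]
    storms = covs.storms[i, t]
    if age == "juv":
        if i == E_INDEX:
            lps = [_logit(hyper.alpha_phiJ[g]) + hyper.beta_storm_J[g] * covs.storms[g, t]
                   + (hyper.hunt_J[g, h - 1] if h > 0 else 0.0) + hyper.eps_phiJ[g, t]
                   for g in range(N_FOCAL)]
            return float(special.expit(np.mean(lps)))
        a = hyper.alpha_phiJ[i]
        lp = _logit(a) + hyper.beta_storm_J[i] * storms + hyper.eps_phiJ[i, t]
        if h > 0:
            lp += hyper.hunt_J[i, h - 1]
    elif age == "adult":
        a = hyper.alpha_phiA[i]
        lp = _logit(a) + hyper.beta_storm_A[i] * storms + hyper.eps_phiA[i, t]
        if h > 0:
            lp += hyper.hunt_A[i, h - 1]
    else:
        raise ValueError(f"unknown age class {age!r}")
    if not 0 < a < 1:
        raise ValueError("survival intercept outside (0,1)")
    return float(special.expit(lp))


def movement_detection(hyper: HyperParams, t: int):
    """(ψJ, ψA, p) at interval/occasion ``t``.

    ψ_t = inverse-logit(logit(α^ψ) + ε_t) per flow (α = 0 pins a flow at 0);
    p likewise around logit(α^p).  Rows with Σψ ≥ 1 are invalid and are
    rejected by the sampler rather than renormalized.
    """
    G = N_GROUPS
    psiJ = np.zeros((G, G))
    psiA = np.zeros((G, G))
    for f, (s, j) in enumerate(juvenile_flows()):
        a = hyper.alpha_psiJ[f]
        if not 0 <= a <= PSI_CAP:
            raise ValueError(f"alpha_psiJ[{f}]={a} outside [0,{PSI_CAP}]")
        if a > 0:
            psiJ[s, j] = special.expit(_logit(a) + hyper.eps_psiJ[f, t])
    for f, (s, j) in enumerate(adult_flows()):
        a = hyper.alpha_psiA[f]
        if not 0 <= a <= PSI_CAP:
            raise ValueError(f"alpha_psiA[{f}]={a} outside [0,{PSI_CAP}]")
        if a > 0:
            psiA[s, j] = special.expit(_logit(a) + hyper.eps_psiA[f, t])
    if np.any(hyper.alpha_p <= 0) or np.any(hyper.alpha_p >= 1):
        raise ValueError("alpha_p outside (0,1)")
    p = special.expit(_logit(hyper.alpha_p) + hyper.eps_p[:, t])
    return psiJ, psiA, p


def build_rates(hyper: HyperParams, covs: CovariateSet) -> DemographicRates:
    """Assemble the full DemographicRates trajectory from hyperparameters.

    Vectorized equivalent of evaluating :func:`fecundity_linpred`,
    :func:`survival_linpred` and :func:`movement_detection` cell by cell.
    """
    G, T = N_GROUPS, hyper.n_years
    Ti = T - 1
    h = hyper
    if np.any((h.alpha_gamma <= 0) | (h.alpha_gamma >= 1)):
        raise ValueError("alpha_gamma outside (0,1)")
    for a in np.concatenate([h.alpha_phiJ, h.alpha_phiA, h.alpha_p]):
        if not 0 < a < 1:
            raise ValueError("survival/detection intercept outside (0,1)")
    X = covs.fecundity_design()
    gamma = np.exp(np.log(h.alpha_gamma)[:, None]
                   + np.einsum("gk,kgt->gt", h.beta_fec, X) + h.eps_gamma)

    hsel = covs.hunt_level[:Ti]
    hunt1 = np.zeros((N_FOCAL, Ti))
    hunt2 = np.zeros((G, Ti))
    for lev in (1, 2):
        mask = hsel == lev
        hunt1[:, mask] = h.hunt_J[:, lev - 1][:, None]
        hunt2[:, mask] = h.hunt_A[:, lev - 1][:, None]
    lpJ = (_logit(h.alpha_phiJ)[:, None]
           + h.beta_storm_J[:, None] * covs.storms[:N_FOCAL, :Ti]
           + hunt1 + h.eps_phiJ)
    phiJ = np.empty((G, Ti))
    phiJ[:N_FOCAL] = special.expit(lpJ)
    phiJ[E_INDEX] = special.expit(lpJ.mean(axis=0))
    phiA = special.expit(_logit(h.alpha_phiA)[:, None]
                         + h.beta_storm_A[:, None] * covs.storms[:, :Ti]
                         + hunt2 + h.eps_phiA)

    def psi_mats(alpha, eps, flows):
        out = np.zeros((G, G, Ti))
        for f, (s, j) in enumerate(flows):
            a = alpha[f]
            if not 0 <= a <= PSI_CAP:
                raise ValueError(f"movement mean {a} outside [0,{PSI_CAP}]")
            if a > 0:
                out[s, j] = special.expit(_logit(a) + eps[f])
        return out

    psiJ = psi_mats(h.alpha_psiJ, h.eps_psiJ, juvenile_flows())
    psiA = psi_mats(h.alpha_psiA, h.eps_psiA, adult_flows())
    p = special.expit(_logit(h.alpha_p)[:, None] + h.eps_p)
    return DemographicRates(gamma, phiJ, phiA, psiJ, psiA, p)


# ---------------------------------------------------------------------------
# process model
# ---------------------------------------------------------------------------

def process_expectation(state_t: dict, rates_t: dict) -> dict:
    """Expected next-year stage abundances given this year's state.

    ``state_t``: {'J': (G,), 'A': (G,)}; ``rates_t``: {'gamma_next': (G,),
    'phiJ', 'phiA': (G,), 'psiJ', 'psiA': (G,G)} for the connecting interval.
    Returns expectations of J, N1, Nad, I (and A, Ntot) at t+1.
    """
    J = np.asarray(state_t["J"], float)
    A = np.asarray(state_t["A"], float)
    phiJ, phiA = rates_t["phiJ"], rates_t["phiA"]
    psiJ, psiA = rates_t["psiJ"], rates_t["psiA"]
    fidJ = 1.0 - psiJ.sum(axis=1)
    fidA = 1.0 - psiA.sum(axis=1)
    N1 = phiJ * fidJ * J
    Nad = phiA * fidA * A
    I = (phiJ * J) @ psiJ + (phiA * A) @ psiA
    A_next = N1 + Nad + I
    out = {"N1": N1, "Nad": Nad, "I": I, "A": A_next}
    if "gamma_next" in rates_t:
        out["J"] = rates_t["gamma_next"] * A_next
        out["Ntot"] = out["J"] + A_next
    return out


def process_loglik(latent: LatentState, rates: DemographicRates) -> float:
    """Log-density of the latent trajectory under the process model."""
    G, T = latent.J.shape
    A = latent.A
    ll = 0.0
    # local recruitment, all years (year 1 initializes J from A1·γ1)
    lam = rates.gamma * A
    ll += float(stats.poisson.logpmf(latent.J, np.maximum(lam, 1e-300)).sum())
    fidJ, fidA = rates.fidelityJ, rates.fidelityA
    for t in range(1, T):
        qJ = rates.phiJ[:, t - 1] * fidJ[:, t - 1]
        qA = rates.phiA[:, t - 1] * fidA[:, t - 1]
        ll += float(stats.binom.logpmf(latent.N1[:, t], latent.J[:, t - 1], qJ).sum())
        ll += float(stats.binom.logpmf(latent.Nad[:, t], A[:, t - 1], qA).sum())
        inflow = ((rates.phiJ[:, t - 1] * latent.J[:, t - 1]) @ rates.psiJ[:, :, t - 1]
                  + (rates.phiA[:, t - 1] * A[:, t - 1]) @ rates.psiA[:, :, t - 1])
        with np.errstate(divide="ignore"):
            ll += float(stats.poisson.logpmf(latent.I[:, t],
                                             np.maximum(inflow, 1e-300)).sum())
    return ll


# ---------------------------------------------------------------------------
# observation likelihoods
# ---------------------------------------------------------------------------

def loglik_counts(y, Ntot, tau_y: float) -> float:
    """Lognormal count likelihood: y ~ logNormal(log Ntot, τ_y).

    τ_y is the log-scale *variance*.  NaN cells are treated as unobserved
    and skipped; nonpositive y on a modeled cell is an error.
    """
    if tau_y <= 0:
        raise ValueError("tau_y must be positive")
    y = np.asarray(y, float)
    Ntot = np.asarray(Ntot, float)
    mask = ~np.isnan(y)
    yv, nv = y[mask], Ntot[mask]
    if np.any(yv <= 0):
        raise ValueError("nonpositive count on a modeled cell")
    if np.any(nv <= 0):
        return -np.inf
    sd = math.sqrt(tau_y)
    return float(stats.lognorm.logpdf(yv, s=sd, scale=nv).sum())


def loglik_juveniles(Jobs, J) -> float:
    """Poisson juvenile-count likelihood: Jobs ~ Poisson(J).

    J = 0 is allowed: it contributes 0 when Jobs = 0 and −inf otherwise.
    """
    Jobs = np.asarray(Jobs, float)
    J = np.asarray(J, float)
    mask = ~np.isnan(Jobs)
    jo, jl = Jobs[mask], J[mask]
    if np.any(jo < 0) or np.any(jo != np.round(jo)):
        raise ValueError("Jobs must be nonnegative integers")
    if np.any((jl == 0) & (jo > 0)):
        return -np.inf
    zero = (jl == 0) & (jo == 0)
    with np.errstate(divide="ignore"):
        return float(stats.poisson.logpmf(jo[~zero], jl[~zero]).sum())


def _transition_matrix(rates: DemographicRates, t: int, juvenile: bool) -> np.ndarray:
    """M[s, j] = Pr(alive in j at t+1 | in s at t) for the given age class."""
    if juvenile:
        phi, psi = rates.phiJ[:, t], rates.psiJ[:, :, t]
    else:
        phi, psi = rates.phiA[:, t], rates.psiA[:, :, t]
    M = psi * phi[:, None]
    np.fill_diagonal(M, phi * (1.0 - psi.sum(axis=1)))
    return M


def marray_cell_probs(rates: DemographicRates, group: int, age: str,
                      year: int) -> np.ndarray:
    """Multinomial cell probabilities for one release cohort.

    The vector matches the MArray column layout: cell ((u−1)·G + j) is the
    probability of first resighting in group j at occasion u, obtained by
    propagating survival/movement with non-detection at intermediate
    occasions; the final entry is never-seen-again.  Juvenile rates apply
    only to the first interval after a juvenile release.
    """
    G, T = rates.gamma.shape
    C = (T - 1) * G + 1
    out = np.zeros(C)
    if year >= T - 1:
        out[-1] = 1.0
        return out
    q = np.zeros(G)
    q[group] = 1.0
    total = 0.0
    for u in range(year + 1, T):
        M = _transition_matrix(rates, u - 1, juvenile=(age == "juv" and u == year + 1))
        q = q @ M
        cells = q * rates.p[:, u]
        out[(u - 1) * G:(u - 1) * G + G] = cells
        total += cells.sum()
        q = q * (1.0 - rates.p[:, u])
    out[-1] = 1.0 - total
    return out


def loglik_marray(marray: MArray, rates: DemographicRates) -> float:
    """Multistate multinomial m-array log-likelihood.

    Multinomial normalizing constants are dropped, so absolute values are
    comparable only within a fixed data set.  A positive count on a
    zero-probability cell yields −inf.
    """
    ll = 0.0
    for r, (is_juv, g, y) in enumerate(marray.row_meta()):
        row = marray.counts[r]
        if row.sum() == 0:
            continue
        probs = marray_cell_probs(rates, g, "juv" if is_juv else "adult", y)
        nz = row > 0
        if np.any(probs[nz] <= 0):
            return -np.inf
        ll += float((row[nz] * np.log(probs[nz])).sum())
    return ll


# ---------------------------------------------------------------------------
# priors and joint posterior
# ---------------------------------------------------------------------------

#: Discrete-uniform support (lo, hi inclusive) of initial adults per group.
A1_SUPPORT = ((1000, 4000), (1000, 4000), (1, 400), (1000, 7500))


def _log_uniform(x, lo, hi):
    return -math.log(hi - lo) if lo < x < hi else -np.inf


def _log_laplace(x, mu, b):
    return -math.log(2.0 * b) - abs(x - mu) / b


def log_prior(hyper: HyperParams, A1) -> float:
    """Joint log prior over hyperparameters and initial adult abundances.

    Returns −inf outside any support (the contract: no exceptions).
    Laplace shrinkage scales are b = 1/λ² with λ ~ Exponential(0.1).
    """
    lp = 0.0
    A1 = np.asarray(A1)
    for i, (lo, hi) in enumerate(A1_SUPPORT):
        if not lo <= A1[i] <= hi:
            return -np.inf
        lp += -math.log(hi - lo + 1)
    h = hyper
    # fecundity
    for a in h.alpha_gamma:
        lp += _log_uniform(a, 0, 1)
    lp += float(stats.norm.logpdf(h.beta_fec, 0, 10).sum())
    lp += _log_uniform(h.sigma_gamma, 0, 10)
    if not np.isfinite(lp):
        return -np.inf
    lp += float(stats.norm.logpdf(h.eps_gamma, 0, h.sigma_gamma).sum())
    # survival intercepts and variances
    for a in np.concatenate([h.alpha_phiJ, h.alpha_phiA, h.alpha_p]):
        lp += _log_uniform(a, 0, 1)
    lp += _log_uniform(h.sigma_phiJ, 0, 10)
    lp += _log_uniform(h.sigma_phiA, 0, 10)
    lp += _log_uniform(h.sigma_p, 0, 10)
    if not np.isfinite(lp):
        return -np.inf
    lp += float(stats.norm.logpdf(h.eps_phiJ, 0, h.sigma_phiJ).sum())
    lp += float(stats.norm.logpdf(h.eps_phiA, 0, h.sigma_phiA).sum())
    lp += float(stats.norm.logpdf(h.eps_p, 0, h.sigma_p).sum())
    # shrinkage hierarchy on storm and hunting effects
    for mu, lam, vals in (
        (h.mu_beta_J, h.lam_beta_J, h.beta_storm_J),
        (h.mu_beta_A, h.lam_beta_A, h.beta_storm_A),
    ):
        if lam <= 0:
            return -np.inf
        lp += float(stats.norm.logpdf(mu, 0, 1))
        lp += float(stats.expon.logpdf(lam, scale=10.0))
        b = 1.0 / lam ** 2
        lp += sum(_log_laplace(v, mu, b) for v in np.atleast_1d(vals))
    for lev in range(2):
        for mu, lam, vals in (
            (h.mu_hunt_J[lev], h.lam_hunt_J[lev], h.hunt_J[:, lev]),
            (h.mu_hunt_A[lev], h.lam_hunt_A[lev], h.hunt_A[:, lev]),
        ):
            if lam <= 0:
                return -np.inf
            lp += float(stats.norm.logpdf(mu, 0, 1))
            lp += float(stats.expon.logpdf(lam, scale=10.0))
            b = 1.0 / lam ** 2
            lp += sum(_log_laplace(v, mu, b) for v in np.atleast_1d(vals))
    # movement and detection
    for a in np.concatenate([h.alpha_psiJ, h.alpha_psiA]):
        if not 0 <= a <= PSI_CAP:
            return -np.inf
        lp += -math.log(PSI_CAP)
    lp += _log_uniform(h.sigma_psi, 0, 1)
    if not np.isfinite(lp):
        return -np.inf
    lp += float(stats.norm.logpdf(h.eps_psiJ, 0, h.sigma_psi).sum())
    lp += float(stats.norm.logpdf(h.eps_psiA, 0, h.sigma_psi).sum())
    # count observation variance
    if h.tau_y <= 0:
        return -np.inf
    lp += float(stats.invgamma.logpdf(h.tau_y, 0.01, scale=0.01))
    return float(lp)


def joint_log_posterior(hyper: HyperParams, latent: LatentState,
                        data: ObservedData) -> float:
    """log prior + process density + the three observation log-likelihoods."""
    lp = log_prior(hyper, latent.A1)
    if not np.isfinite(lp):
        return -np.inf
    try:
        rates = build_rates(hyper, data.covs)
    except ValueError:
        return -np.inf
    for t in range(1, latent.J.shape[1]):
        if np.any(latent.N1[:, t] > latent.J[:, t - 1]):
            return -np.inf
        if np.any(latent.Nad[:, t] > latent.A[:, t - 1]):
            return -np.inf
    lp += process_loglik(latent, rates)
    if not np.isfinite(lp):
        return -np.inf
    lp += loglik_counts(data.y, latent.Ntot, hyper.tau_y)
    lp += loglik_juveniles(data.Jobs, latent.J)
    lp += loglik_marray(data.marray, rates)
    return float(lp)


# ---------------------------------------------------------------------------
# model-structure serialization
# ---------------------------------------------------------------------------

def model_spec(n_years: int = 39) -> dict:
    """Structural description of the model: groups, movement flows,
    covariate mapping and prior settings.  Round-trips through YAML."""
    lab = GROUP_LABELS
    return {
        "groups": list(lab),
        "focal_groups": list(lab[:N_FOCAL]),
        "n_years": n_years,
        "juvenile_flows": [f"{lab[s]}->{lab[d]}" for s, d in juvenile_flows()],
        "adult_flows": [f"{lab[s]}->{lab[d]}" for s, d in adult_flows()],
        "fecundity_covariates": ["gdd_winter", "gdd_stage", "gdd_breed",
                                 "snow_breed"],
        "survival_covariates": ["storms", "hunt_level"],
        "priors": {
            "alpha_gamma": "Uniform(0,1)",
            "alpha_phiJ": "Uniform(0,1)",
            "alpha_phiA": "Uniform(0,1)",
            "alpha_p": "Uniform(0,1)",
            "alpha_psi": f"Uniform(0,{PSI_CAP})",
            "beta_fecundity": "Normal(0,10)",
            "beta_storm_and_hunt": "Laplace(mu, 1/lambda^2); "
                                   "mu~Normal(0,1), lambda~Exponential(0.1)",
            "sigma_gamma": "Uniform(0,10)",
            "sigma_phi": "Uniform(0,10)",
            "sigma_psi": "Uniform(0,1)",
            "sigma_p": "Uniform(0,10)",
            "tau_y": "InverseGamma(0.01,0.01)",
            "initial_adults": {lab[i]: list(A1_SUPPORT[i])
                               for i in range(N_GROUPS)},
        },
    }


def spec_to_yaml(path, n_years: int = 39) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(model_spec(n_years), fh, sort_keys=False)


def spec_from_yaml(path) -> dict:
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    expected = model_spec(spec.get("n_years", 39))
    for key in ("groups", "juvenile_flows", "adult_flows"):
        if spec.get(key) != expected[key]:
            raise ValueError(f"model spec field {key!r} does not match the "
                             "implemented structure")
    return spec
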