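"""Post-fit demography: realised growth, transient-LTRE decompositions,
net immigration rates and movement-scenario projections.

The realised growth rate of group *i* is λ_t = Ntot_{t+1}/Ntot_t.  For the
decompositions it is written as a function of the realised demographic
parameters θ:

    λ_t = (1 + γ_{t+1}) · [ φJ_t σJ_t πJ_t + φA_t σA_t (πN1 + πNad + πI)_t
                            + Σ_s ι_{s,t} ]

with σ = 1 − Σψ the fidelity, π the stage proportions of Ntot, and
ι_{s,t} the adult-equivalent immigrants from source s arriving at t+1 per
capita of Ntot_t.  A transient LTRE then attributes Var_t(λ) to the θ's:
contribution(θ_k) = Σ_j (∂λ/∂θ_k)(∂λ/∂θ_j) Cov_t(θ_k, θ_j), sensitivities
evaluated at the temporal means, computed per posterior draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model import (
    E_INDEX, GROUP_LABELS, N_FOCAL, N_GROUPS,
    adult_flows, juvenile_flows,
)

__all__ = [
    "THETA_LABELS", "SCENARIOS",
    "LTREResult", "SourceSinkResult", "ProjectionResult",
    "realized_growth", "theta_series", "lambda_from_theta",
    "tltre_single", "tltre_decompose",
    "delta_lambda_contributions", "dominant_driver_summary",
    "net_immigration", "project_scenarios",
]

SCENARIOS = ("emigration_only", "immigration_only", "no_movement", "both")


def theta_labels(group: int) -> list:
    """Names of the 12 demographic parameters in a group's tLTRE."""
    others = [GROUP_LABELS[s] for s in range(N_GROUPS) if s != group]
    return (["fecundity", "juv_survival", "adult_survival",
             "juv_fidelity", "adult_fidelity"]
            + [f"immigration_from_{s}" for s in others]
            + ["prop_J", "prop_N1", "prop_Nad", "prop_I"])


THETA_LABELS = theta_labels  # alias; labels depend on the focal group


# ---------------------------------------------------------------------------
# extraction helpers
# ---------------------------------------------------------------------------

def _as_arrays(draws):
    """(rates dict, latent dict) with a leading draw axis.

    Accepts a :class:`PosteriorDraws`, a ``(rates, latent)`` tuple of dicts,
    or a synthetic-truth object carrying ``rates`` and ``latent``.
    """
    if isinstance(draws, PosteriorDraws):
        return draws.rate_arrays(), draws.latent_arrays()
    if isinstance(draws, tuple) and len(draws) == 2:
        return draws
    if hasattr(draws, "rates") and hasattr(draws, "latent"):
        r = draws.rates
        lat = draws.latent
        psiJ = np.array([r.psiJ[s, d] for s, d in juvenile_flows()])[None]
        psiA = np.array([r.psiA[s, d] for s, d in adult_flows()])[None]
        ra = dict(
            gamma=r.gamma[None], phiJ=r.phiJ[None], phiA=r.phiA[None],
            psiJ=psiJ, psiA=psiA,
            fidJ=r.fidelityJ[None], fidA=r.fidelityA[None], p=r.p[None],
        )
        A = lat.A
        la = dict(J=lat.J[None], N1=lat.N1[None], Nad=lat.Nad[None],
                  I=lat.I[None], A=A[None], Ntot=lat.Ntot[None])
        return ra, la
    raise TypeError(f"cannot extract rate/latent arrays from {type(draws)!r}")


def realized_growth(Ntot: np.ndarray) -> np.ndarray:
    """λ_t = Ntot_{t+1}/Ntot_t along the last (year) axis."""
    Ntot = np.asarray(Ntot, dtype=float)
    if Ntot.shape[-1] < 2:
        raise ValueError("need at least two years")
    if np.any(Ntot[..., :-1] == 0):
        bad = np.argwhere(Ntot[..., :-1] == 0)[0]
        raise ValueError(f"zero Ntot at index {tuple(bad)}: growth undefined")
    return Ntot[..., 1:] / Ntot[..., :-1]


# ---------------------------------------------------------------------------
# tLTRE machinery
# ---------------------------------------------------------------------------

def theta_series(draws, group: int) -> np.ndarray:
    """Realised θ series, shape (n_draws, 12, T−2), for one focal group.

    The series starts at the second winter: the stage composition of the
    year-1 adults (N1 vs Nad vs I) is not defined by the model, so the first
    transition has no well-defined stage proportions and is excluded from
    the decomposition window.
    """
    if group == E_INDEX:
        raise ValueError("the pooled Elsewhere group has no tLTRE "
                         "(its juvenile rates are not separately estimated)")
    ra, la = _as_arrays(draws)
    n = ra["gamma"].shape[0]
    T = ra["gamma"].shape[2]
    g = group
    Ntot = la["Ntot"].astype(float)
    J, N1, Nad, I, A = (la[k].astype(float) for k in ("J", "N1", "Nad", "I", "A"))
    th = np.empty((n, 12, T - 2))
    th[:, 0] = ra["gamma"][:, g, 2:]          # fecundity realized at t+1
    th[:, 1] = ra["phiJ"][:, g, 1:]           # rates over interval t -> t+1
    th[:, 2] = ra["phiA"][:, g, 1:]
    th[:, 3] = ra["fidJ"][:, g, 1:]
    th[:, 4] = ra["fidA"][:, g, 1:]
    jf = {(s, d): f for f, (s, d) in enumerate(juvenile_flows())}
    af = {(s, d): f for f, (s, d) in enumerate(adult_flows())}
    k = 5
    for s in range(N_GROUPS):
        if s == g:
            continue
        flow = ra["phiA"][:, s, 1:] * ra["psiA"][:, af[(s, g)], 1:] \
            * A[:, s, 1:-1]
        if (s, g) in jf:
            flow = flow + ra["phiJ"][:, s, 1:] * ra["psiJ"][:, jf[(s, g)], 1:] \
                * J[:, s, 1:-1]
        th[:, k] = flow / Ntot[:, g, 1:-1]
        k += 1
    th[:, 8] = J[:, g, 1:-1] / Ntot[:, g, 1:-1]
    th[:, 9] = N1[:, g, 1:-1] / Ntot[:, g, 1:-1]
    th[:, 10] = Nad[:, g, 1:-1] / Ntot[:, g, 1:-1]
    th[:, 11] = I[:, g, 1:-1] / Ntot[:, g, 1:-1]
    return th


def lambda_from_theta(th: np.ndarray) -> np.ndarray:
    """λ as a function of the θ vector (last-but-one axis of length 12)."""
    th = np.asarray(th, dtype=float)
    gam, phiJ, phiA, fidJ, fidA = (th[..., k, :] for k in range(5))
    iota = th[..., 5:8, :].sum(axis=-2)
    piJ = th[..., 8, :]
    piA = th[..., 9:12, :].sum(axis=-2)
    return (1.0 + gam) * (phiJ * fidJ * piJ + phiA * fidA * piA + iota)


def _sensitivities(mean_th: np.ndarray) -> np.ndarray:
    """Analytic ∂λ/∂θ at the temporal means (vectorized over leading axes)."""
    gam, phiJ, phiA, fidJ, fidA = (mean_th[..., k] for k in range(5))
    iota = mean_th[..., 5:8].sum(axis=-1)
    piJ = mean_th[..., 8]
    piA = mean_th[..., 9:12].sum(axis=-1)
    inner = phiJ * fidJ * piJ + phiA * fidA * piA + iota
    one_g = 1.0 + gam
    s = np.empty(mean_th.shape)
    s[..., 0] = inner
    s[..., 1] = one_g * fidJ * piJ
    s[..., 2] = one_g * fidA * piA
    s[..., 3] = one_g * phiJ * piJ
    s[..., 4] = one_g * phiA * piA
    s[..., 5] = s[..., 6] = s[..., 7] = one_g
    s[..., 8] = one_g * phiJ * fidJ
    for k in (9, 10, 11):
        s[..., k] = one_g * phiA * fidA
    return s


def tltre_single(th: np.ndarray):
    """tLTRE for one θ series (12 × T−1).

    Returns (contributions, sensitivities, Var_t(λ)); contributions sum to
    the first-order approximation of Var_t(λ).
    """
    th = np.asarray(th, dtype=float)
    mean_th = th.mean(axis=-1)
    sens = _sensitivities(mean_th)
    C = np.cov(th)
    contrib = sens * (C @ sens)
    lam = lambda_from_theta(th)
    return contrib, sens, float(np.var(lam, ddof=1))


@dataclass
class LTREResult:
    group: int
    labels: list
    contributions: np.ndarray    # (draws, 12) absolute
    pct: np.ndarray              # (draws, 12) percent of the positive total
    sensitivities: np.ndarray    # (draws, 12)
    var_lambda: np.ndarray       # (draws,)

    def summary(self, level: float = 0.9) -> pd.DataFrame:
        a = (1 - level) / 2
        rows = []
        for k, lab in enumerate(self.labels):
            rows.append({
                "parameter": lab,
                "contribution": np.median(self.contributions[:, k]),
                "pct": np.median(self.pct[:, k]),
                "pct_lo": np.quantile(self.pct[:, k], a),
                "pct_hi": np.quantile(self.pct[:, k], 1 - a),
                "sensitivity": np.median(self.sensitivities[:, k]),
            })
        return pd.DataFrame(rows).set_index("parameter")


def tltre_decompose(draws, group: int, max_draws: int = 500) -> LTREResult:
    """Transient-LTRE variance decomposition for one focal group.

    Percentage contributions are relative to the summed contributions per
    draw, so they total 100 within each draw.
    """
    th = theta_series(draws, group)
    n = th.shape[0]
    use = np.linspace(0, n - 1, min(max_draws, n)).astype(int)
    th = th[use]
    K = th.shape[1]
    contrib = np.empty((len(use), K))
    sens = np.empty((len(use), K))
    varlam = np.empty(len(use))
    for d in range(len(use)):
        c, s, v = tltre_single(th[d])
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite tLTRE sensitivities")
        contrib[d], sens[d], varlam[d] = c, s, v
    tot = contrib.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * contrib / tot
    return LTREResult(group, theta_labels(group), contrib, pct, sens, varlam)


def delta_lambda_contributions(draws, group: int, max_draws: int = 500,
                               big_change: float = 0.1) -> pd.DataFrame:
    """Per-year contributions of each θ to the change Δλ_t = λ_{t+1} − λ_t.

    The contribution of θ_k in year t is (θ_{k,t+1} − θ_{k,t}) · ∂λ/∂θ_k
    evaluated at the midpoint, summarized by the posterior median.  Rows are
    transition years; columns are the drivers plus ``delta_lambda`` and a
    ``big_change`` flag for |Δλ| > 0.1 and the dominant driver.
    """
    th = theta_series(draws, group)
    if th.shape[-1] < 2:
        raise ValueError("need at least 3 years for year-to-year changes")
    n = th.shape[0]
    use = np.linspace(0, n - 1, min(max_draws, n)).astype(int)
    th = th[use]
    dth = th[..., 1:] - th[..., :-1]                # (n, 12, Ti-1)
    mid = 0.5 * (th[..., 1:] + th[..., :-1])
    sens = _sensitivities(np.moveaxis(mid, 1, -1))  # (n, Ti-1, 12)
    contrib = np.moveaxis(dth, 1, -1) * sens        # (n, Ti-1, 12)
    lam = lambda_from_theta(th)
    dlam = lam[:, 1:] - lam[:, :-1]
    med_c = np.median(contrib, axis=0)              # (Ti-1, 12)
    med_d = np.median(dlam, axis=0)
    labels = theta_labels(group)
    tab = pd.DataFrame(med_c, columns=labels)
    tab.index.name = "transition"
    tab["delta_lambda"] = med_d
    tab["big_change"] = np.abs(med_d) > big_change
    dom = np.argmax(np.abs(med_c), axis=1)
    tab["dominant_driver"] = [labels[k] for k in dom]
    return tab


def dominant_driver_summary(contributions: pd.DataFrame) -> pd.Series:
    """Percent of years in which each driver has the largest |contribution|.

    Ties are split equally among the tied drivers; the result sums to 100.
    """
    drop = [c for c in ("delta_lambda", "big_change", "dominant_driver")
            if c in contributions.columns]
    tab = contributions.drop(columns=drop)
    if tab.empty:
        raise ValueError("empty contribution table")
    vals = np.abs(tab.to_numpy(dtype=float))
    frac = pd.Series(0.0, index=tab.columns)
    for row in vals:
        mx = row.max()
        ties = np.isclose(row, mx)
        frac[tab.columns[ties]] += 1.0 / ties.sum()
    return 100.0 * frac / len(vals)


# ---------------------------------------------------------------------------
# source–sink dynamics
# ---------------------------------------------------------------------------

@dataclass
class SourceSinkResult:
    pairwise: np.ndarray      # (draws, G, G): net adult immigration s→i rate
    overall: np.ndarray       # (draws, G)

    def summary(self, level: float = 0.9) -> pd.DataFrame:
        a = (1 - level) / 2
        rows = []
        for i in range(N_GROUPS):
            lo_, md, hi_ = np.quantile(self.overall[:, i], [a, 0.5, 1 - a])
            cls = "sink" if lo_ > 0 else ("source" if hi_ < 0 else "neutral")
            rows.append({"group": GROUP_LABELS[i], "source": "overall",
                         "Inet": md, "lo": lo_, "hi": hi_, "class": cls})
            for s in range(N_GROUPS):
                if s == i:
                    continue
                q = np.quantile(self.pairwise[:, s, i], [a, 0.5, 1 - a])
                cls = "sink" if q[0] > 0 else ("source" if q[2] < 0 else "neutral")
                rows.append({"group": GROUP_LABELS[i],
                             "source": GROUP_LABELS[s],
                             "Inet": q[1], "lo": q[0], "hi": q[2], "class": cls})
        return pd.DataFrame(rows)


def net_immigration(draws) -> SourceSinkResult:
    """Post hoc net adult immigration rates per group and group pair.

    Inet_{s→i} = mean_t [(expected adult immigrants s→i at t+1 −
    expected adult emigrants i→s at t+1) / A_{i,t}]; overall Inet_i sums the
    pairwise rates.  Years with A_{i,t} = 0 are skipped with a warning.
    """
    ra, la = _as_arrays(draws)
    A = la["A"].astype(float)
    phiA = ra["phiA"]
    psiA = ra["psiA"]
    af = {(s, d): f for f, (s, d) in enumerate(adult_flows())}
    n, G, T = A.shape
    pair = np.zeros((n, G, G))
    Aprev = A[:, :, :-1]
    if np.any(Aprev == 0):
        warnings.warn("zero adult abundance in some group-years; those cells "
                      "are skipped in net immigration rates")
    for s in range(G):
        for i in range(G):
            if s == i:
                continue
            inflow = phiA[:, s, :] * psiA[:, af[(s, i)], :] * Aprev[:, s, :]
            outflow = phiA[:, i, :] * psiA[:, af[(i, s)], :] * Aprev[:, i, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = (inflow - outflow) / Aprev[:, i, :]
            pair[:, s, i] = np.nanmean(np.where(Aprev[:, i, :] > 0, rate,
                                                np.nan), axis=-1)
    overall = pair.sum(axis=1)
    return SourceSinkResult(pair, overall)


# ---------------------------------------------------------------------------
# movement-scenario projections
# ---------------------------------------------------------------------------

@dataclass
class ProjectionResult:
    scenario: str
    Ntot: np.ndarray          # (draws, G, T) projected trajectories
    growth: np.ndarray        # (draws, G) among-year geometric mean λ
    r: np.ndarray             # (draws, G) Pearson correlation vs estimates
    pr_r_positive: np.ndarray  # (G,)

    def summary(self, level: float = 0.9) -> pd.DataFrame:
        a = (1 - level) / 2
        rows = []
        for i in range(N_GROUPS):
            q = np.quantile(self.growth[:, i], [a, 0.5, 1 - a])
            rows.append({"group": GROUP_LABELS[i], "growth": q[1],
                         "lo": q[0], "hi": q[2],
                         "r": np.median(self.r[:, i]),
                         "pr_r_positive": self.pr_r_positive[i]})
        return pd.DataFrame(rows)


def _project_one(gamma, phiJ, phiA, psiJ_f, psiA_f, fidJ, fidA,
                 J0, A0, scenario: str):
    """Deterministic annual projection of all groups for one rate draw."""
    G, T = gamma.shape
    jf = juvenile_flows()
    af = adult_flows()
    emi = scenario in ("emigration_only", "both")
    imm = scenario in ("immigration_only", "both")
    J = np.zeros((G, T))
    A = np.zeros((G, T))
    J[:, 0] = J0
    A[:, 0] = A0
    for t in range(T - 1):
        retJ = phiJ[:, t] * (fidJ[:, t] if emi else 1.0)
        retA = phiA[:, t] * (fidA[:, t] if emi else 1.0)
        A[:, t + 1] = retJ * J[:, t] + retA * A[:, t]
        if imm:
            for f, (s, d) in enumerate(jf):
                A[d, t + 1] += phiJ[s, t] * psiJ_f[f, t] * J[s, t]
            for f, (s, d) in enumerate(af):
                A[d, t + 1] += phiA[s, t] * psiA_f[f, t] * A[s, t]
        J[:, t + 1] = gamma[:, t + 1] * A[:, t + 1]
    return J + A


def project_scenarios(draws, scenario: str, init=None, horizon=None,
                      max_draws: int = 500,
                      annual_rates: bool = True) -> ProjectionResult:
    """Project subpopulation trajectories under a movement scenario.

    Scenarios: ``emigration_only`` (outflow retained, inflow zeroed),
    ``immigration_only`` (inflow retained, no emigration losses),
    ``no_movement`` and ``both``.  Rates are the year-specific draws
    (``annual_rates=False`` replaces them with their among-year means).
    Initial states default to each draw's estimated year-1 state.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    ra, la = _as_arrays(draws)
    n = ra["gamma"].shape[0]
    use = np.linspace(0, n - 1, min(max_draws, n)).astype(int)
    T = ra["gamma"].shape[2] if horizon is None else horizon
    Ntot_est = la["Ntot"].astype(float)
    out = np.zeros((len(use), N_GROUPS, T))
    growth = np.zeros((len(use), N_GROUPS))
    rr = np.zeros((len(use), N_GROUPS))
    for k, d in enumerate(use):
        gamma = ra["gamma"][d][:, :T]
        phiJ, phiA = ra["phiJ"][d], ra["phiA"][d]
        psiJ_f, psiA_f = ra["psiJ"][d], ra["psiA"][d]
        fidJ, fidA = ra["fidJ"][d], ra["fidA"][d]
        if not annual_rates:
            def rep(x):
                return np.repeat(x.mean(axis=-1, keepdims=True), x.shape[-1],
                                 axis=-1)
            gamma, phiJ, phiA = rep(gamma), rep(phiJ), rep(phiA)
            psiJ_f, psiA_f, fidJ, fidA = (rep(x) for x in
                                          (psiJ_f, psiA_f, fidJ, fidA))
        if init is None:
            J0 = la["J"][d, :, 0].astype(float)
            A0 = la["A"][d, :, 0].astype(float)
        else:
            J0, A0 = (np.asarray(v, dtype=float) for v in init)
        traj = _project_one(gamma, phiJ, phiA, psiJ_f, psiA_f, fidJ, fidA,
                            J0, A0, scenario)
        out[k] = traj
        growth[k] = (traj[:, -1] / np.maximum(traj[:, 0], 1e-12)) \
            ** (1.0 / (T - 1))
        for i in range(N_GROUPS):
            est = Ntot_est[d, i, :T]
            if traj[i].std() == 0 or est.std() == 0:
                rr[k, i] = 0.0
            else:
                rr[k, i] = np.corrcoef(traj[i], est)[0, 1]
    pr_pos = (rr > 0).mean(axis=0)
    return ProjectionResult(scenario, out, growth, rr, pr_pos)
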