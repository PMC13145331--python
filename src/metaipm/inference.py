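"""Posterior inference: adaptive MCMC, convergence diagnostics, posterior
predictive checks and summaries.

The sampler is an adaptive Metropolis-within-Gibbs: scalar random walks on
unconstrained transforms of the hyperparameters (Robbins–Monro tuned to 0.44
acceptance; small vector blocks for the year effects of rates that enter the
m-array globally, tuned to 0.23) and symmetric discrete random walks for the
integer latent states.  Any correct MCMC targeting the joint posterior is
acceptable; correctness is established against conjugate closed forms and
simulation-based recovery rather than by matching a particular sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from . import _kernels as K
from ._layout import NFA, NFJ, HyperLayout
from .model import (
    A1_SUPPORT, E_INDEX, GROUP_LABELS, N_FOCAL, N_GROUPS,
    DemographicRates, MArray, ObservedData,
    adult_flows, juvenile_flows, log_prior,
)

__all__ = [
    "MCMCConfig", "PosteriorDraws", "PPCResult",
    "fit_mcmc", "adaptive_metropolis",
    "gelman_rubin", "posterior_predictive_check", "summarize",
]


@dataclass
class MCMCConfig:
    """Sampler schedule.  The full-study schedule (3 × 270,000 iterations,
    10,000 burn-in, thin 10 → 78,000 retained draws) is config-selectable;
    the default is a desk-scale schedule for simulation work."""

    n_chains: int = 3
    n_iter: int = 3000
    n_burn: int = 1000
    thin: int = 4
    seed: int = 0
    latent_mode: str = "discrete"
    target_accept: float = 0.44

    def __post_init__(self):
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.latent_mode not in ("discrete", "continuous-relaxation"):
            raise ValueError(f"unknown latent_mode {self.latent_mode!r}")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    @property
    def total_retained(self) -> int:
        return self.n_chains * self.retained_per_chain

    @classmethod
    def full_study(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_chains=3, n_iter=270_000, n_burn=10_000, thin=10, seed=seed)


def _flow_structs():
    """CSR-style flow index arrays shared by the kernels."""
    fj = juvenile_flows()
    fa = adult_flows()
    flowJ_s = np.array([s for s, _ in fj], dtype=np.int64)
    flowJ_d = np.array([d for _, d in fj], dtype=np.int64)
    flowA_s = np.array([s for s, _ in fa], dtype=np.int64)
    flowA_d = np.array([d for _, d in fa], dtype=np.int64)

    def by(key, ss, dd):
        ptr = np.zeros(N_GROUPS + 1, dtype=np.int64)
        idx, other = [], []
        for g in range(N_GROUPS):
            for f in range(len(ss)):
                if (ss[f] if key == "out" else dd[f]) == g:
                    idx.append(f)
                    other.append(dd[f] if key == "out" else ss[f])
            ptr[g + 1] = len(idx)
        return ptr, np.array(idx, dtype=np.int64), np.array(other, dtype=np.int64)

    outJ_ptr, outJ_f, outJ_d = by("out", flowJ_s, flowJ_d)
    outA_ptr, outA_f, outA_d = by("out", flowA_s, flowA_d)
    inJ_ptr, inJ_f, inJ_s = by("in", flowJ_s, flowJ_d)
    inA_ptr, inA_f, inA_s = by("in", flowA_s, flowA_d)
    return dict(flowJ_s=flowJ_s, flowJ_d=flowJ_d, flowA_s=flowA_s,
                flowA_d=flowA_d, outJ_ptr=outJ_ptr, outJ_f=outJ_f,
                outJ_d=outJ_d, outA_ptr=outA_ptr, outA_f=outA_f,
                outA_d=outA_d, inJ_ptr=inJ_ptr, inJ_f=inJ_f, inJ_s=inJ_s,
                inA_ptr=inA_ptr, inA_f=inA_f, inA_s=inA_s)


def _marray_csr(marray: MArray):
    counts = marray.counts
    body = counts[:, :-1]
    row_ptr = [0]
    nz_cell, nz_cnt = [], []
    for r in range(body.shape[0]):
        cells = np.nonzero(body[r])[0]
        nz_cell.extend(cells.tolist())
        nz_cnt.extend(body[r, cells].tolist())
        row_ptr.append(len(nz_cell))
    return (np.array(row_ptr, dtype=np.int64),
            np.array(nz_cell, dtype=np.int64),
            np.array(nz_cnt, dtype=np.float64),
            counts[:, -1].astype(np.float64),
            counts.sum(axis=1).astype(np.int64))


@dataclass
class PosteriorDraws:
    """Retained draws: transformed hyper vectors plus latent integer states.

    ``hv`` is (chains × draws × n_hyper) on the sampling scale; ``lat`` is
    (chains × draws × 4 stages [J, N1, Nad, I] × groups × years).  All rate
    trajectories are deterministic transforms of ``hv`` and are rebuilt on
    demand.
    """

    hv: np.ndarray
    lat: np.ndarray
    layout: HyperLayout
    covs: object
    config: MCMCConfig
    chain_seeds: tuple

    @property
    def n_chains(self) -> int:
        return self.hv.shape[0]

    @property
    def n_draws(self) -> int:
        return self.hv.shape[0] * self.hv.shape[1]

    def flat_hv(self) -> np.ndarray:
        return self.hv.reshape(-1, self.hv.shape[-1])

    def flat_lat(self) -> np.ndarray:
        return self.lat.reshape(-1, *self.lat.shape[2:])

    # -- named scalar parameters -------------------------------------------
    def scalars(self) -> dict:
        """Interpretable scalar parameters as (chains × draws) arrays."""
        lo = self.layout
        hv = self.hv
        expit = special.expit
        out = {}
        for i, gl in enumerate(GROUP_LABELS):
            out[f"alpha_gamma[{gl}]"] = expit(hv[..., lo.sl("a_gam").start + i])
            out[f"alpha_phiA[{gl}]"] = expit(hv[..., lo.sl("a_phiA").start + i])
            out[f"alpha_p[{gl}]"] = expit(hv[..., lo.sl("a_p").start + i])
            out[f"beta_storm_A[{gl}]"] = hv[..., lo.sl("b6").start + i]
            for k in range(4):
                out[f"beta_fec{k + 1}[{gl}]"] = hv[..., lo.sl("b_fec").start + 4 * i + k]
            for h in (1, 2):
                out[f"hunt_A{h}[{gl}]"] = hv[..., lo.sl("hunt2").start + 2 * i + h - 1]
        for g in range(N_FOCAL):
            gl = GROUP_LABELS[g]
            out[f"alpha_phiJ[{gl}]"] = expit(hv[..., lo.sl("a_phiJ").start + g])
            out[f"beta_storm_J[{gl}]"] = hv[..., lo.sl("b5").start + g]
            for h in (1, 2):
                out[f"hunt_J{h}[{gl}]"] = hv[..., lo.sl("hunt1").start + 2 * g + h - 1]
        for f, (s, d) in enumerate(juvenile_flows()):
            out[f"alpha_psiJ[{GROUP_LABELS[s]}->{GROUP_LABELS[d]}]"] = \
                K.PSI_CAP * expit(hv[..., lo.sl("a_psiJ").start + f])
        for f, (s, d) in enumerate(adult_flows()):
            out[f"alpha_psiA[{GROUP_LABELS[s]}->{GROUP_LABELS[d]}]"] = \
                K.PSI_CAP * expit(hv[..., lo.sl("a_psiA").start + f])
        out["sigma_gamma"] = 10 * expit(hv[..., lo.sl("s_gam").start])
        out["sigma_phiJ"] = 10 * expit(hv[..., lo.sl("s_phiJ").start])
        out["sigma_phiA"] = 10 * expit(hv[..., lo.sl("s_phiA").start])
        out["sigma_psi"] = expit(hv[..., lo.sl("s_psi").start])
        out["sigma_p"] = 10 * expit(hv[..., lo.sl("s_p").start])
        out["tau_y"] = np.exp(hv[..., lo.sl("ltau").start])
        return out

    # -- rate trajectories --------------------------------------------------
    def rate_arrays(self) -> dict:
        """Vectorized rate trajectories across all (flattened) draws.

        Returns gamma (n, G, T); phiJ, phiA (n, G, Ti); psiJ, psiA as flow
        arrays (n, F, Ti); fidJ, fidA (n, G, Ti); p (n, G, T).
        """
        lo = self.layout
        T = lo.T
        Ti = T - 1
        hv = self.flat_hv()
        n = hv.shape[0]
        expit = special.expit
        X = self.covs.fecundity_design()
        storms = self.covs.storms
        hlev = self.covs.hunt_level

        la = np.log(expit(hv[:, lo.sl("a_gam")]))            # (n, G)
        bf = hv[:, lo.sl("b_fec")].reshape(n, N_GROUPS, 4)
        eg = hv[:, lo.sl("eps_gam")].reshape(n, N_GROUPS, T)
        gamma = np.exp(la[:, :, None] + np.einsum("ngk,kgt->ngt", bf, X) + eg)

        hunt1 = hv[:, lo.sl("hunt1")].reshape(n, N_FOCAL, 2)
        hunt2 = hv[:, lo.sl("hunt2")].reshape(n, N_GROUPS, 2)
        hsel = hlev[:Ti]
        h1 = np.zeros((n, N_FOCAL, Ti))
        h2 = np.zeros((n, N_GROUPS, Ti))
        for lev in (1, 2):
            mask = hsel == lev
            h1[:, :, mask] = hunt1[:, :, lev - 1][:, :, None]
            h2[:, :, mask] = hunt2[:, :, lev - 1][:, :, None]
        lpJ = (hv[:, lo.sl("a_phiJ")][:, :, None]
               + hv[:, lo.sl("b5")][:, :, None] * storms[None, :N_FOCAL, :Ti]
               + h1 + hv[:, lo.sl("eps_phiJ")].reshape(n, N_FOCAL, Ti))
        phiJ = np.empty((n, N_GROUPS, Ti))
        phiJ[:, :N_FOCAL] = expit(lpJ)
        phiJ[:, E_INDEX] = expit(lpJ.mean(axis=1))
        lpA = (hv[:, lo.sl("a_phiA")][:, :, None]
               + hv[:, lo.sl("b6")][:, :, None] * storms[None, :, :Ti]
               + h2 + hv[:, lo.sl("eps_phiA")].reshape(n, N_GROUPS, Ti))
        phiA = expit(lpA)

        def psi_flows(aname, ename, F):
            alpha = K.PSI_CAP * expit(hv[:, lo.sl(aname)])
            la = special.logit(alpha)
            eps = hv[:, lo.sl(ename)].reshape(n, F, Ti)
            return expit(la[:, :, None] + eps)

        psiJ = psi_flows("a_psiJ", "eps_psiJ", NFJ)
        psiA = psi_flows("a_psiA", "eps_psiA", NFA)
        fidJ = np.ones((n, N_GROUPS, Ti))
        fidA = np.ones((n, N_GROUPS, Ti))
        for f, (s, d) in enumerate(juvenile_flows()):
            fidJ[:, s] -= psiJ[:, f]
        for f, (s, d) in enumerate(adult_flows()):
            fidA[:, s] -= psiA[:, f]
        p = expit(hv[:, lo.sl("a_p")][:, :, None]
                  + hv[:, lo.sl("eps_p")].reshape(n, N_GROUPS, T))
        return dict(gamma=gamma, phiJ=phiJ, phiA=phiA, psiJ=psiJ, psiA=psiA,
                    fidJ=fidJ, fidA=fidA, p=p)

    def rates_for(self, flat_index: int) -> DemographicRates:
        """DemographicRates object for one flattened draw (test/diagnostics)."""
        ra = self.rate_arrays()
        T = self.layout.T
        psiJ = np.zeros((N_GROUPS, N_GROUPS, T - 1))
        psiA = np.zeros((N_GROUPS, N_GROUPS, T - 1))
        for f, (s, d) in enumerate(juvenile_flows()):
            psiJ[s, d] = ra["psiJ"][flat_index, f]
        for f, (s, d) in enumerate(adult_flows()):
            psiA[s, d] = ra["psiA"][flat_index, f]
        return DemographicRates(ra["gamma"][flat_index], ra["phiJ"][flat_index],
                                ra["phiA"][flat_index], psiJ, psiA,
                                ra["p"][flat_index])

    def latent_arrays(self) -> dict:
        """J, N1, Nad, I, A, Ntot as (draws × G × T) arrays.

        Year-1 adults are carried in the I slot (N1 and Nad are structurally
        zero in year 1), so A = N1 + Nad + I holds in every year; I[:, :, 0]
        must not be read as immigrants.
        """
        lat = self.flat_lat()
        J, N1, Nad, I = lat[:, 0], lat[:, 1], lat[:, 2], lat[:, 3]
        A = N1 + Nad + I
        return dict(J=J, N1=N1, Nad=Nad, I=I, A=A, Ntot=J + A)


def _init_latents(data: ObservedData, rng: np.random.Generator):
    """Data-driven starting latent states satisfying every hard constraint."""
    y = data.y.copy()
    Jobs = data.Jobs.copy()
    G, T = y.shape
    # fill unobserved cells by within-site interpolation
    idx = np.arange(T)
    for arr in (y, Jobs):
        for i in range(G):
            obs = ~np.isnan(arr[i])
            if not obs.any():
                arr[i] = 100.0
            else:
                arr[i] = np.interp(idx, idx[obs], arr[i, obs])
    J = np.maximum(np.round(Jobs), 0).astype(np.int64)
    Ntot = np.maximum(np.round(y), J + 1).astype(np.int64)
    A = np.maximum(Ntot - J, 1)
    A1 = A[:, 0].copy()
    for i, (lo, hi) in enumerate(A1_SUPPORT):
        A1[i] = min(max(A1[i], lo), hi)
    A[:, 0] = A1
    N1 = np.zeros((G, T), dtype=np.int64)
    Nad = np.zeros((G, T), dtype=np.int64)
    I = np.zeros((G, T), dtype=np.int64)
    for t in range(1, T):
        tgt = A[:, t]
        Nad[:, t] = np.minimum((0.85 * A[:, t - 1]).astype(np.int64), tgt)
        rem = tgt - Nad[:, t]
        N1[:, t] = np.minimum(np.minimum((0.6 * J[:, t - 1]).astype(np.int64),
                                         rem), J[:, t - 1])
        I[:, t] = tgt - Nad[:, t] - N1[:, t]
    return J, N1, Nad, I, A, A1


def _init_hv(data: ObservedData, layout: HyperLayout,
             rng: np.random.Generator) -> np.ndarray:
    """Heuristic overdispersed starting point on the sampling scale."""
    logit = special.logit
    lo = layout
    hv = np.zeros(layout.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.nanmean(data.Jobs / np.maximum(data.y - data.Jobs, 1.0), axis=1)
    ratio = np.where(np.isfinite(ratio), ratio, 0.12)
    ag = np.clip(ratio, 0.03, 0.5)
    hv[lo.sl("a_gam")] = logit(ag) + 0.2 * rng.normal(size=N_GROUPS)
    hv[lo.sl("s_gam")] = logit(0.03)
    hv[lo.sl("a_phiJ")] = logit(0.75) + 0.2 * rng.normal(size=N_FOCAL)
    hv[lo.sl("s_phiJ")] = logit(0.02)
    hv[lo.sl("a_phiA")] = logit(0.85) + 0.2 * rng.normal(size=N_GROUPS)
    hv[lo.sl("s_phiA")] = logit(0.02)
    hv[lo.sl("l_b5")] = hv[lo.sl("l_b6")] = math.log(2.0)
    hv[lo.sl("l_h1")] = hv[lo.sl("l_h2")] = math.log(2.0)
    hv[lo.sl("a_psiJ")] = logit(0.02 / K.PSI_CAP) + 0.2 * rng.normal(size=NFJ)
    hv[lo.sl("a_psiA")] = logit(0.02 / K.PSI_CAP) + 0.2 * rng.normal(size=NFA)
    hv[lo.sl("s_psi")] = logit(0.3)
    ap = np.array([0.8, 0.8, 0.8, 0.3])
    hv[lo.sl("a_p")] = logit(ap) + 0.2 * rng.normal(size=N_GROUPS)
    hv[lo.sl("s_p")] = logit(0.03)
    hv[lo.sl("ltau")] = math.log(0.01)
    # non-degenerate year effects so the scale parameters start off the
    # funnel's neck
    for name in ("eps_gam", "eps_phiJ", "eps_phiA", "eps_psiJ", "eps_psiA",
                 "eps_p"):
        sl = lo.sl(name)
        hv[sl] = 0.1 * rng.normal(size=sl.stop - sl.start)
    return hv


def fit_mcmc(data, spec=None, config: MCMCConfig | None = None) -> PosteriorDraws:
    """Fit the joint posterior by MCMC.

    ``data`` is an :class:`ObservedData` for the metapopulation model, or any
    object exposing ``log_posterior(x)``/``initial(rng)``/``dim`` for generic
    problems (sampled with :func:`adaptive_metropolis`; used for closed-form
    validation).  ``spec`` is reserved for model-structure overrides.
    """
    config = config or MCMCConfig()
    if config.latent_mode != "discrete":
        raise NotImplementedError(
            "only the discrete latent-state sampler is implemented")
    if not isinstance(data, ObservedData):
        return _fit_generic(data, config)

    layout = HyperLayout(data.n_years)
    flows = _flow_structs()
    row_ptr, nz_cell, nz_cnt, nev_cnt, row_tot = _marray_csr(data.marray)
    G, T = N_GROUPS, data.n_years
    Ti = T - 1
    X = np.ascontiguousarray(data.covs.fecundity_design())
    storms = np.ascontiguousarray(data.covs.storms)
    hlev = data.covs.hunt_level.astype(np.int64)
    yobs = data.y.astype(np.float64)
    jobs = data.Jobs.astype(np.float64)
    A1_lo = np.array([s[0] for s in A1_SUPPORT], dtype=np.int64)
    A1_hi = np.array([s[1] for s in A1_SUPPORT], dtype=np.int64)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = tuple(int(s) for s in ss.generate_state(config.n_chains))
    n_keep = config.retained_per_chain
    out_hv = np.zeros((config.n_chains, n_keep, layout.size))
    out_lat = np.zeros((config.n_chains, n_keep, 4, G, T), dtype=np.int64)

    R = data.marray.counts.shape[0]
    for c, cseed in enumerate(chain_seeds):
        rng = np.random.default_rng(cseed)
        # find a finite start
        for attempt in range(1000):
            hv = _init_hv(data, layout, rng)
            J, N1, Nad, I, A, A1 = _init_latents(data, rng)
            gamma = np.zeros((G, T))
            lpJ = np.zeros((N_FOCAL, Ti))
            phiJ = np.zeros((G, Ti))
            phiA = np.zeros((G, Ti))
            psiJ = np.zeros((NFJ, Ti))
            psiA = np.zeros((NFA, Ti))
            fidJ = np.ones((G, Ti))
            fidA = np.ones((G, Ti))
            pdet = np.zeros((G, T))
            MA = np.zeros((Ti, G, G))
            ok = K.rebuild_all_rates(
                hv, layout.offsets, X, storms, hlev, gamma, lpJ, phiJ, phiA,
                psiJ, psiA, fidJ, fidA, pdet, MA,
                flows["outJ_ptr"], flows["outJ_f"],
                flows["outA_ptr"], flows["outA_f"], flows["outA_d"])
            if not ok:
                continue
            rowll = np.zeros(R)
            comp = K.total_components(
                J, N1, Nad, I, A, gamma, phiJ, phiA, psiJ, psiA,
                fidJ, fidA, pdet, MA, yobs, jobs, math.exp(hv[layout.sl("ltau").start]),
                flows["inJ_ptr"], flows["inJ_f"], flows["inJ_s"],
                flows["inA_ptr"], flows["inA_f"], flows["inA_s"],
                flows["outJ_ptr"], flows["outJ_f"], flows["outJ_d"],
                row_ptr, nz_cell, nz_cnt, nev_cnt, row_tot, rowll)
            lp = log_prior(layout.unpack(hv), A1)
            if np.isfinite(sum(comp)) and np.isfinite(lp):
                break
        else:
            raise RuntimeError(
                f"no finite starting point found for chain {c}: "
                f"components={comp}, prior={lp}")

        ls = np.full(layout.size, math.log(0.1))
        ls[layout.sl("eps_gam")] = math.log(0.3)
        ls[layout.sl("eps_phiJ")] = math.log(0.3)
        ls[layout.sl("eps_psiJ")] = math.log(0.3)
        ls_blk = np.full(20, math.log(0.05))
        ls_lat = np.zeros(4 * G * T)
        for stg, arr in enumerate((J, N1, Nad, I)):
            ls_lat[stg * G * T:(stg + 1) * G * T] = np.log(
                1.0 + 0.15 * np.sqrt(np.maximum(arr, 1)).ravel())
        ls_A1 = np.full(G, math.log(30.0))
        ls_shift = np.full(36, math.log(0.2))
        ls_ex = np.concatenate([
            np.log(1.0 + 0.15 * np.sqrt(np.maximum(J, 1)).ravel()),
            np.log(1.0 + 0.15 * np.sqrt(np.maximum(Nad, 1)).ravel())])
        rowll_new = np.zeros(R)

        K.run_chain(cseed % (2 ** 31), config.n_iter, config.n_burn, config.thin,
                    hv, layout.offsets,
                    J, N1, Nad, I, A, A1,
                    gamma, lpJ, phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                    X, storms, hlev, yobs, jobs,
                    row_ptr, nz_cell, nz_cnt, nev_cnt, row_tot, rowll, rowll_new,
                    flows["outJ_ptr"], flows["outJ_f"], flows["outJ_d"],
                    flows["outA_ptr"], flows["outA_f"], flows["outA_d"],
                    flows["inJ_ptr"], flows["inJ_f"], flows["inJ_s"],
                    flows["inA_ptr"], flows["inA_f"], flows["inA_s"],
                    flows["flowJ_s"], flows["flowJ_d"],
                    flows["flowA_s"], flows["flowA_d"],
                    A1_lo, A1_hi,
                    ls, ls_blk, ls_lat, ls_A1, ls_shift, ls_ex,
                    out_hv[c], out_lat[c])

    return PosteriorDraws(out_hv, out_lat, layout, data.covs, config, chain_seeds)


# ---------------------------------------------------------------------------
# generic adaptive Metropolis (used for closed-form validation problems)
# ---------------------------------------------------------------------------

@dataclass
class GenericDraws:
    x: np.ndarray          # (chains, draws, dim)
    config: MCMCConfig

    def flat(self) -> np.ndarray:
        return self.x.reshape(-1, self.x.shape[-1])


def adaptive_metropolis(log_post, x0, n_iter: int, n_burn: int, thin: int,
                        seed: int, target: float = 0.44) -> np.ndarray:
    """Scalar-wise adaptive random-walk Metropolis on a generic target.

    Robbins–Monro adaptation of per-coordinate step sizes toward ``target``
    acceptance, diminishing with iteration.  Returns retained draws
    ((n_iter − n_burn)//thin × dim).
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float)
    d = x.size
    ls = np.full(d, math.log(0.5))
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("log posterior not finite at x0")
    keep = np.empty(((n_iter - n_burn) // thin, d))
    k = 0
    for it in range(n_iter):
        gain = (20.0 + it) ** -0.6
        for j in range(d):
            prop = x.copy()
            prop[j] += math.exp(ls[j]) * rng.normal()
            lpn = log_post(prop)
            acc = 0.0
            if math.log(rng.random()) < lpn - lp:
                x, lp = prop, lpn
                acc = 1.0
            ls[j] = min(max(ls[j] + gain * (acc - target), -12.0), 5.0)
        if it >= n_burn and (it - n_burn) % thin == 0 and k < keep.shape[0]:
            keep[k] = x
            k += 1
    return keep


def _fit_generic(model, config: MCMCConfig) -> GenericDraws:
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_chains)
    out = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(int(seeds[c]))
        x0 = model.initial(rng)
        out.append(adaptive_metropolis(model.log_posterior, x0, config.n_iter,
                                       config.n_burn, config.thin,
                                       int(seeds[c]) % (2 ** 31),
                                       config.target_accept))
    return GenericDraws(np.stack(out), config)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _psrf(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman–Rubin R-hat)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n:2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def gelman_rubin(draws, threshold: float = 1.1) -> pd.DataFrame:
    """R-hat per parameter with a convergence flag at the given threshold.

    Accepts a :class:`PosteriorDraws` (monitors the interpretable scalar
    parameters), a dict of (chains × draws) arrays, or a single such array.
    """
    if isinstance(draws, PosteriorDraws):
        series = draws.scalars()
    elif isinstance(draws, GenericDraws):
        series = {f"x{j}": draws.x[:, :, j] for j in range(draws.x.shape[-1])}
    elif isinstance(draws, dict):
        series = draws
    else:
        series = {"x": np.asarray(draws)}
    rows = []
    for name, arr in series.items():
        r = _psrf(np.asarray(arr))
        rows.append((name, r, r >= threshold))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "flagged"]) \
        .set_index("parameter")


def summarize(draws, levels=(0.9,)) -> pd.DataFrame:
    """Posterior medians with equal-tailed credible intervals."""
    if isinstance(draws, PosteriorDraws):
        series = {k: v.ravel() for k, v in draws.scalars().items()}
    elif isinstance(draws, GenericDraws):
        flat = draws.flat()
        series = {f"x{j}": flat[:, j] for j in range(flat.shape[1])}
    elif isinstance(draws, dict):
        series = {k: np.ravel(v) for k, v in draws.items()}
    else:
        arr = np.asarray(draws)
        if arr.size == 0:
            raise ValueError("empty draws")
        series = {"x": arr.ravel()}
    if any(v.size == 0 for v in series.values()) or not series:
        raise ValueError("empty draws")
    rows = {}
    for name, v in series.items():
        row = {"median": float(np.median(v))}
        for lev in levels:
            a = (1 - lev) / 2
            row[f"lo{int(lev * 100)}"] = float(np.quantile(v, a))
            row[f"hi{int(lev * 100)}"] = float(np.quantile(v, 1 - a))
        rows[name] = row
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

PPC_STATISTICS = ("freeman_tukey_counts", "freeman_tukey_juveniles",
                  "marray_chisq_by_group")


@dataclass
class PPCResult:
    statistic: str
    observed: np.ndarray       # (draws_used, n_series)
    replicated: np.ndarray
    p_values: np.ndarray       # per series (group)
    p_value: float             # combined over series

    def __post_init__(self):
        assert np.all((self.p_values >= 0) & (self.p_values <= 1))


def posterior_predictive_check(draws: PosteriorDraws, data: ObservedData,
                               statistic: str, max_draws: int = 300,
                               seed: int = 0) -> PPCResult:
    """Replicate the data under each retained draw and compare discrepancies.

    ``freeman_tukey_*`` use D = Σ (√obs − √E)² per group; the m-array check
    uses Pearson chi-square over cells grouped by release group.  The
    Bayesian p-value is the fraction of draws whose replicated discrepancy
    is at least the observed one.
    """
    if statistic not in PPC_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; "
                         f"choose from {PPC_STATISTICS}")
    rng = np.random.default_rng(seed)
    n_all = draws.n_draws
    use = np.linspace(0, n_all - 1, min(max_draws, n_all)).astype(int)
    lat = draws.flat_lat()[use]
    hv = draws.flat_hv()[use]
    lo = draws.layout
    T = lo.T

    if statistic == "freeman_tukey_counts":
        tau = np.exp(hv[:, lo.sl("ltau").start])
        J = lat[:, 0]
        A = lat[:, 1] + lat[:, 2] + lat[:, 3]
        Ntot = (J + A).astype(float)                      # (n, G, T)
        mask = ~np.isnan(data.y)
        obs = np.zeros((len(use), N_GROUPS))
        rep = np.zeros((len(use), N_GROUPS))
        for k in range(len(use)):
            yrep = np.exp(rng.normal(np.log(np.maximum(Ntot[k], 1)),
                                     math.sqrt(tau[k])))
            for i in range(N_GROUPS):
                m = mask[i]
                obs[k, i] = np.sum((np.sqrt(data.y[i, m])
                                    - np.sqrt(Ntot[k, i, m])) ** 2)
                rep[k, i] = np.sum((np.sqrt(yrep[i, m])
                                    - np.sqrt(Ntot[k, i, m])) ** 2)
    elif statistic == "freeman_tukey_juveniles":
        J = lat[:, 0].astype(float)
        mask = ~np.isnan(data.Jobs)
        obs = np.zeros((len(use), N_GROUPS))
        rep = np.zeros((len(use), N_GROUPS))
        for k in range(len(use)):
            jrep = rng.poisson(J[k])
            for i in range(N_GROUPS):
                m = mask[i]
                obs[k, i] = np.sum((np.sqrt(data.Jobs[i, m])
                                    - np.sqrt(J[k, i, m])) ** 2)
                rep[k, i] = np.sum((np.sqrt(jrep[i, m])
                                    - np.sqrt(J[k, i, m])) ** 2)
    else:
        obs, rep = _ppc_marray(draws, data, use, rng)

    p = (rep >= obs).mean(axis=0)
    p_comb = float((rep.sum(axis=1) >= obs.sum(axis=1)).mean())
    return PPCResult(statistic, obs, rep, p, p_comb)


def _ppc_marray(draws: PosteriorDraws, data: ObservedData, use, rng):
    lo = draws.layout
    T = lo.T
    Ti = T - 1
    flows = _flow_structs()
    ra_all = draws.rate_arrays()
    counts = data.marray.counts
    R, C = counts.shape
    row_tot = counts.sum(axis=1)
    # release-group label per row (m-array rows: juvenile then adult blocks)
    row_group = np.array([g for g in range(N_FOCAL) for _ in range(Ti)]
                         + [g for g in range(N_GROUPS) for _ in range(Ti)])
    obs = np.zeros((len(use), N_GROUPS))
    rep = np.zeros((len(use), N_GROUPS))
    probs = np.zeros((R, C))
    for k, u in enumerate(use):
        phiJ = ra_all["phiJ"][u]
        phiA = ra_all["phiA"][u]
        psiJ = ra_all["psiJ"][u]
        psiA = ra_all["psiA"][u]
        fidJ = ra_all["fidJ"][u]
        fidA = ra_all["fidA"][u]
        p = ra_all["p"][u]
        MA = np.zeros((Ti, N_GROUPS, N_GROUPS))
        for s in range(N_GROUPS):
            K.upd_MA_row(phiA, psiA, fidA, MA, flows["outA_ptr"],
                         flows["outA_f"], flows["outA_d"], s)
        K.marray_probs_full(phiJ, phiA, psiJ, psiA, fidJ, fidA, p, MA,
                            flows["outJ_ptr"], flows["outJ_f"],
                            flows["outJ_d"], T, probs)
        for r in range(R):
            n_rel = row_tot[r]
            if n_rel == 0:
                continue
            pr = np.maximum(probs[r], 0)
            pr = pr / pr.sum()
            exp_cnt = n_rel * pr
            m_rep = rng.multinomial(n_rel, pr)
            keep = exp_cnt > 1e-9
            g = row_group[r]
            obs[k, g] += np.sum((counts[r, keep] - exp_cnt[keep]) ** 2
                                / exp_cnt[keep])
            rep[k, g] += np.sum((m_rep[keep] - exp_cnt[keep]) ** 2
                                / exp_cnt[keep])
    return obs, rep


# ---------------------------------------------------------------------------
# conjugate validation model and persistence
# ---------------------------------------------------------------------------

@dataclass
class GammaPoissonModel:
    """Poisson counts with a Gamma(a, b) prior on the rate.

    The posterior is Gamma(a + Σy, b + n) in closed form, which makes this a
    sharp end-to-end check of the Metropolis machinery: the sampled
    posterior mean must match (a + Σy)/(b + n) to Monte-Carlo error.
    """

    y: np.ndarray
    a: float = 2.0
    b: float = 1.0
    dim: int = 1

    def log_posterior(self, x) -> float:
        lam = x[0]
        if lam <= 0:
            return -np.inf
        n = self.y.size
        return ((self.a - 1) * math.log(lam) - self.b * lam
                + self.y.sum() * math.log(lam) - n * lam)

    def initial(self, rng) -> np.ndarray:
        return np.array([rng.gamma(self.a, 1.0 / self.b)])

    @property
    def posterior_mean(self) -> float:
        return (self.a + self.y.sum()) / (self.b + self.y.size)

    @property
    def posterior_var(self) -> float:
        return (self.a + self.y.sum()) / (self.b + self.y.size) ** 2


def save_draws(draws: PosteriorDraws, path):
    """Persist draws plus everything needed to rebuild rate trajectories."""
    import hashlib
    import json

    cfg = draws.config
    cfg_json = json.dumps({k: getattr(cfg, k) for k in
                           ("n_chains", "n_iter", "n_burn", "thin", "seed",
                            "latent_mode")}, sort_keys=True)
    np.savez_compressed(
        path, hv=draws.hv, lat=draws.lat, T=draws.layout.T,
        gdd_winter=draws.covs.gdd_winter, gdd_stage=draws.covs.gdd_stage,
        gdd_breed=draws.covs.gdd_breed, snow_breed=draws.covs.snow_breed,
        storms=draws.covs.storms, hunt_level=draws.covs.hunt_level,
        years=draws.covs.years, chain_seeds=np.array(draws.chain_seeds),
        config_json=np.array(cfg_json),
        config_hash=np.array(hashlib.sha256(cfg_json.encode()).hexdigest()),
    )


def load_draws(path) -> PosteriorDraws:
    import json

    from .data_io import CovariateSet

    z = np.load(path, allow_pickle=False)
    cfg = MCMCConfig(**json.loads(str(z["config_json"])))
    covs = CovariateSet(z["gdd_winter"], z["gdd_stage"], z["gdd_breed"],
                        z["snow_breed"], z["storms"],
                        hunt_level=z["hunt_level"], years=z["years"])
    layout = HyperLayout(int(z["T"]))
    return PosteriorDraws(z["hv"], z["lat"], layout, covs, cfg,
                          tuple(int(s) for s in z["chain_seeds"]))
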