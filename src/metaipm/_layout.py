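"""Flat packing of the hyperparameter vector used by the MCMC kernels.

The sampler random-walks on unconstrained transforms: logit for (0,1)
intercepts, scaled logit for bounded standard deviations and the movement
means (bounded by the 0.2 prior cap), log for τ_y and the Laplace rates,
identity for regression/hunting effects and year effects.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .model import HyperParams, N_FOCAL, N_GROUPS, PSI_CAP

# field order; sizes depend on T only
_FIELDS = (
    "a_gam", "b_fec", "s_gam", "eps_gam",
    "a_phiJ", "b5", "hunt1", "eps_phiJ", "s_phiJ",
    "a_phiA", "b6", "hunt2", "eps_phiA", "s_phiA",
    "mu_b5", "l_b5", "mu_b6", "l_b6",
    "mu_h1", "l_h1", "mu_h2", "l_h2",
    "a_psiJ", "eps_psiJ", "a_psiA", "eps_psiA", "s_psi",
    "a_p", "eps_p", "s_p", "ltau",
)

# offsets array positions, importable by the kernels as constants
for _i, _name in enumerate(_FIELDS):
    globals()["F_" + _name.upper()] = _i
N_FIELDS = len(_FIELDS)

NFJ = 9    # juvenile flows (focal origins only)
NFA = 12   # adult flows


def field_sizes(T: int) -> dict:
    G, Gf, Ti = N_GROUPS, N_FOCAL, T - 1
    return {
        "a_gam": G, "b_fec": G * 4, "s_gam": 1, "eps_gam": G * T,
        "a_phiJ": Gf, "b5": Gf, "hunt1": Gf * 2, "eps_phiJ": Gf * Ti,
        "s_phiJ": 1,
        "a_phiA": G, "b6": G, "hunt2": G * 2, "eps_phiA": G * Ti, "s_phiA": 1,
        "mu_b5": 1, "l_b5": 1, "mu_b6": 1, "l_b6": 1,
        "mu_h1": 2, "l_h1": 2, "mu_h2": 2, "l_h2": 2,
        "a_psiJ": NFJ, "eps_psiJ": NFJ * Ti,
        "a_psiA": NFA, "eps_psiA": NFA * Ti, "s_psi": 1,
        "a_p": G, "eps_p": G * T, "s_p": 1, "ltau": 1,
    }


class HyperLayout:
    """Offsets of each field inside the flat transformed vector."""

    def __init__(self, T: int):
        self.T = T
        sizes = field_sizes(T)
        self.offsets = np.zeros(N_FIELDS + 1, dtype=np.int64)
        for i, name in enumerate(_FIELDS):
            self.offsets[i + 1] = self.offsets[i] + sizes[name]
        self.size = int(self.offsets[-1])

    def sl(self, name: str) -> slice:
        i = _FIELDS.index(name)
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))

    # -- transforms ---------------------------------------------------------
    def pack(self, h: HyperParams) -> np.ndarray:
        logit = special.logit
        hv = np.zeros(self.size)
        hv[self.sl("a_gam")] = logit(h.alpha_gamma)
        hv[self.sl("b_fec")] = h.beta_fec.ravel()
        hv[self.sl("s_gam")] = logit(h.sigma_gamma / 10.0)
        hv[self.sl("eps_gam")] = h.eps_gamma.ravel()
        hv[self.sl("a_phiJ")] = logit(h.alpha_phiJ)
        hv[self.sl("b5")] = h.beta_storm_J
        hv[self.sl("hunt1")] = h.hunt_J.ravel()
        hv[self.sl("eps_phiJ")] = h.eps_phiJ.ravel()
        hv[self.sl("s_phiJ")] = logit(h.sigma_phiJ / 10.0)
        hv[self.sl("a_phiA")] = logit(h.alpha_phiA)
        hv[self.sl("b6")] = h.beta_storm_A
        hv[self.sl("hunt2")] = h.hunt_A.ravel()
        hv[self.sl("eps_phiA")] = h.eps_phiA.ravel()
        hv[self.sl("s_phiA")] = logit(h.sigma_phiA / 10.0)
        hv[self.sl("mu_b5")] = h.mu_beta_J
        hv[self.sl("l_b5")] = np.log(h.lam_beta_J)
        hv[self.sl("mu_b6")] = h.mu_beta_A
        hv[self.sl("l_b6")] = np.log(h.lam_beta_A)
        hv[self.sl("mu_h1")] = h.mu_hunt_J
        hv[self.sl("l_h1")] = np.log(h.lam_hunt_J)
        hv[self.sl("mu_h2")] = h.mu_hunt_A
        hv[self.sl("l_h2")] = np.log(h.lam_hunt_A)
        hv[self.sl("a_psiJ")] = logit(np.asarray(h.alpha_psiJ) / PSI_CAP)
        hv[self.sl("eps_psiJ")] = h.eps_psiJ.ravel()
        hv[self.sl("a_psiA")] = logit(np.asarray(h.alpha_psiA) / PSI_CAP)
        hv[self.sl("eps_psiA")] = h.eps_psiA.ravel()
        hv[self.sl("s_psi")] = logit(h.sigma_psi)
        hv[self.sl("a_p")] = logit(h.alpha_p)
        hv[self.sl("eps_p")] = h.eps_p.ravel()
        hv[self.sl("s_p")] = logit(h.sigma_p / 10.0)
        hv[self.sl("ltau")] = np.log(h.tau_y)
        return hv

    def unpack(self, hv: np.ndarray) -> HyperParams:
        T, Ti = self.T, self.T - 1
        G, Gf = N_GROUPS, N_FOCAL
        expit = special.expit

        def get(name, shape=None):
            v = hv[self.sl(name)]
            return v.reshape(shape) if shape else v

        return HyperParams(
            alpha_gamma=expit(get("a_gam")),
            beta_fec=get("b_fec", (G, 4)).copy(),
            sigma_gamma=float(10 * expit(get("s_gam")[0])),
            eps_gamma=get("eps_gam", (G, T)).copy(),
            alpha_phiJ=expit(get("a_phiJ")),
            beta_storm_J=get("b5").copy(),
            hunt_J=get("hunt1", (Gf, 2)).copy(),
            sigma_phiJ=float(10 * expit(get("s_phiJ")[0])),
            eps_phiJ=get("eps_phiJ", (Gf, Ti)).copy(),
            alpha_phiA=expit(get("a_phiA")),
            beta_storm_A=get("b6").copy(),
            hunt_A=get("hunt2", (G, 2)).copy(),
            sigma_phiA=float(10 * expit(get("s_phiA")[0])),
            eps_phiA=get("eps_phiA", (G, Ti)).copy(),
            mu_beta_J=float(get("mu_b5")[0]),
            lam_beta_J=float(np.exp(get("l_b5")[0])),
            mu_beta_A=float(get("mu_b6")[0]),
            lam_beta_A=float(np.exp(get("l_b6")[0])),
            mu_hunt_J=get("mu_h1").copy(),
            lam_hunt_J=np.exp(get("l_h1")),
            mu_hunt_A=get("mu_h2").copy(),
            lam_hunt_A=np.exp(get("l_h2")),
            alpha_psiJ=PSI_CAP * expit(get("a_psiJ")),
            eps_psiJ=get("eps_psiJ", (NFJ, Ti)).copy(),
            alpha_psiA=PSI_CAP * expit(get("a_psiA")),
            eps_psiA=get("eps_psiA", (NFA, Ti)).copy(),
            sigma_psi=float(expit(get("s_psi")[0])),
            alpha_p=expit(get("a_p")),
            sigma_p=float(10 * expit(get("s_p")[0])),
            eps_p=get("eps_p", (G, T)).copy(),
            tau_y=float(np.exp(get("ltau")[0])),
        )
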