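"""Independent oracles shared across test modules."""

import itertools

import numpy as np


def brute_force_cell_probs(rates, group, age, year):
    """Exhaustive enumeration over site trajectories, death times and
    detection patterns — independent of the recursive implementation."""
    G, T = rates.gamma.shape
    C = (T - 1) * G + 1
    out = np.zeros(C)
    if year >= T - 1:
        out[-1] = 1.0
        return out
    horizon = T - 1  # last occasion index
    for a in range(year, horizon + 1):        # last occasion alive
        n_moves = a - year
        for seq in itertools.product(range(G), repeat=n_moves):
            path = (group,) + seq
            pr = 1.0
            for step in range(n_moves):
                t = year + step
                juv = (age == "juv" and step == 0)
                phi = rates.phiJ[path[step], t] if juv else rates.phiA[path[step], t]
                psi = rates.psiJ[path[step], :, t] if juv else rates.psiA[path[step], :, t]
                stay = 1 - psi.sum()
                move = stay if path[step + 1] == path[step] else psi[path[step + 1]]
                pr *= phi * move
            if a < horizon:  # dies during interval a -> a+1
                juv = (age == "juv" and a == year)
                phi_next = rates.phiJ[path[-1], a] if juv else rates.phiA[path[-1], a]
                pr *= 1 - phi_next
            if pr == 0:
                continue
            # detection patterns on occasions year+1 .. a
            undet = 1.0
            for k in range(1, n_moves + 1):
                u = year + k
                j = path[k]
                out[(u - 1) * G + j] += pr * undet * rates.p[j, u]
                undet *= 1 - rates.p[j, u]
            out[-1] += pr * undet
    return out
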