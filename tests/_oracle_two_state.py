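"""Independent 4-state (u/m-only) reference model used as a reduction oracle.

When hydroxylation is switched off and the starting population carries no
5hmC, the dyad chain lives on {u,m}^2 and the full model must collapse to
this much smaller one.  Everything here — state space, transition matrices,
emission channels, likelihood and optimiser wrapper — is written directly
against the 4-state chain, sharing no code with the package implementation.
"""

import numpy as np
from scipy import optimize

S4 = ("uu", "um", "mu", "mm")
I4 = {s: i for i, s in enumerate(S4)}


def division4() -> np.ndarray:
    D = np.zeros((4, 4))
    for i, (up, lo) in enumerate(S4):
        D[i, I4[up + "u"]] += 0.5
        D[i, I4["u" + lo]] += 0.5
    return D


def methylation4(mu_m: float, mu_d: float) -> np.ndarray:
    lam = mu_m + (1 - mu_m) * mu_d
    M = np.eye(4)
    M[I4["uu"]] = [(1 - mu_d) ** 2, (1 - mu_d) * mu_d, mu_d * (1 - mu_d), mu_d**2]
    M[I4["um"], I4["um"]], M[I4["um"], I4["mm"]] = 1 - lam, lam
    M[I4["mu"], I4["mu"]], M[I4["mu"], I4["mm"]] = 1 - lam, lam
    return M


def emission4(c: float, d: float) -> np.ndarray:
    """4x4 hidden-to-read matrix; columns TT, TC, CT, CC."""
    pT = {"u": c, "m": 1 - d}
    E = np.empty((4, 4))
    for i, (up, lo) in enumerate(S4):
        E[i] = [pT[up] * pT[lo], pT[up] * (1 - pT[lo]),
                (1 - pT[up]) * pT[lo], (1 - pT[up]) * (1 - pT[lo])]
    return E


def nll4(theta, pi0_4, data) -> float:
    """-log L2 of the 4-state chain; theta = (mm0, mm1, md0, md1)."""
    mm0, mm1, md0, md1 = theta
    D = division4()
    pi = np.asarray(pi0_4, dtype=float)
    total, div = 0.0, 0
    for day in data.post_days:
        for k in range(div + 1, data.divisions(day) + 1):
            mu_m = min(max(mm0 + mm1 * k, 0.0), 1.0)
            mu_d = min(max(md0 + md1 * k, 0.0), 1.0)
            pi = pi @ (D @ methylation4(mu_m, mu_d))
        div = data.divisions(day)
        for tr in ("bs", "ox"):
            key = (day, tr)
            if key not in data.counts:
                continue
            prof = data.profiles[key]
            probs = np.clip(pi @ emission4(prof.c, prof.d), 1e-300, None)
            total -= data.counts[key] @ np.log(probs)
    return float(total)


def fit4(data, pi0_4, starts_4):
    """Multi-start SLSQP over (mm0, mm1, md0, md1) with endpoint box constraints."""
    t_max = data.divisions(data.post_days[-1])
    constraints = []
    for j in (0, 2):
        for t in {1, t_max}:
            r = np.zeros(4)
            r[j], r[j + 1] = 1.0, t
            constraints.append({"type": "ineq", "fun": (lambda x, r=r: r @ x)})
            constraints.append({"type": "ineq", "fun": (lambda x, r=r: 1.0 - r @ x)})
    bounds = [(-1.0, 2.0), (-1.0, 1.0)] * 2
    best = None
    for x0 in starts_4:
        res = optimize.minimize(lambda x: nll4(x, pi0_4, data), x0, method="SLSQP",
                                bounds=bounds, constraints=constraints,
                                options={"ftol": 1e-9, "maxiter": 500})
        if res.success and (best is None or res.fun < best[0]):
            best = (float(res.fun), res.x.copy())
    assert best is not None, "oracle optimisation failed on all starts"
    return best
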