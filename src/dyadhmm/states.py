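"""Hidden state space and transition matrices for a CpG dyad.

A CpG dyad is the palindromic pair of cytosines on the two strands of a
CpG site.  Each strand carries one of three marks: ``u`` (unmodified),
``m`` (5-methylcytosine) or ``h`` (5-hydroxymethylcytosine), so the dyad
lives in a 9-element state space.  Between two observation days the dyad
undergoes, in order, one semi-conservative DNA replication (matrix ``D``),
one round of maintenance / de novo methylation (``M``) and one round of
Tet-mediated hydroxylation (``H``); the per-division transition matrix is
the product ``P(t) = D @ M(t) @ H(t)``.

The canonical state order used for every vector and matrix index is

    uu, um, mu, uh, hu, mm, mh, hm, hh

(grouped by number of modified strands; first letter = upper strand).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

#: Canonical ordering of the 9 hidden dyad states.
STATES: tuple[str, ...] = ("uu", "um", "mu", "uh", "hu", "mm", "mh", "hm", "hh")

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

#: Upper- and lower-strand mark of each state, in canonical order.
UPPER_MARK: tuple[str, ...] = tuple(s[0] for s in STATES)
LOWER_MARK: tuple[str, ...] = tuple(s[1] for s in STATES)

#: Index permutation exchanging the two strands (um <-> mu, uh <-> hu, ...).
SWAP: np.ndarray = np.array([STATE_INDEX[s[1] + s[0]] for s in STATES])

#: States carrying at least one hydroxyl group.
H_STATES: tuple[int, ...] = tuple(i for i, s in enumerate(STATES) if "h" in s)

_ATOL = 1e-12


def swap_state(state: str) -> str:
    """Return the state with upper and lower strand exchanged."""
    return state[1] + state[0]


def validate_distribution(pi: np.ndarray) -> np.ndarray:
    """Check that ``pi`` is a probability vector over the 9 dyad states."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (9,):
        raise ValueError(f"hidden-state distribution must have shape (9,), got {pi.shape}")
    if np.any(pi < -_ATOL):
        raise ValueError("hidden-state distribution has negative entries")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError(f"hidden-state distribution sums to {pi.sum()!r}, not 1")
    return pi


def _check_prob(name: str, value: float) -> float:
    """Validate a probability, clamping numerical noise within 1e-9 of the box."""
    value = float(value)
    if not -1e-9 <= value <= 1.0 + 1e-9:
        raise ValueError(f"{name}={value} outside [0, 1]")
    return min(max(value, 0.0), 1.0)


@dataclass
class EfficiencyModel:
    """Linear-in-time enzymatic efficiency functions plus the 5hmC blocking term.

    Each per-division efficiency is linear in the division index ``t``
    (``f(t) = intercept + slope * t``):

    * ``mu_m(t)`` — maintenance methylation (Dnmt1/Uhrf1) on a hemimethylated
      dyad, applied immediately after replication;
    * ``mu_d(t)`` — de novo methylation (Dnmt3a/b), acting with the same
      efficiency on unmethylated and hemimethylated dyads;
    * ``eta(t)`` — hydroxylation (Tet) of a methylated cytosine;
    * ``p`` — constant probability that a dyad with 5hmC opposite an
      unmodified cytosine is *not* recognised by the maintenance machinery,
      leaving only de novo methylation available there.

    The total methylation probability on a hemimethylated site is
    ``lam(t) = mu_m + mu_d - mu_m * mu_d`` (maintenance first, de novo as
    fallback).
    """

    mu_m_intercept: float = 0.0
    mu_m_slope: float = 0.0
    mu_d_intercept: float = 0.0
    mu_d_slope: float = 0.0
    eta_intercept: float = 0.0
    eta_slope: float = 0.0
    p: float = 0.0

    #: Parameter names in the canonical 7-vector order.
    PARAM_NAMES = (
        "mu_m_intercept",
        "mu_m_slope",
        "mu_d_intercept",
        "mu_d_slope",
        "eta_intercept",
        "eta_slope",
        "p",
    )

    def mu_m(self, t: float) -> float:
        return self.mu_m_intercept + self.mu_m_slope * t

    def mu_d(self, t: float) -> float:
        return self.mu_d_intercept + self.mu_d_slope * t

    def eta(self, t: float) -> float:
        return self.eta_intercept + self.eta_slope * t

    def lam(self, t: float) -> float:
        """Total methylation efficiency on a hemimethylated site at division t."""
        mm, md = self.mu_m(t), self.mu_d(t)
        return mm + md - mm * md

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, v: np.ndarray) -> "EfficiencyModel":
        v = np.asarray(v, dtype=float)
        if v.shape != (7,):
            raise ValueError("efficiency parameter vector must have length 7")
        return cls(**dict(zip(cls.PARAM_NAMES, v)))

    def validate(self, t_max: int) -> None:
        """Raise if any efficiency leaves [0, 1] on divisions 1..t_max.

        By linearity it suffices to check the endpoints of the range.
        """
        _check_prob("p", self.p)
        for name, f in (("mu_m", self.mu_m), ("mu_d", self.mu_d), ("eta", self.eta)):
            for t in (1, t_max):
                _check_prob(f"{name}({t})", f(t))

    def lambda_coefficients(self) -> tuple[float, float, float]:
        """Coefficients (beta0, beta1, beta2) of lam(t) as a quadratic in t.

        With mu_m = a0 + a1 t and mu_d = b0 + b1 t,
        lam(t) = (a0+b0-a0*b0) + (a1+b1-a0*b1-a1*b0) t + (-a1*b1) t^2.
        """
        a0, a1 = self.mu_m_intercept, self.mu_m_slope
        b0, b1 = self.mu_d_intercept, self.mu_d_slope
        return (a0 + b0 - a0 * b0, a1 + b1 - a0 * b1 - a1 * b0, -a1 * b1)

    def copy(self) -> "EfficiencyModel":
        return EfficiencyModel(**{f.name: getattr(self, f.name) for f in fields(self)})


def division_matrix() -> np.ndarray:
    """Transition matrix of one semi-conservative DNA replication.

    Averaging over the two daughter cells, the newly synthesised (all-``u``)
    strand is the upper or the lower one with probability 0.5 each: from
    state (s1, s2) the chain moves to (s1, u) or (u, s2).  The matrix is
    parameter-free and identical for every division.
    """
    D = np.zeros((9, 9))
    for i, (up, lo) in enumerate(zip(UPPER_MARK, LOWER_MARK)):
        D[i, STATE_INDEX[up + "u"]] += 0.5
        D[i, STATE_INDEX["u" + lo]] += 0.5
    return D


#: Cached division matrix (time-invariant).
_D = division_matrix()


def methylation_matrix(mu_m: float, mu_d: float, p: float) -> np.ndarray:
    """Transition matrix of one round of maintenance + de novo methylation.

    Rules per dyad state:

    * ``(uu)``: each strand is independently de novo methylated with
      probability ``mu_d``;
    * ``(um)/(mu)``: the unmodified strand is methylated with the total
      efficiency ``lam = mu_m + mu_d - mu_m*mu_d``;
    * ``(uh)/(hu)``: with probability ``p`` the hydroxyl group hides the dyad
      from maintenance and only de novo applies; otherwise the dyad is treated
      as hemimethylated, so the unmodified strand gains a methyl group with
      probability ``p*mu_d + (1-p)*lam``;
    * ``(mm), (mh), (hm), (hh)``: self-loops only — Dnmts do not touch
      hydroxyl groups and fully modified dyads offer no substrate.
    """
    mu_m = _check_prob("mu_m", mu_m)
    mu_d = _check_prob("mu_d", mu_d)
    p = _check_prob("p", p)
    lam = mu_m + mu_d - mu_m * mu_d
    q = p * mu_d + (1.0 - p) * lam  # methylation of the u strand opposite an h

    M = np.eye(9)
    i = STATE_INDEX
    # (uu): two independent de novo events
    M[i["uu"], i["uu"]] = (1 - mu_d) ** 2
    M[i["uu"], i["um"]] = (1 - mu_d) * mu_d
    M[i["uu"], i["mu"]] = mu_d * (1 - mu_d)
    M[i["uu"], i["mm"]] = mu_d**2
    # hemimethylated
    M[i["um"], i["um"]] = 1 - lam
    M[i["um"], i["mm"]] = lam
    M[i["mu"], i["mu"]] = 1 - lam
    M[i["mu"], i["mm"]] = lam
    # hemihydroxylated
    M[i["uh"], i["uh"]] = 1 - q
    M[i["uh"], i["mh"]] = q
    M[i["hu"], i["hu"]] = 1 - q
    M[i["hu"], i["hm"]] = q
    return M


def hydroxylation_matrix(eta: float) -> np.ndarray:
    """Transition matrix of one round of Tet-mediated oxidation.

    Each methylated strand independently becomes hydroxylated with
    probability ``eta``; unmodified and hydroxylated strands are inert.
    """
    eta = _check_prob("eta", eta)
    # Per-strand channel: rows u,m,h -> columns u,m,h
    ch = {"u": {"u": 1.0}, "m": {"m": 1.0 - eta, "h": eta}, "h": {"h": 1.0}}
    H = np.zeros((9, 9))
    for si, (up, lo) in enumerate(zip(UPPER_MARK, LOWER_MARK)):
        for up2, pu in ch[up].items():
            for lo2, pl in ch[lo].items():
                H[si, STATE_INDEX[up2 + lo2]] += pu * pl
    return H


def transition_matrix(t: int, model: EfficiencyModel) -> np.ndarray:
    """Per-division transition matrix ``P(t) = D @ M(t) @ H(t)``.

    ``t`` is the 1-based division index; the efficiencies are evaluated at
    ``t`` and must lie in [0, 1] there.
    """
    if t < 1:
        raise ValueError("division index t must be >= 1")
    return _D @ methylation_matrix(model.mu_m(t), model.mu_d(t), model.p) @ hydroxylation_matrix(
        model.eta(t)
    )


def propagate(pi0: np.ndarray, model: EfficiencyModel, t: int) -> np.ndarray:
    """Hidden-state distribution after ``t`` divisions: pi(0) @ P(1) ... P(t)."""
    pi = validate_distribution(pi0)
    for k in range(1, int(t) + 1):
        pi = pi @ transition_matrix(k, model)
    return pi
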