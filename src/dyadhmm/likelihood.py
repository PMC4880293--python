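"""Negative log-likelihoods of the two-stage estimation.

Stage one fits the initial hidden-state distribution pi(0) to the day-0
BS and oxBS counts:

    L1(pi0) = prod_j pi_bs(j,0)^n_bs(j,0) * pi_ox(j,0)^n_ox(j,0)

Stage two, with pi(0) fixed, fits the seven efficiency parameters to the
counts of all later days, propagating pi through P(1)..P(t) per day:

    L2(v) = prod_{t>0} prod_j pi_bs(j,t)^n_bs(j,t) * pi_ox(j,t)^n_ox(j,t)

Observations at different days are treated as independent (distinct small
samples from a large cell pool).  Both functions return +inf when a
zero-probability observable carries a positive count; the ``*_smoothed``
closures used inside the optimiser floor predicted probabilities instead so
that gradients stay finite.
"""

from __future__ import annotations

import numpy as np

from .data import ObservationDataset
from .emission import emission_matrix
from .states import EfficiencyModel, transition_matrix, validate_distribution

_FLOOR = 1e-300


def _nll_terms(counts: np.ndarray, probs: np.ndarray) -> float:
    """-sum n_j log p_j, with the 0*log(0) convention and +inf on impossible data."""
    pos = counts > 0
    if np.any(probs[pos] <= 0.0):
        return np.inf
    return -float(counts[pos] @ np.log(probs[pos]))


def neg_log_likelihood_initial(pi0: np.ndarray, data: ObservationDataset) -> float:
    """-log L1 at ``pi0`` from the day-0 counts of both treatments."""
    pi0 = validate_distribution(pi0)
    if not data.has_day0():
        raise ValueError("dataset has no day-0 counts for both treatments")
    total = 0.0
    for treatment in ("bs", "ox"):
        E = emission_matrix(data.profiles[(0, treatment)])
        total += _nll_terms(data.counts[(0, treatment)], pi0 @ E)
    return total


def neg_log_likelihood_dynamics(
    model: EfficiencyModel, pi0: np.ndarray, data: ObservationDataset
) -> float:
    """-log L2 at ``model`` given ``pi0``, over all post-day-0 counts."""
    pi0 = validate_distribution(pi0)
    days = data.post_days
    if not days:
        raise ValueError("dataset has no post-day-0 counts")
    model.validate(data.divisions(days[-1]))
    total = 0.0
    pi = pi0
    div = 0
    for day in days:
        for k in range(div + 1, data.divisions(day) + 1):
            pi = pi @ transition_matrix(k, model)
        div = data.divisions(day)
        for treatment in ("bs", "ox"):
            key = (day, treatment)
            if key not in data.counts:
                continue
            E = emission_matrix(data.profiles[key])
            total += _nll_terms(data.counts[key], pi @ E)
    return total


def make_initial_nll(data: ObservationDataset):
    """Smoothed, precomputed -log L1 objective pi0 -> float for the optimiser."""
    if not data.has_day0():
        raise ValueError("dataset has no day-0 counts for both treatments")
    pairs = []
    for treatment in ("bs", "ox"):
        pairs.append(
            (data.counts[(0, treatment)].astype(float), emission_matrix(data.profiles[(0, treatment)]))
        )

    def nll(pi0: np.ndarray) -> float:
        total = 0.0
        for n, E in pairs:
            probs = np.clip(pi0 @ E, _FLOOR, None)
            total -= n @ np.log(probs)
        return float(total)

    return nll


def make_dynamics_nll(data: ObservationDataset, pi0: np.ndarray):
    """Smoothed -log L2 objective over the 7-parameter vector.

    Emission matrices and day/division bookkeeping are precomputed; the
    efficiencies are clipped into [0, 1] per division so that the objective
    stays finite at the slightly infeasible points an SQP line search may
    probe.
    """
    pi0 = validate_distribution(pi0).copy()
    days = data.post_days
    if not days:
        raise ValueError("dataset has no post-day-0 counts")
    schedule = []  # (n_divisions_since_last, [(counts, E), ...]) per observation day
    div = 0
    for day in days:
        obs = []
        for treatment in ("bs", "ox"):
            key = (day, treatment)
            if key in data.counts:
                obs.append(
                    (data.counts[key].astype(float), emission_matrix(data.profiles[key]))
                )
        schedule.append((data.divisions(day) - div, obs))
        div = data.divisions(day)

    from .states import _D, hydroxylation_matrix, methylation_matrix

    def nll(v: np.ndarray) -> float:
        model = EfficiencyModel.from_array(v)
        p = min(max(model.p, 0.0), 1.0)
        total = 0.0
        pi = pi0
        t = 0
        for n_div, obs in schedule:
            for _ in range(n_div):
                t += 1
                mm = min(max(model.mu_m(t), 0.0), 1.0)
                md = min(max(model.mu_d(t), 0.0), 1.0)
                et = min(max(model.eta(t), 0.0), 1.0)
                pi = pi @ (_D @ methylation_matrix(mm, md, p) @ hydroxylation_matrix(et))
            for n, E in obs:
                probs = np.clip(pi @ E, _FLOOR, None)
                total -= n @ np.log(probs)
        return float(total)

    return nll
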