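"""Synthetic hairpin BS/oxBS data from known ground-truth parameters.

Two simulators are provided:

* :func:`sample_chain` draws dyad trajectories by categorical sampling from
  the rows of the per-division transition matrices P(1)..P(t);
* :func:`simulate_cycle_events` plays out one division cycle at the level
  of the individual molecular events (uniform choice of the replaced
  strand; maintenance attempted before de novo on hemimethylated sites;
  recognition coin for 5hmC-opposite sites; per-strand hydroxylation)
  without ever forming a transition matrix.  It exists as an independent
  cross-check of the matrix algebra.

Dyads are i.i.d. — cells sampled from a large pool share no recent
ancestry — and the BS and oxBS pools are disjoint samples of the same
hidden distribution, mirroring the split of the hairpin-ligated DNA into
two halves before treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ObservationDataset
from .emission import ConversionProfile, strand_emission
from .states import (
    LOWER_MARK,
    STATE_INDEX,
    STATES,
    UPPER_MARK,
    EfficiencyModel,
    transition_matrix,
    validate_distribution,
)

#: Realistic default conversion chemistry: near-complete conversion of
#: unmodified C (c), slight over-conversion of 5mC (d), partial loss of 5hmC
#: under plain bisulfite (e) and slightly incomplete 5hmC oxidation (f).
DEFAULT_CONVERSION = {"c": 0.995, "d": 0.98, "e": 0.90, "f": 0.92}

#: A serum/LIF-like baseline: mostly methylated, some hemimethylation, a
#: small symmetric hydroxylated fraction (5hmC is scarce before the shift
#: to 2i medium).
DEFAULT_PI0 = np.array([0.20, 0.08, 0.08, 0.02, 0.02, 0.56, 0.015, 0.015, 0.01])


def default_profiles(days, conversion: dict | None = None):
    conv = dict(DEFAULT_CONVERSION, **(conversion or {}))
    profiles = {}
    for day in days:
        profiles[(day, "bs")] = ConversionProfile("bs", c=conv["c"], d=conv["d"],
                                                  e=conv["e"], day=day)
        profiles[(day, "ox")] = ConversionProfile("ox", c=conv["c"], d=conv["d"],
                                                  f=conv["f"], day=day)
    return profiles


@dataclass
class SimulationConfig:
    """Ground truth and sampling design of a synthetic hairpin experiment.

    Defaults emulate the study design the model targets: observation at
    days 0/1/3/6 with one division per day, coverage 10^4 molecules per day
    and treatment, a mostly-methylated symmetric starting distribution and
    mildly imperfect conversion chemistry.
    """

    model: EfficiencyModel = field(
        default_factory=lambda: EfficiencyModel(
            mu_m_intercept=0.8, mu_d_intercept=0.3, mu_d_slope=-0.02,
            eta_intercept=0.05, eta_slope=0.03, p=1.0,
        )
    )
    pi0: np.ndarray = field(default_factory=lambda: DEFAULT_PI0.copy())
    days: tuple[int, ...] = (0, 1, 3, 6)
    coverage: int = 10_000
    profiles: dict | None = None
    n_positions: int = 1
    divisions_per_day: int = 1
    locus: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pi0 = validate_distribution(self.pi0)
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if 0 not in self.days:
            raise ValueError("observation days must include day 0")
        if self.profiles is None:
            self.profiles = default_profiles(self.days)
        self.model.validate(max(self.days) * self.divisions_per_day)


def sample_chain(config: SimulationConfig, rng: np.random.Generator,
                 size: int, t: int) -> np.ndarray:
    """Sample ``size`` i.i.d. dyads from pi(0) propagated through t divisions.

    Sampling is by transition-matrix rows: at each division every dyad jumps
    according to the row of P(k) for its current state.
    """
    states = rng.choice(9, size=size, p=config.pi0)
    for k in range(1, t + 1):
        P = transition_matrix(k, config.model)
        new = np.empty_like(states)
        for s in range(9):
            mask = states == s
            n = int(mask.sum())
            if n:
                new[mask] = rng.choice(9, size=n, p=P[s])
        states = new
    return states


def simulate_hidden_states(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Per-(day, treatment) samples of hidden dyad states.

    Returns a dict mapping ``(day, treatment)`` to an integer array of
    canonical state indices of length ``coverage``.  The two treatments get
    independent pools.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    samples = {}
    for day in sorted(config.days):
        t = day * config.divisions_per_day
        for treatment in ("bs", "ox"):
            samples[(day, treatment)] = sample_chain(config, rng, config.coverage, t)
    return samples


def simulate_reads(hidden: dict, profiles: dict, rng: np.random.Generator) -> dict:
    """Convert hidden-state samples to read-pair counts over TT/TC/CT/CC.

    Each strand is pushed through its conversion channel independently
    (Bernoulli draw of T versus C given the strand mark and the treatment's
    profile); counts are tallied in canonical observable order.
    """
    counts = {}
    for (day, treatment), states in hidden.items():
        profile = profiles[(day, treatment)]
        p_T = {mark: strand_emission(mark, profile)[0] for mark in "umh"}
        up_pT = np.array([p_T[m] for m in UPPER_MARK])[states]
        lo_pT = np.array([p_T[m] for m in LOWER_MARK])[states]
        up_is_T = rng.random(states.shape) < up_pT
        lo_is_T = rng.random(states.shape) < lo_pT
        # observable index: TT=0, TC=1, CT=2, CC=3 (T first in each slot)
        obs = (~up_is_T) * 2 + (~lo_is_T) * 1
        counts[(day, treatment)] = np.bincount(obs, minlength=4).astype(np.int64)
    return counts


def generate_dataset(config: SimulationConfig):
    """Simulate a full observation dataset (or one per CpG position).

    Returns ``(datasets, truth)`` where ``datasets`` is a single
    :class:`ObservationDataset` when ``n_positions == 1`` and a list of
    per-position datasets sharing the same ground truth otherwise, and
    ``truth`` is a plain dict recording the generating parameters for
    recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    truth = {
        "locus": config.locus,
        "pi0": {s: float(v) for s, v in zip(STATES, config.pi0)},
        "efficiencies": {n: float(v) for n, v in
                         zip(EfficiencyModel.PARAM_NAMES, config.model.to_array())},
        "days": list(config.days),
        "coverage": config.coverage,
        "divisions_per_day": config.divisions_per_day,
        "seed": config.seed,
    }
    datasets = []
    for pos in range(config.n_positions):
        hidden = simulate_hidden_states(config, rng)
        counts = simulate_reads(hidden, config.profiles, rng)
        datasets.append(ObservationDataset(
            locus=config.locus,
            counts=counts,
            profiles=dict(config.profiles),
            position=f"cpg{pos + 1}" if config.n_positions > 1 else "aggregate",
            divisions_per_day=config.divisions_per_day,
        ))
    if config.n_positions == 1:
        return datasets[0], truth
    return datasets, truth


# ---------------------------------------------------------------------------
# Event-level one-cycle simulator (matrix-free oracle)
# ---------------------------------------------------------------------------

_U, _M, _H = 0, 1, 2
_MARK_CODE = {"u": _U, "m": _M, "h": _H}
_STATE_TO_MARKS = np.array([[_MARK_CODE[s[0]], _MARK_CODE[s[1]]] for s in STATES])
_MARKS_TO_STATE = np.full((3, 3), -1)
for _i, (_a, _b) in enumerate(_STATE_TO_MARKS):
    _MARKS_TO_STATE[_a, _b] = _i


def simulate_cycle_events(states: np.ndarray, mu_m: float, mu_d: float, eta: float,
                          p: float, rng: np.random.Generator) -> np.ndarray:
    """One division cycle simulated event by event, without matrices.

    Steps, per dyad: (1) the replaced strand is chosen uniformly and reset
    to ``u``; (2) methylation: on (uu) each strand is independently de novo
    methylated with probability mu_d; on a hemimethylated dyad maintenance
    is attempted first (mu_m) and, on failure, de novo (mu_d); on a dyad
    with 5hmC opposite a ``u``, a recognition coin with probability p hides
    the site from maintenance leaving only de novo, otherwise the
    maintenance-then-de-novo cascade runs; (3) every methylated strand is
    hydroxylated with probability eta, independently.
    """
    marks = _STATE_TO_MARKS[np.asarray(states)].copy()  # (n, 2)
    n = marks.shape[0]

    # (1) replication: one strand, chosen uniformly, becomes unmodified
    replaced = rng.integers(0, 2, size=n)
    marks[np.arange(n), replaced] = _U

    # (2) methylation; both strands decide on the post-replication snapshot,
    # so a de novo gain on one strand cannot enable maintenance of the other
    # within the same cycle (single enzymatic pass per division)
    snapshot = marks.copy()
    for strand in (0, 1):
        other = 1 - strand
        is_u = snapshot[:, strand] == _U
        other_mark = snapshot[:, other]
        maint_coin = rng.random(n) < mu_m
        denovo_coin = rng.random(n) < mu_d
        recog_coin = rng.random(n) < p  # True: 5hmC hides the dyad from Dnmt1

        hemi = is_u & (other_mark == _M)
        gains = hemi & (maint_coin | denovo_coin)

        opp_u = is_u & (other_mark == _U)
        gains |= opp_u & denovo_coin

        opp_h = is_u & (other_mark == _H)
        gains |= opp_h & np.where(recog_coin, denovo_coin, maint_coin | denovo_coin)

        marks[gains, strand] = _M

    # (3) hydroxylation of methylated strands
    for strand in (0, 1):
        oxidised = (marks[:, strand] == _M) & (rng.random(n) < eta)
        marks[oxidised, strand] = _H

    return _MARKS_TO_STATE[marks[:, 0], marks[:, 1]]


def empirical_transition_row(state: str, mu_m: float, mu_d: float, eta: float, p: float,
                             n: int, rng: np.random.Generator) -> np.ndarray:
    """Empirical one-step distribution from ``n`` event-level simulations."""
    start = np.full(n, STATE_INDEX[state])
    end = simulate_cycle_events(start, mu_m, mu_d, eta, p, rng)
    return np.bincount(end, minlength=9) / n
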