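"""Maximum-likelihood estimators for the dyad methylation HMM.

Estimation is two-stage, mirroring how the hairpin BS/oxBS experiment is
analysed: :class:`InitialDistributionEstimator` fits the initial
hidden-state distribution pi(0) to the day-0 counts, then
:class:`EfficiencyEstimator` fits, with pi(0) held fixed, the seven
parameters of the linear efficiency functions (intercept/slope of
maintenance, de novo and hydroxylation, plus the 5hmC non-recognition
probability p).  :class:`DyadMethylationHMM` chains the two and exposes
time-course prediction.

All estimators follow the scikit-learn conventions: constructor arguments
are plain hyperparameters, ``fit`` returns ``self`` and fitted quantities
carry a trailing underscore.  Optimisation is multi-start SLSQP on the
negative log-likelihood; box feasibility of each efficiency over the fitted
division range is imposed through linear constraints at the endpoint
divisions (sufficient by linearity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .data import ObservationDataset
from .likelihood import (
    make_dynamics_nll,
    make_initial_nll,
    neg_log_likelihood_dynamics,
    neg_log_likelihood_initial,
)
from .states import STATES, EfficiencyModel, H_STATES, propagate, validate_distribution

PARAM_NAMES = EfficiencyModel.PARAM_NAMES
_PAIRS = ((0, 1, "mu_m"), (2, 3, "mu_d"), (4, 5, "eta"))


class EstimationError(RuntimeError):
    """Raised when no optimisation start converges."""


@dataclass
class WaldTest:
    """Result of a Wald hypothesis test."""

    statistic: float
    p_value: float
    alpha: float
    reject: bool
    df: int = 1
    description: str = ""


@dataclass
class FitResult:
    """Bundle of everything a fitted model reports.

    Standard deviations and confidence intervals come from the observed
    Fisher information of the stage-two likelihood at the optimum,
    conditional on the fitted pi(0); parameters pinned at a box boundary
    are flagged and their intervals truncated to the feasible range.
    """

    locus: str
    pi0: np.ndarray
    model: EfficiencyModel
    nll_initial: float | None
    nll_dynamics: float
    t_max: int
    free_names: tuple[str, ...]
    sd: dict[str, float]
    ci: dict[str, tuple[float, float]]
    fim: np.ndarray
    cov: np.ndarray
    conf_level: float
    fim_reliable: bool
    boundary_flags: dict[str, bool]
    n_starts: int
    n_converged: int
    start_objectives: list[float] = field(default_factory=list)
    pi0_spread: float | None = None

    @property
    def log_likelihood_initial(self) -> float | None:
        return None if self.nll_initial is None else -self.nll_initial

    @property
    def log_likelihood_dynamics(self) -> float:
        return -self.nll_dynamics


# ---------------------------------------------------------------------------
# Stage one: initial distribution
# ---------------------------------------------------------------------------

# Strand-symmetric parameterisation: 6 state classes -> 9 states, with the
# mass of each asymmetric class split equally between its two members.
_SYM_CLASSES = (("uu",), ("um", "mu"), ("uh", "hu"), ("mm",), ("mh", "hm"), ("hh",))
_SYM_MAP = np.zeros((6, 9))
for _ci, _members in enumerate(_SYM_CLASSES):
    for _s in _members:
        _SYM_MAP[_ci, STATES.index(_s)] = 1.0 / len(_members)


class InitialDistributionEstimator(BaseEstimator):
    """Maximum-likelihood estimate of pi(0) from day-0 BS and oxBS counts.

    Day-0 data constrains only 6 degrees of freedom (3 per treatment) while
    the 9-state simplex has 8, so the optimum can be non-unique; the spread
    of near-optimal multi-start solutions is reported in ``spread_`` as a
    non-identifiability diagnostic.  Setting ``symmetric=True`` ties
    strand-swapped states (um=mu, uh=hu, mh=hm), which restores
    identifiability whenever the conversion rates of 5mC and 5hmC differ.

    Parameters
    ----------
    n_starts : number of optimisation starts (Dirichlet-uniform draws plus
        the barycentre).
    symmetric : tie strand-swapped state pairs.
    tol : convergence tolerance on the objective.
    random_state : seed for the start draws.
    """

    def __init__(self, n_starts: int = 20, symmetric: bool = False, tol: float = 1e-9,
                 random_state: int | None = None):
        self.n_starts = n_starts
        self.symmetric = symmetric
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: ObservationDataset, y=None):
        nll9 = make_initial_nll(X)
        k = 6 if self.symmetric else 9
        expand = (lambda w: w @ _SYM_MAP) if self.symmetric else (lambda w: w)
        objective = lambda w: nll9(expand(w))

        rng = np.random.default_rng(self.random_state)
        starts = [np.full(k, 1.0 / k)]
        starts += [rng.dirichlet(np.ones(k)) for _ in range(max(0, self.n_starts - 1))]

        constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                        "jac": lambda w: np.ones_like(w)}]
        optima = []
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, method="SLSQP", bounds=[(0.0, 1.0)] * k,
                constraints=constraints, options={"ftol": self.tol, "maxiter": 500},
            )
            if res.success and np.isfinite(res.fun):
                w = np.clip(res.x, 0.0, None)
                w /= w.sum()
                optima.append((float(objective(w)), w))
        if not optima:
            raise EstimationError(
                f"initial-distribution estimation failed on all {self.n_starts} starts"
            )
        optima.sort(key=lambda o: (o[0], tuple(o[1])))
        best_nll, best_w = optima[0]
        near = [w for f, w in optima if f <= best_nll + 1e-6]
        self.pi0_ = expand(best_w)
        self.nll_ = best_nll
        self.optima_ = [(f, expand(w)) for f, w in optima]
        self.spread_ = float(max(np.max(np.abs(expand(w) - self.pi0_)) for w in near))
        self.n_converged_ = len(optima)
        return self

    def score(self, X: ObservationDataset, y=None) -> float:
        """Day-0 log-likelihood of the fitted pi(0) on ``X``."""
        return -neg_log_likelihood_initial(self.pi0_, X)


# ---------------------------------------------------------------------------
# Stage two: efficiency functions
# ---------------------------------------------------------------------------


def _feasible_linear_start(rng: np.random.Generator, t_max: int) -> tuple[float, float]:
    """Draw (intercept, slope) with values uniform in [0,1] at t=1 and t=t_max."""
    v1, v2 = rng.uniform(0.0, 1.0, size=2)
    slope = 0.0 if t_max <= 1 else (v2 - v1) / (t_max - 1)
    return v1 - slope, slope


class EfficiencyEstimator(BaseEstimator):
    """Maximum-likelihood fit of the 7 efficiency parameters given pi(0).

    Parameters
    ----------
    n_starts : number of SLSQP starts, drawn uniformly from the feasible box.
    constant : fit the constant-efficiency model (all slopes fixed at 0).
    fixed : mapping of parameter name to a fixed value, e.g.
        ``{"eta_intercept": 0.0, "eta_slope": 0.0, "p": 0.0}``.
    tol : convergence tolerance on the objective.
    conf_level : level of the normal-approximation confidence intervals.
    random_state : seed for the start draws.

    Attributes
    ----------
    model_ : fitted :class:`EfficiencyModel`.
    v_ : fitted 7-vector in canonical parameter order.
    nll_ : minimised negative log-likelihood (stage two).
    result_ : full :class:`FitResult` including sds, CIs and flags.
    """

    def __init__(self, n_starts: int = 20, constant: bool = False,
                 fixed: dict | None = None, tol: float = 1e-9,
                 conf_level: float = 0.95, random_state: int | None = None):
        self.n_starts = n_starts
        self.constant = constant
        self.fixed = fixed
        self.tol = tol
        self.conf_level = conf_level
        self.random_state = random_state

    def _fixed_map(self) -> dict[str, float]:
        fixed = dict(self.fixed or {})
        if self.constant:
            for name in ("mu_m_slope", "mu_d_slope", "eta_slope"):
                fixed.setdefault(name, 0.0)
        for name in fixed:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r} in fixed")
        return fixed

    def fit(self, X: ObservationDataset, y=None, pi0: np.ndarray | None = None):
        if pi0 is None:
            raise ValueError("pi0 is required: estimate it first (InitialDistributionEstimator)")
        pi0 = validate_distribution(pi0)
        if not X.post_days:
            raise ValueError("dataset has no post-day-0 observations to fit dynamics on")
        t_max = X.divisions(X.post_days[-1])

        fixed = self._fixed_map()
        free_idx = [i for i, n in enumerate(PARAM_NAMES) if n not in fixed]
        if not free_idx:
            raise ValueError("all parameters fixed; nothing to fit")
        base = np.zeros(7)
        for name, value in fixed.items():
            base[PARAM_NAMES.index(name)] = value

        def full(x: np.ndarray) -> np.ndarray:
            v = base.copy()
            v[free_idx] = x
            return v

        nll7 = make_dynamics_nll(X, pi0)
        objective = lambda x: nll7(full(x))

        constraints = []
        for i0, i1, _name in _PAIRS:
            for t in {1, t_max}:
                row = np.zeros(7)
                row[i0], row[i1] = 1.0, t
                r = row[free_idx]
                offs = row @ base - (row[free_idx] @ base[free_idx])
                constraints.append(
                    {"type": "ineq", "fun": (lambda x, r=r, o=offs: r @ x + o),
                     "jac": (lambda x, r=r: r)}
                )
                constraints.append(
                    {"type": "ineq", "fun": (lambda x, r=r, o=offs: 1.0 - (r @ x + o)),
                     "jac": (lambda x, r=r: -r)}
                )

        bounds = []
        for i in free_idx:
            if PARAM_NAMES[i] == "p":
                bounds.append((0.0, 1.0))
            elif PARAM_NAMES[i].endswith("slope"):
                bounds.append((-1.0, 1.0))
            else:
                bounds.append((-1.0, 2.0))

        rng = np.random.default_rng(self.random_state)
        starts = []
        for _ in range(self.n_starts):
            v = np.zeros(7)
            for i0, i1, _name in _PAIRS:
                v[i0], v[i1] = _feasible_linear_start(rng, t_max)
            v[6] = rng.uniform(0.0, 1.0)
            starts.append(v[free_idx])

        optima, objectives = [], []
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, method="SLSQP", bounds=bounds, constraints=constraints,
                options={"ftol": self.tol, "maxiter": 500},
            )
            objectives.append(float(res.fun) if np.isfinite(res.fun) else np.inf)
            if res.success and np.isfinite(res.fun):
                optima.append((float(res.fun), tuple(full(res.x))))
        if not optima:
            raise EstimationError(f"efficiency estimation failed on all {self.n_starts} starts")
        optima.sort(key=lambda o: (o[0], o[1]))
        best_nll, best_v = optima[0]
        v = np.array(best_v)

        self.v_ = v
        self.model_ = EfficiencyModel.from_array(v)
        self.nll_ = best_nll
        self.pi0_ = pi0
        self.t_max_ = t_max
        self.free_names_ = tuple(PARAM_NAMES[i] for i in free_idx)
        self.n_converged_ = len(optima)
        self.start_objectives_ = objectives
        self.start_points_ = [full(x0) for x0 in starts]

        from .stats import observed_fim

        fim = observed_fim(self.model_, pi0, X, free_names=self.free_names_,
                           conf_level=self.conf_level)
        self.fim_ = fim.fim
        self.cov_ = fim.cov
        self.sd_ = fim.sd
        self.ci_ = fim.ci
        self.fim_reliable_ = fim.reliable
        self.boundary_flags_ = fim.boundary_flags

        self.result_ = FitResult(
            locus=X.locus, pi0=pi0, model=self.model_, nll_initial=None,
            nll_dynamics=best_nll, t_max=t_max, free_names=self.free_names_,
            sd=fim.sd, ci=fim.ci, fim=fim.fim, cov=fim.cov, conf_level=self.conf_level,
            fim_reliable=fim.reliable, boundary_flags=fim.boundary_flags,
            n_starts=self.n_starts, n_converged=len(optima),
            start_objectives=objectives,
        )
        return self

    def score(self, X: ObservationDataset, y=None) -> float:
        """Stage-two log-likelihood of the fitted parameters on ``X``."""
        return -neg_log_likelihood_dynamics(self.model_, self.pi0_, X)


# ---------------------------------------------------------------------------
# Combined two-stage estimator
# ---------------------------------------------------------------------------


class DyadMethylationHMM(BaseEstimator):
    """Two-stage fit of the full dyad methylation/hydroxylation HMM.

    ``fit`` estimates pi(0) from the day-0 counts, then the efficiency
    parameters from the later days with pi(0) fixed.  ``predict_timecourse``
    returns the hidden-state and observable-state trajectories implied by
    the fit.
    """

    def __init__(self, n_starts: int = 20, symmetric_initial: bool = False,
                 constant: bool = False, fixed: dict | None = None, tol: float = 1e-9,
                 conf_level: float = 0.95, random_state: int | None = None):
        self.n_starts = n_starts
        self.symmetric_initial = symmetric_initial
        self.constant = constant
        self.fixed = fixed
        self.tol = tol
        self.conf_level = conf_level
        self.random_state = random_state

    def fit(self, X: ObservationDataset, y=None):
        rng = np.random.default_rng(self.random_state)
        seed0, seed1 = rng.integers(0, 2**31 - 1, size=2)
        init = InitialDistributionEstimator(
            n_starts=self.n_starts, symmetric=self.symmetric_initial, tol=self.tol,
            random_state=int(seed0),
        ).fit(X)
        eff = EfficiencyEstimator(
            n_starts=self.n_starts, constant=self.constant, fixed=self.fixed,
            tol=self.tol, conf_level=self.conf_level, random_state=int(seed1),
        ).fit(X, pi0=init.pi0_)

        self.initial_estimator_ = init
        self.efficiency_estimator_ = eff
        self.pi0_ = init.pi0_
        self.model_ = eff.model_
        self.v_ = eff.v_
        result = eff.result_
        result.nll_initial = init.nll_
        result.pi0_spread = init.spread_
        self.result_ = result
        self.dataset_ = X
        return self

    def predict_timecourse(self, days=None, X: ObservationDataset | None = None):
        """Predicted hidden and observable distributions per observation day."""
        X = X if X is not None else self.dataset_
        days = list(days) if days is not None else X.days
        return predict_timecourse(self.model_, self.pi0_, days, data=X)

    def score(self, X: ObservationDataset, y=None) -> float:
        return -neg_log_likelihood_dynamics(self.model_, self.pi0_, X)


def predict_timecourse(model: EfficiencyModel, pi0: np.ndarray, days,
                       data: ObservationDataset | None = None,
                       divisions_per_day: int = 1):
    """Hidden/observable trajectories and headline summaries per day.

    Returns a pandas DataFrame with one row per requested day: the 9
    hidden-state probabilities, the observable TT/TC/CT/CC probabilities per
    treatment (when conversion profiles are available), and the summaries of
    interest: fully methylated (mm), hemimethylated (um+mu), unmethylated
    (uu), total hydroxylated (any state containing h), per-strand 5hmC
    level, and the total methylation efficiency lam(t) on hemimethylated
    sites at the day's division index.
    """
    import pandas as pd

    from .emission import observable_distribution, OBS_STATES

    dpd = data.divisions_per_day if data is not None else divisions_per_day
    h_strands = np.array([s.count("h") for s in STATES], dtype=float)
    rows = []
    for day in sorted(days):
        t = int(day) * dpd
        pi = propagate(pi0, model, t)
        row = {"day": day, "divisions": t}
        row.update({f"pi_{s}": pi[i] for i, s in enumerate(STATES)})
        row["fully_methylated"] = pi[STATES.index("mm")]
        row["hemimethylated"] = pi[STATES.index("um")] + pi[STATES.index("mu")]
        row["unmethylated"] = pi[STATES.index("uu")]
        row["total_hydroxylated"] = float(pi[list(H_STATES)].sum())
        row["strand_5hmC_level"] = float(pi @ h_strands) / 2.0
        row["lambda"] = model.lam(t) if t >= 1 else np.nan
        if data is not None:
            for treatment in ("bs", "ox"):
                key = (day, treatment)
                if key in data.profiles:
                    obs = observable_distribution(pi, data.profiles[key])
                    row.update({f"{treatment}_{s}": obs[j] for j, s in enumerate(OBS_STATES)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def estimate_initial_distribution(data: ObservationDataset, starts: int = 20,
                                  seed: int | None = None, symmetric: bool = False):
    """Fit pi(0) and return (pi0, fitted estimator with diagnostics)."""
    est = InitialDistributionEstimator(n_starts=starts, symmetric=symmetric,
                                       random_state=seed).fit(data)
    return est.pi0_, est


def fit_efficiencies(data: ObservationDataset, pi0: np.ndarray, starts: int = 20,
                     seed: int | None = None, **kwargs) -> FitResult:
    """Fit the 7-parameter efficiency vector given pi(0); returns a FitResult."""
    est = EfficiencyEstimator(n_starts=starts, random_state=seed, **kwargs).fit(data, pi0=pi0)
    return est.result_
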