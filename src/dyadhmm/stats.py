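"""Uncertainty quantification and hypothesis tests for fitted efficiencies.

The observed Fisher information matrix (the Hessian of the negative
log-likelihood at the optimum) yields, through its inverse, the asymptotic
covariance of the maximum-likelihood estimator; large multinomial samples
make the normal approximation appropriate.  On top of it sit:

* per-efficiency Wald tests of H0: slope = 0 (are the enzymatic
  efficiencies constant over time?), two-sided at the 1% level;
* a joint chi-square Wald test that the total hemimethylation efficiency
  lam(t) = mu_m + mu_d - mu_m*mu_d is constant, i.e. that both the linear
  and the quadratic coefficient of lam(t) in t vanish, with the coefficient
  covariance obtained by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.tools.numdiff import approx_hess2

from .data import ObservationDataset
from .likelihood import make_dynamics_nll
from .states import EfficiencyModel

PARAM_NAMES = EfficiencyModel.PARAM_NAMES

_BOUNDARY_TOL = 1e-6


@dataclass
class FIMResult:
    """Observed Fisher information at the optimum and derived uncertainty."""

    fim: np.ndarray
    cov: np.ndarray
    sd: dict[str, float]
    ci: dict[str, tuple[float, float]]
    free_names: tuple[str, ...]
    reliable: bool
    boundary_flags: dict[str, bool]
    conf_level: float


def _boundary_flags(model: EfficiencyModel, t_max: int) -> dict[str, bool]:
    """Flag parameters taking part in an active box constraint at the optimum."""
    flags = {name: False for name in PARAM_NAMES}
    for prefix, f in (("mu_m", model.mu_m), ("mu_d", model.mu_d), ("eta", model.eta)):
        for t in (1, t_max):
            v = f(t)
            if min(v, 1.0 - v) < _BOUNDARY_TOL:
                flags[f"{prefix}_intercept"] = True
                flags[f"{prefix}_slope"] = True
    if min(model.p, 1.0 - model.p) < _BOUNDARY_TOL:
        flags["p"] = True
    return flags


def observed_fim(model: EfficiencyModel, pi0: np.ndarray, data: ObservationDataset,
                 free_names: tuple[str, ...] = PARAM_NAMES,
                 conf_level: float = 0.95) -> FIMResult:
    """Observed FIM of the stage-two likelihood at ``model`` and derived CIs.

    The Hessian is computed by central finite differences over the free
    parameters.  A singular (or non-positive) information matrix is handled
    with the Moore-Penrose pseudo-inverse and the result is marked
    unreliable.  Parameters pinned at a box boundary are flagged and the
    confidence interval of ``p`` is truncated to [0, 1].
    """
    nll = make_dynamics_nll(data, pi0)
    v = model.to_array()
    free_idx = [PARAM_NAMES.index(n) for n in free_names]

    def nll_free(x: np.ndarray) -> float:
        w = v.copy()
        w[free_idx] = x
        return nll(w)

    fim = approx_hess2(v[free_idx].copy(), nll_free)
    fim = 0.5 * (fim + fim.T)

    reliable = True
    try:
        cov = np.linalg.inv(fim)
        if np.any(np.diag(cov) < 0) or not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(fim)
        reliable = False

    t_max = data.divisions(data.post_days[-1]) if data.post_days else 1
    flags = _boundary_flags(model, t_max)
    z = sps.norm.ppf(0.5 + conf_level / 2.0)

    sd: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for name in PARAM_NAMES:
        if name not in free_names:
            sd[name] = np.nan
            ci[name] = (np.nan, np.nan)
            continue
        k = free_names.index(name)
        var = cov[k, k]
        s = float(np.sqrt(var)) if var >= 0 else np.nan
        sd[name] = s
        est = v[PARAM_NAMES.index(name)]
        lo, hi = est - z * s, est + z * s
        if name == "p":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        ci[name] = (lo, hi)

    return FIMResult(fim=fim, cov=cov, sd=sd, ci=ci, free_names=tuple(free_names),
                     reliable=reliable, boundary_flags=flags, conf_level=conf_level)


def wald_slope_test(fit, which: str, alpha: float = 0.01):
    """Two-sided Wald test of H0: the slope of ``which`` is zero.

    ``which`` is one of ``mu_m``, ``mu_d``, ``eta``.  Refuses (raises
    ValueError) when the slope was not a free parameter, its standard
    deviation is zero or undefined, or the information matrix was singular.
    """
    from .estimators import WaldTest

    if which not in ("mu_m", "mu_d", "eta"):
        raise ValueError(f"which must be mu_m, mu_d or eta, got {which!r}")
    name = f"{which}_slope"
    if name not in fit.free_names:
        raise ValueError(f"test refused: {name} was fixed, not estimated")
    if not fit.fim_reliable:
        raise ValueError("test refused: observed information matrix is singular/unreliable")
    s = fit.sd[name]
    if not np.isfinite(s) or s <= 0:
        raise ValueError(f"test refused: standard deviation of {name} is {s}")
    slope = getattr(fit.model, name)
    z = slope / s
    p = 2.0 * sps.norm.sf(abs(z))
    return WaldTest(statistic=float(z), p_value=float(p), alpha=alpha,
                    reject=bool(p < alpha), df=1,
                    description=f"H0: slope of {which}(t) = 0")


def wald_lambda_joint_test(fit, alpha: float = 0.01):
    """Joint Wald test of H0: lam(t) constant (its t and t^2 coefficients zero).

    Writing mu_m = a0 + a1 t and mu_d = b0 + b1 t, the coefficients of
    lam(t) in t and t^2 are a1 + b1 - a0*b1 - a1*b0 and -a1*b1.  Whenever
    the intercepts are below 1 these vanish exactly when a1 = b1 = 0, so
    H0 is equivalent to both methylation slopes being zero.  The test is
    carried out in that full-rank parameterisation — the quadratic-in-t
    coefficients themselves have a rank-deficient delta-method Jacobian
    under H0 (the variance of -a1*b1 vanishes to first order), which would
    invalidate the chi-square reference exactly where the null holds.  The
    statistic is the joint Wald quadratic form of the two slopes, chi-square
    with 2 degrees of freedom.
    """
    from .estimators import WaldTest

    needed = ("mu_m_intercept", "mu_m_slope", "mu_d_intercept", "mu_d_slope")
    for name in needed:
        if name not in fit.free_names:
            raise ValueError(f"test refused: {name} was fixed, not estimated")
    if not fit.fim_reliable:
        raise ValueError("test refused: observed information matrix is singular/unreliable")

    desc = "H0: lambda(t) constant (t and t^2 coefficients zero)"
    g = np.array([fit.model.mu_m_slope, fit.model.mu_d_slope])
    if np.allclose(g, 0.0, atol=1e-15):
        return WaldTest(statistic=0.0, p_value=1.0, alpha=alpha, reject=False,
                        df=2, description=desc)
    cols = [fit.free_names.index(n) for n in ("mu_m_slope", "mu_d_slope")]
    cov_g = fit.cov[np.ix_(cols, cols)]
    try:
        stat = float(g @ np.linalg.solve(cov_g, g))
    except np.linalg.LinAlgError as exc:
        raise ValueError("test refused: singular slope covariance") from exc
    if stat < 0:
        raise ValueError("test refused: non-positive-definite slope covariance")
    p = float(sps.chi2.sf(stat, df=2))
    return WaldTest(statistic=stat, p_value=p, alpha=alpha, reject=bool(p < alpha),
                    df=2, description=desc)
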