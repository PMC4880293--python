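"""Leave-one-out cross-validation of linear versus constant efficiencies.

The exchangeable blocks of a hairpin time-course are its post-day-0
observation days.  Each fold holds one such day out, refits both the
linear-efficiency model and the constant-efficiency model (slopes fixed at
zero) on the remaining days — keeping pi(0) fixed from the day-0 data —
and scores the held-out day's empirical read-pair distributions against
the predicted ones with two divergences, each summed over the two
treatments:

* Kullback-Leibler, KL(empirical || predicted), with the predicted
  probabilities floored at 1e-12;
* Bhattacharyya distance, -ln sum_j sqrt(empirical_j * predicted_j).

The relative improvement of the linear over the constant model is
(constant - linear) / constant per divergence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ObservationDataset
from .emission import emission_matrix
from .estimators import EfficiencyEstimator, InitialDistributionEstimator
from .states import propagate

_SMOOTH = 1e-12


def kl_divergence(empirical: np.ndarray, predicted: np.ndarray) -> float:
    """KL(empirical || predicted) with smoothing of the predicted side."""
    empirical = np.asarray(empirical, dtype=float)
    predicted = np.clip(np.asarray(predicted, dtype=float), _SMOOTH, None)
    pos = empirical > 0
    return float(np.sum(empirical[pos] * np.log(empirical[pos] / predicted[pos])))


def bhattacharyya_distance(empirical: np.ndarray, predicted: np.ndarray) -> float:
    """-ln of the Bhattacharyya coefficient of the two distributions."""
    bc = float(np.sum(np.sqrt(np.asarray(empirical) * np.asarray(predicted))))
    return -np.log(max(bc, _SMOOTH))


def _propagate_clamped(pi0, model, t: int):
    """Propagate with efficiencies clamped into [0, 1].

    A fold's model is constrained only over its training divisions; when the
    held-out day lies beyond them, the linear extrapolation may leave the
    unit interval and is truncated there.
    """
    from .states import _D, hydroxylation_matrix, methylation_matrix

    clamp = lambda x: min(max(x, 0.0), 1.0)
    pi = pi0
    for k in range(1, t + 1):
        M = methylation_matrix(clamp(model.mu_m(k)), clamp(model.mu_d(k)), clamp(model.p))
        pi = pi @ (_D @ M @ hydroxylation_matrix(clamp(model.eta(k))))
    return pi


def _fold_divergences(model, pi0, data: ObservationDataset, day: int) -> tuple[float, float]:
    pi = _propagate_clamped(pi0, model, data.divisions(day))
    kl = bh = 0.0
    for treatment in ("bs", "ox"):
        key = (day, treatment)
        if key not in data.counts:
            continue
        n = data.counts[key].astype(float)
        emp = n / n.sum()
        pred = pi @ emission_matrix(data.profiles[key])
        kl += kl_divergence(emp, pred)
        bh += bhattacharyya_distance(emp, pred)
    return kl, bh


def loocv_compare(data: ObservationDataset, n_starts: int = 10,
                  random_state: int | None = None, pi0: np.ndarray | None = None,
                  symmetric_initial: bool = False) -> pd.DataFrame:
    """Per-fold LOOCV divergences of the linear and constant models.

    Returns a DataFrame with one row per held-out day and columns
    ``kl_linear, kl_constant, bhattacharyya_linear, bhattacharyya_constant,
    kl_improvement, bhattacharyya_improvement`` (improvement =
    (constant - linear)/constant).  Requires at least three post-day-0
    observation days so that every training fold retains two.
    """
    days = data.post_days
    if len(days) < 3:
        raise ValueError(
            f"LOOCV needs at least 3 post-day-0 observation days, got {len(days)}"
        )
    if pi0 is None:
        pi0 = InitialDistributionEstimator(
            n_starts=n_starts, symmetric=symmetric_initial, random_state=random_state
        ).fit(data).pi0_

    rng = np.random.default_rng(random_state)
    rows = []
    for day in days:
        train = data.subset([0] + [d for d in days if d != day])
        seeds = rng.integers(0, 2**31 - 1, size=2)
        divs = {}
        for label, constant, seed in (("linear", False, seeds[0]), ("constant", True, seeds[1])):
            est = EfficiencyEstimator(
                n_starts=n_starts, constant=constant, random_state=int(seed)
            ).fit(train, pi0=pi0)
            divs[label] = _fold_divergences(est.model_, pi0, data, day)
        kl_lin, bh_lin = divs["linear"]
        kl_con, bh_con = divs["constant"]
        rows.append({
            "held_out_day": day,
            "kl_linear": kl_lin, "kl_constant": kl_con,
            "bhattacharyya_linear": bh_lin, "bhattacharyya_constant": bh_con,
            "kl_improvement": (kl_con - kl_lin) / kl_con if kl_con > 0 else 0.0,
            "bhattacharyya_improvement": (bh_con - bh_lin) / bh_con if bh_con > 0 else 0.0,
        })
    return pd.DataFrame(rows)
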