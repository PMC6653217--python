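"""Cohort-level validation: NMF patient clustering, metastasis association
and lung-metastasis-free (LMF) survival.

Patients are clustered unsupervised with non-negative matrix factorization
of a log2(x+1)-transformed expression panel (multiplicative Frobenius
updates, best of several seeded restarts); cluster membership is tested for
association with the metastasis label by Pearson chi-square.  For a single
gene, patients split at the arithmetic mean expression into high/low groups
whose LMF survival is compared by the Kaplan-Meier estimator and the
log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


@dataclass
class SurvivalRecord:
    """One patient's follow-up for lung-metastasis-free survival."""

    patient_id: str
    time: float
    event: int
    group: str | None = None  # high / low
    metastasis_label: int | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("follow-up time must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


@dataclass
class NmfResult:
    basis: np.ndarray        # genes x k
    weights: np.ndarray      # k x patients
    cluster: np.ndarray      # patient -> argmax component
    objective: float
    objective_history: np.ndarray
    seed: int


def _nmf_once(
    X: np.ndarray, k: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    eps = 1e-12
    m, n = X.shape
    scale = np.sqrt(X.mean() / k) or 1.0
    W = rng.uniform(0.1, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, n)) * scale
    history = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ H @ H.T + eps)
        obj = float(np.linalg.norm(X - W @ H) ** 2)
        if history and obj > history[-1] * (1 + 1e-9) + 1e-12:
            raise RuntimeError("NMF objective increased between iterations")
        history.append(obj)
        if prev - obj < tol * max(prev, 1.0):
            break
        prev = obj
    return W, H, np.array(history)


def nmf_cluster(
    expr_matrix: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 30,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> NmfResult:
    """Cluster patients (columns) by NMF of a non-negative genes x patients
    matrix; a patient's cluster is the argmax component of its weights.

    Multiplicative Frobenius updates guarantee a non-increasing objective,
    which is asserted every iteration; the best of ``n_restarts`` random
    initializations (by final objective) is returned.  Deterministic given
    ``seed``.
    """
    X = np.asarray(expr_matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("NMF requires a non-negative matrix")
    if k < 2:
        raise ValueError("k must be >= 2")
    best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        W, H, history = _nmf_once(X, k, max_iter, tol, rng)
        if best is None or history[-1] < best[2][-1]:
            best = (W, H, history)
    W, H, history = best
    # factor scales are arbitrary (W column vs H row); normalize W columns
    # so the per-patient argmax compares components on a common scale
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    H_scaled = H * norms[:, None]
    return NmfResult(W, H, H_scaled.argmax(axis=0), float(history[-1]), history, seed)


def contingency_chisq(
    clusters: Sequence[int], labels: Sequence[int]
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the cluster x label
    contingency table."""
    table = pd.crosstab(np.asarray(clusters), np.asarray(labels)).values
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs at least two rows and columns")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def split_by_mean(values: Mapping[str, float]) -> dict[str, str]:
    """Per-patient high/low split at the arithmetic mean (ties go low)."""
    if len(values) < 2:
        raise ValueError("need at least 2 patients to split")
    mean = float(np.mean(list(values.values())))
    return {p: ("high" if v > mean else "low") for p, v in values.items()}


def _to_arrays(
    records: Sequence[SurvivalRecord] | tuple[Sequence[float], Sequence[int]],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, tuple):
        times, events = records
    else:
        times = [r.time for r in records]
        events = [r.event for r in records]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("negative follow-up times")
    return t, e


def km_curve(
    records: Sequence[SurvivalRecord] | tuple[Sequence[float], Sequence[int]],
) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate S(t).

    Returns a stepwise table with one row per distinct time (plus t=0);
    S(0) = 1 and the curve is non-increasing and right-continuous.
    """
    t, e = _to_arrays(records)
    if len(t) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Evaluate a km_curve table at time ``t`` (right-continuous step)."""
    mask = curve["time"] <= t
    return float(curve.loc[mask, "survival"].iloc[-1]) if mask.any() else 1.0


def logrank_test(
    records_a: Sequence[SurvivalRecord] | tuple[Sequence[float], Sequence[int]],
    records_b: Sequence[SurvivalRecord] | tuple[Sequence[float], Sequence[int]],
) -> tuple[float, float]:
    """Standard (unweighted) log-rank test between two groups.

    The statistic is chi-square distributed with 1 df under the null; with
    no events in either group the test is undefined and (0, 1) is returned
    with a warning.
    """
    ta, ea = _to_arrays(records_a)
    tb, eb = _to_arrays(records_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined, p = 1")
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
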