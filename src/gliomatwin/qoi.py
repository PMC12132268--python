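"""Prediction map, clinical quantities of interest, and pushforwards.

A prediction is a forward solve over (t0, t_pred) from a given initial state.
Four QoIs summarize a predicted state u against a reference: total tumor
cellularity (integral of the thresholded state), tumor volume (measure of the
thresholded region), Lin's concordance correlation coefficient (voxelwise
agreement with a penalty for leaving the identity line), and the Dice overlap
of thresholded regions.  The measurable-tumor threshold defaults to 0.1
volume fraction.  Pushforward distributions are Monte-Carlo: sample the
parameter distribution, predict, score — prior predictive vs posterior
(Laplace) predictive distributions are compared with Mann-Whitney (location)
and Levene (spread) tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .forward import ForwardSettings, ParameterField, TreatmentSchedule, solve_forward
from .geometry import TissueDomain, VoxelGrid, observation_matrix

DEFAULT_THRESHOLD = 0.1


def predict(
    m: ParameterField,
    u0: np.ndarray,
    t0: float,
    t_pred: float,
    schedule: TreatmentSchedule,
    settings: ForwardSettings,
    domain: TissueDomain,
) -> np.ndarray:
    """State at t_pred from u0 at t0 (t_pred == t0 returns u0 unchanged)."""
    if t_pred < t0:
        raise ValueError("t_pred must be >= t0")
    if t_pred == t0:
        return np.asarray(u0, dtype=float).copy()
    s = ForwardSettings(
        dt=settings.dt, t0=t0, tf=t_pred,
        newton_tol=settings.newton_tol,
        max_newton_per_step=settings.max_newton_per_step,
    )
    return solve_forward(u0, m, schedule, s, domain).final


def measurable_region(u: np.ndarray, threshold: float = DEFAULT_THRESHOLD):
    """Thresholded state u_hat (u where u > threshold, else 0) and indicator."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    u = np.asarray(u, dtype=float)
    ind = (u > threshold).astype(float)
    return u * ind, ind


def total_tumor_cellularity(
    u: np.ndarray, domain: TissueDomain, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """q_TTC = integral of the thresholded volume fraction [mm^dim].

    Vertex (lumped-mass) quadrature: appropriate for the discontinuous
    thresholded integrand.
    """
    uhat, _ = measurable_region(u, threshold)
    return float(domain.lumped_mass @ uhat)


def tumor_volume(
    u: np.ndarray, domain: TissueDomain, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """q_TV = measure of the measurable-tumor region [mm^dim]."""
    _, ind = measurable_region(u, threshold)
    return float(domain.lumped_mass @ ind)


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length vectors with >= 2 entries")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise ValueError("CCC undefined for two constant inputs")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); both empty counts as 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("indicator sets must share a support")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0  # perfect agreement on absence
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def compare_distributions(a: np.ndarray, b: np.ndarray) -> tuple:
    """(Mann-Whitney U two-sided p, Levene p) for location and spread."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 20 or len(b) < 20:
        raise ValueError("need at least 20 samples per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise ValueError("degenerate comparison: all samples identical")
    mw = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    lev = stats.levene(a, b).pvalue
    return float(mw), float(lev)


@dataclass
class PredictionSetup:
    """Everything needed to score one predicted state against the truth."""

    domain: TissueDomain
    u0: np.ndarray
    t0: float
    t_pred: float
    schedule: TreatmentSchedule
    settings: ForwardSettings
    grid: VoxelGrid | None = None
    truth_voxels: np.ndarray | None = None      # noise-free truth at t_pred
    truth_volume: float | None = None           # q_TV of the truth at t_pred
    truth_cellularity: float | None = None      # q_TTC of the truth
    threshold: float = DEFAULT_THRESHOLD


def _score(u_pred: np.ndarray, setup: PredictionSetup, B) -> dict:
    out = {
        "total_cellularity": total_tumor_cellularity(
            u_pred, setup.domain, setup.threshold
        ),
        "tumor_volume": tumor_volume(u_pred, setup.domain, setup.threshold),
    }
    if setup.truth_volume is not None:
        out["rel_error_volume"] = (
            out["tumor_volume"] - setup.truth_volume
        ) / setup.truth_volume
    if setup.truth_cellularity is not None:
        out["rel_error_cellularity"] = (
            out["total_cellularity"] - setup.truth_cellularity
        ) / setup.truth_cellularity
    if setup.truth_voxels is not None and B is not None:
        pred_vox = B @ u_pred
        out["ccc"] = ccc(pred_vox, setup.truth_voxels)
        out["dice"] = dice(
            pred_vox > setup.threshold, setup.truth_voxels > setup.threshold
        )
    return out


def pushforward_qoi(
    dist,
    n: int,
    seed: int,
    setup: PredictionSetup,
    provenance: str = "sample",
    param_map=None,
) -> pd.DataFrame:
    """Push n parameter samples through the prediction map and score QoIs.

    ``dist`` is anything with ``sample(n, seed) -> (n, dim)`` returning block
    parameter vectors (a BlockPrior or a LaplacePosterior), or a callable
    mapping a sample index to a ParameterField.  Individual forward failures
    are recorded (``failed=True``) rather than fatal.  Returns a tidy frame
    with one row per sample and one column per QoI.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from .map_estimation import IdentityParameterMap  # avoid cycle

    samples = dist.sample(n, seed)
    pm = (
        param_map
        or getattr(dist, "param_map", None)
        or IdentityParameterMap(setup.domain.n_vertices)
    )
    B = (
        observation_matrix(setup.domain, setup.grid)
        if setup.grid is not None
        else None
    )
    rows = []
    for i in range(n):
        rec = {"sample_id": i, "provenance": provenance, "t_pred": setup.t_pred,
               "failed": False}
        try:
            fields = pm.to_fields(samples[i])
            u_pred = predict(
                fields, setup.u0, setup.t0, setup.t_pred,
                setup.schedule, setup.settings, setup.domain,
            )
            rec.update(_score(u_pred, setup, B))
        except Exception as err:  # per-sample failure is data, not a crash
            rec["failed"] = True
            rec["error"] = str(err)
        rows.append(rec)
    return pd.DataFrame(rows)


def score_single(m: ParameterField, setup: PredictionSetup) -> dict:
    """QoIs of one deterministic prediction (e.g. MAP or truth parameters)."""
    B = (
        observation_matrix(setup.domain, setup.grid)
        if setup.grid is not None
        else None
    )
    u_pred = predict(
        m, setup.u0, setup.t0, setup.t_pred, setup.schedule,
        setup.settings, setup.domain,
    )
    return _score(u_pred, setup, B)
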