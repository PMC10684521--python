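"""Population trajectories in a low-dimensional value-context space.

Trials are sorted into four conditions by subject-specific median splits
of the current and previous trial's bid: [current, previous] =
[high, low], [high, high], [low, low], [low, high].  After Gaussian
temporal smoothing and subtraction of each contact's mean timeseries,
the condition-averaged activity matrices X_c (contacts x time) are
stacked side by side into X (contacts x 4*time) and analyzed two ways:

* PCA with contacts as features and timepoints as observations, each
  condition projected onto the first two principal components;
* a regression subspace: a projector D onto the span of the top
  principal components denoises the per-timepoint coefficient vectors
  of the encoding model, the timepoint with the largest denoised-vector
  L2 norm is selected per variable, and the two selected vectors are
  orthogonalized by QR decomposition into a current-value axis and a
  previous-value axis onto which each X_c is projected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA

from .core import GLMResult, PowerEpochs, TIME_STEP

logger = logging.getLogger(__name__)

#: Fixed condition order used for stacking: (current, previous).
CONDITION_ORDER = ("high_low", "high_high", "low_low", "low_high")

#: Gaussian smoothing windows (FWHM, ms) the analysis supports.
SMOOTHING_CHOICES = (0, 100, 200, 300, 400)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_timeseries(a: np.ndarray, fwhm_ms: float, dt_ms: float = None) -> np.ndarray:
    """Gaussian smoothing along the last axis.

    ``fwhm_ms`` is the full width at half maximum of the kernel in
    milliseconds; the kernel is truncated at +-3 sigma and renormalized
    at the epoch edges (division by the smoothed all-ones series), so no
    energy leaks outside the epoch.
    """
    if fwhm_ms == 0:
        return np.asarray(a, dtype=float)
    if dt_ms is None:
        dt_ms = TIME_STEP * 1000
    sigma = fwhm_ms * _FWHM_TO_SIGMA / dt_ms
    num = gaussian_filter1d(np.asarray(a, dtype=float), sigma, axis=-1,
                            mode="constant", cval=0.0, truncate=3.0)
    den = gaussian_filter1d(np.ones(a.shape[-1]), sigma,
                            mode="constant", cval=0.0, truncate=3.0)
    return num / den


@dataclass
class ConditionSet:
    """Per-trial condition labels and the subject medians behind them."""

    labels: pd.DataFrame  # subject, trial_index, condition (or None)
    medians: dict  # subject -> median bid


@dataclass
class PopulationData:
    """Condition-averaged population activity ready for projection."""

    conditions: ConditionSet
    X_c: dict  # condition -> (n_contacts, n_time)
    X: np.ndarray  # (n_contacts, 4 * n_time)
    n_time: int
    contact_ids: list
    smoothing_ms: float


@dataclass
class TaskAxes:
    """Two orthonormal contact-space axes (current, previous value)."""

    axes: np.ndarray  # (n_contacts, 2)
    t_max: np.ndarray  # (2,) selected timepoint index per variable
    source: str  # "pca" or "regression"

    def __post_init__(self) -> None:
        gram = self.axes.T @ self.axes
        if not np.allclose(gram, np.eye(2), atol=1e-10):
            raise ValueError("axis columns are not orthonormal")


@dataclass
class TrajectorySet:
    """Condition trajectories: coords (n_conditions, n_time, 2)."""

    coords: np.ndarray
    axis_names: tuple
    condition_order: tuple = CONDITION_ORDER
    explained_variance_ratio: np.ndarray | None = None

    def to_frame(self, time: np.ndarray) -> pd.DataFrame:
        rows = []
        for ci, cond in enumerate(self.condition_order):
            rows.append(
                pd.DataFrame(
                    {
                        "condition": cond,
                        "time_ms": time * 1000,
                        "axis1": self.coords[ci, :, 0],
                        "axis2": self.coords[ci, :, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def label_conditions(trials: pd.DataFrame, tie: str = "low") -> ConditionSet:
    """Median-split condition labels per trial.

    The median is the subject's own, over all valid trials' bids.  A bid
    strictly above the median is "high"; a bid at the median goes to the
    ``tie`` side (default "low").  A trial is labelled only when it and
    its immediately preceding presented trial are both valid.
    """
    if tie not in ("low", "high"):
        raise ValueError("tie must be 'low' or 'high'")
    medians = {}
    frames = []
    for s, grp in trials.groupby("subject"):
        grp = grp.sort_values("trial_index")
        med = float(grp.loc[grp["valid"], "bid"].median())
        medians[s] = med
        bid = grp["bid"].to_numpy(dtype=float)
        idx = grp["trial_index"].to_numpy()
        valid = grp["valid"].to_numpy(dtype=bool)
        if tie == "low":
            hi = bid > med
        else:
            hi = bid >= med
        cond = np.full(len(grp), None, dtype=object)
        for i in range(1, len(grp)):
            if valid[i] and valid[i - 1] and idx[i] - idx[i - 1] == 1:
                cond[i] = ("high" if hi[i] else "low") + "_" + (
                    "high" if hi[i - 1] else "low"
                )
        frames.append(
            pd.DataFrame(
                {"subject": s, "trial_index": idx, "condition": cond}
            )
        )
    return ConditionSet(labels=pd.concat(frames, ignore_index=True), medians=medians)


def prepare_population(
    power: PowerEpochs,
    trials: pd.DataFrame,
    contacts: pd.DataFrame,
    smoothing_ms: float = 400,
    tie: str = "low",
) -> PopulationData:
    """Build the condition matrices X_c and the stacked matrix X.

    Per contact: smooth every trial's timeseries, subtract the mean
    timeseries across all of the subject's valid trials, then average
    within each condition.  A contact whose subject has no trials in
    some condition contributes a zero row for that condition (the grand
    mean), with a warning.
    """
    if smoothing_ms not in SMOOTHING_CHOICES:
        raise ValueError(f"smoothing_ms must be one of {SMOOTHING_CHOICES}")
    conditions = label_conditions(trials, tie=tie)
    labels = conditions.labels
    n_contacts = power.n_contacts
    n_time = power.time.size
    X_c = {c: np.zeros((n_contacts, n_time)) for c in CONDITION_ORDER}
    contact_rows = {cid: i for i, cid in enumerate(power.contact_ids)}

    for subj, sub_contacts in contacts.groupby("subject"):
        sub = labels[labels["subject"] == subj].sort_values("trial_index")
        cond = sub["condition"].to_numpy()
        tr_valid = (
            trials[trials["subject"] == subj]
            .sort_values("trial_index")["valid"]
            .to_numpy(dtype=bool)
        )
        cond_rows = {c: np.flatnonzero(cond == c) for c in CONDITION_ORDER}
        for c, rows_c in cond_rows.items():
            if rows_c.size == 0:
                logger.warning("subject %s has no trials in condition %s", subj, c)
        for cid in sub_contacts["contact"]:
            if cid not in contact_rows:
                continue
            ci = contact_rows[cid]
            arr = smooth_timeseries(power.power[ci], smoothing_ms)
            arr = arr - arr[tr_valid].mean(axis=0, keepdims=True)
            for c, rows_c in cond_rows.items():
                if rows_c.size:
                    X_c[c][ci] = arr[rows_c].mean(axis=0)
    X = np.concatenate([X_c[c] for c in CONDITION_ORDER], axis=1)
    return PopulationData(
        conditions=conditions,
        X_c=X_c,
        X=X,
        n_time=n_time,
        contact_ids=list(power.contact_ids),
        smoothing_ms=smoothing_ms,
    )


def _fit_pca(X: np.ndarray, n_components: int, center: bool) -> PCA:
    # observations are the stacked timepoints, features the contacts
    obs = X.T.copy()
    if not center:
        obs = np.vstack([obs, -obs])  # symmetrize so the mean is exactly 0
    pca = PCA(n_components=n_components)
    pca.fit(obs)
    return pca


def pca_trajectories(
    pop: PopulationData, center: bool = True
) -> TrajectorySet:
    """Project each condition onto the first two principal components."""
    rank = np.linalg.matrix_rank(pop.X - pop.X.mean(axis=1, keepdims=True))
    if rank < 2:
        raise ValueError("stacked data matrix has rank < 2")
    pca = _fit_pca(pop.X, 2, center)
    mean = pca.mean_  # (n_contacts,)
    coords = np.empty((len(CONDITION_ORDER), pop.n_time, 2))
    for ci, c in enumerate(CONDITION_ORDER):
        coords[ci] = (pop.X_c[c] - mean[:, None]).T @ pca.components_.T
    return TrajectorySet(
        coords=coords,
        axis_names=("PC1", "PC2"),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def denoising_matrix(
    pop: PopulationData | np.ndarray, n_pc: int = 12, center: bool = True
) -> np.ndarray:
    """Projector onto the span of the top ``n_pc`` principal components.

    D = sum_i PC_i PC_i^T is symmetric and idempotent with trace n_pc.
    """
    X = pop.X if isinstance(pop, PopulationData) else np.asarray(pop, dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=1, keepdims=True) if center else X)
    if n_pc > rank:
        raise ValueError(f"n_pc={n_pc} exceeds data rank {rank}")
    pca = _fit_pca(X, n_pc, center)
    V = pca.components_  # (n_pc, n_contacts)
    return V.T @ V


def regression_axes(
    glm: GLMResult,
    D: np.ndarray,
    variables: tuple = ("sv_current", "sv_previous"),
) -> TaskAxes:
    """Orthonormal task axes from denoised encoding coefficients.

    Per variable, every timepoint's coefficient vector across contacts
    is denoised with D; the timepoint with the largest L2 norm is
    selected (ties broken toward the earliest), and the two selected
    vectors, ordered (current, previous), are orthogonalized by QR.
    Each axis is sign-flipped if needed so that its inner product with
    its own raw selected vector is positive.
    """
    cols = []
    t_max = []
    for v in variables:
        B = glm.coef(v)  # (n_contacts, n_time)
        ok = glm.usable
        B = np.where(ok[:, None], B, 0.0)
        B_d = D @ B
        norms = np.linalg.norm(B_d, axis=0)
        idx = int(np.argmax(norms))  # argmax takes the earliest tie
        t_max.append(idx)
        cols.append(B_d[:, idx])
    Bmax = np.column_stack(cols)
    if np.linalg.matrix_rank(Bmax) < 2:
        raise ValueError("selected coefficient vectors are collinear")
    Q, R = np.linalg.qr(Bmax)
    Q = Q[:, :2]
    for j in range(2):
        if Q[:, j] @ Bmax[:, j] < 0:
            Q[:, j] = -Q[:, j]
    return TaskAxes(axes=Q, t_max=np.asarray(t_max), source="regression")


def project_conditions(pop: PopulationData, axes: TaskAxes) -> TrajectorySet:
    """P_{v,c} = axes^T X_c: four 2D trajectories over the epoch."""
    if axes.axes.shape[0] != len(pop.contact_ids):
        raise ValueError("axes and population data disagree on contact count")
    coords = np.empty((len(CONDITION_ORDER), pop.n_time, 2))
    for ci, c in enumerate(CONDITION_ORDER):
        coords[ci] = (axes.axes.T @ pop.X_c[c]).T
    return TrajectorySet(
        coords=coords, axis_names=("current_sv_axis", "previous_sv_axis")
    )


def axis_separation(
    traj: TrajectorySet,
    variable: str,
    axis: int,
    window: slice | None = None,
) -> float:
    """Mean separation along one axis between high and low conditions.

    ``variable`` is "current" or "previous"; conditions are paired by
    the other variable's level and the mean coordinate difference
    (high minus low) along ``axis`` is averaged over ``window``.
    """
    w = window if window is not None else slice(None)
    order = {c: i for i, c in enumerate(traj.condition_order)}

    def mean_coord(cond):
        return traj.coords[order[cond], w, axis].mean()

    if variable == "current":
        return 0.5 * (
            (mean_coord("high_low") - mean_coord("low_low"))
            + (mean_coord("high_high") - mean_coord("low_high"))
        )
    if variable == "previous":
        return 0.5 * (
            (mean_coord("high_high") - mean_coord("high_low"))
            + (mean_coord("low_high") - mean_coord("low_low"))
        )
    raise ValueError("variable must be 'current' or 'previous'")
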