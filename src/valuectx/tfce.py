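"""Threshold-free cluster enhancement (TFCE) permutation inference.

TFCE replaces the arbitrary cluster-forming threshold of cluster-based
statistics: each point of a z-statistic series (or time-frequency map)
is scored by the sum, over height levels h = dh, 2dh, ..., of
e_h(p)^E * h^H * dh, where e_h(p) is the extent of the connected
supra-threshold component containing p at level h.  Signed statistics
are enhanced separately in each direction: the positive part on
max(z, 0) and the negative part as minus the TFCE of max(-z, 0).

Familywise error is controlled with maximum-statistic permutation nulls:

* group level — random half/half +-1 relabellings of the contacts, a
  per-timepoint regression of the observed coefficients on the label,
  t -> z -> TFCE, and the null of the maximum (positive tail) and
  minimum (negative tail) TFCE over the series;
* individual contact level — joint row shuffles of the trial design
  applied identically at every timepoint;
* time-frequency — the group scheme with 2D connected components
  (E = 1, H = 2).

A bootstrap of the Pearson median skewness over contacts checks the
symmetry assumption that underlies the sign-flip null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .encoding import ols_timeseries, t_to_z

__all__ = [
    "TFCEParams",
    "tfce_signed",
    "group_permutation",
    "individual_permutation",
    "tf_group_permutation",
    "classify_contacts",
    "summarize_clusters",
    "skewness_symmetry_test",
    "null_fwer",
]


@dataclass
class TFCEParams:
    """Enhancement exponents and the height discretization.

    ``dh=None`` (default) sets the level step per input as
    max|z| / n_levels; the resulting score approximates the level
    integral and is insensitive to ``n_levels`` in the 50-200 range.
    The 1D default (E=2, H=2) is used for time series; time-frequency
    maps use E=1, H=2 with 4-neighbor connectivity.
    """

    E: float = 2.0
    H: float = 2.0
    dh: float | None = None
    n_levels: int = 100
    connectivity_2d: int = 4

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_levels < 1:
            raise ValueError("n_levels must be at least 1")
        if self.connectivity_2d not in (4, 8):
            raise ValueError("connectivity_2d must be 4 or 8")


TF_PARAMS = TFCEParams(E=1.0, H=2.0)


def _levels(dh: float, top: float, n_levels: int) -> np.ndarray:
    if dh is None:
        raise ValueError("dh unresolved")
    n = max(1, int(np.ceil(top / dh - 1e-12)))
    return dh * np.arange(1, n + 1)


def _tfce_nonneg_1d(a: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    """Exact level summation for one non-negative 1D series."""
    out = np.zeros_like(a)
    top = a.max()
    if top <= 0 or dh is None or dh <= 0:
        return out
    for h in _levels(dh, top, 0):
        mask = a >= h
        if not mask.any():
            break
        lab, n_lab = ndimage.label(mask)
        sizes = np.bincount(lab.ravel())
        out[mask] += sizes[lab[mask]] ** E * h**H * dh
    return out


def _tfce_nonneg_2d(
    a: np.ndarray, E: float, H: float, dh: float, connectivity: int
) -> np.ndarray:
    out = np.zeros_like(a)
    top = a.max()
    if top <= 0 or dh is None or dh <= 0:
        return out
    structure = (
        ndimage.generate_binary_structure(2, 1)
        if connectivity == 4
        else ndimage.generate_binary_structure(2, 2)
    )
    n = max(1, int(np.ceil(top / dh - 1e-12)))
    for h in dh * np.arange(1, n + 1):
        mask = a >= h
        if not mask.any():
            break
        lab, _ = ndimage.label(mask, structure=structure)
        sizes = np.bincount(lab.ravel())
        out[mask] += sizes[lab[mask]] ** E * h**H * dh
    return out


def tfce_signed(z: np.ndarray, params: TFCEParams | None = None) -> np.ndarray:
    """Signed TFCE of a 1D z series or a 2D z map (same shape out).

    The positive part is the TFCE of max(z, 0); the negative part is
    minus the TFCE of max(-z, 0).  With ``params.dh=None`` the level
    step is max|z| / n_levels of this input (shared by both signs).
    """
    if params is None:
        params = TFCEParams()
    z = np.asarray(z, dtype=float)
    if z.ndim not in (1, 2):
        raise ValueError("z must be 1D (time) or 2D (frequency x time)")
    if np.isnan(z).all():
        raise ValueError("z is all-NaN")
    dh = params.dh
    if dh is None:
        top = np.abs(z).max()
        if top == 0:
            return np.zeros_like(z)
        dh = top / params.n_levels
    if z.ndim == 1:
        pos = _tfce_nonneg_1d(np.maximum(z, 0.0), params.E, params.H, dh)
        neg = _tfce_nonneg_1d(np.maximum(-z, 0.0), params.E, params.H, dh)
    else:
        pos = _tfce_nonneg_2d(
            np.maximum(z, 0.0), params.E, params.H, dh, params.connectivity_2d
        )
        neg = _tfce_nonneg_2d(
            np.maximum(-z, 0.0), params.E, params.H, dh, params.connectivity_2d
        )
    return pos - neg


def _tfce_signed_batch_1d(Z: np.ndarray, params: TFCEParams) -> np.ndarray:
    """Vectorized signed TFCE for a stack of independent 1D series.

    ``Z`` is (P, T); each row gets its own level step (max|z| of that
    row divided by n_levels) unless ``params.dh`` fixes a global one.
    Fully vectorized over rows and levels via run labelling.
    """
    Z = np.asarray(Z, dtype=float)
    P, T = Z.shape
    L = params.n_levels
    if params.dh is not None:
        dh_row = np.full(P, params.dh)
        n_lev = int(np.ceil(np.abs(Z).max() / params.dh - 1e-12)) if Z.size else 1
        L = max(1, n_lev)
    else:
        dh_row = np.abs(Z).max(axis=1) / L
    def _pow(x: np.ndarray, e: float) -> np.ndarray:
        if e == 1.0:
            return x
        if e == 2.0:
            return x * x
        return x**e

    out = np.zeros_like(Z)
    for sign in (1.0, -1.0):
        A = np.maximum(sign * Z, 0.0)
        live = dh_row > 0
        if not live.any():
            continue
        a = A[live]
        dhl = dh_row[live]
        levels = dhl[:, None] * np.arange(1, L + 1)  # (p, L)
        mask = a[:, None, :] >= levels[:, :, None]  # (p, L, T)
        # a new run starts at each first True of a (row, level) slice; a
        # flat cumsum then yields globally unique run ids because every
        # slice boundary restarts the run bookkeeping
        starts = np.empty_like(mask)
        starts[:, :, 0] = mask[:, :, 0]
        np.logical_and(mask[:, :, 1:], ~mask[:, :, :-1], out=starts[:, :, 1:])
        gid = np.cumsum(starts.reshape(-1), dtype=np.int64)
        mflat = mask.reshape(-1)
        ids = gid[mflat]
        counts = np.bincount(ids)
        ext = np.zeros(mask.size)
        ext[mflat] = counts[ids]
        ext = ext.reshape(mask.shape)
        contrib = _pow(ext, params.E)
        contrib *= _pow(levels, params.H)[:, :, None]
        tf = contrib.sum(axis=1) * dhl[:, None]
        out[live] += sign * tf
    return out


def _balanced_labels(
    n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) matrix of +-1 labels, floor(n/2) of them +1 per row."""
    n_pos = n // 2
    order = rng.random((n_perm, n)).argsort(axis=1)
    S = np.where(order < n_pos, 1.0, -1.0)
    return S


def _label_regression_t(S: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """t statistic of the label slope, per permutation and timepoint.

    ``S`` is (n_perm, n_contacts) of +-1 labels; ``Y`` is
    (n_contacts, n_cols).  Per permutation and column, OLS of the
    observed coefficients on [1, label]; returns (n_perm, n_cols).
    """
    n = Y.shape[0]
    ybar = Y.mean(axis=0)  # (n_cols,)
    syy = ((Y - ybar) ** 2).sum(axis=0)
    sbar = S.mean(axis=1)  # (n_perm,)
    sxx = n * (1.0 - sbar**2)
    sxy = S @ Y - n * np.outer(sbar, ybar)
    slope = sxy / sxx[:, None]
    sse = syy[None, :] - slope**2 * sxx[:, None]
    sse = np.maximum(sse, 0.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(sse / dof / sxx[:, None])
    return np.nan_to_num(t, posinf=1e6, neginf=-1e6), dof


def _one_sample_tz(Y: np.ndarray) -> np.ndarray:
    """Across-contact one-sample t per column, mapped to z."""
    n = Y.shape[0]
    mean = Y.mean(axis=0)
    se = Y.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, 0.0)
    return t, t_to_z(t, n - 1)


@dataclass
class GroupTFCEResult:
    """Observed group statistics, permutation nulls, and the FWE mask."""

    t: np.ndarray
    z: np.ndarray
    tfce: np.ndarray
    max_stats: np.ndarray
    min_stats: np.ndarray
    upper: float
    lower: float
    mask: np.ndarray
    p: np.ndarray
    n_perm: int
    seed: int | None
    alpha: float


def group_permutation(
    betas: np.ndarray,
    params: TFCEParams | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> GroupTFCEResult:
    """Group-level sign-flip TFCE test over a contacts x time beta matrix.

    The observed statistic at each timepoint is the one-sample t of the
    coefficients across contacts, mapped to z and enhanced with TFCE.
    Each of ``n_perm`` permutations assigns +1 to half of the contacts
    and -1 to the rest (one assignment for all timepoints), regresses
    the coefficients on the label per timepoint, and records the maximum
    and minimum TFCE of the resulting z series.  A timepoint is declared
    significant (one-tailed in each direction, FWE-corrected) when its
    observed TFCE exceeds the (1-alpha) quantile of the max null or
    falls below the alpha quantile of the min null.
    """
    if params is None:
        params = TFCEParams()
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 2:
        raise ValueError("betas must be (n_contacts, n_time)")
    n_contacts = betas.shape[0]
    if n_contacts < 4:
        raise ValueError("need at least 4 contacts")
    rng = np.random.default_rng(seed)

    t_obs, z_obs = _one_sample_tz(betas)
    tfce_obs = tfce_signed(z_obs, params)

    S = _balanced_labels(n_contacts, n_perm, rng)
    t_perm, dof = _label_regression_t(S, betas)
    z_perm = t_to_z(t_perm, dof)
    tf_perm = _tfce_signed_batch_1d(z_perm, params)
    max_stats = tf_perm.max(axis=1)
    min_stats = tf_perm.min(axis=1)

    upper = float(np.quantile(max_stats, 1.0 - alpha, method="higher"))
    lower = float(np.quantile(min_stats, alpha, method="lower"))
    mask = (tfce_obs > upper) | (tfce_obs < lower)

    p_pos = (1 + (max_stats[:, None] >= tfce_obs[None, :]).sum(axis=0)) / (1 + n_perm)
    p_neg = (1 + (min_stats[:, None] <= tfce_obs[None, :]).sum(axis=0)) / (1 + n_perm)
    p = np.where(tfce_obs >= 0, p_pos, p_neg)

    return GroupTFCEResult(
        t=t_obs,
        z=z_obs,
        tfce=tfce_obs,
        max_stats=max_stats,
        min_stats=min_stats,
        upper=upper,
        lower=lower,
        mask=mask,
        p=p,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )


@dataclass
class ContactTFCEResult:
    """Per-contact permutation outcome for the regressors of interest."""

    names: list
    tfce: np.ndarray  # (n_reg, n_time)
    mask: np.ndarray  # (n_reg, n_time)
    extreme_t: np.ndarray  # (n_reg,) t at the most extreme TFCE timepoint
    extreme_time_idx: np.ndarray  # (n_reg,)
    significant: np.ndarray  # (n_reg,) any timepoint significant
    n_perm: int


def individual_permutation(
    Y: np.ndarray,
    X: np.ndarray,
    names: list,
    of_interest: list | None = None,
    params: TFCEParams | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ContactTFCEResult:
    """Trial-shuffle TFCE test for a single contact.

    ``Y`` is (n_trials, n_time) power, ``X`` the (n_trials, k) design.
    Each permutation shuffles the design rows jointly — the same row
    order at every timepoint — refits the per-timepoint OLS, and records
    the max/min TFCE of each regressor of interest's z series.  The most
    extreme observed TFCE timepoint (ties broken toward the earliest) is
    reported with its t statistic.
    """
    if params is None:
        params = TFCEParams()
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n < k + 2:
        raise ValueError("too few trials for a usable design")
    if of_interest is None:
        of_interest = [nm for nm in names if nm != "const"]
    j_idx = [names.index(nm) for nm in of_interest]
    rng = np.random.default_rng(seed)

    _, _, t_obs, z_obs, dof = ols_timeseries(Y, X)
    n_reg = len(j_idx)
    n_time = Y.shape[1]
    tfce_obs = np.empty((n_reg, n_time))
    for r, j in enumerate(j_idx):
        tfce_obs[r] = tfce_signed(z_obs[j], params)

    t_perm = np.empty((n_reg, n_perm, n_time))
    dof_p = n - k
    for p_i in range(n_perm):
        Xp = X[rng.permutation(n)]
        xtx_inv = np.linalg.inv(Xp.T @ Xp)
        beta = xtx_inv @ (Xp.T @ Y)
        resid = Y - Xp @ beta
        sigma2 = (resid**2).sum(axis=0) / dof_p
        d = np.diag(xtx_inv)
        for r, j in enumerate(j_idx):
            se = np.sqrt(d[j] * sigma2)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_perm[r, p_i] = np.where(se > 0, beta[j] / se, 0.0)
    z_perm = t_to_z(t_perm, dof_p)

    mask = np.zeros((n_reg, n_time), dtype=bool)
    extreme_t = np.empty(n_reg)
    extreme_idx = np.empty(n_reg, dtype=int)
    significant = np.zeros(n_reg, dtype=bool)
    for r, j in enumerate(j_idx):
        tf_perm = _tfce_signed_batch_1d(z_perm[r], params)
        upper = np.quantile(tf_perm.max(axis=1), 1.0 - alpha, method="higher")
        lower = np.quantile(tf_perm.min(axis=1), alpha, method="lower")
        mask[r] = (tfce_obs[r] > upper) | (tfce_obs[r] < lower)
        significant[r] = mask[r].any()
        idx = int(np.argmax(np.abs(tfce_obs[r])))
        extreme_idx[r] = idx
        extreme_t[r] = t_obs[j, idx]
    return ContactTFCEResult(
        names=list(of_interest),
        tfce=tfce_obs,
        mask=mask,
        extreme_t=extreme_t,
        extreme_time_idx=extreme_idx,
        significant=significant,
        n_perm=n_perm,
    )


def classify_contacts(
    sig_current: np.ndarray,
    sig_previous: np.ndarray,
    contact_ids: list | None = None,
    extreme_t_current: np.ndarray | None = None,
    extreme_t_previous: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Four-way partition of contacts by which value signals they carry.

    Returns the per-contact table and the proportions of each category
    among all contacts plus the current/previous/both shares among the
    significant contacts.
    """
    sig_current = np.asarray(sig_current, dtype=bool)
    sig_previous = np.asarray(sig_previous, dtype=bool)
    if sig_current.shape != sig_previous.shape:
        raise ValueError("mask shapes differ")
    n = sig_current.size
    if contact_ids is None:
        contact_ids = list(range(n))
    category = np.where(
        sig_current & sig_previous,
        "both",
        np.where(
            sig_current,
            "current_only",
            np.where(sig_previous, "previous_only", "neither"),
        ),
    )
    table = pd.DataFrame({"contact": contact_ids, "category": category})
    if extreme_t_current is not None:
        table["t_current"] = extreme_t_current
    if extreme_t_previous is not None:
        table["t_previous"] = extreme_t_previous
    n_sig = int((category != "neither").sum())
    props = {
        "n_contacts": n,
        "n_significant": n_sig,
        "frac_significant": n_sig / n if n else np.nan,
    }
    for cat in ("current_only", "previous_only", "both", "neither"):
        props[f"frac_{cat}_all"] = float((category == cat).mean()) if n else np.nan
    for cat in ("current_only", "previous_only", "both"):
        props[f"frac_{cat}_significant"] = (
            float((category == cat).sum() / n_sig) if n_sig else np.nan
        )
    return table, props


def summarize_clusters(
    mask: np.ndarray,
    tfce: np.ndarray,
    max_stats: np.ndarray,
    min_stats: np.ndarray,
    time: np.ndarray,
    regressor: str = "",
) -> pd.DataFrame:
    """Table of maximal runs of FWE-significant timepoints.

    Per cluster: size in timepoints, start/end/peak in ms relative to
    onset (peak = the timepoint of the most extreme TFCE within the
    cluster), the extreme signed TFCE, and its p value against the max
    null (positive clusters) or min null (negative clusters).
    """
    mask = np.asarray(mask, dtype=bool)
    tfce = np.asarray(tfce, dtype=float)
    n_perm = max_stats.size
    rows = []
    if mask.any():
        lab, n_lab = ndimage.label(mask)
        for li in range(1, n_lab + 1):
            pts = np.flatnonzero(lab == li)
            seg = tfce[pts]
            k = int(np.argmax(np.abs(seg)))
            extreme = float(seg[k])
            if extreme >= 0:
                p = (1 + (max_stats >= extreme).sum()) / (1 + n_perm)
            else:
                p = (1 + (min_stats <= extreme).sum()) / (1 + n_perm)
            rows.append(
                {
                    "regressor": regressor,
                    "cluster_size": pts.size,
                    "start_ms": float(time[pts[0]] * 1000),
                    "end_ms": float(time[pts[-1]] * 1000),
                    "peak_ms": float(time[pts[k]] * 1000),
                    "extreme_tfce": extreme,
                    "p": float(p),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "regressor",
            "cluster_size",
            "start_ms",
            "end_ms",
            "peak_ms",
            "extreme_tfce",
            "p",
        ],
    )


def tf_group_permutation(
    betas: np.ndarray,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> GroupTFCEResult:
    """Group sign-flip TFCE test on a (contacts, freq, time) beta stack.

    Same labelling scheme as the 1D group test; connected components are
    2D in time-frequency space (E=1, H=2 by default, 4-neighbor).
    """
    if params is None:
        params = TF_PARAMS
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 3:
        raise ValueError("betas must be (n_contacts, n_freq, n_time)")
    n_contacts, n_freq, n_time = betas.shape
    if n_contacts < 4:
        raise ValueError("need at least 4 contacts")
    rng = np.random.default_rng(seed)
    flat = betas.reshape(n_contacts, n_freq * n_time)

    t_obs, z_obs = _one_sample_tz(flat)
    tfce_obs = tfce_signed(z_obs.reshape(n_freq, n_time), params)

    S = _balanced_labels(n_contacts, n_perm, rng)
    t_perm, dof = _label_regression_t(S, flat)
    z_perm = t_to_z(t_perm, dof)
    max_stats = np.empty(n_perm)
    min_stats = np.empty(n_perm)
    for i in range(n_perm):
        tf_map = tfce_signed(z_perm[i].reshape(n_freq, n_time), params)
        max_stats[i] = tf_map.max()
        min_stats[i] = tf_map.min()
    upper = float(np.quantile(max_stats, 1.0 - alpha, method="higher"))
    lower = float(np.quantile(min_stats, alpha, method="lower"))
    mask = (tfce_obs > upper) | (tfce_obs < lower)
    p_pos = (1 + (max_stats[:, None] >= tfce_obs.ravel()[None, :]).sum(axis=0)) / (
        1 + n_perm
    )
    p_neg = (1 + (min_stats[:, None] <= tfce_obs.ravel()[None, :]).sum(axis=0)) / (
        1 + n_perm
    )
    p = np.where(tfce_obs.ravel() >= 0, p_pos, p_neg).reshape(n_freq, n_time)
    return GroupTFCEResult(
        t=t_obs.reshape(n_freq, n_time),
        z=z_obs.reshape(n_freq, n_time),
        tfce=tfce_obs,
        max_stats=max_stats,
        min_stats=min_stats,
        upper=upper,
        lower=lower,
        mask=mask,
        p=p,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )


@dataclass
class SymmetryResult:
    skewness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    symmetric: np.ndarray
    n_boot: int


def pearson_median_skewness(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """3 * (mean - median) / SD (sample SD, ddof=1)."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=axis)
    median = np.median(x, axis=axis)
    sd = x.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, 3.0 * (mean - median) / sd, np.nan)


def skewness_symmetry_test(
    betas: np.ndarray,
    n_boot: int = 10000,
    seed: int | None = None,
    ci: float = 0.95,
    chunk: int = 200,
) -> SymmetryResult:
    """Bootstrap test of distributional symmetry across contacts.

    Per timepoint, the Pearson median skewness of the coefficients
    across contacts is bootstrapped by resampling contacts with
    replacement (the same resample at every timepoint).  A timepoint is
    compatible with symmetry when the percentile CI contains 0.
    Timepoints with zero cross-contact SD yield NaN skewness and are
    flagged asymmetric-indeterminate (symmetric=False).
    """
    betas = np.asarray(betas, dtype=float)
    n_contacts, n_time = betas.shape
    if n_contacts < 3:
        raise ValueError("need at least 3 contacts")
    rng = np.random.default_rng(seed)
    obs = pearson_median_skewness(betas, axis=0)
    boots = np.empty((n_boot, n_time))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n_contacts, size=(m, n_contacts))
        sample = betas[idx]  # (m, n_contacts, n_time)
        boots[done : done + m] = pearson_median_skewness(sample, axis=1)
        done += m
    lo = np.nanquantile(boots, (1 - ci) / 2, axis=0)
    hi = np.nanquantile(boots, 1 - (1 - ci) / 2, axis=0)
    symmetric = (lo <= 0) & (hi >= 0) & np.isfinite(obs)
    return SymmetryResult(
        skewness=obs, ci_low=lo, ci_high=hi, symmetric=symmetric, n_boot=n_boot
    )


def null_fwer(
    n_datasets: int = 1000,
    n_contacts: int = 20,
    n_time: int = 30,
    n_perm: int = 300,
    params: TFCEParams | None = None,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> dict:
    """Empirical familywise error rate of the group test on null data.

    Draws ``n_datasets`` independent coefficient matrices with no true
    effect (i.i.d. standard normal), runs the group sign-flip TFCE test
    on each, and reports the fraction of datasets in which any timepoint
    is declared significant.
    """
    if params is None:
        params = TFCEParams()
    root = np.random.SeedSequence(seed)
    data_ss, perm_ss = root.spawn(2)
    data_rng = np.random.default_rng(data_ss)
    perm_seeds = perm_ss.generate_state(n_datasets)
    hits = 0
    for i in range(n_datasets):
        betas = data_rng.standard_normal((n_contacts, n_time))
        res = group_permutation(
            betas, params, n_perm=n_perm, seed=int(perm_seeds[i]), alpha=alpha
        )
        hits += bool(res.mask.any())
    return {
        "fwer": hits / n_datasets,
        "n_datasets": n_datasets,
        "n_hits": hits,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_datasets)),
    }
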