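"""Per-timepoint linear encoding models of band power.

For every contact and every point of the peri-stimulus grid, band power
across trials is regressed on the subjective value (the bid) of the
current trial and of the previous trial, plus a constant — the main
model — with variants that exclude zero-bid trials, add response time,
add the value two trials back, add the previous trial's power at the
matched timepoint, or restrict trials by the preceding inter-trial
interval.  t statistics are mapped to z scores through the Student-t CDF
matched to the standard-normal quantile, computed on the log scale so
the far tails survive the round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import GLMResult, PowerEpochs

_VARIANTS = {
    "GLM1": ["const", "sv_current", "sv_previous"],
    "GLM2": ["const", "sv_current", "sv_previous"],  # fit in two steps
    "GLM3": ["const", "sv_current", "sv_previous"],
    "GLM4": ["const", "sv_current", "sv_previous", "rt"],
    "GLM5": ["const", "sv_current", "sv_previous", "sv_two_back"],
    "GLM6": ["const", "sv_current", "sv_previous", "prev_trial_power"],
}


@dataclass
class DesignSpec:
    """Which model to fit and on which trials."""

    variant: str = "GLM1"
    trial_filter: str = "all"  # or "nonzero_bid"
    iti: float | None = None  # restrict to trials with this preceding ITI
    standardize: bool = False  # z-score the SV regressors per subject

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.trial_filter not in ("all", "nonzero_bid"):
            raise ValueError(f"unknown trial_filter {self.trial_filter!r}")
        if self.variant == "GLM3":
            self.trial_filter = "nonzero_bid"

    @property
    def regressors(self) -> list:
        return list(_VARIANTS[self.variant])


def t_to_z(t: np.ndarray, dof) -> np.ndarray:
    """Map Student-t statistics to standard-normal quantiles.

    z = Phi^{-1}(F_t(t; dof)) evaluated symmetrically via the survival
    function of |t| on the log scale, so that |t| as large as ~40 still
    maps to a finite, accurate z.  |z| is capped at 38 (the quantile of
    the smallest positive double) so near-noiseless fits stay finite.
    """
    t = np.asarray(t, dtype=float)
    logsf = stats.t.logsf(np.abs(t), dof)
    with np.errstate(invalid="ignore"):
        z = np.minimum(-special.ndtri_exp(logsf), 38.0)
    return np.sign(t) * z


def build_design(
    trials: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray, list]:
    """Design matrix for one subject's presentation-ordered trial table.

    Returns (X, rows, names) where ``rows`` indexes the subject's trials
    in presentation order (0-based), aligning X's rows with the trial
    axis of that subject's power epochs.  A trial is usable when it is
    valid and its previous trial (and two-back trial, for the model that
    needs it) was presented immediately before and is itself valid;
    session-initial trials are dropped.  The previous-trial power column
    of the autocorrelation-control model is timepoint-dependent and is
    filled during fitting (NaN here).
    """
    grp = trials.sort_values("trial_index").reset_index(drop=True)
    idx = grp["trial_index"].to_numpy()
    bid = grp["bid"].to_numpy(dtype=float)
    rt = grp["rt"].to_numpy(dtype=float)
    iti = grp["iti"].to_numpy(dtype=float)
    valid = grp["valid"].to_numpy(dtype=bool)
    n = len(grp)
    names = spec.regressors
    need_two_back = "sv_two_back" in names

    usable = np.zeros(n, dtype=bool)
    for i in range(1, n):
        ok = valid[i] and valid[i - 1] and idx[i] - idx[i - 1] == 1
        if need_two_back:
            ok = ok and i >= 2 and valid[i - 2] and idx[i] - idx[i - 2] == 2
        usable[i] = ok
    if spec.trial_filter == "nonzero_bid":
        usable &= bid > 0
    if spec.iti is not None:
        prev_iti = np.concatenate([[np.nan], iti[:-1]])
        usable &= prev_iti == spec.iti

    rows = np.flatnonzero(usable)
    if rows.size == 0:
        raise ValueError("no usable trials after filtering")

    sv_cur = bid[rows]
    sv_prev = bid[rows - 1]
    if spec.standardize:
        sv_cur = (sv_cur - sv_cur.mean()) / sv_cur.std(ddof=0)
        sv_prev = (sv_prev - sv_prev.mean()) / sv_prev.std(ddof=0)
    cols = {"const": np.ones(rows.size), "sv_current": sv_cur, "sv_previous": sv_prev}
    if "rt" in names:
        cols["rt"] = rt[rows]
    if need_two_back:
        cols["sv_two_back"] = bid[rows - 2]
    if "prev_trial_power" in names:
        cols["prev_trial_power"] = np.full(rows.size, np.nan)
    X = np.column_stack([cols[c] for c in names])
    _check_rank(X, names, allow_nan="prev_trial_power" in names)
    return X, rows, names


def _check_rank(X: np.ndarray, names: list, allow_nan: bool = False) -> None:
    cols = [j for j in range(X.shape[1]) if not np.isnan(X[:, j]).any()]
    sub = X[:, cols]
    if np.linalg.matrix_rank(sub) < sub.shape[1]:
        # name the offending columns via pairwise correlation / degeneracy
        bad = []
        for j in cols:
            others = [c for c in cols if c != j]
            rank_wo = np.linalg.matrix_rank(X[:, others]) if others else 0
            if np.linalg.matrix_rank(sub) == rank_wo:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if not allow_nan and np.isnan(X).any():
        raise ValueError("design contains NaNs")


def ols_timeseries(
    Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of every column-timeseries of ``Y`` (n_rows, n_time) on ``X``.

    Returns (beta, se, t, z, dof), each (k, n_time).
    """
    Y = np.asarray(Y, dtype=float)
    n, k = X.shape
    dof = n - k
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    z = t_to_z(t, dof)
    return beta, se, t, z, dof


def fit_pointwise(
    power: PowerEpochs | np.ndarray,
    X: np.ndarray,
    rows: np.ndarray | None = None,
    names: list | None = None,
    contact_ids: list | None = None,
) -> GLMResult:
    """Independent per-timepoint OLS for one or many contacts.

    ``power`` may be a PowerEpochs (contacts x trials x time) or a single
    contact's (trials x time) array; ``rows`` selects and orders the
    trials that X's rows describe.
    """
    if isinstance(power, PowerEpochs):
        arr = power.power
        if contact_ids is None:
            contact_ids = power.contact_ids
    else:
        arr = np.asarray(power, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if rows is not None:
        arr = arr[:, rows, :]
    if arr.shape[1] != X.shape[0]:
        raise ValueError(
            f"power has {arr.shape[1]} trials but design has {X.shape[0]} rows"
        )
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    n_contacts, _, n_time = arr.shape
    k = X.shape[1]
    beta = np.empty((k, n_contacts, n_time))
    se = np.empty_like(beta)
    t = np.empty_like(beta)
    z = np.empty_like(beta)
    for c in range(n_contacts):
        b, s, tt, zz, dof = ols_timeseries(arr[c], X)
        beta[:, c], se[:, c], t[:, c], z[:, c] = b, s, tt, zz
    return GLMResult(
        names=list(names),
        beta=beta,
        se=se,
        t=t,
        z=z,
        dof=np.full(n_contacts, X.shape[0] - k),
        n_used=np.full(n_contacts, X.shape[0]),
        contact_ids=list(contact_ids) if contact_ids is not None else list(range(n_contacts)),
        usable=np.ones(n_contacts, dtype=bool),
    )


def fit_glm(
    power: PowerEpochs,
    trials: pd.DataFrame,
    contacts: pd.DataFrame,
    spec: DesignSpec | None = None,
) -> GLMResult:
    """Fit a model for every contact of a multi-subject dataset.

    Each subject's design is built once from that subject's trial table;
    the subject's contacts share it.  Contacts whose design cannot be
    built (too few usable trials) are flagged unusable and carry NaNs.
    """
    if spec is None:
        spec = DesignSpec()
    names = spec.regressors
    k = len(names)
    n_contacts = power.n_contacts
    n_time = power.time.size
    beta = np.full((k, n_contacts, n_time), np.nan)
    se = np.full_like(beta, np.nan)
    t = np.full_like(beta, np.nan)
    z = np.full_like(beta, np.nan)
    dof = np.zeros(n_contacts, dtype=int)
    n_used = np.zeros(n_contacts, dtype=int)
    usable = np.zeros(n_contacts, dtype=bool)

    contact_rows = {cid: i for i, cid in enumerate(power.contact_ids)}
    for subj, sub_contacts in contacts.groupby("subject"):
        sub_trials = trials[trials["subject"] == subj]
        if sub_trials.empty:
            continue
        try:
            X, rows, _ = build_design(sub_trials, spec)
        except ValueError:
            continue
        if X.shape[0] < k + 2:
            continue
        c_idx = [contact_rows[c] for c in sub_contacts["contact"] if c in contact_rows]
        for ci in c_idx:
            Yfull = power.power[ci]
            Y = Yfull[rows]
            if spec.variant == "GLM6":
                j = names.index("prev_trial_power")
                prev = Yfull[rows - 1]  # (n_rows, n_time)
                for tp in range(n_time):
                    Xt = X.copy()
                    Xt[:, j] = prev[:, tp]
                    b, s, tt, zz, d = ols_timeseries(Y[:, [tp]], Xt)
                    beta[:, ci, tp] = b[:, 0]
                    se[:, ci, tp] = s[:, 0]
                    t[:, ci, tp] = tt[:, 0]
                    z[:, ci, tp] = zz[:, 0]
                dof[ci] = X.shape[0] - k
            else:
                b, s, tt, zz, d = ols_timeseries(Y, X)
                beta[:, ci], se[:, ci], t[:, ci], z[:, ci] = b, s, tt, zz
                dof[ci] = d
            n_used[ci] = X.shape[0]
            usable[ci] = True
    return GLMResult(
        names=names,
        beta=beta,
        se=se,
        t=t,
        z=z,
        dof=dof,
        n_used=n_used,
        contact_ids=list(power.contact_ids),
        usable=usable,
    )


def fit_two_step(
    Y: np.ndarray,
    x_first: np.ndarray,
    x_second: np.ndarray,
    ) -> dict:
    """Sequential two-step regression for one contact.

    Step 1 regresses the power timeseries on a constant and ``x_first``;
    step 2 regresses the step-1 residuals on a constant and ``x_second``.
    Returns both steps' slope estimates and t statistics, each of shape
    (n_time,).  Swap the argument order for the reversed direction.
    """
    Y = np.asarray(Y, dtype=float)
    X1 = np.column_stack([np.ones_like(x_first), x_first])
    b1, s1, t1, z1, dof1 = ols_timeseries(Y, X1)
    resid = Y - X1 @ b1
    X2 = np.column_stack([np.ones_like(x_second), x_second])
    b2, s2, t2, z2, dof2 = ols_timeseries(resid, X2)
    return {
        "beta_first": b1[1],
        "t_first": t1[1],
        "z_first": z1[1],
        "beta_second": b2[1],
        "t_second": t2[1],
        "z_second": z2[1],
        "dof": (dof1, dof2),
    }


def fit_by_iti(
    power: PowerEpochs,
    trials: pd.DataFrame,
    contacts: pd.DataFrame,
    iti: float,
    spec: DesignSpec | None = None,
) -> GLMResult:
    """Main model restricted to trials whose *preceding* ITI equals ``iti``."""
    base = spec or DesignSpec()
    restricted = DesignSpec(
        variant=base.variant,
        trial_filter=base.trial_filter,
        iti=float(iti),
        standardize=base.standardize,
    )
    return fit_glm(power, trials, contacts, restricted)


def result_to_frame(res: GLMResult, time: np.ndarray) -> pd.DataFrame:
    """Tidy per-(contact, timepoint, regressor) table of estimates."""
    rows = []
    for j, name in enumerate(res.names):
        for c, cid in enumerate(res.contact_ids):
            if not res.usable[c]:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "contact": cid,
                        "regressor": name,
                        "time_s": time,
                        "beta": res.beta[j, c],
                        "t": res.t[j, c],
                        "z": res.z[j, c],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
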