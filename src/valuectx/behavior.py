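"""Auction-task logic and subject-level behavioral regressions.

The task is a Becker-DeGroot-Marschak (BDM) auction: on each trial the
subject states a bid x for a food item on a 0-200 TWD grid.  At the end
of the session one trial is realized: a price y is drawn uniformly from
{10, 20, ..., 200}; the subject buys at price y iff x >= y, which makes
truthful bidding the optimal strategy.

The behavioral analyses are per-subject OLS regressions: current bid on
the previous trial's bid (temporal context), and response time against
the bid (a null check), followed by a one-sample t test on the
per-subject coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BID_GRID, PRICE_GRID

logger = logging.getLogger(__name__)


@dataclass
class AuctionOutcome:
    purchased: bool
    price_paid: float
    endowment_remaining: float


@dataclass
class SubjectRegressionResult:
    """Slope of a simple per-subject OLS with intercept."""

    coefficient: float
    t_stat: float
    p: float
    n_used: int
    usable: bool = True


def bdm_realize(bid: float, y: float, endowment: float = 200.0) -> AuctionOutcome:
    """Realize one auction trial: buy at price ``y`` iff ``bid >= y``."""
    if bid not in BID_GRID:
        raise ValueError(f"bid {bid} is not on the 0-200 grid (step 10)")
    if y not in PRICE_GRID:
        raise ValueError(f"price {y} is not on the 10-200 grid (step 10)")
    if endowment < 200:
        raise ValueError("endowment must cover the maximum price (200 TWD)")
    if bid >= y:
        return AuctionOutcome(True, float(y), float(endowment - y))
    return AuctionOutcome(False, 0.0, float(endowment))


def exclude_rt_outliers(trials: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Flag trials whose RT is more than ``k`` SDs from the subject mean.

    Mean and (sample) SD are computed per subject over all of that
    subject's trials; flagged trials get ``valid=False``, everything else
    is returned unchanged.  A subject with zero RT variance produces no
    exclusions (a warning is logged).
    """
    out = trials.copy()
    for s, grp in out.groupby("subject"):
        if len(grp) < 3:
            raise ValueError(f"subject {s} has fewer than 3 trials")
        mu = grp["rt"].mean()
        sd = grp["rt"].std(ddof=1)
        if sd == 0:
            if k > 0:
                logger.warning(
                    "subject %s has zero RT variance; no exclusions applied", s
                )
            continue
        bad = (grp["rt"] - mu).abs() > k * sd
        out.loc[grp.index[bad], "valid"] = False
    return out


def _simple_ols(x: np.ndarray, y: np.ndarray) -> SubjectRegressionResult:
    n = x.size
    res = stats.linregress(x, y)
    if res.stderr == 0:
        t = 0.0 if res.slope == 0 else np.inf * np.sign(res.slope)
        p = 1.0 if res.slope == 0 else 0.0
    else:
        t = res.slope / res.stderr
        p = res.pvalue
    return SubjectRegressionResult(
        coefficient=float(res.slope), t_stat=float(t), p=float(p), n_used=int(n)
    )


def _lagged_pairs(trials: pd.DataFrame, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """(previous, current) bid pairs at presentation-order gap ``lag``.

    Both members of a pair must be valid; the gap in trial_index must be
    exactly ``lag``, so pairs spanning an excluded trial are dropped.
    """
    grp = trials.sort_values("trial_index")
    idx = grp["trial_index"].to_numpy()
    bid = grp["bid"].to_numpy(dtype=float)
    valid = grp["valid"].to_numpy(dtype=bool)
    prev, cur = [], []
    for i in range(lag, len(grp)):
        j = i - lag
        if idx[i] - idx[j] == lag and valid[i] and valid[j]:
            prev.append(bid[j])
            cur.append(bid[i])
    return np.asarray(prev), np.asarray(cur)


def regress_bid_on_previous(
    trials: pd.DataFrame, lag: int = 1
) -> SubjectRegressionResult:
    """OLS of the current bid on the bid ``lag`` trials back (one subject)."""
    if lag not in (1, 2):
        raise ValueError("lag must be 1 or 2")
    prev, cur = _lagged_pairs(trials, lag)
    if prev.size < 3 or np.ptp(prev) == 0:
        return SubjectRegressionResult(np.nan, np.nan, np.nan, int(prev.size), False)
    return _simple_ols(prev, cur)


def regress_bid_rt(
    trials: pd.DataFrame, bid_as_response: bool = False
) -> SubjectRegressionResult:
    """OLS relating RT and bid for one subject.

    Default: RT is the response and the bid the regressor.  Set
    ``bid_as_response=True`` for the transposed variant (bid regressed on
    RT).
    """
    grp = trials[trials["valid"]]
    bid = grp["bid"].to_numpy(dtype=float)
    rt = grp["rt"].to_numpy(dtype=float)
    if len(grp) < 3:
        return SubjectRegressionResult(np.nan, np.nan, np.nan, len(grp), False)
    x, y = (rt, bid) if bid_as_response else (bid, rt)
    if np.ptp(x) == 0:
        return SubjectRegressionResult(np.nan, np.nan, np.nan, len(grp), False)
    if np.ptp(y) == 0:
        return SubjectRegressionResult(0.0, 0.0, 1.0, len(grp), True)
    return _simple_ols(x, y)


def regress_all_subjects(
    trials: pd.DataFrame, operation="previous", **kwargs
) -> pd.DataFrame:
    """Run a per-subject regression for every subject; one row each."""
    fn = {
        "previous": regress_bid_on_previous,
        "rt": regress_bid_rt,
    }[operation]
    rows = []
    for s, grp in trials.groupby("subject"):
        res = fn(grp, **kwargs)
        rows.append(
            {
                "subject": s,
                "coefficient": res.coefficient,
                "t_stat": res.t_stat,
                "p": res.p,
                "n_used": res.n_used,
                "usable": res.usable,
            }
        )
    return pd.DataFrame(rows)


def group_ttest(coefficients: np.ndarray) -> tuple[float, float]:
    """Two-tailed one-sample t test of the subject coefficients against 0."""
    c = np.asarray(coefficients, dtype=float)
    c = c[np.isfinite(c)]
    if c.size < 2:
        raise ValueError("need at least two finite coefficients")
    if np.ptp(c) == 0:
        raise ValueError("coefficients have zero variance")
    res = stats.ttest_1samp(c, 0.0)
    return float(res.statistic), float(res.pvalue)
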