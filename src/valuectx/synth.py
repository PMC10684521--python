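"""Synthetic behavioral and neural datasets with known ground truth.

The generator emulates the statistical structure of a willingness-to-pay
auction experiment recorded with depth electrodes:

* bids live on a 0-200 grid (steps of 10), are positively skewed, are
  zero-inflated (roughly a quarter of trials are zero bids), and carry
  over from one trial to the next (an AR(1)-like temporal context effect);
* response times are positive, unrelated to the bids, and occasionally
  contain gross outliers so that the exclusion rule has something to do;
* band power on the canonical peri-stimulus grid is pure noise on most
  contacts, while a configurable fraction of "encoding" contacts carries
  a value signal: positive in the current-trial value and negative in the
  previous-trial value for high-frequency bands, with reversed signs in
  the low-frequency bands.

Every injected coefficient and its latency window is recorded in a truth
table so that recovery can be tested against the generator itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    BANDS,
    BID_GRID,
    ITI_SET,
    N_TIME,
    PowerEpochs,
    time_axis,
)

#: Rough MNI centroids (mm) used to scatter synthetic contact coordinates.
ROI_CENTERS = {
    "OFC-medial": (6.0, 32.0, -18.0),
    "OFC-central": (24.0, 30.0, -16.0),
    "OFC-lateral": (38.0, 28.0, -12.0),
    "amygdala": (24.0, -4.0, -18.0),
    "hippocampus": (28.0, -20.0, -14.0),
    "striatum": (14.0, 8.0, -2.0),
    "insula": (38.0, 4.0, 2.0),
    "ACC-MCC": (6.0, 18.0, 30.0),
    "PCC": (6.0, -44.0, 28.0),
    "IPS": (30.0, -52.0, 44.0),
    "other": (0.0, 0.0, 0.0),
}

_DEFAULT_EFFECT_CURRENT = {
    "high_gamma": 0.015,
    "gamma": 0.015,
    "beta": -0.009,
    "alpha": -0.009,
    "theta": -0.009,
}
_DEFAULT_EFFECT_PREVIOUS = {
    "high_gamma": -0.015,
    "gamma": -0.015,
    "beta": 0.009,
    "alpha": 0.009,
    "theta": 0.009,
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the emulated study's conditions: 20 subjects with
    200 trials each (8 blocks of 25), 166 orbitofrontal contacts, ~23%
    zero bids, inter-trial intervals of 1/1.5/2 s, a median response time
    near 1.5 s, and ~30% of contacts encoding value.
    """

    n_subjects: int = 20
    n_trials_per_subject: int = 200
    n_contacts_per_roi: dict = field(
        default_factory=lambda: {
            "OFC-medial": 40,
            "OFC-central": 92,
            "OFC-lateral": 34,
        }
    )
    zero_bid_rate: float = 0.23
    bid_carryover: float = 0.3
    bid_scale: float = 60.0  # stationary mean of the latent bid process, TWD
    bid_sd: float = 35.0  # stationary SD of the latent bid process, TWD
    rt_mean: float = 1.5
    rt_sd: float = 0.4
    rt_outlier_rate: float = 0.01
    iti_set: tuple = ITI_SET
    effect_current: dict = field(
        default_factory=lambda: dict(_DEFAULT_EFFECT_CURRENT)
    )
    effect_previous: dict = field(
        default_factory=lambda: dict(_DEFAULT_EFFECT_PREVIOUS)
    )
    effect_onset: float = 0.3
    effect_offset: float = 1.2
    frac_encoding_contacts: float = 0.3
    # shares of encoding contacts carrying only the current value, only the
    # previous value, or both (the emulated study's observed mix)
    encoding_mix: tuple = (0.52, 0.31, 0.17)
    noise_sd: float = 1.0
    bands: tuple = ("high_gamma", "alpha")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("zero_bid_rate", "frac_encoding_contacts", "rt_outlier_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.effect_offset <= self.effect_onset:
            raise ValueError("effect_offset must exceed effect_onset")
        if not set(self.iti_set) <= set(ITI_SET):
            raise ValueError(f"iti_set must be a subset of {ITI_SET}")
        if self.bid_scale <= 0 or self.bid_sd <= 0:
            raise ValueError("bid_scale and bid_sd must be positive")
        if not -1.0 < self.bid_carryover < 1.0:
            raise ValueError("bid_carryover must lie in (-1, 1)")
        if self.rt_sd < 0 or self.noise_sd < 0:
            raise ValueError("rt_sd and noise_sd must be non-negative")
        if len(self.encoding_mix) != 3 or not np.isclose(sum(self.encoding_mix), 1.0):
            raise ValueError("encoding_mix must be three shares summing to 1")
        unknown = set(self.bands) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "SynthConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["iti_set"] = tuple(payload.get("iti_set", ITI_SET))
        payload["bands"] = tuple(payload.get("bands", ("high_gamma", "alpha")))
        return cls(**payload)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class SynthDataset:
    """A complete synthetic study: behavior, contacts, power, and truth."""

    trials: pd.DataFrame
    contacts: pd.DataFrame
    power: dict
    truth: pd.DataFrame
    config: SynthConfig


def _rng(config: SynthConfig, *key) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key))
    )


def generate_bids(
    config: SynthConfig,
    subject: int,
    n_trials: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one subject's bid series on the 0-200 TWD grid.

    A latent stationary AR(1) process with mean ``bid_scale``, SD
    ``bid_sd`` and lag-1 coefficient ``bid_carryover`` is rounded to the
    nearest 10 and clipped to [0, 200].  Zero inflation is then applied
    with an independent Bernoulli mask whose probability is adjusted for
    the (small) natural zero rate of the clipped latent process, so the
    marginal zero-bid fraction matches ``zero_bid_rate`` in expectation.
    """
    n = config.n_trials_per_subject if n_trials is None else int(n_trials)
    if n < 2:
        raise ValueError("need at least two trials")
    if rng is None:
        rng = _rng(config, 1, subject)
    mu, sd, rho = config.bid_scale, config.bid_sd, config.bid_carryover
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    v = np.empty(n)
    v[0] = rng.normal(mu, sd)
    eps = rng.normal(0.0, innov_sd, n - 1)
    for t in range(1, n):
        v[t] = mu + rho * (v[t - 1] - mu) + eps[t - 1]
    bids = np.clip(np.round(v / 10.0) * 10.0, 0.0, 200.0)
    # bid rounds to zero iff latent value < 5 TWD
    p_nat = norm.cdf((5.0 - mu) / sd)
    p_mask = max(0.0, (config.zero_bid_rate - p_nat) / (1.0 - p_nat))
    if config.zero_bid_rate == 0.0:
        p_mask = 0.0
    bids[rng.random(n) < p_mask] = 0.0
    return bids


def generate_rts(
    config: SynthConfig,
    n_trials: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate response times (s), independent of the bids.

    Gaussian around ``rt_mean`` with SD ``rt_sd``; a fraction
    ``rt_outlier_rate`` of trials is shifted 5-9 SDs upward to exercise
    the outlier-exclusion rule.  All quantities degrade gracefully at
    ``rt_sd=0`` (every RT equals ``rt_mean``).
    """
    if config.rt_sd < 0:
        raise ValueError("rt_sd must be non-negative")
    if rng is None:
        rng = _rng(config, 2, 0)
    rt = rng.normal(config.rt_mean, config.rt_sd, int(n_trials))
    out = rng.random(int(n_trials)) < config.rt_outlier_rate
    rt[out] = config.rt_mean + rng.uniform(5.0, 9.0, out.sum()) * config.rt_sd
    return np.maximum(rt, 1e-3)


def generate_trials(config: SynthConfig) -> pd.DataFrame:
    """Per-subject trial tables: bids, RTs, ITIs, block and item labels."""
    frames = []
    n = config.n_trials_per_subject
    n_items = max(1, (n + 1) // 2)
    for s in range(config.n_subjects):
        rng = _rng(config, 3, s)
        bids = generate_bids(config, s)
        rts = generate_rts(config, n, rng=_rng(config, 2, s))
        itis = rng.choice(np.asarray(config.iti_set, dtype=float), size=n)
        items = rng.permutation(np.tile(np.arange(n_items), 2)[:n])
        frames.append(
            pd.DataFrame(
                {
                    "subject": s,
                    "trial_index": np.arange(1, n + 1),
                    "block": np.arange(n) // 25 + 1,
                    "item": items,
                    "bid": bids,
                    "rt": rts,
                    "iti": itis,
                    "valid": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_contacts(config: SynthConfig) -> pd.DataFrame:
    """Synthetic contact table with MNI coordinates scattered per ROI."""
    rng = _rng(config, 4, 0)
    rows = []
    cid = 0
    for roi, count in config.n_contacts_per_roi.items():
        if roi not in ROI_CENTERS:
            raise ValueError(f"unknown ROI label: {roi}")
        cx, cy, cz = ROI_CENTERS[roi]
        for i in range(int(count)):
            side = rng.choice([-1.0, 1.0])
            x, y, z = rng.normal([cx * side, cy, cz], 4.0)
            rows.append(
                {
                    "contact": f"c{cid:04d}",
                    "subject": cid % config.n_subjects,
                    "x": x,
                    "y": y,
                    "z": z,
                    "roi": roi,
                }
            )
            cid += 1
    return pd.DataFrame(rows)


def latency_window(
    onset: float,
    offset: float,
    t: np.ndarray | None = None,
    ramp: float = 0.05,
) -> np.ndarray:
    """Boxcar on [onset, offset] with half-cosine ramps of width ``ramp``."""
    if t is None:
        t = time_axis()
    w = np.zeros_like(t, dtype=float)
    w[(t >= onset) & (t <= offset)] = 1.0
    rise = (t >= onset - ramp) & (t < onset)
    w[rise] = 0.5 * (1.0 + np.cos(np.pi * (onset - t[rise]) / ramp))
    fall = (t > offset) & (t <= offset + ramp)
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - offset) / ramp))
    return w


def generate_power_epochs(
    trials: pd.DataFrame,
    contacts: pd.DataFrame,
    config: SynthConfig,
) -> tuple[dict, pd.DataFrame]:
    """Band-power epochs plus the ground-truth coefficient table.

    For an encoding contact, power(t) = noise + w(t) * (b_cur * SV_t +
    b_prev * SV_{t-1}) with w the smoothed latency window; the previous-
    value term is zero on each subject's first trial (no previous trial
    exists).  Non-encoding contacts are pure Gaussian noise.

    Encoding contacts are split into current-only, previous-only, and
    both-signal categories per ``config.encoding_mix`` — the two value
    signals live on largely distinct contact populations, which is what
    makes the current and previous coefficient patterns separable in
    contact space.
    """
    n_trials = config.n_trials_per_subject
    counts = trials.groupby("subject").size()
    if not (counts == n_trials).all():
        raise ValueError("trial table does not match n_trials_per_subject")
    n_contacts = len(contacts)
    rng = _rng(config, 5, 0)
    n_enc = int(round(config.frac_encoding_contacts * n_contacts))
    enc_idx = np.sort(rng.choice(n_contacts, size=n_enc, replace=False))
    enc_set = set(enc_idx.tolist())
    n_cur = int(round(config.encoding_mix[0] * n_enc))
    n_prev = int(round(config.encoding_mix[1] * n_enc))
    n_prev = min(n_prev, n_enc - n_cur)
    shuffled = rng.permutation(enc_idx)
    has_current = set(shuffled[:n_cur]) | set(shuffled[n_cur + n_prev :])
    has_previous = set(shuffled[n_cur:])

    t = time_axis()
    w = latency_window(config.effect_onset, config.effect_offset, t)
    sv = {}
    sv_prev = {}
    for s, grp in trials.sort_values("trial_index").groupby("subject"):
        b = grp["bid"].to_numpy()
        sv[s] = b
        sv_prev[s] = np.concatenate([[0.0], b[:-1]])

    power = {}
    truth_rows = []
    for band in config.bands:
        noise_rng = _rng(config, 6, list(BANDS).index(band))
        arr = noise_rng.normal(0.0, config.noise_sd, (n_contacts, n_trials, N_TIME))
        bc = config.effect_current[band]
        bp = config.effect_previous[band]
        for ci in enc_idx:
            s = int(contacts.iloc[ci]["subject"])
            bc_i = bc if ci in has_current else 0.0
            bp_i = bp if ci in has_previous else 0.0
            arr[ci] += np.outer(bc_i * sv[s] + bp_i * sv_prev[s], w)
            for reg, coef in (("sv_current", bc_i), ("sv_previous", bp_i)):
                if coef != 0.0:
                    truth_rows.append(
                        {
                            "contact": contacts.iloc[ci]["contact"],
                            "band": band,
                            "regressor": reg,
                            "coef": coef,
                            "onset": config.effect_onset,
                            "offset": config.effect_offset,
                        }
                    )
        power[band] = PowerEpochs(
            band=band,
            power=arr,
            time=t,
            contact_ids=contacts["contact"].tolist(),
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["contact", "band", "regressor", "coef", "onset", "offset"],
    )
    assert set(truth["contact"]) == {contacts.iloc[i]["contact"] for i in enc_set}
    return power, truth


def generate_dataset(config: SynthConfig | None = None) -> SynthDataset:
    """Generate a full synthetic study, reproducible from ``config.seed``."""
    if config is None:
        config = SynthConfig()
    trials = generate_trials(config)
    contacts = generate_contacts(config)
    power, truth = generate_power_epochs(trials, contacts, config)
    return SynthDataset(
        trials=trials, contacts=contacts, power=power, truth=truth, config=config
    )
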