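"""From continuous LFP to baseline-corrected band power on the 10-ms grid.

Stages: neighbor re-referencing along each electrode shaft, epoching
around stimulus onsets (-1.5 to +2.0 s so that wavelets never see zero
padding inside the analysis window), Morlet wavelet power from 4-200 Hz,
two-step baseline correction (divisive full-epoch single-trial
normalization followed by subtraction of the mean over the 1 s preceding
stimulus onset), and band aggregation onto the canonical 251-point grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import BANDS, EPOCH_END, EPOCH_START, TIME_STEP, PowerEpochs

logger = logging.getLogger(__name__)

#: Spectral estimation range (Hz) and resolution.
FREQ_MIN, FREQ_MAX, N_FREQS = 4.0, 200.0, 60
#: Morlet cycles grow linearly with frequency: 3 cycles at 4 Hz, 12 at 200 Hz.
CYCLES_MIN, CYCLES_MAX = 3.0, 12.0


def default_freqs(n_freqs: int = N_FREQS) -> np.ndarray:
    """Log-spaced analysis frequencies, 4-200 Hz."""
    return np.geomspace(FREQ_MIN, FREQ_MAX, n_freqs)


def default_cycles(freqs: np.ndarray) -> np.ndarray:
    return CYCLES_MIN + (np.asarray(freqs) - FREQ_MIN) / (FREQ_MAX - FREQ_MIN) * (
        CYCLES_MAX - CYCLES_MIN
    )


@dataclass
class LFPEpochs:
    """Epoched LFP at the native sampling rate.

    samples : (n_contacts, n_trials, n_samples)
    window : (start, end) in seconds relative to stimulus onset.
    """

    samples: np.ndarray
    sample_rate: float
    window: tuple = (-1.5, 2.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValueError("samples must be (n_contacts, n_trials, n_samples)")

    @property
    def times(self) -> np.ndarray:
        n = self.samples.shape[-1]
        return self.window[0] + np.arange(n) / self.sample_rate


@dataclass
class TFPower:
    """Single-trial spectral power: (n_freqs, n_contacts, n_trials, n_times)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


def rereference_neighbors(raw: np.ndarray) -> np.ndarray:
    """Re-reference each shaft contact to the mean of its two neighbors.

    ``raw`` is shaft-ordered with contacts on axis 0.  Interior contacts:
    out_i = in_i - (in_{i-1} + in_{i+1}) / 2.  The two shaft-end contacts
    only have one neighbor and are referenced to it.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    if n < 3:
        raise ValueError("neighbor re-referencing needs at least 3 contacts")
    out = np.empty_like(raw)
    out[1:-1] = raw[1:-1] - 0.5 * (raw[:-2] + raw[2:])
    out[0] = raw[0] - raw[1]
    out[-1] = raw[-1] - raw[-2]
    return out


def epoch_signal(
    continuous: np.ndarray,
    onsets: np.ndarray,
    sample_rate: float,
    window: tuple = (-1.5, 2.0),
) -> LFPEpochs:
    """Cut sample-exact epochs around stimulus-onset samples.

    ``continuous`` is (n_contacts, n_samples); ``onsets`` are onset
    sample indices.  The epoch covers the closed interval
    [onset + window[0], onset + window[1]], i.e. round(rate * span) + 1
    samples.  Onsets whose epoch would fall outside the recording are
    dropped with a log entry.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    onsets = np.asarray(onsets, dtype=int)
    pre = int(round(-window[0] * sample_rate))
    post = int(round(window[1] * sample_rate))
    n_samp = pre + post + 1
    keep, epochs = [], []
    for k, o in enumerate(onsets):
        if o - pre < 0 or o + post >= continuous.shape[1]:
            logger.warning("onset %d at sample %d too close to edge; dropped", k, o)
            continue
        keep.append(k)
        epochs.append(continuous[:, o - pre : o + post + 1])
    if not epochs:
        raise ValueError("no onset fits inside the recording")
    samples = np.stack(epochs, axis=1)  # (contacts, trials, time)
    return LFPEpochs(samples=samples, sample_rate=sample_rate, window=window)


def wavelet_power(
    epochs: LFPEpochs,
    freqs: np.ndarray | None = None,
    n_cycles: np.ndarray | None = None,
) -> TFPower:
    """Per-trial Morlet wavelet power.

    Defaults to 60 log-spaced frequencies from 4 to 200 Hz with cycles
    scaling linearly from 3 to 12, a standard trade-off between temporal
    and spectral resolution across this range.
    """
    from mne.time_frequency import tfr_array_morlet

    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= epochs.sample_rate / 2:
        raise ValueError(
            f"max frequency {freqs.max()} Hz violates Nyquist at "
            f"{epochs.sample_rate} Hz"
        )
    if n_cycles is None:
        n_cycles = default_cycles(freqs)
    data = np.transpose(epochs.samples, (1, 0, 2))  # (trials, contacts, time)
    power = tfr_array_morlet(
        data,
        sfreq=epochs.sample_rate,
        freqs=freqs,
        n_cycles=n_cycles,
        output="power",
        zero_mean=True,
    )
    # (trials, contacts, freqs, time) -> (freqs, contacts, trials, time)
    power = np.transpose(power, (2, 1, 0, 3))
    return TFPower(power=power, freqs=freqs, times=epochs.times)


def baseline_correct(
    tf: TFPower,
    mode: str = "divisive",
    pre_window: tuple = (-1.0, 0.0),
) -> TFPower:
    """Two-step single-trial baseline correction.

    Step 1 normalizes each (frequency, contact, trial) power timeseries
    by its own full-epoch mean — divisively by default, or as dB with
    ``mode="db"``.  Step 2 subtracts, per frequency bin and trial, the
    mean over the pre-stimulus second.  Output power may be negative.
    """
    if tf.baseline_corrected:
        raise ValueError("power is already baseline corrected")
    full_mean = tf.power.mean(axis=-1, keepdims=True)
    if np.any(full_mean <= 0):
        raise ValueError("full-epoch mean power must be positive")
    if mode == "divisive":
        p = tf.power / full_mean
    elif mode == "db":
        p = 10.0 * np.log10(tf.power / full_mean + np.finfo(float).tiny)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    pre = (tf.times >= pre_window[0]) & (tf.times < pre_window[1])
    if not pre.any():
        raise ValueError("pre-stimulus window not covered by the epoch")
    p = p - p[..., pre].mean(axis=-1, keepdims=True)
    return TFPower(
        power=p, freqs=tf.freqs, times=tf.times, baseline_corrected=True
    )


def band_power(
    tf: TFPower,
    band: str | tuple,
    contact_ids: list | None = None,
) -> PowerEpochs:
    """Average a frequency band and resample onto the canonical grid.

    The band mean is unweighted across the frequency bins inside the band
    (edges inclusive).  Downsampling to the 10-ms grid averages native
    samples over non-overlapping 10-ms windows centred on the grid points
    (an anti-aliasing mean), and the output is trimmed to -1.0 ... +1.5 s,
    yielding the canonical 251 points.
    """
    if isinstance(band, str):
        if band not in BANDS:
            raise ValueError(f"unknown band {band!r}")
        lo, hi = BANDS[band]
        name = band
    else:
        lo, hi = band
        name = f"{lo:g}-{hi:g}Hz"
    sel = (tf.freqs >= lo) & (tf.freqs <= hi)
    if not sel.any():
        raise ValueError(f"no analysis frequencies inside band {lo}-{hi} Hz")
    bp = tf.power[sel].mean(axis=0)  # (contacts, trials, native time)

    grid = EPOCH_START + TIME_STEP * np.arange(
        int(round((EPOCH_END - EPOCH_START) / TIME_STEP)) + 1
    )
    edges = np.concatenate([grid - TIME_STEP / 2, [grid[-1] + TIME_STEP / 2]])
    which = np.digitize(tf.times, edges) - 1
    ok = (which >= 0) & (which < grid.size)
    counts = np.bincount(which[ok], minlength=grid.size)
    if np.any(counts == 0):
        raise ValueError("native sampling too coarse for the 10-ms grid")
    sums = np.zeros(bp.shape[:2] + (grid.size,))
    np.add.at(sums.transpose(2, 0, 1), which[ok], bp[..., ok].transpose(2, 0, 1))
    out = sums / counts
    return PowerEpochs(band=name, power=out, time=grid, contact_ids=contact_ids)
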