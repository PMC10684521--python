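"""Shared containers and the canonical epoch grid.

All band-power analyses operate on a fixed peri-stimulus grid: -1.0 s to
+1.5 s relative to stimulus onset, sampled every 10 ms, both endpoints
included.  Every array container in the package carries this grid (or a
sub-grid of it) on a ``time`` attribute expressed in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Epoch window relative to stimulus onset (seconds).
EPOCH_START: float = -1.0
EPOCH_END: float = 1.5
#: Grid resolution (seconds).
TIME_STEP: float = 0.010
#: Number of grid points, endpoints inclusive.
N_TIME: int = int(round((EPOCH_END - EPOCH_START) / TIME_STEP)) + 1

#: Canonical frequency bands (Hz), low and high edge inclusive.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
    "high_gamma": (80.0, 150.0),
}

#: Allowed bids in the auction task (New Taiwan Dollars).
BID_GRID = np.arange(0, 201, 10)
#: Prices the auction can draw (TWD); zero is never drawn.
PRICE_GRID = np.arange(10, 201, 10)

#: Inter-trial intervals used in the task (seconds).
ITI_SET = (1.0, 1.5, 2.0)


def time_axis() -> np.ndarray:
    """Return the canonical peri-stimulus time grid in seconds."""
    return EPOCH_START + TIME_STEP * np.arange(N_TIME)


@dataclass
class PowerEpochs:
    """Baseline-corrected band power on the canonical grid.

    Attributes
    ----------
    band : name of the frequency band.
    power : array, shape (n_contacts, n_trials, n_time).  May be negative
        after baseline subtraction.
    time : peri-stimulus time axis in seconds.
    contact_ids : one identifier per row of ``power``.
    """

    band: str
    power: np.ndarray
    time: np.ndarray = field(default_factory=time_axis)
    contact_ids: list | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be (n_contacts, n_trials, n_time)")
        if self.power.shape[-1] != self.time.size:
            raise ValueError(
                f"power has {self.power.shape[-1]} time points but the time "
                f"axis has {self.time.size}"
            )
        if self.contact_ids is None:
            self.contact_ids = list(range(self.power.shape[0]))

    @property
    def n_contacts(self) -> int:
        return self.power.shape[0]

    @property
    def n_trials(self) -> int:
        return self.power.shape[1]


@dataclass
class GLMResult:
    """Per-timepoint OLS estimates for one band and one design.

    Arrays are indexed (regressor, contact, timepoint).  ``dof`` and
    ``n_used`` are per contact; contacts whose design could not be fit
    (too few usable trials) are flagged in ``usable`` and carry NaNs.
    """

    names: list
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    z: np.ndarray
    dof: np.ndarray
    n_used: np.ndarray
    contact_ids: list
    usable: np.ndarray

    def index(self, name: str) -> int:
        return self.names.index(name)

    def coef(self, name: str) -> np.ndarray:
        """Betas for one regressor, shape (n_contacts, n_time)."""
        return self.beta[self.index(name)]

    def tstat(self, name: str) -> np.ndarray:
        return self.t[self.index(name)]

    def zstat(self, name: str) -> np.ndarray:
        return self.z[self.index(name)]
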