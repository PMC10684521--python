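"""File formats: trial CSV, contact TSV, HDF5 power container, config.

The hierarchical power container stores one group per band —
``/band/<name>/power`` (contacts x trials x time) — plus ``/time_axis``
and, when ground truth exists, a ``/truth`` table of injected
coefficients, so synthetic and recorded data flow through the same
downstream code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import BID_GRID, ITI_SET, PowerEpochs

TRIAL_COLUMNS = ["subject", "trial_index", "block", "item", "bid", "rt", "iti", "valid"]
CONTACT_COLUMNS = ["contact", "subject", "x", "y", "z", "roi"]

ROI_LABELS = (
    "OFC-medial",
    "OFC-central",
    "OFC-lateral",
    "amygdala",
    "hippocampus",
    "striatum",
    "insula",
    "ACC-MCC",
    "PCC",
    "IPS",
    "other",
)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    validate_trials(trials)
    return trials


def validate_trials(trials: pd.DataFrame) -> None:
    for s, grp in trials.groupby("subject"):
        d = np.diff(grp["trial_index"].to_numpy())
        if np.any(d <= 0):
            raise ValueError(f"trial_index not strictly increasing for subject {s}")
    if not trials["bid"].isin(BID_GRID).all():
        raise ValueError("bids must lie on the 0-200 TWD grid (step 10)")
    if not (trials["rt"] > 0).all():
        raise ValueError("RTs must be positive")
    if not trials["iti"].isin(ITI_SET).all():
        raise ValueError(f"ITIs must lie in {ITI_SET}")


def write_contacts(contacts: pd.DataFrame, path) -> None:
    contacts[CONTACT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_contacts(path) -> pd.DataFrame:
    contacts = pd.read_csv(path, sep="\t")
    missing = set(CONTACT_COLUMNS) - set(contacts.columns)
    if missing:
        raise ValueError(f"contact table missing columns: {sorted(missing)}")
    validate_contacts(contacts)
    return contacts


def validate_contacts(contacts: pd.DataFrame) -> None:
    if contacts["contact"].duplicated().any():
        raise ValueError("contact ids must be unique")
    if not np.isfinite(contacts[["x", "y", "z"]].to_numpy()).all():
        raise ValueError("contact coordinates must be finite")
    bad = set(contacts["roi"]) - set(ROI_LABELS)
    if bad:
        raise ValueError(f"unknown ROI labels: {sorted(bad)}")


def save_power(path, power: dict, truth: pd.DataFrame | None = None) -> None:
    """Write band-power epochs (and optional truth) to an HDF5 container."""
    bands = list(power)
    time = power[bands[0]].time
    contact_ids = power[bands[0]].contact_ids
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_axis", data=time)
        fh.create_dataset(
            "contact_ids", data=np.asarray(contact_ids, dtype="S")
        )
        grp = fh.create_group("band")
        for band in bands:
            g = grp.create_group(band)
            g.create_dataset("power", data=power[band].power, compression="gzip")
        if truth is not None and len(truth):
            g = fh.create_group("truth")
            for col in truth.columns:
                data = truth[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                g.create_dataset(col, data=data)


def load_power(path) -> tuple[dict, pd.DataFrame | None]:
    with h5py.File(path, "r") as fh:
        time = fh["time_axis"][:]
        contact_ids = [c.decode() for c in fh["contact_ids"][:]]
        power = {}
        for band in fh["band"]:
            power[band] = PowerEpochs(
                band=band,
                power=fh["band"][band]["power"][:],
                time=time,
                contact_ids=contact_ids,
            )
        truth = None
        if "truth" in fh:
            cols = {}
            for col in fh["truth"]:
                data = fh["truth"][col][:]
                if data.dtype.kind == "S":
                    data = np.asarray([d.decode() for d in data])
                cols[col] = data
            truth = pd.DataFrame(cols)
    return power, truth


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, round-trippable through JSON."""

    outdir: str = "valuectx_out"
    band: str = "high_gamma"
    glm_variant: str = "GLM1"
    tfce_E: float = 2.0
    tfce_H: float = 2.0
    tfce_n_levels: int = 100
    n_perm_group: int = 1000
    n_perm_contact: int = 200
    alpha: float = 0.05
    ap_y_threshold: float = 35.0
    smoothing_ms: float = 400
    n_pc: int = 12
    seed: int = 0
    synth: dict = field(default_factory=dict)
    trials_csv: str | None = None
    contacts_tsv: str | None = None
    power_h5: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        from .core import BANDS

        if self.band not in BANDS:
            raise ValueError(f"band: unknown band {self.band!r}")
        if self.glm_variant not in (f"GLM{i}" for i in range(1, 7)):
            raise ValueError(f"glm_variant: unknown variant {self.glm_variant!r}")
        for name in ("tfce_E", "tfce_H"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be positive")
        for name in ("n_perm_group", "n_perm_contact", "tfce_n_levels"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name}: must be a positive integer")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha: must be in (0, 1)")
        if self.smoothing_ms not in (0, 100, 200, 300, 400):
            raise ValueError("smoothing_ms: must be one of 0/100/200/300/400")
        if self.n_pc < 2:
            raise ValueError("n_pc: must be at least 2")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed: must be an integer")
        external = [self.trials_csv, self.contacts_tsv, self.power_h5]
        if any(external) and not all(external):
            raise ValueError(
                "trials_csv/contacts_tsv/power_h5: provide all three or none"
            )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
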