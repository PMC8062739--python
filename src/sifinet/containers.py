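"""Core in-memory containers shared across the pipeline.

The central object is :class:`TrialEnsemble`, a per-subject stack of
equal-length trials over labelled channels, with a sampling rate and a
time axis relative to stimulus onset.  All downstream stages (wavelet
power, transfer entropy, spectral model fits) consume this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TrialEnsemble"]


@dataclass
class TrialEnsemble:
    """Equal-length multichannel trials for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial time series.
    sfreq : float
        Sampling rate in Hz.
    subject : str
        Subject identifier.
    channel_names : list of str
        Unique channel labels, one per channel.
    times : ndarray, shape (n_samples,)
        Strictly increasing time axis in seconds relative to the onset
        of the first stimulus.
    conditions : list of str
        Condition label per trial.
    """

    data: np.ndarray
    sfreq: float
    subject: str = "S00"
    channel_names: list[str] = field(default_factory=list)
    times: np.ndarray | None = None
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_channels)]
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length mismatch")
        if len(set(self.channel_names)) != n_channels:
            raise ValueError("channel labels must be unique")
        if self.times is None:
            self.times = np.arange(n_samples) / self.sfreq
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (n_samples,):
            raise ValueError("times length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not self.conditions:
            self.conditions = ["default"] * n_trials
        if len(self.conditions) != n_trials:
            raise ValueError("conditions length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return (n_trials, n_samples) series for one labelled channel."""
        return self.data[:, self.channel_names.index(name), :]

    def select_trials(self, idx) -> "TrialEnsemble":
        idx = np.asarray(idx)
        return TrialEnsemble(
            data=self.data[idx],
            sfreq=self.sfreq,
            subject=self.subject,
            channel_names=list(self.channel_names),
            times=self.times.copy(),
            conditions=[self.conditions[i] for i in idx],
        )

    def select_channels(self, names) -> "TrialEnsemble":
        idx = [self.channel_names.index(n) for n in names]
        return TrialEnsemble(
            data=self.data[:, idx, :],
            sfreq=self.sfreq,
            subject=self.subject,
            channel_names=list(names),
            times=self.times.copy(),
            conditions=list(self.conditions),
        )

    def select_conditions(self, labels) -> "TrialEnsemble":
        labels = set(labels) if not isinstance(labels, str) else {labels}
        idx = [i for i, c in enumerate(self.conditions) if c in labels]
        return self.select_trials(idx)

    def crop(self, tmin: float, tmax: float) -> "TrialEnsemble":
        """Restrict to samples with tmin <= t <= tmax (inclusive)."""
        mask = (self.times >= tmin) & (self.times <= tmax)
        if not mask.any():
            raise ValueError(f"window [{tmin}, {tmax}] outside epoch")
        return TrialEnsemble(
            data=self.data[:, :, mask],
            sfreq=self.sfreq,
            subject=self.subject,
            channel_names=list(self.channel_names),
            times=self.times[mask],
            conditions=list(self.conditions),
        )

    # -- on-disk form: .npy payload with a JSON sidecar ------------------
    def save(self, path) -> None:
        """Write ``<path>.npy`` plus ``<path>.json`` with the metadata."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        meta = {
            "subject": self.subject,
            "sampling_rate": self.sfreq,
            "channel_names": self.channel_names,
            "times": self.times.tolist(),
            "conditions": self.conditions,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "TrialEnsemble":
        path = Path(path)
        data = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=data,
            sfreq=meta["sampling_rate"],
            subject=meta["subject"],
            channel_names=meta["channel_names"],
            times=np.asarray(meta["times"]),
            conditions=meta["conditions"],
        )
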