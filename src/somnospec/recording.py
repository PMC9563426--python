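"""In-memory container for a polysomnographic recording.

A recording bundles the multi-channel signal matrix (EEG screw electrodes
plus a 3-axis head accelerometer), the sample rate, and a role label per
channel so downstream stages can aggregate frontal vs parietal sites and
locate the movement channels without caring about channel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: channel roles understood by the pipeline
EEG_ROLES = ("frontal", "parietal")
ACCEL_ROLE = "accelerometer"

STATES = ("WAKE", "NREM", "REM")


@dataclass
class Recording:
    data: np.ndarray  # (n_channels, n_samples)
    sample_rate: float
    channel_names: list[str]
    channel_roles: list[str]  # "frontal" | "parietal" | "accelerometer"
    lights_on: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n = self.data.shape[0]
        if not (len(self.channel_names) == len(self.channel_roles) == n):
            raise ValueError(
                f"channel metadata length mismatch: {len(self.channel_names)} names, "
                f"{len(self.channel_roles)} roles, {n} data rows"
            )
        bad = set(self.channel_roles) - {*EEG_ROLES, ACCEL_ROLE}
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")
        if self.lights_on is None:
            self.lights_on = (0.0, self.duration_s)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel_indices(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == role]

    @property
    def eeg_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r in EEG_ROLES]

    @property
    def accel_indices(self) -> list[int]:
        return self.channel_indices(ACCEL_ROLE)
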