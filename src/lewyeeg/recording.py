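"""Single-subject EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np


@dataclass
class Recording:
    """One subject's multichannel EEG.

    data is channels x samples in microvolts.  ``ground_truth`` carries the
    generating :class:`~lewyeeg.synth.SubjectProfile` for synthetic recordings;
    analysis stages never read it.
    """

    subject_id: str
    channel_labels: tuple
    fs: float
    data: np.ndarray
    provenance: str = "synthetic"
    ground_truth: Optional[Any] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"channel count {self.data.shape[0]} != label count "
                f"{len(self.channel_labels)}"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.provenance not in ("synthetic", "edf"):
            raise ValueError("provenance must be 'synthetic' or 'edf'")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs
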