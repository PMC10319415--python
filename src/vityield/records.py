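"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PlotRecord:
    """One experimental plot: an ordered image time series, the seed
    combination, and the measured yield.

    Images are float arrays of shape (H, W, 3) in [0, 1], ordered by
    acquisition timestamp.
    """

    plot_id: int
    images: list  # list[np.ndarray], length n_timestamps
    combo_index: int
    yield_kg_ha: float
    treatment: str = ""
    variety: str = ""
    rate: str = ""
    masks: list = field(default_factory=list)  # optional ground-truth masks

    @property
    def n_timestamps(self) -> int:
        return len(self.images)

    def __post_init__(self):
        for img in self.images:
            arr = np.asarray(img)
            if arr.ndim != 3 or arr.shape[2] != 3:
                raise ValueError(
                    f"plot {self.plot_id}: images must be HxWx3, got {arr.shape}")
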