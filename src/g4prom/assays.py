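"""Proliferation/viability assay formulas and fluctuation-analysis summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GrowthObservation:
    """One exponential-growth interval: duration and cell concentrations."""

    duration: float  # hours
    c_initial: float  # cells/ml
    c_final: float  # cells/ml

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.c_initial <= 0 or self.c_final <= 0:
            raise ValueError("cell concentrations must be positive")


@dataclass(frozen=True)
class FluctuationDataset:
    """Per-clone percentages of cells that lost the marker."""

    label: str
    loss_percent: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.loss_percent, dtype=float)
        object.__setattr__(self, "loss_percent", v)
        if v.size < 1:
            raise ValueError("need at least one clone")
        if ((v < 0) | (v > 100)).any():
            raise ValueError("loss percentages must lie in [0, 100]")


def doubling_time(obs: GrowthObservation) -> float:
    """Doubling time = duration * log(2) / (log(c_final) - log(c_initial)).

    Positive for growing cultures; negative for declining ones (callers
    should flag negative values as decline, not growth).
    """
    if obs.c_final == obs.c_initial:
        raise ValueError("doubling time undefined when final equals initial concentration")
    return obs.duration * math.log(2) / (math.log(obs.c_final) - math.log(obs.c_initial))


def viability_percent(test_abs: float, control_abs: float) -> float:
    """Cell viability (%) = test absorbance / control absorbance * 100."""
    if control_abs <= 0:
        raise ValueError("control absorbance must be positive")
    return test_abs / control_abs * 100.0


def summarize_fluctuation(data: FluctuationDataset) -> dict:
    """Median and interquartile range of per-clone loss percentages.

    Quartiles use linear interpolation between order statistics.
    """
    v = data.loss_percent
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "label": data.label,
        "median": float(med),
        "iqr": float(q3 - q1),
        "q1": float(q1),
        "q3": float(q3),
        "n_clones": int(v.size),
    }
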