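"""Construction of the five-component hemoglobin signal.

The two independently measured quantities are per-voxel time series of
oxygenated- and deoxygenated-hemoglobin concentration deviations about their
temporal means (``oxy``, ``deoxy``; molar units).  Three dependent components
are derived from them:

* ``total``  = deoxy + oxy                      (molar)
* ``exc``    = deoxy - oxy  (oxygen exchange)   (molar)
* ``sat``    = 100 * change in oxy/total        (percent)

Saturation requires absolute baselines, which deviation-only inputs cannot
supply; ``DEFAULT_S0`` / ``DEFAULT_TOTAL0`` encode a typical-tissue
convention (70% saturation, 100 uM total hemoglobin) and are configurable
everywhere they are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "COMPONENTS",
    "DEFAULT_S0",
    "DEFAULT_TOTAL0",
    "DEFAULT_FRAME_RATE",
    "HbImageTimeSeries",
    "DegenerateSaturationError",
    "detrend_linear",
    "compute_dependent_components",
]

#: Canonical component ordering used throughout the package.
COMPONENTS: Tuple[str, ...] = ("deoxy", "exc", "oxy", "sat", "total")

DEFAULT_S0 = 0.7          # baseline oxy/total saturation fraction
DEFAULT_TOTAL0 = 1e-4     # molar baseline total hemoglobin
DEFAULT_FRAME_RATE = 1.8  # frames / second


class DegenerateSaturationError(ValueError):
    """Raised when a voxel's absolute total hemoglobin becomes non-positive."""


@dataclass
class HbImageTimeSeries:
    """Five co-registered N_t x N_v component matrices on a shared time base.

    ``components`` maps each name in :data:`COMPONENTS` to an
    ``(n_frames, n_voxels)`` float array.  ``baseline`` holds the absolute
    molar (oxy0, deoxy0) baselines used for the saturation computation.
    """

    components: Dict[str, np.ndarray]
    frame_rate: float = DEFAULT_FRAME_RATE
    baseline: Tuple[float, float] = field(
        default=(DEFAULT_S0 * DEFAULT_TOTAL0, (1.0 - DEFAULT_S0) * DEFAULT_TOTAL0)
    )

    def __post_init__(self) -> None:
        missing = set(COMPONENTS) - set(self.components)
        if missing:
            raise ValueError(f"missing components: {sorted(missing)}")
        shapes = {name: np.asarray(m).shape for name, m in self.components.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"component shape mismatch: {shapes}")
        shape = next(iter(shapes.values()))
        if len(shape) != 2 or shape[0] < 2 or shape[1] < 1:
            raise ValueError(f"need an (N_t >= 2, N_v >= 1) matrix, got {shape}")
        self.components = {
            name: np.asarray(m, dtype=float) for name, m in self.components.items()
        }

    @property
    def n_frames(self) -> int:
        return self.components["oxy"].shape[0]

    @property
    def n_voxels(self) -> int:
        return self.components["oxy"].shape[1]

    @property
    def s0(self) -> float:
        oxy0, deoxy0 = self.baseline
        return oxy0 / (oxy0 + deoxy0)

    @property
    def total0(self) -> float:
        return float(sum(self.baseline))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.components[name]


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the per-voxel least-squares linear trend along the time axis.

    Parameters
    ----------
    series : (N_t, N_v) array
        One matrix per call; columns are voxels.

    Returns
    -------
    (N_t, N_v) array of residuals about each column's fitted line.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    n_t = series.shape[0]
    if n_t < 2:
        raise ValueError("detrend_linear requires at least 2 time frames")
    t = np.arange(n_t, dtype=float)
    t = t - t.mean()
    # OLS on centered time: slope = <t, x> / <t, t>, intercept = mean(x)
    slope = t @ (series - series.mean(axis=0)) / (t @ t)
    return series - series.mean(axis=0) - np.outer(t, slope)


def compute_dependent_components(
    oxy: np.ndarray,
    deoxy: np.ndarray,
    baseline: Tuple[float, float] = (
        DEFAULT_S0 * DEFAULT_TOTAL0,
        (1.0 - DEFAULT_S0) * DEFAULT_TOTAL0,
    ),
    frame_rate: float = DEFAULT_FRAME_RATE,
    detrend: bool = True,
) -> HbImageTimeSeries:
    """Build the five-component series from independent oxy/deoxy inputs.

    The independent components are (optionally) linearly detrended first;
    the dependent components are computed from the detrended matrices.
    Saturation uses the absolute baselines::

        sat = 100 * [(oxy0 + oxy) / (total0 + total) - oxy0 / total0]

    after which every component is re-referenced to zero temporal mean per
    voxel (state signs are defined relative to temporal means).
    """
    oxy = np.atleast_2d(np.asarray(oxy, dtype=float))
    deoxy = np.atleast_2d(np.asarray(deoxy, dtype=float))
    if oxy.shape != deoxy.shape:
        raise ValueError(f"oxy {oxy.shape} and deoxy {deoxy.shape} shapes differ")
    oxy0, deoxy0 = baseline
    if oxy0 <= 0 or deoxy0 <= 0:
        raise ValueError("baselines (oxy0, deoxy0) must be positive")

    if detrend:
        oxy = detrend_linear(oxy)
        deoxy = detrend_linear(deoxy)

    total = deoxy + oxy
    exc = deoxy - oxy
    total0 = oxy0 + deoxy0

    abs_total = total0 + total
    if np.any(abs_total <= 0):
        i, j = np.unravel_index(int(np.argmin(abs_total)), abs_total.shape)
        raise DegenerateSaturationError(
            f"absolute totalHb <= 0 at frame {i}, voxel {j} "
            f"(value {abs_total[i, j]:.3e} M)"
        )
    sat = 100.0 * ((oxy0 + oxy) / abs_total - oxy0 / total0)

    components = {"deoxy": deoxy, "exc": exc, "oxy": oxy, "sat": sat, "total": total}
    # zero-mean re-referencing: signs are deviations about the temporal mean
    components = {k: v - v.mean(axis=0) for k, v in components.items()}
    return HbImageTimeSeries(
        components=components, frame_rate=frame_rate, baseline=(oxy0, deoxy0)
    )
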