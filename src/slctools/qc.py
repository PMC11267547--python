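"""Plate-level screening QC: percent-activity normalisation and robust Z'.

Raw plate readouts are normalised against the medians of the minimum-signal
(blank) and maximum-signal (neutral) control wells,

    %Activity = 100 * (x - MIN) / (MAX - MIN),

and plate quality is summarised by the robust Z' factor,

    RZ' = 1 - 3 * (RSD_max + RSD_min) / |median_max - median_min|,

the classic Z' with means and standard deviations replaced by medians and
robust standard deviations (1.4826 x the median absolute deviation, the
normal-consistent scaling).  RZ' is at most 1; values near 1 indicate a
wide, low-noise assay window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlateControls", "robust_sd", "percent_activity", "robust_z_prime"]

#: Normal-consistency factor turning a MAD into a standard-deviation scale.
MAD_SCALE = 1.4826


@dataclass
class PlateControls:
    """Control-well readouts for one plate.

    max_values: neutral controls defining the 100% activity level.
    min_values: blank controls defining the 0% level.
    """

    max_values: "np.ndarray"
    min_values: "np.ndarray"

    def __post_init__(self):
        self.max_values = np.asarray(self.max_values, dtype=float)
        self.min_values = np.asarray(self.min_values, dtype=float)
        for name, arr in (("max_values", self.max_values), ("min_values", self.min_values)):
            if arr.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")

    @property
    def median_max(self) -> float:
        return float(np.median(self.max_values))

    @property
    def median_min(self) -> float:
        return float(np.median(self.min_values))


def robust_sd(values) -> float:
    """Robust standard deviation: 1.4826 x median absolute deviation."""
    arr = np.asarray(values, dtype=float)
    return MAD_SCALE * float(np.median(np.abs(arr - np.median(arr))))


def percent_activity(x, controls: PlateControls):
    """Normalise readouts to percent activity between the control medians.

    The blank-control median maps to 0%, the neutral-control median to 100%;
    values outside [0, 100] are allowed.  Affine-invariant: rescaling all
    readouts (controls included) by a*x + b leaves percentages unchanged.
    """
    lo, hi = controls.median_min, controls.median_max
    if hi == lo:
        raise ValueError("control medians are equal; %activity undefined")
    out = 100.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo)
    return float(out) if np.ndim(x) == 0 else out


def robust_z_prime(controls: PlateControls) -> float:
    """Robust Z' factor of a plate from its control wells.

    1 for zero-spread controls; decreases as control spread grows relative
    to the assay window.
    """
    window = abs(controls.median_max - controls.median_min)
    if window == 0:
        raise ValueError("control medians are equal; robust Z' undefined")
    spread = robust_sd(controls.max_values) + robust_sd(controls.min_values)
    return 1.0 - 3.0 * spread / window
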