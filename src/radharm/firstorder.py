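"""Intensity statistics of the ROI.

Minimum, maximum, mean and standard deviation are computed on the raw masked
intensities and therefore do not depend on any calculation setting; skewness
is computed on the *discretised* grey levels (the "intensity histogram"
convention), so it inherits the discretisation settings.  This split is the
mechanism by which harmonising settings affects some first-order features and
not others.

Moments are population (1/N) moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .discretise import DiscretisedROI
from .volume import VolumeWithMask

__all__ = ["FirstOrderFeatures", "first_order", "discretised_skewness"]


@dataclass
class FirstOrderFeatures:
    minimum: float
    maximum: float
    mean: float
    standard_deviation: float


def first_order(vol: VolumeWithMask) -> FirstOrderFeatures:
    """Raw-intensity statistics over the masked voxels (population SD)."""
    if vol.n_voxels == 0:
        raise ValueError("empty mask")
    x = vol.roi_values
    return FirstOrderFeatures(
        minimum=float(x.min()),
        maximum=float(x.max()),
        mean=float(x.mean()),
        standard_deviation=float(x.std()),  # 1/N normaliser
    )


def discretised_skewness(disc: DiscretisedROI) -> float:
    """Fisher skewness g1 = m3 / m2^(3/2) of the grey-level values.

    A flat (single-level) ROI has undefined skewness; by convention it is
    returned as 0 with a warning.
    """
    g = disc.roi_levels.astype(float)
    m = g.mean()
    m2 = np.mean((g - m) ** 2)
    if m2 == 0:
        warnings.warn("degenerate ROI: single grey level, skewness set to 0", stacklevel=2)
        return 0.0
    m3 = np.mean((g - m) ** 3)
    return float(m3 / m2 ** 1.5)
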