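"""Grey-level discretisation under the three dialects used by the platforms.

All texture and histogram features operate on integer grey levels rather than
raw intensities.  Platforms differ in how they map intensities to levels:

* ``fixed_bin_number_roi_range`` (IBSI FBN): ``g = floor(Ng*(x-lo)/(hi-lo)) + 1``
  with ``lo``/``hi`` the masked minimum/maximum and ``x = hi`` clamped into
  bin ``Ng``.  Invariant under affine rescaling of the ROI intensities.
* ``fixed_bin_number_fixed_range``: the same formula with fixed numeric
  bounds; out-of-range intensities are clamped to the end bins so that the
  voxel count is conserved.
* ``fixed_bin_width`` (IBSI FBS): ``g = floor((x - lo)/w) + 1`` with bin
  width ``w``; a numeric upper bound, when present, clamps intensities first.

The choice of dialect and its parameters is exactly what differs between the
shipped platform profiles, and is the mechanism by which texture features
lose cross-platform reliability when settings are not harmonised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import ROI_MAX, ROI_MIN, DiscretisationSettings, SettingsProfile
from .volume import VolumeWithMask

__all__ = ["DiscretisedROI", "discretise", "discretise_with"]


@dataclass
class DiscretisedROI:
    """Integer grey levels for the masked voxels, kept on the original grid.

    ``levels`` is a full-grid int array; unmasked voxels hold 0 and carry no
    level.  ``ng_eff`` bounds the occupied levels (``n_bins`` for the
    fixed-bin-number modes, the highest occupied level for fixed bin width).
    """

    levels: np.ndarray
    mask: np.ndarray
    ng_eff: int
    resolved_bounds: tuple[float, float]
    degenerate: bool = False

    @property
    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    def histogram(self) -> np.ndarray:
        """Counts per level 1..ng_eff; sums to the masked voxel count."""
        return np.bincount(self.roi_levels, minlength=self.ng_eff + 1)[1:]


def _resolve_bounds(settings: DiscretisationSettings, roi: np.ndarray) -> tuple[float, float]:
    lo = float(roi.min()) if settings.lower_bound == ROI_MIN else float(settings.lower_bound)
    hi = float(roi.max()) if settings.upper_bound == ROI_MAX else float(settings.upper_bound)
    return lo, hi


def discretise_with(vol: VolumeWithMask, settings: DiscretisationSettings) -> DiscretisedROI:
    """Discretise the masked intensities under one settings block."""
    if vol.n_voxels == 0:
        raise ValueError("cannot discretise an empty mask")
    roi = vol.roi_values
    lo, hi = _resolve_bounds(settings, roi)

    levels = np.zeros(vol.image.shape, dtype=np.int64)
    degenerate = False

    if settings.mode == "fixed_bin_width":
        w = float(settings.bin_width)
        x = roi
        if isinstance(settings.upper_bound, (int, float)):
            x = np.clip(x, lo, hi)
        else:
            x = np.maximum(x, lo)
        g = np.floor((x - lo) / w).astype(np.int64) + 1
        if isinstance(settings.upper_bound, (int, float)):
            # the exact upper edge of the window belongs to the last bin
            span = (hi - lo) / w
            top = int(span) if span == int(span) else int(span) + 1
            g = np.minimum(g, max(top, 1))
        ng_eff = int(g.max())
        if ng_eff == 1 and np.ptp(roi) == 0:
            degenerate = True
    else:
        ng = int(settings.n_bins)
        if hi == lo:
            g = np.ones(roi.shape, dtype=np.int64)
            levels[vol.mask] = g
            return DiscretisedROI(levels, vol.mask, 1, (lo, hi), degenerate=True)
        x = np.clip(roi, lo, hi)
        g = np.floor(ng * (x - lo) / (hi - lo)).astype(np.int64) + 1
        g = np.minimum(g, ng)  # close the top edge (and guard float round-up)
        ng_eff = ng

    levels[vol.mask] = g
    return DiscretisedROI(levels, vol.mask, ng_eff, (lo, hi), degenerate=degenerate)


def discretise(vol: VolumeWithMask, profile: SettingsProfile,
               family: str = "histogram") -> DiscretisedROI:
    """Discretise under the profile's settings for one matrix family.

    ``family`` is ``"histogram"``, ``"glcm"`` or ``"ngtdm"`` — platforms may
    configure these independently.
    """
    if family not in ("histogram", "glcm", "ngtdm"):
        raise ValueError(f"unknown discretisation family {family!r}")
    return discretise_with(vol, getattr(profile, family))
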