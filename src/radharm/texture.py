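"""Grey-level co-occurrence (GLCM) and neighbourhood grey tone difference
(NGTDM) matrices and their features.

GLCM
    Pairs of grey levels at the profile's displacement vectors (direction x
    offset) are counted over the ROI; both voxels of a pair must be masked.
    All directions and offsets are merged into one symmetric matrix per
    subject (IBSI "3D merged" aggregation), from which six features are
    computed: correlation, contrast, angular second moment, joint entropy,
    difference average and inverse difference.

NGTDM
    For each valid voxel (one with at least one masked neighbour within
    Chebyshev distance d) the absolute difference between its level i and the
    mean level of its masked neighbours is accumulated into s_i.  Coarseness,
    busyness and contrast follow Amadasun & King's definitions, with
    degeneracy conventions: coarseness is capped at 1e6 when sum(p_i s_i)
    vanishes, busyness is 0 when its denominator vanishes, contrast is 0 when
    only one grey level is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretise import DiscretisedROI
from .profiles import SettingsProfile

__all__ = [
    "CooccurrenceMatrix",
    "NgtdmTable",
    "build_glcm",
    "glcm_features",
    "build_ngtdm",
    "ngtdm_features",
    "COARSENESS_CAP",
]

COARSENESS_CAP = 1e6


@dataclass
class CooccurrenceMatrix:
    """Symmetric co-occurrence counts over grey levels 1..Ng."""

    counts: np.ndarray  # (Ng, Ng) int, symmetric
    degenerate: bool = False  # no valid pair

    @property
    def n_levels(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("degenerate matrix: no co-occurring pair")
        return self.counts / total

    def difference_distribution(self) -> np.ndarray:
        """p_diff(k) = sum of P(i, j) over |i - j| = k, k = 0..Ng-1."""
        p = self.probabilities
        ng = self.n_levels
        i, j = np.indices((ng, ng))
        return np.bincount(np.abs(i - j).ravel(), weights=p.ravel(), minlength=ng)


@dataclass
class NgtdmTable:
    """Per-level neighbourhood grey tone difference sums."""

    n: np.ndarray      # n_i, voxel count per level (1-based level i = index+1)
    s: np.ndarray      # s_i, summed |i - neighbourhood mean|
    n_valid: int       # N_v, voxels with >= 1 masked neighbour
    degenerate: bool = False

    @property
    def p(self) -> np.ndarray:
        return self.n / self.n_valid if self.n_valid else np.zeros_like(self.s)

    @property
    def n_grey_levels_present(self) -> int:
        return int((self.n > 0).sum())


def build_glcm(disc: DiscretisedROI, profile: SettingsProfile) -> CooccurrenceMatrix:
    """Accumulate the merged symmetric co-occurrence matrix for one ROI."""
    ng = disc.ng_eff
    levels = disc.levels  # 0 outside the mask
    counts = np.zeros((ng, ng), dtype=np.int64)
    shape = levels.shape

    for direction in profile.glcm_directions:
        for offset in profile.glcm_offsets:
            dz, dy, dx = (c * offset for c in direction)
            src = tuple(
                slice(max(0, -d), max(0, min(s, s - d))) for d, s in zip((dz, dy, dx), shape)
            )
            dst = tuple(
                slice(max(0, d), max(0, min(s, s + d))) for d, s in zip((dz, dy, dx), shape)
            )
            a = levels[src].ravel()
            b = levels[dst].ravel()
            keep = (a > 0) & (b > 0)  # both voxels masked
            if not keep.any():
                continue
            flat = (a[keep] - 1) * ng + (b[keep] - 1)
            counts += np.bincount(flat, minlength=ng * ng).reshape(ng, ng)

    if profile.glcm_symmetric:
        counts = counts + counts.T  # each pair counted in both orders

    return CooccurrenceMatrix(counts=counts, degenerate=counts.sum() == 0)


def glcm_features(m: CooccurrenceMatrix, eps_guard: float = 1e-12) -> dict[str, float]:
    """The six co-occurrence features from a merged symmetric matrix.

    A degenerate (single-cell) matrix takes the homogeneous-ROI conventions:
    correlation 1, contrast 0, ASM 1, entropy 0, difference average 0,
    inverse difference 1.
    """
    p = m.probabilities
    ng = m.n_levels
    i, j = np.indices((ng, ng), dtype=float)
    i += 1
    j += 1

    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())

    if var_i < eps_guard or var_j < eps_guard:
        correlation = 1.0  # flat region: perfectly self-correlated by convention
    else:
        correlation = float((((i - mu_i) * (j - mu_j) * p).sum())
                            / np.sqrt(var_i * var_j))

    nz = p[p > 0]
    k = np.arange(ng, dtype=float)
    p_diff = m.difference_distribution()
    return {
        "glcm_correlation": correlation,
        "glcm_contrast": float((((i - j) ** 2) * p).sum()),
        "glcm_angular_second_moment": float((p ** 2).sum()),
        "glcm_joint_entropy": float(-(nz * np.log2(nz)).sum()),
        "glcm_difference_average": float((k * p_diff).sum()),
        "glcm_inverse_difference": float((p / (1.0 + np.abs(i - j))).sum()),
    }


def build_ngtdm(disc: DiscretisedROI, profile: SettingsProfile) -> NgtdmTable:
    """Neighbourhood grey tone difference table at the profile's distance.

    The neighbourhood is the full Chebyshev-d cube minus the centre,
    intersected with the mask; voxels with no masked neighbour are excluded
    from N_v.
    """
    d = profile.ngtdm_distance
    ng = disc.ng_eff
    mask = disc.mask
    levels = disc.levels.astype(float)

    size = 2 * d + 1
    kernel = np.ones((size, size, size))
    kernel[d, d, d] = 0.0

    neigh_sum = ndimage.convolve(levels * mask, kernel, mode="constant", cval=0.0)
    neigh_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    neigh_cnt = np.round(neigh_cnt)  # counts are integers; kill float fuzz

    valid = mask & (neigh_cnt > 0)
    n_valid = int(valid.sum())
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng, dtype=float)
    if n_valid == 0:
        return NgtdmTable(n=n, s=s, n_valid=0, degenerate=True)

    g = disc.levels[valid]
    abar = neigh_sum[valid] / neigh_cnt[valid]
    diffs = np.abs(g - abar)
    n = np.bincount(g - 1, minlength=ng)
    s = np.bincount(g - 1, weights=diffs, minlength=ng)
    return NgtdmTable(n=n, s=s, n_valid=n_valid)


def ngtdm_features(t: NgtdmTable, eps_guard: float = 1e-12) -> dict[str, float]:
    """Coarseness, busyness and contrast from an NGTDM table."""
    if t.n_valid == 0:
        return {"ngtdm_coarseness": COARSENESS_CAP, "ngtdm_busyness": 0.0,
                "ngtdm_contrast": 0.0}
    p = t.p
    s = t.s
    ng = len(p)
    i = np.arange(1, ng + 1, dtype=float)
    present = p > 0
    n_gp = int(present.sum())

    ps = float((p * s).sum())
    coarseness = COARSENESS_CAP if ps < eps_guard else min(1.0 / ps, COARSENESS_CAP)

    ip = i * p
    ii, jj = np.meshgrid(np.where(present)[0], np.where(present)[0], indexing="ij")
    busy_den = float(np.abs(ip[ii] - ip[jj]).sum())
    busyness = 0.0 if busy_den < eps_guard else ps / busy_den

    if n_gp <= 1:
        contrast = 0.0
    else:
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        gi, gj = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float(
            (pi * pj * (gi - gj) ** 2).sum() / (n_gp * (n_gp - 1))
            * (s.sum() / t.n_valid)
        )
    return {"ngtdm_coarseness": float(coarseness),
            "ngtdm_busyness": float(busyness),
            "ngtdm_contrast": contrast}
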