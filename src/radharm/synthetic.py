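"""Synthetic stand-ins for the clinical inputs: CT-like tumour phantoms,
multi-rater ratings with known variance components, and survival cohorts
with a planted feature-hazard link.

Phantoms are ellipsoids (optionally lobulated) filled with a spatially
correlated Gaussian texture — Gaussian-filtered white noise rescaled to a
target SD and laid over a base intensity in Hounsfield-like units — plus
independent voxel noise.  The correlation length and texture SD are the two
interpretable knobs: the first moves texture features that measure local
homogeneity (NGTDM coarseness, GLCM correlation/entropy), the second moves
the ROI intensity range and everything discretised over fixed intensity
windows.

Survival cohorts use an exponential baseline hazard h0 * exp(beta * z) with
administrative censoring at the follow-up horizon; h0 is calibrated so the
expected event count matches the target fraction.  Default calibration:
108 subjects, 28 expected events within a 2.2-year horizon — the scale of a
typical single-centre head-and-neck radiotherapy cohort.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .survival import SurvivalCohort
from .volume import VolumeWithMask

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_phantom_cohort",
    "generate_cohort",
    "generate_ratings",
    "theoretical_icc",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tumour volume."""

    shape: tuple[int, int, int] = (40, 48, 48)
    spacing: tuple[float, float, float] = (3.0, 0.97, 0.97)  # mm, CT-like anisotropy
    semi_axes: tuple[float, float, float] = (12.0, 14.0, 14.0)  # mm
    lobulation: float = 0.0          # relative radial perturbation amplitude
    base_intensity: float = 40.0     # HU, soft-tissue-like
    texture_corr_length: float = 2.0  # voxels (isotropic filter sigma)
    texture_sd: float = 40.0         # HU
    noise_sd: float = 10.0           # HU
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if self.texture_sd < 0 or self.noise_sd < 0 or self.lobulation < 0:
            raise ValueError("SDs and lobulation amplitude must be non-negative")
        # the mask must fit the grid with at least a one-voxel margin
        for ax, (n, sp, a) in enumerate(zip(self.shape, self.spacing, self.semi_axes)):
            if a * (1 + self.lobulation) >= (n / 2 - 1.5) * sp:
                raise ValueError(
                    f"semi-axis {a} mm (axis {ax}) does not fit a {n}-voxel grid "
                    f"at {sp} mm spacing with a one-voxel margin"
                )


@dataclass
class CohortSpec:
    """Parameters of a synthetic survival cohort."""

    n: int = 108
    horizon_years: float = 2.2
    event_fraction: float = 28 / 108
    beta: float = 0.0               # planted log-hazard per SD of the feature
    feature_name: str = ""          # the canonical feature carrying the effect
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.event_fraction < 1:
            raise ValueError("event fraction must lie in (0, 1)")
        if self.horizon_years <= 0:
            raise ValueError("follow-up horizon must be positive")
        if self.n < 2:
            raise ValueError("cohort needs at least 2 subjects")


def generate_phantom(spec: PhantomSpec, subject_id: str = "") -> VolumeWithMask:
    """Deterministically generate one phantom from its spec and seed."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing

    coords = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2) * sp for n, sp in zip(shape, spacing)],
        indexing="ij",
    )
    scaled = [c / a for c, a in zip(coords, spec.semi_axes)]
    r = np.sqrt(sum(s ** 2 for s in scaled))

    if spec.lobulation > 0:
        # low-order angular modulation of the ellipsoid radius
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.where(r > 0, scaled[0] / np.maximum(r, 1e-12), 0), -1, 1))
            phi = np.arctan2(scaled[1], scaled[2])
        bump = 1 + spec.lobulation * (np.cos(3 * phi) * np.sin(theta) ** 2
                                      + 0.5 * np.cos(2 * theta))
        mask = r <= bump
    else:
        mask = r <= 1.0

    field = rng.standard_normal(shape)
    if spec.texture_corr_length > 0:
        field = ndimage.gaussian_filter(field, sigma=spec.texture_corr_length)
    std = field.std()
    texture = field / std * spec.texture_sd if std > 0 and spec.texture_sd > 0 else np.zeros(shape)
    noise = rng.normal(0.0, spec.noise_sd, shape) if spec.noise_sd > 0 else 0.0

    image = spec.base_intensity + texture + noise
    return VolumeWithMask(image=image, mask=mask, spacing=spacing,
                          subject_id=subject_id or f"phantom_{spec.seed}")


def generate_phantom_cohort(
    n: int,
    seed: int = 0,
    *,
    shape: tuple[int, int, int] = (40, 48, 48),
    spacing: tuple[float, float, float] = (3.0, 0.97, 0.97),
    semi_axis_range: tuple[float, float] = (8.0, 15.0),
    lobulation_range: tuple[float, float] = (0.0, 0.25),
    base_range: tuple[float, float] = (20.0, 60.0),
    corr_length_range: tuple[float, float] = (1.0, 3.5),
    texture_sd_range: tuple[float, float] = (15.0, 90.0),
    noise_sd: float = 10.0,
) -> tuple[list[VolumeWithMask], pd.DataFrame]:
    """A cohort of phantoms with independently varying shape and texture.

    Returns the volumes plus a frame of the latent per-subject knobs
    (semi-axes, lobulation, correlation length, texture SD) that downstream
    demos can plant survival effects on.
    """
    rng = np.random.default_rng(seed)
    volumes, latents = [], []
    for i in range(n):
        axes = tuple(rng.uniform(*semi_axis_range, size=3))
        spec = PhantomSpec(
            shape=shape,
            spacing=spacing,
            semi_axes=axes,
            lobulation=float(rng.uniform(*lobulation_range)),
            base_intensity=float(rng.uniform(*base_range)),
            texture_corr_length=float(rng.uniform(*corr_length_range)),
            texture_sd=float(rng.uniform(*texture_sd_range)),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sid = f"s{i:04d}"
        volumes.append(generate_phantom(spec, subject_id=sid))
        latents.append({
            "subject_id": sid,
            "semi_a": axes[0], "semi_b": axes[1], "semi_c": axes[2],
            "lobulation": spec.lobulation,
            "base_intensity": spec.base_intensity,
            "corr_length": spec.texture_corr_length,
            "texture_sd": spec.texture_sd,
        })
    return volumes, pd.DataFrame(latents)


def generate_cohort(spec: CohortSpec, z: np.ndarray | None = None) -> SurvivalCohort:
    """Survival cohort with hazard h0 * exp(beta * z), censored at the horizon.

    ``z`` is the per-subject (standardised) feature carrying the planted
    effect; omitted or with ``beta = 0`` the cohort is null.  The baseline
    hazard h0 is calibrated so the *expected* number of events over the
    horizon equals ``event_fraction * n``.
    """
    if z is None:
        z = np.zeros(spec.n)
    z = np.asarray(z, dtype=float)
    if len(z) != spec.n:
        raise ValueError(f"feature vector length {len(z)} != cohort size {spec.n}")

    rel = np.exp(spec.beta * z)
    h = spec.horizon_years
    f = spec.event_fraction

    def expected_fraction(h0: float) -> float:
        return float(np.mean(1.0 - np.exp(-h0 * rel * h)))

    # expected fraction is monotone in h0, 0 at 0 and -> 1 as h0 -> inf
    hi = 1.0
    while expected_fraction(hi) < f:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(
                f"event fraction {f} unattainable; bound {expected_fraction(1e12):.4f}"
            )
    h0 = optimize.brentq(lambda x: expected_fraction(x) - f, 1e-12, hi)

    rng = np.random.default_rng(spec.seed)
    t_event = rng.exponential(1.0, size=spec.n) / (h0 * rel)
    event = (t_event <= h).astype(int)
    time = np.minimum(t_event, h)
    time = np.maximum(time, 1e-6)  # guard exact zeros
    return SurvivalCohort(time=time, event=event)


def generate_ratings(n: int, k: int, subject_sd: float, rater_bias_sd: float,
                     noise_sd: float, seed: int = 0) -> np.ndarray:
    """n x k matrix value(s, r) = subject effect + rater effect + noise."""
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 subjects and k >= 2 raters")
    if min(subject_sd, rater_bias_sd, noise_sd) < 0:
        raise ValueError("SDs must be non-negative")
    rng = np.random.default_rng(seed)
    subjects = rng.normal(0.0, subject_sd, size=(n, 1))
    raters = rng.normal(0.0, rater_bias_sd, size=(1, k))
    noise = rng.normal(0.0, noise_sd, size=(n, k))
    return subjects + raters + noise


def theoretical_icc(subject_sd: float, rater_bias_sd: float, noise_sd: float) -> float:
    """Absolute-agreement ICC implied by the variance components."""
    s2, r2, e2 = subject_sd ** 2, rater_bias_sd ** 2, noise_sd ** 2
    return s2 / (s2 + r2 + e2)
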