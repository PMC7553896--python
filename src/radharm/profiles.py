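"""Calculation-settings profiles and feature-name harmonisation.

A :class:`SettingsProfile` captures every user-defined parameter that goes
into computing the 17-feature panel: how intensities are discretised for the
histogram, GLCM and NGTDM families (the three families may use different
settings, as real platforms do), which displacement vectors and offsets the
co-occurrence matrix accumulates, and the NGTDM neighbourhood distance.  A
profile plays the role of a "rater" in the downstream reliability analysis:
two profiles with different settings stand in for two software platforms, a
profile and a perturbed clone stand in for two versions of one platform.

Five profiles ship with the package: the published default settings of four
widely used radiomics platforms (LIFEx, IBEX, PyRadiomics, CERR) and a
harmonised profile (64 grey levels over the ROI intensity range, 13 GLCM
directions at offset 1, symmetric accumulation, NGTDM distance 1).

The :class:`FeatureAliasRegistry` maps each platform's naming of the 17
features onto one canonical snake_case vocabulary used everywhere else.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

import yaml

__all__ = [
    "CANONICAL_FEATURES",
    "DiscretisationSettings",
    "SettingsProfile",
    "FeatureAliasRegistry",
    "builtin_profile",
    "builtin_profile_names",
    "canonical_feature_name",
    "load_profile",
    "directions_3d_13",
    "directions_2d_4",
]

#: The canonical 17-feature panel, in report order.
CANONICAL_FEATURES: tuple[str, ...] = (
    "volume",
    "area",
    "sphericity",
    "minimum",
    "maximum",
    "mean",
    "standard_deviation",
    "skewness",
    "glcm_correlation",
    "glcm_contrast",
    "glcm_angular_second_moment",
    "glcm_joint_entropy",
    "glcm_difference_average",
    "glcm_inverse_difference",
    "ngtdm_coarseness",
    "ngtdm_busyness",
    "ngtdm_contrast",
)

ROI_MIN = "roi_min"
ROI_MAX = "roi_max"

Bound = Union[float, str]


class ProfileError(ValueError):
    """Invalid or unknown settings profile."""


class AliasLookupError(KeyError):
    """Unknown platform feature alias."""


def directions_3d_13() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique symmetric displacement vectors at Chebyshev distance 1.

    Of the 26 neighbours of a voxel, opposite vectors produce the same
    symmetric co-occurrence pairs, leaving 26/2 = 13 distinct directions.
    """
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d == (0, 0, 0):
                    continue
                if d > (0, 0, 0):  # keep one of each ± pair
                    dirs.append(d)
    assert len(dirs) == 13
    return tuple(dirs)


def directions_2d_4() -> tuple[tuple[int, int, int], ...]:
    """The 4 canonical in-plane (2D, slice-wise) directions: 0/45/90/135 deg."""
    return ((0, 0, 1), (0, 1, 1), (0, 1, 0), (0, 1, -1))


@dataclass(frozen=True)
class DiscretisationSettings:
    """How continuous intensities become integer grey levels.

    mode
        ``fixed_bin_number_roi_range`` — Ng bins between the masked minimum
        and maximum (IBSI FBN); ``fixed_bin_number_fixed_range`` — Ng bins
        between fixed numeric bounds, out-of-range values clamped to the end
        bins; ``fixed_bin_width`` — bins of width ``bin_width`` starting at
        ``lower_bound`` (IBSI FBS).
    lower_bound / upper_bound
        numeric, or the symbolic strings ``"roi_min"`` / ``"roi_max"``
        resolved against the masked voxels at extraction time.
    """

    mode: str
    n_bins: int | None = None
    bin_width: float | None = None
    lower_bound: Bound = ROI_MIN
    upper_bound: Bound = ROI_MAX

    _MODES = ("fixed_bin_number_roi_range", "fixed_bin_number_fixed_range", "fixed_bin_width")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ProfileError(f"unknown discretisation mode {self.mode!r}; expected one of {self._MODES}")
        if self.mode.startswith("fixed_bin_number"):
            if self.n_bins is None or self.n_bins < 2:
                raise ProfileError("fixed_bin_number modes require n_bins >= 2")
        else:
            if self.bin_width is None or self.bin_width <= 0:
                raise ProfileError("fixed_bin_width requires bin_width > 0")
        lo, hi = self.lower_bound, self.upper_bound
        if isinstance(lo, (int, float)) and isinstance(hi, (int, float)) and not lo < hi:
            raise ProfileError(f"lower_bound {lo} must be < upper_bound {hi}")


@dataclass(frozen=True)
class SettingsProfile:
    """A complete set of calculation settings identifying one 'platform' rater."""

    name: str
    histogram: DiscretisationSettings
    glcm: DiscretisationSettings
    ngtdm: DiscretisationSettings
    glcm_directions: tuple[tuple[int, int, int], ...] = field(default_factory=directions_3d_13)
    glcm_offsets: tuple[int, ...] = (1,)
    glcm_symmetric: bool = True
    ngtdm_distance: int = 1
    eps_guard: float = 1e-12

    def __post_init__(self) -> None:
        if not self.glcm_directions:
            raise ProfileError("glcm_directions must be non-empty")
        if any(o < 1 for o in self.glcm_offsets) or not self.glcm_offsets:
            raise ProfileError("glcm_offsets must be positive integers")
        if self.ngtdm_distance < 1:
            raise ProfileError("ngtdm_distance must be a positive integer")
        if self.eps_guard <= 0:
            raise ProfileError("eps_guard must be positive")

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["glcm_directions"] = [list(v) for v in self.glcm_directions]
        d["glcm_offsets"] = list(self.glcm_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SettingsProfile":
        d = dict(d)
        for key in ("histogram", "glcm", "ngtdm"):
            if isinstance(d.get(key), dict):
                d[key] = DiscretisationSettings(**d[key])
        if "glcm_directions" in d:
            d["glcm_directions"] = tuple(tuple(int(c) for c in v) for v in d["glcm_directions"])
        if "glcm_offsets" in d:
            d["glcm_offsets"] = tuple(int(o) for o in d["glcm_offsets"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SettingsProfile":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def perturbed(self, name: str | None = None, **changes) -> "SettingsProfile":
        """Clone with modified settings — emulates a 'version change' rater.

        Discretisation changes given as ``histogram=...``/``glcm=...``/
        ``ngtdm=...`` dicts are merged into the existing blocks.
        """
        merged = {}
        for key in ("histogram", "glcm", "ngtdm"):
            if key in changes and isinstance(changes[key], dict):
                merged[key] = replace(getattr(self, key), **changes.pop(key))
        return replace(self, name=name or f"{self.name}_perturbed", **merged, **changes)


def _fbn(n: int, lo: Bound, hi: Bound) -> DiscretisationSettings:
    mode = (
        "fixed_bin_number_roi_range"
        if lo == ROI_MIN and hi == ROI_MAX
        else "fixed_bin_number_fixed_range"
    )
    return DiscretisationSettings(mode=mode, n_bins=n, lower_bound=lo, upper_bound=hi)


def _fbs(w: float, lo: Bound, hi: Bound = ROI_MAX) -> DiscretisationSettings:
    return DiscretisationSettings(mode="fixed_bin_width", bin_width=w, lower_bound=lo, upper_bound=hi)


def _builtin_profiles() -> dict[str, SettingsProfile]:
    d13, d4 = directions_3d_13(), directions_2d_4()
    return {
        # LIFEx defaults: 400 grey levels over the fixed CT range [-1000, 3000].
        "lifex_default": SettingsProfile(
            name="lifex_default",
            histogram=_fbn(400, -1000.0, 3000.0),
            glcm=_fbn(400, -1000.0, 3000.0),
            ngtdm=_fbn(400, -1000.0, 3000.0),
            glcm_directions=d13,
            glcm_offsets=(1,),
            ngtdm_distance=1,
        ),
        # IBEX defaults: per-family fixed ranges; GLCM offsets 1, 4 and 7;
        # NGTDM distance 2.
        "ibex_default": SettingsProfile(
            name="ibex_default",
            histogram=_fbn(256, 0.0, 4096.0),
            glcm=_fbn(100, 0.0, 2100.0),
            ngtdm=_fbn(256, 0.0, 4096.0),
            glcm_directions=d13,
            glcm_offsets=(1, 4, 7),
            ngtdm_distance=2,
        ),
        # PyRadiomics defaults: bin width 25 from the ROI minimum.
        "pyradiomics_default": SettingsProfile(
            name="pyradiomics_default",
            histogram=_fbs(25.0, ROI_MIN),
            glcm=_fbs(25.0, ROI_MIN),
            ngtdm=_fbs(25.0, ROI_MIN),
            glcm_directions=d13,
            glcm_offsets=(1,),
            ngtdm_distance=1,
        ),
        # CERR defaults: bin width 25 on the fixed window [0, 500];
        # 4 in-plane GLCM directions.
        "cerr_default": SettingsProfile(
            name="cerr_default",
            histogram=_fbs(25.0, 0.0, 500.0),
            glcm=_fbs(25.0, 0.0, 500.0),
            ngtdm=_fbs(25.0, 0.0, 500.0),
            glcm_directions=d4,
            glcm_offsets=(1,),
            ngtdm_distance=1,
        ),
        # Harmonised settings: 64 grey levels between ROI min and max,
        # 13 directions, offset 1, symmetric, NGTDM distance 1.
        "harmonised": SettingsProfile(
            name="harmonised",
            histogram=_fbn(64, ROI_MIN, ROI_MAX),
            glcm=_fbn(64, ROI_MIN, ROI_MAX),
            ngtdm=_fbn(64, ROI_MIN, ROI_MAX),
            glcm_directions=d13,
            glcm_offsets=(1,),
            ngtdm_distance=1,
        ),
    }


def builtin_profile_names() -> tuple[str, ...]:
    return tuple(_builtin_profiles())


def builtin_profile(name: str) -> SettingsProfile:
    """Return a shipped profile by name.

    Raises :class:`ProfileError` for unknown names.
    """
    profiles = _builtin_profiles()
    try:
        return profiles[name]
    except KeyError:
        raise ProfileError(
            f"unknown profile {name!r}; available: {', '.join(sorted(profiles))}"
        ) from None


def load_profile(name_or_path: str | Path) -> SettingsProfile:
    """Resolve a builtin profile name or a YAML profile file path."""
    if str(name_or_path) in _builtin_profiles():
        return builtin_profile(str(name_or_path))
    p = Path(name_or_path)
    if p.exists():
        return SettingsProfile.from_yaml(p)
    raise ProfileError(f"{name_or_path!r} is neither a builtin profile nor an existing file")


# ---------------------------------------------------------------------------
# Feature alias registry
# ---------------------------------------------------------------------------

# platform alias -> canonical name, one row per panel feature.
_ALIAS_TABLE: dict[str, dict[str, str]] = {
    "lifex": {
        "Volume": "volume",
        "Surface area": "area",
        "Sphericity": "sphericity",
        "Histogram skewness": "skewness",
        "GLCM correlation": "glcm_correlation",
        "GLCM contrast = variance": "glcm_contrast",
        "GLCM energy = angular second moment": "glcm_angular_second_moment",
        "GLCM entropy Log2 = joint entropy": "glcm_joint_entropy",
        "GLCM dissimilarly": "glcm_difference_average",
        "GLCM homogeneity = inverse difference": "glcm_inverse_difference",
        "NGLDM busyness": "ngtdm_busyness",
        "NGLDM coarseness": "ngtdm_coarseness",
        "NGLDM contrast": "ngtdm_contrast",
        "Conventional HU minimum": "minimum",
        "Conventional HU maximum": "maximum",
        "Conventional HU mean": "mean",
        "Conventional HU standard deviation": "standard_deviation",
    },
    "ibex": {
        "Volume": "volume",
        "Surface area": "area",
        "Sphericity": "sphericity",
        "Intensity histogram skewness": "skewness",
        "GLCM correlation": "glcm_correlation",
        "GLCM contrast": "glcm_contrast",
        "GLCM energy": "glcm_angular_second_moment",
        "GLCM entropy": "glcm_joint_entropy",
        "GLCM dissimilarly": "glcm_difference_average",
        "GLCM homogeneity": "glcm_inverse_difference",
        "Neighbour intensity difference busyness": "ngtdm_busyness",
        "Neighbour intensity difference coarseness": "ngtdm_coarseness",
        "Neighbour intensity difference contrast": "ngtdm_contrast",
        "Global Minimum": "minimum",
        "Global maximum": "maximum",
        "Global mean": "mean",
        "Global standard deviation": "standard_deviation",
    },
    "pyradiomics": {
        "Mesh volume and voxel volume": "volume",
        "Surface area": "area",
        "Sphericity": "sphericity",
        "First-order skewness": "skewness",
        "GLCM correlation": "glcm_correlation",
        "GLCM contrast": "glcm_contrast",
        "GLCM joint energy": "glcm_angular_second_moment",
        "GLCM joint entropy": "glcm_joint_entropy",
        "GLCM difference average": "glcm_difference_average",
        "GLCM ID": "glcm_inverse_difference",
        "NGTDM busyness": "ngtdm_busyness",
        "NGTDM coarseness": "ngtdm_coarseness",
        "NGTDM contrast": "ngtdm_contrast",
        "First-order minimum": "minimum",
        "First-order maximum": "maximum",
        "First-order mean": "mean",
        "First-order standard deviation": "standard_deviation",
    },
    "cerr": {
        "Volume": "volume",
        "Surface area": "area",
        "Sphericity": "sphericity",
        "Skewness": "skewness",
        "GLCM correlation": "glcm_correlation",
        "GLCM contrast": "glcm_contrast",
        "GLCM joint energy": "glcm_angular_second_moment",
        "GLCM joint entropy": "glcm_joint_entropy",
        "Dissimilarity (difference average)": "glcm_difference_average",
        "GLCM inverse difference": "glcm_inverse_difference",
        "NGTDM busyness": "ngtdm_busyness",
        "NGTDM coarseness": "ngtdm_coarseness",
        "NGTDM contrast": "ngtdm_contrast",
        "Minimum": "minimum",
        "Maximum": "maximum",
        "Mean": "mean",
        "Standard deviation": "standard_deviation",
    },
    "ibsi": {
        "Volume (mesh) and volume (voxel counting)": "volume",
        "Surface area (mesh)": "area",
        "Sphericity": "sphericity",
        "Discretised intensity skewness": "skewness",
        "GLCM correlation": "glcm_correlation",
        "GLCM contrast": "glcm_contrast",
        "GLCM angular Second moment": "glcm_angular_second_moment",
        "GLCM joint entropy": "glcm_joint_entropy",
        "GLCM difference average": "glcm_difference_average",
        "GLCM inverse difference": "glcm_inverse_difference",
        "NGTDM busyness": "ngtdm_busyness",
        "NGTDM coarseness": "ngtdm_coarseness",
        "NGTDM contrast": "ngtdm_contrast",
        "Minimum intensity": "minimum",
        "Maximum intensity": "maximum",
        "Mean intensity": "mean",
        "Not defined (variance is defined)": "standard_deviation",
    },
}


def _norm(s: str) -> str:
    return " ".join(s.lower().split())


class FeatureAliasRegistry:
    """Platform-name → canonical-name lookup for the 17-feature panel."""

    def __init__(self, table: dict[str, dict[str, str]] | None = None) -> None:
        self._table = table or _ALIAS_TABLE
        self._lookup: dict[str, dict[str, str]] = {
            platform: {_norm(alias): canon for alias, canon in aliases.items()}
            for platform, aliases in self._table.items()
        }
        for platform, aliases in self._table.items():
            canons = list(aliases.values())
            if sorted(set(canons)) != sorted(canons):
                raise ValueError(f"duplicate canonical mapping for platform {platform!r}")

    @property
    def platforms(self) -> tuple[str, ...]:
        return tuple(self._table)

    def canonical(self, platform: str, alias: str) -> str:
        """Resolve a platform alias; canonical names resolve to themselves."""
        if alias in CANONICAL_FEATURES:
            return alias
        platform = platform.lower()
        if platform not in self._lookup:
            raise AliasLookupError(f"unknown platform {platform!r}; known: {self.platforms}")
        table = self._lookup[platform]
        key = _norm(alias)
        if key in table:
            return table[key]
        near = difflib.get_close_matches(key, table, n=3, cutoff=0.4)
        raise AliasLookupError(
            f"unknown {platform} feature alias {alias!r}; nearest matches: {near}"
        )

    def aliases(self, platform: str) -> dict[str, str]:
        return dict(self._table[platform.lower()])


_DEFAULT_REGISTRY = FeatureAliasRegistry()


def canonical_feature_name(platform: str, alias: str) -> str:
    """Map a platform-specific feature name onto the canonical vocabulary."""
    return _DEFAULT_REGISTRY.canonical(platform, alias)
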