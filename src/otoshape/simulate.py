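"""Synthetic otolith-like contours with controllable anatomy.

Shapes are built in polar form around an ellipse: localized von-Mises-shaped
angular bumps add a rostrum (near angle 0, displaced up or down by a signed
elevation), an antirostrum above it with an adjacent negative notch bump in
between, and a posterior feature near angle pi; low-amplitude random harmonics
add individual irregularity.  Because r(theta) stays single-valued and
positive, every generated polygon is star-shaped and therefore simple.

Populations draw individual shape parameters around a mean with Gaussian
spread, an allometric per-mm shift with otolith length, and truncated-normal
otolith lengths; a metapopulation concatenates populations with seeds fanned
out deterministically from one master seed.  The eleven-river survey preset
mirrors a published American shad survey design: sample sizes 18-278 summing
to 1141, otolith lengths around 3.9-4.3 mm, and a north-to-south gradient from
upper-rostrum (positive elevation) to lower-rostrum (negative elevation)
shapes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw as _draw
from skimage import measure as _measure

from .contour import Contour

__all__ = [
    "ShapeParams",
    "PopulationSpec",
    "SyntheticDataset",
    "ContourGenerationError",
    "generate_contour",
    "generate_population",
    "generate_metapopulation",
    "render_binary_image",
    "morphotype_families",
    "family_specs",
    "shad_survey_specs",
]


class ContourGenerationError(ValueError):
    """Raised when a parameter draw cannot yield a valid simple polygon."""


# angular geometry of the anatomical features (radians, relative to the
# rostrum axis); widths are von Mises concentrations
_ANTIROSTRUM_OFFSET = 0.9
_NOTCH_OFFSET = 0.45
_KAPPA_ROSTRUM = 12.0
_KAPPA_NOTCH = 60.0
_KAPPA_ANTIROSTRUM = 30.0
_KAPPA_POSTERIOR = 8.0
_NOISE_HARMONICS = range(2, 9)


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of one synthetic otolith outline (lengths in mm).

    Amplitudes are dimensionless fractions of the local ellipse radius;
    ``rostrum_elevation`` is the signed angular offset of the rostrum bump
    (positive = upper rostrum, negative = lower rostrum).
    """

    base_semi_major: float = 2.05
    base_semi_minor: float = 1.30
    rostrum_amp: float = 0.18
    rostrum_elevation: float = 0.0
    antirostrum_amp: float = 0.10
    notch_depth: float = 0.12
    posterior_angularity: float = 0.08
    irregularity_sd: float = 0.01

    def __post_init__(self) -> None:
        for name in ("base_semi_major", "base_semi_minor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rostrum_amp", "antirostrum_amp", "notch_depth",
                     "posterior_angularity", "irregularity_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not np.isfinite(self.rostrum_elevation):
            raise ValueError("rostrum_elevation must be finite")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


PARAM_NAMES = tuple(f.name for f in dataclasses.fields(ShapeParams))


@dataclass
class PopulationSpec:
    """Recipe for one population of synthetic otoliths."""

    name: str
    n: int
    mean_params: ShapeParams = field(default_factory=ShapeParams)
    between_individual_sd: dict = field(default_factory=dict)  # param -> sd
    size_mean: float = 4.1  # otolith length, mm
    size_sd: float = 0.25
    allometry_slope: dict = field(default_factory=dict)  # param -> change per mm
    family: str | None = None  # generator shape family id
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.size_sd < 0 or self.size_mean <= 0:
            raise ValueError("sizes must have positive mean and nonnegative sd")
        for d in (self.between_individual_sd, self.allometry_slope):
            unknown = set(d) - set(PARAM_NAMES)
            if unknown:
                raise ValueError(f"unknown shape parameters: {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    """Contours plus per-individual sizes, population labels and family ids."""

    contours: list
    sizes: np.ndarray
    labels: list
    true_morphotype: list
    params: list  # ShapeParams actually used per individual

    def __post_init__(self) -> None:
        n = len(self.contours)
        if not (len(self.labels) == len(self.true_morphotype)
                == len(self.params) == self.sizes.size == n):
            raise ValueError("all per-individual lists must share one length")

    def __len__(self) -> int:
        return len(self.contours)

    def extend(self, other: "SyntheticDataset") -> "SyntheticDataset":
        return SyntheticDataset(
            contours=self.contours + other.contours,
            sizes=np.concatenate([self.sizes, other.sizes]),
            labels=self.labels + other.labels,
            true_morphotype=self.true_morphotype + other.true_morphotype,
            params=self.params + other.params,
        )


def _vonmises_bump(theta: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """Unit-height localized bump at angle mu (von Mises shape)."""
    return np.exp(kappa * (np.cos(theta - mu) - 1.0))


def generate_contour(params: ShapeParams, rng=None, n_vertices: int = 1024) -> Contour:
    """One synthetic otolith outline as a counterclockwise simple polygon.

    The radius function is the polar ellipse radius times a modulation of 1
    plus the feature bumps minus the notch plus (optionally) random harmonics
    scaled by ``irregularity_sd``.  A modulation that drops to zero or below
    anywhere would self-intersect and raises :class:`ContourGenerationError`.
    """
    if n_vertices < 1024:
        raise ValueError("n_vertices must be >= 1024")
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a, b = params.base_semi_major, params.base_semi_minor
    r_ellipse = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    mu_r = params.rostrum_elevation
    mod = (
        1.0
        + params.rostrum_amp * _vonmises_bump(theta, mu_r, _KAPPA_ROSTRUM)
        - params.notch_depth * _vonmises_bump(theta, mu_r + _NOTCH_OFFSET, _KAPPA_NOTCH)
        + params.antirostrum_amp * _vonmises_bump(theta, mu_r + _ANTIROSTRUM_OFFSET, _KAPPA_ANTIROSTRUM)
        + params.posterior_angularity * _vonmises_bump(theta, np.pi, _KAPPA_POSTERIOR)
    )
    if params.irregularity_sd > 0:
        rng = np.random.default_rng(rng)
        for k in _NOISE_HARMONICS:
            ak, bk = rng.normal(0.0, params.irregularity_sd / k, size=2)
            mod += ak * np.cos(k * theta) + bk * np.sin(k * theta)
    if np.any(mod <= 0):
        raise ContourGenerationError(
            "radius modulation is non-positive: feature amplitudes too large "
            "for a simple polygon"
        )
    r = r_ellipse * mod
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Contour(verts, side="left", units="mm")


def _perturbed_params(spec: PopulationSpec, size: float, rng) -> ShapeParams:
    base = spec.mean_params
    # isometric axis scaling tracks otolith length; shape features shift with
    # the allometric slopes and individual Gaussian deviations
    scale = size / spec.size_mean
    values = base.as_dict()
    values["base_semi_major"] *= scale
    values["base_semi_minor"] *= scale
    for name, sd in spec.between_individual_sd.items():
        values[name] += rng.normal(0.0, sd)
    for name, slope in spec.allometry_slope.items():
        values[name] += slope * (size - spec.size_mean)
    # clip nonnegative amplitudes that noise pushed slightly below zero
    for name in ("rostrum_amp", "antirostrum_amp", "notch_depth",
                 "posterior_angularity", "irregularity_sd"):
        values[name] = max(0.0, values[name])
    values["base_semi_major"] = max(1e-3, values["base_semi_major"])
    values["base_semi_minor"] = max(1e-3, values["base_semi_minor"])
    return ShapeParams(**values)


def generate_population(spec: PopulationSpec, max_retries: int = 100) -> SyntheticDataset:
    """Draw ``spec.n`` individuals: sizes, perturbed parameters, contours.

    Sizes come from a normal truncated to positive values (negative draws are
    resampled).  A draw whose contour would self-intersect is redrawn up to
    ``max_retries`` times before erroring.
    """
    rng = np.random.default_rng(spec.seed)
    contours, sizes, params_used = [], [], []
    for _ in range(spec.n):
        size = rng.normal(spec.size_mean, spec.size_sd)
        while size <= 0:
            size = rng.normal(spec.size_mean, spec.size_sd)
        for attempt in range(max_retries + 1):
            p = _perturbed_params(spec, size, rng)
            try:
                c = generate_contour(p, rng)
                break
            except ContourGenerationError:
                if attempt == max_retries:
                    raise ContourGenerationError(
                        f"population {spec.name!r}: no valid contour in "
                        f"{max_retries} retries"
                    )
        contours.append(c)
        sizes.append(size)
        params_used.append(p)
    fam = spec.family if spec.family is not None else spec.name
    return SyntheticDataset(
        contours=contours,
        sizes=np.asarray(sizes),
        labels=[spec.name] * spec.n,
        true_morphotype=[fam] * spec.n,
        params=params_used,
    )


def generate_metapopulation(specs: list, seed: int | None = None) -> SyntheticDataset:
    """Concatenate populations with per-population seeds fanned out from ``seed``.

    Population names must be unique.  Each population i receives the seed
    derived from SeedSequence(seed, spawn_key=(i,)), so the whole dataset is
    reproducible from the single master seed.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 population specs")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate population names")
    out = None
    for i, spec in enumerate(specs):
        child = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] % 2**31)
        ds = generate_population(replace(spec, seed=child))
        out = ds if out is None else out.extend(ds)
    return out


def render_binary_image(contour: Contour, pixels_per_unit: float = 256.0) -> np.ndarray:
    """Rasterize a contour into a filled boolean mask (foreground True).

    The image row axis points down, so y is flipped during rasterization; the
    mask carries a 2-pixel margin.  A resolution too low to resolve the
    outline (disconnected foreground, or holes from a pinched notch) raises.
    """
    if pixels_per_unit <= 0:
        raise ValueError("pixels_per_unit must be > 0")
    v = contour.vertices
    closed = np.vstack([v, v[:1]])
    perimeter_px = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()) * pixels_per_unit
    if perimeter_px < 64:
        raise ValueError(
            "resolution too low: outline spans fewer than 64 boundary pixels"
        )
    x = (v[:, 0] - v[:, 0].min()) * pixels_per_unit + 2.0
    y = (v[:, 1] - v[:, 1].min()) * pixels_per_unit + 2.0
    w = int(np.ceil(x.max())) + 3
    h = int(np.ceil(y.max())) + 3
    rows = (h - 1.0) - y
    rr, cc = _draw.polygon(rows, x, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("resolution too low: rasterized mask is empty")
    if _measure.label(mask, connectivity=2).max() != 1:
        raise ValueError("resolution too low: foreground is disconnected")
    if _measure.label(~mask, connectivity=1).max() != 1:
        raise ValueError("resolution too low: mask contains holes")
    return mask


def morphotype_families(irregularity_sd: float = 0.015) -> dict[str, ShapeParams]:
    """Five reference shape families spanning the observed anatomy axes.

    M2/M4 are upper-rostrum (positive elevation), M1/M3/M5 lower-rostrum; M2
    and M3 carry a subtle antirostrum, M1/M4/M5 a well-developed one; M1 is
    elongated with a deep notch, M3 wide with a shallow notch.
    """
    return {
        "M1": ShapeParams(base_semi_major=2.2, base_semi_minor=1.15,
                          rostrum_amp=0.26, rostrum_elevation=-0.05,
                          antirostrum_amp=0.18, notch_depth=0.20,
                          posterior_angularity=0.04, irregularity_sd=irregularity_sd),
        "M2": ShapeParams(base_semi_major=2.05, base_semi_minor=1.25,
                          rostrum_amp=0.12, rostrum_elevation=0.30,
                          antirostrum_amp=0.04, notch_depth=0.10,
                          posterior_angularity=0.08, irregularity_sd=irregularity_sd),
        "M3": ShapeParams(base_semi_major=1.95, base_semi_minor=1.45,
                          rostrum_amp=0.20, rostrum_elevation=-0.30,
                          antirostrum_amp=0.08, notch_depth=0.04,
                          posterior_angularity=0.14, irregularity_sd=irregularity_sd),
        "M4": ShapeParams(base_semi_major=1.95, base_semi_minor=1.40,
                          rostrum_amp=0.14, rostrum_elevation=0.28,
                          antirostrum_amp=0.20, notch_depth=0.14,
                          posterior_angularity=0.02, irregularity_sd=irregularity_sd),
        "M5": ShapeParams(base_semi_major=2.05, base_semi_minor=1.30,
                          rostrum_amp=0.20, rostrum_elevation=-0.28,
                          antirostrum_amp=0.14, notch_depth=0.26,
                          posterior_angularity=0.10, irregularity_sd=irregularity_sd),
    }


# within-family individual spread: tighter than the river-level spread below,
# because a morphotype family is one shape class while a river population
# mixes several
_FAMILY_SPREAD = {
    "rostrum_amp": 0.01,
    "rostrum_elevation": 0.025,
    "antirostrum_amp": 0.01,
    "notch_depth": 0.01,
    "posterior_angularity": 0.0075,
    "base_semi_minor": 0.015,
}


def family_specs(n_per_family: int = 30, irregularity_sd: float = 0.015) -> list:
    """One PopulationSpec per reference shape family (true family recorded)."""
    return [
        PopulationSpec(
            name=f"fam_{m}",
            n=n_per_family,
            mean_params=p,
            between_individual_sd=dict(_FAMILY_SPREAD),
            family=m,
        )
        for m, p in morphotype_families(irregularity_sd).items()
    ]


# eleven-river survey design: (name, n, OL mean, OL sd), north to south
_SHAD_SURVEY = [
    ("STL", 85, 4.29, 0.24),
    ("MER", 278, 4.01, 0.26),
    ("HUD", 49, 4.19, 0.28),
    ("DEL", 26, 4.09, 0.29),
    ("RAPP", 86, 4.09, 0.23),
    ("YOR", 78, 4.12, 0.24),
    ("JAM", 18, 4.10, 0.24),
    ("NEU", 89, 4.15, 0.26),
    ("CF", 120, 3.98, 0.26),
    ("SAN", 77, 4.15, 0.29),
    ("STJ", 235, 3.91, 0.22),
]

# rostrum-elevation gradient: upper rostrum in the four northern rivers,
# lower rostrum southward, strongest at the range ends
_SHAD_ELEVATION = [0.30, 0.24, 0.20, 0.12, -0.08, -0.12, -0.14, -0.18, -0.22, -0.26, -0.30]


def shad_survey_specs(scale: float = 1.0, irregularity_sd: float = 0.015) -> list:
    """Eleven PopulationSpecs emulating the shad survey design.

    ``scale`` multiplies the per-river sample sizes (minimum 4 kept per river)
    for desk-scale runs; at scale 1 the total is 1141 individuals.  Each river
    gets a position on the rostrum-elevation gradient, a mild allometric slope
    of rostrum prominence on otolith length, and individual spread in every
    feature amplitude.
    """
    specs = []
    sd = {
        "rostrum_amp": 0.02,
        "rostrum_elevation": 0.05,
        "antirostrum_amp": 0.02,
        "notch_depth": 0.02,
        "posterior_angularity": 0.015,
        "base_semi_minor": 0.03,
    }
    for (name, n, ol_mean, ol_sd), elev in zip(_SHAD_SURVEY, _SHAD_ELEVATION):
        mean = ShapeParams(
            base_semi_major=ol_mean / 2.0,
            base_semi_minor=ol_mean / 3.2,
            rostrum_amp=0.18,
            rostrum_elevation=elev,
            antirostrum_amp=0.10,
            notch_depth=0.12 + (0.06 if name == "STL" else 0.0),
            posterior_angularity=0.06,
            irregularity_sd=irregularity_sd,
        )
        specs.append(
            PopulationSpec(
                name=name,
                n=max(4, round(n * scale)),
                mean_params=mean,
                between_individual_sd=sd,
                size_mean=ol_mean,
                size_sd=ol_sd,
                allometry_slope={"rostrum_amp": 0.03},
            )
        )
    return specs
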