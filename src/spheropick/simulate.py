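"""Seeded synthetic brightfield spheroid scenes with exact ground truth.

Emulates transmitted-light imaging of tumour spheroids: a bright, slightly
uneven background; darker, roughly circular objects 200–250 µm in diameter
with a thin bright halo; optional per-object defocus blur; additive sensor
noise; and the artifact classes that defeat classical thresholding
pipelines (air bubbles, well borders, plastic defects). Every scene is
rendered from an explicit :class:`SceneSpec`, so the instance label mask is
exact by construction and rendering is bit-reproducible from the seed.

Object boundaries follow a truncated Fourier radial model

    r(θ) = R · (1 + Σ_k a_k · cos(kθ + φ_k)),   k ≥ 2,  Σ|a_k| < 0.5,

which keeps the contour smooth, star-shaped and simple, while the harmonic
amplitudes control circularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CalibratedImage

# Intensity model defaults (fractions of dynamic range / of background):
# bright background at 0.75, spheroid interior at 0.55x background, halo a
# thin ring 1.1x background just outside the boundary.
DEFAULT_BACKGROUND = 0.75
DEFAULT_INTERIOR = 0.55
DEFAULT_HALO_GAIN = 0.10
HALO_WIDTH_PX = 3

ARTIFACT_KINDS = ("air_bubble", "plate_border", "plastic_defect")


@dataclass
class ObjectSpec:
    """Geometry and appearance of one spheroid.

    irregularity is a list of (harmonic order k >= 2, amplitude in [0, 0.3),
    phase) triples; the summed |amplitude| must stay below 0.5 so the
    boundary is a simple closed star-shaped curve around the centre.
    """

    center_px: tuple[float, float]
    radius_px: float
    irregularity: list[tuple[int, float, float]] = field(default_factory=list)
    interior_level: float = DEFAULT_INTERIOR
    halo_gain: float = DEFAULT_HALO_GAIN
    defocus_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_px < 2:
            raise ValueError(f"radius_px must be >= 2, got {self.radius_px}")
        amp_sum = 0.0
        for k, a, _phi in self.irregularity:
            if k < 2:
                raise ValueError(f"harmonic order must be >= 2, got {k}")
            if not (0 <= a < 0.3):
                raise ValueError(f"harmonic amplitude must be in [0, 0.3), got {a}")
            amp_sum += abs(a)
        if amp_sum >= 0.5:
            raise ValueError(f"sum of harmonic amplitudes must be < 0.5, got {amp_sum}")
        if not (0 <= self.interior_level <= 1):
            raise ValueError("interior_level must be in [0, 1]")
        if self.halo_gain < 0:
            raise ValueError("halo_gain must be nonnegative")
        if self.defocus_sigma_px < 0:
            raise ValueError("defocus_sigma_px must be nonnegative")

    @property
    def max_radius_px(self) -> float:
        return self.radius_px * (1.0 + sum(abs(a) for _, a, _ in self.irregularity))


@dataclass
class ArtifactSpec:
    """A non-object image perturbation: never enters the label mask.

    kind: one of air_bubble (dark ring with brighter lumen), plate_border
    (dark arc band from a large out-of-frame circle, the well wall), or
    plastic_defect (thin dark bent crack). params are kind-specific.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}; expected one of {ARTIFACT_KINDS}")


@dataclass
class SceneSpec:
    """Full description of one synthetic field of view."""

    image_shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.0
    background_level: float = DEFAULT_BACKGROUND
    illumination_gradient: tuple[float, float] = (0.0, 0.0)
    noise_sigma: float = 0.0
    objects: list[ObjectSpec] = field(default_factory=list)
    artifacts: list[ArtifactSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape_px
        if h < 1 or w < 1:
            raise ValueError("image_shape_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        for i, obj in enumerate(self.objects):
            r, c = obj.center_px
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"object {i} center {obj.center_px} outside image bounds {self.image_shape_px}")


def _radial_distance_field(spec: ObjectSpec, image_shape_px: tuple[int, int]):
    """Return (rho, r_theta): pixel distances from centre and the boundary
    radius sampled at each pixel's polar angle."""
    h, w = image_shape_px
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    dy = rows - spec.center_px[0]
    dx = cols - spec.center_px[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_theta = np.full_like(rho, spec.radius_px)
    for k, a, phi in spec.irregularity:
        r_theta += spec.radius_px * a * np.cos(k * theta + phi)
    return rho, r_theta


def render_object_mask(spec: ObjectSpec, image_shape_px: tuple[int, int]) -> np.ndarray:
    """Render one object as a binary mask (dtype int32, label 1).

    A pixel belongs to the object when its centre lies inside the radial
    curve r(θ). Raises if the object's maximal radius extends beyond the
    image bounds.
    """
    h, w = image_shape_px
    cr, cc = spec.center_px
    rmax = spec.max_radius_px
    if cr - rmax < 0 or cc - rmax < 0 or cr + rmax > h - 1 or cc + rmax > w - 1:
        raise ValueError(
            f"object at {spec.center_px} with max radius {rmax:.1f} px "
            f"extends beyond image bounds {image_shape_px}"
        )
    rho, r_theta = _radial_distance_field(spec, image_shape_px)
    return (rho <= r_theta).astype(np.int32)


def _paint_artifact(image: np.ndarray, art: ArtifactSpec, base: np.ndarray, rng: np.random.Generator) -> None:
    """Perturb ``image`` in place; ``base`` is the noise-free background."""
    h, w = image.shape
    p = art.params
    if art.kind == "air_bubble":
        # dark refractive ring around a brighter lumen; the rim is broken by
        # an illumination gap, as on real bubbles lit off-axis
        cr = p.get("center_px", (h * rng.uniform(0.2, 0.8), w * rng.uniform(0.2, 0.8)))
        radius = p.get("radius_px", rng.uniform(15, 35))
        width = p.get("width_px", 4.0)
        gap_angle = p.get("gap_angle", 1.1)
        gap_at = p.get("gap_at", rng.uniform(0, 2 * math.pi))
        rows = np.arange(h)[:, None] - cr[0]
        cols = np.arange(w)[None, :] - cr[1]
        rho = np.hypot(rows, cols)
        theta = np.arctan2(rows, cols)
        in_gap = np.abs(np.angle(np.exp(1j * (theta - gap_at)))) <= gap_angle / 2
        ring = (np.abs(rho - radius) <= width / 2) & ~in_gap
        lumen = rho < radius - width / 2
        image[ring] = base[ring] * p.get("ring_level", 0.45)
        image[lumen] = np.minimum(base[lumen] * p.get("lumen_level", 1.12), 1.0)
    elif art.kind == "plate_border":
        # arc of a large circle whose centre lies outside the frame: the
        # dark shadow of a well wall crossing a corner of the image
        cr = p.get("center_px", (-0.8 * h, w * rng.uniform(0.0, 1.0)))
        radius = p.get("radius_px", 1.1 * h)
        width = p.get("width_px", 10.0)
        rows = np.arange(h)[:, None] - cr[0]
        cols = np.arange(w)[None, :] - cr[1]
        rho = np.hypot(rows, cols)
        band = np.abs(rho - radius) <= width / 2
        image[band] = base[band] * p.get("level", 0.5)
    elif art.kind == "plastic_defect":
        # thin bent dark crack: two joined line segments, 2 px wide
        start = p.get("start_px", (h * rng.uniform(0.2, 0.8), w * rng.uniform(0.2, 0.8)))
        length = p.get("length_px", rng.uniform(25, 60))
        angle = p.get("angle", rng.uniform(0, 2 * math.pi))
        kink = p.get("kink", math.pi / 2.5)
        width = p.get("width_px", 2.0)
        mid = (start[0] + length / 2 * math.sin(angle), start[1] + length / 2 * math.cos(angle))
        end = (mid[0] + length / 2 * math.sin(angle + kink), mid[1] + length / 2 * math.cos(angle + kink))
        crack = np.zeros(image.shape, dtype=bool)
        for (r0, c0), (r1, c1) in (((start), (mid)), ((mid), (end))):
            n = max(int(2 * max(abs(r1 - r0), abs(c1 - c0))) + 1, 2)
            rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, h - 1)
            cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, w - 1)
            crack[rr, cc] = True
        crack = ndimage.binary_dilation(crack, iterations=max(int(width / 2), 1))
        image[crack] = base[crack] * p.get("level", 0.4)


def render_scene(spec: SceneSpec) -> tuple[CalibratedImage, np.ndarray]:
    """Render a scene to a calibrated image and its instance label mask.

    The image is background + illumination gradient; each object is painted
    darker than the local background with a thin bright halo ring, then
    blurred by its own defocus sigma; artifacts perturb the image but never
    the mask; Gaussian noise (drawn from a generator seeded by spec.seed) is
    added last. Objects are labelled 1..n in list order. Raises if two
    object masks overlap.
    """
    h, w = spec.image_shape_px
    yy = np.linspace(-0.5, 0.5, h)[:, None]
    xx = np.linspace(-0.5, 0.5, w)[None, :]
    gy, gx = spec.illumination_gradient
    base = spec.background_level * (1.0 + gy * yy + gx * xx)
    base = np.clip(base, 0.0, 1.0)

    label_mask = np.zeros((h, w), dtype=np.int32)
    image = base.copy()
    for i, obj in enumerate(spec.objects, start=1):
        m = render_object_mask(obj, spec.image_shape_px).astype(bool)
        clash = label_mask[m]
        if clash.any():
            j = int(clash[clash > 0][0])
            raise ValueError(f"objects {j} and {i} overlap; scenes require non-overlapping spheroids")
        label_mask[m] = i

        # delta layer: darker interior + bright halo ring just outside
        delta = np.zeros((h, w))
        delta[m] = base[m] * (obj.interior_level - 1.0)
        if obj.halo_gain > 0:
            ring = ndimage.binary_dilation(m, iterations=HALO_WIDTH_PX) & ~m
            delta[ring] = base[ring] * obj.halo_gain
        if obj.defocus_sigma_px > 0:
            delta = ndimage.gaussian_filter(delta, obj.defocus_sigma_px)
        image = image + delta

    for j, art in enumerate(spec.artifacts):
        rng_art = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, j]))
        _paint_artifact(image, art, base, rng_art)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)

    image = np.clip(image, 0.0, 1.0)
    return CalibratedImage(image, spec.pixel_size_um), label_mask


# ---------------------------------------------------------------------------
# benchmark-set generation

#: difficulty profiles: object count, diameter range (µm), boundary
#: irregularity, defocus, noise and artifact frequency
PROFILES = {
    "clean": dict(
        n_objects=(1, 4), diameter_um=(200.0, 250.0), max_harmonics=0,
        max_amplitude=0.0, defocus_sigma=(0.0, 0.0), noise_sigma=0.0,
        gradient=0.0, artifact_prob=0.0,
    ),
    "default": dict(
        n_objects=(1, 4), diameter_um=(200.0, 250.0), max_harmonics=3,
        max_amplitude=0.08, defocus_sigma=(0.0, 2.0), noise_sigma=0.02,
        gradient=0.1, artifact_prob=0.2,
    ),
    "artifact": dict(
        n_objects=(1, 3), diameter_um=(200.0, 250.0), max_harmonics=3,
        max_amplitude=0.08, defocus_sigma=(0.0, 2.0), noise_sigma=0.02,
        gradient=0.1, artifact_prob=1.0,
    ),
}


def _sample_object(rng, profile, shape, pixel_size_um, existing: list[ObjectSpec],
                   defocus_sigma: float) -> ObjectSpec | None:
    d_lo, d_hi = profile["diameter_um"]
    radius_px = rng.uniform(d_lo, d_hi) / 2.0 / pixel_size_um
    irregularity = []
    if profile["max_harmonics"] > 0 and profile["max_amplitude"] > 0:
        n_h = rng.integers(0, profile["max_harmonics"] + 1)
        for _ in range(n_h):
            irregularity.append((
                int(rng.integers(2, 7)),
                float(rng.uniform(0, profile["max_amplitude"])),
                float(rng.uniform(0, 2 * math.pi)),
            ))
    rmax = radius_px * (1 + sum(a for _, a, _ in irregularity))
    margin = rmax + HALO_WIDTH_PX + 2
    h, w = shape
    if 2 * margin >= min(h, w):
        return None
    for _ in range(50):  # rejection sampling of a non-overlapping position
        center = (float(rng.uniform(margin, h - 1 - margin)),
                  float(rng.uniform(margin, w - 1 - margin)))
        ok = True
        for other in existing:
            dist = math.hypot(center[0] - other.center_px[0], center[1] - other.center_px[1])
            if dist < rmax + other.max_radius_px + 2 * HALO_WIDTH_PX + 4:
                ok = False
                break
        if ok:
            return ObjectSpec(center_px=center, radius_px=radius_px,
                              irregularity=irregularity, defocus_sigma_px=defocus_sigma)
    return None


def make_scene_spec(profile_name: str, seed: int, image_shape_px=(512, 512),
                    pixel_size_um: float = 2.0) -> SceneSpec:
    """Sample one SceneSpec from a named difficulty profile."""
    if profile_name not in PROFILES:
        raise ValueError(f"unknown profile {profile_name!r}; expected one of {sorted(PROFILES)}")
    profile = PROFILES[profile_name]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n_lo, n_hi = profile["n_objects"]
    n_objects = int(rng.integers(n_lo, n_hi + 1))
    s_lo, s_hi = profile["defocus_sigma"]
    objects: list[ObjectSpec] = []
    for _ in range(n_objects):
        obj = _sample_object(rng, profile, image_shape_px, pixel_size_um,
                             objects, float(rng.uniform(s_lo, s_hi)))
        if obj is not None:
            objects.append(obj)
    artifacts = []
    if rng.uniform() < profile["artifact_prob"]:
        n_art = int(rng.integers(1, 3))
        kinds = rng.choice(ARTIFACT_KINDS, size=n_art)
        artifacts = [ArtifactSpec(kind=str(k)) for k in kinds]
    g = profile["gradient"]
    gradient = (float(rng.uniform(-g, g)), float(rng.uniform(-g, g))) if g > 0 else (0.0, 0.0)
    return SceneSpec(
        image_shape_px=image_shape_px,
        pixel_size_um=pixel_size_um,
        illumination_gradient=gradient,
        noise_sigma=profile["noise_sigma"],
        objects=objects,
        artifacts=artifacts,
        seed=seed,
    )


def sample_feature_population(n: int, seed: int = 0, mean_area_um2: float = 25_000.0,
                              sd_area_um2: float = 4_000.0, mean_circularity: float = 0.84,
                              sd_circularity: float = 0.03):
    """Sample a synthetic morphometric population (no images rendered).

    Emulates the feature spread of a spheroid batch centred on the common
    178 µm / 25,000 µm² target, for studying selection policies at scale.
    Returns SpheroidRecords with consistent derived features.
    """
    from .morphometrics import SpheroidRecord, circularity as _circ  # noqa: F401
    from .morphometrics import equivalent_diameter, volume_estimate

    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        area = float(rng.normal(mean_area_um2, sd_area_um2))
        while area <= 1000:
            area = float(rng.normal(mean_area_um2, sd_area_um2))
        circ = float(np.clip(rng.normal(mean_circularity, sd_circularity), 0.05, 1.0))
        perimeter = math.sqrt(4 * math.pi * area / circ)
        records.append(SpheroidRecord(
            label=i + 1, area_um2=area, perimeter_um=perimeter, circularity=circ,
            equivalent_diameter_um=equivalent_diameter(area),
            solidity=float(np.clip(rng.normal(0.97, 0.02), 0.5, 1.0)),
            volume_um3=volume_estimate(area),
            centroid_px=(0.0, 0.0), bbox_px=(0, 0, 0, 0),
            stage_um=(float(rng.uniform(0, 50_000)), float(rng.uniform(0, 50_000))),
        ))
    return records


def make_benchmark_set(n_images: int, profile: str = "default", seed: int = 0,
                       image_shape_px=(512, 512), pixel_size_um: float = 2.0,
                       return_specs: bool = False):
    """Generate a deterministic list of (CalibratedImage, label mask) pairs.

    Per-image seeds are derived from ``seed``, so the whole set is
    reproducible and individual images are independent of n_images.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    root = np.random.SeedSequence(seed)
    image_seeds = [int(s) for s in root.generate_state(n_images) % (2**31)]
    specs = [make_scene_spec(profile, s, image_shape_px, pixel_size_um) for s in image_seeds]
    rendered = [render_scene(sp) for sp in specs]
    if return_specs:
        return rendered, specs
    return rendered
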