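"""Seeded synthetic cross-polarised scenes with ground truth.

Generates the optical classes seen when marine fine-fraction sediment is
run through an imaging flow cytometer between crossed polarisers:

* **face-on coccoliths** - radial calcite crystallography produces a
  pseudo-extinction cross: four bright quadrants separated by dark arms
  aligned with the polariser axes (intensity modulated as a squared
  sinusoid of twice the azimuth);
* **coccospheres** - quasi-circular bright bodies carrying one unresolved
  bright spot per face-on coccolith tiled around the sphere outline;
* **birefringent sediment** - irregular bright fragments (non-biological
  calcite, quartz, shell debris) with low circularity;
* **non-birefringent sediment** - isotropic material that stays dark
  between crossed polarisers;
* **speed beads**, **doublets** (two touching objects) and **defocused**
  copies of any class.

Images are 8-bit-scale grayscale (background mean ~5, calcite peak ~230),
64x64 px at 0.33 um^2/pixel by default; every maker is bit-deterministic
in its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import InvalidParameterError
from .masking import ObjectImage, object_tight_mask

DEFAULT_PIXEL_AREA = 0.33
DEFAULT_SHAPE = (64, 64)

BACKGROUND_MEAN = 5.0
BACKGROUND_SD = 1.5
CALCITE_PEAK = 230.0
SPHERE_BODY = 110.0

#: Dark core radius (px) at the cross centre where all quadrants meet.
CORE_RADIUS_PX = 1.0

#: Minimum centre-to-centre spacing (px) between rendered coccosphere
#: spots; keeps adjacent spots disconnected under 8-connectivity.
SPOT_PITCH_PX = 4.2

CLASSES = (
    "coccosphere",
    "coccolith",
    "birefringent_sediment",
    "nonbirefringent_sediment",
    "bead",
    "doublet",
)

DEFAULT_DIAMETER_RANGES = {
    "coccosphere": (6.0, 12.0),
    "coccolith": (3.5, 7.0),
    "birefringent_sediment": (4.0, 15.0),
    "nonbirefringent_sediment": (4.0, 15.0),
    "doublet": (5.0, 9.0),
}


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one generated object."""

    object_id: str
    true_class: str
    true_diameter_um: float
    n_coccoliths: int = 0
    n_face_on: int = 0
    defocused: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise InvalidParameterError(f"unknown class {self.true_class!r}")
        if self.n_face_on > self.n_coccoliths:
            raise InvalidParameterError("n_face_on cannot exceed n_coccoliths")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SampleSpec:
    """Composition of a whole synthetic sample."""

    counts_per_class: dict
    defocus_fraction: float = 0.0
    doublet_fraction: float = 0.0
    diameter_distributions: dict | None = None
    pixel_area: float = DEFAULT_PIXEL_AREA
    seed: int = 0
    face_on_fraction: float = 0.5
    shape: tuple[int, int] = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        for name in ("defocus_fraction", "doublet_fraction", "face_on_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        if not self.pixel_area > 0:
            raise InvalidParameterError("pixel_area must be > 0")
        for cls, count in self.counts_per_class.items():
            if cls not in CLASSES:
                raise InvalidParameterError(f"unknown class {cls!r}")
            if count < 0:
                raise InvalidParameterError(f"negative count for class {cls!r}")

    def diameter_range(self, cls: str) -> tuple[float, float]:
        dists = dict(DEFAULT_DIAMETER_RANGES)
        if self.diameter_distributions:
            dists.update(self.diameter_distributions)
        return dists[cls]


def _quantize(img: np.ndarray) -> np.ndarray:
    """Emulate the camera's 8-bit quantisation (kept as float)."""
    return np.clip(np.round(img), 0, 255).astype(float)


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    return np.clip(rng.normal(BACKGROUND_MEAN, BACKGROUND_SD, shape), 0.0, 12.0)


def _grid(shape: tuple[int, int], center: tuple[float, float]):
    yy, xx = np.indices(shape, dtype=float)
    return yy - center[0], xx - center[1]


def _radius_px(diameter_um: float, pixel_area: float) -> float:
    return diameter_um / 2.0 / math.sqrt(pixel_area)


def _render_cross(
    canvas: np.ndarray,
    center: tuple[float, float],
    radius_px: float,
    rng: np.random.Generator,
    peak: float = CALCITE_PEAK,
) -> None:
    """Paint a pseudo-extinction cross (4 bright quadrants) onto canvas."""
    dy, dx = _grid(canvas.shape, center)
    rho = np.hypot(dy, dx)
    s = np.sin(2.0 * np.arctan2(dy, dx))
    texture = rng.normal(1.0, 0.05, canvas.shape)
    vals = peak * s**2 * texture
    sel = (rho <= radius_px) & (rho >= CORE_RADIUS_PX)
    np.maximum(canvas, np.where(sel, vals, 0.0), out=canvas)


def make_coccolith(
    diameter_um: float,
    pixel_area: float = DEFAULT_PIXEL_AREA,
    orientation: str = "face_on",
    seed: int = 0,
    *,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    object_id: str = "coccolith",
) -> tuple[ObjectImage, SceneTruth]:
    """One detached coccolith.

    ``face_on`` orientation shows the full extinction cross (spot count 4
    downstream when the quadrants are resolved); ``tilted`` shows a
    foreshortened plate with two merged bright lobes.
    """
    if not diameter_um > 0:
        raise InvalidParameterError("diameter_um must be > 0")
    if not pixel_area > 0:
        raise InvalidParameterError("pixel_area must be > 0")
    if orientation not in ("face_on", "tilted"):
        raise InvalidParameterError(
            f"orientation must be 'face_on' or 'tilted', got {orientation!r}"
        )
    rng = np.random.default_rng(seed)
    canvas = _background(shape, rng)
    # integer-pixel centre keeps the dark arms aligned with pixel rows and
    # columns, so the four quadrants stay 8-disconnected after rasterisation
    cy = shape[0] // 2 + int(rng.integers(-2, 3))
    cx = shape[1] // 2 + int(rng.integers(-2, 3))
    radius = _radius_px(diameter_um, pixel_area)

    if orientation == "face_on":
        _render_cross(canvas, (cy, cx), radius, rng)
    else:
        phi = rng.uniform(0.0, math.pi)
        ratio = rng.uniform(0.78, 0.92)
        dy, dx = _grid(shape, (cy, cx))
        u = math.cos(phi) * dx + math.sin(phi) * dy
        v = -math.sin(phi) * dx + math.cos(phi) * dy
        inside = (u / radius) ** 2 + (v / (ratio * radius)) ** 2 <= 1.0
        psi = np.arctan2(v, u)
        c = np.cos(psi)
        texture = rng.normal(1.0, 0.05, shape)
        vals = CALCITE_PEAK * c**2 * texture
        sel = inside & (np.hypot(u, v) >= 1.2)
        np.maximum(canvas, np.where(sel, vals, 0.0), out=canvas)

    image = ObjectImage(_quantize(canvas), pixel_area, object_id)
    truth = SceneTruth(
        object_id=object_id,
        true_class="coccolith",
        true_diameter_um=diameter_um,
        n_coccoliths=1,
        n_face_on=1 if orientation == "face_on" else 0,
        seed=seed,
    )
    return image, truth


def _boundary_profile(rng: np.random.Generator, harmonics=(3, 4, 5, 6), norm="max"):
    """Smooth periodic radial-roughness profile.

    ``norm="max"`` scales to max |f| = 1 (a hard bound on the radial
    deviation, used for coccosphere bodies); ``norm="rms"`` scales to unit
    RMS with a +-2.5 clip (a guaranteed radial *variance*, used for
    sediment fragments so their circularity stays low).
    """
    amps = rng.uniform(0.3, 1.0, len(harmonics))
    phases = rng.uniform(0.0, 2.0 * math.pi, len(harmonics))

    def f(theta: np.ndarray) -> np.ndarray:
        out = np.zeros_like(theta)
        for m, a, p in zip(harmonics, amps, phases):
            out += a * np.cos(m * theta + p)
        return out

    probe = f(np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False))
    if norm == "max":
        scale = np.abs(probe).max() or 1.0

        def profile(theta: np.ndarray) -> np.ndarray:
            return f(theta) / scale

    else:
        scale = probe.std() or 1.0

        def profile(theta: np.ndarray) -> np.ndarray:
            return np.clip(f(theta) / scale, -2.5, 2.5)

    return profile


def make_coccosphere(
    diameter_um: float,
    n_coccoliths: int,
    pixel_area: float = DEFAULT_PIXEL_AREA,
    seed: int = 0,
    *,
    roughness: float = 0.03,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    object_id: str = "coccosphere",
) -> tuple[ObjectImage, SceneTruth]:
    """A coccosphere: bright quasi-circular body with multiple bright spots.

    The body is a disk whose boundary radius varies by at most
    ``roughness`` (fraction of radius; default 3%, keeping circularity
    high). Face-on coccoliths are tiled around the sphere outline as
    unresolved bright spots (at 0.33 um^2/px the extinction cross of a
    1-3 um plate is below the resolvable spot scale); the number of
    rendered spots is capped by the outline circumference at a minimum
    spot pitch so neighbouring spots stay separable.
    """
    if not diameter_um > 0:
        raise InvalidParameterError("diameter_um must be > 0")
    if n_coccoliths < 3:
        raise InvalidParameterError("a coccosphere needs >= 3 coccoliths")
    if not 0.0 <= roughness < 0.5:
        raise InvalidParameterError("roughness must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    canvas = _background(shape, rng)
    radius = _radius_px(diameter_um, pixel_area)
    cy = shape[0] / 2.0 + rng.uniform(-1.5, 1.5)
    cx = shape[1] / 2.0 + rng.uniform(-1.5, 1.5)

    dy, dx = _grid(shape, (cy, cx))
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    profile = _boundary_profile(rng)
    edge = radius * (1.0 + roughness * profile(theta))
    body = rho <= edge
    # low-relief texture: local relief on the body must stay below the
    # peak threshold so only coccolith spots count as bright detail
    body_vals = np.clip(rng.normal(SPHERE_BODY, 2.5, shape), 104.0, 116.0)
    canvas = np.where(body, np.maximum(canvas, body_vals), canvas)

    ring = 0.64 * radius
    n_slots = max(3, int(2.0 * math.pi * ring / SPOT_PITCH_PX))
    n_ring = min(n_coccoliths, n_slots)
    pitch = 2.0 * math.pi * ring / n_ring
    spot_r = float(np.clip(0.27 * pitch, 0.9, 2.2))
    centers = []
    angle0 = rng.uniform(0.0, 2.0 * math.pi)
    jitter = rng.uniform(-0.05, 0.05, n_ring) * (2.0 * math.pi / n_ring)
    for i in range(n_ring):
        ang = angle0 + 2.0 * math.pi * i / n_ring + jitter[i]
        centers.append((cy + ring * math.sin(ang), cx + ring * math.cos(ang)))
    # a pole-facing coccolith shows as one more central spot on crowded,
    # large spheres (ring must leave a resolvable gap to the centre)
    if n_coccoliths > n_ring and ring - 2.0 * spot_r >= 1.5:
        centers.append((cy, cx))
    n_spots = len(centers)
    for sy, sx in centers:
        d2 = (dy - (sy - cy)) ** 2 + (dx - (sx - cx)) ** 2
        spot = d2 <= spot_r**2
        vals = np.clip(rng.normal(CALCITE_PEAK, 8.0, shape), 200.0, 255.0)
        canvas = np.where(spot & body, np.maximum(canvas, vals), canvas)

    image = ObjectImage(_quantize(canvas), pixel_area, object_id)
    truth = SceneTruth(
        object_id=object_id,
        true_class="coccosphere",
        true_diameter_um=diameter_um,
        n_coccoliths=n_coccoliths,
        n_face_on=n_spots,
        seed=seed,
    )
    return image, truth


def make_sediment(
    kind: str,
    size_um: float | None = None,
    pixel_area: float = DEFAULT_PIXEL_AREA,
    seed: int = 0,
    *,
    irregularity: tuple[float, float] = (0.25, 0.45),
    shape: tuple[int, int] = DEFAULT_SHAPE,
    object_id: str = "sediment",
) -> tuple[ObjectImage, SceneTruth]:
    """An irregular sediment fragment.

    ``birefringent`` fragments are bright with strong radial-boundary
    irregularity (circularity well below the coccosphere gate);
    ``nonbirefringent`` fragments share the geometry but stay below the
    birefringence detection threshold (isotropic material passes no light
    between crossed polarisers).
    """
    if kind not in ("birefringent", "nonbirefringent"):
        raise InvalidParameterError(
            f"kind must be 'birefringent' or 'nonbirefringent', got {kind!r}"
        )
    rng = np.random.default_rng(seed)
    if size_um is None:
        size_um = rng.uniform(4.0, 15.0)
    if not size_um > 0:
        raise InvalidParameterError("size_um must be > 0")
    canvas = _background(shape, rng)
    radius = _radius_px(size_um, pixel_area)
    cy = shape[0] / 2.0 + rng.uniform(-2.0, 2.0)
    cx = shape[1] / 2.0 + rng.uniform(-2.0, 2.0)
    dy, dx = _grid(shape, (cy, cx))

    phi = rng.uniform(0.0, math.pi)
    ellip = rng.uniform(0.75, 1.0)
    u = math.cos(phi) * dx + math.sin(phi) * dy
    v = -math.sin(phi) * dx + math.cos(phi) * dy
    rho = np.hypot(u, v / ellip)
    theta = np.arctan2(v, u)
    # amplitude floor in pixels: small fragments must still rasterise as
    # irregular, or mask smoothing would round them into pseudo-circles
    amp = max(rng.uniform(*irregularity), 1.6 / radius)
    profile = _boundary_profile(rng, harmonics=(2, 3, 4, 5, 7), norm="rms")
    inside = rho <= radius * (1.0 + amp * profile(theta))

    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, shape), 1.2)
    if kind == "birefringent":
        vals = np.clip(175.0 + 55.0 * texture / max(texture.std(), 1e-9), 40.0, 255.0)
    else:
        vals = np.clip(9.0 + 2.0 * texture / max(texture.std(), 1e-9), 0.0, 13.0)
    canvas = np.where(inside, np.maximum(canvas, vals), canvas)

    image = ObjectImage(_quantize(canvas), pixel_area, object_id)
    truth = SceneTruth(
        object_id=object_id,
        true_class=f"{kind}_sediment",
        true_diameter_um=size_um,
        seed=seed,
    )
    return image, truth


def make_bead(
    pixel_area: float = DEFAULT_PIXEL_AREA,
    seed: int = 0,
    *,
    diameter_um: float = 1.0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    object_id: str = "bead",
) -> tuple[ObjectImage, SceneTruth]:
    """A 1-um polystyrene speed bead: tiny, bright, round."""
    if not diameter_um > 0:
        raise InvalidParameterError("diameter_um must be > 0")
    rng = np.random.default_rng(seed)
    canvas = _background(shape, rng)
    cy = shape[0] // 2 + int(rng.integers(-2, 3))
    cx = shape[1] // 2 + int(rng.integers(-2, 3))
    dy, dx = _grid(shape, (cy, cx))
    radius = max(_radius_px(diameter_um, pixel_area), 1.1)
    sel = np.hypot(dy, dx) <= radius
    canvas = np.where(sel, 210.0, canvas)
    image = ObjectImage(_quantize(canvas), pixel_area, object_id)
    truth = SceneTruth(object_id, "bead", diameter_um, seed=seed)
    return image, truth


def make_doublet(
    pixel_area: float = DEFAULT_PIXEL_AREA,
    seed: int = 0,
    *,
    diameter_range_um: tuple[float, float] = (5.0, 9.0),
    shape: tuple[int, int] = DEFAULT_SHAPE,
    object_id: str = "doublet",
) -> tuple[ObjectImage, SceneTruth]:
    """Two tangent bright disks; the elongated composite fails the singlet gate."""
    rng = np.random.default_rng(seed)
    d1 = rng.uniform(*diameter_range_um)
    d2 = rng.uniform(*diameter_range_um)
    r1 = _radius_px(d1, pixel_area)
    r2 = _radius_px(d2, pixel_area)
    canvas = _background(shape, rng)
    cy = shape[0] / 2.0
    cx = shape[1] / 2.0
    phi = rng.uniform(0.0, math.pi)
    sep = 0.95 * (r1 + r2)
    centers = [
        (cy - 0.5 * sep * math.sin(phi), cx - 0.5 * sep * math.cos(phi), r1),
        (cy + 0.5 * sep * math.sin(phi), cx + 0.5 * sep * math.cos(phi), r2),
    ]
    for oy, ox, rr in centers:
        dy, dx = _grid(shape, (oy, ox))
        sel = np.hypot(dy, dx) <= rr
        vals = np.clip(rng.normal(150.0, 8.0, shape), 110.0, 200.0)
        canvas = np.where(sel, np.maximum(canvas, vals), canvas)
    image = ObjectImage(_quantize(canvas), pixel_area, object_id)
    truth = SceneTruth(object_id, "doublet", max(d1, d2), seed=seed)
    return image, truth


def defocus(
    pixels: np.ndarray,
    pixel_area: float,
    grms_threshold: float = 15.0,
    *,
    max_sigma: float = 9.0,
) -> np.ndarray:
    """Gaussian-blur an image until its Gradient RMS drops to the threshold."""
    from .features import gradient_rms  # deferred: features imports masking only

    blurred = pixels
    sigma = 3.0
    while sigma <= max_sigma:
        blurred = _quantize(ndi.gaussian_filter(pixels, sigma))
        oi = ObjectImage(blurred, pixel_area, "defocus_probe")
        mask = object_tight_mask(oi)
        if mask.is_empty() or gradient_rms(oi, mask) <= grms_threshold:
            break
        sigma += 1.0
    return blurred


def _make_one(
    cls: str, spec: SampleSpec, seed: int, object_id: str
) -> tuple[ObjectImage, SceneTruth]:
    rng = np.random.default_rng(seed)
    child = int(rng.integers(2**31))
    common = dict(shape=spec.shape, object_id=object_id)
    if cls == "coccosphere":
        d = rng.uniform(*spec.diameter_range(cls))
        n_cocc = int(rng.integers(8, 17))
        return make_coccosphere(d, n_cocc, spec.pixel_area, child, **common)
    if cls == "coccolith":
        d = rng.uniform(*spec.diameter_range(cls))
        orientation = "face_on" if rng.random() < spec.face_on_fraction else "tilted"
        return make_coccolith(d, spec.pixel_area, orientation, child, **common)
    if cls in ("birefringent_sediment", "nonbirefringent_sediment"):
        d = rng.uniform(*spec.diameter_range(cls))
        kind = cls.replace("_sediment", "")
        return make_sediment(kind, d, spec.pixel_area, child, **common)
    if cls == "bead":
        return make_bead(spec.pixel_area, child, **common)
    if cls == "doublet":
        return make_doublet(
            spec.pixel_area,
            child,
            diameter_range_um=spec.diameter_range("doublet"),
            **common,
        )
    raise InvalidParameterError(f"unknown class {cls!r}")


def make_sample(spec: SampleSpec) -> tuple[list[ObjectImage], pd.DataFrame]:
    """Generate a whole sample gallery plus its truth table.

    Returns exactly the requested per-class counts (plus extra doublets
    from ``doublet_fraction``), shuffled by the seed; ``defocus_fraction``
    of the objects are blurred until they fail the focus gate. An empty
    spec yields empty outputs.
    """
    classes: list[str] = []
    for cls in CLASSES:
        classes.extend([cls] * int(spec.counts_per_class.get(cls, 0)))
    n_extra = int(round(spec.doublet_fraction * len(classes)))
    classes.extend(["doublet"] * n_extra)
    n = len(classes)
    truth_cols = [
        "object_id",
        "true_class",
        "true_diameter_um",
        "n_coccoliths",
        "n_face_on",
        "defocused",
        "seed",
    ]
    if n == 0:
        return [], pd.DataFrame(columns=truth_cols)

    rng = np.random.default_rng(spec.seed)
    child_seeds = rng.integers(2**31, size=n)
    blur_flags = rng.random(n) < spec.defocus_fraction
    perm = rng.permutation(n)

    images: list[ObjectImage] = []
    truths: list[dict] = []
    for k, j in enumerate(perm):
        object_id = f"obj_{k:05d}"
        image, truth = _make_one(classes[j], spec, int(child_seeds[j]), object_id)
        row = truth.to_dict()
        if blur_flags[j]:
            image = ObjectImage(
                defocus(image.pixels, spec.pixel_area),
                spec.pixel_area,
                object_id,
            )
            row["defocused"] = True
        images.append(image)
        truths.append(row)
    return images, pd.DataFrame(truths)[truth_cols]


def noise_sd_for_r2(
    slope: float, d_range: tuple[float, float], r_squared: float
) -> float:
    """Gaussian noise SD giving an expected R^2 for uniform x on d_range."""
    if not 0.0 < r_squared <= 1.0:
        raise InvalidParameterError("r_squared must be in (0, 1]")
    var_x = (d_range[1] - d_range[0]) ** 2 / 12.0
    return math.sqrt(slope**2 * var_x * (1.0 - r_squared) / r_squared)


def make_calibration_pairs(
    n: int,
    slope: float = 0.836,
    intercept: float = 0.0,
    noise_sd: float | None = 0.3,
    species_specs: list[dict] | None = None,
    seed: int = 0,
    *,
    d_range: tuple[float, float] = (3.0, 16.0),
    r_squared: float | None = None,
) -> pd.DataFrame:
    """Synthetic coccosphere-diameter / cell-diameter pairs.

    ``cell_d = intercept + slope * coccosphere_d + N(0, noise_sd)`` with
    coccosphere diameters uniform on ``d_range``. ``r_squared`` (when
    given) overrides ``noise_sd`` with the value from
    :func:`noise_sd_for_r2`. ``species_specs`` is a list of dicts, each
    optionally carrying name/slope/intercept/noise_sd/r_squared/d_range/n,
    producing one species per entry.
    """
    rng = np.random.default_rng(seed)
    if species_specs is None:
        species_specs = [{"name": "pooled"}]
    rows = []
    for i, sp in enumerate(species_specs):
        name = sp.get("name", f"species_{i}")
        ni = int(sp.get("n", n))
        if ni < 3:
            raise InvalidParameterError(f"species {name!r}: need n >= 3, got {ni}")
        b = float(sp.get("slope", slope))
        a = float(sp.get("intercept", intercept))
        rng_i = sp.get("d_range", d_range)
        r2 = sp.get("r_squared", r_squared)
        sd = sp.get("noise_sd", noise_sd)
        if r2 is not None:
            sd = noise_sd_for_r2(b, rng_i, r2)
        if sd is None or sd < 0:
            raise InvalidParameterError(f"species {name!r}: noise_sd must be >= 0")
        x = rng.uniform(rng_i[0], rng_i[1], ni)
        y = a + b * x + rng.normal(0.0, sd, ni)
        for xi, yi in zip(x, y):
            rows.append(
                {"species": name, "coccosphere_d_um": xi, "cell_d_um": yi}
            )
    return pd.DataFrame(rows)
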