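"""Procedural generation of material-discrimination stimuli.

Stand-in for a physically based global-illumination pipeline: bumpy-sphere
height fields shaded with the Ward model under parametric illumination
proxies.  Images vary monotonically along each of six material dimensions:

- GC  gloss contrast        (specular energy rho_s, 0.00-0.12 step 0.02)
- GD  gloss distinctness    (DOI d = 1 - alpha, 0.88-1.00 step 0.02)
- OT  opaque vs translucent (medium density scale, 0.0039-1.00, log-spaced)
- MP  gold vs plastic       (BRDF blend weight, 0.00-0.80 step 0.20)
- MG  silver vs glass       (BRDF blend weight, 0.00-0.80 step 0.20)
- GP  glossy vs painted     (DOI d, 0.88-1.00 step 0.04; highlight
                             consistency flag)

The five object geometries are a sphere modulated by five kinds of surface
noise; the six illumination proxies form two triples, one mutually similar
(used for illumination condition 2) and one mutually dissimilar (condition
3); condition 1 uses a single proxy with four object poses in 36-degree
steps.  A synthetic observer answers oddity displays through the same
decision rule as the sensitivity estimator, with a configurable link from
stimulus parameter distance to d'.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .psychophysics import ResponseRecord, TaskCondition
from .reflectance import PerceptualGloss, WardBRDF, perceptual_to_ward

__all__ = [
    "GeometrySpec",
    "SceneSpec",
    "MaterialSpec",
    "OddityDisplay",
    "PARAMETER_GRIDS",
    "ANCHORS",
    "OBJECTS",
    "ILLUMINATION_PROXIES",
    "proxies_for_condition",
    "render_object",
    "render_layers",
    "make_inconsistent_highlights",
    "make_oddity_display",
    "simulate_observer",
    "white_point",
    "highlight_shading_coherence",
]

DIMENSIONS = ("GC", "GD", "OT", "MP", "MG", "GP")

#: task parameter grids (difficulty axes)
PARAMETER_GRIDS: dict[str, tuple[float, ...]] = {
    "GC": tuple(np.round(np.arange(0.00, 0.1201, 0.02), 4)),
    "GD": tuple(np.round(np.arange(0.88, 1.0001, 0.02), 4)),
    "OT": (0.0039, 0.0156, 0.0625, 0.25, 1.00),
    "MP": tuple(np.round(np.arange(0.00, 0.8001, 0.20), 4)),
    "MG": tuple(np.round(np.arange(0.00, 0.8001, 0.20), 4)),
    "GP": tuple(np.round(np.arange(0.88, 1.0001, 0.04), 4)),
}

#: non-target (context) parameter per dimension.  GP non-targets share the
#: target's DOI but carry inconsistent (painted-looking) highlights.
ANCHORS: dict[str, float] = {
    "GC": 0.06,
    "GD": 0.94,
    "OT": 1.00,
    "MP": 0.00,
    "MG": 0.00,
}

GLOSS_RHO_D = 0.416  # diffuse reflectance shared by the gloss tasks
GP_CONTRAST = 0.067  # contrast gloss of the glossy-vs-painted stimuli
_ALPHA_MIN = 0.004  # lobe spread floor so d = 1.00 stays evaluable

POSES_DEG = (0, 36, 72, 108, 144)


# ---------------------------------------------------------------------------
# geometry

@dataclass(frozen=True)
class GeometrySpec:
    """Bumpy sphere: unit-sphere height field plus one kind of surface noise."""

    name: str
    noise_kind: str  # lowfreq_crater | bandpass | sine | perlin_a | perlin_b
    amplitude: float
    seed: int

    def __post_init__(self) -> None:
        kinds = {"lowfreq_crater", "bandpass", "sine", "perlin_a", "perlin_b"}
        if self.noise_kind not in kinds:
            raise ValueError(f"noise_kind must be one of {sorted(kinds)}")


OBJECTS: dict[int, GeometrySpec] = {
    1: GeometrySpec("object_1", "lowfreq_crater", 0.10, 101),
    2: GeometrySpec("object_2", "bandpass", 0.05, 102),
    3: GeometrySpec("object_3", "sine", 0.05, 103),
    4: GeometrySpec("object_4", "perlin_a", 0.09, 104),
    5: GeometrySpec("object_5", "perlin_b", 0.09, 105),
}


@dataclass(frozen=True)
class SceneSpec:
    geometry: GeometrySpec
    illumination_id: int  # 1..6
    pose_deg: int = 0

    def __post_init__(self) -> None:
        if self.illumination_id not in range(1, 7):
            raise ValueError("illumination_id must be in 1..6")
        if self.pose_deg % 36 != 0:
            raise ValueError("pose_deg must be a multiple of 36")


@dataclass(frozen=True)
class MaterialSpec:
    dimension: str
    value: float
    consistent: bool = True  # GP only: highlight-shading consistency

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"dimension must be one of {DIMENSIONS}")
        grid = PARAMETER_GRIDS[self.dimension]
        if not any(abs(self.value - g) < 1e-9 for g in grid):
            raise ValueError(
                f"value {self.value} for {self.dimension} is off-grid; "
                f"valid grid: {list(grid)}"
            )


@dataclass(frozen=True)
class OddityDisplay:
    images: tuple[np.ndarray, ...]  # 3 or 4 8-bit sRGB images
    target_index: int
    condition: TaskCondition
    param_distance: float

    @property
    def m(self) -> int:
        return len(self.images)


def _texture_noise(spec: GeometrySpec, shape=(192, 384)) -> np.ndarray:
    """Periodic (in longitude) noise texture on a (lat, lon) grid, unit RMS."""
    rng = np.random.default_rng(spec.seed)
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None] * h
    fx = np.fft.fftfreq(w)[None, :] * w
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    if spec.noise_kind in ("lowfreq_crater", "perlin_a", "perlin_b"):
        beta = {"lowfreq_crater": 3.0, "perlin_a": 1.8, "perlin_b": 1.2}[
            spec.noise_kind
        ]
        amp = f ** (-beta / 2.0)
    elif spec.noise_kind == "bandpass":
        amp = np.exp(-0.5 * ((f - 10.0) / 4.0) ** 2)
    else:  # sine handled analytically below; texture unused
        amp = np.zeros_like(f)
    amp[0, 0] = 0.0
    phase = rng.uniform(0, 2 * np.pi, size=(h, w))
    tex = np.fft.ifft2(amp * np.exp(1j * phase)).real
    rms = tex.std()
    if rms > 0:
        tex = tex / rms
    if spec.noise_kind == "lowfreq_crater":
        # a few crater-like depressions at seeded positions
        lat = np.linspace(-np.pi / 2, np.pi / 2, h)[:, None]
        lon = np.linspace(-np.pi, np.pi, w, endpoint=False)[None, :]
        for _ in range(5):
            c_lat = rng.uniform(-1.0, 1.0)
            c_lon = rng.uniform(-np.pi, np.pi)
            sigma = rng.uniform(0.15, 0.35)
            # spherical distance via the chord between unit vectors
            cosd = np.sin(lat) * np.sin(c_lat) + np.cos(lat) * np.cos(c_lat) * np.cos(
                lon - c_lon
            )
            ang = np.arccos(np.clip(cosd, -1, 1))
            tex = tex - 2.5 * np.exp(-0.5 * (ang / sigma) ** 2)
    return tex


def _height_field(scene: SceneSpec, size: int):
    """Height map, mask, and per-pixel (lat, lon) for a posed bumpy sphere."""
    g = scene.geometry
    half = 1.1
    coords = (np.arange(size) + 0.5) / size * (2 * half) - half
    x = coords[None, :]
    y = -coords[:, None]  # row 0 is the top of the image
    r2 = x**2 + y**2
    mask = r2 < 1.0
    z = np.sqrt(np.clip(1.0 - r2, 0.0, None))
    with np.errstate(invalid="ignore"):
        lat = np.arcsin(np.clip(y / 1.0, -1, 1)) * np.ones_like(z)
        lon = np.arctan2(x * np.ones_like(y), z)
    lon = lon + math.radians(scene.pose_deg)
    if g.noise_kind == "sine":
        bump = np.sin(6.0 * lon) * np.sin(5.0 * (lat + 0.3))
    else:
        tex = _texture_noise(g)
        h, w = tex.shape
        row = (lat + np.pi / 2) / np.pi * (h - 1)
        col = np.mod(lon + np.pi, 2 * np.pi) / (2 * np.pi) * w
        bump = ndimage.map_coordinates(
            tex, [row.ravel(), col.ravel()], order=1, mode="grid-wrap"
        ).reshape(size, size)
    height = z + g.amplitude * bump * np.clip(z, 0.0, None) ** 0.5
    height[~mask] = 0.0
    return height, mask, lat, lon


def _normals(height: np.ndarray, mask: np.ndarray, size: int) -> np.ndarray:
    d = 2.2 / size
    gy, gx = np.gradient(height, d)
    n = np.stack([-gx, gy, np.ones_like(height)], axis=-1)  # y up in world
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    n[~mask] = np.array([0.0, 0.0, 1.0])
    return n


# ---------------------------------------------------------------------------
# illumination proxies

@dataclass(frozen=True)
class IlluminationProxy:
    """Directional + ambient lighting mixture emulating one light probe."""

    proxy_id: int
    lights: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...]
    ambient: tuple[float, float, float]
    backlight: tuple[float, float, float]


def _norm(v):
    a = np.asarray(v, float)
    return tuple(a / np.linalg.norm(a))


# proxies 1-3 are mutually similar (overcast daylight family, illumination
# condition 2); proxies 4-6 are mutually dissimilar (condition 3).
ILLUMINATION_PROXIES: dict[int, IlluminationProxy] = {
    1: IlluminationProxy(
        1,
        ((_norm((-0.35, 0.55, 0.76)), (0.95, 0.96, 1.00)),
         (_norm((0.45, 0.25, 0.86)), (0.38, 0.39, 0.42))),
        (0.33, 0.34, 0.38),
        (0.30, 0.31, 0.35),
    ),
    2: IlluminationProxy(
        2,
        ((_norm((-0.30, 0.60, 0.74)), (0.92, 0.92, 0.96)),
         (_norm((0.50, 0.20, 0.84)), (0.42, 0.42, 0.44))),
        (0.31, 0.32, 0.35),
        (0.28, 0.29, 0.32),
    ),
    3: IlluminationProxy(
        3,
        ((_norm((-0.40, 0.50, 0.77)), (0.98, 0.97, 0.99)),
         (_norm((0.40, 0.30, 0.87)), (0.35, 0.36, 0.40))),
        (0.35, 0.35, 0.38),
        (0.31, 0.32, 0.34),
    ),
    4: IlluminationProxy(  # tunnel interior: single strong lateral light
        4,
        ((_norm((-0.85, 0.05, 0.53)), (1.25, 1.05, 0.78)),),
        (0.07, 0.06, 0.055),
        (0.05, 0.045, 0.04),
    ),
    5: IlluminationProxy(  # tungsten evening: warm, from above right
        5,
        ((_norm((0.60, 0.45, 0.66)), (1.30, 0.88, 0.48)),
         (_norm((-0.20, -0.30, 0.93)), (0.20, 0.12, 0.06))),
        (0.16, 0.10, 0.06),
        (0.13, 0.08, 0.05),
    ),
    6: IlluminationProxy(  # cool interior: two soft greenish-blue sources
        6,
        ((_norm((0.10, 0.80, 0.59)), (0.55, 0.66, 0.62)),
         (_norm((-0.55, -0.10, 0.83)), (0.40, 0.48, 0.50))),
        (0.22, 0.27, 0.28),
        (0.20, 0.24, 0.26),
    ),
}


def proxies_for_condition(illumination_condition: int) -> tuple[int, ...]:
    """Illumination proxy ids used under each illumination condition."""
    if illumination_condition == 1:
        return (1,)
    if illumination_condition == 2:
        return (1, 2, 3)
    if illumination_condition == 3:
        return (4, 5, 6)
    raise ValueError("illumination_condition must be 1, 2 or 3")


# ---------------------------------------------------------------------------
# shading

def _ward_layers(n, mask, proxy, ward: WardBRDF, albedo, spec_tint, size):
    """Diffuse and specular linear-RGB layers for one Ward material."""
    view = np.array([0.0, 0.0, 1.0])
    cos_o = np.clip(n @ view, 0.0, 1.0)
    albedo = np.asarray(albedo, float)
    spec_tint = np.asarray(spec_tint, float)
    diffuse = np.zeros((*mask.shape, 3))
    specular = np.zeros((*mask.shape, 3))
    # The lobe is evaluated at a resolvable angular spread so that very sharp
    # materials do not fall between pixel normals; distinctness-of-image is
    # then realized entirely by the blur below, whose width is proportional
    # to the true alpha.  Specular energy stays proportional to rho_s.
    shape_alpha = max(ward.alpha, 0.05)
    for ldir, lrgb in proxy.lights:
        l = np.asarray(ldir, float)
        lrgb = np.asarray(lrgb, float)
        cos_i = np.clip(n @ l, 0.0, 1.0)
        diffuse += (ward.rho_d / math.pi) * cos_i[..., None] * lrgb * albedo
        if ward.rho_s > 0:
            h = l + view
            h = h / np.linalg.norm(h)
            cos_delta = np.clip(n @ h, 1e-9, 1.0)
            tan2 = (1.0 - cos_delta**2) / cos_delta**2
            denom = 4 * math.pi * shape_alpha**2 * np.sqrt(
                np.clip(cos_i * cos_o, 1e-6, None)
            )
            lobe = np.exp(-tan2 / shape_alpha**2) / denom
            lobe = np.where((cos_i > 1e-6) & (cos_o > 1e-6), lobe, 0.0)
            specular += (
                ward.rho_s * lobe[..., None] * cos_i[..., None] * lrgb * spec_tint
            )
    diffuse += ward.rho_d * np.asarray(proxy.ambient) * albedo
    # DOI blur: kernel width monotone in alpha = 1 - d
    sigma = 0.5 * ward.alpha * size
    if sigma > 0.05:
        specular = ndimage.gaussian_filter(specular, sigma=(sigma, sigma, 0))
    diffuse[~mask] = 0.0
    specular[~mask] = 0.0
    return diffuse, specular


def _alpha_from_doi(d: float) -> float:
    return max(1.0 - d, _ALPHA_MIN)


def _background(proxy: IlluminationProxy, size: int) -> np.ndarray:
    """Soft vertical gradient standing in for the table and room."""
    amb = np.asarray(proxy.ambient)
    grad = np.linspace(1.15, 0.55, size)[:, None, None]
    return 0.35 * amb * grad * np.ones((size, size, 3))


def _material_linear(scene: SceneSpec, material: MaterialSpec, size: int):
    """Linear-RGB (diffuse, specular, transmission) layers for one material."""
    height, mask, lat, lon = _height_field(scene, size)
    n = _normals(height, mask, size)
    proxy = ILLUMINATION_PROXIES[scene.illumination_id]
    dim, v = material.dimension, material.value
    trans = np.zeros((size, size, 3))

    if dim == "GC":
        ward = WardBRDF(GLOSS_RHO_D, v, _alpha_from_doi(0.94))
        diff, spec = _ward_layers(n, mask, proxy, ward, (1, 1, 1), (1, 1, 1), size)
    elif dim == "GD":
        ward = WardBRDF(GLOSS_RHO_D, 0.06, _alpha_from_doi(v))
        diff, spec = _ward_layers(n, mask, proxy, ward, (1, 1, 1), (1, 1, 1), size)
    elif dim == "GP":
        ward = perceptual_to_ward(
            PerceptualGloss(c=GP_CONTRAST, d=v), GLOSS_RHO_D
        )
        ward = WardBRDF(ward.rho_d, ward.rho_s, max(ward.alpha, _ALPHA_MIN))
        diff, spec = _ward_layers(n, mask, proxy, ward, (1, 1, 1), (1, 1, 1), size)
    elif dim == "OT":
        # translucency proxy: optical depth proportional to the density scale
        # times the chord length through the object; the transmitted backlight
        # grows as the medium thins
        milk = np.array([0.96, 0.93, 0.88])
        thickness = 2.0 * np.clip(height, 0.0, None)  # chord proxy from the height field
        tau = 6.0 * v * thickness
        transmit = np.exp(-tau)[..., None]
        ward = WardBRDF(0.85, 0.05, 0.05)
        diff, spec = _ward_layers(n, mask, proxy, ward, milk, (1, 1, 1), size)
        back = np.asarray(proxy.backlight) * np.array([1.0, 0.98, 0.94])
        trans = 0.9 * transmit * back * mask[..., None]
        diff = diff * (1.0 - 0.85 * transmit)
    elif dim in ("MP", "MG"):
        if dim == "MP":
            a_diff, a_spec = _ward_layers(
                n, mask, proxy, WardBRDF(0.08, 0.65, 0.08),
                (1.00, 0.76, 0.33), (1.00, 0.78, 0.36), size)   # gold
            b_diff, b_spec = _ward_layers(
                n, mask, proxy, WardBRDF(0.55, 0.05, 0.05),
                (0.95, 0.80, 0.22), (1, 1, 1), size)            # plastic yellow
            a_trans = np.zeros_like(trans)
            b_trans = np.zeros_like(trans)
        else:
            a_diff, a_spec = _ward_layers(
                n, mask, proxy, WardBRDF(0.03, 0.85, 0.05),
                (0.95, 0.96, 1.00), (0.96, 0.97, 1.00), size)   # silver
            b_diff, b_spec = _ward_layers(
                n, mask, proxy, WardBRDF(0.02, 0.10, 0.02),
                (1, 1, 1), (1, 1, 1), size)                     # glass shell
            a_trans = np.zeros_like(trans)
            back = np.asarray(proxy.backlight) + np.asarray(proxy.ambient)
            b_trans = 0.8 * back * np.ones_like(trans) * mask[..., None]
        diff = (1 - v) * a_diff + v * b_diff
        spec = (1 - v) * a_spec + v * b_spec
        trans = (1 - v) * a_trans + v * b_trans
    else:  # pragma: no cover
        raise AssertionError(dim)
    return diff, spec, trans, mask, lat, lon


def _to_srgb8(linear: np.ndarray) -> np.ndarray:
    """Encode linear RGB to 8-bit with the display gamma of 2.2."""
    return np.round(np.clip(linear, 0.0, 1.0) ** (1.0 / 2.2) * 255.0).astype(np.uint8)


def srgb8_to_linear(img: np.ndarray) -> np.ndarray:
    return (img.astype(float) / 255.0) ** 2.2


def render_layers(scene: SceneSpec, material: MaterialSpec, size: int = 256):
    """Linear-RGB layer decomposition: diffuse+transmission vs specular."""
    if size < 128:
        raise ValueError("size must be at least 128")
    diff, spec, trans, mask, lat, lon = _material_linear(scene, material, size)
    proxy = ILLUMINATION_PROXIES[scene.illumination_id]
    bg = _background(proxy, size)
    base = np.where(mask[..., None], diff + trans, bg)
    return {
        "shading": base,
        "specular": spec,
        "mask": mask,
        "lat": lat,
        "lon": lon,
    }


from functools import lru_cache


@lru_cache(maxsize=512)
def _render_cached(scene: SceneSpec, material: MaterialSpec, size: int) -> bytes:
    layers = render_layers(scene, material, size)
    return _to_srgb8(layers["shading"] + layers["specular"]).tobytes()


def render_object(
    scene: SceneSpec, material: MaterialSpec, size: int = 256
) -> np.ndarray:
    """Render one object as an 8-bit sRGB image (gamma 2.2).

    Deterministic in (scene, material, size); repeated renders are served
    from a cache.
    """
    buf = _render_cached(scene, material, size)
    return np.frombuffer(buf, dtype=np.uint8).reshape(size, size, 3).copy()


def white_point(illumination_id: int, size: int = 128) -> np.ndarray:
    """XYZ of a matte white sphere under one illumination proxy.

    The mean linear RGB over the sphere of a Lambertian rho_d = 1 render,
    converted to XYZ; serves as the reference white for CIELAB conversion.
    """
    geom = GeometrySpec("white_ref", "sine", 0.0, 0)
    scene = SceneSpec(geom, illumination_id, 0)
    height, mask, _, _ = _height_field(scene, size)
    n = _normals(height, mask, size)
    proxy = ILLUMINATION_PROXIES[illumination_id]
    diff, _ = _ward_layers(
        n, mask, proxy, WardBRDF(0.99, 0.0, 1.0), (1, 1, 1), (1, 1, 1), size
    )
    mean_rgb = diff[mask].mean(axis=0) / 0.99
    from .features import linear_rgb_to_xyz

    return linear_rgb_to_xyz(mean_rgb[None, None, :])[0, 0]


# ---------------------------------------------------------------------------
# highlight inconsistency (glossy vs painted)

def make_inconsistent_highlights(
    scene: SceneSpec,
    d: float,
    seed: int,
    size: int = 256,
    repeat: int = 2,
    identity: bool = False,
    return_layers: bool = False,
):
    """Painted-looking object: highlights displaced from the shading.

    The specular layer of a consistent render is re-applied to the shape by
    spherical mapping with a seeded random longitude/latitude offset and
    ``repeat``-fold tiling, so highlight positions no longer agree with the
    diffuse shading.  The result's per-channel color histogram is then
    matched to the consistent render, so the two images differ only in
    highlight placement.  With ``identity=True`` the remap is skipped
    (degenerate case: reproduces the consistent image).
    """
    material = MaterialSpec("GP", d, consistent=True)
    layers = render_layers(scene, material, size)
    consistent = _to_srgb8(layers["shading"] + layers["specular"])
    if identity:
        return (consistent, layers) if return_layers else consistent
    rng = np.random.default_rng(seed)
    dlon = rng.uniform(0, 2 * np.pi)
    dlat = rng.uniform(-0.5, 0.5)
    spec = layers["specular"]
    mask = layers["mask"]
    lat, lon = layers["lat"], layers["lon"]
    # tile the rendered specular image over the sphere's (lat, lon) chart
    h = w = size
    row = np.mod((lat + dlat + np.pi / 2) / np.pi * repeat, 1.0) * (h - 1)
    col = np.mod((lon + dlon + np.pi) / (2 * np.pi) * repeat, 1.0) * (w - 1)
    remapped = np.stack(
        [
            ndimage.map_coordinates(
                spec[..., ch], [row.ravel(), col.ravel()], order=1, mode="wrap"
            ).reshape(size, size)
            for ch in range(3)
        ],
        axis=-1,
    )
    remapped[~mask] = 0.0
    inconsistent = _to_srgb8(layers["shading"] + remapped)
    matched = exact_histogram_match(inconsistent, consistent)
    if return_layers:
        layers = dict(layers, remapped_specular=remapped)
        return matched, layers
    return matched


def exact_histogram_match(source: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rank-based per-channel histogram matching.

    Pixels of ``source`` are replaced, in rank order, by the sorted pixel
    values of ``reference``; the output's per-channel pixel multiset equals
    the reference's exactly.  Ties in the source are broken by a stable sort
    (scan order), which only permutes equal output values.
    """
    if source.shape != reference.shape:
        raise ValueError("source and reference must share a shape")
    out = np.empty_like(reference)
    for ch in range(source.shape[-1]):
        src = source[..., ch].ravel()
        ref = np.sort(reference[..., ch].ravel())
        order = np.argsort(src, kind="stable")
        flat = np.empty_like(ref)
        flat[order] = ref
        out[..., ch] = flat.reshape(source.shape[:2])
    return out


def highlight_shading_coherence(
    shading: np.ndarray, specular: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Photometric consistency between the highlight and shading layers.

    Pearson correlation of the two layers' intensities over the object
    region.  Highlights produced by the same lighting as the shading sit on
    bright shading regions (both follow the surface normals), giving a
    clearly positive correlation; spatially remapped highlights land at
    random shading levels, pulling the index toward zero.
    """
    s = shading.mean(axis=-1) if shading.ndim == 3 else shading
    p = specular.mean(axis=-1) if specular.ndim == 3 else specular
    if mask is not None:
        s, p = s[mask], p[mask]
    s = s - s.mean()
    p = p - p.mean()
    denom = np.sqrt((s**2).sum() * (p**2).sum())
    if denom == 0:
        return 0.0
    return float((s * p).sum() / denom)


# ---------------------------------------------------------------------------
# oddity displays and the synthetic observer

def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-artifact seed from the master seed and identifying parts."""
    key = ":".join(str(p) for p in (master_seed, *parts))
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big") % (2**31)


def _material_for(dimension: str, value: float, consistent: bool = True) -> MaterialSpec:
    return MaterialSpec(dimension, value, consistent=consistent)


def make_oddity_display(
    condition: TaskCondition, seed: int, size: int = 256
) -> OddityDisplay:
    """Assemble one oddity display for a task condition.

    Illumination condition 1: four images, one illumination proxy, four of
    the five 36-degree poses drawn without replacement.  Conditions 2 and 3:
    three images, one pose, the condition's three distinct proxies.  The
    target carries the difficulty parameter (for GP, consistent highlights);
    non-targets carry the anchor (for GP, inconsistent highlights at the
    same DOI).
    """
    dim = condition.dimension
    ill = condition.illumination
    if dim == "GP" and ill != 1:
        raise ValueError("GP (glossy vs painted) exists only under illumination condition 1")
    geometry = OBJECTS[condition.object_id]
    rng = np.random.default_rng(seed)
    proxies = proxies_for_condition(ill)
    if ill == 1:
        m = 4
        poses = rng.choice(POSES_DEG, size=4, replace=False)
        scenes = [SceneSpec(geometry, proxies[0], int(p)) for p in poses]
    else:
        m = 3
        order = rng.permutation(len(proxies))
        scenes = [SceneSpec(geometry, proxies[i], 0) for i in order]
    target_index = int(rng.integers(m))

    images = []
    if dim == "GP":
        param_distance = 1.0  # consistency flag difference
        for i, sc in enumerate(scenes):
            if i == target_index:
                images.append(
                    render_object(sc, _material_for("GP", condition.difficulty), size)
                )
            else:
                images.append(
                    make_inconsistent_highlights(
                        sc, condition.difficulty,
                        seed=derive_seed(seed, "gp", i), size=size,
                    )
                )
    else:
        anchor = ANCHORS[dim]
        param_distance = abs(condition.difficulty - anchor)
        for i, sc in enumerate(scenes):
            value = condition.difficulty if i == target_index else anchor
            images.append(render_object(sc, _material_for(dim, value), size))
    return OddityDisplay(
        images=tuple(images),
        target_index=target_index,
        condition=condition,
        param_distance=param_distance,
    )


def display_plan(condition: TaskCondition) -> tuple[int, float]:
    """(m, parameter distance) of a condition's display, without rendering."""
    m = 4 if condition.illumination == 1 else 3
    if condition.dimension == "GP":
        return m, 1.0
    return m, abs(condition.difficulty - ANCHORS[condition.dimension])


def simulate_observer(
    display_or_condition,
    link,
    lapse: float,
    seed: int,
    observer_id: str = "sim",
    environment: str = "crowd",
) -> ResponseRecord:
    """One simulated response to an oddity display.

    ``link`` maps stimulus parameter distance to d' (monotone nondecreasing,
    link(0) = 0).  The response follows the same differencing decision rule
    as the sensitivity estimator; with probability ``lapse`` the observer
    instead answers uniformly at random.
    """
    if not (0.0 <= lapse < 0.5):
        raise ValueError("lapse must lie in [0, 0.5)")
    if isinstance(display_or_condition, OddityDisplay):
        m = display_or_condition.m
        distance = display_or_condition.param_distance
        target = display_or_condition.target_index
        condition = display_or_condition.condition
    else:
        condition = display_or_condition
        m, distance = display_plan(condition)
        target = None
    d_prime = float(link(distance))
    if d_prime < 0 or float(link(0.0)) != 0.0:
        raise ValueError("link must be nonnegative with link(0) = 0")
    rng = np.random.default_rng(seed)
    if target is None:
        target = int(rng.integers(m))
    if rng.uniform() < lapse:
        chosen = int(rng.integers(m))
    else:
        x = rng.standard_normal(m)
        x[target] += d_prime
        chosen = int(np.abs(x - x.mean()).argmax())
    return ResponseRecord(
        observer_id=observer_id,
        environment=environment,
        condition=condition,
        chosen_index=chosen,
        correct=chosen == target,
    )
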