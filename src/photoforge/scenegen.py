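"""Procedural scene rendering and ground-truth photo manipulations.

Real forgery-perception experiments edit photographs by hand, which makes
the manipulated area, its grid span and its physical implausibility matters
of judgement.  Here scenes are rendered procedurally — a sky/ground
gradient, buildings, a person, vehicles and trees, each casting a shadow
polygon projected from a single light azimuth — so every manipulation has
an analytically known ground-truth mask:

* ``airbrush``      smoothing/recoloring of the person's face (plausible)
* ``addsub``        removal or insertion of one object (plausible)
* ``geometry``      shearing the top of a building (implausible)
* ``shadow``        reflecting or deleting one cast shadow (implausible)
* ``superadditive`` all four at once, on disjoint targets

The mask of a stimulus pair is *defined* as the exact set of pixels whose
8-bit RGB values differ between original and manipulated renders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon

from .gridchance import Grid, mask_regions

__all__ = [
    "SceneSpec",
    "ObjectSpec",
    "ManipulationType",
    "MANIPULATION_TYPES",
    "StimulusPair",
    "StimulusSet",
    "DegenerateManipulationError",
    "UnsupportedManipulationError",
    "CalibrationError",
    "render_scene",
    "apply_manipulation",
    "random_scene_spec",
    "build_stimulus_set",
    "save_stimulus_set",
    "load_stimulus_pairs",
]

MTYPE_LABELS = ("airbrush", "addsub", "geometry", "shadow", "superadditive")


class DegenerateManipulationError(ValueError):
    """Raised when a manipulation would change no pixel (e.g. strength 0)."""


class UnsupportedManipulationError(ValueError):
    """Raised when the scene lacks an object compatible with the manipulation."""


class CalibrationError(RuntimeError):
    """Raised when the grid-span target cannot be met within the retry budget."""


@dataclass(frozen=True)
class ManipulationType:
    label: str
    plausibility: str  # plausible | implausible | both


MANIPULATION_TYPES: dict[str, ManipulationType] = {
    "airbrush": ManipulationType("airbrush", "plausible"),
    "addsub": ManipulationType("addsub", "plausible"),
    "geometry": ManipulationType("geometry", "implausible"),
    "shadow": ManipulationType("shadow", "implausible"),
    "superadditive": ManipulationType("superadditive", "both"),
}


@dataclass(frozen=True)
class ObjectSpec:
    """A scene primitive standing on the ground plane.

    ``cx`` is the footprint centre column, ``base_y`` the ground-contact
    row; ``w``/``h`` the bounding width/height in pixels.
    """

    kind: str  # building | person | vehicle | tree
    cx: float
    base_y: float
    w: float
    h: float
    color: tuple[int, int, int]


@dataclass(frozen=True)
class SceneSpec:
    seed: int
    width: int = 400
    height: int = 300
    light_azimuth: float = 110.0  # degrees, 0 = north (up), 90 = east (right)
    objects: tuple[ObjectSpec, ...] = ()
    sky_top: tuple[int, int, int] = (110, 150, 210)
    sky_horizon: tuple[int, int, int] = (190, 205, 225)
    ground_top: tuple[int, int, int] = (150, 140, 110)
    ground_bottom: tuple[int, int, int] = (110, 100, 80)
    horizon_frac: float = 0.45
    shadow_factor: float = 0.55
    shadow_len_frac: float = 0.6
    cast_shadows: bool = True

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if not 0.0 <= self.light_azimuth < 360.0:
            raise ValueError("light_azimuth must lie in [0, 360)")
        for obj in self.objects:
            if not (0 <= obj.cx - obj.w / 2 and obj.cx + obj.w / 2 < self.width):
                raise ValueError(f"{obj.kind} does not fit horizontally")
            if not (obj.h <= obj.base_y < self.height):
                raise ValueError(f"{obj.kind} does not fit vertically")


@dataclass
class RenderedScene:
    """Render output plus the per-object masks the manipulations rely on."""

    image: np.ndarray  # uint8 (H, W, 3)
    object_masks: list[np.ndarray]
    shadow_masks: list[np.ndarray]  # visible (non-occluded) shadow pixels
    face_masks: dict[int, np.ndarray]  # person index -> face disk


@dataclass
class StimulusPair:
    scene_id: str
    original: np.ndarray
    manipulated: np.ndarray
    mask: np.ndarray
    mtype: ManipulationType
    strength: float
    component_masks: dict[str, np.ndarray] = field(default_factory=dict)
    evidence_mask: np.ndarray | None = None
    variant: str = ""


@dataclass
class StimulusSet:
    design: str
    grid: Grid
    originals: dict[str, np.ndarray]
    pairs: list[StimulusPair]
    specs: dict[str, SceneSpec]
    extent_scale: float


# ---------------------------------------------------------------------------
# rendering


def _shadow_polygon(obj: ObjectSpec, azimuth: float, len_frac: float) -> np.ndarray:
    """Quad (4x2 array of x, y) cast from the object's footprint segment.

    The shadow extends opposite the light azimuth with a fixed downward
    tilt so the polygon stays on the visible ground plane.
    """
    theta = np.deg2rad(azimuth)
    L = len_frac * obj.h
    dx = -np.sin(theta) * L
    dy = max(0.15, 0.35 + 0.25 * np.cos(theta)) * L
    x0, x1 = obj.cx - obj.w / 2, obj.cx + obj.w / 2
    y = obj.base_y
    return np.array([[x0, y], [x1, y], [x1 + dx, y + dy], [x0 + dx, y + dy]])


def _poly_mask(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = _draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _disk_mask(cy: float, cx: float, r: float, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = _draw_disk((cy, cx), max(r, 1.0), shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _rect_mask(x0: float, x1: float, y0: float, y1: float, shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    ia, ib = int(np.clip(round(y0), 0, shape[0])), int(np.clip(round(y1), 0, shape[0]))
    ja, jb = int(np.clip(round(x0), 0, shape[1])), int(np.clip(round(x1), 0, shape[1]))
    m[ia:ib, ja:jb] = True
    return m


def _shade(color: tuple[int, int, int], f: float) -> np.ndarray:
    return np.clip(np.asarray(color, dtype=float) * f, 0, 255)


def _draw_object(
    img: np.ndarray, obj: ObjectSpec, shear_slope: float = 0.0
) -> tuple[np.ndarray, np.ndarray | None]:
    """Paint one object; returns (object mask, face mask for persons)."""
    shape = img.shape[:2]
    color = np.asarray(obj.color, dtype=float)
    x0, x1 = obj.cx - obj.w / 2, obj.cx + obj.w / 2
    top, base = obj.base_y - obj.h, obj.base_y
    mask = np.zeros(shape, dtype=bool)
    face = None

    if obj.kind == "building":
        split = top + 0.5 * obj.h  # rows above this shear horizontally
        body = np.zeros(shape, dtype=bool)
        for y in range(int(round(top)), int(round(base))):
            if not 0 <= y < shape[0]:
                continue
            off = shear_slope * max(0.0, split - y)
            ja = int(np.clip(round(x0 + off), 0, shape[1]))
            jb = int(np.clip(round(x1 + off), 0, shape[1]))
            body[y, ja:jb] = True
        img[body] = color
        # windows: a deterministic grid of darker panes, sheared with the wall
        n_wx, n_wy = 3, 4
        for iy in range(n_wy):
            for ix in range(n_wx):
                wx0 = x0 + obj.w * (0.12 + 0.3 * ix)
                wy0 = top + obj.h * (0.08 + 0.22 * iy)
                for y in range(int(round(wy0)), int(round(wy0 + obj.h * 0.12))):
                    if not 0 <= y < shape[0]:
                        continue
                    off = shear_slope * max(0.0, split - y)
                    ja = int(np.clip(round(wx0 + off), 0, shape[1]))
                    jb = int(np.clip(round(wx0 + obj.w * 0.18 + off), 0, shape[1]))
                    img[y, ja:jb] = _shade(obj.color, 0.45)
        mask = body
    elif obj.kind == "person":
        r = max(2.0, 0.22 * obj.h)
        head_c = (top + r, obj.cx)
        head = _disk_mask(head_c[0], head_c[1], r, shape)
        body = _rect_mask(obj.cx - 0.3 * obj.w, obj.cx + 0.3 * obj.w, top + 2 * r, base, shape)
        img[body] = color
        img[head] = _shade((224, 172, 138), 1.0)  # skin tone
        mask = head | body
        face = _disk_mask(head_c[0], head_c[1], 0.85 * r, shape)
    elif obj.kind == "vehicle":
        body = _rect_mask(x0, x1, base - 0.55 * obj.h, base - 0.15 * obj.h, shape)
        cabin = _rect_mask(
            obj.cx - 0.28 * obj.w, obj.cx + 0.28 * obj.w, top, base - 0.55 * obj.h, shape
        )
        img[body] = color
        img[cabin] = _shade(obj.color, 0.8)
        wheels = _disk_mask(base - 0.14 * obj.h, obj.cx - 0.3 * obj.w, 0.14 * obj.h, shape)
        wheels |= _disk_mask(base - 0.14 * obj.h, obj.cx + 0.3 * obj.w, 0.14 * obj.h, shape)
        img[wheels] = (35.0, 35.0, 38.0)
        mask = body | cabin | wheels
    elif obj.kind == "tree":
        trunk = _rect_mask(obj.cx - 0.08 * obj.w, obj.cx + 0.08 * obj.w, top + 0.4 * obj.h, base, shape)
        canopy = _disk_mask(top + 0.38 * obj.h, obj.cx, 0.4 * obj.h, shape)
        img[trunk] = (95.0, 70.0, 48.0)
        img[canopy] = color
        mask = trunk | canopy
    else:
        raise ValueError(f"unknown object kind: {obj.kind!r}")
    return mask, face


def _render(
    spec: SceneSpec,
    shadow_mode: dict[int, str] | None = None,
    shear: dict[int, float] | None = None,
) -> RenderedScene:
    shadow_mode = shadow_mode or {}
    shear = shear or {}
    H, W = spec.height, spec.width
    img = np.zeros((H, W, 3), dtype=float)

    # background gradients
    horizon = max(1, int(spec.horizon_frac * H))
    t_sky = (np.arange(horizon) / max(horizon - 1, 1))[:, None]
    img[:horizon] = (1 - t_sky)[..., None] * np.asarray(spec.sky_top) + t_sky[..., None] * np.asarray(
        spec.sky_horizon
    )
    n_g = H - horizon
    t_g = (np.arange(n_g) / max(n_g - 1, 1))[:, None]
    img[horizon:] = (1 - t_g)[..., None] * np.asarray(spec.ground_top) + t_g[..., None] * np.asarray(
        spec.ground_bottom
    )

    # shadows first, then objects (objects occlude shadows)
    shadow_polys: list[np.ndarray | None] = []
    for i, obj in enumerate(spec.objects):
        mode = shadow_mode.get(i)
        if not spec.cast_shadows or mode == "delete":
            shadow_polys.append(None)
            continue
        az = (spec.light_azimuth + 180.0) % 360.0 if mode == "reflect" else spec.light_azimuth
        shadow_polys.append(_shadow_polygon(obj, az, spec.shadow_len_frac))
    raw_shadows = [
        _poly_mask(p, (H, W)) if p is not None else np.zeros((H, W), dtype=bool)
        for p in shadow_polys
    ]
    for sh in raw_shadows:
        img[sh] *= spec.shadow_factor

    object_masks: list[np.ndarray] = []
    face_masks: dict[int, np.ndarray] = {}
    for i, obj in enumerate(spec.objects):
        m, face = _draw_object(img, obj, shear_slope=shear.get(i, 0.0))
        object_masks.append(m)
        if face is not None:
            face_masks[i] = face

    occluded = np.zeros((H, W), dtype=bool)
    for m in object_masks:
        occluded |= m
    shadow_masks = [sh & ~occluded for sh in raw_shadows]

    return RenderedScene(
        image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        object_masks=object_masks,
        shadow_masks=shadow_masks,
        face_masks=face_masks,
    )


def render_scene(spec: SceneSpec) -> np.ndarray:
    """Deterministic 8-bit RGB render of a scene spec."""
    return _render(spec).image


# ---------------------------------------------------------------------------
# manipulations


def _diff_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a != b).any(axis=2)


def _indices(spec: SceneSpec, kind: str) -> list[int]:
    return [i for i, o in enumerate(spec.objects) if o.kind == kind]


def _airbrush(
    original: np.ndarray, scene: RenderedScene, spec: SceneSpec, strength: float, rng,
    target: int | None = None, variant: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None, str]:
    persons = [i for i in _indices(spec, "person") if i in scene.face_masks]
    if not persons:
        raise UnsupportedManipulationError("airbrush needs a person with a visible face")
    idx = int(rng.choice(persons)) if target is None else target
    face = scene.face_masks[idx]
    out = original.astype(float)
    smooth = ndimage.gaussian_filter(out, sigma=(1.0 + 1.5 * strength, 1.0 + 1.5 * strength, 0))
    alpha = float(np.clip(0.8 * strength, 0.0, 1.0))
    out[face] = (1 - alpha) * out[face] + alpha * (smooth[face] + 10.0 * strength)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if not _diff_mask(original, out).any():
        raise DegenerateManipulationError("airbrush changed no pixel at this strength")
    return out, None, "smooth"


def _addsub(
    original: np.ndarray, scene: RenderedScene, spec: SceneSpec, strength: float, rng,
    target: int | None = None, variant: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None, str]:
    removable = _indices(spec, "tree") + _indices(spec, "vehicle")
    if variant is None:
        variant = "remove" if removable and rng.random() < 0.75 else "insert"
    if variant == "remove" and not removable:
        raise UnsupportedManipulationError("no removable object (tree/vehicle) in scene")
    out = original.copy()
    if variant == "remove":
        idx = int(rng.choice(removable)) if target is None else target
        region = scene.object_masks[idx] | scene.shadow_masks[idx]
        region = ndimage.binary_dilation(region, iterations=1)
        ring = ndimage.binary_dilation(region, iterations=6) & ~region
        fill = np.median(original[ring].astype(float), axis=0)
        out[region] = np.clip(np.rint(fill), 0, 255).astype(np.uint8)
    else:
        # insert a tree at a horizontal position clear of existing objects
        H, W = spec.height, spec.width
        h = np.clip(45.0 * strength + 25.0, 20.0, 0.4 * H)
        w = 0.8 * h
        base_y = min(H - 2.0, spec.horizon_frac * H + 0.35 * (H - spec.horizon_frac * H))
        taken = [(o.cx - o.w, o.cx + o.w) for o in spec.objects]
        candidates = [
            x
            for x in np.linspace(w, W - w, 24)
            if all(x < lo or x > hi for lo, hi in taken)
        ]
        if not candidates:
            raise UnsupportedManipulationError("no free location to insert an object")
        cx = float(rng.choice(candidates))
        obj = ObjectSpec("tree", cx, base_y, w, h, (60, 110, 55))
        imgf = out.astype(float)
        if spec.cast_shadows:
            sh = _poly_mask(_shadow_polygon(obj, spec.light_azimuth, spec.shadow_len_frac), (H, W))
            imgf[sh] *= spec.shadow_factor
        _draw_object(imgf, obj)
        out = np.clip(np.rint(imgf), 0, 255).astype(np.uint8)
    if not _diff_mask(original, out).any():
        raise DegenerateManipulationError("add/sub manipulation changed no pixel")
    return out, None, variant


def _geometry(
    original: np.ndarray, scene: RenderedScene, spec: SceneSpec, strength: float, rng,
    target: int | None = None, variant: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None, str]:
    buildings = _indices(spec, "building")
    if not buildings:
        raise UnsupportedManipulationError("geometry manipulation needs a building")
    idx = int(rng.choice(buildings)) if target is None else target
    slope = 0.35 * strength
    if slope <= 0:
        raise DegenerateManipulationError("zero shear angle")
    out = _render(spec, shear={idx: slope}).image
    if not _diff_mask(original, out).any():
        raise DegenerateManipulationError("shear too small to move any pixel")
    return out, scene.object_masks[idx], "shear"


def _shadow(
    original: np.ndarray, scene: RenderedScene, spec: SceneSpec, strength: float, rng,
    target: int | None = None, variant: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None, str]:
    casting = [i for i, m in enumerate(scene.shadow_masks) if m.any()]
    if not casting:
        raise UnsupportedManipulationError("no object casts a visible shadow")
    idx = int(rng.choice(casting)) if target is None else target
    if variant is None:
        variant = "reflect" if rng.random() < 0.5 else "delete"
    out = _render(spec, shadow_mode={idx: variant}).image
    if not _diff_mask(original, out).any():
        raise DegenerateManipulationError("shadow manipulation changed no pixel")
    return out, scene.object_masks[idx], variant


_COMPONENT_FNS = {
    "airbrush": _airbrush,
    "addsub": _addsub,
    "geometry": _geometry,
    "shadow": _shadow,
}


def apply_manipulation(
    pair_source: np.ndarray,
    spec: SceneSpec,
    mtype: ManipulationType | str,
    strength: float,
    rng: np.random.Generator,
    scene_id: str = "scene",
) -> StimulusPair:
    """Apply one manipulation class to a rendered scene.

    ``pair_source`` must be the render of ``spec`` (it is re-derived
    internally for the re-rendering manipulations).  The returned pair's
    mask is exactly the set of differing pixels; for the super-additive
    composite the per-component masks are pairwise disjoint and union to
    the full mask.
    """
    if isinstance(mtype, str):
        mtype = MANIPULATION_TYPES[mtype]
    if strength <= 0:
        raise DegenerateManipulationError("strength must be positive")
    scene = _render(spec)
    original = scene.image
    if pair_source.shape != original.shape:
        raise ValueError("pair_source does not match the spec's render dimensions")

    if mtype.label == "superadditive":
        # compose the four elementary manipulations on pairwise-distinct
        # targets so the component masks stay disjoint
        persons = [i for i in _indices(spec, "person") if i in scene.face_masks]
        trees = _indices(spec, "tree")
        vehicles = _indices(spec, "vehicle")
        buildings = _indices(spec, "building")
        if not (persons and buildings and (trees or vehicles)):
            raise UnsupportedManipulationError(
                "super-additive needs a person, a building and a removable object"
            )
        addsub_target = trees[0] if trees else vehicles[0]
        shadow_candidates = [
            i
            for i, m in enumerate(scene.shadow_masks)
            if m.any() and i != addsub_target and i not in buildings
        ]
        if not shadow_candidates:
            raise UnsupportedManipulationError("no free shadow-casting object remains")
        targets = {
            "airbrush": persons[0],
            "addsub": addsub_target,
            "geometry": buildings[0],
            "shadow": shadow_candidates[0],
        }
        variants = {"addsub": "remove"}
        out = original.copy()
        component_masks: dict[str, np.ndarray] = {}
        evidence = np.zeros(original.shape[:2], dtype=bool)
        covered = np.zeros(original.shape[:2], dtype=bool)
        for label in ("airbrush", "addsub", "geometry", "shadow"):
            manip, ev, _variant = _COMPONENT_FNS[label](
                original, scene, spec, strength, rng,
                target=targets[label], variant=variants.get(label),
            )
            m = _diff_mask(original, manip)
            if (m & covered).any():
                raise UnsupportedManipulationError(
                    "super-additive components overlap; scene objects are too close"
                )
            out[m] = manip[m]
            component_masks[label] = m
            covered |= m
            if ev is not None:
                evidence |= ev
        return StimulusPair(
            scene_id=scene_id,
            original=original,
            manipulated=out,
            mask=covered,
            mtype=mtype,
            strength=strength,
            component_masks=component_masks,
            evidence_mask=evidence if evidence.any() else None,
            variant="composite",
        )

    fn = _COMPONENT_FNS.get(mtype.label)
    if fn is None:
        raise ValueError(f"unknown manipulation type: {mtype.label!r}")
    manipulated, evidence, variant = fn(original, scene, spec, strength, rng)
    return StimulusPair(
        scene_id=scene_id,
        original=original,
        manipulated=manipulated,
        mask=_diff_mask(original, manipulated),
        mtype=mtype,
        strength=strength,
        evidence_mask=evidence,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# scene sampling and set construction

_PALETTES = {
    "building": [(165, 160, 155), (150, 130, 120), (180, 170, 150)],
    "person": [(60, 70, 120), (130, 50, 55), (50, 95, 70)],
    "vehicle": [(170, 55, 50), (70, 90, 140), (200, 180, 70)],
    "tree": [(55, 105, 50), (70, 120, 60), (45, 95, 55)],
}


def random_scene_spec(
    rng: np.random.Generator,
    width: int = 400,
    height: int = 300,
    extent_scale: float = 1.0,
    seed: int = 0,
) -> SceneSpec:
    """Sample a layout with a person, a building, a tree and a vehicle.

    Objects are placed in horizontal lanes with margins so that the
    super-additive manipulation's four component masks stay disjoint.
    ``extent_scale`` multiplies object sizes; the set builder uses it to
    calibrate how many grid regions a manipulation spans.
    """
    H, W = height, width
    s = extent_scale

    def col(frac_lo, frac_hi):
        return float(rng.uniform(frac_lo, frac_hi) * W)

    def pick(kind):
        return tuple(
            int(np.clip(c + rng.integers(-12, 13), 0, 255))
            for c in _PALETTES[kind][rng.integers(len(_PALETTES[kind]))]
        )

    ground0 = 0.45 * H

    def clamp(obj: ObjectSpec) -> ObjectSpec:
        # shrink/move as needed so the primitive fits the canvas
        h = min(obj.h, obj.base_y - 1.0)
        w = min(obj.w, W - 4.0)
        cx = float(np.clip(obj.cx, w / 2 + 1, W - w / 2 - 2))
        return replace(obj, cx=cx, w=w, h=h)

    objects = [
        ObjectSpec(
            "person",
            cx=col(0.08, 0.16),
            base_y=float(rng.uniform(0.80, 0.92) * H),
            w=s * 0.085 * H,
            h=s * float(rng.uniform(0.30, 0.38)) * H,
            color=pick("person"),
        ),
        ObjectSpec(
            "tree",
            cx=col(0.34, 0.44),
            base_y=float(rng.uniform(0.62, 0.72) * H),
            w=s * float(rng.uniform(0.16, 0.20)) * H,
            h=s * float(rng.uniform(0.26, 0.33)) * H,
            color=pick("tree"),
        ),
        ObjectSpec(
            "vehicle",
            cx=col(0.56, 0.64),
            base_y=float(rng.uniform(0.86, 0.94) * H),
            w=s * float(rng.uniform(0.24, 0.30)) * H,
            h=s * float(rng.uniform(0.12, 0.16)) * H,
            color=pick("vehicle"),
        ),
        ObjectSpec(
            "building",
            cx=col(0.82, 0.90),
            base_y=float(rng.uniform(0.58, 0.66) * H),
            w=s * float(rng.uniform(0.24, 0.30)) * H,
            h=s * float(rng.uniform(0.42, 0.52)) * H,
            color=pick("building"),
        ),
    ]
    return SceneSpec(
        seed=seed,
        width=W,
        height=H,
        light_azimuth=float(rng.uniform(60.0, 120.0)),
        objects=tuple(clamp(o) for o in objects),
        horizon_frac=ground0 / H,
    )


DESIGN_DEFAULTS = {
    "exp1": {"width": 400, "height": 300, "rows": 3, "cols": 3},
    "exp2": {"width": 480, "height": 320, "rows": 3, "cols": 4},
}

# strength schedule: airbrushing must produce the smallest pixel change,
# the super-additive composite (the sum of all four) the largest
DEFAULT_STRENGTHS = {
    "airbrush": 0.5,
    "addsub": 1.0,
    "geometry": 1.0,
    "shadow": 1.0,
    "superadditive": 1.0,
}


def build_stimulus_set(
    n_scenes: int,
    design: str = "exp1",
    grid: Grid | None = None,
    rng: np.random.Generator | None = None,
    n_manipulated_scenes: int | None = None,
    mtypes: tuple[str, ...] = MTYPE_LABELS,
    target_regions: float = 2.0,
    region_tol: float = 0.5,
    strengths: dict[str, float] | None = None,
    max_retries: int = 8,
) -> StimulusSet:
    """Generate originals plus manipulated variants for a design.

    ``n_manipulated_scenes`` of the ``n_scenes`` scenes (default
    ``min(6, n_scenes)``) receive every manipulation type in ``mtypes``.
    Object extents are calibrated, by bounded retries on a global scale
    factor, until the mean number of mask-covered grid regions over all
    pairs lands within ``region_tol`` of ``target_regions``.
    """
    if n_scenes < 1:
        raise ValueError("need at least one scene")
    if design not in DESIGN_DEFAULTS:
        raise ValueError(f"unknown design {design!r}")
    dd = DESIGN_DEFAULTS[design]
    if grid is None:
        grid = Grid(rows=dd["rows"], cols=dd["cols"], width=dd["width"], height=dd["height"])
    if rng is None:
        rng = np.random.default_rng()
    if n_manipulated_scenes is None:
        n_manipulated_scenes = min(6, n_scenes)
    if n_manipulated_scenes > n_scenes:
        raise ValueError("cannot manipulate more scenes than exist")
    strengths = {**DEFAULT_STRENGTHS, **(strengths or {})}

    extent_scale = 1.0
    history = []
    for _attempt in range(max_retries):
        attempt_rng = np.random.default_rng(rng.integers(2**31))
        specs: dict[str, SceneSpec] = {}
        originals: dict[str, np.ndarray] = {}
        pairs: list[StimulusPair] = []
        try:
            for i in range(n_scenes):
                sid = f"{design}_scene{i:03d}"
                spec = random_scene_spec(
                    attempt_rng, grid.width, grid.height, extent_scale=extent_scale, seed=i
                )
                specs[sid] = spec
                original = render_scene(spec)
                originals[sid] = original
                if i < n_manipulated_scenes:
                    for label in mtypes:
                        pairs.append(
                            apply_manipulation(
                                original, spec, label, strengths[label], attempt_rng,
                                scene_id=sid,
                            )
                        )
        except UnsupportedManipulationError as err:
            # objects grew until they collide; back the scale off and retry
            history.append((extent_scale, f"overlap: {err}"))
            extent_scale *= 0.85
            continue
        counts = [len(mask_regions(p.mask, grid)) for p in pairs]
        mean_count = float(np.mean(counts))
        history.append((extent_scale, mean_count))
        if abs(mean_count - target_regions) <= region_tol:
            return StimulusSet(
                design=design,
                grid=grid,
                originals=originals,
                pairs=pairs,
                specs=specs,
                extent_scale=extent_scale,
            )
        extent_scale = float(
            np.clip(extent_scale * (target_regions / mean_count) ** 0.7, 0.35, 2.5)
        )
    raise CalibrationError(
        f"mean grid span did not reach {target_regions}+/-{region_tol} "
        f"after {max_retries} attempts; (scale, mean) history: {history}"
    )


def save_stimulus_set(stimset: StimulusSet, out_dir) -> pd.DataFrame:
    """Write PNG originals/manipulated/masks plus a manifest CSV."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, img in stimset.originals.items():
        Image.fromarray(img).save(out / f"{sid}_original.png")
    rows = []
    for p in stimset.pairs:
        stem = f"{p.scene_id}_{p.mtype.label}"
        Image.fromarray(p.manipulated).save(out / f"{stem}.png")
        Image.fromarray((p.mask * np.uint8(255))).save(out / f"{stem}_mask.png")
        rows.append(
            {
                "scene_id": p.scene_id,
                "mtype": p.mtype.label,
                "strength": p.strength,
                "variant": p.variant,
                "mask_region_count": len(mask_regions(p.mask, stimset.grid)),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_stimulus_pairs(in_dir) -> list[StimulusPair]:
    """Read pairs back from a saved set (manifest CSV + PNGs).

    Component and evidence masks are not serialized; reloaded pairs carry
    the composite mask only.
    """
    from pathlib import Path

    from PIL import Image

    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    pairs = []
    for row in manifest.itertuples(index=False):
        stem = f"{row.scene_id}_{row.mtype}"
        original = np.asarray(Image.open(src / f"{row.scene_id}_original.png"))
        manipulated = np.asarray(Image.open(src / f"{stem}.png"))
        mask = np.asarray(Image.open(src / f"{stem}_mask.png")) > 0
        pairs.append(
            StimulusPair(
                scene_id=row.scene_id,
                original=original,
                manipulated=manipulated,
                mask=mask,
                mtype=MANIPULATION_TYPES[row.mtype],
                strength=float(row.strength),
                variant=str(row.variant),
            )
        )
    return pairs
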