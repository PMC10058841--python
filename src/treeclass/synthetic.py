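"""Synthetic spectral-tree scenes for end-to-end pipeline exercise.

Real hyperspectral-LiDAR orchard scans pair tree geometry with
component-specific reflectance spectra, and are degraded at component
edges where the laser footprint partially misses the target.  This module
emulates that structure so every pipeline stage can be driven and scored
without instrument data:

* geometry — a vertical trunk cylinder with side branches (wood), fruit
  spheres hung from the branches, and leaf discs scattered around them;
* spectra — four analytic base curves reproducing the qualitative class
  signatures: wood rising monotonically with wavelength; leaf and unripe
  fruit showing a chlorophyll red edge (NIR reflectance more than twice
  the 680 nm value); ripe fruit an approximately 20% plateau over
  600-900 nm;
* edge degradation — points near each primitive's silhouette (as seen
  from the scanner, looking along +y) are flagged as edges; their spectra
  are attenuated so that the non-edge class mean exceeds the edge mean by
  a configured relative margin (defaults 10.36% unripe fruit, 17.81% ripe
  fruit, 18.18% leaf, 11.06% wood) and flattened toward a slowly rising
  ramp, mimicking footprint spillover onto the background.

The attenuated-and-flattened edge construction is mean-preserving per
channel average, so the configured percentages are exactly the expected
non-edge-over-edge relative excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .cloud import ComponentLabel, SpectralPointCloud
from .grid import DEFAULT_GRID, WavelengthGrid
from .preprocess import ReferencePanel

__all__ = [
    "SpectralTemplate",
    "SceneConfig",
    "SyntheticScene",
    "default_templates",
    "sample_component_geometry",
    "synth_spectrum",
    "generate_scene",
    "synthetic_panel",
]

#: Scanner view direction used for silhouette computation (range axis +y).
VIEW_DIRECTION = np.array([0.0, 1.0, 0.0])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _wood_curve(wl: np.ndarray) -> np.ndarray:
    # bark brightens steadily into the NIR
    return 0.15 + 0.25 * (wl - 550.0) / 500.0


def _leaf_curve(wl: np.ndarray) -> np.ndarray:
    # strong chlorophyll red edge near 715 nm
    return 0.08 + 0.37 * _sigmoid((wl - 715.0) / 18.0)


def _unripe_curve(wl: np.ndarray) -> np.ndarray:
    # chlorophyll still present: leaf-like red edge, slightly brighter visible
    return 0.10 + 0.28 * _sigmoid((wl - 715.0) / 18.0)


def _ripe_curve(wl: np.ndarray) -> np.ndarray:
    # chlorophyll gone: flat ~20% plateau across 600-900 nm
    return 0.19 + 0.03 * (wl - 550.0) / 500.0


_BASE_CURVES: Mapping[ComponentLabel, Callable[[np.ndarray], np.ndarray]] = {
    ComponentLabel.WOOD: _wood_curve,
    ComponentLabel.LEAF: _leaf_curve,
    ComponentLabel.UNRIPE_FRUIT: _unripe_curve,
    ComponentLabel.RIPE_FRUIT: _ripe_curve,
}

#: Non-edge over edge mean-reflectance relative excess, per class.
DEFAULT_EDGE_ATTENUATION: Mapping[ComponentLabel, float] = {
    ComponentLabel.UNRIPE_FRUIT: 0.1036,
    ComponentLabel.RIPE_FRUIT: 0.1781,
    ComponentLabel.LEAF: 0.1818,
    ComponentLabel.WOOD: 0.1106,
}


@dataclass
class SpectralTemplate:
    """Spectral recipe of one component class.

    ``edge_attenuation`` is the relative margin by which the class's
    non-edge mean reflectance exceeds its edge mean (edge spectra are
    scaled by 1/(1 + attenuation)); ``edge_flattening`` mixes the scaled
    curve toward a slowly increasing linear ramp of identical channel
    mean, washing out the class's spectral shape at edges.
    """

    label: ComponentLabel
    base: Callable[[np.ndarray], np.ndarray]
    noise_sd: float = 0.02
    edge_attenuation: float = 0.15
    edge_flattening: float = 0.9


def default_templates(
    noise_sd: float = 0.02,
    edge_attenuation: Mapping[ComponentLabel, float] | None = None,
    edge_flattening: float = 0.9,
) -> dict[ComponentLabel, SpectralTemplate]:
    att = dict(DEFAULT_EDGE_ATTENUATION)
    if edge_attenuation:
        att.update(edge_attenuation)
    return {
        lab: SpectralTemplate(
            label=lab,
            base=_BASE_CURVES[lab],
            noise_sd=noise_sd,
            edge_attenuation=att[lab],
            edge_flattening=edge_flattening,
        )
        for lab in ComponentLabel
    }


@dataclass
class SceneConfig:
    """Scene parameters: per-component counts, geometry sizes (metres),
    edge regime and spectral noise."""

    counts: dict[ComponentLabel, int] = field(
        default_factory=lambda: {
            ComponentLabel.UNRIPE_FRUIT: 750,
            ComponentLabel.RIPE_FRUIT: 750,
            ComponentLabel.WOOD: 1500,
            ComponentLabel.LEAF: 2000,
        }
    )
    trunk_radius: float = 0.05
    trunk_height: float = 1.4
    n_branches: int = 5
    branch_radius: float = 0.02
    branch_length: float = 0.45
    fruit_radius: float = 0.05
    leaf_disc_radius: float = 0.06
    edge_fraction: float = 0.15
    edge_attenuation: dict[ComponentLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_ATTENUATION)
    )
    edge_flattening: float = 0.9
    noise_sd: float = 0.02
    range_offset: float = 5.0  # scene centre distance from the scanner (m)
    seed: int = 0

    def __post_init__(self) -> None:
        for lab, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative point count for {lab}")
        if not 0.0 <= self.edge_fraction < 1.0:
            raise ValueError("edge_fraction must lie in [0, 1)")
        for lab, a in self.edge_attenuation.items():
            if not 0.0 <= a < 1.0:
                raise ValueError(f"edge attenuation for {lab} must lie in [0, 1)")


@dataclass
class SyntheticScene:
    """Generated scene: labeled cloud plus the ground-truth edge flags."""

    cloud: SpectralPointCloud
    edge_flags: np.ndarray


# ------------------------------------------------------------- geometry


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    return e1, np.cross(u, e1)


def _cylinder_points(
    rng: np.random.Generator,
    n: int,
    origin: np.ndarray,
    axis: np.ndarray,
    radius: float,
    length: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points on a cylinder's lateral surface, with outward normals."""
    e1, e2 = _orthonormal_frame(axis)
    t = rng.uniform(0.0, length, n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    normal = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)
    pts = origin + np.outer(t, axis) + radius * normal
    return pts, normal


def _sphere_points(
    rng: np.random.Generator, n: int, center: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    normal = rng.normal(size=(n, 3))
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    return center + radius * normal, normal


def _branches(config: SceneConfig, rng: np.random.Generator):
    """Branch origins and unit directions fanned around the upper trunk."""
    out = []
    for b in range(config.n_branches):
        h = config.trunk_height * (0.45 + 0.5 * (b + rng.uniform(0.2, 0.8)) / config.n_branches)
        phi = rng.uniform(0, 2 * np.pi)
        tilt = rng.uniform(0.1, 0.45)  # radians above horizontal
        d = _unit(np.array([np.cos(phi) * np.cos(tilt),
                            np.sin(phi) * np.cos(tilt),
                            np.sin(tilt)]))
        origin = np.array([config.trunk_radius * np.cos(phi),
                           config.trunk_radius * np.sin(phi), h])
        out.append((origin, d))
    return out


def sample_component_geometry(
    config: SceneConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample coordinates, labels and edge flags for one tree scene.

    Edge flags mark, per component class, the configured fraction of
    points geometrically closest to their primitive's silhouette as seen
    from the scanner (sphere and cylinder points whose surface normal is
    near-perpendicular to the view direction; leaf-disc points near the
    disc rim).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    branches = _branches(config, rng)

    coords_parts: list[np.ndarray] = []
    labels_parts: list[np.ndarray] = []
    score_parts: list[np.ndarray] = []

    # a scanner samples every surface at roughly the same areal density;
    # primitive counts therefore follow from the wood density
    wood_area = (
        2 * np.pi * config.trunk_radius * config.trunk_height
        + config.n_branches * 2 * np.pi * config.branch_radius * config.branch_length
    )
    n_wood_cfg = config.counts.get(ComponentLabel.WOOD, 0)
    density = (n_wood_cfg / wood_area) if n_wood_cfg else 2000.0
    sphere_area = 4 * np.pi * config.fruit_radius**2
    disc_area = np.pi * config.leaf_disc_radius**2

    # --- wood: trunk plus branch cylinders, split by lateral surface area
    n_wood = config.counts.get(ComponentLabel.WOOD, 0)
    if n_wood:
        areas = [config.trunk_radius * config.trunk_height] + [
            config.branch_radius * config.branch_length
        ] * len(branches)
        alloc = _allocate(n_wood, np.asarray(areas))
        pts, normals = _cylinder_points(
            rng, alloc[0], np.zeros(3), np.array([0.0, 0.0, 1.0]),
            config.trunk_radius, config.trunk_height,
        )
        all_pts, all_nrm = [pts], [normals]
        for (origin, d), k in zip(branches, alloc[1:]):
            pts, normals = _cylinder_points(
                rng, k, origin, d, config.branch_radius, config.branch_length
            )
            all_pts.append(pts)
            all_nrm.append(normals)
        pts = np.vstack(all_pts)
        normals = np.vstack(all_nrm)
        coords_parts.append(pts)
        labels_parts.append(np.full(n_wood, ComponentLabel.WOOD, dtype=np.int64))
        score_parts.append(np.abs(normals @ VIEW_DIRECTION))

    # --- fruits: non-overlapping spheres hung beneath branch points
    sphere_centers: list[np.ndarray] = []
    for lab in (ComponentLabel.UNRIPE_FRUIT, ComponentLabel.RIPE_FRUIT):
        n = config.counts.get(lab, 0)
        if not n:
            continue
        n_spheres = max(1, int(round(n / (density * sphere_area))))
        alloc = _allocate(n, np.ones(n_spheres))
        pts_list, nrm_list = [], []
        for k in alloc:
            center = _place_fruit(config, rng, branches, sphere_centers)
            sphere_centers.append(center)
            pts, normals = _sphere_points(rng, k, center, config.fruit_radius)
            pts_list.append(pts)
            nrm_list.append(normals)
        coords_parts.append(np.vstack(pts_list))
        labels_parts.append(np.full(n, lab, dtype=np.int64))
        score_parts.append(np.abs(np.vstack(nrm_list) @ VIEW_DIRECTION))

    # --- leaves: randomly oriented discs floating around the branches,
    #     kept clear of the fruit spheres and the trunk
    n_leaf = config.counts.get(ComponentLabel.LEAF, 0)
    if n_leaf:
        n_discs = max(1, int(round(n_leaf / (density * disc_area))))
        alloc = _allocate(n_leaf, np.ones(n_discs))
        pts_list, score_list = [], []
        for k in alloc:
            center = _place_leaf(config, rng, branches, sphere_centers)
            nd = _unit(rng.normal(size=3))
            e1, e2 = _orthonormal_frame(nd)
            rr = config.leaf_disc_radius * np.sqrt(rng.uniform(size=k))
            phi = rng.uniform(0, 2 * np.pi, k)
            pts = center + np.outer(rr * np.cos(phi), e1) + np.outer(rr * np.sin(phi), e2)
            pts_list.append(pts)
            # rim proximity: 0 at the boundary, 1 at the centre
            score_list.append(1.0 - rr / config.leaf_disc_radius)
        coords_parts.append(np.vstack(pts_list))
        labels_parts.append(np.full(n_leaf, ComponentLabel.LEAF, dtype=np.int64))
        score_parts.append(np.concatenate(score_list))

    if not coords_parts:
        return (np.empty((0, 3)), np.empty(0, dtype=np.int64),
                np.empty(0, dtype=bool))

    coords = np.vstack(coords_parts)
    coords[:, 1] += config.range_offset
    labels = np.concatenate(labels_parts)
    scores = np.concatenate(score_parts)

    # flag the configured fraction of lowest-score (most silhouette-near)
    # points per class; the rim width follows from the fraction
    edge = np.zeros(len(coords), dtype=bool)
    if config.edge_fraction > 0:
        for lab in ComponentLabel:
            sel = labels == lab
            if not sel.any():
                continue
            thr = np.quantile(scores[sel], config.edge_fraction)
            edge[sel] = scores[sel] <= thr
    return coords, labels, edge


def _segment_distance(p: np.ndarray, origin: np.ndarray, d: np.ndarray,
                      length: float) -> float:
    """Distance from point p to the segment origin + t*d, t in [0, length]."""
    t = np.clip(np.dot(p - origin, d), 0.0, length)
    return float(np.linalg.norm(p - (origin + t * d)))


def _branch_clearance(p: np.ndarray, branches, config: SceneConfig) -> float:
    """Smallest gap between p and any branch surface."""
    return min(
        _segment_distance(p, o, d, config.branch_length) for o, d in branches
    ) - config.branch_radius


#: Inter-component gap kept during placement; comparable to the radius a
#: 12-point neighborhood spans at the default sampling density, so that
#: neighborhoods stay class-pure away from silhouettes.
_CLEAR = 0.05


def _place_fruit(
    config: SceneConfig,
    rng: np.random.Generator,
    branches,
    existing: list[np.ndarray],
    tries: int = 300,
) -> np.ndarray:
    """Fruit-sphere centre dangling below a branch on a stem of varying
    length, colliding with neither other fruit nor foreign branches."""
    min_sep = 2.0 * config.fruit_radius + 0.01
    best = None
    for _ in range(tries):
        origin, d = branches[rng.integers(len(branches))]
        t = rng.uniform(0.3, 1.0) * config.branch_length
        drop = config.fruit_radius + config.branch_radius + rng.uniform(_CLEAR, 0.25)
        sway = rng.uniform(-0.12, 0.12, size=2)
        center = origin + t * d + np.array([sway[0], sway[1], -drop])
        gap = min(np.linalg.norm(center - c) for c in existing) if existing else np.inf
        branch_gap = _branch_clearance(center, branches, config) - config.fruit_radius
        score = min(gap - min_sep, branch_gap - _CLEAR)
        if score >= 0:
            return center
        if best is None or score > best[0]:
            best = (score, center)
    return best[1]  # densest admissible placement found


def _place_leaf(
    config: SceneConfig,
    rng: np.random.Generator,
    branches,
    sphere_centers: list[np.ndarray],
    tries: int = 300,
) -> np.ndarray:
    """Leaf-disc centre floating near a branch, clear of fruit spheres,
    branch cylinders and the trunk."""
    fruit_clearance = config.leaf_disc_radius + config.fruit_radius + _CLEAR
    best = None
    for _ in range(tries):
        origin, d = branches[rng.integers(len(branches))]
        t = rng.uniform(0.1, 1.0) * config.branch_length
        offset = _unit(rng.normal(size=3)) * rng.uniform(0.13, 0.28)
        center = origin + t * d + offset
        trunk_clear = np.hypot(center[0], center[1]) - (
            config.trunk_radius + config.leaf_disc_radius + _CLEAR
        )
        branch_clear = (
            _branch_clearance(center, branches, config)
            - config.leaf_disc_radius - _CLEAR
        )
        fruit_clear = (
            min(np.linalg.norm(center - c) for c in sphere_centers)
            - fruit_clearance
            if sphere_centers
            else np.inf
        )
        score = min(trunk_clear, branch_clear, fruit_clear)
        if score >= 0:
            return center
        if best is None or score > best[0]:
            best = (score, center)
    return best[1]


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    frac = weights / weights.sum() * total
    alloc = np.floor(frac).astype(int)
    remainder = total - alloc.sum()
    order = np.argsort(frac - alloc)[::-1]
    alloc[order[:remainder]] += 1
    return alloc


# -------------------------------------------------------------- spectra


def synth_spectrum(
    label: ComponentLabel,
    edge: bool,
    template: SpectralTemplate,
    rng: np.random.Generator | int,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Draw one reflectance spectrum for a point of the given class.

    Non-edge: base curve plus i.i.d. Gaussian channel noise.  Edge: the
    base curve scaled by 1/(1 + attenuation) and mixed with a
    mean-preserving slowly increasing ramp by the flattening weight, plus
    noise.  Results are clipped at zero.
    """
    if template.label != label:
        raise ValueError(f"template is for {template.label}, not {label}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    wl = grid.wavelengths
    base = np.asarray(template.base(wl), dtype=float)
    if edge:
        scaled = base / (1.0 + template.edge_attenuation)
        m = scaled.mean()
        t = (wl - wl[0]) / (wl[-1] - wl[0])
        ramp = m * (0.7 + 0.6 * t)  # mean over the grid is exactly m
        curve = (1.0 - template.edge_flattening) * scaled \
            + template.edge_flattening * ramp
    else:
        curve = base
    if template.noise_sd > 0:
        curve = curve + rng.normal(0.0, template.noise_sd, size=wl.shape)
    return np.maximum(curve, 0.0)


def generate_scene(
    config: SceneConfig,
    templates: Mapping[ComponentLabel, SpectralTemplate] | None = None,
    as_intensity: bool = False,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> SyntheticScene:
    """Generate a complete labeled spectral tree scene.

    Deterministic for a fixed ``config.seed``.  With ``as_intensity`` the
    reflectance spectra are multiplied by a synthetic panel response (see
    :func:`synthetic_panel`) to produce uncalibrated echo intensities, so
    the calibration stage can be exercised end to end.
    """
    if templates is None:
        templates = default_templates(
            noise_sd=config.noise_sd,
            edge_attenuation=config.edge_attenuation,
            edge_flattening=config.edge_flattening,
        )
    coords, labels, edge = sample_component_geometry(config)
    rng = np.random.default_rng(config.seed + 1)  # spectral stream
    spectra = np.empty((len(coords), grid.n_channels))
    for i in range(len(coords)):
        spectra[i] = synth_spectrum(
            ComponentLabel(labels[i]), bool(edge[i]),
            templates[ComponentLabel(labels[i])], rng, grid,
        )
    kind = "reflectance"
    if as_intensity:
        panel = synthetic_panel(grid)
        spectra = spectra * panel.peak_voltages / panel.reflectance
        kind = "intensity"
    cloud = SpectralPointCloud(
        coords=coords, spectra=spectra, spectra_kind=kind,
        labels=labels, grid=grid,
    )
    return SyntheticScene(cloud=cloud, edge_flags=edge)


def synthetic_panel(grid: WavelengthGrid = DEFAULT_GRID) -> ReferencePanel:
    """A plausible white-reference response: smooth, peaked mid-spectrum.

    Synthetic stand-in for a whiteboard scan (no instrument data ships
    with the package); used to turn reflectance scenes into intensity
    scenes and back.
    """
    wl = grid.wavelengths
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    vb = 0.6 + 0.8 * np.exp(-((t - 0.45) ** 2) / 0.18)
    return ReferencePanel(peak_voltages=vb, reflectance=0.99, grid=grid)
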