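"""Seeded generator of synthetic lacunar-canalicular network scenes.

Produces confocal-style 2D grayscale images of bright elliptical osteocyte
somas connected by thin (1.5-3 px) curved dendrites, together with the exact
3-class label mask and the planted graph that generated them.  The generator
is the ground-truth source for every downstream test: segmentation quality is
scored against the planted mask, and graph extraction against the planted
topology.

Scenes are constructed so that the planted topology is recoverable exactly
from the noise-free mask: somas keep a clearance that survives the 4x4
merging dilation of the connectomics stage without fusing, and dendrites keep
a clearance from each other and from non-endpoint somas that survives the 2x2
dendrite dilation without spurious merges or contacts.

An "aged" phenotype regime is derived from any base configuration by
``degrade_to_aged``: fewer osteocytes, fewer and shorter connections, and more
dead-end stubs per cell, scaling monotonically with a severity in [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .graph import DeadEnd, LcnEdge, LcnGraph, LcnNode

__all__ = [
    "SceneConfig",
    "GroundTruthScene",
    "CapacityError",
    "generate_scene",
    "degrade_to_aged",
    "apply_noise",
]


class CapacityError(RuntimeError):
    """Raised when somas cannot be placed at the requested density."""


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic scene.

    Intensities are 8-bit levels; geometric quantities are pixels.  The
    defaults emulate a confocal field of phalloidin-stained cortical bone:
    seven somas per field (the labelled average in this kind of scan), dim
    background, somas brighter than dendrites, additive Gaussian noise and a
    linear illumination fall-off across the field.
    """

    image_height: int = 256
    image_width: int = 256
    n_osteocytes: int = 7
    osteocyte_axes_range: tuple[float, float] = (5.0, 10.0)  # semi-axes, px
    connection_probability: float = 0.9
    connection_radius_px: float = 140.0
    connection_length_scale_px: float = 110.0  # distance decay of pairing odds
    dead_end_rate: float = 1.5  # expected stubs per soma
    dendrite_width_range: tuple[float, float] = (1.5, 3.0)
    dendrite_waviness: float = 0.2
    stub_length_range: tuple[float, float] = (8.0, 25.0)
    soma_intensity: float = 210.0
    dendrite_intensity: float = 190.0
    background_intensity: float = 20.0
    noise_sd: float = 8.0
    illumination_gradient: float = 0.15
    um_per_px: float = 0.284
    seed: int = 0

    def validate(self) -> None:
        if self.n_osteocytes < 0:
            raise ValueError("n_osteocytes must be >= 0")
        for name in ("soma_intensity", "dendrite_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.dendrite_width_range[0] < 1.0:
            raise ValueError("dendrite width minimum must be >= 1 px")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not 0 <= self.connection_probability <= 1:
            raise ValueError("connection_probability must be in [0, 1]")


@dataclass
class GroundTruthScene:
    image: np.ndarray  # uint8 (H, W)
    mask: np.ndarray  # uint8 (H, W), values {0 bg, 1 osteocyte, 2 dendrite}
    graph: LcnGraph  # planted topology
    config: SceneConfig


# severity-1 scalings of the aged phenotype (documented defaults):
# somas halved, connection probability halved, pairing length scale to 65%
# and stub lengths to 60% (canalicular truncation), dead-end rate doubled.
_AGED_N_OSTEO = 0.5
_AGED_CONN_PROB = 0.5
_AGED_LENGTH_SCALE = 0.35
_AGED_STUB_LENGTH = 0.4
_AGED_DEAD_END = 1.0


def degrade_to_aged(config: SceneConfig, severity: float) -> SceneConfig:
    """Scale a configuration toward the aged-bone regime.

    severity 0 returns the configuration unchanged; severity 1 applies the
    full documented scalings.  All changes are monotone in severity.
    """
    if not 0 <= severity <= 1:
        raise ValueError("severity must be in [0, 1]")
    return dataclasses.replace(
        config,
        n_osteocytes=int(round(config.n_osteocytes * (1 - _AGED_N_OSTEO * severity))),
        connection_probability=config.connection_probability * (1 - _AGED_CONN_PROB * severity),
        connection_length_scale_px=config.connection_length_scale_px
        * (1 - _AGED_LENGTH_SCALE * severity),
        stub_length_range=tuple(
            v * (1 - _AGED_STUB_LENGTH * severity) for v in config.stub_length_range
        ),
        dead_end_rate=config.dead_end_rate * (1 + _AGED_DEAD_END * severity),
    )


def apply_noise(
    image: np.ndarray, noise_sd: float, illumination_gradient: float, seed: int
) -> np.ndarray:
    """Additive Gaussian noise plus a multiplicative linear illumination ramp.

    The ramp scales intensity from 1.0 at the left edge of the field to
    ``1 - illumination_gradient`` at the right edge, so the expected
    left/right column-mean ratio is ``1 / (1 - illumination_gradient)``.
    With ``noise_sd == 0`` and gradient 0 the input is returned unchanged.
    Output is clipped to [0, 255] and returned in the input dtype.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0 and illumination_gradient == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    out = image.astype(np.float64)
    ramp = 1.0 - illumination_gradient * np.linspace(0.0, 1.0, image.shape[1])
    out = out * ramp[None, :]
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=image.shape)
    out = np.clip(out, 0.0, 255.0)
    if np.issubdtype(image.dtype, np.integer):
        return np.round(out).astype(image.dtype)
    return out.astype(image.dtype)


# ---------------------------------------------------------------------------
# geometry helpers

# clearance budgets (px).  The connectomics stage dilates somas by a 4x4
# ellipsoid (growth <= 2 px) and dendrites by a 2x2 square (growth <= 1 px);
# margins below keep distinct structures non-adjacent after those dilations.
_SOMA_GAP = 7.0  # min raw gap between soma boundaries
_DEND_SOMA_MARGIN = 6.0  # path centreline to foreign soma boundary, + half width
_DEND_DEND_MARGIN = 4.0  # path centreline to existing dendrite pixels, + half width
_INSET = 2.0  # how far a dendrite endpoint sits inside its soma
_MIN_PAIR_GAP = 12.0  # min boundary gap for a candidate connection


@dataclass
class _Soma:
    id: int
    center: np.ndarray  # (row, col)
    axes: tuple[float, float]  # (a, b) semi-axes
    theta: float  # rotation, radians


def _ellipse_frame(points: np.ndarray, soma: _Soma) -> np.ndarray:
    d = points - soma.center[None, :]
    c, s = np.cos(soma.theta), np.sin(soma.theta)
    # rows are (row, col); rotate into the ellipse frame
    u = d[:, 0] * c + d[:, 1] * s
    v = -d[:, 0] * s + d[:, 1] * c
    return np.stack([u, v], axis=1)

def _inside_ellipse(points: np.ndarray, soma: _Soma, shrink: float = 0.0) -> np.ndarray:
    a, b = soma.axes[0] - shrink, soma.axes[1] - shrink
    if a <= 0 or b <= 0:
        return np.zeros(len(points), dtype=bool)
    f = _ellipse_frame(points, soma)
    return (f[:, 0] / a) ** 2 + (f[:, 1] / b) ** 2 <= 1.0


def _ellipse_distance_lb(points: np.ndarray, soma: _Soma) -> np.ndarray:
    """Conservative lower bound on distance from points to an ellipse."""
    f = _ellipse_frame(points, soma)
    a, b = soma.axes
    q = np.sqrt((f[:, 0] / a) ** 2 + (f[:, 1] / b) ** 2)
    return np.maximum(q - 1.0, 0.0) * min(a, b)


def _boundary_point(soma: _Soma, direction: np.ndarray, inset: float) -> np.ndarray:
    """Point on the ray from the soma centre, ``inset`` px inside its boundary."""
    d = direction / (np.linalg.norm(direction) + 1e-12)
    c, s = np.cos(soma.theta), np.sin(soma.theta)
    u = d[0] * c + d[1] * s
    v = -d[0] * s + d[1] * c
    a, b = soma.axes
    r = 1.0 / np.sqrt((u / a) ** 2 + (v / b) ** 2 + 1e-12)
    return soma.center + d * max(r - inset, 0.5)


def _bezier(p0: np.ndarray, p1: np.ndarray, ctrl: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0[None, :] + 2 * t * (1 - t) * ctrl[None, :] + t**2 * p1[None, :]


def _polyline_length(points: np.ndarray, keep: np.ndarray | None = None) -> float:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if keep is not None:
        both = keep[:-1] & keep[1:]
        seg = seg[both]
    return float(seg.sum())


def _paint_path(mask: np.ndarray, points: np.ndarray, width: float) -> np.ndarray:
    """Rasterise a centreline of the given width; returns painted pixel mask."""
    painted = np.zeros_like(mask, dtype=bool)
    r = max(width / 2.0, 0.6)
    for p in points:
        rr, cc = draw_disk((p[0], p[1]), r, shape=mask.shape)
        painted[rr, cc] = True
    mask |= painted
    return painted


class _PathValidator:
    """Clearance checks for candidate dendrite centrelines."""

    def __init__(self, somas: list[_Soma], shape: tuple[int, int]):
        self.somas = somas
        self.shape = shape
        self._dend_edt = np.full(shape, np.inf)

    def update_dendrites(self, dend_mask: np.ndarray) -> None:
        if dend_mask.any():
            self._dend_edt = ndi.distance_transform_edt(~dend_mask)
        else:
            self._dend_edt = np.full(self.shape, np.inf)

    def ok(self, points: np.ndarray, width: float, exempt: set[int]) -> bool:
        # points outside exempt somas must clear foreign somas and old dendrites
        free = np.ones(len(points), dtype=bool)
        for sid in exempt:
            free &= ~_inside_ellipse(points, self.somas[sid])
        pts = points[free]
        if len(pts) == 0:
            return False
        for soma in self.somas:
            if soma.id in exempt:
                continue
            if np.any(_ellipse_distance_lb(pts, soma) < width / 2 + _DEND_SOMA_MARGIN):
                return False
        ij = np.clip(np.round(pts).astype(int), 0, np.array(self.shape) - 1)
        if np.any(self._dend_edt[ij[:, 0], ij[:, 1]] < width / 2 + _DEND_DEND_MARGIN):
            return False
        return True


def _place_somas(cfg: SceneConfig, rng: np.random.Generator) -> list[_Soma]:
    H, W = cfg.image_height, cfg.image_width
    occupied = np.zeros((H, W), dtype=bool)
    gap_disk = _disk_footprint(_SOMA_GAP)
    somas: list[_Soma] = []
    for i in range(cfg.n_osteocytes):
        for _attempt in range(1000):
            a = rng.uniform(*cfg.osteocyte_axes_range)
            b = rng.uniform(cfg.osteocyte_axes_range[0], a)
            theta = rng.uniform(0, np.pi)
            margin = a + 2
            if H - 2 * margin <= 1 or W - 2 * margin <= 1:
                raise CapacityError("image too small for requested soma size")
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(H, W), rotation=theta)
            if occupied[rr, cc].any():
                continue
            somas.append(_Soma(id=i, center=np.array([cy, cx]), axes=(a, b), theta=theta))
            stamp = np.zeros((H, W), dtype=bool)
            stamp[rr, cc] = True
            occupied |= ndi.binary_dilation(stamp, structure=gap_disk)
            break
        else:
            raise CapacityError(
                f"could not place soma {i + 1}/{cfg.n_osteocytes} after 1000 retries"
            )
    return somas


def _disk_footprint(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (y**2 + x**2) <= radius**2


def generate_scene(config: SceneConfig) -> GroundTruthScene:
    """Render a scene with exact ground truth.

    Identical configurations (including ``config.seed``) produce byte-identical
    scenes.  Raises :class:`CapacityError` when ``n_osteocytes`` cannot be
    placed at the requested density within bounded retries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, W = config.image_height, config.image_width

    somas = _place_somas(config, rng)

    soma_mask = np.zeros((H, W), dtype=bool)
    soma_label = np.zeros((H, W), dtype=np.int32)
    nodes: list[LcnNode] = []
    for soma in somas:
        rr, cc = draw_ellipse(*soma.center, *soma.axes, shape=(H, W), rotation=soma.theta)
        soma_mask[rr, cc] = True
        soma_label[rr, cc] = soma.id + 1
        nodes.append(LcnNode(id=soma.id, centroid=(float(soma.center[0]), float(soma.center[1])),
                             area=float(len(rr))))

    validator = _PathValidator(somas, (H, W))
    dend_mask = np.zeros((H, W), dtype=bool)
    edges: list[LcnEdge] = []
    dead_ends: list[DeadEnd] = []
    component_id = 0

    def try_path(p0, p1, ctrl_base, length, width, exempt, record_inside):
        """Rasterise a Bezier if clearances hold; returns (points, keep) or None."""
        nonlocal dend_mask
        n = max(int(np.ceil(length * 2.5)), 8)
        for trial in range(6):
            amp = config.dendrite_waviness * length * rng.uniform(-1, 1)
            if trial == 5:
                amp = 0.0
            d = p1 - p0
            nvec = np.array([-d[1], d[0]])
            nvec = nvec / (np.linalg.norm(nvec) + 1e-12)
            ctrl = ctrl_base + nvec * amp
            pts = _bezier(p0, p1, ctrl, n)
            inside = np.any([_inside_ellipse(pts, somas[s]) for s in record_inside], axis=0) \
                if record_inside else np.zeros(n, dtype=bool)
            if not validator.ok(pts, width, exempt):
                continue
            probe = np.zeros((H, W), dtype=bool)
            painted = _paint_path(probe, pts, width)
            outside = painted & ~soma_mask
            if not outside.any():
                continue
            n_comp = ndi.label(outside, structure=np.ones((3, 3)))[1]
            if n_comp != 1:
                continue  # path dipped through a soma mid-way; resample
            dend_mask |= painted
            validator.update_dendrites(dend_mask & ~soma_mask)
            return pts, ~inside
        return None

    # --- edges between soma pairs ---------------------------------------
    n = len(somas)
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.linalg.norm(somas[i].center - somas[j].center))
            if dist > config.connection_radius_px:
                continue
            gap = dist - max(somas[i].axes) - max(somas[j].axes)
            if gap < _MIN_PAIR_GAP:
                continue
            # pairing odds decay with centroid distance; the length scale is
            # the "mean connection length" dial of the phenotype regimes
            p_pair = config.connection_probability * np.exp(
                -dist / config.connection_length_scale_px
            )
            if rng.uniform() >= p_pair:
                continue
            width = rng.uniform(*config.dendrite_width_range)
            u = somas[j].center - somas[i].center
            p0 = _boundary_point(somas[i], u, _INSET)
            p1 = _boundary_point(somas[j], -u, _INSET)
            res = try_path(p0, p1, (p0 + p1) / 2, np.linalg.norm(p1 - p0), width,
                           exempt={i, j}, record_inside=[i, j])
            if res is None:
                continue  # could not route without violating clearances
            pts, keep = res
            arc = _polyline_length(pts, keep)
            edges.append(LcnEdge(node_a=i, node_b=j, component_id=component_id,
                                 length_um=arc * config.um_per_px,
                                 thickness_um=width * config.um_per_px, path=pts))
            component_id += 1

    # --- dead-end stubs --------------------------------------------------
    for soma in somas:
        for _ in range(rng.poisson(config.dead_end_rate)):
            width = rng.uniform(*config.dendrite_width_range)
            placed = False
            for _attempt in range(20):
                phi = rng.uniform(0, 2 * np.pi)
                direction = np.array([np.sin(phi), np.cos(phi)])
                length = rng.uniform(*config.stub_length_range)
                p0 = _boundary_point(soma, direction, _INSET)
                p1 = p0 + direction * length
                if not (0 <= p1[0] < H and 0 <= p1[1] < W):
                    continue
                res = try_path(p0, p1, (p0 + p1) / 2, length, width,
                               exempt={soma.id}, record_inside=[soma.id])
                if res is not None:
                    pts, keep = res
                    dead_ends.append(DeadEnd(node_id=soma.id, component_id=component_id,
                                             length_um=_polyline_length(pts, keep)
                                             * config.um_per_px))
                    placed = True
                    break
            if not placed:
                continue  # stub dropped; planted record stays consistent
            component_id += 1

    # --- compose mask and image ------------------------------------------
    mask = np.zeros((H, W), dtype=np.uint8)
    mask[dend_mask & ~soma_mask] = 2
    mask[soma_mask] = 1

    image = np.full((H, W), config.background_intensity, dtype=np.float64)
    image[dend_mask] = config.dendrite_intensity
    image[soma_mask] = config.soma_intensity
    image = ndi.gaussian_filter(image, sigma=0.5)  # soften hard raster edges
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    image = apply_noise(image, config.noise_sd, config.illumination_gradient,
                        seed=int(rng.integers(2**31)))

    graph = LcnGraph(nodes=nodes, edges=edges, dead_ends=dead_ends)
    graph.validate()
    return GroundTruthScene(image=image, mask=mask, graph=graph, config=config)
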