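"""Synthetic ground truth: random neuron trees rendered into noisy stacks.

The generator emulates a singly-stained neuron imaged by confocal microscopy:
a randomly grown binary-branching tree with tapering radii is rasterized as a
chain of capsules into an anisotropic voxel grid (default 0.36 μm pixels,
1 μm sections), optionally blurred, and corrupted by additive Gaussian
background noise at a configurable signal-to-noise ratio.  The hard case of
two arbors of one neuron ramifying through the same region — with an oracle
mask standing in for a manual trace of one arbor — is generated by
:func:`overlapping_pair`.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .morpho import NeuronNode, NeuronTree
from .stack import BinaryMask, ImageStack

__all__ = [
    "SynthParams",
    "random_tree",
    "overlapping_pair",
    "render",
    "mask_from_tree",
    "arbor_subtree",
]


@dataclass
class SynthParams:
    """Generation parameters.

    n_branch_events: number of binary branch points grown (terminals = events + 1).
    segment_length_range: (min, max) μm length of a straight run between events.
    branch_angle_range: (min, max) degrees between daughter directions.
    radius_root: root neurite radius, μm.
    radius_taper: per-generation multiplicative radius factor.
    radius_min: lower clamp on radii so distal neurites stay resolvable, μm.
    spacing: (z, y, x) voxel size, μm.
    shape: (z, y, x) voxel grid of the rendered stack.
    signal_level: mean foreground intensity above background.
    background_level: constant background offset.
    snr: signal_level / noise sigma; ``math.inf`` disables noise.
    psf_blur: lateral Gaussian blur sigma in μm applied before noise (0 = off).
    seed: RNG seed; fixed seed ⇒ bitwise-identical trees and stacks.
    """

    n_branch_events: int = 8
    segment_length_range: tuple[float, float] = (8.0, 18.0)
    branch_angle_range: tuple[float, float] = (40.0, 80.0)
    radius_root: float = 1.4
    radius_taper: float = 0.88
    radius_min: float = 0.8
    spacing: tuple[float, float, float] = (1.0, 0.36, 0.36)
    shape: tuple[int, int, int] = (64, 256, 256)
    signal_level: float = 200.0
    background_level: float = 20.0
    snr: float = 10.0
    psf_blur: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if min(self.segment_length_range) <= 0 or min(self.branch_angle_range) <= 0:
            raise ValueError("length and angle ranges must be positive")

    @property
    def extent(self) -> np.ndarray:
        """Physical (x, y, z) size of the volume, μm."""
        return (np.asarray(self.shape) * np.asarray(self.spacing))[::-1]


# ---------------------------------------------------------------------------
# Tree growth


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _jitter(direction: np.ndarray, rng, degrees: float) -> np.ndarray:
    axis = _unit(rng.normal(size=3))
    angle = math.radians(degrees)
    return _unit(
        direction * math.cos(angle)
        + np.cross(axis, direction) * math.sin(angle)
        + axis * np.dot(axis, direction) * (1 - math.cos(angle))
    )


def _clamp_direction(p: np.ndarray, d: np.ndarray, extent: np.ndarray, margin: float) -> np.ndarray:
    """Reflect direction components that would push the tip out of bounds."""
    d = d.copy()
    for a in range(3):
        if (p[a] < margin and d[a] < 0) or (p[a] > extent[a] - margin and d[a] > 0):
            d[a] = -d[a]
    return _unit(d)


class _Grower:
    """Incremental tree builder with densely resampled straight runs."""

    def __init__(self, params: SynthParams):
        self.params = params
        self.step = min(params.spacing)  # ≤ 1 voxel between consecutive nodes
        self.nodes: list[NeuronNode] = []
        self.margin = 2.0 * params.radius_root + 1.0

    def add_root(self, pos: np.ndarray, radius: float) -> int:
        nid = len(self.nodes) + 1
        self.nodes.append(NeuronNode(nid, 0, tuple(pos), radius, -1))
        return nid

    def grow_run(self, from_id: int, direction: np.ndarray, length: float, radius: float) -> int:
        """Straight (slightly bent at bounds) run of `length` μm; returns tip id."""
        p = np.asarray(self.nodes[from_id - 1].position, dtype=float)
        d = _unit(direction)
        nid = from_id
        n_steps = max(int(round(length / self.step)), 1)
        for _ in range(n_steps):
            d = _clamp_direction(p, d, self.params.extent, self.margin)
            p = p + d * self.step
            new_id = len(self.nodes) + 1
            self.nodes.append(NeuronNode(new_id, 0, tuple(p), radius, nid))
            nid = new_id
        return nid

    def tree(self) -> NeuronTree:
        return NeuronTree(self.nodes)


def _grow_arbor(
    grower: _Grower,
    rng,
    root_id: int,
    direction: np.ndarray,
    n_events: int,
    radius: float,
    center_bias: np.ndarray | None = None,
) -> None:
    """Binary-branching growth producing exactly n_events branch points."""
    p = grower.params
    lo, hi = p.segment_length_range
    a_lo, a_hi = p.branch_angle_range
    tips: list[tuple[int, np.ndarray, float]] = [(root_id, _unit(direction), radius)]
    for _ in range(n_events):
        # split the tip with the thickest radius (ties: oldest) — keeps the
        # arbor balanced the way real dendritic trees branch mostly proximally
        i = max(range(len(tips)), key=lambda k: (tips[k][2], -k))
        nid, d, r = tips.pop(i)
        tip = grower.grow_run(nid, d, rng.uniform(lo, hi), r)
        angle = rng.uniform(a_lo, a_hi)
        child_r = max(r * p.radius_taper, p.radius_min)
        axis = _unit(np.cross(d, rng.normal(size=3)))
        for sign in (+1, -1):
            rot = math.radians(sign * angle / 2.0)
            child_d = _unit(d * math.cos(rot) + np.cross(axis, d) * math.sin(rot))
            if center_bias is not None:
                tip_pos = np.asarray(grower.nodes[tip - 1].position)
                child_d = _unit(child_d + 0.25 * _unit(center_bias - tip_pos))
            child_d = _jitter(child_d, rng, rng.uniform(0, 8))
            tips.append((tip, child_d, child_r))
    for nid, d, r in tips:
        grower.grow_run(nid, d, rng.uniform(lo, hi), r)


def random_tree(params: SynthParams) -> NeuronTree:
    """A single randomly grown arbor centred in the volume.

    ``n_branch_events`` binary branch points ⇒ exactly ``n_branch_events + 1``
    terminals; consecutive nodes at most one (minimum-spacing) voxel apart.
    """
    rng = np.random.default_rng(params.seed)
    g = _Grower(params)
    extent = params.extent
    start = np.array([extent[0] * 0.5, extent[1] * 0.5, extent[2] * 0.5])
    direction = _unit(np.array([rng.normal(), rng.normal(), 0.3 * rng.normal()]))
    root = g.add_root(start, params.radius_root)
    _grow_arbor(g, rng, root, direction, params.n_branch_events, params.radius_root)
    t = g.tree()
    t.metadata["generator"] = "random_tree"
    t.metadata["seed"] = str(params.seed)
    return t


def overlapping_pair(params: SynthParams) -> tuple[NeuronTree, NeuronTree, NeuronTree]:
    """Two sibling arbors sharing a primary neurite and ramifying in one region.

    Returns ``(treeA, treeB, combined)``: each arbor tree contains the shared
    primary neurite up to the bifurcation point plus its own distal arbor; the
    combined tree is their union under the common root.  The distal bounding
    boxes overlap by at least half because both arbors are grown with a bias
    toward the same target region.  The bifurcation node id is recorded in
    each tree's metadata under ``bifurcation_id``.
    """
    rng = np.random.default_rng(params.seed)
    extent = params.extent

    def build(which: str) -> tuple[_Grower, int]:
        g = _Grower(params)
        start = np.array([extent[0] * 0.5, extent[1] * 0.15, extent[2] * 0.5])
        root = g.add_root(start, params.radius_root)
        n1 = g.grow_run(root, np.array([0.0, 1.0, 0.0]), extent[1] * 0.18, params.radius_root)
        rng_a = np.random.default_rng([params.seed, 101])
        rng_b = np.random.default_rng([params.seed, 202])
        target = np.array([extent[0] * 0.5, extent[1] * 0.62, extent[2] * 0.5])
        r_child = max(params.radius_root * params.radius_taper, params.radius_min)
        if which in ("A", "both"):
            _grow_arbor(
                g, rng_a, n1, _unit(np.array([0.35, 1.0, 0.10])),
                params.n_branch_events, r_child, center_bias=target,
            )
        if which in ("B", "both"):
            _grow_arbor(
                g, rng_b, n1, _unit(np.array([-0.35, 1.0, -0.10])),
                params.n_branch_events, r_child, center_bias=target,
            )
        return g, n1

    ga, n1 = build("A")
    gb, _ = build("B")
    gc, _ = build("both")
    tree_a, tree_b, combined = ga.tree(), gb.tree(), gc.tree()
    for t in (tree_a, tree_b, combined):
        t.metadata["generator"] = "overlapping_pair"
        t.metadata["seed"] = str(params.seed)
        t.metadata["bifurcation_id"] = str(n1)
    return tree_a, tree_b, combined


def arbor_subtree(tree: NeuronTree, from_id: int) -> NeuronTree:
    """The subtree rooted at ``from_id`` (that node becomes the new root)."""
    cm = tree.child_map()
    keep = []
    stack = [from_id]
    while stack:
        nid = stack.pop()
        keep.append(nid)
        stack.extend(reversed(cm[nid]))
    keep_set = set(keep)
    nodes = [
        replace(tree.node(nid), parent_id=-1 if nid == from_id else tree.node(nid).parent_id)
        for nid in keep
    ]
    assert all(n.parent_id == -1 or n.parent_id in keep_set for n in nodes)
    return NeuronTree(nodes)


# ---------------------------------------------------------------------------
# Rendering


def _rasterize(
    tree: NeuronTree,
    shape: tuple[int, int, int],
    spacing,
    extra_radius: float = 0.0,
) -> np.ndarray:
    """Boolean capsule rasterization of all parent→child edges."""
    sp = np.asarray(spacing, dtype=float)
    vol = np.zeros(shape, dtype=bool)
    by_id = {n.id: n for n in tree.nodes}
    extent = (np.asarray(shape) * sp)[::-1]
    for n in tree.nodes:
        r = n.radius + extra_radius
        pos = np.asarray(n.position)
        if np.any(pos < -r) or np.any(pos > extent + r):
            raise ValueError(f"node {n.id} at {n.position} exceeds the render volume")
        segs = []
        if n.parent_id == -1:
            segs.append((pos, pos, r))
        else:
            p = by_id[n.parent_id]
            segs.append((np.asarray(p.position), pos, 0.5 * (p.radius + n.radius) + extra_radius))
        for a_xyz, b_xyz, rad in segs:
            a = a_xyz[::-1] / sp  # (z, y, x) index coords
            b = b_xyz[::-1] / sp
            r_idx = rad / sp
            lo = np.floor(np.minimum(a, b) - r_idx - 1).astype(int)
            hi = np.ceil(np.maximum(a, b) + r_idx + 1).astype(int)
            lo = np.maximum(lo, 0)
            hi = np.minimum(hi, np.asarray(shape) - 1)
            if np.any(hi < lo):
                continue
            zz, yy, xx = np.meshgrid(
                *(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij"
            )
            pts = np.stack([zz, yy, xx], axis=-1).astype(float) * sp  # physical (z,y,x)
            av, bv = a * sp, b * sp
            ab = bv - av
            denom = float(np.dot(ab, ab))
            if denom < 1e-18:
                d2 = np.sum((pts - av) ** 2, axis=-1)
            else:
                tpar = np.clip(np.einsum("...k,k->...", pts - av, ab) / denom, 0.0, 1.0)
                proj = av + tpar[..., None] * ab
                d2 = np.sum((pts - proj) ** 2, axis=-1)
            hit = d2 <= rad * rad
            vol[zz[hit], yy[hit], xx[hit]] = True
    return vol


def render(tree: NeuronTree, params: SynthParams) -> ImageStack:
    """Rasterize a tree into a noisy anisotropic stack.

    Foreground capsules at ``signal_level`` over ``background_level``, optional
    Gaussian blur, additive Gaussian noise with sigma ``signal_level / snr``.
    """
    support = _rasterize(tree, params.shape, params.spacing)
    img = params.background_level + params.signal_level * support.astype(float)
    if params.psf_blur > 0:
        sigma_vox = params.psf_blur / np.asarray(params.spacing)
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if math.isfinite(params.snr):
        rng = np.random.default_rng([params.seed, 77])
        img = img + rng.normal(0.0, params.signal_level / params.snr, size=img.shape)
    return ImageStack(np.clip(img, 0.0, None), spacing=params.spacing)


def mask_from_tree(tree: NeuronTree, dilation_radius: float, params: SynthParams) -> BinaryMask:
    """Oracle mask: the tree's capsule support dilated by ``dilation_radius`` μm.

    Stands in for the manual partial-arbor trace that selects one arbor for
    AND extraction.
    """
    vol = _rasterize(tree, params.shape, params.spacing, extra_radius=dilation_radius)
    return BinaryMask(vol, spacing=params.spacing)
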