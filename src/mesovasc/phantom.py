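"""Synthetic skin/vessel phantoms with known ground truth.

The generator emulates what a raster-scan optoacoustic mesoscopy scan of the
distal leg delivers: a thin epidermal/SVP band above a thicker dermal band, a
tubular branching vessel network per layer, and a two-band (HF/LF) intensity
rendering with additive noise.  Every phantom carries its exact ground truth
— layer label volume, per-layer vessel masks, and the planted vessel tree
with known junction/endpoint/branch counts — so each downstream stage of the
pipeline can be validated against construction rather than annotation.

Networks are built from three motif primitives placed with a minimum
clearance between structures:

* a straight segment   (2 endpoints, 1 e2e branch),
* a "Y"                (1 junction, 3 endpoints, 3 j2e branches),
* an "H"               (2 junctions, 4 endpoints, 1 j2j and 4 j2e branches).

Arrays are indexed ``[z, y, x]`` (z = depth); geometry lives in micrometres
with explicit voxel spacing, voxel centres at ``index * spacing``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .preprocess import Volume3D
from .taxonomy import all_feature_keys, split_key, stage_trend_directions

BACKGROUND, EPI_SVP, DERMAL = 0, 1, 2
LAYER_LABELS = {"epi_svp": EPI_SVP, "dermal": DERMAL}

#: radius (um) at which the HF band weight falls to 1/e; small vessels emit
#: predominantly high frequencies.
HF_DECAY_UM = 50.0


# ---------------------------------------------------------------------------
# phantom geometry spec


@dataclass(frozen=True)
class PhantomSpec:
    """Field geometry of one synthetic scan.

    Defaults reproduce the scanned field: 4 x 2 mm laterally, ~2 mm deep,
    at 15 um (x), 7.5 um (y) steps and 4 um depth sampling.
    """

    field_of_view_mm: tuple[float, float, float] = (4.0, 2.0, 2.0)  # (x, y, z)
    voxel_spacing_um: tuple[float, float, float] = (4.0, 7.5, 15.0)  # (z, y, x)
    epidermis_band_um: tuple[float, float] = (100.0, 300.0)
    dermis_band_um: tuple[float, float] = (300.0, 1500.0)
    undulation_amplitude_um: float = 0.0
    undulation_period_um: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacing must be positive")
        e0, e1 = self.epidermis_band_um
        d0, d1 = self.dermis_band_um
        if not (0 <= e0 < e1 <= d0 < d1):
            raise ValueError(
                "bands must be disjoint, contiguous-or-below, and ordered "
                "epidermis above dermis")
        if d1 + self.undulation_amplitude_um > self.field_of_view_mm[2] * 1000.0:
            raise ValueError("bands exceed the imaged depth range")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Voxel grid shape (nz, ny, nx)."""
        fx, fy, fz = (v * 1000.0 for v in self.field_of_view_mm)
        dz, dy, dx = self.voxel_spacing_um
        return (int(round(fz / dz)), int(round(fy / dy)), int(round(fx / dx)))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in um."""
        fx, fy, fz = (v * 1000.0 for v in self.field_of_view_mm)
        return (fz, fy, fx)


def boundary_depth_um(spec: PhantomSpec, x_um: np.ndarray) -> np.ndarray:
    """Depth offset of the undulating interfaces at lateral position x (um)."""
    if spec.undulation_amplitude_um == 0:
        return np.zeros_like(np.asarray(x_um, dtype=float))
    return spec.undulation_amplitude_um * np.sin(
        2.0 * math.pi * np.asarray(x_um, dtype=float) / spec.undulation_period_um)


def make_layer_volume(spec: PhantomSpec) -> np.ndarray:
    """Label volume with values {0 background, 1 epidermal/SVP, 2 dermal}.

    Both band interfaces ride the same sinusoidal undulation along x, so band
    thicknesses are preserved column by column.
    """
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.voxel_spacing_um
    x_um = np.arange(nx) * dx
    offset = boundary_depth_um(spec, x_um)  # (nx,)

    z_um = np.arange(nz) * dz
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    e0, e1 = spec.epidermis_band_um
    d0, d1 = spec.dermis_band_um
    # half-open intervals [top, bottom) on voxel-centre depths
    zcol = z_um[:, None] - offset[None, :]          # (nz, nx)
    epi = (zcol >= e0 - dz / 2) & (zcol < e1 - dz / 2)
    derm = (zcol >= d0 - dz / 2) & (zcol < d1 - dz / 2)
    labels[:, :, :] = np.where(epi, EPI_SVP, np.where(derm, DERMAL, BACKGROUND)
                               )[:, None, :]
    return labels


# ---------------------------------------------------------------------------
# vessel trees


@dataclass
class TreeNode:
    position_um: np.ndarray          # (z, y, x)
    kind: str                        # "junction" | "endpoint"


@dataclass
class TreeSegment:
    """One branch: a polyline between two nodes with a constant radius."""

    node_a: int
    node_b: int
    points_um: np.ndarray            # (n, 3) polyline incl. both node points
    radius_um: float
    layer: str                       # "epi_svp" | "dermal"


@dataclass
class VesselTree:
    nodes: list[TreeNode] = field(default_factory=list)
    segments: list[TreeSegment] = field(default_factory=list)

    def validate(self) -> None:
        deg = self.node_degrees()
        for i, node in enumerate(self.nodes):
            if node.kind == "junction" and deg[i] < 3:
                raise ValueError(f"junction node {i} has degree {deg[i]} < 3")
            if node.kind == "endpoint" and deg[i] != 1:
                raise ValueError(f"endpoint node {i} has degree {deg[i]} != 1")
        for s in self.segments:
            if s.radius_um <= 0:
                raise ValueError("segment radius must be positive")
            for ni, pt in ((s.node_a, s.points_um[0]), (s.node_b, s.points_um[-1])):
                if not np.allclose(pt, self.nodes[ni].position_um):
                    raise ValueError("segment endpoint does not coincide with its node")

    def node_degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for s in self.segments:
            deg[s.node_a] += 1
            deg[s.node_b] += 1
        return deg

    def planted_counts(self, layer: str | None = None) -> dict[str, int]:
        """Exact (vessels, junctions, endpoints, j2j, j2e, e2e) by construction."""
        segs = [s for s in self.segments if layer is None or s.layer == layer]
        node_ids = sorted({s.node_a for s in segs} | {s.node_b for s in segs})
        kinds = {i: self.nodes[i].kind for i in node_ids}
        n_j2j = n_j2e = n_e2e = 0
        for s in segs:
            ka, kb = kinds[s.node_a], kinds[s.node_b]
            n_junc_ends = (ka == "junction") + (kb == "junction")
            if n_junc_ends == 2:
                n_j2j += 1
            elif n_junc_ends == 1:
                n_j2e += 1
            else:
                n_e2e += 1
        # connected components over the induced subgraph
        parent = {i: i for i in node_ids}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for s in segs:
            ra, rb = find(s.node_a), find(s.node_b)
            if ra != rb:
                parent[ra] = rb
        n_components = len({find(i) for i in node_ids})
        return {
            "n_vessels": n_components,
            "n_junctions": sum(k == "junction" for k in kinds.values()),
            "n_endpoints": sum(k == "endpoint" for k in kinds.values()),
            "n_j2j_branches": n_j2j,
            "n_j2e_branches": n_j2e,
            "n_e2e_branches": n_e2e,
        }

    def to_json_dict(self) -> dict:
        return {
            "nodes": [{"position_um": n.position_um.tolist(), "kind": n.kind}
                      for n in self.nodes],
            "segments": [{"node_a": s.node_a, "node_b": s.node_b,
                          "points_um": s.points_um.tolist(),
                          "radius_um": s.radius_um, "layer": s.layer}
                         for s in self.segments],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "VesselTree":
        tree = cls()
        tree.nodes = [TreeNode(np.asarray(n["position_um"], float), n["kind"])
                      for n in d["nodes"]]
        tree.segments = [TreeSegment(s["node_a"], s["node_b"],
                                     np.asarray(s["points_um"], float),
                                     s["radius_um"], s["layer"])
                         for s in d["segments"]]
        return tree


@dataclass(frozen=True)
class LayerVesselParams:
    """Motif budget and size ranges for one layer's network."""

    n_lines: int = 3
    n_y: int = 2
    n_h: int = 1
    radius_um: tuple[float, float] = (20.0, 40.0)
    arm_length_um: tuple[float, float] = (250.0, 450.0)
    clearance_um: float = 60.0
    max_tilt: float = 0.35           # max |dz|/|d| of any arm direction
    planar: bool = False             # confine motifs to the (z, x) plane

    def __post_init__(self) -> None:
        if min(self.n_lines, self.n_y, self.n_h) < 0:
            raise ValueError("motif counts must be >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _arm_dir(rng: np.random.Generator, azimuth: float, max_tilt: float) -> np.ndarray:
    """Unit direction (z, y, x) with bounded depth tilt so motifs stay in-layer."""
    tilt = rng.uniform(-max_tilt, max_tilt)
    horiz = math.sqrt(max(1.0 - tilt * tilt, 0.0))
    return np.array([tilt, horiz * math.sin(azimuth), horiz * math.cos(azimuth)])


def _planar_dir(azimuth: float) -> np.ndarray:
    """Unit direction in the (z, x) plane for planar (2D MIP-like) motifs."""
    return np.array([math.sin(azimuth), 0.0, math.cos(azimuth)])


def _motif_polylines(kind: str, rng: np.random.Generator,
                     params: LayerVesselParams) -> tuple[list, list]:
    """Local motif geometry around the origin.

    Returns (nodes, edges): nodes are (point, kind), edges are
    (i_node, j_node) polylines given as straight two-point paths.
    """
    L = rng.uniform(*params.arm_length_um)
    t = params.max_tilt

    def direction(az: float) -> np.ndarray:
        return _planar_dir(az) if params.planar else _arm_dir(rng, az, t)

    if kind == "line":
        d = direction(rng.uniform(0, 2 * math.pi))
        nodes = [(-0.5 * L * d, "endpoint"), (0.5 * L * d, "endpoint")]
        edges = [(0, 1)]
    elif kind == "y":
        az = rng.uniform(0, 2 * math.pi)
        c = np.zeros(3)
        nodes = [(c, "junction")]
        edges = []
        for k in range(3):
            d = direction(az + k * 2 * math.pi / 3)
            nodes.append((0.6 * L * d, "endpoint"))
            edges.append((0, k + 1))
    elif kind == "h":
        az = rng.uniform(0, 2 * math.pi)
        bar = _planar_dir(az) if params.planar else _arm_dir(rng, az, t * 0.5)
        c1, c2 = -0.5 * L * bar, 0.5 * L * bar
        # perpendicular arms, one up-ish one down-ish at each bar end
        nodes = [(c1, "junction"), (c2, "junction")]
        edges = [(0, 1)]
        arm = 0.6 * L
        perp = None if params.planar else _arm_dir(rng, az + math.pi / 2, t)
        for ci, base in ((0, c1), (1, c2)):
            for sgn in (1.0, -1.0):
                if params.planar:
                    d = _planar_dir(az + sgn * (math.pi / 2
                                                + rng.uniform(-0.15, 0.15)))
                else:
                    d = _unit(sgn * perp + rng.uniform(-0.15, 0.15, size=3))
                    d[0] = np.clip(d[0], -t, t)
                    d = _unit(d)
                nodes.append((base + arm * d, "endpoint"))
                edges.append((ci, len(nodes) - 1))
    else:
        raise ValueError(f"unknown motif kind {kind!r}")
    return nodes, edges


def _sample_polyline(p: np.ndarray, q: np.ndarray, step: float) -> np.ndarray:
    n = max(int(np.ceil(np.linalg.norm(q - p) / step)), 1)
    ts = np.linspace(0.0, 1.0, n + 1)[:, None]
    return p[None, :] + ts * (q - p)[None, :]


def make_vessel_network(spec: PhantomSpec,
                        layer_params: dict[str, LayerVesselParams],
                        seed: int | None = None,
                        max_retries: int = 200) -> VesselTree:
    """Place motif primitives per layer with guaranteed clearance.

    Raises ``RuntimeError`` when the requested density cannot be placed with
    the requested clearance after ``max_retries`` rejection-sampling attempts
    per motif.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    tree = VesselTree()
    ez, ey, ex = spec.extent_um
    occupied_pts: list[np.ndarray] = []
    occupied_r: list[float] = []
    kd: cKDTree | None = None
    max_r = 0.0

    bands = {"epi_svp": spec.epidermis_band_um, "dermal": spec.dermis_band_um}
    for layer, params in layer_params.items():
        z0, z1 = bands[layer]
        motifs = (["line"] * params.n_lines + ["y"] * params.n_y
                  + ["h"] * params.n_h)
        rng.shuffle(motifs)
        for kind in motifs:
            placed = False
            for _ in range(max_retries):
                r = rng.uniform(*params.radius_um)
                local_nodes, local_edges = _motif_polylines(kind, rng, params)
                margin = r + params.clearance_um / 2
                lo = np.array([z0 + margin, margin, margin])
                hi = np.array([z1 - margin, ey - margin, ex - margin])
                if np.any(hi <= lo):
                    continue
                centre = rng.uniform(lo, hi)
                if params.planar:
                    # shared mid-plane so the clearance check is planar too
                    centre[1] = ey / 2.0
                pts = [centre + p for p, _ in local_nodes]
                all_pts = np.array(pts)
                if (np.any(all_pts < lo[None, :] - 1e-9)
                        or np.any(all_pts > hi[None, :] + 1e-9)):
                    continue
                if np.any(all_pts[:, 0] < z0 + margin) or np.any(all_pts[:, 0] > z1 - margin):
                    continue
                samples = np.concatenate([
                    _sample_polyline(pts[i], pts[j], step=max(r, 10.0) / 2)
                    for i, j in local_edges])
                if kd is not None:
                    dmin, _ = kd.query(samples, k=1)
                    # conservative: use the largest existing radius
                    if np.min(dmin) < r + max_r + params.clearance_um:
                        continue
                base = len(tree.nodes)
                for p, k in zip(pts, (k for _, k in local_nodes)):
                    tree.nodes.append(TreeNode(np.asarray(p, float), k))
                for i, j in local_edges:
                    tree.segments.append(TreeSegment(
                        base + i, base + j,
                        np.stack([pts[i], pts[j]]), r, layer))
                occupied_pts.append(samples)
                occupied_r.append(r)
                max_r = max(max_r, r)
                kd = cKDTree(np.concatenate(occupied_pts))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place motif {kind!r} in layer {layer!r} with "
                    f"clearance {params.clearance_um} um after {max_retries} tries; "
                    "requested density is infeasible for this volume")
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# rasterization and rendering


def rasterize_mask(tree: VesselTree, shape: tuple[int, int, int],
                   spacing: tuple[float, float, float],
                   layer: str | None = None) -> np.ndarray:
    """Binary mask: voxels whose centre lies within a segment radius."""
    mask = np.zeros(shape, dtype=bool)
    sp = np.asarray(spacing, dtype=float)
    for seg in tree.segments:
        if layer is not None and seg.layer != layer:
            continue
        for p, q in zip(seg.points_um[:-1], seg.points_um[1:]):
            _rasterize_capsule(mask, p, q, seg.radius_um, sp)
    return mask


def rasterize_mask_2d(tree: VesselTree, shape: tuple[int, int],
                      spacing: tuple[float, float],
                      layer: str | None = None) -> np.ndarray:
    """2D (z, x) rasterization of a planar tree (y coordinates are ignored)."""
    mask = np.zeros(shape, dtype=bool)
    sp = np.asarray(spacing, dtype=float)
    for seg in tree.segments:
        if layer is not None and seg.layer != layer:
            continue
        pts2 = seg.points_um[:, [0, 2]]
        for p, q in zip(pts2[:-1], pts2[1:]):
            _rasterize_capsule(mask, p, q, seg.radius_um, sp)
    return mask


def _rasterize_capsule(mask: np.ndarray, p: np.ndarray, q: np.ndarray,
                       r: float, sp: np.ndarray) -> None:
    ndim = mask.ndim
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    lo_um = np.minimum(p, q) - r
    hi_um = np.maximum(p, q) + r
    lo = np.maximum(np.floor(lo_um / sp).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / sp).astype(int) + 1, np.array(mask.shape))
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(*[np.arange(lo[d], hi[d]) * sp[d] for d in range(ndim)],
                        indexing="ij")
    pts = np.stack(grids, axis=-1)              # (..., ndim)
    d = q - p
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.linalg.norm(pts - p, axis=-1)
    else:
        t = np.clip(((pts - p) @ d) / L2, 0.0, 1.0)
        proj = p + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    sub = dist <= r
    mask[tuple(slice(lo[d], hi[d]) for d in range(ndim))] |= sub


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian intensity noise plus optional salt speckle."""

    sigma: float = 0.05              # fraction of the peak intensity
    salt_prob: float = 0.0
    salt_amplitude: float = 1.0


@dataclass
class GroundTruth:
    labels: np.ndarray               # layer label volume
    vessel_masks: dict[str, np.ndarray]
    tree: VesselTree

    @property
    def vessel_mask(self) -> np.ndarray:
        out = np.zeros_like(next(iter(self.vessel_masks.values())))
        for m in self.vessel_masks.values():
            out |= m
        return out


def rasterize_and_render(tree: VesselTree, labels: np.ndarray,
                         spacing: tuple[float, float, float],
                         noise: NoiseModel = NoiseModel(),
                         seed: int = 0,
                         amplitude: float = 1.0) -> tuple[Volume3D, GroundTruth]:
    """Rasterize the tree and render HF/LF channels.

    Band weighting is monotone in radius: HF weight ``exp(-r / 50 um)``,
    LF weight the complement, so per-voxel HF+LF equals the assigned
    amplitude exactly when ``noise.sigma == 0``.
    """
    shape = labels.shape
    sp = np.asarray(spacing, dtype=float)
    hf = np.zeros(shape, dtype=float)
    lf = np.zeros(shape, dtype=float)
    masks = {layer: np.zeros(shape, dtype=bool) for layer in LAYER_LABELS}
    for seg in tree.segments:
        seg_mask = np.zeros(shape, dtype=bool)
        for p, q in zip(seg.points_um[:-1], seg.points_um[1:]):
            _rasterize_capsule(seg_mask, p, q, seg.radius_um, sp)
        masks[seg.layer] |= seg_mask
        w_hf = math.exp(-seg.radius_um / HF_DECAY_UM)
        hf[seg_mask] = np.maximum(hf[seg_mask], amplitude * w_hf)
        lf[seg_mask] = np.maximum(lf[seg_mask], amplitude * (1.0 - w_hf))
    rng = np.random.default_rng(seed)
    if noise.sigma > 0:
        scale = noise.sigma * amplitude
        hf = hf + rng.normal(0.0, scale, size=shape)
        lf = lf + rng.normal(0.0, scale, size=shape)
    if noise.salt_prob > 0:
        salt = rng.random(shape) < noise.salt_prob
        hf[salt] = noise.salt_amplitude
    vol = Volume3D(channels={"HF": hf, "LF": lf}, spacing=tuple(sp))
    return vol, GroundTruth(labels=labels, vessel_masks=masks, tree=tree)


# ---------------------------------------------------------------------------
# cohorts with planted effects


#: generator knob each feature-effect multiplier maps onto
_KNOB_BY_BASE = {
    "n_vessels": "motif_count",
    "n_junctions": "junction_motif_count",
    "n_j2j_branches": "h_count",
    "n_j2e_branches": "junction_motif_count",
    "n_endpoints": "motif_count",
    "avg_vessel_length": "length_scale",
    "avg_branch_length": "length_scale",
    "total_skeleton_length": "motif_count",
    "avg_vessel_area": "radius_scale",
    "avg_vessel_volume": "radius_scale",
    "total_vessel_area": "radius_scale",
    "avg_vessel_diameter": "radius_scale",
    "vessel_density": "radius_scale",
    "layer_area": "thickness_scale",
    "layer_thickness": "thickness_scale",
    "junction_density": "junction_motif_count",
    "endpoint_density": "motif_count",
}

#: default planted stage-effect profile mirroring the published monotone
#: directions: dermal network features fall A -> C, epidermal/SVP features rise
DEFAULT_STAGE_EFFECTS: dict[str, dict[str, float]] = {
    key: ({"A": 0.90, "B": 0.75, "C": 0.60} if direction == "decrease"
          else {"A": 1.15, "B": 1.30, "C": 1.50})
    for key, direction in stage_trend_directions().items()
}

#: planted healthy-vs-diabetes contrast on the dominant published features:
#: epidermal/SVP 2D network counts fall in diabetes, dermal j2j falls too
DEFAULT_DIABETES_EFFECTS: dict[str, dict[str, float]] = {
    "n_vessels__epi_svp__2d": {"A": 0.75, "B": 0.75, "C": 0.75},
    "n_junctions__epi_svp__2d": {"A": 0.75, "B": 0.75, "C": 0.75},
    "n_j2j_branches__dermal__2d": {"A": 0.80, "B": 0.70, "C": 0.60},
}


@dataclass(frozen=True)
class BaselineConfig:
    """Healthy-skin generator conditions; effects multiply these."""

    epi: LayerVesselParams = LayerVesselParams(
        n_lines=3, n_y=3, n_h=2, radius_um=(15.0, 35.0),
        arm_length_um=(150.0, 300.0), clearance_um=50.0)
    derm: LayerVesselParams = LayerVesselParams(
        n_lines=3, n_y=3, n_h=3, radius_um=(25.0, 80.0),
        arm_length_um=(250.0, 500.0), clearance_um=60.0)
    images_per_participant: int = 1
    noise: NoiseModel = NoiseModel()


@dataclass
class Participant:
    participant_id: str
    group: str                       # "healthy" | "diabetes"
    stage: str                       # "A" | "B" | "C" | "none"
    age: float
    sex: int
    seed: int
    multipliers: dict[str, float]    # knob -> multiplier, per layer prefix


@dataclass
class Cohort:
    table: pd.DataFrame
    participants: dict[str, Participant]
    spec: PhantomSpec
    baseline: BaselineConfig
    effect_config: dict[str, dict[str, float]]


def _knob_multipliers(effect_config: dict[str, dict[str, float]],
                      group_key: str) -> dict[str, float]:
    """Collapse per-feature multipliers onto generator knobs (product rule)."""
    knobs: dict[str, float] = {}
    for feat, per_group in effect_config.items():
        base, layer, _ = split_key(feat)
        mult = float(per_group.get(group_key, 1.0))
        knob = f"{layer}.{_KNOB_BY_BASE[base]}"
        knobs[knob] = knobs.get(knob, 1.0) * mult
    return knobs


def _validate_effect_config(effect_config: dict) -> None:
    valid = set(all_feature_keys())
    unknown = [k for k in effect_config if k not in valid]
    if unknown:
        raise KeyError(
            f"unknown feature name(s) in effect_config: {unknown}; valid names "
            f"are the canonical 64 keys, e.g. {sorted(valid)[:4]} ...")


def make_cohort(n_healthy: int = 40,
                n_per_stage: tuple[int, int, int] = (22, 29, 24),
                effect_config: dict[str, dict[str, float]] | None = None,
                seed: int = 0,
                spec: PhantomSpec | None = None,
                baseline: BaselineConfig | None = None) -> Cohort:
    """Cohort table plus per-participant generator parameters.

    ``effect_config`` maps canonical feature keys to per-group multipliers,
    groups keyed "healthy", "A", "B", "C" (missing groups default to 1).
    Ground-truth parameters are stored per participant so planted effects are
    recoverable without re-deriving them from images.
    """
    if effect_config is None:
        effect_config = DEFAULT_DIABETES_EFFECTS
    _validate_effect_config(effect_config)
    spec = spec or PhantomSpec()
    baseline = baseline or BaselineConfig()
    master = np.random.SeedSequence(seed)
    rows = []
    participants: dict[str, Participant] = {}
    groups = [("healthy", "none")] * n_healthy
    for stage, n in zip("ABC", n_per_stage):
        groups += [("diabetes", stage)] * n
    child_seeds = master.generate_state(len(groups) + 1)
    rng = np.random.default_rng(child_seeds[0])
    for i, (group, stage) in enumerate(groups):
        pid = f"P{i:03d}"
        pseed = int(child_seeds[i + 1] % (2 ** 31))
        age = float(np.clip(rng.normal(58 if group == "diabetes" else 52, 12), 20, 90))
        sex = int(rng.integers(0, 2))
        key = "healthy" if group == "healthy" else stage
        knobs = _knob_multipliers(effect_config, key)
        participants[pid] = Participant(pid, group, stage, age, sex, pseed, knobs)
        rows.append({"participant_id": pid, "group": group, "stage": stage,
                     "age": age, "sex": sex,
                     "n_images": baseline.images_per_participant, "seed": pseed})
    table = pd.DataFrame(rows)
    return Cohort(table=table, participants=participants, spec=spec,
                  baseline=baseline, effect_config=effect_config)


def _scaled_layer_params(base: LayerVesselParams, layer: str,
                         knobs: dict[str, float],
                         rng: np.random.Generator) -> LayerVesselParams:
    def k(name: str) -> float:
        return knobs.get(f"{layer}.{name}", 1.0)

    count_m = k("motif_count")
    junc_m = k("junction_motif_count")
    h_m = k("h_count")
    # cap draws at 2x the (scaled) rate + 1 so a lucky Poisson draw cannot
    # exceed the placeable density of the small rendered field
    def draw(rate: float) -> int:
        return int(min(rng.poisson(rate), math.ceil(2 * rate) + 1))

    n_lines = draw(base.n_lines * count_m)
    n_y = draw(base.n_y * count_m * junc_m)
    n_h = draw(base.n_h * count_m * junc_m * h_m)
    r_m, l_m = k("radius_scale"), k("length_scale")
    return replace(base,
                   n_lines=n_lines, n_y=n_y, n_h=n_h,
                   radius_um=(base.radius_um[0] * r_m, base.radius_um[1] * r_m),
                   arm_length_um=(base.arm_length_um[0] * l_m,
                                  base.arm_length_um[1] * l_m))


def participant_spec(cohort: Cohort, pid: str) -> PhantomSpec:
    """Phantom spec for one participant, with thickness effects applied."""
    p = cohort.participants[pid]
    spec = cohort.spec
    t_epi = p.multipliers.get("epi_svp.thickness_scale", 1.0)
    t_derm = p.multipliers.get("dermal.thickness_scale", 1.0)
    e0, e1 = spec.epidermis_band_um
    d0, d1 = spec.dermis_band_um
    e1s = e0 + (e1 - e0) * t_epi
    return replace(spec, seed=p.seed,
                   epidermis_band_um=(e0, e1s),
                   dermis_band_um=(e1s, e1s + (d1 - d0) * t_derm))


def render_participant(cohort: Cohort, pid: str, image_index: int = 0
                       ) -> tuple[Volume3D, GroundTruth]:
    """Generate one image for one participant from its private RNG stream."""
    p = cohort.participants[pid]
    spec = participant_spec(cohort, pid)
    sseq = np.random.SeedSequence([p.seed, image_index])
    s_net, s_noise = (int(s % (2 ** 31)) for s in sseq.generate_state(2))
    rng = np.random.default_rng(s_net)
    layer_params = {
        "epi_svp": _scaled_layer_params(cohort.baseline.epi, "epi_svp",
                                        p.multipliers, rng),
        "dermal": _scaled_layer_params(cohort.baseline.derm, "dermal",
                                       p.multipliers, rng),
    }
    tree = None
    for attempt in range(5):
        try:
            tree = make_vessel_network(spec, layer_params,
                                       seed=(s_net + attempt * 1000003) % (2 ** 31))
            break
        except RuntimeError:
            if attempt == 4:
                raise
    labels = make_layer_volume(spec)
    vol, truth = rasterize_and_render(tree, labels, spec.voxel_spacing_um,
                                      noise=cohort.baseline.noise, seed=s_noise)
    vol.provenance = f"{pid}/img{image_index}"
    return vol, truth


# ---------------------------------------------------------------------------
# fast feature-level cohort simulation (no rendering)

#: baseline expected feature values used by the feature-level simulator;
#: order-of-magnitude choices for healthy skin, config-exposed
_SIM_BASE = {
    "n_vessels": 8.0, "n_junctions": 7.0, "n_j2j_branches": 3.0,
    "n_j2e_branches": 17.0, "n_endpoints": 23.0,
    "avg_vessel_length": 600.0, "avg_branch_length": 220.0,
    "total_skeleton_length": 5500.0, "avg_vessel_area": 2.0e4,
    "avg_vessel_volume": 8.0e5, "total_vessel_area": 2.2e5,
    "avg_vessel_diameter": 45.0, "vessel_density": 0.12,
    "layer_area": 2.4e6, "layer_thickness": 500.0,
    "junction_density": 3.0e-6, "endpoint_density": 1.0e-5,
}


def simulate_feature_matrix(cohort: Cohort, seed: int = 0,
                            noise_cv: float = 0.15) -> pd.DataFrame:
    """Draw per-image feature vectors directly from the planted distributions.

    Count features are Poisson around the planted rate, continuous features
    Gaussian with coefficient of variation ``noise_cv``.  One row per image,
    indexed by image id with a ``participant_id`` column — a fast surrogate
    for render->segment->measure when only cohort statistics are exercised.
    """
    rng = np.random.default_rng(seed)
    keys = all_feature_keys()
    rows, index = [], []
    for pid, p in cohort.participants.items():
        for img in range(cohort.baseline.images_per_participant):
            row = {"participant_id": pid}
            for key in keys:
                base, layer, _ = split_key(key)
                knob = _KNOB_BY_BASE[base]
                mult = p.multipliers.get(f"{layer}.{knob}", 1.0)
                mean = _SIM_BASE[base] * mult
                if base.startswith("n_"):
                    row[key] = float(rng.poisson(mean))
                else:
                    row[key] = float(max(rng.normal(mean, noise_cv * mean), 0.0))
            rows.append(row)
            index.append(f"{pid}_img{img}")
    return pd.DataFrame(rows, index=index)
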