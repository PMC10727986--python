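"""Skeleton-graph morphometry of layer-restricted vessel masks.

Binary vessel masks (2D MIP or 3D volume, per skin layer) are thinned to
1-voxel-wide medial lines, the skeleton is decomposed into a node/branch
graph (junction nodes: >=3 skeleton neighbours, merged over adjacent
clusters; endpoint nodes: exactly 1 neighbour), and 16 morphological
features are computed per (layer x dimensionality) subgroup — 64 per image.

Connectivity is 8-neighbourhood in 2D and 26-neighbourhood in 3D.  Branches
are typed junction-to-junction (j2j), junction-to-endpoint (j2e),
endpoint-to-endpoint (e2e) or cycle; lengths are sums of inter-voxel steps
calibrated by the anisotropic voxel spacing.  Vessel diameters are estimated
as twice the Euclidean distance transform sampled on skeleton voxels — the
standard medial-axis estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from . import taxonomy
from .taxonomy import all_feature_keys, feature_bases, make_key


# ---------------------------------------------------------------------------
# skeletonization


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Medial-line thinning (2D or 3D); empty input yields an empty skeleton.

    Uses Lee's thinning in both dimensionalities: unlike Zhang's 2D scheme it
    protects line ends, so narrow diagonal branches are not eroded away.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim not in (2, 3):
        raise ValueError("mask must be 2D or 3D")
    if not mask.any():
        return np.zeros_like(mask)
    return _sk_skeletonize(mask, method="lee").astype(bool)


# ---------------------------------------------------------------------------
# skeleton graph


@dataclass
class Branch:
    path: np.ndarray                 # (n, d) ordered voxel coordinates
    kind: str                        # j2j | j2e | e2e | cycle
    length_um: float
    node_a: int                      # -1 for cycles
    node_b: int
    mean_radius_um: float = 0.0


@dataclass
class GraphNode:
    voxels: np.ndarray               # (m, d) cluster member coordinates
    kind: str                        # junction | endpoint
    centroid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.centroid is None:
            self.centroid = self.voxels.mean(axis=0)


@dataclass
class SkeletonGraph:
    nodes: list[GraphNode]
    branches: list[Branch]
    skeleton: np.ndarray
    spacing: tuple[float, ...]

    @property
    def n_junctions(self) -> int:
        return sum(n.kind == "junction" for n in self.nodes)

    @property
    def n_endpoints(self) -> int:
        return sum(n.kind == "endpoint" for n in self.nodes)

    def branch_count(self, kind: str) -> int:
        return sum(b.kind == kind for b in self.branches)

    @property
    def n_components(self) -> int:
        structure = np.ones((3,) * self.skeleton.ndim, dtype=bool)
        _, n = ndimage.label(self.skeleton, structure=structure)
        return int(n)

    @property
    def total_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))

    def counts(self) -> dict[str, int]:
        return {
            "n_vessels": self.n_components,
            "n_junctions": self.n_junctions,
            "n_endpoints": self.n_endpoints,
            "n_j2j_branches": self.branch_count("j2j"),
            "n_j2e_branches": self.branch_count("j2e"),
            "n_e2e_branches": self.branch_count("e2e"),
        }


def _neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    return [o for o in itertools.product((-1, 0, 1), repeat=ndim)
            if any(o)]


def _step_length(a: tuple, b: tuple, spacing: np.ndarray) -> float:
    return float(np.linalg.norm((np.asarray(a) - np.asarray(b)) * spacing))


def build_graph(skeleton: np.ndarray, spacing: tuple[float, ...] | None = None,
                prune_below_um: float = 0.0, _depth: int = 0) -> SkeletonGraph:
    """Decompose a thinned skeleton into nodes and typed branches.

    Adjacent >=3-neighbour voxels are merged into a single junction node so
    that thinning clumps do not inflate junction counts.  ``prune_below_um``
    removes junction-to-endpoint spurs shorter than the threshold (thinning
    artefacts at tube ends) and rebuilds the graph.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    ndim = skeleton.ndim
    if spacing is None:
        spacing = (1.0,) * ndim
    sp = np.asarray(spacing, dtype=float)
    offsets = _neighbor_offsets(ndim)

    voxels = set(map(tuple, np.argwhere(skeleton)))
    nbrs: dict[tuple, list[tuple]] = {}
    for v in voxels:
        nbrs[v] = [tuple(np.add(v, o)) for o in offsets
                   if tuple(np.add(v, o)) in voxels]
    deg = {v: len(n) for v, n in nbrs.items()}

    node_voxels = {v for v, d in deg.items() if d != 2}
    # cluster adjacent node voxels
    cluster_of: dict[tuple, int] = {}
    clusters: list[list[tuple]] = []
    for v in sorted(node_voxels):
        if v in cluster_of:
            continue
        stack, members = [v], []
        cluster_of[v] = len(clusters)
        while stack:
            u = stack.pop()
            members.append(u)
            for w in nbrs[u]:
                if w in node_voxels and w not in cluster_of:
                    cluster_of[w] = len(clusters)
                    stack.append(w)
        clusters.append(members)

    nodes = []
    for members in clusters:
        kind = "junction" if any(deg[m] >= 3 for m in members) else "endpoint"
        nodes.append(GraphNode(voxels=np.asarray(members), kind=kind))

    branches: list[Branch] = []
    visited_mid: set[tuple] = set()
    visited_pairs: set[frozenset] = set()

    def path_length(path: list[tuple]) -> float:
        return sum(_step_length(a, b, sp) for a, b in zip(path[:-1], path[1:]))

    for ci, members in enumerate(clusters):
        for v in members:
            for u in nbrs[v]:
                if u in node_voxels:
                    cj = cluster_of[u]
                    if cj == ci:
                        continue  # intra-cluster adjacency
                    pair = frozenset((ci, cj, v, u))
                    if pair in visited_pairs:
                        continue
                    visited_pairs.add(pair)
                    path = [v, u]
                else:
                    if u in visited_mid:
                        continue
                    path = [v, u]
                    prev, cur = v, u
                    while cur not in node_voxels:
                        visited_mid.add(cur)
                        nxt = [w for w in nbrs[cur] if w != prev]
                        if not nxt:
                            break  # dangling degree-1 mid voxel (cannot happen)
                        prev, cur = cur, nxt[0]
                        path.append(cur)
                    if path[-1] not in node_voxels:
                        continue
                    cj = cluster_of[path[-1]]
                ka, kb = nodes[ci].kind, nodes[cj].kind
                kind = ("j2j" if ka == kb == "junction"
                        else "e2e" if ka == kb == "endpoint" else "j2e")
                branches.append(Branch(path=np.asarray(path), kind=kind,
                                       length_um=path_length(path),
                                       node_a=ci, node_b=cj))

    # remaining unvisited degree-2 voxels form pure cycles
    remaining = {v for v in voxels if deg[v] == 2} - visited_mid
    for b in branches:
        remaining -= set(map(tuple, b.path))
    while remaining:
        start = next(iter(sorted(remaining)))
        path = [start]
        remaining.discard(start)
        prev, cur = None, start
        while True:
            nxt = [w for w in nbrs[cur] if w != prev and w in remaining]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
            remaining.discard(cur)
        path.append(start)  # close the loop
        branches.append(Branch(path=np.asarray(path), kind="cycle",
                               length_um=path_length(path),
                               node_a=-1, node_b=-1))

    graph = SkeletonGraph(nodes=nodes, branches=branches,
                          skeleton=skeleton, spacing=tuple(sp))

    if prune_below_um > 0 and _depth < 4:
        spur_voxels: set[tuple] = set()
        for b in graph.branches:
            if b.kind == "j2e" and b.length_um < prune_below_um:
                # drop everything except the junction-side voxel
                junction_side = (b.path[0] if nodes[b.node_a].kind == "junction"
                                 else b.path[-1])
                spur_voxels |= set(map(tuple, b.path)) - {tuple(junction_side)}
        if spur_voxels:
            pruned = skeleton.copy()
            for v in spur_voxels:
                pruned[v] = False
            return build_graph(pruned, spacing, prune_below_um, _depth + 1)
    return graph


# ---------------------------------------------------------------------------
# features


@dataclass
class SkinMasks:
    """Layer masks plus layer-restricted vessel masks (one geometry)."""

    layer_masks: dict[str, np.ndarray]
    vessel_masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        layers = list(self.layer_masks)
        for a, b in itertools.combinations(layers, 2):
            if np.logical_and(self.layer_masks[a], self.layer_masks[b]).any():
                raise ValueError(f"layer masks {a!r} and {b!r} overlap")
        for layer, vm in self.vessel_masks.items():
            if np.logical_and(vm, ~self.layer_masks[layer]).any():
                raise ValueError(f"vessel mask exceeds layer mask for {layer!r}")


def _layer_thickness_um(layer_mask: np.ndarray, spacing) -> float:
    """Mean per-column extent of the layer along z (axis 0), in um."""
    if not layer_mask.any():
        return 0.0
    counts = layer_mask.sum(axis=0)
    occupied = counts > 0
    return float(counts[occupied].mean() * spacing[0])


def _component_lengths(graph: SkeletonGraph) -> list[float]:
    """Total skeleton length per connected component."""
    structure = np.ones((3,) * graph.skeleton.ndim, dtype=bool)
    labels, n = ndimage.label(graph.skeleton, structure=structure)
    totals = np.zeros(n + 1)
    for b in graph.branches:
        lbl = labels[tuple(b.path[0])]
        totals[lbl] += b.length_um
    return [float(t) for t in totals[1:]]


def compute_subgroup_features(layer_mask: np.ndarray, vessel_mask: np.ndarray,
                              spacing, domain: str,
                              prune_below_um: float = 0.0
                              ) -> tuple[dict[str, float], dict[str, bool]]:
    """The canonical 16 features for one (layer, domain) subgroup.

    Returns (values, undefined_flags); undefined averages over empty sets are
    reported as 0 with the flag raised so downstream vectors stay complete.
    """
    sp = np.asarray(spacing, dtype=float)
    pixel_measure = float(np.prod(sp))     # um^2 in 2D, um^3 in 3D
    flags: dict[str, bool] = {}
    vals: dict[str, float] = {}

    skel = skeletonize_mask(vessel_mask)
    graph = build_graph(skel, spacing=sp, prune_below_um=prune_below_um)
    counts = graph.counts()
    vals["n_vessels"] = counts["n_vessels"]
    vals["n_junctions"] = counts["n_junctions"]
    vals["n_j2j_branches"] = counts["n_j2j_branches"]
    vals["n_j2e_branches"] = counts["n_j2e_branches"]
    vals["n_endpoints"] = counts["n_endpoints"]

    comp_lengths = _component_lengths(graph)
    branch_lengths = [b.length_um for b in graph.branches]

    def avg(xs, name):
        if len(xs) == 0:
            flags[name] = True
            return 0.0
        return float(np.mean(xs))

    vals["avg_vessel_length"] = avg(comp_lengths, "avg_vessel_length")
    vals["avg_branch_length"] = avg(branch_lengths, "avg_branch_length")
    vals["total_skeleton_length"] = graph.total_length_um

    n_vessel_px = int(vessel_mask.sum())
    n_layer_px = int(layer_mask.sum())
    vals["total_vessel_area"] = n_vessel_px * pixel_measure
    size_key = "avg_vessel_area" if domain == "2d" else "avg_vessel_volume"
    if counts["n_vessels"] > 0:
        vals[size_key] = vals["total_vessel_area"] / counts["n_vessels"]
    else:
        vals[size_key] = 0.0
        flags[size_key] = True

    if skel.any():
        edt = ndimage.distance_transform_edt(vessel_mask, sampling=sp)
        vals["avg_vessel_diameter"] = float(2.0 * edt[skel].mean())
    else:
        vals["avg_vessel_diameter"] = 0.0
        flags["avg_vessel_diameter"] = True

    if n_layer_px > 0:
        vals["vessel_density"] = n_vessel_px / n_layer_px
        vals["junction_density"] = counts["n_junctions"] / (n_layer_px * pixel_measure)
        vals["endpoint_density"] = counts["n_endpoints"] / (n_layer_px * pixel_measure)
    else:
        vals["vessel_density"] = vals["junction_density"] = 0.0
        vals["endpoint_density"] = 0.0
        flags["vessel_density"] = flags["junction_density"] = True
        flags["endpoint_density"] = True
    vals["layer_area"] = n_layer_px * pixel_measure
    vals["layer_thickness"] = _layer_thickness_um(layer_mask, sp)
    return vals, flags


@dataclass
class FeatureVector:
    """The 64 named features with per-entry unit/scale metadata."""

    values: pd.Series
    undefined: dict[str, bool]

    def __post_init__(self) -> None:
        expected = list(all_feature_keys())
        if list(self.values.index) != expected:
            raise ValueError("feature vector must carry the canonical 64 keys "
                             "in canonical order")

    @property
    def scales(self) -> dict[str, str]:
        return taxonomy.assign_scales(self.values.index)

    @property
    def units(self) -> dict[str, str]:
        return {k: taxonomy.feature_unit(k) for k in self.values.index}


def compute_features(masks_2d: SkinMasks, masks_3d: SkinMasks,
                     spacing_3d, spacing_2d=None,
                     prune_below_um: float = 0.0) -> FeatureVector:
    """All 64 features from the four (layer, domain) subgroup masks.

    ``spacing_3d`` is (z, y, x) um; the 2D MIP spacing defaults to (z, x).
    Raw (un-normalized) masks are expected — counts are intensity-invariant
    by construction.
    """
    if spacing_2d is None:
        spacing_2d = (spacing_3d[0], spacing_3d[2])
    out: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for domain, masks, sp in (("2d", masks_2d, spacing_2d),
                              ("3d", masks_3d, spacing_3d)):
        for layer in taxonomy.LAYERS:
            vals, f = compute_subgroup_features(
                masks.layer_masks[layer], masks.vessel_masks[layer],
                sp, domain, prune_below_um=prune_below_um)
            for base in feature_bases(domain):
                key = make_key(base, layer, domain)
                out[key] = vals[base]
                if f.get(base):
                    flags[key] = True
    series = pd.Series({k: out[k] for k in all_feature_keys()})
    return FeatureVector(values=series, undefined=flags)


def assign_scales(keys) -> dict[str, str]:
    """Scale label (micro/meso/macroscale) per canonical feature key."""
    return taxonomy.assign_scales(keys)


def segmental_map(feature_matrix: pd.DataFrame, groups: pd.Series
                  ) -> pd.DataFrame:
    """Per-group mean features normalized per feature by the max group mean.

    Cells lie in (0, 1] with the per-feature maximum cell equal to 1; a
    feature whose group means are all 0 gets 0 cells (with a warning).
    """
    import warnings

    if len(feature_matrix) == 0 or feature_matrix.shape[1] == 0:
        raise ValueError("need at least one group and one feature")
    means = feature_matrix.groupby(groups.loc[feature_matrix.index]).mean()
    peak = means.max(axis=0)
    zero = peak <= 0
    if zero.any():
        warnings.warn(f"features with zero per-group means: {list(peak[zero].index)}")
        peak = peak.replace(0, np.nan)
    out = (means / peak).fillna(0.0)
    return out
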