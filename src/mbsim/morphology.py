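"""Neuronal tree morphologies: SWC I/O, morphometry, region labeling,
electrical discretization, and a seeded synthetic GGN generator.

The giant GABAergic neuron (GGN) of the locust mushroom body is modeled as a
labeled tree of 3-D neurite points with radii (SWC semantics).  Regions follow
the anatomy: a basal neurite from the soma splits into an alpha-lobe subtree
(KC input), lateral and medial calyceal subtrees (inhibitory output onto KCs),
and a lateral-horn subtree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

__all__ = [
    "RegionLabel",
    "MorphNode",
    "Morphology",
    "MorphometryStats",
    "CompartmentalModel",
    "load_swc",
    "save_swc",
    "morphometry",
    "label_regions",
    "compartmentalize",
    "generate_synthetic_ggn",
    "SWC_REGION_CODES",
]


class RegionLabel(IntEnum):
    """Anatomical region of a GGN neurite."""

    SOMA = 0
    BASAL = 1
    ALPHA_LOBE = 2
    CALYX_LATERAL = 3
    CALYX_MEDIAL = 4
    LATERAL_HORN = 5


#: Calyceal output regions (GGN->KC graded synapses live here).
CALYX_REGIONS = (RegionLabel.CALYX_LATERAL, RegionLabel.CALYX_MEDIAL)

#: SWC struct_type codes used by the synthetic generator.  Code 1 is the
#: standard soma code; 5-9 are custom codes carrying the region labels.
SWC_REGION_CODES = {
    1: RegionLabel.SOMA,
    5: RegionLabel.BASAL,
    6: RegionLabel.ALPHA_LOBE,
    7: RegionLabel.CALYX_LATERAL,
    8: RegionLabel.CALYX_MEDIAL,
    9: RegionLabel.LATERAL_HORN,
}
REGION_SWC_CODES = {v: k for k, v in SWC_REGION_CODES.items()}


class MorphologyError(ValueError):
    """Structural or validation failure of a morphology."""


@dataclass(frozen=True)
class MorphNode:
    """One SWC point: position and radius in micrometres."""

    id: int
    parent_id: int  # -1 for the root
    position: tuple[float, float, float]
    radius: float
    struct_type: int = 0


@dataclass
class Morphology:
    """A connected neurite tree.

    Nodes are stored in parallel arrays; ``order`` preserves the source file's
    node order.  ``parent_index`` holds positional indices (root: -1), so the
    tree structure is independent of the SWC id numbering.
    """

    ids: np.ndarray           # (N,) int
    parent_index: np.ndarray  # (N,) int, -1 at root
    xyz: np.ndarray           # (N, 3) float, um
    radius: np.ndarray        # (N,) float, um
    struct_type: np.ndarray   # (N,) int
    region: np.ndarray | None = None  # (N,) int RegionLabel values

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise MorphologyError("morphology has no nodes")
        if np.any(self.radius <= 0):
            raise MorphologyError("non-positive radius")
        roots = np.flatnonzero(self.parent_index < 0)
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        # every non-root parent must be a valid index and the graph a tree:
        # N nodes, N-1 edges, all reachable from the root.
        pi = self.parent_index
        if np.any(pi >= n):
            raise MorphologyError("parent reference out of range")
        seen = np.zeros(n, dtype=bool)
        order = self.topological_order()
        seen[order] = True
        if not seen.all():
            raise MorphologyError("cycle or orphan node detected")

    def topological_order(self) -> np.ndarray:
        """Indices ordered root-first so parent precedes child; raises on cycles."""
        n = self.n_nodes
        children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent_index):
            if p < 0:
                root = i
            else:
                children[p].append(i)
        order = np.empty(n, dtype=np.int64)
        stack = [root]
        k = 0
        while stack:
            i = stack.pop()
            if k >= n:  # more reachable entries than nodes: cycle
                raise MorphologyError("cycle detected")
            order[k] = i
            k += 1
            stack.extend(reversed(children[i]))
        return order[:k]

    def children_lists(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent_index):
            if p >= 0:
                ch[p].append(i)
        return ch

    def segment_lengths(self) -> np.ndarray:
        """Euclidean parent-child segment length per node (0 at root), um."""
        L = np.zeros(self.n_nodes)
        mask = self.parent_index >= 0
        d = self.xyz[mask] - self.xyz[self.parent_index[mask]]
        L[mask] = np.linalg.norm(d, axis=1)
        return L

    def nodes(self) -> list[MorphNode]:
        return [
            MorphNode(
                int(self.ids[i]),
                int(self.ids[self.parent_index[i]]) if self.parent_index[i] >= 0 else -1,
                tuple(self.xyz[i]),
                float(self.radius[i]),
                int(self.struct_type[i]),
            )
            for i in range(self.n_nodes)
        ]


@dataclass(frozen=True)
class MorphometryStats:
    """Summary geometry of a tree, all in micrometres/counts."""

    total_length: float
    max_path_length: float
    max_euclidean: float
    n_branch_points: int
    max_diameter: float


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def load_swc(path: str | Path) -> Morphology:
    """Read a standard 7-column SWC file (``# `` comments allowed), units um.

    Raises :class:`MorphologyError` on cycles, orphans, multiple roots, or
    non-positive radii.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(f"malformed SWC line: {line!r}")
            rows.append(parts)
    if not rows:
        raise MorphologyError(f"no nodes in SWC file {path}")
    ids = np.array([int(r[0]) for r in rows])
    stype = np.array([int(r[1]) for r in rows])
    xyz = np.array([[float(r[2]), float(r[3]), float(r[4])] for r in rows])
    radius = np.array([float(r[5]) for r in rows])
    parent = np.array([int(r[6]) for r in rows])
    index_of = {int(i): k for k, i in enumerate(ids)}
    if len(index_of) != len(ids):
        raise MorphologyError("duplicate node ids")
    pidx = np.empty(len(ids), dtype=np.int64)
    for k, p in enumerate(parent):
        if p < 0:
            pidx[k] = -1
        elif int(p) in index_of:
            pidx[k] = index_of[int(p)]
        else:
            raise MorphologyError(f"orphan node {ids[k]}: parent {p} missing")
    region = None
    if all(int(t) in SWC_REGION_CODES for t in stype):
        region = np.array([int(SWC_REGION_CODES[int(t)]) for t in stype])
    return Morphology(ids, pidx, xyz, radius, stype, region)


def save_swc(m: Morphology, path: str | Path) -> None:
    """Write ``m`` as standard SWC; node ids are remapped to contiguous 1..N.

    Region labels, when present, are encoded in the struct_type column using
    the custom codes in :data:`SWC_REGION_CODES`.
    """
    m.validate()
    order = m.topological_order()
    newid = np.empty(m.n_nodes, dtype=np.int64)
    newid[order] = np.arange(1, m.n_nodes + 1)
    with open(path, "w") as fh:
        fh.write("# SWC written by mbsim; units um; radius column is radius\n")
        fh.write("# custom struct_type codes: "
                 + ", ".join(f"{k}={RegionLabel(v).name}" for k, v in SWC_REGION_CODES.items())
                 + "\n")
        for i in order:
            if m.region is not None:
                code = REGION_SWC_CODES[RegionLabel(int(m.region[i]))]
            else:
                code = int(m.struct_type[i])
            p = m.parent_index[i]
            fh.write(
                f"{newid[i]} {code} {m.xyz[i,0]:.4f} {m.xyz[i,1]:.4f} "
                f"{m.xyz[i,2]:.4f} {m.radius[i]:.4f} "
                f"{newid[p] if p >= 0 else -1}\n"
            )


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

def morphometry(m: Morphology) -> MorphometryStats:
    """Geometric summary: lengths are sums of straight parent-child segments.

    ``max_path_length`` is the tree diameter in along-neurite distance (two-pass
    farthest-node search); ``max_euclidean`` the largest 3-D point distance.
    """
    seg = m.segment_lengths()
    total = float(seg.sum())
    order = m.topological_order()
    children = m.children_lists()

    def farthest(src: int) -> tuple[int, float, np.ndarray]:
        dist = np.full(m.n_nodes, -1.0)
        dist[src] = 0.0
        # relax along topological order in both directions (tree: BFS)
        stack = [src]
        while stack:
            i = stack.pop()
            nbrs = list(children[i])
            if m.parent_index[i] >= 0:
                nbrs.append(int(m.parent_index[i]))
            for j in nbrs:
                if dist[j] < 0:
                    w = seg[j] if m.parent_index[j] == i else seg[i]
                    dist[j] = dist[i] + w
                    stack.append(j)
        k = int(np.argmax(dist))
        return k, float(dist[k]), dist

    a, _, _ = farthest(int(order[0]))
    _, diam, _ = farthest(a)

    # max euclidean over all node pairs; O(N^2) memory avoided by chunking
    max_eu = 0.0
    xyz = m.xyz
    step = 512
    for i0 in range(0, m.n_nodes, step):
        chunk = xyz[i0:i0 + step]
        d2 = ((chunk[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
        max_eu = max(max_eu, float(np.sqrt(d2.max())))

    n_children = np.bincount(m.parent_index[m.parent_index >= 0], minlength=m.n_nodes)
    n_branch = int(np.sum(n_children >= 2))
    return MorphometryStats(
        total_length=total,
        max_path_length=diam,
        max_euclidean=max_eu,
        n_branch_points=n_branch,
        max_diameter=float(2.0 * m.radius.max()),
    )


# ---------------------------------------------------------------------------
# Region labeling
# ---------------------------------------------------------------------------

def label_regions(m: Morphology, scheme: dict[int, RegionLabel] | None = None) -> Morphology:
    """Assign a :class:`RegionLabel` to every node.

    ``scheme`` maps struct_type codes to labels (default:
    :data:`SWC_REGION_CODES`).  Raises if any node is left unlabeled.
    """
    if scheme is None:
        if m.region is not None:
            return m
        scheme = SWC_REGION_CODES
    region = np.full(m.n_nodes, -1, dtype=np.int64)
    for i in range(m.n_nodes):
        code = int(m.struct_type[i])
        if code in scheme:
            region[i] = int(scheme[code])
    if np.any(region < 0):
        missing = np.unique(m.struct_type[region < 0])
        raise MorphologyError(f"unlabeled struct_type codes: {missing.tolist()}")
    m.region = region
    return m


# ---------------------------------------------------------------------------
# Electrical discretization
# ---------------------------------------------------------------------------

@dataclass
class CompartmentalModel:
    """Electrically discretized tree in Hines (parent-before-child) order.

    Units: lengths/diameters um, areas cm^2, conductances uS, capacitances nF,
    voltages mV, currents nA, times ms.
    """

    parent: np.ndarray      # (M,) int, -1 at root
    length: np.ndarray      # (M,) um
    diam: np.ndarray        # (M,) um
    area: np.ndarray        # (M,) cm^2, cylinder lateral area
    g_leak: np.ndarray      # (M,) uS
    cap: np.ndarray         # (M,) nF
    g_axial: np.ndarray     # (M,) uS, conductance to parent (0 at root)
    region: np.ndarray      # (M,) int RegionLabel
    xyz: np.ndarray         # (M, 3) compartment centers, um
    e_rest: float           # mV
    path_dist: np.ndarray = field(default=None)  # (M,) um from root

    @property
    def n_comp(self) -> int:
        return len(self.parent)

    def terminal_mask(self) -> np.ndarray:
        has_child = np.zeros(self.n_comp, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return ~has_child

    def region_indices(self, label: RegionLabel, terminal_only: bool = False) -> np.ndarray:
        mask = self.region == int(label)
        if terminal_only:
            mask &= self.terminal_mask()
        return np.flatnonzero(mask)


def _lambda_um(diam_um: float, rm_kohm_cm2: float, ra_ohm_cm: float) -> float:
    """DC length constant sqrt(RM*d/(4*RA)) for a cable of diameter d, in um."""
    d_cm = diam_um * 1e-4
    lam_cm = math.sqrt(rm_kohm_cm2 * 1e3 * d_cm / (4.0 * ra_ohm_cm))
    return lam_cm * 1e4


def compartmentalize(m: Morphology, bio, max_elec_len: float = 0.1) -> CompartmentalModel:
    """Discretize a labeled morphology into isopotential compartments.

    Each parent-child segment is treated as a cylinder (diameter = child node
    diameter) and split so every compartment is shorter than
    ``max_elec_len * lambda(d)`` with ``lambda = sqrt(RM*d/(4*RA))``.  Membrane
    area is the cylinder lateral area; axial conductances combine the two
    half-compartment resistances.  Region labels are inherited from the child
    node of the segment.
    """
    if max_elec_len <= 0:
        raise ValueError("max_elec_len must be positive")
    if m.region is None:
        # fall back to the standard struct_type code mapping
        label_regions(m)
    order = m.topological_order()
    seg = m.segment_lengths()

    par, length, diam, region, centers = [], [], [], [], []
    comp_of_node = np.full(m.n_nodes, -1, dtype=np.int64)
    # root: small isopotential sphere-equivalent cylinder from the root node
    root = int(order[0])
    d0 = 2.0 * float(m.radius[root])
    par.append(-1)
    length.append(d0)
    diam.append(d0)
    region.append(int(m.region[root]))
    centers.append(m.xyz[root].copy())
    comp_of_node[root] = 0

    for i in order[1:]:
        p = int(m.parent_index[i])
        L = float(seg[i])
        d = 2.0 * float(m.radius[i])
        reg = int(m.region[i])
        parent_comp = comp_of_node[p]
        if L <= 1e-9:
            # zero-length segment: merge with parent compartment
            comp_of_node[i] = parent_comp
            continue
        lam = _lambda_um(d, bio.RM, bio.RA)
        nseg = max(1, int(math.ceil(L / (max_elec_len * lam))))
        a, b = m.xyz[p], m.xyz[i]
        for k in range(nseg):
            par.append(int(parent_comp))
            length.append(L / nseg)
            diam.append(d)
            region.append(reg)
            frac = (k + 0.5) / nseg
            centers.append(a + frac * (b - a))
            parent_comp = len(par) - 1
        comp_of_node[i] = parent_comp

    parent = np.array(par)
    length_a = np.array(length)
    diam_a = np.array(diam)
    area = math.pi * (diam_a * 1e-4) * (length_a * 1e-4)  # cm^2
    g_leak = area / bio.RM * 1e3       # (cm^2 / kOhm.cm^2) -> mS -> uS
    cap = bio.Cm * area * 1e3          # uF/cm^2 * cm^2 -> uF -> nF

    g_ax = np.zeros(len(parent))
    for i in range(1, len(parent)):
        p = parent[i]
        # series resistance of the two facing half-compartments, in MOhm
        def half_r(j):
            l_cm = length_a[j] * 1e-4 / 2.0
            d_cm = diam_a[j] * 1e-4
            return 4.0 * bio.RA * l_cm / (math.pi * d_cm ** 2) / 1e6
        r = half_r(i) + half_r(p)
        g_ax[i] = 1.0 / r  # uS

    path = np.zeros(len(parent))
    for i in range(1, len(parent)):
        path[i] = path[parent[i]] + 0.5 * (length_a[i] + length_a[parent[i]])

    return CompartmentalModel(
        parent=parent, length=length_a, diam=diam_a, area=area,
        g_leak=g_leak, cap=cap, g_axial=g_ax,
        region=np.array(region), xyz=np.array(centers),
        e_rest=bio.E_rest, path_dist=path,
    )


# ---------------------------------------------------------------------------
# Synthetic GGN generator
# ---------------------------------------------------------------------------

#: Default morphometry targets emulating the traced GGN: ~65 mm total neurite
#: length, ~2 mm maximum along-tree path, thickest processes ~20 um diameter.
DEFAULT_GGN_TARGETS = MorphometryStats(
    total_length=65_000.0, max_path_length=2_000.0, max_euclidean=1_000.0,
    n_branch_points=600, max_diameter=20.0,
)

# region share of the total length budget; calyces dominate the arbor
_REGION_BUDGET = {
    RegionLabel.BASAL: 0.02,
    RegionLabel.ALPHA_LOBE: 0.21,
    RegionLabel.CALYX_LATERAL: 0.34,
    RegionLabel.CALYX_MEDIAL: 0.34,
    RegionLabel.LATERAL_HORN: 0.09,
}


class _TreeBuilder:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.parent: list[int] = []
        self.xyz: list[np.ndarray] = []
        self.radius: list[float] = []
        self.stype: list[int] = []

    def add(self, parent: int, pos: np.ndarray, radius: float, code: int) -> int:
        self.parent.append(parent)
        self.xyz.append(pos)
        self.radius.append(max(radius, 0.25))
        self.stype.append(code)
        return len(self.parent) - 1

    def chain(self, start: int, direction: np.ndarray, n: int, seg: float,
              r0: float, r1: float, code: int) -> int:
        node = start
        pos = self.xyz[start].copy()
        for k in range(n):
            drift = self.rng.normal(scale=0.35, size=3)
            d = direction + drift
            d /= np.linalg.norm(d)
            pos = pos + d * seg
            r = r0 + (r1 - r0) * (k + 1) / n
            node = self.add(node, pos.copy(), r, code)
        return node


def _grow_subtree(tb: _TreeBuilder, root: int, direction: np.ndarray,
                  budget_um: float, code: int, seg_um: float,
                  r_start: float, r_tip: float, max_depth: int,
                  twig_um: float = 30.0) -> None:
    """Recursive stochastic binary branching with a length budget.

    Each section is a short chain of ~seg_um segments; the remaining budget is
    split randomly between two daughters whose radii taper geometrically until
    the tip radius is reached.  Terminal sections end in a short twig.
    """
    rng = tb.rng
    stack = [(root, direction, budget_um, r_start, 0)]
    while stack:
        node, dirv, budget, r, depth = stack.pop()
        n_seg = int(rng.integers(2, 4))
        sec_len = min(budget, n_seg * seg_um)
        if sec_len <= 0:
            continue
        n = max(1, int(round(sec_len / seg_um)))
        r_next = max(r_tip, r * 0.78)
        end = tb.chain(node, dirv, n, sec_len / n, r, r_next, code)
        budget -= sec_len
        if budget < twig_um or depth >= max_depth:
            if budget > 0:
                # spend leftover length as terminal twigs fanning from `end`
                n_twigs = max(1, int(budget // twig_um))
                for _ in range(n_twigs):
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    tb.chain(end, d, 1, min(twig_um, budget), r_tip, r_tip, code)
                    budget -= twig_um
                    if budget <= 0:
                        break
            continue
        split = rng.uniform(0.4, 0.6)
        for frac in (split, 1.0 - split):
            d = dirv + rng.normal(scale=0.6, size=3)
            d /= np.linalg.norm(d)
            stack.append((end, d, budget * frac, r_next, depth + 1))


def generate_synthetic_ggn(seed: int = 1,
                           targets: MorphometryStats = DEFAULT_GGN_TARGETS,
                           seg_um: float = 50.0) -> Morphology:
    """Generate a labeled GGN-like tree, deterministic for a fixed seed.

    The tree has one soma->basal neurite, an alpha-lobe subtree, lateral and
    medial calyceal subtrees with short terminal twigs, and a lateral-horn
    subtree; total neurite length lands within 10% of ``targets.total_length``
    and diameters taper from ~20 um at the primary neurite to ~0.5 um tips.
    """
    if targets.total_length <= 0 or targets.max_path_length <= 0:
        raise ValueError("morphometry targets must be positive")
    rng = np.random.default_rng(seed)
    tb = _TreeBuilder(rng)
    r_trunk = targets.max_diameter / 2.0

    soma = tb.add(-1, np.zeros(3), r_trunk * 0.6,
                  REGION_SWC_CODES[RegionLabel.SOMA])
    # basal neurite: soma -> main branch point
    basal_budget = _REGION_BUDGET[RegionLabel.BASAL] * targets.total_length
    n_basal = max(3, int(basal_budget / seg_um))
    hub = tb.chain(soma, np.array([0.0, 0.0, 1.0]), n_basal,
                   basal_budget / n_basal, r_trunk * 0.8, r_trunk,
                   REGION_SWC_CODES[RegionLabel.BASAL])

    # depth cap keeps the root-to-tip path near targets.max_path_length / 2
    max_depth = max(3, int(targets.max_path_length / 2.0 / (2.5 * seg_um)) - 1)

    specs = [
        (RegionLabel.ALPHA_LOBE, np.array([1.0, 0.0, 0.5]), hub),
        (RegionLabel.CALYX_LATERAL, np.array([-1.0, 0.5, 0.5]), hub),
        (RegionLabel.CALYX_MEDIAL, np.array([-0.5, -1.0, 0.5]), hub),
    ]
    lca_stem = None
    for label, direction, origin in specs:
        budget = _REGION_BUDGET[label] * targets.total_length
        code = REGION_SWC_CODES[label]
        stem = tb.chain(origin, direction, 3, seg_um, r_trunk, r_trunk * 0.8, code)
        if label is RegionLabel.CALYX_LATERAL:
            lca_stem = stem
        _grow_subtree(tb, stem, direction, budget - 3 * seg_um, code,
                      seg_um, r_trunk * 0.8, 0.25, max_depth)

    # lateral horn: thin neurite looping off the lateral calyceal stem
    lh_budget = _REGION_BUDGET[RegionLabel.LATERAL_HORN] * targets.total_length
    code = REGION_SWC_CODES[RegionLabel.LATERAL_HORN]
    lh_stem = tb.chain(lca_stem, np.array([0.0, 1.0, -1.0]), 3, seg_um,
                       2.0, 1.5, code)
    _grow_subtree(tb, lh_stem, np.array([0.0, 1.0, -1.0]),
                  lh_budget - 3 * seg_um, code, seg_um, 1.5, 0.25, max_depth)

    m = Morphology(
        ids=np.arange(1, len(tb.parent) + 1),
        parent_index=np.array(tb.parent),
        xyz=np.array(tb.xyz),
        radius=np.array(tb.radius),
        struct_type=np.array(tb.stype),
    )
    return label_regions(m)
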