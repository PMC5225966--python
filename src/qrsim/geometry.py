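"""Idealized biventricular geometry on a regular lattice.

The heart is modelled as two truncated ellipsoids: a thick-walled left
ventricle (LV) and a thin crescent-shaped right ventricle (RV) wrapped
around it, sharing an interventricular septum.  Both are rasterized on a
regular hexahedral lattice, which keeps the construction deterministic and
fully parameterizable and provides the node/element sets used by the
activation and forward-ECG modules.

Frames and conventions
----------------------
Mesh coordinates live in the *heart frame*: the long axis is +z
(apex -> base), the base is the cut plane z = 0 and the apex points toward
negative z.  +x is the LV lateral free wall, -x the septum/RV, +y anterior.
The rotational coordinate ``theta = atan2(y, x)`` therefore reads
0 = lateral, pi/2 = anterior, pi = septal, 3*pi/2 = posterior.

The torso (patient) frame has x toward the patient's left, y anterior and
z superior.  The heart long axis is tilted ``tilt_deg`` leftward in the
frontal plane, i.e. the patient frame is rotated relative to the heart
frame about the shared anterior axis.  Electrodes are specified in patient
coordinates and mapped into the heart frame, so mesh node coordinates stay
on the lattice.

Anatomical coordinates per node:

* ``a``     apicobasal, 0 at the (epicardial) apex, 1 at the base;
* ``m``     transmural, 0 on the endocardium, 1 on the epicardium
            (distance-transform based, exact on the labelled surfaces);
* ``theta`` rotational angle about the long axis, in [0, 2*pi);
* ``side``  LV, RV or SEPT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

__all__ = [
    "GeometryParams",
    "BiventricularMesh",
    "ElectrodeSet",
    "DegenerateGeometryError",
    "build_biventricular_mesh",
    "extract_surface_nodes",
    "anat_to_node",
    "standard_electrodes",
    "LV_WALL",
    "RV_WALL",
    "SEPTUM",
    "SIDE_LV",
    "SIDE_RV",
    "SIDE_SEPT",
    "SURFACE_LABELS",
]

log = logging.getLogger(__name__)

# region labels (per node)
LV_WALL, RV_WALL, SEPTUM = 1, 2, 3
REGION_NAMES = {LV_WALL: "LV_WALL", RV_WALL: "RV_WALL", SEPTUM: "SEPTUM"}

# anatomical side labels
SIDE_LV, SIDE_RV, SIDE_SEPT = 1, 2, 3
SIDE_NAMES = {SIDE_LV: "LV", SIDE_RV: "RV", SIDE_SEPT: "SEPT"}
SIDE_IDS = {v: k for k, v in SIDE_NAMES.items()}

SURFACE_LABELS = ("LV_ENDO", "RV_ENDO", "EPI", "BASE")

# 26-neighbourhood half-offsets (13 directions, each edge stored once)
NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ],
    dtype=int,
)


class DegenerateGeometryError(ValueError):
    """Raised when lattice spacing cannot resolve the thinnest wall."""


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the idealized biventricular anatomy (lengths in mm).

    Defaults approximate a human heart: LV inner long axis 68 mm, LV
    free-wall thickness 12 mm, RV free-wall thickness 4 mm.
    ``septal_buffer`` thickens the septum beyond the free wall (the basal
    septum is thicker than the free wall in humans).
    ``lv_apex_thickness`` sets the wall of the apical cap, whose compact
    wall plus dense trabecular/papillary mass is modelled as a thicker
    solid layer; it depolarizes last, as in measured human activation
    sequences where the epicardial apex is among the latest regions.
    ``tilt_deg``/``rot_deg`` fix the heart orientation in the torso and
    are calibrated once so that the baseline activation sequence yields a
    normally oriented frontal QRS axis and precordial polarities.
    """

    spacing: float = 2.0
    lv_cavity_radius: float = 22.0
    lv_wall_thickness: float = 12.0
    lv_apex_thickness: float = 16.0
    lv_inner_length: float = 68.0
    rv_center: tuple[float, float, float] = (-20.0, 4.0, 0.0)
    rv_semiaxes: tuple[float, float, float] = (38.0, 30.0, 56.0)
    rv_wall_thickness: float = 4.0
    septal_buffer: float = 5.0
    tilt_deg: float = 10.0
    rot_deg: float = -77.0
    fiber_angle_endo_deg: float = 60.0
    fiber_angle_epi_deg: float = -60.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        thinnest = min(
            self.lv_wall_thickness, self.lv_apex_thickness, self.rv_wall_thickness
        )
        if self.spacing >= thinnest:
            raise DegenerateGeometryError(
                f"spacing {self.spacing} mm cannot resolve the thinnest wall "
                f"({thinnest} mm)"
            )

    @property
    def lv_endo_semiaxes(self) -> np.ndarray:
        r = self.lv_cavity_radius
        return np.array([r, r, self.lv_inner_length])

    @property
    def lv_epi_semiaxes(self) -> np.ndarray:
        # equatorial wall = lv_wall_thickness; the apical cap carries
        # lv_apex_thickness (compact wall + trabecular mass)
        r = self.lv_cavity_radius + self.lv_wall_thickness
        return np.array([r, r, self.lv_inner_length + self.lv_apex_thickness])

    @property
    def long_axis_length(self) -> float:
        return self.lv_inner_length + self.lv_wall_thickness


@dataclass(frozen=True)
class ElectrodeSet:
    """Nine named body-surface electrodes in the mesh (heart) frame.

    RA/LA/LL define the Einthoven limb system and the Wilson central
    terminal; V1..V6 are the precordial electrodes.
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (9, 3) mm, heart frame
    reference: str = "wilson_central_terminal"

    def __post_init__(self) -> None:
        if len(self.names) != 9 or self.positions.shape != (9, 3):
            raise ValueError("an ElectrodeSet has exactly 9 electrodes")

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.names.index(name)]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: self.positions[i] for i, n in enumerate(self.names)}


@dataclass
class BiventricularMesh:
    """Rasterized biventricular volume with labels and anatomical coords."""

    params: GeometryParams
    nodes: np.ndarray        # (N, 3) float, mm, heart frame (lattice points)
    ijk: np.ndarray          # (N, 3) int lattice indices
    origin: np.ndarray       # (3,) lattice origin, mm
    grid_shape: tuple[int, int, int]
    elements: np.ndarray     # (M, 8) int, VTK hexahedron corner order
    region: np.ndarray       # (N,) uint8 in {LV_WALL, RV_WALL, SEPTUM}
    side: np.ndarray         # (N,) uint8 in {SIDE_LV, SIDE_RV, SIDE_SEPT}
    surface: dict[str, np.ndarray] = field(default_factory=dict)  # label -> bool (N,)
    fiber_dir: np.ndarray = None       # (N, 3) unit
    transmural_dir: np.ndarray = None  # (N, 3) unit
    a: np.ndarray = None     # (N,) apicobasal in [0, 1]
    m: np.ndarray = None     # (N,) transmural in [0, 1]
    theta: np.ndarray = None  # (N,) rotational in [0, 2*pi)
    node_index: np.ndarray = None  # grid -> node id (or -1)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def spacing(self) -> float:
        return self.params.spacing

    @property
    def centroid(self) -> np.ndarray:
        return self.nodes.mean(axis=0)

    def anat_coords(self, node: int) -> tuple[float, float, float, str]:
        return (
            float(self.a[node]),
            float(self.m[node]),
            float(self.theta[node]),
            SIDE_NAMES[int(self.side[node])],
        )

    def surface_mask(self, label: str) -> np.ndarray:
        if label not in self.surface:
            raise KeyError(f"unknown surface label {label!r}; "
                           f"expected one of {SURFACE_LABELS}")
        return self.surface[label]

    def patient_to_mesh(self, offsets: np.ndarray) -> np.ndarray:
        """Map patient-frame offsets (relative to the heart centroid) to
        absolute heart-frame positions.

        The heart orientation combines the frontal-plane tilt of the long
        axis (``tilt_deg`` leftward) with a rotation about the long axis
        (``rot_deg``) that turns the septum to face anterior-right and the
        LV free wall posterior-left, as in situ.
        """
        tau = np.deg2rad(self.params.tilt_deg)
        rho = np.deg2rad(self.params.rot_deg)
        r_y = np.array(  # R_y(tau): undoes the leftward tilt
            [[np.cos(tau), 0.0, np.sin(tau)],
             [0.0, 1.0, 0.0],
             [-np.sin(tau), 0.0, np.cos(tau)]]
        )
        r_z = np.array(  # R_z(-rho): undoes the long-axis rotation
            [[np.cos(rho), np.sin(rho), 0.0],
             [-np.sin(rho), np.cos(rho), 0.0],
             [0.0, 0.0, 1.0]]
        )
        patient_to_mesh = r_z @ r_y
        return self.centroid + offsets @ patient_to_mesh.T


def _ellipsoid_value(pts: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    q = (pts - center) / semi
    return np.einsum("ij,ij->i", q, q)


def build_biventricular_mesh(params: GeometryParams | None = None) -> BiventricularMesh:
    """Rasterize the two-ellipsoid biventricular anatomy.

    Deterministic for a fixed parameter set.  Nodes are lattice points
    (integer multiples of ``spacing`` relative to the lattice origin) that
    fall inside the myocardium; only the largest connected component is
    kept.  Elements are the lattice cells whose eight corners are all
    myocardial.
    """
    p = params or GeometryParams()
    s = p.spacing

    lv_endo_c = np.zeros(3)
    lv_endo_s = p.lv_endo_semiaxes
    lv_epi_s = p.lv_epi_semiaxes
    lv_buf_s = lv_epi_s + p.septal_buffer
    rv_c = np.asarray(p.rv_center, dtype=float)
    rv_s = np.asarray(p.rv_semiaxes, dtype=float)
    rv_epi_s = rv_s + p.rv_wall_thickness

    # lattice bounds with one voxel of padding
    lo = np.minimum(-lv_epi_s, rv_c - rv_epi_s) - s
    hi = np.maximum(lv_epi_s, rv_c + rv_epi_s) + s
    hi[2] = 0.0  # basal truncation plane
    origin = np.floor(lo / s) * s
    n_ijk = np.floor((hi - origin) / s).astype(int) + 1
    grid_shape = tuple(int(n) for n in n_ijk)

    ii, jj, kk = np.meshgrid(
        np.arange(grid_shape[0]),
        np.arange(grid_shape[1]),
        np.arange(grid_shape[2]),
        indexing="ij",
    )
    ijk_all = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = origin + ijk_all * s
    below_base = pts[:, 2] <= 1e-9

    v_lv_endo = _ellipsoid_value(pts, lv_endo_c, lv_endo_s)
    v_lv_epi = _ellipsoid_value(pts, lv_endo_c, lv_epi_s)
    v_lv_buf = _ellipsoid_value(pts, lv_endo_c, lv_buf_s)
    v_rv = _ellipsoid_value(pts, rv_c, rv_s)
    v_rv_epi = _ellipsoid_value(pts, rv_c, rv_epi_s)

    in_lv_cav = (v_lv_endo < 1.0) & below_base
    lv_myo = (v_lv_epi < 1.0) & ~in_lv_cav & below_base
    in_rv_cav = (v_rv < 1.0) & (v_lv_buf >= 1.0) & below_base
    # RV wall: true offset shell of the crescent cavity (a plain inflated
    # ellipsoid would smear extra myocardium onto the LV epicardium past
    # the insertion lines)
    from scipy import ndimage

    d_rv = ndimage.distance_transform_edt(
        ~in_rv_cav.reshape(grid_shape), sampling=s
    ).ravel()
    rv_myo = (
        (d_rv <= p.rv_wall_thickness + 1e-9)
        & ~in_rv_cav
        & ~lv_myo
        & ~in_lv_cav
        & below_base
    )
    myo = lv_myo | rv_myo

    # voxel classes for surface detection
    CLS_OUT, CLS_MYO, CLS_LVCAV, CLS_RVCAV = 0, 1, 2, 3
    cls = np.full(pts.shape[0], CLS_OUT, dtype=np.uint8)
    cls[myo] = CLS_MYO
    cls[in_lv_cav] = CLS_LVCAV
    cls[in_rv_cav] = CLS_RVCAV
    cls3 = cls.reshape(grid_shape)

    myo3 = myo.reshape(grid_shape)
    node_index = np.full(grid_shape, -1, dtype=np.int64)
    ids = np.flatnonzero(myo)
    node_index.ravel()[ids] = np.arange(ids.size)
    ijk = ijk_all[ids]
    nodes = pts[ids]
    n = nodes.shape[0]

    # keep only the largest 26-connected component
    rows, cols = _lattice_edges(node_index, ijk)
    adj = sparse.coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
    ).tocsr()
    ncomp, comp = csgraph.connected_components(adj, directed=False)
    if ncomp > 1:
        keep_comp = np.bincount(comp).argmax()
        keep = comp == keep_comp
        dropped = int((~keep).sum())
        log.info("dropping %d disconnected myocardial nodes", dropped)
        remap = np.full(n, -1, dtype=np.int64)
        remap[keep] = np.arange(int(keep.sum()))
        node_index[tuple(ijk[~keep].T)] = -1
        node_index[node_index >= 0] = remap[node_index[node_index >= 0]]
        ids = ids[keep]
        ijk = ijk[keep]
        nodes = nodes[keep]
        n = nodes.shape[0]

    # region / side labels; the septum is the myocardium sandwiched between
    # the RV cavity (toward -x) and the LV cavity (toward +x)
    region = np.full(n, LV_WALL, dtype=np.uint8)
    rvm = rv_myo[ids]
    region[rvm] = RV_WALL
    rv_cav3 = in_rv_cav.reshape(grid_shape)
    lv_cav3 = in_lv_cav.reshape(grid_shape)
    rv_below = np.maximum.accumulate(rv_cav3, axis=0)
    lv_above = np.maximum.accumulate(lv_cav3[::-1], axis=0)[::-1]
    sept3 = rv_below & lv_above
    sept = sept3[tuple(ijk.T)]
    region[sept] = SEPTUM
    side = np.full(n, SIDE_LV, dtype=np.uint8)
    side[region == RV_WALL] = SIDE_RV
    side[region == SEPTUM] = SIDE_SEPT

    # surface labels from 6-adjacency of voxel classes
    surface = _surface_labels(cls3, ijk, grid_shape)

    # anatomical coordinates
    apex_z = float(-lv_epi_s[2])
    a = np.clip((nodes[:, 2] - apex_z) / (0.0 - apex_z), 0.0, 1.0)
    theta = np.mod(np.arctan2(nodes[:, 1], nodes[:, 0]), 2.0 * np.pi)
    m = _transmural_coordinate(nodes, surface)

    # transmural direction: outward ellipsoid normals
    tdir = np.empty((n, 3))
    lv_like = region != RV_WALL
    tdir[lv_like] = (nodes[lv_like] - lv_endo_c) / lv_endo_s**2
    tdir[~lv_like] = (nodes[~lv_like] - rv_c) / rv_s**2
    tdir /= np.linalg.norm(tdir, axis=1, keepdims=True)

    fiber = _rule_based_fibers(tdir, m, p)

    elements = _hex_elements(node_index, grid_shape)

    mesh = BiventricularMesh(
        params=p,
        nodes=nodes,
        ijk=ijk,
        origin=origin,
        grid_shape=grid_shape,
        elements=elements,
        region=region,
        side=side,
        surface=surface,
        fiber_dir=fiber,
        transmural_dir=tdir,
        a=a,
        m=m,
        theta=theta,
        node_index=node_index,
    )
    return mesh


def _lattice_edges(node_index: np.ndarray, ijk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """26-neighbourhood edges among lattice nodes (each pair once)."""
    shape = np.array(node_index.shape)
    rows, cols = [], []
    for off in NEIGHBOR_OFFSETS:
        nb = ijk + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        tgt = np.full(ijk.shape[0], -1, dtype=np.int64)
        tgt[ok] = node_index[tuple(nb[ok].T)]
        src = node_index[tuple(ijk.T)]
        good = tgt >= 0
        rows.append(src[good])
        cols.append(tgt[good])
    return np.concatenate(rows), np.concatenate(cols)


def _surface_labels(cls3: np.ndarray, ijk: np.ndarray, grid_shape) -> dict[str, np.ndarray]:
    CLS_OUT, CLS_LVCAV, CLS_RVCAV = 0, 2, 3
    n = ijk.shape[0]
    shape = np.array(grid_shape)

    def neighbor_class(off):
        nb = ijk + off
        inside = np.all((nb >= 0) & (nb < shape), axis=1)
        out = np.full(n, CLS_OUT, dtype=np.uint8)
        out[inside] = cls3[tuple(nb[inside].T)]
        return out

    lv_endo = np.zeros(n, dtype=bool)
    rv_endo = np.zeros(n, dtype=bool)
    epi = np.zeros(n, dtype=bool)
    base = np.zeros(n, dtype=bool)
    top_k = grid_shape[2] - 1
    for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        nc = neighbor_class(off)
        lv_endo |= nc == CLS_LVCAV
        rv_endo |= nc == CLS_RVCAV
        if off == (0, 0, 1):
            # out-of-volume above the basal plane is the base cut, not epicardium
            at_top = ijk[:, 2] == top_k
            epi |= (nc == CLS_OUT) & ~at_top
            base |= (nc == CLS_OUT) & at_top
        else:
            epi |= nc == CLS_OUT
    # endocardium takes precedence so LV_ENDO/RV_ENDO/EPI stay disjoint
    epi &= ~(lv_endo | rv_endo)
    rv_endo &= ~lv_endo
    return {"LV_ENDO": lv_endo, "RV_ENDO": rv_endo, "EPI": epi, "BASE": base}


def _transmural_coordinate(nodes: np.ndarray, surface: dict[str, np.ndarray]) -> np.ndarray:
    endo = surface["LV_ENDO"] | surface["RV_ENDO"]
    epi = surface["EPI"]
    d_endo = cKDTree(nodes[endo]).query(nodes)[0]
    d_epi = cKDTree(nodes[epi]).query(nodes)[0]
    m = d_endo / np.maximum(d_endo + d_epi, 1e-12)
    m[endo] = 0.0
    m[epi] = 1.0
    return m


def _rule_based_fibers(tdir: np.ndarray, m: np.ndarray, p: GeometryParams) -> np.ndarray:
    """Helix-angle rule: fibers rotate from +60 deg (endo) to -60 deg (epi)
    about the transmural axis, measured from the circumferential direction."""
    n = tdir.shape[0]
    zhat = np.array([0.0, 0.0, 1.0])
    circ = np.cross(tdir, np.broadcast_to(zhat, (n, 3)))
    norm = np.linalg.norm(circ, axis=1)
    degenerate = norm < 1e-8
    if degenerate.any():
        # near the apex the transmural axis is parallel to the long axis
        alt = np.cross(tdir[degenerate], np.array([1.0, 0.0, 0.0]))
        circ[degenerate] = alt
        norm[degenerate] = np.linalg.norm(alt, axis=1)
    circ /= norm[:, None]
    longi = np.cross(tdir, circ)  # unit, orthogonal to tdir and circ
    a_endo = np.deg2rad(p.fiber_angle_endo_deg)
    a_epi = np.deg2rad(p.fiber_angle_epi_deg)
    alpha = a_endo + (a_epi - a_endo) * m
    fiber = circ * np.cos(alpha)[:, None] + longi * np.sin(alpha)[:, None]
    return fiber


def _hex_elements(node_index: np.ndarray, grid_shape) -> np.ndarray:
    """Lattice cells whose 8 corners are all myocardial (VTK corner order)."""
    ni, nj, nk = grid_shape
    c = node_index
    corners = [
        c[:-1, :-1, :-1], c[1:, :-1, :-1], c[1:, 1:, :-1], c[:-1, 1:, :-1],
        c[:-1, :-1, 1:], c[1:, :-1, 1:], c[1:, 1:, 1:], c[:-1, 1:, 1:],
    ]
    stack = np.stack([x.ravel() for x in corners], axis=1)
    ok = np.all(stack >= 0, axis=1)
    return stack[ok].astype(np.int64)


def extract_surface_nodes(mesh: BiventricularMesh, label: str) -> np.ndarray:
    """Node ids carrying a surface label (LV_ENDO, RV_ENDO, EPI or BASE)."""
    return np.flatnonzero(mesh.surface_mask(label))


def anat_to_node(
    mesh: BiventricularMesh,
    a: float,
    m: float,
    theta: float,
    side: str,
    surface: str | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0 / np.pi),
) -> int:
    """Node closest to an anatomical query ``(a, m, theta, side)``.

    Minimizes a weighted squared distance in anatomical-coordinate space
    (rotational differences are wrapped); candidates are restricted to the
    requested side and, optionally, to one surface label.  Ties break to
    the lowest node id.
    """
    if side not in SIDE_IDS:
        raise ValueError(f"unknown side {side!r}")
    cand = mesh.side == SIDE_IDS[side]
    if surface is not None:
        cand &= mesh.surface_mask(surface)
    cand_ids = np.flatnonzero(cand)
    if cand_ids.size == 0:
        raise ValueError(f"no candidate nodes for side={side} surface={surface}")
    wa, wm, wt = weights
    dth = np.abs(mesh.theta[cand_ids] - (theta % (2 * np.pi)))
    dth = np.minimum(dth, 2 * np.pi - dth)
    cost = (
        (wa * (mesh.a[cand_ids] - a)) ** 2
        + (wm * (mesh.m[cand_ids] - m)) ** 2
        + (wt * dth) ** 2
    )
    return int(cand_ids[np.argmin(cost)])  # argmin -> first = lowest id


def standard_electrodes(
    mesh: BiventricularMesh,
    chest_radius: float = 120.0,
    limb_distance: float = 400.0,
) -> ElectrodeSet:
    """Standard 9-electrode set in the patient frame, mapped to mesh frame.

    The limb electrodes RA/LA/LL sit on an equilateral (Einthoven) triangle
    of circumradius ``limb_distance`` in the frontal plane, centred on the
    heart, so the limb lead vectors point at 0/60/120 degrees exactly in
    the far field.  V1..V6 lie on an anterior-left chest arc of radius
    ``chest_radius``.
    """
    bounding = float(np.linalg.norm(mesh.nodes - mesh.centroid, axis=1).max())
    if chest_radius <= bounding:
        raise ValueError(
            f"chest radius {chest_radius} mm is inside the heart "
            f"(bounding radius {bounding:.1f} mm)"
        )
    L = float(limb_distance)
    R = float(chest_radius)
    limb = {
        "RA": np.array([-np.sqrt(3) / 2 * L, 0.0, L / 2]),
        "LA": np.array([np.sqrt(3) / 2 * L, 0.0, L / 2]),
        "LL": np.array([0.0, 0.0, -L]),
    }
    # (angle from anterior toward patient-left, superior offset)
    chest = {
        "V1": (-15.0, 0.0),
        "V2": (10.0, 0.0),
        "V3": (32.0, -10.0),
        "V4": (55.0, -20.0),
        "V5": (80.0, -20.0),
        "V6": (100.0, -20.0),
    }
    names = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")
    offsets = []
    for name in names:
        if name in limb:
            offsets.append(limb[name])
        else:
            phi, dz = chest[name]
            phi = np.deg2rad(phi)
            offsets.append(np.array([R * np.sin(phi), R * np.cos(phi), dz]))
    positions = mesh.patient_to_mesh(np.array(offsets))
    return ElectrodeSet(names=names, positions=positions)
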