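"""Pseudo-bidomain forward ECG: core-conductor volume-conductor integral.

During depolarization the transmembrane potential at every node is a
template upstroke shifted by the node's activation time (repolarization
and the T-wave are out of scope, so only the upstroke matters for the
QRS).  The extracellular potential at a body-surface point x follows the
core-conductor / infinite-volume-conductor integral

    phi_e(t, x) = -1/(4*pi*sigma_bulk) * integral_heart
                  (Sigma_i grad(Vm)) . grad_y(1/|x - y|) dOmega,

with Sigma_i the intracellular conductivity tensor in the local fiber
frame (phi_i ~ Vm: extracellular gradients are neglected in the source
term).  The bulk denominator carries the body conductivity (sigma_b and
its scale factor) and the extracellular scale factor, so that with a
frozen activation sequence amplitudes are exactly proportional to
``scale_i`` and exactly inversely proportional to ``scale_b`` and
``scale_e`` — the classical core-conductor proportionality
phi_e ∝ sigma_i/sigma_e.
The torso is an unbounded homogeneous conductor: bounded-torso damping of
conductivity effects is deliberately absent.

The integral is evaluated per hexahedral cell with trilinear finite
differences for grad(Vm), and the 12-lead ECG is assembled with the
standard Einthoven/Goldberger/Wilson definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation import (
    ActivationMap,
    ConductivitySet,
    RootConfig,
    V_REF_L_DEFAULT,
    compute_activation,
)
from .geometry import BiventricularMesh, ElectrodeSet, standard_electrodes

__all__ = [
    "CellParams",
    "TransmembraneField",
    "ECG12",
    "LEAD_NAMES",
    "ECG_CALIBRATION_DEFAULT",
    "upstroke_waveform",
    "transmembrane_field",
    "extracellular_potential",
    "ForwardOperator",
    "assemble_12lead",
    "simulate_ecg",
]

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

#: Amplitude calibration so the baseline simulation has a lead-II R peak of
#: 1.0 mV (documented convention; raw units are otherwise arbitrary).
ECG_CALIBRATION_DEFAULT = 23.661


@dataclass(frozen=True)
class CellParams:
    """Template action-potential upstroke: resting/peak levels and rise time."""

    v_rest: float = -85.0  # mV
    v_peak: float = 20.0   # mV
    tau: float = 0.5       # ms; 10-90% rise time ~ 2.2 * tau

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def upstroke_waveform(t_rel: np.ndarray | float, params: CellParams | None = None) -> np.ndarray:
    """Sigmoidal V_rest -> V_peak transition centred at t_rel = 0 (mV)."""
    p = params or CellParams()
    x = np.clip(np.asarray(t_rel, dtype=float) * (2.0 / p.tau), -500.0, 500.0)
    return p.v_rest + (p.v_peak - p.v_rest) / (1.0 + np.exp(-x))


@dataclass
class TransmembraneField:
    """Vm(node, t): upstroke shifted by each node's activation time."""

    times: np.ndarray      # (T,) ms
    vm: np.ndarray         # (T, N) mV
    params: CellParams
    fs: float              # Hz


def transmembrane_field(
    activation: ActivationMap,
    params: CellParams | None = None,
    fs: float = 1000.0,
    t_end: float | None = None,
    margin: float = 15.0,
) -> TransmembraneField:
    """Sample Vm(x, t) = upstroke(t - t_act(x)) on a regular time grid."""
    p = params or CellParams()
    t_act = activation.t_act
    if not np.isfinite(t_act).all():
        raise ValueError("activation map contains unreached nodes")
    if t_end is None:
        t_end = float(t_act.max()) + margin
    elif t_end < t_act.max():
        raise ValueError("time window shorter than the latest activation")
    times = np.arange(0.0, t_end, 1000.0 / fs)
    vm = upstroke_waveform(times[:, None] - t_act[None, :], p)
    return TransmembraneField(times=times, vm=vm, params=p, fs=fs)


# hexahedron corners with positive offset along each axis (VTK ordering)
_XP = (1, 2, 5, 6)
_YP = (2, 3, 6, 7)
_ZP = (4, 5, 6, 7)


class ForwardOperator:
    """Precomputed lead-field map from nodal Vm to electrode potentials.

    For each electrode, the per-cell vector ``A_c = Sigma_i,c^T g_c vol_c``
    (g the gradient of 1/r at the cell centroid) is precomputed once; a
    time sample then costs one cell-gradient evaluation and one dot
    product.
    """

    def __init__(
        self,
        mesh: BiventricularMesh,
        cond: ConductivitySet | None = None,
        electrodes: ElectrodeSet | None = None,
    ):
        self.mesh = mesh
        self.cond = cond or ConductivitySet()
        self.electrodes = electrodes or standard_electrodes(mesh)
        elems = mesh.elements
        if elems.size == 0:
            raise ValueError("mesh has no hexahedral elements")
        self._elems = elems
        centroids = mesh.nodes[elems].mean(axis=1)
        vol = mesh.spacing**3
        fiber = mesh.fiber_dir[elems].mean(axis=1)
        fiber /= np.linalg.norm(fiber, axis=1, keepdims=True)

        c = self.cond
        si_l, si_t = c.scale_i * c.sigma_il, c.scale_i * c.sigma_it
        # Sigma_i g = si_t * g + (si_l - si_t) * (f.g) f
        pref = -vol / (4.0 * np.pi * c.sigma_b * c.scale_b * c.scale_e)
        A = np.empty((9, elems.shape[0], 3))
        for e, pos in enumerate(self.electrodes.positions):
            d = pos[None, :] - centroids
            r3 = np.linalg.norm(d, axis=1, keepdims=True) ** 3
            if np.any(r3 == 0.0):
                raise ValueError("electrode coincides with a cell centroid")
            g = d / r3
            fg = np.einsum("ij,ij->i", fiber, g)
            A[e] = pref * (si_t * g + (si_l - si_t) * fg[:, None] * fiber)
        self._A = A.reshape(9, -1)  # (9, 3*M)
        self._inv_spacing = 1.0 / mesh.spacing

    def _cell_gradients(self, vm: np.ndarray) -> np.ndarray:
        v = vm[self._elems]  # (M, 8)
        gx = (v[:, _XP].mean(axis=1) - v[:, [i for i in range(8) if i not in _XP]].mean(axis=1))
        gy = (v[:, _YP].mean(axis=1) - v[:, [i for i in range(8) if i not in _YP]].mean(axis=1))
        gz = (v[:, _ZP].mean(axis=1) - v[:, [i for i in range(8) if i not in _ZP]].mean(axis=1))
        return np.stack([gx, gy, gz], axis=1) * self._inv_spacing

    def potentials_at(self, vm: np.ndarray) -> np.ndarray:
        """Electrode potentials (9,) for one nodal Vm sample."""
        grad = self._cell_gradients(vm)
        return self._A @ grad.ravel()

    def run(
        self,
        activation: ActivationMap,
        params: CellParams | None = None,
        fs: float = 1000.0,
        t_end: float | None = None,
        margin: float = 15.0,
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Electrode potential traces for a full activation sequence."""
        p = params or CellParams()
        t_act = activation.t_act
        if not np.isfinite(t_act).all():
            raise ValueError("activation map contains unreached nodes")
        if t_end is None:
            t_end = float(t_act.max()) + margin
        times = np.arange(0.0, t_end, 1000.0 / fs)
        traces = np.empty((9, times.size))
        for k, t in enumerate(times):
            vm = upstroke_waveform(t - t_act, p)
            traces[:, k] = self.potentials_at(vm)
        return times, {n: traces[i] for i, n in enumerate(self.electrodes.names)}


def extracellular_potential(
    mesh: BiventricularMesh,
    vm: np.ndarray,
    electrode_pos: np.ndarray,
    cond: ConductivitySet | None = None,
) -> float:
    """One-shot core-conductor integral at a single point (arbitrary units).

    Convenience wrapper over the same per-cell quadrature the
    ``ForwardOperator`` uses; the electrode must lie outside the
    myocardial volume.
    """
    cond = cond or ConductivitySet()
    pos = np.asarray(electrode_pos, dtype=float)
    d_min = np.linalg.norm(mesh.nodes - pos, axis=1).min()
    if d_min < mesh.spacing:
        raise ValueError("electrode lies inside (or on) the myocardial volume")
    elems = mesh.elements
    centroids = mesh.nodes[elems].mean(axis=1)
    vol = mesh.spacing**3
    fiber = mesh.fiber_dir[elems].mean(axis=1)
    fiber /= np.linalg.norm(fiber, axis=1, keepdims=True)
    si_l, si_t = cond.scale_i * cond.sigma_il, cond.scale_i * cond.sigma_it
    v = vm[elems]
    gx = (v[:, _XP].mean(axis=1) - v[:, [i for i in range(8) if i not in _XP]].mean(axis=1))
    gy = (v[:, _YP].mean(axis=1) - v[:, [i for i in range(8) if i not in _YP]].mean(axis=1))
    gz = (v[:, _ZP].mean(axis=1) - v[:, [i for i in range(8) if i not in _ZP]].mean(axis=1))
    grad = np.stack([gx, gy, gz], axis=1) / mesh.spacing
    d = pos[None, :] - centroids
    g = d / np.linalg.norm(d, axis=1, keepdims=True) ** 3
    fg = np.einsum("ij,ij->i", fiber, grad)
    source = si_t * grad + (si_l - si_t) * fg[:, None] * fiber
    pref = -vol / (4.0 * np.pi * cond.sigma_b * cond.scale_b * cond.scale_e)
    return float(pref * np.einsum("ij,ij->", source, g))


@dataclass
class ECG12:
    """12-lead ECG traces plus the raw electrode potentials."""

    time: np.ndarray                       # (T,) ms
    leads: dict[str, np.ndarray]           # lead name -> (T,) mV
    fs: float
    electrode_potentials: dict[str, np.ndarray]
    calibration: float

    def lead_matrix(self) -> np.ndarray:
        return np.stack([self.leads[n] for n in LEAD_NAMES], axis=0)


def assemble_12lead(
    potentials: dict[str, np.ndarray],
    fs: float,
    time: np.ndarray,
    calibration: float = ECG_CALIBRATION_DEFAULT,
) -> ECG12:
    """Standard 12-lead assembly from 9 electrode potentials.

    Einthoven: I = LA-RA, II = LL-RA, III = LL-LA; Goldberger augmented
    leads; precordial leads referenced to the Wilson central terminal
    (RA+LA+LL)/3.  ``calibration`` converts raw volume-conductor units to
    mV (convention: baseline lead-II R peak = 1.0 mV).
    """
    required = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")
    missing = [n for n in required if n not in potentials]
    if missing:
        raise ValueError(f"missing electrode traces: {missing}")
    lengths = {len(v) for v in potentials.values()}
    if len(lengths) != 1:
        raise ValueError("electrode traces must have equal length")
    ra, la, ll = potentials["RA"], potentials["LA"], potentials["LL"]
    wct = (ra + la + ll) / 3.0
    leads = {
        "I": la - ra,
        "II": ll - ra,
        "III": ll - la,
        "aVR": ra - (la + ll) / 2.0,
        "aVL": la - (ra + ll) / 2.0,
        "aVF": ll - (ra + la) / 2.0,
    }
    for k in ("V1", "V2", "V3", "V4", "V5", "V6"):
        leads[k] = potentials[k] - wct
    leads = {k: calibration * v for k, v in leads.items()}
    return ECG12(
        time=time,
        leads=leads,
        fs=fs,
        electrode_potentials=dict(potentials),
        calibration=calibration,
    )


def simulate_ecg(
    mesh: BiventricularMesh,
    roots: RootConfig,
    cond: ConductivitySet | None = None,
    electrodes: ElectrodeSet | None = None,
    v_ref_l: float = V_REF_L_DEFAULT,
    cell_params: CellParams | None = None,
    fs: float = 1000.0,
    t_end: float | None = None,
    calibration: float = ECG_CALIBRATION_DEFAULT,
    activation: ActivationMap | None = None,
) -> ECG12:
    """End-to-end 12-lead QRS simulation (deterministic for fixed inputs).

    Passing a precomputed ``activation`` freezes the activation sequence,
    which isolates the purely multiplicative amplitude effects of the
    conductivity scale factors in the forward model.
    """
    cond = cond or ConductivitySet()
    if activation is None:
        activation = compute_activation(mesh, roots, cond, v_ref_l)
    op = ForwardOperator(mesh, cond, electrodes)
    times, pots = op.run(activation, params=cell_params, fs=fs, t_end=t_end)
    return assemble_12lead(pots, fs=fs, time=times, calibration=calibration)
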