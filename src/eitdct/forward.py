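"""FEM forward solver for 2D time-difference EIT.

Solves the electrostatic potential for the adjacent stimulation protocol
(current driven between each pair of neighbouring electrodes in turn,
voltages measured between all neighbouring pairs not touching a driven
electrode), giving ``n_elec * (n_elec - 3)`` measurements per frame.  Linear
(P1) triangular elements, point electrodes: current is injected at the
electrode node groups.  The potential is grounded at node 0; measurements
are potential differences, so the grounding choice is immaterial.

The Jacobian of the measurements with respect to per-element conductivity is
computed with the standard adjoint formula: for measurement i driven on pair
d and measured on pair m,

    J[i, j] = - grad(u_d) . grad(u_m) * area_j   on element j,

with u_d and u_m the unit-current fields of the two pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .mesh import Mesh


class NumericalError(RuntimeError):
    """Raised when the discrete forward problem cannot be solved."""


@dataclass(frozen=True)
class StimulationProtocol:
    """Adjacent drive/measurement protocol.

    ``pairs[i]`` is ``(drive_electrode, measurement_electrode)``: current is
    driven between electrodes (d, d+1) and voltage measured between
    (m, m+1), skipping measurement pairs that touch a driven electrode.
    """

    n_elec: int = 16
    current: float = 1.0

    @property
    def n_meas(self) -> int:
        return self.n_elec * (self.n_elec - 3)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        out = []
        for d in range(self.n_elec):
            skip = {(d - 1) % self.n_elec, d, (d + 1) % self.n_elec}
            for m in range(self.n_elec):
                if m not in skip:
                    out.append((d, m))
        return out


@dataclass(frozen=True)
class ConductivityField:
    """Per-element conductivity, arbitrary relative units (all entries > 0)."""

    sigma: np.ndarray
    baseline: bool = False

    def __post_init__(self):
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("conductivity must be strictly positive")


@dataclass(frozen=True)
class VoltageFrame:
    v: np.ndarray
    protocol: StimulationProtocol = field(default=StimulationProtocol())

    def __post_init__(self):
        if len(self.v) != self.protocol.n_meas:
            raise ValueError(
                f"frame length {len(self.v)} != protocol n_meas {self.protocol.n_meas}"
            )


@dataclass(frozen=True)
class Jacobian:
    """Sensitivity matrix d(v)/d(sigma), shape n_meas x n_elem."""

    J: np.ndarray
    sigma_baseline: np.ndarray


def _element_gradients(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element gradient operators G (n_elem, 2, 3) with grad u = G @ u_nodes."""
    p = mesh.nodes[mesh.elements]  # (n_elem, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = mesh.element_areas()
    G = np.stack([b, c], axis=1) / (2.0 * area)[:, None, None]
    return G, area


def _stiffness(mesh: Mesh, sigma: np.ndarray) -> sparse.csc_matrix:
    G, area = _element_gradients(mesh)
    # local 3x3 blocks: sigma * area * G^T G
    local = np.einsum("eki,ekj->eij", G, G) * (sigma * area)[:, None, None]
    rows = np.repeat(mesh.elements, 3, axis=1).reshape(-1)
    cols = np.tile(mesh.elements, (1, 3)).reshape(-1)
    K = sparse.coo_matrix((local.reshape(-1), (rows, cols)),
                          shape=(len(mesh.nodes),) * 2)
    return K.tocsc()


def _electrode_node(mesh: Mesh, e: int) -> int:
    return mesh.electrode_nodes[e][0]


def _pair_current_vectors(mesh: Mesh, protocol: StimulationProtocol) -> np.ndarray:
    """Current vector for each adjacent pair (e, e+1), shape (n_nodes, n_elec)."""
    n = len(mesh.nodes)
    B = np.zeros((n, protocol.n_elec))
    for e in range(protocol.n_elec):
        for node in mesh.electrode_nodes[e]:
            B[node, e] += protocol.current / len(mesh.electrode_nodes[e])
        nxt = (e + 1) % protocol.n_elec
        for node in mesh.electrode_nodes[nxt]:
            B[node, e] -= protocol.current / len(mesh.electrode_nodes[nxt])
    return B


def _solve_all_pairs(mesh: Mesh, sigma: np.ndarray,
                     protocol: StimulationProtocol) -> np.ndarray:
    """Nodal potentials for unit current on every adjacent pair (n_nodes, n_elec)."""
    K = _stiffness(mesh, sigma)
    B = _pair_current_vectors(mesh, protocol)
    # ground node 0: solve the symmetric reduced system
    Kr = K[1:, :][:, 1:]
    try:
        lu = splu(Kr.tocsc())
    except RuntimeError as exc:  # pragma: no cover - singular only on bad input
        raise NumericalError(f"singular FEM system: {exc}") from exc
    U = np.zeros_like(B)
    U[1:, :] = lu.solve(B[1:, :])
    if not np.all(np.isfinite(U)):
        raise NumericalError("FEM solve produced non-finite potentials")
    return U


def _measure(mesh: Mesh, U: np.ndarray, protocol: StimulationProtocol) -> np.ndarray:
    v = np.empty(protocol.n_meas)
    for i, (d, m) in enumerate(protocol.pairs):
        nm = _electrode_node(mesh, m)
        np1 = _electrode_node(mesh, (m + 1) % protocol.n_elec)
        v[i] = U[nm, d] - U[np1, d]
    return v


def solve_forward(mesh: Mesh, field: ConductivityField,
                  protocol: StimulationProtocol | None = None) -> VoltageFrame:
    """Boundary voltages of the adjacent protocol for one conductivity field."""
    protocol = protocol or StimulationProtocol(n_elec=mesh.n_elec)
    sigma = np.asarray(field.sigma, float)
    if len(sigma) != mesh.n_elem:
        raise ValueError("conductivity length != n_elem")
    U = _solve_all_pairs(mesh, sigma, protocol)
    return VoltageFrame(v=_measure(mesh, U, protocol), protocol=protocol)


def assign_conductivity(mesh: Mesh, mask: np.ndarray, extent,
                        sigma_in: float, sigma_out: float,
                        base: np.ndarray | None = None) -> ConductivityField:
    """Per-element field: ``sigma_in`` where the element centroid falls on a
    mask pixel, else ``sigma_out`` (or the entry of ``base`` when given).

    ``extent`` is the :class:`~eitdct.geometry.RasterExtent` of ``mask``.
    """
    if sigma_in <= 0 or sigma_out <= 0:
        raise ValueError("conductivities must be positive")
    cent = mesh.element_centroids()
    if not np.all(extent.contains(cent[:, 0], cent[:, 1])):
        raise ValueError("raster extent does not cover the mesh")
    M, N = mask.shape
    col = np.clip(((cent[:, 0] - extent.x_min) / extent.dx).astype(int), 0, N - 1)
    row = np.clip(((extent.y_max - cent[:, 1]) / extent.dy).astype(int), 0, M - 1)
    inside = mask[row, col].astype(bool)
    sigma = np.full(mesh.n_elem, float(sigma_out)) if base is None \
        else np.asarray(base, float).copy()
    sigma[inside] = sigma_in
    return ConductivityField(sigma=sigma)


def compute_jacobian(mesh: Mesh, field: ConductivityField,
                     protocol: StimulationProtocol | None = None) -> Jacobian:
    """Adjoint-method Jacobian at the given linearization conductivity."""
    protocol = protocol or StimulationProtocol(n_elec=mesh.n_elec)
    sigma = np.asarray(field.sigma, float)
    U = _solve_all_pairs(mesh, sigma, protocol)
    G, area = _element_gradients(mesh)
    # per-pair element gradients: (n_elem, 2, n_elec)
    grads = np.einsum("eki,eip->ekp", G, U[mesh.elements])
    J = np.empty((protocol.n_meas, mesh.n_elem))
    for i, (d, m) in enumerate(protocol.pairs):
        J[i] = -np.einsum("ek,ek->e", grads[:, :, d], grads[:, :, m]) * area
    return Jacobian(J=J, sigma_baseline=sigma)


def normalize_difference(v: VoltageFrame, v_baseline: VoltageFrame) -> np.ndarray:
    """Normalized voltage difference y_i = (v_i - v0_i) / v0_i."""
    if v.protocol.n_elec != v_baseline.protocol.n_elec:
        raise ValueError("frames use different protocols")
    zero = np.where(v_baseline.v == 0)[0]
    if len(zero):
        raise NumericalError(
            f"zero baseline voltage at measurement index {zero[0]}"
        )
    return (v.v - v_baseline.v) / v_baseline.v


def normalized_jacobian(jac: Jacobian, v_baseline: VoltageFrame) -> np.ndarray:
    """Row-scale J by 1/v_baseline so it linearizes the normalized difference."""
    return jac.J / v_baseline.v[:, None]


def add_noise(y: np.ndarray, percent: float, seed: int) -> np.ndarray:
    """Add zero-mean Gaussian noise with std = (percent/100) * RMS(y)."""
    if percent < 0:
        raise ValueError("noise percent must be >= 0")
    if percent == 0:
        return np.asarray(y, float).copy()
    rng = np.random.default_rng(seed)
    rms = float(np.sqrt(np.mean(np.square(y))))
    return y + rng.normal(0.0, percent / 100.0 * rms, size=len(y))
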