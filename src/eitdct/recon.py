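"""One-step Gauss-Newton reconstruction and noise-figure calibration.

Time-difference EIT solves the linearized, regularized least-squares problem

    x_hat = argmin_x || J x - y ||^2 + lambda^2 || R x ||^2
          = (J^T J + lambda^2 R^T R)^-1 J^T y  =  B y,

where y is the (normalized) voltage change, J the Jacobian at the baseline
conductivity, and R a regularization prior: the Tikhonov prior R = I
(penalizing solution norm) or the Laplace prior, the discrete Laplacian over
the element face-adjacency graph (penalizing non-smooth solutions).

Regularization strength is made comparable across solvers by calibrating
lambda to a fixed amplitude noise figure

    NF = SNR_in / SNR_out
       = [ mean|y_ref| / E mean|n_i| ] / [ mean|B y_ref| / E mean|(B n)_i| ],

with n unit-variance Gaussian measurement noise.  Because E|(Bn)_i| is
proportional to the i-th row norm of B, NF has the closed form

    NF = mean|y_ref| * mean_i ||B_i|| / mean|B y_ref|

(the Gaussian constant sqrt(2/pi) cancels).  NF decreases monotonically
with lambda, so the paper's target NF = 0.5 is found by bisection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from .forward import Jacobian
from .mesh import Mesh

PriorKind = str  # {"tikhonov", "laplace", "identity_dct", "expected_solution"}


class CalibrationError(RuntimeError):
    """Raised when noise-figure calibration cannot bracket the target."""


@dataclass(frozen=True)
class RegularizationPrior:
    R: np.ndarray | sparse.spmatrix
    kind: PriorKind = "tikhonov"

    def rtr(self) -> np.ndarray:
        R = self.R
        if sparse.issparse(R):
            return np.asarray((R.T @ R).todense())
        return R.T @ R


def tikhonov_prior(n: int) -> RegularizationPrior:
    return RegularizationPrior(R=np.eye(n), kind="tikhonov")


def build_laplace_prior(mesh: Mesh) -> RegularizationPrior:
    """Discrete Laplacian over the element face-adjacency graph.

    R[j, j] = number of face-adjacent neighbours of element j (at most 3),
    R[j, k] = -1 for each adjacent pair; symmetric, zero row sums for
    interior elements.
    """
    edges: dict[tuple[int, int], list[int]] = {}
    for e, (a, b, c) in enumerate(mesh.elements):
        for u, v in ((a, b), (b, c), (c, a)):
            edges.setdefault((min(u, v), max(u, v)), []).append(e)
    rows, cols, vals = [], [], []
    deg = np.zeros(mesh.n_elem)
    for elems in edges.values():
        if len(elems) == 2:
            i, j = elems
            rows += [i, j]
            cols += [j, i]
            vals += [-1.0, -1.0]
            deg[i] += 1
            deg[j] += 1
    rows += list(range(mesh.n_elem))
    cols += list(range(mesh.n_elem))
    vals += list(deg)
    R = sparse.coo_matrix((vals, (rows, cols)),
                          shape=(mesh.n_elem,) * 2).tocsr()
    return RegularizationPrior(R=R, kind="laplace")


@dataclass(frozen=True)
class ReconstructionMatrix:
    """Precomputed linear map B from voltage change to solution coefficients."""

    B: np.ndarray
    lam: float
    prior_kind: PriorKind

    def apply(self, y: np.ndarray) -> np.ndarray:
        return self.B @ y


def _normal_matrix(J: np.ndarray, prior: RegularizationPrior,
                   lam: float) -> np.ndarray:
    return J.T @ J + lam**2 * prior.rtr()


def solve_one_step(jac: Jacobian | np.ndarray, y: np.ndarray,
                   prior: RegularizationPrior, lam: float,
                   shift: np.ndarray | None = None) -> np.ndarray:
    """Closed-form one-step solution x = (J^T J + lam^2 R^T R)^-1 J^T y.

    With ``shift`` = h (an expected solution) the penalty becomes
    ``||R (x - h)||^2``, drawing the solution towards h.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    J = jac.J if isinstance(jac, Jacobian) else np.asarray(jac)
    if J.shape[0] != len(y):
        raise ValueError("y length does not match Jacobian rows")
    A = _normal_matrix(J, prior, lam)
    rhs = J.T @ y
    if shift is not None:
        rhs = rhs + lam**2 * (prior.rtr() @ shift)
    try:
        c = cho_factor(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"normal matrix not positive definite (lambda={lam}): {exc}"
        ) from exc
    return cho_solve(c, rhs)


def reconstruction_matrix(jac: Jacobian | np.ndarray,
                          prior: RegularizationPrior,
                          lam: float) -> ReconstructionMatrix:
    """Precompute B = (J^T J + lam^2 R^T R)^-1 J^T."""
    J = jac.J if isinstance(jac, Jacobian) else np.asarray(jac)
    A = _normal_matrix(J, prior, lam)
    c = cho_factor(A)
    B = cho_solve(c, J.T)
    return ReconstructionMatrix(B=B, lam=lam, prior_kind=prior.kind)


def noise_figure(B: ReconstructionMatrix | np.ndarray, y_ref: np.ndarray,
                 output_map: np.ndarray | None = None) -> float:
    """Closed-form amplitude noise figure of a reconstruction matrix.

    ``output_map``, if given, maps solution coefficients to the image domain
    in which signal and noise amplitudes are measured (used by the DCT
    solver, whose coefficients are not themselves conductivities).
    """
    Bm = B.B if isinstance(B, ReconstructionMatrix) else np.asarray(B)
    if output_map is not None:
        Bm = output_map @ Bm
    sig_out = float(np.mean(np.abs(Bm @ y_ref)))
    if sig_out == 0:
        raise CalibrationError("reconstruction of the reference signal is zero")
    noise_out = float(np.mean(np.linalg.norm(Bm, axis=1)))
    sig_in = float(np.mean(np.abs(y_ref)))
    return sig_in * noise_out / sig_out


def noise_figure_monte_carlo(B: ReconstructionMatrix | np.ndarray,
                             y_ref: np.ndarray, n_trials: int = 10_000,
                             seed: int = 0,
                             output_map: np.ndarray | None = None) -> float:
    """Monte-Carlo estimate of the noise figure (oracle for the closed form)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    Bm = B.B if isinstance(B, ReconstructionMatrix) else np.asarray(B)
    if output_map is not None:
        Bm = output_map @ Bm
    rng = np.random.default_rng(seed)
    n = rng.standard_normal((Bm.shape[1], n_trials))
    noise_in = float(np.mean(np.abs(n)))
    noise_out = float(np.mean(np.abs(Bm @ n)))
    snr_in = float(np.mean(np.abs(y_ref))) / noise_in
    snr_out = float(np.mean(np.abs(Bm @ y_ref))) / noise_out
    return snr_in / snr_out


def calibrate_lambda_nf(jac: Jacobian | np.ndarray, prior: RegularizationPrior,
                        y_ref: np.ndarray, target_nf: float = 0.5,
                        tol: float = 1e-3,
                        output_map: np.ndarray | None = None,
                        report_path: str | Path | None = None) -> float:
    """Bisection search for lambda achieving |NF(lambda) - target_nf| <= tol.

    NF decreases monotonically with lambda; the bracket is expanded
    geometrically inside [1e-8, 1e8] until the target is enclosed.
    """
    if target_nf <= 0:
        raise ValueError("target_nf must be > 0")
    J = jac.J if isinstance(jac, Jacobian) else np.asarray(jac)

    def nf_at(lam: float) -> float:
        return noise_figure(reconstruction_matrix(J, prior, lam), y_ref,
                            output_map=output_map)

    lo, hi = 1e-2, 1.0  # lambda bracket; NF(lo) > NF(hi)
    nf_lo, nf_hi = nf_at(lo), nf_at(hi)
    while nf_lo < target_nf and lo > 1e-8:
        lo /= 10.0
        nf_lo = nf_at(lo)
    while nf_hi > target_nf and hi < 1e8:
        hi *= 10.0
        nf_hi = nf_at(hi)
    if not (nf_lo >= target_nf >= nf_hi):
        raise CalibrationError(
            f"target NF={target_nf} not bracketed: NF({lo:.2e})={nf_lo:.4g}, "
            f"NF({hi:.2e})={nf_hi:.4g}"
        )
    iterations = 0
    lam = np.sqrt(lo * hi)
    nf = nf_at(lam)
    while abs(nf - target_nf) > tol and iterations < 100:
        if nf > target_nf:
            lo = lam
        else:
            hi = lam
        lam = np.sqrt(lo * hi)
        nf = nf_at(lam)
        iterations += 1
    if abs(nf - target_nf) > tol:
        raise CalibrationError(
            f"bisection did not converge: NF({lam:.3e})={nf:.5f}"
        )
    if report_path is not None:
        Path(report_path).write_text(json.dumps({
            "lambda": lam, "nf_achieved": nf, "iterations": iterations,
            "bracket": [lo, hi], "prior": prior.kind,
        }, indent=2) + "\n")
    return float(lam)
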