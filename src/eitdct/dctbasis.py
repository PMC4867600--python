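"""Masked, truncated 2D DCT basis for shape-constrained EIT reconstruction.

The reconstructed conductivity change is expressed as a weighted sum of
low-frequency 2D cosine images restricted to a binary lung mask:

    C(p, q) = D(p, q) * L      (elementwise; L = binary lung image)
    H       = sum_j g_j C(p_j, q_j),

where D(p, q) is the orthonormal DCT-II basis image at frequencies (p, q).
Each masked basis image is mapped onto the FEM elements through the
pixel-to-element map, giving the basis matrix K (n_elem x n_DCT).  The
reduced Jacobian J_DCT = J K turns the inverse problem into a least-squares
fit of only n_DCT coefficients (default 15 x 15 = 225), and by construction
the synthesized image H is exactly zero outside the lungs.

Column j of K corresponds to frequencies (p, q) = (j // n_y, j % n_y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn, idctn

from .geometry import RasterExtent
from .mesh import Mesh


class BasisError(RuntimeError):
    """Raised when the masked DCT basis is rank deficient."""


@dataclass(frozen=True)
class DctGrid:
    """Raster dimensions and the retained frequencies per axis.

    Column index j maps to frequencies (p, q) = (j // n_y, j % n_y), with p
    the vertical (row) frequency and q the horizontal (column) frequency.
    """

    M: int = 64
    N: int = 64
    n_x: int = 15
    n_y: int = 15

    def __post_init__(self):
        if self.n_x > self.M or self.n_y > self.N:
            raise ValueError("retained frequencies exceed raster dimensions")

    @property
    def n_dct(self) -> int:
        return self.n_x * self.n_y

    def freq(self, j: int) -> tuple[int, int]:
        return divmod(j, self.n_y)


def dct_basis_image(p: int, q: int, M: int, N: int) -> np.ndarray:
    """Orthonormal DCT-II basis image at frequencies (p, q).

    D[m, n] = a_p a_q cos(pi (2m+1) p / 2M) cos(pi (2n+1) q / 2N) with
    a_0 = sqrt(1/M) and a_k = sqrt(2/M) for k > 0 (and likewise for N).
    """
    if not (0 <= p < M and 0 <= q < N):
        raise ValueError(f"frequencies ({p},{q}) out of range for {M}x{N}")
    ap = np.sqrt(1.0 / M) if p == 0 else np.sqrt(2.0 / M)
    aq = np.sqrt(1.0 / N) if q == 0 else np.sqrt(2.0 / N)
    m = np.arange(M)
    n = np.arange(N)
    col = np.cos(np.pi * (2 * m + 1) * p / (2 * M))
    row = np.cos(np.pi * (2 * n + 1) * q / (2 * N))
    return ap * aq * np.outer(col, row)


def dct2_truncated_roundtrip(A: np.ndarray, keep: int) -> np.ndarray:
    """Forward 2D DCT, zero coefficients with row/col index >= keep, invert.

    This is the classic lossy-compression demonstration: keeping the
    ``keep`` lowest frequencies per axis discards a fraction
    ``1 - keep**2 / (M*N)`` of the coefficients.
    """
    A = np.asarray(A, float)
    if keep > min(A.shape):
        raise ValueError("keep exceeds raster dimensions")
    V = dctn(A, norm="ortho")
    V[keep:, :] = 0.0
    V[:, keep:] = 0.0
    return idctn(V, norm="ortho")


def mask_basis(D: np.ndarray, lung_mask: np.ndarray) -> np.ndarray:
    """C(p, q) = D elementwise-multiplied by the binary lung image."""
    if D.shape != lung_mask.shape:
        raise ValueError("basis image and lung mask shapes differ")
    return D * (lung_mask != 0)


def basis_image_stack(grid: DctGrid, lung_mask: np.ndarray) -> np.ndarray:
    """All masked basis images C(p_j, q_j), shape (n_dct, M, N)."""
    out = np.empty((grid.n_dct, grid.M, grid.N))
    for j in range(grid.n_dct):
        p, q = grid.freq(j)
        out[j] = mask_basis(dct_basis_image(p, q, grid.M, grid.N), lung_mask)
    return out


@dataclass(frozen=True)
class PixelElementMap:
    """For each pixel (m, n): index of the element covering its center, or -1."""

    element_of: np.ndarray  # (M, N) int
    extent: RasterExtent


def build_pixel_element_map(mesh: Mesh, extent: RasterExtent,
                            shape: tuple[int, int]) -> PixelElementMap:
    """Locate every pixel center in the mesh (lowest covering element wins).

    Uses a vectorized barycentric test per element over the pixels in its
    bounding box; pixels outside all elements map to -1.
    """
    M, N = shape
    X, Y = RasterExtent(extent.x_min, extent.x_max, extent.y_min,
                        extent.y_max, (M, N)).pixel_centers()
    px, py = X.ravel(), Y.ravel()
    out = np.full(M * N, -1, dtype=int)
    tri = mesh.nodes[mesh.elements]  # (n_elem, 3, 2)
    eps = 1e-12
    # iterate elements in reverse so the lowest index wins on shared edges
    for e in range(mesh.n_elem - 1, -1, -1):
        (x0, y0), (x1, y1), (x2, y2) = tri[e]
        det = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        cand = np.where(
            (px >= min(x0, x1, x2) - eps) & (px <= max(x0, x1, x2) + eps)
            & (py >= min(y0, y1, y2) - eps) & (py <= max(y0, y1, y2) + eps)
        )[0]
        if not len(cand):
            continue
        l0 = ((y1 - y2) * (px[cand] - x2) + (x2 - x1) * (py[cand] - y2)) / det
        l1 = ((y2 - y0) * (px[cand] - x2) + (x0 - x2) * (py[cand] - y2)) / det
        l2 = 1.0 - l0 - l1
        hit = (l0 >= -eps) & (l1 >= -eps) & (l2 >= -eps)
        out[cand[hit]] = e
    return PixelElementMap(element_of=out.reshape(M, N), extent=extent)


@dataclass(frozen=True)
class BasisMatrixK:
    """Masked-DCT basis mapped to FEM elements, shape (n_elem, n_dct)."""

    K: np.ndarray
    grid: DctGrid
    lung_mask: np.ndarray


def build_K(mesh: Mesh, lung_mask: np.ndarray, grid: DctGrid,
            pixel_map: PixelElementMap, reduce_rule: str = "mean"
            ) -> BasisMatrixK:
    """Aggregate each masked basis image onto the FEM elements.

    The entry for element e in column j is the ``reduce_rule`` aggregate
    (default: mean) of C(p_j, q_j) over the lung pixels whose center element
    is e.  Rows of elements containing no lung pixel are zero.  Raises
    :class:`BasisError` if the columns are not linearly independent.
    """
    if lung_mask.shape != (grid.M, grid.N):
        raise ValueError("lung mask shape inconsistent with DCT grid")
    if reduce_rule not in ("mean", "sum"):
        raise ValueError(f"unknown reduce_rule {reduce_rule!r}")
    lung = (lung_mask != 0).ravel()
    elem = pixel_map.element_of.ravel()
    sel = lung & (elem >= 0)
    if sel.sum() < grid.n_dct:
        raise BasisError(
            f"only {int(sel.sum())} lung pixels map into the mesh; "
            f"need at least n_dct = {grid.n_dct} for a valid basis"
        )
    elem_sel = elem[sel]
    counts = np.bincount(elem_sel, minlength=mesh.n_elem)
    C = basis_image_stack(grid, lung_mask).reshape(grid.n_dct, -1)[:, sel]
    K = np.zeros((mesh.n_elem, grid.n_dct))
    for j in range(grid.n_dct):
        K[:, j] = np.bincount(elem_sel, weights=C[j], minlength=mesh.n_elem)
    if reduce_rule == "mean":
        nz = counts > 0
        K[nz] /= counts[nz, None]
    rank = np.linalg.matrix_rank(K)
    if rank < grid.n_dct:
        raise BasisError(
            f"masked DCT basis is rank deficient: rank {rank} < {grid.n_dct}"
        )
    return BasisMatrixK(K=K, grid=grid, lung_mask=np.asarray(lung_mask))


@dataclass(frozen=True)
class DctCoefficients:
    g_hat: np.ndarray
    grid: DctGrid

    def __post_init__(self):
        if len(self.g_hat) != self.grid.n_dct:
            raise ValueError("coefficient length does not match grid")


def reconstruct_dct(J: np.ndarray, basis: BasisMatrixK, y: np.ndarray,
                    lam: float, prior=None,
                    expected: np.ndarray | None = None) -> DctCoefficients:
    """One-step solve for the DCT coefficients of the conductivity change.

    Minimizes ``||J K g - y||^2 + lam^2 ||R (g - h)||^2`` with R the
    identity by default and h the optional expected-solution coefficients.
    """
    from .recon import solve_one_step, tikhonov_prior

    if J.shape[1] != basis.K.shape[0]:
        raise ValueError("Jacobian columns do not match basis rows")
    prior = prior or tikhonov_prior(basis.grid.n_dct)
    if prior.rtr().shape[0] != basis.grid.n_dct:
        raise ValueError("prior dimension must equal n_dct")
    g = solve_one_step(J @ basis.K, y, prior, lam, shift=expected)
    return DctCoefficients(g_hat=g, grid=basis.grid)


def synthesize_image(coeffs: DctCoefficients, C_stack: np.ndarray) -> np.ndarray:
    """H = sum_j g_j C(p_j, q_j); exactly zero outside the lung mask."""
    if len(C_stack) != len(coeffs.g_hat):
        raise ValueError("coefficient/basis stack length mismatch")
    return np.tensordot(coeffs.g_hat, C_stack, axes=1)


def synthesis_operator(C_stack: np.ndarray,
                       lung_mask: np.ndarray | None = None) -> np.ndarray:
    """Matrix mapping coefficients to pixel values (rows = lung pixels).

    Used to evaluate the noise figure of the DCT solver in image space.
    """
    P = C_stack.reshape(len(C_stack), -1).T  # (M*N, n_dct)
    if lung_mask is not None:
        P = P[lung_mask.ravel() != 0]
    return P
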