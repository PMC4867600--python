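"""End-to-end simulation / calibration / reconstruction / evaluation studies.

The pipeline reproduces the reference simulation protocol on the synthetic
phantom: boundary voltages are simulated on a fine mesh (baseline: lung
conductivity 0.5, background 1; inflation: ventilated lung tissue drops to
0.25), while reconstruction uses a distinct, coarser mesh to avoid the
'inverse crime'.  All solvers (masked-DCT, Tikhonov, Laplace) are calibrated
to the same noise figure (default 0.5) against the homogeneous-ventilation
reference signal, then applied to the normalized voltage differences of each
ventilation pattern, with optional Gaussian measurement noise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dctbasis, evaluation, forward, recon
from .forward import StimulationProtocol
from .mesh import Mesh, build_mesh
from .phantom import (PhantomConfig, ThoraxPhantom, make_atelectasis_series,
                      make_thorax_phantom, make_ventilation_pattern)

logger = logging.getLogger(__name__)

SIGMA_BACKGROUND = 1.0
SIGMA_LUNG_BASELINE = 0.5
SIGMA_LUNG_VENTILATED = 0.25

METHODS = ("dct", "tikhonov", "laplace")


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of a simulation study; a pure value object (hashable to JSON)."""

    phantom: PhantomConfig = field(default=PhantomConfig())
    n_elec: int = 16
    sim_n_elem: int = 2000
    recon_n_elem: int = 1000
    n_x: int = 15
    n_y: int = 15
    alpha: float = 0.65
    target_nf: float = 0.5
    nf_tol: float = 1e-3
    noise_percents: tuple[float, ...] = (0.0, 25.0)
    n_noise_seeds: int = 1
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class InverseCrimeError(ValueError):
    """Simulation and reconstruction meshes must differ."""


@dataclass
class ReconstructionSuite:
    """Everything that is computed once per study configuration.

    Holds both meshes, the linearization Jacobian on the reconstruction
    mesh, the masked DCT basis, and the NF-calibrated reconstruction
    matrices of all three solvers.
    """

    config: StudyConfig
    phantom: ThoraxPhantom
    sim_mesh: Mesh
    recon_mesh: Mesh
    protocol: StimulationProtocol
    sim_baseline: forward.ConductivityField
    vb_sim: forward.VoltageFrame
    J_norm: np.ndarray
    y_ref: np.ndarray
    pixel_map: dctbasis.PixelElementMap
    C_stack: np.ndarray
    basis: dctbasis.BasisMatrixK
    lambdas: dict[str, float]
    recon_mats: dict[str, recon.ReconstructionMatrix]
    nf_achieved: dict[str, float]

    @property
    def roi(self) -> np.ndarray:
        return self.phantom.thorax_mask().astype(bool)


def _pattern_a_reference(recon_mesh: Mesh, phantom: ThoraxPhantom,
                         protocol: StimulationProtocol) -> np.ndarray:
    """Noise-free homogeneous-ventilation signal on the reconstruction mesh."""
    base = forward.assign_conductivity(
        recon_mesh, phantom.lung_mask, phantom.extent,
        SIGMA_LUNG_BASELINE, SIGMA_BACKGROUND)
    infl = forward.assign_conductivity(
        recon_mesh, phantom.lung_mask, phantom.extent,
        SIGMA_LUNG_VENTILATED, SIGMA_BACKGROUND)
    vb = forward.solve_forward(recon_mesh, base, protocol)
    v = forward.solve_forward(recon_mesh, infl, protocol)
    return forward.normalize_difference(v, vb)


def build_suite(config: StudyConfig | None = None) -> ReconstructionSuite:
    """Build meshes, Jacobian, DCT basis and NF-calibrated solvers."""
    cfg = config or StudyConfig()
    if cfg.sim_n_elem == cfg.recon_n_elem:
        raise InverseCrimeError(
            "sim_n_elem == recon_n_elem: refusing to commit the inverse crime"
        )
    t0 = time.perf_counter()
    phantom = make_thorax_phantom(cfg.phantom)
    protocol = StimulationProtocol(n_elec=cfg.n_elec)
    sim_mesh = build_mesh(phantom, cfg.n_elec, cfg.sim_n_elem)
    recon_mesh = build_mesh(phantom, cfg.n_elec, cfg.recon_n_elem)
    assert sim_mesh.n_elem != recon_mesh.n_elem, "inverse-crime guard"

    sim_baseline = forward.assign_conductivity(
        sim_mesh, phantom.lung_mask, phantom.extent,
        SIGMA_LUNG_BASELINE, SIGMA_BACKGROUND)
    vb_sim = forward.solve_forward(sim_mesh, sim_baseline, protocol)

    lin = forward.assign_conductivity(
        recon_mesh, phantom.lung_mask, phantom.extent,
        SIGMA_LUNG_BASELINE, SIGMA_BACKGROUND)
    vb_recon = forward.solve_forward(recon_mesh, lin, protocol)
    jac = forward.compute_jacobian(recon_mesh, lin, protocol)
    J_norm = forward.normalized_jacobian(jac, vb_recon)
    y_ref = _pattern_a_reference(recon_mesh, phantom, protocol)

    M, N = phantom.raster_shape
    grid = dctbasis.DctGrid(M=M, N=N, n_x=cfg.n_x, n_y=cfg.n_y)
    pixel_map = dctbasis.build_pixel_element_map(recon_mesh, phantom.extent,
                                                (M, N))
    C_stack = dctbasis.basis_image_stack(grid, phantom.lung_mask)
    basis = dctbasis.build_K(recon_mesh, phantom.lung_mask, grid, pixel_map)

    J_dct = J_norm @ basis.K
    synth = dctbasis.synthesis_operator(C_stack, phantom.lung_mask)
    systems = {
        "dct": (J_dct, recon.tikhonov_prior(grid.n_dct), synth),
        "tikhonov": (J_norm, recon.tikhonov_prior(recon_mesh.n_elem), None),
        "laplace": (J_norm, recon.build_laplace_prior(recon_mesh), None),
    }
    lambdas, recon_mats, nf_achieved = {}, {}, {}
    for name, (J, prior, outmap) in systems.items():
        lam = recon.calibrate_lambda_nf(J, prior, y_ref,
                                        target_nf=cfg.target_nf,
                                        tol=cfg.nf_tol, output_map=outmap)
        B = recon.reconstruction_matrix(J, prior, lam)
        lambdas[name] = lam
        recon_mats[name] = B
        nf_achieved[name] = recon.noise_figure(B, y_ref, output_map=outmap)
        logger.info("calibrated %s: lambda=%.4e NF=%.5f", name, lam,
                    nf_achieved[name])
    logger.info("suite built in %.1f s (config %s)",
                time.perf_counter() - t0, cfg.config_hash())
    return ReconstructionSuite(
        config=cfg, phantom=phantom, sim_mesh=sim_mesh, recon_mesh=recon_mesh,
        protocol=protocol, sim_baseline=sim_baseline, vb_sim=vb_sim,
        J_norm=J_norm, y_ref=y_ref, pixel_map=pixel_map, C_stack=C_stack,
        basis=basis, lambdas=lambdas, recon_mats=recon_mats,
        nf_achieved=nf_achieved)


def simulate_pattern(suite: ReconstructionSuite, ventilated_mask: np.ndarray,
                     noise_percent: float = 0.0, seed: int = 0) -> np.ndarray:
    """Normalized voltage difference of one ventilation pattern (+ noise)."""
    infl = forward.assign_conductivity(
        suite.sim_mesh, ventilated_mask, suite.phantom.extent,
        SIGMA_LUNG_VENTILATED, SIGMA_BACKGROUND,
        base=suite.sim_baseline.sigma)
    v = forward.solve_forward(suite.sim_mesh, infl, suite.protocol)
    y = forward.normalize_difference(v, suite.vb_sim)
    return forward.add_noise(y, noise_percent, seed)


def reconstruct_all(suite: ReconstructionSuite, y: np.ndarray
                    ) -> dict[str, np.ndarray]:
    """Raster images of the conductivity change for all three solvers."""
    out = {}
    for name, B in suite.recon_mats.items():
        x = B.apply(y)
        if name == "dct":
            coeffs = dctbasis.DctCoefficients(g_hat=x, grid=suite.basis.grid)
            out[name] = dctbasis.synthesize_image(coeffs, suite.C_stack)
        else:
            out[name] = evaluation.rasterize_fem_solution(
                suite.recon_mesh, x, suite.pixel_map)
    return out


def score_reconstruction(suite: ReconstructionSuite, H: np.ndarray,
                         ventilated_mask: np.ndarray
                         ) -> evaluation.ClassificationResult:
    pred = evaluation.classify_pixels(H, suite.config.alpha)
    t = suite.config.alpha * float(np.min(H))
    return evaluation.confusion_fractions(pred, ventilated_mask, suite.roi,
                                          alpha=suite.config.alpha,
                                          threshold=t)


def _truth_image(ventilated_mask: np.ndarray) -> np.ndarray:
    """Ground-truth conductivity-change raster (peak-normalized to -1)."""
    return -1.0 * (np.asarray(ventilated_mask) != 0)


def _noise_seed(base_seed: int, tag: str, k: int) -> int:
    h = hashlib.sha256(f"{base_seed}:{tag}:{k}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pattern_study(config: StudyConfig | None = None,
                      suite: ReconstructionSuite | None = None,
                      out_dir: str | Path | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Patterns a-d x noise levels x solvers: G-fraction table and images.

    Returns a tidy DataFrame (pattern, noise_percent, method, g1..g4,
    correct, lambda) and a dict of the reconstructed rasters keyed by
    (pattern, noise_percent, method).  With several noise seeds the
    fractions are averaged and the first seed's image kept.
    """
    suite = suite or build_suite(config)
    cfg = suite.config
    rows, images = [], {}
    for pattern_id in ("a", "b", "c", "d"):
        pat = make_ventilation_pattern(suite.phantom, pattern_id)
        for noise in cfg.noise_percents:
            n_seeds = cfg.n_noise_seeds if noise > 0 else 1
            acc = {m: np.zeros(4) for m in METHODS}
            for k in range(n_seeds):
                seed = _noise_seed(cfg.seed, f"{pattern_id}:{noise}", k)
                y = simulate_pattern(suite, pat.ventilated_mask, noise, seed)
                recs = reconstruct_all(suite, y)
                for m, H in recs.items():
                    r = score_reconstruction(suite, H, pat.ventilated_mask)
                    acc[m] += np.array([r.g1, r.g2, r.g3, r.g4])
                    if k == 0:
                        images[(pattern_id, noise, m)] = H
            for m in METHODS:
                g1, g2, g3, g4 = acc[m] / n_seeds
                rows.append(dict(pattern=pattern_id, noise_percent=noise,
                                 method=m, g1=g1, g2=g2, g3=g3, g4=g4,
                                 correct=g1 + g4, lam=suite.lambdas[m]))
    table = pd.DataFrame(rows)
    if out_dir is not None:
        _write_bundle(out_dir, cfg, table, images, "pattern_study")
    return table, images


def run_atelectasis_study(config: StudyConfig | None = None,
                          suite: ReconstructionSuite | None = None,
                          n_levels: int = 25, max_fraction: float = 0.5,
                          noise_percent: float = 0.0,
                          out_dir: str | Path | None = None) -> pd.DataFrame:
    """l1 image error vs dorsal collapse fraction for all three solvers."""
    suite = suite or build_suite(config)
    cfg = suite.config
    series = make_atelectasis_series(suite.phantom, n_levels, max_fraction)
    rows = []
    for i, pat in enumerate(series):
        seed = _noise_seed(cfg.seed, f"atel:{noise_percent}", i)
        y = simulate_pattern(suite, pat.ventilated_mask, noise_percent, seed)
        recs = reconstruct_all(suite, y)
        truth = _truth_image(pat.ventilated_mask)
        for m, H in recs.items():
            err = evaluation.l1_image_difference(H, truth, roi=suite.roi)
            rows.append(dict(level=i, atelectasis_fraction=pat.atelectasis_fraction,
                             method=m, l1_error=err))
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "atelectasis_l1.csv", index=False)
        (out / "config.json").write_text(json.dumps(
            {"config_hash": cfg.config_hash(), **asdict(cfg)},
            indent=2, default=str) + "\n")
    return table


def _write_bundle(out_dir, cfg, table, images, name) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{name}_fractions.csv", index=False)
    for (pat, noise, m), H in images.items():
        np.savetxt(out / f"H_{pat}_noise{int(noise)}_{m}.csv", H,
                   delimiter=",")
    (out / "config.json").write_text(json.dumps(
        {"config_hash": cfg.config_hash(), **asdict(cfg)},
        indent=2, default=str) + "\n")


def render_overlay(H: np.ndarray, structural: np.ndarray,
                   out_path: str | Path) -> np.ndarray:
    """Alpha-blend the reconstruction over a grayscale structural image.

    Negative conductivity change is shown light blue to white (large
    negative change = white), positive change purple; pixels with no change
    stay fully transparent, so non-lung regions show the structural image
    unchanged.  Returns the blended RGB array and writes it as PNG.
    """
    if H.shape != structural.shape:
        raise ValueError("overlay and structural image sizes differ")
    from matplotlib.colors import LinearSegmentedColormap

    s = np.asarray(structural, float)
    s = (s - s.min()) / (s.max() - s.min()) if s.max() > s.min() else s * 0.0
    rgb = np.stack([s] * 3, axis=-1)

    peak = np.max(np.abs(H))
    cmap = LinearSegmentedColormap.from_list(
        "eit", [(0.55, 0.2, 0.6), (0.0, 0.0, 0.0), (0.55, 0.75, 0.95),
                (1.0, 1.0, 1.0)])
    if peak > 0:
        val = np.clip(-H / peak, -1, 1)  # +1 = strongest decrease -> white
        colored = cmap((val + 1) / 2)[..., :3]
        a = np.abs(H) / peak
        rgb = (1 - a[..., None]) * rgb + a[..., None] * colored
    out = (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    from PIL import Image

    Image.fromarray(out).save(Path(out_path))
    return out
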