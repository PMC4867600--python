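"""Plain-text and image I/O for masks, voltages, matrices and configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .forward import StimulationProtocol, VoltageFrame
from .phantom import PhantomConfig


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """8-bit grayscale PNG: 255 on mask pixels, 0 background."""
    img = (np.asarray(mask) != 0).astype(np.uint8) * 255
    Image.fromarray(img, mode="L").save(Path(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    img = np.asarray(Image.open(Path(path)).convert("L"))
    return (img >= 128).astype(np.uint8)


def write_mask_csv(mask: np.ndarray, path: str | Path) -> None:
    np.savetxt(Path(path), (np.asarray(mask) != 0).astype(int),
               fmt="%d", delimiter=",")


def read_mask_csv(path: str | Path) -> np.ndarray:
    return (np.loadtxt(Path(path), delimiter=",") != 0).astype(np.uint8)


def write_boundary_csv(boundary: np.ndarray, path: str | Path) -> None:
    np.savetxt(Path(path), boundary, delimiter=",", header="x,y", comments="")


def read_boundary_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter=",", skiprows=1)


def write_voltage_csv(frame: VoltageFrame, path: str | Path) -> None:
    """CSV with columns drive_pair, meas_pair, value."""
    n = frame.protocol.n_elec
    rows = [
        {"drive_pair": f"{d}-{(d + 1) % n}", "meas_pair": f"{m}-{(m + 1) % n}",
         "value": v}
        for (d, m), v in zip(frame.protocol.pairs, frame.v)
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_voltage_csv(path: str | Path,
                     protocol: StimulationProtocol | None = None) -> VoltageFrame:
    df = pd.read_csv(Path(path))
    if protocol is None:
        n_elec = int(round((3 + np.sqrt(9 + 4 * len(df))) / 2))
        protocol = StimulationProtocol(n_elec=n_elec)
    return VoltageFrame(v=df["value"].to_numpy(float), protocol=protocol)


def write_image_raster(H: np.ndarray, path: str | Path, bits: int = 16) -> None:
    """Grayscale raster of a real-valued image plus a sidecar JSON scale.

    Values are mapped linearly from [vmin, vmax] to the integer range; the
    sidecar ``<path>.json`` records vmin/vmax for exact de-scaling.
    """
    H = np.asarray(H, float)
    vmin, vmax = float(H.min()), float(H.max())
    span = vmax - vmin if vmax > vmin else 1.0
    top = 65535 if bits == 16 else 255
    scaled = np.round((H - vmin) / span * top).astype(
        np.uint16 if bits == 16 else np.uint8)
    Image.fromarray(scaled, mode="I;16" if bits == 16 else "L").save(Path(path))
    Path(str(path) + ".json").write_text(json.dumps(
        {"vmin": vmin, "vmax": vmax, "bits": bits}) + "\n")


def read_image_raster(path: str | Path) -> np.ndarray:
    meta = json.loads(Path(str(path) + ".json").read_text())
    raw = np.asarray(Image.open(Path(path)), dtype=float)
    top = 65535 if meta["bits"] == 16 else 255
    return raw / top * (meta["vmax"] - meta["vmin"]) + meta["vmin"]


def write_coefficients_csv(coeffs, path: str | Path) -> None:
    """DCT coefficients as CSV with p, q, value columns."""
    rows = [{"p": coeffs.grid.freq(j)[0], "q": coeffs.grid.freq(j)[1],
             "value": v} for j, v in enumerate(coeffs.g_hat)]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def load_phantom_config(path: str | Path) -> PhantomConfig:
    """Phantom parameters from a JSON or YAML key-value file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    for key in ("thorax_radii", "lung_radii", "lung_offsets", "raster_shape"):
        if key in data:
            data[key] = tuple(data[key])
    return PhantomConfig(**data)


def save_phantom_config(cfg: PhantomConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(cfg), indent=2) + "\n")
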