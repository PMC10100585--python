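"""Output helpers: HDF5 maps, PNG renderings, TIFF images, CSV diagnostics."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .solvability import SolvabilityMap, display_transform

__all__ = ["save_map_h5", "load_map_h5", "save_map_png", "save_image_tiff",
           "save_diagnostics_csv"]


def save_map_h5(path: str | Path, m: SolvabilityMap, attrs: dict | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("map", data=m.values)
        d.attrs["n_phantoms"] = m.n_phantoms
        for k, v in (attrs or {}).items():
            d.attrs[k] = v


def load_map_h5(path: str | Path) -> SolvabilityMap:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["map"]
        return SolvabilityMap(values=d[...], n_phantoms=int(d.attrs["n_phantoms"]))


def save_map_png(path: str | Path, m: SolvabilityMap) -> None:
    """Render the map after the nonlinear display transform, linear gray [0,1]."""
    import imageio.v3 as iio

    disp = display_transform(m.values)
    iio.imwrite(Path(path), (np.clip(disp, 0, 1) * 255).astype(np.uint8))


def save_image_tiff(path: str | Path, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def save_diagnostics_csv(path: str | Path, data_fit) -> None:
    lines = ["iteration,data_fit"]
    lines += [f"{k},{v!r}" for k, v in enumerate(data_fit)]
    Path(path).write_text("\n".join(lines) + "\n")
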