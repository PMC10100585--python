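"""End-to-end Monte Carlo experiment driver.

One experiment runs, for each of n random phantoms: generation on the fine
grid, fine-detector forward projection, Poisson noise, 3:1 detector bin-down,
reconstruction with every requested algorithm variant on the coarse grid, and
accumulation of the squared-error images into one solvability map per variant.
The fine-grid generator and the coarse-grid reconstructor are distinct
operators by construction (inverse-crime guard).

Runs are deterministic given (config, base seed): phantom m uses seed
base_seed + m, with phantom and noise draws on independent substreams.
Long runs can checkpoint their running sums and be resumed bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geometry import Detector, Geometry, ImageGrid, ViewSet, make_geometry, refine_geometry
from .phantom import EllipseRanges, downsample_truth, generate_phantom
from .projector import ProjectionOperator, add_poisson_noise, bin_down
from .recon import ReconConfig, default_step_size, reconstruct, support_from_truth
from .solvability import MapAccumulator, SolvabilityMap, map_summary, squared_error_image

__all__ = [
    "VariantSpec",
    "RunConfig",
    "RunReport",
    "ALL_VARIANTS",
    "run_experiment",
    "resume_experiment",
]

log = logging.getLogger("solvmap")


@dataclass(frozen=True)
class VariantSpec:
    """One algorithm variant: GD or ML-EM, with or without finite-support
    enforcement and the truncation modification."""

    algorithm: str
    use_support: bool = False
    use_truncation_modification: bool = False

    @property
    def name(self) -> str:
        parts = [self.algorithm]
        if self.use_support:
            parts.append("support")
        if self.use_truncation_modification:
            parts.append("mod")
        return "_".join(parts)


ALL_VARIANTS: tuple[VariantSpec, ...] = tuple(
    VariantSpec(alg, sup, mod)
    for alg in ("gd", "mlem")
    for sup, mod in ((True, True), (True, False), (False, True), (False, False))
)


@dataclass
class RunConfig:
    """Full experiment description (serialisable to/from YAML or JSON)."""

    geometry: Geometry
    n_phantoms: int = 1000
    base_seed: int = 0
    n_ellipses: int = 4
    ranges: EllipseRanges = field(default_factory=EllipseRanges)
    fine_factor: int = 3
    noise_enabled: bool = True
    counts_per_unit: float = 500.0
    variants: tuple[VariantSpec, ...] = ALL_VARIANTS
    gd_iterations: int = 200
    mlem_iterations: int = 100
    gd_alpha: float | None = None
    output_dir: str | None = None
    checkpoint_every: int = 10

    def __post_init__(self) -> None:
        if self.n_phantoms < 1:
            raise ValueError("need at least one phantom")
        if not self.variants:
            raise ValueError("need at least one algorithm variant")

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "phantoms": {
                "count": self.n_phantoms,
                "base_seed": self.base_seed,
                "n_ellipses": self.n_ellipses,
                "ranges": asdict(self.ranges),
            },
            "noise": {"enabled": self.noise_enabled,
                      "counts_per_unit": self.counts_per_unit},
            "recon": {
                "fine_factor": self.fine_factor,
                "gd_iterations": self.gd_iterations,
                "mlem_iterations": self.mlem_iterations,
                "gd_alpha": self.gd_alpha,
                "variants": [
                    {"algorithm": v.algorithm, "support": v.use_support,
                     "truncation_modification": v.use_truncation_modification}
                    for v in self.variants
                ],
            },
            "output": {"dir": self.output_dir,
                       "checkpoint_every": self.checkpoint_every},
        }

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        ph = d.get("phantoms", {})
        noise = d.get("noise", {})
        rec = d.get("recon", {})
        out = d.get("output", {})
        variants = tuple(
            VariantSpec(v["algorithm"], bool(v.get("support", False)),
                        bool(v.get("truncation_modification", False)))
            for v in rec.get("variants", [])
        ) or ALL_VARIANTS
        return RunConfig(
            geometry=Geometry.from_dict(d["geometry"]),
            n_phantoms=ph.get("count", 1000),
            base_seed=ph.get("base_seed", 0),
            n_ellipses=ph.get("n_ellipses", 4),
            ranges=EllipseRanges(**ph.get("ranges", {})),
            fine_factor=rec.get("fine_factor", 3),
            noise_enabled=noise.get("enabled", True),
            counts_per_unit=noise.get("counts_per_unit", 500.0),
            variants=variants,
            gd_iterations=rec.get("gd_iterations", 200),
            mlem_iterations=rec.get("mlem_iterations", 100),
            gd_alpha=rec.get("gd_alpha"),
            output_dir=out.get("dir"),
            checkpoint_every=out.get("checkpoint_every", 10),
        )

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        return RunConfig.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        """Hash of everything that affects the computed maps (not output paths)."""
        d = self.to_dict()
        d.pop("output", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()

    # --- canonical profiles --------------------------------------------
    @staticmethod
    def full_profile(truncated: bool = True, n_phantoms: int = 1000,
                     base_seed: int = 0, **kw) -> "RunConfig":
        """The full-fidelity study: 128x128 reconstruction from 384x384
        phantoms, 180 views over 180deg, 107-bin asymmetric (offset +39) or
        185-bin symmetric detector, 1000 phantoms."""
        det = Detector(107, 1.0, 39.0) if truncated else Detector(185, 1.0, 0.0)
        geom = make_geometry(ImageGrid(128, 128, 1.0), det, ViewSet(180, 0.0, 1.0))
        return RunConfig(geometry=geom, n_phantoms=n_phantoms,
                         base_seed=base_seed, **kw)

    @staticmethod
    def test_profile(truncated: bool = True, n_phantoms: int = 50,
                     base_seed: int = 0, **kw) -> "RunConfig":
        """Reduced half-scale profile (64x64 reconstruction from 192x192
        phantoms) with proportionally scaled detectors, for desk-scale runs."""
        det = Detector(53, 1.0, 19.0) if truncated else Detector(93, 1.0, 0.0)
        geom = make_geometry(ImageGrid(64, 64, 1.0), det, ViewSet(180, 0.0, 1.0))
        kw.setdefault("gd_iterations", 150)
        kw.setdefault("mlem_iterations", 80)
        return RunConfig(geometry=geom, n_phantoms=n_phantoms,
                         base_seed=base_seed, **kw)


@dataclass
class RunReport:
    """Per-variant map summaries plus provenance."""

    variants: dict  # name -> {"min":, "max":, "n":}
    maps: dict  # name -> SolvabilityMap
    files: dict  # name -> {"h5":, "png":}
    config: dict
    elapsed_seconds: float
    mean_truth: np.ndarray | None = None  # average ground truth over phantoms

    def to_dict(self) -> dict:
        return {
            "variants": self.variants,
            "files": self.files,
            "config": self.config,
            "elapsed_seconds": self.elapsed_seconds,
        }


def _checkpoint_path(cfg: RunConfig) -> Path | None:
    if cfg.output_dir is None:
        return None
    return Path(cfg.output_dir) / "checkpoint.npz"


def _save_checkpoint(path: Path, cfg: RunConfig, accs: dict,
                     truth_acc, last_m: int) -> None:
    arrays = {f"sum_{name}": acc.total for name, acc in accs.items()}
    np.savez(path, last_m=last_m, config_hash=cfg.config_hash(),
             truth_sum=truth_acc.total, **arrays)


def _load_checkpoint(path: Path, cfg: RunConfig, accs: dict, truth_acc) -> int:
    with np.load(path, allow_pickle=False) as ck:
        if str(ck["config_hash"]) != cfg.config_hash():
            raise ValueError(
                "checkpoint was produced with a different configuration; refusing to resume"
            )
        last_m = int(ck["last_m"])
        for name, acc in accs.items():
            acc.total[...] = ck[f"sum_{name}"]
            acc.count = last_m
        truth_acc.total[...] = ck["truth_sum"]
        truth_acc.count = last_m
    return last_m


def run_experiment(cfg: RunConfig, checkpoint: str | Path | None = None) -> RunReport:
    """Run (or resume) the Monte Carlo experiment and return the report.

    ``checkpoint`` optionally names an existing checkpoint file holding running
    sums; the resumed result is identical to an uninterrupted run because the
    per-phantom seeds depend only on the base seed and phantom index.
    """
    t0 = time.time()
    coarse = cfg.geometry
    fine = refine_geometry(coarse, cfg.fine_factor)
    assert fine != coarse, "generation and reconstruction must use distinct models"
    op_coarse = ProjectionOperator(coarse)
    op_fine = ProjectionOperator(fine)
    assert op_fine is not op_coarse

    alpha = cfg.gd_alpha
    if any(v.algorithm == "gd" for v in cfg.variants) and alpha is None:
        alpha = default_step_size(op_coarse)
        log.info("GD step size alpha = %.3e (power iteration)", alpha)

    grid_shape = (coarse.grid.n_rows, coarse.grid.n_cols)
    accs = {v.name: MapAccumulator(grid_shape) for v in cfg.variants}
    truth_acc = MapAccumulator(grid_shape)

    start_m = 0
    ck_path = Path(checkpoint) if checkpoint is not None else None
    if ck_path is not None and ck_path.exists():
        start_m = _load_checkpoint(ck_path, cfg, accs, truth_acc)
        log.info("resumed from checkpoint after phantom %d", start_m)

    out_ck = _checkpoint_path(cfg)
    if cfg.output_dir is not None:
        Path(cfg.output_dir).mkdir(parents=True, exist_ok=True)

    fine_grid = fine.grid
    for m in range(start_m + 1, cfg.n_phantoms + 1):
        seed = cfg.base_seed + m
        ph = generate_phantom(seed, fine_grid, cfg.n_ellipses, cfg.ranges)
        truth = downsample_truth(ph, cfg.fine_factor)
        truth_acc.add(truth)
        support = support_from_truth(truth)
        sino = op_fine.forward(ph.image)
        if cfg.noise_enabled:
            sino = add_poisson_noise(sino, cfg.counts_per_unit, seed=seed)
        data = bin_down(sino, cfg.fine_factor).zero_unmeasured()
        for v in cfg.variants:
            rcfg = ReconConfig(
                algorithm=v.algorithm,
                n_iterations=(cfg.gd_iterations if v.algorithm == "gd"
                              else cfg.mlem_iterations),
                step_size_alpha=alpha if v.algorithm == "gd" else None,
                use_support=v.use_support,
                use_truncation_modification=v.use_truncation_modification,
                support_mask=support if v.use_support else None,
            )
            res = reconstruct(data, op_coarse, rcfg)
            accs[v.name].add(squared_error_image(res.image, truth))
        if out_ck is not None and cfg.checkpoint_every and (
                m % cfg.checkpoint_every == 0 or m == cfg.n_phantoms):
            _save_checkpoint(out_ck, cfg, accs, truth_acc, m)
        log.info("phantom %d/%d done", m, cfg.n_phantoms)

    maps = {name: acc.result() for name, acc in accs.items()}
    summaries = {}
    files = {}
    for name, smap in maps.items():
        summaries[name] = {**map_summary(smap), "n": smap.n_phantoms}
        if cfg.output_dir is not None:
            from .io import save_map_h5, save_map_png

            h5 = Path(cfg.output_dir) / f"map_{name}.h5"
            png = Path(cfg.output_dir) / f"map_{name}.png"
            save_map_h5(h5, smap, attrs={"variant": name,
                                         "config_hash": cfg.config_hash()})
            save_map_png(png, smap)
            files[name] = {"h5": str(h5), "png": str(png)}

    report = RunReport(
        variants=summaries, maps=maps, files=files,
        config=cfg.to_dict(), elapsed_seconds=time.time() - t0,
        mean_truth=truth_acc.total / truth_acc.count,
    )
    if cfg.output_dir is not None:
        (Path(cfg.output_dir) / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2))
    return report


def resume_experiment(cfg: RunConfig, checkpoint: str | Path) -> RunReport:
    """Resume from a checkpoint written by an earlier, interrupted run."""
    ck = Path(checkpoint)
    if not ck.exists():
        return run_experiment(cfg)
    return run_experiment(cfg, checkpoint=ck)
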