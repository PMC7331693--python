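"""End-to-end orchestration: phantom or file-based cohorts -> cohort report.

Per animal the chain is lung segmentation -> velocimetry -> fractional
expansion -> histogram / double-Gaussian scoring -> volume/time curve and
expiratory time constant -> heart-blur QC; the cohort step normalises HD
against the littermate population. Every run writes its configuration
snapshot, a log with package versions and the seed, the cohort table
(CSV + JSON) and a QC table beside its outputs, so runs are reproducible
and individual stages reloadable.
"""

from __future__ import annotations

import dataclasses
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ConfigurationError, XVError
from .expansion import fractional_expansion
from .global_function import expiratory_time_constant, volume_time_curve
from .phantom import (
    PhantomConfig,
    ground_truth_fields,
    make_breath_curve,
    make_expansion_scene,
    make_lung_mask,
    make_speckle_sequence,
    xv_mask,
)
from .preprocess import detect_heart_blur, lung_volume, segment_lungs
from .quantify import CohortTable, cohort_scores, expansion_histogram, fit_double_gaussian
from .velocimetry import accumulate_fields, estimate_displacements

__all__ = ["RunConfig", "CohortReport", "run_pipeline", "analyse_fields"]


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    out_dir: str = "xv_run"
    seed: int = 0
    # phantom cohort settings (used when manifest is None)
    n_littermates: int = 3
    n_disease: int = 3
    disease_profile: str = "clustered"
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    phantom_overrides: dict = field(default_factory=dict)
    heart_blur_ids: list[str] = field(default_factory=list)
    heart_blur_fraction: float = 0.10
    # analysis settings
    engine: str = "measured"  # 'measured' (cross-correlation) or 'truth'
    window_size: int = 16
    overlap_fraction: float = 0.5
    n_bins: int = 50
    tau_threshold: float = 0.67
    zero_tol: float = 0.05
    blob_threshold: float = 0.05
    make_plots: bool = False
    # file-based cohort: CSV with columns id, group, paths (';'-separated phases)
    manifest: str | None = None

    def __post_init__(self) -> None:
        if self.engine not in ("measured", "truth"):
            raise ConfigurationError("engine must be 'measured' or 'truth'")
        if not (0 < self.tau_threshold < 1):
            raise ConfigurationError("tau_threshold must be in (0, 1)")
        self.grid_shape = tuple(self.grid_shape)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class CohortReport:
    cohort: CohortTable
    qc: pd.DataFrame
    out_dir: Path
    failures: list[str] = field(default_factory=list)


def analyse_fields(fields, fine_mask, times, voxel_size, cfg: RunConfig) -> dict:
    """Displacement fields -> expansion map, scores inputs, curve, tau, QC."""
    window = fields[0].window_size
    xvm = xv_mask(fine_mask, window, 1.0 - fields[0].grid_stride / window)
    total_volume = lung_volume(fine_mask, voxel_size)
    curve = volume_time_curve(fields, xvm, total_volume, voxel_size, times, fine_mask=fine_mask)
    tau = expiratory_time_constant(curve, cfg.tau_threshold)
    peak = curve.peak_phase
    emap = fractional_expansion(fields, xvm, peak_phase=peak, voxel_size=voxel_size)
    qc = detect_heart_blur(
        accumulate_fields(fields, peak), xvm, zero_tol=cfg.zero_tol, blob_threshold=cfg.blob_threshold
    )
    return {
        "expansion_map": emap,
        "curve": curve,
        "tau": tau,
        "fractional_tidal_volume": curve.tidal_fraction,
        "qc": qc,
    }


def _phantom_animals(cfg: RunConfig):
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=cfg.n_littermates + cfg.n_disease)
    animals = []
    for i in range(cfg.n_littermates):
        animals.append((f"L{i + 1:02d}", "littermate", "healthy", int(seeds[i])))
    for i in range(cfg.n_disease):
        animals.append(
            (f"D{i + 1:02d}", "disease", cfg.disease_profile, int(seeds[cfg.n_littermates + i]))
        )
    return animals


def _run_phantom_animal(animal_id, profile, seed, cfg: RunConfig) -> dict:
    overrides = dict(cfg.phantom_overrides)
    if animal_id in cfg.heart_blur_ids:
        overrides["heart_blur"] = cfg.heart_blur_fraction
    pc = PhantomConfig(grid_shape=cfg.grid_shape, profile=profile, seed=seed, **overrides)
    mask = make_lung_mask(pc)
    _, truth = make_expansion_scene(pc, mask)
    curve_true = make_breath_curve(pc)
    if cfg.engine == "measured":
        volumes, truth = make_speckle_sequence(truth, curve_true, pc)
        seg = segment_lungs(volumes[0])
        fields = estimate_displacements(
            volumes, window_size=cfg.window_size, overlap_fraction=cfg.overlap_fraction, mask=seg.data
        )
        fine_mask = seg.data
    else:
        volumes, truth = _attach_truth_fields(truth, curve_true, pc)
        fields = ground_truth_fields(truth, cfg.window_size, cfg.overlap_fraction)
        fine_mask = truth.lung_mask
    out = analyse_fields(fields, fine_mask, curve_true.times, pc.voxel_size, cfg)
    out["truth"] = truth
    return out


def _attach_truth_fields(truth, curve, pc):
    """Solve the displacement potential without rendering speckle volumes."""
    from .phantom import _solve_peak_displacement  # internal by design

    mask = truth.lung_mask
    e = truth.expansion_map
    mean_e = e[mask].mean() if mask.any() else 0.0
    tidal = curve.tidal_fraction
    scale = tidal / mean_e if (mean_e > 0 and tidal > 0) else 0.0
    e_peak = scale * e
    if scale == 0.0:
        u = np.zeros(e.shape + (3,), dtype=np.float32)
    else:
        u = _solve_peak_displacement(e_peak, mask)
        if truth.blur_region.any():
            u[truth.blur_region] = 0.0
        u = u.astype(np.float32)
    s = np.zeros(curve.n_phases) if tidal <= 0 else curve.fractional_volume / tidal
    truth = dataclasses.replace(
        truth,
        expansion_map=e_peak,
        peak_displacement=u,
        phase_scales=s,
        params={**truth.params, "expansion_scale": scale, "tidal_fraction": tidal},
    )
    return None, truth


def run_pipeline(config: RunConfig) -> CohortReport:
    """Execute the full chain for a cohort and write the report.

    Per-animal failures are recorded and the cohort continues; a failure of
    the cohort-level normalisation (no littermates) raises.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")

    records, extras, qc_rows, failures = [], {}, [], []
    if config.manifest is not None:
        per_animal = _file_animals(config)
    else:
        per_animal = [
            (animal_id, group, lambda a=animal_id, p=profile, s=seed: _run_phantom_animal(a, p, s, config))
            for animal_id, group, profile, seed in _phantom_animals(config)
        ]

    for animal_id, group, runner in per_animal:
        try:
            res = runner()
        except XVError as exc:
            failures.append(f"{animal_id}: {exc}")
            continue
        records.append((animal_id, group, res["expansion_map"]))
        qc = res["qc"]
        extras[animal_id] = {
            "tau": res["tau"],
            "fractional_tidal_volume": res["fractional_tidal_volume"],
            "heart_blur_flag": qc.heart_blur_flag,
        }
        qc_rows.append(
            {
                "id": animal_id,
                "zero_fraction": qc.zero_fraction,
                "largest_blob_fraction": qc.largest_blob_fraction,
                "heart_blur_flag": qc.heart_blur_flag,
            }
        )
        if config.make_plots:
            from .plots import plot_histogram_fit, plot_volume_curve

            hist = expansion_histogram(res["expansion_map"], n_bins=config.n_bins)
            try:
                fit = fit_double_gaussian(hist)
            except XVError:
                fit = None
            plot_histogram_fit(hist, fit, path=out_dir / f"{animal_id}_histogram.png")
            plot_volume_curve(res["curve"], path=out_dir / f"{animal_id}_curve.png")

    cohort = cohort_scores(records, n_bins=config.n_bins, extras=extras)
    qc_df = pd.DataFrame(qc_rows)
    cohort.to_csv(out_dir / "cohort.csv")
    cohort.to_json(out_dir / "cohort.json")
    qc_df.to_csv(out_dir / "qc.csv", index=False, float_format="%.10g")
    _write_log(out_dir, config, failures)
    return CohortReport(cohort=cohort, qc=qc_df, out_dir=out_dir, failures=failures)


def _file_animals(config: RunConfig):
    from .io import load_volume, read_manifest

    df = read_manifest(config.manifest)

    def make_runner(row):
        def runner():
            paths = str(row["paths"]).split(";")
            volumes = [load_volume(p) for p in paths]
            seg = segment_lungs(volumes[0])
            fields = estimate_displacements(
                volumes,
                window_size=config.window_size,
                overlap_fraction=config.overlap_fraction,
                mask=seg.data,
            )
            times = np.arange(len(volumes), dtype=float)
            if "times" in row and isinstance(row["times"], str):
                times = np.array([float(t) for t in row["times"].split(";")])
            return analyse_fields(fields, seg.data, times, volumes[0].voxel_size, config)

        return runner

    return [(str(row["id"]), str(row["group"]), make_runner(row)) for _, row in df.iterrows()]


def _write_log(out_dir: Path, config: RunConfig, failures: list[str]) -> None:
    lines = [
        f"xvlung {__version__}",
        f"python {sys.version.split()[0]} ({platform.platform()})",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {config.seed}",
        f"engine {config.engine}",
    ]
    if failures:
        lines.append("failures:")
        lines.extend(f"  {f}" for f in failures)
    (out_dir / "run.log").write_text("\n".join(lines) + "\n")
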