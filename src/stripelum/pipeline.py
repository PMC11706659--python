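"""End-to-end orchestration: simulate -> calibrate -> measure -> stats -> acuity.

Each stage reads the previous stage's artifacts from disk, writes CSV/TIFF/PNG
outputs and a JSON manifest sidecar (inputs, resolved-config hash, seed,
package version) sufficient to re-derive them.  Identical (config, seed)
pairs produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .acuity import contrast_vs_distance
from .calibration import CalibratedImage, calibrate, compute_scale, measure_standard
from .metrics import HistogramConfig, measure_batch
from .models import ModelSpec, build_selection_table, emm_pairwise, pearson_test
from .synthetic import SyntheticImageSpec, generate_fish_image

__all__ = [
    "RunConfig",
    "run_experiment",
    "validate_metadata",
    "candidate_specs",
    "STAGES",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "calibrate", "measure", "stats", "acuity")

ARENAS = ("black", "white")
STIMULI = ("control", "predatory", "social")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: str = "run"
    images_dir: str | None = None  # defaults under out_dir
    masks_dir: str | None = None
    metadata: str | None = None
    seed: int = 0
    n_per_cell: int = 11
    n_sessions: int = 11
    standard_reflectance: float = 0.18
    experiment: int = 2
    histogram: dict = field(default_factory=dict)
    acuity_cpd: float = 1.0
    distances_cm: tuple[float, ...] = (2.0, 7.5, 20.0, 50.0)
    decode_srgb: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["distances_cm"] = list(self.distances_cm)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def paths(self) -> dict[str, Path]:
        out = Path(self.out_dir)
        return {
            "out": out,
            "images": Path(self.images_dir) if self.images_dir else out / "images",
            "masks": Path(self.masks_dir) if self.masks_dir else out / "masks",
            "meta": Path(self.metadata) if self.metadata else out / "metadata.csv",
            "calibrated": out / "calibrated",
            "metrics": out / "metrics.csv",
            "stats": out / "stats",
            "acuity": out / "acuity_curve.csv",
        }


def _write_manifest(artifact: Path, config: RunConfig, inputs: list[str]) -> None:
    manifest = {
        "artifact": artifact.name,
        "inputs": sorted(inputs),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    artifact.with_suffix(artifact.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def validate_metadata(meta: pd.DataFrame) -> list[dict]:
    """Check a metadata table against the two-arena, three-stimulus design.

    Returns machine-readable issue records (kind, detail); issues are data,
    not exceptions.
    """
    issues: list[dict] = []
    required = {"fish_id", "session", "arena", "stimulus"}
    missing = required - set(meta.columns)
    if missing:
        return [{"kind": "missing_columns", "detail": sorted(missing)}]
    for col, allowed in (("arena", ARENAS), ("stimulus", STIMULI)):
        bad = sorted(set(meta[col].astype(str)) - set(allowed))
        if bad:
            issues.append({"kind": f"unknown_{col}_level", "detail": bad})
    dup = meta["fish_id"][meta["fish_id"].duplicated()].tolist()
    if dup:
        issues.append({"kind": "duplicate_fish_id", "detail": sorted(set(dup))})
    counts = (
        meta.groupby(["arena", "stimulus"], sort=True).size().to_dict()
    )
    issues.append(
        {"kind": "cell_counts", "detail": {f"{a}/{s}": n for (a, s), n in counts.items()}}
    )
    return issues


def _simulate(config: RunConfig) -> None:
    """Write synthetic images, masks and the metadata CSV."""
    paths = config.paths()
    for key in ("images", "masks"):
        paths[key].mkdir(parents=True, exist_ok=True)
    paths["out"].mkdir(parents=True, exist_ok=True)

    rows = []
    i = 0
    base = SyntheticImageSpec(standard_reflectance=config.standard_reflectance)
    for rep in range(config.n_per_cell):
        for arena in ARENAS:
            for stim in STIMULI:
                i += 1
                fish_id = f"fish{i:03d}"
                # Arena shifts the dark-stripe reflectance (background matching);
                # the social stimulus deepens it slightly (contrast enhancement).
                r_dark = base.r_dark + (0.02 if arena == "white" else -0.02)
                r_dark += -0.005 if stim == "social" else 0.0
                spec = dataclasses.replace(
                    base, r_dark=r_dark, seed=config.seed * 100000 + i
                )
                image, truth = generate_fish_image(spec)
                img_name, mask_name = f"{fish_id}.tif", f"{fish_id}.png"
                tifffile.imwrite(paths["images"] / img_name, image)
                iio.imwrite(
                    paths["masks"] / mask_name,
                    (truth.roi_mask * 255).astype(np.uint8),
                )
                x, y, w, h = spec.standard_rect
                session = str((i - 1) // (len(ARENAS) * len(STIMULI)) % config.n_sessions + 1)
                rows.append(
                    {
                        "fish_id": fish_id,
                        "session": session,
                        "arena": arena,
                        "stimulus": stim,
                        "image": img_name,
                        "mask": mask_name,
                        "std_x": x,
                        "std_y": y,
                        "std_w": w,
                        "std_h": h,
                        "std_length_mm": spec.standard_length_mm,
                    }
                )
    meta = pd.DataFrame(rows)
    meta.to_csv(paths["meta"], index=False)
    _write_manifest(paths["meta"], config, [])
    logger.info("simulate: wrote %d fish", len(meta))


def _calibrate(config: RunConfig) -> None:
    paths = config.paths()
    meta = pd.read_csv(paths["meta"], dtype={"session": str})
    paths["calibrated"].mkdir(parents=True, exist_ok=True)
    for _, row in meta.iterrows():
        img_path = paths["images"] / row["image"]
        image = (
            tifffile.imread(img_path)
            if img_path.suffix in (".tif", ".tiff")
            else iio.imread(img_path)
        )
        rect = (int(row.std_x), int(row.std_y), int(row.std_w), int(row.std_h))
        std = measure_standard(
            image,
            rect,
            reflectance=config.standard_reflectance,
            known_length_mm=float(row.std_length_mm),
        )
        scale = compute_scale(rect[2], float(row.std_length_mm))
        cal = calibrate(
            image,
            std,
            px_per_mm=scale,
            decode_srgb=config.decode_srgb,
            source=row["image"],
        )
        out = paths["calibrated"] / f"{row.fish_id}.tif"
        tifffile.imwrite(out, cal.luminance.astype(np.float32))
        out.with_suffix(".json").write_text(
            json.dumps({"px_per_mm": scale, "source": row["image"]}) + "\n"
        )
    _write_manifest(paths["calibrated"] / "done", config, [str(paths["meta"])])
    logger.info("calibrate: %d images", len(meta))


def _load_calibrated(path: Path) -> CalibratedImage:
    lum = tifffile.imread(path).astype(float)
    side = json.loads(path.with_suffix(".json").read_text())
    return CalibratedImage(luminance=lum, px_per_mm=side["px_per_mm"],
                           source=side.get("source"))


def _measure(config: RunConfig) -> None:
    paths = config.paths()
    meta = pd.read_csv(paths["meta"], dtype={"session": str})
    cfg = HistogramConfig(**config.histogram)
    items = []
    for _, row in meta.iterrows():
        cal_path = paths["calibrated"] / f"{row.fish_id}.tif"
        mask_path = paths["masks"] / row["mask"]
        item = {
            "fish_id": row.fish_id,
            "session": row.session,
            "arena": row.arena,
            "stimulus": row.stimulus,
            "image": _load_calibrated(cal_path) if cal_path.exists() else None,
            "mask": iio.imread(mask_path) > 127 if mask_path.exists() else None,
        }
        items.append(item)
    table = measure_batch(items, cfg)
    table.to_csv(paths["metrics"], index=False, float_format="%.10g")
    _write_manifest(paths["metrics"], config, [str(paths["meta"])])
    logger.info("measure: %d rows", len(table))


def candidate_specs(response: str, experiment: int) -> list[ModelSpec]:
    """The candidate Gaussian-GLM sets compared for each experiment."""
    if experiment == 1:
        return [
            ModelSpec(response, ("arena",), label="arena colour"),
            ModelSpec(response, ("arena", "session"), label="arena colour + session"),
            ModelSpec(response, (), label="1 (null model)"),
            ModelSpec(response, ("session",), label="session"),
        ]
    if experiment == 2:
        return [
            ModelSpec(response, ("arena",), label="arena colour"),
            ModelSpec(response, ("arena", "stimulus"),
                      label="arena colour + stimulus"),
            ModelSpec(response, ("arena", "stimulus", "session"),
                      label="arena colour + stimulus + session"),
            ModelSpec(
                response,
                ("arena", "stimulus", "session"),
                interactions=(("arena", "stimulus"),),
                label="arena colour + stimulus + session + arena colour x stimulus",
            ),
            ModelSpec(response, (), label="1 (null model)"),
            ModelSpec(response, ("stimulus",), label="stimulus"),
            ModelSpec(response, ("session",), label="session"),
        ]
    raise ValueError("experiment must be 1 or 2")


def _stats(config: RunConfig) -> None:
    paths = config.paths()
    table = pd.read_csv(paths["metrics"], dtype={"session": str})
    if "flags" in table.columns:
        flagged = table["flags"].fillna("").str.contains("scale_outlier")
        if flagged.any():
            logger.info("stats: excluding %d scale outlier(s)", int(flagged.sum()))
            table = table.loc[~flagged]
    paths["stats"].mkdir(parents=True, exist_ok=True)
    responses = (
        ["mean_lum"] if config.experiment == 1
        else ["mean_lum", "l_min", "l_max", "cw"]
    )
    report_lines = []
    for resp in responses:
        sel = build_selection_table(table, candidate_specs(resp, config.experiment))
        out_csv = paths["stats"] / f"selection_{resp}.csv"
        sel.table.rename(columns={"model": "explanatory variables",
                                  "delta_aicc": "dAICc", "k": "d.f."}).to_csv(
            out_csv, index=False, float_format="%.10g"
        )
        _write_manifest(out_csv, config, [str(paths["metrics"])])
        report_lines.append(f"[{resp}] {sel.verdict}")
        preferred = sel.table.loc[sel.table["preferred"], "model"]
        if not preferred.empty:
            fit = sel.fits[preferred.iloc[0]]
            multi = [f for f, levs in fit.levels.items() if len(levs) > 2]
            for factor in multi:
                contrasts = emm_pairwise(fit, factor)
                cdf = pd.DataFrame([dataclasses.asdict(c) for c in contrasts])
                ccsv = paths["stats"] / f"contrasts_{resp}_{factor}.csv"
                cdf.to_csv(ccsv, index=False, float_format="%.10g")
                _write_manifest(ccsv, config, [str(paths["metrics"])])
                for c in contrasts:
                    report_lines.append(
                        f"  {c.pair}: t({c.df}) = {c.t:.3f}, p = {c.p_adjusted:.4g}"
                    )
    if config.experiment == 2:
        sub = table.dropna(subset=["l_min", "l_max"])
        corr = pearson_test(sub["l_min"], sub["l_max"])
        report_lines.append(
            f"[l_min ~ l_max] r({corr.df}) = {corr.r:.2f}, p = {corr.p:.4g}"
        )
    report = paths["stats"] / "report.txt"
    report.write_text("\n".join(report_lines) + "\n")
    _write_manifest(report, config, [str(paths["metrics"])])
    logger.info("stats: %d responses", len(responses))


def _acuity(config: RunConfig) -> None:
    paths = config.paths()
    meta = pd.read_csv(paths["meta"], dtype={"session": str})
    row = meta.iloc[0]
    cal = _load_calibrated(paths["calibrated"] / f"{row.fish_id}.tif")
    mask = iio.imread(paths["masks"] / row["mask"]) > 127
    curve = contrast_vs_distance(
        cal, config.acuity_cpd, config.distances_cm, mask
    )
    curve.to_csv(paths["acuity"], index=False, float_format="%.10g")
    _write_manifest(paths["acuity"], config, [str(paths["meta"])])
    logger.info("acuity: %d distances", len(curve))


_STAGE_FUNCS = {
    "simulate": _simulate,
    "calibrate": _calibrate,
    "measure": _measure,
    "stats": _stats,
    "acuity": _acuity,
}


def run_experiment(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in pipeline order; halt on the first error.

    Returns a run report dict (stages run, output paths, config hash).
    Upstream artifacts already on disk are reused by later stages, so partial
    reruns are possible.
    """
    paths = config.paths()
    paths["out"].mkdir(parents=True, exist_ok=True)
    (paths["out"] / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True)
    )
    run = [s for s in STAGES if s in stages]
    for stage in run:
        try:
            _STAGE_FUNCS[stage](config)
        except Exception as exc:
            logger.error("stage %r failed: %s", stage, exc)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return {
        "stages": run,
        "out_dir": str(paths["out"]),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
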