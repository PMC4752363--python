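"""Pipeline orchestration: simulate -> colorimetry -> signal -> pgls -> report.

Each stage reads and writes only declared files below a run directory, so
stages can be re-run independently; a JSON manifest records the config
snapshot, seeds and a SHA-256 checksum of every output, and a fixed seed
reproduces identical checksums end to end.

Layout of a run directory::

    tree.nwk                 newick phylogeny
    traits.csv               one row per species x replicate
    image_params.csv         per-image generating parameters
    params.yaml              flat key-value config snapshot
    images/<id>.tif          16-bit linear-RGB egg photographs
    images/<id>_egg.png      ground-truth egg mask
    images/<id>_spots.png    ground-truth maculation mask
    colorimetry.csv          one row per image
    signal.json              lambda / ICC / Spearman records
    table1_<pigment>.csv     colorimetrics model-averaged estimates
    table2_<pigment>.csv     life-history model-averaged estimates
    report.md                human-readable summary
    manifest.json            checksums + provenance
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from . import __version__
from .colorimetry import analyze_image, load_image
from .pgls import fit_model_set
from .phylosignal import estimate_lambda, repeatability_icc, spearman_rho
from .simulate import SimulationConfig, simulate_species_dataset
from .trees import read_newick, write_newick

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "stage_simulate",
    "stage_colorimetry",
    "stage_signal",
    "stage_pgls",
    "stage_report",
]

logger = logging.getLogger("ovotrait.pipeline")

PIGMENTS = ("protoporphyrin", "biliverdin")
LIFE_HISTORY_PREDICTORS = [
    "nest_location",
    "parasitized",
    "nest_type",
    "log10_body_mass",
    "clutch_size",
    "shell_thickness_mm",
]
COLORIMETRIC_PREDICTORS = ["a_mean", "L_mean", "maculation_pct", "b_mean"]

#: pipeline-level options on top of the simulation config
PIPELINE_KEYS = {
    "icc_n_boot": 2000,
    "weight_threshold": 0.95,
    "lambda_mode": "ml",
    "ci_level": 0.95,
}


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig
    icc_n_boot: int = 2000
    weight_threshold: float = 0.95
    lambda_mode: str | float = "ml"
    ci_level: float = 0.95


def load_config(path) -> PipelineConfig:
    """Parse a flat key-value YAML config; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    sim_kwargs, pipe_kwargs = {}, dict(PIPELINE_KEYS)
    for key, value in raw.items():
        if key in sim_fields:
            sim_kwargs[key] = value
        elif key in PIPELINE_KEYS:
            pipe_kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: {key!r}")
    sim = SimulationConfig(**sim_kwargs)
    sim.validate()
    return PipelineConfig(simulation=sim, **pipe_kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_mask_png(path: Path, mask: np.ndarray) -> None:
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


# -- stages ------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_species_dataset(config.simulation)
    written = []

    tree_path = outdir / "tree.nwk"
    write_newick(ds.tree, tree_path)
    written.append(tree_path)

    traits_path = outdir / "traits.csv"
    ds.traits.to_csv(traits_path, index=False)
    written.append(traits_path)

    ip_path = outdir / "image_params.csv"
    ds.image_params.to_csv(ip_path)
    written.append(ip_path)

    params_path = outdir / "params.yaml"
    flat = {}
    for key, value in ds.config.as_dict().items():
        if isinstance(value, dict):
            for sub, v in value.items():
                flat[f"{key}.{sub}"] = float(v)
        else:
            flat[key] = value
    with open(params_path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)
    written.append(params_path)

    imgdir = outdir / "images"
    imgdir.mkdir(exist_ok=True)
    for image_id, bundle in ds.iter_images():
        img_path = imgdir / f"{image_id}.tif"
        tifffile.imwrite(
            img_path,
            np.round(bundle.image * 65535).astype(np.uint16),
            photometric="rgb",
        )
        _write_mask_png(imgdir / f"{image_id}_egg.png", bundle.egg_mask)
        _write_mask_png(imgdir / f"{image_id}_spots.png", bundle.maculation_mask)
        written += [
            img_path,
            imgdir / f"{image_id}_egg.png",
            imgdir / f"{image_id}_spots.png",
        ]
    logger.info("simulate: %d species, %d images", config.simulation.n_species,
                len(ds.image_params))
    return written


def stage_colorimetry(config: PipelineConfig, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    ip = pd.read_csv(outdir / "image_params.csv", index_col="image_id")
    rows = []
    for image_id, meta in ip.iterrows():
        img = load_image(outdir / "images" / f"{image_id}.tif")
        summary = analyze_image(img, pixel_scale=config.simulation.pixel_scale)
        logger.info(
            "colorimetry: %s subsample fraction %.3f",
            image_id, summary.diagnostics["subsample_fraction"],
        )
        rows.append(
            {
                "image_id": image_id,
                "species": meta["species"],
                "replicate": int(meta["replicate"]),
                **summary.as_dict(),
                "subsample_fraction": summary.diagnostics["subsample_fraction"],
            }
        )
    out = outdir / "colorimetry.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return [out]


def _species_model_table(outdir: Path) -> pd.DataFrame:
    """Species-mean table joining traits and per-image colorimetrics."""
    traits = pd.read_csv(outdir / "traits.csv")
    num = (
        traits.drop(columns=["replicate"])
        .groupby("species")
        .mean(numeric_only=True)
    )
    cats = traits.groupby("species")[["nest_type", "nest_location", "parasitized"]].first()
    df = num.join(cats)
    df["nest_type"] = (df["nest_type"] == "open").astype(float)
    df["nest_location"] = (df["nest_location"] == "off_ground").astype(float)
    df["parasitized"] = (df["parasitized"] == "yes").astype(float)
    df["shell_thickness_mm"] = df["shell_thickness_um"] / 1000.0
    df["log10_body_mass"] = np.log10(df["body_mass_g"])
    color_path = outdir / "colorimetry.csv"
    if color_path.exists():
        color = (
            pd.read_csv(color_path)
            .drop(columns=["image_id", "replicate"])
            .groupby("species")
            .mean(numeric_only=True)
        )
        df = df.join(color)
    return df


def stage_signal(config: PipelineConfig, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    tree = read_newick(outdir / "tree.nwk")
    traits = pd.read_csv(outdir / "traits.csv")
    means = traits.groupby("species").mean(numeric_only=True)
    record: dict = {}
    for pigment in PIGMENTS:
        col = f"log10_{pigment}"
        fit = estimate_lambda(
            means[col].to_numpy(), tree=tree, species=list(means.index),
            ci_level=config.ci_level,
        )
        icc = repeatability_icc(
            traits[col].to_numpy(),
            traits["species"].to_numpy(),
            n_boot=config.icc_n_boot,
            seed=config.simulation.seed,
        )
        rho = spearman_rho(
            means[f"{pigment}_ug_g"].to_numpy(),
            means[f"{pigment}_ug_mm2"].to_numpy(),
        )
        record[pigment] = {
            "lambda_hat": fit.lambda_,
            "lambda_ci_low": fit.ci_low,
            "lambda_ci_high": fit.ci_high,
            "sigma2_hat": fit.sigma2,
            "mu_hat": fit.mu,
            "loglik": fit.llf,
            "icc": icc.icc,
            "icc_p5": icc.p5,
            "icc_p95": icc.p95,
            "spearman_mass_vs_area": rho,
            "n_species": fit.n,
        }
    out = outdir / "signal.json"
    with open(out, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
    return [out]


def stage_pgls(config: PipelineConfig, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    tree = read_newick(outdir / "tree.nwk")
    df = _species_model_table(outdir)
    written = []
    for pigment in PIGMENTS:
        response = f"log10_{pigment}"
        co = f"log10_{'biliverdin' if pigment == 'protoporphyrin' else 'protoporphyrin'}"
        res2 = fit_model_set(
            df, response, LIFE_HISTORY_PREDICTORS, tree=tree, always=(co,),
            lambda_mode=config.lambda_mode, threshold=config.weight_threshold,
        )
        path2 = outdir / f"table2_{pigment}.csv"
        res2.averaged.to_csv(path2)
        written.append(path2)
        if all(c in df.columns for c in COLORIMETRIC_PREDICTORS):
            res1 = fit_model_set(
                df, response, COLORIMETRIC_PREDICTORS, tree=tree,
                lambda_mode=config.lambda_mode, threshold=config.weight_threshold,
            )
            path1 = outdir / f"table1_{pigment}.csv"
            res1.averaged.to_csv(path1)
            written.append(path1)
    return written


def _format_table(df: pd.DataFrame) -> str:
    """Markdown-ish table with the bold (95% CI) / asterisk (90% CI) convention."""
    lines = [
        "| term | estimate (95% CI) | importance | N models |",
        "| --- | --- | --- | --- |",
    ]
    for term, row in df.iterrows():
        if np.isnan(row["estimate"]):
            continue
        est = f"{row['estimate']:.3f} ({row['ci95_low']:.3f} to {row['ci95_high']:.3f})"
        if row["significant_95"]:
            est = f"**{est}**"
        elif row["significant_90"]:
            est = f"{est}*"
        imp = "" if term == "intercept" else f"{row['importance']:.2f}"
        nm = "" if term == "intercept" else f"{int(row['n_containing_models'])}"
        lines.append(f"| {term} | {est} | {imp} | {nm} |")
    return "\n".join(lines)


def stage_report(config: PipelineConfig, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    sig_path = outdir / "signal.json"
    if not sig_path.exists():
        raise FileNotFoundError("signal stage outputs missing (signal.json)")
    with open(sig_path) as fh:
        signal = json.load(fh)
    parts = ["# ovotrait run report", ""]
    parts.append("## Phylogenetic signal and repeatability")
    for pigment in PIGMENTS:
        s = signal[pigment]
        parts.append(
            f"- {pigment}: lambda = {s['lambda_hat']:.2f} "
            f"[{s['lambda_ci_low']:.3f}, {s['lambda_ci_high']:.3f}]; "
            f"ICC = {s['icc']:.2f} [5th {s['icc_p5']:.2f}, 95th {s['icc_p95']:.2f}]; "
            f"Spearman rho (per mass vs per area) = {s['spearman_mass_vs_area']:.2f} "
            f"(n = {s['n_species']})"
        )
    for label, prefix in [
        ("Colorimetrics models", "table1"),
        ("Life-history and nesting ecology models", "table2"),
    ]:
        for pigment in PIGMENTS:
            path = outdir / f"{prefix}_{pigment}.csv"
            if not path.exists():
                if prefix == "table2":
                    raise FileNotFoundError(f"pgls stage outputs missing ({path.name})")
                continue
            df = pd.read_csv(path, index_col="term")
            parts += ["", f"## {label}: {pigment}", "", _format_table(df)]
    parts.append("")
    parts.append(
        "Bold marks estimates whose 95% CI excludes zero; an asterisk marks "
        "estimates significant at the 90% CI only."
    )
    out = outdir / "report.md"
    out.write_text("\n".join(parts))
    return [out]


STAGES = {
    "simulate": stage_simulate,
    "colorimetry": stage_colorimetry,
    "signal": stage_signal,
    "pgls": stage_pgls,
    "report": stage_report,
}
STAGE_ORDER = ["simulate", "colorimetry", "signal", "pgls", "report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def run_pipeline(config: PipelineConfig, outdir, stages=None) -> dict:
    """Run the requested stages (default: all) and write the manifest.

    Returns the manifest dict.  A stage failure raises :class:`StageError`
    after writing a failure marker; earlier outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = STAGE_ORDER if stages is None else list(stages)
    outputs: dict[str, list[str]] = {}
    for name in stages:
        try:
            written = STAGES[name](config, outdir)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise StageError(name, exc) from exc
        outputs[name] = [str(p.relative_to(outdir)) for p in written]
    manifest = {
        "version": __version__,
        "seed": config.simulation.seed,
        "config": {
            **{
                k: (v if not isinstance(v, dict) else dict(v))
                for k, v in config.simulation.as_dict().items()
            },
            "icc_n_boot": config.icc_n_boot,
            "weight_threshold": config.weight_threshold,
            "lambda_mode": config.lambda_mode,
            "ci_level": config.ci_level,
        },
        "stages": outputs,
        "checksums": {
            rel: _sha256(outdir / rel)
            for stage_files in outputs.values()
            for rel in stage_files
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
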