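"""Tabular formats, configuration, and the reproducible pipeline runner.

All tables are plain text (CSV) with unit-suffixed column names (``x_um``,
``t_min``) to prevent unit drift; image stacks are TIFF.  Output tables
carry ``#``-prefixed metadata lines recording the global seed and a hash of
the configuration, so any result file can be traced to the exact run that
produced it.  Exclusion reasons are data columns, not log-only messages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import msd_pipeline, synthetic_data
from .msd_pipeline import BeadTrajectory

__all__ = [
    "RunConfig",
    "read_trajectory_table",
    "write_trajectory_table",
    "read_table",
    "write_table",
    "load_config",
    "config_hash",
    "run_pipeline",
]

logger = logging.getLogger("colonydrift")

TRAJECTORY_COLUMNS = ["colony_id", "bead_id", "frame", "t_min", "x_um", "y_um"]

#: Parameter classes accepted in each stage block of a run configuration.
STAGE_SCHEMAS = {
    "simulate_colonies": synthetic_data.PlateEffectParams,
    "simulate_trajectories": synthetic_data.LineageSimParams,
    "simulate_sectors": synthetic_data.SectorSimParams,
    "simulate_establishment": synthetic_data.EstablishmentSimParams,
    "msd": None,
    "normalize": None,
    "summarize": None,
    "compare": None,
}


class FormatError(ValueError):
    """A table violated the expected schema."""


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "colonydrift_out"
    verbosity: str = "INFO"
    stages: dict = field(default_factory=dict)

    def canonical(self) -> str:
        # the output directory is deliberately excluded: the hash identifies
        # the scientific content of a run, not where it was written
        return json.dumps(
            {"seed": self.seed, "stages": self.stages}, sort_keys=True, default=str
        )


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.canonical().encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    stages = raw.get("stages", {})
    for name, block in stages.items():
        if name not in STAGE_SCHEMAS:
            raise ValueError(f"unknown stage {name!r}")
        cls = STAGE_SCHEMAS[name]
        if cls is not None and block:
            cls(**block)  # validate against the parameter schema
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "colonydrift_out")),
        verbosity=str(raw.get("verbosity", "INFO")),
        stages=stages,
    )


# ---------------------------------------------------------------------------
# trajectory tables


def read_trajectory_table(
    path: str | Path, pixel_size: float | None = None
) -> list[BeadTrajectory]:
    """Read a trajectory table into per-bead trajectories.

    Expected columns: ``colony_id, bead_id, frame, t_min, x_um, y_um``
    (optional ``qc_flag``), or ``x_px, y_px`` together with a ``pixel_size``
    (µm/px) to convert.  Rows are grouped by (colony, bead) and sorted by
    frame; duplicated or non-monotone frames within a bead raise a
    ``FormatError`` naming the offender.
    """
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if {"x_px", "y_px"} <= cols and pixel_size is not None:
        df["x_um"] = df["x_px"] * pixel_size
        df["y_um"] = df["y_px"] * pixel_size
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for c in ("t_min", "x_um", "y_um"):
        if not np.issubdtype(df[c].dtype, np.number):
            raise FormatError(f"{path}: non-numeric values in column {c!r}")
    if df[["x_um", "y_um", "t_min"]].isna().any().any():
        bad = int(df[["x_um", "y_um", "t_min"]].isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: non-numeric or missing coordinate at row {bad}")
    trajs = []
    for (colony, bead), grp in df.groupby(["colony_id", "bead_id"], sort=True):
        if grp["frame"].duplicated().any():
            frame = int(grp.loc[grp["frame"].duplicated(), "frame"].iloc[0])
            raise FormatError(
                f"{path}: duplicated frame {frame} for bead {bead!r} in colony {colony!r}"
            )
        grp = grp.sort_values("frame")
        if not grp["t_min"].is_monotonic_increasing:
            raise FormatError(
                f"{path}: non-monotone times for bead {bead!r} in colony {colony!r}"
            )
        qc = ""
        if "qc_flag" in grp and grp["qc_flag"].notna().any():
            flags = set(map(str, grp["qc_flag"].dropna())) - {"", "nan"}
            qc = ";".join(sorted(flags))
        trajs.append(
            BeadTrajectory(
                str(colony),
                str(bead),
                grp["t_min"].to_numpy(dtype=float),
                grp[["x_um", "y_um"]].to_numpy(dtype=float),
                qc_flag=qc,
            )
        )
    return trajs


def write_trajectory_table(
    trajectories: list[BeadTrajectory],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    rows = []
    for tr in trajectories:
        for i in range(len(tr)):
            rows.append(
                {
                    "colony_id": tr.colony_id,
                    "bead_id": tr.bead_id,
                    "frame": i,
                    "t_min": tr.t_min[i],
                    "x_um": tr.xy_um[i, 0],
                    "y_um": tr.xy_um[i, 1],
                    "qc_flag": tr.qc_flag,
                }
            )
    write_table(pd.DataFrame(rows), path, metadata)


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write a CSV with ``#``-prefixed metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# pipeline runner


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write result tables plus a log.

    Stages run in the fixed order simulate-colonies → normalize → summarize
    → compare, with optional simulate-trajectories → msd alongside.  Every
    stage's randomness derives from the single global seed; every output
    table records the seed and configuration hash.  Exclusion counts are
    logged and also present as data in the written tables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config_hash(config)}
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {}
    ss = np.random.SeedSequence(config.seed)
    try:
        stages = config.stages
        if "simulate_trajectories" in stages:
            params = synthetic_data.LineageSimParams(
                **{**stages["simulate_trajectories"], "seed": int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)}
            )
            trajs, truth = synthetic_data.simulate_lineage_trajectories(params)
            write_trajectory_table(trajs, outdir / "trajectories.csv", meta)
            msd_block = stages.get("msd", {}) or {}
            fit = msd_pipeline.colony_msd(trajs, **msd_block)
            results["msd_fit"] = fit
            write_table(
                pd.DataFrame(
                    [
                        {
                            "amplitude": fit.amplitude,
                            "exponent": fit.exponent,
                            "msd50_um2": fit.msd50_um2,
                            "msd50_err_um2": fit.msd50_err_um2,
                            "qc_pass": fit.qc_pass,
                            "true_beta": truth["beta"],
                            "true_amplitude": truth["amplitude"],
                        }
                    ]
                ),
                outdir / "msd_fit.csv",
                meta,
            )
            logger.info("msd: fitted beta=%.3f (truth %.3f)", fit.exponent, truth["beta"])
        if "simulate_colonies" in stages:
            params = synthetic_data.PlateEffectParams(
                **{**stages["simulate_colonies"], "seed": int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)}
            )
            colonies = synthetic_data.apply_plate_effects(params)
            results["colonies"] = colonies
            write_table(colonies, outdir / "colonies.csv", meta)
            norm_block = stages.get("normalize", {}) or {}
            normalized = msd_pipeline.normalize_to_wildtype(
                colonies, wt_strain=norm_block.get("wt_strain", params.wt_strain)
            )
            results["normalized"] = normalized
            write_table(normalized, outdir / "colonies_normalized.csv", meta)
            n_excl = int((normalized["exclusion_reason"] != "").sum())
            logger.info("normalize: %d colonies excluded", n_excl)
            sum_block = stages.get("summarize", {}) or {}
            summary = msd_pipeline.summarize_strain(
                normalized, min_replicates=int(sum_block.get("min_replicates", 2))
            )
            results["summary"] = summary
            write_table(summary, outdir / "strain_summary.csv", meta)
            logger.info("summarize: %d strains kept", len(summary))
            if "compare" in stages:
                cmp_block = stages.get("compare", {}) or {}
                wt_name = norm_block.get("wt_strain", params.wt_strain)
                ko = summary.loc[summary["strain_id"] != wt_name, "relative_msd"]
                wt = normalized.loc[
                    (normalized["strain_id"] == wt_name)
                    & (normalized["exclusion_reason"] == ""),
                    "relative_msd",
                ]
                comparison = msd_pipeline.compare_distributions(
                    ko,
                    wt,
                    n_bootstrap=int(cmp_block.get("n_bootstrap", 10_000)),
                    seed=config.seed,
                )
                results["comparison"] = comparison
                write_table(
                    pd.DataFrame([{k: v for k, v in comparison.items() if k != "median_shift_ci"}
                                  | {"ci_lo": comparison["median_shift_ci"][0],
                                     "ci_hi": comparison["median_shift_ci"][1]}]),
                    outdir / "distribution_comparison.csv",
                    meta,
                )
                logger.info(
                    "compare: KS p=%.3g median shift=%.3f", comparison["ks_p"], comparison["median_shift"]
                )
    except Exception as exc:  # annotate the failing stage, then re-raise
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        handler.close()
        logger.removeHandler(handler)
    return results
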