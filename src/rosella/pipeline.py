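"""End-to-end synthetic pipeline run: simulate → quantify → test → report.

One call to :func:`run_pipeline` executes, for every independent experiment
and condition, the imaging, colocalization and MEA stages on synthetic data,
then the grouping/normalization/testing stage, writing long-format CSVs (all
tagged with the run id and config hash) into one directory per run.
"""

from __future__ import annotations

import logging
import os
import platform
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .config import config_hash, default_config, write_config
from .coloc import pairwise_coloc
from .mea import SpikeDetectionParams, analyse_well
from .synthetic import (
    FieldSpec,
    NoiseModel,
    generate_coloc_field,
    generate_mea_recording,
    generate_rosella_field,
)
from .vesicles import (
    compute_cell_area,
    compute_metrics,
    detect_autolysosomes,
    get_scheme,
    threshold_channel,
)

logger = logging.getLogger("rosella")

__all__ = ["run_pipeline", "PipelineError", "RunResult"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunResult:
    run_dir: str | None
    grouped: pd.DataFrame
    normalized: pd.DataFrame
    summary: pd.DataFrame
    config: dict
    config_hash: str


def _vesicle_counts(base: dict, effect: float, rng: np.random.Generator) -> dict:
    counts = {}
    for key, n in base.items():
        state, cls = key.rsplit("_", 1)
        counts[(state, cls)] = int(rng.poisson(n * effect))
    return counts


def _imaging_stage(cfg: dict, cond: str, exp: int, rng: np.random.Generator) -> list[dict]:
    img = cfg["imaging"]
    effect = cfg["effects"]["autolysosome"] if cond != "control" else 1.0
    scheme = get_scheme(cfg["scheme"])
    rows = []
    for f in range(cfg["fields_per_experiment"]):
        spec = FieldSpec(
            field_shape=tuple(img["field_shape"]),
            n_cells=img["n_cells"],
            reporter_fraction=img["reporter_fraction"],
            vesicles_per_class=_vesicle_counts(img["base_counts"], effect, rng),
            noise=NoiseModel(**img["noise"]),
            scheme=cfg["scheme"],
            seed=int(rng.integers(2**31)),
        )
        stack, truth = generate_rosella_field(spec)
        thr = truth.suggested_thresholds
        # red: robust background threshold (exact when noiseless, ~3 noise
        # SDs above background otherwise); green puncta: documented
        # cytoplasm/vesicle midpoint, unsmoothed
        red = threshold_channel(stack, "DsRed", method="robust", robust_k=img["robust_k"])
        green = threshold_channel(
            stack, "pHluorin", method="fixed", threshold=thr["pHluorin"]
        )
        records = detect_autolysosomes(
            red, green, stack,
            min_voxels=img["min_voxels"],
            dual_positive_cutoff=img["dual_positive_cutoff"],
            field_id=f"{cond}_exp{exp:02d}_f{f}",
        )
        cell_area = compute_cell_area(
            stack, "pHluorin", method="fixed",
            threshold=thr["pHluorin_cell"],
            smooth_sigma=img["cell_smooth_sigma"] if spec.noise.kind != "none" else 0.0,
        )
        metrics = compute_metrics(records, cell_area, scheme)
        for name, value in (
            ("autolysosome_count_per_cell_area", metrics.autolysosome_count_per_cell_area),
            ("total_autolysosome_area_per_cell_area", metrics.total_autolysosome_area_per_cell_area),
        ):
            rows.append({"metric": name, "value": value, "field": f})
    return rows


def _coloc_stage(cfg: dict, cond: str, rng: np.random.Generator) -> list[dict]:
    cl = cfg["coloc"]
    effect = cfg["effects"]["coloc"] if cond != "control" else 1.0
    target = float(np.clip(rng.normal(cl["target_fraction"] * effect, cl["jitter_sd"]), 0.0, 1.0))
    markers = list(cl["markers"])
    stack, truth = generate_coloc_field(
        markers,
        {(markers[0], markers[1]): target},
        mask_voxels=cl["mask_voxels"],
    )
    masks = {
        m: threshold_channel(stack, m, method="fixed", threshold=truth.threshold)
        for m in markers
    }
    percent = pairwise_coloc(
        masks[markers[0]], masks[markers[1]], denominator_mode=cl["denominator_mode"]
    )
    return [{"metric": "coloc_overlap_percent", "value": percent, "field": 0}]


def _mea_stage(cfg: dict, cond: str, rng: np.random.Generator) -> list[dict]:
    m = cfg["mea"]
    effect = cfg["effects"]["firing_rate"] if cond != "control" else 1.0
    recordings, _ = generate_mea_recording(
        n_electrodes=m["n_electrodes"],
        duration_s=m["duration_s"],
        fs=m["fs"],
        spike_rate=m["base_rate_hz"] * effect,
        spike_amplitude_sd=m["spike_amplitude_sd"],
        noise_sd=m["noise_sd"],
        seed=int(rng.integers(2**31)),
    )
    params = SpikeDetectionParams(threshold_k=m["threshold_k"])
    activity, _, _ = analyse_well(
        recordings, params, min_rate_per_min=m["min_rate_per_min"]
    )
    return [{"metric": "mean_fire_rate_hz", "value": activity.mean_fire_rate_hz, "field": 0}]


def run_pipeline(
    config: dict | None = None,
    out: str | None = None,
    seed: int | None = None,
) -> RunResult:
    """Execute the full synthetic pipeline under one config and seed.

    With ``out`` set, writes per-stage CSVs, the resolved config, and a run
    log into ``out``; with ``out=None`` runs purely in memory (used by the
    power/calibration checks). Deterministic under (config, seed).
    """
    from .stats import aggregate, compare_table, normalize_to_control

    cfg = config if config is not None else default_config()
    if seed is not None:
        cfg = {**cfg, "seed": seed}
    chash = config_hash(cfg)
    run_id = f"run_{cfg['seed']}_{chash}"
    rng = np.random.default_rng(cfg["seed"])

    run_dir = None
    if out is not None:
        run_dir = os.path.join(out, run_id)
        os.makedirs(run_dir, exist_ok=True)
        write_config(cfg, os.path.join(run_dir, "config_resolved.yaml"))
        handler = logging.FileHandler(os.path.join(run_dir, "log.txt"), mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.info(
            "rosella %s on python %s; seed=%s config=%s",
            __version__, platform.python_version(), cfg["seed"], chash,
        )

    stage_rows: list[dict] = []
    stages = {
        "imaging": _imaging_stage,
        "coloc": _coloc_stage,
        "mea": _mea_stage,
    }
    try:
        t_all = time.perf_counter()
        for exp in range(1, cfg["n_experiments"] + 1):
            for cond in ("control", "PD"):
                for stage_name, fn in stages.items():
                    t0 = time.perf_counter()
                    try:
                        if stage_name == "imaging":
                            rows = fn(cfg, cond, exp, rng)
                        else:
                            rows = fn(cfg, cond, rng)
                    except Exception as err:  # noqa: BLE001 - re-raised with stage label
                        raise PipelineError(stage_name, err) from err
                    for row in rows:
                        stage_rows.append(
                            {
                                "condition": cond,
                                "line_id": f"{cond}_line",
                                "experiment_id": f"exp{exp:02d}",
                                "timepoint": cfg["timepoint"],
                                **row,
                            }
                        )
                    logger.debug(
                        "%s %s exp%02d: %.3fs", stage_name, cond, exp,
                        time.perf_counter() - t0,
                    )
        raw = pd.DataFrame(stage_rows)
        try:
            grouped = aggregate(raw)
            normalized = normalize_to_control(
                grouped, mode=cfg["stats"]["normalization"]
            )
            summary = compare_table(normalized, per_timepoint=False)
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001
            raise PipelineError("stats", err) from err
        logger.info("pipeline done in %.2fs", time.perf_counter() - t_all)
    except PipelineError:
        if run_dir is not None:
            os.makedirs(os.path.join(run_dir, "failed"), exist_ok=True)
            if stage_rows:
                _write(pd.DataFrame(stage_rows), run_dir, "failed/partial_measurements.csv", run_id, chash)
        raise
    finally:
        if out is not None:
            logger.handlers = [
                h for h in logger.handlers if not isinstance(h, logging.FileHandler)
            ]

    if run_dir is not None:
        _write(raw, run_dir, "measurements/raw.csv", run_id, chash)
        _write(grouped, run_dir, "stats/grouped.csv", run_id, chash)
        _write(normalized, run_dir, "stats/normalized.csv", run_id, chash)
        _write(summary, run_dir, "report/summary.csv", run_id, chash)
    return RunResult(
        run_dir=run_dir,
        grouped=grouped,
        normalized=normalized,
        summary=summary,
        config=cfg,
        config_hash=chash,
    )


def _write(frame: pd.DataFrame, run_dir: str, rel: str, run_id: str, chash: str) -> None:
    frame = frame.copy()
    frame["run_id"] = run_id
    frame["config_hash"] = chash
    path = os.path.join(run_dir, rel)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    frame.to_csv(path, index=False)
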