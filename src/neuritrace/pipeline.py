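"""Batch orchestration: config, per-frame analysis chain, deterministic merging.

Every frame is an independent unit of work and passes through the full
chain: preprocessing of both channels, watershed nuclei separation, neuron
identification and orphan removal, soma detection, upscaled skeletonization
with pruning, soma-overlap pruning, and metric assembly.  Results are merged
sorted by frame id, so the output is identical for any worker count and any
manifest ordering.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd
import yaml

from .calibration import Calibration, Condition, MicrographFrame, read_frame
from .nuclei import (
    DEFAULT_H_DEPTH,
    DEFAULT_MIN_PEAK_SEPARATION_PX,
    measure_regions,
    split_touching_nuclei,
)
from .preprocess import PreprocessParams, preprocess_channel
from .skeleton import (
    branch_statistics,
    skeletonize_propagated,
    smooth_mask,
    total_length_um,
    upscale_mask,
)
from .soma import (
    DEFAULT_SOMA_RADIUS_PX,
    detect_somata,
    identify_neurons,
    neurite_area_um2,
    prune_soma_overlap,
    remove_orphan_components,
)
from .stats import (
    ImageMetrics,
    compute_image_metrics,
    fit_four_param_logistic,
    metrics_table,
    normalize_to_control,
)

logger = logging.getLogger("neuritrace")

MANIFEST_COLUMNS = ["frame", "experiment_id", "compound", "concentration_nM", "is_control"]


@dataclass
class PipelineConfig:
    """Central configuration: every pipeline parameter with its default.

    Serialized as a flat YAML mapping; unknown keys are rejected so that a
    typo cannot silently fall back to a default.
    """

    # calibration
    frame_width_px: int = Calibration().frame_width_px
    frame_height_px: int = Calibration().frame_height_px
    physical_width_um: float = Calibration().physical_width_um
    physical_height_um: float = Calibration().physical_height_um
    nuclear_page: int = 0
    # preprocessing (both channels)
    window_px: int = PreprocessParams().window_px
    phansalkar_p: float = PreprocessParams().p
    phansalkar_q: float = PreprocessParams().q
    phansalkar_k: float = PreprocessParams().k
    phansalkar_r: float = PreprocessParams().r
    closing_radius_px: int = PreprocessParams().closing_radius_px
    max_implausible_area_um2: float = PreprocessParams().max_implausible_area_um2
    saturation_fraction: float = PreprocessParams().saturation_fraction
    clip_percentile: float = PreprocessParams().clip_percentile
    # nuclei watershed
    min_peak_separation_px: int = DEFAULT_MIN_PEAK_SEPARATION_PX
    h_depth: float = DEFAULT_H_DEPTH
    # skeletonization
    upscale_factor: int = 3
    smoothing_sigma_px: float = 1.5  # rounds upscaling staircase, in upscaled px
    epsilon_px: float = 10.0
    # soma
    soma_radius_px: int = DEFAULT_SOMA_RADIUS_PX
    # quantification
    denominator: str = "nuclei"  # 'nuclei' (e.g. SH-SY5Y) or 'neurons' (e.g. TH+ MDN)
    control_compound: str = "DMSO"
    # execution
    output_dir: str = "results"
    workers: int = 1

    def __post_init__(self) -> None:
        if self.denominator not in ("nuclei", "neurons"):
            raise ValueError("denominator must be 'nuclei' or 'neurons'")
        if self.upscale_factor < 1 or self.workers < 1:
            raise ValueError("upscale_factor and workers must be >= 1")

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            self.frame_width_px, self.frame_height_px,
            self.physical_width_um, self.physical_height_um,
        )

    @property
    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            window_px=self.window_px,
            p=self.phansalkar_p, q=self.phansalkar_q,
            k=self.phansalkar_k, r=self.phansalkar_r,
            closing_radius_px=self.closing_radius_px,
            max_implausible_area_um2=self.max_implausible_area_um2,
            saturation_fraction=self.saturation_fraction,
            clip_percentile=self.clip_percentile,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return Path(path)


def analyze_frame(frame: MicrographFrame, config: Optional[PipelineConfig] = None) -> ImageMetrics:
    """Run the full analysis chain on one frame and return its metrics row."""
    if config is None:
        config = PipelineConfig()
    params = config.preprocess_params
    cal = frame.calibration

    nuc_mask = preprocess_channel(frame.nuclear_channel, params, cal)
    neu_mask = preprocess_channel(frame.neurite_channel, params, cal)

    regions = split_touching_nuclei(
        nuc_mask, config.min_peak_separation_px, config.h_depth
    )
    nuclei_summary = measure_regions(regions)

    assignment = identify_neurons(regions, neu_mask)
    neu_mask = remove_orphan_components(neu_mask, assignment, regions)
    soma_mask = detect_somata(neu_mask, regions, config.soma_radius_px)

    upscaled = upscale_mask(neu_mask, config.upscale_factor)
    upscaled = smooth_mask(upscaled, config.smoothing_sigma_px)
    skeleton = skeletonize_propagated(upscaled, config.epsilon_px)
    skeleton = prune_soma_overlap(skeleton, soma_mask)

    return compute_image_metrics(
        frame_id=frame.frame_id,
        condition=frame.condition,
        nuclei_summary=nuclei_summary,
        neuron_count=assignment.neuron_count,
        total_soma_area_um2=soma_mask.area_um2(),
        neurite_area_um2=neurite_area_um2(neu_mask, soma_mask),
        total_neurite_length_um=total_length_um(skeleton, tip_correction=True),
        branch_stats=branch_statistics(skeleton),
        denominator=config.denominator,
    )


def _process_row(row: dict, config: PipelineConfig) -> ImageMetrics:
    condition = Condition(
        compound=str(row["compound"]),
        concentration_nM=float(row["concentration_nM"]),
        is_control=bool(row["is_control"]),
        experiment_id=str(row["experiment_id"]),
    )
    t0 = time.perf_counter()
    frame = read_frame(row["frame"], config.calibration, condition)
    metrics = analyze_frame(frame, config)
    logger.info("frame %s analysed in %.2f s", frame.frame_id, time.perf_counter() - t0)
    return metrics


def run_batch(
    config: PipelineConfig,
    manifest: "pd.DataFrame | str | Path",
    frames: Optional[Sequence[MicrographFrame]] = None,
) -> dict:
    """Process every manifest row through all stages and write result tables.

    The manifest needs columns ``frame`` (TIFF path), ``experiment_id``,
    ``compound``, ``concentration_nM`` and ``is_control``.  Alternatively,
    in-memory frames can be passed directly (``frames``), in which case the
    manifest is derived from their condition labels.

    Per-image rows are appended to ``metrics.csv`` as they complete; a
    failing frame is logged and flagged excluded without aborting the batch.
    After all frames: sorted rewrite of the metrics table, percent-of-control
    normalization, per-condition summary and (when the design allows it) a
    dose-response fit.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_path = out_dir / "metrics.csv"

    if frames is not None:
        manifest = pd.DataFrame(
            {
                "frame": ["<memory>"] * len(frames),
                "experiment_id": [f.condition.experiment_id for f in frames],
                "compound": [f.condition.compound for f in frames],
                "concentration_nM": [f.condition.concentration_nM for f in frames],
                "is_control": [f.condition.is_control for f in frames],
            }
        )
    elif not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        raise ValueError("empty manifest")
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")

    rows = manifest.to_dict("records")
    results: List[ImageMetrics] = []
    columns = list(ImageMetrics("x").as_dict())
    with open(metrics_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        fh.flush()

        def handle(metrics: ImageMetrics) -> None:
            results.append(metrics)
            writer.writerow(metrics.as_dict())
            fh.flush()

        if frames is not None:
            for frame in frames:
                try:
                    handle(analyze_frame(frame, config))
                except Exception as exc:  # noqa: BLE001 - a bad frame must not kill the batch
                    logger.exception("frame %s failed", frame.frame_id)
                    handle(ImageMetrics(frame_id=frame.frame_id, excluded=True,
                                        exclude_reason=f"error: {exc}"))
        elif config.workers > 1:
            from joblib import Parallel, delayed

            outs = Parallel(n_jobs=config.workers, backend="threading")(
                delayed(_safe_process)(row, config) for row in rows
            )
            for metrics in outs:
                handle(metrics)
        else:
            for row in rows:
                handle(_safe_process(row, config))

    table = metrics_table(results).sort_values("frame_id", kind="mergesort").reset_index(drop=True)
    table.to_csv(metrics_path, index=False)

    outputs = {"metrics": table, "metrics_path": metrics_path}

    usable = table[~table["excluded"]]
    has_control = (
        ((usable["compound"] == config.control_compound) | usable["is_control"]).any()
        if not usable.empty
        else False
    )
    if has_control:
        normalized = normalize_to_control(table, config.control_compound)
        normalized.to_csv(out_dir / "metrics_normalized.csv", index=False)
        outputs["normalized"] = normalized

        summary = (
            normalized[~normalized["excluded"]]
            .groupby(["compound", "concentration_nM"])
            .agg(
                n=("frame_id", "size"),
                mean_length_pct=("neurite_length_per_cell_um_pct_control", "mean"),
                sem_length_pct=("neurite_length_per_cell_um_pct_control", "sem"),
                mean_length_um=("neurite_length_per_cell_um", "mean"),
                mean_nuclei=("nuclei_count", "mean"),
                mean_branches_per_cell=("branches_per_cell", "mean"),
            )
            .reset_index()
        )
        summary.to_csv(out_dir / "summary.csv", index=False)
        outputs["summary"] = summary

        dosed = normalized[
            ~normalized["excluded"]
            & ~normalized["is_control"]
            & (normalized["concentration_nM"] > 0)
        ]
        if len(dosed["concentration_nM"].unique()) >= 4:
            fit = fit_four_param_logistic(
                dosed["concentration_nM"].to_numpy(),
                dosed["neurite_length_per_cell_um_pct_control"].to_numpy(),
                top_value=100.0,
            )
            pd.DataFrame([fit.__dict__]).to_csv(out_dir / "dose_response_fit.csv", index=False)
            outputs["fit"] = fit
    return outputs


def _safe_process(row: dict, config: PipelineConfig) -> ImageMetrics:
    try:
        return _process_row(row, config)
    except Exception as exc:  # noqa: BLE001
        logger.exception("frame %s failed", row.get("frame"))
        return ImageMetrics(
            frame_id=str(Path(str(row.get("frame", "unknown"))).stem),
            compound=str(row.get("compound", "")),
            concentration_nM=float(row.get("concentration_nM", 0.0)),
            is_control=bool(row.get("is_control", False)),
            experiment_id=str(row.get("experiment_id", "")),
            excluded=True,
            exclude_reason=f"error: {exc}",
        )
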