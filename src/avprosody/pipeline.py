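"""End-to-end orchestration: frames -> windows -> sine fits -> models -> report.

A pipeline run is a pure function of (inputs, config, seed).  Every bundle is
stamped with a hash of the configuration, and an audit log records how many
records survive each stage, so runs are comparable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import measurements_io as mio
from .errors import MissingArtifactError
from .peak_windows import SegmentWindow, build_windows, raise_scope, window_meta, windows_to_frame
from .prominence_stats import (
    MixedModelResult,
    combined_model,
    fit_peak_model,
    make_model_table,
    positional_summary,
    select_best_window,
    split_by_peak,
)
from .sine_model import sweep_window_sizes, window_duration_ms
from .synthetic import SyntheticConfig, generate_dataset

REGION_PREDICTORS = ("I", "A", "f", "phi")


@dataclass
class PipelineConfig:
    """Settings of one analysis run."""

    fps: float = 30.0
    half_width: int = 60
    sweep_sizes: tuple[int, ...] = tuple(range(10, 21))
    pre_size: int = 19
    post_size: int = 17
    peak_split_threshold: float = 1.5
    alpha: float = 0.05
    scope_correction: str = "holm"
    gam_k: int = 30
    gam_k_split: int = 10
    pitch_scale: str = "as-is"  # or "zscore" (per-speaker standardization)
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineBundle:
    """All artifacts of one run, with provenance."""

    config: PipelineConfig
    config_hash: str
    windows: list[SegmentWindow]
    window_meta: pd.DataFrame
    fits_pre: pd.DataFrame
    fits_post: pd.DataFrame
    scope: object  # ScopeResult
    summaries: dict  # label -> {signal -> PositionalSummary}
    models: dict[str, MixedModelResult]
    selection_table: pd.DataFrame
    audit_log: list[str] = field(default_factory=list)

    ARTIFACTS = (
        "windows",
        "fits_pre",
        "fits_post",
        "scope",
        "summaries",
        "models",
        "selection_table",
    )


def run_pipeline(
    records: pd.DataFrame, config: PipelineConfig | None = None
) -> PipelineBundle:
    """Run every stage on an already-segmented frame table.

    ``records`` must carry segment_id (use peak_windows.attach_segments or the
    synthetic generator first).  With ``pitch_scale="zscore"`` pitch and
    eyebrow height are per-speaker standardized before windowing.
    """
    cfg = config or PipelineConfig()
    log: list[str] = [f"frames: {len(records)}"]
    if cfg.pitch_scale == "zscore":
        from .face_geometry import standardize_by_speaker

        records = standardize_by_speaker(records)
        log.append("standardized eyebrow/pitch per speaker")

    windows = build_windows(records, half_width=cfg.half_width)
    log.append(f"segments with eyebrow peak: {len(windows)}")

    scope = (
        raise_scope(windows, alpha=cfg.alpha, correction=cfg.scope_correction)
        if len(windows) >= 2
        else None
    )

    fits_pre = sweep_window_sizes(windows, "pre", cfg.sweep_sizes, fps=cfg.fps)
    fits_post = sweep_window_sizes(windows, "post", cfg.sweep_sizes, fps=cfg.fps)
    for region, fits in (("pre", fits_pre), ("post", fits_post)):
        ok = int((~fits["skipped"].astype(bool)).sum())
        log.append(f"{region} fits: {ok} ok / {len(fits)} attempted")

    meta = window_meta(windows)
    low, high = split_by_peak(windows, cfg.peak_split_threshold)
    log.append(f"peak split at {cfg.peak_split_threshold} SD: {len(low)} low, {len(high)} high")

    summaries: dict = {}
    for label, subset, k in (
        ("all", windows, cfg.gam_k),
        ("low", low, cfg.gam_k_split),
        ("high", high, cfg.gam_k_split),
    ):
        summaries[label] = {}
        for signal in ("eyebrow", "pitch"):
            try:
                summaries[label][signal] = positional_summary(
                    subset, signal=signal, k=k, subset_label=label
                )
            except Exception as exc:  # degenerate subsets stay absent, logged
                log.append(f"summary {label}/{signal} unavailable: {exc}")

    models: dict[str, MixedModelResult] = {}
    # Window-size selection: AIC values are only comparable when every
    # candidate model sees the same response data, so the per-size models are
    # restricted to segments whose pre region is fittable at all sizes.
    per_size: dict[int, MixedModelResult] = {}
    size_tables = {
        size: make_model_table(fits_pre, meta, "pre", size) for size in cfg.sweep_sizes
    }
    common = None
    for table in size_tables.values():
        ids = set(table["segment_id"])
        common = ids if common is None else (common & ids)
    common = common or set()
    log.append(f"segments fittable at every pre size: {len(common)}")
    for size, table in size_tables.items():
        table = table[table["segment_id"].isin(common)]
        if len(table) < 10 or table["speaker"].nunique() < 2:
            continue
        try:
            per_size[size] = fit_peak_model(
                table, predictors=REGION_PREDICTORS, region="pre", window_sizes=(size,)
            )
        except Exception as exc:
            log.append(f"pre model at size {size} failed: {exc}")
    if per_size:
        best_size, best_model, selection_table = select_best_window(per_size)
        log.append(f"best pre window by ML-AIC: {best_size}")
    else:
        best_size, best_model = None, None
        selection_table = pd.DataFrame(columns=["window_size", "aic_ml", "n_obs"])

    def _named_model(region, fits, size):
        table = make_model_table(fits, meta, region, size)
        if len(table) < 10 or table["speaker"].nunique() < 2:
            log.append(f"{region}-{size} model: no data")
            return None
        return fit_peak_model(
            table, predictors=REGION_PREDICTORS, region=region, window_sizes=(size,)
        )

    m_pre = _named_model("pre", fits_pre, cfg.pre_size)
    if m_pre is not None:
        models[f"pre_{cfg.pre_size}"] = m_pre
    m_post = _named_model("post", fits_post, cfg.post_size)
    if m_post is not None:
        models[f"post_{cfg.post_size}"] = m_post
    if m_pre is not None and m_post is not None:
        try:
            models["combined"] = combined_model(
                fits_pre, fits_post, meta, pre_size=cfg.pre_size, post_size=cfg.post_size
            )
        except Exception as exc:
            log.append(f"combined model failed: {exc}")
    if best_model is not None and best_size is not None:
        models[f"pre_best_{best_size}"] = best_model

    return PipelineBundle(
        config=cfg,
        config_hash=cfg.config_hash(),
        windows=windows,
        window_meta=meta,
        fits_pre=fits_pre,
        fits_post=fits_post,
        scope=scope,
        summaries=summaries,
        models=models,
        selection_table=selection_table,
        audit_log=log,
    )


def run_synthetic_pipeline(
    syn_config: SyntheticConfig, pipe_config: PipelineConfig | None = None
) -> tuple[PipelineBundle, "object"]:
    """Generate a synthetic dataset and run the pipeline on it.

    Returns (bundle, truth).  Synthetic eyebrow series are already in z-like
    units, so the default pitch_scale="as-is" applies.
    """
    records, _, truth = generate_dataset(syn_config)
    bundle = run_pipeline(records, pipe_config)
    return bundle, truth


def write_bundle(bundle: PipelineBundle, out_dir: str | Path) -> dict:
    """Serialize all artifacts as TSV/JSON under ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    windows_pitch = windows_to_frame(bundle.windows, "pitch")
    windows_eyebrow = windows_to_frame(bundle.windows, "eyebrow")
    mio.write_window_table(windows_pitch, out / "windows_pitch.tsv")
    mio.write_window_table(windows_eyebrow, out / "windows_eyebrow.tsv")
    bundle.window_meta.to_csv(out / "window_meta.tsv", sep="\t", index=False, na_rep="NA")
    bundle.fits_pre.to_csv(out / "fits_pre.tsv", sep="\t", index=False, na_rep="NA")
    bundle.fits_post.to_csv(out / "fits_post.tsv", sep="\t", index=False, na_rep="NA")
    if bundle.scope is not None:
        scope_df = pd.DataFrame(
            {
                "position": bundle.scope.positions,
                "p_corrected": bundle.scope.p_values,
                "elevated": bundle.scope.elevated,
                "significant": [
                    int(p) in bundle.scope.significant_positions
                    for p in bundle.scope.positions
                ],
            }
        )
        scope_df.to_csv(out / "scope.tsv", sep="\t", index=False)
    for label, by_signal in bundle.summaries.items():
        for signal, summ in by_signal.items():
            summ.to_frame().to_csv(
                out / f"summary_{label}_{signal}.tsv", sep="\t", index=False
            )
    for name, model in bundle.models.items():
        model.to_frame().to_csv(out / f"model_{name}.tsv", sep="\t", index=False)
    bundle.selection_table.to_csv(out / "window_selection.tsv", sep="\t", index=False)
    manifest = {
        "config_hash": bundle.config_hash,
        "seed": bundle.config.seed,
        "artifacts": sorted(p.name for p in out.glob("*.tsv")),
        "audit_log": bundle.audit_log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_report(bundle: PipelineBundle) -> str:
    """Human-readable summary: model tables, scope interval, mean r^2 per size."""
    for name in ("fits_pre", "fits_post"):
        if getattr(bundle, name, None) is None:
            raise MissingArtifactError(f"bundle lacks artifact {name!r}")
    lines = [
        "avprosody pipeline report",
        f"config hash: {bundle.config_hash}   seed: {bundle.config.seed}",
        "",
        f"windows: {len(bundle.windows)}",
        f"pre window: {bundle.config.pre_size} frames "
        f"(~{window_duration_ms(bundle.config.pre_size, bundle.config.fps):.0f} ms); "
        f"post window: {bundle.config.post_size} frames "
        f"(~{window_duration_ms(bundle.config.post_size, bundle.config.fps):.0f} ms)",
        "",
    ]
    if bundle.scope is not None:
        run = bundle.scope.significant_run()
        lines.append(
            "raise scope (elevated positions): "
            + (f"{run[0]} .. {run[1]}" if run else "none")
        )
        lines.append("")
    if not bundle.models:
        lines.append("no model")
    for name, model in bundle.models.items():
        lines.append(f"model {name} (n={model.n_obs}, speakers={model.n_groups}):")
        tab = model.fixed_effects.copy()
        lines.append(
            tab.to_string(
                float_format=lambda v: f"{v:10.3f}", header=True, justify="right"
            )
        )
        lines.append(
            f"  random-intercept var {model.random_intercept_variance:.4f}, "
            f"residual var {model.residual_variance:.4f}"
        )
        lines.append("")
    for region, fits in (("pre", bundle.fits_pre), ("post", bundle.fits_post)):
        ok = fits[~fits["skipped"].astype(bool)]
        if len(ok):
            r2 = ok.groupby("window_size")["r2"].mean()
            lines.append(
                f"mean r2 ({region}): "
                + ", ".join(f"size {int(s)}: {v:.3f}" for s, v in r2.items())
            )
    return "\n".join(lines) + "\n"


def reproduce_supplementary(
    pitch_windows_path: str | Path,
    eyebrow_windows_path: str | Path,
    meta_path: str | Path | None = None,
    pre_size: int = 19,
    post_size: int = 17,
    r2_size: int = 20,
) -> dict:
    """Recompute the headline quantities from window-table files.

    Intended for the published per-segment window tables (pitch and eyebrow
    series at positions -60...60 around the peak).  Speakers are taken from a
    meta table (segment_id, speaker) when given, else from the episode prefix
    of each segment id.  Returns worked-example post-fits, per-region model
    coefficients at the named sizes, mean r^2 at ``r2_size``, and the segment
    count.
    """
    pitch = mio.read_window_table(pitch_windows_path)
    eyebrow = mio.read_window_table(eyebrow_windows_path)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        speaker_of = dict(zip(meta["segment_id"], meta["speaker"]))
    else:
        speaker_of = {}
    windows = []
    for seg_id in pitch.index:
        eb = (
            eyebrow.loc[seg_id].to_numpy(dtype=float)
            if seg_id in eyebrow.index
            else np.full(len(mio.POSITIONS), np.nan)
        )
        center = len(mio.POSITIONS) // 2
        windows.append(
            SegmentWindow(
                segment_id=str(seg_id),
                speaker=speaker_of.get(seg_id, str(seg_id).split("-")[0]),
                peak_frame=0,
                peak_height=float(eb[center]) if np.isfinite(eb[center]) else np.nan,
                eyebrow=eb,
                pitch=pitch.loc[seg_id].to_numpy(dtype=float),
            )
        )
    out: dict = {"n_segments": len(windows)}
    sizes = sorted({pre_size, post_size, r2_size})
    fits_pre = sweep_window_sizes(windows, "pre", sizes)
    fits_post = sweep_window_sizes(windows, "post", sizes)
    for table, region in ((fits_pre, "pre"), (fits_post, "post")):
        ok = table[(~table["skipped"].astype(bool)) & (table["window_size"] == r2_size)]
        if len(ok):
            out[f"mean_r2_{region}_{r2_size}"] = float(ok["r2"].mean())
    meta_df = window_meta(windows)
    try:
        pre_model = fit_peak_model(
            make_model_table(fits_pre, meta_df, "pre", pre_size),
            predictors=REGION_PREDICTORS,
            region="pre",
            window_sizes=(pre_size,),
        )
        post_model = fit_peak_model(
            make_model_table(fits_post, meta_df, "post", post_size),
            predictors=REGION_PREDICTORS,
            region="post",
            window_sizes=(post_size,),
        )
        comb = combined_model(fits_pre, fits_post, meta_df, pre_size, post_size)
        out["pre_model"] = pre_model.fixed_effects
        out["post_model"] = post_model.fixed_effects
        out["combined_model"] = comb.fixed_effects
    except Exception as exc:
        out["model_error"] = str(exc)
    out["post_fits"] = fits_post[
        (fits_post["window_size"] == post_size) & (~fits_post["skipped"].astype(bool))
    ][["segment_id", "I", "A", "f", "phi", "r2"]]
    return out
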