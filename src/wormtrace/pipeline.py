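"""End-to-end orchestration: simulate/load -> project -> register ->
segment -> track -> trace -> pool -> classify -> summarize.

A run processes a batch of movies with shared stage parameters, excludes
movies whose tracking fails (recording them in the manifest rather than
dropping them silently), pools the surviving normalized traces per
condition, and writes a results bundle of CSV/JSON files whose manifest
(config + seed) suffices to reproduce every output bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import MovieStack, max_project, read_stack, write_traces
from .registration import register_movie
from .segmentation import (DEFAULT_FEATURE_BANK, FeatureBankConfig,
                           TrainingSet, apply_classifier, postprocess_masks,
                           train_pixel_classifier, UNLABELED)
from .synthetic import SceneConfig, simulate_movie
from .tracking import track_movie
from .traces import (ClassifierThresholds, classify_response,
                     compute_background_series, extract_trace,
                     normalize_trace, pool_traces, summarize_calls,
                     traces_to_frame)

__all__ = ["StageParams", "RunConfig", "MovieResult", "ResultsBundle",
           "process_movie", "run"]


@dataclass
class StageParams:
    """Every tunable of the analysis, with its default."""

    max_shift: int = 20
    score_floor: float = 0.3
    feature_bank: FeatureBankConfig = DEFAULT_FEATURE_BANK
    tree_max_depth: int = 8
    tree_min_leaf: int = 20
    n_training_frames: int = 10
    min_area: int = 5
    expected_count: int = 2
    gate_px: float = 15.0
    max_gap: int = 10
    init_window: int = 10
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    subtract_background: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_bank"] = self.feature_bank.to_list()
        return d


@dataclass
class RunConfig:
    """One batch: synthetic scenes and/or movie files, plus stage params."""

    scenes: list[SceneConfig] = field(default_factory=list)
    movie_paths: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)  # one per movie
    params: StageParams = field(default_factory=StageParams)
    out_dir: str | None = None
    seed: int = 0

    def n_movies(self) -> int:
        return len(self.scenes) + len(self.movie_paths)

    def to_dict(self) -> dict:
        return {
            "scenes": [s.to_dict() for s in self.scenes],
            "movie_paths": list(self.movie_paths),
            "conditions": list(self.conditions),
            "params": self.params.to_dict(),
            "out_dir": self.out_dir,
            "seed": self.seed,
        }


@dataclass
class MovieResult:
    movie_id: str
    condition: str
    failed: bool = False
    failure_reason: str = ""
    shift_series: object = None
    tracking: object = None
    raw_traces: list = field(default_factory=list)
    norm_traces: list = field(default_factory=list)
    calls: list = field(default_factory=list)
    ground_truth: object = None


@dataclass
class ResultsBundle:
    movies: list[MovieResult]
    calls_table: pd.DataFrame
    fraction_table: pd.DataFrame
    pooled: dict[str, object]  # condition -> PooledResponse
    manifest: dict


def _training_labels_from_truth(gt, frame_ids) -> list[np.ndarray]:
    """Dense labels (neuron=1, background=0) from simulator masks, standing
    in for manual annotation of the training frames."""
    labels = []
    any_masks = None
    for m in gt.masks.values():
        any_masks = m.copy() if any_masks is None else (any_masks | m)
    for t in frame_ids:
        lab = np.zeros(any_masks.shape[1:], dtype=np.uint8)
        lab[any_masks[t]] = 1
        labels.append(lab)
    return labels


def process_movie(movie: MovieStack, params: StageParams,
                  classifier=None, ground_truth=None,
                  movie_id: str = "", condition: str = "",
                  seed: int = 0) -> MovieResult:
    """Run the full single-movie analysis.

    A classifier must either be supplied or trainable from simulator ground
    truth (the stand-in for manual scribble labels on ~10 frames).
    """
    res = MovieResult(movie_id=movie_id or movie.source_id, condition=condition,
                      ground_truth=ground_truth)
    proj = max_project(movie)
    registered, shifts = register_movie(proj, params.max_shift, params.score_floor)
    res.shift_series = shifts

    if classifier is None:
        if ground_truth is None:
            raise ValueError("need a trained classifier or simulator ground truth")
        T = proj.n_frames
        frame_ids = sorted(set(np.linspace(0, T - 1, params.n_training_frames,
                                           dtype=int).tolist()))
        training = TrainingSet(
            frames=[proj.data[t].astype(float) for t in frame_ids],
            labels=_training_labels_from_truth(ground_truth, frame_ids),
            frame_ids=frame_ids,
        )
        classifier = train_pixel_classifier(
            training, params.feature_bank,
            max_depth=params.tree_max_depth,
            min_leaf=params.tree_min_leaf,
            seed=seed,
        )

    masks = apply_classifier(registered.data.astype(float), classifier)
    segmentations = [
        postprocess_masks(masks[t], registered.data[t].astype(float), frame=t,
                          min_area=params.min_area,
                          expected_count=params.expected_count)
        for t in range(registered.n_frames)
    ]
    tracking = track_movie(segmentations, params.expected_count,
                           params.gate_px, params.max_gap, params.init_window)
    res.tracking = tracking
    if tracking.failed or any(t.terminated for t in tracking.tracks):
        res.failed = True
        res.failure_reason = tracking.failure_reason or "track terminated by gap rule"
        return res

    background = compute_background_series(registered, segmentations, shifts)
    for track in tracking.tracks:
        try:
            raw = extract_trace(registered, track, segmentations,
                                shift_series=shifts, max_gap=params.max_gap,
                                background=background,
                                movie_id=res.movie_id)
            norm = normalize_trace(raw, params.subtract_background)
        except ValueError as exc:
            res.failed = True
            res.failure_reason = str(exc)
            return res
        res.raw_traces.append(raw)
        res.norm_traces.append(norm)
        res.calls.append(classify_response(norm, params.thresholds))
    return res


def run(config: RunConfig) -> ResultsBundle:
    """Process the whole batch and assemble (optionally write) the bundle.

    Per-movie errors are contained: a movie that fails tracking or loading
    is excluded from pooling and listed in the manifest.
    """
    movies: list[MovieResult] = []
    conditions = config.conditions or ["all"] * config.n_movies()
    if len(conditions) != config.n_movies():
        raise ValueError("conditions must match the number of movies")

    idx = 0
    for scene in config.scenes:
        movie, gt = simulate_movie(scene)
        movies.append(process_movie(
            movie, config.params, ground_truth=gt,
            movie_id=f"scene{idx:03d}", condition=conditions[idx],
            seed=config.seed))
        idx += 1
    for path in config.movie_paths:
        try:
            movie = read_stack(path)
        except Exception as exc:  # containment: record, continue
            movies.append(MovieResult(movie_id=str(path), condition=conditions[idx],
                                      failed=True, failure_reason=f"load error: {exc}"))
            idx += 1
            continue
        movies.append(process_movie(
            movie, config.params,
            movie_id=str(path), condition=conditions[idx], seed=config.seed))
        idx += 1

    ok = [m for m in movies if not m.failed]
    all_calls = [c for m in ok for c in m.calls]
    call_conditions = [m.condition for m in ok for _ in m.calls]
    calls_table = pd.DataFrame([{
        "movie_id": c.movie_id, "condition": cond, "neuron": c.identity,
        "class": c.response_class, "peak_dff": c.peak_dff,
        "peak_offset_s": c.peak_offset_frames * m.raw_traces[0].frame_interval_s
        if m.raw_traces else np.nan,
        "baseline_sigma": c.baseline_sigma,
        "theta_abs": c.thresholds.theta_abs,
        "theta_high": c.thresholds.theta_high,
        "k_sigma": c.thresholds.k_sigma,
    } for m in ok for cond, c in zip([m.condition] * len(m.calls), m.calls)])
    fraction_table = (summarize_calls(all_calls, call_conditions)
                      if all_calls else pd.DataFrame())

    pooled = {}
    for cond in sorted(set(call_conditions)):
        traces = [tr for m in ok if m.condition == cond for tr in m.norm_traces]
        if len(traces) >= 2:
            pooled[cond] = pool_traces(traces)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_movies": config.n_movies(),
        "failed_movies": [{"movie_id": m.movie_id, "reason": m.failure_reason}
                          for m in movies if m.failed],
    }
    bundle = ResultsBundle(movies=movies, calls_table=calls_table,
                           fraction_table=fraction_table, pooled=pooled,
                           manifest=manifest)
    if config.out_dir:
        _write_bundle(bundle, config.out_dir)
    return bundle


def _write_bundle(bundle: ResultsBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ok = [m for m in bundle.movies if not m.failed]
    if ok:
        frames = [traces_to_frame(m.raw_traces, m.norm_traces) for m in ok]
        write_traces(pd.concat(frames, ignore_index=True), out / "traces.csv")
    bundle.calls_table.to_csv(out / "calls.csv", index=False, float_format="%.9g")
    if len(bundle.fraction_table):
        bundle.fraction_table.to_csv(out / "fractions.csv", index=False,
                                     float_format="%.9g")
    for cond, pr in bundle.pooled.items():
        pd.DataFrame({"offset_frames": pr.offsets, "mean": pr.mean,
                      "sd": pr.sd, "n": pr.n}).to_csv(
            out / f"pooled_{cond}.csv", index=False, float_format="%.9g")
    for m in bundle.movies:
        if m.shift_series is not None:
            m.shift_series.to_json(out / f"shifts_{m.movie_id}.json")
        if m.tracking is not None:
            m.tracking.to_json(out / f"tracks_{m.movie_id}.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1)
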