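"""End-to-end pipeline orchestration and persisted stage outputs.

Stage order: spectra -> coupling -> global quartiles -> per-subject
summaries -> subgroup averages -> group regression -> difference matrices.
Each stage persists its output under the run directory so any stage can be
re-run standalone on the previous stage's files; a ``run_manifest.json``
records the configuration, input hashes and stage timings.  All tabular
outputs are deterministic TSV; the WW maps (the expensive intermediate)
are stored as one compressed ``.npz`` per subject.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import coupling, group_stats, io_core, quartiles, spectra
from .io_core import (
    CohortMetadata,
    NetworkLabels,
    TimecourseDataset,
    ValidationError,
    write_matrix,
    write_table,
)

logger = logging.getLogger("trsc")
if not logger.handlers:  # stage/timing lines to stderr, results on stdout only via report
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("[trsc] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    manifest: str = ""
    metadata: str = ""
    labels: str = ""
    out_dir: str = "out"
    window_length: int = 50
    step: int = 1
    taper: str | None = None
    zscore: bool = False
    strict: bool = True
    alpha: float = 0.05
    fdr_family: str = "per-matrix"
    render: bool = False
    seed: int = 0

    def validate(self, n_timepoints: int) -> spectra.WindowingScheme:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        return spectra.make_scheme(n_timepoints, self.window_length, self.step)


@dataclass
class AnalysisResult:
    """In-memory result bundle of one cohort analysis."""

    scheme: spectra.WindowingScheme
    thresholds: quartiles.QuartileThresholds
    summaries: pd.DataFrame
    stats: pd.DataFrame
    matrices: dict
    subgroup_means: dict = field(default_factory=dict)


def analyze_cohort(
    dataset: TimecourseDataset,
    metadata: CohortMetadata,
    window_length: int = 50,
    step: int = 1,
    taper: str | None = None,
    zscore: bool = False,
    strict: bool = True,
    alpha: float = 0.05,
    fdr_family: str = "per-matrix",
    subgroup_averages: bool = False,
) -> AnalysisResult:
    """Run the full trSC analysis in memory (vectorized fast path).

    Computes spectrograms, all pairwise WW maps, global quartile
    thresholds, per-subject occupancy summaries, and the group-difference
    regression.  Suitable whenever the full stack of WW maps
    (subjects x pairs x Tw^2 float32) fits in memory.
    """
    scheme = spectra.make_scheme(dataset.n_timepoints, window_length, step)
    power = spectra.spectrogram_stack(
        dataset.data, scheme, dataset.tr_seconds, taper=taper, zscore=zscore
    )  # (N, C, S, Tw)
    pairs = coupling.component_pairs(dataset.n_components)
    n = dataset.n_subjects
    ww = np.empty((n, len(pairs), scheme.n_windows, scheme.n_windows), dtype=np.float32)
    for s in range(n):
        ww[s] = coupling.ww_map_stack(power[s], strict=strict)
    th = quartiles.global_quartiles(ww)
    records = []
    for s in range(n):
        counts, avgs = quartiles.summarize_stack(ww[s], th)
        sid = dataset.subject_ids[s]
        for p, (i, j) in enumerate(pairs):
            for q in range(4):
                records.append((sid, i, j, q + 1, counts[p, q], avgs[p, q]))
    summaries = pd.DataFrame(
        records,
        columns=["subject", "pair_i", "pair_j", "quartile", "cell_count", "avg_cluster_size"],
    )
    stats = group_stats.fit_all(summaries, metadata, alpha=alpha, fdr_family=fdr_family)
    matrices = group_stats.difference_matrices(stats, alpha, dataset.n_components)
    result = AnalysisResult(scheme, th, summaries, stats, matrices)
    if subgroup_averages:
        for grouping in ("diagnosis", "sex"):
            result.subgroup_means.update(
                {
                    (grouping,) + k: v
                    for k, v in quartiles.subgroup_average(
                        summaries, metadata, grouping, dataset.n_components
                    ).items()
                }
            )
    return result


# ---------------------------------------------------------------------------
# persisted stage runners (file in, file out)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_spectra(config: RunConfig, dataset: TimecourseDataset) -> str:
    scheme = config.validate(dataset.n_timepoints)
    out = os.path.join(config.out_dir, "spectrograms")
    os.makedirs(out, exist_ok=True)
    power = spectra.spectrogram_stack(
        dataset.data, scheme, dataset.tr_seconds, taper=config.taper, zscore=config.zscore
    )
    freq = spectra.bin_frequencies(config.window_length, dataset.tr_seconds)
    for sid, p in zip(dataset.subject_ids, power):
        np.savez_compressed(os.path.join(out, f"{sid}.npz"), power=p, freq_hz=freq)
    return out


def stage_coupling(config: RunConfig, dataset: TimecourseDataset) -> str:
    spec_dir = os.path.join(config.out_dir, "spectrograms")
    out = os.path.join(config.out_dir, "wwmaps")
    os.makedirs(out, exist_ok=True)
    for sid in dataset.subject_ids:
        with np.load(os.path.join(spec_dir, f"{sid}.npz")) as z:
            power = z["power"]
        ww = coupling.ww_map_stack(power, strict=config.strict)
        np.savez_compressed(os.path.join(out, f"{sid}.npz"), ww=ww)
    return out


def stage_quartiles(
    config: RunConfig, dataset: TimecourseDataset, metadata: CohortMetadata
) -> tuple[quartiles.QuartileThresholds, pd.DataFrame]:
    ww_dir = os.path.join(config.out_dir, "wwmaps")

    def _stream():
        for sid in dataset.subject_ids:
            with np.load(os.path.join(ww_dir, f"{sid}.npz")) as z:
                yield z["ww"]

    th = quartiles.global_quartiles(_stream())
    write_table(
        pd.DataFrame({"quantile": [0.25, 0.50, 0.75], "threshold": list(th.as_array())}),
        os.path.join(config.out_dir, "thresholds.tsv"),
    )
    pairs = coupling.component_pairs(dataset.n_components)
    records = []
    for sid in dataset.subject_ids:
        with np.load(os.path.join(ww_dir, f"{sid}.npz")) as z:
            counts, avgs = quartiles.summarize_stack(z["ww"], th)
        for p, (i, j) in enumerate(pairs):
            for q in range(4):
                records.append((sid, i, j, q + 1, counts[p, q], avgs[p, q]))
    summaries = pd.DataFrame(
        records,
        columns=["subject", "pair_i", "pair_j", "quartile", "cell_count", "avg_cluster_size"],
    )
    write_table(
        summaries,
        os.path.join(config.out_dir, "quartile_summaries.tsv"),
        sort_keys=["subject", "pair_i", "pair_j", "quartile"],
    )
    for grouping in ("diagnosis", "sex"):
        means = quartiles.subgroup_average(summaries, metadata, grouping, dataset.n_components)
        for (level, q, measure), mat in means.items():
            write_matrix(
                mat,  # diagonal stays NaN (self-pairs undefined)
                dataset.component_ids,
                os.path.join(config.out_dir, "subgroup_means", f"{level}_q{q}_{measure}.tsv"),
                header_lines=[f"group mean of {measure}, quartile {q}, {grouping}={level}"],
            )
    return th, summaries


def stage_stats(
    config: RunConfig, dataset: TimecourseDataset, metadata: CohortMetadata
) -> pd.DataFrame:
    summaries = io_core.read_table(os.path.join(config.out_dir, "quartile_summaries.tsv"))
    stats = group_stats.fit_all(
        summaries, metadata, alpha=config.alpha, fdr_family=config.fdr_family
    )
    write_table(
        stats,
        os.path.join(config.out_dir, "pair_stats.tsv"),
        sort_keys=["quartile", "measure", "contrast", "pair_i", "pair_j"],
    )
    matrices = group_stats.difference_matrices(stats, config.alpha, dataset.n_components)
    for (q, measure, contrast), mat in matrices.items():
        if config.render:
            group_stats.render_heatmap(
                mat,
                os.path.join(
                    config.out_dir, "difference_matrices", f"q{q}_{measure}_{contrast}.png"
                ),
                component_ids=dataset.component_ids,
                title=f"Q{q} {measure} {contrast}",
            )
        write_matrix(
            mat,
            dataset.component_ids,
            os.path.join(config.out_dir, "difference_matrices", f"q{q}_{measure}_{contrast}.tsv"),
            header_lines=[
                "signed -log10(p) * sign(t); upper triangle: p <= alpha; lower: BH-FDR",
                "negative values = HC (diagnosis) or F (sex) dominance (SZ=1, M=1 coding)",
            ],
        )
    return stats


def run_pipeline(config: RunConfig) -> str:
    """Execute all stages on the configured inputs; returns the output directory."""
    t_all = time.perf_counter()
    dataset = io_core.load_dataset(config.manifest)
    metadata = io_core.load_metadata(config.metadata, dataset)
    if config.labels:
        io_core.load_network_labels(config.labels, dataset)
    config.validate(dataset.n_timepoints)  # fail fast before any compute
    os.makedirs(config.out_dir, exist_ok=True)
    timings = {}
    for name, fn in (
        ("spectra", lambda: stage_spectra(config, dataset)),
        ("coupling", lambda: stage_coupling(config, dataset)),
        ("quartiles", lambda: stage_quartiles(config, dataset, metadata)),
        ("stats", lambda: stage_stats(config, dataset, metadata)),
    ):
        t0 = time.perf_counter()
        logger.info("stage %s ...", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, timings[name])
    manifest = {
        "tool": "trsc",
        "version": VERSION,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {
            "manifest_sha256": _hash_file(config.manifest),
            "metadata_sha256": _hash_file(config.metadata),
            **({"labels_sha256": _hash_file(config.labels)} if config.labels else {}),
        },
        "dimensions": {
            "n_subjects": dataset.n_subjects,
            "n_components": dataset.n_components,
            "n_timepoints": dataset.n_timepoints,
            "n_pairs": len(coupling.component_pairs(dataset.n_components)),
            "n_windows": config.validate(dataset.n_timepoints).n_windows,
            "n_bins": config.window_length // 2,
        },
        "stage_seconds": timings,
    }
    with open(os.path.join(config.out_dir, "run_manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete in %.2fs -> %s", time.perf_counter() - t_all, config.out_dir)
    return config.out_dir


def report(out_dir: str) -> str:
    """Human-readable summary of a completed run (counts, thresholds, rejections)."""
    manifest_path = os.path.join(out_dir, "run_manifest.json")
    if not os.path.exists(manifest_path):
        raise ValidationError(f"{out_dir} does not contain a completed run (no run_manifest.json)")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    dims = manifest["dimensions"]
    th = io_core.read_table(os.path.join(out_dir, "thresholds.tsv"))
    stats = io_core.read_table(os.path.join(out_dir, "pair_stats.tsv"))
    lines = [
        f"trsc run summary ({out_dir})",
        f"  subjects: {dims['n_subjects']}  components: {dims['n_components']}  "
        f"timepoints: {dims['n_timepoints']}",
        f"  pairs: {dims['n_pairs']}  windows: {dims['n_windows']}  bins: {dims['n_bins']}",
        "  global quartile thresholds: "
        + ", ".join(f"q{int(q * 100)}={v:.4f}" for q, v in zip(th["quantile"], th["threshold"])),
        "  FDR rejections per (quartile, measure, contrast):",
    ]
    rej = (
        stats.groupby(["quartile", "measure", "contrast"], sort=True)["reject_fdr"]
        .sum()
        .astype(int)
    )
    for (q, measure, contrast), n in rej.items():
        lines.append(f"    Q{q} {measure:17s} {contrast:12s} {n}")
    return "\n".join(lines)
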