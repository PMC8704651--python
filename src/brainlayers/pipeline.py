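"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
threshold -> graph metrics -> statistics -> clustering.

The pipeline mirrors the study flow: for every recording and motor-imagery
class, trial-averaged coherence yields one adjacency matrix per band; each
matrix is binarized with both the fixed and the Otsu threshold; the four
single-layer metrics are computed per band network and the four multilayer
metrics on the supra-adjacency; the statistics chain then localizes key
electrodes and the LDA/k-means chain scores how completely the multilayer
metrics separate the classes.

All intermediates are plain pandas DataFrames (and TSV/JSON on disk via
:func:`run_all`), so every stage is independently testable and re-runnable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import embed_and_cluster
from .connectivity import BANDS, band_layers, coherence, cross_spectra
from .group_stats import (
    StatReport,
    electrode_posthoc,
    key_electrodes,
    metrics_to_table,
    paired_t_fdr,
    pooled_anova,
)
from .multilayer import build_supra, ml_degree, ml_eigenvector, ml_kcore, ml_pagerank
from .preprocess import DEFAULT_WINDOW, car_filter, epoch
from .single_layer import METRIC_FUNCS
from .synthetic import EEGRecording, SynthConfig, default_config, generate_recording
from .threshold import fixed_threshold, otsu_threshold, binarize

__all__ = [
    "RunConfig",
    "analyze_recording",
    "analyze_dataset",
    "single_layer_stats",
    "multilayer_stats",
    "run_all",
    "reports_to_frame",
]

log = logging.getLogger("brainlayers")


def _zero_metrics(name: str, net) -> "NodeMetrics":
    from .single_layer import NodeMetrics

    return NodeMetrics(
        values=np.zeros(net.n_nodes),
        metric=name,
        band=net.band,
        class_label=net.class_label,
        recording_id=net.recording_id,
        channel_labels=net.channel_labels,
    )

THRESHOLD_FUNCS = {"fixed": fixed_threshold, "otsu": otsu_threshold}
ML_FUNCS = {
    "degree": ml_degree,
    "eigenvector": ml_eigenvector,
    "kcore": ml_kcore,
    "pagerank": ml_pagerank,
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    synth: SynthConfig = field(default_factory=default_config)
    window: tuple[float, float] = DEFAULT_WINDOW
    bands: dict = field(default_factory=lambda: dict(BANDS))
    threshold_methods: tuple[str, ...] = ("fixed", "otsu")
    damping: float = 0.85
    interlayer_weight: float = 1.0
    alpha: float = 0.05
    seed: int = 0
    run_single_layer: bool = True
    run_multilayer: bool = True

    def __post_init__(self) -> None:
        for name in self.bands:
            if name not in BANDS:
                raise ValueError(
                    f"unknown band {name!r}; expected a subset of {sorted(BANDS)}"
                )
        for m in self.threshold_methods:
            if m not in THRESHOLD_FUNCS:
                raise ValueError(f"unknown threshold method {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_kw = raw.pop("synth", {})
        seed = raw.get("seed", 0)
        synth_kw.setdefault("seed", seed)
        synth = default_config(**synth_kw)
        kw = {}
        for key in (
            "window", "threshold_methods", "damping", "interlayer_weight",
            "alpha", "seed", "run_single_layer", "run_multilayer", "bands",
        ):
            if key in raw:
                kw[key] = raw[key]
        if "window" in kw:
            kw["window"] = tuple(kw["window"])
        if "threshold_methods" in kw:
            kw["threshold_methods"] = tuple(kw["threshold_methods"])
        return cls(synth=synth, **kw)

    def manifest(self) -> dict:
        d = asdict(self)
        d["synth"]["couplings"] = [list(map(str, c.values())) if isinstance(c, dict) else str(c) for c in d["synth"]["couplings"]]
        d["version"] = __version__
        return d


def analyze_recording(
    rec: EEGRecording,
    *,
    window: tuple[float, float] = DEFAULT_WINDOW,
    bands: dict = BANDS,
    threshold_methods: Sequence[str] = ("fixed", "otsu"),
    damping: float = 0.85,
    interlayer_weight: float = 1.0,
) -> dict:
    """CAR -> epoch -> coherence layers -> threshold -> metrics for one recording.

    Returns, per threshold method, the single-layer and multilayer
    NodeMetrics lists plus a list of per-layer threshold records.
    """
    referenced = EEGRecording(
        data=car_filter(rec.data),
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        events=rec.events,
        recording_id=rec.recording_id,
    )
    out = {
        m: {"single": [], "multilayer": [], "thresholds": []}
        for m in threshold_methods
    }
    for ts in epoch(referenced, window=window):
        if ts.n_trials < 2:
            continue
        spec = cross_spectra(ts)
        C = coherence(spec)
        stack = band_layers(
            C,
            spec.freqs,
            bands,
            class_label=ts.class_label,
            recording_id=rec.recording_id,
            channel_labels=ts.channel_labels,
        )
        for method in threshold_methods:
            nets = []
            for layer in stack.layers:
                thr = THRESHOLD_FUNCS[method](layer)
                net = binarize(layer, thr)
                nets.append(net)
                out[method]["thresholds"].append(
                    {
                        "recording_id": rec.recording_id,
                        "class_label": ts.class_label,
                        "band": layer.band,
                        "method": method,
                        "T": thr.T,
                        "n_edges": net.n_edges,
                    }
                )
                for name, fn in METRIC_FUNCS.items():
                    try:
                        nm = fn(net)
                    except ValueError:
                        # empty network (threshold above every weight):
                        # centrality is identically zero there
                        nm = _zero_metrics(name, net)
                    out[method]["single"].append(nm)
            supra = build_supra(nets, interlayer_weight=interlayer_weight)
            for name, fn in ML_FUNCS.items():
                nm = fn(supra, r=damping) if name == "pagerank" else fn(supra)
                out[method]["multilayer"].append(nm)
    return out


def analyze_dataset(cfg: SynthConfig, **kwargs) -> dict:
    """Run :func:`analyze_recording` over the whole synthetic study.

    Returns ``{method: {"single": DataFrame, "multilayer": DataFrame,
    "thresholds": DataFrame}}`` with long-format metric tables.
    """
    methods = kwargs.get("threshold_methods", ("fixed", "otsu"))
    acc = {m: {"single": [], "multilayer": [], "thresholds": []} for m in methods}
    for r in range(cfg.n_recordings):
        t0 = time.perf_counter()
        rec = generate_recording(cfg, r)
        res = analyze_recording(rec, **kwargs)
        for m in methods:
            for key in acc[m]:
                acc[m][key].extend(res[m][key])
        log.info("recording %d analyzed in %.1fs", r, time.perf_counter() - t0)
    return {
        m: {
            "single": metrics_to_table(acc[m]["single"]),
            "multilayer": metrics_to_table(acc[m]["multilayer"]),
            "thresholds": pd.DataFrame(acc[m]["thresholds"]),
        }
        for m in methods
    }


def single_layer_stats(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[StatReport], list[str]]:
    """Per-(band, metric) MANOVA + post hoc chains and the key-electrode call."""
    reports: list[StatReport] = []
    for band in table["band"].unique():
        for metric in table["metric"].unique():
            reports.extend(electrode_posthoc(table, metric, band, alpha=alpha))
    return reports, key_electrodes(reports)


def multilayer_stats(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[StatReport], list[str]]:
    """Pooled ANOVA, paired-t/FDR and MANOVA post hoc chains on multilayer metrics."""
    reports: list[StatReport] = []
    for metric in table["metric"].unique():
        reports.append(pooled_anova(table, metric, "multilayer", alpha=alpha))
        reports.extend(paired_t_fdr(table, metric, "multilayer", alpha=alpha))
        reports.extend(electrode_posthoc(table, metric, "multilayer", alpha=alpha))
    return reports, key_electrodes(reports)


def reports_to_frame(reports: Sequence[StatReport]) -> pd.DataFrame:
    """Flatten StatReports into a TSV-friendly table."""
    rows = []
    for r in reports:
        rows.append(
            {
                "test": r.test,
                "metric": r.scope.get("metric"),
                "band": r.scope.get("band"),
                "electrode": r.scope.get("electrode"),
                "comparison": "" if r.comparison is None else f"{r.comparison[0]}-{r.comparison[1]}",
                "statistic": r.statistic,
                "df": ",".join(f"{d:g}" for d in r.df),
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline for every threshold method and persist artifacts.

    Writes per-method metric tables, threshold tables, statistics reports and
    embedding coordinates as TSV, plus ``manifest.json`` (config echo) and
    ``summary.json`` (key electrodes, completeness, mean thresholds).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    log.info("pipeline start: %d recordings, methods=%s",
             config.synth.n_recordings, config.threshold_methods)
    tables = analyze_dataset(
        config.synth,
        window=config.window,
        bands=config.bands,
        threshold_methods=config.threshold_methods,
        damping=config.damping,
        interlayer_weight=config.interlayer_weight,
    )
    summary: dict = {"methods": {}}
    for method, tabs in tables.items():
        mdir = out / method
        mdir.mkdir(exist_ok=True)
        tabs["single"].to_csv(mdir / "metrics_single.tsv", sep="\t", index=False)
        tabs["multilayer"].to_csv(mdir / "metrics_multilayer.tsv", sep="\t", index=False)
        tabs["thresholds"].to_csv(mdir / "thresholds.tsv", sep="\t", index=False)
        entry: dict = {
            "mean_threshold_per_band": tabs["thresholds"].groupby("band")["T"].mean().to_dict()
        }
        if config.run_single_layer:
            reports, keys = single_layer_stats(tabs["single"], alpha=config.alpha)
            reports_to_frame(reports).to_csv(
                mdir / "stats_single.tsv", sep="\t", index=False
            )
            entry["key_electrodes_single"] = keys
        if config.run_multilayer:
            reports, keys = multilayer_stats(tabs["multilayer"], alpha=config.alpha)
            reports_to_frame(reports).to_csv(
                mdir / "stats_multilayer.tsv", sep="\t", index=False
            )
            entry["key_electrodes_multilayer"] = keys
            emb = embed_and_cluster(
                tabs["multilayer"], seed=config.seed, threshold_method=method
            )
            coords = pd.DataFrame(emb.coords, columns=["ld1", "ld2", "ld3"][: emb.coords.shape[1]])
            coords["cluster"] = emb.cluster_labels
            coords["class_label"] = emb.true_labels
            coords.to_csv(mdir / "embedding.tsv", sep="\t", index=False)
            entry["completeness"] = emb.completeness
            log.info("method=%s completeness=%.3f", method, emb.completeness)
        summary["methods"][method] = entry
    summary["runtime_s"] = round(time.perf_counter() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(config.manifest(), fh, indent=2, default=str)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("pipeline done in %.1fs", summary["runtime_s"])
    return summary
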