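"""End-to-end orchestration: load inputs, build networks, detect communities,
compute dynamic features, and run the downstream inference stages.

Every stage reads and writes plain-text artifacts (CSV/JSON) under the
configured output directory and records its parameters in a manifest, so a
run is fully reproducible from the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, pls, stats
from .community import ModularityParams, repeat_optimization
from .measures import RSNPartition, feature_names, module_allegiance, subject_features
from .networks import RegionTimeSeries, subject_multilayer
from .synthetic import SimulationDesign, generate_cohort, write_cohort

log = logging.getLogger("tmfc")


@dataclass
class PipelineConfig:
    input_dir: str = "cohort"
    output_dir: str = "results"
    tr_s: float = 3.0
    window_len_s: float = 30.0
    window_timepoints: int | None = None
    drop_initial: int = 2
    gamma: float = 1.0
    omega: float = 0.5
    n_repetitions: int = 100
    n_perm: int = 10_000
    n_boot: int = 1000
    fdr_q: float = 0.05
    mad_threshold: float = 3.0
    pls_max_components: int = 10
    pls_folds: int = 10
    seed: int = 0
    stages: tuple[str, ...] = ("measures", "stats", "classify", "pls")

    def __post_init__(self) -> None:
        for name, lo in [("tr_s", 0), ("window_len_s", 0), ("gamma", 0)]:
            if getattr(self, name) <= lo:
                raise ValueError(f"{name} must be > {lo}")
        for name in ["omega", "drop_initial"]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ["n_repetitions", "n_perm", "n_boot"]:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")

    @classmethod
    def from_manifest(cls, path: str | Path) -> "PipelineConfig":
        """Rebuild the configuration recorded in a run's manifest."""
        payload = json.loads(Path(path).read_text())["config"]
        payload["stages"] = tuple(payload["stages"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(payload))


def load_inputs(
    config: PipelineConfig,
) -> tuple[list[RegionTimeSeries], RSNPartition, pd.DataFrame]:
    """Load and validate per-subject matrices, the RSN map, and the cohort table."""
    root = Path(config.input_dir)
    cohort_path = root / "cohort.csv"
    map_path = root / "rsn_map.csv"
    for p in (cohort_path, map_path):
        if not p.exists():
            raise FileNotFoundError(p)
    cohort = pd.read_csv(cohort_path)
    if "subject_id" not in cohort.columns or "group" not in cohort.columns:
        raise ValueError(f"{cohort_path}: missing subject_id or group column")
    if cohort["subject_id"].duplicated().any():
        dups = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{cohort_path}: duplicated subject ids {dups}")
    rsn_map = pd.read_csv(map_path)
    if not {"region_index", "rsn_label"} <= set(rsn_map.columns):
        raise ValueError(f"{map_path}: expected columns region_index, rsn_label")
    rsn_map = rsn_map.sort_values("region_index")
    n_regions = len(rsn_map)
    if not np.array_equal(rsn_map["region_index"].to_numpy(), np.arange(n_regions)):
        missing = sorted(set(range(n_regions)) - set(rsn_map["region_index"]))
        raise ValueError(f"{map_path}: region indices not contiguous; missing {missing}")
    partition = RSNPartition(labels=rsn_map["rsn_label"].to_numpy())
    series = []
    for sid in cohort["subject_id"]:
        path = root / "timeseries" / f"{sid}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            values = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as err:
            raise ValueError(f"{path}: non-numeric cell ({err})") from err
        if values.shape[0] != n_regions:
            raise ValueError(
                f"{path}: {values.shape[0]} regions, mapping has {n_regions}"
            )
        series.append(RegionTimeSeries(values=values, tr_s=config.tr_s))
    return series, partition, cohort


def compute_subject_features(
    series: list[RegionTimeSeries],
    partition: RSNPartition,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Dynamic feature vectors for every subject (rows) x features (columns)."""
    rows = []
    seeds = np.random.SeedSequence(config.seed).generate_state(len(series))
    for i, (ts, s) in enumerate(zip(series, seeds)):
        net = subject_multilayer(
            ts, window_len_s=config.window_len_s, drop_initial=config.drop_initial,
            omega=config.omega, window_timepoints=config.window_timepoints,
        )
        params = ModularityParams(
            gamma=config.gamma, omega=config.omega,
            n_repetitions=config.n_repetitions, seed=int(s) % (2**31),
        )
        ensemble = repeat_optimization(net, params)
        allegiance = module_allegiance(ensemble)
        rows.append(subject_features(ensemble, partition, allegiance=allegiance))
    return pd.DataFrame(rows).reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages end-to-end, writing artifacts and a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {**asdict(config), "stages": list(config.stages)},
                      "stages": {}}
    results: dict = {}

    def _stage(name: str, fn):
        t0 = time.time()
        log.info("stage %s: starting", name)
        try:
            results[name] = fn()
        except Exception as err:  # preserve partial results
            manifest["stages"][name] = {"status": "failed", "error": str(err)}
            _write_manifest()
            raise
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.time() - t0, 2)}
        log.info("stage %s: done in %.1fs", name, time.time() - t0)

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    series, partition, cohort = load_inputs(config)
    fcols = feature_names(partition)

    if "measures" in config.stages:
        def _measures():
            feats = compute_subject_features(series, partition, config)
            table = pd.concat([cohort.reset_index(drop=True), feats], axis=1)
            table.to_csv(out / "features_wide.csv", index=False)
            tidy = feats.assign(subject_id=cohort["subject_id"].to_numpy()).melt(
                id_vars="subject_id", var_name="feature", value_name="value"
            )
            tidy[["measure", "system"]] = tidy["feature"].str.split("_", n=1, expand=True)
            tidy.drop(columns="feature").to_csv(out / "features_tidy.csv", index=False)
            return table
        _stage("measures", _measures)
        table = results["measures"]
    else:
        table = pd.read_csv(out / "features_wide.csv")

    if "stats" in config.stages:
        def _stats():
            res = stats.run_group_comparisons(
                table, fcols, n_perm=config.n_perm, q=config.fdr_q,
                mad_threshold=config.mad_threshold, seed=config.seed,
            )
            res.to_csv(out / "group_comparisons.csv", index=False)
            return res
        _stage("stats", _stats)

    if "classify" in config.stages:
        def _classify():
            clean = stats.screen_outliers(table, fcols, threshold=config.mad_threshold)
            suite = classify.run_classification_suite(
                clean, fcols, n_boot=config.n_boot, seed=config.seed,
            )
            summary = []
            for comp, models in suite.items():
                for m in ("F", "R", "F+R"):
                    auc = models[m]["auc"]
                    summary.append(
                        {"comparison": comp, "model": m, "auc": auc.auc,
                         "sensitivity": auc.sensitivity,
                         "specificity": auc.specificity,
                         "selected": ";".join(models[m]["model"].selected),
                         **{k: v for k, v in auc.confusion.items()}}
                    )
                summary[-1]["kruskal_p"] = models["kruskal"]["p"]
            pd.DataFrame(summary).to_csv(out / "classification.csv", index=False)
            return suite
        _stage("classify", _classify)

    if "pls" in config.stages:
        def _pls():
            clean = stats.screen_outliers(table, fcols, threshold=config.mad_threshold)
            reports = pls.run_pls_suite(
                clean, fcols, max_components=config.pls_max_components,
                folds=config.pls_folds, seed=config.seed,
            )
            frames = []
            for resp, rep in reports.items():
                frame = rep.to_frame().reset_index(names="predictor")
                frame.insert(0, "response", resp)
                frames.append(frame)
            pd.concat(frames).to_csv(out / "pls_vip.csv", index=False)
            return reports
        _stage("pls", _pls)

    _write_manifest()
    return results


def simulate_to_disk(design: SimulationDesign, out_dir: str | Path) -> None:
    """Generate a synthetic cohort and write it in the pipeline input format."""
    series, cohort, truth = generate_cohort(design)
    rsn_labels = RSNPartition.from_sizes(list(design.rsn_sizes)).labels
    write_cohort(out_dir, series, cohort, truth, rsn_labels)
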