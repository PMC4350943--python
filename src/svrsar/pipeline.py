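"""Study orchestration: config validation, the full pipeline, report bundle.

A study runs, per configured data set: observed SAR scoring, the SVR
regularization sweep, prediction summaries at the best C, predicted SAR
scores, global regression metrics, and the landscape comparison; across
data sets it correlates observed discontinuity with mean test error. All
outputs are plain TSV/JSON without timestamps, so a study is byte-for-byte
reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data_io import DataSet, read_dataset
from .errors import ConfigError, ValidationError
from .landscape import (
    SmoothingReport,
    compare_surfaces,
    embed_mds,
    interpolate_surface,
    write_surface_tsv,
)
from .sar_reproduction import (
    CorrelationResult,
    correlate_disc_vs_error,
    predicted_scores,
    summarize_predictions,
)
from .sari import PanelStats, SariScores, panel_stats, score_dataset
from .similarity import pairwise_matrix
from .svr import SvrConfig, mean_abs_error, r_squared, run_trials, sweep
from .synthetic_data import (
    PanelConfig,
    SyntheticConfig,
    generate_dataset,
    generate_reference_panel,
)

log = logging.getLogger("svrsar")


def derive_seed(global_seed: int, label: str) -> int:
    """Stable per-stage seed below 2^31 from the global seed and a label."""
    digest = hashlib.sha256(f"{global_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class DatasetSource:
    """Either a synthetic config or a TSV path, with a stable name."""

    kind: str  # "synthetic" | "tsv"
    name: str
    synthetic: SyntheticConfig | None = None
    path: str | None = None

    def load(self) -> DataSet:
        if self.kind == "synthetic":
            ds = generate_dataset(self.synthetic)
            ds.target_id = self.name
            return ds
        return read_dataset(self.path)


@dataclass
class StudyConfig:
    seed: int
    datasets: list[DatasetSource]
    panel: PanelConfig
    svr: SvrConfig
    landscape_resolution: int = 100

    def __post_init__(self):
        if not self.datasets:
            raise ConfigError("a study needs at least one dataset source")
        if self.landscape_resolution < 2:
            raise ConfigError("landscape resolution must be >= 2")


@dataclass
class DatasetReport:
    target_id: str
    n: int
    observed: SariScores
    predicted_train: SariScores
    predicted_test: SariScores
    best_c: float
    mean_test_r2: float
    mean_test_mae: float
    smoothing: SmoothingReport


@dataclass
class StudyReport:
    rows: list[DatasetReport]
    correlation: CorrelationResult | None
    provenance: dict = field(default_factory=dict)


_KNOWN_TOP = {"seed", "datasets", "panel", "svr", "landscape"}
_KNOWN_SYNTH = {
    "kind", "name", "n_compounds", "n_clusters", "universe", "core_bits",
    "private_bits", "potency_range", "within_cluster_spread", "cliff_fraction",
    "cliff_magnitude", "tc_threshold", "seed",
}
_KNOWN_PANEL = {"n_sets", "size_range", "cliff_fraction_range", "spread_range"}
_KNOWN_SVR = {"c_grid", "epsilon", "n_trials", "split_fraction"}
_KNOWN_LANDSCAPE = {"resolution"}


def _reject_unknown(section: dict, known: set[str], where: str) -> None:
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def validate_config(raw) -> StudyConfig:
    """Parse and validate a study config (YAML text or a mapping).

    Unknown keys are rejected; omitted values take the protocol defaults
    (ε = 0.1, the full C grid, 10 trials of 50/50 splits, resolution 100).
    A global seed and at least one dataset source are mandatory — there is
    no silent nondeterminism.
    """
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _reject_unknown(raw, _KNOWN_TOP, "config")
    if "seed" not in raw:
        raise ConfigError("config must set an explicit seed")
    seed = int(raw["seed"])
    if "datasets" not in raw or not raw["datasets"]:
        raise ConfigError("config must list at least one dataset")
    if "panel" not in raw:
        raise ConfigError("config must provide a panel source")

    sources = []
    for i, entry in enumerate(raw["datasets"]):
        if not isinstance(entry, dict) or "kind" not in entry:
            raise ConfigError(f"dataset #{i}: each entry needs a 'kind'")
        kind = entry["kind"]
        if kind == "synthetic":
            _reject_unknown(entry, _KNOWN_SYNTH, f"dataset #{i}")
            name = entry.get("name", f"synthetic-{i:02d}")
            kwargs = {
                k: v for k, v in entry.items() if k not in ("kind", "name", "seed")
            }
            for tup_key in ("potency_range",):
                if tup_key in kwargs:
                    kwargs[tup_key] = tuple(kwargs[tup_key])
            cfg = SyntheticConfig(
                seed=int(entry.get("seed", derive_seed(seed, f"dataset:{name}"))),
                **kwargs,
            )
            sources.append(DatasetSource(kind="synthetic", name=name, synthetic=cfg))
        elif kind == "tsv":
            _reject_unknown(entry, {"kind", "name", "path"}, f"dataset #{i}")
            if "path" not in entry:
                raise ConfigError(f"dataset #{i}: tsv source needs a path")
            sources.append(
                DatasetSource(
                    kind="tsv",
                    name=entry.get("name", Path(entry["path"]).stem),
                    path=str(entry["path"]),
                )
            )
        else:
            raise ConfigError(f"dataset #{i}: unknown kind {kind!r}")

    panel_raw = dict(raw["panel"])
    _reject_unknown(panel_raw, _KNOWN_PANEL, "panel")
    for tup_key in ("size_range", "cliff_fraction_range", "spread_range"):
        if tup_key in panel_raw:
            panel_raw[tup_key] = tuple(panel_raw[tup_key])
    panel = PanelConfig(seed=derive_seed(seed, "panel"), **panel_raw)

    svr_raw = dict(raw.get("svr", {}))
    _reject_unknown(svr_raw, _KNOWN_SVR, "svr")
    if "c_grid" in svr_raw:
        if not svr_raw["c_grid"]:
            raise ConfigError("svr.c_grid must be non-empty")
        svr_raw["c_grid"] = tuple(float(c) for c in svr_raw["c_grid"])
    svr_cfg = SvrConfig(seed=derive_seed(seed, "svr"), **svr_raw)

    land_raw = dict(raw.get("landscape", {}))
    _reject_unknown(land_raw, _KNOWN_LANDSCAPE, "landscape")

    return StudyConfig(
        seed=seed,
        datasets=sources,
        panel=panel,
        svr=svr_cfg,
        landscape_resolution=int(land_raw.get("resolution", 100)),
    )


def compute_panel_stats(panel: PanelConfig) -> PanelStats:
    """Score every panel set and summarize the raw-score distributions."""
    sets_ = generate_reference_panel(panel)
    conts, discs = [], []
    for ds in sets_:
        s = score_dataset(ds)
        conts.append(s.cont_raw)
        discs.append(s.disc_raw)
    return panel_stats(conts, discs)


def _scores_row(tag: str, s: SariScores) -> dict:
    return {
        "context": tag,
        "cont_raw": s.cont_raw,
        "disc_raw": s.disc_raw,
        "cont_norm": s.cont_norm,
        "disc_norm": s.disc_norm,
        "n_qualifying_pairs": s.n_qualifying_pairs,
    }


def _write_tsv(path: Path, rows: list[dict]) -> None:
    cols = list(rows[0].keys())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    repr(v) if isinstance(v, float) else str(v) for v in
                    (row[c] for c in cols)
                )
                + "\n"
            )


def run_dataset(
    dataset: DataSet,
    svr_cfg: SvrConfig,
    stats: PanelStats | None,
    resolution: int,
    landscape_seed: int,
    out_dir: Path | None = None,
) -> DatasetReport:
    """Run the full per-dataset pipeline (score, sweep, reproduce, landscape)."""
    sim = pairwise_matrix(dataset)
    y = dataset.potencies()
    observed = score_dataset(dataset, stats=stats, sim_matrix=sim)

    sw = sweep(dataset, svr_cfg, sim_matrix=sim)
    best_c = sw.best_c
    # run_trials regenerates the identical seeded splits used inside the sweep
    trials = run_trials(dataset, best_c, svr_cfg, sim_matrix=sim)
    summ_train = summarize_predictions(trials, dataset, "train")
    summ_test = summarize_predictions(trials, dataset, "test")
    pred_train = predicted_scores(dataset, summ_train, stats=stats, sim_matrix=sim)
    pred_test = predicted_scores(dataset, summ_test, stats=stats, sim_matrix=sim)

    r2s = [r_squared(y[t.test_indices], t.test_predictions) for t in trials]
    maes = [
        mean_abs_error(y[t.test_indices], t.test_predictions, svr_cfg.epsilon)
        for t in trials
    ]

    emb = embed_mds(sim, seed=landscape_seed)
    surf_obs = interpolate_surface(emb, y, resolution)
    surf_pred = interpolate_surface(emb, summ_test.mean_predictions, resolution)
    smoothing = compare_surfaces(
        surf_obs, surf_pred, observed.disc_raw, pred_test.disc_raw
    )

    report = DatasetReport(
        target_id=dataset.target_id,
        n=len(dataset),
        observed=observed,
        predicted_train=pred_train,
        predicted_test=pred_test,
        best_c=best_c,
        mean_test_r2=float(np.mean(r2s)),
        mean_test_mae=float(np.mean(maes)),
        smoothing=smoothing,
    )

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_tsv(
            out_dir / "scores.tsv",
            [
                _scores_row("observed", observed),
                _scores_row("predicted_train", pred_train),
                _scores_row("predicted_test", pred_test),
            ],
        )
        _write_tsv(
            out_dir / "sweep.tsv",
            [
                {
                    "C": c,
                    "mean_train_err": float(sw.mean_train_errors[i]),
                    "sd_train_err": float(sw.sd_train_errors[i]),
                    "mean_test_err": float(sw.mean_test_errors[i]),
                    "sd_test_err": float(sw.sd_test_errors[i]),
                    "best": int(c == best_c),
                }
                for i, c in enumerate(sw.c_values)
            ],
        )
        _write_tsv(
            out_dir / "predictions.tsv",
            [
                {
                    "compound_id": r.compound_id,
                    "observed_pki": r.pki,
                    "mean_train_prediction": float(summ_train.mean_predictions[i]),
                    "n_train_occurrences": int(summ_train.n_occurrences[i]),
                    "mean_test_prediction": float(summ_test.mean_predictions[i]),
                    "n_test_occurrences": int(summ_test.n_occurrences[i]),
                    "fallback_used": int(
                        bool(summ_train.fallback_used[i] or summ_test.fallback_used[i])
                    ),
                }
                for i, r in enumerate(dataset.records)
            ],
        )
        _write_tsv(
            out_dir / "coordinates.tsv",
            [
                {
                    "compound_id": r.compound_id,
                    "x": float(emb.coords[i, 0]),
                    "y": float(emb.coords[i, 1]),
                }
                for i, r in enumerate(dataset.records)
            ],
        )
        write_surface_tsv(surf_obs, out_dir / "surface_observed.tsv")
        write_surface_tsv(surf_pred, out_dir / "surface_predicted.tsv")
        _write_tsv(
            out_dir / "smoothing.tsv",
            [
                {
                    "peak_height_loss": smoothing.peak_height_loss,
                    "surface_range_ratio": smoothing.surface_range_ratio,
                    "disc_delta": smoothing.disc_delta,
                    "n_lost_peaks": smoothing.n_lost_peaks,
                }
            ],
        )
    return report


def run_study(config: StudyConfig, out_dir: Path | str) -> StudyReport:
    """Run the whole study and write the report bundle.

    Any stage failure aborts with the stage and dataset named; the report is
    reproducible byte-for-byte under the same config and seed (no timestamps
    in any bundle file; log output goes to stderr, not into the bundle).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("computing reference panel stats (%d sets)", config.panel.n_sets)
    try:
        stats = compute_panel_stats(config.panel)
    except Exception as exc:
        raise type(exc)(f"stage=panel: {exc}") from exc

    rows: list[DatasetReport] = []
    for src in config.datasets:
        log.info("dataset %s: running pipeline", src.name)
        try:
            ds = src.load()
            report = run_dataset(
                ds,
                config.svr,
                stats,
                config.landscape_resolution,
                landscape_seed=derive_seed(config.seed, f"landscape:{src.name}"),
                out_dir=out_dir / src.name,
            )
        except Exception as exc:
            raise type(exc)(f"stage=dataset({src.name}): {exc}") from exc
        rows.append(report)

    correlation = None
    if len(rows) >= 3:
        try:
            correlation = correlate_disc_vs_error(
                [r.observed.disc_raw for r in rows],
                [r.mean_test_mae for r in rows],
            )
        except ValidationError as exc:
            log.warning("cross-dataset correlation skipped: %s", exc)
    _write_tsv(
        out_dir / "correlation.tsv",
        [
            {
                "r": correlation.r if correlation else float("nan"),
                "p_two_tailed": correlation.p_two_tailed
                if correlation
                else float("nan"),
                "n": correlation.n if correlation else 0,
            }
        ],
    )

    canonical = json.dumps(_config_fingerprint(config), sort_keys=True)
    provenance = {
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    summary = {
        "provenance": provenance,
        "datasets": [
            {
                "target_id": r.target_id,
                "n": r.n,
                "best_c": r.best_c,
                "mean_test_r2": r.mean_test_r2,
                "mean_test_mae": r.mean_test_mae,
                "observed": _scores_row("observed", r.observed),
                "predicted_train": _scores_row("predicted_train", r.predicted_train),
                "predicted_test": _scores_row("predicted_test", r.predicted_test),
                "smoothing": asdict(r.smoothing),
            }
            for r in rows
        ],
        "correlation": asdict(correlation) if correlation else None,
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return StudyReport(rows=rows, correlation=correlation, provenance=provenance)


def headline_artifact_study(
    seed: int,
    n_sets: int = 12,
    n_compounds: int = 150,
    max_cliff_fraction: float = 0.2,
    c_grid: tuple[float, ...] = tuple(float(c) for c in range(1, 11)) + (25.0, 50.0),
    n_trials: int = 10,
    epsilon: float = 0.1,
    resolution: int = 60,
) -> dict:
    """Scaled-down reproduction of the systematic-artifact analysis.

    Generates ``n_sets`` synthetic data sets whose planted cliff fraction
    spans [0, max_cliff_fraction], runs the per-dataset pipeline on each,
    and aggregates the quantities that characterize the artifact: how often
    predicted test-context discontinuity falls below the observed score, the
    Pearson correlation between observed discontinuity and mean test error,
    the worst continuity deviation, and landscape peak-height losses.
    """
    fractions = np.linspace(0.0, max_cliff_fraction, n_sets)
    rows = []
    for i, cf in enumerate(fractions):
        ds_cfg = SyntheticConfig(
            n_compounds=n_compounds,
            n_clusters=max(6, n_compounds // 12),
            cliff_fraction=float(cf),
            seed=derive_seed(seed, f"headline-dataset:{i}"),
        )
        ds = generate_dataset(ds_cfg)
        ds.target_id = f"headline-{i:02d}"
        svr_cfg = SvrConfig(
            c_grid=c_grid,
            epsilon=epsilon,
            n_trials=n_trials,
            seed=derive_seed(seed, f"headline-svr:{i}"),
        )
        rep = run_dataset(
            ds, svr_cfg, stats=None, resolution=resolution,
            landscape_seed=derive_seed(seed, f"headline-landscape:{i}"),
        )
        rows.append({"cliff_fraction": float(cf), "report": rep})

    discs = np.array([r["report"].observed.disc_raw for r in rows])
    errors = np.array([r["report"].mean_test_mae for r in rows])
    corr = correlate_disc_vs_error(discs, errors)
    under = [
        r["report"].predicted_test.disc_raw < r["report"].observed.disc_raw
        for r in rows
    ]
    cont_dev = [
        abs(r["report"].predicted_test.cont_raw - r["report"].observed.cont_raw)
        for r in rows
    ]
    cliff_rows = [r for r in rows if r["cliff_fraction"] >= 0.1]
    return {
        "rows": rows,
        "n_sets": n_sets,
        "n_underpredicted": int(sum(under)),
        "underprediction_fraction": float(np.mean(under)),
        "pearson_r_disc_vs_test_error": corr.r,
        "pearson_p_two_tailed": corr.p_two_tailed,
        "max_abs_continuity_deviation": float(max(cont_dev)),
        "peak_height_losses_cliff_sets": [
            r["report"].smoothing.peak_height_loss for r in cliff_rows
        ],
        "mean_test_r2_best_c": float(
            np.mean([r["report"].mean_test_r2 for r in rows])
        ),
        "mean_test_mae_best_c": float(np.mean(errors)),
    }


def _config_fingerprint(config: StudyConfig) -> dict:
    return {
        "seed": config.seed,
        "datasets": [
            {
                "kind": s.kind,
                "name": s.name,
                "synthetic": asdict(s.synthetic) if s.synthetic else None,
                "path": s.path,
            }
            for s in config.datasets
        ],
        "panel": asdict(config.panel),
        "svr": asdict(config.svr),
        "landscape_resolution": config.landscape_resolution,
    }
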