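"""End-to-end orchestration: features -> outcomes -> PLS -> signatures.

Runs the full chain from a config mapping, writes publication-style artifacts
(descriptive table, univariate correlation table, SR profiles, selection
curves, model JSON), and accounts for every excluded subject.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accel import (
    BinScheme,
    WearCriteria,
    process_stream,
    read_epoch_csv,
    spectra_to_frame,
)
from .metabolic import (
    COMPOSITE_OUTCOMES,
    adjust_outcomes,
    composite_score,
    derive_indices,
    read_panel_csv,
    validate_panel,
)
from .pls import fit_autoscaled, select_components
from .signature import (
    SignatureProfile,
    build_signature,
    compare_patterns,
    sed_sensitivity,
    univariate_profile,
)

__all__ = ["PipelineConfig", "run_pipeline", "export_sr_plot_data", "import_sr_plot_data"]


@dataclass
class PipelineConfig:
    """Run settings; defaults mirror the reference analysis throughout."""

    epoch_csv: str | None = None
    spectrum_csv: str | None = None  # precomputed features, bypasses epoch stage
    panel_csv: str = ""
    output_dir: str = "results"
    epoch_length_s: int = 10
    nonwear_window_min: float = 60.0
    min_wear_hours: float = 8.0
    min_valid_days: int = 4
    day_start_hour: int = 6
    day_end: str = "23:59"
    bin_edges: tuple[int, ...] = ()
    outcomes: tuple[str, ...] = COMPOSITE_OUTCOMES
    repetitions: int = 100
    holdout_fraction: float = 0.5
    a_max: int = 10
    seed: int = 0
    per_outcome_models: bool = True
    sex_stratified: bool = False
    sed_sensitivity_edges: tuple[int, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def wear_criteria(self) -> WearCriteria:
        return WearCriteria(
            min_hours_per_day=self.min_wear_hours,
            min_days=self.min_valid_days,
            nonwear_window_minutes=self.nonwear_window_min,
            day_start_hour=self.day_start_hour,
            day_end=self.day_end,
        )

    def bin_scheme(self) -> BinScheme:
        if self.bin_edges:
            return BinScheme(edges=tuple(self.bin_edges))
        return BinScheme.default()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fit_outcome(
    X: np.ndarray,
    y: np.ndarray,
    labels: Sequence[str],
    config: PipelineConfig,
    seed_offset: int,
) -> tuple[SignatureProfile, "pd.DataFrame", object]:
    sel = select_components(
        X, y,
        repetitions=config.repetitions,
        holdout_fraction=config.holdout_fraction,
        a_max=min(config.a_max, X.shape[1]),
        seed=config.seed + seed_offset,
    )
    profile = build_signature(
        X, y, labels, sel.n_components,
        repetitions=config.repetitions,
        holdout_fraction=config.holdout_fraction,
        seed=config.seed + seed_offset + 1,
        predictive=sel.predictive,
    )
    return profile, sel.to_frame(), sel


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a report bundle and writes artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    criteria = config.wear_criteria()
    scheme = config.bin_scheme()
    log: dict = {"n_streams": 0, "n_invalid_wear": 0, "n_panel": 0,
                 "n_panel_excluded": 0, "n_analyzed": 0}

    # --- features -----------------------------------------------------------
    if config.spectrum_csv:
        feat = pd.read_csv(config.spectrum_csv).set_index("subject_id")
        feat.index = feat.index.astype(str)
        bin_cols = [c for c in feat.columns
                    if c not in ("n_valid_days", "mean_wear_minutes", "overall_cpm")]
        feat = feat[bin_cols]
        streams = None
    elif config.epoch_csv:
        streams = read_epoch_csv(config.epoch_csv, epoch_length=config.epoch_length_s)
        log["n_streams"] = len(streams)
        spectra, summaries = [], []
        for stream in streams:
            spectrum, summary, _ = process_stream(stream, criteria, scheme)
            if spectrum is None:
                log["n_invalid_wear"] += 1
                continue
            spectra.append(spectrum)
            summaries.append(summary)
        if not spectra:
            raise RuntimeError("empty analysis set: no subject met wear criteria")
        frame = spectra_to_frame(spectra)
        frame.to_csv(out / "spectrum.csv", index=False)
        pd.DataFrame([vars(s) for s in summaries]).to_csv(
            out / "evenson.csv", index=False
        )
        feat = frame.set_index("subject_id")[list(scheme.labels)]
    else:
        raise ValueError("config needs epoch_csv or spectrum_csv")

    # --- outcomes -----------------------------------------------------------
    panel = read_panel_csv(config.panel_csv)
    panel["subject_id"] = panel["subject_id"].astype(str)
    log["n_panel"] = len(panel)
    valid, excluded = validate_panel(panel)
    log["n_panel_excluded"] = len(excluded)
    merged = valid[valid["subject_id"].isin(feat.index)].reset_index(drop=True)
    derived = derive_indices(merged)
    adjusted = adjust_outcomes(derived, config.outcomes)
    composite = composite_score(adjusted)
    log["n_analyzed"] = len(merged)
    if len(merged) < 10:
        raise RuntimeError(f"empty/undersized analysis set (n={len(merged)})")

    X = feat.loc[merged["subject_id"]].to_numpy(dtype=float)
    labels = list(feat.columns)
    outcomes_out = derived.copy()
    for name in adjusted.columns:
        outcomes_out[f"{name}_adj"] = adjusted[name].to_numpy()
    outcomes_out["composite"] = composite
    outcomes_out.to_csv(out / "outcomes.csv", index=False)

    # descriptive table (Table-1 layout)
    desc_cols = ["age", "body_mass", "height", "bmi", "waist", "wc_height",
                 "andersen_distance", "sbp", "dbp", "tc", "ldl", "hdl",
                 "tc_hdl", "tg", "glucose", "insulin", "homa", "composite"]
    desc_cols = [c for c in desc_cols if c in outcomes_out.columns]
    descript = outcomes_out[desc_cols].agg(["mean", "std"]).T
    descript.to_csv(out / "descriptives.csv")

    # univariate table (Table-2 layout)
    univ_targets = adjusted.copy()
    univ_targets.insert(0, "composite", composite)
    univ = univariate_profile(X, univ_targets, labels)
    univ.to_csv(out / "univariate.csv")

    # --- multivariate models ------------------------------------------------
    profiles: dict[str, SignatureProfile] = {}
    targets = {"composite": composite}
    if config.per_outcome_models:
        for name in adjusted.columns:
            targets[name] = adjusted[name].to_numpy()
    for i, (name, y) in enumerate(targets.items()):
        profile, curve, sel = _fit_outcome(X, y, labels, config, seed_offset=10 * i)
        profiles[name] = profile
        profile.to_frame().to_csv(out / f"sr_{name}.csv", index=False)
        curve.to_csv(out / f"selection_{name}.csv", index=False)
        model = fit_autoscaled(X, y, profile.n_components, labels)
        model.to_json(out / f"model_{name}.json")

    report: dict = {"profiles": profiles, "univariate": univ, "log": log,
                    "features": feat, "composite": composite}

    # sex-stratified pattern comparison
    if config.sex_stratified:
        sex = pd.factorize(merged["sex"], sort=True)[0]
        strat = {}
        for code, label in ((0, "group0"), (1, "group1")):
            idx = np.flatnonzero(sex == code)
            adj_g = adjust_outcomes(merged.iloc[idx].pipe(derive_indices), config.outcomes)
            y_g = composite_score(adj_g)
            profile, _, _ = _fit_outcome(
                X[idx], y_g, labels, config, seed_offset=100 + 10 * code
            )
            profile.to_frame().to_csv(out / f"sr_composite_{label}.csv", index=False)
            strat[label] = profile
        pattern_r = compare_patterns(
            strat["group0"].unweighted_loading, strat["group1"].unweighted_loading
        )
        report["sex_stratified"] = strat
        report["pattern_r"] = pattern_r
        (out / "sex_pattern.json").write_text(
            json.dumps({"pattern_r": pattern_r}, indent=2)
        )

    # SED cut-point sensitivity (needs epoch-level data)
    if config.sed_sensitivity_edges and streams is not None:
        y_series = pd.Series(composite, index=merged["subject_id"].to_numpy())
        sens = sed_sensitivity(
            streams, y_series, scheme,
            alt_first_edges=config.sed_sensitivity_edges,
            criteria=criteria,
            repetitions=config.repetitions,
            holdout_fraction=config.holdout_fraction,
            seed=config.seed + 999,
        )
        sens.to_csv(out / "sed_sensitivity.csv", index=False)
        report["sed_sensitivity"] = sens

    export_sr_plot_data(profiles, out / "sr_plot_data.json")
    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "log": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return report


def export_sr_plot_data(
    profiles: dict[str, SignatureProfile], path: str | Path | None = None
) -> dict:
    """Plot-ready SR bars with CI whiskers, one entry per fitted outcome.

    Sign convention follows the fitted models: with a higher-is-worse outcome,
    bins where activity tracks better health get negative bars.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    data = {
        name: {
            "bins": list(p.labels),
            "sr": p.sr.tolist(),
            "ci_low": p.ci_low.tolist(),
            "ci_high": p.ci_high.tolist(),
            "n_components": p.n_components,
            "r2": p.r2,
            "predictive": bool(p.predictive),
        }
        for name, p in profiles.items()
    }
    if path is not None:
        Path(path).write_text(json.dumps(data, indent=2))
    return data


def import_sr_plot_data(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
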