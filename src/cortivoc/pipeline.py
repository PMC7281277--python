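"""End-to-end pipeline orchestration with a validated run configuration.

Stages run in the fixed order simulate -> preprocess -> screen -> select ->
fit -> diagnose -> predict, each reading the previous stage's artifacts and
writing its own under the run directory, plus a manifest capturing the
configuration, seed and package version.  A stage failure leaves a FAILED
marker naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cortivoc
from cortivoc.cohort import (
    CohortConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from cortivoc.diagnostics import (
    compute_diagnostics,
    predicted_vs_observed,
    residual_summary,
    subgroup_ttests,
)
from cortivoc.factor_screen import anova_report, screen_factors, two_way_anova
from cortivoc.model_select import build_design, compare_models, stepwise
from cortivoc.preprocess import preprocess_pipeline
from cortivoc.published import load_published_model
from cortivoc.selection import SelectionConfig, bootstrap_select, top_k


def _strict_dataclass(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Full pipeline configuration; unknown keys are rejected on load."""

    seed: int = 0
    out_dir: str = "results/run"
    cohort_dir: str | None = None  # read an existing cohort instead of simulating
    # cohort generation
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # preprocessing
    min_fraction: float = 0.5
    min_rt1_s: float = 358.0
    max_ug: float = 45.0
    exclude_samples: tuple[str, ...] = ()
    impute: str = "half_min"
    # factor screen
    screen_alpha: float = 0.05
    log_response_screen: bool = True
    # stability selection
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    # model selection
    criterion: str = "aicc"
    direction: str = "both"
    hierarchy: bool = True
    log_response: bool = True
    # diagnostics
    subgroup_fdr: float = 0.10

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        cohort = _strict_dataclass(CohortConfig, data.pop("cohort", {}), "cohort")
        sel = data.pop("selection", {})
        if isinstance(sel, dict):
            if "top_k" in sel:
                sel["top_k"] = tuple(sel["top_k"])
            sel = _strict_dataclass(SelectionConfig, sel, "selection")
        if "exclude_samples" in data:
            data["exclude_samples"] = tuple(data["exclude_samples"])
        cfg = _strict_dataclass(cls, data, "run")
        return dataclasses.replace(cfg, cohort=cohort, selection=sel)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["timepoints"] = list(self.cohort.timepoints)
        d["cohort"]["diurnal_means"] = list(self.cohort.diurnal_means)
        d["selection"]["top_k"] = list(self.selection.top_k)
        d["exclude_samples"] = list(self.exclude_samples)
        return d


def _seeded(config: RunConfig) -> RunConfig:
    """Propagate the run seed into the stage configs that draw randomness."""
    return dataclasses.replace(
        config,
        cohort=dataclasses.replace(config.cohort, seed=config.seed),
        selection=dataclasses.replace(config.selection, seed=config.seed + 1),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict of artifact paths."""
    config = _seeded(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "init"
    try:
        stage = "simulate"
        if config.cohort_dir is not None:
            meta, table = read_cohort(config.cohort_dir)
            truth = None
        else:
            meta, table, truth = generate_cohort(config.cohort)
            write_cohort(meta, table, out / "cohort", truth)

        stage = "preprocess"
        processed, kept = preprocess_pipeline(
            table,
            meta,
            min_fraction=config.min_fraction,
            min_rt1_s=config.min_rt1_s,
            max_ug=config.max_ug,
            exclude=config.exclude_samples,
            impute=config.impute,
        )
        processed.z.to_csv(out / "processed.csv")
        processed.save_params(out / "transform_params.json")

        stage = "screen"
        anova = two_way_anova(kept, log_response=config.log_response_screen)
        factors = screen_factors(anova, alpha=config.screen_alpha)
        (out / "anova.json").write_text(
            json.dumps(
                {"table": anova_report(anova), "factors": sorted(factors)}, indent=1
            )
        )

        stage = "select"
        freq = bootstrap_select(processed, kept, config.selection)
        freq.to_frame().to_csv(out / "selection_frequency.csv")

        stage = "fit"
        y = kept["cortisol_ug"].to_numpy(dtype=float)
        if config.log_response:
            y = np.log10(y)
        fits, names = [], []
        for k in config.selection.top_k:
            candidates = top_k(freq, min(k, processed.z.shape[1]))
            design = build_design(processed, kept, candidates, factors)
            fit = stepwise(
                design,
                y,
                direction=config.direction,
                criterion=config.criterion,
                hierarchy=config.hierarchy,
            )
            fits.append((fit, design))
            names.append(f"top{k}")
            (out / f"fit_result_top{k}.json").write_text(
                json.dumps(fit.to_dict(), indent=1)
            )
        report = compare_models([f for f, _ in fits], names)
        report.to_csv(out / "model_comparison.csv")
        best_name = report.iloc[0]["name"]
        best_fit, best_design = fits[names.index(best_name)]

        stage = "diagnose"
        diag = compute_diagnostics(
            best_fit,
            best_design[best_fit.terms],
            y,
            run_order=kept["run_order"].to_numpy(),
        )
        pvo = predicted_vs_observed(best_fit, best_design[best_fit.terms], y)
        dummy_labels = {"Male", "Morning", "Afternoon"}
        model_metabolites = sorted(
            {t for t in best_fit.terms if ":" not in t and t not in dummy_labels}
        )
        ttests = subgroup_ttests(
            processed, kept, model_metabolites, fdr=config.subgroup_fdr
        )
        ttests.to_csv(out / "subgroup_ttests.csv", index=False)
        (out / "diagnostics.json").write_text(
            json.dumps(
                {
                    "flags": diag.flags,
                    "vif": diag.vif,
                    "adj_r2": diag.adj_r2,
                    "shapiro_p": diag.shapiro_p,
                    "breusch_pagan_p": diag.breusch_pagan_p,
                    "best_model": best_name,
                },
                indent=1,
            )
        )
        pvo.to_csv(out / "predicted_vs_observed.csv")

        stage = "predict"
        model = load_published_model()
        mapping = model.map_by_retention(table.feature_meta)
        published_eval = None
        if len(mapping) == len(model.labels):
            published_eval = model.evaluate_on_cohort(
                processed.z[[mapping[lab] for lab in model.labels]].rename(
                    columns={v: k for k, v in mapping.items()}
                ),
                kept,
                {lab: lab for lab in model.labels},
            )
            published_eval.to_csv(out / "published_predictions.csv")
            summary = residual_summary(
                published_eval["residual_log10"], kept
            )
            summary.to_csv(out / "published_residual_summary.csv", index=False)

        manifest = {
            "package_version": cortivoc.__version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": [
                "simulate",
                "preprocess",
                "screen",
                "select",
                "fit",
                "diagnose",
                "predict",
            ],
            "best_model": str(best_name),
            "screened_factors": sorted(factors),
            "published_model_mapped": published_eval is not None,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as exc:
        failed_marker.write_text(
            f"stage: {stage}\nerror: {exc}\n\n{traceback.format_exc()}"
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
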