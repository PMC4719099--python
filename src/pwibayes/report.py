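"""End-to-end pipeline runner and analysis report assembly.

``run_pipeline`` takes a trial-level table through exclusion, condition
medians, the distractor effects with single-case standardized scores and
general-slowing RT ratios, the Bayesian split-plot estimation with its
contrast table, and the frequentist comparators, and bundles everything in
an :class:`AnalysisReport` that renders to machine-readable JSON/CSV and a
plain-text summary. Sections whose inputs are unavailable (e.g. no retained
trials) are reported as explicit gaps rather than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, preprocess
from .model import McmcConfig, PriorSpec, contrast_table, fit_model, named_contrasts
from .preprocess import ExclusionReport

__all__ = ["AnalysisReport", "run_pipeline", "build_report"]


@dataclass
class AnalysisReport:
    """All analysis artifacts for one dataset. ``None`` marks a section whose
    inputs were unavailable; ``gaps`` lists why."""

    exclusion: ExclusionReport
    medians: pd.DataFrame | None = None
    descriptives: pd.DataFrame | None = None
    effect_scores: pd.DataFrame | None = None
    bayes_contrasts: pd.DataFrame | None = None
    bayes_diagnostics: dict | None = None
    anova: compare.AnovaTable | None = None
    ttests: pd.DataFrame | None = None
    error_rates: pd.DataFrame | None = None
    gaps: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def frame(df: pd.DataFrame | None):
            if df is None:
                return None
            out = df.copy()
            for col in out.columns:
                if out[col].dtype == "boolean":
                    out[col] = out[col].astype(object).where(out[col].notna(), None)
            return json.loads(out.to_json(orient="records", double_precision=6))

        d = {
            "exclusion": {
                "n_total": self.exclusion.n_total,
                "n_retained": self.exclusion.n_retained,
                "n_errors": self.exclusion.n_errors,
                "n_voicekey": self.exclusion.n_voicekey,
                "n_fast": self.exclusion.n_fast,
                "min_rt_ms": self.exclusion.min_rt_ms,
                "per_group": self.exclusion.per_group,
                "percentages": {
                    g: self.exclusion.percentages(g) for g in self.exclusion.per_group
                },
            },
            "medians": frame(self.medians),
            "descriptives": frame(self.descriptives),
            "effect_scores": frame(self.effect_scores),
            "bayes_contrasts": frame(self.bayes_contrasts),
            "bayes_diagnostics": self.bayes_diagnostics,
            "anova": frame(self.anova.omnibus) if self.anova is not None else None,
            "ttests": frame(self.ttests),
            "error_rates": frame(self.error_rates),
            "gaps": self.gaps,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)

    def to_text(self) -> str:
        lines = ["Picture-word interference analysis report", "=" * 42, ""]
        lines.append("Trial exclusion")
        lines.append(self.exclusion.as_frame().to_string(index=False, float_format="%.2f"))
        sections = [
            ("Per-group condition medians (descriptives)", self.descriptives),
            ("Distractor effects, standardized scores, RT ratios", self.effect_scores),
            ("Bayesian posterior contrasts (mean, 95% HDI, tail %)", self.bayes_contrasts),
            ("Split-plot ANOVA", self.anova.omnibus if self.anova is not None else None),
            ("Effect t-tests (one-sample and Welch between-group)", self.ttests),
            ("Error-rate comparison (logistic, per condition)", self.error_rates),
        ]
        for title, df in sections:
            lines += ["", title]
            if df is None:
                lines.append("  [section unavailable]")
            else:
                lines.append(df.to_string(index=False, float_format="%.3f"))
        if self.gaps:
            lines += ["", "Gaps: " + "; ".join(self.gaps)]
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        (out / "report.txt").write_text(self.to_text())
        for name in ("medians", "effect_scores", "bayes_contrasts", "ttests", "error_rates"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
        if self.anova is not None:
            self.anova.omnibus.to_csv(out / "anova.csv", index=False, float_format="%.6g")


def run_pipeline(
    trials: pd.DataFrame,
    min_rt_ms: float = preprocess.DEFAULT_MIN_RT_MS,
    mcmc: McmcConfig | None = None,
    priors: PriorSpec | None = None,
    run_bayes: bool = True,
) -> AnalysisReport:
    """Full analysis of a trial-level table; see the module docstring."""
    retained, exclusion = preprocess.exclude_trials(trials, min_rt_ms)
    report = AnalysisReport(exclusion=exclusion)

    if retained.empty:
        report.gaps.append("no retained trials: inferential sections skipped")
        return report

    medians = preprocess.condition_medians(retained)
    report.medians = medians
    cond_cols = [c for c in medians.columns if c not in ("participant_id", "group")]
    report.descriptives = (
        medians.groupby("group")[cond_cols].agg(["mean", "std", "median"]).round(3).reset_index()
    )
    report.descriptives.columns = [
        "_".join(c).rstrip("_") for c in report.descriptives.columns.to_flat_index()
    ]

    try:
        report.effect_scores = preprocess.effect_scores(medians)
    except ValueError as err:
        report.gaps.append(f"effect scores unavailable: {err}")

    if run_bayes:
        try:
            samples = fit_model(medians, priors=priors, mcmc=mcmc)
            results = named_contrasts(samples)
            report.bayes_contrasts = contrast_table(results)
            report.bayes_diagnostics = {
                "rhat": samples.rhat,
                "ess": samples.ess,
                "converged": samples.converged,
                "n_draws": samples.n_draws,
                "backend": samples.backend,
            }
        except ValueError as err:
            report.gaps.append(f"Bayesian estimation unavailable: {err}")
    else:
        report.gaps.append("Bayesian estimation skipped by request")

    try:
        report.anova = compare.splitplot_anova(medians)
    except ValueError as err:
        report.gaps.append(f"ANOVA unavailable: {err}")
    try:
        effects = preprocess.compute_effects(medians)
        report.ttests = compare.effect_ttests(effects)
    except ValueError as err:
        report.gaps.append(f"effect t-tests unavailable: {err}")
    report.error_rates = compare.error_rate_comparison(trials)
    return report


def build_report(trials: pd.DataFrame, **kwargs) -> AnalysisReport:
    """Alias of :func:`run_pipeline`."""
    return run_pipeline(trials, **kwargs)
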