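"""Trial exclusion, condition medians, distractor effects, and derived scores.

The analysis unit throughout the package is the per-participant,
per-condition *median* correct-response latency: naming latencies are
right-skewed, so the median is the preferred central-tendency summary, and
all inference downstream (Bayesian and frequentist) operates on the median
table produced here.

Sign convention for the three distractor effects (interference positive,
facilitation negative):

* lexical interference   = unrelated - neutral
* semantic interference  = related - unrelated
* phonological facilitation = phonological - unrelated

Single-case standardized scores express each patient's effect in SD units of
the control sample (mean/SD with the n-1 denominator); |z| > 2 is flagged as
beyond the ~95th percentile. The general-slowing correction divides each
effect by that participant's unrelated-condition median, which is common to
all three effects, so purely multiplicative slowing cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DEFAULT_CONDITIONS
from .simulate import GROUPS, STATUS_CORRECT, STATUS_ERROR, STATUS_VOICEKEY

DEFAULT_MIN_RT_MS = 200.0

EFFECT_NAMES = ("lexical", "semantic", "phonological")

#: (minuend condition, subtrahend condition) per effect.
EFFECT_DEFS: dict[str, tuple[str, str]] = {
    "lexical": ("unrelated", "neutral"),
    "semantic": ("related", "unrelated"),
    "phonological": ("phonological", "unrelated"),
}


@dataclass(frozen=True)
class ExclusionReport:
    """Partition of all trials into retained and the three exclusion classes.

    Each trial is counted exactly once, with precedence
    error > voice-key failure > fast (RT below the floor).
    """

    n_total: int
    n_retained: int
    n_errors: int
    n_voicekey: int
    n_fast: int
    per_group: dict[str, dict[str, int]]
    min_rt_ms: float = DEFAULT_MIN_RT_MS

    def __post_init__(self) -> None:
        if self.n_total != self.n_retained + self.n_errors + self.n_voicekey + self.n_fast:
            raise ValueError("exclusion counts do not partition the total")

    def percentages(self, group: str | None = None) -> dict[str, float]:
        """Exclusion-class percentages, overall or for one group."""
        if group is None:
            counts = {
                "errors": self.n_errors,
                "voicekey": self.n_voicekey,
                "fast": self.n_fast,
                "retained": self.n_retained,
            }
            total = self.n_total
        else:
            g = self.per_group[group]
            counts = {k: g[k] for k in ("errors", "voicekey", "fast", "retained")}
            total = g["total"]
        if total == 0:
            return {k: 0.0 for k in counts}
        return {k: 100.0 * v / total for k, v in counts.items()}

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for group in sorted(self.per_group):
            g = self.per_group[group]
            pct = self.percentages(group)
            rows.append({"group": group, **g, **{f"pct_{k}": v for k, v in pct.items()}})
        pct = self.percentages()
        rows.append(
            {
                "group": "all",
                "total": self.n_total,
                "retained": self.n_retained,
                "errors": self.n_errors,
                "voicekey": self.n_voicekey,
                "fast": self.n_fast,
                **{f"pct_{k}": v for k, v in pct.items()},
            }
        )
        return pd.DataFrame(rows)


def exclude_trials(
    trials: pd.DataFrame, min_rt_ms: float = DEFAULT_MIN_RT_MS
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion rules and account for every removed trial.

    Removed are: trials coded as errors; voice-key failures (including any
    trial without a usable latency); and trials with RT below ``min_rt_ms``.
    Retained trials are correct responses with RT >= ``min_rt_ms``.
    """
    if min_rt_ms <= 0:
        raise ValueError("min_rt_ms must be positive")
    if trials.empty:
        report = ExclusionReport(0, 0, 0, 0, 0, {}, min_rt_ms)
        return trials.copy(), report

    status = trials["status"]
    rt = pd.to_numeric(trials["rt_ms"], errors="coerce")
    is_error = status == STATUS_ERROR
    # a correct-coded trial without a latency is a missed voice-key trigger
    is_voicekey = ~is_error & ((status == STATUS_VOICEKEY) | rt.isna())
    is_fast = ~is_error & ~is_voicekey & (rt < min_rt_ms)
    retained_mask = ~is_error & ~is_voicekey & ~is_fast & (status == STATUS_CORRECT)
    # anything with an unknown status label is dropped but still counted
    unknown = ~is_error & ~is_voicekey & ~is_fast & (status != STATUS_CORRECT)
    if unknown.any():
        bad = sorted(trials.loc[unknown, "status"].unique())
        raise ValueError(f"unknown trial status labels: {bad}")

    per_group: dict[str, dict[str, int]] = {}
    for group, sub in trials.groupby("group", sort=True):
        idx = sub.index
        per_group[str(group)] = {
            "total": int(len(idx)),
            "retained": int(retained_mask[idx].sum()),
            "errors": int(is_error[idx].sum()),
            "voicekey": int(is_voicekey[idx].sum()),
            "fast": int(is_fast[idx].sum()),
        }
    report = ExclusionReport(
        n_total=int(len(trials)),
        n_retained=int(retained_mask.sum()),
        n_errors=int(is_error.sum()),
        n_voicekey=int(is_voicekey.sum()),
        n_fast=int(is_fast.sum()),
        per_group=per_group,
        min_rt_ms=min_rt_ms,
    )
    return trials.loc[retained_mask].copy(), report


def condition_medians(
    retained: pd.DataFrame, conditions: tuple[str, ...] = DEFAULT_CONDITIONS
) -> pd.DataFrame:
    """Per-participant median RT for each condition, as a wide table.

    Columns: ``participant_id, group`` plus one column per condition.  A
    participant-condition cell with no retained trials is NaN (explicitly
    missing, never imputed).  Even trial counts use the mean of the two
    central order statistics.
    """
    if retained.empty:
        return pd.DataFrame(columns=["participant_id", "group", *conditions])
    unknown = set(retained["condition"].unique()) - set(conditions)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    wide = (
        retained.pivot_table(
            index=["participant_id", "group"],
            columns="condition",
            values="rt_ms",
            aggfunc="median",
        )
        .reindex(columns=list(conditions))
        .reset_index()
    )
    wide.columns.name = None
    return wide.sort_values("participant_id", ignore_index=True)


def medians_long(medians: pd.DataFrame, conditions: tuple[str, ...] = DEFAULT_CONDITIONS) -> pd.DataFrame:
    """Melt the wide median table to (participant_id, group, condition, median_rt)."""
    long = medians.melt(
        id_vars=["participant_id", "group"],
        value_vars=[c for c in conditions if c in medians.columns],
        var_name="condition",
        value_name="median_rt",
    )
    return long.dropna(subset=["median_rt"]).reset_index(drop=True)


def compute_effects(medians: pd.DataFrame) -> pd.DataFrame:
    """The three distractor effects per participant, in ms.

    Any effect whose ingredient medians are missing is NaN.
    """
    out = medians[["participant_id", "group"]].copy()
    for name, (a, b) in EFFECT_DEFS.items():
        if a in medians.columns and b in medians.columns:
            out[f"{name}_ms"] = medians[a] - medians[b]
        else:
            out[f"{name}_ms"] = np.nan
    return out


def standardized_scores(effects: pd.DataFrame) -> pd.DataFrame:
    """Express each participant's effects in control-sample SD units.

    z = (effect - control mean) / control SD, with the sample (n-1) SD of the
    control group; |z| > 2 is flagged.  Controls are scored against their own
    group, so their z columns standardize to mean 0, SD 1 by construction.
    A zero or undefined control SD yields NaN scores.
    """
    controls = effects[effects["group"] == "control"]
    if len(controls) < 2:
        raise ValueError("need >= 2 control participants for standardized scores")
    out = effects.copy()
    for name in EFFECT_NAMES:
        col = f"{name}_ms"
        vals = controls[col].dropna()
        mean = vals.mean() if len(vals) >= 2 else np.nan
        sd = vals.std(ddof=1) if len(vals) >= 2 else np.nan
        if not np.isfinite(sd) or sd == 0:
            out[f"z_{name}"] = np.nan
            out[f"beyond_2sd_{name}"] = pd.array([pd.NA] * len(out), dtype="boolean")
            continue
        z = (out[col] - mean) / sd
        out[f"z_{name}"] = z
        out[f"beyond_2sd_{name}"] = pd.array(np.abs(z) > 2.0, dtype="boolean")
        out.loc[z.isna(), f"beyond_2sd_{name}"] = pd.NA
    return out


def rt_ratios(medians: pd.DataFrame) -> pd.DataFrame:
    """General-slowing-corrected effects: each effect / unrelated median.

    Dividing by the unrelated median (common to all three effects) removes a
    multiplicative slowing factor, so slow and fast groups become comparable
    on a dimensionless scale.  Missing or non-positive unrelated medians
    yield NaN ratios.
    """
    effects = compute_effects(medians)
    out = medians[["participant_id", "group"]].copy()
    denom = medians["unrelated"] if "unrelated" in medians.columns else pd.Series(np.nan, index=medians.index)
    denom = denom.where(denom > 0)
    for name in EFFECT_NAMES:
        out[f"ratio_{name}"] = effects[f"{name}_ms"] / denom
    return out


def effect_scores(medians: pd.DataFrame) -> pd.DataFrame:
    """Combined per-participant table: effects (ms), z-scores, and RT ratios."""
    effects = compute_effects(medians)
    scored = standardized_scores(effects)
    ratios = rt_ratios(medians)
    return scored.merge(ratios, on=["participant_id", "group"], validate="one_to_one")
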