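"""Model-free behavioural analysis: exclusions, choice rates, pro-variance
bias and trait correlations.

Option "a" in every block is the higher-mean deck, or the broader deck when
means are equal, so per-block a-choice rates read directly as accuracy
(different-mean blocks) or broader-option preference (same-mean blocks).
The mean pro-variance bias is the unweighted average of the four same-mean
block rates.
"""

from __future__ import annotations

import sys

import numpy as np
import pandas as pd
from scipy import stats

from . import task

ACCURACY_THRESHOLD = 60.0  # exclude strictly below this mean accuracy (%)


def block_choice_rates(subject_data: pd.DataFrame) -> pd.Series:
    """Percent of option-a choices per block for one subject."""
    counts = subject_data.groupby("block_type")["choice"].agg(["size", lambda c: (c == "a").sum()])
    if (counts["size"] == 0).any():
        raise ValueError("zero-trial block in subject data")
    rates = 100.0 * counts["<lambda_0>"] / counts["size"]
    rates.name = "pct_choose_a"
    return rates


def provariance_bias(rates) -> float:
    """Unweighted mean broader-choice rate over the four same-mean blocks."""
    missing = [b for b in task.SAME_MEAN_BLOCKS if b not in rates]
    if missing:
        raise ValueError(f"missing same-mean block rates: {missing}")
    return float(np.mean([rates[b] for b in task.SAME_MEAN_BLOCKS]))


def provariance_bias_components(rates) -> dict[str, float]:
    """Overall, unimodal-only and bimodal-only pro-variance means."""
    return {
        "provariance_bias": provariance_bias(rates),
        "provariance_bias_unimodal": float(
            np.mean([rates[b] for b in task.UNIMODAL_SAME_MEAN_BLOCKS])),
        "provariance_bias_bimodal": float(
            np.mean([rates[b] for b in task.BIMODAL_SAME_MEAN_BLOCKS])),
    }


def summarize_subjects(data: pd.DataFrame) -> pd.DataFrame:
    """Per-subject block rates, different-mean accuracy and pro-variance bias.

    Subjects without all eight blocks are flagged ``incomplete`` rather than
    silently dropped.
    """
    rows = []
    for sid, sub in data.groupby("subject_id"):
        rates = block_choice_rates(sub)
        row = {"subject_id": sid}
        complete = all(b in rates.index for b in task.BLOCK_TYPES)
        row["incomplete"] = not complete
        for b in task.BLOCK_TYPES:
            row[f"rate_{b}"] = float(rates[b]) if b in rates.index else np.nan
        if complete:
            row["mean_accuracy_diffmean"] = float(
                np.mean([rates[b] for b in task.DIFF_MEAN_BLOCKS]))
            row.update(provariance_bias_components(rates))
            row["any_constant_same_mean_block"] = any(
                rates[b] in (0.0, 100.0) for b in task.SAME_MEAN_BLOCKS)
        else:
            row["mean_accuracy_diffmean"] = np.nan
            row["provariance_bias"] = np.nan
            row["provariance_bias_unimodal"] = np.nan
            row["provariance_bias_bimodal"] = np.nan
            row["any_constant_same_mean_block"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def apply_exclusions(summaries: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the two exclusion rules; returns (retained, exclusion log).

    Rule 1 excludes mean different-mean accuracy strictly below 60%; rule 2
    excludes any subject whose choices are constant across all trials of at
    least one same-mean block.  Incomplete subjects are logged separately.
    Idempotent: re-applying to the retained set excludes no one further.
    """
    reasons = []
    for _, row in summaries.iterrows():
        if row.get("excluded", False):
            reason = row.get("exclusion_reason", "")
        elif row["incomplete"]:
            reason = "incomplete"
        elif row["mean_accuracy_diffmean"] < ACCURACY_THRESHOLD:
            reason = "low_diffmean_accuracy"
        elif row["any_constant_same_mean_block"]:
            reason = "constant_same_mean_block"
        else:
            reason = ""
        reasons.append(reason)
    out = summaries.copy()
    out["excluded"] = [r != "" for r in reasons]
    out["exclusion_reason"] = reasons
    log = out.loc[out["excluded"], ["subject_id", "exclusion_reason"]].reset_index(drop=True)
    return out[~out["excluded"]].reset_index(drop=True), log


def correlate_with_trait(values, traits) -> tuple[float, float, int]:
    """Two-tailed Pearson correlation: returns (r, p, n)."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(traits, dtype=float)
    if v.shape != t.shape:
        raise ValueError("values and traits must be paired")
    if len(v) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite values in correlation inputs")
    if np.std(v) == 0 or np.std(t) == 0:
        raise ValueError("zero variance in correlation inputs")
    res = stats.pearsonr(v, t)
    return float(res.statistic), float(res.pvalue), len(v)


def trait_correlation_table(summaries: pd.DataFrame, traits: pd.DataFrame,
                            fits: pd.DataFrame | None = None,
                            measures: tuple[str, ...] = ("provariance_bias",),
                            ) -> pd.DataFrame:
    """Correlate behavioural (and optionally fitted) measures with the trait.

    ``fits`` rows, if given, are merged on subject_id and their parameter
    columns added to the measure list.
    """
    merged = summaries.merge(traits, on="subject_id")
    measures = list(measures)
    if fits is not None:
        param_cols = [c for c in fits.columns
                      if c not in ("subject_id", "model", "loglik", "k", "n",
                                   "bic", "converged")]
        merged = merged.merge(fits[["subject_id"] + param_cols], on="subject_id")
        measures += param_cols
    rows = []
    for m in measures:
        r, p, n = correlate_with_trait(merged[m], merged["trait_score"])
        rows.append({"measure": m, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def log_stage(msg: str) -> None:
    print(msg, file=sys.stderr)
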