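"""Behavioral facilitation analysis.

Reaction times and accuracy are analyzed in a three-condition design:
expected trials, unexpected trials requiring the same button press as the
expected image (same animacy), and unexpected trials requiring a different
press.  Statistical learning predicts expected < unexpected-same <
unexpected-different RTs.  The battery: trial filtering, a one-way
repeated-measures ANOVA with Greenhouse-Geisser correction, Holm-corrected
post-hoc paired t tests with Cohen's dz, Cousineau-Morey within-subject
confidence intervals, and directional 2-SD subject-exclusion screening.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import cohens_dz
from .stimuli import StimulusSet

CONDITIONS3 = ("expected", "unexpected_same", "unexpected_diff")

RT_MIN_MS = 100.0
RT_MAX_MS = 1500.0


def filter_trials(responses: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the trial-exclusion rules for the behavioral analysis.

    No-go trials are dropped; go trials with RT < 100 ms or > 1,500 ms are
    excluded (boundary values retained); the correct-response subset used
    for RT analysis is marked with ``rt_eligible``.
    """
    go = responses[responses["condition3"] != "nogo"].copy()
    n_go = len(go)
    responded = go["responded"].fillna(False).astype(bool)
    rt_ok = responded & (go["rt_ms"] >= RT_MIN_MS) & (go["rt_ms"] <= RT_MAX_MS)
    # misses stay for the accuracy analysis; RT analysis needs correct + in-range
    kept = go[rt_ok | ~responded].copy()
    kept["rt_eligible"] = rt_ok.loc[kept.index] & kept["correct"].astype(bool)
    report = {
        "n_go": n_go,
        "n_nogo_dropped": int((responses["condition3"] == "nogo").sum()),
        "n_rt_out_of_bounds": int((responded & ~rt_ok).sum()),
        "n_rt_eligible": int(kept["rt_eligible"].sum()),
    }
    return kept, report


def condition_split(filtered: pd.DataFrame, subject_column: str = "subject",
                    ) -> pd.DataFrame:
    """Per-subject mean RT (correct, in-bounds trials) and accuracy per
    three-way condition."""
    rows = []
    for (subject, cond), grp in filtered.groupby([subject_column, "condition3"]):
        rt = grp.loc[grp["rt_eligible"], "rt_ms"]
        rows.append({
            "subject": subject, "condition3": cond,
            "mean_rt_ms": float(rt.mean()) if len(rt) else np.nan,
            "accuracy": float(grp["correct"].mean()),
            "n_trials": len(grp),
        })
    return pd.DataFrame(rows)


def classify_condition3(trials: pd.DataFrame, stimuli: StimulusSet) -> pd.Series:
    """Map raw trial conditions to the three-way behavioral split by animacy
    agreement between the seen and the cue-predicted image."""
    out = []
    for _, row in trials.iterrows():
        if row["condition"] == "nogo":
            out.append("nogo")
        elif row["condition"] == "expected":
            out.append("expected")
        else:
            expected_img = stimuli.stimulus_for_cue(row["cue"])
            same = stimuli.animacy_of(expected_img) == stimuli.animacy_of(row["stim_id"])
            out.append("unexpected_same" if same else "unexpected_diff")
    return pd.Series(out, index=trials.index)


def rm_anova(summary: pd.DataFrame, measure: str = "mean_rt_ms") -> dict:
    """One-way repeated-measures ANOVA (3 levels) with Greenhouse-Geisser
    correction applied whenever sphericity epsilon < 1."""
    aov = pg.rm_anova(data=summary, dv=measure, within="condition3",
                      subject="subject", correction=True, detailed=True)
    row = aov.iloc[0]
    n_sub = summary["subject"].nunique()
    eps = float(row.get("eps", 1.0))
    df1, df2 = row["DF"], aov.iloc[1]["DF"]
    gg_col = next((c for c in aov.columns if c.replace("-", "_") == "p_GG_corr"), None)
    p_col = next(c for c in aov.columns if c.replace("-", "_") == "p_unc")
    if eps < 1.0 and gg_col is not None and not np.isnan(row[gg_col]):
        p = float(row[gg_col])
        df1, df2 = df1 * eps, df2 * eps
    else:
        p = float(row[p_col])
    ss_effect = float(row["SS"])
    ss_error = float(aov.iloc[1]["SS"])
    return {"F": float(row["F"]), "df1": float(df1), "df2": float(df2),
            "p": p, "epsilon": eps, "n_subjects": n_sub,
            "partial_eta_sq": ss_effect / (ss_effect + ss_error)}


def posthoc(summary: pd.DataFrame, measure: str = "mean_rt_ms") -> pd.DataFrame:
    """Pairwise paired t tests between the 3 conditions with Holm-adjusted p
    and Cohen's dz."""
    wide = summary.pivot(index="subject", columns="condition3", values=measure)
    pairs = [("expected", "unexpected_same"),
             ("expected", "unexpected_diff"),
             ("unexpected_same", "unexpected_diff")]
    rows = []
    for a, b in pairs:
        diff = (wide[b] - wide[a]).dropna().to_numpy()
        if np.allclose(diff, 0.0):
            t, p, dz = 0.0, 1.0, 0.0
        else:
            res = stats.ttest_rel(wide[a].dropna(), wide[b].dropna())
            t, p, dz = float(res.statistic), float(res.pvalue), cohens_dz(diff)
        rows.append({"a": a, "b": b, "t": t, "p": p, "dz": dz,
                     "mean_diff": float(np.mean(diff))})
    table = pd.DataFrame(rows)
    _, p_holm, _, _ = multipletests(table["p"], method="holm")
    table["p_holm"] = p_holm
    return table


def cousineau_morey(wide: pd.DataFrame) -> pd.DataFrame:
    """Cousineau within-subject normalization with the Morey bias correction.

    Subtract each subject's mean, add the grand mean, then scale condition
    variances by C/(C-1) for C conditions (applied downstream as a variance
    multiplier in the CI computation).
    """
    c = wide.shape[1]
    if c < 2:
        raise ValueError("within-subject normalization needs >= 2 conditions")
    subject_means = wide.mean(axis=1)
    grand = float(wide.to_numpy().mean())
    return wide.sub(subject_means, axis=0) + grand


def within_subject_ci(summary: pd.DataFrame, measure: str = "mean_rt_ms",
                      level: float = 0.95) -> pd.DataFrame:
    """Per-condition CI half-widths from Cousineau-Morey normalized data."""
    wide = summary.pivot(index="subject", columns="condition3", values=measure)
    c = wide.shape[1]
    normalized = cousineau_morey(wide)
    n = len(normalized)
    correction = c / (c - 1)
    var = normalized.var(ddof=1) * correction
    sem = np.sqrt(var / n)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return pd.DataFrame({
        "condition3": wide.columns,
        "mean": wide.mean().to_numpy(),
        "ci_half_width": (tcrit * sem).to_numpy(),
    })


HIGHER_IS_WORSE = {"mean_fd": True, "fd_percent": True, "dvars": True,
                   "rt": True, "tsnr": False, "accuracy": False}


def exclusion_screen(metrics: pd.DataFrame,
                     directions: dict[str, bool] | None = None,
                     n_sd: float = 2.0) -> pd.DataFrame:
    """Directional 2-SD subject-exclusion rule.

    A subject is flagged if any metric is worse than the sample mean by more
    than ``n_sd`` standard deviations, with "worse" being higher for motion/
    noise/RT metrics and lower for tSNR/accuracy.
    """
    directions = dict(HIGHER_IS_WORSE if directions is None else directions)
    rows = []
    for idx, row in metrics.iterrows():
        reasons = []
        for col, higher_worse in directions.items():
            if col not in metrics.columns:
                continue
            mean, sd = metrics[col].mean(), metrics[col].std(ddof=1)
            if sd == 0 or np.isnan(sd):
                continue
            if higher_worse and row[col] > mean + n_sd * sd:
                reasons.append(col)
            elif not higher_worse and row[col] < mean - n_sd * sd:
                reasons.append(col)
        rows.append({"subject": row.get("subject", idx),
                     "excluded": bool(reasons),
                     "reasons": ",".join(reasons)})
    return pd.DataFrame(rows)
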