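"""qPCR amplification efficiency and relative quantification (2^-ddCt).

Efficiency comes from the slope of Ct vs log10(input) over a dilution
series: E = 10^(-1/slope) - 1 (a perfect 1:2 series gives slope
-3.3219 and E = 100%). Relative expression uses the 2^-ddCt method: the
target's Ct is normalized to a reference gene within each sample
(dCt), the treated sample is compared with the control (ddCt), and the
fold change is 2^-ddCt. Replicate means are taken before differencing;
the reported standard error propagates the replicate scatter of the two
dCt terms.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


def efficiency(dilution_points: list[tuple[float, float]]) -> dict:
    """Amplification efficiency from (log10 input, Ct) dilution points.

    Returns slope, intercept, r-squared and E = 10^(-1/slope) - 1.
    Requires >= 3 points with varying input.
    """
    if len(dilution_points) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.array([p[0] for p in dilution_points], dtype=float)
    y = np.array([p[1] for p in dilution_points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("dilution inputs have zero variance")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "efficiency": float(10 ** (-1.0 / fit.slope) - 1.0),
    }


def ddct(
    ct_target_treated: float | list[float],
    ct_ref_treated: float | list[float],
    ct_target_control: float | list[float],
    ct_ref_control: float | list[float],
) -> dict:
    """Fold change by 2^-ddCt with SE propagated from replicate dCts.

    Scalars or replicate lists are accepted; replicate means are taken
    before differencing. ddCt = (CtT - CtRef)_treated -
    (CtT - CtRef)_control; fold = 2^-ddCt.
    """
    def as_arr(v):
        a = np.atleast_1d(np.asarray(v, dtype=float))
        if a.size == 0 or not np.isfinite(a).all():
            raise ValueError("Ct values must be finite and non-empty")
        return a

    tt, rt = as_arr(ct_target_treated), as_arr(ct_ref_treated)
    tc, rc = as_arr(ct_target_control), as_arr(ct_ref_control)
    dct_t = tt.mean() - rt.mean()
    dct_c = tc.mean() - rc.mean()
    ddct_val = dct_t - dct_c

    def se_dct(t, r):
        parts = []
        for a in (t, r):
            if a.size > 1:
                parts.append(a.var(ddof=1) / a.size)
        return math.sqrt(sum(parts)) if parts else 0.0

    se = math.sqrt(se_dct(tt, rt) ** 2 + se_dct(tc, rc) ** 2)
    return {
        "ddct": float(ddct_val),
        "fold": float(2.0 ** (-ddct_val)),
        "log2_fold": float(-ddct_val),
        "se_ddct": float(se),
    }


def fold_table(
    ct_table: pd.DataFrame, reference_target: str, control_time: str = "control"
) -> pd.DataFrame:
    """2^-ddCt folds for every target x tissue x stressed time point.

    ``ct_table`` is the long-format table (target, tissue, time, bio_rep,
    tech_rep, ct); technical replicates are averaged within biological
    replicates, and biological-replicate dCts feed the SE.
    """
    if reference_target not in set(ct_table["target"]):
        raise ValueError(f"reference target {reference_target!r} missing from table")
    bio = (
        ct_table.groupby(["target", "tissue", "time", "bio_rep"])["ct"]
        .mean()
        .reset_index()
    )
    rows = []
    for (target, tissue), sub in bio.groupby(["target", "tissue"]):
        if target == reference_target:
            continue
        ref = bio[(bio["target"] == reference_target) & (bio["tissue"] == tissue)]
        for time in sorted(set(sub["time"]) - {control_time}):
            def cts(frame, t):
                return frame.loc[frame["time"] == t, "ct"].to_numpy()

            ref_t, ref_c = cts(ref, time), cts(ref, control_time)
            tgt_t, tgt_c = cts(sub, time), cts(sub, control_time)
            if min(map(len, (ref_t, ref_c, tgt_t, tgt_c))) == 0:
                raise ValueError(f"missing Ct values for {target}/{tissue}/{time}")
            # pair replicate dCts so the SE reflects replicate scatter
            nt = min(len(tgt_t), len(ref_t))
            nc = min(len(tgt_c), len(ref_c))
            dct_t = tgt_t[:nt] - ref_t[:nt]
            dct_c = tgt_c[:nc] - ref_c[:nc]
            ddct_val = dct_t.mean() - dct_c.mean()
            se = math.sqrt(
                (dct_t.var(ddof=1) / nt if nt > 1 else 0.0)
                + (dct_c.var(ddof=1) / nc if nc > 1 else 0.0)
            )
            rows.append(
                {
                    "target": target,
                    "tissue": tissue,
                    "time": time,
                    "ddct": float(ddct_val),
                    "fold": float(2.0 ** (-ddct_val)),
                    "log2_fold": float(-ddct_val),
                    "se_ddct": float(se),
                }
            )
    return pd.DataFrame(rows)


def compare_with_rnaseq(
    folds: pd.DataFrame, de: pd.DataFrame, time_of_contrast=None
) -> dict:
    """R-squared between qPCR and RNA-seq fold changes, on both the fold
    and the log2-fold scale (matched by target, tissue and time)."""
    time_of_contrast = time_of_contrast or {
        "3h": "3h_vs_control",
        "96h": "96h_vs_control",
    }
    x_log, y_log = [], []
    for _, row in folds.iterrows():
        contrast = time_of_contrast.get(row["time"])
        m = de[
            (de["transcript_id"] == row["target"])
            & (de["tissue"] == row["tissue"])
            & (de["contrast"] == contrast)
        ]
        if len(m) == 1:
            x_log.append(row["log2_fold"])
            y_log.append(float(m["log2fc"].iloc[0]))
    if len(x_log) < 3:
        return {"n": len(x_log), "r_squared_log2": float("nan"), "r_squared_fold": float("nan")}
    x, y = np.array(x_log), np.array(y_log)
    r_log = stats.pearsonr(x, y).statistic
    r_fold = stats.pearsonr(2.0**x, 2.0**y).statistic
    return {
        "n": len(x_log),
        "r_squared_log2": float(r_log**2),
        "r_squared_fold": float(r_fold**2),
    }
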