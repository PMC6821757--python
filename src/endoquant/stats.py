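"""Statistical procedures: t-tests, contingency chi-square, the
fold-change/p-value expression screen, and qPCR relative expression.

The expression screen keeps genes showing a more than ``fold_threshold``
(default 3.8) fold difference between conditions — in either direction,
strict inequality — at a per-gene t-test p-value below ``alpha`` (0.05),
ranked by absolute log2 fold change and truncated to the top N.  qPCR
relative expression uses the 2^-ddCt method against a reference gene,
normalized to a baseline condition (amplification efficiency 2, no
efficiency correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "t_test_two_sample",
    "chi_square_test",
    "screen_filter",
    "relative_expression",
    "ScreenRecord",
    "DEFAULT_FOLD_THRESHOLD",
    "DEFAULT_ALPHA",
]

DEFAULT_FOLD_THRESHOLD = 3.8
DEFAULT_ALPHA = 0.05


@dataclass
class ScreenRecord:
    gene_id: str
    fold_change: float  # condition / control, linear scale
    p_value: float
    passes: bool


def t_test_two_sample(a, b, variant: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test.

    ``variant`` is ``"welch"`` (default, unequal variances) or
    ``"student"`` (pooled variance).  When both samples have zero
    variance and equal means the statistic is 0 and p = 1 by convention
    (a warning is emitted).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            warnings.warn("both samples constant and equal; p = 1 by convention")
            return 0.0, 1.0
        return np.inf, 0.0
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on an R x C count table.

    ``table`` is a DataFrame (conditions x categories) or 2-D array.
    Returns (chi2, df, p).  Warns when any expected count is below 5.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be non-negative integers")
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("zero marginal row or column")
    chi2, p, df, expected = sps.chi2_contingency(counts, correction=False)
    if np.any(expected < 5):
        warnings.warn("expected count below 5; chi-square approximation is weak")
    return float(chi2), int(df), float(p)


def _condition_columns(table: pd.DataFrame) -> tuple[str, str, list[str], list[str]]:
    cols = [c for c in table.columns if c != "gene_id"]
    prefixes = []
    for c in cols:
        p = c.rsplit("_", 1)[0]
        if p not in prefixes:
            prefixes.append(p)
    if len(prefixes) != 2:
        raise ValueError("expression table must hold exactly two conditions")
    ca, cb = prefixes
    return ca, cb, [c for c in cols if c.rsplit("_", 1)[0] == ca], \
        [c for c in cols if c.rsplit("_", 1)[0] == cb]


def screen_filter(
    table: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    top_n: int = 100,
    multiple_testing: str | None = None,
) -> pd.DataFrame:
    """Differential-expression screen on a two-condition replicate table.

    The per-gene fold change is the ratio of condition means (second
    condition over first); a gene passes iff ``max(FC, 1/FC)`` strictly
    exceeds ``fold_threshold`` and its Welch t-test p-value is below
    ``alpha``.  Passing genes are ranked by absolute log2 fold change and
    truncated to ``top_n``.  ``multiple_testing="bh"`` optionally applies
    a Benjamini-Hochberg adjustment to the p-values first (off by
    default).
    """
    ca, cb, cols_a, cols_b = _condition_columns(table)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 replicates per condition")
    va = table[cols_a].to_numpy(dtype=float)
    vb = table[cols_b].to_numpy(dtype=float)
    fc = vb.mean(axis=1) / va.mean(axis=1)
    with warnings.catch_warnings():
        # constant replicate rows trigger a scipy precision warning; they
        # are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(vb, va, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    # constant, identical replicate rows (noise-free nulls) give NaN: no evidence
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    if multiple_testing == "bh":
        pvals = _benjamini_hochberg(pvals)
    elif multiple_testing is not None:
        raise ValueError("multiple_testing must be None or 'bh'")
    magnitude = np.maximum(fc, 1.0 / fc)
    # strict "more than" gate with a float tie tolerance: a fold change
    # numerically equal to the threshold does not pass
    above = (magnitude > fold_threshold) & ~np.isclose(magnitude, fold_threshold,
                                                       rtol=1e-9, atol=0.0)
    passes = above & (pvals < alpha)
    out = pd.DataFrame({
        "gene_id": table["gene_id"],
        "fold_change": fc,
        "p_value": pvals,
        "passes": passes,
    })
    out = out[out.passes].copy()
    out["abs_log2_fc"] = np.abs(np.log2(out.fold_change))
    out = out.sort_values(["abs_log2_fc", "gene_id"], ascending=[False, True])
    return out.head(top_n).drop(columns="abs_log2_fc").reset_index(drop=True)


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def relative_expression(
    samples: pd.DataFrame,
    baseline_condition: str = "wild_type",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR relative expression by the 2^-ddCt method.

    ``samples`` needs columns (condition, ct_target, ct_reference); each
    row is one biological sample.  dCt = ct_target - ct_reference;
    ddCt is taken against the baseline condition's mean dCt, and the
    per-condition relative expression is 2^-(mean dCt - baseline mean
    dCt), so the baseline condition is exactly 1.  Returns
    (per_sample, summary); the summary carries mean, sem (propagated from
    the dCt scale) and a Welch t-test p-value of each condition's dCt
    against the baseline.
    """
    required = {"condition", "ct_target", "ct_reference"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(required)}")
    if samples[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct value")
    df = samples.copy()
    df["delta_ct"] = df.ct_target - df.ct_reference
    if baseline_condition not in set(df.condition):
        raise ValueError(f"baseline condition {baseline_condition!r} absent")
    base_mean = df.loc[df.condition == baseline_condition, "delta_ct"].mean()
    df["ddct"] = df.delta_ct - base_mean
    df["relative_expression"] = 2.0 ** (-df.ddct)

    rows = []
    base_vals = df.loc[df.condition == baseline_condition, "delta_ct"].to_numpy()
    for cond, grp in df.groupby("condition", sort=False):
        dct = grp.delta_ct.to_numpy()
        rel = 2.0 ** (-(dct.mean() - base_mean))
        sem_dct = dct.std(ddof=1) / np.sqrt(dct.size) if dct.size > 1 else 0.0
        # first-order propagation of the dCt SEM onto the 2^-ddCt scale
        sem_rel = rel * np.log(2.0) * sem_dct
        if cond == baseline_condition or dct.size < 2 or base_vals.size < 2:
            p = 1.0 if cond == baseline_condition else float("nan")
        else:
            _, p = t_test_two_sample(dct, base_vals)
        rows.append({
            "condition": cond,
            "n": dct.size,
            "relative_expression": rel,
            "sem": sem_rel,
            "p_value_vs_baseline": p,
        })
    return df, pd.DataFrame(rows)
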