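"""Agreement statistics between estimator variants and ground truth.

Reusable reporting on any (predictions, truth) pair: mean absolute error,
intraclass correlation, Bland-Altman mean difference with 95% limits of
agreement, and the two-sample Kolmogorov-Smirnov test, plus a grid
comparison of the demographic and fixed estimator variants per demographic
group.

The ICC defaults to the two-way random-effects, absolute-agreement,
single-measures form (ICC2 in the Shrout-Fleiss taxonomy, computed by
pingouin); other forms change the value materially, so the choice is
explicit and configurable. The source naming "inter coder coefficient" is
taken to mean the intraclass correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import InputError

ALPHA = 0.05  # report annotation only, never a hard gate

#: Bland-Altman difference orientation: differences are truth - prediction,
#: so a positive mean difference means the estimator under-estimates.
BA_ORIENTATION = "truth - prediction"


@dataclass
class EvaluationReport:
    label: str
    n: int
    mae_mmhg: float
    icc: float
    bland_altman: dict
    ks: dict

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mae_mmHg": self.mae_mmhg,
            "icc": self.icc,
            "bland_altman": self.bland_altman,
            "ks": self.ks,
        }


def _paired(pred, truth, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise InputError("pred and truth must be equal-length 1-D sequences")
    if pred.size < min_n:
        raise InputError(f"need at least {min_n} paired values")
    return pred, truth


def mae(pred, truth) -> float:
    """Mean absolute error, mmHg."""
    pred, truth = _paired(pred, truth, 1)
    return float(np.mean(np.abs(pred - truth)))


def bland_altman(pred, truth) -> dict:
    """Mean difference (truth - pred) and mean +/- 1.96 sd agreement limits."""
    pred, truth = _paired(pred, truth, 2)
    diff = truth - pred
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "mean_diff_mmHg": mean_diff,
        "sd_diff_mmHg": sd,
        "loa_low": mean_diff - 1.96 * sd,
        "loa_high": mean_diff + 1.96 * sd,
        "orientation": BA_ORIENTATION,
    }


#: Aliases between the Shrout-Fleiss and McGraw-Wong ICC naming schemes.
_ICC_ALIASES = {
    "ICC1": "ICC(1,1)",
    "ICC2": "ICC(A,1)",
    "ICC3": "ICC(C,1)",
    "ICC1k": "ICC(1,k)",
    "ICC2k": "ICC(A,k)",
    "ICC3k": "ICC(C,k)",
}


def icc(pred, truth, form: str = "ICC2") -> float:
    """Intraclass correlation between the two raters (estimator, truth)."""
    pred, truth = _paired(pred, truth, 3)
    form = _ICC_ALIASES.get(form, form)
    n = pred.size
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["pred", "truth"], n),
            "value": np.concatenate([pred, truth]),
        }
    )
    import pingouin as pg

    table = pg.intraclass_corr(
        data=df, targets="subject", raters="rater", ratings="value"
    )
    names = {form} | {k for k, v in _ICC_ALIASES.items() if v == form}
    row = table.loc[table["Type"].isin(names), "ICC"]
    if row.empty:
        raise InputError(f"unknown ICC form {form!r}")
    return float(row.iloc[0])


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("KS test needs two nonempty samples")
    res = _stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def evaluate(pred, truth, label: str = "all") -> EvaluationReport:
    """Full agreement report for one (pred, truth) pair."""
    pred, truth = _paired(pred, truth, 3)
    stat, p = ks_two_sample(pred, truth)
    return EvaluationReport(
        label=label,
        n=int(pred.size),
        mae_mmhg=mae(pred, truth),
        icc=icc(pred, truth),
        bland_altman=bland_altman(pred, truth),
        ks={"statistic": stat, "p_value": p, "alpha": ALPHA},
    )


def compare_variants(
    demographic: pd.DataFrame,
    fixed: pd.DataFrame,
    group_by: tuple[str, ...] = ("country", "gender"),
) -> pd.DataFrame:
    """Variant-comparison grid over demographic groups.

    Both inputs are per-subject frames as produced by
    :func:`vbpe.synthetic.cohort_estimates` (columns ``subject_id``,
    ``true_sbp``, ``true_dbp``, ``sbp``, ``dbp`` plus group labels),
    aligned on ``subject_id``. For each group (the whole cohort plus one
    row-set per label value present) and each measure (SBP, DBP), the grid
    holds KS p-values for demographic-vs-fixed, demographic-vs-truth and
    fixed-vs-truth, with MAE per variant.
    """
    d = demographic.set_index("subject_id").sort_index()
    f = fixed.set_index("subject_id").sort_index()
    if not d.index.equals(f.index):
        raise InputError("variant frames must cover the same subjects")

    groups: list[tuple[str, pd.Index]] = [("all", d.index)]
    for col in group_by:
        if col not in d.columns:
            continue
        values = [v for v in d[col].dropna().unique()]
        if len(values) >= 2:
            for v in sorted(values):
                groups.append((f"{col}={v}", d.index[d[col] == v]))

    rows = []
    for label, idx in groups:
        dg, fg = d.loc[idx], f.loc[idx]
        for measure, est_col, true_col in (
            ("SBP", "sbp", "true_sbp"),
            ("DBP", "dbp", "true_dbp"),
        ):
            truth = dg[true_col].to_numpy()
            de = dg[est_col].to_numpy()
            fe = fg[est_col].to_numpy()
            for comparison, a, b in (
                ("demographic_vs_fixed", de, fe),
                ("demographic_vs_truth", de, truth),
                ("fixed_vs_truth", fe, truth),
            ):
                stat, p = ks_two_sample(a, b)
                rows.append(
                    {
                        "group": label,
                        "measure": measure,
                        "comparison": comparison,
                        "n": len(idx),
                        "ks_statistic": stat,
                        "p_value": p,
                        "significant": bool(p < ALPHA),
                        "mae_mmHg": mae(a, b)
                        if "truth" in comparison
                        else np.nan,
                    }
                )
    return pd.DataFrame(rows)
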