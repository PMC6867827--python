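"""RT-qPCR relative quantification and smFISH knockdown comparisons.

Relative expression uses the 2^-DeltaDeltaCt method normalized to a
housekeeping reference gene and a control condition, followed by the
replicate standardization chain used for variable biological material:
natural-log transform of every fold change within a biological replicate,
mean centering and autoscaling (unit SD) per replicate, then per
gene-condition means with Student-t 95% confidence intervals.  Both the
standardized-scale CI and the back-transformed geometric-mean fold CI are
reported.

Technical replicates are averaged at the Ct level before any differencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class MissingReferenceError(ValueError):
    """Reference gene or control condition absent from a replicate."""


REQUIRED_CT_COLUMNS = ("sample", "condition", "gene", "ct")


def ddct(ct_table: pd.DataFrame, reference_gene: str, control_condition: str) -> pd.DataFrame:
    """Per-replicate fold changes by the 2^-DeltaDeltaCt method.

    ``sample`` labels the biological replicate and must pair conditions:
    DeltaCt = Ct_gene - Ct_reference within (sample, condition), and
    DeltaDeltaCt subtracts the same replicate's control-condition DeltaCt.
    Technical replicates (repeated rows) are averaged at the Ct level.
    The reference gene is dropped from the output (its fold is identically 1).

    Returns columns ``sample, condition, gene, delta_ct, ddct, fold``.
    """
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    ct = (
        ct_table.groupby(["sample", "condition", "gene"], as_index=False)["ct"].mean()
    )
    ref = ct[ct["gene"] == reference_gene].set_index(["sample", "condition"])["ct"]
    if ref.empty:
        raise MissingReferenceError(f"reference gene {reference_gene!r} not found")
    work = ct[ct["gene"] != reference_gene].copy()
    key = list(zip(work["sample"], work["condition"]))
    try:
        work["delta_ct"] = work["ct"].to_numpy() - ref.loc[key].to_numpy()
    except KeyError as err:
        raise MissingReferenceError(
            f"reference gene {reference_gene!r} missing in some (sample, condition)"
        ) from err
    ctrl = work[work["condition"] == control_condition].set_index(["sample", "gene"])[
        "delta_ct"
    ]
    if ctrl.empty:
        raise MissingReferenceError(
            f"control condition {control_condition!r} not found"
        )
    key2 = list(zip(work["sample"], work["gene"]))
    try:
        work["ddct"] = work["delta_ct"].to_numpy() - ctrl.loc[key2].to_numpy()
    except KeyError as err:
        raise MissingReferenceError(
            "control condition missing for some (sample, gene)"
        ) from err
    work["fold"] = 2.0 ** (-work["ddct"])
    return work[["sample", "condition", "gene", "delta_ct", "ddct", "fold"]].reset_index(
        drop=True
    )


def standardize_replicates(
    folds: pd.DataFrame, control_condition: str | None = None
):
    """Log-transform, mean-center and autoscale fold changes per replicate.

    Within each biological replicate (``sample``) the natural logs of all
    measured gene-condition fold changes are centered to mean 0 and scaled
    to SD 1.  Control-condition rows (fold identically 1 by construction)
    are excluded from the standardized set when ``control_condition`` is
    given.

    Returns ``(standardized, summary)``: the per-replicate standardized
    values, and a per (condition, gene) table with the standardized mean
    and t-based 95% CI plus the geometric-mean fold and its back-transformed
    95% CI.
    """
    work = folds.copy()
    if control_condition is not None:
        work = work[work["condition"] != control_condition]
    if work["sample"].nunique() < 2:
        raise ValueError("at least 2 biological replicates are required")
    work["log_fold"] = np.log(work["fold"].to_numpy(dtype=float))

    def _scale(g):
        v = g["log_fold"]
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            g["standardized"] = 0.0
        else:
            g["standardized"] = (v - v.mean()) / sd
        return g

    if work.groupby("sample")["log_fold"].size().min() < 2:
        raise ValueError("each replicate needs at least 2 gene-condition values")
    work = (
        work.groupby("sample", group_keys=False)[work.columns]
        .apply(_scale)
        .reset_index(drop=True)
    )

    rows = []
    for (cond, gene), g in work.groupby(["condition", "gene"]):
        n = len(g)
        tcrit = stats.t.ppf(0.975, n - 1) if n > 1 else np.nan
        m_std = g["standardized"].mean()
        se_std = g["standardized"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        m_log = g["log_fold"].mean()
        se_log = g["log_fold"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rows.append(
            {
                "condition": cond,
                "gene": gene,
                "n_bio": n,
                "mean_standardized": m_std,
                "ci95_low_standardized": m_std - tcrit * se_std,
                "ci95_high_standardized": m_std + tcrit * se_std,
                "geo_mean_fold": np.exp(m_log),
                "ci95_low_fold": np.exp(m_log - tcrit * se_log),
                "ci95_high_fold": np.exp(m_log + tcrit * se_log),
            }
        )
    return work, pd.DataFrame(rows)


@dataclass
class RelativeExpressionResult:
    """Fold changes, standardized values and CI summary per gene-condition."""

    folds: pd.DataFrame
    standardized: pd.DataFrame
    table: pd.DataFrame
    reference_gene: str
    control_condition: str

    def summary(self) -> str:
        lines = [
            f"Relative expression (2^-ddCt), reference {self.reference_gene!r}, "
            f"control {self.control_condition!r}",
        ]
        for row in self.table.itertuples():
            lines.append(
                f"  {row.condition} / {row.gene}: fold {row.geo_mean_fold:.3f} "
                f"[{row.ci95_low_fold:.3f}, {row.ci95_high_fold:.3f}] "
                f"(standardized {row.mean_standardized:+.2f} "
                f"[{row.ci95_low_standardized:+.2f}, {row.ci95_high_standardized:+.2f}],"
                f" n={row.n_bio})"
            )
        return "\n".join(lines)


class RelativeExpressionModel:
    """2^-DeltaDeltaCt model for a long-format Ct table.

    Parameters
    ----------
    ct_table : DataFrame with columns ``sample, condition, gene, ct``
    reference_gene : housekeeping gene used for within-sample normalization
    control_condition : condition whose DeltaCt anchors DeltaDeltaCt
    """

    def __init__(self, ct_table: pd.DataFrame, reference_gene: str, control_condition: str):
        self.ct_table = ct_table
        self.reference_gene = reference_gene
        self.control_condition = control_condition

    def fit(self) -> RelativeExpressionResult:
        folds = ddct(self.ct_table, self.reference_gene, self.control_condition)
        standardized, table = standardize_replicates(
            folds, control_condition=self.control_condition
        )
        return RelativeExpressionResult(
            folds=folds,
            standardized=standardized,
            table=table,
            reference_gene=self.reference_gene,
            control_condition=self.control_condition,
        )


@dataclass
class KnockdownResult:
    """Percent change of mean per-cell counts between two conditions."""

    mean_control: float
    mean_treated: float
    percent_reduction: float
    t_stat: float
    p_value: float

    def summary(self) -> str:
        return (
            f"knockdown: control mean {self.mean_control:.2f}, treated mean "
            f"{self.mean_treated:.2f} -> {self.percent_reduction:.1f}% reduction "
            f"(Welch t = {self.t_stat:.2f}, p = {self.p_value:.3g})"
        )


def count_knockdown(counts_control, counts_treated) -> KnockdownResult:
    """Percent reduction of mean per-cell counts, with a Welch t test.

    Applies equally to per-cell spot counts and per-cell colocalized-pair
    counts.
    """
    a = np.asarray(counts_control, dtype=float)
    b = np.asarray(counts_treated, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both conditions need at least one cell")
    mean_a, mean_b = a.mean(), b.mean()
    if mean_a == 0:
        raise ValueError("control mean count is zero; reduction undefined")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if mean_a == mean_b else (np.inf * np.sign(mean_a - mean_b), 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return KnockdownResult(
        mean_control=float(mean_a),
        mean_treated=float(mean_b),
        percent_reduction=float(100.0 * (1.0 - mean_b / mean_a)),
        t_stat=float(t),
        p_value=float(p),
    )
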