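"""Relative qPCR quantification (2^-dCT against a housekeeping reference).

Technical-replicate CTs are averaged per (gene, condition, biological
replicate); dCT = mean CT of the gene minus mean CT of the reference gene
(lsm12b in the original assays) within the same biological replicate; the
relative abundance is 2^-dCT. Group comparisons report the mean +/- SEM
fold change across replicates with a paired or unpaired t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import ValidationError

__all__ = [
    "CtTable",
    "GroupFoldChange",
    "TTestResult",
    "average_technical_replicates",
    "group_fold_change",
    "rel_abundance_table",
    "relative_abundance",
    "t_test",
]

DEFAULT_REFERENCE_GENE = "lsm12b"


@dataclass
class CtTable:
    """Long-format CT table: gene, condition, bio_rep, tech_rep, ct."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"gene", "condition", "bio_rep", "tech_rep", "ct"} - set(self.data.columns)
        if missing:
            raise ValidationError(f"CT table missing columns: {sorted(missing)}")
        ct = self.data["ct"].to_numpy(float)
        if np.isnan(ct).any() or np.isinf(ct).any() or (ct <= 0).any():
            raise ValidationError("CT values must be finite and > 0")


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    flag: str = ""


@dataclass
class GroupFoldChange:
    """Fold change of test vs control with the paper-style 'fold decrease'.

    ``mean_ratio`` is always the test/control scale; when the mean ratio is
    below 1 a ``fold_decrease`` (reciprocal scale, mean +/- SEM over
    per-replicate reciprocals in paired mode) is reported alongside.
    """

    mean_ratio: float
    sem_ratio: float
    fold_decrease: float | None
    fold_decrease_sem: float | None
    n_control: int
    n_test: int
    paired: bool
    test: TTestResult
    flag: str = ""


def average_technical_replicates(table: CtTable) -> pd.DataFrame:
    """Mean CT per (gene, condition, bio_rep); warns on lone technical reps."""
    grouped = table.data.groupby(["gene", "condition", "bio_rep"], observed=True)["ct"]
    out = grouped.agg(mean_ct="mean", n_tech="size").reset_index()
    singles = out[out["n_tech"] == 1]
    for _, row in singles.iterrows():
        warnings.warn(
            f"single technical replicate for gene={row['gene']} "
            f"condition={row['condition']} bio_rep={row['bio_rep']}",
            stacklevel=2,
        )
    return out


def relative_abundance(mean_ct_gene: float, mean_ct_ref: float) -> float:
    """2^-(CT_gene - CT_ref)."""
    return float(2.0 ** -(mean_ct_gene - mean_ct_ref))


def rel_abundance_table(
    table: CtTable, ref_gene: str = DEFAULT_REFERENCE_GENE
) -> pd.DataFrame:
    """Per (gene, condition, bio_rep) relative abundance vs the reference gene.

    Every (condition, bio_rep) must carry the reference gene; the offending
    replicate is named otherwise.
    """
    means = average_technical_replicates(table)
    ref = means[means["gene"] == ref_gene].set_index(["condition", "bio_rep"])["mean_ct"]
    if ref.empty:
        raise ValidationError(f"reference gene {ref_gene!r} absent from CT table")
    rows = []
    for _, row in means.iterrows():
        key = (row["condition"], row["bio_rep"])
        if key not in ref.index:
            raise ValidationError(
                f"reference gene {ref_gene!r} missing for condition={key[0]} bio_rep={key[1]}"
            )
        rows.append(
            {
                "gene": row["gene"],
                "condition": row["condition"],
                "bio_rep": row["bio_rep"],
                "rel_abundance": relative_abundance(row["mean_ct"], ref.loc[key]),
            }
        )
    return pd.DataFrame(rows)


def t_test(x, y, paired: bool = False) -> TTestResult:
    """Two-sided Student t-test (paired: on differences; unpaired: pooled variance).

    Degenerate zero-variance cases are kept total: identical paired samples
    give p = 1, a constant nonzero paired shift gives p = 0, both flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValidationError(f"paired test needs equal n (got {len(x)}, {len(y)})")
        if len(x) < 2:
            raise ValidationError("paired test needs n >= 2")
        d = x - y
        df = len(d) - 1
        sd = d.std(ddof=1)
        if sd == 0:
            if np.allclose(d, 0):
                return TTestResult(t=0.0, p=1.0, df=df, flag="degenerate")
            return TTestResult(t=math.inf * np.sign(d.mean()), p=0.0, df=df, flag="degenerate")
        t = d.mean() / (sd / math.sqrt(len(d)))
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValidationError("unpaired test needs n >= 2 per group")
        df = len(x) + len(y) - 2
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
        if sp2 == 0:
            if x.mean() == y.mean():
                return TTestResult(t=0.0, p=1.0, df=df, flag="degenerate")
            return TTestResult(
                t=math.inf * np.sign(x.mean() - y.mean()), p=0.0, df=df, flag="degenerate"
            )
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), p=float(p), df=df)


def group_fold_change(rel_control, rel_test, paired: bool = True) -> GroupFoldChange:
    """Fold change of test vs control relative abundances.

    Paired mode forms per-replicate ratios r_k = test_k / control_k and
    reports mean(r) +/- SEM; the 'fold decrease' convention (used when the
    mean ratio is below 1) is the mean +/- SEM of the per-replicate
    reciprocals control_k / test_k, matching how replicate experiments are
    usually summarised. Unpaired mode uses the ratio of group means with a
    delta-method SEM. The attached t-test compares the abundances directly.
    """
    control = np.asarray(rel_control, dtype=float)
    test = np.asarray(rel_test, dtype=float)
    if (control <= 0).any():
        raise ValidationError("zero or negative control abundance; ratio undefined")
    if (test <= 0).any():
        raise ValidationError("zero or negative test abundance; ratio undefined")
    flag = ""
    if paired:
        if len(control) != len(test):
            raise ValidationError(
                f"paired fold change needs matched replicates (got {len(control)}, {len(test)})"
            )
        r = test / control
        mean_ratio = float(r.mean())
        if len(r) >= 2:
            sem_ratio = float(r.std(ddof=1) / math.sqrt(len(r)))
        else:
            sem_ratio, flag = math.nan, "n<2: no SEM"
        if mean_ratio < 1:
            recip = 1.0 / r
            fold_decrease = float(recip.mean())
            fd_sem = (
                float(recip.std(ddof=1) / math.sqrt(len(recip))) if len(recip) >= 2 else math.nan
            )
        else:
            fold_decrease = fd_sem = None
        ttest = t_test(control, test, paired=True)
    else:
        mc, mt = control.mean(), test.mean()
        mean_ratio = float(mt / mc)
        if len(control) >= 2 and len(test) >= 2:
            sem_c = control.std(ddof=1) / math.sqrt(len(control))
            sem_t = test.std(ddof=1) / math.sqrt(len(test))
            sem_ratio = float(mean_ratio * math.sqrt((sem_c / mc) ** 2 + (sem_t / mt) ** 2))
        else:
            sem_ratio, flag = math.nan, "n<2: no SEM"
        if mean_ratio < 1:
            fold_decrease = float(1.0 / mean_ratio)
            fd_sem = (
                float(fold_decrease * sem_ratio / mean_ratio)
                if not math.isnan(sem_ratio)
                else math.nan
            )
        else:
            fold_decrease = fd_sem = None
        ttest = t_test(control, test, paired=False)
    return GroupFoldChange(
        mean_ratio=mean_ratio,
        sem_ratio=sem_ratio,
        fold_decrease=fold_decrease,
        fold_decrease_sem=fd_sem,
        n_control=len(control),
        n_test=len(test),
        paired=paired,
        test=ttest,
        flag=flag,
    )
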