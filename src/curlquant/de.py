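"""Dual-allele differential-expression consistency pipeline.

Identifies genes whose expression change between curled-down and straight
zebrafish embryos replicates across two independent scospondin mutant
alleles (a null and a hypomorph), beyond allele-family batch effects.

The procedure runs, in order:

1. library-size normalisation to counts per million (CPM);
2. within each (allele, phenotype) condition cell, selection of the most
   mutually consistent replicates (default: best 2 of 3 by mean Spearman
   correlation of log2 CPM);
3. removal of genes below 1 CPM averaged over the straight-control
   replicates;
4. shortlisting by average curled/straight fold change (<= 0.75 down,
   >= 1.45 up);
5. a per-gene general linear model on log2 CPM of *all* original samples,
   with phenotype indicators as regressors of interest and allele-family
   indicators as confounders, testing the curled - straight contrast with
   a t-test;
6. a Benjamini-Hochberg rank cutoff at q = 0.2, applied to the down- and
   up-regulated shortlists separately: genes are sorted by increasing
   p-value and selection stops at the first rank i where
   p_(i) > (i / N) * q.

The two phenotype-indicator plus two allele-indicator columns are rank
deficient (rank 3); estimation uses the Moore-Penrose pseudo-inverse, under
which the curled - straight contrast is estimable and unique.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountExperiment",
    "CpmMatrix",
    "DeConfig",
    "DeReport",
    "DesignMatrix",
    "ReplicateSelection",
    "ValidationError",
    "bh_rank_cutoff",
    "build_design_matrix",
    "compute_cpm",
    "filter_low_expression",
    "fit_consistency_glm",
    "run_de_pipeline",
    "select_reliable_replicates",
    "shortlist_by_fold_change",
]

PHENOTYPES = ("straight", "curled")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountExperiment:
    """A gene x sample integer count matrix bound to its sample sheet.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id;
        nonnegative integers.
    sheet
        DataFrame indexed by sample id with columns ``allele``,
        ``phenotype`` (``straight`` or ``curled``) and ``replicate``.
    """

    counts: pd.DataFrame
    sheet: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts, sheet = self.counts, self.sheet
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in count matrix: {dupes}")
        if sheet.index.duplicated().any():
            dupes = sheet.index[sheet.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in sample sheet: {dupes}")
        missing = {"allele", "phenotype", "replicate"} - set(sheet.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        mat_only = set(counts.columns) - set(sheet.index)
        sheet_only = set(sheet.index) - set(counts.columns)
        if mat_only or sheet_only:
            raise ValidationError(
                "count matrix / sample sheet mismatch: "
                f"only in matrix {sorted(mat_only)}, only in sheet {sorted(sheet_only)}"
            )
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.rint(vals), atol=0):
                bad = np.argwhere(vals != np.rint(vals))[0]
                raise ValidationError(
                    f"non-integer count at gene {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
            self.counts = counts = counts.astype(np.int64)
            vals = counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at gene {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        bad_phen = set(sheet["phenotype"]) - set(PHENOTYPES)
        if bad_phen:
            raise ValidationError(f"unknown phenotype labels: {sorted(bad_phen)}")
        cell_sizes = sheet.groupby(["allele", "phenotype"], observed=True).size()
        thin = cell_sizes[cell_sizes < 2]
        if len(thin):
            raise ValidationError(
                f"each (allele, phenotype) cell needs >= 2 replicates; got {thin.to_dict()}"
            )
        # align sheet row order to the matrix column order
        self.sheet = sheet.loc[counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def alleles(self) -> list[str]:
        return sorted(self.sheet["allele"].unique())


@dataclass
class CpmMatrix:
    """Counts-per-million matrix; each column sums to 1e6."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0).to_numpy(float)
        if not np.allclose(sums, 1e6, rtol=1e-6):
            raise ValidationError("CPM columns must sum to 1e6")


@dataclass
class ReplicateSelection:
    """Replicates kept per (allele, phenotype) condition cell."""

    kept: dict[tuple[str, str], list[str]]
    dropped: list[str]

    @property
    def kept_samples(self) -> list[str]:
        return [s for cell in self.kept.values() for s in cell]


@dataclass
class DesignMatrix:
    """Design matrix with the curled - straight contrast.

    ``rank`` is reported because the indicator encoding (2 phenotype +
    2 allele columns) is rank deficient by construction; the contrast is
    still estimable via a generalized inverse.
    """

    matrix: np.ndarray
    columns: list[str]
    contrast: np.ndarray
    rank: int
    sample_ids: list[str]
    warnings: list[str] = field(default_factory=list)


@dataclass
class DeConfig:
    """Pipeline thresholds; defaults follow the published procedure."""

    min_cpm: float = 1.0
    fc_down: float = 0.75
    fc_up: float = 1.45
    q: float = 0.2
    reliable_k: int = 2
    pseudocount: float = 0.5
    glm_response: str = "log2"  # or "linear" for raw-cpm response
    reliability_metric: str = "spearman"  # or "pca"
    bh_pooling: str = "separate"  # or "pooled"

    def validate(self) -> None:
        if not 0 < self.q <= 1:
            raise ValidationError(f"q must be in (0, 1], got {self.q}")
        if self.fc_down <= 0 or self.fc_up <= self.fc_down:
            raise ValidationError("need 0 < fc_down < fc_up")
        if self.min_cpm < 0:
            raise ValidationError("min_cpm must be >= 0")
        if self.reliable_k < 1:
            raise ValidationError("reliable_k must be >= 1")
        if self.glm_response not in ("log2", "linear"):
            raise ValidationError(f"unknown glm_response {self.glm_response!r}")
        if self.reliability_metric not in ("spearman", "pca"):
            raise ValidationError(f"unknown reliability_metric {self.reliability_metric!r}")
        if self.bh_pooling not in ("separate", "pooled"):
            raise ValidationError(f"unknown bh_pooling {self.bh_pooling!r}")


@dataclass
class DeReport:
    """Ranked result table plus run provenance."""

    table: pd.DataFrame
    dropped_replicates: list[str]
    n_genes_input: int
    n_genes_expressed: int
    n_down_shortlist: int
    n_up_shortlist: int
    config: DeConfig
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def compute_cpm(experiment: CountExperiment) -> CpmMatrix:
    """Normalise each sample to counts per million.

    Raises
    ------
    ValidationError
        If any sample has zero total counts (CPM undefined).
    """
    totals = experiment.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero sample(s), CPM undefined: {zero}")
    cpm = experiment.counts / totals * 1e6
    return CpmMatrix(cpm)


def _spearman_reliability(log_cpm: pd.DataFrame, members: list[str]) -> pd.Series:
    """Mean Spearman correlation of each replicate against its cell mates.

    A constant replicate has no defined rank correlation; it scores -2 so
    it always ranks below any informative replicate.
    """
    m = len(members)
    rho = np.full((m, m), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield NaN rho
        for i in range(m):
            for j in range(i + 1, m):
                r = stats.spearmanr(
                    log_cpm[members[i]], log_cpm[members[j]]
                ).statistic
                rho[i, j] = rho[j, i] = r
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        score = np.nanmean(rho, axis=1)
    return pd.Series(np.nan_to_num(score, nan=-2.0), index=members)


def _pca_reliability(log_cpm: pd.DataFrame, members: list[str]) -> pd.Series:
    """Negative distance to the cell centroid in log2-CPM space (alternative metric)."""
    x = log_cpm[members].to_numpy(float)
    centroid = x.mean(axis=1, keepdims=True)
    dist = np.sqrt(((x - centroid) ** 2).sum(axis=0))
    return pd.Series(-dist, index=members)


def select_reliable_replicates(
    cpm: CpmMatrix,
    sheet: pd.DataFrame,
    k: int = 2,
    metric: str = "spearman",
) -> ReplicateSelection:
    """Keep the ``k`` most mutually consistent replicates per condition cell.

    Within each (allele, phenotype) cell, replicates are ranked by their
    mean Spearman correlation of log2(CPM + 1) against the other replicates
    of the same cell, and the top ``k`` are kept. This automates the
    quality-control step of excluding the least reproducible replicate
    before computing average expression levels. Ties break by sample id
    so the selection is deterministic.
    """
    log_cpm = np.log2(cpm.values + 1.0)
    kept: dict[tuple[str, str], list[str]] = {}
    dropped: list[str] = []
    scorer = _spearman_reliability if metric == "spearman" else _pca_reliability
    for (allele, phen), cell in sheet.groupby(["allele", "phenotype"], observed=True):
        members = sorted(cell.index.tolist())
        if k > len(members):
            raise ValidationError(
                f"k={k} exceeds the {len(members)} replicates of cell ({allele}, {phen})"
            )
        if k == len(members):
            kept[(allele, phen)] = members
            continue
        score = scorer(log_cpm, members)
        # sort: best score first, sample id as deterministic tie-break
        order = sorted(members, key=lambda s: (-score[s], s))
        kept[(allele, phen)] = sorted(order[:k])
        dropped.extend(order[k:])
    return ReplicateSelection(kept=kept, dropped=sorted(dropped))


def filter_low_expression(avg_straight_cpm: pd.Series, threshold: float = 1.0) -> pd.Index:
    """Keep genes at or above ``threshold`` CPM in the straight-control average.

    Genes strictly below the threshold are removed.
    """
    return avg_straight_cpm.index[avg_straight_cpm >= threshold]


def shortlist_by_fold_change(
    avg_straight: pd.Series,
    avg_curled: pd.Series,
    down: float = 0.75,
    up: float = 1.45,
) -> pd.DataFrame:
    """Assign each gene a direction from its curled/straight fold change.

    ``down`` and ``up`` thresholds are inclusive; genes strictly between
    them get direction ``none``. Requires strictly positive straight
    averages (guaranteed upstream by the expression filter).
    """
    if (avg_straight <= 0).any():
        bad = avg_straight.index[avg_straight <= 0].tolist()[:5]
        raise ValidationError(f"nonpositive straight average for genes {bad}")
    fc = avg_curled / avg_straight
    direction = pd.Series("none", index=fc.index, dtype=object)
    direction[fc <= down] = "down"
    direction[fc >= up] = "up"
    return pd.DataFrame(
        {
            "avg_cpm_straight": avg_straight,
            "avg_cpm_curled": avg_curled,
            "fold_change": fc,
            "direction": direction,
        }
    )


def build_design_matrix(sheet: pd.DataFrame, encoding: str = "phenotype") -> DesignMatrix:
    """Indicator design with phenotype regressors and allele-family confounders.

    Default encoding: one column per phenotype (straight, curled) plus one
    column per allele family; contrast is curled - straight. The alternative
    ``per_allele`` encoding replaces the two phenotype columns with one
    curled indicator per allele (contrast: mean of the two per-allele
    curled effects minus zero baseline handled via straight columns).
    """
    phen = sheet["phenotype"]
    alleles = sorted(sheet["allele"].unique())
    warns: list[str] = []
    for level in PHENOTYPES:
        if (phen == level).sum() == 0:
            raise ValidationError(f"sample sheet has no {level!r} samples")
    if len(alleles) < 2:
        warns.append(
            f"single allele family {alleles}: confounder column degenerate, "
            "consistency across alleles cannot be assessed"
        )
    if encoding == "phenotype":
        cols = [f"phen_{p}" for p in PHENOTYPES] + [f"allele_{a}" for a in alleles]
        X = np.zeros((len(sheet), len(cols)))
        for i, p in enumerate(PHENOTYPES):
            X[:, i] = (phen == p).to_numpy(float)
        for j, a in enumerate(alleles):
            X[:, 2 + j] = (sheet["allele"] == a).to_numpy(float)
        contrast = np.zeros(len(cols))
        contrast[0], contrast[1] = -1.0, 1.0  # curled - straight
    elif encoding == "per_allele":
        cols = [f"curled_{a}" for a in alleles] + [f"allele_{a}" for a in alleles]
        X = np.zeros((len(sheet), len(cols)))
        for j, a in enumerate(alleles):
            X[:, j] = ((phen == "curled") & (sheet["allele"] == a)).to_numpy(float)
            X[:, len(alleles) + j] = (sheet["allele"] == a).to_numpy(float)
        contrast = np.zeros(len(cols))
        contrast[: len(alleles)] = 1.0 / len(alleles)
    else:
        raise ValidationError(f"unknown design encoding {encoding!r}")
    for j, name in enumerate(cols):
        if not X[:, j].any():
            warns.append(f"design column {name!r} is all zero (degenerate)")
    rank = int(np.linalg.matrix_rank(X))
    return DesignMatrix(
        matrix=X,
        columns=cols,
        contrast=contrast,
        rank=rank,
        sample_ids=sheet.index.tolist(),
        warnings=warns,
    )


def fit_consistency_glm(
    cpm: pd.DataFrame,
    design: DesignMatrix,
    pseudocount: float = 0.5,
    response: str = "log2",
) -> pd.DataFrame:
    """Per-gene least-squares fit of the design; t-test on the contrast.

    The response is log2(CPM + pseudocount) by default (variance
    stabilising, and making the contrast estimate a log2 fold change); a
    linear-CPM response is available. Coefficients use the Moore-Penrose
    pseudo-inverse so the rank-deficient indicator encoding poses no
    problem; the contrast variance uses c' (X'X)^+ c.

    Degenerate fits are kept total rather than erroring: a gene with zero
    residual variance but a nonzero contrast gets p = 0 and flag
    ``degenerate_fit``; a gene constant across samples gets p = 1 and flag
    ``constant``.

    Returns a DataFrame with columns beta, se, t, p, df, flag.
    """
    X = design.matrix
    c = design.contrast
    n, _ = X.shape
    df = n - design.rank
    if df <= 0:
        raise ValidationError(f"residual df = {df} <= 0: design saturates the samples")
    Y = cpm[design.sample_ids].to_numpy(float)
    if response == "log2":
        Y = np.log2(Y + pseudocount)
    elif response != "linear":
        raise ValidationError(f"unknown GLM response {response!r}")

    pinv_X = np.linalg.pinv(X)
    B = Y @ pinv_X.T  # genes x p coefficients (minimum-norm solution)
    beta = B @ c
    resid = Y - B @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    var_c = float(c @ np.linalg.pinv(X.T @ X) @ c)
    s2 = rss / df
    se = np.sqrt(s2 * var_c)

    scale = np.maximum(np.abs(Y).max(axis=1), 1.0)
    zero_rss = rss <= (1e-12 * scale) ** 2 * n
    constant = zero_rss & (np.abs(beta) <= 1e-10)
    degenerate = zero_rss & ~constant

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 0.0, p)
    p = np.where(constant, 1.0, p)
    inf_t = np.where(beta >= 0, np.inf, -np.inf)
    t = np.where(zero_rss, np.where(degenerate, inf_t, 0.0), t)

    flag = np.where(degenerate, "degenerate_fit", np.where(constant, "constant", ""))
    return pd.DataFrame(
        {"beta": beta, "se": se, "t": t, "p": p, "df": df, "flag": flag},
        index=cpm.index,
    )


def bh_rank_cutoff(pvalues: pd.Series, q: float = 0.2) -> pd.DataFrame:
    """Benjamini-Hochberg rank rule: stop at the first exceedance.

    Sorts p-values ascending (ties broken by gene id for determinism) and
    finds the smallest rank i at which p_(i) strictly exceeds the criterion
    (i / N) * q with N the number tested; ranks before that cutoff are
    selected. If no rank exceeds its criterion, everything is selected.
    This stop-at-first-exceedance reading is conservative relative to the
    classical largest-rank BH rule (it selects a prefix of the same sorted
    list), so its false-discovery rate is bounded by the same q.

    Returns a DataFrame indexed like the sorted input with columns
    p, rank, criterion, selected.
    """
    if len(pvalues) == 0:
        return pd.DataFrame(columns=["p", "rank", "criterion", "selected"])
    pv = pvalues.to_numpy(float)
    if ((pv < 0) | (pv > 1)).any() or np.isnan(pv).any():
        raise ValidationError("p-values must lie in [0, 1]")
    order = sorted(range(len(pvalues)), key=lambda i: (pv[i], str(pvalues.index[i])))
    n = len(order)
    ranks = np.arange(1, n + 1)
    criterion = ranks / n * q
    p_sorted = pv[order]
    exceed = p_sorted > criterion
    cutoff_rank = int(ranks[exceed][0]) if exceed.any() else n + 1
    selected = ranks < cutoff_rank
    return pd.DataFrame(
        {
            "p": p_sorted,
            "rank": ranks,
            "criterion": criterion,
            "selected": selected,
        },
        index=pvalues.index[order],
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_de_pipeline(experiment: CountExperiment, config: DeConfig | None = None) -> DeReport:
    """Run the full consistency procedure on a count experiment.

    Fold changes for the shortlist use the reliable-replicate averages;
    the GLM then goes back to all original replicates of both alleles. The
    BH rank cutoff is applied to the down- and up-regulated lists
    separately. The report table carries per-allele fold changes, their
    mean, the contrast statistics, BH rank/criterion and the selected flag,
    sorted by direction then rank.
    """
    config = config or DeConfig()
    config.validate()
    cpm = compute_cpm(experiment)
    selection = select_reliable_replicates(
        cpm, experiment.sheet, k=config.reliable_k, metric=config.reliability_metric
    )

    sheet = experiment.sheet
    alleles = experiment.alleles

    def _cell_mean(allele: str | None, phen: str) -> pd.Series:
        cells = [
            samples
            for (a, p), samples in selection.kept.items()
            if p == phen and (allele is None or a == allele)
        ]
        cols = [s for cell in cells for s in cell]
        return cpm.values[cols].mean(axis=1)

    avg_straight = _cell_mean(None, "straight")
    avg_curled = _cell_mean(None, "curled")

    expressed = filter_low_expression(avg_straight, config.min_cpm)
    shortlist = shortlist_by_fold_change(
        avg_straight.loc[expressed],
        avg_curled.loc[expressed],
        down=config.fc_down,
        up=config.fc_up,
    )
    candidates = shortlist.index[shortlist["direction"] != "none"]

    design = build_design_matrix(sheet)
    table_parts: list[pd.DataFrame] = []
    if len(candidates):
        glm = fit_consistency_glm(
            cpm.values.loc[candidates],
            design,
            pseudocount=config.pseudocount,
            response=config.glm_response,
        )
        per_allele_fc = {
            a: (_cell_mean(a, "curled") / _cell_mean(a, "straight")).loc[candidates]
            for a in alleles
        }
        if config.bh_pooling == "pooled":
            direction_lists = [("pooled", candidates)]
        else:
            direction_lists = [
                (d, shortlist.index[shortlist["direction"] == d]) for d in ("down", "up")
            ]
        for _, members in direction_lists:
            if len(members) == 0:
                continue
            bh = bh_rank_cutoff(glm.loc[members, "p"], q=config.q)
            part = pd.DataFrame(index=bh.index)
            part["direction"] = shortlist.loc[bh.index, "direction"]
            for a in alleles:
                part[f"fc_{a}"] = per_allele_fc[a].loc[bh.index]
            part["fc_mean"] = np.mean(
                [per_allele_fc[a].loc[bh.index] for a in alleles], axis=0
            )
            part["avg_cpm_straight"] = shortlist.loc[bh.index, "avg_cpm_straight"]
            part["avg_cpm_curled"] = shortlist.loc[bh.index, "avg_cpm_curled"]
            for col in ("beta", "se", "t", "p", "flag"):
                part[col] = glm.loc[bh.index, col]
            part["rank"] = bh["rank"]
            part["criterion"] = bh["criterion"]
            part["selected"] = bh["selected"]
            table_parts.append(part)

    if table_parts:
        table = pd.concat(table_parts)
        table.index.name = "gene"
    else:
        cols = (
            ["direction"]
            + [f"fc_{a}" for a in alleles]
            + [
                "fc_mean",
                "avg_cpm_straight",
                "avg_cpm_curled",
                "beta",
                "se",
                "t",
                "p",
                "flag",
                "rank",
                "criterion",
                "selected",
            ]
        )
        table = pd.DataFrame(columns=cols)
        table.index.name = "gene"

    warns = list(design.warnings)
    if selection.dropped:
        warns.append(f"dropped replicates: {selection.dropped}")
    n_down = int((shortlist["direction"] == "down").sum()) if len(shortlist) else 0
    n_up = int((shortlist["direction"] == "up").sum()) if len(shortlist) else 0
    return DeReport(
        table=table,
        dropped_replicates=selection.dropped,
        n_genes_input=len(experiment.genes),
        n_genes_expressed=len(expressed),
        n_down_shortlist=n_down,
        n_up_shortlist=n_up,
        config=config,
        warnings=warns,
    )
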