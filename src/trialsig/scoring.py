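"""Single-sample signature scoring and clinical association statistics.

Two scoring schemes are provided.  The rank-based score ranks all measured
genes within each sample (ascending, average ties), takes the mean rank of
the signature genes divided by the number of genes, rescales by the
theoretical minimum (n_up+1)/(2N) and maximum (2N-n_up+1)/(2N) of that
quantity, and centers at zero, so scores live in [-0.5, 0.5] and are
invariant to any strictly monotone transform of a sample's expression.  The
z-mean score z-scores each signature gene across samples (sample SD, ddof=1)
and averages, for use on variance-stabilized external cohorts.

Associations cover the statistics a phase-II translational analysis needs:
rank-sum AUC for benefit classification, Wilcoxon tests, Spearman correlation
with progression-free survival, and Kaplan-Meier / log-rank / proportional-
hazards comparison of score-defined groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

__all__ = [
    "AssociationResult",
    "singscore_up",
    "zscore_mean_score",
    "auc_benefit",
    "rank_tests",
    "spearman_pfs",
    "km_logrank_hr",
    "label_benefit",
    "median_split",
]

CB_THRESHOLD_MONTHS = 4.0
EXCEPTIONAL_THRESHOLD_MONTHS = 12.0


@dataclass(frozen=True)
class AssociationResult:
    """A named test statistic with p-value and optional confidence bounds."""

    statistic_name: str
    statistic: float
    p_value: float
    ci_low: float | None = None
    ci_high: float | None = None
    extra: dict | None = None


def singscore_up(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Rank-based single-sample score for an up-oriented gene set.

    Returns one score in [-0.5, 0.5] per sample (column of ``expr``).
    """
    present = sorted(gene_set.members & set(expr.index.astype(str)))
    missing = sorted(gene_set.members - set(expr.index.astype(str)))
    if len(present) < 2:
        raise ValueError(
            f"gene set {gene_set.name!r}: fewer than 2 members measured; missing {missing}"
        )
    n_total = expr.shape[0]
    n_up = len(present)
    ranks = expr.rank(axis=0, method="average")  # ascending within each sample
    raw = ranks.loc[present].mean(axis=0) / n_total
    low = (n_up + 1.0) / (2.0 * n_total)
    high = (2.0 * n_total - n_up + 1.0) / (2.0 * n_total)
    score = (raw - low) / (high - low) - 0.5
    score.name = gene_set.name
    return score


def zscore_mean_score(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Mean across signature genes of per-gene z-scores taken across samples."""
    if expr.shape[1] < 2:
        raise ValueError("z-scoring across samples needs >= 2 samples")
    present = sorted(gene_set.members & set(expr.index.astype(str)))
    if not present:
        raise ValueError(f"no members of {gene_set.name!r} measured")
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        if len(constant) == len(present):
            raise ValueError(
                f"all measured members of {gene_set.name!r} are constant across samples"
            )
        warnings.warn(
            f"excluding constant gene(s) from {gene_set.name!r}: {constant}",
            stacklevel=2,
        )
        sub = sub.drop(index=constant)
        sd = sd.drop(index=constant)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    score = z.mean(axis=0)
    score.name = gene_set.name
    return score


def auc_benefit(scores, labels, flip: bool = False) -> AssociationResult:
    """AUC of a score for a binary label via the rank-sum identity.

    ``flip`` reports 1 - AUC, the orientation used when a resistance score is
    evaluated as a predictor of non-benefit.  The p-value is the two-sided
    normal-approximation rank-sum test with tie correction.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two label classes, got {classes.tolist()}")
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = res.statistic / (len(pos) * len(neg))
    if flip:
        auc = 1.0 - auc
    return AssociationResult(
        statistic_name="auc",
        statistic=float(auc),
        p_value=float(res.pvalue),
        extra={"positive_class": str(classes[1]), "flipped": flip},
    )


def rank_tests(x, y, paired: bool = False) -> AssociationResult:
    """Two-sided Wilcoxon test: rank-sum for unpaired samples, signed-rank for pairs.

    Exact p-values are used for small tie-free samples (both n <= 25),
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if len(x) != len(y):
            raise ValueError(f"paired samples differ in length: {len(x)} vs {len(y)}")
        if len(x) < 3:
            raise ValueError("need >= 3 pairs")
        d = x - y
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1 by convention", stacklevel=2)
            return AssociationResult("wilcoxon_signed_rank", 0.0, 1.0)
        res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
        return AssociationResult("wilcoxon_signed_rank", float(res.statistic), float(res.pvalue))
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >= 3 observations per group")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return AssociationResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue))


def spearman_pfs(scores, pfs) -> AssociationResult:
    """Spearman rank correlation of a score with progression-free survival.

    Observed (possibly censored) times are used as-is; the p-value comes from
    the t approximation on midranks.
    """
    scores = np.asarray(scores, float)
    pfs = np.asarray(pfs, float)
    if len(scores) != len(pfs):
        raise ValueError("scores and pfs must align")
    if len(scores) < 4:
        raise ValueError("need n >= 4")
    if np.ptp(scores) == 0 or np.ptp(pfs) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(scores, pfs)
    return AssociationResult("spearman_rho", float(rho), float(p))


def km_logrank_hr(records: pd.DataFrame, group, reference: str | None = None) -> AssociationResult:
    """Kaplan-Meier comparison of two groups with log-rank test and hazard ratio.

    ``records`` needs ``pfs_months`` and ``event`` columns; ``group`` is a
    binary label per row.  The hazard ratio (non-reference level vs
    ``reference``, which defaults to the first sorted level) and its 95% CI
    come from a single-covariate proportional-hazards fit with Efron tie
    handling; curves and median survival per group are returned in ``extra``.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test

    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference {reference!r} is not a group level in {levels}")
        levels = [reference, next(l for l in levels if l != reference)]
    t = records["pfs_months"].to_numpy(float)
    e = records["event"].to_numpy(int)
    if e.sum() == 0:
        raise ValueError("no events in either group; survival comparison undefined")

    curves: dict[str, dict] = {}
    for lev in levels:
        m = group == lev
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=str(lev))
        sf = kmf.survival_function_
        curves[str(lev)] = {
            "time": [float(v) for v in sf.index],
            "survival": [float(v) for v in sf.iloc[:, 0]],
            "median": float(kmf.median_survival_time_),
        }

    m1 = group == levels[1]
    lr = logrank_test(t[~m1], t[m1], event_observed_A=e[~m1], event_observed_B=e[m1])

    df = pd.DataFrame({"pfs_months": t, "event": e, "x": (group == levels[1]).astype(float)})
    if df.loc[df.x == 0, "event"].sum() == 0 or df.loc[df.x == 1, "event"].sum() == 0:
        raise ValueError("each group needs >= 1 event for a hazard ratio")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df,
            duration_col="pfs_months",
            event_col="event",
            fit_options={"precision": 1e-9},
        )
    with np.errstate(over="ignore"):
        hr = float(np.exp(cph.params_["x"]))
        ci = cph.confidence_intervals_
        ci_lo, ci_hi = float(np.exp(ci.loc["x"].iloc[0])), float(np.exp(ci.loc["x"].iloc[1]))
    return AssociationResult(
        statistic_name="hazard_ratio",
        statistic=hr,
        p_value=float(lr.p_value),
        ci_low=ci_lo,
        ci_high=ci_hi,
        extra={
            "logrank_chisq": float(lr.test_statistic),
            "hr_reference": str(levels[0]),
            "curves": curves,
        },
    )


def label_benefit(records: pd.DataFrame) -> pd.DataFrame:
    """Derive clinical-benefit and exceptional-responder labels.

    Clinical benefit (CB) is a partial/complete response, or stable disease
    lasting at least 4 months; no clinical benefit (NCB) is progressive
    disease or stable disease under 4 months.  Exceptional responders have
    PFS of at least 12 months.  Response dominates: a responder is CB
    regardless of PFS.
    """
    valid = {"CR", "PR", "SD", "PD"}
    resp = records["response"].astype(str)
    unknown = sorted(set(resp) - valid)
    if unknown:
        raise ValueError(f"unknown response code(s): {unknown}; expected one of {sorted(valid)}")
    if (records["pfs_months"] < 0).any():
        raise ValueError("pfs_months must be >= 0")
    out = records.copy()
    is_resp = resp.isin({"CR", "PR"})
    cb = is_resp | ((resp == "SD") & (records["pfs_months"] >= CB_THRESHOLD_MONTHS))
    out["benefit"] = np.where(cb, "CB", "NCB")
    out["exceptional"] = records["pfs_months"] >= EXCEPTIONAL_THRESHOLD_MONTHS
    return out


def median_split(scores: pd.Series, labels: tuple[str, str] = ("low", "high")) -> pd.Series:
    """Dichotomize scores at the median: strictly above -> second label."""
    med = scores.median()
    return pd.Series(
        np.where(scores > med, labels[1], labels[0]), index=scores.index, name="score_group"
    )
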