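"""Differential tests and calling rules.

The workhorse is a weighted t-type test on count proportions: each
replicate's proportion x_i/n_i carries binomial sampling variance plus a
shared between-replicate variance component estimated by method of moments
(clamped at zero), and the group estimate is the variance-minimizing weighted
mean, iterated to convergence.  Differential genes use the fold-change +
p-value rule (default: fold change > 3 and p < 0.05); translational
regulation requires both a >= 2-fold significant TE increase (Student t) and
a significant ribosome-profiling increase (weighted t-type test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantify import CountTable


@dataclass
class DiffResult:
    """Per-gene differential outcome."""

    gene_id: str
    fold_change: float
    log2_fc: float
    statistic: float
    df: float
    p_value: float
    p_adjusted: float | None
    call: str  # "up" | "down" | "none"


@dataclass
class GlobalShiftResult:
    """Summary of a genome-wide fold-change distribution shift."""

    mean_fc: float
    null_mean_fc: float
    fc_histogram: pd.DataFrame  # columns: bin_left, bin_right, case, null
    ks_D: float
    ks_p: float
    n_genes: int


def _group_estimate(
    counts: np.ndarray,
    totals: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[float, float]:
    """Weighted proportion estimate and its squared standard error.

    Replicate proportions p_i = x_i/n_i are combined with weights
    1/(p(1-p)/n_i + tau^2) where tau^2, the between-replicate variance, is a
    method-of-moments estimate clamped at zero; the weight/estimate updates
    are iterated to convergence.
    """
    x = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    k = x.size
    p = x / n
    phat = x.sum() / n.sum()
    tau2 = 0.0
    floor = 0.5 / n.sum()  # keeps binomial variance positive at phat in {0, 1}
    for _ in range(max_iter):
        ps = min(max(phat, floor), 1.0 - floor)
        v = ps * (1.0 - ps) / n
        wf = 1.0 / v
        p_fixed = (wf * p).sum() / wf.sum()
        q = (wf * (p - p_fixed) ** 2).sum()
        c = wf.sum() - (wf**2).sum() / wf.sum()
        tau2_new = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
        w = 1.0 / (v + tau2_new)
        phat_new = (w * p).sum() / w.sum()
        if abs(phat_new - phat) < tol and abs(tau2_new - tau2) < tol:
            phat, tau2 = phat_new, tau2_new
            break
        phat, tau2 = phat_new, tau2_new
    ps = min(max(phat, floor), 1.0 - floor)
    v = ps * (1.0 - ps) / n
    se2 = 1.0 / (1.0 / (v + tau2)).sum()
    return float(phat), float(se2)


def weighted_t_test(
    counts_a, totals_a, counts_b, totals_b
) -> tuple[float, float, float]:
    """Weighted t-type test for a difference in count proportions.

    Returns (statistic, df, p_value): the statistic is the difference of the
    two group proportion estimates over the root of their summed squared
    standard errors, degrees of freedom follow Welch-Satterthwaite, and the
    p-value is two-sided from the t distribution.
    """
    xa, na = np.asarray(counts_a, float), np.asarray(totals_a, float)
    xb, nb = np.asarray(counts_b, float), np.asarray(totals_b, float)
    for x, n, label in ((xa, na, "a"), (xb, nb, "b")):
        if x.size < 2:
            raise ValueError(f"group {label}: need >= 2 replicates")
        if x.size != n.size:
            raise ValueError(f"group {label}: counts/totals length mismatch")
        if np.any(n <= 0):
            raise ValueError(f"group {label}: totals must be > 0")
        if np.any((x < 0) | (x > n)):
            raise ValueError(f"group {label}: counts must lie in [0, totals]")
    ka, kb = xa.size, xb.size
    if xa.sum() == 0 and xb.sum() == 0:
        return 0.0, float(ka + kb - 2), 1.0
    pa, sa = _group_estimate(xa, na)
    pb, sb = _group_estimate(xb, nb)
    denom = np.sqrt(sa + sb)
    if denom == 0 or pa == pb:
        return 0.0, float(ka + kb - 2), 1.0
    statistic = (pa - pb) / denom
    df = (sa + sb) ** 2 / (sa**2 / (ka - 1) + sb**2 / (kb - 1))
    p_value = float(2.0 * sps.t.sf(abs(statistic), df))
    return float(statistic), float(df), p_value


def te_student_test(te_reps_a, te_reps_b, log_scale: bool = True) -> float:
    """Two-sided two-sample Student t on per-replicate TE values.

    Runs on log2 TE by default (variance stabilization for ratio data); pass
    ``log_scale=False`` for the raw scale.  Zero variance in both groups with
    equal means gives p = 1.
    """
    a = np.asarray(te_reps_a, dtype=float)
    b = np.asarray(te_reps_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if log_scale:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log-scale TE test requires TE > 0; prefilter genes")
        a, b = np.log2(a), np.log2(b)
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    result = sps.ttest_ind(a, b, equal_var=True)
    return float(result.pvalue)


def call_translational_regulation(
    te_fc: float,
    te_p: float,
    ribo_p: float,
    te_fold_min: float = 2.0,
    alpha: float = 0.05,
    ribo_fc: float | None = None,
) -> bool:
    """Two-criteria translational up-regulation call.

    True iff the TE increased by at least ``te_fold_min`` with p < alpha
    (Student t on replicate TEs) AND the ribosome-profiling expression change
    is significant (p < alpha, weighted t-type test) in the increasing
    direction.  ``ribo_fc`` supplies the direction of the expression change
    when available; left as None only the two p-values and the TE fold gate.
    """
    for value in (te_fc, te_p, ribo_p):
        if not np.isfinite(value):
            return False
    if te_fc < te_fold_min or te_p >= alpha or ribo_p >= alpha:
        return False
    if ribo_fc is not None and ribo_fc <= 1.0:
        return False
    return True


def call_differential(
    fold_change: float,
    p_value: float,
    fold_min: float = 3.0,
    alpha: float = 0.05,
) -> str:
    """Threshold rule: up/down iff fold change beyond ``fold_min`` and p < alpha."""
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    if p_value < alpha:
        if fold_change > fold_min:
            return "up"
        if fold_change < 1.0 / fold_min:
            return "down"
    return "none"


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """qPCR relative quantification by the 2^-ddCt method."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def _paired_ratios(case: pd.DataFrame, ctrl: pd.DataFrame) -> np.ndarray:
    """Pooled per-gene fold changes from replicate columns paired by index."""
    shared = case.index.intersection(ctrl.index)
    if not len(shared):
        raise ValueError("no shared genes between case and control")
    n_pairs = min(case.shape[1], ctrl.shape[1])
    ratios = []
    for i in range(n_pairs):
        c = case.loc[shared].iloc[:, i].to_numpy(dtype=float)
        r = ctrl.loc[shared].iloc[:, i].to_numpy(dtype=float)
        ok = (r > 0) & (c > 0) & np.isfinite(c) & np.isfinite(r)
        ratios.append(c[ok] / r[ok])
    return np.concatenate(ratios)


def replicate_split_null(expr_ctrl: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Control-vs-control split for the null fold-change distribution.

    Pairs each control replicate with the next one (cyclically), so the null
    ratios have the same single-replicate marginal structure as a
    case-vs-control comparison under no effect.
    """
    if expr_ctrl.shape[1] < 2:
        raise ValueError("need >= 2 control replicates for a null split")
    rotated = expr_ctrl.iloc[:, list(range(1, expr_ctrl.shape[1])) + [0]]
    return expr_ctrl, rotated


def global_shift(
    expr_case: pd.DataFrame,
    expr_ctrl: pd.DataFrame,
    null_case: pd.DataFrame,
    null_ctrl: pd.DataFrame,
    bins: int = 40,
    mean_type: str = "arithmetic",
) -> GlobalShiftResult:
    """Genome-wide fold-change distribution versus a control-split null.

    Per-gene fold changes are the pooled index-paired replicate ratios
    case/control; the same construction on the null pair (typically the
    control against its own rotated replicates, see
    :func:`replicate_split_null`) gives the intrinsic-variability
    distribution.  The two log2 fold-change distributions are compared with a
    two-sample Kolmogorov-Smirnov test.  ``mean_fc`` is the arithmetic mean
    of the per-gene ratios (a geometric option is provided and labeled).
    """
    def _frame(x) -> pd.DataFrame:
        if isinstance(x, pd.Series):
            return x.to_frame()
        return pd.DataFrame(x)

    fc = _paired_ratios(_frame(expr_case), _frame(expr_ctrl))
    null_fc = _paired_ratios(_frame(null_case), _frame(null_ctrl))
    if fc.size == 0 or null_fc.size == 0:
        raise ValueError("no usable fold changes (zero or missing expression)")
    if mean_type == "arithmetic":
        mean_fc, null_mean = float(fc.mean()), float(null_fc.mean())
    elif mean_type == "geometric":
        mean_fc = float(np.exp(np.log(fc).mean()))
        null_mean = float(np.exp(np.log(null_fc).mean()))
    else:
        raise ValueError("mean_type must be 'arithmetic' or 'geometric'")
    log2_fc, log2_null = np.log2(fc), np.log2(null_fc)
    if np.all(log2_fc == log2_fc[0]) and np.all(log2_null == log2_fc[0]):
        ks_d, ks_p = 0.0, 1.0  # degenerate identical distributions
    else:
        ks = sps.ks_2samp(log2_fc, log2_null)
        ks_d, ks_p = float(ks.statistic), float(ks.pvalue)
    lo = min(log2_fc.min(), log2_null.min())
    hi = max(log2_fc.max(), log2_null.max())
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, bins + 1)
    case_hist, _ = np.histogram(log2_fc, bins=edges)
    null_hist, _ = np.histogram(log2_null, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:],
         "case": case_hist, "null": null_hist}
    )
    n_genes = len(_frame(expr_case).index.intersection(_frame(expr_ctrl).index))
    return GlobalShiftResult(
        mean_fc=mean_fc, null_mean_fc=null_mean, fc_histogram=hist,
        ks_D=ks_d, ks_p=ks_p, n_genes=n_genes,
    )


def differential_table(
    case: CountTable,
    control: CountTable,
    assay: str,
    genes=None,
    fold_min: float = 3.0,
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-gene weighted t-type test between two genotypes for one assay.

    Fold change is the ratio of the two weighted proportion estimates
    (depth-normalized expression ratio).  ``adjust='bh'`` adds
    Benjamini-Hochberg adjusted p-values; calls use raw p-values by default,
    adjusted ones when adjustment is requested.
    """
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    sub_case = case.counts[assay]
    sub_ctrl = control.counts[assay]
    tot_case = case.total_mapped[assay].reindex(sub_case.columns).to_numpy(float)
    tot_ctrl = control.total_mapped[assay].reindex(sub_ctrl.columns).to_numpy(float)
    index = (
        sub_case.index.intersection(sub_ctrl.index)
        if genes is None
        else pd.Index(sorted(genes))
    )
    rows = []
    for gene in index:
        xa = sub_case.loc[gene].to_numpy(float)
        xb = sub_ctrl.loc[gene].to_numpy(float)
        statistic, df, p = weighted_t_test(xa, tot_case, xb, tot_ctrl)
        pa, _ = _group_estimate(xa, tot_case)
        pb, _ = _group_estimate(xb, tot_ctrl)
        fc = pa / pb if pb > 0 else np.inf
        rows.append((gene, fc, statistic, df, p))
    frame = pd.DataFrame(
        rows, columns=["gene_id", "fold_change", "statistic", "df", "p_value"]
    ).set_index("gene_id")
    with np.errstate(divide="ignore"):
        frame.insert(1, "log2_fc", np.log2(frame["fold_change"]))
    if adjust == "bh":
        frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy())
        p_for_call = frame["p_adjusted"]
    else:
        frame["p_adjusted"] = np.nan
        p_for_call = frame["p_value"]
    frame["call"] = [
        call_differential(fc, p, fold_min=fold_min, alpha=alpha)
        if np.isfinite(fc) and fc > 0
        else "none"
        for fc, p in zip(frame["fold_change"], p_for_call)
    ]
    return frame


def translational_regulation_table(
    te_case_reps: pd.DataFrame,
    te_ctrl_reps: pd.DataFrame,
    ribo_diff: pd.DataFrame,
    te_fold_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-criteria translational-regulation calls per gene.

    ``te_*_reps`` are gene x replicate TE tables; ``ribo_diff`` is the
    footprint-assay output of :func:`differential_table` supplying the
    expression-change p-value and direction.
    """
    shared = te_case_reps.index.intersection(te_ctrl_reps.index).intersection(
        ribo_diff.index
    )
    rows = []
    for gene in shared:
        a = te_case_reps.loc[gene].to_numpy(float)
        b = te_ctrl_reps.loc[gene].to_numpy(float)
        if np.any(a <= 0) or np.any(b <= 0):
            continue
        te_fc = float(a.mean() / b.mean())
        te_p = te_student_test(a, b)
        ribo_p = float(ribo_diff.loc[gene, "p_value"])
        ribo_fc = float(ribo_diff.loc[gene, "fold_change"])
        flag = call_translational_regulation(
            te_fc, te_p, ribo_p, te_fold_min=te_fold_min, alpha=alpha, ribo_fc=ribo_fc
        )
        rows.append((gene, te_fc, te_p, ribo_fc, ribo_p, flag))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "te_fc", "te_p", "ribo_fc", "ribo_p",
                 "translational_regulation"],
    ).set_index("gene_id")


def simulate_null_proportions(
    n_genes: int = 2000,
    n_replicates: int = 3,
    depth: int = 200_000,
    mean_proportion: float = 5e-3,
    dispersion: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Beta-binomial null counts with equal group proportions, for calibration.

    ``dispersion`` is the squared biological coefficient of variation of the
    replicate proportions (the negative-binomial alpha used throughout the
    package): the per-replicate proportion is Beta-distributed with mean
    ``mean_proportion`` and variance dispersion x mean^2.  The default mean
    proportion corresponds to a well-expressed gene (~depth x proportion
    counts per replicate), the regime in which the between-replicate variance
    component is identifiable.
    """
    rng = np.random.default_rng(seed)
    p0 = mean_proportion
    var = dispersion * p0**2
    if var <= 0:
        p_draws = np.full((n_genes, 2 * n_replicates), p0)
    else:
        ab = p0 * (1 - p0) / var - 1
        if ab <= 0:
            raise ValueError("dispersion too large for a Beta proportion model")
        p_draws = rng.beta(p0 * ab, (1 - p0) * ab, size=(n_genes, 2 * n_replicates))
    counts = rng.binomial(depth, p_draws)
    cols = [f"a{i}" for i in range(n_replicates)] + [
        f"b{i}" for i in range(n_replicates)
    ]
    frame = pd.DataFrame(counts, columns=cols)
    frame.attrs["depth"] = depth
    return frame


def null_calibration(
    n_genes: int = 2000,
    n_replicates: int = 3,
    depth: int = 200_000,
    dispersion: float = 0.01,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of null genes with p < alpha under the weighted t-type test."""
    frame = simulate_null_proportions(
        n_genes=n_genes, n_replicates=n_replicates, depth=depth,
        dispersion=dispersion, seed=seed,
    )
    totals = np.full(n_replicates, depth)
    a_cols = [c for c in frame.columns if c.startswith("a")]
    b_cols = [c for c in frame.columns if c.startswith("b")]
    hits = 0
    for _, row in frame.iterrows():
        _, _, p = weighted_t_test(
            row[a_cols].to_numpy(), totals, row[b_cols].to_numpy(), totals
        )
        hits += p < alpha
    return hits / len(frame)
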