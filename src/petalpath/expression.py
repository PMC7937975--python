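"""Candidate-panel differential expression screening on raw count matrices.

The screen follows the classic count-based workflow for a two-group
(blue vs orange phenotype) comparison:

1. between-sample normalization by the trimmed mean of M-values (TMM),
2. a conditional negative-binomial exact test per gene with a common
   method-of-moments dispersion,
3. Benjamini–Hochberg FDR adjustment, and
4. thresholding at FDR < 1e-5 and |log2 fold-change| > 1.

The exact test is a documented stand-in reproducing the behaviour of the
conditional exact tests used for small-replicate RNA-seq designs: given the
two group sums conditional on their total, the null distribution is the
ratio of negative-binomial pmfs, which reduces to a binomial when the
dispersion is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

__all__ = [
    "DegThresholds",
    "ExpressionMatrix",
    "tmm_factors",
    "normalize_expression",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_degs",
    "fold_ratio",
    "format_fold_ratio",
    "wilcoxon_rank_sum",
    "pathway_summary",
    "scale_for_heatmap",
]


@dataclass(frozen=True)
class DegThresholds:
    """Significance thresholds for calling a differentially expressed gene."""

    fdr_max: float = 1e-5
    log2fc_min: float = 1.0

    def __post_init__(self):
        if not (0 < self.fdr_max < 1):
            raise ValueError("fdr_max must be in (0,1)")
        if self.log2fc_min < 0:
            raise ValueError("log2fc_min must be >= 0")


@dataclass(frozen=True)
class ExpressionMatrix:
    """TMM-normalized expression values (genes x samples) plus the factors."""

    values: pd.DataFrame
    norm_factors: pd.Series


def _as_count_frame(counts) -> pd.DataFrame:
    df = pd.DataFrame(counts)
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("count matrix contains negative values")
    return df


def tmm_factors(counts, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Per-sample trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the median of those fractions across samples.  For every
    other sample, genes with a zero in either library are dropped, the top
    and bottom ``trim_m`` of genes by M-value (log2 expression ratio) and
    ``trim_a`` by A-value (mean log2 abundance) are trimmed, and the factor
    is 2 to the precision-weighted mean of the surviving M-values.  Factors
    are rescaled to geometric mean 1.
    """
    df = _as_count_frame(counts)
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("TMM normalization needs at least 2 samples")
    lib = arr.sum(axis=0)
    for j, total in enumerate(lib):
        if total == 0:
            raise ValueError(f"sample {df.columns[j]!r} has all-zero counts")

    # upper-quartile count fraction; reference = closest to the median
    q75 = np.percentile(arr, 75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(q75 - np.median(q75))))
    ref = arr[:, ref_idx]
    nref = lib[ref_idx]

    log_factors = np.zeros(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref_idx:
            continue
        obs = arr[:, j]
        nobs = lib[j]
        # also drop the degenerate one-gene-is-the-whole-library case (v = 0)
        keep = (obs > 0) & (ref > 0) & ((obs < nobs) | (ref < nref))
        o, r = obs[keep], ref[keep]
        m = np.log2((o / nobs) / (r / nref))
        a = 0.5 * (np.log2(o / nobs) + np.log2(r / nref))
        # asymptotic (delta-method) variance of M for precision weighting
        v = (nobs - o) / (nobs * o) + (nref - r) / (nref * r)

        n = m.size
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if m.size == 0 or not kept.any():
            log_factors[j] = 0.0
            continue
        f = np.sum(m[kept] / v[kept]) / np.sum(1.0 / v[kept])
        log_factors[j] = 0.0 if abs(f) < 1e-6 else f

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="norm_factor")


def normalize_expression(counts, factors, lengths=None) -> ExpressionMatrix:
    """Counts-per-million on TMM-effective library sizes.

    value(g,s) = count(g,s) / (library_size(s) * factor(s)) * 1e6, further
    divided by the gene's effective length in kb when lengths are given.
    """
    df = _as_count_frame(counts)
    factors = pd.Series(factors)
    if not df.columns.equals(factors.index):
        factors = factors.reindex(df.columns)
        if factors.isna().any():
            raise ValueError("normalization factors do not cover all samples")
    lib = df.sum(axis=0)
    values = df / (lib * factors) * 1e6
    if lengths is not None:
        lengths_kb = pd.Series(lengths).reindex(df.index) / 1e3
        values = values.div(lengths_kb, axis=0)
    return ExpressionMatrix(values=values, norm_factors=factors)


def equalized_counts(counts, factors) -> pd.DataFrame:
    """Counts rescaled to a common effective library size (pseudo-counts)."""
    df = _as_count_frame(counts)
    lib = df.sum(axis=0) * pd.Series(factors).reindex(df.columns)
    common = np.exp(np.mean(np.log(lib)))
    return df / lib * common


def estimate_common_dispersion(counts, groups) -> float:
    """Method-of-moments common negative-binomial dispersion.

    Per gene and phenotype group, phi_g = (s^2 - m) / m^2 on library-
    equalized counts; group values are averaged per gene and the estimate
    is the median over genes of max(0, phi_g).  Returns 0 (with a
    warning-style fallback) when no gene is informative.
    """
    df = _as_count_frame(counts)
    groups = pd.Series(groups).reindex(df.columns)
    factors = tmm_factors(df)
    eq = equalized_counts(df, factors)
    labels = groups.unique()
    stats = np.full((df.shape[0], len(labels)), np.nan)
    for k, lab in enumerate(labels):
        sub = eq.loc[:, groups[groups == lab].index].to_numpy()
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            stats[:, k] = np.where(m > 0, (s2 - m) / m**2, np.nan)
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        per_gene = np.nanmean(stats, axis=1)
    per_gene = per_gene[~np.isnan(per_gene)]
    if per_gene.size == 0:
        return 0.0
    return float(max(0.0, np.median(np.maximum(per_gene, 0.0))))


def _conditional_log_pmf(s: int, n_a: float, n_b: float, phi: float) -> np.ndarray:
    """Log pmf of the group-A sum conditional on total s under the null."""
    k = np.arange(s + 1)
    if phi == 0:
        p = n_a / (n_a + n_b)
        logw = (gammaln(s + 1) - gammaln(k + 1) - gammaln(s - k + 1)
                + k * math.log(p) + (s - k) * math.log1p(-p))
    else:
        r1 = n_a / phi
        r2 = n_b / phi
        logw = (gammaln(k + r1) - gammaln(k + 1)
                + gammaln(s - k + r2) - gammaln(s - k + 1))
    return logw - logsumexp(logw)


def nb_exact_test(count_sum_a, count_sum_b, n_a, n_b, phi) -> float:
    """Two-sided conditional exact test on two group sums.

    Conditional on the total s = a + b, the p-value sums P(X = k | s) over
    every outcome k no more probable than the observed one.  X follows the
    negative-binomial conditional distribution (binomial with proportion
    n_a/(n_a+n_b) when phi = 0).
    """
    if phi < 0:
        raise ValueError("dispersion phi must be >= 0")
    a = int(round(count_sum_a))
    b = int(round(count_sum_b))
    if a < 0 or b < 0:
        raise ValueError("count sums must be non-negative")
    s = a + b
    if s == 0:
        return 1.0
    logp = _conditional_log_pmf(s, float(n_a), float(n_b), float(phi))
    obs = logp[a]
    # tolerance guards against ties broken by rounding error
    qualify = logp <= obs + 1e-10
    if qualify.all():
        return 1.0
    return float(min(1.0, math.exp(logsumexp(logp[qualify]))))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_degs(counts, sample_sheet, panel=None, thresholds: DegThresholds | None = None,
              pseudocount: float = 0.125, dispersion: float | None = None) -> pd.DataFrame:
    """Run the full screen and return one row per gene, sorted by log2FC.

    log2fc = log2((mean_blue + c)/(mean_orange + c)) on TMM-normalized
    expression with pseudo-count ``c``; positive values mean higher
    expression in blue.  ``is_deg`` applies the FDR and fold-change
    thresholds jointly.
    """
    thresholds = thresholds or DegThresholds()
    df = _as_count_frame(counts)
    sheet = sample_sheet.set_index("sample_id")["phenotype"] if isinstance(
        sample_sheet, pd.DataFrame) else pd.Series(sample_sheet)
    sheet = sheet.reindex(df.columns)
    if sheet.isna().any():
        raise ValueError("sample sheet does not cover all count columns")
    blue = sheet[sheet == "blue"].index
    orange = sheet[sheet == "orange"].index
    if len(blue) == 0 or len(orange) == 0:
        raise ValueError("each phenotype group needs at least one sample")

    factors = tmm_factors(df)
    expr = normalize_expression(df, factors)
    if dispersion is None:
        dispersion = estimate_common_dispersion(df, sheet)
    eq = equalized_counts(df, factors)
    sum_blue = eq[blue].sum(axis=1).round().astype(int)
    sum_orange = eq[orange].sum(axis=1).round().astype(int)

    pvals = np.array([
        nb_exact_test(a, b, len(blue), len(orange), dispersion)
        for a, b in zip(sum_blue, sum_orange)
    ])
    fdr = bh_adjust(pvals)

    mean_blue = expr.values[blue].mean(axis=1)
    mean_orange = expr.values[orange].mean(axis=1)
    log2fc = np.log2((mean_blue + pseudocount) / (mean_orange + pseudocount))
    is_deg = (fdr < thresholds.fdr_max) & (np.abs(log2fc) > thresholds.log2fc_min)
    direction = np.where(log2fc > 0, "B>O", "O>B")

    out = pd.DataFrame({
        "gene_id": df.index,
        "mean_tmm_blue": mean_blue.to_numpy(),
        "mean_tmm_orange": mean_orange.to_numpy(),
        "log2fc": log2fc.to_numpy(),
        "p_value": pvals,
        "fdr": fdr,
        "is_deg": is_deg,
        "direction": direction,
    })
    if panel is not None:
        out["category"] = out["gene_id"].map(panel).fillna("unassigned")
    else:
        out["category"] = "unassigned"
    return out.sort_values("log2fc", kind="mergesort").reset_index(drop=True)


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def fold_ratio(mean_high: float, mean_low: float) -> float:
    """Reported fold ratio between two group means.

    Rounded half-away-from-zero: one decimal below 10, nearest integer at
    10 and above.  A zero denominator yields ``inf`` (the "only present in
    one color" sentinel).
    """
    if mean_high < 0 or mean_low < 0:
        raise ValueError("group means must be non-negative")
    if mean_low == 0:
        return math.inf
    ratio = mean_high / mean_low
    if ratio < 10:
        return _round_half_away(ratio, 1)
    return float(_round_half_away(ratio, 0))


def format_fold_ratio(ratio: float) -> str:
    if math.isinf(ratio):
        return "∞"
    if ratio >= 10:
        return f"{int(ratio)}×"
    return f"{ratio:.1f}×"


def wilcoxon_rank_sum(x, y) -> tuple:
    """Mann–Whitney W statistic and two-sided p for two samples.

    W is the rank-sum of ``x`` minus n_x(n_x+1)/2, with midranks for ties.
    The p-value is exact (enumeration over all labelings) when
    n_x + n_y <= 12, else a normal approximation with continuity and tie
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:nx].sum() - nx * (nx + 1) / 2)

    if nx + ny <= 12:
        idx = range(nx + ny)
        stats = []
        for combo in combinations(idx, nx):
            rs = ranks[list(combo)].sum()
            stats.append(rs - nx * (nx + 1) / 2)
        stats = np.asarray(stats)
        lo = np.mean(stats <= w + 1e-9)
        hi = np.mean(stats >= w - 1e-9)
        p = min(1.0, 2 * min(lo, hi))
        return w, float(p)

    mu = nx * ny / 2
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = nx * ny / 12 * (n + 1 - tie_term)
    if sigma2 == 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(sigma2)
    from scipy.stats import norm
    p = min(1.0, 2 * norm.sf(max(z, 0.0)))
    return w, float(p)


def pathway_summary(degs: pd.DataFrame) -> dict:
    """Counts, mean fold ratios and ABP vs non-ABP rank tests on a DEG table."""
    deg_rows = degs[degs["is_deg"]]
    counts = {}
    mean_ratio = {}
    mean_tmm = {}
    for cat in sorted(degs["category"].unique()):
        for direction in ("B>O", "O>B"):
            sub = deg_rows[(deg_rows["category"] == cat)
                           & (deg_rows["direction"] == direction)]
            counts[(cat, direction)] = len(sub)
            if len(sub):
                highs = sub["mean_tmm_blue"] if direction == "B>O" else sub["mean_tmm_orange"]
                lows = sub["mean_tmm_orange"] if direction == "B>O" else sub["mean_tmm_blue"]
                ratios = [fold_ratio(h, l) for h, l in zip(highs, lows)]
                finite = [r for r in ratios if math.isfinite(r)]
                mean_ratio[(cat, direction)] = float(np.mean(finite)) if finite else math.inf
                mean_tmm[(cat, direction)] = float(np.mean(highs))
            else:
                mean_ratio[(cat, direction)] = float("nan")
                mean_tmm[(cat, direction)] = float("nan")

    wilcoxon = {}
    abp = degs[degs["category"] == "ABP"]
    non = degs[degs["category"] == "nonABP"]
    if len(abp) and len(non):
        for color, col in (("blue", "mean_tmm_blue"), ("orange", "mean_tmm_orange")):
            wilcoxon[color] = wilcoxon_rank_sum(abp[col].to_numpy(), non[col].to_numpy())
        pooled_abp = np.concatenate([abp["mean_tmm_blue"], abp["mean_tmm_orange"]])
        pooled_non = np.concatenate([non["mean_tmm_blue"], non["mean_tmm_orange"]])
        wilcoxon["pooled"] = wilcoxon_rank_sum(pooled_abp, pooled_non)
    return {
        "n_degs": counts,
        "mean_fold_ratio": mean_ratio,
        "mean_tmm": mean_tmm,
        "wilcoxon": wilcoxon,
        "n_degs_total": int(degs["is_deg"].sum()),
    }


def scale_for_heatmap(expr) -> pd.DataFrame:
    """Per-gene centering and unit-variance scaling (sample SD, ddof=1).

    Constant genes map to all-zero rows.
    """
    df = pd.DataFrame(expr).astype(float)
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    scaled = df.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    return scaled.fillna(0.0)
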