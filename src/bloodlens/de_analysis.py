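"""Negative-binomial differential expression with median-of-ratios
normalization, plus the nonparametric per-gene comparison and DEG filtering.

The DE model is a per-gene NB GLM with log link on a two-level group
indicator and a log size-factor offset:

    K_gs ~ NB(mu_gs, phi_g),    log mu_gs = log s_s + beta0_g + beta1_g x_s

with Var(K) = mu + phi mu^2.  Gene dispersions come from a method-of-moments
estimate on normalized counts, floored at 1e-8 and shrunk 50/50 toward a
fitted mean-dispersion trend phi(mu) = a/mu + b; the Wald statistic is
beta1 / SE(beta1) against a two-sided normal reference.  This is a
documented, calibration-tested simplification of DESeq2's empirical-Bayes
machinery, not a re-implementation of its internals.

Reported fold changes use the group mean normalized counts (nRC) with a 0.5
pseudo-count, in the "signed fold" convention of clinical transcriptomics
tables: a ratio r is printed as +r when r >= 1 and as -1/r otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import CountMatrix, logger

DISPERSION_FLOOR = 1e-8
MIN_NONZERO_SAMPLES = 3  # genes below this are flagged, not tested


@dataclass
class SizeFactors:
    """Per-sample scale factors from the median-of-ratios estimator."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values <= 0).any() or not np.isfinite(self.values).all():
            raise ValueError("size factors must be positive and finite")


def _as_matrix(counts) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(counts, CountMatrix):
        return counts.counts.astype(float), counts.gene_ids, counts.sample_ids
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index), list(counts.columns)
    arr = np.asarray(counts, dtype=float)
    return arr, [f"g{i}" for i in range(arr.shape[0])], [f"s{j}" for j in range(arr.shape[1])]


def estimate_size_factors(counts) -> SizeFactors:
    """Median-of-ratios size factors.

    The per-gene reference is the geometric mean over samples, restricted to
    genes with strictly positive counts in every sample; each sample's
    factor is the median over those genes of count / reference.
    """
    mat, _, sample_ids = _as_matrix(counts)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; median-of-ratios is "
            "undefined — consider the positive-counts fallback (e.g. drop "
            "samples or use a pseudo-counted reference)"
        )
    logref = np.log(mat[positive]).mean(axis=1)
    ratios = np.log(mat[positive]) - logref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return SizeFactors(sample_ids, factors)


def normalize_counts(counts, size_factors) -> np.ndarray:
    """nRC[g, s] = counts[g, s] / factor[s]."""
    mat, _, sample_ids = _as_matrix(counts)
    values = size_factors.values if isinstance(size_factors, SizeFactors) else np.asarray(size_factors, float)
    if values.shape[0] != mat.shape[1]:
        raise ValueError(
            f"{values.shape[0]} size factors for {mat.shape[1]} samples"
        )
    return mat / values[None, :]


@dataclass
class DEGTable:
    """Per-gene differential expression results (one row per input gene)."""

    table: pd.DataFrame
    case: str
    control: str

    def log2fc(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["log2FC"]))

    def __len__(self) -> int:
        return len(self.table)


def _fit_nb_glm(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, phi: np.ndarray,
    n_iter: int = 50, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-gene NB GLMs with shared design (1, x).

    y: (G, n) counts; x: (n,) 0/1 indicator; offset: (n,) log size factors;
    phi: (G,) dispersions.  Returns (beta0, beta1, se_beta1).
    """
    G, n = y.shape
    eps = 1e-8
    m0 = (y / np.exp(offset))[:, x == 0].mean(axis=1)
    m1 = (y / np.exp(offset))[:, x == 1].mean(axis=1)
    beta0 = np.log(m0 + eps)
    beta1 = np.log(m1 + eps) - beta0
    xb = x[None, :]
    for _ in range(n_iter):
        eta = np.clip(beta0[:, None] + beta1[:, None] * xb + offset[None, :], -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * xb).sum(axis=1)
        swx2 = (w * xb * xb).sum(axis=1)
        bz = (w * z).sum(axis=1)
        bxz = (w * xb * z).sum(axis=1)
        det = sw * swx2 - swx**2
        det = np.where(det <= 0, np.nan, det)
        new0 = (swx2 * bz - swx * bxz) / det
        new1 = (sw * bxz - swx * bz) / det
        new0 = np.where(np.isfinite(new0), new0, beta0)
        new1 = np.clip(np.where(np.isfinite(new1), new1, beta1), -30, 30)
        delta = np.maximum(np.abs(new0 - beta0), np.abs(new1 - beta1))
        beta0, beta1 = new0, new1
        if np.nanmax(delta) < tol:
            break
    eta = np.clip(beta0[:, None] + beta1[:, None] * xb + offset[None, :], -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + phi[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * xb).sum(axis=1)
    swx2 = (w * xb * xb).sum(axis=1)
    det = sw * swx2 - swx**2
    se1 = np.sqrt(np.where(det > 0, sw / det, np.nan))
    return beta0, beta1, se1


def _dispersion_mom(
    q: np.ndarray, groups01: np.ndarray, inv_sf_mean: float
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments dispersion on normalized counts, with a fitted
    mean-dispersion trend phi(mu) = a/mu + b.  Returns (phi_gene, phi_trend).
    """
    n = q.shape[1]
    means = q.mean(axis=1)
    # pooled within-group variance (removes the group effect from s^2)
    ss = np.zeros(q.shape[0])
    df = 0
    for g in (0, 1):
        sub = q[:, groups01 == g]
        if sub.shape[1] >= 2:
            ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
            df += sub.shape[1] - 1
    s2 = ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - means * inv_sf_mean) / means**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    phi_gene = np.maximum(raw, DISPERSION_FLOOR)

    # trend fit on genes with decent means, least squares in (1/mu, 1)
    ok = means > 1.0
    if ok.sum() >= 10:
        A = np.column_stack([1.0 / means[ok], np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a, b = max(coef[0], 0.0), max(coef[1], 0.0)
    else:  # too few genes to fit a trend: fall back to the global mean
        a, b = 0.0, max(float(np.mean(raw)), DISPERSION_FLOOR)
    with np.errstate(divide="ignore"):
        phi_trend = np.maximum(a / means + b, DISPERSION_FLOOR)
    phi_trend = np.where(np.isfinite(phi_trend), phi_trend, DISPERSION_FLOOR)
    return phi_gene, phi_trend


def nb_wald_test(
    counts,
    groups,
    case: str,
    control: str,
    padj_method: str = "bonferroni",
    size_factors: SizeFactors | None = None,
) -> DEGTable:
    """Per-gene NB Wald test of ``case`` vs ``control``.

    Genes with all-zero counts get p = 1 and log2FC = 0; genes with fewer
    than 3 nonzero samples are flagged untested (p = NA).  ``padj`` columns
    (Bonferroni and BH) are computed over tested genes only.
    """
    mat, gene_ids, sample_ids = _as_matrix(counts)
    groups = np.asarray(groups)
    levels = set(groups)
    if not {case, control} <= levels:
        raise ValueError(f"groups must contain both {case!r} and {control!r}")
    keep = np.isin(groups, [case, control])
    mat = mat[:, keep]
    sample_ids = [s for s, k in zip(sample_ids, keep) if k]
    x = (groups[keep] == case).astype(float)
    if len(set(x)) < 2:
        raise ValueError("group factor must have two levels")
    if (x == 1).sum() < 2 or (x == 0).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    if size_factors is None:
        size_factors = estimate_size_factors(
            pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
        )
    sf = size_factors.values
    q = mat / sf[None, :]

    nonzero = (mat > 0).sum(axis=1)
    all_zero = nonzero == 0
    tested = nonzero >= MIN_NONZERO_SAMPLES
    n_flagged = int((~tested & ~all_zero).sum())
    if n_flagged:
        logger.info("nb_wald_test: %d near-zero genes flagged untested", n_flagged)

    phi_gene, phi_trend = _dispersion_mom(q[tested], x, float(np.mean(1.0 / sf)))
    phi = 0.5 * phi_gene + 0.5 * phi_trend

    p = np.full(len(gene_ids), np.nan)
    wald_l2fc = np.full(len(gene_ids), np.nan)
    se = np.full(len(gene_ids), np.nan)
    if tested.any():
        b0, b1, se1 = _fit_nb_glm(mat[tested], x, np.log(sf), phi)
        z = b1 / se1
        p_t = 2.0 * stats.norm.sf(np.abs(z))
        p_t = np.where(np.isfinite(p_t), p_t, 1.0)
        p[tested] = p_t
        wald_l2fc[tested] = b1 / np.log(2.0)
        se[tested] = se1 / np.log(2.0)
    p[all_zero] = 1.0

    mean_ctrl = q[:, x == 0].mean(axis=1)
    mean_case = q[:, x == 1].mean(axis=1)
    ratio = (mean_case + 0.5) / (mean_ctrl + 0.5)
    log2fc = np.log2(ratio)
    log2fc[all_zero] = 0.0
    ratio[all_zero] = 1.0
    signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    direction = np.where(ratio >= 1.0, "up", "down")

    padj_bonf = np.full(len(gene_ids), np.nan)
    padj_bh = np.full(len(gene_ids), np.nan)
    if tested.any():
        pt = p[tested]
        padj_bonf[tested] = np.minimum(pt * tested.sum(), 1.0)
        padj_bh[tested] = multipletests(pt, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": gene_ids,
            "baseMean": q.mean(axis=1),
            "mean_nRC_ctrl": mean_ctrl,
            "mean_nRC_case": mean_case,
            "log2FC": log2fc,
            "signed_fc": signed,
            "p": p,
            "padj_bonferroni": padj_bonf,
            "padj_bh": padj_bh,
            "direction": direction,
            "tested": tested,
            "wald_log2fc": wald_l2fc,
            "se_log2fc": se,
        }
    )
    table["padj"] = table["padj_bonferroni"] if padj_method == "bonferroni" else table["padj_bh"]
    return DEGTable(table, case=case, control=control)


def mann_whitney_compare(expr, groups, case=None, control=None) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per gene (tie-corrected; exact for small
    untied samples).  U is reported as min(U_case, U_control).

    ``expr`` is a genes x samples frame/array of (normalized) expression.
    """
    mat, gene_ids, _ = _as_matrix(expr)
    groups = np.asarray(groups)
    levels = sorted(set(groups)) if case is None else [control, case]
    if case is None:
        if len(levels) != 2:
            raise ValueError("groups must have exactly two levels")
        control, case = levels
    a = mat[:, groups == control]
    b = mat[:, groups == case]
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both groups must be nonempty")
    out_u = np.empty(len(gene_ids))
    out_p = np.empty(len(gene_ids))
    half = a.shape[1] * b.shape[1] / 2.0
    for i in range(len(gene_ids)):
        xa, xb = a[i], b[i]
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):  # degenerate: no variation at all
            out_u[i], out_p[i] = half, 1.0
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        out_u[i] = min(res.statistic, a.shape[1] * b.shape[1] - res.statistic)
        out_p[i] = min(float(res.pvalue), 1.0)
    return pd.DataFrame({"gene": gene_ids, "U": out_u, "p": out_p})


@dataclass
class FilteredDEGs:
    """DEG list after thresholding, partitioned by direction."""

    table: pd.DataFrame
    up: list[str]
    down: list[str]
    p_threshold: float
    fc_threshold: float
    use_padj: bool

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


def filter_degs(
    deg: DEGTable,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    use_padj: bool = False,
) -> FilteredDEGs:
    """Keep genes with p < p_threshold AND |signed fold| strictly greater
    than fc_threshold.  In ``use_padj`` (Bonferroni) mode the adjusted p is
    thresholded instead and the fold criterion is ignored.
    """
    if p_threshold <= 0 or fc_threshold <= 1:
        raise ValueError("invalid thresholds")
    t = deg.table
    if use_padj:
        kept = t["padj_bonferroni"] < p_threshold
    else:
        kept = (t["p"] < p_threshold) & (t["signed_fc"].abs() > fc_threshold)
    kept = kept.fillna(False)
    sub = t[kept].copy()
    up = list(sub.loc[sub["direction"] == "up", "gene"])
    down = list(sub.loc[sub["direction"] == "down", "gene"])
    logger.info(
        "filter_degs: kept %d of %d genes (%d up, %d down)",
        len(sub), len(t), len(up), len(down),
    )
    return FilteredDEGs(sub, up, down, p_threshold, fc_threshold, use_padj)
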