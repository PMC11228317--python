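"""Cross-signature statistics: gene-list overlap, over-representation,
fold-change concordance, biomarker-panel scoring and stratified medians.

The overlap and ORA tests are exact hypergeometric upper tails computed in
log space, so overlaps as extreme as a 23-gene intersection of two ~200-gene
lists in a ~28,000-gene universe (tail probabilities around 1e-21) evaluate
without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .de_analysis import DEGTable, mann_whitney_compare
from .io_core import PanelDefinition, logger

#: |log2FC| below this is treated as sign-agnostic when calling discordance
DISCORDANCE_DEAD_ZONE = 0.05


def hypergeom_upper_tail(k: int, universe_n: int, n_a: int, n_b: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=universe_n, K=n_a, n=n_b),
    accumulated in log space."""
    lo = max(0, n_a + n_b - universe_n)
    hi = min(n_a, n_b)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    ks = np.arange(k, hi + 1)
    logp = stats.hypergeom.logpmf(ks, universe_n, n_a, n_b)
    return float(min(np.exp(logsumexp(logp)), 1.0))


@dataclass
class OverlapReport:
    n_list_a: int
    n_list_b: int
    n_overlap: int
    universe_n: int
    expected_overlap: float
    p: float
    overlap_genes: list[str]
    discordant_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_list_a": self.n_list_a,
                    "n_list_b": self.n_list_b,
                    "n_overlap": self.n_overlap,
                    "universe_n": self.universe_n,
                    "expected_overlap": self.expected_overlap,
                    "p": self.p,
                    "overlap_genes": ";".join(self.overlap_genes),
                    "discordant_genes": ";".join(self.discordant_genes),
                }
            ]
        )


def overlap_test(
    list_a,
    list_b,
    universe_n: int,
    fc_a: dict[str, float] | None = None,
    fc_b: dict[str, float] | None = None,
    universe: set[str] | None = None,
) -> OverlapReport:
    """Exact hypergeometric test of the overlap between two gene lists.

    ``fc_a``/``fc_b`` map gene -> log2FC in each signature; overlap genes
    whose folds point in opposite directions (both beyond the ±0.05 dead
    zone) are reported as discordant — the FN1-style discriminators between
    two signatures.
    """
    a, b = list(dict.fromkeys(list_a)), list(dict.fromkeys(list_b))
    if universe is not None:
        outside = [g for g in a + b if g not in universe]
        if outside:
            raise ValueError(f"gene(s) outside the universe: {outside[:5]}")
    union = set(a) | set(b)
    if universe_n < len(union):
        raise ValueError(
            f"universe_n={universe_n} smaller than |A union B|={len(union)}"
        )
    overlap = sorted(set(a) & set(b))
    p = hypergeom_upper_tail(len(overlap), universe_n, len(a), len(b))
    discordant = []
    if fc_a is not None and fc_b is not None:
        for g in overlap:
            la, lb = fc_a.get(g), fc_b.get(g)
            if la is None or lb is None:
                continue
            if abs(la) < DISCORDANCE_DEAD_ZONE or abs(lb) < DISCORDANCE_DEAD_ZONE:
                continue
            if np.sign(la) != np.sign(lb):
                discordant.append(g)
    return OverlapReport(
        n_list_a=len(a),
        n_list_b=len(b),
        n_overlap=len(overlap),
        universe_n=universe_n,
        expected_overlap=len(a) * len(b) / universe_n,
        p=p,
        overlap_genes=overlap,
        discordant_genes=discordant,
    )


def ora(
    query,
    gene_sets: dict[str, list[str]],
    universe_n: int,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """One-tailed hypergeometric over-representation of ``query`` in each
    gene set, BH-corrected over tested sets, sorted by p."""
    query = list(dict.fromkeys(query))
    if not query:
        raise ValueError("empty query gene list")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    if universe is not None:
        query = [g for g in query if g in universe]
    rows = []
    qset = set(query)
    for name, genes in gene_sets.items():
        members = set(genes) if universe is None else set(genes) & universe
        k = len(qset & members)
        p = hypergeom_upper_tail(k, universe_n, len(members), len(query))
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "n_query": len(query),
                "k_overlap": k,
                "expected": len(members) * len(query) / universe_n,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


@dataclass
class ConcordanceReport:
    """Agreement of two signatures' log2 fold changes over a pooled list."""

    pooled_genes: list[str]
    spearman: float
    pearson: float
    scatter: pd.DataFrame  # gene, log2fc_a, log2fc_b


def fc_concordance(
    deg_a: DEGTable, deg_b: DEGTable, pooled: list[str]
) -> ConcordanceReport:
    """Correlate log2FC between two groupings of the data over a pooled DEG
    list (genes must be present in both tables); Spearman and Pearson are
    both reported since the appropriate scale is a judgement call."""
    fa, fb = deg_a.log2fc(), deg_b.log2fc()
    pooled = list(dict.fromkeys(pooled))
    missing = [g for g in pooled if g not in fa or g not in fb]
    if missing:
        raise ValueError(f"pooled gene(s) absent from a DEG table: {missing[:5]}")
    if len(pooled) < 3:
        raise ValueError("pooled list must contain at least 3 genes")
    va = np.array([fa[g] for g in pooled])
    vb = np.array([fb[g] for g in pooled])
    sp = float(stats.spearmanr(va, vb).statistic)
    pe = float(stats.pearsonr(va, vb).statistic)
    scatter = pd.DataFrame({"gene": pooled, "log2fc_a": va, "log2fc_b": vb})
    return ConcordanceReport(pooled, sp, pe, scatter)


def panel_score(
    nrc: pd.DataFrame,
    panels,
    groups,
    reference_group: str,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Infection/biomarker panel table: per panel gene, mean (sd) nRC in
    each group plus an uncorrected two-sided Mann-Whitney p versus the
    reference group for every other group, flagged at ``p_threshold``.
    Panel genes absent from the matrix are logged and skipped."""
    groups = np.asarray(groups)
    level_order = list(dict.fromkeys(groups))
    if reference_group not in level_order:
        raise ValueError(f"reference group {reference_group!r} not present")
    if isinstance(panels, PanelDefinition):
        panels = [panels]
    rows = []
    any_gene = False
    for panel in panels:
        for g in panel.gene_ids:
            if g not in nrc.index:
                logger.info("panel_score: gene %s absent from counts, skipped", g)
                continue
            any_gene = True
            vals = nrc.loc[g].to_numpy()
            row = {
                "gene": g,
                "description": panel.descriptions.get(g, ""),
                "panel_name": panel.panel_name,
                "panel_type": panel.panel_type,
            }
            ref_vals = vals[groups == reference_group]
            for lv in level_order:
                gv = vals[groups == lv]
                row[f"mean_{lv}"] = float(gv.mean()) if gv.size else np.nan
                row[f"sd_{lv}"] = float(gv.std(ddof=1)) if gv.size > 1 else np.nan
            for lv in level_order:
                if lv == reference_group:
                    continue
                gv = vals[groups == lv]
                if gv.size == 0 or ref_vals.size == 0:
                    p = np.nan
                else:
                    p = float(
                        mann_whitney_compare(
                            vals[None, (groups == lv) | (groups == reference_group)],
                            groups[(groups == lv) | (groups == reference_group)],
                            case=lv,
                            control=reference_group,
                        )["p"].iloc[0]
                    )
                row[f"p_{lv}_vs_{reference_group}"] = p
                row[f"sig_{lv}"] = bool(np.isfinite(p) and p < p_threshold)
            rows.append(row)
    if not any_gene:
        raise ValueError("no panel gene present in the expression matrix")
    return pd.DataFrame(rows)


def stratified_medians(
    nrc: pd.DataFrame,
    strata,
    reference_stratum: str,
) -> pd.DataFrame:
    """Median nRC per stratum as a percent of the reference stratum's
    median (the reference reports 100 by construction).  A zero reference
    median yields NA for that gene, logged."""
    strata = np.asarray(strata)
    levels = list(dict.fromkeys(strata))
    if reference_stratum not in levels:
        raise ValueError(f"reference stratum {reference_stratum!r} not present")
    ref_cols = strata == reference_stratum
    if not ref_cols.any():
        raise ValueError("reference stratum is empty")
    out = {"gene": list(nrc.index)}
    ref_med = np.median(nrc.to_numpy()[:, ref_cols], axis=1)
    zero_ref = ref_med == 0
    if zero_ref.any():
        logger.info(
            "stratified_medians: %d gene(s) with zero reference median -> NA",
            int(zero_ref.sum()),
        )
    for lv in levels:
        med = np.median(nrc.to_numpy()[:, strata == lv], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * med / ref_med
        out[f"pct_{lv}"] = np.where(zero_ref, np.nan, pct)
    return pd.DataFrame(out)
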