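"""Cell-type attribution of DEGs and the abundance-vs-regulation verdict.

Two complementary reads of a DEG list against an immune reference atlas:

* Approach A (``attribute_degs``): average the atlas expression of the up-
  and down-regulated DEGs in each cell type — which cell types carry the
  changed transcripts?
* Approach B (``select_markers`` + ``abundance_score``): ignore the DEGs
  and track atlas-derived cell-type-exclusive markers in the cohort — did
  the abundance of any cell type actually change?

``classify_scenario`` combines both: a cell type whose markers moved more
than the flag threshold is called an abundance shift; a cell type that
carries the DEGs (top-2 by mean, significant vs. the aggregate total_pbmc
reference) without a marker shift is called a per-cell expression shift —
the configuration the study interprets as cell-intrinsic regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import TOTAL_PBMC, ReferenceAtlas, logger


@dataclass
class AttributionReport:
    """Per (direction, cell type) mean atlas expression of mapped DEGs,
    mapping counts and paired significance vs. total_pbmc."""

    table: pd.DataFrame  # direction, cell_type, mean_expr, n_mapped, n_unmapped, p_vs_pbmc, rank

    def top_types(self, direction: str, k: int = 2) -> list[str]:
        sub = self.table[self.table["direction"] == direction]
        return list(sub.nsmallest(k, "rank")["cell_type"])

    def for_type(self, direction: str, cell_type: str) -> pd.Series:
        sub = self.table[
            (self.table["direction"] == direction) & (self.table["cell_type"] == cell_type)
        ]
        return sub.iloc[0] if len(sub) else pd.Series(dtype=float)


def _paired_wilcoxon_vs_pbmc(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank on (cell-type - total_pbmc) pairs.
    Zero differences are dropped; fewer than 5 informative pairs -> p = 1."""
    nz = diffs[diffs != 0]
    if len(nz) < 5:
        return 1.0
    res = stats.wilcoxon(nz, alternative="two-sided")
    return float(min(res.pvalue, 1.0))


def attribute_degs(
    up: list[str],
    down: list[str],
    atlas: ReferenceAtlas,
    allow_empty: bool = False,
) -> AttributionReport:
    """Approach A: mean atlas expression of mapped DEGs per cell type,
    up- and down-regulated lists handled separately (they may represent
    different cell types).  Unmapped transcripts are counted, never imputed.
    """
    frame = atlas.to_frame()
    pbmc = atlas.total_pbmc_profile()
    rows = []
    for direction, genes in (("up", list(up)), ("down", list(down))):
        mapped = [g for g in genes if g in frame.columns]
        n_unmapped = len(genes) - len(mapped)
        if not mapped:
            if genes and not allow_empty:
                raise ValueError(
                    f"no {direction}-regulated transcript maps to the atlas"
                )
            continue
        logger.info(
            "attribute_degs: %s list, %d of %d mapped to atlas",
            direction, len(mapped), len(genes),
        )
        sub = frame[mapped]
        pb = pbmc[mapped].to_numpy()
        for ct in atlas.specific_types:
            expr = sub.loc[ct].to_numpy()
            rows.append(
                {
                    "direction": direction,
                    "cell_type": ct,
                    "mean_expr": float(expr.mean()),
                    "n_mapped": len(mapped),
                    "n_unmapped": n_unmapped,
                    "p_vs_pbmc": _paired_wilcoxon_vs_pbmc(expr - pb),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["direction", "cell_type", "mean_expr", "n_mapped", "n_unmapped", "p_vs_pbmc"],
    )
    if len(table):
        table["rank"] = (
            table.groupby("direction")["mean_expr"].rank(ascending=False, method="first")
        )
    else:
        table["rank"] = pd.Series(dtype=float)
    return AttributionReport(table)


@dataclass
class MarkerPanelSet:
    """Per cell type, the retained (gene, enrichment-fold) marker pairs."""

    panels: dict[str, list[tuple[str, float]]]
    marker_k: int
    min_enrichment: float

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {"cell_type": ct, "gene": g, "enrichment": e}
            for ct, pairs in self.panels.items()
            for g, e in pairs
        ]
        return pd.DataFrame(rows, columns=["cell_type", "gene", "enrichment"])

    def genes(self, cell_type: str) -> list[str]:
        return [g for g, _ in self.panels.get(cell_type, [])]


def select_markers(
    atlas: ReferenceAtlas,
    marker_k: int = 10,
    marker_min_enrichment: float = 4.0,
    exclude: list[str] | None = None,
) -> MarkerPanelSet:
    """Approach B marker panels: per cell type, the top ``marker_k`` genes
    by enrichment = expression in the type / highest expression among the
    *other* specific types (total_pbmc excluded from the comparison), kept
    only above ``marker_min_enrichment``.  Ties break by gene id.

    ``exclude`` drops genes (e.g. the current DEG list) before ranking, so
    panels stay independent of the differential signal they are meant to
    audit.
    """
    types = atlas.specific_types
    if len(types) < 2:
        raise ValueError("marker selection needs at least 2 cell types")
    excluded = set(exclude or ())
    sub = atlas.expr[[atlas.cell_types.index(t) for t in types]]
    panels: dict[str, list[tuple[str, float]]] = {}
    for i, ct in enumerate(types):
        others_max = np.delete(sub, i, axis=0).max(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = np.where(
                others_max > 0,
                sub[i] / others_max,
                np.where(sub[i] > 0, np.inf, 0.0),
            )
        cand = [
            (g, float(e))
            for g, e in zip(atlas.gene_ids, enr)
            if e >= marker_min_enrichment and g not in excluded
        ]
        cand.sort(key=lambda t: (-t[1], t[0]))
        panels[ct] = cand[:marker_k]
        if not panels[ct]:
            logger.info("select_markers: no markers pass for %s", ct)
    return MarkerPanelSet(panels, marker_k, marker_min_enrichment)


@dataclass
class AbundanceReport:
    """Marker-panel nRC means per group and the percent-change flag."""

    table: pd.DataFrame  # cell_type, mean_a, mean_b, pct_change, flag, n_genes
    group_a: str
    group_b: str
    flag_pct: float

    def for_type(self, cell_type: str) -> pd.Series:
        sub = self.table[self.table["cell_type"] == cell_type]
        return sub.iloc[0] if len(sub) else pd.Series(dtype=float)


def abundance_score(
    nrc: pd.DataFrame,
    panels: MarkerPanelSet,
    groups,
    group_a: str,
    group_b: str,
    flag_pct: float = 20.0,
) -> AbundanceReport:
    """Approach B: per cell type, the mean marker nRC in each group
    (averaged per sample first, then over samples) and the percent change
    of group B relative to group A; |change| strictly greater than
    ``flag_pct`` raises the abundance flag.
    """
    if not any(panels.panels.values()):
        raise ValueError("no cell type has a nonempty marker panel")
    groups = np.asarray(groups)
    rows = []
    for ct, pairs in panels.panels.items():
        genes = [g for g, _ in pairs]
        present = [g for g in genes if g in nrc.index]
        skipped = len(genes) - len(present)
        if skipped:
            logger.info(
                "abundance_score: %d/%d %s marker genes absent from counts",
                skipped, len(genes), ct,
            )
        if not present:
            rows.append(
                {"cell_type": ct, "mean_a": np.nan, "mean_b": np.nan,
                 "pct_change": np.nan, "flag": False, "n_genes": 0}
            )
            continue
        per_sample = nrc.loc[present].mean(axis=0).to_numpy()
        mean_a = float(per_sample[groups == group_a].mean())
        mean_b = float(per_sample[groups == group_b].mean())
        pct = 100.0 * (mean_b - mean_a) / mean_a if mean_a > 0 else np.nan
        flag = bool(np.isfinite(pct) and abs(pct) > flag_pct)
        rows.append(
            {"cell_type": ct, "mean_a": mean_a, "mean_b": mean_b,
             "pct_change": pct, "flag": flag, "n_genes": len(present)}
        )
    return AbundanceReport(pd.DataFrame(rows), group_a, group_b, flag_pct)


def classify_scenario(
    attr: AttributionReport,
    abund: AbundanceReport,
    p_threshold: float = 0.05,
    top_k: int = 2,
) -> pd.DataFrame:
    """Verdict per cell type: ``abundance_shift`` when its marker panel
    moved beyond the flag threshold; ``expression_shift`` when it carries
    the DEGs (top-``top_k`` attribution mean with p < ``p_threshold`` vs.
    total_pbmc in either direction) without a marker shift; ``none``
    otherwise.  Returns the verdicts with their evidence.
    """
    hits: dict[str, tuple[str, float, float]] = {}
    for direction in ("up", "down"):
        sub = attr.table[attr.table["direction"] == direction]
        if not len(sub):
            continue
        top = sub.nsmallest(top_k, "rank")
        for _, r in top.iterrows():
            if r["p_vs_pbmc"] < p_threshold:
                prev = hits.get(r["cell_type"])
                if prev is None or r["p_vs_pbmc"] < prev[1]:
                    hits[r["cell_type"]] = (direction, r["p_vs_pbmc"], r["rank"])
    rows = []
    for _, ab in abund.table.iterrows():
        ct = ab["cell_type"]
        hit = ct in hits
        flagged = bool(ab["flag"])
        if flagged:
            verdict = "abundance_shift"
        elif hit:
            verdict = "expression_shift"
        else:
            verdict = "none"
        direction, p_hit, rank = hits.get(ct, (None, np.nan, np.nan))
        rows.append(
            {
                "cell_type": ct,
                "verdict": verdict,
                "attribution_hit": hit,
                "hit_direction": direction,
                "p_vs_pbmc": p_hit,
                "attribution_rank": rank,
                "pct_change": ab["pct_change"],
                "abundance_flag": flagged,
            }
        )
    return pd.DataFrame(rows)
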