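"""Domain types, file I/O, configuration and pipeline orchestration.

The package analyses whole-blood bulk RNA-seq cohorts stratified by a
stress test and invasive coronary angiography into four groups:

* ``control``        — stress negative, no obstructive CAD
* ``inoca``          — stress positive (ischemia), no obstructive CAD
* ``cad_stress_neg`` — obstructive CAD, stress negative
* ``cad_stress_pos`` — obstructive CAD, stress positive

All count matrices are oriented genes x samples (genes as rows), the usual
RNA-seq convention; every internal matrix in the package follows this.
Gene identifiers are matched by exact, case-sensitive string comparison
across counts, atlas, gene sets and panels (a synonym-table hook exists but
ships empty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bloodlens")
if not logger.handlers:  # library default: stderr handler, INFO
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

STRESS_LEVELS = ("positive", "negative")
CAD_LEVELS = ("positive", "negative")
SEX_LEVELS = ("male", "female", "unknown")
GROUPS = ("control", "inoca", "cad_stress_neg", "cad_stress_pos")

#: aggregate row name used as the pan-leukocyte reference in the atlas
TOTAL_PBMC = "total_pbmc"

_POS = {"positive", "pos", "+", "1", "true", "yes"}
_NEG = {"negative", "neg", "-", "0", "false", "no"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} identifier(s): {', '.join(dups)}")


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # int64, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {arr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            bad = ~np.isclose(arr, rounded, atol=1e-6, rtol=0)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-integer count {arr[g, s]!r} at gene "
                    f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
                )
            arr = rounded.astype(np.int64)
        neg = arr < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self.counts = arr.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return CountMatrix(list(genes), list(self.sample_ids), self.counts[rows])


def derive_group(stress: str, cad: str) -> str:
    """Group label as a pure function of the (stress, cad) pair."""
    s, c = stress == "positive", cad == "positive"
    if not s and not c:
        return "control"
    if s and not c:
        return "inoca"
    if not s and c:
        return "cad_stress_neg"
    return "cad_stress_pos"


def _norm_level(value: object, field_name: str, sample: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"sample {sample!r}: missing {field_name}")
    v = str(value).strip().lower()
    if v in _POS:
        return "positive"
    if v in _NEG:
        return "negative"
    raise ValueError(f"sample {sample!r}: unrecognized {field_name} value {value!r}")


@dataclass
class SampleTable:
    """Per-sample metadata with the derived four-cell group label.

    Backed by a DataFrame with columns sample_id, stress, cad, sex, age,
    group.  ``group`` is always recomputed from (stress, cad).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("sample_id", "stress", "cad"):
            if col not in df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        df["stress"] = [
            _norm_level(v, "stress", s) for v, s in zip(df["stress"], df["sample_id"])
        ]
        df["cad"] = [
            _norm_level(v, "cad", s) for v, s in zip(df["cad"], df["sample_id"])
        ]
        if "sex" in df.columns:
            df["sex"] = (
                df["sex"].astype(str).str.strip().str.lower().replace({"m": "male", "f": "female", "nan": "unknown"})
            )
            bad = ~df["sex"].isin(SEX_LEVELS)
            if bad.any():
                df.loc[bad, "sex"] = "unknown"
        else:
            df["sex"] = "unknown"
        if "age" not in df.columns:
            df["age"] = np.nan
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        df["group"] = [derive_group(s, c) for s, c in zip(df["stress"], df["cad"])]
        self.frame = df.reset_index(drop=True)[
            ["sample_id", "stress", "cad", "sex", "age", "group"]
        ]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def groups_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        m = dict(zip(self.frame["sample_id"], self.frame["group"]))
        missing = [s for s in sample_ids if s not in m]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")
        return np.array([m[s] for s in sample_ids])

    def check_matches(self, counts: CountMatrix) -> None:
        meta = set(self.frame["sample_id"])
        cts = set(counts.sample_ids)
        if meta != cts:
            raise ValueError(
                f"metadata/count sample mismatch: only in metadata {sorted(meta - cts)[:5]}, "
                f"only in counts {sorted(cts - meta)[:5]}"
            )


@dataclass
class ReferenceAtlas:
    """Cell type x gene normalized expression (immune blood-cell reference).

    An aggregate ``total_pbmc`` row may be present; if absent it is derived
    on demand as the unweighted mean over cell types.
    """

    cell_types: list[str]
    gene_ids: list[str]
    expr: np.ndarray  # float, (n_cell_types, n_genes), non-negative

    def __post_init__(self) -> None:
        self.cell_types = [str(c) for c in self.cell_types]
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.cell_types, "cell type")
        _check_unique(self.gene_ids, "gene")
        arr = np.asarray(self.expr, dtype=float)
        if arr.shape != (len(self.cell_types), len(self.gene_ids)):
            raise ValueError(
                f"atlas shape {arr.shape} does not match "
                f"{len(self.cell_types)} cell types x {len(self.gene_ids)} genes"
            )
        if (arr < 0).any():
            c, g = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative atlas expression at cell type {self.cell_types[c]!r}, "
                f"gene {self.gene_ids[g]!r}"
            )
        self.expr = arr

    @property
    def specific_types(self) -> list[str]:
        """Cell types excluding the aggregate total_pbmc row."""
        return [c for c in self.cell_types if c != TOTAL_PBMC]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, index=self.cell_types, columns=self.gene_ids)

    def total_pbmc_profile(self) -> pd.Series:
        """Aggregate reference: the atlas's own row if present, else the
        unweighted mean over cell types."""
        df = self.to_frame()
        if TOTAL_PBMC in df.index:
            return df.loc[TOTAL_PBMC]
        return df.mean(axis=0)


@dataclass
class PanelDefinition:
    """A named biomarker panel (e.g. bacterial, biofilm, viral, neutrophil)."""

    panel_name: str
    panel_type: str
    gene_ids: list[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"panel {self.panel_name!r} has an empty gene list")


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across pipeline stages.

    p_threshold         uncorrected p cut-off for DEG calling (0.05)
    fc_threshold        fold-change cut-off, strict > (1.5-fold)
    padj_method         'bonferroni' (default) or 'bh'
    marker_k            markers retained per cell type (top ~10)
    marker_min_enrichment  fold over next-highest type a marker must reach
    abundance_flag_pct  |percent change| beyond which a cell type's marker
                        score flags a possible abundance shift (20%)
    universe_size_mode  'expressed_genes', 'all_genes' or 'fixed:N'
    linkage             'average' or 'complete'
    cluster_cut_height  dendrogram cut height on 1 - rho (0.6)
    rng_seed            seed for any stochastic stage
    """

    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    padj_method: str = "bonferroni"
    marker_k: int = 10
    marker_min_enrichment: float = 4.0
    abundance_flag_pct: float = 20.0
    universe_size_mode: str = "expressed_genes"
    linkage: str = "average"
    cluster_cut_height: float = 0.6
    case_group: str = "inoca"
    control_group: str = "control"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.fc_threshold <= 1:
            raise ValueError("p_threshold must be > 0 and fc_threshold > 1")
        if self.padj_method not in ("bonferroni", "bh"):
            raise ValueError(f"unknown padj_method {self.padj_method!r}")
        if self.linkage not in ("average", "complete"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.abundance_flag_pct <= 0 or self.marker_min_enrichment <= 0:
            raise ValueError("thresholds must be positive")

    def universe_size(self, n_expressed: int, n_all: int) -> int:
        mode = self.universe_size_mode
        if mode == "expressed_genes":
            return n_expressed
        if mode == "all_genes":
            return n_all
        if mode.startswith("fixed:"):
            return int(mode.split(":", 1)[1])
        raise ValueError(f"unknown universe_size_mode {mode!r}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, fmt: str = "tsv") -> CountMatrix:
    """Read a genes x samples count matrix.

    ``fmt`` is one of ``tsv``, ``csv`` or ``mtx_triplet``.  The triplet form
    expects ``<stem>.mtx`` together with ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` (one identifier per line).
    """
    path = Path(path)
    if fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        return CountMatrix(list(df.index), list(df.columns), df.to_numpy())
    if fmt == "mtx_triplet":
        from scipy.io import mmread

        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        mat = np.asarray(mmread(str(path if path.suffix == ".mtx" else f"{stem}.mtx")).todense())
        return CountMatrix(genes, samples, mat)
    raise ValueError(f"unknown counts format {fmt!r}")


def write_counts(cm: CountMatrix, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt in ("tsv", "csv"):
        df = cm.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx_triplet":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        mmwrite(str(f"{stem}.mtx"), coo_matrix(cm.counts))
        Path(f"{stem}.genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_metadata(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep=None, engine="python")
    return SampleTable(df)


def write_metadata(meta: SampleTable, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_reference_atlas(path: str | Path) -> ReferenceAtlas:
    """Read a cell-type x gene atlas.

    Accepts the wide form (first column = cell type, remaining columns =
    genes) or the long triplet form with columns cell_type, gene, expression;
    both yield the identical atlas.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3 and {"cell_type", "gene"} <= set(cols):
        df.columns = cols
        value_col = [c for c in cols if c not in ("cell_type", "gene")][0]
        wide = df.pivot(index="cell_type", columns="gene", values=value_col)
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        if wide.isna().any().any():
            wide = wide.fillna(0.0)
        return ReferenceAtlas(list(wide.index), list(wide.columns), wide.to_numpy())
    df = df.set_index(df.columns[0])
    return ReferenceAtlas(list(df.index.astype(str)), list(df.columns), df.to_numpy())


def write_reference_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    df = atlas.to_frame()
    df.index.name = "cell_type"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_panels(path: str | Path) -> list[PanelDefinition]:
    """Read biomarker panels from TSV with columns panel_name, panel_type,
    gene (one row per gene; optional description column)."""
    df = pd.read_csv(path, sep="\t")
    need = {"panel_name", "panel_type", "gene"}
    if not need <= set(df.columns):
        raise ValueError(f"panel table must have columns {sorted(need)}")
    panels = []
    for (name, ptype), sub in df.groupby(["panel_name", "panel_type"], sort=False):
        desc = {}
        if "description" in sub.columns:
            desc = dict(zip(sub["gene"], sub["description"].fillna("")))
        panels.append(PanelDefinition(str(name), str(ptype), list(sub["gene"].astype(str)), desc))
    return panels


def format_float(x: float) -> str:
    """Render a float at 6 significant digits (fixed output convention)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with floats at 6 significant digits and NA for missing."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(format_float)
    out.to_csv(path, sep="\t", index=index, na_rep="NA")


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix,
    metadata: SampleTable,
    atlas: ReferenceAtlas,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    panels: Sequence[PanelDefinition] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis: DE -> DEG filter -> cell-type attribution
    (both approaches) -> scenario verdicts -> DEG correlation clustering ->
    optional ORA and panel scoring.

    Returns a dict of result objects; if ``out_dir`` is given, also writes
    one TSV per stage.  Deterministic given the inputs and config.
    """
    from . import celltype_attribution as ct
    from . import correlation_clustering as cc
    from . import de_analysis as de
    from . import signature_enrichment as se

    metadata.check_matches(counts)
    groups_all = metadata.groups_for(counts.sample_ids)
    case, ctrl = config.case_group, config.control_group
    keep = np.isin(groups_all, [case, ctrl])
    if keep.sum() < 4:
        raise RuntimeError(f"stage de: fewer than 4 samples in contrast {case}:{ctrl}")
    sub_samples = [s for s, k in zip(counts.sample_ids, keep) if k]
    sub = CountMatrix(counts.gene_ids, sub_samples, counts.counts[:, keep])
    sub_groups = groups_all[keep]

    logger.info(
        "pipeline: contrast %s vs %s; p<%g, fold>%g, padj=%s, marker_k=%d, "
        "min_enrichment=%g, abundance flag >%g%%, linkage=%s, cut height=%g, seed=%d",
        case, ctrl, config.p_threshold, config.fc_threshold, config.padj_method,
        config.marker_k, config.marker_min_enrichment, config.abundance_flag_pct,
        config.linkage, config.cluster_cut_height, config.rng_seed,
    )

    results: dict = {}

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"stage {name}: {exc}") from exc

    sf = _stage("size_factors", de.estimate_size_factors, sub)
    nrc = _stage("normalize", de.normalize_counts, sub, sf)
    deg = _stage("de", de.nb_wald_test, sub, sub_groups, case=case, control=ctrl,
                 padj_method=config.padj_method)
    filt = _stage("filter", de.filter_degs, deg, config.p_threshold, config.fc_threshold)
    results.update(size_factors=sf, nrc=nrc, deg_table=deg, filtered=filt)

    up, down = filt.up, filt.down
    attribution = _stage(
        "attribute", ct.attribute_degs, up, down, atlas, allow_empty=True
    )
    deg_genes = list(up) + list(down)
    marker_panels = _stage(
        "markers", ct.select_markers, atlas, config.marker_k,
        config.marker_min_enrichment, exclude=deg_genes,
    )
    nrc_df = pd.DataFrame(nrc, index=sub.gene_ids, columns=sub.sample_ids)
    abundance = _stage(
        "abundance", ct.abundance_score, nrc_df, marker_panels, sub_groups,
        group_a=ctrl, group_b=case, flag_pct=config.abundance_flag_pct,
    )
    verdicts = _stage("classify", ct.classify_scenario, attribution, abundance)
    results.update(
        attribution=attribution, marker_panels=marker_panels,
        abundance=abundance, verdicts=verdicts,
    )

    cluster_out = None
    if len(deg_genes) >= 2 and nrc_df.shape[1] >= 3:
        present = [g for g in deg_genes if g in nrc_df.index]
        if len(present) >= 2:
            corr = _stage("cluster", cc.spearman_matrix, nrc_df.loc[present])
            model = _stage(
                "cluster", cc.hierarchical_cluster, corr, config.linkage,
                height=config.cluster_cut_height,
            )
            model = _stage("cluster", cc.annotate_clusters, model, atlas)
            inter = _stage("cluster", cc.intercluster_correlation, model, corr)
            cluster_out = {"corr": corr, "model": model, "intercluster": inter}
    results["clustering"] = cluster_out

    n_expressed = int((sub.counts.sum(axis=1) > 0).sum())
    universe_n = config.universe_size(n_expressed, len(sub.gene_ids))
    if gene_sets:
        query = [g for g in deg_genes if g in set(sub.gene_ids)]
        if query:
            results["ora"] = _stage(
                "ora", se.ora, query, gene_sets, universe_n,
                universe=set(sub.gene_ids),
            )
        else:
            results["ora"] = None
    if panels:
        results["panel_table"] = _stage(
            "panels", se.panel_score, nrc_df, panels, sub_groups, reference_group=case,
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(deg.table, out / "deg_table.tsv")
        write_table(filt.table, out / "deg_filtered.tsv")
        write_table(attribution.table, out / "attribution.tsv")
        write_table(marker_panels.table, out / "marker_panels.tsv")
        write_table(abundance.table, out / "abundance.tsv")
        write_table(verdicts, out / "verdicts.tsv")
        if cluster_out is not None:
            write_table(cluster_out["model"].assignment_table(), out / "clusters.tsv")
            write_table(cluster_out["intercluster"], out / "intercluster.tsv")
        if results.get("ora") is not None:
            write_table(results["ora"], out / "ora.tsv")
        if results.get("panel_table") is not None:
            write_table(results["panel_table"], out / "panels.tsv")
    return results
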