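"""Synthetic immune-cell-mixture cohorts with full ground truth.

Bulk whole-blood RNA-seq counts are modelled as a mixture over cell types:
the expected relative expression of gene ``g`` in sample ``s`` is

    x_gs  =  sum_c  pi_sc * ref_cg * reg_cg

where ``pi_sc`` are cell-type proportions, ``ref_cg`` the reference atlas
expression, and ``reg_cg`` a per-cell regulation factor (1 everywhere except
for perturbed genes in the target type of case samples).  Counts are drawn
negative-binomially with mean ``library_size * x_gs / sum_g x_gs`` and
variance ``mu + phi * mu**2``; dispersion ``phi = 0`` degenerates to Poisson.

Three scenario families mirror the two ways a gene can move in bulk blood:

* ``abundance_shift``   — the target cell type's mixing fraction is
  multiplied in case samples (then renormalized), so all of its transcripts
  move together;
* ``expression_shift``  — per-cell regulation of selected genes (by default
  the target type's exclusive markers, so the bulk fold approximately equals
  the per-cell fold);
* ``null`` / ``combined`` — no perturbation, or both at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import CountMatrix, ReferenceAtlas, SampleTable, logger

#: default immune cell types, mirroring the ~19 blood-atlas lineages
DEFAULT_CELL_TYPES = [
    "neutrophil",
    "basophil",
    "eosinophil",
    "classical_monocyte",
    "intermediate_monocyte",
    "non_classical_monocyte",
    "myeloid_dc",
    "plasmacytoid_dc",
    "naive_b",
    "memory_b",
    "plasmablast",
    "naive_cd4_t",
    "memory_cd4_t",
    "naive_cd8_t",
    "memory_cd8_t",
    "treg",
    "gd_t",
    "mait_t",
    "nk",
]


@dataclass
class ScenarioSpec:
    """Parameters of one simulated case/control cohort.

    kind                  null | abundance_shift | expression_shift | combined
    target_cell_type      cell type carrying the perturbation; ``None`` in
                          expression scenarios applies the per-cell fold in
                          every type, so the bulk fold equals the per-cell
                          fold exactly (a pure spike-in benchmark)
    abundance_multiplier  case-vs-control multiplier on the target type's
                          mixing fraction, applied before renormalization
    perturbed_gene_count  number of genes receiving the per-cell fold
    per_cell_fold         per-cell expression fold on perturbed genes
    n_per_group           samples per group (>= 2)
    library_size_mean     median library size (log-normal, sigma = 0.2)
    dispersion            NB dispersion phi >= 0 (0 = Poisson)
    perturb_shared        allow perturbed genes outside the target type's
                          exclusive markers (harder attribution cases)
    """

    kind: str = "null"
    target_cell_type: str | None = None
    abundance_multiplier: float = 1.0
    perturbed_gene_count: int = 10
    per_cell_fold: float = 1.0
    n_per_group: int = 20
    library_size_mean: float = 1e6
    dispersion: float = 0.1
    seed: int = 0
    perturb_shared: bool = False
    case_group: str = "inoca"

    def __post_init__(self) -> None:
        if self.kind not in ("null", "abundance_shift", "expression_shift", "combined"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.abundance_multiplier <= 0 or self.per_cell_fold <= 0:
            raise ValueError("multipliers and folds must be > 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did: realized per-sample proportions,
    perturbed genes with their true per-cell fold, and the scenario kind."""

    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    perturbed: dict[str, float]
    kind: str
    target_cell_type: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy()
        if (arr < 0).any():
            raise ValueError("ground-truth proportions must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ground-truth proportions must sum to 1 per sample")


def make_reference(
    n_cell_types: int = 19,
    n_genes: int = 2000,
    markers_per_type: int = 20,
    marker_enrichment: float = 1024.0,
    baseline_mean: float = 5.0,
    seed: int = 0,
    cell_type_names: list[str] | None = None,
) -> tuple[ReferenceAtlas, dict[str, list[str]]]:
    """Build a reference atlas with planted cell-type-exclusive markers.

    Every gene gets a shared log-normal baseline level (identical across
    cell types); each cell type additionally receives ``markers_per_type``
    exclusive marker genes whose expression in that type is exactly
    ``marker_enrichment`` times the next-highest type.  The default
    enrichment (1,024-fold, the magnitude reported for top neutrophil
    markers in blood atlases) makes planted markers effectively
    cell-exclusive, the regime in which marker averaging reads out cell
    abundance.  Returns the atlas and the marker truth (cell type ->
    marker gene ids).
    """
    if markers_per_type * n_cell_types > n_genes:
        raise ValueError(
            f"cannot plant {markers_per_type} markers x {n_cell_types} types "
            f"in {n_genes} genes"
        )
    if cell_type_names is None:
        if n_cell_types <= len(DEFAULT_CELL_TYPES):
            cell_type_names = DEFAULT_CELL_TYPES[:n_cell_types]
        else:
            cell_type_names = [f"cell_type_{i:02d}" for i in range(n_cell_types)]
    elif len(cell_type_names) != n_cell_types:
        raise ValueError("cell_type_names length must equal n_cell_types")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    baseline = baseline_mean * rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    expr = np.tile(baseline, (n_cell_types, 1))

    marker_genes = rng.choice(n_genes, size=markers_per_type * n_cell_types, replace=False)
    truth: dict[str, list[str]] = {}
    for c, ct in enumerate(cell_type_names):
        mine = marker_genes[c * markers_per_type : (c + 1) * markers_per_type]
        expr[c, mine] = marker_enrichment * baseline[mine]
        truth[ct] = sorted(gene_ids[g] for g in mine)

    atlas = ReferenceAtlas(list(cell_type_names), gene_ids, expr)
    # post-hoc check of the enrichment definition on every planted marker
    for c, ct in enumerate(cell_type_names):
        for g in truth[ct]:
            j = gene_ids.index(g)
            others = np.delete(expr[:, j], c)
            assert expr[c, j] >= marker_enrichment * others.max() - 1e-9
    return atlas, truth


def default_proportions(atlas: ReferenceAtlas) -> np.ndarray:
    """Neutrophil-dominant mixture (half the leukocytes, as in whole blood)
    when the atlas has a 'neutrophil' type; uniform otherwise."""
    types = atlas.specific_types
    k = len(types)
    if "neutrophil" in types and k > 1:
        p = np.full(k, 0.5 / (k - 1))
        p[types.index("neutrophil")] = 0.5
        return p
    return np.full(k, 1.0 / k)


def exclusive_markers(atlas: ReferenceAtlas, cell_type: str) -> list[str]:
    """Genes strictly maximal in ``cell_type`` versus all other types."""
    types = atlas.specific_types
    if cell_type not in types:
        raise ValueError(f"unknown cell type {cell_type!r}")
    c = types.index(cell_type)
    sub = atlas.expr[[atlas.cell_types.index(t) for t in types]]
    others = np.delete(sub, c, axis=0).max(axis=0)
    mask = sub[c] > others
    return [g for g, m in zip(atlas.gene_ids, mask) if m]


def simulate_cohort(
    atlas: ReferenceAtlas,
    spec: ScenarioSpec,
    base_proportions: np.ndarray | None = None,
    perturb_genes: list[str] | dict[str, float] | None = None,
    sex_effect: dict[str, float] | None = None,
) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    """Draw a two-group cohort (control vs. case) from the mixture model.

    ``base_proportions`` is the control-group mixing vector over the atlas's
    specific cell types (must sum to 1); the case group's target-type
    fraction is multiplied by ``spec.abundance_multiplier`` and the vector
    renormalized.  ``perturb_genes`` overrides the automatic choice of
    perturbed genes — a list (all at ``spec.per_cell_fold``) or a
    gene -> fold mapping.  ``sex_effect`` maps gene id -> fold applied to
    female samples (sexes alternate deterministically), for sex-stratified
    tests.
    """
    types = atlas.specific_types
    k = len(types)
    if base_proportions is None:
        base_proportions = default_proportions(atlas)
    base_proportions = np.asarray(base_proportions, dtype=float)
    if base_proportions.shape != (k,):
        raise ValueError(f"base_proportions must have length {k}")
    if not np.isclose(base_proportions.sum(), 1.0, atol=1e-8):
        raise ValueError("base_proportions must sum to 1")

    rng = np.random.default_rng(spec.seed)
    ref = atlas.expr[[atlas.cell_types.index(t) for t in types]]  # k x G
    gene_ids = atlas.gene_ids
    n_genes = len(gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # --- perturbed genes and per-cell regulation -------------------------
    perturbed: dict[str, float] = {}
    reg = np.ones((k, n_genes))
    wants_expr = spec.kind in ("expression_shift", "combined")
    if wants_expr and (spec.per_cell_fold != 1.0 or perturb_genes is not None):
        if perturb_genes is None:
            if spec.target_cell_type is None or spec.perturb_shared:
                pool = list(gene_ids)
            else:
                pool = exclusive_markers(atlas, spec.target_cell_type)
            if len(pool) < spec.perturbed_gene_count:
                raise ValueError(
                    f"only {len(pool)} candidate genes for "
                    f"{spec.perturbed_gene_count} perturbations"
                )
            perturbed = {
                g: spec.per_cell_fold
                for g in sorted(rng.choice(pool, size=spec.perturbed_gene_count, replace=False))
            }
        elif isinstance(perturb_genes, dict):
            perturbed = {g: float(f) for g, f in perturb_genes.items()}
        else:
            perturbed = {g: spec.per_cell_fold for g in perturb_genes}
        rows = (
            slice(None)
            if spec.target_cell_type is None
            else [types.index(spec.target_cell_type)]
        )
        for g, f in perturbed.items():
            reg[rows, gene_index[g]] = f

    # --- proportions per group ------------------------------------------
    ctrl_pi = base_proportions
    case_pi = base_proportions.copy()
    if spec.kind in ("abundance_shift", "combined") and spec.abundance_multiplier != 1.0:
        if spec.target_cell_type is None:
            raise ValueError("abundance_shift requires a target_cell_type")
        t = types.index(spec.target_cell_type)
        case_pi[t] *= spec.abundance_multiplier
        case_pi = case_pi / case_pi.sum()

    # --- expected relative expression per group --------------------------
    ctrl_x = ctrl_pi @ ref                      # control: no regulation
    case_x = case_pi @ (ref * reg)
    ctrl_x = ctrl_x / ctrl_x.sum()
    case_x = case_x / case_x.sum()

    n = spec.n_per_group
    sample_ids = [f"C{i:03d}" for i in range(n)] + [f"P{i:03d}" for i in range(n)]
    sexes = [("male", "female")[i % 2] for i in range(2 * n)]
    is_case = np.array([False] * n + [True] * n)

    lib = spec.library_size_mean * np.exp(0.2 * rng.standard_normal(2 * n))
    mu = np.empty((n_genes, 2 * n))
    for j in range(2 * n):
        x = case_x if is_case[j] else ctrl_x
        if sex_effect and sexes[j] == "female":
            x = x.copy()
            for g, f in sex_effect.items():
                x[gene_index[g]] *= f
            x = x / x.sum()
        mu[:, j] = lib[j] * x

    if spec.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / spec.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)

    cm = CountMatrix(list(gene_ids), sample_ids, counts)
    stress = "positive" if spec.case_group in ("inoca", "cad_stress_pos") else "negative"
    cad = "positive" if spec.case_group.startswith("cad") else "negative"
    meta = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "stress": ["negative"] * n + [stress] * n,
                "cad": ["negative"] * n + [cad] * n,
                "sex": sexes,
                "age": np.round(rng.normal(65, 10, size=2 * n), 1),
            }
        )
    )
    props = pd.DataFrame(
        np.vstack([np.tile(ctrl_pi, (n, 1)), np.tile(case_pi, (n, 1))]),
        index=sample_ids,
        columns=types,
    )
    truth = GroundTruth(
        proportions=props,
        perturbed=perturbed,
        kind=spec.kind,
        target_cell_type=spec.target_cell_type,
        extras={"library_sizes": dict(zip(sample_ids, lib)), "sex_effect": sex_effect or {}},
    )
    logger.debug(
        "simulated %s cohort: %d genes, %d samples, %d perturbed genes",
        spec.kind, n_genes, 2 * n, len(perturbed),
    )
    return cm, meta, truth


def expected_bulk_fold(
    atlas: ReferenceAtlas,
    spec: ScenarioSpec,
    base_proportions: np.ndarray,
    gene: str,
    perturb_genes: list[str] | None = None,
) -> float:
    """Closed-form case/control ratio of normalized relative expression for
    one gene under the mixture model — the oracle the simulator must match."""
    types = atlas.specific_types
    ref = atlas.expr[[atlas.cell_types.index(t) for t in types]]
    gi = atlas.gene_ids.index(gene)
    reg = np.ones_like(ref)
    if spec.kind in ("expression_shift", "combined") and perturb_genes:
        rows = slice(None) if spec.target_cell_type is None else [types.index(spec.target_cell_type)]
        folds = (
            perturb_genes
            if isinstance(perturb_genes, dict)
            else {g: spec.per_cell_fold for g in perturb_genes}
        )
        for g, f in folds.items():
            reg[rows, atlas.gene_ids.index(g)] = f
    case_pi = np.asarray(base_proportions, float).copy()
    if spec.kind in ("abundance_shift", "combined") and spec.abundance_multiplier != 1.0:
        t = types.index(spec.target_cell_type)
        case_pi[t] *= spec.abundance_multiplier
        case_pi /= case_pi.sum()
    ctrl_x = base_proportions @ ref
    case_x = case_pi @ (ref * reg)
    return float((case_x[gi] / case_x.sum()) / (ctrl_x[gi] / ctrl_x.sum()))


def simulate_correlated_blocks(
    block_sizes: tuple[int, int] = (10, 10),
    rho_within: float = 0.9,
    rho_between: float = -0.3,
    n_samples: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian expression with a planted two-block correlation structure
    (for cluster-recovery tests).  Returns (genes x samples frame, true
    block labels)."""
    m1, m2 = block_sizes
    p = m1 + m2
    corr = np.full((p, p), rho_between)
    corr[:m1, :m1] = rho_within
    corr[m1:, m1:] = rho_within
    np.fill_diagonal(corr, 1.0)
    # two-block matrices of this form are PSD for the defaults; verify anyway
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        raise ValueError("requested block correlation matrix is not PSD")
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(p))
    rng = np.random.default_rng(seed)
    z = L @ rng.standard_normal((p, n_samples))
    genes = [f"B{j:03d}" for j in range(p)]
    labels = np.array([0] * m1 + [1] * m2)
    return pd.DataFrame(z, index=genes, columns=[f"S{i:03d}" for i in range(n_samples)]), labels
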