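"""Synthetic cohorts with planted methylation subgroup structure.

Every input the subgrouping pipeline consumes can be generated here: a
probe x sample beta-value matrix with missingness, an HM450K-manifest-like
probe annotation, pathway gene sets, labeled single cells, bulk expression
mixed from cell-type signatures, and a clinical table with subgroup-dependent
survival. The generators plant known structure (subgroup labels, key genes,
co-methylation modules, cell-type proportions) and return it as ground truth
so that every stage of the analysis can be scored against what was planted.

Beta values are drawn from Beta distributions around subgroup-specific means,
which keeps the [0,1] support and gives marginals qualitatively similar to
methylation-array data. Co-methylation modules are induced by a shared latent
factor per module that perturbs the Beta mean. Missingness is missing
completely at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methylation import BetaMatrix, ProbeAnnotation

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "PathwayCollection",
    "LabeledCellMatrix",
    "generate_cohort",
    "generate_pathways",
    "generate_single_cell",
    "generate_bulk_expression",
    "generate_survival",
    "generate_comethylation_blocks",
    "luminal_a_preset",
    "luminal_b_preset",
    "write_cohort",
]

# Cell types used for the expression side of the cohort. "T_cell" is the
# cytotoxic compartment: GZMA/PRF1 are its reserved marker genes so the
# cytolytic-activity score has a planted correlate.
CELL_TYPES = ("T_cell", "B_cell", "Epithelial", "Macrophage", "Stromal")
CYTOTOXIC_TYPE = "T_cell"
MARKERS_PER_TYPE = 20

PROBES_PER_KEY_GENE = 3
DECOY_MODULE_SIZE = 15


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic tumor/normal methylation cohort.

    delta_beta is the promoter beta shift of key genes in the most-shifted
    subgroup; subgroup s receives the graded fraction 1 - 0.6*s/(k-1) of
    it, so tumors pooled against normals remain differential while any two
    subgroups stay separable on every key gene. ``n_modules`` counts the
    planted co-methylation modules: module 0 is the key-gene block, the
    rest are decoy differential modules of 15 genes each. beta_noise is the
    concentration of the Beta noise (larger = tighter around the mean).
    """

    n_tumor: int = 40
    n_normal: int = 20
    n_subgroups: int = 2
    subgroup_props: tuple[float, ...] | None = None
    n_probes: int = 500
    n_key_genes: int = 30
    n_modules: int = 2
    delta_beta: float = 0.3
    beta_noise: float = 50.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tumor, self.n_normal, self.n_probes, self.n_key_genes) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_subgroups < 2:
            raise ValueError("need at least 2 subgroups")
        props = self.subgroup_props
        if props is None:
            props = tuple([1.0 / self.n_subgroups] * self.n_subgroups)
            object.__setattr__(self, "subgroup_props", props)
        if len(props) != self.n_subgroups:
            raise ValueError("subgroup_props length must equal n_subgroups")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("subgroup_props must sum to 1")
        if not (0.0 < self.delta_beta <= 1.0):
            raise ValueError("delta_beta must lie in (0, 1]")
        if not (0.0 <= self.missing_rate <= 0.9):
            raise ValueError("missing_rate must lie in [0, 0.9]")
        if self.n_key_genes * PROBES_PER_KEY_GENE > self.n_probes:
            raise ValueError("n_probes too small for the requested key genes")
        # If every probe is expected to exceed the 50% missingness QC filter
        # the fixture would be empty after preprocessing.
        if self.missing_rate > 0.5:
            raise ValueError(
                "missing_rate > 0.5 would drop every probe at the default "
                "missingness filter"
            )


@dataclass
class GroundTruth:
    """What was planted: the answer key for every pipeline stage."""

    subgroup_of_sample: dict[str, int]
    key_gene_ids: list[str]
    planted_module_of_gene: dict[str, int]
    true_proportions: pd.DataFrame  # sample x cell type, rows on the simplex
    true_signature: pd.DataFrame  # gene x cell type, nonnegative

    def __post_init__(self) -> None:
        rowsums = self.true_proportions.sum(axis=1).to_numpy()
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("true_proportions rows must sum to 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subgroup_of_sample": self.subgroup_of_sample,
            "key_gene_ids": self.key_gene_ids,
            "planted_module_of_gene": self.planted_module_of_gene,
            "true_proportions": self.true_proportions.to_dict(orient="index"),
            "true_signature": self.true_signature.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        props = pd.DataFrame.from_dict(payload["true_proportions"], orient="index")
        sig = pd.DataFrame.from_dict(payload["true_signature"], orient="index")
        return cls(
            subgroup_of_sample=payload["subgroup_of_sample"],
            key_gene_ids=payload["key_gene_ids"],
            planted_module_of_gene={
                g: int(m) for g, m in payload["planted_module_of_gene"].items()
            },
            true_proportions=props,
            true_signature=sig,
        )


@dataclass
class PathwayCollection:
    """Named gene sets over a gene universe, GMT-serializable."""

    pathways: dict[str, set[str]]
    universe: set[str]
    cancer_related_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"pathway {name} has genes outside the universe")

    def write_gmt(self, path: str | Path) -> None:
        lines = []
        for name in sorted(self.pathways):
            genes = "\t".join(sorted(self.pathways[name]))
            desc = "cancer_related" if name in self.cancer_related_ids else "na"
            lines.append(f"{name}\t{desc}\t{genes}".rstrip("\t"))
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    @classmethod
    def read_gmt(cls, path: str | Path, universe: set[str] | None = None) -> "PathwayCollection":
        pathways: dict[str, set[str]] = {}
        cancer: set[str] = set()
        text = Path(path).read_text()
        for line in text.splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            name, desc, genes = fields[0], fields[1], set(fields[2:])
            pathways[name] = genes
            if desc == "cancer_related":
                cancer.add(name)
        if universe is None:
            universe = set().union(*pathways.values()) if pathways else set()
        return cls(pathways=pathways, universe=universe, cancer_related_ids=cancer)


@dataclass
class LabeledCellMatrix:
    """Single-cell expression with known cell-type labels (gene x cell)."""

    expression: pd.DataFrame
    cell_types: pd.Series  # index = cell ids, values = type labels

    def __post_init__(self) -> None:
        if not self.expression.columns.equals(self.cell_types.index):
            raise ValueError("cell labels must match expression columns")


def _subgroup_multipliers(k: int) -> np.ndarray:
    """Graded per-subgroup shift multipliers for the key-gene module.

    Subgroup s scales the key-gene shift by 1 - 0.6*s/(k-1), so every
    subgroup is shifted in the same direction per gene (tumors pooled
    against normals keep |mean shift| >= 0.7*delta_beta) while any two
    subgroups differ by at least 0.6*delta_beta/(k-1) on every key gene.
    All key genes share this one subgroup pattern, which is what
    co-methylates them into a single module across tumors.
    """
    s = np.arange(k, dtype=float)
    return 1.0 - 0.6 * s / (k - 1)


def generate_cohort(spec: CohortSpec) -> tuple[BetaMatrix, ProbeAnnotation, GroundTruth]:
    """Generate a tumor/normal beta matrix, its annotation, and ground truth.

    Key genes receive promoter probes whose beta mean is shifted (hyper- or
    hypomethylated, alternating by gene) in tumors relative to normals, with
    graded subgroup-dependent magnitude; they form planted module 0, whose
    co-methylation across tumors arises from the shared subgroup pattern.
    The remaining ``spec.n_modules - 1`` planted modules are "decoy"
    differential genes, shifted uniformly in all tumors and co-methylated
    through a per-module latent factor. Remaining probes share one
    background distribution. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_subgroups

    tumor_ids = [f"T{i:03d}" for i in range(spec.n_tumor)]
    normal_ids = [f"N{i:03d}" for i in range(spec.n_normal)]
    sample_ids = tumor_ids + normal_ids

    # subgroup labels: deterministic proportional allocation, then shuffled
    counts = np.floor(np.asarray(spec.subgroup_props) * spec.n_tumor).astype(int)
    while counts.sum() < spec.n_tumor:
        counts[int(np.argmax(np.asarray(spec.subgroup_props) * spec.n_tumor - counts))] += 1
    labels = np.repeat(np.arange(k), counts)
    rng.shuffle(labels)
    if len(set(labels.tolist())) < k:
        raise ValueError("n_tumor too small for the requested subgroup proportions")
    subgroup_of_sample = {s: int(l) for s, l in zip(tumor_ids, labels)}

    key_genes = [f"KEY{g:03d}" for g in range(spec.n_key_genes)]
    module_of_gene = {g: 0 for g in key_genes}
    decoy_genes: list[str] = []
    for m in range(1, spec.n_modules):
        for g in range(DECOY_MODULE_SIZE):
            gene = f"DEC{m}_{g:03d}"
            decoy_genes.append(gene)
            module_of_gene[gene] = m

    planted_genes = key_genes + decoy_genes
    n_planted_probes = len(planted_genes) * PROBES_PER_KEY_GENE
    n_bg_probes = spec.n_probes - n_planted_probes
    if n_bg_probes < 0:
        raise ValueError("n_probes too small for the planted modules")
    bg_genes = [f"BG{g:04d}" for g in range(max(1, n_bg_probes))]

    # --- annotation -------------------------------------------------------
    rows = []
    probe_idx = 0
    gene_tss: dict[str, tuple[str, int, str]] = {}
    all_genes = planted_genes + bg_genes
    for i, gene in enumerate(all_genes):
        chrom = f"chr{(i % 22) + 1}"
        tss = 100_000 + 10_000 * i
        strand = "+" if i % 2 == 0 else "-"
        gene_tss[gene] = (chrom, tss, strand)
    for gene in planted_genes:
        chrom, tss, strand = gene_tss[gene]
        # promoter offsets along transcription direction: -1500, -500, +200
        for off in (-1500, -500, 200):
            pos = tss + off if strand == "+" else tss - off
            rows.append((f"cg{probe_idx:07d}", chrom, pos, strand, gene, tss))
            probe_idx += 1
    bg_i = 0
    while probe_idx < spec.n_probes:
        gene = bg_genes[bg_i % len(bg_genes)]
        chrom, tss, strand = gene_tss[gene]
        off = int(rng.integers(-1800, 400))
        pos = tss + off if strand == "+" else tss - off
        rows.append((f"cg{probe_idx:07d}", chrom, pos, strand, gene, tss))
        probe_idx += 1
        bg_i += 1
    annotation = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "strand", "gene_symbol", "tss"]
    )

    # --- beta means -------------------------------------------------------
    n = len(sample_ids)
    nt = spec.n_tumor
    mean = np.empty((spec.n_probes, n))
    base = rng.uniform(0.35, 0.5, size=len(planted_genes))
    # hyper/hypo direction alternates by gene
    sign = np.where(np.arange(len(planted_genes)) % 2 == 0, 1.0, -1.0)
    mult = _subgroup_multipliers(k)
    pooled_mult = float(mult.mean())  # decoys use the same pooled magnitude

    # Latent factor per decoy module and sample induces intra-module
    # correlation. It is centered within the tumor and normal groups so it
    # never biases tumor-vs-normal mean differences.
    latent = rng.normal(0.0, 1.0, size=(spec.n_modules, n))
    latent[:, :nt] -= latent[:, :nt].mean(axis=1, keepdims=True)
    latent[:, nt:] -= latent[:, nt:].mean(axis=1, keepdims=True)
    latent_load = 0.06

    for g, gene in enumerate(planted_genes):
        mod = module_of_gene[gene]
        shift = np.zeros(n)
        for j, sid in enumerate(tumor_ids):
            if mod == 0:
                shift[j] = sign[g] * spec.delta_beta * mult[subgroup_of_sample[sid]]
            else:
                shift[j] = sign[g] * spec.delta_beta * pooled_mult
        gene_mean = base[g] + shift
        if mod > 0:
            gene_mean = gene_mean + latent_load * latent[mod]
        for p in range(PROBES_PER_KEY_GENE):
            mean[g * PROBES_PER_KEY_GENE + p] = gene_mean
    bg_base = rng.uniform(0.2, 0.8, size=max(0, n_bg_probes))
    for i in range(n_bg_probes):
        mean[n_planted_probes + i] = bg_base[i]
    mean = np.clip(mean, 0.02, 0.98)

    nu = spec.beta_noise
    values = rng.beta(mean * nu, (1.0 - mean) * nu)

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.copy()
        values[mask] = np.nan

    beta = BetaMatrix(
        values=pd.DataFrame(values, index=annotation["probe_id"].tolist(), columns=sample_ids),
        sample_groups={**{s: "tumor" for s in tumor_ids}, **{s: "normal" for s in normal_ids}},
    )

    # --- expression-side ground truth ------------------------------------
    signature = _make_signature(rng)
    proportions = _make_proportions(rng, tumor_ids, subgroup_of_sample, k)

    truth = GroundTruth(
        subgroup_of_sample=subgroup_of_sample,
        key_gene_ids=key_genes,
        planted_module_of_gene=module_of_gene,
        true_proportions=proportions,
        true_signature=signature,
    )
    return beta, ProbeAnnotation(annotation), truth


def _make_signature(rng: np.random.Generator) -> pd.DataFrame:
    """Block signature: each cell type expresses its own marker block."""
    genes: list[str] = []
    for ct in CELL_TYPES:
        genes.extend(f"{ct}_MK{i:02d}" for i in range(MARKERS_PER_TYPE))
    genes += ["GZMA", "PRF1", "PDCD1", "CD274"]
    sig = pd.DataFrame(
        rng.uniform(0.0, 0.3, size=(len(genes), len(CELL_TYPES))),
        index=genes,
        columns=list(CELL_TYPES),
    )
    for t, ct in enumerate(CELL_TYPES):
        block = [f"{ct}_MK{i:02d}" for i in range(MARKERS_PER_TYPE)]
        sig.loc[block, ct] = rng.uniform(5.0, 10.0, size=len(block))
    # cytolytic effectors and checkpoint genes track the T-cell compartment
    sig.loc[["GZMA", "PRF1", "PDCD1", "CD274"], CYTOTOXIC_TYPE] = rng.uniform(
        6.0, 9.0, size=4
    )
    return sig


def _make_proportions(
    rng: np.random.Generator,
    tumor_ids: list[str],
    subgroup_of_sample: dict[str, int],
    k: int,
) -> pd.DataFrame:
    """Dirichlet cell-type proportions with subgroup-dependent centers.

    Subgroup 0 is immune-enriched (high T-cell fraction), subgroup 1 is
    epithelial-enriched, further subgroups are balanced.
    """
    base = np.full(len(CELL_TYPES), 2.0)
    t_idx = CELL_TYPES.index(CYTOTOXIC_TYPE)
    e_idx = CELL_TYPES.index("Epithelial")
    centers = []
    for s in range(k):
        alpha = base.copy()
        if s == 0:
            alpha[t_idx] = 14.0
        elif s == 1:
            alpha[e_idx] = 14.0
        centers.append(alpha * 4.0)  # concentration keeps groups distinct
    rows = [rng.dirichlet(centers[subgroup_of_sample[sid]]) for sid in tumor_ids]
    return pd.DataFrame(rows, index=tumor_ids, columns=list(CELL_TYPES))


def generate_pathways(
    truth: GroundTruth,
    n_pathways: int = 12,
    overlap: float = 0.6,
    pathway_size: int = 15,
    universe: set[str] | None = None,
    target_module: int = 0,
    seed: int = 0,
) -> PathwayCollection:
    """Gene sets where a 'cancer-related' third is enriched for planted genes.

    Each cancer-related pathway draws ``overlap * pathway_size`` genes from
    planted module ``target_module`` (default: the key-gene module) and the
    rest from the universe; other pathways are uniform draws.
    """
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = set(truth.key_gene_ids) | {f"BG{g:04d}" for g in range(200)}
    universe_list = sorted(universe)
    if pathway_size > len(universe_list):
        raise ValueError("pathway_size exceeds the gene universe")

    modules: dict[int, list[str]] = {}
    for g, m in truth.planted_module_of_gene.items():
        modules.setdefault(m, []).append(g)
    for m in modules:
        modules[m].sort()

    pathways: dict[str, set[str]] = {}
    cancer_ids: set[str] = set()
    n_cancer = max(1, n_pathways // 3) if n_pathways else 0
    for i in range(n_pathways):
        name = f"PW{i:03d}"
        if i < n_cancer:
            mod_genes = modules[target_module]
            n_planted = int(round(overlap * pathway_size))
            if n_planted > len(mod_genes):
                raise ValueError(
                    f"overlap {overlap} needs {n_planted} planted genes but "
                    f"module has only {len(mod_genes)}"
                )
            chosen = set(
                rng.choice(mod_genes, size=n_planted, replace=False).tolist()
            )
            rest = [g for g in universe_list if g not in chosen]
            chosen |= set(
                rng.choice(rest, size=pathway_size - n_planted, replace=False).tolist()
            )
            cancer_ids.add(name)
        else:
            chosen = set(
                rng.choice(universe_list, size=pathway_size, replace=False).tolist()
            )
        pathways[name] = chosen
    return PathwayCollection(pathways=pathways, universe=set(universe_list), cancer_related_ids=cancer_ids)


def generate_single_cell(
    truth: GroundTruth,
    cells_per_type: int = 50,
    dispersion: float = 0.3,
    seed: int = 0,
) -> LabeledCellMatrix:
    """Labeled cells: each cell is its type's signature column with
    multiplicative lognormal-style noise (mean-one), clipped at zero."""
    if cells_per_type < 2:
        raise ValueError("need at least 2 cells per type for marker testing")
    sig = truth.true_signature
    if sig.shape[1] < 2:
        raise ValueError("signature must carry at least 2 cell types")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for ct in sig.columns:
        base = sig[ct].to_numpy()
        for c in range(cells_per_type):
            cid = f"{ct}_c{c:03d}"
            if dispersion > 0:
                noise = np.exp(rng.normal(-0.5 * dispersion**2, dispersion, size=base.shape))
            else:
                noise = 1.0
            cols[cid] = np.clip(base * noise, 0.0, None)
            labels[cid] = ct
    expr = pd.DataFrame(cols, index=sig.index)
    return LabeledCellMatrix(expression=expr, cell_types=pd.Series(labels))


def generate_bulk_expression(
    truth: GroundTruth, noise_sd: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Bulk gene x sample expression: signature . proportions^T + noise, >= 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    sig = truth.true_signature
    props = truth.true_proportions
    if list(sig.columns) != list(props.columns):
        raise ValueError("signature and proportions cell types must match")
    rng = np.random.default_rng(seed)
    bulk = sig.to_numpy() @ props.to_numpy().T
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd, size=bulk.shape)
    bulk = np.clip(bulk, 0.0, None)
    return pd.DataFrame(bulk, index=sig.index, columns=props.index)


def _uniform_censor_bound(hazard: float, censor_rate: float) -> float:
    """Upper bound b of U(0,b) censoring giving the target censor fraction.

    For T ~ Exp(hazard) and independent C ~ U(0,b),
    P(C < T) = (1 - exp(-hazard*b)) / (hazard*b); solved for b by bisection.
    """
    from scipy.optimize import brentq

    f = lambda b: (1.0 - np.exp(-hazard * b)) / (hazard * b) - censor_rate
    # f decreases from 1 at b->0 to 0 as b->inf
    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(f, lo, hi)


def generate_survival(
    truth: GroundTruth,
    hazard_by_subgroup: dict[int, float] | None = None,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical table with exponential event times per subgroup hazard,
    independent uniform censoring, and subgroup-dependent T/N/M stages.

    Returns a DataFrame with columns sample_id, time, event, stage_T,
    stage_N, stage_M, subgroup.
    """
    samples = sorted(truth.subgroup_of_sample)
    k = max(truth.subgroup_of_sample.values()) + 1
    if hazard_by_subgroup is None:
        hazard_by_subgroup = {s: 1.0 / 365.0 for s in range(k)}
    if any(h <= 0 for h in hazard_by_subgroup.values()):
        raise ValueError("hazards must be positive")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    t_levels = ["T1", "T2", "T3", "T4"]
    n_levels = ["N0", "N1", "N2"]
    m_levels = ["M0", "M1"]

    def stage_probs(levels: list[str], s: int) -> np.ndarray:
        # later subgroups skew toward higher stages
        w = np.arange(1, len(levels) + 1, dtype=float)
        skew = 1.0 + 0.8 * s / max(1, k - 1)
        p = w ** (skew - 1.0)
        p = p[::-1] if s == 0 else p
        return p / p.sum()

    rows = []
    for sid in samples:
        s = truth.subgroup_of_sample[sid]
        h = hazard_by_subgroup[s]
        t_event = rng.exponential(1.0 / h)
        if censor_rate > 0:
            b = _uniform_censor_bound(h, censor_rate)
            c = rng.uniform(0.0, b)
            time = min(t_event, c)
            event = int(t_event <= c)
        else:
            time, event = t_event, 1
        rows.append(
            {
                "sample_id": sid,
                "time": float(time),
                "event": event,
                "stage_T": rng.choice(t_levels, p=stage_probs(t_levels, s)),
                "stage_N": rng.choice(n_levels, p=stage_probs(n_levels, s)),
                "stage_M": rng.choice(m_levels, p=stage_probs(m_levels, s)),
                "subgroup": s,
            }
        )
    return pd.DataFrame(rows)


def generate_comethylation_blocks(
    n_blocks: int = 3,
    genes_per_block: int = 40,
    n_samples: int = 30,
    intra_cor: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x sample methylation-like values with block-correlated genes.

    Each block shares a latent factor: x = sqrt(rho)*z_block +
    sqrt(1-rho)*noise, mapped affinely into [0,1]. Inter-block correlation
    is zero by construction. Returns (matrix, true block labels).
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_blocks, n_samples))
    rows, labels = [], {}
    for b in range(n_blocks):
        for g in range(genes_per_block):
            gene = f"B{b}_G{g:03d}"
            x = np.sqrt(intra_cor) * z[b] + np.sqrt(1 - intra_cor) * rng.normal(size=n_samples)
            rows.append(np.clip(0.5 + 0.12 * x, 0.0, 1.0))
            labels[gene] = b
    genes = list(labels)
    return pd.DataFrame(rows, index=genes, columns=[f"S{i:03d}" for i in range(n_samples)]), pd.Series(labels)


def luminal_a_preset(seed: int = 0, **overrides) -> CohortSpec:
    """Two planted subgroups (immune- vs epithelial-enriched), desk scale."""
    kw = dict(n_tumor=40, n_normal=20, n_subgroups=2, n_probes=500,
              n_key_genes=30, delta_beta=0.3, missing_rate=0.05, seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def luminal_b_preset(seed: int = 0, **overrides) -> CohortSpec:
    """Three planted subgroups, desk scale."""
    kw = dict(n_tumor=48, n_normal=20, n_subgroups=3, n_probes=500,
              n_key_genes=30, delta_beta=0.3, missing_rate=0.05, seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def write_cohort(
    outdir: str | Path,
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    truth: GroundTruth,
) -> None:
    """Serialize a cohort to TSV/JSON files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    beta.values.to_csv(outdir / "beta.tsv", sep="\t", na_rep="NA")
    pd.Series(beta.sample_groups, name="group").rename_axis("sample_id").to_csv(
        outdir / "sample_groups.tsv", sep="\t"
    )
    annotation.table.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    truth.to_json(outdir / "ground_truth.json")
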