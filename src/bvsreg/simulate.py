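"""GAW17-like synthetic genotype/phenotype simulator with known truth.

The simulator emulates the structure of the GAW17 mini-exome: a fixed
dosage matrix over unrelated individuals (697 by default), a minor-allele
frequency spectrum spanning very rare to common (0.0717% to 49.9283% by
default, log-uniform so the rare tail is well populated), SNPs partitioned
into contiguous gene blocks, and many phenotype replications drawn over the
one fixed genotype matrix.  Three trait presets mirror the workshop traits:

* ``q1`` — 39 causal SNPs in 9 genes;
* ``q2`` — 72 causal SNPs in 13 genes;
* ``q4`` — a null trait, no causal SNPs (h2 = 0).

Genotypes are Binomial(2, MAF) per individual (Hardy-Weinberg, no linkage
disequilibrium between columns); an optional duplicate-column injector
creates the perfect-LD false-positive scenario that identical coding SNPs
produce in real exomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import GenotypeMatrix, PhenotypeSet, TruthTable
from .exceptions import DesignError

__all__ = [
    "SimDesign",
    "simulate_genotypes",
    "assign_causal_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "pick_causal_snps",
    "recovery_truth",
    "inject_duplicate",
    "q1_design",
    "q2_design",
    "q4_design",
]

GAW17_N = 697
GAW17_P = 24_487
GAW17_MAF_RANGE = (0.000717, 0.499283)


@dataclass
class SimDesign:
    """Parameters of one simulated study.

    ``causal_spec`` lists (gene_index, n_causal) pairs; effect sizes are
    assigned by ``effect_mode``: ``"inverse_maf"`` scales |beta| by
    1/sqrt(2 MAF (1-MAF)) so every causal SNP explains an equal share of
    the genetic variance (rare variants get larger per-allele effects),
    ``"log_uniform"`` draws |beta| log-uniformly from ``effect_range`` with
    random sign.  ``h2`` is the proportion of phenotypic variance explained
    by all causal SNPs jointly; phenotypes are scaled to unit variance in
    expectation.
    """

    n_individuals: int = GAW17_N
    n_snps: int = GAW17_P
    maf_range: tuple[float, float] = GAW17_MAF_RANGE
    rare_fraction: float = 0.5
    n_genes: int | None = None
    causal_spec: list[tuple[int, int]] = field(default_factory=list)
    effect_mode: str = "inverse_maf"
    effect_range: tuple[float, float] = (0.3, 1.0)
    h2: float = 0.4
    n_replicates: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5 + 1e-12):
            raise DesignError("need 0 < maf_lo <= maf_hi <= 0.5")
        if not (0.0 <= self.rare_fraction <= 1.0):
            raise DesignError("rare_fraction must be in [0, 1]")
        if self.rare_fraction > 0 and lo >= 0.01:
            raise DesignError(
                "rare_fraction > 0 requires the MAF range to reach below 0.01"
            )
        if not (0.0 <= self.h2 < 1.0):
            raise DesignError("h2 must lie in [0, 1)")
        if self.n_genes is None:
            # GAW17 averages ~8 SNPs per gene
            self.n_genes = max(1, round(self.n_snps / 8))
        if self.n_genes > self.n_snps:
            raise DesignError("more genes than SNPs")
        if self.h2 == 0 and self.causal_spec:
            raise DesignError("a null trait (h2 = 0) cannot have causal SNPs")


def _distribute(total: int, n_bins: int) -> list[int]:
    """Split `total` into n_bins near-equal integer parts (larger first)."""
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def _gene_blocks(n_snps: int, n_genes: int) -> np.ndarray:
    sizes = _distribute(n_snps, n_genes)
    return np.repeat([f"GENE{g + 1}" for g in range(n_genes)], sizes)


def _trait_design(n_causal: int, n_causal_genes: int, overrides) -> SimDesign:
    d = SimDesign(causal_spec=[], h2=overrides.pop("h2", 0.4), **overrides)
    if "n_genes" in overrides and d.n_genes < n_causal_genes:
        raise DesignError(
            f"preset needs at least {n_causal_genes} genes, got {d.n_genes}"
        )
    if d.n_genes < n_causal_genes:
        d = replace(d, n_genes=n_causal_genes)
    counts = _distribute(n_causal, n_causal_genes)
    return replace(d, causal_spec=[(g, c) for g, c in enumerate(counts)])


def q1_design(**overrides) -> SimDesign:
    """Q1-like preset: 39 causal SNPs spread over 9 genes."""
    return _trait_design(39, 9, overrides)


def q2_design(**overrides) -> SimDesign:
    """Q2-like preset: 72 causal SNPs spread over 13 genes."""
    return _trait_design(72, 13, overrides)


def q4_design(**overrides) -> SimDesign:
    """Q4-like preset: a null trait with no causal SNPs."""
    overrides.pop("h2", None)
    return SimDesign(causal_spec=[], h2=0.0, **overrides)


PRESETS = {"q1": q1_design, "q2": q2_design, "q4": q4_design}


def _draw_mafs(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    """Log-uniform MAFs with `rare_fraction` of SNPs forced below 1%."""
    lo, hi = design.maf_range
    p = design.n_snps
    n_rare = int(round(design.rare_fraction * p))
    if n_rare > 0 and lo >= 0.01:
        raise DesignError("cannot place rare SNPs: MAF lower bound >= 0.01")
    mafs = np.empty(p)
    if n_rare > 0:
        rare_hi = min(0.01, hi)
        mafs[:n_rare] = np.exp(
            rng.uniform(np.log(lo), np.log(rare_hi), size=n_rare)
        )
    common_lo = max(lo, 0.01) if n_rare > 0 else lo
    if p - n_rare > 0 and common_lo > hi:
        raise DesignError("cannot place common SNPs: MAF range entirely below 1%")
    mafs[n_rare:] = np.exp(
        rng.uniform(np.log(common_lo), np.log(hi), size=p - n_rare)
    )
    return rng.permutation(mafs)


def simulate_genotypes(
    design: SimDesign, rng: np.random.Generator
) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw the fixed dosage matrix and a truth-table skeleton.

    Dosages are Binomial(2, MAF) per individual under Hardy-Weinberg;
    columns that come out monomorphic are redrawn up to 10 times, then
    kept as-is.  The returned truth table has the true MAFs and gene
    labels but no causal SNPs yet (see :func:`assign_causal_effects`).
    """
    n, p = design.n_individuals, design.n_snps
    mafs = _draw_mafs(design, rng)
    X = rng.binomial(2, mafs, size=(n, p)).astype(np.int8)
    for _ in range(10):
        mono = X.var(axis=0) == 0
        if not mono.any():
            break
        X[:, mono] = rng.binomial(2, mafs[mono], size=(n, int(mono.sum())))
    genes = _gene_blocks(p, design.n_genes)
    snp_ids = np.array([f"S{j + 1}" for j in range(p)], dtype=object)
    geno = GenotypeMatrix(
        X=X,
        snp_ids=snp_ids,
        individual_ids=np.array([f"IND{i + 1}" for i in range(n)], dtype=object),
        gene=genes,
    )
    truth = TruthTable(
        snp_id=snp_ids,
        gene=genes.astype(object),
        is_causal=np.zeros(p, dtype=bool),
        effect=np.zeros(p),
        maf=mafs,
    )
    return geno, truth


def assign_causal_effects(
    geno: GenotypeMatrix,
    truth: TruthTable,
    design: SimDesign,
    rng: np.random.Generator,
) -> TruthTable:
    """Mark causal SNPs per ``design.causal_spec`` and draw relative effects.

    Within each listed gene the requested number of polymorphic SNPs is
    chosen at random.  Effects here are *relative*; they are rescaled to
    hit ``design.h2`` by :func:`simulate_phenotypes`.
    """
    genes = np.asarray(truth.gene)
    gene_names = [f"GENE{g + 1}" for g in range(design.n_genes)]
    is_causal = np.zeros(len(truth.snp_id), dtype=bool)
    effect = np.zeros(len(truth.snp_id))
    poly = ~geno.monomorphic
    for gene_idx, n_causal in design.causal_spec:
        if gene_idx >= design.n_genes:
            raise DesignError(f"causal gene index {gene_idx} out of range")
        pool = np.flatnonzero((genes == gene_names[gene_idx]) & poly)
        if len(pool) < n_causal:
            raise DesignError(
                f"gene {gene_names[gene_idx]} has {len(pool)} usable SNPs, "
                f"needs {n_causal}"
            )
        chosen = rng.choice(pool, size=n_causal, replace=False)
        is_causal[chosen] = True
    idx = np.flatnonzero(is_causal)
    if design.effect_mode == "inverse_maf":
        m = truth.maf[idx]
        mag = 1.0 / np.sqrt(2.0 * m * (1.0 - m))
    elif design.effect_mode == "log_uniform":
        lo, hi = design.effect_range
        mag = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(idx)))
    else:
        raise DesignError(f"unknown effect_mode {design.effect_mode!r}")
    effect[idx] = mag * rng.choice([-1.0, 1.0], size=len(idx))
    return TruthTable(
        snp_id=truth.snp_id,
        gene=truth.gene,
        is_causal=is_causal,
        effect=effect,
        maf=truth.maf,
    )


def simulate_phenotypes(
    geno: GenotypeMatrix,
    truth: TruthTable,
    design: SimDesign,
    rng: np.random.Generator,
) -> tuple[PhenotypeSet, TruthTable]:
    """Draw ``n_replicates`` phenotype vectors over the fixed genotypes.

    The genetic value g = X beta is computed once; per replicate only the
    environmental noise is re-drawn, mirroring the GAW17 replication
    design.  Relative effects are rescaled so Var(g) = h2 and the noise
    variance is 1 - h2, giving Var(y) = 1 in expectation; the returned
    truth table carries the rescaled effects actually used.
    """
    beta = truth.effect.copy()
    if design.h2 > 0:
        if truth.n_causal == 0:
            raise DesignError("h2 > 0 requires causal SNPs in the truth table")
        g = geno.X.astype(np.float64) @ beta
        var_g = float(np.var(g))
        if var_g <= 0:
            raise DesignError("causal SNPs carry no genotypic variance")
        scale = np.sqrt(design.h2 / var_g)
        beta *= scale
        g *= scale
        sigma_e = np.sqrt(1.0 - design.h2)
    else:
        if truth.n_causal > 0:
            raise DesignError("null trait (h2 = 0) requires an empty causal set")
        g = np.zeros(geno.n_individuals)
        sigma_e = 1.0
    Y = g[:, None] + rng.normal(0.0, sigma_e, size=(geno.n_individuals, design.n_replicates))
    var_y = Y.var(axis=0)
    realized_h2 = np.divide(
        float(np.var(g)), var_y, out=np.zeros_like(var_y), where=var_y > 0
    )
    phenos = PhenotypeSet(
        Y=Y, individual_ids=geno.individual_ids, realized_h2=realized_h2
    )
    scaled_truth = TruthTable(
        snp_id=truth.snp_id,
        gene=truth.gene,
        is_causal=truth.is_causal,
        effect=beta,
        maf=truth.maf,
    )
    return phenos, scaled_truth


def simulate_dataset(
    preset_or_design: str | SimDesign,
    seed: int | None = None,
    **overrides,
) -> tuple[GenotypeMatrix, TruthTable, PhenotypeSet]:
    """One-call simulation: genotypes, scaled truth and phenotype replicates."""
    if isinstance(preset_or_design, str):
        try:
            design = PRESETS[preset_or_design](**overrides)
        except KeyError:
            raise DesignError(
                f"unknown preset {preset_or_design!r}; choose from {sorted(PRESETS)}"
            ) from None
    else:
        design = preset_or_design
    rng = np.random.default_rng(seed if seed is not None else design.seed)
    geno, skeleton = simulate_genotypes(design, rng)
    if design.causal_spec:
        skeleton = assign_causal_effects(geno, skeleton, design, rng)
    phenos, truth = simulate_phenotypes(geno, skeleton, design, rng)
    return geno, truth, phenos


def pick_causal_snps(
    geno: GenotypeMatrix,
    n_common: int,
    n_rare: int,
    rng: np.random.Generator,
    common_maf: tuple[float, float] = (0.05, 0.5),
    rare_maf: tuple[float, float] = (0.004, 0.01),
) -> tuple[np.ndarray, np.ndarray]:
    """Pick causal columns by empirical MAF band (common vs rare)."""
    maf = geno.maf
    poly = ~geno.monomorphic
    common_pool = np.flatnonzero(poly & (maf >= common_maf[0]) & (maf <= common_maf[1]))
    rare_pool = np.flatnonzero(poly & (maf >= rare_maf[0]) & (maf < rare_maf[1]))
    if len(common_pool) < n_common or len(rare_pool) < n_rare:
        raise DesignError(
            f"not enough SNPs in the requested MAF bands "
            f"(common {len(common_pool)}/{n_common}, rare {len(rare_pool)}/{n_rare})"
        )
    common = rng.choice(common_pool, size=n_common, replace=False)
    rare = rng.choice(rare_pool, size=n_rare, replace=False)
    return common, rare


def recovery_truth(
    geno: GenotypeMatrix,
    truth_skeleton: TruthTable,
    rng: np.random.Generator,
    n_common: int = 5,
    n_rare: int = 5,
    common_share: float = 0.07,
    rare_share: float = 0.01,
) -> tuple[TruthTable, np.ndarray, np.ndarray]:
    """Truth table for recovery studies: strong common + weak rare causal SNPs.

    Each common causal SNP is given a relative effect sized to explain
    ``common_share`` of phenotypic variance and each rare one
    ``rare_share`` (use h2 = n_common*common_share + n_rare*rare_share in
    the design so :func:`simulate_phenotypes` preserves these shares).
    Returns the truth plus the common and rare causal column indices.
    """
    common, rare = pick_causal_snps(geno, n_common, n_rare, rng)
    maf = geno.maf
    effect = np.zeros(geno.n_snps)
    for idx, share in ((common, common_share), (rare, rare_share)):
        var_x = 2.0 * maf[idx] * (1.0 - maf[idx])
        effect[idx] = np.sqrt(share / var_x) * rng.choice([-1.0, 1.0], size=len(idx))
    is_causal = effect != 0
    truth = TruthTable(
        snp_id=truth_skeleton.snp_id,
        gene=truth_skeleton.gene,
        is_causal=is_causal,
        effect=effect,
        maf=truth_skeleton.maf,
    )
    return truth, common, rare


def inject_duplicate(
    geno: GenotypeMatrix, truth: TruthTable, snp_index: int, new_id: str | None = None
) -> tuple[GenotypeMatrix, TruthTable]:
    """Append an exact copy of one column (a perfect-LD pair).

    Mimics identical coding SNPs (e.g. a synonymous twin of a causal
    variant) that produce rank-based false positives: the copy is marked
    non-causal in the truth table.
    """
    if not (0 <= snp_index < geno.n_snps):
        raise DesignError(f"snp_index {snp_index} out of range")
    new_id = new_id or f"{geno.snp_ids[snp_index]}_dup"
    X = np.column_stack([geno.X, geno.X[:, snp_index]])
    geno2 = GenotypeMatrix(
        X=X,
        snp_ids=np.append(geno.snp_ids, new_id),
        individual_ids=geno.individual_ids,
        gene=None if geno.gene is None else np.append(geno.gene, geno.gene[snp_index]),
    )
    truth2 = TruthTable(
        snp_id=np.append(truth.snp_id, new_id),
        gene=np.append(truth.gene, truth.gene[snp_index]),
        is_causal=np.append(truth.is_causal, False),
        effect=np.append(truth.effect, 0.0),
        maf=np.append(truth.maf, truth.maf[snp_index]),
    )
    return geno2, truth2
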