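"""Forward simulator: LD-structured founders, gene dropping, QTL and traits.

Founder gametes are drawn from a latent first-order Gaussian process along
each chromosome: gamete g carries a standard-normal latent x_j with
autocorrelation rho_j = adjacent_corr**(gap_bp / corr_ref_dist_bp) between
neighboring SNPs, and the allele is 1 when x_j falls below the SNP's own
frequency quantile. Marginal allele frequencies therefore follow the
configured spectrum exactly — including rare variants embedded in common
haplotype backgrounds (high D', low r2, as in real data) — while LD decays
monotonically with distance through the latent autocorrelation. Offspring are
produced by random mating with allele dropping; crossovers per meiosis
follow a binomial map function with an expectation of one crossover per
Morgan. Traits: standard-normal QTL effects rescaled so the cohort's true
breeding values (TBV) have unit variance, plus normal residuals sized for
the target heritability (h2 = 0.5 gives unit-variance residuals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import (
    GenotypeMatrix,
    HaplotypePanel,
    MarkerMap,
    WindowPartition,
    build_md_panel,
    build_window_partition,
    center_genotypes,
    mask_qtl_from_panel,
)

__all__ = [
    "FounderConfig",
    "MeiosisModel",
    "TraitArchitecture",
    "PhenotypeSet",
    "ScenarioConfig",
    "Replicate",
    "HD_LD",
    "MD_LD",
    "generate_founder_haplotypes",
    "draw_crossover_positions",
    "simulate_meiosis",
    "drop_genes",
    "select_qtl",
    "simulate_trait",
    "make_replicate",
]


# Latent autocorrelations calibrated so the founder panel reproduces the
# adjacent-LD levels typical of dense (~0.57 r2 at 4.4 kb spacing) and
# sparse (~0.24 r2 at 50.5 kb spacing) bovine SNP panels.
HD_LD = {"adjacent_corr": 0.95, "corr_ref_dist_bp": 4400}
MD_LD = {"adjacent_corr": 0.56, "corr_ref_dist_bp": 50500}


@dataclass
class FounderConfig:
    """Synthetic founder population (stand-in for real genotyped founders)."""

    n_founders: int = 948
    chrom_lengths_bp: tuple = (10_000_000,)
    snps_per_chrom: tuple = (2272,)
    adjacent_corr: float = 0.95
    corr_ref_dist_bp: int = 4400
    maf_beta_a: float = 0.6
    maf_beta_b: float = 0.6
    freq_corr: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_lengths_bp) != len(self.snps_per_chrom):
            raise ValueError("chrom_lengths_bp and snps_per_chrom lengths differ")
        if not 0.0 <= self.adjacent_corr < 1.0:
            raise ValueError("adjacent_corr must lie in [0, 1)")
        if not 0.0 <= self.freq_corr < 1.0:
            raise ValueError("freq_corr must lie in [0, 1)")
        if self.corr_ref_dist_bp <= 0:
            raise ValueError("corr_ref_dist_bp must be positive")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")


@dataclass
class MeiosisModel:
    """Genetic map scaling and the binomial map-function parameter.

    Crossover count on a chromosome of genetic length L Morgans is
    Binomial(N, L/N) so the expectation is one crossover per Morgan.
    binomial_N=None sizes N as ceil(10*L) per chromosome.
    """

    cm_per_mb: float = 1.0
    binomial_N: int | None = None

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")
        if self.binomial_N is not None and self.binomial_N < 1:
            raise ValueError("binomial_N must be positive")

    def length_morgans(self, span_bp: int) -> float:
        return span_bp * self.cm_per_mb / 1e8

    def n_for(self, L: float) -> int:
        if self.binomial_N is not None:
            n = self.binomial_N
        else:
            n = max(1, math.ceil(10.0 * L))
        if L > n:
            raise ValueError(
                f"binomial success probability L/N = {L / n:.3f} exceeds 1"
            )
        return n


@dataclass
class TraitArchitecture:
    """QTL positions, standardized effects and per-individual TBV."""

    qtl_index: np.ndarray
    qtl_effect: np.ndarray
    tbv: np.ndarray
    V_A: float  # realized additive variance of the raw (unstandardized) TBV

    @property
    def s(self) -> int:
        return len(self.qtl_index)


@dataclass
class PhenotypeSet:
    y: np.ndarray
    h2_target: float
    V_E: float


def generate_founder_haplotypes(cfg: FounderConfig) -> HaplotypePanel:
    """Draw 2*n_founders gametes from the latent-AR(1) threshold process.

    Per chromosome, each gamete's latent path is x_j = rho_j x_{j-1} +
    sqrt(1 - rho_j^2) eps with rho_j = adjacent_corr**(gap_j/ref); the
    allele is the indicator x_j < Phi^{-1}(f_j), so the marginal frequency
    of SNP j is exactly its drawn founder frequency f_j.
    """
    if sum(cfg.snps_per_chrom) == 0:
        raise ValueError("zero SNPs requested")
    from scipy.stats import norm

    rng = np.random.default_rng(cfg.seed)
    n_gam = 2 * cfg.n_founders
    all_chrom, all_pos, cols = [], [], []
    for c, (length, n_snp) in enumerate(
        zip(cfg.chrom_lengths_bp, cfg.snps_per_chrom), start=1
    ):
        if n_snp == 0:
            continue
        pos = np.sort(rng.choice(length, size=n_snp, replace=False))
        gaps_all = np.diff(pos)
        # allele frequencies are themselves spatially correlated (shared
        # genealogy of neighboring SNPs): a latent AR(1) field mapped onto
        # the Beta spectrum through its quantile function
        from scipy.stats import beta as beta_dist

        v = np.empty(n_snp)
        v[0] = rng.standard_normal()
        for j in range(1, n_snp):
            rho_f = cfg.freq_corr ** (gaps_all[j - 1] / cfg.corr_ref_dist_bp)
            v[j] = rho_f * v[j - 1] + math.sqrt(1.0 - rho_f * rho_f) * (
                rng.standard_normal()
            )
        freq = beta_dist.ppf(norm.cdf(v), cfg.maf_beta_a, cfg.maf_beta_b)
        freq = np.clip(freq, 0.005, 0.995)
        thresh = norm.ppf(freq)
        x = rng.standard_normal(n_gam)
        block = np.empty((n_gam, n_snp), dtype=np.int8)
        block[:, 0] = x < thresh[0]
        gaps = np.diff(pos)
        for j in range(1, n_snp):
            rho = cfg.adjacent_corr ** (gaps[j - 1] / cfg.corr_ref_dist_bp)
            x = rho * x + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n_gam)
            block[:, j] = x < thresh[j]
        all_chrom.append(np.full(n_snp, c, dtype=np.int64))
        all_pos.append(pos)
        cols.append(block)
    chrom = np.concatenate(all_chrom)
    pos = np.concatenate(all_pos)
    ids = np.array([f"snp_{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    return HaplotypePanel(np.concatenate(cols, axis=1), MarkerMap(ids, chrom, pos))


def draw_crossover_positions(
    span_bp: int, mm: MeiosisModel, rng: np.random.Generator
) -> np.ndarray:
    """Crossover bp positions for one meiosis on a chromosome of span_bp.

    Count ~ Binomial(N, L/N) for genetic length L Morgans (expectation one
    crossover per Morgan); positions uniform along the chromosome.
    """
    L = mm.length_morgans(span_bp)
    if L <= 0.0:
        return np.empty(0)
    n = mm.n_for(L)
    k = rng.binomial(n, L / n)
    return np.sort(rng.random(k) * span_bp)


def simulate_meiosis(
    parent_gametes: np.ndarray,
    map: MarkerMap,
    mm: MeiosisModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a parent's two gametes.

    Per chromosome the recombinant alternates parental strands at the drawn
    crossover positions, starting from a fair random strand.
    """
    parent_gametes = np.asarray(parent_gametes)
    if parent_gametes.shape != (2, len(map)):
        raise ValueError("parent_gametes must be 2 x n_loci matching the map")
    gamete = np.empty(len(map), dtype=np.int8)
    for _, sl in map.chrom_slices():
        pos = map.pos_bp[sl]
        span = int(pos[-1]) + 1
        xo_bp = draw_crossover_positions(span, mm, rng)
        start = rng.integers(0, 2)
        if len(xo_bp) == 0:
            gamete[sl] = parent_gametes[start, sl]
            continue
        strand = (start + np.searchsorted(xo_bp, pos, side="right")) % 2
        block = parent_gametes[:, sl]
        gamete[sl] = block[strand, np.arange(sl.stop - sl.start)]
    return gamete


def drop_genes(
    founders: HaplotypePanel,
    n_offspring: int,
    mm: MeiosisModel,
    seed: int,
):
    """Random mating with allele dropping; returns offspring + pedigree.

    Each offspring receives one recombinant gamete from each of two
    distinct founders drawn uniformly (no selfing, no mutation).
    """
    if founders.n_individuals < 2:
        raise ValueError("need at least 2 founders for random mating")
    if n_offspring < 1:
        raise ValueError("n_offspring must be positive")
    rng = np.random.default_rng(seed)
    nf = founders.n_individuals
    alleles = np.empty((2 * n_offspring, founders.n_snps), dtype=np.int8)
    pedigree = np.empty((n_offspring, 2), dtype=np.int64)
    for i in range(n_offspring):
        sire = rng.integers(nf)
        dam = rng.integers(nf - 1)
        if dam >= sire:
            dam += 1
        pedigree[i] = (sire, dam)
        alleles[2 * i] = simulate_meiosis(
            founders.alleles[2 * sire : 2 * sire + 2], founders.map, mm, rng
        )
        alleles[2 * i + 1] = simulate_meiosis(
            founders.alleles[2 * dam : 2 * dam + 2], founders.map, mm, rng
        )
    return HaplotypePanel(alleles, founders.map), pedigree


def select_qtl(
    freqs: np.ndarray,
    n_qtl: int,
    regime: str = "common",
    maf_cut: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Uniform sample of QTL among SNPs with MAF above/below the cutoff."""
    if regime not in ("common", "rare"):
        raise ValueError("regime must be 'common' or 'rare'")
    freqs = np.asarray(freqs, dtype=np.float64)
    maf = np.minimum(freqs, 1.0 - freqs)
    if regime == "common":
        eligible = np.flatnonzero(maf > maf_cut)
    else:
        eligible = np.flatnonzero((maf > 0.0) & (maf < maf_cut))
    if len(eligible) < n_qtl:
        raise ValueError(
            f"only {len(eligible)} eligible SNPs for {n_qtl} {regime} QTL"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(eligible, size=n_qtl, replace=False))


def simulate_trait(Z_qtl: np.ndarray, h2: float, seed: int = 0):
    """Standard-normal QTL effects, TBV standardized to unit variance.

    Raw effects ~ N(0,1); TBV_raw = Z_qtl @ effects; both are divided by
    the realized SD of TBV_raw so Var(TBV) = 1 in the cohort; residual
    variance V_E = (1-h2)/h2 * Var(TBV) (= 1 at h2 = 0.5).
    """
    Z_qtl = np.asarray(Z_qtl, dtype=np.float64)
    if Z_qtl.ndim != 2 or Z_qtl.shape[0] < 2:
        raise ValueError("Z_qtl must be 2-D with >= 2 individuals")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    effects = rng.standard_normal(Z_qtl.shape[1])
    tbv_raw = Z_qtl @ effects
    V_A = float(np.var(tbv_raw))
    # relative guard: a constant TBV vector has var ~ eps^2 * scale^2
    if V_A <= 1e-20 * max(1.0, float(np.abs(tbv_raw).max()) ** 2):
        raise ValueError("all QTL are monomorphic in the cohort (zero variance)")
    sd = math.sqrt(V_A)
    effects = effects / sd
    tbv = tbv_raw / sd
    V_E = (1.0 - h2) / h2 * float(np.var(tbv))
    y = tbv + rng.standard_normal(len(tbv)) * math.sqrt(V_E)
    arch = TraitArchitecture(
        qtl_index=np.arange(Z_qtl.shape[1]), qtl_effect=effects, tbv=tbv, V_A=V_A
    )
    return arch, PhenotypeSet(y=y, h2_target=h2, V_E=V_E)


@dataclass
class ScenarioConfig:
    """One simulation scenario; a single seed drives every random stage."""

    founder: FounderConfig = field(default_factory=FounderConfig)
    meiosis: MeiosisModel = field(default_factory=MeiosisModel)
    regime: str = "rare"
    n_qtl: int = 300
    maf_cut: float = 0.05
    panel_maf_cut: float = 0.05
    md_stride: int = 12
    window_size_bp: int = 1_000_000
    n_offspring: int = 5_000
    n_train: int = 4_000
    h2: float = 0.5
    seed: int = 0


@dataclass
class Replicate:
    """Everything one replicate of the study produces."""

    scenario: ScenarioConfig
    offspring: HaplotypePanel
    pedigree: np.ndarray
    qtl_index: np.ndarray
    trait: TraitArchitecture
    phenotypes: PhenotypeSet
    panels: dict  # density -> dict(panel_index, Z_train, Z_validate, windows)
    train_idx: np.ndarray
    validate_idx: np.ndarray
    manifest: dict


def make_replicate(scenario: ScenarioConfig) -> Replicate:
    """Founders -> gene dropping -> QTL -> masking -> panels -> trait.

    Panels: 'hd' holds every SNP with founder MAF above panel_maf_cut,
    'md' every md_stride-th HD SNP (per chromosome); QTL are masked from
    both. The train/validate split is by simulation order.
    """
    ss = np.random.SeedSequence(scenario.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    founder_cfg = FounderConfig(**{**scenario.founder.__dict__, "seed": seeds[0]})
    founders = generate_founder_haplotypes(founder_cfg)
    offspring, pedigree = drop_genes(
        founders, scenario.n_offspring, scenario.meiosis, seeds[1]
    )
    founder_freq = founders.allele_freq()
    qtl = select_qtl(
        founder_freq, scenario.n_qtl, scenario.regime, scenario.maf_cut, seeds[2]
    )
    maf = np.minimum(founder_freq, 1.0 - founder_freq)
    hd_all = np.flatnonzero(maf > scenario.panel_maf_cut)
    hd_map = founders.map.subset(hd_all)
    md_rel = build_md_panel(hd_map, scenario.md_stride)
    md_all = hd_all[md_rel]
    hd_panel = mask_qtl_from_panel(hd_all, qtl)
    md_panel = mask_qtl_from_panel(md_all, qtl)

    geno = offspring.genotypes()
    arch, phen = simulate_trait(geno.scores[:, qtl], scenario.h2, seeds[3])
    arch.qtl_index = qtl

    n = scenario.n_offspring
    train_idx = np.arange(scenario.n_train)
    validate_idx = np.arange(scenario.n_train, n)

    panels = {}
    for name, idx in (("hd", hd_panel), ("md", md_panel)):
        sub = geno.subset_loci(idx)
        Z_train = center_genotypes(
            GenotypeMatrix(sub.scores[train_idx], map=sub.map)
        )
        Z_validate = GenotypeMatrix(
            sub.scores[validate_idx] - Z_train.column_means,
            map=sub.map,
            centered=False,  # centered with TRAINING means; sums need not be 0
            column_means=Z_train.column_means,
        )
        windows = build_window_partition(sub.map, scenario.window_size_bp)
        panels[name] = {
            "panel_index": idx,
            "Z_train": Z_train,
            "Z_validate": Z_validate,
            "windows": windows,
        }

    manifest = {
        "seed": scenario.seed,
        "stage_seeds": seeds,
        "regime": scenario.regime,
        "n_qtl": scenario.n_qtl,
        "maf_cut": scenario.maf_cut,
        "qtl_maf": maf[qtl].tolist(),
        "n_offspring": n,
        "n_train": scenario.n_train,
        "h2": scenario.h2,
        "window_size_bp": scenario.window_size_bp,
        "md_stride": scenario.md_stride,
        "n_snps_hd": int(len(hd_panel)),
        "n_snps_md": int(len(md_panel)),
        "V_A_raw": arch.V_A,
        "V_E": phen.V_E,
        "founder": founder_cfg.__dict__.copy(),
        "meiosis": scenario.meiosis.__dict__.copy(),
    }
    return Replicate(
        scenario=scenario,
        offspring=offspring,
        pedigree=pedigree,
        qtl_index=qtl,
        trait=arch,
        phenotypes=phen,
        panels=panels,
        train_idx=train_idx,
        validate_idx=validate_idx,
        manifest=manifest,
    )
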