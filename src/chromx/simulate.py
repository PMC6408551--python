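"""Seeded generator of synthetic childhood-obesity cohorts with X-linked markers.

Emulates the structure of a candidate-gene study of ~915 children (438 boys,
477 girls): seven X-linked SNPs in two haploblocks (3 + 4 markers) with MAFs
in the 0.25-0.48 range, partial LD between blocks, quantitative phenotypes
(BMI z-score, waist circumference, glucose/insulin and derived indices, lipids,
IL-6) with optional additive genetic effects under either X-inactivation
dosage model, age/height covariates, an obesity case/control label driven by a
logistic liability on the BMI z-score, and sex-specific per-SNP missingness.

Haplotypes are drawn per X chromosome (two per girl, one per boy) from
per-block pools; the two blocks are coupled by an inverse-CDF draw and broken
apart with a configurable recombination fraction, which tunes the multiallelic
D' between blocks (default 0.5 -> D' roughly 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genodata import (
    CASE,
    CONTROL,
    FEMALE,
    MALE,
    MISSING,
    GenotypeDataset,
    SampleRecord,
    VariantInfo,
)


@dataclass(frozen=True)
class BlockSpec:
    """One haploblock: member variants and a haplotype pool with frequencies.

    ``haplotypes`` maps a 0/1 tuple per member SNP (1 = minor/A1 allele) to a
    population frequency; frequencies must sum to 1.
    """

    variants: tuple[VariantInfo, ...]
    haplotypes: tuple[tuple[tuple[int, ...], float], ...]

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        for hap, _ in self.haplotypes:
            if len(hap) != len(self.variants):
                raise ValueError("haplotype length does not match block size")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One quantitative trait: base level, covariate terms, genetic effect."""

    name: str
    mean: float
    noise_sd: float
    causal: str | None = None
    beta_male: float = 0.0
    beta_female: float = 0.0
    dosage_model: str = "escape"  # escape | xci
    age_beta: float = 0.0
    height_beta: float = 0.0
    log_scale: bool = False  # draw on log scale (positive, skewed traits)
    missing_rate: float = 0.04
    min_value: float | None = None


def _default_blocks() -> tuple[BlockSpec, BlockSpec]:
    X = "X"
    b1_vars = (
        VariantInfo("rs11798018", X, 100600646, "A", "C"),
        VariantInfo("rs5966709", X, 100604240, "T", "G"),
        VariantInfo("rs4828037", X, 100606173, "C", "T"),
    )
    # nested minor-allele pool: MAFs 0.27/0.29/0.31, D'=1 within the block
    b1_haps = (
        ((1, 1, 1), 0.27),
        ((0, 1, 1), 0.02),
        ((0, 0, 1), 0.02),
        ((0, 0, 0), 0.69),
    )
    b2_vars = (
        VariantInfo("rs2073162", X, 100609288, "A", "G"),
        VariantInfo("rs2073163", X, 100610426, "C", "T"),
        VariantInfo("rs4828038", X, 100612265, "T", "C"),
        VariantInfo("rs1155974", X, 100613818, "T", "C"),
    )
    # pool chosen so the third marker is the block's single tag at r2 >= 0.8
    # (population r2 to the others ~0.83-0.84) while the remaining pairs sit
    # at r2 ~0.67-0.69 with D' ~0.88-1.0; MAFs 0.40-0.47
    b2_haps = (
        ((1, 1, 1, 1), 0.372),
        ((0, 0, 0, 0), 0.497),
        ((1, 0, 0, 0), 0.047),
        ((1, 0, 1, 1), 0.030),
        ((0, 0, 0, 1), 0.026),
        ((1, 1, 1, 0), 0.017),
        ((0, 1, 0, 0), 0.011),
    )
    return BlockSpec(b1_vars, b1_haps), BlockSpec(b2_vars, b2_haps)


def _default_phenotypes() -> tuple[PhenotypeSpec, ...]:
    return (
        PhenotypeSpec(
            "bmi_z", mean=1.3, noise_sd=1.0,
            causal="rs2073162", beta_male=0.65, beta_female=0.11,
            dosage_model="escape", missing_rate=0.01,
        ),
        PhenotypeSpec("waist_cm", mean=77.0, noise_sd=13.0, age_beta=2.5, missing_rate=0.02),
        PhenotypeSpec("sbp_mmHg", mean=105.5, noise_sd=13.0, age_beta=0.8, missing_rate=0.08),
        PhenotypeSpec("dbp_mmHg", mean=64.3, noise_sd=10.5, age_beta=0.5, missing_rate=0.08),
        PhenotypeSpec("glucose_mg_dl", mean=84.5, noise_sd=7.5, age_beta=0.3,
                      missing_rate=0.04, min_value=40.0),
        PhenotypeSpec("insulin_mU_l", mean=2.30, noise_sd=0.55, age_beta=0.04,
                      log_scale=True, missing_rate=0.05),
        PhenotypeSpec("tag_mg_dl", mean=68.0, noise_sd=32.0, missing_rate=0.04, min_value=15.0),
        PhenotypeSpec("hdl_mg_dl", mean=53.5, noise_sd=14.0, missing_rate=0.04, min_value=15.0),
        PhenotypeSpec("il6_ng_l", mean=0.92, noise_sd=0.90, log_scale=True, missing_rate=0.18),
    )


@dataclass
class SimConfig:
    """Study-shaped defaults: 915 children (438 boys / 477 girls), 7 SNPs."""

    n_total: int = 915
    n_male: int = 438
    blocks: tuple[BlockSpec, ...] = field(default_factory=_default_blocks)
    inter_block_recomb: float = 0.5
    #: per-variant missing-call rate, by sex (ordered as blocks concatenate);
    #: first marker emulates the panel's one low-call-rate assay, and the
    #: block-2 tag carries excess male missingness
    missing_female: tuple[float, ...] = (0.07, 0.015, 0.01, 0.015, 0.015, 0.018, 0.015)
    missing_male: tuple[float, ...] = (0.075, 0.02, 0.015, 0.02, 0.02, 0.035, 0.02)
    phenotypes: tuple[PhenotypeSpec, ...] = field(default_factory=_default_phenotypes)
    obesity_intercept: float = -0.8
    obesity_slope: float = 1.4
    age_mean: float = 10.2
    age_sd: float = 2.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_male < self.n_total):
            raise ValueError("need 0 < n_male < n_total")
        n_snps = sum(len(b.variants) for b in self.blocks)
        if len(self.missing_female) != n_snps or len(self.missing_male) != n_snps:
            raise ValueError("missing-rate vectors must have one entry per SNP")

    @property
    def variants(self) -> tuple[VariantInfo, ...]:
        return tuple(v for b in self.blocks for v in b.variants)


@dataclass
class SimTruth:
    """Ground truth behind one simulated cohort, for recovery tests."""

    effects: dict  # phenotype -> {causal, beta_male, beta_female, dosage_model}
    haplotypes: np.ndarray  # (n_samples, 2, n_snps); males NaN on second row
    true_calls: np.ndarray  # pre-missingness genotype matrix


def derive_indices(glucose_mg_dl, insulin_mU_l):
    """HOMA-IR and QUICKI from fasting glucose (mg/dl) and insulin (mU/l).

    HOMA-IR = glucose * insulin / 405; QUICKI = 1 / (log10 insulin +
    log10 glucose).  Non-positive inputs yield NaN.
    """
    g = np.asarray(glucose_mg_dl, float)
    ins = np.asarray(insulin_mU_l, float)
    ok = (g > 0) & (ins > 0)
    homa = np.where(ok, g * ins / 405.0, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        quicki = np.where(ok, 1.0 / (np.log10(ins, where=ok, out=np.ones_like(ins))
                                     + np.log10(g, where=ok, out=np.ones_like(g))), np.nan)
    return homa, quicki


def _draw_block_haps(rng, blocks, recomb, n_chrom):
    """Inverse-CDF-coupled haplotype indices per block for n chromosomes."""
    pools = []
    for b in blocks:
        freqs = np.array([f for _, f in b.haplotypes])
        pools.append(np.cumsum(freqs))
    u = rng.random(n_chrom)
    draws = []
    for bi, cum in enumerate(pools):
        if bi == 0:
            ub = u
        else:
            indep = rng.random(n_chrom) < recomb
            ub = np.where(indep, rng.random(n_chrom), u)
        draws.append(np.searchsorted(cum, ub, side="right").clip(0, len(cum) - 1))
    return draws


def simulate_cohort(cfg: SimConfig = SimConfig(), seed: int | None = None):
    """Draw one cohort; returns (GenotypeDataset, PhenotypeTable, SimTruth)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, nm = cfg.n_total, cfg.n_male
    nf = n - nm
    variants = list(cfg.variants)
    n_snps = len(variants)
    is_male = np.zeros(n, bool)
    is_male[:nm] = True

    # two chromosomes per female, one per male
    n_chrom = nm + 2 * nf
    block_draws = _draw_block_haps(rng, cfg.blocks, cfg.inter_block_recomb, n_chrom)
    hap_bits = np.empty((n_chrom, n_snps), dtype=np.int8)
    col = 0
    for b, idx in zip(cfg.blocks, block_draws):
        pool = np.array([h for h, _ in b.haplotypes], dtype=np.int8)
        hap_bits[:, col : col + len(b.variants)] = pool[idx]
        col += len(b.variants)

    haplos = np.full((n, 2, n_snps), np.nan)
    calls = np.empty((n, n_snps), dtype=np.int8)
    haplos[:nm, 0] = hap_bits[:nm]
    calls[:nm] = hap_bits[:nm]
    fem = hap_bits[nm:].reshape(nf, 2, n_snps)
    haplos[nm:] = fem
    calls[nm:] = fem.sum(axis=1)

    # covariates
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 3.0, 16.0)
    height = 85.0 + 5.9 * age + rng.normal(0.0, 7.0, n)

    pheno = pd.DataFrame(index=[f"S{i + 1:04d}" for i in range(n)])
    pheno.index.name = "iid"
    pheno["age_years"] = np.round(age, 2)
    pheno["height_cm"] = np.round(height, 1)

    vid_to_col = {v.id: j for j, v in enumerate(variants)}
    effects = {}
    values: dict[str, np.ndarray] = {}
    for spec in cfg.phenotypes:
        y = spec.mean + spec.age_beta * (age - cfg.age_mean) + spec.height_beta * (
            height - np.mean(height)
        ) + rng.normal(0.0, spec.noise_sd, n)
        if spec.causal is not None:
            dose = calls[:, vid_to_col[spec.causal]].astype(float)
            if spec.dosage_model == "xci":
                dose = np.where(is_male & (dose == 1), 2.0, dose)
            beta = np.where(is_male, spec.beta_male, spec.beta_female)
            y = y + beta * dose
            effects[spec.name] = {
                "causal": spec.causal,
                "beta_male": spec.beta_male,
                "beta_female": spec.beta_female,
                "dosage_model": spec.dosage_model,
            }
        if spec.log_scale:
            y = np.exp(y)
        if spec.min_value is not None:
            y = np.maximum(y, spec.min_value)
        values[spec.name] = y

    # derived traits before missingness
    if "glucose_mg_dl" in values and "insulin_mU_l" in values:
        homa, quicki = derive_indices(values["glucose_mg_dl"], values["insulin_mU_l"])
        values["homa_ir"], values["quicki"] = homa, quicki
    if "waist_cm" in values:
        values["whtr"] = values["waist_cm"] / height

    # obesity class from logistic liability on the BMI z-score
    bmi_z = values["bmi_z"]
    p_case = 1.0 / (1.0 + np.exp(-(cfg.obesity_intercept + cfg.obesity_slope * bmi_z)))
    case = rng.random(n) < p_case

    # phenotype missingness (MCAR); derived traits inherit their parents'
    miss_by_name = {s.name: s.missing_rate for s in cfg.phenotypes}
    parent_missing: dict[str, np.ndarray] = {}
    for name, y in values.items():
        rate = miss_by_name.get(name)
        if rate is None:
            continue
        drop = rng.random(n) < rate
        parent_missing[name] = drop
        y = y.copy()
        y[drop] = np.nan
        values[name] = y
    if "homa_ir" in values:
        drop = parent_missing["glucose_mg_dl"] | parent_missing["insulin_mU_l"]
        for name in ("homa_ir", "quicki"):
            v = values[name].copy()
            v[drop] = np.nan
            values[name] = v
    if "whtr" in values:
        v = values["whtr"].copy()
        v[parent_missing["waist_cm"]] = np.nan
        values["whtr"] = v

    order = [
        "bmi_z", "waist_cm", "whtr", "sbp_mmHg", "dbp_mmHg", "glucose_mg_dl",
        "insulin_mU_l", "homa_ir", "quicki", "tag_mg_dl", "hdl_mg_dl", "il6_ng_l",
    ]
    for name in order:
        if name in values:
            pheno[name] = values[name]

    # genotype missingness, MCAR within sex
    true_calls = calls.copy()
    obs_calls = calls.copy()
    for j in range(n_snps):
        rate = np.where(is_male, cfg.missing_male[j], cfg.missing_female[j])
        obs_calls[rng.random(n) < rate, j] = MISSING

    samples = [
        SampleRecord(
            iid=f"S{i + 1:04d}",
            sex=MALE if is_male[i] else FEMALE,
            group=CASE if case[i] else CONTROL,
        )
        for i in range(n)
    ]
    ds = GenotypeDataset(samples=samples, variants=variants, calls=obs_calls)
    truth = SimTruth(effects=effects, haplotypes=haplos, true_calls=true_calls)
    return ds, pheno, truth
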