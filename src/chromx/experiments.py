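"""Reusable calibration and recovery experiments on synthetic cohorts.

These drive the package's own validation: type-I-error calibration of the
pooled-sex score test and the haplotype omnibus test under the null,
planted-effect recovery of the sex-stratified escape-model regression, and the
structural checks (haploblock partition, single block-2 tag) on the default
cohort.  Both the test suite and the reproduction script call these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import assoc as xassoc
from . import ld as ldmod
from .genodata import FEMALE, MALE
from .qc import QCThresholds, run_qc
from .simulate import SimConfig, simulate_cohort

#: raw two-sided P values of the study's published BMI z-score scan
#: (7 X-linked SNPs x 2 sexes) -- printed inputs for the adjustment family
TABLE1_RAW_P = {
    ("rs11798018", FEMALE): 0.369,
    ("rs5966709", FEMALE): 0.202,
    ("rs4828037", FEMALE): 0.161,
    ("rs2073162", FEMALE): 0.267,
    ("rs2073163", FEMALE): 0.274,
    ("rs4828038", FEMALE): 0.193,
    ("rs1155974", FEMALE): 0.339,
    ("rs11798018", MALE): 0.561,
    ("rs5966709", MALE): 0.762,
    ("rs4828037", MALE): 0.952,
    ("rs2073162", MALE): 0.003,
    ("rs2073163", MALE): 0.008,
    ("rs4828038", MALE): 0.004,
    ("rs1155974", MALE): 0.005,
}


def clayton_type1_error(
    n_sims: int = 5000,
    seed: int = 0,
    n_male: int = 438,
    n_female: int = 477,
    maf: float = 0.45,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the stratified score test on null cohorts.

    Each replicate draws Hardy-Weinberg genotypes (females Binom(2, maf),
    males Binom(1, maf)) and an independent standard-normal phenotype.
    """
    rng = np.random.default_rng(seed)
    n = n_male + n_female
    is_male = np.zeros(n, bool)
    is_male[:n_male] = True
    rejections = 0
    for _ in range(n_sims):
        calls = np.where(
            is_male, rng.binomial(1, maf, n), rng.binomial(2, maf, n)
        ).astype(np.int8)
        y = rng.standard_normal(n)
        _, p = xassoc.clayton_x_test(y, calls, is_male)
        rejections += p < alpha
    return rejections / n_sims


def haplotype_omnibus_type1_error(
    n_sims: int = 5000,
    seed: int = 0,
    n_male: int = 438,
    n_female: int = 477,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the haplotype omnibus F test on null cohorts.

    Haplotypes come from the default first haploblock's pool (3 SNPs); the
    phenotype is independent standard normal, so every rejection is a type-I
    error.
    """
    rng = np.random.default_rng(seed)
    block = SimConfig().blocks[0]
    pool = np.array([h for h, _ in block.haplotypes], dtype=np.int8)
    freqs = np.array([f for _, f in block.haplotypes])
    n = n_male + n_female
    is_male = np.zeros(n, bool)
    is_male[:n_male] = True
    n_chrom = n_male + 2 * n_female
    rejections = 0
    for _ in range(n_sims):
        hap_idx = rng.choice(len(freqs), size=n_chrom, p=freqs)
        bits = pool[hap_idx]
        calls = np.empty((n, pool.shape[1]), dtype=np.int8)
        calls[:n_male] = bits[:n_male]
        calls[n_male:] = bits[n_male:].reshape(n_female, 2, -1).sum(axis=1)
        hs = ldmod.em_haplotype_freqs(calls, is_male)
        y = rng.standard_normal(n)
        res = ldmod.haplotype_assoc_test(y, hs)
        rejections += res.omnibus_p < alpha
    return rejections / n_sims


@dataclass
class RecoverySummary:
    frac_within_2se: float
    frac_top_ranked: float
    mean_beta: float
    n_sims: int


def planted_effect_recovery(n_sims: int = 200, seed: int = 0) -> RecoverySummary:
    """Sex-stratified escape-model regression against the generator's truth.

    Each replicate simulates a default cohort (planted male effect beta=0.65
    on the first block-2 SNP), fits the male-stratum additive model for every
    SNP, and records whether the planted SNP's estimate lies within 2 SE of
    the truth and whether it is the top-ranked (smallest-P) male association.
    """
    within = 0
    top = 0
    betas = []
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_sims)
    for s in base:
        cfg = SimConfig(seed=int(s))
        ds, pheno, truth = simulate_cohort(cfg)
        eff = truth.effects["bmi_z"]
        y = pheno["bmi_z"].to_numpy(float)
        dos = xassoc.code_dosage(ds, model=eff["dosage_model"], sex=MALE)
        pvals = {}
        for j, v in enumerate(ds.variants):
            res = xassoc.linear_assoc(y, dos[:, j], variant=v.id, stratum=MALE)
            pvals[v.id] = res.p
            if v.id == eff["causal"]:
                betas.append(res.beta)
                if abs(res.beta - eff["beta_male"]) <= 2 * res.se:
                    within += 1
        if min(pvals, key=pvals.get) == eff["causal"]:
            top += 1
    return RecoverySummary(
        frac_within_2se=within / n_sims,
        frac_top_ranked=top / n_sims,
        mean_beta=float(np.mean(betas)),
        n_sims=n_sims,
    )


@dataclass
class StructureSummary:
    block_sizes: tuple[int, ...]
    block_members: tuple[tuple[str, ...], ...]
    n_tags_block2: int
    tag_block2: str | None
    multiallelic_dprime: float


def cohort_structure(seed: int = 0, spine_threshold: float = 0.8, tag_r2: float = 0.8) -> StructureSummary:
    """Haploblock partition, block-2 tagging, and between-block D' of one cohort."""
    ds, _, _ = simulate_cohort(SimConfig(seed=seed))
    dp, r2 = ldmod.ld_matrices(ds)
    blocks = ldmod.solid_spine_blocks(dp.to_numpy(), spine_threshold)
    members = tuple(tuple(ds.variants[j].id for j in blk.members) for blk in blocks)
    n_tags_b2, tag_b2 = 0, None
    mdp = np.nan
    if len(blocks) >= 2:
        blk2 = blocks[1]
        sub = r2.to_numpy()[np.ix_(blk2.members, blk2.members)]
        tags, _ = ldmod.tag_snps(
            sub, positions=[ds.variants[j].bp for j in blk2.members], capture_threshold=tag_r2
        )
        n_tags_b2 = len(tags)
        tag_b2 = ds.variants[blk2.members[tags[0]]].id if tags else None
        joint_idx = list(blocks[0].members) + list(blk2.members)
        joint = ldmod.hapset_from_dataset(ds, joint_idx)
        mdp = ldmod.multiallelic_dprime(joint, k_a=len(blocks[0].members))
    return StructureSummary(
        block_sizes=tuple(len(m) for m in members),
        block_members=members,
        n_tags_block2=n_tags_b2,
        tag_block2=tag_b2,
        multiallelic_dprime=float(mdp),
    )
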