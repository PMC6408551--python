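"""Sex-specific genotype quality-control battery for X-linked candidate markers.

Five per-variant rules, each an exact test or simple rate, evaluated separately
for the two sexes where that matters:

* equal allele frequencies between sexes (Fisher exact on allele counts,
  females contributing two alleles and hemizygous males one);
* per-sex missing-call rate (pass when the female rate is <= 2% by default);
* differential missingness between sexes (Fisher exact, pass when P >= 1e-7);
* per-sex minor-allele frequency (>= 1% in each sex);
* Hardy-Weinberg equilibrium, exact test on control (normal-BMI) females only
  (pass when P >= 1e-4) -- males carry one X and cannot inform HWE.

Missingness rules default to report-only (candidate-gene panels routinely keep
a marker that trips a missingness recommendation); MAF and HWE failures exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genodata import CONTROL, FEMALE, MALE, MISSING, GenotypeDataset, compute_maf

#: rules whose failure drops the variant, by default
DEFAULT_EXCLUDE_ON = ("maf", "hwe")


@dataclass(frozen=True)
class QCThresholds:
    """Pass boundaries; all inclusive (``<=`` / ``>=``)."""

    female_missing_max: float = 0.02
    diff_missing_p_min: float = 1e-7
    maf_min_per_sex: float = 0.01
    hwe_p_min: float = 1e-4
    sex_freq_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0,1), got {v}")


@dataclass
class QCReport:
    """Per-variant QC statistics plus pass/fail flags.

    ``table`` has one row per variant with every intermediate statistic; the
    ``pass_*`` columns flag each rule and ``pass_all`` is their conjunction.
    """

    table: pd.DataFrame
    thresholds: QCThresholds
    exclude_on: tuple[str, ...]

    @property
    def n_fail(self) -> dict[str, int]:
        return {
            rule: int((~self.table[f"pass_{rule}"]).sum())
            for rule in ("sex_freq", "female_missing", "diff_missing", "maf", "hwe")
        }

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="variant", na_rep="NA")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P for the 2x2 table [[a, b], [c, d]].

    Probability-mass ordering: the P value sums hypergeometric probabilities of
    all tables with the observed margins whose probability does not exceed the
    observed table's (the PLINK / R convention).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d < 1:
        raise ValueError("empty table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _allele_counts(ds: GenotypeDataset, j: int, sample_mask: np.ndarray) -> tuple[int, int]:
    """(a1, a2) allele counts at variant j; females weight 2, males 1."""
    calls = ds.calls[sample_mask, j]
    male = ds.is_male[sample_mask]
    obs = calls != MISSING
    a1 = int(calls[obs].sum())
    total = int(np.where(male[obs], 1, 2).sum())
    return a1, total - a1


def sex_allele_freq_test(ds: GenotypeDataset, variant: str | int) -> float:
    """Two-sided Fisher exact test of equal allele frequencies in the sexes."""
    j = variant if isinstance(variant, int) else ds.variant_index(variant)
    male = ds.is_male
    f_a1, f_a2 = _allele_counts(ds, j, ~male)
    m_a1, m_a2 = _allele_counts(ds, j, male)
    if f_a1 + f_a2 == 0 or m_a1 + m_a2 == 0:
        return np.nan
    return fisher_exact_2x2(f_a1, f_a2, m_a1, m_a2)


def differential_missingness_test(ds: GenotypeDataset, variant: str | int) -> float:
    """Fisher exact on (missing, called) x (female, male) counts."""
    j = variant if isinstance(variant, int) else ds.variant_index(variant)
    male = ds.is_male
    miss = ds.calls[:, j] == MISSING
    f_miss = int((miss & ~male).sum())
    f_ok = int((~miss & ~male).sum())
    m_miss = int((miss & male).sum())
    m_ok = int((~miss & male).sum())
    return fisher_exact_2x2(f_miss, f_ok, m_miss, m_ok)


def hwe_exact_females(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact Hardy-Weinberg test from female genotype counts.

    Enumerates every heterozygote count with the observed allele counts (same
    parity as the rare-allele total) under the exact sampling distribution
    P(n_het) proportional to n! 2^n_het / (n_AA! n_Aa! n_aa!), and sums the
    probabilities not exceeding the observed configuration's.
    """
    if min(n_hom_a1, n_het, n_hom_a2) < 0:
        raise ValueError("counts must be non-negative")
    n = n_hom_a1 + n_het + n_hom_a2
    if n < 1:
        raise ValueError("no genotypes")
    n_a1 = 2 * n_hom_a1 + n_het
    n_a2 = 2 * n_hom_a2 + n_het
    rare = min(n_a1, n_a2)
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = n - hets - homs_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homs_rare + 1)
        - gammaln(homs_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def run_qc(
    ds: GenotypeDataset,
    thresholds: QCThresholds = QCThresholds(),
    exclude_on: tuple[str, ...] = DEFAULT_EXCLUDE_ON,
) -> tuple[QCReport, GenotypeDataset]:
    """Evaluate all five rules per variant; drop variants failing enabled rules.

    Every rule is evaluated on the full cohort except HWE, which uses control
    females only.  ``exclude_on`` names the rules whose failure removes the
    variant from the returned dataset; all failures are reported either way.
    """
    if ds.n_samples == 0 or ds.n_variants == 0:
        raise ValueError("empty dataset")
    male = ds.is_male
    ctrl_f = (~male) & np.array([s.group == CONTROL for s in ds.samples])

    maf_f = compute_maf(ds, sex=FEMALE)
    maf_m = compute_maf(ds, sex=MALE)

    rows = []
    for j, v in enumerate(ds.variants):
        calls = ds.calls[:, j]
        miss = calls == MISSING
        miss_f = float(miss[~male].mean()) if (~male).any() else np.nan
        miss_m = float(miss[male].mean()) if male.any() else np.nan
        sex_p = sex_allele_freq_test(ds, j)
        dm_p = differential_missingness_test(ds, j)
        cf = calls[ctrl_f]
        hwe_p = (
            hwe_exact_females(int((cf == 2).sum()), int((cf == 1).sum()), int((cf == 0).sum()))
            if (cf != MISSING).any()
            else np.nan
        )
        mafs = (maf_f[j], maf_m[j])
        rows.append(
            {
                "sex_freq_p": sex_p,
                "missing_rate_female": miss_f,
                "missing_rate_male": miss_m,
                "diff_missing_p": dm_p,
                "maf_female": mafs[0],
                "maf_male": mafs[1],
                "hwe_p_control_females": hwe_p,
                "pass_sex_freq": bool(np.isnan(sex_p) or sex_p >= thresholds.sex_freq_alpha),
                "pass_female_missing": bool(miss_f <= thresholds.female_missing_max),
                "pass_diff_missing": bool(np.isnan(dm_p) or dm_p >= thresholds.diff_missing_p_min),
                "pass_maf": bool(
                    min(np.nan_to_num(mafs[0], nan=1.0), np.nan_to_num(mafs[1], nan=1.0))
                    >= thresholds.maf_min_per_sex
                ),
                "pass_hwe": bool(np.isnan(hwe_p) or hwe_p >= thresholds.hwe_p_min),
            }
        )
    table = pd.DataFrame(rows, index=ds.variant_ids)
    table["pass_all"] = table[[c for c in table.columns if c.startswith("pass_")]].all(axis=1)

    keep = np.ones(ds.n_variants, bool)
    for rule in exclude_on:
        keep &= table[f"pass_{rule}"].to_numpy()
    report = QCReport(table=table, thresholds=thresholds, exclude_on=tuple(exclude_on))
    return report, ds.subset(variant_mask=keep)
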