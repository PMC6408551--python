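"""Haplotype-frequency estimation and linkage disequilibrium on the X.

The EM estimator handles the mixed ploidy of an X-linked region: every male is
a fully phased single-haplotype observation (hemizygosity makes his genotype
his haplotype), while unphased female multi-locus genotypes are summed over
compatible ordered haplotype pairs.  On top of the EM sit pairwise D'/r^2,
solid-spine-of-LD haploblock detection, the multiallelic D' between blocks,
greedy pairwise tag-SNP selection, and haplotype-dosage association tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genodata import MISSING, GenotypeDataset

_MAX_K = 12  # 2^k haplotype enumeration bound


@dataclass(frozen=True)
class PairwiseLD:
    """Two-locus LD summary. NaN fields flag a monomorphic (undefined) pair."""

    id_a: str
    id_b: str
    D: float
    Dprime: float
    r2: float

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.Dprime) or np.isnan(self.r2))


@dataclass(frozen=True)
class Haploblock:
    """Contiguous run of map-ordered variant indices forming one LD block."""

    members: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a haploblock needs >= 2 members")
        if list(self.members) != list(range(self.members[0], self.members[-1] + 1)):
            raise ValueError("members must be contiguous in map order")


@dataclass
class HaplotypeSet:
    """EM-estimated haplotype distribution over one set of SNPs.

    ``haplotypes[h]`` is a 0/1 tuple (1 = A1 allele) per member SNP,
    ``freqs[h]`` its population frequency, and ``dosages[i, h]`` sample i's
    posterior expected count of haplotype h (rows sum to 2 for females, 1 for
    males).  ``labels`` renders haplotypes with the variants' allele letters.
    """

    variant_ids: tuple[str, ...]
    haplotypes: tuple[tuple[int, ...], ...]
    freqs: np.ndarray
    dosages: np.ndarray
    is_male: np.ndarray
    loglik: float
    n_iter: int
    labels: tuple[str, ...] = ()

    def frequency_table(self) -> pd.DataFrame:
        names = self.labels if self.labels else tuple(
            "".join(map(str, h)) for h in self.haplotypes
        )
        return pd.DataFrame({"haplotype": names, "frequency": self.freqs})


def _compatible_pairs(geno: tuple[int, ...], k: int):
    """Ordered haplotype-index pairs (h1, h2) compatible with a female genotype."""
    per_site = []
    for g in geno:
        if g == 0:
            per_site.append([(0, 0)])
        elif g == 2:
            per_site.append([(1, 1)])
        elif g == 1:
            per_site.append([(0, 1), (1, 0)])
        else:  # missing
            per_site.append([(0, 0), (0, 1), (1, 0), (1, 1)])
    pairs = []
    for combo in product(*per_site):
        h1 = h2 = 0
        for j in range(k):
            h1 = (h1 << 1) | combo[j][0]
            h2 = (h2 << 1) | combo[j][1]
        pairs.append((h1, h2))
    return pairs


def _compatible_haps(geno: tuple[int, ...], k: int):
    """Haplotype indices compatible with a hemizygous male genotype."""
    per_site = [[0, 1] if g not in (0, 1) else [g] for g in geno]
    haps = []
    for combo in product(*per_site):
        h = 0
        for b in combo:
            h = (h << 1) | b
        haps.append(h)
    return haps


def em_haplotype_freqs(
    calls: np.ndarray,
    is_male: np.ndarray,
    variant_ids: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    allele_labels: tuple[tuple[str, str], ...] | None = None,
) -> HaplotypeSet:
    """EM over the 2^k haplotypes of k SNPs with mixed-ploidy observations.

    Initialised at linkage-equilibrium product frequencies (deterministic).
    Missing calls are summed over compatible genotypes.  The E-step assigns
    each female diplotype posterior weight proportional to f[h1] * f[h2]
    (ordered pairs, so heterozygous pairs implicitly count twice); the M-step
    re-estimates frequencies from expected haplotype counts.  Iteration stops
    when the largest frequency change drops below ``tol``.
    """
    calls = np.asarray(calls)
    if calls.ndim == 1:
        calls = calls[:, None]
    n, k = calls.shape
    if n == 0:
        raise ValueError("no samples")
    if k > _MAX_K:
        raise ValueError(f"k={k} exceeds enumeration bound {_MAX_K}")
    is_male = np.asarray(is_male, bool)
    if variant_ids is None:
        variant_ids = tuple(f"snp{j + 1}" for j in range(k))

    n_h = 1 << k
    # collapse identical (genotype, sex) patterns for speed
    fem_patterns: dict[tuple[int, ...], list[int]] = {}
    mal_patterns: dict[tuple[int, ...], list[int]] = {}
    for i in range(n):
        key = tuple(int(c) for c in calls[i])
        (mal_patterns if is_male[i] else fem_patterns).setdefault(key, []).append(i)

    fem_entries = [
        (rows, np.array(_compatible_pairs(g, k))) for g, rows in fem_patterns.items()
    ]
    mal_entries = [
        (rows, np.array(_compatible_haps(g, k))) for g, rows in mal_patterns.items()
    ]

    # initialise at product of per-site A1 frequencies (X-aware allele counting)
    w = np.where(is_male, 1, 2)[:, None].astype(float)
    obs = calls != MISSING
    denom = (w * obs).sum(axis=0)
    num = np.where(obs, calls, 0).sum(axis=0).astype(float)
    p_site = np.where(denom > 0, num / denom, 0.5)
    freqs = np.ones(n_h)
    for h in range(n_h):
        for j in range(k):
            bit = (h >> (k - 1 - j)) & 1
            freqs[h] *= p_site[j] if bit else (1 - p_site[j])
    freqs = np.clip(freqs, 1e-12, None)
    freqs /= freqs.sum()

    total_chrom = float(2 * (~is_male).sum() + is_male.sum())
    loglik = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        counts = np.zeros(n_h)
        ll = 0.0
        for rows, pairs in fem_entries:
            wts = freqs[pairs[:, 0]] * freqs[pairs[:, 1]]
            tot = wts.sum()
            ll += len(rows) * np.log(tot)
            wts = wts / tot * len(rows)
            np.add.at(counts, pairs[:, 0], wts)
            np.add.at(counts, pairs[:, 1], wts)
        for rows, haps in mal_entries:
            wts = freqs[haps]
            tot = wts.sum()
            ll += len(rows) * np.log(tot)
            np.add.at(counts, haps, wts / tot * len(rows))
        new = counts / total_chrom
        delta = np.abs(new - freqs).max()
        freqs, loglik = new, ll
        if delta < tol:
            break

    # posterior expected haplotype dosages per sample
    dosages = np.zeros((n, n_h))
    for rows, pairs in fem_entries:
        wts = freqs[pairs[:, 0]] * freqs[pairs[:, 1]]
        wts /= wts.sum()
        d = np.zeros(n_h)
        np.add.at(d, pairs[:, 0], wts)
        np.add.at(d, pairs[:, 1], wts)
        dosages[rows] = d
    for rows, haps in mal_entries:
        wts = freqs[haps]
        wts /= wts.sum()
        d = np.zeros(n_h)
        np.add.at(d, haps, wts)
        dosages[rows] = d

    haplotypes = tuple(
        tuple((h >> (k - 1 - j)) & 1 for j in range(k)) for h in range(n_h)
    )
    labels = ()
    if allele_labels is not None:
        labels = tuple(
            "".join(allele_labels[j][1 - bit] for j, bit in enumerate(hap))
            for hap in haplotypes
        )
    return HaplotypeSet(
        variant_ids=tuple(variant_ids),
        haplotypes=haplotypes,
        freqs=freqs,
        dosages=dosages,
        is_male=is_male,
        loglik=float(loglik),
        n_iter=n_iter,
        labels=labels,
    )


def hapset_from_dataset(
    ds: GenotypeDataset, variant_idx, sample_mask=None, **kwargs
) -> HaplotypeSet:
    """Run the EM on a subset of a dataset's variants (and optionally samples)."""
    variant_idx = list(variant_idx)
    mask = np.ones(ds.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
    return em_haplotype_freqs(
        ds.calls[np.ix_(mask, np.array(variant_idx))],
        ds.is_male[mask],
        variant_ids=tuple(ds.variants[j].id for j in variant_idx),
        allele_labels=tuple((ds.variants[j].a1, ds.variants[j].a2) for j in variant_idx),
        **kwargs,
    )


def ld_from_freqs(p_ab: float, p_a: float, p_b: float, id_a="A", id_b="B") -> PairwiseLD:
    """D, D', r^2 from two-locus haplotype/allele frequencies."""
    q_a, q_b = 1 - p_a, 1 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0:
        return PairwiseLD(id_a, id_b, np.nan, np.nan, np.nan)
    D = p_ab - p_a * p_b
    dmax = min(p_a * q_b, q_a * p_b) if D > 0 else min(p_a * p_b, q_a * q_b)
    dprime = 0.0 if D == 0 else abs(D) / dmax
    r2 = D * D / (p_a * q_a * p_b * q_b)
    return PairwiseLD(id_a, id_b, float(D), float(min(dprime, 1.0)), float(min(r2, 1.0)))


def pairwise_ld(hapset: HaplotypeSet) -> PairwiseLD:
    """Pairwise LD from a 2-SNP haplotype set (EM output)."""
    if len(hapset.variant_ids) != 2:
        raise ValueError("pairwise_ld needs exactly 2 SNPs")
    f = hapset.freqs  # order: 00, 01, 10, 11 (bit 0 = A1)
    p_ab = f[3]
    p_a = f[2] + f[3]
    p_b = f[1] + f[3]
    return ld_from_freqs(p_ab, p_a, p_b, *hapset.variant_ids)


def ld_matrices(
    ds: GenotypeDataset, sample_mask=None, **em_kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs D' and r^2 matrices (per-pair 2-SNP EM)."""
    m = ds.n_variants
    dp = np.full((m, m), np.nan)
    r2 = np.full((m, m), np.nan)
    np.fill_diagonal(dp, 1.0)
    np.fill_diagonal(r2, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            hs = hapset_from_dataset(ds, [i, j], sample_mask=sample_mask, **em_kwargs)
            ld = pairwise_ld(hs)
            dp[i, j] = dp[j, i] = ld.Dprime
            r2[i, j] = r2[j, i] = ld.r2
    ids = ds.variant_ids
    return (
        pd.DataFrame(dp, index=ids, columns=ids),
        pd.DataFrame(r2, index=ids, columns=ids),
    )


def _spine_valid(dp: np.ndarray, i: int, j: int, thr: float) -> bool:
    if np.isnan(dp[i, j]) or dp[i, j] < thr:
        return False
    for k in range(i + 1, j):
        if np.isnan(dp[i, k]) or dp[i, k] < thr:
            return False
        if np.isnan(dp[k, j]) or dp[k, j] < thr:
            return False
    return True


def solid_spine_blocks(dprime, spine_threshold: float = 0.8) -> list[Haploblock]:
    """Solid-spine-of-LD haploblocks over map-ordered SNPs.

    A candidate block [i..j] is valid when the first and last SNPs are in
    strong LD (D' >= threshold) with each other and with every intermediate
    SNP.  Greedy left-to-right scan keeps the maximal valid j for each i;
    blocks are disjoint and contain >= 2 SNPs.
    """
    dp = np.asarray(dprime, float)
    if dp.ndim != 2 or dp.shape[0] != dp.shape[1]:
        raise ValueError("D' matrix must be square")
    m = dp.shape[0]
    blocks: list[Haploblock] = []
    i = 0
    while i < m - 1:
        best_j = None
        for j in range(m - 1, i, -1):
            if _spine_valid(dp, i, j, spine_threshold):
                best_j = j
                break
        if best_j is None:
            i += 1
        else:
            blocks.append(Haploblock(tuple(range(i, best_j + 1))))
            i = best_j + 1
    return blocks


def multiallelic_dprime(joint: HaplotypeSet, k_a: int) -> float:
    """Multiallelic D' between two adjacent blocks from their joint haplotypes.

    ``joint`` is an EM fit over the pooled SNPs of both blocks; the first
    ``k_a`` SNPs belong to block A.  Treating each block haplotype as one
    allele, returns sum_ij p_i q_j D'_ij, the frequency-weighted average of the
    biallelic |D|/Dmax between indicator pairs -- the usual between-block
    recombination summary shown on LD plots.
    """
    k = len(joint.variant_ids)
    k_b = k - k_a
    if k_a < 1 or k_b < 1:
        raise ValueError("both blocks need >= 1 SNP")
    p_joint: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}
    for hap, f in zip(joint.haplotypes, joint.freqs):
        key = (hap[:k_a], hap[k_a:])
        p_joint[key] = p_joint.get(key, 0.0) + float(f)
    p_a: dict[tuple[int, ...], float] = {}
    p_b: dict[tuple[int, ...], float] = {}
    for (ha, hb), f in p_joint.items():
        p_a[ha] = p_a.get(ha, 0.0) + f
        p_b[hb] = p_b.get(hb, 0.0) + f
    p_a = {h: f for h, f in p_a.items() if f > 1e-9}
    p_b = {h: f for h, f in p_b.items() if f > 1e-9}
    if len(p_a) < 2 or len(p_b) < 2:
        return np.nan
    total = 0.0
    for ha, pa in p_a.items():
        for hb, pb in p_b.items():
            pab = p_joint.get((ha, hb), 0.0)
            D = pab - pa * pb
            qa, qb = 1 - pa, 1 - pb
            dmax = min(pa * qb, qa * pb) if D > 0 else min(pa * pb, qa * qb)
            if dmax > 0:
                total += pa * pb * abs(D) / dmax
    return float(min(total, 1.0))


def tag_snps(
    r2, positions=None, capture_threshold: float = 0.8
) -> tuple[list[int], dict[int, int]]:
    """Greedy pairwise tag selection.

    Repeatedly picks the SNP whose r^2 >= threshold neighbourhood (itself
    included) covers the most not-yet-captured SNPs; ties go to the lower map
    position.  Returns (tag indices, SNP -> tag assignment covering all SNPs).
    """
    r2 = np.asarray(r2, float)
    m = r2.shape[0]
    if positions is None:
        positions = list(range(m))
    capt = (np.nan_to_num(r2, nan=-1.0) >= capture_threshold)
    np.fill_diagonal(capt, True)
    uncaptured = set(range(m))
    tags: list[int] = []
    assignment: dict[int, int] = {}
    while uncaptured:
        best, best_gain = None, -1
        for cand in range(m):
            gain = len(uncaptured & set(np.nonzero(capt[cand])[0]))
            if gain > best_gain or (
                gain == best_gain and best is not None and positions[cand] < positions[best]
            ):
                best, best_gain = cand, gain
        tags.append(best)
        for s in sorted(uncaptured & set(np.nonzero(capt[best])[0])):
            assignment[s] = best
        uncaptured -= set(np.nonzero(capt[best])[0])
    return tags, assignment


@dataclass
class HaplotypeAssocResult:
    omnibus_stat: float
    omnibus_df: int
    omnibus_p: float
    reference: str
    per_haplotype: pd.DataFrame  # haplotype, freq, beta, ci_low, ci_high, p
    n_used: int


def haplotype_assoc_test(
    y,
    hapset: HaplotypeSet,
    covariates: pd.DataFrame | np.ndarray | None = None,
    rare_pool_threshold: float = 0.01,
    binary: bool = False,
) -> HaplotypeAssocResult:
    """Regression of a phenotype on posterior expected haplotype dosages.

    Haplotypes rarer than ``rare_pool_threshold`` are pooled into one "rare"
    dosage column; the most frequent haplotype is the omitted reference.  The
    omnibus statistic jointly tests all haplotype coefficients (F test for a
    linear model, likelihood ratio for logistic); per-haplotype Wald results
    are returned alongside.
    """
    y = np.asarray(y, float)
    freqs = hapset.freqs
    names = list(hapset.labels) if hapset.labels else [
        "".join(map(str, h)) for h in hapset.haplotypes
    ]
    # haplotypes the EM left with less than half a chromosome of expected
    # count are numerical dust, not rare variants: excluded entirely so the
    # rare pool never becomes a near-zero degenerate design column
    total_chrom = 2 * int((~hapset.is_male).sum()) + int(hapset.is_male.sum())
    min_freq = 0.5 / max(total_chrom, 1)
    present = [h for h in range(len(freqs)) if freqs[h] >= min_freq]
    common = [h for h in present if freqs[h] >= rare_pool_threshold]
    rare = [h for h in present if freqs[h] < rare_pool_threshold]
    if not common:
        raise ValueError("no haplotype above the pooling threshold")
    ref = common[int(np.argmax(freqs[common]))]
    cols, colnames, colfreqs = [], [], []
    for h in common:
        if h == ref:
            continue
        cols.append(hapset.dosages[:, h])
        colnames.append(names[h])
        colfreqs.append(float(freqs[h]))
    if rare and float(freqs[rare].sum()) > 0:
        cols.append(hapset.dosages[:, rare].sum(axis=1))
        colnames.append("rare")
        colfreqs.append(float(freqs[rare].sum()))
    if not cols:
        raise ValueError("only one haplotype after pooling; no test possible")

    X_hap = np.column_stack(cols)
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([X_hap, cov])
    else:
        X = X_hap
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y_, X_ = y[keep], X[keep]
    Xc = sm.add_constant(X_, has_constant="add")
    n_hap = X_hap.shape[1]

    if binary:
        full = sm.Logit(y_, Xc).fit(disp=0)
        restr_cols = [0] + list(range(1 + n_hap, Xc.shape[1]))
        restricted = sm.Logit(y_, Xc[:, restr_cols]).fit(disp=0)
        stat = 2 * (full.llf - restricted.llf)
        df = n_hap
        p = float(stats.chi2.sf(stat, df))
        params, ses = full.params[1 : 1 + n_hap], full.bse[1 : 1 + n_hap]
        z = stats.norm.ppf(0.975)
        per = pd.DataFrame(
            {
                "haplotype": colnames,
                "frequency": colfreqs,
                "beta": params,
                "ci_low": params - z * ses,
                "ci_high": params + z * ses,
                "p": 2 * stats.norm.sf(np.abs(params / ses)),
            }
        )
    else:
        full = sm.OLS(y_, Xc).fit()
        # omnibus F by restricted-vs-full RSS; numerator df is the effective
        # rank the haplotype dosage columns add to the design
        restr_cols = [0] + list(range(1 + n_hap, Xc.shape[1]))
        restricted = sm.OLS(y_, Xc[:, restr_cols]).fit()
        q = int(np.linalg.matrix_rank(Xc) - np.linalg.matrix_rank(Xc[:, restr_cols]))
        if q < 1:
            raise ValueError("haplotype dosages add no rank; no omnibus test")
        df_resid = len(y_) - np.linalg.matrix_rank(Xc)
        stat = ((restricted.ssr - full.ssr) / q) / (full.ssr / df_resid)
        df = q
        p = float(stats.f.sf(stat, q, df_resid))
        params, ses = full.params[1 : 1 + n_hap], full.bse[1 : 1 + n_hap]
        tcrit = stats.t.ppf(0.975, full.df_resid)
        per = pd.DataFrame(
            {
                "haplotype": colnames,
                "frequency": colfreqs,
                "beta": params,
                "ci_low": params - tcrit * ses,
                "ci_high": params + tcrit * ses,
                "p": full.pvalues[1 : 1 + n_hap],
            }
        )
    return HaplotypeAssocResult(
        omnibus_stat=float(stat),
        omnibus_df=int(df),
        omnibus_p=float(p),
        reference=names[ref],
        per_haplotype=per,
        n_used=int(keep.sum()),
    )
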