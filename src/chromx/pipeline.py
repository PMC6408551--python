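"""End-to-end orchestration: load/simulate -> QC -> LD/blocks/tags ->
sex-stratified association -> Clayton replication -> joint & haplotype tests
-> multiple-testing adjustment -> report tables.

The per-sex escape-model regressions are the primary analysis; the stratified
random-XCI score test re-tests every escape-model hit (raw P below
``clayton_alpha``) as a model-robustness replication.  Every raw P lands in
exactly one adjustment family (one family per phenotype x model: all SNPs,
both sexes), mirroring how per-phenotype FDR columns are computed for a
candidate-gene table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as xassoc
from . import ld as ldmod
from . import mtc
from .genodata import (
    FEMALE,
    MALE,
    GenotypeDataset,
    read_phenotypes,
    read_plink_binary,
    validate_x_males,
    write_phenotypes,
    write_plink_binary,
    compute_maf,
)
from .qc import DEFAULT_EXCLUDE_ON, QCThresholds, run_qc
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger("chromx")

COVARIATE_PROFILES = {
    "none": (),
    "age": ("age_years",),
    "age_height": ("age_years", "height_cm"),
    "age_bmi": ("age_years", "bmi_z"),
    "age_height_bmi": ("age_years", "height_cm", "bmi_z"),
}

#: trait -> covariate profile; blood pressure adjusts for age and height,
#: other metabolic traits for age, the BMI z-score itself for nothing
DEFAULT_PHENOTYPES = {
    "bmi_z": "none",
    "waist_cm": "age",
    "whtr": "age",
    "sbp_mmHg": "age_height",
    "dbp_mmHg": "age_height",
    "glucose_mg_dl": "age",
    "insulin_mU_l": "age",
    "homa_ir": "age",
    "quicki": "age",
    "tag_mg_dl": "age",
    "hdl_mg_dl": "age",
    "il6_ng_l": "age",
}


@dataclass
class PipelineConfig:
    simulate: bool = True
    plink_prefix: str | None = None
    pheno_path: str | None = None
    out_dir: str = "chromx_out"
    seed: int = 0
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    qc_exclude_on: tuple[str, ...] = DEFAULT_EXCLUDE_ON
    spine_threshold: float = 0.8
    tag_r2: float = 0.8
    rare_pool_threshold: float = 0.01
    phenotypes: dict = field(default_factory=lambda: dict(DEFAULT_PHENOTYPES))
    dosage_models: tuple[str, ...] = (xassoc.ESCAPE, xassoc.XCI)
    mt_methods: tuple[str, ...] = mtc.METHODS
    clayton_alpha: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "qc_thresholds" in raw:
            raw["qc_thresholds"] = QCThresholds(**raw["qc_thresholds"])
        for key in ("qc_exclude_on", "dosage_models", "mt_methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = {k: repr(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _covariate_matrix(pheno: pd.DataFrame, profile: str, iids) -> np.ndarray | None:
    cols = COVARIATE_PROFILES[profile]
    if not cols:
        return None
    return pheno.reindex(iids)[list(cols)].to_numpy(float)


def association_scan(
    ds: GenotypeDataset,
    pheno: pd.DataFrame,
    phenotypes: dict,
    dosage_models=(xassoc.ESCAPE,),
) -> pd.DataFrame:
    """Per-SNP, per-sex additive regressions for every phenotype/model."""
    rows = []
    for phen, profile in phenotypes.items():
        if phen not in pheno.columns:
            raise KeyError(f"phenotype column {phen!r} missing from table")
        y = pheno.reindex(ds.iids)[phen].to_numpy(float)
        cov = _covariate_matrix(pheno, profile, ds.iids)
        for model in dosage_models:
            for sex in (FEMALE, MALE):
                dos = xassoc.code_dosage(ds, model=model, sex=sex)
                for j, v in enumerate(ds.variants):
                    try:
                        res = xassoc.linear_assoc(
                            y, dos[:, j], covariates=cov, variant=v.id,
                            stratum=sex, model=model, covariate_label=profile,
                        )
                    except ValueError as exc:
                        log.warning("skip %s/%s/%s/%s: %s", phen, v.id, sex, model, exc)
                        continue
                    row = res.as_dict()
                    row["phenotype"] = phen
                    rows.append(row)
    return pd.DataFrame(rows)


def adjust_families(results: pd.DataFrame, methods=mtc.METHODS) -> pd.DataFrame:
    """One family per (phenotype, model): all SNPs x both sexes."""
    out = []
    for (phen, model), grp in results.groupby(["phenotype", "model"], sort=False):
        fam = mtc.PValueFamily(
            label=f"{phen}:{model}",
            test_ids=(grp["variant"] + ":" + grp["stratum"]).tolist(),
            raw=grp["p"].to_numpy(float),
        ).adjust_all(methods)
        sub = grp.copy()
        for m in methods:
            sub[f"p_{m}"] = fam.adjusted[m]
        sub["family"] = fam.label
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def clayton_replication(
    ds: GenotypeDataset,
    pheno: pd.DataFrame,
    results: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-test every escape-model hit with the pooled-sex random-XCI score test."""
    hits = results[(results["model"] == xassoc.ESCAPE) & (results["p"] < alpha)]
    rows = []
    for (phen, vid), _ in hits.groupby(["phenotype", "variant"]):
        y = pheno.reindex(ds.iids)[phen].to_numpy(float)
        j = ds.variant_index(vid)
        stat, p = xassoc.clayton_x_test(y, ds.calls[:, j], ds.is_male)
        rows.append({"phenotype": phen, "variant": vid, "clayton_stat": stat, "clayton_p": p})
    return pd.DataFrame(rows, columns=["phenotype", "variant", "clayton_stat", "clayton_p"])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns in-memory results and writes report files."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- load or simulate -------------------------------------------------
    if cfg.simulate:
        sim_cfg = SimConfig(seed=cfg.seed)
        ds, pheno, truth = simulate_cohort(sim_cfg)
        write_plink_binary(ds, out / "cohort")
        write_phenotypes(pheno, out / "phenotypes.tsv")
        (out / "truth.json").write_text(json.dumps(truth.effects, indent=2))
        log.info("simulated cohort: %d samples, %d variants", ds.n_samples, ds.n_variants)
    else:
        if not (cfg.plink_prefix and cfg.pheno_path):
            raise ValueError("plink_prefix and pheno_path required when simulate is off")
        ds = read_plink_binary(cfg.plink_prefix)
        pheno = read_phenotypes(cfg.pheno_path)
        log.info("loaded cohort: %d samples, %d variants", ds.n_samples, ds.n_variants)

    ds, n_het_males = validate_x_males(ds)
    log.info("male heterozygous calls set missing: %d", n_het_males)

    # --- QC ---------------------------------------------------------------
    qc_report, ds_clean = run_qc(ds, cfg.qc_thresholds, cfg.qc_exclude_on)
    qc_report.to_tsv(out / "qc_report.tsv")
    log.info("QC: %d -> %d variants; failures per rule: %s",
             ds.n_variants, ds_clean.n_variants, qc_report.n_fail)

    # --- LD / blocks / tags ----------------------------------------------
    male = ds_clean.is_male
    ld_tables = {}
    for label, mask in (("pooled", None), ("male", male), ("female", ~male)):
        dp, r2 = ldmod.ld_matrices(ds_clean, sample_mask=mask)
        dp.to_csv(out / f"ld_dprime_{label}.tsv", sep="\t")
        r2.to_csv(out / f"ld_r2_{label}.tsv", sep="\t")
        ld_tables[label] = (dp, r2)
    dp_pooled, r2_pooled = ld_tables["pooled"]
    blocks = ldmod.solid_spine_blocks(dp_pooled.to_numpy(), cfg.spine_threshold)
    block_rows = []
    for bi, blk in enumerate(blocks, 1):
        vids = [ds_clean.variants[j] for j in blk.members]
        block_rows.append({
            "block": f"haploblock-{bi}",
            "chrom": vids[0].chrom,
            "start_bp": vids[0].bp,
            "end_bp": vids[-1].bp,
            "members": ",".join(v.id for v in vids),
        })
    pd.DataFrame(block_rows).to_csv(out / "haploblocks.tsv", sep="\t", index=False)
    log.info("haploblocks: %s", [b["members"] for b in block_rows])

    tag_rows = []
    for bi, blk in enumerate(blocks, 1):
        sub = r2_pooled.to_numpy()[np.ix_(blk.members, blk.members)]
        tags, assign = ldmod.tag_snps(
            sub, positions=[ds_clean.variants[j].bp for j in blk.members],
            capture_threshold=cfg.tag_r2,
        )
        for t in tags:
            captured = [ds_clean.variants[blk.members[s]].id for s, tt in assign.items() if tt == t]
            tag_rows.append({
                "block": f"haploblock-{bi}",
                "tag": ds_clean.variants[blk.members[t]].id,
                "captures": ",".join(captured),
            })
    tags_df = pd.DataFrame(tag_rows)
    tags_df.to_csv(out / "tag_snps.tsv", sep="\t", index=False)

    # per-block haplotype frequencies (pooled EM), written with allele letters
    hap_freq_frames = []
    for bi, blk in enumerate(blocks, 1):
        hs = ldmod.hapset_from_dataset(ds_clean, blk.members)
        ft = hs.frequency_table()
        ft = ft[ft["frequency"] > 1e-4].copy()
        ft["block"] = f"haploblock-{bi}"
        hap_freq_frames.append(ft)
    if hap_freq_frames:
        pd.concat(hap_freq_frames).to_csv(out / "haplotype_freqs.tsv", sep="\t", index=False)

    # --- association ------------------------------------------------------
    results = association_scan(ds_clean, pheno, cfg.phenotypes, cfg.dosage_models)
    results = adjust_families(results, cfg.mt_methods)
    results.to_csv(out / "association.tsv", sep="\t", index=False)

    # --- Clayton replication ---------------------------------------------
    clayton = clayton_replication(ds_clean, pheno, results, cfg.clayton_alpha)
    clayton.to_csv(out / "clayton_replication.tsv", sep="\t", index=False)

    # --- joint conditional & haplotype tests per block --------------------
    joint_rows, hap_rows = [], []
    esc = results[results["model"] == xassoc.ESCAPE]
    for bi, blk in enumerate(blocks, 1):
        member_ids = [ds_clean.variants[j].id for j in blk.members]
        for phen in cfg.phenotypes:
            sig = esc[(esc["phenotype"] == phen) & esc["variant"].isin(member_ids)
                      & (esc["p"] < cfg.clayton_alpha)]
            if sig.empty:
                continue
            y = pheno.reindex(ds_clean.iids)[phen].to_numpy(float)
            cov_prof = cfg.phenotypes[phen]
            cov = _covariate_matrix(pheno, cov_prof, ds_clean.iids)
            for sex in sorted(set(sig["stratum"])):
                mask = male if sex == MALE else ~male
                dos = xassoc.code_dosage(ds_clean, model=xassoc.ESCAPE, sex=sex)
                dos_df = pd.DataFrame(
                    {vid: dos[:, ds_clean.variant_index(vid)] for vid in member_ids}
                )
                try:
                    joint = xassoc.joint_conditional_assoc(y, dos_df, covariates=cov)
                except ValueError as exc:
                    log.warning("joint model %s/%s/%s skipped: %s", phen, bi, sex, exc)
                    continue
                for vid, r in joint.table.iterrows():
                    joint_rows.append({
                        "block": f"haploblock-{bi}", "phenotype": phen, "stratum": sex,
                        "variant": vid, "beta": r["beta"], "se": r["se"], "p": r["p"],
                        "vif": r["vif"], "n_used": joint.n_used,
                        "dropped": ",".join(joint.dropped),
                    })
                hs = ldmod.hapset_from_dataset(ds_clean, blk.members, sample_mask=mask)
                cov_sex = cov[mask] if cov is not None else None
                try:
                    hres = ldmod.haplotype_assoc_test(
                        y[mask], hs, covariates=cov_sex,
                        rare_pool_threshold=cfg.rare_pool_threshold,
                    )
                except ValueError as exc:
                    log.warning("haplotype test %s/%s/%s skipped: %s", phen, bi, sex, exc)
                    continue
                hap_rows.append({
                    "block": f"haploblock-{bi}", "phenotype": phen, "stratum": sex,
                    "omnibus_stat": hres.omnibus_stat, "omnibus_df": hres.omnibus_df,
                    "omnibus_p": hres.omnibus_p, "reference": hres.reference,
                    "n_used": hres.n_used,
                })
    joint_df = pd.DataFrame(joint_rows)
    hap_df = pd.DataFrame(hap_rows)
    joint_df.to_csv(out / "joint_conditional.tsv", sep="\t", index=False)
    hap_df.to_csv(out / "haplotype_tests.tsv", sep="\t", index=False)

    # --- report tables & manifest ----------------------------------------
    table1 = format_table1(results, ds_clean)
    table1.to_csv(out / "table1_bmi_z.tsv", sep="\t", index=False)
    tag_for_table2 = None
    b2 = tags_df[tags_df["block"] == "haploblock-2"]
    if len(b2) == 1:
        tag_for_table2 = b2["tag"].iloc[0]
    table2 = format_table2(results, tag=tag_for_table2)
    table2.to_csv(out / "table2_tag_snp.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "config_sha256": cfg.digest(),
        "n_samples": ds.n_samples,
        "n_variants_input": ds.n_variants,
        "n_variants_after_qc": ds_clean.n_variants,
        "n_male_het_calls_removed": n_het_males,
        "haploblocks": [b["members"] for b in block_rows],
        "tags": tag_rows,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "dataset": ds_clean,
        "phenotypes": pheno,
        "qc": qc_report,
        "ld": ld_tables,
        "blocks": blocks,
        "tags": tags_df,
        "association": results,
        "clayton": clayton,
        "joint": joint_df,
        "haplotype_tests": hap_df,
        "table1": table1,
        "table2": table2,
        "manifest": manifest,
    }


def format_table1(results: pd.DataFrame, ds: GenotypeDataset | None = None) -> pd.DataFrame:
    """BMI-z association table: one row per SNP x sex, escape model.

    Columns mirror the classic candidate-gene layout: alleles, MAF by obesity
    group, beta (2 d.p.) with 95% CI, raw P and the FDR/Bonferroni columns
    (4 d.p.).
    """
    cols = ["variant", "a1_a2", "stratum", "maf_control", "maf_case", "beta",
            "ci_low", "ci_high", "p", "p_bh", "p_bonferroni", "n_used"]
    sub = results[(results.get("phenotype") == "bmi_z")
                  & (results["model"] == xassoc.ESCAPE)].copy() if len(results) else results
    if sub is None or len(sub) == 0:
        return pd.DataFrame(columns=cols)
    alleles, maf_ctrl, maf_case = {}, {}, {}
    if ds is not None:
        mc = compute_maf(ds, group="control")
        mk = compute_maf(ds, group="case")
        for j, v in enumerate(ds.variants):
            alleles[v.id] = f"{v.a1}/{v.a2}"
            maf_ctrl[v.id] = mc[j]
            maf_case[v.id] = mk[j]
    rows = []
    for _, r in sub.iterrows():
        rows.append({
            "variant": r["variant"],
            "a1_a2": alleles.get(r["variant"], ""),
            "stratum": r["stratum"],
            "maf_control": round(maf_ctrl.get(r["variant"], np.nan), 3),
            "maf_case": round(maf_case.get(r["variant"], np.nan), 3),
            "beta": round(r["beta"], 2),
            "ci_low": round(r["ci_low"], 2),
            "ci_high": round(r["ci_high"], 2),
            "p": round(r["p"], 4),
            "p_bh": round(r.get("p_bh", np.nan), 4),
            "p_bonferroni": round(r.get("p_bonferroni", np.nan), 4),
            "n_used": r["n_used"],
        })
    return pd.DataFrame(rows, columns=cols)


def format_table2(results: pd.DataFrame, tag: str | None) -> pd.DataFrame:
    """Tag-SNP table across phenotypes: beta/CI/P per sex, escape model."""
    cols = ["phenotype", "stratum", "covariates", "beta", "ci_low", "ci_high",
            "p", "p_bh", "n_used"]
    if tag is None or len(results) == 0:
        return pd.DataFrame(columns=cols)
    sub = results[(results["variant"] == tag) & (results["model"] == xassoc.ESCAPE)]
    rows = []
    for _, r in sub.iterrows():
        rows.append({
            "phenotype": r["phenotype"],
            "stratum": r["stratum"],
            "covariates": r["covariates"],
            "beta": round(r["beta"], 3),
            "ci_low": round(r["ci_low"], 3),
            "ci_high": round(r["ci_high"], 3),
            "p": round(r["p"], 4),
            "p_bh": round(r.get("p_bh", np.nan), 4),
            "n_used": r["n_used"],
        })
    return pd.DataFrame(rows, columns=cols)
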