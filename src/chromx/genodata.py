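"""Domain types and PLINK-1 binary I/O with X-chromosome (hemizygous male) semantics.

Genotype calls are stored as counts of the A1 (minor) allele: females take values
in {0, 1, 2}, hemizygous males in {0, 1}, and missing calls are coded ``MISSING``
(-1).  This convention maps directly onto the escape-from-XCI dosage coding used
downstream, where a male's single allele contributes one dose.

Only the PLINK-1 variant-major binary dialect is supported (magic bytes
``0x6C 0x1B``, mode byte ``0x01``), matching the format of deposited
candidate-gene filesets.  Sample-major mode (``0x00``) is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

MALE = "male"
FEMALE = "female"
CONTROL = "control"
CASE = "case"

# PLINK1 2-bit codes -> A1-allele count (01 is the missing code)
_BED_MAGIC = bytes([0x6C, 0x1B])
_DECODE2BIT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_ENCODE2BIT = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Malformed PLINK binary fileset."""


@dataclass(frozen=True)
class VariantInfo:
    """One genotyped marker. ``a1`` is the minor allele, ``a2`` the major."""

    id: str
    chrom: str
    bp: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.a1 == self.a2:
            raise ValueError(f"{self.id}: a1 and a2 must differ")
        if self.bp <= 0:
            raise ValueError(f"{self.id}: bp must be positive")


@dataclass(frozen=True)
class SampleRecord:
    """One study child: identifier, sex, and obesity (case/control) group."""

    iid: str
    sex: str
    group: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"{self.iid}: sex must be male/female, got {self.sex!r}")
        if self.group not in (CONTROL, CASE, None):
            raise ValueError(f"{self.iid}: bad group {self.group!r}")


@dataclass
class GenotypeDataset:
    """Sample-by-variant call matrix with X-chromosome semantics.

    ``calls[i, j]`` counts A1 alleles of sample i at variant j; -1 is missing.
    """

    samples: list[SampleRecord]
    variants: list[VariantInfo]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        iids = [s.iid for s in self.samples]
        if len(set(iids)) != len(iids):
            raise ValueError("sample iids not unique")
        vids = [v.id for v in self.variants]
        if len(set(vids)) != len(vids):
            raise ValueError("variant ids not unique")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls contain codes outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def is_male(self) -> np.ndarray:
        return np.array([s.sex == MALE for s in self.samples], dtype=bool)

    @property
    def is_case(self) -> np.ndarray:
        return np.array([s.group == CASE for s in self.samples], dtype=bool)

    @property
    def iids(self) -> list[str]:
        return [s.iid for s in self.samples]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, vid: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == vid:
                return j
        raise KeyError(vid)

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeDataset":
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        vmask = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask, bool)
        return GenotypeDataset(
            samples=[s for s, k in zip(self.samples, smask) if k],
            variants=[v for v, k in zip(self.variants, vmask) if k],
            calls=self.calls[np.ix_(smask, vmask)].copy(),
        )


def read_plink_binary(path_prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK-1 ``.bed``/``.bim``/``.fam`` fileset.

    fam sex code 1 -> male, 2 -> female; any other sex code excludes the sample
    with a warning.  fam phenotype 1 -> control, 2 -> case; anything else is
    kept with group=None.

    Males come back on the hemizygous scale: the bed hom-A1 code decodes to a
    male call of 1 (one A1 copy, the PLINK "0/2" storage convention) and the
    bed heterozygote code -- invalid for one X -- decodes to the marker value
    2, which only :func:`validate_x_males` may clear.
    """
    prefix = Path(path_prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"], dtype=str,
    )
    if bim.shape[1] != 6:
        raise PlinkFormatError(".bim must have 6 columns")
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )

    variants = [
        VariantInfo(id=r.id, chrom=str(r.chrom), bp=int(r.bp), a1=r.a1, a2=r.a2)
        for r in bim.itertuples()
    ]

    samples: list[SampleRecord] = []
    keep_rows: list[int] = []
    for i, r in enumerate(fam.itertuples()):
        if r.sex == "1":
            sex = MALE
        elif r.sex == "2":
            sex = FEMALE
        else:
            warnings.warn(f"sample {r.iid}: unknown sex code {r.sex!r}; excluded")
            continue
        group = {"1": CONTROL, "2": CASE}.get(r.pheno)
        samples.append(SampleRecord(iid=r.iid, sex=sex, group=group))
        keep_rows.append(i)

    n_fam, m = len(fam), len(variants)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(".bed magic bytes are wrong")
    if len(raw) < 3 or raw[2] != 0x01:
        raise PlinkFormatError(".bed is not variant-major (mode byte != 0x01)")
    bytes_per_variant = (n_fam + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * m:
        raise PlinkFormatError(
            f".bed payload is {payload.size} bytes, expected {bytes_per_variant * m}"
        )

    if m == 0:
        calls = np.empty((len(samples), 0), dtype=np.int8)
        return GenotypeDataset(samples=samples, variants=variants, calls=calls)

    blocks = payload.reshape(m, bytes_per_variant)
    # unpack the four 2-bit fields of every byte, sample-order within byte is LSB-first
    two_bit = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, bytes_per_variant * 4)[:, :n_fam]
    calls = _DECODE2BIT[two_bit].T  # samples x variants
    calls = calls[keep_rows, :].copy()
    # hemizygous recode for males: bed hom-A1 (diploid 2) is one A1 copy;
    # a bed heterozygote is invalid on one X and becomes the marker value 2
    male_rows = np.array([s.sex == MALE for s in samples], dtype=bool)
    mc = calls[male_rows]
    swap1, swap2 = mc == 1, mc == 2
    mc[swap1] = 2
    mc[swap2] = 1
    calls[male_rows] = mc
    return GenotypeDataset(samples=samples, variants=variants, calls=calls)


def write_plink_binary(ds: GenotypeDataset, path_prefix: str | Path) -> None:
    """Write ``ds`` as a bit-exact PLINK-1 variant-major fileset."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    bim_rows = [f"{v.chrom}\t{v.id}\t0\t{v.bp}\t{v.a1}\t{v.a2}" for v in ds.variants]
    prefix.with_suffix(".bim").write_text("\n".join(bim_rows) + ("\n" if bim_rows else ""))

    sex_code = {MALE: "1", FEMALE: "2"}
    grp_code = {CONTROL: "1", CASE: "2", None: "-9"}
    fam_rows = [
        f"{s.iid}\t{s.iid}\t0\t0\t{sex_code[s.sex]}\t{grp_code[s.group]}" for s in ds.samples
    ]
    prefix.with_suffix(".fam").write_text("\n".join(fam_rows) + ("\n" if fam_rows else ""))

    n, m = ds.n_samples, ds.n_variants
    bytes_per_variant = (n + 3) // 4
    enc = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    enc[:] = _ENCODE2BIT[0]  # pad slots encode hom-a2, as PLINK does
    calls = ds.calls.copy()
    # inverse of the reader's hemizygous recode: male 1 is stored as bed
    # hom-A1, the marker value 2 round-trips through the bed het code
    male_rows = ds.is_male
    mc = calls[male_rows]
    swap1, swap2 = mc == 1, mc == 2
    mc[swap1] = 2
    mc[swap2] = 1
    calls[male_rows] = mc
    code = np.empty(calls.shape, dtype=np.uint8)
    for val, bits in _ENCODE2BIT.items():
        code[calls == val] = bits
    enc[:, :n] = code.T
    enc4 = enc.reshape(m, bytes_per_variant, 4)
    packed = (enc4[:, :, 0] | (enc4[:, :, 1] << 2) | (enc4[:, :, 2] << 4) | (enc4[:, :, 3] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.astype(np.uint8).tobytes())


def validate_x_males(ds: GenotypeDataset) -> tuple[GenotypeDataset, int]:
    """Set heterozygous male calls to missing; return cleaned dataset and count.

    A male has one X, so a diploid-scale het call is a genotyping artifact.
    The reader parks such calls at the marker value 2 (valid male calls are
    0/1 on the hemizygous scale); they are set missing rather than dropped so
    the sample's other markers survive.  The count feeds the QC log; females
    are untouched.
    """
    calls = ds.calls.copy()
    male = ds.is_male
    het_male = (calls == 2) & male[:, None]
    n_set = int(het_male.sum())
    calls[het_male] = MISSING
    return GenotypeDataset(samples=ds.samples, variants=ds.variants, calls=calls), n_set


def compute_maf(
    ds: GenotypeDataset,
    sex: str | None = None,
    group: str | None = None,
) -> np.ndarray:
    """X-aware A1 allele frequency per variant.

    Each non-missing female call contributes two allele observations, each male
    call one.  Variants with zero observations in the stratum get NaN.
    """
    mask = np.ones(ds.n_samples, bool)
    if sex is not None:
        mask &= np.array([s.sex == sex for s in ds.samples])
    if group is not None:
        mask &= np.array([s.group == group for s in ds.samples])
    if not mask.any():
        raise ValueError("stratum is empty")
    calls = ds.calls[mask]
    male = ds.is_male[mask]
    obs = calls != MISSING
    weights = np.where(male, 1, 2)[:, None] * obs
    a1 = np.where(obs, calls, 0)
    denom = weights.sum(axis=0).astype(float)
    num = a1.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, num / denom, np.nan)
    return freq


def read_phenotypes(path: str | Path, index_col: str = "iid") -> pd.DataFrame:
    """Read the per-sample phenotype/covariate table (TSV, NA = missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if index_col in df.columns:
        df = df.set_index(index_col)
    df.index = df.index.astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="iid")
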