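"""Genotype and summary-statistics containers plus on-disk formats.

The pipeline's interchange formats are PLINK-1 binary genotypes
(``.bed``/``.bim``/``.fam``), a tab-separated summary-statistics table
(``SNP CHR BP A1 A2 BETA SE P EAF``), and a tab-separated samples sidecar
carrying phenotype and survival columns that ``.fam`` has no slot for.

Dosages are stored as minor-allele (A1) counts in ``{0, 1, 2}`` with
``NaN`` marking missing hard calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "SummaryStats",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "read_sumstats",
    "write_sumstats",
    "read_samples_table",
    "write_samples_table",
]

#: columns every variant table carries, in order
VARIANT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]

#: mandatory summary-statistics columns after column mapping
SUMSTAT_REQUIRED = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"]
SUMSTAT_OPTIONAL = ["SE", "EAF"]


class PlinkFormatError(ValueError):
    """Raised when a .bed payload violates the PLINK-1 binary format."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant and sample metadata.

    Attributes
    ----------
    dosages
        ``(n_samples, n_variants)`` float array of A1-allele counts;
        ``NaN`` encodes a missing call.
    variants
        DataFrame with columns ``snp, chrom, pos, a1, a2`` (1-based bim
        positions; A1 is the scored/minor allele by convention).
    samples
        DataFrame indexed 0..n-1 with at least ``sample_id``; phenotype
        columns (``status, age, event, sex, e2_dosage, e4_dosage``) are
        attached when known.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"variant table has {len(self.variants)} rows but dosage "
                f"matrix has {self.dosages.shape[1]} columns"
            )
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError(
                f"sample table has {len(self.samples)} rows but dosage "
                f"matrix has {self.dosages.shape[0]} rows"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be hard calls in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-variant A1 allele frequency, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            self.samples.copy(),
        )

    def subset_samples(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[idx, :],
            self.variants.copy(),
            self.samples.iloc[idx].reset_index(drop=True),
        )


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics.

    ``table`` holds one row per SNP with columns ``SNP CHR BP A1 A2 BETA P``
    plus optional ``SE`` and ``EAF``; ``A1`` is the effect allele, ``BETA``
    its per-allele effect size and ``P`` the association p-value in (0, 1].
    """

    table: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def replace_table(self, table: pd.DataFrame) -> "SummaryStats":
        return replace(self, table=table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# PLINK-1 binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit genotype code -> A1-allele count (PLINK-1 spec):
# 00 = hom A1 (2), 01 = missing, 10 = het (1), 11 = hom A2 (0)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK-1 fileset ``prefix.{bed,bim,fam}`` into memory.

    Only the SNP-major variant-by-variant layout (mode byte 0x01) is
    supported, which is what every modern PLINK writes.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp": str, "pos": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "sample_id", "pid", "mid", "sex", "pheno"],
        dtype={"sample_id": str},
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        found = raw[0] if raw else None
        raise PlinkFormatError(
            f"not a PLINK-1 bed file: first bytes "
            f"{raw[:2].hex() if raw else '<empty>'} (expected 6c1b); "
            f"offending byte 0x{found:02x}" if raw else "empty bed file"
        )
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"unsupported bed mode byte 0x{raw[2]:02x} (need 0x01, SNP-major)"
        )
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"bed payload has {len(raw) - 3} bytes, expected "
            f"{bytes_per_variant} x {m} = {expected - 3} for "
            f"{n} samples x {m} variants (truncated or wrong fam/bim?)"
        )

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if m == 0 or n == 0:
        dos = np.empty((n, m))
    else:
        blocks = payload.reshape(m, bytes_per_variant)
        # unpack the four 2-bit codes of each byte, sample-index order
        codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
        for k in range(4):
            codes[:, k::4] = (blocks >> (2 * k)) & 0b11
        dos = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    samples = fam[["sample_id", "sex"]].copy()
    variants = bim[VARIANT_COLUMNS].copy()
    return GenotypeMatrix(dos, variants, samples)


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``geno`` as a PLINK-1 fileset; exact inverse of `read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.n_samples, geno.n_variants

    v = geno.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"].astype(int),
            "snp": v["snp"],
            "cm": 0,
            "pos": v["pos"].astype(int),
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    s = geno.samples
    fam = pd.DataFrame(
        {
            "fid": s["sample_id"],
            "sample_id": s["sample_id"],
            "pid": 0,
            "mid": 0,
            "sex": s["sex"].astype(int) if "sex" in s else 0,
            "pheno": (s["status"].astype(int) + 1) if "status" in s else -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bytes_per_variant = (n + 3) // 4
    codes = np.full((m, bytes_per_variant * 4), 0b01, dtype=np.uint8)
    dosage_t = geno.dosages.T
    for val, code in _DOSAGE_TO_CODE.items():
        rows, cols = np.nonzero(dosage_t == val)
        codes[rows, cols] = code
    codes[:, :n][np.isnan(dosage_t)] = 0b01

    packed = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Summary statistics and samples tables
# ---------------------------------------------------------------------------


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait: str = "trait",
) -> tuple[SummaryStats, dict[str, int]]:
    """Read a whitespace/tab-separated summary-statistics file.

    Parameters
    ----------
    path
        File with a header line.
    column_map
        Mapping from the file's column names to the canonical names
        (``SNP CHR BP A1 A2 BETA SE P EAF``). Columns already canonically
        named need no entry. Source dialects vary too much for inference,
        so the mapping is explicit configuration.
    trait
        Trait label attached to the result.

    Returns
    -------
    (SummaryStats, drop_log)
        ``drop_log`` counts rows removed for unparseable ``BETA``/``P``
        and for out-of-domain p-values (``p_nonpositive``: p <= 0 cannot
        enter log-scale thresholding; ``p_above_one``).
    """
    df = pd.read_csv(path, sep=r"\s+", header=0, dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SUMSTAT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(
            f"summary statistics at {path} lack mandatory columns {missing} "
            f"after mapping; found headers {list(df.columns)}"
        )

    drop_log = {"beta_unparseable": 0, "p_unparseable": 0, "p_nonpositive": 0, "p_above_one": 0}
    beta = pd.to_numeric(df["BETA"], errors="coerce")
    pval = pd.to_numeric(df["P"], errors="coerce")

    bad_beta = beta.isna()
    bad_p = pval.isna()
    drop_log["beta_unparseable"] = int(bad_beta.sum())
    drop_log["p_unparseable"] = int((bad_p & ~bad_beta).sum())
    keep = ~(bad_beta | bad_p)

    nonpos = keep & (pval <= 0)
    above = keep & (pval > 1)
    drop_log["p_nonpositive"] = int(nonpos.sum())
    drop_log["p_above_one"] = int(above.sum())
    keep &= ~(nonpos | above)

    out = df.loc[keep].copy()
    out["BETA"] = beta[keep]
    out["P"] = pval[keep]
    out["CHR"] = pd.to_numeric(out["CHR"], errors="coerce").astype(int)
    out["BP"] = pd.to_numeric(out["BP"], errors="coerce").astype(int)
    for col in SUMSTAT_OPTIONAL:
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in ("A1", "A2"):
        out[col] = out[col].str.upper()

    dropped = int(len(df) - len(out))
    if dropped:
        logger.info("read_sumstats(%s): dropped %d rows (%s)", path, dropped, drop_log)
    return SummaryStats(out.reset_index(drop=True), trait=trait), drop_log


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    cols = [c for c in ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "EAF"] if c in ss.table.columns]
    ss.table.to_csv(path, sep="\t", index=False, columns=cols)


SAMPLES_COLUMNS = ["sample_id", "status", "age", "event", "sex", "e2_dosage", "e4_dosage"]


def write_samples_table(samples: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SAMPLES_COLUMNS if c in samples.columns]
    extra = [c for c in samples.columns if c not in cols]
    samples.to_csv(path, sep="\t", index=False, columns=cols + extra)


def read_samples_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id",) if c not in df.columns]
    if missing:
        raise ValueError(f"samples table {path} lacks columns {missing}")
    return df
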