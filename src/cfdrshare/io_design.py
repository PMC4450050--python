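"""Reading, harmonising and QC-filtering GWAS summary statistics.

Summary statistics live in pandas DataFrames with standardised column
names.  A single-phenotype table carries ``snp_id, chrom, pos, p, z`` (plus
whatever extra columns the input had); a harmonised pair table carries
``snp_id, chrom, pos, p_i, p_j, z_i, z_j`` and, after adjustment,
``p_adj``.

The two-sided convention is used throughout: z = Phi^-1(1 - p/2) is the
magnitude of the association Z score.  Effect signs are never needed by
any downstream formula and are not stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: smallest representable p value; exact zeros are clamped here
P_FLOOR = 1e-300

#: default QC thresholds
CALL_RATE_MIN = 0.99
MAF_MIN = 0.02
HWE_Z_MAX = 5.0

#: default exclusion: a wide band around the MHC on chromosome 6
#: (1-based inclusive coordinates, NCBI36)
MHC_INTERVAL = ("6", 24_500_000, 34_800_000)

_STANDARD_ROLES = ("snp", "chr", "pos", "p", "z", "maf")


class ConfigurationError(ValueError):
    """Raised when required input structure (columns, designs) is missing."""


def p_to_z(p):
    """Two-sided |Z| magnitude for p values: Phi^-1(1 - p/2)."""
    p = np.asarray(p, float)
    return norm.isf(p / 2.0)


def z_to_p(z):
    """Two-sided p value for |Z| magnitudes: 2 * (1 - Phi(|z|))."""
    z = np.abs(np.asarray(z, float))
    return np.minimum(2.0 * norm.sf(z), 1.0)


def clamp_p(p, floor: float = P_FLOOR):
    """Clamp p values of exactly 0 up to ``floor`` (with a warning)."""
    p = np.asarray(p, float)
    n_zero = int(np.sum(p <= 0))
    if n_zero:
        logger.warning("clamping %d p value(s) <= 0 to %g", n_zero, floor)
    return np.maximum(p, floor)


@dataclass(frozen=True)
class StudyPairDesign:
    """Case/control structure of a pair of case-control studies.

    Attributes
    ----------
    n_cases_i, n_cases_j
        Numbers of cases in the principal / conditional study.
    n_controls_unique_i, n_controls_unique_j
        Controls used by only one of the two studies.
    n_controls_shared
        Controls genotyped once and used by both studies; the source of
        the correlation between null Z scores.
    """

    n_cases_i: int
    n_cases_j: int
    n_controls_unique_i: int
    n_controls_unique_j: int
    n_controls_shared: int

    def __post_init__(self):
        for name in ("n_cases_i", "n_cases_j"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_controls_unique_i", "n_controls_unique_j",
                     "n_controls_shared"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_controls_unique_i + self.n_controls_shared < 1:
            raise ValueError("study i has no controls")
        if self.n_controls_unique_j + self.n_controls_shared < 1:
            raise ValueError("study j has no controls")

    @property
    def n_controls_total_i(self) -> int:
        return self.n_controls_unique_i + self.n_controls_shared

    @property
    def n_controls_total_j(self) -> int:
        return self.n_controls_unique_j + self.n_controls_shared

    @property
    def rho(self) -> float:
        """Asymptotic correlation of null Z scores induced by sharing."""
        from .shared_control import rho_shared

        return rho_shared(self)


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_summary(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read one phenotype's summary statistics from delimited text.

    Parameters
    ----------
    path
        TSV or CSV file with a header (dialect auto-detected).
    column_map
        Mapping from standard roles (``snp, chr, pos, p, z, maf``) to the
        column names used in the file.  Roles absent from the mapping fall
        back to the role name itself.

    Returns
    -------
    DataFrame with columns ``snp_id, chrom, pos, p, z`` (plus ``maf`` if
    present).  ``z`` is computed from ``p`` when absent; rows with
    missing or non-finite p are dropped with a logged count.
    """
    column_map = dict(column_map or {})
    unknown = set(column_map) - set(_STANDARD_ROLES)
    if unknown:
        raise ConfigurationError(f"unknown roles in column_map: {sorted(unknown)}")

    df = pd.read_csv(path, sep=_detect_sep(path))
    names = {role: column_map.get(role, role) for role in _STANDARD_ROLES}
    if names["p"] not in df.columns:
        raise ConfigurationError(
            f"mandatory p column {names['p']!r} not found in {path}"
        )

    out = pd.DataFrame()
    out["snp_id"] = (
        df[names["snp"]].astype(str)
        if names["snp"] in df.columns
        else [f"snp{i}" for i in range(len(df))]
    )
    out["chrom"] = (
        df[names["chr"]].astype(str) if names["chr"] in df.columns else "0"
    )
    out["pos"] = (
        pd.to_numeric(df[names["pos"]], errors="coerce").astype("Int64")
        if names["pos"] in df.columns
        else pd.array(range(len(df)), dtype="Int64")
    )
    p = pd.to_numeric(df[names["p"]], errors="coerce").to_numpy(float)

    bad = ~np.isfinite(p)
    if bad.any():
        logger.warning("dropping %d row(s) with missing/non-finite p", int(bad.sum()))
    out["p"] = p
    if names["maf"] in df.columns:
        out["maf"] = pd.to_numeric(df[names["maf"]], errors="coerce")
    out = out.loc[~bad].reset_index(drop=True)
    out["p"] = clamp_p(out["p"].to_numpy())
    if names["z"] in df.columns:
        z = pd.to_numeric(df.loc[~bad, names["z"]], errors="coerce").abs()
        out["z"] = z.to_numpy(float)
        missing_z = ~np.isfinite(out["z"].to_numpy())
        out.loc[missing_z, "z"] = p_to_z(out.loc[missing_z, "p"].to_numpy())
    else:
        out["z"] = p_to_z(out["p"].to_numpy())
    return out


def harmonize(records_i: pd.DataFrame, records_j: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two single-phenotype tables on snp_id.

    Returns a pair table sorted by (chrom, pos, snp_id) with columns
    ``snp_id, chrom, pos, p_i, p_j, z_i, z_j``.  SNPs typed in only one
    study are dropped (counts logged).  Duplicate snp_ids within one
    study raise a ValueError naming the first offending id.
    """
    for side, df in (("i", records_i), ("j", records_j)):
        dup = df["snp_id"][df["snp_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate snp_id in study {side}: {dup.iloc[0]!r}"
            )
    left = records_i.rename(columns={"p": "p_i", "z": "z_i"})
    right = records_j.rename(columns={"p": "p_j", "z": "z_j"})
    keep_j = ["snp_id", "p_j", "z_j"]
    merged = left.merge(right[keep_j], on="snp_id", how="inner")
    n_drop_i = len(records_i) - len(merged)
    n_drop_j = len(records_j) - len(merged)
    if n_drop_i or n_drop_j:
        logger.info(
            "harmonize: dropped %d id(s) from study i, %d from study j",
            n_drop_i, n_drop_j,
        )
    if merged.empty:
        logger.warning("harmonize: studies share no snp_ids")
    merged = merged.sort_values(["chrom", "pos", "snp_id"], kind="mergesort")
    return merged.reset_index(drop=True)


@dataclass
class QcFilterResult:
    records: pd.DataFrame
    removed: dict[str, int] = field(default_factory=dict)


def qc_filter(
    records: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    call_rate_min: float = CALL_RATE_MIN,
    maf_min: float = MAF_MIN,
    hwe_z_max: float = HWE_Z_MAX,
    exclusions: list[tuple[str, int, int]] | None = None,
) -> QcFilterResult:
    """Remove SNPs failing QC rules or lying in excluded intervals.

    ``qc`` is a per-SNP table with columns ``snp_id, call_rate, maf,
    hwe_z``; records without a QC row are retained with a warning (the
    QC panel need not cover every study).  ``exclusions`` is a list of
    closed 1-based intervals ``(chrom, start, end)``; the default is a
    wide band around the MHC on chromosome 6.  Returns the surviving
    records and per-rule removal counts (a SNP failing several rules is
    counted once per rule).
    """
    if exclusions is None:
        exclusions = [MHC_INTERVAL]

    n = len(records)
    fail = {
        "call_rate": np.zeros(n, bool),
        "maf": np.zeros(n, bool),
        "hwe": np.zeros(n, bool),
        "exclusion": np.zeros(n, bool),
    }

    if qc is not None and n:
        merged = records[["snp_id"]].merge(qc, on="snp_id", how="left")
        has_qc = merged["call_rate"].notna().to_numpy()
        n_missing = int((~has_qc).sum())
        if n_missing:
            logger.warning("qc_filter: %d record(s) lack QC summaries; retained",
                           n_missing)
        cr = merged["call_rate"].to_numpy(float)
        maf = merged["maf"].to_numpy(float)
        hz = merged["hwe_z"].to_numpy(float)
        fail["call_rate"] = has_qc & (cr < call_rate_min)
        fail["maf"] = has_qc & (maf < maf_min)
        fail["hwe"] = has_qc & (np.abs(hz) > hwe_z_max)

    if n:
        chrom = records["chrom"].astype(str).to_numpy()
        pos = records["pos"].to_numpy(float)
        for (c, start, end) in exclusions:
            fail["exclusion"] |= (chrom == str(c)) & (pos >= start) & (pos <= end)

    any_fail = np.zeros(n, bool)
    for mask in fail.values():
        any_fail |= mask
    removed = {rule: int(mask.sum()) for rule, mask in fail.items()}
    return QcFilterResult(
        records=records.loc[~any_fail].reset_index(drop=True), removed=removed
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write any table as TSV (the package's only output dialect)."""
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    """Read a harmonised pair table previously written by write_table."""
    df = pd.read_csv(path, sep="\t")
    for col in ("p_i", "p_j"):
        if col not in df.columns:
            raise ConfigurationError(f"pair table lacks column {col!r}")
        df[col] = clamp_p(df[col].to_numpy(float))
    for pcol, zcol in (("p_i", "z_i"), ("p_j", "z_j")):
        if zcol not in df.columns:
            df[zcol] = p_to_z(df[pcol].to_numpy())
    return df
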