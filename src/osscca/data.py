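"""Aligned imaging/genotype/target data containers, readers, and SNP quality control.

The genotype block follows the additive PLINK ``--recode A`` convention:
each entry is the number of copies of the counted (minor) allele, i.e.
0, 1 or 2, with ``NA`` for missing calls. Missing values are represented
as ``numpy.nan`` throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "QcThresholds",
    "QcReport",
    "ColumnStats",
    "read_imaging_table",
    "read_target",
    "read_plink_raw",
    "write_imaging_table",
    "write_target",
    "write_plink_raw",
    "mask_low_gq",
    "variant_stats",
    "hwe_exact_test",
    "apply_qc",
    "impute_and_standardize",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected text dialect."""


@dataclass
class Dataset:
    """Aligned subject-level blocks: imaging X (n×p), genotypes Y (n×q), target Z (n).

    X holds continuous imaging features (e.g. mean FA per brain region),
    Y minor-allele counts in {0, 1, 2} with ``nan`` for missing calls,
    and Z one continuous target value per subject (e.g. age at onset in
    years). Rows of all three blocks refer to the same subjects in the
    same order.
    """

    subject_ids: list[str]
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    imaging_names: list[str]
    variant_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float).ravel()
        n = len(self.subject_ids)
        if n < 2:
            raise ValueError("a Dataset needs at least 2 subjects")
        if self.X.shape[0] != n or self.Y.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X, Y and Z must share the same number of rows")
        if self.X.shape[1] != len(self.imaging_names):
            raise ValueError("imaging_names length must match X columns")
        if self.Y.shape[1] != len(self.variant_names):
            raise ValueError("variant_names length must match Y columns")
        for labels, what in (
            (self.subject_ids, "subject ids"),
            (self.imaging_names, "imaging feature labels"),
            (self.variant_names, "variant names"),
        ):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {what}")
        obs = self.Y[~np.isnan(self.Y)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing genotype entries must be 0, 1 or 2")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class QcThresholds:
    """Per-variant QC cut-offs: MAF, call rate, HWE exact-test p, genotype quality."""

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    gq_min: int = 20

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.gq_min < 0:
            raise ValueError("gq_min must be non-negative")


@dataclass
class QcReport:
    """One row per input variant recording its statistics and the keep/drop decision."""

    table: pd.DataFrame  # columns: variant, maf, call_rate, hwe_p, kept, reasons
    thresholds: QcThresholds

    def __post_init__(self) -> None:
        expected = {"variant", "maf", "call_rate", "hwe_p", "kept", "reasons"}
        missing = expected - set(self.table.columns)
        if missing:
            raise ValueError(f"QcReport table missing columns: {sorted(missing)}")

    @property
    def kept_variants(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "variant"])

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["reasons"] = out["reasons"].map(";".join)
        out.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": {
                "maf_min": self.thresholds.maf_min,
                "call_rate_min": self.thresholds.call_rate_min,
                "hwe_p_min": self.thresholds.hwe_p_min,
                "gq_min": self.thresholds.gq_min,
            },
            "variants": [
                {
                    "variant": r.variant,
                    "maf": None if pd.isna(r.maf) else float(r.maf),
                    "call_rate": float(r.call_rate),
                    "hwe_p": None if pd.isna(r.hwe_p) else float(r.hwe_p),
                    "kept": bool(r.kept),
                    "reasons": list(r.reasons),
                }
                for r in self.table.itertuples(index=False)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):  # pandas would silently rename duplicates
        raise FormatError(f"{path}: duplicate labels in header")
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"{path}: malformed delimited text: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected an ID column plus at least one feature")
    return df


def read_imaging_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a subjects × features table (CSV/TSV, first column = subject ID)."""
    df = _read_delimited(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    labels = [str(c) for c in df.columns[1:]]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate subject IDs")
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate feature labels in header")
    try:
        mat = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in feature table: {exc}") from exc
    return mat, ids, labels


def read_target(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a per-subject target vector (CSV: ID column then one value column)."""
    mat, ids, labels = read_imaging_table(path)
    if mat.shape[1] != 1:
        raise FormatError(f"{path}: target file must have exactly one value column")
    return mat[:, 0], ids


_RAW_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_plink_raw(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an additively recoded genotype file (PLINK ``--recode A`` dialect).

    Whitespace-delimited; six leading columns (FID IID PAT MAT SEX
    PHENOTYPE) then one column per variant with cells in {0, 1, 2, NA}.
    Returns (matrix with nan for NA, subject IIDs, variant names).
    """
    path = Path(path)
    lines = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0]
    if len(header) < 6 or [h.upper() for h in header[:6]] != _RAW_LEAD:
        raise FormatError(
            f"{path}: header must start with the six standard columns {' '.join(_RAW_LEAD)}"
        )
    variant_names = header[6:]
    n_cols = len(header)
    ids: list[str] = []
    rows: list[list[float]] = []
    for i, tok in enumerate(lines[1:], start=2):
        if len(tok) != n_cols:
            raise FormatError(f"{path}: line {i} has {len(tok)} fields, expected {n_cols}")
        ids.append(tok[1])
        row = []
        for cell in tok[6:]:
            if cell == "NA":
                row.append(math.nan)
            elif cell in ("0", "1", "2"):
                row.append(float(cell))
            else:
                raise FormatError(
                    f"{path}: line {i}: genotype cell {cell!r} not in {{0,1,2,NA}}"
                )
        rows.append(row)
    return np.array(rows, dtype=float).reshape(len(rows), len(variant_names)), ids, variant_names


def write_imaging_table(
    path: str | Path, mat: np.ndarray, ids: Sequence[str], labels: Sequence[str]
) -> None:
    df = pd.DataFrame(np.asarray(mat, dtype=float), columns=list(labels))
    df.insert(0, "subject_id", list(ids))
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


def write_target(path: str | Path, values: Sequence[float], ids: Sequence[str]) -> None:
    write_imaging_table(path, np.asarray(values, dtype=float).reshape(-1, 1), ids, ["target"])


def write_plink_raw(
    path: str | Path, Y: np.ndarray, ids: Sequence[str], variant_names: Sequence[str]
) -> None:
    Y = np.asarray(Y, dtype=float)
    with open(path, "w") as fh:
        fh.write(" ".join(_RAW_LEAD + list(variant_names)) + "\n")
        for i, sid in enumerate(ids):
            cells = [
                "NA" if math.isnan(v) else str(int(v)) for v in Y[i]
            ]
            fh.write(" ".join([sid, sid, "0", "0", "0", "-9"] + cells) + "\n")


# ---------------------------------------------------------------------------
# QC arithmetic
# ---------------------------------------------------------------------------


def mask_low_gq(genotypes: np.ndarray, gq: np.ndarray, gq_min: int) -> np.ndarray:
    """Set genotype calls with quality below ``gq_min`` to missing."""
    genotypes = np.asarray(genotypes, dtype=float)
    gq = np.asarray(gq)
    if genotypes.shape != gq.shape:
        raise ValueError("genotype and GQ matrices must have the same shape")
    out = genotypes.copy()
    out[gq < gq_min] = np.nan
    return out


def variant_stats(column: np.ndarray) -> tuple[float, float]:
    """Return (maf, call_rate) for one genotype column.

    The allele frequency of the counted allele is computed over
    non-missing calls; maf = min(f, 1 − f). An all-missing column has
    call_rate 0 and maf ``nan``.
    """
    col = np.asarray(column, dtype=float).ravel()
    obs = col[~np.isnan(col)]
    call_rate = obs.size / col.size if col.size else 0.0
    if obs.size == 0:
        return math.nan, 0.0
    f = obs.sum() / (2.0 * obs.size)
    return min(f, 1.0 - f), call_rate


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg equilibrium test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed that of
    the observed count (the convention used by PLINK; no mid-p
    correction). A monomorphic site returns 1 by convention.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("total genotype count must be at least 1")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # copies of the rarer allele
    if rare == 0:
        return 1.0
    probs = _hwe_het_probabilities(rare, n)
    obs_p = probs[n_het]
    # tolerance guards against float round-off when comparing equal masses
    p = probs[probs <= obs_p * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_het_probabilities(rare: int, n: int) -> np.ndarray:
    """Conditional distribution of the heterozygote count.

    Given ``rare`` copies of the minor allele among ``n`` diploid
    genotypes, returns an array indexed by heterozygote count (0..n with
    impossible counts at probability 0), computed by the standard
    Levene–Haldane recurrence.
    """
    probs = np.zeros(n + 1)
    # heterozygote count shares parity with the minor-allele count
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * (c-h+2)/2) inverse
    het = mid
    hom_r = (rare - het) // 2
    hom_c = n - het - hom_r
    h, hr, hc = het, hom_r, hom_c
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hr + 1) * (hc + 1))
        h -= 2
        hr += 1
        hc += 1
    h, hr, hc = het, hom_r, hom_c
    while h <= min(rare, 2 * n - rare) - 2:
        probs[h + 2] = probs[h] * 4.0 * hr * hc / ((h + 2.0) * (h + 1.0))
        h += 2
        hr -= 1
        hc -= 1
    probs /= probs.sum()
    return probs


def apply_qc(
    Y: np.ndarray,
    thresholds: QcThresholds,
    variant_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, QcReport]:
    """Drop variants failing the MAF, call-rate or HWE thresholds.

    Column order of the survivors is preserved. Raises if no variant
    survives. GQ masking is a per-call operation and is applied
    beforehand via :func:`mask_low_gq`.
    """
    Y = np.asarray(Y, dtype=float)
    q = Y.shape[1]
    names = list(variant_names) if variant_names is not None else [f"var{j}" for j in range(q)]
    if len(names) != q:
        raise ValueError("variant_names length must match the number of columns")
    rows = []
    keep = []
    for j in range(q):
        col = Y[:, j]
        maf, call_rate = variant_stats(col)
        obs = col[~np.isnan(col)]
        if obs.size:
            counts = ((obs == 0).sum(), (obs == 1).sum(), (obs == 2).sum())
            hwe_p = hwe_exact_test(*counts)
        else:
            hwe_p = math.nan
        reasons = []
        if math.isnan(maf) or maf < thresholds.maf_min:
            reasons.append("maf")
        if call_rate < thresholds.call_rate_min:
            reasons.append("call_rate")
        if math.isnan(hwe_p) or hwe_p < thresholds.hwe_p_min:
            reasons.append("hwe")
        kept = not reasons
        keep.append(kept)
        rows.append(
            {
                "variant": names[j],
                "maf": maf,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "kept": kept,
                "reasons": tuple(reasons),
            }
        )
    report = QcReport(table=pd.DataFrame(rows), thresholds=thresholds)
    keep = np.array(keep, dtype=bool)
    if not keep.any():
        raise ValueError("empty panel: no variant passed QC")
    return Y[:, keep], report


# ---------------------------------------------------------------------------
# imputation + standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnStats:
    """Training-fold column means / sds reused to transform held-out rows."""

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.constant is None:
            object.__setattr__(self, "constant", np.zeros_like(np.asarray(self.mean), dtype=bool))


def impute_and_standardize(
    M: np.ndarray, stats: ColumnStats | None = None
) -> tuple[np.ndarray, ColumnStats]:
    """Mean-impute missing entries, then center and scale each column.

    Scaling uses the sample (n−1) standard deviation. When ``stats`` is
    supplied (held-out folds), the training means and sds are applied
    unchanged — including for imputation — so no information flows from
    the transformed rows. Zero-variance columns are scaled by 1 and
    flagged, yielding all-zero output columns.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M.reshape(-1, 1)
    if stats is None:
        if np.isnan(M).all(axis=0).any():
            raise ValueError("cannot standardize a column with no observed values")
        mean = np.nanmean(M, axis=0)
        filled = np.where(np.isnan(M), mean, M)
        sd = filled.std(axis=0, ddof=1) if M.shape[0] > 1 else np.zeros(M.shape[1])
        constant = sd <= 0.0
        sd_safe = np.where(constant, 1.0, sd)
        stats = ColumnStats(mean=mean, sd=sd_safe, constant=constant)
    else:
        filled = np.where(np.isnan(M), stats.mean, M)
    out = (filled - stats.mean) / stats.sd
    return out, stats
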