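"""Bulk TRB-CDR3 repertoire I/O, diversity/clonality and similarity.

A repertoire is the set of unique rearranged TRB sequences observed in one
sample (tumor, normal adjacent tissue, or PBMC), each with a read count and a
frequency. Diversity is summarized by Shannon entropy of the clonotype
frequency distribution; *clonality* = 1 − H/ln(U) rescales it so that 0 is a
perfectly even repertoire and 1 a monoclonal one.

Two tab-separated dialects are read and auto-detected by header:

* immunoSEQ-export style: ``nucleotide``, ``aminoAcid``, ``count``
  (or ``count (templates/reads)``), ``vGeneName``, ``jGeneName``,
  ``sequenceStatus`` (``In`` = productive).
* AIRR Rearrangement: ``junction``, ``junction_aa``, ``duplicate_count``,
  ``v_call``, ``j_call``, ``productive`` (T/F).

File-supplied frequencies are never trusted: frequencies are always
recomputed so productive frequencies sum to 1 per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

CANONICAL_COLUMNS = ["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "read_count", "frequency"]


class RepertoireFormatError(ValueError):
    """Raised when an input table is missing mandatory columns."""


class EmptyRepertoireError(ValueError):
    """Raised when no productive records remain."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One unique TRB rearrangement in one sample."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    read_count: int
    frequency: float
    productive: bool


@dataclass
class Repertoire:
    """A per-sample collection of clonotype records with metadata.

    ``data`` holds one row per unique ``cdr3_nt`` with canonical columns
    (cdr3_nt, cdr3_aa, v_gene, j_gene, read_count, frequency, productive).
    """

    sample_id: str
    patient_id: str
    tissue: str
    data: pd.DataFrame
    timepoint: str | None = None
    parse_report: dict = field(default_factory=dict)

    @property
    def records(self) -> list[ClonotypeRecord]:
        return [ClonotypeRecord(**row) for row in self.data[CANONICAL_COLUMNS + ["productive"]].to_dict("records")]

    @property
    def productive(self) -> pd.DataFrame:
        return self.data[self.data["productive"]]

    @property
    def unique_count(self) -> int:
        return int(self.productive.shape[0])

    @property
    def total_productive_reads(self) -> int:
        return int(self.productive["read_count"].sum())

    def frequencies(self, key: str = "cdr3_nt") -> pd.Series:
        """Productive clonotype frequencies aggregated by ``key``."""
        prod = self.productive
        return prod.groupby(key)["frequency"].sum()

    def unique_sequences(self, key: str = "cdr3_aa") -> set[str]:
        return set(self.productive[key])


@dataclass(frozen=True)
class DiversitySummary:
    unique_count: int
    entropy: float
    normalized_entropy: float
    clonality: float


# ---------------------------------------------------------------------------
# Reading

_IMMUNOSEQ_MAP = {
    "nucleotide": "cdr3_nt",
    "aminoAcid": "cdr3_aa",
    "count": "read_count",
    "count (templates/reads)": "read_count",
    "vGeneName": "v_gene",
    "jGeneName": "j_gene",
}

_AIRR_MAP = {
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "duplicate_count": "read_count",
    "v_call": "v_gene",
    "j_call": "j_gene",
}


def _detect_dialect(columns) -> str:
    cols = set(columns)
    if "junction" in cols or "junction_aa" in cols:
        return "airr"
    if "nucleotide" in cols or "aminoAcid" in cols:
        return "immunoseq"
    raise RepertoireFormatError(
        f"cannot detect repertoire dialect from header {sorted(cols)!r}"
    )


def _is_productive_aa(aa: str) -> bool:
    return bool(aa) and ("*" not in aa) and ("_" not in aa) and set(aa) <= AA_ALPHABET


def read_repertoire(path, sample_id, patient_id, tissue, timepoint=None) -> Repertoire:
    """Read a bulk TRB repertoire TSV (immunoSEQ or AIRR dialect).

    Counts are aggregated by ``cdr3_nt``; non-productive rows are flagged
    (not dropped) and frequencies are recomputed over productive reads.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    dialect = _detect_dialect(raw.columns)
    colmap = _AIRR_MAP if dialect == "airr" else _IMMUNOSEQ_MAP
    df = raw.rename(columns=colmap)

    for col in ("cdr3_nt", "cdr3_aa", "read_count"):
        if col not in df.columns:
            missing = [k for k, v in colmap.items() if v == col]
            raise RepertoireFormatError(
                f"missing mandatory column for {col!r} (one of {missing}) in {path}"
            )
    for col in ("v_gene", "j_gene"):
        if col not in df.columns:
            df[col] = "NA"

    df = df.copy()
    df["cdr3_nt"] = df["cdr3_nt"].str.strip().str.upper()
    df["cdr3_aa"] = df["cdr3_aa"].fillna("").str.strip().str.upper()
    df["read_count"] = pd.to_numeric(df["read_count"]).astype(int)
    df = df[df["read_count"] >= 1]

    if dialect == "airr" and "productive" in df.columns:
        df["productive"] = df["productive"].str.upper().isin(("T", "TRUE", "1"))
    elif dialect == "immunoseq" and "sequenceStatus" in df.columns:
        df["productive"] = df["sequenceStatus"].str.strip().str.lower() == "in"
    else:
        df["productive"] = df["cdr3_aa"].map(_is_productive_aa)
    # a productive call never overrides a visibly broken amino-acid string
    df["productive"] &= df["cdr3_aa"].map(_is_productive_aa)

    n_input = len(df)
    agg = (
        df.groupby("cdr3_nt", as_index=False)
        .agg(
            cdr3_aa=("cdr3_aa", "first"),
            v_gene=("v_gene", "first"),
            j_gene=("j_gene", "first"),
            read_count=("read_count", "sum"),
            productive=("productive", "all"),
        )
        .sort_values(["cdr3_aa", "cdr3_nt"], kind="mergesort")
        .reset_index(drop=True)
    )
    total_prod = agg.loc[agg["productive"], "read_count"].sum()
    if total_prod == 0:
        raise EmptyRepertoireError(f"no productive records in {path}")
    agg["frequency"] = np.where(
        agg["productive"], agg["read_count"] / total_prod, 0.0
    )
    report = {
        "dialect": dialect,
        "rows_in": n_input,
        "unique_nt": len(agg),
        "non_productive": int((~agg["productive"]).sum()),
    }
    return Repertoire(sample_id, patient_id, tissue, agg, timepoint, report)


def write_repertoire(rep: Repertoire, path) -> None:
    """Write the canonical repertoire TSV (productive records only)."""
    out = rep.productive[CANONICAL_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV (sample_id, patient_id, tissue[, timepoint], path)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "patient_id", "tissue", "path"}
    if not needed <= set(sheet.columns):
        raise RepertoireFormatError(
            f"sample sheet must have columns {sorted(needed)}; got {list(sheet.columns)}"
        )
    if "timepoint" not in sheet.columns:
        sheet["timepoint"] = None
    # relative paths resolve against the sheet's own directory
    from pathlib import Path

    base = Path(path).parent
    sheet["path"] = [str(p) if Path(p).is_absolute() else str(base / p)
                     for p in sheet["path"]]
    return sheet


# ---------------------------------------------------------------------------
# Statistics


def filter_productive(rep: Repertoire) -> Repertoire:
    """Drop non-productive records and renormalize frequencies to sum to 1."""
    prod = rep.data[rep.data["productive"]].copy()
    if prod.empty:
        raise EmptyRepertoireError(f"{rep.sample_id}: all records non-productive")
    prod["frequency"] = prod["read_count"] / prod["read_count"].sum()
    return replace(rep, data=prod.reset_index(drop=True))


def diversity(rep: Repertoire) -> DiversitySummary:
    """Shannon entropy, normalized entropy and clonality of a repertoire.

    H = −Σ pᵢ ln pᵢ over unique productive clonotypes; normalized entropy
    H/ln(U) is base-invariant; clonality = 1 − H/ln(U). A single-clone
    repertoire (U = 1) is defined to have clonality 1 (limit of a vanishing
    second clone).
    """
    freqs = rep.productive["frequency"].to_numpy(float)
    u = freqs.size
    if u == 0:
        raise EmptyRepertoireError(f"{rep.sample_id}: empty repertoire")
    freqs = freqs / freqs.sum()
    h = float(_shannon_entropy(freqs))  # natural log
    if u == 1:
        return DiversitySummary(1, 0.0, 0.0, 1.0)
    norm = h / math.log(u)
    return DiversitySummary(int(u), h, norm, 1.0 - norm)


def clonality(frequencies) -> float:
    """Clonality of a bare frequency vector (convenience wrapper)."""
    p = np.asarray(frequencies, float)
    p = p[p > 0]
    p = p / p.sum()
    if p.size <= 1:
        return 1.0
    return 1.0 - float(_shannon_entropy(p)) / math.log(p.size)


def similarity_score(rep_a: Repertoire, rep_b: Repertoire, key: str = "cdr3_aa",
                     denominator: str = "union") -> float:
    """Fraction of shared unique sequences between two samples.

    ``denominator='union'`` gives |A∩B| / |A∪B| (Jaccard); ``'sum'`` gives
    |A∩B| / (|A| + |B|). Symmetric, in [0, 1].
    """
    a = rep_a.unique_sequences(key)
    b = rep_b.unique_sequences(key)
    if not a and not b:
        raise EmptyRepertoireError("similarity undefined: both repertoires empty")
    shared = len(a & b)
    if denominator == "union":
        return shared / len(a | b)
    if denominator == "sum":
        return shared / (len(a) + len(b))
    raise ValueError(f"unknown denominator {denominator!r}")


def top_n(rep: Repertoire, n: int, key: str = "cdr3_aa") -> pd.DataFrame:
    """The ``n`` most frequent clonotypes (aggregated by ``key``).

    Deterministic: ties broken lexicographically by cdr3_aa then cdr3_nt.
    Returns all clonotypes (no error) when fewer than ``n`` exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prod = rep.productive
    spec = {"frequency": ("frequency", "sum"), "read_count": ("read_count", "sum")}
    other = "cdr3_nt" if key == "cdr3_aa" else "cdr3_aa"
    spec[other] = (other, "min")
    agg = prod.groupby(key, as_index=False).agg(**spec)
    agg = agg.sort_values(
        ["frequency", "cdr3_aa", "cdr3_nt"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return agg.head(n)


def diversity_table(reps) -> pd.DataFrame:
    """One diversity-summary row per sample."""
    rows = []
    for rep in reps:
        d = diversity(rep)
        rows.append({
            "sample_id": rep.sample_id, "patient_id": rep.patient_id,
            "tissue": rep.tissue, "unique_count": d.unique_count,
            "entropy": d.entropy, "normalized_entropy": d.normalized_entropy,
            "clonality": d.clonality,
        })
    return pd.DataFrame(rows)
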