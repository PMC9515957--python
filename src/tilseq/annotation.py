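"""Specificity-database annotation, public clonotypes, convergent nucleotypes.

Clonotypes are annotated by exact CDR3 amino-acid match against a VDJdb-style
table, screened against a donor-wise control TRB library to estimate how
prevalent each sequence is among healthy individuals, and pooled across a
patient cohort to detect putative *public* clonotypes (many cells in at least
one tumor, shared across many patients). *Convergent recombination* — several
distinct nucleotide sequences encoding the same CDR3 protein, each with solid
cell/read support — is detected per amino-acid clonotype.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import PUBLIC_MIN_CELLS, PUBLIC_MIN_PATIENTS


class DatabaseFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VDJdb-style annotation

_VDJDB_ALIASES = {
    "cdr3": "cdr3_aa",
    "cdr3_aa": "cdr3_aa",
    "antigen.epitope": "antigen",
    "antigen_epitope": "antigen",
    "antigen": "antigen",
    "antigen.species": "species",
    "antigen_species": "species",
    "species": "species",
    "v": "v_gene",
    "j": "j_gene",
}


def read_annotation_db(path) -> pd.DataFrame:
    """Read a VDJdb-style TSV (columns cdr3, v, j, antigen.epitope, antigen.species)."""
    db = pd.read_csv(path, sep="\t", dtype=str)
    db = db.rename(columns={c: _VDJDB_ALIASES.get(c, c) for c in db.columns})
    if "cdr3_aa" not in db.columns or "antigen" not in db.columns:
        raise DatabaseFormatError(
            f"annotation db must provide cdr3 and antigen columns; got {list(db.columns)}")
    db["cdr3_aa"] = db["cdr3_aa"].str.strip().str.upper()
    return db


def match_database(clonotypes: pd.DataFrame, db: pd.DataFrame,
                   require_vj: bool = False) -> tuple[pd.DataFrame, float]:
    """Exact-match clonotypes against an annotation database.

    Parameters
    ----------
    clonotypes
        Table with ``cdr3_aa`` and ``frequency`` (per-sample clonotype table).
    db
        Annotation table with ``cdr3_aa`` and ``antigen`` (plus ``species``,
        ``v_gene``/``j_gene`` if ``require_vj``).

    Returns
    -------
    (hits, annotated_fraction)
        ``hits`` has one row per (clonotype, db row) match;
        ``annotated_fraction`` is the summed frequency of annotated clonotypes.
    """
    if "cdr3_aa" not in db.columns or "antigen" not in db.columns:
        raise DatabaseFormatError("db lacks cdr3_aa/antigen columns")
    keys = ["cdr3_aa"] + (["v_gene", "j_gene"] if require_vj else [])
    hits = clonotypes.merge(db, on=keys, how="inner", suffixes=("", "_db"))
    if "frequency" in clonotypes.columns:
        annotated = clonotypes["cdr3_aa"].isin(set(hits["cdr3_aa"]))
        annotated_fraction = float(clonotypes.loc[annotated, "frequency"].sum())
    else:
        annotated_fraction = float(
            clonotypes["cdr3_aa"].isin(set(hits["cdr3_aa"])).mean())
    return hits, annotated_fraction


def annotated_unique_fraction(clonotypes: pd.DataFrame, db: pd.DataFrame) -> float:
    """Fraction of *unique* clonotypes with at least one database hit."""
    uniq = pd.Index(clonotypes["cdr3_aa"].unique())
    return float(uniq.isin(set(db["cdr3_aa"])).mean())


# ---------------------------------------------------------------------------
# Control-donor library screening


def read_control_library(path) -> pd.DataFrame:
    """Read a donor-wise control library TSV (donor_id, cdr3_aa)."""
    lib = pd.read_csv(path, sep="\t", dtype=str)
    if not {"donor_id", "cdr3_aa"} <= set(lib.columns):
        raise DatabaseFormatError("control library needs donor_id and cdr3_aa columns")
    lib["cdr3_aa"] = lib["cdr3_aa"].str.strip().str.upper()
    return lib


def screen_control_library(sequences, library: pd.DataFrame) -> pd.DataFrame:
    """Per-sequence prevalence among control donors.

    ``prevalence`` = fraction of donors carrying the exact sequence;
    ``patient_unique`` is True when prevalence is 0. Prevalence is monotone
    non-decreasing as donors are added to the library.
    """
    n_donors = library["donor_id"].nunique()
    carriers = library.drop_duplicates(["donor_id", "cdr3_aa"]).groupby("cdr3_aa")[
        "donor_id"].nunique()
    seqs = pd.Index(pd.unique(pd.Series(list(sequences))), name="cdr3_aa")
    n_carriers = carriers.reindex(seqs).fillna(0).astype(int)
    out = pd.DataFrame({
        "cdr3_aa": seqs,
        "n_donors_carrying": n_carriers.to_numpy(),
        "prevalence": n_carriers.to_numpy() / n_donors,
    })
    out["patient_unique"] = out["n_donors_carrying"] == 0
    return out


# ---------------------------------------------------------------------------
# Public clonotypes


def find_public_clonotypes(cohort: pd.DataFrame,
                           min_patients: int = PUBLIC_MIN_PATIENTS,
                           min_cells: int = PUBLIC_MIN_CELLS) -> pd.DataFrame:
    """Detect public clonotypes in a pooled multi-patient cohort.

    Parameters
    ----------
    cohort
        Long table with columns ``patient_id``, ``key`` (clonotype key) and
        ``cells`` (cell count of that clonotype in that patient's tumor).
    min_patients, min_cells
        Public ⇔ detected in ≥ ``min_patients`` patients and reaching
        ≥ ``min_cells`` cells in at least one tumor (default: "more than 10
        cells/tumor" = ≥ 11, shared by ≥ 10 patients).

    Ranked by patients_detected, then max cells per tumor.
    """
    if cohort["patient_id"].nunique() < 2:
        raise ValueError("cohort must pool at least 2 patients")
    grp = cohort.groupby("key").agg(
        patients_detected=("patient_id", "nunique"),
        max_cells_per_tumor=("cells", "max"),
        total_cells=("cells", "sum"),
    )
    public = grp[(grp["patients_detected"] >= min_patients)
                 & (grp["max_cells_per_tumor"] >= min_cells)]
    return public.sort_values(
        ["patients_detected", "max_cells_per_tumor", "key"],
        ascending=[False, False, True], kind="mergesort").reset_index()


# ---------------------------------------------------------------------------
# Convergent nucleotypes


def detect_convergence(records: pd.DataFrame, support_col: str = "cells",
                       min_support: int = 2) -> pd.DataFrame:
    """Group nucleotide variants per CDR3 protein and flag convergence.

    ``records`` has columns ``cdr3_aa``, ``cdr3_nt`` and a support column
    (cells or reads per nucleotype). A clonotype is *convergent* when at
    least two distinct nucleotypes are each supported by ≥ ``min_support``.
    Rows lacking a nucleotide sequence, or containing ambiguous bases (N),
    are excluded with a warning.
    """
    rec = records.copy()
    bad = rec["cdr3_nt"].isna() | rec["cdr3_nt"].astype(str).str.contains("N")
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} records without unambiguous cdr3_nt",
                      stacklevel=2)
        rec = rec[~bad]
    per_nt = rec.groupby(["cdr3_aa", "cdr3_nt"])[support_col].sum().reset_index()
    rows = []
    for aa, grp in per_nt.groupby("cdr3_aa"):
        supported = (grp[support_col] >= min_support).sum()
        rows.append({
            "cdr3_aa": aa,
            "n_nucleotypes": len(grp),
            "n_supported_nucleotypes": int(supported),
            "convergent": bool(supported >= 2),
            "support_per_nucleotype": dict(zip(grp["cdr3_nt"], grp[support_col].astype(int))),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Case/control frequency contrast


def case_control_frequency_contrast(sequences, case_frequencies: pd.DataFrame,
                                    control_frequencies: pd.DataFrame) -> pd.DataFrame:
    """Mean-frequency ratio of clonotypes among carriers, cases vs controls.

    Both frequency tables are long format (``sample_id``, ``cdr3_aa``,
    ``frequency``); only samples actually carrying the sequence enter its
    mean. A sequence with zero control carriers gets an infinite ratio and is
    flagged (excluded from downstream means by the caller).
    """
    rows = []
    for seq in sequences:
        case = case_frequencies.loc[case_frequencies["cdr3_aa"] == seq, "frequency"]
        ctrl = control_frequencies.loc[control_frequencies["cdr3_aa"] == seq, "frequency"]
        mean_case = float(case.mean()) if len(case) else np.nan
        mean_ctrl = float(ctrl.mean()) if len(ctrl) else np.nan
        if len(ctrl) == 0 or mean_ctrl == 0:
            ratio = np.inf
        else:
            ratio = mean_case / mean_ctrl
        rows.append({
            "cdr3_aa": seq,
            "mean_frequency_cases": mean_case,
            "mean_frequency_controls": mean_ctrl,
            "n_case_carriers": int(len(case)),
            "n_control_carriers": int(len(ctrl)),
            "ratio": ratio,
            "log10_ratio": float(np.log10(ratio)) if np.isfinite(ratio) and ratio > 0 else np.nan,
        })
    return pd.DataFrame(rows)
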