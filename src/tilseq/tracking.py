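"""Cross-tissue clonotype tracking and tissue-distribution patterns.

Within a patient, each unique clonotype (bulk: TRB-CDR3 amino-acid sequence;
single cell: TRA/TRB pair) is looked up in the tumor, normal-adjacent-tissue
(NAT) and PBMC repertoires and labeled with one of seven tissue-distribution
patterns — the three tissue-specific labels, the three pairwise-shared labels
TN / TP / PN, and ALL for clones found in every tissue. A clone is *expanded
in tumor* when its tumor frequency strictly exceeds 1%.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .config import EXPANDED_THRESHOLD, PATTERNS, TISSUES
from .repertoire import Repertoire, top_n

_PATTERN_BY_SET = {
    frozenset({"TUMOR"}): "TUMOR",
    frozenset({"NAT"}): "NAT",
    frozenset({"PBMC"}): "PBMC",
    frozenset({"TUMOR", "NAT"}): "TN",
    frozenset({"TUMOR", "PBMC"}): "TP",
    frozenset({"NAT", "PBMC"}): "PN",
    frozenset({"TUMOR", "NAT", "PBMC"}): "ALL",
}


def classify_tissue_pattern(occurrences) -> str:
    """Map the set of tissues a clonotype occurs in to its 7-way pattern label."""
    occ = frozenset(occurrences)
    if not occ:
        raise ValueError("occurrences must be nonempty")
    unknown = occ - set(TISSUES)
    if unknown:
        raise ValueError(f"unknown tissue label(s) {sorted(unknown)}; expected {TISSUES}")
    return _PATTERN_BY_SET[occ]


def flag_expanded(frequency: float, threshold: float = EXPANDED_THRESHOLD) -> bool:
    """Strict expansion test: frequency > threshold (default 1%)."""
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"frequency {frequency} outside [0, 1]")
    return frequency > threshold


def track_clonotypes(repertoires, key: str = "cdr3_aa", min_count: int = 1) -> pd.DataFrame:
    """Track clonotypes across one patient's tissue repertoires.

    Parameters
    ----------
    repertoires
        All productive-filtered samples of one patient (one per tissue per
        timepoint; duplicate (tissue, timepoint) combinations are an error).
    key
        Tracking key: ``cdr3_aa`` (default) or ``cdr3_nt``.
    min_count
        Minimum read count for a clone to count as *detected* in a tissue.

    Returns a table with one row per unique key: ``freq_<TISSUE>`` /
    ``count_<TISSUE>`` columns, ``pattern``, ``expanded_in_tumor`` and
    ``tissues_assayed`` (so ALL is never claimed without 3 assayed tissues).
    """
    reps = list(repertoires)
    if not reps:
        raise ValueError("need at least one repertoire")
    patients = {r.patient_id for r in reps}
    if len(patients) > 1:
        raise ValueError(f"repertoires from multiple patients: {sorted(patients)}")
    seen = set()
    for r in reps:
        sig = (r.tissue, r.timepoint)
        if sig in seen:
            raise ValueError(f"duplicate sample for tissue/timepoint {sig}; merge explicitly")
        seen.add(sig)

    assayed = sorted({r.tissue for r in reps}, key=TISSUES.index)
    per_tissue = {}
    for r in sorted(reps, key=lambda r: TISSUES.index(r.tissue)):
        prod = r.productive
        grp = prod.groupby(key).agg(frequency=("frequency", "sum"),
                                    read_count=("read_count", "sum"))
        per_tissue.setdefault(r.tissue, []).append(grp)
    # merge timepoints of the same tissue by summing counts, averaging freq
    merged = {}
    for tissue, frames in per_tissue.items():
        if len(frames) == 1:
            merged[tissue] = frames[0]
        else:
            cat = pd.concat(frames)
            merged[tissue] = cat.groupby(level=0).agg(
                frequency=("frequency", "mean"), read_count=("read_count", "sum"))

    keys = sorted(set().union(*[set(g.index) for g in merged.values()]))
    out = pd.DataFrame(index=pd.Index(keys, name=key))
    for tissue in TISSUES:
        if tissue in merged:
            out[f"freq_{tissue}"] = merged[tissue]["frequency"].reindex(keys).fillna(0.0)
            out[f"count_{tissue}"] = (
                merged[tissue]["read_count"].reindex(keys).fillna(0).astype(int))
        else:
            out[f"freq_{tissue}"] = 0.0
            out[f"count_{tissue}"] = 0

    def _pattern(row):
        occ = {t for t in assayed if row[f"count_{t}"] >= min_count}
        return classify_tissue_pattern(occ) if occ else "NONE"

    out["pattern"] = out.apply(_pattern, axis=1)
    out = out[out["pattern"] != "NONE"]
    out["expanded_in_tumor"] = out["freq_TUMOR"] > EXPANDED_THRESHOLD
    out["tissues_assayed"] = ",".join(assayed)
    return out.reset_index()


def pattern_summary(tracked: pd.DataFrame) -> pd.Series:
    """Clonotype counts per tissue-distribution pattern (all 7 labels, zeros kept)."""
    counts = tracked["pattern"].value_counts()
    return counts.reindex(PATTERNS, fill_value=0).astype(int)


def alluvial_table(repertoires, n: int = 120, key: str = "cdr3_aa") -> pd.DataFrame:
    """Long-format table for alluvial plots of the top-``n`` clonotypes.

    Rows are (clonotype × tissue → frequency) for the union of each tissue's
    ``n`` most frequent clonotypes, with zero-frequency cells explicit and a
    deterministic ordering (descending max frequency, then key).
    """
    reps = list(repertoires)
    tops = set()
    for r in reps:
        tops.update(top_n(r, n, key=key)[key])
    tracked = track_clonotypes(reps, key=key)
    tracked = tracked[tracked[key].isin(tops)]
    tissues = sorted({r.tissue for r in reps}, key=TISSUES.index)
    long = tracked.melt(
        id_vars=[key], value_vars=[f"freq_{t}" for t in tissues],
        var_name="tissue", value_name="frequency")
    long["tissue"] = long["tissue"].str.removeprefix("freq_")
    order = (
        long.groupby(key)["frequency"].max().sort_values(ascending=False).index)
    rank = {k: i for i, k in enumerate(order)}
    long["__rank"] = long[key].map(rank)
    long = long.sort_values(["__rank", key, "tissue"], kind="mergesort")
    return long.drop(columns="__rank").reset_index(drop=True)


def longitudinal_persistence(repertoires, key: str = "cdr3_aa") -> pd.DataFrame:
    """Frequency trajectories across timepoints within one tissue.

    A clonotype is *persistent* when detected at every timepoint. With a
    single timepoint a warning is raised and an empty table returned.
    """
    reps = list(repertoires)
    timepoints = sorted({r.timepoint for r in reps}, key=lambda t: str(t))
    if len(timepoints) < 2:
        warnings.warn("longitudinal persistence needs >= 2 timepoints", stacklevel=2)
        return pd.DataFrame(columns=[key, "persistent", "max_frequency"])
    frames = {}
    for r in reps:
        frames[r.timepoint] = r.productive.groupby(key)["frequency"].sum()
    keys = sorted(set().union(*[set(s.index) for s in frames.values()]))
    out = pd.DataFrame(index=pd.Index(keys, name=key))
    for tp in timepoints:
        out[f"freq_{tp}"] = frames[tp].reindex(keys).fillna(0.0)
    freq_cols = [f"freq_{tp}" for tp in timepoints]
    out["persistent"] = (out[freq_cols] > 0).all(axis=1)
    out["max_frequency"] = out[freq_cols].max(axis=1)
    return out.reset_index()
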