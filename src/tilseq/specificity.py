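"""Motif-based CDR3 specificity grouping (a simplified GLIPH-style scheme).

CDR3 sequences are clustered into predicted shared-specificity groups using
two kinds of evidence: (i) a shared *interior* k-mer motif (first and last 3
residues trimmed, k ∈ {3, 4}) carried by at least ``min_clonotypes`` distinct
sequences and — when a background repertoire is supplied — fold-enriched over
the background interior k-mer frequency; and (ii) near-identity: equal-length
sequences within Hamming distance 1. Groups are the connected components of
the resulting graph; unclustered sequences form singleton groups. The full
statistical machinery of GLIPH2 (Fisher enrichment against a naive reference,
V-gene bias, HLA partitioning) is deliberately not reproduced: the readout
used downstream is group-size structure per tissue, not motif p-values.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Motif:
    kmer: str
    member_cdr3s: frozenset
    enrichment_fold: float | None = None


@dataclass
class SpecificityGroup:
    group_id: str
    member_cdr3s: frozenset
    seeds: tuple = ()

    @property
    def size(self) -> int:
        return len(self.member_cdr3s)


def _interior(seq: str, trim: int = 3) -> str:
    return seq[trim:-trim] if len(seq) > 2 * trim else ""


def _interior_kmer_members(sequences, k: int, trim: int) -> dict[str, set]:
    members = defaultdict(set)
    for seq in sequences:
        core = _interior(seq, trim)
        for i in range(len(core) - k + 1):
            members[core[i:i + k]].add(seq)
    return members


def mine_motifs(cdr3_set, reference=None, k_values=(3, 4), min_clonotypes: int = 3,
                min_fold: float = 10.0, trim: int = 3) -> list[Motif]:
    """Interior k-mer motifs supported by ≥ ``min_clonotypes`` distinct CDR3s.

    With a ``reference`` background set, a motif must additionally be
    fold-enriched ≥ ``min_fold``: the per-sequence carrier rate in the sample
    divided by the carrier rate in the reference, with a pseudocount of 1 on
    the reference carrier count. Sequences too short to have an interior
    k-mer are skipped (their count is not an error).
    """
    seqs = sorted(set(cdr3_set))
    motifs = []
    for k in sorted(k_values):
        members = _interior_kmer_members(seqs, k, trim)
        if reference is not None:
            ref_seqs = sorted(set(reference))
            ref_members = _interior_kmer_members(ref_seqs, k, trim)
            n_ref = max(len(ref_seqs), 1)
        for kmer in sorted(members):
            carriers = members[kmer]
            if len(carriers) < min_clonotypes:
                continue
            fold = None
            if reference is not None:
                sample_rate = len(carriers) / len(seqs)
                ref_rate = (len(ref_members.get(kmer, ())) + 1) / (n_ref + 1)
                fold = sample_rate / ref_rate
                if fold < min_fold:
                    continue
            motifs.append(Motif(kmer, frozenset(carriers), fold))
    return motifs


def _hamming1_pairs(sequences):
    """Equal-length sequence pairs at Hamming distance <= 1 (exact, banded by length)."""
    by_len = defaultdict(list)
    for s in sequences:
        by_len[len(s)].append(s)
    for group in by_len.values():
        group.sort()
        # wildcard bucketing: two sequences are Hamming<=1 iff they share a
        # pattern with one position masked
        buckets = defaultdict(list)
        for s in group:
            for i in range(len(s)):
                buckets[(i, s[:i] + "*" + s[i + 1:])].append(s)
        for bucket in buckets.values():
            for i in range(len(bucket)):
                for j in range(i + 1, len(bucket)):
                    yield bucket[i], bucket[j]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label wins as root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def build_groups(cdr3_set, motifs, hamming_radius: int = 1) -> list[SpecificityGroup]:
    """Connected-component specificity groups over motif and near-identity edges.

    Edges: (i) two sequences share an enriched motif; (ii) equal length and
    Hamming distance ≤ ``hamming_radius`` (only radius 1 is implemented).
    Output is order-invariant: groups carry canonical ids named after their
    lexicographically smallest member and are sorted by (size desc, id).
    """
    seqs = sorted(set(cdr3_set))
    uf = _UnionFind(seqs)
    motif_of = defaultdict(set)
    for motif in motifs:
        members = sorted(motif.member_cdr3s & set(seqs))
        for a, b in zip(members, members[1:]):
            uf.union(a, b)
        for m in members:
            motif_of[m].add(motif.kmer)
    if hamming_radius >= 1:
        for a, b in _hamming1_pairs(seqs):
            uf.union(a, b)

    components = defaultdict(set)
    for s in seqs:
        components[uf.find(s)].add(s)
    groups = []
    for root in sorted(components, key=lambda r: (-len(components[r]), r)):
        members = components[root]
        seeds = sorted(set().union(*[motif_of[m] for m in members]) if members else set())
        groups.append(SpecificityGroup(f"G:{min(members)}", frozenset(members), tuple(seeds)))
    return groups


def group_membership_table(groups, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long membership table (cdr3_aa, group_id, group_size, seed motifs)."""
    rows = []
    for g in groups:
        for m in sorted(g.member_cdr3s):
            rows.append({"cdr3_aa": m, "group_id": g.group_id,
                         "group_size": g.size, "seeds": ";".join(g.seeds)})
    out = pd.DataFrame(rows)
    if metadata is not None:
        out = out.merge(metadata, on="cdr3_aa", how="left")
    return out


def group_stats(groups_by_tissue: dict[str, list[SpecificityGroup]]) -> pd.DataFrame:
    """Per-tissue mean/SD of unique sequences per specificity group.

    Also reports Welch t statistics between every tissue pair (the group-size
    contrast used to compare tumor against blood/NAT repertoires).
    """
    rows = []
    sizes = {t: np.array([g.size for g in gs], float)
             for t, gs in groups_by_tissue.items()}
    for tissue, sz in sizes.items():
        rows.append({"tissue": tissue, "n_groups": sz.size,
                     "mean_group_size": float(sz.mean()) if sz.size else np.nan,
                     "sd_group_size": float(sz.std(ddof=1)) if sz.size > 1 else 0.0})
    summary = pd.DataFrame(rows)
    contrasts = []
    tissues = sorted(sizes)
    for i, a in enumerate(tissues):
        for b in tissues[i + 1:]:
            if sizes[a].size > 1 and sizes[b].size > 1:
                t, p = stats.ttest_ind(sizes[a], sizes[b], equal_var=False)
            else:
                t, p = np.nan, np.nan
            contrasts.append({"tissue_a": a, "tissue_b": b,
                              "t_stat": float(t), "p_value": float(p)})
    summary.attrs["contrasts"] = pd.DataFrame(contrasts)
    return summary


def cross_patient_grouping(cdr3_by_patient: dict[str, set], **kwargs) -> pd.DataFrame:
    """Pool patients, group, and annotate each group with patient multiplicity."""
    if len(cdr3_by_patient) < 2:
        raise ValueError("need >= 2 patients to pool")
    pooled = sorted(set().union(*cdr3_by_patient.values()))
    motifs = mine_motifs(pooled, **{k: v for k, v in kwargs.items()
                                    if k in ("reference", "k_values", "min_clonotypes",
                                             "min_fold", "trim")})
    groups = build_groups(pooled, motifs,
                          hamming_radius=kwargs.get("hamming_radius", 1))
    rows = []
    for g in groups:
        patients = sorted(p for p, seqs in cdr3_by_patient.items()
                          if g.member_cdr3s & seqs)
        rows.append({"group_id": g.group_id, "size": g.size,
                     "patients": ",".join(patients),
                     "patient_multiplicity": len(patients)})
    return pd.DataFrame(rows)
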