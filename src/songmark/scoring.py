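"""Probe collapsing, majority-rule gene scoring, and in-situ merging.

Arrays designed from EST collections often carry several oligos probing the
same stretch of a transcript; such probes are not independent measurements.
Probes of a gene whose genomic intervals overlap by more than 75% of the
shorter interval are grouped by single linkage and each group contributes a
single averaged p-value (and averaged log2 fold change) to the score.  A
gene is called differential when at least half of its unique probe groups
fall at or below the calibrated p-value cutoff; direction is up or down
only when all significant groups agree, otherwise the conflict is surfaced
for manual review.  Where an independent in-situ hybridization call exists
it takes precedence over the array call, with discordances flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OVERLAP_MIN",
    "GeneScore",
    "collapse_redundant",
    "score_gene",
    "assign_direction",
    "score_genes",
    "merge_insitu",
]

OVERLAP_MIN = 0.75  # strict: shared length / shorter length must exceed this


@dataclass
class GeneScore:
    """Majority-rule call for one gene in one contrast."""

    gene_id: str
    contrast: str
    n_sig_unique: int
    n_nonsig_unique: int
    status: str        # differential | nondifferential | not_assessed
    direction: str     # up | down | conflict | none
    evidence: str      # array | insitu | both
    flags: str = ""


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _overlap_fraction(s1, e1, s2, e2) -> float:
    shared = min(e1, e2) - max(s1, s2)
    if shared <= 0:
        return 0.0
    return shared / min(e1 - s1, e2 - s2)


def collapse_redundant(probes: pd.DataFrame) -> pd.DataFrame:
    """Group one gene's probes into unique (non-redundant) probe groups.

    ``probes`` needs probe_id, p, M and genomic chrom/start/end columns.
    Probes on the same chromosome whose intervals share more than 75% of
    the shorter interval are linked; single-linkage connected components
    form the groups.  Each group carries the arithmetic mean p and mean M
    of its members and is counted once in scoring.  Probes without
    coordinates become flagged singleton groups.

    Returns a frame with group_id, probe_ids (tuple, sorted), n_members,
    p, M, no_coords flag.
    """
    df = probes.reset_index(drop=True)
    n = len(df)
    uf = _UnionFind(n)
    has_coords = (
        df["start"].notna() & df["end"].notna() & df["chrom"].notna()
    ).to_numpy()
    starts = df["start"].to_numpy(dtype=float)
    ends = df["end"].to_numpy(dtype=float)
    chroms = df["chrom"].to_numpy(dtype=object)
    for i in range(n):
        if not has_coords[i]:
            continue
        for j in range(i + 1, n):
            if not has_coords[j] or chroms[i] != chroms[j]:
                continue
            if _overlap_fraction(starts[i], ends[i], starts[j], ends[j]) > OVERLAP_MIN:
                uf.union(i, j)
    roots = [uf.find(i) for i in range(n)]
    rows = []
    for gid, root in enumerate(sorted(set(roots))):
        members = [i for i in range(n) if roots[i] == root]
        rows.append(
            {
                "group_id": gid,
                "probe_ids": tuple(sorted(df.loc[members, "probe_id"])),
                "n_members": len(members),
                "p": float(df.loc[members, "p"].mean()),
                "M": float(df.loc[members, "M"].mean()),
                "no_coords": bool(not has_coords[members[0]] and len(members) == 1),
            }
        )
    return pd.DataFrame(rows)


def assign_direction(m_values) -> str:
    """Direction from the significant groups' average log2 fold changes:
    ``up`` if all positive, ``down`` if all negative, else ``conflict``."""
    m = np.asarray(list(m_values), dtype=float)
    if len(m) == 0:
        return "none"
    if np.all(m > 0):
        return "up"
    if np.all(m < 0):
        return "down"
    return "conflict"


def score_gene(
    groups: pd.DataFrame, cutoff_p: float, gene_id: str, contrast: str
) -> GeneScore:
    """Apply the majority rule to one gene's unique probe groups.

    A group is significant when its averaged p-value is at or below the
    cutoff.  With at least one group, the gene is differential iff at
    least 50% of groups are significant (inclusive boundary); with no
    groups it is not assessed.
    """
    if len(groups) == 0:
        return GeneScore(gene_id, contrast, 0, 0, "not_assessed", "none", "array")
    sig = groups["p"] <= cutoff_p
    n_sig = int(sig.sum())
    n_nonsig = int((~sig).sum())
    if n_sig / (n_sig + n_nonsig) >= 0.5:
        direction = assign_direction(groups.loc[sig, "M"])
        flags = "direction_conflict" if direction == "conflict" else ""
        return GeneScore(
            gene_id, contrast, n_sig, n_nonsig, "differential", direction,
            "array", flags,
        )
    return GeneScore(
        gene_id, contrast, n_sig, n_nonsig, "nondifferential", "none", "array"
    )


def score_genes(
    stats: pd.DataFrame,
    curated: pd.DataFrame,
    cutoff_p: float,
    contrast: str,
    all_genes=None,
) -> pd.DataFrame:
    """Score every gene of a contrast from its retained probes.

    ``stats`` holds the retained probes' statistics (probe_id, M, p);
    ``curated`` supplies the probe-to-gene annotation and coordinates.
    Genes listed in ``all_genes`` but lacking retained probes are emitted
    with status ``not_assessed`` so the assessed universe is explicit.
    """
    ann = curated.loc[
        curated["keep"]
        & curated["gene_id"].notna()
        & curated["relation"].isin(["exonic_or_overlapping", "proximal"]),
        ["probe_id", "gene_id", "chrom", "start", "end"],
    ]
    merged = stats[["probe_id", "M", "p"]].merge(ann, on="probe_id", how="inner")
    scores = []
    seen = set()
    for gene_id, sub in merged.groupby("gene_id", sort=True):
        groups = collapse_redundant(sub)
        scores.append(score_gene(groups, cutoff_p, gene_id, contrast))
        seen.add(gene_id)
    if all_genes is not None:
        for gene_id in all_genes:
            if gene_id not in seen:
                scores.append(
                    GeneScore(gene_id, contrast, 0, 0, "not_assessed", "none", "array")
                )
    out = pd.DataFrame([s.__dict__ for s in scores])
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)


_INSITU_STATUS = {
    "up": ("differential", "up"),
    "down": ("differential", "down"),
    "nondifferential": ("nondifferential", "none"),
}


def merge_insitu(scores: pd.DataFrame, insitu: pd.DataFrame) -> pd.DataFrame:
    """Merge in-situ hybridization calls into the array scores.

    The in-situ outcome wins on conflict (the call is replaced and flagged
    ``$`` discordant), fills genes the array did not assess, and an
    unevaluable image leaves the array call untouched.
    """
    out = scores.copy()
    calls = insitu.set_index("gene_id")["call"]
    idx = out.set_index("gene_id").index
    for i, gene_id in enumerate(out["gene_id"]):
        if gene_id not in calls.index:
            continue
        call = calls.loc[gene_id]
        if call == "unevaluable":
            continue
        status, direction = _INSITU_STATUS[call]
        arr_status = out.at[i, "status"]
        if arr_status == "not_assessed":
            out.at[i, "status"] = status
            out.at[i, "direction"] = direction
            out.at[i, "evidence"] = "insitu"
        else:
            concordant = (arr_status == status) and (
                status != "differential" or out.at[i, "direction"] == direction
            )
            out.at[i, "evidence"] = "both"
            if not concordant:
                out.at[i, "status"] = status
                out.at[i, "direction"] = direction
                flags = out.at[i, "flags"]
                out.at[i, "flags"] = (flags + ";" if flags else "") + "$discordant"
    return out
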