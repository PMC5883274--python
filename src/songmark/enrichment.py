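"""Cross-contrast marker intersection and gene-set over-representation.

The assessed gene sets of all contrasts are intersected into a common
universe; markers restricted to that universe are partitioned into the
exclusive Venn regions (15 regions for four contrasts), with named
aggregates for the biologically meaningful intersections (all four nuclei,
the direct motor pathway HVC/RA/nXIIts, the telencephalic song nuclei
HVC/RA/AreaX, and the per-nucleus unique sets).  Over-representation of a
marker list against a GMT collection uses the upper-tail hypergeometric
test with a minimum overlap of 2 and a p <= 0.01 retention cutoff, with
Benjamini-Hochberg q-values and a q < 0.05 reporting flag.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import adjust_pvalues

__all__ = [
    "build_common_universe",
    "venn_partition",
    "named_regions",
    "ora",
    "summarize_markers",
]


def build_common_universe(assessed_sets: Mapping[str, set]) -> set:
    """Genes assessed in every contrast."""
    if not assessed_sets:
        raise ValueError("no assessed gene sets supplied")
    sets = list(assessed_sets.values())
    universe = set(sets[0])
    for s in sets[1:]:
        universe &= set(s)
    return universe


def venn_partition(
    marker_sets: Mapping[str, set], common_universe: set
) -> dict[tuple[str, ...], set]:
    """Exact disjoint partition of markers by contrast-membership pattern.

    Markers are first restricted to the common universe.  Every non-empty
    subset of contrasts gets a region keyed by the sorted tuple of contrast
    names; the region holds the genes that are markers in exactly those
    contrasts.  Region sizes sum to the size of the marker union.
    """
    if len(marker_sets) < 2:
        raise ValueError("need >= 2 contrasts for a Venn partition")
    names = sorted(marker_sets)
    restricted = {c: set(marker_sets[c]) & set(common_universe) for c in names}
    partition: dict[tuple[str, ...], set] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            partition[combo] = set()
    for gene in set().union(*restricted.values()):
        pattern = tuple(c for c in names if gene in restricted[c])
        partition[pattern].add(gene)
    total = sum(len(v) for v in partition.values())
    union = len(set().union(*restricted.values()))
    assert total == union, "Venn regions must partition the marker union"
    return partition


def named_regions(
    partition: dict[tuple[str, ...], set],
    all_contrasts: Sequence[str] | None = None,
    motor_pathway: Sequence[str] = ("HVC", "RA", "nXIIts"),
    telencephalic: Sequence[str] = ("HVC", "RA", "AreaX"),
) -> dict[str, set]:
    """Biologically named aggregate regions of a four-contrast partition.

    ``shared_all`` is the all-contrast region; ``shared_motor_pathway`` and
    ``shared_telencephalic`` are the exclusive three-way regions for the
    direct motor pathway and the forebrain song nuclei; ``unique_<c>`` are
    the per-contrast singleton regions.
    """
    names = sorted({c for combo in partition for c in combo})
    if all_contrasts is None:
        all_contrasts = names
    out: dict[str, set] = {}
    key_all = tuple(sorted(all_contrasts))
    if key_all in partition:
        out["shared_all"] = partition[key_all]
    key_dmp = tuple(sorted(motor_pathway))
    if key_dmp in partition:
        out["shared_motor_pathway"] = partition[key_dmp]
    key_tel = tuple(sorted(telencephalic))
    if key_tel in partition:
        out["shared_telencephalic"] = partition[key_tel]
    for c in names:
        out[f"unique_{c}"] = partition.get((c,), set())
    return out


def ora(
    query: set,
    universe: set,
    gene_sets: Mapping[str, Sequence[str]],
    min_overlap: int = 2,
    p_cutoff: float = 0.01,
    q_report: float = 0.05,
    bh_family: str = "retained",
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis of a marker list.

    Each gene set is intersected with the universe (size K); sets whose
    overlap k with the query (size n, drawn from universe size N) reaches
    ``min_overlap`` are tested with the upper-tail hypergeometric
    probability P(X >= k).  Rows with p <= ``p_cutoff`` are retained and,
    under the default ``bh_family='retained'``, the BH adjustment runs over
    those retained tests (mirroring tools that only report sets passing the
    screen); ``bh_family='eligible'`` instead adjusts across all tested
    sets.  The ``significant`` column marks q < ``q_report``.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        k = len(in_universe & query)
        if K == 0 or k < min_overlap:
            continue
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set_name": name, "set_size": K, "universe_size": N,
             "query_size": n, "overlap": k, "p": p}
        )
    table = pd.DataFrame(
        rows,
        columns=["set_name", "set_size", "universe_size", "query_size", "overlap", "p"],
    )
    if bh_family == "eligible" and len(table):
        table["q"] = adjust_pvalues(table["p"].to_numpy())
        table = table[table["p"] <= p_cutoff].reset_index(drop=True)
    else:
        table = table[table["p"] <= p_cutoff].reset_index(drop=True)
        table["q"] = (
            adjust_pvalues(table["p"].to_numpy()) if len(table) else pd.Series(dtype=float)
        )
    table["significant"] = table["q"] < q_report if len(table) else pd.Series(dtype=bool)
    return table.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)


def summarize_markers(score_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-contrast breakdown of assessed genes and markers.

    Columns: assessed (genes with an array or in-situ call), up
    (nucleus-enriched), down (nucleus-impoverished), conflict (differential
    with discordant probe directions), total (up + down), nondifferential.
    """
    rows = []
    for contrast, scores in score_tables.items():
        assessed = int((scores["status"] != "not_assessed").sum())
        diff = scores[scores["status"] == "differential"]
        up = int((diff["direction"] == "up").sum())
        down = int((diff["direction"] == "down").sum())
        conflict = int((diff["direction"] == "conflict").sum())
        rows.append(
            {
                "contrast": contrast,
                "assessed": assessed,
                "up": up,
                "down": down,
                "conflict": conflict,
                "total": up + down,
                "nondifferential": int((scores["status"] == "nondifferential").sum()),
            }
        )
    return pd.DataFrame(rows)
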