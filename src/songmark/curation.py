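"""Probe-level QC, strand-aware gene annotation, and BED-track export.

EST/cDNA clone collections and the oligo arrays derived from them carry a
known set of defects: second-strand oligo-dT priming artifacts (a 5' poly-T
run), probes whose sequence aligns to multiple named chromosomes, probes
that fail to align at all, and probes whose only extra alignment is a
high-identity secondary hit on the unplaced-scaffold pseudo-chromosome
(presumed allelic copies, retained but flagged).  This module removes or
flags each class, assigns every surviving probe to a gene model on the same
strand, and exports per-probe regulation calls as a BED9 browser track.

Coordinates are 0-based half-open throughout, matching the BED convention.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "POLYT_MIN_RUN",
    "POLYT_START_WINDOW",
    "detect_polyt_artifact",
    "is_unplaced",
    "filter_alignments",
    "assign_annotation",
    "curate_probes",
    "probe_regulation_calls",
    "export_bed",
    "read_bed",
]

POLYT_MIN_RUN = 15          # shortest 5' T-run treated as a priming artifact
POLYT_START_WINDOW = 5      # run must begin within this many bases of the 5' end
IDENTITY_MIN_CDNA = 95.0    # minimum percent identity for cDNA/EST alignments
SCORE_MIN_OLIGO = 25.0      # minimum alignment score for 60-mer oligos
CHRUN_IDENTITY_MIN = 95.0   # secondary chrUn hits above this identity are allelic
ANNOTATION_WINDOW = {"cDNA": 3000, "oligo": 5000}  # proximity window in bp

BED_COLORS = {"up": "0,170,0", "down": "200,0,0", "nondifferential": "0,0,0"}

_T_RUN = re.compile(r"T{%d,}" % POLYT_MIN_RUN)


def detect_polyt_artifact(
    sequence: str,
    min_run: int = POLYT_MIN_RUN,
    start_window: int = POLYT_START_WINDOW,
) -> bool:
    """True iff a run of >= ``min_run`` consecutive T begins within the
    first ``start_window`` bases of the 5' end.

    Such runs mark clones produced by second-strand oligo-dT priming, which
    probe the wrong strand and are removed wholesale.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    pattern = re.compile("T{%d,}" % min_run) if min_run != POLYT_MIN_RUN else _T_RUN
    for match in pattern.finditer(seq):
        if match.start() < start_window:
            return True
        break  # later runs start even further from the 5' end
    return False


def is_unplaced(chrom: str) -> bool:
    """Unplaced-scaffold pseudo-chromosome test (chrUn and variants)."""
    return str(chrom).lower().startswith("chrun")


def _passes(aln: pd.DataFrame, platform: str) -> pd.Series:
    if platform == "cDNA":
        return aln["identity"] >= IDENTITY_MIN_CDNA
    if platform == "oligo":
        return aln["score"] >= SCORE_MIN_OLIGO
    raise ValueError(f"unknown platform {platform!r}")


def filter_alignments(
    alignments: pd.DataFrame, platform: str
) -> tuple[bool, set[str], pd.Series | None]:
    """Alignment-level QC for a single probe.

    Returns ``(keep, flags, best_alignment)``.  A probe is removed when no
    alignment passes the platform threshold (flag ``unaligned`` if it has no
    alignments at all, else ``low_score``), or when passing alignments land
    on two or more distinct named chromosomes (flag ``multilocus``).
    Secondary passing alignments on the unplaced pseudo-chromosome with
    identity > 95% are tolerated; the probe is kept with flag
    ``chrun_allelic_retained``.
    """
    flags: set[str] = set()
    if alignments is None or len(alignments) == 0:
        return False, {"unaligned"}, None
    ok = alignments[_passes(alignments, platform)]
    if ok.empty:
        return False, {"low_score"}, None
    named = ok[~ok["chrom"].map(is_unplaced)]
    if named["chrom"].nunique() >= 2:
        return False, {"multilocus"}, None
    chrun = ok[ok["chrom"].map(is_unplaced)]
    if not chrun.empty and not named.empty:
        if (chrun["identity"] > CHRUN_IDENTITY_MIN).any():
            flags.add("chrun_allelic_retained")
        else:
            # low-identity extra chrUn hits are ignored rather than fatal
            pass
    if named.empty:
        # probe only aligns to unplaced scaffolds: kept but flagged so the
        # call is auditable (its locus cannot be placed on a named chromosome)
        flags.add("chrun_allelic_retained")
        pool = chrun
    else:
        pool = named
    key = "score" if platform == "oligo" else "identity"
    primary = pool[pool["rank"] == "primary"]
    pool = primary if not primary.empty else pool
    best = pool.sort_values([key, "identity"], ascending=False, kind="stable").iloc[0]
    return True, flags, best


class _ModelIndex:
    """Interval index of gene models keyed by (chrom, strand)."""

    def __init__(self, models: pd.DataFrame):
        self.by_strand: dict[tuple[str, str], IntervalTree] = {}
        self.by_chrom: dict[str, IntervalTree] = {}
        for row in models.itertuples(index=False):
            iv_data = (row.gene_id, row.start, row.end)
            self.by_strand.setdefault((row.chrom, row.strand), IntervalTree()).addi(
                row.start, row.end, iv_data
            )
            self.by_chrom.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end, iv_data
            )


def assign_annotation(
    chrom: str,
    strand: str,
    start: int,
    end: int,
    index: _ModelIndex,
    platform: str,
) -> tuple[str | None, str]:
    """Assign a probe interval to a gene model, same strand only.

    Overlapping same-strand model -> ``exonic_or_overlapping``; else the
    nearest same-strand model within the platform window (3 kb cDNA, 5 kb
    oligo, closest edges) -> ``proximal``; an overlap that exists only on
    the opposite strand -> ``antisense_conflict`` (reported, not assigned);
    otherwise ``unassigned``.
    """
    window = ANNOTATION_WINDOW[platform]
    tree = index.by_strand.get((chrom, strand))
    if tree is not None:
        hits = tree.overlap(start, end)
        if hits:
            # prefer the model with the largest overlap, ties by gene_id
            best = max(
                hits,
                key=lambda iv: (min(iv.end, end) - max(iv.begin, start), iv.data[0]),
            )
            return best.data[0], "exonic_or_overlapping"
        near = tree.overlap(start - window, end + window)
        if near:
            def gap(iv):
                if iv.end <= start:
                    return start - iv.end
                return iv.begin - end
            best = min(near, key=lambda iv: (gap(iv), iv.data[0]))
            if gap(best) <= window:
                return best.data[0], "proximal"
    other = index.by_strand.get((chrom, "-" if strand == "+" else "+"))
    if other is not None and other.overlap(start, end):
        return None, "antisense_conflict"
    return None, "unassigned"


def curate_probes(
    probes: pd.DataFrame,
    alignments: pd.DataFrame,
    gene_models: pd.DataFrame,
) -> pd.DataFrame:
    """Run sequence and alignment QC plus gene annotation over a library.

    Returns one row per probe: probe_id, platform, keep, flags
    (comma-joined), chrom/strand/start/end of the best alignment, gene_id,
    relation.  Probes carrying polyT_artifact, unaligned, low_score or
    multilocus have ``keep=False`` and must never reach downstream
    statistics.  The operation is idempotent: curating the kept subset again
    reproduces it.
    """
    index = _ModelIndex(gene_models)
    by_probe = dict(tuple(alignments.groupby("probe_id", sort=False)))
    rows = []
    for row in probes.itertuples(index=False):
        flags: set[str] = set()
        keep = True
        chrom = strand = gene_id = relation = None
        start = end = np.nan
        seq = getattr(row, "sequence", None)
        if isinstance(seq, str) and seq and detect_polyt_artifact(seq):
            flags.add("polyT_artifact")
            keep = False
        if keep:
            aln = by_probe.get(row.probe_id)
            keep_aln, aln_flags, best = filter_alignments(
                aln if aln is not None else pd.DataFrame(), row.platform
            )
            flags |= aln_flags
            keep = keep_aln
            if keep and best is not None:
                chrom, strand = best["chrom"], best["strand"]
                start, end = int(best["start"]), int(best["end"])
                gene_id, relation = assign_annotation(
                    chrom, strand, start, end, index, row.platform
                )
        rows.append(
            {
                "probe_id": row.probe_id,
                "platform": row.platform,
                "keep": keep,
                "flags": ",".join(sorted(flags)),
                "chrom": chrom,
                "strand": strand,
                "start": start,
                "end": end,
                "gene_id": gene_id,
                "relation": relation if keep else None,
            }
        )
    return pd.DataFrame(rows)


def probe_regulation_calls(
    stats: pd.DataFrame, cutoff_p: float, contrast: str
) -> pd.DataFrame:
    """Per-probe regulation calls at the calibrated cutoff.

    ``stats`` needs probe_id, M and p columns.  Probes at or below the
    cutoff are called up/down by the sign of M; the rest are assessed but
    nondifferential.
    """
    sig = stats["p"] <= cutoff_p
    regulation = np.where(
        sig, np.where(stats["M"] > 0, "up", "down"), "nondifferential"
    )
    return pd.DataFrame(
        {
            "probe_id": stats["probe_id"].to_numpy(),
            "contrast": contrast,
            "regulation": regulation,
        }
    )


def export_bed(
    calls: pd.DataFrame, curated: pd.DataFrame, path
) -> pd.DataFrame:
    """Write per-probe regulation calls as a BED9 track.

    One line per probe x contrast, name ``<probe_id>_<contrast>_<regulation>``,
    itemRgb green for up, red for down, black for assessed-but-not-
    differential.  Probes without genomic coordinates are skipped with a
    warning.  Returns the frame that was written.
    """
    coords = curated.set_index("probe_id")
    rows = []
    for row in calls.itertuples(index=False):
        if row.probe_id not in coords.index:
            log.warning("probe %s has no curated record; skipped", row.probe_id)
            continue
        c = coords.loc[row.probe_id]
        if pd.isna(c["start"]) or c["chrom"] is None:
            log.warning("probe %s has no alignment; skipped", row.probe_id)
            continue
        start, end = int(c["start"]), int(c["end"])
        rows.append(
            {
                "chrom": c["chrom"],
                "start": start,
                "end": end,
                "name": f"{row.probe_id}_{row.contrast}_{row.regulation}",
                "score": 0,
                "strand": c["strand"],
                "thickStart": start,
                "thickEnd": end,
                "itemRgb": BED_COLORS[row.regulation],
            }
        )
    bed = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score",
            "strand", "thickStart", "thickEnd", "itemRgb",
        ],
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
    return bed


def read_bed(path) -> pd.DataFrame:
    """Parse a BED9 file back into the frame layout written by export_bed."""
    names = [
        "chrom", "start", "end", "name", "score",
        "strand", "thickStart", "thickEnd", "itemRgb",
    ]
    try:
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=names,
            dtype={"chrom": str, "name": str, "strand": str, "itemRgb": str},
        )
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame(columns=names)
    return bed
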