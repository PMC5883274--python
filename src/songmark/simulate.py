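"""Synthetic paired-region microarray studies.

This module generates every input the marker-discovery pipeline consumes:
a probe library aligned to a small synthetic genome, paired nucleus/surround
intensity data (two-channel common-reference or pre-normalized single
channel), an in-situ-style validation label table, and GMT gene-set
collections.  Ground truth (which genes are differential, which probes are
planted artifacts) is carried alongside so every downstream stage can be
scored exactly.

All randomness flows from a single integer seed through named substreams,
so identical configurations produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArtifactRates",
    "SimulationConfig",
    "GroundTruth",
    "ProbeLibrary",
    "IntensityData",
    "generate_probe_library",
    "generate_intensities",
    "generate_validation_labels",
    "generate_gmt",
]

# Named chromosomes of the synthetic genome; chrUn is the unplaced-scaffold
# pseudo-chromosome and is never counted as "named".
NAMED_CHROMS = ("chr1", "chr2", "chr3", "chr4")
CHRUN = "chrUn"

# Substream labels: each generator stage draws from default_rng([seed, tag]).
_STAGE = {
    "genome": 11,
    "probes": 12,
    "artifacts": 13,
    "intensities": 14,
    "labels": 15,
    "gmt": 16,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE[stage]])


@dataclass(frozen=True)
class ArtifactRates:
    """Per-probe planting rates for the defect classes the curation stage
    must catch (polyT, multilocus, unaligned are removed; a retained chrUn
    secondary alignment is flagged but kept)."""

    polyT: float = 0.0
    multilocus: float = 0.0
    unaligned: float = 0.0
    chrun_secondary: float = 0.0

    def __post_init__(self) -> None:
        for name in ("polyT", "multilocus", "unaligned", "chrun_secondary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"artifact rate {name} must be in [0,1], got {v}")
        if self.polyT + self.multilocus + self.unaligned > 1.0:
            raise ValueError("removal-class artifact rates must sum to <= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic nucleus-vs-surround contrast.

    Parameters
    ----------
    seed
        Master seed; every stage derives its own substream from it.
    n_genes
        Number of gene models in the synthetic genome.
    probes_per_gene
        Either a constant count or a mapping ``{count: probability}`` over
        1..6 probes per gene.
    frac_differential
        Fraction of genes planted as differential (nucleus vs surround).
    frac_up_among_diff
        Among differential genes, fraction up-regulated in the nucleus.
    effect_size_sd
        Planted |log2 fold change| expressed as a multiple of the
        within-group standard deviation ``noise_sd``.
    noise_sd
        Within-group SD of log2 intensities (typical array replicate noise).
    probe_sd_spread
        Lognormal sigma of per-probe noise-SD heterogeneity; 0 gives a
        homoskedastic array.
    n_pairs
        Number of nucleus/surround sample pairs (birds).
    platform
        ``"two_channel_common_reference"`` (spotted cDNA arrays, every
        sample hybridized against one shared reference, dye-balanced) or
        ``"single_channel_normalized"`` (pre-normalized oligo-array values).
    artifact_rates
        Planting rates for probe defects.
    label_coverage
        Fraction of genes receiving an in-situ-style validation label.
        The default emulates a 320-gene atlas label set at the default
        1000-gene study scale.
    label_error_rate
        Fraction of labels flipped (differential <-> nondifferential).
    label_excluded_fraction
        Fraction of labeled genes marked ``excluded`` (unevaluable images).
    low_expression_fraction
        Fraction of genes whose probes sit in a near-background intensity
        regime in both regions (exercises the low-signal filter).
    print_tip_groups
        Number of print-tip groups on two-channel arrays.
    redundant_probe_fraction
        For genes with >= 2 probes, probability that each additional probe
        targets the same transcript segment as the first (>75% coordinate
        overlap), emulating the redundant near-identical oligos these
        arrays are known for; the collapsing stage merges such probes.
    pair_effect_sd
        SD of an optional shared per-pair (per-bird) random intercept.
    """

    seed: int = 0
    n_genes: int = 1000
    probes_per_gene: Mapping[int, float] | int = 2
    frac_differential: float = 0.1
    frac_up_among_diff: float = 0.6
    effect_size_sd: float = 2.0
    noise_sd: float = 0.4
    probe_sd_spread: float = 0.15
    n_pairs: int = 6
    platform: str = "single_channel_normalized"
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    label_coverage: float = 0.32
    label_error_rate: float = 0.0
    label_excluded_fraction: float = 0.05
    low_expression_fraction: float = 0.2
    print_tip_groups: int = 16
    redundant_probe_fraction: float = 1.0
    pair_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_pairs <= 0 or self.print_tip_groups <= 0:
            raise ValueError("counts must be positive")
        if self.n_pairs < 2:
            raise ValueError("need >= 2 sample pairs per contrast")
        for name in (
            "frac_differential",
            "frac_up_among_diff",
            "label_coverage",
            "label_error_rate",
            "label_excluded_fraction",
            "low_expression_fraction",
            "redundant_probe_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.effect_size_sd < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size_sd must be >= 0 and noise_sd > 0")
        if self.platform not in (
            "two_channel_common_reference",
            "single_channel_normalized",
        ):
            raise ValueError(f"unknown platform {self.platform!r}")
        dist = self.probes_per_gene
        if isinstance(dist, int):
            if not 1 <= dist <= 6:
                raise ValueError("probes_per_gene must lie in 1..6")
            dist = {dist: 1.0}
        else:
            dist = {int(k): float(v) for k, v in dist.items()}
            if not dist or any(not 1 <= k <= 6 for k in dist):
                raise ValueError("probes_per_gene support must lie in 1..6")
            if any(v < 0 for v in dist.values()):
                raise ValueError("probes_per_gene weights must be >= 0")
            total = sum(dist.values())
            if total <= 0:
                raise ValueError("probes_per_gene weights sum to 0")
            dist = {k: v / total for k, v in sorted(dist.items())}
        object.__setattr__(self, "probes_per_gene", dist)

    @property
    def probe_platform(self) -> str:
        """Probe chemistry implied by the intensity platform."""
        return "cDNA" if self.platform == "two_channel_common_reference" else "oligo"

    @property
    def true_effect(self) -> float:
        """Planted |log2 fold change| in log2 units."""
        return self.effect_size_sd * self.noise_sd


@dataclass
class GroundTruth:
    """Planted truth for one simulated study.

    ``genes`` columns: gene_id, status (up/down/null), true_log2fc, expressed.
    ``probes`` columns: probe_id, parent_gene, artifact_class
    (none/polyT/multilocus/unaligned), chrun_secondary (bool).
    """

    genes: pd.DataFrame
    probes: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "probes": self.probes.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genes=pd.DataFrame(payload["genes"]),
            probes=pd.DataFrame(payload["probes"]),
        )


@dataclass
class ProbeLibrary:
    """A simulated probe collection: probe table, genome alignments,
    gene models, and the generating truth."""

    probes: pd.DataFrame      # probe_id, platform, sequence, tip_group
    alignments: pd.DataFrame  # probe_id, chrom, strand, start, end, identity, score, rank
    gene_models: pd.DataFrame  # gene_id, symbol, chrom, strand, start, end
    truth: GroundTruth
    config: SimulationConfig


@dataclass
class IntensityData:
    """Per-sample intensities for one contrast.

    Two-channel: ``arrays`` maps array_id to a frame with columns
    F_Cy5, B_Cy5, F_Cy3, B_Cy3 indexed by probe_id; ``design`` carries
    array_id, region, pair, dye_of_sample.  Single-channel: ``values`` is a
    probes x samples frame of normalized log2 values; ``design`` carries
    sample_id, region, pair.
    """

    design: pd.DataFrame
    values: pd.DataFrame | None = None
    arrays: dict[str, pd.DataFrame] | None = None
    platform: str = "single_channel_normalized"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def generate_probe_library(config: SimulationConfig) -> ProbeLibrary:
    """Build the synthetic genome, gene models, probes and alignments.

    Gene models are placed without overlap on the named chromosomes with
    intergenic gaps larger than any annotation window, so each probe's only
    in-window model is its parent gene.  Artifact probes carry exactly the
    defining defect of their class: a 5' poly-T run, a second passing
    alignment on a different named chromosome, no alignment at all, or a
    retained high-identity secondary chrUn alignment (kept, flagged).
    """
    g = _rng(config.seed, "genome")
    pr = _rng(config.seed, "probes")
    ar = _rng(config.seed, "artifacts")

    n = config.n_genes
    chroms = np.array(NAMED_CHROMS)[g.integers(0, len(NAMED_CHROMS), n)]
    strands = np.where(g.random(n) < 0.5, "+", "-")
    lengths = g.integers(2_000, 20_000, n)
    gaps = g.integers(12_000, 30_000, n)

    starts = np.zeros(n, dtype=np.int64)
    cursors: dict[str, int] = {c: 0 for c in NAMED_CHROMS}
    for i in range(n):
        c = chroms[i]
        starts[i] = cursors[c] + gaps[i]
        cursors[c] = starts[i] + lengths[i]

    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    gene_models = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"SYN{i:05d}" for i in range(n)],
            "chrom": chroms,
            "strand": strands,
            "start": starts,
            "end": starts + lengths,
        }
    )

    # differential status and expression regime per gene
    status = np.full(n, "null", dtype=object)
    diff_mask = g.random(n) < config.frac_differential
    up_mask = g.random(n) < config.frac_up_among_diff
    status[diff_mask & up_mask] = "up"
    status[diff_mask & ~up_mask] = "down"
    lfc = np.zeros(n)
    lfc[status == "up"] = config.true_effect
    lfc[status == "down"] = -config.true_effect
    expressed = g.random(n) >= config.low_expression_fraction

    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "status": status,
            "true_log2fc": lfc,
            "expressed": expressed,
        }
    )

    # probes per gene
    counts_support = np.array(list(config.probes_per_gene.keys()))
    counts_probs = np.array(list(config.probes_per_gene.values()))
    per_gene = counts_support[pr.choice(len(counts_support), n, p=counts_probs)]

    probe_len = 60 if config.probe_platform == "oligo" else int(500)
    rows_probe, rows_aln, rows_truth = [], [], []
    probe_counter = 0
    for gi in range(n):
        gstart, gend = int(starts[gi]), int(starts[gi] + lengths[gi])
        strand = strands[gi]
        chrom = chroms[gi]
        k = int(per_gene[gi])
        L = probe_len if config.probe_platform == "oligo" else int(pr.integers(300, 900))
        span = gend - gstart - L
        anchor = gstart + int(pr.integers(0, max(span, 1)))
        placed: list[tuple[int, int]] = []
        for j in range(k):
            if j == 0:
                p_start = anchor
            elif pr.random() < config.redundant_probe_fraction:
                # same transcript segment: shift < 25% of length keeps
                # mutual overlap above the 75% collapsing threshold
                shift = int(pr.integers(1, max(int(0.24 * L), 2)))
                p_start = min(max(anchor + shift, gstart), gend - L)
            else:
                # independent, non-overlapping placement when room permits
                for _ in range(20):
                    cand = gstart + int(pr.integers(0, max(span, 1)))
                    if all(abs(cand - s) >= L for s, _ in placed):
                        p_start = cand
                        break
                else:
                    p_start = min(anchor + 2 * L, gend - L)
            p_start = max(gstart, min(p_start, gend - L))
            placed.append((p_start, p_start + L))
            probe_id = f"P{probe_counter:06d}"
            probe_counter += 1
            rows_probe.append(
                {
                    "probe_id": probe_id,
                    "platform": config.probe_platform,
                    "sequence": _random_seq(pr, L),
                    "length": L,
                }
            )
            rows_aln.append(
                {
                    "probe_id": probe_id,
                    "chrom": chrom,
                    "strand": strand,
                    "start": p_start,
                    "end": p_start + L,
                    "identity": round(float(pr.uniform(96.5, 99.9)), 2),
                    "score": int(pr.integers(40, 80)),
                    "rank": "primary",
                }
            )
            rows_truth.append(
                {
                    "probe_id": probe_id,
                    "parent_gene": gene_ids[gi],
                    "artifact_class": "none",
                    "chrun_secondary": False,
                }
            )

    probes = pd.DataFrame(rows_probe)
    alignments = pd.DataFrame(rows_aln)
    truth_probes = pd.DataFrame(rows_truth)

    # plant artifacts (mutually exclusive removal classes per probe)
    rates = config.artifact_rates
    m = len(probes)
    p_none = 1.0 - rates.polyT - rates.multilocus - rates.unaligned
    classes = ar.choice(
        ["none", "polyT", "multilocus", "unaligned"],
        size=m,
        p=[p_none, rates.polyT, rates.multilocus, rates.unaligned],
    )
    truth_probes["artifact_class"] = classes

    drop_aln = set()
    extra_aln = []
    seqs = probes["sequence"].to_numpy(dtype=object)
    for i in range(m):
        cls = classes[i]
        pid = probes.at[i, "probe_id"]
        if cls == "polyT":
            run = int(ar.integers(15, 21))
            seqs[i] = "T" * run + seqs[i][run:]
        elif cls == "unaligned":
            drop_aln.add(pid)
        elif cls == "multilocus":
            home = alignments.loc[alignments["probe_id"] == pid, "chrom"].iloc[0]
            other = [c for c in NAMED_CHROMS if c != home]
            pos = int(ar.integers(0, 1_000_000))
            extra_aln.append(
                {
                    "probe_id": pid,
                    "chrom": other[int(ar.integers(0, len(other)))],
                    "strand": "+" if ar.random() < 0.5 else "-",
                    "start": pos,
                    "end": pos + int(probes.at[i, "length"]),
                    "identity": round(float(ar.uniform(96.0, 99.0)), 2),
                    "score": int(ar.integers(30, 60)),
                    "rank": "secondary",
                }
            )
        if cls == "none" and ar.random() < rates.chrun_secondary:
            truth_probes.at[i, "chrun_secondary"] = True
            pos = int(ar.integers(0, 1_000_000))
            extra_aln.append(
                {
                    "probe_id": pid,
                    "chrom": CHRUN,
                    "strand": "+" if ar.random() < 0.5 else "-",
                    "start": pos,
                    "end": pos + int(probes.at[i, "length"]),
                    "identity": round(float(ar.uniform(95.1, 99.0)), 2),
                    "score": int(ar.integers(30, 60)),
                    "rank": "secondary",
                }
            )
    probes["sequence"] = seqs
    if extra_aln:
        alignments = pd.concat(
            [alignments, pd.DataFrame(extra_aln)], ignore_index=True
        )
    alignments = alignments[~alignments["probe_id"].isin(drop_aln)].reset_index(
        drop=True
    )
    alignments["end"] = np.maximum(alignments["end"], alignments["start"] + 1)
    alignments = alignments.sort_values(
        ["probe_id", "rank", "chrom", "start"], kind="stable"
    ).reset_index(drop=True)

    probes["tip_group"] = np.arange(len(probes)) % config.print_tip_groups
    probes = probes.drop(columns=["length"])

    truth = GroundTruth(genes=truth_genes, probes=truth_probes)
    return ProbeLibrary(
        probes=probes,
        alignments=alignments,
        gene_models=gene_models,
        truth=truth,
        config=config,
    )


# intensity model constants (log2 scale): expressed genes sit well above a
# near-background regime so the ranked-intensity curve shows a clear shoulder
EXPRESSED_MEAN = 10.0
EXPRESSED_GENE_SD = 1.5
EXPRESSED_PROBE_SD = 0.5
BACKGROUND_MEAN = 4.0
BACKGROUND_SD = 0.5
ADDITIVE_BG_MEAN = 80.0


def _probe_baselines(lib: ProbeLibrary, rng: np.random.Generator) -> np.ndarray:
    """Per-probe baseline log2 intensity from the expressed/near-background
    two-component mixture; the regime is a property of the parent gene."""
    genes = lib.truth.genes.set_index("gene_id")
    parent = lib.truth.probes["parent_gene"].to_numpy()
    expressed = genes.loc[parent, "expressed"].to_numpy()
    gene_level = pd.Series(
        EXPRESSED_MEAN + rng.normal(0.0, EXPRESSED_GENE_SD, len(genes)),
        index=genes.index,
    )
    base = np.where(
        expressed,
        gene_level.loc[parent].to_numpy() + rng.normal(0.0, EXPRESSED_PROBE_SD, len(parent)),
        rng.normal(BACKGROUND_MEAN, BACKGROUND_SD, len(parent)),
    )
    return base


def generate_intensities(lib: ProbeLibrary, config: SimulationConfig | None = None) -> IntensityData:
    """Simulate per-sample intensities for the library's contrast.

    Differential genes are shifted by their true log2 fold change in nucleus
    samples only; near-background genes stay near background in both regions
    and receive no shift.  Two-channel arrays get log-normal foreground over
    an additive background, alternating dye orientation, and a smooth
    per-print-tip intensity-dependent bias for the normalization stage to
    remove.
    """
    if lib is None:
        raise ValueError("a probe library is required")
    config = config or lib.config
    rng = _rng(config.seed, "intensities")

    probes = lib.truth.probes
    genes = lib.truth.genes.set_index("gene_id")
    parent = probes["parent_gene"].to_numpy()
    expressed = genes.loc[parent, "expressed"].to_numpy()
    lfc = np.where(expressed, genes.loc[parent, "true_log2fc"].to_numpy(), 0.0)
    probe_ids = probes["probe_id"].to_numpy()
    m = len(probe_ids)

    base = _probe_baselines(lib, rng)
    probe_sd = config.noise_sd * np.exp(
        rng.normal(0.0, config.probe_sd_spread, m)
    )
    pair_fx = rng.normal(0.0, config.pair_effect_sd, (config.n_pairs, m)) if config.pair_effect_sd > 0 else np.zeros((config.n_pairs, m))

    if config.platform == "single_channel_normalized":
        cols, data = [], []
        for i in range(config.n_pairs):
            for region, shift in (("nucleus", lfc), ("surround", 0.0)):
                vals = (
                    base
                    + shift
                    + pair_fx[i]
                    + rng.normal(0.0, 1.0, m) * probe_sd
                )
                cols.append(f"{region}_{i + 1}")
                data.append(vals)
        values = pd.DataFrame(
            np.column_stack(data), index=pd.Index(probe_ids, name="probe_id"), columns=cols
        )
        design = pd.DataFrame(
            {
                "sample_id": cols,
                "region": [c.rsplit("_", 1)[0] for c in cols],
                "pair": [int(c.rsplit("_", 1)[1]) for c in cols],
            }
        )
        return IntensityData(design=design, values=values, platform=config.platform)

    # two-channel common-reference design
    tips = lib.probes.set_index("probe_id").loc[probe_ids, "tip_group"].to_numpy()
    n_tips = config.print_tip_groups
    amp = rng.uniform(-0.6, 0.6, n_tips)
    phase = rng.uniform(0.0, 2 * np.pi, n_tips)

    arrays: dict[str, pd.DataFrame] = {}
    design_rows = []
    array_idx = 0
    for i in range(config.n_pairs):
        for region, shift in (("nucleus", lfc), ("surround", 0.0)):
            sample_log2 = (
                base + shift + pair_fx[i] + rng.normal(0.0, 1.0, m) * probe_sd
            )
            ref_log2 = base + rng.normal(0.0, 1.0, m) * probe_sd
            a_val = 0.5 * (sample_log2 + ref_log2)
            bias = amp[tips] * np.sin(a_val / 2.0 + phase[tips])
            # dye balancing: sample in Cy5 on even arrays, Cy3 on odd
            dye = "Cy5" if array_idx % 2 == 0 else "Cy3"
            if dye == "Cy5":
                cy5_log2 = sample_log2 + bias / 2.0
                cy3_log2 = ref_log2 - bias / 2.0
            else:
                cy5_log2 = ref_log2 + bias / 2.0
                cy3_log2 = sample_log2 - bias / 2.0
            bg5 = rng.gamma(16.0, ADDITIVE_BG_MEAN / 16.0, m)
            bg3 = rng.gamma(16.0, ADDITIVE_BG_MEAN / 16.0, m)
            array_id = f"array_{array_idx + 1:02d}"
            arrays[array_id] = pd.DataFrame(
                {
                    "F_Cy5": np.exp2(cy5_log2) + bg5,
                    "B_Cy5": bg5,
                    "F_Cy3": np.exp2(cy3_log2) + bg3,
                    "B_Cy3": bg3,
                },
                index=pd.Index(probe_ids, name="probe_id"),
            )
            design_rows.append(
                {
                    "array_id": array_id,
                    "region": region,
                    "pair": i + 1,
                    "dye_of_sample": dye,
                }
            )
            array_idx += 1
    design = pd.DataFrame(design_rows)
    return IntensityData(design=design, arrays=arrays, platform=config.platform)


def generate_validation_labels(
    truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Sample an in-situ-style validation label table from the truth.

    Validation panels for cutoff calibration are built deliberately, with
    genes chosen to represent both the differential and the expressed
    non-differential class — an atlas of expression images over-represents
    genes with distinctive patterns.  The generator therefore stratifies:
    of the ``label_coverage * n_genes`` panel slots, up to half go to
    differential genes (all of them when fewer exist) and the rest to
    non-differential genes.  Planted status collapses to differential /
    nondifferential; ``label_error_rate`` of the informative labels are
    flipped and ``label_excluded_fraction`` are marked excluded (images
    unevaluable).  Columns: gene_id, label.
    """
    if truth is None:
        raise ValueError("ground truth is required")
    rng = _rng(config.seed, "labels")
    genes = truth.genes
    n = len(genes)
    n_target = int(round(config.label_coverage * n))
    diff_pool = genes.index[genes["status"].isin(["up", "down"])].to_numpy()
    null_pool = genes.index[genes["status"] == "null"].to_numpy()
    n_diff = min(len(diff_pool), n_target // 2) if len(null_pool) else n_target
    n_null = min(len(null_pool), n_target - n_diff)
    chosen = np.concatenate(
        [
            rng.choice(diff_pool, size=n_diff, replace=False),
            rng.choice(null_pool, size=n_null, replace=False),
        ]
    ).astype(int)
    chosen.sort()
    sub = genes.loc[chosen, ["gene_id", "status"]].copy()
    if sub.empty:
        return pd.DataFrame(columns=["gene_id", "label"])
    label = np.where(sub["status"].isin(["up", "down"]), "differential", "nondifferential")
    flip = rng.random(len(sub)) < config.label_error_rate
    label = np.where(
        flip,
        np.where(label == "differential", "nondifferential", "differential"),
        label,
    )
    excluded = rng.random(len(sub)) < config.label_excluded_fraction
    label = np.where(excluded, "excluded", label)
    return pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(), "label": label})


def generate_gmt(
    truth: GroundTruth,
    n_sets: int = 50,
    enriched_sets: int = 0,
    set_size: tuple[int, int] = (10, 40),
    odds_ratio: float = 1.0,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Draw a GMT-style gene-set collection over the simulated gene universe.

    ``enriched_sets`` of the sets over-sample differential genes with the
    given odds ratio; the remainder are uniform draws from all genes.
    """
    if truth is None:
        raise ValueError("ground truth is required")
    rng = np.random.default_rng([int(seed) if seed is not None else 0, _STAGE["gmt"]])
    genes = truth.genes["gene_id"].to_numpy()
    is_diff = truth.genes["status"].isin(["up", "down"]).to_numpy()
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        size = min(size, len(genes))
        if s < enriched_sets and odds_ratio != 1.0 and is_diff.any():
            w = np.where(is_diff, odds_ratio, 1.0)
            w = w / w.sum()
            members = rng.choice(genes, size=size, replace=False, p=w)
        else:
            members = rng.choice(genes, size=size, replace=False)
        name = f"SET_{s:03d}" + ("_ENR" if s < enriched_sets and odds_ratio != 1.0 else "")
        sets[name] = sorted(members.tolist())
    return sets
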