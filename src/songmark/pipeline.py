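"""End-to-end drivers: one contrast, or a multi-contrast marker study.

A contrast run chains the full procedure: simulate (or accept) a probe
library, curate probes, build intensities, filter low-signal and
high-variance oligos (single-channel path) or background-correct,
normalize and orient log-ratios (two-channel path), fit the moderated
t-test, calibrate the significance cutoff against validation labels, and
score genes by the majority rule.  A study run repeats this over several
contrasts and intersects the resulting marker sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import calibration as cal
from . import curation, enrichment, scoring, simulate, stats

__all__ = ["ContrastResult", "StudyResult", "run_contrast", "run_study"]


@dataclass
class ContrastResult:
    """Everything produced by one nucleus-vs-surround analysis."""

    contrast: str
    config: simulate.SimulationConfig
    library: simulate.ProbeLibrary
    curated: pd.DataFrame
    intensities: simulate.IntensityData
    stats: pd.DataFrame
    model: stats.ModeratedModel
    filter_report: pd.DataFrame
    calibration: cal.CalibrationResult
    labels: pd.DataFrame
    scores: pd.DataFrame

    @property
    def assessed_genes(self) -> set:
        return set(
            self.scores.loc[self.scores["status"] != "not_assessed", "gene_id"]
        )

    @property
    def marker_genes(self) -> set:
        return set(
            self.scores.loc[self.scores["status"] == "differential", "gene_id"]
        )


@dataclass
class StudyResult:
    """A multi-contrast study with its marker intersection."""

    contrasts: dict[str, ContrastResult]
    common_universe: set
    venn: dict[tuple[str, ...], set]
    regions: dict[str, set]
    summary: pd.DataFrame


def _single_channel_stats(lib, curated, inten, config):
    kept = curated.loc[curated["keep"], "probe_id"]
    values = inten.values.loc[kept]
    regions = inten.design.set_index("sample_id")["region"]
    report_rows = [
        {"probe_id": pid, "reason": flags}
        for pid, flags in curated.loc[~curated["keep"], ["probe_id", "flags"]].itertuples(
            index=False
        )
    ]

    # low-signal filter on per-region mean intensities
    region_means = values.T.groupby(regions).mean().T
    threshold, removed_low, info = stats.low_signal_cutoff(region_means)
    report_rows += [{"probe_id": p, "reason": "low_signal"} for p in removed_low]
    values = values.drop(index=removed_low)

    # CV filter on the unlogged scale
    removed_cv, _, _, nonpos = stats.high_variance_filter(np.exp2(values))
    report_rows += [{"probe_id": p, "reason": "high_cv"} for p in removed_cv]
    report_rows += [{"probe_id": p, "reason": "nonpositive_mean"} for p in nonpos]
    values = values.drop(index=removed_cv.union(nonpos))

    table, model = stats.fit_moderated_t(
        values, regions.loc[values.columns].to_numpy()
    )
    report = pd.DataFrame(report_rows, columns=["probe_id", "reason"])
    return table, model, report, {"low_signal_threshold": threshold, **info}


def _two_channel_stats(lib, curated, inten, config):
    kept = set(curated.loc[curated["keep"], "probe_id"])
    tips = lib.probes.set_index("probe_id")["tip_group"]
    ratios, _ = stats.process_two_channel(
        inten.arrays, inten.design, tip_groups=tips.loc[inten.arrays[
            inten.design["array_id"].iloc[0]
        ].index].to_numpy(),
    )
    ratios = ratios.loc[[p for p in ratios.index if p in kept]]
    regions = inten.design.set_index("array_id")["region"]
    table, model = stats.fit_moderated_t(
        ratios, regions.loc[ratios.columns].to_numpy()
    )
    report = pd.DataFrame(
        [
            {"probe_id": pid, "reason": flags}
            for pid, flags in curated.loc[
                ~curated["keep"], ["probe_id", "flags"]
            ].itertuples(index=False)
        ],
        columns=["probe_id", "reason"],
    )
    return table, model, report, {}


def run_contrast(
    config: simulate.SimulationConfig,
    contrast: str = "HVC",
    labels: pd.DataFrame | None = None,
    insitu: pd.DataFrame | None = None,
    cutoff_override: float | None = None,
) -> ContrastResult:
    """Run the full pipeline for one simulated contrast.

    ``labels`` defaults to labels generated from the library's own truth;
    ``cutoff_override`` forces a manual cutoff (mirroring a visually chosen
    one) in place of the automatic calibration.
    """
    lib = simulate.generate_probe_library(config)
    curated = curation.curate_probes(lib.probes, lib.alignments, lib.gene_models)
    inten = simulate.generate_intensities(lib, config)

    if config.platform == "single_channel_normalized":
        table, model, report, _ = _single_channel_stats(lib, curated, inten, config)
    else:
        table, model, report, _ = _two_channel_stats(lib, curated, inten, config)

    if labels is None:
        labels = simulate.generate_validation_labels(lib.truth, config)
    if cutoff_override is not None:
        calib = cal.default_cutoff(contrast, cutoff=cutoff_override)
        calib.note = "manual override"
    else:
        try:
            diff_p, nondiff_p = cal.collect_labeled_pvalues(table, curated, labels)
            calib = cal.choose_cutoff(diff_p, nondiff_p, contrast=contrast)
        except cal.CalibrationError:
            calib = cal.default_cutoff(contrast)

    scores = scoring.score_genes(
        table,
        curated,
        calib.cutoff_p,
        contrast,
        all_genes=lib.gene_models["gene_id"],
    )
    if insitu is not None:
        scores = scoring.merge_insitu(scores, insitu)

    # exclusion-flag invariant: no removed probe may appear in the stats
    excluded = set(curated.loc[~curated["keep"], "probe_id"])
    assert not excluded & set(table["probe_id"]), (
        "excluded probes leaked into downstream statistics"
    )
    return ContrastResult(
        contrast=contrast,
        config=config,
        library=lib,
        curated=curated,
        intensities=inten,
        stats=table,
        model=model,
        filter_report=report,
        calibration=calib,
        labels=labels,
        scores=scores,
    )


def run_study(
    configs: Mapping[str, simulate.SimulationConfig],
    **kwargs,
) -> StudyResult:
    """Run several contrasts and intersect their markers.

    ``configs`` maps contrast name (e.g. nucleus) to its simulation
    configuration; each contrast should use a distinct seed to represent an
    independent experiment.
    """
    results = {
        name: run_contrast(cfg, contrast=name, **kwargs)
        for name, cfg in configs.items()
    }
    universe = enrichment.build_common_universe(
        {name: r.assessed_genes for name, r in results.items()}
    )
    venn = enrichment.venn_partition(
        {name: r.marker_genes for name, r in results.items()}, universe
    )
    regions = enrichment.named_regions(venn)
    summary = enrichment.summarize_markers(
        {name: r.scores for name, r in results.items()}
    )
    return StudyResult(
        contrasts=results,
        common_universe=universe,
        venn=venn,
        regions=regions,
        summary=summary,
    )
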