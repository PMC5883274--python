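"""Readers and writers for the pipeline's plain-text formats.

Tables travel as TSV, gene sets as GMT, regulation tracks as BED9 (see
:mod:`songmark.curation`), configurations and array designs as YAML, and
ground truth as JSON.  Coordinates in all on-disk tables are 0-based
half-open; 1-based inputs must be converted before loading.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .simulate import (
    ArtifactRates,
    IntensityData,
    ProbeLibrary,
    SimulationConfig,
)

__all__ = [
    "read_gmt",
    "write_gmt",
    "load_config",
    "load_design",
    "write_library",
    "write_intensities",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line, name TAB description TAB genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(
    gene_sets: Mapping[str, Sequence[str]], path, descriptions: Mapping[str, str] | None = None
) -> None:
    """Write a gene-set collection in GMT format."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *map(str, members)]) + "\n")


def load_config(path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "artifact_rates" in raw and isinstance(raw["artifact_rates"], dict):
        raw["artifact_rates"] = ArtifactRates(**raw["artifact_rates"])
    return SimulationConfig(**raw)


def load_design(path) -> pd.DataFrame:
    """Array design YAML: a list of records with array_id/sample_id,
    region, pair and (two-channel) dye_of_sample."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return pd.DataFrame(raw["arrays"] if isinstance(raw, dict) else raw)


def write_library(lib: ProbeLibrary, outdir) -> None:
    """Write a simulated library as TSV tables plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lib.probes.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    lib.alignments.to_csv(outdir / "alignments.tsv", sep="\t", index=False)
    lib.gene_models.to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
    lib.truth.to_json(outdir / "truth.json")


def write_intensities(data: IntensityData, outdir) -> None:
    """Write intensity data: one TSV per two-channel array, or a single
    matrix for single-channel values, plus the design table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    if data.values is not None:
        data.values.to_csv(outdir / "values.tsv", sep="\t")
    if data.arrays is not None:
        for array_id, frame in data.arrays.items():
            frame.to_csv(outdir / f"{array_id}.tsv", sep="\t")
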