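"""Tests for probe QC, annotation, and BED export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from songmark import curation as cu


def _naive_polyt(seq, min_run=15, window=5):
    """Independent oracle: scan every position for a qualifying T-run."""
    seq = seq.upper()
    for start in range(min(window, len(seq))):
        run = 0
        for ch in seq[start:]:
            if ch == "T":
                run += 1
            else:
                break
        if run >= min_run:
            return True
    return False


class TestPolyT:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("T" * 15 + "ACGTACGT", True),      # boundary run of exactly 15
            ("A" + "T" * 14 + "GCAGCA", False),  # run of 14 only
            ("ACGTACGTAC" + "T" * 20, False),    # run starts at position 10
            ("AC" + "T" * 16 + "GGG", True),     # run starts inside window
            ("ACGTA" + "T" * 20, False),         # run starts at position 5
            ("ACGT" + "T" * 15, True),           # run reaches 16 from position 4
        ],
    )
    def test_known_cases(self, seq, expected):
        assert cu.detect_polyt_artifact(seq) is expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cu.detect_polyt_artifact("")

    @settings(max_examples=300, derandomize=True)
    @given(hst.text(alphabet="ACGT", min_size=1, max_size=80))
    def test_matches_bruteforce_scan(self, seq):
        assert cu.detect_polyt_artifact(seq) == _naive_polyt(seq)


def _aln(rows):
    return pd.DataFrame(
        rows,
        columns=["probe_id", "chrom", "strand", "start", "end", "identity",
                 "score", "rank"],
    )


class TestAlignmentFilter:
    def test_clean_oligo_kept_without_flags(self):
        aln = _aln([("p1", "chr2", "+", 100, 160, 98.0, 30, "primary")])
        keep, flags, best = cu.filter_alignments(aln, "oligo")
        assert keep and not flags
        assert best["chrom"] == "chr2"

    def test_two_named_chromosomes_flag_multilocus(self):
        aln = _aln([
            ("p1", "chr1", "+", 100, 160, 98.0, 30, "primary"),
            ("p1", "chr5", "-", 900, 960, 97.0, 28, "secondary"),
        ])
        keep, flags, _ = cu.filter_alignments(aln, "oligo")
        assert not keep and flags == {"multilocus"}

    def test_chrun_secondary_retained_with_flag(self):
        aln = _aln([
            ("p1", "chr3", "+", 100, 600, 98.0, 400, "primary"),
            ("p1", "chrUn", "+", 5000, 5500, 97.0, 380, "secondary"),
        ])
        keep, flags, best = cu.filter_alignments(aln, "cDNA")
        assert keep and flags == {"chrun_allelic_retained"}
        assert best["chrom"] == "chr3"

    def test_below_identity_threshold_removed(self):
        aln = _aln([("p1", "chr1", "+", 100, 600, 90.0, 200, "primary")])
        keep, flags, _ = cu.filter_alignments(aln, "cDNA")
        assert not keep and flags == {"low_score"}

    def test_no_alignments_flag_unaligned(self):
        keep, flags, _ = cu.filter_alignments(pd.DataFrame(), "oligo")
        assert not keep and flags == {"unaligned"}

    def test_same_chromosome_double_hit_is_kept(self):
        # the multi-locus rule only fires across different named chromosomes
        aln = _aln([
            ("p1", "chr1", "+", 100, 160, 98.0, 30, "primary"),
            ("p1", "chr1", "+", 7000, 7060, 96.0, 27, "secondary"),
        ])
        keep, flags, _ = cu.filter_alignments(aln, "oligo")
        assert keep and not flags

    def test_unknown_platform_rejected(self):
        aln = _aln([("p1", "chr1", "+", 0, 60, 99.0, 30, "primary")])
        with pytest.raises(ValueError):
            cu.filter_alignments(aln, "agilent")


class TestAnnotation:
    def _assign(self, models, chrom, strand, start, end, platform="cDNA"):
        index = cu._ModelIndex(models)
        return cu.assign_annotation(chrom, strand, start, end, index, platform)

    def test_probe_inside_model_is_overlapping(self, toy_models):
        gene, rel = self._assign(toy_models, "chr1", "+", 2000, 2500)
        assert (gene, rel) == ("gA", "exonic_or_overlapping")

    def test_proximity_window_boundary(self, toy_models):
        # model gA ends at 5000; cDNA window is 3 kb measured edge to edge
        gene, rel = self._assign(toy_models, "chr1", "+", 7999, 8200)
        assert (gene, rel) == ("gA", "proximal")
        gene, rel = self._assign(toy_models, "chr1", "+", 8001, 8200)
        assert gene is None and rel == "unassigned"

    def test_oligo_window_is_5kb(self, toy_models):
        gene, rel = self._assign(toy_models, "chr1", "+", 9500, 9560, "oligo")
        assert (gene, rel) == ("gA", "proximal")

    def test_opposite_strand_overlap_is_antisense_conflict(self, toy_models):
        gene, rel = self._assign(toy_models, "chr1", "+", 41000, 41500)
        assert gene is None and rel == "antisense_conflict"

    def test_toy_locus_exhaustive_against_hand_enumeration(self, toy_models):
        """Every query interval in a scripted sweep matches the relation
        worked out by hand from the five-model toy locus."""
        cases = [
            (("+", 1500, 1600), ("gA", "exonic_or_overlapping")),
            (("+", 4900, 5100), ("gA", "exonic_or_overlapping")),
            (("+", 6000, 6100), ("gA", "proximal")),
            (("+", 17500, 17600), ("gB", "proximal")),
            (("+", 27500, 27600), ("gB", "proximal")),
            (("+", 33000, 33100), (None, "unassigned")),
            (("-", 42000, 42100), ("gC", "exonic_or_overlapping")),
            (("+", 42000, 42100), (None, "antisense_conflict")),
            (("-", 52000, 52100), (None, "unassigned")),
            (("-", 83000, 83100), ("gE", "exonic_or_overlapping")),
        ]
        for (strand, s, e), expected in cases:
            assert self._assign(toy_models, "chr1", strand, s, e) == expected


class TestCuration:
    def test_planted_artifacts_recovered_exactly(self, small_library):
        """Removal counts per artifact class equal the planted counts."""
        lib = small_library
        curated = cu.curate_probes(lib.probes, lib.alignments, lib.gene_models)
        merged = curated.merge(lib.truth.probes, on="probe_id")
        flag_for = {"polyT": "polyT_artifact", "multilocus": "multilocus",
                    "unaligned": "unaligned"}
        for cls, flag in flag_for.items():
            planted = set(merged.loc[merged["artifact_class"] == cls, "probe_id"])
            flagged = set(
                merged.loc[merged["flags"].str.contains(flag, na=False), "probe_id"]
            )
            assert planted == flagged
        clean = merged["artifact_class"] == "none"
        assert merged.loc[clean, "keep"].all()
        chrun = merged["chrun_secondary"]
        assert (
            merged.loc[chrun, "flags"].str.contains("chrun_allelic_retained")
        ).all()

    def test_curation_is_idempotent(self, small_library):
        lib = small_library
        first = cu.curate_probes(lib.probes, lib.alignments, lib.gene_models)
        kept_probes = lib.probes[lib.probes["probe_id"].isin(
            first.loc[first["keep"], "probe_id"])]
        second = cu.curate_probes(kept_probes, lib.alignments, lib.gene_models)
        assert second["keep"].all()
        merged = second.merge(first, on="probe_id", suffixes=("_2", "_1"))
        assert (merged["flags_2"] == merged["flags_1"]).all()
        assert (merged["gene_id_2"] == merged["gene_id_1"]).all()

    def test_kept_probes_annotate_to_parent_gene(self, small_library):
        lib = small_library
        curated = cu.curate_probes(lib.probes, lib.alignments, lib.gene_models)
        kept = curated[curated["keep"]].merge(
            lib.truth.probes[["probe_id", "parent_gene"]], on="probe_id"
        )
        assert (kept["gene_id"] == kept["parent_gene"]).all()


class TestBedExport:
    def _calls(self):
        return pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "contrast": ["HVC"] * 3,
                "regulation": ["up", "down", "nondifferential"],
            }
        )

    def _curated(self):
        return pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "keep": True,
                "chrom": ["chr1", "chr1", "chr2"],
                "strand": ["+", "-", "+"],
                "start": [100, 500, 900],
                "end": [160, 560, 960],
            }
        )

    def test_colors_follow_regulation(self, tmp_path):
        path = tmp_path / "track.bed"
        bed = cu.export_bed(self._calls(), self._curated(), path)
        assert list(bed["itemRgb"]) == ["0,170,0", "200,0,0", "0,0,0"]
        assert bed["name"].iloc[0] == "p1_HVC_up"

    def test_roundtrip_recovers_intervals(self, tmp_path):
        """Writing then parsing the BED track reproduces every interval,
        0-based half-open."""
        path = tmp_path / "track.bed"
        written = cu.export_bed(self._calls(), self._curated(), path)
        back = cu.read_bed(path)
        pd.testing.assert_frame_equal(
            back.astype(written.dtypes.to_dict()), written
        )
        assert list(back["start"]) == [100, 500, 900]
        assert list(back["end"]) == [160, 560, 960]

    def test_empty_calls_write_empty_track(self, tmp_path):
        path = tmp_path / "empty.bed"
        cu.export_bed(self._calls().iloc[:0], self._curated(), path)
        assert cu.read_bed(path).empty

    def test_probe_without_alignment_skipped(self, tmp_path):
        curated = self._curated()
        curated.loc[2, ["chrom", "start", "end"]] = [None, np.nan, np.nan]
        bed = cu.export_bed(self._calls(), curated, tmp_path / "t.bed")
        assert len(bed) == 2
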