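"""Significance-cutoff calibration against labeled validation genes.

Instead of a blind FDR threshold, the per-contrast p-value cutoff is chosen
from class-conditional p-value histograms: probe-level p-values for genes
independently labeled differential vs non-differential (e.g. by in-situ
hybridization imaging) are compared, and the cutoff maximizing the true-
minus-false positive rate (Youden's J) over the histogram bin edges is
selected.  Contrasts without labels fall back to a conventional p < 0.05.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CUTOFF",
    "CalibrationError",
    "CalibrationResult",
    "default_bin_edges",
    "collect_labeled_pvalues",
    "choose_cutoff",
    "default_cutoff",
    "plot_calibration",
]

DEFAULT_CUTOFF = 0.05


class CalibrationError(ValueError):
    """Raised when no usable labeled p-values exist; callers should fall
    back to :func:`default_cutoff`."""


def default_bin_edges() -> np.ndarray:
    """20 equal-width bins on [0,1] plus refined small-p edges so the
    region where calibrated cutoffs typically live is resolved."""
    edges = np.concatenate([np.linspace(0.0, 1.0, 21), [0.001, 0.005, 0.01, 0.02]])
    return np.unique(np.round(edges, 6))


@dataclass
class CalibrationResult:
    """A chosen per-contrast significance cutoff with its evidence."""

    contrast: str
    cutoff_p: float
    bin_edges: np.ndarray
    diff_hist: np.ndarray
    nondiff_hist: np.ndarray
    tpr_at_cutoff: float
    fpr_at_cutoff: float
    n_diff_probes: int
    n_nondiff_probes: int
    method: str = "calibrated"  # or "default"
    note: str = ""

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        for k in ("bin_edges", "diff_hist", "nondiff_hist"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("bin_edges", "diff_hist", "nondiff_hist"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def collect_labeled_pvalues(
    stats: pd.DataFrame,
    annotations: pd.DataFrame,
    labels: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Probe-level p-values for the labeled differential and
    non-differential gene classes.

    Every retained probe of a labeled gene contributes its own p-value (a
    gene with three probes contributes three entries).  Excluded labels are
    dropped.  Raises :class:`CalibrationError` when either class ends up
    empty, directing the caller to the default cutoff.
    """
    ann = annotations.loc[annotations["gene_id"].notna(), ["probe_id", "gene_id"]]
    merged = stats[["probe_id", "p"]].merge(ann, on="probe_id", how="inner")
    merged = merged.merge(labels, on="gene_id", how="inner")
    merged = merged[merged["label"] != "excluded"]
    diff_p = merged.loc[merged["label"] == "differential", "p"].to_numpy(dtype=float)
    nondiff_p = merged.loc[
        merged["label"] == "nondifferential", "p"
    ].to_numpy(dtype=float)
    if len(diff_p) == 0 or len(nondiff_p) == 0:
        raise CalibrationError(
            "no labeled p-values in one or both classes; use default_cutoff()"
        )
    return diff_p, nondiff_p


def choose_cutoff(
    diff_p: np.ndarray,
    nondiff_p: np.ndarray,
    bin_edges: np.ndarray | None = None,
    contrast: str = "",
    fpr_weight: float = 1.5,
) -> CalibrationResult:
    """Pick the cutoff maximizing TPR - fpr_weight * FPR over the
    cumulative bin edges.

    TPR is the fraction of differential-class probe p-values at or below
    the candidate cutoff, FPR the same for the non-differential class.
    The default weight 1.5 encodes that the cutoff is meant to be
    high-confidence: admitting a false marker costs more downstream
    validation effort than missing a true one, so the objective stops
    short of the point where the class densities merely cross.
    ``fpr_weight=1`` recovers the classical (unweighted) Youden index.
    Ties break toward the smaller (more conservative) cutoff; identical
    class distributions (max objective <= 0) degrade to the default
    cutoff with a warning.
    """
    diff_p = np.sort(np.asarray(diff_p, dtype=float))
    nondiff_p = np.sort(np.asarray(nondiff_p, dtype=float))
    if len(diff_p) == 0 or len(nondiff_p) == 0:
        raise CalibrationError("both p-value lists must be non-empty")
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, float)
    diff_hist = np.histogram(diff_p, bins=edges)[0] / len(diff_p)
    nondiff_hist = np.histogram(nondiff_p, bins=edges)[0] / len(nondiff_p)

    cands = edges[(edges > 0) & (edges <= 1)]
    tpr = np.searchsorted(diff_p, cands, side="right") / len(diff_p)
    fpr = np.searchsorted(nondiff_p, cands, side="right") / len(nondiff_p)
    j = tpr - fpr_weight * fpr
    best = int(np.argmax(j))  # first maximum = smallest cutoff on ties
    if j[best] <= 0:
        warnings.warn(
            "class-conditional p-value distributions are indistinguishable; "
            "falling back to the default cutoff"
        )
        return CalibrationResult(
            contrast=contrast,
            cutoff_p=DEFAULT_CUTOFF,
            bin_edges=edges,
            diff_hist=diff_hist,
            nondiff_hist=nondiff_hist,
            tpr_at_cutoff=float(np.mean(diff_p <= DEFAULT_CUTOFF)),
            fpr_at_cutoff=float(np.mean(nondiff_p <= DEFAULT_CUTOFF)),
            n_diff_probes=len(diff_p),
            n_nondiff_probes=len(nondiff_p),
            method="default",
            note="degenerate class distributions",
        )
    return CalibrationResult(
        contrast=contrast,
        cutoff_p=float(cands[best]),
        bin_edges=edges,
        diff_hist=diff_hist,
        nondiff_hist=nondiff_hist,
        tpr_at_cutoff=float(tpr[best]),
        fpr_at_cutoff=float(fpr[best]),
        n_diff_probes=len(diff_p),
        n_nondiff_probes=len(nondiff_p),
        method="calibrated",
    )


def default_cutoff(contrast: str = "", cutoff: float = DEFAULT_CUTOFF) -> CalibrationResult:
    """Conventional cutoff for contrasts without validation labels
    (p < 0.05 unless overridden)."""
    edges = default_bin_edges()
    nbins = len(edges) - 1
    return CalibrationResult(
        contrast=contrast,
        cutoff_p=float(cutoff),
        bin_edges=edges,
        diff_hist=np.zeros(nbins),
        nondiff_hist=np.zeros(nbins),
        tpr_at_cutoff=float("nan"),
        fpr_at_cutoff=float("nan"),
        n_diff_probes=0,
        n_nondiff_probes=0,
        method="default",
    )


def plot_calibration(result: CalibrationResult, path) -> None:
    """Overlaid class-conditional p-value histograms with the chosen cutoff
    as a dotted vertical line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = np.asarray(result.bin_edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, result.diff_hist, width=widths, alpha=0.6,
           label=f"differential (n={result.n_diff_probes})", color="#c23b22")
    ax.bar(centers, result.nondiff_hist, width=widths, alpha=0.6,
           label=f"non-differential (n={result.n_nondiff_probes})", color="#4477aa")
    ax.axvline(result.cutoff_p, ls=":", color="k",
               label=f"cutoff p = {result.cutoff_p:g}")
    ax.set_xlabel("p-value")
    ax.set_ylabel("proportion of probes")
    ax.set_title(result.contrast or "cutoff calibration")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
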