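"""Single-cell expression-noise statistics.

Per gene and condition: detection frequency, mean, sample sd, CV
(= sd / mean) and CV² over *detected* cells only — dropout is reported
separately as a frequency change (Fisher exact test) rather than folded
into the level statistics as zeros.  Condition contrasts use paired t
tests across the gene panel (on CV and, separately, on mean), and the
per-gene relative noise change is the CV gain

    (CV_alt − CV_ref) / CV_ref.

Input values are log2 expression; Ct-scale tables are converted upstream
(``log2 expression = LOD − Ct``).  Spike-in columns carry constant input
and are used only for cell-level QC, never entered into gene statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "GeneNoiseStats",
    "NoiseComparison",
    "qc_filter_cells",
    "gene_stats",
    "panel_stats",
    "cv_gain",
    "compare_noise",
    "frequency_change_test",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Cells × genes log2-expression with per-entry detection flags.

    ``values`` holds NaN where an entry is undetected; ``detected`` is the
    boolean mask.  ``cell_meta`` (indexed like the rows) carries at least a
    ``condition`` column and optionally ``culture``; ``gene_meta`` (indexed
    like the columns) carries boolean ``is_spikein`` and optionally
    ``is_h3k9ac_target``.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detected.index) or not self.values.columns.equals(
            self.detected.columns
        ):
            raise ValueError("values and detected must share index and columns")
        if not self.values.index.equals(self.cell_meta.index):
            raise ValueError("cell_meta index must match cell rows")
        if not self.values.columns.equals(self.gene_meta.index):
            raise ValueError("gene_meta index must match gene columns")
        if "condition" not in self.cell_meta.columns:
            raise ValueError("cell_meta requires a 'condition' column")
        if "is_spikein" not in self.gene_meta.columns:
            raise ValueError("gene_meta requires an 'is_spikein' column")
        det = self.detected.to_numpy()
        vals = self.values.to_numpy()
        if np.any(~np.isfinite(vals[det])):
            raise ValueError("detected entries must carry finite values")

    @property
    def genes(self) -> pd.Index:
        """Panel genes (spike-ins excluded)."""
        return self.gene_meta.index[~self.gene_meta["is_spikein"]]

    @property
    def spikeins(self) -> pd.Index:
        return self.gene_meta.index[self.gene_meta["is_spikein"]]

    @property
    def conditions(self) -> list[str]:
        return sorted(self.cell_meta["condition"].unique())

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        mask = self.cell_meta["condition"] == condition
        if not mask.any():
            raise ValueError(f"condition {condition!r} not present")
        return ExpressionMatrix(
            values=self.values.loc[mask],
            detected=self.detected.loc[mask],
            cell_meta=self.cell_meta.loc[mask],
            gene_meta=self.gene_meta,
        )


def qc_filter_cells(matrix: ExpressionMatrix, mad_threshold: float = 3.0) -> ExpressionMatrix:
    """Drop cells whose spike-in signal marks them as technical outliers.

    A cell is removed when its mean spike-in value deviates from the cohort
    median by more than ``mad_threshold`` robust (MAD-scaled) deviations, or
    when any spike-in is undetected.  The removed count is logged.
    """
    spikes = matrix.spikeins
    if len(spikes) == 0:
        raise ValueError("spike-in QC requested but the matrix has no spike-in columns")
    spike_vals = matrix.values[spikes]
    all_detected = matrix.detected[spikes].all(axis=1)
    cell_mean = spike_vals.mean(axis=1)
    med = cell_mean.median()
    mad = stats.median_abs_deviation(cell_mean.dropna(), scale="normal")
    if mad == 0:
        within = cell_mean == med
    else:
        within = (cell_mean - med).abs() <= mad_threshold * mad
    keep = all_detected & within
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("spike-in QC removed %d of %d cells", n_removed, len(keep))
    return ExpressionMatrix(
        values=matrix.values.loc[keep],
        detected=matrix.detected.loc[keep],
        cell_meta=matrix.cell_meta.loc[keep],
        gene_meta=matrix.gene_meta,
    )


@dataclass
class GeneNoiseStats:
    """Detection frequency and level-noise statistics for one gene in one
    condition; CV uses the sample (n−1) sd over detected cells and is
    flagged undefined below ``min_detected`` or at nonpositive mean."""

    gene: str
    condition: str
    n_cells: int
    n_detected: int
    frequency: float
    mean: float
    sd: float
    cv: float
    cv2: float
    cv_defined: bool


def gene_stats(
    matrix: ExpressionMatrix, gene: str, condition: str, min_detected: int = 5
) -> GeneNoiseStats:
    """Noise statistics for ``gene`` within ``condition``."""
    if gene not in matrix.values.columns:
        raise KeyError(f"unknown gene {gene!r}")
    sub = matrix.subset_condition(condition)
    det = sub.detected[gene].to_numpy()
    vals = sub.values[gene].to_numpy()[det]
    n_cells = len(det)
    n_det = int(det.sum())
    freq = n_det / n_cells
    if n_det == 0:
        return GeneNoiseStats(gene, condition, n_cells, 0, 0.0,
                              np.nan, np.nan, np.nan, np.nan, False)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n_det > 1 else np.nan
    defined = n_det >= min_detected and mean > 0 and np.isfinite(sd)
    cv = sd / mean if defined else np.nan
    return GeneNoiseStats(
        gene=gene,
        condition=condition,
        n_cells=n_cells,
        n_detected=n_det,
        frequency=freq,
        mean=mean,
        sd=sd,
        cv=cv,
        cv2=cv**2 if defined else np.nan,
        cv_defined=bool(defined),
    )


def panel_stats(matrix: ExpressionMatrix, condition: str, min_detected: int = 5) -> pd.DataFrame:
    """:func:`gene_stats` for every panel gene, as a gene-indexed table."""
    rows = [gene_stats(matrix, g, condition, min_detected) for g in matrix.genes]
    return pd.DataFrame([vars(r) for r in rows]).set_index("gene")


def cv_gain(cv_ref: float, cv_alt: float) -> float:
    """Relative CV change (cv_alt − cv_ref) / cv_ref; NaN when the reference
    CV is nonpositive or undefined."""
    if not np.isfinite(cv_ref) or cv_ref <= 0 or not np.isfinite(cv_alt):
        return float("nan")
    return (cv_alt - cv_ref) / cv_ref


@dataclass
class NoiseComparison:
    """Panel-level noise contrast between a reference and an alternative
    condition: per-gene table plus paired t tests across genes."""

    condition_ref: str
    condition_alt: str
    per_gene: pd.DataFrame = field(repr=False)
    cv_t: float = np.nan
    cv_p: float = np.nan
    mean_t: float = np.nan
    mean_p: float = np.nan
    n_genes_used: int = 0
    n_genes_excluded: int = 0

    def gains(self) -> pd.Series:
        """Per-gene CV gain, defined genes only."""
        return self.per_gene["cv_gain"].dropna()


def compare_noise(
    matrix: ExpressionMatrix,
    condition_ref: str,
    condition_alt: str,
    min_detected: int = 5,
) -> NoiseComparison:
    """Panel-wide comparison of noise between two conditions.

    Genes with a defined CV in both conditions enter the paired two-sided t
    tests (on CV and on mean); the rest are excluded and counted.  Each gene
    also gets a detection-frequency Fisher exact test, BH-adjusted across
    the panel.
    """
    stats_ref = panel_stats(matrix, condition_ref, min_detected)
    stats_alt = panel_stats(matrix, condition_alt, min_detected)

    per_gene = pd.DataFrame(
        {
            "freq_ref": stats_ref["frequency"],
            "freq_alt": stats_alt["frequency"],
            "mean_ref": stats_ref["mean"],
            "mean_alt": stats_alt["mean"],
            "cv_ref": stats_ref["cv"],
            "cv_alt": stats_alt["cv"],
        }
    )
    per_gene["cv_gain"] = [
        cv_gain(r, a) for r, a in zip(per_gene["cv_ref"], per_gene["cv_alt"])
    ]
    fisher = [
        frequency_change_test(matrix, g, condition_ref, condition_alt)[1]
        for g in per_gene.index
    ]
    per_gene["fisher_p"] = fisher
    per_gene["fisher_q"] = multipletests(per_gene["fisher_p"], method="fdr_bh")[1]

    usable = stats_ref["cv_defined"] & stats_alt["cv_defined"]
    per_gene["used_in_cv_test"] = usable
    n_used = int(usable.sum())
    if n_used < 2:
        raise ValueError(
            f"need at least 2 genes with defined CV in both conditions, got {n_used}"
        )
    cv_t, cv_p = stats.ttest_rel(per_gene.loc[usable, "cv_ref"], per_gene.loc[usable, "cv_alt"])
    mean_t, mean_p = stats.ttest_rel(
        per_gene.loc[usable, "mean_ref"], per_gene.loc[usable, "mean_alt"]
    )
    return NoiseComparison(
        condition_ref=condition_ref,
        condition_alt=condition_alt,
        per_gene=per_gene,
        cv_t=float(cv_t),
        cv_p=float(cv_p),
        mean_t=float(mean_t),
        mean_p=float(mean_p),
        n_genes_used=n_used,
        n_genes_excluded=int(len(per_gene) - n_used),
    )


def frequency_change_test(
    matrix: ExpressionMatrix, gene: str, condition_a: str, condition_b: str
) -> tuple[np.ndarray, float]:
    """Two-sided Fisher exact test on the detected/undetected × condition
    2×2 table for one gene; returns (table, p)."""
    if gene not in matrix.values.columns:
        raise KeyError(f"unknown gene {gene!r}")
    table = []
    for cond in (condition_a, condition_b):
        det = matrix.subset_condition(cond).detected[gene]
        if len(det) == 0:
            raise ValueError(f"no cells in condition {cond!r}")
        table.append([int(det.sum()), int((~det).sum())])
    table = np.array(table)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)
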