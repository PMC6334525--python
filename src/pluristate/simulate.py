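"""Synthetic flow-cytometry and single-cell expression data with known truth.

Two generators mirror the two assay arms of a reporter wash-off study:

* **Flow arm** — state fractions evolve in time under known four-rate
  kinetics (:func:`simulate_state_trajectory`, the same propagator the
  fitting side uses); per-cell log10 fluorescence is then drawn from a
  three-component Gaussian mixture whose weights are those fractions
  (:func:`sample_flow_readings`).  :func:`make_washoff_dataset` assembles
  a full condition × duration × day × replicate panel; replicate noise is
  the natural binomial sampling of finite cell counts.

* **Expression arm** — dropout-bearing cells × genes log2-expression with
  planted rank correlations (Gaussian copula on the latent values, thinned
  by independent per-entry dropout), condition-specific CV inflation at
  unchanged means, and constant-input spike-ins with a small technical sd.

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParams, ProportionSeries, predict_proportions
from .mixture import FlowSample
from .noise import ExpressionMatrix

__all__ = [
    "MixtureTruth",
    "ConditionTruth",
    "GenePanelTruth",
    "SimulationConfig",
    "simulate_state_trajectory",
    "sample_flow_readings",
    "simulate_expression_matrix",
    "make_washoff_dataset",
    "concat_conditions",
    "default_panel",
]

#: Technical sd of spike-in readings, log2 units.  Plausible plate-scale
#: qPCR technical floor; configurable per panel.
DEFAULT_SPIKEIN_SD = 0.25


@dataclass
class MixtureTruth:
    """True 3-component log10-fluorescence mixture, means ordered LN<MN<HN."""

    means: tuple[float, float, float] = (1.0, 3.0, 5.0)
    sds: tuple[float, float, float] = (0.4, 0.4, 0.4)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("mixture means must be strictly increasing LN < MN < HN")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError("mixture sds must be positive")


@dataclass
class ConditionTruth:
    """Ground-truth kinetics for one experimental condition."""

    label: str
    params: KineticParams
    p0: tuple[float, float, float]  # (HN, MN, LN)
    duration_days: float = 1.0

    def __post_init__(self) -> None:
        p0 = np.asarray(self.p0, dtype=float)
        if abs(p0.sum() - 1.0) > 1e-9 or np.any(p0 < 0):
            raise ValueError("initial proportions must be nonnegative and sum to 1 within 1e-9")


@dataclass
class GenePanelTruth:
    """Per-gene generative truth for the single-cell expression arm.

    ``genes`` is indexed by gene name with columns ``mean`` and ``sd``
    (log2 scale) and one ``p_detect_<condition>`` column per condition.
    ``planted_correlations`` lists (gene_a, gene_b, spearman_rho) triples
    realized through a Gaussian copula on the latent values.
    ``cv_inflation`` multiplies the latent sd per condition, leaving means
    unchanged, so a gene's CV scales by the same factor.
    """

    genes: pd.DataFrame
    planted_correlations: list[tuple[str, str, float]] = field(default_factory=list)
    cv_inflation: dict[str, float] = field(default_factory=dict)
    n_spikeins: int = 3
    spikein_level: float = 12.0
    spikein_sd: float = DEFAULT_SPIKEIN_SD
    h3k9ac_targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for a, b, rho in self.planted_correlations:
            if a == b:
                raise ValueError("planted correlations must join distinct genes")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"planted correlation must lie in (-1, 1), got {rho}")
            for g in (a, b):
                if g not in self.genes.index:
                    raise ValueError(f"planted correlation references unknown gene {g!r}")
        det_cols = [c for c in self.genes.columns if c.startswith("p_detect_")]
        if not det_cols:
            raise ValueError("genes table needs at least one p_detect_<condition> column")
        for c in det_cols:
            p = self.genes[c]
            if np.any((p < 0) | (p > 1)):
                raise ValueError("detection probabilities must lie in [0, 1]")

    def detection_probs(self, condition: str) -> pd.Series:
        col = f"p_detect_{condition}"
        if col not in self.genes.columns:
            raise KeyError(f"no detection probabilities for condition {condition!r}")
        return self.genes[col]


@dataclass
class SimulationConfig:
    """Full wash-off study design: conditions with true kinetics, the true
    fluorescence mixture, timepoints, replication and per-sample depth."""

    seed: int = 17
    n_cells_per_sample: int = 10_000
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    n_replicates: int = 4
    conditions: list[ConditionTruth] = field(default_factory=list)
    mixture_truth: MixtureTruth = field(default_factory=MixtureTruth)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.timepoints) < 0):
            raise ValueError("timepoints must be sorted ascending")
        if np.any(np.asarray(self.timepoints) < 0):
            raise ValueError("timepoints must be nonnegative days")


def simulate_state_trajectory(params: KineticParams, p0, times) -> ProportionSeries:
    """Ground-truth state fractions over time: the exact propagator of
    dp/dt = Q p.  Shared kernel with the model side
    (:func:`pluristate.kinetics.predict_proportions`) by construction."""
    return predict_proportions(params, p0, times, condition="truth")


def sample_flow_readings(
    mixture_truth: MixtureTruth,
    proportions,
    n: int,
    seed: int,
    condition: str = "sim",
    duration_days: float = 1.0,
    day: float = 0.0,
    replicate: str | int = 0,
) -> FlowSample:
    """Draw n per-cell linear-scale fluorescence readings from the
    3-component log10 mixture with component weights = (HN, MN, LN)
    proportions mapped onto the (LN, MN, HN)-ordered components."""
    p = np.asarray(proportions, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be a nonnegative 3-vector summing to 1")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    # proportions arrive in (HN, MN, LN) order; components are LN, MN, HN
    weights = p[::-1]
    comp = rng.choice(3, size=n, p=weights)
    logs = rng.normal(np.asarray(mixture_truth.means)[comp], np.asarray(mixture_truth.sds)[comp])
    return FlowSample(
        condition=condition,
        duration_days=duration_days,
        day=day,
        replicate=replicate,
        intensities=10.0**logs,
    )


def make_washoff_dataset(config: SimulationConfig) -> dict[tuple, FlowSample]:
    """Simulate the full wash-off panel.

    For each condition and replicate, the true trajectory feeds per-day
    mixture draws of ``n_cells_per_sample`` cells; keys are
    (condition, duration_days, day, replicate).  Replicate-to-replicate
    scatter arises solely from the finite-n sampling.
    """
    if not config.conditions:
        raise ValueError("config must define at least one condition")
    rng = np.random.default_rng(config.seed)
    out: dict[tuple, FlowSample] = {}
    for cond in config.conditions:
        traj = simulate_state_trajectory(cond.params, cond.p0, config.timepoints)
        for rep in range(config.n_replicates):
            for t_idx, day in enumerate(config.timepoints):
                sample = sample_flow_readings(
                    config.mixture_truth,
                    traj.proportions[t_idx],
                    config.n_cells_per_sample,
                    seed=int(rng.integers(2**31 - 1)),
                    condition=cond.label,
                    duration_days=cond.duration_days,
                    day=float(day),
                    replicate=rep,
                )
                out[sample.key] = sample
    return out


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation realizing a target Spearman rho under a
    Gaussian copula: r = 2 sin(pi * rho_s / 6)."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _latent_correlation(panel: GenePanelTruth) -> np.ndarray:
    genes = list(panel.genes.index)
    idx = {g: i for i, g in enumerate(genes)}
    r = np.eye(len(genes))
    for a, b, rho_s in panel.planted_correlations:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = _spearman_to_pearson(rho_s)
    # repair indefiniteness from conflicting plants by eigenvalue clipping
    w, v = np.linalg.eigh(r)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        r = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


def simulate_expression_matrix(
    panel: GenePanelTruth,
    n_cells: int,
    condition: str,
    seed: int,
    culture: str = "2i",
) -> ExpressionMatrix:
    """Cells × genes log2-expression for one condition.

    Latent values follow a Gaussian copula with the planted rank
    correlations; per-gene sd is scaled by the condition's ``cv_inflation``
    factor (default 1.0) at unchanged mean.  Each entry is then observed
    with the gene × condition detection probability; spike-ins are always
    detected at constant mean with technical sd ``panel.spikein_sd``.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be at least 2")
    rng = np.random.default_rng(seed)
    genes = list(panel.genes.index)
    corr = _latent_correlation(panel)
    z = rng.multivariate_normal(np.zeros(len(genes)), corr, size=n_cells, method="cholesky")
    inflation = panel.cv_inflation.get(condition, 1.0)
    mu = panel.genes["mean"].to_numpy()
    sd = panel.genes["sd"].to_numpy() * inflation
    vals = mu + sd * z

    p_det = panel.detection_probs(condition).to_numpy()
    detected = rng.random((n_cells, len(genes))) < p_det
    vals = np.where(detected, vals, np.nan)

    spike_names = [f"spike_{i+1}" for i in range(panel.n_spikeins)]
    spikes = rng.normal(panel.spikein_level, panel.spikein_sd, size=(n_cells, panel.n_spikeins))

    cells = [f"{condition}_cell_{i+1}" for i in range(n_cells)]
    values = pd.DataFrame(
        np.hstack([vals, spikes]), index=cells, columns=genes + spike_names
    )
    det_df = pd.DataFrame(
        np.hstack([detected, np.ones((n_cells, panel.n_spikeins), dtype=bool)]),
        index=cells,
        columns=genes + spike_names,
    )
    cell_meta = pd.DataFrame({"condition": condition, "culture": culture}, index=cells)
    gene_meta = pd.DataFrame(
        {
            "is_spikein": [False] * len(genes) + [True] * len(spike_names),
            "is_h3k9ac_target": [g in panel.h3k9ac_targets for g in genes]
            + [False] * len(spike_names),
        },
        index=genes + spike_names,
    )
    return ExpressionMatrix(values=values, detected=det_df, cell_meta=cell_meta, gene_meta=gene_meta)


def default_panel(
    n_genes: int = 40,
    conditions: tuple[str, str] = ("DMSO", "MB3"),
    p_detect: float = 0.85,
    cv_inflation_alt: float = 1.3,
    planted: list[tuple[str, str, float]] | None = None,
    n_targets: int = 10,
    seed: int = 17,
) -> GenePanelTruth:
    """A study-scale gene panel: log2 means spread over a qPCR-typical
    range, per-gene sds giving CVs near 0.3–0.5, a shared detection
    probability, and CV inflation at unchanged means in the second
    (treatment) condition.  The first ``n_targets`` genes are flagged as
    acetylation targets."""
    rng = np.random.default_rng(seed)
    names = [f"g{i+1:02d}" for i in range(n_genes)]
    means = rng.uniform(4.0, 10.0, n_genes)
    sds = means * rng.uniform(0.3, 0.5, n_genes)
    genes = pd.DataFrame({"mean": means, "sd": sds}, index=names)
    ref, alt = conditions
    genes[f"p_detect_{ref}"] = p_detect
    genes[f"p_detect_{alt}"] = p_detect
    return GenePanelTruth(
        genes=genes,
        planted_correlations=planted or [],
        cv_inflation={ref: 1.0, alt: cv_inflation_alt},
        h3k9ac_targets=set(names[:n_targets]),
    )


def concat_conditions(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Stack per-condition matrices sharing one gene panel."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    gm = matrices[0].gene_meta
    for m in matrices[1:]:
        if not m.gene_meta.index.equals(gm.index):
            raise ValueError("matrices must share the same gene panel")
    return ExpressionMatrix(
        values=pd.concat([m.values for m in matrices]),
        detected=pd.concat([m.detected for m in matrices]),
        cell_meta=pd.concat([m.cell_meta for m in matrices]),
        gene_meta=gm,
    )
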