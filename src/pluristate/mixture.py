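"""Virtual-ensemble mixture gating of reporter fluorescence.

A single Gaussian mixture is fit to a pooled ("virtual ensemble")
log10-fluorescence sample drawn evenly across all conditions and
timepoints, and then frozen: every cell in every sample is soft-assigned
a posterior over the LN/MN/HN components of that one shared model.  This
makes state proportions comparable across conditions and days, which a
per-sample refit would not guarantee.

Components are always relabeled by ascending mean, so LN < MN < HN on the
log scale regardless of EM initialization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .kinetics import ProportionSeries

__all__ = [
    "FlowSample",
    "MixtureModel",
    "StateAssignment",
    "pool_virtual_ensemble",
    "fit_mixture",
    "bic_scan",
    "assign_states",
    "state_proportions",
]

logger = logging.getLogger(__name__)


@dataclass
class FlowSample:
    """Per-cell fluorescence readings for one (condition, duration, day,
    replicate) sample, on the linear instrument scale."""

    condition: str
    duration_days: float
    day: float
    replicate: str | int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size < 1:
            raise ValueError("FlowSample requires at least one cell")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def key(self) -> tuple:
        return (self.condition, self.duration_days, self.day, self.replicate)

    def log10_intensities(self) -> np.ndarray:
        """Log10 values; nonpositive readings (instrument artifacts) are
        dropped with a logged count before the transform."""
        pos = self.intensities > 0
        n_dropped = int((~pos).sum())
        if n_dropped:
            logger.info("dropped %d nonpositive intensities from sample %s", n_dropped, self.key)
        return np.log10(self.intensities[pos])


@dataclass
class MixtureModel:
    """A fitted 1-D Gaussian mixture on log10 fluorescence.

    With k=3 the components, ordered by ascending mean, are the LN, MN and
    HN reporter states.  ``weights``, ``means`` and ``sds`` are length-k
    arrays sorted by mean.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n_fit: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1 within 1e-9")
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("component means must be strictly increasing")
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def state_labels(self) -> tuple[str, ...]:
        """Component labels in ascending-mean order (LN, MN, HN for k=3)."""
        if self.k == 3:
            return ("LN", "MN", "HN")
        return tuple(f"c{i}" for i in range(self.k))


@dataclass
class StateAssignment:
    """Per-cell posterior probabilities over (LN, MN, HN) and the argmax
    hard state; ties in the argmax are broken toward MN."""

    posteriors: np.ndarray  # (n, 3) columns in (LN, MN, HN) order
    hard_state: np.ndarray  # array of labels from STATES

    def proportions_hnmnln(self, mode: str = "soft") -> np.ndarray:
        """Overall state fractions in the package-wide (HN, MN, LN) order."""
        if mode == "soft":
            p = self.posteriors.mean(axis=0)
        elif mode == "hard":
            p = np.array([(self.hard_state == lab).mean() for lab in ("LN", "MN", "HN")])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return p[::-1]


def pool_virtual_ensemble(samples, per_sample_n: int, seed: int = 17) -> np.ndarray:
    """Concatenate ``per_sample_n`` random draws (without replacement) from
    every sample, log10-transformed — the composite distribution the shared
    mixture is fit on.  Samples smaller than ``per_sample_n`` contribute all
    their cells, with a warning.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("pool_virtual_ensemble requires at least one sample")
    rng = np.random.default_rng(seed)
    parts = []
    for s in samples:
        logs = s.log10_intensities()
        if len(logs) <= per_sample_n:
            if len(logs) < per_sample_n:
                warnings.warn(
                    f"sample {s.key} has {len(logs)} cells < per_sample_n={per_sample_n}; using all",
                    RuntimeWarning,
                    stacklevel=2,
                )
            parts.append(logs)
        else:
            parts.append(rng.choice(logs, size=per_sample_n, replace=False))
    return np.concatenate(parts)


def fit_mixture(
    pooled: np.ndarray,
    k: int = 3,
    seed: int = 17,
    n_init: int = 10,
    sd_floor: float = 1e-3,
) -> MixtureModel:
    """EM fit of a k-component Gaussian mixture to pooled log10 values.

    k-means initialization with ``n_init`` restarts; component sds floored
    at ``sd_floor`` through the covariance regularizer; components relabeled
    by ascending mean.  Reports log-likelihood and BIC.
    """
    pooled = np.asarray(pooled, dtype=float).ravel()
    if len(pooled) < 10 * k:
        raise ValueError(f"need at least {10 * k} points to fit k={k} components")
    if not np.all(np.isfinite(pooled)):
        raise ValueError("pooled values must be finite")
    if np.std(pooled) < sd_floor:
        raise ValueError("degenerate pooled data: essentially zero variance")

    x = pooled.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        init_params="kmeans",
        reg_covar=sd_floor**2,
        random_state=seed,
        max_iter=500,
    ).fit(x)

    order = np.argsort(gm.means_.ravel())
    sds = np.sqrt(gm.covariances_.ravel()[order])
    means = gm.means_.ravel()[order]
    if np.any(np.diff(means) <= 0):
        raise ValueError(
            "EM collapsed two components onto the same mean; "
            "the data do not support k distinct modes"
        )
    return MixtureModel(
        weights=gm.weights_[order],
        means=means,
        sds=np.maximum(sds, sd_floor),
        loglik=float(gm.score(x) * len(x)),
        bic=float(gm.bic(x)),
        n_fit=len(x),
    )


def bic_scan(pooled: np.ndarray, k_range=range(1, 6), seed: int = 17) -> dict[int, float]:
    """BIC for each candidate component count; the argmin selects k."""
    return {k: fit_mixture(pooled, k=k, seed=seed).bic for k in k_range}


def assign_states(model: MixtureModel, values: np.ndarray) -> StateAssignment:
    """Posterior state probabilities for log10 values, by Bayes' rule from
    the frozen mixture's component densities and weights."""
    values = np.asarray(values, dtype=float).ravel()
    if model.k != 3:
        raise ValueError("state assignment requires a 3-component model")
    # log-space Bayes rule: stable arbitrarily far into the tails
    logdens = np.log(model.weights) + norm.logpdf(values[:, None], model.means, model.sds)
    logdens -= logdens.max(axis=1, keepdims=True)
    dens = np.exp(logdens)
    post = dens / dens.sum(axis=1, keepdims=True)
    # argmax with ties broken toward MN: scan columns in MN, HN, LN order
    pref = np.array([1, 2, 0])  # indices into (LN, MN, HN)
    hard_idx = pref[np.argmax(post[:, pref], axis=1)]
    hard = np.array(["LN", "MN", "HN"])[hard_idx]
    return StateAssignment(posteriors=post, hard_state=hard)


def state_proportions(
    model: MixtureModel,
    samples,
    mode: str = "soft",
) -> dict[tuple, ProportionSeries]:
    """Per-sample state fractions under the frozen mixture, grouped into
    time courses keyed by (condition, duration, replicate).

    ``mode="soft"`` (default) averages posterior responsibilities per state;
    ``mode="hard"`` counts argmax assignments.  Rows are in the package-wide
    (HN, MN, LN) order of :data:`~pluristate.kinetics.STATES`.
    """
    groups: dict[tuple, list] = {}
    for s in samples:
        logs = s.log10_intensities()
        if logs.size == 0:
            warnings.warn(f"sample {s.key} empty after dropping nonpositive values; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        asg = assign_states(model, logs)
        p = asg.proportions_hnmnln(mode=mode)
        groups.setdefault((s.condition, s.duration_days, s.replicate), []).append(
            (s.day, p, logs.size)
        )
    out = {}
    for key, rows in groups.items():
        rows.sort(key=lambda r: r[0])
        times = np.array([r[0] for r in rows])
        props = np.vstack([r[1] for r in rows])
        ncells = np.array([r[2] for r in rows])
        out[key] = ProportionSeries(
            condition=key[0], times=times, proportions=props, replicate=key[2], n_cells=ncells
        )
    return out
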