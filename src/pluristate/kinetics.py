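"""Three-state transition kinetics for a trimodal pluripotency reporter.

Cells occupy one of three reporter states — HN (high), MN (mid), LN (low) —
and switch along the chain HN <-> MN <-> LN with four first-order rates:

    A1: HN -> MN    (exit from pluripotency)
    A2: MN -> HN    (return to pluripotency)
    A3: MN -> LN    (commitment / differentiation)
    A4: LN -> MN    (reversal of commitment)

There is no direct HN <-> LN transition.  The population composition
``p = (p_HN, p_MN, p_LN)`` evolves under the linear system ``dp/dt = Q p``
with the generator ``Q`` built by :func:`rate_matrix`; the exact propagator
is the matrix exponential ``expm(Q t)``.  Rates are per day.

The reversibility index ``(A2 + A4) / (A1 + A3)`` summarizes whether the
reverse (toward pluripotency) or the forward (toward commitment) flux
dominates: > 1 favors return to the high-reporter state, < 1 favors
irreversible commitment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "STATES",
    "KineticParams",
    "KineticFit",
    "ProportionSeries",
    "rate_matrix",
    "predict_proportions",
    "fit_kinetics",
    "reversibility_index",
    "compare_conditions",
]

#: Fixed state order used for every proportion vector / matrix in the package.
STATES = ("HN", "MN", "LN")


@dataclass(frozen=True)
class KineticParams:
    """The four transition rates, in events per day.

    Attributes
    ----------
    a1, a2, a3, a4
        HN->MN, MN->HN, MN->LN and LN->MN rates respectively.  All must be
        nonnegative; there is no direct HN<->LN rate in the model.
    """

    a1: float
    a2: float
    a3: float
    a4: float

    def __post_init__(self) -> None:
        rates = self.as_array()
        if not np.all(np.isfinite(rates)):
            raise ValueError("kinetic rates must be finite")
        if np.any(rates < 0):
            raise ValueError(f"kinetic rates must be nonnegative, got {tuple(rates)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.a4], dtype=float)


@dataclass
class ProportionSeries:
    """State-fraction time course for one condition/replicate.

    ``proportions`` is a (T, 3) matrix in the fixed (HN, MN, LN) order of
    :data:`STATES`; each row sums to 1.
    """

    condition: str
    times: np.ndarray
    proportions: np.ndarray
    replicate: str | int = 0
    n_cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2 or self.proportions.shape[1] != 3:
            raise ValueError("proportions must be a (T, 3) matrix in (HN, MN, LN) order")
        if len(self.times) != len(self.proportions):
            raise ValueError("times and proportions length mismatch")
        _validate_proportion_rows(self.proportions)


def _validate_proportion_rows(p: np.ndarray, atol: float = 1e-6) -> None:
    if np.any(p < -atol) or np.any(p > 1 + atol):
        raise ValueError("proportions must lie in [0, 1]")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > atol):
        raise ValueError("each proportions row must sum to 1")


def _validate_p0(p0) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (3,):
        raise ValueError("p0 must be a 3-vector (HN, MN, LN)")
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 entries must be nonnegative and sum to 1 within 1e-9")
    return p0


def rate_matrix(params: KineticParams) -> np.ndarray:
    """Generator matrix Q of the HN<->MN<->LN chain, column convention.

    Off-diagonals carry the four rates on the HN-MN and MN-LN links (HN-LN
    entries are zero); diagonals make every column sum to zero, so total
    mass is conserved under dp/dt = Q p.
    """
    a1, a2, a3, a4 = params.as_array()
    return np.array(
        [
            [-a1, a2, 0.0],
            [a1, -(a2 + a3), a4],
            [0.0, a3, -a4],
        ]
    )


def predict_proportions(
    params: KineticParams,
    p0,
    times,
    condition: str = "model",
    replicate: str | int = 0,
) -> ProportionSeries:
    """Exact state fractions at ``times`` from ``p0`` under ``params``.

    Uses the matrix-exponential propagator of the linear system; the result
    is exact up to floating point, independent of timepoint spacing.
    """
    p0 = _validate_p0(p0)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    q = rate_matrix(params)
    out = np.empty((len(times), 3))
    for i, t in enumerate(times):
        out[i] = expm(q * t) @ p0
    # clip tiny negative round-off and renormalize
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return ProportionSeries(condition=condition, times=times, proportions=out, replicate=replicate)


def reversibility_index(params: KineticParams) -> float:
    """(A2 + A4) / (A1 + A3): reverse over forward total flux.

    Scale-invariant under multiplying all four rates by a positive constant.
    Returns ``inf`` with a warning when the forward rates are both zero.
    """
    forward = params.a1 + params.a3
    reverse = params.a2 + params.a4
    if forward == 0:
        warnings.warn("reversibility index undefined: A1 + A3 = 0", RuntimeWarning, stacklevel=2)
        return float("inf")
    return reverse / forward


@dataclass
class KineticFit:
    """Result of fitting the four-rate model to proportion time courses."""

    params: KineticParams
    p0: np.ndarray
    residual_ss: float
    n_obs: int
    converged: bool
    n_starts: int
    bootstrap_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    degenerate_rates: tuple[str, ...] = ()

    @property
    def reversibility(self) -> float:
        return reversibility_index(self.params)


def _residuals(x: np.ndarray, series_list, p0_fixed) -> np.ndarray:
    params = KineticParams(*np.maximum(x[:4], 0.0))
    p0 = p0_fixed if p0_fixed is not None else _normalize_free_p0(x[4:])
    res = []
    for s in series_list:
        pred = predict_proportions(params, p0, s.times)
        res.append((s.proportions - pred.proportions).ravel())
    return np.concatenate(res)


def _normalize_free_p0(raw: np.ndarray) -> np.ndarray:
    v = np.abs(raw) + 1e-12
    return v / v.sum()


def _single_fit(x0, series_list, p0_fixed, bounds):
    return least_squares(
        _residuals,
        x0,
        args=(series_list, p0_fixed),
        bounds=bounds,
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )


def fit_kinetics(
    series,
    p0_mode: str = "measured",
    n_starts: int = 25,
    n_boot: int = 200,
    seed: int = 17,
    rate_upper: float = 3.0,
) -> KineticFit:
    """Fit the four rates to one or more replicate proportion time courses.

    Nonnegatively-constrained least squares on the summed squared deviation
    between observed and predicted state fractions over all replicates,
    timepoints and states.  Multi-start (Latin hypercube over
    ``[0, rate_upper]^4``, fixed ``seed``); the best residual wins, ties
    broken by the smallest parameter-vector norm.

    Parameters
    ----------
    series
        One :class:`ProportionSeries` or an iterable of replicate series.
    p0_mode
        ``"measured"`` (default) fixes the initial composition to the
        replicate-averaged earliest-time observation; ``"free"``
        co-estimates it.
    n_boot
        Number of case-resampling bootstrap draws over replicates for the
        95% rate intervals; 0 disables the bootstrap.  Bootstrap refits
        start from the point estimate.
    """
    if isinstance(series, ProportionSeries):
        series_list = [series]
    else:
        series_list = list(series)
    if not series_list:
        raise ValueError("no proportion series supplied")
    for s in series_list:
        if len(s.times) < 2:
            raise ValueError("fit_kinetics requires at least 2 timepoints per series")
    if p0_mode not in ("measured", "free"):
        raise ValueError(f"unknown p0_mode {p0_mode!r}")

    if p0_mode == "measured":
        day0 = np.mean([s.proportions[0] for s in series_list], axis=0)
        p0_fixed = day0 / day0.sum()
        lower = np.zeros(4)
        upper = np.full(4, np.inf)
    else:
        p0_fixed = None
        lower = np.zeros(7)
        upper = np.concatenate([np.full(4, np.inf), np.ones(3)])

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=4, seed=rng.integers(2**31 - 1))
    # deterministic all-zero start keeps degenerate (no-flux) optima reachable
    starts = np.vstack([np.zeros(4), sampler.random(n=max(n_starts - 1, 1)) * rate_upper])

    tie_tol = 1e-10  # near-equal residuals: prefer the smaller rate vector
    best = None
    for x0_rates in starts:
        if p0_fixed is None:
            mean0 = np.mean([s.proportions[0] for s in series_list], axis=0)
            x0 = np.concatenate([x0_rates, mean0 / mean0.sum()])
        else:
            x0 = x0_rates
        sol = _single_fit(x0, series_list, p0_fixed, (lower, upper))
        if best is None or sol.cost < best.cost - tie_tol or (
            abs(sol.cost - best.cost) <= tie_tol
            and np.linalg.norm(sol.x[:4]) < np.linalg.norm(best.x[:4])
        ):
            best = sol

    params = KineticParams(*best.x[:4])
    p0_hat = p0_fixed if p0_fixed is not None else _normalize_free_p0(best.x[4:])
    n_obs = sum(s.proportions.size for s in series_list)
    residual_ss = float(2.0 * best.cost)

    degenerate = _flag_degenerate(series_list, p0_hat)
    if degenerate:
        warnings.warn(
            "rates unidentifiable from the observed trajectories: " + ", ".join(degenerate),
            RuntimeWarning,
            stacklevel=2,
        )

    intervals: dict[str, tuple[float, float]] = {}
    if n_boot > 0 and len(series_list) >= 2:
        boot = np.empty((n_boot, 4))
        for b in range(n_boot):
            idx = rng.integers(0, len(series_list), size=len(series_list))
            resampled = [series_list[i] for i in idx]
            if p0_fixed is not None:
                day0 = np.mean([s.proportions[0] for s in resampled], axis=0)
                pf = day0 / day0.sum()
            else:
                pf = None
            sol = _single_fit(best.x, resampled, pf, (lower, upper))
            boot[b] = sol.x[:4]
        lo = np.percentile(boot, 2.5, axis=0)
        hi = np.percentile(boot, 97.5, axis=0)
        point = params.as_array()
        for k, name in enumerate(("a1", "a2", "a3", "a4")):
            intervals[name] = (float(min(lo[k], point[k])), float(max(hi[k], point[k])))

    return KineticFit(
        params=params,
        p0=p0_hat,
        residual_ss=residual_ss,
        n_obs=n_obs,
        converged=bool(best.success),
        n_starts=n_starts,
        bootstrap_intervals=intervals,
        degenerate_rates=degenerate,
    )


def _flag_degenerate(series_list, p0: np.ndarray) -> tuple[str, ...]:
    """Rates with no observable flux: a state never populated leaves its
    efflux rates unconstrained (e.g. a constant all-HN series pins A1 only)."""
    occ = np.max([s.proportions.max(axis=0) for s in series_list], axis=0)
    flags = []
    if occ[1] < 1e-9:  # MN never populated
        flags += ["a2", "a3"]
    if occ[2] < 1e-9:  # LN never populated
        flags.append("a4")
    return tuple(flags)


def compare_conditions(fits: dict[str, KineticFit], reference: str):
    """Tabulate rates, reversibility indices and bootstrap intervals per
    condition, plus each condition's index as a ratio to the reference's.
    """
    import pandas as pd

    if reference not in fits:
        raise ValueError(f"reference condition {reference!r} not among fits: {sorted(fits)}")
    if len(fits) < 2:
        raise ValueError("compare_conditions requires at least 2 fitted conditions")
    ref_index = fits[reference].reversibility
    rows = []
    for cond, fit in fits.items():
        row = {
            "condition": cond,
            "a1": fit.params.a1,
            "a2": fit.params.a2,
            "a3": fit.params.a3,
            "a4": fit.params.a4,
            "reversibility_index": fit.reversibility,
            "index_ratio_vs_reference": fit.reversibility / ref_index,
            "residual_ss": fit.residual_ss,
            "converged": fit.converged,
        }
        for name, (lo, hi) in fit.bootstrap_intervals.items():
            row[f"{name}_ci_lo"] = lo
            row[f"{name}_ci_hi"] = hi
        rows.append(row)
    df = pd.DataFrame(rows).set_index("condition")
    return df.loc[[reference] + [c for c in fits if c != reference]]
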