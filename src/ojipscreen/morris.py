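"""Morris one-at-a-time (OAT) elementary-effects screening.

The Morris method probes a k-factor model along random *trajectories*:
sequences of k+1 points in a discretised unit factor space in which
consecutive points differ in exactly one factor by a fixed grid step
``delta``.  Each trajectory yields one elementary effect (EE) per factor
— a finite-difference derivative estimate — and the EEs from ``m``
trajectories are condensed into the screening measures

* ``mu``      signed mean EE (can cancel across sign changes),
* ``mu_star`` mean absolute EE (importance measure used for ranking),
* ``sigma``   EE standard deviation (nonlinearity / interaction flag).

This implementation works on *time-resolved* outputs: the model maps a
parameter vector to a full time series, every EE is itself a time
series, and the measures are aggregated over trajectories and time
points (see :func:`aggregate_measures`).

Unit-space conventions
----------------------
Factor levels live on the grid {0, 1/(p-1), ..., 1}.  Base points are
drawn from *all* p levels, so a +delta step from level 1 overshoots the
nominal [0, 1] interval; the affine map to real parameter values
(:func:`map_to_rates`) extrapolates linearly in that case.  This mirrors
the sampling actually used for the worked example and the fluorescence
screening (trajectory entries above the +scale bound do occur).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MorrisDesign",
    "TrajectoryMatrix",
    "EESeries",
    "MorrisSummary",
    "build_base_point",
    "build_trajectory",
    "map_to_rates",
    "elementary_effects",
    "aggregate_measures",
    "rank_parameters",
    "summaries_to_frame",
    "ee_series_to_frame",
]


@dataclass(frozen=True)
class MorrisDesign:
    """Parameters of a Morris screening design.

    Parameters
    ----------
    k : int
        Number of factors.
    p : int
        Number of levels of the unit grid (>= 2).
    m : int
        Number of trajectories.
    delta : float, optional
        Unit grid step.  Defaults to the canonical ``(p-2)/(p-1)``
        (2/3 for p=4); may be overridden.
    """

    k: int
    p: int = 4
    m: int = 4
    delta: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.p < 2:
            raise ValueError(f"p must be >= 2, got {self.p}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.delta is None:
            # canonical (p-2)/(p-1) degenerates to 0 at p=2, where the only
            # possible step on the two-level grid is the full interval
            default = (self.p - 2) / (self.p - 1) if self.p > 2 else 1.0
            object.__setattr__(self, "delta", default)
        if not 0 < self.delta <= 1:
            raise ValueError(f"delta must lie in (0, 1], got {self.delta}")

    @property
    def levels(self) -> np.ndarray:
        """The unit level grid {0, 1/(p-1), ..., 1}."""
        return np.linspace(0.0, 1.0, self.p)


@dataclass
class TrajectoryMatrix:
    """A single Morris trajectory in unit and (optionally) real space.

    ``unit_matrix`` has k+1 rows; consecutive rows differ in exactly one
    column by ``+-delta``.  ``factor_order[s]`` is the factor index that
    changes between rows s and s+1, and ``step_signs[s]`` the sign of
    that unit step.  ``real_matrix`` is filled in by
    :func:`map_to_rates`.
    """

    unit_matrix: np.ndarray
    factor_order: np.ndarray
    step_signs: np.ndarray
    real_matrix: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.unit_matrix.shape[1]

    def validate(self, delta: float) -> None:
        """Check the one-factor-per-step property."""
        diffs = np.diff(self.unit_matrix, axis=0)
        for s, row in enumerate(diffs):
            nz = np.nonzero(np.abs(row) > 1e-12)[0]
            if len(nz) != 1:
                raise ValueError(f"step {s} changes {len(nz)} factors, expected 1")
            if not np.isclose(abs(row[nz[0]]), delta):
                raise ValueError(
                    f"step {s} has size {row[nz[0]]}, expected +-{delta}"
                )


@dataclass
class EESeries:
    """Elementary effects of one factor, per trajectory and time point."""

    parameter_name: str
    time_grid: np.ndarray
    ee_values: np.ndarray  # shape (m, n_time)

    def __post_init__(self) -> None:
        self.ee_values = np.atleast_2d(np.asarray(self.ee_values, dtype=float))
        if self.ee_values.shape[1] != len(self.time_grid):
            raise ValueError("ee_values row length must equal time grid length")


@dataclass
class MorrisSummary:
    """Aggregated Morris measures for one factor."""

    parameter_name: str
    mu: float
    mu_star: float
    sigma: float
    rank: int | None = None


def build_base_point(design: MorrisDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw a base point X* uniformly from the full level grid.

    Every entry is drawn independently from {0, 1/(p-1), ..., 1}.  Note
    that, unlike the canonical Morris scheme, levels above ``1 - delta``
    are *not* excluded; a subsequent +delta step may overshoot 1 and the
    real-space mapping extrapolates.
    """
    idx = rng.integers(0, design.p, size=design.k)
    return design.levels[idx]


def build_trajectory(
    design: MorrisDesign,
    rng: np.random.Generator,
    base_point: np.ndarray | None = None,
) -> TrajectoryMatrix:
    """Build one randomised trajectory matrix B*.

    Implements ``B* = (J X* + (delta/2) [(2 B - J) D* + J]) P*`` where B
    is the strictly lower-triangular matrix of ones, D* a random +-1
    diagonal and P* a random permutation matrix.  Draws are taken from
    ``rng`` in the fixed order: base point (if not supplied), D*, P*, so
    a seeded generator reproduces trajectories exactly.
    """
    k, delta = design.k, design.delta
    if base_point is None:
        base_point = build_base_point(design, rng)
    x_star = np.asarray(base_point, dtype=float)
    if x_star.shape != (k,):
        raise ValueError(f"base point must have shape ({k},)")

    d_star = rng.choice([-1.0, 1.0], size=k)
    perm = rng.permutation(k)
    p_star = np.zeros((k, k))
    p_star[np.arange(k), perm] = 1.0

    b = np.tri(k + 1, k, -1)  # strictly lower triangular ones
    j_mat = np.ones((k + 1, k))
    core = j_mat * x_star + (delta / 2.0) * ((2.0 * b - j_mat) * d_star + j_mat)
    unit = core @ p_star

    diffs = np.diff(unit, axis=0)
    factor_order = np.argmax(np.abs(diffs) > 1e-12, axis=1)
    step_signs = np.sign(diffs[np.arange(k), factor_order])
    traj = TrajectoryMatrix(unit, factor_order, step_signs.astype(int))
    traj.validate(delta)
    return traj


def map_to_rates(
    unit_matrix: np.ndarray,
    base_values: np.ndarray,
    scale_fraction: float,
) -> np.ndarray:
    """Map unit levels to real parameter values.

    Level 0 maps to ``v0 (1 - s)`` and level 1 to ``v0 (1 + s)`` where
    ``s`` is the scale fraction (e.g. 0.2 screens each rate constant
    over +-20% of its base value).  Levels outside [0, 1] extrapolate
    linearly: ``v = v0 (1 - s) + u * 2 s v0``.
    """
    base_values = np.asarray(base_values, dtype=float)
    if np.any(base_values <= 0):
        raise ValueError("base values must be positive")
    if not 0 <= scale_fraction < 1:
        raise ValueError(f"scale fraction must lie in [0, 1), got {scale_fraction}")
    return base_values * (1.0 - scale_fraction) + np.asarray(unit_matrix) * (
        2.0 * scale_fraction * base_values
    )


def elementary_effects(
    traj: TrajectoryMatrix,
    output_fn,
    design: MorrisDesign,
    *,
    denominator: str = "unit_signed",
    scale_fraction: float | None = None,
    base_values: np.ndarray | None = None,
) -> np.ndarray:
    """Compute one elementary-effect time series per factor.

    Each of the k+1 rows of ``traj.real_matrix`` (or ``unit_matrix`` if
    no real mapping was set) is evaluated exactly once with
    ``output_fn(params) -> ndarray``; for the step at which factor i
    changes,

        ``EE_i(t) = [f(row_after, t) - f(row_before, t)] / step``

    where ``step`` depends on ``denominator``:

    * ``"unit_signed"`` (default): the signed unit step ``+-delta``, so
      the EE approximates the unit-space directional derivative
      irrespective of step direction;
    * ``"unit_abs"``: the canonical Morris convention, always ``delta``;
    * ``"real_signed"``: the signed real-space step
      ``+-delta * 2 s v0_i`` (requires ``scale_fraction`` and
      ``base_values``).

    Returns an array of shape ``(k, n_time)`` ordered by factor index.
    """
    rows = traj.real_matrix if traj.real_matrix is not None else traj.unit_matrix
    outputs = []
    for r, params in enumerate(rows):
        try:
            outputs.append(np.asarray(output_fn(params), dtype=float))
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(
                f"output function failed on trajectory row {r}: {params!r}"
            ) from exc
    n_time = outputs[0].shape[-1]
    ee = np.empty((design.k, n_time))
    for step in range(design.k):
        i = traj.factor_order[step]
        sign = traj.step_signs[step]
        if denominator == "unit_signed":
            denom = sign * design.delta
        elif denominator == "unit_abs":
            denom = design.delta
        elif denominator == "real_signed":
            if scale_fraction is None or base_values is None:
                raise ValueError(
                    "real_signed denominator needs scale_fraction and base_values"
                )
            denom = sign * design.delta * 2.0 * scale_fraction * base_values[i]
        else:
            raise ValueError(f"unknown denominator convention {denominator!r}")
        ee[i] = (outputs[step + 1] - outputs[step]) / denom
    return ee


def aggregate_measures(
    ee_series: list[EESeries],
    *,
    method: str = "two_stage",
) -> list[MorrisSummary]:
    """Condense per-trajectory, per-time EEs into mu, mu*, sigma.

    ``method="two_stage"`` (default) first averages the EEs across
    trajectories at each time point (the Morris mean with r = m applied
    per time point) and then takes statistics of that averaged series
    across time points: mu = mean, mu* = mean absolute value, sigma =
    sample standard deviation (n-1 denominator).  ``method="pooled"``
    instead treats all trajectory x time EEs as one sample.
    """
    if method not in ("two_stage", "pooled"):
        raise ValueError(f"unknown aggregation method {method!r}")
    out = []
    for series in ee_series:
        e = series.ee_values
        if method == "two_stage":
            sample = e.mean(axis=0)  # average over trajectories per time point
        else:
            sample = e.ravel()
        if sample.size < 2:
            raise ValueError(
                f"{series.parameter_name}: need >= 2 values for sigma, "
                f"got {sample.size}"
            )
        out.append(
            MorrisSummary(
                parameter_name=series.parameter_name,
                mu=float(sample.mean()),
                mu_star=float(np.abs(sample).mean()),
                sigma=float(sample.std(ddof=1)),
            )
        )
    return out


def rank_parameters(summaries: list[MorrisSummary]) -> list[MorrisSummary]:
    """Order factors by importance and assign 1-based ranks.

    Descending mu*; ties broken by descending sigma, then by parameter
    name (ascending), making the ordering fully deterministic.
    """
    ordered = sorted(
        summaries,
        key=lambda s: (-s.mu_star, -s.sigma, s.parameter_name),
    )
    for pos, summary in enumerate(ordered, start=1):
        summary.rank = pos
    return ordered


def summaries_to_frame(summaries: list[MorrisSummary]) -> pd.DataFrame:
    """Export summaries as a DataFrame (parameter, mu, mu_star, sigma, rank)."""
    return pd.DataFrame(
        {
            "parameter": [s.parameter_name for s in summaries],
            "mu": [s.mu for s in summaries],
            "mu_star": [s.mu_star for s in summaries],
            "sigma": [s.sigma for s in summaries],
            "rank": [s.rank for s in summaries],
        }
    )


def ee_series_to_frame(ee_series: list[EESeries]) -> pd.DataFrame:
    """Export EE series in long form (parameter, trajectory, time_s, ee)."""
    frames = []
    for series in ee_series:
        m, nt = series.ee_values.shape
        frames.append(
            pd.DataFrame(
                {
                    "parameter": np.repeat(series.parameter_name, m * nt),
                    "trajectory": np.repeat(np.arange(1, m + 1), nt),
                    "time_s": np.tile(series.time_grid, m),
                    "ee": series.ee_values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
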