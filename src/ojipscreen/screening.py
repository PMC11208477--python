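"""Morris screening of the electron-transport-chain rate constants.

Screens the 18 forward or 14 backward rate constants of the
fluorescence-induction model: each Morris trajectory perturbs one group
of rate constants around their tabulated base values (scaled by 10, 20
or 30%), the model is simulated at every trajectory point under the
chosen light regime, and the elementary effects are computed on the
fluorescence observable F(t).  A forward screening costs m * (18 + 1)
full stiff simulations, a backward one m * (14 + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .etc_model import (
    BACKWARD_NAMES,
    FORWARD_NAMES,
    InitialStateConfig,
    LightRegime,
    PoolConfig,
    QuenchConfig,
    RateConstantSet,
    default_time_grid,
    simulate_fi,
)
from .morris import (
    EESeries,
    MorrisDesign,
    MorrisSummary,
    TrajectoryMatrix,
    aggregate_measures,
    build_trajectory,
    elementary_effects,
    map_to_rates,
    rank_parameters,
)

__all__ = [
    "ScreeningConfig",
    "ScreeningResult",
    "CurveEnsemble",
    "run_screening",
    "percentile_envelope",
    "ee_time_course",
    "compare_orderings",
]

_VALID_SCALES = (0.10, 0.20, 0.30)


@dataclass(frozen=True)
class ScreeningConfig:
    """Configuration of one screening run.

    The 30% scale is meaningful only for the forward group under low
    light (the combination actually exercised); other scale/light
    combinations are permitted but flagged by ``validate_scales``.
    """

    group: str = "forward"  # "forward" | "backward"
    scale_fraction: float = 0.20
    light: LightRegime = field(default_factory=LightRegime.intense)
    design: MorrisDesign | None = None
    seed: int = 0
    rates: RateConstantSet = field(default_factory=RateConstantSet)
    pools: PoolConfig = field(default_factory=PoolConfig)
    init: InitialStateConfig = field(default_factory=InitialStateConfig)
    quench: QuenchConfig = field(default_factory=QuenchConfig)
    aggregation: str = "two_stage"
    # reduced-cost mode: coarser output grid and looser solver tolerances
    points_per_decade: int = 60
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.group not in ("forward", "backward"):
            raise ValueError(f"group must be 'forward' or 'backward', got {self.group!r}")
        if not 0 <= self.scale_fraction < 1:
            raise ValueError("scale_fraction must lie in [0, 1)")
        if self.design is None:
            object.__setattr__(self, "design", MorrisDesign(k=len(self.parameter_names)))
        if self.design.k != len(self.parameter_names):
            raise ValueError(
                f"design.k={self.design.k} does not match the "
                f"{len(self.parameter_names)} screened constants"
            )

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return FORWARD_NAMES if self.group == "forward" else BACKWARD_NAMES

    @property
    def base_values(self) -> np.ndarray:
        return np.array([self.rates[name] for name in self.parameter_names])

    def reduced(self) -> "ScreeningConfig":
        """Reduced-cost variant for quick runs and tests."""
        return replace(self, points_per_decade=20, rtol=1e-6, atol=1e-9)


@dataclass
class CurveEnsemble:
    """The k+1 simulated F(t) curves of one trajectory."""

    trajectory_index: int  # 1-based
    time_grid: np.ndarray
    curves: np.ndarray  # (k+1, n_time)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.curves.T, columns=[f"row_{i}" for i in range(self.curves.shape[0])]
        )
        df.insert(0, "time_s", self.time_grid)
        return df


@dataclass
class ScreeningResult:
    """All artifacts of one screening run."""

    config: ScreeningConfig
    summaries: list[MorrisSummary]
    ee_series: list[EESeries]
    ensembles: list[CurveEnsemble]
    trajectories: list[TrajectoryMatrix]
    time_grid: np.ndarray

    def ranking_frame(self) -> pd.DataFrame:
        from .morris import summaries_to_frame

        return summaries_to_frame(self.summaries)


def run_screening(config: ScreeningConfig) -> ScreeningResult:
    """Run the full Morris screening defined by ``config``.

    Draws m trajectories from the seeded generator, simulates the
    fluorescence transient at every sampled rate-constant combination
    and aggregates elementary effects into ranked Morris measures.
    """
    design = config.design
    rng = np.random.default_rng(config.seed)
    time_grid = default_time_grid(points_per_decade=config.points_per_decade)
    names = config.parameter_names
    base = config.base_values

    def output_fn(real_params: np.ndarray):
        rates = config.rates.with_values(**dict(zip(names, real_params)))
        result = simulate_fi(
            rates,
            config.light,
            pools=config.pools,
            init=config.init,
            quench=config.quench,
            time_grid=time_grid,
            rtol=config.rtol,
            atol=config.atol,
        )
        return result.fluorescence

    ee_per_traj, ensembles, trajectories = [], [], []
    for t_index in range(design.m):
        traj = build_trajectory(design, rng)
        traj.real_matrix = map_to_rates(traj.unit_matrix, base, config.scale_fraction)
        curves = np.array([output_fn(row) for row in traj.real_matrix])
        ee = np.empty((design.k, len(time_grid)))
        for step in range(design.k):
            i = traj.factor_order[step]
            denom = traj.step_signs[step] * design.delta
            if config.scale_fraction == 0:
                ee[i] = 0.0  # degenerate interval: no perturbation at all
            else:
                ee[i] = (curves[step + 1] - curves[step]) / denom
        ee_per_traj.append(ee)
        ensembles.append(CurveEnsemble(t_index + 1, time_grid, curves))
        trajectories.append(traj)

    stacked = np.stack(ee_per_traj)  # (m, k, n_time)
    series = [EESeries(names[i], time_grid, stacked[:, i, :]) for i in range(design.k)]
    summaries = rank_parameters(aggregate_measures(series, method=config.aggregation))
    return ScreeningResult(config, summaries, series, ensembles, trajectories, time_grid)


def percentile_envelope(
    ensemble: CurveEnsemble | np.ndarray,
    levels: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> pd.DataFrame:
    """Pointwise percentile curves of a curve ensemble.

    Linear interpolation between order statistics (numpy default).
    Returns a DataFrame with one ``p<level>`` column per level.
    """
    curves = ensemble.curves if isinstance(ensemble, CurveEnsemble) else np.asarray(ensemble)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need at least two curves on a shared grid")
    out = {}
    for level in levels:
        out[f"p{level:g}"] = np.percentile(curves, level, axis=0)
    df = pd.DataFrame(out)
    if isinstance(ensemble, CurveEnsemble):
        df.insert(0, "time_s", ensemble.time_grid)
    return df


def ee_time_course(
    result: ScreeningResult,
    parameter: str,
    trajectory_index: int = 4,
) -> pd.DataFrame:
    """EE(t) of one parameter along one trajectory (default the fourth).

    The fourth trajectory is the conventional choice for time-course
    plots here; any 1-based index up to m is accepted.
    """
    names = [s.parameter_name for s in result.ee_series]
    if parameter not in names:
        raise KeyError(f"unknown parameter {parameter!r}; have {names}")
    if not 1 <= trajectory_index <= result.config.design.m:
        raise IndexError(f"trajectory index {trajectory_index} out of range")
    series = result.ee_series[names.index(parameter)]
    return pd.DataFrame(
        {
            "time_s": series.time_grid,
            "ee": series.ee_values[trajectory_index - 1],
        }
    )


def compare_orderings(
    summaries_a: list[MorrisSummary],
    summaries_b: list[MorrisSummary],
) -> dict:
    """Rank-concordance report between two screenings of the same factors.

    Returns Spearman rank correlation of the mu*-based ranks plus the
    per-parameter rank shift (rank_b - rank_a).  Pure bookkeeping over
    ranks; mu*/sigma values are not compared.
    """
    a = {s.parameter_name: s.rank for s in summaries_a}
    b = {s.parameter_name: s.rank for s in summaries_b}
    if set(a) != set(b):
        raise ValueError("parameter sets differ between the two summaries")
    if any(r is None for r in list(a.values()) + list(b.values())):
        raise ValueError("summaries must be ranked first (rank_parameters)")
    names = sorted(a)
    ra = np.array([a[n] for n in names], dtype=float)
    rb = np.array([b[n] for n in names], dtype=float)
    n = len(names)
    if n < 2:
        rho = 1.0
    else:
        rho = float(np.corrcoef(ra, rb)[0, 1])
    return {
        "spearman_rho": rho,
        "rank_shifts": {name: int(b[name] - a[name]) for name in names},
        "n": n,
    }
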