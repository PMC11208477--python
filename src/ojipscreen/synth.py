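"""Pseudo-experimental O-J-I-P curve generation and curve comparison.

Measured fluorescence-induction transients are log-time sampled rises
from the O level through J (~2 ms) and I (~20 ms) inflections to the P
peak (~200 ms).  The generator emulates that structure as a sum of
three logistic steps in log10(t) — the minimal shape carrying the
O-J-I-P landmarks — with multiplicative Gaussian noise (fluorometer
error grows with signal; an additive component is also exposed).
These synthetic curves stand in for measured traces in workflows whose
first step compares simulated and experimental curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OJIPCurveSpec", "generate_ojip_curve", "compare_curves"]


@dataclass(frozen=True)
class OJIPCurveSpec:
    """Shape, sampling and noise of one synthetic O-J-I-P curve.

    Levels are in arbitrary fluorescence units; step times in seconds.
    ``step_width`` is the logistic width in decades of time (~0.25
    gives realistic, clearly separated plateaus for steps one decade
    apart).
    """

    f_o: float = 1.0
    f_j: float = 2.0
    f_i: float = 3.0
    f_p: float = 4.0
    t_j: float = 2e-3
    t_i: float = 2e-2
    t_p: float = 2e-1
    step_widths: tuple[float, float, float] = (0.10, 0.15, 0.25)
    noise_sd: float = 0.02  # relative (multiplicative) noise
    additive_noise_sd: float = 0.0
    t_min: float = 1e-5
    t_max: float = 1.0
    n_points: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.f_o < self.f_j <= self.f_i <= self.f_p:
            raise ValueError("levels must satisfy F_O < F_J <= F_I <= F_P")
        if not 1e-4 < self.t_j < self.t_i < self.t_p <= 1.0:
            raise ValueError("step times must satisfy 1e-4 < t_J < t_I < t_P <= 1")
        if self.noise_sd < 0 or self.additive_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if min(self.step_widths) <= 0:
            raise ValueError("step widths must be positive")

    @property
    def grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.t_min), np.log10(self.t_max), self.n_points
        )


def _logistic_step(log_t: np.ndarray, centre_s: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(log_t - np.log10(centre_s)) / width))


def _shape(log_t: np.ndarray, spec: OJIPCurveSpec, centres: np.ndarray) -> np.ndarray:
    f = np.full_like(log_t, spec.f_o)
    amplitudes = (
        spec.f_j - spec.f_o,
        spec.f_i - spec.f_j,
        spec.f_p - spec.f_i,
    )
    for centre, amplitude, width in zip(centres, amplitudes, spec.step_widths):
        f = f + amplitude * _logistic_step(log_t, centre, width)
    return f


def _slope_dips(log_t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Times of interior local minima of dF/dlog10(t)."""
    s = np.gradient(f, log_t)
    idx = np.nonzero((s[1:-1] < s[:-2]) & (s[1:-1] <= s[2:]))[0] + 1
    return 10.0 ** log_t[idx]


def solve_step_centres(spec: OJIPCurveSpec, n_iter: int = 60) -> np.ndarray:
    """Place the logistic steps so the curve's *features* land on the requested times.

    t_J and t_I name plateau positions (slope minima on the log-time
    axis) and t_P the final-rise inflection — the same operational
    definitions the feature extractor uses.  For a sum of logistic
    steps the plateau dips fall between the step centres (near their
    geometric mean), so the two early centres are solved by fixed-point
    iteration until the dips of the noiseless curve coincide with the
    requested t_J and t_I; the P-step centre is t_P itself.  Converges
    whenever the features are separated by around a decade.
    """
    dense = np.linspace(np.log10(spec.t_min), np.log10(spec.t_max), 1200)
    centres = np.array([spec.t_j / 2.0, np.sqrt(spec.t_j * spec.t_i), spec.t_p])
    for _ in range(n_iter):
        dips = _slope_dips(dense, _shape(dense, spec, centres))
        if len(dips) < 2:
            # merged steps: pull the first two centres apart and retry
            centres[0] /= 1.5
            centres[1] *= 1.1
            continue
        # match the two dips closest to the requested feature times
        d_j = dips[np.argmin(np.abs(np.log10(dips / spec.t_j)))]
        d_i = dips[np.argmin(np.abs(np.log10(dips / spec.t_i)))]
        ratio_j, ratio_i = spec.t_j / d_j, spec.t_i / d_i
        centres[0] *= ratio_j
        centres[1] *= ratio_i
        centres[0] = min(centres[0], 0.9 * centres[1])
        centres[1] = min(centres[1], 0.9 * centres[2])
        if abs(np.log10(ratio_j)) < 1e-3 and abs(np.log10(ratio_i)) < 1e-3:
            break
    return centres


def generate_ojip_curve(spec: OJIPCurveSpec) -> pd.DataFrame:
    """Generate one noisy synthetic transient.

    Noiseless shape: ``F(t) = F_O + sum of three logistic steps`` in
    log10(t) with amplitudes (F_J - F_O), (F_I - F_J), (F_P - F_I) and
    centres chosen (:func:`solve_step_centres`) so that the J and I
    plateaus and the P rise sit at t_J, t_I, t_P as a feature detector
    measures them.  Multiplicative noise scales each point by
    ``1 + N(0, noise_sd)``; optional additive noise adds
    ``N(0, additive_noise_sd)``.  Fully determined by ``spec.seed``.
    """
    t = spec.grid
    log_t = np.log10(t)
    f = _shape(log_t, spec, solve_step_centres(spec))
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        f = f * (1.0 + rng.normal(0.0, spec.noise_sd, size=f.shape))
    if spec.additive_noise_sd > 0:
        f = f + rng.normal(0.0, spec.additive_noise_sd, size=f.shape)
    return pd.DataFrame({"time_s": t, "F": f})


def compare_curves(
    simulated: pd.DataFrame,
    reference: pd.DataFrame,
    *,
    normalize: bool = True,
    n_points: int = 200,
) -> dict:
    """Distance report between two transients.

    Both curves are interpolated onto a shared log grid covering the
    overlap of their time windows.  With ``normalize`` each curve is
    min-max scaled (its own minimum -> 0, maximum -> 1) before
    comparison, mirroring the usual O-to-P normalisation.  Returns the
    RMSE and the maximum absolute deviation on that grid.
    """
    for df, tag in ((simulated, "simulated"), (reference, "reference")):
        if not {"time_s", "F"} <= set(df.columns):
            raise ValueError(f"{tag} curve needs 'time_s' and 'F' columns")
    lo = max(simulated.time_s.min(), reference.time_s.min())
    hi = min(simulated.time_s.max(), reference.time_s.max())
    if not lo < hi:
        raise ValueError("curves do not overlap in time")
    grid = np.logspace(np.log10(lo), np.log10(hi), n_points)

    def sample(df: pd.DataFrame) -> np.ndarray:
        y = np.interp(np.log10(grid), np.log10(df.time_s), df.F)
        if normalize:
            span = y.max() - y.min()
            if span == 0:
                raise ValueError("cannot min-max normalise a constant curve")
            y = (y - y.min()) / span
        return y

    a, b = sample(simulated), sample(reference)
    return {
        "rmse": float(np.sqrt(np.mean((a - b) ** 2))),
        "max_abs_dev": float(np.max(np.abs(a - b))),
        "n_points": n_points,
        "window": (float(lo), float(hi)),
        "normalized": normalize,
    }
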