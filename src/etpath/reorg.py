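"""Outer-sphere (solvent) reorganization energy from vertical energy-gap
fluctuations, under the linear-response (Gaussian) approximation.

For a reactant-ensemble trajectory of vertical gaps
dE(t) = E_product(q_t) - E_reactant(q_t), linear response gives two
routes to the solvent reorganization energy:

    variance route:  lambda = Var(dE) / (2 kB T)
    Stokes route:    lambda = <dE>_R - dG        (since <dE>_R = dG + lambda)

Agreement of the two is the internal check of the Gaussian picture;
disagreement flags non-linear response and is reported, never averaged
away.  Standard errors come from a moving-block bootstrap with block
length tied to the estimated integrated autocorrelation time, since gap
series from molecular dynamics are strongly autocorrelated.

The resulting lambda_out adds to the inner-shell reorganization energies
of both Marcus parabolas; :func:`corrected_activation` reports the new
activation energy and its increment over the inner-only value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .constants import KB_KCAL
from .marcus import MarcusResult, marcus_activation

__all__ = [
    "GapTrajectory",
    "OuterReorgResult",
    "lambda_from_variance",
    "lambda_from_stokes",
    "corrected_activation",
    "integrated_autocorr_time",
]

MIN_FRAMES = 100


@dataclass
class GapTrajectory:
    """Vertical energy-gap time series in one ensemble.

    ``gaps`` holds E_product_distribution - E_reactant_distribution per
    frame (kcal/mol); ``equilibration_fraction`` of initial frames is
    trimmed before analysis (the molecular-dynamics burn-in).
    """

    times: np.ndarray  # ps, strictly increasing
    gaps: np.ndarray  # kcal/mol
    temperature: float = 298.15
    ensemble: Literal["reactant", "product"] = "reactant"
    equilibration_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gaps = np.asarray(self.gaps, dtype=float)
        if self.times.shape != self.gaps.shape:
            raise ValueError("times and gaps must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.production_gaps().size < MIN_FRAMES:
            raise ValueError(
                f"need at least {MIN_FRAMES} frames after equilibration trim"
            )

    def production_gaps(self) -> np.ndarray:
        n_trim = int(self.equilibration_fraction * len(self.gaps))
        return self.gaps[n_trim:]


@dataclass(frozen=True)
class LambdaEstimate:
    value: float
    stderr: float


@dataclass(frozen=True)
class OuterReorgResult:
    lambda_variance: float
    lambda_stokes: Optional[float]
    mean_gap_reactant: float
    linearity_ratio: Optional[float]


def integrated_autocorr_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time in frames, by summing the
    normalized autocorrelation function up to its first non-positive lag
    (initial-positive-sequence truncation)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    var = xc @ xc / n
    if var == 0:
        return 1.0
    tau = 0.5
    for lag in range(1, min(n // 2, 10_000)):
        rho = (xc[:-lag] @ xc[lag:]) / ((n - lag) * var)
        if rho <= 0:
            break
        tau += rho
    return max(2.0 * tau, 1.0)


def _block_bootstrap(
    x: np.ndarray, stat, n_boot: int = 200, seed: int = 0
) -> float:
    """Moving-block bootstrap standard error of ``stat`` with block
    length 20x the integrated autocorrelation time."""
    n = len(x)
    block = int(min(max(20 * integrated_autocorr_time(x), 1), n // 2))
    n_blocks = int(np.ceil(n / block))
    starts_max = n - block
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max + 1, size=n_blocks)
        resample = np.concatenate([x[s : s + block] for s in starts])[:n]
        vals[b] = stat(resample)
    return float(vals.std(ddof=1))


def lambda_from_variance(traj: GapTrajectory, n_boot: int = 200) -> LambdaEstimate:
    """Solvent reorganization energy Var(gap) / (2 kB T), with a
    block-bootstrap standard error."""
    g = traj.production_gaps()
    denom = 2.0 * KB_KCAL * traj.temperature
    est = float(g.var(ddof=1) / denom)
    se = _block_bootstrap(g, lambda y: y.var(ddof=1) / denom, n_boot=n_boot)
    return LambdaEstimate(value=est, stderr=se)


def lambda_from_stokes(
    traj_r: GapTrajectory, delta_g: float, n_boot: int = 200
) -> LambdaEstimate:
    """Solvent reorganization energy <gap>_reactant - dG (linear-response
    identity), with a block-bootstrap standard error."""
    if traj_r.ensemble != "reactant":
        raise ValueError("Stokes estimator requires the reactant-ensemble trajectory")
    g = traj_r.production_gaps()
    est = float(g.mean() - delta_g)
    se = _block_bootstrap(g, lambda y: y.mean() - delta_g, n_boot=n_boot)
    return LambdaEstimate(value=est, stderr=se)


def outer_reorg_summary(
    traj_r: GapTrajectory, delta_g: Optional[float] = None
) -> OuterReorgResult:
    """Both linear-response estimates from one reactant trajectory; the
    linearity ratio (variance/Stokes) is ~1 under Gaussian statistics."""
    lv = lambda_from_variance(traj_r)
    g = traj_r.production_gaps()
    ls = None
    ratio = None
    if delta_g is not None:
        ls = lambda_from_stokes(traj_r, delta_g)
        if ls.value != 0:
            ratio = lv.value / ls.value
    return OuterReorgResult(
        lambda_variance=lv.value,
        lambda_stokes=None if ls is None else ls.value,
        mean_gap_reactant=float(g.mean()),
        linearity_ratio=ratio,
    )


@dataclass(frozen=True)
class CorrectedActivation:
    inner_only: MarcusResult
    total: MarcusResult
    lambda_out: float
    increment: float


def corrected_activation(
    delta_g: float, lambda_r_inner: float, lambda_p_inner: float, lambda_out: float
) -> CorrectedActivation:
    """Activation energy with the solvent reorganization added to both
    parabolas (lambda_total = lambda_inner + lambda_out per state), and
    its increment over the inner-shell-only value."""
    if lambda_out < 0:
        raise ValueError("lambda_out must be non-negative")
    inner = marcus_activation(delta_g, lambda_r_inner, lambda_p_inner)
    total = marcus_activation(
        delta_g, lambda_r_inner + lambda_out, lambda_p_inner + lambda_out
    )
    return CorrectedActivation(
        inner_only=inner,
        total=total,
        lambda_out=lambda_out,
        increment=total.activation_energy - inner.activation_energy,
    )
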