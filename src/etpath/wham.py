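"""1-D weighted histogram analysis (WHAM) of umbrella-sampling windows.

Each window i restrains the coordinate with a harmonic bias
w_i(x) = 0.5 * k_i * (x - x0_i)^2 and contributes a histogram n_i(x_j)
over shared bins.  The self-consistent WHAM equations

    P(x_j)        = sum_i n_i(x_j) / sum_i N_i exp(beta (f_i - w_i(x_j)))
    exp(-beta f_i) = sum_j P(x_j) exp(-beta w_i(x_j))

are iterated to a fixed point in the window free-energy offsets f_i
(first window pinned at 0).  The potential of mean force is
-kB T ln P(x), anchored so its minimum is 0.  Empty bins are excluded
rather than assigned infinite energy; a gap in the pooled histogram
support (non-overlapping windows) is an error naming the gap interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import KB_KCAL

__all__ = ["UmbrellaWindow", "PMFResult", "solve_wham", "binding_depth"]


@dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate under one harmonic bias.

    ``discarded_prefix`` initial samples are dropped before analysis
    (the per-window equilibration discard).
    """

    center: float  # angstrom
    spring_k: float  # kcal/mol/A^2
    samples: np.ndarray  # angstrom
    discarded_prefix: int = 0

    def __post_init__(self) -> None:
        if not self.spring_k > 0:
            raise ValueError("spring_k must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.production_samples().size == 0:
            raise ValueError("window has no samples after prefix discard")

    def production_samples(self) -> np.ndarray:
        return self.samples[self.discarded_prefix :]

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(x) - self.center) ** 2


@dataclass
class PMFResult:
    bin_centers: np.ndarray  # angstrom, occupied bins only
    free_energy: np.ndarray  # kcal/mol, min-anchored at 0
    window_offsets: np.ndarray  # kcal/mol, first window pinned at 0
    converged: bool
    n_iterations: int
    #: (low_edge, high_edge) of empty interior bins, if any
    gaps: list

    def depth(self) -> float:
        return float(self.free_energy.max() - self.free_energy.min())


def solve_wham(
    windows: Sequence[UmbrellaWindow],
    bin_size: float = 0.2,
    temperature: float = 298.15,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> PMFResult:
    """Self-consistent WHAM solution over the pooled histogram support.

    Iterates the window offsets until the largest change falls below
    ``tol`` (kcal/mol); if ``max_iter`` is reached first the result is
    returned with ``converged=False``.
    """
    if len(windows) < 1:
        raise ValueError("need at least one window")
    if not tol > 0:
        raise ValueError("tol must be positive")
    kt = KB_KCAL * temperature
    beta = 1.0 / kt

    pooled = np.concatenate([w.production_samples() for w in windows])
    lo = np.floor(pooled.min() / bin_size) * bin_size
    hi = np.ceil(pooled.max() / bin_size) * bin_size
    edges = np.arange(lo, hi + 0.5 * bin_size, bin_size)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack(
        [np.histogram(w.production_samples(), bins=edges)[0] for w in windows]
    ).astype(float)
    n_i = counts.sum(axis=1)  # samples per window
    pooled_counts = counts.sum(axis=0)

    # interior empty bins signal non-overlapping windows
    occupied = pooled_counts > 0
    gaps = []
    idx = np.nonzero(occupied)[0]
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a > 1:
            gaps.append((float(edges[a + 1]), float(edges[b])))
    if len(windows) > 1 and gaps:
        raise ValueError(
            "umbrella windows do not overlap: empty coordinate interval(s) "
            + ", ".join(f"[{g0:.3f}, {g1:.3f}]" for g0, g1 in gaps)
        )

    bias = np.stack([w.bias(centers) for w in windows])  # (n_win, n_bin)
    exp_neg_bias = np.exp(-beta * bias)

    f = np.zeros(len(windows))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = (n_i[:, None] * np.exp(beta * f)[:, None] * exp_neg_bias).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, pooled_counts / denom, 0.0)
        z = exp_neg_bias @ p
        f_new = -kt * np.log(z)
        f_new -= f_new[0]  # pin first window
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            converged = True
            break

    denom = (n_i[:, None] * np.exp(beta * f)[:, None] * exp_neg_bias).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, pooled_counts / denom, 0.0)
    keep = p > 0
    with np.errstate(divide="ignore"):
        pmf = -kt * np.log(p[keep])
    pmf -= pmf.min()
    return PMFResult(
        bin_centers=centers[keep],
        free_energy=pmf,
        window_offsets=f,
        converged=converged,
        n_iterations=it,
        gaps=gaps,
    )


def binding_depth(
    pmf: PMFResult,
    bound_region: tuple,
    unbound_region: tuple,
) -> float:
    """Binding free-energy depth: mean plateau free energy over the
    unbound region minus the minimum over the bound region (kcal/mol)."""
    x = pmf.bin_centers
    for name, (a, b) in (("bound", bound_region), ("unbound", unbound_region)):
        if a > b:
            raise ValueError(f"{name} region is reversed: ({a}, {b})")
        if not np.any((x >= a) & (x <= b)):
            raise ValueError(
                f"{name} region ({a}, {b}) lies outside the PMF support "
                f"[{x.min():.3f}, {x.max():.3f}]"
            )
    in_bound = (x >= bound_region[0]) & (x <= bound_region[1])
    in_unbound = (x >= unbound_region[0]) & (x <= unbound_region[1])
    return float(pmf.free_energy[in_unbound].mean() - pmf.free_energy[in_bound].min())
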