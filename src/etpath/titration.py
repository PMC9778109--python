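"""Metropolis Monte Carlo titration of coupled protonation/redox sites.

Each titrable site is a two-state unit: a reference form and a
non-reference form (deprotonated for proton sites, reduced/anionic for
redox sites).  A microstate is a binary occupancy vector over sites, and
its energy relative to the all-reference state is

    E(x) = sum_i x_i * e_i(pH, E_h)  +  sum_{i<j} x_i x_j W_ij

with per-site terms

    proton site:  e_i = ln(10) * kB * T * (pKa_i - pH)
    redox  site:  e_i = F * (E_h - E0_i)

so a lone proton site reproduces Henderson-Hasselbalch (deprotonated
fraction 1/(1 + 10^(pKa - pH))) and a lone redox site a Nernst curve with
midpoint E0.  W is the symmetric pairwise interaction matrix (kcal/mol)
from continuum electrostatics; it applies when both sites are in their
non-reference forms.

Sampling is single-site-flip Metropolis; small systems can instead be
solved exactly by Boltzmann enumeration over all 2^n microstates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from numba import njit

from .constants import F_KCAL_PER_V, KB_KCAL

__all__ = [
    "TitrationSite",
    "TitrationSystem",
    "OccupancyResult",
    "RedoxShiftPoint",
    "microstate_energy",
    "enumerate_occupancies",
    "sample_occupancies",
    "redox_shift",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class TitrationSite:
    """One two-state titrable site.

    ``intrinsic_value`` is the intrinsic pKa (pH units) for proton sites
    or the intrinsic midpoint potential E0 (mV) for redox sites.
    """

    label: str
    site_kind: Literal["proton", "redox"]
    intrinsic_value: float
    reference_form_charge: int = 0

    def __post_init__(self) -> None:
        if self.site_kind not in ("proton", "redox"):
            raise ValueError(f"unknown site_kind {self.site_kind!r}")


@dataclass
class TitrationSystem:
    sites: list[TitrationSite]
    interaction: np.ndarray  # (n, n) kcal/mol, symmetric, zero diagonal
    temperature: float = 300.0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError("site labels must be unique")
        n = len(self.sites)
        W = np.asarray(self.interaction, dtype=float)
        if W.shape != (n, n):
            raise ValueError(f"interaction matrix must be {n}x{n}")
        if not np.allclose(W, W.T):
            raise ValueError("interaction matrix must be symmetric")
        if not np.allclose(np.diag(W), 0.0):
            raise ValueError("interaction matrix must have zero diagonal")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        self.interaction = W

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, label: str) -> int:
        for i, s in enumerate(self.sites):
            if s.label == label:
                return i
        raise KeyError(label)

    def site_energies(self, ph: float, e_h: float) -> np.ndarray:
        """Per-site energy (kcal/mol) of the non-reference form at the
        given pH and solution redox potential E_h (mV)."""
        kt = KB_KCAL * self.temperature
        e = np.empty(self.n_sites)
        for i, s in enumerate(self.sites):
            if s.site_kind == "proton":
                e[i] = LN10 * kt * (s.intrinsic_value - ph)
            else:
                e[i] = F_KCAL_PER_V * (e_h - s.intrinsic_value) / 1000.0
        return e


@dataclass(frozen=True)
class OccupancyResult:
    """Non-reference-form fractions at one (pH, E_h) grid point."""

    ph: float
    e_h: float
    fractions: dict
    stderr: dict
    mc_steps: int
    seed: Optional[int]


@dataclass(frozen=True)
class RedoxShiftPoint:
    ph: float
    midpoint_a: Optional[float]
    midpoint_b: Optional[float]
    shift_mv: Optional[float]
    in_window: bool


def microstate_energy(
    system: TitrationSystem, occupancy: Sequence[int], ph: float, e_h: float = 0.0
) -> float:
    """Energy (kcal/mol) of one microstate relative to the all-reference
    state; deterministic."""
    x = np.asarray(occupancy, dtype=float)
    if x.shape != (system.n_sites,):
        raise ValueError(
            f"occupancy length {x.shape} does not match {system.n_sites} sites"
        )
    e = system.site_energies(ph, e_h)
    return float(x @ e + 0.5 * x @ system.interaction @ x)


def enumerate_occupancies(
    system: TitrationSystem, ph: float, e_h: float = 0.0
) -> np.ndarray:
    """Exact non-reference-form fractions by Boltzmann enumeration of all
    2^n microstates.  Intended for small systems (n <= 20)."""
    n = system.n_sites
    if n > 20:
        raise ValueError("exact enumeration limited to 20 sites")
    states = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
    e_site = system.site_energies(ph, e_h)
    energies = states @ e_site + 0.5 * np.einsum(
        "si,ij,sj->s", states, system.interaction, states
    )
    beta = 1.0 / (KB_KCAL * system.temperature)
    w = np.exp(-beta * (energies - energies.min()))
    w /= w.sum()
    return states.T @ w


@njit(cache=True)
def _mc_kernel(e_site, W, beta, n_steps, n_burn, block_sums, seed):  # pragma: no cover
    np.random.seed(seed)
    n = e_site.shape[0]
    x = np.zeros(n, dtype=np.int8)
    n_blocks = block_sums.shape[0]
    n_prod = n_steps - n_burn
    block_len = n_prod // n_blocks
    for t in range(n_steps):
        i = np.random.randint(n)
        field = e_site[i]
        for j in range(n):
            if x[j] == 1 and j != i:
                field += W[i, j]
        d_e = field if x[i] == 0 else -field
        if d_e <= 0.0 or np.random.random() < math.exp(-beta * d_e):
            x[i] = 1 - x[i]
        if t >= n_burn:
            k = (t - n_burn) // block_len
            if k >= n_blocks:
                k = n_blocks - 1
            for j in range(n):
                block_sums[k, j] += x[j]


def sample_occupancies(
    system: TitrationSystem,
    grid: Sequence[tuple],
    n_steps: int,
    seed: int,
    burn_in: float = 0.1,
    n_blocks: int = 10,
) -> list[OccupancyResult]:
    """Metropolis sampling of site occupancies over a (pH, E_h) grid.

    One step is one attempted single-site flip.  The first ``burn_in``
    fraction of steps is discarded; the production run is split into
    ``n_blocks`` blocks whose means give the standard error.  Fully
    reproducible for a given seed.
    """
    if n_steps < 10_000:
        raise ValueError("n_steps must be at least 1e4")
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    beta = 1.0 / (KB_KCAL * system.temperature)
    W = np.ascontiguousarray(system.interaction)
    labels = [s.label for s in system.sites]
    results = []
    rng = np.random.default_rng(seed)
    for ph, e_h in grid:
        e_site = system.site_energies(ph, e_h)
        n_burn = int(burn_in * n_steps)
        block_sums = np.zeros((n_blocks, system.n_sites))
        point_seed = int(rng.integers(0, 2**31 - 1))
        _mc_kernel(e_site, W, beta, n_steps, n_burn, block_sums, point_seed)
        n_prod = n_steps - n_burn
        block_len = n_prod // n_blocks
        block_counts = np.full(n_blocks, block_len, dtype=float)
        block_counts[-1] = n_prod - block_len * (n_blocks - 1)
        block_means = block_sums / block_counts[:, None]
        frac = block_sums.sum(axis=0) / n_prod
        se = block_means.std(axis=0, ddof=1) / math.sqrt(n_blocks)
        results.append(
            OccupancyResult(
                ph=float(ph),
                e_h=float(e_h),
                fractions=dict(zip(labels, frac.tolist())),
                stderr=dict(zip(labels, se.tolist())),
                mc_steps=n_steps,
                seed=point_seed,
            )
        )
    return results


def _midpoint(eh_values: np.ndarray, fractions: np.ndarray) -> Optional[float]:
    """E_h at which the reduced fraction crosses 0.5, by linear
    interpolation; None if the curve never crosses inside the window."""
    f = fractions - 0.5
    sign_change = np.nonzero(np.diff(np.sign(f)) != 0)[0]
    if len(sign_change) == 0:
        return None
    i = sign_change[0]
    x0, x1 = eh_values[i], eh_values[i + 1]
    y0, y1 = f[i], f[i + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def redox_shift(
    system: TitrationSystem,
    site_a: str,
    site_b: str,
    grid: Sequence[float],
    eh_window: tuple = None,
    eh_step: float = 20.0,
) -> list[RedoxShiftPoint]:
    """Difference of half-occupancy midpoint potentials between two redox
    sites at each pH, from occupancy-vs-E_h curves solved exactly.

    ``eh_window`` defaults to an 800 mV window centred between the two
    intrinsic potentials; ``eh_step`` is the scan interval in mV.
    """
    ia, ib = system.site_index(site_a), system.site_index(site_b)
    for idx, lab in ((ia, site_a), (ib, site_b)):
        if system.sites[idx].site_kind != "redox":
            raise ValueError(f"site {lab!r} is not a redox site")
    if eh_window is None:
        mid = 0.5 * (
            system.sites[ia].intrinsic_value + system.sites[ib].intrinsic_value
        )
        eh_window = (mid - 400.0, mid + 400.0)
    eh_values = np.arange(eh_window[0], eh_window[1] + 0.5 * eh_step, eh_step)
    out = []
    for ph in grid:
        fr_a = np.empty(len(eh_values))
        fr_b = np.empty(len(eh_values))
        for k, eh in enumerate(eh_values):
            fr = enumerate_occupancies(system, ph, eh)
            fr_a[k], fr_b[k] = fr[ia], fr[ib]
        ma = _midpoint(eh_values, fr_a)
        mb = _midpoint(eh_values, fr_b)
        ok = ma is not None and mb is not None
        out.append(
            RedoxShiftPoint(
                ph=float(ph),
                midpoint_a=ma,
                midpoint_b=mb,
                shift_mv=(ma - mb) if ok else None,
                in_window=ok,
            )
        )
    return out
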