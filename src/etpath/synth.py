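"""Synthetic inputs with known ground truth for every analysis stage,
plus the packaged radical-migration table fixture.

Generators cover the three data classes the estimators consume:

* AR(1) Gaussian energy-gap series obeying linear response exactly
  (mean dG + lambda, variance 2 kB T lambda), so the variance and Stokes
  estimators must agree on them;
* coupled two-state titration systems small enough for exact Boltzmann
  enumeration;
* umbrella windows Metropolis-sampled from a known potential of mean
  force under the standard harmonic-bias protocol.

``table_fixture`` returns the nine tyrosine/cysteine electron-hole
transfer couples of a photoenzyme radical-migration analysis (donor-acceptor
distances from molecular dynamics, activation energies from the Marcus
treatment of the side-chain couples, deprotonated-form abundances from
continuum-electrostatics titration at pH 7), and ``mechanism_network``
the downstream reaction-branching network with its hydride-transfer and
quenching barriers.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .constants import KB_KCAL
from .marcus import ETCouple
from .network import ReactionEdge, ReactionNetwork
from .reorg import GapTrajectory
from .titration import TitrationSite, TitrationSystem
from .wham import UmbrellaWindow

__all__ = [
    "gen_gap_series",
    "gen_titration_system",
    "gen_umbrella_windows",
    "table_fixture",
    "mechanism_network",
]


def gen_gap_series(
    lambda_true: float,
    delta_g: float,
    temperature: float = 298.15,
    n: int = 10_000,
    tau_corr: float = 10.0,
    seed: int = 0,
    dt_ps: float = 1.0,
) -> GapTrajectory:
    """AR(1) Gaussian vertical-gap series with exact linear-response
    statistics: mean delta_g + lambda_true, variance 2 kB T lambda_true,
    correlation time tau_corr frames.  lambda_true = 0 degenerates to a
    constant series at delta_g."""
    if lambda_true < 0:
        raise ValueError("lambda_true must be non-negative")
    rng = np.random.default_rng(seed)
    mu = delta_g + lambda_true
    sigma = math.sqrt(2.0 * KB_KCAL * temperature * lambda_true)
    times = np.arange(n) * dt_ps
    if sigma == 0.0:
        gaps = np.full(n, mu)
    else:
        phi = math.exp(-1.0 / tau_corr)
        innov_sd = sigma * math.sqrt(1.0 - phi * phi)
        eps = rng.normal(0.0, innov_sd, size=n)
        gaps = np.empty(n)
        gaps[0] = rng.normal(mu, sigma)
        for t in range(1, n):
            gaps[t] = mu + phi * (gaps[t - 1] - mu) + eps[t]
    # equilibrium draws: nothing to trim
    return GapTrajectory(
        times=times,
        gaps=gaps,
        temperature=temperature,
        ensemble="reactant",
        equilibration_fraction=0.0,
    )


def gen_titration_system(
    n_sites: int,
    pka_range: tuple = (4.0, 10.0),
    coupling_scale: float = 1.0,
    seed: int = 0,
    temperature: float = 300.0,
) -> TitrationSystem:
    """Random coupled proton-site system: uniform intrinsic pKas in
    ``pka_range`` and symmetric pairwise couplings drawn at
    ``coupling_scale`` (kcal/mol).  Zero scale gives independent sites."""
    rng = np.random.default_rng(seed)
    pkas = rng.uniform(*pka_range, size=n_sites)
    W = np.zeros((n_sites, n_sites))
    if coupling_scale > 0:
        iu = np.triu_indices(n_sites, k=1)
        vals = rng.normal(0.0, coupling_scale, size=len(iu[0]))
        W[iu] = vals
        W = W + W.T
    sites = [
        TitrationSite(label=f"site{i}", site_kind="proton", intrinsic_value=float(p))
        for i, p in enumerate(pkas)
    ]
    return TitrationSystem(sites=sites, interaction=W, temperature=temperature)


def gen_umbrella_windows(
    pmf: Callable[[np.ndarray], np.ndarray],
    centers: Sequence[float],
    spring_k: float = 14.0,
    n_per_window: int = 10_000,
    temperature: float = 298.15,
    seed: int = 0,
    n_burn: int = 2_000,
    thin: int = 5,
) -> list[UmbrellaWindow]:
    """Metropolis samples from exp(-(U(x) + 0.5 k (x - x0)^2)/kT) for
    each window, run as parallel chains.  The acceptance rate is attached
    to each window as ``acceptance_rate``."""
    if n_per_window <= 0:
        raise ValueError("n_per_window must be positive")
    centers = np.asarray(centers, dtype=float)
    if not np.all(np.isfinite(pmf(centers))):
        raise ValueError("pmf must be finite at every window center")
    kt = KB_KCAL * temperature
    rng = np.random.default_rng(seed)
    step = 1.5 * math.sqrt(kt / spring_k)

    x = centers.copy()

    def total_u(xx: np.ndarray) -> np.ndarray:
        return np.asarray(pmf(xx)) + 0.5 * spring_k * (xx - centers) ** 2

    u = total_u(x)
    n_steps = n_burn + n_per_window * thin
    samples = np.empty((n_per_window, len(centers)))
    accepted = np.zeros(len(centers))
    k_out = 0
    for t in range(n_steps):
        prop = x + rng.normal(0.0, step, size=len(centers))
        u_prop = total_u(prop)
        acc = rng.random(len(centers)) < np.exp(np.minimum(0.0, -(u_prop - u) / kt))
        x = np.where(acc, prop, x)
        u = np.where(acc, u_prop, u)
        accepted += acc
        if t >= n_burn and (t - n_burn) % thin == 0:
            samples[k_out] = x
            k_out += 1
    acc_rates = accepted / n_steps
    windows = []
    for i, c in enumerate(centers):
        w = UmbrellaWindow(center=float(c), spring_k=spring_k, samples=samples[:, i])
        w.acceptance_rate = float(acc_rates[i])
        windows.append(w)
    return windows


# --- packaged electron-hole migration benchmark fixture ----------------

# (donor, acceptor, distance mean, distance sd, activation energy kcal/mol)
# Distances are MD averages between side chains; activation energies come
# from the Marcus treatment of the Tyr/Cys couples (tyrosinate donors 2.3,
# thiolate donors 0.1 toward a deprotonated tyrosyl radical acceptor).
_COUPLES = [
    ("Tyr90", "Tyr189-O.", 3.9, 0.4, 2.3),
    ("Tyr219", "Tyr189-O.", 9.0, 0.6, 2.3),
    ("Cys85", "Tyr189-O.", 14.2, 0.6, 0.1),
    ("Cys195", "Tyr189-O.", 11.9, 0.8, 0.1),
    ("Cys222", "Tyr189-O.", 13.4, 1.0, 0.1),
    ("Tyr189", "Tyr90-O.", 3.9, 0.4, 2.3),
    ("Cys222", "Tyr90-O.", 16.2, 1.1, 0.1),
    ("Tyr189", "Tyr219-O.", 9.0, 0.6, 2.3),
    ("Cys222", "Tyr219-O.", 4.9, 0.6, 0.1),
]

# deprotonated-form abundance of each donor at pH 7
_ABUNDANCES = {
    "Tyr90": 3.9e-3,
    "Tyr219": 4.4e-3,
    "Cys85": 1.5e-4,
    "Cys195": 3.0e-5,
    "Cys222": 1.6e-4,
    "Tyr189": 2.3e-2,
}


def table_fixture() -> tuple:
    """The nine packaged electron-hole transfer couples and the donor
    abundances used to weight their rates into velocities."""
    couples = [
        ETCouple(
            donor_label=d,
            acceptor_label=a,
            distance_mean=r,
            distance_sd=sd,
            activation_energy=eact,
        )
        for d, a, r, sd, eact in _COUPLES
    ]
    return couples, dict(_ABUNDANCES)


def mechanism_network() -> ReactionNetwork:
    """Reaction-branching network for the steps downstream of the initial
    photo-induced electron transfer: protonation of the one-electron-
    reduced substrate at C18 or C20, hydride transfer from NADPH, radical
    quenching by the cysteinyl radical, and superoxide-forming side
    reactions with O2.

    Barriers are kcal/mol inputs from the quantum-chemical analysis of
    the truncated active-site models.  The cysteinyl quench of the
    C18-protonated radical is spin-forbidden before a spin flip and also
    carries its 17.0 kcal/mol outer-sphere destabilization; the final
    electron return from reduced chlorophyllide to the cysteinyl radical
    has no resolvable outer-sphere increment.
    """
    species = {
        "PChlide-": "one-electron-reduced substrate",
        "C18H-PChlide.": "C18-protonated one-electron-reduced substrate",
        "C20H-PChlide.": "C20-protonated one-electron-reduced substrate",
        "Chlide-": "one-electron-reduced product",
        "Chlide": "closed-shell product",
        "Cys222.": "cysteinyl radical (hole reservoir)",
        "Cys222-": "thiolate",
        "O2": "triplet dioxygen",
        "superoxide": "O2 radical anion",
    }
    edges = [
        # protonation of the substrate radical anion is barrierless
        ReactionEdge("protonate_C18", "PChlide-", "C18H-PChlide.", "thermal", 0.0),
        ReactionEdge("protonate_C20", "PChlide-", "C20H-PChlide.", "thermal", 0.0),
        ReactionEdge(
            "O2_quench_PChlide-", "PChlide-", "superoxide", "et", 0.4, distance=3.6
        ),
        # productive hydride transfer vs the C20 dead end
        ReactionEdge("hydride_C18", "C18H-PChlide.", "Chlide-", "thermal", 11.3),
        ReactionEdge("hydride_C20", "C20H-PChlide.", "Chlide-", "thermal", 26.6),
        # premature quench of the C18-protonated radical by Cys222.
        ReactionEdge(
            "cys_quench_C18",
            "C18H-PChlide.",
            "PChlide-",
            "et",
            0.3,
            distance=7.3,
            spin_allowed=False,
            lambda_out_increment=17.0,
        ),
        ReactionEdge(
            "O2_quench_C18", "C18H-PChlide.", "superoxide", "et", 9.2, distance=3.6
        ),
        # termination: electron returns from Chlide- to the cysteinyl radical
        ReactionEdge(
            "electron_return_Chlide-", "Chlide-", "Chlide", "et", 5.6, distance=7.3
        ),
        ReactionEdge(
            "O2_quench_Chlide-", "Chlide-", "superoxide", "et", 0.2, distance=3.6
        ),
        # superoxide hands its electron back to the cysteinyl radical
        ReactionEdge(
            "superoxide_to_cys", "superoxide", "Cys222-", "et", 0.05, distance=3.6
        ),
    ]
    return ReactionNetwork(species=species, edges=edges)
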