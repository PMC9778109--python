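"""Marcus activation energies, Moser-Dutton tunneling rates, and
abundance-weighted electron-transfer velocities.

The model: reactant and product free-energy surfaces along a collective
reaction coordinate x are parabolas

    E_R(x) = lambda_R * x**2
    E_P(x) = delta_G + lambda_P * (x - 1)**2

with the reactant minimum at x = 0 and the product minimum at x = 1.
The activation energy is the height of the lowest-energy crossing of the
two parabolas above the reactant minimum.  When the two reorganization
energies are equal this reduces to the textbook closed form
(delta_G + lambda)**2 / (4 * lambda), with the inverted region appearing
for -delta_G > lambda.

Rates follow the empirical protein electron-tunneling ruler

    log10 k_ET = 15.0 - 0.6 R - 12.4 dG_act[eV]

with R the donor-acceptor distance in angstroms.  Pathway velocities
weight each rate by the abundance of the reactive (deprotonated) form of
the donor:  log10 v_ET = log10 k_ET + log10(abundance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .constants import KCAL_PER_EV

__all__ = [
    "ETCouple",
    "MarcusResult",
    "RateResult",
    "VelocityRecord",
    "marcus_activation",
    "moser_dutton_log_rate",
    "moser_dutton_log_rate_symmetric",
    "transfer_velocity",
    "rank_pathways",
]


@dataclass(frozen=True)
class ETCouple:
    """One donor -> acceptor electron transfer.

    Energies are kcal/mol, distances angstroms.  A rate needs either a
    precomputed ``activation_energy`` or the triple
    (``delta_g``, ``lambda_reactant``, ``lambda_product``).
    ``delta_g`` is products minus reactants.
    """

    donor_label: str
    acceptor_label: str
    distance_mean: float
    distance_sd: Optional[float] = None
    delta_g: Optional[float] = None
    lambda_reactant: Optional[float] = None
    lambda_product: Optional[float] = None
    activation_energy: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.distance_mean > 0:
            raise ValueError(f"distance_mean must be > 0, got {self.distance_mean}")
        for name in ("lambda_reactant", "lambda_product"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when given, got {v}")
        if self.activation_energy is not None and self.activation_energy < 0:
            raise ValueError("activation_energy must be >= 0")
        if self.activation_energy is None and not self._has_marcus_inputs():
            raise ValueError(
                f"couple {self.donor_label}->{self.acceptor_label}: need either "
                "activation_energy or (delta_g, lambda_reactant, lambda_product)"
            )

    def _has_marcus_inputs(self) -> bool:
        return (
            self.delta_g is not None
            and self.lambda_reactant is not None
            and self.lambda_product is not None
        )

    def resolve_activation_energy(self) -> float:
        """Activation energy in kcal/mol, computed from Marcus inputs if
        not given directly."""
        if self.activation_energy is not None:
            return self.activation_energy
        res = marcus_activation(self.delta_g, self.lambda_reactant, self.lambda_product)
        return res.activation_energy


@dataclass(frozen=True)
class MarcusResult:
    """Crossing of the two Marcus parabolas.

    ``crossing_coordinate`` lies in [0, 1] for a normal-region transfer;
    ``inverted`` is set when the crossing falls behind the reactant
    minimum (x < 0), the signature of the Marcus inverted region.
    """

    activation_energy: float
    crossing_coordinate: float
    inverted: bool
    reverse_activation_energy: float


@dataclass(frozen=True)
class RateResult:
    log10_rate: float
    distance_used: float
    activation_energy_used: float


@dataclass(frozen=True)
class VelocityRecord:
    """One row of a pathway-velocity report."""

    donor_label: str
    acceptor_label: str
    distance_mean: float
    distance_sd: Optional[float]
    log10_rate: float
    abundance: Optional[float]
    log10_velocity: float
    top_for_acceptor: bool = False
    #: (low, high) log10 rate from distance_mean +/- 1 sd; report-only.
    log10_rate_band: Optional[tuple] = None
    error: Optional[str] = None


def marcus_activation(
    delta_g: float, lambda_r: float, lambda_p: float
) -> MarcusResult:
    """Activation energy from the crossing of two Marcus parabolas with
    possibly different reactant/product reorganization energies.

    Solves E_R(x) = E_P(x) for the quadratic
    (lambda_r - lambda_p) x^2 + 2 lambda_p x - (lambda_p + delta_g) = 0
    and returns the lowest-energy real crossing (smallest |x|, since
    E_R = lambda_r x^2 grows monotonically in |x|).

    Parameters are kcal/mol; ``delta_g`` is products minus reactants.
    """
    if not (lambda_r > 0 and lambda_p > 0):
        raise ValueError("reorganization energies must be positive")

    a = lambda_r - lambda_p
    b = 2.0 * lambda_p
    c = -(lambda_p + delta_g)

    if abs(a) < 1e-12 * max(lambda_r, lambda_p):
        # equal lambdas: single crossing, textbook closed form
        x = (lambda_p + delta_g) / (2.0 * lambda_p)
        roots = [x]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError(
                "Marcus parabolas do not intersect for "
                f"delta_g={delta_g}, lambda_r={lambda_r}, lambda_p={lambda_p}"
            )
        sq = math.sqrt(disc)
        roots = [(-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)]

    x_star = min(roots, key=lambda x: abs(x))
    e_act = lambda_r * x_star * x_star
    inverted = x_star < 0 or (
        abs(lambda_r - lambda_p) < 1e-12 * max(lambda_r, lambda_p)
        and -delta_g > lambda_r
    )
    return MarcusResult(
        activation_energy=e_act,
        crossing_coordinate=x_star,
        inverted=inverted,
        reverse_activation_energy=e_act - delta_g,
    )


def moser_dutton_log_rate(distance: float, activation_energy: float) -> RateResult:
    """log10 of the electron-tunneling rate (s^-1) from the ruler
    15.0 - 0.6 R - 12.4 dG_act, with dG_act converted from kcal/mol to eV.
    """
    if not distance > 0:
        raise ValueError("distance must be positive")
    if activation_energy < 0:
        raise ValueError("activation energy must be non-negative (no silent clamp)")
    log10_k = 15.0 - 0.6 * distance - 12.4 * (activation_energy / KCAL_PER_EV)
    return RateResult(
        log10_rate=log10_k,
        distance_used=distance,
        activation_energy_used=activation_energy,
    )


def moser_dutton_log_rate_symmetric(
    distance: float, delta_g: float, lambda_: float
) -> RateResult:
    """Ruler in its symmetric-reorganization form,
    15.0 - 0.6 R - 3.1 (dG + lambda)^2 / lambda with dG and lambda in eV.

    Equivalent to :func:`moser_dutton_log_rate` with the symmetric Marcus
    activation energy (dG + lambda)^2 / (4 lambda), since 12.4/4 = 3.1.
    """
    if not distance > 0:
        raise ValueError("distance must be positive")
    if not lambda_ > 0:
        raise ValueError("reorganization energy must be positive")
    eact_ev = (delta_g + lambda_) ** 2 / (4.0 * lambda_)
    log10_k = 15.0 - 0.6 * distance - 12.4 * eact_ev
    return RateResult(
        log10_rate=log10_k,
        distance_used=distance,
        activation_energy_used=eact_ev * KCAL_PER_EV,
    )


def transfer_velocity(log10_rate: float, abundance: float) -> float:
    """log10 transfer velocity: the rate weighted by the abundance of the
    reactive (deprotonated) donor form."""
    if not (0.0 < abundance <= 1.0):
        raise ValueError(f"abundance must be in (0, 1], got {abundance}")
    return log10_rate + math.log10(abundance)


def rank_pathways(
    couples: Sequence[ETCouple], abundances: Mapping[str, float]
) -> list[VelocityRecord]:
    """Velocity table for a set of transfer couples.

    Each couple's rate comes from the tunneling ruler at its distance and
    (resolved) activation energy; the velocity weights the rate by the
    donor's reactive-form abundance.  Records are sorted by descending
    velocity; the fastest route into each acceptor is flagged.  A couple
    whose donor has no abundance yields an error record, not a silent drop.
    """
    records: list[VelocityRecord] = []
    for c in couples:
        eact = c.resolve_activation_energy()
        rate = moser_dutton_log_rate(c.distance_mean, eact)
        band = None
        if c.distance_sd is not None:
            lo = moser_dutton_log_rate(c.distance_mean + c.distance_sd, eact).log10_rate
            hi = moser_dutton_log_rate(
                max(c.distance_mean - c.distance_sd, 1e-9), eact
            ).log10_rate
            band = (lo, hi)
        if c.donor_label not in abundances:
            records.append(
                VelocityRecord(
                    donor_label=c.donor_label,
                    acceptor_label=c.acceptor_label,
                    distance_mean=c.distance_mean,
                    distance_sd=c.distance_sd,
                    log10_rate=rate.log10_rate,
                    abundance=None,
                    log10_velocity=float("nan"),
                    log10_rate_band=band,
                    error=f"no abundance for donor {c.donor_label!r}",
                )
            )
            continue
        ab = abundances[c.donor_label]
        records.append(
            VelocityRecord(
                donor_label=c.donor_label,
                acceptor_label=c.acceptor_label,
                distance_mean=c.distance_mean,
                distance_sd=c.distance_sd,
                log10_rate=rate.log10_rate,
                abundance=ab,
                log10_velocity=transfer_velocity(rate.log10_rate, ab),
                log10_rate_band=band,
            )
        )

    ok = [r for r in records if r.error is None]
    bad = [r for r in records if r.error is not None]
    ok.sort(key=lambda r: -r.log10_velocity)

    # flag the fastest route into each acceptor (the table's bolding rule)
    best: dict[str, float] = {}
    for r in ok:
        if r.acceptor_label not in best:
            best[r.acceptor_label] = r.log10_velocity
    flagged = [
        VelocityRecord(
            **{**r.__dict__, "top_for_acceptor": r.log10_velocity == best[r.acceptor_label]}
        )
        for r in ok
    ]
    return flagged + bad
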