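"""Branching analysis over a small reaction network of electron-transfer
and thermally activated steps.

Competing channels out of a species are compared through their rates:
electron-transfer edges use the Moser-Dutton tunneling ruler (they need a
donor-acceptor distance), while bond-making/-breaking steps (proton or
hydride transfers, conformational gates) use transition-state theory,

    k = (kB T / h) * exp(-dG_act / R T)       (transmission coefficient 1).

Spin-forbidden edges are excluded from the branching with an explicit
note rather than silently dropped: the model carries no spin-flip rate,
so a forbidden channel contributes zero until a flip is assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .constants import H_J, KB_J, R_KCAL
from .marcus import moser_dutton_log_rate

__all__ = ["ReactionEdge", "ReactionNetwork", "BranchResult", "eyring_rate", "branch_ratio"]


@dataclass(frozen=True)
class ReactionEdge:
    """One directed step.  ``kind`` is "et" (tunneling; requires
    ``distance``) or "thermal" (transition-state theory).  An optional
    ``lambda_out`` adds an outer-sphere destabilization (kcal/mol) to the
    activation energy of an et edge."""

    name: str
    source: str
    target: str
    kind: str  # "et" | "thermal"
    activation_energy: float  # kcal/mol
    distance: Optional[float] = None  # angstrom, et edges only
    spin_allowed: bool = True
    lambda_out_increment: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("et", "thermal"):
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.activation_energy < 0:
            raise ValueError("activation_energy must be >= 0")
        if self.kind == "et" and self.distance is None:
            raise ValueError(f"et edge {self.name!r} needs a distance")

    def effective_activation_energy(self) -> float:
        return self.activation_energy + self.lambda_out_increment

    def rate(self, temperature: float) -> float:
        """First-order rate in s^-1 (spin ignored; see branch_ratio)."""
        if self.kind == "thermal":
            return eyring_rate(self.effective_activation_energy(), temperature)
        log10_k = moser_dutton_log_rate(
            self.distance, self.effective_activation_energy()
        ).log10_rate
        return 10.0**log10_k


@dataclass
class ReactionNetwork:
    species: dict  # label -> role tag (free-form)
    edges: list

    def __post_init__(self) -> None:
        for e in self.edges:
            for lab in (e.source, e.target):
                if lab not in self.species:
                    raise ValueError(f"edge {e.name!r} references unknown species {lab!r}")

    def edges_from(self, species: str) -> list:
        return [e for e in self.edges if e.source == species]

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        """Build from a plain mapping (the YAML/JSON on-disk form)."""
        species = dict(d["species"])
        edges = [
            ReactionEdge(
                name=e["name"],
                source=e["source"],
                target=e["target"],
                kind=e.get("kind", e.get("type", "thermal")),
                activation_energy=float(e["activation_energy"]),
                distance=e.get("distance"),
                spin_allowed=bool(e.get("spin_allowed", True)),
                lambda_out_increment=float(e.get("lambda_out_increment", 0.0)),
            )
            for e in d["edges"]
        ]
        return cls(species=species, edges=edges)


@dataclass(frozen=True)
class BranchResult:
    species: str
    temperature: float
    rates: dict  # edge name -> s^-1 (allowed edges)
    fractions: dict  # edge name -> branching fraction, sums to 1
    excluded: dict  # edge name -> reason

    def ratio(self, edge_a: str, edge_b: str) -> float:
        return self.rates[edge_a] / self.rates[edge_b]


def eyring_rate(activation_energy: float, temperature: float = 298.15) -> float:
    """Transition-state-theory rate (s^-1), transmission coefficient 1."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    prefactor = KB_J * temperature / H_J
    return prefactor * math.exp(-activation_energy / (R_KCAL * temperature))


def branch_ratio(
    network: ReactionNetwork, species: str, temperature: float = 298.15
) -> BranchResult:
    """Normalized branching fractions over the allowed channels leaving
    ``species``, with spin-forbidden channels excluded and noted."""
    out = network.edges_from(species)
    if not out:
        raise ValueError(f"species {species!r} has no outgoing edges")
    rates = {}
    excluded = {}
    for e in out:
        if not e.spin_allowed:
            excluded[e.name] = "spin-forbidden (excluded until a spin flip occurs)"
            continue
        rates[e.name] = e.rate(temperature)
    total = sum(rates.values())
    fractions = {k: v / total for k, v in rates.items()} if total > 0 else {}
    return BranchResult(
        species=species,
        temperature=temperature,
        rates=rates,
        fractions=fractions,
        excluded=excluded,
    )
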