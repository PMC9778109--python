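"""Readers and writers for the package's tabular on-disk formats.

All formats are plain TSV/CSV (pandas does the parsing) plus YAML/JSON
for reaction networks:

* couples:      donor,acceptor,distance_mean,distance_sd,activation_energy,
                delta_g,lambda_reactant,lambda_product   (blank = absent)
* abundances:   label,fraction
* velocity table (output): donor,acceptor,distance,log_kET,abundance,
                log_vET,top_flag
* gap series:   two columns time_ps, gap_kcal (whitespace or comma)
* umbrella metadata: center,spring_k,file  with one-value-per-line
                sample files
* titration sites: label,kind,intrinsic,charge ; interactions:
                label_a,label_b,energy_kcal
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .marcus import ETCouple, VelocityRecord
from .network import ReactionNetwork
from .reorg import GapTrajectory
from .titration import TitrationSite, TitrationSystem
from .wham import UmbrellaWindow

__all__ = [
    "read_couples",
    "read_abundances",
    "write_velocity_table",
    "read_gap_trajectory",
    "read_umbrella_windows",
    "read_titration_system",
    "write_occupancies",
    "read_network",
]


def _sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_couples(path) -> list[ETCouple]:
    df = pd.read_csv(path, sep=_sep(path))
    required = {"donor", "acceptor", "distance_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"couples file missing columns: {sorted(missing)}")

    def get(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    return [
        ETCouple(
            donor_label=str(row["donor"]),
            acceptor_label=str(row["acceptor"]),
            distance_mean=float(row["distance_mean"]),
            distance_sd=get(row, "distance_sd"),
            delta_g=get(row, "delta_g"),
            lambda_reactant=get(row, "lambda_reactant"),
            lambda_product=get(row, "lambda_product"),
            activation_energy=get(row, "activation_energy"),
        )
        for _, row in df.iterrows()
    ]


def read_abundances(path) -> dict:
    df = pd.read_csv(path, sep=_sep(path))
    if not {"label", "fraction"} <= set(df.columns):
        raise ValueError("abundances file needs columns label,fraction")
    return dict(zip(df["label"].astype(str), df["fraction"].astype(float)))


def velocity_frame(records: Sequence[VelocityRecord], ndigits: int = 1) -> pd.DataFrame:
    """Report-layer frame; log values rounded only here."""
    rows = []
    for r in records:
        rows.append(
            {
                "donor": r.donor_label,
                "acceptor": r.acceptor_label,
                "distance": r.distance_mean,
                "log_kET": round(r.log10_rate, ndigits),
                "abundance": r.abundance,
                "log_vET": (
                    round(r.log10_velocity, ndigits) if r.error is None else float("nan")
                ),
                "top_flag": r.top_for_acceptor,
                "error": r.error or "",
            }
        )
    return pd.DataFrame(rows)


def write_velocity_table(records: Sequence[VelocityRecord], path) -> None:
    velocity_frame(records).to_csv(path, sep="\t", index=False)


def read_gap_trajectory(path, temperature: float = 298.15, **kw) -> GapTrajectory:
    arr = np.loadtxt(path, delimiter="," if _sep(path) == "," else None)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("gap file must have two columns: time_ps gap_kcal")
    return GapTrajectory(times=arr[:, 0], gaps=arr[:, 1], temperature=temperature, **kw)


def read_umbrella_windows(meta_path) -> list[UmbrellaWindow]:
    meta_path = Path(meta_path)
    df = pd.read_csv(meta_path, sep=_sep(meta_path))
    if not {"center", "spring_k", "file"} <= set(df.columns):
        raise ValueError("window metadata needs columns center,spring_k,file")
    windows = []
    for _, row in df.iterrows():
        sample_path = Path(row["file"])
        if not sample_path.is_absolute():
            sample_path = meta_path.parent / sample_path
        samples = np.loadtxt(sample_path)
        windows.append(
            UmbrellaWindow(
                center=float(row["center"]),
                spring_k=float(row["spring_k"]),
                samples=np.atleast_1d(samples),
            )
        )
    return windows


def read_titration_system(
    sites_path, interactions_path=None, temperature: float = 300.0
) -> TitrationSystem:
    df = pd.read_csv(sites_path, sep=_sep(sites_path))
    if not {"label", "kind", "intrinsic"} <= set(df.columns):
        raise ValueError("sites file needs columns label,kind,intrinsic[,charge]")
    sites = [
        TitrationSite(
            label=str(r["label"]),
            site_kind=str(r["kind"]),
            intrinsic_value=float(r["intrinsic"]),
            reference_form_charge=int(r["charge"]) if "charge" in df.columns else 0,
        )
        for _, r in df.iterrows()
    ]
    n = len(sites)
    index = {s.label: i for i, s in enumerate(sites)}
    W = np.zeros((n, n))
    if interactions_path is not None:
        wdf = pd.read_csv(interactions_path, sep=_sep(interactions_path))
        for _, r in wdf.iterrows():
            i, j = index[str(r["label_a"])], index[str(r["label_b"])]
            W[i, j] = W[j, i] = float(r["energy_kcal"])
    return TitrationSystem(sites=sites, interaction=W, temperature=temperature)


def write_occupancies(results, path) -> None:
    rows = []
    for res in results:
        for label, frac in res.fractions.items():
            rows.append(
                {
                    "pH": res.ph,
                    "Eh_mV": res.e_h,
                    "label": label,
                    "fraction": frac,
                    "stderr": res.stderr[label],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_network(path) -> ReactionNetwork:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return ReactionNetwork.from_dict(d)
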