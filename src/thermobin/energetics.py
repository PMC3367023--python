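"""Chemical-affinity estimation for chemolithotrophic reactions.

The affinity of reaction r, ``A_r = 2.303 R T log10(K_r / Q_r)``, measures
the energy available from catalysing the reaction at in-situ conditions;
positive values mean energy is available.  For alkaline hot-spring outflow
fluids the affinity per mole of electrons transferred is, to good
approximation, linear in pH, so each reaction is summarised by a
(slope, intercept) pair in kcal/(mol e-)/pH and kcal/(mol e-) plus the
number of electrons transferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Gas constant in kcal mol-1 K-1.
R_KCAL = 1.9872e-3
#: ln(10); converts log10 ratios to natural-log form.
LOG10 = 2.303

KCAL_TO_KJ = 4.184


@dataclass(frozen=True)
class ReactionEnergetics:
    """Per-reaction energetic parameters (affinity linear in pH)."""

    reaction_id: str
    slope: float  # kcal / (mol e-) per pH unit
    intercept: float  # kcal / (mol e-) at pH 0
    n_electrons: int
    oxidant: str = ""
    reductant: str = ""

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError(f"{self.reaction_id}: n_electrons must be >= 1")


@dataclass(frozen=True)
class SiteConditions:
    """Measured field conditions at one sampling site."""

    site_id: str
    temperature_c: float
    ph: float

    def __post_init__(self) -> None:
        if self.temperature_c <= -273.15:
            raise ValueError("temperature below absolute zero")
        if not (0.0 < self.ph < 14.0):
            raise ValueError(f"pH {self.ph} outside (0, 14)")


def affinity_from_logs(log_k: float, log_q: float, temperature_k: float) -> float:
    """Affinity in kcal/mol from log10 equilibrium constant and activity product.

    ``A = 2.303 * R * T * (logK - logQ)``; zero at equilibrium, positive when
    the reaction as written releases energy.
    """
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive kelvin, got {temperature_k}")
    return LOG10 * R_KCAL * temperature_k * (log_k - log_q)


def affinity_linear(
    reaction: ReactionEnergetics, site: SiteConditions, units: str = "kcal"
) -> tuple[float, float]:
    """Per-electron and total affinity of one reaction at one site.

    Returns ``(A_per_electron, A_total)`` where the per-electron value is
    ``slope * pH + intercept`` and the total multiplies by the number of
    electrons transferred.  ``units`` is ``kcal`` (default) or ``kJ``.
    """
    per_e = reaction.slope * site.ph + reaction.intercept
    if units == "kJ":
        per_e *= KCAL_TO_KJ
    elif units != "kcal":
        raise ValueError(f"unknown units {units!r}")
    return per_e, per_e * reaction.n_electrons


def affinity_table(
    reactions: Sequence[ReactionEnergetics],
    sites: Sequence[SiteConditions],
    units: str = "kcal",
) -> pd.DataFrame:
    """Long-format table of affinities: one row per (reaction, site)."""
    rows = []
    for rxn in reactions:
        for site in sites:
            per_e, total = affinity_linear(rxn, site, units=units)
            rows.append(
                {
                    "reaction_id": rxn.reaction_id,
                    "site_id": site.site_id,
                    "ph": site.ph,
                    "affinity_per_electron": per_e,
                    "affinity_total": total,
                    "n_electrons": rxn.n_electrons,
                    "oxidant": rxn.oxidant,
                    "reductant": rxn.reductant,
                }
            )
    return pd.DataFrame(rows)


def rank_reactions(affinities: pd.DataFrame) -> dict[str, object]:
    """Rank reactions per site and summarise cross-site sign behaviour.

    Input is the long-format table from :func:`affinity_table`.  Returns a
    dict with:

    ``ranked``
        copy of the table with a per-site ``rank`` column (1 = most
        positive affinity; ties broken by reaction id).
    ``sign_crossing``
        sorted reaction ids whose per-electron affinity is positive at at
        least one site and negative at another.
    ``always_negative``
        sorted reaction ids with negative affinity at every site.
    """
    df = affinities.sort_values(
        ["site_id", "affinity_per_electron", "reaction_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).copy()
    df["rank"] = df.groupby("site_id").cumcount() + 1

    crossing: list[str] = []
    negative: list[str] = []
    for rid, grp in df.groupby("reaction_id"):
        vals = grp["affinity_per_electron"].to_numpy()
        if (vals > 0).any() and (vals < 0).any():
            crossing.append(rid)
        if (vals < 0).all():
            negative.append(rid)
    return {
        "ranked": df.reset_index(drop=True),
        "sign_crossing": sorted(crossing),
        "always_negative": sorted(negative),
    }
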