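"""Per-specimen lipidome summary variables used as regression responses.

The double bond index (DBI) and mean chain length are mole-fraction-weighted
means over a basis pool of fatty acids; by default the even-chain fatty acid
pool, renormalized so each metric is a true weighted mean.  Saturation-class
totals (SFA/MUFA/PUFA), odd-chain fatty acid (OCFA) totals and fatty-alcohol
totals are plain sums over the full profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import pandas as pd

from .lipids import CompositionProfile, LipidSpecies

__all__ = [
    "MetricsRow",
    "double_bond_index",
    "mean_chain_length",
    "class_fractions",
    "group_totals",
    "metrics_row",
    "metrics_table",
    "BASIS_EVEN_CHAIN_FA",
    "BASIS_ALL_FA",
]

#: default basis: even-chain fatty acids (alcohols and OCFAs excluded)
BASIS_EVEN_CHAIN_FA: Callable[[LipidSpecies], bool] = (
    lambda sp: sp.is_fatty_acid and not sp.odd_chain
)
#: widened basis: every fatty acid regardless of parity
BASIS_ALL_FA: Callable[[LipidSpecies], bool] = lambda sp: sp.is_fatty_acid


@dataclass(frozen=True)
class MetricsRow:
    sample_id: str
    dbi: float
    chain_length: float
    sfa: float
    mufa: float
    pufa: float
    ocfa: float
    alcohol: float


def _renormalized_basis(
    profile: CompositionProfile, basis: Callable[[LipidSpecies], bool]
) -> dict[LipidSpecies, float]:
    pool = profile.subset(basis)
    total = sum(pool.values())
    if total <= 0.0:
        raise ValueError(
            f"basis pool is empty for sample {profile.sample_id}: "
            "no fatty acid of the requested subset has positive mole fraction"
        )
    return {sp: x / total for sp, x in pool.items()}


def double_bond_index(
    profile: CompositionProfile,
    basis: Callable[[LipidSpecies], bool] = BASIS_EVEN_CHAIN_FA,
) -> float:
    """Mean number of double bonds per acyl chain over the basis pool."""
    pool = _renormalized_basis(profile, basis)
    return sum(x * sp.double_bonds for sp, x in pool.items())


def mean_chain_length(
    profile: CompositionProfile,
    basis: Callable[[LipidSpecies], bool] = BASIS_EVEN_CHAIN_FA,
) -> float:
    """Mean carbon count per acyl chain over the basis pool."""
    pool = _renormalized_basis(profile, basis)
    return sum(x * sp.carbons for sp, x in pool.items())


def class_fractions(profile: CompositionProfile) -> tuple[float, float, float]:
    """Total mole fraction of each fatty acid saturation class.

    Returns ``(sfa, mufa, pufa)``; fatty alcohols are excluded, so the
    three classes sum to the total fatty-acid fraction.
    """
    sfa = mufa = pufa = 0.0
    for sp, x in profile.entries.items():
        if not sp.is_fatty_acid:
            continue
        if sp.double_bonds == 0:
            sfa += x
        elif sp.double_bonds == 1:
            mufa += x
        else:
            pufa += x
    return sfa, mufa, pufa


def group_totals(profile: CompositionProfile) -> tuple[float, float]:
    """Totals of odd-chain fatty acids and of fatty alcohols."""
    ocfa = sum(x for sp, x in profile.entries.items() if sp.is_fatty_acid and sp.odd_chain)
    alcohol = sum(x for sp, x in profile.entries.items() if sp.is_alcohol)
    return ocfa, alcohol


def metrics_row(
    profile: CompositionProfile,
    basis: Callable[[LipidSpecies], bool] = BASIS_EVEN_CHAIN_FA,
) -> MetricsRow:
    sfa, mufa, pufa = class_fractions(profile)
    ocfa, alcohol = group_totals(profile)
    return MetricsRow(
        sample_id=profile.sample_id,
        dbi=double_bond_index(profile, basis),
        chain_length=mean_chain_length(profile, basis),
        sfa=sfa,
        mufa=mufa,
        pufa=pufa,
        ocfa=ocfa,
        alcohol=alcohol,
    )


def metrics_table(
    profiles: Iterable[CompositionProfile],
    basis: Callable[[LipidSpecies], bool] = BASIS_EVEN_CHAIN_FA,
) -> pd.DataFrame:
    """One MetricsRow per sample as a DataFrame indexed by sample_id."""
    rows = [metrics_row(p, basis) for p in profiles]
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")
    return df
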