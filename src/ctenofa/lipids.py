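"""Lipid species identities and per-specimen composition profiles.

A lipid species here is a fatty acid (quantified as its methyl ester, FAME)
or a fatty alcohol, identified by its carbon count and number of double
bonds.  Saturation class (SFA/MUFA/PUFA), odd/even chain parity, and the
molar mass of the analyzed derivative are all derived from that identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "LipidSpecies",
    "CompositionProfile",
    "parse_lipid_label",
]

_LABEL_RE = re.compile(
    r"^\s*C(?P<carbons>\d+):(?P<db>\d+)"
    r"(?:\s*\(\s*n-(?P<omega>\d+)\s*\))?"
    r"(?P<alcohol>\s+(?:alcohol|OH))?\s*$",
    re.IGNORECASE,
)

# atomic masses (g/mol), CODATA-style values sufficient for GC-MS work
_M_C, _M_H, _M_O = 12.011, 1.008, 15.999


@dataclass(frozen=True)
class LipidSpecies:
    """A fatty acid or fatty alcohol identified by chain structure.

    Parameters
    ----------
    carbons : int
        Number of carbon atoms in the acyl/alkyl chain (>= 4).
    double_bonds : int
        Number of carbon-carbon double bonds; bounded by the chain length.
    backbone : str
        ``"fatty-acid"`` or ``"fatty-alcohol"``.
    omega : int or None
        Optional (n-x) double-bond position, carried for display only.
    """

    carbons: int
    double_bonds: int = 0
    backbone: str = "fatty-acid"
    omega: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 4:
            raise ValueError(f"carbon count must be >= 4, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double bond count must be >= 0")
        if self.double_bonds > (self.carbons - 2) // 2:
            raise ValueError(
                f"C{self.carbons} chain cannot carry {self.double_bonds} "
                "methylene-interrupted double bonds"
            )
        if self.backbone not in ("fatty-acid", "fatty-alcohol"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    # -- derived identity ------------------------------------------------
    @property
    def is_alcohol(self) -> bool:
        return self.backbone == "fatty-alcohol"

    @property
    def is_fatty_acid(self) -> bool:
        return self.backbone == "fatty-acid"

    @property
    def odd_chain(self) -> bool:
        """Odd carbon count marks bacterially derived chains (OCFA)."""
        return self.carbons % 2 == 1

    @property
    def saturation_class(self) -> str:
        """SFA (0 double bonds), MUFA (1) or PUFA (>=2)."""
        if self.double_bonds == 0:
            return "SFA"
        if self.double_bonds == 1:
            return "MUFA"
        return "PUFA"

    @property
    def label(self) -> str:
        base = f"C{self.carbons}:{self.double_bonds}"
        if self.omega is not None:
            base += f"(n-{self.omega})"
        if self.is_alcohol:
            base += " alcohol"
        return base

    @property
    def molar_mass(self) -> float:
        """Molar mass (g/mol) of the analyzed derivative.

        Fatty acids are measured as methyl esters C(n+1)H(2n+2-2d)O2;
        fatty alcohols run underivatized as CnH(2n+2-2d)O.
        """
        n, d = self.carbons, self.double_bonds
        if self.is_fatty_acid:
            return (n + 1) * _M_C + (2 * n + 2 - 2 * d) * _M_H + 2 * _M_O
        return n * _M_C + (2 * n + 2 - 2 * d) * _M_H + _M_O

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_lipid_label(label: str) -> LipidSpecies:
    """Parse a compound label such as ``C18:1``, ``C18:1(n-9)`` or
    ``C22:1(n-9) alcohol`` into a :class:`LipidSpecies`.

    Raises
    ------
    ValueError
        If the label does not match any accepted dialect.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unparseable lipid label: {label!r}")
    omega = m.group("omega")
    return LipidSpecies(
        carbons=int(m.group("carbons")),
        double_bonds=int(m.group("db")),
        backbone="fatty-alcohol" if m.group("alcohol") else "fatty-acid",
        omega=int(omega) if omega else None,
    )


class CompositionProfile:
    """One specimen's mole-fraction vector over identified lipid species.

    Fractions must be non-negative and sum to 1 (closure) within ``tol``.
    """

    def __init__(
        self,
        sample_id: str,
        entries: Mapping[LipidSpecies | str, float],
        tol: float = 1e-9,
    ) -> None:
        parsed: dict[LipidSpecies, float] = {}
        for key, frac in entries.items():
            sp = parse_lipid_label(key) if isinstance(key, str) else key
            if frac < -tol:
                raise ValueError(
                    f"negative mole fraction {frac} for {sp.label} in {sample_id}"
                )
            parsed[sp] = max(float(frac), 0.0)
        total = sum(parsed.values())
        if abs(total - 1.0) > max(tol, 1e-9):
            raise ValueError(
                f"mole fractions for {sample_id} sum to {total}, expected 1"
            )
        self.sample_id = sample_id
        self.entries: dict[LipidSpecies, float] = parsed

    def __getitem__(self, key: LipidSpecies | str) -> float:
        sp = parse_lipid_label(key) if isinstance(key, str) else key
        return self.entries.get(sp, 0.0)

    def __iter__(self) -> Iterable[LipidSpecies]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def species(self) -> list[LipidSpecies]:
        return list(self.entries)

    def subset(self, keep) -> dict[LipidSpecies, float]:
        """Entries whose species satisfy predicate ``keep`` (not renormalized)."""
        return {sp: x for sp, x in self.entries.items() if keep(sp)}

    def __repr__(self) -> str:  # pragma: no cover
        return f"CompositionProfile({self.sample_id!r}, {len(self)} species)"
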