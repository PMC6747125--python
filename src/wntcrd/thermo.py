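"""Dissociation-constant thermodynamics and ordinal affinity-range classes.

Binding free energies and dissociation constants are related by
``dG = RT ln Kd`` with Kd in molar units.  Throughout the package Kd is
carried in nM (the unit experimental Wnt--Frizzled CRD affinities are
reported in) and converted to molar inside the formula; dG is in kcal/mol.

Affinity ranges are the ordinal bins used to summarise predictions:
``++++`` (< 10 nM, tightest) down to ``-`` (> 400 nM).
"""

from __future__ import annotations

import enum
import math

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE_K",
    "AffinityRange",
    "delta_g_from_kd",
    "kd_from_delta_g",
    "classify_affinity",
    "range_distance",
]

#: Gas constant in kcal K^-1 mol^-1.
GAS_CONSTANT_KCAL: float = 1.987e-3

#: Standard temperature in K.
STANDARD_TEMPERATURE_K: float = 298.0

_NM_PER_MOLAR = 1e9


class AffinityRange(enum.IntEnum):
    """Ordinal affinity-range class; higher value = tighter binding."""

    NONE = 0        # > 400 nM
    LOW = 1         # 100-400 nM
    MODERATE = 2    # 40-100 nM
    HIGH = 3        # 10-40 nM
    VERY_HIGH = 4   # < 10 nM

    @property
    def symbol(self) -> str:
        return _SYMBOLS[self]

    @classmethod
    def from_symbol(cls, symbol: str) -> "AffinityRange":
        s = symbol.strip().replace("−", "-")
        try:
            return _FROM_SYMBOL[s]
        except KeyError:
            raise ValueError(f"unknown affinity range symbol: {symbol!r}") from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbol


_SYMBOLS = {
    AffinityRange.NONE: "-",
    AffinityRange.LOW: "+",
    AffinityRange.MODERATE: "++",
    AffinityRange.HIGH: "+++",
    AffinityRange.VERY_HIGH: "++++",
}
_FROM_SYMBOL = {v: k for k, v in _SYMBOLS.items()}


def _rt(temperature: float) -> float:
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT_KCAL * temperature


def delta_g_from_kd(kd_nm: float, temperature: float = STANDARD_TEMPERATURE_K) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant in nM.

    ``dG = RT ln(Kd)`` with Kd expressed in molar units, so any Kd below
    1 M (1e9 nM) gives a negative dG.  Strictly increasing in Kd.

    Raises
    ------
    ValueError
        If ``kd_nm`` is not strictly positive.
    """
    if not kd_nm > 0:
        raise ValueError(f"Kd must be strictly positive, got {kd_nm} nM")
    return _rt(temperature) * math.log(kd_nm / _NM_PER_MOLAR)


def kd_from_delta_g(dg_kcal_mol: float, temperature: float = STANDARD_TEMPERATURE_K) -> float:
    """Dissociation constant in nM from a binding free energy in kcal/mol.

    Exact inverse of :func:`delta_g_from_kd`.
    """
    return math.exp(dg_kcal_mol / _rt(temperature)) * _NM_PER_MOLAR


def classify_affinity(kd_nm: float) -> AffinityRange:
    """Ordinal affinity range for a dissociation constant in nM.

    Bins: < 10 nM ``++++``; 10-40 nM ``+++``; 40-100 nM ``++``;
    100-400 nM ``+``; > 400 nM ``-``.  The printed 10-40 style ranges are
    read as closed at both ends, so an exact boundary value takes the
    higher-affinity label (40 nM -> ``+++``, 100 nM -> ``++``,
    400 nM -> ``+``), while "< 10 nM" is strict.

    Classification is monotone non-increasing in Kd.
    """
    if not kd_nm > 0:
        raise ValueError(f"Kd must be strictly positive, got {kd_nm} nM")
    if kd_nm < 10.0:
        return AffinityRange.VERY_HIGH
    if kd_nm <= 40.0:
        return AffinityRange.HIGH
    if kd_nm <= 100.0:
        return AffinityRange.MODERATE
    if kd_nm <= 400.0:
        return AffinityRange.LOW
    return AffinityRange.NONE


def range_distance(a: AffinityRange, b: AffinityRange) -> int:
    """Absolute ordinal distance between two affinity ranges."""
    return abs(int(a) - int(b))
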