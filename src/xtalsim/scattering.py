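"""Atomic X-ray scattering factors with Debye-Waller damping.

The scattering amplitude of atom *j* per unit incident amplitude is

    A0_j(s) = [ sum_m a_m exp(-b_m s^2) + c ] * exp(-B_j s^2)

with s = sin(theta)/lambda in 1/A, the four-Gaussian-plus-constant
parameterization of the International Tables (Vol. C), and B_j the
isotropic displacement (B) factor in A^2.  At s = 0 the bracket equals the
electron count of the (neutral or ionic) species, which is the consistency
check applied to the shipped table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "ScatteringCoefficients",
    "ScatteringTable",
    "load_table",
    "form_factor",
    "electron_count",
]


@dataclass(frozen=True)
class ScatteringCoefficients:
    """Four-Gaussian coefficients for one chemical species.

    ``a`` (electrons) and ``b`` (A^2) are length-4 arrays; ``c`` is the
    constant term in electrons.
    """

    symbol: str
    a: np.ndarray
    b: np.ndarray
    c: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.b) < 0):
            raise ValueError(f"{self.symbol}: negative Gaussian width b_m")

    def evaluate(self, s, b_factor=0.0):
        """f(s) * exp(-B s^2) for s = sin(theta)/lambda >= 0."""
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("momentum transfer s must be >= 0")
        b_factor = np.asarray(b_factor, dtype=float)
        if np.any(b_factor < 0):
            raise ValueError("B factor must be >= 0")
        s2 = s * s
        f = self.c + np.einsum(
            "m,m...->...", self.a, np.exp(-np.multiply.outer(self.b, s2))
        )
        return f * np.exp(-b_factor * s2)


class ScatteringTable:
    """Lookup of per-species coefficients, keyed by symbol (e.g. 'C', 'Cl1-')."""

    def __init__(self, entries: dict[str, ScatteringCoefficients]):
        self._entries = entries

    @classmethod
    def from_csv(cls, text: str) -> "ScatteringTable":
        entries = {}
        rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
        for row in csv.DictReader(rows):
            sym = row["element"].strip()
            a = np.array([float(row[f"a{m}"]) for m in range(1, 5)])
            b = np.array([float(row[f"b{m}"]) for m in range(1, 5)])
            entries[sym] = ScatteringCoefficients(sym, a, b, float(row["c"]))
        return cls(entries)

    def __contains__(self, symbol: str) -> bool:
        return self._normalize(symbol) in self._entries

    def elements(self) -> list[str]:
        return sorted(self._entries)

    @staticmethod
    def _normalize(symbol: str) -> str:
        symbol = symbol.strip()
        if not symbol:
            return symbol
        if symbol[-1] in "+-":  # ionic entry like 'Cl1-'
            return symbol[:-2].capitalize() + symbol[-2:]
        return symbol.capitalize()

    def __getitem__(self, symbol: str) -> ScatteringCoefficients:
        key = self._normalize(symbol)
        try:
            return self._entries[key]
        except KeyError:
            raise KeyError(
                f"element {symbol!r} not in scattering table "
                f"(available: {', '.join(self.elements())})"
            ) from None


_DEFAULT: ScatteringTable | None = None


def load_table(path=None) -> ScatteringTable:
    """Load the shipped coefficient table, or a user CSV given a path."""
    global _DEFAULT
    if path is not None:
        with open(path) as fh:
            return ScatteringTable.from_csv(fh.read())
    if _DEFAULT is None:
        text = (
            resources.files("xtalsim.data")
            .joinpath("it92_coefficients.csv")
            .read_text()
        )
        _DEFAULT = ScatteringTable.from_csv(text)
    return _DEFAULT


def form_factor(element: str, s, b_factor=0.0, table: ScatteringTable | None = None):
    """Scattering amplitude of one atom in electrons.

    Parameters
    ----------
    element : chemical symbol, optionally ionic ('Cl1-').
    s : sin(theta)/lambda in 1/A (scalar or array), >= 0.
    b_factor : isotropic B factor in A^2, >= 0.
    """
    table = table or load_table()
    return table[element].evaluate(s, b_factor)


def electron_count(element: str, table: ScatteringTable | None = None) -> float:
    """f(0) of the species - its electron count for a well-formed table."""
    table = table or load_table()
    entry = table[element]
    return float(entry.a.sum() + entry.c)
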