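"""Atomic property tables used by the QNA and whole-molecule descriptors.

The shipped table carries, per element: ionization potential and electron
affinity (eV, experimental atomic values on the Mulliken scale), a single-bond
covalent radius (Å, Cordero-type compilation) and a coarse atomic additive
lipophilicity contribution (unitless, log-units).  The table is data, not
code — swap in a different TSV to change conventions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["ElementProperties", "load_default_properties"]


@dataclass(frozen=True)
class ElementEntry:
    ip_ev: float
    ea_ev: float
    r_cov_a: float
    logp_contrib: float


class ElementProperties:
    """Element symbol -> (IP, EA, covalent radius, logP contribution)."""

    def __init__(self, entries: dict[str, ElementEntry]):
        for sym, e in entries.items():
            if not e.ip_ev > e.ea_ev:
                raise ValueError(f"{sym}: IP ({e.ip_ev}) must exceed EA ({e.ea_ev})")
        self._entries = dict(entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._entries

    def __getitem__(self, symbol: str) -> ElementEntry:
        try:
            return self._entries[symbol]
        except KeyError:
            raise KeyError(f"no property entry for element {symbol!r}") from None

    @property
    def symbols(self) -> list[str]:
        return sorted(self._entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ElementProperties":
        entries: dict[str, ElementEntry] = {}
        with open(path, encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                entries[row["symbol"]] = ElementEntry(
                    ip_ev=float(row["IP_eV"]),
                    ea_ev=float(row["EA_eV"]),
                    r_cov_a=float(row["r_cov_A"]),
                    logp_contrib=float(row["logp_contrib"]),
                )
        return cls(entries)


def load_default_properties() -> ElementProperties:
    """Load the bundled element property table."""
    with resources.as_file(
        resources.files("loxqsar.data") / "element_properties.tsv"
    ) as path:
        return ElementProperties.from_tsv(path)
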