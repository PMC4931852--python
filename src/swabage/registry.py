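"""Registry binding the five model CpGs to Illumina-style probe IDs.

The pyrosequencing assays target five CpG sites, conventionally labelled
by Greek letters in the model formulas:

====== ==================== ========= =====================================
symbol probe ID             gene      role
====== ==================== ========= =====================================
alpha   cg02228185          ASPA      age-associated
beta    cg25809905          ITGA2B    age-associated
gamma   cg17861230_upstream PDE4C     age-associated (assayed CpG lies
                                      upstream of cg17861230 and is not on
                                      Illumina Bead Chips)
delta   cg07380416          CD6       cell-type-specific (leuko hypo-meth)
epsilon cg20837735          SERPINB5  cell-type-specific (leuko hyper-meth)
====== ==================== ========= =====================================

For array data the gamma assay has no probe; ``array_alias`` maps it to the
neighbouring on-chip CpG cg17861230, selected via ``use_array_alias``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import yaml

SYMBOLS = ("alpha", "beta", "gamma", "delta", "epsilon")

#: on-array neighbour usable in place of the off-array gamma assay
GAMMA_ARRAY_ALIAS = "cg17861230"


@dataclass(frozen=True)
class RegistryEntry:
    symbol: str
    probe_id: str
    gene: str


@dataclass(frozen=True)
class CpGRegistry:
    """Immutable mapping symbol -> (probe_id, gene) for the five model CpGs."""

    entries: tuple[RegistryEntry, ...] = field(
        default_factory=lambda: (
            RegistryEntry("alpha", "cg02228185", "ASPA"),
            RegistryEntry("beta", "cg25809905", "ITGA2B"),
            RegistryEntry("gamma", "cg17861230_upstream", "PDE4C"),
            RegistryEntry("delta", "cg07380416", "CD6"),
            RegistryEntry("epsilon", "cg20837735", "SERPINB5"),
        )
    )

    def __post_init__(self) -> None:
        symbols = [e.symbol for e in self.entries]
        probes = [e.probe_id for e in self.entries]
        if len(self.entries) != 5:
            raise ValueError(f"registry must hold exactly 5 entries, got {len(self.entries)}")
        if sorted(symbols) != sorted(SYMBOLS):
            raise ValueError(f"registry symbols must be {SYMBOLS}, got {symbols}")
        if len(set(probes)) != len(probes):
            raise ValueError("probe IDs must be unique")

    def __iter__(self) -> Iterator[RegistryEntry]:
        return iter(self.entries)

    def probe(self, symbol: str) -> str:
        for e in self.entries:
            if e.symbol == symbol:
                return e.probe_id
        raise KeyError(symbol)

    def gene(self, symbol: str) -> str:
        for e in self.entries:
            if e.symbol == symbol:
                return e.gene
        raise KeyError(symbol)

    @property
    def probes(self) -> tuple[str, ...]:
        return tuple(e.probe_id for e in self.entries)

    def age_probes(self) -> tuple[str, str, str]:
        """Probe IDs of the three age-associated CpGs (alpha, beta, gamma)."""
        return (self.probe("alpha"), self.probe("beta"), self.probe("gamma"))

    def signature_probes(self) -> tuple[str, str]:
        """Probe IDs of the two cell-type-specific CpGs (delta, epsilon)."""
        return (self.probe("delta"), self.probe("epsilon"))

    def with_array_gamma(self) -> "CpGRegistry":
        """Registry variant mapping gamma to the on-chip neighbour cg17861230."""
        entries = tuple(
            replace(e, probe_id=GAMMA_ARRAY_ALIAS) if e.symbol == "gamma" else e
            for e in self.entries
        )
        return CpGRegistry(entries)

    @classmethod
    def from_config(cls, path) -> "CpGRegistry":
        """Load probe-ID overrides from a YAML mapping symbol -> probe_id.

        Symbols absent from the file keep their defaults; genes are kept.
        """
        with open(path, "r", encoding="utf-8") as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"{path}: expected a mapping of symbol -> probe_id")
        unknown = set(overrides) - set(SYMBOLS)
        if unknown:
            raise ValueError(f"{path}: unknown symbols {sorted(unknown)}")
        base = cls()
        entries = tuple(
            replace(e, probe_id=str(overrides[e.symbol])) if e.symbol in overrides else e
            for e in base.entries
        )
        return cls(entries)


DEFAULT_REGISTRY = CpGRegistry()
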