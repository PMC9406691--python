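"""Core data containers shared across the pipeline.

A molecule enters the pipeline as a :class:`MoleculeRecord` (SMILES plus
optional observed activity and split label) and is featurized into an
:class:`AttributeProfile`, a multiset of fixed-width 12-character attribute
keys.  Every downstream stage (correlation-weight optimization, applicability
domain, analogue design) consumes these two types only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

KEY_WIDTH = 12

#: attribute-key categories, in the order they appear in the descriptor sum
CATEGORIES = (
    "S", "SS", "SSS",
    "NOSP", "HALO", "BOND", "ATOMPAIR", "HARD", "XMAX",
    "EC0", "VS2", "VS3", "PT2", "PT3", "NNC",
)


@dataclass(frozen=True)
class AttributeKey:
    """One fixed-width attribute key with its category tag.

    ``key`` is exactly 12 characters, '.'-padded; two structurally equal
    molecules yield identical key multisets.
    """

    key: str
    category: str

    def __post_init__(self) -> None:
        if len(self.key) != KEY_WIDTH:
            raise ValueError(
                f"attribute key must be {KEY_WIDTH} chars, got {self.key!r}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown attribute category {self.category!r}")


@dataclass
class MoleculeRecord:
    """One molecule: identifier, SMILES, optional activity and split label."""

    molecule_id: str
    smiles: str
    activity: float | None = None
    split: str | None = None


@dataclass
class AttributeProfile:
    """Multiset of attribute keys for one molecule."""

    molecule_id: str
    counts: Counter = field(default_factory=Counter)

    def add(self, key: AttributeKey, n: int = 1) -> None:
        self.counts[key] += n

    def merge(self, other: "AttributeProfile") -> "AttributeProfile":
        merged = AttributeProfile(self.molecule_id, Counter(self.counts))
        merged.counts.update(other.counts)
        return merged

    def keys(self):
        return self.counts.keys()

    def total(self) -> int:
        return sum(self.counts.values())

    def by_category(self, category: str) -> Counter:
        return Counter(
            {k: n for k, n in self.counts.items() if k.category == category}
        )
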