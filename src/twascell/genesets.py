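"""Named gene sets (GMT-representable)."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene identifiers.

    The canonical use here is the TWAS risk-gene set: genes whose
    predicted expression associates with the trait at FDR < alpha.
    """

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersect(self, universe) -> "GeneSet":
        """Restrict to genes present in ``universe``, preserving order."""
        keep = set(universe)
        return GeneSet(self.name, tuple(g for g in self.genes if g in keep), self.description)
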