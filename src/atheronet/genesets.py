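"""Calcification geneset compilation and DEG intersection.

A geneset library (GMT-style) of vascular-calcification genesets is
collapsed into one deduplicated symbol set, optionally restricted to a
curated allow-list, and intersected with the module-retained DEGs to give
the calcification-and-atherosclerosis-specific (CASS) DEGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .data import DataValidationError


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class GeneSetLibrary:
    """Named genesets of uppercase gene symbols with per-set provenance."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(
        cls, sets: dict[str, list[str] | set[str]], provenance: str = "local"
    ) -> "GeneSetLibrary":
        lib = cls()
        for name, members in sets.items():
            lib.sets[name] = {_norm(g) for g in members}
            lib.provenance[name] = provenance
        return lib

    def universe(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


def compile_vc_genes(
    lib: GeneSetLibrary, keep: set[str] | None = None
) -> set[str]:
    """Union of all library sets, deduplicated and uppercased; if a curated
    allow-list ``keep`` is given (literature-validated genes), restrict the
    union to it."""
    if not lib.sets:
        raise DataValidationError("geneset library is empty")
    union = lib.universe()
    if not union:
        raise DataValidationError("geneset library union is empty")
    if keep is not None:
        union &= {_norm(g) for g in keep}
    return union


@dataclass
class VennCounts:
    degs_only: int
    vc_only: int
    both: int

    def total(self) -> int:
        return self.degs_only + self.vc_only + self.both


def intersect_cass(
    degs: set[str], vc: set[str]
) -> tuple[set[str], VennCounts]:
    """Overlap the DEG and vascular-calcification symbol sets; returns the
    CASS genes plus Venn counts (degs only, vc only, both)."""
    degs = {_norm(g) for g in degs}
    vc = {_norm(g) for g in vc}
    both = degs & vc
    counts = VennCounts(
        degs_only=len(degs - vc), vc_only=len(vc - degs), both=len(both)
    )
    if not both:
        warnings.warn("DEG and calcification sets are disjoint: no CASS genes")
    return both, counts
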