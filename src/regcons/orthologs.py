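"""Cross-species comparison of regulated gene sets via an ortholog map.

Regulated genes from two species are first restricted to those with at
least one ortholog pair, then intersected through the map: a conserved
pair (a, b) has a regulated in species A, b regulated in species B, and
(a, b) in the ortholog table.  Conservation is counted both as distinct
species-A genes (the one-row-per-pair presentation of 1:1 tables) and as
raw pairs, which differ only for many-to-many maps.  GO annotation is
tallied flat against a released annotation file, without ontology-graph
propagation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import OrthologMap, ValidationError

_GO_TERM_RE = re.compile(r"^GO:\d{7}$")


def filter_with_orthologs(
    genes: Iterable[str], omap: OrthologMap, side: str = "A"
) -> frozenset[str]:
    """Genes having at least one ortholog pair in the map."""
    if side not in ("A", "B"):
        raise ValidationError(f"side must be 'A' or 'B', got {side!r}")
    known = omap.genes_a() if side == "A" else omap.genes_b()
    return frozenset(genes) & known


@dataclass(frozen=True)
class ConservationComparison:
    """Venn-style accounting of regulated-set conservation across species."""

    n_a_regulated: int
    n_b_regulated: int
    n_a_with_ortholog: int
    n_b_with_ortholog: int
    conserved_pairs: tuple[tuple[str, str], ...]
    n_conserved_a: int  # distinct species-A genes in conserved pairs
    n_conserved_b: int

    @property
    def n_pairs(self) -> int:
        return len(self.conserved_pairs)

    @property
    def venn(self) -> dict[str, int]:
        """Counts for a two-set Venn over ortholog-filtered regulated genes."""
        return {
            "a_only": self.n_a_with_ortholog - self.n_conserved_a,
            "b_only": self.n_b_with_ortholog - self.n_conserved_b,
            "conserved_a": self.n_conserved_a,
            "conserved_b": self.n_conserved_b,
            "conserved_pairs": self.n_pairs,
        }


def conserved_regulated(
    set_a: Iterable[str], set_b: Iterable[str], omap: OrthologMap
) -> ConservationComparison:
    """Conserved regulated genes between two species through the map."""
    a = frozenset(set_a)
    b = frozenset(set_b)
    a_orth = filter_with_orthologs(a, omap, side="A")
    b_orth = filter_with_orthologs(b, omap, side="B")
    pairs = tuple(
        sorted((ga, gb) for ga, gb in omap.pairs if ga in a and gb in b)
    )
    return ConservationComparison(
        n_a_regulated=len(a),
        n_b_regulated=len(b),
        n_a_with_ortholog=len(a_orth),
        n_b_with_ortholog=len(b_orth),
        conserved_pairs=pairs,
        n_conserved_a=len({ga for ga, _ in pairs}),
        n_conserved_b=len({gb for _, gb in pairs}),
    )


def count_go_annotated(
    genes: Iterable[str], go_map: Mapping[str, Iterable[str]], term: str
) -> int:
    """Number of genes whose (flat) annotation set contains the GO term."""
    if not _GO_TERM_RE.match(term):
        raise ValidationError(f"invalid GO term id {term!r}")
    return sum(1 for g in set(genes) if term in set(go_map.get(g, ())))
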