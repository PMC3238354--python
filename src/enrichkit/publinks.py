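"""Gene <-> publication link tables and literature-derived gene lists.

Operates offline on a gene2pubmed-dialect table (tax_id, GeneID, PubMed_ID).
A list of publication identifiers maps to a test gene list (the union of
genes linked to any of the publications); the background is every gene with
at least one publication link.  Both are then handed to the enrichment
engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, TYPE_CHECKING

from .errors import InputError, ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .enrich import EnrichmentReport, QvalueParams
    from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class PubLinkTable:
    """Many-to-many gene <-> publication links for one species.

    ``by_gene`` and ``by_pub`` are exact transposes of ``links``.
    """

    species: int
    links: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    by_gene: dict[int, set[int]] = field(init=False)
    by_pub: dict[int, set[int]] = field(init=False)

    def __post_init__(self) -> None:
        self.links = frozenset(self.links)
        self.by_gene = {}
        self.by_pub = {}
        for gene, pub in self.links:
            self.by_gene.setdefault(gene, set()).add(pub)
            self.by_pub.setdefault(pub, set()).add(gene)


def read_publink(lines: Iterable[str], species: int) -> PubLinkTable:
    """Parse a gene2pubmed-dialect TSV (tax_id, GeneID, PubMed_ID).

    '#' header lines are skipped, only rows for *species* are retained, and
    duplicate rows collapse.
    """
    links: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError("expected tax_id<TAB>GeneID<TAB>PubMed_ID", line=lineno)
        try:
            tax_id, gene, pub = int(parts[0]), int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"non-integer field: {exc}", line=lineno) from exc
        if tax_id != species:
            continue
        links.add((gene, pub))
    return PubLinkTable(species=species, links=frozenset(links))


def write_publink(table: PubLinkTable) -> list[str]:
    """Canonical serialization: header line, rows ascending by (gene, pub)."""
    return ["#tax_id\tGeneID\tPubMed_ID\n"] + [
        f"{table.species}\t{gene}\t{pub}\n" for gene, pub in sorted(table.links)
    ]


def genes_for_pmids(pmids: Iterable[int], links: PubLinkTable) -> list[int]:
    """Genes linked to any of the given publications, ascending, de-duplicated.

    Unknown publication identifiers contribute nothing (counted in the log);
    if every identifier is unknown the result would be empty and an error is
    raised instead.
    """
    pmid_list = list(pmids)
    if not pmid_list:
        raise InputError("publication identifier list is empty")
    genes: set[int] = set()
    unknown = 0
    for pmid in pmid_list:
        hit = links.by_pub.get(pmid)
        if hit is None:
            unknown += 1
        else:
            genes |= hit
    if unknown:
        logger.info("%d of %d publication identifiers had no gene links",
                    unknown, len(pmid_list))
    if not genes:
        raise InputError(
            f"none of the {len(pmid_list)} publication identifiers has gene links"
        )
    return sorted(genes)


def pubmed_background(links: PubLinkTable) -> frozenset[int]:
    """Every gene with at least one publication link — the literature
    background for publication-derived test lists."""
    if not links.links:
        raise InputError("publication link table is empty")
    return frozenset(links.by_gene)


def gen_pubmed(
    pmids: Iterable[int],
    links: PubLinkTable,
    collection: "GeneSetCollection",
    params: "QvalueParams | None" = None,
    p_threshold: float = 0.05,
) -> "EnrichmentReport":
    """Enrichment of the publication-derived gene list against the
    literature background."""
    from .enrich import enrich

    test = genes_for_pmids(pmids, links)
    background = pubmed_background(links)
    return enrich(test, background, collection, method="representation",
                  params=params, p_threshold=p_threshold)
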