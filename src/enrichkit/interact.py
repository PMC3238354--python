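"""Interaction networks: pair sources, depth-bounded expansion, enrichment.

Three sources yield an unordered gene-pair set: a curated two-column pair
list, literature co-occurrence (two genes paired when they share at least a
threshold number of publications, default 5), and KGML pathway XML (two
genes paired when any pathway file asserts a relation between their
entries, all relation subtypes treated identically).

From a seed gene the network is expanded breadth-first to depth 1-3; the
cumulative neighbourhood (seed excluded) becomes the test list and every
gene incident to any pair becomes the background, which is then scored by
the enrichment engine.  No inference is made about the *type* of any
interaction.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, TYPE_CHECKING

import networkx as nx

from .errors import NoInteractionDataError, ParseError, InputError
from .publinks import PubLinkTable

if TYPE_CHECKING:  # pragma: no cover
    from .enrich import EnrichmentReport, QvalueParams
    from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)


def _norm(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass
class PairSet:
    """Species-tagged set of unordered gene pairs; no self-pairs, and (a,b)
    equals (b,a)."""

    species: int
    pairs: set[tuple[int, int]] = field(default_factory=set)
    source_label: str = ""

    def __post_init__(self) -> None:
        self.pairs = {_norm(a, b) for a, b in self.pairs if a != b}

    def genes(self) -> frozenset[int]:
        """Every gene incident to at least one pair."""
        out: set[int] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return frozenset(out)


@dataclass
class ExpansionResult:
    seed: int
    depth: int
    interactors: frozenset[int]
    background: frozenset[int]


def pairs_from_cooccurrence(
    links: PubLinkTable, min_shared: int = 5, source_label: str = "cooccurrence"
) -> PairSet:
    """Pair two genes when they share at least *min_shared* publications."""
    if min_shared < 1:
        raise InputError("min_shared must be >= 1")
    shared: Counter[tuple[int, int]] = Counter()
    for genes in links.by_pub.values():
        for a, b in combinations(sorted(genes), 2):
            shared[(a, b)] += 1
    pairs = {pair for pair, n in shared.items() if n >= min_shared}
    return PairSet(species=links.species, pairs=pairs, source_label=source_label)


def pairs_from_kgml(
    documents: Iterable[tuple[str, str]], species: int = 0
) -> PairSet:
    """Pairs from KGML pathway XML documents, given as (name, xml text).

    Entries of type ``gene`` carry one or more species-prefixed gene
    identifiers in their ``name`` attribute (e.g. ``hsa:10 hsa:11``); every
    relation between two gene entries contributes the cross-product of their
    identifier lists.  Relation subtypes are not distinguished.  Relations
    referencing a missing entry id are skipped with a warning; self-pairs
    are discarded; pairs union across documents.
    """
    pairs: set[tuple[int, int]] = set()
    for name, text in documents:
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise ParseError(f"malformed KGML XML: {exc}", source=name) from exc
        entry_genes: dict[str, list[int]] = {}
        all_entry_ids: set[str | None] = set()
        for entry in root.iter("entry"):
            all_entry_ids.add(entry.get("id"))
            if entry.get("type") != "gene":
                continue
            genes = []
            for token in (entry.get("name") or "").split():
                ident = token.rsplit(":", 1)[-1]
                if ident.isdigit():
                    genes.append(int(ident))
            if genes:
                entry_genes[entry.get("id", "")] = genes
        for relation in root.iter("relation"):
            e1, e2 = relation.get("entry1"), relation.get("entry2")
            g1 = entry_genes.get(e1 or "")
            g2 = entry_genes.get(e2 or "")
            if g1 is None or g2 is None:
                # non-gene endpoints (compounds, maps) contribute nothing;
                # a dangling reference is reported
                if (e1 not in all_entry_ids) or (e2 not in all_entry_ids):
                    logger.warning(
                        "%s: relation references missing entry id (%s, %s); skipped",
                        name, e1, e2,
                    )
                continue
            for a in g1:
                for b in g2:
                    if a != b:
                        pairs.add(_norm(a, b))
    return PairSet(species=species, pairs=pairs, source_label="kgml")


def read_pair_list(lines: Iterable[str], species: int,
                   source_label: str = "pair_list") -> PairSet:
    """Parse a two-column geneA<TAB>geneB TSV ('#' headers skipped).

    Pairs are normalized unordered; self-pairs are dropped (counted in the
    log); extra columns beyond the first two are ignored.
    """
    pairs: set[tuple[int, int]] = set()
    n_self = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError("expected geneA<TAB>geneB", line=lineno)
        try:
            a, b = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ParseError(f"non-integer gene field: {exc}", line=lineno) from exc
        if a == b:
            n_self += 1
            continue
        pairs.add(_norm(a, b))
    if n_self:
        logger.info("dropped %d self-pairs", n_self)
    return PairSet(species=species, pairs=pairs, source_label=source_label)


def write_pair_list(pairs: PairSet) -> list[str]:
    """Canonical two-column serialization: header line, pairs ascending."""
    return ["#geneA\tgeneB\n"] + [f"{a}\t{b}\n" for a, b in sorted(pairs.pairs)]


def expand(seed: int, pairs: PairSet, depth: int) -> ExpansionResult:
    """All genes reachable from the seed within <= depth edges (cumulative
    over levels), excluding the seed itself; the background is every gene
    with any interaction data."""
    if depth not in (1, 2, 3):
        raise InputError(f"depth must be 1, 2 or 3, got {depth}")
    background = pairs.genes()
    if seed not in background:
        raise NoInteractionDataError(f"no interaction data for seed {seed}")
    graph = nx.Graph()
    graph.add_edges_from(pairs.pairs)
    reached = nx.single_source_shortest_path_length(graph, seed, cutoff=depth)
    interactors = frozenset(reached) - {seed}
    return ExpansionResult(seed=seed, depth=depth, interactors=interactors,
                           background=background)


def gen_interact(
    seed: int,
    pairs: PairSet,
    depth: int,
    collection: "GeneSetCollection",
    params: "QvalueParams | None" = None,
    p_threshold: float = 0.05,
) -> tuple["EnrichmentReport", ExpansionResult]:
    """Expand from the seed and score the neighbourhood against a
    collection; returns the report together with the expansion so the
    interactor list can be emitted verbatim."""
    from .enrich import enrich

    expansion = expand(seed, pairs, depth)
    report = enrich(sorted(expansion.interactors), expansion.background,
                    collection, method="representation", params=params,
                    p_threshold=p_threshold)
    return report, expansion
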