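"""Gene-set collections: the flat-file dialect and offline set builders.

A gene set is a named category of Entrez gene identifiers (a pathway, a GO
term, a tissue, a literature topic).  Collections are stored as flat files,
one set per line::

    set_id<TAB>description<TAB>comma-separated gene IDs

Lines starting with ``#`` are comments.  ``set_id`` is a single word; a gene
may appear in any number of sets.

The builders construct collections from pre-extracted annotation tables:

* :func:`build_go_sets` — rolls gene annotations up an ontology DAG so that
  each term's set also contains every gene annotated to any descendant term
  (the "true-path" rule);
* :func:`build_cocitation_sets` — one set per literature topic, from
  topic->publication and gene<->publication link tables, excluding
  publications that discuss more than a cutoff number of genes (default 100,
  which removes unspecific EST-library and microarray papers);
* :func:`build_tissue_sets` — tissue-specific sets from an expression
  matrix: a probeset's gene joins a tissue's set when that tissue carries at
  least a given fraction (default 25%) of the probeset's summed intensity;
* :func:`build_keyword_sets` — one set per annotation term from a generic
  (gene, term) table, e.g. protein keywords or subcellular locations.
"""

from __future__ import annotations

import graphlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import CycleError, DataError, ParseError
from .publinks import PubLinkTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named category of genes."""

    set_id: str
    description: str
    members: frozenset[int]

    def __post_init__(self) -> None:
        if any(ch.isspace() for ch in self.set_id):
            raise DataError(f"set_id may not contain whitespace: {self.set_id!r}")


@dataclass
class GeneSetCollection:
    """An ordered, species-tagged list of gene sets with unique set_ids."""

    name: str
    species: int
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate set_id in collection {self.name!r}: {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    def __contains__(self, set_id: str) -> bool:
        return any(s.set_id == set_id for s in self.sets)

    def all_members(self) -> frozenset[int]:
        """Union of the members of every set in the collection."""
        out: set[int] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)


@dataclass
class OntologyDAG:
    """Parent edges of an ontology: child term -> set of parent terms.

    ``terms`` maps every term identifier to its display name.  The edge
    relation must be acyclic; this is checked when the DAG is traversed.
    """

    parent_edges: dict[str, set[str]] = field(default_factory=dict)
    terms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parents in self.parent_edges.items():
            self.terms.setdefault(child, child)
            for p in parents:
                self.terms.setdefault(p, p)

    @classmethod
    def from_edge_lines(cls, lines: Iterable[str]) -> "OntologyDAG":
        """Parse child<TAB>parent TSV edges ('#' lines skipped)."""
        edges: dict[str, set[str]] = {}
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected child<TAB>parent", line=lineno)
            edges.setdefault(parts[0], set()).add(parts[1])
        return cls(parent_edges=edges)


@dataclass
class AnnotationTable:
    """De-duplicated (gene, term) annotation pairs for one species."""

    species: int
    rows: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        unique: list[tuple[int, str]] = []
        for row in self.rows:
            if row not in seen:
                seen.add(row)
                unique.append(row)
        self.rows = unique

    @classmethod
    def from_lines(cls, lines: Iterable[str], species: int) -> "AnnotationTable":
        """Parse gene<TAB>term TSV ('#' lines skipped)."""
        rows: list[tuple[int, str]] = []
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected gene<TAB>term", line=lineno)
            try:
                gene = int(parts[0])
            except ValueError as exc:
                raise ParseError(f"non-integer gene identifier {parts[0]!r}", line=lineno) from exc
            rows.append((gene, parts[1]))
        return cls(species=species, rows=rows)


@dataclass
class ExpressionMatrix:
    """Tissue x probeset intensities plus a probeset -> gene map."""

    probesets: list[str]
    tissues: list[str]
    intensities: dict[str, list[float]]  # probeset -> per-tissue values
    probe_to_gene: dict[str, int]

    @classmethod
    def from_tsv(
        cls, matrix_lines: Iterable[str], probe_map_lines: Iterable[str]
    ) -> "ExpressionMatrix":
        """Load from a TSV with a header of tissue names and probeset-labelled
        rows, plus a probeset<TAB>gene map file."""
        it = iter(matrix_lines)
        header = None
        lineno = 0
        for raw in it:
            lineno += 1
            line = raw.rstrip("\n")
            if line.strip() and not line.startswith("#"):
                header = line.split("\t")
                break
        if header is None:
            raise ParseError("empty expression matrix")
        tissues = header[1:]
        probesets: list[str] = []
        intensities: dict[str, list[float]] = {}
        for raw in it:
            lineno += 1
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(tissues) + 1:
                raise ParseError(
                    f"expected {len(tissues) + 1} columns, got {len(parts)}", line=lineno
                )
            try:
                values = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"non-numeric intensity: {exc}", line=lineno) from exc
            probesets.append(parts[0])
            intensities[parts[0]] = values
        probe_to_gene: dict[str, int] = {}
        for lineno, raw in enumerate(probe_map_lines, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected probeset<TAB>gene", line=lineno)
            try:
                probe_to_gene[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"non-integer gene identifier {parts[1]!r}", line=lineno) from exc
        return cls(
            probesets=probesets, tissues=tissues, intensities=intensities,
            probe_to_gene=probe_to_gene,
        )


# (species, gene) -> human gene identifier
HomologMap = Mapping[tuple[int, int], int]


def read_homolog_map(lines: Iterable[str]) -> dict[tuple[int, int], int]:
    """Parse species<TAB>gene<TAB>human_gene TSV into a homolog map."""
    out: dict[tuple[int, int], int] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError("expected species<TAB>gene<TAB>human_gene", line=lineno)
        try:
            species, gene, human = int(parts[0]), int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"non-integer field: {exc}", line=lineno) from exc
        if human <= 0:
            raise ParseError(f"target identifier must be positive, got {human}", line=lineno)
        out[(species, gene)] = human
    return out


def read_collection(lines: Iterable[str], name: str, species: int) -> GeneSetCollection:
    """Read a gene-set flat file, preserving file order.

    Duplicate member IDs within a line collapse; a duplicate set_id or a
    non-integer member token is a format error.
    """
    sets: list[GeneSet] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(
                "expected set_id<TAB>description<TAB>comma-separated IDs", line=lineno
            )
        set_id, description, member_field = parts[0], parts[1], parts[2]
        if set_id in seen_ids:
            raise ParseError(f"duplicate set_id {set_id!r}", line=lineno)
        seen_ids.add(set_id)
        members: set[int] = set()
        for tok in member_field.split(","):
            tok = tok.strip()
            if not tok:
                continue
            try:
                members.add(int(tok))
            except ValueError as exc:
                raise ParseError(f"non-integer member token {tok!r}", line=lineno) from exc
        sets.append(GeneSet(set_id=set_id, description=description, members=frozenset(members)))
    return GeneSetCollection(name=name, species=species, sets=sets)


def write_collection(collection: GeneSetCollection) -> list[str]:
    """Serialize to canonical flat-file lines: one set per line, members in
    ascending numeric order.  ``read_collection`` of the output reproduces
    the collection exactly."""
    lines = []
    for s in collection.sets:
        members = ",".join(str(m) for m in sorted(s.members))
        lines.append(f"{s.set_id}\t{s.description}\t{members}\n")
    return lines


def build_go_sets(
    annotations: AnnotationTable, dag: OntologyDAG, name: str = "go"
) -> GeneSetCollection:
    """Roll annotations up the ontology: members(term) = direct annotations
    of the term plus the members of every descendant.

    Implemented as a single reverse-topological accumulation over the parent
    edges (children processed before parents), which is linear in the number
    of edges.  Terms whose rolled-up membership is empty are omitted.
    """
    direct: dict[str, set[int]] = {}
    for gene, term in annotations.rows:
        direct.setdefault(term, set()).add(gene)

    sorter: graphlib.TopologicalSorter[str] = graphlib.TopologicalSorter()
    for term in dag.terms:
        sorter.add(term)
    for child, parents in dag.parent_edges.items():
        for parent in parents:
            # child must be fully accumulated before its parent
            sorter.add(parent, child)
    try:
        order = list(sorter.static_order())
    except graphlib.CycleError as exc:
        raise CycleError(f"ontology parent edges contain a cycle: {exc.args[1]}") from exc

    rolled: dict[str, set[int]] = {t: set(direct.get(t, ())) for t in dag.terms}
    for term in order:
        for parent in dag.parent_edges.get(term, ()):
            rolled[parent] |= rolled[term]

    sets = [
        GeneSet(set_id=term, description=dag.terms.get(term, term),
                members=frozenset(rolled[term]))
        for term in sorted(rolled)
        if rolled[term]
    ]
    return GeneSetCollection(name=name, species=annotations.species, sets=sets)


def build_cocitation_sets(
    topic_pubs: Mapping[str, set[int]],
    links: PubLinkTable,
    homologs: HomologMap | None = None,
    max_genes_per_pub: int = 100,
    name: str = "cocitation",
    species_out: int = 9606,
) -> GeneSetCollection:
    """One gene set per literature topic.

    Publications linked to more than *max_genes_per_pub* genes are dropped
    (strictly more than: a publication at exactly the cutoff is retained).
    When *homologs* is given, genes are mapped through it to human
    identifiers and genes with no homolog are dropped (counted in the log);
    with ``homologs=None`` identifiers pass through unchanged.  Topics whose
    surviving membership is empty are omitted.
    """
    if max_genes_per_pub < 1:
        raise DataError("max_genes_per_pub must be >= 1")
    sets: list[GeneSet] = []
    n_unmapped = 0
    for topic in sorted(topic_pubs):
        genes: set[int] = set()
        for pub in topic_pubs[topic]:
            pub_genes = links.by_pub.get(pub, set())
            if len(pub_genes) > max_genes_per_pub:
                continue
            genes |= pub_genes
        if homologs is not None:
            mapped: set[int] = set()
            for g in genes:
                target = homologs.get((links.species, g))
                if target is None:
                    n_unmapped += 1
                else:
                    mapped.add(target)
            genes = mapped
        if genes:
            sets.append(GeneSet(set_id=topic, description=f"co-cited genes: {topic}",
                                members=frozenset(genes)))
    if n_unmapped:
        logger.info("co-citation builder dropped %d gene occurrences with no homolog",
                    n_unmapped)
    return GeneSetCollection(name=name, species=species_out, sets=sets)


def build_tissue_sets(
    matrix: ExpressionMatrix, fraction: float = 0.25,
    name: str = "tissue", species: int = 9606,
) -> GeneSetCollection:
    """Tissue-specific sets: a probeset's gene joins every tissue holding at
    least ``fraction`` of the probeset's total intensity (inclusive >=).

    Probesets with zero total contribute nothing; probesets mapping to the
    same gene union their memberships.  At fraction f a probeset can join at
    most floor(1/f) tissues.
    """
    if not (0 < fraction <= 1):
        raise DataError("fraction must be in (0, 1]")
    per_tissue: dict[str, set[int]] = {t: set() for t in matrix.tissues}
    for probeset in matrix.probesets:
        values = matrix.intensities[probeset]
        if any(v < 0 for v in values):
            raise DataError(f"negative intensity for probeset {probeset!r}")
        total = sum(values)
        if total == 0:
            continue
        gene = matrix.probe_to_gene.get(probeset)
        if gene is None:
            continue
        for tissue, value in zip(matrix.tissues, values):
            if value >= fraction * total:
                per_tissue[tissue].add(gene)
    sets = [
        GeneSet(set_id=t.replace(" ", "_"), description=f"genes specific to {t}",
                members=frozenset(per_tissue[t]))
        for t in matrix.tissues
        if per_tissue[t]
    ]
    return GeneSetCollection(name=name, species=species, sets=sets)


def build_keyword_sets(
    gene_terms: AnnotationTable, name: str = "keywords"
) -> GeneSetCollection:
    """One set per distinct term in a (gene, term) table; members are the
    genes carrying the term.  Serves keyword and subcellular-location style
    annotations supplied as pre-extracted tables."""
    by_term: dict[str, set[int]] = {}
    for gene, term in gene_terms.rows:
        by_term.setdefault(term, set()).add(gene)
    sets = [
        GeneSet(set_id=term.replace(" ", "_"), description=term,
                members=frozenset(by_term[term]))
        for term in sorted(by_term)
    ]
    return GeneSetCollection(name=name, species=gene_terms.species, sets=sets)
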