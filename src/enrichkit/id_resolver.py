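"""Resolve mixed symbol / Entrez-ID gene lists against a gene_info-dialect table.

The NCBI ``gene_info`` file maps official gene symbols and their synonyms to
stable integer Entrez gene identifiers.  Input gene lists in practice mix
numeric identifiers with symbols; this module parses the symbol table for one
species and resolves such mixed lists deterministically:

* an all-digit token is taken verbatim as an Entrez ID;
* otherwise the lookup order is exact-case official symbol, case-insensitive
  official symbol, then synonyms (exact case before case-insensitive);
* a synonym carried by several genes is reported as ambiguous, never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

_NO_SYNONYM = "-"


@dataclass
class SymbolMap:
    """Symbol/synonym -> Entrez ID lookup table for one species.

    ``primary`` maps each official symbol to exactly one gene identifier;
    ``synonyms`` is set-valued because distinct genes may share a synonym.
    """

    species: int
    primary: dict[str, int] = field(default_factory=dict)
    synonyms: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._primary_ci: dict[str, set[int]] | None = None
        self._synonyms_ci: dict[str, set[int]] | None = None

    def _ci_primary(self) -> dict[str, set[int]]:
        if self._primary_ci is None:
            index: dict[str, set[int]] = {}
            for sym, gid in self.primary.items():
                index.setdefault(sym.casefold(), set()).add(gid)
            self._primary_ci = index
        return self._primary_ci

    def _ci_synonyms(self) -> dict[str, set[int]]:
        if self._synonyms_ci is None:
            index: dict[str, set[int]] = {}
            for syn, gids in self.synonyms.items():
                index.setdefault(syn.casefold(), set()).update(gids)
            self._synonyms_ci = index
        return self._synonyms_ci

    def lookup(self, token: str) -> set[int]:
        """Candidate gene identifiers for one non-numeric token, in the
        documented precedence order; empty set means no match."""
        if token in self.primary:
            return {self.primary[token]}
        ci = self._ci_primary().get(token.casefold())
        if ci:
            return set(ci)
        if token in self.synonyms:
            return set(self.synonyms[token])
        ci = self._ci_synonyms().get(token.casefold())
        if ci:
            return set(ci)
        return set()


@dataclass
class ResolutionResult:
    """Outcome of resolving a token list: resolved IDs in first-occurrence
    order, tokens that matched nothing, and ambiguous tokens with their
    candidate sets."""

    resolved: list[int]
    unresolved: list[str]
    ambiguous: dict[str, set[int]]


def parse_gene_info(lines: Iterable[str], species: int) -> SymbolMap:
    """Parse a gene_info-dialect stream into a :class:`SymbolMap`.

    Expected tab-delimited columns (first five of the NCBI layout, extra
    columns ignored): tax_id, GeneID, Symbol, LocusTag, Synonyms with
    synonyms pipe-separated and ``-`` meaning none.  Lines starting with
    ``#`` are headers.  Only rows whose tax_id equals *species* are kept.
    """
    smap = SymbolMap(species=species)
    n_rows = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(
                f"expected >=5 tab-delimited columns, got {len(fields)}", line=lineno
            )
        try:
            tax_id = int(fields[0])
            gene_id = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"non-integer tax_id/GeneID: {exc}", line=lineno) from exc
        if tax_id != species:
            continue
        if gene_id <= 0:
            raise ParseError(f"gene identifier must be positive, got {gene_id}", line=lineno)
        n_rows += 1
        symbol = fields[2]
        if symbol and symbol != _NO_SYNONYM:
            smap.primary[symbol] = gene_id
        for syn in fields[4].split("|"):
            if syn and syn != _NO_SYNONYM:
                smap.synonyms.setdefault(syn, set()).add(gene_id)
    if n_rows == 0:
        logger.warning("gene_info stream contained no rows for species %d", species)
    return smap


def resolve_tokens(tokens: Iterable[str], smap: SymbolMap) -> ResolutionResult:
    """Resolve a mixed symbol/ID token list to Entrez gene identifiers.

    All-digit tokens are taken as IDs verbatim.  Duplicates collapse,
    preserving first-occurrence order.  Every distinct token ends up in
    exactly one of resolved / unresolved / ambiguous.
    """
    cleaned = [t.strip() for t in tokens]
    cleaned = [t for t in cleaned if t]
    if not cleaned:
        raise InputError("token list is empty after whitespace stripping")

    resolved: list[int] = []
    seen_ids: set[int] = set()
    unresolved: list[str] = []
    ambiguous: dict[str, set[int]] = {}
    seen_tokens: set[str] = set()

    for token in cleaned:
        if token in seen_tokens:
            continue
        seen_tokens.add(token)
        if token.isdigit():
            gid = int(token)
            if gid not in seen_ids:
                seen_ids.add(gid)
                resolved.append(gid)
            continue
        candidates = smap.lookup(token)
        if not candidates:
            unresolved.append(token)
        elif len(candidates) == 1:
            gid = next(iter(candidates))
            if gid not in seen_ids:
                seen_ids.add(gid)
                resolved.append(gid)
        else:
            ambiguous[token] = candidates
    return ResolutionResult(resolved=resolved, unresolved=unresolved, ambiguous=ambiguous)


def read_gene_list(lines: Iterable[str]) -> list[str]:
    """Read a plain-text gene list: one token per line, blank lines ignored."""
    tokens = []
    for raw in lines:
        tok = raw.strip()
        if tok:
            tokens.append(tok)
    return tokens
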