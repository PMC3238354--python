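"""Seeded synthetic fixtures for every input dialect the toolkit reads.

The generator emulates small NCBI-dialect inputs — a gene_info symbol
table, a gene-set flat file, a background list, an interaction pair list, a
KGML pathway document, a gene<->publication link table, a tissue expression
matrix with a probeset->gene map, and a test gene list — all deterministic
given the seed, so test expectations and command-line runs are exactly
reproducible.

A planted signal makes one target set over-represented in the test list:
members of the target set are oversampled by a stated odds multiplier
relative to background frequency (multiplier 1 is an exchangeable draw, the
null case).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FixtureSpecError
from .genesets import GeneSet, GeneSetCollection, write_collection

_BUNDLE_FILES = (
    "gene_info.tsv", "sets.tsv", "background.txt", "pairs.tsv",
    "pathway.xml", "gene2pubmed.tsv", "expression.tsv", "probe2gene.tsv",
    "test_genes.txt",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture bundle."""

    seed: int = 0
    species: int = 9606
    n_genes: int = 2000
    n_sets: int = 50
    set_size_range: tuple[int, int] = (20, 80)
    n_test: int = 200
    n_pairs: int = 400
    n_pubs: int = 200
    links_per_pub_range: tuple[int, int] = (1, 30)
    n_tissues: int = 8
    n_probesets: int = 500
    planted_signal: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        counts = dict(
            n_genes=self.n_genes, n_sets=self.n_sets, n_test=self.n_test,
            n_pairs=self.n_pairs, n_pubs=self.n_pubs, n_tissues=self.n_tissues,
            n_probesets=self.n_probesets,
        )
        for key, value in counts.items():
            if value < 1:
                raise FixtureSpecError(f"{key} must be >= 1, got {value}")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise FixtureSpecError(f"invalid set_size_range {self.set_size_range}")
        if hi > self.n_genes:
            raise FixtureSpecError(
                f"set size {hi} exceeds the gene universe ({self.n_genes})"
            )
        lo, hi = self.links_per_pub_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise FixtureSpecError(f"invalid links_per_pub_range {self.links_per_pub_range}")
        if self.n_test > self.n_genes:
            raise FixtureSpecError("n_test exceeds the gene universe")
        if self.planted_signal is not None and self.planted_signal[1] < 1:
            raise FixtureSpecError("planted odds multiplier must be >= 1")


def simulate_collection(spec: FixtureSpec, rng: np.random.Generator) -> GeneSetCollection:
    """Draw the gene-set collection: uniform sizes, members sampled without
    replacement from the universe 1..n_genes."""
    lo, hi = spec.set_size_range
    sets = []
    for i in range(spec.n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(np.arange(1, spec.n_genes + 1), size=size, replace=False)
        sets.append(
            GeneSet(
                set_id=f"set{i:03d}",
                description=f"synthetic gene set {i}",
                members=frozenset(int(g) for g in members),
            )
        )
    return GeneSetCollection(name="synthetic", species=spec.species, sets=sets)


def simulate_test_list(
    spec: FixtureSpec, collection: GeneSetCollection, rng: np.random.Generator
) -> list[int]:
    """Draw the test list from the universe, oversampling the planted target
    set's genes by the odds multiplier (weight multiplier vs weight 1)."""
    genes = np.arange(1, spec.n_genes + 1)
    weights = np.ones(spec.n_genes, dtype=float)
    if spec.planted_signal is not None:
        target_id, multiplier = spec.planted_signal
        if target_id not in collection:
            raise FixtureSpecError(f"planted target {target_id!r} not in collection")
        target = collection[target_id]
        idx = np.fromiter(target.members, dtype=int) - 1
        weights[idx] = multiplier
    probs = weights / weights.sum()
    drawn = rng.choice(genes, size=spec.n_test, replace=False, p=probs)
    return sorted(int(g) for g in drawn)


def simulate_planted_instance(
    spec: FixtureSpec,
) -> tuple[GeneSetCollection, list[int], list[int]]:
    """(collection, background, test list) for an in-memory enrichment run;
    the same draws the file bundle serializes."""
    rng = np.random.default_rng(spec.seed)
    collection = simulate_collection(spec, rng)
    background = list(range(1, spec.n_genes + 1))
    test = simulate_test_list(spec, collection, rng)
    return collection, background, test


def _gene_info_lines(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    lines = ["#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\n"]
    with_syn = set(
        int(g) for g in rng.choice(
            np.arange(1, spec.n_genes + 1),
            size=max(1, spec.n_genes // 10), replace=False,
        )
    )
    for gid in range(1, spec.n_genes + 1):
        syn = f"SYN{gid}|ALT{gid}" if gid in with_syn else "-"
        lines.append(f"{spec.species}\t{gid}\tG{gid}\t-\t{syn}\n")
    return lines


def _pair_lines(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < min(spec.n_pairs, spec.n_genes * (spec.n_genes - 1) // 2):
        a, b = (int(x) for x in rng.integers(1, spec.n_genes + 1, size=2))
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    return ["#geneA\tgeneB\n"] + [f"{a}\t{b}\n" for a, b in sorted(pairs)]


def _kgml_text(spec: FixtureSpec, rng: np.random.Generator) -> str:
    """A small pathway document: one gene entry per chosen gene, relations
    wiring a random subset of entry pairs."""
    n_entries = min(30, spec.n_genes)
    genes = sorted(
        int(g) for g in rng.choice(np.arange(1, spec.n_genes + 1),
                                   size=n_entries, replace=False)
    )
    org = "hsa" if spec.species == 9606 else f"t{spec.species}"
    out = [
        '<?xml version="1.0"?>\n',
        f'<pathway name="path:{org}99999" org="{org}" number="99999" title="synthetic pathway">\n',
    ]
    for i, g in enumerate(genes, start=1):
        out.append(f'  <entry id="{i}" name="{org}:{g}" type="gene"/>\n')
    n_rel = min(40, n_entries * (n_entries - 1) // 2)
    rel: set[tuple[int, int]] = set()
    while len(rel) < n_rel:
        i, j = (int(x) for x in rng.integers(1, n_entries + 1, size=2))
        if i != j:
            rel.add((min(i, j), max(i, j)))
    for i, j in sorted(rel):
        out.append(
            f'  <relation entry1="{i}" entry2="{j}" type="PPrel">'
            '<subtype name="binding/association" value="---"/></relation>\n'
        )
    out.append("</pathway>\n")
    return "".join(out)


def _publink_lines(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    lines = ["#tax_id\tGeneID\tPubMed_ID\n"]
    lo, hi = spec.links_per_pub_range
    for pub in range(1, spec.n_pubs + 1):
        k = int(rng.integers(lo, hi + 1))
        genes = sorted(
            int(g) for g in rng.choice(np.arange(1, spec.n_genes + 1),
                                       size=k, replace=False)
        )
        for g in genes:
            lines.append(f"{spec.species}\t{g}\t{10_000_000 + pub}\n")
    return lines


def _expression_lines(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    tissues = [f"tissue{t}" for t in range(1, spec.n_tissues + 1)]
    matrix = ["probeset\t" + "\t".join(tissues) + "\n"]
    probe_map = ["#probeset\tGeneID\n"]
    gene_ids = rng.integers(1, spec.n_genes + 1, size=spec.n_probesets)
    for p in range(1, spec.n_probesets + 1):
        values = rng.gamma(shape=0.5, scale=100.0, size=spec.n_tissues)
        row = "\t".join(f"{v:.2f}" for v in values)
        matrix.append(f"ps{p:05d}\t{row}\n")
        probe_map.append(f"ps{p:05d}\t{int(gene_ids[p - 1])}\n")
    return matrix, probe_map


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture bundle into *out_dir*; byte-deterministic
    given the seed.  Returns a name -> path map of the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # collection and test list share the seed stream with simulate_planted_instance
    collection = simulate_collection(spec, rng)
    test = simulate_test_list(spec, collection, rng)

    paths: dict[str, Path] = {name: out / name for name in _BUNDLE_FILES}
    paths["gene_info.tsv"].write_text("".join(_gene_info_lines(spec, rng)))
    paths["sets.tsv"].write_text("".join(write_collection(collection)))
    paths["background.txt"].write_text(
        "".join(f"{g}\n" for g in range(1, spec.n_genes + 1))
    )
    paths["pairs.tsv"].write_text("".join(_pair_lines(spec, rng)))
    paths["pathway.xml"].write_text(_kgml_text(spec, rng))
    paths["gene2pubmed.tsv"].write_text("".join(_publink_lines(spec, rng)))
    matrix, probe_map = _expression_lines(spec, rng)
    paths["expression.tsv"].write_text("".join(matrix))
    paths["probe2gene.tsv"].write_text("".join(probe_map))
    paths["test_genes.txt"].write_text("".join(f"{g}\n" for g in test))
    return paths
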