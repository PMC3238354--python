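# Methods

## Model and procedure

enrichkit implements classical gene-set analysis (GSA) by 2×2 contingency:
a test gene list *T* (e.g. differentially expressed genes) is compared to
each gene set *S* of a collection, conditioning on a background universe
*B* (the genes the test list could have been drawn from — an array's probe
content, a custom disease-gene list, or the genes with interaction or
literature data). All counting is done inside *B*: a set's effective size
is |S ∩ B|, and test genes outside *B* are dropped with a warning rather
than silently included, because they would corrupt the table margins.

### Exact test

The two-sided p-value sums the hypergeometric point probabilities of every
table with the observed margins whose probability does not exceed the
observed table's. Point probabilities are computed as `hypergeom.logpmf`
over the support and summed with `logsumexp`; the comparison uses a
relative tolerance of 1e-7 (probabilities within a factor 1+1e-7 of the
observed one count as "equal"), matching the convention of R's
`fisher.test` so that results are reproducible against R-based stacks.
Verified against exact integer-arithmetic enumeration over all 132,470
tables with positive margins and total ≤ 40, the maximum absolute error is
~7e-15.

Degenerate margins are handled at two levels. The public
`fisher_exact_two_sided` raises on a zero margin, where the test is
undefined. The enrichment loop, however, can legitimately produce tables
whose hypergeometric support is a single point (a set disjoint from the
background, a set covering the whole background, or a test list equal to
the background); there the only possible table has probability 1 and the
p-value is set to 1 directly.

### Direction

A set is "over"-represented iff a/|T| > |S ∩ B|/|B| (computed in integer
arithmetic as a·|B| > |S ∩ B|·|T| to avoid float ties); exact ties resolve
to "under". Directions are labels on the two-sided p-value, not separate
one-sided tests.

### Storey q-values

π0, the proportion of true nulls, is estimated from
π0(λ) = #{p > λ} / (m(1−λ)) on the grid λ = 0, 0.05, …, 0.90 (19 points).
The smoother fits a cubic smoothing spline to (λ, π0(λ)) and evaluates it
at the grid maximum. The spline's penalty is chosen so that the effective
degrees of freedom (trace of the hat matrix, computed by fitting the unit
vectors and bisecting on log-penalty, cached per grid) equal 3 — the
published default of the q-value method, which specifies
`smooth.spline(λ, π0, df = 3)`. We verified agreement with R's
`smooth.spline` to ~1e-5 on identical inputs. The estimate is clamped to
(0, 1]; a non-positive spline value (possible only for very short
p-vectors, where the smoother is unstable) falls back to the conservative
π0 = 1 with a warning, which reduces the correction to Benjamini–Hochberg
rather than driving every q-value toward 0.

q-values are the standard step-up transform
q(i) = min over j ≥ i of π0·m·p(j)/j on ascending p-values, clamped to ≤ 1
and mapped back to input order. With `pi0_method="fixed"` and
`fixed_pi0=1` the output equals Benjamini–Hochberg exactly (tested against
statsmodels' `fdr_bh` on 1000 random vectors).

Null behaviour of the smoother at m = 2000: the estimate's sampling sd is
about 0.03, so individual null simulations occasionally dip to ~0.85; its
mean over 50 simulations sits near 0.98. In the FDR mixture simulation
(m = 2000, π0 = 0.8, alternatives p = U⁴), the mean realized
false-discovery proportion among calls at q ≤ 0.05 is ~0.047 over 200
replicates.

### Report assembly

q-values are computed across **all** sets of the collection before any
display filtering (filtering first would bias π0). In representation mode,
rows with p ≤ 0.05 (configurable) are retained and sorted by ascending p;
q is displayed but never filtered on, so results whose q-value just
exceeds the threshold remain visible. Percent-cover mode ranks all sets by
100·|T ∩ S|/|S ∩ B| descending with no filter (sets absent from the
background get cover 0). All ties break lexicographically by set id so
reports are byte-stable.

## Set construction

* **Ontology rollup.** Each term's set contains its directly annotated
  genes plus the members of every descendant term. Implemented as one
  reverse-topological accumulation over the parent edges (children
  processed before parents, via `graphlib`), which is linear in the edge
  count; verified against a brute-force transitive-closure oracle on
  random DAGs. All edge types are treated uniformly (the parent-edge file
  does not distinguish is_a from part_of), and cycles raise a structural
  error. Terms with empty rolled-up membership are omitted.
* **Co-citation topics.** Per topic, the genes of its publications are
  unioned after dropping publications linked to *more than* 100 genes
  (exactly 100 is retained) — large-gene-count publications are typically
  unspecific library or array papers. An optional homolog map converts
  non-human genes to human identifiers; genes with no homolog are dropped
  and counted in the log.
* **Tissue specificity.** Per probeset, intensities are summed over
  tissues; the probeset's gene joins every tissue carrying ≥ 25%
  (inclusive, configurable) of the total. A probeset can therefore join at
  most ⌊1/fraction⌋ tissues; probesets with zero total contribute nothing;
  multiple probesets for one gene union their memberships (sets hold
  genes, not probes).
* **Keyword sets.** A generic grouping of a pre-extracted (gene, term)
  table — one set per term — standing in for protein-keyword and
  subcellular-location style annotations.

## Interaction networks

Pairs are unordered and self-pairs are discarded everywhere. Co-occurrence
pairing uses **shared** publications: (a, b) is a pair iff
|pubs(a) ∩ pubs(b)| ≥ 5. The threshold is a parameter because the
alternative reading (each gene independently citing ≥ 5 publications)
defines no pairwise relation. KGML relations are taken between entries of
type `gene`, contributing the cross-product of the entries' identifier
lists; relation subtypes (activation, inhibition, binding, …) are
deliberately collapsed — the toolkit makes no inference about interaction
type. Expansion is breadth-first reachability within depth 1–3 (networkx),
cumulative across levels, with the seed excluded so that seed-containing
sets are not trivially hit; the background is every gene incident to at
least one pair, independent of seed and depth. For KGML sources this means
relation-incident genes rather than full pathway membership; an explicit
background file can override it.

## Literature-derived lists

A gene2pubmed-dialect table gives gene ↔ publication links for one
species. The test list is the union of genes linked to any queried
publication identifier (unknown identifiers contribute nothing and are
counted); the background is every gene with at least one link, so querying
all publications makes the test equal the background and every p-value 1.
The live literature-query step is out of scope: publication identifiers
arrive as a file, which keeps the pipeline deterministic and offline. No
per-publication gene-count cap is applied here (that rule belongs to the
co-citation set builder).

## Synthetic fixtures

The generator emulates the NCBI file dialects at desk scale with a single
seeded `numpy` Generator per bundle, so output is byte-identical across
runs. Defaults (2000 genes, 50 sets of 20–80 members, 200-gene test list,
200 publications with 1–30 gene links, 8 tissues × 500 probesets with
gamma-distributed intensities) are sized so that enrichment, co-occurrence
and tissue rules all have non-trivial structure while a full
fixture-to-report run takes milliseconds. The planted signal weights the
target set's genes by an odds multiplier in a without-replacement draw of
the test list; multiplier 1 reproduces the unweighted draw exactly. At the
default scale with multiplier 8, the planted set is recovered as the top
row in ≥ 95 of 100 seeds.

What the fixtures do **not** emulate: correlated set memberships (real GO
terms are nested), scale (real collections have thousands of sets),
annotation bias toward well-studied genes, and the heavy-tailed
publication-per-gene distribution. Passing the planted-recovery tests
therefore demonstrates the statistical machinery is wired correctly, not
that any biological discovery claim transfers to real data.

## Numerical and design choices

* Log-space summation makes the exact test stable for large backgrounds
  (hypergeometric point masses underflow long before the p-value does).
* The symbol resolver takes all-digit tokens as Entrez IDs verbatim (NCBI
  symbols are non-numeric in practice), looks up exact-case official
  symbols before case-insensitive ones before synonyms, and reports
  ambiguous synonyms instead of guessing — silent misresolution would
  corrupt the downstream margins.
* The set-vs-set query uses the union of the target collection's members
  as its default background, mirroring the interaction engine's
  "all genes with data" convention; a flag overrides it.
* Problem sizes in the test suite and acceptance script (tables to total
  40, 50–200 simulation replicates, 100 random graphs/DAGs) are chosen so
  each oracle comparison is exhaustive or statistically decisive while the
  whole battery runs in well under a minute.

## Known limitations

* Only single-species analyses; cross-species resolution exists solely as
  the homolog map input of the co-citation builder.
* The q-value smoother is a point estimate; no bootstrap alternative is
  provided.
* KGML parsing reads entries and relations only (no reaction elements or
  group entries), which covers pairing but not full pathway topology.
* Percent-cover mode attaches no significance statement by construction.
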