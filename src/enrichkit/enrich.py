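"""Over/under-representation statistics: exact tests, q-values, reports.

The engine compares a test gene list against each set of a collection,
conditioning on a background (universe) gene list.  For each set the 2x2
table

    ====================  ============  ================
                          in set        not in set
    ====================  ============  ================
    in test list          a             b
    not in test list      c             d
    ====================  ============  ================

is scored with the two-sided Fisher exact test (summing hypergeometric point
probabilities no larger than the observed one, the convention of R's
``fisher.test``), and the p-values across the whole collection are converted
to Storey q-values.  A percent-cover mode ranks sets by
100*|test ∩ set| / |set ∩ background| instead, with no significance filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence, TextIO
import logging
import warnings

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .errors import DegenerateTableError, InputError
from .genesets import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

# relative tolerance when comparing point probabilities, as in R's fisher.test
_REL_TOL = 1e-7

_DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 0.901, 0.05), 2))


class ContingencyTable(NamedTuple):
    in_test_in_set: int
    in_test_not_set: int
    not_test_in_set: int
    not_test_not_set: int


@dataclass(frozen=True)
class QvalueParams:
    """Parameters of the Storey q-value computation.

    ``lambda_grid`` is the ascending grid of tuning values on [0, 0.9] at
    which pi0 (the null proportion) is estimated; the smoother method fits a
    cubic smoothing spline to the grid estimates and reads off the value at
    the grid maximum, while the fixed method uses ``fixed_pi0`` directly
    (``fixed_pi0 = 1`` reduces the q-values to Benjamini-Hochberg).
    """

    lambda_grid: tuple[float, ...] = _DEFAULT_LAMBDA_GRID
    pi0_method: str = "smoother"
    fixed_pi0: float = 1.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise InputError("lambda_grid must be non-empty and strictly ascending")
        if grid[0] < 0 or grid[-1] > 0.9:
            raise InputError("lambda_grid values must lie in [0, 0.9]")
        if self.pi0_method not in ("smoother", "fixed"):
            raise InputError(f"unknown pi0_method {self.pi0_method!r}")
        if not (0 < self.fixed_pi0 <= 1):
            raise InputError("fixed_pi0 must be in (0, 1]")


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    description: str
    count: int
    set_size: int
    test_size: int
    background_size: int
    direction: str  # "over" | "under"
    p_value: float
    q_value: float
    percent_cover: float


@dataclass
class EnrichmentReport:
    rows: list[EnrichmentRow]
    method: str  # "representation" | "percent_cover"
    dropped_genes: list[int]
    p_threshold: float
    pi0: float
    test_size: int
    background_size: int
    members: dict[str, list[int]] = field(default_factory=dict)


def fisher_exact_two_sided(table: ContingencyTable | Sequence[int]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums, in log space, the hypergeometric point probabilities of every
    table with the same margins whose probability does not exceed the
    observed table's (to within relative tolerance 1e-7).  Raises
    :class:`DegenerateTableError` when a margin is zero.
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise InputError("contingency table cells must be non-negative")
    n_total = a + b + c + d
    row1 = a + b  # test-list size
    col1 = a + c  # set size
    if n_total == 0:
        raise DegenerateTableError("empty table")
    if row1 == 0 or row1 == n_total or col1 == 0 or col1 == n_total:
        raise DegenerateTableError(
            f"zero margin in table ({a},{b},{c},{d}); the exact test is undefined"
        )
    k_min = max(0, row1 + col1 - n_total)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    log_pmf = hypergeom.logpmf(support, n_total, col1, row1)
    log_obs = log_pmf[a - k_min]
    mask = log_pmf <= log_obs + np.log1p(_REL_TOL)
    p = float(np.exp(logsumexp(log_pmf[mask])))
    return min(p, 1.0)


def _hat_trace(x: np.ndarray, lam: float) -> float:
    """Effective degrees of freedom (trace of the smoother matrix) of the
    cubic smoothing spline on design points x at penalty lam."""
    n = x.size
    tr = 0.0
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        tr += float(make_smoothing_spline(x, e, lam=lam)(x[i]))
    return tr


@lru_cache(maxsize=8)
def _lambda_for_df(x_key: tuple[float, ...], df: float) -> float:
    """Penalty value at which the smoothing spline on grid x has the target
    effective degrees of freedom, found by bisection on log10(lam)."""
    x = np.asarray(x_key, dtype=float)
    lo, hi = -12.0, 12.0  # log10 penalty bracket: ~interpolation .. ~linear fit
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _hat_trace(x, 10.0 ** mid) > df:
            lo = mid
        else:
            hi = mid
    return 10.0 ** (0.5 * (lo + hi))


def estimate_pi0(pvals: np.ndarray, params: QvalueParams) -> float:
    """Estimate the proportion of true nulls, pi0.

    Grid estimates pi0(lambda) = #{p > lambda} / (m (1 - lambda)) are
    smoothed with a cubic smoothing spline at ~3 effective degrees of
    freedom and evaluated at the grid maximum; the result is clamped to
    (0, 1].
    """
    m = pvals.size
    if params.pi0_method == "fixed":
        return params.fixed_pi0
    grid = np.asarray(params.lambda_grid, dtype=float)
    pi0_lam = np.array([(pvals > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if grid.size < 4:
        pi0 = float(pi0_lam[-1])
    else:
        lam_star = _lambda_for_df(tuple(grid), 3.0)
        spline = make_smoothing_spline(grid, pi0_lam, lam=lam_star)
        pi0 = float(spline(grid[-1]))
    if pi0 <= 0:
        # too few p-values for the smoother to be stable; fall back to the
        # conservative pi0 = 1 (q-values then reduce to Benjamini-Hochberg)
        warnings.warn(
            "estimated pi0 <= 0 (unstable smoother, typically very few "
            "p-values); falling back to pi0 = 1",
            stacklevel=2,
        )
        pi0 = 1.0
    return min(pi0, 1.0)


def storey_qvalues(
    pvals: Sequence[float], params: QvalueParams | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values for a vector of p-values.

    Returns (q-values in the input order, estimated pi0).  With
    ``pi0_method='fixed'`` and ``fixed_pi0=1`` the q-values equal the
    Benjamini-Hochberg adjusted p-values exactly.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise InputError("p-value list is empty")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    params = params or QvalueParams()
    pi0 = estimate_pi0(p, params)
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q_sorted = pi0 * m * p_sorted / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, pi0


def _set_p_value(count: int, set_size: int, test_size: int, background_size: int) -> float:
    """p-value for one set; degenerate margins (a single-point hypergeometric
    support) give p = 1 directly."""
    if set_size in (0, background_size) or test_size in (0, background_size):
        return 1.0
    return fisher_exact_two_sided(
        (count, test_size - count, set_size - count,
         background_size - test_size - set_size + count)
    )


def enrich(
    test: Iterable[int],
    background: Iterable[int],
    collection: GeneSetCollection,
    method: str = "representation",
    params: QvalueParams | None = None,
    p_threshold: float = 0.05,
) -> EnrichmentReport:
    """Score a test gene list against every set of a collection.

    Test genes absent from the background are dropped (reported in
    ``dropped_genes``).  In representation mode, q-values are computed over
    all sets of the collection before the display filter, rows with
    p <= ``p_threshold`` are retained and sorted by ascending p (q is never
    filtered on); in percent_cover mode all sets are retained, ranked by
    descending percent cover.  Ties break by set_id.
    """
    if method not in ("representation", "percent_cover"):
        raise InputError(f"unknown method {method!r}")
    if len(collection) == 0:
        raise InputError("gene-set collection is empty")
    bg = frozenset(background)
    if not bg:
        raise InputError("background list is empty")

    test_ordered: list[int] = []
    seen: set[int] = set()
    for g in test:
        if g not in seen:
            seen.add(g)
            test_ordered.append(g)
    dropped = sorted(g for g in test_ordered if g not in bg)
    test_in = [g for g in test_ordered if g in bg]
    if not test_in:
        raise InputError(
            f"no test genes found in the background; dropped: {dropped}"
        )
    if dropped:
        logger.warning("%d test genes absent from the background were dropped",
                       len(dropped))

    test_set = frozenset(test_in)
    n = len(test_set)
    big_n = len(bg)

    raw: list[tuple[GeneSet, int, int]] = []
    for s in collection:
        members_bg = s.members & bg
        raw.append((s, len(test_set & members_bg), len(members_bg)))

    pvals = np.array(
        [_set_p_value(count, k, n, big_n) for _, count, k in raw], dtype=float
    )
    qvals, pi0 = storey_qvalues(pvals, params)

    rows: list[EnrichmentRow] = []
    members: dict[str, list[int]] = {}
    for (s, count, k), p, q in zip(raw, pvals, qvals):
        # over iff count/n > k/N, ties resolve to under
        direction = "over" if count * big_n > k * n else "under"
        cover = 100.0 * count / k if k else 0.0
        rows.append(
            EnrichmentRow(
                set_id=s.set_id, description=s.description, count=count,
                set_size=k, test_size=n, background_size=big_n,
                direction=direction, p_value=float(p), q_value=float(q),
                percent_cover=cover,
            )
        )
        members[s.set_id] = sorted(test_set & s.members)

    if method == "representation":
        rows = [r for r in rows if r.p_value <= p_threshold]
        rows.sort(key=lambda r: (r.p_value, r.set_id))
    else:
        rows.sort(key=lambda r: (-r.percent_cover, r.set_id))
    members = {r.set_id: members[r.set_id] for r in rows}
    return EnrichmentReport(
        rows=rows, method=method, dropped_genes=dropped, p_threshold=p_threshold,
        pi0=pi0, test_size=n, background_size=big_n, members=members,
    )


def query_set_vs_collection(
    source_set_id: str,
    source_collection: GeneSetCollection,
    target_collection: GeneSetCollection,
    params: QvalueParams | None = None,
    p_threshold: float = 0.05,
    background: Iterable[int] | None = None,
) -> EnrichmentReport:
    """Enrich one gene set of a source collection against a target collection.

    The default background is the union of all members across the target
    collection; an explicit background overrides it.
    """
    if source_set_id not in source_collection:
        raise InputError(
            f"set {source_set_id!r} not in collection {source_collection.name!r}"
        )
    source = source_collection[source_set_id]
    bg = frozenset(background) if background is not None else target_collection.all_members()
    return enrich(sorted(source.members), bg, target_collection,
                  method="representation", params=params, p_threshold=p_threshold)


_REPORT_COLUMNS = (
    "rank", "set_id", "description", "count", "set_size", "test_size",
    "background_size", "direction", "percent_cover", "p_value", "q_value",
)


def write_report(report: EnrichmentReport, handle: TextIO) -> None:
    """Write the ranked report as TSV (columns fixed, floats in %.6g)."""
    handle.write("\t".join(_REPORT_COLUMNS) + "\n")
    for rank, r in enumerate(report.rows, start=1):
        handle.write(
            "\t".join(
                (
                    str(rank), r.set_id, r.description, str(r.count),
                    str(r.set_size), str(r.test_size), str(r.background_size),
                    r.direction, f"{r.percent_cover:.6g}",
                    f"{r.p_value:.6g}", f"{r.q_value:.6g}",
                )
            )
            + "\n"
        )


def write_membership(report: EnrichmentReport, handle: TextIO) -> None:
    """Companion file: per retained set, the intersecting test gene IDs."""
    for r in report.rows:
        ids = ",".join(str(g) for g in report.members.get(r.set_id, []))
        handle.write(f"{r.set_id}\t{ids}\n")
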