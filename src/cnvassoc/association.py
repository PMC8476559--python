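"""Case-control association statistics for digitized copy numbers.

Builds 2xk contingency tables from dCN calls under named binning schemes
and provides the tests used to analyze them: Pearson chi-squared,
Fisher's exact test generalized to 2xk tables (Freeman-Halton, with exact
enumeration or Monte Carlo under fixed margins), odds ratios with an
explicit zero-cell policy (the substitute-one lower bound or the
Haldane-Anscombe correction), the Wilcoxon rank-sum test on continuous
sCN, and Bonferroni adjustment with a declared family size.

The two-sided exact p-value follows the point-probability convention:
the total null probability of all tables (with the observed margins)
whose probability does not exceed the observed table's.  At k=2 this is
the standard two-sided Fisher test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "FisherResult",
    "OddsRatioResult",
    "build_contingency",
    "fisher_exact",
    "chi_squared",
    "odds_ratio",
    "wilcoxon_rank_sum",
    "bonferroni",
    "clinical_association",
]

# above this many candidate first rows, exact enumeration refuses and the
# auto policy switches to Monte Carlo
_ENUMERATION_LIMIT = 2_000_000
# tie tolerance when comparing table log-probabilities: wide enough for
# float error in summed gammaln terms, narrow enough never to merge
# genuinely distinct hypergeometric probabilities
_LOG_TIE_TOL = 1e-10


@dataclass(frozen=True)
class ContingencyTable:
    """A 2xk group-by-category count table (rows: control, case)."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("control", "case")
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != 2 or c.shape[1] < 2:
            raise ValueError("counts must be a 2 x k matrix with k >= 2")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if np.any(c.sum(axis=1) == 0):
            raise ValueError("each row must have a positive total")
        object.__setattr__(self, "counts", c)
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels", tuple(str(i) for i in range(c.shape[1]))
            )

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FisherResult:
    p: float
    method: str  # "exact" or "monte_carlo"
    mc_se: float | None = None
    n_tables: int | None = None


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    is_lower_bound: bool
    ci95: tuple[float, float] | None
    policy: str


@dataclass
class AssociationResult:
    """One association test outcome as reported in the per-gene table."""

    test: str
    p: float
    statistic: float | None = None
    p_adjusted: float | None = None
    m_tests: int | None = None
    odds_ratio: float | None = None
    or_is_lower_bound: bool = False
    ci95: tuple[float, float] | None = None
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# contingency construction


def build_contingency(
    calls: pd.DataFrame,
    gene: str,
    scheme: str = "per_dcn",
    groups: pd.Series | dict | None = None,
    pool_from: int | None = 4,
    custom_bins: list[tuple[str, set]] | None = None,
) -> ContingencyTable:
    """Build a 2xk table of dCN category counts by case/control group.

    Schemes: ``per_dcn`` (one column per dCN, optionally pooling
    ``pool_from`` and above into one bin, as in a "4-6" display bin;
    columns empty in both groups are dropped), ``null_vs_rest`` (dCN 0 vs
    >= 1), ``low_vs_rest`` (dCN 1 vs >= 2) and ``custom`` (explicit
    ``custom_bins`` as (label, set-of-dCN) pairs, all retained).
    """
    sub = calls[calls["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no calls for gene {gene!r}")
    if "group" in sub.columns:
        grp = sub["group"]
    elif groups is not None:
        gmap = dict(groups) if not isinstance(groups, pd.Series) else groups
        grp = sub["sample"].map(gmap)
    else:
        raise ValueError("need a 'group' column or a groups mapping")
    dcn = sub["dCN"].to_numpy(dtype=float)
    keep = np.isfinite(dcn)
    dcn = dcn[keep].astype(int)
    grp = np.asarray(grp)[keep]

    if scheme == "per_dcn":
        top = int(dcn.max())
        if pool_from is not None and top > pool_from:
            bins = [(str(v), {v}) for v in range(0, pool_from)]
            bins.append((f"{pool_from}-{top}", set(range(pool_from, top + 1))))
        else:
            bins = [(str(v), {v}) for v in range(0, top + 1)]
        drop_empty = True
    elif scheme == "null_vs_rest":
        bins = [("0", {0}), ("1+", set(range(1, max(int(dcn.max()), 1) + 1)))]
        drop_empty = False
    elif scheme == "low_vs_rest":
        bins = [("1", {1}), ("2+", set(range(2, max(int(dcn.max()), 2) + 1)))]
        drop_empty = False
    elif scheme == "custom":
        if not custom_bins:
            raise ValueError("custom scheme requires custom_bins")
        bins = custom_bins
        drop_empty = False
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows = []
    for group in ("control", "case"):
        mask = grp == group
        rows.append([int(np.isin(dcn[mask], list(members)).sum()) for _, members in bins])
    counts = np.array(rows)
    labels = [label for label, _ in bins]
    if drop_empty:
        nonzero = counts.sum(axis=0) > 0
        counts = counts[:, nonzero]
        labels = [l for l, keep_col in zip(labels, nonzero) if keep_col]
    if counts.shape[1] < 2:
        raise ValueError(
            f"scheme {scheme!r} leaves fewer than 2 non-empty categories for {gene!r}"
        )
    return ContingencyTable(counts, col_labels=tuple(labels))


# ---------------------------------------------------------------------------
# Fisher exact (Freeman-Halton)


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.add(n, 1)) - gammaln(np.add(k, 1)) - gammaln(np.subtract(n, k) + 1)


def _enumerate_first_rows(cols: np.ndarray, r1: int, limit: int) -> tuple[np.ndarray, np.ndarray]:
    """All feasible first rows with their log "column weight"
    sum_j log C(c_j, a_j), via a vectorized sweep over columns.

    Returns (log-weights, multiplicity is implicit: one entry per table).
    Raises MemoryError-like ValueError beyond ``limit`` candidate rows.
    """
    k = len(cols)
    suffix = np.concatenate([np.cumsum(cols[::-1])[::-1][1:], [0]])
    # states: partial sums with an array of accumulated log-weights each
    states: dict[int, np.ndarray] = {0: np.zeros(1)}
    for j in range(k):
        new: dict[int, list] = {}
        total = 0
        for s, lws in states.items():
            lo = max(0, r1 - s - int(suffix[j]))
            hi = min(int(cols[j]), r1 - s)
            for a in range(lo, hi + 1):
                arr = lws + _log_binom(int(cols[j]), a)
                new.setdefault(s + a, []).append(arr)
                total += arr.size
        if total > limit:
            raise ValueError("table too large for exact enumeration")
        states = {s: np.concatenate(v) for s, v in new.items()}
    lw = states.get(r1)
    if lw is None:
        raise ValueError("margins are infeasible")
    return lw, suffix


def fisher_exact(
    table: ContingencyTable | np.ndarray,
    method: str = "auto",
    B: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
) -> FisherResult:
    """Two-sided exact test of independence for a 2xk table.

    The p-value is the total probability, under the multivariate
    hypergeometric null with the observed margins, of all tables whose
    point probability is at most the observed table's (ties compared with
    a small relative tolerance on the log scale).  ``method`` is
    ``exact`` (full enumeration of first rows, refused above an internal
    size limit), ``monte_carlo`` (B sampled tables under the null, p
    reported with its standard error), or ``auto`` (exact when feasible,
    Monte Carlo otherwise).
    """
    t = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, int)
    cols = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    obs_lw = float(_log_binom(cols, t[0]).sum())
    tol = _LOG_TIE_TOL * max(1.0, abs(obs_lw))

    if method not in ("auto", "exact", "exact_enumeration", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")

    if method in ("auto", "exact", "exact_enumeration"):
        try:
            lw, _ = _enumerate_first_rows(cols, r1, _ENUMERATION_LIMIT)
        except ValueError:
            if method != "auto":
                raise ValueError(
                    "table too large for exact enumeration; use method='monte_carlo'"
                ) from None
        else:
            log_norm = float(_log_binom(n, r1))
            keep = lw <= obs_lw + tol
            m = lw[keep] - log_norm
            p = float(np.exp(m).sum()) if m.size else 0.0
            return FisherResult(p=min(p, 1.0), method="exact", n_tables=int(lw.size))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols.astype(np.int64), r1, size=B)
    lw = _log_binom(cols[None, :], draws).sum(axis=1)
    hits = int((lw <= obs_lw + tol).sum())
    # add-one estimator keeps p positive and nearly unbiased
    p = (hits + 1) / (B + 1)
    se = float(np.sqrt(p * (1 - p) / B))
    return FisherResult(p=float(p), method="monte_carlo", mc_se=se)


def chi_squared(
    table: ContingencyTable | np.ndarray, yates: bool = False
) -> tuple[float, float, list]:
    """Pearson chi-squared test of independence for a 2xk table.

    No continuity correction by default (``yates`` applies it for 2x2).
    Returns (statistic, p, warnings); a warning is recorded when any
    expected cell is below 5, but the test is never silently switched.
    """
    t = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-squared undefined")
    stat, p, _, expected = stats.chi2_contingency(t, correction=yates)
    warns = []
    if np.any(expected < 5):
        warns.append("expected count below 5 in at least one cell")
    return float(stat), float(p), warns


def odds_ratio(
    table: ContingencyTable | np.ndarray, zero_cell_policy: str = "substitute_one"
) -> OddsRatioResult:
    """Odds ratio of exposure (first column) for cases vs controls.

    Layout: ``[[control_exposed, control_unexposed], [case_exposed,
    case_unexposed]]``.  With a zero cell the OR is unbounded; policies:
    ``substitute_one`` replaces each zero cell with 1 and flags the result
    as a lower bound (CI suppressed), ``haldane`` adds 0.5 to every cell,
    ``error`` raises.  The 95% CI is the Woolf log-OR normal interval.
    """
    t = np.asarray(
        table.counts if isinstance(table, ContingencyTable) else table, dtype=float
    )
    if t.shape != (2, 2):
        raise ValueError("odds ratio needs a 2x2 table")
    has_zero = bool(np.any(t == 0))
    is_bound = False
    if has_zero:
        if zero_cell_policy == "substitute_one":
            t = np.where(t == 0, 1.0, t)
            is_bound = True
        elif zero_cell_policy == "haldane":
            t = t + 0.5
        elif zero_cell_policy == "error":
            raise ValueError("zero cell in table and zero_cell_policy='error'")
        else:
            raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    (a, b), (c, d) = t  # a,b: control exposed/unexposed; c,d: case
    orv = (c * b) / (d * a)
    ci = None
    if not is_bound:
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci = (float(orv * np.exp(-1.959963984540054 * se)), float(orv * np.exp(1.959963984540054 * se)))
    return OddsRatioResult(
        odds_ratio=float(orv), is_lower_bound=is_bound, ci95=ci, policy=zero_cell_policy
    )


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 50
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when both samples are small and
    untied, the tie-corrected normal approximation otherwise.  Returns
    (U statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni(p_values, m: int):
    """Bonferroni adjustment with a declared family size: min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < p.size:
        raise ValueError("declared family size m smaller than the number of p-values")
    adj = np.minimum(1.0, m * p)
    return float(adj[0]) if scalar else adj


def clinical_association(
    null_status: pd.Series,
    clinical_flags: pd.DataFrame,
    m: int | None = None,
) -> pd.DataFrame:
    """Fisher 2x2 association of a binary genotype status (e.g.
    gene-null) with each binary clinical variable.

    Rows are aligned on the shared sample index.  Variables that are
    constant after alignment are skipped with a warning.  ``m`` declares
    a Bonferroni family size over the tested variables.
    """
    common = null_status.index.intersection(clinical_flags.index)
    if len(common) == 0:
        raise ValueError("no shared sample ids")
    status = null_status.loc[common].astype(bool)
    rows = []
    for var in clinical_flags.columns:
        flag = clinical_flags.loc[common, var]
        ok = flag.notna()
        f = flag[ok].astype(bool)
        s = status[ok]
        if f.nunique() < 2 or s.nunique() < 2 or ok.sum() < 2:
            warnings.warn(f"clinical variable {var!r} is constant/degenerate; skipped",
                          stacklevel=2)
            continue
        tab = np.array(
            [
                [int((~s & f).sum()), int((~s & ~f).sum())],
                [int((s & f).sum()), int((s & ~f).sum())],
            ]
        )
        res = fisher_exact(ContingencyTable(tab, row_labels=("status-", "status+"),
                                            col_labels=("flag+", "flag-")))
        rows.append({"variable": var, "p": res.p, "n": int(ok.sum())})
    out = pd.DataFrame(rows, columns=["variable", "p", "n"])
    if m is not None and len(out):
        out["p_adjusted"] = bonferroni(out["p"].to_numpy(), m)
    return out
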