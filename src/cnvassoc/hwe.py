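"""Hardy-Weinberg equilibrium testing for unphased copy-number data.

Only the diploid *total* copy number is observed, so the per-haplotype
copy-class frequencies q_a are estimated by expectation-maximization:
an individual with total k is fractionally assigned to the unordered
haplotype pairs (a, k-a) in proportion to their Hardy-Weinberg
probability, and the M-step averages the implied haplotype counts.  The
expected diploid distribution is then the self-convolution of q, and the
goodness of fit is a Pearson chi-squared with explicit pooling and
degrees-of-freedom conventions, plus a parametric-bootstrap p-value that
sidesteps the df convention entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CNHistogram",
    "AlleleFreqModel",
    "HWEResult",
    "em_fit",
    "expected_diploid",
    "hwe_chisq",
    "hwe_bootstrap",
    "hwe_test",
]


@dataclass(frozen=True)
class CNHistogram:
    """Counts of individuals by diploid total copy number k = 0..k_max."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("counts must be a 1-D vector over k = 0..k_max")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_dict(cls, mapping: dict) -> "CNHistogram":
        kmax = max(int(k) for k in mapping)
        c = np.zeros(kmax + 1)
        for k, v in mapping.items():
            c[int(k)] = v
        return cls(c)

    @classmethod
    def from_calls(cls, calls, gene: str, group: str | None = None) -> "CNHistogram":
        sub = calls[calls["gene"] == gene]
        if group is not None:
            sub = sub[sub["group"] == group]
        dcn = sub["dCN"].to_numpy(dtype=float)
        dcn = dcn[np.isfinite(dcn)].astype(int)
        if dcn.size == 0:
            raise ValueError(f"no calls for {gene!r}/{group!r}")
        return cls(np.bincount(dcn))

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def k_max(self) -> int:
        return len(self.counts) - 1


@dataclass(frozen=True)
class AlleleFreqModel:
    """EM-fitted haplotype copy-class frequencies."""

    q: np.ndarray
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    a_max: int


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p_asymptotic: float
    expected: np.ndarray
    observed: np.ndarray
    pooling_applied: tuple = ()
    saturated: bool = False
    p_bootstrap: float | None = None
    model: AlleleFreqModel | None = None


def _default_a_max(hist: CNHistogram) -> int:
    """Smallest haplotype space consistent with the data."""
    observed = np.flatnonzero(hist.counts)
    kmax = int(observed.max()) if observed.size else 1
    return max(1, int(np.ceil(kmax / 2)))


def _pair_index(a_max: int):
    """Ordered-pair bookkeeping shared by E-steps."""
    A = a_max + 1
    ai, bi = np.meshgrid(np.arange(A), np.arange(A), indexing="ij")
    ai, bi = ai.ravel(), bi.ravel()
    return ai, bi, ai + bi


def _em_q(
    counts: np.ndarray,
    a_max: int,
    q0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, bool]:
    """Lean EM inner loop (no trace), shared with the bootstrap."""
    n = counts.sum()
    K = len(counts) - 1
    ai, bi, ks = _pair_index(a_max)
    ck = np.zeros(2 * a_max + 1)
    ck[: K + 1] = counts
    q = q0.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = q[ai] * q[bi]  # ordered-pair HW probabilities
        pk = np.bincount(ks, weights=w, minlength=2 * a_max + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            resp = np.where(pk > 0, ck / pk, 0.0)
        # each ordered pair contributes its first haplotype; over both
        # orders this averages the two haplotypes of each individual
        newq = np.bincount(ai, weights=w * resp[ks], minlength=a_max + 1) / n
        delta = np.max(np.abs(newq - q))
        q = newq
        if delta < tol:
            converged = True
            break
    return q, it, converged


def _loglik(counts: np.ndarray, q: np.ndarray) -> float:
    pk = np.convolve(q, q)[: len(counts)]
    with np.errstate(divide="ignore"):
        terms = np.where(counts > 0, counts * np.log(pk), 0.0)
    return float(terms.sum())


def _moment_init(counts: np.ndarray, a_max: int) -> np.ndarray:
    """Initial q proportional to smoothed marginal haplotype counts:
    an individual with total k spreads uniformly over its feasible
    haplotype classes.  Strictly positive so EM never truncates support."""
    q0 = np.full(a_max + 1, 0.5)
    for k, nk in enumerate(counts):
        if nk == 0:
            continue
        lo = max(0, k - a_max)
        hi = min(a_max, k)
        q0[lo : hi + 1] += nk / (hi - lo + 1)
    return q0 / q0.sum()


def em_fit(
    hist: CNHistogram | np.ndarray,
    a_max: int | None = None,
    tol: float = 1e-9,
    max_iter: int = 2000,
    init: str = "moment",
) -> AlleleFreqModel:
    """Maximum-likelihood haplotype copy-class frequencies by EM.

    ``a_max`` defaults to ceil(k_max / 2), the smallest haplotype space
    consistent with the observed totals.  The multinomial log-likelihood
    of the self-convolved q is recorded at each iteration and is
    guaranteed non-decreasing; non-convergence within ``max_iter`` warns
    but still returns the current fit.
    """
    hist = hist if isinstance(hist, CNHistogram) else CNHistogram(hist)
    if hist.n <= 0:
        raise ValueError("empty histogram")
    if a_max is None:
        a_max = _default_a_max(hist)
    if 2 * a_max < hist.k_max and np.any(hist.counts[2 * a_max + 1 :] > 0):
        raise ValueError(
            f"a_max={a_max} cannot produce observed totals up to {hist.k_max}"
        )
    if tol <= 0:
        raise ValueError("tol must be positive")
    counts = hist.counts

    if init == "moment":
        q = _moment_init(counts, a_max)
    elif init == "uniform":
        q = np.full(a_max + 1, 1.0 / (a_max + 1))
    else:
        raise ValueError(f"unknown init {init!r}")

    trace = [_loglik(counts, q)]
    ai, bi, ks = _pair_index(a_max)
    ck = np.zeros(2 * a_max + 1)
    ck[: hist.k_max + 1] = counts
    n = counts.sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = q[ai] * q[bi]
        pk = np.bincount(ks, weights=w, minlength=2 * a_max + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            resp = np.where(pk > 0, ck / pk, 0.0)
        newq = np.bincount(ai, weights=w * resp[ks], minlength=a_max + 1) / n
        delta = np.max(np.abs(newq - q))
        q = newq
        trace.append(_loglik(counts, q))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)
    return AlleleFreqModel(
        q=q,
        loglik=trace[-1],
        loglik_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
        a_max=a_max,
    )


def expected_diploid(model: AlleleFreqModel | np.ndarray, n: float) -> np.ndarray:
    """Expected diploid total-CN counts: n times the self-convolution of
    the haplotype frequencies (sums to n by construction)."""
    q = model.q if isinstance(model, AlleleFreqModel) else np.asarray(model, float)
    return np.convolve(q, q) * n


def _pool_tails(
    observed: np.ndarray, expected: np.ndarray, min_expected: float, labels: list[str]
):
    """Merge categories with small expectation from both tails inward."""
    o = list(observed)
    e = list(expected)
    lab = list(labels)
    merged: list[str] = []
    while len(e) > 2 and e[0] < min_expected:
        merged.append(f"{lab[0]}+{lab[1]}")
        o[1] += o[0]
        e[1] += e[0]
        lab[1] = f"{lab[0]},{lab[1]}"
        del o[0], e[0], lab[0]
    while len(e) > 2 and e[-1] < min_expected:
        merged.append(f"{lab[-2]}+{lab[-1]}")
        o[-2] += o[-1]
        e[-2] += e[-1]
        lab[-2] = f"{lab[-2]},{lab[-1]}"
        del o[-1], e[-1], lab[-1]
    return np.array(o), np.array(e), lab, merged


def hwe_chisq(
    hist: CNHistogram | np.ndarray,
    model: AlleleFreqModel | None = None,
    pooling_min_expected: float = 1.0,
    df_rule: str = "categories_minus_params",
    a_max: int | None = None,
) -> HWEResult:
    """Pearson chi-squared goodness-of-fit test of Hardy-Weinberg
    equilibrium for diploid total-CN counts.

    The expected counts come from the EM-fitted model's self-convolution
    on the grid k = 0..2*a_max.  Adjacent categories with expected counts
    below ``pooling_min_expected`` are merged from both tails inward.
    Default df: (categories after pooling - 1) - a_max free frequency
    parameters, clamped at 1 (flagged as saturated when clamping binds or
    fewer than 2 categories remain).
    """
    hist = hist if isinstance(hist, CNHistogram) else CNHistogram(hist)
    if model is None:
        model = em_fit(hist, a_max=a_max)
    exp = expected_diploid(model, hist.n)
    obs = np.zeros_like(exp)
    obs[: hist.k_max + 1] = hist.counts
    labels = [str(k) for k in range(len(exp))]

    o, e, lab, merged = _pool_tails(obs, exp, pooling_min_expected, labels)
    if len(e) < 2:
        return HWEResult(
            chi2=0.0, df=1, p_asymptotic=1.0, expected=e, observed=o,
            pooling_applied=tuple(merged), saturated=True, model=model,
        )
    chi2 = float(np.sum((o - e) ** 2 / e))
    if df_rule == "categories_minus_params":
        df_raw = (len(e) - 1) - model.a_max
    elif df_rule == "categories_minus_one":
        df_raw = len(e) - 1
    else:
        raise ValueError(f"unknown df_rule {df_rule!r}")
    saturated = df_raw < 1
    df = max(df_raw, 1)
    p = float(stats.chi2.sf(chi2, df))
    return HWEResult(
        chi2=chi2, df=df, p_asymptotic=p, expected=e, observed=o,
        pooling_applied=tuple(merged), saturated=saturated, model=model,
    )


def hwe_bootstrap(
    hist: CNHistogram | np.ndarray,
    a_max: int | None = None,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    pooling_min_expected: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> float:
    """Parametric-bootstrap HWE p-value.

    Draws B cohorts from the fitted Hardy-Weinberg model, refits the EM
    on each and returns (1 + #{chi2* >= chi2_obs}) / (B + 1) — immune to
    the df and pooling conventions of the asymptotic test.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    hist = hist if isinstance(hist, CNHistogram) else CNHistogram(hist)
    res = hwe_chisq(hist, a_max=a_max, pooling_min_expected=pooling_min_expected)
    amax = res.model.a_max
    pk = np.convolve(res.model.q, res.model.q)
    pk = np.maximum(pk, 0)
    pk = pk / pk.sum()
    n = int(round(hist.n))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    q0 = _moment_init(hist.counts, amax)
    exceed = 0
    labels = [str(k) for k in range(2 * amax + 1)]
    for _ in range(B):
        sim = rng.multinomial(n, pk).astype(float)
        q, _, _ = _em_q(sim, amax, q0, tol, max_iter)
        exp = np.convolve(q, q) * n
        o, e, _, _ = _pool_tails(sim, exp, pooling_min_expected, labels)
        if len(e) < 2:
            chi2_b = 0.0
        else:
            chi2_b = float(np.sum((o - e) ** 2 / e))
        if chi2_b >= res.chi2:
            exceed += 1
    return (1 + exceed) / (B + 1)


def hwe_test(
    hist: CNHistogram | np.ndarray,
    a_max: int | None = None,
    bootstrap_B: int | None = None,
    seed: int | np.random.Generator | None = None,
    pooling_min_expected: float = 1.0,
) -> HWEResult:
    """Convenience wrapper: asymptotic test, optionally with a
    parametric-bootstrap p-value attached."""
    res = hwe_chisq(hist, a_max=a_max, pooling_min_expected=pooling_min_expected)
    if bootstrap_B:
        p_boot = hwe_bootstrap(
            hist, a_max=a_max, B=bootstrap_B, seed=seed,
            pooling_min_expected=pooling_min_expected,
        )
        res = HWEResult(
            chi2=res.chi2, df=res.df, p_asymptotic=res.p_asymptotic,
            expected=res.expected, observed=res.observed,
            pooling_applied=res.pooling_applied, saturated=res.saturated,
            p_bootstrap=p_boot, model=res.model,
        )
    return res
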