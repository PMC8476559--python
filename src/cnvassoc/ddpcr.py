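"""Droplet digital PCR quantification.

Gates droplet amplitudes into positive/negative counts, converts counts
to concentrations by limiting-dilution Poisson statistics
(lambda = -ln(1 - k/n) copies per droplet) and calls copy number against
a diploid reference channel.  Includes a linear-regression concordance
check against an independent assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GateResult",
    "DdpcrQuant",
    "ConcordanceResult",
    "gate_droplets",
    "poisson_concentration",
    "copy_number_ddpcr",
    "quantify_well",
    "concordance",
]


@dataclass(frozen=True)
class GateResult:
    n_positive: int
    n_total: int
    threshold: float
    fallback: bool = False  # valley policy fell back to a fixed threshold


@dataclass(frozen=True)
class DdpcrQuant:
    """Per-well quantification: concentrations with 95% CIs and the
    resulting copy-number estimate."""

    lambda_target: float
    lambda_target_ci: tuple[float, float]
    lambda_ref: float
    lambda_ref_ci: tuple[float, float]
    cn_estimate: float
    n_positive_target: int
    n_positive_ref: int
    n_droplets: int


@dataclass(frozen=True)
class ConcordanceResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def _histogram_modes(amplitudes: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed histogram and the indices of its well-separated modes.

    Candidate local maxima (at least 2% of the peak density) are merged
    unless the density between neighbours drops below half the smaller
    one — sampling noise on a single cluster then never splits it.
    """
    counts, edges = np.histogram(amplitudes, bins=bins)
    width = max(3, bins // 32) | 1
    kernel = np.ones(width) / width
    smooth = np.convolve(counts, kernel, mode="same")
    half = width // 2
    candidates = []
    for i in range(len(smooth)):
        lo, hi = max(i - half, 0), i + half + 1
        window = smooth[lo:hi]
        # a real cluster must rise above both relative and absolute floors,
        # or single stray droplets in the tails would count as modes
        floor = max(0.02 * smooth.max(), 1.5)
        if smooth[i] > 0 and smooth[i] == window.max() and smooth[i] >= floor:
            if not candidates or i - candidates[-1] > half:
                candidates.append(i)
    modes: list[int] = []
    for c in candidates:
        if not modes:
            modes.append(c)
            continue
        prev = modes[-1]
        valley = smooth[prev : c + 1].min()
        if valley < 0.5 * min(smooth[prev], smooth[c]):
            modes.append(c)  # genuinely separated cluster
        elif smooth[c] > smooth[prev]:
            modes[-1] = c  # same cluster, keep its taller summit
    centers = 0.5 * (edges[:-1] + edges[1:])
    return smooth, centers, np.array(modes, dtype=int)


def gate_droplets(
    amplitudes: np.ndarray | pd.Series,
    policy: str = "valley",
    threshold: float | None = None,
    bins: int = 256,
    min_positive: float | None = None,
) -> GateResult:
    """Count positive droplets in one channel.

    policy="fixed" counts amplitudes above ``threshold``.  policy="valley"
    places the threshold at the minimum-density point between the two
    uppermost modes of a smoothed histogram, so a cross-reactive
    mid-amplitude cluster below the true-positive cluster is excluded.
    If the distribution is unimodal the valley policy falls back to the
    fixed threshold (flagged).

    ``min_positive`` is an optional amplitude floor — e.g. taken from a
    positive-control well — below which droplets are never counted as
    positive; it protects null samples whose only non-negative cluster is
    the cross-reactive one.
    """
    amp = np.asarray(amplitudes, dtype=float)
    if amp.size < 100:
        raise ValueError("need at least 100 droplets to gate")

    fallback = False
    if policy == "fixed":
        if threshold is None:
            raise ValueError("fixed policy requires a threshold")
        thr = float(threshold)
    elif policy == "valley":
        smooth, centers, modes = _histogram_modes(amp, bins)
        if len(modes) >= 2:
            lo, hi = modes[-2], modes[-1]  # the two uppermost modes
            valley = lo + int(np.argmin(smooth[lo : hi + 1]))
            thr = float(centers[valley])
        else:
            fallback = True
            if threshold is not None:
                thr = float(threshold)
            else:
                thr = float(0.5 * (amp.min() + amp.max()))
            warnings.warn(
                "amplitude distribution looks unimodal; valley gating fell "
                "back to a fixed threshold",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown gating policy {policy!r}")

    if min_positive is not None:
        thr = max(thr, float(min_positive))
    return GateResult(
        n_positive=int((amp > thr).sum()), n_total=amp.size, threshold=thr, fallback=fallback
    )


def poisson_concentration(k: int, n: int, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Copies per droplet from positive/total droplet counts.

    ``lambda = -ln(1 - k/n)``; the 95% CI propagates a Wilson interval
    for the positive fraction through the same transform (well-behaved
    at k near 0).  ``k == n`` means every droplet is positive and the
    concentration is unbounded: an error instructing dilution.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    if k == n:
        raise ValueError(
            "all droplets positive: concentration not estimable, dilute the sample"
        )
    lam = -np.log1p(-k / n)
    lo_p, hi_p = proportion_confint(k, n, alpha=alpha, method="wilson")
    ci = (-np.log1p(-min(lo_p, 1 - 1e-12)), -np.log1p(-min(hi_p, 1 - 1e-12)))
    return float(lam), (float(ci[0]), float(ci[1]))


def copy_number_ddpcr(
    lambda_target: float, lambda_ref: float, reference_ploidy: int = 2
) -> float:
    """Copy number relative to a reference gene of known ploidy."""
    if lambda_ref <= 0:
        raise ValueError("reference concentration must be positive")
    if lambda_target < 0:
        raise ValueError("target concentration must be non-negative")
    return reference_ploidy * lambda_target / lambda_ref


def quantify_well(
    droplets: pd.DataFrame,
    reference_ploidy: int = 2,
    gate_kwargs_target: dict | None = None,
    gate_kwargs_ref: dict | None = None,
) -> DdpcrQuant:
    """Gate both channels of one well and call the copy number.

    ``droplets`` uses the long format written by the simulator: columns
    ``droplet_id``, ``channel`` ('target'/'reference'), ``amplitude``.
    """
    tgt = droplets.loc[droplets["channel"] == "target", "amplitude"]
    ref = droplets.loc[droplets["channel"] == "reference", "amplitude"]
    g_t = gate_droplets(tgt, **(gate_kwargs_target or {}))
    g_r = gate_droplets(ref, **(gate_kwargs_ref or {}))
    lam_t, ci_t = poisson_concentration(g_t.n_positive, g_t.n_total)
    lam_r, ci_r = poisson_concentration(g_r.n_positive, g_r.n_total)
    return DdpcrQuant(
        lambda_target=lam_t,
        lambda_target_ci=ci_t,
        lambda_ref=lam_r,
        lambda_ref_ci=ci_r,
        cn_estimate=copy_number_ddpcr(lam_t, lam_r, reference_ploidy),
        n_positive_target=g_t.n_positive,
        n_positive_ref=g_r.n_positive,
        n_droplets=g_t.n_total,
    )


def concordance(x: np.ndarray, y: np.ndarray) -> ConcordanceResult:
    """Ordinary least-squares concordance between two assays' copy-number
    calls (e.g. competitive-PCR sCN vs ddPCR CN).

    R^2 is the squared Pearson correlation; p comes from the slope
    t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: concordance undefined")
    fit = stats.linregress(x, y)
    return ConcordanceResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=x.size,
    )
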