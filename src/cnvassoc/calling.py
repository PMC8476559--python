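"""Copy-number calling from competitive-PCR peak tables.

The measurement chain is: raw relative copy number (target peak ratio
normalized by the control-gene peak ratio) -> standardized copy number
(sCN; the cohort median individual is anchored at the expected median
copy number, 2 for autosomes) -> digitized copy number (dCN; integer bins
with half-open boundaries at x.5) -> cohort-level QC with an explicit
exclusion ledger.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "compute_raw_ratio",
    "standardize",
    "standardize_x_linked",
    "digitize",
    "call_cohort",
    "qc_filter",
    "ExclusionLedger",
]

DCN_MAX = 6  # last published bin is [5.5, 6.5)


def compute_raw_ratio(peaks: pd.DataFrame) -> pd.Series:
    """Raw relative copy number per peak record.

    ``(g_T / c_T) / mean_j(g_Ij / c_Ij)`` — the target genomic/competitor
    ratio normalized by the control-gene ratio.  Assays with two
    control-gene peak pairs (columns ``g_I2``/``c_I2``) combine them by
    the arithmetic mean of their ratios.  Failed records propagate NaN.

    Raises on a non-failed record with a zero competitor or control peak.
    """
    failed = peaks["failed"].to_numpy(dtype=bool) if "failed" in peaks else np.zeros(len(peaks), bool)
    g_t = peaks["g_T"].to_numpy(dtype=float)
    c_t = peaks["c_T"].to_numpy(dtype=float)
    ok = ~failed
    if np.any((c_t[ok] <= 0)):
        raise ValueError("zero/negative competitor peak on a non-failed record")

    ctrl_ratios = []
    for suffix in ("", "2"):
        gcol, ccol = f"g_I{suffix}", f"c_I{suffix}"
        if gcol in peaks.columns:
            g_i = peaks[gcol].to_numpy(dtype=float)
            c_i = peaks[ccol].to_numpy(dtype=float)
            if np.any(c_i[ok] <= 0) or np.any(g_i[ok] <= 0):
                raise ValueError("zero/negative control-gene peak on a non-failed record")
            with np.errstate(divide="ignore", invalid="ignore"):
                ctrl_ratios.append(g_i / c_i)
    if not ctrl_ratios:
        raise ValueError("no control-gene peak pair columns (g_I/c_I)")
    ctrl = np.mean(ctrl_ratios, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (g_t / c_t) / ctrl
    raw = np.where(failed, np.nan, raw)
    return pd.Series(raw, index=peaks.index, name="raw_ratio")


def standardize(
    raw_ratios: np.ndarray | pd.Series, expected_median_cn: int = 2
) -> tuple[np.ndarray, float]:
    """Standardize raw relative copy numbers against the cohort median.

    Divides by ``median / expected_median_cn`` so the median individual
    scores exactly ``expected_median_cn`` (for the default 2 this is
    division by half the median).  Missing values are ignored for the
    median and propagate.  Returns ``(sCN, median_used)``.
    """
    if expected_median_cn not in (1, 2):
        raise ValueError("expected_median_cn must be 1 or 2")
    raw = np.asarray(raw_ratios, dtype=float)
    finite = raw[np.isfinite(raw)]
    if finite.size == 0:
        raise ValueError("no non-missing raw ratios to standardize")
    med = float(np.median(finite))
    if med <= 0:
        raise ValueError("median raw ratio is zero; cohort cannot be standardized")
    return raw / (med / expected_median_cn), med


def standardize_x_linked(
    raw_ratios: np.ndarray | pd.Series, sexes: np.ndarray | pd.Series
) -> tuple[np.ndarray, dict]:
    """Standardize an X-linked gene separately by sex.

    Females are anchored at a median copy number of 2, hemizygous males
    at 1, each stratum against its own median.  Returns ``(sCN,
    medians_by_sex)``.
    """
    raw = np.asarray(raw_ratios, dtype=float)
    sexes = np.asarray(sexes)
    if sexes.shape != raw.shape:
        raise ValueError("sexes must align with raw_ratios")
    out = np.full_like(raw, np.nan)
    medians: dict[str, float] = {}
    for sex, expected in (("F", 2), ("M", 1)):
        idx = sexes == sex
        if not idx.any():
            continue
        out[idx], medians[sex] = standardize(raw[idx], expected_median_cn=expected)
    return out, medians


def digitize(scn: np.ndarray | float) -> np.ndarray | float:
    """Digitize sCN into integer copy-number bins.

    Bins are half-open with boundaries at x.5 (``0 <= sCN < 0.5 -> 0``,
    ``0.5 <= sCN < 1.5 -> 1``, ... ``5.5 <= sCN < 6.5 -> 6``), i.e.
    ``floor(sCN + 0.5)``.  Values at or beyond 6.5 are clamped to 6 with
    a warning; missing values propagate.
    """
    arr = np.asarray(scn, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("sCN must be non-negative")
    out = np.floor(arr + 0.5)
    over = np.isfinite(out) & (out > DCN_MAX)
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} sCN value(s) >= {DCN_MAX}.5 clamped to dCN {DCN_MAX}",
            stacklevel=2,
        )
        out = np.where(over, DCN_MAX, out)
    if np.isscalar(scn):
        return float(out) if np.isnan(out) else int(out)
    return out


def call_cohort(
    peaks: pd.DataFrame,
    sexes: pd.Series | dict | None = None,
    x_linked_genes: set[str] = frozenset({"TLR7"}),
) -> tuple[pd.DataFrame, dict]:
    """Run the full calling chain on a peak table.

    Standardization is per gene over the pooled cohort (cases plus
    controls); X-linked genes are standardized separately by sex, which
    requires ``sexes`` (mapping sample id -> 'M'/'F').  Returns the call
    table (sample, gene, raw_ratio, sCN, dCN, qc_pass) and the per-gene
    standardization medians.
    """
    calls = peaks[["sample", "gene"]].copy()
    calls["raw_ratio"] = compute_raw_ratio(peaks)
    calls["sCN"] = np.nan
    medians: dict[str, object] = {}
    for gene, idx in calls.groupby("gene").groups.items():
        raw = calls.loc[idx, "raw_ratio"]
        if gene in x_linked_genes:
            if sexes is None:
                raise ValueError(f"sexes required to standardize X-linked gene {gene!r}")
            sex_vec = calls.loc[idx, "sample"].map(dict(sexes) if not isinstance(sexes, dict) else sexes)
            calls.loc[idx, "sCN"], medians[gene] = standardize_x_linked(raw, sex_vec)
        else:
            calls.loc[idx, "sCN"], medians[gene] = standardize(raw)
    calls["dCN"] = digitize(calls["sCN"].to_numpy())
    calls["qc_pass"] = np.isfinite(calls["dCN"].to_numpy(dtype=float))
    return calls, medians


@dataclass
class ExclusionLedger:
    """Bookkeeping of cohort-level QC: why samples were dropped, in the
    order the filters were applied (DNA quantity first, then assay
    failure in any required gene)."""

    n_input: int = 0
    n_low_dna: int = 0
    n_assay_failure: int = 0
    n_retained: int = 0
    by_group: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_low_dna": self.n_low_dna,
                "n_assay_failure": self.n_assay_failure,
                "n_retained": self.n_retained,
                "by_group": self.by_group,
            },
            indent=2,
            sort_keys=True,
        )


def qc_filter(
    calls: pd.DataFrame,
    required_genes: set[str],
    dna_ok: pd.Series | dict | None = None,
    groups: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Retain samples that pass the DNA-quantity flag and have a passing
    call for every required gene.

    Exclusions are applied in order — insufficient DNA first, then assay
    failure — and tallied in the returned :class:`ExclusionLedger`
    (optionally per group).
    """
    if not required_genes:
        raise ValueError("required_genes must be non-empty")
    samples = pd.Index(calls["sample"].unique())
    ledger = ExclusionLedger(n_input=len(samples))

    dna = pd.Series(True, index=samples)
    if dna_ok is not None:
        dna = dna & pd.Series(dict(dna_ok) if not isinstance(dna_ok, dict) else dna_ok).reindex(
            samples, fill_value=True
        )
    after_dna = samples[dna.loc[samples].to_numpy()]
    ledger.n_low_dna = len(samples) - len(after_dna)

    sub = calls[calls["gene"].isin(required_genes) & calls["sample"].isin(after_dna)]
    ok_counts = sub[sub["qc_pass"].astype(bool)].groupby("sample")["gene"].nunique()
    passing = ok_counts[ok_counts == len(required_genes)].index
    retained = after_dna[after_dna.isin(passing)]
    ledger.n_assay_failure = len(after_dna) - len(retained)
    ledger.n_retained = len(retained)

    if groups is not None:
        gmap = pd.Series(dict(groups) if not isinstance(groups, dict) else groups)
        for grp in sorted(gmap.unique()):
            members = samples[gmap.reindex(samples).to_numpy() == grp]
            after = [s for s in after_dna if s in set(members)]
            kept = [s for s in retained if s in set(members)]
            ledger.by_group[str(grp)] = {
                "n_input": len(members),
                "n_low_dna": len(members) - len(after),
                "n_assay_failure": len(after) - len(kept),
                "n_retained": len(kept),
            }

    return calls[calls["sample"].isin(retained)].copy(), ledger
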