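"""Synthetic case-control CNV cohorts and forward models of both assays.

This module generates cohorts with *known* diploid copy-number genotypes
and simulates the two measurement processes used to genotype them:

* competitive-PCR peak heights (a genomic and a competitor peak for the
  target gene, plus the same pair for a diploid control gene), from which
  relative copy numbers are derived downstream, and
* droplet digital PCR (ddPCR) droplet amplitudes, with Poisson
  partitioning of template molecules and an optional cross-reactive
  cluster contributed by a homologous gene.

Genotypes are drawn under Hardy-Weinberg equilibrium from per-haplotype
copy-class frequencies; case cohorts can be enriched for a risk copy-number
category at a chosen odds ratio (retrospective sampling, so the target odds
ratio holds in expectation by construction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "CohortSpec",
    "MrcPcrAssay",
    "DdpcrAssay",
    "Cohort",
    "default_gene_models",
    "default_cohort_spec",
    "population_cn_distribution",
    "sample_population_genotypes",
    "tilt_case_genotypes",
    "simulate_mrcpcr_peaks",
    "simulate_ddpcr_droplets",
    "generate_cohort",
]


@dataclass(frozen=True)
class GeneModel:
    """Population model for one gene: inheritance mode and haplotype
    copy-class frequencies.

    ``allele_freqs[a]`` is the population frequency of haplotypes carrying
    ``a`` copies of the gene, for ``a = 0 .. A_max``.  Autosomal
    individuals carry two haplotypes; X-linked males carry one.
    """

    name: str
    allele_freqs: tuple[float, ...]
    inheritance: str = "autosomal"
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.allele_freqs, dtype=float)
        if q.ndim != 1 or q.size < 2:
            raise ValueError("allele_freqs needs at least classes 0 and 1 (A_max >= 1)")
        if np.any(q < 0):
            raise ValueError("allele_freqs must be non-negative")
        if abs(q.sum() - 1.0) > 1e-12:
            raise ValueError(f"allele_freqs must sum to 1, got {q.sum()!r}")
        if self.inheritance not in ("autosomal", "x_linked"):
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        object.__setattr__(self, "allele_freqs", tuple(float(x) for x in q))

    @property
    def a_max(self) -> int:
        return len(self.allele_freqs) - 1

    @property
    def q(self) -> np.ndarray:
        return np.asarray(self.allele_freqs, dtype=float)


@dataclass(frozen=True)
class MrcPcrAssay:
    """Parameters of the competitive-PCR peak forward model.

    ``k_target``/``k_control`` are the competitor spike amounts in
    arbitrary fluorescence units; they cancel in the downstream median
    standardization.  ``noise_cv`` is the coefficient of variation of a
    single peak height; each of the four peaks receives an independent
    multiplicative log-normal error with sigma = ln(1 + noise_cv).
    """

    noise_cv: float = 0.05
    failure_rate: float = 0.01
    k_target: float = 1.0
    k_control: float = 1.0
    control_cn: int = 2  # the IGF1-like control gene is diploid

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.failure_rate < 1:
            raise ValueError("failure_rate must be in [0, 1)")
        if self.k_target <= 0 or self.k_control <= 0:
            raise ValueError("competitor spike amounts must be positive")


@dataclass(frozen=True)
class DdpcrAssay:
    """Parameters of the droplet digital PCR forward model.

    Droplets partition template molecules Poisson(lambda) with
    lambda = CN * c0 for the target channel and lambda = 2 * c0 for the
    diploid reference channel.  Target-channel amplitudes fall in three
    Gaussian clusters: negative, cross-reactive positive (droplets holding
    only homolog template, which the probe detects weakly) and true
    positive.  Cluster means must be strictly ordered.
    """

    n_droplets: int = 15000
    c0: float = 0.5  # copies per droplet per template copy
    negative_mean: float = 1000.0
    negative_sd: float = 50.0
    cross_mean: float = 3500.0
    cross_sd: float = 300.0
    positive_mean: float = 8000.0
    positive_sd: float = 300.0
    cross_efficiency: float = 1.0  # homolog template partitioned at this relative rate

    def __post_init__(self) -> None:
        if self.n_droplets < 100:
            raise ValueError("need at least 100 droplets")
        if self.c0 <= 0:
            raise ValueError("base concentration c0 must be positive")
        if not self.negative_mean < self.cross_mean < self.positive_mean:
            raise ValueError(
                "cluster means must be strictly ordered: negative < cross < positive"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic case-control cohort."""

    n_cases: int = 368
    n_controls: int = 375
    genes: tuple[GeneModel, ...] = ()
    # gene name -> (risk dCN category, odds ratio of that category in cases)
    case_or: dict = field(default_factory=dict)
    female_fraction: float = 0.9
    assay_failure_rate: float = 0.01
    noise_cv: float = 0.05
    low_dna_rate_cases: float = 5.0 / 368.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p, nm in [
            (self.female_fraction, "female_fraction"),
            (self.assay_failure_rate, "assay_failure_rate"),
            (self.low_dna_rate_cases, "low_dna_rate_cases"),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{nm} must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        names = {g.name for g in self.genes}
        for gene, (_, oratio) in self.case_or.items():
            if gene not in names:
                raise ValueError(f"case_or refers to unknown gene {gene!r}")
            if oratio <= 0:
                raise ValueError("odds_ratio must be positive")

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


def default_gene_models() -> tuple[GeneModel, ...]:
    """The nine immunity-related genes of the reference SLE cohort.

    Haplotype copy-class frequencies are maximum-likelihood
    Hardy-Weinberg fits to the control dCN distributions of the published
    Korean case-control study (338 controls); the rare-variant genes use
    simple haplotype counts.  TLR7 is X-linked, everything else autosomal.
    """
    return (
        GeneModel("TNFAIP3", (0.0008, 0.9992)),
        GeneModel("TNIP1", (0.0015, 0.9985)),
        GeneModel("IL12B", (0.0023, 0.9977)),
        GeneModel("TBX21", (0.0023, 0.9977)),
        GeneModel("TLR7", (0.0, 0.9985, 0.0015), inheritance="x_linked"),
        GeneModel("C4A", (0.062, 0.861, 0.077)),
        GeneModel("C4B", (0.078, 0.755, 0.167)),
        GeneModel("CCL3L1", (0.237, 0.592, 0.094, 0.077)),
        GeneModel("CCL3L3", (0.159, 0.602, 0.239)),
    )


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort emulating the reference study: 368 accrued cases / 375
    controls, female-predominant, with CCL3L3-null and C4B-low case
    enrichment at the study's observed odds ratios."""
    return CohortSpec(
        genes=default_gene_models(),
        case_or={"CCL3L3": (0, 18.5), "C4B": (1, 1.6)},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genotype sampling


def _pair_distribution(model: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    """All ordered haplotype pairs (a, b) with their HW probabilities."""
    q = model.q
    amax = model.a_max
    pairs = np.array(list(itertools.product(range(amax + 1), repeat=2)))
    probs = q[pairs[:, 0]] * q[pairs[:, 1]]
    return pairs, probs


def population_cn_distribution(model: GeneModel, sex: str = "F") -> np.ndarray:
    """Distribution of the diploid total copy number under HWE.

    For autosomal genes (or X-linked females) this is the self-convolution
    of the haplotype frequencies; X-linked males follow the haplotype
    frequencies directly.
    """
    q = model.q
    if model.inheritance == "x_linked" and sex == "M":
        return q.copy()
    return np.convolve(q, q)


def sample_population_genotypes(
    model: GeneModel,
    n: int,
    sexes: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` genotypes i.i.d. under Hardy-Weinberg equilibrium.

    Returns a frame with columns ``hap1``, ``hap2`` and ``total_cn``;
    X-linked males are hemizygous (``hap2`` is the missing sentinel -1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    if sexes is None:
        sexes = np.full(n, "F")
    sexes = np.asarray(sexes)
    if sexes.shape != (n,):
        raise ValueError("sexes must have length n")
    q = model.q
    hap1 = rng.choice(model.a_max + 1, size=n, p=q)
    hap2 = rng.choice(model.a_max + 1, size=n, p=q)
    if model.inheritance == "x_linked":
        hap2 = np.where(sexes == "M", -1, hap2)
    total = hap1 + np.maximum(hap2, 0)
    return pd.DataFrame({"hap1": hap1, "hap2": hap2, "total_cn": total})


def tilt_case_genotypes(
    model: GeneModel,
    risk_category: int,
    odds_ratio: float,
    n_cases: int,
    sexes: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw case genotypes whose risk-category odds are the population's
    multiplied by ``odds_ratio`` (retrospective case-control sampling).

    Every genotype whose total copy number equals ``risk_category`` has
    its probability multiplied by ``odds_ratio`` before renormalization,
    which multiplies the category's *odds* by exactly that factor while
    preserving the genotype composition within each category.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(rng)
    if sexes is None:
        sexes = np.full(n_cases, "F")
    sexes = np.asarray(sexes)

    out = pd.DataFrame(
        {"hap1": np.zeros(n_cases, dtype=int), "hap2": np.zeros(n_cases, dtype=int)}
    )
    for sex in ("F", "M"):
        idx = np.flatnonzero(sexes == sex)
        if idx.size == 0:
            continue
        if model.inheritance == "x_linked" and sex == "M":
            support = np.arange(model.a_max + 1)[:, None]
            probs = model.q.copy()
            totals = support[:, 0]
            hemizygous = True
        else:
            support, probs = _pair_distribution(model)
            totals = support.sum(axis=1)
            hemizygous = False
        weights = np.where(totals == risk_category, odds_ratio, 1.0) * probs
        if probs[totals == risk_category].sum() == 0 and odds_ratio != 1.0:
            raise ValueError(
                f"risk category {risk_category} has zero population mass; "
                "cannot tilt odds onto an impossible category"
            )
        weights = weights / weights.sum()
        draw = rng.choice(len(weights), size=idx.size, p=weights)
        out.loc[idx, "hap1"] = support[draw, 0]
        out.loc[idx, "hap2"] = -1 if hemizygous else support[draw, 1]
    out["total_cn"] = out["hap1"] + np.maximum(out["hap2"], 0)
    return out


def tilted_cn_distribution(
    model: GeneModel, risk_category: int, odds_ratio: float, sex: str = "F"
) -> np.ndarray:
    """Closed-form total-CN distribution of the tilted (case) population."""
    p = population_cn_distribution(model, sex=sex)
    w = np.ones_like(p)
    w[risk_category] = odds_ratio
    tilted = p * w
    return tilted / tilted.sum()


# ---------------------------------------------------------------------------
# measurement forward models


def simulate_mrcpcr_peaks(
    individuals: pd.DataFrame,
    assay: MrcPcrAssay | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate competitive-PCR peak heights for each sample x gene row.

    ``individuals`` must carry columns ``id``, ``gene`` and ``total_cn``.
    Emits the four peaks of one assay well: target genomic (``g_T``),
    target competitor (``c_T``), control-gene genomic (``g_I``) and
    control-gene competitor (``c_I``), each with independent multiplicative
    log-normal noise, plus a ``failed`` flag for dropped assays.
    """
    assay = assay or MrcPcrAssay()
    rng = np.random.default_rng(rng)
    n = len(individuals)
    sigma = np.log1p(assay.noise_cv)
    eps = rng.normal(0.0, sigma, size=(n, 4)) if sigma > 0 else np.zeros((n, 4))
    cn = individuals["total_cn"].to_numpy(dtype=float)
    peaks = pd.DataFrame(
        {
            "sample": individuals["id"].to_numpy(),
            "gene": individuals["gene"].to_numpy(),
            "g_T": cn * np.exp(eps[:, 0]),
            "c_T": assay.k_target * np.exp(eps[:, 1]),
            "g_I": assay.control_cn * np.exp(eps[:, 2]),
            "c_I": assay.k_control * np.exp(eps[:, 3]),
            "failed": rng.random(n) < assay.failure_rate,
        }
    )
    return peaks


def simulate_ddpcr_droplets(
    total_cn: int,
    homolog_cn: int = 0,
    assay: DdpcrAssay | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate one ddPCR well: droplet amplitudes for the target and the
    diploid reference channel.

    Template molecules partition Poisson with lambda = CN * c0.  A droplet
    containing target template reads in the true-positive cluster; one
    containing only homolog template reads in the low, cross-reactive
    cluster; empty droplets read in the negative cluster.
    """
    assay = assay or DdpcrAssay()
    if total_cn < 0 or homolog_cn < 0:
        raise ValueError("copy numbers must be non-negative")
    rng = np.random.default_rng(rng)
    n = assay.n_droplets

    has_target = rng.poisson(total_cn * assay.c0, size=n) > 0
    has_cross = rng.poisson(homolog_cn * assay.c0 * assay.cross_efficiency, size=n) > 0
    amp = rng.normal(assay.negative_mean, assay.negative_sd, size=n)
    amp = np.where(
        has_cross & ~has_target, rng.normal(assay.cross_mean, assay.cross_sd, size=n), amp
    )
    amp = np.where(
        has_target, rng.normal(assay.positive_mean, assay.positive_sd, size=n), amp
    )

    has_ref = rng.poisson(2 * assay.c0, size=n) > 0
    ref_amp = np.where(
        has_ref,
        rng.normal(assay.positive_mean, assay.positive_sd, size=n),
        rng.normal(assay.negative_mean, assay.negative_sd, size=n),
    )

    return pd.DataFrame(
        {
            "droplet_id": np.concatenate([np.arange(n), np.arange(n)]),
            "channel": ["target"] * n + ["reference"] * n,
            "amplitude": np.concatenate([amp, ref_amp]),
        }
    )


# ---------------------------------------------------------------------------
# whole-cohort generation


@dataclass
class Cohort:
    """A generated cohort: per-sample truth, per-sample DNA-quantity flag
    and the simulated peak table."""

    truth: pd.DataFrame  # id, group, sex, gene, hap1, hap2, total_cn
    samples: pd.DataFrame  # id, group, sex, dna_ok
    peaks: pd.DataFrame  # sample, gene, g_T, c_T, g_I, c_I, failed
    spec: CohortSpec

    def write(self, truth_csv, peaks_tsv, samples_csv=None) -> None:
        self.truth.to_csv(truth_csv, index=False)
        self.peaks.to_csv(peaks_tsv, sep="\t", index=False)
        if samples_csv is not None:
            self.samples.to_csv(samples_csv, index=False)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Generate a full case-control cohort and its simulated peak table.

    All randomness flows from one root seed through named substreams
    (sexes / genotypes / peaks / DNA flags), so the output is
    bit-reproducible given (spec, seed).
    """
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(spec.seed if seed is None else seed)
    ss_sex, ss_geno, ss_peaks, ss_dna = root.spawn(4)
    rng_sex = np.random.default_rng(ss_sex)
    rng_geno = np.random.default_rng(ss_geno)
    rng_dna = np.random.default_rng(ss_dna)

    n_total = spec.n_controls + spec.n_cases
    groups = np.array(["control"] * spec.n_controls + ["case"] * spec.n_cases)
    sexes = np.where(rng_sex.random(n_total) < spec.female_fraction, "F", "M")
    ids = np.array(
        [f"CT{i:04d}" for i in range(spec.n_controls)]
        + [f"SLE{i:04d}" for i in range(spec.n_cases)]
    )

    frames = []
    ctrl = groups == "control"
    for gene in spec.genes:
        geno = pd.DataFrame(index=np.arange(n_total), columns=["hap1", "hap2"], dtype=int)
        g_ctrl = sample_population_genotypes(
            gene, int(ctrl.sum()), sexes[ctrl], rng_geno
        )
        if gene.name in spec.case_or:
            risk, oratio = spec.case_or[gene.name]
            g_case = tilt_case_genotypes(
                gene, risk, oratio, int((~ctrl).sum()), sexes[~ctrl], rng_geno
            )
        else:
            g_case = sample_population_genotypes(
                gene, int((~ctrl).sum()), sexes[~ctrl], rng_geno
            )
        block = pd.concat([g_ctrl, g_case], ignore_index=True)
        block.index = np.concatenate([np.flatnonzero(ctrl), np.flatnonzero(~ctrl)])
        block = block.sort_index()
        block.insert(0, "id", ids)
        block.insert(1, "group", groups)
        block.insert(2, "sex", sexes)
        block.insert(3, "gene", gene.name)
        frames.append(block)
    truth = pd.concat(frames, ignore_index=True)

    assay = MrcPcrAssay(noise_cv=spec.noise_cv, failure_rate=spec.assay_failure_rate)
    peaks = simulate_mrcpcr_peaks(truth, assay, np.random.default_rng(ss_peaks))

    dna_ok = np.ones(n_total, dtype=bool)
    is_case = ~ctrl
    dna_ok[is_case] = rng_dna.random(int(is_case.sum())) >= spec.low_dna_rate_cases
    samples = pd.DataFrame({"id": ids, "group": groups, "sex": sexes, "dna_ok": dna_ok})

    return Cohort(truth=truth, samples=samples, peaks=peaks, spec=spec)
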