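# cnvassoc

Copy-number genotyping from competitive-PCR peak data and case-control
association analysis of copy-number variation (CNV), with an EM-based
Hardy-Weinberg test for copy-number histograms and droplet digital PCR
(ddPCR) cross-validation.

## The problem

Multi-allelic CNVs in immunity-related genes (the *CCL3L* cluster, the
complement *C4A*/*C4B* genes, *TLR7*, ...) are recurrent candidate risk
factors for autoimmune disease, but genotyping them is error-prone:
homologous paralogs cross-react, continuous intensity measures drift, and
naive tests on raw intensities produce false positives.  A robust design —
used by a recent systemic lupus erythematosus (SLE) case-control study of
nine immunity genes in 338 controls and 327 patients — is:

1. **Competitive PCR** — co-amplify each target with a spiked synthetic
   competitor and a diploid control gene; the double peak-height ratio
   `(g_T/c_T) / (g_I/c_I)` is proportional to the copy number and cancels
   amplification efficiency.
2. **Standardize** — divide each gene's raw ratios by half their cohort
   median, anchoring the median individual at sCN = 2 (sCN = 1 for
   hemizygous males of X-linked genes, standardized separately by sex).
3. **Digitize** — bin sCN into integer dCN with half-open boundaries at
   x.5 (`floor(sCN + 0.5)`), so association tests run on genotype
   categories rather than noisy continuous values.
4. **Test** — 2×k contingency tables of dCN by case-control status:
   Fisher's exact test (Freeman-Halton for k > 2), Pearson chi-squared,
   odds ratios with an explicit zero-cell policy (substituting 1 for an
   empty cell yields a *lower bound*, e.g. OR > 18.5355 for a null
   genotype absent from all controls), and Bonferroni correction with a
   declared family size.
5. **Check Hardy-Weinberg equilibrium** — only diploid totals are
   observed, so per-haplotype copy-class frequencies q_a are estimated by
   EM (an individual with total k is fractionally assigned to haplotype
   pairs (a, k−a) ∝ q_a·q_{k−a}); the expected diploid distribution is
   the self-convolution of q̂, tested by Pearson chi-squared with
   explicit pooling/df conventions and by parametric bootstrap.
6. **Confirm by ddPCR** — Poisson partitioning statistics
   (λ = −ln(1 − k/n) copies/droplet) against a diploid reference gene,
   with valley-based amplitude gating that excludes cross-reactive
   homolog clusters, and OLS concordance against the competitive-PCR
   calls.

`cnvassoc` implements this entire chain as a tested library plus CLI, and
ships a synthetic-cohort generator (Hardy-Weinberg genotypes, retrospective
case enrichment at a known odds ratio, log-normal peak noise, per-assay
failure, droplet-level ddPCR simulation) so that every stage is verifiable
against known truth without any patient data.

## Worked example

Run the full pipeline on a synthetic cohort emulating the reference
study design (375 controls / 368 accrued cases, nine genes, CCL3L3-null
enriched in cases at OR 18.5, C4B single-copy at OR 1.6):

```python
from cnvassoc import RunConfig, run

report = run(RunConfig(seed=7))
print(report.exclusions)
print(report.associations["CCL3L3"]["binary"])
print(report.hwe["CCL3L3"]["control"])
print(report.concordance)
```

prints (abridged):

```text
{'n_input': 743, 'n_low_dna': 3, 'n_assay_failure': 66, 'n_retained': 674, ...}
{'test': 'fisher', 'p': 3.85e-27, 'method': 'exact',
 'odds_ratio': 27.67, 'ci95': (11.09, 69.01), 'p_adjusted': 4.2e-26, 'm_tests': 11}
{'chi2': 1.02, 'df': 2, 'p_asymptotic': 0.60,
 'q': [0.138, 0.627, 0.217, 0.018], 'saturated': False}
{'gene': 'CCL3L3', 'slope': 1.023, 'intercept': -0.035, 'r_squared': 0.9886, 'n': 16}
```

Reading this: 674 of 743 samples survive QC (3 low-DNA cases, 66 samples
with an assay failure in one of the seven required genes); the simulated
CCL3L3-null enrichment is recovered as a highly significant Fisher test
whose Woolf CI covers the true OR of 18.5; the control group's
copy-number distribution is consistent with Hardy-Weinberg (p = 0.60) and
the EM haplotype-class frequencies q̂ are close to the generating values
(0.159, 0.602, 0.239); and a simulated 16-well ddPCR re-measurement of
CCL3L3 agrees with the peak-based sCN at R² = 0.989.

The same analyses are available from the shell:

```sh
cnvassoc simulate --seed 7 --out sim/
cnvassoc call --peaks sim/peaks.tsv --samples sim/samples.csv \
              --out calls.csv --required-genes TNFAIP3,TNIP1,IL12B,TBX21,TLR7,C4A,C4B
cnvassoc hwe --calls calls_grouped.csv --gene CCL3L3 --group control --bootstrap 1000
cnvassoc report --seed 7 --out run/
cnvassoc regress-published
```

`cnvassoc regress-published` recomputes every statistic of the reference
study's printed count table:

```text
       name  k     chi2      chi2_p    fisher_p           p  p_adjusted  odds_ratio  or_is_lower_bound
    TNFAIP3  2 0.968913    0.324952           1           1           1         NaN              False
      IL12B  2  3.11497   0.0775759    0.118344    0.118344           1         NaN              False
        C4A  3  2.08369    0.352804    0.359592    0.352804           1         NaN              False
        C4B  4  8.43194   0.0378794   0.0381164   0.0378794    0.416673         NaN              False
     CCL3L3  5  21.7852 0.000221146       5e-05 0.000221146  0.00243261         NaN              False
    C4B_low  2  4.86461   0.0274129     0.03312     0.03312     0.36432     1.60509              False
CCL3L3_null  2  18.0329 2.17125e-05 4.62556e-06 4.62556e-06 5.08812e-05     18.5355               True
```

The `p` column follows the convention of the published values (Fisher for
2×2 tables, chi-squared for the multi-category tables; both are always
reported side by side), and the two headline odds ratios — 1.6051 for
single-copy *C4B* and the zero-cell lower bound 18.5355 for
*CCL3L3*-null — drop out of the printed counts exactly.

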