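# silentsnp

Stochastic modelling of how a **synonymous ("silent") SNP** can change the
amount of protein a gene produces, and classification of cell-line drug
sensitivity by the genotype at such a site.

A synonymous variant does not change the encoded amino acid, but it can
swap the codon to one read by a more (or less) abundant tRNA. Because the
ribosome dwells on a codon until the cognate tRNA arrives, codon identity
modulates translational throughput — and with it the steady-state protein
level — without any change in the protein sequence. For the PARP1 site this
package models (rs1805414, GCT→GCC), the downstream question is clinical:
carriers of the SNP allele respond differently to PARP inhibitors such as
olaparib, so the genotype is a candidate response biomarker.

The package is aimed at computational biologists who want a small, exact,
fully reproducible pipeline for both halves of that argument:

1. **Simulation** — a delayed stochastic simulation algorithm (delayed SSA)
   and a five-reaction model of translation focused on one codon.
2. **Analysis** — Z-score standardisation of drug-response AUC values
   across a cell-line panel, sensitivity calls at `Z < −1.5`, and genotype
   cohort comparison, with a seeded synthetic-panel generator replacing
   database downloads.

## The model

Translation of a single mRNA is coarse-grained into mass-action reactions
with delayed product release (delays in parentheses, seconds):

```
R1  Rib + mRNA₁        —k_p1→       p1·Rib·mRNA₁ (τ_p1)
R2  p1·Rib·mRNA₁ + tRNA —k_snp→     snp·p1·Rib·mRNA₁ (τ_snp) + tRNA (τ_snp)
R3  snp·p1·Rib·mRNA₁ + mRNA₂ —k_p1→ mRNA₂·snp·p1·Rib·mRNA₁ (τ_p2)
R4  mRNA₂·snp·p1·Rib·mRNA₁ —1→      mRNA₁ (τ_mRNA) + mRNA₂ (τ_mRNA)
                                    + Rib (τ_Rib) + Prot (τ_prot)
R5  Prot               —k_P_decay→  ∅
```

`mRNA₁`/`mRNA₂` are bookkeeping labels for the subsequences before and
after the focal codon of one physical mRNA. R2 is the codon of interest:
its rate `k_snp` stands for cognate-tRNA availability and its delay `τ_snp`
for the decoding time. Everything except the protein is conserved
(`Rib = 100`, `mRNA₁ = mRNA₂ = 50`, `tRNA = 50` at all times, counting
molecules in complexes and on the waitlist). Defaults: `k_p1 = 0.01`,
`k_P_decay = 3×10⁻⁴`, `τ_p1 = 10`, `τ_p2 = 25`, `τ_mRNA = 5`, `τ_Rib = 50`,
`τ_prot = 300`; the wild-type codon reference is
`(k_WT, τ_WT) = (0.4×10⁻³, 0.1)`.

The delayed SSA is exact: candidate reaction times are exponential with the
total mass-action propensity, and scheduled releases pre-empt them (the
discarded exponential is redrawn, which is statistically exact by
memorylessness).

The analysis half standardises AUC per drug within each dataset
(`z = (AUC − mean)/sd`, sample sd), calls `z < −1.5` sensitive, pools
heterozygotes with homozygous SNP lines into the SNP cohort, and compares
cohorts with an unpaired two-tailed t-test (Welch by default).

## Worked example

Plateau protein level (time average over `t > 10⁴ s`, `t_end = 3×10⁴ s`)
for the wild-type codon and for the SNP codon at the largest rate of the
swept grid:

```
$ silentsnp simulate --n-runs 5 --seed 7 --out wt_demo
WT: plateau protein 1694.2 +/- 3.1 (sd 6.9, n=5)

$ silentsnp simulate --k-codon 0.004 --label SNP --n-runs 5 --seed 8 --out snp_demo
SNP: plateau protein 2923.6 +/- 8.3 (sd 18.5, n=5)
```

The SNP codon (tenfold-faster decoding, i.e. a tenfold more available tRNA)
raises the plateau from ~1694 to ~2924 molecules — a ~73% increase, driven
by faster clearing of the rate-limiting codon. The ratio surface over the
full grid (`k_snp ∈ 10⁻³·{0.4, 0.8, 1.6, 4}`, `τ_snp ∈ {0.1, 1, 5}`) comes
from `silentsnp sweep --out sweep/`.

Synthetic drug-response panel and sensitivity classification:

```
$ silentsnp generate --seed 7 --out panel.csv
wrote 140 records for 70 lines

$ silentsnp classify --in panel.csv --drug olaparib --out calls.csv
dataset     drug  n_wt  n_snp  mean_auc_wt  mean_auc_snp  t_statistic  p_value  sensitive_wt  sensitive_snp
  SYNTH olaparib    40     30     0.816232       0.73085    -2.723619 0.009864             0              3
```

The generated panel plants a genotype-linked AUC shift plus a small
strongly-sensitive SNP subpopulation; the classifier recovers it: the SNP
cohort's mean AUC is significantly lower (p ≈ 0.01) and the three sensitive
calls (`Z < −1.5`) all fall in the SNP cohort. Every command writes a JSON
sidecar (config, seed, version) from which the run can be regenerated.

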