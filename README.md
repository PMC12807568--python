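# protmr

Reusable pipeline for proteome-wide **cis-Mendelian randomization**,
**Bayesian colocalization**, and **network-MR mediation** linking plasma
proteins, blood pressure (BP), and cardiovascular disease (CVD) — together
with a **synthetic GWAS summary-statistics generator** that provides ground
truth for every stage.

## What it does

1. **Synthetic GWAS** (`protmr.simulate`) — LD-structured genotypes from a
   Gaussian-copula AR(1) haplotype model; a protein → SBP → binary-CVD causal
   chain over four mutually disjoint cohorts (protein, BP, CVD, LD reference);
   the +15/+10 mmHg BP medication adjustment; per-SNP linear or logistic
   association scans; multi-gene panels with a known subset of truly
   BP-mediated proteins.
2. **Instrument selection** (`protmr.instruments`) — cis-window (±1 Mb of the
   gene body, inclusive) and MAF > 0.01 filtering, greedy LD clumping
   (p < 5e-8, r² < 0.001, 10 000 kb window), per-SNP F-statistics.
3. **MR engine** (`protmr.mr`) — Wald ratio and IVW (multiplicative
   random-effects with φ = max(1, Q/(J−1))), Cochran's Q, Steiger
   directionality, bidirectional reverse-MR check, BH-FDR.
4. **Colocalization** (`protmr.coloc`) — Wakefield log-ABFs, two-trait
   five-hypothesis colocalization (priors 1e-4/1e-4/1e-5), three-trait
   colocalization over all 15 configurations (priors 1e-4/1e-6/1e-7),
   summary-statistic conditional analysis, and pairwise-conditional
   colocalization (PWCoCo-style) for regions with multiple independent
   signals. All posterior algebra in log space.
5. **Mediation** (`protmr.mediation`) — proportion mediated β1·β2/βTE with
   first-order delta-method CI and sign-consistency check.
6. **Pipeline** (`protmr.pipeline`) — the full screen: per-protein cis-MR
   against BP → same battery against CVD outcomes → colocalization
   prioritization (PP ≥ 70 %, gene-dense regions routed to PWCoCo, three-trait
   PP reported) → mediation for prioritized candidates, with a complete
   per-protein audit trail.

## CLI

```bash
# simulate one causal chain -> sumstats TSVs + LD TSV + truth YAML
protmr simulate --config chain.yaml --out simdir/

# instrument selection and MR
protmr clump simdir/protein.tsv --ld simdir/ld.tsv --out instruments.tsv
protmr mr instruments.tsv simdir/bp.tsv --out mr.tsv

# colocalization
protmr coloc simdir/protein.tsv simdir/bp.tsv --out coloc.json
protmr moloc simdir/protein.tsv simdir/bp.tsv simdir/cvd.tsv --binary 3 --out moloc.json
protmr pwcoco simdir/protein.tsv simdir/bp.tsv --ld simdir/ld.tsv --out pwcoco.json

# mediation from three MR estimates
protmr mediate --beta1 0.5 --se1 0.1 --beta2 0.4 --se2 0.1 --beta-te 0.4 --se-te 0.1

# full synthetic screen (simulate -> screen -> outcome stage -> coloc -> mediation)
protmr run-all --seed 1 --out results/
```

File formats: summary statistics are TSV with columns
`SNP CHR POS EA OA EAF BETA SE P N [N_CASES]`; LD is a square TSV with SNP
ids as first row and column.

## Notes on conventions

- Positions are 1-based; windows are inclusive on both ends.
- Palindromic variants are oriented by allele frequency when informative
  (minor frequency < 0.42 on both sides), otherwise dropped; configurable.
- Binary-trait effects are log odds ratios; `odds_ratio = exp(beta)` is
  reported alongside.
- The IVW variance never shrinks below the fixed-effect variance
  (`overdispersion=False` gives the exactly calibrated fixed-effect test).
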