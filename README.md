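# mtexpand

Phylogeographic analysis of mitochondrial control-region data: haplotype
accounting, molecular diversity, neutrality tests, mismatch-distribution
expansion dating, model-corrected distances and median-joining haplotype
networks — with a built-in coalescent simulator for validating every stage.

The package is aimed at the standard workflow of intraspecific mtDNA
studies: a few dozen to a few hundred aligned haploid sequences (or a
published haplotype-by-variable-site table with per-locality counts) are
collapsed into haplotypes, summarised by diversity indices, tested for
departures from the constant-size neutral model, dated under a sudden-
expansion model, and drawn as a haplotype network.  It ships the
control-region and cytochrome-*b* haplotype tables of the golden jackal
(*Canis aureus*) across India, Israel and Europe as packaged datasets, and
reproduces the published results for that system.

## The statistics

For n sequences with haplotype frequencies p_i, S segregating sites, and
mean pairwise differences k:

- haplotype diversity `h = n(1 − Σp_i²)/(n − 1)`; nucleotide diversity
  `π = k/L`
- Tajima's `D = (k − S/a₁) / √(e₁S + e₂S(S−1))`, negative under recent
  expansion
- Fu's `Fs = ln(S′/(1−S′))` with `S′ = P(K ≥ k_obs | θ = k)` under the
  Ewens sampling distribution
- mismatch distributions fitted to the stepwise-growth curve F(i; τ, θ₀, θ₁)
  by least squares, smoothness measured by Harpending's raggedness r, and
  the expansion age dated by rearranging `τ = 2μt`
- Tamura–Nei (TN93) distances with gamma rate heterogeneity and complete
  deletion
- median-joining networks: the ε-relaxed minimum-spanning network augmented
  with median (consensus) vectors of connected triplets

Conventions and numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from mtexpand import (
    jackal_cr_table, expand_table, haplotype_alignment, diversity_stats,
    mismatch_histogram, fit_sudden_expansion, tau_bootstrap_ci,
    expansion_time, build_mjn, network_stats,
)
from mtexpand.tables import INDIA_LOCALITIES

tbl = jackal_cr_table()                       # 18 haplotypes, 27 variable sites
india = expand_table(tbl, set(INDIA_LOCALITIES), length=440)

d = diversity_stats(india, L=440)
print(f"India: n={d.n}  S={d.S}  haplotypes={d.n_hap}  "
      f"h={d.h:.4f}+-{d.sd_h:.4f}  k={d.k:.3f}")

hap = haplotype_alignment(tbl, set(INDIA_LOCALITIES), length=440)
fit = fit_sudden_expansion(mismatch_histogram(hap))
ci = tau_bootstrap_ci(hap, B=1000, level=0.90, seed=42)
t, tci = expansion_time(fit.tau, tau_ci=ci)
print(f"expansion: tau={fit.tau:.3f}  raggedness={fit.r:.3f}  "
      f"t={t} YBP  90% CI {tci}")

st = network_stats(build_mjn(tbl))
print(f"network: {len(st['peripheral'])} of 18 haplotypes peripheral; "
      f"most interior: {st['interior_ranking'][0]} "
      f"(degree {st['degrees'][st['interior_ranking'][0]]})")
```

prints

```
India: n=52  S=25  haplotypes=16  h=0.8718+-0.0331  k=3.264
expansion: tau=4.193  raggedness=0.031  t=28720 YBP  90% CI (13778, 36818)
network: 11 of 18 haplotypes peripheral; most interior: Ind11 (degree 6)
```

Reading the output: the 52 Indian control-region sequences collapse into 16
haplotypes with 25 polymorphic sites and high gene diversity (h ≈ 0.87) —
many closely related haplotypes rather than a few divergent ones.  The
mismatch distribution among those haplotypes fits a sudden-expansion curve
with τ ≈ 4.2 mutational units and a low raggedness index, which at the
control-region rate of 7.3 × 10⁻⁵ per generation and one-year generations
dates the expansion to roughly 29,000 years before present (late
Pleistocene).  In the median-joining network most haplotypes hang off the
network by a single mutation while haplotype Ind11 sits at the centre with
six connections — the star-like shape characteristic of a recent radiation,
with the Indian haplotypes interior (ancestral) and the Israeli and
European haplotypes peripheral (derived).

The same stages are available from the shell:

```sh
mtexpand collapse --fasta aln.fa --localities map.tsv -o haps.tsv
mtexpand diversity --haps haps.tsv --group GJ --group UP --length 440
mtexpand mjn --haps haps.tsv -o network.graphml
mtexpand run --config run.toml       # full pipeline, TSV + JSON report
```

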