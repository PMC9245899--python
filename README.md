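# insulome

Runs-of-homozygosity (ROH) and identity-by-descent (IBD) analysis of
population insularity, for diploid genotype panels at common biallelic
SNPs — the kind of data produced by imputing low-coverage ancient
genomes. The package asks, and answers quantitatively, the questions one
asks of a putatively isolated population:

* **How inbred is each genome?** Sliding-window ROH calling with the
  standard PLINK parameterisation (`--homozyg-window-het 0 --homozyg-snp
  50 --homozyg-kb 1 --homozyg-density 5000 --homozyg-gap 5000`), genetic
  lengths in cM, and F_ROH = total ROH length / autosomal map length.
* **Is the inbreeding a recent pedigree loop or long-term drift?**
  Gene-dropping simulation of six consanguinity pedigrees (full sib,
  parent–offspring, avuncular, grandparent–grandchild, first cousins,
  great-avuncular; expected F = 1/4, 1/4, 1/8, 1/8, 1/16, 1/16) builds
  null clouds in (N_ROH, F_ROH) space; query genomes are classified by
  Mahalanobis distance and its empirical quantile (inside / edge /
  outside).
* **How small is the population?** A maximum-likelihood constant-Ne
  estimator from the 4–20 cM ROH length spectrum. With geometric
  coalescence times P(T=t) = (1/2Ne)(1−1/2Ne)^(t−1) and Poisson
  recombination, the expected segment-length density is
  λ(x) = Σ_c Σ_t P(t)[(2t)²(G_c−x) + 2(2t)]e^(−2tx); a composite Poisson
  likelihood over length bins yields the MLE and a profile-likelihood
  95% CI.
* **Who shares ancestry with whom?** LOD-score IBD segment detection on
  unphased genotypes (error-tolerant IBD1 vs Hardy–Weinberg likelihood
  ratio, ε = 0.005, LOD ≥ 3, segments ≥ 2 cM), KING-robust kinship
  filtering of close relatives (φ̂ > 0.0442), within/between-group IBD
  sharing summaries, and PCA of the total-IBD matrix.

A forward-in-time Wright–Fisher simulator with exact founder-mosaic
ancestry tracking generates analysis-ready synthetic panels with known
pedigrees, demography and ground-truth ROH/IBD segments, and underpins
the validation suite. See `docs/methods.md` for models, assumptions and
limitations.

## Worked example

Simulate a small island population and recover its size from the ROH
spectrum of 25 sampled genomes:

```python
import numpy as np
from insulome.core_io import GeneticMap
from insulome.synthetic_data import make_founders, NeTrajectory, simulate_population
from insulome.roh import RohParams, call_roh, f_roh
from insulome.ne_from_roh import RohNeModel, fit_ne_roh

# 6 chromosomes x 150 cM; diploid Ne = 250 for 60 generations
gmap = GeneticMap.uniform({f"chr{i+1}": 150.0 for i in range(6)})
founders = make_founders(1000, 0, gmap, seed=7, sites_per_cm=20)
panel, truth = simulate_population(
    founders, NeTrajectory.constant(250, 60), seed=7, gmap=gmap
)

sample = panel.ids[:25]
segments = {i: call_roh(panel, i, RohParams()) for i in sample}
f = [f_roh(segments[i], gmap.total_length_cm) for i in sample]
print(f"mean F_ROH over {len(sample)} genomes: {np.mean(f):.4f}")

est = fit_ne_roh(segments, RohNeModel.from_map(gmap))
print(f"Ne estimate: {est.ne_hat:.0f} (95% CI {est.ci95[0]:.0f}-{est.ci95[1]:.0f}) "
      f"from {est.n_segments} segments of 4-20 cM")
```

Output:

```
mean F_ROH over 25 genomes: 0.0665
Ne estimate: 239 (95% CI 201-287) from 134 segments of 4-20 cM
```

The mean F_ROH of 6.7% reflects sixty generations of drift at Ne = 250
(no pedigree loops were planted), and the spectrum-based estimate
recovers the true size of 250 inside its confidence interval.

## Command line

```sh
insulome demo-config --out demo.cfg && insulome run --config demo.cfg
insulome simulate --out panel.vcf --demes 2 --deme-size 100 --generations 30
insulome roh --vcf panel.vcf --map panel.vcf.map.tsv --out roh.tsv
insulome ibd --vcf panel.vcf --map panel.vcf.map.tsv --groups panel.vcf.groups --out-prefix ibd
insulome ne  --segments roh.tsv --map panel.vcf.map.tsv
insulome classify --vcf panel.vcf --map panel.vcf.map.tsv --out classes.tsv
```

`insulome run` executes the full pipeline (site filters → relative
removal → ROH/F_ROH → pedigree nulls → classification → per-group Ne →
IBD matrix → group summary → PCA) from one INI config and writes a
TSV/JSON report bundle; identical config and seed reproduce every output
byte-for-byte.

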