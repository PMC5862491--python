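# bayesn

Bayesian whole-genome regression for genomic prediction with a **nested
mixture prior over genomic windows** (BayesN), its comparators
(BayesB, BayesC/BayesCπ, BayesNC, a modified antedependence model
anteBayesB), a forward gene-dropping simulator, and an
accuracy/bias/window-count evaluation harness. It is written for
quantitative geneticists who want to study — or use — window-level
variable selection for traits whose causal variants (QTL) may be rare,
where no single SNP tags the QTL and several flanking markers must
capture its effect jointly.

## The model

All methods fit the mixed linear model

```
y = Xβ + Zu + e,    e ~ N(0, σ²ₑ I)
```

with `Z` the centered n×m SNP genotype matrix and `u` the SNP effects.
BayesB places an i.i.d. spike-and-slab prior on each effect,
`u_j = α_j δ_j` with `δ_j ~ Bern(1−π)` and a t-distributed slab. BayesN
nests this inside non-overlapping genomic windows (e.g. 1 or 0.2 Mb):

```
u_ij = α_ij · δ_ij · Δ_i
Δ_i  ~ Bern(1−Π)           window i in/out of the model
δ_ij ~ Bern(1−π_i)         SNP j selected within an in-model window
α_i | σ²_i ~ N(0, σ²_i I),  σ²_i ~ ν S²_α χ⁻²_ν   (multivariate-t window)
```

with `π_i = (m_i−k)/m_i` (k = SNPs fitted per QTL), `Π = (w−s)/w`
(s = assumed QTL count, w = SNP-bearing windows), so that for constant
window size `(1−Π)(1−π_i) = s·k/m = 1−π` — the same prior mass on
nonzero effects as BayesB. Effects of linked SNPs become dependent
through the shared window indicator and window variance: windows with a
QTL enter the model as a unit and the signal is refined by within-window
selection. Inference is Gibbs sampling with all indicators drawn with
their effects integrated out; correctness is pinned to an
exact-enumeration oracle on small instances.

## Worked example

Simulate a rare-QTL scenario on a dense panel, fit BayesN and BayesB,
and evaluate on held-out offspring:

```python
import numpy as np
from bayesn import engine
from bayesn.popsim import FounderConfig, ScenarioConfig, make_replicate, HD_LD
from bayesn.priors import ModelSpec

founder = FounderConfig(n_founders=300, chrom_lengths_bp=(5_000_000,)*2,
                        snps_per_chrom=(1136,)*2, **HD_LD, seed=0)
scen = ScenarioConfig(founder=founder, regime="rare", n_qtl=6,
                      window_size_bp=200_000, n_offspring=900, n_train=600,
                      h2=0.5, seed=4)
rep = make_replicate(scen)
hd = rep.panels["hd"]
y_tr = rep.phenotypes.y[rep.train_idx]
tbv_va = rep.trait.tbv[rep.validate_idx]
print(f"panel: {hd['Z_train'].n_snps} SNPs, {hd['windows'].w} windows "
      f"({hd['windows'].m_i.mean():.1f} SNPs/window), {scen.n_qtl} masked rare QTL")
for method in ("bayesn", "bayesb"):
    spec = ModelSpec(method=method, k=2, s=scen.n_qtl,
                     chain_length=2000, burn_in=500, seed=1)
    summ = engine.run_chain(y_tr, hd["Z_train"], spec, windows=hd["windows"])
    gebv = engine.predict_gebv(summ, hd["Z_validate"])
    print(f"{method:8s} accuracy={engine.accuracy(gebv, tbv_va):.3f} "
          f"bias_slope={engine.bias_slope(tbv_va, gebv):.3f} "
          f"windows_in={summ.mean_n_windows_in:.1f} "
          f"snps_in={summ.mean_n_snps_in:.1f}")
```

Output (one replicate; ~15 s):

```
panel: 1776 SNPs, 50 windows (35.5 SNPs/window), 6 masked rare QTL
bayesn   accuracy=0.631 bias_slope=0.827 windows_in=5.7 snps_in=10.9
bayesb   accuracy=0.662 bias_slope=0.888 windows_in=9.1 snps_in=10.6
```

Reading this: *accuracy* is the correlation between predicted (GEBV) and
true breeding values in the 300 validation offspring; *bias_slope* is
the regression of TBV on GEBV (1 = unbiased); *windows_in* is the
posterior-mean number of windows carrying a nonzero effect. BayesN's
windows-in (5.7) sits at the simulated QTL count (6), while BayesB
spreads its SNPs over half again as many windows — the window counts
estimate the number of QTL under the nested prior. Accuracy on a single
replicate is noisy in either direction; across replicates (see the
acceptance suite) BayesN's mean accuracy is at or above BayesB's in the
rare-QTL dense-panel setting.

The same workflow is available from the shell:

```
bayesn simulate --out sim --n-chrom 2 --chrom-length-bp 5000000 \
    --snps-per-chrom 1136 --regime rare --n-qtl 6 --window-mb 0.2 --seed 4
bayesn fit --bed sim/rep0/hd --pheno sim/rep0/phenotypes.tsv \
    --method bayesn --window-mb 0.2 --k 2 --s 6 --out fit
bayesn predict --fit-dir fit --bed sim/rep0/hd --out gebv.tsv
bayesn evaluate --gebv gebv.tsv --tbv sim/rep0/phenotypes.tsv --out metrics.tsv
```

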