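# msabias

Benchmarks for structure-based predictors are drawn from proteins whose 3D
structures have been solved — and those proteins systematically have far
richer evolutionary records (more homologs, deeper multiple sequence
alignments) than the average sequence a predictor meets in practice. For
methods whose accuracy grows with alignment depth, such as unsupervised
residue–residue contact predictors, this *observation selection bias*
inflates benchmark performance relative to real use.

`msabias` is a toolkit for quantifying and removing that bias:

* **MSA information content** — homolog count; NEFF, the mean over
  alignment columns of the number of distinct amino-acid types
  (1 = all sequences identical, 20 = complete variability); per-residue
  Shannon entropy in bits.
* **Ground-truth contacts** — CASP-style contact maps from PDB coordinates:
  residues i, j are in contact iff their Cβ atoms (Cα for glycine) are
  strictly closer than 8 Å.
* **Prediction scoring** — top-*L* precision (PPV) of ranked contact
  predictions with sequence separation |i − j| ≥ 5, where *L* is the chain
  length; dataset summaries as median with 25/40/60/75-percentile bands.
* **Bias-free benchmark construction** — record filters (length window,
  ≥ *L* contacts) and a distribution-matched sampler that selects a
  benchmark subset whose homolog-count distribution matches a reference
  population, by quantile matching on log1p counts.
* **Depth control** — rank-paired MSA truncation so an existing benchmark
  can be re-scored at another dataset's homolog budget.
* **Statistics** — two-tailed Wilcoxon rank-sum tests (exact for tiny
  samples, tie-corrected normal otherwise), Pearson correlations,
  stratified per-group comparisons.
* **A self-contained baseline predictor** — mutual information with
  average-product correction (MI+APC), depth-dependent like the heavyweight
  coevolution methods it stands in for.
* **Synthetic data** with known ground truth for every input: MSAs of
  controlled diversity, coupled-column MSAs with planted contacts, compact
  self-avoiding 3D chains, prediction lists of controlled precision, and
  two-population homolog-count models.

## Worked example

The whole pipeline on synthetic data — plant 20 coupled column pairs in a
500-row alignment, predict contacts with MI+APC, then cut the alignment to
5 % of its depth and watch the precision fall:

```python
from msabias import (SimConfig, gen_coupled_msa, metric_report,
                     predict_contacts, top_l_precision, subsample_msa)

pairs = tuple((i, i + 30) for i in range(1, 21))
cfg = SimConfig(seed=7, length=60, depth=500, planted_pairs=pairs, coupling=0.5)
aln, planted = gen_coupled_msa(cfg)

rep = metric_report(aln)
print(rep.homolog_count, round(rep.neff, 2), round(rep.mean_entropy_bits, 2))
# 500 20.0 4.3

full = top_l_precision(predict_contacts(aln), planted, fraction=20 / 60)
cut_aln = subsample_msa(aln, 25, seed=7)          # 5 % of the homologs
cut = top_l_precision(predict_contacts(cut_aln), planted, fraction=20 / 60)
print(full.ppv, cut.ppv)
# 1.0 0.6
```

With 500 homologs the baseline recovers all 20 planted contacts
(PPV 1.00); at 25 homologs it finds only 12 of 20 (PPV 0.60). That drop is
the bias mechanism in miniature: identical proteins, identical contacts —
only the evolutionary record changed.

The sampler side: two log-normal homolog-count populations whose means
differ 6-fold (a structure-biased set vs a sequence-only reference) are
distinguishable at z ≈ 52, and quantile matching picks 150 proteins from
the biased pool whose count distribution sits at Kolmogorov–Smirnov
distance 0.010 from the reference, versus 0.498 for a uniform-random pick
of the same size.

The same steps are available from a shell via the `msabias` command
(`metrics`, `contacts`, `evaluate`, `build-dataset`, `stats`,
`predict-baseline`, `simulate`); see `msabias --help`.

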