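# mrtline

Mutation, selection, and the *Caenorhabditis elegans* heat-sensitive
mortal-germline (Mrt) phenotype.

Strains with the Mrt phenotype become progressively sterile over a few to a
few tens of generations when cultured near the top of *C. elegans*' thermal
range (25°C). The phenotype is transgenerationally heritable and ultimately
genetic, which raises a population-genetics question: how fast do Mrt
alleles arise by mutation, how strongly does selection remove them, and is
the standing variation in nature consistent with mutation–selection balance
(MSB)?

`mrtline` implements the full inference chain for that question, for anyone
analysing Mrt-style transgenerational assays (mutation-accumulation lines
or wild-isolate panels with replicated time-to-sterility data):

* **phenotyping** — classify each line from its replicate outcomes into
  strong / moderate / weak Mrt, wild type, ts-sterile, or excluded
  (low fitness), using threshold rules on the mean and maximum generation
  at sterility; compare time-to-failure distributions between groups
  (Kolmogorov–Smirnov statistic with a permutation p-value).
* **rate_estimation** — the genomic mutation rate to the phenotype,
  `U = k/(n·t)` for `k` mutations in `n` MA lines over `t` generations,
  with the exact (Garwood) Poisson confidence interval via chi-square
  fractiles: `2λ_L = χ²_{2k}(α/2)`, `2λ_U = χ²_{2(k+1)}(1−α/2)`; plus the
  mutational-target size `U/μ_site`.
* **msb_inference** — selection coefficients from the MSB relation
  `q̂ ≈ U/s` for a highly selfing species, exact binomial intervals on
  phenotype frequencies, and a deterministic selfing recursion
  (`q → q + U(1−q)`, then `q → q(1−s)/(1−sq)`) validating the equilibrium
  approximation.
* **popgen_sim** — simulators for the two assumptions behind the estimator:
  loss probability 1/2 of a new neutral mutation under single-descent
  selfing, and MSB equilibrium in a finite Wright–Fisher selfing
  population; plus end-to-end parameter recovery of `U`.
* **tree_neighbors** — map phenotypes onto a Newick haplotype tree and test
  the MSB prediction that carrier strains scatter on tip branches (nearest
  phenotyped neighbor by patristic distance, permutation null).
* **synthetic_data** — generate assay tables with the study's designs
  (34 N2 lines × 10 reps × 21 generations, 33 PB306 lines × 10 reps × 14,
  18 pseudolines × 10 reps, 95 wild isolates × 3 reps × 21) and realistic
  per-class time-to-sterility distributions, censoring, and low-fitness
  contaminants.

## Worked example

One strong-Mrt mutation observed in 67 MA lines propagated for 250
generations (16,750 meioses):

```bash
mrtline rate --k 1 --lines 67 --gens 250
```

```json
{
  "k": 1,
  "meioses": 16750,
  "alpha": 0.05,
  "U": 5.9701492537313435e-05,
  "U_low": 1.5115109244352164e-06,
  "U_high": 0.0003326354263247103,
  "rounded": { "U": 6e-05, "U_low": 1.51e-06, "U_high": 0.000333 },
  "target_size": {
    "n_sites": 21321.961620469086,
    "fraction_pct": 0.021321961620469086,
    "upper_fraction_pct": 0.1187983665445394,
    "rounded_fraction_pct": 0.02,
    "rounded_upper_fraction_pct": 0.1
  }
}
```

Read: the point estimate is `U ≈ 6×10⁻⁵` per genome per generation, with
exact 95% bounds `1.5×10⁻⁶`–`3.3×10⁻⁴`. At a per-nucleotide rate of
`2.8×10⁻⁹` per generation, that rate implies a mutational target of roughly
21,000 sites — about 0.02% (possibly up to ~0.1%) of the 10⁸-bp genome.

With 6 of 95 wild isolates carrying the strong Mrt phenotype
(`q̂ ≈ 0.06`), mutation–selection balance gives the selection coefficient:

```bash
mrtline msb --U 6e-5 --count 6 --total 95 --lower-bound-count
```

reports `s_hat ≈ 0.00095` (≈ 0.001; an upper bound, since the carrier
count is a lower bound). The same relation applied to the single
ts-sterile mutation (`U = 1/16750`) and its single wild carrier
(`q̂ = 1/95`) gives `s ≈ 0.006`.

The whole pipeline on simulated data:

```bash
mrtline demo --seed 1
```

simulates 67 MA lines for 250 generations at the true rate `6×10⁻⁵`,
classifies the resulting assay table (with seed 1: one strong-Mrt line,
66 wild type), and re-estimates the rate with its interval.

Other subcommands: `simulate-assay`, `simulate-ma`, `classify`,
`compare-failure-times`, `sim-transmission`, `sim-wf`, `tree-nn`
(see `mrtline --help`).

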