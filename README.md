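# rumencm

Ecological-assembly analysis for rumen metatranscriptomes: Sloan's neutral
community model (NCM) on SGB read-count matrices, with Wilson-band selection
partitioning, animal-level bootstrap uncertainty, random-effects pooling
across sampling days, compositional statistics (CLR, Aitchison distance,
CLR-difference log2 fold changes) and CAZyme carbohydrate-binding-module
(CBM) tandem-architecture profiling.

The package is written for microbiome researchers who quantify how much of a
community's structure is stochastic (drift + immigration) versus
deterministic (selection), at the resolution of species-level genome bins
(SGBs), in longitudinal animal studies — the motivating design is a cattle
feed-efficiency study with two feed-efficiency groups (HFE/LFE), two diets
(forage/grain) and four sampling days. Because raw study data of this kind
is typically deposited as sequencing reads only, the package ships a
first-class synthetic-data generator that reproduces the statistical
structure the analysis assumes, so the entire pipeline is testable
end-to-end.

## The model

For SGB *i* with metacommunity relative abundance
*p<sub>i</sub>* = Σ<sub>j</sub> a<sub>ij</sub> / Σ<sub>ij</sub> a<sub>ij</sub>
(raw counts *a<sub>ij</sub>* pooled over the animals of one group-timepoint
slice), the NCM predicts its occurrence frequency across animals as the
upper tail of a Beta distribution:

    F̂_i = 1 − BetaCDF(d; α = Nm·p_i, β = Nm·(1 − p_i))

where *N* is the mean per-sample read total, *d* = 1/*N* the detection
limit, and *Nm* (community size × immigration probability) the single free
parameter, estimated by Levenberg–Marquardt nonlinear least squares against
the observed frequencies *F<sub>i</sub>* (fraction of animals with ≥ 1
read). Goodness of fit is R² = 1 − SS<sub>res</sub>/SS<sub>tot</sub>. Each
SGB is then classified against the 95% Wilson score band around its
predicted frequency (*n* = animals): **above** the band → positive
selection, **below** → negative selection, inside → consistent with neutral
assembly. Per-slice *Nm* and R² get animal-level bootstrap CIs, and
per-group estimates are pooled across sampling days by DerSimonian–Laird
random-effects meta-analysis (*Nm* on the log scale, R² linear).

## Worked example

Simulate a full study (2 groups × 4 days × 10 animals, 2000 SGBs,
~10⁵ reads/sample, 50 positively selected taxa injected per group) and run
the per-group NCM analysis:

```bash
rumencm simulate --n-sgb 2000 --n-animals 10 --depth-mean 100000 \
    --nm-hfe 110000 --nm-lfe 135000 --n-above 50 --seed 7 --out demo
rumencm run-study --counts demo/counts.tsv --metadata demo/metadata.csv \
    -B 100 --seed 7 --out demo/study
```

prints

```
wrote 2000 SGBs x 80 samples to demo
HFE: R^2 = 0.803 [95% CI 0.768-0.837], Nm = 162801 [95% CI 150326-176312]
LFE: R^2 = 0.790 [95% CI 0.755-0.826], Nm = 183794 [95% CI 171045-197493]
```

R² ≈ 0.8 says neutral processes explain most of the variation in SGB
occurrence frequencies; *Nm* is the effective immigration parameter pooled
over the four days (reported with its bootstrap-based random-effects CI).
`demo/study/` additionally contains one partition TSV per slice
(`sgb_id, p, F, F_hat, lower, upper, label`) and a JSON summary with
partition proportions — the fraction of SGBs under positive/negative
selection. Downstream, `rumencm summarize` aggregates partitions into
group- and genus-level selection ranges ("20.4%–28.2%"-style strings),
`rumencm clr | distance | log2fc` compute the compositional statistics, and
`rumencm cbm-profile` counts CBM-associated catalytic enzyme structures and
tandem CBM runs (e.g. CBM11+CBM11+CBM11+GH51) per genome. Every subcommand
writes a JSON run manifest (parameters, input digests, seed, version).

The same operations are available as a library
(`rumencm.simulate_study`, `rumencm.fit_ncm`, `rumencm.run_ncm_study`,
`rumencm.clr_transform`, `rumencm.count_cbm_structures`, ...).

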