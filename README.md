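# dadsim

Stochastic lattice models of **diffusive histone inheritance at the
replication fork**, and a genomics pipeline that tests the model's
predicted histone-mark similarity patterns in Hi-C / replication-timing /
ChIP-seq data.

## The scientific problem

When the replication fork passes, parental histones — and the
post-translational marks they carry — are dislodged and redeposited on the
two daughter strands.  The textbook picture is strictly local recycling.
The *diffusion-accessible-domain* (DAD) hypothesis instead allows a
dislodged histone to diffuse for a short time and land on **any** spatially
proximal locus that is replicating at the same moment, with faster
diffusion in open (euchromatic, early-replicating) chromatin than in
compact (heterochromatic, late-replicating) chromatin.  Two consequences
follow:

1. tagged histones at a single locus dilute across cell cycles faster in
   active than in repressed chromatin;
2. pairs of loci accumulate *similar* mark levels at rates set by their
   spatial distance and their compartment's diffusivity, leaving
   detectable fingerprints in genome-wide data.

`dadsim` implements both the models and the detection pipeline:

| module | what it does |
| --- | --- |
| `dadsim.lattice_model` | Model 1: R x N nucleosome lattice; Gaussian transfer kernel `p(i,i') ∝ (4πDT)^(-1/2) exp(-x²/4DT)` with `x = |i-i'|`; stochastic replication; tagged-fraction dilution curves; deterministic expectation oracle; one-parameter fit of D; the `√(6Dt)` domain-size bound |
| `dadsim.mark_model` | Model 2: marks of interest vs other marks on an Early/Late lattice, two diffusion constants `D_EE > D_LL`, compartment-restricted transfer, nearest-neighbour mark copying |
| `dadsim.similarity_stats` | the similarity statistic `Q(i₁,i₂) = \|log₁₀(signal₁/signal₂)\|`, binned medians, OLS slopes, chance medians from 10000 random pairs, ΔΔ |
| `dadsim.epigenome_pipeline` | 1 Mb binning, ±cutoff replication-timing classification, per-bin ChIP-seq signal `Σ Hₚ·Wₚ`, Hi-C spatial proximity (Pearson row correlation; observed / enrichment variants), pair tables, pattern summaries |
| `dadsim.synthetic_data` | dilution curves with known D, and a coherent synthetic genome (bimodal timing tracks, narrowPeak tracks, plaid Hi-C) with planted DAD-like similarity structure |
| `dadsim.cli` | the `dadsim` command: `simulate-dilution`, `fit-d`, `simulate-marks`, `synth`, `epigenome-q` |

## Worked example

Simulate tagged-histone dilution at the centre locus of a 9-locus lattice
and re-fit the diffusion constant:

```python
from dadsim import simulate_dilution, fit_diffusion_constant, dad_size_estimate

curve = simulate_dilution(n_rows=9, n_cols=50, tagged_row=4,
                          diffusion_constant=0.5, n_generations=6,
                          n_replicates=500, seed=1)
print(curve.to_frame().round(4))
fit = fit_diffusion_constant(curve, 9, 50, 4, search_interval=(1e-3, 10.0))
print("D_hat =", round(fit.diffusion_constant, 4))
print("DAD size bound:", round(dad_size_estimate(10.0, 1.0), 3), "um")
```

prints

```
 generation  mean_fraction     sd  n_replicates
          0         1.0000 0.0000           500
          1         0.2066 0.0533           500
          2         0.0712 0.0353           500
          3         0.0299 0.0254           500
          4         0.0128 0.0163           500
          5         0.0053 0.0106           500
          6         0.0029 0.0075           500
D_hat = 0.4687
DAD size bound: 7.746 um
```

The tagged fraction starts at 1 and decays faster than the no-diffusion
halving law `2⁻ᵍ` (0.207 rather than 0.5 after one division) because
diffusion carries tagged histones to neighbouring loci, where they are
counted as lost.  The least-squares fit recovers the generating
`D = 0.5` within ~6% from 500 stochastic replicates.  The last line is the
rough physical bound on the diffusion-accessible-domain radius for
`D = 10 um²/s` and ~1 s of diffusion: about 8 um, comparable to distances
between chromosomes.

The same workflow from a shell:

```sh
dadsim simulate-dilution -R 9 -N 50 --r-star 4 -D 0.5 \
    --generations 6 --replicates 500 --seed 1 --outdir run/
dadsim fit-d --curve run/dilution_curve.csv -R 9 -N 50 --r-star 4 --outdir run/
```

To run the full pattern analysis on the bundled synthetic genome:

```sh
dadsim synth --seed 1 --outdir genome/
dadsim epigenome-q --chrom-sizes genome/chrom.sizes \
    --early-bg genome/early.bedGraph --late-bg genome/late.bedGraph \
    --peaks planted=genome/planted.narrowPeak --hic genome/hic_matrix.tsv \
    --seed 1 --outdir out/
```

which reports, per mark, whether the three predicted patterns are present
(EE pairs more similar than LL at every proximity, similarity decaying
with distance, and a steeper decay for LL pairs), and writes pair and
summary TSVs.

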