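# stratanet

Analysis of **multi-layer, time-resolved biological networks**: the same set
of entities (genes, proteins, knockdown targets) is replicated across several
*layers* — categories of measurement such as histone acetylation, RNA
polymerase II binding, mRNA abundance, protein levels, or morphological
phenotypes from an RNAi screen — and every entity carries one time-series
vector per layer. stratanet is a scriptable library plus a CLI for people who
have this kind of data (perturbation time courses, multi-omics dynamics,
time-lapse phenotype screens) and want to find which entities move together,
which jump suddenly, and which show persistent signal.

## What it computes

**Per-layer color encoding.** Values map linearly onto a yellow–blue gradient
anchored at each layer's own (min, max) over the whole time course; exactly
zero or missing values are drawn grey; a colorblind-safe blue–orange preset
and a reversed orientation are available. Layers are never pooled — their
units may be incomparable.

**Per-time-point clustering by distance geometry.** At time *t* each entity
on a layer is a scalar v_i(t); the distance matrix D_ij = |v_i(t) − v_j(t)| is
embedded in 3-D by classical multidimensional scaling (double-center
−½·J·D²·J, keep the top three nonnegative eigenpairs, scale eigenvectors by
√λ). A 1-D metric embeds exactly, so similar entities land next to each
other. "Top changers" — entities with the largest |Δv| between consecutive
time points — are flagged and connected across layer panels in snapshots.

**Correlation significance.** For every entity pair on a layer, the Pearson
correlation r over the n shared time points is significant at level α iff
|r| ≥ r_crit(n, α), with r_crit obtained by exact inversion of the Student-t
critical value: r_crit = t_crit / √(t_crit² + df), df = n − 2. With three
time points (df = 1) this demands |r| > 0.997 at α = 0.05. The Spearman rank
alternative uses t = r·√(n−2)/√(1−r²) ~ t(df = n−2). Offered levels:
α ∈ {0.10, 0.05, 0.02, 0.01}. A pair significant on ≥ 2 layers is a
**recurrent correlation**; per-layer signs are kept (mixed-sign recurrence is
biologically meaningful). These are screening statistics — consecutive time
points are not independent samples.

**Similarity scoring.** Each trajectory is summarized either by (a) its mean,
or (b) the lower bound of the Wilson score confidence interval for the
fraction p̂ of time points whose value exceeds a threshold:

    S = ( p̂ + z²/2n − z·√( p̂(1−p̂)/n + z²/4n² ) ) / ( 1 + z²/n ),

z = z_{α/2}. Raw scores are binned 0–10 against the layer's own score range
and colored white → red; entities with equal scores get identical colors.

**Synthetic data.** A seeded generator produces networks shaped after two
study designs — `esc_core` (4 layers × 3 time points, a stem-cell core
network) and `mitotic_screen` (7 phenotype layers × 90 time points over
45 h, 1067 knockdown targets, a sparse rare phenotype, a late-onset latent
signal) — with *planted* correlated pairs, step changes and latent onsets
recorded in a manifest, so every analysis above can be validated against
known ground truth.

## Worked example

```
stratanet simulate --preset esc_core --seed 1 --out esc.tsv
stratanet correlate --in esc.tsv --recurrent
```

```
entity_a  entity_b  layers                         signs              consistent
gene_02   gene_05   histone_acetylation,mrna       positive,positive  True
gene_03   gene_07   pol2_binding,protein           negative,negative  True
gene_09   gene_11   histone_acetylation,protein    negative,negative  True
...
```

The two planted pairs (gene_02–gene_05 positive on the acetylation and mRNA
layers; gene_03–gene_07 negative on the Pol II and protein layers) are
recovered; the remaining rows are chance recurrences — with n = 3 time
points each pair has a 5% false-positive rate per layer, so a few of the
435 × 4 tested pair-layer combinations recur by chance.

```
stratanet changes --in esc.tsv --layer histone_acetylation --from-time day1
```

```
layer                from  to    entity   delta
histone_acetylation  day1  day3  gene_11  8.115561545
```

gene_11 carries the planted step change (magnitude 8) between days 1 and 3.

```
stratanet score --in esc.tsv --layer protein --scheme wilson --threshold 5.0
```

```
layer    entity   scheme  raw           bin  color
protein  gene_01  wilson  0             0    #ffffff
protein  gene_03  wilson  0.2076596008  4    #ff9999
protein  gene_04  wilson  0.4385029682  10   #ff0000
...
```

gene_04 exceeds the threshold at all 3 time points (p̂ = 1), but the Wilson
lower bound tempers that to 0.44 because n = 3 is tiny; gene_03 exceeds it
at 2 of 3 points. `snapshot --time day3 --embed --show-correlations` renders
the per-layer panels; `track --entity gene_02 --plot out.png` draws one
line per layer for a single gene.

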