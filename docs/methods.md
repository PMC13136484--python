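# Methods

## Model and estimator

A segmented imaging field (a *sample*; typically one hemisphere) is
treated as a realization of a marked point process observed in an
axis-aligned rectangular window `W`: cell centers `x_i` (nuclei
projected to the apical plane, μm) carry numeric marks `m_i` — nuclear
intensity sum, concentration (sum / nuclear volume), apical area or
transcript counts. Fields are analyzed independently and only summary
curves are pooled, because absolute intensity scales vary between
animals and staining runs.

For a chosen center group `C` (default: the per-sample 20% of cells
with the lowest mark, rank-based with stable input-order tie-breaking,
exactly `floor(0.2 n)` cells) the group-centered mark-weighted
K-function is

    K_m(r) = 1/(λ μ̄ n_c) Σ_{i∈C} Σ_{j≠i} f(m_i, m_j) 1(d_ij ≤ r) w_ij

with pair weight `f(m_i, m_j) = m_j` (the neighbor's mark, so the inner
sum is the total mark surrounding a center; `m_i·m_j` and `|m_i−m_j|`
are available but experimental), mean mark `μ̄` over *all* cells of the
sample, `n_c = |C|`, and translation edge-correction weight
`w_ij = |W|/((a−|Δx_ij|)(b−|Δy_ij|))`. Self-pairs are excluded;
center–center pairs are not. `L_m = sqrt(K_m/π)` is the
variance-stabilized form; all inference operates on `L`.

Numerical conventions:

- **Neighbor intensity** `λ = (n−1)/|W|` (leave-one-out): each center
  sees `n−1` potential neighbors, and this choice makes the unmarked
  translation-corrected estimator exactly unbiased for a binomial
  pattern. The alternative `n/|W|` differs by `O(1/n)` and cancels in
  `L̂_m − L̂₀` in any case.
- **Radius grid**: 0 to 30 μm in 0.5 μm steps by default (the
  biological signal of interest lives in the first ~8 μm; 30 μm gives
  context). At radii with no center–neighbor pair `K̂ = 0` by
  convention, so curves are always comparable across permutations.
- **Window**: image frames are rarely exported, so the default window
  is data-driven — the per-sample bounding rectangle expanded on each
  side by half the median nearest-neighbour distance, so boundary cells
  do not sit exactly on the window edge (which would make a translation
  weight singular). A JSON sidecar can supply exact frames instead.
  Rectangles only; non-rectangular windows are out of scope.
- **Small-radius bias**: `E[√K] < √E[K]`, so `L̂` is biased downward at
  radii where the expected pair count is ≪ 1. This matters only for
  absolute CSR comparisons at the first one or two grid steps, never
  for the permutation contrast, which compares identically-constructed
  curves.
- **Pooling**: pointwise unweighted mean of per-sample `L̂` curves.
  Valid because each curve is normalized by its own sample's intensity
  and mean mark; no registration of coordinates across samples is
  attempted or needed.

The optimized estimator bins pairwise distances once per sample
(`SamplePairCache`) and accumulates mark-weighted counts per
permutation in O(n_c·n); a literal double-loop implementation
(`marked_k_naive`) is kept as an independent oracle and the two agree
to 1e−10 on every tested instance.

## Permutation inference

The null hypothesis is the absence of space–mark correlation,
H₀: L_m = L₀. The benchmark is built by fixing positions and permuting
marks within each sample. The reference curve `L̂₀` averages
`n_ref = 100` permutation replicates of the pooled curve; the deviation
test draws `s = 99` fresh replicates and computes

    u   = max_{r∈[0,R]} |L̂_m(r) − L̂₀(r)|,   u_i likewise per replicate,
    p̂  = 1 − (1/(s+1)) Σ_i 1(u_i < u),

so `p̂ ∈ {0.01, 0.02, …, 1}` at the defaults and ties count toward the
larger, conservative value. `R` defaults to the full grid. The global
envelope `±D_max = ±max_i u_i` is reported with per-radius exceedance
flags; a crossing at radius `r` localizes where marks around a typical
center are higher (above) or lower (below) than chance, and any
crossing implies `u > D_max`, hence the minimal p-value. The reference
and test replicate sets are independent by default; `reuse_reference`
re-uses the reference replicates as the test set for speed.

**Center handling under permutation** was the one genuinely open design
choice, and the three candidate schemes differ sharply:

- `stratified` (default): the center group is classified once from the
  observed marks and held fixed; marks are exchanged within the group
  and within its complement separately. Conditionally on the group
  partition, the within-stratum assignments are uniformly exchangeable
  under H₀, so the p-value is exactly valid — and because every curve
  (observed and permuted) shares the same center geometry, the null
  deviations isolate exactly the question being asked: are the marks
  *around* low cells arranged relative to them, or scattered at
  random? Measured on iid-mark niches the rejection rate at α = 0.01
  is nominal.
- `full`: all marks exchanged, centers fixed. The observed pattern
  carries its lowest marks at the centers, a constraint replicates
  ignore; center–center pairs then make the observed curve sit
  systematically below the replicate distribution and the test is
  anticonservative (measured ≈5% rejection at nominal 1%).
- `recompute`: all marks exchanged and the low group re-derived per
  replicate. Exactly exchangeable, but the spatial variability of
  random 20%-subsets then dominates the null deviations; since the
  estimator normalizes marks away, this geometric noise scales with
  the signal and the test has essentially no power at any effect size
  at niche-scale cell counts. Kept for the p-uniformity property test
  and for comparison.

RNG streams derive deterministically from one master seed per
(phase, replicate, sample), so identical config + seed give
bit-identical outputs end to end. Multi-channel analyses are
independent runs sharing the seed stream; no multiplicity correction is
applied (per-mark p-values are reported separately).

## Mark processing

- Concentration = intensity sum / nuclear volume (μm⁻³ units).
- Z-scores use the population SD (ddof = 0) per-sample or pooled;
  group summaries report population SD, while the two-group variance
  comparison uses sample variances (ddof = 1) with a two-sided F-test
  by default (Brown–Forsythe Levene via option — the F-test assumes
  normality; with skewed marks prefer Levene).
- Rank correlations are Spearman with average-rank ties.
- Neighbor counts consume a per-sample undirected edge list (cells
  sharing a membrane segment, or a Delaunay / fixed-radius synthetic
  stand-in) and report per-cell totals and flagged-neighbor totals.
- Quantile classification is invariant under strictly increasing mark
  transforms and commutes with z-scoring and variance attenuation.
- An optional inner-buffer filter restricts *centers* (not neighbors)
  to cells away from the window edge; default off, since the
  translation correction already handles edges and segmentation-time
  exclusion should not be double-applied.

## Synthetic niche generator

The generator emulates the statistical structure the analysis assumes,
not the biology that produces it.

- **Geometry**: random sequential adsorption with a hard-core minimum
  center distance `d_min = 4 μm` in an 80×80 μm window holding
  100–200 cells (drawn uniformly when unspecified). This gives apical
  footprints of `|W|/n ≈ 32–64 μm²` and nearest-neighbour spacings of
  4–6 μm — a contact epithelium at realistic density, which is what
  gives the contact-scale statistic its resolution. A feasibility
  screen rejects packings beyond RSA saturation.
- **iid null**: marks drawn independently of position, normal
  (mean 2000, SD 400, arbitrary concentration-like units) or lognormal
  with matched moments.
- **Lateral inhibition**: `floor(0.15 n)` sender cells chosen
  uniformly; a sender's mark is its base draw divided by 3; every
  non-sender gains `A·exp(−d/ρ)` per sender within `3ρ`, with
  `A = 3500` and `ρ = 2.5 μm`. The kernel's reach (≈7.5 μm) confines
  the elevation to a sender's contact ring, and the amplitude places
  first-ring neighbors 1–2 base SDs above the mean — low-signaling
  cells ringed by top-quantile cells, the salt-and-pepper fingerprint
  of contact-mediated inhibition, detectable as an envelope exceedance
  over roughly the first 8 μm. Because an imaged field is a crop of a
  larger sheet, boost sources are additionally drawn as a Poisson
  field of *virtual* senders (same intensity) in a `3ρ` band outside
  the window; omitting them depresses boost near the frame edge and
  biases the low group toward edge cells — a crop artifact, not a
  tissue feature.
- **Attenuated**: the lateral-inhibition field transformed by
  `m' = mean(m) + sqrt(v)·(m − mean(m))` with `v = 0.5` per sample —
  variance exactly halved, mean and ranks preserved. This emulates a
  condition in which the signaling pattern's spatial structure
  persists while the dynamic range between senders and receivers
  shrinks (as under knockdown of an amplifying ligand).
- **Transcript counts**: a geometric channel (support 0,1,2,…; mode at
  zero, heavy right tail) and an independent rounded truncated-normal
  channel (narrow, bell-shaped) mimic the two observed classes of
  per-cell count distributions.
- Volumes are lognormal (mean 250 μm³, CV 0.25); the apical-area
  channel is position-independent by construction and serves as the
  negative-control mark.

Every generator call is a pure function of (config, seed).

**What passing tests do and do not show.** The generator reproduces
hard-core packing, per-sample mark-scale heterogeneity, a localized
low-center/high-surround regime and its variance-attenuated variant; it
does not model imaging noise, segmentation error, 3D geometry,
mechanistic signaling dynamics, or spatial inhomogeneity of cell
density. Calibration and power measured here therefore demonstrate the
statistical machinery under the stated regimes, not performance on any
particular real tissue.

## Operating characteristics

Computed end to end by the test suite and `scripts/acceptance.py`:

- Type-I error of the full pipeline at s = 99, α = 0.01 on iid-mark
  niches stays within the exact 99% binomial band around 0.01 over 500
  runs.
- Power on the default lateral-inhibition regime (two pooled fields
  per run) exceeds 80% over 100 runs, with envelope exceedance
  confined to small radii (median outermost flagged radius ≈ 9–10 μm).
- The uncorrelated apical-area channel rejects at the nominal rate.
- The CSR calibration (200 uniform 200-point patterns, 50×50 μm
  window) keeps `mean(L̂(r) − r)` within 3 standard errors of zero for
  r up to a quarter of the window side.

Problem sizes in the default test run (field sizes, replicate counts,
permutation counts) match the figures above; they were chosen as the
smallest studies that measure each property with meaningful binomial
precision.

## Known limitations

- Rectangular windows only; the translation correction and the window
  inference assume axis-aligned rectangles.
- The deviation test reports one p-value per mark channel; no
  multiplicity correction across channels.
- Under the stratified scheme the test conditions on the observed
  group partition; it does not ask whether the low cells themselves
  cluster or disperse spatially (the `recompute` scheme does, at a
  severe power cost; a dedicated unmarked statistic on the center
  pattern would be the right tool for that question).
- The F-test variance comparison is normality-sensitive; use Levene
  for skewed marks.
- `L̂` is biased low at radii with ≪ 1 expected pair (√ concavity);
  absolute comparisons at the first grid steps need dense patterns.
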