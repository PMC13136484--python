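# nichemark

Spatial statistics for marked cell niches: do the cells with the lowest
signaling sit in neighborhoods whose signaling is higher than chance?

`nichemark` analyzes per-cell quantification tables exported from image
segmentation (one row per nucleus: apical-plane position in μm, nuclear
volume, and numeric *marks* such as nuclear signaling intensity,
concentration, apical area or transcript-dot counts). It was built for
the kind of question raised by Notch signaling in adult neural-stem-cell
niches — whether cells receiving the least Notch3 signal (N3ICD-low) are
surrounded, within a cell diameter or two, by the highest-signaling
cells, the spatial fingerprint of lateral inhibition — but applies to
any marked point pattern in a rectangular window.

## The statistic

The tissue is modeled as a marked point process: positions `x_i` with
marks `m_i`. For center cells taken as the per-sample lowest 20% of a
mark, the mark-weighted Besag L-function

    K_m(r) = 1/(λ μ̄ n_c) Σ_{i∈centers} Σ_{j≠i} m_j 1(d_ij ≤ r) w_ij
    L_m(r) = sqrt(K_m(r) / π)

accumulates the total mark surrounding a center within radius `r`,
normalized by the neighbor intensity `λ = (n−1)/|W|` and the mean mark
`μ̄`, with translation edge-correction weights
`w_ij = |W| / ((a−|Δx|)(b−|Δy|))` for a rectangular window with sides
`(a, b)`. Per-sample curves are directly comparable and are pooled by
pointwise averaging.

Inference is by mark permutation: positions fixed, marks exchanged
within each sample (by default *within* the low group and *within* its
complement, an exactly valid conditional randomization; see
`docs/methods.md`). The reference curve `L̂₀` averages 100 permutation
replicates; the deviation test compares

    u = max_{r ≤ R} |L̂_m(r) − L̂₀(r)|

against `s = 99` fresh replicate deviations `u_i`, giving
`p̂ = 1 − (1/(s+1)) Σ 1(u_i < u)` (minimum 0.01), and the global
envelope `±D_max = ±max_i u_i` localizes at which radii marks around a
typical low cell are higher (or lower) than expected by chance.

A synthetic-niche generator (hard-core packed epithelial fields of
100–200 cells, iid-null / lateral-inhibition / variance-attenuated mark
regimes, exponential-like and normal-like transcript-count channels)
makes every stage testable without imaging data.

## Worked example

```
$ python analysis/01_simulate_niches.py
lateral_inhibition: 278 cells in 2 fields (41 ground-truth senders) -> results/data/lateral_inhibition
$ python analysis/02_spatial_deviation_test.py
n3icd_conc: u=0.257 p_hat=0.01 d_max=0.222 exceed_hi=6.0-10.0 um
n3icd_sum: u=0.399 p_hat=0.01 d_max=0.348 exceed_hi=6.0-7.5 um
apical_area: u=0.098 p_hat=0.63 d_max=0.204 exceed_hi=none
```

Reading: in a two-field lateral-inhibition niche, the signaling
concentration around low-signaling cells deviates above the permutation
envelope at radii of ~6–10 μm — the contact ring — and the test rejects
the uncorrelated null at its smallest attainable p-value (0.01 at
s = 99). The apical-area channel, generated independently of position,
behaves as a null (p = 0.63). The same comparison on the
variance-attenuated regime (`analysis/04_variance_attenuation.py`)
halves the per-cell mark variance (5.1×10⁵ → 2.6×10⁵, F-test
p ≈ 1e−8) yet leaves the exceedance band unchanged — the spatial
structure survives, only its amplitude shrinks.

The same analyses run from the shell on any cell table:

```
nichemark simulate --out mydata --model lateral_inhibition --seed 1
nichemark analyze --cells mydata/cells.csv --channel n3icd_conc \
    --windows mydata/windows.json --s 99 --n-ref 100 --seed 1 --out out/
nichemark calibrate --n-replicates 100 --out calib/
nichemark summarize --cells mydata/cells.csv --channel n3icd_conc
```

`analyze` writes `curves_<channel>.csv` (observed and reference curves,
envelope, exceedance flags per radius), `report_<channel>.json`,
`groups.csv` and `run.log`; identical config and seed give bit-identical
outputs.

## Layout

- `src/nichemark/` — the library: `cell_tables` (I/O, windows),
  `marks` (z-scores, quantile groups, variance/correlation summaries,
  neighbor counts), `lfunction` (marked K/L with translation
  correction), `inference` (permutation null, deviation test,
  envelope), `synthetic` (niche generator), `pipeline` + `cli`.
- `analysis/` — numbered drivers reproducing the study-style analyses.
- `tests/` — unit, property and end-to-end statistical tests.
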