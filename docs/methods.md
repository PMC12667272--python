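# Methods

## Isotope bookkeeping

All enrichments are carried internally as atom fractions in [0, 1]; atom%
is converted at I/O boundaries only (`percent_to_fraction`, `*_pct` TSV
columns, `*_pct` config keys). Natural-abundance references default to
0.0036765 for ¹⁵N (atmospheric N₂ standard) and 0.0111 for ¹³C
(VPDB-derived); both are overridable in the `labeling:` config block. The
¹⁵N enrichment of the dissolved N₂ pool after tracer addition (`a_N2`) is
an experiment-specific quantity — it depends on how much labelled gas
dissolved — and is therefore a required user input, never a default.

## Bulk rates and detection

The tracer mass balance assumes the ¹⁵N label enters PN only through N₂
fixation and that the source-pool enrichment is constant over the
incubation. Negative enrichments produce negative rates that are reported
and flagged (`negative=True`, `detected=False`), never clipped or zeroed —
they are the natural sign of measurement noise at zero rate and belong in
the audit trail.

Detection uses a minimum quantifiable rate: the smallest resolvable
enrichment `k·σ_a` (coverage factor `k`, default 3; atom-fraction
measurement noise `σ_a`, configurable, default 2×10⁻⁶) propagated through
the rate equation. Under the default study conditions (PN = 500 nmol L⁻¹,
`a_N2` = 0.025, 1-day incubation) this gives an MQR of ≈0.14
nmol N L⁻¹ d⁻¹, of the same order as the ~0.1 nmol N L⁻¹ d⁻¹ working
threshold typical of oligotrophic surveys. The group-level MQR is the mean
of the replicate-level MQRs; `detected` compares the replicate-mean rate
against it. Incubation durations are in days; ~24 h incubations are t ≈ 1.

## Single-cell rates

Per-ROI atom fractions come directly from secondary-ion counts. The
nitrogen quota chain is: elliptic-prism biovolume `V = π/4·L·W·H` (height
defaults to width, appropriate for pennate cells imaged in valve view),
carbon by the diatom power law `pgC = a·V^b` with defaults a = 0.288,
b = 0.811, nitrogen at a configurable C:N (Redfield 6.625 default). This
quota model is a deliberate, documented stand-in for cell-specific N
measurements; all three parameters are exposed.

The ¹³C growth model assumes exponential growth with new biomass labelled
at the DIC source enrichment, so relative enrichment approaches the source
as `1 − e^(−μt)`; inverting gives `μ = −ln(1 − E/S)/t`. Enrichment at or
above the source is impossible under this model and raises; negative
excess is clipped to zero growth with a flag.

A whole-symbiosis rate sums host and symbiont ROI rates. Because fixed
¹⁵N is transferred from symbionts to the host, the host ROI carries most
of the newly fixed N; summing disjoint parts counts each atom once. Users
who want symbiont-only rates can restrict the ROI set. Negative ¹⁵N excess
is clipped to zero at the rate stage only (flagged); raw atom fractions
are never altered.

## Contribution scaling

Abundance is count over equivalent seawater volume; the equivalent volume
of a filter piece is a user input (directly, or as piece area / effective
filtration area × filtered volume — the effective area excludes the
filtration-tower rim and is not assumed from the nominal filter diameter).
Contribution = abundance × mean single-cell rate × 10⁻⁶ (fmol → nmol).
Printed-table output rounds half away from zero to 2 decimals; machine
output always retains full precision, and percentages are computed from
unrounded values. Percent-of-bulk is defined only for detected, positive
bulk rates; otherwise it is NaN with a flag. Expected gene copies default
to one *nifH* copy per symbiont genome and two symbionts per host (the
minimum observed occupancy), both configurable. The quantifiability
classification treats copy numbers within a factor (default 2×) above the
upper limit of quantification as "marginal".

## Amplicon clades

The bleed-through filter removes dataset-wide singletons and ASVs whose
total count is below 0.1% of the mean per-sample depth. The threshold is
applied to dataset-wide ASV totals (the convention of the amplicon
workflow this emulates, where the phrase "relative abundance below 0.1% of
mean sample depth" is dataset-wide); filtering is idempotent.

Pairwise identity uses a global alignment with free terminal gaps
(match +1, mismatch −1, gap −2). Identity is matches over aligned columns,
terminal-gap columns excluded; `N` never matches but its columns count.
Among co-optimal alignments the one maximising matches (then minimising
columns) defines the reported identity, making it a deterministic,
symmetric function of the pair — implemented as a single dynamic program
over the lexicographic objective (score, matches, −columns) packed into
64-bit integers and vectorised row-wise with numpy. Free terminal gaps
make the optimum of two *unrelated* sequences degenerate to a short
perfect overlap; pairs whose optimal alignment covers less than half the
shorter sequence are therefore reported at identity 0. Same-trim amplicons
with genuine homology are unaffected.

Clustering is agglomerative complete linkage (scipy) on distance
1 − identity, cut at 1 − θ (θ = 0.95 default). Complete linkage is chosen
because it guarantees the within-clade minimum identity ≥ θ by
construction — consistent with reported within-clade similarities sitting
at or above the clustering cutoff — where single linkage could chain below
it. The guarantee is additionally asserted on every clustering output.
Clade labels are deterministic (lexicographic by smallest member id), so
clustering is permutation-invariant up to relabelling. Phylogenetic clade
naming and "Marine 1" membership are user-supplied metadata, not computed.

## Synthetic data

The generator emulates the study conditions and writes the same TSV/FASTA
dialects the analysis reads, with every planted quantity in a `truth.json`
sidecar. One root seed fans out to independent per-generator streams via
`numpy.random.SeedSequence.spawn`; identical seeds give byte-identical
bundles.

* **Incubations**: three gyre stations with true rates 0.58/0.32/0.43
  nmol N L⁻¹ d⁻¹ at 62/21/27 m, triplicates, PN = 500 nmol L⁻¹,
  Gaussian atom-fraction noise sd 2×10⁻⁶ (≈0.05 nmol N L⁻¹ d⁻¹ on the
  rate scale, the replicate variability of the lower-variance stations).
  Final atom fractions invert the rate equation exactly before noise;
  draws outside [0, 1] are resampled and counted.
* **ROIs**: four symbioses with planted rates {186, 747, 747, 2552}
  fmol N symb⁻¹ d⁻¹ (mean exactly 1058, spanning the observed range) and
  growth 0.5 d⁻¹. Symbiont cells are pinned at 40% of the source ¹⁵N
  excess — emulating rapid transfer of fixed N to the host — and the host
  receives the remainder; host geometry is scaled so its planted rate sits
  at 50% of source excess, so more active symbioses have larger hosts
  (morphologically distinct large hosts do occur). Ion counts are Poisson
  draws splitting a per-ROI budget (default 10⁶) between isotopologues.
  Planted rates whose implied enrichment would reach the source labelling
  are rejected.
* **Amplicons**: clade seed sequences are homologous variants of one
  ancestor kept ≥ between-divergence apart by rejection sampling (real
  marker-gene clades share most of their sequence; independent random
  draws would be ~75% divergent). Members carry exactly
  round(within/2 × L) substitutions, bounding the within-clade pairwise
  divergence at the configured value — so with within < 1 − θ < between,
  planted-clade recovery is guaranteed by construction rather than merely
  probable. Counts are Dirichlet-multinomial per sample; the first half of
  the clades form a planted "Marine 1"-like group holding 92% of the base
  weight. One dataset-wide singleton ASV is planted as filter fodder.
* **Microscopy counts** are deterministic (count = abundance × volume,
  with the planted abundance defined as count/volume exactly): the study's
  19–31 ml equivalent volumes mean only 3–4 cells per piece, and a Poisson
  draw at that expectation would dominate the end-to-end error budget.
  This idealisation means the generator does **not** exercise counting
  statistics; real surveys carry ±50%-scale Poisson uncertainty on such
  counts, and passing end-to-end tests say nothing about that term.

What passing tests show: unbiased rate recovery under Gaussian/Poisson
measurement noise, exact clade recovery under the planted divergence
structure, and end-to-end consistency of the scaling arithmetic. What they
do not show: robustness to bottle effects or replicate-level outliers,
count sampling error, chimeric/indel-rich amplicons, or uncertainty in the
quota model.

## Pipeline

Station + depth is the universal join key, with depths matched within a
tolerance (default ±5 m, the deviation that conventionally triggers
profile interpolation). Counts without a matching rate keep their
abundance and contribution, get NaN bulk fields and a `rate_missing` flag,
and do not fail the run. The manifest records the config snapshot, input
and output SHA-256 digests and per-stage row counts; deterministic stages
reproduce digests exactly under identical inputs.

## Numerical notes and limitations

* The alignment DP packs (score, matches, −columns) into int64 with bases
  2⁴⁰/2¹⁸, safe for sequences to ~50 kb; amplicons are ~325 nt.
* `ratio → fraction → ratio` round-trips to ≤10⁻¹² relative error
  throughout the tracer-relevant range (ratios ≪ 1); for ratios of order
  10⁶ the achievable error grows as (1+R)·ulp because the fraction
  saturates toward 1.
* Problem sizes in the tests (1000 simulated triplicates, ion budgets
  10⁴–10⁶, 12-sample × ~20-ASV amplicon sets, a 3-station mock cruise)
  were chosen to estimate each recovery statistic with comfortable margin
  while keeping the default suite fast.
* The MQR formula is a standard k·σ propagation, stated as this package's
  detection convention; campaign-specific limit-of-detection workups may
  differ.
* Rounding of printed contributions is half-away-from-zero; banker's
  rounding would print 0.135 as 0.13 rather than 0.14 and disagree with
  conventional table formatting.
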