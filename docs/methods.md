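# Methods

This note records the models, parameter choices and numerical conventions
behind `mitophos`, and what the synthetic-data validation does and does not
establish about real data.

## Phosphoproteomics arm

### Preprocessing

Intensities are log2-transformed and median-centred per sample. Missing
values are imputed per sample from a down-shifted Gaussian with mean
`sample_mean − 1.8·sample_sd` and width `0.3·sample_sd`, computed on the
observed log2-centred values, with one seeded draw per missing cell. These
shift/width factors are the de-facto standard for label-free proteomics
imputation, reflecting that missing LFQ peptides are predominantly
low-abundance; both are keyword arguments of `preprocess`. Normalisation
is deliberately minimal (median centring): more aggressive schemes
(quantile, LOESS) alter fold changes and are out of scope.

A consequence worth stating plainly: down-shifted imputation inflates
within-group variance for sites with missing observations, which makes the
Welch test *conservative* on those sites. The calibration and recovery
properties below are therefore characterised on complete matrices, which
isolates the behaviour of the testing machinery itself; the imputation's
own contract (draws fall below the per-sample observed median in ≥95% of
cases) is tested separately. On data with 10% missingness, end-to-end
sensitivity at |log2FC| = 2 drops from ≈0.99 to ≈0.4–0.5 — users comparing
groups with substantial missingness should expect this and consider
filtering sites by observation count.

### Testing and significance calling

Per site, a two-tailed Welch t-test (unequal variances,
Welch–Satterthwaite degrees of freedom) compares treatment against the
control group; the degenerate all-equal case returns p = 1 by convention.
Benjamini–Hochberg adjustment is applied across sites and the BH rule
(p_adj < 0.05) is the primary caller. When BH yields zero hits, the raw
p-value distribution is inspected for anti-conservativeness. The visual
histogram inspection common in practice is codified deterministically:
the distribution is anti-conservative when the fraction of p < 0.05
exceeds 1.5 × 0.05. Only then does the fallback rule fire: raw p < 0.05
combined with |log2FC| > log2(1.5), two-sided, since cohorts contain both
up- and down-regulated sites. The `procedure` column records which rule
produced the calls. With fewer than 50 p-values the histogram is
uninformative and the caller stays with BH.

### Cumulative phosphorylation state (ΔPs)

Per protein, ΔPs is the sum of log2 fold changes over the protein's sites
with raw p < 0.05 (not BH-adjusted — the score aggregates site-level
evidence, and its own 2σ cutoff provides the stringency); a protein with
no such site scores exactly 0. σ is the population (n-denominator)
standard deviation of ΔPs over **all** proteins including the zeros; this
is the conservative reading, since excluding zeros shrinks the cohort and
inflates classification. `delta_ps(..., sigma_over="nonzero")` provides
the alternative. Classification is strict: hyper iff ΔPs > 2σ, hypo iff
ΔPs < −2σ.

### Z-scores and clustering

Site profiles are z-scored with the population (n) standard deviation;
rows of identical values map to zero vectors with a warning (flatness is
detected by range, not by the computed sd, which can be a tiny nonzero
number for constant rows due to the inexact mean). Clustering is
agglomerative with Euclidean distance and Ward linkage, cut to k flat
clusters; with a design, per-cluster per-group mean z summarises
coordinate modulation. Group comparison of a cluster's per-sample mean z
uses Kruskal–Wallis with Dunn's post-hoc z-tests (tie-corrected pooled-rank
variance, BH-adjusted) — routine statistics exposed as a convenience
wrapper.

## Synthetic phosphoproteomics generator

Site base levels are drawn N(25, 2) on the log2 scale (typical LFQ
magnitude); observation noise is Gaussian on the log2 scale with sd
`sqrt(ln(1+cv²))/ln 2`, the exact log-normal equivalent of a
multiplicative coefficient of variation. Effects of magnitude
`effect_log2fc` with random sign are planted on `effect_fraction` of
sites in all non-control groups. Defaults (100 proteins, 1–4 peptides
per protein, 2 groups × 4 replicates, effect fraction 0.1, |log2FC| 2,
cv 0.2, 10% missingness half-MNAR) emulate a small two-condition liver
phosphoproteome comparison.

Missingness is a calibrated mixture with *exact* counts: of
`round(missing_rate · n_cells)` missing cells, a `mnar_weight` share is
sampled without replacement with probability decreasing logistically in
log2 intensity (centred 1.5 sd below the global mean, scale 0.5 sd), the
remainder uniformly. The realised rate therefore matches the requested
rate to rounding, and MNAR cells concentrate at low intensities. The
true missingness mechanism of real instruments is uncharacterised; this
mixture is an explicit, parameterised assumption.

What the generator does **not** emulate: peptide-level correlation within
a protein beyond the shared planted effect, batch structure, retention-time
drift, phosphosite localisation ambiguity, or intensity-dependent variance.
Passing tests show the analysis machinery is correct and calibrated under
the stated model, not that it is robust to these real-data features.

## Imaging arm

### Morphology

Denoising is a Gaussian filter (default σ = 1 px, reflective boundary).
Auto-thresholding offers Otsu (default) and IsoData (the ImageJ default);
the chosen threshold is logged. Particles are 8-connected components
(the analyze-particles convention), counted in a calibrated ROI — 35 μm²
is the live-imaging default, 71.2 μm² the EM convention — using a
centroid rule (a particle belongs to the ROI iff its centroid lies
inside), which avoids double counting across tiled ROIs. Particles below
0.05 μm² are treated as noise specks.

Perimeter uses the 4-direction Crofton estimator. Circularity is
estimator-sensitive and no digital perimeter reproduces analytic values
on rasters exactly: Crofton slightly *overestimates* disk circularity
(values marginally above 1 are clipped to 1, mirroring ImageJ) and a
rasterised square does not measure exactly π/4. The analytic identities
(square π/4, elongation = 1/circularity) are exposed and tested through
the pure `circularity(area, perimeter)`/`elongation` functions; rasterised
disks of radius ≥ 10 px measure within [0.95, 1.0].

### Dynamics

Tracking is greedy bipartite matching on mask-overlap IoU (default
threshold 0.3) with deterministic tie-breaking (IoU descending, then label
ascending). The event rules operate on dominant-overlap assignments:
a fission is a particle at frame t that is the dominant parent of ≥2
particles at t+1; a fusion is the mirror image; an event's time is the
frame where the new configuration first appears, times the frame
interval. Three guards suppress artefacts: events involving particles
within 2 px of the field border are discarded (objects entering/leaving
the field masquerade as events), an event undone within one frame
(merge–split flicker) is debounced, and a minimum child overlap of 1 px
is required. Rates are `n_events / (n_cells · observation_time)` in
events·cell⁻¹·s⁻¹.

Interactions: a contact exists when the binary marker mask overlaps a
mitochondrion's mask by ≥1 px; contiguous contact frames form one
interaction of duration `(end − start + 1) · frame_interval`. The fate is
useful iff that mitochondrion undergoes fission between contact start and
`fate_window` frames (default 2) after contact end — a window consistent
with fission following contact on the ~1–2 frame timescale at a 13 s
cadence — otherwise futile.

### Synthetic time-lapse generator

Mitochondria are 2D capsules (rectangle plus semicircular caps; rod 20 px,
radius 3 px at 0.1 μm/px), the simplest geometry with closed-form area
`L·2r + πr²` used by the area-recovery checks. Defaults follow
single-channel confocal practice: one frame per 13 s over 10 min (27 s
suits dual-channel acquisition), with PSF blur σ = 1 px, Gaussian read
noise, and a small random walk (σ = 0.3 px/frame) clamped so objects stay
clear of the border. Scripted fission splits a capsule at its midpoint
into two daughters separated by a 2 px gap; fusion replaces a pair with
one capsule spanning both (so the product overlaps both parents, which the
overlap-based detector requires — callers should fuse neighbouring
objects, as a product spanning distant parents can cross third objects).
Noiseless label masks are the ground truth; detection on those masks is
exact, while detection on blurred/thresholded frames can miss a fresh
2 px fission gap until drift separates the daughters — the same resolution
limit real confocal data has.

### Contacts and co-localization

Distances are measured edge-to-edge: the Euclidean distance transform of
the ER complement is sampled over each mitochondrion's pixels and one
pixel is subtracted, so touching pixels have gap 0; pixel gaps convert to
nm by the pixel size without sub-pixel interpolation, hence sampling at
≤5 nm/px is required for the 10–30 nm band to be resolvable (the
generator defaults to 2.5 nm/px). A mitochondrion is contacted iff its
minimum gap lies in the inclusive band; each mitochondrion counts once
regardless of how many appositions it has (the percentage is normalised
to the number of mitochondria). Sub-10 nm gaps are excluded by default to
honour the strict band; `include_closer=True` counts them, since sub-10 nm
appositions are biologically contacts. A brute-force all-pairs distance
oracle validates the transform route exactly on small images.
Co-localization is `100 · |marker ∩ reference| / |marker|` on binary
masks (Manders-style).

## Pipelines, determinism, problem sizes

Both pipeline arms echo every parameter into their JSON report, and all
randomness flows through `numpy.random.Generator` instances seeded from
the run seed — identical seeds give byte-identical tables, stacks and
reports. The validation suites use 20-replicate Monte-Carlo designs at
~250–1,100 sites per run and 192–256 px fields over 10 simulated minutes;
these sizes put Monte-Carlo error well below the asserted margins while
keeping the whole suite fast.

## Known limitations

- Single-plane 2D only: no 3D morphology, no sub-pixel tracking, no
  linear-assignment/Kalman trackers.
- The anti-conservativeness detector is a fixed-threshold surrogate for
  histogram inspection; at the 1.5× factor it is insensitive to weak
  enrichment just above the uniform level.
- ΔPs classification depends on the σ convention (all proteins vs nonzero
  only); both are implemented, and cohort composition shifts the 2σ line.
- The contact band rule inherits pixel quantisation: at p nm/px, measured
  gaps are multiples of ~p nm, so band-edge distances can flip at coarse
  sampling.
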