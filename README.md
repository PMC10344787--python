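# mitophos

Quantitative analysis of phosphoproteomics and mitochondrial-dynamics
imaging, built for studies of how signalling (e.g. mTOR-pathway kinases)
reshapes the mitochondrial network. The package provides two analysis arms
plus synthetic-data generators with exact ground truth, so every stage can
be validated without external downloads.

**Phosphoproteomics arm.** Label-free phosphopeptide intensity tables
(site × sample, with a group design) are log2-transformed, median-centred
per sample, and missing values imputed from a per-sample down-shifted
Gaussian. Each site is tested against the control group with a two-tailed
Welch (heteroscedastic) t-test. Significance calling applies
Benjamini–Hochberg FDR at 0.05 first; when BH returns no hits but the raw
p-value histogram is anti-conservative (excess mass below 0.05), a fallback
rule is applied instead: raw p < 0.05 combined with fold change > 1.5.
Per protein, the cumulative phosphorylation-state change is

```
ΔPs = Σ log2(FC_i)  over the protein's sites with p_i < 0.05
```

(exactly 0 when no site passes), and proteins with |ΔPs| beyond twice the
population standard deviation of the cohort's ΔPs distribution are classed
hyper-/hypo-phosphorylated. Z-scoring, Ward hierarchical clustering and a
Kruskal–Wallis + Dunn group comparison of cluster profiles round out the arm.

**Imaging arm.** Time-lapse stacks are denoised (Gaussian), auto-thresholded
(Otsu or IsoData), and quantified per region of interest with the classic
analyze-particles descriptors: area, perimeter (Crofton), circularity
`C = 4πA/P²` and elongation `E = 1/C`. Particles are tracked across frames
by mask-overlap IoU; a fission is one particle splitting into two, a fusion
the reverse, and rates are reported in events·cell⁻¹·s⁻¹. Marker–mitochondrion
contacts are timed and classed useful (followed by fission of the contacted
mitochondrion within a window) or futile. ER–mitochondria contacts follow the
EM convention — a mitochondrion counts as contacted when its minimum
edge-to-edge gap to the ER lies in the inclusive 10–30 nm band — and
co-localization is the Manders-style overlap percentage of binary masks.

## Worked example

`examples/phospho_differential.py` simulates 100 proteins (1–4 phosphopeptides
each, 4 replicates per group, |log2FC| = 2 planted on 10% of sites, 10%
missingness) and runs the full arm:

```
simulated 258 phosphosites, 10.0% missing
11/258 sites significant (4.26%) via BH
planted-site sensitivity 0.38, false discoveries 1
without missing values: sensitivity 0.96
delta-Ps classification at 2*sigma = 1.64: 8 hyperphosphorylated, 5 hypophosphorylated proteins
```

The two sensitivity lines show a real property of down-shifted imputation:
imputed values inflate within-group variance, so sites with missing
observations test conservatively; on complete data the Welch + BH pipeline
recovers 96% of planted effects. The last line counts proteins whose summed
significant fold changes exceed ±2σ of the cohort ΔPs distribution.

`examples/timelapse_dynamics.py` scripts two fissions and one fusion into a
13 s/frame, 10 min capsule time-lapse and recovers them:

```
47 frames at 13 s/frame, 5 -> 6 particles
  fission at t=130 s: [1] -> [6, 7]
  fission at t=312 s: [2] -> [8, 9]
  fusion at t=455 s: [4, 5] -> [10]
fission rate 0.00334 events/cell/s, fusion rate 0.00167 events/cell/s
```

`examples/morphology.py` and `examples/er_contacts_coloc.py` demonstrate the
shape descriptors and the contact/co-localization rules (four mitochondria at
5/15/25/40 nm gaps → 50% contacted under the strict band, 75% when sub-10 nm
appositions are included).

A thin CLI mirrors the library:
`mitophos simulate phospho|timelapse|contacts`, `mitophos phospho run`,
`mitophos morph`, `mitophos dynamics`, `mitophos contacts`, `mitophos coloc`,
`mitophos pipeline`.

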