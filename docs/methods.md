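# Methods

`junctomech` re-implements, as a tested library, the quantitative analyses
used to characterise how the junctional adaptors cingulin (CGN) and
paracingulin (CGNL1) tether nonmuscle myosin-2 (NM2) isoforms to epithelial
tight and adherens junctions: coiled-coil assembly-mode prediction,
AFM contact-mechanics fitting, binding-isotherm K_d estimation, and
junction morphometrics. Raw microscopy and AFM data are replaced by seeded
synthetic generators that reproduce the statistical structure each stage
assumes, so every analysis can be validated by parameter recovery.

## Coiled-coil assembly scan (`coilscan`)

**Model.** Two rod domains are represented as 1-D lattices: each residue of
the declared coiled-coil span occupies one axial unit (supercoil pitch is
ignored, so staggers are expressed in residues). Chain A residue *i* sits at
axial coordinate *i−1*; in the parallel orientation chain B residue *j* sits
at *(j−1)+s* for stagger *s* (the stagger separates the two N-termini); in
the antiparallel orientation B residue *j* sits at *s+(L_B−j)*, i.e. B's
C-terminus sits *s* axial units from A's N-terminus and B runs C→N.

An **apolar interaction** is a pair of apolar residues, one per chain,
within ±1 residue axially; an **ionic interaction** is an oppositely charged
pair (D/E vs R/K) within ±2 residues. Each qualifying (i, j) pair counts
once, regardless of how many window offsets it satisfies — the definition
describes a pair state, not a per-offset tally. Histidine is treated as
neutral. The apolar set defaults to {A, F, I, L, M, V, W, Y}, the standard
hydrophobic alphabet of coiled-coil core analyses; it is configurable
because different traditions include or exclude A and Y.

**Score.** For every stagger with nonzero overlap and both orientations, the
total interaction count is normalised by the overlap length in residues,
making the score a per-residue interaction density; the published
significance cutoff of 0.23 and minimum overlap of 32 residues are the
defaults. Implementation: pair counts over all staggers at once are
cross-correlations (parallel) or convolutions (antiparallel) of per-chain
class-indicator arrays, followed by a moving sum over the axial window; an
exhaustive double-loop enumeration over residue pairs serves as the
independent oracle in the tests.

**Peaks.** Candidate assembly modes are strict local maxima of the score
profile after a centred moving average (window 3; window 1 disables
smoothing), localised at the raw-score maximum inside the smoothing window
— the average finds the peak, the raw profile places it. Modes with raw
score ≥ cutoff and overlap ≥ minimum are significant, others NS; an
orientation with no admissible peak is ND. Overlap labels encode which ends
of the chains share the overlap (CC50 = C-terminal 50 residues of both;
CN46 = C-terminus of A over an N-terminal region of B; FULL = one chain
contained in the other's span).

**Species combination.** How per-species calculations were "combined" is
not specified anywhere we could find, so the package matches peaks of the
same orientation across species within a ±5 residue stagger tolerance and
reports the arithmetic mean of stagger and score; a combined mode is
significant only if significant in every species, and single-species peaks
are returned flagged rather than dropped.

**FFT periodicity.** The periodogram of a mean-subtracted per-residue
property profile; the dominant period is the reciprocal of the nonzero
frequency with maximal power (a perfect heptad apolar indicator yields
3.5 residues/cycle). Constant profiles are flagged rather than fitted.

## Contact mechanics and binding (`mechanofit`)

**Hertz model.** F = 4·E·√r·x^{3/2} / (3(1−ν²)) for a spherical probe:
indentation x in µm, probe radius r (default 5 µm), Poisson ratio ν
(default 0.5, incompressible cell), force in nN, Young's modulus E in MPa;
the prefactor is evaluated in SI internally. Inputs are declared as
tip-sample separation; a helper converts piezo travel plus deflection, but
that conversion is the caller's responsibility.

**Preprocessing.** The pre-contact baseline is the mean force over the flat
approach segment; contact is first detected where the force exceeds the
baseline by 3 pre-contact noise SDs for 5 consecutive samples (the
persistence requirement guards against noise excursions when the SD is
estimated from few samples), then refined as the abscissa intercept of a
linear regression of F^{2/3} over the early post-contact rise — the
threshold crossing alone is biased late because the Hertz force grows only
as x^{3/2}. On noise-free curves both baseline and contact are recovered
exactly; at 0.02 nN noise the contact lands within 2 samples of truth.

**Fitting.** Nonlinear least squares of the Hertz form over samples in the
0.5–4.5 nN contact-force window, with E and a small contact-point
refinement free (the refinement can be disabled; whether the original
analysis refined or fixed the contact is not stated, and freeing it is the
safer default given threshold-estimation bias). Fewer than 10 in-window
samples is an error, not a silent fit.

**Group statistics.** Per-condition mean ± SD tables with Kruskal–Wallis
and Dunn's pairwise post-hoc comparisons. Dunn's test is implemented
directly from the pooled rank statistics (z on mean-rank differences with
tie correction, Bonferroni adjustment) because no installed package
provides it; Kruskal–Wallis and Mann–Whitney come from scipy.

**Binding isotherms.** The exact 1:1 quadratic solution
f = ((T+L+K_d) − √((T+L+K_d)² − 4TL)) / 2T is the default because the
titrations of interest use target concentrations (50–200 nM) that are not
negligible against the fitted K_d values; the hyperbolic form L/(K_d+L) is
selectable and the two agree to <1% when T < K_d/100. Fits free K_d,
response scale and baseline; a fitted K_d beyond the largest ligand
concentration is flagged as poorly constrained. In the depletion regime
(K_d ≪ target, e.g. 7.7 nM vs 50 nM) the per-series estimator reaches the
Cramér–Rao bound (SD ≈ 1.0 nM at 2% response noise on a 16-point grid), so
the scatter seen across replicate titrations is information-limited, not an
optimiser artefact.

**Solubility.** Percent soluble = 100·S/(S+P) from supernatant and pellet
band densitometry; scale-invariant by construction.

## Morphometrics (`morphometry`)

Inputs are digitised geometry and intensity tables in physical units —
tracing, segmentation and spot detection are upstream, as they were manual
ImageJ/ICY operations in the original workflow.

- **Zigzag index**: polyline arc length divided by the endpoint chord;
  1 for a straight junction, invariant under rigid motion and scaling.
  Coincident endpoints are an error (undefined ratio).
- **Relative fluorescence intensity**: (signal − background)/(reference −
  background), with one image-level background subtracted from both terms;
  correcting both keeps the ratio invariant under intensity rescaling.
  Negative numerators are clipped to zero and flagged.
- **Linescan peak distances**: per-channel single-Gaussian least squares
  (amplitude, mean, width, offset) over the ~1 µm scan; the channel's
  distance is the absolute difference of its fitted mean from the midline
  channel's. Initialisation uses the empirical maximum and a half-width at
  half-maximum estimate (a second-moment start is corrupted by noise in the
  tails), with bounds keeping the mean inside the scan. Channels flanking
  the junction on both sides can be fitted with a two-Gaussian model that
  reports the mean absolute offset of the two peaks — whether the original
  distances used signed or absolute offsets is not stated; absolute was
  chosen and noted. Flat channels, edge peaks and non-convergent fits carry
  per-channel failure flags.
- **Puncta metrics**: density as count per 10 µm of junction; punctum
  length end−start; gap edge-to-edge; inter-puncta distance
  centre-to-centre (= length + gap for a periodic train). A thresholding
  helper (Otsu default) extracts trains from 1-D intensity profiles for
  synthetic tests.
- **PLA counts**: whole-cell ROI minus cytoplasmic ROI; negative results
  are reported as-is with a quality flag.
- **Filament dimensions**: mean ± SD summaries with a two-sided
  Mann–Whitney comparison per dimension for two groups; a zero-variance
  rank statistic (all values tied) maps to p = 1, matching exact
  enumeration.

## Synthetic data (`synthdata`)

Every generator is a pure function of (seed, parameters) — same call,
bit-identical data — and emits a `GroundTruth` record of all planted
quantities. Noise is additive Gaussian throughout, since the study reports
only means ± SD. Defaults are the study conditions:

| generator | planted defaults |
|---|---|
| `gen_coiled_coil_pair` | 150+150 residues, antiparallel, stagger 100 (C-terminal 50-residue overlap), density 0.5 |
| `gen_afm_curves` | E = 0.0037 MPa (wild-type apical stiffness), r = 5 µm, ν = 0.5, max force 5 nN, noise SD 0.1 nN, baseline 0.2 nN, 0.3 µm pre-contact |
| `gen_linescans` | offsets 64.6 nm (CGN) and 117.13 nm (NM2B) from the ZO-1 midline, FWHM 80 nm, noise 5% of amplitude, 1 µm scan |
| `gen_puncta_trains` | 20 µm junctions, punctum 0.27 µm, gap 0.66 µm, edge jitter SD 0.05 µm |
| `gen_binding_series` | K_d 346 nM, target 200 nM, ligand 0–10,000 nM (two-fold dilutions), 2% response noise; a positive ligand minimum switches to geometric spacing |

The coiled-coil generator lays down a heptad background (apolar a/d core,
neutral elsewhere, no charges) and plants interacting pairs — acidic↔basic
or apolar↔apolar — at axially matched positions of the planted stagger,
with partners at the *boundary* of their interaction window (±2 ionic, ±1
apolar). Boundary placement is what makes the planted peak strict and
sharp: every planted pair counts at the planted stagger, but half fall out
of the window one stagger away, whereas in-register placement would
produce a plateau as wide as the window. With the antiparallel default the
scan recovers the planted stagger in ≈98 of 100 seeded replicates.
Recovery is weaker for parallel plantings (≈70%): two in-register parallel
heptad lattices are far more self-similar under axial shifts, so the
background score profile carries higher, more correlated fluctuations —
an inherent property of parallel assembly maps, not of the scanner.

What the generators do **not** emulate: real rod sequences (no charge
periodicity of genuine myosin rods, no sequence homology), AFM curve
artefacts other than baseline/contact offsets (no drift, adhesion, or
viscoelastic hysteresis), optical blurring beyond a Gaussian peak shape,
and spatially correlated noise. Passing recovery tests therefore
demonstrates correctness and calibration of the estimators under the
stated noise model, not robustness to every artefact of real data.

## Pipeline (`workbench`)

A run configuration (JSON/YAML) lists stages with parameter blocks,
validated against per-stage schemas before anything executes — an unknown
stage or parameter aborts with no partial outputs. Each stage gets a
deterministic seed substream derived from the run seed. The bundle contains
the per-stage tables (TSV), ground-truth JSONs, a `summary.json` carrying
provenance (config hash, seed, package version) and per-stage numeric
results, and a `run.log` with wall times. `summary.json` is byte-identical
across reruns of the same configuration and seed; timing lives only in the
log. ND/NS strings are rendered literally in mode tables so that published
table layouts round-trip through parsing.

## Problem sizes and tolerances

The test suite and the acceptance script use the study's own sample sizes
(200 force curves, 25 linescans, 100 puncta trains, 5–7 titrations,
100 coiled-coil replicates); the whole suite runs in well under a minute.
Noise-free inputs must invert essentially exactly (4–6 significant
digits); noisy recoveries are required within 2–10% depending on the
stage's information content. Degenerate inputs (zero overlap, flat
channels, non-contacting curves, zero-chord traces, empty trains) raise
typed errors or carry flags rather than returning silently wrong numbers.

## Known limitations

- The published assembly-score table cannot be reproduced end-to-end
  without the canonical human and dog rod sequences and their coiled-coil
  boundaries, which are not printed with the result; the corresponding
  check fails explicitly until those sequences are supplied (see
  `tests/test_acceptance.py`). The published staggers imply an effective
  cingulin coiled-coil length of ≈471 residues, and the package reproduces
  the printed overlap geometry (CC50, CN46) exactly from interval
  arithmetic at those lengths.
- The normalisation divisor (overlap length) and apolar set reproduce the
  published score magnitudes (0.23–0.27 for heptad-dense rods) but are not
  uniquely determined by the published description.
- The MST vendor normalisation from raw fluorescence to fraction bound is
  proprietary; inputs are assumed already normalised (or fitted with free
  scale/baseline).
- No viscoelastic or substrate corrections in the AFM fit; curves are
  assumed quasi-static spherical indentation of a half-space.
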