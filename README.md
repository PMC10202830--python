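# junctomech

Quantitative analyses of epithelial junction mechanobiology, packaged as a
tested Python library with a CLI. The scientific setting: the cytoplasmic
junctional adaptors **cingulin (CGN)** and **paracingulin (CGNL1)** tether
**nonmuscle myosin-2 (NM2A/B/C)** isoforms to tight and adherens junctions
through coiled-coil interactions of their rod domains, and this coupling
shapes junction architecture and apical membrane mechanics. The package
implements the four analysis families such a study rests on, for anyone who
needs them reusable and testable:

1. **Coiled-coil assembly scan** (`junctomech.coilscan`) — slide one rod
   past another in both orientations and count potential inter-chain
   interactions as a function of axial stagger *s*:
   apolar pairs within ±1 residue axially, oppositely charged pairs
   (D/E ↔ R/K) within ±2. The normalised score is

   `score(s, orientation) = (n_apolar + n_ionic) / overlap_length`,

   with peaks over staggers as candidate assembly modes (cutoff 0.23,
   minimum overlap 32 residues), overlap labels such as CC50 (C-terminal
   50 residues of both chains), species combination and an FFT sequence
   periodogram.
2. **Contact mechanics & binding** (`junctomech.mechanofit`) — spherical
   Hertz fits of AFM force-indentation curves,
   `F = 4E√r·x^{3/2} / 3(1−ν²)` (E in MPa, r = 5 µm, ν = 0.5, fit window
   0.5–4.5 nN), with baseline correction and contact-point estimation;
   exact 1:1 binding isotherm
   `f = ((T+L+K_d) − √((T+L+K_d)² − 4TL)) / 2T` for MST-style titrations;
   soluble-fraction arithmetic for pelleting assays; Kruskal–Wallis/Dunn
   and Mann–Whitney group comparisons.
3. **Junction morphometrics** (`junctomech.morphometry`) — zigzag index
   (arc length / chord of a traced junction), relative fluorescence
   intensity, Gaussian linescan peak distances from a midline marker,
   puncta density and spacing along junctions, PLA ROI arithmetic,
   filament dimension summaries.
4. **Synthetic data** (`junctomech.synthdata`) — seeded, bit-reproducible
   generators for every input type, with planted ground truth at the
   study's published parameter values (wild-type stiffness 0.0037 MPa;
   linescan offsets 64.6/117.13 nm; punctum/gap 0.27/0.66 µm; K_d 346 and
   7.7 nM), so the full pipeline is testable by parameter recovery without
   any raw data.

`junctomech.workbench` chains generators and analyses into deterministic,
provenance-stamped report bundles.

## Worked example

Generate a synthetic coiled-coil pair with an interaction-rich stagger
planted at 100 residues (antiparallel, C-terminal 50-residue overlap), then
scan it:

```sh
$ junctomech simulate coiled_coil_pair --seed 0 --out demo/
$ junctomech coil-scan --fasta demo/rods.fa --manifest demo/rods.json --out demo/modes.tsv
synthA-synthB: top mode antiparallel stagger 100 score 0.8800 [significant]
$ cat demo/modes.tsv
pair	par_stagger	par_score	par_overlap	anti_stagger	anti_score	anti_overlap
synthA-synthB	-112	0.4474	NC38	100	0.8800	CC50
```

The scanner recovers the planted antiparallel stagger (100) exactly; the
label `CC50` says the two chains overlap by their C-terminal 50 residues,
and the score 0.88 is the per-residue density of potential interactions in
that overlap — far above the 0.23 significance cutoff, as expected for a
planted signal (the weaker parallel peak is lattice background).

The same pattern works for the other stages, e.g. AFM curves at the
wild-type stiffness:

```sh
$ junctomech simulate afm_curves --seed 5 --out sim/
$ junctomech afm-fit --curves sim/force_curves.csv --out stiffness.tsv
3 curves, mean Young's modulus 0.00368 MPa
```

The fitted mean (0.00368 MPa) recovers the generator's planted Young's
modulus of 0.0037 MPa to within the force-noise-limited precision.

## Layout

```
src/junctomech/
  coilscan.py     axial-stagger interaction scanning, assembly modes, FFT
  mechanofit.py   Hertz fits, binding isotherms, solubility, group stats
  morphometry.py  zigzag, RFI, linescans, puncta, PLA, filament summaries
  synthdata.py    seeded generators with ground truth
  io.py           FASTA+manifest and CSV/TSV readers/writers
  workbench.py    validated pipeline runs, mode-table rendering
  cli.py          `junctomech` command group
docs/methods.md   models, assumptions, design choices, limitations
tests/            unit, property and acceptance suites
```
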