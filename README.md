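# locsig

Quantitative analysis of bent stem-loop mRNA localization signals.

Many developmentally important mRNAs are trafficked along microtubules
after an adaptor protein recognizes a *localization signal* in the
transcript. For the *Drosophila* Egalitarian–Bicaudal D (Egl–BicD)
pathway these signals have no conserved primary sequence; recognition
instead combines **shape** (two A-form helices of ≥ 6 bp bent by ~19–26°
at a 3′-strand bulge), **positional sequence features** (a preference
for U–A base pairs at two minor-groove sites, ED1 and ED2, separated by
8 bp) and **element count** (transport activates only when two stem
loops of the same transcript occupy both RNA-binding pockets of the
protein dimer). `locsig` packages the analyses needed to work with this
recognition code, each testable against synthetic ground truth:

* **`secstruct`** — pair tables from dot-bracket, stem-loop annotation
  (lower helix / bulged internal segment / upper helix / terminal
  loop), bulge-deletion (Δb) construct generation, and a Nussinov
  base-pair-maximization fallback folder.
* **`scanner`** — ED-site assignment on a stem-loop stack, ordinal
  base-pair preference scoring (U–A > C–G > A–U > G–C; C–U tolerated at
  ED1 only), tiering into primary / support / reject, and the
  dual-element coincidence verdict per transcript.
* **`geom3d`** — geometric base-pair detection from PDB/mmCIF
  coordinates, C1′-midpoint helical trajectories, SVD best-fit axes,
  the inter-helix bend angle θ = arccos(d̂₁·d̂₂), and Kabsch RMSD
  superposition.
* **`coloc`** — the dual-colour single-molecule occupancy model: with a
  50:50 Cy3/Cy5 mix, a fraction *f*₂ of two-copy complexes yields a
  dual-colour fraction *f*₂/2, so the maximum-likelihood estimate from
  observed counts is f̂₂ = 2·n_dual/n_total (bootstrap CIs; general
  dye/detection parameters supported).
* **`locquant`** — the embryo-injection localization-efficiency metric:
  background-corrected mean intensity of four 7.391 µm² apical ROIs
  over their vertically translated basal counterparts.
* **`synth`** — seeded generators for kinked pseudo-atomic A-form
  hairpins with programmed bend, transcripts with implanted signal
  elements, simulated dual-colour event counts, and embryo-like images
  with a known apical:basal ratio.

See `docs/methods.md` for the model definitions, parameter defaults and
limitations.

## Worked example

Score a 44-nt stem loop against the recognition rules:

```python
from locsig import scanner, secstruct, synth
from locsig.io import RnaSequence

seq_str, dotbracket = synth.tls_like_element()   # synthetic reference signal
seq = RnaSequence("signal", seq_str)
pairs = secstruct.build_pair_table(seq, dotbracket)
ann = secstruct.annotate_stemloop(pairs, sequence=seq)
sites = scanner.assign_ed_sites(ann)
cand = scanner.score_candidate(ann, sites)
print(sites.ed1_pair, sites.ed2_pair, sites.spacing_bp, cand.tier)
```

prints

```
(6, 39) (15, 28) 8 primary
```

— the ED1 site is the U6–A39 pair, the ED2 site U15–A28, the two sites
are separated by 8 base pairs along the 5′ strand (the 3′-strand bulges
at positions 33 and 36 do not interrupt the count), and the hairpin
passes every primary-signal rule.

Measure a bend from coordinates (here a synthetic kinked helix written
to PDB with a programmed 22° bend and 0.15 Å coordinate noise):

```sh
locsig simulate helix --kink 22 --noise 0.15 --seed 11 --out helix22.pdb
locsig bend --structure helix22.pdb --out bend22.json
```

```
bend angle: 22.66 degrees -> bend22.json
```

The JSON output contains the two fitted axes (centroid, direction, rms
residual), the trajectory ranges used and a run manifest.

Estimate RNA copy number per motile complex from dual-colour counts.
With 1,000 visible complexes of which 440 showed both dyes (a 44% dual
fraction, as observed for isolated stem loops):

```python
from locsig import coloc

counts = coloc.ColocCounts(n_cy3_only=280, n_cy5_only=280, n_dual=440)
est = coloc.estimate_two_copy_fraction(counts, seed=1)
print(f"f_hat {est.f_hat:.3f}  CI [{est.ci_low:.3f}, {est.ci_high:.3f}]")
```

```
f_hat 0.880  CI [0.820, 0.942]
```

i.e. an 88% two-copy fraction — the vast majority of motile complexes
carry two RNA molecules.

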