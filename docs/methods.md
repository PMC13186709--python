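# Methods

`locsig` implements the quantitative analyses surrounding recognition of
mRNA localization signals by the Egalitarian–Bicaudal D (Egl–BicD)
adaptor of the *Drosophila* dynein transport machinery. Four analyses
share one theme — localizing mRNAs are selected by a combination of
shape (a bent stem loop), positional sequence features (base-pair
identities at two minor-groove sites) and element count (two stem loops
per transcript) — and each is backed by a synthetic-data generator that
provides ground truth.

## Stem-loop model and annotation (`secstruct`)

A localization signal is modelled as a simple hairpin partitioned into a
lower helix, an internal segment (optionally a short helix, plus
unpaired bulges labelled by strand), an upper helix and a terminal loop.
Helices are maximal runs of stacked pairs in which both strands advance
by exactly one position per step. Noncanonical pairs (anything other
than Watson–Crick or G–U) count as stack members, because in the
empirical structures bulge- or loop-predicted nucleotides are often
integrated into the duplex through stacking and noncanonical pairing;
they are flagged in the output so a caller can apply a stricter helix
definition if desired. A bulge-free hairpin is annotated with the full
stack as the lower helix and an empty upper helix: the upper/lower
distinction only has meaning relative to an internal segment. Pseudoknots
are rejected.

`delete_bulges` mirrors the construction of bulge-deletion (Δb) mutants:
the nucleotides removed are those annotated as bulges from an
experimentally determined architecture rather than from a secondary-
structure prediction, and the flanking helices fuse into one contiguous
stack. The operation is idempotent.

`fold_fallback` is a Nussinov base-pair–maximization dynamic program
over Watson–Crick + G–U pairs with a minimum loop of 3 nt. It exists so
that the scanner can run on sequence-only input without an external
thermodynamic folder; it is *not* a substitute for free-energy folding
and is validated only against an exhaustive enumeration oracle at
n ≤ 12. Traceback is deterministic (pair the 5′-most position whenever
pairing is optimal; prefer partners that allow continued stacking, then
the 5′-most partner).

## Recognition rules and the scanner (`scanner`)

The empirical recognition criteria are:

* upper and lower helices of at least 6 bp (`min_helix_bp`, default 6);
* bulged nucleotides on the 3′ strand between them (`bulge3_present`),
  the feature that instigates the inter-helix bend;
* two minor-groove sites, ED2 and ED1, separated by exactly 8 bp
  (`spacing`, default 8), counted as pairs strictly between the two
  sites along the 5′-strand stack. 3′-strand bulges do not interrupt
  the count; a 5′-strand discontinuity does.
* ED2 sits at a fixed number of pairs from the closing pair of the
  terminal loop (`ed2_offset_from_loop`, default 5, closing pair = 1),
  reflecting the protein interaction that sets the distance between the
  ED2 site and the start of the loop. Because this offset is read off
  a single reference register, the scanner tries offsets within a ±2
  window (`offset_window`) and keeps the best-scoring assignment,
  breaking ties toward the default offset.

Base-pair preference at the sites uses ordinal weights reflecting the
measured rank order U–A (3) > C–G (2) > A–U (1) > G–C (0) — steric
exclusion of guanine's N2 amino group plus a 5′-pyrimidine/3′-purine
bias. The noncanonical C–U pair scores 2 at ED1 (no bulky purine to
clash with the recognition surface) and 0 at ED2. Weights are
configurable but must preserve the rank order.

Tiers: `primary` requires all four geometry flags plus acceptable ED
sites; `support` keeps the ED-site requirement but relaxes the
helix-length/bulge geometry tied to docking of the ExoHD–XAD module
(the behaviour of low-affinity support elements that engage ED1 and ED2
only); anything else is `reject`. The ED-site requirement is a strict
U–A at ED2 — the ED2-adjacent pair is U–A in every solved signal — and
any positively scored pair at ED1, the variable site. Requiring the
top-ranked pair at ED2 also prevents a mutated signal from being
re-registered onto its neighbouring pairs by the offset window.

A transcript verdict applies coincidence detection: transport-competent
means at least one primary signal plus at least one additional
primary-or-support element, i.e. both RNA-binding pockets of the Egl
dimer can be occupied by elements of the same RNA.

The reference fixture (`synth.tls_like_element`) is a **synthetic**
44-nt hairpin, not a natural sequence: it reproduces the published
register of the K10 transport-and-localization signal (U–A pairs at
positions 6–39 and 15–28, the stacked U7–A38 neighbour, A16–U27, a 4-nt
loop, ≥6 bp helices, and two 3′-strand bulges around a short internal
helix) with arbitrary G/C identities elsewhere.

## Bend analysis (`geom3d`)

The bend between the upper and lower helices is measured from atomic
coordinates in four steps: detect base pairs geometrically, build a
helical trajectory (one point per pair, ordered base → loop), fit each
helix's points with a best-fit 3D line by SVD, and report
arccos(d̂_lower · d̂_upper) in degrees.

* Pair detection requires a C1′–C1′ distance of 10.4 ± 1.5 Å, at least
  one inter-base donor–acceptor heavy-atom contact ≤ 3.5 Å, and base
  planes (least-squares planes through the purine 9-atom or pyrimidine
  6-atom ring) within 30°. Competing assignments are resolved greedily
  by a combined score over the three criteria with one partner per
  residue; the combination matters at kinked junctions, where a
  cross-strand neighbour can beat a true pair on contact distance alone
  but not on C1′ distance and coplanarity.
* The trajectory is deliberately simple: the C1′ midpoint of each pair.
  A full helicoidal-parameter analysis (Curves+-style) is out of scope;
  for line fits over ≥4-pair segments the segment-scale geometry is
  insensitive to per-step axis refinement, and externally computed
  trajectories can be imported verbatim (TSV: index, x, y, z) when
  bit-faithful replication of an external axis definition is needed.
* Default segment ranges are the annotated lower and upper helices;
  junction/bulge steps are excluded. This choice is exposed (CLI
  `--lower/--upper`) because reasonable alternatives exist.
* Direction sign convention: both fitted directions are oriented
  base → loop along the vector between the two segment centroids before
  the dot product. This orientation is independent of the order of
  points within a segment (a mirrored or re-sorted segment yields the
  same angle). The trade-off is that a hypothetical bend above 90°
  would be folded toward the centroid axis; every bend relevant here is
  well below that (the measured signals bend ~19–26°, and recovery is
  validated to 60°).

Kabsch superposition (SVD with a determinant correction enforcing a
proper rotation) provides RMSD comparison between stem loops; it is
cross-checked in the tests against an independent quaternion
implementation.

## Two-copy occupancy model (`coloc`)

Complexes carry 1 or 2 RNA copies (two-copy probability `f_two`,
capped at 2 per the dimeric stoichiometry); each copy is Cy3 with
probability `p_dye` (0.5 for a 50:50 labelling mix) and detectable with
probability `lab_eff`. The ideal model (`lab_eff = 1`) reproduces the
textbook expectations — no dual-colour complexes under single-copy
binding, 50% dual under pure two-copy binding — and `lab_eff` is an
extension (default 1, so the ideal expectations are the default
behaviour) that lets users explore detection losses as one explanation
for observed dual fractions below 50%.

Estimation is maximum likelihood on the visible categories (dark
complexes cannot be seen in kymographs, so the likelihood is conditioned
on at least one visible dye). For the ideal model the MLE has the
closed form f̂ = 2·(n_dual/n_total), clipped to [0, 1] with a flag; for
general parameters a bounded scalar optimizer maximizes the conditional
multinomial likelihood. Confidence intervals are percentile bootstrap
(default 10,000 resamples, seeded) rather than Wald, because n_dual can
sit near a boundary. Applied to a 44% observed dual fraction — the
published value for isolated stem loops on motile complexes — the
closed form gives f̂ = 0.88.

## Localization efficiency (`locquant`)

ROIs default to discs of 7.391 µm² (the published mean footprint of
apically localized RNA at a microtubule organizing centre; the shape is
unstated in the source protocol, so it is configurable). Four apical
ROIs are placed greedily on the Gaussian-smoothed image (σ = ROI
radius/2): take the brightest pixel in the apical band, exclude that
footprint, repeat; ties break in row-major order. Basal ROIs are the
apical centres translated vertically (default 30% of image height,
overridable in µm); "apical band" and "just above the yolk" are
anatomical notions with no pixel definition, so both are fractional-
height parameters (defaults: band 0–15%, background region 80–95% of
height). Manually chosen centres can be supplied instead of automatic
placement. The metric is
(apical − background) / (basal − background) using the mean intensity
of a distant background region; saturated pixels (the dtype maximum)
are excluded from every mean with a warning. The ratio is exactly
invariant under additive offsets; under a multiplicative gain it is
invariant only if the background region scales identically with the
signal regions (documented, not asserted).

## Synthetic data (`synth`)

* **Kinked helix.** Two ideal A-form segments (textbook values: rise
  2.81 Å, twist 32.7° — standard constants, not fitted) joined at a
  junction with the upper axis rotated by `kink_deg`, a 4-nt terminal
  loop, and (by default) two unpaired 3′-strand junction nucleotides.
  Nucleotides are pseudo-atomic: C1′, a planar base ring whose
  Watson–Crick edge nitrogen sits 1.45 Å from the pair midpoint, and
  the exocyclic donors/acceptors (N6/O6/O4/N4/N2/O2) flanking it, so
  each pair presents 2–3 polar contacts at 2.9 Å, as real pairs do.
  C1′ atoms of a pair are placed symmetrically about the local axis
  10.4 Å apart, so pair midpoints trace the axis exactly and the
  trajectory of a straight helix is collinear by construction. This is
  *not* physically realistic RNA (no backbone, no sequence-dependent
  geometry); it is sufficient ground truth for C1′-midpoint
  trajectories, geometric pair detection and base-plane estimates, and
  conclusions about real structures require real coordinates.
* **Implanted transcripts.** Uniform-random ACGU background, unpaired
  in the composite structure, with signal elements spliced in at fixed
  coordinates and a truth table of spans/tiers. Because the background
  is unpaired, scanner sensitivity is measured against the implanted
  structure, not against folding errors; the false-positive check runs
  separately on fallback-folded random sequences.
* **Embryo images.** Background plateau (100 counts) + basal band
  (rows 30–55%, +50 counts) + apical flat-disc puncta of one ROI area
  whose amplitude is `ratio` × the basal amplitude, with optional
  per-pixel Poisson noise. The programmed ratio is therefore exact by
  construction up to disc discretization. Real embryo images differ in
  every other respect (anatomy, yolk autofluorescence, optical blur),
  so passing recovery tests validates the measurement pipeline, not
  biological image handling.

All generators are bit-reproducible under fixed seeds.

## Problem sizes and numerical choices

The bundled checks use: 10⁶ events for the simulator/analytic
comparison; 50 replicates per programmed kink at 0.3 Å coordinate
noise; 1,000 replicates of 500 complexes with 10,000 bootstrap
resamples for estimator recovery; 200 implanted 1,500-nt transcripts
per scanner condition; and 20 Poisson seeds per programmed image ratio.
Dot products are clamped to [−1, 1] before arccos; SVD directions are
unit-normalized to 1e−9; degenerate line fits (all points identical)
and rank-deficient superpositions are errors/warnings rather than
silent results; ROI placement ties break row-major.

## Known limitations

* The bend trajectory is a C1′-midpoint approximation; absolute angles
  from real structures can differ by a few degrees from a full
  helicoidal analysis (hence the import path).
* The ED2-offset default (5 pairs from the closing pair) is derived
  from a single reference register; the ±2 scan window compensates but
  has not been calibrated against more than the bundled fixtures.
* Whether noncanonical pairs should count toward the 6-bp helix
  minimum is unresolved in the source material; they are counted, and
  flagged in the annotation output.
* The coincidence verdict treats elements independently; it does not
  model avidity, linker length between elements, or higher-order RNA
  oligomers.
* The colocalization counts are taken as input; defining "colocalized"
  from kymograph geometry is out of scope.
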