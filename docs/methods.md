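# Methods

## The knockdown-dilution model

All three generators and both analysis layers share one kinetic picture.
A stable fluorescent reporter (or any stable target protein) is
synthesised at a constant per-biomass rate `alpha` while cells grow
exponentially at specific rate `mu`; its concentration sits at the
balance point `alpha / mu`.  When CRISPRi against the gene is induced at
`t_ind`, nothing observable happens for a quiescent delay `tau_q`
(dCas9 expression, complex formation and promoter occupancy all happen
upstream of the protein pool); from `t_ind + tau_q` onward synthesis runs
at a residual fraction `r` of its former rate.  Because the protein is
stable, the only loss channel is dilution by growth, so concentration
relaxes from `alpha/mu` toward `r * alpha/mu` as `c(t) = (alpha/mu) *
(r + (1-r) e^{-mu (t - t_on)})` — i.e. it halves per doubling when
`r = 0`.  `r > 1` is allowed, to represent guide designs that enhance
rather than repress expression.  No degradation term is included; the
reporter is treated as protease-stable, which is the regime in which
dilution dominates and the model is exact.

Defaults encode the study conditions this package targets: `tau_q =
1.75 h`, `r = 0.17`, and `mu = 1.5 ln2 / 1.75 ≈ 0.594 /h` so that the
quiescent phase spans 1.5 doublings (a 70-min doubling time, typical of
rich/glucose growth at 30 °C).

## Microcolony generator

Cells are 2-D capsules (rectangle plus semicircular caps) on a plane,
which makes length–area relations analytic: `A = w(L - w) + pi w^2 / 4`.
Each cell elongates as `dL/dt = mu L`, divides when it exceeds a
per-cell division threshold drawn as `N(L_div, cv * L_div)`, and splits
with a small asymmetry (`CV 0.02`); daughters inherit the mother's
concentration exactly (binomial partitioning noise is second-order at
typical copy numbers and is omitted).  Total per-cell fluorescence obeys
`dP/dt = alpha(t) L` with the switch model above, integrated in closed
form per frame interval, so the dilution law holds to machine precision
in the ground truth.  Division-blocked (filamenting) lineages are drawn
per generation from `filament_prob`; blocked cells keep elongating at
`mu` but never divide.  Overlaps are resolved by a pairwise capsule
repulsion relaxation each frame; a colony that reaches the image border
raises an error naming the frame rather than silently truncating cells.

Rendering: the fluorescence channel paints each cell's pixels at
`P / area_px` (so integrated intensity equals the true total) plus
Gaussian shot noise; the brightfield channel shows a *conservative core*
— the capsule eroded by `halo_shrink_px` (default 6 px) — at
`background + cell_contrast`, over a Gaussian background.  This emulates
the under-filled footprint that offset-brightfield imaging produces, and
is exactly the footprint the segmentation chain's 6-px growth step is
designed to undo: erosion followed by Euclidean dilation by the same
radius is a morphological opening, which is the identity on capsules
whose radius exceeds the growth radius.  Default cell geometry
(width 1.4 µm, division length 6.0 µm at 0.065 µm/px) sits at the large
end of the species range so that even a newborn cell's eroded core stays
above the 200 px segmentation floor.

What the generator does **not** emulate: 3-D optics and the point-spread
function, agar-pad drift, photobleaching, segmentation artifacts from
debris, and cell–cell mechanical alignment.  Passing tests therefore
demonstrate correctness of the estimators and of the pipeline contracts,
not robustness to every imaging pathology of real movies.

## Plate-reader and cultivation generators

Plate wells grow logistically (exact closed form; carrying capacity
`None` gives pure exponential).  Cellular fluorescence per volume obeys
`dF_cell/dt = alpha(t) * OD`, also integrated in closed form; measured
fluorescence adds `autofluorescence_per_od * OD` and Gaussian noise, and
measured OD adds Gaussian noise.  Replicate wells share the kinetics and
differ only by noise realisation (per-well seeds are spawned from the
config seed).  Default induction at 4.0 h puts the culture at OD ≈ 0.1,
early exponential phase.

The batch cultivation couples Monod substrate uptake
`q = (mu_max / Y) * S/(K_S + S) * X` to a knockdown-completeness split:
after induction a fraction `eta` of consumed p-coumarate accumulates
mole-for-mole as β-ketoadipate; the remainder is fully catabolised.  The
acetyl-CoA co-product of the upstream pathway (about 2 of the 9 substrate
carbons) supports biomass even at `eta = 1`, scaled by
`acetyl_coa_yield_fraction = 0.22`.  Upstream aromatic intermediates
(4-HBA, PCA) are held at zero, matching their observed non-accumulation.
Integration is classical fixed-step RK4 (`dt = 0.01 h`); because
`dP = -eta dS` is linear, the molar balance `S + P <= S0` is preserved
exactly by the integrator, and a negative concentration aborts the run
as a step-size misconfiguration.  When substrate falls below 1e-12 mM
the balance is closed exactly to avoid an asymptotic Monod tail.
Defaults (`S0 = 40 mM`, `eta = 0.76`, lag 13.5 h, induction at 14 h,
`mu_max = 0.35 /h`, `Y = 0.15 OD/mM`, `K_S = 0.5 mM`) produce exhaustion
near 36 h, a titer of ≈ 4.85 g/L and a molar yield of ≈ 0.76 on initial
substrate.

## Segmentation

The background of an offset-brightfield image is estimated by fitting a
single Gaussian to the intensity histogram: 256 bins over a robust
central range (median ± 5 robust sigma from the MAD), nonlinear least
squares initialised from the median and MAD so bright foreground cannot
drag the fit.  The initial mask is the strict inequality
`I > mean + k_sd * sd` (default `k_sd = 1.5`, valid range [1, 2]).  Size
filtering is boundary-inclusive: components of exactly 200 or exactly
50,000 px survive.  Mask growth assigns every background pixel within
Euclidean distance `grow_px` (inclusive) of a label to its *nearest*
label, ties to the smaller id — label-preserving growth, so adjacent
cells never merge (a point label grown by 6 px covers the 113 lattice
points with squared distance ≤ 36).  One lattice caveat: growing by
`d1` then `d2` is a subset of, but not identical to, growing once by
`d1 + d2`, because integer-lattice balls do not compose exactly under
Minkowski sums; the one-shot distance-to-original-support semantics is
the contract.  Final labels are consecutive integers ordered by first
pixel in row-major scan.

## Tracking

Frame-to-frame linking solves a gated linear assignment (Hungarian
algorithm) over centroid distance (or 1 − IoU); objects whose best match
exceeds the gate stay unmatched.  A track that ends while exactly two
unmatched objects appear within the division gate of its last centroid,
with combined area within [0.6, 1.4]× its last area, becomes a mother;
its daughters get generation + 1.  Ambiguous configurations (≠ 2
candidates, area mismatch, shared candidates) are logged and left as
plain ends/starts.  There is no gap closing: at 7–8 min frame cadence a
cell missing from one frame legitimately terminates its track.  The
generic gate defaults (10 / 15 px) suit small objects; because a
daughter's centroid sits ~L/4 from the mother's centroid, the
scale-aware constructor `LinkingParams.for_colony(pixel_size,
division_length)` derives gates from the imaging geometry and is what
the pipeline and validation use.  Root cells (no identified mother) get
a configurable root generation, since colonies typically undergo
doublings before filming starts and generation numbering may begin
above zero.

## Single-cell metrics

Cell length is the major-axis length of the mask's second-moment
ellipse (the length measure is otherwise under-determined).  Cellular
GFP concentration divides background-subtracted total intensity by area;
the background is the per-frame mode (densest of 256 histogram bins) of
the non-cell pixels, switchable off.  Growth rate and dF/dt are
ordinary least-squares slopes of ln(length) and of concentration over a
track's full lifespan, undefined (NaN with a warning) below 3 frames.
Filamentation is `never divides over the observation AND max area
> 9 µm²` with a strict inequality at the boundary; population statistics
exclude border-touching cells by default because their areas are biased.

## Bulk assay

Reporter concentration is read at the first OD600 threshold crossing
(0.1 rich media, 0.05 minimal), located by linear interpolation in both
OD and fluorescence.  The GFP fraction subtracts the non-fluorescent
strain's concentration from both numerator and denominator and divides
replicate means; its 95% CI is the 2.5/97.5 percentile band of 10,000
resampled ratios, resampling the replicate-level knockdown and control
concentrations independently with replacement, with the lower limit
clamped at zero (negative concentrations are unphysical; the upper limit
cannot go negative when the point estimate is non-negative).  With
triplicate wells this small-sample percentile interval is known to
undercover the truth (~80–85% rather than the nominal 95%: with n = 3
the true mean falls outside the sample range a quarter of the time);
the method is kept as specified because it is the field's standard
reporting convention, and the undercoverage is documented rather than
patched.

Onset detection smooths the knockdown/control-normalised F/OD ratio with
a centred 3-sample moving average, takes the smoothed ratio at induction
as baseline, and declares onset at the first (linearly interpolated)
time after induction where the ratio drops below `(1 - delta)` baseline
(default `delta = 0.05`) and stays below for at least two samples.  The
quiescent phase is `onset - t_ind`; doublings convert it via the
realised ln-OD slope of the knockdown wells over the quiescent window
divided by ln 2.  The `delta` rule introduces a small positive bias
(~0.1 h at the default kinetics: the time to fall 5%), well inside one
15-min sampling interval.

Titer/yield accounting takes exhaustion as the first sample at which
substrate falls to the tolerance (default 0.5 mM), converts product to
g/L via molecular weights computed from elemental formulas (βKA
C6H8O5 = 160.13 g/mol, p-CA C9H8O3 = 164.16 g/mol, overridable), and
divides product moles at exhaustion by substrate moles at time zero —
the *initial*-substrate convention, which is the conservative one when
some substrate feeds biomass.

## Guide screening

The off-target scan Hamming-compares the 20-nt spacer to every genomic
20-mer whose immediately 3'-adjacent triplet matches the PAM motif
(NGG by default; NAG can be passed) on either strand; comparisons are on
the protospacer strand, positions are reported as 0-based forward-strand
starts, ambiguous bases count as mismatches and never satisfy a PAM
letter, and the genome is treated as linear.  A spacer is discarded iff
any site other than its annotated intended site lies at ≤ 4 mismatches.
Non-targeting spacers are rejection-sampled with exactly 10 G/C bases
among 20 until the genome-wide minimum distance is ≥ 5; the sentinel 21
is returned when a genome has no PAM-adjacent site at all.  On-target
activity scoring is out of scope; a hook accepts externally supplied
scores.

## Problem sizes and determinism

Validation movies use 512×512 px frames, 20–25 frames and single-lineage
colonies (4–8 cells), enough to exercise ≥ 2 division rounds; plate
ensembles use 20 replicate experiments of 41 samples; the cultivation
integrates 48 h at 0.01-h steps.  Every stochastic component takes an
explicit seed (per-well and per-stage seeds are spawned from a single
global seed), and equal seeds give bit-identical outputs.

## Known limitations

* The percentile-bootstrap undercoverage at n = 3 described above.
* The colony relaxation is a heuristic, not a mechanical model; very
  dense colonies (beyond ~50 cells) may develop contacts that lower
  segmentation IoU.
* Division detection requires both daughters to be segmented in the
  frame after the mother's last; there is no gap closing or merge
  handling.
* The cultivation model lumps maintenance and byproducts into the yield
  coefficient; it reproduces stoichiometry and timing, not physiology.
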