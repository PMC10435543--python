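# Methods

This note documents the models, conventions and design choices behind each
pipeline, what the synthetic generators do and do not emulate, and the
numerical rules applied at boundaries and degenerate inputs.  No empirical
claim is made here that the test suite or `scripts/acceptance.py` does not
itself compute.

## Arbor representation and morphometry

An arbor is a rooted tree of 3-D sample points in µm with exactly one
parentless node (the soma); the 7-column SWC text dialect is the on-disk
form.  The soma is taken to be the root node's coordinates — multi-node
somata are out of scope.  Total dendritic length is the sum of Euclidean
edge lengths, soma-adjacent edges included.

**Sholl profile.**  Along a straight segment the distance to the soma,
`d(t) = ‖a + t(b − a)‖`, is unimodal with at most one interior minimum (the
foot of the perpendicular).  Each segment is split at that minimum into
monotone pieces and a crossing of the shell of radius `r` is counted per
strict sign change of `d − r` over a piece.  Consequently a segment dipping
into a shell and back out counts twice (standard Sholl semantics), and a
tangency — the shell touching the segment in a single point — counts zero;
the tangent case has measure zero and the strict-inequality rule makes it
deterministic.  Default shell radii are 10, 20, …, 200 µm (spanning the
typical extent of tectal arbors at readable resolution); they are fully
configurable, as is a 2-D projected variant (`projected=True`) since 3-D
versus projected Sholl is an open convention — 3-D is the default.
Correctness is checked against a dense-sampling oracle that walks every
segment at 0.01 µm steps.

**Maturity.**  Arbors with total length < 500 µm are classified immature;
the boundary value 500 µm itself is mature ("≥ 500 µm").

## Terminal-process dynamics

The unit of analysis is the terminal process: the path from a leaf back to
the nearest ancestor that is a branch point (> 1 child) or the soma.
Internal shaft growth is not analyzed.  Processes shorter than 10 µm are
filopodia; 10 µm exactly and longer are branches (the figure-caption
convention "≥ 10 µm" wins over looser prose).

Correspondence across timepoints comes from persistent identities attached
to leaves by the reconstruction (manual 4-D reconstruction in the original
workflow); no image-based tracking is implemented.  Per interval:
additions are identities present only in the later arbor, losses only in
the earlier one, and shared identities contribute a signed length change.
Class attribution when a process crosses the 10 µm boundary is
deterministic: a shared process is attributed to its class at the earlier
timepoint, an added process by its first observed length, a lost one by its
last.  Elongation and retraction totals are sums of positive and of
absolute negative deltas over all intervals (per-interval summation; an
end-minus-start variant can be computed from `diff_arbors` directly).
Motility per interval is `Σ |δ|` over persisting processes of the class.
Density is processes per µm of arbor; timepoints with zero arbor length
(bare somata) are excluded from the mean density, and `process_density`
on a zero-length arbor raises.

A consequence of the earlier-timepoint attribution rule is that time
reversal swaps additions↔losses and elongation↔retraction exactly in the
class-combined totals, while per-class totals can differ when a process
crosses the class boundary within an interval; the test suite asserts the
combined identity.

## Puncta pipelines

**Rolling-ball background subtraction** is implemented as grayscale opening
with a non-flat, ball-shaped structuring element (height profile
`√(r² − x² − y²)`; a paraboloid dialect is available), subtracted from the
image and clipped at zero.  Reflect boundary handling throughout.  The
default radius is 10 px, the median filter a 2 px disk, per the published
preprocessing.

**Auto-thresholding** is histogram-based with 256 levels.  Integer images
with a range of at most 256 gray levels are histogrammed at their exact
values, which makes thresholds land on actual gray levels and translate
exactly under constant intensity shifts; other images use 256 uniform bins
over the intensity range.  Foreground is pixels *strictly above* the
returned threshold, a single convention for both methods.

* *MaxEntropy (Kapur)*: the threshold maximizing the summed Shannon
  entropies of the normalized below- and above-threshold histograms.
* *Moments (Tsai)*: for each candidate threshold the two-level image that
  keeps the below/above fractions and matches the histogram's first two
  moments exactly is constructed, and the candidate minimizing the error in
  the third moment is chosen — the exhaustive form of the moment-
  preservation criterion.

Both methods break ties by taking the middle of the optimal plateau, so a
perfectly bimodal 0/255 image thresholds near mid-range rather than at 0.
Constant images raise (no threshold exists); the end-to-end pipelines catch
this and treat such slices as empty foreground, which is what a blank slice
means in practice.  Both methods are verified against independent
enumeration oracles on random histograms.

**Particles.**  Connected components use 8-connectivity by default
(4-connectivity is an option); the size criterion 0.1–5.0 µm² is a closed
interval on `n_pixels × pixel_size²`.

**Anatomical synapse density** applies rolling ball → median → Moments to
each channel, ANDs the binary masks, size-filters, and reports the count,
the density per µm² and per 400 µm² (the 20 µm × 20 µm sampling-field
convention), since the published denominator is not stated.

**Dendritic punctum density** thresholds per slice (MaxEntropy for the
structural channel, Moments for the puncta channel), removes the
soma/axon exclusion mask from the dendritic mask, size-filters puncta
within the dendritic mask per slice, and merges components in adjacent
slices whose pixel footprints overlap (in-plane 8-connectivity plus
same-pixel z-adjacency), counting each merged punctum once; pure per-slice
counting is available via `merge_slices=False`.  Whether the original
analysis counted in projections or across z is unstated, so both are
exposed.  Density is count per µm³ of dendritic mask volume
(`voxels × pixel_size² × z_step`); an empty dendritic mask raises.

## Retinotopic mapping

ΔF/F₀ uses a per-pixel F₀ equal to the mean over designated stimulus-free
baseline frames (the protocol's pre-stimulus period plus the tail of each
inter-stimulus gap); pixels with non-positive baseline are flagged invalid
(NaN) rather than dropped silently.  The response window runs from
stimulus onset to offset plus a decay allowance (default 1 s) for the slow
indicator transient; windows of the same bar position are averaged, per ROI
or per pixel (grid map).

The receptive-field centre is the response-weighted average position over
the 5 bar positions after rectifying negative responses to zero (the
weighted average is undefined for negative weights); if no response is
positive the estimate is undefined and the cell is excluded.  Sharpness
ranks positions by `|i − p*|` with ties broken toward the lower index (a
deterministic rule for the measure-zero tie case) and divides the mean
response of the two closest positions by the mean of the remaining three;
a non-positive denominator makes sharpness undefined, which is logged as an
exclusion rather than clipped.  Both statistics are invariant to positive
scaling of the responses.

Inclusion criteria follow the published evaluation rules: maximal response
ΔF/F₀ > 2 (read as 2.0 ΔF/F units, configurable), optimal position within
the three central stimulus positions (read as the closed interval [2, 4]),
ROI at least 30 px, and whole animals dropped when fewer than 30 cells
survive.  Every exclusion carries a reason
(`weak_response`, `peripheral_optimum`, `small_roi`, `undefined_sharpness`,
`animal_below_min_cells`).

The two-sample KS statistic is the exact supremum ECDF distance with the
asymptotic Kolmogorov p-value at effective sample size
`n_a n_b / (n_a + n_b)`; it is cross-checked against a brute-force pooled
ECDF evaluation and scipy's implementation.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic in their seed (bit-identical outputs), and
each generator's ground truth is recovered exactly by the corresponding
noiseless pipeline run — that is the core testing contract.

**Arbors and series.**  Trees grow by splitting random tips; segment
lengths are uniform in [0.5, 1.5] × 20 µm by default, so a handful of
branch events yields the few-hundred-µm immature arbors the morphometry
targets.  Series default to 6 intervals (the 10-min × 1-h short-interval
imaging design): per interval each process is lost with probability 0.15,
one new process sprouts with probability 0.4 (initial length uniform in
[1, 5] µm, so newcomers are filopodia), and survivors take a Gaussian
length step of s.d. 1.5 µm along their terminal segment (clipped so the
segment stays ≥ 0.1 µm; the realized delta is what is logged).  Two
structural rules keep the event log exact: new processes attach only at
the soma or existing branch points (attaching mid-segment would split
another process), and when a loss demotes a branch point the sibling
process absorbs the parent segment, the absorbed length being part of its
logged `delta_length`; internal stubs orphaned when all daughters of a
branch vanish are pruned.  The turnover rates are chosen to produce a few
additions and losses per hour on a 5–10-process arbor, the regime of the
time-lapse figures; they are parameters, not calibrated fits.

**Punctate fields** place Gaussian spots (σ 0.4 µm, peak 150 over
background 20, 8-bit) at rejection-sampled positions at least 2 µm apart in
a 20 µm × 20 µm field at 0.496 µm/px, with `n_coloc` centres shared across
channels; additive Gaussian noise (default s.d. 4) models detector noise
only.  **Dendrite stacks** hold a flat-cored bright tube (radius 1 µm)
along x plus a soma blob covered by the returned exclusion mask; puncta
are 3-D Gaussian blobs on the tube axis, well off it, or inside the soma.
The flat-cored intensity profile makes the structural foreground a single
bright histogram mode, which is what entropy-based thresholding expects of
a filled fluorescent structure.

**Calcium movies.**  Each cell has a Gaussian tuning curve over the bar
axis in degrees (positions 18° apart, centred on zero — position-index
units with a degrees mapping; no screen geometry is simulated) and
responds to each presentation with an instantaneous-rise,
single-exponential-decay transient (τ = 1.5 s by default, a GCaMP6s-scale
stand-in) of peak `A·exp(−(deg(p) − c)²/(2σ²))` in ΔF/F₀ units; the
fluorescence is `f0(1 + signal)` inside the ROI plus additive Gaussian
noise.  The Gaussian-over-position receptive field is a modelling
assumption of the generator, not a claim about tectal biology.  The cohort
helper (`generate_rf_cohort`) encodes the comparison conditions: 36 cells
per animal on a disjoint ROI grid, amplitude 8 ± 1 ΔF/F₀, 6 Hz imaging,
3 randomized repeats of 1 s bars with 4 s gaps, 2% noise.

Not emulated anywhere: photon-counting statistics, bleaching, motion,
optical PSFs, electroporation efficiency, or ROI segmentation errors
(ROI masks are ground truth).  Passing tests therefore demonstrate the
correctness of the measurement code under its stated model, not robustness
to every artifact of real microscopy.

## Problem sizes and numerical tolerances

The test suite and acceptance script run at desk scale: 100 histograms per
thresholding oracle, 100 arbors for the Sholl oracle (0.01 µm sampling),
50 series for event-log recovery, 10 + 60 fields and 5 stacks for the
puncta pipelines, and 10 cohort pairs of 36 cells for the KS comparison —
sizes chosen to exercise every code path in seconds while keeping the
stochastic checks well-powered (the narrow/wide sharpness distributions are
non-overlapping at these sizes, so KS p-values are far below 0.05).

Exact-recovery assertions compare counts exactly and continuous magnitudes
to 1e-9 (float associativity).  Movie-level "exact" centre recovery is
asserted to 1e-3: the response-vector symmetry identity is exact, but
decay transients bleed across presentations, so tests use 20 τ
inter-stimulus gaps, which bounds the bleed-induced bias around 1e-4.  The
weighted-average centre of an on-grid cell equals the grid position only up
to tuning-curve tails at the axis ends; tests either use narrow fields
(tails ~1e-8) or tolerate the documented ~2e-3 bias.  A discretized ball
leaves a sub-0.1 residual when opening removes an isolated impulse, which
the relevant test tolerates explicitly.
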