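# Methods

## Scope and data model

The pipeline analyses pairs of single-channel 2D grayscale micrographs
(16-bit TIFF) of membrane sheets at a fixed physical scale
(default 20 nm/pixel; taken from the parameter file, not from TIFF
metadata, so one parameter set governs a whole experiment). All
geometric parameters are specified in nanometres and converted through
the pixel size. Pixel (row, col) covers the square
[col·p, (col+1)·p) × [row·p, (row+1)·p); its centre is
((col+0.5)·p, (row+0.5)·p). An optional binary mask restricts the
analysis to the sheet and defines the area used for densities.

## Preprocessing

Co-excitation bleed-through between the two spectral channels is
removed by subtracting a fixed fraction (default 0.5) of one channel
from the other, clipping at zero. Noise is reduced by a Gaussian blur
of σ = 0.5 px (reflective boundary). All downstream measurements are
taken on the corrected, blurred image.

## Maxima detection (noise tolerance)

The detector reports a candidate pixel p (≥ all 8 neighbours;
outside-image neighbours count as −∞, so border pixels can be maxima)
iff the 8-connected region of pixels with value > I(p) − t reachable
from p contains no higher pixel and no already-accepted maximum, with
candidates processed in descending intensity (ties row-major). t is
the per-target noise tolerance (defaults: 4 a.u. for CD9/CD81/CD151,
8 for CD44, 5 for pERM, 6 for EWI-2). An equal-valued plateau yields
exactly one maximum — the member pixel nearest the plateau centroid,
ties broken row-major — and a plateau with no strictly lower in-image
neighbour (a constant image) has no prominence and yields nothing;
this auxiliary rule is the minimal completion of the flood contract
for degenerate inputs. The flood loop is compiled with numba; its
semantics are pinned by an independent reference implementation
(connected-component labelling of the thresholded mask) that the test
suite checks for set-identity on hundreds of random images. Raising t
can only merge or remove maxima, never create them; detection commutes
with translation. Bit-compatibility with any particular external tool
is not claimed — the contract above is normative.

## Per-maximum quantification

* **ROI intensity.** Mean over a digital disk centred on the maximum
  pixel. "5 pixel diameter" is read as 5 pixels across the centre row,
  i.e. Euclidean radius (5−1)/2 = 2, giving the 13-pixel disk. Both
  channels are measured at the same position; the off-sheet background
  (a ROI at a configured position, or an explicit per-channel value)
  is subtracted and negative values are retained — the 2 a.u. noise
  gate deals with them downstream.
* **Mass centre.** Intensity-weighted centroid over the same disk,
  weights background-corrected and clipped at zero (so off-sheet noise
  cannot drag the centroid); zero total weight falls back to the pixel
  centre. The fixed window truncates the spot, which shrinks a true
  sub-pixel offset towards the pixel centre — measured ≈ 0.17–0.24 px
  error for a 0.3 px offset at PSF 65–100 nm, in line with the
  analytic truncated-Gaussian shrinkage. The bias is shared by the two
  channels of a co-assembled spot (both shrink toward the same pixel
  grid), so cross-channel distances — the quantity that matters — are
  far less affected; end-to-end overlap recovery confirms this.
* **Linescan fits.** A horizontal and a vertical profile (31 samples
  long, averaged over 3 px across) are each fitted with
  b + A·exp(−(x−μ)²/2σ²) by bounded least squares (A ≥ 0,
  μ ∈ [0, 30], σ ∈ [0.5, 15] px). The additive offset b is included
  because the membrane background is non-zero and offset-free fits
  bias σ upward. Start values come from the profile (argmax, range,
  σ₀ = 2 px) with two fallback widths tried only when the first fit is
  absent or poor; a flat profile or non-convergence yields an R²
  sentinel of −∞. The higher-R² orientation wins; an exact tie goes to
  the horizontal scan.
* **Cluster criterion.** R² > 0.8 (strict) and |μ − 15| ≤ 5 px
  (the central 10 pixels). Of the two phrasings in circulation —
  "middle third" vs "central 10 pixels" — the latter is adopted; they
  differ by a third of a pixel. Maxima within 15 px of a border cannot
  host the linescan window; they are flagged, still measured
  photometrically where the 2 px ROI fits, and never rated clusters.
* **Size.** FWHM = 2√(2 ln 2)·σ·p. On noiseless rendered spots the
  estimate is resolution-floored: it recovers the PSF width, not the
  emitter extent, so sizes at or near the PSF FWHM are upper bounds.

## Spatial statistics

Cluster-to-cluster shortest distances use the sub-pixel mass centres
and only maxima rated clusters; the analysis is directional (A→B and
B→A both reported). Clusters with distance ≤ 60 nm (inclusive) count
as overlapping. Distance histograms use 10 nm left-closed bins — wide
enough for counting statistics, narrow enough to resolve a ~30 nm
displaced peak with ≥ 3 bins below the threshold.

Crowding uses *all* maxima at their pixel positions: for each maximum
the number of other same-channel maxima within a 900 nm diameter
circle (boundary inclusive; the centre is never its own neighbour).
Under complete spatial randomness at intensity λ the count averages
λπ(0.45 µm)². No edge correction is applied by default (matching the
original procedure); a flag restricts the statistic to maxima ≥ 450 nm
from the border, which is what all analytic comparisons in the test
suite use, since border circles are truncated and bias the mean low by
several percent on small fields.

Densities are cluster counts divided by sheet area (mask pixels ×
pixel area, or the full field without a mask). On small simulated
fields the 15 px linescan margin excludes ~10–20% of the area from
cluster classification; validation against ground truth therefore
compares densities after renormalising to the interior area.

## Mixture decomposition and intensity correlation

The percentage histogram of neighboured-maxima counts (unit bins on
the integers) is fitted with a sum of one or two Gaussians by
nonlinear least squares with deterministic multi-start initialisation
(means at weighted quantile pairs, two width guesses; the lowest-SSE
solution wins, making the result invariant to start order). Area
fractions are Aσ-normalised; components are reported in increasing
mean, the higher-mean component being the arranged-crowd population.
Model preference is an F-test on the SSE reduction of the 6- over the
3-parameter model (3 numerator df, α = 0.05); a numerically perfect
single-component fit short-circuits to "single". A two-component fit
requires ≥ 6 non-empty bins. Whether the two components should be
fitted jointly or the control peak anchored first is not decidable
from the source procedure; the joint fit is normative here.

Inter-channel intensity correlation uses *all* maxima: y regressed on
x through the origin, slope = Σxy/Σx², with R² defined about the mean
of y — deliberately, so that R² < 0 flags data that a proportional
model describes worse than a constant, the signature of segregated
populations. Points are partitioned by the 2 a.u. noise gate
(inclusive): both channels above, self-only, below noise.

Replicate aggregation averages per-sheet metrics within biological
replicates, reports grand mean ± SD across replicates, and compares two
conditions with a two-sided unpaired equal-variance Student's t-test
(Welch available behind a flag); stars at p < 0.05/0.01/0.001.

## The simulator

The generator emulates immunostained membrane sheets imaged by STED:

* **Point process.** A fraction 1 − `crowd_fraction` of assemblies is
  homogeneous Poisson ("complete spatial randomness") with total
  density `density_per_um2`; the rest follows a Thomas-type process —
  parent (crowd) centres CSR, Poisson(`assemblies_per_crowd`) children
  per parent, isotropic Gaussian scatter of scale `crowd_radius_nm`
  (default 450 nm, half the 900 nm counting circle). The real arranged
  crowds are irregular µm-scale architectures; the Gaussian-scatter
  parameterisation is the simplest stand-in, not an inference about
  their geometry. Children falling outside the field are discarded, so
  realised density is slightly edge-deflated.
* **Composition and brightness.** Channel membership (both / A-only /
  B-only) is i.i.d. with default fractions 0.4/0.3/0.3. Integrated
  spot brightness is log-normal (default mean 3000, SD 1500 photons)
  to produce the observed variable brightness; the two amplitudes of a
  "both" assembly are independent, since no inter-channel intensity
  correlation was observed in the data this emulates. Per channel,
  spots are kept with probability `detect_prob` (labelling efficiency /
  epitope shielding); dropped spots remain in the truth table with
  `det_* = false`.
* **Image formation.** Each detected spot is an isotropic Gaussian of
  FWHM `psf_fwhm_nm` (default 80 nm, middle of the 65–100 nm STED
  range) integrated exactly over the pixel grid; pixels record
  Poisson(signal + `background_offset`) + N(0, `read_noise_sd`),
  clipped at zero, quantised to 16 bit. Everything is a deterministic
  function of the seed; identical configs give byte-identical TIFF and
  CSV outputs.

Default calibration choices: total density 6/µm² so each channel
carries ~4.2/µm² of assemblies (3–5 clusters/µm² is the observed
per-channel range); background offset 2 a.u. with read noise 1 a.u.,
placing the 4 a.u. noise tolerance well above the blurred shot-noise
fluctuation — the regime in which most detected maxima pass the R²
criterion and noise maxima are a minority, as in the real data. At a
10× higher background the simulated images would contain an order of
magnitude more noise maxima than real micrographs show relative to
cluster density.

What the simulator does *not* model: 3D PSF, drift, vignetting,
antibody linkage error, irregular crowd shapes, fluorophore blinking
or saturation, spatially varying background. Passing tests therefore
demonstrate the correctness of the estimators under the stated point-
process and noise model, not robustness to every artefact of real
micrographs.

## Validation strategy and problem sizes

Every algorithmic core has an independent oracle in the test suite:
the maxima finder against a labelling-based reference on random
images; distances and crowding counts against all-pairs enumeration;
CSR statistics against closed forms (nearest-neighbour CDF
1 − exp(−λπr²), chance overlap at 60 nm ≈ 4.4% at λ = 4/µm², mean
count λπ(0.45 µm)²); the t-test against its textbook value. End-to-end
recovery is checked on 10.24 µm fields (512² px) at composition
fractions 0, 0.4 and 1, where the measured cluster overlap must track
the truth composition plus analytic chance overlap; mixture recovery
is checked on count samples of 500–5000 maxima (error shrinking with
n, within ±0.05 of the true 32% crowded fraction at n = 5000). These
sizes keep the whole suite around a minute while leaving estimator
standard errors well inside the asserted tolerances.

## Known limitations

* Sub-pixel mass centres are shrunk toward pixel centres by the fixed
  13-px window (see above); absolute localisation is good to ~0.2 px,
  relative (cross-channel) localisation considerably better.
* FWHM reports the PSF for any emitter at or below the resolution
  limit.
* The detector's plateau handling and tie-breaks are normative
  conventions; other implementations may differ on exactly-equal
  values.
* Densities on small fields are biased low unless renormalised to the
  classifiable interior area.
* The two-Gaussian decomposition assumes the count histogram is well
  described by normals on the integer axis; at very low means the
  zero-truncation of counts distorts the background component.
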