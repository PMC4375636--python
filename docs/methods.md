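# Methods

## The intensity-transition model

The detector treats quantized white-matter intensities as the state space of
a pairwise stochastic process. Intensities inside the white-matter mask are
clipped to a percentile range (default 1–99, computed over in-mask pixels
only), rescaled to `[0, 1]`, and binned into `N + 1` equal-width states
(half-open bins, last bin closed, so the map is total and bit-reproducible).
Working in states makes the detector invariant to affine intensity changes —
scanner gain and per-slice brightness offsets drop out.

For an 8-connected in-mask pixel pair, the conditional probability that one
pixel sits `k` states below the brighter one is modelled as `q·α^k`. The
probabilities of all drops from the top state must sum to one, which by the
geometric series forces

    q·α^(N+1) − α + (1 − q) = 0.

`α = 1` always solves this but violates the normalization; the model uses the
unique root strictly inside `(0, 1)`, which exists iff `q > 1/(N+1)`. The
root is found by a sign-change scan over `(0, 1)` followed by bracketed
Brent/bisection refinement (absolute tolerance ~1e−12): on a bracketed
monotone segment this converges unconditionally, and the method never sees
the polynomial's complex roots. An infeasible `(q, N)` pair raises an error
naming both values rather than returning a boundary root.

The drop distribution is symmetric by convention: a darker→brighter
transition is the mirror of the brighter→darker one with identical
probability `q·α^|Δ|`. Only the brighter member of a rare pair seeds region
growth, because WMI is hyperintense on T1.

**Estimating q.** `q` is the probability that two adjacent in-mask pixels
share a state, estimated as the fraction of unordered 8-connected in-mask
pairs with equal states (each pair counted once). An estimate of exactly 0
or 1 is clamped into the open interval by `1/(P+1)` for `P` pairs, with a
warning, so the root solve stays defined. The estimator is validated against
exhaustive pair enumeration.

## Detection pipeline

1. **Mark boundaries.** Every 8-connected in-mask pair with
   `q·α^|Δstate| < threshold` (default 0.01) is flagged; both pixels enter
   the boundary set and the strictly brighter one becomes a growth seed.
   Because the drop distribution is strictly decreasing, the significant
   set is "all drops of at least the minimal rare drop".
   An optional calibration (`calibrate_threshold`) instead takes the
   empirical f-quantile (default f = 0.001) of observed pair probabilities
   over the whole mask.
2. **Remove margin false boundaries.** Pixels whose Euclidean distance to
   the nearest out-of-mask pixel (image border counts as out-of-mask) is
   ≤ `margin_px` (default 2) are discarded — transitions at the mask border
   are dominated by partial-volume mixing with grey matter, not injury.
   Surviving 8-connected boundary components smaller than `min_boundary_px`
   (default 3) are then dropped. The two filters are independently
   configurable because border proximity and component size address
   different failure modes.
3. **Grow regions.** Seeds are processed in deterministic row-major order,
   skipping seeds already absorbed. Growth is breadth-first over 8-connected
   in-mask pixels on the *stretched* intensities: candidate `p` joins region
   `R` when `|I(p) − mean(R)| / sd(R) < growth_fraction` (default 0.5;
   population sd, updated incrementally after every accepted pixel). While
   `R` has fewer than 4 pixels or `sd(R) < 1e−6` the ratio is undefined, and
   a candidate is accepted only if its quantized state equals the seed's
   state — the natural zero-tolerance reading of the similarity criterion.
   Setting `growth_fraction = 0` exactly disables growth (seeds only); this
   takes precedence over the degenerate-sd rule so the strict inequality's
   limit behaviour is honoured. Each region is capped at `max_region_px`
   (default: 10% of the mask area) so a mis-set fraction cannot silently
   flood the mask; hitting the cap is reported, never silent. Touching
   regions merge in the final 8-connected labelling.

The whole pipeline is deterministic: identical inputs and configuration give
identical masks and reports, and every run report embeds the fully resolved
configuration.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `n_states` | 7 | states `s_0…s_6`; small enough to be robust to noise, fine enough to resolve lesion contrast |
| `clip_percentiles` | (1, 99) | robust stretch; hot pixels cannot collapse the dynamic range |
| `threshold` | 0.01 | rare-transition cutoff; 0.05 is a more sensitive alternative |
| `margin_px` | 2 | border exclusion band; set ≥ the expected grey-matter rim width |
| `min_boundary_px` | 3 | smallest credible boundary component |
| `growth_fraction` | 0.5 | acceptance band in region-sd units |
| `max_region_px` | 10% of mask | safety cap per region, reported when hit |

The threshold and growth fraction are operating-point choices a site would
tune against a few expert-delineated slices; the defaults are sensible
starting points, not clinical constants.

## Synthetic phantoms

Patient data cannot ship with the package, so every stage is exercised on
synthetic 2D phantoms that emulate exactly the features the detector relies
on:

- a compact irregular white-matter region (perturbed ellipse, axes 34×40 px
  on a 128×128 grid, ≈ 4300 px);
- smooth background shading inside it (random planar tilt plus one broad
  Gaussian bump, amplitude 0.02 around a base intensity of 0.5): normal
  unmyelinated white matter on early T1 is fairly homogeneous, so the
  shading is deliberately mild relative to lesion contrast;
- additive Gaussian noise of sd 0.01 with a correlation length of 2.5 px
  (white noise smoothed and rescaled to the exact target sd), matching the
  in-plane smoothness of reconstructed MR data — truly independent
  per-pixel noise would make adjacent-pixel transitions far rougher than
  real tissue;
- bright punctate lesions (exact discs or radially warped "blobs") of known
  centre, radius and area, with contrast specified as a multiple of the
  noise sd and added on top of the local background, so the in-lesion minus
  surrounding mean difference is calibrated to the requested contrast;
- optionally a bright rim along the mask border emulating grey-matter
  contamination from an imperfect white-matter segmentation.

Ground truth is derived only from the lesion specifications, never from the
noise draw, and the generator is fully deterministic per seed. Batch suites
(`generate_suite`) assign lesions to the first `round(prevalence·n)`
phantoms; lesioned phantoms carry 2–5 lesions (punctate WMI is
characteristically multi-focal), radius 3–5 px, contrast 5–8× the noise sd,
placed clear of the margin band, with clustered placement half of the time.

**What phantom results do and do not show.** The fixed-seed suite
establishes that the implementation detects every injected lesion at the
contrast ≥ 5×sd / radius ≥ 3 px operating point, stays empty on at least
18 of 20 lesion-free slices, and that margin filtering removes rim false
positives. These are properties of the algorithm under controlled
conditions, not clinical performance figures: the phantoms contain no
anatomy, no bias field, no Rician noise floor, no partial-volume texture,
and their lesion contrast distribution is assumed rather than measured. A
known boundary case is intrinsic to the method, not the phantom: with
percentile stretching, a lesion of sub-percentile area sitting on the very
brightest background can be clipped into the top state together with its
surroundings and lose its local transition signature. Multi-focal lesion
loads (which themselves contribute to the upper intensity percentiles) make
this configuration rare; it would equally affect clinical slices whose
injury lies in the brightest normal-appearing tissue.

## Evaluation machinery

- **Accuracy-distance histogram**: Euclidean distance (via the distance
  transform of the ground-truth mask) from each detected pixel to the
  nearest truth pixel, rounded half-up to integers; distance 0 means inside
  the truth. Mass is conserved (counts sum to the detected pixel count);
  detections with an empty ground truth land in a distinguished "no-truth"
  bucket. Whether to round or take the ceiling is a free choice at the bin
  boundary; rounding half-up is used consistently.
- **Bland–Altman**: per-case mean `(auto+gt)/2` and difference `gt − auto`;
  bias is the mean difference and the limits of agreement are
  `bias ± 1.96·sd` with the sample sd (ddof = 1, requiring ≥ 2 cases). The
  sign convention is fixed and asserted in tests: a detector that hugs the
  bright lesion core under-segments relative to expert delineation, giving
  a positive bias.
- **Binned difference table**: cases bucketed along the mean-area axis into
  `[k·w, (k+1)·w)` bins with per-bin mean difference and count; empty bins
  omitted. Areas come from pixel counts times the pixel spacing
  (`area_cm2`), taken from the NIfTI header or supplied explicitly for
  raster formats.

## Known limitations

- Strictly 2D: no 26-connectivity volumetric extension, no multi-slice
  consistency.
- The white-matter mask is an input (manual or external segmentation); the
  detector inherits its errors, and grey matter included in the mask
  produces border false positives by design (mitigated by `margin_px`).
- The transition model is pairwise only — no Markov dynamics along pixel
  paths and no distance-indexed transitions for non-adjacent pixels.
- `q` is estimated per slice; very small masks (few hundred pairs) give a
  noisy estimate, and masks with no adjacent pairs are rejected.
- Lesions darker than their surroundings (T2-like contrast) are out of
  scope: seeding assumes bright injury.
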