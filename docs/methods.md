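# Methods

## Detection model

The detector assumes a single-band thermal raster in °C on a projected,
meter-unit grid, stored north-up: row 0 is the northernmost row and the
center of pixel (r, c) maps to world coordinates
(origin_x + (c + 0.5)·g, origin_y − (r + 0.5)·g) with g the ground sampling
distance (GSD) in meters. Only rasters of this form are accepted; there is
no on-the-fly reprojection, because all area thresholds are in m². Without a
full CRS database, the package stores CRS identity as an EPSG code and
rejects the common geographic (degree-unit) codes; responsibility for
supplying a projected CRS rests with the user.

**Thresholding** selects pixels with T ≥ T₀ (inclusive). T₀ is the one
site-specific input: it should sit below seal surface temperature and above
warm landscape. Nodata and NaN cells are never selected. Exclusion masking
uses pixel-center point-in-polygon semantics (a pixel is removed iff its
center lies in a mask polygon, boundary included): deterministic, idempotent,
and the convention of common GIS raster masking. Partial-coverage weighting
is deliberately not used.

**Clustering** uses rook (4-) connectivity by default — the behavior of the
usual GIS raster-to-polygon conversion, where diagonal-only neighbors form
separate polygons — with queen (8-) connectivity available everywhere the
connectivity appears. No polygon simplification is applied, so the polygon's
geometric area equals pixel_count·g² exactly, and that product is what the
classifier uses. No minimum cluster size is enforced: a single hot pixel is
a legitimate YOY detection at 8 cm GSD, and winnowing would delete real
pups.

**Solidity** (polygon area / convex-hull area) is computed on the rasterized
polygon; holes subtract from the polygon area but not from the hull.
Rasterized convex bodies score high (> 0.9 for bodies of ≥ 100 pixels);
irregular multi-animal outlines score lower.

**Classification** applies the rule table in the fixed precedence
individual YOY → individual adult → YOY aggregation → adult aggregation,
first match wins. The printed rules overlap in places and leave gaps (the
strict/non-strict asymmetry between "≤ 0.85" for individuals and "< 0.85"
for aggregations; a polygon with mean temperature exactly at the split
matches neither "< T\*" nor "> T\*"), so precedence plus an explicit
`unclassified` outcome make the mapping total and deterministic.
Individuals-first matches the pipeline's logic, where aggregations are the
residual routed to splitting; unclassified polygons are excluded from counts
but written out and logged with their attributes rather than silently
dropped. Inequalities are implemented exactly as printed.

Cross-site transfer: `ClassificationParams.for_site(t0, mode="complex")`
sets the temperature offset to t0 − 9.0 (the difference from the training
threshold), reproducing the −3.5 °C shift used when moving from a 9 °C to a
5.5 °C site; the offset can be passed explicitly to decouple the two.

## Aggregation splitting

The high-pass kernel defaults to the standard 3×3 GIS high-pass (center
6.8, edge −1.0, corner −0.7; zero-sum, positive center) and is fully
configurable — the exact kernel used to train the original rule set is not
public, and any zero-sum positive-center 3×3 kernel preserves the sign
structure the splitter relies on.

The filter is evaluated on the aggregation's own temperatures: within the
footprint's bounding box, cells outside the footprint are filled with their
nearest footprint value before convolution (`high_pass` applies the same
nearest-valid fill to nodata cells, and replicates the grid edge). Filtering
the raw scene instead would be dominated by the body-to-ambient edge: the
footprint rim forms one strongly positive connected ring, every aggregation
yields a single component, and the splitter never separates anything. With
the footprint-extended field the response reflects only internal structure —
positive at member cores, negative along cooler seams.

Selection keeps footprint cells with response strictly greater than zero, up
to a floating-point guard of 1e-9·(1 + max |T|): a zero-sum kernel over a
flat region returns summation roundoff of either sign rather than exact
zero, and strict > 0 would otherwise promote O(1e-15) noise into
components. Components are extracted at the detection connectivity, each
becomes an individual with the class implied by its parent (adult
aggregation → adults, YOY aggregation → YOY), and a footprint with no
positive response — e.g. a perfectly uniform blob — falls back to one
individual covering the aggregation, since a warm object above threshold is
at least one animal. Split components are re-measured (area, mean
temperature, solidity) but not re-classified; their `parent_id` records the
source aggregation.

## Accuracy assessment

Human annotation points carry GPS error, so points within the snap radius
(default 0.5 m) of a prediction polygon are moved to the nearest location
within the nearest polygon (nearest boundary wins; ties broken by lowest
polygon id; points already inside, or farther than the radius from every
polygon, are untouched — making snapping idempotent). The spatial join then
assigns each point to the lowest-id polygon covering it, so every point is
counted exactly once. Per prediction polygon: points of both classes →
"adult and juvenile pair" (a mother beside her pup merged in one
aggregation); a matching-class point → true positive; only other-class
points → confusion with the source aggregation when the polygon was carved
from one, otherwise plain cross-class confusion; no point → not detected by
humans. A polygon holding several own-class points still counts once — it is
a single prediction. The four prediction-side categories partition each
class's predictions, so their proportions sum to 1; points covered by no
polygon are tallied as missed by the model per class.

## Synthetic scenes

The generator emulates what the detector assumes about a winter colony
survey, with these defaults (all configurable):

- grid: 8 cm GSD, 40 m × 40 m extent, UTM-style projected coordinates;
- background: ambient 0 °C with 0.8 °C i.i.d. Gaussian spatial noise —
  far enough below the 9 °C threshold that a false-positive background pixel
  is a > 11σ event;
- landscape confounders: a few smooth warm patches peaking 3–5 °C above
  ambient, i.e. below threshold, as sun-warmed ground is at dawn;
- seals: rasterized ellipses with uniform body surface temperature,
  YOY 12–14 °C over 0.25–0.60 m², adults 13–16 °C over 1.2–3.0 m²
  (aspect ratios 1.4–2.2 and 2.0–3.0). Isolated footprints are kept ≥ 2
  pixels apart;
- aggregations: members chained along a sharply zigzagging path
  (alternating ±85–115° turns) with steps short enough that neighboring
  bodies overlap, so the merged footprint is irregular (solidity typically
  0.70–0.78). All members of a huddle share one base surface temperature —
  touching bodies are thermally coupled, and a base-temperature step between
  members would itself read as an edge to the filter. Each member adds a
  truncated Gaussian core (peak +3 °C, support cut at 2σ with σ ≈ 0.45 of
  the body half-width, rescaled to zero at the cutoff) so the field equals
  the shared base near the footprint rim; an optional additional seam
  depression along the inter-member equidistance band defaults to 0 °C
  because the saddle between cores already cools the seam, and a narrow
  subtracted groove would add spurious positive response on its flanks.

One global random stream drives everything, consumed in a fixed order
(background → patches → isolated YOY → isolated adults → aggregations);
identical (config, seed) is bit-reproducible, but reproducibility under
config edits is not promised. Placement is by bounded rejection sampling;
infeasible densities raise an error reporting the occupied fraction.

The generator intentionally omits much of real thermal imagery: no
photogrammetric mosaicking artifacts, no atmospheric or emissivity effects,
no within-body temperature texture beyond the aggregation cores, no partial
(mixed) boundary pixels, and landscape that never crosses the detection
threshold. Passing tests therefore demonstrate that the pipeline's logic is
correct under its own assumptions — exact recovery on clean scenes, correct
splitting of cored huddles — not that field imagery of arbitrary quality
will be counted exactly.

## Problem sizes and tolerances

The test suite and the acceptance script use scenes of 40–80 m at 8 cm GSD
(500–1000 pixels on a side), 20-seed recovery sweeps, and 100 aggregation
trials; the whole suite runs in seconds on one CPU, and these sizes already
exercise every code path at realistic animal densities. Geometry
comparisons use 1e-9 m tolerances; the high-pass "annihilates constants"
check allows 1e-10 °C of convolution roundoff; classification boundary
audits probe each printed threshold at ±1e-9.

## Known limitations

- Split components are not re-classified by size, so an adult lying inside
  a YOY aggregation is counted as a YOY (and vice versa); a second round of
  size analysis would be needed to fix this.
- Solidity-based aggregation detection is scale-sensitive: large GSD changes
  alter rasterized solidity and hence which polygons reach the splitter.
- Compact huddles can score solidity ≥ 0.8 and be misread as a single large
  individual; the rule set has no remedy, and such cases surface in the
  accuracy table as class confusions.
- Single-species scenes are assumed; any similar-sized homeotherm would be
  counted as a seal.
- Mask input is GeoJSON (no shapefile reader among the dependencies);
  detections are written as GeoJSON only.
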