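# Methods

## Measurement model

The size estimator assumes a pinhole RGB camera with square pixels and no
lens distortion. The built-in `d415-vga` profile models the RealSense D415
RGB camera at 640×480: focal length 1.88 mm, sensor die 2.73 × 1.55 mm,
pixel pitch 1.55/480 mm, so the crop's active sensor area is
2.07 × 1.55 mm. Pixel coordinates are 0-based with pixel centres at
integer coordinates (the COCO convention); the principal point is taken at
the image centre ((W−1)/2, (H−1)/2).

A pixel chord `lp` between two keypoints maps to the sensor as
`ls = pitch · lp` and to the world as `lr = ls · d / f`. The radius
correction replaces the flat-object scaling: the Left/Right and Top/Bottom
keypoints lie on the widest cross-section, which — for a circular
cross-section of diameter D — sits D/2 behind the centre-point depth `d`
returned by the depth map. Solving `D/Ds = (d + D/2)/f` yields
`D = d·Ds/(f − Ds/2)` and `L = d·Ls/(f − Ds/2)`. The length denominator
deliberately uses the *diameter* chord `Ds`, because the depth offset of
the measured section is set by the cross-section radius regardless of
which chord is being scaled; this is algebraically identical to
`L = Ls·(d + D/2)/f`. The correction degenerates when `Ds ≥ 2f`
(a subtense outside the model's validity) and the estimator raises
instead of returning a value.

Lengths are chords, not arc lengths: a curved cucumber is under-measured
by construction. Working depths below 310 mm are rejected by the synthetic
scene generator because the stereo camera cannot produce depth there at
VGA resolution. All distances are millimetres end to end; human-readable
summaries that use centimetres label them.

Depth for a measurement is taken at the Center keypoint of the (possibly
zoom-reverted) detection, on the repaired depth map, with nearest-cell
lookup — bilinear interpolation would blend across the object/background
discontinuity and bias the depth at silhouette edges. If the centre cell
is still invalid the pipeline falls back to the median of valid depths
inside the detection box and flags the estimate.

## Depth repair

`spatial_filter` is an edge-preserving exponential smoother: each
iteration sweeps the grid left→right, right→left, top→bottom, bottom→top;
a pixel blends `alpha·current + (1−alpha)·previous` only when both values
are valid and within `delta` of each other. Defaults `alpha = 0.5`,
`delta = 20 mm`, 2 iterations: strong enough to suppress the few-mm sensor
noise, while 20 mm is far below any object/background depth gap at the
300–1600 mm working range, so silhouette edges survive exactly. Holes are
never created, consumed or used as sources.

`hole_fill` is directional by design: stereo matching referenced to the
left camera loses depth on an object's *left* edge, so the first valid
pixel to the right of a hole belongs to the occluding object surface.
Remaining holes (none valid to the right) fall back to the nearest valid
value to the left, then to the nearest valid pixel in flat scan order;
an all-invalid map is returned unchanged with a warning flag.

Alignment between the depth and colour frames deprojects every valid
depth pixel, applies the depth→colour rigid transform, reprojects, and
resolves collisions by keeping the smallest depth (the nearer surface
occludes). Filtering runs *after* alignment in the pipeline, so the
filter's edge gate operates in the same frame the measurements use.

## Zoom-in loop

Magnifications M = α^k are evaluated while M ≤ cap (defaults α = 1.2,
cap = 5, giving the nine scales 1.2⁰ … 1.2⁸). The zoomed frame is the
central (W/M)×(H/M) region bilinearly resampled to full size; the
coordinate map fixes the image centre, and `revert` is its exact inverse,
so reverted coordinates are sub-pixel accurate. The winning scale is the
one whose detections have the strictly highest total score; ties keep the
smaller M because less interpolation means less blur. Summing *all*
surviving detection scores is the faithful objective; an optional
per-class cap is not implemented because duplicate-box suppression belongs
to the detector. Detections are cached per scale (one detector pass per
M). The depth map is never zoomed — only the colour image — so metric
estimates are invariant to the winning magnification for an exact
detector (verified to 1 % in tests).

## Synthetic study conditions

The synthetic module is the oracle for every other module. Shapes:
tomato and pepper are ellipsoids, cucumber and eggplant are capsules —
the simplest solids with the circular cross-section the correction
assumes. The twelve catalogued standard models (diameters 27–85 mm,
lengths 54–264 mm) define the benchmark sizes. Ground-truth keypoints are
analytic: Left/Right are the endpoints of the widest section
perpendicular to the axis, chosen in the image plane so both share the
centre's Z; Top/Bottom are the axis endpoints; Center is the centroid
projection whose map depth is the front-surface depth (centre Z minus the
cross-section radius); the peduncle is a decorative point 10 % of the
length beyond Top and never enters any equation. Under these definitions
the radius-corrected equations are exact for in-plane axes, so noiseless
recovery error measures only rasterisation and depth-lookup effects
(≈0.003 % MAPE in practice).

Study conditions, fixed once: depths 400–1000 mm in 200 mm steps; "repeated
measurements at different angles" realised as seeded in-plane axis angles
uniform within ±45° of upright plus lateral offsets within ±30 mm;
detector noise of 1 px i.i.d. Gaussian keypoint jitter; 2 mm depth noise;
3 px left-edge occlusion holes; background at 2.5 m with 15 leaf blobs and
8 dark shadow blobs in green hues. The detector-score model is
`s(a) = min(1, a/6000 px²)`, so far objects fall below the 0.6 contract
threshold until zoomed. The grid uses 100 trials per cell for the
jittered-keypoint error envelope (analytic detections, no rasterisation
needed) and 8 rendered trials per cell for the three-method comparison;
these sizes keep the whole suite a few minutes on one CPU while leaving
the compared effects far larger than their seed-to-seed variation.

What the generator does *not* emulate: photometric realism, lighting,
lens distortion, occlusion between vegetables (overlap is warned about,
not modelled), out-of-image-plane axis tilt, and detector failure modes
beyond score decay and coordinate jitter. Passing tests therefore
demonstrate the geometric and algorithmic correctness of the pipeline
under the stated noise model — not detector robustness on real imagery.

## Baselines

The two comparison baselines are deliberately simplified re-creations of
the standard alternatives, present to reproduce the *structure* of the
method comparison, not any particular implementation. The bounding-box
method scales box width/height by `ls·d/f` with no radius correction; the
edge-detection method thresholds colour distance from the image's median
colour, keeps the largest connected component, and measures extents along
and across its principal axis. Both query the same repaired depth map as
the keypoint method and therefore inherit the front-surface depth without
correcting for it — their characteristic bias. On the synthetic leafy
background the colour-threshold segmentation also fails in the authentic
ways: green-on-green objects (cucumber, pepper) fragment, and dark shadow
blobs join or outgrow small distant objects, so the baselines degrade with
depth faster than the keypoint method.

## Numerical and design choices

- Tie-breaks: zoom score ties keep the smaller magnification; equal-depth
  alignment collisions keep the nearer (smaller) value.
- Nearest-cell depth lookup rounds half-integers with banker's rounding
  (NumPy `rint`); the half-pixel case does not occur for detector output.
- The silhouette-based synthetic detector identifies the object axis as
  the PCA major axis when the silhouette elongation exceeds 1.35, else as
  the principal direction closer to vertical. Oblate tomatoes are wider
  than long, so at axis tilts near ±45° the two choices collide and the
  detector can swap diameter and length — an inherent ambiguity of
  shape-only detection that a trained appearance-based detector does not
  share. The measurement grid therefore uses analytic ground-truth
  detections plus jitter; the image detector drives the zoom-loop and CLI
  demonstrations.
- Degenerate inputs are contracts, not crashes: empty trial lists raise
  an undefined-metric error, non-positive truths an invalid-truth error,
  all-zero depth maps return unchanged with a warning, and an empty
  detection list is a valid "nothing found" result (exit code 0).
- Serialisation is deterministic everywhere (sorted JSON keys, seeded
  randomness, fixed CSV float format) so outputs are diffable.

## Known limitations

- The radius correction assumes the depth difference between centre and
  silhouette equals the cross-section radius; strongly non-circular
  cross-sections (bell peppers with deep lobes) violate this.
- Chord-based length under-measures curved fruit.
- One reference source prints a pepper size once in centimetres and once
  in millimetres for the same object; this package standardises on
  millimetres throughout.
- The synthetic detector contract covers score decay and jitter only; no
  attempt is made to train or bundle a neural keypoint detector, and the
  external-detector adapter is a plug-in point (any callable mapping an
  image to detections filtered at score ≥ 0.6).
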