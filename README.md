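# ivote — iterative radial voting for cell nucleus detection

`ivote` locates cell nuclei in 2D images and 3D microscopy volumes by
iterative radial voting. It targets the regime where classical blob
detectors struggle: densely packed tissue imaged in a single channel
(e.g. Nissl/thionine-stained brightfield stacks from high-throughput
serial-sectioning microscopy), where nuclei vary several-fold in size,
touch each other, and often contain a nucleolus that breaks the "solid
blob" assumption. The detector needs a single tuning parameter: the
maximum cell radius *r*, given in micrometers (the per-axis pixel size
makes the result independent of sampling resolution and anisotropy).

## The algorithm

Every pixel is a voter. After an optional Gaussian blur, the image
gradient initializes each voter's weight *M* = |∇I| and direction Θ
(negated for dark-on-light cells so it points toward the cell interior).
Each iteration:

1. **Cast votes** — every voter adds *M*(**t**) to the vote field *V* at
   each lattice site inside its *vote cone*: the region within distance
   *r* of the voter and within angle ϕ/2 of its direction,

       cos∠(**p** − **t**, **d**) > cos(ϕ/2)   and   0 < |**p** − **t**| < r,

   evaluated in physical (micrometer) space. Candidate sites are pruned
   with the tight axis-aligned bounding box of the cone.
2. **Update directions** — every voter re-orients toward the argmax of
   *V* inside its cone; magnitudes are preserved.
3. **Narrow the cone** — ϕ starts at π/2 and is halved each iteration;
   the run stops after the first pass with ϕ < 1/r pixels (the cone arc
   is then narrower than one pixel, so no further information exists).

Votes pile up at centers of radial symmetry. Local maxima of the final
field, subject to a minimum separation of *r*, are the detected centers;
their vote scores can be thresholded manually or automatically (Otsu, by
default on the log-scores). A scale-normalized Laplacian-of-Gaussian
detector is included as the classical baseline, and a validation module
scores detections against ground truth (a detection is a true positive
if it lies within 50% of the maximum radius of an unmatched annotated
center) and integrates precision-recall curves.

A phantom generator produces 2D/3D images with known ground truth in two
flavors — `kesm_like` (dark, dense, partly hollow nuclei on a light
background) and `fluor_like` (bright, sparse, solid nuclei) — so the
whole pipeline is testable end to end without external data.

## Worked example

```sh
$ ivote synth --preset kesm_like --shape 128,128,128 --seed 0 \
        -o phantom.tif --truth truth.csv
phantom written to phantom.tif, truth to truth.csv

$ ivote detect phantom.tif --radius-um 8 --pixel-size 1,1,1 -o dets.csv
INFO ivote.voting: iteration 0: phi=1.5708 rad, vote mass=3.56999e+06
INFO ivote.voting: iteration 1: phi=0.7854 rad, vote mass=923719
INFO ivote.voting: iteration 2: phi=0.3927 rad, vote mass=240579
INFO ivote.voting: iteration 3: phi=0.1963 rad, vote mass=56096.6
INFO ivote.voting: iteration 4: phi=0.0982 rad, vote mass=23007.4
50 detections written to dets.csv

$ ivote eval dets.csv truth.csv --r-max-um 8 --pixel-size 1,1,1
precision=1.0000 recall=1.0000 (tp=50 fp=0 fn=0)
```

The logged vote mass shrinks as the cone narrows (each voter covers
fewer sites) while the votes concentrate at cell centers. All 50 cells
of the phantom are recovered with no false positives at the automated
log-Otsu threshold. Detection CSVs hold 0-based pixel coordinates in
(x, y, z) order plus micrometer coordinates and the vote score.

The same thing in Python:

```python
from ivote import (kesm_like, generate_phantom, iterative_vote,
                   find_local_maxima, threshold_detections, match_detections)

phantom = generate_phantom(kesm_like(seed=0))
votes = iterative_vote(phantom.image, radius_um=8.0)
dets = threshold_detections(find_local_maxima(votes, 8.0), "otsu_log")
report = match_detections(dets, phantom, r_max_um=8.0)
print(report.precision, report.recall)
```

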