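# Methods

## The model

Spatial similarity networking (SSN) rests on one physical premise: product
ions generated from the same precursor inherit that precursor's spatial
distribution across the tissue. In a chimeric isolation window the MS²
signal at every pixel is a superposition of several precursors' fragment
spectra, but each fragment's *image* is (up to noise) proportional to the
image of its parent. Spatial distribution therefore acts as an orthogonal
separation axis — the role retention time plays in chromatography — next
to accurate mass and fragmentation pattern.

Operationally: all product-ion images of one isolation window are scored
pairwise, scores passing a threshold τ become edges of an undirected
graph, and the connected components of that graph are the deconvoluted
precursors. Connected components (rather than modularity or density-based
clustering) make the partition deterministic, parameter-free beyond τ, and
guarantee that every ion belongs to exactly one cluster; singlets are kept
and flagged, since an unclustered ion is still annotatable by fragmentation
rules. Raising τ can only refine the partition (edges are removed, never
added), which the test suite asserts on seeded random matrices.

The parallel-image-acquisition (PIA) model is deliberately plain
arithmetic: ion utilization is accumulation time over transient time;
coverage is N lists × n windows per list; the MS² x-pixel is N× the FT
x-pixel because list k only revisits every Nth x position. The schedule
builder assigns pixel (r, c) list c mod N, so over any N consecutive
x positions every window is scheduled exactly once.

## Similarity metrics

* **cosine** (similarity, edge iff score ≥ τ): scale-invariant, hence the
  default and the right choice when comparing runs acquired under
  different conditions. Computed over jointly valid pixels; an all-zero
  image is degenerate, scores 0 against everything, and is reported rather
  than dropped.
* **SSE / MSE** (dissimilarity, edge iff score ≤ τ): retain absolute
  intensity differences. By default each image is normalized to unit
  maximum first, so one τ is meaningful across ion pairs of very different
  abundance; the normalization is explicit in `MetricSpec` and switchable
  (`none`, `unit_max`, `unit_norm`).

Ties at exactly τ are inclusive, making the edge rule a closed condition.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| similarity threshold τ | 0.90 | — | high enough to separate disjoint-region species (cosine between disjoint supports is 0), low enough to tolerate moderate shot noise |
| MS² m/z tolerance | 0.3 | Th | ion-trap unit resolution |
| FT precursor tolerance | 3 | ppm | separates isobars ~2–3 mDa apart near m/z 800 (e.g. a +Na vs +H pair differing by 2.4 mDa) |
| patch size p | 4 | pixels | averages ~16 pixels, enough to damp single-pixel spikes without erasing anatomical structure; p = 1 reduces to plain SSN |
| patch pooling | mean | — | median also available; mean keeps weak coherent signal |
| product-ion binning | 0.5 | Th | one ion-trap nominal-mass bin |
| detection floor | 1 % of base bin, ≥ 5 % of pixels | — | mirrors the recovery criterion used for deconvoluted-vs-standard comparison |

Adduct shifts include the electron mass (+H = 1.007276 Da); library
precursors are recomputed from formula + adduct at load time and must
agree with the stored value within 1e-4 Th.

## Cluster reproducibility

Replicate cluster sets are compared by Jaccard index after matching ion
m/z values across datasets (greedy nearest within 0.3 Th; unmatched ions
stay in the union). For more than two replicates both readings are
implemented: the multi-way intersection-over-union (the headline value;
three sets sharing 17 ions with a 19-ion union give 17/19 = 0.895) and the
list of pairwise Jaccards.

## The synthetic generator

The generator emulates the *structure* of a PIA MS²I run, not an
instrument: named regions (band, disk, full field, complements, optional
linear gradients) stand in for anatomical features; each species has a
precursor m/z, an abundance (counts), and fragments with fixed relative
intensities; each pixel contributes one FT survey spectrum (locally
present precursors) plus its inclusion list's MS² spectra, chimeric where
regions overlap. Noise has three knobs:

* shot noise — Poisson sampling of every expected peak count;
* baseline — Poisson-many spurious peaks per spectrum, uniform in m/z,
  exponential intensities (defaults: mean 2 peaks, scale 30 counts against
  a species abundance of 1000);
* dropout — with probability 0.05 per pixel, a weak fragment (relative
  intensity ≤ 0.25) is unrecorded; this is the mechanism that leaves
  low-S/N ions as singlets at high τ.

What the generator does **not** model — and therefore what passing tests
do not establish about real data: isotope envelopes, charge states > 1,
peak shape and resolution, ion suppression/matrix effects, stage-speed
distortion of the raster, and realistic tissue texture. Fragment peaks are
exact centroids (5-decimal m/z for FT, 4 for IT). Runs are written as
minimal centroided mzML 1.1 with uncompressed 64-bit float arrays, so peak
values round-trip bit-identically; the reader additionally accepts 32-bit
and zlib-compressed arrays.

All randomness flows through one `numpy` generator seeded per run, so a
run is byte-reproducible; the ground truth (fragment→species map, region
masks, expected partition) depends only on phantom and species, never on
the noise seed.

## Numerical and design choices

* Pixel convention: 0-based, row-major; row = scan line, column = position
  along the scan direction; the first acquired spectrum is (0, 0). Line
  segmentation comes from an explicit line-break list (deterministic), not
  from retention-time gaps.
* MS² channels are ceil(width/N) columns wide; a trailing column a list
  never visits is masked invalid. A pixel acquired without the target peak
  scores 0 and stays valid; only never-acquired pixels are excluded from P.
* Profile-mode spectra are rejected rather than centroided.
* Patches straddling the valid-pixel mask pool only valid pixels; a patch
  with no valid pixel is masked.
* Candidate ranking for annotation is lexicographic: fraction of
  diagnostics matched, then fraction of the cluster explained, then
  smallest |precursor ppm|; ties are kept in rank order, not broken
  silently.
* Confidence Level 4 is never auto-assigned: the rubric between Levels 3
  and 5 is exposed as a user-supplied predicate, because its defining
  evidence is institution-specific.
* The bundled library (`data/synthetic_demo_library.tsv`) is a synthetic
  fixture: real formulas and adduct masses, diagnostic ions partly derived
  from sodiated-PC head-group rules (−59.0735 trimethylamine, −183.0660
  phosphocholine, −59.0735−FA per chain) and partly invented so that demo
  species are separable at ion-trap resolution.

## Problem sizes

The test suite and the acceptance script use phantom grids of 10×12 to
16×24 pixels with one isolation window (a few hundred spectra per run),
20 seeds for the exact-recovery sweep, and two noise realizations for the
reproducibility check; the exhaustive component-oracle comparison covers
200 random graphs of up to 8 nodes plus 100 random 15-node graphs. These
sizes give stable statistics for the properties checked while keeping the
default runs fast; all of them scale up by passing a larger `shape` or
more seeds.

## Known limitations

* Only singly-charged cation adducts (+H, +Na, +K, +Ag) are built in.
* The rule-based fragment generator covers sodiated/protonated PC head
  groups only; it is a convenience, not a lipid fragmentation engine.
* mzML support is the subset described above (no imzML, no vendor
  formats, no profile data).
* Pixel registration assumes a uniform raster; continuous line-scan
  time-to-position correction is out of scope.
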