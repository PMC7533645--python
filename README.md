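# cortiparcel

Connectivity-driven subdivision of coarse anatomical cortical parcels.

Given per-subject tractograms (TRK/TCK), a fiber-bundle atlas (named bundles
of 21-point fibers with per-bundle distance thresholds and region
annotations) and a shared labeled cortical mesh (GIfTI or OBJ + text labels),
the pipeline:

1. **segments** each tractogram against the bundle atlas by maximum
   corresponding-point distance (orientation-invariant, per-bundle
   thresholds);
2. **intersects** each segmented fiber's extremities with the mesh
   (Möller–Trumbore rays with a nearest-triangle fallback, grid-accelerated
   but exact);
3. **filters** fibers whose end-triangle labels contradict their bundle's
   region pair and aligns fiber orientation to the bundle centroid;
4. **parcellates**: each bundle extremity seeds a sub-parcel; per-triangle
   counts are accumulated over the endpoint's vertex-neighborhood across all
   subjects (clipped at region boundaries), normalized into probability
   maps, size-filtered, and merged within each region via maximal cliques of
   the density-center overlap graph; the most probable label per triangle
   yields a hard parcellation;
5. **post-processes** the label field: small connected components are
   reassigned to their second most probable label, then one morphological
   opening is applied;
6. **evaluates** reproducibility via binary connectivity matrices and
   pairwise Dice over subjects, parcellation-vs-parcellation similarity with
   best-match Dice binning, coefficient of variation, and
   volumetric-label-to-mesh mapping.

A fully controlled synthetic cohort generator (labeled icosphere, bundle
atlas with known ground-truth footprints, jittered/flipped subject
tractograms with rejected distractors) makes every stage testable offline.

## CLI

```sh
# generate a synthetic cohort directory
cortiparcel simulate --out cohort/ --subjects 10 --seed 1

# full pipeline (stages 1-6) with optional connectivity evaluation
cortiparcel run-all --cohort cohort/ --out parcellation/ --evaluate

# individual stages
cortiparcel segment   --tractogram cohort/subjects/subject_000.tck \
                      --atlas cohort/atlas/ --out segmented/
cortiparcel intersect --tractogram ... --atlas ... --mesh cohort/mesh.obj \
                      --labels cohort/labels.txt --out intersections.tsv
cortiparcel filter    --tractogram ... --atlas ... --mesh ... --labels ... \
                      --intersections intersections.tsv --out filtered.tsv
cortiparcel parcellate  --cohort cohort/ --out parc/
cortiparcel postprocess --cohort cohort/ --parcellation parc/ --out final/
cortiparcel evaluate    --cohort cohort/ --parcellation final/ --out eval/
```

Thresholds (`size_thr`, `dc_thr`, `idc_thr`), the endpoint search radius and
ray extension live in a TOML config (`--config cfg.toml`); defaults are
(0.10, 0.15, 0.10), 3 mm and 2 mm.

## Layout

```
src/cortiparcel/
  data_model_io.py        domain types, TRK/TCK + GIfTI/OBJ IO, adjacency, resampling
  bundle_segmentation.py  fiber-to-bundle classification (stage 1)
  mesh_intersection.py    endpoint/triangle location (stage 3)
  fiber_filtering.py      anatomical filtering + alignment (stage 4)
  cortex_parcellation.py  sub-parcel construction and clique merging (stage 5)
  parcel_postprocessing.py  component cleanup + opening (stage 6)
  evaluation.py           connectivity matrices, Dice, CV, volume mapping
  synthetic_cohort.py     ground-truth cohort generator
  pipeline.py, cli.py     orchestration, manifest, command line
tests/                    unit + property + acceptance suites (oracles in tests/oracles.py)
scripts/acceptance.py     property-based acceptance report
```
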