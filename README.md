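# serialreg

Fully automatic, robust 3D registration of serial-section microscopy image
stacks: pairwise coarse-then-elastic 2D registration applied sequentially and
bidirectionally outward from a reference section, guarded by a
deformation-field validation model, plus a quantitative registration-accuracy
metric and a synthetic deformed-sequence generator.

The pipeline per neighboring pair:

1. **Normalization** — per-channel percentile saturation contrast stretch.
2. **Feature extraction** — grayscale sections pass through; RGB histology is
   deconvolved in optical-density space with a row-normalized stain matrix
   (H&E by default) and the eosin channel becomes the feature image.
3. **Coarse global alignment** — difference-of-Gaussian keypoints with
   descriptors, ratio-test matching, seeded RANSAC consensus (translation /
   rigid / similarity / affine).
4. **Elastic refinement** — bidirectional cubic B-spline deformation fields
   optimized coarse-to-fine to minimize a four-term energy: image similarity
   (both directions), divergence and curl regularization, and forward/backward
   consistency.
5. **Validation** — the mean geometric deformation of the total field is
   compared against a user threshold `alpha`; rejected pairs pass the original
   section through unchanged, containing accumulated over-deformation.

Stack accuracy `R` is the mean over consecutive pairs of the fraction of
bright pixels (>= `t`, default 200) of one section, inside the pair's common
foreground, that are also bright in its neighbor.

## CLI

```bash
# generate a synthetic deformed 10-section sequence
serialreg synth seq.tif --n 10 --size 512 512 --magnitude 8 --seed 0

# evaluate accuracy of a stack
serialreg evaluate seq.tif --t 200 --json

# register a stack (multi-page TIFF in, TIFF + JSON report out)
serialreg register seq.tif registered.tif --alpha 50 --evaluate

# orthogonal reslice for qualitative continuity inspection
serialreg sideview registered.tif view.png --axis y --position 256
```

Input stacks are multi-page TIFFs or directories of numbered TIFF/PNG
sections (natural numeric order, `s2` before `s10`). All tunables live in a
YAML config (`--config`), e.g.:

```yaml
stack: {alpha: 50.0, reference: middle}
elastic: {spacing_px: 16, pyramid_levels: 3, w_img: 1.0, w_div: 0.1, w_rot: 0.1, w_cons: 1.0}
coarse: {model_class: similarity, ratio: 0.8, inlier_tol: 3.0, seed: 0}
metric: {t: 200}
```

CLI flags override the file. Useful `alpha` ranges depend on the data; as a
guide: ssTEM VNC 20-200, ssTEM neuropile 30-95, renal histology 200-350,
confocal brain 10-30. `alpha: 0` rejects every pair (bit-exact pass-through).

## Layout

- `src/serialreg/imaging_io.py` — stack I/O, size conforming, reslicing
- `src/serialreg/preprocess.py` — normalization, OD stain deconvolution
- `src/serialreg/coarse_registration.py` — DoG keypoints, matching, RANSAC
- `src/serialreg/bspline.py` — cubic B-spline deformation fields
- `src/serialreg/elastic_registration.py` — bidirectional elastic energy + optimizer
- `src/serialreg/stack3d.py` — sequential bidirectional chains + validation
- `src/serialreg/metrics.py` — pair/stack accuracy metric
- `src/serialreg/synth.py` — synthetic sequence generator
- `src/serialreg/config.py`, `src/serialreg/cli.py` — configuration and CLI
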