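# txmkit

A scriptable Python toolkit for evaluating full-field transmission X-ray
microscopy (TXM) data:

- **Mosaic stitching** — motor-position seeding, phase-correlation refinement
  of tile offsets (global least squares), feathered weighted-average blending.
- **Dual-energy (2E) elemental mapping** — magnification correction from the
  zone-plate optics model, phase-correlation alignment, optical-density
  subtraction of below/above-edge images.
- **Tomography** — parallel-beam forward projector, filtered back projection
  (Ram-Lak / Shepp-Logan / Hann filters, ROI reconstruction), iterative
  Kaczmarz ART, projection jitter correction, rotation-center finding.
- **XANES spectro-imaging** — per-pixel edge-jump maps and noise filtering,
  pre/post-edge regression normalization with slope filtering, half-height
  edge-energy maps and histograms, non-negative least-squares linear-combination
  fitting with R-factor maps, and edge-jump-weighted RGB phase maps.
- **Phantoms** — seeded synthetic generators (Shepp-Logan, XANES stacks with
  full truth bundles, mosaic tile sets, projection series) used by the entire
  test suite; no instrument data is required anywhere.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (registration
accuracy, reconstruction error bounds, mosaic stitch fidelity, XANES
parameter recovery, the gold-marker 2E suppression figure, and the
normalization-filter economy bound), each recomputed from scratch on seeded
phantoms.

## CLI

All analysis commands read plain TIFF series + CSV metadata sidecars or a
single self-describing HDF5 container (datasets `/data`, `/energies_eV` or
`/angles_deg`, attribute `pixel_size_nm`).

```sh
# generate demo datasets
txmkit simulate xanes  --seed 1 --out demo_xanes/
txmkit simulate mosaic --seed 1 --out demo_mosaic/
txmkit simulate tomo   --seed 1 --out demo_tomo/

# stitch a tile directory
txmkit stitch --tiles demo_mosaic/ --metadata demo_mosaic/tile_metadata.csv \
    --overlap 0.2 --out mosaic.tiff

# reconstruct a projection series
txmkit tomo --input demo_tomo/projections.h5 --algorithm fbp --filter ramlak \
    --center auto --out vol.h5

# dual-energy difference map (optionally with optics-based rescaling)
txmkit 2e --below below.tiff --above above.tiff \
    --below-energy 6500 --above-energy 6650 \
    --zoneplate 60,30 --distance 1000 --out map.tiff

# per-pixel XANES analysis with linear-combination fitting
txmkit xanes --stack demo_xanes/xanes_stack.h5 \
    --pre 7090,7110 --post 7150,7180 --e0 7120 --k 3 \
    --refs demo_xanes/ref1.txt,demo_xanes/ref2.txt \
    --rgb r=ref1,g=ref2,b=rest --out result.h5
```

## Conventions

- Arrays are `(row, col)`, origin top-left, 0-based; stacks are
  `(energy|angle, row, col)`.
- Spectra are optical density (`-ln T`) after flat-field reference correction.
- `Shift(dy, dx)` is the displacement *added* to the moving image's content to
  land on the reference.
- Angles are degrees everywhere; energies are eV; motor positions µm; pixel
  sizes nm.
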