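# cellcount

Counting cells on phase-contrast microscope images with **redundant count
maps** and a fully convolutional network — including red-fluorescent
(reporter-positive) cell counting, batch processing, error metrics,
time-course statistics, a CLI and a JSON-RPC service.

## Who this is for

Labs that image cultured cells (e.g. HEK 293A expressing a fluorescent
stress biosensor) on systems like Cell-IQ produce thousands of frames per
experiment. The cells are polymorphic, non-convex and grow in dense
clusters, which defeats watershed/edge-detection counting. This package
implements a counting approach that needs only **one-pixel marks** as
training labels and is accurate on clustered cells.

## The method

For a frame of size H × W and an odd kernel size k (default 65,
pad p = (k−1)/2 = 32), the regression target is a map of size
(H+2p) × (W+2p) whose pixel (i, j) counts the annotated cells in the
k × k window centred on it. Every cell contributes to exactly k² = 4225
map pixels, so the cell count is recovered as

```
N = Σ map / k²
```

exactly for targets and approximately for predictions, with per-pixel
errors partially cancelling in the sum (redundancy averaging). The map is
predicted by an inception-style fully convolutional network whose
receptive field covers k and whose convolutions preserve spatial size;
large frames are quartered (1040 × 1392 → four 520 × 696 quadrants, padded
to 584 × 760) and the quadrant counts summed. Red-fluorescent cells are
counted by thresholding the red channel, zeroing the grayscale image
outside the mask, and counting the masked image with the same model.

The network and its training loop (Adam, batch size 1, Glorot-uniform
initialization, batch normalization, MAE/MSE pixel loss, rotation
augmentation, best-validation-epoch selection) are implemented in pure
numpy/scipy — see `docs/methods.md` for the architecture, the loss
discussion, and all numerical conventions.

## Worked example

Generate a synthetic annotated suite, train a model, and batch-count a
directory of frames from the shell:

```sh
cellcount fixtures --out suite/ --n-train 16 --n-val 4 --n-test 8 --seed 7
cellcount train --train-dir suite/train --val-dir suite/val \
    --kernel-size 33 --compact --epochs 50 --seed 7 --out model.npz
cellcount count --checkpoint model.npz --input suite/test \
    --red-threshold 100 --out counts.csv
```

Through the Python API, the package's standard recovery experiment trains
the compact network (35 plain epochs plus a 15-epoch red-calibration
fine-tune, a few CPU-minutes) and counts held-out frames:

```python
import cellcount as cc
from cellcount.benchmark import run_synthetic_recovery
from cellcount.image_io import luma_grayscale

res = run_synthetic_recovery(seed=7)
scene = res.test_scenes[0]
total = cc.count_frame(res.model, luma_grayscale(scene.image), res.spec)
red = cc.count_red(res.model, scene.image, cc.RedThreshold(100), res.spec)
print(f"{total:.1f} cells ({scene.n_cells} planted), "
      f"{red:.1f} red ({scene.n_red} planted), "
      f"{cc.percent_red(total, red):.1f}% red")
print(f"mean relative error over {len(res.test_scenes)} held-out frames: "
      f"{100 * res.mean_total_rel_error:.1f}% total, "
      f"{100 * res.mean_red_rel_error:.1f}% red")
```

which prints:

```
35.3 cells (40 planted), 12.7 red (12 planted), 36.0% red
mean relative error over 8 held-out frames: 7.1% total, 4.4% red
```

Counts are real-valued by design and rounded only for display.

Scoring predictions against expert counts uses the evaluation module; on
the published 26-frame validation series of this method (the
(predicted, true) pairs ship with the package):

```python
from cellcount.evaluation import REFERENCE_VALIDATION_PAIRS, evaluate_pairs
s = evaluate_pairs(REFERENCE_VALIDATION_PAIRS)
print(f"mean relative error {s.mean_relative_error_pct:.2f}% | "
      f"overall difference {s.overall_difference_pct:.2f}% | "
      f"{100 * s.fraction_below(5.0):.0f}% of frames under 5%")
```

```
mean relative error 3.12% | overall difference 2.27% | 81% of frames under 5%
```

A trained checkpoint can also be served over JSON-RPC 2.0
(`cellcount serve --checkpoint model.npz --port 8080`); POST to `/api`:

```json
{"jsonrpc": "2.0", "id": 1, "method": "count_cells",
 "params": {"image": "<Base64 TIFF/PNG>", "red_threshold": 100}}
```

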