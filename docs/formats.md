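# File formats

## Images

TIFF (`.tif`/`.tiff`) or PNG.  On load every channel is min–max normalized
to [0, 1] (constant channels map to 0).  Channels-first TIFFs with ≤4
channels are transposed to H×W×C automatically.

## Label dialects

Ground-truth and predicted instances are *stacks of binary masks* because
masks may overlap; a flat integer label image cannot express that.  Two
on-disk dialects are supported and round-trip bit-exactly, preserving both
overlap and mask order:

### Multi-page TIFF (`.tif`)

One uint8 page per instance; nonzero = member pixel.  Page order is the
mask order.

### RLE JSON sidecar (`.json`)

```json
{
  "height": 64,
  "width": 64,
  "masks": [
    [[2, 5, 10], [3, 4, 12]],
    [[7, 0, 3]]
  ]
}
```

`masks[i]` is the run list of instance *i*; each run is
`[row, start_col, length]` with 0-based row-major coordinates.  Runs of one
instance may be in any order; rows may repeat (multiple runs per row).

### Flat integer import

A single-page *integer* TIFF with values > 1 is accepted on **import only**
as a convenience for conventional non-overlapping labels: one mask per
distinct nonzero value, in increasing value order.  Export always writes one
of the two dialects above.

## Model checkpoints

`*.npz` archives holding every weight array plus batch-norm running
statistics, with the architecture description stored as JSON under the
`__spec__` key.  `UNet.load` / `SemanticModel.load` / `SplitModel.load`
reconstruct the network from the archive alone.

## Metrics CSV

`evaluate` and `run-all` write `threshold,n_truth,n_matched,recall` rows,
one per IoU threshold, counts pooled over scenes.
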