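"""Overlapping block decomposition and the block-parameter sweep.

Splits an image into overlapping tiles (the reference setting: 32x32
blocks at overlap step 16), applies a per-tile task, and merges losslessly
with partition-of-unity weights.  The sweep table reports tile counts,
wall time (informational -- it depends on hardware) and the error of the
blocked pipeline against the unblocked one.
"""

import warnings

import numpy as np
from scipy.ndimage import median_filter

import ctrecon as cr

warnings.simplefilter("ignore", cr.TruncationWarning)

phantom = cr.make_shepp_logan(256)

bs = cr.split_blocks(phantom, cr.BlockConfig(32, 16))
print(f"32x32 blocks at step 16 over a 256 image: {len(bs.tiles)} tiles (15 x 15 lattice)")

round_trip = cr.merge_blocks(bs, "raised-cosine")
print(f"unmodified split->merge exact: {np.array_equal(round_trip.pixels, phantom.pixels)}")

configs = [
    cr.BlockConfig(b, s) for b in (16, 32, 48, 64) for s in (8, 16, 32) if s <= b
]
table = cr.benchmark_block_configs(lambda t: median_filter(t, 3), phantom, configs)
print("\nper-tile 3x3 median filter, blocked vs unblocked:")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(
    "\n(overlap plus raised-cosine weighting suppresses tile seams;"
    "\n residual RMSE comes from the filter seeing tile borders)"
)
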