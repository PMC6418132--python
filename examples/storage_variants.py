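"""Compare the three storage strategies for the quantized streams.

Delta-coded indices saved straight to chunked-gzip HDF5 (the default), the
same streams Huffman-coded before storage, and a run-length-coded
significance map instead of delta-coded indices.  All three decode to the
identical reconstruction; only the file size differs.
"""

import tempfile
from pathlib import Path

import numpy as np

from ecgcodec import CodecConfig, SynthConfig, TransformSpec, compress, decompress
from ecgcodec import generate_synthetic_ecg

signal = generate_synthetic_ecg(SynthConfig(n_beats=200, seed=5))
spec = TransformSpec("cdf97", 4)
tmp = Path(tempfile.mkdtemp())

variants = {
    "delta-coded indices": {},
    "huffman then hdf5": {"huffman": True},
    "run-length map": {"index_coding": "rl"},
}
reference = None
for label, kw in variants.items():
    cfg = CodecConfig(method="b", delta=25.0, spec=spec, **kw)
    res = compress(signal, cfg, tmp / f"{label[:4]}.h5")
    rec = decompress(res.path)
    if reference is None:
        reference = rec
    assert np.allclose(rec, reference)
    print(f"{label:>20}: {res.compressed_bytes:7d} bytes  CR={res.cr:6.2f}  "
          f"PRD={res.prd:.4f}%")
print("all variants reconstruct the identical signal")
# The chunk-wise DEFLATE of HDF5 already entropy-codes the integer streams,
# which is why plain storage is competitive with an explicit Huffman stage.
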