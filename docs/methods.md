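# Methods

## Signal model and conventions

A record is an integer vector of stored ADC values: offset included,
no physical-unit scaling.  All distortion metrics operate on these raw
values by default because that is the convention under which the
headline PRD figures of the wavelet-threshold ECG compression
literature are computed; subtracting the 1024 ADC baseline before
computing PRD inflates the number several-fold for the identical
reconstruction, so baseline subtraction is an explicit option
(`baseline_subtract`), never a silent default.  The WFDB reader
likewise returns stored integers and never rescales.

The MIT-BIH-style geometry (650000 samples, 360 Hz, 11-bit, offset
1024, two leads in format 212) is the reference use case.  Which of the
two leads a published benchmark used is generally unstated; the reader
defaults to channel 0 (MLII in those records) and the benchmark harness
records the channel in its manifest.

## Transform

`pywt.wavedec`/`waverec` provide the filter-bank engine.  The flat
coefficient vector concatenates the approximation band followed by
detail bands coarsest→finest; any fixed ordering would do because
indices are stored explicitly, but this one keeps the low-frequency
coefficients (the bulk of the survivors) at small indices, which makes
the index deltas small where entries are dense.  "cdf97" maps to
PyWavelets' `bior4.4`, the 9/7-tap Cohen–Daubechies–Feauveau pair.

Boundary handling defaults to half-sample symmetric extension, with
periodization available.  Under symmetric extension the coefficient
count slightly exceeds N; band lengths are a pure function of
(N, family, level, mode), so the decoder recomputes them and the
container stores only N and the transform descriptor.  CR is always
computed against the original N samples.  Perfect reconstruction is
asserted at 1e−8 relative error across the whole family/level/length
test grid; Parseval equality is asserted exactly (1e−8) for the
orthonormal families under periodization, and only a loose energy band
(ratio in [0.5, 2]) for the biorthogonal 9/7 pair, whose frame bounds
are close to but not equal to 1.

## Selection and quantization

The cumulative-energy selection sorts |w| ascending with a stable sort,
so equal magnitudes are discarded in ascending index order — a
deterministic tie-break independent of the sorting backend.  The
smallest n with t(n) ≥ tol² marks the cut; if even the total energy is
below tol² the selection is empty (and the codec then stores an empty
payload rather than failing).  With tol = 0 the selection is the
identity, which is exactly method (b): the two methods produce
byte-identical containers at equal Δ, and the test suite asserts this.

The quantizer applies ⌊c/Δ + ½⌋ to the *signed* coefficient, and the
separately-stored sign bit is derived from the quantized integer.
Quantizing magnitudes instead would differ at exact half-step ties
(c = −Δ/2 maps to 0 under the signed rule but to magnitude 1 under the
unsigned one); the signed reading is adopted and pinned by tests at the
decision boundary.  Zero-quantized entries are eliminated together with
their indices, which is what makes method (b) a thinning method at all.

PRD₀, the selection budget of method (a), defaults to 75% of the target
PRD when tuning — the middle of the recommended 70–80% band.  Setting
it near 100% of the target forces a tiny Δ and hurts CR; setting it
near 0 degenerates to method (b).

## Index storage

Surviving indices are sorted ascending (re-ordering magnitudes and
signs identically) and stored as first differences, 1-based on disk so
every delta is ≥ 1 and a narrow unsigned dtype always fits after a max
check.  Recovery is the prefix sum.  The run-length alternative encodes
the binary significance map as alternating run lengths starting with
the (possibly empty) zero-run; it exists for storage-strategy
comparisons and decodes to the identical index set.

The optional Huffman stage builds a canonical code from empirical
frequencies per stream (magnitudes and index deltas; sign bits are
already one bit each) and stores the code as a (symbols, lengths) table
beside the packed bitstream.  A single-symbol alphabet degenerates to
one bit per symbol.  On the noisy synthetic corpus the Huffman variant
does not beat plain storage, because HDF5's per-chunk DEFLATE already
entropy-codes the integer streams and the bitstream it receives instead
is incompressible; on long real records with highly skewed magnitude
distributions the stage is worth a few percent.  Both variants are
measured, not assumed.

## Container

HDF5, layout version "1": scalar datasets `n_signal` and `delta`;
`magnitudes` and `delta_indices` in the narrowest unsigned dtype that
fits (widening on overflow, never truncating); signs packed 8/byte.
Defaults: gzip level 4, 64 KiB chunks, shuffle off, `libver="latest"`
(the compact metadata layout — with the older default layout the ~2 KiB
per-dataset metadata overhead would dominate sparse payloads).  All
settings are recorded as file attributes because the achieved CR
depends on them.  Datasets are written with HDF5 time-tracking off, so
identical inputs yield byte-identical files; the thinning method is
deliberately *not* stored (decoding never needs it — it lives in the
run manifest), which is what makes the method-equivalence guarantee
expressible at the byte level.

The uncompressed reference size for CR defaults to N packed 11-bit
samples (⌈11N/8⌉ bytes); ⌈3N/2⌉ (the on-disk 212 packing) and 2N (a
plain int16 file) are selectable, since "size of the uncompressed file"
is convention-dependent and shifts every CR by a constant factor.

## Step tuning

`tune_delta` bisects Δ over [10⁻³·max|f|, max|f|] (growing the upper
bound if needed), measuring PRD through the complete
quantize→reconstruct loop at every trial, and stops within 0.005
percent points of the target — tight enough that two-decimal published
PRDs are matched — or after 40 iterations, returning the best step
seen.  Non-integer steps are allowed.  A target below the
configuration's reachable floor raises, reporting the floor.  For
database-level work the protocol is different and deliberately so: one
global Δ (and PRD₀) for all records, tuned to the database-mean PRD
(`bench.run_database` plus the global tuner in
`scripts/acceptance.py`); per-record tuning would overstate CR.

## Synthetic generator

Each beat is five Gaussian bumps (P, Q, R, S, T) at fixed offsets from
the R peak; beat-to-beat RR intervals are Gaussian with configurable
jitter, plus sinusoidal baseline wander (0.33 Hz) and white noise,
digitised to 11 bits around offset 1024.  Defaults (R ≈ 600 ADU ≈ 1.5 mV
at gain 200, noise σ = 6 ADU, RR 0.8 s) are chosen to look like a clean
adult sinus-rhythm Holter lead.  Output is exactly reproducible per
seed, and amplitudes that would clip the ADC raise instead of
saturating silently.

What the generator does not emulate: real electrode artefacts,
arrhythmic morphology changes, muscle noise with 1/f structure, or the
smooth spectral decay of real ECG.  Its white noise floor puts
proportionally more energy into fine-scale wavelet bands than a real
record has, so at a given PRD the codec must keep many more
coefficients and the measured CR (~11 at mean PRD 0.53 on the
six-record corpus) sits well below what the same pipeline achieves on
real 30-minute clinical records (~23 at the same PRD).  Passing tests
on synthetic data therefore validate correctness, determinism, the
target-PRD contract and the ordering of variants — not the absolute CR
level of clinical benchmarks, which require the real database
(`data/mitdb`, see README).

## Problem sizes and numerical choices

The test suite and the acceptance script run on records of the full
benchmark length (650000 samples) where the contract concerns them, and
on shorter records (10⁴–10⁵ samples) elsewhere; the acceptance corpus
is six records, enough for stable database means from a deterministic
seed.  Local-prd statistics drop a trailing partial segment and use the
unbiased (Q−1) std divisor; argmax ties break toward the earlier
segment.  Database summaries are unweighted per-record means — the mean
QS is the mean of per-record QS values, *not* mean CR over mean PRD.
The double-average p̄̄rd weights every record equally.

## Known limitations

Single channel per container; no annotation (.atr) handling; WFDB
format 212 only; no arithmetic coding or bit-plane (SPIHT-style)
coding; Δ is uniform across bands (per-band steps were considered and
rejected — uniform quantization of a whole-signal wavelet expansion is
the point of the design, and the storage stage, not the quantizer, is
where this codec wins).  Huffman decoding is a bit-serial Python loop,
fine for the stream sizes here but not for streaming use.
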