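# Methods

## Block code

The error-correcting layer is a systematic Levenshtein/Varshamov–Tenengolts
(VT) binary code. A codeword `x ∈ {0,1}^m` is valid when its weighted
position sum `Σ k·x_k` (1-based `k`) is `≡ r (mod U)`. We fix `r = 0` and
`U = 2m`; both are fields of `LCParams` but the decoder's substitution
arithmetic assumes these defaults, which is why they are not exposed as
user configuration. For a message of `l` bits the codeword length is the
smallest `m` with `l = m − ⌈log₂ m⌉ − 1`, i.e. the check overhead is
`⌈log₂ m⌉ + 1` bits placed at positions `{2^i ≤ m} ∪ {m}`. Consequences
used by the tests: the last position is always a check bit, the
second-to-last never is, and the parity set has exactly `m − l` elements.

Encoding fills the non-parity positions with message bits in ascending
order, computes the deficit `s = (U − Σk·x_k mod U) mod U`, and decomposes
`s` over the parity weights greedily, largest first. The decomposition is
total on `[0, U)`: if `s ≥ m`, the remainder `s − m ≤ m − 1` is covered by
the distinct powers of two below `m` (plain binary expansion); if `s < m`
the binary expansion suffices directly. The suite checks this exhaustively
for every geometry up to `m = 64`.

Decoding accepts words of length `m−1`, `m`, `m+1`:

- length `m`: syndrome `d = Σk·x_k mod U`. `d = 0` → intact. A 0→1 flip at
  position `p` gives `d = p ≤ m`; a 1→0 flip gives `d = U − p ≥ m`. The
  received bit value at the implied position disambiguates, including the
  boundary case `d = m`.
- length `m±1`: all single reinsertions/deletions are enumerated with an
  O(m) incremental syndrome (suffix one-counts), and the unique syndrome-0
  candidate string is accepted. Zero or several distinct candidates are
  reported `ambiguous` — the decoder never guesses. Uniqueness for true
  single indels is the VT deletion-ball disjointness property, which the
  suite verifies by enumeration at `m = 8` and exercises exhaustively at
  `m = 18` (4096 messages × every single substitution, deletion and
  insertion).

Messages of length 0 are rejected: the geometry equation degenerates and a
zero-payload block has no use in the pipeline.

## Constrained mapping

Three bits map to one dinucleotide pairing one weak (A/T) and one strong
(G/C) base in either order; the 8 such ordered pairs are exactly the
codebook, and the 8 weak-weak/strong-strong pairs are non-codewords.
Three structural theorems follow (tested exhaustively over all 8³
three-pair windows, which cover both motifs and any length-3 run):

- every window aligned to pair boundaries has GC content exactly 50%;
- no homopolymer run exceeds 2 nt (a length-3 run would force a
  same-base pair somewhere);
- GAATTC and GGC cannot occur at any alignment.

A substitution between two valid pairs is possible only as T↔A or C↔G
(the complement transversions) and flips exactly one mapped bit — which is
what makes single substitutions of that type transparently correctable by
the block code. All other substitutions produce a non-codebook pair; the
inverse mapping flags the pair as an erasure (placeholder bits 000) instead
of aborting, so the layer above can search the 8 possible originals for the
unique syndrome-0 completion. That erasure path also repairs transition
substitutions (A↔G, C↔T), which a pure bit-level decoder cannot see; it is
limited to ≤2 erased pairs per block to keep the search trivially small.
The constraint auditor scans the encoded strand only by default; encoder
outputs are what is being certified, and reverse-complement scanning is
available behind a flag.

## Packetization

An oligo of `L` nt carries `3L/2` bits: `k = ⌊3L/2 / m⌋` LC blocks plus a
zero tail of `3L/2 − km` bits (6 bits = 4 nt at the default `L = 208`,
`m = 18`). The concatenated block messages hold
`[index ‖ payload slice ‖ zero padding]`. Defaults: `l = 12` blocks in
208-nt oligos; index width is the smallest that can address the pool
(resolved by a fixed-point loop, since capacity depends on the width) and
is recorded in the sidecar. Protecting the index inside the first block(s)
was chosen over an unprotected prefix so that addressing errors are
corrected by the same machinery; padding is zeros; the sidecar carries the
payload bit length, the geometry, the compressor name and a SHA-256
checksum of the payload bitstream. Pools are serialized as single-line
FASTA (`>seq_<i>`); the index is also recoverable from sequence content
alone, and the decoder relies only on the content.

## Channel model

Errors are i.i.d. per base: each base errs with probability `p`; the error
type is drawn from a (substitution, deletion, insertion) mix defaulting to
(0.5, 0.25, 0.25) — substitutions are half of all errors. Substitutions
draw uniformly among the three alternative bases, insertions place a
uniform base after the erring position. These conventions (and the
insert-after choice) are the simplest neutral ones; no position- or
motif-dependent profile is modeled, so homopolymer-correlated error rates
of real platforms are out of scope. `reads_per_oligo` independent reads are
generated per oligo and shuffled; everything is reproducible from the
config seed. An `exact_counts` mode plants `round(p·len)` errors per read
for variance-matched experiments.

## Read decoding and selection

A read of expected length `L` is parsed by tiling it with the per-block
nucleotide spans (12 nt per block at the default geometry, plus the 4-nt
zero tail). Spans may take a length offset of −1/0/+1 nt; offsets share the
sign of the read's net length change, so `j` net deletions are localized as
`j` spans at −1 (and symmetrically for insertions) — multiple errors of the
same type across different blocks are repairable, while a read carrying
both an insertion and a deletion parses at no framing and is discarded.
Offset spans are repaired by exhaustive single-base reinsertion/deletion
filtered on pair validity and syndrome zero; zero-offset spans decode
directly (intact, substitution-corrected, or erasure-searched). The
zero-tail span is content-checked only when it absorbs the indel; a
substitution landing in the tail carries no information and must not
invalidate the read.

Each full parse is scored by its number of corrected spans and only the
minimum-cost parses are kept: under i.i.d. low-rate errors fewer
corrections is strictly more likely, and a spurious resynchronization must
pay for every misframed block it patches. A read is valid iff exactly one
minimum-cost parse exists. Measured on single-base-deletion reads, ~83%
repair uniquely and the rest are honestly ambiguous (a base deletion
re-frames the pair grid, and two different reinsertions can both yield
valid codewords); none miscorrect. The search is capped (20 000 nodes,
≤4 candidate repairs per block, ≤8 distinct parses) and a capped read is
reported invalid rather than half-decoded.

Valid reads vote per recovered index. Because two errors inside one block
can alias to a valid wrong codeword, the winning assembly is not taken on
faith: candidate payloads are assembled from the per-index alternatives
(bounded product over contested indices, ≤4096 assemblies, ≤3 candidates
per index) and the one matching the sidecar checksum is returned. No
payload is ever emitted without a verified checksum; exhaustion raises an
integrity error and missing indices raise a partial-recovery error, both
carrying the full report (per-read validity, per-index candidate counts,
recovery rate).

## Metrics

Net information density is original-file bits over total synthesized
nucleotides; KB means 1024 bytes — the convention under which the published
pool sizes and densities for the 95.2-KB reference file are mutually
consistent (one published value, the 2787 × 180 nt Reed–Solomon pool's
1.56 bits/nt, differs from the printed dimensions by 0.01; the suite
asserts our formula against the dimensions). SSIM uses the standard
formulation — Gaussian 11×11 window with σ = 1.5, K1 = 0.01, K2 = 0.03,
population covariances, dynamic range from the integer dtype (explicit for
float inputs) — via scikit-image; RGB images are compared as the mean of
per-channel SSIM by default, with a BT.601-luma mode behind a flag. For
constant images the implementation matches the closed form
`(2ab+C1)/(a²+b²+C1)` to numerical precision.

## Compression stage

The learned-image-codec stage is a pluggable interface, not a model:
`passthrough` (identity) and `zlib` (DEFLATE) are registered, both
lossless, and externally compressed payloads can be injected through
`passthrough`. With a lossless compressor a successful decode reproduces
the input bit-exactly, so image SSIM after recovery is 1 by construction;
rate–distortion behavior of lossy neural codecs is explicitly out of
scope.

## Problem sizes and runtime

The test suite exercises: exhaustive round trips for all messages at
`l ≤ 8` plus seeded samples to `l = 14`; the full 4096 × 74 single-error
grid at `m = 18`; all 8³ mapping windows; pools up to a few thousand bits
of payload; channel statistics on a 1293 × 208 nt pool; and end-to-end
decodes of ~400-read pools at 0.1–2% error with 10 reads per oligo. These
sizes keep the default run around fifteen seconds while leaving every
claim tested at, or exhaustively beyond, the scale it is stated for.
Deterministic seeds are fixed in the tests; the acceptance script takes its
seed on the command line.

## Known limitations

- Sequence dropout is detected (partial-recovery with the gap list) but
  not repaired: no inter-sequence redundancy (fountain/RS across oligos) is
  added, mirroring the scheme this package implements.
- Within a block, only a single error (or ≤2 erased pairs) is correctable;
  two errors can alias and are caught only by multi-read voting plus the
  payload checksum.
- The channel is i.i.d.; platform-specific error structure is not
  emulated, so recovery rates here are optimistic for homopolymer-rich
  contexts (which the mapping largely avoids anyway).
- Indel repair assumes block-aligned pair boundaries (`m ≡ 0 mod 3`, true
  for the default `m = 18`); other geometries fall back to
  substitution/erasure handling only.
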