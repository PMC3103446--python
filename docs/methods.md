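# Methods

## Model and procedure

The caller operates on a per-chromosome integer depth profile built by
*blind extension*: every read is extended from its 5′-most aligned base
to the library shear size `ext_len`, on its own strand, and clipped to
the chromosome. The shear size is a user parameter, never estimated
from the alignments — with modern read lengths approaching the
200–500 bp shear range of ChIP protocols, strand-shift estimation is
unreliable, and a fixed extension keeps the pileup exact: the total
profile mass equals the summed clipped fragment lengths, an invariant
the tests enforce.

Region detection treats the genome-wide mean depth
λ = mass / genome length as a homogeneous Poisson background and takes
the smallest depth `h ≥ 1` with `P(Poisson(λ) ≥ h) < thr_p` as the
enrichment threshold. Candidate regions are maximal runs of depth ≥ h;
runs separated by strictly fewer than `max_gap` below-threshold
positions are merged, gap included. This analytic threshold stands in
for a mappability-aware background simulation; mappability and GC
correction are out of scope, so the background is exchangeable by
construction and the analytic tail is exact for it.

Significance is a two-sample count comparison. The number of treatment
fragments overlapping a region, `k_t`, is compared with the scaled
control count `r·k_c` via the one-sided binomial test
`p = P(X ≥ k_t)`, `X ~ Binomial(k_t + round(r·k_c), ½)` — the classic
equal-split null for two Poisson processes after normalisation. The
scaling factor `r` is the zero-intercept least-squares slope of
treatment on control fragment counts over 10 kb bins, excluding bins
overlapping any candidate region so enrichment does not inflate the
fit; when the regression is degenerate (no usable control counts) the
library-size ratio is used and recorded. Without a control the test is
the Poisson tail at the background expectation `λ·len/ext_len`.
Benjamini–Hochberg q-values are computed across **all** candidate
regions genome-wide — a deliberate contract: parallel per-chromosome
execution must gather p-values before filtering, and a test verifies
that per-chromosome correction would give different q-values.

## Summit detection

Within each surviving region the raw depth segment is smoothed by a
centered moving average whose window shrinks at the segment boundaries
(divisor = positions actually covered; window 1 is the identity), then
scanned by the summit-valley-alternator with sensitivity δ ∈ (0,1),
exclusive. The summit half of the scan — emit the leftmost running
maximum when coverage drops below δ·max — follows the published
description; the valley half re-arms when coverage rises strictly above
(running minimum)/δ. That multiplicative-symmetric re-arming criterion
is this package's reconstruction (the original's exact rule is not
published): it guarantees that a monotone decay emits exactly one
summit rather than a cascade, which the oracle suite checks. Plateaus
tie-break to the leftmost index. Summit heights are reported from the
smoothed track.

Two filters follow. First, summits separated only by zero-coverage
stretches of the **raw** track are iteratively collapsed to the higher
summit (ties drop the right one) — a guard against fragmented summits
in undersequenced regions; the zero test uses the raw track because
the rule is about absent reads, which smoothing would blur. Whether
the original "padding" mechanism merges summits or extends region
boundaries is ambiguous; the merge reading is implemented. Second, an
optional relative-height filter (`min_rel_height`, default 0 = off)
drops summits below that fraction of the region's top summit, for
analyses that require comparable-height summits. Every surviving
region reports at least one summit: if the filters empty it, the
global maximum of the smoothed segment is reinstated.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ext_len` | 200 bp | shear size for blind extension; low end of the typical 200–500 bp range |
| `thr_p` | 1e-4 | per-bp Poisson tail probability behind the depth threshold |
| `max_gap` | 100 bp | merge distance between above-threshold runs; below typical fragment size so one binding event is not fragmented |
| `fdr_cutoff` | 0.01 | BH q-value cutoff over all candidate regions |
| `delta` | 0.5 region / 0.8 resolution | valley sensitivity; resolution mode must split shallower valleys |
| `smooth_window` | 31 region / 5 resolution | broad histone signal is noisy, punctate signal needs minimal distortion |
| `min_rel_height` | 0 | relative-height summit filter, disabled by default |
| `bin_size` | 10 kb | bins for the control scaling regression |

Preset values are this package's documented choices; the published tool
does not print its own. Precedence is CLI flags > config file > preset.
No duplicate-read or MAPQ filtering is applied by default (`--max-dup`
enables capping). Coordinates are 0-based half-open internally; SAM
input and wiggle output are converted at the boundary.

## Synthetic benchmarks

The generators emulate the spike-in design used to benchmark peak
callers in the absence of gold standards. `generate_background` draws
fragment starts uniformly over the positions where a full fragment
fits (strand fair-coin), `spike_peak` draws each fragment's start
uniformly over `(center − ext_len, center]` so that every fragment
covers the true site — raw coverage at the center equals the fragment
count exactly, and expected coverage decays linearly to zero `ext_len`
away. The paired series places pair anchors evenly, at least 5 kb
apart, at separations 200–500 bp in 25 bp steps (13 datasets); each
dataset's control is an independent background with the same total
read count as its treatment, mirroring the matched-count design.

Default geometry: one 10 Mb chromosome, 20,000 background reads
(0.4× mean depth), 100 fragments per peak, 36 bp reads, 200 bp
fragments — peaks are unambiguous while inter-peak valleys at
200–500 bp remain informative. Problem sizes in the test suite (e.g.
2 Mb null chromosomes in unit tests, the full 10 Mb geometry in the
acceptance tests) are the package's own choices balancing statistical
resolution against suite runtime.

What the emulation does **not** model: mappability holes, duplicate
towers, copy-number waves, GC bias, or the irregular local rates of a
real input library. Passing benchmarks therefore demonstrate
correctness of the algorithms under the stated generative model, not
performance on any particular real dataset; the uniform background
stands in for the real no-antibody library the original benchmark
resampled, which is not redistributable here.

Evaluation matches called summits to truth greedily by increasing
distance, one-to-one, within a 100 bp radius (matches are sparse by
construction, so optimal assignment would change nothing); recall is
the matched fraction of truth positions, the false-positive rate the
unmatched fraction of calls, and a pair is *resolved* when both its
summits are matched by distinct calls.

## Numerical and degenerate-input choices

Poisson and binomial tails use scipy's survival functions; q-values
use scipy's BH implementation, cross-checked in the tests against a
quadratic-time reference. `λ = 0` gives threshold 1; an empty read
stream is a fatal error for table derivation but yields an all-zero
profile in coverage building; fragments falling entirely off a
chromosome are dropped and counted. Scaled control counts are rounded
to the nearest integer (minimum 0) before the binomial test. Region
ranking for output names is ascending p-value, ties broken by
descending peak height then coordinate; rows are written in coordinate
order.

## Known limitations

- The inter-peak resolution curve is not monotone in separation under
  the default sparse background: near separations of twice the
  fragment length (~400–450 bp) the two fragment piles just stop
  overlapping, a few-bp zero-coverage stretch appears between the two
  summits with probability ≈ e^(−0.4) per position, and the zero-gap
  rule then collapses the pair while the `max_gap` merge still holds
  both summits in one region. With deeper backgrounds (λ ≳ 2) the
  valley never reaches zero and the dip disappears. This is a property
  of the zero-gap rule itself, faithfully implemented, not of the
  detection statistics.
- Local background variation (MACS-style local λ) is intentionally
  absent; the control comparison is the only local correction.
- No paired-end support: fragment length is always the user's
  `ext_len`, even where templates are observed.
- BigWig output is not written; the wiggle writer (plain or gzip)
  covers browser use.
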