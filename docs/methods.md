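# Methods

## Model of piRNA biogenesis

The simulator implements the minimal two-branch biogenesis model of the
silkworm BmN4 ping-pong system. A transposon consensus sequence is the fixed
reference; "sense" means the consensus as written in its FASTA.

**Primary processing.** Primary piRNAs are modelled as fragments of the
antisense transcript: a read of length `L` with antisense 5′ coordinate `q`
is the reverse complement of `consensus[q−L+1 .. q]` (0-based, inclusive
ends here for readability; the code uses half-open intervals throughout).
Its first nucleotide is therefore the complement of `consensus[q]`, so a
5′-U read requires consensus base A at `q`. The 5′-U preference parameter
`p_1U` is the **target marginal**: for each length the generator mixes a
U-conditioned uniform start draw with an unconditioned one, with mixing
weight `q_L = clamp((p_1U − f_A(L)) / (1 − f_A(L)), 0, 1)` where `f_A(L)` is
the fraction of A among eligible starts (`q ≥ L−1`), computed by direct
enumeration. The realized expected 1U fraction — returned exactly by
`expected_u1` — then equals `p_1U` whenever `p_1U` is at or above the
consensus background; requests below background degrade gracefully to
unconditioned sampling (so `p_1U = 0` yields the background ≈ 0.25 on a
uniform consensus, and `p_1U = 1` forces every read to start with U). The
calibration was chosen over a raw two-component mixture so that the
parameter means what its name says: a library simulated at preference 0.8
measures ~80% 1U, the figure reported for Siwi-bound primary piRNAs.

**Secondary (ping-pong) processing.** Each secondary read picks a partner
uniformly over primary *read instances* (i.e. abundance-weighted), draws a
fresh length, and is placed on the sense strand with 5′ coordinate
`p = q − (overlap − 1)` (default overlap 10 nt), so the two 5′ ends overlap
by exactly `overlap`: the overlap statistic `d = q − p + 1` evaluates to 10
for true partner pairs. Only the 5′ end is slicer-defined; the 3′ end
(length) is independent of the partner. Reads that would run off the
consensus trigger a full resample of partner and length. Position
`overlap` of a secondary pairs with the partner's first base, so a 1U
partner forces an A there — the 10A-bias of secondaries is emergent, never
parameterized. One round only: iterated amplification of the ping-pong loop
is out of scope (no rates are available to calibrate it).

**Mixtures.** A chimera-like library draws each read either novel (with
probability `novel_fraction`; uniform random sequence at the configured GC,
rejected if it collides with a parent sequence) or from a parent library
chosen by the given proportions, abundance-weighted within the parent. The
defaults used in the workflow — 37% novel, parents weighted toward the
secondary library — emulate a chimera-bound population that is mostly
secondary-derived with a substantial unassignable remainder.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `p_1U` | 0.8 | target 1U fraction of primaries (Siwi-like) |
| `overlap` | 10 nt | 5′-5′ overlap enforced for secondaries |
| length law | triangular on 24–32 nt | mode 28 (primary) / 27 (secondary), matching the reported modal lengths of Siwi- and Ago3-bound reads |
| `gc_content` | 0.5 | consensus and novel-read base composition |
| fold threshold | 5 | enrichment rule for exclusive read assignment |
| normalization | rpm | fold rule compared on reads-per-million (raw-count mode behind a flag) |
| overlap range | 1–30 nt | histogram support; z-score background = all bins but the target |
| seed k-mer `k` | 12 (CLI) | exact-match seed length; any `k ≤` read length gives identical results (shorter reads fall back to a direct scan) |

The length law's exact shape is a declared default, not an inference — only
the support (24–32 nt) and the modes are anchored in reported data.

## Statistics

All library statistics are abundance-weighted by default (`weighted=False`
gives unique-sequence mode); whether the field's reported percentages are
abundance- or sequence-weighted is generally unstated, so both are exposed.
Bias statistics run over *all* reads of a library, not only mapped ones;
per-transposon statistics use mapped hits with multimapper weights
(`count / n_hits`, conserving totals). The strand score is `2f − 1` with
`f` the sense weight fraction; transposons with zero mapped weight are
flagged rather than scored. Modal lengths and modal overlap distances break
ties toward the smaller value, deterministically.

The overlap histogram counts **every** opposite-strand hit pair on a shared
transposon at distance `d = q_antisense − p_sense + 1 ∈ [dmin, dmax]`, with
pair weight the product of hit weights; configurations with `d < 1`
(3′-side overlaps, disjoint reads) are ignored. On dense simulated data
this background is substantial — at 2,000 + 2,000 reads on 5 kb roughly
`n_A·n_B/C ≈ 800` weight per bin against ~3,000 in the d = 10 bin — so the
signature manifests as a sharply dominant modal bin and a large z-score
(z ≈ 50–60 at those sizes), not as near-total weight concentration; the
latter only occurs in sparse regimes (few distinct primary sites on a long
consensus). The z-score uses the sample (n−1) SD of the background bins; a
perfectly flat histogram scores 0, and an empty background SD (all mass in
the target bin) is flagged undefined rather than infinite.

The enrichment classifier works on exact full-sequence identity after
normalization (uppercase, U→T). Absence from a library counts as abundance
zero, so any sequence seen in only one parent is that parent's exclusive
class; ties at exactly the fold threshold count as enriched (≥, not >),
making the boundary testable. No pseudocounts are added.

## Mapping

Exact substring matching only, both strands, every occurrence reported
(deduplicated, deterministically ordered). This is a deliberate restriction:
it makes the mapper verifiable against a brute-force all-substring oracle
(asserted over hundreds of random cases) and guarantees that every simulated
read maps back to its ground-truth placement. Mismatch/indel alignment and
genome-scale heuristics are non-goals.

## What the simulator does and does not emulate

It reproduces the *population-level* signatures — 1U/10A biases, strand
polarity, the 10-nt overlap peak, mixture composition — with full ground
truth, which is exactly what the downstream statistics consume. It does not
model nuclease sequence specificity, 3′ trimming or methylation, real
transposon sequence families (consensus sequences are i.i.d. random),
multi-copy elements, or sequencing error. Passing tests therefore validate
the statistics' correctness and calibration on idealized data, not their
robustness to artifacts of real libraries (adapter read-through, ligation
bias, mismatched mapping), which upstream tools must handle.

## Numerical and design choices

- One `numpy` Generator per simulation stage, seeded from its config; draw
  order is fixed and documented per operation, so outputs are byte-identical
  across runs and platforms.
- Reads containing N are dropped (not wildcard-matched); both `_xN` and `_N`
  collapsed-count header dialects are accepted, `xN` winning when both match.
- Coordinates are 0-based half-open everywhere; the antisense 5′ end is
  `end − 1`. Stated once, asserted in the `MappedHit` constructor.
- The workflow's problem sizes (5-kb consensus, 2×10³–10⁴ reads) were chosen
  so every statistic sits well inside its asymptotic regime (binomial SEs of
  ~0.4 percentage points at n = 10⁴) while keeping simulations instantaneous.
- Degenerate inputs fail loudly: empty libraries, positions beyond all read
  lengths, consensus sets without entries, geometrically impossible overlap
  configurations, and fold thresholds ≤ 1 all raise with messages naming the
  offender.

## Known limitations

- Exact matching understates mapped fractions on data with sequencing errors
  or polymorphism relative to the consensus.
- The fold-enrichment classifier has no uncertainty model; near-threshold
  assignments are deterministic and sensitive to sampling depth (no
  saturation correction).
- Aggregating ping-pong signal across transposons is a plain sum; no
  per-transposon significance testing is attempted.
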