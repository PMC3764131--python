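# Methods

## Codon elongation-time model

The decoding time of a sense codon is modeled as a cognate insertion time
plus linear delay terms from unproductive binding attempts:

    tau(codon) = tau1 + c_near * tau2 + c_non * tau3

where `c_near` and `c_non` are the ratios of summed diffusion-limited
arrival frequencies of near-cognate and non-cognate tRNAs to those of the
cognates. The arrival frequency of one species is the Smoluchowski
encounter rate for `N` molecules in a cell of volume `V`:

    f = kappa * D * s * N / V        [events/s]

with `D` in m²/s, `s` (molecule size) in m, and `kappa = 4*pi` exposed as a
single configuration constant. Because both competition measures are
quotients of such frequencies, they are exactly independent of `kappa` and
of any uniform rescaling of abundances; the test suite asserts both
invariances. Consequences of the linear form that the tests also rely on:
`tau = tau1` when competition vanishes, `tau >= tau1` always, and `tau` is
non-decreasing in every competitor abundance.

Classification is table-driven: a species is **cognate** for every codon its
specificity table lists, wobble pairing included — the anticodon is never
used to infer decoding. A **near-cognate** is a non-decoding species whose
anticodon (read 3'->5' against the codon read 5'->3') forms exactly one
non-Watson–Crick pair, located at codon position 2 or 3; strict A–U/G–C
pairing is used for this mismatch count, so a wobble-decoding cognate with a
3rd-position mismatch is excluded from the near-cognate set by the cognate
test, not by pairing geometry. Everything else is non-cognate.

`tau1`, `tau2`, `tau3` are configuration (globally or per codon, per
temperature). The packaged defaults (50 ms, 5 ms, 0.5 ms) are synthetic
placeholders of plausible magnitude, labeled as such; they are not
calibrated to any organism, and deriving them from elementary ribosome
kinetics is out of scope. Relative tRNA abundances (summing to <= 1) are
rescaled to the organism's total tRNA count before kernel evaluation;
absolute pools pass through unchanged. The selenocysteine isoacceptor
inherits the cysteine species' diffusion coefficient when its own is
missing, since tRNA size varies little with the accepted amino acid.

## Ribosome-traffic simulation

A transcript is a 1-D lattice of codons; a ribosome is its active-site
index (1-based). The process is deterministic: dwell exactly `tau_k` at
codon `k`, then advance iff the next ribosome's active site is at least
`footprint` codons beyond the target codon (footprint default 10; setting
it to 1 reproduces the literal "next codon vacant" rule). Initiation
attempts occur at `t = 0, I, 2I, ...` and succeed iff the rearmost ribosome
is beyond the entry exclusion zone. After dwelling on the final codon the
ribosome vacates immediately — no separate termination time is modeled; all
non-elongation time is booked to initiation.

Numerical choices:

- **Tie-break.** Simultaneous events resolve downstream-first: the leading
  ribosome moves before its followers, and initiation is considered last.
  A follower whose dwell has elapsed moves at the very instant space frees.
- **Time resolution.** Event times within a relative tolerance of 1e-9 are
  treated as simultaneous. This absorbs float accumulation drift between
  independently summed dwell clocks, so the knife-edge configuration
  `I = footprint * tau` (uniform profile) resolves by the tie-break rule —
  collision-free — rather than by rounding noise. Advancing ribosomes
  resynchronize their clocks to the processed event time, keeping the drift
  from growing. Dwell times closer than ~1 ns are far below any physical
  resolution of the model.
- **Collision policy.** `halt` stops at the first blocked advance or
  blocked entry and reports the blocked site and its blocker (what an
  interactive display wants); `queue` lets ribosomes wait, and discards
  blocked initiation attempts (the next attempt comes one interval later).
  Both modes produce identical event logs up to the first blocked event.
- **Horizon.** Default 10x the total elongation time or 100 completed
  proteins, whichever first. The time-averaged occupancy integrates the
  ribosome count over the full horizon.

For a uniform dwell profile the queuing condition has a closed form —
queuing occurs iff `I < footprint * tau` — which the tests verify against
an independent integer-tick brute-force replay. For collision-free
transcripts the long-run occupancy converges to `E/I` (Little's law:
arrival rate `1/I` times residence time `E`); at a `50*E` horizon the
boundary bias is ~1%, and the acceptance checks use a 5% band.

## Per-gene parameters

`E = sum(tau_k)` over the CDS, `tau_mean = E/L`, `I = E/w`, `b = m/I`.
The ribosome load is normalized **per transcript copy**:

    w = (gene footprint share) * active_fraction * ribosomes_per_cell / x

with `active_fraction = 0.85` (fraction of cellular ribosomes engaged in
translation) and `x` the gene's absolute transcript count, obtained by
rescaling relative abundances to the transcriptome size under the
complete-coverage assumption. The identities `I*w = E`, `g*L = 100*w`,
`b*I = m` then hold by construction and are asserted to machine precision.

For organisms expressing only a fraction of their genome at once (the
bacterial case), the cell-wide footprint total is estimated as the mean of
1000 sums over 600 genes sampled without replacement from the profiled
pool; this subsample-sum estimator is unbiased for `(600/N) *` (pool
total), which the tests check against the exact SRSWOR variance.

Filters: eukaryote rule — drop genes lacking footprint or mRNA counts or
with combined sum < 128; bacterial rule — drop genes with any replicate's
footprint count < 100; all organisms — retain only `g <= 10`, the packing
ceiling implied by a 10-codon footprint (`mean_gap = 100/g - footprint`
reaches 0 at `g = 10`). The rules are predicate-based and hence
order-independent. The collision-free restriction replays each gene through
the simulator at its own `I` and dwell profile and drops any gene whose
replay contains a blocked event.

The Spearman confidence interval defaults to the Fisher-z construction
(`atanh(rho) ± z_crit/sqrt(n-3)`), with a percentile bootstrap as an
option; the two agree within Monte-Carlo tolerance on well-behaved data and
the tests compare the bootstrap against an independent resampling oracle.

## Speed profiles

Smoothed translation speed over a window is codons-per-total-dwell-time
(harmonic aggregation), `window / sum(tau)` in aa/s, window-start aligned,
for window sizes {1, 2, 5, 10, 20, 30, 50} capped at the CDS length. This
choice (rather than an arithmetic mean of per-codon speeds) preserves
`sum(1/speed) = E` at window 1 and keeps every smoothed value between the
slowest and fastest per-codon speed in its window.

## Synthetic data

The fixture generator emulates every input so nothing external is needed:

- **tRNA pools**: isoacceptor groups partition each amino acid's codons;
  anticodons are the Watson–Crick complement of the group's first codon, so
  near-cognate competition arises naturally; abundances are lognormal
  (median 2000, sigma 0.8), `D ~ 1e-11 m²/s`, `s ~ 1e-8 m`. A minimal
  single-species "universal decoder" pool provides the competition-free
  limit where every `tau = tau1`.
- **Gene sets**: CDS lengths uniform on 60–400 codons with a lognormal
  codon-usage bias; true densities g uniform on 0.5–8 (safely below the
  ceiling); lifetimes uniform on 300–3000 s; two replicates; counts are
  constructed by inverting the derivation chain, and the returned organism
  constants make the gene set account for the whole active ribosome pool
  and transcriptome, so noise-free derivation is an exact inverse (asserted
  to machine precision).
- **Count noise**: gamma-Poisson with user-set dispersion (variance
  `mu + phi*mu²`), applied to footprint and mRNA counts. At the stated
  dispersion `phi = 0.1`, a 40-seed reference run gave a median relative
  error of the recovered initiation time of ~0.27 (worst seed 0.34); the
  recovery tests use 0.40 as the bound.

What the fixtures do **not** emulate: wobble decoding rules, codon-usage /
tRNA-abundance co-adaptation, positional coverage bias of real profiling
libraries, or replicate-specific library sizes. Passing tests therefore
validate the arithmetic, the simulation semantics and the estimator
properties — not biological claims about any particular genome.

## Known limitations

- Elongation dwell times are deterministic; stochastic (exponential-dwell)
  exclusion-process variants, ribosome drop-off and initiation scanning are
  out of scope.
- The packaged kinetic defaults are synthetic; quantitative organism-level
  results require calibrated `tau1–tau3` and measured tRNA tables.
- Whether the original applet's vacancy check spanned one codon or the full
  footprint is not documented; both are supported via the `footprint`
  setting, with 10 as the default.
- Problem sizes in the test and acceptance runs (gene sets of 50–60, CDS
  lengths ≤ 400 codons, 50x-elongation-time horizons) are chosen as the
  smallest scales at which the targeted statistical bands are comfortably
  resolved.
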