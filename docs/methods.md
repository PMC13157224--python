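# Methods

This note records the models, protocol realizations, parameter choices and
numerical decisions behind `fedcrypt`, and what the test suite does and
does not establish.

## Study model

Two cohorts are analyzed, each vertically partitioned: a *genomic site*
holds (participant id, polygenic score); a *phenotype site* holds
(participant id, sex, systolic/diastolic blood pressure, hypertension
history). Participants are labelled *control* iff they have no hypertension
history and SBP < 130 mmHg and DBP < 85 mmHg, otherwise *case*. Scores are
standardized against the control group's mean and SD and participants are
grouped into quintiles of the standardized score. Because standardization
is strictly monotone, quintile membership equals that of the raw scores;
the genomic site can therefore form its private group indicators without
seeing the (phenotype-side) control labels.

Quintile rule: rank-based; a tied block of equal scores receives the
quintile of the block's smallest rank. This is deterministic and
permutation-invariant, assigns every scored participant a quintile, and
degenerates to "all quintile 1" when all scores are equal. Group sizes
differ by at most one in the absence of ties. Quintiles are computed on the
whole cohort (not per case/control stratum).

Stratified analyses (case/control x sex) are configured by the phenotype
site, which applies the stratum filter locally before encryption. Stratum
*positions* within the linked order thereby become session knowledge, like
the public totals N and K; attribute values and group memberships do not.

## Protocol realizations

### Division of labour

Per-group sums S_k and sums of squares SS_k of the attribute vector are
masked inner products between the phenotype site's ciphertexts of x and
x*x and the genomic site's plaintext 0/1 indicators, summed with a log2
rotation tree. These and the genomic site's private group sizes n_k are
the only inputs to the MPC phase, which computes the statistic and the
grid p-value. Group sizes stay private; only N, K, and each protocol's
declared outputs are revealed. The Welch t statistic is computed as
t^2 = (m1-m2)^2 n1 n2 / (s1^2 n2 + s2^2 n1) plus a separate sign bit, so
no secure square root is ever taken on the statistic path; the square root
of the revealed t^2 is applied in cleartext. The Welch-Satterthwaite
degrees of freedom are revealed rounded to the nearest integer (treated as
plaintext, as table lookups require); this leaks coarse variance-ratio
information and is documented rather than mitigated.

### Secret sharing and fixed point

Values are two's-complement integers in Z_{2^k} scaled by 2^f. The
primitive default is k=64, f=16 with 40-bit statistical masking, matching
a SPDZ2k-style semi-honest deployment. The *protocol* layer opens its
sessions at k=192, f=40: its pipelines chain many fixed-point products of
aggregates as large as N*value_max^2 (~2^26) and divide results as small
as a null-stratum F statistic (~0.01), so the wider ring keeps both the
probabilistic-truncation wrap probability (~2^(l+1-k) per truncation for
operand magnitude 2^l) and the absolute fixed-point noise negligible at
the 99.9%-agreement scale. Ring width only changes Python integer
arithmetic; there is no hardware word-size constraint.

Truncation after a fixed-point multiply is the local-share probabilistic
shift (party 0 shifts its share, party 1 shifts the negation of its own).
The single borrow term contributes +1/2 ulp in expectation, exactly
cancelling the floor's -1/2, so the truncation is unbiased with error
within about one ulp. The construction is specific to two computing
parties — with more ring-sharing parties multiple modular wraps appear —
and the protocols never need more: nonlinear steps always run between the
two computing sites, while additional phenotype sites contribute through
the HE aggregation layer.

### Nonlinear primitives

*Division* num/den with a public magnitude bound B (rounded up to a power
of two) iterates Newton's reciprocal on the scaled variable rt = B/den >= 1:
rt <- rt(2 - den*rt/B), seeded with the affine approximation A - 2*den/B
(A = 2.9142), and finishes with num*rt/B; the /B steps are exact
power-of-two shifts folded into the multiplication rescale. Keeping rt >= 1
and recomputing den*rt each step makes the iteration self-correcting, so
only the final step's truncation noise survives. The iteration count is
sized from B and a public lower bound on the denominator (`den_floor`,
supplied per call site from declared attribute ranges, never from data);
error decays as eps0^(2^T) with eps0 = 1 - den*x0 < 1.

*Inverse square root* iterates y <- y(3 - a y^2)/2 from y0 = 2^-ceil(log2
B / 2) <= 1/sqrt(a), associating a*y^2 as (a*y)*y so truncation noise on
the small y^2 is never amplified by a large a.

*Comparison* [a >= t] opens (a - t)*r for a dealer-supplied random
positive r (up to 2^40). The sign of the masked opening is exact, so
comparisons are never a source of numerical error; the outcome bit is
visible to the computing parties. In every protocol use — the p-lookup
breakpoint ladder, the tau^2 >= 0 gate, the t sign — the bit is derivable
from a declared revealed output, so no information beyond the declared
outputs leaks; the magnitude of the opening leaks roughly the bit-length
of the difference, a documented relaxation of this reference realization.

### Tiered p-value lookup

The grid holds 28 p-values (0.001..0.01 step 0.001; 0.02..0.1 step 0.01;
0.2..1.0 step 0.1). For F(df1, df2) — a squared t enters as F(1, nu) — the
27 breakpoints are the critical values at the p-space midpoints of
adjacent grid points, strictly decreasing. The shared statistic is
compared against each breakpoint with strict inequality at ring
resolution, so a statistic exactly on a breakpoint snaps to the *larger*
p (conservative); statistics beyond the lowest breakpoint clamp to 0.001
and set an at-resolution-floor flag. Degrees of freedom above 200 use the
large-df limit F(d1, inf) = chi2(d1)/d1. The monotone ladder of comparison
bits selects the p-value by adjacent differences (a one-hot inner product
with the grid); only the selected p is revealed.

### HE reference backend

The backend contract (encrypt, add, multiply, rotate, level tracking,
collaborative decryption) has one shipped implementation: cleartext slots
behind an enforced ciphertext API (slots are unreachable except through
one valid partial decryption per party, checked against keygen
commitments), with seeded additive Gaussian noise of magnitude
2^-scale_bits per operation — emulating a scale-managed approximate
scheme whose error floor is set by rescaling precision rather than slot
magnitude. Default parameters mirror a 128-bit-secure CKKS instantiation:
ring dimension 32768 (16384 slots), scale 2^40, depth budget 6, no
bootstrapping. Vectors longer than one batch are chunked into
ceil(N/16384) ciphertexts and results are invariant to the chunk
boundary. A lattice-backed implementation would slot behind the same
contract; none is bundled, keeping protocol correctness independent of
crypto-library availability.

HE->MPC conversion isolates a slot with a one-hot plaintext multiply, has
each party homomorphically add a private uniform mask, and collaboratively
decrypts only the masked value, which the lead party folds into its ring
share. Masks span 2^20 times the declared value bound: within the
reference backend's float64 slot width this hides the value while
preserving its low bits (the masked slot rides in extended precision,
standing in for the exact big-integer plaintext space of a lattice
scheme); a lattice backend would widen masks to 2^stat_sec times the
bound.

### PSI

Commutative-masking (Diffie-Hellman) intersection in the quadratic-residue
subgroup of a safe-prime MODP group; identifiers are hashed into the
group, masked by each party's secret exponent, exchanged, re-masked, and
matched as doubly masked values. Both data owners learn exactly the
intersection, canonically sorted; transcripts carry only masked group
elements. The 2048-bit IKE group is the conservative choice and the unit
tests exercise it; in-process simulation runs that execute hundreds of
intersections default to a 256-bit demo group for throughput — a
documented demo-grade setting, not a security recommendation. Exponents
are capped at 256 bits (standard short-exponent practice).

## Synthetic cohorts

The generator emulates the study's structure, not any real cohort's
distributions. Per cohort: scores ~ N(0,1); SBP = 118 + shift +
3*(quintile-3) + 4*[male] + N(0, 12) mmHg (DBP analogous with smaller
coefficients); hypertension history ~ Bernoulli(0.12); the second cohort
gets +12 mmHg and a tripled history rate, emulating a cardiovascular
cohort alongside healthy volunteers. The case/control label is always
derived by the labelling rule, never sampled, so labels and pressures are
consistent by construction. Sites miss disjoint 2.5% slices of
participants (95% overlap) so record linkage is genuinely exercised. The
effect is linear in quintile *rank* rather than in the raw score — it
matches the quintile-stratified analyses directly and makes the injected
top-vs-bottom SMD exactly 4 steps x d*sd/4 for the recovery harness.

What passing tests show: the secure pipeline reproduces the plaintext
statistics on data with the declared structure, magnitudes and
missingness. What they do not show: robustness to real-data features the
generator omits — heavy-tailed or device-truncated pressures, informative
missingness, score-phenotype confounding, relatedness between cohorts.

## Default parameters

| parameter | default | why |
|---|---|---|
| ring k / fractional f (primitives) | 64 / 16 | SPDZ2k-style word size; meets the stated 2^(-f+c) primitive bounds |
| ring k / f (protocol sessions) | 192 / 40 | headroom for aggregate products; sub-1e-9 absolute noise on O(1) statistics |
| statistical security | 40 bits | masked-opening hiding in the MPC layer |
| HE ring / slots / scale | 32768 / 16384 / 2^40 | 128-bit-security CKKS-style profile |
| attribute bound (SBP) | 256 mmHg | covers any physiological reading; public, from config |
| within-group SD range | [2, 32] mmHg | plausible blood-pressure dispersion; sizes division iteration counts |
| cohort n (scenario) | 1000 | two-cohort study scale used by the agreement runs |
| quintile effect / sex effect / noise SD | 3 / 4 / 12 mmHg | moderate, clinically plausible effects |
| site overlap | 95% | forces non-trivial PSI |

## Problem sizes used by the checks

The agreement runs use 100 seeded scenarios of n=1000 per cohort (about
46 revealed statistics each); the lookup exactness sweep covers F(1, df)
and F(4, df) for df = 1..30 with 1000 random statistics per table; the
primitive bounds use 1000 random inputs per operation; the recovery study
uses 500 replicates of two cohorts of n=500 with injected d = 0.5. These
sizes are the package's own validation choices.

## Known limitations

- Semi-honest model with a trusted dealer; no MACs, OT, or malicious
  security. In-process "parties" share one address space: isolation is by
  API discipline and transcript audit, not OS boundaries.
- Comparison outcomes (and hence p-lookup ladder positions) are public to
  the computing parties; acceptable here because every such bit is
  implied by a declared output, but a stricter deployment would use a
  bit-shared comparison.
- Fixed-point truncation is two-computing-party; more MPC parties would
  need a different truncation gadget.
- The reference HE backend models noise and access control, not lattice
  hardness; security claims about the HE layer attach to the contract,
  not the bundled backend.
- Revealed rounded Welch degrees of freedom leak coarse variance
  information (documented, unmitigated).
- tau^2 is truncated at zero through a revealed gate bit, so "no
  between-study heterogeneity detected" is itself visible — as it is in
  any published random-effect summary.
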