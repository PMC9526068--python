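# Methods

## Model

`coalratios` works under the standard (Kingman) coalescent for a haploid
population of constant size N, with time in units of N generations.  While k
lineages remain, the waiting time T_k to the next coalescence is exponential
with rate k(k−1)/2, the merging pair is uniform over the k(k−1)/2 unordered
pairs, and the T_k are mutually independent, so

    E[T_k] = 2/(k(k−1)),   Var[T_k] = 4/(k²(k−1)²).

Six summaries of a genealogy with n leaves are covered:

| symbol | meaning | defined for |
|---|---|---|
| H_n | tree height (TMRCA), Σ T_k | n ≥ 2 |
| L_n | total branch length, Σ k·T_k | n ≥ 2 |
| E_n | total external branch length | n ≥ 2 |
| I_n | total internal branch length, L_n − E_n | n ≥ 3 |
| B_n | mean length of the two basal (root-incident) branches | n ≥ 4 |
| T_k | coalescence time at level k | 2 ≤ k ≤ n |

The package provides (i) exact finite-n means, variances, and all 15
pairwise covariances of these summaries, as closed forms in the generalized
harmonic sums S_{p,m} = Σ_{j≤m} j^(−p); (ii) delta-method approximations to
E[X/Y] and Var[X/Y] for every pair, namely the second-order expansion

    E[X/Y]  ≈ E[X]/E[Y] − Cov[X,Y]/E[Y]² + E[X]·Var[Y]/E[Y]³

and the first-order expansion

    Var[X/Y] ≈ (E[X]/E[Y])²·(Var[X]/E[X]² − 2Cov[X,Y]/(E[X]E[Y]) + Var[Y]/E[Y]²);

(iii) exact n → ∞ limits of all of the above; and (iv) a simulator used to
validate every formula empirically.

Thirteen of the covariances are exact; those of (E_n, B_n) and (I_n, B_n)
are themselves approximations.  Results built on them carry
`approximate=True`, and the delta-method variance of B_n/E_n inherits the
flag — it is the quantity for which approximation and simulation differ
most.

## Exact arithmetic and the constant basis

All finite-n values are computed with `fractions.Fraction`; floats appear
only at rendering (default 5 decimal places, the precision at which the
constants are conventionally printed).  This makes the central consistency
check — that the generic delta-method composition equals the transcribed
per-pair closed forms — a test of *exact equality of rationals* rather than
a tolerance comparison.

Limits lie in the 6-dimensional rational vector space spanned by
{1, π², π⁴, π⁶, ζ(3), π²·ζ(3)} (ζ(3) is Apéry's constant).  `ExactScalar`
stores the six rational coefficients, so equality of limits is decidable
coefficient-wise.  Two sentinels are distinguished: `DIVERGES` (the limit is
+∞, e.g. E[L_n]) and `UNDEFINED` (outside the validity domain, e.g. B_3).

## Limits are computed, not transcribed

Every `*_limit` function takes the n → ∞ limit of the *same formula body*
used for exact finite-n evaluation.  The harmonic sums are replaced by their
standard asymptotic expansions,

    S_{1,m} = log m + γ + 1/(2m) + O(m⁻²)
    S_{2,m} = π²/6 − 1/m + 1/(2m²) + O(m⁻³)
    S_{3,m} = ζ(3) − 1/(2m²) + 1/(2m³) + O(m⁻⁴),

and sympy evaluates the limit of the resulting elementary expression.  The
formulas are rational in (n, S_{p,·}), so the neglected remainders contribute
only vanishing relative corrections; the first correction terms are retained
because several limits arise from cancellations of the form n·(π²/6 −
S_{2,n−1}) → 1.  Every limit is then cross-checked numerically: the finite-n
formula is evaluated directly at n = 10⁷ (under mpmath extended precision —
see below) and must agree with the symbolic limit.

The large-n float path runs at 40 decimal digits internally because formulas
such as Cov[H_n, B_n] multiply harmonic sums by n² before subtracting
near-equal terms; at n = 10⁷ this cancellation consumes ~14 significant
digits and float64 would return noise.

Convergence rates differ by entry.  Moments, covariances, and ratio entries
whose denominator variable has bounded mean (H, E, B, T_k) converge at rate
O(log n / n): at n = 10⁷ they agree with their limits to ≈3·10⁻⁵, which is
the tolerance of the numeric cross-check.  Ratio entries with L_n or I_n in
the denominator converge only like 1/log n (e.g. the approximate E[H_n/L_n]
is still ≈0.069 at n = 10⁶ on its way to 0, and E[L_n/I_n] ≈ 1.24 on its way
to 1); for these the limits are asserted exactly from the symbolic path, and
the numeric check verifies only the monotone approach.

## Reconstruction of the tabulated closed forms

The per-pair closed forms were transcribed from a source whose typography
flattens fraction bars, sub- and superscripts, making several readings
ambiguous (for instance "S2,n−1" can denote S_{2,n−1} or S_{2,n} − 1).  Each
candidate reading was accepted only when it passed all three oracles:

1. algebraic identities from the independence of the T_k (e.g.
   Var[H_n] = Σ Var[T_k], Cov[L_n, T_k] = k·Var[T_k], and linearity of every
   I_n-covariance under I = L − E);
2. exact rational equality with the generic delta-method composition over
   the exact moments and covariances, for all n in the joint validity domain
   up to 200 (k = 2..n at n ∈ {5, 10, 20} for T-pairs);
3. the printed limit constants (to 5 decimals) and Monte-Carlo agreement.

Two readings required correction by this protocol: the leading factor of the
Var[B_n/T_k] form is k/2 (reading it as k² is off by exactly 2k), and the
limit of Var[B_n/E_n] is −π⁴/36 + π²/4 + 1/2 ≈ 0.26159.  The generic
composition is the runtime path throughout; the transcribed forms exist to
cross-validate it.

Note that B_n = Σ T_k/(k−1) holds in expectation — and, remarkably, for the
covariances of B_n with H_n, L_n, and T_k — but *not* per realization (a
counterexample: the balanced 4-leaf topology) and not for Var[B_n], whose
closed form contains an S² term that no fixed linear combination of the
independent T_k can produce.  The simulator therefore always measures the
topology-defined B_n (mean of the two root-incident branch lengths).

## Validity domains

Moments follow the definitional domains in the table above; covariance pairs
involving I_n require n ≥ 3 and pairs involving B_n require n ≥ 4.  Pairs of
E_n with H_n, L_n, or T_k are additionally allowed at n = 2, where
E_2 = L_2 = 2T_2 makes the tabulated forms exact; this supports the
degenerate-exactness checks (at n = 2, H/L ≡ 1/2, H/T_2 ≡ 1, E/L ≡ 1,
E/T_2 ≡ 2, each with zero variance, and the approximations reproduce these
values exactly).  The *transcribed* closed forms stick to the published
validity notes (n ≥ 3 when E_n or I_n is involved; some contain (n−2)
denominators).  Where a denominator mean is zero or a statistic undefined,
operations raise instead of returning limits.

Ratios may be requested in either orientation; only the canonical
orientations carry transcribed closed forms, the generic machinery covers
the rest.  Pairs (T_j, T_k), j ≠ k, are rejected rather than given the
independence value 0, keeping exactly to the 15 tabulated pairs.

## Simulator

`simulate_tree` draws T_n..T_2 as scaled standard exponentials and merges a
uniformly chosen pair at each level (index sampling without replacement).
Per-tree summaries: H is the root age; L = Σ k·T_k; E sums each leaf's
branch up to its first coalescence; I = L − E; B is the mean of the two
root-child branch lengths, reported as `UNDEFINED` for n < 4 unless
explicitly opted in.  Identities (I = L − E, H = Σ T_k, two root children)
are property-tested on every simulated tree to 10⁻¹².

Reproducibility: replicate r of a run at sample size n uses
`numpy.random.default_rng([seed, n, r])`, so a single integer seed
determines the full replicate stream and runs can be chunked or parallelized
over r without changing results.  The simulator is cross-validated against
msprime (an independent coalescent implementation) on the means of H and L.

Newick output uses unquoted integer leaf labels "1".."n", branch lengths in
coalescent units at up to 12 significant digits, no internal-node labels;
round-trips are tested with dendropy.

What the simulator emulates is exactly the model the formulas assume, so
Monte-Carlo agreement validates the algebra (transcription, composition,
limit machinery), not the model's fit to any real data: constant population
size, no migration, selection, recombination, or mutation.

## Validation protocol and problem sizes

The validation suite uses 100,000 replicates per tree size — the replicate
count of the evaluation protocol the tables come from — at n ∈ {5, 10, 20}
for moment/covariance recovery and n ∈ {10, 50} for ratio tracking, with a
fixed seed (12345).

* Moment and covariance recovery: empirical values within 4 standard errors
  of the exact formulas.  At 100,000 replicates this resolves deviations of
  roughly 0.5–2% of each quantity.  For the two published-approximate
  covariances, (E,B) and (I,B), an additional 0.05 absolute slack is allowed:
  their measured bias (quantified on an independent seed) is a stable ≤0.03
  and ≤0.05 respectively across n ∈ {5,...,50} — a genuine property of the
  published approximation, not simulation noise.  A relative tolerance would
  be wrong here because Cov[E_n, B_n] → 0 while its bias shrinks more
  slowly (≈25% relative at n = 50 yet only ≈0.013 absolute).
* Ratio expectations at n = 50: simulated E[X/Y] within 5% relative of the
  approximation for the six pairs among {H, L, E, I} (observed ≈1%).
* Ratio variances: held only to trend agreement (the sign of the change from
  n = 10 to n = 50 matches), since the first-order variance approximation is
  known to be visibly off at small n, most of all for B_n/E_n.

## Known limitations

* Only first/second-order delta-method approximations; no higher-order
  corrections, no exact ratio distributions.
* Constant-size neutral coalescent only; no demography or selection.
* `harmonic_sum` is exact-rational and therefore practical to n ~ 10³–10⁴;
  beyond that use the float path (`mean_float` etc.), which is what the
  limit-consistency checks do.
* ζ(p) for odd p ≥ 5 is outside the constant basis; no formula here needs it.
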