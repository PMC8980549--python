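# Methods

This note records the models, conventions and numerical choices behind
`founderage`, in the order the pipeline applies them.

## Data model and coordinates

Markers live on one chromosome at 1-based physical positions, strictly
increasing. Genetic distance is derived from physical distance with a
constant conversion, default 1 cM/Mb, so the recombination fraction
between the focal mutation and a marker is θ = Δbp × 10⁻⁸. This is the
standard genome-wide average; true local rates vary severalfold, and
that uncertainty — not sampling noise — dominates the spread of the
per-block age estimates.

Carriers are autozygous, so each family contributes two chromosomes
expected to be identical; they are collapsed to one family haplotype
for inference, while chromosomes remain the counting unit for sharing
and frequencies (a family contributes 2). Within-family discordances
are reported as data errors, not resolved silently. A missing genotype
(`-`) is compatible with any allele everywhere: it never votes for a
founder allele, never deactivates a chromosome, and counts as matching
in sharing, breakpoint and group logic. This keeps partially genotyped
families inside every count rather than dropping them marker-wise.

## Shared core and founder extension

The shared core is the maximal contiguous marker run containing the
focal site on which all chromosomes' non-missing alleles agree. The
founder haplotype equals the shared allele there, and is extended
outward one marker at a time: among chromosomes still consistent with
the founder on that side, the founder allele is the plurality allele,
and mismatching chromosomes become inactive for all farther markers.
Per-marker support (active chromosomes after the choice) is therefore
maximal on the core and non-increasing outward.

Plurality ties are real in small panels. They are broken in a fixed
cascade: (1) plurality over *distinct lineages* — families whose full
haplotypes are identical (missing-tolerant) are counted once, since
identical haplotypes most plausibly share post-founder ancestry and
should not vote twice; (2) greedy look-ahead — the allele whose
surviving set retains the largest total downstream agreement with a
plurality-extended founder; (3) deterministic lexicographic order.
Tie markers are flagged in the output. On the packaged data the
distinct-lineage rule decides the genuine 6–6 split at rs12239350
(two of the six carrier families are haplotype-identical), keeping the
founder consistent with the family that shows no recombination at all;
a pure look-ahead rule would instead assign that family a spurious
event. Markers where no active chromosome is genotyped get the
allele `N` (unknown) with support 0.

## Block partition

A block boundary belongs wherever the set of founder-consistent
chromosomes changes, i.e. at each family's divergence marker (its first
non-missing founder mismatch moving outward). Blocks are labeled by
their member marker nearest the mutation — the divergence marker that
opened them — and θ is measured to the label. Markers outside the
first divergence on each side extend the focal block.

Two terminal conventions mirror the practice of stopping haplotype
extension once only two families retain the ancestral haplotype:

* if the divergence that leaves two surviving families is followed by
  no further divergence, it opens a terminal block running to the map
  end (the two survivors stay ancestral throughout);
* otherwise that divergence marker closes the current block inclusively
  and regular blocking stops; the outermost remaining divergence gets a
  detached two-marker block (the unit used by two-marker estimators at
  the far edge of the haplotype), and leftover markers are reported
  unassigned as tail markers rather than forced into blocks.

On the packaged data this yields ten blocks of sizes
10, 13, 6, 8, 24, 9, 2, 17, 4, 2 and four unassigned distal markers.

**Sharing counts.** A block's sharing count is the number of
chromosomes matching the founder at every marker from the mutation
*through the block's label marker*. This is the quantity that pairs
with θ-to-label in the decay model (probability of no recombination
over that interval); it equals the per-block divergence bookkeeping
wherever divergences coincide with block starts, and is non-increasing
outward by construction. P_D = sharing / (number of chromosomes).

**Family derivations.** Each family gets at most one breakpoint per
side (the outermost interval where it stops matching the founder);
`n_events` counts sides with a breakpoint. Families diverging at the
same marker on the same side with identical recombined-in alleles over
the remainder of that marker's block are assigned one shared-ancestor
group. Identity is required only within the divergence block: the
recombination-free block is the span over which the recombined-in
segment can be compared with confidence, and demanding identity to the
map end would split pairs whose haplotypes differ far outside it.

**Segment lengths.** Per chromosome and side, the recombination point
is placed at the midpoint of the interval between the last
founder-matching and the first discordant marker (midpoint is the
least-biased point estimate for a breakpoint known only to an
interval; `last-match` and `first-mismatch` conventions are available
and bracket it). With no discordance before the map end the segment is
censored at the outermost genotyped marker.

## Haplotype frequencies

EM: standard multilocus haplotype-frequency EM. The E-step distributes
each sample over its compatible phase resolutions proportionally to
current haplotype-frequency products (missing genotypes marginalized
over the alleles observed at that marker); the M-step re-estimates from
expected counts. Initialization is uniform over observed-compatible
haplotypes for determinism; optional seeded Dirichlet restarts probe
multimodality. Iteration stops when the largest absolute frequency
change drops below 1e-8 (default) or at 10,000 iterations with a
warning; the log-likelihood is monotone up to rounding and is checked.
Per-sample phase expansion is capped at 2¹⁶ resolutions — beyond that
the marker subset must be restricted.

CHM: composite counting — every compatible phase resolution of an
ambiguous sample receives equal fractional weight in one pass. This is
a from-scratch definition of composite counting, not a bit-compatible
re-implementation of any commercial tool; it coincides with EM exactly
on data with at most one heterozygous marker per sample, and with many
multi-heterozygotes it knowingly leaks weight onto phase-consistent
ghost haplotypes.

The packaged per-block control frequencies (Fn) were estimated from an
external reference panel and ship as data; the estimators here are
validated on synthetic controls with known pools instead.

## Age estimators

*Decay.* δ = (P_D − P_N)/(1 − P_N); g = ln δ / ln(1 − θ). δ ≤ 0 means
the block haplotype is no rarer in controls than carriers; the block is
flagged not estimable rather than given a sign-flipped age. θ = 0 (the
focal block) has no clock and is skipped.

*Iterative.* K = cR + μM + (1 − c − μ)I with R column-constant at the
control frequency a and M the SNP mutation matrix (M11 = 0, M12 = 1/3,
M21 = 1, M22 = 2/3: a mutation always destroys the ancestral allele
and recreates it 1 time in 3). The state starts at (1, 0) and is
iterated (cap 10⁵ generations). Because the deviation of the state
from K's fixed point contracts by the subdominant eigenvalue each
generation, interpolation between the bracketing generations is done
geometrically in (state − fixed point); at μ = 0 the result then equals
the closed form to floating-point error, and the two agree within one
generation at SNP-scale μ. Targets at or below the fixed point are not
estimable.

*Mutation rate.* μ defaults to 10⁻⁸ per site per generation, a typical
SNP rate; at that scale the μM term is negligible over 10²–10³
generations, which is why decay and iterative estimates coincide after
rounding.

*Gamma (segment lengths).* One-sided conserved segments are
Exponential(g) in Morgans under Haldane recombination. With S the
summed lengths and m the number of uncensored segments, the point
estimate is the bias-corrected MLE (m − 1)/S (the naive m/S is upward
biased by ~1/(m−1)); the 95% CI is [q_Γ(0.025; m)/S, q_Γ(0.975; m)/S].
Censored segments contribute their observed length to S but not to m —
the censored-exponential likelihood — and can instead be dropped
entirely via a switch. Correlated genealogy collapses chromosomes to
one lineage per family per side and families sharing a recombinant
ancestor on a side to one effective lineage on that side, reducing both
S and m; it is the appropriate mode when shared-ancestor groups exist.
Fewer than two uncensored segments → not estimable.

*Bootstrap CIs.* The per-block printed inputs carry no replication, so
CIs are parametric: carrier sharing is resampled as
Binomial(2n_families, P_D), the estimator re-applied, and the 2.5/97.5
percentiles taken (deterministic under a fixed seed; fails loudly if
more than half the replicates are inestimable). These intervals
reflect carrier-sampling noise only — not uncertainty in θ or Fn — and
are not expected to match any externally computed interval.

*Rounding.* Reported generations are rounded half-up to integers for
table display; floats are kept internally. Years = generations × 25 by
default.

## Simulator

The generator emulates the descent model the estimators assume: each
carrier chromosome keeps founder material within Exponential(g)
distances of the focal site per side (the nearest-breakpoint distance
under a Poisson crossover process over g meioses) and carries a fresh
background-pool draw beyond; only the breakpoint nearest the mutation
is tracked, because nothing closer to the data depends on the later
history of replaced material. Markers mutate Binomial(g, μ) times,
uniformly to one of the other three bases, except the focal site
(carriers are ascertained on the mutation). Controls are two
independent pool draws per sample with phase discarded. One seeded
numpy generator drives each operation, so outputs are replayable.

What this does *not* emulate: crossover interference, gene conversion,
genotyping error, population growth or structure, allele-frequency
drift in the background pool, and relatedness among carriers beyond
what the pool frequencies imply. Passing recovery tests therefore
demonstrate estimator correctness under the model's own assumptions,
not robustness to these real-data features — the spread of the
per-block estimates on the packaged data (79–196 generations) is a
reminder that map-rate misspecification alone moves the answer by a
factor of ~2.

## Problem sizes used in validation

Deterministic checks run on the packaged 99 × 18 table. Stochastic
checks use: EM recovery on 96 synthetic control diplotypes (the size
of the reference control panel); Gamma coverage on 200 replicates of
18 one-sided segments; end-to-end recovery on 200 replicates of 18
chromosomes over an 81-marker map (±2 cM at 0.05 cM spacing) with
bootstrap B = 400, checking ≥ 90% coverage at nominal 95%. These sizes
give binomial standard errors of ~1.5% on coverage estimates, small
enough to distinguish a broken interval from a nominal one.

## Known limitations

* The blocking terminal conventions are tailored to the two-families
  stopping rule; data with very different sharing topology will fall
  back to plain divergence-boundary blocking.
* CHM is equal-weight composite counting (see above), not a
  reimplementation of any specific tool's estimator.
* The two-marker decay variant for blocks with δ ≤ 0 at the haplotype
  level is not implemented; such blocks are reported not-estimable.
* Bayesian (MCMC) dating is out of scope.
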