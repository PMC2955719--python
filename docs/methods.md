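# Methods

This note documents the models and procedures implemented in `tandemfam`,
the parameter choices that matter, and what the synthetic test bed does and
does not establish about real data.

## The analysis problem

A tandem array of paralogous genes is partitioned into six region classes —
promoter, 5'-UTR, signal-peptide coding region (SPCR), intron(s),
mature-protein coding region (MPCR), and 3'-UTR. The pipeline asks three
questions about the family:

1. **Which regions are conserved across paralogs?** (per-region all-vs-all
   pairwise scores, summarized as average and range)
2. **Is the coding diversification driven by positive selection?**
   (pairwise dN/dS; allele-level nonsyn/syn tallies)
3. **Do different regions record different genealogies?** (per-region NJ
   trees and Robinson–Foulds distances — the signature of gene conversion)

An *inverted* family answers yes/yes/yes: noncoding regions and the SPCR
are homogenized by concerted evolution while the MPCR is diversified by
selection.

## Pairwise scoring (0–100 scale)

Both scorers report `round(100 · identities / min(len_a, len_b))`, rounding
half-up, so identical sequences score 100 and a sequence fully containing
the other scores 100. The minimum-length denominator lets regions of
unequal length be compared untrimmed.

**Exact scorer.** Global alignment with affine gaps (defaults: match +2,
mismatch −1, a gap of length g costs −5 − g). The DP optimizes
(alignment score, identity count) lexicographically, so the reported
identity count is the maximum achievable among optimal-score alignments and
therefore deterministic. IUPAC ambiguity codes are accepted but never count
as identities — a conservative choice that also means the self-score
invariant holds only for unambiguous sequences.

**k-tuple scorer.** A Wilbur–Lipman-style diagonal method (defaults k=2,
band=5): shared k-tuple positions are grouped by diagonal, the best-covered
diagonal is located, and maximal match runs on diagonals within the band
are chained; a diagonal shift of d while chaining costs `4 + 2·|d|`
matched positions. The chained match count substitutes for the identity
count. The shift penalties were chosen so that the scorer (a) stays within
±5 of the exact scorer on substitution-diverged pairs scoring ≥ 80 and
(b) keeps unrelated random 300-mers near the noise floor (empirically mean
≈ 18, maximum ≈ 24 over 1000 pairs). This scale is a declared convention:
published family-similarity tables computed with other tools are
qualitative reference points, not bit-exact targets.

## Conservation profile

Per region, the average is the sum of pair scores over the number of pairs
(rounded half-up) and the range is (min, max), matching how such tables are
conventionally reported. Classification compares averages with two
configurable thresholds, conserved=80 and diversified=60, chosen inside the
empirical gap between conserved-region averages (roughly 52–96 in published
family tables) and diversified-MPCR averages (roughly 10–49):

- `inverted` — all conserved-class regions (promoter, 5'-UTR, SPCR, intron,
  3'-UTR) ≥ 80 and MPCR ≤ 60;
- `conventional` — MPCR ≥ 80 and some noncoding region ≤ 60;
- `uniform` — everything ≥ 80; otherwise `mixed`.

`contrast` = mean conserved-class average − MPCR average; positive values
indicate the inverted regime.

## Nei–Gojobori dN/dS

For each ungapped sense-codon pair: synonymous site counts weight each
position by its synonymous fraction (each of the three possible changes
contributes 1/3); sites are averaged between the two codons. Differences in
multi-hit codons are averaged over all orderings of the changed positions.
Proportions pN = Nd/N and pS = Sd/S are Jukes–Cantor corrected,
`d = −(3/4)·ln(1 − 4p/3)`, and omega = dN/dS. Conventions:

- changes **to** a stop codon count as nonsynonymous with no site
  renormalization, preserving N + S = 3 × n_codons exactly;
- pathways passing **through** a stop are excluded unless all pathways do;
- codon pairs containing a gap or a stop codon in either sequence are
  excluded from counting;
- p ≥ 3/4 or dS = 0 flag omega as undefined (never a silent NaN).

Standard errors come from a codon bootstrap (default 1000 replicates,
seedable): codon columns are resampled with replacement and dN/dS
recomputed per replicate. Counting-based dN/dS is used deliberately — it is
fully specified and desk-checkable against exhaustive enumeration; no
maximum-likelihood codon model is attempted, so published ML estimates are
comparable only in regime (omega above or below 1), not in value.

**Codon-aware alignment** aligns translated proteins (BLOSUM62, gap open
−10 / extend −0.5) and threads codons back, so nucleotide gaps come in
multiples of 3; terminal stop codons are stripped for alignment and
re-appended.

**Allele tallies** collapse exact duplicate cDNAs, then pool substitutions
across the unique alleles. A substitution is identified by (coding
position, alternate base) and counted once no matter how many alleles carry
it; it is classified syn/nonsyn in the reference codon carrying only that
change, and assigned to SPCR or MPCR by nucleotide position (a split
boundary codon belongs to the SPCR partition; protein-level signal-peptide
annotation covers only full SPCR codons). Alleles whose length differs from
the reference by a non-multiple of 3 are excluded with a warning and
reported. The deduplication rule is a declared convention — pooled counts
published without one cannot be reproduced exactly otherwise.

## Region phylogenies and discordance

Pairwise p-distances exclude gapped columns (unequal-length pairs are
globally aligned first); JC69 distances flag p ≥ 3/4 as undefined. NJ
follows Saitou–Nei with two deterministic choices the literature leaves
open: Q-criterion ties break toward the lowest (row, column) index, and a
negative branch length at a join is clamped to zero with the deficit moved
to its sister branch (final three-taxon star branches are clamped at zero).
On additive matrices NJ reproduces the generating topology and path
lengths to 1e−9, and matches an exhaustive least-squares search over all 15
five-taxon topologies.

RF distance is the size of the symmetric difference of non-trivial
bipartitions (computed via dendropy on a shared taxon namespace). A family
is `discordant` when any pair of region trees has RF > 0. Note that
near-identical regions (very few segregating differences) produce
arbitrarily resolved trees, so discordance among highly conserved regions
is expected noise; the informative contrast is conserved-region trees vs
the MPCR tree.

## The simulator

One gene unit is laid out as
`[flank 200] promoter 200 | 5'-UTR 58 | SPCR 57 | intron 100 | MPCR 300 | 3'-UTR 200 [flank 200]`
(region lengths configurable; defaults sit in the ranges reported for such
families, and SPCR+MPCR must be a multiple of 3). The ancestral coding
sequence starts with ATG, contains no internal stop, and ends with a stop
codon. The unit is duplicated into `n_copies` (default 7) and evolved for
`generations` steps; copies are kept in sense orientation and the first
copy is written to the output array reverse-complemented, representing an
inverted repeat that is compared in sense orientation like the rest.

**Mutation as origin-fixation.** Substitutions arrive per region at rate
`mu × w × length`, where the acceptance weight w is `omega_mpcr` for
nonsynonymous MPCR changes, 1 for synonymous MPCR changes, and
`accept_conserved` for all other gene regions (intergenic flanks are
neutral). Implementation: proposals are drawn at the region's maximal rate
and thinned, so per-proposal acceptance probabilities stay in [0, 1] while
net rates equal mu × w. This is the standard weak-mutation view of
selection — beneficial changes fix at super-neutral rates — and it is what
lets one mutation budget produce both a diversified MPCR (defaults) and a
uniformly conserved neutral control. A literal acceptance-probability cap
at 1 cannot do both, because capped acceptance can never push a region
*above* the neutral rate. Proposals creating a premature stop or destroying
the terminal stop are always rejected, keeping every copy translatable.

**Conversion.** Per generation each copy is a conversion recipient with
probability `gamma`; the donor is uniform among the other copies. The
initiation point falls in the intergenic flanks with probability
`init_bias` (default 0.8 — conversion is preferentially initiated
intergenically) and uniformly along the unit otherwise; the tract extends
in a random direction with geometric length (mean `tract_mean`, default
300 nt — tracts of a few hundred base pairs), clipped to the unit, and the
homologous recipient segment is overwritten. Conversions that would disrupt
the recipient's reading frame are rejected (selection against pseudogenized
chimeras). Both the applied (clipped) and drawn tract lengths are logged.

**Event log.** Every proposal and conversion is logged with its acceptance
flag, in a documented order (generation → copy → region → conversion pass),
under a single seeded RNG stream. `replay(log, ancestor, n)` reproduces the
final sequences bit-exactly; fixed seeds give byte-identical output.

**Default calibration.** mu = 3e−5 per site per generation, 1500
generations, gamma = 0.005, omega_mpcr = 10, accept_conserved = 0.1. These
were chosen once so the defaults reproduce the qualitative published
regime: MPCR average score ≈ 50 with conserved-class averages ≥ 98
(inverted), while the matched neutral control (gamma = 0, omega = 1,
accept = 1) keeps every region near 90 (uniform). omega_mpcr = 10 sits
within the span of published pairwise dN/dS estimates for such families
(≈ 1.1–18.8). The two-copy condition used for dN/dS regime experiments
(`divergent_pair_params`: gamma = 0, mu = 1e−4, 1000 generations) diverges
the MPCR to ≈ 80–85% identity — the moderately diverged window in which
counting-based dN/dS is informative; at this divergence the mean neutral
omega estimate is ≈ 1.0 (the upward bias of the ratio estimator shrinks as
synonymous counts grow).

## What the synthetic test bed does not show

The simulator omits indels (so real alignment uncertainty is absent),
population-genetic dynamics (drift, effective population size, allele
frequencies — selection is collapsed into acceptance weights), crossover
between arrays, inter-family conversion, and any rate heterogeneity along
the sequence beyond the region partition. Passing regime-recovery tests
therefore shows the pipeline detects the pattern its generative model
produces, not that real families evolve by exactly this mechanism.
Conversely, the analysis side makes no simulator-specific assumptions: it
consumes any FASTA + GFF3 family annotated with the six region classes.

## Numerical choices

- Score and average rounding: half-up to integers; printed ratios half-up
  to 2 decimals.
- Degenerate inputs: empty sequences, non-nucleotide characters, <2
  sequences, <3 taxa, all-gap overlaps, and asymmetric or NaN distance
  matrices raise typed errors naming the offender; regions present in
  fewer than two members are skipped with a warning rather than an error.
- Problem sizes in the test suite and acceptance script (50 profile
  replicates, 200 dN/dS pairs, 1000 random score pairs, 500+ logged
  conversion events) were chosen to make the stochastic assertions stable
  at the stated thresholds while keeping a full run in well under a minute
  per component.
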