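# Methods

`suprapop` asks a single question in several ways: are the single-nucleotide
polymorphisms that two related species share compatible with neutral drift
acting on each species independently, or do they require ongoing gene flow
(hybridisation)? The motivating system is the dabbling ducks (genus *Anas*),
where a SNP panel developed in the mallard remains polymorphic in congeners
that diverged millions of years ago at rates far above what comparable
species pairs show.

## The persistence-time calculus (`suprapop.drift`)

A neutral biallelic polymorphism at initial minor-allele frequency `p` in a
Wright–Fisher population of effective size `Ne` segregates on average for

    t(p) = -4 Ne [ (1 - p) ln(1 - p) + p ln p ]

generations before being lost or fixed (the classical diffusion result
combining expected time to loss and to fixation). Everything in the module
follows from this closed form:

- **Ne from census counts.** `Ne = r · Nc` with `r = 0.1` by default. Duck
  census estimates are winter counts made before heavy pre-breeding
  mortality, populations fluctuate strongly (Ne is dominated by the small
  years), and the one congeneric measurement available puts `r` between
  0.05 and 0.09 — so 0.1 is deliberately on the generous side: it makes
  drift-only persistence look as long as defensible.
- **Species table.** For the six study species (census sizes 19, 5.4, 6.9,
  3.3, 3.8, 2.9 million) the module reproduces the published persistence
  table cell-for-cell at `p ∈ {0.5, 0.1}` — with one exception. The
  published *Anas strepera* `p = 0.1` entry (702,179) is identical to the
  *Anas acuta* entry, which the formula does not allow for a different Ne;
  with `Ne = 380,000` the formula gives 494,126. We treat the published
  entry as a typesetting duplication: the code outputs the formula value
  and the pipeline flags the cell (`persistence_frame`'s `*_flag` column).
- **Retention threshold.** `3.8 · Ne · g` years (generation time `g = 1`
  year) is the horizon beyond which only ~5% of polymorphisms starting at
  `p = 0.5` are expected to remain. See the simulator section for what the
  5% figure means precisely.
- **Scenarios.** The threshold depends on Ne and `g` only through their
  product, so "three times larger Ne *or* generation time" is one
  multiplier on that product (`ScenarioConfig.ne_multiplier`). Divergence
  times (6.4 My for the pintail/teal split from the mallard, 8 My minimum
  for wigeon/gadwall) are consumed as cited constants, never estimated.
- **Pooling.** A supra-population — sympatric species connected by ongoing
  hybridisation — is pooled by summing census sizes (members must share
  `r` and `g`). Mallard + pintail + teal gives `Nc = 31.3 M`, `Ne = 3.13 M`
  and a mean `p = 0.5` persistence of 8.68 My.
- **Rounding.** Generation values are rounded half-up to integers (matching
  the published table); million-year values to one decimal.
- Ne is the *diploid* effective number of individuals; this is the
  convention under which the published table reproduces, and it maps
  directly onto the simulator's diploid size `N`.

## The Wright–Fisher simulator and its oracle (`suprapop.wright_fisher`)

`simulate_absorption` iterates `count' ~ Binomial(2N, count/2N)` per
replicate locus until absorption, vectorised across replicates.
Replicates still segregating at the horizon (default `40N` generations)
are reported as `unabsorbed_fraction`, never folded into the mean.

`markov_absorption_oracle` builds the exact `(2N+1)`-state binomial
transition matrix, solves `(I - Q) t = 1` for expected absorption times,
solves the analogous system for fixation probabilities (a cross-check on
the martingale value `i/2N`), and obtains exact `P(segregating at g)` by
powering the transient block. Dense linear algebra limits it to `2N ≤ 400`,
ample for validation. The simulator is tested to agree with the oracle
within Monte-Carlo error at `N ∈ {1, 2, 5, 10, 25}`, and the
oracle/diffusion ratio approaches 1 as N grows — the bridge that licenses
applying the closed form at the study's `Ne ~ 10^6`, which no forward
simulation can reach directly. Desk-scale validation uses `N ≤ 200`;
linearity of `t(p)` in Ne is tested separately in the drift module.

**What "5% after 3.8 Ne generations" means.** The exact chain shows that a
*single* population starting from `p = 0.5` still segregates with
probability ≈ 0.21 at `3.8N` generations (N = 50: 0.218). The often-quoted
5% emerges for *joint* retention: the probability that **both** of two
independently drifting descendant lineages still segregate is the square,
≈ 0.045–0.048. Shared polymorphism requires exactly this joint event, so
the two-lineage reading is the relevant one; the acceptance script reports
both numbers rather than asserting either against the quoted figure.

`simulate_divergence_with_geneflow` models hybridisation as symmetric
gametic migration: two populations start at a common ancestral frequency,
and each generation population i samples `2N_i` copies from the pool
`(1 - m) p_i + m p_j`. No mutation, selection, or recombination. The rate
`m` is a free parameter (the study quantifies no hybridisation rate); the
pipeline sweeps `m ∈ {0, 10⁻³, 10⁻², 10⁻¹}`. At `m = 0.5` both pools
coincide and the pair is distributionally equivalent to one merged
population of the summed size — a tested identity. Joint shared
polymorphism is non-decreasing in `m`, which is the qualitative core of
the gene-flow argument: hybridisation opposes drift by re-importing
alleles a lineage has lost.

All randomness flows from a single seeded `numpy` generator per run;
identical config + seed gives identical output.

## The synthetic panel generator (`suprapop.synth`)

No genotype data accompany the study, so the generator emulates their
statistical shape end-to-end:

1. **Ancestral frequencies** uniform on [0.05, 0.5] (the study does not
   state the panel's ancestral spectrum; this is a documented default, not
   a claim).
2. **Star-shaped divergence.** The focal (mallard-like) lineage is
   simulated once; each satellite species branches off it at its
   divergence time and then drifts with *one-way* gametic migration from
   the focal species' contemporaneous frequency. One-way flow keeps a
   single coherent focal truth trajectory and reflects introgression
   pressure from a vastly more abundant focal species; the full species
   tree is deliberately not modelled (the tested properties do not need
   it).
3. **Ascertainment** draws a finite focal discovery sample (default 20
   individuals) and keeps only loci with both alleles observed — the
   mechanism that produces real panels' bias toward high-MAF loci, which
   the sharing percentages inherit. Candidates are oversampled (1500 for a
   364-locus panel); failure to fill the panel raises, never truncates
   silently.
4. **Genotype sampling** is Hardy–Weinberg within species (panmixia per
   species is the study's own working assumption, and it keeps the HWE
   test calibrated on null data), with independent per-entry missingness
   (4% focal, 14–24% others) and optional F1 hybrids receiving one gamete
   from each parent species per locus.

Default shape mirrors the study: 364 loci, six species, sample sizes
197/7/9/14/10/17, one F1 hybrid. Demography is desk-scale: satellite
diploid size 200 with divergences of 800/800/1200/1200/2000 generations
(4N–10N, the drift-dominated regime in which isolated lineages lose most
ancestral polymorphism, as the real divergence/Ne ratios imply) and
hybridisation rates 10⁻³/10⁻³/2.5·10⁻⁴/2.5·10⁻⁴/0 (4Nm ≈ 0.8 down to 0,
the migration–drift-balance regime). The focal lineage is large (N = 5000)
relative to the tree depth so its own panel survives ascertainment — a
stand-in for the fact that real panels are discovered in present-day
polymorphism, which our mutation-free model cannot regenerate along deep
branches.

**What passing tests do and do not show.** The generator reproduces the
study's *qualitative* structure: a sharing gradient that rises with
hybridisation rate and falls with divergence, ascertainment bias, realistic
missingness, HWE-calibrated genotypes. It does not reproduce the study's
empirical sharing percentages (those depend on the unreleased data and on
demographic details no one measured), linkage structure (loci are
unlinked, as the study's panel was screened to be), mutation, selection, or
within-species geographic structure.

## QC statistics (`suprapop.genotypes`)

MAF is the minor-allele count over `2 × n_called`; observed heterozygosity
is the heterozygote fraction of called individuals; both are computed per
group over non-missing genotypes only. "Polymorphic in a species" means
both alleles observed among the species' called genotypes — a sample-level
definition with no frequency floor, matching what a genotyped panel can
actually assess. Loci with no called genotypes in a group carry NaN
statistics and are excluded from that group's sharing set (logged).

The Hardy–Weinberg test is the exact conditional test: given the allele
counts, every attainable heterozygote count is enumerated with probability
`∝ 2^h / (h! a! b!)`, and the two-sided p-value sums configurations no more
probable than the observed one (probability-ordering convention). Full
enumeration is cheap and deterministic for biallelic loci, so no
Markov-chain approximation is used. The discrete p-values are conservative
by construction; for calibration checks the package exposes the
conditional null distribution (`hwe_null_distribution`) and a randomised
probability-integral transform (`hwe_calibration_pit`) that is exactly
Uniform(0,1) under the null, making Kolmogorov–Smirnov aggregation valid.

LD itself is out of scope; only the multiple-testing bookkeeping is
implemented (`pairwise_test_count`, `bonferroni_alpha`): a 364-locus panel
implies C(364,2) = 66,066 pairwise tests. (Note each individual SNP sits
in 363 of them; 66,066 is the total.)

## Numerical and design notes

- Rounding half-up, not banker's rounding, for the persistence table.
- HWE enumeration uses log-gamma weights with a 1e-9 log-tolerance for
  probability ties; the test suite checks it against an independent
  exact-rational enumeration.
- Boundary initial frequencies (`p ∈ {0, 1}`) return persistence 0 by
  convention rather than raising: an absent or fixed allele does not
  segregate.
- Venn decomposition is exact set algebra over up to 6 named sets; region
  counts sum to the union size by construction and are order-invariant.
- Problem sizes in tests and the acceptance script (N ≤ 100, ≤ 20,000
  replicates, ≤ 2,000 loci, 20 seeds for trend checks) were chosen as the
  smallest at which the targeted effects are resolved beyond Monte-Carlo
  noise.

## Known limitations

- No mutation: deep-branch polymorphism can only be ancestral or
  introgressed, so satellite sharing fractions are not comparable to the
  study's absolute percentages.
- One-way star-shaped gene flow; no satellite–satellite hybridisation.
- The simulator's island model is symmetric in rate but the generator's is
  not; neither models assortative-mating substructure, which the study
  itself notes makes pooled-Ne estimates optimistic.
- The census sizes, Ne:Nc ratio and divergence times are consumed
  constants; no genetic estimation of any of them is attempted.
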