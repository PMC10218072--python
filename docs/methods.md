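# Methods notes

## Scoring model

Genotypes are categorical classes, not allele dosages. The target panels are
inbred selfing lines, almost entirely homozygous, so each distinct genotype
string ("A/A", "A/T", ...) at a locus is treated as its own class; by default
heterozygous calls form their own class (`het_policy="own_class"` in
`read_vcf`), with an option to treat them as missing. The informativeness of
a locus is the genotype-frequency form of polymorphism information content,

    PIC = 1 - sum_g f_g^2,

the probability that two randomly drawn varieties differ at the locus. It is
zero for monomorphic loci and maximised at equal class frequencies (0.5 for a
balanced biallelic homozygous locus).

During selection the panel is a partition into leaves. A locus's score under
a partition ("PIC·sum") is its PIC recomputed inside each leaf and summed,
**unweighted by leaf size**: the score is a redundancy-aware count of how
much splitting power the locus retains, and a small leaf that still needs
splitting matters as much as a large one. A locus already on the selection
path is monomorphic inside every leaf it created and scores exactly zero.

Missing calls are excluded from every frequency computation. When a leaf is
split by a locus, samples missing that call are kept together as a child of
their own rather than merged into a genotype class; real workflows are
expected to impute before selection, and the synthetic generator produces
complete data, so this path only matters for externally supplied matrices.

## Selection procedure

Stage 1 repeatedly (i) scores all remaining candidate loci (plain PIC at the
root, PIC·sum afterwards), (ii) draws one locus uniformly from the top
`top_fraction` (default 0.10) of the score ranking, and (iii) splits every
leaf by that locus, until all leaves are singletons. Numerical details:

- Candidates are restricted to positive scores; when none exists the
  remaining multi-variety leaves are genotypically identical over the
  available loci and are returned as *unsplittable* rather than failing.
- The cut is `ceil(top_fraction * n_candidates)`, so at least one candidate
  is always eligible; ranking ties are broken by (score desc, locus id asc)
  and every locus tying the boundary score stays eligible, which keeps the
  rule well defined when many loci share a score.
- Because the drawn locus has positive score it always splits at least one
  leaf, so the loop terminates.

Stage 2 visits the screened markers in one seeded random shuffle and deletes
a marker iff the remainder still separates every pair of varieties that the
whole matrix separates. Deletions only ever shrink what a set can separate,
so a single complete pass yields an irreducible set; the irreducibility
property is asserted by tests (single-removal check) and, on tiny instances,
compared against exhaustive search over all locus subsets. Greedy sets may
exceed the exhaustive minimum — optimal minimal-set search is out of scope.

Multiple simplified sets are produced by re-running both stages with the loci
of earlier sets excluded (`disjoint_sets=True`, the default); per-set random
streams are spawned from the single configuration seed, so any set can be
regenerated independently. When the remaining loci cannot separate a pair
that the full matrix separates, selection stops with an error that carries
the sets already completed.

Baselines: high-PIC selection draws uniformly from the pool of loci with
PIC > 0.45 (how the original protocol sampled from this pool is not
specified; uniform sampling is the neutral choice), and random selection
draws uniformly from all loci.

## Accuracy metrics and the modification model

*Distinguishing accuracy* is the percentage of varieties whose restricted
genotype vector identifies them: on unmodified data, the fraction of unique
fingerprints; against a reference panel, a variety counts as distinguished iff
its unique best similarity match in the reference is itself. The two
formulations coincide on unmodified data; the nearest-match form is what makes
accuracy degrade smoothly as genotypes are perturbed.

The fault-tolerance simulation perturbs, for each variety independently,
`round(rate * n_markers)` marker calls (round half up), each replaced by a
different genotype class already observed at that locus panel-wide — the
model is *inconsistency between genotyping runs of the same germplasm*, not
novel mutation. Default protocol: rates 5/10/15 % with five repeats;
stochastic trend assertions in the test suite use 20 repeats.

*Identification accuracy* is the percentage of test queries whose unique
highest-similarity match is their true variety; tied best matches count as
incorrect. Similarity between a query and a database fingerprint is the
percentage of identical calls over the loci shared and non-missing in both —
chosen because independent test sets typically share only a minority of loci
with the training panel, and a match-proportion score remains comparable
across queries with different shared-marker counts. The best match and tie
detection use exact rational arithmetic so that 15/30 and 5/10 tie reliably.
A query whose claimed label exists in the database but is not the best match
is flagged as a potential mislabel; the runner-up and its similarity are
reported so users can judge the margin.

## Synthetic data

The generator emulates a resequenced inbred panel: biallelic loci, fully
homozygous calls, and a per-locus major-genotype frequency drawn uniformly
from [0.05, 0.95], which spreads per-locus PIC over essentially its whole
range instead of collapsing onto one mode. Founder varieties draw calls
independently per locus; all varieties are guaranteed pairwise distinct
(duplicate rows are redrawn). Optional *derivative* varieties copy a parent
and flip `max(1, round((1 - similarity) * n_loci))` calls, modelling the
near-duplicate accessions (around 99.99 % similarity) found in real stock
collections; the floor of one flip preserves distinctness at desk-scale locus
counts. Defaults are 200 varieties x 5000 loci with no derivatives.

Test sets copy chosen varieties' calls over a random subset of loci
(default overlap fraction 0.16, mirroring how little two independently
genotyped datasets of the same species overlap), optionally add per-call
genotyping errors, relabel a chosen number of samples with genotypes copied
from a different donor (planted mislabels), and append newly named
derivatives of panel varieties ("different-named" samples). Every planted
fact is recorded in a truth dictionary.

What the generator deliberately omits: linkage disequilibrium, population
structure, geography, and locus-quality artefacts. Passing tests therefore
demonstrate the method's combinatorial behaviour (validity, irreducibility,
fault-tolerance trends, mislabel recovery), not its performance on panels
with strong LD — on real data, LD pruning is expected upstream.

## Study sizes used by tests and the acceptance script

The test suite and `scripts/acceptance.py` work on a 200-variety x
5000-locus panel: large enough that a simplified set (~12 markers, against
the counting floor of ceil(log2 200) = 8) is non-trivial, small enough that
the entire workflow runs in seconds. Monotonicity of accuracy in the
modification rate is asserted on the combined two-set fingerprint
(~24 markers) so that the 5/10/15 % rates map to distinct per-variety
modification counts (1, 2 and 4 calls). Exhaustive-search comparisons use
panels of at most 10 varieties x 12 loci, where all 2^12 marker subsets can
be enumerated.

## QR fingerprint labels

A variety's payload is plain text: the variety name followed by
`chrom:pos=genotype` for each database marker locus, semicolon-separated.
The package contains a complete model-2 QR encoder/decoder (byte mode,
versions 1-40, error-correction levels L/M/Q/H, Reed-Solomon over GF(256)
with Berlekamp-Massey error location, standard mask selection by penalty
score) and PNG rendering. Correctness anchors: published format- and
version-information test strings are asserted in the suite, Reed-Solomon
blocks are corrected up to capacity and rejected beyond it, and
encode-render-decode round trips are exercised across versions, levels and
masks. The decoder targets clean, axis-aligned renders such as those the
package writes (module size is recovered from the finder pattern); decoding
photographs of printed labels is out of scope.

## Known limitations

- Simplified sets are for identification only; they distort marker-based
  genetic distances and must not be used for similarity or cluster analyses.
- Upstream quality control (LD pruning, imputation, coding-region
  annotation) is expected to happen before the matrix reaches this package;
  only the monomorphic-locus, missing-rate and minor-allele-frequency
  filters are built in. With multi-allelic genotypes the minor-allele
  frequency is taken as the second-highest allele frequency.
- Greedy selection does not guarantee minimum-size sets, only irreducible
  ones.
- Identification quality degrades with the number of shared markers; with
  very few shared loci many varieties tie at 100 % similarity and ties are
  reported rather than resolved.
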