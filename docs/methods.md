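# Methods

## The screen

The package implements a phylogenetic-profiling screen for proteins with an
inferred ciliary function, and for the subset of those retained through
evolutionary loss of cilia in land plants and fungi.

**Orthology.** Orthologues between the reference proteome and each target
genome are inferred by reciprocal best hit (RBB) on precomputed 12-column
tabular similarity output. A hit participates only if its e-value is
strictly below 10⁻⁵; the threshold is applied in both search directions
(the reciprocal direction is assumed to use the same cutoff). "Top hit"
means minimum e-value; ties are resolved by highest bit score, then
lexicographically smallest subject identifier, which makes the result
deterministic and independent of line order. Repeated lines for one
(query, subject) pair collapse to the lowest-e-value line first; self-hits
are ignored; an e-value of exactly 0.0 passes any positive threshold. RBB
yields at most one orthologue per (reference protein, target species).

**Profiles and counts.** Presence/absence profiles are taken over an
annotated panel: each genome is ciliated or not, belongs to one of six
eukaryotic supergroups (Archaeplastida, Excavata, Chromalveolata, Holozoa,
Fungi, Amoebozoa), and may be flagged as a non-ciliated land plant or a
fungus. The reference species' own column is all-present (a protein
trivially exists in its own proteome), counts toward β and toward its
supergroup for the LECA set, but is **excluded** from the ≥ 5-species
retention filter — that filter concerns identifiable hits in *other*
genomes. Whether the original screen counted the query species in the
filter is not stated; excluding it is the conservative reading and is the
package's choice. Per protein: β = ciliated species with an orthologue,
α = non-ciliated species with an orthologue, μ = α excluding non-ciliated
plants, plus the plant and fungal decompositions of α
(μ + plants = α; fungal + non-fungal = α).

**Classification.** The ciliary-profile rule is β − 10α > 10, strict. The
−10 weight encodes the asymmetry of profile evidence: missing a true
orthologue in a ciliated genome (annotation gaps, divergence) is common,
whereas a confident hit in a non-ciliated genome is strong evidence against
a cilium-specific role; one false positive therefore outweighs ten true
positives. CCP ("conserved in ciliated and plants") is β > 18 and μ < 2
with an orthologue in at least one non-ciliated plant — "with plant
orthologues" is read as ≥ 1 plant, the weaker of the two possible readings,
and is configurable. The fungal-retained rule has no printed formula; it is
implemented as the exact mirror of CCP with the non-ciliated fungi in the
plants' role (β > 18, non-fungal non-ciliated count < 2, ≥ 1 non-ciliated
fungal orthologue), thresholds shared. All thresholds are keyword
parameters with these defaults, so sensitivity analyses are one call away.
The LECA set requires presence in ≥ 1 species of each of the six
supergroups.

**Overlap accounting.** Candidate sets are intersected exact-string with
reference ciliary-proteome ID lists; mapping between identifier namespaces
is deliberately left to the caller. Percentages render at 1 decimal place
when ≥ 1% and 2 when < 1%, rounding half away from zero — the rule chosen
because it reproduces every published summary figure from its count pair.

**Expression enrichment.** Expression matrices (genes × stages, one stage
designated mature pollen) are rescaled per gene by dividing by the gene's
median across stages ("fold change from median"); the ratio is kept on the
natural scale, not logged, since the set statistic is a plain sum of fold
changes. Genes with a zero median are excluded and reported; an optional
pseudocount mode (add the matrix's smallest positive value) retains them.
The test statistic for a k-gene set is the sum of its pollen fold changes.
Its null distribution is sampled by drawing N random k-gene sets uniformly
without replacement from all genes on the array (the test genes are *not*
excluded from the universe by default, matching sampling "within the
genome"; exclusion is an option). p = (r + 1)/(N + 1), where r counts null
statistics ≥ observed (ties are exceedances); this estimator can never be 0
and is exactly uniform under the null up to discreteness. The plain r/N
estimator is available since the convention behind historical reports is
ambiguous. N defaults to 22,640 — the published choice, treated as an
ordinary parameter. Heatmap row ordering uses average-linkage hierarchical
clustering on Euclidean distances between log2 fold-change rows (log only
for distances; zero cells clipped at 10⁻¹² to keep distances finite); it is
cosmetic and nothing downstream depends on it.

## Synthetic data

The generator produces the study conditions end to end. The default panel
has 29 ciliated and 16 non-ciliated genomes, of which 3 are non-ciliated
land plants; the number of non-ciliated fungi is not printed anywhere, and
5 is used (the typical yeast/microsporidian complement of such panels).
Ciliated species cycle through all six supergroups so the LECA rule is
exercisable. Planted profile classes before noise: ubiquitous (present
everywhere), ciliary-profile (all ciliated, no non-ciliated),
CCP (ciliated + non-ciliated plants), fungal-retained (ciliated +
non-ciliated fungi), and random background with per-cell presence 0.3
(arbitrary but fixed; configurable). Noise flips truly-absent cells on with
probability `fp_rate` and truly-present cells off with `fn_rate`,
independently per cell; the query column is never flipped. Synthetic hit
tables realise a presence matrix as mutual-top hit pairs (e-values ≪ 10⁻⁵),
optionally adding weaker never-top decoy hits and, separately,
reciprocity-breaking decoys that redirect a reverse best hit — with only
harmless decoys, parse → RBB → matrix is the identity. Expression
backgrounds are log-normal per cell (log-mean 0, log-sd `noise_sd`), the
simplest strictly positive model compatible with ratio fold changes; the
planted set's pollen values are multiplied by `effect`.

What the synthetic data does **not** emulate: sequence evolution and
realistic similarity-score distributions, correlated presence/absence
between related species (noise is i.i.d. per cell), paralogy and
lineage-specific duplications, microarray probe effects and normalisation
artefacts, and correlated expression between stages. Passing tests
therefore demonstrate the machinery's correctness and its statistical
behaviour under the stated noise model, not performance on real proteomes.

## Verification scale and numerical choices

Test and acceptance problem sizes are chosen so the full suite runs in
seconds on one CPU while keeping estimates well inside their tolerance
bands: RBB oracle equivalence on 200 random two-proteome instances (≤ 10
proteins a side, tie-heavy e-value grid); round trips on 5 seeds;
planted-class recovery with 200 ciliary + 800 background proteins at
fp = 0.02, fn = 0.1 (sensitivity ≥ 0.9 and specificity ≥ 0.99 — with these
rates a planted profile fails mainly when ≥ 2 false-positive non-ciliated
hits land on it, probability ≈ 4%); permutation calibration over 500 null
replicates of a 200-gene × 10-stage universe at N = 999 (type-I error
within the binomial 95% band around 0.05); power over 100 replicates with a
3-fold effect at noise_sd 0.25 (p at the 1/1000 floor in ≥ 95%); and a
6-gene/choose-2 universe where the Monte Carlo null is compared against
exhaustive enumeration of all 15 subsets.

Degenerate inputs are defined rather than accidental: an empty hit stream
is an empty table; absence of a passing hit is a result, not an error; an
empty gene set sums to 0 but has no mean; a single-stage expression matrix,
a set not smaller than its universe, and a zero denominator in percentage
formatting are errors.

## Known limitations

- Real-data headline counts (e.g. a 4,802-protein dataset yielding 213
  ciliary-profile and 21 CCP proteins) depend on 45 real proteomes and full
  similarity-search runs plus undeposited expression tables; they are not
  recomputable here, and the package validates the machinery on synthetic
  conditions instead.
- Exact-string overlap accounting ignores cross-namespace identifier
  mapping, which in practice dominates the error in "previously detected"
  percentages.
- RBB is a deliberately simple orthology heuristic: no in-paralog
  clustering, no synteny, at most one orthologue per species.
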