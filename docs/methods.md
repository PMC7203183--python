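# Methods

## Model and assumptions

The package operationalizes one hypothesis: small-subunit rRNA grew by
accretion of proto-tRNA-like elements, so a structural subelement's age
should predict how much its secondary-structure phenotype resembles that
of a proto-tRNA reference. Theoretical minimal RNA rings serve as the
reference family, and two externally derived age scales are consumed as
data: phylogenetic accretion ranks (1–39) and structural onion-model
ranks (1–27). Both scales enter only through Pearson correlations, so
any positive affine rescaling of the ranks leaves every statistic
unchanged.

The analysis is deliberately phenotype-level: structures are reduced to
four percentages, similarity is a four-point correlation, and inference
is by the sign of rank correlations pooled over a factorial design
(6 organisms × 25 rings × 22 splicings). No sequence alignment or
phylogenetic computation happens inside the package; re-deriving the
rank scales is out of scope.

## The four structure variables

For a canonical-pair-masked structure with `n_total` nucleotides,
`n_paired` of them paired:

* `pct_stem  = 100 · n_paired / n_total`
* `pct_eloop = 100 · n_eloop / n_unpaired`
* `pct_gc_stem = 100 · n_gc_paired / n_paired`
* `pct_gc_loop = 100 · n_gc_unpaired / n_unpaired`

"eloop" counts unpaired positions whose nearest paired neighbours on both
sides form one and the same pair — hairpin loops, called *external loops*
in this analysis's nomenclature (not the standard exterior loop). Bulges,
internal loops, multibranch loops and dangling ends are all internal.
Only Watson–Crick pairs and the G–U wobble are canonical; any other drawn
pair is removed and both positions counted as unpaired.

Zero denominators (a fully paired or fully unpaired structure) yield 0.0
for the affected percentages plus a degeneracy flag; the similarity stage
excludes flagged vectors rather than fabricate values, which is why the
per-organism sample sizes `n_phyl`/`n_stru` can fall below the number of
catalogued subelements.

## The ring family and its constraint readings

A minimal ring is a 22-nt circular sequence whose 22 overlapping
trinucleotide windows are exactly the codons of three consecutive
translation rounds (gcd(3, 22) = 1 makes the two sets coincide). The
published design constraints — one start, one stop "physically next" to
the start, all 20 amino acids — admit more than one formal reading, so
`constraint_mode` exposes three, each enumerated by an exhaustive pruned
depth-first search and re-verified by an independent checker:

* `coding`: exactly one stop; the start AUG sits three nucleotides after
  the stop (the reading frame from the start ends at that stop, which
  therefore occupies the 3 nt immediately 5′ of the start, closing the
  ring); the remaining 20 windows code the 20 amino acids exactly once.
  1280 rotation-distinct solutions.
* `coding_adjacent`: additionally the met-coding AUG overlaps the stop
  (the AUGA motif seen in the reference ring). 336 solutions.
* `canonical_codons` (default): the family shares one fixed codon per
  amino acid — the assignment realized by the published reference ring
  (AB) — plus the AUG start and UGA stop; rings are the circular
  arrangements whose window multiset realizes that codon set exactly.
  24 solutions, the only reading within the published bound of
  "at most 25", and the reference ring is one of them.

The coding constraints alone therefore do not reproduce the published
family size; the fixed-codon-assignment reading does, and it is the
package's own design choice for the default. Ring identity is the
lexicographically smallest rotation; enumeration order is deterministic
(nucleotide order A<C<G<U, no randomness). Splicing position 1 is the
rotation published as having highest homology with an ancestral tRNA,
shipped as an annotation (`anchor_offset`); positions 2–22 shift by one
nucleotide each. Cognate amino acids and genetic-code integration orders
are only published for two rings (the reference ring, Gly; one ring
whose predicted anticodon reads the UGA stop, Sec); the annotation
catalogue ships those and leaves the rest null and user-editable, so the
per-ring integration-order trend is a reported correlation, never a
pass/fail gate.

## Similarity and its transform: calibration

rS is the Pearson correlation across the four variable pairs of two
feature vectors. Degenerate vectors (zero variance, or missing cells in
fixture rows) make the pair invalid; invalid pairs reduce the rank-
correlation sample instead of entering as zeros.

Three conventions are implemented for the value that enters the rank
correlation rH:

* `identity` — rH = corr(rS, rank) on the raw similarities (default);
* `fisher` — z = arctanh(rS), the conventional variance-stabilizer;
* `paper_literal` — z = −ln((1+rS)/(1−rS)) = −2·arctanh(rS), a printed
  formula whose sign is inverted relative to `fisher`, so every
  downstream rH flips sign exactly between the two log modes (an
  invariant the tests assert).

The default was fixed by calibration against the published per-organism
rH extrema achieved by the reference ring: recomputing from the packaged
tables, `identity` reproduces the Thermus extrema exactly
(−46.1 and +38.7, ×100) and five further extrema across the other
organisms within input-rounding error, while both log conventions miss by
5–10 points (×100). The published methods text prints the log formula,
but the published numbers are only consistent with correlating raw rS;
both options remain available and sign-dual.

Correlations are clamped to ±(1 − 10⁻¹²) before the log transforms so z
stays finite.

## Aggregation

For each organism the per-(ring, splicing) rH values are summarized by
their extrema (×100, with the achieving ring's cognate where annotated),
the percentage of strictly negative values (zero counts as non-negative),
and a 1-df chi-square of the sign split against 50/50, two-sided, no
continuity correction, significance at 0.05, no multiple-testing
correction (matching the original analysis; reports carry a note).
Undefined rH values (degenerate structures, too few complete pairs) are
excluded from numerator and denominator and reported separately; a
fixed-denominator option reproduces the published accounting that divides
by the full rings × splicings total. Per-ring pooling (6 organisms × 22
splicings = 132 values per method) and per-splicing pooling (6 × 25 =
150) conserve the grand total of 6 × 550 per method, asserted in tests.

## Rank-scale congruence

The two age scales are compared directly: ranks normalized by their scale
maxima (39 and 27) times 100, a point "congruent" when the absolute
normalized difference is strictly below 25 (ties hollow). On the packaged
tables: 44 dual-ranked subelements, 26 congruent (59%), in exact
agreement with the published counts. The correlations computed from the
printed rank columns are r = 0.245 (all points) and r = 0.882 (congruent
subset) versus published values of 0.308 and 0.898. An exhaustive
sensitivity analysis over every grammar-consistent re-reading of the rank
columns, all single-row integer substitutions and all two-row
combinations found no reading that reproduces the published r values
while preserving the counts, so the figure behind those values must have
used rank data differing from the printed table in at least two rows.
The package reports what the packaged tables imply.

## Fixture curation

The six-organism tables ship as CSVs hand-curated from a plain-text
rendering that concatenates all columns without separators. Decoding used
a grammar (one-decimal percentages; integer or fractional ranks; blank
patterns for degenerate structures, e.g. a fully unpaired subelement
prints 0.0, 0.0, blank, x) plus cross-checks against independently
verifiable anchors: the worked h44/h45 feature examples, the dual-rank
and congruence counts, the structural-rank sample sizes per organism
(48/46/48/48/48/48, all reproduced), and the per-organism rH extrema
achieved by the reference ring. Residual ambiguities were resolved to the
unique reading consistent with all anchors simultaneously.

Known blemishes are preserved, not repaired: several GC percentages print
above 100 (arithmetic slips in the source) and are kept verbatim with an
out-of-range flag and a switch to exclude flagged rows; one structural
rank is fractional (3.3, a tied rank), so rank fields are floats; the
published phylogenetic-rank sample sizes for four organisms (38/44/42/39)
cannot be derived from any missing-data rule on the printed tables
(realized: 43/43/44/43) — the validator reports expected versus realized
and only raises in strict mode; and one organism's published
phylogenetic extrema lie outside the envelope computable from its printed
features, with no two-row exclusion explaining the gap. None of these
affect the reproduced quantities above.

## Synthetic data generator

The generator emulates the one statistical feature the analysis relies
on: a reference structural phenotype whose similarity to a subelement
decays with the subelement's accretion rank. A reference vector is drawn
within the empirical per-variable ranges of the reference ring's
splicing table; subelement i is

    reference + effect_size · rank_i · u + Normal(0, noise_sd)

clipped to [0, 100] (clip rate reported), with u the reversed-profile
unit direction −(ref − mean(ref))/‖·‖, so growing rank progressively
inverts the profile and ring-versus-subelement correlations trend
negative. Ring tables are the same reference plus noise, kept within the
empirical ranges — ring structures form one family, as the real splicing
variants do; tables generated with a shared `reference_seed` share the
reference, which is how a multi-organism run plants a common signal.
Defaults: 45 subelements, 25 rings × 22 splicings (the study dimensions),
effect_size 0.5 percentage points per rank unit and noise_sd 10
percentage points, chosen so the planted signal is comparable to the
observed sign percentages (60–90% negative) rather than saturated.
Effect 0 makes ranks exchangeable; rank schemes are identity or seeded
permutation. A single seeded generator (numpy PCG64, stream-tagged)
drives all randomness; seeds are recorded in the table attributes.

Limits: the generator does not simulate sequences or structures, only
feature vectors, and its Gaussian, single-direction drift is far tidier
than real structural evolution — passing the recovery tests shows the
statistics detect a planted monotone signal at realistic noise, not that
real rRNA data contain one. Within one organism table the 550 ring
structures are near-duplicates, so per-organism rH values are strongly
correlated and a single bad noise draw can flip one organism's sign
majority; pooling across organisms is what stabilizes the sign statistics,
in the simulation as in the real design.

## Numerical choices

* Built-in folding is a maximum-canonical-pairing dynamic programme
  (minimum hairpin 3) with a deterministic traceback preferring the
  5′-most pairings; it is a reproducible baseline, not a thermodynamic
  model. The external backend shells out to RNAfold at its defaults
  (37 °C), recorded in provenance.
* Coordinates are 0-based half-open internally, 1-based in CT I/O.
* Feature values are stored at full precision; comparisons against the
  packaged tables round to one decimal, the printed precision.
* Pipeline reruns with an identical configuration are byte-identical;
  the manifest lists every output with a SHA-256 hash.

## Problem sizes used in tests

The test suite runs the full fixture pipeline (6 × 22 rH pairs), a
catalogue-folded run (24 rings × 22 splicings), a 550-structure synthetic
run for the counting invariants, 100 seeded sign-recovery replicates at
the six-organism design with 30 subelements and 5 rings per table, and
200 null replicates of 20 independent single-ring tables for the
chi-square type-I check. Enumeration of all three constraint modes takes
a few seconds in total.
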