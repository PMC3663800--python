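# Methods

## Model and assumptions

The pipeline assumes that a biologically meaningful miRNA–mRNA interaction
in a two-group comparison expresses itself as *bimodality*: each involved
probe takes one of two expression levels across the collective, and the
level assignment of the miRNA is opposite to that of its target. The method
therefore never compares group means; it discretizes each probe on its own,
combines discrete states per sample, and only afterwards asks how well the
per-sample pattern matches the experimental grouping. Because the
discretizer is driven by data coverage rather than by absolute values, a
single extreme outlier sample has essentially no influence on the states of
the other samples (this is verified on fixtures, not claimed universally).

## Discretization

Log-normalized values are exponentiated so that all quantities are positive
and fold changes are well defined. For one probe with values
V = {e₁ … e_m} (multiset over the m samples):

- afc(x, y) = max(x, y)/min(x, y); symmetric, ≥ 1, scale-invariant.
- The neighborhood of an observed value a under threshold n is
  A = {x ∈ V : afc(x, a) ≤ n} — the values "similarly expressed" to a.
- A candidate split is an ordered pair of distinct observed values a < b
  with neighborhoods A, B. Its score is

      s(a,b) = (|A∪B|/m) · ( |A∪B| / (afc(a, Ā)·afc(b, B̄)) ) · 4|A||B|/(|A|+|B|)²

  where Ā, B̄ are the neighborhood means: a quadratic data-coverage term,
  with the two representative-centrality penalties folded into one of the
  two coverage factors (so they weigh less than coverage itself), and a
  size-distribution term that favors balanced neighborhoods. The final
  score is s if afc(a, b) > f and 0 otherwise — representatives must be
  genuinely separated.
- The maximizer over all candidate pairs and over the configured list of
  (f, n) threshold pairs defines boundaries b₁ = max A, b₂ = min B,
  switched if b₁ > b₂. States: v ≤ b₁ → L, v ≥ b₂ → H, else M; at a shared
  boundary L wins (deterministic, the tie is genuinely ambiguous).

The candidate search is exhaustive over all ordered pairs of distinct
observed values, O(m²) per probe — exact and fast at the sample sizes this
method targets (tens of samples). Equally scoring candidates are resolved
by larger joint coverage |A∪B|, then the lexicographically smallest (a, b),
then earlier position in the threshold-pair list.

### Choice of the score's algebraic form

The verbal contract for the score fixes its structure (quadratic coverage,
balance term, penalties inside one coverage factor, separation constraint)
but not every algebraic detail. Two choices were made here, once, on
a-priori grounds:

- **Balance term 4|A||B|/(|A|+|B|)²** rather than min/max. The method is
  documented to work on collectives where one group is twice the other
  (8 vs 16 samples). With min/max, a perfect 8/16 split scores exactly
  0.5·m, i.e. *at* the default probe-score cutoff, and every such probe
  would be discarded; the smoother 4ab/(a+b)² term (0.89 at 8/16, max 1 at
  equality) preserves the intended behavior while still penalizing
  one-vs-rest splits strongly (0.15 at 1/24).
- **Penalty form afc(representative, neighborhood mean)**, the natural
  "distance of a representative from its set" in fold-change terms; both
  penalties divide the second coverage factor.

With these choices the attainable maximum of the final score is m (full
coverage, equal halves, perfectly central representatives), which is why
the probe filter threshold is expressed as t·m.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| threshold_pairs | (2.0, 1.5), (1.5, 1.25) | candidate (fold f, neighborhood n) pairs, tried per probe |
| probe_score_factor t | 0.5 | keep probes with score > t·m (m = samples) |
| medium_ratio_max r_M | 0.5 | drop rows with a strictly larger fraction of M states |
| undefined_freq_max u | 0.5 | drop interactions with a strictly larger fraction of undefined states |
| correlation_cutoff | −0.4 | keep interactions with ρ ≤ cutoff in ≥ 1 group (inclusive) |
| present_call_min_fraction | 0.20 | keep probes present in at least this fraction of samples (inclusive) |

The threshold-pair list and the three filter constants are *defaults of this
package*, chosen so that an e²-fold bimodal probe passes comfortably while
constant probes never do; any reproduction of a specific published analysis
must set them explicitly from that analysis (they are mandatory keys in the
YAML config for exactly this reason). "Higher than a threshold" is read as
strict inequality for the score, medium-ratio and undefined-frequency
filters; "at least" and "ρ ≤ −0.4" are inclusive.

The medium-ratio filter is applied to the rows actually fed into
interaction construction: miRNA probe rows and aggregated gene rows. The
underlying function operates on any state matrix, so filtering at the mRNA
probe level instead is a one-line change for users who prefer it.

## Ranking and its degenerate cases

The Jaccard index between the expected partition (G_HL / G_LH / G_undef) and
the experimental partition is the pair-counting cluster-validity form — the
only "Jaccard" defined between partitions with different block counts. The
3-block expected partition is compared against the 2-block experimental one
directly; no artificial third experimental block is invented. If no sample
pair is co-clustered in either partition the index is defined as 0 (no
evidence of agreement). Group-modal states that tie across comp sets make
the interaction non-differential (conservative and deterministic).

## Classifier and bootstrap

The vote classifier stores, per selected interaction, the comp set
containing the reference group's modal training state. A test sample votes
+1 for the reference group per interaction whose state falls in that set,
+1 against per opposite-set state, nothing for undefined states. Ties —
including the all-undefined case — predict the *non*-reference group
(conservative toward the negative class). Bootstrap replicates split every
group in half without replacement (odd groups give training the extra
sample) and re-run the entire pipeline on each half independently; test
samples are scored with test-side states of training-selected interactions
(models are not re-selected on the test side; a strict re-selection mode
would only shrink the usable interaction set). Replicate r uses seed
base + r, so replicates are individually reproducible and order-independent.
Replicates whose training half yields an empty model at a threshold are
skipped and counted.

## Synthetic data

The generator emulates a small clinical collective: by default 24 samples
in three groups of 8 (one control, two tumor stages) with a two-class
normal/tumor contrast, 500 catalog pairs of which 50 are planted. A planted
pair has its miRNA at log level 2 in one contrast class and 0 in the other
(e² ≈ 7.4-fold, a clearly bimodal microarray signal), the target mirrored,
and Gaussian noise of sd 0.2 on the log scale; the target's within-group
noise is anti-correlated with the miRNA's (coupling 0.8) so that genuine
repression leaves the moderate negative within-group correlation the ρ
filter looks for. Decoys sit at a single level. `flip_fraction` flips
individual samples of a planted pair to the opposite regulation; at 0.5 the
pair is bimodal but carries no group information, which is the generator's
"pure noise" setting.

What a green test on this world does establish: the pipeline recovers
planted regulation, ranks it above unstructured decoys, and its bootstrap
classifier behaves correctly at both the strong-signal and the
no-signal extremes. What it does not establish: behavior under realistic
microarray artifacts (batch effects, dye bias, probe cross-hybridization),
non-bimodal regulation, or catalogs with correlated decoys — none of which
the generator models.

One caveat the synthetic world makes visible: at noise sd 0.2 even
*unimodal* decoy probes can pass the probe-score filter, because a
neighborhood threshold of 1.5 spans the entire noise distribution and any
median split of pure noise covers all samples. The downstream filters and
the Jaccard ranking, not the probe score alone, are what separates planted
signal (JI = 1.0) from such decoys (JI ≤ ≈0.4 in practice); this mirrors
the method's own design, where the score only gates plausibly bimodal
probes and the ranking carries the inferential weight.

## Numerical choices

- States are computed on exponentiated values; shift invariance on the log
  scale holds because every term depends only on fold changes and set sizes.
- The discretizer is validated against an independent exhaustive brute-force
  search for exact equality (score, chosen thresholds, states), not within
  a tolerance; all predicates use the same division forms as their
  definitions so the two routes agree bit-for-bit.
- Ward linkage is applied to the city-block distance matrix as-is, although
  Ward's method classically assumes Euclidean distances — fidelity to the
  analysis this package mirrors, over orthodoxy.
- PCA of the distance matrix centers columns, decomposes by SVD, orders
  components by variance and fixes signs so each component's
  largest-magnitude loading is positive.
- Spearman ρ uses the midrank convention for ties; a constant vector within
  a group yields a missing ρ, which never satisfies the negative-correlation
  criterion.

## Known limitations

- The discretizer assumes exactly two expression levels; probes with three
  or more genuine levels are forced into the closest two-level description.
- Strongly unbalanced groups degrade the balance term and with it the
  probe score; the method is not recommended when group sizes differ by
  much more than a factor of two.
- The probe-score filter does not by itself reject unimodal noise when the
  neighborhood threshold is wide relative to the noise scale (see above).
- Correlation filtering needs ≥ 3 samples per group and loses power in very
  small groups.
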