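# Methods

## Contact definition and extraction

Two residues are in contact when their representative atoms lie strictly
within a threshold distance (default 8.0 Å, configurable). The
representative atom is Cβ, or Cα for glycine; a non-glycine residue whose
Cβ is unresolved falls back to Cα rather than being dropped, maximizing the
number of evaluable pairs (the fallback is logged). Residues whose
representative atom is absent altogether are *unobserved*: they appear in
no true contact and predictions touching them are excluded before
selection, so predictors are not penalized for unresolved structure
regions. The 8.0 Å boundary is exclusive: a pair at exactly the threshold
is not a contact.

Sequence separation s = |j − i| bins contacts into short [6, 12),
medium [12, 24) and long [24, ∞) range. The half-open convention resolves
the ambiguity of verbal ranges like "6 to 12" at the shared endpoints and
matches the unambiguous "24 or more" lower edge of the long class; s < 6 is
outside every evaluated class. All pairs are normalized to i < j and
positions are 1-based throughout.

Structure files are parsed with gemmi (PDB; mmCIF via the same contract).
Structure residue numbers are assumed to equal 1-based sequence positions;
an explicit (residue number, insertion code) → position map overrides this
for renumbered or insertion-coded files. Full sequence-to-structure
alignment is deliberately out of scope — the residue-identity cross-check
against the FASTA sequence raises on the first mismatch, which catches
off-by-one numbering early. The first alternate location of an atom wins.

## Metrics

* **Top-L/n selection** keeps the ⌊L/n⌋ highest-scored pairs of one
  separation class, with a minimum of one so tiny targets still contribute
  a denominator. Rounding is not standardized anywhere authoritative; floor
  is the common assessment convention. Ties are broken by (i, j)
  lexicographic order after score descending, making selections fully
  deterministic and nested: the top-L/10 list is a prefix of the top-L/5
  list, which is a prefix of the top-L list.
* **Exact accuracy** is (selected ∩ true) / |selected|.
* **Neighbourhood accuracy** at offset δ counts a prediction (x, y) as
  correct when some true contact (u, v) has |x − u| ≤ δ and |y − v| ≤ δ — a
  Chebyshev box on normalized pairs. One true contact may validate several
  predictions (the criterion is existence, not assignment), and the
  matching contact need not share the prediction's separation class. δ = 0
  reduces exactly to exact accuracy, and the metric is non-decreasing in δ.
* **Greedy clustering** scans the selection in rank order; a pair is kept
  as a representative iff it differs by more than the radius (default 8)
  on at least one index from every earlier representative. Representatives
  are scored with neighbourhood accuracy at δ = 2 (cluster accuracy); the
  count proxies the number of distinct interaction areas identified.
  Dataset-level cluster counts are summed over targets, matching the
  hundreds-scale totals such counts are reported at.
* **Pooled ROC/AUC** pools every target's top-L/n selection with exact
  contact labels and sweeps all distinct scores as decision thresholds
  (scikit-learn's sweep, no intermediate points dropped); AUC is the
  trapezoidal area, which equals the tie-adjusted Mann–Whitney statistic.
  The separation class of the pooled selection is a parameter (default
  long, for consistency with the per-class accuracy tables).
* **Dataset summaries** are per-target means; SE is the sample standard
  deviation (N − 1 denominator) over √N, undefined for a single target.

The evaluation unit is the full protein: no per-domain splitting. Targets a
method did not submit are excluded from that method's averages rather than
scored zero — averaging over a method's own coverage is the only rule
consistent with restricting comparisons to methods that predicted most
targets; coverage is logged and reported.

## Synthetic data

The chain generator is a fixed-step (3.8 Å) random walk whose step
direction mixes an isotropic Gaussian with a pull toward the running
centroid. The compactness default (pull scale 0.06) gives globules
whose contact maps combine the near-diagonal band of a polymer with genuine
long-range contacts at a sparse, protein-like density (roughly 5–25% of
long-range pairs); chains of 60+ residues are regenerated with a perturbed
seed (bounded retries) until a long-range contact exists. This is not a
physical model: there is no excluded volume, no secondary structure, and
residue identities are uniform random, so passing tests demonstrate metric
correctness, not predictor performance on real proteins.

The prediction generator plants *exact counts*: round(p_exact·m) true
contacts, round(p_near·m) pairs at Chebyshev distance exactly δ* from the
true contact set (and not contacts themselves), and the remainder at
Chebyshev distance > δ*, all within one separation class, with strictly
decreasing scores in a shuffled order. Exact-count planting (largest
remainder on rounding conflicts) makes every expected accuracy a closed
form — exact accuracy is round(p_exact·m)/m, neighbourhood accuracy at δ*
adds exactly the near-miss fraction — so recovery tests are equalities, not
statistical bounds. Dataset generation derives per-target seeds from the
master seed via seed sequences; no global random state is used anywhere.

## Numerical choices and degenerate inputs

* Distances are plain Euclidean double precision; the strict `<` at the
  threshold is applied to the computed distance.
* RR scores are serialized with shortest-round-trip float formatting so
  read∘write is the identity and rankings survive exactly. Duplicate pairs
  with identical scores are deduplicated silently; conflicting scores are
  an error, since any resolution rule would silently change rankings.
* Empty selections are errors at the metric level and recorded as *absent*
  (not zero) at the benchmark level, so a method that never predicts
  short-range pairs is not charged a zero in that class.
* Reports round to 3 decimals in TSV/markdown; JSON keeps full precision.
* Benchmark table rows are ordered by top-L/10 long-range accuracy,
  descending.

## Problem sizes

The test suite and the reproduction script run entirely on synthetic data:
oracle-equivalence checks use a few hundred random instances on chains of
up to 100 residues, and the benchmark demonstration uses ten 80-residue
targets with 16 predictions each — sizes at which brute-force oracles
(all-pairs distance scans, exhaustive neighbourhood loops, Mann–Whitney
pair counting) remain exact and cheap.

## Limitations

Multi-chain and inter-chain contacts, heavy-atom or Cα-only contact
definitions, per-domain assessment, precision–recall analysis, and
significance testing between methods are out of scope. The synthetic error
model (uniform near misses at one fixed offset) does not emulate any real
predictor's error profile; conclusions about real methods require real
submissions and structures.
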