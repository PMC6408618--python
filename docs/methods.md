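# Methods

## Pipeline model

`phylocat` treats supermatrix construction as a fixed sequence of
set-to-set transforms on a collection of per-orthogroup amino-acid
alignments over a shared taxon universe:

    mask → occupancy-select → [rate-trim] → [recode] → concatenate

Masking runs first because discarding low-confidence columns can empty
a taxon's row, which changes the occupancy that the next stage counts.
Each stage only removes information (columns, loci, character-state
resolution), so per-stage locus counts are monotonically
non-increasing — the `run` manifest records them and the property is
asserted in tests.

Assumptions inherited from orthology-inference output: at most one
sequence per taxon per orthogroup (violations are reported, never
silently resolved — the upstream transcript-selection rule is not
ours to guess); all rows of a locus are aligned to equal length;
alignments are amino-acid. Nucleotide and codon data are out of scope.

### Missing data vs gaps

`?` marks a taxon absent from a locus; `-` marks an alignment gap.
Both are "no information" for statistics (occupancy, conservation,
missingness) but are never rewritten into each other in the matrices.
Because published "% missing data" figures rarely say which cells they
count, the occupancy report carries both `percent_missing`
(`?` and `-`) and `percent_missing_absent_only` (`?` only).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| masking threshold | 5 | minimum per-column confidence score kept (0–10 scale) |
| occupancy `fraction` / `min_taxa` | — | minimum share or count of taxa per locus |
| occupancy `rounding` | `ceil` | how a fraction becomes a count (see below) |
| `q_low`, `q_high` | 0.2, 0.2 | slow/fast rate-tail fractions discarded, `floor(q·N)` per tail |
| `gap_policy` | `exclude_pairs_with_gap` | gap handling in pairwise identity |
| partition model token | `LG4X` | per-partition model string in RAxML-dialect files |

**Fraction rounding.** Published count/fraction pairs ("50% → 55 of
108", "70% → 77 of 108", "50% → 28 of 58") follow no single rounding
rule, so the rule is an explicit parameter: `ceil` (smallest count
meeting the fraction), `floor_plus_one` (strictly above it), or
`explicit` (pass a published count through and log the fraction it
implies — the recommended mode for replication).

**Rate trimming.** Locus conservation is the mean of percent pairwise
identity over all unordered pairs of non-empty rows, in [0, 1]; the
raw accumulated sum over pairs is exposed as an alternative statistic
(`statistic="sum"`) since per-locus "accumulated conservation" values
in the literature are sometimes unnormalised. `q_low` trims the
lowest-rate (most conserved, slowest-evolving) end and `q_high` the
highest-rate end; ranking ties are broken by locus id, and loci with
fewer than two non-empty rows are excluded from ranking and dropped
with a warning, since their conservation is undefined. A pair of rows
with zero comparable columns contributes nothing to the mean.

**Gap policy.** Under the default `exclude_pairs_with_gap`, a column
contributes to a pair's identity only when both rows carry residues,
so missingness is not conflated with divergence; `count_as_mismatch`
instead scores residue-versus-gap as a comparable mismatch
(gap-versus-gap columns never count under either policy).

**Dayhoff recoding** maps the 20 canonical letters onto `0`–`5`
(AGPST / FWY / C / HKR / ILMV / EDNQ; class sizes 5,3,1,3,4,4), keeps
`-`, and maps ambiguity letters (B, Z, J, X, U, O), `?` and `*` to
`?`. By default even single-class ambiguities (B = D/N, both class 5)
become `?` — explicitness over cleverness; `resolve_ambiguities=True`
resolves exactly those cases. Digit output is directly consumable by
multi-state inference programs; tree inference itself is out of scope.

## Synthetic data generator

`simulate_dataset` emulates the statistical structure the pipeline
assumes, with full ground truth:

* **Tree**: random rooted binary topology by sequential random joins;
  branch lengths i.i.d. exponential with mean `branch_length_mean`
  (default 0.05 substitutions/site, giving pairwise tip depths around
  0.5 for 20 taxa).
* **Sequences**: root residues i.i.d. uniform over the 20 amino
  acids, evolved under a 20-state equal-exchangeability Markov model
  ("JC-20") where a branch of length `t` in a locus with rate
  multiplier `r` leaves a site unchanged with probability
  `1/20 + (19/20)·exp(−(20/19)·r·t)`. The closed form allows the
  simulator itself to be checked against hand-computed expectations
  (see `test_jc20_identity_decays_with_branch_length`). The choice of
  an equal-exchangeability model over an empirical matrix is
  deliberate: it keeps oracle checks analytic and needs no external
  model files.
* **Rates**: per-locus multipliers `r_g ~ lognormal(0, σ)`, default
  σ = 0.5, producing the conservation gradient the rate-trim stage
  ranks.
* **Occupancy**: per-taxon capture probabilities `c_i ~ Beta(8, 2)`
  (mean 0.8), shared across loci; a taxon's whole row is dropped from
  a locus with probability `1 − c_i`, matching orthogroup semantics
  (`capture_beta = 0` forces the no-dropout limit `c_i = 1`).
* **Unreliable columns**: each column is independently noisy with
  probability `f` (default 0.1); noisy columns are overwritten with
  i.i.d. uniform residues and scored from U[0, 3], others from
  U[6, 10], well separated around the default masking threshold 5.

Default sizes (20 taxa, 100 loci of 100–300 columns) are a modest
transcriptome-scale study; they run in seconds and are the problem
sizes used throughout the tests and the acceptance script (the oracle
comparison uses 200 loci; occupancy recovery uses 500).

What the simulator does **not** model: indels (gaps enter only through
real input alignments), compositional heterogeneity, heterotachy,
alignment error beyond whole-column noise, and paralogy. Passing
recovery tests therefore show the pipeline computes its definitions
correctly and recovers structure under its own assumptions — not that
those filters improve inference on real data.

All randomness flows from one seed through a single generator in a
documented draw order (capture, tree, then per locus: length, rate,
evolution, noise, scores, dropout), so identical parameters give
byte-identical datasets; the composite `run` command is bytewise
deterministic end-to-end (no timestamps in any artifact).

## Numerical and design choices

* Taxon order and locus order are lexicographic unless the user
  supplies an explicit taxon list; concatenation order is therefore
  reproducible without recording tool-internal ordering.
* Partition coordinates are 1-based inclusive; partition files
  round-trip through their parsers to identical schemes.
* Score tracks must match their alignment's column count exactly —
  mismatch is a hard error, not a truncation, because silently shifted
  scores corrupt masking. Pairing is by file stem.
* Relaxed PHYLIP only (full labels, single-space separator): strict
  10-character labels collide on modern sample names.
* `floor(q·N)` per trimmed tail is conservative and deterministic;
  with the default 0.2/0.2 on 100 rankable loci exactly 60 remain.
* Masking keeps columns with score **≥** threshold (the published
  rule discards "below the threshold").
* Degenerate inputs: masking may produce length-0 alignments (kept,
  warned); an occupancy threshold of 0 is the identity; concatenating
  an empty locus set is an error (exit code 3 in the CLI); missingness
  of a 0-cell matrix is undefined rather than 0.

## Known limitations

* Conservation-as-rate is a proxy; it saturates for very fast loci
  and is noisy for short or sparse ones (loci with < 2 rows are
  unrankable and dropped).
* The trimming fractions follow the stated rule `floor(q·N)` per
  tail; published locus counts that are inconsistent with that
  arithmetic are not force-matched.
* No attempt is made to reproduce upstream stages (assembly,
  orthology inference, alignment, confidence scoring) — their outputs
  are this package's inputs, and the simulator stands in for them
  only at the statistical level described above.
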