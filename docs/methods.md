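# Methods

This note records the statistical model behind `glycoctx`, the choices made
where the procedure admitted more than one reasonable reading, and what the
synthetic benchmark does and does not establish.

## Data model

The unit of analysis is the **context window**: `2·flank + 1` residues
(default flank 10, so 21-mers) with the target Asn at signed offset 0.
Annotations are 1-based (UniProt convention); window offsets are signed
integers with downstream positive. Windows running past a terminus are
padded with `-`; pads never match any item and are excluded from all
composition counts. A site is *positive* (N+) when annotated glycosylated
and *negative* (N−) when the Asn carries no annotation — an assumption, not
an experimental negative, which is one reason the N− class is analysed
symmetrically rather than treated as ground truth.

Cleaning removes, in order: sites on proteins containing non-standard
characters (the whole protein is excluded, because its composition would
pollute the background model), out-of-range positions, positions whose
residue is not Asn, and exact (protein, position) duplicates. Conflicting
labels at one position resolve to positive: an annotated modification
outweighs an assumed negative. Cleaning is idempotent.

Negatives are subsampled to `ratio · |positives|` (1:1 default, 1:2
available) by a stated shuffle-then-take contract: sort by (protein id,
position), permute with `numpy.random.default_rng(seed)`, take the first k.
This pins the subsample across platforms and languages.

## Encoding

The five charge/polarity classes are fixed:

| class | side chain | members |
|---|---|---|
| P | positively charged | K, R, H |
| N | negatively charged | D, E |
| L | polar, uncharged | S, T, C, M, N, Q |
| O | non-polar, aliphatic | G, A, V, L, I |
| A | aromatic | F, Y, W |

Proline belongs to no class. Rather than silently folding it into O, it maps
to a reserved symbol `X` that can never become a mined item; a custom
`ClassificationScheme` may reassign it. Group symbol `N` (acidic) and
residue letter `N` (Asn) are unrelated; raw and encoded alphabets are never
mixed within one string, and the window centre always encodes to `L`
(Asn is polar-uncharged).

## Preference estimation

For one class of windows, each (symbol, offset) pair with offset ≠ 0 is
tested for enrichment with a one-sided exact binomial test: observed count
k out of the position's non-pad occupancy n against the class's **pooled
composition** (all non-centre, non-pad symbols of the same windows). A pair
is *preferred* iff observed frequency exceeds background and P(X ≥ k) < α.

Choices worth stating:

- **α = 0.05, no multiple-testing correction by default.** The analysis is
  deliberately permissive at this stage — preferred items are candidates
  for mining, not end results; the support grid and confidence then do the
  filtering. Benjamini–Hochberg is available (`correction="BH"`).
- **Self-contained background.** The pooled same-class composition avoids
  any dependence on an external proteome snapshot; it also means a strong
  planted signal slightly inflates its own symbol's background (making the
  test conservative for that symbol) and dilutes others. At study sizes the
  effect is second-order.
- Position 0 is excluded everywhere: it is Asn by construction and carries
  no information.
- Fewer than 10 windows triggers an underpowered-test warning; the test is
  still computed.

## Association-pattern mining

Items are preferred (symbol, offset) pairs; a pattern is an item set.
Definitions (both were left implicit in prior tooling; these are the only
readings consistent with the published support/confidence tables):

- **support(I)** = 100 · #{consequent-class windows containing every item
  of I} / #{consequent-class windows};
- **confidence(I)** = 100 · matches in the consequent class / matches in
  both classes of the balanced set — P(class | pattern) under a 50% prior.
  Undefined (explicit error) when nothing matches.

Mining runs a classic levelwise Apriori with subset pruning over boolean
item-match columns; the item universes are small (tens of items), so the
search is exact. At each threshold of the support grid (default 5–95% in
steps of 5) the frequent itemsets are filtered to **maximal** ones — no
frequent proper superset at that threshold — which uniquely explains the
observed cascade where three-item patterns appear at low support and their
sub-patterns take over as the threshold rises; `maximal_only=False` emits
all frequent itemsets. Patterns repeated across thresholds are merged with
threshold sets unioned; both the total emission count and the unique count
are reported, since published pattern counts have used either convention.
Output ordering is deterministic: items by (position, symbol), rules by
support descending then notation.

Numerical note: threshold comparisons use `count ≥ min_pct·n/100 − 1e-9`
so grid percentages expressed in floats cannot drop a boundary itemset.

## Validation

**Conformity** of a peptide set with a rule set is the percentage of
peptides containing at least one rule, rounded **half-up** to an integer —
the rounding that reproduces the published validation percentages (94, 59,
85, 62) from their printed matched/total counts exactly. Sequon classes are
assigned from the +2 residue alone (S → NXS, T → NXT, C → NXC, else
non-canonical), with a separate flag for Pro at +1. Literature motif tables
(4-mer sequons) are embedded at offsets 0..+3 of an otherwise-pad window;
rules referencing offsets outside the sequon span are skipped and reported,
since a 4-mer carries no evidence about them.

The curated EGFR (12 sequons) and E-cadherin (4 sequons) tables ship as
package constants. Note the EGFR NYDL sequon is non-canonical (D at +2) and
does not match the ⟨L,2⟩-anchored rules; honest matching reports 11/12.

## Synthetic benchmark

The generator emulates the statistical shape of a curated assembly:
proteins drawn i.i.d. from a background composition (default uniform over
the 20 residues), positive windows laid out in non-overlapping slots,
negatives arising as background Asn. Defaults mirror the study scale —
2,909 positives across 1,117 proteins, lengths uniform on [300, 800] — and
the default planted structure is the headline sequon-context signal: group
L at +2 in 95% of positives, and O at +1 jointly with L at +2 in 30%.

**Planting semantics.** Each spec fires independently with probability q
per positive site. Offsets covered by a spec are fully controlled: a firing
spec writes its symbol (uniformly chosen group member for class symbols —
no within-group frequencies are assumed); when no firing spec covers the
offset, the background draw is resampled to lie *outside* every covering
symbol's set. Realized pattern rates therefore equal planting rates up to
binomial noise; uncontrolled background occupancy (e.g. the L class covers
6/20 of a uniform background) cannot inflate them. Two specs may share an
offset only with the same symbol; with the default specs the realized
⟨L,2⟩ rate is 1 − 0.05·0.70 = 96.5%.

**Terminal Asn.** By default no Asn — positive or negative — sits within
`flank` residues of a terminus, so every window is pad-free. This keeps the
two classes exchangeable under the null: padded negative windows next to
never-padded positive windows would otherwise make extreme-offset items
match fewer negatives purely through pads, a systematic artefact the
preference/confidence machinery would report as signal. The
`terminal_sites` flag restores terminal sites and padded windows for
boundary testing.

**What passing the benchmark shows — and what it does not.** Recovery of
planted items at their planted rates shows the chain (window extraction →
encoding → binomial preference → Apriori → confidence) is correctly wired
and calibrated at study sizes. It does not show that real proteomes satisfy
the generator's assumptions: real background composition is non-uniform and
position-dependent, real sites cluster in homologous proteins (windows are
not i.i.d.), and real negatives are unverified absences. Two dependence
effects are visible even in the benchmark: preference gating *selects*
items with upward-noisy positive counts, so mined rules on null data sit
slightly above 50% confidence (the permutation pipeline is the correct
reference, and the false-positive audit in the test suite is calibrated
against it); and unannotated Asn cluster in sequence, so negative windows
overlap and their match counts are mildly overdispersed relative to an
independence null — the null audit therefore controls the empirical
false-positive *rate* at the permutation-calibrated 5% level rather than
asserting a literal zero.

## Pipeline and reproducibility

`run_pipeline` executes the four dataset analyses (raw/encoded × N+/N−),
optional predictor-conformity and motif validation, and writes a summary
mirroring the assembled-data statistics table plus a manifest with SHA-256
hashes of all inputs and outputs, the seed and the package version. No
timestamps enter any artifact, so a rerun with the same configuration is
bit-identical and the manifests can be diffed directly. Every source of
randomness in the package flows from an explicit integer seed through
`numpy.random.default_rng`.

Problem sizes used by the shipped checks (the package's own choices for a
balance of statistical resolution and turnaround): miner-vs-enumeration
equivalence on 200 random instances of ≤ 50 windows; parameter recovery at
2,000 positives × 50 seeds with a ±3-point support band; null calibration
at 1,000 positives × 200 real + 200 permuted replicates; the acceptance
script runs one full study-scale analysis (2,909 positives).

## Known limitations

- The negative class is "unannotated", not "experimentally unmodified".
- The preference background is estimated from the same windows it tests
  (no external composition), with the conservativeness noted above.
- Items are fixed-position symbol equalities; absence items, gapped or
  degenerate patterns, and inter-position dependencies are out of scope.
- The external predictor is consumed as a site list, never recomputed; the
  plain-text report parser is a convenience, not a reimplementation.
- Conformity weights every peptide equally and asks only for ≥ 1 matching
  rule; it is a coverage measure, not a classification accuracy.
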