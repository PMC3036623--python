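# Methods

## Model and assumptions

The predictor rests on one evolutionary assumption: domains are units of
evolution, so a database of homologs will contain relatives of a
multi-domain query that carry only a contiguous subset of its domains
(products of gene fusion, fission and domain shuffling). In an alignment
anchored on the query, such a relative shows a long gap anchored at one
terminus, and the first (or last) aligned residue beyond that gap tends
to fall near a domain boundary. The method turns these terminal-gap
events into candidate sites and delegates the judgement — boundary or
not — to a supervised classifier, which restricts the search space to at
most 35 candidate positions per chain instead of scoring every residue.

The approach fails, by construction, when no signals are generated:
chains shorter than 90 residues (see the length bound below), chains
with too few detectable homologs, and boundaries of domains that never
occur independently in the database.

## Signal rules and parameters

| parameter | default | meaning |
|---|---|---|
| `min_gap` | 45 residues | minimum continuous terminal gap run in a row |
| `min_aligned` | 45 residues | minimum non-gap residues in the row (all gaps removed) |
| `max_unique_sites` | 35 | collection halts at this many distinct positions |
| `near_tol` | 20 residues | site-to-boundary distance for the *near* label (inclusive) |

Rows are processed in order of non-decreasing e-value so the cap retains
the most reliable signals. Three rule details were genuinely open and
are resolved as follows, each configurable through `SignalParams`:

* **C-terminal placement.** The rule names the first non-gap residue of
  a row, which is stated for the N-terminal case; the C-terminal signal
  is placed at the *last* non-gap residue, the symmetric gap-adjacent
  aligned position.
* **Aligned-length stipulation.** "With the gaps removed" is read
  literally: the row's total non-gap count must reach `min_aligned`,
  counting interior gaps as removed too, not merely the segment left
  after stripping the terminal run.
* **Cap semantics.** The halt is event-level and immediate: if a row's
  N-side signal fills the last free position slot, the C-side of the
  same row is not recorded.

The exhaustive search in `minimum_signal_length` shows the two 45s imply
a minimum signal-capable chain length of 90: a signal needs `min_gap`
gap columns plus `min_aligned` aligned columns in one row.

**Boundary points.** A domain definition with ranges
(s₁,e₁),…,(s_K,e_K) contributes both flanks eᵢ and sᵢ₊₁ of every
transition; chain termini s₁ and e_K are never boundary points. The
both-flank reading (rather than linker midpoints) keeps labelling and
evaluation consistent with adjacent-range definitions such as
`2-302, 303-585`, where the two flanks differ by one residue.

## Feature encoding

The layout is frozen (see `feature_schema`) because trained models
depend on byte-identical ordering; a SHA-256 of the schema travels with
every saved model and is checked at predict time. Choices the encoding
makes where the layout was open:

* Profiles are **raw column frequencies** of the anchored MSA including
  the query row — 20 amino acids plus an explicit gap frequency —
  normalised to sum 1. Ambiguity codes (X, B, Z, J) are spread uniformly
  over their member residues.
* Window positions outside the chain contribute all-zero 26-blocks, so
  out-of-range is represented explicitly and the dimension stays fixed.
* The neighbouring-site count includes the site itself (an isolated site
  scores 1).
* Density z-scores use the population standard deviation over the
  chain's residues; a flat density profile maps to all-zero z-scores
  rather than a division by zero.

## Classification

Both stages are soft-margin RBF-kernel SVMs with γ = 0.015. The
regularization constant is unreported in the field's standard setups and
is left at C = 1 (the common default), exposed in `ClassifierConfig`;
results at other C are a sensitivity the user can probe. Scores are raw
signed margins, not probabilities, so the −1.5…1.5 threshold sweep is
meaningful. Cross-validation always splits at the **protein** level:
sites of one chain share the MSA and annotation, and site-level splits
would leak that shared context between train and test folds. Stage 2 is
fitted only on sites from truly multi-domain chains.

## Evaluation conventions

* Distance tolerances are inclusive (≤ 20 residues).
* Coverage and recall count **boundaries**, not sites: several near
  calls at one boundary count it once.
* Recall is computed only over boundary points more than 40 residues
  from both chain termini; coverage excludes nothing beyond the
  chain-termini rule above.
* A threshold with zero near calls has undefined precision, flagged as
  `None`/`NA`, never coerced to 0 or 1.
* The break-even point is located by linear interpolation of
  (precision − recall) between adjacent sweep points (default step
  0.05); it is absent when the curves never cross.

## Synthetic data generator

`simulate` plants the exact structure the extractor exploits: queries of
1–3 domains (lengths uniform on 100–180 residues by default), homologs
that are full-length (point substitutions only), **partial** (a
contiguous proper domain subset, endpoints jittered around the true
boundaries by rounded zero-mean Gaussian noise, missing domains rendered
as terminal gaps), or **random fragments** (truncation points anywhere —
the source of away signals on multi-domain chains and false signals on
single-domain decoys). Sequence content is i.i.d. with a per-domain
Dirichlet compositional bias; secondary structure is loop-enriched and
accessibility exposure-enriched within ±3 residues of true boundaries,
mimicking linkers. E-values are rank-assigned so the least corrupted hit
is processed first, making the capped collection order meaningful.
Partial-hit domain subsets are cycled through a shuffled enumeration so
that, with enough hits, every boundary flank is planted — this is what
makes zero-jitter coverage exactly 1.0 rather than merely high.

What the generator does **not** emulate: real substitution processes and
phylogenetic correlation between hits, indels inside aligned regions,
discontinuous domains, and realistic length distributions — in
particular, multi-domain chains are systematically longer than
single-domain ones, which makes the single/multi distinction (task 1)
easier than in nature. Passing tests on synthetic data therefore
demonstrate that the pipeline is implemented coherently and carries
signal end-to-end, not that real-data accuracies would match.

Test and benchmark problem sizes (30–100 chains, ≤ 25 hits each) were
chosen so the full suite completes in well under a minute while keeping
binomial checks and cross-validation statistically meaningful.

## Obtaining real inputs

The tool consumes — but never runs — a homology search and a structure
predictor. A typical search recipe producing the XML that
`boundscan convert` anchors:

```sh
psiblast -query q.fasta -db nr -num_iterations 3 -evalue 0.001 \
         -outfmt 5 -out q.xml
```

By default the final iteration's alignments are used
(`--iteration` overrides). Per-residue secondary structure and
solvent accessibility are expected in SSpro/ACCpro-style 3-line flat
files (id, H/E/C string, b/e string).

## Known limitations

* Discontinuous domains are out of scope; range definitions must be
  non-overlapping and ordered.
* Signals depend on homolog availability; a chain with no qualifying
  hits yields no prediction (reported as single-domain).
* The SVM cost parameter materially affects the precision/recall
  balance; γ = 0.015 was adopted as the established default for this
  encoding, but no hyperparameter search is built in beyond overriding
  the config.
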