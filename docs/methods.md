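# Methods

`clmprobe` is a control-experiment harness for sequence-conditioned compound
generation. The question it operationalizes: when an encoder-decoder
transformer trained on (protein sequence → active compound SMILES) pairs
"reproduces" known actives for held-out targets, is it exploiting target
biology, or a statistical shortcut built from sequence similarity, compound
memorization, and multi-target (MT) leakage between training and test data?
Every experiment runs on a synthetic universe with known ground truth, so
each mechanism can be switched on and off by construction.

## The synthetic universe

`UniverseConfig` / `generate_universe` produce:

* **Families.** Each protein family is a set of point-mutated copies of a
  family ancestor over the 20-letter amino-acid alphabet. Members are
  mutated at `round((1 - within_family_identity)/2 * L)` positions each, so
  *pairwise* within-family identity matches `within_family_identity`
  (default 0.90) in expectation. A family-specific motif (default: a
  12-residue window at one third of the sequence) is written verbatim into
  every member; motif coordinates are 1-based inclusive, the convention of
  sequence-signature databases.
* **Compounds.** Each family owns `n_series_per_family` analog series. A
  series is a ring scaffold (benzene, pyridine, pyrimidine, furan,
  thiophene, pyrrole, saturated rings, naphthalene, and linked two-ring
  systems) carrying two or three substituents at random ring-carbon sites,
  drawn from ~40 composite linker×terminal groups. All SMILES are emitted in
  canonical nonisomeric form, and the Murcko scaffold of every analog equals
  its series scaffold — the generator stores this as the ground-truth core.
  Scaffold sets of different families are disjoint, which is what makes the
  family-holdout experiment meaningful.

  Analogs are a *sparse random subset* of the series' combinatorial space
  (10^4–10^5 analogs per scaffold). This emulates a central property of
  real curated chemistry: the analogs present in a corpus are a vanishing
  fraction of the accessible series, so an exact unseen analog cannot be
  produced by pattern completion. A dense, enumerable analog grammar would
  let a model "reproduce" held-out compounds it never saw, which real
  chemical space does not permit at any realistic scale.
* **Pairs and MT structure.** Each family contributes
  `sequences_per_family × compounds_per_sequence` pairs. A configured
  fraction of unique compounds (default 0.29) is multi-target: the same
  compound is assigned to several sequences of the owning family, with
  multiplicities drawn from a shifted geometric distribution
  (`m = 1 + Geometric(p)`, `p = 1/(mean - 1)`) tuned to the configured mean
  (default 2.91) and capped at the family size. Assignments fill the least
  loaded sequences first, keeping per-sequence compound counts balanced.
  The defaults (4 families × 10 sequences × 20 compounds/sequence ≈ 800
  pairs, ~520 unique compounds) reproduce the corpus-shape statistics the
  harness is calibrated to — ≈29% MT compounds, ≈2.9 sequences per MT
  compound — at a size a single CPU can train against in minutes.
* **Positive control.** With `motif_coupled=True`, all families derive from
  a *single* ancestor, so background positions carry no family information
  and the motif window (15 residues in this mode) is the only
  family-discriminative signal. Series ownership still follows families,
  hence follows motifs. A model trained on this universe must rely on the
  motif, so motif masking must hurt — this is the regime in which the
  masking harness is required to produce a positive. Coupled universes are
  generated with longer sequences (96 residues in the standard study
  configuration): the motif must remain a small fraction of the sequence,
  as real family signatures are relative to full-length proteins, or the
  random-position controls — which modify the *same number* of residues —
  would routinely corrupt the motif themselves and the masked-vs-control
  contrast would measure nothing.

What the generator does **not** emulate: realistic protein evolution
(substitutions are uniform over the 19 alternatives), bioactivity values,
assay noise, 3D structure, and the heavy-tailed target-size distribution of
real corpora. Conclusions from passing tests are therefore about the
*mechanisms* (leakage, memorization, similarity shortcuts), not about any
particular real target family.

## Curation

`filter_records` retains records with confidence score 9, direct binding,
no external-filter exclusion, compound weight ≤ 1,000 Da, and target length
≤ 1,000 residues. Repeated (compound, target) measurements must agree within
one order of magnitude; this is implemented as `max/min ≤ 10` (scale-free
and monotone) with a `floor(log10)` binning rule available behind
`order_rule="log_bin"` — the binning alternative makes 9.9 vs 10.1 nM
"different orders", which is why the ratio rule is the default.
`build_pairs` canonicalizes to nonisomeric SMILES (stereo and isotopes
stripped before canonicalization) and deduplicates pairs; per-compound
multiplicity over distinct targets defines the MT annotation.

## Partitioning and dilution

Both schemes target a 70/30 pair ratio. The sequence split randomly assigns
whole sequences; MT compounds may then appear on both sides through
different partners — the leakage channel under study. The family split
assigns whole families; the train fraction is targeted on *pair* counts
(pairs are the training unit) using exact subset-sum search for up to 20
families (ties broken by fewer train families, then lexicographically),
with a greedy fallback beyond.

`dilute_mt(dataset, retain, seed)` converts a fraction `1 - retain` of MT
compounds to single-target by keeping one pair uniformly at random.
Dilution runs on the full dataset *before* splitting, so a converted
compound's surviving pair lands on exactly one side. The conversion order
and each compound's kept pair derive from the seed alone, making converted
sets nested across retain levels (default schedule 100/75/50/25/0%) and
dilution series monotone in expectation.

## Encoding and model

SMILES are tokenized with the standard chemistry-NLP regular expression
(bracket atoms, `Cl`/`Br`, ring-closure digits and `%nn` as single tokens);
tokenization is lossless and a character the pattern cannot consume is an
error, not a silent unknown token. Proteins are tokenized per residue over
the IUPAC alphabet (extended codes B/Z/X/U/O are rejected by default, or
mapped to X with `permissive=True`). Vocabularies are corpus-derived, carry
`[pad]/[start]/[end]` at indices 0/1/2, and are frozen after pre-training.

The model is the classical encoder-decoder transformer implemented in NumPy
with hand-written backpropagation (verified against finite differences in
the test suite): learned embeddings scaled by √d plus fixed sinusoidal
positional encodings (base 10,000), multi-head scaled dot-product attention,
ReLU feed-forward blocks, residual connections with layer normalization in
the pre-norm arrangement (stable without warmup), and padding-masked
cross-entropy. Training uses Adam with a triangular cyclic learning rate
(base 1e-4, max 1e-3, 4-epoch cycle). Sampling is multinomial at
temperature 1 (logits divided by temperature before the softmax), decoding
autoregressively from `[start]` with per-layer key/value caches; greedy
argmax decoding is exposed for tests.

Desk-scale defaults: d_model 64, 4 heads, 2+2 layers, feed-forward 128,
float32, batch 32, 60 epochs — the smallest configuration that reliably
memorizes the synthetic corpora on one CPU (a few minutes per model).
Dropout is off in the experiment configuration: with a few hundred training
pairs, memorization is the phenomenon under study and regularization only
delays its onset; the estimator default keeps dropout available. Training
is bit-reproducible given `random_state` and independent of input pair
order (pairs are sorted canonically before shuffling, so the shuffle is
owned by the seed).

## Evaluation metrics

For each eligible test sequence (more than 20 available compounds by
default; explicit sequence lists override), n output strings are sampled
(2,500 default, 5,000 extended), invalid strings dropped but counted
(validity is a health metric), and the remainder canonicalized.
`n_uq_repro` counts *distinct* test compounds of that sequence reproduced
exactly; core counting applies the same rule to Murcko scaffolds (ring
systems plus linkers; acyclic molecules fall back to themselves). The
Murcko operator stands in for analog-series core extraction: it maps all
members of one synthetic series to the generator's stored scaffold, which
the tests assert, and the operator is pluggable should a faithful
compound-core-relationship implementation be preferred. Memorization
statistics relate reproduced compounds to training pairs: the fraction
present verbatim among training compounds, and the mean Tanimoto similarity
(binary Morgan fingerprints, radius 2, 2,048 bits) to the nearest training
neighbor. Both are reported as absent when nothing was reproduced.

## Perturbation protocols

Residue randomization draws replacements from the amino-acid frequency
distribution of the full corpus. A targeted position counts as randomized
even if the draw equals the original residue — the draw does not exclude
it, so "n residues randomized" is the number of *targeted* positions.

* **Cumulative randomization**: 15-residue segments from the N or C
  terminus, cumulatively (variant k keeps variant k−1's draws and extends
  them), until the whole sequence is randomized; the last segment may be
  shorter than 15. Positional controls randomize the same number of
  residues at freshly drawn random positions at each step (fresh, not
  cumulative — the choice is recorded here because the alternative,
  re-targeting supersets, is equally defensible). Five repeats; curves
  report mean ± sample sd per step, with step 0 the unperturbed sequence.
* **Motif masking**: motif windows are randomized or replaced with alanine
  ("computational alanine scanning"); controls modify the same number of
  residues at random positions, re-drawn each of 10 trials to absorb
  positional variance. Alanine masking is deterministic; its trials differ
  only in the sampling draw.

## Statistics

Masked-vs-control count distributions are compared with the two-sided
Mann-Whitney U test: exact permutation null when n1+n2 ≤ 12 without ties,
otherwise the normal approximation with midrank tie correction and
continuity correction (scipy backend; an independent enumeration oracle in
the tests checks the exact branch). Stars follow the conventional
thresholds (ns > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥ ***). Boxplot summaries use
linear-interpolation quartiles and 1.5-IQR whiskers clipped to the data.
Curve summaries report the sample standard deviation and mark it absent
(not zero) for a single repeat. Direction insensitivity is quantified as
the fraction of steps at which the mean ± 2 sd bands of the N→C, C→N and
control curves mutually overlap.

## Sequence selection for perturbation experiments

Perturbation effects are only measurable on sequences the unperturbed model
reproduces something for. Mirroring the convention of reporting perturbation
results for test sequences with substantial baseline reproduction, the
randomization and masking experiments screen the largest test sequences
with a quick sampling pass (500 samples) and run on the best-reproducing
ones (`best_reproducing_sequences`).

## Problem sizes used by the acceptance script and tests

One desk-scale universe (40 sequences of 60 residues, ~800 pairs) per
experiment, plus the 96-residue coupled universe for the positive control;
2,500 samples per sequence for the dilution experiment, 1,000 for the
partition comparison, 300 per randomization variant (5 repeats) and 400 per
masking trial (10 trials); model budgets as above. These sizes were chosen
once as the smallest at which the qualitative phenomena are stable across
seeds.

## Known limitations

* The transformer is CPU-scale; absolute reproduction counts are far below
  what GPU-scale training on a full corpus produces, so only directions and
  zero/non-zero contrasts are meaningful, not magnitudes.
* Exact reproduction of an *unseen* analog is improbable but not impossible
  in a finite synthetic space; the zero-reproduction experiment can in
  principle show a stray count on an adversarial seed, a finite-size
  artifact real chemical space does not share.
* The Mann-Whitney exact branch requires tie-free samples; integer
  reproduction counts usually tie, so masking comparisons typically use the
  corrected normal approximation.
* No multiple-testing correction across sequences: per-instance tests are
  reported as-is, mirroring the per-sequence reporting convention of the
  figure this mirrors.
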