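# Methods

## The task and its decomposition

DRG assignment is single-label multi-class classification: one MS-DRG code
per hospital stay, predicted here from the "brief hospital course" narrative
of the discharge summary. Because an MS-DRG is composite — a base DRG (the
principal diagnosis or procedure) plus a CC/MCC severity split — the package
supports two formulations:

* **single-label**: predict the code directly over all C codes;
* **two-label**: predict the base DRG (B classes) and the CC/MCC status
  (5 classes) jointly, then derive the code.

Both use the causal-LM classification convention: the backbone produces one
embedding per token, a linear head is applied to the last token's embedding,
and the raw output is a logit vector. The two-label head emits one joint
vector of dimension B + 5; the first B dimensions score the base DRG and the
last 5 the CC/MCC label. Its training loss is

    L = CE(logits[0:B], y_base) + λ · CE(logits[B:B+5], y_cc),    λ = 1/2,

and inference takes independent argmaxes over the two slices.

### The five CC/MCC labels and dissection

Catalog titles carry the severity phrase at the end of the title; dissection
parses it off. Training labels are, in fixed index order: `without CC/MCC`
(0), `with CC` (1), `with MCC` (2), `without MCC` (3), `not applicable` (4).
A code whose title carries no severity phrase is labelled `not applicable`
rather than `without CC/MCC`: an unsplit DRG says nothing about the patient's
actual complication status, and conflating "unsplit" with "no complications"
would inject systematically wrong severity signal. The catalog-side suffix
`with CC/MCC` (two-way split families) has no counterpart among the five
labels; such codes are trained as `with CC`, the minimal severity consistent
with the title. Since the inference mapping sends both `with CC` and `with
MCC` back to the same `with CC/MCC` code, the dissect→infer round trip is
exact for every catalog code regardless of this choice.

### The inference mapping rule

Deriving a code from a (base, CC/MCC) prediction is a two-step total map.
If the family contains a code whose suffix corresponds directly to the
predicted label, that code is returned. Otherwise a per-split-type fallback
applies:

| split type | predicted label | target code |
|---|---|---|
| no split | any | the single code |
| with MCC / without MCC | without CC/MCC, with CC, not applicable | `WITHOUT MCC` |
| with CC/MCC / without CC/MCC | with CC, with MCC | `WITH CC/MCC` |
| with CC/MCC / without CC/MCC | without MCC, not applicable | `WITHOUT CC/MCC` |
| three-way | without MCC, not applicable | `WITHOUT CC/MCC` |

The three-way fallback maps `without MCC` (which asserts only the absence of
MCC) and `not applicable` to the least severe code: absent positive CC
evidence, the conservative choice. The table is exportable
(`drgkit catalog map`) and replaceable via the `fallback` argument of
`infer_drg`, since reasonable groupers could choose `WITH CC` for
`without MCC` in a three-way family. Final-DRG accuracy is bounded above by
base-DRG accuracy by construction.

## Harmonization

CMS revises MS-DRG definitions annually and renumbers codes, so stays coded
under other versions are consolidated by *title*: normalize (uppercase,
whole-token abbreviation expansion — `W/O`→`WITHOUT`, `CATH`→
`CATHETERIZATION`, `PROC`→`PROCEDURES`, `&`→`AND` — whitespace collapse),
then exact match, then a manual conversion table, then fuzzy matching, else
exclusion. The fuzzy score is a token-set edit ratio on a 0–100 scale with
two deliberate deviations from the classic construction: the pure
intersection-vs-intersection comparisons are omitted (they saturate whenever
one token set contains the other, which would auto-accept a legacy title
that merely *adds* a severity phrase to a current title), and 100 is
reserved for exact normalized identity. The default acceptance bar is 95
with a unique-top requirement; anything below it is excluded, mirroring a
workflow in which fuzzy matching only flags candidates for human review and
unresolved titles drop out of the cohort. The threshold is monotone by
construction: raising it never accepts more records.

Harmonization is deterministic given (records, catalog, manual map,
threshold), and re-running it on its own output is the identity.

## Corpus preparation

* Section extraction: the text between a case-insensitive "Brief Hospital
  Course" header and the next section-like line (short line ending in `:`),
  or end of document; an empty section counts as absent. Real systems vary
  in header conventions; the pattern set is a module constant.
* Quality filter: drop missing sections, sections under 40 whitespace-
  delimited words ("less than 40" read literally: 39 drops, 40 stays), and
  exact duplicates of an earlier section (first occurrence kept, document
  order). The filter is idempotent and reports each drop reason.
* Rare-DRG filter: codes with fewer than 2 occurrences are removed — a class
  needs at least one potential training and one potential test instance.
* Stratified split: per class, round(n·f) test records (half-up), at least
  one training record always retained — so 2-record classes land entirely in
  training, which is why a stratified test set can legitimately contain
  fewer distinct DRGs than the training set. Single integer seed; byte-
  identical reruns.
* Tokenization: the reference tokenizer lowercases, splits on
  non-alphanumerics and hashes tokens into a fixed vocabulary (md5-based,
  default 2¹⁵) — a stand-in for whatever vocabulary a pretrained backbone
  brings. Truncation keeps the head of the note: the hospital-course
  narrative opens with the presenting problem, so the head carries the
  densest diagnostic signal.

## Backbones, adapters, training

The backbone contract is deliberately small (tokenizer, per-token
embeddings, linear head) so large pretrained models can plug in. Two
reference implementations ship:

* **Linear bag-of-tokens** — each position's "embedding" is the running sum
  of one-hot token vectors, so the last-token embedding is the sequence's
  count vector and the model is multinomial logistic regression: convex,
  deterministic, fast. The head is zero-initialized (the natural origin for
  a convex problem). It is the backbone used for desk-scale training runs.
* **Tiny causal self-attention encoder** (1 layer, width ≤ 64) — genuine
  last-token semantics and real attention weights for the adapter contract.
  It is a forward-pass/adapters reference; gradient training targets the
  linear backbone.

Low-rank adapters follow `W₀ + (α/r)·B·A` with `B` zero-initialized, `A`
Gaussian, scaling α/r, applied to all four attention matrices; base weights
are shared and frozen. Zero-initialized `B` makes the adapted model exactly
equal to the base model at initialization — tested bit-for-bit.

Training uses mini-batch AdamW (decoupled weight decay, default betas) with
defaults lr 2×10⁻⁵, weight decay 0.01, 3 epochs, batch size 4, λ = ½ — the
standard sequence-classification fine-tuning recipe for large pretrained
backbones. The learning rate is backbone-relative: the convex linear
reference backbone uses 0.02 in the examples and acceptance runs (2×10⁻⁵ is
far below the escape velocity of a freshly initialized linear model on
count features; 0.02 reaches the optimum's neighbourhood within the 3-epoch
budget). Ties in argmax/ranking resolve to the lowest index everywhere.

## Evaluation

ACC@k (target among the k highest-scored codes; ties broken by index),
macro/micro F1 of top-1 predictions (macro over classes present in the test
set by default — configurable — with 0/0-classes contributing 0), one-vs-rest
ROC AUC with midrank ties (macro skips classes without both a positive and a
negative; micro stacks the (record, class) binary problem), and bootstrap
SDs: the metric recomputed on 30 with-replacement resamples of the full test
set, sample SD (ddof = 1), seeded. In single-label multi-class scoring over
all classes micro-F1 ≡ ACC@1; this identity is property-tested and doubles
as a cross-check between the accuracy and F1 code paths. The per-class
report tabulates top-5 accuracy against training-case counts with
configurable accuracy bands — the tabular form of accuracy-vs-frequency
analysis (no spline fitting here; the table is meant for external plotting).

## What the synthetic generator does and does not emulate

Generated catalogs realize the four split-family types in the v34.0
proportions (154:44:65:77 by default, largest-remainder apportionment, so
340 families yield exactly 757 codes) with pronounceable nonsense base
titles that can never collide with severity grammar. Corpora draw codes from
a Zipf distribution (exponent 1.0 by default) over shuffled code ranks,
emulating the heavy head/long tail of real hospital DRG counts; each note is
a genuine multi-section document whose hospital-course section contains
base-specific keywords, severity cue words that are truthful with
probability `severity_cue_strength`, and optional hash-vocabulary noise and
filler. With truthful cues and the noise vocabulary disabled, the text
determines the DRG exactly (a keyword-matching oracle scores 1.0); with
default noise on, a fully converged linear model tops out around 0.96 and
the 3-epoch run near 0.89 on held-out stays — the intended regime for
exercising imperfect-classifier evaluation. Legacy titles are perturbed
invertibly (abbreviations, case) plus, for a configurable fraction of
families lacking a split, unmappable severity variants (the "URINARY STONES
W MCC" pattern) whose intended disposition is exclusion.

What passing tests on this data do **not** show: anything about clinical
language (the text is statistically, not medically, faithful — no negation,
no temporal structure, no synonymy), about real CC/MCC label noise beyond
the cue-strength dial, or about the absolute accuracy of large pretrained
backbones on real corpora. The generator validates the *machinery* —
dissection, mapping, filtering, training dynamics, metrics — not clinical
performance.

## Problem sizes

Default test and acceptance runs use catalogs of 4–20 families (plus the
340-family structural catalog), corpora of a few hundred to 2,000 stays, and
a 2¹³ hash vocabulary for trained backbones — sizes chosen so the full suite
and the acceptance script each complete in well under a minute on one CPU
core while still exercising every code path at realistic class imbalance.

## Known limitations

* The suffix grammar anchors severity phrases at end-of-title only; a
  hypothetical catalog title with a trailing parenthetical after the phrase
  would parse as unsplit.
* The fuzzy matcher is intentionally conservative; genuinely equivalent
  retitled DRGs below the bar require a manual-map entry, as in the original
  workflow.
* The three-way fallback cells of the mapping rule are a documented design
  choice, not an authoritative grouper specification; they are configurable.
* The tiny attention encoder does not implement backpropagation; training
  experiments use the linear backbone.
* `not applicable` training labels are noisy by construction for unsplit
  DRGs (a real stay may well have complications); this mirrors the task, not
  a defect of the generator.
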