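# drgkit

Predicting the Diagnosis-Related Group (DRG) of a hospital stay from the
free-text discharge summary — and doing it the way the DRG system is actually
structured.

Every inpatient stay paid under the Medicare prospective payment system gets
exactly one MS-DRG code. A code such as `53 SPINAL DISORDERS AND INJURIES
WITHOUT CC/MCC` is composite: a **base DRG** (the principal diagnosis or
procedure, here "spinal disorders and injuries") plus a **CC/MCC severity
split** ("without CC/MCC" — no complication or comorbidity). Families of
codes share a base title and differ only in the split, and a family carries
one of four split patterns: three-way (`with MCC` / `with CC` / `without
CC/MCC`), two-way `with CC/MCC` / `without CC/MCC`, two-way `with MCC` /
`without MCC`, or no split at all. In MS-DRG v34.0 these number 154, 44, 65
and 77 families respectively — 340 base DRGs and 757 codes in total.

`drgkit` is a toolkit for building and evaluating DRG classifiers over this
structure:

* **catalog** — parse catalog titles into (base title, severity suffix),
  classify split families, assign each code one of five CC/MCC training
  labels (`without CC/MCC`, `with CC`, `with MCC`, `without MCC`,
  `not applicable`), build deterministic integer label spaces, and map a
  (base DRG, CC/MCC) prediction pair back to a concrete code via a total,
  split-aware mapping rule.
* **harmonize** — consolidate codes assigned under older MS-DRG versions onto
  a target catalog by title: normalize → exact match → manual conversion
  table → conservative fuzzy token-set match → exclude; plus the rare-DRG
  (< 2 occurrences) filter.
* **corpus** — extract the "brief hospital course" section, drop short
  (< 40 words) and duplicated notes, split 90/10 stratified by DRG, tokenize
  and head-truncate.
* **model** — last-token-logit classification behind a pluggable backbone
  contract: single-label categorical cross-entropy over all C codes, or a
  two-label objective `CE_base + λ·CE_cc` (λ = ½) over a joint (B + 5)-dim
  logit vector with dual argmax at inference; a low-rank adapter contract
  `W₀ + (α/r)·BA` on attention weights; an AdamW training loop. Two numpy
  reference backbones (linear bag-of-tokens; tiny causal self-attention
  encoder) make everything runnable on a laptop CPU.
* **evaluate** — ACC@1/5/10, macro/micro F1, one-vs-rest macro/micro AUC,
  30-iteration bootstrap SDs, per-class accuracy-vs-frequency tables, and the
  two-label report (base block, CC/MCC block, final-DRG accuracy).
* **synthetic** — generators for catalogs, long-tailed (Zipf) corpora with
  keyword/severity-cue signal, and perturbed legacy titles, all with exact
  truth bookkeeping.

Real clinical corpora (e.g. MIMIC-IV) are access-restricted; nothing here
requires them. The synthetic module reproduces the statistical shape of the
task so the full pipeline is testable end to end.

## Worked example

```python
from drgkit import (CcMccLabel, GeneratorConfig, SplitType, dissect,
                    generate_catalog, infer_drg)

cfg = GeneratorConfig(n_base_families=340, seed=0)
catalog = generate_catalog(cfg)
space = dissect(catalog)
print(f"catalog: {space.n_drg} DRG codes from {space.n_base} base families")
for split, n in catalog.split_census().items():
    print(f"  {split.value:24s} {n:4d} families")
```

prints

```
catalog: 757 DRG codes from 340 base families
  three_way                 154 families
  two_way_ccmcc_vs_none      44 families
  two_way_mcc_vs_rest        65 families
  no_split                   77 families
```

i.e. the v34.0 census: 3·154 + 2·44 + 2·65 + 77 = 757 codes. The mapping rule
is total — for a family that only splits on MCC, a `with CC` prediction maps
to its `WITHOUT MCC` code; for an unsplit family any severity prediction maps
to the single code — and round-trips every catalog code exactly.

Training and evaluating the linear reference backbone on a generated corpus
(`examples/05_bootstrap_evaluation.py`, severity cues truthful 90% of the
time) prints:

```
ACC@1      0.879 (0.045)
ACC@5      0.966 (0.023)
ACC@10     0.983 (0.016)
MACRO-F1   0.715 (0.068)
MICRO-F1   0.879 (0.045)
MACRO-AUC  0.986 (0.006)
MICRO-AUC  0.990 (0.006)
```

Point estimates on the held-out stays with bootstrap SDs in parentheses (30
with-replacement resamples of the test set). MICRO-F1 equals ACC@1 exactly —
the standard single-label multi-class identity — and macro-F1 sits lower
because rare tail DRGs are hardest.

See `examples/` for one short script per capability, and `drgkit --help` for
the CLI (`simulate`, `prepare`, `harmonize`, `catalog validate|dissect|map`).

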