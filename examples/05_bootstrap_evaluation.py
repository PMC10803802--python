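"""Evaluate ranked DRG predictions with bootstrap standard deviations.

Builds a small noisy corpus, trains the linear backbone, and prints the
metric table (ACC@k, macro/micro F1 and AUC) with 30-iteration bootstrap SDs.
"""

from drgkit import (
    GeneratorConfig,
    LinearBagBackbone,
    TrainConfig,
    dissect,
    evaluate_single_label,
    extract_bhc,
    generate_catalog,
    generate_corpus,
    quality_filter,
    stratified_split,
    train,
)
from drgkit.corpus import build_dataset
from drgkit.harmonize import filter_rare
from drgkit.model import rank_logits, softmax

cfg = GeneratorConfig(n_base_families=8, n_records=600, severity_cue_strength=0.9, seed=3)
catalog = generate_catalog(cfg)
space = dissect(catalog)
corpus, _ = generate_corpus(catalog, cfg)
corpus["bhc_text"] = corpus["text"].map(extract_bhc)
corpus, _ = quality_filter(corpus)
corpus, _ = filter_rare(corpus)
split = stratified_split(corpus, 0.1, seed=3)
tr, te = build_dataset(split.train, space), build_dataset(split.test, space)

fit = train(LinearBagBackbone(space.n_drg, vocab_size=2**13),
            tr["bhc_text"].tolist(), tr["drg_index"].tolist(),
            TrainConfig(learning_rate=0.02, seed=0), "single")
logits = fit.score(te["bhc_text"])
ranked = [rank_logits(row, k=10).indices for row in logits]
report = evaluate_single_label(
    ranked, softmax(logits, axis=1), te["drg_index"].to_numpy(),
    n_bootstrap=30, seed=3,
)
for name, (value, sd) in report.metrics.items():
    print(f"{name:10s} {value:.3f} ({sd:.3f})")
# Values are metric point estimates on the test stays; parentheses hold the
# SD over 30 with-replacement resamples of the test set. With imperfect
# severity cues (strength 0.9) accuracy sits below 1, and MICRO-F1 equals
# ACC@1 exactly — the single-label multi-class identity.
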