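"""Turn raw discharge-summary notes into a model-ready stratified dataset.

Extracts the "brief hospital course" section, drops short/duplicate notes and
rare DRGs, and splits 90/10 stratified by DRG code.
"""

from drgkit import (
    GeneratorConfig,
    dissect,
    extract_bhc,
    generate_catalog,
    generate_corpus,
    quality_filter,
    stratified_split,
)
from drgkit.corpus import build_dataset
from drgkit.harmonize import filter_rare

cfg = GeneratorConfig(
    n_base_families=10, n_records=600, seed=5, short_fraction=0.05, dup_fraction=0.03
)
catalog = generate_catalog(cfg)
corpus, truth = generate_corpus(catalog, cfg)

corpus["bhc_text"] = corpus["text"].map(extract_bhc)
corpus, q_report = quality_filter(corpus, min_words=40)
print("quality filter:", q_report)
# 'short' and 'duplicate' counts equal the generator's injected violations.

corpus, dropped = filter_rare(corpus, min_count=2)
print(f"rare-DRG filter dropped {len(dropped)} codes with < 2 stays")

split = stratified_split(corpus, test_fraction=0.1, seed=5)
space = dissect(catalog)
train = build_dataset(split.train, space)
print(f"train {len(split.train)} / test {len(split.test)} stays; "
      f"{split.train['drg_code'].nunique()} train vs {split.test['drg_code'].nunique()} test DRGs")
# The test set can hold fewer unique DRGs: 2-stay classes stay entirely in train.
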