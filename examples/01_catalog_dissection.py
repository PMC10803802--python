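"""Dissect a DRG catalog into base DRGs + CC/MCC labels and map predictions back.

Builds a synthetic MS-DRG-style catalog at full scale (340 families in the
v34.0 split-mix), dissects it, and shows the inference mapping rule on a
two-way split family.
"""

from drgkit import (
    CcMccLabel,
    GeneratorConfig,
    SplitType,
    dissect,
    generate_catalog,
    infer_drg,
)

cfg = GeneratorConfig(n_base_families=340, seed=0)
catalog = generate_catalog(cfg)
space = dissect(catalog)

print(f"catalog: {space.n_drg} DRG codes from {space.n_base} base families")
for split, n in catalog.split_census().items():
    print(f"  {split.value:24s} {n:4d} families")
# 757 codes from 340 families, split 154/44/65/77 — the v34.0 structure.

fam = next(f for f in catalog.families.values() if f.split is SplitType.TWO_WAY_MCC_VS_REST)
b = space.base_index(fam.base_title)
print(f"\nfamily {fam.base_title!r} splits only on MCC, so a 'with CC' prediction")
code = infer_drg(b, CcMccLabel.WITH_CC, catalog, space)
print(f"maps to its least-severe code: {code.code} {code.title!r}")
# The mapping is total: every (base, CC/MCC) pair yields exactly one code.
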