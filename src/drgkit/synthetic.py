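"""Synthetic catalogs, discharge corpora and legacy titles.

Real DRG-labelled discharge summaries are access-restricted, so every other
module is exercised on generated data that reproduces the *statistical* shape
of the task while staying deliberately non-clinical in content:

* catalogs with the four split-family types mixed in the v34.0 proportions
  (154 three-way : 44 two-way with-CC/MCC : 65 two-way MCC-vs-rest : 77
  unsplit — the default mix, scaled to the requested family count);
* a long-tailed (Zipf) case distribution over codes, mimicking the heavy
  class imbalance of hospital DRG counts;
* notes consisting of a "Brief Hospital Course" section holding base-specific
  keywords (the learnable principal-diagnosis signal), severity cue words
  tied to the CC/MCC label (truthful with a configurable probability, echoing
  how CC/MCC labelling is noisy for unsplit codes), and hash-vocabulary noise;
* legacy titles with invertible abbreviation/case perturbations plus, for a
  configurable fraction of families that lack a given split, unmappable
  variants carrying a severity phrase absent from the family.

Every generated artifact comes with exact bookkeeping (truth maps, injected
violation ids) so downstream dispositions are checkable, not just plausible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (
    CatalogSuffix,
    CcMccLabel,
    DrgCatalog,
    SplitType,
    SPLIT_SIZE,
    SPLIT_SUFFIXES,
)

#: Family-count proportions of the four split types in MS-DRG v34.0.
DEFAULT_SPLIT_MIX: dict[SplitType, float] = {
    SplitType.THREE_WAY: 154 / 340,
    SplitType.TWO_WAY_CCMCC_VS_NONE: 44 / 340,
    SplitType.TWO_WAY_MCC_VS_REST: 65 / 340,
    SplitType.NO_SPLIT: 77 / 340,
}

#: Severity cue lexicon: words whose presence signals each CC/MCC label.
SEVERITY_CUES: dict[CcMccLabel, tuple[str, ...]] = {
    CcMccLabel.WITHOUT_CC_MCC: ("uncomplicated", "uneventful", "stable"),
    CcMccLabel.WITH_CC: ("anemia", "dehydration", "hyponatremia"),
    CcMccLabel.WITH_MCC: ("septic", "shock", "intubated"),
    CcMccLabel.WITHOUT_MCC: ("moderate", "managed", "improving"),
    CcMccLabel.NOT_APPLICABLE: ("routine", "observation", "baseline"),
}

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for synthetic catalog/corpus generation.

    ``split_mix`` defaults to the v34.0 family proportions; ``zipf_exponent``
    shapes the class imbalance (1.0 gives the familiar heavy head/long tail);
    ``severity_cue_strength`` is the probability that a record's severity cues
    are truthful rather than misleading; ``short_fraction``/``dup_fraction``
    inject quality violations for filter testing.
    """

    n_base_families: int = 20
    split_mix: dict[SplitType, float] = field(
        default_factory=lambda: dict(DEFAULT_SPLIT_MIX)
    )
    n_records: int = 1000
    zipf_exponent: float = 1.0
    keyword_per_base: int = 3
    severity_cue_strength: float = 1.0
    noise_vocab_size: int = 200
    n_noise_words: int = 10
    min_words: int = 40
    short_fraction: float = 0.0
    dup_fraction: float = 0.0
    legacy_perturb_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.split_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("split_mix proportions must sum to 1")
        if self.n_base_families < 1 or self.n_records < 1:
            raise ValueError("counts must be positive")


def _word(rng: np.random.Generator, n_syllables: int = 2) -> str:
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(n_syllables)
    )


def _apportion(mix: dict[SplitType, float], n: int) -> dict[SplitType, int]:
    """Largest-remainder apportionment of n families across split types."""
    order = [SplitType.THREE_WAY, SplitType.TWO_WAY_CCMCC_VS_NONE,
             SplitType.TWO_WAY_MCC_VS_REST, SplitType.NO_SPLIT]
    quotas = {st: mix.get(st, 0.0) * n for st in order}
    counts = {st: int(np.floor(q)) for st, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(order, key=lambda st: -(quotas[st] - counts[st]))
    for st in by_remainder[:short]:
        counts[st] += 1
    return counts


def generate_catalog(config: GeneratorConfig) -> DrgCatalog:
    """Generate a validated catalog with pronounceable multi-word base titles,
    families realized per the split mix, and sequential code numbers."""
    rng = np.random.default_rng(config.seed)
    counts = _apportion(config.split_mix, config.n_base_families)
    titles: set[str] = set()
    while len(titles) < config.n_base_families:
        n_words = int(rng.integers(2, 4))
        titles.add(" ".join(_word(rng, int(rng.integers(2, 4))) for _ in range(n_words)).upper())
    title_list = sorted(titles)
    rng.shuffle(title_list)
    rows: list[tuple[int, str, str]] = []
    code = 1
    pos = 0
    for st, n_fam in counts.items():
        for _ in range(n_fam):
            base = title_list[pos]
            pos += 1
            for suffix in sorted(SPLIT_SUFFIXES[st], key=lambda s: s.name):
                title = f"{base} {suffix.value}".strip()
                rows.append((code, title, "34.0"))
                code += 1
    return DrgCatalog.from_rows(rows)


@dataclass
class CorpusTruth:
    """Bookkeeping for a generated corpus: which stay ids were deliberately
    degraded, and the keyword map the text was built from."""

    short_ids: list[str]
    dup_ids: list[str]
    base_keywords: dict[str, tuple[str, ...]]


def generate_corpus(
    catalog: DrgCatalog, config: GeneratorConfig
) -> tuple[pd.DataFrame, CorpusTruth]:
    """Generate a stay table with Zipf class frequencies and recoverable text.

    Returns a DataFrame with columns ``stay_id, text, drg_code, drg_title,
    drg_version`` plus the bookkeeping truth object.  With
    ``severity_cue_strength=1`` the text determines the DRG exactly: base
    keywords identify the family, cue words the severity split.
    """
    rng = np.random.default_rng(config.seed + 1)
    codes = sorted(catalog.codes, key=lambda c: c.code)
    # Zipf weights over codes in a shuffled rank order.
    rank_order = rng.permutation(len(codes))
    ranks = np.empty(len(codes), dtype=int)
    ranks[rank_order] = np.arange(1, len(codes) + 1)
    weights = 1.0 / ranks.astype(float) ** config.zipf_exponent
    weights /= weights.sum()
    draws = rng.choice(len(codes), size=config.n_records, p=weights)

    base_keywords = {
        base: tuple(f"{_word(rng, 3)}" for _ in range(config.keyword_per_base))
        for base in sorted(catalog.families)
    }
    cc_values = list(CcMccLabel)

    rows = []
    bodies: list[str] = []
    for i, ci in enumerate(draws):
        code = codes[ci]
        words: list[str] = list(base_keywords[code.base_title])
        truthful = rng.random() < config.severity_cue_strength
        if truthful:
            cue_label = code.cc_training_label
        else:
            others = [l for l in cc_values if l is not code.cc_training_label]
            cue_label = others[int(rng.integers(len(others)))]
        words.extend(SEVERITY_CUES[cue_label])
        noisy = config.noise_vocab_size > 0
        if noisy:
            words.extend(
                f"noise{int(rng.integers(config.noise_vocab_size))}"
                for _ in range(config.n_noise_words)
            )
        # Pad to the minimum length: random filler when a noise vocabulary is
        # configured, otherwise cycle the signal words so a noiseless corpus
        # stays fully class-determined.
        signal = list(words)
        j = 0
        while len(words) < config.min_words:
            if noisy:
                words.append(f"filler{int(rng.integers(config.noise_vocab_size))}")
            else:
                words.append(signal[j % len(signal)])
                j += 1
        rng.shuffle(words)
        bodies.append(" ".join(words))
        rows.append(
            {
                "stay_id": f"stay{i:06d}",
                "drg_code": code.code,
                "drg_title": code.title,
                "drg_version": code.version,
            }
        )

    # Inject quality violations with exact bookkeeping.
    n = len(rows)
    n_short = int(round(config.short_fraction * n))
    n_dup = int(round(config.dup_fraction * n))
    degraded = sorted(rng.choice(n, size=min(n, n_short + n_dup), replace=False).tolist())
    short_idx = degraded[:n_short]
    short_ids = [rows[i]["stay_id"] for i in short_idx]
    for i in short_idx:
        bodies[i] = " ".join(bodies[i].split()[: config.min_words - 1])
    clean = sorted(set(range(n)) - set(degraded))
    dup_ids = []
    for i in degraded[n_short:]:
        # a duplicate must occur after its source: the filter keeps the first
        # occurrence of a body, so only copies of *earlier* clean records are
        # guaranteed to be the ones dropped
        earlier = [j for j in clean if j < i]
        if not earlier:
            continue
        bodies[i] = bodies[earlier[int(rng.integers(len(earlier)))]]
        dup_ids.append(rows[i]["stay_id"])

    for row, body in zip(rows, bodies):
        row["text"] = (
            "Admission Date: [**2130-1-1**]\n\n"
            "Brief Hospital Course:\n"
            f"{body}\n\n"
            "Medications on Discharge:\naspirin\n"
        )
    frame = pd.DataFrame(rows, columns=["stay_id", "text", "drg_code", "drg_title", "drg_version"])
    return frame, CorpusTruth(short_ids, dup_ids, base_keywords)


#: Invertible perturbations (undone by title normalization).
_INVERSE_ABBREV = {
    "WITHOUT": "W/O",
    "CATHETERIZATION": "CATH",
    "PROCEDURES": "PROC",
}

#: Severity phrase absent from each splittable-family type, used to fabricate
#: unmappable legacy variants (the "URINARY STONES W MCC" pattern: a historic
#: split the target family does not carry).  Three-way families carry every
#: CC-severity phrase in some form and are not used for injection.
_UNMAPPABLE_PHRASE = {
    SplitType.NO_SPLIT: "W MCC",
    SplitType.TWO_WAY_CCMCC_VS_NONE: "W MCC",
    SplitType.TWO_WAY_MCC_VS_REST: "W CC",
}


def generate_legacy_titles(
    catalog: DrgCatalog, config: GeneratorConfig
) -> tuple[list[str], dict[str, int | str]]:
    """Produce legacy-version titles plus their intended dispositions.

    Every catalog title yields one perturbed variant (abbreviations and case
    changes that normalization inverts, so the truth target is the original
    code).  Additionally, for ``legacy_perturb_rate`` of the eligible
    families an unmappable split variant is emitted with truth ``EXCLUDE``.
    """
    from .harmonize import EXCLUDE  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed + 2)
    titles: list[str] = []
    truth: dict[str, int | str] = {}
    for code in sorted(catalog.codes, key=lambda c: c.code):
        tokens = code.title.split()
        out = []
        for tok in tokens:
            if tok in _INVERSE_ABBREV and rng.random() < 0.5:
                out.append(_INVERSE_ABBREV[tok])
            else:
                out.append(tok)
        legacy = " ".join(out)
        style = rng.random()
        if style < 0.3:
            legacy = legacy.lower()
        elif style < 0.6:
            legacy = legacy.title()
        titles.append(legacy)
        truth[legacy] = code.code

    eligible = [
        fam for fam in sorted(catalog.families)
        if catalog.families[fam].split in _UNMAPPABLE_PHRASE
    ]
    n_unmappable = int(round(config.legacy_perturb_rate * len(eligible)))
    for fam in rng.choice(eligible, size=n_unmappable, replace=False) if n_unmappable else []:
        phrase = _UNMAPPABLE_PHRASE[catalog.families[fam].split]
        variant = f"{fam} {phrase}"
        titles.append(variant)
        truth[variant] = EXCLUDE
    return titles, truth
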