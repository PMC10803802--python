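"""MS-DRG catalog modelling: dissection into base DRG + CC/MCC and the inference
mapping rule.

A Medicare-severity DRG (MS-DRG) family consists of a *base DRG* — the principal
diagnosis (medical) or procedure (surgical) — and a set of severity *splits*
selected by complication/comorbidity (CC) or major complication/comorbidity
(MCC) secondary diagnoses.  In version 34.0 of the system a family is one of

* a three-way split:   ``WITH MCC`` / ``WITH CC`` / ``WITHOUT CC/MCC``
* a two-way split:     ``WITH CC/MCC`` / ``WITHOUT CC/MCC``
* a two-way split:     ``WITH MCC`` / ``WITHOUT MCC``
* unsplit:             a single code with no severity phrase in its title.

This module parses catalog titles into (base title, suffix), classifies
families, assigns each code one of five CC/MCC training labels, builds the
deterministic integer label spaces used by classifiers, and implements the
total mapping that turns a (base DRG, CC/MCC) prediction pair back into a
concrete catalog code.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class CatalogError(ValueError):
    """Raised when a catalog or title violates the MS-DRG structural rules."""


class CcMccLabel(IntEnum):
    """The five CC/MCC training labels, in their canonical bracketed order."""

    WITHOUT_CC_MCC = 0
    WITH_CC = 1
    WITH_MCC = 2
    WITHOUT_MCC = 3
    NOT_APPLICABLE = 4


class CatalogSuffix(Enum):
    """Severity phrases as they appear in catalog titles.

    ``WITH_CC_MCC`` exists only on catalog codes (the two-way "with CC/MCC"
    titles); it is deliberately *not* a CC/MCC training label.
    """

    WITH_MCC = "WITH MCC"
    WITH_CC = "WITH CC"
    WITHOUT_CC_MCC = "WITHOUT CC/MCC"
    WITHOUT_MCC = "WITHOUT MCC"
    WITH_CC_MCC = "WITH CC/MCC"
    NONE = ""


class SplitType(Enum):
    THREE_WAY = "three_way"
    TWO_WAY_CCMCC_VS_NONE = "two_way_ccmcc_vs_none"
    TWO_WAY_MCC_VS_REST = "two_way_mcc_vs_rest"
    NO_SPLIT = "no_split"


#: Exact suffix set that each split type must carry.
SPLIT_SUFFIXES: dict[SplitType, frozenset[CatalogSuffix]] = {
    SplitType.THREE_WAY: frozenset(
        {CatalogSuffix.WITH_MCC, CatalogSuffix.WITH_CC, CatalogSuffix.WITHOUT_CC_MCC}
    ),
    SplitType.TWO_WAY_CCMCC_VS_NONE: frozenset(
        {CatalogSuffix.WITH_CC_MCC, CatalogSuffix.WITHOUT_CC_MCC}
    ),
    SplitType.TWO_WAY_MCC_VS_REST: frozenset(
        {CatalogSuffix.WITH_MCC, CatalogSuffix.WITHOUT_MCC}
    ),
    SplitType.NO_SPLIT: frozenset({CatalogSuffix.NONE}),
}

_SUFFIX_TO_SPLIT: dict[frozenset[CatalogSuffix], SplitType] = {
    v: k for k, v in SPLIT_SUFFIXES.items()
}

#: Number of codes a family of each split type contributes.
SPLIT_SIZE = {
    SplitType.THREE_WAY: 3,
    SplitType.TWO_WAY_CCMCC_VS_NONE: 2,
    SplitType.TWO_WAY_MCC_VS_REST: 2,
    SplitType.NO_SPLIT: 1,
}

#: Training label assigned to each catalog suffix at dissection time.
#: WITH_CC_MCC has no direct member among the five labels; WITH_CC is the
#: minimal severity consistent with the title and the inference mapping sends
#: both WITH_CC and WITH_MCC back to the same code, preserving the round trip.
SUFFIX_TRAINING_LABEL: dict[CatalogSuffix, CcMccLabel] = {
    CatalogSuffix.WITH_MCC: CcMccLabel.WITH_MCC,
    CatalogSuffix.WITH_CC: CcMccLabel.WITH_CC,
    CatalogSuffix.WITHOUT_CC_MCC: CcMccLabel.WITHOUT_CC_MCC,
    CatalogSuffix.WITHOUT_MCC: CcMccLabel.WITHOUT_MCC,
    CatalogSuffix.WITH_CC_MCC: CcMccLabel.WITH_CC,
    CatalogSuffix.NONE: CcMccLabel.NOT_APPLICABLE,
}

#: Suffix whose training label is the given label, where one exists (the
#: "direct comparison" step of the inference rule).
_DIRECT_SUFFIX: dict[CcMccLabel, CatalogSuffix] = {
    CcMccLabel.WITH_MCC: CatalogSuffix.WITH_MCC,
    CcMccLabel.WITH_CC: CatalogSuffix.WITH_CC,
    CcMccLabel.WITHOUT_CC_MCC: CatalogSuffix.WITHOUT_CC_MCC,
    CcMccLabel.WITHOUT_MCC: CatalogSuffix.WITHOUT_MCC,
}

#: Fallback mapping, per split type, for predicted labels whose direct suffix is
#: absent from the family.  Totality over all 5 labels x 4 split types is what
#: makes a final DRG derivable from any (base, CC/MCC) prediction pair.
DEFAULT_FALLBACK_MAPPING: dict[SplitType, dict[CcMccLabel, CatalogSuffix]] = {
    SplitType.NO_SPLIT: {label: CatalogSuffix.NONE for label in CcMccLabel},
    SplitType.TWO_WAY_MCC_VS_REST: {
        CcMccLabel.WITHOUT_CC_MCC: CatalogSuffix.WITHOUT_MCC,
        CcMccLabel.WITH_CC: CatalogSuffix.WITHOUT_MCC,
        CcMccLabel.NOT_APPLICABLE: CatalogSuffix.WITHOUT_MCC,
    },
    SplitType.TWO_WAY_CCMCC_VS_NONE: {
        CcMccLabel.WITH_CC: CatalogSuffix.WITH_CC_MCC,
        CcMccLabel.WITH_MCC: CatalogSuffix.WITH_CC_MCC,
        CcMccLabel.WITHOUT_MCC: CatalogSuffix.WITHOUT_CC_MCC,
        CcMccLabel.NOT_APPLICABLE: CatalogSuffix.WITHOUT_CC_MCC,
    },
    SplitType.THREE_WAY: {
        CcMccLabel.WITHOUT_MCC: CatalogSuffix.WITHOUT_CC_MCC,
        CcMccLabel.NOT_APPLICABLE: CatalogSuffix.WITHOUT_CC_MCC,
    },
}


# ---------------------------------------------------------------------------
# Title normalization and suffix parsing
# ---------------------------------------------------------------------------

#: Whole-token abbreviation substitutions applied during normalization.  The
#: table is deliberately conservative: only unambiguous whole tokens, so
#: normalization can never corrupt a clinical phrase.
DEFAULT_ABBREVIATIONS: dict[str, str] = {
    "W/O": "WITHOUT",
    "CATH": "CATHETERIZATION",
    "PROC": "PROCEDURES",
    "PROCS": "PROCEDURES",
    "&": "AND",
}


def normalize_title(title: str, abbreviations: Mapping[str, str] | None = None) -> str:
    """Uppercase a DRG title, expand abbreviations and collapse whitespace.

    Idempotent: applying it twice equals applying it once.
    """
    table = DEFAULT_ABBREVIATIONS if abbreviations is None else abbreviations
    text = title.upper()
    # Tokenize on whitespace only; substitutions are whole-token.
    tokens = [table.get(tok, tok) for tok in text.split()]
    return " ".join(tokens)


# Suffix phrases recognized at end of title, longest first so that e.g.
# "WITH CC/MCC" is never mis-read as "WITH CC".  Slashless variants accepted.
_SUFFIX_PATTERNS: list[tuple[str, CatalogSuffix]] = [
    (r"WITHOUT\s+CC[/\s]\s*MCC", CatalogSuffix.WITHOUT_CC_MCC),
    (r"WITH\s+CC[/\s]\s*MCC", CatalogSuffix.WITH_CC_MCC),
    (r"WITHOUT\s+MCC", CatalogSuffix.WITHOUT_MCC),
    (r"WITH\s+MCC", CatalogSuffix.WITH_MCC),
    (r"WITH\s+CC", CatalogSuffix.WITH_CC),
]

_SUFFIX_RE = re.compile(
    r"\s+(?P<phrase>" + "|".join(p for p, _ in _SUFFIX_PATTERNS) + r")\s*$",
    re.IGNORECASE,
)

_SUFFIX_MATCHERS = [
    (re.compile(r"^" + pat + r"$", re.IGNORECASE), suffix)
    for pat, suffix in _SUFFIX_PATTERNS
]


def parse_suffix(title: str) -> tuple[str, CatalogSuffix]:
    """Split a normalized title into (base title, severity suffix).

    The severity grammar is anchored at the end of the title only; severity
    words mid-title are part of the base title.  A title carrying two stacked
    severity phrases is rejected as ambiguous.
    """
    m = _SUFFIX_RE.search(title)
    if m is None:
        return title.strip(), CatalogSuffix.NONE
    phrase = m.group("phrase")
    base = title[: m.start()].strip()
    if not base:
        # Title is only a severity phrase; treat as unsplit raw title.
        return title.strip(), CatalogSuffix.NONE
    if _SUFFIX_RE.search(base):
        raise CatalogError(
            f"ambiguous title with stacked severity phrases: {title!r}"
        )
    for matcher, suffix in _SUFFIX_MATCHERS:
        if matcher.match(phrase):
            return base, suffix
    raise CatalogError(f"unrecognized severity phrase {phrase!r} in {title!r}")


def split_type(suffixes: Iterable[CatalogSuffix]) -> SplitType:
    """Classify a family's suffix set into one of the four split types."""
    suffix_set = frozenset(suffixes)
    if not suffix_set:
        raise CatalogError("empty suffix set")
    try:
        return _SUFFIX_TO_SPLIT[suffix_set]
    except KeyError:
        names = sorted(s.name for s in suffix_set)
        raise CatalogError(
            f"suffix set {names} matches no MS-DRG split type"
        ) from None


# ---------------------------------------------------------------------------
# Catalog containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrgCode:
    """One catalog entry, dissected into base title + severity suffix."""

    code: int
    title: str
    version: str
    base_title: str
    suffix: CatalogSuffix
    cc_training_label: CcMccLabel

    @classmethod
    def from_row(cls, code: int, title: str, version: str = "34.0") -> "DrgCode":
        norm = normalize_title(title)
        base, suffix = parse_suffix(norm)
        return cls(
            code=int(code),
            title=norm,
            version=str(version),
            base_title=base,
            suffix=suffix,
            cc_training_label=SUFFIX_TRAINING_LABEL[suffix],
        )


@dataclass(frozen=True)
class Family:
    base_title: str
    split: SplitType
    by_suffix: Mapping[CatalogSuffix, DrgCode]


@dataclass
class DrgCatalog:
    """A validated, versioned MS-DRG catalog grouped into split families."""

    codes: list[DrgCode]
    families: dict[str, Family] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[int, DrgCode] = {}
        for c in self.codes:
            if c.code in seen:
                raise CatalogError(f"duplicate DRG code number {c.code}")
            seen[c.code] = c
        grouped: dict[str, dict[CatalogSuffix, DrgCode]] = {}
        for c in self.codes:
            fam = grouped.setdefault(c.base_title, {})
            if c.suffix in fam:
                raise CatalogError(
                    f"family {c.base_title!r} has two codes with suffix {c.suffix.name}"
                )
            fam[c.suffix] = c
        self.families = {}
        for base, by_suffix in grouped.items():
            st = split_type(by_suffix)  # raises on invalid suffix sets
            self.families[base] = Family(base, st, dict(by_suffix))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[int, str, str]] | Iterable[tuple[int, str]]
    ) -> "DrgCatalog":
        codes = []
        for row in rows:
            code, title, *rest = row
            version = rest[0] if rest else "34.0"
            codes.append(DrgCode.from_row(code, title, version))
        return cls(codes)

    @classmethod
    def read(cls, path: str | Path) -> "DrgCatalog":
        """Read a catalog from CSV/TSV with columns code,title[,version]."""
        path = Path(path)
        delim = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            rows = [
                (int(r["code"]), r["title"], r.get("version", "34.0"))
                for r in reader
            ]
        return cls.from_rows(rows)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        delim = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=delim)
            w.writerow(["code", "title", "version"])
            for c in sorted(self.codes, key=lambda c: c.code):
                w.writerow([c.code, c.title, c.version])

    # -- views --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.codes)

    def by_code(self, code: int) -> DrgCode:
        for c in self.codes:
            if c.code == code:
                return c
        raise KeyError(code)

    def split_census(self) -> dict[SplitType, int]:
        """Count families per split type (the Discussion-style census)."""
        census = {st: 0 for st in SplitType}
        for fam in self.families.values():
            census[fam.split] += 1
        return census


@dataclass(frozen=True)
class LabelSpace:
    """Deterministic integer index mappings for a dissected catalog.

    DRG codes are indexed in ascending code-number order (0..C-1), base titles
    lexicographically (0..B-1), CC/MCC labels by their enum value (0..4), so
    indices are reproducible across runs and machines.
    """

    codes: tuple[DrgCode, ...]
    base_titles: tuple[str, ...]

    @property
    def n_drg(self) -> int:
        return len(self.codes)

    @property
    def n_base(self) -> int:
        return len(self.base_titles)

    @property
    def n_cc(self) -> int:
        return len(CcMccLabel)

    def drg_index(self, code: int) -> int:
        return self._drg_lookup()[code]

    def base_index(self, base_title: str) -> int:
        return self._base_lookup()[base_title]

    def _drg_lookup(self) -> dict[int, int]:
        if not hasattr(self, "_drg_cache"):
            object.__setattr__(
                self, "_drg_cache", {c.code: i for i, c in enumerate(self.codes)}
            )
        return self._drg_cache  # type: ignore[attr-defined]

    def _base_lookup(self) -> dict[str, int]:
        if not hasattr(self, "_base_cache"):
            object.__setattr__(
                self, "_base_cache", {t: i for i, t in enumerate(self.base_titles)}
            )
        return self._base_cache  # type: ignore[attr-defined]

    def targets_for(self, code: int) -> tuple[int, int, int]:
        """(drg_index, base_index, cc_label value) for a catalog code number."""
        i = self.drg_index(code)
        c = self.codes[i]
        return i, self.base_index(c.base_title), int(c.cc_training_label)


def dissect(catalog: DrgCatalog) -> LabelSpace:
    """Build the label space: every code gets one base index and one of the
    five CC/MCC training labels (already assigned at parse time)."""
    codes = tuple(sorted(catalog.codes, key=lambda c: c.code))
    base_titles = tuple(sorted(catalog.families))
    return LabelSpace(codes=codes, base_titles=base_titles)


# ---------------------------------------------------------------------------
# Inference mapping rule
# ---------------------------------------------------------------------------


def infer_drg(
    base_index: int,
    cc_label: CcMccLabel | int,
    catalog: DrgCatalog,
    space: LabelSpace | None = None,
    fallback: Mapping[SplitType, Mapping[CcMccLabel, CatalogSuffix]] | None = None,
) -> DrgCode:
    """Map a (base DRG, CC/MCC) prediction pair to a concrete catalog code.

    If the predicted label's direct suffix exists in the family, that code is
    returned; otherwise the split-type fallback table decides.  The mapping is
    total: every (base, label) pair yields exactly one code.
    """
    space = dissect(catalog) if space is None else space
    cc_label = CcMccLabel(cc_label)
    base_title = space.base_titles[base_index]
    family = catalog.families[base_title]
    if family.split is SplitType.NO_SPLIT:
        return family.by_suffix[CatalogSuffix.NONE]
    direct = _DIRECT_SUFFIX.get(cc_label)
    if direct is not None and direct in family.by_suffix:
        return family.by_suffix[direct]
    table = DEFAULT_FALLBACK_MAPPING if fallback is None else fallback
    target_suffix = table[family.split][cc_label]
    return family.by_suffix[target_suffix]


def mapping_table_rows() -> list[tuple[str, str, str]]:
    """Flatten the full inference mapping as (split_type, cc_label,
    target_suffix) rows for audit export, direct matches included."""
    rows = []
    for st, suffixes in SPLIT_SUFFIXES.items():
        for label in CcMccLabel:
            direct = _DIRECT_SUFFIX.get(label)
            if st is SplitType.NO_SPLIT:
                target = CatalogSuffix.NONE
            elif direct is not None and direct in suffixes:
                target = direct
            else:
                target = DEFAULT_FALLBACK_MAPPING[st][label]
            rows.append((st.value, label.name, target.name))
    return rows


def write_dissection(catalog: DrgCatalog, path: str | Path) -> None:
    """Write the dissection as TSV: code, base_title, split_type, cc_label."""
    space = dissect(catalog)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["code", "base_title", "split_type", "cc_label"])
        for c in space.codes:
            fam = catalog.families[c.base_title]
            w.writerow([c.code, c.base_title, fam.split.value, c.cc_training_label.name])
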