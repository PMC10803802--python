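"""Consolidation of DRG codes assigned under different MS-DRG versions.

CMS adjusts MS-DRG definitions (and renumbers codes) annually, so the same
clinical condition can carry different codes across admission years.  The
harmonization pipeline maps every stay's historical DRG *title* onto the
target catalog (v34.0 by convention):

1. normalize the title (abbreviations, case, whitespace);
2. exact match against the target catalog;
3. manual conversion map lookup (the physician/CDI-reviewed table);
4. fuzzy token-set match, accepted only above a high similarity bar with a
   unique best candidate;
5. everything else is excluded from the cohort.

Matching operates on titles rather than code numbers precisely because the
numbers are not stable across versions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from difflib import SequenceMatcher
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

from .catalog import DrgCatalog, normalize_title

EXCLUDE = "EXCLUDE"

#: Default fuzzy acceptance bar on the 0-100 token-set scale.  Fuzzy matching
#: in the source procedure only *flagged* non-matches for physician review; a
#: high bar plus the manual map reproduces that conservatism automatically.
DEFAULT_THRESHOLD = 95


class Provenance(Enum):
    EXACT = "EXACT"
    MANUAL = "MANUAL"
    FUZZY_ACCEPTED = "FUZZY_ACCEPTED"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class MatchCandidate:
    code: int
    score: int  # 0-100; 100 iff normalized titles identical
    method: str  # "exact" | "fuzzy"


def _ratio(a: str, b: str) -> float:
    return SequenceMatcher(None, a, b).ratio()


def token_set_ratio(a: str, b: str) -> int:
    """Token-set similarity on a 0-100 scale.

    Token-set construction: each string is rewritten as its sorted token
    intersection followed by its sorted remainder, and the two rewritings are
    compared by edit ratio.  Unlike the fully saturating variant, the pure
    intersection-vs-intersection comparisons are deliberately omitted, so a
    title that merely *contains* a catalog title (e.g. a legacy title with an
    extra severity phrase) does not score as a perfect match.  100 is reserved
    for exact string identity.
    """
    if a == b:
        return 100
    ta, tb = set(a.split()), set(b.split())
    inter = " ".join(sorted(ta & tb))
    s1 = (inter + " " + " ".join(sorted(ta - tb))).strip()
    s2 = (inter + " " + " ".join(sorted(tb - ta))).strip()
    return min(99, int(round(100 * _ratio(s1, s2))))


def fuzzy_candidates(
    title: str, catalog: DrgCatalog, k: int = 5
) -> list[MatchCandidate]:
    """Top-k catalog candidates for a normalized title, best first.

    Ties are broken by ascending code number; an exact normalized match always
    ranks first with score 100.
    """
    if not catalog.codes:
        raise ValueError("cannot match against an empty catalog")
    title = normalize_title(title)
    cands = []
    for code in catalog.codes:
        if code.title == title:
            cands.append(MatchCandidate(code.code, 100, "exact"))
        else:
            cands.append(
                MatchCandidate(code.code, token_set_ratio(title, code.title), "fuzzy")
            )
    cands.sort(key=lambda c: (-c.score, c.code))
    return cands[:k]


@dataclass
class HarmonizationMap:
    """Manual conversion table: normalized source title -> target code or EXCLUDE."""

    entries: dict[str, int | str]

    def __post_init__(self) -> None:
        self.entries = {normalize_title(t): v for t, v in self.entries.items()}

    def validate(self, catalog: DrgCatalog) -> None:
        valid = {c.code for c in catalog.codes}
        for title, target in self.entries.items():
            if target != EXCLUDE and target not in valid:
                raise ValueError(
                    f"manual map target {target!r} for {title!r} is not in the catalog"
                )

    @classmethod
    def read(cls, path: str | Path) -> "HarmonizationMap":
        """CSV columns: source_title, target_code, action(map|exclude)[, note]."""
        entries: dict[str, int | str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                title = row["source_title"]
                if title in entries:
                    raise ValueError(f"duplicate manual-map source title {title!r}")
                if row.get("action", "map").strip().lower() == "exclude":
                    entries[title] = EXCLUDE
                else:
                    entries[title] = int(row["target_code"])
        return cls(entries)

    @classmethod
    def empty(cls) -> "HarmonizationMap":
        return cls({})


def harmonize_records(
    records: pd.DataFrame,
    target_catalog: DrgCatalog,
    manual_map: HarmonizationMap | None = None,
    threshold: int = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize a stay table onto the target catalog.

    ``records`` needs a ``drg_title`` column (plus whatever else the caller
    carries — stay_id, text, drg_version ...).  Returns ``(kept, report)``:
    *kept* is the input restricted to harmonized stays with two new columns
    ``drg_code`` (target code number) and ``provenance``; *report* lists every
    input record's disposition, so kept + excluded partitions the input.
    """
    if "drg_title" not in records.columns:
        raise ValueError("records must carry a 'drg_title' column")
    manual_map = HarmonizationMap.empty() if manual_map is None else manual_map
    manual_map.validate(target_catalog)

    by_title = {c.title: c.code for c in target_catalog.codes}
    dispositions: list[tuple[str, int | None, str]] = []
    cache: dict[str, tuple[int | None, Provenance]] = {}

    for raw_title in records["drg_title"]:
        norm = normalize_title(str(raw_title))
        if norm in cache:
            code, prov = cache[norm]
        elif norm in by_title:
            code, prov = by_title[norm], Provenance.EXACT
        elif norm in manual_map.entries:
            target = manual_map.entries[norm]
            if target == EXCLUDE:
                code, prov = None, Provenance.EXCLUDED
            else:
                code, prov = int(target), Provenance.MANUAL
        else:
            top = fuzzy_candidates(norm, target_catalog, k=2)
            unique_top = len(top) < 2 or top[0].score > top[1].score
            if top[0].score >= threshold and unique_top:
                code, prov = top[0].code, Provenance.FUZZY_ACCEPTED
            else:
                code, prov = None, Provenance.EXCLUDED
        cache[norm] = (code, prov)
        dispositions.append((norm, code, prov.value))

    report = pd.DataFrame(
        dispositions, columns=["normalized_title", "target_code", "provenance"]
    )
    report.index = records.index
    keep = report["provenance"] != Provenance.EXCLUDED.value
    kept = records.loc[keep].copy()
    kept["drg_code"] = report.loc[keep, "target_code"].astype(int)
    kept["provenance"] = report.loc[keep, "provenance"]
    return kept, report


def filter_rare(
    records: pd.DataFrame, min_count: int = 2, label_col: str = "drg_code"
) -> tuple[pd.DataFrame, list]:
    """Drop stays whose DRG label occurs fewer than ``min_count`` times.

    Returns the surviving records and the sorted list of dropped labels.
    """
    counts = records[label_col].value_counts()
    dropped = sorted(counts.index[counts < min_count].tolist())
    kept = records[~records[label_col].isin(dropped)].copy()
    return kept, dropped
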