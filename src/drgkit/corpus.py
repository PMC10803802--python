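"""Discharge-summary preparation: section extraction, quality filtering,
stratified splitting and tokenization.

The model input is the "brief hospital course" narrative of the discharge
summary, not the whole note.  Preparation mirrors a standard clinical-NLP
cohort build: extract the section, drop empty/short/duplicated notes, split
90/10 stratified by DRG so that even moderately rare codes appear in training,
then tokenize and truncate to the backbone's context size.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Case-insensitive variants of the section header.
_BHC_HEADER = re.compile(
    r"^[ \t]*brief\s+hospital\s+course\s*:?\s*$|brief\s+hospital\s+course\s*:",
    re.IGNORECASE | re.MULTILINE,
)
# A following section header: a short title-like line ending with ':'.
_NEXT_SECTION = re.compile(r"^[ \t]*[A-Za-z][A-Za-z0-9 ,'()/-]{0,79}:[ \t]*$", re.MULTILINE)


def extract_bhc(raw_text: str) -> str | None:
    """Extract the "brief hospital course" section, or None when absent.

    The section runs from the header to the next section header (a short line
    ending in a colon) or the end of the document.  An empty section is
    treated as absent.
    """
    m = _BHC_HEADER.search(raw_text)
    if m is None:
        return None
    start = m.end()
    nxt = _NEXT_SECTION.search(raw_text, pos=start)
    body = raw_text[start : nxt.start()] if nxt else raw_text[start:]
    body = body.strip()
    return body or None


def word_count(text: str) -> int:
    """Whitespace-delimited token count (no punctuation stripping)."""
    return len(text.split())


def quality_filter(
    records: pd.DataFrame,
    min_words: int = 40,
    text_col: str = "bhc_text",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop missing, short (< ``min_words`` words) and duplicated sections.

    A duplicate is an exact string match of the extracted section text; the
    first occurrence in document order is kept.  Returns the kept records and
    a report counting each drop reason (a record is counted once, under the
    first rule that fires).
    """
    report = {"missing": 0, "short": 0, "duplicate": 0, "kept": 0}
    seen: set[str] = set()
    keep_mask = []
    for text in records[text_col]:
        if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
            report["missing"] += 1
            keep_mask.append(False)
        elif word_count(text) < min_words:
            report["short"] += 1
            keep_mask.append(False)
        elif text in seen:
            report["duplicate"] += 1
            keep_mask.append(False)
        else:
            seen.add(text)
            report["kept"] += 1
            keep_mask.append(True)
    return records.loc[keep_mask].copy(), report


@dataclass
class DatasetSplit:
    """A stratified train/test partition with its per-class report."""

    train: pd.DataFrame
    test: pd.DataFrame
    seed: int
    report: pd.DataFrame  # per-label: n, n_train, n_test

    def __post_init__(self) -> None:
        overlap = set(self.train.index) & set(self.test.index)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]} ...")


def stratified_split(
    records: pd.DataFrame,
    test_fraction: float = 0.1,
    seed: int = 0,
    label_col: str = "drg_code",
) -> DatasetSplit:
    """Per-DRG allocation of round(n_c * test_fraction) test records.

    Every class keeps at least one training record, so a 2-record class may
    legitimately end up entirely in training — which is why a stratified test
    set can contain fewer unique labels than the training set.  Deterministic
    given the seed (half-up rounding; sampling via a seeded generator).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list = []
    rows = []
    # Sort labels for a deterministic iteration order regardless of input order.
    for label in sorted(records[label_col].unique()):
        idx = records.index[records[label_col] == label].to_numpy()
        n = len(idx)
        n_test = int(n * test_fraction + 0.5)
        n_test = min(n_test, n - 1)  # at least one training record per class
        if n_test > 0:
            chosen = rng.choice(idx, size=n_test, replace=False)
            test_idx.extend(chosen.tolist())
        rows.append((label, n, n - n_test, n_test))
    test_set = set(test_idx)
    in_test = records.index.isin(test_set)
    report = pd.DataFrame(rows, columns=[label_col, "n", "n_train", "n_test"])
    return DatasetSplit(
        train=records.loc[~in_test].copy(),
        test=records.loc[in_test].copy(),
        seed=seed,
        report=report,
    )


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TokenSequence:
    ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.ids)


_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class HashingTokenizer:
    """Reference tokenizer: lowercase, split on non-alphanumerics, hash each
    token into a fixed-size vocabulary with a stable (md5-based) hash.

    This stands in for a backbone-supplied tokenizer contract; an LLM adapter
    would carry its own vocabulary instead.
    """

    vocab_size: int = 2**15

    def tokenize(self, text: str) -> list[int]:
        tokens = _TOKEN_RE.findall(text.lower())
        return [self._hash(t) for t in tokens]

    def _hash(self, token: str) -> int:
        digest = hashlib.md5(token.encode()).digest()
        return int.from_bytes(digest[:8], "little") % self.vocab_size


def tokenize_truncate(
    text: str, tokenizer: HashingTokenizer, max_tokens: int
) -> TokenSequence:
    """Tokenize and keep the FIRST ``max_tokens`` tokens.

    Head truncation: the hospital-course narrative opens with the presenting
    problem, so the head carries the diagnostic signal.  Idempotent on already
    short sequences; rejects empty text.
    """
    if not text or not text.strip():
        raise ValueError("cannot tokenize empty text")
    ids = tokenizer.tokenize(text)
    if not ids:
        raise ValueError("text produced no tokens")
    return TokenSequence(tuple(ids[:max_tokens]))


def build_dataset(
    records: pd.DataFrame,
    space,
    text_col: str = "bhc_text",
    label_col: str = "drg_code",
) -> pd.DataFrame:
    """Attach integer targets (drg_index, base_index, cc_index) from a
    dissected label space to a record table."""
    out = records.copy()
    targets = [space.targets_for(code) for code in out[label_col]]
    out["drg_index"] = [t[0] for t in targets]
    out["base_index"] = [t[1] for t in targets]
    out["cc_index"] = [t[2] for t in targets]
    return out
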