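"""Microblog text cleaning, length filtering, tokenization and vocabulary.

The cleaning pipeline targets the noise typical of Chinese microblog
(Weibo-style) posts: HTML markup, URLs, emojis, topic hashtags delimited
by ``#...#``, ``@user`` mentions and platform behaviour markers such as
``[reposts]``.  Rules are applied in a fixed order so that the whole
pipeline is idempotent: ``clean_text(clean_text(s)) == clean_text(s)``.

Records whose cleaned text is shorter than five non-whitespace
characters carry too little emotional content to classify and are
dropped by :func:`length_filter`.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .errors import ConfigError, DataError

PAD_TOKEN = "<PAD>"
UNK_TOKEN = "<UNK>"
PAD_INDEX = 0
UNK_INDEX = 1
NUM_TOKEN = "NUM"

# --------------------------------------------------------------------------
# Domain records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RawDocument:
    """A raw labeled microblog record.

    ``label`` is 1 for text indicative of suicidal ideation, 0 otherwise,
    and may be ``None`` for prediction-only input.
    """

    doc_id: str
    text: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise DataError(f"label must be 0, 1 or None, got {self.label!r}")


@dataclass(frozen=True)
class CleanDocument:
    """A document after cleaning, tokenization and length filtering."""

    doc_id: str
    cleaned_text: str
    tokens: tuple[str, ...]
    kept: bool
    label: int | None = None


# --------------------------------------------------------------------------
# Cleaning
# --------------------------------------------------------------------------

_HTML_TAG_RE = re.compile(r"<[^<>]+>")
_URL_RE = re.compile(r"(?:https?://|www\.)[\w\-./?%&=+:~#@]*", re.IGNORECASE)
# Unicode emoji and pictograph blocks plus variation selectors / ZWJ.
_EMOJI_RE = re.compile(
    "["
    "\U0001f000-\U0001faff"  # pictographs, emoticons, symbols, extended-A
    "☀-➿"          # misc symbols and dingbats
    "⬀-⯿"
    "︎️‍"
    "\U000e0020-\U000e007f"  # emoji tag sequences
    "]+"
)
# Weibo topic hashtags are delimited on both sides: #topic#.  A trailing
# bare hashtag token (#topic) is also stripped.
_HASHTAG_RE = re.compile(r"#[^#\s]+#|#[\w一-鿿]+")
_MENTION_RE = re.compile(r"@[\w一-鿿\-.]+")
# Behaviour markers appear as bracketed tokens: [reposts], [doge], 【转发】
_BRACKET_RE = re.compile(r"\[[^\[\]]*\]|【[^【】]*】")
_DIGIT_RUN_RE = re.compile(r"\d+(?:[.,]\d+)*")
_WS_RE = re.compile(r"\s+")
# Punctuation stripped only at the edges of the text.
_EDGE_PUNCT_RE = re.compile(
    r"^[\s!-/:-@\[-`{-~、。，！？；：“”‘’…—·《》（）〔〕「」]+"
    r"|[\s!-/:-@\[-`{-~、。，！？；：“”‘’…—·《》（）〔〕「」]+$"
)


def clean_text(raw: str) -> str:
    """Apply the microblog cleaning rules in fixed order.

    Order: HTML tags, URLs, emojis, topic hashtags, @mentions, bracketed
    behaviour markers, digit-run normalization to ``NUM``, whitespace
    collapse and edge punctuation trimming.  The function is idempotent.
    """
    if not isinstance(raw, str):
        raise DataError(f"clean_text expects str, got {type(raw).__name__}")
    s = _HTML_TAG_RE.sub(" ", raw)
    s = _URL_RE.sub(" ", s)
    s = _EMOJI_RE.sub(" ", s)
    s = _HASHTAG_RE.sub(" ", s)
    s = _MENTION_RE.sub(" ", s)
    s = _BRACKET_RE.sub(" ", s)
    s = _DIGIT_RUN_RE.sub(NUM_TOKEN, s)
    s = _EDGE_PUNCT_RE.sub("", s)
    s = _WS_RE.sub(" ", s).strip()
    return s


def length_filter(cleaned: str, min_chars: int = 5) -> bool:
    """Return ``True`` iff the cleaned text is long enough to keep.

    Counts non-whitespace characters; a text of exactly ``min_chars``
    characters is kept (strictly-shorter records are dropped).
    """
    if min_chars < 1:
        raise ConfigError(f"min_chars must be >= 1, got {min_chars}")
    n = sum(1 for ch in cleaned if not ch.isspace())
    return n >= min_chars


# --------------------------------------------------------------------------
# Tokenization
# --------------------------------------------------------------------------

Segmenter = Callable[[str], list[str]]

_SEGMENTERS: dict[str, Segmenter] = {}


def register_segmenter(name: str, fn: Segmenter) -> None:
    """Register a word segmenter under ``name`` (e.g. a jieba wrapper)."""
    _SEGMENTERS[name] = fn


register_segmenter("whitespace", str.split)
register_segmenter(
    "character", lambda s: [ch for ch in s if not ch.isspace()]
)


def tokenize(cleaned: str, segmenter: str = "whitespace") -> list[str]:
    """Segment cleaned text into tokens with a registered segmenter."""
    try:
        fn = _SEGMENTERS[segmenter]
    except KeyError:
        raise ConfigError(
            f"unknown segmenter {segmenter!r}; registered: "
            f"{sorted(_SEGMENTERS)}"
        ) from None
    return fn(cleaned)


# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------


@dataclass
class Vocabulary:
    """Top-N frequency vocabulary with reserved PAD and UNK entries.

    Content words occupy dense indices ``2 .. size+1``; index 0 is PAD
    and index 1 is UNK.  Looking up an out-of-vocabulary token returns
    the UNK index, never raises.
    """

    index: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        """Number of content entries (excluding PAD/UNK)."""
        return len(self.index)

    @property
    def total_size(self) -> int:
        return len(self.index) + 2

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def lookup(self, word: str) -> int:
        return self.index.get(word, UNK_INDEX)

    def encode(self, tokens: Sequence[str]) -> list[int]:
        return [self.lookup(t) for t in tokens]

    def to_json(self) -> str:
        return json.dumps(self.index, ensure_ascii=False, sort_keys=False)

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        return cls(index=dict(json.loads(payload)))


def build_vocab(corpus: Iterable[Sequence[str]], n: int) -> Vocabulary:
    """Build the top-``n`` frequency vocabulary from training token lists.

    Ties in frequency are broken lexicographically (ascending), so the
    vocabulary is a deterministic function of the corpus.
    """
    if n <= 0:
        raise ConfigError(f"vocabulary size N must be >= 1, got {n}")
    counts: Counter[str] = Counter()
    seen_any = False
    for tokens in corpus:
        seen_any = True
        counts.update(tokens)
    if not seen_any:
        raise DataError("cannot build a vocabulary from an empty corpus")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    index = {w: i + 2 for i, (w, _) in enumerate(ranked[:n])}
    return Vocabulary(index=index)


# --------------------------------------------------------------------------
# Corpus pipeline and IO
# --------------------------------------------------------------------------


def preprocess(
    docs: Iterable[RawDocument],
    min_chars: int = 5,
    segmenter: str = "whitespace",
) -> list[CleanDocument]:
    """Clean, length-filter and tokenize a corpus.

    Every input record yields exactly one output record; dropped records
    have ``kept=False`` and an empty token tuple, so downstream counts
    are conserved (kept + dropped = input).
    """
    out: list[CleanDocument] = []
    for doc in docs:
        cleaned = clean_text(doc.text)
        kept = length_filter(cleaned, min_chars=min_chars)
        tokens = tuple(tokenize(cleaned, segmenter)) if kept else ()
        if kept and not tokens:
            kept = False
        out.append(
            CleanDocument(
                doc_id=doc.doc_id,
                cleaned_text=cleaned,
                tokens=tokens,
                kept=kept,
                label=doc.label,
            )
        )
    return out


def read_jsonl(path: str | Path) -> list[RawDocument]:
    """Read a corpus from JSONL with fields ``id``, ``text``, ``label``."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DataError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            label = rec.get("label")
            docs.append(
                RawDocument(
                    doc_id=str(rec["id"]),
                    text=rec["text"],
                    label=None if label is None else int(label),
                )
            )
    return docs


def write_jsonl(path: str | Path, docs: Iterable[RawDocument]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec: dict = {"id": doc.doc_id, "text": doc.text}
            if doc.label is not None:
                rec["label"] = doc.label
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_clean_jsonl(path: str | Path, docs: Iterable[CleanDocument]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec: dict = {
                "id": doc.doc_id,
                "text": doc.cleaned_text,
                "tokens": list(doc.tokens),
                "kept": doc.kept,
            }
            if doc.label is not None:
                rec["label"] = doc.label
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_clean_jsonl(path: str | Path) -> list[CleanDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            label = rec.get("label")
            docs.append(
                CleanDocument(
                    doc_id=str(rec["id"]),
                    cleaned_text=rec["text"],
                    tokens=tuple(rec.get("tokens", ())),
                    kept=bool(rec.get("kept", True)),
                    label=None if label is None else int(label),
                )
            )
    return docs


def read_csv(path: str | Path) -> list[RawDocument]:
    """Read a corpus from CSV with columns ``id``, ``text``, ``label``."""
    docs = []
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            label = rec.get("label")
            docs.append(
                RawDocument(
                    doc_id=str(rec["id"]),
                    text=rec["text"],
                    label=int(label) if label not in (None, "") else None,
                )
            )
    return docs


def write_csv(path: str | Path, docs: Iterable[RawDocument]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "text", "label"])
        for doc in docs:
            writer.writerow(
                [doc.doc_id, doc.text, "" if doc.label is None else doc.label]
            )


def read_corpus(path: str | Path) -> list[RawDocument]:
    """Dispatch on file extension (.jsonl/.json → JSONL, .csv → CSV)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_csv(path)
    return read_jsonl(path)
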