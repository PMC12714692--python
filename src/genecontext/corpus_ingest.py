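"""Gene-set and document ingestion, text preprocessing, and document-term matrices.

Reads MSigDB-style GMT gene-set collections and the per-set document table
(concatenated abstracts or, failing that, the curator's description), runs the
standard text-mining preprocessing chain (normalisation, lowercasing,
punctuation/digit stripping, stopword removal, Porter stemming), and produces
a pruned sparse document-term matrix ready for topic modelling.
"""

from __future__ import annotations

import json
import re
import string
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GeneSet",
    "DocumentRecord",
    "TokenizedDoc",
    "DocumentTermMatrix",
    "read_gmt",
    "write_gmt",
    "read_documents",
    "read_stopwords",
    "merge_documents",
    "preprocess_text",
    "porter_stem",
    "build_dtm",
    "prune_rare_tokens",
    "write_dtm",
    "read_dtm",
    "DEFAULT_STOPWORDS",
]

#: Minimal built-in stopword list; real analyses should supply a curated one.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be by for from has have in is it its of on or that the
    this to was were will with we our these those which been not also may can
    using used show shown study studies result results cell cells gene genes
    expression protein proteins pathway pathways""".split()
)


@dataclass
class GeneSet:
    """A named, identified collection of gene symbols with linked documents.

    Gene symbols are case-sensitive opaque strings; duplicates are collapsed
    preserving first occurrence.
    """

    set_id: str
    name: str
    genes: tuple[str, ...]
    doc_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = tuple(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} has no genes")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class DocumentRecord:
    doc_id: str
    set_id: str
    text: str
    source: str = "abstract"  # "abstract" or "description"

    def __post_init__(self) -> None:
        if self.source not in ("abstract", "description"):
            raise ValueError(f"unknown document source {self.source!r}")


@dataclass
class TokenizedDoc:
    doc_id: str
    tokens: list[str]


@dataclass
class DocumentTermMatrix:
    """Sparse docs x tokens count matrix with aligned identifier lists."""

    doc_ids: list[str]
    vocabulary: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise ValueError("counts shape does not match doc_ids x vocabulary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def token_frequencies(self) -> np.ndarray:
        """Corpus-wide frequency (column sum) of every vocabulary token."""
        return np.asarray(self.counts.sum(axis=0)).ravel()


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (tab-separated: id, description, gene symbols...).

    Duplicate gene symbols within a line are collapsed preserving first
    occurrence; duplicate set ids across lines raise ``ValueError``.
    """
    sets: list[GeneSet] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, name, *genes = fields
            genes = [g for g in genes if g]
            if set_id in seen_ids:
                raise ValueError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            seen_ids.add(set_id)
            sets.append(GeneSet(set_id=set_id, name=name, genes=tuple(genes)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Documents and stopwords
# ---------------------------------------------------------------------------

def read_documents(path: str | Path) -> list[DocumentRecord]:
    """Read a document table (TSV or line-JSON) with columns
    doc_id, set_id, source, text."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.read(1)
    if first == "{":
        df = pd.read_json(path, lines=True, dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"doc_id", "set_id", "source", "text"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing document columns {sorted(missing)}")
    return [
        DocumentRecord(doc_id=r.doc_id, set_id=r.set_id, text=r.text, source=r.source)
        for r in df.itertuples()
    ]


def write_documents(records: list[DocumentRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "doc_id": [r.doc_id for r in records],
            "set_id": [r.set_id for r in records],
            "source": [r.source for r in records],
            "text": [r.text for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_stopwords(path: str | Path) -> frozenset[str]:
    """One token per line; '#'-prefixed lines are comments."""
    words: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                words.add(token.lower())
    return frozenset(words)


def merge_documents(records: list[DocumentRecord]) -> list[DocumentRecord]:
    """Collapse to exactly one document per gene set.

    Texts are joined in input order with a single space. When both abstracts
    and a description exist for a set, the abstracts take precedence and the
    description is dropped; the description is used only when no abstract is
    available.
    """
    by_set: dict[str, list[DocumentRecord]] = {}
    for rec in records:
        by_set.setdefault(rec.set_id, []).append(rec)
    merged: list[DocumentRecord] = []
    for set_id, recs in by_set.items():
        abstracts = [r for r in recs if r.source == "abstract"]
        chosen = abstracts if abstracts else recs
        text = " ".join(r.text for r in chosen if r.text)
        source = "abstract" if abstracts else "description"
        merged.append(
            DocumentRecord(doc_id=set_id, set_id=set_id, text=text, source=source)
        )
    return merged


# ---------------------------------------------------------------------------
# Porter stemmer (Porter 1980). No installed package provides one, and the
# algorithm itself is short and fully specified, so it lives here.
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions ("VC" blocks) in the stem."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        vowel = not _is_consonant(stem, i)
        if not vowel and prev_vowel:
            m += 1
        prev_vowel = vowel
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Stem a lower-case word with the classic Porter algorithm."""
    if len(word) <= 2:
        return word
    w = word

    # step 1a: plural forms
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # step 1b: -eed / -ed / -ing
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        stripped = None
        if w.endswith("ed") and _contains_vowel(w[:-2]):
            stripped = w[:-2]
        elif w.endswith("ing") and _contains_vowel(w[:-3]):
            stripped = w[:-3]
        if stripped is not None:
            w = stripped
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_consonant(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # step 1c: terminal y -> i
    if w.endswith("y") and _contains_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # step 3
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # step 4
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and not stem.endswith(("s", "t")):
                    break
                w = stem
            break

    # step 5a: terminal e
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # step 5b: -ll with m > 1
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        w = w[:-1]

    return w


# ---------------------------------------------------------------------------
# Preprocessing pipeline
# ---------------------------------------------------------------------------

_ASCII_KEEP = set(string.ascii_letters + string.digits + string.punctuation + " \t\n\r")
_PUNCT_DIGIT = re.compile(r"[^a-z]+")


def preprocess_text(
    raw: str, stopwords: frozenset[str] | set[str], doc_id: str = ""
) -> TokenizedDoc:
    """Normalise, tokenize, filter and stem raw document text.

    Applies, in order: Unicode compatibility normalisation; removal of any
    character outside ASCII letters/digits/punctuation/whitespace (Greek
    letters and other non-Latin residues are decomposed first, so e.g. an
    accented Latin letter keeps its base form); lowercasing; replacement of
    punctuation and digits by spaces; whitespace tokenization; stopword
    removal; Porter stemming; and removal of tokens shorter than 2 characters.
    """
    text = unicodedata.normalize("NFKD", raw)
    text = "".join(ch for ch in text if ch in _ASCII_KEEP)
    text = text.lower()
    text = _PUNCT_DIGIT.sub(" ", text)
    tokens = [t for t in text.split() if t not in stopwords]
    tokens = [porter_stem(t) for t in tokens]
    tokens = [t for t in tokens if len(t) >= 2]
    return TokenizedDoc(doc_id=doc_id, tokens=tokens)


def build_dtm(docs: list[TokenizedDoc]) -> DocumentTermMatrix:
    """Assemble the sparse document-term count matrix.

    Vocabulary is sorted lexicographically; counts[i, j] is the multiplicity
    of vocabulary[j] in document i.
    """
    if not docs:
        raise ValueError("build_dtm requires at least one document")
    vocabulary = sorted({t for d in docs for t in d.tokens})
    index = {t: j for j, t in enumerate(vocabulary)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    for i, doc in enumerate(docs):
        counts: dict[int, int] = {}
        for t in doc.tokens:
            j = index[t]
            counts[j] = counts.get(j, 0) + 1
        rows.extend([i] * len(counts))
        cols.extend(counts)
        data.extend(counts.values())
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(docs), len(vocabulary)), dtype=np.int64
    )
    return DocumentTermMatrix([d.doc_id for d in docs], vocabulary, mat)


def prune_rare_tokens(dtm: DocumentTermMatrix, min_freq: int = 5) -> DocumentTermMatrix:
    """Iteratively drop tokens with corpus frequency < ``min_freq`` and the
    documents they empty, until both invariants hold simultaneously.

    Frequency is corpus-wide (summed over documents), the text-mining
    convention. Raises if every document is removed.
    """
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    counts = dtm.counts.copy()
    doc_ids = list(dtm.doc_ids)
    vocab = list(dtm.vocabulary)
    while True:
        col_freq = np.asarray(counts.sum(axis=0)).ravel()
        keep_cols = col_freq >= min_freq
        changed = not keep_cols.all()
        if changed:
            counts = counts[:, keep_cols]
            vocab = [v for v, k in zip(vocab, keep_cols) if k]
        row_tot = np.asarray(counts.sum(axis=1)).ravel()
        keep_rows = row_tot > 0
        if not keep_rows.any():
            raise ValueError("corpus emptied by pruning")
        if not keep_rows.all():
            counts = counts[keep_rows]
            doc_ids = [d for d, k in zip(doc_ids, keep_rows) if k]
            changed = True
        if not changed:
            break
    return DocumentTermMatrix(doc_ids, vocab, counts)


# ---------------------------------------------------------------------------
# DTM persistence: MatrixMarket triplet + sidecar id lists
# ---------------------------------------------------------------------------

def write_dtm(dtm: DocumentTermMatrix, prefix: str | Path) -> dict[str, str]:
    """Write counts as MTX plus sidecar vocabulary / doc-id text files."""
    prefix = Path(prefix)
    paths = {
        "counts": str(prefix) + ".mtx",
        "vocabulary": str(prefix) + ".vocab.txt",
        "doc_ids": str(prefix) + ".docs.txt",
    }
    scipy.io.mmwrite(paths["counts"], dtm.counts)
    Path(paths["vocabulary"]).write_text("\n".join(dtm.vocabulary) + "\n")
    Path(paths["doc_ids"]).write_text("\n".join(dtm.doc_ids) + "\n")
    return paths


def read_dtm(prefix: str | Path) -> DocumentTermMatrix:
    prefix = Path(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    vocab = Path(str(prefix) + ".vocab.txt").read_text().splitlines()
    doc_ids = Path(str(prefix) + ".docs.txt").read_text().splitlines()
    return DocumentTermMatrix(doc_ids, vocab, counts.astype(np.int64))
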