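"""Text preprocessing: tokenization, stop-word removal, Porter stemming.

One document is one video — title and description concatenated.  The
pipeline is the exact composition ``stem ∘ remove_stopwords ∘ tokenize``;
each step is also exposed on its own.  Lemmatization is a configurable
hook that defaults to the identity, since stemming already maps
inflectional variants (vape / vaped / vaping) onto a common base form.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from ._porter import porter_stem
from ._stopwords import STOPWORDS

logger = logging.getLogger(__name__)

_ALPHA = re.compile(r"[a-z]+")
_ALNUM = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class ProcessedDoc:
    """A video's text reduced to an ordered list of lowercase stems."""

    video_id: str
    tokens: tuple[str, ...]


def tokenize(text: str, keep_numbers: bool = False) -> list[str]:
    """Split *text* into lowercase tokens, dropping punctuation.

    Text is NFKC-normalized and diacritics are stripped before matching, so
    scraped dialectal spellings ("vapé") fold onto plain ASCII.  Purely
    numeric tokens are dropped under the default policy; pass
    ``keep_numbers=True`` to retain alphanumeric runs.
    """
    if not text:
        return []
    text = unicodedata.normalize("NFKC", text)
    text = "".join(c for c in unicodedata.normalize("NFD", text)
                   if not unicodedata.combining(c))
    pattern = _ALNUM if keep_numbers else _ALPHA
    return pattern.findall(text.lower())


def remove_stopwords(tokens: Iterable[str],
                     stoplist: frozenset[str] = STOPWORDS) -> list[str]:
    """Order-preserving filter of *tokens* against *stoplist*."""
    return [t for t in tokens if t not in stoplist]


def preprocess_text(text: str,
                    stoplist: frozenset[str] = STOPWORDS,
                    lemmatizer: Callable[[str], str] | None = None,
                    keep_numbers: bool = False) -> list[str]:
    """tokenize → stop-word filter → Porter stem (→ optional lemmatizer)."""
    stems = [porter_stem(t)
             for t in remove_stopwords(tokenize(text, keep_numbers), stoplist)]
    if lemmatizer is not None:
        stems = [lemmatizer(s) for s in stems]
    return stems


def preprocess_corpus(pool: Sequence,
                      stoplist: frozenset[str] = STOPWORDS,
                      lemmatizer: Callable[[str], str] | None = None,
                      keep_numbers: bool = False) -> list[ProcessedDoc]:
    """Preprocess every video in *pool* (title + description per document).

    Videos whose text is entirely stop words (or empty after tokenization)
    yield an empty token list and are flagged in the log; downstream stages
    exclude them from vector-space operations.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    docs = []
    for video in pool:
        tokens = preprocess_text(f"{video.title} {video.description}",
                                 stoplist, lemmatizer, keep_numbers)
        if not tokens:
            logger.warning("video %s has no tokens after preprocessing",
                           video.video_id)
        docs.append(ProcessedDoc(video.video_id, tuple(tokens)))
    return docs


def write_corpus_jsonl(docs: Sequence[ProcessedDoc], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps({"video_id": doc.video_id,
                                 "tokens": list(doc.tokens)}) + "\n")


def read_corpus_jsonl(path) -> list[ProcessedDoc]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                docs.append(ProcessedDoc(rec["video_id"], tuple(rec["tokens"])))
    return docs
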