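"""TF-IDF contrast of enriched-term lists from two (or more) screens.

Each screen's significantly enriched terms (e.g. gene-set names like
``GOBP_LYSOSOME_ORGANIZATION``) are concatenated into one document: the
ontology prefix (first underscore token) is dropped, underscores become
spaces, words are lower-cased.  Word scores are

    TF-IDF(t, d) = TF(t, d) x (log10(D / DF(t)) + 1)

with TF the word count in document d, DF the number of documents
containing the word, and D the number of documents (two when contrasting
two screens).  For log2 score ratios between documents, zero scores are
replaced by half the smallest positive score of that document, so a word
unique to one screen gets a large but finite ratio.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ciber.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TermDocument:
    label: str
    words: Counter


def build_documents(term_lists: Mapping[str, Sequence[str]]) -> list[TermDocument]:
    """One document per screen from its enriched-term list.

    Per term: replace underscores with spaces, drop the first word (the
    ontology prefix), lower-case and add the remaining words to the
    document's multiset.  Terms that are empty after prefix removal are
    skipped with a warning.
    """
    documents = []
    for label, terms in term_lists.items():
        words: Counter = Counter()
        for term in terms:
            tokens = term.strip().replace("_", " ").lower().split()
            if len(tokens) < 2:
                logger.warning("document %r: term %r is empty after prefix removal; skipped", label, term)
                continue
            words.update(tokens[1:])
        documents.append(TermDocument(label=label, words=words))
    return documents


def tfidf(documents: Sequence[TermDocument]) -> pd.DataFrame:
    """Word x document TF-IDF matrix.

    Returns a DataFrame indexed by word with one score column per document
    label, plus ``df`` (document frequency).  Scores are zero exactly where
    TF is zero, since the IDF factor log10(D/DF) + 1 is positive for
    1 <= DF <= D < 10*D.
    """
    if not documents:
        raise ValidationError("need at least one document")
    labels = [d.label for d in documents]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"document labels are not unique: {labels}")
    vocabulary = sorted(set().union(*(d.words.keys() for d in documents)))
    if not vocabulary:
        raise ValidationError("all documents are empty")
    n_docs = len(documents)

    tf = pd.DataFrame(
        {d.label: [d.words.get(w, 0) for w in vocabulary] for d in documents},
        index=pd.Index(vocabulary, name="word"),
        dtype=float,
    )
    df = (tf > 0).sum(axis=1)
    idf = np.log10(n_docs / df) + 1.0
    scores = tf.mul(idf, axis=0)
    scores["df"] = df
    return scores


def log2_ratio(scores: pd.DataFrame, doc_a: str, doc_b: str) -> pd.Series:
    """Per-word log2(score_a / score_b) with zero-protection.

    Zero scores in a document are replaced by (that document's minimal
    positive score) / 2 before taking the ratio; a document with no
    positive score at all is an error.
    """
    for doc in (doc_a, doc_b):
        if doc not in scores.columns:
            raise ValidationError(f"no document named {doc!r} in the score matrix")
    a = scores[doc_a].to_numpy(dtype=float).copy()
    b = scores[doc_b].to_numpy(dtype=float).copy()
    for name, values in ((doc_a, a), (doc_b, b)):
        positive = values[values > 0]
        if positive.size == 0:
            raise ValidationError(f"document {name!r} has no positive TF-IDF score")
        values[values == 0] = positive.min() / 2.0
    return pd.Series(np.log2(a / b), index=scores.index, name=f"log2_{doc_a}_vs_{doc_b}")


def read_term_list(path) -> list[str]:
    """One term per line; blank lines and '#' comments ignored."""
    terms = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                terms.append(line)
    return terms
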