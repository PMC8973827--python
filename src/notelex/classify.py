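"""Three-way context classification of descriptor-containing sentences.

A matched descriptor is only evidence of stigmatizing language when it
is used *negatively about the patient*.  Each descriptor-containing
sentence therefore gets one of three labels:

``negative``
    the descriptor characterizes the patient or their behaviour
    unfavourably ("has been poorly compliant");
``positive``
    the descriptor is used favourably ("is calm and cooperative with
    interview");
``out_of_context``
    the descriptor is applied to something other than the patient
    ("using a non-compliant balloon", "multi-drug resistant organisms").

Two classifiers are provided: a deterministic rule system
(:func:`classify_rule_based`) built from fused/free-standing negation
cues and non-patient-entity cue words, and a trainable multinomial
logistic model over hit-windowed n-gram features
(:class:`ContextClassifier`), evaluated with macro-averaged F1 on a
held-out split as is standard for imbalanced multi-class text tasks.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .lexicon import Descriptor, DescriptorHit, build_default_lexicon, match_descriptors

__all__ = [
    "NEGATIVE",
    "POSITIVE",
    "OUT_OF_CONTEXT",
    "CONTEXT_LABELS",
    "LabeledSentence",
    "EvalMetrics",
    "classify_rule_based",
    "featurize",
    "ContextClassifier",
    "train_classifier",
    "predict",
]

NEGATIVE = "negative"
POSITIVE = "positive"
OUT_OF_CONTEXT = "out_of_context"

#: Admissible labels, in tie-break priority order (negative wins ties).
CONTEXT_LABELS = (NEGATIVE, POSITIVE, OUT_OF_CONTEXT)

# Non-patient entities: a descriptor adjacent to one of these refers to
# equipment, supplies or microbes, not the patient.
_ENTITY_CUES = {
    "balloon", "balloons", "bandage", "bandages", "dressing", "dressings",
    "airway", "organism", "organisms", "bacteria", "tourniquet", "valve",
    "catheter",
}
#: Window (in tokens, each side) for entity-cue adjacency.
ENTITY_WINDOW = 2

# Antimicrobial / organism collocates: "resistant" within a few tokens
# of these is microbiology, not patient behaviour.
_MICRO_CUES = {"methicillin", "vancomycin", "drug", "multi", "antibiotic", "mrsa", "vre"}
MICRO_WINDOW = 3

# Free-standing negators scoping a polarity_by_negation descriptor.
_NEGATION_CUES = {"not", "non", "poorly", "never"}
#: Token window (before the hit) for free-standing negation scope.
NEGATION_WINDOW = 4

# Denial cues that flip an inherently negative descriptor to a benign
# reading ("denies feeling angry").
_DENIAL_CUES = {"denies", "denied", "without"}

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class LabeledSentence:
    """A descriptor-containing sentence with its annotated context label."""

    text: str
    hits: tuple[DescriptorHit, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.hits:
            raise ValueError("LabeledSentence requires at least one descriptor hit")
        if self.label not in CONTEXT_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class EvalMetrics:
    """Held-out evaluation of a three-class context classifier."""

    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    per_class_f1: dict[str, float]
    macro_f1: float
    confusion: np.ndarray  # rows = true label, cols = predicted, CONTEXT_LABELS order
    n_test: int

    def to_dict(self) -> dict:
        return {
            "per_class_precision": self.per_class_precision,
            "per_class_recall": self.per_class_recall,
            "per_class_f1": self.per_class_f1,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test,
        }


def _tokens_with_spans(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text.lower())]


def _hit_token_indices(
    tokens: list[tuple[str, int, int]], hit: DescriptorHit
) -> list[int]:
    lo, hi = hit.span
    return [i for i, (_, s, e) in enumerate(tokens) if s < hi and e > lo]


def _classify_hit(tokens: list[tuple[str, int, int]], hit: DescriptorHit) -> str:
    idx = _hit_token_indices(tokens, hit)
    if not idx:  # degenerate: hit not aligned to any token
        return OUT_OF_CONTEXT
    first, last = idx[0], idx[-1]
    window = {
        tokens[i][0]
        for i in range(max(0, first - ENTITY_WINDOW), min(len(tokens), last + 1 + ENTITY_WINDOW))
    }
    if window & _ENTITY_CUES:
        return OUT_OF_CONTEXT
    if hit.descriptor.stem == "resist":
        before = {tokens[i][0] for i in range(max(0, first - MICRO_WINDOW), first)}
        if before & _MICRO_CUES:
            return OUT_OF_CONTEXT

    preceding = [tokens[i][0] for i in range(max(0, first - NEGATION_WINDOW), first)]
    negated = hit.negation_prefix is not None or bool(set(preceding) & _NEGATION_CUES)
    if not negated:  # "no longer compliant"
        negated = any(
            a == "no" and b == "longer" for a, b in zip(preceding, preceding[1:])
        )
    denied = bool(set(preceding) & _DENIAL_CUES)

    if hit.descriptor.polarity_class == "polarity_by_negation":
        return NEGATIVE if negated else POSITIVE
    # inherent_negative: negative unless explicitly denied or negated away
    if denied or negated:
        return POSITIVE
    return NEGATIVE


def classify_rule_based(sentence_text: str, hits: list[DescriptorHit]) -> str:
    """Label a descriptor-containing sentence with the rule system.

    Per hit, in order: out-of-context if a non-patient-entity cue sits
    within ±2 tokens (or a microbiology collocate precedes "resistant");
    otherwise negative/positive by negation state and polarity class.
    A sentence with several hits is negative if any hit is negative,
    else positive if any hit is positive, else out of context.
    """
    if not hits:
        raise ValueError("classify_rule_based requires at least one descriptor hit")
    tokens = _tokens_with_spans(sentence_text)
    labels = [_classify_hit(tokens, h) for h in hits]
    if NEGATIVE in labels:
        return NEGATIVE
    if POSITIVE in labels:
        return POSITIVE
    return OUT_OF_CONTEXT


#: Tokens around each hit (each side) used for n-gram features.
FEATURE_WINDOW = 6


def featurize(sentence_text: str, hits: list[DescriptorHit]) -> list[str]:
    """Extract sparse string features for one sentence.

    Lowercased uni- and bi-grams within ±6 tokens of each hit, plus
    indicators for the descriptor identity, fused negation prefixes and
    cue-list proximity.  Deterministic, so identical sentences always
    map to identical feature multisets.
    """
    tokens = _tokens_with_spans(sentence_text)
    feats: list[str] = []
    for hit in hits:
        idx = _hit_token_indices(tokens, hit)
        first, last = (idx[0], idx[-1]) if idx else (0, -1)
        lo = max(0, first - FEATURE_WINDOW)
        hi = min(len(tokens), last + 1 + FEATURE_WINDOW)
        words = [tokens[i][0] for i in range(lo, hi)]
        feats.extend(words)
        feats.extend(f"{a}_{b}" for a, b in zip(words, words[1:]))
        feats.append(f"DESC={hit.descriptor.term}")
        if hit.negation_prefix is not None:
            feats.append("NEGPREFIX")
            feats.append(f"NEGPREFIX_{hit.descriptor.term}")
        if set(words) & _ENTITY_CUES:
            feats.append("ENTITY_CUE_NEAR")
        if set(words) & _MICRO_CUES and hit.descriptor.stem == "resist":
            feats.append("MICRO_CUE_NEAR")
    return feats


class ContextClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial logistic regression over hit-windowed n-gram features.

    A scikit-learn estimator: ``fit(texts, labels)`` builds the feature
    vocabulary on the training data only and fits an L2-regularized
    multinomial model; ``predict(texts)`` returns context labels with a
    fixed tie-break (negative > positive > out_of_context).  Descriptor
    hits are recomputed from the lexicon, so the classifier consumes
    plain sentence strings.

    Parameters
    ----------
    C : float
        Inverse regularization strength of the logistic model.
    max_iter : int
        LBFGS iteration cap.
    random_state : int
        Seed recorded for provenance; the fit itself is deterministic.
    """

    def __init__(self, C: float = 10.0, max_iter: int = 2000, random_state: int = 0):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def _features(self, texts, hits_list=None) -> list[list[str]]:
        lexicon = getattr(self, "_lexicon", None) or build_default_lexicon()
        self._lexicon = lexicon
        out = []
        for i, text in enumerate(texts):
            hits = hits_list[i] if hits_list is not None else match_descriptors(text, lexicon)
            out.append(featurize(text, list(hits)))
        return out

    def fit(self, X, y, hits_list=None):
        y = np.asarray(y, dtype=object)
        missing = set(CONTEXT_LABELS) - set(y)
        if missing:
            raise ValueError(f"training corpus is missing label(s): {sorted(missing)}")
        feats = self._features(X, hits_list)
        self.vectorizer_ = CountVectorizer(analyzer=lambda doc: doc, lowercase=False)
        M = self.vectorizer_.fit_transform(feats)
        self.model_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.random_state
        )
        self.model_.fit(M, y)
        self.classes_ = np.asarray(CONTEXT_LABELS, dtype=object)
        return self

    def decision_scores(self, X, hits_list=None) -> np.ndarray:
        """Per-class linear scores, columns in CONTEXT_LABELS order."""
        M = self.vectorizer_.transform(self._features(X, hits_list))
        raw = self.model_.decision_function(M)
        if raw.ndim == 1:  # binary edge case, not reachable with 3 classes
            raw = np.column_stack([raw, -raw])
        order = [list(self.model_.classes_).index(lbl) for lbl in CONTEXT_LABELS]
        return raw[:, order]

    def predict(self, X, hits_list=None) -> np.ndarray:
        scores = self.decision_scores(X, hits_list)
        # argmax with fixed priority: on exact ties the earlier label in
        # CONTEXT_LABELS (negative first) wins.
        best = np.zeros(len(scores), dtype=int)
        for j in range(1, scores.shape[1]):
            better = scores[:, j] > scores[np.arange(len(scores)), best]
            best[better] = j
        return np.asarray([CONTEXT_LABELS[j] for j in best], dtype=object)

    # -- flat-file serialization ------------------------------------------

    FORMAT_VERSION = 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": self.FORMAT_VERSION,
            "params": self.get_params(),
            "vocabulary": {k: int(v) for k, v in self.vectorizer_.vocabulary_.items()},
            "classes": list(self.model_.classes_),
            "coef": self.model_.coef_.tolist(),
            "intercept": self.model_.intercept_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ContextClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError("unsupported classifier file version")
        est = cls(**payload["params"])
        vocab = {k: int(v) for k, v in payload["vocabulary"].items()}
        est.vectorizer_ = CountVectorizer(
            analyzer=lambda doc: doc, lowercase=False, vocabulary=vocab
        )
        model = LogisticRegression(C=est.C, max_iter=est.max_iter, random_state=est.random_state)
        model.classes_ = np.asarray(payload["classes"], dtype=object)
        model.coef_ = np.asarray(payload["coef"])
        model.intercept_ = np.asarray(payload["intercept"])
        model.n_features_in_ = model.coef_.shape[1]
        est.model_ = model
        est.classes_ = np.asarray(CONTEXT_LABELS, dtype=object)
        return est


def train_classifier(
    corpus: list[LabeledSentence],
    split_fraction: float = 2 / 3,
    seed: int = 0,
    **estimator_params,
) -> tuple[ContextClassifier, EvalMetrics]:
    """Train on a stratified ``split_fraction`` of the corpus and
    evaluate on the held-out remainder.

    Mirrors the standard protocol for this task: two-thirds of the
    labeled sentences train the model, the remaining third is scored
    with per-class precision/recall/F1 and their unweighted (macro)
    mean.
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    texts = [s.text for s in corpus]
    labels = [s.label for s in corpus]
    missing = set(CONTEXT_LABELS) - set(labels)
    if missing:
        raise ValueError(f"macro-F1 undefined: corpus missing label(s) {sorted(missing)}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        texts, labels, train_size=split_fraction, stratify=labels, random_state=seed
    )
    est = ContextClassifier(random_state=seed, **estimator_params).fit(X_tr, y_tr)
    y_pred = est.predict(X_te)
    return est, evaluate_predictions(y_te, y_pred)


def evaluate_predictions(y_true, y_pred) -> EvalMetrics:
    labels = list(CONTEXT_LABELS)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    return EvalMetrics(
        per_class_precision=dict(zip(labels, prec.tolist())),
        per_class_recall=dict(zip(labels, rec.tolist())),
        per_class_f1=dict(zip(labels, f1.tolist())),
        macro_f1=float(np.mean(f1)),
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
        n_test=len(list(y_true)),
    )


def predict(model: ContextClassifier, sentence_text: str, hits=None) -> str:
    """Label one sentence with a trained model (pure function of inputs)."""
    hits_list = [tuple(hits)] if hits is not None else None
    return str(model.predict([sentence_text], hits_list)[0])
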