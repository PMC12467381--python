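"""Adverse-effect term normalisation and precision/recall evaluation.

Free-text adverse-effect terms — from ground-truth side-effect resources and
from the screen's predictions alike — are mapped onto a shared
preferred-term vocabulary before comparison, so that spelling variants and
synonyms of the same clinical concept count as matches.  The normaliser is
deterministic: text clean-up, exact synonym lookup, then nearest-term edit
distance within a length-relative budget; it sits behind a small interface
so a learned normaliser can be plugged in.  Evaluation is set-based
precision/recall over normalised preferred terms.
"""

from __future__ import annotations

import dataclasses
import string
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .knowledge import AnnotationSet, levenshtein
from .screening import InteractionScore

__all__ = [
    "TermDictionary",
    "NormalizedTermSet",
    "EvaluationResult",
    "Normalizer",
    "EditDistanceNormalizer",
    "normalize_term",
    "normalize_term_set",
    "predict_adverse_effect_terms",
    "precision_recall",
    "read_term_dictionary",
    "read_ground_truth",
]

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def clean_text(raw: str) -> str:
    """Lower-case, trim, strip punctuation, collapse whitespace."""
    return " ".join(str(raw).lower().translate(_PUNCT_TABLE).split())


@dataclasses.dataclass
class TermDictionary:
    """Preferred adverse-event terms plus a synonym -> preferred map."""

    preferred_terms: list[str]
    synonyms: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.preferred_terms = sorted({clean_text(t) for t in self.preferred_terms})
        pref = set(self.preferred_terms)
        cleaned = {}
        for variant, target in self.synonyms.items():
            t = clean_text(target)
            if t not in pref:
                raise ValueError(
                    f"synonym {variant!r} maps to unlisted preferred term {target!r}"
                )
            cleaned[clean_text(variant)] = t
        self.synonyms = cleaned

    def lookup(self, cleaned: str) -> str | None:
        if cleaned in self.synonyms:
            return self.synonyms[cleaned]
        if cleaned in set(self.preferred_terms):
            return cleaned
        return None

    def candidates(self) -> list[tuple[str, str]]:
        """(surface form, preferred term) pairs for fuzzy matching."""
        pairs = [(t, t) for t in self.preferred_terms]
        pairs.extend(sorted(self.synonyms.items()))
        return pairs


@dataclasses.dataclass
class NormalizedTermSet:
    """A compound's adverse-effect terms after preferred-term mapping."""

    compound_id: str
    preferred: set[str]
    unmapped: list[tuple[str, str]] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class EvaluationResult:
    """Set-based precision/recall with per-term diagnostics.

    ``precision`` is None when nothing was predicted, ``recall`` is None when
    the truth set is empty — undefined ratios stay absent rather than being
    zeroed, to keep averages honest.
    """

    compound_id: str
    precision: float | None
    recall: float | None
    true_positives: set[str]
    false_positives: set[str]
    false_negatives: set[str]


class Normalizer(Protocol):
    """Anything that maps a raw term to a preferred term or None."""

    def __call__(self, raw: str) -> str | None: ...


@dataclasses.dataclass
class EditDistanceNormalizer:
    """The default deterministic normaliser.

    Pipeline: text clean-up; exact synonym/preferred lookup; otherwise the
    nearest dictionary surface form by Levenshtein distance, accepted when
    the distance is at most ``max_edit_fraction`` of the longer string.
    Ties break on (distance, surface form).
    """

    dictionary: TermDictionary
    max_edit_fraction: float = 0.2

    def __call__(self, raw: str) -> str | None:
        cleaned = clean_text(raw)
        if not cleaned:
            return None
        exact = self.dictionary.lookup(cleaned)
        if exact is not None:
            return exact
        best: tuple[int, str, str] | None = None
        for surface, preferred in self.dictionary.candidates():
            d = levenshtein(cleaned, surface)
            if best is None or (d, surface) < best[:2]:
                best = (d, surface, preferred)
        if best is None:
            return None
        d, surface, preferred = best
        if d <= self.max_edit_fraction * max(len(cleaned), len(surface)):
            return preferred
        return None


def normalize_term(
    raw: str, dictionary: TermDictionary, max_edit_fraction: float = 0.2
) -> str | None:
    """Map one raw term to its preferred term, or None when unmappable."""
    if not dictionary.preferred_terms:
        raise ValueError("empty term dictionary")
    return EditDistanceNormalizer(dictionary, max_edit_fraction)(raw)


def normalize_term_set(
    compound_id: str,
    raw_terms: Sequence[str],
    normalizer: Normalizer,
) -> NormalizedTermSet:
    """Normalise a list of raw terms, recording unmappable ones with reasons."""
    preferred: set[str] = set()
    unmapped: list[tuple[str, str]] = []
    for raw in raw_terms:
        hit = normalizer(raw)
        if hit is None:
            unmapped.append((raw, "no dictionary match within edit budget"))
        else:
            preferred.add(hit)
    return NormalizedTermSet(compound_id, preferred, unmapped)


def predict_adverse_effect_terms(
    compound_id: str,
    scores: Sequence[InteractionScore],
    annotations: AnnotationSet,
    control_scores: Sequence[float],
    threshold_quantile: float = 0.05,
) -> NormalizedTermSet:
    """Raw (pre-normalisation) predicted term set for one compound.

    A target counts as a predicted interactor when its distance lies strictly
    below the ``threshold_quantile`` quantile of the control-protein
    distances; the prediction is the union of the interactors'
    adverse-effect terms.
    """
    ctl = np.asarray(control_scores, float)
    if ctl.size == 0:
        raise ValueError("empty control distance list")
    threshold = float(np.quantile(ctl, threshold_quantile))
    by_tid = {r.target_id: r for r in annotations.records}
    terms: list[str] = []
    for s in scores:
        if s.compound_id != compound_id:
            continue
        if s.distance < threshold and s.target_id in by_tid:
            terms.extend(by_tid[s.target_id].ae_terms)
    # raw set: dedup exact strings only; semantic dedup happens in normalisation
    return NormalizedTermSet(compound_id=compound_id, preferred=set(terms))


def precision_recall(
    predicted: NormalizedTermSet, truth: NormalizedTermSet
) -> EvaluationResult:
    """Set precision/recall of predicted vs ground-truth preferred terms."""
    tp = predicted.preferred & truth.preferred
    fp = predicted.preferred - truth.preferred
    fn = truth.preferred - predicted.preferred
    precision = len(tp) / len(predicted.preferred) if predicted.preferred else None
    recall = len(tp) / len(truth.preferred) if truth.preferred else None
    return EvaluationResult(
        compound_id=predicted.compound_id,
        precision=precision,
        recall=recall,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_term_dictionary(path: str | Path) -> TermDictionary:
    """CSV with columns preferred_term, synonym (one row per variant).

    A row with an empty synonym declares a preferred term with no variants.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    need = {"preferred_term", "synonym"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    preferred = sorted(set(df["preferred_term"].astype(str)))
    synonyms: dict[str, str] = {}
    for _, row in df.iterrows():
        syn = row["synonym"]
        if isinstance(syn, str) and syn.strip():
            synonyms[syn] = str(row["preferred_term"])
    return TermDictionary(preferred_terms=preferred, synonyms=synonyms)


def read_ground_truth(path: str | Path) -> dict[str, list[str]]:
    """CSV with columns compound_id, ae_term -> per-compound raw term lists."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    need = {"compound_id", "ae_term"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    out: dict[str, list[str]] = {}
    for cid, grp in df.groupby("compound_id", sort=True):
        out[str(cid)] = [str(t) for t in grp["ae_term"]]
    return out
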