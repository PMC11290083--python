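"""Contextual disambiguation of dictionary candidates.

Candidates are scored with a sentence-pair task: the mention's context title
is embedded once, each *candidate title* (the title with the mention span
replaced by the candidate entity's preferred name) is embedded once, and the
candidate with maximum cosine similarity wins.  The embedder is a contract
(`embed(text) -> vector`), with three bundled backends:

* :class:`StubEmbedder` — realizes externally supplied cosine scores, used
  to replay worked examples through the real argmax path;
* the deterministic trigram embedder from :mod:`chemnorm.fixtures` — no
  model download, suitable for tests and desk-scale runs;
* :class:`TransformerEmbedder` — optional mean-pooled transformer backend
  (requires the ``transformer`` extra), reproducing the sentence-embedding
  recipe (mean pooling, 512-token truncation) with any trained checkpoint.

A Levenshtein-ratio baseline (`fuzzy_disambiguate`) and a cosine-threshold
flagging step (`apply_threshold`) complete the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Protocol, runtime_checkable

import numpy as np

from .errors import ChemnormError, ValidationError
from .matcher import Candidate, CandidateSet, MatchLevel, chebi_num, levenshtein_ratio
from .ontology_io import Mention, Ontology

METHOD_EXACT = "exact"
METHOD_RELAXED = "relaxed"
METHOD_PUBCHEM = "pubchem"
METHOD_FUZZY_BASELINE = "fuzzy-baseline"
METHOD_EMBEDDER = "embedder"

_LEVEL_METHOD = {
    MatchLevel.EXACT_NAME: METHOD_EXACT,
    MatchLevel.EXACT_SYNONYM: METHOD_EXACT,
    MatchLevel.RELAXED_CHEBI: METHOD_RELAXED,
    MatchLevel.EXACT_PUBCHEM: METHOD_PUBCHEM,
    MatchLevel.RELAXED_PUBCHEM: METHOD_PUBCHEM,
    MatchLevel.FUZZY: METHOD_FUZZY_BASELINE,
}


@runtime_checkable
class Embedder(Protocol):
    """Deterministic text -> fixed-dimension vector contract."""

    dimension: int
    identifier: str

    def embed(self, text: str) -> np.ndarray: ...


class StubEmbedder:
    """Embedder that realizes a prescribed cosine score per text.

    The reference text maps to the first basis vector; any text with an
    injected score ``s`` maps to ``(s, sqrt(1 - s^2))`` so that its cosine
    against the reference is exactly ``s``.  Unknown texts default to 0.
    """

    dimension = 2

    def __init__(self, reference: str, scores: dict[str, float]):
        self.identifier = "stub"
        self.reference = reference
        self.scores = dict(scores)

    def embed(self, text: str) -> np.ndarray:
        if text == self.reference:
            return np.array([1.0, 0.0])
        s = float(self.scores.get(text, 0.0))
        if not -1.0 <= s <= 1.0:
            raise ValidationError(f"injected score {s} outside [-1, 1]")
        return np.array([s, math.sqrt(max(0.0, 1.0 - s * s))])


class TransformerEmbedder:
    """Mean-pooled transformer sentence embedder (optional heavy backend).

    Wraps any Hugging Face checkpoint: tokens are truncated at ``max_tokens``
    and the final hidden states are mean-pooled over the attention mask.
    Imports ``transformers``/``torch`` lazily so the core package carries no
    deep-learning dependency.
    """

    def __init__(self, model_name: str, max_tokens: int = 512):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ChemnormError(
                "TransformerEmbedder requires the 'transformer' extra"
            ) from exc
        self.identifier = f"transformer:{model_name}"
        self.max_tokens = max_tokens
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()
        self.dimension = int(self._model.config.hidden_size)

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - optional extra
        import torch

        enc = self._tokenizer(
            text, truncation=True, max_length=self.max_tokens, return_tensors="pt"
        )
        with torch.no_grad():
            hidden = self._model(**enc).last_hidden_state[0]
        mask = enc["attention_mask"][0].unsqueeze(-1)
        pooled = (hidden * mask).sum(0) / mask.sum()
        return pooled.numpy()


@dataclass(frozen=True)
class ScoredCandidate:
    chebi_id: str
    candidate_title: str
    cosine: float
    source: int = 0


@dataclass
class NormalizationResult:
    """Final link decision for one mention."""

    mention: Mention
    chebi_id: Optional[str]
    method: str
    score: Optional[float] = None
    flagged_below_threshold: bool = False
    level: MatchLevel = MatchLevel.UNMATCHED
    needs_disambiguation: bool = False


def make_candidate_title(title: str, span: tuple[int, int], candidate_name: str) -> str:
    """Title with the mention span spliced out and the candidate name spliced in."""
    s, e = span
    if not (0 <= s <= e <= len(title)):
        raise ValidationError(f"span {span} invalid for title of length {len(title)}")
    return title[:s] + candidate_name + title[e:]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """``u.v / (|u||v|)`` clamped to [-1, 1]; zero vectors signal a degenerate embedding."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValidationError("cosine undefined for a zero vector (degenerate embedding)")
    return float(np.clip(float(np.dot(u, v)) / (nu * nv), -1.0, 1.0))


def _candidate_key(sc: ScoredCandidate) -> tuple:
    return (-sc.cosine, sc.source, chebi_num(sc.chebi_id))


def rank_candidates(
    title: str,
    mention: Mention,
    candidates: CandidateSet,
    embedder: Embedder,
    ontology: Optional[Ontology] = None,
) -> tuple[NormalizationResult, list[ScoredCandidate]]:
    """Embed title and candidate titles, select the argmax-cosine candidate.

    Ties break toward the earlier surface source, then the lower numeric
    accession, so candidate order never affects the outcome.  All scored
    candidates are returned for audit.
    """
    if not candidates.candidates:
        raise ValidationError("rank_candidates requires at least one candidate")
    try:
        v_title = embedder.embed(title)
    except Exception as exc:
        raise ChemnormError(f"embedder failed on the context title: {exc}") from exc
    scored: list[ScoredCandidate] = []
    for cand in candidates.candidates:
        name = ontology.name_of(cand.chebi_id) if ontology is not None else None
        cand_title = make_candidate_title(title, mention.span, name or cand.surface)
        try:
            v_cand = embedder.embed(cand_title)
        except Exception as exc:
            raise ChemnormError(f"embedder failed on candidate {cand.chebi_id}: {exc}") from exc
        scored.append(
            ScoredCandidate(cand.chebi_id, cand_title, cosine(v_title, v_cand), cand.source)
        )
    winner = min(scored, key=_candidate_key)
    result = NormalizationResult(
        mention=mention,
        chebi_id=winner.chebi_id,
        method=METHOD_EMBEDDER,
        score=winner.cosine,
        level=candidates.level,
        needs_disambiguation=candidates.needs_disambiguation,
    )
    return result, scored


def fuzzy_disambiguate(mention: Mention, candidates: CandidateSet) -> NormalizationResult:
    """Baseline: keep the candidate with the largest Levenshtein ratio."""
    if not candidates.candidates:
        raise ValidationError("fuzzy_disambiguate requires at least one candidate")
    text = (mention.lookup_text or mention.text).lower()

    def key(c: Candidate) -> tuple:
        r = c.ratio if c.ratio is not None else levenshtein_ratio(text, c.surface.lower())
        return (-r, c.source, chebi_num(c.chebi_id))

    best = min(candidates.candidates, key=key)
    score = best.ratio if best.ratio is not None else levenshtein_ratio(text, best.surface.lower())
    return NormalizationResult(
        mention=mention,
        chebi_id=best.chebi_id,
        method=METHOD_FUZZY_BASELINE,
        score=float(score),
        level=candidates.level,
        needs_disambiguation=candidates.needs_disambiguation,
    )


def apply_threshold(result: NormalizationResult, tau: float) -> NormalizationResult:
    """Flag embedder links scoring below ``tau``; the link itself is retained.

    Reporting decides whether a flagged link counts as "no entity" — the
    evaluation module interprets the flag when sweeping thresholds.
    """
    if result.method != METHOD_EMBEDDER:
        return result
    return replace(result, flagged_below_threshold=(result.score is not None and result.score < tau))


def resolve(
    candidates: CandidateSet,
    ontology: Optional[Ontology] = None,
    embedder: Optional[Embedder] = None,
    tau: float = 0.0,
) -> NormalizationResult:
    """Turn one candidate set into a final decision.

    Unambiguous sets link directly with the method named after their level;
    ambiguous sets go through the embedder when one is supplied, otherwise
    through the fuzzy-ratio baseline.
    """
    mention = candidates.mention
    if candidates.level is MatchLevel.UNMATCHED or not candidates.candidates:
        return NormalizationResult(
            mention=mention, chebi_id=None, method="unmatched", level=MatchLevel.UNMATCHED
        )
    if not candidates.needs_disambiguation:
        cand = candidates.candidates[0]
        return NormalizationResult(
            mention=mention,
            chebi_id=cand.chebi_id,
            method=_LEVEL_METHOD[candidates.level],
            score=float(cand.ratio) if cand.ratio is not None else None,
            level=candidates.level,
            needs_disambiguation=False,
        )
    if embedder is None:
        return fuzzy_disambiguate(mention, candidates)
    result, _scored = rank_candidates(mention.context, mention, candidates, embedder, ontology)
    return apply_threshold(result, tau)
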