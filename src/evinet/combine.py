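"""Probabilistic integration of evidence scores.

Two combination problems share one algebra:

* **Across channels** — independent evidence channels are integrated into a
  combined association confidence by (i) removing the prior ``p0`` from each
  channel score, ``s' = max(0, (s - p0) / (1 - p0))``, (ii) combining the
  corrected scores with a noisy-OR, ``S = 1 - prod(1 - s'_c)``, and (iii)
  re-adding the prior, ``S_final = S + p0 * (1 - S)``. With ``p0 = 0`` this
  is a plain noisy-OR; a channel scoring exactly at the prior contributes
  nothing.

* **Within/across documents** — sentence- or document-level physical
  interaction probabilities ``p_i`` are pooled relative to a sentence prior
  ``p*`` through::

      (1 - p) = (1 - p*) * prod_i (1 - p_i) / (1 - p*)

  Evidence below the prior pulls ``p`` below ``p*`` exactly as the algebra
  dictates; only the final result is clipped to ``[0, 1]``. The same
  functional form is applied first within a document (over sentences) and
  then across documents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

from .core import CHANNELS, DataError, validate_channel


@dataclass
class CombineConfig:
    """Configuration for channel integration.

    prior
        Probability ``p0 in [0, 1)`` that a random pair is associated.
    channels_enabled
        Channels taken into account; ``None`` enables all.
    """

    prior: float = 0.0
    channels_enabled: Optional[Set[str]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.prior < 1.0):
            raise DataError(f"prior must be in [0, 1), got {self.prior}")
        if self.channels_enabled is not None:
            self.channels_enabled = {validate_channel(c) for c in self.channels_enabled}

    def enabled(self, channel: str) -> bool:
        return self.channels_enabled is None or channel in self.channels_enabled


@dataclass
class DocumentEvidence:
    """Per-document physical-interaction probabilities for one protein pair."""

    pair: Tuple[str, str]
    per_document: Sequence[float] = field(default_factory=list)
    sentence_prior: float = 0.0

    def __post_init__(self) -> None:
        _check_probs(self.per_document, self.sentence_prior)


def prior_correct(s: float, p0: float) -> float:
    """Remove the prior from a raw channel score: ``max(0, (s - p0)/(1 - p0))``."""
    if not (0.0 <= p0 < 1.0):
        raise DataError(f"prior must be in [0, 1), got {p0}")
    if not (0.0 <= s <= 1.0):
        raise DataError(f"score must be in [0, 1], got {s}")
    return max(0.0, (s - p0) / (1.0 - p0))


def combine_channels(scores: Dict[str, float], cfg: Optional[CombineConfig] = None) -> float:
    """Integrate per-channel scores into a combined score.

    Returns ``p0`` when no enabled channel exceeds the prior. Unknown channel
    ids are an error; disabled channels are ignored.
    """
    if cfg is None:
        cfg = CombineConfig()
    p0 = cfg.prior
    survive = 1.0
    for channel, score in scores.items():
        validate_channel(channel)
        if not cfg.enabled(channel):
            continue
        survive *= 1.0 - prior_correct(score, p0)
    combined = 1.0 - survive
    return combined + p0 * (1.0 - combined)


def _check_probs(probs: Iterable[float], prior: float) -> None:
    if not (0.0 <= prior < 1.0):
        raise DataError(f"sentence prior must be in [0, 1), got {prior}")
    for p in probs:
        if not (0.0 <= p < 1.0):
            raise DataError(f"evidence probability must be in [0, 1), got {p}")


def _pool(probs: Sequence[float], prior: float) -> float:
    """Apply ``(1 - p) = (1 - p*) * prod (1 - p_i)/(1 - p*)`` and clip to [0, 1]."""
    _check_probs(probs, prior)
    survive = 1.0 - prior
    for p_i in probs:
        survive *= (1.0 - p_i) / (1.0 - prior)
    return min(1.0, max(0.0, 1.0 - survive))


def combine_within_document(sentence_probs: Sequence[float], sentence_prior: float) -> float:
    """Pool sentence-level probabilities into a single per-document probability.

    An empty sentence list carries no evidence and returns the prior.
    """
    return _pool(sentence_probs, sentence_prior)


def combine_across_documents(ev: DocumentEvidence) -> float:
    """Pool per-document probabilities into one probability for the pair."""
    return _pool(ev.per_document, ev.sentence_prior)


def combine_network(net, cfg: Optional[CombineConfig] = None) -> None:
    """Recompute the combined score of every edge of a network in place."""
    for rec in net.edges():
        rec.combined = combine_channels(rec.channel_scores, cfg)
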