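"""Functional-consequence calls: predictor consensus and stability class.

Missense variants are kept only when at least ``min_damaging`` of the
nine structure/homology-based predictor tools call them damaging
(consensus voting). Protein-stability impact is classified from the
predicted folding free-energy change upon substitution: a variant is
destabilizing when ΔΔG < −0.5 kcal/mol (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_model import AnnotationRecord, DAMAGING

__all__ = [
    "StabilityCall",
    "damaging_vote",
    "classify_stability",
    "destabilizing_fraction",
    "passes_functional_consensus",
    "DDG_DESTABILIZING_THRESHOLD",
]

DDG_DESTABILIZING_THRESHOLD = -0.5  # kcal/mol, strict

# Effects that alter the protein bluntly enough that the missense
# predictors do not apply; they pass the consensus step unconditionally.
_TRUNCATING_EFFECTS = frozenset(
    {"stop_gain", "frameshift_indel", "splicing", "inframe_indel"}
)


@dataclass(frozen=True)
class StabilityCall:
    """ΔΔG-based protein-stability classification of one variant."""

    ddg: Optional[float]
    label: str  # destabilizing | non_destabilizing | not_applicable


def damaging_vote(predictor_calls: Sequence[str], min_damaging: int = 4) -> bool:
    """Consensus vote over the 9 predictor slots.

    A missing prediction counts against the vote (conservative): only
    explicit damaging calls contribute.
    """
    if len(predictor_calls) != 9:
        raise ValueError(
            f"exactly 9 predictor slots required, got {len(predictor_calls)}"
        )
    return sum(1 for call in predictor_calls if call == DAMAGING) >= min_damaging


def classify_stability(ddg: Optional[float]) -> StabilityCall:
    """Threshold classification: destabilizing iff ΔΔG < −0.5 kcal/mol.

    ``ddg=None`` (no prediction, e.g. a non-missense variant) maps to
    ``not_applicable``; the boundary value −0.5 itself is
    ``non_destabilizing`` (strict inequality).
    """
    if ddg is None:
        return StabilityCall(None, "not_applicable")
    if ddg < DDG_DESTABILIZING_THRESHOLD:
        return StabilityCall(ddg, "destabilizing")
    return StabilityCall(ddg, "non_destabilizing")


def destabilizing_fraction(calls: Iterable[StabilityCall]) -> tuple[int, int]:
    """(k, n): destabilizing count over applicable (ΔΔG-bearing) count."""
    k = n = 0
    for call in calls:
        if call.label == "not_applicable":
            continue
        n += 1
        if call.label == "destabilizing":
            k += 1
    return k, n


def passes_functional_consensus(
    annotation: AnnotationRecord, min_damaging: int = 4
) -> bool:
    """Whether a retained variant clears the functional-consequence step.

    Missense variants require the 4-of-9 predictor consensus; truncating
    and splice-disrupting changes pass unconditionally (the predictors
    only score amino-acid substitutions); anything else fails.
    """
    if annotation.effect == "missense":
        return damaging_vote(annotation.predictor_calls, min_damaging)
    return annotation.effect in _TRUNCATING_EFFECTS
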