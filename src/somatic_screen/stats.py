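"""Cohort-level mutation statistics.

Covers the descriptive layer of the analysis: transition/transversion
spectrum with reverse-complement-collapsed six-class substitution
counts, per-sample mutation burden (counts and rates per megabase),
the sample-collapsed gene recurrence matrix, targeted-panel
construction, and the immunohistochemical H-score.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_model import VariantCall

__all__ = [
    "SpectrumSummary",
    "BurdenSummary",
    "RecurrenceMatrix",
    "classify_substitution",
    "spectrum_summary",
    "mutation_burden",
    "recurrence",
    "build_panel",
    "h_score",
]

_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a ref→alt change as transition / transversion / not_snv.

    Transitions are the purine↔purine and pyrimidine↔pyrimidine
    exchanges (A↔G, C↔T); every other single-base change is a
    transversion; multi-base alleles (indels) are not SNVs.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return "not_snv"
    if (ref, alt) in _TRANSITIONS:
        return "transition"
    return "transversion"


def _six_class(ref: str, alt: str) -> str:
    # Collapse onto pyrimidine reference (community convention).
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class SpectrumSummary:
    """Substitution-spectrum counts for a set of SNVs."""

    ti_count: int
    tv_count: int
    ratio: Optional[float]  # None when no transversions observed
    ratio_truncated: Optional[float]  # one decimal, truncated (printed style)
    class_counts: dict[str, int]
    gc_targeted_fraction: float

    @property
    def total_snvs(self) -> int:
        return self.ti_count + self.tv_count


def spectrum_summary(calls: Iterable[VariantCall]) -> SpectrumSummary:
    """Ti/Tv counts, six-class spectrum and G/C-targeting fraction.

    Non-SNV records are ignored. The ratio is additionally reported
    truncated to one decimal, matching how such ratios are customarily
    printed (1676/857 = 1.9557 → 1.9).
    """
    ti = tv = gc = 0
    class_counts = {c: 0 for c in SIX_CLASSES}
    for call in calls:
        ref, alt = call.position.ref, call.position.alt
        kind = classify_substitution(ref, alt)
        if kind == "not_snv":
            continue
        if kind == "transition":
            ti += 1
        else:
            tv += 1
        if ref in ("G", "C"):
            gc += 1
        class_counts[_six_class(ref, alt)] += 1
    if ti + tv == 0:
        raise ValueError("no SNVs in input; spectrum undefined")
    if tv == 0:
        ratio = ratio_trunc = None  # undefined, flagged by None
    else:
        ratio = ti / tv
        ratio_trunc = math.floor(ratio * 10) / 10
    return SpectrumSummary(
        ti_count=ti,
        tv_count=tv,
        ratio=ratio,
        ratio_truncated=ratio_trunc,
        class_counts=class_counts,
        gc_targeted_fraction=gc / (ti + tv),
    )


@dataclass(frozen=True)
class BurdenSummary:
    """Per-sample nonsynonymous mutation burden and per-Mb rates."""

    counts: dict[str, int]
    rates: dict[str, float]
    exome_mb: float
    median_count: float
    count_range: tuple[int, int]
    median_rate: float
    rate_range: tuple[float, float]


def mutation_burden(
    per_sample_counts: Mapping[str, int], exome_mb: float
) -> BurdenSummary:
    """Summarize per-sample counts as counts and rates per megabase.

    ``per_sample_counts`` should already be restricted to retained
    nonsynonymous variants; samples with zero retained variants must be
    present with count 0 to enter the median.
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    if not per_sample_counts:
        raise ValueError("empty cohort")
    counts = dict(per_sample_counts)
    rates = {s: c / exome_mb for s, c in counts.items()}
    values = list(counts.values())
    rate_values = list(rates.values())
    return BurdenSummary(
        counts=counts,
        rates=rates,
        exome_mb=exome_mb,
        median_count=statistics.median(values),
        count_range=(min(values), max(values)),
        median_rate=statistics.median(rate_values),
        rate_range=(min(rate_values), max(rate_values)),
    )


@dataclass
class RecurrenceMatrix:
    """Binary genes × samples matrix, collapsed to one hit per gene/sample."""

    matrix: pd.DataFrame  # index: gene, columns: sample_id, values 0/1
    gene_counts: dict[str, int] = field(default_factory=dict)

    def recurrent_genes(self, min_samples: int = 2) -> list[tuple[str, int]]:
        """Genes mutated in ≥ min_samples samples, by count desc then name."""
        hits = [(g, c) for g, c in self.gene_counts.items() if c >= min_samples]
        return sorted(hits, key=lambda gc: (-gc[1], gc[0]))


def recurrence(
    gene_sample_pairs: Iterable[tuple[str, str]],
    all_samples: Optional[Sequence[str]] = None,
) -> RecurrenceMatrix:
    """Build the sample-collapsed recurrence matrix.

    ``gene_sample_pairs`` yields one (gene, sample_id) per retained
    variant; multiple variants of one gene in one sample collapse to a
    single matrix entry. ``all_samples`` optionally fixes the column
    set (samples with no retained variant appear as all-zero columns).
    """
    hits: set[tuple[str, str]] = set(gene_sample_pairs)
    genes = sorted({g for g, _ in hits})
    samples = list(all_samples) if all_samples is not None else sorted(
        {s for _, s in hits}
    )
    matrix = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for gene, sample in hits:
        if sample in matrix.columns:
            matrix.loc[gene, sample] = 1
    gene_counts = {g: int(matrix.loc[g].sum()) for g in genes}
    return RecurrenceMatrix(matrix=matrix, gene_counts=gene_counts)


def build_panel(wes_genes: Iterable[str], literature_genes: Iterable[str]) -> list[str]:
    """Union a discovery gene set with a disjoint literature add-on set.

    The literature genes are by definition those *not* recorded in the
    discovery screen, so any overlap is a configuration error.
    """
    wes = set(wes_genes)
    lit = set(literature_genes)
    overlap = wes & lit
    if overlap:
        raise ValueError(f"literature genes overlap discovery genes: {sorted(overlap)}")
    return sorted(wes | lit)


def h_score(percent_positive: float, intensity: float) -> float:
    """Semiquantitative immunostaining score: % positive × intensity.

    Percent positive cells in [0, 100], staining intensity in [0, 3];
    the product lies in [0, 300].
    """
    if not 0 <= percent_positive <= 100:
        raise ValueError(f"percent_positive outside [0, 100]: {percent_positive}")
    if not 0 <= intensity <= 3:
        raise ValueError(f"intensity outside [0, 3]: {intensity}")
    return percent_positive * intensity
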