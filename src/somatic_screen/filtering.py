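"""The two somatic-variant filtering cascades, with per-variant tracing.

Discovery (exome) cascade
    Paired tumors require site depth ≥ 10 in both tumor and matched
    normal, tumor VAF > 10% and normal VAF < 3%; tumor-only samples
    require depth > 20 and VAF > 25% (strict inequalities throughout,
    as this cascade's thresholds are exclusive). Candidates are then
    subtracted against a panel of normals, screened against germline
    databases (dbSNP / 1000 Genomes) with a COSMIC rescue, required to
    be in COSMIC, required to show RNA-level concordance when the
    patient was RNA-sequenced, and finally required to have a uniquely
    mapping 41-base flanking context (an exact-match stand-in for BLAT
    multi-mapping detection of captured pseudogenes).

Targeted (deep-panel) cascade
    Caller quality, VAF ≥ 10%, ≥ 3 variant reads (inclusive
    thresholds), 1000 Genomes allele frequency ≤ 1%, COSMIC
    membership, a dbSNP screen with pathogenic/COSMIC exemptions,
    exclusion of synonymous variants and of intronic variants more than
    2 bp from the coding sequence, and subtraction of everything seen
    in the sequenced normal and hyperplastic control samples.

Every gate is evaluated for every variant (no short-circuiting), so the
trace records the full cascade; the verdict is the conjunction and the
rejecting gate is the first failure. Gate order therefore never changes
the retained set, only the attributed rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_model import AnnotationRecord, VariantCall

__all__ = [
    "FilterParams",
    "Gate",
    "FilterTrace",
    "PanelOfNormals",
    "build_pon",
    "wes_discovery_filter",
    "targeted_filter",
    "rna_concordant",
    "context_is_unique",
    "AnnotationMissingError",
]

Key = tuple[str, int, str, str]


class AnnotationMissingError(ValueError):
    """A variant reached a cascade without a joined annotation record."""


@dataclass(frozen=True)
class FilterParams:
    """Every threshold in the two cascades, named and overridable."""

    # exome discovery cascade (strict comparisons)
    wes_min_depth: int = 10  # inclusive: depth >= 10 passes
    wes_tumor_vaf: float = 0.10  # strict: vaf > 0.10
    wes_normal_vaf: float = 0.03  # strict: vaf < 0.03
    wes_unpaired_depth: int = 20  # strict: depth > 20
    wes_unpaired_vaf: float = 0.25  # strict: vaf > 0.25
    # targeted cascade (inclusive comparisons)
    targeted_min_vaf: float = 0.10  # vaf >= 0.10
    targeted_min_alt_reads: int = 3  # alt_reads >= 3
    kg_af_max: float = 0.01  # kg_af <= 0.01
    intronic_max_dist: int = 2  # intronic kept only when <= 2 bp from CDS
    # shared evidence thresholds
    pon_min_alt_reads: int = 2  # "present in a normal" = >= 2 alt reads
    rna_min_alt_reads: int = 2  # RNA concordance = >= 2 alt reads at key
    min_damaging_votes: int = 4  # consensus voting (consequence step)


@dataclass(frozen=True)
class Gate:
    name: str
    passed: bool
    observed: object


@dataclass
class FilterTrace:
    """Ordered record of every gate one variant passed or failed."""

    key: Key
    sample_id: str
    gates: list[Gate] = field(default_factory=list)

    def add(self, name: str, passed: bool, observed: object) -> None:
        self.gates.append(Gate(name, bool(passed), observed))

    @property
    def retained(self) -> bool:
        return all(g.passed for g in self.gates)

    @property
    def final_verdict(self) -> str:
        return "retained" if self.retained else "rejected"

    @property
    def rejecting_gate(self) -> Optional[str]:
        for gate in self.gates:
            if not gate.passed:
                return gate.name
        return None


@dataclass
class PanelOfNormals:
    """Identity keys seen in any normal sample, with provenance."""

    keys: frozenset[Key]
    provenance: dict[Key, tuple[str, ...]]
    min_alt_reads: int

    def __contains__(self, key: Key) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def build_pon(
    normal_tables: Sequence[Sequence[VariantCall]], min_alt_reads: int = 2
) -> PanelOfNormals:
    """Union the variant keys of the normal tables into a panel.

    A variant is a member when at least one normal carries it with
    ``min_alt_reads`` supporting reads; zero-alt coverage rows (site
    observed but reference-only) never enter the panel. Order of the
    tables is irrelevant and rebuilding is idempotent.
    """
    if not normal_tables:
        raise ValueError("build_pon requires at least one normal table")
    provenance: dict[Key, set[str]] = {}
    for table in normal_tables:
        for call in table:
            if call.alt_reads >= min_alt_reads:
                provenance.setdefault(call.key, set()).add(call.sample_id)
    return PanelOfNormals(
        keys=frozenset(provenance),
        provenance={k: tuple(sorted(v)) for k, v in provenance.items()},
        min_alt_reads=min_alt_reads,
    )


def rna_concordant(
    key: Key, rna_table: Iterable[VariantCall], min_alt_reads: int = 2
) -> bool:
    """True iff the key is seen in the patient's RNA with enough reads."""
    return any(
        call.key == key and call.alt_reads >= min_alt_reads for call in rna_table
    )


def _count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        start = haystack.find(needle, start)
        if start == -1:
            return count
        count += 1
        start += 1  # self-overlap counts


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def context_is_unique(context41: str, reference: Mapping[str, str] | str) -> bool:
    """Exact-match uniqueness of a 41-base context in the reference.

    Counts overlapping occurrences on both strands; a context equal to
    its own reverse complement is counted once per locus (odd-length
    contexts can never truly be palindromic, but the guard keeps the
    rule total). True iff exactly one locus matches.
    """
    if len(context41) != 41:
        raise ValueError(f"context must have length 41, got {len(context41)}")
    sequences = (
        reference.values() if isinstance(reference, Mapping) else (reference,)
    )
    rc = _revcomp(context41)
    hits = 0
    for seq in sequences:
        hits += _count_overlapping(seq, context41)
        if rc != context41:
            hits += _count_overlapping(seq, rc)
        if hits > 1:
            return False
    return hits == 1


def wes_discovery_filter(
    tumor_call: VariantCall,
    annotation: Optional[AnnotationRecord],
    pon: PanelOfNormals,
    matched_normal_call: Optional[VariantCall] = None,
    rna_table: Optional[Iterable[VariantCall]] = None,
    has_rna: bool = False,
    reference: Optional[Mapping[str, str] | str] = None,
    params: FilterParams = FilterParams(),
    context_unique: Optional[bool] = None,
) -> FilterTrace:
    """Exome discovery-set candidate-somatic cascade for one variant.

    ``matched_normal_call`` is the normal-sample evidence at the same
    site (None for tumor-only patients). ``context_unique`` may be
    supplied precomputed to avoid rescanning the reference; otherwise
    it is derived from ``annotation.context41`` and ``reference``.
    """
    if annotation is None:
        raise AnnotationMissingError(
            f"variant {tumor_call.key} has no annotation; cannot adjudicate"
        )
    trace = FilterTrace(key=tumor_call.key, sample_id=tumor_call.sample_id)
    paired = matched_normal_call is not None

    if paired:
        depth_ok = (
            tumor_call.depth >= params.wes_min_depth
            and matched_normal_call.depth >= params.wes_min_depth
        )
        depth_obs = (tumor_call.depth, matched_normal_call.depth)
    else:
        depth_ok = tumor_call.depth >= params.wes_min_depth
        depth_obs = (tumor_call.depth, None)
    trace.add("depth", depth_ok, depth_obs)

    if paired:
        vaf_ok = (
            tumor_call.vaf > params.wes_tumor_vaf
            and matched_normal_call.vaf < params.wes_normal_vaf
        )
        vaf_obs = (tumor_call.vaf, matched_normal_call.vaf)
    else:
        vaf_ok = (
            tumor_call.depth > params.wes_unpaired_depth
            and tumor_call.vaf > params.wes_unpaired_vaf
        )
        vaf_obs = (tumor_call.vaf, None)
    trace.add("vaf", vaf_ok, vaf_obs)

    trace.add("pon", tumor_call.key not in pon, tumor_call.key in pon)

    germline_flagged = annotation.in_dbsnp or annotation.kg_af > 0
    trace.add(
        "germline_db",
        annotation.in_cosmic or not germline_flagged,
        (annotation.in_dbsnp, annotation.kg_af),
    )

    trace.add("cosmic", annotation.in_cosmic, annotation.in_cosmic)

    if has_rna and rna_table is not None:
        concordant = rna_concordant(
            tumor_call.key, rna_table, params.rna_min_alt_reads
        )
        trace.add("rna_concordance", concordant, concordant)
    else:
        trace.add("rna_concordance", True, "not_applicable")

    if context_unique is None:
        if annotation.context41 is not None and reference is not None:
            context_unique = context_is_unique(annotation.context41, reference)
        else:
            context_unique = True  # no context to adjudicate: pass-through
    trace.add("context_unique", context_unique, context_unique)
    return trace


def targeted_filter(
    tumor_call: VariantCall,
    annotation: Optional[AnnotationRecord],
    pon_plus_controls: PanelOfNormals,
    params: FilterParams = FilterParams(),
) -> FilterTrace:
    """Targeted deep-sequencing cascade for one variant.

    ``pon_plus_controls`` is built from the sequenced normal saliva
    samples plus the hyperplastic lymph-node controls.
    """
    if annotation is None:
        raise AnnotationMissingError(
            f"variant {tumor_call.key} has no annotation; cannot adjudicate"
        )
    trace = FilterTrace(key=tumor_call.key, sample_id=tumor_call.sample_id)
    trace.add("call_quality", tumor_call.caller_quality_ok, tumor_call.caller_quality_ok)
    trace.add("vaf", tumor_call.vaf >= params.targeted_min_vaf, tumor_call.vaf)
    trace.add(
        "alt_reads",
        tumor_call.alt_reads >= params.targeted_min_alt_reads,
        tumor_call.alt_reads,
    )
    trace.add("kg_af", annotation.kg_af <= params.kg_af_max, annotation.kg_af)
    trace.add("cosmic", annotation.in_cosmic, annotation.in_cosmic)
    # Subsumed by the COSMIC gate (any non-exempt dbSNP variant already
    # lacks COSMIC membership) but traced for auditability.
    dbsnp_reject = (
        annotation.in_dbsnp
        and not annotation.dbsnp_pathogenic
        and not annotation.in_cosmic
    )
    trace.add(
        "dbsnp_exempt",
        not dbsnp_reject,
        (annotation.in_dbsnp, annotation.dbsnp_pathogenic),
    )
    effect_ok = annotation.effect != "synonymous" and (
        annotation.effect != "intronic"
        or annotation.dist_to_cds <= params.intronic_max_dist
    )
    trace.add("effect", effect_ok, (annotation.effect, annotation.dist_to_cds))
    trace.add(
        "controls",
        tumor_call.key not in pon_plus_controls,
        tumor_call.key in pon_plus_controls,
    )
    return trace


# ---------------------------------------------------------------------------
# Gate-predicate replay (trace soundness)
# ---------------------------------------------------------------------------


def replay_trace(trace: FilterTrace) -> str:
    """Recompute the verdict from the trace's own gate outcomes."""
    return "retained" if all(g.passed for g in trace.gates) else "rejected"
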