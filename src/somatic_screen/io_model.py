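"""Domain types and readers/writers for the pipeline's interchange formats.

The pipeline moves variant evidence around as pairs of
:class:`VariantCall` (read-count evidence for one variant in one sample)
and :class:`AnnotationRecord` (everything the filters need to know about
the variant site: gene, effect class, database membership, population
allele frequency, the nine damaging-predictor calls, the predicted
folding free-energy change, and the 41-base reference context).

Two on-disk dialects are supported:

* a native annotated TSV (the interchange format every stage reads and
  writes; fixed column order, see :data:`TSV_COLUMNS`), and
* VCF 4.x (read-only, via pysam), with INFO/FORMAT keys mapped to the
  native columns per :data:`VCF_KEY_TABLE`.

Coordinates are 1-based, fully closed (VCF convention). The identity key
used for every set operation (panel-of-normals membership, RNA
concordance, recurrence) is ``(chrom, pos, ref, alt)`` after minimal
representation of indels; it is sample-agnostic.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "GenomicPosition",
    "VariantCall",
    "SampleRecord",
    "AnnotationRecord",
    "SurvivalRecord",
    "SurvivalPlan",
    "CohortProfile",
    "MalformedRowError",
    "ProfileError",
    "read_variant_table",
    "write_variant_table",
    "write_maf_like",
    "read_maf_like",
    "read_clinical_table",
    "write_clinical_table",
    "read_cohort_profile",
    "load_reference_profile",
    "NONSYNONYMOUS_EFFECTS",
    "EFFECTS",
    "DAMAGING",
    "TOLERATED",
    "MISSING",
]

# Effect vocabulary; "nonsynonymous" = protein-altering.
EFFECTS = (
    "missense",
    "stop_gain",
    "splicing",
    "frameshift_indel",
    "inframe_indel",
    "synonymous",
    "intronic",
    "other",
)
NONSYNONYMOUS_EFFECTS = frozenset(
    {"missense", "stop_gain", "splicing", "frameshift_indel", "inframe_indel"}
)

# Ternary predictor codes as they appear in the annotation TSV.
DAMAGING = "D"
TOLERATED = "T"
MISSING = "."

PREDICTOR_TOOLS = (
    "Polyphen2",
    "Polyphen2_HVAR",
    "Polyphen2_HDIV",
    "LRT_pred",
    "MutationTaster_pred",
    "FATHMM_pred",
    "RadialSVM_pred",
    "LR_pred",
    "MutationAssessor",
)

_BASES = frozenset("ACGT")


class MalformedRowError(ValueError):
    """A variant-table row that does not parse under the named dialect."""


class ProfileError(ValueError):
    """A cohort profile that violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicPosition:
    """One variant locus: 1-based coordinate plus ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def normalized(self) -> "GenomicPosition":
        """Minimal representation: trim shared suffix then shared prefix.

        Makes indel identity keys deterministic regardless of how the
        caller padded the alleles. SNVs pass through unchanged.
        """
        ref, alt, pos = self.ref, self.alt, self.pos
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        if (ref, alt, pos) == (self.ref, self.alt, self.pos):
            return self
        return GenomicPosition(self.chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantCall:
    """One observed variant in one sample, with read-count evidence."""

    sample_id: str
    position: GenomicPosition
    depth: int
    alt_reads: int
    vaf: float
    caller_quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be nonnegative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )
        expected = self.alt_reads / self.depth if self.depth > 0 else 0.0
        if not math.isclose(self.vaf, expected, abs_tol=1e-9):
            raise ValueError(
                f"vaf {self.vaf} inconsistent with {self.alt_reads}/{self.depth}"
            )

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        position: GenomicPosition,
        depth: int,
        alt_reads: int,
        caller_quality_ok: bool = True,
    ) -> "VariantCall":
        vaf = alt_reads / depth if depth > 0 else 0.0
        return cls(sample_id, position, depth, alt_reads, vaf, caller_quality_ok)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.position.key


SAMPLE_ROLES = (
    "tumor_discovery",
    "tumor_extension",
    "matched_normal",
    "pon_normal",
    "hyperplastic_control",
)
TUMOR_ROLES = frozenset({"tumor_discovery", "tumor_extension"})


@dataclass(frozen=True)
class SampleRecord:
    """Cohort membership and per-sample QC for one sequenced sample."""

    sample_id: str
    role: str
    paired: bool = False
    has_rna: bool = False
    tumor_fraction: float = 0.0
    frac_reads_ge_q30: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in SAMPLE_ROLES:
            raise ValueError(f"unknown sample role {self.role!r}")
        for frac in (self.tumor_fraction, self.frac_reads_ge_q30):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def is_tumor(self) -> bool:
        return self.role in TUMOR_ROLES


@dataclass(frozen=True)
class AnnotationRecord:
    """Site-level annotation consumed (never computed) by the filters."""

    position: GenomicPosition
    gene: str
    effect: str
    dist_to_cds: int = 0
    in_dbsnp: bool = False
    dbsnp_pathogenic: bool = False
    kg_af: float = 0.0
    in_cosmic: bool = False
    predictor_calls: tuple[str, ...] = (MISSING,) * 9
    ddg: Optional[float] = None
    context41: Optional[str] = None

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if len(self.predictor_calls) != 9:
            raise ValueError(
                f"exactly 9 predictor slots required, got {len(self.predictor_calls)}"
            )
        for call in self.predictor_calls:
            if call not in (DAMAGING, TOLERATED, MISSING):
                raise ValueError(f"predictor call must be D/T/., got {call!r}")
        if not 0.0 <= self.kg_af <= 1.0:
            raise ValueError("kg_af must lie in [0, 1]")
        if self.context41 is not None and len(self.context41) != 41:
            raise ValueError(
                f"context41 must have length 41, got {len(self.context41)}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.position.key

    @property
    def is_nonsynonymous(self) -> bool:
        return self.effect in NONSYNONYMOUS_EFFECTS


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's overall-survival observation."""

    patient_id: str
    os_months: float
    event: bool  # True = death observed, False = censored
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise ValueError("os_months must be nonnegative")


@dataclass(frozen=True)
class SurvivalPlan:
    """Target survival structure for the synthetic clinical table."""

    gene: str
    n_clinical: int
    median_mutated: float
    median_wildtype: float
    survival_at_36m: float
    followup_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.followup_range
        if not (0 <= lo < hi):
            raise ValueError("followup_range must be an increasing pair of times")
        if not 0.0 < self.survival_at_36m < 1.0:
            raise ValueError("survival_at_36m must lie strictly in (0, 1)")


@dataclass
class CohortProfile:
    """Configuration encoding the cohort structure driving the generator.

    ``gene_freqs`` maps each panel gene discovered by exome sequencing to
    the number of tumors that must carry a filter-surviving variant in
    it; ``per_sample_burden`` fixes the exome-wide nonsynonymous count of
    each discovery tumor.
    """

    n_discovery: int
    n_extension: int
    n_matched_pairs: int
    n_matched_discovery: int
    n_pon: int
    n_hyperplastic: int
    n_rna: int
    exome_mb: float
    gene_freqs: dict[str, int]
    literature_genes: list[str]
    per_sample_burden: list[int]
    titv_ratio: float
    gc_bias: float
    survival: Optional[SurvivalPlan]
    seed: int = 0
    germline_per_tumor: int = 50
    artifacts_per_tumor: int = 20
    germline_pool: int = 300
    artifact_pool: int = 100
    n_context_duplicated: int = 5
    stability_plan: dict[str, dict[str, int]] = field(default_factory=dict)
    name: str = "unnamed"

    @property
    def n_tumors(self) -> int:
        return self.n_discovery + self.n_extension

    @property
    def wes_genes(self) -> list[str]:
        return sorted(self.gene_freqs)

    @property
    def panel_genes(self) -> list[str]:
        return sorted(set(self.gene_freqs) | set(self.literature_genes))

    def validate(self) -> "CohortProfile":
        counts = {
            "n_discovery": self.n_discovery,
            "n_extension": self.n_extension,
            "n_matched_pairs": self.n_matched_pairs,
            "n_matched_discovery": self.n_matched_discovery,
            "n_pon": self.n_pon,
            "n_hyperplastic": self.n_hyperplastic,
            "n_rna": self.n_rna,
        }
        for name, value in counts.items():
            if value < 0:
                raise ProfileError(f"{name} must be nonnegative, got {value}")
        if self.n_matched_pairs > self.n_tumors:
            raise ProfileError("n_matched_pairs exceeds the number of tumors")
        if self.n_matched_discovery > min(self.n_matched_pairs, self.n_discovery):
            raise ProfileError("n_matched_discovery exceeds available samples")
        if self.n_rna > self.n_discovery:
            raise ProfileError("n_rna exceeds n_discovery")
        if self.exome_mb <= 0:
            raise ProfileError("exome_mb must be positive")
        if self.titv_ratio <= 0:
            raise ProfileError("titv_ratio must be positive")
        if not 0.0 <= self.gc_bias <= 1.0:
            raise ProfileError("gc_bias must lie in [0, 1]")
        for gene, freq in self.gene_freqs.items():
            if freq < 0 or freq > self.n_tumors:
                raise ProfileError(
                    f"gene_freqs[{gene}] = {freq} outside [0, {self.n_tumors}]"
                )
        overlap = set(self.gene_freqs) & set(self.literature_genes)
        if overlap:
            raise ProfileError(
                f"literature genes overlap exome genes: {sorted(overlap)}"
            )
        if len(self.per_sample_burden) != self.n_discovery:
            raise ProfileError(
                f"per_sample_burden has {len(self.per_sample_burden)} entries, "
                f"expected {self.n_discovery}"
            )
        if any(b < 0 for b in self.per_sample_burden):
            raise ProfileError("per_sample_burden entries must be nonnegative")
        if self.survival is not None and self.survival.n_clinical > self.n_tumors:
            raise ProfileError("n_clinical exceeds the number of tumors")
        for gene, plan in self.stability_plan.items():
            if gene not in self.gene_freqs:
                raise ProfileError(f"stability_plan gene {gene} not in gene_freqs")
            if plan.get("destabilizing", 0) > plan.get("missense", 0):
                raise ProfileError(f"stability_plan[{gene}]: destabilizing > missense")
            if plan.get("missense", 0) > self.gene_freqs[gene]:
                raise ProfileError(f"stability_plan[{gene}]: missense > gene_freqs")
        return self

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortProfile":
        raw = dict(raw)
        surv = raw.pop("survival", None)
        plan = None
        if surv is not None:
            plan = SurvivalPlan(
                gene=surv["gene"],
                n_clinical=int(surv["n_clinical"]),
                median_mutated=float(surv["median_mutated"]),
                median_wildtype=float(surv["median_wildtype"]),
                survival_at_36m=float(surv["survival_at_36m"]),
                followup_range=tuple(float(x) for x in surv["followup_range"]),
            )
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ProfileError(f"unknown profile keys: {sorted(unknown)}")
        return cls(survival=plan, **raw).validate()


# ---------------------------------------------------------------------------
# Native annotated TSV dialect
# ---------------------------------------------------------------------------

TSV_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
    "vaf",
    "quality_ok",
    "gene",
    "effect",
    "dist_to_cds",
    "in_dbsnp",
    "dbsnp_pathogenic",
    "kg_af",
    "in_cosmic",
    *(f"pred_{i}" for i in range(1, 10)),
    "ddg",
    "context41",
)

#: VCF INFO/FORMAT keys mapped onto native TSV columns.
VCF_KEY_TABLE = {
    "GENE": "gene",
    "EFFECT": "effect",
    "DIST": "dist_to_cds",
    "DBSNP": "in_dbsnp",
    "DBSNP_PATH": "dbsnp_pathogenic",
    "KG_AF": "kg_af",
    "COSMIC": "in_cosmic",
    "PRED": "pred_1..pred_9 (9-character D/T/. string)",
    "DDG": "ddg",
    "CTX": "context41",
    "FORMAT/DP": "depth",
    "FORMAT/AD": "alt_reads (per-allele depths, ref first)",
}


def _fmt_bool(value: bool) -> str:
    return "1" if value else "0"


def _parse_bool(text: str, path: str, line_no: int) -> bool:
    if text in ("1", "0"):
        return text == "1"
    raise MalformedRowError(f"{path}:{line_no}: boolean field must be 0/1, got {text!r}")


def write_variant_table(
    records: Iterable[tuple[VariantCall, AnnotationRecord]], path: str | Path
) -> None:
    """Write (call, annotation) pairs in the native TSV dialect."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for call, ann in records:
            pos = call.position
            writer.writerow(
                [
                    call.sample_id,
                    pos.chrom,
                    pos.pos,
                    pos.ref,
                    pos.alt,
                    call.depth,
                    call.alt_reads,
                    repr(call.vaf),
                    _fmt_bool(call.caller_quality_ok),
                    ann.gene,
                    ann.effect,
                    ann.dist_to_cds,
                    _fmt_bool(ann.in_dbsnp),
                    _fmt_bool(ann.dbsnp_pathogenic),
                    repr(ann.kg_af),
                    _fmt_bool(ann.in_cosmic),
                    *ann.predictor_calls,
                    "." if ann.ddg is None else repr(ann.ddg),
                    "." if ann.context41 is None else ann.context41,
                ]
            )


def _read_native_tsv(path: str | Path) -> list[tuple[VariantCall, AnnotationRecord]]:
    out: list[tuple[VariantCall, AnnotationRecord]] = []
    path = str(path)
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise MalformedRowError(f"{path}:1: empty file, expected header")
        if tuple(header) != TSV_COLUMNS:
            raise MalformedRowError(f"{path}:1: unexpected header {header!r}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TSV_COLUMNS):
                raise MalformedRowError(
                    f"{path}:{line_no}: expected {len(TSV_COLUMNS)} fields, got {len(row)}"
                )
            rec = dict(zip(TSV_COLUMNS, row))
            try:
                position = GenomicPosition(
                    rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"]
                )
                call = VariantCall(
                    sample_id=rec["sample_id"],
                    position=position,
                    depth=int(rec["depth"]),
                    alt_reads=int(rec["alt_reads"]),
                    vaf=float(rec["vaf"]),
                    caller_quality_ok=_parse_bool(rec["quality_ok"], path, line_no),
                )
                ann = AnnotationRecord(
                    position=position,
                    gene=rec["gene"],
                    effect=rec["effect"],
                    dist_to_cds=int(rec["dist_to_cds"]),
                    in_dbsnp=_parse_bool(rec["in_dbsnp"], path, line_no),
                    dbsnp_pathogenic=_parse_bool(rec["dbsnp_pathogenic"], path, line_no),
                    kg_af=float(rec["kg_af"]),
                    in_cosmic=_parse_bool(rec["in_cosmic"], path, line_no),
                    predictor_calls=tuple(rec[f"pred_{i}"] for i in range(1, 10)),
                    ddg=None if rec["ddg"] == "." else float(rec["ddg"]),
                    context41=None if rec["context41"] == "." else rec["context41"],
                )
            except MalformedRowError:
                raise
            except (ValueError, KeyError) as exc:
                raise MalformedRowError(f"{path}:{line_no}: {exc}") from exc
            out.append((call, ann))
    return out


def _info_get(info, key: str, default):
    # pysam raises for INFO keys absent from the header; treat those
    # exactly like keys absent from the record.
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _read_vcf(path: str | Path) -> list[tuple[VariantCall, AnnotationRecord]]:
    import pysam

    out: list[tuple[VariantCall, AnnotationRecord]] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            info = rec.info
            pred = str(_info_get(info, "PRED", "." * 9))
            for alt_index, alt in enumerate(alts):
                position = GenomicPosition(rec.chrom, rec.pos, rec.ref, alt)
                kg_af = _info_get(info, "KG_AF", 0.0)
                if isinstance(kg_af, tuple):  # Number=A: one value per alt
                    kg_af = kg_af[alt_index]
                ddg = _info_get(info, "DDG", None)
                if isinstance(ddg, tuple):
                    ddg = ddg[alt_index]
                ann = AnnotationRecord(
                    position=position,
                    gene=str(_info_get(info, "GENE", "NA")),
                    effect=str(_info_get(info, "EFFECT", "other")),
                    dist_to_cds=int(_info_get(info, "DIST", 0)),
                    in_dbsnp=_info_get(info, "DBSNP", False) is not False,
                    dbsnp_pathogenic=_info_get(info, "DBSNP_PATH", False) is not False,
                    kg_af=float(kg_af or 0.0),
                    in_cosmic=_info_get(info, "COSMIC", False) is not False,
                    predictor_calls=tuple(pred[:9]),
                    ddg=None if ddg is None else float(ddg),
                    context41=_info_get(info, "CTX", None),
                )
                for sample_name in sample_names:
                    fmt = rec.samples[sample_name]
                    depth = int(fmt.get("DP") or 0)
                    ad = fmt.get("AD")
                    alt_reads = int(ad[alt_index + 1]) if ad is not None else 0
                    out.append(
                        (
                            VariantCall.from_counts(
                                sample_name, position, depth, alt_reads
                            ),
                            ann,
                        )
                    )
    return out


def read_variant_table(
    path: str | Path, dialect: str = "tsv"
) -> list[tuple[VariantCall, AnnotationRecord]]:
    """Read one variant table; returns (VariantCall, AnnotationRecord) pairs.

    Multi-allelic VCF rows are split into one record per alternate
    allele, so each returned pair describes exactly one (sample, site,
    alt) observation.
    """
    if dialect == "tsv":
        return _read_native_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


# ---------------------------------------------------------------------------
# MAF-like retained-variant output
# ---------------------------------------------------------------------------

MAF_COLUMNS = (
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "effect",
    "depth",
    "alt_reads",
    "vaf",
    "verdict",
    "rejecting_gate",
)


def write_maf_like(
    records: Sequence[tuple[VariantCall, AnnotationRecord]],
    traces: Sequence,
    path: str | Path,
) -> None:
    """Write one MAF-like row per record, with its filter verdict.

    ``traces`` is aligned with ``records``; each element exposes
    ``final_verdict`` and ``rejecting_gate`` (see somatic_filtering).
    """
    if len(records) != len(traces):
        raise ValueError("records and traces must be aligned")
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MAF_COLUMNS)
        for (call, ann), trace in zip(records, traces):
            pos = call.position
            writer.writerow(
                [
                    call.sample_id,
                    ann.gene,
                    pos.chrom,
                    pos.pos,
                    pos.ref,
                    pos.alt,
                    ann.effect,
                    call.depth,
                    call.alt_reads,
                    repr(call.vaf),
                    trace.final_verdict,
                    trace.rejecting_gate or ".",
                ]
            )


def read_maf_like(path: str | Path) -> list[dict]:
    """Read back a MAF-like file; values are typed per column."""
    rows: list[dict] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if tuple(reader.fieldnames or ()) != MAF_COLUMNS:
            raise MalformedRowError(f"{path}: unexpected MAF header")
        for row in reader:
            row["pos"] = int(row["pos"])
            row["depth"] = int(row["depth"])
            row["alt_reads"] = int(row["alt_reads"])
            row["vaf"] = float(row["vaf"])
            row["rejecting_gate"] = (
                None if row["rejecting_gate"] == "." else row["rejecting_gate"]
            )
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


def write_clinical_table(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_id", "os_months", "event", "group"])
        for rec in records:
            writer.writerow(
                [rec.patient_id, repr(rec.os_months), int(rec.event), rec.group or "."]
            )


def read_clinical_table(path: str | Path) -> list[SurvivalRecord]:
    out = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for line_no, row in enumerate(reader, start=2):
            try:
                out.append(
                    SurvivalRecord(
                        patient_id=row["patient_id"],
                        os_months=float(row["os_months"]),
                        event=bool(int(row["event"])),
                        group=None if row.get("group") in (None, ".") else row["group"],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise MalformedRowError(f"{path}:{line_no}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Cohort profile
# ---------------------------------------------------------------------------


def read_cohort_profile(path: str | Path) -> CohortProfile:
    """Read and validate a YAML (or JSON) cohort profile."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ProfileError(f"{path}: profile must be a mapping")
    try:
        return CohortProfile.from_dict(raw)
    except ProfileError as exc:
        raise ProfileError(f"{path}: {exc}") from exc


def load_reference_profile() -> CohortProfile:
    """The packaged reference profile encoding the published cohort."""
    ref = resources.files("somatic_screen.data").joinpath("reference_profile.yaml")
    raw = yaml.safe_load(ref.read_text())
    return CohortProfile.from_dict(raw)
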