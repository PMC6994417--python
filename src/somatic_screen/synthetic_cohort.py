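"""Seeded generator of a full synthetic tumor/normal cohort.

The generator emulates a two-stage lymphoma sequencing study: an exome
discovery set of frozen-biopsy tumors (a minority with matched saliva
normals, most RNA-sequenced as well), a larger targeted-panel extension
set, a panel of unmatched healthy-donor saliva normals, and reactive
hyperplastic lymph-node controls. It plants three classes of variants
with known truth labels:

``somatic``
    Constructed to survive both filtering cascades: deep, clonal
    (VAF > 25%), COSMIC-listed, absent from every normal, uniquely
    mapping 41-base context, nonsynonymous effect, and a 4-of-9
    damaging predictor consensus. Per-gene mutated-sample counts and
    per-discovery-sample burdens follow the profile exactly.

``germline``
    Common polymorphisms (dbSNP-listed, population AF > 1%) drawn from
    a shared site pool, present at ~50% VAF in the tumor and in the
    patient's matched normal.

``artifact``
    Recurrent systematic errors drawn from a shared pool and planted in
    at least one unmatched normal and one hyperplastic control, so both
    cascades' normal-subtraction gates remove them. A configurable few
    additionally have their 41-base context copied to a second
    reference locus, exercising the multi-mapping context gate.

Everything is drawn from one ``numpy`` generator seeded by the caller,
so identical (profile, seed) inputs give byte-identical output bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_model import (
    AnnotationRecord,
    CohortProfile,
    DAMAGING,
    GenomicPosition,
    MISSING,
    SampleRecord,
    SurvivalRecord,
    TOLERATED,
    VariantCall,
    read_clinical_table,
    read_variant_table,
    write_clinical_table,
    write_variant_table,
)
from . import survival as surv

__all__ = [
    "PlantedTruth",
    "CohortBundle",
    "GenerationError",
    "generate_cohort",
    "sample_substitution",
    "generate_survival",
    "tumor_ids",
]

Key = tuple[str, int, str, str]

CHROM = "toy1"
REFERENCE_LENGTH = 1_000_000
GENE_LENGTH = 2_000
GENE_STRIDE = 3_000
PANEL_REGION_START = 1_000
N_FILLER_GENES = 160
SPARE_REGION_START = 900_000  # hosts duplicated artifact contexts

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_TRUNCATING_CYCLE = ("stop_gain", "frameshift_indel", "splicing")


class GenerationError(RuntimeError):
    """The profile's constraints cannot be realized."""


@dataclass
class PlantedTruth:
    """Ground-truth labels for every emitted tumor variant."""

    labels: dict[tuple[str, Key], str] = field(default_factory=dict)
    somatic_by_sample: dict[str, list[Key]] = field(default_factory=dict)
    gene_samples: dict[str, set[str]] = field(default_factory=dict)

    def label(self, sample_id: str, key: Key) -> str:
        return self.labels[(sample_id, key)]

    def to_json_dict(self) -> dict:
        return {
            "labels": [
                [sample, *key, label] for (sample, key), label in self.labels.items()
            ],
            "somatic_by_sample": {
                s: [list(k) for k in keys] for s, keys in self.somatic_by_sample.items()
            },
            "gene_samples": {g: sorted(s) for g, s in self.gene_samples.items()},
        }

    @classmethod
    def from_json_dict(cls, raw: dict) -> "PlantedTruth":
        truth = cls()
        for sample, chrom, pos, ref, alt, label in raw["labels"]:
            truth.labels[(sample, (chrom, int(pos), ref, alt))] = label
        truth.somatic_by_sample = {
            s: [(c, int(p), r, a) for c, p, r, a in keys]
            for s, keys in raw["somatic_by_sample"].items()
        }
        truth.gene_samples = {g: set(s) for g, s in raw["gene_samples"].items()}
        return truth


@dataclass
class CohortBundle:
    """Everything one synthetic study produces, held in memory."""

    profile: CohortProfile
    samples: list[SampleRecord]
    calls: dict[str, list[VariantCall]]
    annotations: dict[Key, AnnotationRecord]
    rna: dict[str, list[VariantCall]]
    clinical: list[SurvivalRecord]
    reference: dict[str, str]
    gene_map: dict[str, tuple[str, int, int]]
    matched_normal_of: dict[str, str]
    truth: PlantedTruth

    def sample(self, sample_id: str) -> SampleRecord:
        for rec in self.samples:
            if rec.sample_id == sample_id:
                return rec
        raise KeyError(sample_id)

    def tumors(self) -> list[SampleRecord]:
        return [s for s in self.samples if s.is_tumor]

    def by_role(self, role: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.role == role]

    def table(self, sample_id: str) -> list[tuple[VariantCall, AnnotationRecord]]:
        return [(c, self.annotations[c.key]) for c in self.calls[sample_id]]

    # -- on-disk layout ----------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        """Emit the bundle as the native TSV/FASTA/JSON directory layout."""
        outdir = Path(outdir)
        subdir_of_role = {
            "tumor_discovery": "tumors",
            "tumor_extension": "tumors",
            "matched_normal": "matched",
            "pon_normal": "pon",
            "hyperplastic_control": "controls",
        }
        for sub in set(subdir_of_role.values()) | {"rna"}:
            (outdir / sub).mkdir(parents=True, exist_ok=True)
        for rec in self.samples:
            path = outdir / subdir_of_role[rec.role] / f"{rec.sample_id}.tsv"
            write_variant_table(self.table(rec.sample_id), path)
        for sample_id, table in self.rna.items():
            pairs = [(c, self.annotations[c.key]) for c in table]
            write_variant_table(pairs, outdir / "rna" / f"{sample_id}.tsv")
        with open(outdir / "samples.tsv", "w") as handle:
            handle.write(
                "sample_id\trole\tpaired\thas_rna\ttumor_fraction"
                "\tfrac_reads_ge_q30\tmatched_normal\n"
            )
            for rec in self.samples:
                handle.write(
                    f"{rec.sample_id}\t{rec.role}\t{int(rec.paired)}"
                    f"\t{int(rec.has_rna)}\t{rec.tumor_fraction!r}"
                    f"\t{rec.frac_reads_ge_q30!r}"
                    f"\t{self.matched_normal_of.get(rec.sample_id, '.')}\n"
                )
        with open(outdir / "gene_map.tsv", "w") as handle:
            handle.write("gene\tchrom\tstart\tend\n")
            for gene in sorted(self.gene_map):
                chrom, start, end = self.gene_map[gene]
                handle.write(f"{gene}\t{chrom}\t{start}\t{end}\n")
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        SeqIO.write(
            [SeqRecord(Seq(seq), id=name, description="") for name, seq in self.reference.items()],
            str(outdir / "reference.fa"),
            "fasta",
        )
        if self.clinical:
            write_clinical_table(self.clinical, outdir / "clinical.tsv")
        with open(outdir / "truth.json", "w") as handle:
            json.dump(self.truth.to_json_dict(), handle, indent=1, sort_keys=True)


def load_cohort_dir(outdir: str | Path, profile: CohortProfile) -> CohortBundle:
    """Read a directory written by :meth:`CohortBundle.write`."""
    from Bio import SeqIO

    outdir = Path(outdir)
    samples: list[SampleRecord] = []
    matched: dict[str, str] = {}
    with open(outdir / "samples.tsv") as handle:
        next(handle)
        for line in handle:
            sid, role, paired, has_rna, tf, q30, normal = line.rstrip("\n").split("\t")
            samples.append(
                SampleRecord(sid, role, paired == "1", has_rna == "1", float(tf), float(q30))
            )
            if normal != ".":
                matched[sid] = normal
    calls: dict[str, list[VariantCall]] = {}
    annotations: dict[Key, AnnotationRecord] = {}
    subdir_of_role = {
        "tumor_discovery": "tumors",
        "tumor_extension": "tumors",
        "matched_normal": "matched",
        "pon_normal": "pon",
        "hyperplastic_control": "controls",
    }
    for rec in samples:
        pairs = read_variant_table(
            outdir / subdir_of_role[rec.role] / f"{rec.sample_id}.tsv"
        )
        calls[rec.sample_id] = [c for c, _ in pairs]
        for c, ann in pairs:
            annotations[c.key] = ann
    rna: dict[str, list[VariantCall]] = {}
    for rec in samples:
        path = outdir / "rna" / f"{rec.sample_id}.tsv"
        if rec.has_rna and path.exists():
            rna[rec.sample_id] = [c for c, _ in read_variant_table(path)]
    reference = {
        r.id: str(r.seq) for r in SeqIO.parse(str(outdir / "reference.fa"), "fasta")
    }
    gene_map: dict[str, tuple[str, int, int]] = {}
    with open(outdir / "gene_map.tsv") as handle:
        next(handle)
        for line in handle:
            gene, chrom, start, end = line.rstrip("\n").split("\t")
            gene_map[gene] = (chrom, int(start), int(end))
    clinical_path = outdir / "clinical.tsv"
    clinical = read_clinical_table(clinical_path) if clinical_path.exists() else []
    with open(outdir / "truth.json") as handle:
        truth = PlantedTruth.from_json_dict(json.load(handle))
    return CohortBundle(
        profile=profile,
        samples=samples,
        calls=calls,
        annotations=annotations,
        rna=rna,
        clinical=clinical,
        reference=reference,
        gene_map=gene_map,
        matched_normal_of=matched,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Substitution sampling
# ---------------------------------------------------------------------------


def sample_substitution(
    titv_ratio: float, gc_bias: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Draw a (ref, alt) single-base substitution.

    P(transition) = titv_ratio / (1 + titv_ratio) and
    P(ref ∈ {G, C}) = gc_bias, so over many draws the empirical Ti/Tv
    converges to ``titv_ratio`` and the G/C-targeted fraction to
    ``gc_bias``.
    """
    if titv_ratio <= 0:
        raise ValueError("titv_ratio must be positive")
    if not 0.0 <= gc_bias <= 1.0:
        raise ValueError("gc_bias must lie in [0, 1]")
    if rng.random() < gc_bias:
        ref = "G" if rng.random() < 0.5 else "C"
    else:
        ref = "A" if rng.random() < 0.5 else "T"
    if rng.random() < titv_ratio / (1.0 + titv_ratio):
        alt = _TRANSITION[ref]
    else:
        alt = _TRANSVERSIONS[ref][int(rng.random() < 0.5)]
    return ref, alt


# ---------------------------------------------------------------------------
# Reference and position bookkeeping
# ---------------------------------------------------------------------------


def _build_reference(rng: np.random.Generator, length: int = REFERENCE_LENGTH) -> str:
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.integers(0, 4, size=length)])


class _PositionAllocator:
    """Hands out unused 1-based positions inside gene intervals."""

    def __init__(self, reference: str, gene_map: dict, rng: np.random.Generator):
        self._reference = reference
        self._gene_map = gene_map
        self._rng = rng
        self._free: dict[str, dict[str, list[int]]] = {}

    def _space(self, gene: str) -> dict[str, list[int]]:
        if gene not in self._free:
            _, start, end = self._gene_map[gene]
            by_base: dict[str, list[int]] = {b: [] for b in "ACGT"}
            for pos in range(start, end + 1):
                by_base[self._reference[pos - 1]].append(pos)
            for base in "ACGT":
                self._rng.shuffle(by_base[base])
            self._free[gene] = by_base
        return self._free[gene]

    def take(self, gene: str, base: Optional[str] = None) -> int:
        space = self._space(gene)
        if base is None:
            base = max("ACGT", key=lambda b: len(space[b]))
        if not space[base]:
            raise GenerationError(f"gene {gene} exhausted positions for base {base}")
        return space[base].pop()


def _context(reference: str, pos: int) -> str:
    return reference[pos - 21 : pos + 20]


def tumor_ids(profile: CohortProfile) -> list[str]:
    return [f"T{i:03d}" for i in range(1, profile.n_tumors + 1)]


def _shuffled_predictors(
    rng: np.random.Generator, n_damaging: int, allow_missing: bool = True
) -> tuple[str, ...]:
    rest = 9 - n_damaging
    n_missing = int(rng.integers(0, rest + 1)) if allow_missing and rest else 0
    calls = (
        [DAMAGING] * n_damaging
        + [TOLERATED] * (rest - n_missing)
        + [MISSING] * n_missing
    )
    rng.shuffle(calls)
    return tuple(calls)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(profile: CohortProfile, seed: int) -> CohortBundle:
    """Generate the full synthetic cohort for a validated profile."""
    profile.validate()
    rng = np.random.default_rng(seed)

    # --- reference and gene intervals -------------------------------------
    reference = _build_reference(rng)
    panel = profile.panel_genes
    filler_genes = [f"EXG{i:03d}" for i in range(1, N_FILLER_GENES + 1)]
    gene_map: dict[str, tuple[str, int, int]] = {}
    cursor = PANEL_REGION_START
    for gene in panel + filler_genes:
        gene_map[gene] = (CHROM, cursor, cursor + GENE_LENGTH - 1)
        cursor += GENE_STRIDE
    if cursor >= SPARE_REGION_START:
        raise GenerationError("gene intervals overflow the toy reference")

    # --- sample sheet ------------------------------------------------------
    tumors = tumor_ids(profile)
    discovery = tumors[: profile.n_discovery]
    extension = tumors[profile.n_discovery :]
    paired_tumors = (
        discovery[: profile.n_matched_discovery]
        + extension[: profile.n_matched_pairs - profile.n_matched_discovery]
    )
    matched_normal_of = {
        t: f"N{i:03d}" for i, t in enumerate(paired_tumors, start=1)
    }
    rna_samples = discovery[: profile.n_rna]
    pon_normals = [f"P{i:03d}" for i in range(1, profile.n_pon + 1)]
    hyperplastic = [f"H{i:03d}" for i in range(1, profile.n_hyperplastic + 1)]

    samples: list[SampleRecord] = []
    for t in tumors:
        samples.append(
            SampleRecord(
                sample_id=t,
                role="tumor_discovery" if t in discovery else "tumor_extension",
                paired=t in matched_normal_of,
                has_rna=t in rna_samples,
                tumor_fraction=float(round(rng.uniform(0.76, 0.95), 3)),
                frac_reads_ge_q30=float(round(rng.uniform(0.70, 0.95), 3)),
            )
        )
    for n in matched_normal_of.values():
        samples.append(SampleRecord(n, "matched_normal", frac_reads_ge_q30=0.9))
    for p in pon_normals:
        samples.append(SampleRecord(p, "pon_normal", frac_reads_ge_q30=0.9))
    for h in hyperplastic:
        samples.append(SampleRecord(h, "hyperplastic_control", frac_reads_ge_q30=0.9))

    alloc = _PositionAllocator(reference, gene_map, rng)
    annotations: dict[Key, AnnotationRecord] = {}
    truth = PlantedTruth(somatic_by_sample={t: [] for t in tumors})

    # --- shared germline SNP pool ------------------------------------------
    germline_pool: list[Key] = []
    for i in range(profile.germline_pool):
        gene = panel[i % len(panel)] if panel else filler_genes[i % len(filler_genes)]
        ref_base, alt_base = sample_substitution(profile.titv_ratio, 0.5, rng)
        pos = alloc.take(gene, ref_base)
        gp = GenomicPosition(CHROM, pos, ref_base, alt_base)
        annotations[gp.key] = AnnotationRecord(
            position=gp,
            gene=gene,
            effect="missense",
            in_dbsnp=True,
            kg_af=float(rng.uniform(0.02, 0.45)),
            in_cosmic=False,
            predictor_calls=_shuffled_predictors(rng, int(rng.integers(0, 4))),
            ddg=float(rng.uniform(-1.0, 1.0)),
            context41=None,  # filled after reference is final
        )
        germline_pool.append(gp.key)

    # --- shared artifact pool ----------------------------------------------
    artifact_pool: list[Key] = []
    artifact_pon_members: dict[Key, list[str]] = {}
    artifact_control_members: dict[Key, list[str]] = {}
    for i in range(profile.artifact_pool):
        gene = panel[(i * 7) % len(panel)] if panel else filler_genes[i % len(filler_genes)]
        ref_base, alt_base = sample_substitution(profile.titv_ratio, profile.gc_bias, rng)
        pos = alloc.take(gene, ref_base)
        gp = GenomicPosition(CHROM, pos, ref_base, alt_base)
        annotations[gp.key] = AnnotationRecord(
            position=gp,
            gene=gene,
            effect="missense",
            in_dbsnp=False,
            kg_af=0.0,
            in_cosmic=True,
            predictor_calls=_shuffled_predictors(rng, int(rng.integers(4, 10))),
            ddg=float(rng.uniform(-2.0, 0.5)),
            context41=None,
        )
        artifact_pool.append(gp.key)
        if pon_normals:
            n_members = int(rng.integers(1, min(3, len(pon_normals)) + 1))
            idx = rng.choice(len(pon_normals), size=n_members, replace=False)
            artifact_pon_members[gp.key] = [pon_normals[j] for j in sorted(idx)]
        if hyperplastic:
            n_members = int(rng.integers(1, min(2, len(hyperplastic)) + 1))
            idx = rng.choice(len(hyperplastic), size=n_members, replace=False)
            artifact_control_members[gp.key] = [hyperplastic[j] for j in sorted(idx)]

    # Duplicate the context of the first few artifact sites to a spare
    # locus, making those contexts multi-mapping.
    n_dup = min(profile.n_context_duplicated, len(artifact_pool))
    ref_chars = list(reference)
    for i in range(n_dup):
        _, pos, _, _ = artifact_pool[i]
        ctx = _context(reference, pos)
        start = SPARE_REGION_START + i * 200
        ref_chars[start : start + 41] = ctx
    reference = "".join(ref_chars)
    alloc._reference = reference  # positions already handed out are unaffected

    # Reference is now final: fill in contexts for pool sites.
    for key in germline_pool + artifact_pool:
        _, pos, _, _ = key
        ann = annotations[key]
        annotations[key] = AnnotationRecord(
            position=ann.position,
            gene=ann.gene,
            effect=ann.effect,
            dist_to_cds=ann.dist_to_cds,
            in_dbsnp=ann.in_dbsnp,
            dbsnp_pathogenic=ann.dbsnp_pathogenic,
            kg_af=ann.kg_af,
            in_cosmic=ann.in_cosmic,
            predictor_calls=ann.predictor_calls,
            ddg=ann.ddg,
            context41=_context(reference, pos),
        )

    # --- recurrent-gene sample assignment (capacity-aware) ------------------
    capacity: dict[str, Optional[int]] = {}
    for i, t in enumerate(discovery):
        capacity[t] = profile.per_sample_burden[i]
    for t in extension:
        capacity[t] = None  # unconstrained
    assigned: dict[str, list[str]] = {t: [] for t in tumors}  # tumor -> genes

    ordered_genes = sorted(profile.gene_freqs, key=lambda g: (-profile.gene_freqs[g], g))
    gene_carriers: dict[str, list[str]] = {}
    for gene in ordered_genes:
        freq = profile.gene_freqs[gene]
        if freq == 0:
            continue
        eligible = [
            t
            for t in tumors
            if capacity[t] is None or capacity[t] - len(assigned[t]) > 0
        ]
        if len(eligible) < freq:
            raise GenerationError(
                f"cannot place {freq} carriers for {gene}: only "
                f"{len(eligible)} tumors have remaining burden capacity"
            )
        idx = rng.choice(len(eligible), size=freq, replace=False)
        carriers = [eligible[j] for j in sorted(idx)]
        gene_carriers[gene] = carriers
        for t in carriers:
            assigned[t].append(gene)

    # --- plant somatic variants ---------------------------------------------
    def _plant_somatic(
        sample_id: str, gene: str, effect: str, ddg: Optional[float]
    ) -> Key:
        if effect == "frameshift_indel":
            pos = alloc.take(gene)
            ref_allele = reference[pos - 1]
            alt_allele = ref_allele + "ACGT"[int(rng.integers(0, 4))]
        else:
            ref_allele, alt_allele = sample_substitution(
                profile.titv_ratio, profile.gc_bias, rng
            )
            pos = alloc.take(gene, ref_allele)
        gp = GenomicPosition(CHROM, pos, ref_allele, alt_allele)
        annotations[gp.key] = AnnotationRecord(
            position=gp,
            gene=gene,
            effect=effect,
            in_dbsnp=False,
            kg_af=0.0,
            in_cosmic=True,
            predictor_calls=_shuffled_predictors(rng, int(rng.integers(4, 10))),
            ddg=ddg,
            context41=_context(reference, pos),
        )
        truth.labels[(sample_id, gp.key)] = "somatic"
        truth.somatic_by_sample[sample_id].append(gp.key)
        truth.gene_samples.setdefault(gene, set()).add(sample_id)
        return gp.key

    def _draw_effect() -> tuple[str, Optional[float]]:
        u = rng.random()
        if u < 0.70:
            return "missense", float(rng.uniform(-3.0, 1.0))
        if u < 0.80:
            return "stop_gain", None
        if u < 0.90:
            return "frameshift_indel", None
        return "splicing", None

    for gene in ordered_genes:
        carriers = gene_carriers.get(gene, [])
        plan = profile.stability_plan.get(gene)
        for rank, sample_id in enumerate(carriers):
            if plan is not None:
                n_mis = plan["missense"]
                n_destab = plan["destabilizing"]
                if rank < n_mis:
                    effect = "missense"
                    if rank < n_destab:
                        ddg = float(rng.uniform(-2.5, -0.6))
                    else:
                        ddg = float(rng.uniform(-0.45, 0.9))
                else:
                    effect = _TRUNCATING_CYCLE[(rank - n_mis) % len(_TRUNCATING_CYCLE)]
                    ddg = None
            else:
                effect, ddg = _draw_effect()
            _plant_somatic(sample_id, gene, effect, ddg)

    # Exome-wide filler mutations bring each discovery sample to its
    # profiled burden; they sit in off-panel genes so the targeted panel
    # never sees them.
    filler_cursor = 0
    for i, sample_id in enumerate(discovery):
        n_fill = profile.per_sample_burden[i] - len(assigned[sample_id])
        if n_fill < 0:
            raise GenerationError(
                f"{sample_id}: recurrent-gene assignments exceed burden"
            )
        for _ in range(n_fill):
            gene = filler_genes[filler_cursor % len(filler_genes)]
            filler_cursor += 1
            effect, ddg = _draw_effect()
            _plant_somatic(sample_id, gene, effect, ddg)

    # --- per-tumor contamination draws --------------------------------------
    germline_of: dict[str, list[Key]] = {}
    artifacts_of: dict[str, list[Key]] = {}
    for t in tumors:
        n_g = min(profile.germline_per_tumor, len(germline_pool))
        idx = rng.choice(len(germline_pool), size=n_g, replace=False)
        germline_of[t] = [germline_pool[j] for j in sorted(idx)]
        n_a = min(profile.artifacts_per_tumor, len(artifact_pool))
        idx = rng.choice(len(artifact_pool), size=n_a, replace=False)
        artifacts_of[t] = [artifact_pool[j] for j in sorted(idx)]
        for key in germline_of[t]:
            truth.labels[(t, key)] = "germline"
        for key in artifacts_of[t]:
            truth.labels[(t, key)] = "artifact"

    # --- read-count evidence -------------------------------------------------
    def _call(sample_id: str, key: Key, depth: int, alt_reads: int) -> VariantCall:
        return VariantCall.from_counts(
            sample_id, annotations[key].position, depth, alt_reads
        )

    def _somatic_call(sample_id: str, key: Key) -> VariantCall:
        depth = int(rng.integers(80, 401))
        target = rng.uniform(0.26, 0.60)
        alt = max(int(round(target * depth)), int(0.25 * depth) + 1, 3)
        return _call(sample_id, key, depth, alt)

    def _het_call(sample_id: str, key: Key) -> VariantCall:
        depth = int(rng.integers(80, 401))
        vaf = float(np.clip(rng.normal(0.5, 0.03), 0.42, 0.58))
        return _call(sample_id, key, depth, max(int(round(vaf * depth)), 1))

    def _artifact_call(sample_id: str, key: Key) -> VariantCall:
        depth = int(rng.integers(100, 401))
        alt = max(int(round(rng.uniform(0.12, 0.30) * depth)), 3)
        return _call(sample_id, key, depth, alt)

    calls: dict[str, list[VariantCall]] = {}
    for t in tumors:
        table = (
            [_somatic_call(t, k) for k in truth.somatic_by_sample[t]]
            + [_het_call(t, k) for k in germline_of[t]]
            + [_artifact_call(t, k) for k in artifacts_of[t]]
        )
        calls[t] = sorted(table, key=lambda c: c.key)

    for t, n in matched_normal_of.items():
        table = [_het_call(n, k) for k in germline_of[t]]
        # Reference-only coverage rows at the tumor's somatic and
        # artifact sites: the site was sequenced, no variant reads.
        for key in truth.somatic_by_sample[t] + artifacts_of[t]:
            table.append(_call(n, key, int(rng.integers(80, 301)), 0))
        calls[n] = sorted(table, key=lambda c: c.key)

    for p in pon_normals:
        n_g = min(40, len(germline_pool))
        idx = rng.choice(len(germline_pool), size=n_g, replace=False)
        table = [_het_call(p, germline_pool[j]) for j in sorted(idx)]
        for key, members in artifact_pon_members.items():
            if p in members:
                table.append(
                    _call(p, key, int(rng.integers(60, 201)), int(rng.integers(3, 11)))
                )
        calls[p] = sorted(table, key=lambda c: c.key)

    for h in hyperplastic:
        n_g = min(40, len(germline_pool))
        idx = rng.choice(len(germline_pool), size=n_g, replace=False)
        table = [_het_call(h, germline_pool[j]) for j in sorted(idx)]
        for key, members in artifact_control_members.items():
            if h in members:
                table.append(
                    _call(h, key, int(rng.integers(60, 201)), int(rng.integers(2, 9)))
                )
        calls[h] = sorted(table, key=lambda c: c.key)

    # --- RNA evidence ---------------------------------------------------------
    rna: dict[str, list[VariantCall]] = {}
    for t in rna_samples:
        table = []
        for key in truth.somatic_by_sample[t] + germline_of[t]:
            alt = int(rng.integers(5, 41))
            depth = alt + int(rng.integers(20, 81))
            table.append(_call(t, key, depth, alt))
        rna[t] = sorted(table, key=lambda c: c.key)

    # --- clinical table --------------------------------------------------------
    clinical: list[SurvivalRecord] = []
    if profile.survival is not None:
        clinical = generate_survival(profile, truth, int(rng.integers(0, 2**31)))

    bundle = CohortBundle(
        profile=profile,
        samples=samples,
        calls=calls,
        annotations=annotations,
        rna=rna,
        clinical=clinical,
        reference={CHROM: reference},
        gene_map=gene_map,
        matched_normal_of=matched_normal_of,
        truth=truth,
    )
    _verify_bundle(bundle)
    return bundle


def _verify_bundle(bundle: CohortBundle) -> None:
    """Structural self-checks against the profile (cheap, always run)."""
    profile = bundle.profile
    discovery = tumor_ids(profile)[: profile.n_discovery]
    for i, t in enumerate(discovery):
        planted = len(bundle.truth.somatic_by_sample[t])
        if planted != profile.per_sample_burden[i]:
            raise GenerationError(
                f"{t}: planted {planted} somatic, profile says "
                f"{profile.per_sample_burden[i]}"
            )
    for gene, freq in profile.gene_freqs.items():
        got = len(bundle.truth.gene_samples.get(gene, ()))
        if got != freq:
            raise GenerationError(f"{gene}: planted in {got} tumors, expected {freq}")


# ---------------------------------------------------------------------------
# Survival construction
# ---------------------------------------------------------------------------


def generate_survival(
    profile: CohortProfile, truth: PlantedTruth, seed: int
) -> list[SurvivalRecord]:
    """Build a clinical table hitting the profiled survival quantities.

    Group medians are exact: each group receives an uncensored event at
    the median-defining rank (risk-set sizes arranged so the curve hits
    0.5 exactly there). The cohort-level estimate at 36 months is made
    exact by censoring a block of patients at the start of follow-up,
    before the first event, which shrinks the risk set to a size where
    the target proportion is attainable; between that point and 36
    months nobody else is censored.
    """
    sv = profile.survival
    if sv is None:
        raise GenerationError("profile has no survival plan")
    rng = np.random.default_rng(seed)
    lo, hi = sv.followup_range
    if not (lo < sv.median_mutated < 36 and lo < sv.median_wildtype < 36 <= hi):
        raise GenerationError("survival plan medians must lie in (lo, 36)")

    all_tumors = tumor_ids(profile)
    mut_all = sorted(truth.gene_samples.get(sv.gene, set()))
    wt_all = sorted(set(all_tumors) - set(mut_all))
    n_clin = sv.n_clinical
    n_excl = profile.n_tumors - n_clin
    if n_excl < 0:
        raise GenerationError("n_clinical exceeds cohort size")

    # Early censorings (c0) make p * risk-set integral.
    p = sv.survival_at_36m
    for c0 in range(0, n_clin - 1):
        if abs(p * (n_clin - c0) - round(p * (n_clin - c0))) < 1e-9:
            break
    else:
        raise GenerationError(f"survival_at_36m={p} not attainable at n={n_clin}")
    n_risk = n_clin - c0
    deaths_by_36 = n_risk - round(p * n_risk)

    solution = None
    for e_m in range(0, n_excl + 1):
        e_w = n_excl - e_m
        if e_m > len(mut_all) or e_w > len(wt_all):
            continue
        m, w = len(mut_all) - e_m, len(wt_all) - e_w
        for c_m in range(0, c0 + 1):
            c_w = c0 - c_m
            rm, rw = m - c_m, w - c_w
            if rm < 2 or rw < 2 or rm % 2 or rw % 2:
                continue
            k_m, k_w = rm // 2, rw // 2  # deaths to reach each median
            d_lo = max(k_m, deaths_by_36 - rw)
            d_hi = min(rm, deaths_by_36 - k_w)
            if d_lo > d_hi:
                continue
            # The mutated group carries the worst feasible event
            # fraction: its inferior survival is the planted effect.
            solution = (e_m, e_w, c_m, c_w, d_hi)
            break
        if solution:
            break
    if solution is None:
        raise GenerationError("survival plan constraints jointly infeasible")
    e_m, e_w, c_m, c_w, d_m = solution
    d_w = deaths_by_36 - d_m

    def _group_times(
        size: int, n_early: int, median: float, n_deaths: int
    ) -> tuple[list[float], list[float], list[float]]:
        at_risk = size - n_early
        k = at_risk // 2
        if k > 1 and lo + 1.0 >= median:
            raise GenerationError("median too close to start of follow-up")
        pre = [median] if k == 1 else list(np.linspace(lo + 1.0, median, k))
        n_post = n_deaths - k
        if n_post and median + 1.0 > 35.0:
            raise GenerationError("median too close to the 36-month anchor")
        post = list(np.linspace(median + 1.0, 35.0, n_post)) if n_post else []
        n_surv = at_risk - n_deaths
        censored = list(np.linspace(37.0, hi, n_surv)) if n_surv else []
        return pre, post, censored

    records: list[SurvivalRecord] = []

    def _emit_group(
        ids: list[str], n_excluded: int, n_early: int, median: float,
        n_deaths: int, label: str,
    ) -> None:
        ids = list(ids)
        order = rng.permutation(len(ids))
        ids = [ids[j] for j in order]
        kept = ids[: len(ids) - n_excluded] if n_excluded else ids
        pre, post, censored = _group_times(len(kept), n_early, median, n_deaths)
        it = iter(kept)
        for _ in range(n_early):
            records.append(SurvivalRecord(next(it), lo, event=False, group=label))
        for t in pre + post:
            records.append(SurvivalRecord(next(it), float(t), event=True, group=label))
        for t in censored:
            records.append(SurvivalRecord(next(it), float(t), event=False, group=label))

    _emit_group(mut_all, e_m, c_m, sv.median_mutated, d_m, "mutated")
    _emit_group(wt_all, e_w, c_w, sv.median_wildtype, d_w, "wild_type")
    records.sort(key=lambda r: r.patient_id)

    # Self-check with the package's own product-limit estimator.
    mut_records = [r for r in records if r.group == "mutated"]
    wt_records = [r for r in records if r.group == "wild_type"]
    checks = (
        (surv.km_median(surv.km_estimate(mut_records)), sv.median_mutated),
        (surv.km_median(surv.km_estimate(wt_records)), sv.median_wildtype),
        (surv.survival_at(surv.km_estimate(records), 36.0), p),
    )
    for got, want in checks:
        if got is None or abs(got - want) > 1e-9:
            raise GenerationError(
                f"survival construction failed self-check: got {got}, wanted {want}"
            )
    return records
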