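"""Cohort-level cascade runners and the end-to-end pipeline.

``run_wes_cascade`` applies the exome discovery cascade to every
discovery tumor; ``run_targeted_cascade`` applies the deep-panel
cascade plus the functional-consequence consensus to every tumor.
``run_pipeline`` chains synthesis → filtering → statistics → survival
from a single YAML config, writing all artifacts plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .consequence import classify_stability, destabilizing_fraction, passes_functional_consensus
from .filtering import (
    FilterParams,
    FilterTrace,
    PanelOfNormals,
    build_pon,
    context_is_unique,
    targeted_filter,
    wes_discovery_filter,
)
from .io_model import (
    AnnotationRecord,
    VariantCall,
    load_reference_profile,
    read_cohort_profile,
    write_maf_like,
)
from .stats import mutation_burden, recurrence, spectrum_summary
from .survival import km_estimate, km_median, logrank_test, stratify_by_gene, survival_at
from .synthetic_cohort import CohortBundle, generate_cohort

__all__ = [
    "CascadeResult",
    "run_wes_cascade",
    "run_targeted_cascade",
    "mutated_samples_by_gene",
    "run_pipeline",
    "PipelineError",
]

Key = tuple[str, int, str, str]
Pair = tuple[VariantCall, AnnotationRecord]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""


@dataclass
class CascadeResult:
    """Outcome of one cascade over the whole cohort."""

    retained: dict[str, list[Pair]]  # sample_id -> retained (call, annotation)
    traces: dict[str, list[FilterTrace]]  # sample_id -> all traces, input order
    inputs: dict[str, list[Pair]]  # sample_id -> adjudicated pairs
    pon: Optional[PanelOfNormals] = None

    @property
    def n_input(self) -> int:
        return sum(len(v) for v in self.inputs.values())

    @property
    def n_retained(self) -> int:
        return sum(len(v) for v in self.retained.values())

    def retained_pairs(self) -> list[Pair]:
        return [pair for sample in sorted(self.retained) for pair in self.retained[sample]]

    def all_pairs_and_traces(self) -> tuple[list[Pair], list[FilterTrace]]:
        pairs, traces = [], []
        for sample in sorted(self.inputs):
            pairs.extend(self.inputs[sample])
            traces.extend(self.traces[sample])
        return pairs, traces


def run_wes_cascade(
    bundle: CohortBundle, params: FilterParams = FilterParams()
) -> CascadeResult:
    """Exome discovery cascade over all discovery tumors.

    The panel of normals is built from the unmatched healthy-donor
    saliva samples; matched-normal evidence and RNA concordance are
    used where the sample sheet says they exist. Context uniqueness is
    memoized per distinct 41-mer.
    """
    pon = build_pon(
        [bundle.calls[s.sample_id] for s in bundle.by_role("pon_normal")],
        params.pon_min_alt_reads,
    )
    context_cache: dict[str, bool] = {}

    def _ctx_unique(ann: AnnotationRecord) -> bool:
        if ann.context41 is None:
            return True
        if ann.context41 not in context_cache:
            context_cache[ann.context41] = context_is_unique(
                ann.context41, bundle.reference
            )
        return context_cache[ann.context41]

    result = CascadeResult(retained={}, traces={}, inputs={}, pon=pon)
    for sample in bundle.by_role("tumor_discovery"):
        sid = sample.sample_id
        pairs = bundle.table(sid)
        normal_lookup: dict[Key, VariantCall] = {}
        if sample.paired:
            normal_id = bundle.matched_normal_of[sid]
            normal_lookup = {c.key: c for c in bundle.calls[normal_id]}
        rna_table = bundle.rna.get(sid) if sample.has_rna else None
        traces, retained = [], []
        for call, ann in pairs:
            trace = wes_discovery_filter(
                call,
                ann,
                pon,
                matched_normal_call=normal_lookup.get(call.key) if sample.paired else None,
                rna_table=rna_table,
                has_rna=sample.has_rna,
                params=params,
                context_unique=_ctx_unique(ann),
            )
            traces.append(trace)
            if trace.retained:
                retained.append((call, ann))
        result.inputs[sid] = pairs
        result.traces[sid] = traces
        result.retained[sid] = retained
    return result


def run_targeted_cascade(
    bundle: CohortBundle,
    params: FilterParams = FilterParams(),
    apply_consensus: bool = True,
) -> CascadeResult:
    """Targeted deep-panel cascade over all tumors.

    Restricted to variants in panel genes (the panel is what was
    sequenced). The subtraction panel unions the sequenced matched
    saliva normals with the hyperplastic lymph-node controls. When
    ``apply_consensus`` is set, retained variants must additionally
    clear the 4-of-9 predictor consensus (missense) or be truncating.
    """
    panel = set(bundle.profile.panel_genes)
    control_tables = [
        bundle.calls[s.sample_id]
        for s in bundle.samples
        if s.role in ("matched_normal", "hyperplastic_control")
    ]
    pon_plus_controls = build_pon(control_tables, params.pon_min_alt_reads)

    result = CascadeResult(retained={}, traces={}, inputs={}, pon=pon_plus_controls)
    for sample in bundle.tumors():
        sid = sample.sample_id
        pairs = [(c, a) for c, a in bundle.table(sid) if a.gene in panel]
        traces, retained = [], []
        for call, ann in pairs:
            trace = targeted_filter(call, ann, pon_plus_controls, params)
            if apply_consensus:
                trace.add(
                    "functional_consensus",
                    passes_functional_consensus(ann, params.min_damaging_votes),
                    ann.predictor_calls,
                )
            traces.append(trace)
            if trace.retained:
                retained.append((call, ann))
        result.inputs[sid] = pairs
        result.traces[sid] = traces
        result.retained[sid] = retained
    return result


def mutated_samples_by_gene(result: CascadeResult) -> dict[str, set[str]]:
    """Gene → samples with ≥1 retained nonsynonymous variant."""
    out: dict[str, set[str]] = {}
    for sid, pairs in result.retained.items():
        for _, ann in pairs:
            if ann.is_nonsynonymous:
                out.setdefault(ann.gene, set()).add(sid)
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def _write_trace_tsv(result: CascadeResult, path: Path) -> int:
    rows = 0
    with open(path, "w") as handle:
        handle.write(
            "sample_id\tchrom\tpos\tref\talt\tgate\tpassed\tobserved\tverdict\n"
        )
        for sid in sorted(result.traces):
            for trace in result.traces[sid]:
                chrom, pos, ref, alt = trace.key
                for gate in trace.gates:
                    handle.write(
                        f"{sid}\t{chrom}\t{pos}\t{ref}\t{alt}\t{gate.name}"
                        f"\t{int(gate.passed)}\t{gate.observed}\t{trace.final_verdict}\n"
                    )
                    rows += 1
    return rows


def _summary_dict(
    bundle: CohortBundle,
    wes_result: CascadeResult,
    targeted_result: CascadeResult,
    min_recurrence: int,
) -> dict:
    profile = bundle.profile
    wes_retained = wes_result.retained_pairs()
    spectrum = spectrum_summary([c for c, _ in wes_retained])
    burden = mutation_burden(
        {
            sid: sum(1 for _, a in pairs if a.is_nonsynonymous)
            for sid, pairs in wes_result.retained.items()
        },
        profile.exome_mb,
    )
    gene_sample_pairs = [
        (ann.gene, sid)
        for sid, pairs in targeted_result.retained.items()
        for _, ann in pairs
        if ann.is_nonsynonymous
    ]
    matrix = recurrence(
        gene_sample_pairs, all_samples=[s.sample_id for s in bundle.tumors()]
    )
    recurrent = matrix.recurrent_genes(min_recurrence)
    stability = {}
    for gene in sorted(profile.stability_plan):
        calls = [
            classify_stability(ann.ddg)
            for pairs in targeted_result.retained.values()
            for _, ann in pairs
            if ann.gene == gene and ann.effect == "missense"
        ]
        k, n = destabilizing_fraction(calls)
        stability[gene] = {"destabilizing": k, "missense_with_ddg": n}
    return {
        "spectrum": {
            "ti_count": spectrum.ti_count,
            "tv_count": spectrum.tv_count,
            "ratio": spectrum.ratio,
            "ratio_truncated": spectrum.ratio_truncated,
            "class_counts": spectrum.class_counts,
            "gc_targeted_fraction": spectrum.gc_targeted_fraction,
        },
        "burden": {
            "median_count": burden.median_count,
            "count_range": list(burden.count_range),
            "median_rate_per_mb": burden.median_rate,
            "rate_range_per_mb": list(burden.rate_range),
            "exome_mb": burden.exome_mb,
            "per_sample_counts": burden.counts,
        },
        "recurrence": {
            "min_samples": min_recurrence,
            "n_recurrent_genes": len(recurrent),
            "recurrent_genes": [[g, c] for g, c in recurrent],
        },
        "stability": stability,
        "panel_size": len(profile.panel_genes),
    }


def _survival_dict(bundle: CohortBundle, targeted_result: CascadeResult, gene: str) -> dict:
    by_gene = mutated_samples_by_gene(targeted_result)
    mutated, wildtype = stratify_by_gene(by_gene, bundle.clinical, gene)
    curves = {}
    for label, records in (("mutated", mutated), ("wild_type", wildtype)):
        curve = km_estimate(records)
        curves[label] = {
            "n": len(records),
            "event_times": [float(t) for t in curve.event_times],
            "survival": [float(s) for s in curve.survival],
            "median_months": km_median(curve),
        }
    overall = km_estimate(bundle.clinical)
    test = logrank_test(mutated, wildtype)
    return {
        "gene": gene,
        "groups": curves,
        "overall": {
            "n": len(bundle.clinical),
            "survival_at_36m": survival_at(overall, 36.0),
            "median_months": km_median(overall),
        },
        "logrank": {
            "statistic": test.statistic,
            "p_value": test.p_value,
            "observed": list(test.observed),
            "expected": list(test.expected),
            "significant": test.significant,
        },
    }


def run_pipeline(config_path: str | Path) -> dict:
    """Run synth → filter → stats → survival from one YAML config.

    Returns the manifest dict (also written to ``manifest.json``).
    Outputs are byte-identical across reruns with the same config and
    seed, manifest timestamps aside.
    """
    config_path = Path(config_path)
    with open(config_path) as handle:
        config = yaml.safe_load(handle) or {}
    outdir = Path(config.get("outdir", "somatic_screen_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = FilterParams(**config.get("thresholds", {}))
    min_recurrence = int(config.get("min_recurrence", 2))

    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "version": __version__,
        "stages": {},
        "status": "running",
    }

    current_stage = {"name": None}

    def _stage(name: str):
        manifest["stages"][name] = {"started": time.time()}
        current_stage["name"] = name
        return manifest["stages"][name]

    def _log(stage_rec: dict, **counts) -> None:
        stage_rec.update(counts)
        stage_rec["finished"] = time.time()
        print(
            json.dumps(
                {"stage": current_stage["name"], "status": "ok", **counts},
                default=str,
            )
        )

    try:
        stage = _stage("synth")
        profile_spec = config.get("profile", "reference")
        if profile_spec == "reference":
            profile = load_reference_profile()
        else:
            profile_path = Path(profile_spec)
            if not profile_path.is_absolute():
                profile_path = config_path.parent / profile_path
            if not profile_path.exists():
                raise PipelineError(f"profile file not found: {profile_path}")
            profile = read_cohort_profile(profile_path)
        bundle = generate_cohort(profile, seed)
        cohort_dir = outdir / "cohort"
        bundle.write(cohort_dir)
        _log(stage, n_samples=len(bundle.samples),
             n_calls=sum(len(v) for v in bundle.calls.values()))

        stage = _stage("wes_filter")
        wes_result = run_wes_cascade(bundle, params)
        pairs, traces = wes_result.all_pairs_and_traces()
        write_maf_like(pairs, traces, outdir / "retained_wes.tsv")
        _write_trace_tsv(wes_result, outdir / "trace_wes.tsv")
        _log(stage, n_in=wes_result.n_input, n_retained=wes_result.n_retained)

        stage = _stage("targeted_filter")
        targeted_result = run_targeted_cascade(bundle, params)
        pairs, traces = targeted_result.all_pairs_and_traces()
        write_maf_like(pairs, traces, outdir / "retained_targeted.tsv")
        _write_trace_tsv(targeted_result, outdir / "trace_targeted.tsv")
        _log(stage, n_in=targeted_result.n_input, n_retained=targeted_result.n_retained)

        stage = _stage("stats")
        summary = _summary_dict(bundle, wes_result, targeted_result, min_recurrence)
        with open(outdir / "summary.json", "w") as handle:
            json.dump(summary, handle, indent=1, sort_keys=True)
        gene_sample_pairs = [
            (ann.gene, sid)
            for sid, prs in targeted_result.retained.items()
            for _, ann in prs
            if ann.is_nonsynonymous
        ]
        matrix = recurrence(
            gene_sample_pairs, all_samples=[s.sample_id for s in bundle.tumors()]
        )
        matrix.matrix.to_csv(outdir / "recurrence.tsv", sep="\t")
        _log(stage, n_recurrent=summary["recurrence"]["n_recurrent_genes"])

        if bundle.clinical:
            stage = _stage("survival")
            gene = config.get("survival_gene") or (
                profile.survival.gene if profile.survival else None
            )
            km = _survival_dict(bundle, targeted_result, gene)
            with open(outdir / "km.json", "w") as handle:
                json.dump(km, handle, indent=1, sort_keys=True)
            _log(stage, n_clinical=len(bundle.clinical))

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "error"
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=1, sort_keys=True)
        raise
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return manifest
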