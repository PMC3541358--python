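"""End-to-end orchestration: read inputs, run the analysis, write reports.

Each ``run_*`` function corresponds to one analysis stage and is a thin
composition of the library modules; the CLI wraps these one-to-one.
Reports are written as TSV (per-record tables) plus JSON (summaries with
provenance) and are deterministic for fixed inputs apart from the
timestamp field.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

from . import __version__
from .annotations import (
    Vocabulary,
    default_vocabulary,
    profiles_from_calls,
    read_bed,
    read_expression_table,
    read_line_calls,
    aggregate_lines,
    restrict_to_comparable,
)
from .conservation import (
    group_ratio_comparison,
    read_bedgraph,
    read_fixed_step_wiggle,
    stratified_score_comparison,
    tracks_from_coverage,
)
from .divergence import (
    UndefinedDivergenceError,
    compare_profiles,
    summarize_dataset,
    write_divergence_table,
    write_summary_json,
)
from .simulate import SimulationConfig, recover_parameters, simulate_dataset, write_dataset
from .trans_gene import (
    classify_records,
    read_fourway_table,
    summarize_gene_set,
    write_fourway_table,
)

__all__ = [
    "run_compare",
    "run_fourway",
    "run_conservation",
    "run_simulate",
]

log = logging.getLogger("cnediv")

REPORT_SCHEMA_VERSION = 1


def _provenance(config: Mapping) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": dict(config),
    }


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def _load_vocabulary(path: str | Path | None) -> Vocabulary:
    return Vocabulary.from_yaml(path) if path else default_vocabulary()


def run_compare(
    annotations: str | Path,
    out_dir: str | Path,
    vocabulary: str | Path | None = None,
    line_calls: str | Path | None = None,
    threshold: float = 0.75,
) -> dict:
    """Cross-species divergence analysis of transgenic profiles.

    Reads the expression table (and, if given, a replicate line-call
    table whose majority-rule aggregates replace/extend the zebrafish
    transgenic calls), restricts profiles to comparable anatomy, compares
    species per CNE and writes divergence.tsv + summary.json.  CNEs with
    no active comparable domain in either species are excluded with a
    warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vocab = _load_vocabulary(vocabulary)
    calls = read_expression_table(annotations, vocab)
    if line_calls is not None:
        raw = read_line_calls(line_calls, vocab)
        slots = sorted({(c.cne_id, c.domain) for c in raw})
        by_slot: dict[tuple[str, str], list] = {}
        for c in raw:
            by_slot.setdefault((c.cne_id, c.domain), []).append(c)
        existing = {
            (c.cne_id, c.species, c.assay, c.domain) for c in calls
        }
        for cne_id, domain in slots:
            agg = aggregate_lines(by_slot[(cne_id, domain)], cne_id, domain)
            key = (agg.cne_id, agg.species, agg.assay, agg.domain)
            if key in existing:
                calls = [c for c in calls if (c.cne_id, c.species, c.assay, c.domain) != key]
            calls.append(agg)

    profiles = profiles_from_calls(calls)
    cne_ids = sorted({p.cne_id for p in profiles.values()})
    results = []
    excluded = []
    kept_profiles = []
    for cne_id in cne_ids:
        mouse = profiles.get((cne_id, "mouse", "transgenic"))
        zebra = profiles.get((cne_id, "zebrafish", "transgenic"))
        if mouse is None or zebra is None:
            log.warning("%s: missing transgenic profile in one species; skipped", cne_id)
            excluded.append(cne_id)
            continue
        mouse = restrict_to_comparable(mouse, vocab)
        zebra = restrict_to_comparable(zebra, vocab)
        try:
            results.append(compare_profiles(mouse, zebra, threshold))
            kept_profiles.extend([mouse, zebra])
        except UndefinedDivergenceError as exc:
            log.warning("%s", exc)
            excluded.append(cne_id)
    summary = summarize_dataset(results, kept_profiles)

    write_divergence_table(results, out / "divergence.tsv")
    write_summary_json(summary, out / "summary.json")
    report = {
        "provenance": _provenance(
            {
                "annotations": str(annotations),
                "vocabulary": str(vocabulary) if vocabulary else "builtin",
                "line_calls": str(line_calls) if line_calls else None,
                "threshold": threshold,
            }
        ),
        "summary": summary.to_dict(),
        "excluded_cnes": excluded,
        "results": [
            {
                "cne_id": r.cne_id,
                "shared": sorted(r.shared),
                "mouse_only": sorted(r.mouse_only),
                "zebrafish_only": sorted(r.zebrafish_only),
                "fraction": r.fraction,
                "category": r.category,
            }
            for r in results
        ],
    }
    _write_json(report, out / "compare_report.json")
    return report


def run_fourway(
    table: str | Path,
    out_dir: str | Path,
    rule: str = "asymmetric",
) -> dict:
    """Classify a four-way Mt/Zt/Mg/Zg table and summarize the gene set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = classify_records(read_fourway_table(table), rule)
    summary = summarize_gene_set(records)
    write_fourway_table(records, out / "fourway.tsv")
    report = {
        "provenance": _provenance({"table": str(table), "rule": rule}),
        "summary": summary.to_dict(),
    }
    _write_json(report, out / "fourway_report.json")
    return report


def run_conservation(
    bed: str | Path,
    scores: str | Path,
    groups: Mapping[str, str] | str | Path,
    out_dir: str | Path,
    kind: str = "phyloP",
    low: float = -1.0,
    high: float = 1.0,
) -> dict:
    """Conserved-vs-lost comparison of per-element conservation scores.

    ``groups`` maps cne_id to conserved/lost (or a TSV path with those
    two columns); ``scores`` is a bedGraph or fixedStep wiggle file
    (selected by extension).  Writes a JSON report with the stratified
    ANOVA and, for phyloP, the pooled accelerated/constrained ratio
    comparison.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(groups, Mapping):
        mapping: dict[str, str] = {}
        with open(groups) as handle:
            for lineno, line in enumerate(handle, start=1):
                fields = line.strip().split("\t")
                if not line.strip() or line.startswith("#"):
                    continue
                if lineno == 1 and fields[0] == "cne_id":
                    continue
                mapping[fields[0]] = fields[1]
        groups = mapping
    cnes = read_bed(bed)
    reader = (
        read_fixed_step_wiggle
        if str(scores).endswith((".wig", ".wiggle"))
        else read_bedgraph
    )
    tracks = tracks_from_coverage(reader(scores), cnes, kind)
    conserved = [t for t in tracks if groups.get(t.cne_id) == "conserved"]
    lost = [t for t in tracks if groups.get(t.cne_id) == "lost"]
    stratified = stratified_score_comparison(conserved, lost, kind)
    report = {
        "provenance": _provenance(
            {
                "bed": str(bed),
                "scores": str(scores),
                "kind": kind,
                "low": low,
                "high": high,
            }
        ),
        "n_conserved": len(conserved),
        "n_lost": len(lost),
        "stratified": {
            "kind": stratified.kind,
            "mean_conserved": stratified.mean_a,
            "mean_lost": stratified.mean_b,
            "test": stratified.test.to_dict(),
        },
    }
    if kind == "phyloP":
        # ratio is lost-vs-conserved so the fold reads "times higher in lost"
        ratio = group_ratio_comparison(lost, conserved, low, high)
        report["accel_constraint_ratio"] = {
            "counts_lost": ratio.counts_a,
            "counts_conserved": ratio.counts_b,
            "ratio_lost": ratio.ratio_a,
            "ratio_conserved": ratio.ratio_b,
            "fold": ratio.fold,
            "test": ratio.test.to_dict(),
        }
    _write_json(report, out / "conservation_report.json")
    return report


def run_simulate(
    out_dir: str | Path,
    config: SimulationConfig | Mapping | None = None,
    seed: int | None = None,
    recover: bool = False,
) -> dict:
    """Generate a synthetic dataset directory (optionally with recovery).

    ``config`` may be a SimulationConfig or a mapping of overrides to the
    defaults; ``seed`` overrides the config seed when given.
    """
    if config is None:
        config = SimulationConfig()
    elif isinstance(config, Mapping):
        config = SimulationConfig(**config)
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    dataset = simulate_dataset(config)
    paths = write_dataset(dataset, out_dir)
    report = {
        "provenance": _provenance(config.__dict__),
        "files": {k: str(v) for k, v in paths.items()},
        "redraw_count": dataset.truth.redraw_count,
    }
    if recover:
        rec = recover_parameters(dataset)
        report["recovery"] = {
            "divergent_domain_fraction": rec.divergent_domain_fraction,
            "expected_divergent_fraction": rec.expected_divergent_fraction,
            "trans_and_gene_fraction": rec.trans_and_gene_fraction,
            "phylop_mean_conserved": rec.phylop_mean_conserved,
            "phylop_mean_lost": rec.phylop_mean_lost,
            "stratified_p": rec.stratified.test.p_value if rec.stratified else None,
        }
    _write_json(report, Path(out_dir) / "simulate_report.json")
    return report
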