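"""Four-way consistency between enhancer activity and gene expression.

For each anatomical domain of a CNE with a confidently associated target
gene, four presence calls are compared: mouse transgenic reporter (Mt),
zebrafish transgenic reporter (Zt), mouse endogenous gene (Mg) and
zebrafish endogenous gene (Zg).  A domain supports a trans-change driving
gene-expression evolution (``trans_and_gene``) when both the reporter and
the gene differ between species and each species' reporter mirrors its
own gene.  A domain where the gene diverged but the reporter did not
(``notrans_and_gene``) is evidence that the expression change is not read
by the tested element.  Everything else is ``unclassified``.

Two rule variants are provided.  The default ``asymmetric`` rule requires
the concordant reporter calls of a notrans domain to match the *mouse*
gene (the tested sequences are mammalian, so mouse is the native trans
environment); the ``symmetric`` variant requires only reporter
concordance plus gene divergence.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotations import AnnotationError, DuplicateRecordError, ParseError, _open_text, parse_presence
from .stats import StatTestResult, two_sample_t

__all__ = [
    "TRANS_AND_GENE",
    "NOTRANS_AND_GENE",
    "UNCLASSIFIED",
    "FourWayRecord",
    "GeneSetSummary",
    "GeneDivergenceComparison",
    "classify_fourway",
    "classify_records",
    "summarize_gene_set",
    "compare_divergence_by_gene_status",
    "read_fourway_table",
    "write_fourway_table",
    "load_divergent_gene_table",
]

TRANS_AND_GENE = "trans_and_gene"
NOTRANS_AND_GENE = "notrans_and_gene"
UNCLASSIFIED = "unclassified"

RULES = ("asymmetric", "symmetric")


@dataclass(frozen=True)
class FourWayRecord:
    """One domain's Mt/Zt/Mg/Zg booleans plus its consistency label."""

    cne_id: str
    domain: str
    mt: bool
    zt: bool
    mg: bool
    zg: bool
    label: str = UNCLASSIFIED


@dataclass(frozen=True)
class GeneSetSummary:
    """Dataset-level counts over classified four-way records."""

    n_cnes: int
    n_trans_consistent: int
    label_counts: dict[str, int] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_trans_consistent / self.n_cnes if self.n_cnes else 0.0

    def to_dict(self) -> dict:
        return {
            "n_cnes": self.n_cnes,
            "n_trans_consistent": self.n_trans_consistent,
            "fraction": self.fraction,
            "label_counts": dict(self.label_counts),
        }


@dataclass(frozen=True)
class GeneDivergenceComparison:
    """Divergence-fraction comparison between two gene sets."""

    mean_divergent: float
    mean_conserved: float
    test: StatTestResult


def classify_fourway(
    mt: bool, zt: bool, mg: bool, zg: bool, rule: str = "asymmetric"
) -> str:
    """Label one domain's four-way presence pattern.

    ``trans_and_gene``: reporter and gene both differ between species and
    each species' reporter matches its own gene — only (+,-,+,-) and
    (-,+,-,+) qualify.  ``notrans_and_gene``: concordant reporters, a
    diverged gene, and (asymmetric rule) the reporters match the mouse
    gene.  All other patterns are ``unclassified``.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}, got {rule!r}")
    if mt != zt and mg != zg and mt == mg and zt == zg:
        return TRANS_AND_GENE
    if mt == zt and mg != zg:
        if rule == "symmetric" or mt == mg:
            return NOTRANS_AND_GENE
    return UNCLASSIFIED


def classify_records(
    records: Iterable[FourWayRecord], rule: str = "asymmetric"
) -> list[FourWayRecord]:
    """Return records with the label column filled in by the chosen rule."""
    return [
        replace(r, label=classify_fourway(r.mt, r.zt, r.mg, r.zg, rule))
        for r in records
    ]


def summarize_gene_set(records: Sequence[FourWayRecord]) -> GeneSetSummary:
    """Count trans-consistent CNEs and per-label rows.

    A CNE is trans-consistent when at least one of its domains is labeled
    ``trans_and_gene``.
    """
    if not records:
        return GeneSetSummary(0, 0, {})
    cnes: dict[str, bool] = {}
    label_counts: dict[str, int] = {}
    for rec in records:
        cnes[rec.cne_id] = cnes.get(rec.cne_id, False) or rec.label == TRANS_AND_GENE
        label_counts[rec.label] = label_counts.get(rec.label, 0) + 1
    return GeneSetSummary(
        n_cnes=len(cnes),
        n_trans_consistent=sum(cnes.values()),
        label_counts=label_counts,
    )


def compare_divergence_by_gene_status(
    fracs_divergent_genes: Sequence[float],
    fracs_conserved_genes: Sequence[float],
    welch: bool = True,
) -> GeneDivergenceComparison:
    """Compare per-CNE reporter divergence fractions between gene sets.

    The first sample holds CNEs whose target genes changed expression
    between species, the second those whose genes did not; the test is a
    two-sample t on the divergence fractions.
    """
    test = two_sample_t(fracs_divergent_genes, fracs_conserved_genes, welch=welch)
    return GeneDivergenceComparison(
        mean_divergent=float(np.mean(fracs_divergent_genes)),
        mean_conserved=float(np.mean(fracs_conserved_genes)),
        test=test,
    )


# ---------------------------------------------------------------------------
# I/O

_FOURWAY_COLUMNS = ("cne_id", "domain", "mt", "zt", "mg", "zg")


def read_fourway_table(source) -> list[FourWayRecord]:
    """Read a TSV with columns cne_id, domain, mt, zt, mg, zg (+/-)."""
    handle = _open_text(source)
    reader = csv.DictReader(handle, delimiter="\t")
    if reader.fieldnames is None:
        return []
    missing = [c for c in _FOURWAY_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise ParseError(f"missing columns: {', '.join(missing)}", 1)
    records: list[FourWayRecord] = []
    seen: set[tuple[str, str]] = set()
    for row in reader:
        lineno = reader.line_num
        values = [row.get(c) for c in _FOURWAY_COLUMNS]
        if any(v is None or v == "" for v in values):
            raise ParseError("incomplete row", lineno)
        cne, domain = values[0].strip(), values[1].strip()
        key = (cne, domain)
        if key in seen:
            raise DuplicateRecordError(f"line {lineno}: duplicate record {key}")
        seen.add(key)
        mt, zt, mg, zg = (parse_presence(v, lineno) for v in values[2:])
        records.append(FourWayRecord(cne, domain, mt, zt, mg, zg))
    return records


def write_fourway_table(records: Sequence[FourWayRecord], path: str | Path) -> None:
    """Write classified records as TSV with a trailing label column."""
    with open(path, "w") as handle:
        handle.write("\t".join([*_FOURWAY_COLUMNS, "label"]) + "\n")
        for r in records:
            flags = "\t".join("+" if v else "-" for v in (r.mt, r.zt, r.mg, r.zg))
            handle.write(f"{r.cne_id}\t{r.domain}\t{flags}\t{r.label}\n")


def load_divergent_gene_table() -> list[FourWayRecord]:
    """Load the packaged four-way table of CNEs with divergent target genes.

    Eleven CNEs whose associated genes show major expression-domain
    changes between mouse and zebrafish, with per-domain Mt/Zt/Mg/Zg
    presence calls (39 domain rows).
    """
    ref = resources.files("cnediv").joinpath("data/fourway_divergent_genes.tsv")
    with ref.open() as handle:
        return read_fourway_table(handle)
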