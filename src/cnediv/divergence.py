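"""Cross-species divergence of transgenic expression profiles.

For each CNE the mouse and zebrafish transgenic profiles (restricted to
comparable anatomy) are compared by set algebra.  The divergence fraction
is the share of species-specific domains among all domains active in at
least one species; a CNE is *identical* at fraction 0, *global* at or
above the threshold (default 0.75, i.e. three quarters or more of its
active domains are species-specific), and *partial* in between.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotations import AnnotationError, ExpressionProfile

__all__ = [
    "CATEGORY_IDENTICAL",
    "CATEGORY_PARTIAL",
    "CATEGORY_GLOBAL",
    "UndefinedDivergenceError",
    "DivergenceResult",
    "DatasetSummary",
    "compare_profiles",
    "summarize_dataset",
    "write_divergence_table",
    "write_summary_json",
]

CATEGORY_IDENTICAL = "identical"
CATEGORY_PARTIAL = "partial"
CATEGORY_GLOBAL = "global"


class UndefinedDivergenceError(AnnotationError):
    """Neither species has any active comparable domain for this CNE."""


@dataclass(frozen=True)
class DivergenceResult:
    """Per-CNE cross-species comparison of transgenic activity."""

    cne_id: str
    shared: frozenset[str]
    mouse_only: frozenset[str]
    zebrafish_only: frozenset[str]
    threshold: float = 0.75

    @property
    def union_size(self) -> int:
        return len(self.shared) + len(self.mouse_only) + len(self.zebrafish_only)

    @property
    def n_specific(self) -> int:
        return len(self.mouse_only) + len(self.zebrafish_only)

    @property
    def fraction(self) -> float:
        return self.n_specific / self.union_size

    @property
    def category(self) -> str:
        frac = self.fraction
        if frac == 0:
            return CATEGORY_IDENTICAL
        if frac >= self.threshold:
            return CATEGORY_GLOBAL
        return CATEGORY_PARTIAL


@dataclass
class DatasetSummary:
    """Dataset-level counts over a collection of divergence results."""

    n_cnes: int = 0
    n_any_specific: int = 0
    n_global: int = 0
    n_identical: int = 0
    mean_domains: dict[str, float] = field(default_factory=dict)
    total_domains: dict[str, int] = field(default_factory=dict)
    ectopic_counts: dict[str, Counter] = field(default_factory=dict)

    @property
    def ectopic_totals(self) -> dict[str, int]:
        return {sp: sum(cnt.values()) for sp, cnt in self.ectopic_counts.items()}

    def to_dict(self) -> dict:
        return {
            "n_cnes": self.n_cnes,
            "n_any_specific": self.n_any_specific,
            "n_global": self.n_global,
            "n_identical": self.n_identical,
            "mean_domains": dict(self.mean_domains),
            "total_domains": dict(self.total_domains),
            "ectopic_counts": {sp: dict(c) for sp, c in self.ectopic_counts.items()},
            "ectopic_totals": self.ectopic_totals,
        }


def compare_profiles(
    mouse: ExpressionProfile,
    zebrafish: ExpressionProfile,
    threshold: float = 0.75,
) -> DivergenceResult:
    """Compare one CNE's transgenic profiles between mouse and zebrafish.

    Both profiles must belong to the same CNE and already be restricted to
    comparable anatomy.  The divergence denominator is the union of domains
    active in either species; a CNE active in neither species has no
    defined divergence and raises :class:`UndefinedDivergenceError`.
    """
    if mouse.cne_id != zebrafish.cne_id:
        raise AnnotationError(
            f"profile CNE mismatch: {mouse.cne_id!r} vs {zebrafish.cne_id!r}"
        )
    if (mouse.species, zebrafish.species) != ("mouse", "zebrafish"):
        raise AnnotationError("expected a (mouse, zebrafish) profile pair")
    if not 0 < threshold <= 1:
        raise AnnotationError(f"threshold {threshold} outside (0, 1]")
    union = mouse.domains | zebrafish.domains
    if not union:
        raise UndefinedDivergenceError(
            f"{mouse.cne_id}: no active comparable domain in either species"
        )
    return DivergenceResult(
        cne_id=mouse.cne_id,
        shared=frozenset(mouse.domains & zebrafish.domains),
        mouse_only=frozenset(mouse.domains - zebrafish.domains),
        zebrafish_only=frozenset(zebrafish.domains - mouse.domains),
        threshold=threshold,
    )


def summarize_dataset(
    results: Sequence[DivergenceResult],
    profiles: Iterable[ExpressionProfile] | Mapping | None = None,
) -> DatasetSummary:
    """Aggregate per-CNE divergence results into dataset-level counts.

    ``profiles`` (optional) supplies the per-species transgenic profiles
    used for mean/total active-domain statistics; each mouse-only domain is
    attributed to mouse and each zebrafish-only domain to zebrafish in the
    ectopic counts.
    """
    ids = [r.cne_id for r in results]
    if len(set(ids)) != len(ids):
        raise AnnotationError("multiple divergence results for one CNE")
    summary = DatasetSummary(n_cnes=len(results))
    summary.ectopic_counts = {"mouse": Counter(), "zebrafish": Counter()}
    for res in results:
        if res.fraction == 0:
            summary.n_identical += 1
        else:
            summary.n_any_specific += 1
        if res.category == CATEGORY_GLOBAL:
            summary.n_global += 1
        summary.ectopic_counts["mouse"].update(res.mouse_only)
        summary.ectopic_counts["zebrafish"].update(res.zebrafish_only)
    if profiles is not None:
        if isinstance(profiles, Mapping):
            profiles = profiles.values()
        sizes: dict[str, list[int]] = {"mouse": [], "zebrafish": []}
        for prof in profiles:
            if prof.assay == "transgenic" and prof.species in sizes:
                sizes[prof.species].append(len(prof.domains))
        summary.mean_domains = {
            sp: (sum(v) / len(v) if v else 0.0) for sp, v in sizes.items()
        }
        summary.total_domains = {sp: sum(v) for sp, v in sizes.items()}
    return summary


def _fmt_set(domains: frozenset[str]) -> str:
    return ",".join(sorted(domains)) if domains else "."


def write_divergence_table(
    results: Sequence[DivergenceResult], path: str | Path
) -> None:
    """Write the per-CNE divergence report as TSV."""
    with open(path, "w") as handle:
        handle.write(
            "cne_id\tshared\tmouse_only\tzebrafish_only\tunion_size\t"
            "fraction\tcategory\n"
        )
        for res in results:
            handle.write(
                f"{res.cne_id}\t{_fmt_set(res.shared)}\t{_fmt_set(res.mouse_only)}"
                f"\t{_fmt_set(res.zebrafish_only)}\t{res.union_size}"
                f"\t{res.fraction:.4f}\t{res.category}\n"
            )


def write_summary_json(summary: DatasetSummary, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(summary.to_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")
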