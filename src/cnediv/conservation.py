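"""Sequence-conservation analysis of ancestral CNEs.

Ancestral CNEs (elements detectable in the gnathostome ancestor) fall
into two groups by whether they are still recognisable in the zebrafish
genome.  This module calls ancestry from homology-search hit tables,
aggregates per-base conservation scores (phyloP, phastCons) per element,
computes alignment identity, and runs the conserved-vs-lost group
comparisons: ANOVA on per-element mean scores and a chi-square test on
pooled counts of accelerated (phyloP < -1) vs constrained (phyloP > +1)
positions.

Score tracks are read from text bedGraph or fixed-step wiggle files and
intersected with CNE intervals; alignments from multi-FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .annotations import CNERecord, ParseError, _open_text
from .stats import StatTestResult, anova_oneway, chi_square_2x2

__all__ = [
    "ScoreTrack",
    "AncestryCall",
    "AlignmentBlock",
    "GroupRatioResult",
    "StratifiedComparison",
    "classify_ancestral",
    "mean_track_score",
    "accel_constraint_counts",
    "group_ratio_comparison",
    "mean_pairwise_identity",
    "stratified_score_comparison",
    "read_bedgraph",
    "read_fixed_step_wiggle",
    "tracks_from_coverage",
    "read_alignment_fasta",
    "read_hits_table",
]

TRACK_KINDS = ("phyloP", "phastCons")


@dataclass(frozen=True)
class ScoreTrack:
    """Per-base conservation scores covering one element."""

    cne_id: str
    kind: str
    values: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        if len(self.values) == 0:
            raise ValueError(f"{self.cne_id}: empty score track")
        if self.kind == "phastCons" and not all(0.0 <= v <= 1.0 for v in self.values):
            raise ValueError(f"{self.cne_id}: phastCons values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class AncestryCall:
    """Ancestry decision for one element from homology-search hits."""

    cne_id: str
    best_evalue: float | None
    ancestral: bool


@dataclass(frozen=True)
class AlignmentBlock:
    """A gapped multiple alignment of orthologous element sequences."""

    sequences: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least two sequences")
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise ValueError("aligned sequences must have equal length")
        if all(set(s) <= {"-"} for s in self.sequences):
            raise ValueError("alignment has no non-gap column")
        if len(self.labels) != len(self.sequences):
            raise ValueError("one label per sequence required")


@dataclass(frozen=True)
class GroupRatioResult:
    """Pooled accelerated/constrained position ratios for two groups."""

    counts_a: tuple[int, int]
    counts_b: tuple[int, int]
    ratio_a: float
    ratio_b: float
    fold: float
    test: StatTestResult


@dataclass(frozen=True)
class StratifiedComparison:
    """Group means of per-element mean scores plus the ANOVA result."""

    kind: str
    mean_a: float
    mean_b: float
    element_means_a: tuple[float, ...]
    element_means_b: tuple[float, ...]
    test: StatTestResult


# ---------------------------------------------------------------------------
# Operations


def classify_ancestral(
    hits: Iterable[tuple[str, float]],
    threshold: float = 1e-5,
    all_ids: Iterable[str] | None = None,
) -> list[AncestryCall]:
    """Call elements ancestral from homology-search significance values.

    An element is ancestral when its best (smallest) hit significance is
    strictly below ``threshold``; elements listed in ``all_ids`` but
    absent from the hit table are called non-ancestral.
    """
    best: dict[str, float] = {}
    for cne_id, evalue in hits:
        evalue = float(evalue)
        if evalue < 0:
            raise ValueError(f"{cne_id}: negative significance value {evalue}")
        if cne_id not in best or evalue < best[cne_id]:
            best[cne_id] = evalue
    ids = list(best)
    if all_ids is not None:
        ids = list(dict.fromkeys([*all_ids, *best]))
    return [
        AncestryCall(
            cne_id,
            best.get(cne_id),
            cne_id in best and best[cne_id] < threshold,
        )
        for cne_id in ids
    ]


def mean_track_score(track: ScoreTrack) -> float:
    """Arithmetic mean of the per-base scores of one element."""
    return float(np.mean(track.values))


def accel_constraint_counts(
    track: ScoreTrack, low: float = -1.0, high: float = 1.0
) -> tuple[int, int]:
    """Count accelerated (< low) and constrained (> high) phyloP positions.

    Both comparisons are strict, so boundary values count in neither bin.
    """
    if track.kind != "phyloP":
        raise ValueError("acceleration/constraint counts are defined for phyloP")
    values = np.asarray(track.values)
    return int(np.sum(values < low)), int(np.sum(values > high))


def group_ratio_comparison(
    tracks_a: Sequence[ScoreTrack],
    tracks_b: Sequence[ScoreTrack],
    low: float = -1.0,
    high: float = 1.0,
) -> GroupRatioResult:
    """Compare pooled accelerated/constrained ratios between two groups.

    Positions are pooled across elements within each group; the ratio is
    n(accelerated)/n(constrained), the fold is ratio_a/ratio_b, and the
    chi-square test runs on the pooled 2x2 table.
    """
    if not tracks_a or not tracks_b:
        raise ValueError("both groups must be non-empty")
    pooled = []
    for tracks in (tracks_a, tracks_b):
        counts = [accel_constraint_counts(t, low, high) for t in tracks]
        n_low = sum(c[0] for c in counts)
        n_high = sum(c[1] for c in counts)
        if n_high == 0:
            raise ValueError("pooled constrained-position count is zero; ratio undefined")
        pooled.append((n_low, n_high))
    (low_a, high_a), (low_b, high_b) = pooled
    ratio_a = low_a / high_a
    ratio_b = low_b / high_b
    test = chi_square_2x2([[low_a, high_a], [low_b, high_b]])
    return GroupRatioResult(
        counts_a=(low_a, high_a),
        counts_b=(low_b, high_b),
        ratio_a=ratio_a,
        ratio_b=ratio_b,
        fold=ratio_a / ratio_b if ratio_b > 0 else float("inf"),
        test=test,
    )


def mean_pairwise_identity(block: AlignmentBlock) -> float:
    """Mean percent identity over all unordered sequence pairs.

    For each pair, identity = matches / columns where neither sequence is
    gapped, in percent; comparison is case-insensitive.  Pairs with no
    gap-free column are excluded; if every pair is excluded the identity
    is undefined and a ValueError is raised.
    """
    identities = []
    seqs = [s.upper() for s in block.sequences]
    for s1, s2 in combinations(seqs, 2):
        matches = 0
        columns = 0
        for c1, c2 in zip(s1, s2):
            if c1 == "-" or c2 == "-":
                continue
            columns += 1
            if c1 == c2:
                matches += 1
        if columns:
            identities.append(100.0 * matches / columns)
    if not identities:
        raise ValueError("no pair shares a gap-free column; identity undefined")
    return float(np.mean(identities))


def stratified_score_comparison(
    conserved: Sequence[ScoreTrack],
    lost: Sequence[ScoreTrack],
    kind: str | None = None,
) -> StratifiedComparison:
    """Compare per-element mean scores between conserved and lost groups.

    The unit of observation is the element (its mean score), not the
    base: group means are unweighted over elements and the test is a
    one-way ANOVA across the two groups of per-element means.
    """
    if kind is None:
        kinds = {t.kind for t in [*conserved, *lost]}
        if len(kinds) != 1:
            raise ValueError(f"mixed track kinds {sorted(kinds)}; pass kind explicitly")
        kind = kinds.pop()
    groups = []
    for tracks in (conserved, lost):
        selected = [t for t in tracks if t.kind == kind]
        if len(selected) < 2:
            raise ValueError(f"need >= 2 {kind} elements per group")
        groups.append(tuple(mean_track_score(t) for t in selected))
    means_a, means_b = groups
    return StratifiedComparison(
        kind=kind,
        mean_a=float(np.mean(means_a)),
        mean_b=float(np.mean(means_b)),
        element_means_a=means_a,
        element_means_b=means_b,
        test=anova_oneway([means_a, means_b]),
    )


# ---------------------------------------------------------------------------
# Readers


def read_bedgraph(source) -> dict[str, list[tuple[int, int, float]]]:
    """Read a text bedGraph into per-chromosome (start, end, value) lists.

    Coordinates are 0-based half-open, as in the format definition.
    """
    handle = _open_text(source)
    coverage: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ParseError("bedGraph row needs chrom, start, end, value", lineno)
        chrom, start_s, end_s, value_s = fields[:4]
        try:
            start, end, value = int(start_s), int(end_s), float(value_s)
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
        if start < 0 or start >= end:
            raise ParseError(f"invalid interval [{start}, {end})", lineno)
        coverage.setdefault(chrom, []).append((start, end, value))
    for intervals in coverage.values():
        intervals.sort()
    return coverage


def read_fixed_step_wiggle(source) -> dict[str, list[tuple[int, int, float]]]:
    """Read fixedStep wiggle data into the same structure as bedGraph.

    Wiggle declaration lines use 1-based starts; values are converted to
    0-based half-open intervals of width ``span`` (default 1).
    """
    handle = _open_text(source)
    coverage: dict[str, list[tuple[int, int, float]]] = {}
    chrom: str | None = None
    pos = step = span = 0
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            params = dict(
                item.split("=", 1) for item in line.split()[1:] if "=" in item
            )
            try:
                chrom = params["chrom"]
                pos = int(params["start"]) - 1  # wiggle is 1-based
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"bad fixedStep declaration: {exc}", lineno) from exc
            if pos < 0 or step < 1 or span < 1:
                raise ParseError("invalid fixedStep parameters", lineno)
            continue
        if line.startswith("variableStep"):
            raise ParseError("variableStep wiggle is not supported", lineno)
        if chrom is None:
            raise ParseError("data before any fixedStep declaration", lineno)
        try:
            value = float(line)
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
        coverage.setdefault(chrom, []).append((pos, pos + span, value))
        pos += step
    for intervals in coverage.values():
        intervals.sort()
    return coverage


def tracks_from_coverage(
    coverage: Mapping[str, Sequence[tuple[int, int, float]]],
    cnes: Iterable[CNERecord],
    kind: str,
) -> list[ScoreTrack]:
    """Intersect per-base coverage with CNE intervals to build ScoreTracks.

    Every base of every element must be covered; an uncovered base means
    the score file does not span the element and raises ValueError.
    """
    tracks = []
    for cne in cnes:
        values = np.full(len(cne), np.nan)
        for start, end, value in coverage.get(cne.chrom, ()):
            lo = max(start, cne.start)
            hi = min(end, cne.end)
            if lo < hi:
                values[lo - cne.start : hi - cne.start] = value
        if np.isnan(values).any():
            n_missing = int(np.isnan(values).sum())
            raise ValueError(
                f"{cne.id}: {n_missing}/{len(cne)} bases lack {kind} scores"
            )
        tracks.append(ScoreTrack(cne.id, kind, tuple(float(v) for v in values)))
    return tracks


def read_alignment_fasta(source) -> AlignmentBlock:
    """Read a gapped multi-FASTA alignment into an AlignmentBlock."""
    handle = _open_text(source)
    records = list(SeqIO.parse(handle, "fasta"))
    return AlignmentBlock(
        sequences=tuple(str(rec.seq) for rec in records),
        labels=tuple(rec.id for rec in records),
    )


def read_hits_table(source) -> list[tuple[str, float]]:
    """Read a TSV homology-hit table (cne_id, evalue), header optional."""
    handle = _open_text(source)
    hits: list[tuple[str, float]] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError("hit row needs cne_id and evalue", lineno)
        if lineno == 1 and fields[0].lower() in ("cne_id", "id", "element"):
            continue
        try:
            hits.append((fields[0], float(fields[1])))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
    return hits
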