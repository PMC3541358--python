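"""Data model and I/O for expression-domain annotations of enhancer assays.

The unit of observation throughout the package is a presence/absence call:
did a given conserved non-coding element (CNE) drive reporter expression —
or its associated endogenous gene show expression — in a given anatomical
domain, in a given species?  This module defines the anatomical vocabulary,
the CNE records, raw replicate-line calls, aggregated expression calls, and
per-context expression profiles, together with TSV/BED/YAML readers.

Conventions
-----------
* Genomic coordinates are 0-based half-open (BED convention).
* Species are ``mouse`` and ``zebrafish``; assays are ``transgenic``
  (reporter construct) and ``endogenous`` (native gene expression).
* A domain is called present when the reporter was seen in at least half
  of the replicate lines; ties count as present.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "SPECIES",
    "ASSAYS",
    "AnnotationError",
    "ParseError",
    "DuplicateRecordError",
    "UndefinedSupportError",
    "AnatomicalDomain",
    "Vocabulary",
    "default_vocabulary",
    "CNERecord",
    "LineCall",
    "ExpressionCall",
    "ExpressionProfile",
    "call_domain_presence",
    "parse_presence",
    "read_expression_table",
    "read_line_calls",
    "read_bed",
    "write_bed",
    "aggregate_lines",
    "profiles_from_calls",
    "restrict_to_comparable",
]

SPECIES = ("mouse", "zebrafish")
ASSAYS = ("transgenic", "endogenous")

_TRUE_TOKENS = {"+", "1", "true", "yes"}
_FALSE_TOKENS = {"-", "0", "false", "no", "−"}  # U+2212 minus sign


class AnnotationError(ValueError):
    """Base class for annotation data-model violations."""


class ParseError(AnnotationError):
    """Malformed input row; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateRecordError(AnnotationError):
    """Two rows describe the same (cne, species, assay, domain) context."""


class UndefinedSupportError(AnnotationError):
    """Presence requested for an observation with zero replicate lines."""


# ---------------------------------------------------------------------------
# Vocabulary


@dataclass(frozen=True)
class AnatomicalDomain:
    """One canonical anatomical term with its per-species local names.

    A domain is *comparable* when both species have a homologous term
    (e.g. mouse "limbs" vs zebrafish "pectoral fins"); only comparable
    domains enter cross-species comparisons.
    """

    name: str
    species_terms: Mapping[str, str] = field(default_factory=dict)

    @property
    def comparable(self) -> bool:
        return all(sp in self.species_terms for sp in SPECIES)


class Vocabulary:
    """An ordered collection of anatomical domains with unique names."""

    def __init__(self, domains: Iterable[AnatomicalDomain]):
        self._domains: dict[str, AnatomicalDomain] = {}
        for dom in domains:
            if dom.name in self._domains:
                raise AnnotationError(f"duplicate domain name {dom.name!r}")
            self._domains[dom.name] = dom

    def __contains__(self, name: str) -> bool:
        return name in self._domains

    def __iter__(self) -> Iterator[AnatomicalDomain]:
        return iter(self._domains.values())

    def __len__(self) -> int:
        return len(self._domains)

    def __getitem__(self, name: str) -> AnatomicalDomain:
        return self._domains[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._domains)

    @property
    def comparable_names(self) -> frozenset[str]:
        return frozenset(d.name for d in self if d.comparable)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Vocabulary":
        """Load a vocabulary from a YAML list of mappings.

        Each entry has ``name`` plus optional ``mouse`` / ``zebrafish``
        local terms; a null or missing species entry means the domain has
        no homolog in that species.
        """
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, list):
            raise ParseError("vocabulary YAML must be a list of domain entries")
        domains = []
        for entry in raw:
            if not isinstance(entry, dict) or "name" not in entry:
                raise ParseError(f"bad vocabulary entry: {entry!r}")
            terms = {
                sp: str(entry[sp]) for sp in SPECIES if entry.get(sp) is not None
            }
            domains.append(AnatomicalDomain(str(entry["name"]), terms))
        return cls(domains)

    def to_yaml(self, path: str | Path) -> None:
        entries = []
        for dom in self:
            entry: dict[str, str | None] = {"name": dom.name}
            for sp in SPECIES:
                entry[sp] = dom.species_terms.get(sp)
            entries.append(entry)
        with open(path, "w") as handle:
            yaml.safe_dump(entries, handle, sort_keys=False)


#: Major anatomical terms used for mouse/zebrafish embryo comparisons at the
#: phylotypic stage.  "limbs" maps to pectoral fins in zebrafish; all twelve
#: terms have homologs in both species.  User vocabularies may extend this.
_DEFAULT_TERMS: tuple[tuple[str, str, str], ...] = (
    ("forebrain", "forebrain", "forebrain"),
    ("midbrain", "midbrain", "midbrain"),
    ("hindbrain", "hindbrain", "hindbrain"),
    ("spinal cord", "spinal cord", "spinal cord"),
    ("DRG", "dorsal root ganglia", "dorsal root ganglia"),
    ("eye", "eye", "eye"),
    ("nose", "nose", "olfactory placode"),
    ("limbs", "limbs", "pectoral fins"),
    ("somites", "somites", "somites"),
    ("notochord", "notochord", "notochord"),
    ("heart", "heart", "heart"),
    ("otic vesicle", "otic vesicle", "otic vesicle"),
)


def default_vocabulary() -> Vocabulary:
    """The built-in twelve-term anatomical vocabulary."""
    return Vocabulary(
        AnatomicalDomain(name, {"mouse": m, "zebrafish": z})
        for name, m, z in _DEFAULT_TERMS
    )


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class CNERecord:
    """One conserved non-coding element and its evolutionary annotations.

    ``ancestral`` marks elements inferred present in the gnathostome
    ancestor; ``zebrafish_status`` records whether an ancestral element is
    still recognisable in the zebrafish genome (``conserved``), has diverged
    beyond recognition or been deleted (``lost``), or was not assessed
    (``unknown``).
    """

    id: str
    build: str
    chrom: str
    start: int
    end: int
    ancestral: bool = False
    zebrafish_status: str = "unknown"
    gene: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise AnnotationError(
                f"{self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.zebrafish_status not in ("conserved", "lost", "unknown"):
            raise AnnotationError(
                f"{self.id}: bad zebrafish_status {self.zebrafish_status!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LineCall:
    """Raw observation from one replicate transgenic line."""

    cne_id: str
    line_id: str
    domain: str
    observed: bool


@dataclass(frozen=True)
class ExpressionCall:
    """Aggregated presence/absence for one (CNE, species, assay, domain).

    ``support`` optionally carries the (positive, total) replicate-line
    counts behind the call; when present it must agree with the majority
    rule.
    """

    cne_id: str
    species: str
    assay: str
    domain: str
    present: bool
    support: tuple[int, int] | None = None

    def __post_init__(self):
        if self.species not in SPECIES:
            raise AnnotationError(f"unknown species {self.species!r}")
        if self.assay not in ASSAYS:
            raise AnnotationError(f"unknown assay {self.assay!r}")
        if self.support is not None:
            pos, tot = self.support
            if not (0 <= pos <= tot) or tot < 1:
                raise AnnotationError(f"invalid support {self.support!r}")
            if self.present != call_domain_presence(pos, tot):
                raise AnnotationError(
                    f"{self.cne_id}/{self.domain}: present={self.present} "
                    f"disagrees with majority rule on support {self.support}"
                )


@dataclass(frozen=True)
class ExpressionProfile:
    """Set of domains called present for one (CNE, species, assay)."""

    cne_id: str
    species: str
    assay: str
    domains: frozenset[str] = frozenset()

    def restricted(self, keep: frozenset[str]) -> "ExpressionProfile":
        return replace(self, domains=self.domains & keep)


# ---------------------------------------------------------------------------
# Operations


def call_domain_presence(positive: int, total: int) -> bool:
    """Majority rule for replicate lines: present iff positive in >= half.

    Ties (exactly half the lines positive) count as present.
    """
    if total < 1:
        raise UndefinedSupportError("presence undefined without replicate lines")
    if not 0 <= positive <= total:
        raise AnnotationError(f"positive={positive} outside [0, {total}]")
    return 2 * positive >= total


def parse_presence(token: str, line: int | None = None) -> bool:
    tok = token.strip().lower()
    if tok in _TRUE_TOKENS:
        return True
    if tok in _FALSE_TOKENS:
        return False
    raise ParseError(f"unrecognised presence value {token!r}", line)


def _open_text(source) -> io.TextIOBase:
    if isinstance(source, (str, Path)):
        return open(source, newline="")
    return source


_EXPR_REQUIRED = ("cne_id", "species", "assay", "domain", "present")


def read_expression_table(
    source, vocabulary: Vocabulary | None = None
) -> list[ExpressionCall]:
    """Read a TSV of expression calls.

    Required columns: cne_id, species, assay, domain, present; optional
    positive/total columns attach replicate support.  Presence accepts
    '+'/'-', 1/0 or true/false.  Domains are validated against
    ``vocabulary`` when one is given; duplicate contexts are rejected.
    """
    handle = _open_text(source)
    reader = csv.DictReader(handle, delimiter="\t")
    if reader.fieldnames is None:
        return []
    missing = [c for c in _EXPR_REQUIRED if c not in reader.fieldnames]
    if missing:
        raise ParseError(f"missing columns: {', '.join(missing)}", 1)
    has_support = "positive" in reader.fieldnames and "total" in reader.fieldnames
    calls: list[ExpressionCall] = []
    seen: set[tuple[str, str, str, str]] = set()
    for row in reader:
        lineno = reader.line_num
        values = [row.get(c) for c in _EXPR_REQUIRED]
        if any(v is None or v == "" for v in values):
            raise ParseError("incomplete row", lineno)
        cne, species, assay, domain, present_tok = (v.strip() for v in values)
        if species not in SPECIES:
            raise ParseError(f"unknown species {species!r}", lineno)
        if assay not in ASSAYS:
            raise ParseError(f"unknown assay {assay!r}", lineno)
        if vocabulary is not None and domain not in vocabulary:
            raise ParseError(f"unknown domain {domain!r}", lineno)
        key = (cne, species, assay, domain)
        if key in seen:
            raise DuplicateRecordError(
                f"line {lineno}: duplicate record for {key}"
            )
        seen.add(key)
        support = None
        if has_support and row["positive"] not in (None, "") and row["total"] not in (None, ""):
            try:
                support = (int(row["positive"]), int(row["total"]))
            except ValueError as exc:
                raise ParseError(f"bad support counts: {exc}", lineno) from exc
        try:
            call = ExpressionCall(
                cne, species, assay, domain,
                parse_presence(present_tok, lineno), support,
            )
        except AnnotationError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(str(exc), lineno) from exc
        calls.append(call)
    return calls


def read_line_calls(source, vocabulary: Vocabulary | None = None) -> list[LineCall]:
    """Read a TSV of per-line observations (cne_id, line_id, domain, observed)."""
    handle = _open_text(source)
    reader = csv.DictReader(handle, delimiter="\t")
    if reader.fieldnames is None:
        return []
    required = ("cne_id", "line_id", "domain", "observed")
    missing = [c for c in required if c not in reader.fieldnames]
    if missing:
        raise ParseError(f"missing columns: {', '.join(missing)}", 1)
    calls: list[LineCall] = []
    seen: set[tuple[str, str, str]] = set()
    for row in reader:
        lineno = reader.line_num
        values = [row.get(c) for c in required]
        if any(v is None or v == "" for v in values):
            raise ParseError("incomplete row", lineno)
        cne, line_id, domain, obs_tok = (v.strip() for v in values)
        if vocabulary is not None and domain not in vocabulary:
            raise ParseError(f"unknown domain {domain!r}", lineno)
        key = (cne, line_id, domain)
        if key in seen:
            raise DuplicateRecordError(f"line {lineno}: duplicate line call {key}")
        seen.add(key)
        calls.append(LineCall(cne, line_id, domain, parse_presence(obs_tok, lineno)))
    return calls


def read_bed(
    source,
    build: str = "hg19",
    ancestry: Mapping[str, bool] | None = None,
    zebrafish_status: Mapping[str, str] | None = None,
    genes: Mapping[str, str] | None = None,
) -> list[CNERecord]:
    """Read CNE intervals from BED (chrom, start, end, name).

    The name column carries the element id.  Optional mappings attach
    ancestry flags, zebrafish conservation status and associated genes.
    """
    handle = _open_text(source)
    records: list[CNERecord] = []
    ids: set[str] = set()
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError("BED row needs chrom, start, end, name", lineno)
        chrom, start_s, end_s, name = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"bad coordinates: {exc}", lineno) from exc
        if name in ids:
            raise DuplicateRecordError(f"line {lineno}: duplicate element id {name!r}")
        ids.add(name)
        try:
            records.append(
                CNERecord(
                    id=name,
                    build=build,
                    chrom=chrom,
                    start=start,
                    end=end,
                    ancestral=bool(ancestry.get(name, False)) if ancestry else False,
                    zebrafish_status=(
                        zebrafish_status.get(name, "unknown")
                        if zebrafish_status
                        else "unknown"
                    ),
                    gene=genes.get(name) if genes else None,
                )
            )
        except AnnotationError as exc:
            raise ParseError(str(exc), lineno) from exc
    return records


def write_bed(records: Sequence[CNERecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.id}\n")


def aggregate_lines(
    calls: Iterable[LineCall],
    cne_id: str,
    domain: str,
    species: str = "zebrafish",
    assay: str = "transgenic",
) -> ExpressionCall:
    """Aggregate replicate-line observations into one majority-rule call.

    Returns an :class:`ExpressionCall` with ``support = (n observed,
    n lines)`` and presence decided by :func:`call_domain_presence`.
    """
    relevant = [c for c in calls if c.cne_id == cne_id and c.domain == domain]
    if not relevant:
        raise UndefinedSupportError(
            f"no line calls for ({cne_id}, {domain})"
        )
    positive = sum(c.observed for c in relevant)
    total = len(relevant)
    return ExpressionCall(
        cne_id,
        species,
        assay,
        domain,
        call_domain_presence(positive, total),
        (positive, total),
    )


def profiles_from_calls(
    calls: Iterable[ExpressionCall],
) -> dict[tuple[str, str, str], ExpressionProfile]:
    """Group calls into per-(cne, species, assay) presence profiles.

    Every context seen in the input gets a profile, including contexts
    whose calls are all negative (empty domain set).
    """
    grouped: dict[tuple[str, str, str], set[str]] = {}
    for call in calls:
        key = (call.cne_id, call.species, call.assay)
        grouped.setdefault(key, set())
        if call.present:
            grouped[key].add(call.domain)
    return {
        key: ExpressionProfile(key[0], key[1], key[2], frozenset(domains))
        for key, domains in grouped.items()
    }


def restrict_to_comparable(
    profile: ExpressionProfile, vocabulary: Vocabulary
) -> ExpressionProfile:
    """Drop domains without a homologous term in both species.

    Cross-species comparison is only meaningful for anatomy present in
    both species; the input profile is left unmodified.
    """
    for name in profile.domains:
        if name not in vocabulary:
            raise AnnotationError(f"domain {name!r} not in vocabulary")
    return profile.restricted(vocabulary.comparable_names)
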