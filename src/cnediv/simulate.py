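"""Synthetic datasets with recorded ground truth.

The generator emulates the statistical structure of a two-species
enhancer-reporter screen: per-domain Bernoulli ancestral activity (the
mouse transgenic state, since elements are ascertained by mouse
activity), species-specific trans changes that flip the zebrafish
transgenic state at a configurable rate, endogenous gene calls that
mirror each species' transgenic state with configurable fidelity,
replicate-line detection noise on the zebrafish assay, and per-base
phyloP tracks whose distribution differs between zebrafish-conserved and
zebrafish-lost elements.

Every generated record is backed by a :class:`SimulationTruth` entry, so
each pipeline stage can be checked against known parameters.
``recover_parameters`` runs the full aggregate -> compare -> classify
pipeline and returns the recovered rates next to their analytic
expectations.

A single integer seed drives one root SeedSequence; each component draws
from its own spawned substream, so adding components never perturbs
earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import (
    AnatomicalDomain,
    CNERecord,
    ExpressionCall,
    ExpressionProfile,
    LineCall,
    Vocabulary,
    aggregate_lines,
    call_domain_presence,
    default_vocabulary,
    profiles_from_calls,
    restrict_to_comparable,
    write_bed,
)
from .conservation import ScoreTrack, StratifiedComparison, stratified_score_comparison
from .divergence import compare_profiles
from .trans_gene import TRANS_AND_GENE, classify_fourway

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "RecoveryReport",
    "simulate_dataset",
    "recover_parameters",
    "write_dataset",
]


class ConfigError(ValueError):
    """A simulation parameter is outside its valid range."""


_PROB_FIELDS = (
    "activity_prob",
    "trans_change_rate",
    "gene_mirror_prob",
    "lost_fraction",
    "detection_prob",
    "false_positive_prob",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic screen.

    Defaults mirror a screen of 47 elements annotated over twelve major
    anatomical domains with about 2.4 active domains per element, a
    per-domain trans-change rate giving most elements at least one
    species-specific domain, endogenous genes mirroring the reporter in
    ~85% of domains, roughly half of ancestral elements lost in
    zebrafish, three replicate lines, and phyloP score levels that differ
    subtly between the conserved and lost groups.
    """

    n_cnes: int = 47
    vocabulary_size: int = 12
    activity_prob: float = 0.2
    trans_change_rate: float = 0.14
    gene_mirror_prob: float = 0.85
    lost_fraction: float = 0.46
    n_lines: int = 3
    detection_prob: float = 0.9
    false_positive_prob: float = 0.02
    phylop_conserved: tuple[float, float] = (0.107, 1.0)
    phylop_lost: tuple[float, float] = (0.159, 1.0)
    track_length: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in _PROB_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.n_cnes < 1:
            raise ConfigError("n_cnes must be >= 1")
        if not 1 <= self.vocabulary_size:
            raise ConfigError("vocabulary_size must be >= 1")
        if self.n_lines < 1:
            raise ConfigError("n_lines must be >= 1")
        if self.track_length < 1:
            raise ConfigError("track_length must be >= 1")
        for name in ("phylop_conserved", "phylop_lost"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ConfigError(f"{name} sd must be >= 0")
        if self.activity_prob == 0.0:
            raise ConfigError(
                "activity_prob=0 leaves no mouse-active element to ascertain"
            )

    def vocabulary(self) -> Vocabulary:
        """Anatomical vocabulary of the simulated screen.

        The first twelve domains reuse the built-in terms; larger
        vocabularies are padded with synthetic comparable terms.
        """
        base = list(default_vocabulary())
        if self.vocabulary_size <= len(base):
            return Vocabulary(base[: self.vocabulary_size])
        extra = [
            AnatomicalDomain(f"domain{i:02d}", {"mouse": f"domain{i:02d}", "zebrafish": f"domain{i:02d}"})
            for i in range(len(base), self.vocabulary_size)
        ]
        return Vocabulary(base + extra)


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset.

    ``states`` maps (cne_id, domain) to a dict with the true mouse/
    zebrafish transgenic states, whether a trans flip was applied, and
    the two endogenous-gene states.  ``zebrafish_status`` maps cne_id to
    conserved/lost.  ``expected_divergent_fraction`` is the analytic
    probability that a (cne, domain) slot is species-specific, which for
    this flip model equals the trans-change rate (flips are independent
    of the mouse-activity ascertainment).
    """

    states: dict[tuple[str, str], dict] = field(default_factory=dict)
    zebrafish_status: dict[str, str] = field(default_factory=dict)
    expected_divergent_fraction: float = 0.0
    redraw_count: int = 0


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    vocabulary: Vocabulary
    cne_records: list[CNERecord]
    line_calls: list[LineCall]
    expression_calls: list[ExpressionCall]
    score_tracks: list[ScoreTrack]
    truth: SimulationTruth


@dataclass
class RecoveryReport:
    """Pipeline estimates next to the generating parameters."""

    n_cnes: int
    n_slots: int
    divergent_domain_fraction: float
    expected_divergent_fraction: float
    trans_and_gene_fraction: float | None
    phylop_mean_conserved: float | None
    phylop_mean_lost: float | None
    stratified: StratifiedComparison | None
    n_compared: int
    n_skipped_empty: int


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one complete synthetic screen from the configured model.

    Mouse transgenic activity is drawn per domain (redrawing elements
    with no active domain, mirroring ascertainment by mouse activity);
    the zebrafish transgenic state flips each domain independently with
    the trans-change rate; endogenous calls mirror their species'
    transgenic state with the configured fidelity; replicate-line
    observations add detection noise to the zebrafish assay; phyloP
    tracks are Gaussian per base with group-specific parameters.
    Deterministic for a fixed config (including seed).
    """
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("status", "activity", "flips", "mirror", "lines", "tracks"),
            root.spawn(6),
        )
    }
    vocab = config.vocabulary()
    domains = vocab.names
    n_dom = len(domains)
    width = len(str(config.n_cnes))

    truth = SimulationTruth(
        expected_divergent_fraction=config.trans_change_rate
    )
    cne_records: list[CNERecord] = []
    line_calls: list[LineCall] = []
    expression_calls: list[ExpressionCall] = []
    score_tracks: list[ScoreTrack] = []

    for i in range(config.n_cnes):
        cne_id = f"Sim{i + 1:0{width}d}"
        status = (
            "lost"
            if streams["status"].random() < config.lost_fraction
            else "conserved"
        )
        truth.zebrafish_status[cne_id] = status

        # ascertainment: elements are in the screen because they were
        # active somewhere in mouse; inactive draws are rejected
        while True:
            mouse_true = streams["activity"].random(n_dom) < config.activity_prob
            if mouse_true.any():
                break
            truth.redraw_count += 1
        flips = streams["flips"].random(n_dom) < config.trans_change_rate
        zebra_true = mouse_true ^ flips
        mirror_m = streams["mirror"].random(n_dom) < config.gene_mirror_prob
        mirror_z = streams["mirror"].random(n_dom) < config.gene_mirror_prob
        mouse_gene = np.where(mirror_m, mouse_true, ~mouse_true)
        zebra_gene = np.where(mirror_z, zebra_true, ~zebra_true)

        start = i * (config.track_length + 100)
        cne_records.append(
            CNERecord(
                id=cne_id,
                build="sim1",
                chrom="chrS",
                start=start,
                end=start + config.track_length,
                ancestral=True,
                zebrafish_status=status,
                gene=f"gene{i + 1:0{width}d}",
            )
        )

        obs = np.empty((config.n_lines, n_dom), dtype=bool)
        for j in range(config.n_lines):
            u = streams["lines"].random(n_dom)
            obs[j] = np.where(
                zebra_true,
                u < config.detection_prob,
                u < config.false_positive_prob,
            )
            line_calls.extend(
                LineCall(cne_id, f"L{j + 1}", domains[d], bool(obs[j, d]))
                for d in range(n_dom)
            )

        positives = obs.sum(axis=0)
        for d, domain in enumerate(domains):
            truth.states[(cne_id, domain)] = {
                "mouse_transgenic": bool(mouse_true[d]),
                "zebrafish_transgenic": bool(zebra_true[d]),
                "flip": bool(flips[d]),
                "mouse_gene": bool(mouse_gene[d]),
                "zebrafish_gene": bool(zebra_gene[d]),
            }
            expression_calls.append(
                ExpressionCall(cne_id, "mouse", "transgenic", domain, bool(mouse_true[d]))
            )
            expression_calls.append(
                ExpressionCall(
                    cne_id,
                    "zebrafish",
                    "transgenic",
                    domain,
                    call_domain_presence(int(positives[d]), config.n_lines),
                    (int(positives[d]), config.n_lines),
                )
            )
            expression_calls.append(
                ExpressionCall(cne_id, "mouse", "endogenous", domain, bool(mouse_gene[d]))
            )
            expression_calls.append(
                ExpressionCall(cne_id, "zebrafish", "endogenous", domain, bool(zebra_gene[d]))
            )

        mean, sd = (
            config.phylop_lost if status == "lost" else config.phylop_conserved
        )
        values = streams["tracks"].normal(mean, sd, config.track_length)
        score_tracks.append(
            ScoreTrack(cne_id, "phyloP", tuple(float(v) for v in values))
        )

    return SimulatedDataset(
        config=config,
        vocabulary=vocab,
        cne_records=cne_records,
        line_calls=line_calls,
        expression_calls=expression_calls,
        score_tracks=score_tracks,
        truth=truth,
    )


def recover_parameters(dataset: SimulatedDataset) -> RecoveryReport:
    """Run the full pipeline on a simulated dataset and estimate rates.

    Replicate lines are aggregated with the majority rule, profiles are
    compared between species, and each (cne, domain) slot is classified
    four-way.  The divergent-domain fraction is the share of all slots
    whose aggregated transgenic calls differ between species (its
    analytic expectation under the generator is the trans-change rate);
    the trans_and_gene fraction is measured among divergent slots.
    """
    config = dataset.config
    vocab = dataset.vocabulary
    domains = vocab.names

    by_slot: dict[tuple[str, str], list[LineCall]] = {}
    for call in dataset.line_calls:
        by_slot.setdefault((call.cne_id, call.domain), []).append(call)

    calls = [
        c
        for c in dataset.expression_calls
        if not (c.species == "zebrafish" and c.assay == "transgenic")
    ]
    for (cne_id, domain), slot_calls in by_slot.items():
        calls.append(aggregate_lines(slot_calls, cne_id, domain))

    profiles = profiles_from_calls(calls)
    n_divergent = 0
    n_slots = 0
    n_trans_and_gene = 0
    n_compared = 0
    n_skipped = 0
    present = {
        (c.cne_id, c.species, c.assay, c.domain): c.present for c in calls
    }
    for rec in dataset.cne_records:
        mouse_prof = restrict_to_comparable(
            profiles[(rec.id, "mouse", "transgenic")], vocab
        )
        zebra_prof = restrict_to_comparable(
            profiles[(rec.id, "zebrafish", "transgenic")], vocab
        )
        if mouse_prof.domains | zebra_prof.domains:
            compare_profiles(mouse_prof, zebra_prof)
            n_compared += 1
        else:
            n_skipped += 1
        for domain in domains:
            mt = domain in mouse_prof.domains
            zt = domain in zebra_prof.domains
            mg = present[(rec.id, "mouse", "endogenous", domain)]
            zg = present[(rec.id, "zebrafish", "endogenous", domain)]
            n_slots += 1
            if mt != zt:
                n_divergent += 1
                if classify_fourway(mt, zt, mg, zg) == TRANS_AND_GENE:
                    n_trans_and_gene += 1

    conserved = [
        t
        for t in dataset.score_tracks
        if dataset.truth.zebrafish_status[t.cne_id] == "conserved"
    ]
    lost = [
        t
        for t in dataset.score_tracks
        if dataset.truth.zebrafish_status[t.cne_id] == "lost"
    ]
    stratified = (
        stratified_score_comparison(conserved, lost, "phyloP")
        if len(conserved) >= 2 and len(lost) >= 2
        else None
    )

    def _group_mean(tracks: list[ScoreTrack]) -> float | None:
        if not tracks:
            return None
        return float(np.mean([np.mean(t.values) for t in tracks]))

    return RecoveryReport(
        n_cnes=config.n_cnes,
        n_slots=n_slots,
        divergent_domain_fraction=n_divergent / n_slots,
        expected_divergent_fraction=dataset.truth.expected_divergent_fraction,
        trans_and_gene_fraction=(
            n_trans_and_gene / n_divergent if n_divergent else None
        ),
        phylop_mean_conserved=_group_mean(conserved),
        phylop_mean_lost=_group_mean(lost),
        stratified=stratified,
        n_compared=n_compared,
        n_skipped_empty=n_skipped,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset in the TSV/BED/bedGraph dialects the readers accept.

    Emits annotations.tsv (four-context expression calls), line_calls.tsv,
    cnes.bed, phylop.bedGraph, vocabulary.yaml and truth.json; returns the
    path of each file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "line_calls": outdir / "line_calls.tsv",
        "bed": outdir / "cnes.bed",
        "phylop": outdir / "phylop.bedGraph",
        "vocabulary": outdir / "vocabulary.yaml",
        "truth": outdir / "truth.json",
    }

    with open(paths["annotations"], "w") as handle:
        handle.write("cne_id\tspecies\tassay\tdomain\tpresent\tpositive\ttotal\n")
        for c in dataset.expression_calls:
            pos, tot = c.support if c.support else ("", "")
            flag = "+" if c.present else "-"
            handle.write(
                f"{c.cne_id}\t{c.species}\t{c.assay}\t{c.domain}\t{flag}\t{pos}\t{tot}\n"
            )

    with open(paths["line_calls"], "w") as handle:
        handle.write("cne_id\tline_id\tdomain\tobserved\n")
        for lc in dataset.line_calls:
            flag = "+" if lc.observed else "-"
            handle.write(f"{lc.cne_id}\t{lc.line_id}\t{lc.domain}\t{flag}\n")

    write_bed(dataset.cne_records, paths["bed"])
    dataset.vocabulary.to_yaml(paths["vocabulary"])

    by_id = {rec.id: rec for rec in dataset.cne_records}
    with open(paths["phylop"], "w") as handle:
        for track in dataset.score_tracks:
            rec = by_id[track.cne_id]
            for offset, value in enumerate(track.values):
                pos = rec.start + offset
                handle.write(f"{rec.chrom}\t{pos}\t{pos + 1}\t{value:.6g}\n")

    truth_payload = {
        "config": asdict(dataset.config),
        "expected_divergent_fraction": dataset.truth.expected_divergent_fraction,
        "redraw_count": dataset.truth.redraw_count,
        "zebrafish_status": dataset.truth.zebrafish_status,
        "states": [
            {"cne_id": cne_id, "domain": domain, **state}
            for (cne_id, domain), state in dataset.truth.states.items()
        ],
    }
    with open(paths["truth"], "w") as handle:
        json.dump(truth_payload, handle, indent=2)
        handle.write("\n")
    return paths
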