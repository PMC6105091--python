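"""Per-transcript metrics and configurable requirements/scoring.

Each transcript is described by a vector of named metrics, some intrinsic
(cDNA length, CDS fraction, completeness) and some defined only relative to
the other transcripts staged at the same locus (exon/intron fractions,
retained introns).  A scoring configuration then (a) hard-filters
transcripts through a boolean *requirements* expression and (b) converts
the metric values of a locus group into a numeric score per transcript by
rescaling each metric over the group and summing weighted contributions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from .evidence import EvidenceStore, verify_introns
from .models import TranscriptModel

EPSILON = 1e-9


class ScoringConfigError(ValueError):
    """Raised at configuration load time for unknown metrics/operators."""


# ---------------------------------------------------------------------------
# Metric computation


METRIC_NAMES = [
    "cdna_length", "exon_num", "max_intron_length", "min_intron_length",
    "is_monoexonic", "canonical_intron_proportion", "cds_length",
    "cds_fraction", "number_internal_orfs", "utr_length", "five_utr_length",
    "three_utr_length", "five_utr_num", "three_utr_num", "has_start_codon",
    "has_stop_codon", "is_complete", "end_distance_from_junction",
    "exon_fraction", "intron_fraction", "retained_intron_num",
    "retained_fraction", "verified_introns_num",
    "proportion_verified_introns", "best_bitscore", "best_hit_coverage",
]

#: Extension point: user configs may bind additional metric names to
#: callables (transcript, group, store) -> value.
EXTRA_METRICS: dict[str, object] = {}


def _cds_cdna_span(t: TranscriptModel) -> tuple[int, int] | None:
    """The CDS as a cDNA interval in transcript orientation, or None."""
    if not t.cds_segments:
        return None
    positions = []
    for s, e in t.cds_segments:
        positions.append(t.genome_to_cdna(s))
        positions.append(t.genome_to_cdna(e - 1))
    return min(positions), max(positions) + 1


def _junction_cdna_positions(t: TranscriptModel) -> list[int]:
    """Splice-junction positions on the cDNA, 5'→3'."""
    lengths = [e - s for s, e in t.exons]
    if t.strand == "-":
        lengths = lengths[::-1]
    out, acc = [], 0
    for length in lengths[:-1]:
        acc += length
        out.append(acc)
    return out


def compute_metrics(
    t: TranscriptModel,
    group: list[TranscriptModel],
    store: EvidenceStore | None = None,
) -> dict[str, float | bool]:
    """Metric vector for ``t`` in the context of its locus ``group``.

    ``group`` must contain ``t``; intrinsic metrics are independent of the
    group, locus-relative ones (exon/intron fractions, retained introns)
    are computed against the union of features over the group.
    """
    mv: dict[str, float | bool] = {}
    introns = t.introns
    mv["cdna_length"] = t.cdna_length
    mv["exon_num"] = t.exon_count
    mv["max_intron_length"] = max((e - s for s, e in introns), default=0)
    mv["min_intron_length"] = min((e - s for s, e in introns), default=0)
    mv["is_monoexonic"] = t.is_monoexonic
    if t.is_monoexonic:
        mv["canonical_intron_proportion"] = 0.0
    else:
        mv["canonical_intron_proportion"] = float(
            t.attributes.get("canonical_proportion", 1.0)
        )
    mv["cds_length"] = t.cds_length
    mv["cds_fraction"] = t.cds_length / t.cdna_length if t.cdna_length else 0.0
    has_cds = bool(t.cds_segments)
    mv["number_internal_orfs"] = int(
        t.attributes.get("number_internal_orfs", 1 if has_cds else 0)
    )
    span = _cds_cdna_span(t)
    if span is None:
        five_utr = three_utr = 0
        mv["five_utr_num"] = 0
        mv["three_utr_num"] = 0
        mv["end_distance_from_junction"] = 0
    else:
        cs, ce = span
        five_utr, three_utr = cs, t.cdna_length - ce
        # exon lengths in transcript orientation
        lengths = [e - s for s, e in t.exons]
        if t.strand == "-":
            lengths = lengths[::-1]
        bounds, acc = [], 0
        for length in lengths:
            bounds.append((acc, acc + length))
            acc += length
        mv["five_utr_num"] = sum(1 for lo, hi in bounds if min(hi, cs) - lo > 0)
        mv["three_utr_num"] = sum(1 for lo, hi in bounds if hi - max(lo, ce) > 0)
        junctions = _junction_cdna_positions(t)
        if junctions:
            mv["end_distance_from_junction"] = max(0, junctions[-1] - ce)
        else:
            mv["end_distance_from_junction"] = 0
    mv["utr_length"] = five_utr + three_utr
    mv["five_utr_length"] = five_utr
    mv["three_utr_length"] = three_utr
    mv["has_start_codon"] = t.attributes.get("has_start_codon") == "True"
    mv["has_stop_codon"] = t.attributes.get("has_stop_codon") == "True"
    mv["is_complete"] = mv["has_start_codon"] and mv["has_stop_codon"]

    # locus-relative metrics over the group feature unions
    group_exons = {(s, e) for g in group for s, e in g.exons}
    group_introns = {(s, e) for g in group for s, e in g.introns}
    own_exons = {(s, e) for s, e in t.exons}
    own_introns = set(introns)
    mv["exon_fraction"] = (
        len(own_exons & group_exons) / len(group_exons) if group_exons else 1.0
    )
    mv["intron_fraction"] = (
        len(own_introns & group_introns) / len(group_introns)
        if group_introns
        else 1.0
    )
    retaining_exons: set[tuple[int, int]] = set()
    for other in group:
        if other.id == t.id:
            continue
        other_exons = other.exons
        for i, (is_, ie) in enumerate(other.introns):
            for xs, xe in t.exons:
                if xs <= is_ and ie <= xe:
                    left, right = other_exons[i], other_exons[i + 1]
                    if left[0] < xe and xs < left[1] and right[0] < xe and xs < right[1]:
                        retaining_exons.add((xs, xe))
    mv["retained_intron_num"] = len(retaining_exons)
    mv["retained_fraction"] = (
        sum(e - s for s, e in retaining_exons) / t.cdna_length
        if t.cdna_length
        else 0.0
    )

    if store is not None:
        verified, total = verify_introns(t, store.junctions)
        hits = store.hits_for(t.id)
    else:
        verified, total = 0, len(introns)
        hits = []
    mv["verified_introns_num"] = verified
    mv["proportion_verified_introns"] = verified / total if total else 0.0
    mv["best_bitscore"] = max((h.bitscore for h in hits), default=0.0)
    if hits:
        best = min(hits, key=lambda h: (h.evalue, -h.bitscore))
        mv["best_hit_coverage"] = best.query_coverage_of((0, t.cdna_length))
    else:
        mv["best_hit_coverage"] = 0.0

    for name, fn in EXTRA_METRICS.items():
        mv[name] = fn(t, group, store)
    return mv


# ---------------------------------------------------------------------------
# Requirements expressions


_OPERATORS = {
    "eq": lambda v, x: v == x,
    "ne": lambda v, x: v != x,
    "gt": lambda v, x: v > x,
    "ge": lambda v, x: v >= x,
    "lt": lambda v, x: v < x,
    "le": lambda v, x: v <= x,
    "in": lambda v, x: v in x,
    "within": lambda v, x: x[0] <= v <= x[1],
}


@dataclass(frozen=True)
class Atom:
    """One comparison of a metric against a value."""

    metric: str
    operator: str
    value: object

    def evaluate(self, mv: dict) -> bool:
        v = mv[self.metric]
        if isinstance(v, bool):
            v = float(v)
        return _OPERATORS[self.operator](v, self.value)


_EXPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|\bnot\b|[A-Za-z_][A-Za-z0-9_.]*")


@dataclass
class RequirementExpression:
    """A boolean expression over named atoms; empty means 'always pass'."""

    atoms: dict[str, Atom] = field(default_factory=dict)
    expression: str | None = None

    def __post_init__(self) -> None:
        known = set(METRIC_NAMES) | set(EXTRA_METRICS)
        for name, atom in self.atoms.items():
            if atom.metric not in known:
                raise ScoringConfigError(f"unknown metric {atom.metric!r} in atom {name!r}")
            if atom.operator not in _OPERATORS:
                raise ScoringConfigError(f"unknown operator {atom.operator!r}")
        if self.expression is not None:
            stripped = re.sub(r"\(|\)|\band\b|\bor\b|\bnot\b|\s+", " ", self.expression)
            for token in stripped.split():
                if token not in self.atoms:
                    raise ScoringConfigError(
                        f"expression references unknown atom {token!r}"
                    )

    def evaluate(self, mv: dict) -> tuple[bool, list[str]]:
        """(passed, failing atom names)."""
        if not self.atoms:
            return True, []
        results = {name: atom.evaluate(mv) for name, atom in self.atoms.items()}
        failing = sorted(name for name, ok in results.items() if not ok)
        if self.expression is None:
            return not failing, failing
        expr = _EXPR_TOKEN.sub(
            lambda m: m.group(0)
            if m.group(0) in ("and", "or", "not")
            else ("(" if m.group(0) == "(" else ")")
            if m.group(0) in "()"
            else str(results[m.group(0)]),
            self.expression,
        )
        return bool(eval(expr, {"__builtins__": {}}, {})), failing


def evaluate_requirements(mv: dict, expr: RequirementExpression) -> tuple[bool, list[str]]:
    return expr.evaluate(mv)


# ---------------------------------------------------------------------------
# Scoring directives


@dataclass
class MetricDirective:
    """How one metric contributes to the transcript score."""

    metric: str
    rescaling: str  # max | min | target
    multiplier: float = 1.0
    target: float | None = None
    filter: Atom | None = None

    def __post_init__(self) -> None:
        known = set(METRIC_NAMES) | set(EXTRA_METRICS)
        if self.metric not in known:
            raise ScoringConfigError(f"unknown metric {self.metric!r}")
        if self.rescaling not in ("max", "min", "target"):
            raise ScoringConfigError(f"unknown rescaling {self.rescaling!r}")
        if self.rescaling == "target" and self.target is None:
            raise ScoringConfigError(f"{self.metric}: target rescaling needs a target")
        if self.multiplier <= 0:
            raise ScoringConfigError(f"{self.metric}: multiplier must be > 0")


@dataclass
class AsRules:
    """Alternative-splicing admission rules."""

    min_score_ratio: float = 0.5
    max_isoforms: int = 5
    valid_class_codes: tuple[str, ...] = ("j", "J", "h", "G")


@dataclass
class ScoringConfig:
    requirements: RequirementExpression = field(default_factory=RequirementExpression)
    not_fragmentary: RequirementExpression = field(default_factory=RequirementExpression)
    scoring: list[MetricDirective] = field(default_factory=list)
    as_rules: AsRules = field(default_factory=AsRules)
    # pick-stage knobs (the general-configuration half of the two-file model)
    flank: int = 200
    fragment_max_distance: int = 2000
    fragment_codes: tuple[str, ...] = ("i", "I", "p", "P", "x", "X")
    fusion_min_overlap: float = 0.2
    purge_fragments: bool = True
    min_length: int = 200

    @classmethod
    def from_yaml(cls, path: str) -> "ScoringConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScoringConfig":
        def parse_expr(section) -> RequirementExpression:
            if not section:
                return RequirementExpression()
            atoms = {
                name: Atom(d["metric"], d["operator"], d["value"])
                for name, d in (section.get("parameters") or {}).items()
            }
            return RequirementExpression(atoms, section.get("expression"))

        directives = []
        for metric, d in (raw.get("scoring") or {}).items():
            filt = None
            if "filter" in d:
                f = d["filter"]
                filt = Atom(f.get("metric", metric), f["operator"], f["value"])
            directives.append(
                MetricDirective(
                    metric=metric,
                    rescaling=d["rescaling"],
                    multiplier=float(d.get("multiplier", 1.0)),
                    target=d.get("target"),
                    filter=filt,
                )
            )
        as_raw = raw.get("alternative_splicing") or {}
        as_rules = AsRules(
            min_score_ratio=float(as_raw.get("min_score_ratio", 0.5)),
            max_isoforms=int(as_raw.get("max_isoforms", 5)),
            valid_class_codes=tuple(
                as_raw.get("valid_class_codes", ("j", "J", "h", "G"))
            ),
        )
        pick_raw = raw.get("pick") or {}
        return cls(
            requirements=parse_expr(raw.get("requirements")),
            not_fragmentary=parse_expr(raw.get("not_fragmentary")),
            scoring=directives,
            as_rules=as_rules,
            flank=int(pick_raw.get("flank", 200)),
            fragment_max_distance=int(pick_raw.get("fragment_max_distance", 2000)),
            fragment_codes=tuple(
                pick_raw.get("fragment_codes", ("i", "I", "p", "P", "x", "X"))
            ),
            fusion_min_overlap=float(pick_raw.get("fusion_min_overlap", 0.2)),
            purge_fragments=bool(pick_raw.get("purge_fragments", True)),
            min_length=int(pick_raw.get("min_length", 200)),
        )


def default_config() -> ScoringConfig:
    """A general-purpose configuration prioritising complete coding models."""
    return ScoringConfig(
        requirements=RequirementExpression(
            atoms={"long_enough": Atom("cdna_length", "ge", 200)}
        ),
        not_fragmentary=RequirementExpression(
            atoms={
                "multiexonic": Atom("is_monoexonic", "eq", 0),
                "complete": Atom("is_complete", "eq", 1),
            },
            expression="multiexonic or complete",
        ),
        scoring=[
            MetricDirective("cds_length", "max", 3.0),
            MetricDirective("cdna_length", "max", 1.0),
            MetricDirective("is_complete", "max", 2.0),
            MetricDirective("proportion_verified_introns", "max", 2.0),
            MetricDirective("canonical_intron_proportion", "max", 1.0),
            MetricDirective("exon_fraction", "max", 1.0),
            MetricDirective("intron_fraction", "max", 1.0),
            MetricDirective("number_internal_orfs", "target", 2.0, target=1),
            MetricDirective("retained_fraction", "min", 1.0),
            MetricDirective("best_bitscore", "max", 1.0),
            MetricDirective("best_hit_coverage", "max", 1.0),
        ],
    )


# ---------------------------------------------------------------------------
# Group scoring


def score_group(
    group: list[TranscriptModel],
    mvs: dict[str, dict],
    config: ScoringConfig,
) -> dict[str, float]:
    """Score every transcript of a locus group relative to the others.

    Per metric with group minimum ``lo`` and maximum ``hi``:
    ``max`` rescaling scores ``multiplier*(v-lo)/(hi-lo)``, ``min`` the
    mirror image, ``target t`` scores ``multiplier*(1-|v-t|/max(|hi-t|,
    |lo-t|, eps))``.  A degenerate metric (``hi == lo``) awards the full
    multiplier to everyone; a failing per-metric filter forces that
    transcript's contribution to 0 and removes it from the lo/hi range.
    Boolean metrics are cast to {0, 1}.  The total score is the sum over
    directives.
    """
    scores = {t.id: 0.0 for t in group}
    for directive in config.scoring:
        values: dict[str, float] = {}
        for t in group:
            v = mvs[t.id][directive.metric]
            values[t.id] = float(v)
        eligible = {
            tid: v
            for tid, v in values.items()
            if directive.filter is None or directive.filter.evaluate(mvs[tid])
        }
        if not eligible:
            continue
        lo, hi = min(eligible.values()), max(eligible.values())
        for tid in values:
            if tid not in eligible:
                continue
            v = values[tid]
            if hi == lo:
                s = directive.multiplier
            elif directive.rescaling == "max":
                s = directive.multiplier * (v - lo) / (hi - lo)
            elif directive.rescaling == "min":
                s = directive.multiplier * (hi - v) / (hi - lo)
            else:
                tgt = float(directive.target)
                denom = max(abs(hi - tgt), abs(lo - tgt), EPSILON)
                s = directive.multiplier * (1 - abs(v - tgt) / denom)
            scores[tid] += max(0.0, s)
    return scores
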