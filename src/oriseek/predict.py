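"""Origin and terminus prediction by intergenic-sequence scoring.

Every intergenic sequence (IGS) of a replicon receives three additive score
components, each in [0, 1]:

* ``s_dist`` — base-composition evidence: proximity of the IGS midpoint to
  the GC-disparity minimum, ``max(0, 1 - d / (L/2))``.
* ``s_gene`` — indicator-gene evidence: 1.0 when a principal indicator gene
  (dnaA by default) immediately flanks the IGS, 0.75 for a secondary
  indicator flank, 0.5 when any indicator lies within 5 kb, else 0.
* ``s_box`` — DnaA-box evidence: each box with m <= k_max mismatches
  contributes (k_max + 1 - m) / (k_max + 1) box-equivalents; the component
  saturates at three box-equivalents (a "cluster"), i.e.
  ``min(sum / 3, 1)``.

The highest-total IGS is the predicted oriC; exact ties are screened by
functional elements (DnaA-trios, then GATC count, then AT fraction). Draft
genomes are scored per contig against that contig's own GC-disparity
minimum and length, then pooled. The terminus of a complete genome comes
from the dif motif when configured, else the GC-disparity maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import UnsupportedOperationError
from .genome_io import IGS, GeneFeature, GenomeRecord, extract_igs, find_orfs_fallback
from .motifs import (
    MotifConfig,
    MotifHit,
    TrioArray,
    due_window,
    find_dnaa_boxes,
    find_dnaa_trios,
    find_fixed_elements,
    find_loose_boxes_near_trios,
    scan_iupac,
)
from .zcurve import DisparitySet, circular_distance, disparity_curves, gc_extrema

INDICATOR_PROXIMITY_BP = 5000


@dataclass
class IndicatorTable:
    """Indicator-gene name patterns by chromosome type.

    On secondary chromosomes/replicons (e.g. Vibrio chromosome 2) replication
    initiates via RctB/RepA rather than DnaA, so chromosome_type="secondary"
    swaps the tiers: the secondary list becomes principal.
    """

    primary_genes: list[str] = field(default_factory=lambda: ["dnaA"])
    secondary_genes: list[str] = field(default_factory=lambda: ["dnaN", "repA", "rctB"])
    chromosome_type: str = "primary"

    def __post_init__(self) -> None:
        if not self.primary_genes:
            raise ValueError("primary indicator-gene list must be non-empty")

    def tiers(self) -> tuple[list[str], list[str]]:
        if self.chromosome_type == "secondary":
            return self.secondary_genes, self.primary_genes
        return self.primary_genes, self.secondary_genes


@dataclass(frozen=True)
class IndicatorHit:
    feature: GeneFeature
    tier: str  # "primary" | "secondary"


@dataclass
class CandidateScore:
    """One IGS with its score components and element annotations.

    Motif coordinates in ``boxes``/``trios``/``elements``/``due_window`` are
    local to the IGS sequence.
    """

    igs: IGS
    s_dist: float
    s_gene: float
    s_box: float
    total: float
    boxes: list[MotifHit] = field(default_factory=list)
    trios: list[TrioArray] = field(default_factory=list)
    elements: list[MotifHit] = field(default_factory=list)
    gatc_count: int = 0
    due_window: tuple[int, int] = (0, 0)

    @property
    def at_fraction(self) -> float:
        return self.igs.at_fraction()


@dataclass
class OriCPrediction:
    """A reported oriC candidate; coordinates 0-based internally."""

    record_id: str
    candidate: CandidateScore
    rank: int
    L: int
    topology: str

    @property
    def start(self) -> int:
        return self.candidate.igs.start

    @property
    def end(self) -> int:
        return self.candidate.igs.end

    @property
    def total(self) -> float:
        return self.candidate.total


@dataclass
class TerminusPrediction:
    position: int
    method: str  # "dif" | "gc_max"
    dif_hit: Optional[MotifHit] = None


def _word_in(needle: str, haystack: str) -> bool:
    words = haystack.lower().replace("/", " ").split()
    return needle.lower() in words


def find_indicator_genes(
    record: GenomeRecord, table: Optional[IndicatorTable] = None
) -> list[IndicatorHit]:
    """Features matching the indicator table by gene name or product word.

    Matching is case-insensitive on the gene name (exact) and on the product
    description (whole word, e.g. product "chromosomal replication initiator
    protein DnaA" matches pattern "dnaA"). Fallback ORFs carry no names and
    never match.
    """
    table = table or IndicatorTable()
    primary, secondary = table.tiers()
    hits = []
    for feat in record.features:
        matched_tier = None
        for tier, patterns in (("primary", primary), ("secondary", secondary)):
            for pat in patterns:
                if feat.gene_name.lower() == pat.lower() or (
                    feat.product and _word_in(pat, feat.product)
                ):
                    matched_tier = tier
                    break
            if matched_tier:
                break
        if matched_tier:
            hits.append(IndicatorHit(feat, matched_tier))
    return hits


def _distance_to_interval(pos: int, igs: IGS, L: int, topology: str) -> int:
    start = igs.start
    end_excl = (igs.start + igs.length) % L if topology == "circular" else igs.start + igs.length
    if topology == "circular":
        off = (pos - start) % L
        if off < igs.length:
            return 0
        return min(
            circular_distance(pos, start, L, topology),
            circular_distance(pos, end_excl, L, topology),
        )
    if start <= pos < end_excl:
        return 0
    return min(abs(pos - start), abs(pos - end_excl))


def score_igs(
    igs: IGS,
    gc_min_pos: int,
    L: int,
    topology: str,
    indicators: Sequence[IndicatorHit],
    config: Optional[MotifConfig] = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    due_window_bp: int = 30,
) -> CandidateScore:
    """Score one IGS and annotate all functional elements on it."""
    config = config or MotifConfig()

    d = circular_distance(igs.midpoint(L), gc_min_pos, L, topology)
    s_dist = max(0.0, 1.0 - d / (L / 2))

    flanks = [g for g in (igs.left_gene, igs.right_gene) if g is not None]
    s_gene = 0.0
    if any(ind.tier == "primary" and ind.feature in flanks for ind in indicators):
        s_gene = 1.0
    elif any(ind.tier == "secondary" and ind.feature in flanks for ind in indicators):
        s_gene = 0.75
    elif any(
        _distance_to_interval(ind.feature.midpoint, igs, L, topology)
        <= INDICATOR_PROXIMITY_BP
        for ind in indicators
    ):
        s_gene = 0.5

    k = config.dnaa_box_max_mm
    boxes = find_dnaa_boxes(igs.sequence, config)
    s_box = min(sum((k + 1 - h.mismatches) / (k + 1) for h in boxes) / 3.0, 1.0)

    trios = find_dnaa_trios(igs.sequence, boxes, config)
    elements = find_fixed_elements(igs.sequence, config)
    elements += find_loose_boxes_near_trios(igs.sequence, trios, config)
    gatc_count = sum(1 for h in elements if h.pattern_name == "GATC")
    due = due_window(igs.sequence, due_window_bp)

    total = weights[0] * s_dist + weights[1] * s_gene + weights[2] * s_box
    return CandidateScore(
        igs=igs,
        s_dist=s_dist,
        s_gene=s_gene,
        s_box=s_box,
        total=total,
        boxes=boxes,
        trios=trios,
        elements=elements,
        gatc_count=gatc_count,
        due_window=due,
    )


def rank_candidates(
    candidates: list[CandidateScore],
    record_order: Optional[dict[str, int]] = None,
) -> list[CandidateScore]:
    """Order candidates by total, screening exact ties by functional elements.

    Tie order: more DnaA-trio arrays, then more GATC sites, then higher AT
    fraction, then smaller start coordinate (and input record order when
    candidates from several contigs are pooled).
    """
    if not candidates:
        warnings.warn("rank_candidates: no candidates to rank")
        return []
    order = record_order or {}

    def key(c: CandidateScore):
        return (
            -c.total,
            -len(c.trios),
            -c.gatc_count,
            -c.at_fraction,
            order.get(c.igs.record_id, 0),
            c.igs.start,
        )

    return sorted(candidates, key=key)


def ensure_features(record: GenomeRecord, orf_min_len: int = 300) -> GenomeRecord:
    """Return the record with gene features, running the ORF fallback if bare."""
    if record.features:
        return record
    feats = find_orfs_fallback(record, min_len=orf_min_len)
    return GenomeRecord(
        id=record.id,
        sequence=record.sequence,
        description=record.description,
        topology=record.topology,
        features=feats,
        source=record.source,
    )


def _score_record(
    record: GenomeRecord,
    config: MotifConfig,
    table: IndicatorTable,
    min_igs_len: int,
    weights: tuple[float, float, float],
    orf_min_len: int,
    topology: Optional[str] = None,
) -> list[CandidateScore]:
    topo = topology or record.topology
    record = ensure_features(record, orf_min_len)
    igss = extract_igs(record, min_len=min_igs_len)
    if not igss:
        return []
    curves = disparity_curves(record.sequence)
    gc_min, _ = gc_extrema(curves, topo)
    indicators = find_indicator_genes(record, table)
    return [
        score_igs(igs, gc_min, len(record), topo, indicators, config, weights)
        for igs in igss
    ]


def _select_predictions(
    ranked: list[CandidateScore],
    topology_of: dict[str, tuple[int, str]],
    epsilon: float,
    min_total: float,
) -> list[OriCPrediction]:
    reported = []
    if ranked:
        top = ranked[0].total
        for c in ranked:
            if top - c.total <= epsilon and c.total > min_total:
                reported.append(c)
            else:
                break
    preds = []
    for rank, c in enumerate(reported, start=1):
        L, topo = topology_of[c.igs.record_id]
        preds.append(OriCPrediction(c.igs.record_id, c, rank, L, topo))
    return preds


def predict_oric(
    record: GenomeRecord,
    config: Optional[MotifConfig] = None,
    indicator_table: Optional[IndicatorTable] = None,
    min_igs_len: int = 80,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    epsilon: float = 0.0,
    min_total: float = 0.0,
    orf_min_len: int = 300,
) -> list[OriCPrediction]:
    """Predict oriC(s) of one complete replicon.

    Returns the top-scoring IGS, plus any co-ranked candidate within
    ``epsilon`` of the top total (default: exact ties only — multiple equal
    winners are all reported, as chromosomes can carry more than one origin).
    Candidates whose total is not above ``min_total`` are suppressed.
    """
    config = config or MotifConfig()
    table = indicator_table or IndicatorTable()
    scored = _score_record(
        record, config, table, min_igs_len, weights, orf_min_len
    )
    if not scored:
        warnings.warn(f"record {record.id}: no IGS of length >= {min_igs_len}; no prediction")
        return []
    ranked = rank_candidates(scored)
    preds = _select_predictions(
        ranked, {record.id: (len(record), record.topology)}, epsilon, min_total
    )
    if not preds:
        warnings.warn(f"record {record.id}: no candidate scored above {min_total}")
    return preds


def predict_oric_draft(
    records: Sequence[GenomeRecord],
    config: Optional[MotifConfig] = None,
    indicator_table: Optional[IndicatorTable] = None,
    min_igs_len: int = 80,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    epsilon: float = 0.0,
    min_total: float = 0.0,
    orf_min_len: int = 300,
) -> list[OriCPrediction]:
    """Predict oriC(s) across the contigs of a draft genome.

    Each contig is treated as a linear fragment and scored against its own
    GC-disparity minimum and its own length; candidates are then pooled and
    ranked globally.
    """
    config = config or MotifConfig()
    table = indicator_table or IndicatorTable()
    pooled: list[CandidateScore] = []
    meta: dict[str, tuple[int, str]] = {}
    order: dict[str, int] = {}
    for i, rec in enumerate(records):
        order[rec.id] = i
        meta[rec.id] = (len(rec), "linear")
        pooled.extend(
            _score_record(rec, config, table, min_igs_len, weights, orf_min_len, "linear")
        )
    if not pooled:
        warnings.warn("draft prediction: no IGS found on any contig")
        return []
    ranked = rank_candidates(pooled, record_order=order)
    preds = _select_predictions(ranked, meta, epsilon, min_total)
    if not preds:
        warnings.warn(f"draft prediction: no candidate scored above {min_total}")
    return preds


def predict_terminus(
    record: GenomeRecord | Sequence[GenomeRecord],
    config: Optional[MotifConfig] = None,
    curves: Optional[DisparitySet] = None,
) -> TerminusPrediction:
    """Predict the replication terminus of a complete genome.

    Uses the configured dif motif when it yields a hit (best = fewest
    mismatches, then nearest to the GC-disparity maximum); otherwise falls
    back to the GC-disparity maximum itself. Only defined for a single
    complete replicon.
    """
    if not isinstance(record, GenomeRecord):
        recs = list(record)
        if len(recs) != 1:
            raise UnsupportedOperationError(
                "terminus prediction is defined only for a complete single-replicon genome"
            )
        record = recs[0]
    config = config or MotifConfig()
    curves = curves or disparity_curves(record.sequence)
    _, gc_max = gc_extrema(curves, record.topology)
    if config.dif is not None:
        hits = scan_iupac(record.sequence, config.dif, config.dif_max_mm, "both")
        if hits:
            L = len(record)
            best = min(
                hits,
                key=lambda h: (
                    h.mismatches,
                    circular_distance((h.start + h.end) // 2, gc_max, L, record.topology),
                    h.start,
                ),
            )
            return TerminusPrediction((best.start + best.end) // 2, "dif", best)
    return TerminusPrediction(gc_max, "gc_max", None)
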