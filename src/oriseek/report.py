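"""Report generation: result JSON, candidate table, BED, annotated oriC view.

All user-facing coordinates are 1-based inclusive (GenBank convention);
internal coordinates are 0-based half-open. ``local`` element coordinates
(relative to an IGS) are converted to genome coordinates here.
"""

from __future__ import annotations

import json
import re
from typing import Optional

import pandas as pd

from .predict import CandidateScore, OriCPrediction, TerminusPrediction
from .strandbias import StrandBiasReport

# display priority when labeled element spans overlap (lower = wins)
ELEMENT_PRIORITY = {
    "DnaA_box": 0,
    "DnaA_box_loose": 1,
    "DnaA_trio": 2,
    "ATP_DnaA_box": 3,
    "CtrA": 4,
    "GATC": 5,
    "DUE": 6,
}
_LABEL_OPEN = re.compile(r"\[[A-Za-z0-9_+-]+\|")


def _one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def _candidate_spans(cand: CandidateScore) -> list[tuple[str, int, int, str, int]]:
    """(name, local start, local end, strand, mismatches/units) for all elements."""
    spans = []
    for h in cand.boxes:
        spans.append(("DnaA_box", h.start, h.end, h.strand, h.mismatches))
    for t in cand.trios:
        spans.append(("DnaA_trio", t.start, t.end, t.strand, t.n_units))
    for h in cand.elements:
        spans.append((h.pattern_name, h.start, h.end, h.strand, h.mismatches))
    s, e = cand.due_window
    if e > s:
        spans.append(("DUE", s, e, "+", 0))
    return spans


def render_annotated_oric(pred: OriCPrediction) -> str:
    """Plain-text view of the predicted oriC with inline element labels.

    Labels are non-destructive: stripping them (see :func:`strip_labels`)
    reproduces the raw IGS sequence byte-for-byte. Overlaps are resolved for
    display by element priority; every hit remains in the machine-readable
    outputs regardless.
    """
    cand = pred.candidate
    igs = cand.igs
    seq = igs.sequence
    spans = _candidate_spans(cand)
    spans.sort(key=lambda s: (ELEMENT_PRIORITY.get(s[0], 9), s[1], -(s[2] - s[1])))
    chosen: list[tuple[str, int, int]] = []
    for name, s, e, _strand, _x in spans:
        if all(e <= cs or s >= ce for _, cs, ce in chosen):
            chosen.append((name, s, e))
    chosen.sort(key=lambda c: c[1], reverse=True)
    labeled = seq
    for name, s, e in chosen:
        labeled = labeled[:s] + f"[{name}|" + labeled[s:e] + "]" + labeled[e:]

    lines = [
        f"# predicted oriC  record={pred.record_id}  rank={pred.rank}",
        f"# interval (1-based): {igs.start + 1}..{igs.end} length={igs.length} bp"
        + ("  (wraps coordinate origin)" if igs.end <= igs.start else ""),
        f"# scores: total={cand.total:.4f} dist={cand.s_dist:.4f} "
        f"gene={cand.s_gene:.4f} box={cand.s_box:.4f}",
        f"# flanking genes: left={_gene_label(igs.left_gene)} "
        f"right={_gene_label(igs.right_gene)}",
        labeled,
    ]
    return "\n".join(lines)


def _gene_label(g) -> str:
    if g is None:
        return "-"
    return g.gene_name or g.locus_tag


def strip_labels(text: str) -> str:
    """Recover the raw sequence from an annotated oriC view."""
    seq_line = text.rstrip("\n").split("\n")[-1]
    return _LABEL_OPEN.sub("", seq_line).replace("]", "")


def render_annotated_oric_html(pred: OriCPrediction) -> str:
    """Static HTML version of the annotated oriC view."""
    colors = {
        "DnaA_box": "#d62728",
        "DnaA_box_loose": "#ff9896",
        "DnaA_trio": "#2ca02c",
        "ATP_DnaA_box": "#9467bd",
        "CtrA": "#8c564b",
        "GATC": "#1f77b4",
        "DUE": "#e6c700",
    }
    text = render_annotated_oric(pred)
    body = text
    for name, col in colors.items():
        body = body.replace(
            f"[{name}|", f'<span style="background:{col};color:#fff" title="{name}">'
        )
    body = re.sub(r"\[[A-Za-z0-9_+-]+\|", '<span style="background:#999">', body)
    body = body.replace("]", "</span>")
    legend = " ".join(
        f'<span style="background:{c};color:#fff;padding:1px 4px">{n}</span>'
        for n, c in colors.items()
    )
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>predicted oriC</title></head><body>"
        f"<p>{legend}</p><pre style='white-space:pre-wrap;word-break:break-all'>"
        f"{body}</pre></body></html>"
    )


def prediction_to_dict(pred: OriCPrediction) -> dict:
    cand = pred.candidate
    igs = cand.igs
    L = pred.L
    elements = []
    for name, s, e, strand, score in _candidate_spans(cand):
        gs = (igs.start + s) % L
        ge = gs + (e - s)
        s1, e1 = _one_based(gs, ge)
        elements.append(
            {
                "name": name,
                "start": s1,
                "end": ((e1 - 1) % L) + 1,
                "strand": strand,
                "score": score,
            }
        )
    start1 = igs.start + 1
    end1 = igs.end if igs.end > igs.start else igs.end  # end is exclusive==inclusive 1-based
    return {
        "record_id": pred.record_id,
        "rank": pred.rank,
        "start": start1,
        "end": end1,
        "wraps_origin": igs.end <= igs.start,
        "length": igs.length,
        "total": round(cand.total, 6),
        "s_dist": round(cand.s_dist, 6),
        "s_gene": round(cand.s_gene, 6),
        "s_box": round(cand.s_box, 6),
        "n_dnaa_boxes": len(cand.boxes),
        "n_trios": len(cand.trios),
        "gatc_count": cand.gatc_count,
        "at_fraction": round(cand.at_fraction, 4),
        "left_gene": _gene_label(igs.left_gene),
        "right_gene": _gene_label(igs.right_gene),
        "elements": elements,
    }


def build_result(
    records: list,
    predictions: list[OriCPrediction],
    terminus: Optional[TerminusPrediction] = None,
    strand_bias: Optional[StrandBiasReport] = None,
    run_meta: Optional[dict] = None,
    warnings_list: Optional[list[str]] = None,
) -> dict:
    out = {
        "tool": "oriseek",
        "run": run_meta or {},
        "records": [
            {
                "id": r.id,
                "length": len(r),
                "topology": r.topology,
                "n_features": len(r.features),
                "source": r.source,
            }
            for r in records
        ],
        "predictions": [prediction_to_dict(p) for p in predictions],
        "terminus": None,
        "strand_bias": None,
        "warnings": warnings_list or [],
    }
    if terminus is not None:
        out["terminus"] = {
            "position": terminus.position + 1,
            "method": terminus.method,
            "dif_mismatches": terminus.dif_hit.mismatches if terminus.dif_hit else None,
        }
    if strand_bias is not None:
        part = strand_bias.partition
        out["strand_bias"] = {
            "note": "strand lengths are the two replichore arc lengths (oriC->ter, ter->oriC)",
            "arc1_frac": round(part.arc1_frac, 2),
            "arc2_frac": round(part.arc2_frac, 2),
            "leading_genes": strand_bias.leading_genes,
            "lagging_genes": strand_bias.lagging_genes,
            "leading_gene_frac": round(strand_bias.leading_gene_frac, 2),
            "leading_base_pct": {k: round(v, 2) for k, v in strand_bias.leading_base_pct.items()},
            "lagging_base_pct": {k: round(v, 2) for k, v in strand_bias.lagging_base_pct.items()},
        }
    return out


def write_result_json(result: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2)
        fh.write("\n")


def candidates_dataframe(candidates: list[CandidateScore]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        igs = c.igs
        rows.append(
            {
                "record_id": igs.record_id,
                "start": igs.start + 1,
                "end": igs.end,
                "length": igs.length,
                "s_dist": round(c.s_dist, 6),
                "s_gene": c.s_gene,
                "s_box": round(c.s_box, 6),
                "total": round(c.total, 6),
                "n_dnaa_boxes": len(c.boxes),
                "n_trios": len(c.trios),
                "gatc_count": c.gatc_count,
                "at_fraction": round(c.at_fraction, 4),
            }
        )
    return pd.DataFrame(rows)


def write_candidates_tsv(candidates: list[CandidateScore], path: str) -> None:
    candidates_dataframe(candidates).to_csv(path, sep="\t", index=False)


def write_elements_bed(
    predictions: list[OriCPrediction],
    path: str,
    terminus: Optional[TerminusPrediction] = None,
) -> None:
    """BED6 of predicted oriC interval(s), their elements, and the terminus."""
    with open(path, "w") as fh:
        for p in predictions:
            igs = p.candidate.igs
            end = igs.end if igs.end > igs.start else p.L  # truncate wrap display
            fh.write(f"{p.record_id}\t{igs.start}\t{end}\toriC\t{p.rank}\t+\n")
            for name, s, e, strand, score in _candidate_spans(p.candidate):
                gs = (igs.start + s) % p.L
                fh.write(f"{p.record_id}\t{gs}\t{gs + (e - s)}\t{name}\t{score}\t{strand}\n")
        if terminus is not None and predictions:
            rid = predictions[0].record_id
            fh.write(f"{rid}\t{terminus.position}\t{terminus.position + 1}\t"
                     f"terminus_{terminus.method}\t0\t+\n")
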