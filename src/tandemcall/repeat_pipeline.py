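"""Staged whole-genome repeat genotyping: anchor extraction, locus and
haplotype assignment, per-read copy counting, period estimation, dotplot
export.

The stages mirror how a long-read macrosatellite genotyping run proceeds:
reads carrying the centromeric flank anchor are pulled out under strict
placement confidence (mismap <= 1e-10, alignment length > 2 kb with the
published probe; small synthetic anchors use proportionally smaller
minima), assigned to a source locus (chr4 vs chr10 analog) by chained
alignment score over candidate references, and the inter-anchor segment is
decomposed into repeat copies by wraparound alignment against a single unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align_core import (ScoreModel, SplitAlignment, WrapAlignment,
                         local_align, mismap_of_score, placement_posterior,
                         split_align, wraparound_align)
from .synthetic_locus import POLYA_MOTIF, revcomp


@dataclass
class AnchorHit:
    read_id: str
    anchor_id: str
    score: float
    aligned_length: int
    mismap: float
    strand: str


@dataclass
class LocusAssignment:
    read_id: str
    best_ref: str | None
    error_prob: float
    margin: float
    status: str  # assigned / ambiguous / unassigned
    scores: dict


@dataclass
class RepeatCall:
    read_id: str
    copy_number: int
    fractional_copies: float
    left_partial: bool
    right_partial: bool
    haplotype_class: str | None  # A / AL / B / ambiguous; None when no 3' flank
    locus: str | None
    polya_motif_found: bool | None = None
    wrap: WrapAlignment | None = None


def extract_anchor_reads(reads, anchor_seq: str, model: ScoreModel,
                         min_len: int = 2000, max_mismap: float = 1e-10,
                         anchor_id: str = "anchor") -> list[AnchorHit]:
    """Report reads whose best anchor alignment is long and confidently placed.

    A hit is emitted iff the best alignment spans more than ``min_len``
    columns and its single-candidate mismap (1/(exp(lambda*score)+1)) is at
    most ``max_mismap``.  Both strands are searched; one hit per read.
    """
    hits: list[AnchorHit] = []
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        rid = getattr(read, "read_id", getattr(read, "id", "read"))
        cands = local_align(seq, anchor_seq, model, max_hits=4,
                            query_id=rid, ref_id=anchor_id)
        if not cands:
            continue
        best = cands[0]
        length = sum(n for n, op in _edit_lengths(best.edit_string))
        mm = mismap_of_score(best.score, model)
        if length > min_len and mm <= max_mismap:
            hits.append(AnchorHit(read_id=rid, anchor_id=anchor_id,
                                  score=best.score, aligned_length=length,
                                  mismap=mm, strand=best.strand))
    return hits


def _edit_lengths(edit_string: str):
    from .align_core import expand_ops
    return list(expand_ops(edit_string))


def assign_locus(read, candidate_refs: dict[str, str], model: ScoreModel,
                 max_errprob: float = 1e-5, max_hits: int = 4) -> LocusAssignment:
    """Assign a read to one of several candidate loci by chained score.

    Each reference is chain-aligned separately; the per-reference totals are
    softmaxed (with a null) to get the assignment error probability.  Repeat
    content shared between candidates cancels in the posterior, so the
    discriminating signal is the flank sequence, as it should be.
    """
    if len(candidate_refs) < 2:
        raise ValueError("need at least two candidate references")
    seq = read if isinstance(read, str) else read.sequence
    rid = getattr(read, "read_id", getattr(read, "id", "read"))
    totals: dict[str, float] = {}
    for ref_id, ref_seq in candidate_refs.items():
        sa = split_align(seq, {ref_id: ref_seq}, model, max_hits=max_hits)
        totals[ref_id] = sa.total_score
    if all(t <= 0 for t in totals.values()):
        return LocusAssignment(rid, None, 1.0, 0.0, "unassigned", totals)
    order = sorted(totals, key=totals.get, reverse=True)
    best = order[0]
    margin = totals[best] - (totals[order[1]] if len(order) > 1 else 0.0)
    post, _, _ = placement_posterior([totals[r] for r in order], model)
    err = float(1.0 - post[0])
    status = "assigned" if err <= max_errprob else "ambiguous"
    return LocusAssignment(rid, best, err, margin, status, totals)


def assign_haplotype(read, flank3_refs: dict[str, str], model: ScoreModel,
                     min_margin: float = 25.0) -> tuple[str, float, bool | None]:
    """Classify the telomeric flank of an array-spanning read.

    The best-scoring flank variant wins; a top-two margin under
    ``min_margin`` score units is called ambiguous.  For class A the
    polyadenylation-signal analog (ATTAAA) is additionally searched in the
    read segment aligned to the variant.  Returns (class, margin,
    motif_found or None).
    """
    seq = read if isinstance(read, str) else read.sequence
    results: dict[str, object] = {}
    for name, ref in flank3_refs.items():
        cands = local_align(seq, ref, model, max_hits=2)
        results[name] = cands[0] if cands else None
    scored = {n: (a.score if a else 0.0) for n, a in results.items()}
    order = sorted(scored, key=scored.get, reverse=True)
    if len(order) < 2 or scored[order[0]] - scored[order[1]] < min_margin:
        return "ambiguous", scored[order[0]] - scored[order[1]] if len(order) > 1 else 0.0, None
    cls = order[0]
    motif_found = None
    if cls in ("A", "AL"):
        best = results[cls]
        qseq = seq if best.strand == "+" else revcomp(seq)
        segment = qseq[best.query_start:best.query_end]
        motif_found = POLYA_MOTIF in segment
    return cls, scored[order[0]] - scored[order[1]], motif_found


def count_repeats(read, unit: str, flank5: str, flank3: str,
                  model: ScoreModel, completeness: float = 0.9,
                  flank3_refs: dict[str, str] | None = None,
                  min_anchor_score: float = 30.0,
                  locus: str | None = None) -> RepeatCall:
    """Count repeat copies in one read by wraparound alignment.

    Flank anchors are located first; the segment between them is aligned to
    the single unit with free wraparound.  Missing anchors set the partial
    flags and leave the corresponding boundary at the read end, so partial
    (array-edge) reads still yield a lower-bound count.
    """
    seq = read if isinstance(read, str) else read.sequence
    rid = getattr(read, "read_id", getattr(read, "id", "read"))
    h5 = local_align(seq, flank5, model, max_hits=2, min_score=min_anchor_score)
    h3 = local_align(seq, flank3, model, max_hits=2, min_score=min_anchor_score)
    best5 = h5[0] if h5 else None
    best3 = h3[0] if h3 else None
    # orient the read by the stronger anchor
    lead = max((a for a in (best5, best3) if a is not None),
               key=lambda a: a.score, default=None)
    strand = lead.strand if lead else "+"
    oriented = seq if strand == "+" else revcomp(seq)
    if best5 is not None and best5.strand != strand:
        best5 = None
    if best3 is not None and best3.strand != strand:
        best3 = None
    left_partial = best5 is None
    right_partial = best3 is None
    start = 0
    end = len(oriented)
    if best5 is not None:
        # advance to the 3' end of the flank even if the hit stopped short
        start = min(len(oriented), best5.query_end + (len(flank5) - best5.ref_end))
    if best3 is not None:
        end = max(start, best3.query_start - best3.ref_start)
    segment = oriented[start:end]
    if len(segment) < 10:
        return RepeatCall(rid, 0, 0.0, left_partial, right_partial,
                          None, locus)
    wrapped = wraparound_align(segment, unit, model, completeness)
    hap = None
    motif = None
    if not right_partial and flank3_refs:
        hap, _, motif = assign_haplotype(oriented, flank3_refs, model)
    return RepeatCall(rid, wrapped.copy_count, wrapped.fractional_copies,
                      left_partial, right_partial, hap, locus,
                      polya_motif_found=motif, wrap=wrapped)


def estimate_period(array_seq: str, min_p: int = 16,
                    max_p: int | None = None,
                    coarse_step_above: int = 200_000,
                    tie_tol: float = 0.005) -> int:
    """Smallest period minimizing the normalized self-match distance.

    Compares ``array_seq[:-p]`` with ``array_seq[p:]`` for every candidate
    shift p (coarse scan with local refinement on very long inputs) and
    returns the smallest p whose distance is within a small tolerance of the
    global minimum — exact on noiseless arrays, where the true period gives
    distance zero and its multiples tie.
    """
    L = len(array_seq)
    if max_p is None:
        max_p = L // 2
    if L < 2 * min_p or max_p < min_p:
        raise ValueError("sequence shorter than twice the minimum period")
    a = np.frombuffer(array_seq.encode("ascii"), np.uint8)
    step = 1 if L <= coarse_step_above else max(1, max_p // 20_000)

    def dist(p: int) -> float:
        return float(np.count_nonzero(a[:-p] != a[p:])) / (L - p)

    ps = np.arange(min_p, max_p + 1, step)
    d = np.array([dist(int(p)) for p in ps])
    if step > 1:
        best = int(ps[int(np.argmin(d))])
        lo, hi = max(min_p, best - step), min(max_p, best + step)
        ps = np.arange(lo, hi + 1)
        d = np.array([dist(int(p)) for p in ps])
    dmin = float(d.min())
    # multiples of the true period tie up to sampling noise, which scales
    # with the error-driven floor dmin; prefer the smallest near-tied p
    thresh = dmin + max(tie_tol, 0.25 * dmin)
    return int(ps[np.flatnonzero(d <= thresh)[0]])


def dotplot_segments(alignment, query_id: str = "query",
                     ref_id: str = "ref") -> list[tuple]:
    """Flatten a split or wraparound alignment into dotplot segments."""
    segs: list[tuple] = []
    if isinstance(alignment, WrapAlignment):
        for t in alignment.traversals:
            segs.append((query_id, ref_id, t.query_start, t.query_end,
                         t.unit_start, t.unit_end, "+"))
    elif isinstance(alignment, SplitAlignment):
        for p in alignment.parts:
            segs.append((p.query_id, p.ref_id, p.query_start, p.query_end,
                         p.ref_start, p.ref_end, p.strand))
    elif alignment is not None:
        p = alignment
        segs.append((p.query_id, p.ref_id, p.query_start, p.query_end,
                     p.ref_start, p.ref_end, p.strand))
    return segs
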