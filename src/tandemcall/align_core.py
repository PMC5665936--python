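"""Pairwise alignment engine with a trainable error model.

This is the computational analog of a LAST-style workflow: local alignment
under a log-odds score model, iterative (Viterbi-EM) training of that model
from reads, split alignment with a placement posterior ("mismap"), and
wraparound alignment of a read against a single tandem-repeat unit to count
copies.

Score model
-----------
Scores are log-odds in units of ``scale_lambda`` nats:
``s(a,b) = log(P(b observed | a true) / bg(b)) / scale_lambda``.  The default
untrained model is +1 match / -1 mismatch with gap open -2 / extend -1 (a gap
of length L scores ``gap_open + L * gap_extend``), and ``scale_lambda`` is
calibrated Karlin-Altschul style so that sum_ij p_i p_j e^{lambda s_ij} = 1
under the background composition.

The placement posterior for a query segment with candidate scores s_1..s_k is
a softmax over ``exp(lambda * s_i)`` plus a null hypothesis of score 0;
``mismap = 1 - max posterior``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .io_formats import AlignmentRow
from .synthetic_locus import revcomp

_CODE = np.full(256, 4, np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_OPCHARS = "=XID"
PROB_FLOOR = 1e-6


class AlignError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]


def compress_ops(ops: np.ndarray) -> str:
    """Run-length encode an op-code array into a CIGAR-like string."""
    if len(ops) == 0:
        return ""
    parts = []
    run_op = ops[0]
    run = 1
    for o in ops[1:]:
        if o == run_op:
            run += 1
        else:
            parts.append(f"{run}{_OPCHARS[run_op]}")
            run_op = o
            run = 1
    parts.append(f"{run}{_OPCHARS[run_op]}")
    return "".join(parts)


def expand_ops(edit_string: str):
    """Yield (count, opchar) pairs from a CIGAR-like string."""
    num = ""
    for c in edit_string:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def calibrate_lambda(subst_scores: np.ndarray, bg: np.ndarray) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0 (bisection)."""

    def f(lam: float) -> float:
        return float(np.sum(np.outer(bg, bg) * np.exp(lam * subst_scores))) - 1.0

    hi = 1.0
    for _ in range(64):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:
        raise AlignError("expected score under background must be negative")
    lo = 1e-9
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class ScoreModel:
    subst_scores: np.ndarray
    gap_open: float = -2.0
    gap_extend: float = -1.0
    scale_lambda: float = 0.0
    background_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    subst_probs: np.ndarray | None = None   # rows: true base, cols: observed
    gap_probs: dict | None = None           # {'open': p, 'extend': p}

    @classmethod
    def default(cls) -> "ScoreModel":
        s = np.full((4, 4), -1.0)
        np.fill_diagonal(s, 1.0)
        m = cls(subst_scores=s)
        m.scale_lambda = calibrate_lambda(s, m.background_freqs)
        return m

    def matrix5(self) -> np.ndarray:
        """5x5 score matrix with an ambiguity row/column at the worst score."""
        worst = float(self.subst_scores.min())
        S = np.full((5, 5), worst)
        S[:4, :4] = self.subst_scores
        return S

    # -- serialization (documented key=value layout, bit-exact round trip) --

    def to_text(self) -> str:
        lines = [f"gap_open\t{float(self.gap_open)!r}",
                 f"gap_extend\t{float(self.gap_extend)!r}",
                 f"scale_lambda\t{float(self.scale_lambda)!r}"]
        lines.append("background\t" + "\t".join(repr(float(x)) for x in self.background_freqs))
        for i, b in enumerate("ACGT"):
            lines.append(f"score_{b}\t" + "\t".join(repr(float(x)) for x in self.subst_scores[i]))
        if self.subst_probs is not None:
            for i, b in enumerate("ACGT"):
                lines.append(f"prob_{b}\t" + "\t".join(repr(float(x)) for x in self.subst_probs[i]))
        if self.gap_probs is not None:
            lines.append(f"gap_probs\t{float(self.gap_probs['open'])!r}\t"
                         f"{float(self.gap_probs['extend'])!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ScoreModel":
        vals: dict[str, list[str]] = {}
        for line in text.strip().splitlines():
            key, *rest = line.split("\t")
            vals[key] = rest
        scores = np.array([[float(x) for x in vals[f"score_{b}"]] for b in "ACGT"])
        m = cls(subst_scores=scores,
                gap_open=float(vals["gap_open"][0]),
                gap_extend=float(vals["gap_extend"][0]),
                scale_lambda=float(vals["scale_lambda"][0]),
                background_freqs=np.array([float(x) for x in vals["background"]]))
        if "prob_A" in vals:
            m.subst_probs = np.array([[float(x) for x in vals[f"prob_{b}"]] for b in "ACGT"])
        if "gap_probs" in vals:
            m.gap_probs = {"open": float(vals["gap_probs"][0]),
                           "extend": float(vals["gap_probs"][1])}
        return m

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "ScoreModel":
        with open(path) as fh:
            return cls.from_text(fh.read())


def rescore(edit_string: str, query: str, ref: str, q_start: int, r_start: int,
            model: ScoreModel) -> float:
    """Recompute an alignment score from its edit string (audit helper)."""
    S = model.matrix5()
    qi, ri = q_start, r_start
    qc, rc = encode(query), encode(ref)
    total = 0.0
    for n, op in expand_ops(edit_string):
        if op in "=X":
            for _ in range(n):
                total += S[qc[qi], rc[ri]]
                qi += 1
                ri += 1
        elif op == "I":
            total += model.gap_open + n * model.gap_extend
            qi += n
        elif op == "D":
            total += model.gap_open + n * model.gap_extend
            ri += n
    return total


def identity_of(edit_string: str) -> float:
    cols = match = 0
    for n, op in expand_ops(edit_string):
        cols += n
        if op == "=":
            match += n
    return match / cols if cols else 0.0


# ---------------------------------------------------------------------------
# seeding


class KmerIndex:
    """Exact k-mer index of a reference for diagonal seeding."""

    def __init__(self, ref: str, k: int = 12):
        self.k = k
        self.ref = ref
        self.index: dict[str, list[int]] = {}
        for i in range(len(ref) - k + 1):
            self.index.setdefault(ref[i:i + k], []).append(i)

    def diagonal_clusters(self, query: str, bucket: int = 64,
                          max_per_kmer: int = 64) -> list[tuple[int, int, int]]:
        """Return (support, dmin, dmax) clusters of diagonals d = ref - query."""
        k = self.k
        hist: dict[int, int] = {}
        lo: dict[int, int] = {}
        hi: dict[int, int] = {}
        for q in range(0, len(query) - k + 1):
            hits = self.index.get(query[q:q + k])
            if not hits or len(hits) > max_per_kmer:
                continue
            for r in hits:
                d = r - q
                b = d // bucket
                hist[b] = hist.get(b, 0) + 1
                if b not in lo or d < lo[b]:
                    lo[b] = d
                if b not in hi or d > hi[b]:
                    hi[b] = d
        if not hist:
            return []
        # merge adjacent buckets into clusters
        clusters = []
        for b in sorted(hist):
            if clusters and b == clusters[-1][3] + 1:
                s, dmin, dmax, _ = clusters[-1]
                clusters[-1] = (s + hist[b], min(dmin, lo[b]), max(dmax, hi[b]), b)
            else:
                clusters.append((hist[b], lo[b], hi[b], b))
        return sorted(((s, dmin, dmax) for s, dmin, dmax, _ in clusters),
                      key=lambda c: (-c[0], c[1]))


# ---------------------------------------------------------------------------
# local alignment

SW_FULL_LIMIT = 4_000_000  # cells; above this, seed-and-extend is used


def _band_pad(qlen: int) -> int:
    return 96 + int(0.03 * qlen)


def _row_from_tb(ops_rev, qi, ri, bi, bj, score, strand, query_id, ref_id,
                 mismap=0.0) -> AlignmentRow:
    edit = compress_ops(ops_rev[::-1])
    return AlignmentRow(query_id=query_id, ref_id=ref_id,
                        query_start=qi, query_end=bi,
                        ref_start=ri, ref_end=bj, strand=strand,
                        score=float(score), identity=identity_of(edit),
                        mismap=mismap, edit_string=edit)


def _local_one_strand(qseq: str, ref: str, model: ScoreModel, strand: str,
                      query_id: str, ref_id: str, max_hits: int,
                      min_score: float, index: KmerIndex | None) -> list[AlignmentRow]:
    S = model.matrix5()
    qc, rc = encode(qseq), encode(ref)
    out: list[AlignmentRow] = []
    if len(qseq) * len(ref) <= SW_FULL_LIMIT:
        best, bi, bj, ptr = _dp.sw_full(qc, rc, S, model.gap_open, model.gap_extend)
        if best >= min_score:
            ops, si, sj = _dp.tb_full(ptr, qc, rc, bi, bj)
            out.append(_row_from_tb(ops, si, sj, bi, bj, best, strand,
                                    query_id, ref_id))
        return out
    idx = index if index is not None else KmerIndex(ref)
    pad = _band_pad(len(qseq))
    for support, dmin, dmax in idx.diagonal_clusters(qseq)[:max_hits]:
        # KmerIndex diagonals are d = ref - query, matching banded()'s
        # d = j - i with query as rows and ref as columns.
        dlo, dhi = dmin - pad, dmax + pad
        dlo = max(dlo, -len(qseq))
        dhi = min(dhi, len(ref))
        best, bi, bw, ptr = _dp.banded(qc, rc, S, model.gap_open,
                                       model.gap_extend, dlo, dhi, 1)
        if best >= min_score:
            ops, si, sj = _dp.tb_banded(ptr, qc, rc, bi, bw, dlo, 1)
            out.append(_row_from_tb(ops, si, sj, bi, bi + dlo + bw, best,
                                    strand, query_id, ref_id))
    return out


def local_align(query: str, ref: str, model: ScoreModel, max_hits: int = 16,
                query_id: str = "query", ref_id: str = "ref",
                min_score: float = 15.0,
                index: KmerIndex | None = None) -> list[AlignmentRow]:
    """Local affine-gap alignments of query vs ref, both strands.

    Inputs small enough for full Smith-Waterman are solved exactly; longer
    pairs go through k-mer diagonal seeding plus banded Smith-Waterman.
    Results are sorted by score with a deterministic tie-break (smaller
    ref_start, then query_start, then '+' strand).  Query coordinates of '-'
    strand hits refer to the reverse-complemented query.
    """
    if not query or not ref:
        raise AlignError("empty sequence")
    rows = _local_one_strand(query, ref, model, "+", query_id, ref_id,
                             max_hits, min_score, index)
    rows += _local_one_strand(revcomp(query), ref, model, "-", query_id,
                              ref_id, max_hits, min_score, index)
    rows.sort(key=lambda a: (-a.score, a.ref_start, a.query_start,
                             a.strand != "+"))
    # drop duplicate placements (same strand and heavily overlapping ref span)
    kept: list[AlignmentRow] = []
    for r in rows:
        dup = False
        for s in kept:
            if r.strand == s.strand and \
               min(r.ref_end, s.ref_end) - max(r.ref_start, s.ref_start) \
               > 0.5 * (r.ref_end - r.ref_start):
                dup = True
                break
        if not dup:
            kept.append(r)
    return kept[:max_hits]


def map_read(read_seq: str, ref: str, model: ScoreModel,
             index: KmerIndex | None = None,
             rng: np.random.Generator | None = None,
             query_id: str = "read", ref_id: str = "ref",
             tie_ratio: float = 0.8) -> AlignmentRow | None:
    """Glocal placement of a read on a reference (query-global, ref ends free).

    When several seed clusters are nearly as well supported (tandem-repeat
    ambiguity), one is chosen at random via ``rng`` so that coverage spreads
    over equivalent placements; without an rng the best-supported cluster is
    taken deterministically.
    """
    idx = index if index is not None else KmerIndex(ref)
    S = model.matrix5()
    pad = _band_pad(len(read_seq))
    best_row: AlignmentRow | None = None
    for strand in "+-":
        qseq = read_seq if strand == "+" else revcomp(read_seq)
        clusters = idx.diagonal_clusters(qseq)
        if not clusters:
            continue
        top = clusters[0][0]
        cands = [c for c in clusters if c[0] >= tie_ratio * top]
        if rng is not None and len(cands) > 1:
            support, dmin, dmax = cands[int(rng.integers(0, len(cands)))]
        else:
            support, dmin, dmax = cands[0]
        dlo = max(dmin - pad, -len(qseq))
        dhi = min(dmax + pad, len(ref))
        qc = encode(qseq)
        rc = encode(ref)
        best, bi, bw, ptr = _dp.banded(qc, rc, S, model.gap_open,
                                       model.gap_extend, dlo, dhi, 0)
        if best <= _dp.NEG / 2:
            continue
        ops, si, sj = _dp.tb_banded(ptr, qc, rc, bi, bw, dlo, 0)
        row = _row_from_tb(ops, si, sj, bi, bi + dlo + bw, best, strand,
                           query_id, ref_id)
        if best_row is None or row.score > best_row.score:
            best_row = row
    return best_row


# ---------------------------------------------------------------------------
# placement posterior / mismap


def placement_posterior(scores, model: ScoreModel):
    """Posterior over candidate placements plus a null hypothesis of score 0.

    posterior_i = exp(lambda*s_i) / (sum_j exp(lambda*s_j) + exp(0)).
    Returns (candidate posteriors, null posterior, mismap = 1 - max posterior).
    """
    if len(scores) == 0:
        raise AlignError("at least one candidate required")
    lam = model.scale_lambda
    logs = np.asarray([lam * s for s in scores] + [0.0])
    mx = logs.max()
    w = np.exp(logs - mx)
    post = w / w.sum()
    return post[:-1], float(post[-1]), float(1.0 - post[:-1].max())


def mismap_of_score(score: float, model: ScoreModel) -> float:
    """Closed form for a single candidate: 1 / (exp(lambda*score) + 1)."""
    x = model.scale_lambda * score
    if x > 700:
        return math.exp(-x)
    return 1.0 / (math.exp(x) + 1.0)


# ---------------------------------------------------------------------------
# split alignment


@dataclass
class SplitAlignment:
    parts: list[AlignmentRow]
    total_score: float

    @property
    def refs(self) -> list[str]:
        return [p.ref_id for p in self.parts]


def split_align(query: str, refs: dict[str, str], model: ScoreModel,
                switch_penalty: float = 15.0, max_hits: int = 8) -> SplitAlignment:
    """Chain query-disjoint local alignments over one or more references.

    Dynamic programming over candidates ordered by query position maximizes
    total score minus ``switch_penalty`` per change of reference.  Per-part
    mismap comes from the placement posterior restricted to candidates
    overlapping that part's query range.
    """
    cands: list[AlignmentRow] = []
    for rid, rseq in refs.items():
        cands.extend(local_align(query, rseq, model, max_hits=max_hits,
                                 query_id="query", ref_id=rid))
    if not cands:
        return SplitAlignment(parts=[], total_score=0.0)
    cands.sort(key=lambda a: (a.query_start, a.query_end))
    n = len(cands)
    dp = [c.score for c in cands]
    back = [-1] * n
    for i in range(n):
        for j in range(i):
            if cands[j].query_end <= cands[i].query_start:
                pen = switch_penalty if cands[j].ref_id != cands[i].ref_id else 0.0
                v = dp[j] + cands[i].score - pen
                if v > dp[i]:
                    dp[i] = v
                    back[i] = j
    k = int(np.argmax(dp))
    chain = []
    while k >= 0:
        chain.append(cands[k])
        k = back[k]
    chain.reverse()
    parts = []
    for part in chain:
        rivals = [part.score]
        rivals += [c.score for c in cands if c is not part and
                   _overlap(c, part) > 0.5 * (part.query_end - part.query_start)]
        post, _, _ = placement_posterior(rivals, model)
        mm = float(1.0 - post[0])
        parts.append(AlignmentRow(**{**part.__dict__, "mismap": mm}))
    return SplitAlignment(parts=parts, total_score=float(max(dp)))


def _overlap(a: AlignmentRow, b: AlignmentRow) -> int:
    return min(a.query_end, b.query_end) - max(a.query_start, b.query_start)


# ---------------------------------------------------------------------------
# wraparound alignment


@dataclass
class Traversal:
    query_start: int
    query_end: int
    unit_start: int   # 0-based unit coordinate of first consumed column
    unit_end: int     # half-open
    covered: int      # distinct unit columns consumed
    score: float
    partial: bool


@dataclass
class WrapAlignment:
    traversals: list[Traversal]
    copy_count: int
    fractional_copies: float
    total_score: float
    unit_len: int

    @property
    def left_partial(self) -> bool:
        return bool(self.traversals) and self.traversals[0].partial

    @property
    def right_partial(self) -> bool:
        return bool(self.traversals) and self.traversals[-1].partial


def wraparound_align(query: str, unit: str, model: ScoreModel,
                     completeness: float = 0.9) -> WrapAlignment:
    """Align a query against a single repeat unit with free wraparound.

    The DP is global in the query; the start position within the unit is
    free, and the diagonal transition from the last unit column back to the
    first costs nothing, so tandem copies appear as successive traversals.
    ``copy_count`` is the number of traversals covering at least
    ``completeness * unit_len`` unit columns; ``fractional_copies`` is total
    consumed unit columns / unit length.
    """
    if len(unit) < 10:
        raise AlignError("unit must be at least 10 bp")
    if not query:
        raise AlignError("empty query")
    qc, uc = encode(query), encode(unit)
    S = model.matrix5()
    best, bj, ptr = _dp.wrap(qc, uc, S, model.gap_open, model.gap_extend)
    ops, cols, wraps = _dp.tb_wrap(ptr, qc, uc, bj)
    ops, cols, wraps = ops[::-1], cols[::-1], wraps[::-1]
    m = len(unit)
    travs: list[Traversal] = []
    qpos = 0
    cur = None  # [q_start, unit_min, unit_max, covered, score]
    score_here = 0.0
    for t in range(len(ops)):
        op, j, w = int(ops[t]), int(cols[t]), int(wraps[t])
        new_traversal = cur is None or (w == 1 and t > 0)
        if new_traversal and cur is not None:
            travs.append(Traversal(cur[0], qpos, cur[1] - 1, cur[2],
                                   cur[3], cur[4], False))
            cur = None
        if cur is None:
            cur = [qpos, j, j, 0, 0.0]
        if op in (0, 1):
            score_here = S[qc[qpos], uc[j - 1]]
            cur[3] += 1
            cur[2] = max(cur[2], j)
            cur[1] = min(cur[1], j)
            qpos += 1
        elif op == 2:
            score_here = 0.0  # gap run scores folded below
            qpos += 1
        else:
            cur[3] += 1
            cur[2] = max(cur[2], j)
            cur[1] = min(cur[1], j)
        cur[4] += score_here
    if cur is not None:
        travs.append(Traversal(cur[0], qpos, cur[1] - 1, cur[2],
                               cur[3], cur[4], False))
    need = completeness * m
    for k, tr in enumerate(travs):
        if tr.covered < need:
            travs[k] = Traversal(tr.query_start, tr.query_end, tr.unit_start,
                                 tr.unit_end, tr.covered, tr.score, True)
    copy_count = sum(1 for tr in travs if tr.covered >= need)
    frac = sum(tr.covered for tr in travs) / m
    return WrapAlignment(traversals=travs, copy_count=copy_count,
                         fractional_copies=frac, total_score=float(best),
                         unit_len=m)


# ---------------------------------------------------------------------------
# error-model training (Viterbi EM)


def _tally(row: AlignmentRow, qseq: str, ref: str, C: np.ndarray,
           gaps: np.ndarray) -> None:
    qi, ri = row.query_start, row.ref_start
    for n, op in expand_ops(row.edit_string):
        if op in "=X":
            for _ in range(n):
                a = _CODE[ord(ref[ri])]
                b = _CODE[ord(qseq[qi])]
                if a < 4 and b < 4:
                    C[a, b] += 1
                qi += 1
                ri += 1
        else:
            gaps[0] += 1          # opens
            gaps[1] += n - 1      # extensions
            if op == "I":
                qi += n
            else:
                ri += n


def train_error_model(reads, ref: str, init: ScoreModel | None = None,
                      max_iters: int = 10, tol: float = 1e-4) -> ScoreModel:
    """Iteratively re-align reads and re-estimate the substitution/gap model.

    Each iteration aligns every read with the current model, tallies
    substitution and gap events with pseudocount 1, converts tallies to
    probabilities and then to log-odds scores.  Stops when all probabilities
    move by less than ``tol`` or after ``max_iters``.  The tally
    log-likelihood is checked to be non-decreasing (small numerical slack).

    ``reads`` may be strings or objects with a ``sequence`` attribute.
    """
    model = init if init is not None else ScoreModel.default()
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    index = KmerIndex(ref)
    lam = model.scale_lambda
    prev_probs = None
    prev_ll = -np.inf
    history: list[float] = []
    for it in range(max_iters):
        C = np.ones((4, 4))
        gaps = np.ones(2)
        n_aligned = 0
        for s in seqs:
            # deterministic placement: tallies must only move with the model
            row = map_read(s, ref, model, index=index, rng=None)
            if row is None:
                continue
            n_aligned += 1
            _tally(row, s if row.strand == "+" else revcomp(s), ref, C, gaps)
        if n_aligned == 0:
            raise TrainingError("no read aligned to the reference")
        aligned_cols = C.sum()
        p_open = gaps[0] / (aligned_cols + gaps[0])
        p_extend = gaps[1] / (gaps[0] + gaps[1])
        subst_probs = C / C.sum(axis=1, keepdims=True)
        subst_probs = np.maximum(subst_probs, PROB_FLOOR)
        p_open = min(max(p_open, PROB_FLOOR), 0.5)
        p_extend = min(max(p_extend, PROB_FLOOR), 0.95)
        ll = float((C * np.log(subst_probs)).sum()
                   + (aligned_cols + gaps[0]) * 0.0
                   + gaps[0] * np.log(p_open) + aligned_cols * np.log1p(-p_open)
                   + gaps[1] * np.log(p_extend) + gaps[0] * np.log1p(-p_extend))
        history.append(ll)
        if it > 0 and ll < prev_ll - 1e-3 * abs(prev_ll) - 1e-9:
            raise TrainingError(
                f"training log-likelihood decreased at iteration {it}: "
                f"{prev_ll} -> {ll}")
        prev_ll = max(prev_ll, ll)
        bg = model.background_freqs
        scores = np.log(((1.0 - p_open) * subst_probs) / bg[None, :]) / lam
        ge = math.log(p_extend) / lam
        go = (math.log(p_open) + math.log1p(-p_extend)) / lam - ge
        new = ScoreModel(subst_scores=scores, gap_open=go, gap_extend=ge,
                         scale_lambda=lam, background_freqs=bg.copy(),
                         subst_probs=subst_probs,
                         gap_probs={"open": p_open, "extend": p_extend})
        new.training_history = history  # type: ignore[attr-defined]
        if prev_probs is not None:
            delta = max(float(np.abs(subst_probs - prev_probs).max()),
                        abs(p_open - model.gap_probs["open"]) if model.gap_probs else 1.0)
            model = new
            if delta < tol:
                break
        else:
            model = new
        prev_probs = subst_probs
    return model
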