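"""Pileup consensus calling and consensus-error taxonomy.

Two consensus modes are provided.  ``majority`` picks the most common base
(or deletion) per reference column.  ``weighted`` uses a trained error model:
for truth hypothesis ``a`` the posterior is proportional to
``prior(a) * prod_reads P(observed | a)`` with the substitution matrix and
gap probabilities supplying the likelihoods — the single-haplotype analog of
a genotype caller driven by a trained alignment model.  With a
transition-biased error spectrum the weighted caller outresolves the majority
vote at columns where errors pile up on one alternative base.

The error-profile half classifies consensus-vs-truth differences the way a
nanopore error analysis does: transition vs transversion, position of each
error folded modulo the repeat unit (recurrent errors hit the same unit
offset in several copies), and the sequence context of recurrent errors
(CCNGG motif with the error at the center).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from .align_core import ScoreModel, expand_ops
from .io_formats import AlignmentRow
from .synthetic_locus import IUPAC, revcomp

_BASEIDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDXBASE = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
DEL = 4


class PileupError(ValueError):
    pass


@dataclass
class Pileup:
    """Per-column tallies over a reference: A, C, G, T, deletion."""

    counts: np.ndarray                 # (ref_len, 5) int32
    insertions: dict[int, Counter]     # ref_pos -> Counter of inserted strings
    ref: str

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def build_pileup(alignments: list[AlignmentRow], reads: dict[str, str],
                 ref: str) -> Pileup:
    """Tally every aligned base and deletion once per read.

    '-'-strand alignments carry query coordinates in the reverse-complemented
    frame, so the read is complemented before tallying.  Insertions are
    anchored to the preceding reference position.
    """
    counts = np.zeros((len(ref), 5), np.int32)
    insertions: dict[int, Counter] = {}
    for row in alignments:
        if row.query_id not in reads:
            raise PileupError(f"alignment references unknown read {row.query_id!r}")
        seq = reads[row.query_id]
        if row.strand == "-":
            seq = revcomp(seq)
        qi, ri = row.query_start, row.ref_start
        for n, op in expand_ops(row.edit_string):
            if op in "=X":
                for _ in range(n):
                    b = _BASEIDX.get(seq[qi])
                    if b is not None:
                        counts[ri, b] += 1
                    qi += 1
                    ri += 1
            elif op == "D":
                counts[ri:ri + n, DEL] += 1
                ri += n
            else:  # insertion: anchor after previous ref position
                insertions.setdefault(ri - 1, Counter())[seq[qi:qi + n]] += 1
                qi += n
    return Pileup(counts=counts, insertions=insertions, ref=ref)


@dataclass
class ConsensusResult:
    sequence: str
    support: np.ndarray        # per ref column: plurality fraction or posterior
    mode: str
    zero_depth: np.ndarray     # bool per ref column
    inserted_after: dict[int, str] = field(default_factory=dict)


def _weighted_logpost(col: np.ndarray, model: ScoreModel,
                      del_prior: float) -> np.ndarray:
    """Log posterior over truth in {A,C,G,T,deletion} for one column."""
    sp = np.maximum(model.subst_probs, 1e-9)
    p_open = max(model.gap_probs["open"], 1e-9)
    bg = model.background_freqs
    logp = np.empty(5)
    obs_b = col[:4]
    for a in range(4):
        logp[a] = (np.log(bg[a] * (1.0 - del_prior))
                   + float(obs_b @ np.log((1.0 - p_open) * sp[a]))
                   + col[DEL] * np.log(p_open))
    logp[DEL] = (np.log(del_prior)
                 + float(obs_b @ np.log(p_open * bg))
                 + col[DEL] * np.log1p(-p_open))
    return logp


def call_consensus(pileup: Pileup, mode: str = "majority",
                   model: ScoreModel | None = None,
                   ins_threshold: float = 0.5,
                   del_prior: float = 0.02) -> ConsensusResult:
    """Call a consensus from a pileup.

    majority: per-column plurality with the fixed tie order A<C<G<T<deletion;
    weighted: maximum-posterior truth state under the trained error model.
    Zero-depth columns become 'N' and are flagged.  An insertion is emitted
    when more than ``ins_threshold`` of the column depth supports the same
    inserted string.
    """
    if mode not in ("majority", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "weighted":
        if model is None or model.subst_probs is None or model.gap_probs is None:
            raise ValueError("weighted mode requires a trained model")
    L = len(pileup.ref)
    counts = pileup.counts
    depth = pileup.depth
    zero = depth == 0
    support = np.zeros(L)
    out: list[str] = []
    calls = np.zeros(L, np.int8)
    if mode == "majority":
        # argmax with tie-break by state order (A<C<G<T<del): argmax takes
        # the first maximum, which is exactly that order.
        calls = counts.argmax(axis=1).astype(np.int8)
        with np.errstate(invalid="ignore"):
            support = np.where(depth > 0, counts.max(axis=1) / np.maximum(depth, 1), 0.0)
    else:
        for i in range(L):
            if zero[i]:
                continue
            logp = _weighted_logpost(counts[i], model, del_prior)
            a = int(np.argmax(logp))
            calls[i] = a
            w = np.exp(logp - logp.max())
            support[i] = w[a] / w.sum()
    inserted_after: dict[int, str] = {}
    for pos, ctr in pileup.insertions.items():
        ins, c = ctr.most_common(1)[0]
        if 0 <= pos < L and depth[pos] > 0 and c > ins_threshold * depth[pos]:
            inserted_after[pos] = ins
    for i in range(L):
        if zero[i]:
            out.append("N")
        elif calls[i] != DEL:
            out.append(_IDXBASE[calls[i]])
        if i in inserted_after:
            out.append(inserted_after[i])
    return ConsensusResult(sequence="".join(out), support=support, mode=mode,
                           zero_depth=zero, inserted_after=inserted_after)


# ---------------------------------------------------------------------------
# identity and difference taxonomy


def align_to_truth(consensus: str, truth: str) -> list[tuple[str, int, int]]:
    """Column list (op, consensus_pos, truth_pos) of a global alignment.

    Ops are '=', 'X', 'I' (consensus-only base) and 'D' (truth-only base);
    positions are the 0-based coordinates consumed by the column (the
    preceding coordinate for the side a gap column does not consume).
    """
    if not consensus or not truth:
        raise ValueError("both sequences must be non-empty")
    res = edlib.align(consensus, truth, mode="NW", task="path")
    cols: list[tuple[str, int, int]] = []
    ci = ti = 0
    for n, op in expand_ops(res["cigar"]):
        for _ in range(n):
            if op in "=X":
                cols.append((op, ci, ti))
                ci += 1
                ti += 1
            elif op == "I":
                cols.append(("I", ci, ti - 1))
                ci += 1
            else:
                cols.append(("D", ci - 1, ti))
                ti += 1
    return cols


def _trim_end_gaps(cols: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Drop leading/trailing deletion columns (truth not covered by consensus)."""
    lo, hi = 0, len(cols)
    while lo < hi and cols[lo][0] == "D":
        lo += 1
    while hi > lo and cols[hi - 1][0] == "D":
        hi -= 1
    return cols[lo:hi]


def compute_identity(consensus: str, truth: str, region: tuple[int, int] | None = None,
                     cols: list[tuple[str, int, int]] | None = None) -> float:
    """Percent identity of consensus vs truth over global alignment columns.

    Mismatch, insertion and deletion columns each count one column against
    identity; end gaps on the consensus side are free.  ``region`` restricts
    the tally to columns at truth coordinates in [start, end).
    """
    if region is not None:
        if region[0] < 0 or region[1] > len(truth) or region[0] >= region[1]:
            raise ValueError(f"region {region} outside truth")
    if cols is None:
        cols = align_to_truth(consensus, truth)
    cols = _trim_end_gaps(cols)
    if region is not None:
        cols = [c for c in cols if region[0] <= c[2] < region[1]]
    total = len(cols)
    if total == 0:
        raise ValueError("no alignment columns in region")
    match = sum(1 for c in cols if c[0] == "=")
    return 100.0 * match / total


@dataclass
class DifferenceRecord:
    ref_pos: int            # truth coordinate
    ref_base: str           # '' for insertions
    obs: str                # consensus base, or '' for deletions
    unit_index: object      # int copy index, or 'flank5'/'flank3'
    unit_offset: int | None
    context: str            # truth 5-mer around the position
    diff_class: str         # transition / transversion / insertion / deletion


def _diff_class(ref: str, obs: str) -> str:
    pair = {ref, obs}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def classify_differences(consensus: str, truth, locus=None,
                         cols: list[tuple[str, int, int]] | None = None
                         ) -> list[DifferenceRecord]:
    """One record per non-match alignment column, annotated with the unit
    copy index and unit offset from the locus truth annotation."""
    truth_seq = truth if isinstance(truth, str) else truth.sequence
    if cols is None:
        cols = align_to_truth(consensus, truth_seq)
    cols = _trim_end_gaps(cols)
    records: list[DifferenceRecord] = []
    for op, ci, ti in cols:
        if op == "=":
            continue
        if locus is not None:
            unit_index, unit_offset = locus.label_position(ti)
        else:
            unit_index, unit_offset = None, None
        context = truth_seq[max(0, ti - 2):ti + 3]
        if op == "X":
            records.append(DifferenceRecord(ti, truth_seq[ti], consensus[ci],
                                            unit_index, unit_offset, context,
                                            _diff_class(truth_seq[ti], consensus[ci])))
        elif op == "I":
            records.append(DifferenceRecord(ti, "", consensus[ci],
                                            unit_index, unit_offset, context,
                                            "insertion"))
        else:
            records.append(DifferenceRecord(ti, truth_seq[ti], "",
                                            unit_index, unit_offset, context,
                                            "deletion"))
    return records


@dataclass
class RecurrentGroup:
    unit_offset: int
    ref_base: str
    obs_base: str
    unit_count: int
    positions: tuple[int, ...]


def find_recurrent(records: list[DifferenceRecord], unit_len: int,
                   min_units: int = 3) -> list[RecurrentGroup]:
    """Group substitutions by (unit offset, base change); a group is
    recurrent when it appears in >= min_units distinct unit copies.
    Flank records are excluded (no meaningful unit offset)."""
    groups: dict[tuple[int, str, str], dict[object, int]] = {}
    for r in records:
        if r.diff_class not in ("transition", "transversion"):
            continue
        if not isinstance(r.unit_index, int) or r.unit_offset is None:
            continue
        key = (r.unit_offset, r.ref_base, r.obs)
        groups.setdefault(key, {})[r.unit_index] = r.ref_pos
    out = []
    for (off, ref, obs), units in sorted(groups.items()):
        if len(units) >= min_units:
            out.append(RecurrentGroup(off, ref, obs, len(units),
                                      tuple(sorted(units.values()))))
    return out


def _iupac_match(seq: str, motif: str) -> bool:
    return len(seq) == len(motif) and all(c in IUPAC[m] for c, m in zip(seq, motif))


def motif_stats(recurrent_groups: list[RecurrentGroup], truth: str,
                motif: str = "CCNGG", x_index: int = 2):
    """Count recurrent groups whose truth context matches ``motif`` with the
    error at position ``x_index``.  Returns (n_in_motif, n_recurrent,
    fraction or None)."""
    if not 0 <= x_index < len(motif):
        raise ValueError("x_index outside motif")
    n_in = 0
    for g in recurrent_groups:
        pos = g.positions[0]
        start = pos - x_index
        ctx = truth[max(0, start):start + len(motif)]
        if start >= 0 and _iupac_match(ctx, motif):
            n_in += 1
    n_rec = len(recurrent_groups)
    return n_in, n_rec, (n_in / n_rec if n_rec else None)


@dataclass
class ErrorProfile:
    n_diffs: int
    ref_len: int
    error_rate_pct: float
    n_subs: int
    n_transitions: int
    transition_pct: float | None
    recurrent_groups: list[RecurrentGroup]
    n_recurrent: int
    n_recurrent_in_motif: int
    motif: str

    def report(self) -> str:
        tp = "NA" if self.transition_pct is None else f"{self.transition_pct:.1f}"
        mf = ("NA" if self.n_recurrent == 0
              else f"{self.n_recurrent_in_motif / self.n_recurrent:.3f}")
        return (
            f"differences\t{self.n_diffs}\n"
            f"reference_length\t{self.ref_len}\n"
            f"error_rate_pct\t{self.error_rate_pct:.2f}\n"
            f"substitutions\t{self.n_subs}\n"
            f"transitions\t{self.n_transitions}\n"
            f"transition_pct\t{tp}\n"
            f"recurrent_groups\t{self.n_recurrent}\n"
            f"recurrent_in_{self.motif}\t{self.n_recurrent_in_motif}\n"
            f"recurrent_motif_fraction\t{mf}\n")


def error_summary(records: list[DifferenceRecord], ref_len: int,
                  unit_len: int | None = None, min_units: int = 3,
                  truth: str | None = None, motif: str = "CCNGG",
                  x_index: int = 2) -> ErrorProfile:
    """Aggregate difference records into the headline error taxonomy."""
    if ref_len <= 0:
        raise ValueError("ref_len must be > 0")
    n_subs = sum(1 for r in records
                 if r.diff_class in ("transition", "transversion"))
    n_ts = sum(1 for r in records if r.diff_class == "transition")
    groups: list[RecurrentGroup] = []
    n_in = 0
    if unit_len is not None:
        groups = find_recurrent(records, unit_len, min_units)
        if truth is not None and groups:
            n_in, _, _ = motif_stats(groups, truth, motif, x_index)
    return ErrorProfile(
        n_diffs=len(records),
        ref_len=ref_len,
        error_rate_pct=100.0 * len(records) / ref_len,
        n_subs=n_subs,
        n_transitions=n_ts,
        transition_pct=(100.0 * n_ts / n_subs) if n_subs else None,
        recurrent_groups=groups,
        n_recurrent=len(groups),
        n_recurrent_in_motif=n_in,
        motif=motif)
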