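"""Synthetic macrosatellite repeat loci and nanopore-like read simulation.

A locus has the layout  5'-flank + N tandem copies of a repeat unit + 3'-flank,
emulating the D4Z4 macrosatellite array at 4q35 (and its 10q26 homolog).  The
built-in presets mirror the geometry of the published reference material: a
BAC-clone analog with 13 copies of a 3,306-bp unit between a 4,823-bp
centromeric and an 865-bp telomeric flank, and chr4/chr10 whole-genome analogs
with 17 and 20 copies.  Sequence content is synthetic (i.i.d. uniform bases
with rejection sampling for dissimilarity constraints); coordinates, copy
numbers and flank classes are exact ground truth, which is what downstream
recovery tests need.

Reads are simulated with a substitution-dominant nanopore-like error model:
configurable per-base substitution/insertion/deletion rates, a transition bias
(purine<->purine / pyrimidine<->pyrimidine substitutions), and optional error
hotspots at CCNGG motif centers.  Every planted error is recorded in an edit
ledger so that tests can replay it byte-for-byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
# transition partner: A<->G, C<->T
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
POLYA_MOTIF = "ATTAAA"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


@dataclass(frozen=True)
class Interval:
    start: int
    end: int  # 0-based, half-open

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HaplotypePreset:
    """Geometry + class of one synthetic locus.

    ``haplotype_class`` follows the 4qA/4qAL/4qB nomenclature: only A-type
    telomeric flanks carry the polyadenylation-signal analog (ATTAAA).
    ``flank_family`` selects chr4-analog or chr10-analog flank content.
    """

    name: str
    flank5_len: int = 4823
    flank3_len: int = 865
    unit_len: int = 3306
    copy_number: int = 13
    haplotype_class: str = "A"
    polya_motif_present: bool = True
    seed: int = 0
    flank_family: str = "chr4"

    def __post_init__(self) -> None:
        if min(self.flank5_len, self.flank3_len, self.unit_len) <= 0:
            raise ValueError("all lengths must be > 0")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.haplotype_class not in ("A", "AL", "B"):
            raise ValueError(f"unknown haplotype class {self.haplotype_class!r}")
        if self.haplotype_class == "B" and self.polya_motif_present:
            raise ValueError("class B flanks never carry the polyA motif")
        if self.flank_family not in ("chr4", "chr10"):
            raise ValueError(f"unknown flank family {self.flank_family!r}")


def preset(name: str, seed: int = 0) -> HaplotypePreset:
    """Built-in presets: BAC13 (4qA BAC analog), CHR4_17, CHR10_20."""
    builders = {
        "BAC13": dict(copy_number=13, haplotype_class="A",
                      polya_motif_present=True, flank_family="chr4"),
        "CHR4_17": dict(copy_number=17, haplotype_class="B",
                        polya_motif_present=False, flank_family="chr4"),
        "CHR10_20": dict(copy_number=20, haplotype_class="B",
                         polya_motif_present=False, flank_family="chr10"),
    }
    if name not in builders:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(builders)}")
    return HaplotypePreset(name=name, seed=seed, **builders[name])


@dataclass(frozen=True)
class LocusSequence:
    sequence: str
    flank5_iv: Interval
    flank3_iv: Interval
    unit_ivs: tuple[Interval, ...]
    motif_positions: tuple[int, ...]
    preset: HaplotypePreset
    unit_seq: str = ""
    flank3_variants: dict = field(default_factory=dict, compare=False)

    @property
    def array_iv(self) -> Interval:
        return Interval(self.flank5_iv.end, self.flank3_iv.start)

    def label_position(self, pos: int) -> tuple[object, int | None]:
        """Map a locus coordinate to (unit_index | 'flank5' | 'flank3', unit_offset)."""
        if pos < self.flank5_iv.end:
            return "flank5", None
        if pos >= self.flank3_iv.start:
            return "flank3", None
        off = pos - self.flank5_iv.end
        u = self.preset.unit_len
        return off // u, off % u


Edit = tuple[int, str, str, str]  # (locus_pos, type in {sub,ins,del}, ref, alt)


@dataclass(frozen=True)
class ErrorSpec:
    p_sub: float = 0.10
    ts_fraction: float = 0.70
    p_ins: float = 0.01
    p_del: float = 0.01
    hotspot_motif: str = "CCNGG"
    hotspot_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_sub + self.p_ins + self.p_del >= 1.0:
            raise ValueError("p_sub + p_ins + p_del must be < 1")
        if not 0.0 <= self.ts_fraction <= 1.0:
            raise ValueError("ts_fraction must lie in [0, 1]")
        if self.hotspot_multiplier < 1.0:
            raise ValueError("hotspot_multiplier must be >= 1")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    true_start: int
    true_end: int
    strand: str  # '+' or '-'
    edits: tuple[Edit, ...]


# ---------------------------------------------------------------------------
# locus construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = BASES[(_BASE_TO_CODE[out[i]] + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _global_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def _infix_identity(needle: str, hay: str) -> float:
    res = edlib.align(needle, hay, mode="HW", task="distance")
    return 1.0 - res["editDistance"] / len(needle)


def _scrub_motif(rng: np.random.Generator, seq: str, motif: str = POLYA_MOTIF) -> str:
    out = seq
    for _ in range(50):
        i = out.find(motif)
        if i < 0:
            return out
        out = out[:i] + _random_seq(rng, len(motif)) + out[i + len(motif):]
    raise GenerationError("could not scrub motif")


def _plant_motif(seq: str, motif: str, offset: int) -> str:
    offset = min(offset, len(seq) - len(motif))
    return seq[:offset] + motif + seq[offset + len(motif):]


def find_motif_centers(sequence: str, motif: str = "CCNGG", x_index: int = 2) -> tuple[int, ...]:
    """Positions whose surrounding context matches an IUPAC motif at x_index."""
    pattern = "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in motif)
    return tuple(m.start() + x_index
                 for m in re.finditer(f"(?={pattern})", sequence))


def _build_family(seed: int, flank5_len: int, flank3_len: int, unit_len: int,
                  max_attempts: int = 25) -> dict:
    """Generate the shared component sequences of one locus family.

    A single family seed yields a repeat unit shared by the chr4 and chr10
    analogs, chr4 flanks, three telomeric-flank haplotype variants (A, AL, B),
    and chr10 homolog flanks whose repeat-proximal ends stay >=95% identical
    to the chr4 versions while the distal parts are independent.
    """
    rng = np.random.default_rng([seed, 0xD4A4])
    for _ in range(max_attempts):
        unit = _random_seq(rng, unit_len)
        flank5 = _random_seq(rng, flank5_len)
        # flank/unit must be mutually dissimilar so anchors are unambiguous
        probe = min(unit_len, flank5_len)
        if _infix_identity(unit[:probe], flank5) > 0.75:
            continue
        f3_a = _plant_motif(_random_seq(rng, flank3_len), POLYA_MOTIF,
                            int(flank3_len * 0.7))
        f3_al = _plant_motif(_random_seq(rng, flank3_len), POLYA_MOTIF,
                             int(flank3_len * 0.5))
        f3_b = _scrub_motif(rng, _random_seq(rng, flank3_len))
        variants = {"A": f3_a, "AL": f3_al, "B": f3_b}
        ids = [_global_identity(variants[x], variants[y])
               for x, y in (("A", "AL"), ("A", "B"), ("AL", "B"))]
        if max(ids) > 0.70:
            continue
        # chr10 homologs: proximal stretch near-identical, distal independent
        prox5 = min(1000, flank5_len)
        flank5_chr10 = (_random_seq(rng, flank5_len - prox5)
                        + _mutate(rng, flank5[-prox5:], 0.03))
        prox3 = min(150, flank3_len)
        f3_b10 = _scrub_motif(
            rng, _mutate(rng, f3_b[:prox3], 0.03) + _random_seq(rng, flank3_len - prox3))
        return {
            "unit": unit,
            "chr4": {"flank5": flank5, "flank3": variants},
            "chr10": {"flank5": flank5_chr10,
                      "flank3": {"A": f3_a, "AL": f3_al, "B": f3_b10}},
        }
    raise GenerationError("rejection sampling failed to satisfy dissimilarity")


def build_locus(p: HaplotypePreset) -> LocusSequence:
    """Deterministically construct the ground-truth locus for a preset."""
    fam = _build_family(p.seed, p.flank5_len, p.flank3_len, p.unit_len)
    flank5 = fam[p.flank_family]["flank5"]
    flank3 = fam[p.flank_family]["flank3"][p.haplotype_class]
    unit = fam["unit"]
    seq = flank5 + unit * p.copy_number + flank3
    unit_ivs = tuple(
        Interval(p.flank5_len + i * p.unit_len, p.flank5_len + (i + 1) * p.unit_len)
        for i in range(p.copy_number))
    return LocusSequence(
        sequence=seq,
        flank5_iv=Interval(0, p.flank5_len),
        flank3_iv=Interval(len(seq) - p.flank3_len, len(seq)),
        unit_ivs=unit_ivs,
        motif_positions=find_motif_centers(seq),
        preset=p,
        unit_seq=unit,
        flank3_variants=dict(fam[p.flank_family]["flank3"]),
    )


# ---------------------------------------------------------------------------
# in-silico restriction digestion


def digest(sequence: str, site: str = "GAATTC", cut_offset: int = 1) -> list[str]:
    """Cut at every exact occurrence of ``site`` (forward strand).

    The default is EcoRI's G^AATTC.  The cut falls between site[cut_offset-1]
    and site[cut_offset].  The concatenation of the returned fragments equals
    the input.
    """
    if not site:
        raise ValueError("site must be non-empty")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset out of range")
    if not sequence:
        return []
    cuts = [m.start() + cut_offset for m in re.finditer(f"(?={site})", sequence)]
    bounds = [0] + cuts + [len(sequence)]
    return [sequence[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]


# ---------------------------------------------------------------------------
# read simulation


def _hotspot_rates(locus: LocusSequence, spec: ErrorSpec) -> np.ndarray:
    rates = np.full(len(locus.sequence), spec.p_sub)
    if spec.hotspot_multiplier > 1.0:
        centers = find_motif_centers(locus.sequence, spec.hotspot_motif)
        cap = 1.0 - spec.p_ins - spec.p_del
        rates[list(centers)] = min(spec.p_sub * spec.hotspot_multiplier, cap)
    return rates


def _simulate_one(rng: np.random.Generator, locus: LocusSequence,
                  spec: ErrorSpec, sub_rates: np.ndarray,
                  read_id: str, start: int, end: int, strand: str) -> SimulatedRead:
    seq = locus.sequence
    u = rng.random(end - start)
    out: list[str] = []
    edits: list[Edit] = []
    for k in range(end - start):
        pos = start + k
        ref = seq[pos]
        ps = sub_rates[pos]
        x = u[k]
        if x < ps:
            if rng.random() < spec.ts_fraction:
                alt = _TRANSITION[ref]
            else:
                alt = _TRANSVERSIONS[ref][int(rng.integers(0, 2))]
            out.append(alt)
            edits.append((pos, "sub", ref, alt))
        elif x < ps + spec.p_del:
            edits.append((pos, "del", ref, ""))
        else:
            out.append(ref)
        if rng.random() < spec.p_ins:
            ins = BASES[int(rng.integers(0, 4))]
            out.append(ins)
            edits.append((pos, "ins", "", ins))
    read_seq = "".join(out)
    if strand == "-":
        read_seq = revcomp(read_seq)
    return SimulatedRead(read_id=read_id, sequence=read_seq,
                         true_start=start, true_end=end, strand=strand,
                         edits=tuple(edits))


def replay_edits(locus: LocusSequence, read: SimulatedRead) -> str:
    """Reconstruct the read sequence from its edit ledger (ground-truth check)."""
    seq = locus.sequence
    out: list[str] = []
    by_pos: dict[int, list[Edit]] = {}
    for e in read.edits:
        by_pos.setdefault(e[0], []).append(e)
    for pos in range(read.true_start, read.true_end):
        here = by_pos.get(pos, [])
        subs = [e for e in here if e[1] == "sub"]
        dels = [e for e in here if e[1] == "del"]
        inss = [e for e in here if e[1] == "ins"]
        if subs:
            out.append(subs[0][3])
        elif not dels:
            out.append(seq[pos])
        for e in inss:
            out.append(e[3])
    s = "".join(out)
    return revcomp(s) if read.strand == "-" else s


def simulate_reads(locus: LocusSequence, spec: ErrorSpec, mode: str = "full_fragment",
                   coverage: float | None = None, n_reads: int | None = None,
                   length_median: float = 8000.0, length_sigma: float = 0.45,
                   min_read_len: int = 300) -> list[SimulatedRead]:
    """Simulate nanopore-like reads with a fully recorded error ledger.

    ``full_fragment`` emits ``n_reads`` (default 1) reads spanning the whole
    locus on the + strand.  ``coverage`` draws uniform start positions and
    lognormal lengths (median ~8 kb, matching typical MinION 1D runs) on
    random strands until the requested fold coverage is reached.
    """
    if mode not in ("full_fragment", "coverage"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(spec.seed)
    sub_rates = _hotspot_rates(locus, spec)
    L = len(locus.sequence)
    reads: list[SimulatedRead] = []
    if mode == "full_fragment":
        n = n_reads or 1
        if n <= 0:
            raise ValueError("n_reads must be > 0")
        for i in range(n):
            reads.append(_simulate_one(rng, locus, spec, sub_rates,
                                       f"ff{i:04d}", 0, L, "+"))
        return reads
    if not coverage or coverage <= 0:
        raise ValueError("coverage mode requires coverage > 0")
    total = 0
    i = 0
    target = coverage * L
    while total < target:
        length = int(np.exp(np.log(length_median) + length_sigma * rng.standard_normal()))
        length = max(min_read_len, length)
        # fragments overhanging either end are truncated at the locus
        # boundary, so edge columns get the same expected depth as the middle
        start = int(rng.integers(-length + min_read_len, L - min_read_len + 1))
        end = min(L, start + length)
        start = max(0, start)
        if end - start < min_read_len:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(_simulate_one(rng, locus, spec, sub_rates,
                                   f"cov{i:05d}", start, end, strand))
        total += end - start
        i += 1
    return reads


def scale_preset(p: HaplotypePreset, factor: float) -> HaplotypePreset:
    """Geometry-scaled copy of a preset (same copy number and class)."""
    return replace(p,
                   name=f"{p.name}_x{factor:g}",
                   flank5_len=max(60, int(p.flank5_len * factor)),
                   flank3_len=max(40, int(p.flank3_len * factor)),
                   unit_len=max(30, int(p.unit_len * factor)))
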