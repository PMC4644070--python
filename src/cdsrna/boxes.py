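"""C/D box motif detection, k-turn screening and guide extraction.

An archaeal C/D box sRNA carries four conserved elements laid out
5'-[C box]-[D' guide]-[D' box]-[C' box]-[D guide]-[D box]-3'.  The C/C'
consensus is RUGAUGA (R = A or G) and the D/D' consensus is CUGA.  The
guide regions sit immediately 5' of their D or D' box and, by the
convention used throughout this package, include the first nucleotide of
that box as their 3'-terminal residue (that position can participate in
the guide-target duplex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .seqio import RnaSequence

logger = logging.getLogger(__name__)

C_CONSENSUS = "RUGAUGA"
D_CONSENSUS = "CUGA"

#: IUPAC degeneracy actually used by the box consensi.
_IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("U"), "R": frozenset("AG"), "Y": frozenset("CU"),
    "N": frozenset("ACGU"),
}


class BoxKind(str, Enum):
    C = "C"
    DPRIME = "Dprime"
    CPRIME = "Cprime"
    D = "D"


def consensus_for(kind: BoxKind) -> str:
    return C_CONSENSUS if kind in (BoxKind.C, BoxKind.CPRIME) else D_CONSENSUS


class GuideKind(str, Enum):
    D_GUIDE = "D_guide"
    DPRIME_GUIDE = "Dprime_guide"


@dataclass(frozen=True)
class BoxMotif:
    """One box occurrence: 1-based inclusive span plus consensus distance."""

    kind: BoxKind
    start: int
    end: int
    sequence: str
    mismatches: int


@dataclass(frozen=True)
class GuideRegion:
    """A guide: the span between two boxes, ending on the downstream box's
    first nucleotide.

    ``plus5_offset`` is the 1-based index, from the guide 5' end, of the
    nucleotide five positions upstream of the downstream box start; the
    rRNA nucleotide paired with it is the one that gets 2'-O-methylated.
    """

    srna_id: str
    kind: GuideKind
    start: int
    end: int
    sequence: str

    @property
    def plus5_offset(self) -> int:
        return len(self.sequence) - 5

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Rejection:
    """A sequence (or guide) the annotator could not accept, with reason."""

    seq_id: str
    reason: str


@dataclass
class SmallRNA:
    """A fully annotated C/D box sRNA."""

    seq: RnaSequence
    boxes: dict[BoxKind, BoxMotif]
    kturn_ok: dict[str, bool] = field(default_factory=dict)
    d_guide: GuideRegion | None = None
    dprime_guide: GuideRegion | None = None
    guide_rejections: list[Rejection] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.seq.id

    @property
    def total_box_mismatches(self) -> int:
        return sum(b.mismatches for b in self.boxes.values())

    def guides(self) -> list[GuideRegion]:
        return [g for g in (self.d_guide, self.dprime_guide) if g is not None]


@dataclass(frozen=True)
class BoxParams:
    """Box search tolerances and guide length bounds.

    The D box is the best conserved element, hence the asymmetric default
    mismatch budget (0 for D, 1 elsewhere).  Guide lengths of 10-12 nt are
    typical; 6-20 is accepted, with 6 the hard floor imposed by the +5 rule.
    """

    max_mm_c: int = 1
    max_mm_dprime: int = 1
    max_mm_cprime: int = 1
    max_mm_d: int = 0
    guide_min: int = 6
    guide_max: int = 20
    max_srna_len: int = 100

    def max_mm(self, kind: BoxKind) -> int:
        return {
            BoxKind.C: self.max_mm_c,
            BoxKind.DPRIME: self.max_mm_dprime,
            BoxKind.CPRIME: self.max_mm_cprime,
            BoxKind.D: self.max_mm_d,
        }[kind]


def match_consensus(window: str, consensus: str) -> int:
    """Number of positions of *window* outside the IUPAC consensus sets."""
    if len(window) != len(consensus):
        raise ValueError(
            f"window length {len(window)} != consensus length {len(consensus)}"
        )
    return sum(1 for w, c in zip(window, consensus) if w not in _IUPAC[c])


def find_box_motifs(seq: RnaSequence | str, kind: BoxKind, max_mm: int) -> list[BoxMotif]:
    """All windows within *max_mm* of the kind's consensus, sorted by
    (mismatches, start)."""
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    consensus = consensus_for(kind)
    k = len(consensus)
    hits = []
    for i in range(len(residues) - k + 1):
        window = residues[i : i + k]
        mm = match_consensus(window, consensus)
        if mm <= max_mm:
            hits.append(BoxMotif(kind, i + 1, i + k, window, mm))
    hits.sort(key=lambda b: (b.mismatches, b.start))
    return hits


#: Sequence-level k-turn register: when a C box (RUGAUGA) juxtaposes a D box
#: (CUGA) the non-canonical stem is read as the tandem sheared pairs
#: C3(G)·D4(A) and C4(A)·D3(G), flanked by the non-canonical U·U pair
#: C5(U)·D2(U).  Each entry: (C-box position, residue, D-box position, residue).
_KTURN_REGISTER: tuple[tuple[int, str, int, str], ...] = (
    (3, "G", 4, "A"),
    (4, "A", 3, "G"),
    (5, "U", 2, "U"),
)


def check_kturn(cbox: BoxMotif, dbox: BoxMotif) -> bool:
    """Do the juxtaposed box sequences present the sheared-pair residues?

    A sequence-level proxy for k-turn formation: requires the G·A / A·G
    sheared pairs (and the adjacent U·U pair) implied by the consensus
    register.  Purely advisory — the annotator records but does not reject.
    """
    if cbox.kind not in (BoxKind.C, BoxKind.CPRIME):
        raise ValueError(f"expected a C/C' box, got {cbox.kind}")
    if dbox.kind not in (BoxKind.D, BoxKind.DPRIME):
        raise ValueError(f"expected a D/D' box, got {dbox.kind}")
    for cpos, cres, dpos, dres in _KTURN_REGISTER:
        if cbox.sequence[cpos - 1] != cres or dbox.sequence[dpos - 1] != dres:
            return False
    return True


def extract_guides(srna: SmallRNA, params: BoxParams = BoxParams()) -> SmallRNA:
    """Fill in the two guide regions from the annotated boxes.

    The D' guide spans (C box end + 1)..(D' box start); the D guide spans
    (C' box end + 1)..(D box start); both inclusive of the downstream box's
    first nucleotide.  A guide shorter than 6 nt cannot host the +5
    position and is rejected individually.
    """
    seq = srna.seq.residues
    specs = [
        (GuideKind.DPRIME_GUIDE, srna.boxes[BoxKind.C], srna.boxes[BoxKind.DPRIME]),
        (GuideKind.D_GUIDE, srna.boxes[BoxKind.CPRIME], srna.boxes[BoxKind.D]),
    ]
    for kind, upstream, downstream in specs:
        start, end = upstream.end + 1, downstream.start
        length = end - start + 1
        if length < max(6, params.guide_min):
            srna.guide_rejections.append(
                Rejection(srna.id, f"{kind.value} length {length} < 6")
            )
            continue
        if not 9 <= length <= 13:
            logger.warning(
                "%s %s length %d outside the typical 10-12 nt range",
                srna.id, kind.value, length,
            )
        guide = GuideRegion(
            srna_id=srna.id, kind=kind, start=start, end=end,
            sequence=seq[start - 1 : end],
        )
        if kind is GuideKind.D_GUIDE:
            srna.d_guide = guide
        else:
            srna.dprime_guide = guide
    return srna


def annotate_cd_srna(
    seq: RnaSequence, params: BoxParams = BoxParams()
) -> SmallRNA | Rejection:
    """Best consistent C / D' / C' / D arrangement, or a rejection.

    Exhaustive search over candidate box quadruples (sequences are short,
    so this is at most a few tens of thousands of combinations).  Score is
    total box mismatches; ties prefer guide lengths closest to 11 nt, then
    the leftmost arrangement.  Rejections carry a reason and are values,
    not exceptions.
    """
    if len(seq) > params.max_srna_len:
        return Rejection(seq.id, f"sequence longer than {params.max_srna_len} nt")
    candidates = {
        kind: find_box_motifs(seq, kind, params.max_mm(kind)) for kind in BoxKind
    }
    for kind in (BoxKind.D, BoxKind.C, BoxKind.DPRIME, BoxKind.CPRIME):
        if not candidates[kind]:
            return Rejection(seq.id, f"no {kind.value} box within mismatch budget")

    lo, hi = max(6, params.guide_min), params.guide_max
    best: tuple | None = None
    for c in candidates[BoxKind.C]:
        for dp in candidates[BoxKind.DPRIME]:
            g1 = dp.start - c.end  # D' guide length, box first nt included
            if not lo <= g1 <= hi:
                continue
            for cp in candidates[BoxKind.CPRIME]:
                if cp.start <= dp.end:
                    continue
                for d in candidates[BoxKind.D]:
                    g2 = d.start - cp.end
                    if not lo <= g2 <= hi:
                        continue
                    score = c.mismatches + dp.mismatches + cp.mismatches + d.mismatches
                    key = (
                        score,
                        abs(g1 - 11) + abs(g2 - 11),
                        c.start, dp.start, cp.start, d.start,
                    )
                    if best is None or key < best[0]:
                        best = (key, c, dp, cp, d)
    if best is None:
        return Rejection(
            seq.id, "no consistent C/D'/C'/D arrangement with admissible guides"
        )
    _, c, dp, cp, d = best
    srna = SmallRNA(
        seq=seq,
        boxes={BoxKind.C: c, BoxKind.DPRIME: dp, BoxKind.CPRIME: cp, BoxKind.D: d},
        kturn_ok={
            "C/D": check_kturn(c, d),
            "Cprime/Dprime": check_kturn(cp, dp),
        },
    )
    return extract_guides(srna, params)
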