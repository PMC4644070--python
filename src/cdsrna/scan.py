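"""Guide-target duplex scanning and 2'-O-methylation site prediction.

A guide pairs antiparallel and bulge-free with an rRNA window of equal
length: guide position i (1-based, 5'->3') pairs with window position
L - i + 1.  The methylated nucleotide is the one paired with the guide
nucleotide five positions upstream of the D/D' box start (the "N plus
five" rule); with the box's first nucleotide included as the guide's
3'-terminal residue this is always guide position L - 5, i.e. window
position 6, i.e. rRNA position target_start + 5.

Significance (strict mode) requires a run of consecutive Watson-Crick
pairs of length >= 9 covering the +5 pairing column, with at most one
mismatch and two G:U pairs in the whole duplex.  The +5 column itself is
allowed to interrupt the run: the duplex is presumed to form around a
central mismatch or wobble, but methylation happens only when the +5 pair
is canonical Watson-Crick — a mismatch there makes the interaction
significant-but-non-productive, a G:U there is additionally flagged
uncertain.  Relaxed mode (used only to rescue the partner guide of an
already-anchored double-guide sRNA) lets G:U pairs extend the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .boxes import GuideKind, GuideRegion, SmallRNA
from .seqio import Molecule, RnaSequence

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_MM, _GU, _WC = 0, 1, 2

_PAIR_TABLE = np.zeros((4, 4), dtype=np.int8)
for _a, _b in ((0, 3), (1, 2)):  # A:U, C:G
    _PAIR_TABLE[_a, _b] = _PAIR_TABLE[_b, _a] = _WC
_PAIR_TABLE[2, 3] = _PAIR_TABLE[3, 2] = _GU  # G:U wobble


class BasePairClass(str, Enum):
    WC = "WC"
    GU = "GU"
    MM = "MM"


_CLASS_OF_INT = {_WC: BasePairClass.WC, _GU: BasePairClass.GU, _MM: BasePairClass.MM}


class ScanMode(str, Enum):
    STRICT = "strict"
    RELAXED = "relaxed"


@dataclass(frozen=True)
class ScanRules:
    """Duplex acceptance rules.

    ``min_consecutive_wc`` must be >= 6 so the run can reach the +5 column
    from either duplex end.  Bulges are never allowed (the scan is a fixed
    equal-length register).
    """

    min_consecutive_wc: int = 9
    max_mismatch: int = 1
    max_gu: int = 2
    relaxed_mode: bool = False
    relaxed_run_counts_gu: bool = True
    relaxed_max_mismatch: int = 1
    allow_bulges: bool = False

    def __post_init__(self) -> None:
        if self.min_consecutive_wc < 6:
            raise ValueError("min_consecutive_wc must be >= 6 to cover the +5 site")
        if self.allow_bulges:
            raise ValueError("bulged duplexes are not supported")

    def tighter_than(self, other: "ScanRules") -> bool:
        """True if every knob of self is at least as restrictive as other's."""
        return (
            self.min_consecutive_wc >= other.min_consecutive_wc
            and self.max_mismatch <= other.max_mismatch
            and self.max_gu <= other.max_gu
        )


def classify_pair(a: str, b: str) -> BasePairClass:
    """Watson-Crick / wobble / mismatch class of an (unordered) residue pair."""
    try:
        return _CLASS_OF_INT[int(_PAIR_TABLE[_CODE[a], _CODE[b]])]
    except KeyError as exc:
        raise ValueError(f"residues must be in A/C/G/U, got {a!r}, {b!r}") from exc


def encode(residues: str) -> np.ndarray:
    return np.frombuffer(
        residues.encode().translate(bytes.maketrans(b"ACGU", bytes(range(4)))),
        dtype=np.uint8,
    )


@dataclass
class DuplexAlignment:
    """One bulge-free antiparallel guide-rRNA pairing at a fixed register."""

    guide: GuideRegion
    target_id: str
    target_molecule: Molecule
    target_start: int          # 1-based inclusive rRNA window
    target_end: int
    pair_classes: tuple[BasePairClass, ...]  # per guide position, 5'->3'
    n_gu: int
    n_mm: int
    site: int                  # rRNA position paired with the +5 guide nucleotide
    site_class: BasePairClass
    wc_run: int | None = None  # run covering the +5 column (mode-dependent)
    significant: bool | None = None
    mode: ScanMode | None = None
    productive: bool | None = None
    flags: list[str] = field(default_factory=list)


def pair_guide_window(
    guide: GuideRegion,
    window: str,
    target_start: int = 1,
    target_molecule: Molecule = Molecule.OTHER,
    target_id: str = "window",
) -> DuplexAlignment:
    """Pair a guide against an equal-length rRNA window (unscored).

    *window* is given 5'->3'; guide position i pairs with window position
    L - i + 1.
    """
    L = len(guide)
    if len(window) != L:
        raise ValueError(f"window length {len(window)} != guide length {L}")
    classes = tuple(
        classify_pair(guide.sequence[i], window[L - i - 1]) for i in range(L)
    )
    site_idx = guide.plus5_offset - 1
    return DuplexAlignment(
        guide=guide,
        target_id=target_id,
        target_molecule=target_molecule,
        target_start=target_start,
        target_end=target_start + L - 1,
        pair_classes=classes,
        n_gu=sum(c is BasePairClass.GU for c in classes),
        n_mm=sum(c is BasePairClass.MM for c in classes),
        site=target_start + (L - guide.plus5_offset),
        site_class=classes[site_idx],
    )


def _covering_run(classes: Sequence[BasePairClass], site_idx: int, count_gu: bool) -> int:
    """Length of the maximal pairing run through the +5 column.

    WC pairs (and G:U if *count_gu*) extend the run; the +5 column itself
    always bridges it regardless of class.
    """
    def ok(i: int) -> bool:
        if i == site_idx:
            return True
        c = classes[i]
        return c is BasePairClass.WC or (count_gu and c is BasePairClass.GU)

    left = site_idx
    while left > 0 and ok(left - 1):
        left -= 1
    right = site_idx
    while right < len(classes) - 1 and ok(right + 1):
        right += 1
    return right - left + 1


def call_significance(
    d: DuplexAlignment, rules: ScanRules, mode: ScanMode = ScanMode.STRICT
) -> bool:
    """Apply the consecutive-WC significance rule; records wc_run and mode."""
    site_idx = d.guide.plus5_offset - 1
    count_gu = mode is ScanMode.RELAXED and rules.relaxed_run_counts_gu
    d.wc_run = _covering_run(d.pair_classes, site_idx, count_gu)
    if mode is ScanMode.STRICT:
        sig = (
            d.wc_run >= rules.min_consecutive_wc
            and d.n_mm <= rules.max_mismatch
            and d.n_gu <= rules.max_gu
        )
    else:
        sig = (
            d.wc_run >= rules.min_consecutive_wc
            and d.n_mm <= rules.relaxed_max_mismatch
        )
    d.significant = sig
    d.mode = mode
    return sig


def classify_productive(d: DuplexAlignment) -> bool:
    """Methylation only happens with a Watson-Crick pair at the +5 site.

    A significant duplex with a G:U at the site is non-productive but
    flagged ``uncertain_site_GU`` (the wobble may still permit duplex
    formation; such calls were excluded as not robust).
    """
    if d.significant is None:
        raise ValueError("call_significance must run before classify_productive")
    d.productive = bool(d.significant) and d.site_class is BasePairClass.WC
    if d.significant and d.site_class is BasePairClass.GU:
        if "uncertain_site_GU" not in d.flags:
            d.flags.append("uncertain_site_GU")
    return d.productive


def _sort_key(d: DuplexAlignment) -> tuple:
    mol_rank = 0 if d.target_molecule is Molecule.RRNA_16S else 1
    return (-(d.wc_run or 0), d.n_mm + d.n_gu, mol_rank, d.target_start)


def scan_guide(
    guide: GuideRegion,
    rrna: RnaSequence,
    rules: ScanRules = ScanRules(),
    mode: ScanMode = ScanMode.STRICT,
) -> list[DuplexAlignment]:
    """Evaluate every register of *guide* along *rrna*.

    Returns the significance-passing duplexes sorted by decreasing run
    length, then fewest GU+mismatches, then 5'-most target window.  The
    inner loop is vectorized over all windows.
    """
    L = len(guide)
    n_win = len(rrna) - L + 1
    if n_win <= 0:
        return []
    g = encode(guide.sequence)
    r = encode(rrna.residues)
    # window w, guide position i pairs rRNA index w + (L - 1 - i)  (0-based)
    idx = np.arange(n_win)[:, None] + (L - 1 - np.arange(L))[None, :]
    cls = _PAIR_TABLE[g[None, :], r[idx]]  # (n_win, L), guide order
    site_idx = guide.plus5_offset - 1
    ok = cls == _WC
    if mode is ScanMode.RELAXED and rules.relaxed_run_counts_gu:
        ok |= cls == _GU
    ok[:, site_idx] = True  # the +5 column bridges the run
    left = np.cumprod(ok[:, site_idx::-1], axis=1).sum(axis=1)
    right = np.cumprod(ok[:, site_idx:], axis=1).sum(axis=1)
    run = left + right - 1
    n_mm = (cls == _MM).sum(axis=1)
    n_gu = (cls == _GU).sum(axis=1)
    if mode is ScanMode.STRICT:
        passing = (
            (run >= rules.min_consecutive_wc)
            & (n_mm <= rules.max_mismatch)
            & (n_gu <= rules.max_gu)
        )
    else:
        passing = (run >= rules.min_consecutive_wc) & (n_mm <= rules.relaxed_max_mismatch)
    hits: list[DuplexAlignment] = []
    for w in np.flatnonzero(passing):
        d = DuplexAlignment(
            guide=guide,
            target_id=rrna.id,
            target_molecule=rrna.molecule,
            target_start=int(w) + 1,
            target_end=int(w) + L,
            pair_classes=tuple(_CLASS_OF_INT[int(c)] for c in cls[w]),
            n_gu=int(n_gu[w]),
            n_mm=int(n_mm[w]),
            site=int(w) + 1 + (L - guide.plus5_offset),
            site_class=_CLASS_OF_INT[int(cls[w, site_idx])],
            wc_run=int(run[w]),
            significant=True,
            mode=mode,
        )
        classify_productive(d)
        hits.append(d)
    hits.sort(key=_sort_key)
    return hits


@dataclass
class MethylationPrediction:
    """A species-level predicted 2'-O-methylation site."""

    species: str
    srna_id: str
    guide_kind: GuideKind
    molecule: Molecule
    position: int
    productive: bool
    mode: ScanMode
    wc_run: int
    n_gu: int
    n_mm: int
    target_id: str
    alignment_column: int | None = None
    duplex: DuplexAlignment | None = field(default=None, compare=False, repr=False)

    @classmethod
    def from_duplex(cls, species: str, d: DuplexAlignment) -> "MethylationPrediction":
        return cls(
            species=species,
            srna_id=d.guide.srna_id,
            guide_kind=d.guide.kind,
            molecule=d.target_molecule,
            position=d.site,
            productive=bool(d.productive),
            mode=d.mode or ScanMode.STRICT,
            wc_run=int(d.wc_run or 0),
            n_gu=d.n_gu,
            n_mm=d.n_mm,
            target_id=d.target_id,
            duplex=d,
        )


#: Maximum separation (nt, inclusive, same molecule) between the two sites
#: of a double-guide sRNA for the relaxed rescue of the weaker guide.
DOUBLE_GUIDE_WINDOW = 100


@dataclass
class TargetPredictionResult:
    predictions: list[MethylationPrediction]
    srna_classes: dict[str, str]          # srna_id -> double_guide|single_guide|no_target
    summary: dict[str, int]
    extra_hits: list[MethylationPrediction] = field(default_factory=list)
    borderline: list[MethylationPrediction] = field(default_factory=list)


def predict_targets(
    srnas: Iterable[SmallRNA],
    rrnas: Mapping[Molecule, RnaSequence],
    rules: ScanRules = ScanRules(),
    species: str = "",
    multi_target: bool = False,
) -> TargetPredictionResult:
    """Two-pass per-species target prediction.

    Pass 1 scans every guide in strict mode against both rRNAs and keeps
    the best hit per guide.  Pass 2 rescans guides left empty, in relaxed
    mode, when their partner guide is anchored: a relaxed hit is kept only
    if its site falls within 100 nt of the partner's site on the same
    molecule (the simultaneous double-guide interaction is what justifies
    the weaker duplex).  With *multi_target*, all passing strict hits are
    additionally reported in ``extra_hits`` (dual-target guides).
    """
    srnas = list(srnas)
    targets = [rrnas[m] for m in (Molecule.RRNA_16S, Molecule.RRNA_23S) if m in rrnas]
    kept: dict[tuple[str, GuideKind], MethylationPrediction] = {}
    all_guides: list[GuideRegion] = []
    extra: list[MethylationPrediction] = []
    borderline: list[MethylationPrediction] = []

    for srna in srnas:
        for guide in srna.guides():
            all_guides.append(guide)
            hits: list[DuplexAlignment] = []
            for rrna in targets:
                hits.extend(scan_guide(guide, rrna, rules, ScanMode.STRICT))
            hits.sort(key=_sort_key)
            if hits:
                kept[(srna.id, guide.kind)] = MethylationPrediction.from_duplex(
                    species or srna.seq.species, hits[0]
                )
                if multi_target:
                    extra.extend(
                        MethylationPrediction.from_duplex(
                            species or srna.seq.species, h
                        )
                        for h in hits[1:]
                    )

    # pass 2: relaxed rescue of the empty partner of an anchored guide
    for srna in srnas:
        guides = srna.guides()
        if len(guides) != 2:
            continue
        for guide, partner in ((guides[0], guides[1]), (guides[1], guides[0])):
            if (srna.id, guide.kind) in kept or (srna.id, partner.kind) not in kept:
                continue
            anchor = kept[(srna.id, partner.kind)]
            rescued: list[DuplexAlignment] = []
            near_misses: list[DuplexAlignment] = []
            for rrna in targets:
                for d in scan_guide(guide, rrna, rules, ScanMode.RELAXED):
                    if (
                        d.target_molecule is anchor.molecule
                        and abs(d.site - anchor.position) <= DOUBLE_GUIDE_WINDOW
                    ):
                        rescued.append(d)
                    else:
                        near_misses.append(d)
            if rescued:
                rescued.sort(key=_sort_key)
                kept[(srna.id, guide.kind)] = MethylationPrediction.from_duplex(
                    species or srna.seq.species, rescued[0]
                )
            elif near_misses:
                near_misses.sort(key=_sort_key)
                borderline.append(
                    MethylationPrediction.from_duplex(
                        species or srna.seq.species, near_misses[0]
                    )
                )

    predictions = [kept[k] for k in sorted(kept, key=lambda k: (k[0], k[1].value))]
    classes: dict[str, str] = {}
    for srna in srnas:
        n = sum(1 for g in srna.guides() if (srna.id, g.kind) in kept)
        classes[srna.id] = {2: "double_guide", 1: "single_guide"}.get(n, "no_target")

    n_productive = sum(p.productive for p in predictions)
    summary = {
        "n_srnas": len(srnas),
        "n_guides": len(all_guides),
        "n_skipped_guides": sum(2 - len(s.guides()) for s in srnas),
        "n_significant": len(predictions),
        "n_productive": n_productive,
        "n_nonproductive": len(predictions) - n_productive,
        "n_empty_guides": len(all_guides) - len(predictions),
        "n_double_guide": sum(v == "double_guide" for v in classes.values()),
        "n_single_guide": sum(v == "single_guide" for v in classes.values()),
        "n_no_target": sum(v == "no_target" for v in classes.values()),
    }
    return TargetPredictionResult(
        predictions=predictions,
        srna_classes=classes,
        summary=summary,
        extra_hits=extra,
        borderline=borderline,
    )
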