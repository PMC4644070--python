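"""Synthetic sRNA / rRNA / alignment generator with planted ground truth.

The generator emulates the statistical structure of a multi-species
archaeal C/D box sRNA study: ancestor-derived rRNAs diverged by
substitutions and indels (with the true alignment emitted), sRNAs whose
guides are antiparallel complements of rRNA windows positioned so the
"N plus five" rule lands on a chosen site, decoys with shuffled guides,
controlled mismatch/wobble placement including mismatch-at-site
(non-productive) cases, and conserved target columns shared across
species.  Everything is reproducible byte-for-byte from the seed; the
emitted truth tables cover every sRNA so each pipeline stage can be
tested for exact recovery without any downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .boxes import (
    BoxKind, BoxParams, GuideKind, Rejection, annotate_cd_srna,
)
from .scan import ScanMode, ScanRules, scan_guide
from .seqio import (
    Molecule, RnaSequence, build_column_map, reverse_complement, write_fasta,
)

_ALPHABET = np.array(list("ACGU"))

C_BOX = "AUGAUGA"     # RUGAUGA realized with R = A
D_BOX = "CUGA"

#: sRNA truth classes.
CLASSES = ("clean", "decoy", "empty_guide", "site_mismatch", "site_gu", "relaxed_only")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters for one synthetic dataset.

    Default class fractions mirror the composition of the reference
    seven-species survey: roughly a third of sRNAs show no rRNA target,
    about one in eight works through a single guide, and a few percent of
    interactions carry a mismatch at the +5 site.  rRNA lengths and the
    10-12 nt guide range match typical archaeal molecules.
    """

    seed: int = 0
    n_species: int = 2
    rrna_16s_len: int = 1500
    rrna_23s_len: int = 3000
    gc_fraction: float = 0.5
    n_srnas_per_species: int = 30
    guide_len_range: tuple[int, int] = (10, 12)
    frac_decoy: float = 0.33
    frac_empty_guide: float = 0.13
    frac_site_mismatch: float = 0.03
    frac_site_gu: float = 0.01
    frac_relaxed_only: float = 0.0
    n_gu_in_duplex: int = 0
    frac_shared_sites: float = 0.15
    subst_rate: float = 0.05
    per_species_indel_rate: float = 0.005
    flank_len: int = 3

    def __post_init__(self) -> None:
        fracs = (
            self.frac_decoy, self.frac_empty_guide, self.frac_site_mismatch,
            self.frac_site_gu, self.frac_relaxed_only, self.frac_shared_sites,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(fracs[:5]) > 1.0:
            raise ValueError("class fractions sum to more than 1")
        lo, hi = self.guide_len_range
        if not (6 <= lo <= hi <= 20):
            raise ValueError("guide_len_range must lie within [6, 20]")
        if not 0 <= self.n_gu_in_duplex <= 2:
            raise ValueError("n_gu_in_duplex must be 0..2")


@dataclass
class SyntheticDataset:
    """Generated sequences, true alignment and ground-truth tables."""

    spec: SyntheticSpec
    species: list[str]
    rrnas: dict[str, dict[Molecule, RnaSequence]]
    srnas: dict[str, list[RnaSequence]]
    alignments: dict[Molecule, list[tuple[str, str]]]
    truth_srnas: pd.DataFrame     # one row per sRNA: class, box/guide layout
    truth_guides: pd.DataFrame    # one row per guide: intended + realized target

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in self.species:
            write_fasta(self.srnas[sp], outdir / f"{sp}_srnas.fasta")
            write_fasta(self.rrnas[sp].values(), outdir / f"{sp}_rrna.fasta")
            for mol, seq in self.rrnas[sp].items():
                write_fasta([seq], outdir / f"{sp}_{mol.value}.fasta")
        for mol, rows in self.alignments.items():
            with open(outdir / f"alignment_{mol.value}.fasta", "w") as fh:
                for rid, row in rows:
                    fh.write(f">{rid}\n{row}\n")
        self.truth_srnas.to_csv(outdir / "truth_srnas.tsv", sep="\t", index=False)
        self.truth_guides.to_csv(outdir / "truth_guides.tsv", sep="\t", index=False)


def generate_rrna(
    length: int, gc_fraction: float, seed: int | np.random.Generator
) -> str:
    """I.i.d. random RNA with the requested GC content, G/C and A/U split evenly."""
    if length < 100:
        raise ValueError("rRNA length must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_gc, p_au = gc_fraction / 2.0, (1.0 - gc_fraction) / 2.0
    return "".join(rng.choice(_ALPHABET, size=length, p=[p_au, p_gc, p_gc, p_au]))


def dinucleotide_shuffle(s: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson doublet shuffle: permutes s preserving its
    dinucleotide composition (and first/last residues)."""
    if len(s) <= 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    for _ in range(100):
        trial = {k: list(v) for k, v in edges.items()}
        for k in trial:
            rng.shuffle(trial[k])
        # force an Eulerian path ending at `last`: for every other vertex,
        # its final outgoing edge must lie on a tree rooted toward `last`
        out = []
        node = s[0]
        ok = True
        for _ in range(len(s) - 1):
            if not trial.get(node):
                ok = False
                break
            nxt = trial[node].pop(0)
            out.append(nxt)
            node = nxt
        if ok and not any(trial[k] for k in trial) and node == last:
            return s[0] + "".join(out)
    # fallback: plain composition-preserving shuffle
    arr = list(s)
    rng.shuffle(arr)
    return "".join(arr)


# ---------------------------------------------------------------------------
# internals

def _mutate(seq_list: list[str], pos: int, residue: str,
            row: list[str] | None, cmap, patch_alignment: bool) -> None:
    """Substitute species residue at 1-based pos, patching the alignment row."""
    seq_list[pos - 1] = residue
    if patch_alignment and row is not None:
        row[cmap.column(pos) - 1] = residue


@dataclass
class _SpeciesState:
    name: str
    seqs: dict[Molecule, list[str]]           # mutable residue lists
    rows: dict[Molecule, list[str]]           # mutable alignment rows
    cmaps: dict[Molecule, object]
    used: dict[Molecule, list[tuple[int, int]]] = field(default_factory=dict)

    def window_free(self, mol: Molecule, start: int, end: int) -> bool:
        return all(
            end < s or start > e for s, e in self.used.get(mol, [])
        )

    def reserve(self, mol: Molecule, start: int, end: int) -> None:
        self.used.setdefault(mol, []).append((start, end))


def _plant_guide(
    state: _SpeciesState,
    mol: Molecule,
    site: int,
    guide_len: int,
    rng: np.random.Generator,
    site_perturb: str | None = None,   # None | "mismatch" | "gu"
    mid_gu: bool = False,              # G:U mid-run (breaks strict, relaxed-only)
    n_terminal_gu: int = 0,
) -> str:
    """Carve a guide complementary to the rRNA window whose +5 partner is
    *site*; applies requested perturbations.  Returns the guide sequence
    (3'-terminal nt = first nt of the downstream box)."""
    L = guide_len
    start, end = site - 5, site - 5 + L - 1
    seq = state.seqs[mol]
    if start < 1 or end > len(seq):
        raise ValueError(f"site {site} too close to the {mol.value} end")
    row, cmap = state.rows.get(mol), state.cmaps.get(mol)
    patch = row is not None
    # the guide's 3' nt is the D/D' box first nt 'C'; its partner (window
    # start) must therefore be G
    if seq[start - 1] != "G":
        _mutate(seq, start, "G", row, cmap, patch)
    if site_perturb == "gu" and seq[site - 1] not in "GU":
        _mutate(seq, site, "G", row, cmap, patch)
    window = "".join(seq[start - 1 : end])
    guide = list(reverse_complement(window))
    site_res = seq[site - 1]
    gi = L - 5 - 1  # 0-based guide index of the +5 nucleotide
    if site_perturb == "mismatch":
        guide[gi] = site_res  # X:X is always a mismatch
    elif site_perturb == "gu":
        guide[gi] = "U" if site_res == "G" else "G"
    if mid_gu:
        # wobble 3 nt from the guide 5' end: splits the strict WC run into
        # pieces both shorter than 9 for 10-12 nt guides, while the relaxed
        # run still spans the full duplex
        j = 3
        wpos = start + (L - 1 - j)
        if seq[wpos - 1] not in "GU":
            _mutate(seq, wpos, "G", row, cmap, patch)
        guide[j] = "U" if seq[wpos - 1] == "G" else "G"
    # never let wobbles shrink the strict covering run below 9
    for t in range(min(n_terminal_gu, max(0, L - 9))):
        # wobbles at the guide 5' terminus (pairs the window 3' end), far
        # from the +5 column so the strict run stays intact
        wpos = end - t
        if wpos == site or abs(wpos - site) <= 1:
            continue
        if seq[wpos - 1] not in "GU":
            _mutate(seq, wpos, "G", row, cmap, patch)
        guide[t] = "U" if seq[wpos - 1] == "G" else "G"
    state.reserve(mol, start, end)
    return "".join(guide)


def _random_guide(L: int, rng: np.random.Generator) -> str:
    g = "".join(rng.choice(_ALPHABET, size=L - 1))
    return g + "C"  # 3' nt is the box first nucleotide


def _assemble_srna(
    srna_id: str, species: str, g_dprime: str, g_d: str,
    rng: np.random.Generator, flank_len: int,
) -> tuple[RnaSequence, dict[str, int]]:
    """5'-flank C [D' guide] D' C' [D guide] D flank-3'; guides include the
    downstream box first nt, so their last residue is dropped before the box."""
    f5 = "".join(rng.choice(_ALPHABET, size=flank_len))
    f3 = "".join(rng.choice(_ALPHABET, size=flank_len))
    body = C_BOX + g_dprime[:-1] + D_BOX + C_BOX + g_d[:-1] + D_BOX
    residues = f5 + body + f3
    off = flank_len
    layout = {
        "c_start": off + 1,
        "dprime_start": off + 7 + len(g_dprime) - 1 + 1,
        "cprime_start": off + 7 + len(g_dprime) - 1 + 4 + 1,
        "d_start": off + 7 + len(g_dprime) - 1 + 4 + 7 + len(g_d) - 1 + 1,
    }
    seq = RnaSequence(id=srna_id, species=species, molecule=Molecule.SRNA,
                      residues=residues)
    return seq, layout


def _diverge(
    ancestor: str, rng: np.random.Generator, subst_rate: float, indel_rate: float
) -> tuple[list[str | None], dict[int, str]]:
    """Per-ancestor-position residues (None = deleted) plus insertions
    keyed by the ancestor position they follow."""
    out: list[str | None] = []
    insertions: dict[int, str] = {}
    for i, res in enumerate(ancestor):
        r = rng.random()
        if r < indel_rate / 2:
            out.append(None)
            continue
        if r < indel_rate:
            ins_len = int(rng.integers(1, 4))
            insertions[i + 1] = "".join(rng.choice(_ALPHABET, size=ins_len))
        if rng.random() < subst_rate:
            res = str(rng.choice([c for c in "ACGU" if c != res]))
        out.append(res)
    return out, insertions


def _build_alignment(
    species: list[str],
    diverged: dict[str, tuple[list[str | None], dict[int, str]]],
    anc_len: int,
) -> tuple[dict[str, str], dict[str, list[int | None]], list[int]]:
    """Merge per-species edits into one alignment.

    Returns (gapped row per species, per-species ungapped position at each
    ancestor position, alignment column of each ancestor position).
    """
    rows = {sp: [] for sp in species}
    pos_at_anc: dict[str, list[int | None]] = {sp: [None] * (anc_len + 1) for sp in species}
    counts = {sp: 0 for sp in species}
    col_of_anc = [0] * (anc_len + 1)
    col = 0
    for p in range(1, anc_len + 1):
        col += 1
        col_of_anc[p] = col
        for sp in species:
            res = diverged[sp][0][p - 1]
            if res is None:
                rows[sp].append("-")
            else:
                rows[sp].append(res)
                counts[sp] += 1
                pos_at_anc[sp][p] = counts[sp]
        for sp in species:
            ins = diverged[sp][1].get(p)
            if ins:
                for ch in ins:
                    col += 1
                    for sp2 in species:
                        if sp2 == sp:
                            rows[sp2].append(ch)
                        else:
                            rows[sp2].append("-")
                    counts[sp] += 1
    return ({sp: "".join(r) for sp, r in rows.items()}, pos_at_anc, col_of_anc)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full multi-species dataset with ground truth.

    Clean plants are verified at generation time: the annotator must
    recover the planted arrangement and the strict scan's best hit must be
    the planted site; offending sRNAs are re-sampled, so on clean datasets
    the pipeline's recovery is exact by construction and any deviation is
    an implementation defect.
    """
    rng = np.random.default_rng(spec.seed)
    species = [f"S{i + 1:02d}" for i in range(spec.n_species)]
    mols = {
        Molecule.RRNA_16S: spec.rrna_16s_len,
        Molecule.RRNA_23S: spec.rrna_23s_len,
    }
    ancestors = {mol: generate_rrna(ln, spec.gc_fraction, rng) for mol, ln in mols.items()}

    states: dict[str, _SpeciesState] = {}
    alignments: dict[Molecule, list[tuple[str, str]]] = {}
    pos_at_anc: dict[Molecule, dict[str, list[int | None]]] = {}
    for mol, anc in ancestors.items():
        diverged = {
            sp: _diverge(anc, rng, spec.subst_rate, spec.per_species_indel_rate)
            for sp in species
        }
        rows, paa, _ = _build_alignment(species, diverged, len(anc))
        alignments[mol] = [(sp, rows[sp]) for sp in species]
        pos_at_anc[mol] = paa
        for sp in species:
            st = states.setdefault(
                sp, _SpeciesState(name=sp, seqs={}, rows={}, cmaps={})
            )
            st.rows[mol] = list(rows[sp])
            st.seqs[mol] = [c for c in rows[sp] if c != "-"]
            st.cmaps[mol] = build_column_map(rows[sp], sp, mol)

    # conserved (shared) target sites: ancestor positions present in every
    # species, planted in >= 2 species each
    n_shared = int(round(spec.frac_shared_sites * spec.n_srnas_per_species))
    shared_specs: list[tuple[Molecule, dict[str, int], list[str]]] = []
    guard = 0
    while len(shared_specs) < n_shared and guard < 500:
        guard += 1
        mol = Molecule.RRNA_16S if rng.random() < 1 / 3 else Molecule.RRNA_23S
        anc_pos = int(rng.integers(40, len(ancestors[mol]) - 40))
        per_sp = {sp: pos_at_anc[mol][sp][anc_pos] for sp in species}
        if any(v is None for v in per_sp.values()):
            continue
        if spec.n_species >= 2:
            k = int(rng.integers(2, spec.n_species + 1))
            members = list(rng.choice(species, size=k, replace=False))
        else:
            members = list(species)
        ok = all(
            states[sp].window_free(mol, per_sp[sp] - 5 - 2, per_sp[sp] + 17)
            for sp in members
        )
        if not ok:
            continue
        shared_specs.append((mol, {sp: int(per_sp[sp]) for sp in species}, members))
        for sp in members:
            # reserve generously now so later independent plants keep clear
            states[sp].reserve(mol, per_sp[sp] - 7, per_sp[sp] + 17)

    box_params = BoxParams()
    rules = ScanRules()
    srnas: dict[str, list[RnaSequence]] = {sp: [] for sp in species}
    srna_rows: list[dict] = []
    guide_rows: list[dict] = []

    class_names = ["decoy", "empty_guide", "site_mismatch", "site_gu", "relaxed_only"]
    class_probs = [
        spec.frac_decoy, spec.frac_empty_guide, spec.frac_site_mismatch,
        spec.frac_site_gu, spec.frac_relaxed_only,
    ]
    class_probs.append(1.0 - sum(class_probs))  # clean
    class_names.append("clean")

    pending: list[tuple] = []
    shared_use: dict[str, list[tuple[Molecule, int]]] = {sp: [] for sp in species}
    for mol, per_sp, members in shared_specs:
        for sp in members:
            shared_use[sp].append((mol, per_sp[sp]))

    for sp in species:
        st = states[sp]
        for i in range(spec.n_srnas_per_species):
            srna_id = f"{sp}_sr{i + 1:04d}"
            shared_site = shared_use[sp][i] if i < len(shared_use[sp]) else None
            if shared_site is not None:
                cls = "clean"
            else:
                cls = str(rng.choice(class_names, p=class_probs))
            for attempt in range(30):
                result = _make_one_srna(
                    srna_id, sp, cls, st, rng, spec, box_params, rules,
                    shared_site if attempt == 0 or shared_site is None else None,
                )
                if result is not None:
                    break
            else:  # pragma: no cover - resampling exhausts only pathologically
                raise RuntimeError(f"could not build {srna_id} ({cls})")
            seq, layout, guides = result
            srnas[sp].append(seq)
            srna_rows.append(
                {"species": sp, "srna_id": srna_id, "cls": cls, **layout,
                 "length": len(seq)}
            )
            pending.append((sp, srna_id, cls, guides))

    # final RnaSequence objects from the (mutated) residue lists
    rrnas = {
        sp: {
            mol: RnaSequence(
                id=f"{sp}_{mol.value}", species=sp, molecule=mol,
                residues="".join(states[sp].seqs[mol]),
            )
            for mol in mols
        }
        for sp in species
    }
    alignments = {
        mol: [(sp, "".join(states[sp].rows[mol])) for sp in species] for mol in mols
    }
    # realized truth against the *final* sequences: later plants substitute
    # residues inside their own windows and can, rarely, create an equal or
    # better duplex for an earlier guide — the truth table always records
    # what a correct scan of the finished dataset must report
    for sp, srna_id, cls, guides in pending:
        guide_rows.extend(
            _realize_truth_rows(sp, srna_id, cls, guides, rrnas[sp], rules)
        )
    return SyntheticDataset(
        spec=spec,
        species=species,
        rrnas=rrnas,
        srnas=srnas,
        alignments=alignments,
        truth_srnas=pd.DataFrame(srna_rows),
        truth_guides=pd.DataFrame(guide_rows),
    )


def _realize_truth_rows(
    sp: str,
    srna_id: str,
    cls: str,
    guides: Sequence,
    rrnas: dict[Molecule, RnaSequence],
    rules: ScanRules,
) -> list[dict]:
    """Two-pass (strict then anchored relaxed rescue) truth for one sRNA."""

    def best_hits(guide, mode):
        hits = []
        for mol in (Molecule.RRNA_16S, Molecule.RRNA_23S):
            hits.extend(scan_guide(guide, rrnas[mol], rules, mode))
        hits.sort(key=lambda d: (-(d.wc_run or 0), d.n_mm + d.n_gu,
                                 0 if d.target_molecule is Molecule.RRNA_16S else 1,
                                 d.target_start))
        return hits

    realized = {}
    for guide in guides:
        hits = best_hits(guide, ScanMode.STRICT)
        best = hits[0] if hits else None
        realized[guide.kind] = {
            "sig": best is not None,
            "site": best.site if best else None,
            "mol": best.target_molecule if best else None,
            "prod": bool(best.productive) if best else False,
            "mode": "strict",
        }
    for guide, partner in (tuple(guides), tuple(guides)[::-1]):
        mine, anchor = realized[guide.kind], realized[partner.kind]
        if mine["sig"] or not anchor["sig"]:
            continue
        rescued = [
            d for d in best_hits(guide, ScanMode.RELAXED)
            if d.target_molecule is anchor["mol"]
            and abs(d.site - anchor["site"]) <= 100
        ]
        if rescued:
            best = rescued[0]
            mine.update(sig=True, site=best.site, mol=best.target_molecule,
                        prod=bool(best.productive), mode="relaxed")
    rows = []
    for guide in guides:
        r = realized[guide.kind]
        rows.append(
            {
                "species": sp,
                "srna_id": srna_id,
                "guide_kind": guide.kind.value,
                "cls": cls,
                "guide_seq": guide.sequence,
                "guide_start": guide.start,
                "guide_end": guide.end,
                "molecule": r["mol"].value if r["mol"] else "",
                "site": r["site"] if r["site"] is not None else -1,
                "expect_significant": r["sig"],
                "expect_productive": r["prod"],
                "expect_mode": r["mode"] if r["sig"] else "",
            }
        )
    return rows


def _make_one_srna(
    srna_id: str,
    sp: str,
    cls: str,
    st: _SpeciesState,
    rng: np.random.Generator,
    spec: SyntheticSpec,
    box_params: BoxParams,
    rules: ScanRules,
    shared_site: tuple[Molecule, int] | None,
):
    """Build one sRNA of the requested class; returns None to request a
    resample when generation-time verification fails."""
    lo, hi = spec.guide_len_range
    L1 = int(rng.integers(lo, hi + 1))
    L2 = int(rng.integers(lo, hi + 1))
    reserved_before = {m: list(st.used.get(m, [])) for m in st.seqs}

    def undo() -> None:
        for m in st.seqs:
            st.used[m] = reserved_before[m]

    if shared_site is not None:
        mol, site_dp = shared_site
    else:
        mol = Molecule.RRNA_16S if rng.random() < 1 / 3 else Molecule.RRNA_23S
        site_dp = None

    def pick(molc: Molecule, L: int) -> int:
        for _ in range(200):
            s = int(rng.integers(30, len(st.seqs[molc]) - 30))
            if st.window_free(molc, s - 5, s - 5 + L - 1):
                return s
        raise RuntimeError("no free window")

    if site_dp is None:
        site_dp = pick(mol, L1)
    # D site within 100 nt of the D' site (double-guide architecture)
    site_d = None
    for _ in range(200):
        delta = int(rng.integers(20, 81)) * (1 if rng.random() < 0.5 else -1)
        cand = site_dp + delta
        if 30 <= cand <= len(st.seqs[mol]) - 30 and st.window_free(
            mol, cand - 5, cand - 5 + L2 - 1
        ) and abs((cand - 5) - (site_dp - 5)) > max(L1, L2) + 1:
            site_d = cand
            break
    if site_d is None:
        undo()
        return None

    perturb = {"site_mismatch": "mismatch", "site_gu": "gu"}.get(cls)
    expect: dict[GuideKind, dict] = {}

    if cls == "decoy":
        g_dp = dinucleotide_shuffle(_random_guide(L1, rng)[:-1], rng) + "C"
        g_d = dinucleotide_shuffle(_random_guide(L2, rng)[:-1], rng) + "C"
        expect[GuideKind.DPRIME_GUIDE] = {"molecule": None, "site": None}
        expect[GuideKind.D_GUIDE] = {"molecule": None, "site": None}
    elif cls == "empty_guide":
        g_dp = _plant_guide(st, mol, site_dp, L1, rng,
                            n_terminal_gu=spec.n_gu_in_duplex)
        g_d = _random_guide(L2, rng)
        expect[GuideKind.DPRIME_GUIDE] = {
            "molecule": mol, "site": site_dp, "productive": True, "mode": "strict",
        }
        expect[GuideKind.D_GUIDE] = {"molecule": None, "site": None}
    else:
        g_dp = _plant_guide(
            st, mol, site_dp, L1, rng, site_perturb=perturb,
            n_terminal_gu=spec.n_gu_in_duplex,
        )
        g_d = _plant_guide(
            st, mol, site_d, L2, rng, site_perturb=perturb,
            mid_gu=(cls == "relaxed_only"),
            n_terminal_gu=spec.n_gu_in_duplex,
        )
        productive = perturb is None
        expect[GuideKind.DPRIME_GUIDE] = {
            "molecule": mol, "site": site_dp, "productive": productive,
            "mode": "strict",
        }
        expect[GuideKind.D_GUIDE] = {
            "molecule": mol, "site": site_d, "productive": productive,
            "mode": "relaxed" if cls == "relaxed_only" else "strict",
        }

    seq, layout = _assemble_srna(srna_id, sp, g_dp, g_d, rng, spec.flank_len)
    annotated = annotate_cd_srna(seq, box_params)
    if isinstance(annotated, Rejection):
        undo()
        return None
    got = {
        "c_start": annotated.boxes[BoxKind.C].start,
        "dprime_start": annotated.boxes[BoxKind.DPRIME].start,
        "cprime_start": annotated.boxes[BoxKind.CPRIME].start,
        "d_start": annotated.boxes[BoxKind.D].start,
    }
    if got != layout or annotated.d_guide is None or annotated.dprime_guide is None:
        undo()
        return None

    # generation-time verification: emulate the scanner's two-pass logic so
    # the truth table records exactly what a correct pipeline must output
    def _sorted_hits(guide, mode):
        hits = []
        for m, residues in st.seqs.items():
            rrna = RnaSequence(
                id=f"{sp}_{m.value}", species=sp, molecule=m,
                residues="".join(residues),
            )
            hits.extend(scan_guide(guide, rrna, rules, mode))
        hits.sort(key=lambda d: (-(d.wc_run or 0), d.n_mm + d.n_gu,
                                 0 if d.target_molecule is Molecule.RRNA_16S else 1,
                                 d.target_start))
        return hits

    guides = (annotated.d_guide, annotated.dprime_guide)
    realized: dict[GuideKind, dict] = {}
    for guide in guides:
        exp = expect[guide.kind]
        hits = _sorted_hits(guide, ScanMode.STRICT)
        best = hits[0] if hits else None
        if exp.get("site") is not None and exp.get("mode") == "strict":
            # planted strict guide: best hit must be the plant itself
            if best is None or best.site != exp["site"] or \
                    best.target_molecule is not exp["molecule"] or \
                    bool(best.productive) != exp["productive"]:
                undo()
                return None
        elif exp.get("mode") == "relaxed" and best is not None:
            undo()  # relaxed-only plants must NOT be strict-significant
            return None
        realized[guide.kind] = {
            "sig": best is not None,
            "site": best.site if best else None,
            "mol": best.target_molecule if best else None,
            "prod": bool(best.productive) if best else False,
            "mode": "strict",
        }
    # pass 2: relaxed rescue of an empty guide next to an anchored partner
    for guide, partner in (guides, guides[::-1]):
        mine, anchor = realized[guide.kind], realized[partner.kind]
        if not mine["sig"] and anchor["sig"]:
            rescued = [
                d for d in _sorted_hits(guide, ScanMode.RELAXED)
                if d.target_molecule is anchor["mol"]
                and abs(d.site - anchor["site"]) <= 100
            ]
            if rescued:
                best = rescued[0]
                mine.update(sig=True, site=best.site, mol=best.target_molecule,
                            prod=bool(best.productive), mode="relaxed")
        exp = expect[guide.kind]
        if exp.get("mode") == "relaxed":
            # relaxed-only plants must be rescued at the planted site
            if not mine["sig"] or mine["site"] != exp["site"] or \
                    mine["prod"] != exp["productive"]:
                undo()
                return None
    return seq, layout, guides
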