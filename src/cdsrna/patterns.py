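"""Cross-species methylation pattern analysis.

Maps per-species predictions onto a shared rRNA alignment, aggregates
conservation per alignment column, profiles methylation density in sliding
windows, finds within-species redundant targets, and classifies
double-guide sRNAs whose two targets are distant in primary sequence but
potentially close in secondary structure (chaperone candidates).
"""

from __future__ import annotations

import logging
from collections import defaultdict, deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scan import MethylationPrediction
from .seqio import AlignmentColumnMap, Molecule

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConservationSite:
    """An alignment column with the species predicted modified there."""

    molecule: Molecule
    column: int
    species_hits: frozenset[str]
    n_events: int

    @property
    def n_species(self) -> int:
        return len(self.species_hits)


@dataclass
class HotspotProfile:
    """Windowed methylation-event density along alignment columns.

    ``density[c - 1]`` is the number of events in columns
    [c - w//2, c + w//2], truncated at the alignment ends.
    """

    molecule: Molecule
    window: int
    density: np.ndarray


@dataclass(frozen=True)
class RedundantSiteGroup:
    """Two or more sRNAs of one species targeting the same rRNA position."""

    species: str
    molecule: Molecule
    position: int
    srna_ids: tuple[str, ...]


class PairClassification(str, Enum):
    DOUBLE_LOCAL = "double_local"
    DOUBLE_DISTANT = "double_distant"
    CROSS_MOLECULE = "cross_molecule"


@dataclass
class DistantTargetCall:
    """Classification of a double-guide sRNA's two kept sites."""

    species: str
    srna_id: str
    site_a: MethylationPrediction   # D guide
    site_b: MethylationPrediction   # D' guide
    primary_distance: int | None    # |pos_a - pos_b| on the same molecule
    classification: PairClassification
    structure_distance: int | None = None


def map_to_alignment(
    predictions: Iterable[MethylationPrediction],
    column_maps: Mapping[tuple[str, Molecule], AlignmentColumnMap],
) -> tuple[list[MethylationPrediction], list[tuple[MethylationPrediction, str]]]:
    """Annotate predictions with their alignment column.

    Returns (mapped, unmappable); unmappable predictions are reported with
    a reason, never silently dropped.
    """
    mapped: list[MethylationPrediction] = []
    unmappable: list[tuple[MethylationPrediction, str]] = []
    for p in predictions:
        cmap = column_maps.get((p.species, p.molecule))
        if cmap is None:
            unmappable.append((p, f"no column map for {p.species}/{p.molecule.value}"))
            continue
        try:
            p.alignment_column = cmap.column(p.position)
        except KeyError as exc:
            unmappable.append((p, str(exc)))
            continue
        mapped.append(p)
    return mapped, unmappable


def conservation_summary(
    predictions: Iterable[MethylationPrediction],
    productive_only: bool = True,
) -> tuple[list[ConservationSite], dict[str, dict[str, int]]]:
    """Per-column aggregation of mapped predictions, with per-molecule totals.

    Conservation is counted over productive interactions by default
    (non-productive site-mismatch duplexes form but do not methylate).
    Totals per molecule: n_events, n_positions (distinct columns),
    n_single (one species), n_multi (two or more); the identity
    n_positions = n_single + n_multi always holds.
    """
    events: dict[tuple[Molecule, int], list[str]] = defaultdict(list)
    for p in predictions:
        if productive_only and not p.productive:
            continue
        if p.alignment_column is None:
            raise ValueError(
                f"prediction {p.srna_id}/{p.guide_kind.value} lacks an "
                "alignment column; run map_to_alignment first"
            )
        events[(p.molecule, p.alignment_column)].append(p.species)
    sites = [
        ConservationSite(
            molecule=mol,
            column=col,
            species_hits=frozenset(species_list),
            n_events=len(species_list),
        )
        for (mol, col), species_list in sorted(events.items())
    ]
    totals: dict[str, dict[str, int]] = {}
    for mol in {s.molecule for s in sites}:
        mol_sites = [s for s in sites if s.molecule == mol]
        n_single = sum(s.n_species == 1 for s in mol_sites)
        n_multi = sum(s.n_species >= 2 for s in mol_sites)
        totals[mol.value] = {
            "n_events": sum(s.n_events for s in mol_sites),
            "n_positions": len(mol_sites),
            "n_single": n_single,
            "n_multi": n_multi,
        }
        assert totals[mol.value]["n_positions"] == n_single + n_multi
    return sites, totals


def hotspot_profile(
    sites: Sequence[ConservationSite],
    window: int = 9,
    n_columns: int | None = None,
) -> HotspotProfile:
    """Windowed event density per alignment column (no wraparound)."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    molecules = {s.molecule for s in sites}
    if len(molecules) > 1:
        raise ValueError("hotspot_profile expects sites from a single molecule")
    molecule = molecules.pop() if molecules else Molecule.OTHER
    if n_columns is None:
        n_columns = max((s.column for s in sites), default=0)
    events = np.zeros(n_columns, dtype=np.int64)
    for s in sites:
        if s.column <= n_columns:
            events[s.column - 1] += s.n_events
    density = np.convolve(events, np.ones(window, dtype=np.int64), mode="same")
    return HotspotProfile(molecule=molecule, window=window, density=density)


def find_redundant_sites(
    predictions: Iterable[MethylationPrediction],
    productive_only: bool = True,
) -> list[RedundantSiteGroup]:
    """Groups of >= 2 distinct sRNAs of one species hitting one position.

    Keys on species coordinates (not alignment columns): redundancy is a
    within-genome phenomenon (duplicated or rearranged sRNA genes).
    """
    groups: dict[tuple[str, Molecule, int], set[str]] = defaultdict(set)
    for p in predictions:
        if productive_only and not p.productive:
            continue
        groups[(p.species, p.molecule, p.position)].add(p.srna_id)
    out = [
        RedundantSiteGroup(
            species=sp, molecule=mol, position=pos,
            srna_ids=tuple(sorted(ids)),
        )
        for (sp, mol, pos), ids in groups.items()
        if len(ids) >= 2
    ]
    out.sort(key=lambda g: (g.species, g.molecule.value, g.position))
    return out


def classify_guide_pairs(
    predictions: Iterable[MethylationPrediction],
    threshold: int = 100,
) -> list[DistantTargetCall]:
    """Classify each sRNA that keeps one site per guide on both guides.

    Same molecule and |distance| <= threshold -> double_local; same
    molecule further apart -> double_distant; different molecules ->
    cross_molecule.
    """
    by_srna: dict[tuple[str, str], dict[str, MethylationPrediction]] = defaultdict(dict)
    for p in predictions:
        by_srna[(p.species, p.srna_id)][p.guide_kind.value] = p
    calls: list[DistantTargetCall] = []
    for (species, srna_id), kept in sorted(by_srna.items()):
        if set(kept) != {"D_guide", "Dprime_guide"}:
            continue
        a, b = kept["D_guide"], kept["Dprime_guide"]
        if a.molecule != b.molecule:
            calls.append(
                DistantTargetCall(species, srna_id, a, b, None,
                                  PairClassification.CROSS_MOLECULE)
            )
            continue
        dist = abs(a.position - b.position)
        cls = (
            PairClassification.DOUBLE_LOCAL
            if dist <= threshold
            else PairClassification.DOUBLE_DISTANT
        )
        calls.append(DistantTargetCall(species, srna_id, a, b, dist, cls))
    return calls


# ---------------------------------------------------------------------------
# Secondary structure

_BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


def parse_dot_bracket(structure: str) -> list[int]:
    """Dot-bracket string -> 1-based pairing table (0 = unpaired).

    Supports (), [], {} and <> bracket layers; raises on unbalanced input.
    """
    partner = [0] * len(structure)
    stacks: dict[str, list[int]] = {k: [] for k in _BRACKETS}
    for i, ch in enumerate(structure):
        if ch in _BRACKETS:
            stacks[ch].append(i)
        elif ch in _CLOSERS:
            stack = stacks[_CLOSERS[ch]]
            if not stack:
                raise ValueError(f"unbalanced {ch!r} at position {i + 1}")
            j = stack.pop()
            partner[i] = j + 1
            partner[j] = i + 1
        elif ch not in ".,:_-":
            raise ValueError(f"unexpected structure character {ch!r} at {i + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unbalanced {opener!r} at position {stack[-1] + 1}")
    return partner


def parse_ct(path: str | Path) -> list[int]:
    """CT (connectivity table) file -> 1-based pairing table."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty CT file")
    n = int(lines[0].split()[0])
    partner = [0] * n
    for line in lines[1 : n + 1]:
        fields = line.split()
        i, j = int(fields[0]), int(fields[4])
        partner[i - 1] = j
    return partner


def structure_distance(partner: Sequence[int], pos_a: int, pos_b: int) -> int:
    """Shortest path between two nucleotides in the structure graph.

    Nodes are nucleotides; edges are backbone adjacencies (i, i+1) and
    base pairs (i, partner[i]).  Breadth-first search.
    """
    n = len(partner)
    for p in (pos_a, pos_b):
        if not 1 <= p <= n:
            raise ValueError(f"position {p} outside structure of length {n}")
    if pos_a == pos_b:
        return 0
    seen = {pos_a}
    queue = deque([(pos_a, 0)])
    while queue:
        node, dist = queue.popleft()
        neighbors = [node - 1, node + 1]
        if partner[node - 1]:
            neighbors.append(partner[node - 1])
        for nxt in neighbors:
            if 1 <= nxt <= n and nxt not in seen:
                if nxt == pos_b:
                    return dist + 1
                seen.add(nxt)
                queue.append((nxt, dist + 1))
    raise RuntimeError("structure graph is connected; unreachable")  # pragma: no cover


def chaperone_candidates(
    calls: Iterable[DistantTargetCall],
    structures: Mapping[Molecule, Sequence[int]] | None,
    max_struct_dist: int = 10,
) -> list[DistantTargetCall]:
    """Double-distant sRNAs whose two sites are close in structure space.

    With no structure for a molecule, its double_distant calls are
    returned undecided (structure_distance None) with a warning: primary
    distance alone cannot rule chaperone candidacy in or out.
    """
    out: list[DistantTargetCall] = []
    for call in calls:
        if call.classification is not PairClassification.DOUBLE_DISTANT:
            continue
        partner = (structures or {}).get(call.site_a.molecule)
        if partner is None:
            logger.warning(
                "no secondary structure for %s: %s %s kept with structure "
                "distance unknown",
                call.site_a.molecule.value, call.species, call.srna_id,
            )
            call.structure_distance = None
            out.append(call)
            continue
        call.structure_distance = structure_distance(
            partner, call.site_a.position, call.site_b.position
        )
        if call.structure_distance <= max_struct_dist:
            out.append(call)
    return out


def plot_density(profile: HotspotProfile, path: str | Path) -> None:
    """Simple per-column density plot of a hotspot profile (PNG/PDF/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(np.arange(1, len(profile.density) + 1), profile.density, lw=0.8)
    ax.set_xlabel("alignment column")
    ax.set_ylabel(f"events / {profile.window} nt window")
    ax.set_title(f"2'-O-methylation density, {profile.molecule.value}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
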