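"""Reference data from the seven-organism archaeal C/D box sRNA survey.

A published pan-archaeal survey of experimentally detected C/D box sRNAs
(seven species spanning three phyla, six of them thermophiles) is the
study design this package models.  This module bundles that survey's
per-organism registry and its printed summary accounting so the package's
bookkeeping identities can be evaluated against real numbers without any
downloads.  All derived figures below are computed from the printed
components at call time, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import SpeciesRecord

#: The seven organisms of the reference survey: abbreviation, name,
#: phylum/order, optimal growth temperature, genomic GC %, and the number
#: of C/D box sRNA genes detected by RNA-Seq in each.
REFERENCE_SPECIES: tuple[SpeciesRecord, ...] = (
    SpeciesRecord("Neq", "Nanoarchaeum equitans", "Nanoarchaeota",
                  "80-100 C", 31.6, 26),
    SpeciesRecord("Iho", "Ignicoccus hospitalis", "Crenarchaeota/Desulfurococcales",
                  "80-100 C", 56.5, 128),
    SpeciesRecord("Mma", "Methanococcus maripaludis C5", "Euryarchaeota/Methanococcales",
                  "35-40 C", 33.0, 7),
    SpeciesRecord("Mka", "Methanopyrus kandleri", "Euryarchaeota/Methanopyrales",
                  "84-110 C", 61.2, 127),
    SpeciesRecord("Pca", "Pyrobaculum calidifontis", "Crenarchaeota/Thermoproteales",
                  "90-100 C", 57.2, 88),
    SpeciesRecord("Sac", "Sulfolobus acidocaldarius", "Crenarchaeota/Sulfolobales",
                  "67-80 C", 36.7, 61),
    SpeciesRecord("Tte", "Thermoproteus tenax", "Crenarchaeota/Thermoproteales",
                  "70-97 C", 55.1, 52),
)


@dataclass(frozen=True)
class MoleculeTally:
    """Per-molecule site statistics as printed by the reference survey."""

    n_events: int       # predicted modification events mapped to the alignment
    n_positions: int    # distinct alignment positions carrying >= 1 event
    n_single: int       # positions modified in exactly one species
    n_multi: int        # positions modified in two or more species


@dataclass(frozen=True)
class SurveyAccounting:
    """The reference survey's printed guide-interaction bookkeeping."""

    n_srnas: int = 489                    # C/D box sRNAs, two guides each
    n_significant: int = 735              # guide interactions passing significance
    n_site_mismatch: int = 16             # significant but mismatched at the +5 site
    n_double_guide_srnas: int = 262       # sRNAs with both guides targeting rRNA
    n_no_target_srnas: int = 163          # sRNAs with neither guide targeting rRNA
    tally_16s: MoleculeTally = MoleculeTally(266, 195, 152, 43)
    tally_23s: MoleculeTally = MoleculeTally(453, 334, 255, 79)


REFERENCE_ACCOUNTING = SurveyAccounting()


def total_srna_genes(species: tuple[SpeciesRecord, ...] = REFERENCE_SPECIES) -> int:
    """Total sRNA gene count summed over a species registry."""
    return sum(rec.srna_gene_count for rec in species)


def productive_interactions(acc: SurveyAccounting = REFERENCE_ACCOUNTING) -> int:
    """Productive = significant minus site-mismatched (non-productive) ones."""
    return acc.n_significant - acc.n_site_mismatch


def multi_species_site_percent(acc: SurveyAccounting = REFERENCE_ACCOUNTING) -> float:
    """Multi-species positions as a percentage of productive events.

    The survey quotes the share of methylation that is conserved in more
    than one species with productive interactions as denominator; the
    sibling ratio over distinct positions is also meaningful and is
    reported separately by :func:`multi_species_position_percent`.
    """
    multi = acc.tally_16s.n_multi + acc.tally_23s.n_multi
    return 100.0 * multi / productive_interactions(acc)


def multi_species_position_percent(acc: SurveyAccounting = REFERENCE_ACCOUNTING) -> float:
    """Multi-species positions as a percentage of all distinct positions."""
    multi = acc.tally_16s.n_multi + acc.tally_23s.n_multi
    positions = acc.tally_16s.n_positions + acc.tally_23s.n_positions
    return 100.0 * multi / positions


def accounting_identities(acc: SurveyAccounting = REFERENCE_ACCOUNTING) -> dict[str, bool]:
    """Check the internal consistency of a survey accounting.

    positions = single + multi per molecule, and total mapped events equal
    the productive interaction count.
    """
    t16, t23 = acc.tally_16s, acc.tally_23s
    return {
        "positions_16s": t16.n_positions == t16.n_single + t16.n_multi,
        "positions_23s": t23.n_positions == t23.n_single + t23.n_multi,
        "events_equal_productive":
            t16.n_events + t23.n_events == productive_interactions(acc),
    }
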