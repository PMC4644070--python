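"""Sequence and table I/O plus alignment coordinate maps.

All coordinates in this package are 1-based and inclusive, matching the
convention used for rRNA modification positions (e.g. "U2880").  Sequences
are normalized to the RNA alphabet {A, C, G, U} at the boundary: DNA input
(T, lowercase) is accepted and converted, anything else is rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

GAP = "-"
RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class Molecule(str, Enum):
    """Kind of RNA molecule a sequence represents."""

    SRNA = "sRNA"
    RRNA_16S = "rRNA_16S"
    RRNA_23S = "rRNA_23S"
    OTHER = "other"


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class SequenceAlphabetError(ValueError):
    """Residues outside the accepted RNA/DNA alphabet."""

    def __init__(self, seq_id: str, positions: list[int], residues: list[str]):
        self.seq_id = seq_id
        self.positions = positions
        self.residues = residues
        shown = ", ".join(
            f"{r}@{p}" for p, r in list(zip(positions, residues))[:10]
        )
        super().__init__(
            f"sequence {seq_id!r}: invalid residues (1-based): {shown}"
            + (" ..." if len(positions) > 10 else "")
        )


class AlignmentShapeError(ValueError):
    """Rows of a multi-FASTA alignment differ in length."""


def normalize_residues(raw: str, seq_id: str = "<anon>") -> str:
    """Uppercase, map T to U and validate against {A, C, G, U}."""
    s = raw.upper().replace("T", "U")
    bad = [(i + 1, c) for i, c in enumerate(s) if c not in RNA_ALPHABET]
    if bad:
        raise SequenceAlphabetError(seq_id, [p for p, _ in bad], [c for _, c in bad])
    return s


def reverse_complement(residues: str) -> str:
    """Antiparallel complement of an RNA string (A<->U, C<->G)."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RnaSequence:
    """A normalized RNA sequence with species/molecule provenance."""

    id: str
    species: str
    molecule: Molecule
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, self.id)
        )
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SpeciesRecord:
    """One organism in a species registry."""

    abbreviation: str
    name: str
    phylum_order: str
    growth_temp: str
    gc_percent: float
    srna_gene_count: int


def read_fasta(path: str | Path, species: str, molecule: Molecule) -> list[RnaSequence]:
    """Read a FASTA file into normalized :class:`RnaSequence` records.

    Record order is preserved; T is mapped to U; residues outside the
    DNA/RNA alphabet raise :class:`SequenceAlphabetError` naming the record.
    """
    path = Path(path)
    out: list[RnaSequence] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append(
                RnaSequence(
                    id=rec.id, species=species, molecule=molecule,
                    residues=str(rec.seq),
                )
            )
    except SequenceAlphabetError:
        raise
    except ValueError as exc:  # Biopython parse failure
        raise FastaParseError(f"{path}: {exc}") from exc
    return out


def read_alignment(path: str | Path, dot_as_gap: bool = False) -> list[tuple[str, str]]:
    """Read a multi-FASTA alignment as ``[(row id, gapped sequence), ...]``.

    All rows must have equal length; the gap character is ``-``.  ``.`` is an
    error unless *dot_as_gap* maps it to ``-``.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        msg = str(exc)
        if "length" in msg.lower():
            raise AlignmentShapeError(f"{path}: {msg}") from exc
        raise FastaParseError(f"{path}: {msg}") from exc
    for rec in aln:
        s = str(rec.seq).upper().replace("T", "U")
        if dot_as_gap:
            s = s.replace(".", GAP)
        bad = [
            (i + 1, c)
            for i, c in enumerate(s)
            if c not in RNA_ALPHABET and c != GAP
        ]
        if bad:
            raise SequenceAlphabetError(
                rec.id, [p for p, _ in bad], [c for _, c in bad]
            )
        rows.append((rec.id, s))
    lengths = {len(s) for _, s in rows}
    if len(lengths) > 1:
        raise AlignmentShapeError(f"{path}: ragged alignment rows {sorted(lengths)}")
    return rows


@dataclass
class AlignmentColumnMap:
    """Bidirectional map between ungapped positions and alignment columns.

    ``col_of_pos[i-1]`` is the alignment column (1-based) of the i-th
    non-gap residue; ``pos_of_col`` is the inverse partial map.
    """

    species: str
    molecule: Molecule
    col_of_pos: np.ndarray  # shape (n_residues,), 1-based column numbers
    pos_of_col: dict[int, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.col_of_pos)

    def column(self, pos: int) -> int:
        """Alignment column of ungapped position *pos* (1-based)."""
        if not 1 <= pos <= len(self.col_of_pos):
            raise KeyError(
                f"position {pos} outside 1..{len(self.col_of_pos)} "
                f"for {self.species}/{self.molecule.value}"
            )
        return int(self.col_of_pos[pos - 1])

    def position(self, col: int) -> int | None:
        """Ungapped position at alignment column *col*, or None for a gap."""
        return self.pos_of_col.get(col)


def build_column_map(gapped: str, species: str, molecule: Molecule) -> AlignmentColumnMap:
    """Column map of one gapped alignment row (gap character ``-``)."""
    cols = np.flatnonzero(np.frombuffer(gapped.encode(), dtype=np.uint8) != ord(GAP)) + 1
    if len(cols) == 0:
        logger.warning(
            "all-gap alignment row for %s/%s: empty column map",
            species, molecule.value,
        )
    return AlignmentColumnMap(
        species=species,
        molecule=molecule,
        col_of_pos=cols.astype(np.int64),
        pos_of_col={int(c): i + 1 for i, c in enumerate(cols)},
    )


# ---------------------------------------------------------------------------
# Prediction tables

PREDICTION_COLUMNS = [
    "species", "srna_id", "guide_kind", "molecule", "position",
    "productive", "mode", "wc_run", "n_gu", "n_mm", "target_id",
    "alignment_column",
]


def predictions_to_frame(predictions: Iterable) -> pd.DataFrame:
    """Tabulate MethylationPrediction records into a DataFrame."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "species": p.species,
                "srna_id": p.srna_id,
                "guide_kind": p.guide_kind.value,
                "molecule": p.molecule.value,
                "position": p.position,
                "productive": bool(p.productive),
                "mode": p.mode.value,
                "wc_run": p.wc_run,
                "n_gu": p.n_gu,
                "n_mm": p.n_mm,
                "target_id": p.target_id,
                "alignment_column": p.alignment_column,
            }
        )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def write_predictions(predictions: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write predictions as TSV, GFF3 or JSON.

    GFF3 emits 1-based inclusive point features of type
    ``2prime_O_methylation_site`` on the target rRNA sequence id.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        df = predictions_to_frame(predictions)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        df = predictions_to_frame(predictions)
        records = df.replace({np.nan: None}).to_dict(orient="records")
        path.write_text(json.dumps(records, indent=1) + "\n")
    elif fmt == "gff3":
        lines = ["##gff-version 3"]
        for i, p in enumerate(predictions, 1):
            attrs = (
                f"ID=meth{i:05d};species={p.species};srna={p.srna_id};"
                f"guide={p.guide_kind.value};productive={str(bool(p.productive)).lower()};"
                f"mode={p.mode.value}"
            )
            lines.append(
                "\t".join(
                    [
                        p.target_id, "cdsrna", "2prime_O_methylation_site",
                        str(p.position), str(p.position), ".", "+", ".", attrs,
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown prediction format {format!r}")


def read_predictions(path: str | Path) -> list:
    """Read a prediction TSV back into MethylationPrediction records."""
    from .scan import GuideKind, MethylationPrediction, ScanMode

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        col = row.alignment_column
        out.append(
            MethylationPrediction(
                species=row.species,
                srna_id=row.srna_id,
                guide_kind=GuideKind(row.guide_kind),
                molecule=Molecule(row.molecule),
                position=int(row.position),
                productive=bool(row.productive),
                mode=ScanMode(row.mode),
                wc_run=int(row.wc_run),
                n_gu=int(row.n_gu),
                n_mm=int(row.n_mm),
                target_id=row.target_id,
                alignment_column=None if pd.isna(col) else int(col),
            )
        )
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    """Write RnaSequence records as plain FASTA."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 70):
                fh.write(s.residues[i : i + 70] + "\n")


def read_prediction_workbook(path: str | Path, sheet_index: int = 1) -> pd.DataFrame:
    """Optional convenience reader: Excel workbook sheet -> prediction table.

    Expects a sheet whose header row contains (case-insensitively) the
    columns species, srna_id (or sRNA), guide_kind (or guide), molecule
    (or subunit), position (or site).  Returns a DataFrame with canonical
    column names; not required by any core pipeline stage.
    """
    from openpyxl import load_workbook

    wb = load_workbook(str(path), read_only=True, data_only=True)
    ws = wb.worksheets[sheet_index]
    rows = list(ws.iter_rows(values_only=True))
    wb.close()
    if not rows:
        return pd.DataFrame(
            columns=["species", "srna_id", "guide_kind", "molecule", "position"]
        )
    header = [str(h).strip().lower() if h is not None else "" for h in rows[0]]
    aliases = {
        "species": "species", "organism": "species",
        "srna": "srna_id", "srna_id": "srna_id",
        "guide": "guide_kind", "guide_kind": "guide_kind",
        "molecule": "molecule", "subunit": "molecule",
        "position": "position", "site": "position",
        "productive": "productive",
    }
    colmap = {i: aliases[h] for i, h in enumerate(header) if h in aliases}
    records = []
    for row in rows[1:]:
        if row is None or all(v is None for v in row):
            continue
        records.append({name: row[i] for i, name in colmap.items()})
    df = pd.DataFrame(records)
    if "position" in df.columns:
        df["position"] = df["position"].astype(int)
    return df
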