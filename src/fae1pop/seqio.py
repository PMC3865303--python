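"""Alignment, metadata, phenotype and tree I/O, plus coordinate conventions.

The analysis substrate is an in-frame multiple alignment of a protein-coding
DNA fragment.  Columns are 1-based.  Coding positions are 1-based from the
start codon of the reference coding sequence; the default ``coding_offset``
of 431 means alignment column 1 sits at coding position 431 (inside codon
144, phase 2), matching an amplicon that starts mid-gene.

Terminal gap runs are treated as missing data (partial amplicons), not as
deletions; only internal gap runs are candidate indel events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .codons import standard_code
from .errors import AlignmentError, AlphabetError, MetadataError, TreeError

GAP = "-"
MISSING = "N"
ALPHABET = frozenset("ACGTN-")

METADATA_COLUMNS = ["record_id", "tribe", "genus", "species", "clade"]


@dataclass
class SequenceRecord:
    """One aligned sequence with its taxon metadata."""

    record_id: str
    sequence: str
    species: str = ""
    tribe: str = ""
    genus: str = ""
    clade: str = ""

    def __post_init__(self):
        if not self.record_id:
            raise MetadataError("record_id must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.record_id!r} contains characters outside "
                f"A/C/G/T/N/-: {sorted(bad)}"
            )


class AlignmentMatrix:
    """Equal-length DNA records plus the coding-coordinate convention.

    Parameters
    ----------
    records
        Ordered sequence records; all must share one length.
    coding_offset
        Coding-region position of alignment column 1 (1-based, default 431).
    """

    def __init__(self, records: Sequence[SequenceRecord], coding_offset: int = 431):
        records = list(records)
        if not records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"records have unequal lengths: {sorted(lengths)}"
            )
        (n_columns,) = lengths
        if n_columns == 0:
            raise AlignmentError("alignment has zero columns")
        if coding_offset < 1:
            raise AlignmentError("coding_offset must be >= 1")
        ids = [r.record_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate record ids: {dupes}")
        self.records = records
        self.n_columns = n_columns
        self.coding_offset = coding_offset
        self._by_id = {r.record_id: r for r in records}

    # -- basic access -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def record(self, record_id: str) -> SequenceRecord:
        try:
            return self._by_id[record_id]
        except KeyError:
            raise MetadataError(f"unknown record id {record_id!r}") from None

    def subset(self, record_ids: Iterable[str]) -> list[SequenceRecord]:
        return [self.record(i) for i in record_ids]

    def column(self, column: int) -> str:
        """States of a 1-based column, one character per record."""
        self._check_column(column)
        i = column - 1
        return "".join(r.sequence[i] for r in self.records)

    def _check_column(self, column: int) -> None:
        if not 1 <= column <= self.n_columns:
            raise AlignmentError(
                f"column {column} outside [1, {self.n_columns}]"
            )

    # -- coordinates ------------------------------------------------------

    def column_to_coding(self, column: int) -> tuple[int, int, int]:
        """Map an alignment column to (coding_position, codon_index, phase)."""
        self._check_column(column)
        coding = column + self.coding_offset - 1
        codon_index = math.ceil(coding / 3)
        phase = (coding - 1) % 3 + 1
        return coding, codon_index, phase

    def coding_to_column(self, coding_position: int) -> int:
        column = coding_position - self.coding_offset + 1
        self._check_column(column)
        return column

    def codon_columns(self, codon_index: int) -> tuple[int, int, int] | None:
        """Alignment columns of a codon, or None if not fully inside the matrix."""
        first_coding = 3 * (codon_index - 1) + 1
        cols = tuple(first_coding + k - self.coding_offset + 1 for k in range(3))
        if cols[0] < 1 or cols[2] > self.n_columns:
            return None
        return cols  # type: ignore[return-value]

    def codon_range(self) -> tuple[int, int]:
        """(first, last) codon index fully covered by the matrix."""
        first = math.ceil((self.coding_offset - 1) / 3) + 1
        last = (self.coding_offset + self.n_columns - 1) // 3
        if last < first:
            raise AlignmentError("matrix covers no complete codon")
        return first, last

    def codon_of(self, record_id: str, codon_index: int) -> str | None:
        """The record's codon, or None when not covered / containing gap or N."""
        cols = self.codon_columns(codon_index)
        if cols is None:
            return None
        seq = self.record(record_id).sequence
        codon = seq[cols[0] - 1 : cols[2]]
        if GAP in codon or MISSING in codon:
            return None
        return codon


# -- alignment I/O --------------------------------------------------------


def read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata table lacks columns: {missing}")
    if "clade" not in df.columns:
        df["clade"] = ""
    if df["record_id"].duplicated().any():
        dupes = sorted(df.loc[df["record_id"].duplicated(), "record_id"])
        raise MetadataError(f"duplicate record ids in metadata: {dupes}")
    return df[METADATA_COLUMNS]


def read_alignment(
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
    coding_offset: int = 431,
) -> AlignmentMatrix:
    """Read a gapped FASTA alignment and attach taxon metadata.

    Every FASTA id must resolve against the metadata table (when given);
    sequences are uppercased and validated against the A/C/G/T/N/- alphabet.
    """
    meta = None
    if metadata_path is not None:
        meta = read_metadata(metadata_path).set_index("record_id")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        fields = {}
        if meta is not None:
            if rec.id not in meta.index:
                raise MetadataError(
                    f"FASTA id {rec.id!r} absent from metadata table"
                )
            row = meta.loc[rec.id]
            fields = dict(
                tribe=row["tribe"], genus=row["genus"],
                species=row["species"], clade=row["clade"],
            )
        records.append(SequenceRecord(rec.id, str(rec.seq), **fields))
    if not records:
        raise AlignmentError(f"no FASTA records found in {fasta_path}")
    return AlignmentMatrix(records, coding_offset=coding_offset)


def write_alignment(matrix: AlignmentMatrix, fasta_path: str | Path, width: int = 60) -> None:
    """Write uppercase FASTA with a fixed line width (round-trip stable)."""
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.record_id, description="")
        for r in matrix.records
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_metadata(matrix: AlignmentMatrix, metadata_path: str | Path) -> None:
    rows = [
        [r.record_id, r.tribe, r.genus, r.species, r.clade]
        for r in matrix.records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        metadata_path, sep="\t", index=False
    )


def read_phenotypes(phenotype_path: str | Path) -> pd.DataFrame:
    """Phenotype TSV with columns ``accession`` and ``erucic_pct``."""
    df = pd.read_csv(phenotype_path, sep="\t", dtype={"accession": str})
    for col in ("accession", "erucic_pct"):
        if col not in df.columns:
            raise MetadataError(f"phenotype table lacks column {col!r}")
    df["erucic_pct"] = df["erucic_pct"].astype(float)
    return df[["accession", "erucic_pct"]]


# -- indel events ---------------------------------------------------------


@dataclass(frozen=True)
class IndelEvent:
    """A maximal gap run in one record.

    ``start_column``/``end_column`` are 1-based alignment columns;
    ``coding_start``/``coding_end`` restate the run in coding coordinates
    (the two systems differ by ``coding_offset - 1``).  Terminal runs touch
    the matrix edge and are treated as missing data, so their ``frameshift``
    flag is always False.
    """

    record_id: str
    start_column: int
    length: int
    terminal: bool
    coding_start: int
    frameshift: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "frameshift", (self.length % 3 != 0) and not self.terminal
        )

    @property
    def end_column(self) -> int:
        return self.start_column + self.length - 1

    @property
    def coding_end(self) -> int:
        return self.coding_start + self.length - 1


def detect_indel_events(matrix: AlignmentMatrix) -> list[IndelEvent]:
    """One event per maximal gap run per record, flagging terminal runs."""
    events: list[IndelEvent] = []
    n = matrix.n_columns
    for rec in matrix.records:
        seq = rec.sequence
        col = 1
        while col <= n:
            if seq[col - 1] != GAP:
                col += 1
                continue
            start = col
            while col <= n and seq[col - 1] == GAP:
                col += 1
            length = col - start
            terminal = start == 1 or start + length - 1 == n
            events.append(
                IndelEvent(
                    record_id=rec.record_id,
                    start_column=start,
                    length=length,
                    terminal=terminal,
                    coding_start=start + matrix.coding_offset - 1,
                )
            )
    return events


# -- conserved residues ---------------------------------------------------


def check_conserved_residues(
    matrix: AlignmentMatrix,
    residue_spec: Sequence[tuple[str, int]],
) -> pd.DataFrame:
    """Check reference-coordinate residues (e.g. the catalytic Cys223 and the
    conserved His/Cys set of the condensing enzyme) across all records.

    Returns a record x residue table of ``match``, ``mismatch(X)`` or
    ``not_assessable`` (codon not fully covered, or containing gap/N).
    """
    code = standard_code()
    spec = []
    for item in residue_spec:
        try:
            aa, pos = item
            aa = str(aa).upper()
            pos = int(pos)
        except (TypeError, ValueError) as exc:
            raise MetadataError(f"malformed residue spec entry {item!r}") from exc
        if len(aa) != 1 or aa not in "ACDEFGHIKLMNPQRSTVWY" or pos < 1:
            raise MetadataError(f"malformed residue spec entry {item!r}")
        spec.append((aa, pos))

    result: dict[str, list[str]] = {}
    labels = [f"{aa}{pos}" for aa, pos in spec]
    for rec in matrix.records:
        row = []
        for aa, pos in spec:
            codon = matrix.codon_of(rec.record_id, pos)
            if codon is None:
                row.append("not_assessable")
            else:
                observed = code.translate(codon)
                row.append("match" if observed == aa else f"mismatch({observed})")
        result[rec.record_id] = row
    return pd.DataFrame.from_dict(result, orient="index", columns=labels)


# -- trees ----------------------------------------------------------------


def read_tree(newick_path: str | Path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(newick_path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"cannot parse newick file {newick_path}: {exc}") from exc
    return tree


def parse_tree(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"cannot parse newick string: {exc}") from exc


def write_tree(tree: dendropy.Tree, newick_path: str | Path) -> None:
    Path(newick_path).write_text(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    )


def clade_members(tree: dendropy.Tree, node_label: str) -> set[str]:
    """Leaf taxon labels under the named internal node (or a leaf itself)."""
    for node in tree.preorder_node_iter():
        label = node.label or (node.taxon.label if node.taxon else None)
        if label == node_label:
            return {leaf.taxon.label for leaf in node.leaf_iter()}
    raise TreeError(f"no node labelled {node_label!r} in tree")
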