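"""Per-column classification of a coding alignment.

A column is *variable* when it carries >= 2 distinct non-gap, non-N states,
*parsimony-informative* when >= 2 states are each carried by >= 2 records,
and a *singleton* site when variable but not informative.  The silent /
replacement kind of a column is decided at codon level against the column's
majority codon (ties broken lexicographically, for determinism):

* polymorphic column — silent if every observed variant codon encodes the
  majority amino acid, replacement if every variant changes it, mixed
  otherwise;
* monomorphic column — silent if all three possible point changes at that
  position of the majority codon are synonymous (and non-stop), replacement
  if none is, mixed otherwise;
* not_assessable when no record offers a complete gap/N-free codon there.

Two gap policies govern the matrix-level counts. ``complete_deletion``
(default) drops every gap-containing column from the totals, the usual
convention when indels are excluded from the calculations.  The alternative
``indel_as_one_site`` additionally counts each internal indel event as one
polymorphic site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .codons import BASES, standard_code
from .errors import AlignmentError, ParameterError
from .seqio import GAP, MISSING, AlignmentMatrix, detect_indel_events

GAP_POLICIES = ("complete_deletion", "indel_as_one_site")

SITE_KINDS = ("silent", "replacement", "mixed", "not_assessable")


@dataclass
class SiteClassification:
    """Per-column flags plus matrix-level counts under a gap policy."""

    table: pd.DataFrame
    gap_policy: str
    n_columns: int
    n_indel_events: int

    def _counted(self) -> pd.DataFrame:
        # gap-containing columns are excluded from counts under both
        # policies; indel_as_one_site adds events back as single sites
        return self.table[~self.table["has_gap"]]

    @property
    def variable_count(self) -> int:
        count = int(self._counted()["is_variable"].sum())
        if self.gap_policy == "indel_as_one_site":
            count += self.n_indel_events
        return count

    @property
    def informative_count(self) -> int:
        return int(self._counted()["is_parsimony_informative"].sum())

    @property
    def singleton_count(self) -> int:
        return int(self._counted()["is_singleton"].sum())

    def silent_columns(self) -> list[int]:
        """1-based columns whose kind is silent (gap-free under the policy)."""
        t = self._counted()
        return t.loc[t["site_kind"] == "silent", "column"].tolist()


def _column_states(column_chars: str) -> Counter:
    return Counter(c for c in column_chars if c not in (GAP, MISSING))


def classify_sites(
    matrix: AlignmentMatrix, gap_policy: str = "complete_deletion"
) -> SiteClassification:
    """Classify every column of the matrix; see the module docstring."""
    if gap_policy not in GAP_POLICIES:
        raise ParameterError(f"unknown gap policy {gap_policy!r}")
    if len(matrix) == 0:
        raise AlignmentError("empty matrix")

    rows = []
    for col in range(1, matrix.n_columns + 1):
        chars = matrix.column(col)
        states = _column_states(chars)
        n_states = len(states)
        variable = n_states >= 2
        informative = sum(1 for c in states.values() if c >= 2) >= 2
        coding, codon_index, phase = matrix.column_to_coding(col)
        rows.append(
            {
                "column": col,
                "coding_position": coding,
                "codon_index": codon_index,
                "phase": phase,
                "has_gap": GAP in chars,
                "has_missing": MISSING in chars,
                "is_variable": variable,
                "is_parsimony_informative": variable and informative,
                "is_singleton": variable and not informative,
                "site_kind": site_kind(matrix, col),
            }
        )
    table = pd.DataFrame(rows)
    events = [e for e in detect_indel_events(matrix) if not e.terminal]
    return SiteClassification(
        table=table,
        gap_policy=gap_policy,
        n_columns=matrix.n_columns,
        n_indel_events=len(events),
    )


def majority_codon(matrix: AlignmentMatrix, codon_index: int) -> str | None:
    """Most frequent complete codon at an index; lexicographic tie-break."""
    codons = Counter()
    for rec in matrix.records:
        codon = matrix.codon_of(rec.record_id, codon_index)
        if codon is not None:
            codons[codon] += 1
    if not codons:
        return None
    top = max(codons.values())
    return min(c for c, n in codons.items() if n == top)


def site_kind(matrix: AlignmentMatrix, column: int) -> str:
    """Silent / replacement / mixed / not_assessable kind of one column."""
    matrix._check_column(column)
    code = standard_code()
    _, codon_index, phase = matrix.column_to_coding(column)
    if matrix.codon_columns(codon_index) is None:
        return "not_assessable"

    major = majority_codon(matrix, codon_index)
    if major is None:
        return "not_assessable"
    pos = phase - 1
    major_aa = code.translate(major)

    observed = {
        codon
        for rec in matrix.records
        if (codon := matrix.codon_of(rec.record_id, codon_index)) is not None
    }
    variants = {c for c in observed if c[pos] != major[pos]}

    if variants:
        # polymorphic at this column: compare each observed variant codon's
        # amino acid against the majority codon's
        outcomes = {
            "silent" if code.translate(v) == major_aa else "replacement"
            for v in variants
        }
        return outcomes.pop() if len(outcomes) == 1 else "mixed"

    # monomorphic: classify by the degeneracy of the majority codon here
    synonymous = 0
    for base in BASES:
        if base == major[pos]:
            continue
        mutant = major[:pos] + base + major[pos + 1 :]
        if not code.is_stop(mutant) and code.translate(mutant) == major_aa:
            synonymous += 1
    if synonymous == 3:
        return "silent"
    if synonymous == 0:
        return "replacement"
    return "mixed"


def percent_of_matrix(count: int, n_columns: int) -> float:
    """100 * count / n_columns, rounded half-up to two decimals."""
    if not 0 <= count <= n_columns:
        raise ParameterError(
            f"count {count} outside [0, {n_columns}]"
        )
    pct = Decimal(100) * Decimal(count) / Decimal(n_columns)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def site_report(matrix: AlignmentMatrix, gap_policy: str = "complete_deletion") -> pd.DataFrame:
    """The TSV-ready per-column report (flags + kinds + coordinates)."""
    return classify_sites(matrix, gap_policy).table
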