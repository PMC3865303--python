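"""Group-diagnostic character states and relaxed fixed differences.

A *diagnostic site* for a group is a column where every assessable (non-gap,
non-N) member carries one shared state that no assessable non-member
carries.  A *fixed difference* between two groups uses the relaxed frequency
rule: some state's frequency strictly exceeds ``f_high`` (default 0.70)
among the assessable members of one group while staying strictly below
``f_low`` (default 0.30) in the other.  Setting ``f_high = 1`` and
``f_low = 0`` degrades gracefully to the strict fixed-difference definition
(frequency exactly 1 vs exactly 0).

Frequencies are computed over assessable members only, and a column is
evaluated for fixed differences only when both groups retain at least two
assessable members there (partial sequences would otherwise dominate).
Gap characters are never diagnostic states by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .codons import BASES
from .errors import MetadataError, ParameterError
from . import diversity, sites
from .seqio import GAP, MISSING, AlignmentMatrix


@dataclass
class GroupingScheme:
    """Named, pairwise-disjoint sets of record ids; ungrouped ids are fine."""

    groups: dict[str, set[str]]

    def __post_init__(self):
        self.groups = {k: set(v) for k, v in self.groups.items()}
        seen: dict[str, str] = {}
        for label, members in self.groups.items():
            for rid in members:
                if rid in seen:
                    raise MetadataError(
                        f"record {rid!r} is in both {seen[rid]!r} and {label!r}"
                    )
                seen[rid] = label
        self._membership = seen

    @classmethod
    def from_metadata(cls, matrix: AlignmentMatrix, column: str = "clade") -> "GroupingScheme":
        """Build a scheme from a metadata field (records with empty values
        stay ungrouped)."""
        groups: dict[str, set[str]] = {}
        for rec in matrix.records:
            label = getattr(rec, column)
            if label:
                groups.setdefault(label, set()).add(rec.record_id)
        return cls(groups)

    def validate_against(self, matrix: AlignmentMatrix) -> None:
        known = set(matrix.ids)
        for label, members in self.groups.items():
            unknown = members - known
            if unknown:
                raise MetadataError(
                    f"group {label!r} references unknown ids: {sorted(unknown)}"
                )

    def members(self, label: str) -> set[str]:
        try:
            return self.groups[label]
        except KeyError:
            raise MetadataError(f"unknown group label {label!r}") from None

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def grouped_ids(self) -> set[str]:
        return set(self._membership)


@dataclass(frozen=True)
class DiagnosticSite:
    group_label: str
    column: int
    coding_position: int
    state: str


@dataclass(frozen=True)
class FixedDifference:
    column: int
    coding_position: int
    state: str
    freq_in_a: float
    freq_in_b: float


def _assessable_states(matrix: AlignmentMatrix, column: int, ids: Iterable[str]) -> Counter:
    col = column - 1
    return Counter(
        s
        for rid in ids
        if (s := matrix.record(rid).sequence[col]) not in (GAP, MISSING)
    )


def diagnostic_sites(
    matrix: AlignmentMatrix,
    scheme: GroupingScheme,
    focal_group: str,
    allow_gap_state: bool = False,
) -> list[DiagnosticSite]:
    """Columns carrying a state unique to (and uniform within) the focal group.

    Non-members are the records of the scheme's other groups; a column with
    zero assessable focal members contributes nothing.
    """
    scheme.validate_against(matrix)
    members = scheme.members(focal_group)
    others = scheme.grouped_ids() - members
    if not members:
        raise ParameterError(f"focal group {focal_group!r} is empty")
    if not others:
        raise ParameterError("scheme has no non-members to compare against")
    banned = () if allow_gap_state else (GAP, MISSING)
    out = []
    for col in range(1, matrix.n_columns + 1):
        member_states = _assessable_states(matrix, col, members)
        if len(member_states) != 1:
            continue
        (state,) = member_states
        if state in banned:
            continue
        other_states = _assessable_states(matrix, col, others)
        if state in other_states:
            continue
        coding, _, _ = matrix.column_to_coding(col)
        out.append(DiagnosticSite(focal_group, col, coding, state))
    return out


def fixed_differences(
    matrix: AlignmentMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    f_high: float = 0.70,
    f_low: float = 0.30,
    min_assessable: int = 2,
) -> list[FixedDifference]:
    """Relaxed fixed differences between two groups of record ids.

    A state qualifies at a column when its frequency is > ``f_high`` among
    one group's assessable members and < ``f_low`` in the other (strict
    inequalities; the boundary cases ``f_high = 1`` / ``f_low = 0`` mean
    frequency exactly 1 / exactly 0).  Reported frequencies are always
    (freq in A, freq in B) whichever direction qualified.
    """
    if f_low >= f_high:
        raise ParameterError(f"f_low ({f_low}) must be < f_high ({f_high})")
    a, b = list(group_a), list(group_b)
    if set(a) & set(b):
        raise ParameterError("groups must be disjoint")
    out = []
    for col in range(1, matrix.n_columns + 1):
        ca = _assessable_states(matrix, col, a)
        cb = _assessable_states(matrix, col, b)
        na, nb = sum(ca.values()), sum(cb.values())
        if na < min_assessable or nb < min_assessable:
            continue
        coding, _, _ = matrix.column_to_coding(col)
        for state in BASES:
            fa = ca.get(state, 0) / na
            fb = cb.get(state, 0) / nb
            high_a = fa > f_high or (f_high == 1 and fa == 1)
            low_b = fb < f_low or (f_low == 0 and fb == 0)
            high_b = fb > f_high or (f_high == 1 and fb == 1)
            low_a = fa < f_low or (f_low == 0 and fa == 0)
            if (high_a and low_b) or (high_b and low_a):
                out.append(FixedDifference(col, coding, state, fa, fb))
    return out


@dataclass
class GroupReport:
    """Table-shaped summary: within-group diversity on the diagonal,
    (pi_between, dxy) off it, plus per-group polymorphic-site counts."""

    diversity_matrix: pd.DataFrame  # strings "pi" / "pi_between|dxy"
    pi_within: pd.Series
    pi_between: pd.DataFrame
    dxy: pd.DataFrame
    polymorphic: pd.DataFrame  # columns: group, polymorphic_sites, percent


def group_report(matrix: AlignmentMatrix, scheme: GroupingScheme) -> GroupReport:
    scheme.validate_against(matrix)
    labels = scheme.labels
    if len(labels) < 2:
        raise ParameterError("group report needs >= 2 groups")

    pi_within = {}
    poly_rows = []
    for label in labels:
        members = sorted(scheme.members(label))
        if len(members) >= 2:
            pi_within[label] = diversity.nucleotide_diversity(matrix, members).pi
            sub = AlignmentMatrix(
                matrix.subset(members), coding_offset=matrix.coding_offset
            )
            n_poly = sites.classify_sites(sub).variable_count
        else:
            pi_within[label] = float("nan")
            n_poly = 0
        poly_rows.append(
            {
                "group": label,
                "polymorphic_sites": n_poly,
                "percent": sites.percent_of_matrix(n_poly, matrix.n_columns),
            }
        )

    pi_between = pd.DataFrame(index=labels, columns=labels, dtype=float)
    dxy = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            res = diversity.divergence(
                matrix, sorted(scheme.members(la)), sorted(scheme.members(lb))
            )
            pi_between.loc[la, lb] = pi_between.loc[lb, la] = res.pi_between
            dxy.loc[la, lb] = dxy.loc[lb, la] = res.dxy

    cells = pd.DataFrame(index=labels, columns=labels, dtype=object)
    for la in labels:
        for lb in labels:
            if la == lb:
                cells.loc[la, lb] = f"{pi_within[la]:.4f}"
            else:
                cells.loc[la, lb] = (
                    f"{pi_between.loc[la, lb]:.4f}|{dxy.loc[la, lb]:.4f}"
                )
    return GroupReport(
        diversity_matrix=cells,
        pi_within=pd.Series(pi_within),
        pi_between=pi_between,
        dxy=dxy,
        polymorphic=pd.DataFrame(poly_rows),
    )
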