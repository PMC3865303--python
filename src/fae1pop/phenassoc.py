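"""Phenotype categorization and genotype-phenotype association.

The phenotype is the erucic-acid percentage of seed fatty acids.  Observed
gaps in its distribution define five operational categories — low (L),
three intermediates (M1-M3) and high (H) — with cut points at 10.5, 20.5,
31.11 and 41.1; each cut point belongs to the upper category (half-open
intervals).  The boundaries are configuration with these printed defaults,
never auto-detected: the defining gaps are biological, not the widest gaps
in the data.

Association is measured with a Hudson-style Fst built from nucleotide
diversities, Fst = 1 - Hw/Hb, where Hw is the mean pairwise p-distance
pooled over all within-category pairs and Hb the mean over all
between-category pairs.  Significance comes from a label permutation test
that shuffles category labels among records while preserving category
sizes; the reported p-value is (#{Fst_perm >= Fst_obs} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .diversity import encode
from .seqio import AlignmentMatrix, SequenceRecord

DEFAULT_CUTS = (10.5, 20.5, 31.11, 41.1)
DEFAULT_LABELS = ("L", "M1", "M2", "M3", "H")


@dataclass(frozen=True)
class CategoryBoundaries:
    """Ascending cut points; len(labels) must equal len(cuts) + 1."""

    cuts: tuple[float, ...] = DEFAULT_CUTS
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self):
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ParameterError("cut points must be strictly increasing")
        if len(self.labels) != len(self.cuts) + 1:
            raise ParameterError("need exactly one more label than cut points")


def categorize(erucic_pct: float, boundaries: CategoryBoundaries | None = None) -> str:
    """Category of an erucic-acid percentage; cut points go to the upper
    category (e.g. 10.5 -> M1, 41.1 -> H at the defaults)."""
    if boundaries is None:
        boundaries = CategoryBoundaries()
    if not 0 <= erucic_pct <= 100:
        raise ParameterError(f"erucic_pct {erucic_pct} outside [0, 100]")
    return boundaries.labels[bisect_right(boundaries.cuts, erucic_pct)]


def load_erucic_table() -> pd.DataFrame:
    """The published per-accession erucic-acid contents with their printed
    category labels (accession, erucic_pct, category)."""
    with resources.files("fae1pop.data").joinpath("erucic_contents.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"accession": str, "category": str})


# -- Fst ------------------------------------------------------------------


@dataclass(frozen=True)
class FstResult:
    fst: float
    hw: float
    hb: float
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def _pair_distances(matrix: AlignmentMatrix, ids: Sequence[str]) -> np.ndarray:
    """Condensed per-pair p-distance array in combinations(ids, 2) order
    (pairwise deletion per pair)."""
    enc = encode([matrix.record(i).sequence for i in ids])
    n = len(ids)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i, j in itertools.combinations(range(n), 2):
        usable = (enc[i] < 4) & (enc[j] < 4)
        m = int(usable.sum())
        if m == 0:
            raise DegenerateDataError(
                f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
            )
        out[k] = float((enc[i][usable] != enc[j][usable]).sum()) / m
        k += 1
    return out


def _fst_from_labels(dist: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    n = len(labels)
    ii, jj = np.triu_indices(n, k=1)
    same = labels[ii] == labels[jj]
    if same.all() or not same.any():
        raise DegenerateDataError("need both within- and between-category pairs")
    hw = float(dist[same].mean())
    hb = float(dist[~same].mean())
    if hb == 0:
        raise DegenerateDataError("Hb = 0: Fst undefined on degenerate data")
    return 1.0 - hw / hb, hw, hb


def _partition_arrays(
    matrix: AlignmentMatrix, partition: Mapping[str, Iterable[str]]
) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    labels: list[str] = []
    for cat in sorted(partition):
        members = sorted(partition[cat])
        ids.extend(members)
        labels.extend([cat] * len(members))
    if len(set(ids)) != len(ids):
        raise ParameterError("categories must be disjoint")
    cats = [c for c in sorted(partition) if len(list(partition[c])) >= 2]
    if len(cats) < 2:
        raise ParameterError("need >= 2 categories with >= 2 members each")
    return ids, np.asarray(labels)


def hudson_fst(
    matrix: AlignmentMatrix, partition: Mapping[str, Iterable[str]]
) -> FstResult:
    """Fst = 1 - Hw/Hb over a category partition of record ids.

    ``partition`` with two entries gives the pairwise mode; more entries
    give the overall mode (all within pairs pooled vs all between pairs
    pooled, every cross-category pair counted once).
    """
    ids, labels = _partition_arrays(matrix, partition)
    dist = _pair_distances(matrix, ids)
    fst, hw, hb = _fst_from_labels(dist, labels)
    return FstResult(fst=fst, hw=hw, hb=hb)


def permutation_test(
    matrix: AlignmentMatrix,
    partition: Mapping[str, Iterable[str]],
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> FstResult:
    """Permutation null for the observed Fst (labels shuffled among records,
    category sizes preserved); add-one p-value, fully seeded."""
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    ids, labels = _partition_arrays(matrix, partition)
    dist = _pair_distances(matrix, ids)
    fst_obs, hw, hb = _fst_from_labels(dist, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        try:
            fst_perm, _, _ = _fst_from_labels(dist, perm)
        except DegenerateDataError:
            fst_perm = 0.0
        if fst_perm >= fst_obs:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return FstResult(
        fst=fst_obs, hw=hw, hb=hb, p_value=p,
        n_permutations=n_permutations, seed=seed,
    )


# -- report ---------------------------------------------------------------


@dataclass
class AssociationReport:
    assignments: pd.DataFrame  # accession, erucic_pct, category
    dropped: list[str]
    pairwise_fst: pd.DataFrame | None
    overall: FstResult | None


def association_report(
    matrix: AlignmentMatrix,
    phenotypes: pd.DataFrame,
    boundaries: CategoryBoundaries | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> AssociationReport:
    """Categorize phenotypes, map them onto sequence records, and compute
    the pairwise and overall Fst (with permutation p for the overall).

    Accessions without a sequence record are listed as dropped, not fatal.
    With fewer than two usable categories the Fst block is marked not
    applicable (None).
    """
    if boundaries is None:
        boundaries = CategoryBoundaries()
    rows = []
    dropped = []
    known = set(matrix.ids)
    for _, row in phenotypes.iterrows():
        cat = categorize(float(row["erucic_pct"]), boundaries)
        if row["accession"] not in known:
            dropped.append(str(row["accession"]))
            continue
        rows.append(
            {
                "accession": row["accession"],
                "erucic_pct": float(row["erucic_pct"]),
                "category": cat,
            }
        )
    assignments = pd.DataFrame(rows, columns=["accession", "erucic_pct", "category"])

    partition: dict[str, set[str]] = {}
    for _, row in assignments.iterrows():
        partition.setdefault(row["category"], set()).add(row["accession"])
    usable = [c for c in boundaries.labels if len(partition.get(c, ())) >= 2]

    pairwise = None
    overall = None
    if len(usable) >= 2:
        pairwise = pd.DataFrame(index=usable, columns=usable, dtype=float)
        for i, ca in enumerate(usable):
            for cb in usable[i + 1 :]:
                res = hudson_fst(matrix, {ca: partition[ca], cb: partition[cb]})
                pairwise.loc[ca, cb] = pairwise.loc[cb, ca] = res.fst
        overall = permutation_test(
            matrix,
            {c: partition[c] for c in usable},
            n_permutations=n_permutations,
            seed=seed,
        )
    return AssociationReport(
        assignments=assignments,
        dropped=dropped,
        pairwise_fst=pairwise,
        overall=overall,
    )
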