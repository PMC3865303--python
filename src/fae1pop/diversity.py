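"""Pairwise distances, nucleotide diversity, divergence, Ka/Ks and
sliding-window silent-site diversity.

Estimators
----------
* p-distance: proportion of differing sites among sites where neither
  sequence carries a gap or N.
* pi (nucleotide diversity): mean p-distance over all unordered pairs of a
  subset, computed on the complete-deletion site set shared by the whole
  subset (no n/(n-1) correction; equal haplotype weights).
* Dxy: mean cross-group p-distance, Jukes-Cantor corrected,
  d = -(3/4) ln(1 - (4/3) p), defined for p < 3/4.
* Ka/Ks: Nei & Gojobori's unweighted-pathway method.  Per codon, each
  position contributes a synonymous-site fraction equal to the proportion
  of its possible point changes (stop-codon changes excluded from the
  tally) that preserve the amino acid; observed codon differences are
  resolved over all minimal substitution pathways that avoid stop codons,
  weighted equally.  Per-pair proportions pN, pS are averaged over pairs
  and Jukes-Cantor corrected into Ka and Ks.
* Sliding windows: windows of a fixed number of *silent* columns (default
  25), advanced by a fixed number of silent columns (default 10); pi is
  computed within each window over its silent columns only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codons import BASES, standard_code
from .errors import (
    AlignmentError,
    CorrectionDomainError,
    DegenerateDataError,
    ParameterError,
)
from .seqio import GAP, MISSING, AlignmentMatrix, SequenceRecord
from .sites import classify_sites

# integer encoding for vectorised comparisons
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE[MISSING] = 4
_CODE[GAP] = 5


def encode(sequences: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 array."""
    arr = np.frombuffer(
        "".join(sequences).encode("ascii"), dtype=np.uint8
    ).reshape(len(sequences), -1)
    out = np.empty_like(arr)
    for char, val in _CODE.items():
        out[arr == ord(char)] = val
    return out


def _seqs(items: Iterable[SequenceRecord | str]) -> list[str]:
    return [i.sequence if isinstance(i, SequenceRecord) else i for i in items]


# -- p-distance and pi ----------------------------------------------------


def p_distance(record_a: SequenceRecord | str, record_b: SequenceRecord | str) -> float:
    """Proportion of differing sites, gap/N sites in either record excluded."""
    a, b = _seqs([record_a, record_b])
    if len(a) != len(b):
        raise AlignmentError("sequences have unequal lengths")
    ea, eb = encode([a, b])
    usable = (ea < 4) & (eb < 4)
    n = int(usable.sum())
    if n == 0:
        raise DegenerateDataError("no comparable sites between the two sequences")
    return float((ea[usable] != eb[usable]).sum() / n)


@dataclass(frozen=True)
class DiversityResult:
    pi: float
    n_sequences: int
    n_pairs: int
    n_sites_used: int


def _complete_sites(enc: np.ndarray) -> np.ndarray:
    """Boolean mask of columns free of gap/N in every row (complete deletion)."""
    return (enc < 4).all(axis=0)


def nucleotide_diversity(
    matrix: AlignmentMatrix, subset: Iterable[str] | None = None
) -> DiversityResult:
    """Mean pairwise p-distance within a subset (default: all records)."""
    ids = list(subset) if subset is not None else matrix.ids
    if len(ids) < 2:
        raise ParameterError("nucleotide diversity needs >= 2 sequences")
    enc = encode(_seqs(matrix.subset(ids)))
    mask = _complete_sites(enc)
    n_sites = int(mask.sum())
    if n_sites == 0:
        raise DegenerateDataError("complete-deletion site set is empty")
    sub = enc[:, mask]
    n = len(ids)
    total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        total += float((sub[i] != sub[j]).sum()) / n_sites
    n_pairs = n * (n - 1) // 2
    return DiversityResult(
        pi=total / n_pairs, n_sequences=n, n_pairs=n_pairs, n_sites_used=n_sites
    )


# -- divergence -----------------------------------------------------------


def jukes_cantor(p: float) -> float:
    """JC69 distance correction; strictly increasing on [0, 3/4)."""
    if p < 0:
        raise ParameterError("p-distance cannot be negative")
    if p >= 0.75:
        raise CorrectionDomainError(
            f"Jukes-Cantor correction undefined for p = {p:.4f} >= 0.75"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class DivergenceResult:
    pi_between: float
    dxy: float
    n_pairs: int
    n_sites_used: int


def divergence(
    matrix: AlignmentMatrix, group_a: Iterable[str], group_b: Iterable[str]
) -> DivergenceResult:
    """Mean cross-group p-distance and its JC-corrected divergence Dxy."""
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ParameterError("both groups must be non-empty")
    if set(a) & set(b):
        raise ParameterError("groups must be disjoint")
    enc = encode(_seqs(matrix.subset(a + b)))
    mask = _complete_sites(enc)
    n_sites = int(mask.sum())
    if n_sites == 0:
        raise DegenerateDataError("complete-deletion site set is empty")
    sub = enc[:, mask]
    na = len(a)
    total = 0.0
    for i in range(na):
        for j in range(na, na + len(b)):
            total += float((sub[i] != sub[j]).sum()) / n_sites
    n_pairs = na * len(b)
    pi_between = total / n_pairs
    return DivergenceResult(
        pi_between=pi_between,
        dxy=jukes_cantor(pi_between),
        n_pairs=n_pairs,
        n_sites_used=n_sites,
    )


# -- Nei-Gojobori Ka/Ks ---------------------------------------------------


@lru_cache(maxsize=1)
def _ng86_site_counts() -> dict[str, float]:
    """Synonymous-site count per sense codon (stop changes excluded)."""
    code = standard_code()
    counts = {}
    for codon in code.sense_codons:
        s = 0.0
        for pos in range(3):
            syn, possible = 0, 0
            for base in BASES:
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if code.is_stop(mutant):
                    continue
                possible += 1
                if code.translate(mutant) == code.translate(codon):
                    syn += 1
            if possible:
                s += syn / possible
        counts[codon] = s
    return counts


@lru_cache(maxsize=None)
def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all equally-weighted minimal pathways avoiding stops.

    Falls back to all pathways if every minimal pathway passes through a
    stop codon (possible only for 2- and 3-fold differences).
    """
    code = standard_code()
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt) and not allow_stops:
                return None
            if code.is_stop(current) or code.is_stop(nxt):
                nd += 1.0  # stop-involving step counted as nonsynonymous
            elif code.translate(current) == code.translate(nxt):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    for allow_stops in (False, True):
        results = [
            r
            for order in itertools.permutations(diff_pos)
            if (r := walk(order, allow_stops)) is not None
        ]
        if results:
            sd = sum(r[0] for r in results) / len(results)
            nd = sum(r[1] for r in results) / len(results)
            return sd, nd
    raise AssertionError("unreachable")


@lru_cache(maxsize=1)
def _ng86_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised lookup tables indexed by codon integer (base-4).

    Returns (S_sites[64], valid[64], Sd[64, 64], Nd[64, 64]); entries
    involving stop codons are invalid.
    """
    code = standard_code()
    site_counts = _ng86_site_counts()
    idx = {a + b + c: 16 * _CODE[a] + 4 * _CODE[b] + _CODE[c]
           for a in BASES for b in BASES for c in BASES}
    s_sites = np.full(64, np.nan)
    valid = np.zeros(64, dtype=bool)
    for codon in code.sense_codons:
        s_sites[idx[codon]] = site_counts[codon]
        valid[idx[codon]] = True
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for ca in code.sense_codons:
        for cb in code.sense_codons:
            s, n = _pathway_differences(ca, cb)
            sd[idx[ca], idx[cb]] = s
            nd[idx[ca], idx[cb]] = n
    return s_sites, valid, sd, nd


@dataclass(frozen=True)
class KaKsResult:
    N_sites: float
    S_sites: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    ratio: float | None
    n_codons_used: int
    n_pairs: int


def _codon_array(matrix: AlignmentMatrix, ids: Sequence[str]) -> tuple[np.ndarray, int]:
    """Codon-integer array (n, n_codons) over the complete-deletion codon set."""
    first, last = matrix.codon_range()
    enc = encode(_seqs(matrix.subset(ids)))
    cols = []
    for ci in range(first, last + 1):
        c1, _, c3 = matrix.codon_columns(ci)  # type: ignore[misc]
        cols.append((c1 - 1, c3))
    codon_ints = []
    for start, stop in cols:
        block = enc[:, start:stop]
        if (block >= 4).any():
            continue  # gap or N in some record: codon dropped for all
        codon_ints.append(16 * block[:, 0] + 4 * block[:, 1] + block[:, 2])
    if not codon_ints:
        raise DegenerateDataError("no complete shared codon across the subset")
    arr = np.stack(codon_ints, axis=1).astype(np.int64)
    return arr, arr.shape[1]


def ka_ks(matrix: AlignmentMatrix, subset: Iterable[str] | None = None) -> KaKsResult:
    """Nei-Gojobori Ka/Ks averaged over all sequence pairs of a subset."""
    ids = list(subset) if subset is not None else matrix.ids
    if len(ids) < 2:
        raise ParameterError("Ka/Ks needs >= 2 sequences")
    s_sites, valid, sd_tab, nd_tab = _ng86_tables()
    codons, n_codons = _codon_array(matrix, ids)
    if not valid[codons].all():
        bad = np.argwhere(~valid[codons])
        i, j = bad[0]
        raise AlignmentError(
            f"stop codon in record {ids[int(i)]!r} at shared codon #{int(j)}"
        )
    per_seq_s = s_sites[codons].sum(axis=1)

    n = len(ids)
    ps_vals, pn_vals = [], []
    s_pair_total = n_pair_total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        s_pair = (per_seq_s[i] + per_seq_s[j]) / 2.0
        n_pair = 3.0 * n_codons - s_pair
        sd = float(sd_tab[codons[i], codons[j]].sum())
        nd = float(nd_tab[codons[i], codons[j]].sum())
        ps_vals.append(sd / s_pair if s_pair > 0 else 0.0)
        pn_vals.append(nd / n_pair if n_pair > 0 else 0.0)
        s_pair_total += s_pair
        n_pair_total += n_pair

    n_pairs = len(ps_vals)
    pS = float(np.mean(ps_vals))
    pN = float(np.mean(pn_vals))
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    ratio = Ka / Ks if Ks > 0 else None
    return KaKsResult(
        N_sites=n_pair_total / n_pairs,
        S_sites=s_pair_total / n_pairs,
        pN=pN,
        pS=pS,
        Ka=Ka,
        Ks=Ks,
        ratio=ratio,
        n_codons_used=n_codons,
        n_pairs=n_pairs,
    )


# -- sliding windows ------------------------------------------------------


@dataclass(frozen=True)
class WindowProfile:
    """Sliding windows over silent columns: one row per full window."""

    table: pd.DataFrame
    window_size: int
    step: int
    n_silent_columns: int


def _window_pi(enc: np.ndarray, cols0: np.ndarray) -> float:
    """Mean pairwise p-distance over the given 0-based columns."""
    sub = enc[:, cols0]
    n = sub.shape[0]
    total = 0.0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        usable = (sub[i] < 4) & (sub[j] < 4)
        m = int(usable.sum())
        if m == 0:
            continue
        total += float((sub[i][usable] != sub[j][usable]).sum()) / m
        pairs += 1
    if pairs == 0:
        raise DegenerateDataError("no comparable pairs in window")
    return total / pairs


def sliding_window_silent(
    matrix: AlignmentMatrix,
    window_size: int = 25,
    step: int = 10,
    classification=None,
) -> WindowProfile:
    """Diversity profile over silent columns in fixed-size silent windows.

    Window *k* (1-based) starts at silent ordinal ``1 + (k-1) * step`` and
    spans ``window_size`` consecutive silent columns; a trailing partial
    window is dropped.
    """
    if window_size < 1 or step < 1:
        raise ParameterError("window_size and step must be positive")
    if classification is None:
        classification = classify_sites(matrix)
    silent_cols = classification.silent_columns()
    n_silent = len(silent_cols)
    if n_silent < window_size:
        raise DegenerateDataError(
            f"only {n_silent} silent columns; need >= {window_size}"
        )
    enc = encode(_seqs(matrix.records))
    rows = []
    k = 0
    while True:
        start = k * step
        if start + window_size > n_silent:
            break
        cols = silent_cols[start : start + window_size]
        cols0 = np.asarray(cols) - 1
        rows.append(
            {
                "window_index": k + 1,
                "first_silent_ordinal": start + 1,
                "col_start": cols[0],
                "col_end": cols[-1],
                "pi_silent": _window_pi(enc, cols0),
            }
        )
        k += 1
    return WindowProfile(
        table=pd.DataFrame(rows),
        window_size=window_size,
        step=step,
        n_silent_columns=n_silent,
    )


def pairwise_distance_matrix(matrix: AlignmentMatrix) -> pd.DataFrame:
    """All-pairs p-distance table (pairwise deletion), for reporting."""
    enc = encode(_seqs(matrix.records))
    n = len(matrix)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        usable = (enc[i] < 4) & (enc[j] < 4)
        m = int(usable.sum())
        d = float((enc[i][usable] != enc[j][usable]).sum()) / m if m else np.nan
        out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=matrix.ids, columns=matrix.ids)
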