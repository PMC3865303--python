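"""Synthetic coding alignments, trees and phenotypes with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
~900-column in-frame coding alignment over ~60 taxa falling into a handful
of deeply diverged clades, evolved under purifying selection (omega << 1)
with a transition bias, carrying occasional indels, clade-diagnostic
substitutions that can be injected on demand (with an edit ledger usable as
oracle ground truth), and clade-correlated erucic-acid phenotypes whose
means sit far from every category boundary.

Sequence evolution runs at codon granularity with an explicit
accept/reject rule rather than a full rate-matrix exponential: candidate
point mutations arrive along each branch as a Poisson process (branch
lengths are expected candidate substitutions per site), targets are
weighted ``kappa``:1 for transitions vs transversions, mutations creating
stop codons are rejected outright, synonymous changes are always accepted
and nonsynonymous ones with probability ``omega``.  Everything is driven by
one integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .codons import BASES, is_transition, standard_code
from .errors import ParameterError
from .seqio import (
    GAP,
    AlignmentMatrix,
    SequenceRecord,
    clade_members,
    parse_tree,
    tree_to_newick,
    write_alignment,
    write_metadata,
)

# -- configuration --------------------------------------------------------


@dataclass
class SynthConfig:
    """Study-scale defaults: 60 taxa in 5 clades (two large, three small),
    300 codons, purifying selection at omega = 0.1, kappa = 2, shallow
    within-clade branches with deep clade stems, two token indels, and
    clade phenotype means of 47 / 3 / 15 / 25 / 35 % erucic acid (sd 1),
    i.e. one high and one low clade plus three intermediates."""

    n_codons: int = 300
    clade_sizes: dict[str, int] = field(
        default_factory=lambda: {"I": 22, "II": 20, "III": 6, "IV": 6, "V": 6}
    )
    branch_scale: float = 1.0
    within_branch: float = 0.03  # mean within-clade branch length
    stem_length: float = 0.25  # clade stem length
    kappa: float = 2.0
    omega: float = 0.1
    coding_offset: int = 433  # column 1 in phase 1, near the study window
    injected_sites: tuple = ()  # (clade, codon_index, target_codon | None)
    indel_spec: tuple = (("II_t01", 82, 1), ("V_t01", 269, 3))
    phenotype_spec: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (47.0, 1.0),
            "II": (3.0, 1.0),
            "III": (15.0, 1.0),
            "IV": (25.0, 1.0),
            "V": (35.0, 1.0),
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.omega < 0:
            raise ParameterError("omega must be >= 0")
        if self.n_codons < 1:
            raise ParameterError("n_codons must be positive")

    @property
    def n_taxa(self) -> int:
        return sum(self.clade_sizes.values())


# -- trees ----------------------------------------------------------------


def _join_newick(
    parts: list[str], rng: np.random.Generator, mean_branch: float, label_start: int
) -> tuple[str, int]:
    """Random sequential joins of subtree strings; returns (newick_core, next_label)."""
    parts = list(parts)
    k = label_start
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(int(j))
        a = parts.pop(int(i))
        length = rng.exponential(mean_branch)
        parts.append(f"({a},{b})n{k}:{length:.6f}")
        k += 1
    return parts[0], k


def simulate_tree(
    n_taxa: int, seed: int, mean_branch: float = 0.05, prefix: str = "t"
) -> dendropy.Tree:
    """Random rooted binary tree by sequential joins with exponential branch
    lengths; leaves ``t01..``, internal nodes ``n1..``, reproducible."""
    if n_taxa < 3:
        raise ParameterError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_taxa)))
    parts = [
        f"{prefix}{i:0{width}d}:{rng.exponential(mean_branch):.6f}"
        for i in range(1, n_taxa + 1)
    ]
    core, _ = _join_newick(parts, rng, mean_branch, label_start=1)
    # strip the root's own edge length; the last join is the root
    core = core.rsplit(":", 1)[0]
    return parse_tree(core + ";")


def simulate_clade_tree(config: SynthConfig, rng: np.random.Generator) -> dendropy.Tree:
    """Clade-structured tree: one random subtree per clade (labelled with the
    clade name at its root) attached to the root by a long stem."""
    clade_parts = []
    next_label = 1
    for clade, size in config.clade_sizes.items():
        if size < 1:
            raise ParameterError(f"clade {clade!r} has no taxa")
        width = max(2, len(str(size)))
        leaves = [
            f"{clade}_t{i:0{width}d}:"
            f"{rng.exponential(config.within_branch * config.branch_scale):.6f}"
            for i in range(1, size + 1)
        ]
        stem = config.stem_length * config.branch_scale
        if size == 1:
            sub = leaves[0].rsplit(":", 1)[0] + f":{stem:.6f}"
        else:
            core, next_label = _join_newick(
                leaves, rng, config.within_branch * config.branch_scale, next_label
            )
            # drop the root join's edge length and relabel it with the clade name
            sub = core.rsplit(":", 1)[0]
            sub = sub[: sub.rfind(")") + 1] + clade + f":{stem:.6f}"
        clade_parts.append(sub)
    return parse_tree("(" + ",".join(clade_parts) + ")root;")


def clade_map_from_tree(tree: dendropy.Tree, clade_labels: Sequence[str]) -> dict[str, str]:
    """leaf name -> clade label, resolved through labelled internal nodes."""
    out: dict[str, str] = {}
    for label in clade_labels:
        for leaf in clade_members(tree, label):
            out[leaf] = label
    return out


# -- sequence evolution ---------------------------------------------------


def _mutate_branch(
    codons: list[str],
    branch_length: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> list[str]:
    code = standard_code()
    n_sites = 3 * len(codons)
    n_events = rng.poisson(branch_length * n_sites)
    codons = list(codons)
    for _ in range(n_events):
        pos = int(rng.integers(n_sites))
        ci, phase = divmod(pos, 3)
        codon = codons[ci]
        current = codon[phase]
        targets = [b for b in BASES if b != current]
        weights = np.array(
            [config.kappa if is_transition(current, b) else 1.0 for b in targets]
        )
        target = targets[int(rng.choice(3, p=weights / weights.sum()))]
        mutant = codon[:phase] + target + codon[phase + 1 :]
        if code.is_stop(mutant):
            continue
        if code.translate(mutant) != code.translate(codon):
            if rng.random() >= config.omega:
                continue
        codons[ci] = mutant
    return codons


def evolve_alignment(
    tree: dendropy.Tree,
    config: SynthConfig,
    seed: int | None = None,
    clade_map: Mapping[str, str] | None = None,
) -> AlignmentMatrix:
    """Simulate codon sequences down the tree; leaves become the records.

    The root sequence is drawn uniformly from sense codons.  Metadata is
    synthetic: clade from ``clade_map`` (tribe mirrors it), genus/species
    from the leaf name.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    code = standard_code()
    root = [
        code.sense_codons[int(i)]
        for i in rng.integers(len(code.sense_codons), size=config.n_codons)
    ]
    for codon in root:
        if code.is_stop(codon):
            raise ParameterError(f"invalid root codon {codon}")
    clade_map = dict(clade_map or {})

    seqs: dict[str, list[str]] = {}

    def descend(node, codons):
        for child in node.child_nodes():
            length = (child.edge.length or 0.0)
            evolved = _mutate_branch(codons, length, config, rng)
            if child.is_leaf():
                seqs[child.taxon.label] = evolved
            else:
                descend(child, evolved)

    descend(tree.seed_node, root)
    records = []
    for leaf in sorted(seqs):
        clade = clade_map.get(leaf, "")
        records.append(
            SequenceRecord(
                record_id=leaf,
                sequence="".join(seqs[leaf]),
                species=leaf,
                genus="Synthea",
                tribe=f"tribe_{clade}" if clade else "",
                clade=clade,
            )
        )
    return AlignmentMatrix(records, coding_offset=config.coding_offset)


# -- injected clade mutations --------------------------------------------


def inject_clade_mutations(
    matrix: AlignmentMatrix,
    clade_map: Mapping[str, str],
    injected_sites: Sequence[tuple],
) -> tuple[AlignmentMatrix, list[dict]]:
    """Force a target codon onto every member of a clade; return the edited
    matrix and an edit ledger usable as oracle ground truth.

    Each entry of ``injected_sites`` is ``(clade, codon_index, target)``;
    with ``target=None`` a sense codon is chosen that differs from the
    clade's current majority codon at exactly one position, using a base
    absent from that column across the whole matrix (so the edited column
    is a guaranteed strict fixed difference against every other group).
    """
    code = standard_code()
    seqs = {r.record_id: list(r.sequence) for r in matrix.records}
    ledger: list[dict] = []
    for clade, codon_index, target in injected_sites:
        members = sorted(l for l, c in clade_map.items() if c == clade)
        if not members:
            raise ParameterError(f"clade {clade!r} has no members")
        cols = matrix.codon_columns(codon_index)
        if cols is None:
            raise ParameterError(f"codon {codon_index} not covered by the matrix")
        member_codons = [
            matrix.codon_of(m, codon_index) for m in members
        ]
        known = [c for c in member_codons if c is not None]
        if not known:
            raise ParameterError(
                f"clade {clade!r} has no assessable codon at index {codon_index}"
            )
        consensus = max(sorted(set(known)), key=known.count)
        guaranteed = False
        if target is None:
            target = _novel_target(matrix, cols, consensus, code)
            if target is None:
                raise ParameterError(
                    f"no novel single-base target at codon {codon_index}"
                )
            guaranteed = True
        elif code.is_stop(target):
            raise ParameterError(f"target codon {target} is a stop codon")
        changed_cols = [
            cols[k] for k in range(3) if target[k] != consensus[k]
        ]
        for m in members:
            s = seqs[m]
            for k in range(3):
                s[cols[k] - 1] = target[k]
        ledger.append(
            {
                "clade": clade,
                "codon_index": codon_index,
                "target_codon": target,
                "previous_consensus": consensus,
                "columns": changed_cols,
                "novel_state": guaranteed,
            }
        )
    records = [
        SequenceRecord(
            record_id=r.record_id,
            sequence="".join(seqs[r.record_id]),
            species=r.species,
            genus=r.genus,
            tribe=r.tribe,
            clade=r.clade,
        )
        for r in matrix.records
    ]
    return AlignmentMatrix(records, coding_offset=matrix.coding_offset), ledger


def _novel_target(matrix, cols, consensus, code) -> str | None:
    for k in range(3):
        column_states = set(matrix.column(cols[k]))
        for base in BASES:
            if base in column_states:
                continue
            mutant = consensus[:k] + base + consensus[k + 1 :]
            if not code.is_stop(mutant):
                return mutant
    return None


# -- indels and phenotypes ------------------------------------------------


def apply_indels(
    matrix: AlignmentMatrix, indel_spec: Sequence[tuple[str, int, int]]
) -> AlignmentMatrix:
    """Overwrite ``length`` columns with gaps from ``start_column`` in the
    named record (a deletion relative to the other records)."""
    seqs = {r.record_id: list(r.sequence) for r in matrix.records}
    for record_id, start, length in indel_spec:
        if record_id not in seqs:
            raise ParameterError(f"unknown record {record_id!r} in indel spec")
        if start < 1 or start + length - 1 > matrix.n_columns:
            raise ParameterError(
                f"indel {start}+{length} outside the matrix for {record_id!r}"
            )
        for col in range(start, start + length):
            seqs[record_id][col - 1] = GAP
    records = [
        SequenceRecord(
            record_id=r.record_id,
            sequence="".join(seqs[r.record_id]),
            species=r.species,
            genus=r.genus,
            tribe=r.tribe,
            clade=r.clade,
        )
        for r in matrix.records
    ]
    return AlignmentMatrix(records, coding_offset=matrix.coding_offset)


def assign_phenotypes(
    clade_map: Mapping[str, str],
    phenotype_spec: Mapping[str, tuple[float, float]],
    seed: int,
) -> pd.DataFrame:
    """Truncated-normal erucic-acid percentages per clade, on [0, 100]."""
    rng = np.random.default_rng(seed)
    rows = []
    for leaf in sorted(clade_map):
        clade = clade_map[leaf]
        if clade not in phenotype_spec:
            raise ParameterError(f"no phenotype spec for clade {clade!r} ({leaf})")
        mean, sd = phenotype_spec[clade]
        if sd == 0:
            value = float(mean)
        else:
            a, b = (0 - mean) / sd, (100 - mean) / sd
            value = float(
                stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
            )
        rows.append({"accession": leaf, "erucic_pct": value})
    return pd.DataFrame(rows)


# -- one-stop bundle ------------------------------------------------------


@dataclass
class SynthBundle:
    config: SynthConfig
    tree: dendropy.Tree
    matrix: AlignmentMatrix
    phenotypes: pd.DataFrame
    clade_map: dict[str, str]
    ledger: list[dict]


def generate_dataset(config: SynthConfig | None = None) -> SynthBundle:
    """Tree + alignment + phenotypes + injection ledger from one config.

    Sub-seeds for the tree, the sequence evolution and the phenotypes are
    drawn from one generator seeded with ``config.seed``.
    """
    config = config or SynthConfig()
    master = np.random.default_rng(config.seed)
    tree_seed, evo_seed, phen_seed = (
        int(s) for s in master.integers(2**31 - 1, size=3)
    )
    tree = simulate_clade_tree(config, np.random.default_rng(tree_seed))
    cmap = clade_map_from_tree(tree, list(config.clade_sizes))
    matrix = evolve_alignment(tree, config, seed=evo_seed, clade_map=cmap)
    ledger: list[dict] = []
    if config.injected_sites:
        matrix, ledger = inject_clade_mutations(matrix, cmap, config.injected_sites)
    if config.indel_spec:
        matrix = apply_indels(matrix, config.indel_spec)
    phenotypes = assign_phenotypes(cmap, config.phenotype_spec, phen_seed)
    return SynthBundle(
        config=config,
        tree=tree,
        matrix=matrix,
        phenotypes=phenotypes,
        clade_map=cmap,
        ledger=ledger,
    )


def generate_fixed_difference_dataset(
    seed: int = 0,
    n_injected: int = 16,
    n_taxa: int = 40,
    n_codons: int = 300,
    omega: float = 0.1,
) -> tuple[AlignmentMatrix, dict[str, str], list[dict]]:
    """Gap-free alignment with exactly ``n_injected`` strict fixed
    differences between groups I and II, plus the edit ledger as ground
    truth.

    The two groups are an arbitrary alternating half-split of a single
    panmictic pool, deliberately incongruent with the tree: no branch
    separates exactly the group partition, so the only strict
    fixed differences are the injected ones.  Injection targets are novel
    single-base states (absent from the whole column), which makes each
    edited column fixed in group I and absent from group II.
    """
    master = np.random.default_rng(seed)
    tree_seed, evo_seed = (int(s) for s in master.integers(2**31 - 1, size=2))
    tree = simulate_tree(n_taxa, tree_seed, mean_branch=0.03)
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    group_map = {l: ("I" if i % 2 == 0 else "II") for i, l in enumerate(leaves)}
    config = SynthConfig(
        n_codons=n_codons,
        clade_sizes={"I": (n_taxa + 1) // 2, "II": n_taxa // 2},
        omega=omega,
        indel_spec=(),
        phenotype_spec={"I": (47.0, 1.0), "II": (3.0, 1.0)},
        seed=seed,
    )
    matrix = evolve_alignment(tree, config, seed=evo_seed, clade_map=group_map)
    first, last = matrix.codon_range()
    candidates = list(range(first + 1, last))
    stride = max(1, len(candidates) // n_injected)
    ordered = candidates[::stride] + [
        c for c in candidates if c not in candidates[::stride]
    ]
    ledger: list[dict] = []
    for ci in ordered:
        if len(ledger) == n_injected:
            break
        try:
            matrix, led = inject_clade_mutations(matrix, group_map, [("I", ci, None)])
        except ParameterError:
            continue
        ledger.extend(led)
    if len(ledger) < n_injected:
        raise ParameterError(
            f"could only place {len(ledger)} of {n_injected} injections"
        )
    return matrix, group_map, ledger


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + metadata TSV + phenotype TSV + newick + JSON ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "alignment.fasta",
        "metadata": outdir / "metadata.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "tree": outdir / "tree.nwk",
        "ledger": outdir / "ledger.json",
    }
    write_alignment(bundle.matrix, paths["alignment"])
    write_metadata(bundle.matrix, paths["metadata"])
    bundle.phenotypes.to_csv(
        paths["phenotypes"], sep="\t", index=False, float_format="%.6f"
    )
    paths["tree"].write_text(tree_to_newick(bundle.tree))
    cfg = asdict(bundle.config)
    cfg["injected_sites"] = [list(x) for x in cfg["injected_sites"]]
    cfg["indel_spec"] = [list(x) for x in cfg["indel_spec"]]
    paths["ledger"].write_text(
        json.dumps(
            {"config": cfg, "clade_map": bundle.clade_map, "edits": bundle.ledger},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return paths
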