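"""One-config orchestration of the full analysis.

Stages: site classification -> diversity / divergence -> Ka/Ks -> sliding
windows -> diagnostic sites & fixed differences -> phenotype association.
Every report is written as TSV/CSV with a JSON manifest capturing the
config, seeds, package version and per-stage counts; outputs are a pure
function of (inputs, config, seed), so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError, Fae1PopError
from . import diversity, groupdiff, phenassoc, seqio, sites

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    alignment: str
    metadata: str
    outdir: str
    phenotypes: str | None = None
    tree: str | None = None
    coding_offset: int = 431
    gap_policy: str = "complete_deletion"
    group_by: str = "clade"  # metadata column defining the grouping scheme
    f_high: float = 0.70
    f_low: float = 0.30
    fixed_pair: tuple[str, str] | None = None  # default: two largest groups
    boundaries: tuple[float, ...] = phenassoc.DEFAULT_CUTS
    window_size: int = 25
    window_step: int = 10
    n_permutations: int = 10_000
    seed: int | None = None

    def validate(self) -> None:
        for label, path in (
            ("alignment", self.alignment),
            ("metadata", self.metadata),
            ("phenotypes", self.phenotypes),
            ("tree", self.tree),
        ):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{label} file does not exist: {path}")
        if self.phenotypes is not None and self.seed is None:
            raise ConfigError(
                "a seed is required when the permutation test is requested"
            )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Fae1PopError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }

    matrix = _read_inputs(config)
    log.info("read %d records x %d columns", len(matrix), matrix.n_columns)
    manifest["stages"]["read"] = {
        "n_records": len(matrix),
        "n_columns": matrix.n_columns,
    }

    classification = _run_sites(config, matrix, outdir, manifest)
    _run_diversity(config, matrix, outdir, manifest)
    _run_windows(config, matrix, classification, outdir, manifest)
    _run_groups(config, matrix, outdir, manifest)
    if config.phenotypes is not None:
        _run_association(config, matrix, outdir, manifest)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


@_stage("read")
def _read_inputs(config: RunConfig) -> seqio.AlignmentMatrix:
    return seqio.read_alignment(
        config.alignment, config.metadata, coding_offset=config.coding_offset
    )


@_stage("sites")
def _run_sites(config, matrix, outdir, manifest) -> sites.SiteClassification:
    cls = sites.classify_sites(matrix, gap_policy=config.gap_policy)
    cls.table.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    events = seqio.detect_indel_events(matrix)
    pd.DataFrame(
        [
            {
                "record_id": e.record_id,
                "start_column": e.start_column,
                "end_column": e.end_column,
                "coding_start": e.coding_start,
                "coding_end": e.coding_end,
                "length": e.length,
                "terminal": e.terminal,
                "frameshift": e.frameshift,
            }
            for e in events
        ],
        columns=[
            "record_id", "start_column", "end_column", "coding_start",
            "coding_end", "length", "terminal", "frameshift",
        ],
    ).to_csv(outdir / "indels.tsv", sep="\t", index=False)
    manifest["stages"]["sites"] = {
        "variable": cls.variable_count,
        "informative": cls.informative_count,
        "variable_pct": sites.percent_of_matrix(
            cls.variable_count, matrix.n_columns
        ) if cls.variable_count <= matrix.n_columns else None,
        "informative_pct": sites.percent_of_matrix(
            cls.informative_count, matrix.n_columns
        ),
        "gap_columns_dropped": int(cls.table["has_gap"].sum()),
        "indel_events": len(events),
    }
    return cls


@_stage("diversity")
def _run_diversity(config, matrix, outdir, manifest) -> None:
    diversity.pairwise_distance_matrix(matrix).to_csv(
        outdir / "distances.tsv", sep="\t", float_format=FLOAT_FMT
    )
    entry = {}
    if len(matrix) >= 2:
        res = diversity.nucleotide_diversity(matrix)
        entry["pi"] = round(res.pi, 4)
        entry["n_sites_used"] = res.n_sites_used
        try:
            kk = diversity.ka_ks(matrix)
            pd.DataFrame(
                [
                    {
                        "N_sites": kk.N_sites,
                        "S_sites": kk.S_sites,
                        "pN": kk.pN,
                        "pS": kk.pS,
                        "Ka": kk.Ka,
                        "Ks": kk.Ks,
                        "ratio": kk.ratio,
                        "n_codons_used": kk.n_codons_used,
                        "n_pairs": kk.n_pairs,
                    }
                ]
            ).to_csv(outdir / "kaks.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
            entry["ka_ks"] = None if kk.ratio is None else round(kk.ratio, 4)
        except Fae1PopError as exc:
            entry["ka_ks_error"] = str(exc)
    manifest["stages"]["diversity"] = entry


@_stage("windows")
def _run_windows(config, matrix, classification, outdir, manifest) -> None:
    try:
        profile = diversity.sliding_window_silent(
            matrix,
            window_size=config.window_size,
            step=config.window_step,
            classification=classification,
        )
        profile.table.to_csv(
            outdir / "windows.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        manifest["stages"]["windows"] = {
            "n_windows": len(profile.table),
            "n_silent_columns": profile.n_silent_columns,
        }
    except Fae1PopError as exc:
        manifest["stages"]["windows"] = {"skipped": str(exc)}


@_stage("groups")
def _run_groups(config, matrix, outdir, manifest) -> None:
    scheme = groupdiff.GroupingScheme.from_metadata(matrix, config.group_by)
    entry: dict = {"n_groups": len(scheme.labels)}
    if len(scheme.labels) >= 2:
        report = groupdiff.group_report(matrix, scheme)
        report.diversity_matrix.to_csv(outdir / "group_diversity.tsv", sep="\t")
        report.polymorphic.to_csv(
            outdir / "group_polymorphic.tsv", sep="\t", index=False
        )
        diag_rows = []
        for label in scheme.labels:
            for site in groupdiff.diagnostic_sites(matrix, scheme, label):
                diag_rows.append(asdict(site))
        pd.DataFrame(
            diag_rows,
            columns=["group_label", "column", "coding_position", "state"],
        ).to_csv(outdir / "diagnostic.tsv", sep="\t", index=False)
        entry["diagnostic_sites"] = len(diag_rows)

        pair = config.fixed_pair
        if pair is None:
            by_size = sorted(
                scheme.labels, key=lambda l: (-len(scheme.members(l)), l)
            )
            pair = (by_size[0], by_size[1])
        fixed = groupdiff.fixed_differences(
            matrix,
            sorted(scheme.members(pair[0])),
            sorted(scheme.members(pair[1])),
            f_high=config.f_high,
            f_low=config.f_low,
        )
        pd.DataFrame(
            [asdict(f) for f in fixed],
            columns=["column", "coding_position", "state", "freq_in_a", "freq_in_b"],
        ).to_csv(outdir / "fixed.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        entry["fixed_pair"] = list(pair)
        entry["fixed_differences"] = len(fixed)
    manifest["stages"]["groups"] = entry


@_stage("association")
def _run_association(config, matrix, outdir, manifest) -> None:
    phen = seqio.read_phenotypes(config.phenotypes)
    boundaries = phenassoc.CategoryBoundaries(cuts=tuple(config.boundaries))
    report = phenassoc.association_report(
        matrix,
        phen,
        boundaries=boundaries,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    report.assignments.to_csv(
        outdir / "association.csv", index=False, float_format=FLOAT_FMT
    )
    if report.pairwise_fst is not None:
        report.pairwise_fst.to_csv(
            outdir / "fst_pairwise.csv", float_format=FLOAT_FMT
        )
    entry: dict = {"n_assigned": len(report.assignments), "dropped": report.dropped}
    if report.overall is None:
        entry["fst"] = "not applicable (fewer than 2 usable categories)"
    else:
        entry["fst"] = round(report.overall.fst, 4)
        entry["p_value"] = report.overall.p_value
        entry["n_permutations"] = report.overall.n_permutations
    manifest["stages"]["association"] = entry
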