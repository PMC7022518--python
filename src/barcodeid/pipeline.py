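"""End-to-end analysis pipeline and consolidated run report.

Runs the stages in the standard order — distances, threshold,
identification criteria, region analytics, NJ tree and monophyly — and
collects every stage's numbers into one JSON-serializable report. Each
report value is produced by the corresponding module call; reruns on the
same inputs are byte-identical (no timestamps in the report body).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

import barcodeid
from barcodeid.core import AlignedDataset
from barcodeid.distances import (
    barcode_gap_report,
    distance_matrix,
    divergence_summary,
)
from barcodeid.identify import identification_summary
from barcodeid.njtree import neighbor_joining, species_monophyly
from barcodeid.regions import site_classes, spacer_pattern_table, \
    variability_table


class StageError(RuntimeError):
    """Wraps an error with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineOptions:
    threshold_percentile: float = 95.0
    compat_singleton_ambiguous: bool = True
    outgroup_id: str | None = None
    spacer_region: str | None = "spacer"
    variability_region: str | None = "tRNA-leu"
    reference_species: str | None = None
    skip_undefined: bool = False


def run_pipeline(dataset: AlignedDataset,
                 species_map: Mapping[str, str] | None = None,
                 options: PipelineOptions | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run all analysis stages over one aligned dataset.

    Returns the consolidated report as a plain dict. With fewer than three
    sequences the identification and tree stages are skipped with an
    explicit notice. When ``outdir`` is given, the tree (newick), distance
    matrix (TSV) and report (JSON) are written there.
    """
    opts = options or PipelineOptions()
    species_map = dict(species_map or dataset.species_map)
    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "tool": {"name": "barcodeid", "version": barcodeid.__version__},
        "input": {
            "n_sequences": len(dataset.sequences),
            "n_species": len(set(species_map.values())),
            "alignment_length": dataset.length,
            "regions": [{"name": r.name, "start": r.start, "end": r.end}
                        for r in dataset.regions],
        },
        "notices": [],
    }

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(name, exc) from exc

    matrix = stage("distances", lambda: distance_matrix(dataset))
    summary = stage("divergence", lambda: divergence_summary(
        matrix, species_map, skip_undefined=opts.skip_undefined))
    report["divergence"] = {
        "mean_intra_pct": {
            sp: (None if m is None else round(100.0 * m, 2))
            for sp, m in summary.intra_means.items()},
        "mean_inter_pct": {
            " / ".join(k): round(100.0 * v, 2)
            for k, v in summary.inter_means.items()},
    }
    try:
        gap = barcode_gap_report(summary)
        report["barcode_gap"] = {
            "max_intra_pct": round(100.0 * gap.max_intra, 2),
            "min_inter_pct": round(100.0 * gap.min_inter, 2),
            "gap_present": gap.gap_present,
        }
    except ValueError as exc:
        report["barcode_gap"] = None
        report["notices"].append(f"barcode gap skipped: {exc}")

    has_intra = summary.all_intra.size > 0
    if len(dataset.sequences) >= 3 and has_intra:
        ident = stage("identify", lambda: identification_summary(
            dataset, species_map,
            percentile=opts.threshold_percentile,
            compat_singleton_ambiguous=opts.compat_singleton_ambiguous,
            matrix=matrix))
        report["identification"] = ident.to_dict()
    else:
        report["identification"] = None
        report["notices"].append(
            "identification skipped: needs >= 3 sequences and at least "
            "one species with 2 sequences")

    for key, fn in (
        ("spacer_patterns", lambda: spacer_pattern_table(
            dataset, opts.spacer_region)),
        ("site_classes", lambda: site_classes(dataset)),
    ):
        try:
            result = fn()
            report[key] = (result.to_dict() if key == "site_classes" else {
                "ungapped_lengths": result.ungapped_lengths,
                "shared_patterns": {p: list(sps)
                                    for p, sps in result.shared.items()
                                    if len(sps) > 1},
            })
        except (KeyError, ValueError) as exc:
            report[key] = None
            report["notices"].append(f"{key} skipped: {exc}")

    ref = opts.reference_species or dataset.sequences[0].species
    try:
        vtab = variability_table(dataset, opts.variability_region, ref)
        report["variability"] = {
            "region": opts.variability_region,
            "reference_species": ref,
            "variable_columns": list(vtab.columns),
        }
    except (KeyError, ValueError) as exc:
        report["variability"] = None
        report["notices"].append(f"variability skipped: {exc}")

    if len(dataset.sequences) >= 3 and not np.isnan(matrix.d).any():
        tree = stage("tree", lambda: neighbor_joining(matrix))
        tree_path = None
        if outdir_path is not None:
            tree_path = "tree.nwk"  # relative to outdir, keeps reports
            tree.write_newick(outdir_path / tree_path)  # reproducible
        report["tree"] = {"newick": tree.to_newick(),
                          "clamped_branches": tree.clamped,
                          "path": tree_path}
        if opts.outgroup_id is not None:
            mono = stage("monophyly", lambda: species_monophyly(
                tree, species_map, opts.outgroup_id))
            report["monophyly"] = {
                "outgroup": opts.outgroup_id,
                "per_species": mono.monophyletic,
                "n_monophyletic": mono.n_monophyletic,
                "n_species": mono.n_species,
                "all_monophyletic": mono.all_monophyletic,
                "singletons": list(mono.singletons),
            }
        else:
            report["monophyly"] = None
            report["notices"].append("monophyly skipped: no outgroup given")
    else:
        report["tree"] = None
        report["monophyly"] = None
        report["notices"].append(
            "tree skipped: needs >= 3 sequences and fully defined "
            "distances")

    if outdir_path is not None:
        matrix.write_tsv(outdir_path / "distances.tsv")
        (outdir_path / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
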