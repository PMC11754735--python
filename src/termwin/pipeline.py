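"""End-to-end pipeline: annotation -> windows -> classification -> summary.

A :class:`PipelineConfig` carries every stage's parameters plus input
paths; :func:`run_pipeline` executes the stages, persists each stage's
output under ``out_dir`` and writes a machine-readable ``summary.json``
(category counts, medians, parameters, version, input checksums) that is
sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from . import __version__
from .annotation import (
    SelectionParams,
    genes_to_bed,
    genes_to_table,
    load_annotation,
    select_genes,
)
from .calling import (
    BroadCallParams,
    TerminationWindowSet,
    call_termination_windows,
    windows_to_bed,
)
from .classify import (
    ClassParams,
    classified_to_bed,
    classified_to_table,
    classify,
    window_stats,
)
from .coverage import ExtensionParams, read_bedgraph

logger = logging.getLogger(__name__)

_STRAND_KEYS = {"+": "plus", "-": "minus"}


@dataclass
class PipelineConfig:
    """Serializable run configuration; unknown keys are rejected on load."""

    gtf: str
    # one entry per study: {"plus": [paths...], "minus": [paths...]}
    replicate_sets: list[dict[str, list[str]]]
    out_dir: str = "termwin_out"
    strands: tuple[str, ...] = ("+", "-")
    selection: SelectionParams = field(default_factory=SelectionParams)
    extension: ExtensionParams = field(default_factory=ExtensionParams)
    calling: BroadCallParams = field(default_factory=BroadCallParams)
    classification: ClassParams = field(default_factory=ClassParams)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, typ in (
            ("selection", SelectionParams),
            ("extension", ExtensionParams),
            ("calling", BroadCallParams),
            ("classification", ClassParams),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                sub_known = {f.name for f in dataclasses.fields(typ)}
                sub_unknown = set(sub) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown keys in {key}: {sorted(sub_unknown)}"
                    )
                if key == "selection" and "biotype_filter" in sub:
                    sub["biotype_filter"] = frozenset(sub["biotype_filter"])
                if key == "classification" and "priority" in sub:
                    sub["priority"] = tuple(sub["priority"])
                d[key] = typ(**sub)
        if "strands" in d:
            d["strands"] = tuple(d["strands"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection"]["biotype_filter"] = sorted(self.selection.biotype_filter)
        d["strands"] = list(self.strands)
        d["classification"]["priority"] = list(self.classification.priority)
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return the summary dict (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    logger.info("loading annotation %s", config.gtf)
    genes = load_annotation(config.gtf)
    selected = select_genes(genes, config.selection)
    logger.info("selected %d / %d genes", len(selected), len(genes))
    genes_to_bed(selected, os.path.join(config.out_dir, "selected_genes.bed"))
    genes_to_table(selected).to_csv(
        os.path.join(config.out_dir, "selected_genes.tsv"), sep="\t", index=False
    )

    classified = []
    all_windows: list = []
    input_files = [config.gtf]
    for strand in config.strands:
        key = _STRAND_KEYS[strand]
        sets = []
        for study in config.replicate_sets:
            paths = study.get(key, [])
            input_files.extend(paths)
            sets.append([read_bedgraph(p, strand) for p in paths])
        if any(not s for s in sets):
            raise ValueError(
                f"every replicate set needs >= 1 track for strand {strand}"
            )
        windows = call_termination_windows(
            sets, extension=config.extension, params=config.calling
        )
        logger.info("strand %s: %d consensus windows", strand, len(windows))
        all_windows.extend(windows.windows)
        classified.extend(classify(windows, selected, config.classification))

    windows_to_bed(
        TerminationWindowSet(sorted(all_windows)),
        os.path.join(config.out_dir, "termination_windows.bed"),
    )
    classified_to_bed(
        classified, os.path.join(config.out_dir, "classified_windows.bed")
    )
    classified_to_table(classified).to_csv(
        os.path.join(config.out_dir, "classified_windows.tsv"), sep="\t", index=False
    )
    stats = window_stats(classified)
    stats.to_csv(os.path.join(config.out_dir, "window_stats.tsv"), sep="\t", index=False)

    summary = {
        "version": __version__,
        "config": config.to_dict(),
        "n_genes_annotated": len(genes),
        "n_genes_selected": len(selected),
        "n_windows": len(classified),
        "category_counts": {
            row["category"]: int(row["n"]) for _, row in stats.iterrows()
        },
        "median_lengths": {
            row["category"]: (None if row["n"] == 0 else float(row["median_length"]))
            for _, row in stats.iterrows()
        },
        "input_checksums": {p: _sha256(p) for p in input_files},
    }
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
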