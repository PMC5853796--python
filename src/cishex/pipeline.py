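"""End-to-end orchestration: scan -> associate -> meta -> permute (-> regions).

`run_pipeline` wires the library stages together from a `RunConfig`, writes
per-stage TSVs plus a JSON run log (seed, thresholds, package versions) into
an output directory, and returns the tables in memory.  Datasets can be
restricted to early (treatment <= 2 h by default) or late responses before
the meta-analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy

from . import __version__, association, hexamers, io, permutation, regions


@dataclass
class RunConfig:
    promoters: str | None = None        # promoter FASTA
    genome: str | None = None           # genome FASTA (with models, alternative input)
    models: str | None = None           # GFF3 gene models
    deg_manifest: str | None = None     # TSV: dataset_id, path, timepoint_h
    universe: str | None = None         # optional gene list restricting universes
    peaks: str | None = None            # BED
    states: str | None = None           # BED with state labels
    outdir: str = "cishex_out"
    window_len: int = 1501
    alpha: float = 0.005
    fwer: float = 0.05
    permutations: int = 1000
    min_degs: int = 10
    n_tests: int | None = None          # Bonferroni multiplicity; default features x statuses
    seed: int = 0
    grouping: str = "all"               # all | early | late
    early_boundary_h: float = 2.0
    early_inclusive: bool = True
    respect_mask: bool = False

    def __post_init__(self):
        if not (0 < self.alpha < 1) or not (0 < self.fwer < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")


def group_datasets(
    datasets: Sequence[io.DatasetDEG],
    rule: str = "all",
    boundary_h: float = 2.0,
    early_inclusive: bool = True,
) -> list[io.DatasetDEG]:
    """Split datasets by treatment duration: early <= boundary (inclusive by default), late > it."""
    if rule == "all":
        return list(datasets)
    if rule not in ("early", "late"):
        raise ValueError(f"unknown grouping rule {rule!r}")
    out = []
    for d in datasets:
        if d.timepoint_h is None:
            raise ValueError(f"dataset {d.dataset_id}: timepoint required for early/late grouping")
        early = d.timepoint_h <= boundary_h if early_inclusive else d.timepoint_h < boundary_h
        if (rule == "early") == early:
            out.append(d)
    return out


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the configured stages; partial outputs are retained on failure."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise StageError(name, exc) from exc

    def load_promoters():
        if cfg.promoters:
            proms = io.read_promoters_fasta(cfg.promoters)
        elif cfg.genome and cfg.models:
            proms = io.extract_promoters(cfg.genome, cfg.models, window_len=cfg.window_len)
        else:
            raise ValueError("need either a promoter FASTA or genome + gene models")
        if not proms:
            raise ValueError("no promoters loaded")
        return proms

    promoters = stage("promoters", load_promoters)
    universe = {p.gene_id for p in promoters}
    if cfg.universe:
        listed = {ln.strip() for ln in open(cfg.universe) if ln.strip()}
        universe &= listed

    def load_datasets():
        if not cfg.deg_manifest:
            raise ValueError("a DEG manifest is required")
        ds = io.read_deg_manifest(cfg.deg_manifest, universe)
        ds = io.filter_datasets(ds, min_degs=cfg.min_degs)
        ds = group_datasets(ds, cfg.grouping, cfg.early_boundary_h, cfg.early_inclusive)
        if not ds:
            raise ValueError("no datasets left after filtering/grouping")
        return ds

    datasets = stage("datasets", load_datasets)

    pm = stage("scan", lambda: hexamers.scan_promoters(promoters, respect_mask=cfg.respect_mask))
    scan_df = pd.DataFrame(
        dict(gene_id=pm.gene_ids, n_hexamers=pm.matrix.sum(axis=1))
    )
    scan_df.to_csv(outdir / "scan_summary.tsv", sep="\t", index=False)
    tables["scan"] = scan_df

    statuses = ("up", "down")
    n_tests = cfg.n_tests if cfg.n_tests is not None else len(pm.features) * len(statuses)

    def run_stats():
        return permutation.two_stage_selection(
            pm, datasets, M=cfg.permutations, rng_seed=cfg.seed, statuses=statuses,
            alpha=cfg.alpha, n_tests_meta=n_tests,
        )

    meta, perm, selected = stage("associate+permute", run_stats)
    meta_df = association.results_to_frame(meta)
    meta_df.to_csv(outdir / "association.tsv", sep="\t", index=False)
    tables["association"] = meta_df
    perm_df = permutation.permutation_to_frame(perm)
    perm_df.to_csv(outdir / "permutation.tsv", sep="\t", index=False)
    tables["permutation"] = perm_df
    sel_df = permutation.permutation_to_frame(selected)
    sel_df.to_csv(outdir / "selected.tsv", sep="\t", index=False)
    tables["selected"] = sel_df

    if cfg.peaks:
        def run_peaks():
            genome = io.read_genome(cfg.genome) if cfg.genome else None
            if genome is None:
                raise ValueError("peak enrichment needs a genome FASTA")
            pk = regions.read_bed(cfg.peaks, name="peaks")
            return regions.peak_enrichment(
                pk, genome, promoters, fwer=cfg.fwer, respect_mask=cfg.respect_mask
            )
        res = stage("peaks", run_peaks)
        df = regions.enrichment_to_frame(res)
        df.to_csv(outdir / "peak_enrichment.tsv", sep="\t", index=False)
        tables["peaks"] = df

    if cfg.states:
        def run_states():
            st = regions.read_bed(cfg.states, name="chromatin_states")
            segs = regions.state_segments(promoters, st)
            pres = regions.state_presence(segs)
            meta_s, perm_s = regions.state_association(
                datasets, pres, M=cfg.permutations, seed=cfg.seed, alpha=cfg.alpha
            )
            return association.results_to_frame(meta_s), permutation.permutation_to_frame(perm_s)
        meta_s_df, perm_s_df = stage("chromstate", run_states)
        meta_s_df.to_csv(outdir / "state_association.tsv", sep="\t", index=False)
        perm_s_df.to_csv(outdir / "state_permutation.tsv", sep="\t", index=False)
        tables["state_association"] = meta_s_df
        tables["state_permutation"] = perm_s_df

    log = dict(
        config=dataclasses.asdict(cfg),
        n_promoters=len(promoters),
        n_datasets=len(datasets),
        dataset_ids=[d.dataset_id for d in datasets],
        n_tests=n_tests,
        seed=cfg.seed,
        rng="numpy.random.default_rng(PCG64)",
        versions=dict(cishex=__version__, numpy=np.__version__, scipy=scipy.__version__,
                      pandas=pd.__version__),
    )
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return tables
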