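"""Positional hexamer enrichment in peaks and chromatin-state segments.

Occupancy of a hexamer in a set of sequences is the number of 6-bp start
positions it occupies (canonical, both strands collapsed) out of all valid
positions.  Enrichment compares the foreground proportion (peak sequences, or
promoter segments lying in one chromatin state) against a background (all
promoter windows, or the same state's segments in a control gene set) with a
one-tailed Fisher exact test, Bonferroni-corrected across the features
tested (FWER control).

The chromatin-state map is a BED file whose name column carries the state
label ("1"–"9" for the nine-state segmentation); the association machinery
can also be run with the state indicators themselves in place of hexamers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import hexamers
from .association import ContingencyTable, MetaResult, fisher_one_sided, run_association
from .hexamers import CanonicalHexamer, canonical_index, count_occurrences
from .io import DatasetDEG, GeneSets, PromoterRecord
from .permutation import PermutationResult, permutation_test

logger = logging.getLogger(__name__)

CHROMATIN_STATES = tuple(str(i) for i in range(1, 10))


@dataclass
class IntervalSet:
    """Labelled genomic intervals, 0-based half-open."""

    intervals: list[tuple[str, int, int, str]]
    name: str = ""

    def __post_init__(self):
        for chrom, start, end, _ in self.intervals:
            if start >= end:
                raise ValueError(f"{self.name}: empty interval {chrom}:{start}-{end}")

    def labels(self) -> set[str]:
        return {lab for _, _, _, lab in self.intervals}


def read_bed(path: str | Path, name: str = "") -> IntervalSet:
    """BED (3+ columns); the name column, when present, becomes the label."""
    rows = []
    name = name or Path(path).stem
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else name
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    return IntervalSet(intervals=rows, name=name)


def write_bed(ivs: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in ivs.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def merge_intervals(ivs: IntervalSet) -> IntervalSet:
    """Union of all intervals per chromosome (labels discarded)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _ in ivs.intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = []
    for chrom in sorted(by_chrom):
        cur_s, cur_e = None, None
        for s, e in sorted(by_chrom[chrom]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e, ivs.name))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e, ivs.name))
    return IntervalSet(intervals=merged, name=ivs.name)


@dataclass
class EnrichmentResult:
    feature: str
    region_label: str
    occupied_fg: int
    total_fg: int
    occupied_bg: int
    total_bg: int
    p: float
    fwer_p: float
    significant: bool
    degenerate: bool = False


# ---------------------------------------------------------------------------
# occupancy and the two-proportion test


def occupancy(
    seqs: Sequence[str], hexamer: str | CanonicalHexamer, respect_mask: bool = False
) -> tuple[int, int]:
    """(occupied positions, total valid positions) for one canonical hexamer."""
    counts, totals = count_occurrences(seqs, respect_mask=respect_mask)
    j = canonical_index(str(hexamer))
    return int(counts[:, j].sum()), int(totals.sum())


def occupancy_all(
    seqs: Sequence[str], respect_mask: bool = False
) -> tuple[np.ndarray, int]:
    """Occupancy vector over all 2080 canonical hexamers plus the shared total."""
    counts, totals = count_occurrences(seqs, respect_mask=respect_mask)
    if counts.shape[0] == 0:
        return np.zeros(hexamers.N_CANONICAL, dtype=np.int64), 0
    return counts.sum(axis=0), int(totals.sum())


def enrichment_test(fg: tuple[int, int], bg: tuple[int, int]) -> float:
    """One-sided Fisher p for over-representation of the foreground proportion."""
    (fo, ft), (bo, bt) = fg, bg
    if ft <= 0 or bt <= 0:
        raise ValueError("foreground and background totals must be positive")
    return fisher_one_sided(ContingencyTable(fo, ft - fo, bo, bt - bo))


def _fetch_interval_seqs(
    ivs: IntervalSet, genome: Mapping[str, str]
) -> list[str]:
    seqs = []
    for chrom, start, end, _ in ivs.intervals:
        if chrom not in genome:
            logger.warning("interval on unknown chromosome %s skipped", chrom)
            continue
        L = len(genome[chrom])
        if end > L:
            logger.warning("interval %s:%d-%d truncated at chromosome end %d", chrom, start, end, L)
            end = L
        if start < end:
            seqs.append(genome[chrom][start:end])
    return seqs


def peak_enrichment(
    peaks: IntervalSet,
    genome: Mapping[str, str],
    promoter_bg: Sequence[PromoterRecord],
    hexamer_list: Sequence[str] | None = None,
    fwer: float = 0.05,
    respect_mask: bool = False,
) -> list[EnrichmentResult]:
    """Hexamer occupancy in (merged) peak sequences versus all promoter windows."""
    merged = merge_intervals(peaks)
    fg_seqs = _fetch_interval_seqs(merged, genome)
    fg_counts, fg_total = occupancy_all(fg_seqs, respect_mask=respect_mask)
    bg_counts, bg_total = occupancy_all([p.seq for p in promoter_bg], respect_mask=respect_mask)
    all_feats = [h.seq for h in hexamers.enumerate_canonical()]
    feats = list(hexamer_list) if hexamer_list is not None else all_feats
    n_tests = len(feats)
    out = []
    for f in feats:
        j = canonical_index(f)
        degenerate = fg_total == 0
        if degenerate:
            p = 1.0
        else:
            p = enrichment_test((int(fg_counts[j]), fg_total), (int(bg_counts[j]), bg_total))
        fwer_p = min(1.0, p * n_tests)
        out.append(
            EnrichmentResult(
                feature=all_feats[j], region_label=peaks.name,
                occupied_fg=int(fg_counts[j]), total_fg=fg_total,
                occupied_bg=int(bg_counts[j]), total_bg=bg_total,
                p=p, fwer_p=fwer_p, significant=fwer_p < fwer, degenerate=degenerate,
            )
        )
    return out


# ---------------------------------------------------------------------------
# chromatin states


def state_segments(
    promoters: Sequence[PromoterRecord], states: IntervalSet
) -> dict[tuple[str, str], list[str]]:
    """Intersect each promoter window with each state's intervals.

    Returns (gene_id, state label) -> list of sub-sequences in promoter-strand
    orientation.  Promoters whose window is not covered by the state map get
    no entries.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, lab in states.intervals:
        by_chrom.setdefault(chrom, []).append((start, end, lab))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    out: dict[tuple[str, str], list[str]] = {}
    for p in promoters:
        if p.chrom is None or p.start is None or p.strand is None:
            raise ValueError(f"promoter {p.gene_id} lacks genomic coordinates")
        found = False
        for s, e, lab in by_chrom.get(p.chrom, []):
            lo, hi = max(s, p.start), min(e, p.end)
            if lo >= hi:
                continue
            found = True
            if p.strand == "+":
                sub = p.seq[lo - p.start : hi - p.start]
            else:  # seq is already reverse-complemented; local i <-> genomic end-1-i
                sub = p.seq[p.end - hi : p.end - lo]
            out.setdefault((p.gene_id, lab), []).append(sub)
        if not found:
            logger.info("promoter %s not covered by the state map", p.gene_id)
    return out


def state_presence(segments: Mapping[tuple[str, str], list[str]]) -> dict[str, set[str]]:
    """Gene -> set of chromatin states its promoter window touches."""
    out: dict[str, set[str]] = {}
    for (gene, lab), segs in segments.items():
        if any(segs):
            out.setdefault(gene, set()).add(lab)
    return out


def state_association(
    datasets: Sequence[DatasetDEG],
    presence_by_state: Mapping[str, set[str]],
    M: int = 1000,
    seed: int = 0,
    alpha: float = 0.005,
    statuses: Sequence[str] = ("up", "down"),
) -> tuple[list[MetaResult], list[PermutationResult]]:
    """Association + permutation analysis with state indicators replacing hexamers."""
    # genes absent from the map simply carry no state; give them empty sets so
    # they stay in the universe
    genes = set(presence_by_state)
    for d in datasets:
        genes |= d.universe
    full = {g: set(presence_by_state.get(g, set())) for g in sorted(genes)}
    labels = sorted({lab for s in full.values() for lab in s})
    pm = hexamers.PresenceMatrix.from_sets(full, features=labels)
    n_tests = len(labels) * len(statuses)
    meta = run_association(pm, datasets, statuses=statuses, alpha=alpha, n_tests=n_tests)
    perm = permutation_test(
        pm, datasets, meta, M=M, rng_seed=seed, statuses=statuses,
        n_tests=n_tests, alpha=alpha, null="pooled",
    )
    return meta, perm


def state_hexamer_enrichment(
    hexamer: str | CanonicalHexamer,
    state: str,
    segments: Mapping[tuple[str, str], list[str]],
    promoter_bg: Sequence[PromoterRecord],
    mode: str = "genomewide",
    sets: GeneSets | None = None,
    n_tests: int | None = None,
    fwer: float = 0.05,
    respect_mask: bool = False,
) -> EnrichmentResult:
    """Hexamer occupancy inside one chromatin state's promoter segments.

    genomewide mode: foreground = all segments of the state, background = all
    promoter windows.  responsive_vs_control mode: foreground = the state's
    segments in the positive gene set, background = the same segments in the
    control set.
    """
    hx = str(hexamer) if not isinstance(hexamer, CanonicalHexamer) else hexamer.seq
    if mode == "genomewide":
        fg_seqs = [s for (g, lab), segs in segments.items() if lab == state for s in segs]
        bg_seqs = [p.seq for p in promoter_bg]
    elif mode == "responsive_vs_control":
        if sets is None:
            raise ValueError("responsive_vs_control mode needs positive/control gene sets")
        fg_seqs = [
            s for (g, lab), segs in segments.items()
            if lab == state and g in sets.positive for s in segs
        ]
        bg_seqs = [
            s for (g, lab), segs in segments.items()
            if lab == state and g in sets.control for s in segs
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if n_tests is None:
        n_tests = hexamers.N_CANONICAL * len(CHROMATIN_STATES)
    fo, ft = occupancy(fg_seqs, hx, respect_mask=respect_mask)
    bo, bt = occupancy(bg_seqs, hx, respect_mask=respect_mask)
    degenerate = ft == 0 or bt == 0
    p = 1.0 if degenerate else enrichment_test((fo, ft), (bo, bt))
    fwer_p = min(1.0, p * n_tests)
    canon = str(canonicalize_seq(hx))
    return EnrichmentResult(
        feature=canon, region_label=state, occupied_fg=fo, total_fg=ft,
        occupied_bg=bo, total_bg=bt, p=p, fwer_p=fwer_p,
        significant=(not degenerate) and fwer_p < fwer, degenerate=degenerate,
    )


def canonicalize_seq(h: str) -> str:
    return hexamers.canonicalize(h).seq


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(feature=r.feature, region_label=r.region_label,
                 occupied_fg=r.occupied_fg, total_fg=r.total_fg,
                 occupied_bg=r.occupied_bg, total_bg=r.total_bg,
                 p=r.p, fwer_p=r.fwer_p, significant=r.significant,
                 degenerate=r.degenerate)
            for r in results
        ]
    )
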