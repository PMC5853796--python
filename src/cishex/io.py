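"""Promoters, differential-expression tables, gene universes and gene sets.

The analysis is anchored on TSS-relative upstream windows (default
``[-1500; +1]``, a 1501-bp window whose 3'-most base is the TSS base) and on
per-experiment DEG calls: a gene is *up* if its FDR-adjusted p-value
(Benjamini–Yekutieli) is below 0.05 and its linear fold change exceeds 3/2,
*down* below 2/3, *none* otherwise.  From a collection of such datasets two
reference gene sets are built: a control set (no differential expression in
any experiment over the common universe) and a positive set (differentially
expressed in at least ``min_hits`` experiments).

Coordinates: GFF3 is 1-based inclusive on disk; everything in memory is
0-based half-open; BED stays 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from statsmodels.stats.multitest import multipletests

from .hexamers import reverse_complement

logger = logging.getLogger(__name__)

STATUSES = ("up", "down", "none")


@dataclass
class PromoterRecord:
    """One gene's TSS-anchored upstream window, 5'->3' on the gene's strand."""

    gene_id: str
    seq: str
    chrom: str | None = None
    strand: str | None = None
    start: int | None = None  # genomic window, 0-based half-open
    end: int | None = None
    truncated: bool = False

    def __post_init__(self):
        if self.start is not None and self.end is not None:
            if len(self.seq) != self.end - self.start:
                raise ValueError(
                    f"{self.gene_id}: sequence length {len(self.seq)} != window "
                    f"{self.end - self.start}"
                )


@dataclass
class DatasetDEG:
    """One experiment's gene -> up/down/none map over its measured universe."""

    dataset_id: str
    status: dict[str, str]
    universe: set[str]
    timepoint_h: float | None = None

    def __post_init__(self):
        extra = set(self.status) - self.universe
        if extra:
            raise ValueError(f"{self.dataset_id}: statuses outside universe: {sorted(extra)[:5]}")
        bad = set(self.status.values()) - set(STATUSES)
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown statuses {sorted(bad)}")

    def genes_with(self, status: str) -> set[str]:
        if status == "both":
            return {g for g, s in self.status.items() if s in ("up", "down")}
        return {g for g, s in self.status.items() if s == status}

    @property
    def n_degs(self) -> int:
        return sum(1 for s in self.status.values() if s in ("up", "down"))


@dataclass
class GeneSets:
    control: set[str]
    positive: set[str]

    def __post_init__(self):
        if self.control & self.positive:
            raise ValueError("control and positive gene sets overlap")


# ---------------------------------------------------------------------------
# FASTA / GFF3


def read_genome(path: str | Path) -> dict[str, str]:
    """Chromosome name (first token) -> uppercase-preserving sequence string."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_promoters_fasta(path: str | Path) -> list[PromoterRecord]:
    """Promoters from FASTA; the gene id is the first whitespace token of the header."""
    return [
        PromoterRecord(gene_id=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_promoters_fasta(promoters: Iterable[PromoterRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.seq), id=p.gene_id, description="") for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_promoters(
    genome: Mapping[str, str] | str | Path,
    models: str | Path,
    window_len: int = 1501,
) -> list[PromoterRecord]:
    """Cut TSS-anchored upstream windows out of a genome using GFF3 gene models.

    For a plus-strand gene the window is the ``window_len`` bases whose last
    base is the TSS base, read on the forward strand; for a minus-strand gene
    the mirrored window downstream of the (right-end) TSS, reverse
    complemented.  Windows hitting a chromosome edge are truncated and
    flagged.
    """
    if isinstance(genome, (str, Path)):
        genome = read_genome(genome)
    db = gffutils.create_db(
        str(models), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: list[PromoterRecord] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        if gene.seqid not in genome:
            logger.warning("gene %s: chromosome %s absent from genome, skipped", gene_id, gene.seqid)
            continue
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene_id}: missing strand")
        chrom_seq = genome[gene.seqid]
        L = len(chrom_seq)
        if gene.strand == "+":
            tss0 = gene.start - 1  # 0-based TSS position
            start = max(0, tss0 - window_len + 1)
            end = tss0 + 1
            seq = chrom_seq[start:end]
        else:
            tss0 = gene.end - 1
            start = tss0
            end = min(L, tss0 + window_len)
            seq = reverse_complement(chrom_seq[start:end])
        out.append(
            PromoterRecord(
                gene_id=gene_id,
                seq=seq,
                chrom=gene.seqid,
                strand=gene.strand,
                start=start,
                end=end,
                truncated=(end - start) < window_len,
            )
        )
    return out


# ---------------------------------------------------------------------------
# DEG tables


def read_deg_table(
    path: str | Path,
    universe: set[str],
    dataset_id: str | None = None,
    timepoint_h: float | None = None,
) -> DatasetDEG:
    """TSV with columns gene_id, status [, lfc, adj_p]; statuses clipped to the universe."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty and "gene_id" not in df.columns:
        return DatasetDEG(dataset_id or path.stem, {}, set(universe), timepoint_h)
    status: dict[str, str] = {}
    dropped = 0
    for gene, s in zip(df["gene_id"].astype(str), df["status"].astype(str)):
        if s not in STATUSES:
            raise ValueError(f"{path}: unknown status {s!r} for gene {gene}")
        if gene not in universe:
            dropped += 1
            continue
        if gene in status and status[gene] != s:
            raise ValueError(f"{path}: conflicting statuses for gene {gene}")
        status[gene] = s
    if dropped:
        logger.warning("%s: dropped %d rows for genes outside the universe", path, dropped)
    return DatasetDEG(dataset_id or path.stem, status, set(universe), timepoint_h)


def read_deg_manifest(path: str | Path, universe: set[str]) -> list[DatasetDEG]:
    """Manifest TSV: dataset_id, path (relative to the manifest), timepoint_h."""
    path = Path(path)
    man = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in man.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        out.append(
            read_deg_table(p, universe, dataset_id=str(row.dataset_id),
                           timepoint_h=float(row.timepoint_h))
        )
    return out


def by_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def call_degs(
    lfc: Mapping[str, float],
    adj_p: Mapping[str, float],
    fdr: float = 0.05,
    fc_hi: float = 3 / 2,
    fc_lo: float = 2 / 3,
) -> dict[str, str]:
    """Status calls from log2 fold changes and FDR-adjusted p-values.

    up: adj_p < fdr and linear fold change > fc_hi; down: adj_p < fdr and
    fold change < fc_lo; none otherwise.
    """
    if set(lfc) != set(adj_p):
        raise ValueError("lfc and adj_p must cover the same genes")
    out = {}
    for g in lfc:
        fc = 2.0 ** lfc[g]
        if adj_p[g] < fdr and fc > fc_hi:
            out[g] = "up"
        elif adj_p[g] < fdr and fc < fc_lo:
            out[g] = "down"
        else:
            out[g] = "none"
    return out


def filter_datasets(datasets: Sequence[DatasetDEG], min_degs: int = 10) -> list[DatasetDEG]:
    """Keep datasets with at least ``min_degs`` differentially expressed genes."""
    return [d for d in datasets if d.n_degs >= min_degs]


def build_gene_sets(datasets: Sequence[DatasetDEG], min_hits: int = 3) -> GeneSets:
    """Control = never DE anywhere (over the common universe); positive = DE in >= min_hits sets."""
    if not datasets:
        return GeneSets(set(), set())
    common = set.intersection(*(d.universe for d in datasets))
    hits: dict[str, int] = {}
    de_anywhere: set[str] = set()
    for d in datasets:
        for g in d.genes_with("both"):
            hits[g] = hits.get(g, 0) + 1
            de_anywhere.add(g)
    control = common - de_anywhere
    positive = {g for g, n in hits.items() if n >= min_hits}
    return GeneSets(control=control, positive=positive)
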