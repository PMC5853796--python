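"""Synthetic promoters, DEG tables, peaks and chromatin-state maps.

The generator emulates the statistical structure the pipeline assumes:
several differential-expression experiments over a shared gene universe with
controlled cross-dataset overlap of DEG calls; i.i.d. promoter sequences at a
stated GC content with motif instances planted at higher probability in
responsive genes; peak intervals centred on a fraction of the planted
instances; and block-wise chromatin-state segmentations with optional
state-specific base composition (e.g. an A/T-rich distal-promoter state).
Ground truth is returned alongside the data so recovery tests can score the
pipeline against what was actually planted.

Everything is deterministic given ``SimConfig.seed``; with an output
directory the exact on-disk formats the pipeline consumes are emitted
(FASTA, GFF3, TSV, BED) plus truth tables and a config echo.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .hexamers import reverse_complement
from .io import DatasetDEG, PromoterRecord, write_promoters_fasta
from .regions import IntervalSet, write_bed

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_SPACER = 50
_BODY = 60

# Arabidopsis-like upstream composition and a 3-timepoint treatment series
DEFAULT_GC = 0.36
DEFAULT_TIMEPOINTS = (1.0, 2.0, 6.0)


@dataclass
class PlantedMotif:
    """Plant ``hexamer`` with probability p_fg in genes of target_status, p_bg otherwise."""

    hexamer: str
    target_status: str = "up"
    p_fg: float = 0.5
    p_bg: float = 0.1

    def __post_init__(self):
        if not (0 <= self.p_bg <= self.p_fg <= 1):
            raise ValueError("need 0 <= p_bg <= p_fg <= 1 for an enrichment scenario")


@dataclass
class PeakConfig:
    n_peaks: int = 60
    width: int = 100
    frac_centered: float = 0.8  # fraction of peaks centred on planted instances


@dataclass
class StateConfig:
    mean_block_len: int = 300
    state_freqs: tuple[float, ...] = (0.2, 0.2, 0.05, 0.25, 0.15, 0.05, 0.05, 0.03, 0.02)
    comp_bias: dict[str, float] = field(default_factory=dict)  # state label -> gc


@dataclass
class SimConfig:
    n_genes: int = 2000
    window_len: int = 1501
    gc_content: float = DEFAULT_GC
    n_datasets: int = 3
    timepoints_h: tuple[float, ...] | None = None
    frac_up: float = 0.05
    frac_down: float = 0.05
    deg_overlap: float = 0.6
    planted_motifs: tuple[PlantedMotif, ...] = ()
    peak_cfg: PeakConfig | None = None
    state_cfg: StateConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        for m in self.planted_motifs:
            if len(m.hexamer) > self.window_len:
                raise ValueError("motif longer than the promoter window")
        if self.timepoints_h is None:
            self.timepoints_h = tuple(
                DEFAULT_TIMEPOINTS[i % len(DEFAULT_TIMEPOINTS)] for i in range(self.n_datasets)
            )


@dataclass
class SimTruth:
    status: pd.DataFrame          # gene x dataset status table
    planted: pd.DataFrame         # gene, hexamer, offset, chrom, start, end, strand
    states: pd.DataFrame | None   # chrom, start, end, state
    peaks: pd.DataFrame | None    # chrom, start, end, centered


@dataclass
class SimData:
    config: SimConfig
    genome: dict[str, str]
    promoters: list[PromoterRecord]
    datasets: list[DatasetDEG]
    peaks: IntervalSet | None
    states: IntervalSet | None
    truth: SimTruth


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Codes 0..3 at P(A)=P(T)=(1-gc)/2, P(C)=P(G)=gc/2."""
    cum = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.searchsorted(cum, rng.random(n) * cum[-1], side="right").clip(0, 3)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _draw_statuses(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_genes, n_datasets) array over {'up','down','none'} with latent persistence."""
    marg = np.array([cfg.frac_up, cfg.frac_down, 1 - cfg.frac_up - cfg.frac_down])
    cum = np.cumsum(marg)
    labels = np.array(["up", "down", "none"])
    latent = np.searchsorted(cum, rng.random(cfg.n_genes), side="right").clip(0, 2)
    out = np.empty((cfg.n_genes, cfg.n_datasets), dtype=object)
    for d in range(cfg.n_datasets):
        keep = rng.random(cfg.n_genes) < cfg.deg_overlap
        fresh = np.searchsorted(cum, rng.random(cfg.n_genes), side="right").clip(0, 2)
        out[:, d] = labels[np.where(keep, latent, fresh)]
    return out


def _window_blocks(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[int, int, str]]:
    """Chromatin-state blocks tiling one promoter window (local coords)."""
    sc = cfg.state_cfg
    assert sc is not None
    freqs = np.asarray(sc.state_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    cum = np.cumsum(freqs)
    blocks = []
    pos = 0
    while pos < cfg.window_len:
        length = max(20, int(rng.geometric(1.0 / sc.mean_block_len)))
        length = min(length, cfg.window_len - pos)
        state = str(1 + int(np.searchsorted(cum, rng.random(), side="right").clip(0, 8)))
        blocks.append((pos, pos + length, state))
        pos += length
    return blocks


def simulate(cfg: SimConfig, outdir: str | Path | None = None) -> SimData:
    """Generate a full synthetic input bundle; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.window_len
    statuses = _draw_statuses(cfg, rng)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]

    # foreground membership per planted motif: target status in >= 1 dataset
    fg_mask = {
        m.hexamer: np.any(statuses == m.target_status, axis=1) for m in cfg.planted_motifs
    }

    chrom = "chr1"
    genome_parts: list[str] = []
    pos = 0
    promoters: list[PromoterRecord] = []
    gff_rows: list[tuple[int, int, str, str]] = []
    planted_rows = []
    state_rows: list[tuple[str, int, int, str]] = []

    for i, gid in enumerate(gene_ids):
        strand = "+" if i % 2 == 0 else "-"
        spacer = _codes_to_str(_rand_bases(rng, _SPACER, cfg.gc_content))
        body = _codes_to_str(_rand_bases(rng, _BODY, cfg.gc_content))

        # window sequence, 5'->3' on the gene strand
        if cfg.state_cfg is not None:
            blocks = _window_blocks(cfg, rng)
            parts = []
            for s, e, st in blocks:
                gc = cfg.state_cfg.comp_bias.get(st, cfg.gc_content)
                parts.append(_rand_bases(rng, e - s, gc))
            codes = np.concatenate(parts)
        else:
            blocks = []
            codes = _rand_bases(rng, L, cfg.gc_content)
        window = list(_codes_to_str(codes))

        # plant motifs (replacement, keeps window length)
        gene_plants = []
        for m in cfg.planted_motifs:
            p = m.p_fg if fg_mask[m.hexamer][i] else m.p_bg
            if rng.random() < p:
                off = int(rng.integers(0, L - len(m.hexamer) + 1))
                window[off : off + len(m.hexamer)] = list(m.hexamer)
                gene_plants.append((m.hexamer, off))
        window_seq = "".join(window)

        # genomic placement: [spacer][window][body] (+) / [spacer][body][window] (-)
        if strand == "+":
            w0 = pos + _SPACER
            genome_parts.extend([spacer, window_seq, body])
            tss0 = w0 + L - 1
            gff_rows.append((tss0 + 1, tss0 + _BODY, strand, gid))
        else:
            w0 = pos + _SPACER + _BODY
            genome_parts.extend([spacer, body, reverse_complement(window_seq)])
            tss0 = w0
            gff_rows.append((pos + _SPACER + 1, tss0 + 1, strand, gid))
        promoters.append(
            PromoterRecord(gene_id=gid, seq=window_seq, chrom=chrom, strand=strand,
                           start=w0, end=w0 + L)
        )
        for hexamer, off in gene_plants:
            if strand == "+":
                gs = w0 + off
            else:
                gs = w0 + L - off - len(hexamer)
            planted_rows.append(
                dict(gene_id=gid, hexamer=hexamer, offset=off, chrom=chrom,
                     start=gs, end=gs + len(hexamer), strand=strand)
            )
        for s, e, st in blocks:
            if strand == "+":
                state_rows.append((chrom, w0 + s, w0 + e, st))
            else:
                state_rows.append((chrom, w0 + L - e, w0 + L - s, st))
        pos += _SPACER + L + _BODY

    genome = {chrom: "".join(genome_parts)}

    # DEG datasets with synthesised effect sizes consistent with each status
    datasets = []
    universe = set(gene_ids)
    lfc_tables = []
    for d in range(cfg.n_datasets):
        col = statuses[:, d]
        lfc = np.where(
            col == "up", rng.uniform(np.log2(1.6), 3.0, cfg.n_genes),
            np.where(col == "down", -rng.uniform(np.log2(1.6), 3.0, cfg.n_genes),
                     rng.uniform(-0.3, 0.3, cfg.n_genes)),
        )
        adj_p = np.where(
            col == "none", rng.uniform(0.06, 1.0, cfg.n_genes),
            rng.uniform(1e-6, 0.04, cfg.n_genes),
        )
        did = f"ds{d:02d}"
        datasets.append(
            DatasetDEG(
                dataset_id=did, status=dict(zip(gene_ids, col)), universe=universe,
                timepoint_h=cfg.timepoints_h[d],
            )
        )
        lfc_tables.append(pd.DataFrame(
            dict(gene_id=gene_ids, status=col, lfc=np.round(lfc, 4), adj_p=adj_p)
        ))

    peaks = None
    peaks_df = None
    if cfg.peak_cfg is not None:
        peaks, peaks_df = _make_peaks(cfg.peak_cfg, planted_rows, len(genome[chrom]), chrom, rng)

    states = None
    states_df = None
    if cfg.state_cfg is not None:
        state_rows.sort(key=lambda r: r[1])
        states = IntervalSet(intervals=state_rows, name="chromatin_states")
        states_df = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"])

    truth = SimTruth(
        status=pd.DataFrame(statuses, index=gene_ids,
                            columns=[d.dataset_id for d in datasets]),
        planted=pd.DataFrame(
            planted_rows,
            columns=["gene_id", "hexamer", "offset", "chrom", "start", "end", "strand"],
        ),
        states=states_df,
        peaks=peaks_df,
    )
    data = SimData(config=cfg, genome=genome, promoters=promoters, datasets=datasets,
                   peaks=peaks, states=states, truth=truth)
    if outdir is not None:
        _write_bundle(data, lfc_tables, Path(outdir))
    return data


def _make_peaks(pc, planted_rows, chrom_len, chrom, rng):
    n_centered = int(round(pc.frac_centered * pc.n_peaks)) if planted_rows else 0
    rows = []
    if n_centered:
        idx = rng.integers(0, len(planted_rows), n_centered)
        for j in idx:
            r = planted_rows[int(j)]
            mid = (r["start"] + r["end"]) // 2
            s = max(0, mid - pc.width // 2)
            rows.append((chrom, s, min(chrom_len, s + pc.width), True))
    for _ in range(pc.n_peaks - n_centered):
        s = int(rng.integers(0, max(1, chrom_len - pc.width)))
        rows.append((chrom, s, min(chrom_len, s + pc.width), False))
    ivs = IntervalSet(
        intervals=[(c, s, e, "peak") for c, s, e, _ in rows], name="peaks"
    )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "centered"])
    return ivs, df


def _write_bundle(data: SimData, lfc_tables, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in data.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_promoters_fasta(data.promoters, outdir / "promoters.fa")
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for p in data.promoters:
            if p.strand == "+":
                start, end = p.end, p.end + _BODY - 1  # 1-based inclusive
            else:
                start, end = p.start - _BODY + 1, p.start + 1
            fh.write(
                f"{p.chrom}\tcishex_sim\tgene\t{start}\t{end}\t.\t{p.strand}\t.\tID={p.gene_id}\n"
            )
    manifest = []
    for d, table in zip(data.datasets, lfc_tables):
        fname = f"deg_{d.dataset_id}.tsv"
        table.to_csv(outdir / fname, sep="\t", index=False)
        manifest.append(dict(dataset_id=d.dataset_id, path=fname, timepoint_h=d.timepoint_h))
    pd.DataFrame(manifest).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    with open(outdir / "universe.txt", "w") as fh:
        fh.write("\n".join(p.gene_id for p in data.promoters) + "\n")
    if data.peaks is not None:
        write_bed(data.peaks, outdir / "peaks.bed")
    if data.states is not None:
        write_bed(data.states, outdir / "states.bed")
    data.truth.status.to_csv(outdir / "truth_status.tsv", sep="\t")
    data.truth.planted.to_csv(outdir / "truth_planted.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(data.config), fh, indent=2, default=list)


def expected_presence_rate(
    p_plant: float, window_len: int, hexamer: str, gc: float = 0.25 * 2
) -> float:
    """Probability a promoter contains the canonical hexamer at least once.

    Combines the planting probability with the chance of a background hit,
    approximating windows as independent: P(background hit) = 1 - (1-q)^(L-5)
    where q sums the per-window match probability of both pair members (once
    for a palindrome) under the base-composition model.
    """
    from .hexamers import canonicalize

    c = canonicalize(hexamer)
    p_base = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}

    def word_prob(w: str) -> float:
        out = 1.0
        for ch in w:
            out *= p_base[ch]
        return out

    q = word_prob(c.seq)
    if not c.is_palindrome:
        q += word_prob(reverse_complement(c.seq))
    n_windows = max(0, window_len - len(hexamer) + 1)
    p_bg = 1.0 - (1.0 - q) ** n_windows
    return 1.0 - (1.0 - p_plant) * (1.0 - p_bg)
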