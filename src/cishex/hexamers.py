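"""Canonical hexamer algebra and sequence scanning.

A hexamer and its reverse complement are treated as one unit (binding is
strand-symmetric), collapsing the 4096 possible 6-mers into 2080 canonical
classes: 2016 complementary pairs plus 64 palindromes.  All scanning counts
every 6-bp start position (overlaps included); windows containing ``N`` — or
lowercase/masked letters when ``respect_mask`` is on — are excluded from both
the hit counts and the total number of scorable positions, so occupancy
proportions stay comparable between masked and unmasked runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

K = 6
N_KMERS = 4**K
N_CANONICAL = 2080

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_CHARS = frozenset("ACGTNacgtn")

# per-byte lookup tables for the numpy scanning path
_CODE = np.full(256, -1, dtype=np.int32)  # -1 = always invalid (incl. N)
_MASKED = np.zeros(256, dtype=bool)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
    _MASKED[ord(_b.lower())] = True


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside A,C,G,T,N."""


def reverse_complement(s: str) -> str:
    """Reverse complement of a nucleotide string; case is preserved, N maps to N."""
    if not set(s) <= _VALID_CHARS:
        bad = sorted(set(s) - _VALID_CHARS)
        raise InvalidSequenceError(f"non-nucleotide characters: {bad!r}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class CanonicalHexamer:
    """Representative of a reverse-complement pair of 6-mers.

    ``seq`` is the lexicographically smaller member of the pair; a palindrome
    (e.g. the G-box CACGTG) is its own reverse complement.
    """

    seq: str
    is_palindrome: bool = field(compare=False)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.seq


def canonicalize(h: str) -> CanonicalHexamer:
    """Map a hexamer to its canonical (strand-collapsed) representative."""
    h = h.upper()
    if len(h) != K or not set(h) <= set("ACGT"):
        raise InvalidSequenceError(f"not a hexamer over ACGT: {h!r}")
    rc = reverse_complement(h)
    return CanonicalHexamer(seq=min(h, rc), is_palindrome=(h == rc))


def _code_to_seq(code: int) -> str:
    bases = "ACGT"
    return "".join(bases[(code >> (2 * (K - 1 - j))) & 3] for j in range(K))


@lru_cache(maxsize=1)
def _canonical_tables() -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """(canon_index[4096], palindrome flags[2080], canonical seqs[2080]).

    Codes use 2 bits per base (A=0, C=1, G=2, T=3), most-significant first,
    so integer order on codes equals lexicographic order on sequences.
    """
    codes = np.arange(N_KMERS)
    rc = np.zeros(N_KMERS, dtype=np.int64)
    for j in range(K):
        digit = (codes >> (2 * j)) & 3  # j-th base from the right
        rc |= (3 - digit) << (2 * (K - 1 - j))
    canon_code = np.minimum(codes, rc)
    uniq = np.unique(canon_code)
    index = np.searchsorted(uniq, canon_code).astype(np.int32)
    palindrome = (rc[uniq] == uniq)
    seqs = tuple(_code_to_seq(int(c)) for c in uniq)
    return index, palindrome, seqs


@lru_cache(maxsize=1)
def enumerate_canonical() -> tuple[CanonicalHexamer, ...]:
    """All 2080 canonical hexamers in lexicographic order of their representative."""
    _, palindrome, seqs = _canonical_tables()
    return tuple(
        CanonicalHexamer(seq=s, is_palindrome=bool(p)) for s, p in zip(seqs, palindrome)
    )


def canonical_index(h: str) -> int:
    """Position of a hexamer's canonical class in ``enumerate_canonical()``."""
    code = 0
    for ch in h.upper():
        code = (code << 2) | "ACGT".index(ch)
    index, _, _ = _canonical_tables()
    return int(index[code])


@dataclass
class ScanResult:
    """Canonical-hexamer content of one sequence."""

    presence: set[str]
    position_counts: dict[str, int]
    total_positions: int


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[arr], _MASKED[arr]


def _window_counts(codes: np.ndarray, invalid: np.ndarray) -> tuple[np.ndarray, int]:
    """Counts per canonical class (length 2080) and number of valid windows."""
    index, _, _ = _canonical_tables()
    n = codes.shape[0]
    if n < K:
        return np.zeros(N_CANONICAL, dtype=np.int64), 0
    wcodes = np.zeros(n - K + 1, dtype=np.int64)
    bad = np.zeros(n - K + 1, dtype=bool)
    safe = np.where(invalid, 0, codes)
    for j in range(K):
        wcodes |= safe[j : n - K + 1 + j].astype(np.int64) << (2 * (K - 1 - j))
        bad |= invalid[j : n - K + 1 + j]
    valid_codes = wcodes[~bad]
    counts = np.bincount(index[valid_codes], minlength=N_CANONICAL)
    return counts, int(valid_codes.shape[0])


def scan_sequence(seq: str, respect_mask: bool = False) -> ScanResult:
    """Slide a 6-bp window over every start position of ``seq``.

    Each valid window is counted under its canonical hexamer.  Windows that
    touch an N (or a lowercase base when ``respect_mask``) are dropped from
    both the counts and ``total_positions``.
    """
    if not seq:
        raise InvalidSequenceError("empty sequence")
    if not set(seq) <= _VALID_CHARS:
        bad = sorted(set(seq) - _VALID_CHARS)
        raise InvalidSequenceError(f"non-nucleotide characters: {bad!r}")
    codes, masked = _encode(seq)
    invalid = codes < 0
    if respect_mask:
        invalid = invalid | masked
    counts, total = _window_counts(codes, invalid)
    _, _, seqs = _canonical_tables()
    nz = np.nonzero(counts)[0]
    position_counts = {seqs[i]: int(counts[i]) for i in nz}
    return ScanResult(
        presence=set(position_counts), position_counts=position_counts, total_positions=total
    )


def count_occurrences(
    seqs: Iterable[str], respect_mask: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence canonical occupancy: (counts[n_seqs, 2080], totals[n_seqs])."""
    counts = []
    totals = []
    for s in seqs:
        if s and not set(s) <= _VALID_CHARS:
            bad = sorted(set(s) - _VALID_CHARS)
            raise InvalidSequenceError(f"non-nucleotide characters: {bad!r}")
        codes, masked = _encode(s) if s else (np.empty(0, np.int32), np.empty(0, bool))
        invalid = codes < 0
        if respect_mask:
            invalid = invalid | masked
        c, t = _window_counts(codes, invalid)
        counts.append(c)
        totals.append(t)
    if not counts:
        return np.zeros((0, N_CANONICAL), dtype=np.int64), np.zeros(0, dtype=np.int64)
    return np.asarray(counts), np.asarray(totals, dtype=np.int64)


@dataclass
class PresenceMatrix:
    """Gene-by-feature boolean presence, the unit the association stage consumes.

    ``features`` are canonical hexamer strings here, but the association and
    permutation machinery accepts any labelled boolean features (e.g. the nine
    chromatin states).
    """

    gene_ids: tuple[str, ...]
    features: tuple[str, ...]
    matrix: np.ndarray  # bool, shape (len(gene_ids), len(features))

    def to_sets(self) -> dict[str, set[str]]:
        feats = np.asarray(self.features, dtype=object)
        return {
            g: set(feats[self.matrix[i]]) for i, g in enumerate(self.gene_ids)
        }

    @classmethod
    def from_sets(
        cls, sets: Mapping[str, Iterable[str]], features: Sequence[str] | None = None
    ) -> "PresenceMatrix":
        genes = tuple(sets)
        if features is None:
            features = sorted({f for s in sets.values() for f in s})
        features = tuple(features)
        pos = {f: j for j, f in enumerate(features)}
        mat = np.zeros((len(genes), len(features)), dtype=bool)
        for i, g in enumerate(genes):
            for f in sets[g]:
                mat[i, pos[f]] = True
        return cls(gene_ids=genes, features=features, matrix=mat)


def scan_promoters(promoters, respect_mask: bool = False) -> PresenceMatrix:
    """Presence matrix over all 2080 canonical hexamers for a promoter list."""
    gene_ids = [p.gene_id for p in promoters]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in promoter list")
    counts, _ = count_occurrences((p.seq for p in promoters), respect_mask=respect_mask)
    _, _, seqs = _canonical_tables()
    return PresenceMatrix(
        gene_ids=tuple(gene_ids), features=seqs, matrix=counts > 0
    )


def presence_matrix(promoters, respect_mask: bool = False) -> dict[str, set[str]]:
    """Per-gene set of canonical hexamers occurring at least once in the promoter."""
    return scan_promoters(promoters, respect_mask=respect_mask).to_sets()
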