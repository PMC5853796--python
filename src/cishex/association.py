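"""Per-dataset Fisher association tests and Fisher's-method meta-combination.

For every feature (canonical hexamer, or any labelled presence indicator such
as a chromatin state) and each regulation status, each dataset contributes a
2x2 contingency table — feature presence in the upstream region against the
gene being up- (down-) regulated — scored with the one-sided Fisher exact
test for over-representation.  The k per-dataset p-values are combined with
Fisher's method, chi2 = -2 * sum(ln p_i) on 2k degrees of freedom, and the
meta p-values are Bonferroni-corrected over all (feature, status) tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hexamers import PresenceMatrix
from .io import DatasetDEG

DEFAULT_ALPHA = 0.005


@dataclass
class ContingencyTable:
    """Counts: a = feature+/DEG+, b = feature+/DEG-, c = feature-/DEG+, d = rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class MetaResult:
    feature: str
    status: str
    k: int
    chi2: float
    dof: int
    meta_p: float
    bonferroni_p: float
    selected: bool = False


def contingency(presence: set, deg: set, universe: set) -> ContingencyTable:
    """2x2 table of feature presence against differential expression."""
    if not presence <= universe or not deg <= universe:
        raise ValueError("presence and deg sets must lie inside the universe")
    a = len(presence & deg)
    b = len(presence) - a
    c = len(deg) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_one_sided(t: ContingencyTable) -> float:
    """Exact upper-tail (over-representation) Fisher p-value, P(X >= a).

    The tail is the hypergeometric survival function at a-1 given the table's
    margins.  An all-zero table carries no information and returns 1.
    """
    if t.n == 0:
        return 1.0
    return float(stats.hypergeom.sf(t.a - 1, t.n, t.a + t.b, t.a + t.c))


def fisher_method(pvals: Sequence[float]) -> tuple[float, int, float]:
    """Combine p-values: (chi2, dof, meta_p) with chi2 = -2*sum(ln p), dof = 2k."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    chi2 = float(-2.0 * np.sum(np.log(p)))
    dof = 2 * p.size
    meta_p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, meta_p


def bonferroni(p: float, n_tests: int) -> float:
    """min(1, p * n_tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


# ---------------------------------------------------------------------------
# vectorised engine shared with the permutation stage


class AssociationEngine:
    """Precomputed index structures for scoring one presence matrix against datasets.

    Scores all features at once with vectorised hypergeometric tails; the
    permutation stage reuses the same engine so observed and permuted scores
    go through identical arithmetic.
    """

    def __init__(
        self,
        presence: PresenceMatrix | Mapping[str, set],
        datasets: Sequence[DatasetDEG],
        statuses: Sequence[str] = ("up", "down"),
    ):
        if isinstance(presence, Mapping):
            presence = PresenceMatrix.from_sets(presence)
        if not datasets:
            raise ValueError("no datasets supplied")
        self.presence = presence
        self.datasets = list(datasets)
        self.statuses = tuple(statuses)
        self.gene_pos = {g: i for i, g in enumerate(presence.gene_ids)}
        self.X = presence.matrix
        n_genes = len(presence.gene_ids)
        # per (dataset, status): universe row indices, DEG row indices
        self._cells = []
        for d in self.datasets:
            uni = [self.gene_pos[g] for g in d.universe if g in self.gene_pos]
            if not uni:
                raise ValueError(f"dataset {d.dataset_id}: universe shares no genes with promoters")
            uni_arr = np.asarray(sorted(uni), dtype=np.intp)
            full = len(uni_arr) == n_genes
            for s in self.statuses:
                deg = [self.gene_pos[g] for g in d.genes_with(s) if g in self.gene_pos]
                self._cells.append(
                    dict(dataset=d, status=s, universe=uni_arr, full=full,
                         deg=np.asarray(sorted(deg), dtype=np.intp))
                )
        # presence margins on the identity assignment (valid for any permutation
        # when the universe is the full promoter set)
        for cell in self._cells:
            cell["K"] = self.X[cell["universe"]].sum(axis=0)
            cell["N"] = len(cell["universe"])
            cell["n_deg"] = len(cell["deg"])

    @property
    def all_full_universe(self) -> bool:
        return all(c["full"] for c in self._cells)

    def pvalues(self, perm: np.ndarray | None = None) -> np.ndarray:
        """One-sided Fisher p per (cell, feature); perm maps gene row -> promoter row."""
        out = np.empty((len(self._cells), self.X.shape[1]))
        for i, cell in enumerate(self._cells):
            if perm is None:
                deg_rows = cell["deg"]
                K = cell["K"]
            else:
                deg_rows = perm[cell["deg"]]
                K = cell["K"] if cell["full"] else self.X[perm[cell["universe"]]].sum(axis=0)
            a = self.X[deg_rows].sum(axis=0) if deg_rows.size else np.zeros(self.X.shape[1], int)
            out[i] = stats.hypergeom.sf(a - 1, cell["N"], K, cell["n_deg"])
        return out

    def meta(self, pvals: np.ndarray) -> dict[str, tuple[np.ndarray, int]]:
        """Per status: (chi2 vector over features, k datasets combined)."""
        out = {}
        for s in self.statuses:
            rows = [i for i, c in enumerate(self._cells) if c["status"] == s]
            chi2 = -2.0 * np.sum(np.log(np.maximum(pvals[rows], np.finfo(float).tiny)), axis=0)
            out[s] = (chi2, len(rows))
        return out


def run_association(
    presence: PresenceMatrix | Mapping[str, set],
    datasets: Sequence[DatasetDEG],
    statuses: Sequence[str] = ("up", "down"),
    alpha: float = DEFAULT_ALPHA,
    n_tests: int | None = None,
) -> list[MetaResult]:
    """Full association + meta-analysis over every feature and status.

    ``statuses`` may be ("up", "down") (the default, one meta p per status) or
    ("both",) to pool up- and down-regulated genes into a single DEG set.
    ``n_tests`` defaults to n_features * n_statuses (Bonferroni multiplicity).
    """
    eng = AssociationEngine(presence, datasets, statuses)
    features = eng.presence.features
    if n_tests is None:
        n_tests = len(features) * len(statuses)
    pvals = eng.pvalues()
    metas = eng.meta(pvals)
    results: list[MetaResult] = []
    for s in statuses:
        chi2, k = metas[s]
        meta_p = stats.chi2.sf(chi2, 2 * k)
        bonf = np.minimum(1.0, meta_p * n_tests)
        for j, f in enumerate(features):
            results.append(
                MetaResult(
                    feature=f, status=s, k=k, chi2=float(chi2[j]), dof=2 * k,
                    meta_p=float(meta_p[j]), bonferroni_p=float(bonf[j]),
                    selected=bool(bonf[j] < alpha),
                )
            )
    return results


def results_to_frame(results: Sequence[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(feature=r.feature, status=r.status, k=r.k, chi2=r.chi2, dof=r.dof,
                 meta_p=r.meta_p, bonferroni_p=r.bonferroni_p, selected=r.selected)
            for r in results
        ]
    )
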