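"""Promoter-shuffling permutation test for meta p-values.

Each iteration draws one uniform random bijection mixing promoters between
genes — the same assignment is shared by every feature and every dataset, so
the correlation structure between overlapping hexamers is preserved — and the
whole association + meta computation is re-run.  For each (feature, status)
the empirical significance is P = (m + 1) / (M + 1), where m counts permuted
meta p-values not greater than the observed one among M permutations.

Because scanning is permutation-invariant, mixing promoters is implemented by
permuting the rows of the presence matrix; the result is identical to
re-scanning the shuffled sequences.  The inclusive "not greater than"
comparison is carried out on the chi-squared statistics (same degrees of
freedom on both sides, so the order is the same), with observed and permuted
statistics computed by identical arithmetic so that ties count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .association import DEFAULT_ALPHA, AssociationEngine, MetaResult
from .hexamers import PresenceMatrix
from .io import DatasetDEG

# above this many lookup-table entries, fall back to direct scoring
_TABLE_BUDGET = 50_000_000

_LOG_TINY = np.log(np.finfo(float).tiny)


@dataclass
class PermutationResult:
    feature: str
    status: str
    meta_p: float
    m: int
    M: int
    perm_p: float
    bonferroni_perm_p: float
    selected: bool = False


def permute_assignment(
    gene_ids: Sequence[str], rng_seed: int | np.random.Generator
) -> dict[str, str]:
    """Uniform random bijection gene -> gene (whose promoter it receives)."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ids = list(gene_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("gene ids must be distinct")
    perm = rng.permutation(len(ids))
    return {ids[i]: ids[perm[i]] for i in range(len(ids))}


def _draw_permutation(rng: np.random.Generator, n: int) -> np.ndarray:
    """One shared promoter permutation per iteration (row index map)."""
    return rng.permutation(n)


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _log_sf_tables(eng: AssociationEngine) -> list[np.ndarray] | None:
    """Per cell, ln P(X >= a) of the hypergeometric tail, indexed [feature, a].

    Valid when every dataset universe equals the promoter set: the presence
    margins K are then permutation-invariant and only a — the number of DEGs
    whose (shuffled) promoter carries the feature — moves between iterations.
    """
    if not eng.all_full_universe:
        return None
    total = sum((c["n_deg"] + 1) * eng.X.shape[1] for c in eng._cells)
    if total > _TABLE_BUDGET:
        return None
    tables = []
    for cell in eng._cells:
        N, n = cell["N"], cell["n_deg"]
        K = cell["K"][:, None].astype(float)
        a = np.arange(n + 1, dtype=float)[None, :]
        with np.errstate(invalid="ignore"):
            logpmf = (
                _log_comb(K, a) + _log_comb(N - K, n - a) - _log_comb(float(N), float(n))
            )
        logpmf = np.where((a <= K) & (n - a <= N - K), logpmf, -np.inf)
        pmf = np.exp(logpmf)
        sf = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
        tables.append(np.log(np.maximum(np.minimum(sf, 1.0), np.finfo(float).tiny)))
    return tables


def _logp_from_tables(
    eng: AssociationEngine, tables: list[np.ndarray], perm: np.ndarray | None
) -> np.ndarray:
    F = eng.X.shape[1]
    cols = np.arange(F)
    out = np.empty((len(eng._cells), F))
    for i, cell in enumerate(eng._cells):
        rows = cell["deg"] if perm is None else perm[cell["deg"]]
        a = eng.X[rows].sum(axis=0) if rows.size else np.zeros(F, dtype=np.intp)
        out[i] = tables[i][cols, a]
    return out


def _chi2_by_status(eng: AssociationEngine, logp: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for s in eng.statuses:
        rows = [i for i, c in enumerate(eng._cells) if c["status"] == s]
        out[s] = -2.0 * logp[rows].sum(axis=0)
    return out


def permutation_test(
    presence: PresenceMatrix | Mapping[str, set],
    datasets: Sequence[DatasetDEG],
    observed: Sequence[MetaResult],
    M: int = 1000,
    rng_seed: int = 0,
    statuses: Sequence[str] | None = None,
    n_tests: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    null: str = "per_feature",
) -> list[PermutationResult]:
    """Empirical significance of observed meta p-values under promoter shuffling.

    ``n_tests`` is the Bonferroni multiplicity applied to the permutation
    p-values (default: features x statuses).  ``null`` chooses the reference
    distribution for each observed meta p-value: ``"per_feature"`` compares
    it against the M permuted meta p-values of the same (feature, status)
    only; ``"pooled"`` compares it against the permuted meta p-values of
    every (feature, status), giving a common null with M x features x
    statuses draws and a correspondingly finer resolution (the reported ``M``
    and the (m+1)/(M+1) formula refer to that pooled count).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if null not in ("per_feature", "pooled"):
        raise ValueError(f"unknown null mode {null!r}")
    if statuses is None:
        statuses = tuple(dict.fromkeys(r.status for r in observed))
    eng = AssociationEngine(presence, datasets, statuses)
    features = eng.presence.features
    if n_tests is None:
        n_tests = len(features) * len(statuses)
    obs = {(r.feature, r.status): r.meta_p for r in observed}
    missing = [(f, s) for s in statuses for f in features if (f, s) not in obs]
    if missing:
        raise ValueError(f"observed results missing {len(missing)} (feature, status) pairs")

    tables = _log_sf_tables(eng)
    if tables is not None:
        obs_logp = _logp_from_tables(eng, tables, None)
    else:
        obs_logp = np.log(np.maximum(eng.pvalues(None), np.finfo(float).tiny))
    obs_chi2 = _chi2_by_status(eng, obs_logp)
    dof = {s: 2 * sum(1 for c in eng._cells if c["status"] == s) for s in statuses}
    pooled = null == "pooled"
    if pooled:
        from scipy import stats as _st

        obs_meta = {s: _st.chi2.sf(obs_chi2[s], dof[s]) for s in statuses}
        obs_flat = np.concatenate([obs_meta[s] for s in statuses])

    rng = np.random.default_rng(rng_seed)
    n_genes = len(eng.presence.gene_ids)
    m_counts = {s: np.zeros(len(features), dtype=np.int64) for s in statuses}
    m_pooled = np.zeros(len(features) * len(statuses), dtype=np.int64)
    for _ in range(M):
        perm = _draw_permutation(rng, n_genes)
        if tables is not None:
            logp = _logp_from_tables(eng, tables, perm)
        else:
            logp = np.log(np.maximum(eng.pvalues(perm), np.finfo(float).tiny))
        chi2 = _chi2_by_status(eng, logp)
        if pooled:
            from scipy import stats as _st

            perm_meta = np.concatenate([_st.chi2.sf(chi2[s], dof[s]) for s in statuses])
            perm_meta.sort()
            # number of permuted meta p-values not greater than each observed
            m_pooled += np.searchsorted(perm_meta, obs_flat, side="right")
        else:
            for s in statuses:
                # perm meta_p <= observed meta_p  <=>  perm chi2 >= observed chi2
                m_counts[s] += chi2[s] >= obs_chi2[s]

    results = []
    denom = M * len(features) * len(statuses) if pooled else M
    for si, s in enumerate(statuses):
        for j, f in enumerate(features):
            if pooled:
                m = int(m_pooled[si * len(features) + j])
            else:
                m = int(m_counts[s][j])
            perm_p = (m + 1) / (denom + 1)
            bonf = min(1.0, perm_p * n_tests)
            results.append(
                PermutationResult(
                    feature=f, status=s, meta_p=float(obs[(f, s)]), m=m, M=denom,
                    perm_p=perm_p, bonferroni_perm_p=bonf, selected=bonf < alpha,
                )
            )
    return results


def two_stage_selection(
    presence: PresenceMatrix | Mapping[str, set],
    datasets: Sequence[DatasetDEG],
    M: int = 1000,
    rng_seed: int = 0,
    statuses: Sequence[str] = ("up", "down"),
    alpha: float = DEFAULT_ALPHA,
    n_tests_meta: int | None = None,
) -> tuple[list[MetaResult], list[PermutationResult], list[PermutationResult]]:
    """The staged selection: meta-analysis screen, then permutation confirmation.

    Stage one Bonferroni-corrects the meta p-values over all features x
    statuses and selects candidates below ``alpha``: this screen carries the
    full family-wise multiplicity.  Stage two validates each candidate
    empirically against the pooled permutation null (all features share one
    empirical null of M x features x statuses draws, which both captures the
    inter-dataset correlation the analytic meta p ignores and gives the
    resolution a desk-scale M cannot reach per feature), Bonferroni-corrects
    the permutation p-values with the same features-x-statuses multiplicity
    as the screen, and confirms the candidates that stay below ``alpha``.
    Returns (meta results, permutation results, confirmed selections).
    """
    from .association import run_association

    meta = run_association(presence, datasets, statuses=statuses, alpha=alpha,
                           n_tests=n_tests_meta)
    candidates = {(r.feature, r.status) for r in meta if r.selected}
    perm = permutation_test(
        presence, datasets, meta, M=M, rng_seed=rng_seed, statuses=statuses,
        n_tests=n_tests_meta, alpha=alpha, null="pooled",
    )
    confirmed = [
        r for r in perm if (r.feature, r.status) in candidates and r.bonferroni_perm_p < alpha
    ]
    confirmed.sort(key=lambda r: (r.perm_p, r.feature))
    return meta, perm, confirmed


def select_significant(
    results: Sequence[PermutationResult], alpha: float = DEFAULT_ALPHA
) -> list[PermutationResult]:
    """Results with Bonferroni-corrected permutation p strictly below alpha."""
    kept = [r for r in results if r.bonferroni_perm_p < alpha]
    return sorted(kept, key=lambda r: (r.perm_p, r.feature))


def permutation_to_frame(results: Sequence[PermutationResult]) -> pd.DataFrame:
    cols = ["feature", "status", "meta_p", "m", "M", "perm_p", "bonferroni_perm_p", "selected"]
    return pd.DataFrame(
        [
            dict(feature=r.feature, status=r.status, meta_p=r.meta_p, m=r.m, M=r.M,
                 perm_p=r.perm_p, bonferroni_perm_p=r.bonferroni_perm_p, selected=r.selected)
            for r in results
        ],
        columns=cols,
    )
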