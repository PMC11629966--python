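"""Two-stage permutation inference for concordant biomarker detection.

Stage 1 (global test): for every gene, test H0 "no study pair is positively
concordant" against HA "some pair is" with the gMI+ statistic, a pooled
permutation null (class labels shuffled within each study, the same shuffle
applied to every gene so gene-gene dependence is preserved) and
Benjamini-Hochberg q-values.

Stage 2 (post hoc): for genes rejected in stage 1, test every study pair
with the MI+ statistic and extract the largest subset of studies in which
every pair is significantly concordant — a maximum clique in the pairwise
significance graph.

The permutation machinery is vectorized over genes: class membership is a
one-hot matrix per study, so per-class means and second moments for all
genes are two matrix products per study and permutation, and the pairwise
MCC matrix, gMI+, min-MCC and per-pair MI+ all derive from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .core_stats import StudyData, _check_weights, _clip_rho, _logdet_clipped, _one_sided, mi_plus

__all__ = [
    "PermutationNull",
    "GlobalTestResult",
    "permute_labels",
    "null_distribution",
    "pooled_p",
    "bh_q",
    "global_test",
    "posthoc_pairwise",
    "concordant_subsets",
    "discordant_filter",
]


@dataclass(eq=False)
class PermutationNull:
    """Matrix of permuted statistics, shape ``(G, B)``."""

    matrix: np.ndarray
    statistic: str
    seed: int | None = None

    @property
    def n_genes(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_permutations(self) -> int:
        return int(self.matrix.shape[1])


@dataclass(eq=False)
class GlobalTestResult:
    """Stage-1 output: observed statistics, permutation p-values, q-values."""

    statistic: str
    observed: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray
    null: PermutationNull | None = None


# ---------------------------------------------------------------------------
# dataset plumbing


class _Prepared:
    """Per-study arrays shared by all permutation work.

    values: (G, n_s) per study; onehot: (n_s, K); counts: (K,).
    """

    def __init__(self, studies: Sequence[StudyData], weights=None):
        if len(studies) < 2:
            raise ValueError("need at least two studies")
        cls = studies[0].classes
        for s in studies[1:]:
            if not np.array_equal(s.classes, cls):
                raise ValueError(
                    f"studies {studies[0].study!r} and {s.study!r} have "
                    f"different class sets"
                )
        self.classes = cls
        self.K = len(cls)
        self.S = len(studies)
        self.names = [s.study for s in studies]
        self.values = [np.atleast_2d(s.values) for s in studies]
        G = {v.shape[0] for v in self.values}
        if len(G) != 1:
            raise ValueError(f"studies carry different gene counts: {sorted(G)}")
        self.G = G.pop()
        self.onehot = [s.onehot(cls) for s in studies]
        self.counts = [oh.sum(axis=0) for oh in self.onehot]
        if isinstance(weights, str):
            if weights == "equal":
                weights = None
            elif weights != "observed":
                raise ValueError(f"unknown weight mode {weights!r}")
        if weights == "observed":
            # pooled class proportions per study pair (common vector per pair
            # keeps |MCC| <= 1); shape (S, S, K)
            n = np.stack(self.counts)
            pair_n = n[:, None, :] + n[None, :, :]
            self.W = pair_n / pair_n.sum(axis=-1, keepdims=True)
        else:
            w = _check_weights(weights, self.K)
            self.W = np.broadcast_to(w, (self.S, self.S, self.K))

    def rho(self, perms: Sequence[np.ndarray] | None = None) -> np.ndarray:
        """Pairwise MCC matrix for all genes, shape (G, S, S).

        ``perms`` optionally gives a row permutation of each study's one-hot
        matrix (i.e. a label shuffle applied to every gene of that study).
        """
        means = np.empty((self.G, self.S, self.K))
        m2 = np.empty((self.G, self.S, self.K))
        for s in range(self.S):
            oh = self.onehot[s] if perms is None else self.onehot[s][perms[s]]
            inv = oh / self.counts[s]
            means[:, s, :] = self.values[s] @ inv
            m2[:, s, :] = self.values[s] ** 2 @ inv
        # pair-weighted mixture moments: mu[g,i,j] is study i's mixture mean
        # under the (i, j) pair weights
        mu = np.einsum("ijk,gik->gij", self.W, means)
        var = np.einsum("ijk,gik->gij", self.W, m2) - mu**2
        var = np.maximum(var, 0.0)
        cross = np.einsum("ijk,gik,gjk->gij", self.W, means, means)
        num = cross - mu * np.swapaxes(mu, 1, 2)
        den = np.sqrt(var * np.swapaxes(var, 1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        rho = _clip_rho(rho)
        idx = np.arange(self.S)
        rho[:, idx, idx] = 1.0
        return rho

    def draw_perms(self, rng: np.random.Generator) -> list[np.ndarray]:
        return [rng.permutation(oh.shape[0]) for oh in self.onehot]


def _stat_from_rho(rho: np.ndarray, statistic) -> np.ndarray:
    """Evaluate a statistic name (or ('mi_plus', i, j) tuple) on (G, S, S) rho."""
    S = rho.shape[-1]
    if statistic == "gmi_plus":
        return np.maximum(-0.5 * _logdet_clipped(_one_sided(rho.copy())), 0.0)
    if statistic == "min_mcc":
        iu, ju = np.triu_indices(S, k=1)
        return rho[:, iu, ju].min(axis=-1)
    if isinstance(statistic, tuple) and statistic[0] == "mi_plus":
        _, i, j = statistic
        return np.asarray(mi_plus(rho[:, i, j]))
    raise ValueError(f"unknown statistic {statistic!r}")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# spec operations


def permute_labels(
    studies: Sequence[StudyData], rng: np.random.Generator | int | None = None
) -> list[StudyData]:
    """Shuffle class labels within each study independently.

    The label multiset of each study is preserved, and because labels are
    per-study (shared by all genes), the same shuffle applies to every gene,
    preserving the gene-gene dependence structure.
    """
    rng = _as_rng(rng)
    return [
        StudyData(values=s.values, labels=s.labels[rng.permutation(s.n_samples)], study=s.study)
        for s in studies
    ]


def null_distribution(
    studies: Sequence[StudyData],
    statistic="gmi_plus",
    B: int = 500,
    seed: int | np.random.Generator | None = None,
    weights=None,
) -> PermutationNull:
    """Permutation null of a statistic for all genes, shape ``(G, B)``.

    One label shuffle per permutation ``b`` (within each study), the
    statistic recomputed for all genes.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = _as_rng(seed)
    prep = _Prepared(studies, weights)
    out = np.empty((prep.G, B))
    for b in range(B):
        out[:, b] = _stat_from_rho(prep.rho(prep.draw_perms(rng)), statistic)
    name = statistic if isinstance(statistic, str) else "mi_plus"
    return PermutationNull(matrix=out, statistic=name, seed=seed if isinstance(seed, int) else None)


def pooled_p(
    theta: np.ndarray, null: PermutationNull | np.ndarray, pooled: bool = True
) -> np.ndarray:
    """Permutation p-values with inclusive ties.

    Pooled across genes: ``p(theta_g) = (1 + #{(g', b): theta_g'^(b) >=
    theta_g}) / (1 + G B)``, giving resolution ``1 / (1 + G B)``. With
    ``pooled=False`` each gene is ranked only against its own ``B`` permuted
    values.
    """
    mat = null.matrix if isinstance(null, PermutationNull) else np.asarray(null)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if mat.shape[0] != theta.shape[0]:
        raise ValueError("null distribution does not cover the same genes")
    if pooled:
        flat = np.sort(mat, axis=None)
        n_ge = flat.size - np.searchsorted(flat, theta, side="left")
        return (1.0 + n_ge) / (1.0 + flat.size)
    rows = np.sort(mat, axis=1)
    n_ge = np.array(
        [rows.shape[1] - np.searchsorted(rows[g], theta[g], side="left") for g in range(len(theta))]
    )
    return (1.0 + n_ge) / (1.0 + rows.shape[1])


def bh_q(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_i = min{ min_{j >= i} { G p_(j) / j }, 1 }`` over the sorted
    p-values, mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    G = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * G / np.arange(1, G + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(G)
    q[order] = q_sorted
    return q


def global_test(
    studies: Sequence[StudyData],
    B: int = 500,
    seed: int | np.random.Generator | None = None,
    statistic: str = "gmi_plus",
    pooled: bool = True,
    weights=None,
    keep_null: bool = False,
) -> GlobalTestResult:
    """Stage-1 global test: observed statistic, permutation p, BH q per gene."""
    rng = _as_rng(seed)
    prep = _Prepared(studies, weights)
    observed = _stat_from_rho(prep.rho(), statistic)
    null = np.empty((prep.G, B))
    for b in range(B):
        null[:, b] = _stat_from_rho(prep.rho(prep.draw_perms(rng)), statistic)
    p = pooled_p(observed, null, pooled=pooled)
    q = bh_q(p)
    name = statistic if isinstance(statistic, str) else "mi_plus"
    pn = PermutationNull(matrix=null, statistic=name) if keep_null else None
    return GlobalTestResult(statistic=name, observed=observed, pvalues=p, qvalues=q, null=pn)


def posthoc_pairwise(
    studies: Sequence[StudyData],
    genes: np.ndarray | None = None,
    B: int = 500,
    seed: int | np.random.Generator | None = None,
    pooled: bool = True,
    weights=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-2 pairwise MI+ permutation tests.

    Parameters
    ----------
    genes : array of gene indices or boolean mask, optional
        Restricts testing (and the pooled-null gene dimension) to the genes
        that passed stage 1; by default all genes are tested.

    Returns
    -------
    pvalues : ndarray, shape (G_sub, S, S)
        Symmetric per-gene matrix of pairwise p-values (diagonal NaN).
    observed : ndarray, shape (G_sub, S, S)
        Observed pairwise MI+ statistics (diagonal NaN).
    """
    rng = _as_rng(seed)
    if genes is not None:
        genes = np.asarray(genes)
        if genes.dtype == bool:
            genes = np.flatnonzero(genes)
        studies = [
            StudyData(np.atleast_2d(s.values)[genes], s.labels, s.study) for s in studies
        ]
    prep = _Prepared(studies, weights)
    S = prep.S
    iu, ju = np.triu_indices(S, k=1)
    obs_pairs = np.asarray(mi_plus(prep.rho()[:, iu, ju]))
    null = np.empty((prep.G, B, len(iu)))
    for b in range(B):
        null[:, b, :] = mi_plus(prep.rho(prep.draw_perms(rng))[:, iu, ju])

    pvals = np.full((prep.G, S, S), np.nan)
    obs = np.full((prep.G, S, S), np.nan)
    for k in range(len(iu)):
        pk = pooled_p(obs_pairs[:, k], null[:, :, k], pooled=pooled)
        pvals[:, iu[k], ju[k]] = pvals[:, ju[k], iu[k]] = pk
        obs[:, iu[k], ju[k]] = obs[:, ju[k], iu[k]] = obs_pairs[:, k]
    return pvals, obs


def concordant_subsets(
    pmat: np.ndarray, alpha: float = 0.05, labels: Sequence | None = None
) -> list[tuple]:
    """Maximal study subsets in which every pair is significantly concordant.

    Builds the significance graph (edge ``i-j`` iff ``p_ij < alpha``) and
    returns all maximal cliques of size >= 2 as sorted tuples, ordered by
    size descending then lexicographically; the first entry is the largest
    concordant subset (ties broken lexicographically).
    """
    pmat = np.asarray(pmat)
    S = pmat.shape[-1]
    labels = list(range(1, S + 1)) if labels is None else list(labels)
    g = nx.Graph()
    g.add_nodes_from(range(S))
    iu, ju = np.triu_indices(S, k=1)
    for i, j in zip(iu, ju):
        if pmat[i, j] < alpha:
            g.add_edge(int(i), int(j))
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= 2]
    cliques.sort(key=lambda c: (-len(c), c))
    return [tuple(labels[i] for i in c) for c in cliques]


def discordant_filter(
    posthoc_pvalues: np.ndarray,
    concordant_studies: Iterable[int],
    target_study: int,
    p_lo: float = 0.001,
    p_hi: float = 0.5,
) -> np.ndarray:
    """Genes concordant within a study set but discordant with a target study.

    Keeps genes where every pairwise p-value among ``concordant_studies``
    (e.g. immune cell types) is below ``p_lo`` and every p-value between a
    member of the set and ``target_study`` (e.g. tumor) exceeds ``p_hi``.

    Returns a boolean mask over genes.
    """
    inset = sorted(set(int(i) for i in concordant_studies))
    target = int(target_study)
    if target in inset:
        raise ValueError("target study must not be in the concordant set")
    pm = np.asarray(posthoc_pvalues)
    if pm.ndim == 2:
        pm = pm[None]
    iu, ju = np.triu_indices(len(inset), k=1)
    within = pm[:, np.array(inset)[iu], np.array(inset)[ju]]
    to_target = pm[:, inset, target]
    return np.all(within < p_lo, axis=-1) & np.all(to_target > p_hi, axis=-1)
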