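"""Model/results interface for mutual information concordance analysis.

`ConcordanceAnalysis` is built from a multi-study, class-labelled expression
dataset; its :meth:`~ConcordanceAnalysis.fit` runs the two-stage MICA
procedure (global gMI+ permutation test with BH q-values, then post hoc
pairwise MI+ tests and concordant-subset extraction) and returns a
`ConcordanceResults` carrying per-gene statistics, p/q-values, the pairwise
p-value matrices, the detected concordant study subsets and a ``summary()``
table, in the spirit of statsmodels model/results pairs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import inference
from .core_stats import StudyData

__all__ = ["ConcordanceAnalysis", "ConcordanceResults"]


class ConcordanceAnalysis:
    """Concordance model over S class-labelled expression studies.

    Parameters
    ----------
    studies : sequence of StudyData
        One entry per study; ``values`` of shape ``(G, n_s)`` sharing the
        same G genes in the same order, ``labels`` drawn from a class set
        common to all studies.
    gene_ids : sequence of str, optional
        Gene identifiers (defaults to ``gene_0001`` ...).
    weights : {"equal", "observed"} or probability vector
        Class weights of the mixture model. "equal" (the default) weighs
        each class 1/K; "observed" uses the pooled class proportions of
        each study pair.

    Examples
    --------
    >>> model = ConcordanceAnalysis(studies)
    >>> res = model.fit(permutations=500, seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        studies: Sequence[StudyData],
        gene_ids: Sequence[str] | None = None,
        weights="equal",
    ):
        self._prep = inference._Prepared(studies, weights)
        self.studies = list(studies)
        self.weights = weights
        self.n_studies = self._prep.S
        self.n_classes = self._prep.K
        self.n_genes = self._prep.G
        if gene_ids is None:
            width = max(4, len(str(self.n_genes)))
            gene_ids = [f"gene_{i + 1:0{width}d}" for i in range(self.n_genes)]
        if len(gene_ids) != self.n_genes:
            raise ValueError("gene_ids length does not match the gene dimension")
        self.gene_ids = pd.Index(gene_ids, name="gene_id")

    @classmethod
    def from_dataframes(
        cls,
        tables: Mapping[str, pd.DataFrame],
        metadata: pd.DataFrame,
        weights="equal",
    ) -> "ConcordanceAnalysis":
        """Build the model from genes-x-samples tables plus sample metadata.

        ``metadata`` needs columns ``sample``, ``study`` and ``class``; every
        column of every table must appear there exactly once. Gene universes
        are intersected across studies and rows canonicalized (sorted).
        """
        from .io import bundle_from_frames

        bundle = bundle_from_frames(tables, metadata)
        return cls(bundle.studies, gene_ids=bundle.gene_ids, weights=weights)

    def fit(
        self,
        permutations: int = 500,
        seed: int | None = None,
        *,
        statistic: str = "gmi_plus",
        pooled: bool = True,
        q_threshold: float = 0.05,
        posthoc: bool = True,
        alpha_posthoc: float = 0.05,
        posthoc_scope: str = "significant",
        reuse_permutations: bool = False,
    ) -> "ConcordanceResults":
        """Run the two-stage permutation procedure.

        Parameters
        ----------
        permutations : int
            Number of label permutations B per stage.
        seed : int, optional
            Master seed; independent child streams are spawned for the two
            stages, so results are reproducible across machines and
            independent of any parallelism.
        statistic : {"gmi_plus", "min_mcc"}
            Stage-1 statistic; "min_mcc" gives the all-study comparison
            method. Post hoc testing is only meaningful for "gmi_plus".
        pooled : bool
            Pool permuted statistics across genes in the p-value denominator
            (resolution ``1/(1+G B)``); ``False`` ranks each gene against its
            own permutations only.
        q_threshold : float
            BH q-value cutoff defining stage-1 rejections.
        posthoc : bool
            Run stage-2 pairwise tests and subset extraction.
        alpha_posthoc : float
            Raw p-value threshold for an edge in the significance graph.
        posthoc_scope : {"significant", "all"}
            Genes entering stage 2 (and its pooled-null denominator).
        reuse_permutations : bool
            Reuse the stage-1 permutation stream in stage 2 instead of a
            fresh one.
        """
        if statistic not in ("gmi_plus", "min_mcc"):
            raise ValueError(f"unknown statistic {statistic!r}")
        if posthoc_scope not in ("significant", "all"):
            raise ValueError(f"unknown posthoc scope {posthoc_scope!r}")
        ss = np.random.SeedSequence(seed)
        child1, child2 = ss.spawn(2)
        rng1 = np.random.default_rng(child1)
        rng2 = np.random.default_rng(child1 if reuse_permutations else child2)

        stage1 = inference.global_test(
            self.studies,
            B=permutations,
            seed=rng1,
            statistic=statistic,
            pooled=pooled,
            weights=self.weights,
        )
        significant = stage1.qvalues < q_threshold

        S = self.n_studies
        posthoc_p = np.full((self.n_genes, S, S), np.nan)
        posthoc_stat = np.full((self.n_genes, S, S), np.nan)
        subsets: list[list[tuple]] = [[] for _ in range(self.n_genes)]
        if posthoc and statistic == "gmi_plus":
            idx = np.arange(self.n_genes) if posthoc_scope == "all" else np.flatnonzero(significant)
            if idx.size:
                pv, ob = inference.posthoc_pairwise(
                    self.studies,
                    genes=idx,
                    B=permutations,
                    seed=rng2,
                    pooled=pooled,
                    weights=self.weights,
                )
                posthoc_p[idx] = pv
                posthoc_stat[idx] = ob
                for row, g in enumerate(idx):
                    if significant[g]:
                        subsets[g] = inference.concordant_subsets(pv[row], alpha_posthoc)

        return ConcordanceResults(
            model=self,
            statistic_name=statistic,
            statistics=stage1.observed,
            pvalues=stage1.pvalues,
            qvalues=stage1.qvalues,
            posthoc_pvalues=posthoc_p,
            posthoc_statistics=posthoc_stat,
            subsets=subsets,
            n_permutations=permutations,
            seed=seed,
            pooled=pooled,
            q_threshold=q_threshold,
            alpha_posthoc=alpha_posthoc,
        )


class ConcordanceResults:
    """Per-gene results of a fitted concordance analysis.

    Attributes
    ----------
    statistics, pvalues, qvalues : ndarray, shape (G,)
        Observed stage-1 statistic (nats), pooled permutation p-value and
        BH q-value per gene.
    posthoc_pvalues : ndarray, shape (G, S, S)
        Symmetric pairwise MI+ p-value matrices (NaN where stage 2 was not
        run for a gene, and on the diagonal).
    subsets : list of list of tuple
        Maximal concordant study subsets per gene (1-based study indices),
        largest first; empty for genes not rejected in stage 1.
    """

    def __init__(
        self,
        model: ConcordanceAnalysis,
        statistic_name: str,
        statistics: np.ndarray,
        pvalues: np.ndarray,
        qvalues: np.ndarray,
        posthoc_pvalues: np.ndarray,
        posthoc_statistics: np.ndarray,
        subsets: list,
        n_permutations: int,
        seed: int | None,
        pooled: bool,
        q_threshold: float,
        alpha_posthoc: float,
    ):
        self.model = model
        self.statistic_name = statistic_name
        self.statistics = statistics
        self.pvalues = pvalues
        self.qvalues = qvalues
        self.posthoc_pvalues = posthoc_pvalues
        self.posthoc_statistics = posthoc_statistics
        self.subsets = subsets
        self.n_permutations = n_permutations
        self.seed = seed
        self.pooled = pooled
        self.q_threshold = q_threshold
        self.alpha_posthoc = alpha_posthoc

    @property
    def significant(self) -> np.ndarray:
        """Stage-1 rejection mask at the fitted q-value threshold."""
        return self.qvalues < self.q_threshold

    @property
    def module_labels(self) -> list[str]:
        """Canonical module label per gene: the lexicographically smallest
        largest concordant subset, studies joined by '+', or 'none'."""
        out = []
        for subs in self.subsets:
            out.append("+".join(str(i) for i in subs[0]) if subs else "none")
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flat per-gene results table (one row per gene)."""
        S = self.model.n_studies
        data = {
            self.statistic_name: self.statistics,
            "p_value": self.pvalues,
            "q_value": self.qvalues,
        }
        for i in range(S):
            for j in range(i + 1, S):
                data[f"posthoc_p_{i + 1}_{j + 1}"] = self.posthoc_pvalues[:, i, j]
        data["concordant_subsets"] = [
            ";".join("+".join(str(i) for i in sub) for sub in subs) for subs in self.subsets
        ]
        data["module_label"] = self.module_labels
        return pd.DataFrame(data, index=self.model.gene_ids)

    def save(self, path) -> None:
        from .io import write_results

        write_results(self, path)

    def summary(self, top: int = 10) -> str:
        """Text summary: design, detection counts, and the top genes."""
        n_sig = int(self.significant.sum())
        lines = [
            "Mutual Information Concordance Analysis",
            "=" * 55,
            f"Studies:              {self.model.n_studies} "
            f"({', '.join(map(str, self.model._prep.names))})",
            f"Classes:              {self.model.n_classes}",
            f"Genes:                {self.model.n_genes}",
            f"Statistic:            {self.statistic_name}",
            f"Permutations (B):     {self.n_permutations} "
            f"({'pooled' if self.pooled else 'per-gene'} null)",
            f"Seed:                 {self.seed}",
            f"Significant genes:    {n_sig} (q < {self.q_threshold:g})",
            f"Post hoc threshold:   p < {self.alpha_posthoc:g}",
            "-" * 55,
        ]
        df = self.to_frame().sort_values("p_value").head(top)
        cols = [self.statistic_name, "p_value", "q_value", "module_label"]
        lines.append(df[cols].to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ConcordanceResults: {self.model.n_genes} genes, "
            f"{self.model.n_studies} studies, statistic={self.statistic_name}>"
        )
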