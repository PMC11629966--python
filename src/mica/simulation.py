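"""Synthetic multi-study, multi-class expression data and method evaluation.

The generator emulates the archetypes used to benchmark concordance
detection across ``S`` studies with ``K`` classes and ``n`` replicates per
class:

* Type I   — one latent class-mean pattern shared (up to correlation
  ``rho_mean``) by all ``S`` studies;
* Type II  — studies ``1..S-1`` share a pattern, study ``S`` carries its own
  independent pattern;
* Type III — disjoint pairs of studies ({1,2}, {3,4}, ...) each share a
  pattern, independent between pairs;
* Type IV  — pure noise: class means all equal, no signal anywhere.

Class-mean vectors are drawn per gene and block as
``mean_s = tau * (sqrt(rho_mean) * z_block + sqrt(1 - rho_mean) * z_s)`` with
standard-normal ``z``'s of length K, so studies within a block have class
means with pairwise correlation ``rho_mean``; observations add iid
``N(0, noise_sd^2)`` noise. Evaluation utilities compute power/type-I-error
tables, scenario sweeps over n/S/K/rho, and genome-wide ROC metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import inference
from .core_stats import StudyData

__all__ = [
    "SimulationConfig",
    "GENE_TYPES",
    "gene_type_blocks",
    "simulate_gene",
    "simulate_dataset",
    "run_power_study",
    "scenario_sweep",
    "evaluate_genomewide",
]

GENE_TYPES = ("I", "II", "III", "IV")


@dataclass
class SimulationConfig:
    """Study design and effect sizes for the synthetic data generator.

    Defaults follow the benchmark design: four studies, three classes, ten
    replicates per class, unit class-mean spread ``tau`` and unit
    within-class noise, perfectly correlated class means within a
    concordance block, 500 evaluation replicates and 500 permutations.
    """

    n_studies: int = 4
    n_classes: int = 3
    n_per_class: int = 10
    genes_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"I": 500, "II": 500, "III": 500, "IV": 500}
    )
    rho_mean: float = 1.0
    tau: float = 1.0
    noise_sd: float = 1.0
    n_replicates: int = 500
    n_permutations: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_studies < 2:
            raise ValueError("need at least two studies")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_per_class < 1:
            raise ValueError("need at least one replicate per class")
        if not 0.0 <= self.rho_mean <= 1.0:
            raise ValueError("rho_mean must lie in [0, 1]")
        bad = set(self.genes_per_type) - set(GENE_TYPES)
        if bad:
            raise ValueError(f"unknown gene types {sorted(bad)}")

    @property
    def labels(self) -> np.ndarray:
        """Per-study class labels 1..K, ``n_per_class`` each."""
        return np.repeat(np.arange(1, self.n_classes + 1), self.n_per_class)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gene_type_blocks(gene_type: str, n_studies: int) -> list[tuple[int, ...]]:
    """Concordance blocks (1-based study indices) for a gene type.

    Blocks of size 1 mean the study draws its own independent pattern; an
    empty list (type IV) means no class-mean signal at all.
    """
    S = n_studies
    if gene_type == "I":
        return [tuple(range(1, S + 1))]
    if gene_type == "II":
        if S < 3:
            raise ValueError("gene type II requires at least 3 studies")
        return [tuple(range(1, S)), (S,)]
    if gene_type == "III":
        if S < 4:
            raise ValueError("gene type III requires at least 4 studies")
        blocks = [(s, s + 1) for s in range(1, S, 2) if s + 1 <= S]
        if S % 2:
            blocks.append((S,))
        return blocks
    if gene_type == "IV":
        return []
    raise ValueError(f"unknown gene type {gene_type!r}")


def true_subsets(gene_type: str, n_studies: int) -> list[tuple[int, ...]]:
    """Truly concordant study subsets (blocks of size >= 2)."""
    return [b for b in gene_type_blocks(gene_type, n_studies) if len(b) >= 2]


def _draw_class_means(
    gene_type: str, cfg: SimulationConfig, rng: np.random.Generator, n_genes: int
) -> np.ndarray:
    """Class-mean array of shape (n_genes, S, K)."""
    S, K, r = cfg.n_studies, cfg.n_classes, cfg.rho_mean
    means = np.zeros((n_genes, S, K))
    for block in gene_type_blocks(gene_type, S):
        z_block = rng.standard_normal((n_genes, 1, K))
        z_study = rng.standard_normal((n_genes, len(block), K))
        # sqrt weights give pairwise corr(mean_i, mean_j) = r exactly, with
        # unit latent variance, for any two studies of the same block
        latent = np.sqrt(r) * z_block + np.sqrt(1.0 - r) * z_study
        means[:, np.array(block) - 1, :] = cfg.tau * latent
    return means


def _observations(
    means: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-study value matrices (n_genes, K * n_per_class) from class means."""
    G, S, K = means.shape
    out = []
    for s in range(S):
        mu = np.repeat(means[:, s, :], cfg.n_per_class, axis=1)
        out.append(mu + cfg.noise_sd * rng.standard_normal(mu.shape))
    return out


def simulate_gene(
    gene_type: str, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[StudyData]:
    """Simulate one gene of the given type; one StudyData per study."""
    rng = cfg.rng() if rng is None else rng
    means = _draw_class_means(gene_type, cfg, rng, 1)
    values = _observations(means, cfg, rng)
    labels = cfg.labels
    return [
        StudyData(values=v[0], labels=labels, study=str(s + 1))
        for s, v in enumerate(values)
    ]


def simulate_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[StudyData], pd.DataFrame]:
    """Simulate a gene-expression dataset with a recorded truth table.

    Returns per-study StudyData (gene-stacked values) and a truth table with
    one row per gene: ``gene_id``, ``true_type`` and ``true_subsets`` (the
    truly concordant study subsets, ``;``-separated with studies joined by
    ``+``; empty for type IV).
    """
    rng = cfg.rng() if rng is None else rng
    counts = {t: int(cfg.genes_per_type.get(t, 0)) for t in GENE_TYPES}
    G = sum(counts.values())
    if G == 0:
        raise ValueError("no genes requested")
    labels = cfg.labels
    blocks_means = []
    types = []
    for t in GENE_TYPES:
        if counts[t]:
            blocks_means.append(_draw_class_means(t, cfg, rng, counts[t]))
            types.extend([t] * counts[t])
    means = np.concatenate(blocks_means, axis=0)
    values = _observations(means, cfg, rng)
    studies = [
        StudyData(values=v, labels=labels, study=str(s + 1))
        for s, v in enumerate(values)
    ]
    width = max(4, len(str(G)))
    truth = pd.DataFrame(
        {
            "gene_id": [f"gene_{i + 1:0{width}d}" for i in range(G)],
            "true_type": types,
            "true_subsets": [
                ";".join("+".join(map(str, b)) for b in true_subsets(t, cfg.n_studies))
                for t in types
            ],
        }
    )
    return studies, truth


def _power_rates(
    cfg: SimulationConfig,
    gene_types: Sequence[str],
    alpha: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Detection rates for both methods, one permutation pass per gene type.

    The R replicates of a gene type are stacked as independent genes sharing
    one permutation stream; each replicate's p-value ranks its own statistic
    against its own permuted values (per-gene null), which is the pooled
    formula at G = 1.
    """
    rows = []
    for t in gene_types:
        sub = replace(cfg, genes_per_type={t: cfg.n_replicates})
        studies, _ = simulate_dataset(sub, rng)
        prep = inference._Prepared(studies)
        rho = prep.rho()
        obs = {
            "mica": inference._stat_from_rho(rho, "gmi_plus"),
            "min_mcc": inference._stat_from_rho(rho, "min_mcc"),
        }
        null = {m: np.empty((prep.G, cfg.n_permutations)) for m in obs}
        for b in range(cfg.n_permutations):
            rho_b = prep.rho(prep.draw_perms(rng))
            null["mica"][:, b] = inference._stat_from_rho(rho_b, "gmi_plus")
            null["min_mcc"][:, b] = inference._stat_from_rho(rho_b, "min_mcc")
        for m in obs:
            p = inference.pooled_p(obs[m], null[m], pooled=False)
            # inclusive threshold: permutation p-values live on a grid of
            # multiples of 1/(1+B), so p <= alpha matches p < alpha at
            # conventional alpha while keeping alpha = 1 exhaustive
            det = int((p <= alpha).sum())
            rows.append(
                {
                    "gene_type": t,
                    "method": m,
                    "detections": det,
                    "rate": det / cfg.n_replicates,
                    "n_replicates": cfg.n_replicates,
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)


def _valid_types(n_studies: int) -> list[str]:
    out = ["I"]
    if n_studies >= 3:
        out.append("II")
    if n_studies >= 4:
        out.append("III")
    out.append("IV")
    return out


def run_power_study(
    cfg: SimulationConfig,
    method: str = "both",
    alpha: float = 0.05,
    gene_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Single-gene detection rates per gene type over ``n_replicates`` runs.

    ``method`` selects "mica", "min_mcc" or "both"; both methods always see
    identical data and permutations, so at S = 2 (where the statistics are
    equivalent tests) their detection counts coincide.
    """
    if method not in ("mica", "min_mcc", "both"):
        raise ValueError(f"unknown method {method!r}")
    if gene_types is None:
        gene_types = _valid_types(cfg.n_studies)
    table = _power_rates(cfg, gene_types, alpha, cfg.rng())
    if method != "both":
        table = table[table["method"] == method].reset_index(drop=True)
    return table


_AXIS_FIELDS = {"n": "n_per_class", "S": "n_studies", "K": "n_classes", "rho": "rho_mean"}


def scenario_sweep(
    base_cfg: SimulationConfig,
    axis: str,
    values: Sequence,
    alpha: float = 0.05,
    gene_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Detection-count table over a sweep of one design axis.

    ``axis`` is one of ``n`` (replicates per class), ``S`` (studies), ``K``
    (classes) or ``rho`` (within-block class-mean correlation). Gene types
    that need more studies than a condition provides are dropped for that
    condition. Returns a tidy table: one row per condition x gene type x
    method.
    """
    if axis not in _AXIS_FIELDS:
        raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(_AXIS_FIELDS)}")
    out = []
    for v in values:
        cfg = replace(
            base_cfg,
            **{_AXIS_FIELDS[axis]: type(getattr(base_cfg, _AXIS_FIELDS[axis]))(v)},
        )
        types = gene_types or _valid_types(cfg.n_studies)
        types = [t for t in types if t in _valid_types(cfg.n_studies)]
        table = run_power_study(cfg, method="both", alpha=alpha, gene_types=types)
        table.insert(0, axis, v)
        out.append(table)
    return pd.concat(out, ignore_index=True)


def evaluate_genomewide(
    results, truth: pd.DataFrame, q_threshold: float = 0.05
) -> dict[str, float]:
    """Genome-wide detection metrics against the simulation truth.

    ``results`` is a fitted ``ConcordanceResults`` or a DataFrame with
    ``p_value``/``q_value`` columns aligned to ``truth`` (types I-III are
    positives, type IV negatives). The ROC/AUC ranks genes by p-value;
    sensitivity, specificity, F1 and type-I error use the q-value cutoff.
    """
    from sklearn.metrics import roc_auc_score

    if hasattr(results, "to_frame"):
        results = results.to_frame()
    p = np.asarray(results["p_value"], dtype=float)
    q = np.asarray(results["q_value"], dtype=float)
    types = np.asarray(truth["true_type"])
    if p.shape[0] != types.shape[0]:
        raise ValueError("results and truth tables are not aligned")
    positive = types != "IV"
    if positive.all() or not positive.any():
        raise ValueError("truth table must contain both positives and negatives")
    auc = float(roc_auc_score(positive, -p))
    called = q < q_threshold
    tp = int((called & positive).sum())
    fp = int((called & ~positive).sum())
    fn = int((~called & positive).sum())
    tn = int((~called & ~positive).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * precision * sens / (precision + sens) if (precision + sens) else 0.0
    return {
        "auc": auc,
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
        "type_i_error": fp / (tn + fp),
        "q_threshold": q_threshold,
    }


def plot_roc(results, truth: pd.DataFrame, ax=None, label: str | None = None):
    """ROC curve of p-value ranking against the simulation truth."""
    from sklearn.metrics import roc_curve
    import matplotlib.pyplot as plt

    if hasattr(results, "to_frame"):
        results = results.to_frame()
    positive = np.asarray(truth["true_type"]) != "IV"
    fpr, tpr, _ = roc_curve(positive, -np.asarray(results["p_value"], dtype=float))
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if label:
        ax.legend()
    return ax
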