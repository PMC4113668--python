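"""Permutation-based pathway enrichment between tumor and normal samples.

The model tests, for every pathway, whether its member genes are more
dysregulated between the two phenotypes than expected under the null of
exchangeable sample labels.  The per-gene statistic is a Welch two-sample
t (tumor minus normal); the pathway score is the mean of t^2 over the
measured member genes, so up- and downregulation contribute alike; the
null is built by permuting sample labels (preserving inter-gene
correlation, which gene-label permutation would destroy), with the
add-one estimate p = (1 + #{permuted >= observed}) / (1 + B).  Multiple
testing is handled by Benjamini-Hochberg across pathways, and a pathway
is called enriched when its q-value is at or below the FDR cutoff
(default 0.1).

The enrichment engine is deliberately pluggable downstream: profile
construction and the disease network consume only the per-pathway
enriched flags and q-values, not the scoring internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset
from .pathways import Pathway, PathwayCollection

__all__ = [
    "GeneStat",
    "EnrichmentResult",
    "PathwayEnrichment",
    "PathwayEnrichmentResults",
    "gene_level_statistic",
    "pathway_score",
    "permutation_p",
    "bh_fdr",
    "run_enrichment",
    "read_enrichment_tsv",
    "write_enrichment_tsv",
]

VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class GeneStat:
    """Per-gene two-sample statistic and its rank (1 = largest |t|)."""

    gene: str
    t: float
    rank: int


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway enrichment outcome."""

    pathway_id: str
    n_genes_measured: int
    score: float
    p_value: float
    q_value: float
    enriched: bool
    mean_t: float = float("nan")  # directional summary only; not used in calls


def _welch_t_matrix(values: np.ndarray, tumor_cols: np.ndarray, floor: float = VARIANCE_FLOOR) -> np.ndarray:
    """Welch t per gene for one or more column-label assignments.

    ``tumor_cols`` is a boolean array (n_samples,) or (n_samples, B);
    returns shape (n_genes,) or (n_genes, B).  A small variance floor is
    added to each group variance so constant genes give t = 0 rather
    than a division by zero.
    """
    single = tumor_cols.ndim == 1
    M = np.atleast_2d(tumor_cols.T).T.astype(float)  # (n_samples, B)
    n1 = M.sum(axis=0)
    n2 = M.shape[0] - n1
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 samples per group")
    X = values
    X2 = values**2
    s1 = X @ M
    q1 = X2 @ M
    stot = X.sum(axis=1, keepdims=True)
    qtot = X2.sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m2 = (stot - s1) / n2
    v1 = np.maximum(q1 - n1 * m1**2, 0.0) / (n1 - 1) + floor
    v2 = np.maximum((qtot - q1) - n2 * m2**2, 0.0) / (n2 - 1) + floor
    t = (m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)
    return t[:, 0] if single else t


def gene_level_statistic(dataset: ExpressionDataset) -> list:
    """Welch t (tumor minus normal) per gene, ranked by descending |t|.

    Ties in |t| are broken lexicographically by gene symbol so rankings
    (and hence top-k gene sets) are deterministic.  Genes constant in
    both groups get t = 0 via the variance floor.
    """
    mask = dataset.group_mask("tumor")
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 samples in each of tumor and normal")
    t = _welch_t_matrix(dataset.values, mask)
    order = sorted(range(len(t)), key=lambda i: (-abs(t[i]), dataset.genes[i]))
    ranks = np.empty(len(t), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return [GeneStat(g, float(t[i]), int(ranks[i])) for i, g in enumerate(dataset.genes)]


def pathway_score(stats: Sequence[GeneStat], pathway: Pathway) -> float:
    """Mean of t^2 over the pathway's measured member genes.

    Raises ``ValueError`` when no member gene was measured; callers
    building profiles drop such pathways from the universe instead.
    """
    member = [s.t for s in stats if s.gene in pathway.genes]
    if not member:
        raise ValueError(f"pathway {pathway.id!r}: no member genes measured")
    return float(np.mean(np.square(member)))


def _permuted_masks(mask: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """B label permutations of a boolean sample mask, shape (n_samples, B)."""
    n = mask.size
    out = np.empty((n, B), dtype=bool)
    for b in range(B):
        out[:, b] = mask[rng.permutation(n)]
    return out


def permutation_p(
    dataset: ExpressionDataset,
    pathway: Pathway,
    score_observed: float,
    B: int = 999,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Sample-label permutation p-value for one pathway score.

    p = (1 + #{permuted score >= observed}) / (1 + B); always in
    [1/(1+B), 1] and deterministic given the seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng)
    mask = dataset.group_mask("tumor")
    member = np.array([g in pathway.genes for g in dataset.genes])
    if not member.any():
        raise ValueError(f"pathway {pathway.id!r}: no member genes measured")
    perm = _permuted_masks(mask, B, rng)
    t = _welch_t_matrix(dataset.values[member], perm)
    scores = np.mean(t**2, axis=0)
    return float((1 + int(np.sum(scores >= score_observed))) / (1 + B))


def bh_fdr(p_values: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return [float(v) for v in q]


class PathwayEnrichment:
    """Pathway-perturbation model for a two-group expression dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        Log-expression matrix with tumor/normal labels.
    collection : PathwayCollection
        Gene sets to test (already size/category filtered).
    min_measured : int
        Pathways with fewer measured member genes are dropped from the
        testable universe (a one- or two-gene "pathway score" is really
        a gene test); dropped ids are recorded on the results object.
    variance_floor : float
        Added to each group variance in the Welch statistic.

    Examples
    --------
    >>> model = PathwayEnrichment(dataset, collection)
    >>> res = model.fit(n_permutations=999, fdr_cutoff=0.1, seed=1)
    >>> res.enriched_ids()  # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        collection: PathwayCollection,
        min_measured: int = 3,
        variance_floor: float = VARIANCE_FLOOR,
    ) -> None:
        self.dataset = dataset
        self.collection = collection
        self.min_measured = int(min_measured)
        self.variance_floor = float(variance_floor)

        gene_index = {g: i for i, g in enumerate(dataset.genes)}
        self._members: list = []
        self.dropped_pathways: list = []
        for p in collection:
            idx = np.array(sorted(gene_index[g] for g in p.genes if g in gene_index), dtype=int)
            if idx.size >= self.min_measured:
                self._members.append((p.id, idx))
            else:
                self.dropped_pathways.append(p.id)
        if not self._members:
            raise ValueError("no pathway has enough measured member genes")

    def fit(
        self,
        n_permutations: int = 999,
        fdr_cutoff: float = 0.1,
        seed: np.random.Generator | int | None = None,
    ) -> "PathwayEnrichmentResults":
        """Score every testable pathway and call enrichment at the FDR cutoff.

        The same ``n_permutations`` label permutations are shared across
        pathways, so one pass over the matrix prices the whole
        collection.
        """
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        ds = self.dataset
        mask = ds.group_mask("tumor")
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError("need at least 2 samples in each of tumor and normal")

        t_obs = _welch_t_matrix(ds.values, mask, self.variance_floor)
        perm = _permuted_masks(mask, n_permutations, rng)
        t_perm = _welch_t_matrix(ds.values, perm, self.variance_floor)
        sq_obs = t_obs**2
        sq_perm = t_perm**2

        rows = []
        p_values = []
        for pid, idx in self._members:
            obs = float(sq_obs[idx].mean())
            null = sq_perm[idx].mean(axis=0)
            p = (1 + int(np.sum(null >= obs))) / (1 + n_permutations)
            rows.append((pid, int(idx.size), obs, float(t_obs[idx].mean())))
            p_values.append(p)
        q_values = bh_fdr(p_values)

        results = [
            EnrichmentResult(
                pathway_id=pid,
                n_genes_measured=n,
                score=score,
                p_value=float(p),
                q_value=float(q),
                enriched=bool(q <= fdr_cutoff),
                mean_t=mean_t,
            )
            for (pid, n, score, mean_t), p, q in zip(rows, p_values, q_values)
        ]
        gene_stats = gene_level_statistic(ds)
        return PathwayEnrichmentResults(
            model=self,
            results=results,
            gene_stats=gene_stats,
            n_permutations=n_permutations,
            fdr_cutoff=fdr_cutoff,
        )


class PathwayEnrichmentResults:
    """Fitted enrichment results: per-pathway scores, p/q-values, flags."""

    def __init__(self, model, results, gene_stats, n_permutations, fdr_cutoff) -> None:
        self.model = model
        self.results = list(results)
        self.gene_stats = list(gene_stats)
        self.n_permutations = int(n_permutations)
        self.fdr_cutoff = float(fdr_cutoff)

    @property
    def pathway_ids(self) -> list:
        return [r.pathway_id for r in self.results]

    def enriched_ids(self) -> set:
        return {r.pathway_id for r in self.results if r.enriched}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway_id": [r.pathway_id for r in self.results],
                "n_genes_measured": [r.n_genes_measured for r in self.results],
                "score": [r.score for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "q_value": [r.q_value for r in self.results],
                "enriched": [r.enriched for r in self.results],
                "mean_t": [r.mean_t for r in self.results],
            }
        )

    def summary(self, top: int = 10) -> str:
        """Plain-text summary: design, calls, and the strongest pathways."""
        ds = self.model.dataset
        n_t = int(ds.group_mask("tumor").sum())
        n_n = ds.n_samples - n_t
        df = self.to_frame().sort_values(["q_value", "p_value", "pathway_id"])
        lines = [
            "Pathway enrichment (label-permutation, mean-t^2 score)",
            f"  samples: {n_t} tumor / {n_n} normal; genes measured: {ds.n_genes}",
            f"  pathways tested: {len(self.results)} "
            f"(dropped below min_measured: {len(self.model.dropped_pathways)})",
            f"  permutations: {self.n_permutations}; BH FDR cutoff: {self.fdr_cutoff}",
            f"  enriched: {len(self.enriched_ids())}",
            "",
            f"  top {min(top, len(df))} pathways by q-value:",
        ]
        for _, r in df.head(top).iterrows():
            lines.append(
                f"    {r.pathway_id:<16} n={int(r.n_genes_measured):>4} "
                f"score={r.score:8.3f} p={r.p_value:.4g} q={r.q_value:.4g} "
                f"{'*' if r.enriched else ''}"
            )
        return "\n".join(lines)


def run_enrichment(
    dataset: ExpressionDataset,
    collection: PathwayCollection,
    B: int = 999,
    fdr_cutoff: float = 0.1,
    seed: np.random.Generator | int | None = None,
    min_measured: int = 3,
) -> list:
    """Convenience wrapper: fit the model, return the flat result list."""
    model = PathwayEnrichment(dataset, collection, min_measured=min_measured)
    return model.fit(n_permutations=B, fdr_cutoff=fdr_cutoff, seed=seed).results


def write_enrichment_tsv(results: Iterable[EnrichmentResult], path, header_comment: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("pathway_id\tn_genes_measured\tscore\tp_value\tq_value\tenriched\tmean_t\n")
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.n_genes_measured}\t{r.score:.6g}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{int(r.enriched)}\t{r.mean_t:.6g}\n"
            )


def read_enrichment_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        EnrichmentResult(
            pathway_id=str(row.pathway_id),
            n_genes_measured=int(row.n_genes_measured),
            score=float(row.score),
            p_value=float(row.p_value),
            q_value=float(row.q_value),
            enriched=bool(row.enriched),
            mean_t=float(row.mean_t),
        )
        for row in df.itertuples(index=False)
    ]
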