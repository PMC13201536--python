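"""Gene-signature and gene-set activity scores.

* ``ulm_score`` — the treatment-response score: regress a cell's expression
  on signature weights (DEG log2 fold changes as the mode of regulation) and
  report the t-statistic of the slope.
* ``module_score`` — expression-bin-matched control-gene score.
* ``aucell`` — area under the gene-set recovery curve in the top ranks.
* ``preranked_gsea`` — weighted Kolmogorov-Smirnov enrichment with a
  gene-permutation null, normalized enrichment scores and same-sign FDR.
* ``pseudobulk`` — per-group mean profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix

__all__ = [
    "SignatureWeights",
    "GeneSet",
    "EnrichmentResult",
    "build_signature",
    "ulm_score",
    "ulm_scores",
    "module_score",
    "aucell",
    "preranked_gsea",
    "gsea_batch",
    "pseudobulk",
]

SATURATION_SCORE = 1e6


@dataclass
class SignatureWeights:
    """Gene -> real weight map defining a response signature."""

    weights: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weights.index.has_duplicates:
            dup = self.weights.index[self.weights.index.duplicated()][0]
            raise ValueError(f"duplicate gene in signature: {dup}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    source_id: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    pvalue: float
    n_perm: int
    size: int
    fdr_q: float | None = None


def build_signature(deg_table: pd.DataFrame, padj_max: float = 0.05) -> SignatureWeights:
    """Signature from a DEG table: genes below the adjusted-p cutoff,
    weighted by their log2 fold change."""
    required = {"gene", "log2fc", "padj"}
    missing = required - set(deg_table.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    dup = deg_table["gene"][deg_table["gene"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene rows in DEG table: {dup.iloc[0]}")
    kept = deg_table.loc[deg_table["padj"] < padj_max]
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} genes pass padj < {padj_max}; need at least 3"
        )
    weights = pd.Series(kept["log2fc"].to_numpy(), index=kept["gene"].to_numpy())
    return SignatureWeights(weights, {"padj_max": padj_max, "n_genes": len(kept)})


def _ulm_core(y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope t-statistics of OLS y ~ 1 + w, row-wise over cells."""
    n = w.size
    if n < 3:
        raise ValueError("need at least 3 shared genes")
    wc = w - w.mean()
    sxx = float(wc @ wc)
    if sxx == 0:
        raise ValueError("signature weights have zero variance on the shared genes")
    yc = y - y.mean(axis=1, keepdims=True)
    slope = (yc @ wc) / sxx
    sse = np.einsum("ij,ij->i", yc, yc) - slope**2 * sxx
    sse = np.maximum(sse, 0.0)
    saturated = sse <= 1e-12 * np.maximum(np.einsum("ij,ij->i", yc, yc), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope * np.sqrt(sxx * (n - 2) / sse)
    t[saturated] = np.sign(slope[saturated]) * SATURATION_SCORE
    return t, saturated


def ulm_score(cell_profile: pd.Series, sig: SignatureWeights) -> tuple[float, bool]:
    """Score one expression profile against a signature.

    Returns ``(score, saturated)`` where the score is the t-statistic of
    the slope when expression is regressed on the weights over the shared
    genes.  It is invariant to positive affine rescaling of the weights and
    flips sign when the weights are negated.  A perfect linear fit saturates
    to +/-1e6 with the flag set.
    """
    shared = sig.weights.index.intersection(cell_profile.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared with the signature")
    y = cell_profile.loc[shared].to_numpy(dtype=float)[None, :]
    w = sig.weights.loc[shared].to_numpy(dtype=float)
    t, sat = _ulm_core(y, w)
    return float(t[0]), bool(sat[0])


def ulm_scores(norm: NormalizedMatrix, sig: SignatureWeights) -> pd.DataFrame:
    """Vectorized ``ulm_score`` over all cells of a normalized matrix."""
    feats = pd.Index(norm.features)
    shared = sig.weights.index.intersection(feats)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared with the signature")
    cols = feats.get_indexer(shared)
    y = norm.values[:, cols]
    w = sig.weights.loc[shared].to_numpy(dtype=float)
    t, sat = _ulm_core(y, w)
    return pd.DataFrame({"score": t, "saturated": sat}, index=norm.cell_ids)


def module_score(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Mean set expression minus mean of expression-matched control genes.

    Genes are binned by their average expression; for every set gene,
    ``n_ctrl`` control genes are drawn from the same bin (with replacement,
    and a warning, when the bin is smaller than requested).
    """
    feats = pd.Index(norm.features)
    set_idx = feats.get_indexer(feats.intersection(gene_set.genes))
    if len(set_idx) == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the panel")
    means = norm.values.mean(axis=0)
    order = pd.Series(means).rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, len(feats)), labels=False).to_numpy()

    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for j in set_idx:
        pool = np.flatnonzero(bins == bins[j])
        replace = len(pool) < n_ctrl
        if replace:
            warnings.warn(
                f"bin of gene {feats[j]!r} has {len(pool)} genes < n_ctrl="
                f"{n_ctrl}; sampling controls with replacement",
                stacklevel=2,
            )
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_idx)
    score = norm.values[:, set_idx].mean(axis=1) - norm.values[:, ctrl].mean(axis=1)
    return pd.Series(score, index=norm.cell_ids, name=gene_set.name)


def aucell(
    profile: pd.Series, gene_set: GeneSet, top_fraction: float = 0.05
) -> float:
    """Area under the set-recovery curve within the top-ranked genes.

    Genes are ranked by decreasing expression (ties broken by gene name);
    the step recovery curve of set members over the first
    ``ceil(top_fraction * G)`` ranks is integrated and normalized by the
    best attainable curve, yielding a score in [0, 1].
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    genes = profile.index
    if len(gene_set.genes) > len(genes):
        raise ValueError("gene set larger than the expression panel")
    members = genes.intersection(gene_set.genes)
    if len(members) == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the panel")
    order = sorted(genes, key=lambda g: (-profile[g], g))
    max_rank = int(np.ceil(top_fraction * len(genes)))
    member_set = set(members)
    hits = np.array([g in member_set for g in order[:max_rank]])
    cum = np.cumsum(hits)
    raw = float(cum.sum())
    best = float(np.minimum(np.arange(1, max_rank + 1), len(members)).sum())
    return raw / best


def _es_from_indicator(
    stats_sorted: np.ndarray, hit: np.ndarray, weight_p: float
) -> np.ndarray:
    """Enrichment scores for one or many hit-indicator rows.

    ``hit`` is boolean with shape (..., G) aligned to the descending-sorted
    statistics.
    """
    hit = np.atleast_2d(hit)
    g = stats_sorted.size
    m = hit.sum(axis=1)
    absp = np.abs(stats_sorted) ** weight_p
    hw = hit * absp
    denom = hw.sum(axis=1, keepdims=True)
    p_hit = np.cumsum(hw, axis=1) / denom
    p_miss = np.cumsum(~hit, axis=1) / (g - m)[:, None]
    run = p_hit - p_miss
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(run.shape[0]), idx]


def preranked_gsea(
    ranked: pd.Series,
    gene_set: GeneSet,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked enrichment with a gene-permutation null.

    ES is the maximum deviation of the weighted running sum (hit steps
    proportional to |stat|^p, miss steps 1/(G-|S|)); NES divides ES by the
    mean magnitude of same-sign permutation scores; the p-value is the
    same-sign permutation tail with a +1 correction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stats = ranked.to_numpy(dtype=float)
    if np.all(stats == stats[0]):
        raise ValueError("all ranking statistics are equal; no ranking exists")
    # descending sort with gene-name tie break
    idx = sorted(range(len(ranked)), key=lambda i: (-stats[i], str(ranked.index[i])))
    stats_sorted = stats[idx]
    genes_sorted = ranked.index[idx]
    member = genes_sorted.isin(gene_set.genes)
    m = int(member.sum())
    if m < 2:
        raise ValueError(
            f"gene set {gene_set.name!r} shares only {m} genes with the ranking"
        )
    es = float(_es_from_indicator(stats_sorted, member, weight_p)[0])

    rng = np.random.default_rng(seed)
    g = len(stats_sorted)
    pick = np.argpartition(rng.random((n_perm, g)), m - 1, axis=1)[:, :m]
    indicator = np.zeros((n_perm, g), dtype=bool)
    np.put_along_axis(indicator, pick, True, axis=1)
    es_perm = _es_from_indicator(stats_sorted, indicator, weight_p)

    same = es_perm >= 0 if es >= 0 else es_perm < 0
    n_same = int(same.sum())
    if n_same == 0:
        nes = np.sign(es) * np.inf
        pvalue = 1.0 / (n_perm + 1)
    else:
        mean_mag = float(np.abs(es_perm[same]).mean())
        nes = es / mean_mag if mean_mag > 0 else 0.0
        tail = int((np.abs(es_perm[same]) >= abs(es)).sum())
        pvalue = (1 + tail) / (n_same + 1)
    return EnrichmentResult(
        name=gene_set.name, es=es, nes=float(nes), pvalue=float(pvalue),
        n_perm=n_perm, size=m,
    )


def gsea_batch(
    ranked: pd.Series,
    gene_sets: list[GeneSet],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Run several sets against one ranking and attach same-sign NES FDR."""
    results = [
        preranked_gsea(ranked, s, weight_p, n_perm, seed + i)
        for i, s in enumerate(gene_sets)
    ]
    nes = np.array([r.nes for r in results])
    for r in results:
        same_obs = nes >= 0 if r.nes >= 0 else nes < 0
        denom_obs = (np.abs(nes[same_obs]) >= abs(r.nes)).sum() / max(same_obs.sum(), 1)
        r.fdr_q = float(min(1.0, r.pvalue / max(denom_obs, 1e-12)))
    return results


def pseudobulk(norm: NormalizedMatrix, groups: pd.Series) -> pd.DataFrame:
    """Per-group arithmetic mean expression (groups keyed by cell id)."""
    groups = groups.reindex(norm.cell_ids)
    if groups.isna().any():
        raise ValueError("every cell needs a group assignment")
    frame = norm.to_frame()
    return frame.groupby(groups.to_numpy()).mean()
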