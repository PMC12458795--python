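"""Gene-set enrichment engine for single-nucleus cluster x condition comparisons.

Implements the compact analysis chain used to ask how a condition (e.g. social
rank) shifts coordinated gene expression within transcriptomic clusters:

1. nuclei quality control (:func:`qc_filter`) — drop suspected doublets
   (high UMI), high-mitochondrial nuclei, red-blood-cell contamination
   (hemoglobin genes) and dissociation-stressed nuclei (immediate early genes);
2. :func:`log_normalize` — per-nucleus total-count normalization to a fixed
   scale followed by log1p;
3. :func:`s2n_rank` — rank genes by a variance-floored signal-to-noise ratio
   between two conditions;
4. :func:`enrichment_score` — weighted Kolmogorov–Smirnov running sum over the
   ranked list, returning the signed maximum deviation and the leading edge;
5. :func:`permutation_fdr` — condition-label permutations give nominal
   p-values, normalized enrichment scores and a GSEA-convention FDR; a set is
   called significant when FDR < 0.25 and the BH-adjusted p-value < 0.01;
6. :func:`intersect_with_degs` — combine leading-edge genes of significant
   sets with an externally computed differential-expression table.

The engine is intentionally self-contained: the ranking metric, running sum,
permutation scheme and FDR are all implemented here so that each step can be
tested against brute-force oracles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "EnrichmentResult",
    "DEFAULT_QC_THRESHOLDS",
    "DEFAULT_GENE_CLASSES",
    "qc_filter",
    "log_normalize",
    "s2n_rank",
    "enrichment_score",
    "permutation_fdr",
    "enumerate_tests",
    "intersect_with_degs",
    "GSEA",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x nuclei integer count matrix with per-nucleus labels.

    Parameters
    ----------
    counts : ndarray, shape (n_genes, n_nuclei)
        Non-negative integer counts (dense; matrices at this scale are small).
    genes : list of str
        Gene names, one per row.
    barcodes : list of str
        Nucleus barcodes, one per column.
    condition : ndarray of str
        Condition label per nucleus (e.g. ``rank-1``/``rank-3``/``control``).
    cluster : ndarray of str
        Cluster label per nucleus.
    """

    counts: np.ndarray
    genes: list[str]
    barcodes: list[str]
    condition: np.ndarray
    cluster: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.condition = np.asarray(self.condition, dtype=object)
        self.cluster = np.asarray(self.cluster, dtype=object)
        n_genes, n_nuclei = self.counts.shape
        if len(self.genes) != n_genes:
            raise ValueError("gene names do not match matrix rows")
        if not (len(self.barcodes) == len(self.condition) == len(self.cluster) == n_nuclei):
            raise ValueError("barcode/label lengths do not match matrix columns")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]

    def select_nuclei(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            counts=self.counts[:, mask],
            genes=list(self.genes),
            barcodes=[b for b, m in zip(self.barcodes, mask) if m],
            condition=self.condition[mask],
            cluster=self.cluster[mask],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with size bounds applied against a gene universe."""

    sets: dict[str, list[str]]
    min_size: int = 15
    max_size: int = 500

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def filtered(self, universe: list[str]) -> "GeneSetCollection":
        """Restrict each set to ``universe`` and drop sets outside size bounds."""
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = [g for g in dict.fromkeys(members) if g in uni]
            if self.min_size <= len(inter) <= self.max_size:
                kept[name] = inter
        return GeneSetCollection(kept, self.min_size, self.max_size)


@dataclass
class EnrichmentResult:
    """Result of one gene-set test in one cluster/comparison."""

    set_name: str
    cluster: str
    comparison: tuple[str, str]
    es: float
    nes: float
    p_nominal: float
    p_adjusted: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)
    significant: bool = False


DEFAULT_QC_THRESHOLDS = {"mito": 0.10, "umi": 20000, "hemoglobin": 0.01, "ieg": 0.01}

#: Default QC sentinel gene classes. Mitochondrial and hemoglobin genes are
#: matched by prefix; immediate early genes by exact name.
DEFAULT_GENE_CLASSES = {
    "mito_prefix": "mt-",
    "hemoglobin_prefixes": ("Hba", "Hbb"),
    "ieg": ("Fos", "Fosb", "Jun", "Junb", "Egr1", "Arc"),
}


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def _gene_class_masks(genes: list[str], gene_classes: dict) -> dict[str, np.ndarray]:
    genes_arr = np.asarray(genes, dtype=object)
    mito = np.array([g.startswith(gene_classes["mito_prefix"]) for g in genes_arr])
    hgb = np.array([g.startswith(tuple(gene_classes["hemoglobin_prefixes"])) for g in genes_arr])
    ieg_set = set(gene_classes["ieg"])
    ieg = np.array([g in ieg_set for g in genes_arr])
    return {"mito": mito, "hemoglobin": hgb, "ieg": ieg}


def qc_filter(
    cm: CountMatrix,
    thresholds: dict | None = None,
    gene_classes: dict | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove nuclei violating any QC rule; return survivors and a report.

    Rules (a nucleus is removed if it violates *any*):

    - ``mito``: mitochondrial count fraction > threshold (default 0.10)
    - ``umi``: total UMI count > threshold (default 20,000; suspected doublet)
    - ``hemoglobin``: hemoglobin-gene fraction > threshold (default 0.01)
    - ``ieg``: immediate-early-gene fraction > threshold (default 0.01)

    Returns
    -------
    (CountMatrix, DataFrame)
        Filtered matrix and a long report with one row per (barcode, rule)
        violation; a nucleus violating two rules appears under both.
    """
    thr = dict(DEFAULT_QC_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    classes = dict(DEFAULT_GENE_CLASSES)
    if gene_classes:
        classes.update(gene_classes)
    masks = _gene_class_masks(cm.genes, classes)

    totals = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = {k: np.where(totals > 0, cm.counts[m].sum(axis=0) / totals, 0.0) for k, m in masks.items()}

    violations = {
        "mito": frac["mito"] > thr["mito"],
        "umi": totals > thr["umi"],
        "hemoglobin": frac["hemoglobin"] > thr["hemoglobin"],
        "ieg": frac["ieg"] > thr["ieg"],
    }
    rows = []
    for rule, viol in violations.items():
        for idx in np.flatnonzero(viol):
            rows.append({"barcode": cm.barcodes[idx], "rule": rule})
    report = pd.DataFrame(rows, columns=["barcode", "rule"])

    keep = ~np.logical_or.reduce(list(violations.values()))
    out = cm.select_nuclei(keep)
    if out.n_nuclei == 0:
        warnings.warn("all nuclei removed by QC filtering", stacklevel=2)
    return out, report


def log_normalize(cm: CountMatrix, scale: float = 10_000.0) -> tuple[np.ndarray, CountMatrix]:
    """Per-nucleus total-count normalization: ``log(1 + count/total * scale)``.

    Nuclei with zero total counts are removed (with a warning).  Returns the
    normalized dense matrix and the (possibly reduced) CountMatrix it aligns to.
    """
    totals = cm.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        warnings.warn(f"removing {int((totals == 0).sum())} zero-count nuclei", stacklevel=2)
        cm = cm.select_nuclei(totals > 0)
        totals = totals[totals > 0]
    X = np.log1p(cm.counts / totals * scale)
    return X, cm


# ---------------------------------------------------------------------------
# ranking metric
# ---------------------------------------------------------------------------


def s2n_rank(
    X: np.ndarray,
    labels: np.ndarray,
    cond_a: str,
    cond_b: str,
    genes: list[str] | None = None,
    sd_floor_frac: float = 0.2,
    sd_floor_abs: float = 0.2,
) -> pd.DataFrame:
    """Signal-to-noise ranking of genes between two conditions.

    metric = (mean_A - mean_B) / (sd_A' + sd_B') where each sd is floored at
    ``max(sd, sd_floor_frac * |mean|)`` and, if that floor is still zero, at
    ``sd_floor_abs``.  The floor prevents near-constant low-expression genes
    from receiving extreme ranks.  Genes are returned sorted descending
    (condition-A-high first).
    """
    labels = np.asarray(labels, dtype=object)
    in_a = labels == cond_a
    in_b = labels == cond_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("need at least 2 nuclei per condition for signal-to-noise ranking")
    mean_a = X[:, in_a].mean(axis=1)
    mean_b = X[:, in_b].mean(axis=1)
    sd_a = X[:, in_a].std(axis=1, ddof=1)
    sd_b = X[:, in_b].std(axis=1, ddof=1)

    def _floor(sd, mean):
        floored = np.maximum(sd, sd_floor_frac * np.abs(mean))
        return np.where(floored == 0, sd_floor_abs, floored)

    metric = (mean_a - mean_b) / (_floor(sd_a, mean_a) + _floor(sd_b, mean_b))
    if genes is None:
        genes = [f"g{i}" for i in range(X.shape[0])]
    df = pd.DataFrame({"gene": genes, "metric": metric})
    return df.sort_values("metric", ascending=False, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def enrichment_score(
    ranked: pd.DataFrame | tuple[list[str], np.ndarray],
    gene_set: list[str],
    weight: float = 1.0,
    check_size: tuple[int, int] | None = None,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted Kolmogorov–Smirnov running-sum enrichment score.

    Walking down the ranked list, hits (set members) increment the running sum
    by ``|metric|^weight / sum_over_set |metric|^weight`` and misses decrement
    it by ``1/(N - n_set)``.  The enrichment score is the running-sum value of
    maximum absolute deviation from zero; the leading edge comprises the set
    members at or before that position (at or after it for negative scores).

    Parameters
    ----------
    ranked : DataFrame with columns ``gene``/``metric`` (descending) or a
        ``(genes, metrics)`` tuple in ranked order.
    gene_set : genes to test; silently restricted to the ranked universe.
    check_size : optional ``(min, max)`` bounds on the restricted set size;
        violation raises ``ValueError``.

    Returns
    -------
    (es, running_sum, leading_edge)
    """
    if isinstance(ranked, pd.DataFrame):
        genes = ranked["gene"].tolist()
        metrics = ranked["metric"].to_numpy(dtype=float)
    else:
        genes, metrics = list(ranked[0]), np.asarray(ranked[1], dtype=float)
    n = len(genes)
    members = set(gene_set)
    hit = np.array([g in members for g in genes])
    n_hit = int(hit.sum())
    if check_size is not None and not (check_size[0] <= n_hit <= check_size[1]):
        raise ValueError(f"gene set size {n_hit} outside bounds {check_size}")
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranked list")

    w = np.abs(metrics) ** weight
    norm = w[hit].sum()
    if norm == 0:
        # degenerate all-zero metrics over the set: fall back to unweighted hits
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(hit, w / norm, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        lead_idx = np.flatnonzero(hit[: peak + 1])
    else:
        lead_idx = peak + np.flatnonzero(hit[peak:])
    leading_edge = [genes[i] for i in lead_idx]
    return es, running, leading_edge


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------


def _s2n_metric(
    X: np.ndarray,
    in_a: np.ndarray,
    in_b: np.ndarray,
    sd_floor_frac: float = 0.2,
    sd_floor_abs: float = 0.2,
) -> np.ndarray:
    """Vectorized signal-to-noise metric per gene (see :func:`s2n_rank`)."""
    na, nb = int(in_a.sum()), int(in_b.sum())
    mean_a = X[:, in_a].mean(axis=1)
    mean_b = X[:, in_b].mean(axis=1)
    sd_a = X[:, in_a].std(axis=1, ddof=1)
    sd_b = X[:, in_b].std(axis=1, ddof=1)
    fa = np.maximum(sd_a, sd_floor_frac * np.abs(mean_a))
    fb = np.maximum(sd_b, sd_floor_frac * np.abs(mean_b))
    fa = np.where(fa == 0, sd_floor_abs, fa)
    fb = np.where(fb == 0, sd_floor_abs, fb)
    return (mean_a - mean_b) / (fa + fb)


def _es_only(metric_sorted: np.ndarray, hit_sorted: np.ndarray, weight: float) -> float:
    """Enrichment score on a pre-sorted metric/hit-mask pair (hot path)."""
    n = len(metric_sorted)
    n_hit = int(hit_sorted.sum())
    w = np.abs(metric_sorted) ** weight
    norm = w[hit_sorted].sum()
    if norm == 0:
        steps = np.where(hit_sorted, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(hit_sorted, w / norm, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _observed_and_null_es(
    X: np.ndarray,
    labels: np.ndarray,
    cond_a: str,
    cond_b: str,
    genes: list[str],
    collection: GeneSetCollection,
    n_perm: int,
    rng: np.random.Generator,
    weight: float,
) -> tuple[dict[str, float], dict[str, list[str]], np.ndarray, list[str]]:
    """Observed ES + leading edges, plus sets x n_perm null ES matrix."""
    ranked = s2n_rank(X, labels, cond_a, cond_b, genes=genes)
    set_names = collection.names()
    obs, lead = {}, {}
    for name in set_names:
        es, _, le = enrichment_score(ranked, collection.sets[name], weight=weight)
        obs[name] = es
        lead[name] = le

    labels = np.asarray(labels, dtype=object)
    in_a = labels == cond_a
    in_b = labels == cond_b
    sel = in_a | in_b
    n_sel = int(sel.sum())
    if n_sel <= 20:  # only bother checking when the count could plausibly exceed it
        from math import comb

        max_distinct = comb(n_sel, int(in_a.sum()))
        if n_perm > max_distinct:
            warnings.warn(
                f"{n_perm} permutations exceed the {max_distinct} distinct label "
                "arrangements; sampling with replacement",
                stacklevel=3,
            )
    gene_idx = {g: i for i, g in enumerate(genes)}
    hit_masks = np.zeros((len(set_names), len(genes)), dtype=bool)
    for i, name in enumerate(set_names):
        hit_masks[i, [gene_idx[g] for g in collection.sets[name] if g in gene_idx]] = True

    sel_idx = np.flatnonzero(sel)
    Xs = X[:, sel_idx]
    a_sel = in_a[sel_idx]
    null = np.empty((len(set_names), n_perm))
    for j in range(n_perm):
        perm_a = a_sel[rng.permutation(n_sel)]
        metric = _s2n_metric(Xs, perm_a, ~perm_a)
        order = np.argsort(-metric, kind="stable")
        m_sorted = metric[order]
        for i in range(len(set_names)):
            null[i, j] = _es_only(m_sorted, hit_masks[i][order], weight)
    return obs, lead, null, set_names


def _gsea_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """GSEA-convention FDR: ratio of null to observed tail fractions, per set."""
    null_flat = null_nes.ravel()
    fdr = np.empty_like(obs_nes)
    for i, v in enumerate(obs_nes):
        if v >= 0:
            null_tail = np.mean(null_flat[null_flat >= 0] >= v) if np.any(null_flat >= 0) else 0.0
            obs_tail = np.mean(obs_nes[obs_nes >= 0] >= v) if np.any(obs_nes >= 0) else 1.0
        else:
            null_tail = np.mean(null_flat[null_flat < 0] <= v) if np.any(null_flat < 0) else 0.0
            obs_tail = np.mean(obs_nes[obs_nes < 0] <= v) if np.any(obs_nes < 0) else 1.0
        fdr[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 0.0
    return fdr


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjustment (delegating would pull in statsmodels for
    three lines; kept local and cross-checked in tests)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def permutation_fdr(
    X: np.ndarray,
    cm: CountMatrix,
    collection: GeneSetCollection,
    comparisons: list[tuple[str, str]] | None = None,
    clusters: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    fdr_threshold: float = 0.25,
    adj_p_threshold: float = 0.01,
) -> list[EnrichmentResult]:
    """Run the full permutation-tested enrichment analysis.

    For every (cluster, condition pair) the nuclei of that cluster carrying
    either condition are subset, genes are ranked by signal-to-noise, each
    filtered set is scored, and condition labels are permuted ``n_perm`` times
    within the cluster to build a null ES distribution per set.

    NES divides each ES by the mean |null ES| of its sign; nominal p-values
    are sign-matched tail fractions of the pooled null NES across sets (with
    a +1 pseudo-count); FDR follows the GSEA convention (ratio of null to
    observed NES tail fractions); adjusted p-values are Benjamini–Hochberg
    within a comparison.
    A set is flagged significant when FDR < ``fdr_threshold`` and adjusted
    p < ``adj_p_threshold``.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives unstable FDR estimates", stacklevel=2)
    rng = np.random.default_rng(seed)
    if comparisons is None:
        conds = sorted(set(cm.condition))
        comparisons = list(itertools.combinations(conds, 2))
    if clusters is None:
        clusters = sorted(set(cm.cluster))

    results: list[EnrichmentResult] = []
    for comp in comparisons:
        comp_results: list[EnrichmentResult] = []
        for cl in clusters:
            in_cl = cm.cluster == cl
            sub_mask = in_cl & np.isin(cm.condition, comp)
            if sub_mask.sum() < 4:
                continue
            Xc = X[:, sub_mask]
            labels = cm.condition[sub_mask]
            expressed = Xc.sum(axis=1) > 0
            genes_c = [g for g, e in zip(cm.genes, expressed) if e]
            coll_c = collection.filtered(genes_c)
            if len(coll_c) == 0:
                continue
            obs, lead, null, names = _observed_and_null_es(
                Xc[expressed], labels, comp[0], comp[1], genes_c, coll_c, n_perm, rng, weight
            )
            obs_es = np.array([obs[n] for n in names])
            pos_mean = np.array([max(np.mean(np.abs(null[i][null[i] >= 0])) if np.any(null[i] >= 0) else 1.0, 1e-12) for i in range(len(names))])
            neg_mean = np.array([max(np.mean(np.abs(null[i][null[i] < 0])) if np.any(null[i] < 0) else 1.0, 1e-12) for i in range(len(names))])
            nes = np.where(obs_es >= 0, obs_es / pos_mean, obs_es / neg_mean)
            null_nes = np.where(null >= 0, null / pos_mean[:, None], null / neg_mean[:, None])
            # nominal p against the pooled same-sign null NES across sets (the
            # normalization makes set nulls comparable); the pooled floor
            # ~1/(n_perm * n_sets) is what makes adjusted p < 0.01 reachable
            # at 1,000 permutations
            pool = null_nes.ravel()
            pool_pos, pool_neg = pool[pool >= 0], pool[pool < 0]
            p_nom = np.empty(len(names))
            for i in range(len(names)):
                same = pool_pos if nes[i] >= 0 else pool_neg
                p_nom[i] = (1 + np.sum(np.abs(same) >= abs(nes[i]))) / (1 + len(same))
            fdr = _gsea_fdr(nes, null_nes)
            for i, name in enumerate(names):
                comp_results.append(
                    EnrichmentResult(
                        set_name=name,
                        cluster=cl,
                        comparison=tuple(comp),
                        es=float(obs_es[i]),
                        nes=float(nes[i]),
                        p_nominal=float(p_nom[i]),
                        p_adjusted=np.nan,
                        fdr=float(fdr[i]),
                        leading_edge=lead[name],
                    )
                )
        if comp_results:
            adj = _bh_adjust(np.array([r.p_nominal for r in comp_results]))
            for r, a in zip(comp_results, adj):
                r.p_adjusted = float(a)
                r.significant = bool(r.fdr < fdr_threshold and a < adj_p_threshold)
        results.extend(comp_results)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tidy table of enrichment results (one row per set x cluster x comparison)."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "cluster": [r.cluster for r in results],
            "comparison": ["|".join(r.comparison) for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "fdr": [r.fdr for r in results],
            "n_leading": [len(r.leading_edge) for r in results],
            "significant": [r.significant for r in results],
        }
    )


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------


def enumerate_tests(sets, clusters, comparisons) -> int:
    """Total number of enrichment tests: |sets| x |clusters| x |comparisons|.

    Each argument may be an integer count or a sized collection.
    """

    def _n(x):
        return x if isinstance(x, (int, np.integer)) else len(x)

    return _n(sets) * _n(clusters) * _n(comparisons)


def intersect_with_degs(
    results: list[EnrichmentResult],
    degs: pd.DataFrame,
    lfc_min: float = 0.1,
    mode: str = "intersection",
) -> dict[tuple[str, str], list[str]]:
    """Combine leading-edge genes of significant sets with a DEG table.

    ``degs`` must have columns ``gene``, ``log_fc``, ``cluster``, ``comparison``
    (comparison encoded ``"a|b"``).  With ``mode="intersection"`` (default) a
    gene must be a leading-edge member of a significant set *and* appear in the
    DEG table with ``|log_fc| >= lfc_min``; with ``mode="union"`` either
    criterion suffices.  Returns ``{(cluster, comparison): sorted genes}``.
    """
    if mode not in {"intersection", "union"}:
        raise ValueError("mode must be 'intersection' or 'union'")
    required = {"gene", "log_fc", "cluster", "comparison"}
    if degs.shape[0] and not required.issubset(degs.columns):
        raise ValueError(f"DEG table missing columns: {sorted(required - set(degs.columns))}")

    lead_by_key: dict[tuple[str, str], set[str]] = {}
    for r in results:
        if not r.significant:
            continue
        key = (r.cluster, "|".join(r.comparison))
        lead_by_key.setdefault(key, set()).update(r.leading_edge)

    deg_by_key: dict[tuple[str, str], set[str]] = {}
    if degs.shape[0]:
        passing = degs[np.abs(degs["log_fc"]) >= lfc_min]
        for (cl, comp), grp in passing.groupby(["cluster", "comparison"]):
            deg_by_key[(cl, comp)] = set(grp["gene"])

    out = {}
    for key in sorted(set(lead_by_key) | set(deg_by_key)):
        le = lead_by_key.get(key, set())
        dg = deg_by_key.get(key, set())
        out[key] = sorted(le & dg) if mode == "intersection" else sorted(le | dg)
    return out


class GSEA:
    """Model-style wrapper: construct from data, ``fit()`` returns results.

    Example
    -------
    >>> model = GSEA(count_matrix, collection)
    >>> res = model.fit(n_perm=1000, seed=7)
    >>> res.summary()  # tidy DataFrame
    """

    def __init__(self, cm: CountMatrix, collection: GeneSetCollection, qc: bool = True,
                 qc_thresholds: dict | None = None, gene_classes: dict | None = None):
        if qc:
            cm, self.qc_report = qc_filter(cm, qc_thresholds, gene_classes)
        else:
            self.qc_report = pd.DataFrame(columns=["barcode", "rule"])
        self.X, self.cm = log_normalize(cm)
        self.collection = collection

    def fit(self, n_perm: int = 1000, seed: int = 0, **kwargs) -> "GSEAResults":
        results = permutation_fdr(self.X, self.cm, self.collection, n_perm=n_perm, seed=seed, **kwargs)
        return GSEAResults(results, self.qc_report)


@dataclass
class GSEAResults:
    results: list[EnrichmentResult]
    qc_report: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return results_to_frame(self.results)

    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.significant]
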