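"""Immune-infiltration-related lncRNAs: correlation calls, enrichment,
pathway proximity, and one-vs-rest differential methylation.

Within every subtype cluster (with at least 10 samples), the Spearman
correlation between each lncRNA's promoter methylation and each cell type's
estimated infiltration is computed; p-values come from the t approximation
and are Benjamini-Hochberg adjusted across lncRNAs within each
(cluster, cell type) stratum. A lncRNA is called infiltration-related when
|rho| > 0.3 and adjusted p < 0.05 — both conditions are required.

Pathway involvement is assigned by genomic proximity: a called lncRNA linked
to any protein-coding gene whose interval lies within 10 kb (gap between
interval hulls, 0 when overlapping) inherits that gene's immune-pathway
annotations. Differential methylation is a one-vs-rest Welch t-test per
(cluster, gene), called at |delta beta| > 0.2 and raw p < 0.05.
"""

from __future__ import annotations

import logging
import warnings
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel

logger = logging.getLogger(__name__)

RHO_THRESHOLD = 0.3
ALPHA = 0.05
MIN_CLUSTER_SIZE = 10
PROXIMITY_WINDOW = 10_000
DELTA_THRESHOLD = 0.2


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1. NaNs propagate and are
    excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


def bonferroni_adjust(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    m = np.count_nonzero(~np.isnan(p))
    return np.minimum(p * m, 1.0)


_ADJUSTERS = {"bh": bh_adjust, "bonferroni": bonferroni_adjust}


# ---------------------------------------------------------------------------
# Spearman association
# ---------------------------------------------------------------------------


def _rank_zscore(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks column-wise, then z-score; returns (z, constant mask)."""
    ranks = np.apply_along_axis(stats.rankdata, 0, arr)
    mu = ranks.mean(axis=0, keepdims=True)
    sd = ranks.std(axis=0, ddof=0, keepdims=True)
    const = sd[0] == 0
    sd[:, const] = 1.0
    return (ranks - mu) / sd, const


def spearman_assoc(
    pm: pd.DataFrame,
    fractions: pd.DataFrame,
    clusters: Mapping[str, object] | pd.Series,
    rho_threshold: float = RHO_THRESHOLD,
    alpha: float = ALPHA,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    adjust: Literal["bh", "bonferroni"] = "bh",
) -> pd.DataFrame:
    """Per-(cluster, lncRNA, cell type) Spearman association records.

    ``pm`` is samples x genes promoter methylation, ``fractions`` samples x
    cell types. Clusters below ``min_cluster_size`` are skipped with a
    warning. Rho uses average ranks; p comes from the t approximation with
    n - 2 degrees of freedom; adjustment is applied across lncRNAs within
    each (cluster, cell type) stratum. Constant columns yield records with
    missing rho. Returns a tidy frame with columns
    ``cluster, gene_id, cell_type, rho, p_raw, p_adj, called``.
    """
    adjuster = _ADJUSTERS[adjust]
    clusters = pd.Series(clusters)
    cell_cols = [c for c in fractions.columns if c not in ("rmse", "corr", "perm_p")]
    records = []
    for cluster, members in clusters.groupby(clusters):
        samples = members.index.intersection(pm.index).intersection(fractions.index)
        n = len(samples)
        if n < min_cluster_size:
            warnings.warn(f"cluster {cluster!r} has {n} samples (< {min_cluster_size}); skipped")
            continue
        X = pm.loc[samples].to_numpy(dtype=float)
        Y = fractions.loc[samples, cell_cols].to_numpy(dtype=float)
        zx, const_x = _rank_zscore(X)
        zy, const_y = _rank_zscore(Y)
        rho = zx.T @ zy / n  # genes x cell types
        rho = np.clip(rho, -1.0, 1.0)
        rho[const_x, :] = np.nan
        rho[:, const_y] = np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p_raw = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p_raw[np.isclose(np.abs(rho), 1.0)] = 0.0
        for j, cell in enumerate(cell_cols):
            p_adj = adjuster(p_raw[:, j])
            for i, gene in enumerate(pm.columns):
                r = rho[i, j]
                called = (
                    not np.isnan(r)
                    and abs(r) > rho_threshold
                    and p_adj[i] < alpha
                )
                records.append(
                    {"cluster": cluster, "gene_id": gene, "cell_type": cell,
                     "rho": r, "p_raw": p_raw[i, j], "p_adj": p_adj[i],
                     "called": bool(called)}
                )
    return pd.DataFrame(
        records,
        columns=["cluster", "gene_id", "cell_type", "rho", "p_raw", "p_adj", "called"],
    )


# ---------------------------------------------------------------------------
# Category enrichment among called lncRNAs
# ---------------------------------------------------------------------------


def _fisher_by_category(
    called: set, categories: pd.Series
) -> list[dict[str, object]]:
    rows = []
    genes = categories.index
    called_mask = genes.isin(called)
    for cat in sorted(categories.unique()):
        in_cat = (categories == cat).to_numpy()
        table = np.array(
            [
                [int((in_cat & called_mask).sum()), int((in_cat & ~called_mask).sum())],
                [int((~in_cat & called_mask).sum()), int((~in_cat & ~called_mask).sum())],
            ]
        )
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {"category": cat, "odds_ratio": float(odds) if odds == odds else np.nan,
             "p": float(p), "n_called_in_category": int(table[0, 0]),
             "degenerate": bool(degenerate)}
        )
    return rows


def category_enrichment(
    called: set | Sequence[str] | pd.DataFrame,
    categories: pd.Series | Mapping[str, str],
) -> pd.DataFrame:
    """Fisher's exact enrichment of methylation categories among called genes.

    ``called`` may be a plain gene set (per-category test over the category
    universe) or an association frame with ``cell_type`` and ``called``
    columns, in which case the 2x2 test runs per (cell type, category).
    """
    categories = pd.Series(categories)
    if isinstance(called, pd.DataFrame):
        rows = []
        for cell, grp in called.groupby("cell_type"):
            called_set = set(grp.loc[grp["called"], "gene_id"])
            for rec in _fisher_by_category(called_set, categories):
                rec["cell_type"] = cell
                rows.append(rec)
        return pd.DataFrame(rows)
    called_set = set(called)
    uncalled = set(categories.index) - called_set
    if not called_set or not uncalled:
        raise ValueError("need at least one called and one uncalled gene")
    return pd.DataFrame(_fisher_by_category(called_set, categories))


# ---------------------------------------------------------------------------
# Pathway proximity
# ---------------------------------------------------------------------------


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap between two half-open intervals; 0 when they overlap or touch."""
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def link_pathways(
    lncrnas: Sequence[GeneModel],
    pcgs: Sequence[GeneModel],
    pathway_table: Mapping[str, Sequence[str]] | pd.DataFrame,
    window: int = PROXIMITY_WINDOW,
    distance_mode: Literal["hull", "tss"] = "hull",
) -> pd.DataFrame:
    """Link every lncRNA to protein-coding genes within ``window`` bases.

    ``pathway_table`` maps protein-coding gene id -> pathway names (or a
    frame with gene_id/pathway columns). Distance is the gap between the
    interval hulls (``hull``) or |TSS - TSS| (``tss``). Links to genes absent
    from the table carry empty pathway sets. Returns a frame with columns
    ``lncrna_id, pcg_id, distance, pathways`` (semicolon-joined names).
    """
    if isinstance(pathway_table, pd.DataFrame):
        pathway_map = {
            str(g): sorted(set(grp["pathway"].astype(str)))
            for g, grp in pathway_table.groupby("gene_id")
        }
    else:
        pathway_map = {g: sorted(set(v)) for g, v in pathway_table.items()}
    if not pathway_map:
        warnings.warn("empty pathway table: all links will carry empty pathway sets")

    rows = []
    pcg_by_chrom: dict[str, list[GeneModel]] = {}
    for p in pcgs:
        pcg_by_chrom.setdefault(p.chrom, []).append(p)
    for lnc in lncrnas:
        for pcg in pcg_by_chrom.get(lnc.chrom, []):
            if distance_mode == "hull":
                d = interval_gap(lnc.start, lnc.end, pcg.start, pcg.end)
            else:
                d = abs(lnc.tss - pcg.tss)
            if d <= window:
                rows.append(
                    {"lncrna_id": lnc.gene_id, "pcg_id": pcg.gene_id,
                     "distance": int(d),
                     "pathways": ";".join(pathway_map.get(pcg.gene_id, []))}
                )
    return pd.DataFrame(rows, columns=["lncrna_id", "pcg_id", "distance", "pathways"])


def count_pathways(
    links: pd.DataFrame,
    called: Sequence[str] | set | pd.DataFrame,
) -> pd.Series:
    """Distinct immune pathways reachable from each called lncRNA's links."""
    if isinstance(called, pd.DataFrame):
        called = set(called.loc[called["called"], "gene_id"])
    else:
        called = set(called)
    counts = {}
    grouped = links.groupby("lncrna_id") if len(links) else []
    by_lnc = {k: g for k, g in grouped}
    for gene in sorted(called):
        pathways: set[str] = set()
        grp = by_lnc.get(gene)
        if grp is not None:
            for entry in grp["pathways"]:
                if entry:
                    pathways.update(entry.split(";"))
        counts[gene] = len(pathways)
    return pd.Series(counts, dtype=int, name="n_pathways")


# ---------------------------------------------------------------------------
# One-vs-rest differential methylation
# ---------------------------------------------------------------------------


def diff_methylation(
    pm: pd.DataFrame,
    clusters: Mapping[str, object] | pd.Series,
    delta_threshold: float = DELTA_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Welch one-vs-rest t-test per (cluster, gene).

    delta = mean(cluster) - mean(rest); called at |delta| > delta_threshold
    and raw p < alpha (the call uses the unadjusted p). Groups with zero
    variance and equal means give p = 1. Returns a tidy frame with columns
    ``cluster, gene_id, delta, p, called``.
    """
    clusters = pd.Series(clusters).reindex(pm.index)
    records = []
    for cluster in sorted(clusters.dropna().unique()):
        in_mask = (clusters == cluster).to_numpy()
        a = pm.loc[in_mask].to_numpy(dtype=float)
        b = pm.loc[~in_mask].to_numpy(dtype=float)
        if a.shape[0] < 2 or b.shape[0] < 2:
            warnings.warn(f"cluster {cluster!r} or its complement has < 2 samples; skipped")
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit")
        delta = np.nanmean(a, axis=0) - np.nanmean(b, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
        # zero variance in both groups: p undefined by the t-test; equal means
        # mean no evidence (p = 1), unequal means mean certainty (p = 0)
        nanp = np.isnan(p)
        p[nanp & np.isclose(delta, 0.0)] = 1.0
        p[nanp & ~np.isclose(delta, 0.0)] = 0.0
        called = (np.abs(delta) > delta_threshold) & (p < alpha)
        for i, gene in enumerate(pm.columns):
            records.append(
                {"cluster": cluster, "gene_id": gene, "delta": float(delta[i]),
                 "p": float(p[i]), "called": bool(called[i])}
            )
    return pd.DataFrame(records, columns=["cluster", "gene_id", "delta", "p", "called"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_pathway_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    need = {"gene_id", "pathway"}
    if not need <= set(df.columns):
        raise ValueError(f"pathway table needs columns {sorted(need)}")
    return df
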