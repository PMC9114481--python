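"""Methylation subtype discovery by resampled consensus clustering.

The pipeline selects the most variable promoter probes (top 5% by standard
deviation by default), then repeatedly subsamples 80% of the samples without
replacement and clusters each subsample with k-means under a
Pearson-correlation distance (implemented by z-scoring each sample across
features, which makes squared Euclidean distance proportional to
1 - Pearson r). Co-clustering counts normalized by co-sampling counts give
the consensus matrix per k; the final assignment at each k is an
average-linkage hierarchical cut of 1 - consensus, and k is chosen by
minimizing the proportion of ambiguous clustering (PAC), the fraction of
off-diagonal consensus entries strictly between 0.1 and 0.9.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

PAC_WINDOW = (0.1, 0.9)


def select_variable_probes(
    beta: pd.DataFrame, top_fraction: float = 0.05
) -> pd.DataFrame:
    """Retain the ceil(top_fraction * P) probes with the largest SD.

    SD is computed over non-missing samples (ddof=1). Ties at the boundary
    are broken by probe-id lexicographic order so the selection is
    deterministic; the realized SD cutoff is logged.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if beta.shape[0] < 2:
        raise ValueError("need >= 2 samples to compute probe variation")
    sd = beta.std(axis=0, ddof=1, skipna=True)
    if np.nanmax(sd.to_numpy()) == 0:
        warnings.warn("all probes have zero variance; selection is by probe id only")
    n_keep = math.ceil(top_fraction * beta.shape[1])
    order = sorted(beta.columns, key=lambda p: (-sd[p], str(p)))
    keep = order[:n_keep]
    logger.info(
        "variable-probe selection: kept %d/%d probes, SD cutoff %.4f",
        n_keep, beta.shape[1], sd[keep[-1]],
    )
    return beta[keep]


@dataclass
class ConsensusResult:
    """Consensus matrices, assignments and PAC across the evaluated k range."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    assignments: pd.DataFrame  # samples x evaluated k
    pac: pd.Series  # k -> PAC
    chosen_k: int
    history: dict[int, list[tuple[np.ndarray, np.ndarray]]] | None = field(
        default=None, repr=False
    )

    def assignment(self, k: int | None = None) -> pd.Series:
        k = self.chosen_k if k is None else k
        return self.assignments[k]


def _zscore_rows(data: np.ndarray) -> np.ndarray:
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} samples have zero variance across features")
        sd[flat] = 1.0
    return (data - mu) / sd


def consensus_cluster(
    data: pd.DataFrame,
    k_range: Sequence[int] = range(2, 11),
    iterations: int = 50,
    resample: float = 0.8,
    seed: int | None = None,
    keep_history: bool = False,
) -> ConsensusResult:
    """Resampled consensus clustering of a samples x features matrix.

    Per iteration, floor(resample * n) samples are drawn without replacement
    and partitioned by k-means on row-z-scored data (Pearson distance).
    Consensus(i, j) = co-clustered count / co-sampled count. Deterministic
    under ``seed``. k values exceeding the resampled size are skipped with a
    warning. With ``keep_history`` the per-iteration (indices, labels) pairs
    are retained for auditing.
    """
    if not 0 < resample <= 1:
        raise ValueError("resample must be in (0, 1]")
    n = data.shape[0]
    k_range = [int(k) for k in k_range]
    if max(k_range) > n:
        raise ValueError(f"max k {max(k_range)} exceeds sample count {n}")
    m = int(math.floor(resample * n))
    rng = np.random.default_rng(seed)
    X = _zscore_rows(np.nan_to_num(data.to_numpy(dtype=float), nan=0.5))

    consensus: dict[int, np.ndarray] = {}
    history: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    pac = {}
    assignments = {}
    for k in k_range:
        if k > m:
            warnings.warn(f"k={k} exceeds resampled size {m}; skipped")
            continue
        co_clustered = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        runs = []
        for _ in range(iterations):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            km = KMeans(
                n_clusters=k, n_init=10,
                random_state=int(rng.integers(2 ** 31)),
            ).fit(X[idx])
            labels = km.labels_
            co_sampled[np.ix_(idx, idx)] += 1
            for lab in range(k):
                members = idx[labels == lab]
                co_clustered[np.ix_(members, members)] += 1
            if keep_history:
                runs.append((idx, labels))
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(co_sampled > 0, co_clustered / co_sampled, 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2
        consensus[k] = cons
        if keep_history:
            history[k] = runs

        tri = cons[np.triu_indices(n, k=1)]
        pac[k] = float(np.mean((tri > PAC_WINDOW[0]) & (tri < PAC_WINDOW[1])))

        dist = squareform(1.0 - cons, checks=False)
        link = hierarchy.linkage(dist, method="average")
        assignments[k] = hierarchy.fcluster(link, t=k, criterion="maxclust")

    if not consensus:
        raise ValueError("no k in k_range was evaluable")
    pac_series = pd.Series(pac).sort_index()
    chosen_k = int(pac_series.index[np.argmin(pac_series.to_numpy())])
    assign_df = pd.DataFrame(assignments, index=data.index)
    return ConsensusResult(
        sample_ids=list(data.index),
        consensus=consensus,
        assignments=assign_df,
        pac=pac_series,
        chosen_k=chosen_k,
        history=history if keep_history else None,
    )


def sample_correlation(pm: pd.DataFrame) -> pd.DataFrame:
    """Sample-sample Pearson correlation over genes (pairwise-complete).

    ``pm`` is samples x genes. Samples with zero variance get NaN
    correlations with a warning; the diagonal is 1 for defined samples.
    """
    if pm.shape[1] < 2:
        raise ValueError("need >= 2 genes")
    sd = pm.std(axis=1, ddof=0, skipna=True)
    flat = sd[sd == 0]
    if len(flat):
        warnings.warn(f"zero-variance samples, correlations undefined: {list(flat.index)[:5]}")
    return pm.T.corr(method="pearson")
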