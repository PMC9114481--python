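"""Reference-based cell-type deconvolution of methylation profiles.

A bulk beta profile is modelled as a non-negative combination of pure
cell-type reference profiles (the signature matrix, probes x cell types).
The default solver is non-negative least squares; a nu-support-vector
regression option mirrors the CIBERSORT estimator (linear kernel, best of
nu in {0.25, 0.5, 0.75} by reconstruction RMSE, negative coefficients
clipped at zero). Coefficients are renormalized to sum to one. Significance
comes from an empirical null: the profile's values are permuted across
probes and re-deconvolved; the permutation p-value is the add-one fraction
of null fit correlations at or above the observed one. No quantile
normalization is applied anywhere.

Mean-methylation signature scores (immune checkpoints, CYT, HLA, IFN, TILs
and similar probe sets) are plain per-sample means over each set's probes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

DEFAULT_CELL_TYPES = (
    "CD14", "CD19", "CD4_Eff", "CD56", "CD8",
    "Endothelial", "Eos", "Fib", "Neu", "Treg",
)

MIN_PROBE_OVERLAP = 0.8


@dataclass
class SignatureMatrix:
    """Probes x cell types reference betas; must have full column rank."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.shape[0] < vals.shape[1]:
            raise ValueError(
                f"signature has {vals.shape[0]} probes for {vals.shape[1]} "
                "cell types; rank deficient"
            )
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("signature values must be in [0, 1]")
        if np.linalg.matrix_rank(vals) < vals.shape[1]:
            raise ValueError("signature matrix is column-rank deficient")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values.to_numpy(dtype=float)))


@dataclass
class CellFractions:
    """Per-sample deconvolution result."""

    sample_id: str
    fractions: pd.Series
    rmse: float
    corr: float
    perm_p: float | None = None
    degenerate: bool = False


class CoverageError(ValueError):
    """Raised when too few signature probes are present in the profile."""


def _align(profile: pd.Series, signature: SignatureMatrix,
           min_overlap: float) -> tuple[np.ndarray, np.ndarray]:
    common = signature.values.index.intersection(profile.index)
    y = profile.loc[common].astype(float)
    keep = y.notna()
    covered = int(keep.sum())
    needed = min_overlap * len(signature.values)
    if covered < needed:
        raise CoverageError(
            f"only {covered}/{len(signature.values)} signature probes present "
            f"(< {min_overlap:.0%})"
        )
    S = signature.values.loc[common[keep.to_numpy()]].to_numpy(dtype=float)
    return y[keep].to_numpy(), S


def _fit_nnls(y: np.ndarray, S: np.ndarray) -> np.ndarray:
    w, _ = optimize.nnls(S, y)
    return w


def _fit_nu_svr(y: np.ndarray, S: np.ndarray) -> np.ndarray:
    from sklearn.svm import NuSVR

    # CIBERSORT convention: standardize both sides before the linear nu-SVR
    S_z = (S - S.mean()) / S.std()
    y_z = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    best_w, best_rmse = None, np.inf
    for nu in (0.25, 0.5, 0.75):
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(S_z, y_z)
        w = model.coef_.ravel().copy()
        rmse = float(np.sqrt(np.mean((S_z @ w - y_z) ** 2)))
        if rmse < best_rmse:
            best_w, best_rmse = w, rmse
    w = np.clip(best_w, 0.0, None)
    return w


def deconvolve(
    profile: pd.Series,
    signature: SignatureMatrix,
    method: Literal["nnls", "nu_svr"] = "nnls",
    min_overlap: float = MIN_PROBE_OVERLAP,
) -> CellFractions:
    """Estimate cell-type fractions of one beta profile.

    Missing signature probes are dropped pairwise, but at least
    ``min_overlap`` of the signature's probes must be present. Fractions are
    non-negative and renormalized to sum to 1; ``rmse`` and ``corr`` describe
    the reconstruction of the (raw) profile from the estimate.
    """
    y, S = _align(profile, signature, min_overlap)
    if method == "nnls":
        w = _fit_nnls(y, S)
    elif method == "nu_svr":
        w = _fit_nu_svr(y, S)
    else:
        raise ValueError(f"unknown method {method!r}")

    total = w.sum()
    name = str(profile.name) if profile.name is not None else ""
    if total <= 0:
        warnings.warn(f"sample {name}: all-zero coefficient vector; fractions undefined")
        fractions = pd.Series(np.nan, index=signature.cell_types)
        return CellFractions(name, fractions, float("nan"), float("nan"), degenerate=True)
    fractions = pd.Series(w / total, index=signature.cell_types)
    recon = S @ w
    rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
    corr = float(stats.pearsonr(recon, y)[0]) if np.std(recon) > 0 else float("nan")
    return CellFractions(name, fractions, rmse=rmse, corr=corr)


def permutation_p(
    profile: pd.Series,
    signature: SignatureMatrix,
    n_perm: int = 100,
    seed: int | None = None,
    method: Literal["nnls", "nu_svr"] = "nnls",
    min_overlap: float = MIN_PROBE_OVERLAP,
) -> float:
    """Add-one permutation p-value of the deconvolution fit correlation.

    The profile's values are permuted across its probes (signature fixed);
    p = (1 + #{null corr >= observed corr}) / (n_perm + 1), so the smallest
    attainable value is 1 / (n_perm + 1).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    observed = deconvolve(profile, signature, method=method, min_overlap=min_overlap)
    if observed.degenerate or np.isnan(observed.corr):
        raise ValueError("deconvolution must succeed before permutation testing")
    rng = np.random.default_rng(seed)
    vals = profile.to_numpy(dtype=float)
    exceed = 0
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(vals), index=profile.index)
        try:
            null = deconvolve(perm, signature, method=method, min_overlap=min_overlap)
        except CoverageError:  # permuted NaNs landing on signature probes
            continue
        if not null.degenerate and not np.isnan(null.corr) and null.corr >= observed.corr:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def deconvolve_matrix(
    beta: pd.DataFrame,
    signature: SignatureMatrix,
    method: Literal["nnls", "nu_svr"] = "nnls",
    n_perm: int | None = None,
    seed: int | None = None,
    min_overlap: float = MIN_PROBE_OVERLAP,
) -> pd.DataFrame:
    """Deconvolve every sample (row) of a samples x probes beta matrix.

    Returns a samples x cell-types frame with extra columns ``rmse``,
    ``corr`` and, when ``n_perm`` is given, ``perm_p``.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for sample_id, profile in beta.iterrows():
        cf = deconvolve(profile, signature, method=method, min_overlap=min_overlap)
        row = cf.fractions.copy()
        row["rmse"], row["corr"] = cf.rmse, cf.corr
        if n_perm:
            row["perm_p"] = permutation_p(
                profile, signature, n_perm=n_perm,
                seed=int(rng.integers(2 ** 31)), method=method,
                min_overlap=min_overlap,
            )
        row.name = sample_id
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Signature scores and per-cluster summaries
# ---------------------------------------------------------------------------


def signature_score(
    beta: pd.DataFrame,
    cpg_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-sample mean beta over each named probe set (samples x signatures).

    Sets with no probe present in the matrix yield NaN with a warning.
    """
    out = {}
    for name, probes in cpg_sets.items():
        present = [p for p in probes if p in beta.columns]
        if not present:
            warnings.warn(f"signature set {name!r} shares no probes with the matrix")
            out[name] = pd.Series(np.nan, index=beta.index)
            continue
        out[name] = beta[present].mean(axis=1, skipna=True)
    return pd.DataFrame(out)


def fractions_by_cluster(
    fractions: pd.DataFrame,
    clusters: Mapping[str, object] | pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-mean cell fractions and a one-way ANOVA per cell type.

    Clusters with fewer than 2 samples are excluded from the ANOVA (warned).
    Returns ``(means, anova)`` where ``anova`` has columns F and p indexed by
    cell type.
    """
    clusters = pd.Series(clusters).reindex(fractions.index)
    cell_cols = [c for c in fractions.columns if c not in ("rmse", "corr", "perm_p")]
    means = fractions[cell_cols].groupby(clusters).mean()

    usable = [
        grp.index for _, grp in fractions.groupby(clusters) if len(grp) >= 2
    ]
    small = clusters.value_counts()
    small = small[small < 2]
    if len(small):
        warnings.warn(f"clusters excluded from ANOVA (<2 samples): {list(small.index)}")
    if len(usable) < 2:
        raise ValueError("need >= 2 clusters with >= 2 samples for ANOVA")
    rows = {}
    for cell in cell_cols:
        groups = [fractions.loc[idx, cell].dropna().to_numpy() for idx in usable]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*groups)
        if np.isnan(F):  # all values identical across groups
            F, p = 0.0, 1.0
        rows[cell] = {"F": float(F), "p": float(p)}
    return means, pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_signature(path) -> SignatureMatrix:
    return SignatureMatrix(pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"]))


def read_cpg_sets(path) -> dict[str, list[str]]:
    """Read a TSV with columns ``set_name, probe_id`` into named probe sets."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return {str(k): g["probe_id"].astype(str).tolist()
            for k, g in df.groupby("set_name")}
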