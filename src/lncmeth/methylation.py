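"""Probe filtering, probe-to-promoter mapping, and lncRNA categorization.

The beta matrix is a samples x probes :class:`pandas.DataFrame` of methylation
fractions in [0, 1] (NaN allowed). Probes flagged as lying on chrX/Y,
overlapping a SNP, mapping non-uniquely, or absent from the EPIC array are
removed before promoter mapping. Promoter methylation of a gene in a sample is
the mean beta of its mapped probes (missing-aware), and a lncRNA is labelled

* ``hyper`` when its promoter beta exceeds 0.7 in more than 80% of samples,
* ``hypo`` when it is below 0.3 in more than 80% of samples,
* ``inter`` otherwise.

All inequalities are strict and fractions are taken over non-missing samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import PromoterInterval

logger = logging.getLogger(__name__)

EXCLUSION_FLAGS = ("chrXY", "snp_overlap", "non_unique", "not_on_epic")

HYPER_BETA = 0.7
HYPO_BETA = 0.3
SAMPLE_FRACTION = 0.8


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("probe_id", "chrom", "pos") + EXCLUSION_FLAGS


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest columns, uniqueness, and positions; returns the input."""
    missing = set(("probe_id", "chrom", "pos")) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest["probe_id"].duplicated().any():
        dup = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe ids: {dup[:5]}")
    if (manifest["pos"] < 0).any():
        raise ValueError("probe positions must be >= 0")
    return manifest


def filter_probes(manifest: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop probes carrying any exclusion flag; order preserved.

    A probe carrying several flags is removed once but counted under each flag
    in the returned report. Missing flag columns are treated as all-False.
    Returns ``(retained, report)`` where report maps flag -> flagged count.
    """
    validate_manifest(manifest)
    drop = np.zeros(len(manifest), dtype=bool)
    report: dict[str, int] = {}
    for flag in EXCLUSION_FLAGS:
        col = (
            manifest[flag].astype("boolean").fillna(False).to_numpy(dtype=bool)
            if flag in manifest.columns
            else np.zeros(len(manifest), dtype=bool)
        )
        report[flag] = int(col.sum())
        drop |= col
    retained = manifest.loc[~drop].copy()
    report["retained"] = len(retained)
    report["removed"] = int(drop.sum())
    logger.info("probe filter: %s", report)
    if retained.empty:
        warnings.warn("all probes removed by exclusion filters")
    return retained, report


# ---------------------------------------------------------------------------
# Probe -> promoter mapping
# ---------------------------------------------------------------------------


def map_probes_to_promoters(
    probes: pd.DataFrame,
    promoters: Sequence[PromoterInterval],
) -> dict[str, list[str]]:
    """Assign each probe to every promoter whose half-open interval holds it.

    Multi-assignment is allowed when promoters overlap. Genes that receive no
    probe are absent from the result. Raises when the manifest and annotation
    share no chromosome names (a naming-convention mismatch).
    """
    validate_manifest(probes)
    probe_chroms = set(probes["chrom"].astype(str))
    promoter_chroms = {p.chrom for p in promoters}
    if promoters is not None and probe_chroms and promoter_chroms and not (
        probe_chroms & promoter_chroms
    ):
        raise ValueError(
            "no chromosome names shared between probe manifest and annotation; "
            f"manifest has {sorted(probe_chroms)[:5]}, "
            f"annotation has {sorted(promoter_chroms)[:5]}"
        )
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in probes.groupby("chrom"):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        by_chrom[str(chrom)] = (
            grp["pos"].to_numpy()[order],
            grp["probe_id"].to_numpy()[order],
        )
    mapping: dict[str, list[str]] = {}
    for prom in promoters:
        entry = by_chrom.get(prom.chrom)
        if entry is None:
            continue
        pos, ids = entry
        lo = np.searchsorted(pos, prom.start, side="left")
        hi = np.searchsorted(pos, prom.end, side="left")  # half-open: pos < end
        if hi > lo:
            mapping[prom.gene_id] = list(ids[lo:hi])
    return mapping


# ---------------------------------------------------------------------------
# Promoter-level summarization
# ---------------------------------------------------------------------------


@dataclass
class PromoterMethylation:
    """Samples x genes mean promoter beta with the probe sets behind it."""

    values: pd.DataFrame
    probes_per_gene: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


def validate_beta(beta: pd.DataFrame) -> pd.DataFrame:
    vals = beta.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bad = np.nansum((vals < 0) | (vals > 1))
    if bad:
        raise ValueError(f"{int(bad)} beta values outside [0, 1]")
    return beta


def summarize_promoter(
    beta: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]],
) -> PromoterMethylation:
    """Mean beta over each gene's mapped probes, per sample (missing-aware).

    ``beta`` is samples x probes. Genes whose probes are all absent from the
    matrix are dropped with a warning; a sample with no observed probe for a
    gene gets NaN.
    """
    validate_beta(beta)
    have = set(beta.columns)
    cols: dict[str, np.ndarray] = {}
    kept: dict[str, list[str]] = {}
    dropped = []
    arr = beta.to_numpy(dtype=float)
    col_index = {p: i for i, p in enumerate(beta.columns)}
    for gene, probes in mapping.items():
        present = [p for p in probes if p in have]
        if not present:
            dropped.append(gene)
            continue
        idx = [col_index[p] for p in present]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cols[gene] = np.nanmean(arr[:, idx], axis=1)
        kept[gene] = present
    if dropped:
        warnings.warn(
            f"{len(dropped)} genes dropped: no mapped probe present in the "
            f"beta matrix (e.g. {dropped[:3]})"
        )
    values = pd.DataFrame(cols, index=beta.index)
    return PromoterMethylation(values=values, probes_per_gene=kept)


# ---------------------------------------------------------------------------
# Three-way categorization
# ---------------------------------------------------------------------------


def categorize(
    pm: PromoterMethylation | pd.DataFrame,
    hyper_threshold: float = HYPER_BETA,
    hypo_threshold: float = HYPO_BETA,
    sample_fraction: float = SAMPLE_FRACTION,
) -> pd.DataFrame:
    """Label each gene hyper / hypo / inter from its promoter betas.

    Fractions are computed over non-missing samples per gene; a gene observed
    in no sample is labelled ``unclassifiable``. Returns a per-gene frame with
    ``label, frac_above, frac_below, n_samples``.
    """
    values = pm.values if isinstance(pm, PromoterMethylation) else pm
    if values.shape[0] < 1:
        raise ValueError("need at least one sample")
    arr = values.to_numpy(dtype=float)
    observed = ~np.isnan(arr)
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac_above = np.where(
            n_obs > 0, np.nansum(arr > hyper_threshold, axis=0) / np.maximum(n_obs, 1), np.nan
        )
        frac_below = np.where(
            n_obs > 0, np.nansum(arr < hypo_threshold, axis=0) / np.maximum(n_obs, 1), np.nan
        )
    label = np.where(
        frac_above > sample_fraction, "hyper",
        np.where(frac_below > sample_fraction, "hypo", "inter"),
    ).astype(object)
    label[n_obs == 0] = "unclassifiable"
    out = pd.DataFrame(
        {
            "label": label,
            "frac_above": frac_above,
            "frac_below": frac_below,
            "n_samples": n_obs,
        },
        index=values.columns,
    )
    out.index.name = "gene_id"
    n_un = int((out["label"] == "unclassifiable").sum())
    if n_un:
        warnings.warn(f"{n_un} genes unclassifiable (no non-missing sample)")
    return out


def categorize_by_group(
    pm: PromoterMethylation | pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run :func:`categorize` separately on each sample group (e.g. cancer type)."""
    values = pm.values if isinstance(pm, PromoterMethylation) else pm
    groups = pd.Series(groups).reindex(values.index)
    return {
        str(g): categorize(values.loc[idx.index], **kwargs)
        for g, idx in groups.dropna().groupby(groups.dropna())
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for flag in EXCLUSION_FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].fillna(False).astype(bool)
    return validate_manifest(df)


def read_beta(path, probe_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a beta TSV, auto-detecting orientation.

    On disk the matrix may be probes x samples (the written convention) or
    samples x probes; when ``probe_ids`` is given the orientation is detected
    from overlap with the row index, otherwise rows are assumed to be probes.
    Returns samples x probes.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if probe_ids is not None:
        probe_ids = set(probe_ids)
        rows = len(probe_ids & set(df.index.astype(str)))
        cols = len(probe_ids & set(df.columns.astype(str)))
        orient = "probes-by-samples" if rows >= cols else "samples-by-probes"
    else:
        orient = "probes-by-samples"
    logger.info("beta matrix read as %s", orient)
    out = df.T if orient == "probes-by-samples" else df
    return validate_beta(out)


def write_beta(beta: pd.DataFrame, path) -> None:
    """Write samples x probes beta as probes x samples TSV."""
    beta.T.to_csv(path, sep="\t", na_rep="NA")
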