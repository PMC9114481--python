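"""Synthetic methylation-array cohorts with fully planted ground truth.

Everything the downstream stages consume is generated here from one seeded
configuration: a toy single-chromosome annotation (lncRNAs plus protein-coding
genes, some placed within 10 kb of a lncRNA with known linkage truth), a 450K-
style probe manifest with exclusion flags, a block-structured cell-type
signature matrix, a samples x probes beta matrix, and a survival table.

The generative model, briefly:

* every lncRNA is planted ``hyper`` (promoter mean beta 0.85), ``hypo``
  (0.15) or ``inter`` (0.5); probe-level betas are drawn from
  ``Beta(mu * phi, (1 - mu) * phi)`` so values are bounded in [0, 1] and the
  concentration ``phi`` (``beta_precision``) plays the role of array noise —
  ``phi = inf`` is the noiseless limit;
* a small set of ``inter`` lncRNAs is cluster-informative: their promoter mean
  is shifted by ``+/- cluster_shift`` depending on the sample's planted
  cluster, which is what consensus clustering is meant to recover;
* per-sample cell-type mixtures are Dirichlet(1); signature-probe betas equal
  ``mixture . signature`` plus the same beta noise;
* selected ``inter`` lncRNAs are coupled to one cell-type fraction through a
  Gaussian copula on the latent scale, calibrated so the promoter-level
  Spearman correlation is approximately ``assoc_rho`` (rank-based statistics
  only see the copula, not the marginal map);
* survival times are exponential with cluster-specific hazards spanning a
  ``hazard_ratio``-fold range, censored by an independent uniform time whose
  horizon is solved numerically to hit the requested censoring rate.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .annotation import GeneModel, promoter_of, write_gene_table
from .deconvolution import DEFAULT_CELL_TYPES, SignatureMatrix
from .methylation import EXCLUSION_FLAGS, write_beta

# planted promoter means per category
CATEGORY_MU = {"hyper": 0.85, "hypo": 0.15, "inter": 0.5}

# rng stream keys so each operation is reproducible in isolation
_STREAM_ANNOTATION = 1
_STREAM_SIGNATURE = 2
_STREAM_BETA = 3
_STREAM_SURVIVAL = 4
_STREAM_PATHWAYS = 5

# 17 immune-pathway names for the synthetic gene-set table
IMMUNE_PATHWAYS = tuple(f"ImmunePathway{i + 1:02d}" for i in range(17))


@dataclass
class SyntheticConfig:
    """Simulation parameters; defaults are the conditions exercised in tests."""

    n_samples: int = 200
    n_clusters: int = 4
    n_lncrna: int = 300
    n_pcg: int = 100
    probes_per_promoter: int = 3
    n_cell_types: int = 10
    beta_precision: float = 200.0
    cluster_shift: float = 0.3
    frac_hyper: float = 0.3
    frac_hypo: float = 0.4
    assoc_rho: float = 0.5
    hazard_ratio: float = 3.0
    censor_rate: float = 0.2
    seed: int = 0
    # secondary knobs
    flag_fraction: float = 0.02
    probes_per_cell_type: int = 50
    frac_near_pcg: float = 0.5
    frac_cluster_informative: float = 0.05
    n_assoc_lncrna: int = 20
    baseline_hazard: float = 0.1
    with_sequences: bool = True

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples, "n_clusters": self.n_clusters,
            "n_lncrna": self.n_lncrna, "n_pcg": self.n_pcg,
            "probes_per_promoter": self.probes_per_promoter,
            "n_cell_types": self.n_cell_types,
            "probes_per_cell_type": self.probes_per_cell_type,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_clusters > self.n_samples:
            raise ValueError("n_clusters must be <= n_samples")
        if not self.beta_precision > 0:
            raise ValueError("beta_precision must be positive")
        if not 0 <= self.cluster_shift <= 1:
            raise ValueError("cluster_shift must be in [0, 1]")
        if self.frac_hyper < 0 or self.frac_hypo < 0 or self.frac_hyper + self.frac_hypo > 1:
            raise ValueError("frac_hyper + frac_hypo must be <= 1 with both >= 0")
        if not -1 < self.assoc_rho < 1:
            raise ValueError("assoc_rho must be in (-1, 1)")
        if not self.hazard_ratio > 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0 <= self.flag_fraction < 1:
            raise ValueError("flag_fraction must be in [0, 1)")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class SyntheticTruth:
    """Planted ground truth paired with a simulated beta matrix."""

    cluster_of_sample: pd.Series
    category_of_lncrna: pd.Series
    mixture_of_sample: pd.DataFrame
    planted_assoc: pd.DataFrame  # gene_id, cell_type, rho
    cluster_informative: pd.Series  # gene_id -> informative cluster index
    survival_params: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        rows = self.mixture_of_sample.to_numpy()
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise AssertionError("mixture rows must sum to 1")
        if (rows < 0).any():
            raise AssertionError("mixture fractions must be >= 0")


@dataclass
class Annotation:
    """Toy genome annotation plus probe manifest and linkage truth."""

    genes: list[GeneModel]
    manifest: pd.DataFrame
    probe_gene: pd.Series  # probe_id -> gene_id (internal truth)
    linked_pairs: pd.DataFrame  # lncrna_id, pcg_id, distance
    chrom_lengths: dict[str, int]

    @property
    def lncrnas(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "lncRNA"]

    @property
    def pcgs(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "protein_coding"]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

# gap bounds keep promoters disjoint (> 4 kb TSS spacing) while controlling
# whether neighboring gene intervals fall within the 10-kb proximity window
_NEAR_GAP = (4_100, 9_000)
_FAR_GAP = (10_500, 20_000)
_GENE_LEN = (2_000, 5_000)


def _random_sequence(rng: np.random.Generator, length: int, gc: float, cpg_boost: float) -> str:
    """i.i.d. sequence with target GC, plus CG dinucleotides planted at a
    ``cpg_boost`` fraction of non-overlapping (even) positions."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
    starts = 2 * np.flatnonzero(rng.random(length // 2) < cpg_boost)
    starts = starts[starts + 1 < length]
    arr[starts] = b"C"
    arr[starts + 1] = b"G"
    return arr.tobytes().decode()


def generate_annotation(
    config: SyntheticConfig, chrom_length: int | None = None
) -> Annotation:
    """Lay out lncRNAs and protein-coding genes on one toy chromosome.

    Promoters are non-overlapping by construction; a ``frac_near_pcg``
    fraction of protein-coding genes is placed within 10 kb of a distinct
    lncRNA (linkage truth recorded), all other inter-gene gaps exceed 10 kb.
    Each promoter receives on average ``probes_per_promoter`` probes (at least
    one), placed uniformly inside the 4-kb window; each exclusion flag is set
    independently with probability ``flag_fraction``.
    """
    config.validate()
    rng = config._rng(_STREAM_ANNOTATION)
    chrom = "chr1"

    n_near = min(int(round(config.frac_near_pcg * config.n_pcg)), config.n_lncrna)
    near_hosts = set(
        rng.choice(config.n_lncrna, size=n_near, replace=False).tolist()
    )

    genes: list[GeneModel] = []
    linked_rows = []
    cursor = 10_000
    pcg_idx = 0

    def _place(gene_id: str, biotype: str, gap_lo: int, gap_hi: int) -> GeneModel:
        nonlocal cursor
        gap = int(rng.integers(gap_lo, gap_hi + 1))
        length = int(rng.integers(_GENE_LEN[0], _GENE_LEN[1] + 1))
        start = cursor + gap
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(
            gene_id=gene_id, biotype=biotype, chrom=chrom, strand=strand,
            start=start, end=start + length,
            exon_count=1 + int(rng.poisson(2)),
        )
        cursor = gene.end
        genes.append(gene)
        return gene

    far_pcg_pool = config.n_pcg - n_near
    for i in range(config.n_lncrna):
        lnc = _place(f"LNC{i:04d}", "lncRNA", *_FAR_GAP)
        if i in near_hosts:
            pcg = _place(f"PCG{pcg_idx:04d}", "protein_coding", *_NEAR_GAP)
            pcg_idx += 1
            linked_rows.append(
                {"lncrna_id": lnc.gene_id, "pcg_id": pcg.gene_id,
                 "distance": pcg.start - lnc.end}
            )
        if far_pcg_pool > 0 and i % max(1, config.n_lncrna // max(far_pcg_pool, 1)) == 0:
            if pcg_idx < config.n_pcg:
                _place(f"PCG{pcg_idx:04d}", "protein_coding", *_FAR_GAP)
                pcg_idx += 1
    while pcg_idx < config.n_pcg:
        _place(f"PCG{pcg_idx:04d}", "protein_coding", *_FAR_GAP)
        pcg_idx += 1

    total_length = cursor + 10_000
    if chrom_length is not None:
        if cursor + 2_000 > chrom_length:
            raise ValueError(
                f"genes need {cursor + 2000} bases but chromosome is "
                f"{chrom_length}; promoters cannot fit"
            )
        total_length = chrom_length

    if config.with_sequences:
        for gene in genes:
            # CpG-island-like promoters for a subset, echoing the biology that
            # high-CpG promoters tend to be unmethylated
            island = rng.random() < 0.4
            gc = 0.60 if island else 0.45
            boost = 0.12 if island else 0.02
            gene.sequence = _random_sequence(rng, gene.end - gene.start, gc, boost)

    # probes: >= 1 per promoter, mean probes_per_promoter
    probe_rows = []
    probe_gene = {}
    counter = 0
    for gene in genes:
        prom = promoter_of(gene, chrom_length=total_length)
        n_p = 1 + int(rng.poisson(max(config.probes_per_promoter - 1, 0)))
        offsets = np.sort(rng.choice(prom.end - prom.start, size=n_p, replace=False))
        for off in offsets:
            pid = f"cg{counter:08d}"
            counter += 1
            row = {"probe_id": pid, "chrom": chrom, "pos": int(prom.start + off)}
            for flag in EXCLUSION_FLAGS:
                row[flag] = bool(rng.random() < config.flag_fraction)
            probe_rows.append(row)
            probe_gene[pid] = gene.gene_id

    manifest = pd.DataFrame(probe_rows)
    return Annotation(
        genes=genes,
        manifest=manifest,
        probe_gene=pd.Series(probe_gene, name="gene_id"),
        linked_pairs=pd.DataFrame(
            linked_rows, columns=["lncrna_id", "pcg_id", "distance"]
        ),
        chrom_lengths={chrom: total_length},
    )


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------


def generate_signature(config: SyntheticConfig) -> SignatureMatrix:
    """Block-structured reference signature: each cell type owns a block of
    probes with beta near 0.9 in that type and near 0.1 elsewhere."""
    config.validate()
    if config.n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = config._rng(_STREAM_SIGNATURE)
    k = config.n_cell_types
    per = config.probes_per_cell_type
    n_probes = k * per
    if n_probes < k:
        raise ValueError(f"{n_probes} probes cannot span {k} cell types (rank)")
    if k == 10:
        names = list(DEFAULT_CELL_TYPES)
    else:
        names = [f"CT{i + 1:02d}" for i in range(k)]
    values = np.full((n_probes, k), 0.1)
    for j in range(k):
        values[j * per:(j + 1) * per, j] = 0.9
    values += rng.uniform(-0.05, 0.05, size=values.shape)
    values = np.clip(values, 0.01, 0.99)
    probe_ids = [f"sig{i:05d}" for i in range(n_probes)]
    return SignatureMatrix(pd.DataFrame(values, index=probe_ids, columns=names))


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


def _spearman_to_copula_rho(rho_s: float) -> float:
    """Latent Gaussian correlation giving Spearman rho_s under the copula."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def simulate_beta(
    config: SyntheticConfig,
    annotation: Annotation | None = None,
    signature: SignatureMatrix | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the samples x probes beta matrix and its planted truth."""
    config.validate()
    if annotation is None:
        annotation = generate_annotation(config)
    if signature is None:
        signature = generate_signature(config)
    rng = config._rng(_STREAM_BETA)
    phi = config.beta_precision

    n = config.n_samples
    k = config.n_clusters
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # balanced planted clusters
    base = np.tile(np.arange(k), n // k + 1)[:n]
    clusters = pd.Series(rng.permutation(base), index=sample_ids, name="cluster")

    # mixtures
    mixtures = pd.DataFrame(
        rng.dirichlet(np.ones(config.n_cell_types), size=n),
        index=sample_ids, columns=list(signature.cell_types),
    )

    # lncRNA categories
    lnc_ids = [g.gene_id for g in annotation.lncrnas]
    order = rng.permutation(len(lnc_ids))
    n_hyper = int(round(config.frac_hyper * len(lnc_ids)))
    n_hypo = int(round(config.frac_hypo * len(lnc_ids)))
    categories = pd.Series("inter", index=lnc_ids, name="category")
    categories.iloc[order[:n_hyper]] = "hyper"
    categories.iloc[order[n_hyper:n_hyper + n_hypo]] = "hypo"

    inter_ids = [g for g in lnc_ids if categories[g] == "inter"]
    inter_ids = list(rng.permutation(inter_ids))

    # planted associations: half positive, half negative rho
    n_assoc = min(config.n_assoc_lncrna, len(inter_ids))
    assoc_rows = []
    for i in range(n_assoc):
        gene = inter_ids.pop()
        cell = signature.cell_types[i % config.n_cell_types]
        rho = config.assoc_rho if i % 2 == 0 else -config.assoc_rho
        assoc_rows.append({"gene_id": gene, "cell_type": cell, "rho": rho})
    planted_assoc = pd.DataFrame(assoc_rows, columns=["gene_id", "cell_type", "rho"])

    # cluster-informative genes, one block of genes per cluster
    n_info = min(max(k, int(round(config.frac_cluster_informative * len(lnc_ids)))),
                 len(inter_ids))
    informative = {}
    for i in range(n_info):
        informative[inter_ids.pop()] = i % k
    cluster_informative = pd.Series(informative, dtype=int, name="cluster")

    # per-(sample, gene) promoter mean mu
    gene_ids = [g.gene_id for g in annotation.genes]
    mu = np.full((n, len(gene_ids)), CATEGORY_MU["inter"])
    gene_col = {g: j for j, g in enumerate(gene_ids)}
    for g in lnc_ids:
        mu[:, gene_col[g]] = CATEGORY_MU[categories[g]]
    cl = clusters.to_numpy()
    for g, target in cluster_informative.items():
        mu[:, gene_col[g]] = np.where(
            cl == target, 0.5 + config.cluster_shift, 0.5 - config.cluster_shift
        )
    # Gaussian-copula coupling to one cell-type fraction
    for row in planted_assoc.itertuples():
        f = mixtures[row.cell_type].to_numpy()
        rank = stats.rankdata(f)
        z_f = stats.norm.ppf((rank - 0.5) / n)
        r_lat = _spearman_to_copula_rho(row.rho)
        z_g = r_lat * z_f + math.sqrt(1 - r_lat ** 2) * rng.standard_normal(n)
        mu[:, gene_col[row.gene_id]] = 0.5 + 0.3 * (2 * stats.norm.cdf(z_g) - 1)

    # expand gene mu to probes
    probe_ids = annotation.manifest["probe_id"].tolist()
    probe_cols = np.array([gene_col[annotation.probe_gene[p]] for p in probe_ids])
    mu_probes = mu[:, probe_cols]

    # signature probes
    mu_sig = np.clip(mixtures.to_numpy() @ signature.values.to_numpy().T, 0.01, 0.99)

    full_mu = np.concatenate([mu_probes, mu_sig], axis=1)
    if math.isinf(phi):
        values = full_mu
    else:
        values = rng.beta(full_mu * phi, (1.0 - full_mu) * phi)
    values = np.clip(values, 0.0, 1.0)

    beta = pd.DataFrame(
        values, index=sample_ids, columns=probe_ids + list(signature.probe_ids)
    )
    truth = SyntheticTruth(
        cluster_of_sample=clusters,
        category_of_lncrna=categories,
        mixture_of_sample=mixtures,
        planted_assoc=planted_assoc,
        cluster_informative=cluster_informative,
    )
    truth.validate()
    return beta, truth


def generate_pathway_table(config: SyntheticConfig, annotation: Annotation) -> pd.DataFrame:
    """Assign each protein-coding gene 1-3 of 17 immune pathways.

    Emulates an immune gene-set table (gene_id, pathway); one row per
    membership.
    """
    rng = config._rng(_STREAM_PATHWAYS)
    rows = []
    for gene in annotation.pcgs:
        k = int(rng.integers(1, 4))
        for pw in rng.choice(IMMUNE_PATHWAYS, size=k, replace=False):
            rows.append({"gene_id": gene.gene_id, "pathway": str(pw)})
    return pd.DataFrame(rows, columns=["gene_id", "pathway"])


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def _uniform_censor_horizon(hazards: np.ndarray, target: float) -> float:
    """Horizon u of C ~ U(0, u) giving mean censoring probability ``target``.

    For T ~ Exp(lam), P(C < T) = (1 - exp(-lam u)) / (lam u), decreasing in u.
    """

    def mean_censored(u: float) -> float:
        x = hazards * u
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1e9 / hazards.min()
    return float(optimize.brentq(lambda u: mean_censored(u) - target, lo, hi))


def simulate_survival(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Exponential survival with cluster-specific hazards and uniform censoring.

    Hazards span a ``hazard_ratio``-fold range geometrically from the first to
    the last cluster. Age, sex and WHO category are independent of cluster.
    Returns a frame with sample_id index and columns
    ``time, event, age, sex, who_category, lncrna_cluster``.
    """
    config.validate()
    rng = config._rng(_STREAM_SURVIVAL)
    clusters = truth.cluster_of_sample
    k = int(clusters.max()) + 1
    lam0 = config.baseline_hazard
    if k > 1:
        hazards = {j: lam0 * config.hazard_ratio ** (j / (k - 1)) for j in range(k)}
    else:
        hazards = {0: lam0}
    truth.survival_params = hazards

    lam = clusters.map(hazards).to_numpy()
    n = len(clusters)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        horizon = _uniform_censor_horizon(
            np.array(list(hazards.values())), config.censor_rate
        )
        c = rng.uniform(0.0, horizon, size=n)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    df = pd.DataFrame(
        {
            "time": np.maximum(time, 1e-9),
            "event": event,
            "age": np.clip(rng.normal(10.0, 4.0, size=n), 0.0, 18.0),
            "sex": rng.integers(0, 2, size=n),
            "who_category": rng.choice(["WHO_A", "WHO_B", "WHO_C"], size=n),
            "lncrna_cluster": [f"C{j + 1}" for j in clusters],
        },
        index=clusters.index,
    )
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# Bundle + serialization
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    annotation: Annotation
    signature: SignatureMatrix
    beta: pd.DataFrame
    truth: SyntheticTruth
    survival: pd.DataFrame
    pathway_table: pd.DataFrame


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the complete synthetic cohort in one call."""
    annotation = generate_annotation(config)
    signature = generate_signature(config)
    beta, truth = simulate_beta(config, annotation, signature)
    survival = simulate_survival(truth, config)
    pathways = generate_pathway_table(config, annotation)
    return SyntheticDataset(config, annotation, signature, beta, truth, survival, pathways)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write every table as TSV (plus a config echo); returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        paths[name] = path

    _save("genes.tsv", lambda p: write_gene_table(ds.annotation.genes, p))
    _save("manifest.tsv",
          lambda p: ds.annotation.manifest.to_csv(p, sep="\t", index=False, na_rep="NA"))
    _save("beta.tsv", lambda p: write_beta(ds.beta, p))
    _save("signature.tsv",
          lambda p: ds.signature.values.to_csv(p, sep="\t", na_rep="NA"))
    _save("survival.tsv", lambda p: ds.survival.to_csv(p, sep="\t", na_rep="NA"))
    _save("truth_clusters.tsv",
          lambda p: ds.truth.cluster_of_sample.to_csv(p, sep="\t"))
    _save("truth_categories.tsv",
          lambda p: ds.truth.category_of_lncrna.rename_axis("gene_id").to_csv(p, sep="\t"))
    _save("truth_mixtures.tsv",
          lambda p: ds.truth.mixture_of_sample.rename_axis("sample_id").to_csv(p, sep="\t"))
    _save("truth_assoc.tsv",
          lambda p: ds.truth.planted_assoc.to_csv(p, sep="\t", index=False))
    _save("truth_linked_pairs.tsv",
          lambda p: ds.annotation.linked_pairs.to_csv(p, sep="\t", index=False))
    _save("pathways.tsv",
          lambda p: ds.pathway_table.to_csv(p, sep="\t", index=False))
    _save("config.json",
          lambda p: p.write_text(json.dumps(dataclasses.asdict(ds.config), indent=2)))
    return paths
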