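"""End-to-end pipeline: synth -> categorize -> cluster -> deconvolve ->
immune-lncrna -> survival, orchestrated from one validated configuration.

Stages communicate only through TSV files in the output directory, so each is
independently re-runnable; every written file is sha256-hashed into a run
manifest, identical config + seed gives identical hashes, and a rerun resumes
past stages whose outputs already match the manifest. One global seed
deterministically derives per-stage seeds by hashing the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, deconvolution, immune, methylation, survival as surv_mod
from .annotation import promoters_of, read_gene_table
from .synthetic import SyntheticConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

STAGES = ("synth", "categorize", "cluster", "deconvolve", "immune_lncrna", "survival")


@dataclass
class PipelineConfig:
    """All stage parameters plus the output directory and the global seed."""

    outdir: str = "lncmeth_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # categorize
    flank: int = 2000
    hyper_threshold: float = 0.7
    hypo_threshold: float = 0.3
    sample_fraction: float = 0.8
    # cluster
    top_fraction: float = 0.05
    k_min: int = 2
    k_max: int = 8
    iterations: int = 50
    resample: float = 0.8
    # deconvolve
    deconv_method: str = "nnls"
    n_perm: int = 100
    min_overlap: float = 0.8
    # immune
    rho_threshold: float = 0.3
    alpha: float = 0.05
    window: int = 10_000
    adjust: str = "bh"
    distance_mode: str = "hull"
    delta_threshold: float = 0.2
    # survival
    min_prop: float = 0.1
    corrected_p: bool = False
    max_cutpoint_genes: int = 5


def validate_config(config: PipelineConfig) -> list[str]:
    """Return every constraint violation as ``field: message``; empty = ok."""
    errors: list[str] = []

    def check(ok: bool, name: str, msg: str) -> None:
        if not ok:
            errors.append(f"{name}: {msg}")

    c = config
    check(0 < c.hyper_threshold < 1, "hyper_threshold", "must be in (0, 1)")
    check(0 < c.hypo_threshold < 1, "hypo_threshold", "must be in (0, 1)")
    check(c.hypo_threshold < c.hyper_threshold, "hypo_threshold",
          "must be below hyper_threshold")
    check(0 < c.sample_fraction < 1, "sample_fraction", "must be in (0, 1)")
    check(c.flank > 0, "flank", "must be positive")
    check(0 < c.top_fraction <= 1, "top_fraction", "must be in (0, 1]")
    check(2 <= c.k_min <= c.k_max, "k_min", "need 2 <= k_min <= k_max")
    check(c.k_max <= c.synthetic.n_samples, "k_max",
          "must not exceed the sample count")
    check(c.iterations >= 1, "iterations", "must be >= 1")
    check(0 < c.resample <= 1, "resample", "must be in (0, 1]")
    check(c.deconv_method in ("nnls", "nu_svr"), "deconv_method",
          "must be nnls or nu_svr")
    check(c.n_perm == 0 or c.n_perm >= 10, "n_perm", "must be 0 or >= 10")
    check(0 < c.min_overlap <= 1, "min_overlap", "must be in (0, 1]")
    check(0 < c.rho_threshold < 1, "rho_threshold", "must be in (0, 1)")
    check(0 < c.alpha < 1, "alpha", "must be in (0, 1)")
    check(c.window >= 0, "window", "must be >= 0")
    check(c.adjust in ("bh", "bonferroni"), "adjust", "must be bh or bonferroni")
    check(c.distance_mode in ("hull", "tss"), "distance_mode", "must be hull or tss")
    check(0 < c.delta_threshold < 1, "delta_threshold", "must be in (0, 1)")
    check(0 < c.min_prop < 0.5, "min_prop", "must be in (0, 0.5)")
    try:
        c.synthetic.validate()
    except ValueError as err:
        errors.append(f"synthetic: {err}")
    return errors


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRunner:
    """Executes stages in dependency order, hashing outputs into a manifest."""

    def __init__(self, config: PipelineConfig):
        errors = validate_config(config)
        if errors:
            raise ValueError("invalid pipeline config:\n" + "\n".join(errors))
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest: dict[str, dict[str, str]] = {}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())

    # -- bookkeeping --------------------------------------------------------

    def _stage_done(self, stage: str) -> bool:
        entry = self.manifest.get(stage)
        if not entry:
            return False
        for name, digest in entry.items():
            path = self.outdir / name
            if not path.exists() or _sha256(path) != digest:
                return False
        return True

    def _record(self, stage: str, files: list[Path]) -> None:
        self.manifest[stage] = {
            str(p.relative_to(self.outdir)): _sha256(p) for p in files
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    def _path(self, name: str) -> Path:
        return self.outdir / name

    # -- stages -------------------------------------------------------------

    def run(self, resume: bool = True) -> dict[str, dict[str, str]]:
        for stage in STAGES:
            if resume and self._stage_done(stage):
                logger.info("stage %s up to date; skipped", stage)
                continue
            logger.info("running stage %s", stage)
            getattr(self, f"_stage_{stage}")()
        return self.manifest

    def _stage_synth(self) -> None:
        cfg = dataclasses.replace(
            self.config.synthetic, seed=stage_seed(self.config.seed, "synth")
        )
        ds = simulate_dataset(cfg)
        paths = write_dataset(ds, self.outdir / "data")
        self._record("synth", list(paths.values()))

    def _load_inputs(self):
        data = self.outdir / "data"
        genes = read_gene_table(data / "genes.tsv")
        manifest = methylation.read_manifest(data / "manifest.tsv")
        beta = methylation.read_beta(
            data / "beta.tsv", probe_ids=manifest["probe_id"]
        )
        return genes, manifest, beta

    def _stage_categorize(self) -> None:
        genes, manifest, beta = self._load_inputs()
        retained, report = methylation.filter_probes(manifest)
        proms = promoters_of(genes, flank=self.config.flank)
        mapping = methylation.map_probes_to_promoters(retained, proms)
        pm = methylation.summarize_promoter(beta, mapping)
        lnc_ids = {g.gene_id for g in genes if g.biotype == "lncRNA"}
        cats = methylation.categorize(
            pm,
            hyper_threshold=self.config.hyper_threshold,
            hypo_threshold=self.config.hypo_threshold,
            sample_fraction=self.config.sample_fraction,
        )
        cats = cats.loc[cats.index.isin(lnc_ids)]
        files = []
        pm.values.to_csv(self._path("promoter_methylation.tsv"), sep="\t", na_rep="NA")
        files.append(self._path("promoter_methylation.tsv"))
        cats.to_csv(self._path("categories.tsv"), sep="\t", na_rep="NA")
        files.append(self._path("categories.tsv"))
        self._path("filter_report.json").write_text(json.dumps(report, indent=2))
        files.append(self._path("filter_report.json"))
        self._record("categorize", files)

    def _stage_cluster(self) -> None:
        genes, manifest, beta = self._load_inputs()
        retained, _ = methylation.filter_probes(manifest)
        lnc = [g for g in genes if g.biotype == "lncRNA"]
        proms = promoters_of(lnc, flank=self.config.flank)
        mapping = methylation.map_probes_to_promoters(retained, proms)
        lnc_probes = sorted({p for probes in mapping.values() for p in probes})
        sub = beta[[p for p in lnc_probes if p in beta.columns]]
        selected = clustering.select_variable_probes(sub, self.config.top_fraction)
        result = clustering.consensus_cluster(
            selected,
            k_range=range(self.config.k_min, self.config.k_max + 1),
            iterations=self.config.iterations,
            resample=self.config.resample,
            seed=stage_seed(self.config.seed, "cluster"),
        )
        files = []
        assign = result.assignments.copy()
        assign.index.name = "sample_id"
        assign.to_csv(self._path("cluster_assignments.tsv"), sep="\t")
        files.append(self._path("cluster_assignments.tsv"))
        cons = pd.DataFrame(
            result.consensus[result.chosen_k],
            index=result.sample_ids, columns=result.sample_ids,
        )
        cons.to_csv(self._path("consensus_matrix.tsv"), sep="\t")
        files.append(self._path("consensus_matrix.tsv"))
        pac = result.pac.rename_axis("k").rename("pac").to_frame()
        pac["chosen"] = pac.index == result.chosen_k
        pac.to_csv(self._path("pac.tsv"), sep="\t")
        files.append(self._path("pac.tsv"))
        self._record("cluster", files)

    def _stage_deconvolve(self) -> None:
        _, manifest, beta = self._load_inputs()
        signature = deconvolution.read_signature(self.outdir / "data" / "signature.tsv")
        fractions = deconvolution.deconvolve_matrix(
            beta, signature,
            method=self.config.deconv_method,
            n_perm=self.config.n_perm or None,
            seed=stage_seed(self.config.seed, "deconvolve"),
            min_overlap=self.config.min_overlap,
        )
        fractions.index.name = "sample_id"
        fractions.to_csv(self._path("cell_fractions.tsv"), sep="\t", na_rep="NA")
        self._record("deconvolve", [self._path("cell_fractions.tsv")])

    def _chosen_clusters(self) -> pd.Series:
        assign = pd.read_csv(
            self._path("cluster_assignments.tsv"), sep="\t", index_col=0
        )
        pac = pd.read_csv(self._path("pac.tsv"), sep="\t", index_col=0)
        chosen_k = int(pac.index[pac["chosen"]][0])
        return assign[str(chosen_k)]

    def _stage_immune_lncrna(self) -> None:
        genes, _, _ = self._load_inputs()
        pm = pd.read_csv(self._path("promoter_methylation.tsv"), sep="\t", index_col=0,
                         na_values=["NA"])
        cats = pd.read_csv(self._path("categories.tsv"), sep="\t", index_col=0)
        fractions = pd.read_csv(self._path("cell_fractions.tsv"), sep="\t", index_col=0,
                                na_values=["NA"])
        clusters = self._chosen_clusters()
        lnc_ids = [g.gene_id for g in genes if g.biotype == "lncRNA"]
        pm_lnc = pm[[g for g in lnc_ids if g in pm.columns]]
        assoc = immune.spearman_assoc(
            pm_lnc, fractions, clusters,
            rho_threshold=self.config.rho_threshold,
            alpha=self.config.alpha,
            adjust=self.config.adjust,  # type: ignore[arg-type]
        )
        enrich = immune.category_enrichment(assoc, cats["label"])
        pathway_table = immune.read_pathway_table(self.outdir / "data" / "pathways.tsv")
        lnc = [g for g in genes if g.biotype == "lncRNA"]
        pcg = [g for g in genes if g.biotype == "protein_coding"]
        links = immune.link_pathways(
            lnc, pcg, pathway_table,
            window=self.config.window,
            distance_mode=self.config.distance_mode,  # type: ignore[arg-type]
        )
        counts = immune.count_pathways(links, assoc)
        diff = immune.diff_methylation(
            pm_lnc, clusters,
            delta_threshold=self.config.delta_threshold,
            alpha=self.config.alpha,
        )
        files = []
        for name, df, index in (
            ("associations.tsv", assoc, False),
            ("category_enrichment.tsv", enrich, False),
            ("pathway_links.tsv", links, False),
            ("pathway_counts.tsv", counts.rename_axis("gene_id").to_frame(), True),
            ("diff_methylation.tsv", diff, False),
        ):
            df.to_csv(self._path(name), sep="\t", index=index, na_rep="NA")
            files.append(self._path(name))
        self._record("immune_lncrna", files)

    def _stage_survival(self) -> None:
        surv = surv_mod.read_survival_table(self.outdir / "data" / "survival.tsv")
        clusters = self._chosen_clusters()
        surv = surv.copy()
        surv["lncrna_cluster"] = clusters.reindex(surv.index).map(lambda c: f"C{c}")
        lr = surv_mod.nested_cox_lr(surv)
        files = []
        lr.to_csv(self._path("nested_cox_lr.tsv"), sep="\t", index=False, na_rep="NA")
        files.append(self._path("nested_cox_lr.tsv"))

        pm = pd.read_csv(self._path("promoter_methylation.tsv"), sep="\t", index_col=0,
                         na_values=["NA"])
        diff = pd.read_csv(self._path("diff_methylation.tsv"), sep="\t")
        called = (
            diff[diff["called"]]
            .assign(abs_delta=lambda d: d["delta"].abs())
            .sort_values("abs_delta", ascending=False)
        )
        top_genes = list(dict.fromkeys(called["gene_id"]))[: self.config.max_cutpoint_genes]
        rows = []
        for gene in top_genes:
            values = pm[gene].reindex(surv.index)
            try:
                cut = surv_mod.optimal_cutpoint(
                    values, surv["time"], surv["event"],
                    min_prop=self.config.min_prop,
                    corrected_p=self.config.corrected_p,
                    seed=stage_seed(self.config.seed, f"cutpoint:{gene}"),
                )
            except surv_mod.CutpointError as err:
                logger.warning("cutpoint for %s failed: %s", gene, err)
                continue
            rows.append(
                {"gene_id": gene, "cutpoint": cut.cutpoint, "max_stat": cut.max_stat,
                 "n_low": cut.n_low, "n_high": cut.n_high,
                 "logrank_p": cut.logrank_p, "corrected_p": cut.corrected_p}
            )
        pd.DataFrame(
            rows, columns=["gene_id", "cutpoint", "max_stat", "n_low", "n_high",
                           "logrank_p", "corrected_p"],
        ).to_csv(self._path("survival_cutpoints.tsv"), sep="\t", index=False, na_rep="NA")
        files.append(self._path("survival_cutpoints.tsv"))
        self._record("survival", files)


def run_pipeline(config: PipelineConfig, resume: bool = True) -> dict[str, dict[str, str]]:
    """Validate the config, run all stages, and return the output manifest."""
    return PipelineRunner(config).run(resume=resume)


def load_pipeline_config(path) -> PipelineConfig:
    """Load a YAML config; the ``synthetic`` block maps to SyntheticConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    synth = SyntheticConfig(**raw.pop("synthetic", {}))
    return PipelineConfig(synthetic=synth, **raw)
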