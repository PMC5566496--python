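"""End-to-end orchestration of the combined metataxonomic + metabonomic analysis.

``run_full`` chains the stages: simulate (or ingest) -> NMR preprocessing ->
supervised chemometrics (per clinical target) -> community ecology -> qPCR
quantification -> metabolite-taxon networks, writing every artifact under the
output directory and a manifest recording, per stage, the parameters, seed
and SHA-256 hash of every produced file.  All randomness derives from the
single run seed; rerunning the same config and seed reproduces every hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import ecology as eco
from . import io as pio
from . import network as net
from . import nmr
from . import qpcr
from . import synthetic as syn

__all__ = ["RunConfig", "RunManifest", "run_full"]

log = logging.getLogger("mucometa")

STAGES = ("simulate", "nmr", "chemometrics", "ecology", "qpcr", "network")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    In simulate mode (default) the cohort generator provides all inputs;
    otherwise ``otu_path``/``spectra_path``/``metadata_path``/``ct_path``
    must point at existing files in the documented formats.
    """

    outdir: str = "mucometa_run"
    seed: int = 0
    simulate: bool = True
    n_patients: int = 18
    otu_path: str | None = None
    spectra_path: str | None = None
    metadata_path: str | None = None
    ct_path: str | None = None
    resolution: float = nmr.BIN_RESOLUTION
    exclusion_regions: list = field(
        default_factory=lambda: [
            [r.lo_ppm, r.hi_ppm, r.label] for r in nmr.DEFAULT_EXCLUSIONS
        ]
    )
    model_targets: list = field(
        default_factory=lambda: ["EMVI", "LVI", "KRAS", "poor_differentiation"]
    )
    cv_scheme_otu: str = "leave-one-sample-out"
    cv_scheme_nmr: str = "leave-one-patient-out"
    n_orthogonal: int = 1
    mmc_components: int = 2
    pca_components: int = 2
    t2_confidence: float = 0.95
    alpha: float = 0.05
    use_fdr: bool = False
    n_clusters: int = 3
    nmds_restarts: int = 10
    stage_map: dict = field(
        default_factory=lambda: {0: "0/1", 1: "0/1", 2: "0/1", 3: "3", 4: "4"}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        if not self.simulate:
            for name in ("otu_path", "spectra_path", "metadata_path", "ct_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} must point at an existing file")


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, Path], parameters: dict,
               seed: int, started: float) -> None:
        self.stages[stage] = {
            "parameters": parameters,
            "seed": seed,
            "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                        for name, p in outputs.items()},
            "started": started,
            "finished": time.time(),
        }

    def output_hashes(self) -> dict[str, str]:
        return {
            name: meta["sha256"]
            for stage in self.stages.values()
            for name, meta in stage["outputs"].items()
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"seed": self.seed, "config": self.config,
                                          "stages": self.stages}, indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    states = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {s: int(v % (2**31 - 1)) for s, v in zip(STAGES, states)}


def run_full(cfg: RunConfig) -> RunManifest:
    """Execute every pipeline stage; any failure aborts with a stage-named error."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest = RunManifest(seed=cfg.seed, config=asdict(cfg))
    state: dict = {}
    for stage in STAGES:
        started = time.time()
        log.info("stage %s starting", stage)
        try:
            outputs, params = _STAGE_FUNCS[stage](cfg, seeds[stage], outdir, state)
        except Exception as exc:  # re-raise with the stage named
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, outputs, params, seeds[stage], started)
        log.info("stage %s done (%.1fs)", stage, time.time() - started)
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ------------------------------------------------------------------- stages


def _stage_simulate(cfg, seed, outdir, state):
    if cfg.simulate:
        cohort = syn.CohortConfig(n_patients=cfg.n_patients, seed=seed)
        meta, truth = syn.simulate_metadata(cohort)
        otu_cfg = syn.default_otu_config()
        otu, otu_truth = syn.simulate_otu_table(meta, otu_cfg, seed + 1)
        spectra, spec_truth = syn.simulate_spectra(
            meta, resolution=cfg.resolution, seed=seed + 2
        )
        ct, ct_truth = syn.simulate_qpcr(meta, seed=seed + 3)
        truth.dilution_factors = spec_truth.dilution_factors
        truth.concentrations = spec_truth.concentrations
        truth.class_labels = spec_truth.class_labels
        truth.ct_copy_ratios = ct_truth.ct_copy_ratios
        truth.planted_effects = otu_truth.planted_effects
        paths = {
            "metadata": outdir / "metadata.csv",
            "otu": outdir / "otu_table.tsv",
            "spectra": outdir / "spectra.csv",
            "ct": outdir / "ct.csv",
            "truth": outdir / "truth.json",
        }
        pio.write_metadata(meta, paths["metadata"])
        pio.write_otu_table(otu, paths["otu"])
        pio.write_spectra(spectra, paths["spectra"])
        pio.write_ct(ct, paths["ct"])
        truth.to_json(paths["truth"])
        state.update(meta=meta, otu=otu, spectra_df=spectra, ct=ct, truth=truth)
        return paths, {"mode": "simulate", "n_patients": cfg.n_patients}
    meta = pio.read_metadata(cfg.metadata_path)
    state.update(
        meta=meta,
        otu=pio.read_otu_table(cfg.otu_path),
        spectra=pio.read_spectra(cfg.spectra_path),
        ct=pio.read_ct(cfg.ct_path),
        truth=None,
    )
    return {}, {"mode": "ingest"}


def _spectra_from_frame(df: pd.DataFrame) -> list[nmr.Spectrum]:
    ppm = df["ppm"].to_numpy()
    return [nmr.Spectrum(ppm=ppm, intensity=df[c].to_numpy(), sample_id=c)
            for c in df.columns if c != "ppm"]


def _stage_nmr(cfg, seed, outdir, state):
    spectra = state.get("spectra") or _spectra_from_frame(state["spectra_df"])
    calibrated = [nmr.calibrate_to_alanine(s) for s in spectra]
    m = nmr.bin_spectra(calibrated, resolution=cfg.resolution)
    regions = tuple(nmr.ExclusionRegion(lo, hi, label)
                    for lo, hi, label in cfg.exclusion_regions)
    m = nmr.apply_exclusions(m, regions)
    m = nmr.pqn_normalize(m)
    scaled = nmr.unit_variance_scale(m)
    state.update(nmr_normalized=m, nmr_scaled=scaled)
    paths = {"spectral_matrix": outdir / "spectral_matrix.tsv",
             "dilution_factors": outdir / "pqn_dilution_factors.csv"}
    pd.DataFrame(m.X, index=m.sample_ids,
                 columns=[f"{b:.5f}" for b in m.bins]).to_csv(
        paths["spectral_matrix"], sep="\t", index_label="sample_id")
    pd.Series(m.dilution_factors, index=m.sample_ids, name="dilution_factor").to_csv(
        paths["dilution_factors"], index_label="sample_id")
    return paths, {"resolution": cfg.resolution, "n_bins": int(m.bins.size),
                   "exclusions": cfg.exclusion_regions}


def _stage_chemometrics(cfg, seed, outdir, state):
    meta = state["meta"]
    norm = state["nmr_normalized"]
    scaled = state["nmr_scaled"]
    results: dict = {}

    # --- PCA outlier screen on the scaled NMR matrix
    pca = chem.fit_pca(scaled.X, n_components=cfg.pca_components,
                       confidence=cfg.t2_confidence)
    _, removed = chem.remove_outliers(scaled.X, pca, sample_ids=scaled.sample_ids)
    keep_ids = [s for s in scaled.sample_ids if s not in set(removed)]
    keep = np.array([s in set(keep_ids) for s in scaled.sample_ids])
    results["pca_outliers"] = {"removed": removed, "n_retained": int(keep.sum()),
                              "t2_limit": pca.t2_limit}
    log.info("PCA outlier screen removed %d of %d samples", len(removed), keep.size)

    labels = meta.loc[keep_ids, "site"].map(
        lambda s: "tumour" if s == "tumour" else "normal").to_numpy()
    groups = meta.loc[keep_ids, "patient_id"].to_numpy()
    X_norm = norm.X[keep]

    # --- tumour/normal MMC + OPLS-DA on the NMR matrix, patient-held-out CV
    cv_mmc = chem.cross_validate(
        {"kind": "mmc", "n_components": cfg.mmc_components},
        X_norm, labels, groups=groups, scheme=cfg.cv_scheme_nmr)
    roc_mmc = chem.roc_auc(cv_mmc.predictions["decision_score"].to_numpy(),
                           cv_mmc.predictions["label"].to_numpy())
    cv_opls = chem.cross_validate(
        {"kind": "oplsda", "n_orthogonal": cfg.n_orthogonal},
        X_norm, labels, groups=groups, scheme=cfg.cv_scheme_nmr)
    roc_opls = chem.roc_auc(cv_opls.predictions["decision_score"].to_numpy(),
                            cv_opls.predictions["label"].to_numpy())
    results["nmr_tumour_vs_normal"] = {
        "mmc": {"q2": cv_mmc.q2, "accuracy": cv_mmc.accuracy, "auc": roc_mmc.auc},
        "oplsda": {"q2": cv_opls.q2, "accuracy": cv_opls.accuracy,
                   "auc": roc_opls.auc},
        "cv_scheme": cfg.cv_scheme_nmr,
    }

    # --- pseudo-loadings ANOVA coloured by FDR q, driven by the MMC scores
    mmc_model = chem.fit_mmc(
        _uv(X_norm), labels, n_components=cfg.mmc_components)
    ploadings = chem.pseudo_loadings_anova(
        X_norm, labels, scores=mmc_model.scores[:, 0],
        class_of_interest="tumour",
        variable_names=[f"{b:.5f}" for b in norm.bins])

    # --- per-histology PLS-DA on OTU relative abundances
    otu = state["otu"]
    rel = otu.div(otu.sum(axis=1), axis=0)
    per_target = {}
    for target in cfg.model_targets:
        y = meta.loc[rel.index, target]
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2 or counts.min() < 3:
            per_target[target] = {"skipped": "insufficient class balance"}
            continue
        cv = chem.cross_validate(
            {"kind": "plsda", "n_components": 2}, rel.to_numpy(), y.to_numpy(),
            groups=meta.loc[rel.index, "patient_id"].to_numpy(),
            scheme=cfg.cv_scheme_otu)
        roc = chem.roc_auc(cv.predictions["decision_score"].to_numpy(),
                           cv.predictions["label"].to_numpy())
        per_target[target] = {"q2": cv.q2, "accuracy": cv.accuracy, "auc": roc.auc}
    results["otu_plsda_per_target"] = per_target

    state.update(chem_results=results, keep_ids=keep_ids)
    paths = {"model_summary": outdir / "model_summary.json",
             "pseudo_loadings": outdir / "pseudo_loadings.tsv"}
    paths["model_summary"].write_text(json.dumps(results, indent=1, default=float))
    ploadings.to_csv(paths["pseudo_loadings"], sep="\t", index_label="ppm")
    return paths, {"targets": cfg.model_targets}


def _uv(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    return (X - X.mean(axis=0)) / np.where(sd <= 0, 1.0, sd)


def _stage_ecology(cfg, seed, outdir, state):
    meta = state["meta"]
    table = eco.OtuTable.from_frames(state["otu"], meta)
    table = eco.rarefy(table, seed=seed)
    shannon = eco.shannon_per_sample(table)
    tau = eco.tau_per_sample(table)
    shannon_norm = eco.normalize_index_to_tumour(shannon, table.patient_ids, table.sites)
    tau_norm = eco.normalize_index_to_tumour(tau, table.patient_ids, table.sites)
    D = eco.bray_curtis(table)
    dend = eco.ward_cluster(D)
    clusters = dend.cut(cfg.n_clusters)
    flags, n_concordant = eco.patient_concordance(dend, table.patient_ids)
    ordination = eco.nmds(D, n_restarts=cfg.nmds_restarts, seed=seed)
    candidate = meta.loc[clusters.index, ["EMVI", "LVI", "KRAS", "differentiation",
                                          "T_stage", "N_stage"]]
    usable = [c for c in candidate.columns if candidate[c].nunique() >= 2]
    skipped = sorted(set(candidate.columns) - set(usable))
    if skipped:
        log.info("skipping single-level clinical features %s", skipped)
    assoc = eco.cluster_feature_association(
        clusters, candidate[usable],
        ordinal=tuple(c for c in ("T_stage", "N_stage") if c in usable))
    tests = eco.taxon_feature_tests(
        table, meta.loc[table.counts.index, "poor_differentiation"])

    state.update(eco_table=table, eco_summary={
        "n_concordant_patients": n_concordant,
        "n_patients": int(flags.size),
        "nmds_stress": ordination.stress,
        "cluster_sizes": clusters.value_counts().to_dict(),
    })
    paths = {
        "indices": outdir / "ecology_indices.csv",
        "distances": outdir / "bray_curtis.tsv",
        "dendrogram": outdir / "dendrogram.nwk",
        "nmds": outdir / "nmds_coordinates.csv",
        "concordance": outdir / "patient_concordance.csv",
        "cluster_assoc": outdir / "cluster_feature_association.tsv",
        "taxon_tests": outdir / "taxon_feature_tests.tsv",
    }
    pd.DataFrame({"shannon": shannon, "tau": tau, "shannon_norm": shannon_norm,
                  "tau_norm": tau_norm}).to_csv(paths["indices"],
                                                index_label="sample_id")
    D.to_csv(paths["distances"], sep="\t", index_label="sample_id")
    paths["dendrogram"].write_text(dend.to_newick() + "\n")
    ordination.coordinates.to_csv(paths["nmds"], index_label="sample_id")
    flags.rename("concordant").to_csv(paths["concordance"], index_label="patient_id")
    assoc.to_csv(paths["cluster_assoc"], sep="\t")
    tests.to_csv(paths["taxon_tests"], sep="\t")
    return paths, {"n_clusters": cfg.n_clusters, "rarefaction_seed": seed,
                   "n_concordant": n_concordant}


def _stage_qpcr(cfg, seed, outdir, state):
    meta = state["meta"]
    per_sample, excluded = qpcr.delta_ct(state["ct"])
    stat, p, n_pairs = qpcr.site_comparison(
        per_sample["rel_quantity"], meta["site"], meta["patient_id"])
    state["qpcr_summary"] = {"wilcoxon_statistic": stat, "p_value": p,
                             "n_pairs": n_pairs, "excluded": excluded}
    paths = {"qpcr": outdir / "qpcr_relative_quantity.csv",
             "qpcr_test": outdir / "qpcr_site_comparison.json"}
    per_sample.to_csv(paths["qpcr"], index_label="sample_id")
    paths["qpcr_test"].write_text(json.dumps(state["qpcr_summary"], indent=1))
    return paths, {"test": "paired one-sided Wilcoxon (tumour > 10cm)"}


def _stage_network(cfg, seed, outdir, state):
    meta = state["meta"]
    norm = state["nmr_normalized"]
    regions = net.metabolite_regions_from_templates(syn.default_metabolite_templates())
    metab = net.integrate_metabolites(norm, regions)
    otu = state["otu"]
    rel = otu.div(otu.sum(axis=1), axis=0).loc[metab.index]
    # keep genera observed in at least a quarter of samples, else rho is ties-only
    prevalent = (otu.loc[metab.index] > 0).mean(axis=0) >= 0.25
    rel = rel.loc[:, prevalent]
    is_tumour = meta.loc[metab.index, "site"] == "tumour"
    nets = {}
    for name, mask in (("tumour", is_tumour), ("normal", ~is_tumour)):
        rho, p = net.correlate(metab[mask.to_numpy()], rel[mask.to_numpy()])
        nets[name] = net.threshold_network(rho, p, alpha=cfg.alpha, fdr=cfg.use_fdr)
    comparison = net.compare_networks(nets["tumour"], nets["normal"])

    stages = meta.loc[metab.index, "T_stage"].map(cfg.stage_map)
    stage_nets = {}
    for stage_label in sorted(stages.unique()):
        mask = (stages == stage_label).to_numpy()
        if mask.sum() < 6:
            continue
        rho, p = net.correlate(metab[mask], rel[mask])
        stage_nets[stage_label] = net.threshold_network(
            rho, p, alpha=cfg.alpha, fdr=cfg.use_fdr)
    consistent = (net.stage_consistency(stage_nets) if len(stage_nets) >= 2 else [])

    paths = {}
    for name, es in nets.items():
        paths[f"edges_{name}"] = outdir / f"network_edges_{name}.tsv"
        paths[f"nodes_{name}"] = outdir / f"network_nodes_{name}.tsv"
        es.edges.to_csv(paths[f"edges_{name}"], sep="\t", index=False)
        es.nodes.to_csv(paths[f"nodes_{name}"], sep="\t")
        paths[f"layout_{name}"] = outdir / f"network_layout_{name}.csv"
        positions = (net.spring_layout(es, seed=seed).positions
                     if len(es.nodes) else {})
        pd.DataFrame(positions, index=["x", "y"]).T.to_csv(
            paths[f"layout_{name}"], index_label="node")
    paths["comparison"] = outdir / "network_comparison.json"
    paths["comparison"].write_text(json.dumps(comparison, indent=1, default=str))
    paths["stage_consistent"] = outdir / "network_stage_consistent.json"
    paths["stage_consistent"].write_text(json.dumps(
        {"stages": sorted(stage_nets), "consistent_edges":
         [[list(pair), sign] for pair, sign in consistent]}, indent=1))
    state["network_summary"] = {
        "tumour": nets["tumour"].summary(),
        "normal": nets["normal"].summary(),
        "shared_nodes": comparison["shared_nodes"],
        "n_stage_consistent": len(consistent),
    }
    return paths, {"alpha": cfg.alpha, "fdr": cfg.use_fdr,
                   "stages": sorted(stage_nets)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "nmr": _stage_nmr,
    "chemometrics": _stage_chemometrics,
    "ecology": _stage_ecology,
    "qpcr": _stage_qpcr,
    "network": _stage_network,
}
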