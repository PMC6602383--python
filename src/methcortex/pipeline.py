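"""Configuration and orchestration of a full analysis run.

A :class:`PipelineConfig` (single YAML file; unknown keys rejected)
drives the stages in order: QC -> normalisation -> batch adjustment ->
cell composition -> clock -> per-region and cross-cortex differential
methylation -> DMRs -> CNV -> co-methylation network -> enrichment.
Stage parameters default to the pipeline's standard values (discovery
p < 5e-5, DMR seed p < 1e-3 within 300 bp and >= 2 probes at Sidak 0.05,
5% variability in the middle 80% of samples, soft power 7, minimum
module size 100, merge height 0.1, pathway sizes 10-2000). Every output
is written as plain text (CSV/BED/JSON) into the run directory and the
effective configuration is echoed into the run log. ``make_demo``
materialises a fully synthetic input set with its truth tables so the
complete pipeline can be exercised without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv, composition_clock, dmp, dmr, enrichment, ioformats, network, preprocess, synthdata
from ._design import build_design
from .ioformats import FormatError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_demo"]


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters of one run."""

    manifest: str = ""
    phenotypes: str = ""
    beta: str | None = None
    m_intensity: str | None = None
    u_intensity: str | None = None
    detection_p: str | None = None
    pathways: str | None = None
    clock: str | None = None
    cell_reference: str | None = None
    de_table: str | None = None
    out_dir: str = "methcortex_run"
    # differential methylation
    discovery_p: float = 5e-05
    covariates: tuple[str, ...] = ("age", "sex", "bank", "cets")
    # DMR stage
    dmr_seed_p: float = 1e-3
    dmr_max_dist: int = 300
    dmr_min_probes: int = 2
    dmr_sidak_alpha: float = 0.05
    # network stage
    net_min_range: float = 0.05
    net_central_frac: float = 0.80
    net_soft_power: float = 7
    net_min_module_size: int = 100
    net_merge_cut_height: float = 0.1
    net_max_block_size: int = 15_000
    net_max_probes: int = 5_000
    # enrichment
    pathway_size_min: int = 10
    pathway_size_max: int = 2000
    # CNV
    dup15q_locus: str = "chr15:23000000-28500000"
    cnv_gain_threshold: float = 0.3
    cnv_min_probes: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        cfg = cls(**raw)
        if isinstance(cfg.covariates, list):
            cfg.covariates = tuple(cfg.covariates)
        return cfg

    def locus_tuple(self) -> tuple[str, int, int]:
        chrom, span = self.dup15q_locus.split(":")
        start, end = span.split("-")
        return chrom, int(start), int(end)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages and write results to the run directory.

    Returns the run directory. Stages whose inputs are not configured
    (e.g. CNV without intensity matrices) are skipped with a warning;
    any stage failure raises, halting the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("methcortex")
    root.addHandler(handler)
    summary: dict = {"config": dataclasses.asdict(config)}
    logger.info("configuration: %s", json.dumps(dataclasses.asdict(config), default=str))

    try:
        manifest = ioformats.read_manifest(config.manifest)
        pheno = ioformats.read_phenotypes(config.phenotypes)
        m_mat = u_mat = None
        if config.m_intensity and config.u_intensity:
            m_mat = ioformats.read_beta(config.m_intensity, value_range=None)
            u_mat = ioformats.read_beta(config.u_intensity, value_range=None)
            beta = preprocess.normalize_by_probe_type(m_mat, u_mat, manifest)
            logger.info("normalised betas computed from intensities")
        elif config.beta:
            beta = ioformats.read_beta(config.beta)
        else:
            raise FormatError("config needs either a beta matrix or M/U intensities")

        detp = ioformats.read_beta(config.detection_p) if config.detection_p else None
        beta, qc_report = preprocess.run_qc(beta, manifest, pheno, detection_p=detp)
        _write_json(qc_report.to_dict(), out / "qc_report.json")
        summary["qc"] = qc_report.to_dict()
        summary["qc"].pop("donor_mismatch_pairs", None)

        if pheno["bank"].nunique() > 1:
            covs = build_design(pheno.loc[beta.columns], ["diagnosis", "age", "sex"])
            beta = preprocess.eb_batch_adjust(beta, pheno.loc[beta.columns, "bank"], covariates=covs)
            logger.info("empirical-Bayes batch adjustment over %d banks", pheno["bank"].nunique())

        if config.cell_reference:
            ref = ioformats.read_cell_reference(config.cell_reference)
            props = composition_clock.estimate_neuronal_proportions(beta, ref, pheno)
            pheno["neuronal_proportion"] = props
            props.rename("neuronal_proportion").to_csv(out / "neuronal_proportions.csv")

        if config.clock:
            clock = ioformats.read_clock(config.clock)
            ages = composition_clock.dnam_age(beta, clock)
            ages.rename("dnam_age").to_csv(out / "dnam_age.csv")
            accel = {}
            for case in ("iASD", "dup15q"):
                if (pheno["diagnosis"] == case).any():
                    res = composition_clock.age_acceleration_test(ages, pheno, case)
                    accel[case] = res.reset_index().to_dict(orient="records")
            summary["age_acceleration"] = accel

        # differential methylation
        results: dict[str, pd.DataFrame] = {}
        for case in ("iASD", "dup15q"):
            if not (pheno["diagnosis"] == case).any():
                continue
            for region in sorted(set(pheno["region"])):
                res = dmp.fit_ols(beta, pheno, case=case, region=region, covariates=config.covariates)
                res = dmp.call_dmps(res, discovery=config.discovery_p)
                res.to_csv(out / f"dmp_{case}_{region}.csv")
                results[f"{case}_{region}"] = res
            cortical = [r for r in ("PFC", "TC") if (pheno["region"] == r).any()]
            if len(cortical) == 2:
                res = dmp.fit_lme(beta, pheno, case=case, covariates=config.covariates)
                res = dmp.call_dmps(res, discovery=config.discovery_p)
                res.to_csv(out / f"dmp_{case}_cross_cortex.csv")
                results[f"{case}_cross_cortex"] = res
        summary["dmp_counts"] = {
            key: int((res["tier"] != "").sum()) for key, res in results.items()
        }

        # DMRs on the cross-cortex scans
        for key in [k for k in results if k.endswith("cross_cortex")]:
            p = results[key]["p_value"].dropna()
            if len(p) < 2:
                logger.warning("no usable p-values for %s; DMR stage skipped", key)
                continue
            regions = dmr.call_dmrs(
                p,
                manifest,
                seed_p=config.dmr_seed_p,
                max_dist=config.dmr_max_dist,
                min_probes=config.dmr_min_probes,
                sidak_alpha=config.dmr_sidak_alpha,
            )
            regions.to_csv(out / f"dmr_{key}.csv", index=False)
            sig = regions[regions["significant"]]
            ioformats.write_dmr_bed(sig, out / f"dmr_{key}.bed")
            summary[f"dmr_{key}"] = {"n_candidate": len(regions), "n_significant": len(sig)}

        # CNV from intensities
        if m_mat is not None:
            locus = config.locus_tuple()
            controls = list(pheno.index[pheno["diagnosis"] == "CTL"])
            cnv_calls = {}
            for sample in pheno.index[pheno["diagnosis"] == "dup15q"]:
                region = pheno.loc[sample, "region"]
                ctl = [c for c in controls if pheno.loc[c, "region"] == region]
                if len(ctl) < 3:
                    continue
                ratios = cnv.intensity_log2_ratio(m_mat, u_mat, sample, ctl)
                segs = cnv.call_duplication(
                    cnv.segment_ratios(ratios, manifest, min_seg=config.cnv_min_probes),
                    gain_threshold=config.cnv_gain_threshold,
                    min_probes=config.cnv_min_probes,
                )
                cnv_calls[sample] = cnv.dup15q_status(segs, locus)
            _write_json(cnv_calls, out / "cnv_dup15q_status.json")
            summary["cnv_dup15q_positive"] = int(sum(cnv_calls.values()))
            summary["cnv_samples_tested"] = len(cnv_calls)
        else:
            logger.warning("no intensity matrices configured; CNV stage skipped")

        # co-methylation network on cortical samples
        cortex = pheno.index[pheno["region"].isin(["PFC", "TC"])]
        module_probes: list[str] = []
        if len(cortex) >= 10:
            sub = beta[cortex]
            keep = network.variable_probe_filter(sub, config.net_min_range, config.net_central_frac)
            if len(keep) > config.net_max_probes:
                # most variable probes first, for tractability
                spread = sub.loc[keep].std(axis=1).sort_values(ascending=False)
                keep = spread.index[: config.net_max_probes]
            if len(keep) >= config.net_min_module_size:
                adj = network.residualize(sub.loc[keep], pheno.loc[cortex])
                labels, eigengenes = network.build_network(
                    adj,
                    soft_power=config.net_soft_power,
                    min_module_size=config.net_min_module_size,
                    merge_cut_height=config.net_merge_cut_height,
                    max_block_size=config.net_max_block_size,
                    random_state=config.seed,
                )
                labels.rename("module").to_csv(out / "modules.csv")
                eigengenes.to_csv(out / "eigengenes.csv")
                present = set(pheno["diagnosis"])
                contrasts = [
                    (case, "CTL")
                    for case in ("iASD", "dup15q", "ASD")
                    if "CTL" in present
                    and (case in present or (case == "ASD" and present & {"iASD", "dup15q"}))
                ]
                assoc = network.module_trait_association(eigengenes, pheno, contrasts=tuple(contrasts))
                assoc.to_csv(out / "module_associations.csv", index=False)
                summary["n_modules"] = int(labels.max()) if len(labels) else 0
                summary["modules_fdr05"] = int(assoc["significant"].sum()) if len(assoc) else 0
                for m in assoc.loc[assoc["significant"], "module"].unique():
                    module_probes.extend(labels.index[labels == int(str(m).lstrip("M"))])
            else:
                logger.warning("too few variable probes for the network stage")

        # enrichment of disease-associated module genes
        if config.pathways and module_probes:
            db = ioformats.read_gmt(config.pathways)
            test_genes = enrichment.annotate_probes(module_probes, manifest)
            if test_genes:
                universe = enrichment.build_universe(manifest, db, test_genes)
                enr = enrichment.run_enrichment(
                    universe, db, size_range=(config.pathway_size_min, config.pathway_size_max)
                )
                grouped = enrichment.group_pathways(enr.reset_index().set_index("pathway_id"), universe, db)
                enr.to_csv(out / "enrichment.csv")
                grouped.to_csv(out / "enrichment_grouped.csv")
                summary["n_pathways_significant"] = int((enr["p_value"] < 0.05).sum())

        _write_json(summary, out / "summary.json")
        logger.info("pipeline complete: %s", out)
        return out
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

def make_demo(
    seed: int,
    out_dir: str | Path,
    n_probes: int = 6_000,
    n_donors: dict[str, int] | None = None,
) -> tuple[PipelineConfig, synthdata.TruthTables]:
    """Write a complete synthetic input set plus truth tables and return a
    ready-to-run configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_donors = n_donors or {"CTL": 12, "iASD": 12, "dup15q": 4}
    rng = np.random.default_rng(seed)

    design = synthdata.SyntheticDesign(
        n_probes=n_probes,
        n_chromosomes=16,
        probe_spacing_bp=300,
        n_donors_per_group=n_donors,
        batch_effects={"bankB": 0.01, "bankC": -0.01},
        seed=seed,
    )
    manifest = synthdata.generate_manifest(design)
    chr15 = manifest[manifest["chrom"] == "chr15"]
    locus = synthdata.DuplicationSpec(
        chrom="chr15",
        start=int(chr15["pos"].quantile(0.3)),
        end=int(chr15["pos"].quantile(0.7)),
        copy_number=3,
        hyper=(int(chr15["pos"].quantile(0.4)), int(chr15["pos"].quantile(0.5))),
        hypo=(int(chr15["pos"].quantile(0.55)), int(chr15["pos"].quantile(0.6))),
    )
    base_modules = synthdata.plant_modules(manifest, sizes=[150, 150], loading=0.05, rng=rng)
    # first module loads on diagnosis, the second is a neutral control
    module_spec = (
        dataclasses.replace(base_modules[0], diagnosis_shift={"iASD": 1.0, "dup15q": 1.0}),
        base_modules[1],
    )
    design = design.with_(
        spiked_dmps=synthdata.plant_dmps(manifest, 40, (0.05, 0.10), rng=rng),
        spiked_dmrs=synthdata.plant_dmrs(manifest, 3, 5, 0.08, rng=rng),
        planted_modules=module_spec,
        dup15q_locus=locus,
        cell_ref=synthdata.make_cell_reference(manifest, rng=rng),
        clock=synthdata.make_synthetic_clock(manifest, rng=rng),
    )
    beta, (m_mat, u_mat), pheno, truth = synthdata.generate_cohort(design, manifest)

    ioformats.write_manifest(manifest, out / "manifest.csv")
    ioformats.write_phenotypes(pheno, out / "phenotypes.csv")
    ioformats.write_beta(beta, out / "beta.tsv")
    ioformats.write_beta(m_mat, out / "methylated.tsv")
    ioformats.write_beta(u_mat, out / "unmethylated.tsv")
    ioformats.write_clock(design.clock.model, out / "clock.csv")
    ioformats.write_cell_reference(design.cell_ref, out / "cell_reference.csv")
    enriched = set(enrichment.annotate_probes(list(module_spec[0].probe_ids), manifest))
    db, pw_truth = synthdata.generate_pathways(manifest, 30, enriched_genes=enriched, seed=seed)
    ioformats.write_gmt(db, out / "pathways.gmt")
    for name, frame in truth.to_frames().items():
        frame.to_csv(out / f"truth_{name}.csv", index=False)
    pw_truth.to_csv(out / "truth_pathways.csv", index=False)

    cfg = PipelineConfig(
        manifest=str(out / "manifest.csv"),
        phenotypes=str(out / "phenotypes.csv"),
        beta=str(out / "beta.tsv"),
        m_intensity=str(out / "methylated.tsv"),
        u_intensity=str(out / "unmethylated.tsv"),
        pathways=str(out / "pathways.gmt"),
        clock=str(out / "clock.csv"),
        cell_reference=str(out / "cell_reference.csv"),
        out_dir=str(out / "run"),
        dup15q_locus=f"chr15:{locus.start}-{locus.end}",
        seed=seed,
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataclasses.asdict(cfg).items()},
            fh,
        )
    return cfg, truth
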