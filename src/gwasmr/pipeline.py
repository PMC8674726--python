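"""End-to-end orchestration: simulate -> meta -> finemap -> mr -> report.

A :class:`RunConfig` (built in code or loaded from a TOML file with one
block per stage) drives the run.  Each stage reads its inputs from the
output directory (so the pipeline is resumable per stage), writes its
outputs plus a manifest entry (input hashes, parameters, seed, row counts),
and the final run report collects every manifest and every threshold into a
machine-readable JSON file.  Logging goes to stderr; thresholds are never
applied silently — everything is echoed into the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import fine_mapping, locus_tools, meta_analysis, mr_causal, sumstats_io
from .synthetic_data import SimulationConfig, config_header, simulate_cohort_sumstats, simulate_mr_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "meta", "finemap", "mr", "report")


class PipelineError(RuntimeError):
    """Stage failure with a structured payload for the run report."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.message = message


@dataclass
class RunConfig:
    stages: tuple[str, ...] = STAGES[:-1]  # report stage implicit
    out_dir: Path = Path("gwasmr_run")
    seed: int = 0
    log_level: str = "INFO"
    # stage parameter blocks (spec-level thresholds, all echoed in the report)
    simulate: dict = field(default_factory=dict)
    meta: dict = field(default_factory=lambda: {
        "maf_threshold": 0.05, "genomic_control": "post_meta",
    })
    finemap: dict = field(default_factory=lambda: {
        "alpha": 5e-9, "window": 250_000, "credible_level": 0.99,
        "reference_loci": None,
    })
    mr: dict = field(default_factory=lambda: {
        "alpha": 5e-9, "r2_max": 0.001, "window": 250_000,
        "proxy_r2_min": 0.8, "n_boot": 1000, "exclude_pleiotropy": True,
        "proxy_table": None,
    })

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        for key in ("stages", "seed", "log_level"):
            if key in raw:
                setattr(cfg, key, tuple(raw[key]) if key == "stages" else raw[key])
        if "out_dir" in raw:
            cfg.out_dir = Path(raw["out_dir"])
        for stage in ("simulate", "meta", "finemap", "mr"):
            if stage in raw:
                getattr(cfg, stage).update(raw[stage])
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, Path(value) if key == "out_dir" else value)
        return cfg

    def thresholds(self) -> dict:
        return {
            "maf_threshold": self.meta["maf_threshold"],
            "alpha": self.finemap["alpha"],
            "window": self.finemap["window"],
            "r2_max": self.mr["r2_max"],
            "credible_level": self.finemap["credible_level"],
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(stage: str, inputs: list[Path], outputs: list[Path],
              params: dict, seed: int, row_counts: dict) -> dict:
    return {
        "stage": stage,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p): _sha256(p) for p in outputs},
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "seed": seed,
        "row_counts": row_counts,
    }


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(stage, f"required input does not exist: {path}")
    return path


def stage_simulate(cfg: RunConfig) -> dict:
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.simulate)
    study = simulate_cohort_sumstats(sim_cfg)
    header = config_header(sim_cfg)
    outputs = []
    for table in study.tables:
        path = out / f"{table.cohort_name}.tsv"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            table.records.to_csv(fh, sep="\t", index=False)
        outputs.append(path)
    ld_path = out / "ld_r2.tsv"
    study.ld_r2().to_csv(ld_path, sep="\t")
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps({
        "causal_snps": study.causal_snps, "causal_loci": study.causal_loci,
        "seed": sim_cfg.seed,
    }, indent=2))

    exposure, outcome, mr_ld, mr_truth = simulate_mr_dataset(sim_cfg)
    for name, tab in (("exposure", exposure), ("outcome", outcome)):
        path = out / f"mr_{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            tab.records.to_csv(fh, sep="\t", index=False)
        outputs.append(path)
    mr_ld_path = out / "mr_ld_r2.tsv"
    (mr_ld ** 2).to_csv(mr_ld_path, sep="\t")
    mr_truth_path = out / "mr_truth.json"
    mr_truth_path.write_text(json.dumps(mr_truth.to_dict(), indent=2))
    outputs += [ld_path, truth_path, mr_ld_path, mr_truth_path]
    return _manifest("simulate", [], outputs, dataclasses.asdict(sim_cfg), cfg.seed,
                     {"snps": len(study.snp_loci), "cohorts": len(study.tables),
                      "mr_instruments": len(exposure.records)})


def _read_cohorts(cfg: RunConfig) -> list[sumstats_io.CohortTable]:
    paths = sorted(cfg.out_dir.glob("cohort_*.tsv"))
    if not paths:
        raise PipelineError("meta", f"no cohort_*.tsv files under {cfg.out_dir}")
    tables = []
    for p in paths:
        tables.append(sumstats_io.read_sumstats(
            p, cohort_name=p.stem, trait="simulated", sep="\t",
        ))
    return tables


def stage_meta(cfg: RunConfig) -> dict:
    params = cfg.meta
    tables = _read_cohorts(cfg)
    inputs = sorted(cfg.out_dir.glob("cohort_*.tsv"))
    tables = [sumstats_io.filter_maf(t, params["maf_threshold"]) for t in tables]
    tables = sumstats_io.harmonize_alleles(tables, tables[0])
    if params.get("genomic_control") == "per_cohort":
        tables = meta_analysis.genomic_control_per_cohort(tables)
        meta = meta_analysis.meta_analyze(tables)
    else:
        meta = meta_analysis.genomic_control(meta_analysis.meta_analyze(tables))
    meta_path = cfg.out_dir / "meta.tsv"
    meta_analysis.write_meta(meta, meta_path)
    qq_path = cfg.out_dir / "qq.tsv"
    meta_analysis.qq_data(meta).to_csv(qq_path, sep="\t", index=False)
    report_path = cfg.out_dir / "sample_sizes.tsv"
    sumstats_io.sample_size_report(tables).to_csv(report_path, sep="\t")
    return _manifest("meta", inputs, [meta_path, qq_path, report_path],
                     params, cfg.seed,
                     {"snps": len(meta), "lambda_gc": float(meta["LAMBDA_GC"].iloc[0])})


def stage_finemap(cfg: RunConfig) -> dict:
    params = cfg.finemap
    meta_path = _require(cfg.out_dir / "meta.tsv", "finemap")
    meta = meta_analysis.read_meta(meta_path)
    sig = locus_tools.select_significant(meta, params["alpha"])
    loci = locus_tools.define_loci(sig, params["window"])
    if params.get("reference_loci"):
        ref = locus_tools.read_reference_loci(params["reference_loci"])
        loci = locus_tools.novelty_check(loci, ref, params["window"])
    outputs = []
    sets = []
    for L in loci:
        records, cs = fine_mapping.fine_map_locus(
            meta, L.chrom, L.lead_pos, params["window"],
            params["credible_level"], L.locus_id,
        )
        path = cfg.out_dir / f"finemap_{L.locus_id}.tsv"
        records.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        sets.append(cs)
    loci_path = cfg.out_dir / "loci.tsv"
    locus_tools.loci_to_frame(loci).to_csv(loci_path, sep="\t", index=False)
    sets_path = cfg.out_dir / "credible_sets.tsv"
    fine_mapping.credible_set_summary(sets).to_csv(sets_path, sep="\t", index=False)
    return _manifest("finemap", [meta_path], outputs + [loci_path, sets_path],
                     params, cfg.seed,
                     {"significant_snps": len(sig), "loci": len(loci)})


def stage_mr(cfg: RunConfig) -> dict:
    params = cfg.mr
    exp_path = _require(cfg.out_dir / "mr_exposure.tsv", "mr")
    out_path = _require(cfg.out_dir / "mr_outcome.tsv", "mr")
    ld_path = _require(cfg.out_dir / "mr_ld_r2.tsv", "mr")
    exposure = sumstats_io.read_sumstats(exp_path, cohort_name="exposure", sep="\t").records
    outcome = sumstats_io.read_sumstats(out_path, cohort_name="outcome", sep="\t").records
    ld = pd.read_csv(ld_path, sep="\t", index_col=0)

    instruments = mr_causal.clump_instruments(
        exposure, ld, params["alpha"], params["r2_max"], params["window"],
    )
    if not instruments:
        raise PipelineError("mr", "no instrument passed the significance threshold")
    proxy_df = None
    if params.get("proxy_table"):
        proxy_df = pd.read_csv(params["proxy_table"], sep="\t")
    used = mr_causal.substitute_proxies(
        instruments, outcome["SNP"], proxy_df, params["proxy_r2_min"],
    )
    harmonized = mr_causal.harmonize_instruments(exposure, outcome, used)
    excluded: list[str] = []
    if params.get("exclude_pleiotropy") and len(harmonized) >= 3:
        harmonized, excluded = mr_causal.exclude_pleiotropic(harmonized)

    results = [mr_causal.ivw_estimate(harmonized)]
    if len(harmonized) >= 3:
        results.append(mr_causal.egger_estimate(harmonized))
        results.append(mr_causal.weighted_median_estimate(
            harmonized, n_boot=params["n_boot"], seed=cfg.seed,
        ))
    report = mr_causal.mr_report(results, trait="simulated")
    report_path = cfg.out_dir / "mr_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    run_path = cfg.out_dir / "mr_run.json"
    run_path.write_text(json.dumps({
        "instruments_clumped": len(instruments),
        "instruments_used": len(harmonized),
        "pleiotropy_excluded": excluded,
        "seed": cfg.seed,
        "thresholds": {k: params[k] for k in ("alpha", "r2_max", "window", "proxy_r2_min")},
    }, indent=2))
    return _manifest("mr", [exp_path, out_path, ld_path],
                     [report_path, run_path], params, cfg.seed,
                     {"instruments": len(harmonized), "methods": len(results)})


_STAGE_FNS = {
    "simulate": stage_simulate,
    "meta": stage_meta,
    "finemap": stage_finemap,
    "mr": stage_mr,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the report.

    The report (also written to ``<out_dir>/run_report.json``) carries one
    manifest per stage, the threshold echo, and — on failure — a structured
    error naming the failing stage.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in cfg.stages and s != "report"]
    report: dict = {"seed": cfg.seed, "stages": [], "thresholds": cfg.thresholds()}
    try:
        for stage in ordered:
            logger.info("running stage %s", stage)
            report["stages"].append(_STAGE_FNS[stage](cfg))
        report["status"] = "ok"
    except PipelineError as err:
        report["status"] = "error"
        report["error"] = {"stage": err.stage, "message": err.message}
        (cfg.out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
        raise
    (cfg.out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
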