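"""End-to-end orchestration: simulate or ingest, analyse, report.

Stages run in a fixed order — data generation/ingest, differential
expression, drug screening, promoter/peak integration, rewiring
classification — writing every intermediate artifact plus a JSON report
and a human-readable summary.  A run is fully determined by its resolved
configuration (frozen alongside the outputs) and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._errors import RareAMLError
from ._version import __version__
from .drugscreen import DrugScreenModel
from .genomics import assign_peaks, binding_lost, build_promoters, read_bed
from .kernelmcc import DEThresholds, DifferentialExpressionModel
from .qpcr import delta_ct_expression, fold_enrichment
from .rewiring import classify_rewiring
from .simulate import SimConfig, simulate_treatment, write_inputs

logger = logging.getLogger("rareaml")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    mode "simulate" generates all inputs from ``sim`` (+ seed); mode
    "user-data" reads the paths given in ``inputs`` (expression and
    annotation are required, plate/peaks/tss/Ct optional — stages without
    inputs are skipped).
    """

    mode: str = "simulate"
    seed: int | None = 0
    outdir: str = "rareaml_run"
    inputs: dict = field(default_factory=dict)
    # analysis options (defaults mirror the emulated study)
    mcc_threshold: float = 0.105
    l2fc_threshold: float = 0.58
    alpha: float = 0.05
    fc_threshold: float = 1.5
    de_route: str = "both"
    dss_threshold_pct: float = 10.0
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    top_k: int = 10
    threads: int = 1
    sim: dict = field(default_factory=dict)

    def thresholds(self) -> DEThresholds:
        return DEThresholds(self.mcc_threshold, self.l2fc_threshold, self.alpha,
                            self.fc_threshold)

    def sim_config(self) -> SimConfig:
        if self.seed is None:
            raise RareAMLError("seed is mandatory in simulate mode")
        return SimConfig(seed=self.seed, **self.sim)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    """Headline counts and tables of one pipeline run."""

    de_summary: dict = field(default_factory=dict)
    top_drugs: list = field(default_factory=list)
    n_bound: int | None = None
    n_bound_and_de: int | None = None
    bound_and_de_genes: list = field(default_factory=list)
    n_rewired: int | None = None
    rewired_genes: list = field(default_factory=list)
    n_binding_lost: int | None = None
    outputs: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = ["rareaml run report"]
        if self.de_summary:
            d = self.de_summary
            lines.append(
                f"  DE (diagnosis): {d['n_pass']} pass ({d['n_up']} up, {d['n_down']} down) "
                f"of {d['n_genes']} genes"
            )
        if self.top_drugs:
            lines.append("  top selective drugs: "
                         + ", ".join(r["drug_id"] for r in self.top_drugs[:4]))
        if self.n_bound is not None:
            lines.append(f"  promoter-bound genes: {self.n_bound} "
                         f"(bound and DE: {self.n_bound_and_de})")
        if self.n_rewired is not None:
            lines.append(f"  rewired genes: {self.n_rewired} "
                         f"(binding lost: {self.n_binding_lost})")
        return "\n".join(lines)


def _check(checks: list, name: str, ok: bool, message: str = "") -> None:
    checks.append({"check": name, "passed": bool(ok), "message": message})


def validate_inputs(config: RunConfig) -> list:
    """Structural validation of a run's inputs without running analysis.

    Returns a list of {check, passed, message} records covering file
    existence, matrix/annotation consistency, dose-ladder completeness and
    BED coordinate sanity.
    """
    checks: list = []
    if config.mode == "simulate":
        try:
            config.sim_config()
            _check(checks, "sim_config", True)
        except RareAMLError as exc:
            _check(checks, "sim_config", False, str(exc))
        return checks
    paths = config.inputs
    for key in ("expression", "annotation"):
        p = paths.get(key)
        _check(checks, f"{key}_exists", bool(p) and Path(p).exists(), str(p))
    if not all(c["passed"] for c in checks):
        return checks
    expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    ann = pd.read_csv(paths["annotation"])
    _check(checks, "no_missing_values", not expr.isna().any().any())
    unknown = sorted(set(expr.columns) - set(ann["sample_id"]))
    _check(checks, "samples_annotated", not unknown,
           f"samples absent from annotation: {unknown[:5]}" if unknown else "")
    counts = ann["group"].value_counts()
    _check(checks, "two_groups_present",
           counts.get("case", 0) >= 2 and counts.get("reference", 0) >= 2,
           f"group sizes: {counts.to_dict()}")
    if paths.get("plate"):
        if Path(paths["plate"]).exists():
            plate = pd.read_csv(paths["plate"])
            ladder_ok = (plate.groupby(["drug_id", "sample_id"])["dose_nM"].nunique() >= 4).all()
            _check(checks, "dose_ladders_complete", bool(ladder_ok),
                   "every (drug, sample) needs >=4 distinct doses")
            _check(checks, "doses_positive", bool((plate["dose_nM"] > 0).all()))
        else:
            _check(checks, "plate_exists", False, paths["plate"])
    if paths.get("tss"):
        try:
            read_bed(paths["tss"])
            _check(checks, "tss_bed_valid", True)
        except (ValueError, FileNotFoundError) as exc:
            _check(checks, "tss_bed_valid", False, str(exc))
    for key in paths:
        if key.startswith("peaks_"):
            try:
                read_bed(paths[key])
                _check(checks, f"{key}_bed_valid", True)
            except (ValueError, FileNotFoundError) as exc:
                _check(checks, f"{key}_bed_valid", False, str(exc))
    return checks


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Raises a RareAMLError naming the failing stage; reruns with the same
    config and seed are bit-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    report = RunReport(metadata={
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "thresholds": {
            "mcc_threshold": config.mcc_threshold,
            "l2fc_threshold": config.l2fc_threshold,
            "alpha": config.alpha,
            "fc_threshold": config.fc_threshold,
            "dss_threshold_pct": config.dss_threshold_pct,
            "promoter_window": [config.promoter_upstream, config.promoter_downstream],
        },
    })
    if config.mode == "simulate":
        _stage("simulate")
        sim = config.sim_config()
        paths = write_inputs(sim, out / "inputs", config.promoter_upstream,
                             config.promoter_downstream)
    elif config.mode == "user-data":
        paths = dict(config.inputs)
        for key in ("expression", "annotation"):
            if key not in paths or not Path(paths[key]).exists():
                raise RareAMLError(
                    f"stage ingest: required input {key!r} missing "
                    f"(path: {paths.get(key)!r}); provide it in config.inputs"
                )
    else:
        raise RareAMLError(f"unknown mode {config.mode!r}")
    report.outputs["inputs"] = {k: str(v) for k, v in paths.items()}

    _stage("differential expression")
    thresholds = config.thresholds()
    de_model = DifferentialExpressionModel.from_files(
        paths["expression"], paths["annotation"], thresholds
    )
    de = de_model.fit(route=config.de_route, threads=config.threads)
    de.to_csv(out / "de_table.csv")
    de.save_metadata(out / "de_metadata.json")
    report.outputs["de_table"] = str(out / "de_table.csv")
    report.de_summary = {
        "n_genes": len(de.table), "n_pass": de.n_pass, "n_up": de.n_up, "n_down": de.n_down,
        "route": de.route,
    }

    screen = None
    if paths.get("plate") and Path(paths["plate"]).exists():
        _stage("drug screen")
        screen_model = DrugScreenModel.from_files(
            paths["plate"], paths["annotation_screen"]
            if paths.get("annotation_screen") else _screen_annotation(paths, out),
            activity_threshold=config.dss_threshold_pct,
        )
        screen = screen_model.fit()
        screen.scores.to_csv(out / "drug_scores.csv", index=False)
        screen.ranking.to_csv(out / "drug_ranking.csv", index=False)
        report.outputs["drug_ranking"] = str(out / "drug_ranking.csv")
        report.top_drugs = screen.top(config.top_k)[
            ["drug_id", "mean_case_sdss", "mean_case_dss", "rank"]
        ].to_dict("records")

    bound = lost = None
    if paths.get("tss") and paths.get("peaks_antibody_dmso"):
        _stage("promoter binding")
        tss = read_bed(paths["tss"])
        promoters = build_promoters(tss, config.promoter_upstream, config.promoter_downstream)
        promoters.reset_index().assign(score=0)[
            ["chrom", "start", "end", "gene_id", "score", "strand"]
        ].to_csv(out / "promoters.bed", sep="\t", header=False, index=False)
        ab_dmso = read_bed(paths["peaks_antibody_dmso"])
        bound = assign_peaks(ab_dmso, promoters)
        if paths.get("peaks_igg_dmso"):
            bound -= assign_peaks(read_bed(paths["peaks_igg_dmso"]), promoters)
        (out / "bound_genes.txt").write_text("\n".join(sorted(bound)) + "\n")
        report.outputs["bound_genes"] = str(out / "bound_genes.txt")
        report.n_bound = len(bound)
        if paths.get("peaks_antibody_treated"):
            ab_tx = read_bed(paths["peaks_antibody_treated"])
            lost = binding_lost(ab_dmso, ab_tx, promoters)
            if paths.get("peaks_igg_dmso"):
                lost &= bound
            report.n_binding_lost = len(lost)
        from .genomics import intersect_bound_with_de

        inter = intersect_bound_with_de(bound, de)
        report.n_bound_and_de = len(inter)
        report.bound_and_de_genes = sorted(inter["gene_id"])

    if config.mode == "simulate":
        _stage("treatment rewiring")
        comparisons, _ = simulate_treatment(config.sim_config())
        treated_tables = {}
        for name, data in comparisons.items():
            m = DifferentialExpressionModel(data.values, data.groups, thresholds)
            treated_tables[name] = m.fit(route="classic")
            treated_tables[name].to_csv(out / f"de_{name}.csv")
        rew = classify_rewiring(
            de, treated_tables["case_inhibitor"], treated_tables["reference_inhibitor"],
            treated_tables["case_control_drug"], bound or set(), lost or set(),
            alpha=config.alpha, fc=config.fc_threshold,
            diagnosis_route="kmcc" if config.de_route in ("kmcc", "both") else "classic",
        )
        rew.to_csv(out / "rewiring_report.csv")
        report.outputs["rewiring_report"] = str(out / "rewiring_report.csv")
        report.n_rewired = rew.n_rewired
        report.rewired_genes = rew.rewired_genes
        report.n_bound_and_de = rew.n_bound_and_de
        report.bound_and_de_genes = rew.bound_and_de_genes

    if paths.get("expression_ct"):
        _stage("qPCR")
        ct = pd.read_csv(paths["expression_ct"])
        expr_q, _ = delta_ct_expression(ct, control_condition="scramble")
        expr_q.to_csv(out / "qpcr_expression.csv", index=False)
        report.outputs["qpcr_expression"] = str(out / "qpcr_expression.csv")
    if paths.get("enrichment_ct"):
        ct = pd.read_csv(paths["enrichment_ct"])
        conds = sorted(ct["condition"].unique())
        igg_map = {c: (c if "igg" in c else c.replace("antibody", "igg")) for c in conds}
        fe, _ = fold_enrichment(ct, igg_map, control_condition="case_igg")
        fe.to_csv(out / "fold_enrichment.csv", index=False)
        report.outputs["fold_enrichment"] = str(out / "fold_enrichment.csv")

    report.to_json(out / "report.json")
    (out / "summary.txt").write_text(report.summary() + "\n")
    logger.info("run complete: %s", out / "report.json")
    return report


def _screen_annotation(paths: dict, out: Path) -> str:
    """Screen-cohort annotation: derive from the plate's sample ids when the
    expression annotation does not cover them (simulate mode)."""
    plate = pd.read_csv(paths["plate"])
    samples = sorted(plate["sample_id"].unique())
    groups = ["case" if s.startswith("scase") or s.startswith("case") else "reference"
              for s in samples]
    ann = pd.DataFrame({"sample_id": samples, "group": groups})
    path = out / "screen_annotation.csv"
    ann.to_csv(path, index=False)
    return str(path)
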