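"""Synthetic multi-omics cohorts with known ground truth.

Emulates the statistical structure of a rare-fusion AML study: a log2
expression cohort of ~750 samples containing a handful of fusion-positive
cases with spiked up/down genes; a ~527-compound dose-response screen with
a few group-selective drugs; promoter-binding peak tracks (antibody/IgG x
DMSO/inhibitor) in which selected genes lose their promoter peak after
treatment; replicate-level treated-vs-DMSO expression; and qPCR Ct tables
with encoded knockdown efficiency and fold enrichment.

Every generator is a pure function of a :class:`SimConfig`; equal seeds
give bit-identical outputs, and each generator draws from its own seeded
substream so outputs do not depend on call order.  Truth labels (spiked,
selective, rewired, bound gene/drug sets and the generating effect sizes)
are returned alongside for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._errors import SimConfigError
from .drugscreen import dss, fourpl
from .genomics import build_promoters

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ExpressionData",
    "simulate_expression",
    "simulate_annotation",
    "simulate_dose_response",
    "simulate_peaks",
    "simulate_treatment",
    "simulate_qpcr",
    "write_inputs",
]

# substream ids so each generator has an independent, order-free stream
_STREAMS = {"assign": 0, "expression": 1, "drugs": 2, "peaks": 3, "treatment": 4, "qpcr": 5}


@dataclass
class SimConfig:
    """Design constants of the synthetic study.

    The defaults mirror the emulated study: 7 fusion-positive cases against
    741 reference AMLs, 104 up- and 62 down-spiked genes at mean |l2fc| 1.5
    with 0.5 log2 noise, a 527-compound panel (4 selective) screened in 4
    case + 145 reference samples on a 5-point ladder spanning a 10,000-fold
    dose range, 36 rewired genes, 801 promoter-bound genes of which 10 are
    also diagnosis-DE.
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples_reference: int = 741
    n_samples_group: int = 7
    n_up_spiked: int = 104
    n_down_spiked: int = 62
    effect_l2fc_mean: float = 1.5
    effect_l2fc_sd: float = 0.3
    noise_sd: float = 0.5
    n_drugs: int = 527
    n_selective_drugs: int = 4
    n_rewired: int = 36
    n_bound_genes: int = 801
    n_bound_and_de: int = 10
    replicates_per_condition: int = 3
    # screen design
    n_screen_case: int = 4
    n_screen_reference: int = 145
    dose_min_nM: float = 1.0
    dose_max_nM: float = 10000.0
    n_doses: int = 5
    response_noise_sd_pct: float = 5.0
    # treated RNA-seq design
    n_treated_per_cohort: int = 2
    # peaks
    n_background_peaks: int = 200
    # qPCR
    ct_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_reference": self.n_samples_reference,
            "n_samples_group": self.n_samples_group,
            "n_up_spiked": self.n_up_spiked,
            "n_down_spiked": self.n_down_spiked,
            "n_drugs": self.n_drugs,
            "n_selective_drugs": self.n_selective_drugs,
            "n_rewired": self.n_rewired,
            "n_bound_genes": self.n_bound_genes,
            "n_bound_and_de": self.n_bound_and_de,
            "replicates_per_condition": self.replicates_per_condition,
        }
        for name, v in counts.items():
            if v < 0:
                raise SimConfigError(f"{name} must be >= 0 (got {v})")
        if self.n_up_spiked + self.n_down_spiked > self.n_genes:
            raise SimConfigError(
                f"n_up_spiked + n_down_spiked = {self.n_up_spiked + self.n_down_spiked} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if self.n_rewired > self.n_up_spiked:
            raise SimConfigError(
                f"n_rewired = {self.n_rewired} exceeds n_up_spiked = {self.n_up_spiked}"
            )
        if self.n_bound_genes > self.n_genes:
            raise SimConfigError(
                f"n_bound_genes = {self.n_bound_genes} exceeds n_genes = {self.n_genes}"
            )
        if self.n_bound_and_de > min(self.n_bound_genes, self.n_up_spiked + self.n_down_spiked):
            raise SimConfigError(
                f"n_bound_and_de = {self.n_bound_and_de} exceeds "
                "min(n_bound_genes, n_up_spiked + n_down_spiked)"
            )
        if self.n_selective_drugs > self.n_drugs:
            raise SimConfigError(
                f"n_selective_drugs = {self.n_selective_drugs} exceeds n_drugs = {self.n_drugs}"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


@dataclass
class GroundTruth:
    """Truth labels for recovery tests; rewired ⊆ spiked_up by construction."""

    spiked_up: set = field(default_factory=set)
    spiked_down: set = field(default_factory=set)
    selective_drugs: set = field(default_factory=set)
    rewired_genes: set = field(default_factory=set)
    bound_genes: set = field(default_factory=set)
    bound_and_de_genes: set = field(default_factory=set)
    true_l2fc: dict = field(default_factory=dict)
    true_dss: dict = field(default_factory=dict)

    def check(self) -> None:
        assert self.rewired_genes <= self.spiked_up
        assert not (self.spiked_up & self.spiked_down)
        assert self.bound_and_de_genes <= self.bound_genes

    def to_json(self, path) -> None:
        payload = {
            "spiked_up": sorted(self.spiked_up),
            "spiked_down": sorted(self.spiked_down),
            "selective_drugs": sorted(self.selective_drugs),
            "rewired_genes": sorted(self.rewired_genes),
            "bound_genes": sorted(self.bound_genes),
            "bound_and_de_genes": sorted(self.bound_and_de_genes),
            "true_l2fc": {k: v for k, v in sorted(self.true_l2fc.items())},
            "true_dss": {f"{d}|{g}": v for (d, g), v in sorted(self.true_dss.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class ExpressionData(NamedTuple):
    """An expression matrix (genes x samples) with its group labels."""

    values: pd.DataFrame
    groups: pd.Series


def _gene_ids(config: SimConfig) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(config.n_genes)])


def _assignments(config: SimConfig) -> dict:
    """Deterministic gene/drug truth assignments shared by all generators.

    Drawn from the dedicated "assign" substream so that expression, peak
    and treatment generators agree on which genes are spiked, rewired and
    bound without passing state between them.
    """
    rng = config.rng("assign")
    genes = _gene_ids(config)
    n_spiked = config.n_up_spiked + config.n_down_spiked
    spiked = rng.choice(config.n_genes, size=n_spiked, replace=False)
    up = genes[spiked[: config.n_up_spiked]]
    down = genes[spiked[config.n_up_spiked:]]
    rewired = up[: config.n_rewired]
    # bound∩DE genes come from the rewired set first (the emulated shared
    # targets are themselves treatment-sensitive), then other spiked genes
    de_pool = np.concatenate([rewired, up[config.n_rewired:], down])
    bound_de = de_pool[: config.n_bound_and_de]
    unspiked = genes[~np.isin(genes, np.concatenate([up, down]))]
    n_extra = config.n_bound_genes - len(bound_de)
    extra = rng.choice(unspiked, size=n_extra, replace=False) if n_extra > 0 else np.array([])
    bound = np.concatenate([bound_de, extra])
    drugs = np.array([f"D{i:03d}" for i in range(config.n_drugs)])
    selective = rng.choice(drugs, size=config.n_selective_drugs, replace=False)
    return {
        "genes": genes,
        "spiked_up": up,
        "spiked_down": down,
        "rewired": rewired,
        "bound": bound,
        "bound_and_de": bound_de,
        "drugs": drugs,
        "selective_drugs": selective,
    }


def _effect_draws(config: SimConfig, assign: dict) -> tuple[dict, dict]:
    """Per-gene true effect sizes (log2 units), from the assign stream."""
    rng = np.random.default_rng([99, config.seed])
    true_l2fc = {}
    for g in assign["spiked_up"]:
        true_l2fc[g] = float(rng.normal(config.effect_l2fc_mean, config.effect_l2fc_sd))
    for g in assign["spiked_down"]:
        true_l2fc[g] = float(-rng.normal(config.effect_l2fc_mean, config.effect_l2fc_sd))
    treat_delta = {
        g: float(rng.normal(config.effect_l2fc_mean, config.effect_l2fc_sd))
        for g in assign["rewired"]
    }
    return true_l2fc, treat_delta


def _base_truth(config: SimConfig) -> tuple[dict, GroundTruth]:
    assign = _assignments(config)
    true_l2fc, _ = _effect_draws(config, assign)
    truth = GroundTruth(
        spiked_up=set(assign["spiked_up"]),
        spiked_down=set(assign["spiked_down"]),
        selective_drugs=set(assign["selective_drugs"]),
        rewired_genes=set(assign["rewired"]),
        bound_genes=set(assign["bound"]),
        bound_and_de_genes=set(assign["bound_and_de"]),
        true_l2fc={g: true_l2fc.get(g, 0.0) for g in assign["genes"]},
    )
    truth.check()
    return assign, truth


def simulate_expression(config: SimConfig) -> tuple[ExpressionData, GroundTruth]:
    """Diagnosis cohort: reference samples plus a small fusion-positive group.

    Non-spiked genes share a per-gene baseline (uniform on [3, 10] log2
    units) with Gaussian noise; spiked genes are shifted in the minority
    group by their gene-specific true effect (drawn once, centred at
    ±effect_l2fc_mean).
    """
    assign, truth = _base_truth(config)
    rng = config.rng("expression")
    g, n0, n1 = config.n_genes, config.n_samples_reference, config.n_samples_group
    baseline = rng.uniform(3.0, 10.0, size=g)
    x = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(g, n0 + n1))
    genes = assign["genes"]
    effect = np.array([truth.true_l2fc[gid] for gid in genes])
    x[:, n0:] += effect[:, None]
    samples = [f"ref{i:03d}" for i in range(n0)] + [f"case{i:02d}" for i in range(n1)]
    values = pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=samples)
    groups = pd.Series(["reference"] * n0 + ["case"] * n1, index=samples, name="group")
    return ExpressionData(values, groups), truth


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """BED-like 1-bp TSS records for every gene, spread over 22 chromosomes.

    Genes are laid out 100 kb apart with alternating strands, far enough
    that promoter windows can never collide; deterministic in the config.
    """
    genes = _gene_ids(config)
    idx = np.arange(config.n_genes)
    chrom = np.array([f"chr{1 + (i % 22)}" for i in idx])
    tss = 100_000 * (1 + idx // 22) + 10_000
    strand = np.where(idx % 2 == 0, "+", "-")
    return pd.DataFrame(
        {"chrom": chrom, "start": tss, "end": tss + 1, "name": genes,
         "score": 0, "strand": strand}
    )


def simulate_dose_response(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Drug-screen plate: shared 4PL per drug, selective drugs case-shifted.

    Non-selective drugs share one parameter set across groups (top
    asymptote uniform on [0, 70]%, log-uniform EC50 across the ladder,
    Hill in [0.8, 2]) plus response noise; selective drugs are nearly
    inactive in the reference group (top 5-15%) but potent in the case
    group (top 70-90%, EC50 in the low decades).  True DSS per (drug,
    group) is computed from the generating parameters.
    """
    assign, truth = _base_truth(config)
    rng = config.rng("drugs")
    drugs = assign["drugs"]
    nd, ndose = config.n_drugs, config.n_doses
    sel_mask = np.isin(drugs, assign["selective_drugs"])
    n_sel = int(sel_mask.sum())
    lmin, lmax = np.log10(config.dose_min_nM), np.log10(config.dose_max_nM)
    doses = np.logspace(lmin, lmax, ndose)
    # shared parameters (bottom fixed at 0), selective drugs overridden
    top_ref = rng.uniform(0.0, 70.0, size=nd)
    ec50_ref = 10 ** rng.uniform(lmin, lmax, size=nd)
    hill_ref = rng.uniform(0.8, 2.0, size=nd)
    top_case, ec50_case, hill_case = top_ref.copy(), ec50_ref.copy(), hill_ref.copy()
    top_ref[sel_mask] = rng.uniform(5.0, 15.0, size=n_sel)
    top_case[sel_mask] = rng.uniform(70.0, 90.0, size=n_sel)
    ec50_case[sel_mask] = 10 ** rng.uniform(lmin + 0.3, lmin + 1.3, size=n_sel)
    hill_case[sel_mask] = rng.uniform(1.0, 1.5, size=n_sel)
    case_ids = np.array([f"scase{i:02d}" for i in range(config.n_screen_case)])
    ref_ids = np.array([f"sref{i:03d}" for i in range(config.n_screen_reference)])
    zeros = np.zeros(nd)
    frames = []
    for group, ids, top, ec50, hill in (
        ("case", case_ids, top_case, ec50_case, hill_case),
        ("reference", ref_ids, top_ref, ec50_ref, hill_ref),
    ):
        clean = fourpl(doses[None, :], zeros[:, None], top[:, None], ec50[:, None], hill[:, None])
        true = dss(zeros, top, ec50, hill, config.dose_min_nM, config.dose_max_nM)
        for drug, t in zip(drugs, true):
            truth.true_dss[(drug, group)] = float(t)
        ns = len(ids)
        resp = clean[:, None, :] + rng.normal(
            0.0, config.response_noise_sd_pct, size=(nd, ns, ndose)
        )
        frames.append(pd.DataFrame(
            {
                "drug_id": np.repeat(drugs, ns * ndose),
                "sample_id": np.tile(np.repeat(ids, ndose), nd),
                "dose_nM": np.tile(doses, nd * ns),
                "response_pct": resp.ravel(),
            }
        ))
    plate = pd.concat(frames, ignore_index=True)
    return plate, truth


def _peak_rows(rng, promoters: pd.DataFrame, genes, tag: str) -> list:
    rows = []
    for gene in genes:
        p = promoters.loc[gene]
        width = int(rng.integers(200, 1001))
        plen = int(p["end"] - p["start"])
        offset = int(rng.integers(-(width - 1), plen))  # guarantees >=1 bp overlap
        start = max(0, int(p["start"]) + offset)
        rows.append((p["chrom"], start, start + width, f"{tag}_{gene}", 0, "."))
    return rows


def _background_rows(rng, config: SimConfig, promoters: pd.DataFrame, tag: str) -> list:
    """Intervals far from every promoter (genes sit 100 kb apart)."""
    rows = []
    gene_pool = promoters.index.to_numpy()
    picks = rng.choice(gene_pool, size=config.n_background_peaks, replace=True)
    for i, gene in enumerate(picks):
        p = promoters.loc[gene]
        width = int(rng.integers(200, 1001))
        start = int(p["tss"]) + 30_000 + int(rng.integers(0, 20_000))
        rows.append((p["chrom"], start, start + width, f"{tag}_bg{i:04d}", 0, "."))
    return rows


def simulate_peaks(config: SimConfig, promoters: pd.DataFrame) -> tuple[dict, GroundTruth]:
    """Four peak tracks: antibody/IgG x DMSO/treated.

    Bound genes get a peak overlapping their promoter by >=1 bp in the
    antibody+DMSO track; genes that are both bound and rewired lose that
    peak in the antibody+treated track; IgG tracks carry only background
    intervals that never overlap a promoter.
    """
    if len(promoters) == 0:
        raise SimConfigError("promoters must be non-empty")
    assign, truth = _base_truth(config)
    if config.n_bound_genes > len(promoters):
        raise SimConfigError(
            f"n_bound_genes = {config.n_bound_genes} exceeds |promoters| = {len(promoters)}"
        )
    rng = config.rng("peaks")
    bound = [g for g in assign["bound"] if g in promoters.index]
    lost = [g for g in bound if g in truth.rewired_genes]
    kept = [g for g in bound if g not in truth.rewired_genes]
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    tracks = {
        "antibody_dmso": _peak_rows(rng, promoters, bound, "ab")
        + _background_rows(rng, config, promoters, "ab"),
        "antibody_treated": _peak_rows(rng, promoters, kept, "abtx")
        + _background_rows(rng, config, promoters, "abtx"),
        "igg_dmso": _background_rows(rng, config, promoters, "igg"),
        "igg_treated": _background_rows(rng, config, promoters, "iggtx"),
    }
    out = {k: pd.DataFrame(v, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True)
           for k, v in tracks.items()}
    truth.bound_genes = set(bound)
    return out, truth


def simulate_treatment(config: SimConfig) -> tuple[dict, GroundTruth]:
    """Replicate-level treated-vs-DMSO expression for three comparisons.

    Returns a dict of :class:`ExpressionData` keyed by comparison:
    "case_inhibitor", "reference_inhibitor", "case_control_drug"; in each,
    treated replicates are labelled "case" and DMSO replicates
    "reference" so the classical DE route applies directly.  Rewired genes
    drop by their gene-specific treatment effect only in inhibitor-treated
    case cells; the control drug and the reference cohort show no shift.
    """
    if config.replicates_per_condition < 1:
        raise SimConfigError("replicates_per_condition must be >= 1")
    assign, truth = _base_truth(config)
    _, treat_delta = _effect_draws(config, assign)
    rng = config.rng("treatment")
    genes = assign["genes"]
    g = config.n_genes
    baseline = rng.uniform(3.0, 10.0, size=g)
    diag_effect = np.array([truth.true_l2fc[gid] for gid in genes])
    case_profile = baseline + diag_effect  # case cells carry the diagnosis signature
    drop = np.array([treat_delta.get(gid, 0.0) for gid in genes])

    def _matrix(mean_treated, mean_dmso, prefix):
        cols, data = [], []
        for s in range(config.n_treated_per_cohort):
            for r in range(config.replicates_per_condition):
                cols.append(f"{prefix}{s}_dmso_r{r}")
                data.append(mean_dmso + rng.normal(0.0, config.noise_sd, size=g))
        for s in range(config.n_treated_per_cohort):
            for r in range(config.replicates_per_condition):
                cols.append(f"{prefix}{s}_tx_r{r}")
                data.append(mean_treated + rng.normal(0.0, config.noise_sd, size=g))
        values = pd.DataFrame(
            np.column_stack(data), index=pd.Index(genes, name="gene_id"), columns=cols
        )
        groups = pd.Series(
            ["reference" if "_dmso_" in c else "case" for c in cols], index=cols, name="group"
        )
        return ExpressionData(values, groups)

    comparisons = {
        "case_inhibitor": _matrix(case_profile - drop, case_profile, "tc"),
        "reference_inhibitor": _matrix(baseline, baseline, "tr"),
        "case_control_drug": _matrix(case_profile, case_profile, "cc"),
    }
    return comparisons, truth


def simulate_qpcr(config: SimConfig, knockdown_efficiency: float = 0.75,
                  fold_enrichments: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Ct tables with encoded knockdown efficiency and fold enrichment.

    Expression table: conditions "scramble" and "knockdown" over a target
    gene plus two housekeeping controls (GAPDH, RN18S); the knockdown
    condition's target Ct is raised by −log2(1 − efficiency) cycles.
    Enrichment table: antibody/IgG conditions for a case and a control
    sample over three loci, antibody Ct lowered by log2(fold) cycles below
    its IgG.  Returns (expression_ct, enrichment_ct, truth dict).
    """
    if config.replicates_per_condition < 1:
        raise SimConfigError("replicates_per_condition must be >= 1")
    if not 0.0 <= knockdown_efficiency < 1.0:
        raise SimConfigError("knockdown_efficiency must lie in [0, 1)")
    folds = fold_enrichments or {"case_antibody": 12.0, "control_antibody": 1.5}
    rng = config.rng("qpcr")
    reps = config.replicates_per_condition
    base_ct = {"GAPDH": 18.0, "RN18S": 10.0, "TARGET": 24.0}
    shift = -np.log2(1.0 - knockdown_efficiency)
    rows = []
    for cond in ("scramble", "knockdown"):
        for target, base in base_ct.items():
            ct = base + (shift if (cond == "knockdown" and target == "TARGET") else 0.0)
            for r in range(reps):
                rows.append((cond, target, r, ct + rng.normal(0.0, config.ct_noise_sd)))
    expr_ct = pd.DataFrame(rows, columns=["condition", "target_id", "replicate", "ct"])
    loci = ["locus_1", "locus_2", "locus_3"]
    igg_base = 28.0
    rows = []
    for cond_ab, fold in folds.items():
        cond_igg = cond_ab.replace("antibody", "igg")
        for locus in loci:
            for r in range(reps):
                rows.append((cond_igg, locus, r, igg_base + rng.normal(0.0, config.ct_noise_sd)))
                rows.append((cond_ab, locus, r,
                             igg_base - np.log2(fold) + rng.normal(0.0, config.ct_noise_sd)))
    enrich_ct = pd.DataFrame(rows, columns=["condition", "target_id", "replicate", "ct"])
    qtruth = {"knockdown_efficiency": knockdown_efficiency, "fold_enrichments": dict(folds)}
    return expr_ct, enrich_ct, qtruth


def write_inputs(config: SimConfig, outdir, promoter_upstream: int = 2000,
                 promoter_downstream: int = 500) -> dict:
    """Generate every input artifact and write it under ``outdir``.

    Writes expression TSV, annotation CSV, plate CSV, per-track BED files,
    Ct CSVs, TSS BED, and a truth JSON; returns the path map.
    """
    from pathlib import Path

    from .genomics import write_bed

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr, truth = simulate_expression(config)
    plate, truth_d = simulate_dose_response(config)
    truth.true_dss = truth_d.true_dss
    tss = simulate_annotation(config)
    promoters = build_promoters(tss, promoter_upstream, promoter_downstream)
    tracks, _ = simulate_peaks(config, promoters)
    expr_ct, enrich_ct, _ = simulate_qpcr(config)
    paths = {
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.csv",
        "plate": out / "plate.csv",
        "tss": out / "tss.bed",
        "expression_ct": out / "expression_ct.csv",
        "enrichment_ct": out / "enrichment_ct.csv",
        "truth": out / "truth.json",
    }
    expr.values.to_csv(paths["expression"], sep="\t")
    ann = pd.DataFrame({"sample_id": expr.groups.index, "group": expr.groups.to_numpy()})
    ann.to_csv(paths["annotation"], index=False)
    plate.to_csv(paths["plate"], index=False)
    tss_out = tss.copy()
    tss_out.to_csv(paths["tss"], sep="\t", header=False, index=False)
    for name, track in tracks.items():
        paths[f"peaks_{name}"] = out / f"peaks_{name}.bed"
        write_bed(track, paths[f"peaks_{name}"])
    expr_ct.to_csv(paths["expression_ct"], index=False)
    enrich_ct.to_csv(paths["enrichment_ct"], index=False)
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
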