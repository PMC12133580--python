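"""Classification of treatment-dependent ("rewired") target genes.

A gene is *rewired* when it is upregulated in the case subgroup at
diagnosis, selectively downregulated in case cells upon treatment with the
pathway inhibitor, but neither downregulated in treated reference-cohort
cells nor under a control drug.  Promoter-binding evidence (bound at
baseline, binding lost upon treatment) is integrated alongside, together
with the bound∩DE overlap of direct targets and diagnosis DE genes.

Downregulation on treatment is judged on the classical route
(p < alpha and l2fc < −log2(fc)) because the treated comparisons are
replicate-level two-group designs.
"""

from __future__ import annotations

import math

import pandas as pd

from ._errors import NamespaceError

__all__ = ["classify_rewiring", "RewiringReport"]


def _table(de) -> pd.DataFrame:
    return de.table if hasattr(de, "table") else de


def _down_mask(table: pd.DataFrame, alpha: float, fc: float) -> pd.Series:
    cut = -math.log2(fc)
    t = table.set_index("gene_id")
    return (t["p_value"] < alpha) & (t["l2fc"] < cut)


class RewiringReport:
    """Per-gene boolean classification table with headline counts.

    Attributes
    ----------
    frame : DataFrame indexed by gene id with the boolean columns
        up_at_diagnosis, down_on_treatment_case,
        down_on_treatment_control_cohort, changed_on_control_drug,
        bound_at_promoter, binding_lost_on_treatment, rewired, bound_and_de.
    """

    def __init__(self, frame: pd.DataFrame, params: dict):
        self.frame = frame
        self.params = params
        self._check_invariants()

    def _check_invariants(self) -> None:
        f = self.frame
        assert not (f["rewired"] & ~f["up_at_diagnosis"]).any(), "rewired must be up at diagnosis"
        assert not (f["rewired"] & f["down_on_treatment_control_cohort"]).any()
        assert not (f["rewired"] & f["changed_on_control_drug"]).any()
        assert not (f["bound_and_de"] & ~f["bound_at_promoter"]).any()
        assert not (f["binding_lost_on_treatment"] & ~f["bound_at_promoter"]).any()

    def genes(self, column: str) -> list:
        return sorted(self.frame.index[self.frame[column]])

    @property
    def rewired_genes(self) -> list:
        return self.genes("rewired")

    @property
    def bound_and_de_genes(self) -> list:
        return self.genes("bound_and_de")

    @property
    def n_rewired(self) -> int:
        return int(self.frame["rewired"].sum())

    @property
    def n_up_at_diagnosis(self) -> int:
        return int(self.frame["up_at_diagnosis"].sum())

    @property
    def n_bound(self) -> int:
        return int(self.frame["bound_at_promoter"].sum())

    @property
    def n_bound_and_de(self) -> int:
        return int(self.frame["bound_and_de"].sum())

    def summary(self) -> str:
        return (
            "Treatment-rewiring classification\n"
            f"  up at diagnosis:        {self.n_up_at_diagnosis}\n"
            f"  rewired (selective):    {self.n_rewired}\n"
            f"  promoter-bound:         {self.n_bound}\n"
            f"  bound and DE:           {self.n_bound_and_de}\n"
            f"  binding lost:           {int(self.frame['binding_lost_on_treatment'].sum())}"
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="gene_id")


def classify_rewiring(de_diagnosis, de_treated_case, de_treated_reference,
                      de_control_drug, bound: set, lost: set,
                      alpha: float = 0.05, fc: float = 1.5,
                      diagnosis_route: str = "kmcc") -> RewiringReport:
    """Integrate diagnosis DE, treated DE in two cohorts, a control drug and
    promoter binding into per-gene rewiring calls.

    All four DE inputs (results objects or tables) must share one gene
    namespace.  ``bound`` / ``lost`` are promoter-bound genes at baseline
    and genes whose binding disappears upon treatment.

    Rules
    -----
    * down on a treated table: p < alpha and l2fc < −log2(fc).
    * rewired: up at diagnosis AND down in treated case cells AND NOT down
      in treated reference cells AND NOT down under the control drug.
    * bound_and_de: promoter-bound AND in the diagnosis DE pass set
      (either direction, diagnosis route).
    """
    diag = _table(de_diagnosis)
    genes = pd.Index(sorted(diag["gene_id"]), name="gene_id")
    tables = {"treated_case": _table(de_treated_case),
              "treated_reference": _table(de_treated_reference),
              "control_drug": _table(de_control_drug)}
    for name, t in tables.items():
        missing = set(genes) - set(t["gene_id"])
        if missing:
            raise NamespaceError(
                f"{name} table is missing {len(missing)} gene(s), e.g. {sorted(missing)[:5]}"
            )
    pass_col = {"kmcc": "passes_kmcc", "classic": "passes_classic"}[diagnosis_route]
    d = diag.set_index("gene_id").reindex(genes)
    up_diag = (d[pass_col] & (d["direction"] == "up")).fillna(False)
    de_any = d[pass_col].fillna(False)
    down_case = _down_mask(tables["treated_case"], alpha, fc).reindex(genes).fillna(False)
    down_ref = _down_mask(tables["treated_reference"], alpha, fc).reindex(genes).fillna(False)
    down_ctrl = _down_mask(tables["control_drug"], alpha, fc).reindex(genes).fillna(False)
    bound_mask = genes.isin(bound)
    lost_mask = genes.isin(lost) & bound_mask
    frame = pd.DataFrame(
        {
            "up_at_diagnosis": up_diag.to_numpy(dtype=bool),
            "down_on_treatment_case": down_case.to_numpy(dtype=bool),
            "down_on_treatment_control_cohort": down_ref.to_numpy(dtype=bool),
            "changed_on_control_drug": down_ctrl.to_numpy(dtype=bool),
            "bound_at_promoter": bound_mask,
            "binding_lost_on_treatment": lost_mask,
        },
        index=genes,
    )
    frame["rewired"] = (
        frame["up_at_diagnosis"]
        & frame["down_on_treatment_case"]
        & ~frame["down_on_treatment_control_cohort"]
        & ~frame["changed_on_control_drug"]
    )
    frame["bound_and_de"] = frame["bound_at_promoter"] & de_any.to_numpy(dtype=bool)
    params = {"alpha": alpha, "fc": fc, "diagnosis_route": diagnosis_route,
              "down_criterion": "p < alpha and l2fc < -log2(fc) (classic route)"}
    return RewiringReport(frame, params)
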