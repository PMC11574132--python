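"""Multi-condition dependence classification.

A gene (or metabolite/protein feature) is called *dependent* on the
signaling gene when its stress response requires that gene: it changes
significantly with stress on the intact background (g3_vs_g1) and
significantly reverts toward control in the stressed-knockout vs.
stressed-intact comparison (g4_vs_g3), with opposite fold-change signs in
the two contrasts.

Two named presets mirror the two platform-specific rule lists:

- ``microarray`` (also used for feature tables): stress FDR <= 0.05 and
  |log2FC| >= 1; rescue FDR <= 0.05; opposite direction. No rescue
  fold-change magnitude requirement.
- ``rnaseq``: ANCOVA BH-corrected group p < 0.05 (the gate), stress post
  hoc p < 0.05 and |log2FC| > 1, rescue post hoc p < 0.05, opposite
  direction. Inequalities are strict on this path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import ContrastResult


class DependenceError(ValueError):
    pass


@dataclass(frozen=True)
class DependenceCriteria:
    """Thresholds of the dependence decision rule.

    ``stress_significance`` / ``rescue_significance`` choose which column
    of the respective ContrastResult is gated ('fdr' or 'p'; the RNA-seq
    path stores Tukey post hoc p-values in 'p'). ``strict`` switches
    between <=/>= (microarray) and </> (RNA-seq) comparisons at the
    thresholds. ``gate_p_max`` enables the per-gene omnibus gate (ANCOVA
    group FDR) when set.
    """

    fdr_max_stress: float = 0.05
    abs_log2fc_min_stress: float = 1.0
    stress_significance: str = "fdr"
    rescue_significance: str = "fdr"
    rescue_sig_max: float = 0.05
    abs_log2fc_min_rescue: float = 0.0
    require_opposite_direction: bool = True
    gate_p_max: float | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        for v in (self.fdr_max_stress, self.rescue_sig_max):
            if not (0 < v <= 1):
                raise DependenceError("significance thresholds must be in (0, 1]")
        if self.abs_log2fc_min_stress < 0 or self.abs_log2fc_min_rescue < 0:
            raise DependenceError("fold-change thresholds must be >= 0")
        if self.stress_significance not in ("fdr", "p") or self.rescue_significance not in (
            "fdr",
            "p",
        ):
            raise DependenceError("significance column must be 'fdr' or 'p'")
        if self.gate_p_max is not None and not (0 < self.gate_p_max <= 1):
            raise DependenceError("gate_p_max must be in (0, 1]")

    @classmethod
    def microarray(cls) -> "DependenceCriteria":
        return cls()

    @classmethod
    def features(cls) -> "DependenceCriteria":
        """Proteomics/metabolomics reuse the microarray rule with t-test FDRs."""
        return cls()

    @classmethod
    def rnaseq(cls) -> "DependenceCriteria":
        return cls(
            stress_significance="p",
            rescue_significance="p",
            gate_p_max=0.05,
            strict=True,
        )


PROFILES = {
    "microarray": DependenceCriteria.microarray,
    "rnaseq": DependenceCriteria.rnaseq,
    "features": DependenceCriteria.features,
}


def classify_dependence(
    stress: ContrastResult,
    rescue: ContrastResult,
    criteria: DependenceCriteria | None = None,
    gate_p: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the dependence rule gene-wise over aligned contrasts.

    Returns a frame indexed by gene_id with the verdict (``dependent``,
    ``direction``), the per-condition pass/fail trace (``stress_sig``,
    ``rescue_sig``, ``opposite_dir``, ``gate``) and the underlying
    statistics, for auditability.
    """
    criteria = criteria or DependenceCriteria.microarray()
    if set(stress.table.index) != set(rescue.table.index):
        raise DependenceError("stress and rescue contrasts cover different gene universes")
    rescue_t = rescue.table.reindex(stress.table.index)
    st = stress.table

    def le(x: np.ndarray | pd.Series, thr: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x < thr if criteria.strict else x <= thr

    def ge(x: np.ndarray | pd.Series, thr: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x > thr if criteria.strict else x >= thr

    stress_sig = le(st[criteria.stress_significance], criteria.fdr_max_stress) & ge(
        np.abs(st["log2fc"]), criteria.abs_log2fc_min_stress
    )
    rescue_sig = le(rescue_t[criteria.rescue_significance], criteria.rescue_sig_max)
    if criteria.abs_log2fc_min_rescue > 0:
        rescue_sig &= ge(np.abs(rescue_t["log2fc"]), criteria.abs_log2fc_min_rescue)

    s_sign = np.sign(st["log2fc"].to_numpy())
    r_sign = np.sign(rescue_t["log2fc"].to_numpy())
    opposite = (s_sign * r_sign) < 0  # zero fold-change on either side fails

    if criteria.gate_p_max is not None:
        if gate_p is None:
            raise DependenceError("criteria define a gate but no gate_p vector was supplied")
        gp = gate_p.reindex(st.index)
        if gp.isna().any():
            raise DependenceError("gate_p missing for some genes")
        gate = gp.to_numpy(dtype=float) < criteria.gate_p_max
        gate_col = gp.to_numpy(dtype=float)
    else:
        gate = np.ones(len(st), dtype=bool)
        gate_col = np.full(len(st), np.nan)

    dependent = stress_sig & rescue_sig & gate
    if criteria.require_opposite_direction:
        dependent &= opposite
    direction = np.where(dependent, np.where(s_sign > 0, "up", "down"), "")

    return pd.DataFrame(
        {
            "dependent": dependent,
            "direction": direction,
            "stress_sig": np.asarray(stress_sig, dtype=bool),
            "rescue_sig": np.asarray(rescue_sig, dtype=bool),
            "opposite_dir": opposite,
            "gate": gate,
            "stress_log2fc": st["log2fc"].to_numpy(),
            "stress_fdr": st["fdr"].to_numpy(),
            "stress_p": st["p"].to_numpy(),
            "rescue_log2fc": rescue_t["log2fc"].to_numpy(),
            "rescue_fdr": rescue_t["fdr"].to_numpy(),
            "rescue_p": rescue_t["p"].to_numpy(),
            "gate_p": gate_col,
        },
        index=st.index,
    )


def relax(criteria: DependenceCriteria, **changes) -> DependenceCriteria:
    """Return criteria with some thresholds replaced (frozen dataclass helper)."""
    return replace(criteria, **changes)


def dependence_fraction(calls: pd.DataFrame, stress_degs: set[str]) -> float:
    """Fraction of stress DEGs that are dependent.

    ``stress_degs`` must be a non-empty subset of the call universe.
    """
    if not stress_degs:
        raise DependenceError("stress DEG set is empty; fraction undefined")
    universe = set(calls.index)
    outside = set(stress_degs) - universe
    if outside:
        raise DependenceError(f"stress DEGs outside call universe: {sorted(outside)[:5]}")
    degs = sorted(stress_degs)
    return float(calls.loc[degs, "dependent"].mean())
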