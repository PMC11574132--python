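"""Core in-memory containers shared by every stage of the pipeline.

The experimental unit is a four-group factorial design crossing a stress
axis (control vs. mitochondrial stress) with a genotype axis (signaling
gene intact vs. knocked out):

    group 1  ctrl_wt    unstressed, gene intact
    group 2  ctrl_ko    unstressed, knockout
    group 3  stress_wt  stressed, gene intact
    group 4  stress_ko  stressed, knockout

Contrast names follow the ``B_vs_A`` convention (log2FC = mean(B) - mean(A)),
so ``g3_vs_g1`` is the stress response on the intact background and
``g4_vs_g3`` is the rescue (reversion) contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("ctrl_wt", "ctrl_ko", "stress_wt", "stress_ko")
SEXES = ("F", "M")

#: numeric aliases used in contrast names (g1..g4)
GROUP_ALIASES = {f"g{i + 1}": g for i, g in enumerate(GROUPS)}

SCALES = ("counts", "log2", "normalized_log2")


class DesignError(ValueError):
    """Raised for invalid sample designs or unknown group/sex labels."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene_id with one column per sample_id.
    scale
        One of ``counts``, ``log2``, ``normalized_log2``.
    lengths_bp
        Optional per-gene lengths (bp), aligned to ``values.index``.
        Required for gene-length normalization of count data.
    """

    values: pd.DataFrame
    scale: str
    lengths_bp: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        # canonical axis names so written/reloaded matrices compare equal
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample_ids")
        if self.values.isna().to_numpy().any():
            raise ValueError("expression matrix contains missing values")
        if self.lengths_bp is not None:
            self.lengths_bp = self.lengths_bp.reindex(self.values.index)
            if self.lengths_bp.isna().any():
                missing = self.lengths_bp.index[self.lengths_bp.isna()][:5].tolist()
                raise ValueError(f"lengths missing for genes: {missing}")
            if (self.lengths_bp <= 0).any():
                bad = self.lengths_bp.index[self.lengths_bp <= 0][:5].tolist()
                raise ValueError(f"non-positive gene lengths for: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        lengths = None
        if self.lengths_bp is not None:
            lengths = self.lengths_bp.reindex(values.index)
        return ExpressionMatrix(values=values, scale=scale or self.scale, lengths_bp=lengths)


def validate_design(design: pd.DataFrame, require_replicates: bool = True) -> pd.DataFrame:
    """Validate a sample-design table (sample_id, group, sex).

    Returns the validated frame. ``require_replicates`` enforces >= 2
    samples in each of the four groups, the precondition for any
    differential test.
    """
    required = {"sample_id", "group", "sex"}
    missing = required - set(design.columns)
    if missing:
        raise DesignError(f"design missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        raise DesignError("duplicate sample_ids in design")
    bad_groups = set(design["group"]) - set(GROUPS)
    if bad_groups:
        raise DesignError(f"unknown group labels: {sorted(bad_groups)}")
    bad_sex = set(design["sex"]) - set(SEXES)
    if bad_sex:
        raise DesignError(f"unknown sex labels: {sorted(bad_sex)}")
    if require_replicates:
        counts = design["group"].value_counts()
        for g in GROUPS:
            if counts.get(g, 0) < 2:
                raise DesignError(f"group {g!r} has fewer than 2 samples")
    return design


def group_samples(design: pd.DataFrame, group: str) -> list[str]:
    """Sample ids belonging to one group; accepts g1..g4 aliases."""
    group = GROUP_ALIASES.get(group, group)
    if group not in GROUPS:
        raise DesignError(f"unknown group {group!r}")
    return design.loc[design["group"] == group, "sample_id"].tolist()


def parse_contrast(name: str) -> tuple[str, str]:
    """Parse ``B_vs_A`` into the (A, B) group pair, resolving aliases.

    log2FC for the contrast is mean(B) - mean(A).
    """
    parts = name.split("_vs_")
    if len(parts) != 2:
        raise DesignError(f"contrast name {name!r} is not of the form B_vs_A")
    b, a = parts
    a = GROUP_ALIASES.get(a, a)
    b = GROUP_ALIASES.get(b, b)
    for g in (a, b):
        if g not in GROUPS:
            raise DesignError(f"unknown group {g!r} in contrast {name!r}")
    return a, b


@dataclass
class ContrastResult:
    """Per-gene differential statistics for one named contrast.

    ``table`` is indexed by gene_id with columns ``log2fc``, ``p``, ``fdr``.
    """

    name: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("log2fc", "p", "fdr"):
            if col not in self.table.columns:
                raise ValueError(f"ContrastResult table missing column {col!r}")


@dataclass
class AncovaResult:
    """Per-gene additive-model (Expression ~ Group + Sex) fit summary.

    ``table`` holds group_p, sex_p, group_fdr and sex-adjusted group means
    (columns ``adj_mean_<group>``). ``posthoc`` maps contrast names to
    frames with ``estimate`` and ``adjusted_p`` once post hoc testing has
    been run.
    """

    table: pd.DataFrame
    df_resid: int
    mse: pd.Series
    group_n: dict[str, int]
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
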