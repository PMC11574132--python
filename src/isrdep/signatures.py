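"""Signature combination across models/tissues and set-level statistics.

Combines per-model dependence calls into shared/core signatures, tests
overlap of a signature against a reference gene set (e.g., transcription
factor ChIP targets) with the hypergeometric tail, and projects a mouse
signature onto human studies through an ortholog map plus a mean
fold-change filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SignatureError(ValueError):
    pass


@dataclass
class GeneSet:
    name: str
    members: set[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if not self.members:
            raise SignatureError(f"gene set {self.name!r} has no members")


@dataclass
class SignatureTable:
    """Per-model called genes with direction, over a shared universe.

    ``calls`` maps model_id -> {gene_id -> 'up' | 'down'}.
    """

    calls: dict[str, dict[str, str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for model, genes in self.calls.items():
            bad_dir = {d for d in genes.values()} - {"up", "down"}
            if bad_dir:
                raise SignatureError(f"model {model!r} has invalid directions {bad_dir}")
            outside = set(genes) - self.universe
            if outside:
                raise SignatureError(
                    f"model {model!r} calls genes outside the universe: {sorted(outside)[:5]}"
                )

    @property
    def models(self) -> list[str]:
        return list(self.calls)

    @classmethod
    def from_calls(
        cls, call_frames: dict[str, pd.DataFrame], universe: set[str] | None = None
    ) -> "SignatureTable":
        """Build from classifier output frames (columns dependent, direction)."""
        calls = {}
        auto_universe: set[str] = set()
        for model, df in call_frames.items():
            dep = df[df["dependent"]]
            calls[model] = dict(zip(dep.index, dep["direction"]))
            auto_universe |= set(df.index)
        return cls(calls=calls, universe=universe if universe is not None else auto_universe)


def shared_in_k(
    table: SignatureTable, k: int, direction_consistent: bool = True, exactly: bool = False
) -> set[str]:
    """Genes called in at least (or exactly) k models.

    With ``direction_consistent`` a gene whose calls disagree in sign
    across the models that call it is excluded outright.
    """
    n_models = len(table.calls)
    if not (1 <= k <= n_models):
        raise SignatureError(f"k={k} out of range for {n_models} models")
    counts: dict[str, int] = {}
    directions: dict[str, set[str]] = {}
    for genes in table.calls.values():
        for g, d in genes.items():
            counts[g] = counts.get(g, 0) + 1
            directions.setdefault(g, set()).add(d)
    hits = set()
    for g, c in counts.items():
        if (c == k) if exactly else (c >= k):
            if direction_consistent and len(directions[g]) > 1:
                continue
            hits.add(g)
    return hits


def core_signature(table: SignatureTable) -> set[tuple[str, str]]:
    """Genes called with consistent direction in every model, with direction."""
    if len(table.calls) < 2:
        raise SignatureError("core signature needs at least 2 models")
    genes = shared_in_k(table, k=len(table.calls), direction_consistent=True)
    first = next(iter(table.calls.values()))
    return {(g, first[g]) for g in genes}


@dataclass
class EnrichmentResult:
    overlap_count: int
    query_size: int
    set_size: int
    universe_size: int
    p: float
    fold_enrichment: float


def hypergeometric_overlap(
    query: set[str], target: GeneSet | set[str], universe: set[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap test of query vs. target in universe.

    p = P(X >= observed overlap) when drawing |query| genes without
    replacement from a universe containing |target ∩ universe| successes.
    """
    if not universe:
        raise SignatureError("empty universe")
    members = target.members if isinstance(target, GeneSet) else set(target)
    if not set(query) <= set(universe):
        raise SignatureError("query must be a subset of the universe")
    k_set = members & universe
    n_univ, n_query, n_set = len(universe), len(query), len(k_set)
    overlap = len(set(query) & k_set)
    p = float(stats.hypergeom.sf(overlap - 1, n_univ, n_set, n_query))
    expected = n_query * n_set / n_univ
    fold = overlap / expected if expected > 0 else float("nan")
    return EnrichmentResult(
        overlap_count=overlap,
        query_size=n_query,
        set_size=n_set,
        universe_size=n_univ,
        p=min(max(p, 0.0), 1.0),
        fold_enrichment=fold,
    )


@dataclass
class OrthologMapping:
    mapped: set[str]
    unmapped: list[str]


def map_orthologs(genes: set[str], omap: dict[str, str]) -> OrthologMapping:
    """Image of a gene set under a (functional) ortholog map.

    Genes without an entry are dropped and reported.
    """
    mapped = {omap[g] for g in genes if g in omap}
    unmapped = sorted(g for g in genes if g not in omap)
    return OrthologMapping(mapped=mapped, unmapped=unmapped)


@dataclass
class CrossStudyResult:
    selected: set[str]
    excluded_missing: list[str]
    mean_fc: pd.Series


def cross_study_signature(
    candidates: set[str],
    study_fc: pd.DataFrame,
    mean_fc_min: float = 2.0,
    mean: str = "arithmetic",
) -> CrossStudyResult:
    """Candidates whose mean linear fold-change across studies exceeds the cutoff.

    ``study_fc`` is gene x study on the *linear* fold-change scale; the
    comparison is strict (> mean_fc_min). Candidates missing in any study
    are excluded and reported. Arithmetic mean by default; geometric
    available.
    """
    present = [g for g in sorted(candidates) if g in study_fc.index]
    missing = sorted(set(candidates) - set(present))
    sub = study_fc.loc[present]
    complete = sub.notna().all(axis=1)
    missing += sorted(sub.index[~complete])
    sub = sub[complete]
    if (sub.to_numpy() <= 0).any():
        raise SignatureError("fold-changes must be positive on the linear scale")
    if mean == "arithmetic":
        mfc = sub.mean(axis=1)
    elif mean == "geometric":
        mfc = np.exp(np.log(sub).mean(axis=1))
    else:
        raise SignatureError(f"unknown mean {mean!r}")
    selected = set(mfc.index[mfc > mean_fc_min])
    return CrossStudyResult(selected=selected, excluded_missing=missing, mean_fc=mfc)
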