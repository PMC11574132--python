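"""Seeded factorial expression simulators with per-gene ground truth.

The generator emulates the study design every downstream stage consumes: a
four-group stress x genotype factorial with a sex covariate, genes planted
in known classes, and either microarray-like log2 intensities or
RNA-seq-like negative-binomial counts.

Gene classes
------------
``dependent_up`` / ``dependent_down``
    changed by stress on the intact background and reverted toward control
    in the stressed knockout — the class the dependence classifier must
    recover.
``stress_only``
    changed by stress regardless of genotype (reversion fraction 0).
``ko_only``
    shifted on the knockout background in both stress arms.
``null``
    no planted effect.
``floor_noise``
    baseline below the detection floor; exercises noise filtering.

The per-gene log2 mean model is

    mu(g, s) = baseline
               + stress_effect * [group in {stress_wt, stress_ko}]
               - stress_effect * reversion_fraction * [group == stress_ko]
               + sex_effect * [sex == M]

(for ko_only genes the effect instead loads on the two knockout groups),
with N(0, noise_sd) noise on the intensity path and negative-binomial
sampling of length-weighted abundances on the count path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import GROUPS, ExpressionMatrix, validate_design

CLASSES = ("dependent_up", "dependent_down", "stress_only", "ko_only", "null", "floor_noise")

#: default class mix: a modest dependent fraction, some stress-only and
#: genotype-only genes, a floor-noise block, rest null
DEFAULT_CLASS_PROPORTIONS = {
    "dependent_up": 0.04,
    "dependent_down": 0.02,
    "stress_only": 0.04,
    "ko_only": 0.02,
    "null": 0.78,
    "floor_noise": 0.10,
}

#: effect-size defaults (log2 units)
DEFAULT_EFFECT_PARAMS = {
    "effect_size": 2.0,        # |stress effect| for dependent/stress_only/ko_only genes
    "effect_sd": 0.0,          # jitter around effect_size (0 = constant)
    "reversion_fraction": 1.0, # full reversion by default
    "sex_effect_sd": 0.5,      # magnitude scale of sex effects
    "sex_effect_fraction": 0.2,  # fraction of genes with a sex effect
    "baseline_low": 6.0,
    "baseline_high": 12.0,
    "floor_baseline_low": 0.3,   # floor_noise genes sit below the planted floor at ~1.0
    "floor_baseline_high": 0.8,
}


class SimulationError(ValueError):
    """Raised for invalid simulation parameters or sizing."""


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the factorial simulators.

    noise_sd is the within-group SD in log2 units; dispersion is the
    negative-binomial dispersion (variance = m + dispersion * m^2, so 0
    degenerates to Poisson); library_size is expected reads per sample.
    """

    n_genes: int = 2000
    n_per_group: int = 4
    noise_sd: float = 0.25
    dispersion: float = 0.05
    library_size: int = 2_000_000
    gene_length_range: tuple[int, int] = (200, 10_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SimulationError("n_genes must be positive")
        if self.n_per_group < 2:
            raise SimulationError("n_per_group must be >= 2")
        if not self.noise_sd > 0:
            raise SimulationError("noise_sd must be > 0")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.library_size < 1:
            raise SimulationError("library_size must be positive")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise SimulationError("gene_length_range must be a positive interval")


def generate_design(n_per_group: int, seed: int = 0) -> pd.DataFrame:
    """Balanced four-group design with sexes split to parity per group.

    For odd n the majority sex alternates with the group index (group 1
    majority F, group 2 majority M, ...), so the overall design stays as
    balanced as parity allows. The layout is fully determined by
    ``n_per_group``; ``seed`` is accepted for interface uniformity and the
    same-seed determinism contract holds trivially.
    """
    if n_per_group < 2:
        raise SimulationError("n_per_group must be >= 2 for a testable design")
    rows = []
    for gi, group in enumerate(GROUPS):
        start = "F" if gi % 2 == 0 else "M"
        other = "M" if start == "F" else "F"
        for i in range(n_per_group):
            sex = start if i % 2 == 0 else other
            rows.append({"sample_id": f"{group}_{i + 1}", "group": group, "sex": sex})
    design = pd.DataFrame(rows)
    return validate_design(design)


def _largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer class counts matching proportions by largest-remainder rounding."""
    items = list(proportions.items())
    raw = np.array([p * n for _, p in items])
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    # distribute the remainder to the largest fractional parts; ties broken
    # by class listing order for reproducibility
    order = np.argsort(-(raw - counts), kind="stable")
    for idx in order[:short]:
        counts[idx] += 1
    return {name: int(c) for (name, _), c in zip(items, counts)}


def generate_truth(
    n_genes: int,
    class_proportions: dict[str, float] | None = None,
    effect_params: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Truth table with planted per-gene classes and effect sizes.

    Columns: gene_id, class, stress_effect (signed, log2), reversion_fraction,
    sex_effect (log2), baseline (log2).
    """
    props = dict(DEFAULT_CLASS_PROPORTIONS if class_proportions is None else class_proportions)
    unknown = set(props) - set(CLASSES)
    if unknown:
        raise SimulationError(f"unknown truth classes: {sorted(unknown)}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise SimulationError(f"class proportions sum to {total}, expected 1")
    eff = dict(DEFAULT_EFFECT_PARAMS)
    eff.update(effect_params or {})

    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(n_genes, props)
    classes = np.concatenate([[c] * counts.get(c, 0) for c in props]) if n_genes else np.array([])
    # shuffle class assignment over gene positions so class is not confounded
    # with gene order
    rng.shuffle(classes)

    width = max(4, len(str(n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    df = pd.DataFrame({"gene_id": gene_ids, "class": classes})

    magnitude = eff["effect_size"] + (
        rng.normal(0.0, eff["effect_sd"], n_genes) if eff["effect_sd"] > 0 else 0.0
    )
    magnitude = np.abs(np.broadcast_to(magnitude, (n_genes,)).copy())
    sign = np.where(df["class"] == "dependent_down", -1.0, 1.0)
    # stress_only / ko_only genes get a random sign
    rand_sign = rng.choice([-1.0, 1.0], n_genes)
    sign = np.where(df["class"].isin(["stress_only", "ko_only"]), rand_sign, sign)
    has_effect = df["class"].isin(["dependent_up", "dependent_down", "stress_only", "ko_only"])
    df["stress_effect"] = np.where(has_effect, sign * magnitude, 0.0)

    df["reversion_fraction"] = np.where(
        df["class"].isin(["dependent_up", "dependent_down"]), eff["reversion_fraction"], 0.0
    )

    # null and floor_noise genes carry no effects of any kind; sex effects
    # land on a random subset of the effect-carrying classes
    sex_mask = rng.random(n_genes) < eff["sex_effect_fraction"]
    sex_eff = rng.normal(0.0, eff["sex_effect_sd"], n_genes)
    df["sex_effect"] = np.where(sex_mask & has_effect.to_numpy(), sex_eff, 0.0)

    baseline = rng.uniform(eff["baseline_low"], eff["baseline_high"], n_genes)
    floor_base = rng.uniform(eff["floor_baseline_low"], eff["floor_baseline_high"], n_genes)
    df["baseline"] = np.where(df["class"] == "floor_noise", floor_base, baseline)
    # floor_noise genes carry no effects at all
    is_floor = (df["class"] == "floor_noise").to_numpy()
    df.loc[is_floor, ["stress_effect", "reversion_fraction", "sex_effect"]] = 0.0
    return df


def _mean_log2_matrix(design: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """Noise-free log2 means, genes x samples, from the planted linear model."""
    group = design["group"].to_numpy()
    in_stress = np.isin(group, ["stress_wt", "stress_ko"]).astype(float)
    in_ko = np.isin(group, ["ctrl_ko", "stress_ko"]).astype(float)
    is_g4 = (group == "stress_ko").astype(float)
    is_male = (design["sex"].to_numpy() == "M").astype(float)

    eff = truth["stress_effect"].to_numpy()[:, None]
    rev = truth["reversion_fraction"].to_numpy()[:, None]
    sexe = truth["sex_effect"].to_numpy()[:, None]
    base = truth["baseline"].to_numpy()[:, None]

    ko_only = (truth["class"] == "ko_only").to_numpy()[:, None]
    stress_load = np.where(ko_only, in_ko[None, :], in_stress[None, :])
    mu = base + eff * stress_load - eff * rev * is_g4[None, :] + sexe * is_male[None, :]
    return mu


def simulate_intensities(
    design: pd.DataFrame, truth: pd.DataFrame, params: SimulationParams
) -> ExpressionMatrix:
    """Microarray-like log2 intensities: planted means plus Gaussian noise."""
    if design.empty or truth.empty:
        raise SimulationError("design and truth must be non-empty")
    validate_design(design)
    rng = np.random.default_rng(params.seed)
    mu = _mean_log2_matrix(design, truth)
    noise = rng.normal(0.0, params.noise_sd, mu.shape)
    values = pd.DataFrame(
        mu + noise, index=pd.Index(truth["gene_id"], name="gene_id"), columns=design["sample_id"]
    )
    return ExpressionMatrix(values=values, scale="log2")


def simulate_counts(
    design: pd.DataFrame, truth: pd.DataFrame, params: SimulationParams
) -> ExpressionMatrix:
    """RNA-seq-like counts: NB draws around length-weighted abundances.

    Transcript abundance per gene/sample is 2^mu from the planted log2
    model; the expected read count is proportional to abundance x gene
    length (longer genes collect more reads), scaled to the library size.
    Dispersion 0 degenerates to Poisson.
    """
    if design.empty or truth.empty:
        raise SimulationError("design and truth must be non-empty")
    validate_design(design)
    rng = np.random.default_rng(params.seed)
    n_genes = len(truth)
    lo, hi = params.gene_length_range
    lengths = rng.integers(lo, hi + 1, n_genes).astype(float)

    mu_log2 = _mean_log2_matrix(design, truth)
    abundance = np.exp2(mu_log2)
    read_weight = abundance * lengths[:, None]
    expected = params.library_size * read_weight / read_weight.sum(axis=0, keepdims=True)

    if params.dispersion == 0:
        counts = rng.poisson(expected)
    else:
        r = 1.0 / params.dispersion
        p = r / (r + expected)
        counts = rng.negative_binomial(r, p)

    index = pd.Index(truth["gene_id"], name="gene_id")
    values = pd.DataFrame(counts.astype(float), index=index, columns=design["sample_id"])
    lengths_bp = pd.Series(lengths, index=index, name="length_bp")
    return ExpressionMatrix(values=values, scale="counts", lengths_bp=lengths_bp)


@dataclass
class MultiModelSimulation:
    """Per-model datasets plus the planted sharing structure."""

    models: list[tuple[ExpressionMatrix, pd.DataFrame]]
    design: pd.DataFrame
    shared_core: set[str]
    private: dict[str, set[str]]  # model_id -> private dependent genes

    @property
    def model_ids(self) -> list[str]:
        return [f"model{i + 1}" for i in range(len(self.models))]


def simulate_multi_model(
    k_models: int,
    shared_core: int,
    model_private: int,
    params: SimulationParams | None = None,
    mode: str = "intensity",
    class_proportions: dict[str, float] | None = None,
    effect_params: dict[str, float] | None = None,
) -> MultiModelSimulation:
    """Simulate k models sharing a planted core of dependent genes.

    The same ``shared_core`` genes are dependent with the same sign in every
    model; each model additionally gets ``model_private`` genes dependent in
    it alone. Remaining genes follow the background class mix with the
    dependent classes removed. Emulates a multi-model design whose truth
    three-way intersection is the planted core.
    """
    if k_models < 2:
        raise SimulationError("k_models must be >= 2")
    params = params or SimulationParams()
    if shared_core + model_private * k_models > params.n_genes:
        raise SimulationError(
            f"shared_core + model_private*k_models = "
            f"{shared_core + model_private * k_models} exceeds n_genes = {params.n_genes}"
        )
    eff = dict(DEFAULT_EFFECT_PARAMS)
    eff.update(effect_params or {})
    props = dict(DEFAULT_CLASS_PROPORTIONS if class_proportions is None else class_proportions)
    # background mix excludes dependent classes (those are planted explicitly)
    bg = {c: props.get(c, 0.0) for c in ("stress_only", "ko_only", "null", "floor_noise")}
    bg_total = sum(bg.values())
    if bg_total <= 0:
        bg = {"null": 1.0}
        bg_total = 1.0
    bg = {c: v / bg_total for c, v in bg.items()}

    ss = np.random.SeedSequence(params.seed)
    master_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k_models)]

    width = max(4, len(str(params.n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, params.n_genes + 1)]
    perm = master_rng.permutation(params.n_genes)
    core_idx = perm[:shared_core]
    private_idx = {
        f"model{m + 1}": perm[shared_core + m * model_private: shared_core + (m + 1) * model_private]
        for m in range(k_models)
    }
    core_sign = master_rng.choice([-1.0, 1.0], shared_core)
    core_genes = {gene_ids[i] for i in core_idx}

    design = generate_design(params.n_per_group, params.seed)
    models: list[tuple[ExpressionMatrix, pd.DataFrame]] = []
    private_sets: dict[str, set[str]] = {}
    for m in range(k_models):
        model_id = f"model{m + 1}"
        mseed = child_seeds[m]
        truth = generate_truth(params.n_genes, bg, eff, seed=mseed)
        rng = np.random.default_rng(mseed + 1)

        def plant(idx: np.ndarray, signs: np.ndarray) -> None:
            mag = np.full(len(idx), eff["effect_size"])
            if eff["effect_sd"] > 0:
                mag = np.abs(mag + rng.normal(0, eff["effect_sd"], len(idx)))
            truth.loc[idx, "class"] = np.where(signs > 0, "dependent_up", "dependent_down")
            truth.loc[idx, "stress_effect"] = signs * mag
            truth.loc[idx, "reversion_fraction"] = eff["reversion_fraction"]
            # dependent genes must not sit in the noise floor
            low = truth.loc[idx, "baseline"] < eff["baseline_low"]
            truth.loc[idx[low.to_numpy()], "baseline"] = rng.uniform(
                eff["baseline_low"], eff["baseline_high"], int(low.sum())
            )

        plant(core_idx, core_sign)
        priv = private_idx[model_id]
        plant(priv, rng.choice([-1.0, 1.0], len(priv)))
        truth["shared_core"] = truth.index.isin(core_idx)
        truth["model_id"] = model_id
        private_sets[model_id] = {gene_ids[i] for i in priv}

        mparams = replace(params, seed=mseed)
        if mode == "intensity":
            em = simulate_intensities(design, truth, mparams)
        elif mode == "counts":
            em = simulate_counts(design, truth, mparams)
        else:
            raise SimulationError(f"unknown mode {mode!r}")
        models.append((em, truth))

    return MultiModelSimulation(
        models=models, design=design, shared_core=core_genes, private=private_sets
    )
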