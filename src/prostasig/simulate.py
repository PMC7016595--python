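"""Synthetic cohorts with known ground truth.

Four generators cover every input the pipeline consumes:

* a sorted-cell experiment (four purified prostate cell populations —
  luminal and basal epithelium, fibromuscular and endothelial stroma — with
  a few biological replicates each) for signature discovery;
* bulk tumour cohorts that are noisy convex mixtures of the cell-type
  archetypes, with known per-sample mixture proportions and a planted
  low-luminal subpopulation;
* families of datasets with partially overlapping gene universes, emulating
  multiple measurement platforms;
* paired pre/post-treatment profiles with compound-specific planted shifts
  of the standardised luminal score.

Expression follows a log-normal model: genes live on the log2 scale with
additive Gaussian noise, so effect sizes in log2 units are fold changes.
Mixing happens on the linear scale (transcripts add linearly) and the result
is declared linear.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix, GeneSetCollection, SampleAnnotation
from .ssgsea import DEFAULT_ALPHA, ScoreMatrix, score_pipeline

CANONICAL_TYPES = ("luminal", "basal", "fibromuscular", "endothelial")

#: baseline log2 expression of every gene in every archetype
BASELINE_LOG2 = 8.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults emulate the reference design: a 4-compartment sorted experiment
    with 5 replicates per compartment, markers 8-fold (3 log2 units = 3
    within-group SDs) above baseline in their own compartment, and bulk
    cohorts of 300 luminal-dominant mixtures of which a quarter carry a
    strongly depressed luminal weight.
    """

    n_cell_types: int = 4
    markers_per_type: int = 40
    n_background_genes: int = 1000
    marker_effect: float = 3.0  # log2 units added in the marker's own type
    replicates_per_type: int = 5
    n_bulk_samples: int = 300
    mixture_concentration: tuple = (6.0, 3.0, 3.0, 3.0)  # Dirichlet, luminal first
    low_luminal_fraction: float = 0.25
    noise_sd: float = 1.0  # additive log2-scale noise SD
    treatment_shift: float = 2.5  # planted z-score shift of the lead compound
    dedifferentiation: bool = False  # low samples lose marker expression, not cells
    dediff_attenuation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.markers_per_type, self.n_background_genes,
               self.replicates_per_type, self.n_bulk_samples) < 1:
            raise ValueError("all counts must be positive")
        if len(self.mixture_concentration) != self.n_cell_types:
            raise ValueError("mixture_concentration length must equal n_cell_types")
        if not 0 <= self.low_luminal_fraction <= 1:
            raise ValueError("low_luminal_fraction must be in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        if self.n_cell_types <= len(CANONICAL_TYPES):
            return list(CANONICAL_TYPES[: self.n_cell_types])
        extra = [f"type{k}" for k in range(len(CANONICAL_TYPES) + 1, self.n_cell_types + 1)]
        return list(CANONICAL_TYPES) + extra


@dataclass
class SyntheticTruth:
    """Ground truth the generators commit to, for test assertions."""

    marker_sets: GeneSetCollection
    proportions: pd.DataFrame | None = None  # samples x cell types, rows sum to 1
    low_flags: pd.Series | None = None
    planted_deltas: dict = field(default_factory=dict)


def _gene_layout(config: SimulationConfig):
    """Gene ids and the archetype log2 matrix (genes x cell types)."""
    types = config.cell_types
    marker_ids = {
        ct: [f"{ct}_marker_{i + 1:03d}" for i in range(config.markers_per_type)]
        for ct in types
    }
    bg_ids = [f"bg_{i + 1:04d}" for i in range(config.n_background_genes)]
    gene_ids = [g for ct in types for g in marker_ids[ct]] + bg_ids
    arch = pd.DataFrame(BASELINE_LOG2, index=gene_ids, columns=types, dtype=float)
    for ct in types:
        arch.loc[marker_ids[ct], ct] += config.marker_effect
    marker_sets = GeneSetCollection(
        sets={ct: marker_ids[ct] for ct in types},
        descriptions={ct: f"planted {ct} markers" for ct in types},
    )
    return gene_ids, arch, marker_sets


def simulate_sorted_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Sorted-cell design: replicates_per_type pure samples per compartment.

    Log2-scale matrix; background genes are iid Normal(baseline, noise_sd)
    in every compartment, markers gain ``marker_effect`` in their own.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, arch, marker_sets = _gene_layout(config)
    types = config.cell_types
    columns, means = [], []
    for ct in types:
        for r in range(config.replicates_per_type):
            columns.append(f"{ct}_rep{r + 1}")
            means.append(arch[ct].to_numpy())
    mean_mat = np.column_stack(means)
    values = mean_mat + rng.normal(0.0, config.noise_sd, size=mean_mat.shape)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=columns), scale="log2"
    )
    annotations = [
        SampleAnnotation(sample_id=col, labels={"cell_type": col.rsplit("_rep", 1)[0]})
        for col in columns
    ]
    return expr, annotations, SyntheticTruth(marker_sets=marker_sets)


def _draw_proportions(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_bulk_samples
    n_low = int(round(config.low_luminal_fraction * n))
    low_flags = np.zeros(n, dtype=bool)
    low_flags[rng.choice(n, size=n_low, replace=False)] = True
    conc = np.asarray(config.mixture_concentration, dtype=float)
    conc_low = conc.copy()
    conc_low[0] = conc_low[0] / 5.0  # depressed luminal weight
    props = np.empty((n, config.n_cell_types))
    for i in range(n):
        alpha = conc_low if (low_flags[i] and not config.dedifferentiation) else conc
        props[i] = rng.dirichlet(alpha)
    return props, low_flags


def simulate_bulk_cohort(
    config: SimulationConfig,
    sample_prefix: str = "bulk",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Bulk tumours as Dirichlet mixtures of the cell archetypes.

    A ``low_luminal_fraction`` subset is drawn with its luminal Dirichlet
    weight divided by 5 (or, under the dedifferentiation flag, with normal
    weights but attenuated luminal marker expression).  Linear-scale values
    with multiplicative log-normal noise.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, arch, marker_sets = _gene_layout(config)
    props, low_flags = _draw_proportions(config, rng)
    arch_linear = np.exp2(arch.to_numpy())  # genes x types
    bulk = arch_linear @ props.T  # genes x samples
    if config.dedifferentiation:
        lum_markers = arch.index.isin(marker_sets.sets[config.cell_types[0]])
        attenuated = arch.to_numpy().copy()
        attenuated[lum_markers, 0] = (
            BASELINE_LOG2 + config.marker_effect * config.dediff_attenuation
        )
        bulk_low = np.exp2(attenuated) @ props.T
        bulk[:, low_flags] = bulk_low[:, low_flags]
    noise = np.exp2(rng.normal(0.0, config.noise_sd, size=bulk.shape))
    values = bulk * noise
    sample_ids = [f"{sample_prefix}_{i + 1:04d}" for i in range(config.n_bulk_samples)]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale="linear"
    )
    truth = SyntheticTruth(
        marker_sets=marker_sets,
        proportions=pd.DataFrame(props, index=sample_ids, columns=config.cell_types),
        low_flags=pd.Series(low_flags, index=sample_ids, name="low_luminal"),
    )
    return expr, truth


def simulate_platform_family(
    config: SimulationConfig,
    n_datasets: int,
    overlap_fraction: float,
) -> list[tuple[ExpressionMatrix, SyntheticTruth]]:
    """Bulk cohorts whose gene universes only partially overlap.

    Each dataset independently drops a random (1 - overlap_fraction) subset
    of its background (non-marker) genes, so the cross-family gene
    intersection is a strict subset of the full universe when overlap < 1.
    """
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    family = []
    for d in range(n_datasets):
        cfg = replace(config, seed=config.seed + 7919 * (d + 1))
        expr, truth = simulate_bulk_cohort(cfg, sample_prefix=f"ds{d + 1}")
        rng = np.random.default_rng(cfg.seed + 1)
        bg = [g for g in expr.gene_ids if g.startswith("bg_")]
        n_keep = int(round(overlap_fraction * len(bg)))
        kept_bg = set(np.asarray(bg)[rng.choice(len(bg), size=n_keep, replace=False)])
        keep = [g for g in expr.gene_ids if not g.startswith("bg_") or g in kept_bg]
        family.append((expr.subset_genes(keep), truth))
    return family


def _plant_shift(
    pre: ExpressionMatrix,
    luminal_markers: list[str],
    sample_compound: pd.Series,
    targets: dict[str, float],
    alpha: float,
    tol: float = 0.02,
    max_rounds: int = 8,
) -> ExpressionMatrix:
    """Boost luminal-marker expression per compound until the jointly
    standardised luminal z-score shift matches each target delta.

    The z-log2 layer is cohort-relative, so every compound's boost feeds
    back into the common scale; a few rounds of per-compound root finding
    against the actual scoring function converge.
    """
    from .ssgsea import ssgsea_sample

    lum_rows = pre.data.index.isin(luminal_markers)
    samples = list(pre.sample_ids)
    by_compound = {
        c: [s for s in samples if sample_compound[s] == c] for c in targets
    }
    boosts = {c: 0.0 for c in targets}
    pre_raw = np.array(
        [ssgsea_sample(pre.data[s], luminal_markers, alpha=alpha) for s in samples]
    )

    def boosted_raw(sample: str, boost: float) -> float:
        col = pre.data[sample].copy()
        col[lum_rows] = col[lum_rows] * (2.0 ** boost)
        return ssgsea_sample(col, luminal_markers, alpha=alpha)

    def deltas_for(b: dict[str, float], cache: dict) -> dict[str, float]:
        post_raw = np.array(
            [
                cache.setdefault(
                    (s, b[sample_compound[s]]), boosted_raw(s, b[sample_compound[s]])
                )
                for s in samples
            ]
        )
        # replicate the joint z-log2 standardisation on the combined row
        x = np.concatenate([pre_raw, post_raw])
        xp = np.log2(x) if np.all(x > 0) else np.log2(x - x.min() + 1.0)
        z = (xp - xp.mean()) / xp.std(ddof=1)
        z_pre, z_post = z[: len(samples)], z[len(samples):]
        idx = {s: i for i, s in enumerate(samples)}
        return {
            c: float(np.mean([z_post[idx[s]] - z_pre[idx[s]] for s in by_compound[c]]))
            for c in targets
        }

    cache: dict = {}
    for _ in range(max_rounds):
        current = deltas_for(boosts, cache)
        if all(abs(current[c] - targets[c]) < tol for c in targets):
            break
        for compound, target in targets.items():
            if target == 0.0:
                boosts[compound] = 0.0
                continue

            def gap(b, _c=compound):
                trial = dict(boosts, **{_c: float(b)})
                return deltas_for(trial, cache)[_c] - targets[_c]

            lo, hi = -4.0, max(4.0, abs(boosts[compound]) + 1.0)
            while gap(hi) < 0 and hi < 64:
                hi *= 2
            while gap(lo) > 0 and lo > -64:
                lo *= 2
            if gap(hi) < 0 or gap(lo) > 0:
                raise ValueError(
                    f"planted delta {targets[compound]:+g} for {compound!r} is not "
                    "achievable: the standardised score saturates (a z-scale shift "
                    "is bounded by the cohort spread)"
                )
            boosts[compound] = brentq(gap, lo, hi, xtol=1e-4)

    post = pre.data.copy()
    for compound, boost in boosts.items():
        cols = sample_compound.index[sample_compound == compound]
        post.loc[lum_rows, cols] = post.loc[lum_rows, cols] * (2.0 ** boost)
    return ExpressionMatrix(post, scale=pre.scale)


def simulate_treatment_pairs(
    config: SimulationConfig,
    compounds: list[str],
    deltas: dict[str, float] | None = None,
    models_per_compound: int = 3,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[ScoreMatrix, ScoreMatrix, SyntheticTruth]:
    """Paired pre/post profiles with planted standardised luminal shifts.

    Models are low-luminal tumours with replicate-level variability: the
    luminal Dirichlet weight is divided by 5 (the compounds are meant to
    *restore* luminal identity, so the score needs room to rise) and all
    weights are scaled tenfold so pre-treatment mixtures are tight.  Each
    compound is tested in ``models_per_compound`` models (pre/post pairs).
    Unless ``deltas`` is given, compound i receives ``treatment_shift / 2^i``
    (only the lead compound shifts strongly — a z-scale delta is relative to
    the cohort spread, so a shift every sample shares would standardise
    itself away) and a ``control`` compound is planted at 0.  Pre and post
    are scored jointly (one combined standardisation) and returned as two
    aligned ScoreMatrix objects whose columns are model ids.
    """
    if deltas is None:
        deltas = {
            c: config.treatment_shift / 2.0 ** i for i, c in enumerate(compounds)
        }
        deltas.setdefault("control", 0.0)
    all_compounds = list(deltas)
    conc = np.asarray(config.mixture_concentration, dtype=float)
    conc_treat = conc.copy()
    conc_treat[0] /= 5.0
    cfg = replace(
        config, n_bulk_samples=models_per_compound * len(all_compounds),
        low_luminal_fraction=0.0,
        mixture_concentration=tuple(conc_treat * 30.0),
    )
    pre, truth = simulate_bulk_cohort(cfg, sample_prefix="model")
    sample_compound = pd.Series(
        [all_compounds[i // models_per_compound] for i in range(pre.n_samples)],
        index=pre.sample_ids,
        name="compound",
    )
    luminal_name = cfg.cell_types[0]
    post = _plant_shift(
        pre,
        truth.marker_sets.sets[luminal_name],
        sample_compound,
        deltas,
        alpha=alpha,
    )
    combined = pd.concat(
        [pre.data.add_suffix("::pre"), post.data.add_suffix("::post")], axis=1
    )
    scores = score_pipeline(
        ExpressionMatrix(combined, scale=pre.scale), truth.marker_sets, alpha=alpha
    )
    z = scores.layer("zlog2")
    pre_cols = [f"{s}::pre" for s in pre.sample_ids]
    post_cols = [f"{s}::post" for s in pre.sample_ids]
    raw = scores.raw_es
    pre_scores = ScoreMatrix(
        raw_es=raw[pre_cols].set_axis(pre.sample_ids, axis=1),
        zlog2=z[pre_cols].set_axis(pre.sample_ids, axis=1),
        params=dict(scores.params),
    )
    post_scores = ScoreMatrix(
        raw_es=raw[post_cols].set_axis(pre.sample_ids, axis=1),
        zlog2=z[post_cols].set_axis(pre.sample_ids, axis=1),
        params=dict(scores.params),
    )
    truth.planted_deltas = dict(deltas)
    truth.low_flags = None
    truth.proportions = truth.proportions
    pre_scores.params["compounds"] = sample_compound.to_dict()
    post_scores.params["compounds"] = sample_compound.to_dict()
    return pre_scores, post_scores, truth
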