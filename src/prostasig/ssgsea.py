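"""Single-sample gene-set enrichment (ssGSEA) scoring.

For one sample, genes are ordered by expression (descending) and a weighted
running sum walks down that list: positions occupied by set genes push the sum
up in proportion to their rank weight raised to ``alpha``; positions occupied
by non-set genes pull it down by 1/(N - |S|).  The enrichment score is the
*integral* of that running difference over all positions — not the maximum
deviation, which is what distinguishes the single-sample statistic from
classical two-group GSEA.  Because only ranks enter, the score is invariant to
any strictly increasing transform of the sample's values, which is what makes
scores comparable across platforms with different expression distributions.

Scores are subsequently put on a common scale by "z-log2" standardisation:
log2-transform the raw per-set score row, then z-score it across samples
(mean 0, sample SD 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

#: default rank-weight exponent (the widely distributed module default)
DEFAULT_ALPHA = 0.75


@dataclass
class ScoreMatrix:
    """Set x sample enrichment scores in raw, range-normalised and z-log2 layers."""

    raw_es: pd.DataFrame
    norm_es: pd.DataFrame | None = None
    zlog2: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    @property
    def set_names(self) -> list[str]:
        return list(self.raw_es.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw_es.columns)

    def layer(self, name: str) -> pd.DataFrame:
        out = getattr(self, name)
        if out is None:
            raise ValueError(f"layer {name!r} has not been computed")
        return out

    def to_long(self) -> pd.DataFrame:
        """Stacked long-format table (set, sample, raw[, norm][, zlog2])."""
        frames = {"raw": self.raw_es}
        if self.norm_es is not None:
            frames["norm"] = self.norm_es
        if self.zlog2 is not None:
            frames["zlog2"] = self.zlog2
        long = pd.concat(
            {k: v.stack() for k, v in frames.items()}, axis=1
        ).reset_index()
        long.columns = ["set", "sample", *frames]
        return long


def ssgsea_sample(values: pd.Series, gene_set: list[str], alpha: float = DEFAULT_ALPHA) -> float:
    """Raw enrichment score of one gene set in one sample.

    ``values`` maps gene id -> expression for the sample (the gene universe).
    Genes are ordered by expression descending; the walk order among ties is
    by gene id ascending, while rank *weights* use average ranks so tied
    genes weigh equally.  The score is

        sum_i [ P_in^w(i) - P_out(i) ]

    with P_in^w the weighted cumulative fraction of set genes encountered by
    position i (weights r_g^alpha, r_g = N - rank_g + 1) and P_out the plain
    cumulative fraction of non-set genes.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    universe = values.index
    in_set = universe.isin(gene_set)
    n = len(universe)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no overlap with the expression universe")
    if n_in == n:
        raise ValueError("gene set equals the whole universe; complement is empty")

    x = values.to_numpy(dtype=float)
    # descending rank: highest expression -> rank 1; ties share average rank
    asc_rank = rankdata(x, method="average")
    weight = asc_rank ** alpha  # r_g = N - desc_rank + 1 = ascending average rank

    # deterministic walk order: expression descending, gene id ascending on ties
    order = np.lexsort((np.asarray(universe), -x))
    in_sorted = in_set[order]
    w_sorted = weight[order]

    p_in = np.cumsum(np.where(in_sorted, w_sorted, 0.0))
    p_in /= p_in[-1]
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
) -> ScoreMatrix:
    """Raw enrichment score of every set in every sample.

    Set genes absent from the matrix's universe are dropped per set with a
    logged count.  If ``normalize``, a range-normalised layer divides the raw
    scores by (max - min) over the entire raw matrix.
    """
    effective: dict[str, list[str]] = {}
    universe = set(expr.gene_ids)
    for name, genes in sets:
        present = [g for g in genes if g in universe]
        dropped = len(genes) - len(present)
        if dropped:
            logger.info("set %s: %d gene(s) absent from the universe, dropped", name, dropped)
        if not present:
            raise ValueError(f"gene set {name!r} has no overlap with the expression universe")
        effective[name] = present

    raw = pd.DataFrame(
        {
            sample: {
                name: ssgsea_sample(expr.data[sample], genes, alpha=alpha)
                for name, genes in effective.items()
            }
            for sample in expr.sample_ids
        }
    )
    raw = raw.loc[list(effective), expr.sample_ids]
    norm = None
    if normalize:
        span = raw.to_numpy().max() - raw.to_numpy().min()
        if span == 0:
            raise ValueError("all enrichment scores identical; range normalisation undefined")
        norm = raw / span
    return ScoreMatrix(
        raw_es=raw,
        norm_es=norm,
        params={"alpha": alpha, "tie_rule": "average-weight/id-order", "normalize": normalize},
    )


def zlog2_standardize(scores: ScoreMatrix) -> ScoreMatrix:
    """Add the z-log2 layer: per set-row log2 then z-score across samples.

    Raw ssGSEA scores can be negative, for which log2 is undefined; such rows
    are shifted by (1 - min) before the log (offset recorded in params and
    warned about).  Constant rows standardise to all zeros with a warning.
    A single-sample matrix has no sample SD and is rejected.
    """
    raw = scores.raw_es
    if raw.shape[1] < 2:
        raise ValueError("z-log2 standardisation needs >=2 samples (sample SD undefined)")
    offsets: dict[str, float] = {}
    z_rows = {}
    for name, row in raw.iterrows():
        x = row.to_numpy(dtype=float)
        if np.all(x > 0):
            xp = np.log2(x)
        else:
            offset = float(1.0 - x.min())
            logger.warning(
                "set %s: non-positive raw scores; applying offset %+g before log2",
                name, offset,
            )
            offsets[name] = offset
            xp = np.log2(x + offset)
        sd = xp.std(ddof=1)
        if sd == 0:
            logger.warning("set %s: constant scores; z-log2 row set to zeros", name)
            z_rows[name] = np.zeros_like(xp)
        else:
            z_rows[name] = (xp - xp.mean()) / sd
    z = pd.DataFrame(z_rows).T
    z.columns = raw.columns
    z = z.loc[raw.index]
    params = dict(scores.params)
    if offsets:
        params["zlog2_offsets"] = offsets
    return ScoreMatrix(raw_es=raw, norm_es=scores.norm_es, zlog2=z, params=params)


def score_pipeline(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
    zlog2: bool = True,
) -> ScoreMatrix:
    """Convenience: raw ssGSEA scores plus (by default) the z-log2 layer."""
    scores = ssgsea_matrix(expr, sets, alpha=alpha, normalize=normalize)
    if zlog2:
        scores = zlog2_standardize(scores)
    return scores
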