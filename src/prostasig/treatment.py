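"""Treatment-induced metagene score shifts and compound ranking.

Paired pre/post-treatment profiles (e.g., a mouse model before and after a
compound) are compared on the same scoring layer; the per-pair delta is
post - pre.  Compounds are ranked by the luminal-restoring shift they induce:
the default listing rule keeps compounds whose luminal-score increase exceeds
a strict threshold (2 standardised units by default); a "both" mode requires
a luminal increase together with a basal decrease, and consistency across two
cellular contexts is imposed by intersecting per-context pass lists.

Because the z-log2 layer is cohort-relative, pre and post profiles must be
scored together (one combined matrix) before splitting into the two
ScoreMatrix arguments — scoring them separately would standardise the shift
away.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ssgsea import ScoreMatrix


@dataclass
class TreatmentRecord:
    model_id: str
    compound: str
    pre_score: float
    post_score: float

    @property
    def delta(self) -> float:
        return self.post_score - self.pre_score


def delta_scores(
    pre: ScoreMatrix,
    post: ScoreMatrix,
    set_name: str,
    layer: str = "zlog2",
    compounds: pd.Series | None = None,
) -> list[TreatmentRecord]:
    """One record per matched pre/post sample pair for one metagene.

    Pre and post columns are matched by sample id; ``compounds`` optionally
    maps sample id -> compound name (defaults to the sample id itself).
    Both matrices must expose the requested layer.
    """
    for name, sm in (("pre", pre), ("post", post)):
        if getattr(sm, layer) is None:
            raise ValueError(f"{name} scores lack the {layer!r} layer")
    pre_row = pre.layer(layer).loc[set_name]
    post_row = post.layer(layer).loc[set_name]
    unmatched = sorted(set(pre_row.index) ^ set(post_row.index))
    if unmatched:
        raise ValueError(f"unmatched pre/post sample key(s): {unmatched}")
    records = []
    for sample in pre_row.index:
        compound = str(compounds[sample]) if compounds is not None else str(sample)
        records.append(
            TreatmentRecord(
                model_id=str(sample),
                compound=compound,
                pre_score=float(pre_row[sample]),
                post_score=float(post_row[sample]),
            )
        )
    return records


def _mean_delta_by_compound(records: list[TreatmentRecord]) -> pd.Series:
    df = pd.DataFrame(
        {"compound": [r.compound for r in records], "delta": [r.delta for r in records]}
    )
    return df.groupby("compound")["delta"].mean()


def rank_compounds(
    records: list[TreatmentRecord],
    increase_threshold: float = 2.0,
    direction: str = "lume_up",
    base_records: list[TreatmentRecord] | None = None,
) -> list[str]:
    """Compounds passing the shift rule, sorted by |mean delta| descending.

    ``lume_up``: mean luminal delta strictly above ``increase_threshold``.
    ``base_down``: mean basal delta strictly below ``-increase_threshold``.
    ``both``: luminal delta > 0 AND basal delta < 0 for the same compound
    (``base_records`` supplies the basal deltas); pass lists from the two
    score contexts are intersected.
    """
    if not records:
        raise ValueError("no treatment records")
    deltas = _mean_delta_by_compound(records)
    if direction == "lume_up":
        passed = deltas[deltas > increase_threshold]
    elif direction == "base_down":
        passed = deltas[deltas < -increase_threshold]
    elif direction == "both":
        if base_records is None:
            raise ValueError("direction 'both' needs base_records")
        base = _mean_delta_by_compound(base_records)
        names = set(deltas[deltas > 0].index) & set(base[base < 0].index)
        passed = deltas[deltas.index.isin(names)]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    ordered = passed.abs().sort_values(ascending=False, kind="mergesort")
    return list(ordered.index)


def consistent_across_contexts(pass_lists: list[list[str]]) -> list[str]:
    """Compounds passing in every cellular context (order from the first)."""
    if not pass_lists:
        return []
    common = set(pass_lists[0])
    for lst in pass_lists[1:]:
        common &= set(lst)
    return [c for c in pass_lists[0] if c in common]
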