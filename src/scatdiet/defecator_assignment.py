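"""Defecator assignment and scat exclusion rules.

A scat is assigned to a defecator if (1) exactly one candidate carnivore is
present among its retained taxa, or (2) several are present but the
non-dominant carnivores jointly account for less than
``max_other_carnivore_share`` of the sample's retained reads, in which case
the dominant carnivore is the defecator and the others are treated as
contamination.  Assigned scats whose diet is empty, or whose every diet item
falls below ``min_item_share`` of the sample's retained reads, are excluded
from all summaries; sub-threshold items in otherwise retained scats are
dropped individually.
"""

from __future__ import annotations

from typing import Mapping

from .data_model_io import (
    DietItem,
    FilterConfig,
    ScatComposition,
    ScatStatus,
    Taxonomy,
)

__all__ = ["assign_defecator", "apply_exclusions"]


def assign_defecator(
    scat_id: str,
    retained: Mapping[str, int],
    taxonomy: Taxonomy,
    config: FilterConfig,
    exploration: set[str] | None = None,
) -> ScatComposition:
    """Assign a defecator to one filtered scat.

    ``retained`` is the taxon → combined-reads mapping from
    :func:`~scatdiet.replicate_filter.filter_scat`; shares are computed
    against the sum of all retained reads of the sample.
    """
    exploration = exploration or set()
    carnivores = {t: r for t, r in retained.items() if taxonomy.is_carnivore(t)}
    total = sum(retained.values())

    if not carnivores:
        return ScatComposition(
            scat_id=scat_id, status=ScatStatus.NO_CARNIVORE, exploration_items=set(exploration)
        )

    removed_carnivores: set[str] = set()
    if len(carnivores) == 1:
        (defecator,) = carnivores
    else:
        max_reads = max(carnivores.values())
        top = [t for t, r in carnivores.items() if r == max_reads]
        if len(top) > 1:  # tie: never choose arbitrarily
            return ScatComposition(
                scat_id=scat_id,
                status=ScatStatus.AMBIGUOUS_DEFECATOR,
                exploration_items=set(exploration),
            )
        defecator = top[0]
        others = {t: r for t, r in carnivores.items() if t != defecator}
        if config.other_carnivore_scope == "combined":
            ok = sum(others.values()) / total < config.max_other_carnivore_share
        else:
            ok = all(r / total < config.max_other_carnivore_share for r in others.values())
        if not ok:
            return ScatComposition(
                scat_id=scat_id,
                status=ScatStatus.AMBIGUOUS_DEFECATOR,
                exploration_items=set(exploration),
            )
        if not config.carnivores_as_prey:
            removed_carnivores = set(others)

    diet_items = {
        taxon: DietItem(combined_reads=reads, share=reads / total)
        for taxon, reads in retained.items()
        if taxon != defecator and taxon not in removed_carnivores
    }
    return ScatComposition(
        scat_id=scat_id,
        status=ScatStatus.ASSIGNED,
        defecator=defecator,
        diet_items=diet_items,
        exploration_items=set(exploration),
    )


def apply_exclusions(comp: ScatComposition, config: FilterConfig) -> ScatComposition:
    """Apply the no-diet exclusion rules to an assigned scat.

    The scat becomes ``EXCLUDED_NO_DIET`` iff it has no diet items at all or
    every diet item's share is below ``min_item_share``; otherwise
    sub-threshold items are dropped individually and the scat is kept.
    Idempotent; non-assigned scats pass through unchanged.
    """
    if comp.status is not ScatStatus.ASSIGNED:
        return comp
    kept = {
        taxon: item
        for taxon, item in comp.diet_items.items()
        if item.share >= config.min_item_share
    }
    if not kept:
        return ScatComposition(
            scat_id=comp.scat_id,
            status=ScatStatus.EXCLUDED_NO_DIET,
            defecator=comp.defecator,
            diet_items={},
            exploration_items=set(comp.exploration_items),
        )
    return ScatComposition(
        scat_id=comp.scat_id,
        status=ScatStatus.ASSIGNED,
        defecator=comp.defecator,
        diet_items=kept,
        exploration_items=set(comp.exploration_items),
    )
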