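"""Diet composition metrics: FOO, wPOO, rank aggregation and summaries.

FOO_k is the proportion of scats containing taxon k.  wPOO_k gives every
scat equal weight 1/N, split uniformly among the items it contains, so the
wPOO vector sums to one; an alternative read-share weighting is available
behind ``wpoo_weighting="read_share"``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .data_model_io import (
    DietItem,
    DietProfile,
    RANKS,
    ScatComposition,
    ScatStatus,
    Taxonomy,
)

__all__ = [
    "compute_foo",
    "compute_wpoo",
    "build_profile",
    "aggregate_rank",
    "diet_summary",
]


def _check_assigned(compositions: Sequence[ScatComposition]) -> None:
    if not compositions:
        raise ValueError("need at least one scat composition")
    for comp in compositions:
        if comp.status is not ScatStatus.ASSIGNED:
            raise ValueError(
                f"scat {comp.scat_id!r} has status {comp.status.value}; "
                "only assigned scats enter diet summaries"
            )


def compute_foo(compositions: Sequence[ScatComposition]) -> dict[str, float]:
    """Frequency of occurrence: share of scats containing each taxon.

    Taxa occurring in no scat are absent from the mapping rather than mapped
    to zero (sparse support convention).
    """
    _check_assigned(compositions)
    n = len(compositions)
    counts: dict[str, int] = {}
    for comp in compositions:
        for taxon in comp.diet_items:
            counts[taxon] = counts.get(taxon, 0) + 1
    return {taxon: c / n for taxon, c in counts.items()}


def compute_wpoo(
    compositions: Sequence[ScatComposition], weighting: str = "uniform"
) -> dict[str, float]:
    """Weighted percent of occurrence over taxa; sums to 1.

    Every scat must hold at least one diet item — exclusions must run before
    this summary.
    """
    _check_assigned(compositions)
    for comp in compositions:
        if not comp.diet_items:
            raise ValueError(
                f"scat {comp.scat_id!r} has no diet items; run exclusions before wPOO"
            )
    n = len(compositions)
    wpoo: dict[str, float] = {}
    for comp in compositions:
        if weighting == "uniform":
            w = 1.0 / len(comp.diet_items)
            for taxon in comp.diet_items:
                wpoo[taxon] = wpoo.get(taxon, 0.0) + w / n
        elif weighting == "read_share":
            total_share = sum(item.share for item in comp.diet_items.values())
            for taxon, item in comp.diet_items.items():
                wpoo[taxon] = wpoo.get(taxon, 0.0) + (item.share / total_share) / n
        else:
            raise ValueError(f"unknown wpoo weighting {weighting!r}")
    return wpoo


def build_profile(
    species_label: str,
    compositions: Sequence[ScatComposition],
    weighting: str = "uniform",
) -> DietProfile:
    return DietProfile(
        species_label=species_label,
        n_scats=len(compositions),
        foo=compute_foo(compositions),
        wpoo=compute_wpoo(compositions, weighting=weighting),
    )


def aggregate_rank(
    compositions: Sequence[ScatComposition],
    rank: str,
    taxonomy: Taxonomy,
) -> list[ScatComposition]:
    """Re-key each scat's diet items at a coarser taxonomic rank.

    Items sharing a rank label within a scat are presence-merged (reads and
    shares summed); empty rank labels roll up to the nearest nonempty
    ancestor.  FOO/wPOO are recomputable on the result.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    out = []
    for comp in compositions:
        merged: dict[str, DietItem] = {}
        for taxon, item in comp.diet_items.items():
            label = taxonomy[taxon].rank_label(rank)
            if label in merged:
                prev = merged[label]
                merged[label] = DietItem(
                    combined_reads=prev.combined_reads + item.combined_reads,
                    share=prev.share + item.share,
                )
            else:
                merged[label] = DietItem(item.combined_reads, item.share)
        # the defecator keeps its original id: re-keying it could collide
        # with a prey item's coarse-rank label (e.g. both "Mammalia")
        out.append(
            ScatComposition(
                scat_id=comp.scat_id,
                status=comp.status,
                defecator=comp.defecator,
                diet_items=merged,
                exploration_items=set(comp.exploration_items),
            )
        )
    return out


def diet_summary(profile_a: DietProfile, profile_b: DietProfile) -> dict:
    """Richness, union/intersection sizes and shared fraction of two profiles."""
    support_a, support_b = profile_a.support, profile_b.support
    union = support_a | support_b
    inter = support_a & support_b
    return {
        "richness": {
            profile_a.species_label: len(support_a),
            profile_b.species_label: len(support_b),
        },
        "union_size": len(union),
        "intersection_size": len(inter),
        "shared_fraction": (len(inter) / len(union)) if union else 0.0,
    }
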