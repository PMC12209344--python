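"""Replicate-consensus read filtering.

A replicate is *valid* iff its total reads exceed
``min_reads_per_replicate`` (strict, per the wording "over N reads").  A
taxon is *retained* iff its relative read abundance (RRA) meets ``min_rra``
(inclusive) in at least ``min_replicates`` valid replicates.  Taxa that meet
the same rule only at the looser ``exploration_rra`` threshold are reported
in a separate exploration set and never enter any summary.

With ``rra_scope="pooled"`` the RRA threshold is instead applied to reads
pooled across valid replicates, combined with detection (any reads) in at
least ``min_replicates`` valid replicates.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .data_model_io import FilterConfig, ScatStatus

__all__ = ["compute_rra", "filter_scat"]


def compute_rra(replicate_counts: Mapping[str, int]) -> dict[str, float]:
    """Relative read abundance of each taxon within one replicate.

    Raises ``ValueError`` on an all-zero (or empty) replicate: the caller
    must treat such a replicate as absent.
    """
    total = sum(replicate_counts.values())
    if total <= 0:
        raise ValueError("replicate has no positive read counts")
    return {taxon: reads / total for taxon, reads in replicate_counts.items() if reads > 0}


def _qualifying_taxa(
    valid: dict[int, dict[str, int]], threshold: float, min_replicates: int, scope: str
) -> set[str]:
    if scope == "pooled":
        pooled: dict[str, int] = {}
        detections: dict[str, int] = {}
        for counts in valid.values():
            for taxon, reads in counts.items():
                if reads > 0:
                    pooled[taxon] = pooled.get(taxon, 0) + reads
                    detections[taxon] = detections.get(taxon, 0) + 1
        total = sum(pooled.values())
        if total == 0:
            return set()
        return {
            t
            for t, reads in pooled.items()
            if reads / total >= threshold and detections[t] >= min_replicates
        }
    hits: dict[str, int] = {}
    for counts in valid.values():
        rra = compute_rra(counts)
        for taxon, value in rra.items():
            if value >= threshold:
                hits[taxon] = hits.get(taxon, 0) + 1
    return {t for t, n in hits.items() if n >= min_replicates}


def filter_scat(
    scat_records: pd.DataFrame | dict[int, dict[str, int]],
    config: FilterConfig,
) -> tuple[ScatStatus, dict[str, int], set[str]]:
    """Collapse one scat's replicates into a retained composition.

    Parameters
    ----------
    scat_records
        Either a DataFrame slice with columns replicate, taxon_id, reads, or
        a mapping replicate_id → (taxon → reads).
    config
        Thresholds; see :class:`~scatdiet.data_model_io.FilterConfig`.

    Returns
    -------
    (status, retained, exploration)
        ``status`` is ``FAILED_AMPLIFICATION`` or ``ASSIGNED`` (a placeholder
        meaning "passed filtering"; defecator assignment refines it).
        ``retained`` maps each retained taxon to its reads summed across all
        valid replicates.  ``exploration`` holds taxa passing only the
        exploration threshold.
    """
    if isinstance(scat_records, pd.DataFrame):
        replicates: dict[int, dict[str, int]] = {}
        for _, row in scat_records.iterrows():
            if row["reads"] > 0:
                replicates.setdefault(int(row["replicate"]), {})[row["taxon_id"]] = int(
                    row["reads"]
                )
    else:
        replicates = {
            rep: {t: int(r) for t, r in counts.items() if r > 0}
            for rep, counts in scat_records.items()
        }

    valid = {
        rep: counts
        for rep, counts in replicates.items()
        if sum(counts.values()) > config.min_reads_per_replicate
    }
    if len(valid) < config.min_replicates:
        return ScatStatus.FAILED_AMPLIFICATION, {}, set()

    retained_taxa = _qualifying_taxa(
        valid, config.min_rra, config.min_replicates, config.rra_scope
    )
    exploration_taxa = (
        _qualifying_taxa(valid, config.exploration_rra, config.min_replicates, config.rra_scope)
        - retained_taxa
    )

    retained: dict[str, int] = {}
    for taxon in retained_taxa:
        retained[taxon] = sum(counts.get(taxon, 0) for counts in valid.values())
    return ScatStatus.ASSIGNED, retained, exploration_taxa
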