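"""Seeded synthetic scat read-count generator with known ground truth.

Emulates the structure of a two-carnivore scat metabarcoding study: each
scat yields three PCR replicates whose taxon counts are multinomial draws
over (defecator fraction, prey proportions, optional contaminant carnivore
fraction), degraded by proportion-dependent dropout, tag-jump reassignment
and occasional failed (shallow) replicates.

Randomness is organized so that each scat has its own substream derived from
(seed, species index, scat index): adding scats never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model_io import (
    DietProfile,
    ReadCountTable,
    TaxonRecord,
    Taxonomy,
)

__all__ = [
    "SimulationParams",
    "TruthBundle",
    "default_taxonomy",
    "simulate_dataset",
    "make_profiles_with_overlap",
]

# A compact vertebrate-flavoured pool: (class, order, family, genus, species).
_DEFAULT_PREY = [
    ("ground_squirrel", "Mammalia", "Rodentia", "Sciuridae", "Callospermophilus", "Callospermophilus lateralis"),
    ("deer_mouse", "Mammalia", "Rodentia", "Cricetidae", "Peromyscus", "Peromyscus maniculatus"),
    ("red_backed_vole", "Mammalia", "Rodentia", "Cricetidae", "Myodes", "Myodes californicus"),
    ("meadow_vole", "Mammalia", "Rodentia", "Cricetidae", "Microtus", "Microtus montanus"),
    ("heather_vole", "Mammalia", "Rodentia", "Cricetidae", "Phenacomys", "Phenacomys intermedius"),
    ("pocket_gopher", "Mammalia", "Rodentia", "Geomyidae", "Thomomys", "Thomomys talpoides"),
    ("chipmunk", "Mammalia", "Rodentia", "Sciuridae", "Tamias", ""),
    ("douglas_squirrel", "Mammalia", "Rodentia", "Sciuridae", "Tamiasciurus", "Tamiasciurus douglasii"),
    ("flying_squirrel", "Mammalia", "Rodentia", "Sciuridae", "Glaucomys", "Glaucomys oregonensis"),
    ("woodrat", "Mammalia", "Rodentia", "Cricetidae", "Neotoma", "Neotoma cinerea"),
    ("snowshoe_hare", "Mammalia", "Lagomorpha", "Leporidae", "Lepus", "Lepus americanus"),
    ("pika", "Mammalia", "Lagomorpha", "Ochotonidae", "Ochotona", "Ochotona princeps"),
    ("mule_deer", "Mammalia", "Artiodactyla", "Cervidae", "Odocoileus", ""),
    ("elk", "Mammalia", "Artiodactyla", "Cervidae", "Cervus", "Cervus canadensis"),
    ("shrew", "Mammalia", "Eulipotyphla", "Soricidae", "Sorex", ""),
    ("mole", "Mammalia", "Eulipotyphla", "Talpidae", "Scapanus", ""),
    ("grouse", "Aves", "Galliformes", "Phasianidae", "Dendragapus", "Dendragapus fuliginosus"),
    ("junco", "Aves", "Passeriformes", "Passerellidae", "Junco", "Junco hyemalis"),
    ("woodpecker", "Aves", "Piciformes", "Picidae", "Dryobates", "Dryobates villosus"),
    ("frog", "Amphibia", "Anura", "Ranidae", "Rana", "Rana cascadae"),
]

_DEFAULT_CARNIVORES = [
    ("red_fox", "Mammalia", "Carnivora", "Canidae", "Vulpes", "Vulpes vulpes"),
    ("coyote", "Mammalia", "Carnivora", "Canidae", "Canis", "Canis latrans"),
    ("bobcat", "Mammalia", "Carnivora", "Felidae", "Lynx", "Lynx rufus"),
    ("marten", "Mammalia", "Carnivora", "Mustelidae", "Martes", "Martes caurina"),
]


def default_taxonomy(n_prey: int = 20) -> Taxonomy:
    """Built-in taxonomy: ``n_prey`` prey taxa plus four flagged carnivores."""
    if n_prey > len(_DEFAULT_PREY):
        raise ValueError(f"built-in prey pool holds only {len(_DEFAULT_PREY)} taxa")
    records = [
        TaxonRecord(tid, cl, o, f, g, s, candidate_defecator=False)
        for tid, cl, o, f, g, s in _DEFAULT_PREY[:n_prey]
    ]
    records += [
        TaxonRecord(tid, cl, o, f, g, s, candidate_defecator=True)
        for tid, cl, o, f, g, s in _DEFAULT_CARNIVORES
    ]
    return Taxonomy(records)


@dataclass
class SimulationParams:
    n_scats_per_species: int = 30
    defecator_taxa: tuple[str, str] = ("red_fox", "coyote")
    n_prey: int = 20
    prey_weights: np.ndarray | None = None  # per-species rows; Dirichlet-drawn if None
    prey_concentration: float = 1.0
    richness_lambda: float = 1.5  # scat richness = 1 + Poisson(lambda), capped at pool
    within_scat_concentration: float = 1.0
    defecator_beta: tuple[float, float] = (8.0, 2.0)
    depth_median: float = 20000.0
    depth_log_sd: float = 0.5
    dropout_d0: float = 0.5
    dropout_r0: float = 0.02
    contamination_prob: float = 0.1
    contamination_max_fraction: float = 0.08
    tagjump_rate: float = 0.002
    failed_replicate_prob: float = 0.05
    failed_depth_max: int = 1000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "dropout_d0": self.dropout_d0,
            "contamination_prob": self.contamination_prob,
            "tagjump_rate": self.tagjump_rate,
            "failed_replicate_prob": self.failed_replicate_prob,
        }
        for name, v in probs.items():
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.richness_lambda <= 0:
            raise ValueError("richness_lambda must be positive")
        if self.depth_median < 1:
            raise ValueError("depth_median must be >= 1")
        if self.defecator_taxa[0] == self.defecator_taxa[1]:
            raise ValueError("the two defecator taxa must be distinct")
        if self.n_prey < 1:
            raise ValueError("prey pool must contain at least one taxon")


@dataclass
class TruthBundle:
    """Ground truth of a simulated dataset, for recovery tests."""

    defecator_of: dict[str, str]  # scat_id -> true defecator taxon
    prey_sets: dict[str, dict[str, float]]  # scat_id -> taxon -> true proportion
    contamination: list[tuple[str, str, float]]  # (scat_id, contaminant, fraction)
    true_profiles: dict[str, DietProfile] = field(default_factory=dict)


def _true_profiles(
    defecator_of: dict[str, str], prey_sets: dict[str, dict[str, float]]
) -> dict[str, DietProfile]:
    profiles = {}
    for species in sorted(set(defecator_of.values())):
        scats = [s for s, d in defecator_of.items() if d == species]
        foo: dict[str, float] = {}
        wpoo: dict[str, float] = {}
        n = len(scats)
        for s in scats:
            items = prey_sets[s]
            for taxon in items:
                foo[taxon] = foo.get(taxon, 0.0) + 1 / n
                wpoo[taxon] = wpoo.get(taxon, 0.0) + 1 / (n * len(items))
        profiles[species] = DietProfile(species_label=species, n_scats=n, foo=foo, wpoo=wpoo)
    return profiles


def simulate_dataset(
    params: SimulationParams,
) -> tuple[ReadCountTable, TruthBundle, Taxonomy]:
    """Generate a seeded dataset; identical params+seed give identical output."""
    taxonomy = default_taxonomy(params.n_prey)
    prey_ids = [t.taxon_id for t in taxonomy if not t.candidate_defecator]
    all_ids = [t.taxon_id for t in taxonomy]
    for d in params.defecator_taxa:
        if d not in taxonomy or not taxonomy.is_carnivore(d):
            raise ValueError(f"defecator taxon {d!r} missing or not a flagged carnivore")

    master = np.random.default_rng(params.seed)
    if params.prey_weights is not None:
        weights = np.asarray(params.prey_weights, dtype=float)
        if weights.ndim == 1:
            weights = np.vstack([weights, weights])
        if weights.shape != (2, len(prey_ids)):
            raise ValueError(
                f"prey_weights must have shape (2, {len(prey_ids)}), got {weights.shape}"
            )
        weights = weights / weights.sum(axis=1, keepdims=True)
    else:
        weights = master.dirichlet(
            np.full(len(prey_ids), params.prey_concentration), size=2
        )

    rows: list[dict] = []
    defecator_of: dict[str, str] = {}
    prey_sets: dict[str, dict[str, float]] = {}
    contamination: list[tuple[str, str, float]] = []
    pool_w = np.ones(len(all_ids)) / len(all_ids)  # tag-jump destination pool

    for sp_idx, defecator in enumerate(params.defecator_taxa):
        other = params.defecator_taxa[1 - sp_idx]
        for scat_idx in range(params.n_scats_per_species):
            rng = np.random.default_rng([params.seed, sp_idx, scat_idx])
            scat_id = f"{defecator}_{scat_idx + 1:03d}"
            defecator_of[scat_id] = defecator

            w = weights[sp_idx]
            n_available = int((w > 0).sum())
            if n_available < 1:
                raise ValueError("prey pool has no taxa with positive weight")
            k = 1 + rng.poisson(params.richness_lambda)
            k = min(k, n_available)
            chosen = rng.choice(len(prey_ids), size=k, replace=False, p=w)
            props = rng.dirichlet(np.full(k, params.within_scat_concentration))
            prey = {prey_ids[i]: float(pr) for i, pr in zip(chosen, props)}
            prey_sets[scat_id] = prey

            f_def = rng.beta(*params.defecator_beta)
            contaminant_frac = 0.0
            if rng.random() < params.contamination_prob:
                contaminant_frac = rng.uniform(0, params.contamination_max_fraction)
                contamination.append((scat_id, other, contaminant_frac))

            support = [defecator] + list(prey)
            comp = [f_def] + [(1 - f_def) * p for p in prey.values()]
            if contaminant_frac > 0:
                comp = [c * (1 - contaminant_frac) for c in comp]
                support.append(other)
                comp.append(contaminant_frac)
            comp = np.asarray(comp)
            comp = comp / comp.sum()

            for rep in range(1, params.n_replicates + 1):
                if rng.random() < params.failed_replicate_prob:
                    depth = int(rng.integers(1, params.failed_depth_max + 1))
                else:
                    depth = max(
                        1,
                        int(
                            round(
                                rng.lognormal(
                                    math.log(params.depth_median), params.depth_log_sd
                                )
                            )
                        ),
                    )
                counts = rng.multinomial(depth, comp)
                # proportion-dependent dropout: rare taxa fail detection more
                for i, r in enumerate(comp):
                    if counts[i] > 0 and params.dropout_d0 > 0:
                        p_drop = params.dropout_d0 * math.exp(-r / params.dropout_r0)
                        if rng.random() < p_drop:
                            counts[i] = 0
                # tag-jump reassignment: conserve depth, move reads to pool taxa
                total = int(counts.sum())
                if params.tagjump_rate > 0 and total > 0:
                    n_jump = rng.binomial(total, params.tagjump_rate)
                    if n_jump > 0:
                        removed = rng.multivariate_hypergeometric(counts, n_jump)
                        counts = counts - removed
                        dest = rng.multinomial(n_jump, pool_w)
                        dest_map = dict(zip(all_ids, dest))
                        for i, taxon in enumerate(support):
                            if dest_map.get(taxon, 0):
                                counts[i] += dest_map.pop(taxon)
                        for taxon, n in dest_map.items():
                            if n > 0:
                                rows.append(
                                    {
                                        "scat_id": scat_id,
                                        "replicate": rep,
                                        "taxon_id": taxon,
                                        "reads": int(n),
                                    }
                                )
                for taxon, n in zip(support, counts):
                    if n > 0:
                        rows.append(
                            {
                                "scat_id": scat_id,
                                "replicate": rep,
                                "taxon_id": taxon,
                                "reads": int(n),
                            }
                        )

    frame = pd.DataFrame(rows, columns=["scat_id", "replicate", "taxon_id", "reads"])
    frame = (
        frame.groupby(["scat_id", "replicate", "taxon_id"], as_index=False)["reads"]
        .sum()
        .sort_values(["scat_id", "replicate", "taxon_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    table = ReadCountTable(frame=frame, n_replicates=params.n_replicates)
    truth = TruthBundle(
        defecator_of=defecator_of,
        prey_sets=prey_sets,
        contamination=contamination,
        true_profiles=_true_profiles(defecator_of, prey_sets),
    )
    return table, truth, taxonomy


def make_profiles_with_overlap(
    theta: float, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Construct two utilization vectors with a known Pianka overlap.

    p is uniform on categories 1..k, r uniform on the disjoint categories
    k+1..2k, and q = theta*p + (1-theta)*r, giving
    o_true = theta / sqrt(theta^2 + (1-theta)^2).  The seed only shuffles the
    category order (which leaves the overlap invariant).
    """
    if not (0 <= theta <= 1):
        raise ValueError(f"theta must be in [0,1], got {theta}")
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.concatenate([np.full(k, 1.0 / k), np.zeros(k)])
    r = np.concatenate([np.zeros(k), np.full(k, 1.0 / k)])
    q = theta * p + (1 - theta) * r
    perm = np.random.default_rng(seed).permutation(2 * k)
    o_true = theta / math.sqrt(theta**2 + (1 - theta) ** 2) if theta > 0 else 0.0
    return p[perm], q[perm], o_true
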