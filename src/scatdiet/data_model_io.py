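"""Shared domain types and tabular input/output.

The pipeline consumes two long-format text tables — a taxonomy table and a
per-replicate read-count table — plus a flat key-value configuration file.
Results are written as flat CSV tables (per-species diet profiles, per-scat
statuses) and one nested JSON document (overlap and rarefaction results).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TAXONOMY_COLUMNS = (
    "taxon_id",
    "class_name",
    "order_name",
    "family_name",
    "genus_name",
    "species_name",
    "candidate_defecator",
)

COUNT_COLUMNS = ("scat_id", "replicate", "taxon_id", "reads")

RANKS = ("species", "genus", "family", "order", "class")


class ScatStatus(str, enum.Enum):
    """Terminal status of a scat after filtering, assignment and exclusions."""

    ASSIGNED = "assigned"
    AMBIGUOUS_DEFECATOR = "ambiguous_defecator"
    NO_CARNIVORE = "no_carnivore"
    FAILED_AMPLIFICATION = "failed_amplification"
    EXCLUDED_NO_DIET = "excluded_no_diet"


@dataclass(frozen=True)
class TaxonRecord:
    """One row of the taxonomy table.

    Finer ranks may be empty for items identified above species level
    (e.g. a genus-level item such as "Tamias sp." has an empty
    ``species_name``).
    """

    taxon_id: str
    class_name: str
    order_name: str
    family_name: str
    genus_name: str
    species_name: str
    candidate_defecator: bool

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id must be nonempty")
        if not self.class_name:
            raise ValueError(f"taxon {self.taxon_id!r}: class_name must be nonempty")
        if self.candidate_defecator and self.order_name != "Carnivora":
            raise ValueError(
                f"taxon {self.taxon_id!r} is flagged candidate_defecator but its "
                f"order is {self.order_name!r}, not 'Carnivora'"
            )

    def rank_label(self, rank: str) -> str:
        """Label at ``rank``, rolling empty labels up to the nearest nonempty ancestor."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        ladder = (
            ("species", self.species_name),
            ("genus", self.genus_name),
            ("family", self.family_name),
            ("order", self.order_name),
            ("class", self.class_name),
        )
        start = [r for r, _ in ladder].index(rank)
        for _, label in ladder[start:]:
            if label:
                return label
        return self.taxon_id  # class_name is guaranteed nonempty; unreachable


class Taxonomy:
    """Validated collection of :class:`TaxonRecord` keyed by ``taxon_id``."""

    def __init__(self, records: Sequence[TaxonRecord]):
        self._records: dict[str, TaxonRecord] = {}
        for rec in records:
            if rec.taxon_id in self._records:
                raise ValueError(f"duplicate taxon_id {rec.taxon_id!r} in taxonomy table")
            self._records[rec.taxon_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __getitem__(self, taxon_id: str) -> TaxonRecord:
        try:
            return self._records[taxon_id]
        except KeyError:
            raise KeyError(f"taxon {taxon_id!r} not found in taxonomy table") from None

    def is_carnivore(self, taxon_id: str) -> bool:
        return self[taxon_id].candidate_defecator

    @property
    def carnivores(self) -> list[str]:
        return [t.taxon_id for t in self if t.candidate_defecator]


@dataclass
class ReadCountTable:
    """Long-format per-scat, per-replicate, per-taxon read counts.

    Backed by a pandas DataFrame with columns scat_id, replicate, taxon_id,
    reads; one row per (scat, replicate, taxon) key.
    """

    frame: pd.DataFrame
    n_replicates: int = 3

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(COUNT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"read-count table missing columns: {sorted(missing)}")
        df = df.loc[:, list(COUNT_COLUMNS)].copy()
        if len(df):
            if not (df["reads"] >= 0).all():
                bad = df.loc[df["reads"] < 0].iloc[0]
                raise ValueError(
                    f"negative read count for scat {bad['scat_id']!r} taxon {bad['taxon_id']!r}"
                )
            dup = df.duplicated(subset=["scat_id", "replicate", "taxon_id"])
            if dup.any():
                bad = df.loc[dup].iloc[0]
                raise ValueError(
                    "duplicate (scat_id, replicate, taxon_id) key: "
                    f"({bad['scat_id']!r}, {bad['replicate']!r}, {bad['taxon_id']!r})"
                )
        df["replicate"] = df["replicate"].astype(int)
        df["reads"] = df["reads"].astype(int)
        self.frame = df.reset_index(drop=True)

    @property
    def scat_ids(self) -> list[str]:
        return sorted(self.frame["scat_id"].unique())

    def scat(self, scat_id: str) -> pd.DataFrame:
        return self.frame.loc[self.frame["scat_id"] == scat_id]

    def replicate_counts(self, scat_id: str) -> dict[int, dict[str, int]]:
        """Per-replicate taxon→reads mappings for one scat (zero rows dropped)."""
        out: dict[int, dict[str, int]] = {}
        for _, row in self.scat(scat_id).iterrows():
            if row["reads"] > 0:
                out.setdefault(int(row["replicate"]), {})[row["taxon_id"]] = int(row["reads"])
        return out


@dataclass
class FilterConfig:
    """All thresholds of the analysis, in one flat record.

    ``min_reads_per_replicate`` is a strict lower bound (a replicate is valid
    iff its total reads exceed it); ``min_rra`` and ``exploration_rra`` are
    inclusive lower bounds on relative read abundance.
    """

    min_reads_per_replicate: int = 1000
    min_rra: float = 0.01
    exploration_rra: float = 0.005
    min_replicates: int = 2
    max_other_carnivore_share: float = 0.10
    min_item_share: float = 0.01
    null_iterations: int = 10000
    bootstrap_iterations: int = 10000
    seed: int = 0
    # interpretation switches (documented defaults; see module docs)
    rra_scope: str = "replicate"  # or "pooled"
    other_carnivore_scope: str = "combined"  # or "each"
    carnivores_as_prey: bool = False
    wpoo_weighting: str = "uniform"  # or "read_share"

    def __post_init__(self) -> None:
        if not (0 < self.exploration_rra <= self.min_rra < 1):
            raise ValueError(
                "need 0 < exploration_rra <= min_rra < 1, got "
                f"exploration_rra={self.exploration_rra}, min_rra={self.min_rra}"
            )
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        for name in ("max_other_carnivore_share", "min_item_share"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.rra_scope not in ("replicate", "pooled"):
            raise ValueError(f"rra_scope must be 'replicate' or 'pooled', got {self.rra_scope!r}")
        if self.other_carnivore_scope not in ("combined", "each"):
            raise ValueError("other_carnivore_scope must be 'combined' or 'each'")
        if self.wpoo_weighting not in ("uniform", "read_share"):
            raise ValueError("wpoo_weighting must be 'uniform' or 'read_share'")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "FilterConfig":
        """Load from a flat key-value (YAML) file; keys are the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DietItem:
    combined_reads: int
    share: float


@dataclass
class ScatComposition:
    """One scat's assigned defecator, status and retained diet items."""

    scat_id: str
    status: ScatStatus
    defecator: str | None = None
    diet_items: dict[str, DietItem] = field(default_factory=dict)
    exploration_items: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        has_defecator = self.status in (ScatStatus.ASSIGNED, ScatStatus.EXCLUDED_NO_DIET)
        if has_defecator and self.defecator is None:
            raise ValueError(f"scat {self.scat_id!r}: status {self.status.value} requires a defecator")
        if not has_defecator and self.defecator is not None:
            raise ValueError(f"scat {self.scat_id!r}: status {self.status.value} forbids a defecator")
        if self.defecator is not None and self.defecator in self.diet_items:
            raise ValueError(f"scat {self.scat_id!r}: defecator cannot appear in diet_items")

    @property
    def diet_taxa(self) -> frozenset[str]:
        return frozenset(self.diet_items)


@dataclass
class DietProfile:
    """Per-species frequency of occurrence and weighted percent of occurrence."""

    species_label: str
    n_scats: int
    foo: dict[str, float]
    wpoo: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.foo) != set(self.wpoo):
            raise ValueError("foo and wpoo must share the same support")
        if self.n_scats >= 1 and self.wpoo:
            total = sum(self.wpoo.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"wPOO must sum to 1, got {total!r}")

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.foo)


@dataclass
class OverlapResult:
    metric: str  # "foo" or "wpoo"
    o_observed: float
    observed_ci: tuple[float, float]
    null_mean: float
    null_ci: tuple[float, float]
    p_value: float
    n_iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "o_observed": self.o_observed,
            "observed_ci": list(self.observed_ci),
            "null_mean": self.null_mean,
            "null_ci": list(self.null_ci),
            "p_value": self.p_value,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "OverlapResult":
        return cls(
            metric=d["metric"],
            o_observed=d["o_observed"],
            observed_ci=tuple(d["observed_ci"]),
            null_mean=d["null_mean"],
            null_ci=tuple(d["null_ci"]),
            p_value=d["p_value"],
            n_iterations=d["n_iterations"],
            seed=d["seed"],
        )


@dataclass
class IncidenceFrequencies:
    """Sample-based incidence counts: T units, Y_i scats containing taxon i."""

    T: int
    Y: dict[str, int]

    def __post_init__(self) -> None:
        for taxon, y in self.Y.items():
            if not (1 <= y <= self.T):
                raise ValueError(f"incidence of {taxon!r} is {y}, outside 1..{self.T}")

    @property
    def s_obs(self) -> int:
        return len(self.Y)

    @property
    def q1(self) -> int:
        return sum(1 for y in self.Y.values() if y == 1)

    @property
    def q2(self) -> int:
        return sum(1 for y in self.Y.values() if y == 2)


@dataclass
class RarefactionCurve:
    T: int
    t_grid: list[int]
    s_hat: list[float]
    ci: list[tuple[float, float]]
    chao2: float
    q0_hat: float

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "t_grid": self.t_grid,
            "s_hat": self.s_hat,
            "ci": [list(pair) for pair in self.ci],
            "chao2": self.chao2,
            "q0_hat": self.q0_hat,
        }


# ---------------------------------------------------------------------------
# readers


def _sniff_delimiter(header_line: str, path) -> str:
    has_comma = "," in header_line
    has_tab = "\t" in header_line
    if has_comma and has_tab:
        raise ValueError(f"{path}: header mixes comma and tab delimiters")
    if has_tab:
        return "\t"
    if has_comma:
        return ","
    raise ValueError(f"{path}: could not detect delimiter (expected comma or tab)")


def _read_delimited(path: str | os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    sep = _sniff_delimiter(header, path)
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"{context}: cannot interpret {value!r} as a boolean")


def read_taxonomy_table(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
) -> Taxonomy:
    """Read a taxonomy CSV/TSV into a validated :class:`Taxonomy`.

    ``column_map`` maps the canonical column names to the names actually used
    in the file (deposited tables may differ).
    """
    df = _read_delimited(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = set(TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: taxonomy table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            TaxonRecord(
                taxon_id=row["taxon_id"],
                class_name=row["class_name"],
                order_name=row["order_name"],
                family_name=row["family_name"],
                genus_name=row["genus_name"],
                species_name=row["species_name"],
                candidate_defecator=_parse_bool(
                    row["candidate_defecator"], f"taxon {row['taxon_id']!r}"
                ),
            )
        )
    return Taxonomy(records)


def write_taxonomy_table(taxonomy: Taxonomy, path: str | os.PathLike) -> None:
    rows = [
        {
            "taxon_id": t.taxon_id,
            "class_name": t.class_name,
            "order_name": t.order_name,
            "family_name": t.family_name,
            "genus_name": t.genus_name,
            "species_name": t.species_name,
            "candidate_defecator": str(t.candidate_defecator).lower(),
        }
        for t in taxonomy
    ]
    pd.DataFrame(rows, columns=list(TAXONOMY_COLUMNS)).to_csv(path, index=False)


def read_read_count_table(
    path: str | os.PathLike,
    taxonomy: Taxonomy,
    column_map: Mapping[str, str] | None = None,
    n_replicates: int = 3,
) -> ReadCountTable:
    """Read a long-format count CSV/TSV, validating against ``taxonomy``.

    Zero-read rows are legal (dense exporters emit them) and dropped with a
    logged count; any other anomaly is a hard error.
    """
    df = _read_delimited(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: read-count table missing columns {sorted(missing)}")
    df = df.loc[:, list(COUNT_COLUMNS)].copy()

    unknown = set(df["taxon_id"]) - {t.taxon_id for t in taxonomy}
    if unknown:
        raise ValueError(f"{path}: taxa absent from taxonomy table: {sorted(unknown)}")

    for col in ("replicate", "reads"):
        try:
            as_float = df[col].astype(float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc
        as_int = as_float.astype(int)
        if not (as_float == as_int).all():
            bad = df.loc[as_float != as_int].iloc[0]
            raise ValueError(f"{path}: non-integer {col} for scat {bad['scat_id']!r}")
        df[col] = as_int
    if (df["reads"] < 0).any():
        bad = df.loc[df["reads"] < 0].iloc[0]
        raise ValueError(f"{path}: negative reads for scat {bad['scat_id']!r}")

    n_zero = int((df["reads"] == 0).sum())
    if n_zero:
        logger.info("dropped %d zero-read rows from %s", n_zero, path)
        df = df.loc[df["reads"] > 0]

    return ReadCountTable(frame=df.reset_index(drop=True), n_replicates=n_replicates)


def write_read_count_table(table: ReadCountTable, path: str | os.PathLike) -> None:
    table.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result writers


def _fmt(x: float) -> float:
    """Round reals for serialization to 12 significant digits."""
    if isinstance(x, int):
        return x
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.12g}")


def write_results(
    compositions: Sequence[ScatComposition],
    profiles: Sequence[DietProfile],
    overlaps: Sequence[OverlapResult],
    curves: Mapping[str, RarefactionCurve],
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write the result bundle; returns a manifest of logical name → path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    status_rows = []
    for comp in sorted(compositions, key=lambda c: c.scat_id):
        if comp.diet_items:
            for taxon in sorted(comp.diet_items):
                item = comp.diet_items[taxon]
                status_rows.append(
                    {
                        "scat_id": comp.scat_id,
                        "status": comp.status.value,
                        "defecator": comp.defecator or "",
                        "item": taxon,
                        "combined_reads": item.combined_reads,
                        "share": _fmt(item.share),
                    }
                )
        else:
            status_rows.append(
                {
                    "scat_id": comp.scat_id,
                    "status": comp.status.value,
                    "defecator": comp.defecator or "",
                    "item": "",
                    "combined_reads": "",
                    "share": "",
                }
            )
    status_path = out / "scat_statuses.csv"
    pd.DataFrame(
        status_rows,
        columns=["scat_id", "status", "defecator", "item", "combined_reads", "share"],
    ).to_csv(status_path, index=False)
    written["scat_statuses"] = str(status_path)

    for profile in profiles:
        rows = [
            {
                "taxon": taxon,
                "foo": _fmt(profile.foo[taxon]),
                "wpoo": _fmt(profile.wpoo[taxon]),
            }
            for taxon in sorted(profile.support)
        ]
        label = profile.species_label.replace(" ", "_").replace("/", "_")
        p = out / f"diet_profile_{label}.csv"
        pd.DataFrame(rows, columns=["taxon", "foo", "wpoo"]).to_csv(p, index=False)
        written[f"diet_profile:{profile.species_label}"] = str(p)

    structured = {
        "overlaps": [
            {k: (_fmt(v) if isinstance(v, float) else v) for k, v in o.to_dict().items()}
            for o in overlaps
        ],
        "rarefaction": {
            label: {
                "T": c.T,
                "t_grid": c.t_grid,
                "s_hat": [_fmt(v) for v in c.s_hat],
                "ci": [[_fmt(lo), _fmt(hi)] for lo, hi in c.ci],
                "chao2": _fmt(c.chao2),
                "q0_hat": _fmt(c.q0_hat),
            }
            for label, c in sorted(curves.items())
        },
    }
    # normalize tuple CIs for json
    for o in structured["overlaps"]:
        o["observed_ci"] = [_fmt(v) for v in o["observed_ci"]]
        o["null_ci"] = [_fmt(v) for v in o["null_ci"]]
    json_path = out / "analysis_results.json"
    with open(json_path, "w") as fh:
        json.dump(structured, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["analysis_results"] = str(json_path)
    return written


def read_results_json(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
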