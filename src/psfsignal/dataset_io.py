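"""Read, validate and assemble pairwise feedback compilations.

A compilation is a flat table with one row per replicate feedback: the two
species and their families, the four biomass means with standard errors, the
phylogenetic distance between the pair (in Myr), a whole-soil-community flag
and assorted study metadata (ecosystem, origin, glasshouse/field, functional
groups) that is carried through but not modelled.

Column names vary across deposits, so reading goes through a column-mapping
dialect (a plain dict, loadable from YAML) whose defaults match the schema
written by this package's own simulator and exporter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .feedback_core import (
    DissimilarityObservation,
    FeedbackExperiment,
    InvalidExperimentError,
    compute_r,
    compute_r_variance,
    orient_pair,
)

__all__ = [
    "DEFAULT_DIALECT",
    "CompilationTable",
    "SpeciesPair",
    "SchemaError",
    "PairConsistencyError",
    "load_dialect",
    "read_compilation",
    "filter_whole_soil",
    "assemble_pairs",
    "pairs_to_frame",
    "write_pairs",
    "read_pairs",
]

logger = logging.getLogger(__name__)

#: Default column mapping for compilation CSVs (the simulator emits this
#: schema). Keys are internal names, values are file column headers.
DEFAULT_DIALECT: dict[str, str] = {
    "species_a": "species_a",
    "species_b": "species_b",
    "family_a": "family_a",
    "family_b": "family_b",
    "A_a": "biomass_Aa",
    "A_b": "biomass_Ab",
    "B_a": "biomass_Ba",
    "B_b": "biomass_Bb",
    "se_A_a": "se_Aa",
    "se_A_b": "se_Ab",
    "se_B_a": "se_Ba",
    "se_B_b": "se_Bb",
    "phylo_distance_myr": "phylo_distance_myr",
    "whole_soil": "whole_soil",
    "soil_fraction": "soil_fraction",
    "treatment": "treatment",
    "study_id": "study_id",
    "glasshouse": "glasshouse",
    "ecosystem": "ecosystem",
    "origin": "origin",
    "functional_group_a": "functional_group_a",
    "functional_group_b": "functional_group_b",
}

REQUIRED_COLUMNS = (
    "species_a",
    "species_b",
    "A_a",
    "A_b",
    "B_a",
    "B_b",
    "phylo_distance_myr",
    "whole_soil",
)

OPTIONAL_METADATA = (
    "family_a",
    "family_b",
    "treatment",
    "study_id",
    "soil_fraction",
    "glasshouse",
    "ecosystem",
    "origin",
    "functional_group_a",
    "functional_group_b",
)

_TRUTHY = {"true", "t", "yes", "y", "1", "whole", "whole_soil", "whole soil"}
_FALSY = {"false", "f", "no", "n", "0", "fraction", "partial"}


class SchemaError(ValueError):
    """The input file lacks a required column under the given dialect."""


class PairConsistencyError(ValueError):
    """Rows for one species pair disagree (e.g. on phylogenetic distance)."""


@dataclass
class CompilationTable:
    """Validated compilation rows plus a report of rows that failed validation.

    ``data`` uses internal column names (keys of the dialect). ``errors``
    collects (row index, message) for malformed rows, which are excluded from
    ``data`` but never silently dropped.
    """

    data: pd.DataFrame
    errors: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    def experiments(self) -> Iterable[tuple[int, FeedbackExperiment]]:
        """Yield (row label, FeedbackExperiment) for every validated row."""
        for idx, row in self.data.iterrows():
            yield idx, _row_to_experiment(row)


def load_dialect(path: str | Path | None = None) -> dict[str, str]:
    """Load a column-mapping dialect from YAML; fall back to the default.

    The YAML file maps internal names to file headers; unspecified keys keep
    their defaults so a dialect file only needs to list what differs.
    """
    dialect = dict(DEFAULT_DIALECT)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            override = yaml.safe_load(fh) or {}
        unknown = set(override) - set(DEFAULT_DIALECT)
        if unknown:
            raise SchemaError(f"unknown dialect keys: {sorted(unknown)}")
        dialect.update({k: str(v) for k, v in override.items()})
    return dialect


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)) and not isinstance(
        value, bool
    ):
        if value in (0, 1):
            return bool(value)
        raise ValueError(f"cannot interpret {value!r} as a boolean flag")
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def read_compilation(
    path: str | Path,
    dialect: Mapping[str, str] | str | Path | None = None,
    delimiter: str = ",",
) -> CompilationTable:
    """Read a compilation CSV/TSV into a validated :class:`CompilationTable`.

    Rows with non-positive or non-numeric biomasses, negative standard
    errors, missing distances or unparseable whole-soil flags are reported in
    ``CompilationTable.errors`` and excluded from the data; a missing
    required column raises :class:`SchemaError` immediately.
    """
    if dialect is None or isinstance(dialect, (str, Path)):
        dialect = load_dialect(dialect)
    raw = pd.read_csv(path, sep=delimiter, comment="#", float_precision="round_trip")

    missing = [dialect[k] for k in REQUIRED_COLUMNS if dialect[k] not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns in {path}: {missing}")

    inverse = {v: k for k, v in dialect.items() if v in raw.columns}
    table = raw[list(inverse)].rename(columns=inverse)

    errors: list[tuple[int, str]] = []
    keep = np.ones(len(table), dtype=bool)

    numeric_cols = ["A_a", "A_b", "B_a", "B_b", "phylo_distance_myr"]
    se_cols = [c for c in ("se_A_a", "se_A_b", "se_B_a", "se_B_b") if c in table]
    for col in numeric_cols + se_cols:
        parsed = pd.to_numeric(table[col], errors="coerce")
        bad = parsed.isna()
        if col in ("A_a", "A_b", "B_a", "B_b"):
            bad |= parsed <= 0
            reason = "must be a strictly positive number"
        elif col == "phylo_distance_myr":
            bad |= parsed < 0
            reason = "must be a non-negative number"
        else:
            bad |= parsed < 0
            reason = "must be a non-negative number"
        for idx in table.index[bad & keep]:
            errors.append((idx, f"{col}={table.at[idx, col]!r} {reason}"))
        keep &= ~bad.to_numpy()
        table[col] = parsed

    whole = []
    for idx, value in table["whole_soil"].items():
        try:
            whole.append(_parse_bool(value))
        except ValueError as exc:
            whole.append(False)
            if keep[table.index.get_loc(idx)]:
                errors.append((idx, str(exc)))
                keep[table.index.get_loc(idx)] = False
    table["whole_soil"] = whole

    for col in ("se_A_a", "se_A_b", "se_B_a", "se_B_b"):
        if col not in table:
            table[col] = 0.0
    if "soil_fraction" not in table:
        table["soil_fraction"] = 1.0
    if "treatment" not in table:
        table["treatment"] = ""

    clean = table[keep].copy()
    if errors:
        logger.warning("read_compilation: %d row(s) failed validation", len(errors))
    return CompilationTable(data=clean, errors=errors)


def _row_to_experiment(row: pd.Series) -> FeedbackExperiment:
    return FeedbackExperiment(
        species_a_id=str(row["species_a"]),
        species_b_id=str(row["species_b"]),
        A_a=float(row["A_a"]),
        A_b=float(row["A_b"]),
        B_a=float(row["B_a"]),
        B_b=float(row["B_b"]),
        se_A_a=float(row.get("se_A_a", 0.0)),
        se_A_b=float(row.get("se_A_b", 0.0)),
        se_B_a=float(row.get("se_B_a", 0.0)),
        se_B_b=float(row.get("se_B_b", 0.0)),
        treatment_label=str(row.get("treatment", "")),
        soil_fraction=float(row.get("soil_fraction", 1.0)),
        whole_soil=bool(row["whole_soil"]),
    )


def filter_whole_soil(table: CompilationTable) -> CompilationTable:
    """Keep only feedbacks measured with whole soil communities.

    Feedbacks generated by a fraction of the soil biota (e.g. a mycorrhizal
    inoculum alone) are excluded because they measure a different quantity
    from whole-community feedbacks.
    """
    mask = table.data["whole_soil"].astype(bool)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("filter_whole_soil: dropped %d fractional-soil row(s)", dropped)
    return CompilationTable(data=table.data[mask].copy(), errors=list(table.errors))


@dataclass
class SpeciesPair:
    """A unique unordered species pair with its replicate observations.

    ``t_myr`` is the phylogenetic distance (divergence time) in Myr; models
    use it in units of 100 Myr. ``family_pair_id`` is the unordered family
    pair label (sorted, joined by ``|``), shared by all species pairs drawn
    from the same two plant families.
    """

    pair_id: str
    species_a_id: str
    species_b_id: str
    family_a: str
    family_b: str
    t_myr: float
    observations: list[DissimilarityObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_myr) and self.t_myr >= 0):
            raise ValueError(f"t_myr={self.t_myr!r} must be finite and non-negative")

    @property
    def family_pair_id(self) -> str:
        return "|".join(sorted((self.family_a, self.family_b)))

    @property
    def n_replicates(self) -> int:
        return len(self.observations)

    @property
    def r_values(self) -> np.ndarray:
        return np.array([obs.r for obs in self.observations])

    @property
    def var_r_values(self) -> np.ndarray:
        return np.array([obs.var_r for obs in self.observations])


def assemble_pairs(
    table: CompilationTable, distance_tolerance_myr: float = 1.0
) -> list[SpeciesPair]:
    """Group replicate feedbacks into unique unordered species pairs.

    Each row is canonically oriented (sorted species labels) before grouping,
    so row order and species labelling cannot change the result. Replicates
    of a pair are pseudoreplicates: they keep their own measurement variances
    and are attached to a single pair-level unit. Rows of one pair whose
    phylogenetic distances differ by more than ``distance_tolerance_myr``
    raise :class:`PairConsistencyError`.
    """
    groups: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for idx, row in table.data.iterrows():
        exp = orient_pair(_row_to_experiment(row))
        key = (exp.species_a_id, exp.species_b_id)
        fam_a = str(row.get("family_a", ""))
        fam_b = str(row.get("family_b", ""))
        if str(row["species_a"]) != exp.species_a_id:
            fam_a, fam_b = fam_b, fam_a
        entry = groups.get(key)
        if entry is None:
            entry = {
                "family_a": fam_a,
                "family_b": fam_b,
                "t": [],
                "rows": [],
            }
            groups[key] = entry
            order.append(key)
        entry["t"].append(float(row["phylo_distance_myr"]))
        entry["rows"].append(exp)

    pairs: list[SpeciesPair] = []
    for key in sorted(order):
        entry = groups[key]
        t_values = np.array(entry["t"])
        if t_values.max() - t_values.min() > distance_tolerance_myr:
            raise PairConsistencyError(
                f"pair {key} has inconsistent phylogenetic distances: "
                f"{t_values.min():g}..{t_values.max():g} Myr"
            )
        pair_id = f"{key[0]}__{key[1]}"
        observations = [
            DissimilarityObservation(
                r=compute_r(exp),
                var_r=compute_r_variance(exp),
                pair_id=pair_id,
                replicate_index=i + 1,
            )
            for i, exp in enumerate(entry["rows"])
        ]
        pairs.append(
            SpeciesPair(
                pair_id=pair_id,
                species_a_id=key[0],
                species_b_id=key[1],
                family_a=entry["family_a"],
                family_b=entry["family_b"],
                t_myr=float(t_values.mean()),
                observations=observations,
            )
        )
    return pairs


def pairs_to_frame(pairs: Sequence[SpeciesPair]) -> pd.DataFrame:
    """Tidy one-row-per-observation view of assembled pairs."""
    records = []
    for pair in pairs:
        for obs in pair.observations:
            records.append(
                {
                    "pair_id": pair.pair_id,
                    "species_a": pair.species_a_id,
                    "species_b": pair.species_b_id,
                    "family_a": pair.family_a,
                    "family_b": pair.family_b,
                    "family_pair_id": pair.family_pair_id,
                    "t_myr": pair.t_myr,
                    "replicate_index": obs.replicate_index,
                    "r": obs.r,
                    "var_r": obs.var_r,
                }
            )
    return pd.DataFrame.from_records(records)


def write_pairs(pairs: Sequence[SpeciesPair], path: str | Path) -> None:
    """Write assembled pairs to a tidy CSV (full float precision)."""
    frame = pairs_to_frame(pairs)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_pairs(path: str | Path) -> list[SpeciesPair]:
    """Read a CSV written by :func:`write_pairs` back into SpeciesPair objects."""
    frame = pd.read_csv(path, float_precision="round_trip")
    pairs = []
    for pair_id, group in frame.groupby("pair_id", sort=True):
        first = group.iloc[0]
        observations = [
            DissimilarityObservation(
                r=float(row["r"]),
                var_r=float(row["var_r"]),
                pair_id=str(pair_id),
                replicate_index=int(row["replicate_index"]),
            )
            for _, row in group.iterrows()
        ]
        pairs.append(
            SpeciesPair(
                pair_id=str(pair_id),
                species_a_id=str(first["species_a"]),
                species_b_id=str(first["species_b"]),
                family_a=str(first["family_a"]),
                family_b=str(first["family_b"]),
                t_myr=float(first["t_myr"]),
                observations=observations,
            )
        )
    return pairs


def summarize_pairs(pairs: Sequence[SpeciesPair]) -> dict[str, int]:
    """Counts of feedbacks, unique pairs, species and families."""
    species = set()
    families = set()
    n_obs = 0
    for pair in pairs:
        species.update((pair.species_a_id, pair.species_b_id))
        families.update((pair.family_a, pair.family_b))
        n_obs += pair.n_replicates
    families.discard("")
    return {
        "n_feedbacks": n_obs,
        "n_pairs": len(pairs),
        "n_species": len(species),
        "n_families": len(families),
    }
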