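"""Trap-survey data: reading, validation, filtering and aggregation.

The raw material of the whole pipeline is a capture-level trap survey on
one or more mountains: one row per captured animal (species, mountain,
trapping location, elevation, trap class, recapture flag, capture day),
a per-location table of trapping effort (trap nights), and species
metadata carrying the Borneo-endemic classification.  This module turns
those tables into the site-by-species matrices every downstream
diversity statistic consumes, and computes the survey-level summaries
(trap success per 100 trap nights, species accumulation curves, and
camera-trap relative abundance).

Tables are plain :class:`pandas.DataFrame` objects with documented
column schemas (see :data:`RECORD_COLUMNS`, :data:`EFFORT_COLUMNS`,
:data:`META_COLUMNS`); a :class:`SurveyDataset` bundles the three with a
provenance log that grows as filters are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    EmptyDatasetError,
    SchemaError,
    UnsupportedInputError,
    ValidationError,
)

#: Trap classes recognised in the ``trap_class`` column.  "ground" means
#: set below ~3 m off the ground (including traps on low branches);
#: everything higher is "arboreal"; "pitfall" is a buried pit trap.
TRAP_CLASSES = ("ground", "arboreal", "pitfall")

#: Endemism classifications.  "unknown" is used for animals not
#: identified to species level (e.g. shrews recorded as "Suncus sp.");
#: such species are excluded from endemism numerators *and* denominators.
ENDEMIC_LEVELS = ("endemic", "non_endemic", "unknown")

#: Mandatory columns of the capture-record table.
RECORD_COLUMNS = ("species", "mountain", "location", "elevation", "trap_class")
#: Optional record columns filled with defaults when absent.
RECORD_OPTIONAL = ("record_id", "recapture", "capture_day")
#: Columns of the trapping-effort table (one row per mountain/location/class).
EFFORT_COLUMNS = ("mountain", "location", "trap_class", "trap_nights")
#: Columns of the species-metadata table.
META_COLUMNS = ("species", "endemic")


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Published survey tables round 5s up (10.35 -> 10.4), which differs
    from Python's banker's rounding; reproducing printed percentages
    therefore needs an explicit half-up rule.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SurveyDataset:
    """A validated trap survey: capture records, effort, species metadata.

    Attributes
    ----------
    records : pandas.DataFrame
        One row per capture; columns :data:`RECORD_COLUMNS` plus
        ``record_id``, ``recapture`` (bool) and ``capture_day``
        (nullable integer day index, 1-based).
    efforts : pandas.DataFrame
        One row per (mountain, location, trap_class); column
        ``trap_nights`` is the number of trap-nights (one trap
        operational for one night).
    meta : pandas.DataFrame
        One row per species with its endemism classification.
    provenance : list of str
        Free-text history of filters applied; grows monotonically.
    """

    records: pd.DataFrame
    efforts: pd.DataFrame
    meta: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def validate(self) -> "SurveyDataset":
        """Check schemas and invariants, raising on the first violation."""
        for col in RECORD_COLUMNS:
            if col not in self.records.columns:
                raise SchemaError(f"records table is missing mandatory column {col!r}")
        for col in EFFORT_COLUMNS:
            if col not in self.efforts.columns:
                raise SchemaError(f"efforts table is missing mandatory column {col!r}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise SchemaError(f"meta table is missing mandatory column {col!r}")
        r = self.records
        if len(r):
            if (pd.to_numeric(r["elevation"], errors="coerce") <= 0).any() or r[
                "elevation"
            ].isna().any():
                bad = r.loc[
                    pd.to_numeric(r["elevation"], errors="coerce").fillna(-1) <= 0
                ]
                raise ValidationError(
                    f"{len(bad)} record(s) with non-positive or missing elevation"
                )
            unknown_cls = set(r["trap_class"]) - set(TRAP_CLASSES)
            if unknown_cls:
                raise ValidationError(f"unknown trap_class values: {sorted(unknown_cls)}")
            if (r["species"].astype(str).str.strip() == "").any():
                raise ValidationError("empty species label in records")
        if len(self.efforts):
            if (self.efforts["trap_nights"] < 0).any():
                raise ValidationError("negative trap_nights in efforts table")
            key = self.efforts[["mountain", "location", "trap_class"]]
            if key.duplicated().any():
                raise ValidationError(
                    "duplicate (mountain, location, trap_class) rows in efforts"
                )
        bad_levels = set(self.meta["endemic"]) - set(ENDEMIC_LEVELS)
        if bad_levels:
            raise ValidationError(f"unknown endemic levels: {sorted(bad_levels)}")
        missing = set(self.records["species"]) - set(self.meta["species"])
        if missing:
            raise ValidationError(
                f"species without metadata entry: {sorted(missing)}"
            )
        return self

    @property
    def n_records(self) -> int:
        return len(self.records)

    def species_list(self) -> list[str]:
        return sorted(self.records["species"].unique())

    def mountains(self) -> list[str]:
        return sorted(self.records["mountain"].unique())


def _normalise_records(records: pd.DataFrame) -> pd.DataFrame:
    r = records.copy()
    if "record_id" not in r.columns:
        r["record_id"] = [f"r{i:05d}" for i in range(len(r))]
    if "recapture" not in r.columns:
        r["recapture"] = False
    r["recapture"] = r["recapture"].astype(bool)
    if "capture_day" not in r.columns:
        r["capture_day"] = pd.array([pd.NA] * len(r), dtype="Int64")
    else:
        r["capture_day"] = pd.array(r["capture_day"], dtype="Int64")
    r["elevation"] = pd.to_numeric(r["elevation"])
    r["location"] = r["location"].astype(str)
    return r


def read_survey(
    records_path: str | Path,
    efforts_path: str | Path | None = None,
    meta_path: str | Path | None = None,
    sep: str = ",",
) -> SurveyDataset:
    """Read a survey from delimited text files into a validated dataset.

    Parameters
    ----------
    records_path
        CSV/TSV of capture records.  Mandatory columns: ``species``,
        ``mountain``, ``location``, ``elevation``, ``trap_class``.
        Optional: ``record_id``, ``recapture``, ``capture_day``.
    efforts_path
        CSV/TSV of trap-night totals per (mountain, location,
        trap_class).  When omitted an empty effort table is attached
        (operations that need effort will then refuse to run).
    meta_path
        CSV/TSV of species metadata (``species``, ``endemic``).  Species
        appearing in the records but absent here are added with endemic
        status ``unknown`` and a warning.
    sep
        Field delimiter shared by all files.
    """
    records_path = Path(records_path)
    if not records_path.exists():
        raise FileNotFoundError(records_path)
    records = pd.read_csv(records_path, sep=sep)
    for col in RECORD_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"records file is missing mandatory column {col!r}")
    records = _normalise_records(records)

    if efforts_path is not None:
        efforts = pd.read_csv(efforts_path, sep=sep)
        for col in EFFORT_COLUMNS:
            if col not in efforts.columns:
                raise SchemaError(f"efforts file is missing mandatory column {col!r}")
        efforts["location"] = efforts["location"].astype(str)
    else:
        efforts = pd.DataFrame(columns=list(EFFORT_COLUMNS))

    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep=sep)
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise SchemaError(f"meta file is missing mandatory column {col!r}")
    else:
        meta = pd.DataFrame(columns=list(META_COLUMNS))
    missing = sorted(set(records["species"]) - set(meta["species"]))
    if missing:
        warnings.warn(
            f"{len(missing)} species without metadata; endemic status set to "
            f"'unknown': {missing}",
            stacklevel=2,
        )
        meta = pd.concat(
            [meta, pd.DataFrame({"species": missing, "endemic": "unknown"})],
            ignore_index=True,
        )

    ds = SurveyDataset(
        records=records,
        efforts=efforts,
        meta=meta.reset_index(drop=True),
        provenance=[f"read_survey({records_path.name})"],
    )
    return ds.validate()


def filter_records(
    ds: SurveyDataset,
    include_arboreal: bool = False,
    include_pitfall: bool = False,
    include_recaptures: bool = False,
) -> SurveyDataset:
    """Restrict a survey to the analysis subset used throughout the study.

    The default call drops arboreal and pitfall captures together with
    their trapping effort (those trap classes were deployed too
    unevenly to support abundance comparisons) and drops recaptured
    individuals (counts are individuals, not capture events).  The
    resulting dataset records the filter in its provenance log.
    Filtering is idempotent and an empty result is legal.
    """
    keep = pd.Series(True, index=ds.records.index)
    keep_eff = pd.Series(True, index=ds.efforts.index)
    if not include_arboreal:
        keep &= ds.records["trap_class"] != "arboreal"
        keep_eff &= ds.efforts["trap_class"] != "arboreal"
    if not include_pitfall:
        keep &= ds.records["trap_class"] != "pitfall"
        keep_eff &= ds.efforts["trap_class"] != "pitfall"
    if not include_recaptures:
        keep &= ~ds.records["recapture"]
    out = replace(
        ds,
        records=ds.records.loc[keep].reset_index(drop=True),
        efforts=ds.efforts.loc[keep_eff].reset_index(drop=True),
        provenance=ds.provenance
        + [
            "filter_records(include_arboreal=%s, include_pitfall=%s, "
            "include_recaptures=%s)"
            % (include_arboreal, include_pitfall, include_recaptures)
        ],
    )
    return out


def _site_order(records: pd.DataFrame) -> pd.DataFrame:
    """Deterministic site table: mountain, location, nominal elevation.

    The nominal elevation of a trapping location is the median capture
    elevation of its records; sites are ordered by mountain, then
    nominal elevation ascending, then location label.
    """
    g = (
        records.groupby(["mountain", "location"], sort=False)["elevation"]
        .median()
        .rename("elevation")
        .reset_index()
    )
    return g.sort_values(
        ["mountain", "elevation", "location"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class AbundanceMatrix:
    """Sites-by-species capture counts.

    ``counts`` is a DataFrame whose row index is a (mountain, location)
    MultiIndex ordered by mountain then nominal elevation, and whose
    columns are species labels in lexicographic order.
    ``site_elevations`` carries the nominal (median capture) elevation
    of each site on the same index.
    """

    counts: pd.DataFrame
    site_elevations: pd.Series

    @property
    def sites(self) -> list[tuple[str, str]]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def for_mountain(self, mountain: str) -> "AbundanceMatrix":
        """Rows of one mountain, with species absent there dropped."""
        sub = self.counts.loc[[s for s in self.counts.index if s[0] == mountain]]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        return AbundanceMatrix(sub, self.site_elevations.loc[sub.index])

    def to_incidence(self) -> "IncidenceMatrix":
        return IncidenceMatrix(self.counts > 0, self.site_elevations.copy())


@dataclass
class IncidenceMatrix:
    """Sites-by-species presence/absence, same layout as AbundanceMatrix."""

    presence: pd.DataFrame
    site_elevations: pd.Series

    @property
    def sites(self) -> list[tuple[str, str]]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    def for_mountain(self, mountain: str) -> "IncidenceMatrix":
        sub = self.presence.loc[[s for s in self.presence.index if s[0] == mountain]]
        sub = sub.loc[:, sub.any(axis=0)]
        return IncidenceMatrix(sub, self.site_elevations.loc[sub.index])

    def richness(self) -> pd.Series:
        return self.presence.sum(axis=1)


def build_abundance_matrix(ds: SurveyDataset) -> AbundanceMatrix:
    """Cross-tabulate capture records into a sites-by-species count matrix.

    Row and column order is deterministic (mountain, then nominal site
    elevation, then location label; species lexicographic) so that all
    downstream outputs are reproducible.  Raises
    :class:`EmptyDatasetError` on a survey with no records.
    """
    if ds.n_records == 0:
        raise EmptyDatasetError("cannot build an abundance matrix from 0 records")
    site_tab = _site_order(ds.records)
    idx = pd.MultiIndex.from_frame(site_tab[["mountain", "location"]])
    counts = (
        ds.records.groupby(["mountain", "location", "species"])
        .size()
        .unstack(fill_value=0)
        .reindex(idx, fill_value=0)
    )
    counts = counts[sorted(counts.columns)]
    counts = counts.loc[:, counts.sum(axis=0) > 0]  # no all-zero species columns
    elevations = pd.Series(site_tab["elevation"].to_numpy(), index=idx, name="elevation")
    return AbundanceMatrix(counts.astype(int), elevations)


def trap_success(ds: SurveyDataset, group_by: str = "location") -> pd.DataFrame:
    """Captures per 100 trap nights, per trapping location or per mountain.

    Returns a table with columns ``n_captures``, ``trap_nights``,
    ``percent`` (half-up rounded to 1 decimal, as printed in survey
    reports) and ``percent_raw``.  Effort is summed over whatever trap
    classes remain in the dataset, so applying :func:`filter_records`
    first yields the "excluding arboreal and pitfall" figures.
    """
    if group_by == "location":
        keys = ["mountain", "location"]
    elif group_by == "mountain":
        keys = ["mountain"]
    else:
        raise ValueError("group_by must be 'location' or 'mountain'")
    caps = ds.records.groupby(keys).size().rename("n_captures")
    nights = ds.efforts.groupby(keys)["trap_nights"].sum().rename("trap_nights")
    tab = pd.concat([caps, nights], axis=1).fillna({"n_captures": 0})
    if tab["trap_nights"].isna().any():
        missing = tab.index[tab["trap_nights"].isna()].tolist()
        raise ConsistencyError(f"no trapping effort recorded for group(s) {missing}")
    tab["n_captures"] = tab["n_captures"].astype(int)
    tab["trap_nights"] = tab["trap_nights"].astype(int)
    if ((tab["trap_nights"] == 0) & (tab["n_captures"] > 0)).any():
        raise ConsistencyError("captures recorded in a group with zero trap nights")
    raw = np.where(
        tab["trap_nights"] > 0, 100.0 * tab["n_captures"] / tab["trap_nights"], 0.0
    )
    tab["percent_raw"] = raw
    tab["percent"] = [round_half_up(x, 1) for x in raw]
    return tab.reset_index()


def accumulation_curve(ds: SurveyDataset, site: tuple[str, str]) -> pd.DataFrame:
    """Species accumulation across survey effort at one trapping location.

    For each survey day ``d`` (1-based ``capture_day`` index) the curve
    reports the cumulative trap nights through day ``d`` and the number
    of species first captured on or before day ``d``.  Effort is spread
    evenly across the days spanned by the capture log, matching a
    survey in which all traps at the location are set on day 1 and run
    for the whole session.  Both coordinates are non-decreasing and the
    final richness equals the site's observed richness.
    """
    mountain, location = site
    rec = ds.records[
        (ds.records["mountain"] == mountain) & (ds.records["location"] == str(location))
    ]
    eff = ds.efforts[
        (ds.efforts["mountain"] == mountain)
        & (ds.efforts["location"] == str(location))
    ]
    total_nights = int(eff["trap_nights"].sum())
    if len(rec) == 0:
        return pd.DataFrame(
            {"day": [1], "cumulative_trap_nights": [float(total_nights)],
             "cumulative_richness": [0]}
        )
    if rec["capture_day"].isna().any():
        raise UnsupportedInputError(
            f"records at {site} lack capture_day; accumulation curve unavailable"
        )
    n_days = int(rec["capture_day"].max())
    first_day = rec.groupby("species")["capture_day"].min()
    days = np.arange(1, n_days + 1)
    richness = np.array([(first_day <= d).sum() for d in days])
    nights = total_nights * days / n_days
    return pd.DataFrame(
        {"day": days, "cumulative_trap_nights": nights, "cumulative_richness": richness}
    )


def camera_relative_abundance(series: pd.DataFrame) -> pd.DataFrame:
    """Camera-trap relative abundance per 100 camera nights.

    ``series`` has one row per (camera, species) with the number of
    independent visit series (``n_series``) and the camera's total
    operating nights (``camera_nights``).  The rate is
    ``100 * n_series / camera_nights`` rounded half-up to 2 decimals,
    the convention used in camera-survey tables.
    """
    for col in ("camera_id", "species", "n_series", "camera_nights"):
        if col not in series.columns:
            raise SchemaError(f"camera table is missing mandatory column {col!r}")
    if (series["camera_nights"] <= 0).any():
        raise ValidationError("camera_nights must be positive")
    if (series["n_series"] < 0).any():
        raise ValidationError("n_series must be non-negative")
    out = series.copy()
    raw = 100.0 * out["n_series"] / out["camera_nights"]
    out["rate_per_100_nights_raw"] = raw
    out["rate_per_100_nights"] = [round_half_up(x, 2) for x in raw]
    return out


def write_survey(ds: SurveyDataset, outdir: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write records/efforts/meta as delimited text in the read_survey schema."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "efforts": outdir / "efforts.csv",
        "meta": outdir / "meta.csv",
    }
    ds.records.to_csv(paths["records"], sep=sep, index=False)
    ds.efforts.to_csv(paths["efforts"], sep=sep, index=False)
    ds.meta.to_csv(paths["meta"], sep=sep, index=False)
    return paths
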