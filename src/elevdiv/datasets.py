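"""Packaged datasets and loaders for external survey data.

Two kinds of data live here:

* Small fixtures shipped with the package: the published per-location
  trap-success table and camera-trap table of the Kinabalu/Tambuyukon
  survey (printed summary numbers, used to validate the effort
  accounting), and a toy survey for examples and tests.
* A loader for the survey's deposited capture-level raw data
  (Zenodo record 3341178), which is *not* distributed with the package
  and must be downloaded separately.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .survey import SurveyDataset, _normalise_records, read_survey


def _data_path(name: str):
    return resources.files("elevdiv.data").joinpath(name)


def load_trap_success_table() -> pd.DataFrame:
    """The published per-location capture/effort table for both mountains.

    Columns: ``n_all``/``nights_all``/``pct_all`` include arboreal and
    pitfall trapping; ``n_ground``/``nights_ground``/``pct_ground``
    exclude them.  ``pct_*`` are the percentages as printed (1 decimal).
    """
    with resources.as_file(_data_path("trap_success_table.csv")) as p:
        return pd.read_csv(p)


def load_camera_table() -> pd.DataFrame:
    """The published camera-trap series counts with printed rates.

    ``denominator_ambiguous`` flags the one row whose printed rate is
    inconsistent with the camera-night denominator shown in the source
    table; it should not be used as ground truth.
    """
    with resources.as_file(_data_path("camera_table.csv")) as p:
        return pd.read_csv(p)


def trap_success_survey() -> SurveyDataset:
    """Reconstruct a capture-level survey from the published effort table.

    Species identities are not printed in the effort table, so every
    capture is entered as ``unidentified small mammal``; ground-trap
    captures and effort come from the "excluding" columns and the
    remainder is entered as arboreal.  The reconstruction is exact for
    trap-success accounting (captures and trap nights per location and
    per mountain) and is the substrate for reproducing every printed
    trap-success percentage through :func:`elevdiv.survey.trap_success`.
    """
    tab = load_trap_success_table()
    rows = []
    efforts = []
    for _, r in tab.iterrows():
        rows.extend(
            {
                "species": "unidentified small mammal",
                "mountain": r["mountain"],
                "location": str(r["location"]),
                "elevation": r["elevation"],
                "trap_class": "ground",
                "recapture": False,
            }
            for _ in range(int(r["n_ground"]))
        )
        rows.extend(
            {
                "species": "unidentified small mammal",
                "mountain": r["mountain"],
                "location": str(r["location"]),
                "elevation": r["elevation"],
                "trap_class": "arboreal",
                "recapture": False,
            }
            for _ in range(int(r["n_all"] - r["n_ground"]))
        )
        efforts.append(
            {
                "mountain": r["mountain"],
                "location": str(r["location"]),
                "trap_class": "ground",
                "trap_nights": int(r["nights_ground"]),
            }
        )
        extra = int(r["nights_all"] - r["nights_ground"])
        if extra:
            efforts.append(
                {
                    "mountain": r["mountain"],
                    "location": str(r["location"]),
                    "trap_class": "arboreal",
                    "trap_nights": extra,
                }
            )
    records = _normalise_records(pd.DataFrame(rows))
    meta = pd.DataFrame(
        {"species": ["unidentified small mammal"], "endemic": ["unknown"]}
    )
    ds = SurveyDataset(
        records=records,
        efforts=pd.DataFrame(efforts),
        meta=meta,
        provenance=["trap_success_survey()"],
    )
    return ds.validate()


def toy_survey() -> SurveyDataset:
    """An 8-record toy survey used in examples and round-trip tests."""
    with resources.as_file(_data_path("toy_records.csv")) as rp, resources.as_file(
        _data_path("toy_efforts.csv")
    ) as ep, resources.as_file(_data_path("toy_meta.csv")) as mp:
        return read_survey(rp, ep, mp)


def load_deposited_survey(root: str | Path = "data/deposited") -> SurveyDataset:
    """Load the deposited capture-level raw survey data, if present.

    The capture-level raw data of the Kinabalu/Tambuyukon survey is
    archived at DOI 10.5281/zenodo.3341178 and is not redistributed
    with this package.  To reproduce the published beta-diversity and
    species-count results, download it, export the capture records,
    effort totals and species endemism table as ``records.csv``,
    ``efforts.csv`` and ``meta.csv`` in the :func:`read_survey` schema,
    and place them under ``root``.
    """
    root = Path(root)
    records = root / "records.csv"
    if not records.exists():
        raise FileNotFoundError(
            f"deposited raw survey data not found under {root!s}; download the "
            "archived raw data (DOI 10.5281/zenodo.3341178) and export it as "
            "records.csv / efforts.csv / meta.csv in the read_survey schema"
        )
    efforts = root / "efforts.csv"
    meta = root / "meta.csv"
    return read_survey(
        records,
        efforts if efforts.exists() else None,
        meta if meta.exists() else None,
    )
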