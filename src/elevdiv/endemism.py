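"""Endemism: per-site proportions, bootstrap envelopes, and the
endemic-removal permutation test on beta-diversity components.

Endemism at a trapping location is the proportion of its species (or
of its captures) that are endemic to the study region.  Species whose
endemism cannot be classified (animals not identified to species
level) are excluded from both numerator and denominator, and can never
be drawn into resampling pools.

The endemic-removal test asks whether the endemic species are the
ones driving compositional turnover: the multi-site turnover and
nestedness components are recomputed on the non-endemic submatrix and
compared against a null distribution obtained by drawing, without
replacement, random species subsets of the same size from the
mountain's full classified species pool.  One-tailed empirical
p-values use the add-one correction, with the tail chosen by the
direction of the observed departure from the full-matrix component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta import BetaPartition, multisite_partition
from .exceptions import InfeasibleTestError, ParameterError
from .survey import AbundanceMatrix, IncidenceMatrix


def _endemic_lookup(meta: pd.DataFrame) -> pd.Series:
    return meta.set_index("species")["endemic"]


def endemism_profile(m: AbundanceMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-site endemism: proportion of species and of captures endemic.

    Only classified species (endemic or non_endemic) enter the
    denominators.  Sites where every species is unclassified are
    flagged ``defined = False`` with NaN proportions.
    """
    status = _endemic_lookup(meta)
    missing = set(m.species) - set(status.index)
    if missing:
        raise ValueError(f"species without metadata: {sorted(missing)}")
    status = status.reindex(m.species)
    classified = (status != "unknown").to_numpy()
    endemic = (status == "endemic").to_numpy()
    rows = []
    for site, counts in m.counts.iterrows():
        c = counts.to_numpy()
        present = c > 0
        n_cls = int((present & classified).sum())
        n_end = int((present & endemic).sum())
        cap_cls = int(c[classified].sum())
        cap_end = int(c[endemic].sum())
        rows.append(
            {
                "mountain": site[0],
                "location": site[1],
                "elevation": m.site_elevations.loc[site],
                "n_species_classified": n_cls,
                "n_endemic": n_end,
                "prop_endemic_species": n_end / n_cls if n_cls else np.nan,
                "n_captures_classified": cap_cls,
                "n_captures_endemic": cap_end,
                "prop_endemic_captures": cap_end / cap_cls if cap_cls else np.nan,
                "defined": n_cls > 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BootstrapEnvelope:
    """Percentile envelope of resampled endemic proportions per site."""

    table: pd.DataFrame  # per site: estimate, q025, q975, n_classified
    reps: int
    unit: str  # "species" or "captures"
    seed: int


def bootstrap_envelope(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    reps: int = 1000,
    unit: str = "species",
    seed: int = 0,
) -> BootstrapEnvelope:
    """Bootstrap confidence envelope for per-site endemic proportions.

    ``unit="species"`` resamples each site's classified species list
    with replacement (same size) and recomputes the proportion of
    endemic species; ``unit="captures"`` resamples the site's capture
    records of classified species.  The envelope is the 2.5% / 97.5%
    percentile interval over replicates.  Sites with no classified
    species (or no classified captures) get no envelope.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    if unit not in ("species", "captures"):
        raise ParameterError("unit must be 'species' or 'captures'")
    status = _endemic_lookup(meta).reindex(m.species)
    classified = (status != "unknown").to_numpy()
    endemic = (status == "endemic").to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    profile = endemism_profile(m, meta).set_index(["mountain", "location"])
    for site, counts in m.counts.iterrows():
        c = counts.to_numpy()
        if unit == "species":
            flags = endemic[(c > 0) & classified]
            est = profile.loc[site, "prop_endemic_species"]
        else:
            flags = np.repeat(endemic[classified], c[classified])
            est = profile.loc[site, "prop_endemic_captures"]
        n = flags.size
        if n == 0:
            rows.append(
                {"mountain": site[0], "location": site[1],
                 "elevation": m.site_elevations.loc[site],
                 "estimate": np.nan, "q025": np.nan, "q975": np.nan,
                 "n_resampled": 0, "defined": False}
            )
            continue
        draws = rng.integers(0, n, size=(reps, n))
        props = flags[draws].mean(axis=1)
        rows.append(
            {
                "mountain": site[0],
                "location": site[1],
                "elevation": m.site_elevations.loc[site],
                "estimate": float(est),
                "q025": float(np.percentile(props, 2.5)),
                "q975": float(np.percentile(props, 97.5)),
                "n_resampled": int(n),
                "defined": True,
            }
        )
    return BootstrapEnvelope(table=pd.DataFrame(rows), reps=reps, unit=unit, seed=seed)


@dataclass
class EndemicRemovalResult:
    """Observed beta components without endemics vs. random-subset nulls."""

    mountain: str
    observed: BetaPartition  # components on the non-endemic submatrix
    full: BetaPartition  # components on the full classified matrix
    n_endemic: int
    n_non_endemic: int
    reps: int
    seed: int
    p_sim: float
    p_sne: float
    p_sor: float
    direction_sim: str
    direction_sne: str
    direction_sor: str
    null_sim: np.ndarray = field(repr=False, default=None)
    null_sne: np.ndarray = field(repr=False, default=None)
    null_sor: np.ndarray = field(repr=False, default=None)
    #: fixed-tail probabilities, kept for calibration checks
    p_lower: dict = field(default_factory=dict)
    p_upper: dict = field(default_factory=dict)

    def null_summary(self) -> pd.DataFrame:
        rows = []
        for name, null in (
            ("beta_sim", self.null_sim),
            ("beta_sne", self.null_sne),
            ("beta_sor", self.null_sor),
        ):
            rows.append(
                {"component": name, "mean": null.mean(), "sd": null.std(ddof=1),
                 "q025": np.percentile(null, 2.5), "q975": np.percentile(null, 97.5)}
            )
        return pd.DataFrame(rows)


def _tail_p(null: np.ndarray, observed: float, reference: float) -> tuple[float, str, float, float]:
    reps = null.size
    p_lo = (np.count_nonzero(null <= observed) + 1) / (reps + 1)
    p_hi = (np.count_nonzero(null >= observed) + 1) / (reps + 1)
    if observed < reference:
        return p_lo, "decrease", p_lo, p_hi
    if observed > reference:
        return p_hi, "increase", p_lo, p_hi
    return p_hi, "none", p_lo, p_hi


def endemic_removal_test(
    m: IncidenceMatrix,
    meta: pd.DataFrame,
    reps: int = 5000,
    seed: int = 0,
) -> EndemicRemovalResult:
    """Permutation test for the endemics' contribution to beta diversity.

    The observed statistic is the multi-site partition of the
    incidence matrix restricted to non-endemic species.  The null
    re-draws, ``reps`` times without replacement, a species subset of
    the same size from all classified species of the mountain and
    recomputes the partition.  Unclassified species never enter the
    pool.  Mountains must be tested one at a time.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    mountains = {s[0] for s in m.sites}
    if len(mountains) != 1:
        raise ValueError(
            f"incidence matrix spans mountains {sorted(mountains)}; "
            "test one mountain at a time"
        )
    mountain = mountains.pop()
    status = _endemic_lookup(meta).reindex(m.species)
    classified_cols = [
        sp for sp in m.species if status.loc[sp] in ("endemic", "non_endemic")
    ]
    non_endemic_cols = [sp for sp in classified_cols if status.loc[sp] == "non_endemic"]
    k = len(non_endemic_cols)
    n_end = len(classified_cols) - k
    if k < 2:
        raise InfeasibleTestError(
            f"only {k} non-endemic species on {mountain}; need at least 2"
        )
    pres = m.presence[classified_cols]
    full = multisite_partition(pres)
    # a null subset (or the non-endemic submatrix) can leave a site with no
    # species; such sites are dropped by multisite_partition, which is the
    # expected behaviour here rather than something to warn about per draw
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        observed = multisite_partition(pres[non_endemic_cols])

    x = pres.to_numpy(dtype=bool)
    rng = np.random.default_rng(seed)
    n_cls = len(classified_cols)
    null_sim = np.empty(reps)
    null_sne = np.empty(reps)
    null_sor = np.empty(reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for t in range(reps):
            cols = rng.choice(n_cls, size=k, replace=False)
            part = multisite_partition(x[:, cols])
            null_sim[t] = part.beta_sim
            null_sne[t] = part.beta_sne
            null_sor[t] = part.beta_sor
    p_lower, p_upper = {}, {}
    out = {}
    for name, null, obs, ref in (
        ("sim", null_sim, observed.beta_sim, full.beta_sim),
        ("sne", null_sne, observed.beta_sne, full.beta_sne),
        ("sor", null_sor, observed.beta_sor, full.beta_sor),
    ):
        p, direction, p_lo, p_hi = _tail_p(null, obs, ref)
        out[name] = (p, direction)
        p_lower[name] = p_lo
        p_upper[name] = p_hi
    return EndemicRemovalResult(
        mountain=mountain,
        observed=observed,
        full=full,
        n_endemic=n_end,
        n_non_endemic=k,
        reps=reps,
        seed=seed,
        p_sim=out["sim"][0],
        p_sne=out["sne"][0],
        p_sor=out["sor"][0],
        direction_sim=out["sim"][1],
        direction_sne=out["sne"][1],
        direction_sor=out["sor"][1],
        null_sim=null_sim,
        null_sne=null_sne,
        null_sor=null_sor,
        p_lower=p_lower,
        p_upper=p_upper,
    )
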