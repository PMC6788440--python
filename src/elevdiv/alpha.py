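"""Alpha (within-site) diversity indices.

For a community with counts :math:`n_1, \\dots, n_S` and relative
abundances :math:`p_i = n_i / N`:

* species richness ``S`` — number of species with ``n_i > 0``;
* Shannon diversity ``H' = -sum p_i ln p_i`` (natural log, so
  ``H_max = ln S``);
* Simpson's diversity ``D = 1 - sum p_i^2`` (the complement form, a
  diversity that rises with evenness; the inverse form ``1/sum p_i^2``
  is available via ``variant="inverse"``);
* Pielou's evenness ``J' = H' / ln S``, defined for ``S >= 2``.

The ``0 ln 0 = 0`` convention applies throughout.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .exceptions import UndefinedEvennessError, UndefinedIndexError
from .survey import AbundanceMatrix


def _as_props(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise UndefinedIndexError("diversity is undefined for an empty community")
    return c[c > 0] / total


def richness(counts) -> int:
    """Number of species with a positive count."""
    c = np.asarray(counts, dtype=float)
    return int((c > 0).sum())


def shannon(counts, base: float = math.e) -> float:
    """Shannon diversity H' (natural log by default)."""
    p = _as_props(counts)
    return float(-(p * np.log(p)).sum() / math.log(base))


def simpson(counts, variant: str = "complement") -> float:
    """Simpson's diversity: ``1 - sum p_i^2`` or the inverse form."""
    p = _as_props(counts)
    ss = float((p**2).sum())
    if variant == "complement":
        return 1.0 - ss
    if variant == "inverse":
        return 1.0 / ss
    raise ValueError("variant must be 'complement' or 'inverse'")


def pielou(counts, base: float = math.e) -> float:
    """Pielou's evenness J' = H'/H_max; raises for S <= 1 rather than
    silently returning 0, since evenness is meaningless there."""
    s = richness(counts)
    if s < 2:
        raise UndefinedEvennessError(
            f"evenness is undefined for a community with {s} species"
        )
    return shannon(counts, base=base) / (math.log(s) / math.log(base))


def diversity_profile(m: AbundanceMatrix, base: float = math.e) -> pd.DataFrame:
    """Per-site diversity table (S, H, D, J) for an abundance matrix.

    Sites with no captures are flagged (``defined = False``) with NaN
    indices; sites with a single species get NaN evenness.  Row order
    follows the matrix (mountain, then nominal elevation).
    """
    rows = []
    for site, counts in m.counts.iterrows():
        c = counts.to_numpy()
        entry = {
            "mountain": site[0],
            "location": site[1],
            "elevation": m.site_elevations.loc[site],
            "S": richness(c),
        }
        if c.sum() == 0:
            entry.update(H=np.nan, D=np.nan, J=np.nan, defined=False)
        else:
            entry["H"] = shannon(c, base=base)
            entry["D"] = simpson(c)
            try:
                entry["J"] = pielou(c, base=base)
            except UndefinedEvennessError:
                entry["J"] = np.nan
            entry["defined"] = True
        rows.append(entry)
    return pd.DataFrame(rows)
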