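"""Red List category -> extinction probability weightings.

Three published quantifications are shipped (IUCN50, IUCN500 and the
EDGE2 weighting).  Each maps the five assessed categories LC..CR to a
median extinction probability.  Sampling uncertainty around a category
is modelled with a continuous "category rank" axis: LC..CR sit at ranks
0..4, an assessed species draws its rank uniformly from the unit band
centred on its category, and the rank is converted to a probability by
a monotone curve that is piecewise linear in log(probability) against
rank (extended at the ends with the adjacent segment's slope).  The
band medians therefore reproduce the tabulated values exactly.  Data
Deficient and Not Evaluated species draw their rank uniformly over the
whole axis [-0.5, 4.5]: their median lands on the Vulnerable value and
60% of draws fall in the threatened bands (VU and up), 40% in the
non-threatened ones.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SpeciesRecord

__all__ = [
    "WeightScheme", "RiskAssignment", "load_schemes", "get_scheme",
    "median_weight", "sample_weight", "sample_weights", "assign_weights",
    "q_map", "CATEGORY_RANK", "RANK_MIN", "RANK_MAX", "THREATENED_RANK_MIN",
]

logger = logging.getLogger("phylorisk.risk_weights")

#: Rank of each assessed category on the sampling axis.
CATEGORY_RANK = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}
ASSESSED = tuple(CATEGORY_RANK)

RANK_MIN, RANK_MAX = -0.5, 4.5
#: Lower edge of the Vulnerable band: ranks at or above it are "threatened".
THREATENED_RANK_MIN = 1.5

#: Probabilities are clamped below 1 so branch products stay informative
#: (the IUCN500 CR median is printed as 1).
Q_MAX = 1.0 - 1e-9


@dataclass(frozen=True)
class WeightScheme:
    """A named category->median-probability table plus its sampling curve."""

    name: str
    medians: Mapping[str, float]  # keys LC..CR, values in (0, 1]

    def __post_init__(self):
        vals = [self.medians[c] for c in ASSESSED]
        if any(not (0 < v <= 1) for v in vals):
            raise ValueError(f"{self.name}: medians must lie in (0, 1]")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"{self.name}: medians must increase LC -> CR")

    def median(self, category: str) -> float:
        if category not in self.medians:
            raise KeyError(
                f"category {category!r} has no median under scheme "
                f"{self.name!r}; DD/NE/EW/EX weights are sampled, see "
                "sample_weight/assign_weights"
            )
        return float(self.medians[category])

    def curve(self, rank):
        """Probability at a continuous category rank (vectorised).

        Piecewise log-linear through the five (rank, median) knots,
        extended beyond ranks 0 and 4 with the first/last segment's
        slope, and clamped to stay strictly below 1.
        """
        r = np.asarray(rank, dtype=float)
        if np.any(r < RANK_MIN) or np.any(r > RANK_MAX):
            raise ValueError(f"rank outside [{RANK_MIN}, {RANK_MAX}]")
        logm = np.log([self.medians[c] for c in ASSESSED])
        slopes = np.diff(logm)
        seg = np.clip(np.floor(r).astype(int), 0, 3)
        q = np.exp(logm[seg] + slopes[seg] * (r - seg))
        q = np.minimum(q, Q_MAX)
        return q if q.ndim else float(q)

    def rank_band(self, category: str) -> tuple[float, float]:
        """Rank interval a category's draws are taken from."""
        if category in CATEGORY_RANK:
            c = CATEGORY_RANK[category]
            return (c - 0.5, c + 0.5)
        if category in ("DD", "NE"):
            return (RANK_MIN, RANK_MAX)
        raise KeyError(f"no sampling band for category {category!r}")


@dataclass(frozen=True)
class RiskAssignment:
    """A sampled per-species extinction probability."""

    species: str
    category: str
    q: float              # probability in (0, 1)
    rank_value: float     # the rank r the probability was drawn at
    scheme: str
    replicate: int = 0


def load_schemes(path: str | Path | None = None) -> dict[str, WeightScheme]:
    """Load the scheme table (packaged default, or a user CSV of the
    same schema: columns category, then one column per scheme)."""
    if path is None:
        ref = importlib.resources.files("phylorisk") / "data" / "risk_weights.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    df = df.set_index("category")
    schemes = {}
    for col in df.columns:
        schemes[col.lower()] = WeightScheme(
            name=col.lower(),
            medians={c: float(df.loc[c, col]) for c in ASSESSED},
        )
    return schemes


_SCHEMES: dict[str, WeightScheme] | None = None


def get_scheme(name: str | WeightScheme) -> WeightScheme:
    if isinstance(name, WeightScheme):
        return name
    global _SCHEMES
    if _SCHEMES is None:
        _SCHEMES = load_schemes()
    try:
        return _SCHEMES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown scheme {name!r}; "
                       f"available: {sorted(_SCHEMES)}") from None


def median_weight(category: str, scheme: str | WeightScheme) -> float:
    """Tabulated median extinction probability for an assessed category."""
    return get_scheme(scheme).median(category)


def _band_for(category: str, scheme: WeightScheme, ew_as_cr: bool) -> tuple[float, float]:
    if category == "EX":
        raise ValueError("EX species carry no forward extinction risk; "
                         "exclude them before weighting")
    if category == "EW":
        if not ew_as_cr:
            raise ValueError("EW weighting disabled (ew_as_cr=False)")
        return scheme.rank_band("CR")
    return scheme.rank_band(category)


def sample_weights(category: str, scheme: str | WeightScheme,
                   rng: np.random.Generator, size: int,
                   ew_as_cr: bool = True) -> np.ndarray:
    """Vectorised draw of ``size`` probabilities for one category."""
    sch = get_scheme(scheme)
    lo, hi = _band_for(category, sch, ew_as_cr)
    r = rng.uniform(lo, hi, size=size)
    return np.asarray(sch.curve(r))


def sample_weight(category: str, scheme: str | WeightScheme,
                  rng: np.random.Generator, species: str = "",
                  replicate: int = 0, ew_as_cr: bool = True) -> RiskAssignment:
    """Draw one extinction probability for a species of the given category."""
    sch = get_scheme(scheme)
    lo, hi = _band_for(category, sch, ew_as_cr)
    r = float(rng.uniform(lo, hi))
    return RiskAssignment(species=species, category=category,
                          q=float(sch.curve(r)), rank_value=r,
                          scheme=sch.name, replicate=replicate)


def assign_weights(records: Sequence[SpeciesRecord],
                   scheme: str | WeightScheme,
                   replicate_seed: int | np.random.Generator,
                   replicate: int = 0,
                   ew_as_cr: bool = True) -> list[RiskAssignment]:
    """One independent probability draw per species for one replicate.

    Draws are consumed in sorted species-name order, so a fixed seed
    yields identical assignments regardless of input order.  EX species
    are excluded (their lost history is accounted separately); EW
    species are assigned the CR band by default.
    """
    sch = get_scheme(scheme)
    rng = (replicate_seed if isinstance(replicate_seed, np.random.Generator)
           else np.random.default_rng(replicate_seed))
    live = sorted((r for r in records if r.red_list_category != "EX"),
                  key=lambda r: r.key)
    n_ex = len(records) - len(live)
    if n_ex:
        logger.info("assign_weights: excluded %d EX species from weighting", n_ex)
    u = rng.uniform(size=len(live))
    out: list[RiskAssignment] = []
    for rec, ui in zip(live, u):
        lo, hi = _band_for(rec.red_list_category, sch, ew_as_cr)
        r = lo + ui * (hi - lo)
        out.append(RiskAssignment(
            species=rec.species, category=rec.red_list_category,
            q=float(sch.curve(r)), rank_value=float(r),
            scheme=sch.name, replicate=replicate,
        ))
    return out


def q_map(assignments: Sequence[RiskAssignment]) -> dict[str, float]:
    """Normalised-name -> probability lookup for the tree metrics."""
    from .io_formats import normalize_name
    return {normalize_name(a.species): a.q for a in assignments}
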