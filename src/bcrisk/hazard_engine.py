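"""Piecewise-constant age x residence rate tables and the two hazards.

The absolute-risk projection needs two hazards per residence:

* the baseline breast-cancer hazard ``h10(t)``, obtained by deflating the
  composite (population) incidence rate by one minus the population
  attributable risk for the age segment and residence containing ``t``; and
* the competing hazard ``h2(t)`` of death from causes other than breast
  cancer, i.e. all-cause mortality minus breast-cancer mortality.

Rates are piecewise constant on age bands (registries publish 5-year bands),
which makes every projection integral closed-form.  The per-100,000
person-year convention exists only at the file boundary; internally all
hazards are events per person-year.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attributable_risk import PARSet
from .risk_model import ValidationError

logger = logging.getLogger(__name__)

RATE_COLUMNS = [
    "age_start",
    "age_width",
    "residence",
    "bc_incidence_1e5",
    "all_cause_mortality_1e5",
    "bc_mortality_1e5",
]


@dataclass
class RateTable:
    """Validated age-band rates for both residences.

    Bands within a residence must be contiguous, non-overlapping and cover
    a common interval (the shipped default covers [30, 85)).  Validation is
    eager: a malformed table never constructs.
    """

    frame: pd.DataFrame
    provenance: str = "user"
    _bands: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(RATE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"rate table missing columns: {sorted(missing)}")
        for residence in ("urban", "rural"):
            sub = df[df["residence"] == residence].sort_values("age_start")
            if len(sub) == 0:
                raise ValidationError(f"rate table has no rows for {residence}")
            starts = sub["age_start"].to_numpy(dtype=float)
            widths = sub["age_width"].to_numpy(dtype=float)
            if np.any(widths <= 0):
                raise ValidationError(f"{residence}: non-positive band width")
            ends = starts + widths
            if not np.allclose(starts[1:], ends[:-1]):
                raise ValidationError(
                    f"{residence}: age bands not contiguous/non-overlapping"
                )
            rates = sub[["bc_incidence_1e5", "all_cause_mortality_1e5",
                         "bc_mortality_1e5"]].to_numpy(dtype=float)
            if np.any(rates < 0) or not np.all(np.isfinite(rates)):
                raise ValidationError(f"{residence}: negative or non-finite rate")
            if np.any(rates[:, 2] > rates[:, 1]):
                raise ValidationError(
                    f"{residence}: breast-cancer mortality exceeds all-cause "
                    "mortality in some band"
                )
            self._bands[residence] = {
                "start": starts,
                "end": ends,
                "incidence": rates[:, 0] / 1e5,
                "mortality_other": (rates[:, 1] - rates[:, 2]) / 1e5,
            }
        lo = {r: b["start"][0] for r, b in self._bands.items()}
        hi = {r: b["end"][-1] for r, b in self._bands.items()}
        self.age_min = max(lo.values())
        self.age_max = min(hi.values())
        logger.info(
            "rate table loaded (%s): coverage [%g, %g), %d rows",
            self.provenance, self.age_min, self.age_max, len(df),
        )

    # -- queries --------------------------------------------------------

    def _band_index(self, residence: str, age) -> np.ndarray:
        b = self._bands[residence]
        a = np.asarray(age, dtype=float)
        if np.any(a < b["start"][0]) or np.any(a >= b["end"][-1]):
            raise ValidationError(
                f"age outside table coverage [{b['start'][0]}, {b['end'][-1]})"
            )
        return np.searchsorted(b["start"], a, side="right") - 1

    def composite_incidence(self, residence: str, age) -> np.ndarray | float:
        """Population breast-cancer incidence per person-year at ``age``."""
        idx = self._band_index(residence, age)
        out = self._bands[residence]["incidence"][idx]
        return float(out) if np.isscalar(age) else out

    def competing_hazard(self, residence: str, age) -> np.ndarray | float:
        """h2: (all-cause - breast-cancer mortality) per person-year."""
        idx = self._band_index(residence, age)
        out = self._bands[residence]["mortality_other"][idx]
        return float(out) if np.isscalar(age) else out

    def baseline_hazard(self, pars: PARSet, residence: str, age,
                        age_split: float = 50.0) -> np.ndarray | float:
        """h10: composite incidence x (1 - PAR[segment(age), residence])."""
        lam = self.composite_incidence(residence, age)
        a = np.asarray(age, dtype=float)
        par_lt = pars.get(residence, 0.0, age_split)
        par_ge = pars.get(residence, age_split, age_split)
        par = np.where(a < age_split, par_lt, par_ge)
        out = lam * (1.0 - par)
        return float(out) if np.isscalar(age) else out

    def breakpoints(self, residence: str, age_split: float = 50.0) -> np.ndarray:
        """Ascending ages where any hazard may change, incl. the age split."""
        b = self._bands[residence]
        pts = np.unique(np.concatenate([b["start"], b["end"][-1:], [age_split]]))
        return pts[(pts >= b["start"][0]) & (pts <= b["end"][-1])]

    # -- IO -------------------------------------------------------------

    def save(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "RateTable":
        df = pd.read_csv(path)
        if list(df.columns) != RATE_COLUMNS:
            raise ValidationError(
                f"rate CSV header must be exactly {RATE_COLUMNS}, "
                f"got {list(df.columns)}"
            )
        return cls(frame=df, provenance=provenance or str(path))


def competing_hazard(table: RateTable, residence: str, age):
    """Module-level convenience wrapper for :meth:`RateTable.competing_hazard`."""
    return table.competing_hazard(residence, age)


def baseline_hazard(table: RateTable, pars: PARSet, residence: str, age):
    """Module-level convenience wrapper for :meth:`RateTable.baseline_hazard`."""
    return table.baseline_hazard(pars, residence, age)


# ---------------------------------------------------------------------------
# Shipped default: SYNTHETIC rates.
#
# National registry band-level rates are not redistributable here, so the
# package ships a synthetic table whose *all-ages* crude incidence matches the
# published 54.3 (urban) and 34.5 (rural) per 100,000 person-years when
# weighted by an approximate Chinese female age structure (~41% of women are
# under 30, where incidence is negligible, and ~0.8% over 85).  The age
# gradient is monotone non-decreasing, rising steeply through the forties and
# plateauing after 55, as cancer-registry curves do.  Mortality columns follow
# a standard female life-table gradient, slightly higher in rural areas.
# Every output derived from this table is tagged "synthetic-rates"; users
# supply real registry tables via CSV.
# ---------------------------------------------------------------------------

_AGE_STARTS = np.arange(30, 85, 5)

# relative incidence shape, bands 30-34 ... 80-84 (monotone non-decreasing)
_INC_SHAPE = np.array([15, 30, 55, 80, 95, 100, 102, 104, 105, 106, 107.0])
# approximate share of the female population in each band (all-ages basis)
_POP_WEIGHT = np.array(
    [0.074, 0.077, 0.089, 0.085, 0.065, 0.055, 0.052, 0.035, 0.025, 0.018, 0.012]
)
_CRUDE_TARGET = {"urban": 54.3, "rural": 34.5}

_MORT_ALL = {
    "urban": np.array(
        [60, 80, 120, 180, 280, 450, 800, 1500, 2800, 5200, 9500.0]
    ),
    "rural": np.array(
        [70, 95, 140, 210, 330, 530, 950, 1750, 3200, 6000, 11000.0]
    ),
}
_MORT_BC = {
    "urban": np.array([1.5, 3, 6, 10, 14, 17, 19, 21, 22, 23, 24.0]),
    "rural": np.array([1.0, 2, 4, 7, 9.5, 11.5, 13, 14, 15, 16, 16.5]),
}


def default_rate_table() -> RateTable:
    """The shipped synthetic rate table (see module comment)."""
    rows = []
    denom = float(_POP_WEIGHT @ _INC_SHAPE)
    for residence in ("urban", "rural"):
        scale = _CRUDE_TARGET[residence] / denom
        inc = _INC_SHAPE * scale
        for i, start in enumerate(_AGE_STARTS):
            rows.append(
                {
                    "age_start": float(start),
                    "age_width": 5.0,
                    "residence": residence,
                    "bc_incidence_1e5": round(float(inc[i]), 4),
                    "all_cause_mortality_1e5": float(_MORT_ALL[residence][i]),
                    "bc_mortality_1e5": float(_MORT_BC[residence][i]),
                }
            )
    return RateTable(frame=pd.DataFrame(rows), provenance="synthetic-rates")
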