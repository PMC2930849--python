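"""Cohort life tables and the Gompertz death-age baseline.

A life table maps (sex, integer age) to remaining life expectancy in
years.  The built-in table is derived numerically from the same Gompertz
survival law the simulator samples death ages from, calibrated so that
the upper 5% survival tail of the birth cohort falls at age 90 for males
and 95 for females.  A study using a real historical cohort table can
load one from TSV with :func:`read_life_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("male", "female")

# Gompertz shape (years) shared by both sexes; the sex-specific rate is
# solved so that P(T > location) = ANCHOR_TAIL, i.e. the location
# parameter is the age at the upper 5% tail of the cohort for males.
# Females get the same tail 5 years later, mirroring the 90/95 offset of
# the sexes' extreme-age cutoffs.
GOMPERTZ_SCALE = 13.7
GOMPERTZ_LOCATION = 90.0
ANCHOR_TAIL = 0.05
FEMALE_SHIFT = 5.0


def gompertz_rate(sex: str, location: float = GOMPERTZ_LOCATION,
                  scale: float = GOMPERTZ_SCALE) -> float:
    """Rate parameter c of S(t) = exp(-c (e^{t/scale} - 1)) for the sex."""
    a = location + (FEMALE_SHIFT if sex == "female" else 0.0)
    return -np.log(ANCHOR_TAIL) / np.expm1(a / scale)


def gompertz_survival(ages, sex: str, location: float = GOMPERTZ_LOCATION,
                      scale: float = GOMPERTZ_SCALE):
    c = gompertz_rate(sex, location, scale)
    return np.exp(-c * np.expm1(np.asarray(ages, dtype=float) / scale))


def sample_death_ages(rng: np.random.Generator, sex, size=None,
                      location: float = GOMPERTZ_LOCATION,
                      scale: float = GOMPERTZ_SCALE,
                      min_age: float | None = None):
    """Draw death ages by inverting the Gompertz CDF (truncated at 0).

    With ``min_age`` the draw is from the conditional distribution
    T | T >= min_age (exact inverse-CDF conditioning, no rejection).
    """
    sex_arr = np.atleast_1d(np.asarray(sex))
    if size is None:
        size = sex_arr.shape[0]
    c = np.where(sex_arr == "male",
                 gompertz_rate("male", location, scale),
                 gompertz_rate("female", location, scale))
    u = rng.uniform(size=size)
    if min_age is not None:
        s_floor = np.exp(-c * np.expm1(np.asarray(min_age, dtype=float) / scale))
        u = u * s_floor
    else:
        u = np.clip(u, 1e-300, 1.0)
    t = scale * np.log1p(-np.log(u) / c)
    return np.maximum(t, 0.0)


@dataclass
class LifeTable:
    """Remaining life expectancy indexed by sex and integer age.

    ``table[sex]`` is a float array where index ``a`` holds the expected
    number of remaining years for a subject of that sex alive at age
    ``a``.  Lookups truncate fractional ages to whole years, the usual
    life-table convention.
    """

    expectancy: dict = field(default_factory=dict)

    def __post_init__(self):
        for sex, e in self.expectancy.items():
            e = np.asarray(e, dtype=float)
            if (e < 0).any():
                raise ValueError(f"negative life expectancy for {sex}")
            self.expectancy[sex] = e

    def remaining(self, sex: str, age) -> np.ndarray:
        """Expected remaining years at ``age`` (scalar or array)."""
        if sex not in self.expectancy:
            raise KeyError(f"life table has no entries for sex {sex!r}")
        e = self.expectancy[sex]
        idx = np.floor(np.asarray(age, dtype=float)).astype(int)
        if (idx < 0).any():
            raise ValueError("negative age in life-table lookup")
        if (idx >= len(e)).any():
            raise KeyError("age beyond the life table's last entry")
        out = e[idx]
        return out if out.shape else float(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": sex, "age": a, "expectancy": v}
            for sex in self.expectancy
            for a, v in enumerate(self.expectancy[sex])
        ]
        return pd.DataFrame(rows)


def gompertz_life_table(max_age: int = 140,
                        location: float = GOMPERTZ_LOCATION,
                        scale: float = GOMPERTZ_SCALE,
                        grid_step: float = 0.05) -> LifeTable:
    """Life table implied by the Gompertz baseline: e(a) = ∫S dt / S(a)."""
    grid = np.arange(0.0, max_age + 40.0, grid_step)
    expectancy = {}
    for sex in SEXES:
        s = gompertz_survival(grid, sex, location, scale)
        # integral of S from each grid point to the end (trapezoid)
        seg = 0.5 * (s[1:] + s[:-1]) * grid_step
        tail = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
        ages = np.arange(max_age + 1)
        idx = np.searchsorted(grid, ages)
        expectancy[sex] = tail[idx] / np.maximum(s[idx], 1e-300)
    return LifeTable(expectancy)


def read_life_table(path) -> LifeTable:
    """Read a TSV with columns sex, age, expectancy."""
    df = pd.read_csv(path, sep="\t")
    expectancy = {}
    for sex, grp in df.groupby("sex"):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy(dtype=int)
        if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)) or ages[0] != 0:
            raise ValueError("life table must cover consecutive ages from 0")
        expectancy[sex] = grp["expectancy"].to_numpy(dtype=float)
    return LifeTable(expectancy)


def write_life_table(table: LifeTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
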