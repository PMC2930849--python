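"""Longevity phenotype construction and nested age-category trimming.

The analyzed phenotype is the *expected age at death* (EAD): the actual
age at death for deceased subjects, and age at last contact plus the
sex- and age-specific remaining life expectancy for living subjects.
Ten nested categories impose increasingly strict sex-specific minimum
EADs, spanning the upper 5% to the upper 0.2% tail of the birth cohort
(males 90..100, females 95..104).  Sibships are trimmed per category:
a sibling pair loses the whole sibship as soon as either member fails,
while larger sibships merely shed failing members — but must keep at
least two qualifying members to stay informative for allele sharing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .pedio import Cohort, Sibship


@dataclass
class CategoryScheme:
    """Ordered sex-specific minimum-EAD cutoffs with tail fractions."""

    min_ead_male: tuple
    min_ead_female: tuple
    tail_fraction: tuple

    def __post_init__(self):
        for cuts in (self.min_ead_male, self.min_ead_female):
            if (np.diff(cuts) <= 0).any():
                raise ValueError("cutoffs must increase with category index")
        if (np.diff(self.tail_fraction) >= 0).any():
            raise ValueError("tail fractions must decrease with category index")
        if not len(self.min_ead_male) == len(self.min_ead_female) == len(self.tail_fraction):
            raise ValueError("ragged category scheme")

    @property
    def n_categories(self) -> int:
        return len(self.min_ead_male)

    def cutoff(self, sex: str, category: int) -> float:
        cuts = self.min_ead_male if sex == "male" else self.min_ead_female
        return float(cuts[category - 1])


def default_scheme() -> CategoryScheme:
    """The study's ten extreme-age categories."""
    return CategoryScheme(
        min_ead_male=(90, 91, 92, 93, 94, 95, 96, 98, 99, 100),
        min_ead_female=(95, 96, 97, 98, 99, 100, 101, 102, 103, 104),
        tail_fraction=(0.05, 0.04, 0.03, 0.025, 0.02, 0.015, 0.01,
                       0.005, 0.003, 0.002),
    )


def expected_age_at_death(age_last_contact, sex, vital_status,
                          table: LifeTable):
    """EAD for one subject or arrays of subjects.

    Deceased subjects keep their age at death; living subjects add the
    life-table remaining expectancy at their (truncated) current age.
    """
    age = np.asarray(age_last_contact, dtype=float)
    if np.isnan(age).any():
        raise ValueError("age at last contact is missing")
    sex_arr = np.atleast_1d(np.asarray(sex))
    status = np.atleast_1d(np.asarray(vital_status))
    bad = ~np.isin(sex_arr, ("male", "female"))
    if bad.any():
        raise ValueError(f"unknown sex code(s): {set(sex_arr[bad])}")
    remaining = np.zeros_like(np.atleast_1d(age))
    for s in ("male", "female"):
        mask = (sex_arr == s) & (status == "alive")
        if mask.any():
            remaining[mask] = table.remaining(s, np.atleast_1d(age)[mask])
    out = np.atleast_1d(age) + remaining
    return out if out.shape != (1,) or np.ndim(age_last_contact) else float(out[0])


def add_expected_age(cohort: Cohort, table: LifeTable) -> Cohort:
    """Attach an ``expected_age_at_death`` column to the subject table."""
    df = cohort.subjects.copy()
    df["expected_age_at_death"] = expected_age_at_death(
        df["age_last_contact"].to_numpy(), df["sex"].to_numpy(),
        df["vital_status"].to_numpy(), table)
    return Cohort(df, cohort.genotypes, cohort.panel, dict(cohort.extras))


def assign_categories(subjects: pd.DataFrame,
                      scheme: CategoryScheme | None = None) -> pd.DataFrame:
    """Boolean membership table, one row per subject, one column per category.

    A subject qualifies for category k iff EAD >= the sex-specific
    cutoff; memberships are nested by construction of the cutoffs.
    """
    if scheme is None:
        scheme = default_scheme()
    if "expected_age_at_death" not in subjects.columns:
        raise ValueError("compute expected ages first (add_expected_age)")
    ead = subjects["expected_age_at_death"].to_numpy(dtype=float)
    sex = subjects["sex"].to_numpy()
    bad = ~np.isin(sex, ("male", "female"))
    if bad.any():
        raise ValueError(f"unknown sex code(s): {set(sex[bad])}")
    cols = {}
    for k in range(1, scheme.n_categories + 1):
        cut = np.where(sex == "male", scheme.cutoff("male", k),
                       scheme.cutoff("female", k))
        cols[k] = ead >= cut
    return pd.DataFrame(cols, index=subjects["iid"])


def trim_sibships(sibships: list, membership: pd.Series | np.ndarray,
                  id_index=None) -> list:
    """Apply the per-category trimming rule to a list of Sibship objects.

    ``membership`` is indexable by subject id (a pandas Series) or a
    boolean array aligned with each sibship's ``rows``.  Pairs with any
    failing member are dropped whole; larger sibships keep qualifying
    members only, and are dropped if fewer than two remain.
    """
    out = []
    for sib in sibships:
        if sib.size < 2:
            raise ValueError(f"sibship {sib.sid} has fewer than two members")
        if isinstance(membership, pd.Series):
            ok = membership.loc[sib.member_ids].to_numpy(dtype=bool)
        else:
            ok = np.asarray(membership, dtype=bool)[sib.rows]
        if sib.size == 2:
            if ok.all():
                out.append(sib)
            continue
        keep = np.flatnonzero(ok)
        if len(keep) >= 2:
            out.append(sib.subset(keep) if len(keep) < sib.size else sib)
    return out


def trim_cohort(cohort: Cohort, membership: pd.DataFrame,
                category: int) -> Cohort:
    """Cohort restricted to category ``category`` by the trimming rule."""
    col = membership[category]
    member = cohort.subjects["iid"].map(col).to_numpy(dtype=bool)
    kept_rows = []
    for sib in trim_sibships(cohort.sibships(), member):
        kept_rows.extend(sib.rows.tolist())
    if not kept_rows:
        return cohort.subset_subjects(np.array([], dtype=int))
    return cohort.subset_subjects(np.array(sorted(kept_rows), dtype=int))


def subgroup_rows(cohort: Cohort, group: str,
                  membership: pd.DataFrame | None = None,
                  mc_fo_category: int = 1) -> np.ndarray:
    """Row indices of a named analysis group.

    Groups: ``Total`` (everyone), ``Previous``/``New`` (recruitment-wave
    metadata), ``MC``/``FO`` (sibships with >=1 male member vs female-
    only, evaluated among members qualifying for ``mc_fo_category`` when
    a membership table is supplied, else among all members).
    """
    df = cohort.subjects
    if group == "Total":
        return np.arange(len(df))
    if group in ("Previous", "New"):
        return np.flatnonzero((df["wave"] == group.lower()).to_numpy())
    if group in ("MC", "FO"):
        rows = []
        if membership is not None:
            qual = df["iid"].map(membership[mc_fo_category]).to_numpy(dtype=bool)
        else:
            qual = np.ones(len(df), dtype=bool)
        for sid, grp in df.groupby("sibship", sort=False):
            members = grp.index.to_numpy()
            q = qual[members]
            has_male = ((grp["sex"].to_numpy() == "male") & q).any()
            if (group == "MC") == has_male:
                rows.extend(members.tolist())
        return np.array(sorted(rows), dtype=int)
    raise ValueError(f"unknown group {group!r}")


def write_membership(membership: pd.DataFrame, path) -> None:
    membership.astype(int).to_csv(path, sep="\t")
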