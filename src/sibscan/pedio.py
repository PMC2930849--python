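"""Cohort containers and PLINK-style PED/MAP text I/O.

Genotypes are stored as an int8 matrix (subjects x markers) counting
copies of allele "A" (the allele whose frequency the panel records):
0, 1, 2, with -1 for a missing call.  Only siblings are genotyped;
their parents appear in PED files as founder rows with fully missing
genotypes, which is the study design every linkage routine here assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MarkerPanel, read_map, write_map

SUBJECT_COLUMNS = ["iid", "sibship", "father", "mother", "sex",
                   "age_last_contact", "vital_status", "wave"]


@dataclass
class Sibship:
    """A nuclear sibship: 2-5 genotyped siblings, untyped founders.

    ``founders`` lists parent labels; ``child_parents`` maps each member
    (by position in ``rows``) to (father, mother) indices into
    ``founders``.  Full-sib sibships have two founders; sibships with
    half-siblings have three (one shared parent).
    """

    sid: str
    member_ids: list
    rows: np.ndarray              # row indices into the cohort genotype matrix
    founders: list
    child_parents: np.ndarray     # (n, 2) indices into founders

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def subset(self, keep_positions) -> "Sibship":
        keep = np.asarray(keep_positions, dtype=int)
        return Sibship(
            sid=self.sid,
            member_ids=[self.member_ids[i] for i in keep],
            rows=self.rows[keep],
            founders=self.founders,
            child_parents=self.child_parents[keep],
        )


@dataclass
class Cohort:
    """Subject metadata, genotype matrix, and the panel they refer to."""

    subjects: pd.DataFrame
    genotypes: np.ndarray
    panel: MarkerPanel
    extras: dict = field(default_factory=dict)  # simulation truth, etc.

    def __post_init__(self):
        if len(self.subjects) != self.genotypes.shape[0]:
            raise ValueError("subject table and genotype matrix disagree")
        if self.panel.n_markers != self.genotypes.shape[1]:
            raise ValueError("panel and genotype matrix disagree")
        missing = [c for c in SUBJECT_COLUMNS if c not in self.subjects.columns]
        if missing:
            raise ValueError(f"subject table missing columns: {missing}")
        self.subjects = self.subjects.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def sibships(self) -> list:
        """Group subjects into Sibship objects (insertion order)."""
        out = []
        for sid, grp in self.subjects.groupby("sibship", sort=False):
            if len(grp) < 2:
                raise ValueError(f"sibship {sid!r} has fewer than two members")
            parents = list(dict.fromkeys(
                p for pair in zip(grp["father"], grp["mother"]) for p in pair))
            pidx = {p: i for i, p in enumerate(parents)}
            child_parents = np.array(
                [[pidx[f], pidx[m]] for f, m in zip(grp["father"], grp["mother"])],
                dtype=int)
            out.append(Sibship(
                sid=str(sid),
                member_ids=list(grp["iid"]),
                rows=grp.index.to_numpy(),
                founders=parents,
                child_parents=child_parents,
            ))
        return out

    def subset_subjects(self, rows) -> "Cohort":
        rows = np.asarray(rows, dtype=int)
        return Cohort(self.subjects.iloc[rows].reset_index(drop=True),
                      self.genotypes[rows].copy(), self.panel, dict(self.extras))

    def subset_markers(self, cols) -> "Cohort":
        cols = np.asarray(cols, dtype=int)
        return Cohort(self.subjects.copy(), self.genotypes[:, cols].copy(),
                      self.panel.subset(cols), dict(self.extras))


_SEX_CODE = {"male": "1", "female": "2"}
_SEX_DECODE = {"1": "male", "2": "female"}


def write_ped_map(cohort: Cohort, ped_path, map_path) -> None:
    """Write PED (founders untyped, all siblings coded affected) and MAP."""
    write_map(cohort.panel, map_path)
    m = cohort.panel.n_markers
    with open(ped_path, "w") as fh:
        for sib in cohort.sibships():
            for founder in sib.founders:
                fields = [sib.sid, founder, "0", "0", "0", "0"] + ["0", "0"] * m
                fh.write("\t".join(fields) + "\n")
            for pos, iid in enumerate(sib.member_ids):
                row = cohort.subjects.iloc[sib.rows[pos]]
                g = cohort.genotypes[sib.rows[pos]]
                # allele "A" -> 1, allele "a" -> 2, missing -> 0 0
                geno_fields = []
                for code in g:
                    if code < 0:
                        geno_fields += ["0", "0"]
                    else:
                        geno_fields += ["1"] * int(code) + ["2"] * (2 - int(code))
                fields = [sib.sid, str(iid),
                          str(sib.founders[sib.child_parents[pos, 0]]),
                          str(sib.founders[sib.child_parents[pos, 1]]),
                          _SEX_CODE[row["sex"]], "2"] + geno_fields
                fh.write("\t".join(fields) + "\n")


def read_ped_map(ped_path, map_path, panel: MarkerPanel | None = None) -> Cohort:
    """Parse PED/MAP into a Cohort.

    Founder rows (parents named in the sibling rows, fully missing
    genotypes) are recognised and dropped from the genotype matrix.  If
    ``panel`` is given its frequencies are kept; otherwise the MAP file
    is used with placeholder frequencies.
    """
    if panel is None:
        panel = read_map(map_path)
    m = panel.n_markers
    rows, genos = [], []
    parent_names = set()
    records = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"(2 per marker + 6), got {len(fields)}")
            fid, iid, pat, mat, sex, pheno = fields[:6]
            if sex not in ("0", "1", "2"):
                raise ValueError(f"{ped_path}: line {lineno}: bad sex code {sex!r}")
            records.append((lineno, fid, iid, pat, mat, sex, fields[6:]))
            if pat != "0":
                parent_names.add((fid, pat))
            if mat != "0":
                parent_names.add((fid, mat))
    for lineno, fid, iid, pat, mat, sex, alleles in records:
        if pat == "0" and mat == "0" and (fid, iid) in parent_names:
            continue  # untyped founder row
        g = np.empty(m, dtype=np.int8)
        for j in range(m):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                g[j] = -1
            else:
                if a not in ("1", "2") or b not in ("1", "2"):
                    raise ValueError(
                        f"{ped_path}: line {lineno}: allele codes must be 0/1/2")
                g[j] = (a == "1") + (b == "1")
        rows.append({
            "iid": iid, "sibship": fid, "father": pat, "mother": mat,
            "sex": _SEX_DECODE.get(sex, "male"),
            "age_last_contact": np.nan, "vital_status": "alive", "wave": "new",
        })
        genos.append(g)
    if not rows:
        raise ValueError(f"{ped_path}: no genotyped subjects found")
    return Cohort(pd.DataFrame(rows), np.array(genos, dtype=np.int8), panel)


def write_subjects(cohort: Cohort, path) -> None:
    cols = [c for c in cohort.subjects.columns]
    cohort.subjects.to_csv(path, sep="\t", index=False, columns=cols)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject TSV missing columns: {missing}")
    return df
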