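"""Sample- and marker-level genotype QC and relatedness concordance.

Filters follow the usual order for family SNP panels: samples below a
95% call rate first, then markers that are unassigned to a chromosome,
out of Hardy-Weinberg equilibrium (exact conditional test, P < 1e-3,
evaluated in one unrelated subject per sibship), or below a 90% call
rate.  Relationship concordance classifies within-sibship pairs from
identity-by-state counts via method-of-moments IBD estimates; flags are
reported, nothing is removed automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd

from .pedio import Cohort
from .util import stage_rng


@dataclass
class QCReport:
    removed_samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_markers: pd.DataFrame = field(default_factory=pd.DataFrame)

    def marker_counts(self) -> dict:
        out = {}
        if len(self.removed_markers):
            for reason, grp in self.removed_markers.groupby("reason"):
                out[reason] = len(grp)
            out["union"] = self.removed_markers["marker"].nunique()
        else:
            out["union"] = 0
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tid\treason\tvalue\n")
            for _, r in self.removed_samples.iterrows():
                fh.write(f"sample\t{r['iid']}\t{r['reason']}\t{r['value']:.6g}\n")
            for _, r in self.removed_markers.iterrows():
                fh.write(f"marker\t{r['marker']}\t{r['reason']}\t{r['value']:.6g}\n")


def call_rates(genotypes: np.ndarray, axis: int) -> np.ndarray:
    """Fraction of non-missing calls per row (axis=1) or column (axis=0)."""
    return (genotypes >= 0).mean(axis=axis)


def sample_call_rate_filter(cohort: Cohort, threshold: float = 0.95) -> pd.DataFrame:
    """Samples whose call rate falls below ``threshold`` (with values)."""
    if cohort.genotypes.size == 0:
        raise ValueError("empty genotype matrix")
    rates = call_rates(cohort.genotypes, axis=1)
    flagged = np.flatnonzero(rates < threshold)
    return pd.DataFrame({
        "iid": cohort.subjects["iid"].iloc[flagged].to_numpy(),
        "reason": "call_rate",
        "value": rates[flagged],
    })


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele count and sums the probabilities
    of all heterozygote counts no more probable than the observed one.
    Monomorphic tables return 1.  Uses log-factorials; agrees with full
    rational-arithmetic enumeration to ~1e-12.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("empty genotype table")
    na = 2 * n_aa + n_ab          # copies of allele a
    nb = 2 * n - na
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)
    # P(n_ab = h | n, na) ∝ n! / (n_aa! n_ab! n_bb!) * 2^h, h same parity as rare
    hs = np.arange(rare % 2, rare + 1, 2)
    logp = np.array([
        h * np.log(2.0) - lgamma((rare - h) / 2 + 1) - lgamma(h + 1)
        - lgamma((n - (rare + h) / 2) + 1)
        for h in hs
    ])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.flatnonzero(hs == n_ab)[0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def select_unrelated(cohort: Cohort, seed: int = 0,
                     membership=None, category: int = 1) -> np.ndarray:
    """One randomly chosen subject per sibship (row indices).

    Guarantees pairwise unrelatedness by construction; used for the HWE
    filter and LD estimation.
    """
    rng = stage_rng(seed, "unrelated")
    rows = []
    for sid, grp in cohort.subjects.groupby("sibship", sort=False):
        members = grp.index.to_numpy()
        if membership is not None:
            qual = grp["iid"].map(membership[category]).to_numpy(dtype=bool)
            if qual.any():
                members = members[qual]
        rows.append(int(rng.choice(members)))
    return np.array(sorted(rows), dtype=int)


def marker_filters(cohort: Cohort, unrelated_rows: np.ndarray,
                   hwe_threshold: float = 1e-3,
                   call_threshold: float = 0.90,
                   unassigned_chroms=(0, "0", "U", "unassigned")) -> QCReport:
    """Flag markers unassigned / HWE-violating / low call rate; union removed."""
    sibs = cohort.subjects["sibship"].iloc[unrelated_rows]
    if sibs.duplicated().any():
        raise ValueError("unrelated set contains two subjects of one sibship")
    panel = cohort.panel
    rows = []
    chroms = panel.markers["chrom"].to_numpy()
    unassigned = np.isin(chroms, np.asarray(unassigned_chroms, dtype=object))
    for j in np.flatnonzero(unassigned):
        rows.append({"marker": panel.markers["marker"].iloc[j],
                     "reason": "unassigned", "value": 0.0})
    sub = cohort.genotypes[unrelated_rows]
    for j in range(panel.n_markers):
        col = sub[:, j]
        col = col[col >= 0]
        n_bb = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 2).sum())
        if n_aa + n_ab + n_bb == 0:
            continue
        p = hwe_exact_test(n_aa, n_ab, n_bb)
        if p < hwe_threshold:
            rows.append({"marker": panel.markers["marker"].iloc[j],
                         "reason": "hwe", "value": p})
    rates = call_rates(cohort.genotypes, axis=0)
    for j in np.flatnonzero(rates < call_threshold):
        rows.append({"marker": panel.markers["marker"].iloc[j],
                     "reason": "call_rate", "value": rates[j]})
    return QCReport(removed_markers=pd.DataFrame(
        rows, columns=["marker", "reason", "value"]))


def apply_qc(cohort: Cohort, sample_threshold: float = 0.95,
             hwe_threshold: float = 1e-3, call_threshold: float = 0.90,
             seed: int = 0) -> tuple:
    """Sample filter, then marker filters on the surviving samples.

    Returns (filtered cohort, QCReport).
    """
    sample_flags = sample_call_rate_filter(cohort, sample_threshold)
    keep = ~cohort.subjects["iid"].isin(sample_flags["iid"]).to_numpy()
    # keep sibships valid: dropping a member of a pair drops the sibship
    for sid, grp in cohort.subjects.groupby("sibship", sort=False):
        members = grp.index.to_numpy()
        if keep[members].sum() < 2:
            keep[members] = False
    trimmed = cohort.subset_subjects(np.flatnonzero(keep))
    unrelated = select_unrelated(trimmed, seed=seed)
    report = marker_filters(trimmed, unrelated, hwe_threshold, call_threshold)
    report.removed_samples = sample_flags
    bad = set(report.removed_markers["marker"]) if len(report.removed_markers) else set()
    keep_cols = np.flatnonzero(
        ~trimmed.panel.markers["marker"].isin(bad).to_numpy())
    return trimmed.subset_markers(keep_cols), report


# ---------------------------------------------------------------------------
# relationship concordance from identity-by-state sharing

# P(IBS = i | IBD = j) as a function of allele frequency p is integrated
# over the panel below; these are the standard two-allele expressions.

def _ibs_given_ibd(p: np.ndarray) -> np.ndarray:
    q = 1 - p
    e = np.empty((3, 3, len(p)))
    # IBD 0
    e[0, 0] = 2 * p**2 * q**2
    e[0, 1] = 4 * p**3 * q + 4 * p * q**3
    e[0, 2] = p**4 + q**4 + 4 * p**2 * q**2
    # IBD 1
    e[1, 0] = 0.0
    e[1, 1] = 2 * p**2 * q + 2 * p * q**2
    e[1, 2] = 1 - e[1, 1]
    # IBD 2
    e[2, 0] = 0.0
    e[2, 1] = 0.0
    e[2, 2] = 1.0
    return e.mean(axis=2)


def _pair_ibs_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    ok = (g1 >= 0) & (g2 >= 0)
    diff = np.abs(g1[ok] - g2[ok])
    return np.array([(diff == 2).sum(), (diff == 1).sum(), (diff == 0).sum()])


def classify_pair(ibs_counts: np.ndarray, expected: np.ndarray) -> tuple:
    """(label, pihat): solve observed IBS fractions for IBD proportions."""
    total = ibs_counts.sum()
    if total == 0:
        return "uninformative", np.nan
    obs = ibs_counts / total
    if obs[2] >= 0.99:
        return "duplicate_mz", 1.0
    coef, *_ = np.linalg.lstsq(expected.T, obs, rcond=None)
    coef = np.clip(coef, 0.0, None)
    coef = coef / coef.sum() if coef.sum() > 0 else np.array([1.0, 0, 0])
    pihat = 0.5 * coef[1] + coef[2]
    if pihat >= 0.8:
        return "duplicate_mz", pihat
    if 0.35 <= pihat < 0.8:
        return "full_sib", pihat
    if 0.15 <= pihat < 0.35:
        return "half_sib", pihat
    return "unrelated", pihat


def concordance_check(cohort: Cohort, min_markers: int = 100) -> pd.DataFrame:
    """Classify every within-sibship pair; flag pairs discordant with
    their recorded (full/half-sib) relationship."""
    import warnings

    if cohort.panel.n_markers < min_markers:
        warnings.warn("fewer than %d markers; IBS classification is noisy"
                      % min_markers, stacklevel=2)
    expected = _ibs_given_ibd(cohort.panel.markers["freq"].to_numpy())
    rows = []
    for sib in cohort.sibships():
        for i in range(sib.size):
            for j in range(i + 1, sib.size):
                shared = (sib.child_parents[i] == sib.child_parents[j]).sum()
                recorded = "full_sib" if shared == 2 else "half_sib"
                counts = _pair_ibs_counts(cohort.genotypes[sib.rows[i]],
                                          cohort.genotypes[sib.rows[j]])
                label, pihat = classify_pair(counts, expected)
                rows.append({
                    "sibship": sib.sid,
                    "iid1": sib.member_ids[i], "iid2": sib.member_ids[j],
                    "recorded": recorded, "classified": label,
                    "pihat": pihat, "ibs2_fraction": counts[2] / max(counts.sum(), 1),
                    "flag": label != recorded,
                })
    return pd.DataFrame(rows)
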