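"""Gene-dropping empirical significance for multi-category linkage scans.

Null replicates preserve everything about the observed analysis except
linkage itself: the pedigree structures, the marker map, allele and
cluster-haplotype frequencies, the missing-call pattern, and the
observed per-category memberships (each replicate is trimmed through
the same successive categories).  Each replicate set is scanned under
every category; empirical P values use the positively biased but
conservative estimator P = (r+1)/(n+1), with one-sided 95%
Clopper-Pearson upper limits computed on the adjusted count (r+1 events
in n+1 trials) — the convention that reproduces standard worked
examples of this estimator.  A replicate exceeding the observed score
in several categories at the same genomic location counts once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .linkage import linkage_scan
from .pedio import Cohort
from .peaks import local_maxima_above
from .phenotype import trim_cohort
from .util import haldane_theta, stage_rng

#: fixed single-scan genomewide significance screen (fully informative
#: map); peaks at or above it get an empirical P value.
SINGLE_SCAN_LOD = 3.6


# ---------------------------------------------------------------------------
# gene dropping

def _drop_loci(panel, clusters):
    """Per chromosome: ordered drop units (singleton markers / clusters)."""
    clusters = clusters or []
    in_cluster = {}
    for c in clusters:
        for j in c.indices:
            in_cluster[j] = c
    chroms = panel.markers["chrom"].to_numpy()
    cms = panel.markers["cm"].to_numpy()
    freqs = panel.markers["freq"].to_numpy()
    out = {}
    for chrom in panel.chromosomes:
        units = []
        seen = set()
        for j in panel.chrom_indices(chrom):
            j = int(j)
            if j in seen:
                continue
            if j in in_cluster:
                c = in_cluster[j]
                seen.update(c.indices)
                if c.hap_freqs is None:
                    raise ValueError("cluster haplotype frequencies missing")
                units.append({"cm": c.cm, "indices": np.array(c.indices),
                              "freqs": c.hap_freqs, "bits": c.haplotypes})
            else:
                units.append({"cm": cms[j], "indices": np.array([j]),
                              "freqs": np.array([1 - freqs[j], freqs[j]]),
                              "bits": np.array([[0], [1]])})
        out[chrom] = units
    return out


def gene_drop_replicates(cohort: Cohort, clusters=None, n_reps: int = 1000,
                         seed: int = 0, chunk: int = 50):
    """Yield (replicate index, genotype matrix) under no linkage.

    Founder haplotypes are drawn from allele / cluster-haplotype
    frequencies, transmitted with Haldane recombination between drop
    units (zero recombination within a cluster), and masked exactly
    where the observed matrix has missing calls.  Replicates are
    generated in chunks to bound memory (draws are batched over
    replicates within a chunk).
    """
    rng = stage_rng(seed, "genedrop")
    done = 0
    while done < n_reps:
        take = min(chunk, n_reps - done)
        for r, geno in enumerate(_gene_drop_chunk(rng, cohort, clusters, take)):
            yield done + r, geno
        done += take


def _gene_drop_chunk(rng, cohort: Cohort, clusters, n_reps: int):
    sibs = cohort.sibships()
    drop = _drop_loci(cohort.panel, clusters)
    miss = cohort.genotypes < 0
    n_subj, n_mark = cohort.genotypes.shape

    # pre-draw per sibship for all replicates, then emit per replicate
    reps = [np.empty((n_subj, n_mark), dtype=np.int8) for _ in range(n_reps)]
    for sib in sibs:
        n = sib.size
        F = len(sib.founders)
        for chrom, units in drop.items():
            cm = np.array([u["cm"] for u in units])
            T = len(units)
            theta = haldane_theta(np.diff(cm))
            # founder haplotype alleles per unit: (R, F, 2, T)
            founder = np.empty((n_reps, F, 2, T), dtype=np.int8)
            for t, u in enumerate(units):
                founder[:, :, :, t] = rng.choice(
                    len(u["freqs"]), size=(n_reps, F, 2), p=u["freqs"])
            # meiosis indicators: (R, n, 2, T) Markov chains
            bits = np.empty((n_reps, n, 2, T), dtype=np.int8)
            bits[:, :, :, 0] = rng.integers(0, 2, size=(n_reps, n, 2))
            for t in range(1, T):
                flip = rng.uniform(size=(n_reps, n, 2)) < theta[t - 1]
                bits[:, :, :, t] = bits[:, :, :, t - 1] ^ flip
            r_idx = np.arange(n_reps)[:, None]
            t_idx = np.arange(T)[None, :]
            for c in range(n):
                f, mo = sib.child_parents[c]
                pat = founder[r_idx, f, bits[:, c, 0, :], t_idx]   # (R, T)
                mat = founder[r_idx, mo, bits[:, c, 1, :], t_idx]
                row = sib.rows[c]
                for t, u in enumerate(units):
                    bit = u["bits"]
                    g = bit[pat[:, t]] + bit[mat[:, t]]            # (R, L)
                    for r in range(n_reps):
                        reps[r][row, u["indices"]] = g[r]
    for r in range(n_reps):
        reps[r][miss] = -1
        yield reps[r]


# ---------------------------------------------------------------------------
# replicate scanning

@dataclass
class NullEnsemble:
    n_reps: int
    maxima: pd.DataFrame     # replicate, category, chrom, cm, lod (genomewide max)
    peaks: pd.DataFrame      # replicate, category, chrom, cm, lod (local maxima)


def run_null_ensemble(cohort: Cohort, membership: pd.DataFrame,
                      clusters=None, n_reps: int = 1000, seed: int = 0,
                      categories=None, peak_floor: float = 1.0) -> NullEnsemble:
    """Scan gene-dropped replicates under successive category trimming.

    ``cohort`` must already be trimmed to the loosest category;
    ``membership`` is the observed per-subject category table, reused
    verbatim for every replicate ("successive trimming").
    """
    if categories is None:
        categories = list(membership.columns)
    cat_rows = {}
    for k in categories:
        trimmed = trim_cohort(cohort, membership, k)
        cat_rows[k] = cohort.subjects["iid"].isin(trimmed.subjects["iid"])
    max_rows, peak_rows = [], []
    for r, geno in gene_drop_replicates(cohort, clusters, n_reps, seed):
        rep = Cohort(cohort.subjects, geno, cohort.panel)
        for k in categories:
            keep = np.flatnonzero(cat_rows[k].to_numpy())
            if len(keep) == 0:
                continue
            sub = rep.subset_subjects(keep)
            curve = linkage_scan(sub, clusters=clusters)
            i = int(curve["lod"].idxmax())
            max_rows.append({"replicate": r, "category": k,
                             "chrom": curve["chrom"].iloc[i],
                             "cm": float(curve["cm"].iloc[i]),
                             "lod": float(curve["lod"].iloc[i])})
            local = local_maxima_above(curve, peak_floor)
            for _, p in local.iterrows():
                peak_rows.append({"replicate": r, "category": k,
                                  "chrom": p["chrom"], "cm": p["cm"],
                                  "lod": p["lod"]})
    cols = ["replicate", "category", "chrom", "cm", "lod"]
    return NullEnsemble(n_reps,
                        pd.DataFrame(max_rows, columns=cols),
                        pd.DataFrame(peak_rows, columns=cols))


# ---------------------------------------------------------------------------
# exceedance counting and empirical P values

def _distinct_locations(events: pd.DataFrame, window_cm: float) -> int:
    """Distinct genomic locations among (chrom, cm) events of one replicate:
    events on one chromosome within ``window_cm`` of each other merge."""
    n = 0
    for chrom, grp in events.groupby("chrom"):
        cms = np.sort(grp["cm"].to_numpy(dtype=float))
        n += 1 + int((np.diff(cms) > window_cm).sum())
    return n


def count_exceedances(observed_lod, ensemble: NullEnsemble,
                      scope: str = "per-peak",
                      dedup_window_cm: float = 30.0) -> int:
    """Exceedance count r for an observed peak LOD.

    per-peak scope: the number of distinct (replicate, location) events,
    across all categories, whose local-maximum LOD meets or exceeds
    ``observed_lod``; the same location reached in several categories of
    one replicate counts once.

    combined scope: ``observed_lod`` is the smaller of two observed peak
    scores, and r counts replicates harbouring two or more distinct
    qualifying locations.
    """
    hits = ensemble.peaks[ensemble.peaks["lod"] >= float(observed_lod)]
    r = 0
    for rep, grp in hits.groupby("replicate"):
        k = _distinct_locations(grp, dedup_window_cm)
        if scope == "per-peak":
            r += k
        elif scope == "combined":
            r += int(k >= 2)
        else:
            raise ValueError("scope must be 'per-peak' or 'combined'")
    return r


@dataclass
class EmpiricalP:
    r: int
    n: int
    p: float
    upper_cl: float


def empirical_p(r: int, n: int) -> float:
    """The positively biased permutation estimator P = (r+1)/(n+1)."""
    if not 0 <= r <= n:
        raise ValueError("need 0 <= r <= n")
    if n < 1:
        raise ValueError("need at least one replicate")
    return (r + 1) / (n + 1)


def cp_upper_limit(r: int, n: int, level: float = 0.95) -> float:
    """One-sided Clopper-Pearson upper limit on the adjusted count.

    The exact upper binomial bound for r+1 successes in n+1 trials: the
    smallest p whose lower-tail probability of <= r+1 successes is
    1 - level.  This is the convention matching the (r+1)/(n+1)
    estimator, which treats the observed statistic as one extra
    exceedance.
    """
    if not 0 <= r <= n:
        raise ValueError("need 0 <= r <= n")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    x, m = r + 1, n + 1
    if x >= m:
        return 1.0
    return float(beta_dist.ppf(level, x + 1, m - x))


def empirical_report(r: int, n: int, level: float = 0.95) -> EmpiricalP:
    return EmpiricalP(r, n, empirical_p(r, n), cp_upper_limit(r, n, level))


def genomewide_thresholds(ensemble: NullEnsemble, alpha: float = 0.05) -> dict:
    """Empirical genomewide LOD thresholds at type I error ``alpha``.

    per_category: the (1 - alpha) quantile of the per-replicate
    genomewide maximum, averaged over categories.  overall: the same
    quantile of each replicate's maximum over *all* categories (the
    multiple-category-corrected threshold).
    """
    import warnings

    if ensemble.n_reps < 100:
        warnings.warn("fewer than 100 replicates: thresholds are unstable",
                      stacklevel=2)
    per_cat = []
    for k, grp in ensemble.maxima.groupby("category"):
        by_rep = grp.groupby("replicate")["lod"].max()
        per_cat.append(np.quantile(by_rep.to_numpy(), 1 - alpha))
    overall_max = ensemble.maxima.groupby("replicate")["lod"].max()
    return {
        "per_category": float(np.mean(per_cat)),
        "overall": float(np.quantile(overall_max.to_numpy(), 1 - alpha)),
    }


def write_ensemble(ensemble: NullEnsemble, path, seed=None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# master seed: {seed}\n")
        ensemble.maxima.to_csv(fh, sep="\t", index=False)
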