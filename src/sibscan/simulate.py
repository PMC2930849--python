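"""Synthetic sibship cohorts with life-table longevity phenotypes.

The simulator emulates the study design every other module expects:
nuclear sibships of 2-5 genotyped siblings with untyped parents, a
biallelic SNP panel gene-dropped through the families with Haldane
recombination, death ages from a Gompertz baseline, ~70% of subjects
alive at last contact, and recruitment restricted to families whose
members all reached extreme age.  A longevity locus can be planted by
shifting the mean death age of susceptible genotypes at a chosen panel
marker; recruitment then enriches surviving sibships for shared alleles
at that marker, which is exactly the signal a linkage scan hunts for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import (GOMPERTZ_LOCATION, GOMPERTZ_SCALE, LifeTable,
                        gompertz_life_table, sample_death_ages)
from .panel import MarkerPanel
from .pedio import Cohort
from .util import haldane_theta, meiosis_bits, stage_rng

#: sibship-size mix of the full (Category 1) study cohort: 218 pairs,
#: 50 trios, 9 quartets, 2 quintets out of 279 families.
DEFAULT_SIZE_DIST = {2: 218 / 279, 3: 50 / 279, 4: 9 / 279, 5: 2 / 279}

#: recruitment floors on true death age, equal to the loosest extreme-age
#: cutoffs (90 male / 95 female); expected ages at death of living
#: subjects can still fall short of the first category's cutoff, so the
#: first trimming step removes a few percent of sibships.
RECRUIT_FLOOR = {"male": 90.0, "female": 95.0}

#: death ages are truncated at the ceiling of verified human lifespans;
#: the additive frailty + locus-effect model can otherwise wander past it.
DEATH_AGE_CAP = 122.0


@dataclass
class LongevityModel:
    """Genetic architecture of the simulated longevity trait.

    ``effect_years`` shifts the mean death age of susceptible genotypes
    at ``trait_locus`` (dominant: one or more copies of allele "A";
    recessive: two copies).  ``baseline`` is (location, scale) of the
    Gompertz death-age law: location = age of the male upper-5% tail,
    scale = e-folding of the hazard, in years.  ``censor_fraction`` is
    the probability a subject is alive at last contact.  ``frailty_sd``
    (years) is the standard deviation of a shared per-sibship shift in
    death age — the unlinked familial component (polygenes, shared
    environment) that makes siblings of the long-lived long-lived
    themselves; without it, recruited cohorts thin out across the age
    categories far faster than real family studies do.
    """

    trait_locus: str | None = None
    mode: str = "recessive"
    effect_years: float = 0.0
    baseline: tuple = (GOMPERTZ_LOCATION, GOMPERTZ_SCALE)
    censor_fraction: float = 0.7
    frailty_sd: float = 7.0

    def __post_init__(self):
        if self.mode not in ("dominant", "recessive"):
            raise ValueError("mode must be dominant or recessive")
        if self.effect_years < 0:
            raise ValueError("effect_years must be >= 0")
        if not 0.0 <= self.censor_fraction <= 1.0:
            raise ValueError("censor_fraction must lie in [0, 1]")
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be >= 0")


def draw_founder_haplotypes(rng, panel: MarkerPanel, n_founders: int) -> np.ndarray:
    """(n_founders, 2, M) 0/1 alleles; LD blocks copy latent haplotypes."""
    m = panel.n_markers
    freqs = panel.markers["freq"].to_numpy()
    haps = (rng.uniform(size=(n_founders, 2, m)) < freqs).astype(np.int8)
    for block in panel.blocks:
        idx = np.asarray(block["indices"])
        choice = rng.choice(len(block["hap_freqs"]), size=(n_founders, 2),
                            p=block["hap_freqs"])
        alleles = block["haplotypes"][choice]          # (F, 2, L)
        jitter = block["jitter"]
        if jitter > 0:
            flips = rng.uniform(size=alleles.shape) < jitter
            alleles = alleles ^ flips
        haps[:, :, idx] = alleles
    return haps


def drop_through_sibship(rng, panel: MarkerPanel, founder_haps: np.ndarray,
                         child_parents: np.ndarray,
                         fixed_marker: int | None = None,
                         fixed_bits: np.ndarray | None = None) -> np.ndarray:
    """Gene-drop founder haplotypes to children; returns (n, M) genotype codes.

    ``fixed_bits`` (n, 2) conditions each child's paternal/maternal
    meiosis indicator at ``fixed_marker`` (used to extend an accepted
    trait-locus configuration to the whole genome).
    """
    n = len(child_parents)
    m = panel.n_markers
    genos = np.zeros((n, m), dtype=np.int8)
    chrom_col = panel.markers["chrom"].to_numpy()
    cm_col = panel.markers["cm"].to_numpy()
    for chrom in panel.chromosomes:
        idx = np.flatnonzero(chrom_col == chrom)
        local_fix = None
        local_bits = None
        if fixed_marker is not None and chrom_col[fixed_marker] == chrom:
            local_fix = int(np.searchsorted(idx, fixed_marker))
            local_bits = np.concatenate([fixed_bits[:, 0], fixed_bits[:, 1]])
        bits = meiosis_bits(rng, cm_col[idx], 2 * n, local_fix, local_bits)
        pat_bits, mat_bits = bits[:n], bits[n:]
        for c in range(n):
            f, mo = child_parents[c]
            pat = founder_haps[f, :, idx].T[pat_bits[c], np.arange(len(idx))]
            mat = founder_haps[mo, :, idx].T[mat_bits[c], np.arange(len(idx))]
            genos[c, idx] = pat + mat
    return genos


def _susceptible(geno_codes, mode: str) -> np.ndarray:
    if mode == "dominant":
        return geno_codes >= 1
    return geno_codes == 2


def _sibship_structures(rng, n_sibships, size_dist, half_sib_fraction):
    sizes = rng.choice(list(size_dist), size=n_sibships,
                       p=list(size_dist.values()))
    half = rng.uniform(size=n_sibships) < half_sib_fraction
    out = []
    for k, (sz, h) in enumerate(zip(sizes, half)):
        sz = int(sz)
        if h:
            founders = ["p1", "m1", "p2"]
            child_parents = np.array([[0, 1]] * (sz - 1) + [[2, 1]])
        else:
            founders = ["p1", "m1"]
            child_parents = np.array([[0, 1]] * sz)
        out.append((sz, founders, child_parents))
    return out


def simulate_cohort(panel: MarkerPanel, n_sibships: int,
                    size_dist: dict | None = None,
                    model: LongevityModel | None = None,
                    life_table: LifeTable | None = None,
                    seed: int = 0,
                    half_sib_fraction: float = 0.025,
                    previous_fraction: float = 129 / 279) -> Cohort:
    """Simulate a recruited cohort of long-lived sibships.

    Returns a :class:`Cohort`; ``extras`` records per-subject true death
    ages and, when a locus is planted, trait genotypes.  Founder
    recruitment conditions every sibling's true death age on exceeding
    the sex-specific recruitment floor, by exact conditional sampling
    under the null and by rejection sampling when a locus is planted
    (genotype and survival are then dependent).
    """
    if n_sibships < 1:
        raise ValueError("empty cohort requested")
    if size_dist is None:
        size_dist = DEFAULT_SIZE_DIST
    total = sum(size_dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("size distribution must sum to 1")
    if model is None:
        model = LongevityModel()
    if life_table is None:
        life_table = gompertz_life_table(location=model.baseline[0],
                                         scale=model.baseline[1])
    rng = stage_rng(seed, "cohort")
    loc, scale = model.baseline

    trait_idx = None
    if model.trait_locus is not None:
        trait_idx = panel.index_of(model.trait_locus)
        for block in panel.blocks:
            if trait_idx in block["indices"]:
                raise ValueError("trait locus may not sit inside an LD block")

    structures = _sibship_structures(rng, n_sibships, size_dist,
                                     half_sib_fraction)
    subjects = []
    geno_rows = []
    death_ages_all = []
    trait_genos_all = []
    trait_freq = None
    if trait_idx is not None:
        trait_freq = float(panel.markers["freq"].iloc[trait_idx])

    for k, (sz, founders, child_parents) in enumerate(structures):
        sexes = np.where(rng.uniform(size=sz) < 0.28, "male", "female")
        floors = np.array([RECRUIT_FLOOR[s] for s in sexes])
        has_trait = trait_idx is not None and model.effect_years > 0.0
        if not has_trait and model.frailty_sd == 0.0:
            # no within-family dependence: exact conditional sampling
            death = sample_death_ages(rng, sexes, location=loc, scale=scale,
                                      min_age=floors)
            founder_haps = draw_founder_haplotypes(rng, panel, len(founders))
            genos = drop_through_sibship(rng, panel, founder_haps, child_parents)
            trait_g = genos[:, trait_idx] if trait_idx is not None else None
        else:
            death, trait_g, founder_trait, bits = _accept_sibship(
                rng, sz, sexes, floors, child_parents, len(founders),
                trait_freq if has_trait else None, model)
            founder_haps = draw_founder_haplotypes(rng, panel, len(founders))
            if has_trait:
                founder_haps[:, :, trait_idx] = founder_trait
                genos = drop_through_sibship(rng, panel, founder_haps,
                                             child_parents, trait_idx, bits)
            else:
                genos = drop_through_sibship(rng, panel, founder_haps,
                                             child_parents)
                trait_g = genos[:, trait_idx] if trait_idx is not None else None
        death = np.minimum(death, DEATH_AGE_CAP)
        alive = rng.uniform(size=sz) < model.censor_fraction
        recall_gap = rng.exponential(2.5, size=sz)
        alc = np.where(alive, np.maximum(death - recall_gap, 0.0), death)
        sid = f"fam{k + 1}"
        wave = "previous" if rng.uniform() < previous_fraction else "new"
        for c in range(sz):
            subjects.append({
                "iid": f"{sid}_s{c + 1}", "sibship": sid,
                "father": founders[child_parents[c, 0]],
                "mother": founders[child_parents[c, 1]],
                "sex": sexes[c],
                "age_last_contact": float(alc[c]),
                "vital_status": "alive" if alive[c] else "deceased",
                "wave": wave,
            })
        geno_rows.append(genos)
        death_ages_all.append(death)
        if trait_g is not None:
            trait_genos_all.append(trait_g)

    extras = {"death_age": np.concatenate(death_ages_all)}
    if trait_genos_all:
        extras["trait_genotype"] = np.concatenate(trait_genos_all)
        extras["trait_index"] = trait_idx
    cohort = Cohort(pd.DataFrame(subjects), np.vstack(geno_rows), panel, extras)
    cohort.extras["life_table"] = life_table
    return cohort


def _accept_sibship(rng, sz, sexes, floors, child_parents, n_founders,
                    trait_freq, model, batch=1024):
    """Rejection-sample one sibship's death ages (and trait genotypes).

    Joint acceptance on every member exceeding the recruitment floor,
    with death age = Gompertz baseline + shared sibship frailty
    (+ effect_years for susceptible trait genotypes).  Rejection is the
    exact ascertainment law: families with high frailty, or sharing
    longevity alleles, are recruited disproportionately often — the
    phenomenon a sibship linkage design exploits.
    """
    loc, scale = model.baseline
    while True:
        if trait_freq is not None:
            founder_alleles = (rng.uniform(size=(batch, n_founders, 2))
                               < trait_freq).astype(np.int8)
            bits = rng.integers(0, 2, size=(batch, sz, 2), dtype=np.int8)
            pat = founder_alleles[np.arange(batch)[:, None],
                                  child_parents[:, 0][None, :], bits[:, :, 0]]
            mat = founder_alleles[np.arange(batch)[:, None],
                                  child_parents[:, 1][None, :], bits[:, :, 1]]
            trait_g = pat + mat
        base = sample_death_ages(rng, np.tile(sexes, batch),
                                 size=batch * sz, location=loc,
                                 scale=scale).reshape(batch, sz)
        death = base + rng.normal(0.0, model.frailty_sd, size=(batch, 1))
        if trait_freq is not None:
            death = death + model.effect_years * _susceptible(trait_g, model.mode)
        ok = np.flatnonzero((death >= floors).all(axis=1))
        if len(ok):
            i = int(ok[0])
            if trait_freq is not None:
                return death[i], trait_g[i], founder_alleles[i], bits[i]
            return death[i], None, None, None


def drop_sibpair_matrix(panel: MarkerPanel, n_pairs: int, seed: int = 0,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Vectorized null gene drop for many independent sibpairs.

    Returns a (2 * n_pairs, M) genotype matrix (rows 2k, 2k+1 are one
    pair).  Used by calibration experiments that need tens of thousands
    of sibpairs; all pairs are drawn in one batch per chromosome.
    """
    if rng is None:
        rng = stage_rng(seed, "sibpairs")
    m = panel.n_markers
    freqs = panel.markers["freq"].to_numpy()
    genos = np.empty((2 * n_pairs, m), dtype=np.int8)
    chrom_col = panel.markers["chrom"].to_numpy()
    cm_col = panel.markers["cm"].to_numpy()
    for chrom in panel.chromosomes:
        idx = np.flatnonzero(chrom_col == chrom)
        L = len(idx)
        founder = (rng.uniform(size=(n_pairs, 2, 2, L))
                   < freqs[idx]).astype(np.int8)
        theta = haldane_theta(np.diff(cm_col[idx]))
        bits = np.empty((n_pairs, 2, 2, L), dtype=np.int8)  # child, meiosis
        bits[..., 0] = rng.integers(0, 2, size=(n_pairs, 2, 2))
        for t in range(1, L):
            flip = rng.uniform(size=(n_pairs, 2, 2)) < theta[t - 1]
            bits[..., t] = bits[..., t - 1] ^ flip
        pair_idx = np.arange(n_pairs)[:, None]
        t_idx = np.arange(L)[None, :]
        for c in range(2):
            pat = founder[pair_idx, 0, bits[:, c, 0, :], t_idx]
            mat = founder[pair_idx, 1, bits[:, c, 1, :], t_idx]
            genos[c::2][:, idx] = pat + mat
    return genos


def degrade(genotypes: np.ndarray, missing_rate: float, error_rate: float,
            seed: int = 0, return_truth: bool = False):
    """Apply random missingness and allele-substitution errors.

    Returns a new matrix; the input is untouched.  An error flips one of
    the two alleles of a call chosen at random (homozygotes become
    heterozygotes, heterozygotes go either way).  With ``return_truth``
    the planted missing and error masks are also returned, which error-
    detection experiments use as ground truth.
    """
    if not (0 <= missing_rate < 1 and 0 <= error_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = stage_rng(seed, "degrade")
    out = genotypes.copy()
    err_mask = np.zeros(out.shape, dtype=bool)
    if error_rate > 0:
        err_mask = (rng.uniform(size=out.shape) < error_rate) & (out >= 0)
        which = rng.uniform(size=out.shape) < 0.5
        flipped = np.where(out == 1, np.where(which, 0, 2),
                           1)  # 0->1, 2->1, 1->0 or 2
        out = np.where(err_mask, flipped, out).astype(np.int8)
    miss_mask = np.zeros(out.shape, dtype=bool)
    if missing_rate > 0:
        miss_mask = (rng.uniform(size=out.shape) < missing_rate) & (out >= 0)
        out = np.where(miss_mask, np.int8(-1), out)
    if return_truth:
        return out, miss_mask, err_mask & ~miss_mask
    return out
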