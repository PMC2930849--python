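"""Multipoint allele-sharing and parametric linkage for nuclear sibships.

The hidden state at a locus is the inheritance vector: one bit per
meiosis (two per sibling) recording which founder haplotype was
transmitted.  With parents untyped, marker emissions marginalize founder
alleles over population frequencies; LD clusters emit joint haplotypes
with zero internal recombination.  A forward-backward pass over the
ordered loci of each chromosome (Haldane map function, no interference)
yields posteriors over inheritance vectors at every locus, from which
the module computes

* Whittemore-Halpern S_all scores and their exact null moments,
* the Kong-Cox exponential-model allele-sharing LOD with its excess
  sharing parameter delta (one-sided by default),
* conventional parametric LOD and heterogeneity LOD (hLOD, admixture
  parameter alpha) under dominant/recessive single-locus models whose
  phenocopy rate is one-tenth the trait prevalence, and
* per-call genotype-error posteriors against flanking-marker evidence
  ("close double crossovers"), with wiping of implausible calls.

Sibships sharing a pedigree structure are processed as one numpy batch;
this is what makes thousand-replicate gene-dropping runs tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MarkerPanel
from .pedio import Cohort, Sibship
from .util import haldane_theta


class InconsistentGenotypesError(ValueError):
    """Zero likelihood at every inheritance vector: an unremoved error."""


# ---------------------------------------------------------------------------
# loci: SNPs and clusters unified into one multiallelic locus sequence

@dataclass
class Locus:
    chrom: object
    cm: float
    label: str
    freqs: np.ndarray                    # (h,) allele/haplotype frequencies
    snp_index: int | None = None         # set for plain SNP loci
    member_indices: list | None = None   # set for cluster loci
    haplotypes: np.ndarray | None = None  # (h, L) bit patterns for clusters


def build_loci(panel: MarkerPanel, clusters: list | None = None,
               max_alleles: int = 8, min_hap_freq: float = 1e-3,
               sample_freqs: np.ndarray | None = None) -> list:
    """Ordered evaluation loci: unclustered SNPs plus cluster pseudo-markers.

    ``sample_freqs`` overrides panel allele frequencies (used when
    founder frequencies are estimated from the sample instead of
    supplied).  Cluster haplotype alphabets are pruned to the
    ``max_alleles`` most frequent haplotypes above ``min_hap_freq``.
    """
    clusters = clusters or []
    freqs_col = (panel.markers["freq"].to_numpy()
                 if sample_freqs is None else np.asarray(sample_freqs))
    clustered = set()
    for c in clusters:
        clustered.update(c.indices)
    loci = []
    for j in range(panel.n_markers):
        if j in clustered:
            continue
        p = float(freqs_col[j])
        loci.append(Locus(
            chrom=panel.markers["chrom"].iloc[j],
            cm=float(panel.markers["cm"].iloc[j]),
            label=str(panel.markers["marker"].iloc[j]),
            freqs=np.array([1.0 - p, p]),
            snp_index=j,
        ))
    for c in clusters:
        if c.hap_freqs is None:
            raise ValueError("cluster haplotype frequencies not fitted")
        order = np.argsort(c.hap_freqs)[::-1]
        keep = [i for i in order[:max_alleles] if c.hap_freqs[i] >= min_hap_freq]
        if len(keep) < 2:
            keep = list(order[:2])
        f = c.hap_freqs[keep]
        loci.append(Locus(
            chrom=c.chrom, cm=float(c.cm), label=str(c.marker_ids[0]),
            freqs=f / f.sum(),
            member_indices=list(c.indices),
            haplotypes=c.haplotypes[keep],
        ))
    loci.sort(key=lambda L: (_chrom_key(L.chrom), L.cm, L.label))
    return loci


def _chrom_key(chrom):
    try:
        return (0, int(chrom))
    except (TypeError, ValueError):
        return (1, str(chrom))


# ---------------------------------------------------------------------------
# pedigree structure classes (sibships batched by identical structure)

class FamilyClass:
    """All sibships sharing one pedigree structure, batched.

    Precomputes, for the common structure: the inheritance-vector slot
    maps (which founder haplotype each child receives under each
    vector), the S_all score per vector with its exact null moments, and
    the founder-allele combination table used by emissions.
    """

    def __init__(self, child_parents: np.ndarray, n_founders: int):
        self.child_parents = child_parents
        self.n = len(child_parents)
        self.n_founders = n_founders
        self.n_bits = 2 * self.n
        self.V = 1 << self.n_bits
        v = np.arange(self.V)
        pat_bits = (v[:, None] >> (2 * np.arange(self.n))[None, :]) & 1
        mat_bits = (v[:, None] >> (2 * np.arange(self.n) + 1)[None, :]) & 1
        self.SP = 2 * child_parents[:, 0][None, :] + pat_bits     # (V, n)
        self.SM = 2 * child_parents[:, 1][None, :] + mat_bits
        self.sall = self._sall_scores()
        self.mu = float(self.sall.mean())
        sd = float(self.sall.std())
        self.sigma = sd
        if sd > 0:
            z = (self.sall - self.mu) / sd
        else:
            z = np.zeros(self.V)
        self.z_unique, self.z_class = np.unique(np.round(z, 12),
                                                return_inverse=True)
        self.null_mass = np.bincount(self.z_class,
                                     minlength=len(self.z_unique)) / self.V
        self.z_onehot = np.zeros((self.V, len(self.z_unique)))
        self.z_onehot[np.arange(self.V), self.z_class] = 1.0
        self.z_per_vector = z
        self.rows = []          # (S, n) genotype-row indices
        self.sids = []

    def _sall_scores(self) -> np.ndarray:
        """Whittemore-Halpern S_all per inheritance vector by enumeration."""
        n, V = self.n, self.V
        scores = np.empty(V)
        fact = np.array([math.factorial(k) for k in range(n + 1)])
        n_slots = 2 * self.n_founders
        for v in range(V):
            total = 0.0
            for sel in range(1 << n):
                slots = np.where(((sel >> np.arange(n)) & 1) == 1,
                                 self.SM[v], self.SP[v])
                counts = np.bincount(slots, minlength=n_slots)
                total += fact[counts].prod()
            scores[v] = total / (1 << n)
        return scores

    def signature(self):
        return (self.n_founders, tuple(map(tuple, self.child_parents)))


def family_classes(sibships: list) -> list:
    """Group sibships into batched FamilyClass objects."""
    classes = {}
    for sib in sibships:
        if sib.size < 2:
            raise ValueError(f"sibship {sib.sid}: need >=2 genotyped siblings")
        key = (len(sib.founders), tuple(map(tuple, sib.child_parents)))
        if key not in classes:
            classes[key] = FamilyClass(np.asarray(sib.child_parents),
                                       len(sib.founders))
        classes[key].rows.append(sib.rows)
        classes[key].sids.append(sib.sid)
    out = []
    for cls in classes.values():
        cls.rows = np.asarray(cls.rows)
        out.append(cls)
    return out


# ---------------------------------------------------------------------------
# emissions

_SNP_LUT = np.ones((4, 2, 2))     # index: genotype code (-1 -> 3), a, b
for _g in range(3):
    for _a in range(2):
        for _b in range(2):
            _SNP_LUT[_g, _a, _b] = 1.0 if _a + _b == _g else 0.0


def _combo_table(h: int, n_slots: int) -> np.ndarray:
    """(h^n_slots, n_slots) allele index combinations."""
    grids = np.meshgrid(*([np.arange(h)] * n_slots), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _emission_pass(cls: FamilyClass, freqs: np.ndarray, C: np.ndarray,
                   skip_child: int | None = None) -> np.ndarray:
    """Emission probabilities for a batch of like-structured sibships.

    freqs: (M, h) locus allele frequencies; C: (S, M, n, h, h) per-child
    compatibility P(observed | paternal allele a, maternal allele b).
    Returns (S, M, V).  ``skip_child`` treats one child as untyped.
    """
    S, M, n, h, _ = C.shape
    A = _combo_table(h, 2 * cls.n_founders)           # (K, 2F)
    W = np.ones((M, A.shape[0]))
    for s in range(A.shape[1]):
        W *= freqs[:, A[:, s]]
    E = np.empty((S, M, cls.V))
    for v in range(cls.V):
        acc = np.broadcast_to(W, (S, M, A.shape[0])).copy()
        for c in range(n):
            if c == skip_child:
                continue
            acc *= C[:, :, c, A[:, cls.SP[v, c]], A[:, cls.SM[v, c]]]
        E[:, :, v] = acc.sum(axis=2)
    return E


def _snp_compat(genos: np.ndarray) -> np.ndarray:
    """(S, n, M) codes -> (S, M, n, 2, 2) compatibility tensors."""
    codes = np.where(genos < 0, 3, genos)
    return np.transpose(_SNP_LUT[codes], (0, 2, 1, 3, 4))


def _cluster_compat(genos: np.ndarray, haplotypes: np.ndarray) -> np.ndarray:
    """(S, n, L) member genotypes -> (S, n, h, h) compatibility."""
    sums = haplotypes[:, None, :] + haplotypes[None, :, :]       # (h, h, L)
    g = genos[:, :, None, None, :]
    return ((sums[None, None] == g) | (g < 0)).all(axis=-1).astype(float)


def class_emissions(cls: FamilyClass, genotypes: np.ndarray,
                    loci: list, skip_child: int | None = None) -> np.ndarray:
    """(S, T, V) emissions for one chromosome's loci."""
    S = len(cls.rows)
    T = len(loci)
    E = np.ones((S, T, cls.V))
    snp_pos = [t for t, L in enumerate(loci) if L.snp_index is not None]
    if snp_pos:
        idx = [loci[t].snp_index for t in snp_pos]
        genos = genotypes[cls.rows][:, :, idx]                    # (S, n, M)
        C = _snp_compat(genos)
        freqs = np.stack([loci[t].freqs for t in snp_pos])
        E[:, snp_pos, :] = _emission_pass(cls, freqs, C, skip_child)
    for t, L in enumerate(loci):
        if L.snp_index is not None:
            continue
        genos = genotypes[cls.rows][:, :, L.member_indices]      # (S, n, L)
        C = _cluster_compat(genos, L.haplotypes)[:, None]        # (S,1,n,h,h)
        E[:, [t], :] = _emission_pass(cls, L.freqs[None, :], C, skip_child)
    # a row with zero emission everywhere carries no usable information
    # (e.g. a genotype outside the pruned cluster alphabet): treat the
    # locus as untyped for that sibship rather than zeroing the HMM.
    dead = E.max(axis=2) == 0
    if dead.any():
        E[dead] = 1.0
    return E


# ---------------------------------------------------------------------------
# the inheritance-vector HMM

def _transmit(x: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """One inter-locus transition applied to (S, V) state distributions."""
    if theta == 0:
        return x
    S = x.shape[0]
    y = x.reshape((S,) + (2,) * n_bits)
    for axis in range(1, n_bits + 1):
        y = (1 - theta) * y + theta * np.flip(y, axis=axis)
    return y.reshape(S, -1)


def forward_backward(E: np.ndarray, cm: np.ndarray, n_bits: int):
    """Posteriors (S, T, V), plus forward/backward internals.

    Returns (post, fwd, bwd, log_likelihood (S,)).  ``fwd`` rows are
    normalized filtering distributions, ``bwd`` rows are scaled.
    """
    S, T, V = E.shape
    thetas = haldane_theta(np.diff(cm))
    fwd = np.empty_like(E)
    loglik = np.zeros(S)
    a = E[:, 0, :] / V
    for t in range(T):
        if t:
            a = _transmit(fwd[:, t - 1, :], thetas[t - 1], n_bits) * E[:, t, :]
        c = a.sum(axis=1)
        if (c <= 0).any():
            raise InconsistentGenotypesError(
                "zero likelihood at every inheritance vector")
        loglik += np.log(c)
        fwd[:, t, :] = a / c[:, None]
    bwd = np.empty_like(E)
    bwd[:, T - 1, :] = 1.0
    for t in range(T - 2, -1, -1):
        b = _transmit(bwd[:, t + 1, :] * E[:, t + 1, :], thetas[t], n_bits)
        bwd[:, t, :] = b / np.maximum(b.sum(axis=1), 1e-300)[:, None]
    post = fwd * bwd
    post /= post.sum(axis=2, keepdims=True)
    return post, fwd, bwd, loglik


def inheritance_posteriors(sibship: Sibship, genotypes: np.ndarray,
                           loci: list) -> dict:
    """Posterior over inheritance vectors for one sibship, per chromosome.

    Returns {chrom: (positions cM, posterior (T, V))}; the posterior is
    uniform wherever no genotype is informative.
    """
    cls = family_classes([sibship])[0]
    out = {}
    for chrom, chrom_loci in _by_chrom(loci):
        cm = np.array([L.cm for L in chrom_loci])
        E = class_emissions(cls, genotypes, chrom_loci)
        post, *_ = forward_backward(E, cm, cls.n_bits)
        out[chrom] = (cm, post[0])
    return out


def _by_chrom(loci: list):
    groups = {}
    for L in loci:
        groups.setdefault(L.chrom, []).append(L)
    return sorted(groups.items(), key=lambda kv: _chrom_key(kv[0]))


def sall(sibship: Sibship, vector: int) -> float:
    """Whittemore-Halpern S_all for one inheritance vector (0-indexed bits:
    bit 2c = child c's paternal meiosis, bit 2c+1 maternal)."""
    cls = FamilyClass(np.asarray(sibship.child_parents), len(sibship.founders))
    return float(cls.sall[vector])


# ---------------------------------------------------------------------------
# Kong-Cox exponential allele-sharing LOD

@dataclass
class KongCoxResult:
    positions: pd.DataFrame       # chrom, cm, label
    lod: np.ndarray
    delta: np.ndarray
    zmean: np.ndarray             # NPL-style normalized mean score


def _kc_loglik(masses, deltas: np.ndarray) -> np.ndarray:
    """Total base-10 KC log-likelihood ratio at per-position deltas.

    masses: list of (mass (S,T,K), z (K,), null (K,)); deltas: (T,).
    """
    total = None
    for mass, z, null in masses:
        ez = np.exp(deltas[:, None] * z[None, :])          # (T, K)
        num = np.einsum("stk,tk->st", mass, ez)
        den = null @ ez.T                                   # (T,)
        contrib = np.log10(np.maximum(num, 1e-300)) - np.log10(den)[None, :]
        total = contrib.sum(axis=0) if total is None else total + contrib.sum(axis=0)
    return total


def maximize_kong_cox(masses, delta_max: float = 3.0,
                      delta_min: float = 0.0, coarse_step: float = 0.05,
                      tol: float = 1e-6) -> tuple:
    """(lod (T,), delta_hat (T,)) maximizing the KC likelihood per position.

    Coarse grid then golden-section refinement, vectorized over
    positions.  With the default delta_min = 0 the statistic is
    one-sided; a negative delta_min gives the signed diagnostic version.
    """
    T = masses[0][0].shape[1]
    grid = np.arange(delta_min, delta_max + coarse_step / 2, coarse_step)
    vals = np.stack([_kc_loglik(masses, np.full(T, d)) for d in grid])  # (D,T)
    best = vals.argmax(axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, len(grid) - 1)]
    invphi = (np.sqrt(5.0) - 1) / 2
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1 = _kc_loglik(masses, x1)
    f2 = _kc_loglik(masses, x2)
    it = 0
    while (hi - lo).max() > tol and it < 60:
        take1 = f1 >= f2                 # maximum lies in [lo, x2]
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        f1 = _kc_loglik(masses, x1)
        f2 = _kc_loglik(masses, x2)
        it += 1
    delta = np.where(f1 >= f2, x1, x2)
    lod = _kc_loglik(masses, delta)
    if delta_min >= 0.0:
        # one-sided: the null delta = 0 is always admissible
        delta = np.where(lod > 0, delta, 0.0)
        lod = np.maximum(lod, 0.0)
    return lod, delta


# ---------------------------------------------------------------------------
# parametric models

@dataclass
class ParametricModel:
    """Single-locus affected-only model: full penetrance for susceptible
    genotypes, phenocopy rate K/10, allele frequency fitted to K."""

    mode: str
    prevalence: float
    q: float = field(init=False)
    phenocopy: float = field(init=False)

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        self.q = fit_disease_allele_freq(self.prevalence, self.mode)
        self.phenocopy = self.prevalence / 10.0
        # invariant: implied prevalence reproduces K
        p_sus = (1 - (1 - self.q) ** 2 if self.mode == "dominant"
                 else self.q ** 2)
        implied = p_sus * 1.0 + (1 - p_sus) * self.phenocopy
        assert abs(implied - self.prevalence) < 1e-10

    def penetrance_matrix(self) -> np.ndarray:
        """(2, 2) P(affected | paternal allele a, maternal allele b);
        allele 1 is the susceptibility allele."""
        pen = np.full((2, 2), self.phenocopy)
        if self.mode == "dominant":
            pen[1, :] = 1.0
            pen[:, 1] = 1.0
        else:
            pen[1, 1] = 1.0
        return pen


def fit_disease_allele_freq(prevalence: float, mode: str) -> float:
    """Allele frequency solving K = P_sus + (1 - P_sus) K/10 in (0, 1)."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    p_sus = 0.9 * prevalence / (1.0 - 0.1 * prevalence)
    if not 0 < p_sus < 1:
        raise ValueError("no admissible susceptible-genotype probability")
    if mode == "dominant":
        return 1.0 - math.sqrt(1.0 - p_sus)
    if mode == "recessive":
        return math.sqrt(p_sus)
    raise ValueError("mode must be dominant or recessive")


def affection_weights(cls: FamilyClass, model: ParametricModel) -> np.ndarray:
    """(V,) P(all siblings affected | inheritance vector) marginalized
    over founder disease genotypes at HWE with frequency q."""
    pen = model.penetrance_matrix()
    freqs = np.array([[1 - model.q, model.q]])
    C = np.broadcast_to(pen, (1, 1, cls.n, 2, 2))
    return _emission_pass(cls, freqs, C)[0, 0]


def hlod_curve(family_lod10: np.ndarray, alpha_step: float = 0.01) -> tuple:
    """hLOD and alpha-hat per position from per-family base-10 LODs (F, T).

    hLOD(t) = max_alpha sum_f log10(alpha * 10^lod_f + 1 - alpha);
    grid search refined by one parabolic step.
    """
    F, T = family_lod10.shape
    lr = np.power(10.0, family_lod10)                  # (F, T)
    alphas = np.arange(0.0, 1.0 + alpha_step / 2, alpha_step)
    vals = np.stack([
        np.log10(np.maximum(a * lr + (1 - a), 1e-300)).sum(axis=0)
        for a in alphas
    ])                                                  # (A, T)
    best = vals.argmax(axis=0)
    hlod = vals[best, np.arange(T)]
    alpha = alphas[best]
    # one parabolic refinement where the maximum is interior
    interior = (best > 0) & (best < len(alphas) - 1)
    if interior.any():
        y0 = vals[best[interior] - 1, np.flatnonzero(interior)]
        y1 = vals[best[interior], np.flatnonzero(interior)]
        y2 = vals[best[interior] + 1, np.flatnonzero(interior)]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
        a_ref = alpha[interior] + np.clip(shift, -1, 1) * alpha_step
        a_ref = np.clip(a_ref, 0.0, 1.0)
        rows = np.flatnonzero(interior)
        v_ref = np.log10(np.maximum(a_ref[None, :] * lr[:, rows]
                                    + (1 - a_ref)[None, :], 1e-300)).sum(axis=0)
        improve = v_ref > hlod[rows]
        hlod[rows[improve]] = v_ref[improve]
        alpha[rows] = np.where(improve, a_ref, alpha[rows])
    return np.maximum(hlod, 0.0), alpha


# ---------------------------------------------------------------------------
# the scan driver

def linkage_scan(cohort: Cohort, clusters: list | None = None,
                 prevalence: float | None = None,
                 delta_max: float = 3.0, signed_delta: bool = False,
                 sample_freqs: bool = False,
                 loci: list | None = None) -> pd.DataFrame:
    """Multipoint scan of a cohort at every marker/cluster position.

    Returns a DataFrame with one row per evaluation position carrying
    the Kong-Cox LOD and delta-hat, the normalized mean sharing score
    (NPL-style Z), and — when ``prevalence`` is given — conventional
    parametric LOD, hLOD and alpha-hat under dominant and recessive
    models.
    """
    if loci is None:
        sf = _sample_allele_freqs(cohort) if sample_freqs else None
        loci = build_loci(cohort.panel, clusters, sample_freqs=sf)
    sibs = cohort.sibships()
    classes = family_classes(sibs)
    models = {}
    if prevalence is not None:
        models = {"dom": ParametricModel("dominant", prevalence),
                  "rec": ParametricModel("recessive", prevalence)}

    rows = []
    all_masses = []
    zmean_parts = []
    fam_lods = {m: [] for m in models}
    n_fam = sum(len(c.sids) for c in classes)
    for chrom, chrom_loci in _by_chrom(loci):
        cm = np.array([L.cm for L in chrom_loci])
        chrom_masses = []
        chrom_zbar = np.zeros(len(chrom_loci))
        chrom_fam_lods = {m: [] for m in models}
        for cls in classes:
            E = class_emissions(cls, cohort.genotypes, chrom_loci)
            post, *_ = forward_backward(E, cm, cls.n_bits)
            mass = np.einsum("stv,vk->stk", post, cls.z_onehot)
            chrom_masses.append((mass, cls.z_unique, cls.null_mass))
            chrom_zbar += (post @ cls.z_per_vector).sum(axis=0)
            for name, model in models.items():
                w = affection_weights(cls, model)
                lr = (post @ w) / w.mean()                     # (S, T)
                chrom_fam_lods[name].append(np.log10(np.maximum(lr, 1e-300)))
        all_masses.append(chrom_masses)
        zmean_parts.append(chrom_zbar / math.sqrt(n_fam))
        for name in models:
            fam_lods[name].append(np.vstack(chrom_fam_lods[name]))
        for L in chrom_loci:
            rows.append({"chrom": chrom, "cm": L.cm, "marker": L.label})

    df = pd.DataFrame(rows)
    lod_all, delta_all = [], []
    for chrom_masses in all_masses:
        lod, delta = maximize_kong_cox(
            chrom_masses, delta_max=delta_max,
            delta_min=(-delta_max if signed_delta else 0.0))
        lod_all.append(lod)
        delta_all.append(delta)
    df["zmean"] = np.concatenate(zmean_parts)
    df["lod"] = np.concatenate(lod_all)
    df["delta"] = np.concatenate(delta_all)
    df["n_families"] = n_fam
    for name in models:
        stacked = np.concatenate(fam_lods[name], axis=1)       # (F, T_total)
        df[f"plod_{name}"] = stacked.sum(axis=0)
        hl, al = hlod_curve(stacked)
        df[f"hlod_{name}"] = hl
        df[f"alpha_{name}"] = al
    return df


def _sample_allele_freqs(cohort: Cohort) -> np.ndarray:
    g = cohort.genotypes
    counts = np.where(g >= 0, g, 0).sum(axis=0)
    denom = 2 * (g >= 0).sum(axis=0)
    return np.where(denom > 0, counts / np.maximum(denom, 1), 0.5)


# ---------------------------------------------------------------------------
# genotype-error detection and wiping

def detect_and_wipe_errors(cohort: Cohort, error_prior: float = 0.005,
                           flag_threshold: float = 0.99,
                           max_passes: int = 5) -> tuple:
    """Wipe calls whose error posterior against flanking markers is high.

    For each call, the posterior probability that it is erroneous is
    computed under a per-call error prior by comparing the sibship
    likelihood with the call as observed vs uninformative, conditioning
    on all other markers (the multipoint evidence that exposes close
    double crossovers).  Flagged calls are set to missing; passes repeat
    until no new call is flagged, so the operation is idempotent.
    Mendelian checks are impossible without parental genotypes.

    Returns (cleaned cohort, DataFrame of wiped calls).
    """
    geno = cohort.genotypes.copy()
    loci = build_loci(cohort.panel)
    classes = family_classes(cohort.sibships())
    wiped = []
    for _ in range(max_passes):
        new_wipes = 0
        for chrom, chrom_loci in _by_chrom(loci):
            cm = np.array([L.cm for L in chrom_loci])
            snp_idx = np.array([L.snp_index for L in chrom_loci])
            for cls in classes:
                E = class_emissions(cls, geno, chrom_loci)
                post, fwd, bwd, _ = forward_backward(E, cm, cls.n_bits)
                thetas = haldane_theta(np.diff(cm))
                S, T, V = E.shape
                # leave-one-locus-out prior over vectors at each locus
                prior = np.empty_like(E)
                prior[:, 0, :] = 1.0 / V
                for t in range(1, T):
                    prior[:, t, :] = _transmit(fwd[:, t - 1, :],
                                               thetas[t - 1], cls.n_bits)
                prior *= bwd
                prior /= np.maximum(prior.sum(axis=2, keepdims=True), 1e-300)
                b_obs = np.einsum("stv,stv->st", prior, E)
                for c in range(cls.n):
                    Ec = class_emissions(cls, geno, chrom_loci, skip_child=c)
                    a_c = np.einsum("stv,stv->st", prior, Ec)
                    p_err = (error_prior * a_c) / np.maximum(
                        error_prior * a_c + (1 - error_prior) * b_obs, 1e-300)
                    flag = p_err > flag_threshold
                    if not flag.any():
                        continue
                    for s, t in zip(*np.nonzero(flag)):
                        row = cls.rows[s][c]
                        col = snp_idx[t]
                        if geno[row, col] >= 0:
                            wiped.append({"iid_row": int(row),
                                          "marker": chrom_loci[t].label,
                                          "marker_index": int(col),
                                          "posterior": float(p_err[s, t])})
                            geno[row, col] = -1
                            new_wipes += 1
        if new_wipes == 0:
            break
    cleaned = Cohort(cohort.subjects.copy(), geno, cohort.panel,
                     dict(cohort.extras))
    return cleaned, pd.DataFrame(
        wiped, columns=["iid_row", "marker", "marker_index", "posterior"])
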