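"""Pairwise LD estimation and r²-threshold marker clustering.

With untyped parents, inter-marker LD inflates multipoint allele-sharing
LOD scores, so marker pairs whose r² exceeds 0.16 are merged — together
with all map-intervening markers — into a single multiallelic
pseudo-marker whose alleles are haplotypes with EM-estimated
frequencies.  Haplotype frequencies (and hence r²) are estimated from
unphased genotypes of unrelated subjects by a standard EM from a fixed
uniform start, which makes every estimate deterministic given the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MarkerPanel

EM_TOL = 1e-8
EM_MAX_ITER = 500


def _hap_bits(n_markers: int) -> np.ndarray:
    """(2^L, L) matrix of haplotype allele patterns."""
    h = np.arange(2 ** n_markers)
    return (h[:, None] >> np.arange(n_markers)[None, ::-1]) & 1


def _compat_mask(genos: np.ndarray, bits: np.ndarray) -> np.ndarray:
    """(H, H) boolean: ordered haplotype pair consistent with one genotype row."""
    sums = bits[:, None, :] + bits[None, :, :]          # (H, H, L)
    g = genos[None, None, :]
    return ((sums == g) | (g < 0)).all(axis=2)


def em_haplotype_freqs(genotypes: np.ndarray, return_trajectory: bool = False,
                       start: np.ndarray | None = None):
    """ML haplotype frequencies for unphased genotypes at L <= 16 markers.

    ``genotypes`` is (n_subjects, L) with codes 0/1/2/-1.  Returns a
    frequency vector over all 2^L haplotypes (lexicographic in allele
    patterns, allele "A" = 1).  The log-likelihood is non-decreasing
    across iterations; with ``return_trajectory`` the per-iteration
    log-likelihoods are returned too.
    """
    n, L = genotypes.shape
    H = 2 ** L
    bits = _hap_bits(L)
    patterns, counts = np.unique(genotypes, axis=0, return_counts=True)
    masks = np.array([_compat_mask(p, bits) for p in patterns])  # (P, H, H)
    if (masks.sum(axis=(1, 2)) == 0).any():
        raise ValueError("genotype row incompatible with any haplotype pair")
    f = np.full(H, 1.0 / H) if start is None else np.asarray(start, float)
    traj = []
    ll_prev = -np.inf
    for _ in range(EM_MAX_ITER):
        pair = masks * (f[None, :, None] * f[None, None, :])   # (P, H, H)
        tot = pair.sum(axis=(1, 2))
        ll = float((counts * np.log(np.maximum(tot, 1e-300))).sum())
        traj.append(ll)
        pair /= np.maximum(tot, 1e-300)[:, None, None]
        expected = (counts[:, None] * (pair.sum(axis=2) + pair.sum(axis=1))).sum(axis=0)
        f_new = expected / (2 * counts.sum())
        f = f_new
        if ll - ll_prev < EM_TOL * max(1.0, abs(ll)) and len(traj) > 1:
            break
        ll_prev = ll
    if return_trajectory:
        return f, np.array(traj)
    return f


@dataclass
class LDEstimate:
    marker1: str
    marker2: str
    r_squared: float
    hap_freqs: np.ndarray


def r2_from_hap_freqs(f: np.ndarray) -> float:
    """r² of a two-marker haplotype frequency vector (AB, Ab, aB, ab)...

    Frequencies are ordered lexicographically over (allele at marker 1,
    allele at marker 2) with allele "A" = 1: index 3 = A at both.
    """
    pA = f[2] + f[3]
    pB = f[1] + f[3]
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise ValueError("monomorphic marker: r² undefined")
    d = f[3] - pA * pB
    return float(d * d / denom)


def estimate_r2(genos_pair: np.ndarray, marker1: str = "m1",
                marker2: str = "m2") -> LDEstimate:
    """EM haplotype frequencies and r² for two markers in unrelated subjects."""
    f = em_haplotype_freqs(np.asarray(genos_pair))
    return LDEstimate(marker1, marker2, r2_from_hap_freqs(f), f)


def pairwise_r2(cohort_genotypes: np.ndarray, panel: MarkerPanel,
                unrelated_rows: np.ndarray, window_markers: int = 10,
                window_bp: int = 500_000) -> pd.DataFrame:
    """r² for all marker pairs within a sliding map window per chromosome.

    The window is 500 kb or 10 markers, whichever is larger at each
    marker.  Monomorphic markers (in the unrelated set) are skipped.
    """
    sub = cohort_genotypes[unrelated_rows]
    bp = panel.markers["bp"].to_numpy()
    out = []
    for chrom in panel.chromosomes:
        idx = panel.chrom_indices(chrom)
        for a_pos in range(len(idx) - 1):
            i = idx[a_pos]
            gi = sub[:, i]
            if len(np.unique(gi[gi >= 0])) < 2:
                continue
            b_pos = a_pos + 1
            while b_pos < len(idx):
                j = idx[b_pos]
                within = (b_pos - a_pos <= window_markers
                          or bp[j] - bp[i] <= window_bp)
                if not within:
                    break
                gj = sub[:, j]
                if len(np.unique(gj[gj >= 0])) >= 2:
                    est = estimate_r2(
                        np.column_stack([gi, gj]),
                        panel.markers["marker"].iloc[i],
                        panel.markers["marker"].iloc[j])
                    out.append({"i": int(i), "j": int(j),
                                "marker1": est.marker1, "marker2": est.marker2,
                                "r2": est.r_squared})
                b_pos += 1
    return pd.DataFrame(out, columns=["i", "j", "marker1", "marker2", "r2"])


@dataclass
class MarkerCluster:
    """Map-contiguous markers treated as one multiallelic pseudo-marker."""

    indices: list
    marker_ids: list
    chrom: object
    cm: float
    hap_freqs: np.ndarray | None = None     # over 2^L haplotypes
    haplotypes: np.ndarray | None = field(default=None)  # (H, L) bit patterns

    @property
    def size(self) -> int:
        return len(self.indices)


def build_clusters(panel: MarkerPanel, ld_estimates: pd.DataFrame,
                   threshold: float = 0.16) -> list:
    """Merge pairs with r² strictly above ``threshold`` plus intervening
    markers; chained merges coalesce; singleton markers get no cluster.

    Returns a list of MarkerCluster covering only multi-marker clusters;
    together with the unclustered markers they partition the panel.
    """
    clusters = []
    flagged = ld_estimates[ld_estimates["r2"] > threshold]
    for chrom in panel.chromosomes:
        idx = panel.chrom_indices(chrom)
        lo, hi = idx[0], idx[-1]
        ivals = [(int(r.i), int(r.j)) for r in flagged.itertuples()
                 if lo <= r.i <= hi]
        if not ivals:
            continue
        ivals.sort()
        merged = [list(ivals[0])]
        for a, b in ivals[1:]:
            if a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            members = list(range(a, b + 1))
            cm = panel.markers["cm"].iloc[members].to_numpy()
            assert (np.diff(members) == 1).all()
            clusters.append(MarkerCluster(
                indices=members,
                marker_ids=list(panel.markers["marker"].iloc[members]),
                chrom=chrom,
                cm=float(cm.mean()),
            ))
    return clusters


def cluster_haplotype_freqs(genotypes: np.ndarray, cluster: MarkerCluster,
                            unrelated_rows: np.ndarray,
                            max_markers: int = 6) -> MarkerCluster:
    """Fit EM haplotype frequencies for one cluster; returns a filled copy."""
    if cluster.size > max_markers:
        raise ValueError(
            f"cluster of {cluster.size} markers exceeds the cap of "
            f"{max_markers}; raise max_markers to allow it")
    sub = genotypes[np.asarray(unrelated_rows)][:, cluster.indices]
    f = em_haplotype_freqs(sub)
    return MarkerCluster(cluster.indices, cluster.marker_ids, cluster.chrom,
                         cluster.cm, f, _hap_bits(cluster.size))


def cluster_panel(cohort, seed: int = 0, threshold: float = 0.16,
                  window_markers: int = 10, window_bp: int = 500_000,
                  unrelated_rows: np.ndarray | None = None,
                  max_markers: int = 6) -> list:
    """End-to-end: unrelated set -> pairwise r² -> clusters -> EM frequencies.

    Chained clusters larger than ``max_markers`` — which arise from noisy
    r² estimates when the unrelated sample is small — are split into
    contiguous chunks of at most ``max_markers`` so the pipeline stays
    well-posed at any cohort size; size-1 chunks revert to singletons.
    """
    from .qc import select_unrelated

    if unrelated_rows is None:
        unrelated_rows = select_unrelated(cohort, seed=seed)
    ests = pairwise_r2(cohort.genotypes, cohort.panel, unrelated_rows,
                       window_markers, window_bp)
    clusters = []
    for c in build_clusters(cohort.panel, ests, threshold):
        clusters.extend(_split_cluster(c, cohort.panel, max_markers))
    return [cluster_haplotype_freqs(cohort.genotypes, c, unrelated_rows,
                                    max_markers)
            for c in clusters]


def _split_cluster(cluster: MarkerCluster, panel: MarkerPanel,
                   max_markers: int) -> list:
    if cluster.size <= max_markers:
        return [cluster]
    out = []
    n_chunks = -(-cluster.size // max_markers)
    for chunk in np.array_split(np.asarray(cluster.indices), n_chunks):
        if len(chunk) < 2:
            continue
        members = [int(i) for i in chunk]
        cm = panel.markers["cm"].iloc[members].to_numpy()
        out.append(MarkerCluster(
            indices=members,
            marker_ids=list(panel.markers["marker"].iloc[members]),
            chrom=cluster.chrom, cm=float(cm.mean())))
    return out


def write_clusters(clusters: list, path) -> None:
    """One line per cluster: whitespace-separated member marker ids."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(" ".join(c.marker_ids) + "\n")


def read_clusters(path, panel: MarkerPanel) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            ids = line.split()
            if not ids:
                continue
            indices = [panel.index_of(m) for m in ids]
            if indices != list(range(indices[0], indices[-1] + 1)):
                raise ValueError(f"cluster {ids} is not map-contiguous")
            cm = panel.markers["cm"].iloc[indices].to_numpy()
            out.append(MarkerCluster(indices, ids,
                                     panel.markers["chrom"].iloc[indices[0]],
                                     float(cm.mean())))
    return out
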