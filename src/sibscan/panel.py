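"""Marker panels: ordered biallelic SNP maps with allele frequencies.

A :class:`MarkerPanel` is a thin wrapper around a DataFrame with one row
per marker (id, chromosome, bp, cM, frequency of allele "A").  Panels
can be simulated with a target mean minor-allele frequency and optional
LD blocks in which markers are copies of a small set of latent
haplotypes, which guarantees strong pairwise r² inside each block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["marker", "chrom", "bp", "cm", "freq"]

# physical positions are cosmetic; 1 cM ~ 1 Mb on the human sex-averaged map
BP_PER_CM = 1_000_000


@dataclass
class LDSpec:
    """Latent-haplotype LD blocks planted in a simulated panel.

    Every ``spacing``-th run of ``block_size`` consecutive markers on a
    chromosome forms a block.  Alleles inside a block are generated by
    copying one of ``n_haplotypes`` latent haplotypes and flipping each
    allele independently with probability ``jitter``; with the default
    two haplotypes and small jitter every polymorphic pair inside a
    block has r² well above the 0.16 clustering threshold.
    """

    block_size: int = 3
    spacing: int = 10
    n_haplotypes: int = 2
    jitter: float = 0.03


@dataclass
class MarkerPanel:
    markers: pd.DataFrame
    blocks: list = field(default_factory=list)  # list of dicts, see simulate_panel

    def __post_init__(self):
        df = self.markers
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        if df["marker"].duplicated().any():
            raise ValueError("duplicate marker ids")
        for _, grp in df.groupby("chrom", sort=False):
            if (np.diff(grp["cm"].to_numpy()) < 0).any():
                raise ValueError("cM positions must be non-decreasing per chromosome")
        f = df["freq"].to_numpy()
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        self.markers = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.markers["marker"] == marker_id).to_numpy())
        if len(hits) == 0:
            raise KeyError(f"marker {marker_id!r} not in panel")
        return int(hits[0])

    def mean_maf(self) -> float:
        f = self.markers["freq"].to_numpy()
        return float(np.minimum(f, 1 - f).mean())

    def subset(self, indices) -> "MarkerPanel":
        indices = np.asarray(indices)
        keep = self.markers.iloc[indices].reset_index(drop=True)
        old_to_new = {int(o): n for n, o in enumerate(indices)}
        blocks = []
        for b in self.blocks:
            new_idx = [old_to_new[i] for i in b["indices"] if int(i) in old_to_new]
            if len(new_idx) >= 2:
                keep_cols = [list(b["indices"]).index(i) for i in b["indices"]
                             if int(i) in old_to_new]
                blocks.append({
                    "indices": new_idx,
                    "haplotypes": b["haplotypes"][:, keep_cols],
                    "hap_freqs": b["hap_freqs"],
                    "jitter": b["jitter"],
                })
        return MarkerPanel(keep, blocks)


def simulate_panel(n_markers: int, chromosomes, maf_mean: float = 0.27,
                   ld_spec: LDSpec | None = None, seed=0) -> MarkerPanel:
    """Simulate a biallelic panel over chromosomes of given cM lengths.

    Markers are spread uniformly at random along each chromosome
    (strictly increasing cM), allocated to chromosomes proportionally to
    length.  Minor allele frequencies are drawn from a Beta distribution
    rescaled to (0, 0.5] whose mean equals ``maf_mean``.
    """
    if n_markers < 2:
        raise ValueError("need at least two markers")
    lengths = np.asarray(chromosomes, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    if not 0 < maf_mean <= 0.5:
        raise ValueError("maf_mean must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)

    # proportional allocation, at least 2 markers per chromosome
    alloc = np.maximum(2, np.round(n_markers * lengths / lengths.sum()).astype(int))
    while alloc.sum() > n_markers:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_markers:
        alloc[np.argmin(alloc)] += 1

    rows = []
    for ci, (length, k) in enumerate(zip(lengths, alloc)):
        cm = np.sort(rng.uniform(0.0, length, size=k))
        # enforce strict increase at float resolution
        cm += np.arange(k) * 1e-9
        for j, pos in enumerate(cm):
            rows.append({
                "marker": f"rs{ci + 1}_{j + 1}",
                "chrom": ci + 1,
                "bp": int(round(pos * BP_PER_CM)) + 1,
                "cm": float(pos),
                "freq": np.nan,
            })
    df = pd.DataFrame(rows)

    # MAF ~ maf_mean * Beta(2, 2) * 2 clipped into (0.01, 0.5); mean ~ maf_mean
    maf = maf_mean * 2.0 * rng.beta(2.0, 2.0, size=len(df))
    maf = np.clip(maf, 0.01, 0.5)
    # allele "A" is the minor or major allele at random
    flip = rng.uniform(size=len(df)) < 0.5
    df["freq"] = np.where(flip, maf, 1.0 - maf)

    blocks = []
    if ld_spec is not None:
        for chrom in df["chrom"].unique():
            idx = np.flatnonzero((df["chrom"] == chrom).to_numpy())
            start = 0
            while start + ld_spec.block_size <= len(idx):
                members = idx[start:start + ld_spec.block_size]
                haps = _latent_haplotypes(rng, ld_spec)
                hap_freqs = _haplotype_freqs(rng, ld_spec.n_haplotypes)
                # implied marker frequencies (allele "A" = allele 1)
                p1 = hap_freqs @ haps
                p1 = p1 * (1 - ld_spec.jitter) + (1 - p1) * ld_spec.jitter
                df.loc[members, "freq"] = p1
                blocks.append({
                    "indices": [int(i) for i in members],
                    "haplotypes": haps,
                    "hap_freqs": hap_freqs,
                    "jitter": ld_spec.jitter,
                })
                start += ld_spec.spacing
    return MarkerPanel(df, blocks)


def _latent_haplotypes(rng, spec: LDSpec) -> np.ndarray:
    """(H, L) matrix of 0/1 alleles; first two haplotypes forced to differ
    at every site so the block is polymorphic and internally correlated."""
    haps = rng.integers(0, 2, size=(spec.n_haplotypes, spec.block_size))
    haps[1] = 1 - haps[0]
    return haps.astype(np.int8)


def _haplotype_freqs(rng, n: int) -> np.ndarray:
    f = rng.dirichlet(np.full(n, 5.0))
    f = np.clip(f, 0.15, None)
    return f / f.sum()


def write_map(panel: MarkerPanel, path) -> None:
    """PLINK MAP: chromosome, marker id, genetic position (cM), bp."""
    with open(path, "w") as fh:
        for row in panel.markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.marker}\t{row.cm:.6f}\t{row.bp}\n")


def read_map(path) -> MarkerPanel:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "marker", "cm", "bp"])
    df["freq"] = 0.5  # frequencies are not part of MAP; caller overrides
    return MarkerPanel(df[PANEL_COLUMNS])
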