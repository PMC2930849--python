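"""Pipeline orchestration: groups x categories scans, peaks, stability.

This ties the stages together the way a full study runs them: phenotype
construction -> category trimming -> QC -> LD clustering -> multipoint
linkage per analysis group (Total, recruitment-wave subgroups Previous/
New, and the gender-composition subgroups MC/FO), with "Overall"
maxima taken across categories.  The library functions here, driven by
a plain configuration mapping, are the package's command surface; see
the examples directory for narrative usage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .ldcluster import cluster_panel
from .linkage import linkage_scan
from .pedio import Cohort
from .peaks import Peak
from .phenotype import (add_expected_age, assign_categories, default_scheme,
                        subgroup_rows, trim_cohort)
from .qc import apply_qc

GROUPS = ("Total", "Previous", "New", "MC", "FO")


@dataclass
class ScanConfig:
    """Defaults for every tunable the pipeline exposes."""

    categories: tuple = tuple(range(1, 11))
    groups: tuple = ("Total",)
    sample_call_rate: float = 0.95
    snp_call_rate: float = 0.90
    hwe_p: float = 1e-3
    rsq_threshold: float = 0.16
    ld_window_markers: int = 10
    ld_window_bp: int = 500_000
    delta_max: float = 3.0
    parametric: bool = True
    mc_fo_per_category: bool = False   # re-evaluate MC/FO within each category
    peak_min_lod: float = 3.0
    single_scan_lod: float = 3.6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ScanResult:
    curves: dict                  # (group, category) -> scan DataFrame
    membership: pd.DataFrame
    qc_report: object
    clusters: list
    config: ScanConfig

    def overall_max(self, group: str = "Total") -> pd.Series:
        """The maximum-LOD row across this group's categories."""
        best = None
        for (g, k), curve in self.curves.items():
            if g != group or curve.empty:
                continue
            row = curve.loc[curve["lod"].idxmax()].copy()
            row["category"] = k
            if best is None or row["lod"] > best["lod"]:
                best = row
        return best

    def category_maxima(self, group: str = "Total") -> pd.DataFrame:
        rows = []
        for (g, k), curve in self.curves.items():
            if g != group or curve.empty:
                continue
            row = curve.loc[curve["lod"].idxmax()]
            rows.append({"category": k, "chrom": row["chrom"],
                         "cm": row["cm"], "marker": row["marker"],
                         "lod": row["lod"]})
        return pd.DataFrame(rows).sort_values("category").reset_index(drop=True)


def run_scan(cohort: Cohort, life_table, config: ScanConfig | None = None,
             scheme=None, skip_qc: bool = False) -> ScanResult:
    """Run the full pipeline on a cohort for requested groups x categories.

    Categories that trim to nothing are skipped with a warning.  The
    parametric models' trait prevalence for category k is the category's
    birth-cohort tail fraction.
    """
    import warnings

    if config is None:
        config = ScanConfig()
    if scheme is None:
        scheme = default_scheme()
    cohort = add_expected_age(cohort, life_table)
    if skip_qc:
        qc_report = None
    else:
        cohort, qc_report = apply_qc(
            cohort, config.sample_call_rate, config.hwe_p,
            config.snp_call_rate, seed=config.seed)
    membership = assign_categories(cohort.subjects, scheme)
    clusters = cluster_panel(cohort, seed=config.seed,
                             threshold=config.rsq_threshold,
                             window_markers=config.ld_window_markers,
                             window_bp=config.ld_window_bp)
    curves = {}
    for group in config.groups:
        rows = subgroup_rows(
            cohort, group,
            membership=membership if group in ("MC", "FO") else None)
        sub = cohort.subset_subjects(rows) if group != "Total" else cohort
        for k in config.categories:
            mc_fo_cat = k if (config.mc_fo_per_category
                              and group in ("MC", "FO")) else 1
            if group in ("MC", "FO") and config.mc_fo_per_category:
                rows_k = subgroup_rows(cohort, group, membership=membership,
                                       mc_fo_category=mc_fo_cat)
                sub = cohort.subset_subjects(rows_k)
            trimmed = trim_cohort(sub, membership, k)
            if trimmed.n_subjects == 0:
                warnings.warn(f"group {group}, category {k}: empty after "
                              "trimming; curve skipped", stacklevel=2)
                continue
            prevalence = scheme.tail_fraction[k - 1] if config.parametric else None
            curve = linkage_scan(trimmed, clusters=clusters,
                                 prevalence=prevalence,
                                 delta_max=config.delta_max)
            curve.insert(0, "category", k)
            curve.insert(0, "group", group)
            curves[(group, k)] = curve
    return ScanResult(curves, membership, qc_report, clusters, config)


def write_scan_tsv(result: ScanResult, path) -> None:
    frames = [c for c in result.curves.values() if not c.empty]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.6g")


def split_panel_check(cohort: Cohort, peak: Peak, clusters=None,
                      margin_cm: float = 0.0) -> dict:
    """Every-other-SNP stability check for one linkage peak.

    The panel is split into the odd- and even-indexed marker subsets
    (which partition it); the peak's chromosome is re-scanned with each
    half and the maximum LOD within the peak's -2 LOD support interval
    (optionally widened by ``margin_cm``) reported for both halves.
    """
    lo, hi = peak.support_2lod[0] - margin_cm, peak.support_2lod[1] + margin_cm
    out = {}
    for parity, name in ((0, "even"), (1, "odd")):
        half = cohort.subset_markers(np.arange(parity, cohort.panel.n_markers, 2))
        chrom_cols = half.panel.chrom_indices(peak.chrom)
        sub = half.subset_markers(chrom_cols)
        curve = linkage_scan(sub)
        window = curve[(curve["cm"] >= lo) & (curve["cm"] <= hi)]
        out[name] = float(window["lod"].max()) if len(window) else 0.0
    return out
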