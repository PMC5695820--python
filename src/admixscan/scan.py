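"""Genome scan of local-ancestry interval (LAI) counts.

Each LAI is tested by regressing the trait on the count (0/1/2) of
chromosome copies of a given ancestry, against the baseline of the other
ancestries, under the null mixed model (variance components held fixed).
A joint test models the counts of two ancestries as two columns and tests
the 2-df hypothesis that both effects are null. Significant LAIs are
merged into association regions when adjacent on a chromosome; the
genome-wide significance threshold for this design is 5.68e-5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import MixedModelResults
from .simulate import LocalAncestryMatrix

# Genome-wide significance level for admixture mapping in this cohort
# design (autocorrelation-based estimate of the effective number of LAIs).
GENOMEWIDE_ADMIXTURE_THRESHOLD = 5.68e-5


@dataclass
class AssociationRegion:
    """A run of contiguous genome-wide-significant LAIs for one ancestry."""

    trait: str
    ancestry: str
    chrom: str
    start: int
    end: int
    lead_start: int
    lead_end: int
    lead_p: float
    n_intervals: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def scan_ancestry(
    la: LocalAncestryMatrix,
    ancestry: str | int,
    null: MixedModelResults,
    trait: str = "trait",
) -> pd.DataFrame:
    """1-df scan of one ancestry's LAI counts against all other ancestries.

    Returns one row per LAI with coordinates, the tested-ancestry
    frequency (proportion of the 2n chromosomes), effect, SE, and
    p-value. Monomorphic LAIs (ancestry frequency 0 or 1) are emitted
    with NaN statistics and ``monomorphic=True`` rather than dropped.
    """
    if la.n_individuals != null.nobs:
        raise ValueError("null model fitted on a different number of individuals")
    label = ancestry if isinstance(ancestry, str) else la.ancestries[ancestry]
    counts = la.ancestry_counts(ancestry)
    res = null.batch_test(counts)
    out = la.intervals.copy()
    out["trait"] = trait
    out["ancestry"] = label
    out["ancestry_freq"] = counts.sum(axis=0) / (2 * la.n_individuals)
    for col in ("effect", "se", "stat", "p", "monomorphic"):
        out[col] = res[col].to_numpy()
    out["df"] = 1
    return out


def scan_joint(
    la: LocalAncestryMatrix,
    ancestries: tuple,
    null: MixedModelResults,
    trait: str = "trait",
) -> pd.DataFrame:
    """Joint 2-df scan of two ancestries' LAI counts.

    The two count columns are modelled together and tested against the
    2-df null hypothesis that both ancestry effects are zero (baseline:
    both copies from the remaining ancestries). Note the three count
    columns sum to 2, so testing all three is a collinearity error.
    """
    from .lmm import CollinearityError

    if len(ancestries) != 2:
        raise ValueError("joint scan takes exactly two ancestries")
    la1, la2 = ancestries
    label1 = la1 if isinstance(la1, str) else la.ancestries[la1]
    label2 = la2 if isinstance(la2, str) else la.ancestries[la2]
    c1 = la.ancestry_counts(la1)
    c2 = la.ancestry_counts(la2)
    rows = []
    for j in range(la.n_intervals):
        g = np.column_stack([c1[:, j], c2[:, j]])
        if g[:, 0].var() == 0 or g[:, 1].var() == 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, np.nan, True))
            continue
        try:
            t = null.test_fixed_effect(g, names=[label1, label2])
            rows.append((t.effect[0], t.effect[1], t.stat, t.p, t.df, False))
        except CollinearityError:
            rows.append((np.nan, np.nan, np.nan, np.nan, np.nan, True))
    out = la.intervals.copy()
    out["trait"] = trait
    out["ancestry"] = f"{label1}+{label2}"
    out["ancestry_freq"] = (c1.sum(axis=0) + c2.sum(axis=0)) / (2 * la.n_individuals)
    arr = np.array([r[:5] for r in rows], dtype=float)
    for i, col in enumerate(("effect_1", "effect_2", "stat", "p")):
        out[col] = arr[:, i]
    out["monomorphic"] = np.array([r[5] for r in rows], dtype=bool)
    out["df"] = 2
    return out


def significant_regions(
    scan: pd.DataFrame,
    threshold: float = GENOMEWIDE_ADMIXTURE_THRESHOLD,
) -> list[AssociationRegion]:
    """Merge genome-wide-significant LAIs into association regions.

    LAIs with p < threshold are merged when adjacent (consecutive
    intervals, no gap tolerance) on the same chromosome; the lead LAI is
    the most significant member, ties broken by leftmost start. Regions
    come back disjoint and sorted.
    """
    regions: list[AssociationRegion] = []
    scan = scan.sort_values(["chrom", "start"]).reset_index()
    sig = scan["p"] < threshold
    run: list[int] = []

    def close(run):
        block = scan.loc[run]
        lead = block.sort_values(["p", "start"]).iloc[0]
        regions.append(
            AssociationRegion(
                trait=str(block["trait"].iloc[0]),
                ancestry=str(block["ancestry"].iloc[0]),
                chrom=str(block["chrom"].iloc[0]),
                start=int(block["start"].min()),
                end=int(block["end"].max()),
                lead_start=int(lead["start"]),
                lead_end=int(lead["end"]),
                lead_p=float(lead["p"]),
                n_intervals=len(block),
            )
        )

    for i in range(len(scan)):
        if sig.iloc[i]:
            if run and not (
                scan.loc[run[-1], "chrom"] == scan.loc[i, "chrom"] and i == run[-1] + 1
            ):
                close(run)
                run = []
            run.append(i)
        elif run:
            close(run)
            run = []
    if run:
        close(run)
    return regions


def effective_num_tests(trait_corr, variance_fraction: float = 0.995) -> int:
    """Effective number of independent traits (simpleM).

    The smallest m such that the m largest eigenvalues of the trait
    correlation matrix capture at least ``variance_fraction`` of the
    total variance (99.5% is the published simpleM default).
    """
    C = np.asarray(trait_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(C)
    if eigvals.min() < -1e-8 * eigvals.max():
        raise ValueError("correlation matrix is not positive semi-definite")
    eigvals = np.sort(np.clip(eigvals, 0, None))[::-1]
    frac = np.cumsum(eigvals) / eigvals.sum()
    return int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)


def regions_to_bed(regions: list[AssociationRegion], path) -> None:
    """Write association regions as 0-based half-open BED."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.trait}:{r.ancestry}\t{r.lead_p:.3g}\n")


def manhattan_plot(scan: pd.DataFrame, path, threshold: float = GENOMEWIDE_ADMIXTURE_THRESHOLD) -> None:
    """-log10(p) against interval midpoint, with the significance line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    mid = (scan["start"] + scan["end"]) / 2
    ax.scatter(mid, -np.log10(scan["p"]), s=8, c="steelblue")
    ax.axhline(-np.log10(threshold), ls="--", c="grey")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{scan['trait'].iloc[0]} / {scan['ancestry'].iloc[0]}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
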