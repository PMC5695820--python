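"""Fine-mapping of admixture-mapping association regions.

The workflow for a significant region:

1. restrict to variants within the region's significant LAIs and collect
   their association p-values in three analyses (all groups combined,
   Mainland-only, Caribbean-only meta-analyses);
2. walk a candidate ladder from stringent to lenient p-value rungs
   (1e-6 ... 1e-2); at the lenient rungs (1e-3, 1e-2) a variant is
   admitted only if its effect-allele frequency differs sufficiently
   between the analysis groups with the highest and lowest proportion of
   the tested ancestry (decreasing relaxation 0.2, 0.15, 0.1, 0.05) —
   large group-EAF differences proxy ancestral frequency differences,
   the signal admixture mapping keys on;
3. prune admitted candidates to lead variants: single-linkage connected
   components at |Pearson r| > 0.4 between dosages, keeping the smallest
   p per component;
4. re-run the admixture scan with the lead dosages as fixed covariates
   (conditional scan) and classify how much of the LAI signal they
   explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .lmm import MixedModelResults
from .scan import GENOMEWIDE_ADMIXTURE_THRESHOLD, AssociationRegion, scan_ancestry
from .simulate import GenotypeMatrix, LocalAncestryMatrix


@dataclass(frozen=True)
class LadderSpec:
    """Candidate-admission ladder.

    ``p_rungs`` are walked from most to least stringent; rungs at or
    below ``eaf_filter_from`` admit on p alone, the lenient rungs require
    a group-EAF difference of at least the current relaxation value
    between the designated high/low-ancestry group pair.
    """

    p_rungs: tuple[float, ...] = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
    eaf_relaxation: tuple[float, ...] = (0.2, 0.15, 0.1, 0.05)
    eaf_filter_from: float = 1e-3
    high_group: str = "Mexican"
    low_group: str = "Cuban"

    def __post_init__(self):
        if list(self.p_rungs) != sorted(self.p_rungs):
            raise ValueError("p-value rungs must be increasing")
        rel = list(self.eaf_relaxation)
        if rel != sorted(rel, reverse=True) or not all(0 < d < 1 for d in rel):
            raise ValueError("EAF relaxations must be decreasing and in (0, 1)")

    def steps(self):
        """Ordered (p_rung, min_delta_eaf) admission steps."""
        strict = [(r, None) for r in self.p_rungs if r < self.eaf_filter_from]
        lenient_rungs = [r for r in self.p_rungs if r >= self.eaf_filter_from]
        lenient = [(r, d) for d in self.eaf_relaxation for r in lenient_rungs]
        return strict + lenient


def group_eaf(gm: GenotypeMatrix, groups) -> pd.DataFrame:
    """Effect-allele frequency per variant per analysis group.

    EAF = mean dosage / 2 within the group; an empty group yields NaN.
    """
    groups = pd.Series(np.asarray(groups), name="group")
    if len(groups) != gm.n_individuals:
        raise ValueError("group labels misaligned with genotypes")
    out = {}
    for name, idx in groups.groupby(groups).groups.items():
        sub = gm.dosages[np.asarray(idx, dtype=int), :]
        out[name] = sub.mean(axis=0) / 2.0 if len(idx) else np.full(gm.n_variants, np.nan)
    return pd.DataFrame(out, index=gm.variants["name"])


def candidate_ladder(
    assoc: pd.DataFrame,
    region: AssociationRegion | tuple[int, int] | None,
    eafs: pd.DataFrame,
    spec: LadderSpec = LadderSpec(),
    accumulate: bool = False,
) -> pd.DataFrame:
    """Step-wise candidate-variant selection within an association region.

    Parameters
    ----------
    assoc : DataFrame
        One row per variant with columns ``variant``, ``position`` and
        p-values ``p_overall``, ``p_mainland``, ``p_caribbean`` (missing
        analysis columns are ignored).
    region : AssociationRegion or (start, end) or None
        Variants are restricted to [start, end); ``None`` keeps all.
    eafs : DataFrame
        Group EAFs indexed by variant name, with the ladder's high/low
        group columns.
    accumulate : bool
        By default the search stops after the first completed step that
        admits at least one candidate; ``True`` walks the entire ladder.

    Returns a table of admitted candidates with the admitting rung,
    analysis, and EAF difference.
    """
    df = assoc.copy()
    if region is not None:
        start, end = (region.start, region.end) if isinstance(region, AssociationRegion) else region
        df = df[(df["position"] >= start) & (df["position"] < end)]
    if len(df) == 0:
        warnings.warn("no variants within the association region")
        return _empty_candidates()

    p_cols = [c for c in ("p_overall", "p_mainland", "p_caribbean") if c in df.columns]
    if not p_cols:
        raise ValueError("association table lacks p-value columns")
    delta = (eafs[spec.high_group] - eafs[spec.low_group]).reindex(df["variant"]).to_numpy()

    admitted: dict[str, dict] = {}
    for rung, min_delta in spec.steps():
        pass_p = df[p_cols].lt(rung)
        qualifies = pass_p.any(axis=1).to_numpy()
        if min_delta is not None:
            qualifies &= np.abs(delta) >= min_delta
        for i in np.flatnonzero(qualifies):
            row = df.iloc[i]
            if row["variant"] in admitted:
                continue
            which = pass_p.iloc[i]
            analysis = [c.removeprefix("p_") for c in p_cols if which[c]]
            admitted[row["variant"]] = {
                "variant": row["variant"],
                "position": row["position"],
                "p_min": float(row[p_cols].min()),
                "admitting_analysis": ",".join(analysis),
                "rung": rung,
                "min_delta_eaf": np.nan if min_delta is None else min_delta,
                "delta_eaf": float(delta[i]) if np.isfinite(delta[i]) else np.nan,
                "eaf_high": float(eafs.loc[row["variant"], spec.high_group]),
                "eaf_low": float(eafs.loc[row["variant"], spec.low_group]),
            }
        if admitted and not accumulate:
            break
    if not admitted:
        return _empty_candidates()
    out = pd.DataFrame(list(admitted.values())).sort_values("position").reset_index(drop=True)
    out["lead"] = False
    return out


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "variant", "position", "p_min", "admitting_analysis", "rung",
            "min_delta_eaf", "delta_eaf", "eaf_high", "eaf_low", "lead",
        ]
    )


def prune_by_correlation(candidates: pd.DataFrame, gm: GenotypeMatrix, r_max: float = 0.4) -> pd.DataFrame:
    """Prune candidates to lead variants via correlation clustering.

    Builds a graph with an edge wherever |Pearson r| of dosages exceeds
    ``r_max``; within each connected component the variant with the
    smallest p leads (ties: smallest position). Leads are pairwise
    |r| <= r_max. Zero-variance dosages have undefined correlation and
    are treated as unlinked.
    """
    if len(candidates) == 0:
        return candidates
    names = list(candidates["variant"])
    D = np.column_stack([gm.dosage(n) for n in names])
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(D, rowvar=False)
    R = np.atleast_2d(R)
    adj = np.abs(R) > r_max
    np.fill_diagonal(adj, False)
    adj[~np.isfinite(R)] = False
    _, labels = connected_components(csr_matrix(adj), directed=False)
    out = candidates.copy().reset_index(drop=True)
    out["component"] = labels
    out["lead"] = False
    for comp in np.unique(labels):
        members = out[out["component"] == comp]
        lead_idx = members.sort_values(["p_min", "position"]).index[0]
        out.loc[lead_idx, "lead"] = True
    return out


def conditional_scan(
    la: LocalAncestryMatrix,
    ancestry: str | int,
    lead_dosages: np.ndarray,
    null: MixedModelResults,
    trait: str = "trait",
    lead_names: list[str] | None = None,
) -> pd.DataFrame:
    """Admixture scan adjusted for candidate-variant dosages.

    Re-runs the 1-df LAI scan with the lead dosages as additional fixed
    covariates (variance components held at the null fit) and reports,
    per LAI, the primary and conditional p-values and their -log10
    attenuation. Leads collinear with the existing design are dropped
    with a warning and listed in ``.attrs['dropped']``.
    """
    primary = scan_ancestry(la, ancestry, null, trait=trait)
    cond_null = null.with_covariates(np.atleast_2d(lead_dosages), names=lead_names)
    conditional = scan_ancestry(la, ancestry, cond_null, trait=trait)
    out = primary.rename(columns={"effect": "effect_primary", "se": "se_primary", "p": "p_primary"})
    out = out.drop(columns=["stat"])
    out[["effect_conditional", "se_conditional", "p_conditional"]] = conditional[["effect", "se", "p"]].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log10_attenuation"] = np.log10(out["p_conditional"]) - np.log10(out["p_primary"])
    out.attrs["dropped"] = getattr(cond_null, "dropped_covariates", [])
    return out


def classify_explained(
    p_primary: float,
    p_conditional: float,
    genomewide: float = GENOMEWIDE_ADMIXTURE_THRESHOLD,
    full_cut: float = 0.01,
) -> str:
    """Classify how much of an LAI signal the conditioning variants explain.

    ``full`` if the conditional p leaves the suggestive range entirely
    (>= ``full_cut``), ``partial`` if it rises above genome-wide
    significance but stays below ``full_cut``, ``none`` otherwise.
    Requires a genome-wide-significant primary p.
    """
    if not p_primary < genomewide:
        raise ValueError("primary p-value is not genome-wide significant")
    if p_conditional >= full_cut:
        return "full"
    if p_conditional >= genomewide:
        return "partial"
    return "none"


def region_plot(cond_scan: pd.DataFrame, candidates: pd.DataFrame | None, path) -> None:
    """Primary vs conditional scan overlay with candidate variant points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    mid = (cond_scan["start"] + cond_scan["end"]) / 2
    ax.plot(mid, -np.log10(cond_scan["p_primary"]), c="tab:blue", label="primary")
    ax.plot(mid, -np.log10(cond_scan["p_conditional"]), c="tab:green", label="conditional")
    ax.axhline(-np.log10(GENOMEWIDE_ADMIXTURE_THRESHOLD), ls="--", c="grey")
    if candidates is not None and len(candidates):
        ax.scatter(
            candidates["position"], -np.log10(candidates["p_min"]),
            marker="^", c="black", label="candidates", zorder=3,
        )
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
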