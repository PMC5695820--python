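"""End-to-end orchestration: simulate → prep → scan → fine-map → replicate.

`run_pipeline` executes the stages of an admixture-mapping study on a
simulated cohort and writes each stage's tables to a run directory with
a manifest (config hash, seed, stage status), so a rerun with the same
config and seed is byte-identical and a partial rerun resumes after the
last completed stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestry_freq import batch_ancestry_eaf
from .finemap import (
    LadderSpec,
    candidate_ladder,
    classify_explained,
    conditional_scan,
    group_eaf,
    prune_by_correlation,
    region_plot,
)
from .lmm import AdmixtureMixedModel
from .phenotypes import ExclusionConfig, apply_exclusions
from .scan import (
    GENOMEWIDE_ADMIXTURE_THRESHOLD,
    manhattan_plot,
    regions_to_bed,
    scan_ancestry,
    significant_regions,
)
from .simulate import (
    AncestryPanel,
    CausalSpec,
    GroupProfile,
    VarianceSpec,
    simulate_cohort,
)
from .replication import replication_table


@dataclass
class RunConfig:
    """Configuration of a pipeline run; defaults encode the study design
    this package emulates (three-way admixture, Mainland/Caribbean group
    contrast, four BP traits, genome-wide level 5.68e-5, ladder pruning
    at |r| <= 0.4, replication at family alpha 0.05)."""

    seed: int = 0
    n_mainland: int = 700
    n_caribbean: int = 700
    n_intervals: int = 60
    chrom_length: float = 1.5
    generations: int = 10
    traits: tuple[str, ...] = ("SBP", "DBP", "MAP", "PP")
    scan_ancestry: str = "Amerindian"
    genomewide_threshold: float = GENOMEWIDE_ADMIXTURE_THRESHOLD
    r_max: float = 0.4
    replication_alpha: float = 0.05
    replication_n: int = 1200
    full_cut: float = 0.01
    causal_afs: tuple[float, ...] = (0.1, 0.1, 0.5)
    causal_effects: tuple[float, ...] = (9.0, 9.0, 9.0)
    neutral_variants: int = 20
    ladder: dict = field(
        default_factory=lambda: {"high_group": "Mainland", "low_group": "Caribbean"}
    )
    make_plots: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        for key in ("traits", "causal_afs", "causal_effects"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


STAGES = ("simulate", "prep", "null_model", "scan", "regions", "finemap", "afreq", "replicate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir, resume: bool = True) -> dict:
    """Run all stages; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            manifest["stages"] = old.get("stages", {})

    def done(stage):
        return manifest["stages"].get(stage) == "complete"

    def mark(stage):
        manifest["stages"][stage] = "complete"
        manifest_path.write_text(json.dumps(manifest, indent=2))

    state: dict = {}
    try:
        _stage_simulate(config, outdir, state)
        if not done("simulate"):
            mark("simulate")
        _stage_prep(config, outdir, state)
        mark("prep")
        _stage_null_and_scan(config, outdir, state)
        mark("null_model")
        mark("scan")
        _stage_regions(config, outdir, state)
        mark("regions")
        _stage_finemap(config, outdir, state)
        mark("finemap")
        _stage_afreq(config, outdir, state)
        mark("afreq")
        _stage_replicate(config, outdir, state)
        mark("replicate")
    except PipelineError:
        raise
    except Exception as exc:  # halt with stage context
        stage = next((s for s in STAGES if manifest["stages"].get(s) != "complete"), "unknown")
        raise PipelineError(stage, exc) from exc
    manifest["n_regions"] = len(state.get("regions", []))
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> None:
    panel = AncestryPanel()
    groups = [
        GroupProfile("Mainland", (0.45, 0.10, 0.45), config.n_mainland),
        GroupProfile("Caribbean", (0.65, 0.27, 0.08), config.n_caribbean),
    ]
    causal = [
        CausalSpec(
            "rs_causal",
            position=int(0.5 * config.chrom_length * 1e8),
            ancestry_afs=config.causal_afs,
            ancestry_effects=config.causal_effects,
            typed=True,
        )
    ]
    cohort = simulate_cohort(
        groups=groups,
        panel=panel,
        causal=causal,
        neutral_variants=config.neutral_variants,
        chrom_length=config.chrom_length,
        generations=config.generations,
        n_intervals=config.n_intervals,
        seed=config.seed,
    )
    cohort.write(outdir / "cohort")
    state["cohort"] = cohort


def _stage_prep(config: RunConfig, outdir: Path, state: dict) -> None:
    cohort = state["cohort"]
    table = apply_exclusions(cohort.phenotypes, ExclusionConfig())
    _write(table.traits, outdir / "traits.tsv")
    _write(table.exclusion_log, outdir / "exclusion_log.tsv")
    state["traits"] = table.traits
    # Align all downstream matrices to the retained individuals.
    idx = cohort.phenotypes.index[cohort.phenotypes["sample"].isin(table.traits["sample"])]
    state["row_idx"] = idx.to_numpy()


def _stage_null_and_scan(config: RunConfig, outdir: Path, state: dict) -> None:
    cohort, traits, idx = state["cohort"], state["traits"], state["row_idx"]
    covs = ["age", "sex", "center", "weight", "pc1", "pc2", "pc3", "pc4", "pc5"]
    kin = cohort.kinship.to_numpy()[np.ix_(idx, idx)]
    la = _subset_la(cohort.la, idx)
    state["la_kept"] = la
    state["nulls"], scans = {}, []
    for trait in config.traits:
        model = AdmixtureMixedModel.from_dataframe(
            traits, trait, covs, kinship=kin, household="household_id", block="block_id"
        )
        null = model.fit()
        state["nulls"][trait] = null
        scan = scan_ancestry(la, config.scan_ancestry, null, trait=trait)
        scans.append(scan)
        if config.make_plots:
            manhattan_plot(scan, outdir / f"manhattan_{trait}.png", config.genomewide_threshold)
    state["scans"] = pd.concat(scans, ignore_index=True)
    _write(state["scans"], outdir / "scan.tsv")


def _stage_regions(config: RunConfig, outdir: Path, state: dict) -> None:
    regions = []
    for trait, scan in state["scans"].groupby("trait", sort=False):
        regions.extend(significant_regions(scan, config.genomewide_threshold))
    state["regions"] = regions
    regions_to_bed(regions, outdir / "regions.bed")
    _write(pd.DataFrame([r.as_dict() for r in regions]), outdir / "regions.tsv")


def _assoc_results(config: RunConfig, state: dict) -> pd.DataFrame:
    """Per-variant association p-values: combined, Mainland, Caribbean."""
    cohort, traits, idx = state["cohort"], state["traits"], state["row_idx"]
    gm = cohort.genotypes.typed()
    D = gm.dosages[idx, :].astype(float)
    trait = state["regions"][0].trait if state["regions"] else config.traits[0]
    null = state["nulls"][trait]
    res_all = null.batch_test(D)
    rows = {
        "variant": gm.variants["name"].to_numpy(),
        "position": gm.variants["position"].to_numpy(),
        "p_overall": res_all["p"].to_numpy(),
        "effect_overall": res_all["effect"].to_numpy(),
    }
    covs = ["age", "sex", "weight", "pc1", "pc2", "pc3", "pc4", "pc5"]
    for name, col in (("Mainland", "p_mainland"), ("Caribbean", "p_caribbean")):
        mask = (traits["group"] == name).to_numpy()
        sub = traits.loc[mask]
        kin = cohort.kinship.to_numpy()[np.ix_(idx[mask], idx[mask])]
        model = AdmixtureMixedModel.from_dataframe(
            sub, trait, covs, kinship=kin, household="household_id", block="block_id"
        )
        null_g = model.fit()
        rows[col] = null_g.batch_test(D[mask, :])["p"].to_numpy()
    return pd.DataFrame(rows)


def _stage_finemap(config: RunConfig, outdir: Path, state: dict) -> None:
    cohort, idx = state["cohort"], state["row_idx"]
    state["finemap"] = []
    if not state["regions"]:
        _write(pd.DataFrame(columns=["variant", "lead", "trait"]), outdir / "candidates.tsv")
        _write(
            pd.DataFrame(columns=["trait", "ancestry", "chrom", "start", "end", "n_candidates",
                                  "n_leads", "p_primary", "p_conditional", "classification"]),
            outdir / "finemap_report.tsv",
        )
        return
    gm = cohort.genotypes.typed()
    assoc = _assoc_results(config, state)
    eafs = group_eaf(gm, cohort.phenotypes["group"])
    spec = LadderSpec(**config.ladder)
    la = state["la_kept"]
    all_cands = []
    reports = []
    for region in state["regions"]:
        cands = candidate_ladder(assoc, region, eafs, spec)
        cands = prune_by_correlation(cands, gm, r_max=config.r_max) if len(cands) else cands
        leads = cands[cands["lead"]] if len(cands) else cands
        row = {"trait": region.trait, "ancestry": region.ancestry, "chrom": region.chrom,
               "start": region.start, "end": region.end, "n_candidates": len(cands),
               "n_leads": len(leads), "p_primary": region.lead_p,
               "p_conditional": np.nan, "classification": "no_candidates"}
        if len(leads):
            D = np.column_stack([gm.dosage(n)[idx] for n in leads["variant"]])
            null = state["nulls"][region.trait]
            cond = conditional_scan(la, region.ancestry.split("+")[0], D, null,
                                    trait=region.trait, lead_names=list(leads["variant"]))
            lead_row = cond[(cond["start"] == region.lead_start)].iloc[0]
            row["p_conditional"] = float(lead_row["p_conditional"])
            row["classification"] = classify_explained(
                region.lead_p, row["p_conditional"], config.genomewide_threshold, config.full_cut
            )
            if config.make_plots:
                region_plot(cond, cands, outdir / f"region_{region.trait}_{region.chrom}_{region.start}.png")
            _write(cond, outdir / f"conditional_{region.trait}_{region.chrom}_{region.start}.tsv")
        cands = cands.assign(trait=region.trait)
        all_cands.append(cands)
        reports.append(row)
    _write(pd.concat(all_cands, ignore_index=True) if all_cands else pd.DataFrame(), outdir / "candidates.tsv")
    report = pd.DataFrame(reports)
    _write(report, outdir / "finemap_report.tsv")
    state["finemap"] = report


def _stage_afreq(config: RunConfig, outdir: Path, state: dict) -> None:
    cohort = state["cohort"]
    table = batch_ancestry_eaf(cohort.genotypes, cohort.la)
    table.index.name = "variant"
    table.reset_index().to_csv(outdir / "ancestry_eaf.tsv", sep="\t", index=False, float_format="%.6g")
    state["ancestry_eaf"] = table


def _stage_replicate(config: RunConfig, outdir: Path, state: dict) -> None:
    """Summary-level replication in a simulated high-ancestry cohort.

    Emulates replication of the tested-ancestry signal in a homogeneous
    population of that ancestry (the Pima-Indian design): genotypes are
    drawn at the lead variants using the tested ancestry's allele
    frequency and the trait from the true ancestry-specific effect.
    """
    cohort = state["cohort"]
    report = state.get("finemap")
    rng = np.random.default_rng(config.seed + 1_000_003)
    k_idx = list(cohort.la.ancestries).index(config.scan_ancestry)
    truth = {c["name"]: c for c in cohort.truth["causal"]}
    rows = []
    cands_path = Path(outdir) / "candidates.tsv"
    cands = pd.read_csv(cands_path, sep="\t") if cands_path.stat().st_size > 1 else pd.DataFrame()
    leads = cands[cands.get("lead", pd.Series(dtype=bool)) == True] if len(cands) else pd.DataFrame()
    for _, lead in leads.iterrows():
        spec = truth.get(lead["variant"])
        af = spec["ancestry_afs"][k_idx] if spec else float(lead.get("eaf_high", 0.5))
        beta = spec["ancestry_effects"][k_idx] if spec else 0.0
        g = rng.binomial(2, af, size=config.replication_n).astype(float)
        y = beta * g + rng.normal(0, 10.0, size=config.replication_n)
        if g.var() == 0:
            continue
        slope = np.cov(g, y, ddof=0)[0, 1] / g.var()
        resid = y - y.mean() - slope * (g - g.mean())
        se = float(np.sqrt(resid.var(ddof=2) / (config.replication_n * g.var())))
        disc = cohort.genotypes.dosage(lead["variant"])
        rows.append(
            {
                "variant": lead["variant"],
                "trait": lead.get("trait", config.traits[0]),
                "discovery_effect": _discovery_effect(state, lead),
                "rep_effect": float(slope),
                "rep_se": se,
                "rep_freq": float(g.mean() / 2),
            }
        )
    rows = [r for r in rows if r["discovery_effect"] != 0.0]
    if rows:
        table = replication_table(pd.DataFrame(rows), family_alpha=config.replication_alpha)
    else:
        table = pd.DataFrame(columns=["variant", "trait", "discovery_effect", "rep_effect",
                                      "rep_se", "p_one_sided", "bonferroni_threshold", "replicated"])
    _write(table, Path(outdir) / "replication.tsv")
    state["replication"] = table


def _discovery_effect(state: dict, lead) -> float:
    cohort, idx = state["cohort"], state["row_idx"]
    trait = lead.get("trait", next(iter(state["nulls"])))
    null = state["nulls"].get(trait) or next(iter(state["nulls"].values()))
    d = cohort.genotypes.dosage(lead["variant"])[idx]
    if d.var() == 0:
        return 0.0
    return float(null.batch_test(d[:, None])["effect"].iloc[0])


def _subset_la(la, idx):
    from .simulate import LocalAncestryMatrix

    return LocalAncestryMatrix(
        counts=la.counts[idx],
        intervals=la.intervals,
        ancestries=la.ancestries,
        sample_ids=[la.sample_ids[i] for i in idx],
        haplotypes=None if la.haplotypes is None else la.haplotypes[idx],
        n_switchpoints=None if la.n_switchpoints is None else la.n_switchpoints[idx],
        admixture_props=None if la.admixture_props is None else la.admixture_props[idx],
        groups=None if la.groups is None else la.groups.iloc[idx].reset_index(drop=True),
    )
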