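import numpy as np
import pytest

from admixscan import (
    AncestryPanel,
    CausalSpec,
    GroupProfile,
    VarianceSpec,
    simulate_cohort,
    simulate_genotypes,
    simulate_local_ancestry,
)

TWO_WAY = AncestryPanel(("Anc1", "Anc2"))


def two_ancestry_cohort(
    n=2000,
    beta=1.0,
    p1=0.5,
    p2=0.1,
    q=0.5,
    sigma2=4.0,
    seed=0,
    n_intervals=20,
    typed=True,
    vs=None,
):
    """Two-ancestry cohort with one planted causal variant: the estimand
    bench (admixture-mapping slope beta * (p1 - p2))."""
    groups = [GroupProfile("G", (q, 1 - q), n)]
    causal = [
        CausalSpec("rs1", position=int(0.5e8), ancestry_afs=(p1, p2),
                   ancestry_effects=(beta, beta), typed=typed)
    ]
    return simulate_cohort(
        groups=groups,
        panel=TWO_WAY,
        causal=causal,
        neutral_variants=3,
        vs=vs or VarianceSpec(0.0, 0.0, 0.0, sigma2),
        chrom_length=1.0,
        generations=8,
        n_intervals=n_intervals,
        seed=seed,
        inconsistency_rate=0.0,
    )


def estimand_bench(n=4000, beta=1.0, p1=0.5, p2=0.1, sigma2=1.0, seed=0):
    """Prepared two-ancestry benchmark: medication-adjusted SBP scanned
    against ancestry-1 counts; returns (scan row at causal interval,
    expected slope beta*(p1-p2))."""
    from admixscan import AdmixtureMixedModel, scan_ancestry
    from admixscan.phenotypes import apply_exclusions
    import admixscan.pipeline as pl

    cohort = two_ancestry_cohort(n=n, beta=beta, p1=p1, p2=p2, sigma2=sigma2, seed=seed)
    table = apply_exclusions(cohort.phenotypes)
    idx = cohort.phenotypes.index[cohort.phenotypes["sample"].isin(table.traits["sample"])].to_numpy()
    la = pl._subset_la(cohort.la, idx)
    null = AdmixtureMixedModel.from_dataframe(
        table.traits, "SBP", ["age", "sex"], kinship=None, household=None, block=None
    ).fit()
    scan = scan_ancestry(la, "Anc1", null)
    j = la.interval_of(cohort.truth["causal"][0]["position"])
    return scan.iloc[j], beta * (p1 - p2)


@pytest.fixture(scope="session")
def small_cohort():
    """Three-ancestry, two-group cohort reused across scan/fine-map tests."""
    return simulate_cohort(
        groups=[
            GroupProfile("Mainland", (0.45, 0.10, 0.45), 400),
            GroupProfile("Caribbean", (0.65, 0.27, 0.08), 400),
        ],
        neutral_variants=8,
        n_intervals=30,
        chrom_length=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def iid_null_fit():
    """Null mixed-model fit on clustered data with no genetic effect."""
    from admixscan import AdmixtureMixedModel
    from admixscan.phenotypes import apply_exclusions

    cohort = simulate_cohort(
        groups=[GroupProfile("G", (0.5, 0.2, 0.3), 1200)],
        causal=[CausalSpec("rs_null", position=int(0.5e8), ancestry_afs=(0.5, 0.5, 0.5))],
        neutral_variants=2,
        n_intervals=25,
        chrom_length=1.0,
        seed=7,
        inconsistency_rate=0.0,
    )
    table = apply_exclusions(cohort.phenotypes)
    idx = cohort.phenotypes.index[cohort.phenotypes["sample"].isin(table.traits["sample"])].to_numpy()
    import admixscan.pipeline as pl

    la = pl._subset_la(cohort.la, idx)
    kin = cohort.kinship.to_numpy()[np.ix_(idx, idx)]
    covs = ["age", "sex", "weight", "pc1", "pc2"]
    model = AdmixtureMixedModel.from_dataframe(
        table.traits, "SBP", covs, kinship=kin, household="household_id", block="block_id"
    )
    return la, model.fit()
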