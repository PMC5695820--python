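"""Synthetic admixed-cohort generator.

Simulates a three-way (or K-way) admixed cohort with known ground truth:
local-ancestry tracts per haplotype, genotype dosages whose allele
frequencies depend on the ancestral background of each chromosome copy,
and blood-pressure-like phenotypes with kinship (sibling pairs),
household, and block-unit random effects.

Tract model
-----------
Each haplotype is a mosaic of ancestry tracts along a chromosome of length
``chrom_length`` Morgans. Switch points follow a Poisson process with rate
``generations`` per Morgan (the expected number of crossovers accumulated
since admixture), and the ancestry of each tract is drawn independently
from the individual's admixture proportions. Individual proportions are
drawn from a Dirichlet distribution centred at the group profile, which
creates the continuous ancestry gradient that principal components capture.
There is no background LD and no drift; intervals are equal width in
genetic distance and emitted as 0-based half-open physical coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Physical scale used when mapping genetic distance to coordinates:
# 1 cM per Mb, i.e. 100 Mb per Morgan.
BP_PER_MORGAN = 100_000_000

DEFAULT_ANCESTRIES = ("European", "African", "Amerindian")


@dataclass(frozen=True)
class AncestryPanel:
    """Ordered set of ancestral populations contributing to the admixture."""

    labels: tuple[str, ...] = DEFAULT_ANCESTRIES

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("an ancestry panel needs at least two ancestries")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ancestry labels must be unique")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class GroupProfile:
    """A genetic-analysis group with characteristic admixture proportions.

    In the Hispanic/Latino setting, Mainland groups (e.g. Mexican) carry a
    high proportion of Amerindian ancestry and Caribbean groups (e.g.
    Cuban, Dominican) a higher proportion of African ancestry; this
    contrast is what the fine-mapping step's group allele-frequency
    differences proxy.
    """

    name: str
    admixture_props: tuple[float, ...]
    n_individuals: int

    def __post_init__(self):
        props = np.asarray(self.admixture_props, dtype=float)
        if np.any(props < 0) or np.any(props > 1):
            raise ValueError(f"group {self.name!r}: proportions must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"group {self.name!r}: proportions must sum to 1")
        if self.n_individuals <= 0:
            raise ValueError(f"group {self.name!r}: empty group")


@dataclass(frozen=True)
class CausalSpec:
    """A variant with ancestry-specific allele frequencies and effects.

    ``ancestry_afs[k]`` is the effect-allele frequency on chromosomes of
    ancestry k; ``ancestry_effects[k]`` the per-allele trait effect when the
    allele sits on an ancestry-k background. ``typed`` marks whether the
    variant is visible to downstream association testing (untyped causal
    variants are the regime where admixture mapping beats association
    mapping).
    """

    name: str
    position: int
    ancestry_afs: tuple[float, ...]
    ancestry_effects: tuple[float, ...] = None
    typed: bool = True

    def __post_init__(self):
        afs = np.asarray(self.ancestry_afs, dtype=float)
        if np.any(afs < 0) or np.any(afs > 1):
            raise ValueError(f"variant {self.name!r}: allele frequencies must lie in [0, 1]")
        if self.ancestry_effects is None:
            object.__setattr__(self, "ancestry_effects", tuple(0.0 for _ in self.ancestry_afs))
        if len(self.ancestry_effects) != len(self.ancestry_afs):
            raise ValueError(f"variant {self.name!r}: effects and frequencies differ in length")

    @property
    def is_causal(self) -> bool:
        return any(b != 0.0 for b in self.ancestry_effects)


@dataclass(frozen=True)
class VarianceSpec:
    """Variance components of the phenotype model (trait units squared)."""

    sigma2_kin: float = 4.0
    sigma2_household: float = 6.0
    sigma2_block: float = 2.0
    sigma2_resid: float = 120.0

    def __post_init__(self):
        for name in ("sigma2_kin", "sigma2_household", "sigma2_block", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return {
            "kinship": self.sigma2_kin,
            "household": self.sigma2_household,
            "block": self.sigma2_block,
            "residual": self.sigma2_resid,
        }


@dataclass
class LocalAncestryMatrix:
    """Per-individual, per-interval ancestry copy counts.

    ``counts[i, j, k]`` is the number of chromosome copies (0, 1 or 2) of
    individual i at interval j inherited from ancestry k; counts sum to 2
    over k. ``haplotypes[i, c, j]`` stores the ancestry index of copy c,
    retained so genotypes can be simulated conditionally on the ancestral
    background and so the allele-frequency EM can be fed diplotypes.
    """

    counts: np.ndarray
    intervals: pd.DataFrame  # columns: chrom, start, end (0-based half-open bp)
    ancestries: tuple[str, ...]
    sample_ids: list[str]
    haplotypes: np.ndarray | None = None
    n_switchpoints: np.ndarray | None = None
    admixture_props: np.ndarray | None = None
    groups: pd.Series | None = None

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.counts.shape[1]

    @property
    def k(self) -> int:
        return self.counts.shape[2]

    def ancestry_counts(self, ancestry: str | int) -> np.ndarray:
        """(n, n_intervals) matrix of copy counts for one ancestry."""
        k = ancestry if isinstance(ancestry, (int, np.integer)) else self.ancestries.index(ancestry)
        return self.counts[:, :, k].astype(float)

    def ancestry_freq(self, ancestry: str | int) -> np.ndarray:
        """Per-interval proportion of chromosomes of the given ancestry (denominator 2n)."""
        return self.ancestry_counts(ancestry).sum(axis=0) / (2 * self.n_individuals)

    def interval_of(self, position: int) -> int:
        """Index of the interval covering a physical position."""
        starts = self.intervals["start"].to_numpy()
        ends = self.intervals["end"].to_numpy()
        j = int(np.searchsorted(starts, position, side="right")) - 1
        if j < 0 or position >= ends[j]:
            raise ValueError(f"position {position} lies outside the simulated intervals")
        return j

    def to_tsv(self, path) -> None:
        """Long-format table: sample, chrom, start, end, one count column per ancestry."""
        n, m, _ = self.counts.shape
        df = pd.DataFrame(
            {
                "sample": np.repeat(self.sample_ids, m),
                "chrom": np.tile(self.intervals["chrom"].to_numpy(), n),
                "start": np.tile(self.intervals["start"].to_numpy(), n),
                "end": np.tile(self.intervals["end"].to_numpy(), n),
            }
        )
        for k, label in enumerate(self.ancestries):
            df[label] = self.counts[:, :, k].reshape(-1)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, ancestries: tuple[str, ...] | None = None) -> "LocalAncestryMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta = ["sample", "chrom", "start", "end"]
        if ancestries is None:
            ancestries = tuple(c for c in df.columns if c not in meta)
        samples = df["sample"].drop_duplicates().tolist()
        intervals = df.loc[df["sample"] == samples[0], ["chrom", "start", "end"]].reset_index(drop=True)
        m = len(intervals)
        counts = np.zeros((len(samples), m, len(ancestries)), dtype=np.int8)
        for k, label in enumerate(ancestries):
            counts[:, :, k] = df[label].to_numpy().reshape(len(samples), m)
        if not np.all(counts.sum(axis=2) == 2):
            raise ValueError("ancestry counts must sum to 2 per interval")
        return cls(counts=counts, intervals=intervals, ancestries=tuple(ancestries), sample_ids=samples)


@dataclass
class GenotypeMatrix:
    """Allele dosages with variant metadata.

    ``dosages[i, v]`` is the effect-allele count of individual i at variant
    v. ``ancestry_allele_counts[name]`` is an (n, K) matrix splitting each
    individual's effect alleles by the ancestral background of the carrying
    chromosome — the quantity the ancestry-specific genetic effect acts on.
    """

    dosages: np.ndarray
    variants: pd.DataFrame  # name, chrom, position, a1, a2, typed, info
    sample_ids: list[str]
    ancestry_allele_counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def dosage(self, name: str) -> np.ndarray:
        idx = self.variants.index[self.variants["name"] == name]
        if len(idx) == 0:
            raise KeyError(f"no variant named {name!r}")
        return self.dosages[:, int(idx[0])].astype(float)

    def typed(self) -> "GenotypeMatrix":
        """Restrict to variants visible to association testing."""
        mask = self.variants["typed"].to_numpy(dtype=bool)
        sub = self.variants.loc[mask].reset_index(drop=True)
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            variants=sub,
            sample_ids=self.sample_ids,
            ancestry_allele_counts={n: a for n, a in self.ancestry_allele_counts.items() if n in set(sub["name"])},
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.variants["name"])
        df.index.name = "sample"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, variants: pd.DataFrame | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        if variants is None:
            variants = pd.DataFrame(
                {"name": df.columns, "chrom": "1", "position": -1, "a1": "A", "a2": "G", "typed": True, "info": 1.0}
            )
        return cls(dosages=df.to_numpy(float), variants=variants, sample_ids=df.index.tolist())

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read dosages from a VCF: the DS FORMAT field when present,
        otherwise hard-call genotypes."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        dosages, rows = [], []
        for rec in vcf:
            try:
                ds = np.asarray(rec.format("DS"), dtype=float).ravel()
            except (KeyError, TypeError, ValueError):
                gts = np.asarray(rec.genotypes, dtype=object)
                ds = np.array([int(a) + int(b) for a, b, *_ in gts], dtype=float)
            dosages.append(ds)
            rows.append(
                {
                    "name": rec.ID or f"{rec.CHROM}:{rec.POS}",
                    "chrom": rec.CHROM,
                    "position": rec.POS - 1,  # back to 0-based
                    "a1": rec.ALT[0] if rec.ALT else ".",
                    "a2": rec.REF,
                    "typed": True,
                    "info": 1.0,
                }
            )
        return cls(
            dosages=np.column_stack(dosages) if dosages else np.empty((len(samples), 0)),
            variants=pd.DataFrame(rows),
            sample_ids=samples,
        )

    def to_vcf(self, path, chrom: str = "1") -> None:
        """Minimal single-sample-block VCF with genotype dosages in the DS FORMAT field."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.sample_ids) + "\n")
            for v, row in self.variants.iterrows():
                ds = "\t".join(f"{d:g}" for d in self.dosages[:, v])
                fh.write(f"{row.get('chrom', chrom)}\t{row['position'] + 1}\t{row['name']}\t{row['a2']}\t{row['a1']}\t.\tPASS\t.\tDS\t{ds}\n")


@dataclass
class SimulatedCohort:
    """Bundle of all simulated layers plus the planted truth."""

    la: LocalAncestryMatrix
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    kinship: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.la.to_tsv(outdir / "local_ancestry.tsv")
        self.genotypes.to_tsv(outdir / "dosages.tsv")
        self.genotypes.to_vcf(outdir / "dosages.vcf")
        self.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        self.kinship.to_csv(outdir / "kinship.tsv", sep="\t")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


def _individual_props(rng, groups: list[GroupProfile], k: int, concentration: float) -> tuple[np.ndarray, pd.Series]:
    """Draw per-individual admixture proportions around each group profile."""
    if not groups:
        raise ValueError("at least one group profile is required")
    all_props, labels = [], []
    for g in groups:
        base = np.asarray(g.admixture_props, dtype=float)
        if len(base) != k:
            raise ValueError(f"group {g.name!r} has {len(base)} proportions; panel has {k} ancestries")
        pos = base > 0
        props = np.zeros((g.n_individuals, k))
        if pos.sum() == 1:
            props[:, pos] = 1.0
        else:
            # Dirichlet is only defined over the strictly positive components;
            # ancestries absent from the profile stay exactly 0.
            props[:, pos] = rng.dirichlet(concentration * base[pos], size=g.n_individuals)
        all_props.append(props)
        labels.extend([g.name] * g.n_individuals)
    return np.vstack(all_props), pd.Series(labels, name="group")


def _sample_haplotype(rng, props: np.ndarray, length_m: float, rate: float, midpoints_m: np.ndarray):
    """One haplotype: Poisson switch points, iid tract ancestries; returns
    (ancestry index per interval midpoint, number of switch points)."""
    n_switch = rng.poisson(rate * length_m)
    if n_switch == 0:
        anc = rng.choice(len(props), p=props)
        return np.full(len(midpoints_m), anc, dtype=np.int8), 0
    breaks = np.sort(rng.uniform(0.0, length_m, size=n_switch))
    tract_anc = rng.choice(len(props), size=n_switch + 1, p=props)
    idx = np.searchsorted(breaks, midpoints_m, side="right")
    return tract_anc[idx].astype(np.int8), int(n_switch)


def simulate_local_ancestry(
    panel: AncestryPanel,
    groups: list[GroupProfile],
    chrom_length: float = 2.0,
    generations: int = 10,
    n_intervals: int = 100,
    seed: int | np.random.Generator = 0,
    concentration: float = 30.0,
    chrom: str = "1",
) -> LocalAncestryMatrix:
    """Simulate local-ancestry copy counts for an admixed cohort.

    Parameters
    ----------
    chrom_length : float
        Chromosome length in Morgans.
    generations : int
        Generations since admixture; the switch-point rate per Morgan.
    n_intervals : int
        Number of equal-width (in genetic distance) intervals to emit.
    concentration : float
        Dirichlet concentration of individual admixture proportions around
        the group profile; larger = more homogeneous groups.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if not np.isfinite(chrom_length) or chrom_length <= 0:
        raise ValueError("chrom_length must be finite and positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    k = panel.k
    props, group_labels = _individual_props(rng, groups, k, concentration)
    n = props.shape[0]

    edges_m = np.linspace(0.0, chrom_length, n_intervals + 1)
    midpoints_m = (edges_m[:-1] + edges_m[1:]) / 2.0
    starts = np.floor(edges_m[:-1] * BP_PER_MORGAN).astype(np.int64)
    ends = np.floor(edges_m[1:] * BP_PER_MORGAN).astype(np.int64)
    intervals = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})

    haplotypes = np.empty((n, 2, n_intervals), dtype=np.int8)
    n_switch = np.empty((n, 2), dtype=np.int64)
    for i in range(n):
        for c in range(2):
            haplotypes[i, c], n_switch[i, c] = _sample_haplotype(
                rng, props[i], chrom_length, float(generations), midpoints_m
            )

    counts = np.zeros((n, n_intervals, k), dtype=np.int8)
    for c in range(2):
        for anc in range(k):
            counts[:, :, anc] += (haplotypes[:, c, :] == anc).astype(np.int8)

    sample_ids = [f"S{i:05d}" for i in range(n)]
    return LocalAncestryMatrix(
        counts=counts,
        intervals=intervals,
        ancestries=panel.labels,
        sample_ids=sample_ids,
        haplotypes=haplotypes,
        n_switchpoints=n_switch,
        admixture_props=props,
        groups=group_labels,
    )


def simulate_genotypes(
    la: LocalAncestryMatrix,
    variants: list[CausalSpec],
    seed: int | np.random.Generator = 0,
    chrom: str | None = None,
) -> GenotypeMatrix:
    """Draw genotype dosages conditional on local ancestry.

    Each haplotype carries the effect allele with probability ``p_k`` where
    k is the haplotype's ancestry at the interval covering the variant;
    the dosage is the sum over the two copies.
    """
    if la.haplotypes is None:
        raise ValueError("local-ancestry matrix lacks haplotype-level assignments")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = la.n_individuals
    k = la.k
    dosages = np.zeros((n, len(variants)), dtype=np.int16)
    anc_counts: dict[str, np.ndarray] = {}
    rows = []
    for v, spec in enumerate(variants):
        if len(spec.ancestry_afs) != k:
            raise ValueError(f"variant {spec.name!r}: needs {k} ancestry allele frequencies")
        j = la.interval_of(spec.position)
        afs = np.asarray(spec.ancestry_afs, dtype=float)
        per_anc = np.zeros((n, k), dtype=np.int16)
        for c in range(2):
            anc = la.haplotypes[:, c, j]
            allele = rng.random(n) < afs[anc]
            dosages[:, v] += allele
            np.add.at(per_anc, (np.arange(n), anc), allele.astype(np.int16))
        anc_counts[spec.name] = per_anc
        rows.append(
            {
                "name": spec.name,
                "chrom": chrom or la.intervals["chrom"].iloc[0],
                "position": spec.position,
                "a1": "A",
                "a2": "G",
                "typed": spec.typed,
                "info": 1.0,
            }
        )
    return GenotypeMatrix(
        dosages=dosages,
        variants=pd.DataFrame(rows),
        sample_ids=list(la.sample_ids),
        ancestry_allele_counts=anc_counts,
    )


def _cluster_assignments(rng, n: int, sib_fraction: float, households_per_block: int,
                         pair_fraction: float = 0.8):
    """Household/block structure with sibling pairs sharing a household.

    A ``sib_fraction`` share of individuals are paired into two-person
    sibling households (expected kinship 0.5 on the numerator-relationship
    scale with unit diagonal); a further share up to ``pair_fraction``
    live in two-person households of unrelated individuals — these are
    what separates the household variance from the kinship variance
    (sibling-pair covariance is 0.5*sigma2_kin + sigma2_household,
    unrelated cohabitants share only sigma2_household). The rest live
    alone. Consecutive households form census-block-like units.
    """
    n_pairs = int(n * pair_fraction / 2)
    n_sib_pairs = min(int(n * sib_fraction / 2), n_pairs)
    household = np.empty(n, dtype=np.int64)
    sib_of = np.full(n, -1, dtype=np.int64)
    hid = 0
    i = 0
    for p in range(n_pairs):
        if i + 1 >= n:
            break
        household[i] = household[i + 1] = hid
        if p < n_sib_pairs:
            sib_of[i], sib_of[i + 1] = i + 1, i
        hid += 1
        i += 2
    while i < n:
        household[i] = hid
        hid += 1
        i += 1
    block = household // households_per_block
    return household, block, sib_of


def expected_kinship(sib_of: np.ndarray) -> np.ndarray:
    """Expected relationship matrix (unit diagonal, 0.5 between siblings)."""
    n = len(sib_of)
    kin = np.eye(n)
    has_sib = sib_of >= 0
    kin[np.arange(n)[has_sib], sib_of[has_sib]] = 0.5
    return kin


def simulate_phenotypes(
    gm: GenotypeMatrix,
    la: LocalAncestryMatrix,
    causal: list[CausalSpec],
    vs: VarianceSpec = VarianceSpec(),
    covariate_effects: dict | None = None,
    sib_fraction: float = 0.4,
    households_per_block: int = 5,
    med_threshold: float = 140.0,
    med_scale: float = 8.0,
    inconsistency_rate: float = 0.005,
    intercept_sbp: float = 120.0,
    intercept_dbp: float = 75.0,
    dbp_effect_scale: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate BP-like phenotypes on top of a simulated cohort.

    The trait model is the generative counterpart of the analysis mixed
    model: fixed covariate effects plus ancestry-specific per-allele
    genetic effects, plus kinship (sibling), household, block, and
    residual Gaussian effects. Anti-hypertensive medication is drawn from
    a logistic model in the latent SBP; treated individuals' *measured*
    pressures are reduced by 10/5 mmHg (so the standard +10/+5 adjustment
    recovers the latent scale). Device-summary and raw-measure means are
    both emitted, with a small fraction of individuals given inconsistent
    pairs to exercise the measurement-consistency filter.

    Returns the phenotype table and the expected kinship matrix.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = gm.n_individuals
    if la.n_individuals != n:
        raise ValueError("genotype and local-ancestry matrices cover different individuals")

    household, block, sib_of = _cluster_assignments(rng, n, sib_fraction, households_per_block)
    kin = expected_kinship(sib_of)

    # Random effects. Sibling kinship effect via the 2x2 Cholesky of
    # [[1, .5], [.5, 1]]: u2 = .5*z1 + sqrt(.75)*z2.
    z = rng.standard_normal(n)
    u_kin = z.copy()
    has_sib = sib_of >= 0
    first = has_sib & (np.arange(n) < sib_of)
    u_kin[sib_of[first]] = 0.5 * z[first] + np.sqrt(0.75) * z[sib_of[first]]
    u_kin *= np.sqrt(vs.sigma2_kin)
    u_house = np.sqrt(vs.sigma2_household) * rng.standard_normal(household.max() + 1)[household]
    u_block = np.sqrt(vs.sigma2_block) * rng.standard_normal(block.max() + 1)[block]
    resid_sbp = np.sqrt(vs.sigma2_resid) * rng.standard_normal(n)
    resid_dbp = np.sqrt(vs.sigma2_resid) * dbp_effect_scale * rng.standard_normal(n)

    # Covariates.
    age = rng.uniform(18, 75, size=n)
    sex = rng.integers(0, 2, size=n)
    weight = np.exp(rng.normal(0.0, 0.3, size=n))
    groups = la.groups if la.groups is not None else pd.Series(["G0"] * n)
    group_names = list(dict.fromkeys(groups))
    center = np.array([f"C{group_names.index(g) % 4}" for g in groups])
    props = la.admixture_props if la.admixture_props is not None else np.full((n, la.k), 1.0 / la.k)
    pcs = np.zeros((n, 5))
    n_pc = min(la.k - 1, 5)
    pcs[:, :n_pc] = props[:, :n_pc] - props[:, :n_pc].mean(axis=0)
    pcs[:, n_pc:] = rng.normal(0.0, 0.01, size=(n, 5 - n_pc))

    eff = {"age": 0.35, "sex": 4.0, "weight": 0.0, "center": 1.0}
    if covariate_effects:
        eff.update(covariate_effects)
    fixed = eff["age"] * (age - age.mean()) + eff["sex"] * sex + eff["weight"] * weight
    fixed += eff["center"] * (center == "C1")

    genetic = np.zeros(n)
    for spec in causal:
        betas = np.asarray(spec.ancestry_effects, dtype=float)
        if not spec.is_causal:
            continue
        counts = gm.ancestry_allele_counts.get(spec.name)
        if counts is None:
            raise ValueError(f"causal variant {spec.name!r} absent from the genotype matrix")
        genetic += counts @ betas

    latent_sbp = intercept_sbp + fixed + genetic + u_kin + u_house + u_block + resid_sbp
    latent_dbp = intercept_dbp + dbp_effect_scale * (fixed + genetic + u_kin + u_house + u_block) + resid_dbp

    from scipy.special import expit

    on_meds = rng.random(n) < expit((latent_sbp - med_threshold) / med_scale)
    measured_sbp = latent_sbp - 10.0 * on_meds
    measured_dbp = latent_dbp - 5.0 * on_meds

    # Two measurement summaries; occasional large disagreement.
    raw_sbp = measured_sbp + rng.normal(0.0, 0.5, size=n)
    raw_dbp = measured_dbp + rng.normal(0.0, 0.5, size=n)
    bad = rng.random(n) < inconsistency_rate
    raw_sbp[bad] += rng.choice([-6.0, 6.0], size=bad.sum())

    pheno = pd.DataFrame(
        {
            "sample": gm.sample_ids,
            "group": groups.to_numpy(),
            "sbp_mean": measured_sbp,
            "dbp_mean": measured_dbp,
            "sbp_raw_mean": raw_sbp,
            "dbp_raw_mean": raw_dbp,
            "on_meds": on_meds,
            "age": age,
            "sex": sex,
            "center": center,
            "weight": weight,
            "household_id": household,
            "block_id": block,
        }
    )
    for j in range(5):
        pheno[f"pc{j + 1}"] = pcs[:, j]
    kinship = pd.DataFrame(kin, index=gm.sample_ids, columns=gm.sample_ids)
    return pheno, kinship


def simulate_cohort(
    groups: list[GroupProfile] | None = None,
    panel: AncestryPanel | None = None,
    causal: list[CausalSpec] | None = None,
    neutral_variants: int = 20,
    vs: VarianceSpec = VarianceSpec(),
    chrom_length: float = 2.0,
    generations: int = 10,
    n_intervals: int = 100,
    seed: int = 0,
    **pheno_kwargs,
) -> SimulatedCohort:
    """Convenience wrapper producing a complete simulated cohort.

    Defaults emulate a Hispanic/Latino-style design: a Mainland-like group
    with high Amerindian ancestry and a Caribbean-like group with high
    European/African ancestry, one planted causal variant whose allele
    frequency differs between Amerindian and the other ancestries, and a
    handful of neutral variants.
    """
    rng = np.random.default_rng(seed)
    panel = panel or AncestryPanel()
    if groups is None:
        groups = [
            GroupProfile("Mainland", (0.45, 0.10, 0.45), 600),
            GroupProfile("Caribbean", (0.65, 0.27, 0.08), 600),
        ]
    if causal is None:
        causal = [
            CausalSpec(
                "rs_causal",
                position=int(0.5 * chrom_length * BP_PER_MORGAN),
                ancestry_afs=(0.1, 0.1, 0.5),
                ancestry_effects=(9.0, 9.0, 9.0),
                typed=True,
            )
        ]
    la = simulate_local_ancestry(
        panel, groups, chrom_length=chrom_length, generations=generations, n_intervals=n_intervals, seed=rng
    )
    length_bp = int(chrom_length * BP_PER_MORGAN)
    variants = list(causal)
    taken = {v.position for v in variants}
    while len(variants) < len(causal) + neutral_variants:
        pos = int(rng.integers(0, length_bp))
        if pos in taken:
            continue
        taken.add(pos)
        afs = tuple(np.round(rng.uniform(0.05, 0.95, size=panel.k), 3))
        variants.append(CausalSpec(f"rs_neutral_{len(variants)}", pos, afs))
    gm = simulate_genotypes(la, variants, seed=rng)
    pheno, kinship = simulate_phenotypes(gm, la, causal, vs=vs, seed=rng, **pheno_kwargs)
    truth = {
        "seed": seed,
        "groups": [{"name": g.name, "props": list(g.admixture_props), "n": g.n_individuals} for g in groups],
        "variance_components": vs.as_dict(),
        "causal": [
            {
                "name": c.name,
                "position": c.position,
                "ancestry_afs": list(c.ancestry_afs),
                "ancestry_effects": list(c.ancestry_effects),
                "typed": c.typed,
            }
            for c in causal
        ],
        "generations": generations,
        "chrom_length_morgans": chrom_length,
    }
    return SimulatedCohort(la=la, genotypes=gm, phenotypes=pheno, kinship=kinship, truth=truth)
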