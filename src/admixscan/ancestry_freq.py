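"""EM estimation of ancestry-specific effect-allele frequencies.

Given unphased genotypes (dosages 0/1/2) and the local-ancestry
diplotype at the covering interval (the unordered pair of ancestries of
the two chromosome copies), the allele frequency of each ancestral
population is estimated by maximum likelihood. Each chromosome copy
carries the effect allele with probability p_k of its ancestry; the
genotype is the unphased sum, so for heterozygotes on mixed-ancestry
diplotypes the carrying copy is latent. The E-step distributes the
single effect allele between the two ancestral copies in proportion to
the current odds p_a(1-p_b) : p_b(1-p_a); the M-step sets each p_k to
the expected number of ancestry-k effect alleles over the number of
ancestry-k chromosomes. Local ancestry is treated as known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AncestryEAF:
    """Ancestry-specific effect-allele frequency estimates for one variant."""

    freqs: np.ndarray  # length K; NaN for ancestries with no chromosomes
    n_iter: int
    loglik: float
    converged: bool
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    ancestries: tuple | None = None

    def as_series(self) -> pd.Series:
        idx = self.ancestries if self.ancestries is not None else range(len(self.freqs))
        return pd.Series(self.freqs, index=list(idx))


def _loglik(p, g, pair):
    """Log-likelihood of genotypes given diplotype ancestries and p."""
    pa, pb = p[pair[:, 0]], p[pair[:, 1]]
    prob0 = (1 - pa) * (1 - pb)
    prob1 = pa * (1 - pb) + pb * (1 - pa)
    prob2 = pa * pb
    probs = np.where(g == 0, prob0, np.where(g == 1, prob1, prob2))
    return float(np.sum(np.log(np.clip(probs, 1e-300, None))))


def estimate_ancestry_eaf(
    dosages,
    ancestry_counts,
    tol: float = 1e-8,
    max_iter: int = 1000,
    round_dosages: bool = True,
    ancestries: tuple | None = None,
) -> AncestryEAF:
    """EM estimate of per-ancestry effect-allele frequencies at one variant.

    Parameters
    ----------
    dosages : array (n,)
        Effect-allele counts; imputed (non-integer) dosages are rounded to
        the nearest integer (``round_dosages=True``) or the individual is
        excluded (``False``) — the likelihood is defined on allele counts.
    ancestry_counts : array (n, K)
        Local-ancestry copy counts at the covering interval; each row
        sums to 2.
    """
    g = np.asarray(dosages, dtype=float)
    counts = np.asarray(ancestry_counts)
    if counts.ndim != 2 or counts.shape[0] != len(g):
        raise ValueError("ancestry counts misaligned with dosages")
    if not np.all(counts.sum(axis=1) == 2):
        raise ValueError("ancestry counts must sum to 2 per individual")
    integral = np.isclose(g, np.round(g), atol=1e-9)
    if round_dosages:
        g = np.round(g)
    else:
        g, counts = g[integral], counts[integral]
    if np.any((g < 0) | (g > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    g = g.astype(int)
    k = counts.shape[1]

    # Unordered ancestry pair per individual.
    pair = np.empty((len(g), 2), dtype=int)
    for i, row in enumerate(counts):
        anc = np.repeat(np.arange(k), row)
        pair[i] = anc
    chrom_per_anc = np.bincount(pair.ravel(), minlength=k).astype(float)

    present = chrom_per_anc > 0
    pooled = g.sum() / (2.0 * len(g)) if len(g) else np.nan
    p = np.full(k, np.clip(pooled, 1e-6, 1 - 1e-6))

    same = pair[:, 0] == pair[:, 1]
    het_mixed = (g == 1) & ~same
    ll_path = []
    ll_old = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E-step: expected effect alleles per ancestry.
        alleles = np.zeros(k)
        # Homozygous-ancestry diplotypes and non-het genotypes are fully observed:
        # g alleles split g/2 per copy, both copies same ancestry → g to that ancestry;
        # mixed diplotype with g=0 or 2 contributes g/2 to each ancestry.
        np.add.at(alleles, pair[same, 0], g[same])
        fixed_mixed = ~same & ~het_mixed
        np.add.at(alleles, pair[fixed_mixed, 0], g[fixed_mixed] / 2.0)
        np.add.at(alleles, pair[fixed_mixed, 1], g[fixed_mixed] / 2.0)
        if het_mixed.any():
            a, b = pair[het_mixed, 0], pair[het_mixed, 1]
            wa = p[a] * (1 - p[b])
            wb = p[b] * (1 - p[a])
            denom = np.clip(wa + wb, 1e-300, None)
            np.add.at(alleles, a, wa / denom)
            np.add.at(alleles, b, wb / denom)
        # M-step.
        with np.errstate(invalid="ignore", divide="ignore"):
            p_new = np.where(present, alleles / chrom_per_anc, p)
        p_new = np.clip(p_new, 0.0, 1.0)
        ll = _loglik(np.clip(p_new, 1e-12, 1 - 1e-12), g, pair)
        if ll < ll_old - 1e-9:
            raise RuntimeError(f"EM log-likelihood decreased at iteration {n_iter}: {ll_old} -> {ll}")
        ll_path.append(ll)
        p = p_new
        if ll - ll_old < tol and n_iter > 1:
            converged = True
            break
        ll_old = ll

    p = np.where(present, p, np.nan)
    return AncestryEAF(
        freqs=p,
        n_iter=n_iter,
        loglik=ll_path[-1] if ll_path else np.nan,
        converged=converged,
        loglik_path=np.asarray(ll_path),
        ancestries=ancestries,
    )


def batch_ancestry_eaf(gm, la, variant_names=None, **kwargs) -> pd.DataFrame:
    """Ancestry-specific EAFs for a list of variants.

    Uses each variant's covering LAI from the local-ancestry matrix;
    returns a variant x ancestry frequency table.
    """
    names = variant_names if variant_names is not None else list(gm.variants["name"])
    rows = {}
    for name in names:
        row = gm.variants.loc[gm.variants["name"] == name].iloc[0]
        j = la.interval_of(int(row["position"]))
        res = estimate_ancestry_eaf(
            gm.dosage(name), la.counts[:, j, :], ancestries=la.ancestries, **kwargs
        )
        rows[name] = res.as_series()
    return pd.DataFrame(rows).T
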