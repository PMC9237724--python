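"""Synthetic reference panels, loadings and cohorts with known ancestry.

The generator emulates the statistical structure the deconvolution method
assumes, so the whole pipeline can be exercised end to end with a known
ground truth and no external downloads:

* Population allele frequencies follow the Balding–Nichols divergence
  model: an ancestral frequency ``p_j ~ Uniform(0.05, 0.95)`` per variant,
  and each population's frequency drawn from
  ``Beta(p_j (1 - F_k) / F_k, (1 - p_j)(1 - F_k) / F_k)`` so that its
  dispersion around the ancestral value is governed by the divergence
  parameter ``F_k`` (an FST-like quantity).
* Optionally, pairs of *close* populations are generated hierarchically —
  a shared intermediate frequency followed by a small amount of extra
  drift per member — to emulate closely related groups such as
  within-continent populations.
* Reference individuals are diploid genotypes ``Binomial(2, f_jk)``; the
  panel stores the frequencies *observed* in those individuals, and the PC
  loadings are the top right singular vectors of the column-centered
  reference genotype matrix, with shrinkage correction factors estimated
  by split-half cross-validation.
* A cohort's true frequency is the mixture ``f_j(0) = sum_k alpha_k f_jk``;
  the observed summary statistic adds binomial sampling noise at the
  cohort's diploid sample size, and the allele order of each variant is
  randomly swapped (with the frequency complemented) to exercise the
  matching step.

No linkage disequilibrium is simulated: the deconvolution treats variants
exchangeably in both of its objectives, so LD affects standard errors of
real-data estimates but not the mechanics tested here.

All randomness flows from the single ``seed`` in :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pca_projection import (
    LoadingsTable,
    _centered_cross,
    _col_means,
    estimate_correction,
)
from .sumstats_match import FreqTable, ReferencePanel, SumdeconvError

#: non-strand-ambiguous allele pairs (default simulated variants)
_UNAMBIGUOUS_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class ClosePair:
    """Two populations sharing recent drift: hierarchical generation.

    The pair's frequencies are drawn around a shared intermediate frequency
    (itself Balding–Nichols at ``fst_shared`` from the ancestral one) with
    small per-member extra drift ``fst_extra``.
    """

    members: tuple[int, int]
    fst_shared: float
    fst_extra: tuple[float, float]


@dataclass
class SimConfig:
    """Study conditions of one synthetic experiment.

    Defaults describe a cohort of 50,000 diploids mixing four populations
    (two relatively close at F=0.02, two more diverged) genotyped on
    100,000 independent SNPs, with 200 reference individuals per population
    and 8 PCs — a realistic desk-scale stand-in for a biobank-derived
    multi-population reference.
    """

    n_variants: int = 100_000
    n_pops: int = 4
    fst: tuple[float, ...] = (0.02, 0.02, 0.05, 0.1)
    n_ref_per_pop: int = 200
    n_cohort: int = 50_000
    alpha_true: tuple[float, ...] = (0.5, 0.2, 0.2, 0.1)
    n_pcs: int = 8
    seed: int = 0
    close_pairs: tuple[ClosePair, ...] = ()
    ambiguous_fraction: float = 0.0

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha_true, dtype=float)
        if len(alpha) != self.n_pops:
            raise ValueError("alpha_true must have one entry per population")
        if np.any(alpha < 0) or abs(alpha.sum() - 1.0) > 1e-9:
            raise ValueError("alpha_true must lie on the simplex")
        fst = np.asarray(self.fst, dtype=float)
        if len(fst) != self.n_pops:
            raise ValueError("fst must have one entry per population")
        if np.any(fst <= 0) or np.any(fst > 0.5):
            raise ValueError("fst entries must lie in (0, 0.5]")
        if self.n_pcs > self.n_pops * self.n_ref_per_pop - 1:
            raise ValueError("n_pcs must be < total reference individuals")
        if not 0 <= self.ambiguous_fraction <= 1:
            raise ValueError("ambiguous_fraction must lie in [0, 1]")
        for pair in self.close_pairs:
            i, j = pair.members
            if not (0 <= i < self.n_pops and 0 <= j < self.n_pops and i != j):
                raise ValueError(f"invalid close pair {pair.members}")


@dataclass
class PanelSim:
    """Output of :func:`simulate_panel`.

    ``panel`` holds *observed* reference frequencies; ``true_freqs`` the
    underlying population frequencies the genotypes were drawn from;
    ``genotypes`` the (K * n_ref) x M int8 dosage matrix; ``pop_labels``
    each reference individual's population index.
    """

    panel: ReferencePanel
    genotypes: np.ndarray
    pop_labels: np.ndarray
    true_freqs: np.ndarray


def _balding_nichols(rng: np.random.Generator, base: np.ndarray, fst: float) -> np.ndarray:
    """One Beta draw per variant around base frequencies with divergence fst."""
    ratio = (1.0 - fst) / fst
    a = base * ratio
    b = (1.0 - base) * ratio
    if np.any(a <= 0) or np.any(b <= 0):
        raise SumdeconvError("degenerate Beta parameters (base frequency at 0 or 1)")
    f = rng.beta(a, b)
    # keep frequencies away from exact fixation so genotypes stay polymorphic
    return np.clip(f, 1e-6, 1.0 - 1e-6)


def _variant_keys(m: int, rng: np.random.Generator, ambiguous_fraction: float):
    pos = np.arange(1, m + 1, dtype=np.int64) * 100
    chrom = np.full(m, "1", dtype=object)
    pairs = np.array(_UNAMBIGUOUS_PAIRS, dtype=object)
    choice = rng.integers(0, len(pairs), size=m)
    a1 = pairs[choice, 0].copy()
    a2 = pairs[choice, 1].copy()
    if ambiguous_fraction > 0:
        amb = rng.random(m) < ambiguous_fraction
        apairs = np.array(_AMBIGUOUS_PAIRS, dtype=object)
        ac = rng.integers(0, len(apairs), size=int(amb.sum()))
        a1[amb] = apairs[ac, 0]
        a2[amb] = apairs[ac, 1]
    return chrom, pos, a1, a2


def simulate_panel(config: SimConfig) -> PanelSim:
    """Simulate a multi-population reference panel under Balding–Nichols.

    Deterministic given ``config.seed``.  Populations listed in
    ``config.close_pairs`` share an intermediate frequency before their
    small extra drift; all others drift independently from the ancestral
    frequency at their own ``fst``.
    """
    rng = np.random.default_rng(config.seed)
    m, k = config.n_variants, config.n_pops
    chrom, pos, a1, a2 = _variant_keys(m, rng, config.ambiguous_fraction)
    ancestral = rng.uniform(0.05, 0.95, size=m)

    true_freqs = np.empty((m, k))
    in_pair = {i for pair in config.close_pairs for i in pair.members}
    for kk in range(k):
        if kk not in in_pair:
            true_freqs[:, kk] = _balding_nichols(rng, ancestral, config.fst[kk])
    for pair in config.close_pairs:
        shared = _balding_nichols(rng, ancestral, pair.fst_shared)
        for member, extra in zip(pair.members, pair.fst_extra):
            true_freqs[:, member] = _balding_nichols(rng, shared, extra)

    n_ref = config.n_ref_per_pop
    genotypes = np.empty((k * n_ref, m), dtype=np.int8)
    observed = np.empty((m, k))
    pop_labels = np.repeat(np.arange(k), n_ref)
    for kk in range(k):
        g = rng.binomial(2, true_freqs[:, kk], size=(n_ref, m)).astype(np.int8)
        genotypes[kk * n_ref : (kk + 1) * n_ref] = g
        observed[:, kk] = g.mean(axis=0, dtype=np.float64) / 2.0

    panel = ReferencePanel(
        chrom=chrom,
        pos=pos,
        a1=a1,
        a2=a2,
        freqs=observed,
        groups=[f"pop{kk + 1}" for kk in range(k)],
        sizes=np.full(k, n_ref),
    )
    return PanelSim(panel=panel, genotypes=genotypes, pop_labels=pop_labels, true_freqs=true_freqs)


def build_loadings(
    genotypes: np.ndarray,
    panel: ReferencePanel,
    n_pcs: int,
    seed: int = 0,
    correction: str = "estimate",
    n_splits: int = 5,
) -> LoadingsTable:
    """PCA of the reference genotype matrix, packaged as a LoadingsTable.

    Loadings are the top ``n_pcs`` right singular vectors of the
    column-centered genotype matrix (computed through the N x N Gram matrix,
    so the genotypes may stay int8); ``center`` is the per-variant mean
    frequency.  ``correction`` is either ``"estimate"`` (split-half
    estimator) or ``"none"`` (all factors exactly 1).
    """
    geno = np.asarray(genotypes)
    n, m = geno.shape
    max_l = min(n - 1, m)
    if n_pcs > max_l:
        raise SumdeconvError(f"rank allows at most {max_l} PCs, requested {n_pcs}")
    if len(panel) != m:
        raise SumdeconvError("genotype matrix and panel must share the variant axis")
    mu = _col_means(geno)
    gram = _centered_cross(geno, geno, mu)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:n_pcs]
    evals = evals[order]
    if np.any(evals <= 1e-9 * max(evals[0], 1.0)):
        achievable = int(np.sum(evals > 1e-9 * max(evals[0], 1.0)))
        raise SumdeconvError(f"rank deficiency: only {achievable} PCs achievable")
    u = evecs[:, order]
    s = np.sqrt(evals)
    # V = Xc.T @ U / s, chunked over variants
    loadings = np.empty((m, n_pcs))
    chunk = 200_000
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        xc = geno[:, sl].astype(np.float64) - mu[sl]
        loadings[sl] = xc.T @ (u / s)
    # deterministic sign: largest-magnitude loading positive per PC
    for l in range(n_pcs):
        j = int(np.argmax(np.abs(loadings[:, l])))
        if loadings[j, l] < 0:
            loadings[:, l] = -loadings[:, l]
    if correction == "estimate":
        corr = estimate_correction(geno, n_pcs, n_splits=n_splits, seed=seed)
    elif correction == "none":
        corr = np.ones(n_pcs)
    else:
        raise ValueError("correction must be 'estimate' or 'none'")
    return LoadingsTable(
        chrom=panel.chrom,
        pos=panel.pos,
        a1=panel.a1,
        a2=panel.a2,
        loadings=loadings,
        correction=corr,
        center=mu / 2.0,
    )


def simulate_cohort_sumstats(
    panel: ReferencePanel,
    freqs: np.ndarray,
    alpha_true: Sequence[float],
    n_cohort: int | None,
    seed: int,
    swap_fraction: float = 0.5,
) -> FreqTable:
    """Simulate a cohort's summary-statistic allele frequencies.

    The true cohort frequency is the mixture ``freqs @ alpha_true`` (pass
    ``panel.freqs`` for a cohort drawn from the observed panel, or the true
    population frequencies).  With ``n_cohort`` set, the observed frequency
    is ``Binomial(2 n, f) / (2 n)``; with ``n_cohort=None`` the mixture is
    returned noiselessly.  A ``swap_fraction`` of variants has its allele
    order swapped (frequency complemented) to exercise the matching step.
    """
    alpha = np.asarray(alpha_true, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (len(panel), len(alpha)):
        raise SumdeconvError("freqs must be M x K matching the panel and alpha")
    if np.any(alpha < 0) or abs(alpha.sum() - 1.0) > 1e-9:
        raise SumdeconvError("alpha_true must lie on the simplex")
    rng = np.random.default_rng(seed)
    f_true = freqs @ alpha
    if n_cohort is None:
        f_obs = f_true
    else:
        f_obs = rng.binomial(2 * n_cohort, f_true) / (2.0 * n_cohort)
    swap = rng.random(len(panel)) < swap_fraction
    a1 = panel.a1.copy()
    a2 = panel.a2.copy()
    a1[swap], a2[swap] = panel.a2[swap], panel.a1[swap]
    f_out = np.where(swap, 1.0 - f_obs, f_obs)
    return FreqTable(
        chrom=panel.chrom.copy(),
        pos=panel.pos.copy(),
        a1=a1,
        a2=a2,
        freq=f_out,
        n_eff=None if n_cohort is None else float(n_cohort),
    )


def simulate_individual(
    freqs: np.ndarray,
    alpha_true: Sequence[float],
    seed: int,
) -> np.ndarray:
    """Simulate one admixed individual's dosages: Binomial(2, freqs @ alpha)."""
    alpha = np.asarray(alpha_true, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(alpha < 0) or abs(alpha.sum() - 1.0) > 1e-9:
        raise SumdeconvError("alpha_true must lie on the simplex")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, freqs @ alpha).astype(np.int8)


def write_dosages(panel: ReferencePanel, dosages: np.ndarray, path) -> None:
    """Write an individual's dosage file in the dialect read_dosages reads."""
    import pandas as pd

    from .sumstats_match import _sep_for

    df = pd.DataFrame(
        {
            "chr": panel.chrom,
            "pos": panel.pos,
            "a1": panel.a1,
            "a2": panel.a2,
            "dosage": np.asarray(dosages, dtype=int),
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)
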