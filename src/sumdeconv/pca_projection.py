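"""Projection of allele-frequency vectors onto reference PC loadings.

The deconvolution works in the space of principal components computed from
a reference genotype matrix.  Projecting a frequency vector is a matrix
multiplication, ``U.T @ (f - center)``; but a vector that was *not* part of
the sample the PCA was computed on is systematically attracted toward the
origin, because finite-sample loadings partly overfit sampling noise.  The
module therefore carries a per-PC multiplicative *shrinkage correction*
factor ``c_l >= 1`` that is applied to out-of-sample projections only
(the cohort frequency vector), never to the in-sample reference
populations.

:func:`estimate_correction` provides a split-half estimator of the factors
for panels where they were not distributed with the loadings: repeatedly
compute the PCA on a random half of the reference individuals, project the
held-out half, and average the per-PC ratio of in-sample to held-out score
standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats_match import ReferencePanel, SumdeconvError, _clean_variant_frame, _sep_for

#: variants per chunk for matrix products on genotype matrices kept as int8
_CHUNK = 200_000


@dataclass
class LoadingsTable:
    """PC loadings for M variants x L components, keyed like a ReferencePanel.

    ``correction[l]`` is the multiplicative shrinkage factor for PC l
    (exactly 1 means "no correction"); ``center`` is the optional reference
    mean frequency per variant used for centering before projection.
    """

    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    loadings: np.ndarray
    correction: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.correction = np.asarray(self.correction, dtype=float)
        if self.loadings.ndim != 2:
            raise ValueError("loadings must be an M x L matrix")
        m, l = self.loadings.shape
        if len(self.pos) != m:
            raise ValueError("loadings row count must match variant count")
        if self.correction.shape != (l,):
            raise ValueError("correction must have one factor per PC")
        if np.any(self.correction < 1):
            raise ValueError("correction factors must be >= 1")
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)
            if self.center.shape != (m,):
                raise ValueError("center must have one entry per variant")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]

    def subset(self, rows: np.ndarray) -> "LoadingsTable":
        """Row-subset of the table (used after variant subsampling)."""
        return LoadingsTable(
            chrom=self.chrom[rows],
            pos=self.pos[rows],
            a1=self.a1[rows],
            a2=self.a2[rows],
            loadings=self.loadings[rows],
            correction=self.correction,
            center=None if self.center is None else self.center[rows],
        )


@dataclass
class ProjectedPoint:
    """Coordinates of one frequency vector in PC space."""

    coords: np.ndarray
    corrected: bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


def project_frequencies(
    freq: np.ndarray,
    loadings: LoadingsTable,
    apply_correction: bool = True,
) -> ProjectedPoint:
    """Project one aligned frequency vector onto the PC loadings.

    ``coords_l = c_l * sum_j u_jl * (freq_j - center_j)`` with ``c_l = 1``
    when ``apply_correction`` is False and ``center = 0`` when absent.
    """
    f = np.asarray(freq, dtype=float)
    if f.shape != (len(loadings),):
        raise SumdeconvError(
            f"frequency vector length {f.shape} does not match loadings ({len(loadings)} variants)"
        )
    if not np.all(np.isfinite(f)):
        raise SumdeconvError("non-finite frequency in projection input")
    centered = f if loadings.center is None else f - loadings.center
    coords = loadings.loadings.T @ centered
    if apply_correction:
        coords = loadings.correction * coords
    return ProjectedPoint(coords=coords, corrected=apply_correction)


def project_panel(panel: ReferencePanel, loadings: LoadingsTable) -> np.ndarray:
    """Project every panel population; returns an L x K matrix of points.

    Column k equals ``project_frequencies(panel.freqs[:, k], ...)`` without
    shrinkage correction: the reference populations are in-sample to the
    PCA, so their projections are not shrunk.
    """
    if len(panel) != len(loadings) or not (
        np.array_equal(panel.pos, loadings.pos)
        and np.array_equal(panel.chrom, loadings.chrom)
        and np.array_equal(panel.a1, loadings.a1)
        and np.array_equal(panel.a2, loadings.a2)
    ):
        raise SumdeconvError("panel and loadings must list the same variants in the same order")
    freqs = panel.freqs
    centered = freqs if loadings.center is None else freqs - loadings.center[:, None]
    return loadings.loadings.T @ centered


# ---------------------------------------------------------------------------
# split-half shrinkage estimation
# ---------------------------------------------------------------------------

def _col_means(geno: np.ndarray) -> np.ndarray:
    """Column means of a (possibly int8) genotype matrix, chunked."""
    n, m = geno.shape
    out = np.empty(m)
    for start in range(0, m, _CHUNK):
        sl = slice(start, min(start + _CHUNK, m))
        out[sl] = geno[:, sl].mean(axis=0, dtype=np.float64)
    return out


def _centered_cross(a: np.ndarray, b: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """(A - mu) @ (B - mu).T computed in float64 chunks over variants."""
    out = np.zeros((a.shape[0], b.shape[0]))
    for start in range(0, a.shape[1], _CHUNK):
        sl = slice(start, min(start + _CHUNK, a.shape[1]))
        ac = a[:, sl].astype(np.float64) - mu[sl]
        bc = b[:, sl].astype(np.float64) - mu[sl]
        out += ac @ bc.T
    return out


def _pca_scores(geno_in: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a centered genotype matrix via the N x N Gram matrix.

    Returns (mu, U, s): column means, left singular vectors (N x L) and
    singular values; in-sample scores are ``U * s`` and the loadings are
    ``(X - mu).T @ U / s``, neither of which needs the M x L matrix here.
    """
    mu = _col_means(geno_in)
    gram = _centered_cross(geno_in, geno_in, mu)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:n_pcs]
    evals = evals[order]
    if np.any(evals <= 1e-9 * max(evals[0], 1.0)):
        bad = int(np.flatnonzero(evals <= 1e-9 * max(evals[0], 1.0))[0]) + 1
        raise SumdeconvError(f"degenerate PCA: PC{bad} has (near-)zero variance")
    return mu, evecs[:, order], np.sqrt(evals)


def estimate_correction(
    reference_genotypes: np.ndarray,
    n_pcs: int,
    n_splits: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Split-half estimate of the per-PC shrinkage correction factors.

    For each split, PCA is computed on a random half of the individuals and
    the held-out half is projected onto it; the raw per-PC ratio is the
    mean over splits of sd(in-sample scores) / sd(held-out projections).
    Because the excess shrinkage of a PCA scales inversely with the number
    of samples it was computed on, the half-sample ratio over-corrects the
    full-sample loadings by a factor of two in its excess; the returned
    factors are therefore ``1 + (ratio - 1) / 2``, floored at 1.  Genotype
    entries must be 0/1/2 dosages.
    """
    geno = np.asarray(reference_genotypes)
    n, m = geno.shape
    if n < 2 * n_pcs:
        raise SumdeconvError(f"need at least {2 * n_pcs} individuals for {n_pcs} PCs, got {n}")
    rng = np.random.default_rng(seed)
    ratios = np.zeros((n_splits, n_pcs))
    for split in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        idx_in, idx_out = perm[:half], perm[half:]
        mu, u, s = _pca_scores(geno[idx_in], n_pcs)
        scores_in = u * s
        # held-out projection without forming the M x L loadings:
        # (X_out - mu) @ V = (X_out - mu)(X_in - mu).T @ U / s
        cross = _centered_cross(geno[idx_out], geno[idx_in], mu)
        scores_out = cross @ (u / s)
        sd_in = scores_in.std(axis=0)
        sd_out = scores_out.std(axis=0)
        if np.any(sd_out == 0):
            bad = int(np.flatnonzero(sd_out == 0)[0]) + 1
            raise SumdeconvError(f"degenerate PCA: held-out scores on PC{bad} have zero variance")
        ratios[split] = sd_in / sd_out
    # rescale the half-sample excess to the full sample size
    return np.maximum(1.0 + (ratios.mean(axis=0) - 1.0) / 2.0, 1.0)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_loadings(path: str | Path) -> LoadingsTable:
    """Read a loadings table from delimited text.

    Format (documented in the README): an optional line
    ``##correction<TAB>c1<TAB>...<TAB>cL``, an optional line
    ``##center<TAB>...`` is NOT supported (center is recomputed downstream),
    then a header ``chr pos a1 a2 PC1 ... PCL`` and one row per variant.
    An optional ``center`` column holds the per-variant reference mean
    frequency.  Missing correction line means no correction (all ones).
    """
    sep = _sep_for(path)
    correction: np.ndarray | None = None
    try:
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("##correction"):
                correction = np.array([float(x) for x in first.rstrip("\n").split(sep)[1:]])
                df = pd.read_csv(fh, sep=sep, dtype=str)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep=sep, dtype=str)
    except OSError as exc:
        raise SumdeconvError(f"cannot read loadings file {path!r}: {exc}") from exc
    fixed = ["chr", "pos", "a1", "a2"]
    if list(df.columns[:4]) != fixed:
        raise SumdeconvError(f"{path}: loadings must start with columns {fixed}")
    pc_cols = [c for c in df.columns[4:] if c.upper().startswith("PC")]
    if not pc_cols:
        raise SumdeconvError(f"{path}: no PC columns found")
    has_center = "center" in df.columns
    df = df.rename(columns={"chr": "chrom"})
    num_cols = pc_cols + (["center"] if has_center else [])
    nums = df[num_cols].apply(pd.to_numeric, errors="coerce")
    ok = nums.notna().all(axis=1).to_numpy()
    df = df[ok]
    nums = nums[ok]
    df, _ = _clean_variant_frame(df)
    nums = nums.loc[df.index]
    if len(df) == 0:
        raise SumdeconvError(f"{path}: empty loadings after filtering")
    loadings = nums[pc_cols].to_numpy(dtype=float)
    if correction is None:
        correction = np.ones(loadings.shape[1])
    if len(correction) != loadings.shape[1]:
        raise SumdeconvError(
            f"{path}: ##correction has {len(correction)} entries for {loadings.shape[1]} PCs"
        )
    return LoadingsTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        a1=df["a1"].to_numpy(dtype=object),
        a2=df["a2"].to_numpy(dtype=object),
        loadings=loadings,
        correction=correction,
        center=nums["center"].to_numpy(dtype=float) if has_center else None,
    )


def write_loadings(loadings: LoadingsTable, path: str | Path) -> None:
    """Write a LoadingsTable in the dialect :func:`read_loadings` reads."""
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(
            "##correction" + sep + sep.join("%.17g" % c for c in loadings.correction) + "\n"
        )
        df = pd.DataFrame(
            {"chr": loadings.chrom, "pos": loadings.pos, "a1": loadings.a1, "a2": loadings.a2}
        )
        for l in range(loadings.n_pcs):
            df[f"PC{l + 1}"] = loadings.loadings[:, l]
        if loadings.center is not None:
            df["center"] = loadings.center
        df.to_csv(fh, sep=sep, index=False, float_format="%.17g")
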