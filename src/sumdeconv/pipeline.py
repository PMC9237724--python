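"""End-to-end orchestration: read, match, project, solve, merge, report.

The full method runs in four steps: (1) read the summary statistics, the
reference panel of per-population allele frequencies, and the PC loadings;
(2) match variants and alleles between summary statistics and panel;
(3) project the harmonized cohort frequencies (with shrinkage correction)
and the reference populations (without) onto the PC space; (4) solve the
simplex-constrained least-squares problem for the mixing proportions.
A frequency-space mode skips the projection and fits the proportions
directly on allele frequencies (the Summix-style baseline).

Very close reference populations can be merged *a posteriori*: because the
model is linear in alpha, the coefficient of a merged group is simply the
sum of its constituents'.

Individual-level mode replaces the cohort allele-frequency vector by an
individual's genotype dosages divided by 2 and runs the same pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .pca_projection import (
    LoadingsTable,
    project_frequencies,
    read_loadings,
)
from .simplex_qp import (
    AncestryProportions,
    build_problem_freq,
    build_problem_pc,
    solve_simplex_ls,
)
from .sumstats_match import (
    FreqTable,
    ReferencePanel,
    SumdeconvError,
    harmonize,
    match_variants,
    read_freq_table,
    read_panel,
)

logger = logging.getLogger("sumdeconv")

#: below this matched-variant count the run aborts
DEFAULT_MIN_OVERLAP = 50_000
#: between min_overlap and this count, a warning is emitted
COMFORTABLE_OVERLAP = 100_000


@dataclass
class RunConfig:
    """Tunable knobs of one deconvolution run."""

    mode: str = "pc"
    remove_ambiguous: bool = True
    n_subsample_variants: int | None = None
    seed: int = 0
    merge_map: dict[str, str] | None = None
    min_overlap: int = DEFAULT_MIN_OVERLAP
    column_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("pc", "frequency"):
            raise ValueError(f"mode must be 'pc' or 'frequency', got {self.mode!r}")
        if self.n_subsample_variants is not None and self.n_subsample_variants < 1_000:
            raise ValueError("n_subsample_variants must be >= 1000 when set")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class RunReport:
    """Machine-readable record of one run: counts, proportions, objective."""

    groups: list[str]
    alpha: list[float]
    merged_groups: list[str]
    merged_alpha: list[float]
    objective: float
    mode: str
    counts: dict[str, int]
    config: dict
    caveats: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        """Human-readable table, percentages rounded to 0.1."""
        lines = [f"Ancestry proportions ({self.mode} mode), % of cohort:"]
        width = max(len(g) for g in self.merged_groups)
        for g, a in zip(self.merged_groups, self.merged_alpha):
            lines.append(f"  {g:<{width}}  {100 * a:5.1f}")
        lines.append(f"objective (residual sum of squares): {self.objective:.6g}")
        lines.append(f"matched variants: {self.counts['n_matched']}")
        return "\n".join(lines)


def merge_proportions(
    result: AncestryProportions, merge_map: Mapping[str, str] | None
) -> AncestryProportions:
    """Merge fine ancestry groups a posteriori by summing their coefficients.

    ``merge_map`` maps fine group name -> merged group name; unmapped groups
    pass through unchanged.  The merged vector still sums to 1.
    """
    if not merge_map:
        return result
    unknown = [g for g in merge_map if g not in result.groups]
    if unknown:
        raise SumdeconvError(f"merge_map names unknown group(s): {unknown}")
    merged: dict[str, float] = {}
    for g, a in zip(result.groups, result.alpha):
        target = merge_map.get(g, g)
        merged[target] = merged.get(target, 0.0) + float(a)
    return AncestryProportions(
        alpha=np.array(list(merged.values())),
        groups=list(merged.keys()),
        objective=result.objective,
        mode=result.mode,
    )


def _check_overlap(n_matched: int, config: RunConfig) -> None:
    if n_matched < config.min_overlap:
        raise SumdeconvError(
            f"only {n_matched} variants matched the panel "
            f"(minimum required: {config.min_overlap})"
        )
    if n_matched < COMFORTABLE_OVERLAP:
        logger.warning(
            "only %d matched variants; at least %d are recommended",
            n_matched,
            COMFORTABLE_OVERLAP,
        )


def deconvolve_tables(
    sumstats: FreqTable,
    panel: ReferencePanel,
    loadings: LoadingsTable,
    config: RunConfig,
) -> tuple[AncestryProportions, RunReport]:
    """Run match -> harmonize -> (subsample) -> project -> solve on in-memory tables.

    Shared core of summary and individual modes; public so simulated tables
    can be deconvolved without a round-trip through files.
    """
    if len(panel) != len(loadings) or not (
        np.array_equal(panel.pos, loadings.pos)
        and np.array_equal(panel.chrom, loadings.chrom)
        and np.array_equal(panel.a1, loadings.a1)
        and np.array_equal(panel.a2, loadings.a2)
    ):
        raise SumdeconvError("panel and loadings must list the same variants in the same order")

    match = match_variants(sumstats, panel, remove_ambiguous=config.remove_ambiguous)
    _check_overlap(match.n_matched, config)
    f0, fk = harmonize(sumstats, panel, match)
    rows = match.idx_panel

    n_subsampled = match.n_matched
    if config.n_subsample_variants is not None and config.n_subsample_variants < match.n_matched:
        rng = np.random.default_rng(config.seed)
        pick = np.sort(
            rng.choice(match.n_matched, size=config.n_subsample_variants, replace=False)
        )
        f0, fk, rows = f0[pick], fk[pick], rows[pick]
        n_subsampled = len(pick)

    if config.mode == "pc":
        sub_loadings = loadings.subset(rows)
        if sub_loadings.center is None:
            # centering cannot change the fit (coefficients sum to 1) but
            # keeps the projections numerically small
            sub_loadings.center = fk.mean(axis=1)
        cohort_pt = project_frequencies(f0, sub_loadings, apply_correction=True)
        centered = fk - sub_loadings.center[:, None]
        panel_pts = sub_loadings.loadings.T @ centered
        problem = build_problem_pc(cohort_pt, panel_pts, panel.groups)
    else:
        problem = build_problem_freq(f0, fk, panel.groups)

    result = solve_simplex_ls(problem)
    result.mode = config.mode
    merged = merge_proportions(result, config.merge_map)

    counts = {
        "n_input": match.n_input,
        "n_ambiguous_removed": match.n_ambiguous_removed,
        "n_unmatched": match.n_input - match.n_ambiguous_removed - match.n_matched,
        "n_matched": match.n_matched,
        "n_swapped": int(match.swapped.sum()),
        "n_strand_flipped": int(match.strand_flipped.sum()),
        "n_used": n_subsampled,
    }
    cfg = asdict(config)
    report = RunReport(
        groups=result.groups,
        alpha=result.alpha.tolist(),
        merged_groups=merged.groups,
        merged_alpha=merged.alpha.tolist(),
        objective=result.objective,
        mode=config.mode,
        counts=counts,
        config=cfg,
        caveats=[
            "cohort allele frequencies are taken at face value; whether they "
            "were computed before or after quality control, or how meta-"
            "analysis frequencies were weighted, is not verifiable here"
        ],
    )
    return merged, report


def run_summary(
    sumstats_path: str | Path,
    panel_path: str | Path,
    loadings_path: str | Path,
    config: RunConfig | None = None,
) -> tuple[AncestryProportions, RunReport]:
    """Estimate ancestry proportions of a cohort from its summary statistics."""
    config = config or RunConfig()
    sumstats = read_freq_table(sumstats_path, column_map=config.column_map)
    panel = read_panel(panel_path)
    loadings = read_loadings(loadings_path)
    return deconvolve_tables(sumstats, panel, loadings, config)


def read_dosages(path: str | Path, column_map: Mapping[str, str] | None = None) -> FreqTable:
    """Read an individual's dosage file (chr, pos, a1, a2, dosage in {0,1,2}).

    Missing dosages are dropped with a count; dosages are halved into the
    frequency-like vector the pipeline consumes.  Returns a FreqTable whose
    ``n_eff`` records the number of non-missing dosages.
    """
    cmap = {"freq": "dosage"}
    if column_map:
        cmap.update(column_map)
    import pandas as pd

    from .sumstats_match import DEFAULT_COLUMN_MAP, _clean_variant_frame, _sep_for

    full_map = dict(DEFAULT_COLUMN_MAP)
    full_map.update(cmap)
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    except OSError as exc:
        raise SumdeconvError(f"cannot read dosage file {path!r}: {exc}") from exc
    missing_cols = [v for v in full_map.values() if v not in raw.columns]
    if missing_cols:
        raise SumdeconvError(f"{path}: required column(s) {missing_cols} not found")
    df = raw[[full_map[r] for r in ("chrom", "pos", "a1", "a2", "freq")]].copy()
    df.columns = ["chrom", "pos", "a1", "a2", "dosage"]
    dosage = pd.to_numeric(df["dosage"], errors="coerce")
    ok = dosage.isin([0, 1, 2])
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info("read_dosages(%s): %d missing/invalid dosages dropped", path, n_missing)
    df = df[ok]
    df["dosage"] = dosage[ok]
    df, counts = _clean_variant_frame(df)
    if len(df) == 0:
        raise SumdeconvError(f"{path}: no usable dosages")
    table = FreqTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        a1=df["a1"].to_numpy(dtype=object),
        a2=df["a2"].to_numpy(dtype=object),
        freq=df["dosage"].to_numpy(dtype=float) / 2.0,
        n_eff=float(len(df)),
    )
    table.n_missing = n_missing  # type: ignore[attr-defined]
    return table


def run_individual(
    dosage_path: str | Path,
    panel_path: str | Path,
    loadings_path: str | Path,
    config: RunConfig | None = None,
) -> tuple[AncestryProportions, RunReport]:
    """Estimate an individual's ancestry proportions from genotype dosages.

    Identical to :func:`run_summary` with the individual's dosages divided
    by 2 standing in for cohort allele frequencies.  Aborts when more than
    half of the panel-matched positions had missing dosage.
    """
    config = config or RunConfig()
    table = read_dosages(dosage_path, column_map=config.column_map)
    panel = read_panel(panel_path)
    loadings = read_loadings(loadings_path)
    merged, report = deconvolve_tables(table, panel, loadings, config)
    n_missing = getattr(table, "n_missing", 0)
    n_matched = report.counts["n_matched"]
    if n_missing > n_matched:
        raise SumdeconvError(
            f"more than half of dosages missing ({n_missing} missing vs "
            f"{n_matched} matched); refusing to report proportions"
        )
    report.counts["n_missing_dosage"] = n_missing
    return merged, report
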