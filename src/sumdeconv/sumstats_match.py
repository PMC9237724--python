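"""Reading and harmonizing variant tables.

GWAS summary statistics and a multi-population reference panel rarely agree
on how each biallelic SNP is reported: the two alleles may be listed in
either order (an *allele swap*, which complements the reported frequency,
f -> 1 - f) and may be written on either DNA strand (a *strand flip*,
A<->T / C<->G, which leaves the frequency unchanged).  This module reads
both kinds of table from delimited text, matches variants on
chromosome/position/allele-pair under the four possible transformations,
and produces frequency vectors that refer to the same allele of the same
variant on both sides.

Only single-nucleotide biallelic variants are supported; indels and
multi-allelic records are dropped at read time.  Strand-ambiguous variants
(A/T and C/G pairs, for which strand cannot be inferred) are removed by
default before matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sumdeconv")

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs that are their own strand complement
AMBIGUOUS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})

#: default mapping of semantic column roles to header names
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "chrom": "chr",
    "pos": "pos",
    "a1": "a1",
    "a2": "a2",
    "freq": "freq",
}


class SumdeconvError(RuntimeError):
    """Fatal error in the deconvolution pipeline."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of one biallelic SNP: chromosome, 1-based position, alleles."""

    chrom: str
    pos: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.a1 not in VALID_BASES or self.a2 not in VALID_BASES:
            raise ValueError(f"alleles must be single A/C/G/T bases: {self.a1}/{self.a2}")
        if self.a1 == self.a2:
            raise ValueError(f"alleles must differ, got {self.a1}/{self.a2}")

    @property
    def is_ambiguous(self) -> bool:
        return frozenset((self.a1, self.a2)) in AMBIGUOUS_PAIRS


def normalize_chrom(chrom: object) -> str:
    """Normalize a chromosome label: strip 'chr' prefix, uppercase X/Y/MT."""
    s = str(chrom).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y", "mt", "m"):
        s = "MT" if s.lower() in ("mt", "m") else s.upper()
    return s


@dataclass
class FreqTable:
    """Variants with the frequency of allele ``a2``, in file order.

    Columns are stored as parallel arrays for speed; ``variants`` builds
    :class:`VariantKey` objects on demand.
    """

    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    freq: np.ndarray
    n_eff: float | None = None

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "a1", "a2", "freq"):
            if len(getattr(self, name)) != n:
                raise ValueError("FreqTable columns must have equal length")
        if n and (np.min(self.freq) < 0 or np.max(self.freq) > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def variants(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), x, y)
            for c, p, x, y in zip(self.chrom, self.pos, self.a1, self.a2)
        ]


@dataclass
class ReferencePanel:
    """Per-population allele frequencies for M variants across K groups.

    ``freqs[j, k]`` is the frequency of allele ``a2`` of variant j in
    population k; ``sizes`` are the per-group reference sample sizes N.
    """

    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    freqs: np.ndarray
    groups: list[str]
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2:
            raise ValueError("freqs must be an M x K matrix")
        m, k = self.freqs.shape
        if len(self.pos) != m:
            raise ValueError("freqs row count must match variant count")
        if len(self.groups) != k or len(self.sizes) != k:
            raise ValueError("groups and sizes must match freqs column count")
        if len(set(self.groups)) != k:
            raise ValueError("group names must be unique")
        if np.any(np.asarray(self.sizes) <= 0):
            raise ValueError("group sizes must be positive")
        if m and (self.freqs.min() < 0 or self.freqs.max() > 1):
            raise ValueError("panel frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def variants(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), x, y)
            for c, p, x, y in zip(self.chrom, self.pos, self.a1, self.a2)
        ]


@dataclass
class MatchResult:
    """Index pairing between a summary-statistics table and a panel."""

    idx_sumstats: np.ndarray
    idx_panel: np.ndarray
    swapped: np.ndarray
    strand_flipped: np.ndarray
    n_input: int
    n_matched: int = field(init=False)
    n_ambiguous_removed: int = 0

    def __post_init__(self) -> None:
        n = len(self.idx_sumstats)
        if not (len(self.idx_panel) == len(self.swapped) == len(self.strand_flipped) == n):
            raise ValueError("MatchResult arrays must be parallel")
        if len(np.unique(self.idx_panel)) != n:
            raise ValueError("each panel index may appear at most once")
        self.n_matched = n
        if self.n_matched > self.n_input:
            raise ValueError("n_matched cannot exceed n_input")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _clean_variant_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Normalize and filter a variant frame in place; return it with drop counts."""
    counts: dict[str, int] = {}
    df["chrom"] = df["chrom"].map(normalize_chrom)
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.strip().str.upper()

    pos_num = pd.to_numeric(df["pos"], errors="coerce")
    ok_pos = pos_num.notna() & (pos_num >= 1) & (pos_num == pos_num.round())
    counts["n_bad_position"] = int((~ok_pos).sum())

    ok_allele = (
        df["a1"].isin(list(VALID_BASES))
        & df["a2"].isin(list(VALID_BASES))
        & (df["a1"] != df["a2"])
    )
    counts["n_bad_alleles"] = int((ok_pos & ~ok_allele).sum())

    df = df[ok_pos & ok_allele].copy()
    df["pos"] = pos_num[ok_pos & ok_allele].astype(np.int64)

    # duplicate key: same chrom/pos/unordered allele pair; keep first occurrence
    lo = np.minimum(df["a1"].to_numpy(), df["a2"].to_numpy())
    hi = np.maximum(df["a1"].to_numpy(), df["a2"].to_numpy())
    dup = pd.DataFrame({"c": df["chrom"], "p": df["pos"], "l": lo, "h": hi}).duplicated()
    counts["n_duplicate"] = int(dup.sum())
    return df[~dup.to_numpy()], counts


def read_freq_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    n_eff: float | None = None,
) -> FreqTable:
    """Read a summary-statistics table from delimited text.

    ``column_map`` maps the semantic roles chrom/pos/a1/a2/freq to header
    names; unmapped roles use :data:`DEFAULT_COLUMN_MAP`.  Rows with a
    missing or out-of-range frequency, non-ACGT or non-SNP alleles, or a
    duplicate (chrom, pos, {a1,a2}) key are dropped with counts logged;
    surviving rows keep file order.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    except OSError as exc:
        raise SumdeconvError(f"cannot read summary statistics file {path!r}: {exc}") from exc
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise SumdeconvError(
            f"{path}: required column(s) {missing} not found among {list(raw.columns)}"
        )
    df = raw[[cmap[r] for r in ("chrom", "pos", "a1", "a2", "freq")]].copy()
    df.columns = ["chrom", "pos", "a1", "a2", "freq"]

    freq = pd.to_numeric(df["freq"], errors="coerce")
    ok_freq = freq.notna() & (freq >= 0) & (freq <= 1)
    n_bad_freq = int((~ok_freq).sum())
    df = df[ok_freq]
    df["freq"] = freq[ok_freq]

    df, counts = _clean_variant_frame(df)
    counts["n_bad_freq"] = n_bad_freq
    dropped = {k: v for k, v in counts.items() if v}
    if dropped:
        logger.info("read_freq_table(%s): dropped rows %s", path, dropped)
    if len(df) == 0:
        raise SumdeconvError(f"{path}: empty table after filtering")
    return FreqTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        a1=df["a1"].to_numpy(dtype=object),
        a2=df["a2"].to_numpy(dtype=object),
        freq=df["freq"].to_numpy(dtype=float),
        n_eff=n_eff,
    )


def read_panel(path: str | Path) -> ReferencePanel:
    """Read a reference panel from delimited text.

    Format (documented in the README): an optional first line
    ``##sizes<TAB>N1<TAB>...<TAB>NK`` giving the per-group reference sample
    sizes, then a header line ``chr pos a1 a2 <group1> ... <groupK>``, then
    one row per variant.  Separator is comma for ``.csv``, tab otherwise.
    """
    sep = _sep_for(path)
    sizes: np.ndarray | None = None
    try:
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("##sizes"):
                sizes = np.array([int(x) for x in first.rstrip("\n").split(sep)[1:]])
                df = pd.read_csv(fh, sep=sep, dtype=str)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep=sep, dtype=str)
    except OSError as exc:
        raise SumdeconvError(f"cannot read panel file {path!r}: {exc}") from exc
    fixed = ["chr", "pos", "a1", "a2"]
    if list(df.columns[:4]) != fixed:
        raise SumdeconvError(f"{path}: panel must start with columns {fixed}")
    groups = list(df.columns[4:])
    if not groups:
        raise SumdeconvError(f"{path}: panel has no population frequency columns")
    df = df.rename(columns={"chr": "chrom"})
    freqs = df[groups].apply(pd.to_numeric, errors="coerce")
    ok = freqs.notna().all(axis=1).to_numpy()
    n_bad = int((~ok).sum())
    df = df[ok]
    freqs = freqs[ok]
    df, counts = _clean_variant_frame(df)
    freqs = freqs.loc[df.index]
    counts["n_missing_freq"] = n_bad
    dropped = {k: v for k, v in counts.items() if v}
    if dropped:
        logger.info("read_panel(%s): dropped rows %s", path, dropped)
    if len(df) == 0:
        raise SumdeconvError(f"{path}: empty panel after filtering")
    if sizes is None:
        logger.warning("read_panel(%s): no ##sizes line; assuming size 1 per group", path)
        sizes = np.ones(len(groups), dtype=int)
    if len(sizes) != len(groups):
        raise SumdeconvError(f"{path}: ##sizes line has {len(sizes)} entries for {len(groups)} groups")
    return ReferencePanel(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        a1=df["a1"].to_numpy(dtype=object),
        a2=df["a2"].to_numpy(dtype=object),
        freqs=freqs.to_numpy(dtype=float),
        groups=groups,
        sizes=sizes,
    )


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _complement_array(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    for base, comp in COMPLEMENT.items():
        out[a == base] = comp
    return out


def _ambiguous_mask(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | (
        (a1 == "C") & (a2 == "G")
    ) | ((a1 == "G") & (a2 == "C"))


def match_variants(
    sumstats: FreqTable,
    panel: ReferencePanel,
    remove_ambiguous: bool = True,
) -> MatchResult:
    """Match variants between a summary-statistics table and a panel.

    A variant matches when chromosome and position agree and the allele pair
    agrees under one of four transformations: identity, allele swap
    (a1<->a2), strand complement, or swap + complement.  With
    ``remove_ambiguous`` (default), A/T and C/G variants — whose strand
    cannot be inferred — are excluded before matching.  One-to-one matching
    is enforced; on ties the first panel row wins.
    """
    if len(sumstats) == 0 or len(panel) == 0:
        raise SumdeconvError("cannot match empty tables")
    n_input = len(sumstats)

    s_a1 = np.asarray(sumstats.a1, dtype=object)
    s_a2 = np.asarray(sumstats.a2, dtype=object)
    keep = np.ones(n_input, dtype=bool)
    if remove_ambiguous:
        keep = ~_ambiguous_mask(s_a1, s_a2)
    n_ambiguous = int(n_input - keep.sum())

    sdf = pd.DataFrame(
        {
            "chrom": sumstats.chrom[keep],
            "pos": sumstats.pos[keep],
            "a1": s_a1[keep],
            "a2": s_a2[keep],
            "sidx": np.flatnonzero(keep),
        }
    )
    pdf = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "pa1": panel.a1,
            "pa2": panel.a2,
            "pidx": np.arange(len(panel)),
        }
    )
    c1 = _complement_array(sdf["a1"].to_numpy(dtype=object))
    c2 = _complement_array(sdf["a2"].to_numpy(dtype=object))
    # transforms ordered by priority: identity, swap, flip, swap+flip
    transforms = [
        (sdf["a1"], sdf["a2"], False, False),
        (sdf["a2"], sdf["a1"], True, False),
        (c1, c2, False, True),
        (c2, c1, True, True),
    ]
    pieces = []
    for prio, (ta1, ta2, swap, flip) in enumerate(transforms):
        cand = sdf[["chrom", "pos", "sidx"]].copy()
        cand["pa1"] = np.asarray(ta1)
        cand["pa2"] = np.asarray(ta2)
        hit = cand.merge(pdf, on=["chrom", "pos", "pa1", "pa2"], how="inner")
        if len(hit):
            hit = hit[["sidx", "pidx"]].copy()
            hit["swapped"] = swap
            hit["strand_flipped"] = flip
            hit["prio"] = prio
            pieces.append(hit)
    if not pieces:
        raise SumdeconvError("no overlap between summary statistics and panel")
    hits = pd.concat(pieces, ignore_index=True)
    # per sumstats variant: lowest transform priority, then first panel row
    hits = hits.sort_values(["sidx", "prio", "pidx"], kind="stable")
    before = len(hits)
    hits = hits.drop_duplicates("sidx", keep="first")
    if len(hits) < before:
        logger.warning(
            "match_variants: %d multi-way matches resolved to first panel row",
            before - len(hits),
        )
    # enforce one-to-one on the panel side (first sumstats row wins)
    before = len(hits)
    hits = hits.sort_values(["pidx", "sidx"], kind="stable").drop_duplicates("pidx", keep="first")
    if len(hits) < before:
        logger.warning(
            "match_variants: %d summary-statistics rows dropped (panel row already matched)",
            before - len(hits),
        )
    hits = hits.sort_values("pidx", kind="stable")
    if len(hits) == 0:
        raise SumdeconvError("no overlap between summary statistics and panel")
    result = MatchResult(
        idx_sumstats=hits["sidx"].to_numpy(),
        idx_panel=hits["pidx"].to_numpy(),
        swapped=hits["swapped"].to_numpy(dtype=bool),
        strand_flipped=hits["strand_flipped"].to_numpy(dtype=bool),
        n_input=n_input,
        n_ambiguous_removed=n_ambiguous,
    )
    logger.info(
        "match_variants: n_input=%d n_ambiguous_removed=%d n_matched=%d "
        "n_swapped=%d n_strand_flipped=%d",
        n_input,
        n_ambiguous,
        result.n_matched,
        int(result.swapped.sum()),
        int(result.strand_flipped.sum()),
    )
    return result


def harmonize(
    sumstats: FreqTable,
    panel: ReferencePanel,
    match: MatchResult,
) -> tuple[np.ndarray, np.ndarray]:
    """Return aligned (cohort frequency vector, panel frequency matrix).

    Both outputs are ordered by panel index.  Where the match swapped the
    allele order the cohort frequency is complemented (f -> 1 - f); strand
    flips alone leave the frequency unchanged.
    """
    if match.n_matched == 0:
        raise SumdeconvError("empty match")
    if match.idx_sumstats.max() >= len(sumstats) or match.idx_panel.max() >= len(panel):
        raise SumdeconvError("stale MatchResult: index out of range for these tables")
    f0 = sumstats.freq[match.idx_sumstats].astype(float).copy()
    f0[match.swapped] = 1.0 - f0[match.swapped]
    fk = panel.freqs[match.idx_panel, :]
    return f0, fk


def write_freq_table(table: FreqTable, path: str | Path) -> None:
    """Write a FreqTable in the dialect :func:`read_freq_table` reads."""
    sep = _sep_for(path)
    df = pd.DataFrame(
        {
            "chr": table.chrom,
            "pos": table.pos,
            "a1": table.a1,
            "a2": table.a2,
            "freq": table.freq,
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    """Write a ReferencePanel in the dialect :func:`read_panel` reads."""
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write("##sizes" + sep + sep.join(str(int(n)) for n in panel.sizes) + "\n")
        df = pd.DataFrame(
            {"chr": panel.chrom, "pos": panel.pos, "a1": panel.a1, "a2": panel.a2}
        )
        for k, g in enumerate(panel.groups):
            df[g] = panel.freqs[:, k]
        df.to_csv(fh, sep=sep, index=False, float_format="%.17g")
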