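"""Sliding-window divergence statistics over codon-aware alignments.

Two windowed statistics, both computed over all unordered taxon pairs:

* per-codon-position nucleotide diversity (pi), the mean pairwise proportion
  of differing sites at codon positions 1, 2 and 3, with gap/N pair-sites
  treated as missing; and
* dN/dS by the Nei–Gojobori (1986) counting method with the Jukes–Cantor
  multiple-hit correction, summarized per window as mean(dN)/mean(dS) with a
  percentile bootstrap over the window's codon columns for the 95% interval.

The counting estimator stands in for phylogenetic MG94 likelihood fits: it is
exactly specifiable, oracle-checkable against brute-force codon enumeration,
and adequate for the contrast of interest (purifying selection, omega < 1).
Windows default to 90 nt with a 3 nt step; both must be multiples of 3 so
every window starts on a codon boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._genetic_code import (
    NG86_SITES,
    STOP_CODONS,
    ng86_pair_differences_cached,
)
from .io_formats import SequenceRecord

__all__ = [
    "CodonAlignment",
    "WindowStats",
    "Ng86Counts",
    "remove_stop_codons",
    "window_pi",
    "ng86_pair",
    "window_dnds",
    "windows_to_frame",
]

_VALID_BASES = frozenset("ACGT")


@dataclass
class CodonAlignment:
    """An aligned, frame-anchored nucleotide matrix over named taxa.

    Frame is anchored at column 0 and the alignment length must be a multiple
    of three, as produced by codon-aware aligners.
    """

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must have the same length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.length % 3 != 0:
            raise ValueError(f"alignment length {self.length} is not a multiple of 3")
        bad = set("".join(self.rows)) - set("ACGTN-")
        if bad:
            raise ValueError(f"alignment contains characters outside ACGTN-: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @classmethod
    def from_records(cls, records: list[SequenceRecord]) -> "CodonAlignment":
        return cls(taxa=[r.id for r in records], rows=[r.seq for r in records])

    def codon(self, taxon_index: int, codon_index: int) -> str:
        return self.rows[taxon_index][3 * codon_index : 3 * codon_index + 3]

    def slice_codons(self, start_codon: int, end_codon: int) -> "CodonAlignment":
        a, b = 3 * start_codon, 3 * end_codon
        return CodonAlignment(taxa=list(self.taxa), rows=[r[a:b] for r in self.rows])


@dataclass
class Ng86Counts:
    """Site and difference counts for one sequence pair (Nei–Gojobori 1986)."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    n_codons: int
    flag: str = "ok"

    @property
    def dnds(self) -> float:
        if self.dS > 0 and math.isfinite(self.dN):
            return self.dN / self.dS
        return math.nan


@dataclass
class WindowStats:
    """Statistics for one sliding window (all coordinates 0-based columns)."""

    start: int
    width: int
    pi1: float = math.nan
    pi2: float = math.nan
    pi3: float = math.nan
    dn: float = math.nan
    ds: float = math.nan
    dnds_mean: float = math.nan
    dnds_ci_low: float = math.nan
    dnds_ci_high: float = math.nan
    flags: list[str] = field(default_factory=list)

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.start + self.width


# ---------------------------------------------------------------------------
# Stop-codon stripping
# ---------------------------------------------------------------------------

def remove_stop_codons(aln: CodonAlignment) -> tuple[CodonAlignment, list[int]]:
    """Delete every codon column-triplet where any taxon shows an in-frame stop.

    Deleting the full triplet in all taxa keeps the matrix rectangular and in
    frame.  Returns the filtered alignment and the removed codon indices.
    """
    removed: list[int] = []
    for k in range(aln.n_codons):
        for t in range(aln.n_taxa):
            if aln.codon(t, k) in STOP_CODONS:
                removed.append(k)
                break
    if not removed:
        return aln, []
    keep = [k for k in range(aln.n_codons) if k not in set(removed)]
    if not keep:
        warnings.warn("all codon columns contained stop codons; alignment is empty")
    rows = ["".join(r[3 * k : 3 * k + 3] for k in keep) for r in aln.rows]
    return CodonAlignment(taxa=list(aln.taxa), rows=rows), removed


# ---------------------------------------------------------------------------
# Window bookkeeping
# ---------------------------------------------------------------------------

def window_starts(length: int, window: int, step: int) -> list[int]:
    """Start columns 0, step, ... with the last start at length - window."""
    if window % 3 or step % 3:
        raise ValueError("window and step must be multiples of 3")
    if window > length:
        raise ValueError(f"window {window} exceeds alignment length {length}")
    if step <= 0:
        raise ValueError("step must be positive")
    return list(range(0, length - window + 1, step))


def _taxon_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


# ---------------------------------------------------------------------------
# Nucleotide diversity by codon position
# ---------------------------------------------------------------------------

def window_pi(aln: CodonAlignment, window: int = 90, step: int = 3) -> list[WindowStats]:
    """Sliding-window mean pairwise diversity at codon positions 1, 2, 3.

    Per pair, pi_k = (mismatches at position-k sites with both bases ACGT) /
    (position-k sites with both bases ACGT); the window value is the mean
    over pairs with at least one comparable site.  Pairs with none are
    flagged (``pi_pair_undefined``); a window with no defined pair for a
    position reports NaN.
    """
    starts = window_starts(aln.length, window, step)
    pairs = _taxon_pairs(aln.n_taxa)
    if not pairs:
        raise ValueError("need at least 2 taxa")

    mat = np.frombuffer("".join(aln.rows).encode(), dtype="S1").reshape(aln.n_taxa, aln.length)
    valid = np.isin(mat, np.array([b"A", b"C", b"G", b"T"]))
    comp = np.empty((len(pairs), aln.length), dtype=bool)
    diff = np.empty((len(pairs), aln.length), dtype=bool)
    for p, (i, j) in enumerate(pairs):
        comp[p] = valid[i] & valid[j]
        diff[p] = comp[p] & (mat[i] != mat[j])

    out: list[WindowStats] = []
    for s in starts:
        ws = WindowStats(start=s, width=window)
        cols = np.arange(s, s + window)
        for k in (1, 2, 3):
            sel = cols[(cols % 3) == (k - 1)]
            nc = comp[:, sel].sum(axis=1).astype(float)
            nd = diff[:, sel].sum(axis=1).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                per_pair = np.where(nc > 0, nd / np.where(nc > 0, nc, 1), np.nan)
            if np.isnan(per_pair).any():
                ws.flags.append(f"pi{k}_pair_undefined")
            value = float(np.nanmean(per_pair)) if np.isfinite(per_pair).any() else math.nan
            setattr(ws, f"pi{k}", value)
        out.append(ws)
    return out


# ---------------------------------------------------------------------------
# NG86 pairwise dN/dS
# ---------------------------------------------------------------------------

def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes–Cantor distance -3/4 ln(1 - 4p/3); out of domain at p >= 0.75."""
    if p < 0.75:
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0), True
    return p, False


def ng86_pair(codons_a: str, codons_b: str) -> Ng86Counts:
    """Nei–Gojobori site and difference counts for a pair of codon strings.

    Codon pairs where either codon contains a gap or N are skipped.  Multi-hit
    codons are averaged over minimal mutation paths with stop-crossing paths
    excluded.  The Jukes–Cantor correction is applied when the raw proportion
    is in domain (< 0.75); otherwise the raw proportion is reported and the
    pair flagged ``out_of_domain``.
    """
    if len(codons_a) != len(codons_b):
        raise ValueError("codon strings differ in length")
    if len(codons_a) % 3:
        raise ValueError("codon string length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for k in range(0, len(codons_a), 3):
        ca, cb = codons_a[k : k + 3], codons_b[k : k + 3]
        if not (_VALID_BASES.issuperset(ca) and _VALID_BASES.issuperset(cb)):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in input at codon {k // 3}; strip stops first")
        n_codons += 1
        sa, na = NG86_SITES[ca]
        sb, nb = NG86_SITES[cb]
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = ng86_pair_differences_cached(ca, cb)
        Sd += sd
        Nd += nd

    flag = "ok"
    if n_codons == 0:
        return Ng86Counts(0, 0, 0, 0, math.nan, math.nan, math.nan, math.nan, 0, "no_comparable_codons")
    if S == 0:
        flag = "no_synonymous_sites"
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    dS = dN = math.nan
    if not math.isnan(pS):
        dS, ok = _jc_correct(pS)
        if not ok:
            flag = "out_of_domain"
    if not math.isnan(pN):
        dN, ok = _jc_correct(pN)
        if not ok:
            flag = "out_of_domain"
    return Ng86Counts(S, N, Sd, Nd, pS, pN, dS, dN, n_codons, flag)


class _PairCodonTables:
    """Per-pair, per-codon-column NG86 quantities, precomputed once.

    Arrays of shape (n_pairs, n_codons): synonymous/nonsynonymous sites and
    differences, plus a validity mask (both codons fully ACGT).  Window and
    bootstrap sums reduce over codon columns of these tables.
    """

    def __init__(self, aln: CodonAlignment):
        pairs = _taxon_pairs(aln.n_taxa)
        nc = aln.n_codons
        self.pairs = pairs
        self.S = np.zeros((len(pairs), nc))
        self.N = np.zeros((len(pairs), nc))
        self.Sd = np.zeros((len(pairs), nc))
        self.Nd = np.zeros((len(pairs), nc))
        self.valid = np.zeros((len(pairs), nc), dtype=bool)
        codons = [[aln.codon(t, k) for k in range(nc)] for t in range(aln.n_taxa)]
        for p, (i, j) in enumerate(pairs):
            for k in range(nc):
                ca, cb = codons[i][k], codons[j][k]
                if not (_VALID_BASES.issuperset(ca) and _VALID_BASES.issuperset(cb)):
                    continue
                if ca in STOP_CODONS or cb in STOP_CODONS:
                    raise ValueError("stop codon encountered; run remove_stop_codons first")
                sa, na = NG86_SITES[ca]
                sb, nb = NG86_SITES[cb]
                self.S[p, k] = 0.5 * (sa + sb)
                self.N[p, k] = 0.5 * (na + nb)
                sd, nd = ng86_pair_differences_cached(ca, cb)
                self.Sd[p, k] = sd
                self.Nd[p, k] = nd
                self.valid[p, k] = True


def _pairwise_dn_ds(S: np.ndarray, N: np.ndarray, Sd: np.ndarray, Nd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized JC-corrected dN, dS per pair; NaN where degenerate.

    Degenerate pairs (no synonymous or nonsynonymous sites, or a proportion
    at/beyond the JC domain) come back NaN so callers can exclude them.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        pS = np.where(S > 0, Sd / np.where(S > 0, S, 1.0), np.nan)
        pN = np.where(N > 0, Nd / np.where(N > 0, N, 1.0), np.nan)
        dS = np.where(pS < 0.75, -0.75 * np.log(1.0 - 4.0 * np.minimum(pS, 0.7499) / 3.0), np.nan)
        dN = np.where(pN < 0.75, -0.75 * np.log(1.0 - 4.0 * np.minimum(pN, 0.7499) / 3.0), np.nan)
    return dN, dS


def window_dnds(
    aln: CodonAlignment,
    window: int = 90,
    step: int = 3,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[WindowStats]:
    """Sliding-window mean dN, dS and dN/dS with percentile bootstrap CIs.

    Per window: dN and dS are means of the NG86 pairwise distances over
    non-degenerate pairs; ``dnds_mean = mean(dN) / mean(dS)`` (flagged
    ``ds_zero`` when mean dS is 0 and ``no_valid_pairs`` when every pair is
    degenerate).  The 95% CI resamples the window's codon columns with
    replacement ``n_boot`` times; ``n_boot=0`` disables the bootstrap.
    """
    starts = window_starts(aln.length, window, step)
    tables = _PairCodonTables(aln)
    rng = np.random.default_rng(seed)
    w_codons = window // 3
    out: list[WindowStats] = []
    for s in starts:
        k0 = s // 3
        sl = slice(k0, k0 + w_codons)
        S = tables.S[:, sl].sum(axis=1)
        N = tables.N[:, sl].sum(axis=1)
        Sd = tables.Sd[:, sl].sum(axis=1)
        Nd = tables.Nd[:, sl].sum(axis=1)
        ws = WindowStats(start=s, width=window)
        dN, dS = _pairwise_dn_ds(S, N, Sd, Nd)
        good = np.isfinite(dN) & np.isfinite(dS)
        if not good.any():
            ws.flags.append("no_valid_pairs")
            out.append(ws)
            continue
        if good.sum() < 2:
            ws.flags.append("fewer_than_2_pairs")
        ws.dn = float(dN[good].mean())
        ws.ds = float(dS[good].mean())
        if ws.ds > 0:
            ws.dnds_mean = ws.dn / ws.ds
        else:
            ws.flags.append("ds_zero")
        if n_boot > 0 and math.isfinite(ws.dnds_mean):
            idx = rng.integers(k0, k0 + w_codons, size=(n_boot, w_codons))
            ratios = _bootstrap_ratios(tables, idx)
            if np.isfinite(ratios).sum() >= max(2, n_boot // 20):
                ws.dnds_ci_low = float(np.nanpercentile(ratios, 2.5))
                ws.dnds_ci_high = float(np.nanpercentile(ratios, 97.5))
            else:
                ws.flags.append("bootstrap_degenerate")
        out.append(ws)
    return out


def _bootstrap_ratios(tables: _PairCodonTables, idx: np.ndarray) -> np.ndarray:
    """mean(dN)/mean(dS) per bootstrap replicate of codon columns."""
    # (n_pairs, n_boot, w) -> sum over resampled columns -> (n_pairs, n_boot)
    S = tables.S[:, idx].sum(axis=2)
    N = tables.N[:, idx].sum(axis=2)
    Sd = tables.Sd[:, idx].sum(axis=2)
    Nd = tables.Nd[:, idx].sum(axis=2)
    dN, dS = _pairwise_dn_ds(S, N, Sd, Nd)
    good = np.isfinite(dN) & np.isfinite(dS)
    dN = np.where(good, dN, np.nan)
    dS = np.where(good, dS, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dn = np.nanmean(dN, axis=0)
        mean_ds = np.nanmean(dS, axis=0)
        ratios = np.where(mean_ds > 0, mean_dn / np.where(mean_ds > 0, mean_ds, 1.0), np.nan)
    return ratios


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def windows_to_frame(pi_stats: list[WindowStats], dnds_stats: list[WindowStats] | None = None) -> pd.DataFrame:
    """Merge pi and dN/dS window tracks into one table (1-based coordinates)."""
    rows = []
    dnds_by_start = {w.start: w for w in dnds_stats} if dnds_stats else {}
    for w in pi_stats:
        d = dnds_by_start.get(w.start, WindowStats(start=w.start, width=w.width))
        rows.append(
            {
                "start_1based": w.start_1based,
                "end_1based": w.end_1based,
                "pi1": w.pi1,
                "pi2": w.pi2,
                "pi3": w.pi3,
                "dN": d.dn,
                "dS": d.ds,
                "dNdS_mean": d.dnds_mean,
                "ci_low": d.dnds_ci_low,
                "ci_high": d.dnds_ci_high,
                "flags": ";".join(w.flags + d.flags) or ".",
            }
        )
    return pd.DataFrame(rows)
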