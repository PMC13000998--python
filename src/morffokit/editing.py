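"""RNA-editing site classification from per-site read-count pileups.

Fern plastid transcripts undergo C-to-U and, distinctively, reverse U-to-C
editing.  Given a pileup of RNA reads mapped back to the DNA sequence of each
gene, a site is called edited when three thresholds are met simultaneously:

* coverage >= 10 mapped reads,
* >= 3 reads showing the edited base, and
* the edited base on >= 10% of mapped reads.

All three are inclusive (>=) and configurable via :class:`EditingCallConfig`.
Editing efficiency is the proportion of mapped reads displaying the edited
base and is reported for every candidate site, passed or not.  Pileups are
assumed oriented to the CDS sense strand (genes extracted with their flanks
before mapping), so no strand logic lives here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from ._genetic_code import translate_codon
from .io_formats import SequenceRecord

__all__ = [
    "EditingCallConfig",
    "EditingSite",
    "classify_sites",
    "annotate_effect",
    "summarize_editing",
    "sites_to_frame",
]


@dataclass(frozen=True)
class EditingCallConfig:
    min_coverage: int = 10
    min_edit_reads: int = 3
    min_edit_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.min_edit_reads < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_edit_fraction <= 1.0:
            raise ValueError("min_edit_fraction must be in [0, 1]")


@dataclass(frozen=True)
class EditingSite:
    """One candidate editing site (positions 1-based within the pileup region)."""

    gene_id: str
    pos: int
    ref_base: str
    edit_base: str
    edit_type: str  # "C-to-U", "U-to-C", or "other"
    coverage: int
    edit_reads: int
    efficiency: float
    passed: bool
    codon_pos: int | str | None = None  # 1/2/3 or "noncoding"
    ref_aa: str | None = None
    edit_aa: str | None = None
    tied: bool = False

    @property
    def silent(self) -> bool | None:
        if self.ref_aa is None or self.edit_aa is None:
            return None
        return self.ref_aa == self.edit_aa


def _edit_type(ref: str, alt: str) -> str:
    if ref == "C" and alt == "T":
        return "C-to-U"
    if ref == "T" and alt == "C":
        return "U-to-C"
    return "other"


def classify_sites(pileup: pd.DataFrame, cfg: EditingCallConfig | None = None) -> list[EditingSite]:
    """Call candidate editing sites from a validated pileup table.

    The candidate edit base at each site is the non-reference base with the
    highest read count; on ties every tied base is emitted as its own
    candidate row (marked ``tied``) for review.  Sites with no non-reference
    reads yield no candidate.  Output order follows (gene_id, pos), so it is
    invariant under row order of the input.
    """
    cfg = cfg or EditingCallConfig()
    sites: list[EditingSite] = []
    df = pileup.sort_values(["gene_id", "pos"], kind="mergesort")
    for row in df.itertuples(index=False):
        counts = {"A": row.count_A, "C": row.count_C, "G": row.count_G, "T": row.count_T}
        ref = row.ref_base
        alt_counts = {b: c for b, c in counts.items() if b != ref}
        top = max(alt_counts.values())
        if top == 0:
            continue
        tied_bases = sorted(b for b, c in alt_counts.items() if c == top)
        for alt in tied_bases:
            coverage = int(row.total)
            edit_reads = int(alt_counts[alt])
            efficiency = edit_reads / coverage if coverage > 0 else math.nan
            passed = (
                coverage >= cfg.min_coverage
                and edit_reads >= cfg.min_edit_reads
                and coverage > 0
                and efficiency >= cfg.min_edit_fraction
            )
            sites.append(
                EditingSite(
                    gene_id=row.gene_id,
                    pos=int(row.pos),
                    ref_base=ref,
                    edit_base=alt,
                    edit_type=_edit_type(ref, alt),
                    coverage=coverage,
                    edit_reads=edit_reads,
                    efficiency=efficiency,
                    passed=passed,
                    tied=len(tied_bases) > 1,
                )
            )
    return sites


def annotate_effect(
    site: EditingSite,
    cds: SequenceRecord,
    cds_offset: int,
    flank: int = 100,
) -> EditingSite:
    """Fill codon position and amino-acid change for a site.

    ``cds_offset`` is the 1-based position of the site within the CDS proper;
    offsets in [-flank, 0] and (len(cds), len(cds)+flank] fall in the
    extracted flanking regions and are annotated ``noncoding``.  Anything
    further out is an error.
    """
    n = len(cds.seq)
    if n % 3 != 0:
        raise ValueError(f"CDS {cds.id} length {n} is not a multiple of 3")
    if cds_offset < -flank or cds_offset > n + flank:
        raise ValueError(f"offset {cds_offset} outside CDS {cds.id} and its +/-{flank} nt flanks")
    if cds_offset <= 0 or cds_offset > n:
        return replace(site, codon_pos="noncoding", ref_aa=None, edit_aa=None)
    codon_pos = (cds_offset - 1) % 3 + 1
    codon_start = cds_offset - codon_pos
    ref_codon = cds.seq[codon_start : codon_start + 3]
    if ref_codon[codon_pos - 1] != site.ref_base:
        raise ValueError(
            f"pileup ref base {site.ref_base} disagrees with CDS {cds.id} "
            f"base {ref_codon[codon_pos - 1]} at offset {cds_offset}"
        )
    edit_codon = ref_codon[: codon_pos - 1] + site.edit_base + ref_codon[codon_pos:]
    return replace(
        site,
        codon_pos=codon_pos,
        ref_aa=translate_codon(ref_codon),
        edit_aa=translate_codon(edit_codon),
    )


def summarize_editing(
    sites: list[EditingSite],
    gene_lengths: dict[str, int],
    include_other: bool = False,
) -> dict[str, float]:
    """Gene-level and site-level editing summary.

    Counts passed sites (C-to-U and U-to-C only, unless ``include_other``);
    ``overall_site_frequency`` is passed sites over total surveyed CDS bases.
    """
    if any(v <= 0 for v in gene_lengths.values()):
        raise ValueError("gene lengths must be positive")
    kept = [
        s
        for s in sites
        if s.passed and (include_other or s.edit_type in ("C-to-U", "U-to-C"))
    ]
    edited_genes = {s.gene_id for s in kept}
    n_genes = len(gene_lengths)
    total_bases = sum(gene_lengths.values())
    return {
        "genes_total": n_genes,
        "genes_with_editing": len(edited_genes),
        "fraction_of_genes": len(edited_genes) / n_genes if n_genes else 0.0,
        "sites_passed": len(kept),
        "total_surveyed_bases": total_bases,
        "overall_site_frequency": len(kept) / total_bases if total_bases else 0.0,
    }


def sites_to_frame(sites: list[EditingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "pos": s.pos,
                "ref_base": s.ref_base,
                "edit_base": s.edit_base,
                "edit_type": s.edit_type,
                "coverage": s.coverage,
                "edit_reads": s.edit_reads,
                "efficiency": s.efficiency,
                "passed": s.passed,
                "codon_pos": s.codon_pos if s.codon_pos is not None else ".",
                "ref_aa": s.ref_aa or ".",
                "edit_aa": s.edit_aa or ".",
                "tied": s.tied,
            }
            for s in sites
        ]
    )
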