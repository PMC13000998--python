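"""Readers and writers for the formats the pipeline touches, plus ORF scanning.

FASTA goes through Biopython, Newick through dendropy (wrapped in
:class:`PhyloTree`), pileup tables through pandas.  The ORF scanner nominates
candidate mobile reading frames the way genome browsers' "find ORFs" tools do:
six frames, ATG starts, longest ORF per stop per frame, with a length floor
(default 500 nt) counted including the stop codon.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from ._genetic_code import STOP_CODONS, reverse_complement

__all__ = [
    "SequenceRecord",
    "OrfRecord",
    "PhyloTree",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_pileup",
    "find_orfs",
    "orfs_to_frame",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N,-}."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame on forward coordinates (0-based, half-open).

    ``length_nt`` includes the stop codon; ``frame`` is the reading frame
    (0/1/2) on the scanned strand.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    length_nt: int
    frame: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.length_nt:
            raise ValueError("end - start must equal length_nt")
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; sequences are upper-cased and U is transliterated to T.

    Raises ``ValueError`` on duplicate ids or an empty file.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """A rooted tree with named leaves and branch lengths.

    Thin wrapper over a :class:`dendropy.Tree`; branch lengths are expected
    substitutions/site for phylograms and Myr for chronograms.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True, rooting="force-rooted"
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"Newick parse error: {exc}") from exc
        obj = cls(tree)
        obj._check_branch_lengths()
        return obj

    def _check_branch_lengths(self) -> None:
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:  # root's own edge may be lengthless
                continue
            if edge.length is None:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "internal node"
                raise ValueError(f"missing branch length on edge leading to {name}")

    # -- properties ---------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def scale(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``."""
        out = self._tree.clone(depth=1)
        for edge in out.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return PhyloTree(out)

    def path_length_matrix(self) -> pd.DataFrame:
        """Leaf-to-leaf patristic distances as a labelled symmetric matrix."""
        pdm = self._tree.phylogenetic_distance_matrix()
        labels = sorted(self.leaf_labels())
        taxa = {t.label: t for t in self._tree.taxon_namespace if t.label in set(labels)}
        mat = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d = pdm.patristic_distance(taxa[a], taxa[b])
                    mat[i, j] = mat[j, i] = d
        return pd.DataFrame(mat, index=labels, columns=labels)

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        """True if all tip-to-root path lengths agree within ``rel_tol``."""
        depths = []
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths.append(d)
        dmax = max(depths)
        if dmax == 0:
            return True
        return (dmax - min(depths)) / dmax <= rel_tol

    def to_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier=".10f",
            ).strip()
            + "\n"
        )


def read_newick(path: str | Path) -> PhyloTree:
    """Read a single rooted tree; every non-root edge must carry a length."""
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Pileup tables
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ["gene_id", "pos", "ref_base", "total", "count_A", "count_C", "count_G", "count_T"]


def read_pileup(path: str | Path | io.StringIO) -> pd.DataFrame:
    """Read a per-site base-count table (TSV with a header row).

    Columns: gene_id, pos (1-based), ref_base, total mapped reads, and
    count_A/C/G/T.  Count sums may fall short of ``total`` (non-ACGT reads)
    but never exceed it; (gene_id, pos) must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pileup is missing columns: {missing}")
    df = df[PILEUP_COLUMNS].copy()
    count_cols = ["total", "count_A", "count_C", "count_G", "count_T"]
    for col in count_cols:
        if (df[col] < 0).any():
            row = int(df.index[df[col] < 0][0]) + 2  # 1-based, counting the header
            raise ValueError(f"negative value in column {col} at file row {row}")
    bad_ref = ~df["ref_base"].isin(list("ACGT"))
    if bad_ref.any():
        row = int(df.index[bad_ref][0]) + 2
        raise ValueError(f"ref_base outside ACGT at file row {row}")
    sums = df[["count_A", "count_C", "count_G", "count_T"]].sum(axis=1)
    over = sums > df["total"]
    if over.any():
        row = int(df.index[over][0]) + 2
        raise ValueError(f"nucleotide counts exceed total mapped reads at file row {row}")
    dup = df.duplicated(subset=["gene_id", "pos"])
    if dup.any():
        g, p = df.loc[df.index[dup][0], ["gene_id", "pos"]]
        raise ValueError(f"duplicate pileup site ({g}, {p})")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def _scan_strand(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """ORFs on one strand as (start, end, frame) in that strand's coordinates.

    Longest ORF per stop per frame: the start is the first ATG after the
    previous in-frame stop.  Codons containing N neither start nor stop an
    ORF, but an ORF may span them.
    """
    n = len(seq)
    out = []
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                end = i + 3
                if end - start >= min_len:
                    out.append((start, end, frame))
                start = None
        # ORFs without a stop codon before the sequence end are not reported
    return out


def find_orfs(seq: str | SequenceRecord, min_len: int = 500, contig_id: str = "contig") -> list[OrfRecord]:
    """Scan all six frames for ATG...stop ORFs of at least ``min_len`` nt.

    ``min_len`` counts the stop codon.  Reverse-strand ORFs are reported on
    forward coordinates (0-based half-open); results sorted by (start, strand).
    """
    if isinstance(seq, SequenceRecord):
        contig_id = seq.id
        seq = seq.seq
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    records: list[OrfRecord] = []
    for start, end, frame in _scan_strand(seq, min_len):
        records.append(OrfRecord(contig_id, start, end, "+", end - start, frame))
    for start, end, frame in _scan_strand(reverse_complement(seq), min_len):
        records.append(OrfRecord(contig_id, n - end, n - start, "-", end - start, frame))
    records.sort(key=lambda r: (r.start, r.strand, r.end))
    return records


def orfs_to_frame(orfs: list[OrfRecord]) -> pd.DataFrame:
    """Tabulate ORFs with 1-based inclusive coordinates for reporting."""
    rows = [
        {
            "contig_id": o.contig_id,
            "start_1based": o.start + 1,
            "end_1based": o.end,
            "strand": o.strand,
            "length_nt": o.length_nt,
            "frame": o.frame,
        }
        for o in orfs
    ]
    return pd.DataFrame(rows, columns=["contig_id", "start_1based", "end_1based", "strand", "length_nt", "frame"])
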