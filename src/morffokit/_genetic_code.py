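"""Standard genetic code tables and codon bookkeeping shared across modules.

The standard code (NCBI table 1) is used throughout.  Plastid genes are
conventionally translated with table 11, but the two tables differ only in
the set of permitted initiation codons, which none of the statistics here
depend on; ATG-only starts are enforced where starts matter (ORF scanning).
"""

from __future__ import annotations

from itertools import permutations, product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons, lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in product(NUCLEOTIDES, repeat=3)) if c not in STOP_CODONS)
)
SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid -> sorted tuple of its synonymous codons (sense only)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa == "*":
        continue
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-base change a->b is a transition (A<->G or C<->T)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stops. KeyError on ambiguity."""
    return CODON_TO_AA[codon]


COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def codon_neighbors(codon: str) -> list[str]:
    """The 9 codons one nucleotide change away, in deterministic order."""
    out = []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base != codon[pos]:
                out.append(codon[:pos] + base + codon[pos + 1 :])
    return out


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986) per-codon tables, precomputed once.
# ---------------------------------------------------------------------------

def _site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each position contributes the fraction of its three possible changes that
    are synonymous / nonsynonymous; changes creating a stop codon are excluded
    from both counts, so S + N <= 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    s = n = 0.0
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            alt_aa = CODON_TO_AA[alt]
            if alt_aa == "*":
                continue
            if alt_aa == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


#: codon -> (S, N) site counts
NG86_SITES: dict[str, tuple[float, float]] = {c: _site_fractions(c) for c in SENSE_CODONS}


def _path_steps(a: str, b: str, order: tuple[int, ...]) -> tuple[float, float, bool]:
    """Walk a->b mutating positions in `order`; count (syn, nonsyn) steps.

    Third element is False if the path passes through a stop codon.
    """
    cur = a
    sd = nd = 0.0
    clean = True
    for pos in order:
        nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
        if CODON_TO_AA[nxt] == "*":
            clean = False
        if CODON_TO_AA[cur] == CODON_TO_AA[nxt] and CODON_TO_AA[cur] != "*":
            sd += 1.0
        else:
            nd += 1.0
        cur = nxt
    return sd, nd, clean


def ng86_codon_differences(a: str, b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal mutation paths.

    Paths passing through a stop codon are excluded; if every path does, all
    paths are used (stop-crossing steps scored nonsynonymous) so the pair is
    never silently dropped.
    """
    diff_pos = tuple(i for i in range(3) if a[i] != b[i])
    if not diff_pos:
        return 0.0, 0.0
    clean_paths: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        sd, nd, clean = _path_steps(a, b, order)
        all_paths.append((sd, nd))
        if clean:
            clean_paths.append((sd, nd))
    paths = clean_paths or all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


_PAIR_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def ng86_pair_differences_cached(a: str, b: str) -> tuple[float, float]:
    key = (a, b) if a <= b else (b, a)
    hit = _PAIR_DIFF_CACHE.get(key)
    if hit is None:
        hit = ng86_codon_differences(key[0], key[1])
        _PAIR_DIFF_CACHE[key] = hit
    return hit
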