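"""Sliding-window diversity and NG86 dN/dS, checked against hand arithmetic
and an independent brute-force codon-enumeration oracle."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from Bio.Seq import Seq

from morffokit.divergence import (
    CodonAlignment,
    ng86_pair,
    remove_stop_codons,
    window_dnds,
    window_pi,
    window_starts,
)
from morffokit.seqsim import SimConfig, simulate_codon_alignment, simulate_trees, uniform_codon_freqs

# ---------------------------------------------------------------------------
# Independent oracle: Biopython translation + explicit enumeration
# ---------------------------------------------------------------------------

SENSE = [
    "".join(p)
    for p in product("ACGT", repeat=3)
    if str(Seq("".join(p)).translate()) != "*"
]


def oracle_sites(codon: str) -> tuple[float, float]:
    aa = str(Seq(codon).translate())
    s = n = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = str(Seq(alt).translate())
            if alt_aa == "*":
                continue
            s += (alt_aa == aa) / 3
            n += (alt_aa != aa) / 3
    return s, n


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if str(Seq(nxt).translate()) == "*":
                ok = False
            if str(Seq(cur).translate()) == str(Seq(nxt).translate()) and str(Seq(cur).translate()) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        (clean if ok else dirty).append((sd, nd))
    paths = clean or dirty
    return (sum(p[0] for p in paths) / len(paths), sum(p[1] for p in paths) / len(paths))


# ---------------------------------------------------------------------------
# remove_stop_codons
# ---------------------------------------------------------------------------

class TestRemoveStops:
    def test_no_stops_identity(self):
        aln = CodonAlignment(["a", "b"], ["ATGGGG", "ATGGGC"])
        out, removed = remove_stop_codons(aln)
        assert out.rows == aln.rows and removed == []

    def test_stop_column_removed_for_all(self):
        aln = CodonAlignment(["a", "b"], ["ATGTAAGGG", "ATGCAAGGG"])
        out, removed = remove_stop_codons(aln)
        assert removed == [1]
        assert out.rows == ["ATGGGG", "ATGGGG"]

    def test_all_stop_alignment_empties_with_warning(self):
        aln = CodonAlignment(["a", "b"], ["TAA", "TGA"])
        with pytest.warns(UserWarning):
            out, removed = remove_stop_codons(aln)
        assert out.length == 0 and removed == [0]


# ---------------------------------------------------------------------------
# window bookkeeping and pi
# ---------------------------------------------------------------------------

class TestWindows:
    def test_window_count_formula(self):
        assert len(window_starts(300, 90, 3)) == 71

    @pytest.mark.parametrize("L,w,s", [(90, 90, 3), (300, 90, 3), (120, 30, 6), (99, 9, 9)])
    def test_count_matches_floor_formula(self, L, w, s):
        assert len(window_starts(L, w, s)) == (L - w) // s + 1

    def test_window_larger_than_alignment_rejected(self):
        with pytest.raises(ValueError):
            window_starts(60, 90, 3)

    def test_nondivisible_step_rejected(self):
        with pytest.raises(ValueError):
            window_starts(300, 90, 2)

    def test_pi_hand_example(self):
        # A == B; C differs from both at exactly one third-position site
        base = "ATGGCTGCA" * 10  # 90 nt
        c = base[:8] + ("G" if base[8] != "G" else "T") + base[9:]
        aln = CodonAlignment(["A", "B", "C"], [base, base, c])
        [w] = window_pi(aln, window=90, step=90)
        assert w.pi1 == 0 and w.pi2 == 0
        assert w.pi3 == pytest.approx(2 / 90, abs=1e-12)

    def test_identical_alignment_all_zero(self):
        aln = CodonAlignment(["a", "b", "c"], ["ATGGCT" * 20] * 3)
        for w in window_pi(aln, 30, 3):
            assert w.pi1 == w.pi2 == w.pi3 == 0

    def test_pi_invariant_under_taxon_reorder_and_complement(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
        aln = CodonAlignment(list("abcd"), rows)
        comp = str.maketrans("ACGT", "TGCA")
        aln_r = CodonAlignment(list("dcba"), rows[::-1])
        aln_c = CodonAlignment(list("abcd"), [r.translate(comp) for r in rows])
        for other in (aln_r, aln_c):
            for w1, w2 in zip(window_pi(aln, 30, 3), window_pi(other, 30, 3)):
                assert (w1.pi1, w1.pi2, w1.pi3) == pytest.approx((w2.pi1, w2.pi2, w2.pi3))

    def test_gap_sites_excluded_from_numerator_and_denominator(self):
        aln = CodonAlignment(["a", "b"], ["ATG" + "GCT" * 9, "AT-" + "GCT" * 9])
        [w] = window_pi(aln, window=30, step=30)
        assert w.pi3 == 0  # the gapped third-position site simply drops out


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

class TestNg86:
    def test_identical_strings(self):
        c = ng86_pair("ATGGCT", "ATGGCT")
        assert c.Sd == c.Nd == 0 and c.dN == c.dS == 0
        assert math.isnan(c.dnds)

    def test_phe_phe_hand_example(self):
        c = ng86_pair("TTT", "TTC")
        assert c.S == pytest.approx(1 / 3, abs=1e-12)
        assert c.N == pytest.approx(8 / 3, abs=1e-12)
        assert (c.Sd, c.Nd) == (1.0, 0.0)
        assert c.pS == pytest.approx(3.0)
        assert c.flag == "out_of_domain"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng86_pair("ATG", "ATGGCT")

    def test_symmetry(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(SENSE, 10))
            b = "".join(rng.choice(SENSE, 10))
            ca, cb = ng86_pair(a, b), ng86_pair(b, a)
            assert (ca.S, ca.N, ca.Sd, ca.Nd) == pytest.approx((cb.S, cb.N, cb.Sd, cb.Nd), abs=1e-12)

    def test_oracle_equivalence_sites_and_differences(self, rng):
        """S, N, Sd, Nd must match brute-force enumeration to 1e-12."""
        for _ in range(200):
            codons_a = rng.choice(SENSE, 10)
            codons_b = rng.choice(SENSE, 10)
            a, b = "".join(codons_a), "".join(codons_b)
            c = ng86_pair(a, b)
            S = N = Sd = Nd = 0.0
            for ca, cb in zip(codons_a, codons_b):
                sa, na = oracle_sites(ca)
                sb, nb = oracle_sites(cb)
                S += (sa + sb) / 2
                N += (na + nb) / 2
                sd, nd = oracle_differences(ca, cb)
                Sd += sd
                Nd += nd
            assert (c.S, c.N, c.Sd, c.Nd) == pytest.approx((S, N, Sd, Nd), abs=1e-12)

    def test_site_count_conservation(self, rng):
        # S + N = 3 * codons minus the stop-change exclusions
        for _ in range(20):
            a = "".join(rng.choice(SENSE, 20))
            c = ng86_pair(a, a)
            assert c.S + c.N <= 3 * 20 + 1e-9
            assert c.S + c.N > 0


# ---------------------------------------------------------------------------
# windowed dN/dS
# ---------------------------------------------------------------------------

def _purifying_alignment(omega=0.2, n_taxa=10, codons=300, seed=11):
    cfg = SimConfig(seed=seed, n_taxa=n_taxa, omega=omega)
    _, phylo = simulate_trees(cfg)
    return simulate_codon_alignment(
        phylo, omega, cfg.kappa, uniform_codon_freqs(), 1.0, codons, seed=seed + 1
    )


class TestWindowDnds:
    def test_all_synonymous_alignment_gives_zero(self):
        # CTT <-> CTC (Leu) third-position differences only
        aln = CodonAlignment(["a", "b"], ["CTT" * 30, ("CTT" * 15) + ("CTC" * 15)])
        for w in window_dnds(aln, 90, 3, n_boot=0):
            assert w.dnds_mean == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_disabled_leaves_cis_undefined(self):
        aln = _purifying_alignment(codons=60)
        stats = window_dnds(aln, 90, 3, n_boot=0, seed=1)
        assert all(math.isnan(w.dnds_ci_low) for w in stats)
        means0 = [w.dnds_mean for w in stats]
        means1 = [w.dnds_mean for w in window_dnds(aln, 90, 3, n_boot=50, seed=1)]
        assert means0 == pytest.approx(means1, nan_ok=True)

    def test_bootstrap_ci_brackets_typical_windows(self):
        aln = _purifying_alignment(codons=90)
        stats = window_dnds(aln, 90, 9, n_boot=200, seed=3)
        defined = [w for w in stats if math.isfinite(w.dnds_ci_low)]
        assert defined
        inside = [w for w in defined if w.dnds_ci_low <= w.dnds_mean <= w.dnds_ci_high]
        assert len(inside) >= 0.9 * len(defined)

    def test_purifying_selection_detected(self):
        aln = _purifying_alignment(omega=0.2, codons=300)
        stats = window_dnds(aln, 90, 3, n_boot=0)
        vals = np.array([w.dnds_mean for w in stats if math.isfinite(w.dnds_mean)])
        assert (vals < 1).mean() >= 0.95

    @pytest.mark.parametrize("omega", [0.1, 0.2, 0.5])
    def test_genome_wide_omega_recovery(self, omega):
        aln = _purifying_alignment(omega=omega, codons=1000, seed=29)
        [w] = window_dnds(aln, aln.length, aln.length, n_boot=0)
        assert abs(w.dnds_mean - omega) < 0.15
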