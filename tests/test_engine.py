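import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triplexhub.engine import (EngineParams, count_triplexes,
                               enumerate_triplexes, pairing_valid)
from triplexhub.io import NucleicSequence, reverse_complement

from _oracle import exhaustive_windows, naive_windows, windows_as_dict
from conftest import dna, rna, random_dna, random_rna


class TestPairingRules:
    """The Hoogsteen degeneracy table, triple by triple."""

    @pytest.mark.parametrize("rb,db,orientation,motif,expected", [
        # A.A occurs in the antiparallel orientation only (GA motif)
        ("A", "A", "antiparallel", "GA", True),
        ("A", "A", "parallel", "GA", False),
        ("A", "A", "parallel", "TC", False),
        ("A", "A", "parallel", "GT", False),
        # DNA G binds RNA G in both orientations
        ("G", "G", "parallel", "GT", True),
        ("G", "G", "antiparallel", "GT", True),
        ("G", "G", "antiparallel", "GA", True),
        ("G", "G", "parallel", "TC", False),
        # DNA A binds RNA U in both orientations
        ("U", "A", "parallel", "TC", True),
        ("U", "A", "parallel", "GT", True),
        ("U", "A", "antiparallel", "GT", True),
        ("U", "A", "antiparallel", "GA", False),
        # DNA G binds RNA C parallel only
        ("C", "G", "parallel", "TC", True),
        ("C", "G", "antiparallel", "TC", False),
        # U.G is never a valid triple
        ("U", "G", "parallel", "TC", False),
        ("U", "G", "parallel", "GT", False),
        ("U", "G", "antiparallel", "GT", False),
        ("U", "G", "antiparallel", "GA", False),
    ])
    def test_rule_table(self, rb, db, orientation, motif, expected):
        assert pairing_valid(rb, db, orientation, motif) is expected


class TestWorkedExamples:
    def test_gaga_repeat_counts_three_windows(self):
        """A perfect 11-mer alignment at min length 10 yields the long
        window plus its two length-10 sub-windows."""
        ws = enumerate_triplexes(rna("GAGAGAGAGAG"), dna("GAGAGAGAGAG"))
        assert len(ws) == 3
        assert all(w.orientation == "antiparallel" and w.motifs == ("GA",)
                   and w.n_errors == 0 for w in ws)
        spans = {(w.rna_start, w.rna_end, w.dna_start, w.dna_end) for w in ws}
        assert spans == {(0, 11, 0, 11), (0, 10, 1, 11), (1, 11, 0, 10)}

    def test_pyrimidine_polyc_single_parallel_window(self):
        ws = enumerate_triplexes(rna("C" * 10), dna("G" * 10))
        assert len(ws) == 1
        (w,) = ws
        assert w.orientation == "parallel" and w.motifs == ("TC",)

    def test_polyu_polya_two_orientations_deduplicated(self):
        ws = enumerate_triplexes(rna("U" * 10), dna("A" * 10))
        assert len(ws) == 2
        by_orient = {w.orientation: w for w in ws}
        assert by_orient["parallel"].motifs == ("GT", "TC")
        assert by_orient["antiparallel"].motifs == ("GT",)

    def test_polyu_polyg_empty(self):
        assert count_triplexes(rna("U" * 10), dna("G" * 10)) == 0

    def test_below_min_length_counts_zero(self):
        assert count_triplexes(rna("C" * 9), dna("G" * 20)) == 0
        assert count_triplexes(rna("C" * 20), dna("G" * 9)) == 0

    def test_input_validation(self):
        with pytest.raises(TypeError):
            enumerate_triplexes(dna("ACGT" * 5), dna("ACGT" * 5))
        with pytest.raises(TypeError):
            enumerate_triplexes(rna("ACGU" * 5), rna("ACGU" * 5))


def _random_pair(rng, style):
    n = int(rng.integers(8, 26))
    p = int(rng.integers(8, 26))
    if style == 0:
        return random_rna(rng, n), random_dna(rng, p)
    if style == 1:  # triplex-prone compositions
        return random_rna(rng, n, "UUCG"), random_dna(rng, p, "AAGG")
    return random_rna(rng, n, "GAGAU"), random_dna(rng, p, "GAGAT")


_SETTINGS = [
    EngineParams(),
    EngineParams(require_terminal_match=False),
    EngineParams(min_length=6, max_error_rate=20.0),
    EngineParams(min_length=8, max_error_rate=0.0),
    EngineParams(motifs=("GT",), orientations=("parallel",)),
    EngineParams(scan_both_dna_strands=False),
]


class TestOracleEquivalence:
    def test_matches_naive_oracle(self, rng):
        """Exact equality with plain nested-loop enumeration."""
        for trial in range(120):
            r, d = _random_pair(rng, trial % 3)
            params = _SETTINGS[trial % len(_SETTINGS)]
            impl = windows_as_dict(enumerate_triplexes(rna(r), dna(d), params))
            assert impl == naive_windows(r, d, params), (r, d, params)

    def test_vectorised_oracle_agrees_with_naive(self, rng):
        """The fast exhaustive oracle is itself validated against the
        transparent one before it is trusted at scale."""
        for trial in range(60):
            r, d = _random_pair(rng, trial % 3)
            params = _SETTINGS[trial % len(_SETTINGS)]
            assert exhaustive_windows(r, d, params) == naive_windows(r, d, params)

    def test_masked_positions_are_unconditional_errors(self):
        params = EngineParams()
        seq = NucleicSequence("d", "G" * 5 + "X" + "G" * 5, "DNA")
        ws = enumerate_triplexes(rna("C" * 11), seq, params)
        # the mask forces >=1 error in every window covering it; the
        # length-11 window has exactly one (10% of 11 -> 1 allowed) but
        # fails nothing else; terminal positions are fine
        assert windows_as_dict(ws) == naive_windows("C" * 11, "GGGGGXGGGGG", params)


class TestInvariants:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.data())
    def test_strand_symmetry(self, data):
        r = data.draw(st.text("ACGU", min_size=10, max_size=30))
        d = data.draw(st.text("ACGT", min_size=10, max_size=30))
        assert count_triplexes(rna(r), dna(d)) == \
            count_triplexes(rna(r), dna(reverse_complement(d)))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.data())
    def test_appending_residues_never_decreases_count(self, data):
        r = data.draw(st.text("GAU", min_size=10, max_size=25))
        d = data.draw(st.text("GAT", min_size=10, max_size=25))
        extra_r = data.draw(st.text("ACGU", min_size=1, max_size=5))
        extra_d = data.draw(st.text("ACGT", min_size=1, max_size=5))
        base = count_triplexes(rna(r), dna(d))
        assert count_triplexes(rna(r + extra_r), dna(d)) >= base
        assert count_triplexes(rna(r), dna(d + extra_d)) >= base

    @pytest.mark.parametrize("k,m", [(10, 10), (10, 14), (13, 17), (20, 12)])
    def test_quadratic_blowup_matches_closed_form(self, k, m):
        """poly-U RNA vs poly-A DNA: every offset/length combination in
        both orientations qualifies, so the count has a closed form."""
        lmin = 10
        per_orientation = sum(
            (k - L + 1) * (m - L + 1) for L in range(lmin, min(k, m) + 1))
        expected = 2 * per_orientation  # parallel + antiparallel
        got = count_triplexes(rna("U" * k), dna("A" * m))
        assert got == expected
        assert len(naive_windows("U" * k, "A" * m, EngineParams())) == expected

    def test_determinism_and_sorted_output(self, rng):
        r, d = random_rna(rng, 40, "GAU"), random_dna(rng, 40, "GAT")
        ws1 = enumerate_triplexes(rna(r), dna(d))
        ws2 = enumerate_triplexes(rna(r), dna(d))
        assert ws1 == ws2 == sorted(ws1)


class TestOptionalFilters:
    def test_max_consecutive_errors_prunes(self):
        # two adjacent mismatches inside an otherwise perfect window
        r = "C" * 9 + "AA" + "C" * 9   # len 20, errors at 9,10 vs poly-G
        base = EngineParams(require_terminal_match=False)
        strict = EngineParams(require_terminal_match=False,
                              max_consecutive_errors=1)
        n_base = count_triplexes(rna(r), dna("G" * 20), base)
        n_strict = count_triplexes(rna(r), dna("G" * 20), strict)
        assert n_strict < n_base
        # windows within one poly-C arm are unaffected
        assert n_strict >= 2

    def test_min_guanine_rate_prunes(self):
        params = EngineParams(min_guanine_rate=50.0)
        assert count_triplexes(rna("U" * 12), dna("A" * 12), params) == 0
        assert count_triplexes(rna("G" * 12), dna("G" * 12),
                               EngineParams(min_guanine_rate=50.0)) > 0


def test_engine_params_validation():
    with pytest.raises(ValueError):
        EngineParams(min_length=1)
    with pytest.raises(ValueError):
        EngineParams(max_error_rate=100)
    with pytest.raises(ValueError):
        EngineParams(motifs=())
    with pytest.raises(ValueError):
        EngineParams(motifs=("XX",))
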