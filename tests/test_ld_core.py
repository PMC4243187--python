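"""Two-locus LD statistics: counting, D / D' / r^2 / signed r, EM, D' CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldphase.ld_core import (
    MonomorphicPairError,
    dprime_ci,
    em_haplotype_freqs,
    genotype_loglik,
    haplotype_counts,
    pair_ld,
    pair_stats_table,
)
from ldphase.panel import HaplotypePanel, Marker, PanelError


def ld_oracle(n11, n10, n01, n00):
    """Independent transcription of the D, D' and r^2 definitions."""
    n = n11 + n10 + n01 + n00
    p_ij = n11 / n
    p_i = (n11 + n10) / n
    p_j = (n11 + n01) / n
    D = p_ij - p_i * p_j
    r2 = (p_ij - p_i * p_j) ** 2 / (p_i * (1 - p_i) * p_j * (1 - p_j))
    if D > 0:
        dmax = min(p_i * (1 - p_j), (1 - p_i) * p_j)
        dprime = D / dmax
    elif D < 0:
        dmax = min(p_i * p_j, (1 - p_i) * (1 - p_j))
        dprime = -D / dmax
    else:
        dprime = 0.0
    return D, r2, dprime


def make_phased_panel(columns):
    codes = np.asarray(columns, dtype=np.int8).T
    n = codes.shape[0] // 2
    markers = [Marker(f"m{j}", "1", 1000 * (j + 1), "A", "G") for j in range(codes.shape[1])]
    return HaplotypePanel(markers, codes, [f"s{k}" for k in range(n)], ["CA"] * n)


# -------------------------------------------------------------------- counting
def test_haplotype_counts_basic():
    panel = make_phased_panel([[1, 1, 0, 0], [1, 1, 0, 0]])
    assert haplotype_counts(panel, 0, 1) == (2, 0, 0, 2)


def test_haplotype_counts_excludes_missing_rows():
    panel = make_phased_panel([[1, 1, 0, 0], [1, -1, 0, 0]])
    # row 1 is missing at marker 1 and leaves all four cells
    assert haplotype_counts(panel, 0, 1) == (1, 0, 0, 2)


def test_haplotype_counts_monomorphic_marker():
    panel = make_phased_panel([[0, 0, 0, 0], [1, 0, 1, 0]])
    n11, n10, n01, n00 = haplotype_counts(panel, 0, 1)
    assert n11 == 0 and n10 == 0


def test_haplotype_counts_requires_phase():
    panel = make_phased_panel([[1, 1, 0, 0], [1, 1, 0, 0]])
    panel.phased = False
    with pytest.raises(PanelError):
        haplotype_counts(panel, 0, 1)


# ------------------------------------------------------------------ statistics
@pytest.mark.parametrize(
    "counts, r2, dprime, signed_r",
    [
        ((50, 0, 0, 50), 1.0, 1.0, 1.0),     # perfect coupling
        ((25, 25, 25, 25), 0.0, 0.0, 0.0),   # independence
        ((4, 1, 1, 4), 0.36, 0.6, 0.6),      # hand-evaluated
        ((0, 30, 30, 0), 1.0, 1.0, -1.0),    # perfect repulsion
    ],
)
def test_pair_ld_known_values(counts, r2, dprime, signed_r):
    pair = pair_ld(counts)
    assert pair.r2 == pytest.approx(r2, abs=1e-12)
    assert pair.dprime == pytest.approx(dprime, abs=1e-12)
    assert pair.signed_r == pytest.approx(signed_r, abs=1e-12)


def test_pair_ld_monomorphic_raises():
    with pytest.raises(MonomorphicPairError):
        pair_ld((5, 0, 5, 0))


@settings(max_examples=300, derandomize=True)
@given(
    st.tuples(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    )
)
def test_pair_ld_invariants(counts):
    n11, n10, n01, n00 = counts
    n = sum(counts)
    if n == 0 or n11 + n10 in (0, n) or n11 + n01 in (0, n):
        return  # monomorphic: undefined by construction
    pair = pair_ld(counts)
    D, r2, dprime = ld_oracle(*counts)
    assert pair.r2 == pytest.approx(r2, abs=1e-12)
    assert pair.dprime == pytest.approx(dprime, abs=1e-12)
    assert 0 <= pair.r2 <= 1 + 1e-12
    assert 0 <= pair.dprime <= 1 + 1e-12
    assert pair.r2 <= pair.dprime + 1e-12
    assert pair.signed_r**2 == pytest.approx(pair.r2, abs=1e-12)
    assert np.sign(pair.signed_r) == np.sign(pair.D)


def test_pair_stats_table_matches_scalar_path(rng):
    cols = rng.integers(0, 2, size=(20, 6))
    panel = make_phased_panel(cols.T)
    i_idx = np.array([0, 0, 1, 2])
    j_idx = np.array([1, 2, 3, 5])
    stats = pair_stats_table(panel, (i_idx, j_idx))
    for k, (i, j) in enumerate(zip(i_idx, j_idx)):
        counts = haplotype_counts(panel, int(i), int(j))
        if not stats["defined"][k]:
            with pytest.raises(MonomorphicPairError):
                pair_ld(counts)
            continue
        pair = pair_ld(counts)
        assert stats["r2"][k] == pytest.approx(pair.r2, abs=1e-12)
        assert stats["dprime"][k] == pytest.approx(pair.dprime, abs=1e-12)
        assert stats["signed_r"][k] == pytest.approx(pair.signed_r, abs=1e-12)


# ------------------------------------------------------------------------- EM
def test_em_unambiguous_table_is_exact():
    # no double heterozygotes: haplotypes are fully determined
    table = np.array([[3, 2, 0], [1, 0, 0], [0, 2, 4]])
    freqs, _ = em_haplotype_freqs(table)
    n11 = 2 * 4 + 2 + 0   # hom-hom, (2,1) het, (1,2) het
    n10 = 2 * 0 + 2 + 1
    n01 = 2 * 0 + 2 + 0
    n00 = 2 * 3 + 2 + 1
    expect = np.array([n11, n10, n01, n00]) / (2 * table.sum())
    assert freqs == pytest.approx(expect, abs=1e-12)


def test_em_all_double_heterozygotes():
    table = np.zeros((3, 3)); table[1, 1] = 10
    # the symmetric start stays at the symmetric stationary point
    freqs, _ = em_haplotype_freqs(table, starts=(0.5,))
    assert freqs == pytest.approx([0.25] * 4, abs=1e-9)
    # the default multi-start finds a likelier boundary resolution
    freqs, ll = em_haplotype_freqs(table)
    assert ll >= 10 * np.log(0.5) - 1e-9


def test_em_recovers_phased_frequencies_without_ambiguity(rng):
    """Collapsing phased haplotypes to genotypes and running EM reproduces the
    phased haplotype frequencies exactly when no double heterozygote exists."""
    hap_pairs = [(1, 1), (0, 0), (1, 0)]  # no (0,1): coupling-only population
    draws = [hap_pairs[i] for i in rng.integers(0, 3, size=40)]
    table = np.zeros((3, 3))
    phased_counts = np.zeros(4)
    for (a1, b1), (a2, b2) in zip(draws[0::2], draws[1::2]):
        table[a1 + a2, b1 + b2] += 1
        for a, b in ((a1, b1), (a2, b2)):
            phased_counts[{(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(a, b)]] += 1
    if table[1, 1] == 0:
        freqs, _ = em_haplotype_freqs(table)
        assert freqs == pytest.approx(phased_counts / phased_counts.sum(), abs=1e-9)


def grid_search_loglik(table, n_grid=1001, refinements=3):
    """1-D grid-search oracle over the free coupling-haplotype frequency."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    p_a = (2 * t[2].sum() + t[1].sum()) / (2 * n)
    p_b = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    best = -np.inf
    for _ in range(refinements):
        grid = np.linspace(lo, hi, n_grid)
        lls = [
            genotype_loglik(t, (p11, p_a - p11, p_b - p11, 1 - p_a - p_b + p11))
            for p11 in grid
        ]
        k = int(np.argmax(lls))
        best = max(best, lls[k])
        span = (hi - lo) / (n_grid - 1)
        lo, hi = max(lo, grid[k] - span), min(hi, grid[k] + span)
    return best


def test_em_loglik_matches_grid_oracle(rng):
    for _ in range(60):
        table = rng.multinomial(int(rng.integers(4, 31)), np.full(9, 1 / 9)).reshape(3, 3)
        _, ll_em = em_haplotype_freqs(table)
        ll_grid = grid_search_loglik(table)
        assert ll_em == pytest.approx(ll_grid, abs=1e-6)


def test_em_empty_table_errors():
    with pytest.raises(ValueError):
        em_haplotype_freqs(np.zeros((3, 3)))


# ----------------------------------------------------------------- D' interval
def test_dprime_ci_strong_pair():
    lo, hi = dprime_ci((100, 0, 0, 100))
    assert lo >= 0.70 and hi >= 0.98


def test_dprime_ci_independent_pair():
    lo, hi = dprime_ci((25, 25, 25, 25))
    assert hi < 0.90
    assert lo <= 0.1


def test_dprime_ci_small_sample_uninformative():
    lo, hi = dprime_ci((4, 1, 1, 4))
    assert lo < 0.70


def test_dprime_ci_bounds_ordered_and_widen_with_small_n():
    widths = []
    for scale in (40, 10, 1):
        counts = tuple(scale * c for c in (4, 1, 1, 4))
        lo, hi = dprime_ci(counts)
        assert 0 <= lo <= hi <= 1
        widths.append(hi - lo)
    assert widths[0] <= widths[1] <= widths[2]


def test_dprime_ci_monomorphic_raises():
    with pytest.raises(MonomorphicPairError):
        dprime_ci((10, 0, 10, 0))
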