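"""Simulator contracts: determinism, limits, population-genetic sanity."""

from dataclasses import replace

import numpy as np
import pytest

from ldphase.decay_profile import DistanceBinScheme, build_profile, pairs_within
from ldphase.ld_core import pair_stats_table
from ldphase.panel import merge_groups
from ldphase.phase_persistence import persistence_profile, shared_pairs
from ldphase.pipeline import group_pair_table
from ldphase.qc import QCThresholds, apply_qc, hwe_pvalues
from ldphase.synthetic_data import (
    SimConfig,
    simulate_equilibrium,
    simulate_founders,
    simulate_two_groups,
)

QUICK = SimConfig(
    seed=21,
    n_markers=160,
    n_chromosomes=1,
    chromosome_length=500_000,
    n_samples_per_group=(40, 40),
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(admixture_props=(0.7, 0.4))
    with pytest.raises(ValueError):
        SimConfig(n_markers=0)
    with pytest.raises(ValueError):
        SimConfig(recomb_rate=-1e-8)


def test_same_seed_bit_identical_panels():
    pa1, pb1 = simulate_two_groups(QUICK)
    pa2, pb2 = simulate_two_groups(QUICK)
    for x, y in zip(pa1 + pb1, pa2 + pb2):
        assert np.array_equal(x.haplotypes, y.haplotypes)
        assert [m.position for m in x.markers] == [m.position for m in y.markers]
        assert [(m.allele_ref, m.allele_alt) for m in x.markers] == [
            (m.allele_ref, m.allele_alt) for m in y.markers
        ]
    pa3, _ = simulate_two_groups(replace(QUICK, seed=22))
    assert not np.array_equal(pa1[0].haplotypes, pa3[0].haplotypes)


def test_zero_recombination_copies_founder_haplotypes():
    """Without recombination every sampled chromosome is an exact copy of a
    founder haplotype, and surviving haplotype classes stay few."""
    from ldphase.synthetic_data import FixationError, admix_and_split

    cfg = replace(QUICK, recomb_rate=0.0, n_markers=60)
    rng = np.random.default_rng(cfg.seed)
    panel_a = None
    for _ in range(10):  # without recombination whole-panel fixation is common
        try:
            founder_a, founder_b = simulate_founders(cfg, rng)
            panel_a, panel_b = admix_and_split(founder_a, founder_b, cfg, rng)
            break
        except FixationError:
            continue
    assert panel_a is not None
    pos_to_col = {m.position: k for k, m in enumerate(founder_a.markers)}
    cols = [pos_to_col[m.position] for m in panel_a.markers]
    founder_rows = {
        tuple(row)
        for H in (founder_a.haplotypes[:, cols], founder_b.haplotypes[:, cols])
        for row in H
    }
    sampled_rows = {
        tuple(row) for P in (panel_a, panel_b) for row in P.haplotypes
    }
    assert sampled_rows <= founder_rows
    assert len(sampled_rows) <= 10  # drift keeps only a handful of lineages
    # with at most three surviving classes, at most three gametes exist per
    # pair, which forces |D'| = 1 for every defined pair
    if len(sampled_rows) <= 3:
        merged = merge_groups(panel_a, panel_b)
        ii, jj = pairs_within(merged.positions, 500_000)
        stats = pair_stats_table(merged, (ii, jj))
        ok = stats["defined"]
        assert np.allclose(stats["dprime"][ok], 1.0, atol=1e-9)


def hudson_fst(panel_a, panel_b):
    pa = panel_a.haplotypes.mean(axis=0)
    pb = panel_b.haplotypes.mean(axis=0)
    na = panel_a.haplotypes.shape[0]
    nb = panel_b.haplotypes.shape[0]
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


def test_founder_divergence_controls_fst():
    base = replace(QUICK, n_markers=200, founder_divergence_gens=0)
    fa0, fb0 = simulate_founders(base, np.random.default_rng(33))
    assert abs(hudson_fst(fa0, fb0)) < 0.05  # exchangeable draws
    div = replace(base, founder_divergence_gens=100)
    fa1, fb1 = simulate_founders(div, np.random.default_rng(33))
    assert hudson_fst(fa1, fb1) > 0.15


def test_group_split_zero_gives_pl_near_one():
    cfg = replace(QUICK, group_split_gens=0, n_markers=200)
    pas, pbs = simulate_two_groups(cfg)
    thr = QCThresholds()
    scheme = DistanceBinScheme()
    panels = [merge_groups(a, b) for a, b in zip(pas, pbs)]
    ta, _, _ = group_pair_table(panels, "CA", thr, scheme.cap_bp)
    tb, _, _ = group_pair_table(panels, "MA", thr, scheme.cap_bp)
    profile = persistence_profile(shared_pairs(ta, tb), scheme)
    defined = profile.table["pl"].dropna()
    # the two groups are still independent finite samples of one population,
    # so weak-LD bins carry sampling noise; near-one, not exactly one
    assert (defined > 0.8).all()
    assert profile.overall_pairweighted_pl > 0.95


def test_pl_decreases_with_group_split_time():
    """More generations of independent drift lower the cross-group phase
    agreement (majority vote over seeds at fixed configuration)."""
    thr = QCThresholds()
    scheme = DistanceBinScheme()
    wins = 0
    for seed in (1, 2, 3):
        overall = []
        for split in (0, 40):
            cfg = replace(QUICK, seed=seed, group_split_gens=split, n_markers=200)
            pas, pbs = simulate_two_groups(cfg)
            panels = [merge_groups(a, b) for a, b in zip(pas, pbs)]
            ta, _, _ = group_pair_table(panels, "CA", thr, scheme.cap_bp)
            tb, _, _ = group_pair_table(panels, "MA", thr, scheme.cap_bp)
            profile = persistence_profile(shared_pairs(ta, tb), scheme)
            overall.append(profile.overall_pairweighted_pl)
        if overall[0] > overall[1]:
            wins += 1
    assert wins >= 2


def test_higher_recombination_lowers_mid_range_ld():
    """A 10x recombination rate strictly lowers mid-distance mean r^2 at the
    same seed (paired comparison)."""
    mids = []
    for rate in (1e-7, 1e-6):
        panel = simulate_equilibrium(
            replace(QUICK, seed=5, n_markers=300, chromosome_length=1_000_000, recomb_rate=rate)
        )
        qp, _ = apply_qc(panel)
        ii, jj = pairs_within(qp.positions, 500_000)
        stats = pair_stats_table(qp, (ii, jj))
        ok = stats["defined"] & (stats["distance"] >= 10_000) & (stats["distance"] < 50_000)
        mids.append(float(stats["r2"][ok].mean()))
    assert mids[1] < mids[0]


def test_equilibrium_genotypes_near_hardy_weinberg():
    """Random-mating output: the exact-test rejection fraction at alpha is not
    inflated beyond sampling noise (markers are LD-correlated, so only an
    upper bound is asserted)."""
    panel = simulate_equilibrium(replace(QUICK, seed=9, n_markers=300, chromosome_length=1_000_000))
    qp, _ = apply_qc(panel)
    pvals = hwe_pvalues(qp)
    alpha = 0.05
    rate = float((pvals < alpha).mean())
    assert rate < alpha + 3 * np.sqrt(alpha * (1 - alpha) / len(pvals)) + 0.05


def test_heterozygosity_drops_with_split_time():
    hets = []
    for split in (0, 60):
        cfg = replace(QUICK, seed=13, group_split_gens=split, n_markers=200)
        pas, _ = simulate_two_groups(cfg)
        p = pas[0].haplotypes.mean(axis=0)
        hets.append(float((2 * p * (1 - p)).mean()))
    assert hets[1] < hets[0]


def test_admixture_proportions_reflected_in_ancestry():
    """At markers where the founders are fixed for opposite alleles, the
    composite allele frequency estimates the admixture proportion."""
    from ldphase.synthetic_data import admix_and_split

    cfg = replace(
        QUICK,
        n_markers=80,
        founder_divergence_gens=600,
        post_admixture_gens=0,
        group_split_gens=0,
    )
    # ancestry is near all-or-nothing per gamete at this map length, so one
    # realisation has a ~0.04 standard error; average over seeds instead
    from ldphase.synthetic_data import FixationError

    means = []
    for seed in (17, 18, 19, 20, 21, 22):
        if len(means) == 3:
            break
        rng = np.random.default_rng(seed)
        try:
            founder_a, founder_b = simulate_founders(cfg, rng)
            panel_a, panel_b = admix_and_split(founder_a, founder_b, cfg, rng)
        except FixationError:  # long divergence can fix everything
            continue
        fa = dict(zip((m.position for m in founder_a.markers), founder_a.haplotypes.mean(axis=0)))
        fb = dict(zip((m.position for m in founder_b.markers), founder_b.haplotypes.mean(axis=0)))
        merged = merge_groups(panel_a, panel_b)
        p = merged.haplotypes.mean(axis=0)
        diagnostic = [
            k
            for k, m in enumerate(merged.markers)
            if abs(fa[m.position] - fb[m.position]) == 1.0
        ]
        assert len(diagnostic) >= 10
        # alt frequency at an A-fixed/B-fixed marker is the B-ancestry fraction
        ancestry = np.array(
            [p[k] if fb[merged.markers[k].position] == 1.0 else 1 - p[k] for k in diagnostic]
        )
        means.append(float(ancestry.mean()))
    assert abs(np.mean(means) - 0.375) < 0.08
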