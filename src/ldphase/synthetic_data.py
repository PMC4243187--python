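"""Forward Wright-Fisher simulator for two-group admixed haplotype panels.

The generator emulates the demographic structure the analysis assumes: an
ancestral population at drift-recombination equilibrium splits into two
diverged founder pools (the taurine and zebu sides of a composite beef
breed); a composite population is then formed by sampling founder gametes in
5/8 : 3/8 proportions, bred inter se for a few generations, and finally
split into two genetic groups that drift independently before diploid
samples are drawn from each.

Mechanics: discrete non-overlapping generations of N monoecious diploids;
each offspring draws two parents uniformly with replacement and receives one
recombinant gamete from each.  Recombination follows the Markov (Haldane)
model — between adjacent markers the gamete switches parental haplotype with
probability (1 - exp(-2 c g)) / 2 for inter-marker gap g, optionally scaled
by hotspot multipliers.  Variation is standing founder polymorphism only
(no recurrent mutation): the ancestral population starts from random alleles
in linkage equilibrium and the burn-in (4 Ne generations) lets drift build
the equilibrium LD structure.  Markers fixed in the composite are dropped
and the map is down-sampled to ``n_markers``, emulating a genotyping array's
common-SNP ascertainment bias.

All randomness flows from ``SimConfig.seed``: one seed, one byte-identical
panel pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import HaplotypePanel, Marker

_ALLELES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the desk-scale study conditions.

    2,000 markers on a 5 Mb chromosome, founder effective size 100, founder
    divergence 100 generations (strongly diverged pools), admixture 5/8:3/8,
    15 generations of composite breeding, 5 generations of independent
    drift between the two output groups, 100 diploids sampled per group.
    ``recomb_rate`` (per bp per generation) defaults to 1e-7 so that the
    desk-scale product Ne x c matches a cattle-scale population at the
    field's 1e-8 genetic map — the quantity LD decay actually depends on.
    """

    seed: int = 0
    n_markers: int = 2000          # total across chromosomes
    n_chromosomes: int = 4
    chromosome_length: int = 1_250_000  # per chromosome
    Ne_founder: int = 100
    founder_divergence_gens: int = 100
    admixture_props: tuple = (0.625, 0.375)
    post_admixture_gens: int = 15
    group_split_gens: int = 5
    n_samples_per_group: tuple = (100, 100)
    recomb_rate: float = 1e-7
    hotspots: tuple = ()  # ((position, multiplier), ...)
    chromosome: str = "1"
    group_names: tuple = ("CA", "MA")
    burn_in_factor: int = 4
    marker_oversample: float = 30.0

    def __post_init__(self):
        if abs(sum(self.admixture_props) - 1.0) > 1e-9:
            raise ValueError("admixture proportions must sum to 1")
        for name in ("n_markers", "chromosome_length", "Ne_founder"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.n_samples_per_group):
            raise ValueError("n_samples_per_group entries must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")


class FixationError(RuntimeError):
    """Every marker drifted to fixation; increase Ne or shorten divergence."""


# ------------------------------------------------------------------ primitives
def _interval_switch_probs(positions: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-interval haplotype-switch probability (Haldane), with hotspots."""
    gaps = np.diff(positions).astype(float)
    rate = np.full(gaps.shape, config.recomb_rate)
    for pos, mult in config.hotspots:
        k = np.searchsorted(positions, pos, side="right") - 1
        if 0 <= k < len(gaps):
            rate[k] *= mult
    return 0.5 * (1.0 - np.exp(-2.0 * rate * gaps))


def _meiosis(H: np.ndarray, parent_idx: np.ndarray, switch: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per entry of *parent_idx* from diploid rows of *H*.

    Crossovers are drawn as Poisson events with per-interval intensity
    lambda_k = -ln(1 - 2 s_k) / 2 (the inverse Haldane map of the switch
    probability s_k), whose parity per interval reproduces the Markov switch
    model exactly in distribution while costing only O(events) randomness.
    """
    G = len(parent_idx)
    M = H.shape[1]
    h0 = H[2 * parent_idx]
    h1 = H[2 * parent_idx + 1]
    start = rng.integers(0, 2, size=(G, 1), dtype=np.uint8)
    lam = -0.5 * np.log1p(-2.0 * np.clip(switch, 0.0, 0.5 - 1e-12)) if M > 1 else np.zeros(0)
    lam_total = float(lam.sum())
    if M > 1 and lam_total > 0:
        n_events = rng.poisson(lam_total, size=G)
        total = int(n_events.sum())
        parity = np.zeros((G, M - 1), dtype=np.uint8)
        if total:
            intervals = rng.choice(M - 1, size=total, p=lam / lam_total)
            gametes = np.repeat(np.arange(G), n_events)
            np.add.at(parity, (gametes, intervals), 1)
        parity = np.cumsum(parity, axis=1, dtype=np.uint8)  # uint8 wrap keeps parity
        which = (start + np.concatenate(
            [np.zeros((G, 1), dtype=np.uint8), parity], axis=1
        )) % 2
    else:
        which = np.broadcast_to(start, (G, M))
    return np.where(which == 1, h1, h0).astype(np.int8)


def _next_generation(H: np.ndarray, n_offspring: int, switch: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Random-mating Wright-Fisher step; returns (2 * n_offspring, M) haplotypes."""
    n_parents = H.shape[0] // 2
    parent_idx = rng.integers(0, n_parents, size=2 * n_offspring)
    gametes = _meiosis(H, parent_idx, switch, rng)
    # rows 2k, 2k+1 are offspring k's maternal/paternal gametes
    return gametes


def _drift(H: np.ndarray, gens: int, switch: np.ndarray,
           rng: np.random.Generator, pop_size: int) -> np.ndarray:
    for _ in range(gens):
        H = _next_generation(H, pop_size, switch, rng)
    return H


def _make_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(round(config.n_markers * config.marker_oversample))
    pos = np.array([], dtype=np.int64)
    while len(pos) < n:
        draw = rng.integers(1, config.chromosome_length + 1, size=2 * n)
        pos = np.unique(np.concatenate([pos, draw]))
    return np.sort(rng.choice(pos, size=n, replace=False))


# ------------------------------------------------------------------- pipeline
def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None):
    """Burn an ancestral population to approximate equilibrium, split it, and
    drift the two copies apart for ``founder_divergence_gens``.

    Returns ``(panel_a, panel_b)`` on a shared marker map; markers fixed for
    the same allele in both founder pools are dropped (they can never be
    polymorphic downstream).  Raises :class:`FixationError` if nothing
    polymorphic survives.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    positions = _make_positions(config, rng)
    switch = _interval_switch_probs(positions, config)
    K = config.Ne_founder
    H = rng.integers(0, 2, size=(2 * K, len(positions)), dtype=np.int64).astype(np.int8)
    H = _drift(H, config.burn_in_factor * K, switch, rng, K)
    # markers already fixed in the ancestral population can never become
    # polymorphic again (no recurrent mutation): drop them here, which leaves
    # every downstream distribution untouched and saves the divergence work
    freq = H.mean(axis=0)
    alive = np.flatnonzero((freq > 0) & (freq < 1))
    if not len(alive):
        raise FixationError(
            "all markers fixed during burn-in; increase Ne_founder or marker_oversample"
        )
    H = H[:, alive]
    positions = positions[alive]
    switch = _interval_switch_probs(positions, config)
    Ha = _drift(H, config.founder_divergence_gens, switch, rng, K)
    Hb = _drift(H, config.founder_divergence_gens, switch, rng, K)
    fa = Ha.mean(axis=0)
    fb = Hb.mean(axis=0)
    informative = ~(((fa == 0) & (fb == 0)) | ((fa == 1) & (fb == 1)))
    if not informative.any():
        raise FixationError(
            "all markers fixed identically in both founders; "
            "increase Ne_founder or shorten founder_divergence_gens"
        )
    keep = np.flatnonzero(informative)
    markers = _draw_markers(positions[keep], config, rng)
    panel_a = _as_panel(Ha[:, keep], markers, "FOUNDER_A", config)
    panel_b = _as_panel(Hb[:, keep], markers, "FOUNDER_B", config)
    return panel_a, panel_b


def admix_and_split(founder_a: HaplotypePanel, founder_b: HaplotypePanel,
                    config: SimConfig, rng: np.random.Generator | None = None):
    """Form the composite from founder gametes (admixture proportions), breed
    it inter se, split into two groups, drift, and sample diploids.

    Markers fixed in the composite are dropped and the map is down-sampled to
    ``n_markers`` (array-style ascertainment); both output panels share the
    resulting map and are phased.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if [m.position for m in founder_a.markers] != [m.position for m in founder_b.markers]:
        raise ValueError("founder panels must share the marker map")
    positions = founder_a.positions
    switch = _interval_switch_probs(positions, config)
    K = config.Ne_founder

    # generation 0 of the composite: each gamete comes from founder pool A
    # with probability admixture_props[0], else pool B
    from_a = rng.random(2 * K) < config.admixture_props[0]
    gam_a = _meiosis(
        founder_a.haplotypes, rng.integers(0, founder_a.n_samples, size=int(from_a.sum())),
        switch, rng,
    )
    gam_b = _meiosis(
        founder_b.haplotypes, rng.integers(0, founder_b.n_samples, size=int((~from_a).sum())),
        switch, rng,
    )
    H = np.empty((2 * K, len(positions)), dtype=np.int8)
    H[from_a] = gam_a
    H[~from_a] = gam_b

    H = _drift(H, config.post_admixture_gens, switch, rng, K)

    # array-style ascertainment on the composite: markers fixed in the
    # composite are dropped; the panel is drawn uniformly from the common
    # (MAF >= 0.05) survivors, topped up from the most-common remainder only
    # when those run short — emulating a chip's common-SNP discovery bias
    freq = H.mean(axis=0)
    folded = np.minimum(freq, 1 - freq)
    poly = np.flatnonzero(folded > 0)
    if len(poly) < config.n_markers:
        raise FixationError(
            f"only {len(poly)} markers polymorphic in the composite; need "
            f"{config.n_markers} — increase marker_oversample or Ne_founder"
        )
    common = np.flatnonzero(folded >= 0.05)
    if len(common) >= config.n_markers:
        chosen = rng.choice(common, size=config.n_markers, replace=False)
    else:
        rare = np.setdiff1d(poly, common)
        top_up = rare[np.lexsort((rare, -folded[rare]))][: config.n_markers - len(common)]
        chosen = np.concatenate([common, top_up])
    chosen = np.sort(chosen)
    H = H[:, chosen]
    markers = [founder_a.markers[k] for k in chosen]
    switch_sub = _interval_switch_probs(np.asarray([m.position for m in markers]), config)

    panels = []
    for g, (group, n_samples) in enumerate(zip(config.group_names, config.n_samples_per_group)):
        Hg = _drift(H.copy(), config.group_split_gens, switch_sub, rng, K)
        Hg = _next_generation(Hg, n_samples, switch_sub, rng)  # sampling draw
        panels.append(
            HaplotypePanel(
                markers=list(markers),
                haplotypes=Hg,
                sample_ids=[f"{group}_{k + 1:04d}" for k in range(n_samples)],
                group_labels=[group] * n_samples,
                phased=True,
            )
        )
    return panels[0], panels[1]


def simulate_two_groups(config: SimConfig):
    """End-to-end run: founders -> admixture -> group split, independently per
    chromosome; returns ``(panels_a, panels_b)`` lists of per-chromosome
    panels.  Seed-deterministic: one seed, one byte-identical genome.
    """
    rng = np.random.default_rng(config.seed)
    per_chrom = [config.n_markers // config.n_chromosomes] * config.n_chromosomes
    for k in range(config.n_markers % config.n_chromosomes):
        per_chrom[k] += 1
    panels_a, panels_b = [], []
    for c, n_markers in enumerate(per_chrom, start=1):
        sub = replace(config, n_markers=n_markers, chromosome=str(c))
        # drift can wipe out a whole short chromosome's diversity; resample
        # the chromosome with a doubled discovery panel until enough markers
        # survive ascertainment (deterministic: the rng stream is sequential)
        for attempt in range(4):
            try:
                founder_a, founder_b = simulate_founders(sub, rng)
                pa, pb = admix_and_split(founder_a, founder_b, sub, rng)
                break
            except FixationError:
                if attempt == 3:
                    raise
                sub = replace(sub, marker_oversample=sub.marker_oversample * 2)
        panels_a.append(pa)
        panels_b.append(pb)
    return panels_a, panels_b


def simulate_equilibrium(config: SimConfig) -> HaplotypePanel:
    """Single population at drift-recombination equilibrium (burn-in only),
    with known Ne and recombination map; used for calibration checks."""
    rng = np.random.default_rng(config.seed)
    positions = _make_positions(config, rng)
    switch = _interval_switch_probs(positions, config)
    K = config.Ne_founder
    H = rng.integers(0, 2, size=(2 * K, len(positions)), dtype=np.int64).astype(np.int8)
    H = _drift(H, config.burn_in_factor * K, switch, rng, K)
    freq = H.mean(axis=0)
    poly = np.flatnonzero((freq > 0) & (freq < 1))
    if len(poly) < min(config.n_markers, 2):
        raise FixationError("population fixed during burn-in; increase Ne_founder")
    chosen = poly if len(poly) <= config.n_markers else np.sort(
        rng.choice(poly, size=config.n_markers, replace=False)
    )
    markers = _draw_markers(positions[chosen], config, rng)
    n = config.n_samples_per_group[0]
    switch_sub = _interval_switch_probs(positions[chosen], config)
    Hs = _next_generation(H[:, chosen], n, switch_sub, rng)
    return HaplotypePanel(
        markers=markers,
        haplotypes=Hs,
        sample_ids=[f"EQ_{k + 1:04d}" for k in range(n)],
        group_labels=["EQ"] * n,
        phased=True,
    )


# -------------------------------------------------------------------- fixture
def write_fixture(panels_a, panels_b, out_dir):
    """Write the two groups' per-chromosome panels as one phased VCF plus a
    group-map TSV.

    Accepts single panels or per-chromosome lists.  Returns ``(vcf_path,
    group_map_path)``; the files round-trip exactly through
    :func:`ldphase.io_formats.read_vcf`.
    """
    from pathlib import Path

    from .io_formats import write_group_map, write_vcf
    from .panel import merge_groups

    if isinstance(panels_a, HaplotypePanel):
        panels_a = [panels_a]
    if isinstance(panels_b, HaplotypePanel):
        panels_b = [panels_b]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    merged = [merge_groups(pa, pb) for pa, pb in zip(panels_a, panels_b)]
    vcf_path = out_dir / "panel.vcf"
    map_path = out_dir / "groups.tsv"
    write_vcf(merged, vcf_path)
    write_group_map(dict(zip(merged[0].sample_ids, merged[0].group_labels)), map_path)
    return vcf_path, map_path


# -------------------------------------------------------------------- helpers
def _draw_markers(positions: np.ndarray, config: SimConfig,
                  rng: np.random.Generator) -> list[Marker]:
    ref_idx = rng.integers(0, 4, size=len(positions))
    alt_off = rng.integers(1, 4, size=len(positions))
    markers = []
    for k, pos in enumerate(positions):
        ref = _ALLELES[ref_idx[k]]
        alt = _ALLELES[(ref_idx[k] + alt_off[k]) % 4]
        markers.append(Marker(f"snp_{config.chromosome}_{pos}", config.chromosome, int(pos), ref, alt))
    return markers


def _as_panel(H: np.ndarray, markers: list[Marker], group: str,
              config: SimConfig) -> HaplotypePanel:
    n = H.shape[0] // 2
    return HaplotypePanel(
        markers=list(markers),
        haplotypes=H,
        sample_ids=[f"{group}_{k + 1:04d}" for k in range(n)],
        group_labels=[group] * n,
        phased=True,
    )
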