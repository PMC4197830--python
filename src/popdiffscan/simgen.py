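"""Synthetic-data generator: forward Wright–Fisher simulation of a
three-continent demographic history with migration, recombination,
mutation, and trajectory-conditioned selective sweeps.

The model is an out-of-Africa skeleton: a constant-size African
population, a bottlenecked Eurasian founder population splitting off,
and a later Europe/East-Asia split, with symmetric migration between
coexisting continental groups; optionally each continent is subdivided
into recently diverged populations (≈10 in total) to emulate the
population-level structure of large sequencing panels.  Every simulated
mutation is new (infinite sites on an integer bp grid), so ancestral and
derived alleles are known exactly and polarization is by construction.

Desk scaling uses the standard population-size rescaling by a factor λ
(default 10): sizes and times divided by λ, mutation/recombination/
migration/selection rates multiplied by λ, preserving θ = 4Nμ, ρ = 4Nr,
and time in units of 2N generations.  The equilibrium ancestral
population that seeds the forward phase is drawn from an msprime
coalescent simulation; everything after the out-of-Africa split —
demography, migration, and the sweeps — runs forward in time here.

Selective sweeps are additive (fitnesses 1, 1+s, 1+2s), act on a new
mutation at the region centre in one population, last 200–1,200
generations and end 401 generations before sampling; the selection
coefficient is tuned (bisection over s, rejection sampling of
allele-frequency trajectories) until the frequency at the end of the
sweep is within ±0.05 of the target, and the full simulation is then
conditioned on the accepted trajectory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .genodata import (GeneticMap, PolarizedGenotypes, PopulationPanel,
                       VariantRecord, SNP)

logger = logging.getLogger("popdiffscan")

ACCESSIBLE_GENOME_BP = 2_526_390_487
SWEEP_END_GENERATIONS = 401
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# model / scenario types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemographicModel:
    """Three-continent out-of-Africa skeleton (unscaled units).

    Sizes are diploid; times are generations before sampling.  The
    defaults approximate the published calibrated models for AFR/EUR/ASN
    at desk scale (constant post-split sizes instead of recent growth).
    """

    mutation_rate: float = 1.5e-8       # per bp per generation
    recombination_rate: float = 1.0e-8  # per bp per generation
    gene_conversion_rate: float = 4.5e-9  # initiation, per bp per gen
    conversion_tract_bp: int = 500        # mean tract length
    n_afr: int = 12_500
    t_ooa: int = 3_500                  # Eurasian founders leave Africa
    n_founder_ooa: int = 600
    t_founder: int = 100                # founder-episode duration
    n_ooa: int = 7_700
    t_split: int = 2_000                # EUR/ASN split
    n_founder_split: int = 800
    n_eur: int = 8_000
    n_asn: int = 8_000
    migration: float = 2.5e-5           # symmetric, post-split continents
    migration_early: float = 1.5e-4     # AFR ↔ Eurasian ancestor
    pops_per_continent: tuple = (("AFR", 3), ("EUR", 4), ("ASN", 3))
    t_subdivide: int = 200              # within-continent splits
    m_within: float = 5e-3              # migration within a continent
    rescale: float = 10.0               # λ

    def __post_init__(self):
        for name in ("mutation_rate", "recombination_rate", "migration",
                     "m_within"):
            if getattr(self, name) < 0:
                raise ValueError(f"model field {name} must be >= 0")
        if self.rescale < 1:
            raise ValueError("model field rescale must be >= 1")
        if not (self.t_ooa > self.t_split > self.t_subdivide > 0):
            raise ValueError("model times must satisfy "
                             "t_ooa > t_split > t_subdivide > 0")

    def with_migration(self, m: float) -> "DemographicModel":
        return replace(self, migration=m)

    # -- rescaled quantities -------------------------------------------

    def _size(self, n_dip: int) -> int:
        return max(2, int(round(n_dip / self.rescale)))

    def _time(self, t: int) -> int:
        return max(1, int(round(t / self.rescale)))


@dataclass(frozen=True)
class SweepScenario:
    """One selective-sweep scenario.

    The sweep ends ``end_time`` generations before sampling (fixed) and
    lasts ``duration`` generations; ``s`` is tuned so the selected
    allele reaches ``target_af`` (±tolerance) in ``population`` at the
    end of the sweep.
    """

    target_af: float
    duration: int = 800
    population: str = "AFR"
    end_time: int = SWEEP_END_GENERATIONS
    tolerance: float = 0.05

    def __post_init__(self):
        if not (0 < self.target_af <= 1):
            raise ValueError("target_af must be in (0, 1]")
        if not (200 <= self.duration <= 1200):
            raise ValueError("sweep duration must lie in [200, 1200]")


@dataclass
class Replicate:
    """One simulated dataset plus its provenance."""

    gts: PolarizedGenotypes
    panel: PopulationPanel
    genmap: GeneticMap
    focal_index: int | None
    scenario: SweepScenario | None
    realized: dict            # population → focal DAF in the full deme
    end_freq: float | None    # focal frequency at sweep end, selected pop
    s: float | None
    seed: int


# ---------------------------------------------------------------------------
# msprime equilibrium initialisation
# ---------------------------------------------------------------------------

def _equilibrium_population(n_hap, n_dip, length, mu, rec, rng):
    import msprime

    s1 = int(rng.integers(1, 2**31 - 1))
    s2 = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n_hap // 2, population_size=n_dip, ploidy=2,
        sequence_length=length, recombination_rate=rec,
        random_seed=s1, discrete_genome=True)
    mts = msprime.sim_mutations(ts, rate=mu, random_seed=s2,
                                model=msprime.BinaryMutationModel())
    keep = np.array([len(s.mutations) == 1 for s in mts.sites()], dtype=bool)
    G = mts.genotype_matrix()  # sites × haplotypes
    pos = mts.tables.sites.position.astype(np.int64) + 1  # 1-based
    if keep.size:
        G = G[keep]
        pos = pos[keep]
    # drop duplicate positions (possible under the discrete genome)
    _, first = np.unique(pos, return_index=True)
    return G[first].T.astype(np.int8).copy(), pos[first]


# ---------------------------------------------------------------------------
# forward engine
# ---------------------------------------------------------------------------

class _Forward:
    """Wright–Fisher engine over a haplotype × site matrix.

    Columns live in a list of blocks (new mutations append a block per
    generation; periodic compaction merges blocks and drops lost/fixed
    columns), which keeps each generation a single narrow row-gather.
    """

    COMPACT_EVERY = 16

    def __init__(self, H0, positions, length, mu_hap, rho_mei, rng,
                 crossover_cdf=None, conv_mei=0.0, tract_bp=500):
        self.blocks = [np.ascontiguousarray(H0, dtype=np.int8)]
        self.pos_blocks = [np.asarray(positions, dtype=np.int64)]
        self.pos_set = set(self.pos_blocks[0].tolist())
        self.L = int(length)
        self.mu_hap = float(mu_hap)       # expected new mutations per hap
        self.p_rec = 1.0 - math.exp(-rho_mei)
        self.p_conv = 1.0 - math.exp(-conv_mei)
        self.tract_bp = int(tract_bp)
        self.rng = rng
        self.crossover_cdf = crossover_cdf  # (pos, cdf) for map-based recomb
        self.fixed_dropped = 0
        self.focal_pos = -1               # bp position of the sweep site
        self._since_compact = 0

    @property
    def n_rows(self):
        return self.blocks[0].shape[0]

    @property
    def H(self):
        """Single merged matrix (compacts first)."""
        self.compact()
        return self.blocks[0]

    @property
    def pos(self):
        self.compact()
        return self.pos_blocks[0]

    @property
    def focal_col(self):
        if self.focal_pos < 0:
            return -1
        self.compact()
        hit = np.flatnonzero(self.pos_blocks[0] == self.focal_pos)
        return int(hit[0]) if hit.size else -1

    def focal_values(self):
        for b, p in zip(self.blocks, self.pos_blocks):
            hit = np.flatnonzero(p == self.focal_pos)
            if hit.size:
                return b[:, int(hit[0])]
        raise RuntimeError("focal column lost")

    # -- helpers -----------------------------------------------------------

    def _crossover_positions(self, k):
        if k == 0:
            return np.empty(0, dtype=np.int64)
        if self.crossover_cdf is None:
            return self.rng.integers(1, self.L + 1, size=k)
        grid, cdf = self.crossover_cdf
        u = self.rng.random(k)
        return np.interp(u, cdf, grid).astype(np.int64)

    def add_focal(self, deme_rows, position=None):
        """Introduce the selected mutation on one random haplotype."""
        row = int(self.rng.choice(deme_rows))
        if position is None:
            while True:
                position = int(self.rng.integers(1, self.L + 1))
                if position not in self.pos_set:
                    break
        elif position in self.pos_set:
            raise ValueError(f"focal position {position} already mutated")
        col = np.zeros((self.n_rows, 1), dtype=np.int8)
        col[row, 0] = 1
        self.blocks.append(col)
        self.pos_blocks.append(np.array([position], dtype=np.int64))
        self.pos_set.add(position)
        self.focal_pos = int(position)
        return position

    def step(self, old_offsets, old_sizes, new_specs, enforce=None,
             parent_carrier_prob=None):
        """Produce the next generation.

        ``new_specs`` is a list of (size_hap, source_row) per new deme,
        the source row giving parent-deme probabilities over the old
        demes.  ``enforce``: per new deme, the exact number of focal
        carriers (or None); ``parent_carrier_prob``: carrier probability
        of a parent drawn from each old deme (selection-adjusted).
        """
        rng = self.rng
        n_old = len(old_sizes)
        carrier_rows = None
        if enforce is not None:
            fc = self.focal_values()
            carrier_rows = []
            noncarrier_rows = []
            for q in range(n_old):
                sl = slice(old_offsets[q], old_offsets[q] + old_sizes[q])
                local = fc[sl]
                carrier_rows.append(old_offsets[q] + np.flatnonzero(local == 1))
                noncarrier_rows.append(old_offsets[q]
                                       + np.flatnonzero(local == 0))

        primaries = []
        srcs = []
        for d, (size_hap, row) in enumerate(new_specs):
            row = np.asarray(row, dtype=float)
            row = row / row.sum()
            if enforce is None or enforce[d] is None:
                src = rng.choice(n_old, size=size_hap, p=row)
                off = np.asarray(old_offsets)[src]
                sz = np.asarray(old_sizes)[src]
                prim = off + (rng.random(size_hap) * sz).astype(np.int64)
            else:
                k = int(enforce[d])
                x = np.asarray(parent_carrier_prob, dtype=float)
                wc = row * x
                wn = row * (1.0 - x)
                prim = np.empty(size_hap, dtype=np.int64)
                src = np.empty(size_hap, dtype=np.int64)
                if k > 0:
                    if wc.sum() <= 0:
                        raise RuntimeError("trajectory requires carriers "
                                           "but none are available")
                    sc = rng.choice(n_old, size=k, p=wc / wc.sum())
                    for q in range(n_old):
                        m = sc == q
                        if m.any():
                            prim[:k][m] = rng.choice(carrier_rows[q],
                                                     size=int(m.sum()))
                    src[:k] = sc
                if k < size_hap:
                    sn = rng.choice(n_old, size=size_hap - k,
                                    p=wn / wn.sum())
                    for q in range(n_old):
                        m = sn == q
                        if m.any():
                            prim[k:][m] = rng.choice(noncarrier_rows[q],
                                                     size=int(m.sum()))
                    src[k:] = sn
            primaries.append(prim)
            srcs.append(src if enforce is not None else src)

        primary = np.concatenate(primaries)
        src_all = np.concatenate([np.asarray(s) for s in srcs]) \
            if enforce is not None else None
        if enforce is None:
            src_all = np.concatenate(
                [np.asarray(s, dtype=np.int64) for s in srcs])
        n_new = primary.size
        old_blocks = self.blocks
        new_blocks = [np.take(b, primary, axis=0) for b in old_blocks]

        # recombination: at most one crossover per meiosis (ρ ≪ 1)
        rec_rows = np.flatnonzero(rng.random(n_new) < self.p_rec)
        if rec_rows.size:
            k = rec_rows.size
            xs = self._crossover_positions(k)
            q = src_all[rec_rows]
            off = np.asarray(old_offsets)[q]
            sz = np.asarray(old_sizes)[q]
            sec = off + (rng.random(k) * sz).astype(np.int64)
            if self.focal_pos >= 0 and enforce is not None:
                # the focal-site segment always comes from the primary
                # parent, preserving the conditioned carrier counts
                primary_left = self.focal_pos <= xs
            else:
                primary_left = rng.random(k) < 0.5
            for b, ob, p in zip(new_blocks, old_blocks, self.pos_blocks):
                use_prim = (p[None, :] <= xs[:, None]) \
                    == primary_left[:, None]
                b[rec_rows] = np.where(use_prim, b[rec_rows], ob[sec])

        # gene conversion: short tract copied from a second parent
        if self.p_conv > 0:
            conv_rows = np.flatnonzero(rng.random(n_new) < self.p_conv)
            if conv_rows.size:
                k = conv_rows.size
                starts = rng.integers(1, self.L + 1, size=k)
                ends = starts + rng.geometric(1.0 / self.tract_bp, size=k)
                q = src_all[conv_rows]
                off = np.asarray(old_offsets)[q]
                sz = np.asarray(old_sizes)[q]
                sec = off + (rng.random(k) * sz).astype(np.int64)
                if self.focal_pos >= 0 and enforce is not None:
                    # keep conditioned carrier counts: drop tracts that
                    # would overwrite the focal site
                    ok = ~((starts <= self.focal_pos)
                           & (self.focal_pos <= ends))
                    conv_rows, starts, ends, sec = (conv_rows[ok],
                                                    starts[ok], ends[ok],
                                                    sec[ok])
                if conv_rows.size:
                    for b, ob, p in zip(new_blocks, old_blocks,
                                        self.pos_blocks):
                        in_tract = (p[None, :] >= starts[:, None]) \
                            & (p[None, :] <= ends[:, None])
                        b[conv_rows] = np.where(in_tract, ob[sec],
                                                b[conv_rows])

        # mutation: new columns, one carrier each
        m = rng.poisson(n_new * self.mu_hap)
        if m > 0:
            newpos = []
            while len(newpos) < m:
                cand = rng.integers(1, self.L + 1, size=m - len(newpos))
                for p in cand:
                    p = int(p)
                    if p not in self.pos_set:
                        self.pos_set.add(p)
                        newpos.append(p)
            Z = np.zeros((n_new, m), dtype=np.int8)
            Z[rng.integers(0, n_new, size=m), np.arange(m)] = 1
            new_blocks.append(Z)
            self.pos_blocks = list(self.pos_blocks) \
                + [np.asarray(newpos, dtype=np.int64)]
        else:
            self.pos_blocks = list(self.pos_blocks)

        self.blocks = new_blocks
        self._since_compact += 1
        if self._since_compact >= self.COMPACT_EVERY:
            self.compact()

    def compact(self):
        """Merge blocks and drop lost / globally fixed columns."""
        self._since_compact = 0
        if len(self.blocks) == 1:
            merged = self.blocks[0]
            pos = self.pos_blocks[0]
        else:
            merged = np.concatenate(self.blocks, axis=1)
            pos = np.concatenate(self.pos_blocks)
        counts = merged.sum(axis=0, dtype=np.int64)
        n = merged.shape[0]
        keep = (counts > 0) & (counts < n)
        if self.focal_pos >= 0:
            keep |= pos == self.focal_pos
        self.fixed_dropped += int((counts == n).sum())
        if not keep.all():
            idx = np.flatnonzero(keep)
            merged = np.take(merged, idx, axis=1)
            pos = pos[idx]
        self.blocks = [np.ascontiguousarray(merged)]
        self.pos_blocks = [pos]
        self.pos_set = set(pos.tolist())


# ---------------------------------------------------------------------------
# demography timeline
# ---------------------------------------------------------------------------

def _mig_row(d, names, continent_of, m_between, m_within, sizes=None):
    """Source-deme probabilities for offspring of deme ``names[d]``."""
    row = np.zeros(len(names))
    cd = continent_of[names[d]]
    for q, nq in enumerate(names):
        if q == d:
            continue
        cq = continent_of[nq]
        if cq == cd:
            row[q] = m_within
        else:
            k_other = sum(1 for x in names if continent_of[x] == cq)
            row[q] = m_between / k_other
    row[d] = 1.0 - row.sum()
    if row[d] <= 0:
        raise ValueError("migration rates too large after rescaling")
    return row


def _build_timeline(model: DemographicModel, subdivide: bool):
    """List of phases: (duration, names, sizes_hap, parents, continent_of)."""
    lam = model.rescale
    t_ooa = model._time(model.t_ooa)
    t_split = model._time(model.t_split)
    t_found = model._time(model.t_founder)
    t_sub = model._time(model.t_subdivide)
    sz = model._size
    m_b = min(0.2, model.migration * lam)
    m_e = min(0.2, model.migration_early * lam)
    m_w = min(0.2, model.m_within * lam)

    cont = {"AFR": "AFR", "B": "B", "EUR": "EUR", "ASN": "ASN"}
    phases = []
    phases.append(dict(
        gens=t_found, names=["AFR", "B"],
        sizes=[2 * sz(model.n_afr), 2 * sz(model.n_founder_ooa)],
        parents={"B": "AFR"}, m_between=m_e, m_within=m_w))
    phases.append(dict(
        gens=t_ooa - t_found - t_split, names=["AFR", "B"],
        sizes=[2 * sz(model.n_afr), 2 * sz(model.n_ooa)],
        parents={}, m_between=m_e, m_within=m_w))
    phases.append(dict(
        gens=t_found, names=["AFR", "EUR", "ASN"],
        sizes=[2 * sz(model.n_afr), 2 * sz(model.n_founder_split),
               2 * sz(model.n_founder_split)],
        parents={"EUR": "B", "ASN": "B"}, m_between=m_b, m_within=m_w))
    main = dict(
        gens=t_split - t_found - (t_sub if subdivide else 0),
        names=["AFR", "EUR", "ASN"],
        sizes=[2 * sz(model.n_afr), 2 * sz(model.n_eur),
               2 * sz(model.n_asn)],
        parents={}, m_between=m_b, m_within=m_w)
    phases.append(main)
    if subdivide:
        names, sizes, parents = [], [], {}
        for cname, npop in model.pops_per_continent:
            total = {"AFR": model.n_afr, "EUR": model.n_eur,
                     "ASN": model.n_asn}[cname]
            for i in range(1, npop + 1):
                nm = f"{cname}{i}"
                names.append(nm)
                sizes.append(2 * max(2, sz(total) // npop))
                parents[nm] = cname
                cont[nm] = cname
        phases.append(dict(gens=t_sub, names=names, sizes=sizes,
                           parents=parents, m_between=m_b, m_within=m_w))
    for ph in phases:
        if ph["gens"] < 0:
            raise ValueError("model times do not order into a valid timeline")
    return phases, cont


# ---------------------------------------------------------------------------
# sweep trajectory
# ---------------------------------------------------------------------------

def _selection_shift(p, s):
    """Deterministic allele-frequency change under additive selection."""
    return p * (1 + s * (1 + p)) / (1 + 2 * s * p)


def _simulate_trajectory(sizes, M, sel_idx, s, start, end, rng):
    """Per-deme carrier counts from ``start`` down to 0 (scaled gens ago)."""
    n_demes = len(sizes)
    counts = np.zeros((start + 1, n_demes), dtype=np.int64)
    counts[start, sel_idx] = 1
    for t in range(start - 1, -1, -1):
        p = counts[t + 1] / sizes
        p_par = p.copy()
        if t + 1 > end:  # selection while the sweep is running
            p_par[sel_idx] = _selection_shift(p[sel_idx], s)
        p_off = M @ p_par
        counts[t] = rng.binomial(sizes, np.clip(p_off, 0, 1))
        if counts[t].sum() == 0:
            return None
    return counts


def tune_sweep_trajectory(sizes, M, sel_idx, scenario: SweepScenario,
                          rescale: float, rng, max_rounds: int = 14,
                          tries_per_round: int = 400):
    """Find s and an accepted trajectory for the scenario.

    Bisection-flavoured adjustment of s around the deterministic
    solution, with rejection sampling of stochastic trajectories until
    the frequency at sweep end is within tolerance of the target.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    dur = max(2, int(round(scenario.duration / rescale)))
    end = max(1, int(round(scenario.end_time / rescale)))
    start = end + dur
    p0 = 1.0 / sizes[sel_idx]
    pt = min(scenario.target_af, 0.97)
    s = (math.log(pt / (1 - pt)) - math.log(p0 / (1 - p0))) / dur
    lo, hi = s / 8, s * 8
    tried = []
    for _ in range(max_rounds):
        tried.append(s)
        endfreqs = []
        for _ in range(tries_per_round):
            traj = _simulate_trajectory(sizes, M, sel_idx, s, start, end, rng)
            if traj is None:
                continue
            f_end = traj[end, sel_idx] / sizes[sel_idx]
            if abs(f_end - scenario.target_af) <= scenario.tolerance or (
                    scenario.target_af >= 1.0
                    and f_end >= 1.0 - scenario.tolerance):
                return traj, s, start, end
            endfreqs.append(f_end)
        mean_end = float(np.mean(endfreqs)) if endfreqs else 0.0
        if mean_end < scenario.target_af:
            lo = s
            s = (s + hi) / 2 if hi > s else s * 1.5
        else:
            hi = s
            s = (lo + s) / 2
    raise RuntimeError(
        f"sweep tuning failed for target {scenario.target_af} "
        f"(duration {scenario.duration}); attempted s in "
        f"[{min(tried):.4g}, {max(tried):.4g}]")


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------

def _run_simulation(model, region_bp, n_per_pop, seed, subdivide=False,
                    scenario: SweepScenario | None = None,
                    genmap: GeneticMap | None = None) -> Replicate:
    if region_bp < 10_000:
        raise ValueError("region_bp must be at least 10 kb")
    rng = np.random.default_rng(seed)
    lam = model.rescale
    mu_s = model.mutation_rate * lam
    rec_s = model.recombination_rate * lam

    phases, continent_of = _build_timeline(model, subdivide)
    n0_hap = phases[0]["sizes"][0]
    H0, pos0 = _equilibrium_population(
        n0_hap, n0_hap // 2, region_bp, mu_s, rec_s, rng)

    crossover_cdf = None
    if genmap is not None:
        grid = np.linspace(0, region_bp, 512)
        cm = genmap.cm_at(grid)
        tot = cm[-1] - cm[0]
        if tot > 0:
            crossover_cdf = (grid, (cm - cm[0]) / tot)

    eng = _Forward(H0, pos0, region_bp, mu_s * region_bp,
                   rec_s * region_bp, rng, crossover_cdf,
                   conv_mei=model.gene_conversion_rate * lam * region_bp,
                   tract_bp=model.conversion_tract_bp)

    # sweep bookkeeping -----------------------------------------------------
    traj = s_used = None
    start_gen = end_gen = None
    if scenario is not None:
        if subdivide:
            raise ValueError("sweep scenarios use the three-continent model")
        main = phases[3]
        names = main["names"]
        if scenario.population not in names:
            raise ValueError(f"unknown selected population "
                             f"{scenario.population!r}")
        sel_idx = names.index(scenario.population)
        M = np.vstack([_mig_row(d, names, continent_of, main["m_between"],
                                main["m_within"]) for d in range(3)])
        traj, s_used, start_gen, end_gen = tune_sweep_trajectory(
            main["sizes"], M, sel_idx, scenario, lam, rng)
        if start_gen >= main["gens"]:
            raise ValueError("sweep begins before the EUR/ASN split; "
                             "shorten the sweep or deepen the split")

    # forward through the timeline -----------------------------------------
    old_names = [phases[0]["names"][0]]  # msprime output = ancestral AFR
    old_sizes = [n0_hap]
    old_offsets = [0]
    for pi, ph in enumerate(phases):
        names = ph["names"]
        sizes = ph["sizes"]
        rows = []
        for d, nm in enumerate(names):
            base = _mig_row(d, names, continent_of, ph["m_between"],
                            ph["m_within"])
            # translate source demes into the previous generation's demes
            row_old = np.zeros(len(old_names))
            for q, src_nm in enumerate(names):
                target = src_nm
                if target not in old_names:
                    target = ph["parents"].get(target, target)
                while target not in old_names:
                    target = ph["parents"][target]
                row_old[old_names.index(target)] += base[q]
            rows.append(row_old)
        # generations remaining after this phase
        later = sum(p["gens"] for p in phases[pi + 1:])
        for g in range(ph["gens"]):
            t_now = later + ph["gens"] - 1 - g  # time of generation produced
            enforce = None
            pcp = None
            if traj is not None and t_now <= start_gen - 1:
                enforce = [int(traj[t_now, d]) for d in range(len(names))]
                p_prev = traj[t_now + 1] / np.asarray(
                    phases[3]["sizes"], dtype=float)
                pcp = p_prev.copy()
                if t_now + 1 > end_gen:
                    si = names.index(scenario.population)
                    pcp[si] = _selection_shift(p_prev[si], s_used)
            eng.step(old_offsets, old_sizes,
                     list(zip(sizes, rows)), enforce, pcp)
            if (traj is not None and t_now == start_gen
                    and eng.focal_pos < 0):
                si = names.index(scenario.population)
                off = int(np.cumsum([0] + sizes)[si])
                centre = region_bp // 2
                while centre in eng.pos_set:
                    centre += 1
                eng.add_focal(np.arange(off, off + sizes[si]), centre)
            old_names = names
            old_sizes = sizes
            old_offsets = list(np.cumsum([0] + sizes[:-1]))
            if g == 0:
                rows = [
                    _translated_row(d, names, continent_of, ph) for d in
                    range(len(names))]

    eng.compact()
    return _sample_output(eng, model, region_bp, n_per_pop, old_names,
                          old_offsets, old_sizes, continent_of, rng,
                          scenario, traj, s_used, end_gen, seed, genmap)


def _translated_row(d, names, continent_of, ph):
    # after the founding generation, all sources exist by name
    return _mig_row(d, names, continent_of, ph["m_between"], ph["m_within"])


def _sample_output(eng, model, region_bp, n_per_pop, names, offsets, sizes,
                   continent_of, rng, scenario, traj, s_used, end_gen,
                   seed, genmap):
    sample_rows = []
    sample_names = []
    pops = []
    for d, nm in enumerate(names):
        n_hap = 2 * n_per_pop
        if n_hap > sizes[d]:
            raise ValueError(f"cannot sample {n_per_pop} diploids from "
                             f"deme {nm} of {sizes[d] // 2}")
        pick = rng.choice(sizes[d], size=n_hap, replace=False)
        sample_rows.append(offsets[d] + np.sort(pick))
        for i in range(n_per_pop):
            sample_names.append(f"{nm}_{i:04d}")
            pops.append(nm)
    rows = np.concatenate(sample_rows)
    Hs = eng.H[rows].T  # sites × haplotypes
    counts = Hs.sum(axis=1, dtype=np.int64)
    seg = (counts > 0) & (counts < Hs.shape[1])
    focal_pos = int(eng.pos[eng.focal_col]) if eng.focal_col >= 0 else None
    keep = np.flatnonzero(seg)
    Hs = Hs[keep]
    positions = eng.pos[keep]
    order = np.argsort(positions, kind="stable")
    Hs = np.ascontiguousarray(Hs[order])
    positions = positions[order]

    refs = _BASES[rng.integers(0, 4, size=positions.size)]
    alt_off = rng.integers(1, 4, size=positions.size)
    alts = _BASES[(np.searchsorted(_BASES, refs) + alt_off) % 4]
    variants = [VariantRecord("1", int(p), str(r), str(a), SNP,
                              ancestral=str(r))
                for p, r, a in zip(positions, refs, alts)]
    panel = PopulationPanel({s: (p, continent_of[p])
                             for s, p in zip(sample_names, pops)})
    gts = PolarizedGenotypes(variants, Hs, sample_names, phased=True)

    focal_index = None
    if focal_pos is not None:
        hit = np.flatnonzero(positions == focal_pos)
        focal_index = int(hit[0]) if hit.size else None

    realized = {}
    if eng.focal_col >= 0:
        fc = eng.H[:, eng.focal_col]
        for d, nm in enumerate(names):
            sl = slice(offsets[d], offsets[d] + sizes[d])
            realized[nm] = float(fc[sl].mean())
    end_freq = None
    if traj is not None:
        sel_sizes = np.asarray(sizes, dtype=float)
        si = names.index(scenario.population)
        end_freq = float(traj[end_gen, si] / sel_sizes[si])

    if genmap is None:
        genmap = GeneticMap.uniform(model.recombination_rate * 1e8,
                                    region_bp)
    return Replicate(gts=gts, panel=panel, genmap=genmap,
                     focal_index=focal_index, scenario=scenario,
                     realized=realized, end_freq=end_freq, s=s_used,
                     seed=int(seed))


def simulate_neutral(model: DemographicModel, region_bp: int = 100_000,
                     n_per_pop: int = 100, seed: int = 0,
                     subdivide: bool = False,
                     genmap: GeneticMap | None = None) -> Replicate:
    """One neutral replicate of the demographic model."""
    return _run_simulation(model, region_bp, n_per_pop, seed,
                           subdivide=subdivide, genmap=genmap)


def simulate_sweep(model: DemographicModel, scenario: SweepScenario,
                   region_bp: int = 100_000, n_per_pop: int = 100,
                   seed: int = 0,
                   genmap: GeneticMap | None = None) -> Replicate:
    """One replicate with a selective sweep at the region centre."""
    return _run_simulation(model, region_bp, n_per_pop, seed,
                           scenario=scenario, genmap=genmap)


def simulate_single_population(n_dip: int, region_bp: int = 20_000,
                               n_sample: int = 50, seed: int = 0,
                               mutation_rate: float = 1.5e-8,
                               recombination_rate: float = 0.0,
                               forward_generations: int = 0,
                               rescale: float = 10.0):
    """A panmictic constant-size population (for calibration checks).

    Returns (H sites×haplotypes, positions); the population is seeded at
    coalescent equilibrium and optionally run forward.
    """
    rng = np.random.default_rng(seed)
    n_hap = 2 * max(2, int(round(n_dip / rescale)))
    mu_s = mutation_rate * rescale
    rec_s = recombination_rate * rescale
    H0, pos0 = _equilibrium_population(n_hap, n_hap // 2, region_bp,
                                       mu_s, rec_s, rng)
    eng = _Forward(H0, pos0, region_bp, mu_s * region_bp,
                   rec_s * region_bp, rng)
    for _ in range(forward_generations):
        eng.step([0], [n_hap], [(n_hap, np.array([1.0]))])
    eng.compact()
    pick = rng.choice(n_hap, size=min(2 * n_sample, n_hap), replace=False)
    Hs = eng.H[np.sort(pick)].T
    counts = Hs.sum(axis=1, dtype=np.int64)
    seg = (counts > 0) & (counts < Hs.shape[1])
    order = np.argsort(eng.pos[seg], kind="stable")
    return np.ascontiguousarray(Hs[seg][order]), np.sort(eng.pos[seg])


# ---------------------------------------------------------------------------
# neutral expectation / migration sensitivity
# ---------------------------------------------------------------------------

def expected_neutral_highd(model: DemographicModel, n_replicates: int,
                           region_bp: int, scan_cfg=None,
                           accessible_bp: int = ACCESSIBLE_GENOME_BP,
                           n_per_pop: int = 100, seed: int = 0,
                           n_boot: int = 200):
    """Expected genome-wide number of HighD sites under neutrality.

    Runs the between-continent HighD scan on neutral replicates and
    scales the per-bp yield to the accessible genome.  Returns a dict
    with the scaled count, a bootstrap CI over replicates, and the raw
    per-replicate counts.
    """
    from . import popdiff
    from .scan import ScanConfig, highd_scan, dedup_union

    cfg = scan_cfg or ScanConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) + 1
             for s in ss.spawn(n_replicates)]
    counts = []
    for rseed in seeds:
        rep = simulate_neutral(model, region_bp, n_per_pop, rseed)
        freqs = popdiff.daf(rep.gts, rep.panel, level="continent")
        results = []
        for pair in popdiff.continent_pairs(rep.panel):
            dd = popdiff.delta_daf(freqs, pair)
            results.append(highd_scan(dd, cfg, level="between",
                                      pair=f"{pair[0]}-{pair[1]}"))
        counts.append(len(dedup_union(results)))
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no replicates simulated")
    total_bp = n_replicates * region_bp
    scale = accessible_bp / total_bp
    rng = np.random.default_rng(seed + 1)
    boots = [counts[rng.integers(0, counts.size, counts.size)].sum() * scale
             for _ in range(n_boot)]
    return {
        "scaled_count": float(counts.sum() * scale),
        "ci_low": float(np.percentile(boots, 2.5)),
        "ci_high": float(np.percentile(boots, 97.5)),
        "replicate_counts": counts.astype(int).tolist(),
        "simulated_bp": int(total_bp),
        "accessible_bp": int(accessible_bp),
    }


def migration_sensitivity(model: DemographicModel, m_rates,
                          n_replicates: int = 20,
                          region_bp: int = 100_000, scan_cfg=None,
                          n_per_pop: int = 100, seed: int = 0):
    """Expected neutral HighD count as a function of the migration rate."""
    import pandas as pd

    m_rates = list(m_rates)
    if len(m_rates) < 1:
        raise ValueError("need at least one migration rate")
    rows = []
    for m in m_rates:
        res = expected_neutral_highd(model.with_migration(m), n_replicates,
                                     region_bp, scan_cfg,
                                     n_per_pop=n_per_pop, seed=seed)
        rows.append({"m_rate": m, **{k: res[k] for k in
                                     ("scaled_count", "ci_low", "ci_high")}})
    df = pd.DataFrame(rows)
    counts = df["scaled_count"].to_numpy()
    df.attrs["monotone_decreasing"] = bool(
        np.all(np.diff(counts[np.argsort(df['m_rate'].to_numpy())]) <= 0))
    return df
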