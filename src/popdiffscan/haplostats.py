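"""Extended-haplotype homozygosity statistics.

EHH(x) is the probability that two randomly drawn carriers of a core
allele are identical over all sites between the focal position and x.
iHH integrates EHH over genetic distance on both sides (truncated where
EHH falls below a cutoff), iHS is the standardized ln(iHH_ancestral /
iHH_derived) within a population, and XP-EHH is the standardized
ln(iHH_popA / iHH_popB) contrasting two populations at the same site.
Raw scores are normalized within derived-allele-frequency bins so that
scores are comparable across frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import GeneticMap, PolarizedGenotypes

EHH_CUTOFF = 0.05
MAX_EXTEND_BP = 1_000_000


@dataclass
class EHHCurve:
    """EHH values at increasing distance from a focal site, one side each.

    Arrays run outward from the focal site (offset 0, EHH 1).
    """

    focal_pos: int
    core: int              # 0 = ancestral carriers, 1 = derived carriers
    n_core: int
    left_bp: np.ndarray
    left_cm: np.ndarray
    left_ehh: np.ndarray
    right_bp: np.ndarray
    right_cm: np.ndarray
    right_ehh: np.ndarray
    truncated_left: bool = False   # hit window edge before cutoff
    truncated_right: bool = False


def _ehh_side(H, positions, carriers, focal_idx, step, genmap,
              cutoff, max_extend_bp):
    """Walk outward from the focal site refining haplotype classes."""
    n = carriers.size
    pairs_total = n * (n - 1) // 2
    focal_pos = positions[focal_idx]
    cls = np.zeros(n, dtype=np.int64)
    bp = [0.0]
    cm = [0.0]
    ehh = [1.0]
    base_cm = genmap.cm_at(focal_pos)
    i = focal_idx + step
    truncated = True
    while 0 <= i < positions.size:
        if abs(int(positions[i]) - int(focal_pos)) > max_extend_bp:
            break
        alleles = H[i, carriers]
        # refine classes: new id = (old id, allele); missing is own symbol
        cls = cls * 3 + (alleles.astype(np.int64) + 1)
        _, counts = np.unique(cls, return_counts=True)
        h = float((counts * (counts - 1) // 2).sum()) / pairs_total
        bp.append(abs(int(positions[i]) - int(focal_pos)))
        cm.append(abs(genmap.cm_at(positions[i]) - base_cm))
        ehh.append(h)
        if h < cutoff:
            truncated = False
            break
        if h == 0.0:
            truncated = False
            break
        # renumber to avoid overflow of the class encoding
        _, cls = np.unique(cls, return_inverse=True)
        i += step
    return (np.asarray(bp), np.asarray(cm), np.asarray(ehh), truncated)


def ehh(gts: PolarizedGenotypes, focal_idx: int, core: int,
        genmap: GeneticMap, hap_cols=None, cutoff: float = EHH_CUTOFF,
        max_extend_bp: int = MAX_EXTEND_BP) -> EHHCurve | None:
    """EHH curve around a focal site for carriers of one core allele.

    ``core=None`` uses all haplotypes (the XP-EHH convention).  Returns
    None when fewer than two carriers exist.
    """
    H = gts.H
    positions = gts.positions
    cols = (np.arange(gts.n_haplotypes) if hap_cols is None
            else np.asarray(hap_cols))
    if core is None:
        carriers = cols
    else:
        carriers = cols[H[focal_idx, cols] == core]
    if carriers.size < 2:
        return None
    lb, lc, le, tl = _ehh_side(H, positions, carriers, focal_idx, -1,
                               genmap, cutoff, max_extend_bp)
    rb, rc, re, tr = _ehh_side(H, positions, carriers, focal_idx, +1,
                               genmap, cutoff, max_extend_bp)
    return EHHCurve(int(positions[focal_idx]), core if core is not None else -1,
                    int(carriers.size), lb, lc, le, rb, rc, re, tl, tr)


def ihh(curve: EHHCurve, cutoff: float = EHH_CUTOFF) -> tuple[float, bool]:
    """Trapezoidal integral of EHH over genetic distance (cM), both sides.

    Integration stops after the first segment whose far end drops below
    the cutoff; a side that never reaches the cutoff before the window
    edge is integrated to the edge and flagged truncated.
    """
    def side(cm, e, truncated):
        if cm.size == 0:
            raise ValueError("empty EHH curve")
        total = 0.0
        for i in range(1, cm.size):
            total += 0.5 * (e[i - 1] + e[i]) * (cm[i] - cm[i - 1])
            if e[i] < cutoff:
                break
        return total, truncated

    l, tl = side(curve.left_cm, curve.left_ehh, curve.truncated_left)
    r, tr = side(curve.right_cm, curve.right_ehh, curve.truncated_right)
    return l + r, (tl or tr)


def ihs_raw(gts: PolarizedGenotypes, genmap: GeneticMap, focal_idx: int,
            hap_cols=None, cutoff: float = EHH_CUTOFF,
            max_extend_bp: int = MAX_EXTEND_BP):
    """Raw iHS = ln(iHH_ancestral / iHH_derived) at one site.

    Returns (raw, derived_freq, truncated) or None when either allele has
    fewer than two carriers or a zero-length integral.
    """
    ca = ehh(gts, focal_idx, 0, genmap, hap_cols, cutoff, max_extend_bp)
    cd = ehh(gts, focal_idx, 1, genmap, hap_cols, cutoff, max_extend_bp)
    if ca is None or cd is None:
        return None
    ia, ta = ihh(ca, cutoff)
    idv, td = ihh(cd, cutoff)
    if ia <= 0 or idv <= 0:
        return None
    cols = (np.arange(gts.n_haplotypes) if hap_cols is None
            else np.asarray(hap_cols))
    alleles = gts.H[focal_idx, cols]
    freq = float((alleles == 1).sum() / max((alleles >= 0).sum(), 1))
    return math.log(ia / idv), freq, (ta or td)


def xpehh_raw(gts: PolarizedGenotypes, genmap: GeneticMap, focal_idx: int,
              cols_a, cols_b, cutoff: float = EHH_CUTOFF,
              max_extend_bp: int = MAX_EXTEND_BP):
    """Raw XP-EHH = ln(iHH_A / iHH_B); positive means longer haplotypes
    (a sweep signal) in population A."""
    ca = ehh(gts, focal_idx, None, genmap, cols_a, cutoff, max_extend_bp)
    cb = ehh(gts, focal_idx, None, genmap, cols_b, cutoff, max_extend_bp)
    if ca is None or cb is None:
        return None
    ia, ta = ihh(ca, cutoff)
    ib, tb = ihh(cb, cutoff)
    if ia <= 0 or ib <= 0:
        return None
    both = np.concatenate([np.asarray(cols_a), np.asarray(cols_b)])
    alleles = gts.H[focal_idx, both]
    freq = float((alleles == 1).sum() / max((alleles >= 0).sum(), 1))
    return math.log(ia / ib), freq, (ta or tb)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_scores(raw: pd.DataFrame, bin_width: float = 0.05,
                       min_per_bin: int = 20) -> pd.DataFrame:
    """Z-standardize raw scores within derived-frequency bins.

    ``raw`` needs columns ``raw`` and ``freq``.  Bins of width
    ``bin_width`` over [0, 1]; adjacent bins holding fewer than
    ``min_per_bin`` scores are merged left-to-right before standardizing.
    """
    if len(raw) == 0:
        raise ValueError("no scores to standardize")
    f = raw["freq"].to_numpy()
    nbins = int(round(1.0 / bin_width))
    idx = np.clip((f / bin_width).astype(int), 0, nbins - 1)
    # merge thin bins with the next non-empty bin to the right
    merged = np.arange(nbins)
    counts = np.bincount(idx, minlength=nbins)
    j = 0
    while j < nbins - 1:
        members = np.flatnonzero(merged == merged[j])
        if counts[members].sum() < min_per_bin:
            merged[members] = merged[members[-1] + 1]
        j = members[-1] + 1
    # a thin final group merges backwards
    last = merged == merged[nbins - 1]
    if counts[last].sum() < min_per_bin:
        prev = np.flatnonzero(~last)
        if prev.size:
            merged[last] = merged[prev[-1]]
    groups = merged[idx]
    out = raw.copy()
    out["bin"] = groups
    z = np.full(len(raw), np.nan)
    for g in np.unique(groups):
        m = groups == g
        vals = raw["raw"].to_numpy()[m]
        sd = vals.std(ddof=0)
        z[m] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    out["std_score"] = z
    return out


def standardize_against(scores: pd.DataFrame, reference: pd.DataFrame,
                        bin_width: float = 0.05,
                        min_per_bin: int = 20) -> pd.DataFrame:
    """Standardize candidate scores with bin parameters estimated from a
    reference (e.g. genome-wide or neutral) score set.

    Candidate sites under selection would distort their own frequency
    bins; using reference-derived means and standard deviations keeps
    the z-scale anchored to the background.  Both frames need ``raw``
    and ``freq`` columns; candidate scores fall into the reference bin
    covering their frequency (nearest non-empty bin if outside).
    """
    ref = standardize_scores(reference, bin_width, min_per_bin)
    params = {}
    for g, grp in ref.groupby("bin"):
        vals = grp["raw"].to_numpy()
        params[g] = (vals.mean(), vals.std(ddof=0), grp["freq"].mean())
    bins = sorted(params)
    centers = np.array([params[g][2] for g in bins])
    out = scores.copy()
    z = np.full(len(scores), np.nan)
    for i, (raw_v, f) in enumerate(zip(scores["raw"], scores["freq"])):
        g = bins[int(np.argmin(np.abs(centers - f)))]
        mean, sd, _ = params[g]
        z[i] = (raw_v - mean) / sd if sd > 0 else 0.0
    out["std_score"] = z
    return out


def subsample_haplotype_columns(gts: PolarizedGenotypes, samples,
                                n_individuals: int = 30,
                                seed: int = 0) -> np.ndarray:
    """Haplotype columns of a random subset of individuals (the
    fixed-size design that makes population and continent analyses
    comparable)."""
    rng = np.random.default_rng(seed)
    samples = list(samples)
    if len(samples) > n_individuals:
        pick = rng.choice(len(samples), size=n_individuals, replace=False)
        samples = [samples[i] for i in sorted(pick)]
    return gts.haplotype_columns(samples)
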