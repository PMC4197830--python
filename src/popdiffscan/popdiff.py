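"""Per-population derived-allele-frequency statistics.

DAF per group, pairwise ΔDAF with the higher-frequency group recorded as
direction, the coefficient of variation of DAF across populations (cvDAF),
the per-site Weir & Cockerham F_ST estimator, empirical rank P-values and
pairwise linkage disequilibrium (r², D′).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import PolarizedGenotypes, PopulationPanel


# ---------------------------------------------------------------------------
# frequency table
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Per-site DAF and allele counts per group, plus pooled DAF.

    ``daf``/``derived``/``total`` are DataFrames with one column per group;
    a missing DAF (no observed alleles in the group) is NaN.  ``sites``
    carries (chrom, pos, ref, alt, vclass, impq) aligned row-for-row.
    """

    sites: pd.DataFrame
    daf: pd.DataFrame
    derived: pd.DataFrame
    total: pd.DataFrame
    pooled: pd.Series
    level: str

    @property
    def groups(self) -> list[str]:
        return list(self.daf.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def site_frame(gts: PolarizedGenotypes) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [v.chrom for v in gts.variants],
        "pos": [v.pos for v in gts.variants],
        "ref": [v.ref for v in gts.variants],
        "alt": [v.alt for v in gts.variants],
        "vclass": [v.vclass for v in gts.variants],
        "impq": [v.impq for v in gts.variants],
    })


def daf(gts: PolarizedGenotypes, panel: PopulationPanel,
        level: str = "population") -> FrequencyTable:
    """Derived allele frequency per group, over observed alleles only."""
    panel = panel.subset([s for s in gts.samples if s in panel])
    if len(panel) == 0:
        raise ValueError("no overlap between panel and genotype samples")
    groups = (panel.populations() if level == "population"
              else panel.continents())
    ishere = np.array([s in panel for s in gts.samples])
    # one-hot (haplotype × group) membership
    G = np.zeros((gts.n_haplotypes, len(groups)), dtype=np.int64)
    gidx = {g: j for j, g in enumerate(groups)}
    for i, s in enumerate(gts.samples):
        if not ishere[i]:
            continue
        j = gidx[panel.group_of(s, level)]
        G[2 * i, j] = 1
        G[2 * i + 1, j] = 1
    der = ((gts.H == 1).astype(np.int64)) @ G
    tot = ((gts.H >= 0).astype(np.int64)) @ G
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(tot > 0, der / np.maximum(tot, 1), np.nan)
        f[tot == 0] = np.nan
    incl = G.sum(axis=1) > 0
    pd_der = (gts.H[:, incl] == 1).sum(axis=1)
    pd_tot = (gts.H[:, incl] >= 0).sum(axis=1)
    pooled = np.where(pd_tot > 0, pd_der / np.maximum(pd_tot, 1), np.nan)
    sites = site_frame(gts)
    return FrequencyTable(
        sites=sites,
        daf=pd.DataFrame(f, columns=groups),
        derived=pd.DataFrame(der, columns=groups),
        total=pd.DataFrame(tot, columns=groups),
        pooled=pd.Series(pooled, name="pooled_daf"),
        level=level,
    )


# ---------------------------------------------------------------------------
# ΔDAF / cvDAF
# ---------------------------------------------------------------------------

def delta_daf(freqs: FrequencyTable, pair: tuple[str, str]) -> pd.DataFrame:
    """Signed DAF difference for a pair of groups.

    Returns one row per site with both DAFs defined: ``value`` = DAF_A −
    DAF_B, ``score`` = |value| (used for ranking), ``direction`` = the
    group with the higher DAF (empty on ties).  Skipped sites are counted
    in ``df.attrs["skipped"]``.
    """
    a, b = pair
    for g in pair:
        if g not in freqs.daf.columns:
            raise KeyError(f"group {g!r} not in frequency table")
    fa = freqs.daf[a].to_numpy()
    fb = freqs.daf[b].to_numpy()
    ok = ~(np.isnan(fa) | np.isnan(fb))
    value = fa[ok] - fb[ok]
    out = freqs.sites.loc[ok].reset_index(drop=True).copy()
    out["value"] = value
    out["score"] = np.abs(value)
    out["direction"] = np.where(value > 0, a, np.where(value < 0, b, ""))
    out["pair"] = f"{a}-{b}"
    out.attrs["skipped"] = int((~ok).sum())
    return out


def cv_daf(freqs: FrequencyTable, groups=None) -> pd.DataFrame:
    """Coefficient of variation (sample sd / mean) of group DAFs per site.

    Sites with fewer than two non-missing group DAFs or zero mean are
    skipped (NaN), matching the requirement that rarity alone should not
    mimic low differentiation.
    """
    groups = list(groups) if groups is not None else freqs.groups
    F = freqs.daf[groups].to_numpy()
    n = np.sum(~np.isnan(F), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(F), np.nan, F), axis=1)
        sd = np.full(F.shape[0], np.nan)
        ok2 = n >= 2
        if ok2.any():
            sd[ok2] = np.nanstd(F[ok2], axis=1, ddof=1)
    cv = np.where((n >= 2) & (mean > 0), sd / np.where(mean > 0, mean, 1),
                  np.nan)
    out = freqs.sites.copy()
    out["cv"] = cv
    out["pooled_daf"] = freqs.pooled.to_numpy()
    out.attrs["skipped"] = int(np.isnan(cv).sum())
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def fst_from_counts(der1, tot1, der2, tot2):
    """Per-site Weir & Cockerham (1984) two-group F_ST from allele counts.

    Haplotype (allele-count) form of the variance-components estimator:
    F = (MSP − MSG) / (MSP + (n_c − 1)·MSG) with the mean squares computed
    from the two groups' derived-allele frequencies.  Undefined (0/0)
    sites return NaN; slightly negative values are legitimate.
    """
    n1 = np.asarray(tot1, dtype=float)
    n2 = np.asarray(tot2, dtype=float)
    d1 = np.asarray(der1, dtype=float)
    d2 = np.asarray(der2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = d1 / n1
        p2 = d2 / n2
        nt = n1 + n2
        pbar = (d1 + d2) / nt
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r−1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nt - 2)
        nc = nt - (n1 ** 2 + n2 ** 2) / nt  # (r−1) nc
        denom = msp + (nc - 1) * msg
        fst = np.where(denom != 0, (msp - msg) / np.where(denom != 0, denom, 1),
                       np.nan)
    fst = np.where((n1 < 2) | (n2 < 2), np.nan, fst)
    return fst


def weir_cockerham_fst(gts: PolarizedGenotypes, panel: PopulationPanel,
                       pair: tuple[str, str],
                       level: str | None = None) -> pd.DataFrame:
    """Per-site W&C F_ST between two groups of a panel."""
    if level is None:
        level = ("population" if pair[0] in panel.populations()
                 else "continent")
    freqs = daf(gts, panel, level=level)
    a, b = pair
    fst = fst_from_counts(freqs.derived[a], freqs.total[a],
                          freqs.derived[b], freqs.total[b])
    out = freqs.sites.copy()
    out["fst"] = fst
    out["pair"] = f"{a}-{b}"
    return out


# ---------------------------------------------------------------------------
# rank P-values
# ---------------------------------------------------------------------------

def rank_pvalues(scores: pd.DataFrame, order: str = "descending",
                 by: str = "score") -> pd.DataFrame:
    """Assign rank P-values P = rank/N, rank 1 = most extreme.

    ``order="descending"`` ranks the largest score first (ΔDAF);
    ``"ascending"`` ranks the smallest first (cvDAF).  Ties are broken by
    genomic order (chrom, pos) for determinism.
    """
    if len(scores) == 0:
        raise ValueError("empty score list")
    if order not in ("descending", "ascending"):
        raise ValueError("order must be 'descending' or 'ascending'")
    s = scores[by].to_numpy()
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    key = -s if order == "descending" else s
    idx = np.lexsort((scores["pos"].to_numpy(), scores["chrom"].to_numpy(),
                      key))
    rank = np.empty(len(scores), dtype=np.int64)
    rank[idx] = np.arange(1, len(scores) + 1)
    out = scores.copy()
    out["rank"] = rank
    out["rank_p"] = rank / len(scores)
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(gts: PolarizedGenotypes, site_a: int, site_b: int,
          hap_cols=None) -> tuple[float, float]:
    """Haplotype-count r² and D′ between two sites (derived coding).

    Returns (nan, nan) if either site is monomorphic among the selected
    haplotypes.
    """
    ha = gts.H[site_a]
    hb = gts.H[site_b]
    if hap_cols is not None:
        ha = ha[hap_cols]
        hb = hb[hap_cols]
    ok = (ha >= 0) & (hb >= 0)
    ha = ha[ok].astype(float)
    hb = hb[ok].astype(float)
    n = ha.size
    if n == 0:
        return (float("nan"), float("nan"))
    pa, pb = ha.mean(), hb.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return (float("nan"), float("nan"))
    pab = float(np.mean(ha * hb))
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else float("nan")
    return (float(r2), float(dprime))


def continent_pairs(panel: PopulationPanel) -> list[tuple[str, str]]:
    conts = panel.continents()
    return [(a, b) for i, a in enumerate(conts) for b in conts[i + 1:]]


def within_continent_pairs(panel: PopulationPanel) -> list[tuple[str, str]]:
    pairs = []
    for cont in panel.continents():
        pops = panel.populations_in(cont)
        pairs.extend((a, b) for i, a in enumerate(pops) for b in pops[i + 1:])
    return pairs
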