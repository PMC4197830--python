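"""Enrichment and validation statistics.

Overlap of the genes hosting highly differentiated sites with a
published positive-selection gene list against size-matched random
control gene sets; genic enrichment of candidate sites versus matched
controls; genotype and allele-frequency concordance between independent
callsets; and LD-proxy expansion of small site sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genodata import PolarizedGenotypes
from .popdiff import FrequencyTable, ld_r2

logger = logging.getLogger("popdiffscan")


# ---------------------------------------------------------------------------
# gene annotation helpers
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open → 1-based closed).

    Columns used: chrom, start, end, name, (score), strand; the
    transcription start site is ``start`` on +, ``end`` on −.
    """
    rows = []
    from .genodata import _open_text
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            chrom, start, end = p[0], int(p[1]) + 1, int(p[2])
            name = p[3] if len(p) > 3 else f"{chrom}:{start}-{end}"
            strand = p[5] if len(p) > 5 else "+"
            rows.append((chrom, start, end, name, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                     "strand"])
    df["tss"] = np.where(df["strand"] == "-", df["end"], df["start"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def read_gene_list(path) -> set:
    from .genodata import _open_text
    with _open_text(path) as fh:
        return {ln.strip() for ln in fh if ln.strip()}


def annotate_gene_context(sites: pd.DataFrame,
                          genes: pd.DataFrame) -> pd.DataFrame:
    """Add genic flag, hosting gene, and distance to nearest gene start.

    Distance is 0 for sites inside a gene interval, otherwise the bp
    distance to the nearest transcription start site.
    """
    out = sites.copy()
    genic = np.zeros(len(sites), dtype=bool)
    host = np.full(len(sites), "", dtype=object)
    dist = np.full(len(sites), np.inf)
    for chrom, g in genes.groupby("chrom"):
        m = sites["chrom"] == chrom
        if not m.any():
            continue
        pos = sites.loc[m, "pos"].to_numpy()
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        names = g["name"].to_numpy()
        tss = np.sort(g["tss"].to_numpy())
        idx = np.flatnonzero(m.to_numpy())
        for i, p in zip(idx, pos):
            inside = (starts <= p) & (p <= ends)
            if inside.any():
                genic[i] = True
                host[i] = names[np.flatnonzero(inside)[0]]
                dist[i] = 0.0
            else:
                j = np.searchsorted(tss, p)
                cands = []
                if j > 0:
                    cands.append(abs(p - tss[j - 1]))
                if j < tss.size:
                    cands.append(abs(tss[j] - p))
                dist[i] = min(cands) if cands else np.inf
    out["genic"] = genic
    out["gene"] = host
    out["dist_gene_start"] = dist
    return out


# ---------------------------------------------------------------------------
# gene-set overlap enrichment
# ---------------------------------------------------------------------------

def gene_overlap_enrichment(target, reference, universe,
                            n_control: int = 100, seed: int = 0) -> dict:
    """Observed overlap of target genes with a reference list versus
    size-matched random control gene sets.

    Returns observed and control fractions and a one-sided one-sample
    t-test of the control fractions against the observed value
    (alternative: controls are smaller).
    """
    target = set(target)
    reference = set(reference)
    universe = sorted(set(universe))
    if not target <= set(universe):
        raise ValueError("target genes must be a subset of the universe")
    if len(universe) < len(target):
        raise ValueError("universe smaller than target set")
    if not (reference & set(universe)):
        raise ValueError("reference list shares no genes with the universe")
    obs = len(target & reference) / len(target)
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_control)
    uni = np.asarray(universe, dtype=object)
    for i in range(n_control):
        draw = rng.choice(uni, size=len(target), replace=False)
        fractions[i] = len(set(draw) & reference) / len(target)
    sd = fractions.std(ddof=1)
    if sd == 0:
        p = np.nan
        logger.warning("degenerate control distribution (sd = 0); "
                       "t-test undefined")
    else:
        t = sps.ttest_1samp(fractions, obs, alternative="less")
        p = float(t.pvalue)
    return {"observed": obs, "control_mean": float(fractions.mean()),
            "control_sd": float(sd), "p_value": p,
            "control_fractions": fractions}


def genic_enrichment(target_sites: pd.DataFrame,
                     control_sites: pd.DataFrame) -> dict:
    """Odds ratio and Fisher exact P of genic status, targets vs matched
    controls (sites need a boolean ``genic`` column)."""
    a = int(target_sites["genic"].sum())
    b = int((~target_sites["genic"]).sum())
    c = int(control_sites["genic"].sum())
    d = int((~control_sites["genic"]).sum())
    table = [[a, b], [c, d]]
    orr, p = sps.fisher_exact(table)
    out = {"table": table, "odds_ratio": float(orr), "p_value": float(p)}
    if 0 in (a, b, c, d):
        out["odds_ratio_haldane"] = ((a + 0.5) * (d + 0.5)
                                     / ((b + 0.5) * (c + 0.5)))
    return out


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def genotype_concordance(gts_a: PolarizedGenotypes,
                         gts_b: PolarizedGenotypes) -> pd.DataFrame:
    """Per-site fraction of identical unordered genotypes among shared
    samples (0|1 and 1|0 agree); summaries by variant class are in
    ``df.attrs["summary"]``."""
    shared = [s for s in gts_a.samples if s in set(gts_b.samples)]
    if not shared:
        raise ValueError("no shared samples")
    idx_b = gts_b.site_index()
    rows = []
    ca = gts_a.haplotype_columns(shared)
    cb = gts_b.haplotype_columns(shared)
    for i, v in enumerate(gts_a.variants):
        j = idx_b.get(v.key)
        if j is None:
            continue
        ha = gts_a.H[i, ca].reshape(-1, 2)
        hb = gts_b.H[j, cb].reshape(-1, 2)
        ok = (ha >= 0).all(axis=1) & (hb >= 0).all(axis=1)
        if not ok.any():
            continue
        ga = ha[ok].sum(axis=1)  # unordered genotype = derived dose
        gb = hb[ok].sum(axis=1)
        rows.append({"chrom": v.chrom, "pos": v.pos, "vclass": v.vclass,
                     "n": int(ok.sum()),
                     "concordance": float((ga == gb).mean())})
    if not rows:
        raise ValueError("no shared sites")
    df = pd.DataFrame(rows)
    df.attrs["summary"] = (df.groupby("vclass")["concordance"]
                           .agg(["median", "mean", "count"]).to_dict("index"))
    return df


def af_concordance(freqs_a: FrequencyTable, freqs_b: FrequencyTable,
                   groups=None) -> pd.DataFrame:
    """Spearman correlation of group allele frequencies between two
    callsets over shared sites."""
    keys_a = freqs_a.sites[["chrom", "pos", "ref", "alt"]]
    keys_b = freqs_b.sites[["chrom", "pos", "ref", "alt"]]
    merged = keys_a.reset_index().merge(
        keys_b.reset_index(), on=["chrom", "pos", "ref", "alt"],
        suffixes=("_a", "_b"))
    groups = groups or [g for g in freqs_a.groups if g in freqs_b.groups]
    rows = []
    for g in groups:
        fa = freqs_a.daf[g].to_numpy()[merged["index_a"]]
        fb = freqs_b.daf[g].to_numpy()[merged["index_b"]]
        ok = np.isfinite(fa) & np.isfinite(fb)
        if ok.sum() < 3:
            rows.append({"group": g, "n": int(ok.sum()),
                         "spearman_r": np.nan, "p_value": np.nan})
            continue
        r, p = sps.spearmanr(fa[ok], fb[ok])
        rows.append({"group": g, "n": int(ok.sum()),
                     "spearman_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)


def ld_proxy_expand(gts: PolarizedGenotypes, target_idx, r2_min: float = 0.8,
                    window_bp: int = 250_000, hap_cols=None) -> pd.DataFrame:
    """Expand a site set with its LD proxies (r² > ``r2_min``) within a
    window; returns targets plus proxies with the linking r²."""
    positions = gts.positions
    chroms = gts.chroms
    rows = []
    seen = set()
    for t in np.atleast_1d(target_idx):
        t = int(t)
        if t not in seen:
            seen.add(t)
            rows.append({"site": t, "proxy_of": t, "r2": 1.0})
        near = np.flatnonzero((chroms == chroms[t])
                              & (np.abs(positions - positions[t])
                                 <= window_bp))
        for j in near:
            j = int(j)
            if j == t or j in seen:
                continue
            r2, _ = ld_r2(gts, t, j, hap_cols)
            if np.isfinite(r2) and r2 > r2_min:
                seen.add(j)
                rows.append({"site": j, "proxy_of": t, "r2": float(r2)})
    return pd.DataFrame(rows)


def random_gene_intervals(region_bp: int, n_genes: int, seed: int = 0,
                          mean_len: int = 8000, chrom: str = "1"
                          ) -> pd.DataFrame:
    """Synthetic non-overlapping gene intervals for demo/enrichment runs
    on simulated regions."""
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.choice(
        np.arange(1, max(2, region_bp - mean_len), dtype=np.int64),
        size=n_genes, replace=False))
    rows = []
    prev_end = 0
    for i, s in enumerate(starts):
        s = max(int(s), prev_end + 1)
        ln = max(500, int(rng.exponential(mean_len)))
        e = min(region_bp, s + ln)
        if e <= s:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, s, e, f"gene{i + 1}", strand))
        prev_end = e
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                     "strand"])
    df["tss"] = np.where(df["strand"] == "-", df["end"], df["start"])
    return df
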