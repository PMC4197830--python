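"""HighD / LowD genome scans.

The scans are empirical outlier methods: mark the most extreme percentile
of per-site scores genome-wide, partition every scanned variant into
non-overlapping windows of a fixed variant count per chromosome, pick the
single most extreme marked variant in each window, and retain it if it
passes a fixed threshold.  One variant per window/pair avoids re-reporting
the many hitchhikers that cluster around a single differentiation event.

Windows are blocks of consecutive variants over *all* scanned variants
(not only the marked ones), so a window corresponds to a genomic
neighbourhood; the last short block on each chromosome is scanned like any
other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger("popdiffscan")


@dataclass
class ScanConfig:
    """Thresholds and window sizes for the HighD/LowD scans."""

    window_highd: int = 5000        # variants per HighD window
    window_lowd: int = 100          # variants per LowD window
    top_percentile: float = 1.0     # % of sites marked as extreme
    thresh_between: float = 0.7     # ΔDAF threshold, between continents
    thresh_within: float = 0.25     # ΔDAF threshold, within continents
    cv_thresh: float = 0.01         # cvDAF threshold for LowD
    daf_band: tuple = (0.40, 0.60)  # closed pooled-DAF band for LowD
    daf_exclusion: tuple = (0.45, 0.55)  # open exclusion interval
    min_impq: float = 0.8           # imputation-quality QC cut (strict >)

    def __post_init__(self):
        if not (0 < self.top_percentile <= 100):
            raise ValueError("top_percentile must be in (0, 100]")
        for t in (self.thresh_between, self.thresh_within, self.cv_thresh):
            if not (0 <= t <= 1):
                raise ValueError("thresholds must be in [0, 1]")
        lo, hi = self.daf_band
        elo, ehi = self.daf_exclusion
        if not (lo <= elo <= ehi <= hi):
            raise ValueError("DAF band must contain the exclusion interval")


@dataclass
class ScanResult:
    """Retained sites plus per-filter drop counters and a config echo."""

    retained: pd.DataFrame
    counters: dict
    config: dict
    pair: str | None = None
    level: str | None = None

    @property
    def n_retained(self) -> int:
        return len(self.retained)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(sites: pd.DataFrame, min_impq: float = 0.8,
              strict: bool = False) -> pd.DataFrame:
    """Remove sites with imputation quality ≤ ``min_impq``.

    Sites with missing quality are kept (and counted) unless ``strict``.
    """
    if len(sites) == 0:
        return sites.copy()
    q = pd.to_numeric(sites.get("impq"), errors="coerce")
    missing = q.isna()
    keep = (q > min_impq) | (missing & ~strict)
    out = sites.loc[keep.to_numpy()].reset_index(drop=True)
    out.attrs["dropped_lowq"] = int((~keep).sum())
    out.attrs["missing_impq"] = int(missing.sum())
    if missing.any() and not strict:
        logger.warning("%d sites lack imputation quality; kept (lenient mode)",
                       int(missing.sum()))
    return out


# ---------------------------------------------------------------------------
# HighD scan
# ---------------------------------------------------------------------------

def _check_sorted(df: pd.DataFrame):
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    for i in range(1, len(df)):
        if chrom[i] == chrom[i - 1] and pos[i] < pos[i - 1]:
            raise ValueError("sites must be sorted by (chrom, pos)")


def highd_scan(scores: pd.DataFrame, cfg: ScanConfig,
               level: str = "between", pair: str | None = None,
               windowless: bool = False) -> ScanResult:
    """Windowed peak-picking of the most differentiated variants.

    ``scores`` must hold genomically sorted sites with a ``score`` column
    (|ΔDAF|).  ``windowless=True`` applies the threshold only (the mode
    used for the small exomic-INDEL set).
    """
    if level not in ("between", "within"):
        raise ValueError("level must be 'between' or 'within'")
    thresh = cfg.thresh_between if level == "between" else cfg.thresh_within
    counters = {"input": len(scores)}
    if len(scores) == 0:
        return ScanResult(scores.copy(), counters, asdict(cfg), pair, level)
    _check_sorted(scores)
    s = scores["score"].to_numpy()

    if windowless:
        keep = s > thresh
        retained = scores.loc[keep].reset_index(drop=True).copy()
        retained["window"] = -1
        counters.update(below_threshold=int((~keep).sum()),
                        retained=int(keep.sum()))
        return ScanResult(retained, counters, asdict(cfg), pair, level)

    n = len(scores)
    k = max(1, int(n * cfg.top_percentile / 100.0))
    order = np.lexsort((scores["pos"].to_numpy(),
                        scores["chrom"].to_numpy(), -s))
    marked = np.zeros(n, dtype=bool)
    marked[order[:k]] = True
    counters["marked"] = int(k)

    # non-overlapping blocks of window_highd consecutive variants / chrom
    chroms = scores["chrom"].to_numpy()
    window_id = np.empty(n, dtype=np.int64)
    wid = 0
    start = 0
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            length = i - start
            nwin = math.ceil(length / cfg.window_highd)
            off = np.arange(length) // cfg.window_highd
            window_id[start:i] = wid + off
            wid += nwin
            start = i

    keep_idx = []
    for w in range(wid):
        in_w = np.flatnonzero((window_id == w) & marked)
        if in_w.size == 0:
            continue
        best = in_w[np.argmax(s[in_w])]  # argmax keeps first (genomic) tie
        if s[best] > thresh:
            keep_idx.append(best)
    keep_idx = np.array(sorted(keep_idx), dtype=np.int64)
    retained = scores.iloc[keep_idx].reset_index(drop=True).copy()
    retained["window"] = window_id[keep_idx] if keep_idx.size else []
    counters.update(windows=int(wid), retained=int(keep_idx.size))
    return ScanResult(retained, counters, asdict(cfg), pair, level)


# ---------------------------------------------------------------------------
# LowD scan
# ---------------------------------------------------------------------------

def lowd_scan(cv_scores: pd.DataFrame, cfg: ScanConfig) -> ScanResult:
    """Windowed minimum-cvDAF scan for unusually low differentiation.

    ``cv_scores`` is the output of :func:`popdiff.cv_daf` (needs columns
    ``cv`` and ``pooled_daf``).  Sites are first restricted to the closed
    pooled-DAF band excluding the open interval around 0.5 (rare sites are
    trivially undifferentiated; DAF≈0.5 everywhere flags paralog
    miscalls); the minimum-cvDAF site of each 100-variant window of the
    survivors is retained iff its cvDAF is below the threshold.
    """
    counters = {"input": len(cv_scores)}
    if len(cv_scores) == 0:
        return ScanResult(cv_scores.copy(), counters, asdict(cfg))
    _check_sorted(cv_scores)
    p = cv_scores["pooled_daf"].to_numpy()
    cv = cv_scores["cv"].to_numpy()
    lo, hi = cfg.daf_band
    elo, ehi = cfg.daf_exclusion
    in_band = (p >= lo) & (p <= hi)
    excluded = (p > elo) & (p < ehi)
    ok = in_band & ~excluded & ~np.isnan(cv)
    counters.update(outside_band=int((~in_band).sum()),
                    in_exclusion=int((in_band & excluded).sum()),
                    undefined_cv=int((in_band & ~excluded & np.isnan(cv)).sum()))
    surv = cv_scores.loc[ok].reset_index(drop=True)
    if len(surv) == 0:
        out = surv.copy()
        out["window"] = []
        counters["retained"] = 0
        return ScanResult(out, counters, asdict(cfg))

    chroms = surv["chrom"].to_numpy()
    cvs = surv["cv"].to_numpy()
    n = len(surv)
    window_id = np.empty(n, dtype=np.int64)
    wid = 0
    start = 0
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            length = i - start
            off = np.arange(length) // cfg.window_lowd
            window_id[start:i] = wid + off
            wid += math.ceil(length / cfg.window_lowd)
            start = i
    keep_idx = []
    for w in range(wid):
        in_w = np.flatnonzero(window_id == w)
        best = in_w[np.argmin(cvs[in_w])]
        if cvs[best] < cfg.cv_thresh:
            keep_idx.append(best)
    keep_idx = np.array(sorted(keep_idx), dtype=np.int64)
    retained = surv.iloc[keep_idx].reset_index(drop=True).copy()
    retained["window"] = window_id[keep_idx] if keep_idx.size else []
    counters.update(windows=int(wid), retained=int(keep_idx.size))
    return ScanResult(retained, counters, asdict(cfg))


# ---------------------------------------------------------------------------
# union / controls
# ---------------------------------------------------------------------------

def dedup_union(results) -> pd.DataFrame:
    """Union of retained sites across scans, keyed by (chrom,pos,ref,alt).

    Each unique site keeps the list of contributing pair labels and its
    best (maximum) score.
    """
    frames = []
    for r in results:
        df = r.retained if isinstance(r, ScanResult) else r
        if len(df):
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt",
                                     "score", "pairs"])
    allsites = pd.concat(frames, ignore_index=True)
    if "pair" not in allsites.columns:
        allsites["pair"] = ""

    def _agg(g):
        best = g.loc[g["score"].idxmax()] if "score" in g else g.iloc[0]
        row = best.copy()
        row["pairs"] = ",".join(sorted(set(g["pair"].astype(str))))
        return row

    out = (allsites.groupby(["chrom", "pos", "ref", "alt"], sort=True)
           .apply(_agg, include_groups=False).reset_index())
    return out


DIST_BIN_EDGES = (0.0, 1e3, 1e4, 1e5)
DIST_BIN_LABELS = ("genic", "0-1kb", "1-10kb", "10-100kb", ">100kb")


def distance_bin(dist) -> np.ndarray:
    """Bin distance-to-nearest-gene-start: genic(0), (0,1kb], (1,10kb],
    (10,100kb], >100kb."""
    dist = np.asarray(dist, dtype=float)
    out = np.full(dist.shape, DIST_BIN_LABELS[-1], dtype=object)
    out[dist <= 1e5] = DIST_BIN_LABELS[3]
    out[dist <= 1e4] = DIST_BIN_LABELS[2]
    out[dist <= 1e3] = DIST_BIN_LABELS[1]
    out[dist <= 0] = DIST_BIN_LABELS[0]
    return out


def matched_controls(targets: pd.DataFrame, universe: pd.DataFrame,
                     n_per_target: int = 1, seed: int = 0,
                     daf_tol: float = 0.02, max_tol: float = 0.05,
                     tol_step: float = 0.01) -> tuple[pd.DataFrame, list]:
    """Sample control sites matched on DAF and distance-to-gene-start bin.

    ``targets`` rows need ``pop`` (the assigned population), ``daf`` (DAF
    in that population) and ``dist_gene_start``; ``universe`` needs
    ``dist_gene_start`` plus per-population columns ``daf_<POP>``.
    Matching uses the assigned population's DAF within ±``daf_tol``
    (relaxed stepwise to ±``max_tol``) and the same distance bin; draws
    are without replacement, never reusing a control across targets.
    Returns (controls, unmatched_target_indices).
    """
    rng = np.random.default_rng(seed)
    u_bins = distance_bin(universe["dist_gene_start"].to_numpy())
    used = np.zeros(len(universe), dtype=bool)
    rows = []
    unmatched = []
    for ti, t in targets.reset_index(drop=True).iterrows():
        col = f"daf_{t['pop']}"
        if col not in universe.columns:
            raise KeyError(f"universe lacks column {col!r}")
        udaf = universe[col].to_numpy()
        tbin = distance_bin([t["dist_gene_start"]])[0]
        tol = daf_tol
        chosen = None
        while tol <= max_tol + 1e-12:
            cand = np.flatnonzero((u_bins == tbin) & ~used
                                  & (np.abs(udaf - t["daf"]) <= tol + 1e-12))
            if cand.size >= n_per_target:
                chosen = rng.choice(cand, size=n_per_target, replace=False)
                break
            tol += tol_step
        if chosen is None:
            unmatched.append(ti)
            logger.warning("no matched control for target %d "
                           "(pop=%s daf=%.3f bin=%s)", ti, t["pop"],
                           t["daf"], tbin)
            continue
        used[chosen] = True
        sub = universe.iloc[chosen].copy()
        sub["target_index"] = ti
        rows.append(sub)
    controls = (pd.concat(rows, ignore_index=True) if rows
                else universe.iloc[:0].copy())
    return controls, unmatched
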