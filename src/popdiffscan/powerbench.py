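"""Sensitivity / power analysis of the differentiation statistics.

The design: simulate neutral replicates and sweep replicates under the
same demographic model; derive, per statistic, the detection threshold
as the 95th percentile of the neutral score distribution (a 5% false
discovery rate); report the fraction of sweep replicates whose selected
variant scores above the threshold, per final-allele-frequency class and
overall.

Neutral thresholds can be taken from the pooled per-site neutral score
distribution (default — the reading under which partial sweeps remain
detectable) or from per-replicate regional maxima (a stricter,
region-wise criterion, available as ``threshold_mode="replicate_max"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import haplostats, popdiff, sweepclass
from .scan import ScanConfig, highd_scan
from .simgen import DemographicModel, SweepScenario, simulate_neutral, \
    simulate_sweep

logger = logging.getLogger("popdiffscan")

DEFAULT_AF_CLASSES = (0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_DURATIONS = (200, 400, 600, 800, 1000, 1200)
STATS = ("ddaf", "fst", "xpehh", "ihs")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def neutral_threshold(neutral_scores, q: float = 0.95) -> float:
    """Empirical quantile (linear interpolation) of neutral scores."""
    scores = np.asarray(neutral_scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size < 100:
        raise ValueError(f"need at least 100 neutral scores, got {scores.size}")
    return float(np.quantile(scores, q, method="linear"))


def sensitivity(selected_scores, threshold: float,
                conf: float = 0.95) -> dict:
    """Fraction of selected-variant scores above the threshold, with an
    exact (Clopper–Pearson) binomial CI."""
    s = np.asarray(selected_scores, dtype=float)
    n = s.size
    if n == 0:
        raise ValueError("no selected-variant scores")
    k = int(np.sum(s > threshold))
    ci = sps.binomtest(k, n).proportion_ci(confidence_level=conf,
                                           method="exact")
    return {"n": n, "detected": k, "sensitivity": k / n,
            "ci_low": float(ci.low), "ci_high": float(ci.high)}


# ---------------------------------------------------------------------------
# replicate scoring
# ---------------------------------------------------------------------------

def _pair_scores(rep, freqs, pairs):
    """Per-site max |ΔDAF| and max F_ST over continent pairs."""
    n = freqs.n_sites
    dd = np.zeros(n)
    ff = np.full(n, -np.inf)
    for a, b in pairs:
        fa = freqs.daf[a].to_numpy()
        fb = freqs.daf[b].to_numpy()
        dd = np.maximum(dd, np.abs(fa - fb))
        fst = popdiff.fst_from_counts(freqs.derived[a], freqs.total[a],
                                      freqs.derived[b], freqs.total[b])
        ff = np.maximum(ff, np.where(np.isnan(fst), -np.inf, fst))
    ff[~np.isfinite(ff)] = np.nan
    return dd, ff


def _xpehh_max(rep, site_idx, pop_cols):
    best = None
    for a in pop_cols:
        for b in pop_cols:
            if a == b:
                continue
            r = haplostats.xpehh_raw(rep.gts, rep.genmap, site_idx,
                                     pop_cols[a], pop_cols[b])
            if r is not None and (best is None or r[0] > best):
                best = r[0]
    return best


def _ihs_at(rep, site_idx, cols):
    r = haplostats.ihs_raw(rep.gts, rep.genmap, site_idx, cols)
    return r  # (raw, freq, truncated) or None


@dataclass
class Benchmark:
    """Summaries of a simulated neutral + sweep batch."""

    model: DemographicModel
    region_bp: int
    n_per_pop: int
    seed: int
    neutral_sites: dict          # stat → pooled per-site scores
    neutral_max: dict            # stat → per-replicate maxima
    neutral_focal: dict          # stat → one random-site score / replicate
    neutral_ihs: list            # (raw, freq) at random neutral sites
    neutral_D: list              # (freq, D) at frequency-matched sites
    sweeps: pd.DataFrame         # one row per sweep replicate

    @property
    def n_neutral(self) -> int:
        return len(self.neutral_max["ddaf"])


def run_benchmark(model: DemographicModel = None, n_neutral: int = 500,
                  per_class=None, af_classes=DEFAULT_AF_CLASSES,
                  durations=DEFAULT_DURATIONS, region_bp: int = 100_000,
                  n_per_pop: int = 100, seed: int = 0,
                  scan_cfg: ScanConfig | None = None,
                  hap_stats: bool = True,
                  progress: bool = False) -> Benchmark:
    """Simulate and summarize the full neutral + sweep batch.

    ``per_class`` maps final-AF class → replicate count (int for all).
    Sweep replicates cycle through durations and selected populations.
    """
    model = model or DemographicModel()
    cfg = scan_cfg or ScanConfig()
    if per_class is None:
        per_class = {c: 50 for c in af_classes}
    elif isinstance(per_class, int):
        per_class = {c: per_class for c in af_classes}
    ss = np.random.SeedSequence(seed)
    n_sweep = sum(per_class.values())
    child = ss.spawn(n_neutral + n_sweep)

    def _seed(i):
        return int(child[i].generate_state(1)[0] % (2**31 - 1)) + 1

    pops = ("AFR", "EUR", "ASN")
    pairs = [("AFR", "EUR"), ("AFR", "ASN"), ("EUR", "ASN")]

    neutral_sites = {"ddaf": [], "fst": []}
    neutral_max = {"ddaf": [], "fst": [], "xpehh": []}
    neutral_focal = {"ddaf": [], "fst": [], "xpehh": []}
    neutral_ihs = []
    neutral_D = []

    for i in range(n_neutral):
        rep = simulate_neutral(model, region_bp, n_per_pop, _seed(i))
        rng = np.random.default_rng(_seed(i) + 7)
        freqs = popdiff.daf(rep.gts, rep.panel, level="continent")
        dd, ff = _pair_scores(rep, freqs, pairs)
        neutral_sites["ddaf"].append(dd.astype(np.float32))
        neutral_sites["fst"].append(
            np.nan_to_num(ff, nan=0.0).astype(np.float32))
        neutral_max["ddaf"].append(dd.max() if dd.size else 0.0)
        neutral_max["fst"].append(np.nanmax(ff) if ff.size else 0.0)
        site = int(rng.integers(0, rep.gts.n_sites))
        neutral_focal["ddaf"].append(dd[site])
        neutral_focal["fst"].append(np.nan_to_num(ff[site]))
        if hap_stats:
            cols = {p: rep.gts.haplotype_columns(
                rep.panel.samples_in(p)) for p in pops}
            x = _xpehh_max(rep, site, cols)
            neutral_focal["xpehh"].append(np.nan if x is None else x)
            neutral_max["xpehh"].append(np.nan if x is None else x)
            r = _ihs_at(rep, site, cols[pops[int(rng.integers(3))]])
            if r is not None:
                neutral_ihs.append((r[0], r[1]))
            # frequency-matched haplotype-homogeneity baseline
            pop = pops[int(rng.integers(3))]
            fpop = freqs.daf[pop].to_numpy()
            targetf = rng.uniform(0.4, 1.0)
            j = int(np.nanargmin(np.abs(fpop - targetf)))
            if np.isfinite(fpop[j]) and fpop[j] > 0:
                hs = sweepclass.extract_haplotypes(rep.gts, j, cols[pop])
                neutral_D.append((float(fpop[j]),
                                  sweepclass.weighted_levenshtein(hs)))
        if progress and (i + 1) % 50 == 0:
            logger.info("neutral %d/%d", i + 1, n_neutral)

    rows = []
    k = 0
    for target in per_class:
        for j in range(per_class[target]):
            idx = n_neutral + k
            dur = durations[(j + k) % len(durations)]
            pop = pops[k % len(pops)]
            scen = SweepScenario(target_af=target, duration=dur,
                                 population=pop)
            rep = simulate_sweep(model, scen, region_bp, n_per_pop,
                                 _seed(idx))
            k += 1
            row = {"target_af": target, "duration": dur, "population": pop,
                   "end_freq": rep.end_freq,
                   "realized": rep.realized.get(pop, np.nan),
                   "s": rep.s, "seed": rep.seed}
            if rep.focal_index is None:
                row.update(ddaf=np.nan, fst=np.nan, xpehh=np.nan,
                           ihs_raw=np.nan, ihs_freq=np.nan,
                           recovered=False, lev_D=np.nan, n_carriers=0,
                           focal_lost=True)
                rows.append(row)
                continue
            freqs = popdiff.daf(rep.gts, rep.panel, level="continent")
            dd, ff = _pair_scores(rep, freqs, pairs)
            fi = rep.focal_index
            row["ddaf"] = dd[fi]
            row["fst"] = np.nan_to_num(ff[fi])
            row["focal_lost"] = False
            # windowed-scan recovery (site or ≤50 kb neighbour retained)
            sc = popdiff.site_frame(rep.gts)
            sc["score"] = dd
            res = highd_scan(sc, cfg, level="between", pair="max")
            fpos = rep.gts.variants[fi].pos
            row["recovered"] = bool(
                len(res.retained)
                and (np.abs(res.retained["pos"].to_numpy() - fpos)
                     <= 50_000).any())
            cols = {p: rep.gts.haplotype_columns(
                rep.panel.samples_in(p)) for p in pops}
            if hap_stats:
                x = _xpehh_max(rep, fi, cols)
                row["xpehh"] = np.nan if x is None else x
                r = _ihs_at(rep, fi, cols[pop])
                row["ihs_raw"] = np.nan if r is None else r[0]
                row["ihs_freq"] = np.nan if r is None else r[1]
            hs = sweepclass.extract_haplotypes(rep.gts, fi, cols[pop])
            row["lev_D"] = sweepclass.weighted_levenshtein(hs)
            row["n_carriers"] = hs.n_carriers
            rows.append(row)
            if progress and k % 25 == 0:
                logger.info("sweep %d/%d", k, n_sweep)

    bench = Benchmark(
        model=model, region_bp=region_bp, n_per_pop=n_per_pop, seed=seed,
        neutral_sites={s: np.concatenate(v) if v else np.array([])
                       for s, v in neutral_sites.items()},
        neutral_max={s: np.asarray(v, dtype=float)
                     for s, v in neutral_max.items()},
        neutral_focal={s: np.asarray(v, dtype=float)
                       for s, v in neutral_focal.items()},
        neutral_ihs=neutral_ihs, neutral_D=neutral_D,
        sweeps=pd.DataFrame(rows))
    return bench


# ---------------------------------------------------------------------------
# power table
# ---------------------------------------------------------------------------

def _neutral_scores(bench: Benchmark, stat: str, threshold_mode: str):
    if stat == "ihs":
        neut = pd.DataFrame(bench.neutral_ihs, columns=["raw", "freq"])
        if len(neut) == 0:
            raise ValueError("no neutral iHS scores (hap_stats off?)")
        return np.abs(haplostats.standardize_scores(
            neut)["std_score"].to_numpy())
    if threshold_mode == "pooled":
        if stat in bench.neutral_sites and bench.neutral_sites[stat].size:
            return bench.neutral_sites[stat]
        return bench.neutral_focal[stat]
    if threshold_mode == "replicate_max":
        return bench.neutral_max[stat]
    raise ValueError("threshold_mode must be 'pooled' or 'replicate_max'")


def _sweep_scores(bench: Benchmark, sw: pd.DataFrame, stat: str):
    """Per-replicate selected-variant scores for one statistic."""
    if stat == "ihs":
        neut = pd.DataFrame(bench.neutral_ihs, columns=["raw", "freq"])
        ok = np.isfinite(sw["ihs_raw"].to_numpy())
        if not ok.any() or len(neut) == 0:
            return pd.Series(np.full(len(sw), np.nan), index=sw.index)
        z = haplostats.standardize_against(
            pd.DataFrame({"raw": sw.loc[ok, "ihs_raw"].to_numpy(),
                          "freq": sw.loc[ok, "ihs_freq"].to_numpy()}),
            neut)["std_score"].to_numpy()
        out = np.full(len(sw), np.nan)
        out[ok] = np.abs(z)
        return pd.Series(out, index=sw.index)
    return sw[stat]


def power_table(bench: Benchmark, statistics=("ddaf", "fst"),
                threshold_mode: str = "pooled", q: float = 0.95,
                balanced_overall: bool = True) -> pd.DataFrame:
    """Sensitivity per statistic × final-AF class, plus 'overall' and a
    neutral calibration row."""
    rows = []
    sw = bench.sweeps[~bench.sweeps["focal_lost"]]
    for stat in statistics:
        scores = _neutral_scores(bench, stat, threshold_mode)
        scores = scores[np.isfinite(scores)]
        thr = neutral_threshold(scores, q)
        classes = sorted(sw["target_af"].unique())
        per_class_scores = {}
        all_scores = _sweep_scores(bench, sw, stat)
        for c in classes:
            s = all_scores[sw["target_af"] == c].to_numpy()
            s = s[np.isfinite(s)]
            if s.size == 0:
                logger.warning("class %s has no usable replicates", c)
                continue
            per_class_scores[c] = s
            rows.append({"statistic": stat, "scenario": c,
                         "threshold": thr,
                         **sensitivity(s, thr)})
        if per_class_scores:
            if balanced_overall:
                nmin = min(s.size for s in per_class_scores.values())
                overall = np.concatenate(
                    [s[:nmin] for s in per_class_scores.values()])
            else:
                overall = np.concatenate(list(per_class_scores.values()))
            rows.append({"statistic": stat, "scenario": "overall",
                         "threshold": thr, **sensitivity(overall, thr)})
        # calibration: a random neutral site plays the selected variant
        neutral_focal = (scores if stat == "ihs"
                         else bench.neutral_focal[stat])
        neutral_focal = neutral_focal[np.isfinite(neutral_focal)]
        if neutral_focal.size:
            rows.append({"statistic": stat, "scenario": "neutral",
                         "threshold": thr,
                         **sensitivity(neutral_focal, thr)})
    return pd.DataFrame(rows)


def levenshtein_class_means(bench: Benchmark,
                            bands=((0.8, 1.0), (0.4, 0.6))) -> dict:
    """Mean 2-kb haplotype-homogeneity D per final-allele-frequency band.

    Replicates are grouped by the frequency the sweep was driven to (the
    scenario class; the realized end-of-sweep frequency is conditioned
    within ±0.05 of it)."""
    sw = bench.sweeps[~bench.sweeps["focal_lost"]]
    out = {}
    for lo, hi in bands:
        m = (sw["target_af"] >= lo) & (sw["target_af"] <= hi)
        d = sw.loc[m, "lev_D"].to_numpy()
        d = d[np.isfinite(d)]
        out[(lo, hi)] = {"mean_D": float(d.mean()) if d.size else np.nan,
                         "n": int(d.size)}
    return out
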