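"""Phased genotype data model and I/O.

Reads a phased multi-sample VCF with an ancestral-allele annotation
(INFO/AA), a sample→population→continent panel, and a recombination map,
and exposes genotypes polarized to ancestral/derived coding: each haplotype
carries 0 for the ancestral allele and 1 for the derived allele.  All
downstream statistics (DAF, ΔDAF, cvDAF, haplotype homozygosity) operate on
this representation.

Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted on read.  Sites are kept sorted by (chrom, pos, alt).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("popdiffscan")

SNP = "SNP"
INDEL = "INDEL"
SV = "SV"

_MISSING = -1  # missing allele code in genotype matrices


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant.

    ``ancestral`` is the inferred ancestral allele (must equal ``ref`` or
    ``alt`` for the site to be polarizable); ``impq`` is an optional
    genotype-imputation quality in [0, 1].
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vclass: str = SNP
    ancestral: str | None = None
    impq: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def polarizable(self) -> bool:
        return self.ancestral in (self.ref, self.alt)


def classify_alleles(ref: str, alt: str) -> str:
    """SNP iff both alleles are single bases; symbolic ALT is an SV."""
    if alt.startswith("<") or len(ref) >= 50 or len(alt) >= 50:
        return SV
    if len(ref) == 1 and len(alt) == 1:
        return SNP
    return INDEL


class PopulationPanel:
    """Mapping sample → (population, continent)."""

    def __init__(self, assignments: dict[str, tuple[str, str]]):
        self._map = dict(assignments)
        pop2cont: dict[str, str] = {}
        for s, (pop, cont) in self._map.items():
            if pop in pop2cont and pop2cont[pop] != cont:
                raise ValueError(
                    f"population {pop!r} assigned to two continents "
                    f"({pop2cont[pop]!r} and {cont!r})"
                )
            pop2cont[pop] = cont
        self._pop2cont = pop2cont

    def __len__(self):
        return len(self._map)

    def __contains__(self, sample):
        return sample in self._map

    @property
    def samples(self) -> list[str]:
        return list(self._map)

    def population_of(self, sample: str) -> str:
        return self._map[sample][0]

    def continent_of(self, sample: str) -> str:
        return self._map[sample][1]

    def populations(self) -> list[str]:
        return sorted(self._pop2cont)

    def continents(self) -> list[str]:
        return sorted(set(self._pop2cont.values()))

    def continent_of_population(self, pop: str) -> str:
        return self._pop2cont[pop]

    def populations_in(self, continent: str) -> list[str]:
        return sorted(p for p, c in self._pop2cont.items() if c == continent)

    def samples_in(self, group: str, level: str = "population") -> list[str]:
        if level == "population":
            return [s for s, (p, _) in self._map.items() if p == group]
        if level == "continent":
            return [s for s, (_, c) in self._map.items() if c == group]
        raise ValueError(f"unknown level {level!r}")

    def group_of(self, sample: str, level: str) -> str:
        if level == "population":
            return self.population_of(sample)
        if level == "continent":
            return self.continent_of(sample)
        raise ValueError(f"unknown level {level!r}")

    def subset(self, samples) -> "PopulationPanel":
        return PopulationPanel({s: self._map[s] for s in samples if s in self._map})


@dataclass
class RawCalls:
    """Parsed VCF records before polarization.

    ``A`` is an (n_sites, n_haplotypes) int8 matrix coded 0=ref allele,
    1=alt allele, -1=missing; haplotypes of sample *i* occupy columns 2i and
    2i+1.
    """

    variants: list[VariantRecord]
    A: np.ndarray
    samples: list[str]
    phased: bool = True
    skipped_multiallelic: int = 0

    @property
    def n_sites(self):
        return len(self.variants)


class PolarizedGenotypes:
    """Variant × haplotype matrix coded ancestral(0)/derived(1).

    Rows are sorted by (chrom, pos, alt); haplotype count is twice the
    sample count.  Missing alleles are coded -1 and excluded from frequency
    denominators.
    """

    def __init__(self, variants, H, samples, phased=True, drop_counts=None):
        H = np.asarray(H, dtype=np.int8)
        if H.shape != (len(variants), 2 * len(samples)):
            raise ValueError(
                f"H shape {H.shape} does not match {len(variants)} sites × "
                f"{2 * len(samples)} haplotypes"
            )
        order = sorted(range(len(variants)),
                       key=lambda i: (variants[i].chrom, variants[i].pos,
                                      variants[i].alt))
        self.variants = [variants[i] for i in order]
        self.H = H[order]
        self.samples = list(samples)
        self.phased = phased
        self.drop_counts = dict(drop_counts or {})

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def monomorphic_mask(self) -> np.ndarray:
        """True where no site shows both an ancestral and a derived allele."""
        der = (self.H == 1).sum(axis=1)
        anc = (self.H == 0).sum(axis=1)
        return (der == 0) | (anc == 0)

    def haplotype_columns(self, samples) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        cols = []
        for s in samples:
            i = idx[s]
            cols.extend((2 * i, 2 * i + 1))
        return np.array(cols, dtype=np.intp)

    def subset_sites(self, site_idx) -> "PolarizedGenotypes":
        site_idx = np.asarray(site_idx)
        return PolarizedGenotypes(
            [self.variants[i] for i in site_idx], self.H[site_idx],
            self.samples, self.phased, self.drop_counts)

    def subset_samples(self, samples) -> "PolarizedGenotypes":
        cols = self.haplotype_columns(samples)
        return PolarizedGenotypes(self.variants, self.H[:, cols],
                                  list(samples), self.phased, self.drop_counts)

    def site_index(self) -> dict[tuple, int]:
        return {v.key: i for i, v in enumerate(self.variants)}

    # -- output ------------------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write the data back out as a minimal phased VCF 4.1 file."""
        op = gzip.open if str(path).endswith(".gz") else open
        with op(path, "wt") as fh:
            fh.write("##fileformat=VCFv4.1\n")
            fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                     'Description="Ancestral allele">\n')
            fh.write('##INFO=<ID=RSQ,Number=1,Type=Float,'
                     'Description="Imputation quality">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            for chrom in dict.fromkeys(v.chrom for v in self.variants):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            sep = "|" if self.phased else "/"
            for i, v in enumerate(self.variants):
                row = self.H[i]
                # map derived coding back to ref/alt allele indices
                flip = v.ancestral == v.alt
                info = f"AA={v.ancestral}" if v.ancestral else "AA=."
                if v.impq is not None:
                    info += f";RSQ={v.impq:g}"
                gts = []
                for j in range(0, row.size, 2):
                    a, b = row[j], row[j + 1]
                    def code(x):
                        if x < 0:
                            return "."
                        return str(1 - x if flip else x)
                    gts.append(code(a) + sep + code(b))
                fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                         f"{info}\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _normalize_aa(raw) -> str | None:
    if raw is None:
        return None
    if isinstance(raw, bytes):
        raw = raw.decode()
    aa = str(raw).split("|")[0].strip().upper()
    if aa in ("", ".", "-", "N"):
        return None
    return aa


def read_vcf(path, region=None, multiallelic="skip", impq_key="RSQ",
             require_phased=True) -> RawCalls:
    """Read biallelic records and phased genotypes from a VCF.

    Parameters
    ----------
    region : str, optional
        ``chrom`` or ``chrom:start-end`` filter (1-based inclusive).
    multiallelic : {"skip", "split"}
        Skip multiallelic records (default) or split them into one
        biallelic record per alternate allele at the same position.
    impq_key : str
        INFO (or per-sample FORMAT) key holding imputation quality.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("skip", "split"):
        raise ValueError("multiallelic must be 'skip' or 'split'")
    rchrom = rstart = rend = None
    if region:
        if ":" in region:
            rchrom, span = region.split(":", 1)
            a, b = span.split("-")
            rstart, rend = int(a), int(b)
        else:
            rchrom = region

    try:
        vcf = VCF(str(path))
    except OSError as exc:  # pragma: no cover - cyvcf2 error text varies
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    skipped_multi = 0
    phased_all = True

    for rec in vcf:
        if rchrom is not None and rec.CHROM != rchrom:
            continue
        if rstart is not None and not (rstart <= rec.POS <= rend):
            continue
        alts = [a for a in rec.ALT if a not in (".", "")]
        if len(alts) == 0:
            continue
        if len(alts) > 1 and multiallelic == "skip":
            skipped_multi += 1
            continue
        gts = rec.genotypes  # list of [a0, a1, phased]
        impq = None
        try:
            impq = rec.INFO.get(impq_key)
        except KeyError:
            impq = None
        if impq is None:
            try:
                arr = rec.format(impq_key)
                if arr is not None:
                    arr = np.asarray(arr, dtype=float)
                    if np.isfinite(arr).any():
                        impq = float(np.nanmean(arr))
            except (KeyError, ValueError, TypeError):
                impq = None
        aa = _normalize_aa(rec.INFO.get("AA"))
        for k, alt in enumerate(alts, start=1):
            a = np.full(2 * len(samples), _MISSING, dtype=np.int8)
            for j, g in enumerate(gts):
                a0, a1, ph = g[0], g[1], g[-1]
                if require_phased and not ph and a0 != a1 and a0 >= 0 and a1 >= 0:
                    raise ValueError(
                        f"unphased heterozygous genotype for sample "
                        f"{samples[j]} at {rec.CHROM}:{rec.POS}")
                if not g[-1]:
                    phased_all = False
                a[2 * j] = -1 if a0 < 0 else (1 if a0 == k else 0)
                a[2 * j + 1] = -1 if a1 < 0 else (1 if a1 == k else 0)
            variants.append(VariantRecord(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                vclass=classify_alleles(rec.REF, alt), ancestral=aa,
                impq=float(impq) if impq is not None else None))
            rows.append(a)

    A = (np.vstack(rows) if rows
         else np.empty((0, 2 * len(samples)), dtype=np.int8))
    return RawCalls(variants=variants, A=A, samples=samples,
                    phased=phased_all or not require_phased,
                    skipped_multiallelic=skipped_multi)


def polarize(raw: RawCalls, assume_ref_ancestral_for_sv=True) -> PolarizedGenotypes:
    """Recode alleles to ancestral(0)/derived(1) using the AA annotation.

    Sites whose ancestral allele is missing or matches neither allele are
    dropped and counted.  Symbolic/SV records without AA optionally assume
    the reference allele is ancestral (deletions are derived relative to the
    reference state); this assumption is logged.
    """
    keep_variants: list[VariantRecord] = []
    keep_rows: list[int] = []
    flip: list[bool] = []
    drops = {"missing_aa": 0, "aa_mismatch": 0}
    sv_assumed = 0
    for i, v in enumerate(raw.variants):
        anc = v.ancestral
        if anc is None and v.vclass == SV and assume_ref_ancestral_for_sv:
            anc = v.ref
            sv_assumed += 1
            v = VariantRecord(v.chrom, v.pos, v.ref, v.alt, v.vclass,
                              anc, v.impq)
        if anc is None:
            drops["missing_aa"] += 1
            continue
        if anc == v.ref:
            flip.append(False)
        elif anc == v.alt:
            flip.append(True)
        else:
            drops["aa_mismatch"] += 1
            continue
        if v.ancestral is None:
            v = VariantRecord(v.chrom, v.pos, v.ref, v.alt, v.vclass,
                              anc, v.impq)
        keep_variants.append(v)
        keep_rows.append(i)
    if not keep_variants:
        raise ValueError("no polarizable sites "
                         f"(dropped: {drops})")
    if sv_assumed:
        logger.warning(
            "assumed reference allele ancestral for %d SV records without AA",
            sv_assumed)
    H = raw.A[keep_rows].copy()
    flip = np.array(flip, dtype=bool)
    sub = H[flip]
    miss = sub == _MISSING
    sub = 1 - sub
    sub[miss] = _MISSING
    H[flip] = sub
    return PolarizedGenotypes(keep_variants, H, raw.samples,
                              phased=raw.phased, drop_counts=drops)


def _open_text(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return io.open(path, "rt")


def read_panel(path) -> PopulationPanel:
    """Read a sample/population/continent TSV (optional header)."""
    assignments: dict[str, tuple[str, str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            sample, pop, cont = parts[0], parts[1], parts[2]
            if lineno == 1 and sample.lower() in ("sample", "sample_id", "id"):
                continue
            if sample in assignments and assignments[sample] != (pop, cont):
                raise ValueError(
                    f"{path}:{lineno}: sample {sample!r} listed twice with "
                    f"conflicting assignment")
            assignments[sample] = (pop, cont)
    return PopulationPanel(assignments)


def match_panel_to_vcf(panel: PopulationPanel, samples) -> PopulationPanel:
    """Restrict a panel to the samples present in a VCF, with a warning."""
    usable = [s for s in samples if s in panel]
    missing = len(panel) - len(usable)
    if missing:
        logger.warning("%d panel samples absent from the VCF were ignored",
                       missing)
    return panel.subset(usable)


class GeneticMap:
    """Piecewise-linear genetic map: bp → cM, with local cM/Mb rates."""

    def __init__(self, pos_bp, cm):
        pos_bp = np.asarray(pos_bp, dtype=np.int64)
        cm = np.asarray(cm, dtype=float)
        if pos_bp.size < 2:
            raise ValueError("genetic map needs at least two points")
        if np.any(np.diff(pos_bp) <= 0):
            raise ValueError("map positions must be strictly increasing")
        d = np.diff(cm)
        if np.any(d < 0):
            i = int(np.argmax(d < 0))
            raise ValueError(
                f"non-monotone cumulative cM at map point {i + 2}")
        self.pos = pos_bp
        self.cm = cm

    @classmethod
    def uniform(cls, rate_cm_per_mb, length_bp, start_bp=0):
        end = start_bp + length_bp
        return cls([start_bp, end],
                   [0.0, rate_cm_per_mb * length_bp / 1e6])

    @classmethod
    def from_file(cls, path):
        """Read a HapMap-style map: [chrom] pos rate(cM/Mb) cM."""
        pos, cm = [], []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                try:
                    vals = [float(x) for x in parts[-3:]]
                except ValueError:
                    if lineno == 1:
                        continue  # header
                    raise ValueError(f"{path}:{lineno}: unparsable map line")
                pos.append(int(vals[0]))
                cm.append(vals[2])
        try:
            return cls(pos, cm)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc

    def cm_at(self, pos_bp):
        return np.interp(pos_bp, self.pos, self.cm)

    def rate_at(self, pos_bp):
        """Local recombination rate in cM/Mb (segment rate)."""
        pos_bp = np.asarray(pos_bp)
        idx = np.clip(np.searchsorted(self.pos, pos_bp, side="right") - 1,
                      0, self.pos.size - 2)
        seg_bp = np.diff(self.pos)[idx]
        seg_cm = np.diff(self.cm)[idx]
        return seg_cm / (seg_bp / 1e6)

    def mean_rate(self, start_bp, end_bp):
        """Average rate (cM/Mb) over [start, end]."""
        if end_bp <= start_bp:
            raise ValueError("end must exceed start")
        dcm = self.cm_at(end_bp) - self.cm_at(start_bp)
        return float(dcm / ((end_bp - start_bp) / 1e6))


def read_recomb_map(path) -> GeneticMap:
    return GeneticMap.from_file(path)
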