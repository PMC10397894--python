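"""VCF variants: region loading, window intersection, MAF stratification.

The screen works on biallelic PASS SNPs with diploid genotypes. Genotypes are
held as a variants x samples matrix of alt-allele dosages (0/1/2, -1 for
missing) next to a sample-metadata frame (id, population, sex), which is all
that allele-frequency and diversity computations need — no phasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .splice_sites import (
    EXONIC_NT,
    INTRONIC_NT,
    TRACT_NT,
    SpliceSite,
)

logger = logging.getLogger(__name__)

MISSING = -1

#: transcript-orientation window offsets of the invariant dinucleotides
DONOR_GT_OFFSETS = (EXONIC_NT, EXONIC_NT + 1)          # 6, 7
ACCEPTOR_AG_OFFSETS = (TRACT_NT + 2, TRACT_NT + 3)     # 14, 15
ACCEPTOR_Y_OFFSET = TRACT_NT + 1                       # 13


class VariantError(ValueError):
    """Raised for malformed variant input."""


@dataclass(frozen=True)
class Variant:
    """One biallelic SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise VariantError(f"not a SNP: {self.ref}>{self.alt} at {self.pos}")
        if self.ref == self.alt:
            raise VariantError(f"ref == alt at {self.pos}")
        if not self.id:
            # study naming convention: "rs" + genomic position
            object.__setattr__(self, "id", f"rs{self.pos}")


@dataclass
class GenotypeTable:
    """Variants x samples alt-dosage matrix plus sample metadata.

    ``dosage[v, s]`` is the number of alt alleles (0, 1, 2) of sample ``s``
    at variant ``v``, or -1 for a missing call. ``samples`` must carry
    columns ``sample_id``, ``population``, ``sex``.
    """

    variants: list[Variant]
    samples: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise VariantError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        required = {"sample_id", "population", "sex"}
        missing_cols = required - set(self.samples.columns)
        if missing_cols:
            raise VariantError(f"metadata missing columns: {sorted(missing_cols)}")
        if self.samples["sample_id"].duplicated().any():
            raise VariantError("duplicate sample ids in metadata")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def sample_mask(self, population: str | None = None, sex: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if population is not None:
            mask &= (self.samples["population"] == population).to_numpy()
        if sex is not None:
            mask &= (self.samples["sex"] == sex).to_numpy()
        return mask


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample_id, country|population, site,
    year, sex (site/year optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "population" not in df.columns and "country" in df.columns:
        df = df.rename(columns={"country": "population"})
    for col in ("sample_id", "population", "sex"):
        if col not in df.columns:
            raise VariantError(f"metadata lacks required column {col!r}")
        if df[col].isna().any() or (df[col].str.strip() == "").any():
            raise VariantError(f"metadata column {col!r} has empty values")
    if df["sample_id"].duplicated().any():
        raise VariantError("duplicate sample ids in metadata")
    return df


def load_region_snps(
    vcf_path: str | Path,
    span: GenomicInterval,
    metadata: pd.DataFrame,
) -> GenotypeTable:
    """Load biallelic PASS SNPs with genotypes from ``vcf_path`` within ``span``.

    Records failing any filter (non-PASS, multiallelic, indel, outside span)
    are dropped; counts are logged. VCF samples must all be present in the
    metadata (and vice versa), in any order — genotype columns are aligned to
    the metadata row order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    if not vcf_samples:
        raise VariantError(f"{vcf_path}: no genotype (GT) columns")
    meta_ids = list(metadata["sample_id"])
    unmatched = sorted(set(vcf_samples) ^ set(meta_ids))
    if unmatched:
        raise VariantError(f"VCF/metadata sample mismatch: {unmatched}")
    order = [vcf_samples.index(s) for s in meta_ids]

    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_dropped = {"filter": 0, "multiallelic": 0, "not_snp": 0, "outside": 0}
    for rec in vcf:
        if rec.CHROM != span.chrom or not span.contains(rec.POS):
            n_dropped["outside"] += 1
            continue
        if rec.FILTER is not None:  # cyvcf2: None means PASS/'.'
            n_dropped["filter"] += 1
            continue
        if len(rec.ALT) != 1:
            n_dropped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_dropped["not_snp"] += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else ""
        variants.append(Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], id=vid))
        # gts012: 0=hom-ref 1=het 2=hom-alt 3=unknown
        gt = rec.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt[order])
    vcf.close()
    logger.info(
        "loaded %d SNPs in %s:[%d,%d]; dropped %s",
        len(variants), span.chrom, span.low, span.high, n_dropped,
    )
    dosage = (
        np.vstack(rows) if rows else np.empty((0, len(meta_ids)), dtype=np.int8)
    )
    idx = np.argsort([v.pos for v in variants], kind="stable")
    variants = [variants[i] for i in idx]
    dosage = dosage[idx]
    return GenotypeTable(variants=variants, samples=metadata.reset_index(drop=True), dosage=dosage)


# ---------------------------------------------------------------------------
# window intersection and hit classification


@dataclass
class SpliceHit:
    """One variant falling inside one splice-site window."""

    variant: Variant
    site: SpliceSite
    offset: int  # transcript-orientation offset in the 22-nt window
    tier: str    # dinucleotide | NYag_Y | window
    variant_index: int = -1  # row in the originating GenotypeTable


def classify_tier(kind: str, offset: int) -> str:
    """Positional criticality of a window offset.

    ``dinucleotide`` = the invariant gt (donor) / ag (acceptor);
    ``NYag_Y`` = the acceptor pyrimidine position; ``window`` = anything else
    (including the NYag N position and all exonic bases).
    """
    if kind == "donor" and offset in DONOR_GT_OFFSETS:
        return "dinucleotide"
    if kind == "acceptor":
        if offset in ACCEPTOR_AG_OFFSETS:
            return "dinucleotide"
        if offset == ACCEPTOR_Y_OFFSET:
            return "NYag_Y"
    return "window"


def intersect_windows(
    variants: Sequence[Variant], sites: Sequence[SpliceSite]
) -> list[SpliceHit]:
    """All (variant, site) pairs with the variant inside the site window.

    Window edges are inclusive on both sides; a variant in two overlapping
    windows yields two hits.
    """
    hits: list[SpliceHit] = []
    for vidx, v in enumerate(variants):
        for site in sites:
            w = site.window
            if v.chrom == w.chrom and w.contains(v.pos):
                offset = w.offset_of(v.pos)
                hits.append(
                    SpliceHit(
                        variant=v, site=site, offset=offset,
                        tier=classify_tier(site.key.kind, offset),
                        variant_index=vidx,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# stratified frequencies and sex specificity


@dataclass
class StratumFrequency:
    """Allele counts and MAF for one (population, sex) cell."""

    population: str
    sex: str
    n_called: int       # non-missing diploid samples
    alt_count: int      # alt alleles among called samples
    alt_freq: float | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.n_called > 0:
            self.alt_freq = self.alt_count / (2 * self.n_called)
            self.maf = min(self.alt_freq, 1.0 - self.alt_freq)


def stratified_maf(
    table: GenotypeTable,
    variant_index: int,
    strata: tuple[str, ...] = ("population", "sex"),
) -> list[StratumFrequency]:
    """Per-stratum alt-allele frequency and MAF for one variant.

    Cells with no called genotypes are returned with ``maf=None`` (undefined,
    deliberately distinct from 0).
    """
    dose = table.dosage[variant_index]
    out: list[StratumFrequency] = []
    for keys, idx in table.samples.groupby(list(strata), sort=True).groups.items():
        if not isinstance(keys, tuple):
            keys = (keys,)
        cell = dose[np.asarray(idx)]
        called = cell[cell != MISSING]
        labels = dict(zip(strata, keys))
        out.append(
            StratumFrequency(
                population=labels.get("population", "all"),
                sex=labels.get("sex", "all"),
                n_called=int(called.size),
                alt_count=int(called.sum()),
            )
        )
    return out


@dataclass
class SexAssociation:
    """Descriptive sex presence plus a labelled exact association test.

    The presence flag is the screen's primary output; the Fisher test is an
    added descriptive statistic and never overrides the flag.
    """

    presence: str                 # female_only | male_only | both | absent
    odds_ratio: float | None = None
    p_value: float | None = None
    tested: bool = False


def sex_specificity(table: GenotypeTable, variant_index: int) -> SexAssociation:
    """Sex presence of the alt allele and a 2x2 exact test on allele counts.

    Presence is computed from non-missing alt-carrying samples per sex. The
    test is Fisher's exact (two-sided) on the (sex x allele) count table; it
    is skipped (``tested=False``) when a sex has no called samples.
    """
    dose = table.dosage[variant_index]
    sex = table.samples["sex"].to_numpy()
    present = {}
    counts = {}
    for s in ("F", "M"):
        cell = dose[sex == s]
        called = cell[cell != MISSING]
        present[s] = bool((called > 0).any())
        counts[s] = (int(called.sum()), int(2 * called.size - called.sum()))  # (alt, ref)
    if present["F"] and present["M"]:
        presence = "both"
    elif present["F"]:
        presence = "female_only"
    elif present["M"]:
        presence = "male_only"
    else:
        presence = "absent"
    n_called_f = sum(counts["F"]) // 2
    n_called_m = sum(counts["M"]) // 2
    if n_called_f == 0 or n_called_m == 0:
        return SexAssociation(presence=presence, tested=False)
    table22 = [[counts["F"][0], counts["F"][1]], [counts["M"][0], counts["M"][1]]]
    odds, p = stats.fisher_exact(table22, alternative="two-sided")
    return SexAssociation(presence=presence, odds_ratio=float(odds), p_value=float(p), tested=True)


# ---------------------------------------------------------------------------
# splice relevance rule


@dataclass
class RelevanceRule:
    """Operational definition of a 'splice-relevant' hit.

    A hit is relevant when it strikes an invariant position (the gt/ag
    dinucleotide or the NYag Y), or when an ordinary window position carries
    a sex-specific allele at appreciable frequency (max per-stratum MAF >=
    ``maf_threshold``).
    """

    maf_threshold: float = 0.05
    critical_tiers: tuple[str, ...] = ("dinucleotide", "NYag_Y")


def splice_relevance(
    hit: SpliceHit,
    association: SexAssociation,
    strata: Sequence[StratumFrequency],
    rule: RelevanceRule | None = None,
) -> tuple[bool, str]:
    """Apply the relevance rule; returns (relevant, reason)."""
    rule = rule or RelevanceRule()
    if hit.tier in rule.critical_tiers:
        return True, f"tier={hit.tier}"
    max_maf = max((s.maf for s in strata if s.maf is not None), default=0.0)
    sex_specific = association.presence in ("female_only", "male_only")
    if sex_specific and max_maf >= rule.maf_threshold:
        return True, f"sex_specific({association.presence}), max MAF {max_maf:.4g}"
    return False, (
        f"tier=window, presence={association.presence}, "
        f"max MAF {max_maf:.4g} (threshold {rule.maf_threshold})"
    )


# ---------------------------------------------------------------------------
# reports


def hit_report(
    table: GenotypeTable,
    hits: Sequence[SpliceHit],
    rule: RelevanceRule | None = None,
) -> pd.DataFrame:
    """One row per hit: position, window identity, tier, sex presence,
    association test, MAF summary and the relevance verdict."""
    rule = rule or RelevanceRule()
    rows = []
    for hit in hits:
        vidx = hit.variant_index
        assoc = sex_specificity(table, vidx)
        strata = stratified_maf(table, vidx)
        relevant, reason = splice_relevance(hit, assoc, strata, rule)
        defined = [s.maf for s in strata if s.maf is not None]
        rows.append(
            {
                "variant_id": hit.variant.id,
                "chrom": hit.variant.chrom,
                "pos": hit.variant.pos,
                "ref": hit.variant.ref,
                "alt": hit.variant.alt,
                "site_kind": hit.site.key.kind,
                "site_boundary": hit.site.key.boundary,
                "site_sharing": hit.site.sharing.label if hit.site.sharing else "",
                "window_low": hit.site.window.low,
                "window_high": hit.site.window.high,
                "offset": hit.offset,
                "tier": hit.tier,
                "sex_presence": assoc.presence,
                "fisher_odds_ratio": assoc.odds_ratio,
                "fisher_p": assoc.p_value,
                "max_stratum_maf": max(defined, default=np.nan),
                "splice_relevant": relevant,
                "relevance_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def maf_matrix(table: GenotypeTable, variant_indices: Iterable[int] | None = None) -> pd.DataFrame:
    """Long-format per-stratum frequency table for the chosen variants."""
    if variant_indices is None:
        variant_indices = range(table.n_variants)
    rows = []
    for vidx in variant_indices:
        v = table.variants[vidx]
        for s in stratified_maf(table, vidx):
            carriers = None
            mask = table.sample_mask(s.population, s.sex)
            cell = table.dosage[vidx][mask]
            called = cell[cell != MISSING]
            if called.size:
                carriers = float((called > 0).mean())
            rows.append(
                {
                    "variant_id": v.id,
                    "pos": v.pos,
                    "population": s.population,
                    "sex": s.sex,
                    "n_called": s.n_called,
                    "alt_count": s.alt_count,
                    "alt_freq": s.alt_freq,
                    "maf": s.maf,
                    # carrier fraction (samples with >=1 alt) reported alongside
                    # the allele frequency; field descriptions sometimes mean
                    # either by "x% carried the variant"
                    "carrier_freq": carriers,
                }
            )
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path
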