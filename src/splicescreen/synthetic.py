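"""Seeded synthetic fixtures: reference contig, cohort metadata, VCF.

The generator makes the whole pipeline runnable offline. Its defaults encode
the study conditions:

* a forward-strand contig (with an explicit coordinate origin) in which every
  published 22-nt splice-site sequence of the doublesex gene occupies its
  real genomic coordinates (reverse-complemented for forward storage), all
  other bases random;
* a cohort with the published country/sex structure (655 mosquitoes across
  eight populations, heavily female-biased sampling);
* a VCF of biallelic PASS SNPs: background variants at a density calibrated
  to the reported 17,196 polymorphic sites over the 84,797-bp locus, drawn
  panmictically from a neutral-like frequency spectrum, plus *planted*
  variants with chosen per-stratum allele frequencies at the nine reported
  splice-window positions. Genotypes are Hardy-Weinberg draws
  (Binomial(2, p) per sample) — no linkage or coalescent structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

try:
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

from .gene_model import load_packaged_gene
from .intervals import GenomicInterval
from .reference import ReferenceContig
from .variants import MISSING, GenotypeTable, Variant

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


#: Published cohort structure, aggregated to country level: (population, sex, n).
DEFAULT_COHORT: tuple[tuple[str, str, int], ...] = (
    ("Burkina Faso", "F", 67),
    ("Burkina Faso", "M", 25),
    ("Cameroon", "F", 253),
    ("Cameroon", "M", 44),
    ("Equatorial Guinea", "F", 9),
    ("Gabon", "F", 69),
    ("Ghana", "F", 12),
    ("Guinea", "F", 40),
    ("Mayotte", "F", 12),
    ("Mayotte", "M", 12),
    ("Uganda", "F", 112),
)

#: Planted splice-window variants: position -> per-stratum alt-allele
#: frequency ("population|sex" keys; "*" = every other stratum). The nine
#: positions are the reported in-window SNPs: seven in the shared intron 3
#: acceptor window, two in the female-specific exon 5 donor window. Exon-5
#: frequencies follow the reported statements (<1% in females, 2% of
#: Burkina Faso males); intron-3 frequencies are non-specific and variable.
DEFAULT_PLANTED: dict[int, dict[str, float]] = {
    48712947: {"Burkina Faso|F": 0.008, "Burkina Faso|M": 0.02, "Cameroon|F": 0.005},
    48712962: {"Cameroon|F": 0.005},
    48715291: {"*": 0.02},
    48715294: {"*": 0.05},
    48715302: {"*": 0.10},
    48715306: {"*": 0.03},
    48715307: {"*": 0.08},
    48715308: {"*": 0.015},
    48715309: {"*": 0.04},
}

#: Gene span 2R:48703664-48788460 is 84,797 bp; 17,196 polymorphic sites
#: were reported across it, giving the default background density.
GENE_SPAN = (48703664, 48788460)
DEFAULT_DENSITY = 17196 / (GENE_SPAN[1] - GENE_SPAN[0] + 1)
CONTIG_MARGIN = 300


@dataclass
class SimulationConfig:
    """Everything a deterministic fixture build needs."""

    seed: int = 0
    contig_name: str = "2R"
    contig_low: int = GENE_SPAN[0] - CONTIG_MARGIN
    contig_high: int = GENE_SPAN[1] + CONTIG_MARGIN
    offset: int = 0  # uniform coordinate shift (negative for compact contigs)
    cohort: tuple[tuple[str, str, int], ...] = DEFAULT_COHORT
    density: float = DEFAULT_DENSITY  # background SNPs per bp
    planted: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PLANTED.items()}
    )
    missingness: float = 0.0
    exclude_windows_from_background: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.missingness <= 1:
            raise SimulationError("missingness must be in [0, 1]")
        if self.density < 0:
            raise SimulationError("density must be >= 0")
        for pos, freqs in self.planted.items():
            if not self.contig_low <= pos + 0 <= self.contig_high:
                raise SimulationError(f"planted position {pos} outside contig")
            for p in freqs.values():
                if not 0 <= p <= 1:
                    raise SimulationError(f"planted frequency {p} not in [0, 1]")
        for _, _, n in self.cohort:
            if n < 0:
                raise SimulationError("cohort sizes must be >= 0")

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "contig_name": self.contig_name,
            "contig_low": self.contig_low,
            "contig_high": self.contig_high,
            "offset": self.offset,
            "cohort": [list(c) for c in self.cohort],
            "density": self.density,
            "planted": {str(k): dict(v) for k, v in self.planted.items()},
            "missingness": self.missingness,
            "exclude_windows_from_background": self.exclude_windows_from_background,
        }


def load_packaged_sites() -> dict:
    """The published splice-site windows and sequences shipped with the package."""
    text = (_pkg_files("splicescreen") / "data" / "agdsx_sites.json").read_text()
    return json.loads(text)


def _embedded_segments(config: SimulationConfig) -> list[tuple[int, int, str]]:
    """Forward-strand (low, high, seq) segments for every packaged site
    sequence that fits the configured contig, shifted by ``config.offset``."""
    data = load_packaged_sites()
    segments = []
    for group in ("donors", "acceptors"):
        for rec in data[group]:
            start, end = rec["site_pos"]  # transcript order; reverse strand
            low, high = min(start, end) + config.offset, max(start, end) + config.offset
            seq = rec["sequence"].replace("/", "").upper()
            # sequences are printed 5'->3' on the reverse strand
            fwd = reverse_complement(seq)
            if config.contig_low + config.offset <= low and high <= config.contig_high + config.offset:
                segments.append((low, high, fwd))
    return segments


def make_reference(config: SimulationConfig) -> ReferenceContig:
    """Random contig with the published splice-site sequences embedded.

    Deterministic in ``config.seed``. Overlapping embedded segments with
    conflicting bases raise an error.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    origin = config.contig_low + config.offset
    length = config.contig_high - config.contig_low + 1
    arr = _BASES[rng.integers(0, 4, size=length)].copy()
    claimed = np.zeros(length, dtype=bool)
    for low, high, seq in _embedded_segments(config):
        i, j = low - origin, high - origin + 1
        new = np.frombuffer(seq.encode(), dtype=np.uint8)
        overlap = claimed[i:j]
        if overlap.any() and not np.array_equal(arr[i:j][overlap], new[overlap]):
            raise SimulationError(
                f"conflicting embedded bases in overlap at [{low}, {high}]"
            )
        arr[i:j] = new
        claimed[i:j] = True
    desc = f"synthetic contig; shift={config.offset}" if config.offset else "synthetic contig"
    return ReferenceContig(
        name=config.contig_name, seq=arr.tobytes().decode(), origin=origin,
        description=desc,
    )


def build_metadata(cohort: Sequence[tuple[str, str, int]]) -> pd.DataFrame:
    """Sample metadata frame for a (population, sex, n) cohort spec."""
    rows = []
    for pop, sex, n in cohort:
        code = pop.replace(" ", "")[:4].upper()
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{code}{sex}{i + 1:04d}",
                    "country": pop,
                    "site": "synthetic",
                    "year": 2012,
                    "sex": sex,
                }
            )
    df = pd.DataFrame(rows, columns=["sample_id", "country", "site", "year", "sex"])
    if df["sample_id"].duplicated().any():
        raise SimulationError("cohort spec produced duplicate sample ids")
    return df


def _stratum_freq(freqs: Mapping[str, float], pop: str, sex: str) -> float:
    return float(freqs.get(f"{pop}|{sex}", freqs.get("*", 0.0)))


def draw_genotypes(
    p_by_stratum: Mapping[str, float],
    cohort: Sequence[tuple[str, str, int]],
    rng: np.random.Generator,
    missingness: float = 0.0,
) -> np.ndarray:
    """Hardy-Weinberg alt dosages for one variant across the cohort.

    Per sample in stratum (pop, sex) with alt frequency p: dosage ~
    Binomial(2, p); calls dropped to missing (-1) independently at
    ``missingness``.
    """
    parts = []
    for pop, sex, n in cohort:
        p = _stratum_freq(p_by_stratum, pop, sex)
        parts.append(rng.binomial(2, p, size=n).astype(np.int8))
    dose = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
    if missingness > 0:
        dose[rng.random(dose.size) < missingness] = MISSING
    return dose


def _sfs_frequencies(n_variants: int, n_alleles: int, rng: np.random.Generator) -> np.ndarray:
    """Allele frequencies from a neutral-like folded spectrum.

    Allele counts i in 1..2N-1 are drawn with weight 1/i (the standard
    neutral site-frequency spectrum), then converted to frequencies. This
    gives the rare-variant-dominated spectrum expected of population
    resequencing data without simulating genealogies.
    """
    i = np.arange(1, n_alleles)
    w = 1.0 / i
    counts = rng.choice(i, size=n_variants, p=w / w.sum())
    return counts / n_alleles


def _splice_window_intervals(config: SimulationConfig) -> list[tuple[int, int]]:
    data = load_packaged_sites()
    out = []
    for group in ("donors", "acceptors"):
        for rec in data[group]:
            start, end = rec["site_pos"]
            out.append((min(start, end) + config.offset, max(start, end) + config.offset))
    return out


@dataclass
class CohortFixture:
    """In-memory result of a cohort simulation, plus written file paths."""

    table: GenotypeTable
    vcf_path: Path | None = None
    metadata_path: Path | None = None
    config_path: Path | None = None


def simulate_cohort(
    config: SimulationConfig, reference: ReferenceContig
) -> GenotypeTable:
    """Draw the variant set and genotype matrix (no files written).

    Background variant count ~ Binomial(usable bp, density); positions are a
    uniform draw without replacement over the contig, avoiding planted
    positions and (by default) all splice windows, so that the windows carry
    exactly the planted variants. Alt alleles differ from the reference base;
    ids follow the "rs" + position convention.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    metadata = build_metadata(config.cohort)
    n_samples = len(metadata)

    origin, contig_len = reference.origin, len(reference.seq)
    forbidden = set()
    planted_shifted = {pos + config.offset: freqs for pos, freqs in config.planted.items()}
    forbidden.update(planted_shifted)
    if config.exclude_windows_from_background:
        for low, high in _splice_window_intervals(config):
            forbidden.update(range(low, high + 1))

    candidates = np.array(
        sorted(set(range(origin, origin + contig_len)) - forbidden), dtype=np.int64
    )
    n_bg = rng.binomial(len(candidates), min(config.density, 1.0))
    bg_pos = np.sort(rng.choice(candidates, size=n_bg, replace=False))

    # background variants: panmictic frequencies from a neutral-like spectrum
    bg_freq = _sfs_frequencies(n_bg, 2 * max(n_samples, 2), rng)

    positions = sorted(set(bg_pos.tolist()) | set(planted_shifted))
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    bg_freq_by_pos = dict(zip(bg_pos.tolist(), bg_freq))
    for pos in positions:
        ref_base = reference.fetch(pos, pos)
        if ref_base not in "ACGT":
            raise SimulationError(f"planted position {pos} sits on non-ACGT base")
        alt_base = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        if pos in planted_shifted:
            dose = draw_genotypes(
                planted_shifted[pos], config.cohort, rng, config.missingness
            )
        else:
            dose = draw_genotypes(
                {"*": bg_freq_by_pos[pos]}, config.cohort, rng, config.missingness
            )
        variants.append(Variant(reference.name, pos, ref_base, alt_base))
        rows.append(dose)
    dosage = (
        np.vstack(rows) if rows else np.empty((0, n_samples), dtype=np.int8)
    )
    meta = metadata.rename(columns={"country": "population"})
    return GenotypeTable(variants=variants, samples=meta, dosage=dosage)


_GT_STRINGS = np.array(["0/0", "0/1", "1/1", "./."])


def write_vcf(table: GenotypeTable, reference: ReferenceContig, path: str | Path) -> Path:
    """Plain-text VCF 4.2 with PASS biallelic SNPs and GT-only genotypes."""
    path = Path(path)
    sample_ids = list(table.samples["sample_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.name},length={reference.high}>\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##source=splicescreen-synthetic\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for v, dose in zip(table.variants, table.dosage):
            gts = _GT_STRINGS[np.where(dose == MISSING, 3, dose)]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return path


def make_cohort_vcf(
    config: SimulationConfig, reference: ReferenceContig, outdir: str | Path
) -> CohortFixture:
    """Simulate the cohort and write VCF + metadata TSV + config echo JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = simulate_cohort(config, reference)
    vcf_path = write_vcf(table, reference, outdir / "cohort.vcf")
    meta = table.samples.rename(columns={"population": "country"})
    metadata_path = outdir / "metadata.tsv"
    meta.to_csv(metadata_path, sep="\t", index=False)
    config_path = outdir / "sim_config.json"
    config_path.write_text(json.dumps(config.to_json(), indent=2) + "\n")
    return CohortFixture(
        table=table, vcf_path=vcf_path, metadata_path=metadata_path,
        config_path=config_path,
    )


def shifted_gene(offset: int):
    """The packaged gene model with all coordinates shifted by ``offset``."""
    from .gene_model import GeneModel, TranscriptModel

    gene = load_packaged_gene()
    transcripts = tuple(
        TranscriptModel(
            id=t.id,
            exons=tuple(e.shifted(offset) for e in t.exons),
            sex_label=t.sex_label,
        )
        for t in gene.transcripts
    )
    return GeneModel(
        gene_id=gene.gene_id, span=gene.span.shifted(offset), transcripts=transcripts
    )
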