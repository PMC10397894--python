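"""Multi-isoform gene models: introns, junction sharing, cassette exons.

A gene is a set of transcripts on one strand of one chromosome. Junctions
(donor = exon|intron boundary, acceptor = intron|exon boundary) are keyed by
the *genomic coordinate of the exonic edge base*, so that the same physical
splice site is recognised across isoforms even when exon/intron numbering
shifts — as it does for the doublesex gene, where skipping the female
cassette exon renumbers every downstream feature in the male transcript.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import CoordinateError, GenomicInterval

try:  # resources shipped with the package
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None


class ModelError(ValueError):
    """Raised for structurally invalid gene models."""


@dataclass(frozen=True)
class JunctionKey:
    """Identity of a splice junction across isoforms.

    ``boundary`` is the genomic coordinate of the last exonic base (donor) or
    the first exonic base (acceptor), *not* the intronic GT/AG base.
    """

    kind: str  # "donor" | "acceptor"
    boundary: int
    chrom: str
    strand: str

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise ModelError(f"kind must be donor|acceptor, got {self.kind!r}")


@dataclass
class TranscriptModel:
    """One isoform: ordered exons in transcript (5'->3') orientation."""

    id: str
    exons: tuple[GenomicInterval, ...]
    sex_label: str | None = None

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if not self.exons:
            raise ModelError(f"transcript {self.id}: needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ModelError(f"transcript {self.id}: exons on mixed chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.overlaps(b):
                raise ModelError(f"transcript {self.id}: overlapping exons {a} / {b}")
            if self.strand == "-" and not b.high < a.low:
                raise ModelError(
                    f"transcript {self.id}: exons not in transcript order on - strand"
                )
            if self.strand == "+" and not a.high < b.low:
                raise ModelError(
                    f"transcript {self.id}: exons not in transcript order on + strand"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def footprint(self) -> GenomicInterval:
        low = min(e.low for e in self.exons)
        high = max(e.high for e in self.exons)
        return GenomicInterval(self.chrom, low, high, self.strand)


@dataclass
class GeneModel:
    """A gene: its genomic span and >= 1 transcript sharing chrom and strand."""

    gene_id: str
    span: GenomicInterval
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        self.transcripts = tuple(self.transcripts)
        if not self.transcripts:
            raise ModelError(f"gene {self.gene_id}: needs >= 1 transcript")
        for t in self.transcripts:
            if t.chrom != self.span.chrom or t.strand != self.span.strand:
                raise ModelError(f"gene {self.gene_id}: transcript {t.id} chrom/strand mismatch")
            for e in t.exons:
                if not self.span.contains_interval(e):
                    raise ModelError(f"gene {self.gene_id}: exon {e} outside span {self.span}")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    def transcript(self, tid: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.id == tid:
                return t
        raise KeyError(tid)


# ---------------------------------------------------------------------------
# core operations


def derive_introns(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Introns between consecutive exons, in transcript order.

    Intron ``i`` (1-based) lies between exon ``i`` and exon ``i+1``. A
    single-exon transcript has no introns; adjacent exons with a zero-length
    gap are rejected (they should have been merged).
    """
    introns: list[GenomicInterval] = []
    for i, (a, b) in enumerate(zip(transcript.exons, transcript.exons[1:]), start=1):
        if transcript.strand == "-":
            low, high = b.high + 1, a.low - 1
        else:
            low, high = a.high + 1, b.low - 1
        if low > high:
            raise ModelError(
                f"transcript {transcript.id}: zero-length gap between exons {i} and {i + 1}"
            )
        introns.append(GenomicInterval(transcript.chrom, low, high, transcript.strand))
    return introns


def transcript_length(transcript: TranscriptModel) -> int:
    """Spliced mRNA length in bp (sum of exon lengths)."""
    return sum(e.length for e in transcript.exons)


def transcript_junctions(transcript: TranscriptModel) -> dict[JunctionKey, int]:
    """All junctions of one transcript, mapped to their 1-based ordinal.

    Donor of exon ``i`` gets ordinal ``i`` (the terminal exon has none);
    acceptor into exon ``i`` gets the ordinal of the preceding intron,
    ``i - 1``.
    """
    out: dict[JunctionKey, int] = {}
    n = transcript.n_exons
    for i, exon in enumerate(transcript.exons, start=1):
        if i < n:  # donor at the 3' edge of this exon
            boundary = exon.low if transcript.strand == "-" else exon.high
            out[JunctionKey("donor", boundary, transcript.chrom, transcript.strand)] = i
        if i > 1:  # acceptor at the 5' edge of this exon
            boundary = exon.high if transcript.strand == "-" else exon.low
            out[JunctionKey("acceptor", boundary, transcript.chrom, transcript.strand)] = i - 1
    return out


@dataclass
class JunctionSharing:
    """Which transcripts use a junction, with their local ordinals."""

    key: JunctionKey
    transcripts: tuple[str, ...]  # ids of transcripts carrying this junction
    ordinals: dict[str, int] = field(default_factory=dict)
    shared: bool = False  # present in every transcript of the gene

    @property
    def label(self) -> str:
        return "shared" if self.shared else "specific:" + ",".join(self.transcripts)


def classify_junctions(gene: GeneModel) -> dict[JunctionKey, JunctionSharing]:
    """Partition all junctions of a gene into shared vs isoform-specific.

    A junction is *shared* iff its (kind, boundary) occurs in every
    transcript. Keying is by coordinate, so exon-numbering shifts between
    isoforms cannot split one physical site into two.
    """
    per_transcript = {t.id: transcript_junctions(t) for t in gene.transcripts}
    all_ids = tuple(t.id for t in gene.transcripts)
    result: dict[JunctionKey, JunctionSharing] = {}
    for tid, junctions in per_transcript.items():
        for key, ordinal in junctions.items():
            sh = result.setdefault(key, JunctionSharing(key=key, transcripts=()))
            sh.transcripts = tuple([*sh.transcripts, tid])
            sh.ordinals[tid] = ordinal
    for sh in result.values():
        sh.shared = set(sh.transcripts) == set(all_ids)
    return result


@dataclass(frozen=True)
class CassetteExon:
    """An exon of one isoform fully contained in an intron of another."""

    exon_transcript: str
    exon_ordinal: int
    exon: GenomicInterval
    host_transcript: str
    host_intron_ordinal: int
    host_intron: GenomicInterval


def detect_cassette_exons(gene: GeneModel) -> list[CassetteExon]:
    """Find skipped (cassette) exons.

    Exon e of transcript A is a cassette exon w.r.t. transcript B when e and
    both of its flanking introns in A lie inside a single intron of B — i.e.
    B splices straight across e.
    """
    found: list[CassetteExon] = []
    introns_by_tid = {t.id: derive_introns(t) if t.n_exons > 1 else [] for t in gene.transcripts}
    for ta in gene.transcripts:
        if ta.n_exons < 3:
            continue  # internal exons only: need flanking introns on both sides
        introns_a = introns_by_tid[ta.id]
        for i in range(1, ta.n_exons - 1):  # 0-based index of internal exon
            exon = ta.exons[i]
            up, down = introns_a[i - 1], introns_a[i]
            for tb in gene.transcripts:
                if tb.id == ta.id:
                    continue
                for j, host in enumerate(introns_by_tid[tb.id], start=1):
                    if (
                        host.contains_interval(exon)
                        and host.contains_interval(up)
                        and host.contains_interval(down)
                    ):
                        found.append(
                            CassetteExon(ta.id, i + 1, exon, tb.id, j, host)
                        )
    return found


# ---------------------------------------------------------------------------
# readers / writers


def gene_from_dict(d: dict) -> GeneModel:
    """Build a gene model from the JSON dialect.

    Expected shape::

        {"gene_id": ..., "chrom": ..., "strand": "+"|"-",
         "span": [low, high],                      # optional
         "transcripts": [{"id": ..., "sex_label": ...,
                          "exons": [[low, high], ...]}, ...]}

    Exon pairs may be given in either coordinate or transcript order; they
    are normalised to transcript order here.
    """
    chrom, strand = d["chrom"], d["strand"]
    transcripts = []
    for td in d["transcripts"]:
        exons = [
            GenomicInterval(chrom, min(a, b), max(a, b), strand) for a, b in td["exons"]
        ]
        exons.sort(key=lambda e: e.low, reverse=(strand == "-"))
        transcripts.append(
            TranscriptModel(id=td["id"], exons=tuple(exons), sex_label=td.get("sex_label"))
        )
    if "span" in d:
        lo, hi = d["span"]
        span = GenomicInterval(chrom, min(lo, hi), max(lo, hi), strand)
    else:
        lo = min(e.low for t in transcripts for e in t.exons)
        hi = max(e.high for t in transcripts for e in t.exons)
        span = GenomicInterval(chrom, lo, hi, strand)
    return GeneModel(gene_id=d["gene_id"], span=span, transcripts=tuple(transcripts))


def read_gene_json(path: str | Path) -> GeneModel:
    with open(path) as fh:
        return gene_from_dict(json.load(fh))


def read_gene_gff3(path: str | Path, gene_id: str | None = None) -> GeneModel:
    """Read one gene from a GFF3 file.

    Exon features are grouped by their ``Parent`` attribute (the transcript);
    transcripts are grouped under ``gene_id`` via their own Parent. All other
    feature types are ignored. Multi-gene batch parsing is out of scope: if
    ``gene_id`` is None the file must describe a single gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = [g.id for g in db.features_of_type("gene")]
    if gene_id is None:
        if len(genes) != 1:
            raise ModelError(f"expected exactly one gene in {path}, found {genes}")
        gene_id = genes[0]
    elif gene_id not in genes:
        raise ModelError(f"gene {gene_id!r} not found in {path} (have {genes})")
    gfeat = db[gene_id]
    transcripts = []
    for tr in db.children(gfeat, level=1):
        exon_feats = list(db.children(tr, featuretype="exon"))
        if not exon_feats:
            continue
        exons = [
            GenomicInterval(e.seqid, e.start, e.end, e.strand) for e in exon_feats
        ]
        exons.sort(key=lambda e: e.low, reverse=(gfeat.strand == "-"))
        sex = tr.attributes.get("sex_label", [None])[0]
        transcripts.append(TranscriptModel(id=tr.id, exons=tuple(exons), sex_label=sex))
    if not transcripts:
        raise ModelError(f"gene {gene_id}: no transcripts with exons in {path}")
    span = GenomicInterval(gfeat.seqid, gfeat.start, gfeat.end, gfeat.strand)
    return GeneModel(gene_id=gene_id, span=span, transcripts=tuple(transcripts))


def load_packaged_gene() -> GeneModel:
    """The doublesex (AGAP004050) two-isoform model shipped with the package."""
    text = (_pkg_files("splicescreen") / "data" / "agdsx_model.json").read_text()
    return gene_from_dict(json.loads(text))


def load_packaged_cds() -> list[GenomicInterval]:
    """Coding intervals of the packaged female transcript (for case rendering)."""
    text = (_pkg_files("splicescreen") / "data" / "agdsx_model.json").read_text()
    d = json.loads(text)
    chrom, strand = d["chrom"], d["strand"]
    out = []
    for ivs in d.get("cds", {}).values():
        out.extend(GenomicInterval(chrom, lo, hi, strand) for lo, hi in ivs)
    return out


def junction_table(gene: GeneModel) -> pd.DataFrame:
    """Tabulate every junction with its sharing classification.

    Columns: kind, boundary, sharing, transcripts, ordinals (``tid:ordinal``
    per transcript, donor ordinal = exon number, acceptor ordinal = intron
    number).
    """
    rows = []
    for key, sh in sorted(
        classify_junctions(gene).items(), key=lambda kv: (kv[0].kind, kv[0].boundary)
    ):
        rows.append(
            {
                "chrom": key.chrom,
                "strand": key.strand,
                "kind": key.kind,
                "boundary": key.boundary,
                "sharing": sh.label,
                "transcripts": ",".join(sh.transcripts),
                "ordinals": ";".join(f"{tid}:{o}" for tid, o in sh.ordinals.items()),
            }
        )
    return pd.DataFrame(rows)


def write_junction_table(gene: GeneModel, path: str | Path) -> Path:
    path = Path(path)
    junction_table(gene).to_csv(path, sep="\t", index=False)
    return path
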