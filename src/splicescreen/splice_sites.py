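"""Donor/acceptor splice-site windows, sequence extraction and tract scoring.

Window geometry (fixed by the screen design, all lengths in nt):

* donor:     last 6 exonic bases + first 16 intronic bases  -> 22 nt
* acceptor:  last 16 intronic bases + first 6 exonic bases  -> 22 nt, where
  the intronic 16 decompose into a 12-nt polypyrimidine tract followed by
  the 4-nt NYag pattern (N = any base, Y = pyrimidine, ag = the invariant
  acceptor dinucleotide).

Sequences are reported 5'->3' in transcript orientation (reverse-complemented
for reverse-strand genes), with coding bases uppercase when coding intervals
are supplied, and the exon|intron boundary marked "/".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import reverse_complement

from .gene_model import (
    GeneModel,
    JunctionKey,
    JunctionSharing,
    ModelError,
    TranscriptModel,
    classify_junctions,
    derive_introns,
)
from .intervals import CoordinateError, GenomicInterval
from .reference import ReferenceContig

EXONIC_NT = 6
INTRONIC_NT = 16
TRACT_NT = 12
NYAG_NT = 4
WINDOW_NT = EXONIC_NT + INTRONIC_NT

#: Mean pyrimidine count of the 12-nt acceptor tract across Anopheles gambiae
#: splice acceptor sites (literature consensus; configurable, not recomputed).
CONSENSUS_MEAN_PYRIMIDINES = 8.69

PYRIMIDINES = frozenset("ctCT")


class WindowError(CoordinateError):
    """Raised when a splice window cannot be built or extracted."""


def build_donor_window(key: JunctionKey) -> GenomicInterval:
    """22-nt donor window: 6 exonic + 16 intronic bases around the boundary.

    ``key.boundary`` is the genomic coordinate of the last exonic base.
    """
    if key.kind != "donor":
        raise WindowError(f"expected a donor key, got {key.kind}")
    b = key.boundary
    if key.strand == "-":
        # transcript runs towards lower coordinates: exonic bases above, intron below
        return GenomicInterval(key.chrom, b - INTRONIC_NT, b + EXONIC_NT - 1, key.strand)
    return GenomicInterval(key.chrom, b - EXONIC_NT + 1, b + INTRONIC_NT, key.strand)


def build_acceptor_window(key: JunctionKey) -> GenomicInterval:
    """22-nt acceptor window: 12-nt tract + NYag + 6 exonic bases.

    ``key.boundary`` is the genomic coordinate of the first exonic base.
    """
    if key.kind != "acceptor":
        raise WindowError(f"expected an acceptor key, got {key.kind}")
    b = key.boundary
    if key.strand == "-":
        return GenomicInterval(key.chrom, b - EXONIC_NT + 1, b + INTRONIC_NT, key.strand)
    return GenomicInterval(key.chrom, b - INTRONIC_NT, b + EXONIC_NT - 1, key.strand)


def build_window(key: JunctionKey) -> GenomicInterval:
    return build_donor_window(key) if key.kind == "donor" else build_acceptor_window(key)


def donor_key(transcript: TranscriptModel, exon_ordinal: int) -> JunctionKey:
    """Donor junction of exon ``exon_ordinal`` (1-based, transcript order)."""
    if exon_ordinal == transcript.n_exons:
        raise WindowError(f"no donor at terminal exon {exon_ordinal} of {transcript.id}")
    exon = transcript.exons[exon_ordinal - 1]
    b = exon.low if transcript.strand == "-" else exon.high
    return JunctionKey("donor", b, transcript.chrom, transcript.strand)


def acceptor_key(transcript: TranscriptModel, exon_ordinal: int) -> JunctionKey:
    """Acceptor junction into exon ``exon_ordinal`` (1-based, transcript order)."""
    if exon_ordinal == 1:
        raise WindowError(f"no acceptor at first exon of {transcript.id}")
    exon = transcript.exons[exon_ordinal - 1]
    b = exon.high if transcript.strand == "-" else exon.low
    return JunctionKey("acceptor", b, transcript.chrom, transcript.strand)


@dataclass
class AcceptorMotif:
    """Decomposition of the intronic 16-mer of an acceptor site."""

    tract12: str
    nyag: str

    def __post_init__(self) -> None:
        if len(self.tract12) != TRACT_NT or len(self.nyag) != NYAG_NT:
            raise WindowError("acceptor motif must be 12-nt tract + 4-nt NYag")

    @property
    def pyrimidine_count(self) -> int:
        return sum(1 for c in self.tract12 if c in PYRIMIDINES)


@dataclass
class SpliceSite:
    """One donor or acceptor site with its window and extracted sequence."""

    key: JunctionKey
    window: GenomicInterval
    exonic_part: str = ""
    intronic_part: str = ""
    sharing: JunctionSharing | None = None
    truncated: bool = False

    @property
    def rendered(self) -> str:
        """Transcript-orientation sequence with '/' at the exon|intron boundary."""
        if self.key.kind == "donor":
            return f"{self.exonic_part}/{self.intronic_part}"
        return f"{self.intronic_part}/{self.exonic_part}"

    @property
    def acceptor_motif(self) -> AcceptorMotif:
        if self.key.kind != "acceptor":
            raise WindowError("only acceptor sites carry an NYag motif")
        if len(self.intronic_part) != INTRONIC_NT:
            raise WindowError("acceptor intronic part truncated; no motif")
        return AcceptorMotif(
            tract12=self.intronic_part[:TRACT_NT], nyag=self.intronic_part[TRACT_NT:]
        )


def _apply_case(seq: str, positions: Sequence[int], coding: bool | None,
                cds: Sequence[GenomicInterval] | None, exonic: bool) -> str:
    """Uppercase coding bases. With CDS intervals: case follows coding status;
    without: exonic bases upper, intronic lower."""
    if cds is None:
        return seq.upper() if exonic else seq.lower()
    out = []
    for base, pos in zip(seq, positions):
        in_cds = any(iv.contains(pos) for iv in cds)
        out.append(base.upper() if in_cds else base.lower())
    return "".join(out)


def extract_site_sequence(
    key: JunctionKey,
    reference: ReferenceContig,
    cds: Sequence[GenomicInterval] | None = None,
    sharing: JunctionSharing | None = None,
) -> SpliceSite:
    """Extract the 22-nt site sequence in transcript orientation.

    Reverse-strand windows are reverse-complemented; case renders coding
    status (see :func:`_apply_case`). Windows running off the contig edge are
    truncated and flagged rather than padded. Non-ACGT bases are carried
    through with a warning.
    """
    window = build_window(key)
    lo = max(window.low, reference.low)
    hi = min(window.high, reference.high)
    if lo > hi:
        raise WindowError(f"window [{window.low},{window.high}] entirely outside contig")
    truncated = (lo, hi) != (window.low, window.high)
    fwd = reference.fetch(lo, hi)
    if any(c not in "ACGT" for c in fwd):
        warnings.warn(f"non-ACGT base in window [{lo},{hi}]; carried through as-is")
    if key.strand == "-":
        oriented = reverse_complement(fwd)
        positions = list(range(hi, lo - 1, -1))
    else:
        oriented = fwd
        positions = list(range(lo, hi + 1))

    # split into exonic / intronic parts in transcript orientation
    if key.kind == "donor":
        n_exonic_lead = EXONIC_NT - (
            (window.high - hi) if key.strand == "-" else (lo - window.low)
        )
        n_exonic_lead = max(0, min(len(oriented), n_exonic_lead))
        exonic, intronic = oriented[:n_exonic_lead], oriented[n_exonic_lead:]
        ex_pos, in_pos = positions[:n_exonic_lead], positions[n_exonic_lead:]
    else:
        n_intronic_lead = INTRONIC_NT - (
            (window.high - hi) if key.strand == "-" else (lo - window.low)
        )
        n_intronic_lead = max(0, min(len(oriented), n_intronic_lead))
        intronic, exonic = oriented[:n_intronic_lead], oriented[n_intronic_lead:]
        in_pos, ex_pos = positions[:n_intronic_lead], positions[n_intronic_lead:]

    return SpliceSite(
        key=key,
        window=window,
        exonic_part=_apply_case(exonic, ex_pos, None, cds, exonic=True),
        intronic_part=_apply_case(intronic, in_pos, None, cds, exonic=False),
        sharing=sharing,
        truncated=truncated,
    )


@dataclass
class MotifCheck:
    canonical: bool
    violations: tuple[str, ...]


def validate_canonical_motifs(site: SpliceSite) -> MotifCheck:
    """Check the invariant dinucleotides (donor gt.., acceptor ..NYag).

    Donor: intronic part must begin ``gt``. Acceptor: intronic part must end
    ``ag`` preceded by a pyrimidine at the Y position. Violations are
    reported by transcript-orientation offset within the window.
    """
    violations: list[str] = []
    intronic = site.intronic_part.lower()
    if site.key.kind == "donor":
        if not intronic.startswith("gt"):
            violations.append(f"offset {EXONIC_NT}-{EXONIC_NT + 1}: expected gt, got {intronic[:2]}")
    else:
        nyag = intronic[TRACT_NT:]
        if len(nyag) != NYAG_NT:
            violations.append("truncated NYag")
        else:
            if nyag[2:] != "ag":
                violations.append(f"offset {TRACT_NT + 2}-{TRACT_NT + 3}: expected ag, got {nyag[2:]}")
            if nyag[1] not in "ct":
                violations.append(f"offset {TRACT_NT + 1}: Y position is purine {nyag[1]}")
    return MotifCheck(canonical=not violations, violations=tuple(violations))


def polypyrimidine_score(
    motif: AcceptorMotif, consensus_mean: float = CONSENSUS_MEAN_PYRIMIDINES
) -> tuple[int, float]:
    """Pyrimidine (C/T) count of the 12-nt tract and its signed difference
    from the species consensus mean."""
    n = motif.pyrimidine_count
    return n, n - consensus_mean


# ---------------------------------------------------------------------------
# whole-gene site derivation and the report table


def sites_for_gene(
    gene: GeneModel,
    reference: ReferenceContig | None = None,
    cds: Sequence[GenomicInterval] | None = None,
) -> list[SpliceSite]:
    """All splice sites of a gene, sequence-extracted when a reference is given.

    Sites are ordered by transcript position (5'->3' along the gene), donors
    and acceptors interleaved.
    """
    sharing = classify_junctions(gene)
    sites = []
    for key, sh in sharing.items():
        if reference is not None:
            site = extract_site_sequence(key, reference, cds=cds, sharing=sh)
        else:
            site = SpliceSite(key=key, window=build_window(key), sharing=sh)
        sites.append(site)
    reverse = gene.strand == "-"
    sites.sort(key=lambda s: s.key.boundary, reverse=reverse)
    return sites


def site_table(
    gene: GeneModel,
    reference: ReferenceContig | None = None,
    cds: Sequence[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Publication-style site table.

    One row per physical junction. ``site_pos_start``/``site_pos_end`` render
    the window in transcript order (start > end on the reverse strand);
    ``flank_sizes`` gives, per transcript, the donor exon size or acceptor
    intron size. Pyrimidine counts apply to acceptor rows only.
    """
    exon_sizes = {t.id: [e.length for e in t.exons] for t in gene.transcripts}
    intron_sizes = {
        t.id: [iv.length for iv in derive_introns(t)] if t.n_exons > 1 else []
        for t in gene.transcripts
    }
    rows = []
    for site in sites_for_gene(gene, reference, cds):
        sh = site.sharing
        start, end = site.window.transcript_order()
        ordinals = ";".join(f"{tid}:{o}" for tid, o in sh.ordinals.items())
        if site.key.kind == "donor":
            flanks = ";".join(
                f"{tid}:{exon_sizes[tid][o - 1]}" for tid, o in sh.ordinals.items()
            )
        else:
            flanks = ";".join(
                f"{tid}:{intron_sizes[tid][o - 1]}" for tid, o in sh.ordinals.items()
            )
        check = validate_canonical_motifs(site) if site.intronic_part else None
        row = {
            "kind": site.key.kind,
            "sharing": sh.label,
            "ordinals": ordinals,
            "flank_sizes": flanks,
            "boundary": site.key.boundary,
            "site_pos_start": start,
            "site_pos_end": end,
            "window_low": site.window.low,
            "window_high": site.window.high,
            "sequence": site.rendered if site.exonic_part or site.intronic_part else "",
            "canonical": "" if check is None else str(check.canonical),
            "pyrimidine_count": (
                site.acceptor_motif.pyrimidine_count
                if site.key.kind == "acceptor" and len(site.intronic_part) == INTRONIC_NT
                else ""
            ),
            "truncated": site.truncated,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_site_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive, forward genome; "
                 "site_pos_* rendered in transcript order; sizes in bp\n")
        df.to_csv(fh, sep="\t", index=False)
    return path
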