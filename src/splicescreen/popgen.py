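"""Windowed nucleotide diversity (pi) from diploid allele counts.

The statistic is implemented directly from allele counts rather than
delegated to an external library: for a window of length L covering variants
v with non-missing allele count n_v and alt-allele count d_v,

    pi = (1/L) * sum_v  2 * d_v * (n_v - d_v) / (n_v * (n_v - 1))

which is the mean pairwise difference per site over all C(n_v, 2) allele
pairs, with monomorphic and variant-free windows contributing 0. Diploid
genotypes enter only through allele counts, so phasing is irrelevant. The
denominator is the full window length: no accessibility mask is applied, a
documented simplification relative to masked whole-genome pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .variants import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


class DiversityError(ValueError):
    pass


@dataclass
class DiversityTrack:
    """Per-window pi for one stratum."""

    stratum: str
    n_samples: int
    table: pd.DataFrame  # columns: window_low, window_high, n_variants, pi

    @property
    def mean_pi(self) -> float:
        """Length-weighted mean pi over the whole span."""
        lengths = self.table["window_high"] - self.table["window_low"] + 1
        return float((self.table["pi"] * lengths).sum() / lengths.sum())


def tile_span(span: GenomicInterval, window_size: int) -> list[tuple[int, int]]:
    """Non-overlapping windows tiling [span.low, span.high]; the last window
    may be short."""
    if window_size < 1:
        raise DiversityError("window_size must be >= 1")
    out = []
    lo = span.low
    while lo <= span.high:
        out.append((lo, min(lo + window_size - 1, span.high)))
        lo += window_size
    return out


def _per_variant_pi(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant pairwise-difference sums (unnormalised by length).

    Returns (pi_v, ok): pi_v[v] = 2 d (n-d) / (n (n-1)) with allele counts
    from non-missing diploid calls; ok[v] False where n < 2 alleles (variant
    skipped).
    """
    called = dosage != MISSING
    n = 2 * called.sum(axis=1)
    d = np.where(called, dosage, 0).sum(axis=1)
    ok = n >= 2
    pi_v = np.zeros(dosage.shape[0], dtype=float)
    nn = n[ok].astype(float)
    pi_v[ok] = 2.0 * d[ok] * (nn - d[ok]) / (nn * (nn - 1.0))
    return pi_v, ok


def nucleotide_diversity(
    table: GenotypeTable,
    span: GenomicInterval,
    window_size: int = 500,
    sample_mask: np.ndarray | None = None,
    stratum: str = "all",
) -> DiversityTrack:
    """Windowed pi across ``span`` for the samples selected by ``sample_mask``.

    Variants with fewer than two called alleles in the selection are skipped
    (with a log message). Windows without usable variants get pi = 0.
    """
    dosage = table.dosage if sample_mask is None else table.dosage[:, sample_mask]
    n_samples = dosage.shape[1]
    pi_v, ok = _per_variant_pi(dosage)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("stratum %s: %d variants with <2 called alleles skipped",
                       stratum, n_skipped)
    positions = table.positions
    rows = []
    for lo, hi in tile_span(span, window_size):
        in_win = (positions >= lo) & (positions <= hi) & ok
        length = hi - lo + 1
        rows.append(
            {
                "window_low": lo,
                "window_high": hi,
                "n_variants": int(in_win.sum()),
                "pi": float(pi_v[in_win].sum() / length),
            }
        )
    return DiversityTrack(stratum=stratum, n_samples=n_samples, table=pd.DataFrame(rows))


def brute_force_pi(dosage: np.ndarray, window_length: int) -> float:
    """Independent oracle: mean pairwise Hamming distance per site.

    Expands diploid dosages to allele sequences (2 per sample; missing calls
    drop both alleles at that variant for that sample) and averages the
    per-variant pairwise differences over all allele pairs. O(V * n^2) —
    test-sized inputs only.
    """
    total = 0.0
    for v in range(dosage.shape[0]):
        alleles = []
        for dose in dosage[v]:
            if dose == MISSING:
                continue
            alleles.extend([1] * int(dose) + [0] * (2 - int(dose)))
        if len(alleles) < 2:
            continue
        diffs = sum(a != b for a, b in combinations(alleles, 2))
        total += diffs / (len(alleles) * (len(alleles) - 1) / 2)
    return total / window_length


def compare_strata(tracks: Sequence[DiversityTrack]) -> pd.DataFrame:
    """Pairwise per-window comparison of diversity tracks.

    All tracks must share identical windows. For each pair: per-window
    delta_pi (a - b) and ratio (a/b, NaN where b = 0), plus a summary row
    per pair with span means and a paired t-test over windows for a
    systematic mean difference (p = 1 when the tracks are identical;
    windows are disjoint so their pi values are independent).
    """
    if len(tracks) < 2:
        raise DiversityError("need >= 2 tracks to compare")
    base = tracks[0].table[["window_low", "window_high"]]
    for t in tracks[1:]:
        if not base.equals(t.table[["window_low", "window_high"]]):
            raise DiversityError(f"track {t.stratum}: window grid mismatch")
    rows = []
    for i, a in enumerate(tracks):
        for b in tracks[i + 1:]:
            dpi = a.table["pi"] - b.table["pi"]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(b.table["pi"] > 0, a.table["pi"] / b.table["pi"], np.nan)
            if (dpi == 0).all():
                p = 1.0
            elif len(dpi) < 2:
                p = np.nan  # a single window cannot support a paired test
            else:
                _, p = stats.ttest_rel(a.table["pi"], b.table["pi"])
            rows.append(
                {
                    "stratum_a": a.stratum,
                    "stratum_b": b.stratum,
                    "mean_pi_a": a.mean_pi,
                    "mean_pi_b": b.mean_pi,
                    "mean_delta_pi": float(dpi.mean()),
                    "mean_abs_delta_pi": float(dpi.abs().mean()),
                    "mean_ratio": float(np.nanmean(ratio)) if np.isfinite(ratio).any() else np.nan,
                    "paired_t_p": float(p),
                    "n_windows": len(dpi),
                }
            )
    return pd.DataFrame(rows)


def tracks_frame(tracks: Sequence[DiversityTrack]) -> pd.DataFrame:
    """Stack tracks into one long table (stratum, window bounds, n, pi)."""
    frames = []
    for t in tracks:
        df = t.table.copy()
        df.insert(0, "stratum", t.stratum)
        df.insert(1, "n_samples", t.n_samples)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_tracks(tracks: Sequence[DiversityTrack], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# pi: nucleotide diversity per site (pairwise differences / bp); "
                 "windows 1-based inclusive, forward genome\n")
        tracks_frame(tracks).to_csv(fh, sep="\t", index=False)
    return path


def plot_tracks(tracks: Sequence[DiversityTrack], path: str | Path) -> Path:
    """Static per-stratum pi track plot (one line per stratum)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for t in tracks:
        mid = (t.table["window_low"] + t.table["window_high"]) / 2
        ax.plot(mid, t.table["pi"], label=f"{t.stratum} (n={t.n_samples})", lw=1)
    ax.set_xlabel("genomic position (bp)")
    ax.set_ylabel("nucleotide diversity π")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
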