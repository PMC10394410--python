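"""Binned coverage profiles, gene annotations and metagene aggregation.

Coordinates are 0-based half-open throughout.  bedGraph values are treated as
per-base signal, so a bin's value is the sum of the signal over its covered
bases.  Profiles are always oriented along the transcription direction:
index 0 is the most upstream bin (TSS side), whatever the strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "GeneAnnotation",
    "BinnedProfile",
    "read_bed6",
    "read_profile",
    "write_profile",
    "read_profile_table",
    "interpolate_profile",
    "metagene_average",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with orientation.

    ``tss``/``tes`` are genomic coordinates (0-based); for minus-strand genes
    ``tss > tes``, so the transcription direction is always tss -> tes.
    """

    chrom: str
    tss: int
    tes: int
    strand: str
    symbol: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tes:
            raise ParameterError("tss and tes must differ")
        if self.strand == "+" and self.tss > self.tes:
            raise ParameterError("plus-strand gene must have tss < tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ParameterError("minus-strand gene must have tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    def span(self, flank_upstream: int = 0) -> tuple[int, int]:
        """Genomic [start, end) including an upstream flank."""
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        if self.strand == "+":
            return lo - flank_upstream, hi
        return lo, hi + flank_upstream


@dataclass
class BinnedProfile:
    """Per-bin read values along the transcription direction."""

    gene: GeneAnnotation
    bin_width: int
    values: np.ndarray
    time_label: str = "untreated"

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ParameterError("bin values must be non-negative")
        if self.bin_width < 1:
            raise ParameterError("bin_width must be >= 1")

    @property
    def positions(self) -> np.ndarray:
        """Bin-centre offsets (nt) from the start of the profiled span,
        along the transcription direction."""
        return self.bin_width * (np.arange(self.values.size) + 0.5)


def read_bed6(path) -> list[GeneAnnotation]:
    """Gene annotations from a BED6 file (chrom start end name score strand)."""
    genes = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        parts = raw.split("\t")
        if len(parts) < 6:
            raise ParameterError(f"{path}:{ln}: BED6 needs 6 columns, got {len(parts)}")
        chrom, start, end, name, _score, strand = parts[:6]
        start, end = int(start), int(end)
        if strand == "+":
            genes.append(GeneAnnotation(chrom, start, end, "+", name))
        else:
            genes.append(GeneAnnotation(chrom, end, start, "-", name))
    return genes


def _read_bedgraph(path, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base signal over [start, end); overlapping records are summed."""
    base = np.zeros(end - start)
    overlapping = 0
    seen = np.zeros(end - start, dtype=bool)
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParameterError(f"{path}:{ln}: bedGraph needs 4 columns")
        try:
            c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as err:
            raise ParameterError(f"{path}:{ln}: malformed record ({err})") from None
        if c != chrom or e <= start or s >= end:
            continue
        lo, hi = max(s, start) - start, min(e, end) - start
        if seen[lo:hi].any():
            overlapping += 1
        base[lo:hi] += v
        seen[lo:hi] = True
    if overlapping:
        warnings.warn(
            f"{overlapping} overlapping bedGraph records in {path}; values summed"
        )
    return base


def read_profile(
    path,
    format: str,
    gene: GeneAnnotation,
    bin_width: int = 20,
    flank_upstream: int = 500,
    time_label: str = "untreated",
) -> BinnedProfile:
    """Bin a coverage track over a gene's flanked span.

    Parameters
    ----------
    format : {"bedGraph", "tsv"}
        ``bedGraph`` is the standard 4-column track (0-based half-open,
        per-base values).  ``tsv`` is this package's profile table
        (see :func:`write_profile`); ``gene``/``time_label`` select rows.

    The result is oriented along the transcription direction: minus-strand
    coverage is reversed so index 0 is the most upstream (TSS-side) bin.
    A gene with no overlapping signal yields an all-zero profile and a
    warning.
    """
    if format == "tsv":
        return read_profile_table(path, gene, time_label=time_label)
    if format != "bedGraph":
        raise ParameterError(f"unknown profile format {format!r}")
    start, end = gene.span(flank_upstream)
    if start < 0:
        raise ParameterError("flanked span extends below coordinate 0")
    base = _read_bedgraph(path, gene.chrom, start, end)
    if not base.any():
        warnings.warn(f"no coverage overlaps {gene.symbol or gene.chrom} in {path}")
    n_bins = (end - start) // bin_width
    if n_bins * bin_width != end - start:
        warnings.warn(
            f"span length {end - start} is not a multiple of bin width "
            f"{bin_width}; trailing bases dropped"
        )
    vals = base[: n_bins * bin_width].reshape(n_bins, bin_width).sum(axis=1)
    if gene.strand == "-":
        vals = vals[::-1]
    return BinnedProfile(
        gene=gene, bin_width=bin_width, values=vals, time_label=time_label
    )


def write_profile(profile: BinnedProfile, path) -> None:
    """Write the tab-separated profile table
    (gene, bin_start, bin_end, time_label, value); bit-stable given fixed
    inputs.  ``bin_start``/``bin_end`` are offsets along the transcription
    direction."""
    starts = profile.bin_width * np.arange(profile.values.size)
    df = pd.DataFrame(
        {
            "gene": profile.gene.symbol,
            "bin_start": starts,
            "bin_end": starts + profile.bin_width,
            "time_label": profile.time_label,
            "value": profile.values,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_profile_table(path, gene: GeneAnnotation, time_label: str | None = None) -> BinnedProfile:
    """Read back a profile table written by :func:`write_profile`."""
    df = pd.read_csv(path, sep="\t")
    if gene.symbol:
        df = df[df["gene"] == gene.symbol]
    if time_label is not None:
        df = df[df["time_label"].astype(str) == str(time_label)]
    if df.empty:
        raise ParameterError(
            f"no rows for gene {gene.symbol!r} / time {time_label!r} in {path}"
        )
    df = df.sort_values("bin_start")
    widths = (df["bin_end"] - df["bin_start"]).to_numpy()
    if len(set(widths)) != 1 or np.any(np.diff(df["bin_start"].to_numpy()) != widths[0]):
        raise ParameterError("bins must be contiguous and uniform")
    return BinnedProfile(
        gene=gene,
        bin_width=int(widths[0]),
        values=df["value"].to_numpy(),
        time_label=str(df["time_label"].iloc[0]),
    )


def interpolate_profile(values, positions, x_targets) -> np.ndarray:
    """Piecewise-linear interpolation of a binned profile, clamped to the
    first/last value outside the observed range."""
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.size < 2:
        raise ParameterError("need at least 2 positions to interpolate")
    if np.any(np.diff(positions) <= 0):
        raise ParameterError("positions must be strictly increasing")
    return np.interp(np.asarray(x_targets, dtype=float), positions, values)


def metagene_average(
    rate_profiles,
    annotations,
    n_interior_points: int = 100,
    end_window: int = 1000,
    flank_upstream: int = 500,
    bin_width: int = 20,
):
    """Average rate profiles across genes of different lengths.

    Each profile is split into three segments: a TSS-proximal head
    ``[TSS - flank, TSS + end_window]`` and a TES-proximal tail
    ``[TES - end_window, TES]`` that keep their native length scale, and the
    interior, which is stretched to a common support by linear resampling to
    ``n_interior_points`` before averaging.  Genes shorter than
    ``2 * end_window`` are excluded with a warning.

    Parameters
    ----------
    rate_profiles : list of arrays
        Per-gene rate values on uniform bins of ``bin_width`` nt covering
        ``[TSS - flank_upstream, TES)`` along the transcription direction
        (e.g. posterior-median rates).
    annotations : list of GeneAnnotation

    Returns
    -------
    DataFrame with columns ``segment`` (head/interior/tail), ``position``
    (nt offset from TSS for the head, fraction of the interior span for the
    interior, nt offset from TES for the tail), ``rate_mean`` and
    ``rate_iqr`` (across-gene interquartile range).
    """
    if len(rate_profiles) != len(annotations):
        raise ParameterError("need one annotation per profile")
    if len(rate_profiles) == 0:
        raise ParameterError("need at least one gene")
    head_n = (flank_upstream + end_window) // bin_width
    tail_n = end_window // bin_width
    heads, tails, interiors = [], [], []
    for vals, gene in zip(rate_profiles, annotations):
        vals = np.asarray(vals, dtype=float)
        if gene.length <= 2 * end_window:
            warnings.warn(
                f"gene {gene.symbol or gene.chrom} shorter than 2*end_window; excluded"
            )
            continue
        centres = bin_width * (np.arange(vals.size) + 0.5) - flank_upstream
        heads.append(vals[:head_n])
        tails.append(vals[vals.size - tail_n:])
        lo, hi = float(end_window), float(gene.length - end_window)
        targets = lo + (hi - lo) * np.linspace(0.0, 1.0, n_interior_points)
        interiors.append(interpolate_profile(vals, centres, targets))
    if not heads:
        raise ParameterError("no gene is longer than 2*end_window")
    heads, tails, interiors = map(np.asarray, (heads, tails, interiors))

    def _iqr(m):
        return np.quantile(m, 0.75, axis=0) - np.quantile(m, 0.25, axis=0)

    frames = [
        pd.DataFrame(
            {
                "segment": "head",
                "position": bin_width * (np.arange(head_n) + 0.5) - flank_upstream,
                "rate_mean": heads.mean(axis=0),
                "rate_iqr": _iqr(heads),
            }
        ),
        pd.DataFrame(
            {
                "segment": "interior",
                "position": np.linspace(0.0, 1.0, n_interior_points),
                "rate_mean": interiors.mean(axis=0),
                "rate_iqr": _iqr(interiors),
            }
        ),
        pd.DataFrame(
            {
                "segment": "tail",
                "position": bin_width * (np.arange(tail_n) + 0.5) - end_window,
                "rate_mean": tails.mean(axis=0),
                "rate_iqr": _iqr(tails),
            }
        ),
    ]
    return pd.concat(frames, ignore_index=True)
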