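"""Whole-genome sliding-window scan for period-10 NPS, with BED export.

The scan evaluates every width-``w`` window (default 150 bp, step 1) of each
chromosome: windows above the ambiguity threshold are skipped; the embedded
estimator's dominant period is computed for the rest; and the blockwise
bootstrap runs *only* on windows whose dominant period equals the target —
the restriction that makes genome-scale confirmatory testing tractable (and
is itself a dominant-period gate against factor/multiple confounders).

Significant windows are merged into segments: overlapping or book-ended
half-open intervals on one chromosome coalesce (adjacent step-1 windows over
a single NPS region should form one segment).  Two merge modes are exposed:
merge all dominant-period windows and flag segments containing at least one
significant window, or merge only the significant windows.  Coverage is the
merged segment length over the genome length.  Output is BED4 (0-based
half-open), with the segment's minimum P_BWB in the name column.

Randomness is derived per window from the global seed by counter-based
spawning, so step or chromosome order changes never reorder the streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .bootstrap import BootstrapConfig, bwb_pvalue
from .estimators import PeriodRange, dominant_of_matrix
from .seqs import IndicatorSequence, SymbolicFragment, SymbolSet, NPS_DINUCLEOTIDES, indicator

__all__ = [
    "ScanConfig",
    "WindowRecord",
    "GenomicSegment",
    "scan",
    "merge",
    "coverage",
    "write_bed",
    "read_bed",
    "fixed_width_recoordinate",
]


@dataclass(frozen=True)
class ScanConfig:
    width: int = 150
    step: int = 1
    target_period: int = 10
    embedded: str = "ipdft"
    R: int = 250
    alpha: float = 0.05
    seed: int = 0
    max_ambiguity_fraction: float = 0.1
    p_min: int = 2
    p_max: int = 20
    test_all_windows: bool = False  # unconditional BWB (small inputs only)

    def __post_init__(self) -> None:
        if self.width < 2 or self.step < 1:
            raise ValueError("need width >= 2 and step >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"need 0 < alpha < 1, got {self.alpha}")

    @property
    def prange(self) -> PeriodRange:
        return PeriodRange(self.p_min, self.p_max)


@dataclass(frozen=True)
class WindowRecord:
    chrom: str
    start: int
    end: int
    dominant: Optional[int]
    observed_stat: float
    p_bwb: Optional[float]

    def significant(self, alpha: float) -> bool:
        return self.p_bwb is not None and self.p_bwb < alpha


@dataclass(frozen=True)
class GenomicSegment:
    chrom: str
    start: int
    end: int
    n_windows: int
    min_p_bwb: Optional[float]
    significant: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def scan(
    genome: Iterable[SymbolicFragment],
    symbol_set: SymbolSet = NPS_DINUCLEOTIDES,
    config: ScanConfig = ScanConfig(),
) -> List[WindowRecord]:
    """Sliding-window scan of a genome; see module docstring for the protocol."""
    records: List[WindowRecord] = []
    k = symbol_set.k
    for ci, frag in enumerate(genome):
        N = frag.N
        if N < config.width:
            continue
        arr = np.frombuffer(frag.symbols.encode("ascii"), dtype="S1")
        genome_ind = indicator(frag, symbol_set).values
        ambiguous = ~np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
        starts = np.arange(0, N - config.width + 1, config.step)
        W = sliding_window_view(genome_ind, config.width)[:: config.step].astype(np.uint8).copy()
        if k > 1:
            W[:, -(k - 1):] = 0  # k-mers may not cross the window's right edge
        amb_cum = np.concatenate([[0], np.cumsum(ambiguous)])
        amb_count = amb_cum[starts + config.width] - amb_cum[starts]
        keep = amb_count <= config.max_ambiguity_fraction * config.width
        dominants = np.zeros(starts.size, dtype=int)
        dominants[keep] = dominant_of_matrix(W[keep], config.embedded, config.prange)
        # per-period observed stats for reporting
        from .estimators import stat_matrix

        obs = stat_matrix(W, config.embedded, config.target_period)
        for wi, s in enumerate(starts):
            if not keep[wi]:
                continue
            dom = int(dominants[wi]) or None
            p_val: Optional[float] = None
            if dom == config.target_period or (config.test_all_windows and dom is not None):
                window_frag = SymbolicFragment(
                    seq_id=frag.seq_id,
                    symbols=frag.symbols[s : s + config.width],
                    start=frag.start + int(s),
                )
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(ci, int(s)))
                )
                cfg = BootstrapConfig(
                    R=config.R, embedded=config.embedded, alpha=config.alpha
                )
                p_val = bwb_pvalue(
                    window_frag, config.target_period, cfg, symbol_set, rng=rng
                ).p_value
            records.append(
                WindowRecord(
                    chrom=frag.seq_id,
                    start=frag.start + int(s),
                    end=frag.start + int(s) + config.width,
                    dominant=dom,
                    observed_stat=float(obs[wi]),
                    p_bwb=p_val,
                )
            )
    return records


def _check_sorted(windows: Sequence[WindowRecord]) -> None:
    keys = [(w.chrom, w.start) for w in windows]
    if keys != sorted(keys):
        raise ValueError("windows must be sorted by (chrom, start)")


def merge(
    windows: Sequence[WindowRecord],
    alpha: float = 0.05,
    mode: str = "flag",
) -> List[GenomicSegment]:
    """Merge overlapping or book-ended windows into segments.

    ``mode='flag'`` merges every input window and flags segments containing
    at least one window with ``P_BWB < alpha``; ``mode='significant'``
    merges only the significant windows (all resulting segments are
    significant).  Input must be sorted by (chrom, start).
    """
    if mode not in ("flag", "significant"):
        raise ValueError(f"unknown merge mode {mode!r}")
    _check_sorted(windows)
    if mode == "significant":
        windows = [w for w in windows if w.significant(alpha)]
    segments: List[GenomicSegment] = []
    cur: Optional[dict] = None
    for w in windows:
        if cur is not None and w.chrom == cur["chrom"] and w.start <= cur["end"]:
            cur["end"] = max(cur["end"], w.end)
            cur["n"] += 1
            if w.p_bwb is not None:
                cur["min_p"] = w.p_bwb if cur["min_p"] is None else min(cur["min_p"], w.p_bwb)
            cur["sig"] = cur["sig"] or w.significant(alpha)
        else:
            if cur is not None:
                segments.append(_close(cur))
            cur = {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n": 1,
                "min_p": w.p_bwb,
                "sig": w.significant(alpha),
            }
    if cur is not None:
        segments.append(_close(cur))
    return segments


def _close(cur: dict) -> GenomicSegment:
    return GenomicSegment(
        chrom=cur["chrom"],
        start=cur["start"],
        end=cur["end"],
        n_windows=cur["n"],
        min_p_bwb=cur["min_p"],
        significant=cur["sig"],
    )


def coverage(
    segments: Sequence[GenomicSegment], genome_sizes: Mapping[str, int]
) -> Dict[str, float]:
    """Fraction of each chromosome (and 'total') covered by the segments."""
    per_chrom: Dict[str, int] = {c: 0 for c in genome_sizes}
    for seg in segments:
        if seg.chrom not in per_chrom:
            raise KeyError(f"segment chromosome {seg.chrom!r} not in genome sizes")
        per_chrom[seg.chrom] += seg.length
    out = {c: per_chrom[c] / genome_sizes[c] for c in genome_sizes}
    total_len = sum(genome_sizes.values())
    out["total"] = sum(per_chrom.values()) / total_len if total_len else 0.0
    return out


def write_bed(segments: Sequence[GenomicSegment], path) -> None:
    """Write segments as BED4; name column carries the minimum P_BWB."""
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for seg in segments:
            name = "P=NA" if seg.min_p_bwb is None else f"P={seg.min_p_bwb:g}"
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{name}\n")


def read_bed(path) -> List[Tuple[str, int, int, str]]:
    """Strict BED4 reader (comment lines skipped); returns (chrom, start, end, name)."""
    out: List[Tuple[str, int, int, str]] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end must exceed start")
            out.append((chrom, start, end, name))
    return out


def fixed_width_recoordinate(
    intervals: Sequence[Tuple[str, int, int]],
    width: int,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> List[Tuple[str, int, int]]:
    """Symmetrically expand/contract intervals to a fixed width; keep independents.

    The odd remainder of an expansion (or contraction) is assigned to the 5'
    side.  Adjusted intervals that would extend past chromosome bounds are
    dropped with a warning; adjusted intervals that overlap any other
    adjusted interval are all dropped (independence requirement).
    """
    if width < 1:
        raise ValueError(f"need width >= 1, got {width}")
    adjusted: List[Tuple[str, int, int]] = []
    for chrom, start, end in intervals:
        delta = width - (end - start)
        left = (delta + 1) // 2
        new_start = start - left
        new_end = new_start + width
        if new_start < 0 or (
            chrom_sizes is not None and chrom in chrom_sizes and new_end > chrom_sizes[chrom]
        ):
            warnings.warn(
                f"interval {chrom}:{start}-{end} dropped: adjusted coordinates out of bounds"
            )
            continue
        adjusted.append((chrom, new_start, new_end))
    # independence: drop every interval overlapping any other
    keep = []
    srt = sorted(range(len(adjusted)), key=lambda i: (adjusted[i][0], adjusted[i][1]))
    overlapping = set()
    for a, b in zip(srt, srt[1:]):
        ca, sa, ea = adjusted[a]
        cb, sb, eb = adjusted[b]
        if ca == cb and sb < ea:
            overlapping.add(a)
            overlapping.add(b)
    return [iv for i, iv in enumerate(adjusted) if i not in overlapping]
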