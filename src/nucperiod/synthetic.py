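"""Generators for the simulation studies: eroded, approximate and null data.

Three degradation models of a perfect period-10 indicator of length N = 150
(the approximate length of nucleosome-associated DNA):

* **erosion** — flip exactly ``round(fraction * N)`` distinct indicator
  positions chosen uniformly without replacement (the substitution model:
  member dinucleotides replaced by non-members and vice versa), swept in the
  studies from 1% to 50%;
* **approximate periodicity** — inter-occurrence gaps drawn from
  ``Normal(10, sigma)`` and rounded to integers (the insertion/deletion
  model), sigma swept over [0.1, 3];
* **permutation** — a uniform random permutation of positions, preserving
  composition exactly; used as the true-negative class for ROC studies.

All generators are bit-reproducible given a seed; panels derive one child
seed per (level, replicate) cell so the replicate streams are independent of
panel shape.  A small planted-genome builder provides the end-to-end scan
fixture: period-10 blocks of TA dinucleotides separated by spacers that, by
default, contain no NPS dinucleotide at all (C/G only), so the expected
discovery set is exactly the planted blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Literal, Optional, Sequence, Union

import numpy as np

from .seqs import IndicatorSequence, SymbolicFragment, perfect_periodic

__all__ = [
    "PanelItem",
    "erode",
    "approximate_periodic",
    "permute",
    "eroded_panel",
    "approximate_panel",
    "roc_positives",
    "roc_negatives",
    "planted_genome",
]


@dataclass(frozen=True)
class PanelItem:
    """One labeled replicate of a synthetic panel."""

    level: float
    replicate: int
    seed: int
    x: IndicatorSequence


def _rng_of(rng_or_seed: Union[np.random.Generator, int, None]) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def erode(x: IndicatorSequence, fraction: float, rng: Union[np.random.Generator, int, None] = None) -> IndicatorSequence:
    """Flip exactly round(fraction * N) distinct positions of the indicator."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"need 0 <= fraction <= 1, got {fraction}")
    rng = _rng_of(rng)
    n_flip = int(round(fraction * x.N))
    values = x.values.copy()
    if n_flip:
        pos = rng.choice(x.N, size=n_flip, replace=False)
        values[pos] ^= 1
    return IndicatorSequence(values=values, seq_id=f"{x.seq_id}|eroded{fraction:g}")


def approximate_periodic(
    sigma: float,
    N: int = 150,
    mean_period: float = 10.0,
    rng: Union[np.random.Generator, int, None] = None,
) -> IndicatorSequence:
    """Indicator with Gaussian inter-occurrence gaps, mean ``mean_period``.

    Gaps are rounded to integers and redrawn if they round below 1; the
    first occurrence sits at a uniformly random integer phase in
    [0, mean_period).  ``sigma = 0`` reduces to perfect periodicity.
    """
    if sigma < 0:
        raise ValueError(f"need sigma >= 0, got {sigma}")
    if mean_period < 2:
        raise ValueError(f"need mean_period >= 2, got {mean_period}")
    rng = _rng_of(rng)
    values = np.zeros(N, dtype=np.uint8)
    pos = int(rng.integers(0, int(mean_period)))
    while pos < N:
        values[pos] = 1
        gap = int(round(rng.normal(mean_period, sigma))) if sigma > 0 else int(round(mean_period))
        while gap < 1:
            gap = int(round(rng.normal(mean_period, sigma)))
        pos += gap
    return IndicatorSequence(values=values, seq_id=f"approx_sigma{sigma:g}")


def permute(
    source: Union[IndicatorSequence, SymbolicFragment],
    rng: Union[np.random.Generator, int, None] = None,
):
    """Uniform random permutation of positions; composition exactly preserved."""
    rng = _rng_of(rng)
    if isinstance(source, SymbolicFragment):
        arr = np.frombuffer(source.symbols.encode("ascii"), dtype="S1")
        out = rng.permutation(arr)
        return SymbolicFragment(
            seq_id=f"{source.seq_id}|perm", symbols=out.tobytes().decode("ascii"), start=source.start
        )
    return IndicatorSequence(values=rng.permutation(source.values), seq_id=f"{source.seq_id}|perm")


def _child_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def eroded_panel(
    levels: Sequence[float],
    per_level: int = 100,
    base_seed: int = 0,
    N: int = 150,
    p: int = 10,
) -> List[PanelItem]:
    """Fresh perfect period-p sequences (random phase) eroded at each level."""
    items: List[PanelItem] = []
    for li, level in enumerate(levels):
        for rep in range(per_level):
            seed = _child_seed(base_seed, li, rep)
            rng = np.random.default_rng(seed)
            base = perfect_periodic(N, p, int(rng.integers(0, p)))
            items.append(PanelItem(level=float(level), replicate=rep, seed=seed, x=erode(base, level, rng)))
    return items


def approximate_panel(
    sigmas: Sequence[float],
    per_level: int = 100,
    base_seed: int = 0,
    N: int = 150,
    mean_period: float = 10.0,
) -> List[PanelItem]:
    """Approximately periodic sequences at each sigma level."""
    items: List[PanelItem] = []
    for li, sigma in enumerate(sigmas):
        for rep in range(per_level):
            seed = _child_seed(base_seed, 1000 + li, rep)
            rng = np.random.default_rng(seed)
            items.append(
                PanelItem(
                    level=float(sigma),
                    replicate=rep,
                    seed=seed,
                    x=approximate_periodic(sigma, N=N, mean_period=mean_period, rng=rng),
                )
            )
    return items


def roc_positives(
    kind: Literal["eroded", "approximate"],
    n: int = 1000,
    base_seed: int = 0,
    N: int = 150,
    p: int = 10,
) -> List[PanelItem]:
    """True-positive ROC panel.

    ``eroded``: erosion swept uniformly over 1..50% (the full-scale study
    used 20 instances per 1% increment, n = 1000).  ``approximate``: sigma
    swept over [0.2, 4] (50 instances per 0.2 increment at full scale).
    Any ``n`` keeps the same level grid with proportionally many replicates.
    """
    if kind == "eroded":
        levels = [round(0.01 * (1 + i * 49 / max(n - 1, 1)), 4) for i in range(n)]
        per = {}
        items = []
        for i, level in enumerate(levels):
            seed = _child_seed(base_seed, 2000, i)
            rng = np.random.default_rng(seed)
            base = perfect_periodic(N, p, int(rng.integers(0, p)))
            items.append(PanelItem(level=level, replicate=i, seed=seed, x=erode(base, level, rng)))
        return items
    if kind == "approximate":
        items = []
        for i in range(n):
            sigma = round(0.2 + i * 3.8 / max(n - 1, 1), 4)
            seed = _child_seed(base_seed, 3000, i)
            rng = np.random.default_rng(seed)
            items.append(
                PanelItem(level=sigma, replicate=i, seed=seed, x=approximate_periodic(sigma, N=N, rng=rng))
            )
        return items
    raise ValueError(f"unknown panel kind {kind!r}")


def roc_negatives(positives: Iterable[PanelItem], base_seed: int = 0) -> List[PanelItem]:
    """True-negative panel: random permutations of the positive sequences."""
    items = []
    for i, item in enumerate(positives):
        seed = _child_seed(base_seed, 4000, i)
        items.append(
            PanelItem(level=item.level, replicate=i, seed=seed, x=permute(item.x, np.random.default_rng(seed)))
        )
    return items


def planted_genome(
    n_blocks: int = 5,
    block_length: int = 300,
    spacer_length: int = 500,
    p: int = 10,
    base_seed: int = 0,
    at_fraction: float = 0.0,
    seq_id: str = "synthchr1",
) -> tuple[SymbolicFragment, List[tuple[int, int]]]:
    """Synthetic chromosome with planted period-10 NPS blocks.

    Blocks carry a TA dinucleotide every ``p`` positions on a C/G
    background; spacers are random C/G sequence (optionally salted with
    A/T at ``at_fraction``, which re-introduces background NPS matches).
    Returns the fragment and the planted block intervals (0-based
    half-open).
    """
    rng = np.random.default_rng(_child_seed(base_seed, 5000))

    def spacer(n: int) -> str:
        if at_fraction > 0.0:
            probs = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
            return "".join(rng.choice(list("ACGT"), size=n, p=probs))
        return "".join(rng.choice(list("CG"), size=n))

    def block() -> str:
        chars = np.array(list(spacer(block_length)))
        for start in range(0, block_length - 1, p):
            chars[start] = "T"
            chars[start + 1] = "A"
        return "".join(chars)

    parts: List[str] = []
    intervals: List[tuple[int, int]] = []
    pos = 0
    for b in range(n_blocks):
        sp = spacer(spacer_length)
        parts.append(sp)
        pos += len(sp)
        blk = block()
        intervals.append((pos, pos + len(blk)))
        parts.append(blk)
        pos += len(blk)
    parts.append(spacer(spacer_length))
    return SymbolicFragment(seq_id=seq_id, symbols="".join(parts)), intervals
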