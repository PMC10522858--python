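"""Per-round clonotype statistics: abundance, rankings, trajectories,
length distributions, and the cross-library shared-clonotype correlation.

Clonotype identity is the exact CDR3 amino-acid sequence; abundance is
100 x count / total over the CDR3-bearing reads of the round.
"""
from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats as _scipy_stats

from .annotate import Cdr3Record
from .errors import UndefinedStatisticError
from .seqio import RoundTable, sorted_clonotypes


def tally(records: Iterable[Cdr3Record], label: str) -> RoundTable:
    """Build a RoundTable from extracted CDR3 records of one library x round.

    rep_nt is the most frequent nucleotide variant per amino-acid clonotype
    (ties broken by lexicographically smallest nucleotide string).
    """
    counts: Counter[str] = Counter()
    nt_variants: dict[str, Counter[str]] = defaultdict(Counter)
    for rec in records:
        counts[rec.aa] += 1
        nt_variants[rec.aa][rec.nt] += 1
    rep_nt = {
        aa: min(variants.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        for aa, variants in nt_variants.items()
    }
    return RoundTable(label=label, counts=dict(counts), rep_nt=rep_nt)


def abundance(table: RoundTable, cdr3: str) -> float:
    """Abundance of a clonotype as a percentage of the round's CDR3 reads."""
    total = table.total
    if total == 0:
        raise UndefinedStatisticError(f"{table.label}: abundance undefined on empty table")
    return 100.0 * table.counts.get(cdr3, 0) / total


def top_n(table: RoundTable, n: int) -> list[tuple[str, int, float]]:
    """Top-n clonotypes as (cdr3, count, abundance_pct), count-desc order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    total = table.total
    ranked = sorted_clonotypes(table)[:n]
    return [(c, table.counts[c], 100.0 * table.counts[c] / total) for c in ranked]


@dataclass
class Trajectory:
    cdr3: str
    points: list[tuple[str, float]]  # (round label, abundance %)


def trajectory(tables: Sequence[RoundTable], cdr3: str) -> Trajectory:
    """Abundance of one clonotype across round-ordered tables (0 when absent)."""
    return Trajectory(
        cdr3=cdr3, points=[(t.label, abundance(t, cdr3)) for t in tables]
    )


@dataclass
class LengthStats:
    histogram: dict[int, int]  # length (aa) -> number of unique CDR3s
    median: int
    max: int

    @property
    def n_unique(self) -> int:
        return sum(self.histogram.values())


def length_stats(table: RoundTable) -> LengthStats:
    """Length distribution over UNIQUE CDR3 sequences (not read-weighted).

    The median is the lower median for even-sized sets.
    """
    if not table.counts:
        raise UndefinedStatisticError(f"{table.label}: length stats undefined on empty table")
    lengths = sorted(len(c) for c in table.counts)
    histogram = dict(sorted(Counter(lengths).items()))
    median = lengths[(len(lengths) - 1) // 2]
    return LengthStats(histogram=histogram, median=median, max=lengths[-1])


def shared_abundance_correlation(
    a: RoundTable, b: RoundTable, log: bool = False
) -> tuple[float, int]:
    """Pearson r of paired abundances over clonotypes present in BOTH tables.

    Clonotypes seen in only one library are excluded. Raw abundances by
    default; log=True correlates natural-log abundances instead.
    """
    if not a.counts or not b.counts:
        raise UndefinedStatisticError("correlation undefined on an empty table")
    shared = sorted(set(a.counts) & set(b.counts))
    n_shared = len(shared)
    if n_shared < 3:
        raise UndefinedStatisticError(
            f"only {n_shared} shared clonotypes between {a.label} and {b.label}; need >= 3"
        )
    xs = [abundance(a, c) for c in shared]
    ys = [abundance(b, c) for c in shared]
    if log:
        import math

        xs = [math.log(x) for x in xs]
        ys = [math.log(y) for y in ys]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise UndefinedStatisticError("zero variance in a paired abundance vector")
    r = float(_scipy_stats.pearsonr(xs, ys).statistic)
    return r, n_shared


def write_trajectories_tsv(path: str, trajectories: Sequence[Trajectory]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("cdr3\tround\tabundance_pct\n")
        for traj in trajectories:
            for label, pct in traj.points:
                out.write(f"{traj.cdr3}\t{label}\t{pct:.6f}\n")


def write_comparison_json(
    path: str, a: RoundTable, b: RoundTable, r: float, n_shared: int
) -> None:
    shared = sorted(set(a.counts) & set(b.counts))
    payload = {
        "labels": [a.label, b.label],
        "r": r,
        "n_shared": n_shared,
        "pairs": {c: [abundance(a, c), abundance(b, c)] for c in shared},
    }
    with open(path, "w", encoding="utf-8") as out:
        json.dump(payload, out, indent=1)
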