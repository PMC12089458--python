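"""Venn partitioning, GOF/LOF classification and overlap odds ratios.

Per-line results (differentially expressed genes at adjusted p < 0.05, or
dysregulated pathways) are treated as named sets over a universe.  The
module provides:

* the full Venn partition of 2–4 sets (optionally split by up/down
  direction);
* the gain-/loss-of-function partition against a knockout line: changes
  shared by all mutant lines that also appear in the knockout reflect loss
  of function (LOF); shared changes absent from the knockout are bona fide
  gain-of-function (GOF) candidates;
* pairwise overlap statistics: a 2×2 table of membership over the universe,
  the (log2) odds ratio with a Haldane–Anscombe +0.5 correction applied only
  when a zero cell occurs, a two-sided Fisher exact p-value, and
  Benjamini–Hochberg adjustment across all pairs of one invocation, with a
  flag for odds ratios larger than five-fold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DirectionalSetCollection",
    "VennPartition",
    "OverlapStat",
    "venn_partition",
    "gof_lof_partition",
    "overlap_odds",
    "pairwise_overlap_odds",
    "percent_overlap",
    "read_gmt",
    "write_gmt",
]


@dataclass
class DirectionalSetCollection:
    """Named sets whose members carry an up/down direction label.

    ``sets`` maps set name → {member id → "up" | "down"}; ``universe`` is
    the collection of all tested ids and must contain every member.
    """

    sets: dict[str, dict[str, str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            extra = set(members) - self.universe
            if extra:
                raise ValueError(f"set {name!r} has members outside the universe: {sorted(extra)[:5]}")
            bad = {d for d in members.values()} - {"up", "down"}
            if bad:
                raise ValueError(f"set {name!r}: invalid directions {bad}")

    def members(self, name: str, direction: str | None = None) -> frozenset[str]:
        m = self.sets[name]
        if direction is None:
            return frozenset(m)
        return frozenset(k for k, d in m.items() if d == direction)

    @classmethod
    def from_tables(
        cls,
        tables: Mapping[str, pd.DataFrame],
        universe: Iterable[str] | None = None,
        id_col: str = "id",
        stat_col: str = "log2fc",
        padj_col: str = "padj",
        padj_threshold: float = 0.05,
    ) -> "DirectionalSetCollection":
        """Build sets from per-line result tables (DE genes or pathways).

        A row enters its line's set iff adjusted p < ``padj_threshold``; the
        direction comes from the sign of ``stat_col`` (log2 fold change or
        enrichment score).  Without an explicit universe, the union of all
        tested ids across tables is used.
        """
        sets: dict[str, dict[str, str]] = {}
        tested: set[str] = set()
        for name, df in tables.items():
            tested.update(df[id_col].astype(str))
            sig = df[df[padj_col] < padj_threshold]
            sets[name] = {
                str(r[id_col]): ("up" if r[stat_col] > 0 else "down")
                for _, r in sig.iterrows()
            }
        uni = frozenset(str(u) for u in universe) if universe is not None else frozenset(tested)
        return cls(sets=sets, universe=uni)


@dataclass
class VennPartition:
    """Disjoint Venn regions keyed by sorted '&'-joined set-name signatures."""

    regions: dict[str, frozenset[str]]
    set_names: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def reconstruct(self, name: str) -> frozenset[str]:
        """Union of all regions whose signature contains ``name``."""
        out: set[str] = set()
        for sig, members in self.regions.items():
            if name in sig.split("&"):
                out |= members
        return frozenset(out)


def region_label(names: Iterable[str]) -> str:
    return "&".join(sorted(names))


def venn_partition(sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition 2–4 named sets into their 2^k − 1 disjoint Venn regions."""
    names = list(sets)
    if len(names) != len(set(names)) or any(not n for n in names):
        raise ValueError("set names must be unique and non-empty")
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_partition supports 2-4 sets")
    as_sets = {n: frozenset(sets[n]) for n in names}
    regions: dict[str, frozenset[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = frozenset.intersection(*(as_sets[n] for n in combo))
            outside = frozenset.union(
                *(as_sets[n] for n in names if n not in combo), frozenset()
            )
            regions[region_label(combo)] = inside - outside
    return VennPartition(regions=regions, set_names=tuple(names))


def venn_partition_by_direction(
    collection: DirectionalSetCollection, names: Sequence[str] | None = None
) -> dict[str, VennPartition]:
    """Separate up- and down-regulated Venn partitions (red/blue columns)."""
    names = list(names) if names is not None else list(collection.sets)
    return {
        direction: venn_partition({n: collection.members(n, direction) for n in names})
        for direction in ("up", "down")
    }


def gof_lof_partition(
    mut1: Iterable[str], mut2: Iterable[str], mut3: Iterable[str], ko: Iterable[str]
) -> dict[str, frozenset[str]]:
    """Partition shared mutant changes into loss- and gain-of-function.

    ``shared_mutant`` is the three-way intersection of the mutant sets;
    members also present in the knockout are LOF, the remainder GOF.
    """
    shared = frozenset(mut1) & frozenset(mut2) & frozenset(mut3)
    ko_set = frozenset(ko)
    return {
        "shared_mutant": shared,
        "lof": shared & ko_set,
        "gof": shared - ko_set,
    }


@dataclass
class OverlapStat:
    """Pairwise overlap of two sets against a common universe."""

    set_a: str
    set_b: str
    table: tuple[tuple[int, int], tuple[int, int]]  # [[both, a_only], [b_only, neither]]
    intersection: int
    odds_ratio: float  # Haldane-Anscombe corrected iff a zero cell occurs
    odds_ratio_uncorrected: float  # inf/0/nan possible
    log2_odds_ratio: float
    fisher_p: float
    padj: float | None = None

    @property
    def five_fold(self) -> bool:
        return self.odds_ratio > 5.0


def _odds(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(corrected, uncorrected) odds ratio; +0.5 on all cells only if any is 0."""
    if min(a, b, c, d) == 0:
        corrected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        corrected = (a * d) / (b * c)
    uncorrected = (a * d) / (b * c) if b * c != 0 else float("inf") if a * d > 0 else float("nan")
    return corrected, uncorrected


def overlap_odds(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapStat:
    """Fisher-exact overlap of two sets over a universe.

    The 2×2 table counts universe items by joint membership; the odds ratio
    is positive in log2 when the overlap exceeds, and negative when it falls
    short of, what random selection from the universe would give.
    """
    uni = frozenset(universe)
    A, B = frozenset(set_a), frozenset(set_b)
    for name, s in ((name_a, A), (name_b, B)):
        extra = s - uni
        if extra:
            raise ValueError(f"set {name!r} not contained in universe: {sorted(extra)[:5]}")
    if not uni:
        raise ValueError("empty universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(uni) - a - b - c
    corrected, uncorrected = _odds(a, b, c, d)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OverlapStat(
        set_a=name_a,
        set_b=name_b,
        table=((a, b), (c, d)),
        intersection=a,
        odds_ratio=corrected,
        odds_ratio_uncorrected=uncorrected,
        log2_odds_ratio=math.log2(corrected) if corrected > 0 else float("-inf"),
        fisher_p=float(p),
    )


def pairwise_overlap_odds(
    sets: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None
) -> list[OverlapStat]:
    """All pairwise overlap tests with BH adjustment across the invocation.

    Without an explicit universe, the union of all provided sets is used —
    the overlap is judged "against all dysregulated" items of the run.
    """
    as_sets = {n: frozenset(v) for n, v in sets.items()}
    uni = frozenset(universe) if universe is not None else frozenset().union(*as_sets.values())
    results = [
        overlap_odds(as_sets[na], as_sets[nb], uni, na, nb)
        for na, nb in itertools.combinations(as_sets, 2)
    ]
    if results:
        _, padj, _, _ = multipletests([r.fisher_p for r in results], method="fdr_bh")
        for r, q in zip(results, padj):
            r.padj = float(q)
    return results


def percent_overlap(reference_set: Iterable[str], comparison_set: Iterable[str]) -> float:
    """Percentage of the reference set recovered by the comparison set.

    Full precision is returned; round to the nearest integer for reporting.
    """
    ref = frozenset(reference_set)
    if not ref:
        raise ValueError("empty reference set")
    return 100.0 * len(ref & frozenset(comparison_set)) / len(ref)


def overlap_table(stats_: Iterable[OverlapStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_a": s.set_a,
                "set_b": s.set_b,
                "intersection": s.intersection,
                "odds_ratio": s.odds_ratio,
                "log2_odds_ratio": s.log2_odds_ratio,
                "fisher_p": s.fisher_p,
                "padj": s.padj,
                "five_fold": s.five_fold,
            }
            for s in stats_
        ]
    )


def read_gmt(path) -> dict[str, frozenset[str]]:
    """Read plain gene sets from a GMT file (name, description, members...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
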