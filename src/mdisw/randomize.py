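"""Seeded randomisation for M-DISW-CRT trials.

Covers the three randomisation steps of the design:

* allocation of facilities to start-month strata (balanced permutation),
* for variant A, the split of each facility-selected pair of standards into
  "audit x first" / "audit y first", optimised so that each standard is
  audited as equally as possible across the two phases,
* for variant B, generation of row-complete (Williams) Latin squares of
  order 6 and their assignment to facilities and strata so that every
  standard is audited once or twice per phase within each stratum.

All functions are reproducible from a single integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .design_core import ScheduleError

__all__ = [
    "PairCountTable",
    "PhaseAllocation",
    "LatinSquare",
    "allocate_phase_order",
    "assign_strata",
    "assign_sequences_A",
    "complete_latin_squares",
    "assign_rows_B",
]


def _norm_pair(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    if a == b:
        raise ValueError(f"pair must contain two distinct standards, got {pair!r}")
    return (a, b) if a <= b else (b, a)


@dataclass
class PairCountTable:
    """Counts of facilities selecting each unordered pair of standards."""

    entries: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        normed: dict[tuple[str, str], int] = {}
        for pair, count in self.entries.items():
            count = int(count)
            if count < 0:
                raise ValueError("pair counts must be nonnegative")
            key = _norm_pair(tuple(pair))
            normed[key] = normed.get(key, 0) + count
        self.entries = normed

    @property
    def n_facilities(self) -> int:
        return sum(self.entries.values())

    def standards(self) -> list[str]:
        return sorted({s for pair in self.entries for s in pair})

    def selection_totals(self) -> dict[str, int]:
        """How many facilities selected each standard (for audit in either phase)."""
        totals = {s: 0 for s in self.standards()}
        for (a, b), count in self.entries.items():
            totals[a] += count
            totals[b] += count
        return totals


@dataclass
class PhaseAllocation:
    """Counts of facilities auditing (first_standard, second_standard) in that order."""

    entries: dict[tuple[str, str], int]

    def phase_totals(self) -> dict[str, tuple[int, int]]:
        """Per standard, (number audited in phase 1, number audited in phase 2)."""
        firsts: dict[str, int] = {}
        seconds: dict[str, int] = {}
        for (a, b), count in self.entries.items():
            firsts[a] = firsts.get(a, 0) + count
            seconds[b] = seconds.get(b, 0) + count
        stds = sorted(set(firsts) | set(seconds))
        return {s: (firsts.get(s, 0), seconds.get(s, 0)) for s in stds}

    def max_imbalance(self) -> int:
        """Largest per-standard |phase-1 total - phase-2 total|."""
        return max(abs(f - s) for f, s in self.phase_totals().values())

    def consistent_with(self, pairs: PairCountTable) -> bool:
        got: dict[tuple[str, str], int] = {}
        for (a, b), count in self.entries.items():
            key = _norm_pair((a, b))
            got[key] = got.get(key, 0) + count
        return got == {k: v for k, v in pairs.entries.items() if v > 0}


# ---------------------------------------------------------------------------
# Phase-order balancing (variant A)
# ---------------------------------------------------------------------------


def allocate_phase_order(pairs: PairCountTable, seed: int | None = 0) -> PhaseAllocation:
    """Split each pair's facilities between the two phase orders, optimally.

    For a pair {x, y} selected by c facilities, k of them audit x first and
    c - k audit y first.  The split vector is chosen to minimise the maximum
    over standards of |phase-1 total - phase-2 total|; among optima, the one
    with the lexicographically smallest sorted imbalance vector is preferred,
    then the one with the most even per-pair splits (so pairs selected by six
    or more facilities can occupy all six of their sequences), and any
    remaining tie is broken by a seeded uniform draw.

    The search is exact: a branch-and-bound enumeration over split vectors
    with per-standard pruning, equivalent to brute force.
    """
    active = [(pair, c) for pair, c in sorted(pairs.entries.items()) if c > 0]
    if not active:
        raise ValueError("pair count table is empty")
    stds = sorted({s for pair, _ in active for s in pair})
    idx = {s: i for i, s in enumerate(stds)}
    # remaining[i][x] = max further |contribution| to standard x from pairs i..
    n = len(active)
    remaining = np.zeros((n + 1, len(stds)), dtype=int)
    for i in range(n - 1, -1, -1):
        remaining[i] = remaining[i + 1]
        (a, b), c = active[i]
        remaining[i] = remaining[i].copy()
        remaining[i][idx[a]] += c
        remaining[i][idx[b]] += c

    best_max = int(remaining[0].max())  # upper bound: everything one-sided

    # Pass 1: find the optimal max imbalance by iterative deepening.
    def feasible(bound: int, collect: list | None, cap: int) -> bool:
        imb = np.zeros(len(stds), dtype=int)
        found = False

        def rec(i: int) -> bool:
            nonlocal found
            if collect is not None and len(collect) >= cap:
                return True
            if i == n:
                if collect is not None:
                    collect.append(tuple(choice))
                found = True
                return collect is None  # stop early only when not collecting
            (a, b), c = active[i]
            ia, ib = idx[a], idx[b]
            # try deviations d = 2k - c from most balanced outwards
            ds = sorted(range(-c, c + 1, 2), key=abs)
            for d in ds:
                imb[ia] += d
                imb[ib] -= d
                ok = True
                for j in (ia, ib):
                    if abs(imb[j]) > bound + remaining[i + 1][j]:
                        ok = False
                        break
                if ok:
                    choice[i] = (c + d) // 2
                    if rec(i + 1):
                        imb[ia] -= d
                        imb[ib] += d
                        return True
                imb[ia] -= d
                imb[ib] += d
            return False

        choice = [0] * n
        rec(0)
        return found

    opt = None
    for bound in range(0, best_max + 1):
        if feasible(bound, None, 0):
            opt = bound
            break
    assert opt is not None

    # Pass 2: collect optimal split vectors (capped) and refine the tie-break.
    solutions: list[tuple[int, ...]] = []
    feasible(opt, solutions, 200_000)

    def sorted_imbalance(ks: tuple[int, ...]) -> tuple[int, ...]:
        imb = np.zeros(len(stds), dtype=int)
        for ((a, b), c), k in zip(active, ks):
            imb[idx[a]] += 2 * k - c
            imb[idx[b]] -= 2 * k - c
        return tuple(sorted(int(abs(v)) for v in imb))

    def unevenness(ks: tuple[int, ...]) -> int:
        return sum(abs(2 * k - c) for (_, c), k in zip(active, ks))

    best_vec = min(sorted_imbalance(ks) for ks in solutions)
    tied = [ks for ks in solutions if sorted_imbalance(ks) == best_vec]
    best_even = min(unevenness(ks) for ks in tied)
    tied = [ks for ks in tied if unevenness(ks) == best_even]
    rng = np.random.default_rng(seed)
    ks = tied[int(rng.integers(len(tied)))]

    entries: dict[tuple[str, str], int] = {}
    for ((a, b), c), k in zip(active, ks):
        if k:
            entries[(a, b)] = k
        if c - k:
            entries[(b, a)] = c - k
    return PhaseAllocation(entries)


# ---------------------------------------------------------------------------
# Stratum assignment
# ---------------------------------------------------------------------------


def assign_strata(
    facility_ids: Sequence[str], n_strata: int, seed: int | None = 0
) -> dict[str, int]:
    """Randomise facilities to start-month strata with sizes differing by <= 1."""
    ids = list(facility_ids)
    if not ids:
        raise ValueError("facility list is empty")
    if len(set(ids)) != len(ids):
        raise ValueError("facility ids must be unique")
    if n_strata < 1:
        raise ValueError("need at least one stratum")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return {ids[int(j)]: (pos % n_strata) + 1 for pos, j in enumerate(order)}


# ---------------------------------------------------------------------------
# Variant A sequence assignment
# ---------------------------------------------------------------------------


def _spread(items: list, n_bins: int, rng: np.random.Generator) -> list[list]:
    """Deal items into n_bins as evenly as possible, random order of bins."""
    items = list(items)
    rng.shuffle(items)
    sizes = [len(items) // n_bins] * n_bins
    for j in rng.permutation(n_bins)[: len(items) % n_bins]:
        sizes[int(j)] += 1
    bins: list[list] = []
    start = 0
    for size in sizes:
        bins.append(items[start : start + size])
        start += size
    return bins


def assign_sequences_A(
    pairs: PairCountTable,
    allocation: PhaseAllocation,
    seed: int | None = 0,
    facility_ids: Mapping[tuple[str, str], Sequence[str]] | None = None,
) -> list[tuple[str, str, str, int]]:
    """Assign facilities to the six sequences (3 strata x 2 orders) per pair.

    Returns (facility_id, first_standard, second_standard, stratum) rows for
    :func:`~mdisw.design_core.build_schedule_A`.  Within each pair, the
    facilities auditing a given order are spread over the three strata as
    evenly as the counts permit, so a pair selected by six or more facilities
    with a balanced order split occupies all six sequences.

    ``facility_ids`` optionally maps each unordered pair to the ids of the
    facilities that selected it; by default ids f01, f02, ... are generated
    in sorted-pair order.
    """
    if not allocation.consistent_with(pairs):
        raise ValueError("phase allocation is inconsistent with the pair counts")
    rng = np.random.default_rng(seed)
    ids_by_pair: dict[tuple[str, str], list[str]] = {}
    cursor = 0
    for pair, count in sorted(pairs.entries.items()):
        if facility_ids is not None:
            ids = list(facility_ids[pair])
            if len(ids) != count:
                raise ValueError(f"need {count} facility ids for pair {pair}")
        else:
            ids = [f"f{cursor + k + 1:02d}" for k in range(count)]
            cursor += count
        ids_by_pair[pair] = ids

    out: list[tuple[str, str, str, int]] = []
    for pair, count in sorted(pairs.entries.items()):
        if count == 0:
            continue
        pool = list(ids_by_pair[pair])
        rng.shuffle(pool)
        a, b = pair
        k_ab = allocation.entries.get((a, b), 0)
        groups = [((a, b), pool[:k_ab]), ((b, a), pool[k_ab:])]
        for (first, second), members in groups:
            for stratum, bin_members in enumerate(_spread(members, 3, rng), start=1):
                for fid in bin_members:
                    out.append((fid, first, second, stratum))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Latin squares (variant B)
# ---------------------------------------------------------------------------


@dataclass
class LatinSquare:
    """An order-n Latin square of standard ids, required to be row-complete.

    Row-complete (Williams) squares have every ordered pair of distinct
    symbols horizontally adjacent exactly once, which balances first-order
    carry-over between consecutively audited standards.
    """

    order: int
    rows: list[list[str]] = field(default_factory=list)

    def validate(self) -> list[str]:
        problems: list[str] = []
        symbols = sorted({s for row in self.rows for s in row})
        if len(self.rows) != self.order or any(len(r) != self.order for r in self.rows):
            problems.append("square must be order x order")
            return problems
        if len(symbols) != self.order:
            problems.append("square must use exactly `order` symbols")
        for i, row in enumerate(self.rows):
            if sorted(row) != symbols:
                problems.append(f"row {i} repeats a symbol")
        for j in range(self.order):
            col = sorted(row[j] for row in self.rows)
            if col != symbols:
                problems.append(f"column {j} repeats a symbol")
        adjacencies = [
            (row[j], row[j + 1]) for row in self.rows for j in range(self.order - 1)
        ]
        if len(set(adjacencies)) != len(adjacencies) or len(adjacencies) != self.order * (
            self.order - 1
        ):
            problems.append("square is not row-complete")
        return problems


def _williams_base(order: int) -> list[list[int]]:
    """Williams' column-cyclic row-complete square for even order.

    First row 1, 2, n, 3, n-1, 4, ...; subsequent rows add 1 mod n.
    """
    if order % 2 != 0:
        raise ValueError("row-complete construction implemented for even order only")
    first: list[int] = []
    lo, hi = 1, order
    for j in range(order):
        first.append(lo if j % 2 == 0 else hi)
        if j % 2 == 0:
            lo += 1
        else:
            hi -= 1
    return [[(v - 1 + i) % order for v in first] for i in range(order)]


def complete_latin_squares(
    standards: Sequence[str], n_squares: int, seed: int | None = 0
) -> list[LatinSquare]:
    """Generate seeded random row-complete Latin squares over six standards.

    Each square is Williams' base square under an independent random symbol
    relabelling and row permutation (both operations preserve the Latin and
    row-complete properties).
    """
    standards = list(standards)
    if len(standards) != 6:
        raise ValueError("construction requires exactly 6 standards")
    if n_squares < 1:
        raise ValueError("need at least one square")
    rng = np.random.default_rng(seed)
    base = _williams_base(6)
    squares: list[LatinSquare] = []
    for _ in range(n_squares):
        relabel = rng.permutation(6)
        row_order = rng.permutation(6)
        rows = [[standards[int(relabel[v])] for v in base[int(i)]] for i in row_order]
        squares.append(LatinSquare(order=6, rows=rows))
    return squares


def assign_rows_B(
    squares: Sequence[LatinSquare],
    facility_ids: Sequence[str],
    seed: int | None = 0,
) -> list[tuple[str, list[str], int]]:
    """Assign 18 facilities to Latin-square rows across two strata.

    One whole square is embedded in each stratum; the rows of the third
    square are split 3/3 between the strata at random.  Because every column
    of a Latin square contains each standard once, every standard is audited
    once or twice per phase in each stratum, and exactly three times per
    phase overall.  Returns (facility_id, standard order, stratum) rows for
    :func:`~mdisw.design_core.build_schedule_B`.
    """
    squares = list(squares)
    ids = list(facility_ids)
    if len(squares) != 3:
        raise ValueError("exactly three Latin squares are required")
    if any(sq.order != 6 for sq in squares):
        raise ValueError("squares must be of order 6")
    if len(ids) != 18 or len(set(ids)) != 18:
        raise ValueError("exactly 18 distinct facility ids are required")
    rng = np.random.default_rng(seed)
    roles = rng.permutation(3)  # whole-square for stratum 1, stratum 2, split square
    whole1, whole2, split = (squares[int(i)] for i in roles)
    split_rows = [list(r) for r in split.rows]
    picks = sorted(int(i) for i in rng.choice(6, size=3, replace=False))
    stratum_rows = {
        1: [list(r) for r in whole1.rows] + [split_rows[i] for i in picks],
        2: [list(r) for r in whole2.rows]
        + [split_rows[i] for i in range(6) if i not in picks],
    }
    id_order = [ids[int(i)] for i in rng.permutation(18)]
    out: list[tuple[str, list[str], int]] = []
    pos = 0
    for stratum in (1, 2):
        for row in stratum_rows[stratum]:
            out.append((id_order[pos], row, stratum))
            pos += 1
    out.sort(key=lambda r: r[0])
    return out


def phase_stratum_occupancy(
    row_assignment: Iterable[tuple[str, Sequence[str], int]],
) -> dict[tuple[int, int, str], int]:
    """Count, for each (phase, stratum, standard), the facilities auditing it."""
    occ: dict[tuple[int, int, str], int] = {}
    for _, order, stratum in row_assignment:
        for phase, std in enumerate(order, start=1):
            key = (phase, int(stratum), std)
            occ[key] = occ.get(key, 0) + 1
    return occ
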