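"""De novo linkage-map construction for selfed RIL genotypes.

Markers coded A/B/H/- are first merged into bins of redundant genotype
vectors, then grouped by two-point linkage (LOD >= 7 and recombinant-line
fraction <= 0.14 by default), attributed to chromosomes by the majority
putative assignment of their members, ordered within each chromosome by
minimising the sum of adjacent two-point distances (SARF), and finally
given cumulative cM positions.

Two-point analysis uses the Haldane–Waddington correction for selfed RILs:
the observed recombinant-line fraction R relates to the meiotic
recombination fraction r by R = 2r/(1+2r), and map distances follow the
Haldane function d = -50 ln(1-2r). Heterozygote calls are treated as
missing for mapping (the lines are ~98.5% homozygous).

Ordering is exact (Held–Karp dynamic programming) for small groups and a
greedy-insertion + simulated-annealing (2-opt) + exhaustive sliding-window
refinement for larger ones; results are deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from capmap.calling import CALL_A, CALL_B, MISSING

LOG10_2 = math.log10(2.0)

_EXACT_ORDER_MAX = 10  # Held-Karp DP bound; 2^n * n^2 work
_MAX_R_FOR_DISTANCE = 0.45  # numerical cap when converting an adjacent R to cM


# ---------------------------------------------------------------------------
# Map-function algebra
# ---------------------------------------------------------------------------


def rf_to_ril(r: float) -> float:
    """Meiotic recombination fraction r -> recombinant-RIL fraction R = 2r/(1+2r)."""
    return 2.0 * r / (1.0 + 2.0 * r)


def ril_to_rf(R: float) -> float:
    """Recombinant-RIL fraction R -> meiotic r = R/(2(1-R)), capped at 0.5."""
    if R >= 0.5:
        return 0.5
    return min(0.5, R / (2.0 * (1.0 - R)))


def haldane_cm(r: float) -> float:
    """Haldane map distance in cM, d = -50 ln(1-2r); infinite at r = 0.5."""
    if r >= 0.5:
        return math.inf
    return -50.0 * math.log1p(-2.0 * r)


def haldane_inv_cm(d: float) -> float:
    """Inverse Haldane: r = (1 - exp(-2d/100))/2."""
    return 0.5 * (1.0 - math.exp(-2.0 * d / 100.0))


def _lod(k: int, n: int) -> float:
    """LOD of linkage at the MLE R = k/n against free recombination."""
    if n == 0:
        raise ValueError("LOD undefined without shared informative lines")
    R = k / n
    if R >= 0.5:
        return 0.0
    lod = n * LOG10_2 + (n - k) * math.log10(1.0 - R)
    if k:
        lod += k * math.log10(R)
    return lod


@dataclass(frozen=True)
class TwoPointResult:
    R_hat: float  # recombinant-line fraction
    r: float  # meiotic recombination fraction (Haldane-Waddington corrected)
    lod: float
    d_cM: float
    n_shared: int
    n_recomb: int


def two_point(calls_1, calls_2) -> TwoPointResult | None:
    """Two-point linkage between two call vectors (H and missing excluded).

    Returns None when the markers share no informative line.
    """
    a = np.asarray(list(calls_1), dtype="<U1")
    b = np.asarray(list(calls_2), dtype="<U1")
    informative = np.isin(a, (CALL_A, CALL_B)) & np.isin(b, (CALL_A, CALL_B))
    n = int(informative.sum())
    if n == 0:
        return None
    k = int((a[informative] != b[informative]).sum())
    R = k / n
    r = ril_to_rf(R)
    return TwoPointResult(
        R_hat=R, r=r, lod=_lod(k, n), d_cM=haldane_cm(r), n_shared=n, n_recomb=k
    )


def two_point_matrix(genotypes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (R_hat, LOD, n_shared) for a loci x individuals matrix.

    Pairs with no shared informative line get R = NaN, LOD = 0, n = 0.
    """
    values = genotypes.to_numpy(dtype="<U1")
    is_a = (values == CALL_A).astype(np.float64)
    is_b = (values == CALL_B).astype(np.float64)
    shared = (is_a + is_b) @ (is_a + is_b).T
    agree = is_a @ is_a.T + is_b @ is_b.T
    recomb = shared - agree
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(shared > 0, recomb / np.maximum(shared, 1.0), np.nan)
        log_r = np.where(recomb > 0, np.log10(np.where(recomb > 0, R, 1.0)), 0.0)
        log_nr = np.where(R < 1.0, np.log10(np.maximum(1.0 - R, 1e-300)), 0.0)
        lod = shared * LOG10_2 + recomb * log_r + (shared - recomb) * log_nr
    lod = np.where((shared > 0) & (R < 0.5), lod, 0.0)
    return R, lod, shared.astype(np.int64)


# ---------------------------------------------------------------------------
# Redundancy bins
# ---------------------------------------------------------------------------


def merge_redundant(
    genotypes: pd.DataFrame, min_shared: int = 30
) -> tuple[list[str], dict[str, str]]:
    """Bin markers whose genotypes agree wherever both are observed.

    Two markers co-bin when they conflict at no co-genotyped individual and
    share at least ``min_shared`` co-genotyped individuals (H counts as a
    genotype state here). Binning is the transitive closure of that
    relation. Returns (representatives, marker -> representative map); the
    representative is the most-genotyped member, ties broken by name.
    """
    markers = list(genotypes.index)
    values = genotypes.to_numpy(dtype="<U1")
    observed = (values != MISSING).astype(np.float64)
    agree = np.zeros((len(markers), len(markers)))
    for state in (CALL_A, CALL_B, "H"):
        ind = (values == state).astype(np.float64)
        agree += ind @ ind.T
    shared = observed @ observed.T
    conflicts = shared - agree
    mergeable = (conflicts == 0) & (shared >= min_shared)
    np.fill_diagonal(mergeable, False)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(markers)))
    graph.add_edges_from(zip(*np.nonzero(np.triu(mergeable))))
    n_genotyped = observed.sum(axis=1)
    position = {name: i for i, name in enumerate(markers)}
    bin_of: dict[str, str] = {}
    representatives: list[str] = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        rep = min(members, key=lambda i: (-n_genotyped[i], markers[i]))
        representatives.append(markers[rep])
        for i in members:
            bin_of[markers[i]] = markers[rep]
    representatives.sort(key=position.get)
    return representatives, bin_of


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


@dataclass
class LinkageGroup:
    markers: list[str]
    chromosome: str | None = None
    assignment_stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.markers)


def build_groups(
    markers: list[str],
    R: np.ndarray,
    lod: np.ndarray,
    lod_min: float = 7.0,
    rf_max: float = 0.14,
) -> tuple[list[LinkageGroup], list[str]]:
    """Single-linkage transitive closure over pairs with LOD >= lod_min and
    R_hat <= rf_max (conjunction). Returns (groups of >= 2 markers, sorted by
    decreasing size, then first member name) and the unlinked singletons.
    """
    if len(markers) == 0:
        return [], []
    with np.errstate(invalid="ignore"):
        linked = (lod >= lod_min) & (R <= rf_max) & ~np.isnan(R)
    np.fill_diagonal(linked, False)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(markers)))
    graph.add_edges_from(zip(*np.nonzero(np.triu(linked))))
    groups: list[LinkageGroup] = []
    singletons: list[str] = []
    for component in nx.connected_components(graph):
        names = sorted(markers[i] for i in component)
        if len(names) == 1:
            singletons.append(names[0])
        else:
            groups.append(LinkageGroup(markers=names))
    groups.sort(key=lambda g: (-len(g.markers), g.markers[0]))
    singletons.sort()
    return groups, singletons


def assign_chromosome(
    group: LinkageGroup | list[str], putative: dict[str, str]
) -> tuple[str | None, dict]:
    """Attribute a linkage group to the modal putative chromosome.

    Reports the fractions of assigned members consistent with the label,
    attributed to its homeolog (e.g. 1A vs 1B) and to any other chromosome.
    Returns (None, stats) when no member is assigned or the mode is tied.
    """
    members = group.markers if isinstance(group, LinkageGroup) else list(group)
    assigned = [putative[m] for m in members if putative.get(m)]
    stats: dict = {"n_markers": len(members), "n_assigned": len(assigned)}
    if not assigned:
        stats.update(tied=False, fraction_consistent=np.nan,
                     fraction_homeolog=np.nan, fraction_other=np.nan)
        return None, stats
    counts = pd.Series(assigned).value_counts()
    top = counts.iloc[0]
    modal = sorted(counts.index[counts == top])
    if len(modal) > 1:
        stats.update(tied=True, fraction_consistent=np.nan,
                     fraction_homeolog=np.nan, fraction_other=np.nan)
        return None, stats
    label = modal[0]
    homeolog = _homeolog_name(label)
    n = len(assigned)
    n_consistent = sum(1 for c in assigned if c == label)
    n_homeolog = sum(1 for c in assigned if homeolog is not None and c == homeolog)
    stats.update(
        tied=False,
        fraction_consistent=n_consistent / n,
        fraction_homeolog=n_homeolog / n,
        fraction_other=(n - n_consistent - n_homeolog) / n,
    )
    return label, stats


def _homeolog_name(name: str) -> str | None:
    if len(name) >= 2 and name[:-1].isdigit() and name[-1] in "AB":
        return name[:-1] + ("B" if name[-1] == "A" else "A")
    return None


# ---------------------------------------------------------------------------
# Ordering (SARF criterion)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnealParams:
    """Geometric-cooling schedule for the 2-opt refinement."""

    steps_per_marker: int = 300
    t_start: float = 5.0
    t_end: float = 0.01


def sarf(order: np.ndarray, D: np.ndarray) -> float:
    """Sum of adjacent distances along an order (the ordering criterion)."""
    return float(D[order[:-1], order[1:]].sum())


def _held_karp_path(D: np.ndarray) -> np.ndarray:
    """Exact minimum-weight Hamiltonian path with free endpoints."""
    n = len(D)
    full = 1 << n
    cost = np.full((full, n), np.inf)
    parent = np.full((full, n), -1, dtype=np.int64)
    for i in range(n):
        cost[1 << i, i] = 0.0
    for mask in range(full):
        for last in range(n):
            c = cost[mask, last]
            if not np.isfinite(c):
                continue
            for nxt in range(n):
                if mask & (1 << nxt):
                    continue
                nmask = mask | (1 << nxt)
                nc = c + D[last, nxt]
                if nc < cost[nmask, nxt]:
                    cost[nmask, nxt] = nc
                    parent[nmask, nxt] = last
    last = int(np.argmin(cost[full - 1]))
    order = [last]
    mask = full - 1
    while parent[mask, last] >= 0:
        prev = int(parent[mask, last])
        mask ^= 1 << last
        order.append(prev)
        last = prev
    return np.array(order[::-1])


def _greedy_insertion(D: np.ndarray) -> np.ndarray:
    """Seed order: start from the closest pair, insert each remaining marker
    at the position of least SARF increase."""
    n = len(D)
    offdiag = D + np.diag(np.full(n, np.inf))
    i, j = np.unravel_index(np.argmin(offdiag), D.shape)
    order = [int(i), int(j)]
    remaining = [k for k in range(n) if k not in order]
    while remaining:
        dist_to_path = [(min(D[k, order]), k) for k in remaining]
        _, k = min(dist_to_path)
        best_cost, best_pos = np.inf, 0
        for pos in range(len(order) + 1):
            if pos == 0:
                delta = D[k, order[0]]
            elif pos == len(order):
                delta = D[order[-1], k]
            else:
                a, b = order[pos - 1], order[pos]
                delta = D[a, k] + D[k, b] - D[a, b]
            if delta < best_cost:
                best_cost, best_pos = delta, pos
        order.insert(best_pos, k)
        remaining.remove(k)
    return np.array(order)


def _anneal_2opt(order: np.ndarray, D: np.ndarray, rng: np.random.Generator, params: AnnealParams) -> np.ndarray:
    n = len(order)
    steps = params.steps_per_marker * n
    if steps <= 0 or n < 3:
        return order
    order = order.copy()
    decay = (params.t_end / params.t_start) ** (1.0 / steps)
    temp = params.t_start
    for _ in range(steps):
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n))
        if i == 0 and j == n - 1:
            temp *= decay
            continue
        delta = 0.0
        if i > 0:
            delta += D[order[i - 1], order[j]] - D[order[i - 1], order[i]]
        if j < n - 1:
            delta += D[order[i], order[j + 1]] - D[order[j], order[j + 1]]
        if delta < 0 or rng.random() < math.exp(-delta / temp):
            order[i : j + 1] = order[i : j + 1][::-1]
        temp *= decay
    return order


def _window_flips(order: np.ndarray, D: np.ndarray, max_window: int = 5, max_passes: int = 25) -> np.ndarray:
    """Exhaustive permutations of every sliding window until no improvement."""
    n = len(order)
    order = list(order)
    for _ in range(max_passes):
        improved = False
        for w in range(2, min(max_window, n) + 1):
            perms = list(itertools.permutations(range(w)))
            for s in range(n - w + 1):
                window = order[s : s + w]
                left = order[s - 1] if s > 0 else None
                right = order[s + w] if s + w < n else None

                def seg_cost(seq) -> float:
                    c = sum(D[seq[t], seq[t + 1]] for t in range(w - 1))
                    if left is not None:
                        c += D[left, seq[0]]
                    if right is not None:
                        c += D[seq[-1], right]
                    return c

                base = seg_cost(window)
                best, best_seq = base, None
                for perm in perms[1:]:
                    seq = [window[t] for t in perm]
                    c = seg_cost(seq)
                    if c < best - 1e-12:
                        best, best_seq = c, seq
                if best_seq is not None:
                    order[s : s + w] = best_seq
                    improved = True
        if not improved:
            break
    return np.array(order)


def pairwise_distance_matrix(genotypes: pd.DataFrame) -> np.ndarray:
    """Haldane cM distances between all marker pairs (capped at R = 0.45)."""
    R, _, shared = two_point_matrix(genotypes)
    R = np.where(np.isnan(R), _MAX_R_FOR_DISTANCE, np.minimum(R, _MAX_R_FOR_DISTANCE))
    r = R / (2.0 * (1.0 - R))
    D = -50.0 * np.log1p(-2.0 * np.minimum(r, 0.499))
    np.fill_diagonal(D, 0.0)
    return D


def order_markers(
    markers: list[str],
    D: np.ndarray,
    seed: int = 0,
    anneal: AnnealParams = AnnealParams(),
) -> list[str]:
    """Order a linkage group by minimising the SARF criterion.

    Exact dynamic programming for groups of <= 10 markers; greedy insertion,
    simulated annealing (2-opt reversals) and exhaustive sliding-window
    permutations (window <= 5) otherwise. The returned order is canonically
    oriented (first marker name < last) — the criterion is symmetric under
    reversal — and deterministic under a fixed seed.
    """
    n = len(markers)
    if n != len(D):
        raise ValueError("distance matrix does not match the marker list")
    if n == 1:
        return list(markers)
    if n <= _EXACT_ORDER_MAX:
        order = _held_karp_path(np.asarray(D, dtype=float))
    else:
        rng = np.random.default_rng(seed)
        order = _greedy_insertion(D)
        candidate = _anneal_2opt(order, D, rng, anneal)
        candidate = _window_flips(candidate, D)
        baseline = _window_flips(order, D)
        order = candidate if sarf(candidate, D) <= sarf(baseline, D) else baseline
    if markers[order[0]] > markers[order[-1]]:
        order = order[::-1]
    return [markers[i] for i in order]


def positions_from_order(genotypes: pd.DataFrame, ordered_markers: list[str]) -> pd.Series:
    """Cumulative Haldane cM positions along an ordered set of markers."""
    positions = [0.0]
    for m1, m2 in zip(ordered_markers[:-1], ordered_markers[1:]):
        result = two_point(genotypes.loc[m1], genotypes.loc[m2])
        if result is None:
            d = 0.0
        else:
            r = ril_to_rf(min(result.R_hat, _MAX_R_FOR_DISTANCE))
            d = haldane_cm(r)
        positions.append(positions[-1] + d)
    return pd.Series(positions, index=ordered_markers, name="position_cM")


# ---------------------------------------------------------------------------
# Full map assembly
# ---------------------------------------------------------------------------


@dataclass
class GeneticMapResult:
    map: pd.DataFrame  # marker, chromosome, position_cM, type, bin_id
    groups: pd.DataFrame  # per linkage group: size, chromosome, consistency stats
    singletons: list[str]
    dropped_groups: list[LinkageGroup]  # below the minimum mapped-group size


def build_genetic_map(
    genotypes: pd.DataFrame,
    putative: dict[str, str] | None = None,
    orient_by: dict[str, float] | None = None,
    *,
    lod_min: float = 7.0,
    rf_max: float = 0.14,
    min_shared: int = 30,
    min_group_size: int = 3,
    seed: int = 0,
    anneal: AnnealParams = AnnealParams(),
) -> GeneticMapResult:
    """Merge, group, assign, order and position markers into a genetic map.

    Groups attributed to the same chromosome are pooled before ordering;
    groups below ``min_group_size`` markers are reported but left off the
    map. When ``orient_by`` (marker -> external coordinate) is given, each
    chromosome is flipped to correlate positively with it; otherwise the
    orientation is the canonical lexicographic one.
    """
    representatives, bin_of = merge_redundant(genotypes, min_shared=min_shared)
    rep_genotypes = genotypes.loc[representatives]
    R, lod, _ = two_point_matrix(rep_genotypes)
    groups, singletons = build_groups(representatives, R, lod, lod_min=lod_min, rf_max=rf_max)

    group_rows = []
    pooled: dict[str, list[str]] = {}
    for g_id, group in enumerate(groups, start=1):
        label = None
        stats: dict = {"n_markers": len(group), "n_assigned": 0}
        if putative is not None:
            label, stats = assign_chromosome(group, putative)
        group.chromosome = label
        group.assignment_stats = stats
        key = label if label is not None else f"LG{g_id}"
        pooled.setdefault(key, []).extend(group.markers)
        group_rows.append(
            {
                "group_id": f"LG{g_id}",
                "n_markers": len(group),
                "chromosome": label,
                **{k: v for k, v in stats.items() if k != "n_markers"},
            }
        )

    rep_index = {m: i for i, m in enumerate(representatives)}
    D_full = pairwise_distance_matrix(rep_genotypes)
    map_rows = []
    dropped: list[LinkageGroup] = []
    members_of: dict[str, list[str]] = {}
    for marker, rep in bin_of.items():
        members_of.setdefault(rep, []).append(marker)
    for chrom in sorted(pooled):
        members = pooled[chrom]
        expanded_size = sum(len(members_of[m]) for m in members)
        if expanded_size < min_group_size:
            dropped.append(LinkageGroup(markers=members, chromosome=chrom))
            continue
        idx = [rep_index[m] for m in members]
        D = D_full[np.ix_(idx, idx)]
        ordered = order_markers(members, D, seed=seed, anneal=anneal)
        positions = positions_from_order(rep_genotypes, ordered)
        if orient_by is not None:
            known = [(positions[m], orient_by[m]) for m in ordered if m in orient_by]
            if len(known) >= 3:
                ours, theirs = zip(*known)
                rho = pd.Series(ours).corr(pd.Series(theirs), method="spearman")
                if rho is not None and not math.isnan(rho) and rho < 0:
                    end = positions.iloc[-1]
                    ordered = ordered[::-1]
                    positions = pd.Series(
                        [end - positions[m] for m in ordered], index=ordered, name="position_cM"
                    )
        for bin_id, rep in enumerate(ordered):
            for marker in sorted(members_of[rep]):
                map_rows.append(
                    {
                        "marker": marker,
                        "chromosome": chrom,
                        "position_cM": round(float(positions[rep]), 3),
                        "type": "mapped",
                        "bin_id": f"{chrom}.bin{bin_id + 1}",
                    }
                )

    genetic_map = pd.DataFrame(map_rows, columns=["marker", "chromosome", "position_cM", "type", "bin_id"])
    return GeneticMapResult(
        map=genetic_map,
        groups=pd.DataFrame(group_rows),
        singletons=singletons,
        dropped_groups=dropped,
    )
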