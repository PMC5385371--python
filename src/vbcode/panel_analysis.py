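"""Panel-level analyses over barcode matrices.

Distances between cultivars are simple-matching: the fraction of comparable
markers at which two barcodes differ.  Heterozygous (``h``) and missing
(``.``) calls are excluded from identity comparisons by default, since a
heterozygous block signals incomplete fixation rather than a distinct
identity.  Clustering is classical neighbor joining on those distances;
the minimal discriminating marker set is a greedy set cover over cultivar
pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode

from vbcode.barcode_codec import BarcodeMatrix, BarcodeRow, PanelMismatchError
from vbcode.io_formats import MISSING

HET = "h"
HET_POLICIES = ("exclude", "mismatch", "match-either")


def _comparable_and_diff(a: str, b: str, policy: str) -> tuple[bool, bool]:
    """(is the marker comparable, do the calls differ) under a het policy."""
    if a == MISSING or b == MISSING:
        return False, False
    if policy == "exclude":
        if a == HET or b == HET:
            return False, False
        return True, a != b
    if policy == "mismatch":
        return True, a != b
    if policy == "match-either":
        if a == HET or b == HET:
            return True, False
        return True, a != b
    raise ValueError(f"unknown het policy {policy!r}")


def pairwise_difference(
    row_a: BarcodeRow, row_b: BarcodeRow, policy: str = "exclude"
) -> tuple[int, int, float]:
    """Raw difference count, comparable marker count and matching distance.

    ``distance = differences / comparable markers`` (the complement of the
    simple matching coefficient).  Rows must come from the same marker
    panel; with no comparable markers the distance is undefined.
    """
    if row_a.checksum != row_b.checksum:
        raise PanelMismatchError(
            f"panel mismatch: {row_a.checksum} != {row_b.checksum}"
        )
    if len(row_a.codes) != len(row_b.codes):
        raise ValueError("rows have different lengths")
    count = comparable = 0
    for a, b in zip(row_a.codes, row_b.codes):
        ok, diff = _comparable_and_diff(a, b, policy)
        if ok:
            comparable += 1
            if diff:
                count += 1
    if comparable == 0:
        raise ValueError("no comparable markers: distance undefined")
    return count, comparable, count / comparable


@dataclass
class PanelDistances:
    """Pairwise simple-matching distances plus raw difference counts."""

    distances: SkbioDistanceMatrix
    counts: pd.DataFrame
    comparable: pd.DataFrame

    @property
    def mean_pairwise_count(self) -> float:
        """Mean raw difference count over all cultivar pairs."""
        vals = self.counts.values[np.triu_indices(len(self.counts), k=1)]
        return float(np.mean(vals)) if len(vals) else 0.0


def distance_matrix(
    matrix: BarcodeMatrix, policy: str = "exclude"
) -> PanelDistances:
    ids = matrix.cultivars
    n = len(ids)
    counts = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    dist = np.zeros((n, n))
    rows = [matrix.row(c) for c in ids]
    for i, j in itertools.combinations(range(n), 2):
        c, m, d = pairwise_difference(rows[i], rows[j], policy)
        counts[i, j] = counts[j, i] = c
        comp[i, j] = comp[j, i] = m
        dist[i, j] = dist[j, i] = d
    return PanelDistances(
        distances=SkbioDistanceMatrix(dist, ids),
        counts=pd.DataFrame(counts, index=ids, columns=ids),
        comparable=pd.DataFrame(comp, index=ids, columns=ids),
    )


def nj_tree(distances: SkbioDistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou–Nei) with deterministic tie handling.

    Ties on the Q criterion break by lexicographic taxon id; negative branch
    lengths are clamped to zero with the deficit moved onto the sister
    branch.  On an additive distance matrix the generating topology (and its
    branch lengths) is recovered exactly.  Returns an unrooted tree, rooted
    for representation at the final trifurcation.
    """
    data = np.asarray(distances.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("distances must be finite (no NaN/inf)")
    ids = list(distances.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")

    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in ids}
    # each active cluster keyed by its lexicographically first leaf name
    d: dict[tuple[str, str], float] = {}
    active = sorted(ids)
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = sorted((ids[i], ids[j]))
        d[(a, b)] = data[i, j]

    def dist(a: str, b: str) -> float:
        return d[(a, b)] if a < b else d[(b, a)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best: tuple[float, str, str] | None = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * dist(a, b) - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best  # type: ignore[misc]
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        parent = TreeNode()
        ca, cb = nodes.pop(a), nodes.pop(b)
        ca.length, cb.length = la, lb
        parent.extend([ca, cb])
        new_key = min(a, b)
        new_d: dict[str, float] = {}
        for c in active:
            if c in (a, b):
                continue
            new_d[c] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = sorted([c for c in active if c not in (a, b)] + [new_key])
        for pair in list(d):
            if a in pair or b in pair:
                del d[pair]
        for c, v in new_d.items():
            x, y = sorted((new_key, c))
            d[(x, y)] = v
        nodes[new_key] = parent

    root = TreeNode()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
        lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
        lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
        for key, length in zip((a, b, c), (la, lb, lc)):
            child = nodes.pop(key)
            child.length = max(length, 0.0)
            root.append(child)
    else:  # two clusters left: a single edge, split across the root
        a, b = active
        half = dist(a, b) / 2.0
        for key in (a, b):
            child = nodes.pop(key)
            child.length = half
            root.append(child)
    return root


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la  # move the deficit to the sister branch
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def cut_tree_groups(tree: TreeNode, height: float) -> list[set[str]]:
    """Partition leaves by cutting every branch longer than ``height``.

    Leaves connected through branches of length <= ``height`` stay in one
    group; long branches separate groups.  The threshold is user-chosen
    (used to read off major groups and subgroups from a cultivar tree).
    """
    groups: list[set[str]] = []

    def walk(node: TreeNode, current: set[str]) -> None:
        if node.is_tip():
            current.add(node.name)
            return
        for child in node.children:
            if (child.length or 0.0) > height:
                fresh: set[str] = set()
                groups.append(fresh)
                walk(child, fresh)
            else:
                walk(child, current)

    root_group: set[str] = set()
    groups.append(root_group)
    walk(tree, root_group)
    return sorted((g for g in groups if g), key=lambda g: sorted(g)[0])


@dataclass
class MarkerSubset:
    """A discriminating marker subset with coverage diagnostics."""

    marker_ids: list[str]
    resolved_pairs: int
    unresolved_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.marker_ids)


def _distinguishing_sets(
    matrix: BarcodeMatrix, policy: str
) -> tuple[list[tuple[str, str]], dict[str, set[int]]]:
    """Universe of resolvable pairs and, per marker, the pairs it resolves."""
    ids = matrix.cultivars
    pairs = list(itertools.combinations(sorted(ids), 2))
    pair_index = {p: k for k, p in enumerate(pairs)}
    per_marker: dict[str, set[int]] = {m: set() for m in matrix.markers}
    for m in matrix.markers:
        col = matrix.data[m]
        for p in pairs:
            ok, diff = _comparable_and_diff(col[p[0]], col[p[1]], policy)
            if ok and diff:
                per_marker[m].add(pair_index[p])
    return pairs, per_marker


def minimal_discriminating_set(
    matrix: BarcodeMatrix,
    must_resolve: Sequence[tuple[str, str]] | None = None,
    policy: str = "exclude",
    pic_by_marker: Mapping[str, float] | None = None,
    method: str = "greedy",
) -> MarkerSubset:
    """Smallest marker subset separating every cultivar pair (set cover).

    Universe: unordered cultivar pairs (all, or ``must_resolve``); a marker
    covers the pairs it distinguishes.  ``greedy`` iteratively picks the
    marker covering most uncovered pairs, ties broken by higher PIC then
    genomic order, stopping when all pairs are covered or no marker adds
    coverage.  ``exact`` brute-forces the optimum (only for small panels,
    <= 20 markers).  Pairs no marker separates are reported unresolved.
    """
    if len(matrix.cultivars) < 2:
        return MarkerSubset(marker_ids=[], resolved_pairs=0)
    pairs, per_marker = _distinguishing_sets(matrix, policy)
    if must_resolve is not None:
        wanted = {tuple(sorted(p)) for p in must_resolve}
        keep = [k for k, p in enumerate(pairs) if p in wanted]
        keep_set = set(keep)
        per_marker = {m: s & keep_set for m, s in per_marker.items()}
        universe = keep_set
    else:
        universe = set(range(len(pairs)))

    resolvable = set().union(*per_marker.values()) if per_marker else set()
    unresolved_idx = universe - resolvable
    target = universe & resolvable

    marker_order = {m: k for k, m in enumerate(matrix.markers)}
    if pic_by_marker is not None:
        pics = dict(pic_by_marker)
    else:
        # default tie-break PIC from the matrix's own code frequencies
        from vbcode.marker_discovery import pattern_counts_from_calls, pic

        pics = {}
        for m in matrix.markers:
            counts = pattern_counts_from_calls(
                c for c in matrix.data[m] if c not in (HET, MISSING)
            )
            pics[m] = pic(list(counts.values())) if counts else 0.0

    if method == "exact":
        if len(matrix.markers) > 20:
            raise ValueError("exact mode limited to <= 20 markers")
        chosen = _exact_cover(matrix.markers, per_marker, target)
    elif method == "greedy":
        chosen = []
        uncovered = set(target)
        while uncovered:
            best_m = None
            best_key = None
            for m in matrix.markers:
                if m in chosen:
                    continue
                gain = len(per_marker[m] & uncovered)
                if gain == 0:
                    continue
                key = (-gain, -pics.get(m, 0.0), marker_order[m])
                if best_key is None or key < best_key:
                    best_key, best_m = key, m
            if best_m is None:
                break
            chosen.append(best_m)
            uncovered -= per_marker[best_m]
    else:
        raise ValueError(f"unknown method {method!r}")

    return MarkerSubset(
        marker_ids=chosen,
        resolved_pairs=len(target),
        unresolved_pairs=[pairs[k] for k in sorted(unresolved_idx)],
    )


def _exact_cover(
    markers: Sequence[str],
    per_marker: Mapping[str, set[int]],
    target: set[int],
) -> list[str]:
    if not target:
        return []
    for size in range(1, len(markers) + 1):
        for combo in itertools.combinations(markers, size):
            covered: set[int] = set()
            for m in combo:
                covered |= per_marker[m]
            if target <= covered:
                return list(combo)
    return list(markers)


def closest_matches(
    query_row: BarcodeRow,
    matrix: BarcodeMatrix,
    k: int = 5,
    policy: str = "exclude",
) -> tuple[list[tuple[str, int]], float]:
    """Rank database cultivars by raw difference count from the query.

    Ascending by count, ties broken lexicographically; also returns the
    database's mean pairwise difference count for context (how far apart
    cultivars typically sit, so a 3–4 marker difference reads as a
    backcross-level match).
    """
    if query_row.checksum != matrix.checksum:
        raise PanelMismatchError(
            f"panel mismatch: {query_row.checksum} != {matrix.checksum}"
        )
    ranked: list[tuple[str, int]] = []
    for cultivar in matrix.cultivars:
        if cultivar == query_row.cultivar:
            continue
        count, _, _ = pairwise_difference(
            query_row, matrix.row(cultivar), policy
        )
        ranked.append((cultivar, count))
    ranked.sort(key=lambda t: (t[1], t[0]))
    mean_diff = distance_matrix(matrix, policy).mean_pairwise_count
    return ranked[: min(k, len(ranked))], mean_diff


@dataclass
class PedigreeResult:
    verdicts: dict[str, bool]  # marker id -> consistent?
    n_comparable: int
    n_inconsistent: int

    @property
    def inconsistency_rate(self) -> float:
        if self.n_comparable == 0:
            return 0.0
        return self.n_inconsistent / self.n_comparable


def pedigree_consistency(
    offspring_row: BarcodeRow,
    parent1_row: BarcodeRow,
    parent2_row: BarcodeRow,
    marker_ids: Sequence[str] | None = None,
) -> PedigreeResult:
    """Check each marker's offspring code against the two parents.

    A marker is consistent when the offspring code matches either parent, or
    the offspring is heterozygous with parents carrying different codes
    (the Mendelian F1 case), or a parent is itself heterozygous (either
    allele could have been transmitted).  Markers missing in any of the
    three are not comparable.
    """
    for r in (parent1_row, parent2_row):
        if r.checksum != offspring_row.checksum:
            raise PanelMismatchError("pedigree rows from different panels")
    n = len(offspring_row.codes)
    names = list(marker_ids) if marker_ids is not None else [str(i) for i in range(n)]
    verdicts: dict[str, bool] = {}
    comparable = inconsistent = 0
    for name, o, p1, p2 in zip(
        names, offspring_row.codes, parent1_row.codes, parent2_row.codes
    ):
        if MISSING in (o, p1, p2):
            continue
        comparable += 1
        ok = (
            o == p1
            or o == p2
            or (o == HET and p1 != p2)
            or p1 == HET
            or p2 == HET
        )
        verdicts[name] = ok
        if not ok:
            inconsistent += 1
    return PedigreeResult(
        verdicts=verdicts,
        n_comparable=comparable,
        n_inconsistent=inconsistent,
    )


@dataclass
class FixationEntry:
    cultivar: str
    n_het: int
    runs: list[tuple[str, str]]  # (chromosome, dVB id) runs of het markers

    @property
    def fixed(self) -> bool:
        return self.n_het == 0


def fixation_report(
    matrix: BarcodeMatrix,
    marker_dvb: Mapping[str, str] | None = None,
) -> list[FixationEntry]:
    """Per-cultivar heterozygosity: residual-heterozygous dVB runs.

    A cultivar with any ``h`` marker is flagged not fully fixed; its het
    markers are grouped into runs of consecutive markers sharing a
    (chromosome, dVB) so one lingering heterozygous block reads as one run.
    """
    marker_dvb = dict(marker_dvb or matrix.marker_dvb)
    out: list[FixationEntry] = []
    for cultivar in matrix.cultivars:
        runs: list[tuple[str, str]] = []
        n_het = 0
        prev_key = None
        for m in matrix.markers:
            if matrix.data.at[cultivar, m] != HET:
                prev_key = None
                continue
            n_het += 1
            chrom = matrix.marker_pos.get(m, ("?", 0))[0]
            key = (chrom, marker_dvb.get(m, m))
            if key != prev_key:
                runs.append(key)
                prev_key = key
        out.append(FixationEntry(cultivar=cultivar, n_het=n_het, runs=runs))
    return out
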