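"""Genetic-map construction from filtered F2 bin markers.

The map is built in four steps:

1. pairwise recombination fractions by maximum likelihood (EM on the 3×3
   two-locus genotype table, with the double-heterozygote phase ambiguity
   resolved in the expectation step) and two-point LOD scores;
2. single-linkage grouping of markers joined by an edge with
   LOD ≥ ``lod_min`` and r̂ < ``max_r``;
3. ordering within each group by greedy chain extension from the
   highest-LOD pair followed by 2-opt moves that minimize the sum of
   adjacent Kosambi distances;
4. cumulative Kosambi distances of adjacent pairs as centiMorgan positions.

Distances use the Kosambi map function d = 25·ln((1+2r)/(1−2r)), which
allows for partial crossover interference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import segpattern
from .util import atomic_write

log = logging.getLogger(__name__)

#: r̂ values at/above this are treated as "unlinked" when a finite map
#: distance is still needed (adjacent pairs in a group are far below this).
_R_CAP = 0.499


# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------

def kosambi(r):
    """Kosambi map distance in cM: d = 25·ln((1+2r)/(1−2r)); domain 0 ≤ r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d

def kosambi_inverse(d):
    """Inverse Kosambi: r = (e^(4d/100) − 1) / (2(e^(4d/100) + 1)); d ≥ 0 in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    x = np.exp(4.0 * d / 100.0)
    r = (x - 1) / (2 * (x + 1))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# Pairwise recombination fractions (EM) and LOD
# ---------------------------------------------------------------------------

@dataclass
class PairwiseLinkage:
    marker_1: str
    marker_2: str
    r_hat: float
    lod: float
    n_common: int


def _pair_tables(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """3×3 joint genotype count tables for every marker pair, via matmuls.

    Returns (N, singles, doubles, n11) where N[k,l] is the (m×m) count of
    individuals with dosage k at the row marker and l at the column marker;
    ``singles`` counts one-recombinant-gamete classes, ``doubles`` the
    unambiguous two-recombinant classes, ``n11`` the double heterozygotes.
    """
    A = [(dosage == k).astype(np.float64) for k in range(3)]
    N = np.empty((3, 3) + (dosage.shape[0],) * 2)
    for k in range(3):
        for l in range(3):
            N[k, l] = A[k] @ A[l].T
    singles = N[0, 1] + N[1, 0] + N[1, 2] + N[2, 1]
    doubles = N[0, 2] + N[2, 0]
    return N, singles, doubles, N[1, 1]


def _em_r(singles, doubles, n11, n_common, tol=1e-8, max_iter=2000):
    """Vectorized EM for the F2 two-locus recombination fraction."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.full(singles.shape, 0.25)
        gametes = 2.0 * n_common
        for it in range(max_iter):
            # E-step: expected recombinant gametes in the double-het class
            w = 2.0 * r * r / ((1 - r) ** 2 + r * r)
            r_new = (singles + 2.0 * doubles + n11 * w) / gametes
            r_new = np.clip(r_new, 0.0, 0.5)
            delta = np.nanmax(np.abs(r_new - r)) if r_new.size else 0.0
            r = r_new
            if delta < tol:
                break
    return r


def _loglik(N: np.ndarray, r) -> np.ndarray:
    """Multinomial log10-likelihood of the 3×3 tables at r (constant dropped)."""
    r = np.asarray(r, dtype=float)
    h = (1 - r) / 2.0
    q = r / 2.0
    p = np.empty(N.shape, dtype=float)
    p[0, 0] = p[2, 2] = h * h
    p[0, 2] = p[2, 0] = q * q
    p[0, 1] = p[1, 0] = p[1, 2] = p[2, 1] = 2 * h * q
    p[1, 1] = 2 * h * h + 2 * q * q
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = N * np.log10(np.clip(p, 1e-300, None))
    return np.where(N > 0, terms, 0.0).sum(axis=(0, 1))


def pairwise_linkage_matrices(
    dosage: np.ndarray, min_common: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (r̂, LOD, n_common) matrices from a dosage matrix.

    Pairs with fewer than ``min_common`` commonly observed individuals get
    r̂ = NaN and LOD = 0.
    """
    N, singles, doubles, n11 = _pair_tables(dosage)
    n_common = N.sum(axis=(0, 1))
    r = _em_r(singles, doubles, n11, n_common)
    lod = _loglik(N, r) - _loglik(N, np.full(r.shape, 0.5))
    lod = np.maximum(lod, 0.0)
    bad = n_common < min_common
    r[bad] = np.nan
    lod[bad] = 0.0
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    return r, lod, n_common.astype(int)


def estimate_r_f2(calls_1, calls_2, min_common: int = 10) -> PairwiseLinkage:
    """Two-point r̂ and LOD for one pair of aa×bb-coded genotype vectors.

    ``calls_1``/``calls_2`` are dosage vectors (0/1/2, −1 missing).  Raises
    ValueError when fewer than ``min_common`` individuals are observed at
    both markers.
    """
    d = np.vstack([np.asarray(calls_1, dtype=np.int8), np.asarray(calls_2, dtype=np.int8)])
    r, lod, n_common = pairwise_linkage_matrices(d, min_common=min_common)
    if n_common[0, 1] < min_common:
        raise ValueError(
            f"only {n_common[0, 1]} commonly observed individuals (< {min_common})"
        )
    return PairwiseLinkage("m1", "m2", float(r[0, 1]), float(lod[0, 1]), int(n_common[0, 1]))


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def auto_lod_threshold(n_markers: int, floor: float = 3.0) -> float:
    """Grouping LOD threshold controlling genome-wide spurious linkage.

    For unlinked loci P(LOD ≥ T) ≈ 10^−T, so testing all m(m−1)/2 pairs at
    a fixed LOD 3 produces false joins once a few hundred markers are
    involved.  Requiring T = log10(#pairs) + 1 holds the expected number of
    spurious edges near 0.1 genome-wide while staying far below the LOD of
    genuinely adjacent markers.
    """
    n_pairs = max(1, n_markers * (n_markers - 1) // 2)
    return max(floor, np.log10(n_pairs) + 1.0)


def group_markers(
    r: np.ndarray,
    lod: np.ndarray,
    lod_min: float | None = None,
    max_r: float = 0.45,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Single-linkage transitive closure of the (LOD ≥ lod_min, r̂ < max_r) graph.

    ``lod_min=None`` uses :func:`auto_lod_threshold` for the marker count at
    hand.  Returns (groups, unplaced) where groups is a list of index arrays
    for components of size ≥ 2 and unplaced collects singleton indices.
    """
    if lod_min is None:
        lod_min = auto_lod_threshold(r.shape[0])
    with np.errstate(invalid="ignore"):
        adj = (lod >= lod_min) & (r < max_r)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups, unplaced = [], []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        (groups if idx.size >= 2 else unplaced).append(idx)
    unplaced = np.concatenate(unplaced) if unplaced else np.array([], dtype=int)
    return groups, unplaced


# ---------------------------------------------------------------------------
# Ordering (greedy chain + 2-opt on adjacent Kosambi distance)
# ---------------------------------------------------------------------------

def _distance_matrix(r: np.ndarray) -> np.ndarray:
    rc = np.clip(np.nan_to_num(r, nan=_R_CAP), 0.0, _R_CAP)
    return kosambi(rc)


def _chain_cost(order: list[int], D: np.ndarray) -> float:
    return float(sum(D[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _wls_polish(
    order: list[int],
    r: np.ndarray,
    D: np.ndarray,
    max_pair_r: float = 0.4,
    max_rounds: int = 20,
) -> list[int]:
    """Refine a marker order by LOD-weighted least-squares positioning.

    The adjacent-distance chain decides the order of two close markers from
    a handful of noisy pairwise estimates; fitting positions x that minimize
    Σ w_ij (x_j − x_i − δ_ij)² over *all* informative pairs (r̂ <
    ``max_pair_r``, δ signed by the current order) lets every flanking
    marker vote on the local order.  Weights are inverse delta-method
    variances of the Kosambi distance, Var(d̂) ≈ (d′(r̂))² · r̂(1−r̂)/(2n),
    so tight pairs carry the precision they actually have.  Re-sorting by
    the fitted positions and refitting is iterated to a fixed point.  Only
    the order is kept; reported cM positions remain cumulative adjacent
    distances.
    """
    idx = np.array(order)
    m = idx.size
    if m < 3:
        return order
    rsub = r[np.ix_(idx, idx)]
    with np.errstate(invalid="ignore", divide="ignore"):
        rw = np.clip(np.nan_to_num(rsub, nan=0.5), 0.005, 0.5)
        d_prime = 100.0 / (1.0 - 4.0 * rw * rw)
        # sample size is common to all pairs and cancels in the solve
        W = 1.0 / (d_prime**2 * rw * (1.0 - rw))
        W[~(rsub < max_pair_r)] = 0.0
    np.fill_diagonal(W, 0.0)
    # polish needs every marker tied into one component of informative pairs
    n_comp, _ = connected_components(csr_matrix(W > 0), directed=False)
    if n_comp > 1:
        return order
    Dsub = D[np.ix_(idx, idx)]
    L = np.diag(W.sum(axis=1)) - W + np.full((m, m), 1.0 / m)  # pin translation
    perm = np.arange(m)  # current order as local row indices
    for _ in range(max_rounds):
        rank = np.empty(m, dtype=int)
        rank[perm] = np.arange(m)
        sign = np.sign(rank[None, :] - rank[:, None])  # +1 where j after i
        c = (W * (sign * Dsub)).sum(axis=0)  # Σ_i w_ij δ_ij per j
        x = np.linalg.solve(L, c)
        new_perm = np.argsort(x, kind="stable")
        if np.array_equal(new_perm, perm):
            break
        perm = new_perm
    return [int(idx[i]) for i in perm]


def order_group(
    group: np.ndarray,
    r: np.ndarray,
    lod: np.ndarray,
    marker_ids,
) -> tuple[list[int], np.ndarray]:
    """Order one linkage group; return (ordered indices, cM positions).

    Greedy chain extension from the highest-LOD pair, improved by 2-opt
    moves on the sum of adjacent Kosambi distances, then polished by
    multipoint weighted-least-squares positioning (:func:`_wls_polish`).
    Deterministic regardless of input marker order: candidate scans run in
    lexicographic marker-id order and ties break toward the smaller id.  The
    final orientation of the group is normalized so the lexicographically
    smallest marker id lies in the first half.
    """
    ids = {i: str(marker_ids[i]) for i in group}
    missing = [
        (ids[i], ids[j])
        for a, i in enumerate(group)
        for j in group[a + 1 :]
        if np.isnan(r[i, j])
    ]
    if missing:
        raise ValueError(f"missing pairwise estimates within group: {missing[:5]}")
    nodes = sorted(group, key=lambda i: ids[i])
    if len(nodes) == 1:
        return [nodes[0]], np.zeros(1)
    D = _distance_matrix(r)

    # seed with the highest-LOD pair
    best = None
    for a, i in enumerate(nodes):
        for j in nodes[a + 1 :]:
            key = (lod[i, j], -D[i, j])
            if best is None or key > best[0]:
                best = (key, [i, j])
    order = best[1]
    placed = set(order)
    while len(order) < len(nodes):
        cand = None
        for k in nodes:
            if k in placed:
                continue
            for side, end in ((0, order[0]), (1, order[-1])):
                key = (D[end, k], ids[k], side)
                if cand is None or key < cand[0]:
                    cand = (key, k, side)
        _, k, side = cand
        order.insert(0, k) if side == 0 else order.append(k)
        placed.add(k)

    # 2-opt: reverse order[i:j+1] while it shortens the chain
    improved = True
    while improved:
        improved = False
        n = len(order)
        for i in range(n - 1):
            for j in range(i + 1, n):
                before = (D[order[i - 1], order[i]] if i > 0 else 0.0) + (
                    D[order[j], order[j + 1]] if j < n - 1 else 0.0
                )
                after = (D[order[i - 1], order[j]] if i > 0 else 0.0) + (
                    D[order[i], order[j + 1]] if j < n - 1 else 0.0
                )
                if after < before - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True

    order = _wls_polish(order, r, D)

    # orientation convention: smallest marker id in the first half
    pos_of_min = min(range(len(order)), key=lambda k: ids[order[k]])
    if pos_of_min > (len(order) - 1) / 2:
        order.reverse()

    positions = np.concatenate(
        [[0.0], np.cumsum([D[order[i], order[i + 1]] for i in range(len(order) - 1)])]
    )
    return order, positions


def mask_singleton_genotypes(
    dosage: np.ndarray,
    order: list[int],
    positions: np.ndarray,
    max_double_prob: float = 0.005,
) -> int:
    """Mask probable genotyping errors revealed by the marker order (in place).

    A call that disagrees with *both* of its observed chain neighbours while
    those neighbours agree with each other implies a double crossover inside
    the flanking interval.  The per-gamete probability of that event is
    r₁·r₂ (no interference); when it falls below ``max_double_prob`` — the
    scale of plausible per-call genotyping-error rates — an error is the
    likelier explanation and the call is set missing, so the second-pass
    recombination fractions are not inflated by error artifacts.  At wide
    marker spacings the gate leaves genuine double crossovers alone.
    Returns the number of masked calls.
    """
    masked = 0
    for k in range(1, len(order) - 1):
        r1 = kosambi_inverse(max(positions[k] - positions[k - 1], 0.0))
        r2 = kosambi_inverse(max(positions[k + 1] - positions[k], 0.0))
        if r1 * r2 >= max_double_prob:
            continue
        prev_, cur, next_ = dosage[order[k - 1]], dosage[order[k]], dosage[order[k + 1]]
        hit = (prev_ >= 0) & (cur >= 0) & (next_ >= 0) & (prev_ == next_) & (prev_ != cur)
        dosage[order[k]][hit] = -1
        masked += int(hit.sum())
    return masked


# ---------------------------------------------------------------------------
# Map assembly
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Linkage groups of ordered bin markers with cM positions.

    ``positions`` holds one row per *mapped marker* (bin representatives and
    their bin members, which inherit the representative's position) with
    columns ``marker``, ``group``, ``position_cM``, ``is_representative``,
    ``bin``.  ``unplaced`` lists markers not assigned to any group.
    """

    positions: pd.DataFrame
    unplaced: list[str] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        return sorted(self.positions["group"].unique())

    def group_table(self, group: str) -> pd.DataFrame:
        g = self.positions[
            (self.positions["group"] == group) & self.positions["is_representative"]
        ]
        return g.sort_values(["position_cM", "marker"], kind="mergesort").reset_index(drop=True)

    def lengths_cM(self) -> pd.Series:
        return self.positions.groupby("group")["position_cM"].max()

    @property
    def total_length_cM(self) -> float:
        return float(self.lengths_cM().sum())

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with atomic_write(path) as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("group\tmarker\tposition_cM\tis_representative\tbin\n")
            out = self.positions.sort_values(
                ["group", "position_cM", "marker"], kind="mergesort"
            )
            for row in out.itertuples(index=False):
                fh.write(
                    f"{row.group}\t{row.marker}\t{row.position_cM:.4f}\t"
                    f"{int(row.is_representative)}\t{row.bin}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        df["is_representative"] = df["is_representative"].astype(bool)
        return cls(df.reset_index(drop=True))

    def chart_text(self) -> str:
        """Plain-text map chart: one ruler block per linkage group."""
        lines = []
        for g in self.groups:
            tab = self.group_table(g)
            lines.append(f"{g}  ({len(tab)} markers, {tab['position_cM'].max():.1f} cM)")
            for row in tab.itertuples(index=False):
                lines.append(f"  {row.position_cM:8.2f}  {row.marker}")
            lines.append("")
        return "\n".join(lines)


def build_map(
    matrix: "segpattern.GenotypeMatrix",
    p_threshold: float = 0.001,
    max_missing: float = 0.30,
    lod_min: float | None = None,
    max_r: float = 0.45,
    min_common: int = 10,
    prefiltered: bool = False,
    error_correction: bool = True,
) -> GeneticMap:
    """Filter → collapse bins → pairwise linkage → group → order.

    With ``prefiltered=True`` the matrix is assumed to contain only retained
    aa×bb markers and the filter step is skipped.  ``error_correction``
    masks order-revealed singleton calls (:func:`mask_singleton_genotypes`)
    and re-estimates the map in a second pass.
    """
    if matrix.n_markers == 0:
        log.warning("empty genotype matrix: returning empty map")
        return GeneticMap(
            pd.DataFrame(columns=["marker", "group", "position_cM", "is_representative", "bin"])
        )
    if prefiltered:
        retained = matrix
    else:
        retained, verdicts = segpattern.filter_markers(matrix, p_threshold, max_missing)
        log.info(
            "filter: %d/%d markers retained (%s)",
            retained.n_markers,
            matrix.n_markers,
            verdicts["reason"].value_counts().to_dict(),
        )
    if retained.n_markers == 0:
        log.warning("no markers retained: returning empty map")
        return GeneticMap(
            pd.DataFrame(columns=["marker", "group", "position_cM", "is_representative", "bin"])
        )
    reps, bins = segpattern.collapse_bins(retained)
    rep_ids = reps.markers["marker"].to_numpy()
    dosage = segpattern.encode_dosage(reps)

    def one_pass(dos):
        r, lod, _ = pairwise_linkage_matrices(dos, min_common=min_common)
        groups, unplaced_idx = group_markers(r, lod, lod_min=lod_min, max_r=max_r)
        # deterministic group naming: largest first, ties by smallest member id
        groups = sorted(groups, key=lambda g: (-g.size, min(str(rep_ids[i]) for i in g)))
        ordered = [order_group(g, r, lod, rep_ids) for g in groups]
        return ordered, unplaced_idx

    ordered, unplaced_idx = one_pass(dosage)
    if error_correction:
        n_masked = sum(
            mask_singleton_genotypes(dosage, order, pos) for order, pos in ordered
        )
        if n_masked:
            log.info("masked %d singleton calls as probable genotyping errors", n_masked)
            ordered, unplaced_idx = one_pass(dosage)

    rows = []
    for gi, (order, pos) in enumerate(ordered, start=1):
        for idx, cm in zip(order, pos):
            rows.append((str(rep_ids[idx]), f"LG{gi:02d}", float(cm)))
    placed = pd.DataFrame(rows, columns=["marker", "group", "position_cM"])

    # propagate positions from representatives to their bin members
    bin_of = bins.set_index("marker")["bin"]
    members = bins.merge(
        placed.rename(columns={"marker": "representative"}), on="representative", how="inner"
    )
    positions = pd.DataFrame(
        {
            "marker": members["marker"],
            "group": members["group"],
            "position_cM": members["position_cM"],
            "is_representative": members["marker"] == members["representative"],
            "bin": members["bin"],
        }
    ).sort_values(["group", "position_cM", "marker"], kind="mergesort").reset_index(drop=True)

    unplaced = sorted(
        set(str(rep_ids[i]) for i in unplaced_idx)
        | set(bin_of.index[~bin_of.index.isin(positions["marker"])])
    )
    if unplaced:
        log.info("%d markers unplaced (singleton groups)", len(unplaced))
    return GeneticMap(positions, unplaced=unplaced)
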