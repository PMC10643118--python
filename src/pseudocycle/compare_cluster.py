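"""Structure comparison and scaffold-library clustering.

Provides least-squares (Kabsch) superposition, a bidirectionally averaged
TM score, backbone-dihedral secondary-structure strings, agglomerative
clustering of scaffold sets with a singleton-minimizing cluster-count
selection, and subsample coverage analysis (the fraction of structures
with no structural neighbor above a TM threshold).

The TM machinery is a simplified fragment-seeded, iteratively refined
implementation — adequate for self/noise/family comparisons, not a parity
port of the reference TM-align program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from pseudocycle.structure_io import ProteinStructure, RepeatSpec

TM_SINGLETON_THRESHOLD = 0.45
DEFAULT_INTRA_TM_THRESHOLD = 0.85


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition of mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_A: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_rmsd(ref: np.ndarray, mob: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rotation/translation of ``mob`` onto ``ref``
    (reflections excluded) and the resulting CA RMSD.

    Requires equal-length coordinate sets of at least 3 points in 1:1
    correspondence.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    if ref.shape != mob.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mob.shape}")
    if len(ref) < 3:
        raise ValueError("need at least 3 points for superposition")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    H = (mob - mob_c).T @ (ref - ref_c)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd_A=rmsd)


def tm_d0(L_ref: int) -> float:
    """Length-dependent TM normalization distance, floored at 0.5 A."""
    if L_ref > 15:
        return max(0.5, 1.24 * (L_ref - 15) ** (1.0 / 3.0) - 1.8)
    return 0.5


@dataclass
class TMPair:
    """Bidirectional TM scores: each structure once as the length
    reference, and their average."""

    tm_ab: float
    tm_ba: float

    @property
    def tm_avg(self) -> float:
        return (self.tm_ab + self.tm_ba) / 2.0


def _tm_of_distances(d: np.ndarray, d0: float, L_ref: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_ref)


def _refined_tm(X: np.ndarray, Y: np.ndarray, d0: float, L_ref: int,
                max_iter: int = 20) -> float:
    """Max TM over fragment-seeded, distance-selected superposition
    refinements of aligned coordinate sets X (reference) and Y."""
    n = len(X)
    best = 0.0
    frag_lengths = sorted({n, max(4, n // 2), max(4, n // 4)}, reverse=True)
    seeds: list[np.ndarray] = []
    for fl in frag_lengths:
        stride = max(1, fl // 2)
        for start in range(0, n - fl + 1, stride):
            seeds.append(np.arange(start, start + fl))
    for seed in seeds:
        sel = seed
        prev: Optional[np.ndarray] = None
        for _ in range(max_iter):
            if len(sel) < 3:
                break
            sup = kabsch_rmsd(X[sel], Y[sel])
            d = np.linalg.norm(Y @ sup.rotation.T + sup.translation - X,
                               axis=1)
            best = max(best, _tm_of_distances(d, d0, L_ref))
            cut = d0
            new = np.flatnonzero(d < cut)
            while len(new) < 3:
                cut += 0.5
                new = np.flatnonzero(d < cut)
            if prev is not None and np.array_equal(new, prev):
                break
            prev, sel = sel, new
    return min(best, 1.0)


def align_structures(a: ProteinStructure, b: ProteinStructure
                     ) -> list[tuple[int, int]]:
    """Sequence-order-preserving structural alignment.

    Gapless shift seeds superpose one chain onto the other, a dynamic
    program on the inter-residue distance matrix refines the matching,
    and the correspondence with the best min-length-normalized TM is
    returned as 0-based index pairs.
    """
    A, B = a.ca_coords(), b.ca_coords()
    if len(A) < 15 or len(B) < 15:
        raise ValueError("structures must have at least 15 residues")
    d0 = tm_d0(min(len(A), len(B)))
    L_norm = min(len(A), len(B))
    best_tm, best_pairs = -1.0, None
    for shift in range(-(len(B) - 5), len(A) - 4):
        ia0, ib0 = max(0, shift), max(0, -shift)
        ov = min(len(A) - ia0, len(B) - ib0)
        if ov < 5:
            continue
        ia = np.arange(ia0, ia0 + ov)
        ib = np.arange(ib0, ib0 + ov)
        sup = kabsch_rmsd(A[ia], B[ib])
        pairs = list(zip(ia.tolist(), ib.tolist()))
        for _ in range(4):
            Bm = B @ sup.rotation.T + sup.translation
            pairs = _dp_align(A, Bm, d0)
            if len(pairs) < 3:
                break
            pa = np.array([p[0] for p in pairs])
            pb = np.array([p[1] for p in pairs])
            sup = kabsch_rmsd(A[pa], B[pb])
        if len(pairs) < 3:
            continue
        pa = np.array([p[0] for p in pairs])
        pb = np.array([p[1] for p in pairs])
        Bm = B @ sup.rotation.T + sup.translation
        d = np.linalg.norm(Bm[pb] - A[pa], axis=1)
        tm = _tm_of_distances(d, d0, L_norm)
        if tm > best_tm:
            best_tm, best_pairs = tm, pairs
    if best_pairs is None:
        raise ValueError("degenerate geometry: no alignment found")
    return best_pairs


def _dp_align(A: np.ndarray, B: np.ndarray, d0: float,
              gap: float = -0.6) -> list[tuple[int, int]]:
    """Needleman-Wunsch on the TM-weighted distance matrix (linear gaps)."""
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    s = 1.0 / (1.0 + (d / d0) ** 2)
    n, m = s.shape
    F = np.zeros((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    F[1:, 0] = gap * np.arange(1, n + 1)
    F[0, 1:] = gap * np.arange(1, m + 1)
    P[1:, 0] = 1
    P[0, 1:] = 2
    for i in range(1, n + 1):
        diag = F[i - 1, :-1] + s[i - 1]
        up = F[i - 1, 1:] + gap
        row = F[i]
        for j in range(1, m + 1):
            best = diag[j - 1]
            ptr = 0
            if up[j - 1] > best:
                best, ptr = up[j - 1], 1
            left = row[j - 1] + gap
            if left > best:
                best, ptr = left, 2
            row[j] = best
            P[i, j] = ptr
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0 and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif p == 1 or j == 0:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def tm_score(a: ProteinStructure, b: ProteinStructure,
             correspondence: Optional[Sequence[tuple[int, int]]] = None
             ) -> TMPair:
    """Averaged bidirectional TM score of two structures.

    The default correspondence is index-wise for equal lengths and
    structural alignment (:func:`align_structures`) otherwise.  The TM
    iteration is run once per normalization (each structure as the
    length reference) and the two scores are averaged; the average is
    symmetric in its arguments.
    """
    if correspondence is None:
        if len(a) == len(b):
            correspondence = [(i, i) for i in range(len(a))]
        else:
            # canonical order for symmetry of the DP alignment
            if len(a) >= len(b):
                correspondence = align_structures(a, b)
            else:
                correspondence = [(j, i) for i, j in align_structures(b, a)]
    if not correspondence:
        raise ValueError("empty correspondence")
    ia = np.array([p[0] for p in correspondence])
    ib = np.array([p[1] for p in correspondence])
    X = a.ca_coords()[ia]
    Y = b.ca_coords()[ib]
    tm_ab = _refined_tm(X, Y, tm_d0(len(a)), len(a))
    tm_ba = _refined_tm(Y, X, tm_d0(len(b)), len(b))
    return TMPair(tm_ab=tm_ab, tm_ba=tm_ba)


def pairwise_tm_matrix(structures: Sequence[ProteinStructure]) -> np.ndarray:
    """Symmetric all-by-all matrix of averaged TM scores (diagonal 1)."""
    n = len(structures)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = tm_score(structures[i], structures[j]).tm_avg
    return M


# ---------------------------------------------------------------------------
# Secondary structure

def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return math.degrees(math.atan2(np.cross(b1, v) @ w, v @ w))


def assign_ss(structure: ProteinStructure) -> str:
    """Per-residue secondary structure over {H, E, L} from backbone
    dihedral windows; H runs shorter than 4 and E runs shorter than 3 are
    demoted to loop; chain termini are loop."""
    n = len(structure)
    ss = ["L"] * n
    res = structure.residues
    for i in range(1, n - 1):
        phi = _dihedral(res[i - 1].c_xyz, res[i].n_xyz,
                        res[i].ca_xyz, res[i].c_xyz)
        psi = _dihedral(res[i].n_xyz, res[i].ca_xyz,
                        res[i].c_xyz, res[i + 1].n_xyz)
        if -100.0 < phi < -30.0 and -80.0 < psi < -5.0:
            ss[i] = "H"
        elif -180.0 < phi < -80.0 and (80.0 < psi < 180.0
                                       or -180.0 < psi < -170.0):
            ss[i] = "E"
    # demote short runs
    out = ss[:]
    i = 0
    while i < n:
        j = i
        while j < n and ss[j] == ss[i]:
            j += 1
        run = j - i
        if (ss[i] == "H" and run < 4) or (ss[i] == "E" and run < 3):
            for k in range(i, j):
                out[k] = "L"
        i = j
    return "".join(out)


# ---------------------------------------------------------------------------
# Clustering and coverage

@dataclass
class ClusterReport:
    """Assignments plus summary statistics of a scaffold clustering."""

    assignments: dict[int, int]
    n_clusters: int
    singleton_fraction: float
    mean_intra_tm: float
    sd_intra_tm: float
    scan: list[dict] = field(default_factory=list)


def _cluster_stats(labels: np.ndarray, tm: np.ndarray
                   ) -> tuple[float, float, float, int]:
    """(singleton fraction, mean intra TM, sd intra TM, n clusters) for a
    label vector over the TM matrix; intra stats pool all within-cluster
    pairs of non-singleton clusters."""
    uniq, counts = np.unique(labels, return_counts=True)
    n_clusters = len(uniq)
    singleton_fraction = float(np.sum(counts < 2)) / n_clusters
    vals = []
    for c in uniq[counts >= 2]:
        idx = np.flatnonzero(labels == c)
        iu, ju = np.triu_indices(len(idx), k=1)
        vals.extend(tm[idx[iu], idx[ju]].tolist())
    if vals:
        return (singleton_fraction, float(np.mean(vals)),
                float(np.std(vals)), n_clusters)
    return singleton_fraction, float("nan"), float("nan"), n_clusters


def cluster_scaffolds(structures: Sequence[ProteinStructure],
                      specs: Sequence[RepeatSpec],
                      intra_tm_threshold: float = DEFAULT_INTRA_TM_THRESHOLD,
                      tm_matrix: Optional[np.ndarray] = None) -> ClusterReport:
    """Cluster a scaffold library by structural similarity.

    Scaffolds are first grouped by repeat number N and by repeat-unit
    secondary-structure string; within each group average-linkage
    agglomerative clustering runs on distance 1 - tm_avg, scanning the
    cluster count and choosing the one minimizing the singleton fraction
    subject to the pooled mean intra-cluster TM staying at or above
    ``intra_tm_threshold``.  A precomputed TM matrix may be supplied to
    avoid recomputation.
    """
    if len(structures) != len(specs):
        raise ValueError("one RepeatSpec per structure required")
    n = len(structures)
    if n == 0:
        raise ValueError("no structures to cluster")
    if n == 1:
        return ClusterReport({0: 0}, 1, 1.0, float("nan"), float("nan"))
    if tm_matrix is None:
        tm_matrix = pairwise_tm_matrix(structures)
    tm_matrix = np.asarray(tm_matrix, dtype=float)

    groups: dict[tuple[int, str], list[int]] = {}
    for i, (s, spec) in enumerate(zip(structures, specs)):
        unit_ss = assign_ss(s)[:spec.unit_length]
        groups.setdefault((spec.n_units, unit_ss), []).append(i)

    assignments: dict[int, int] = {}
    scan: list[dict] = []
    next_id = 0
    for key in sorted(groups):
        idx = np.array(groups[key])
        g = len(idx)
        if g == 1:
            assignments[int(idx[0])] = next_id
            next_id += 1
            continue
        sub_tm = tm_matrix[np.ix_(idx, idx)]
        D = 1.0 - sub_tm
        np.fill_diagonal(D, 0.0)
        best_k, best_frac, best_labels = None, None, None
        for k in range(1, g + 1):
            if k == g:
                labels = np.arange(g)
            else:
                model = AgglomerativeClustering(
                    n_clusters=k, metric="precomputed", linkage="average")
                labels = model.fit_predict(D)
            frac, mean_tm, sd_tm, _ = _cluster_stats(labels, sub_tm)
            feasible = math.isnan(mean_tm) or mean_tm >= intra_tm_threshold
            scan.append({"group": key, "n_clusters": k,
                         "singleton_fraction": frac,
                         "mean_intra_tm": mean_tm, "sd_intra_tm": sd_tm,
                         "feasible": feasible})
            if feasible and (best_frac is None or frac < best_frac):
                best_k, best_frac, best_labels = k, frac, labels
        for local, i in zip(best_labels, idx):
            assignments[int(i)] = next_id + int(local)
        next_id += int(best_labels.max()) + 1

    labels_all = np.array([assignments[i] for i in range(n)])
    frac, mean_tm, sd_tm, n_clusters = _cluster_stats(labels_all, tm_matrix)
    return ClusterReport(assignments=assignments, n_clusters=n_clusters,
                         singleton_fraction=frac, mean_intra_tm=mean_tm,
                         sd_intra_tm=sd_tm, scan=scan)


@dataclass
class CoverageReport:
    """Singleton fractions of random subsamples of a scaffold set."""

    rows: list[dict]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def mean_fraction(self, size: int) -> float:
        vals = [r["singleton_fraction"] for r in self.rows
                if r["subset_size"] == size]
        return float(np.mean(vals))


def subsample_coverage(structures: Sequence[ProteinStructure],
                       sizes: Sequence[int] = (500, 700, 1000, 5000),
                       replicates: int = 10,
                       threshold: float = TM_SINGLETON_THRESHOLD,
                       seed: int = 0,
                       tm_matrix: Optional[np.ndarray] = None
                       ) -> CoverageReport:
    """Estimate structural coverage by subsampling.

    For each subset size and replicate, a subset is sampled without
    replacement and the fraction of members whose best TM to every other
    subset member falls below ``threshold`` (singletons, i.e. structures
    with no structural neighbor) is recorded.
    """
    n = len(structures)
    if tm_matrix is None:
        tm_matrix = pairwise_tm_matrix(structures)
    tm_matrix = np.asarray(tm_matrix, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > n:
            raise ValueError(f"subset size {size} exceeds population {n}")
        for rep in range(1, replicates + 1):
            sub = rng.choice(n, size=size, replace=False)
            M = tm_matrix[np.ix_(sub, sub)].copy()
            np.fill_diagonal(M, -np.inf)
            singles = np.sum(M.max(axis=1) < threshold)
            rows.append({"subset_size": int(size), "replicate": rep,
                         "singleton_fraction": float(singles) / size})
    return CoverageReport(rows=rows)
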