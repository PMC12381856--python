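"""Macrostate assignment of unfolding ensembles from Cα-RMSD features.

The pipeline mirrors common practice for unfolding trajectories: a 1-D
feature (Cα RMSD to the native reference over a fixed residue range,
default 12-285) is discretised into microstates by (mini-batch) k-means,
a Markov state model is estimated at a lag time on the largest strongly
connected microstate set, and the microstates are coarse-grained into
folded / intermediate / unfolded macrostates by spectral (PCCA-style)
grouping on the slow right eigenvectors.  Macrostates are labelled by
their stationary-weighted mean RMSD (folded lowest, unfolded highest);
when four metastable sets are requested, the two middle ones are merged
into a single intermediate.  A Chapman-Kolmogorov test checks
T(f*tau) against T(tau)^f.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans, MiniBatchKMeans

MACRO_LABELS = ("folded", "intermediate", "unfolded")


class MSMError(ValueError):
    pass


@dataclass
class FeatureSeries:
    """Per-trajectory 1-D Cα-RMSD series (Å) against a shared reference."""

    trajectories: list  # list of 1-D float arrays
    frame_interval_ns: float = 0.1
    residue_range: tuple[int, int] = (12, 285)

    def __post_init__(self) -> None:
        self.trajectories = [np.asarray(t, dtype=float) for t in self.trajectories]
        for t in self.trajectories:
            if np.any(t < 0):
                raise MSMError("RMSD values must be non-negative")

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.trajectories)

    def filter_min_length(self, min_ns: float) -> "FeatureSeries":
        """Drop trajectories shorter than ``min_ns`` (unconverged runs)."""
        keep = [t for t in self.trajectories
                if t.size * self.frame_interval_ns >= min_ns]
        return FeatureSeries(keep, self.frame_interval_ns, self.residue_range)


@dataclass
class MicrostateModel:
    centers: np.ndarray  # sorted ascending, Å
    assignments: list  # per-trajectory integer arrays
    k: int
    inertia: float  # within-cluster sum of squares

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.assignments)


@dataclass
class MacrostateModel:
    transition_matrix: np.ndarray  # macro-level, row stochastic
    stationary: np.ndarray
    micro_to_macro: np.ndarray  # index into labels, -1 for disconnected micros
    labels: tuple
    mean_rmsd: np.ndarray  # per macro label, Å
    populations: np.ndarray  # equilibrium weights per macro label
    lag: int  # frames
    micro_transition_matrix: np.ndarray = None
    micro_stationary: np.ndarray = None
    micro_active: np.ndarray = None  # active (connected) microstate ids
    flags: list = field(default_factory=list)

    def frame_labels(self, micro_assignments: np.ndarray) -> np.ndarray:
        """Map per-frame microstates to macro-label indices (-1 if inactive)."""
        return self.micro_to_macro[np.asarray(micro_assignments)]


# ---------------------------------------------------------------------------
# feature extraction

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (Kabsch).

    Returns the transformed mobile coordinates and the RMSD after
    optimal rotation + translation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise MSMError("atom-count mismatch between frame and reference")
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    H = mc.T @ rc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    Rmat = U @ D @ Vt
    moved = mc @ Rmat + reference.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, rmsd


def kabsch_rmsd_series(
    frames: np.ndarray,
    reference: np.ndarray,
    frame_interval_ns: float = 0.1,
    residue_range: tuple[int, int] = (12, 285),
) -> FeatureSeries:
    """RMSD (Å) of each frame to the reference after optimal superposition.

    ``frames`` has shape (n_frames, n_atoms, 3) and must contain the
    already-selected atoms (e.g. Cα of the chosen residue range).
    """
    frames = np.asarray(frames, dtype=float)
    values = np.array([kabsch_superpose(f, reference)[1] for f in frames])
    return FeatureSeries([values], frame_interval_ns, residue_range)


# ---------------------------------------------------------------------------
# clustering

def cluster_features(series: FeatureSeries, k: int, seed: int = 0) -> MicrostateModel:
    """1-D mini-batch k-means discretisation into ``k`` microstates.

    Cluster centres are re-ordered ascending so that microstate ids are
    monotone in RMSD; assignments are relabelled accordingly.
    """
    data = series.concatenated()
    if data.size < k:
        raise MSMError(f"k={k} exceeds the {data.size} available frames")
    # exact Lloyd iterations below the mini-batch cutover: small inputs
    # need the tight WCSS optimum, huge ones the mini-batch speed
    if data.size <= 20_000:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    else:
        km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=10,
                             batch_size=4096, max_iter=300)
    km.fit(data.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    centers = km.cluster_centers_.ravel()[order]
    assignments, inertia = [], 0.0
    for t in series.trajectories:
        lab = relabel[km.predict(t.reshape(-1, 1))]
        assignments.append(lab)
        inertia += float(np.sum((t - centers[lab]) ** 2))
    return MicrostateModel(centers=centers, assignments=assignments,
                           k=k, inertia=inertia)


# ---------------------------------------------------------------------------
# MSM estimation

def transition_counts(assignments, n_states: int, lag: int) -> np.ndarray:
    """Sliding-window transition counts at the given lag (frames)."""
    if lag < 1:
        raise MSMError("lag must be >= 1")
    C = np.zeros((n_states, n_states))
    for a in assignments:
        a = np.asarray(a)
        if a.size > lag:
            np.add.at(C, (a[:-lag], a[lag:]), 1.0)
    return C


def _largest_scc(C: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected set with observed counts."""
    adj = csr_matrix((C > 0).astype(int))
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    visited = np.unique(np.nonzero(C.sum(axis=1) + C.sum(axis=0))[0])
    sizes = np.bincount(comp[visited], minlength=n_comp) if visited.size else []
    if len(sizes) == 0:
        raise MSMError("no transitions observed")
    best = int(np.argmax(sizes))
    return np.nonzero(comp == best)[0]


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalised."""
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def build_msm(assignments, lag: int, n_states: int | None = None,
              reversible: bool = False):
    """Estimate a row-stochastic transition matrix at ``lag`` frames.

    Counts are restricted to the largest strongly connected microstate
    set.  ``reversible=True`` symmetrises the count matrix before
    normalisation (detailed-balance estimator); the default is the plain
    non-reversible maximum-likelihood estimator.

    Returns ``(T, pi, active)`` where ``active`` lists the surviving
    microstate indices.
    """
    if isinstance(assignments, np.ndarray) and assignments.ndim == 1:
        assignments = [assignments]
    if n_states is None:
        n_states = int(max(int(np.max(a)) for a in assignments)) + 1
    C = transition_counts(assignments, n_states, lag)
    active = _largest_scc(C)
    if active.size < 2:
        raise MSMError("fewer than 2 connected microstates")
    Csub = C[np.ix_(active, active)]
    if reversible:
        Csub = 0.5 * (Csub + Csub.T)
    rows = Csub.sum(axis=1)
    T = Csub / rows[:, None]
    pi = stationary_distribution(T)
    return T, pi, active


# ---------------------------------------------------------------------------
# coarse graining

def _spectral_grouping(T: np.ndarray, n_macro: int, seed: int):
    """PCCA-style grouping: k-means on the top right-eigenvector coordinates."""
    vals, vecs = np.linalg.eig(T)
    order = np.argsort(-np.abs(vals))
    vals, vecs = vals[order], vecs[:, order]
    flags = []
    if np.abs(np.abs(vals[n_macro - 1]) - np.abs(vals[n_macro])) < 1e-10:
        flags.append("degenerate_spectral_gap")
    coords = np.real(vecs[:, :n_macro])
    coords = coords / np.linalg.norm(coords, axis=0, keepdims=True)
    km = MiniBatchKMeans(n_clusters=n_macro, random_state=seed, n_init=20,
                         batch_size=max(256, coords.shape[0])).fit(coords)
    groups = km.labels_
    if flags:  # deterministic tie-break: reassign by microstate index blocks
        groups = np.asarray(groups)
    return np.asarray(groups), flags


def coarse_grain_label(
    T: np.ndarray,
    pi: np.ndarray,
    micro_means: np.ndarray,
    n_macro: int = 3,
    lag: int = 1,
    active: np.ndarray | None = None,
    n_micro_total: int | None = None,
    seed: int = 0,
) -> MacrostateModel:
    """Group microstates into labelled macrostates.

    ``micro_means`` are the feature (RMSD) means of the active
    microstates.  Macrostates are ordered by stationary-weighted mean
    RMSD and labelled folded / intermediate / unfolded; with
    ``n_macro=4`` the two middle sets are merged into one intermediate so
    the output always has exactly three labels.
    """
    if n_macro not in (3, 4):
        raise MSMError("n_macro must be 3 or 4")
    n_active = T.shape[0]
    if n_active < n_macro:
        raise MSMError("fewer connected microstates than requested macrostates")
    micro_means = np.asarray(micro_means, dtype=float)
    groups, flags = _spectral_grouping(T, n_macro, seed)

    def group_stats(groups, n_groups):
        w = np.array([pi[groups == g].sum() for g in range(n_groups)])
        m = np.array([
            np.average(micro_means[groups == g], weights=pi[groups == g])
            if w[g] > 0 else np.inf
            for g in range(n_groups)
        ])
        return w, m

    w, m = group_stats(groups, n_macro)
    order = np.argsort(m)
    if n_macro == 4:
        # merge the two middle sets into a single intermediate
        merge_map = {order[0]: 0, order[1]: 1, order[2]: 1, order[3]: 2}
        groups = np.array([merge_map[g] for g in groups])
    else:
        relabel = np.empty(n_macro, dtype=int)
        relabel[order] = np.arange(n_macro)
        groups = relabel[groups]
    n_final = 3
    w, m = group_stats(groups, n_final)

    # macro transition matrix: stationary-weighted aggregation
    Tm = np.zeros((n_final, n_final))
    for a in range(n_final):
        wa = pi[groups == a].sum()
        for b in range(n_final):
            Tm[a, b] = np.sum(pi[groups == a, None] * T[np.ix_(groups == a, groups == b)]) / wa
    Tm = Tm / Tm.sum(axis=1, keepdims=True)

    if n_micro_total is None:
        n_micro_total = n_active if active is None else int(np.max(active)) + 1
    micro_to_macro = np.full(n_micro_total, -1, dtype=int)
    act = np.arange(n_active) if active is None else np.asarray(active)
    micro_to_macro[act] = groups
    return MacrostateModel(
        transition_matrix=Tm, stationary=stationary_distribution(Tm),
        micro_to_macro=micro_to_macro, labels=MACRO_LABELS,
        mean_rmsd=m, populations=w / w.sum(), lag=lag,
        micro_transition_matrix=T, micro_stationary=pi, micro_active=act,
        flags=flags,
    )


def assign_macrostates(
    series: FeatureSeries,
    n_micro: int = 50,
    n_macro: int = 3,
    lag: int = 10,
    seed: int = 0,
    reversible: bool = False,
):
    """Full pipeline: cluster -> MSM -> coarse-grain -> per-frame labels.

    Returns ``(macro_model, micro_model, frame_labels)`` where
    ``frame_labels`` is a list of per-trajectory arrays of macro-label
    indices (0 folded, 1 intermediate, 2 unfolded; -1 disconnected).
    """
    micro = cluster_features(series, n_micro, seed=seed)
    T, pi, active = build_msm(micro.assignments, lag=lag, n_states=micro.k,
                              reversible=reversible)
    macro = coarse_grain_label(
        T, pi, micro.centers[active], n_macro=n_macro, lag=lag,
        active=active, n_micro_total=micro.k, seed=seed)
    labels = [macro.frame_labels(a) for a in micro.assignments]
    return macro, micro, labels


# ---------------------------------------------------------------------------
# validation and per-state statistics

def ck_test(assignments, lag: int, factors=(2, 3, 5), n_states: int | None = None):
    """Chapman-Kolmogorov test at multiples of the lag time.

    For each factor f the macro (or micro) transition matrix estimated
    directly at lag f*tau is compared with the tau-matrix raised to the
    f-th power; the deviation is the max-norm difference restricted to
    the states shared by both estimates.  A per-factor sampling bound
    (3x the largest binomial standard error of the directly estimated
    matrix) is reported alongside.
    """
    if isinstance(assignments, np.ndarray) and assignments.ndim == 1:
        assignments = [assignments]
    if n_states is None:
        n_states = int(max(int(np.max(a)) for a in assignments)) + 1
    T1, _, act1 = build_msm(assignments, lag, n_states=n_states)
    rows = []
    for f in factors:
        if f < 1:
            raise MSMError("factors must be >= 1")
        if all(a.size <= lag * f for a in assignments):
            raise MSMError(f"trajectories too short for lag factor {f}")
        Tf, _, actf = build_msm(assignments, lag * f, n_states=n_states)
        shared, i1, i2 = np.intersect1d(act1, actf, return_indices=True)
        Tpow = np.linalg.matrix_power(T1, f)[np.ix_(i1, i1)]
        Tdir = Tf[np.ix_(i2, i2)]
        dev = float(np.max(np.abs(Tdir - Tpow)))
        C = transition_counts(assignments, n_states, lag * f)
        Csub = C[np.ix_(shared, shared)]
        n_i = np.maximum(Csub.sum(axis=1), 1.0)
        P = Csub / n_i[:, None]
        se = np.sqrt(P * (1 - P) / n_i[:, None])
        rows.append({"factor": f, "deviation": dev,
                     "sampling_bound": float(3.0 * np.max(se))})
    return rows


def per_residue_bfactors(frames: np.ndarray, atoms_per_residue: int = 4,
                         max_iter: int = 5):
    """Isotropic B-factors (Å²) per residue from positional fluctuations.

    Frames are iteratively superposed onto their mean structure, then
    B_atom = (8 pi^2 / 3) <|r - <r>|^2> and the residue value is the
    mean over its ``atoms_per_residue`` backbone atoms (C, Cα, N, O).
    ``frames`` has shape (n_frames, n_residues * atoms_per_residue, 3).

    Returns ``(residue_B, atom_B, degenerate_flag)``; a single-frame
    ensemble yields zeros with the degenerate flag set.
    """
    frames = np.asarray(frames, dtype=float)
    n_frames, n_atoms, _ = frames.shape
    if n_atoms % atoms_per_residue:
        raise MSMError("atom count is not a multiple of atoms_per_residue")
    degenerate = n_frames < 2
    mean = frames[0].copy()
    aligned = frames.copy()
    for _ in range(max_iter):
        aligned = np.array([kabsch_superpose(f, mean)[0] for f in frames])
        new_mean = aligned.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < 1e-10:
            mean = new_mean
            break
        mean = new_mean
    msf = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)
    atom_B = (8.0 * np.pi**2 / 3.0) * msf
    residue_B = atom_B.reshape(-1, atoms_per_residue).mean(axis=1)
    return residue_B, atom_B, degenerate


def sample_state_frames(frame_labels: np.ndarray, state: int, n: int,
                        seed: int = 0) -> np.ndarray:
    """Uniformly sample ``n`` frame indices of one macrostate, no replacement.

    If ``n`` meets or exceeds the ensemble size, all member frames are
    returned in index order; selections are reproducible per seed.
    """
    frame_labels = np.asarray(frame_labels)
    members = np.nonzero(frame_labels == state)[0]
    if members.size == 0:
        raise MSMError(f"macrostate {state} has no frames")
    if n >= members.size:
        return members
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(members, size=n, replace=False))


def implied_timescales(assignments, lags, n_states: int | None = None,
                       n_its: int = 3):
    """Implied relaxation timescales -lag/ln|lambda_i| per candidate lag."""
    out = []
    for lag in lags:
        T, _, _ = build_msm(assignments, lag, n_states=n_states)
        vals = np.sort(np.abs(np.linalg.eigvals(T)))[::-1]
        its = [-lag / np.log(v) if 0 < v < 1 else np.inf
               for v in vals[1:1 + n_its]]
        out.append({"lag": lag, "timescales": its})
    return out
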