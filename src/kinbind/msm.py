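"""Markov-model statistics over pre-discretised conformational trajectories.

The module consumes integer state sequences (microstate trajectories produced
upstream by dimensionality reduction and clustering, which are outside its
scope), estimates a lag-time transition matrix from sliding-window counts,
computes stationary populations, coarse-grains microstates into the four
helix/coil macrostates of the two terminal motifs (HLH, CLC, HLC, CLH; the
central segment is always a loop), evaluates mean first-passage times between
macrostates, and quantifies uncertainty by bootstrap resampling of whole
trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .exceptions import (
    DisconnectedStateWarning,
    InsufficientDataError,
    InvalidStateError,
    ReducibleChainWarning,
)

__all__ = [
    "TransitionMatrix",
    "MacrostateAssignment",
    "KineticSummary",
    "estimate_transition_matrix",
    "stationary",
    "coarse_grain",
    "lump",
    "mfpt",
    "mfpt_matrix",
    "bootstrap",
    "MACROSTATES",
]

MACROSTATES = ("HLH", "CLC", "HLC", "CLH")


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix with its count matrix and lag time."""

    matrix: np.ndarray
    counts: np.ndarray
    lag_time: float = 1.0  # physical time per lag step
    disconnected: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def is_irreducible(self) -> bool:
        n, _ = connected_components(self.matrix > 0, directed=True,
                                    connection="strong")
        return n == 1


def estimate_transition_matrix(trajectories, lag: int = 1, n_states: int | None = None,
                               lag_time: float = 1.0) -> TransitionMatrix:
    """Sliding-window transition counts at the given lag, row-normalised.

    All state pairs separated by ``lag`` steps are counted.  Rows with no
    outgoing counts get a self-transition of 1 and raise a
    disconnected-state warning.
    """
    trajs = [np.asarray(t, dtype=np.int64) for t in trajectories]
    if not trajs or all(t.size <= lag for t in trajs):
        raise InsufficientDataError("no transitions at this lag")
    if lag < 1:
        raise InvalidStateError("lag must be >= 1 step")
    if any(t.min() < 0 for t in trajs):
        raise InvalidStateError("states must be non-negative integers")
    n = n_states or (max(int(t.max()) for t in trajs) + 1)
    counts = np.zeros((n, n), dtype=np.int64)
    for t in trajs:
        if t.size > lag:
            np.add.at(counts, (t[:-lag], t[lag:]), 1)
    rowsum = counts.sum(axis=1)
    empty = np.flatnonzero(rowsum == 0)
    T = np.zeros((n, n))
    nz = rowsum > 0
    T[nz] = counts[nz] / rowsum[nz, None]
    for s in empty:
        T[s, s] = 1.0
    if empty.size:
        warnings.warn(
            f"states {empty.tolist()} have no outgoing transitions at lag {lag}; "
            "assigned self-transitions",
            DisconnectedStateWarning, stacklevel=2,
        )
    return TransitionMatrix(matrix=T, counts=counts, lag_time=lag_time * lag,
                            disconnected=empty.tolist())


def stationary(T: TransitionMatrix | np.ndarray, counts: np.ndarray | None = None
               ) -> np.ndarray:
    """Stationary distribution π with πT = π, Σπ = 1.

    For a reducible chain the fixed point is not unique; a warning is issued
    and the empirical state frequencies (from the count matrix) are returned
    instead.
    """
    if isinstance(T, TransitionMatrix):
        counts = T.counts if counts is None else counts
        M = T.matrix
    else:
        M = np.asarray(T, float)
    n_comp, _ = connected_components(M > 0, directed=True, connection="strong")
    if n_comp > 1:
        warnings.warn(
            f"chain is reducible ({n_comp} strongly connected components); "
            "returning empirical state frequencies",
            ReducibleChainWarning, stacklevel=2,
        )
        if counts is not None and counts.sum() > 0:
            freq = counts.sum(axis=1).astype(float)
            return freq / freq.sum()
        return np.full(M.shape[0], 1.0 / M.shape[0])
    w, v = np.linalg.eig(M.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    pi /= pi.sum()
    resid = np.max(np.abs(pi @ M - pi))
    if resid > 1e-10:  # eigen solve lost precision: refine by linear solve
        n = M.shape[0]
        A = np.vstack([M.T - np.eye(n), np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
    return pi


@dataclass
class MacrostateAssignment:
    """Per-microstate macrostate labels from motif helicity.

    A motif counts as helical (H) when its mean helical fraction over the
    motif residues is >= ``threshold``, else coil (C); the middle segment is
    always the loop L.
    """

    labels: np.ndarray  # one of MACROSTATES per microstate
    threshold: float

    def members(self, macro: str) -> np.ndarray:
        return np.flatnonzero(self.labels == macro)

    @property
    def present(self) -> list:
        return [m for m in MACROSTATES if (self.labels == m).any()]


def coarse_grain(helicity: pd.DataFrame, threshold: float = 0.5
                 ) -> MacrostateAssignment:
    """Label microstates by terminal-motif helicity.

    ``helicity`` needs columns ``microstate, har_helicity, nes_helicity``
    (mean helical fraction of the N-terminal high-affinity motif and of the
    C-terminal export-signal motif), one row per microstate, fractions in
    [0, 1].
    """
    req = {"microstate", "har_helicity", "nes_helicity"}
    if not req.issubset(helicity.columns):
        raise InvalidStateError(f"helicity table needs columns {sorted(req)}")
    h = helicity.sort_values("microstate")
    ms = h["microstate"].to_numpy()
    if not np.array_equal(ms, np.arange(ms.size)):
        raise InvalidStateError("helicity must cover microstates 0..n-1 exactly")
    for col in ("har_helicity", "nes_helicity"):
        v = h[col].to_numpy(float)
        if np.any(~np.isfinite(v)) or np.any((v < 0) | (v > 1)):
            raise InvalidStateError(f"{col} must be finite fractions in [0, 1]")
    har = np.where(h["har_helicity"].to_numpy(float) >= threshold, "H", "C")
    nes = np.where(h["nes_helicity"].to_numpy(float) >= threshold, "H", "C")
    labels = np.array([a + "L" + b for a, b in zip(har, nes)])
    return MacrostateAssignment(labels=labels, threshold=threshold)


def lump(pi: np.ndarray, assignment: MacrostateAssignment) -> dict:
    """Macrostate populations: sums of member-microstate stationary weights."""
    pi = np.asarray(pi, float)
    if pi.size != assignment.labels.size:
        raise InvalidStateError("stationary vector and assignment sizes differ")
    return {m: float(pi[assignment.members(m)].sum())
            for m in MACROSTATES if (assignment.labels == m).any()}


def mfpt(T: TransitionMatrix, source_states, target_states,
         pi: np.ndarray | None = None) -> float:
    """Mean first-passage time from a source set to a target set.

    Solves the standard hitting-time linear system (h = 0 on the target,
    h_i = 1 + Σ_j T_ij h_j elsewhere), weights the source microstates by the
    stationary distribution restricted to the source set, and scales by the
    lag time.  Returns inf when the target is unreachable.
    """
    M = T.matrix
    n = M.shape[0]
    target = np.zeros(n, bool)
    target[np.asarray(target_states, int)] = True
    source = np.asarray(source_states, int)
    if target[source].all():
        return 0.0
    keep = ~target
    A = np.eye(keep.sum()) - M[np.ix_(keep, keep)]
    try:
        h_keep = np.linalg.solve(A, np.ones(keep.sum()))
    except np.linalg.LinAlgError:
        return np.inf
    if np.any(h_keep < 0) or not np.all(np.isfinite(h_keep)):
        return np.inf
    h = np.zeros(n)
    h[keep] = h_keep
    if pi is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ReducibleChainWarning)
            pi = stationary(T)
    w = pi[source]
    if w.sum() <= 0:
        w = np.ones(source.size)
    return float((w @ h[source]) / w.sum() * T.lag_time)


def mfpt_matrix(T: TransitionMatrix, assignment: MacrostateAssignment,
                pi: np.ndarray | None = None) -> pd.DataFrame:
    """MFPT between every ordered pair of present macrostates (diagonal 0)."""
    if pi is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ReducibleChainWarning)
            pi = stationary(T)
    macros = assignment.present
    out = pd.DataFrame(0.0, index=macros, columns=macros)
    for a in macros:
        for b in macros:
            if a != b:
                out.loc[a, b] = mfpt(T, assignment.members(a),
                                     assignment.members(b), pi=pi)
    return out


@dataclass
class KineticSummary:
    """Bootstrap mean ± SD of macrostate populations and MFPTs."""

    populations: pd.DataFrame       # index macrostate; mean, sd, point
    mfpt_mean: pd.DataFrame
    mfpt_sd: pd.DataFrame
    n_rounds: int
    n_failed: int
    seed: int | None

    def summary(self) -> str:
        lines = [
            f"Markov-model bootstrap summary "
            f"({self.n_rounds} rounds, {self.n_failed} failed)",
            "populations (mean +/- SD):",
        ]
        for m, row in self.populations.iterrows():
            lines.append(f"  {m}: {row['mean']:.3f} +/- {row['sd']:.3f}")
        lines.append("MFPT mean matrix (time units):")
        lines.append(self.mfpt_mean.round(3).to_string())
        return "\n".join(lines)


def bootstrap(trajectories, lag: int, assignment: MacrostateAssignment,
              n_rounds: int = 150, *, seed: int | None = None,
              lag_time: float = 1.0) -> KineticSummary:
    """Bootstrap (with replacement over whole trajectories) of the Markov model.

    Each round re-estimates the transition matrix, stationary populations,
    macrostate populations and macrostate MFPTs; rounds whose resampled chain
    is disconnected are recorded as failed and excluded from the statistics.
    """
    trajs = [np.asarray(t, dtype=np.int64) for t in trajectories]
    if len(trajs) < 2:
        raise InsufficientDataError("bootstrap needs >= 2 trajectories")
    n_states = assignment.labels.size
    rng = np.random.default_rng(seed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        T_point = estimate_transition_matrix(trajs, lag, n_states, lag_time)
        pi_point = stationary(T_point)
    pop_point = lump(pi_point, assignment)
    macros = assignment.present

    pops, mfpts = [], []
    n_failed = 0
    for _ in range(n_rounds):
        idx = rng.integers(len(trajs), size=len(trajs))
        sample = [trajs[i] for i in idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", DisconnectedStateWarning)
                warnings.simplefilter("error", ReducibleChainWarning)
                T = estimate_transition_matrix(sample, lag, n_states, lag_time)
                pi = stationary(T)
        except (Warning, InsufficientDataError):
            n_failed += 1
            continue
        pops.append([lump(pi, assignment).get(m, 0.0) for m in macros])
        M = mfpt_matrix(T, assignment, pi=pi)
        mfpts.append(M.loc[macros, macros].to_numpy())

    if not pops:
        raise InsufficientDataError("every bootstrap round failed")
    pops = np.asarray(pops)
    mfpts = np.asarray(mfpts)
    sd_ok = len(pops) > 1
    populations = pd.DataFrame(
        {
            "mean": pops.mean(axis=0),
            "sd": pops.std(axis=0, ddof=1) if sd_ok else np.nan,
            "point": [pop_point.get(m, 0.0) for m in macros],
        },
        index=macros,
    )
    mfpt_mean = pd.DataFrame(mfpts.mean(axis=0), index=macros, columns=macros)
    mfpt_sd = pd.DataFrame(
        mfpts.std(axis=0, ddof=1) if sd_ok else np.full_like(mfpts[0], np.nan),
        index=macros, columns=macros,
    )
    return KineticSummary(populations=populations, mfpt_mean=mfpt_mean,
                          mfpt_sd=mfpt_sd, n_rounds=n_rounds,
                          n_failed=n_failed, seed=seed)
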