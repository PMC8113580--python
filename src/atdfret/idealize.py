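"""Segmental k-means (SKM) idealization, transition densities, and dwell extraction.

SKM alternates Viterbi segmentation under Gaussian emissions with re-estimation
of the state means, variances, and transition probabilities from the current
segmentation, until the labels stop changing.  The joint (path) likelihood is
non-decreasing over iterations.  States are reported in descending-mean order
(high / middle / low FRET), matching the R / RA / RAA mapping of the binding
chain.

Dwell sequences are extracted after merging every dwell shorter than the dead
time into its neighbor (preceding dwell, or following for the first), which
conserves total idealized time; the kinetics likelihood conditions on
dwell ≥ dead time for consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .traces import FretTrace

__all__ = [
    "IdealizedTrace",
    "EnsembleIdealization",
    "DwellSequence",
    "TransitionDensity",
    "skm_idealize",
    "skm_idealize_ensemble",
    "remove_zero_state",
    "transition_density",
    "extract_dwells",
    "dwell_time_histogram",
]

_LOG_FLOOR = 1e-12
_SD_FLOOR = 5e-3


@dataclass
class IdealizedTrace:
    """Per-frame discrete state labels plus the fitted state parameters."""

    labels: np.ndarray
    fret: np.ndarray
    state_means: np.ndarray
    state_sds: np.ndarray
    transition_matrix: np.ndarray
    frame_interval: float
    loglik: float = np.nan
    loglik_history: list[float] = field(default_factory=list, repr=False)
    zero_state: int | None = None
    trace_id: str = ""
    movie_id: int = 0

    @property
    def n_states(self) -> int:
        return len(self.state_means)

    def runs(self) -> list[tuple[int, int]]:
        """(state, run length in frames) for each label run."""
        lab = self.labels
        if len(lab) == 0:
            return []
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(lab)]])
        return [(int(lab[a]), int(b - a)) for a, b in zip(starts, ends)]


@dataclass
class EnsembleIdealization:
    """Joint SKM over many traces with shared emission and transition parameters."""

    traces: list[IdealizedTrace]
    state_means: np.ndarray
    state_sds: np.ndarray
    transition_matrix: np.ndarray
    loglik: float
    loglik_history: list[float] = field(default_factory=list, repr=False)


@dataclass
class DwellSequence:
    """Ordered (state, duration s) runs after dead-time merging."""

    dwells: list[tuple[int, float]]
    dead_time: float
    frame_interval: float
    censored_first: bool = True
    censored_last: bool = True
    trace_id: str = ""
    empty_reason: str | None = None

    @property
    def total_time(self) -> float:
        return float(sum(d for _, d in self.dwells))


@dataclass
class TransitionDensity:
    """2-D counts over (FRET before, FRET after) at idealized transitions."""

    grid: np.ndarray
    bin_edges: np.ndarray
    n_transitions: int
    t_per_s: float

    def offdiag_fraction(self, i: int, j: int, means: np.ndarray,
                         tol: float = 0.06) -> float:
        """Fraction of transitions falling near (means[i], means[j])."""
        if self.n_transitions == 0:
            return 0.0
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        sel_i = np.abs(centers - means[i]) <= tol
        sel_j = np.abs(centers - means[j]) <= tol
        return float(self.grid[np.ix_(sel_i, sel_j)].sum() / self.n_transitions)


def _viterbi(x: np.ndarray, means: np.ndarray, sds: np.ndarray,
             log_a: np.ndarray, log_pi: np.ndarray) -> tuple[np.ndarray, float]:
    """Most likely state path under Gaussian emissions; ties prefer staying put."""
    k = len(means)
    t_len = len(x)
    emit = (-0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :]) - 0.5 * np.log(2.0 * np.pi))
    score = np.empty((t_len, k))
    ptr = np.zeros((t_len, k), dtype=np.int32)
    score[0] = log_pi + emit[0]
    for t in range(1, t_len):
        cand = score[t - 1][:, None] + log_a          # cand[i, j]: from i to j
        best = cand.max(axis=0)
        arg = cand.argmax(axis=0)
        stay = np.arange(k)
        # exact-tie preference for remaining in the same state
        arg = np.where(cand[stay, stay] == best, stay, arg)
        ptr[t] = arg
        score[t] = best + emit[t]
    labels = np.empty(t_len, dtype=np.int32)
    labels[-1] = int(np.argmax(score[-1]))
    for t in range(t_len - 2, -1, -1):
        labels[t] = ptr[t + 1, labels[t + 1]]
    return labels, float(score[-1].max())


def _skm_core(
    sequences: list[np.ndarray],
    n_states: int,
    init_means: np.ndarray,
    init_sds: np.ndarray,
    max_iter: int,
    fix_transitions: bool,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
    k = n_states
    means = np.asarray(init_means, float).copy()
    sds = np.maximum(np.asarray(init_sds, float).copy(), _SD_FLOOR)
    a = np.full((k, k), 0.05 / max(k - 1, 1))
    np.fill_diagonal(a, 0.95)
    pi = np.full(k, 1.0 / k)
    prev_labels: list[np.ndarray] | None = None
    history: list[float] = []
    labels_list: list[np.ndarray] = []
    loglik = -np.inf

    for _ in range(max_iter):
        log_a = np.log(np.maximum(a, _LOG_FLOOR))
        log_pi = np.log(np.maximum(pi, _LOG_FLOOR))
        labels_list = []
        loglik = 0.0
        for x in sequences:
            lab, ll = _viterbi(x, means, sds, log_a, log_pi)
            labels_list.append(lab)
            loglik += ll
        history.append(loglik)
        if prev_labels is not None and all(
                np.array_equal(p, l) for p, l in zip(prev_labels, labels_list)):
            break
        prev_labels = labels_list

        # re-estimate emission parameters from the pooled segmentation
        allx = np.concatenate(sequences)
        alll = np.concatenate(labels_list)
        occupied = [s for s in range(k) if np.any(alll == s)]
        if len(occupied) < k:
            warnings.warn(f"SKM dropped {k - len(occupied)} empty state(s)")
            remap = -np.ones(k, dtype=int)
            for new, old in enumerate(occupied):
                remap[old] = new
            means = means[occupied]
            sds = sds[occupied]
            a = a[np.ix_(occupied, occupied)]
            a = a / a.sum(axis=1, keepdims=True)
            pi = pi[occupied]
            pi = pi / pi.sum()
            k = len(occupied)
            sequences_labels = [remap[l] for l in labels_list]
            labels_list = sequences_labels
            alll = np.concatenate(labels_list)
            prev_labels = labels_list
        for s in range(k):
            sel = alll == s
            means[s] = allx[sel].mean()
            sds[s] = max(float(allx[sel].std()), _SD_FLOOR)
        if not fix_transitions:
            counts = np.zeros((k, k))
            for lab in labels_list:
                np.add.at(counts, (lab[:-1], lab[1:]), 1.0)
            rowsum = counts.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                a = np.where(rowsum > 0, counts / rowsum, 1.0 / k)
        pi = np.bincount([l[0] for l in labels_list], minlength=k).astype(float)
        pi = pi / pi.sum()

    # canonical descending-mean ordering
    order = np.argsort(-means)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels_list = [remap[l].astype(np.int32) for l in labels_list]
    means = means[order]
    sds = sds[order]
    a = a[np.ix_(order, order)]
    return labels_list, means, sds, a, loglik, history


def _default_init_means(data: np.ndarray, n_states: int) -> np.ndarray:
    qs = 1.0 - (np.arange(n_states) + 0.5) / n_states
    return np.quantile(data[np.isfinite(data)], qs)


def _run_skm(
    sequences: list[np.ndarray],
    n_states: int,
    init_means: np.ndarray | None,
    init_sds: np.ndarray | None,
    max_iter: int,
    restarts: int,
    fix_transitions: bool,
    seed: int,
):
    pooled = np.concatenate(sequences)
    if len(pooled) < n_states:
        raise ValueError("need at least n_states frames")
    base_means = (_default_init_means(pooled, n_states) if init_means is None
                  else np.asarray(init_means, float))
    if len(np.unique(base_means)) != n_states:
        raise ValueError("init_means must be distinct")
    base_sds = (np.full(n_states, 0.05) if init_sds is None
                else np.asarray(init_sds, float))
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(restarts, 1)):
        means = base_means if r == 0 else base_means + rng.normal(0.0, 0.02, n_states)
        out = _skm_core(sequences, n_states, means, base_sds, max_iter, fix_transitions)
        if best is None or out[4] > best[4]:
            best = out
    return best


def skm_idealize(
    ft: FretTrace | np.ndarray,
    n_states: int = 3,
    init_means: np.ndarray | None = None,
    init_sds: np.ndarray | None = None,
    max_iter: int = 100,
    restarts: int = 3,
    fix_transitions: bool = False,
    include_zero_state: bool = False,
    seed: int = 0,
) -> IdealizedTrace:
    """SKM idealization of a single FRET trace.

    ``include_zero_state`` adds one extra class initialized at FRET 0 for
    post-acceptor-bleach frames; the returned trace marks that class in
    ``zero_state`` so :func:`remove_zero_state` can strip it.
    """
    if isinstance(ft, FretTrace):
        x = ft.usable
        dt, tid, mid = ft.frame_interval, ft.trace_id, ft.movie_id
    else:
        x = np.asarray(ft, float)
        dt, tid, mid = 0.1, "", 0
    x = x[np.isfinite(x)]
    k = n_states + (1 if include_zero_state else 0)
    if include_zero_state:
        base = (_default_init_means(x, n_states) if init_means is None
                else np.asarray(init_means, float))
        init_means = np.concatenate([base, [0.0]])
    labels, means, sds, a, ll, hist = _run_skm(
        [x], k, init_means, init_sds, max_iter, restarts, fix_transitions, seed)
    labels = labels[0]
    zero = None
    if include_zero_state and len(means) > 1 and means[-1] < 0.15:
        zero = len(means) - 1
    return IdealizedTrace(labels=labels, fret=x, state_means=means, state_sds=sds,
                          transition_matrix=a, frame_interval=dt, loglik=ll,
                          loglik_history=hist, zero_state=zero,
                          trace_id=tid, movie_id=mid)


def skm_idealize_ensemble(
    fts: list[FretTrace],
    n_states: int = 3,
    init_means: np.ndarray | None = None,
    init_sds: np.ndarray | None = None,
    max_iter: int = 100,
    restarts: int = 3,
    fix_transitions: bool = False,
    seed: int = 0,
) -> EnsembleIdealization:
    """Joint SKM over many traces sharing emission and transition parameters.

    This is the per-movie idealization mode: single 20–60-s traces rarely
    visit all three states, so the state model is estimated from the pooled
    segmentation while the Viterbi path is computed per trace.
    """
    seqs = []
    for ft in fts:
        x = ft.usable
        seqs.append(x[np.isfinite(x)])
    labels_list, means, sds, a, ll, hist = _run_skm(
        seqs, n_states, init_means, init_sds, max_iter, restarts, fix_transitions, seed)
    traces = [IdealizedTrace(labels=lab, fret=x, state_means=means, state_sds=sds,
                             transition_matrix=a, frame_interval=ft.frame_interval,
                             loglik=np.nan, trace_id=ft.trace_id, movie_id=ft.movie_id)
              for lab, x, ft in zip(labels_list, seqs, fts)]
    return EnsembleIdealization(traces=traces, state_means=means, state_sds=sds,
                                transition_matrix=a, loglik=ll, loglik_history=hist)


def remove_zero_state(it: IdealizedTrace) -> IdealizedTrace:
    """Strip the zero-FRET (post-acceptor-bleach / blink) class from a trace.

    Trailing zero-state frames are truncated; an internal zero run splits the
    trace and the longer fragment is retained.  A trace that is entirely
    zero-state returns empty labels.
    """
    if it.zero_state is None:
        return it
    z = it.zero_state
    keep = it.labels != z
    if not np.any(keep):
        out = _strip_state(it, z, np.zeros(0, dtype=np.int32), np.zeros(0))
        return out
    nz = np.flatnonzero(keep)
    # fragments of consecutive non-zero frames
    breaks = np.flatnonzero(np.diff(nz) > 1) + 1
    frag_idx = np.split(nz, breaks)
    best = max(frag_idx, key=len)
    return _strip_state(it, z, it.labels[best], it.fret[best])


def _strip_state(it: IdealizedTrace, z: int, labels: np.ndarray,
                 fret: np.ndarray) -> IdealizedTrace:
    keep_states = [s for s in range(it.n_states) if s != z]
    remap = -np.ones(it.n_states, dtype=int)
    for new, old in enumerate(keep_states):
        remap[old] = new
    sub = it.transition_matrix[np.ix_(keep_states, keep_states)]
    rowsum = sub.sum(axis=1, keepdims=True)
    sub = np.where(rowsum > 0, sub / rowsum, 1.0 / max(len(keep_states), 1))
    return IdealizedTrace(
        labels=remap[labels].astype(np.int32) if len(labels) else labels,
        fret=fret, state_means=it.state_means[keep_states],
        state_sds=it.state_sds[keep_states], transition_matrix=sub,
        frame_interval=it.frame_interval, loglik=np.nan, zero_state=None,
        trace_id=it.trace_id, movie_id=it.movie_id)


def transition_density(
    its: list[IdealizedTrace],
    bin_edges: np.ndarray | None = None,
) -> TransitionDensity:
    """2-D histogram of (mean FRET of preceding dwell, mean FRET of following dwell).

    One count per label-change frame; the diagonal is empty by construction.
    ``t_per_s`` is the total number of transitions divided by the total
    idealized time.
    """
    if bin_edges is None:
        bin_edges = -0.2 + 0.02 * np.arange(71)
    before, after = [], []
    total_time = 0.0
    for it in its:
        total_time += len(it.labels) * it.frame_interval
        runs = it.runs()
        if len(runs) < 2:
            continue
        pos = 0
        means = []
        for _, n in runs:
            means.append(float(np.nanmean(it.fret[pos:pos + n])))
            pos += n
        before.extend(means[:-1])
        after.extend(means[1:])
    n_t = len(before)
    grid, _, _ = np.histogram2d(np.asarray(before), np.asarray(after), bins=[bin_edges] * 2)
    t_per_s = n_t / total_time if total_time > 0 else 0.0
    return TransitionDensity(grid=grid, bin_edges=np.asarray(bin_edges),
                             n_transitions=n_t, t_per_s=float(t_per_s))


def _merge_short_dwells(runs: list[tuple[int, float]],
                        dead_time: float) -> list[tuple[int, float]]:
    """Iterative merge of sub-dead-time dwells into neighbors, conserving time."""
    runs = list(runs)
    while True:
        # coalesce adjacent same-state dwells first
        merged: list[tuple[int, float]] = []
        for s, d in runs:
            if merged and merged[-1][0] == s:
                merged[-1] = (s, merged[-1][1] + d)
            else:
                merged.append((s, d))
        runs = merged
        idx = next((i for i, (_, d) in enumerate(runs) if d < dead_time - 1e-12), None)
        if idx is None or len(runs) == 1:
            break
        if idx == 0:
            s1, d1 = runs[1]
            runs[1] = (s1, d1 + runs[0][1])
            runs.pop(0)
        else:
            s0, d0 = runs[idx - 1]
            runs[idx - 1] = (s0, d0 + runs[idx][1])
            runs.pop(idx)
    return runs


def extract_dwells(it: IdealizedTrace, dead_time: float = 0.2) -> DwellSequence:
    """Dead-time-corrected dwell sequence from an idealized trace.

    Runs shorter than ``dead_time`` are merged into the preceding dwell (the
    first into the following one), iteratively, conserving total time.  First
    and last dwells are flagged censored: the first's entry and the last's
    exit fall outside the observation window.
    """
    dt = it.frame_interval
    runs = [(s, n * dt) for s, n in it.runs()]
    total = sum(d for _, d in runs)
    if total < dead_time or not runs:
        return DwellSequence(dwells=[], dead_time=dead_time, frame_interval=dt,
                             trace_id=it.trace_id, empty_reason="shorter_than_dead_time")
    merged = _merge_short_dwells(runs, dead_time)
    if len(merged) == 1 and merged[0][1] < dead_time:
        return DwellSequence(dwells=[], dead_time=dead_time, frame_interval=dt,
                             trace_id=it.trace_id, empty_reason="shorter_than_dead_time")
    return DwellSequence(dwells=merged, dead_time=dead_time, frame_interval=dt,
                         trace_id=it.trace_id)


def dwell_time_histogram(durations: np.ndarray, log_bins: bool = True,
                         n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Binned dwell-time counts for display (Sigworth–Sine-style log bins).

    Kinetic fitting always uses the raw dwell durations, never these bins.
    """
    durations = np.asarray(durations, float)
    if len(durations) == 0:
        raise ValueError("no dwells")
    if log_bins:
        lo, hi = durations.min(), durations.max() * (1 + 1e-9)
        edges = np.geomspace(max(lo, 1e-3), hi, n_bins + 1)
    else:
        edges = np.linspace(0.0, durations.max() * (1 + 1e-9), n_bins + 1)
    counts, edges = np.histogram(durations, bins=edges)
    return counts, edges
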