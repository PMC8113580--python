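"""Forward simulation of single-molecule FRET recordings of a two-site binding chain.

The generator produces donor/acceptor intensity traces with the statistical
structure the downstream analysis assumes: a receptor whose conformation follows
a continuous-time Markov chain over three states — resting (R), one ligand-binding
site occupied (RA), both sites occupied (RAA) — with concentration-dependent
rates for two identical, independent binding sites; Gaussian emission noise;
donor→acceptor spectral crosstalk and a detection-efficiency asymmetry (γ);
and single-step donor and acceptor photobleaching.  Traces are grouped into
"movies", the unit over which histograms are averaged.

The renderer is the exact inverse of the corrections applied by
:func:`atdfret.traces.compute_fret`: at zero noise, processing a rendered trace
with the same crosstalk and γ returns the frame-averaged state FRET exactly.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

STATE_NAMES = ("R", "RA", "RAA")
N_STATES = 3

__all__ = [
    "STATE_NAMES",
    "KineticParams",
    "EmissionParams",
    "PhotophysicsParams",
    "StatePath",
    "PhotonTrace",
    "TraceSet",
    "build_rate_matrix",
    "stationary_distribution",
    "simulate_state_path",
    "render_trace",
    "simulate_experiment",
    "write_traceset",
    "read_traceset",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class KineticParams:
    """Per-site association/dissociation rate constants and ligand concentration.

    Parameters
    ----------
    kon : float
        Association rate constant per binding site (µM⁻¹ s⁻¹).
    koff : float
        Dissociation rate constant per site (s⁻¹).
    conc : float
        Ligand (glutamate) concentration (µM).
    """

    kon: float = 1.0
    koff: float = 0.46
    conc: float = 0.3

    def __post_init__(self) -> None:
        _require(np.isfinite(self.kon) and self.kon > 0, "kon must be finite and > 0")
        _require(np.isfinite(self.koff) and self.koff > 0, "koff must be finite and > 0")
        _require(np.isfinite(self.conc) and self.conc >= 0, "conc must be finite and >= 0")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant per site, koff/kon (µM)."""
        return self.koff / self.kon


@dataclass(frozen=True)
class EmissionParams:
    """FRET emission model: state means, signal level, noise, and detection distortions.

    ``noise_sd`` is per-channel additive Gaussian noise in intensity units; the
    default (33 a.u. at total_intensity 500) gives a single-state FRET histogram
    SD of ≈0.055 after the crosstalk/γ corrections.
    """

    state_means: tuple[float, ...] = (0.52, 0.40, 0.28)
    total_intensity: float = 500.0
    noise_sd: float = 33.0
    crosstalk: float = 0.105
    gamma: float = 1.1

    def __post_init__(self) -> None:
        means = np.asarray(self.state_means, dtype=float)
        _require(means.ndim == 1 and len(means) >= 1, "state_means must be a 1-D sequence")
        _require(bool(np.all(np.diff(means) < 0)) or len(means) == 1,
                 "state_means must be strictly decreasing from R to RAA")
        _require(0 <= self.crosstalk < 1, "crosstalk must be in [0, 1)")
        _require(self.gamma > 0, "gamma must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.total_intensity > 0, "total_intensity must be > 0")

    def fret_noise_sd(self, fret: float) -> float:
        """Delta-method SD of computed FRET at a given true FRET level.

        Propagates the per-channel intensity noise through the corrected FRET
        formula E = (IA − c·γ·ID)/(γ·ID + IA) at the rendered operating point.
        """
        c, g, T = self.crosstalk, self.gamma, self.total_intensity
        d_corr = T * (1.0 - fret) / (1.0 + c)      # γ·ID
        a = T * (fret + c) / (1.0 + c)             # IA
        # ∂E/∂IA = (1+c)·γ·ID / T²;  ∂E/∂ID = −γ·(1+c)·IA / T²
        grad2 = ((1.0 + c) ** 2) * (d_corr**2 + (g * a) ** 2) / T**4
        return float(self.noise_sd * math.sqrt(grad2))


@dataclass(frozen=True)
class PhotophysicsParams:
    """Single-step photobleaching model: exponential bleach times, flat background."""

    donor_bleach_mean: float = 80.0
    acceptor_bleach_mean: float = 120.0
    background_level: float = 0.0

    def __post_init__(self) -> None:
        _require(self.donor_bleach_mean > 0, "donor_bleach_mean must be > 0")
        _require(self.acceptor_bleach_mean > 0, "acceptor_bleach_mean must be > 0")
        _require(self.background_level >= 0, "background_level must be >= 0")


@dataclass
class StatePath:
    """Piecewise-constant conformational trajectory.

    ``states[k]`` holds between ``bounds[k]`` and ``bounds[k+1]`` (seconds);
    the segments are contiguous and cover [0, duration].
    """

    states: np.ndarray
    bounds: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.bounds[-1])

    @property
    def segments(self) -> list[tuple[int, float, float]]:
        return [(int(s), float(a), float(b))
                for s, a, b in zip(self.states, self.bounds[:-1], self.bounds[1:])]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.bounds = np.asarray(self.bounds, dtype=float)
        _require(len(self.bounds) == len(self.states) + 1, "bounds must have len(states)+1 entries")
        _require(bool(np.all(np.diff(self.bounds) > 0)), "segments must have positive length")


@dataclass
class PhotonTrace:
    """Per-frame donor and acceptor intensities for one molecule."""

    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    trace_id: str = ""
    movie_id: int = 0
    truth: dict = field(default_factory=dict, repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass
class TraceSet:
    """A collection of traces grouped into movies sharing one condition."""

    traces: list[PhotonTrace]
    frame_interval: float
    condition: dict = field(default_factory=dict)
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def movie_ids(self) -> list[int]:
        return sorted({t.movie_id for t in self.traces})

    def by_movie(self) -> dict[int, list[PhotonTrace]]:
        out: dict[int, list[PhotonTrace]] = {}
        for t in self.traces:
            out.setdefault(t.movie_id, []).append(t)
        return out


def build_rate_matrix(kp: KineticParams) -> np.ndarray:
    """Generator matrix Q of the linear R↔RA↔RAA chain for two independent sites.

    Off-diagonal entries: R→RA = 2·kon·conc, RA→RAA = kon·conc,
    RA→R = koff, RAA→RA = 2·koff; rows sum to zero; there is no direct R↔RAA edge.
    """
    if not (np.isfinite(kp.kon) and np.isfinite(kp.koff) and np.isfinite(kp.conc)):
        raise ValueError("kinetic parameters must be finite")
    q = np.zeros((N_STATES, N_STATES), dtype=float)
    q[0, 1] = 2.0 * kp.kon * kp.conc
    q[1, 2] = kp.kon * kp.conc
    q[1, 0] = kp.koff
    q[2, 1] = 2.0 * kp.koff
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _validate_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("Q must be square")
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("Q off-diagonals must be non-negative")
    if np.any(np.diag(q) > 1e-12):
        raise ValueError("Q diagonal must be non-positive")
    if np.any(np.abs(q.sum(axis=1)) > 1e-9 * max(1.0, np.abs(q).max())):
        raise ValueError("Q rows must sum to zero")
    return q


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution π with πQ = 0, Σπ = 1 (least-squares solve)."""
    q = _validate_q(q)
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_state_path(
    q: np.ndarray,
    duration: float,
    start_state: int | None = None,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> StatePath:
    """Exact stochastic (Gillespie) realization of the chain over [0, duration].

    ``start_state=None`` draws the initial state from the stationary
    distribution of Q, which is the relevant ensemble for traces recorded at
    equilibrium.
    """
    q = _validate_q(q)
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = q.shape[0]
    if start_state is None:
        state = int(rng.choice(n, p=stationary_distribution(q)))
    else:
        state = int(start_state)
        if not 0 <= state < n:
            raise ValueError("start_state out of range")

    states = [state]
    bounds = [0.0]
    t = 0.0
    while True:
        rate = -q[state, state]
        if rate <= 0.0:  # absorbing state: dwell covers the rest of the trace
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        probs = q[state].copy()
        probs[state] = 0.0
        probs = probs / rate
        state = int(rng.choice(n, p=probs))
        states.append(state)
        bounds.append(t)
    bounds.append(duration)
    return StatePath(np.array(states), np.array(bounds))


def _frame_average(values: np.ndarray, bounds: np.ndarray, n_frames: int, dt: float) -> np.ndarray:
    """Time-weighted per-frame average of a piecewise-constant signal."""
    out = np.zeros(n_frames)
    for v, a, b in zip(values, bounds[:-1], bounds[1:]):
        a = max(float(a), 0.0)
        b = min(float(b), n_frames * dt)
        if b <= a:
            continue
        i0 = int(a / dt)
        i1 = min(int(math.ceil(b / dt)), n_frames)
        if i1 - i0 == 1:
            out[i0] += v * (b - a)
            continue
        # partial first and last frames, full frames in between
        out[i0] += v * ((i0 + 1) * dt - a)
        out[i1 - 1] += v * (b - (i1 - 1) * dt)
        if i1 - i0 > 2:
            out[i0 + 1:i1 - 1] += v * dt
    return out / dt


def render_trace(
    path: StatePath,
    em: EmissionParams,
    ph: PhotophysicsParams,
    frame_interval: float = 0.1,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    bad: str | None = None,
) -> PhotonTrace:
    """Render a state path into a noisy donor/acceptor intensity trace.

    Per frame the ideal corrected intensities are the time-weighted averages of
    the piecewise-constant emission: before acceptor bleach, corrected donor
    γ·ID = T·(1−E)/(1+c) and acceptor IA = T·(E+c)/(1+c) with E the state mean
    (so that compute_fret inverts them exactly); between acceptor and donor
    bleach E = 0 with the donor signal persisting; after donor bleach both raw
    channels sit at the background level.  Gaussian noise is then added to each
    raw channel.

    ``bad`` switches on a pathological-trace mode used to exercise the
    selection filter: ``"multistep_acceptor"`` adds a second, directly excited
    acceptor fluorophore with its own bleach step; ``"drifting_total"``
    multiplies both channels by a downward linear ramp.
    """
    if not frame_interval > 0:
        raise ValueError("frame_interval must be > 0")
    rng = np.random.default_rng(seed)
    dt = frame_interval
    duration = path.duration
    n_frames = int(round(duration / dt))
    c, g, T = em.crosstalk, em.gamma, em.total_intensity
    bg = ph.background_level

    t_acc = rng.exponential(ph.acceptor_bleach_mean)
    t_don = rng.exponential(ph.donor_bleach_mean)

    # piecewise-constant raw-channel levels: state segments, then bleach regimes
    pieces: list[tuple[float, float, float, float]] = []  # (t0, t1, donor_raw, acceptor)
    t_fret_end = min(t_acc, t_don, duration)
    for s, a, b in path.segments:
        if a >= t_fret_end:
            break
        b = min(b, t_fret_end)
        e = em.state_means[s]
        d_corr = T * (1.0 - e) / (1.0 + c)
        acc = T * (e + c) / (1.0 + c)
        pieces.append((a, b, d_corr / g, acc))
    if t_acc < t_don and t_acc < duration:
        # acceptor dark: E = 0, total corrected signal unchanged
        end = min(t_don, duration)
        pieces.append((t_acc, end, (T / (1.0 + c)) / g, c * T / (1.0 + c)))
    if t_don < duration:
        pieces.append((t_don, duration, bg, bg))

    if pieces:
        vals_d = np.array([p[2] for p in pieces])
        vals_a = np.array([p[3] for p in pieces])
        bnds = np.array([p[0] for p in pieces] + [pieces[-1][1]])
        donor = _frame_average(vals_d, bnds, n_frames, dt)
        acceptor = _frame_average(vals_a, bnds, n_frames, dt)
    else:  # degenerate: bleached before the first frame
        donor = np.full(n_frames, bg)
        acceptor = np.full(n_frames, bg)

    if bad == "multistep_acceptor":
        t_extra = rng.exponential(ph.acceptor_bleach_mean / 2.0)
        extra = np.zeros(n_frames)
        k = min(n_frames, int(t_extra / dt))
        extra[:k] = T / 2.0
        acceptor = acceptor + extra
    elif bad == "drifting_total":
        ramp = np.linspace(1.0, 0.2, n_frames)
        donor = donor * ramp
        acceptor = acceptor * ramp
    elif bad is not None:
        raise ValueError(f"unknown bad-trace mode: {bad!r}")

    if em.noise_sd > 0:
        donor = donor + rng.normal(0.0, em.noise_sd, n_frames)
        acceptor = acceptor + rng.normal(0.0, em.noise_sd, n_frames)

    return PhotonTrace(
        donor=donor,
        acceptor=acceptor,
        frame_interval=dt,
        truth={"t_acceptor_bleach": float(t_acc), "t_donor_bleach": float(t_don),
               "path": path, "bad": bad},
    )


def simulate_experiment(
    kp: KineticParams,
    em: EmissionParams | None = None,
    ph: PhotophysicsParams | None = None,
    n_movies: int = 5,
    traces_per_movie: int = 120,
    duration: float = 60.0,
    frame_interval: float = 0.1,
    seed: int = 0,
    start_state: int | None = None,
    bad_fraction: float = 0.0,
    bad_mode: str = "multistep_acceptor",
    condition: dict | None = None,
) -> TraceSet:
    """Simulate a set of movies under one condition.

    Every trace draws its randomness from a seed derived from
    ``(seed, movie, trace)``, so any subset of traces is reproducible
    independently of the rest.
    """
    if n_movies < 1 or traces_per_movie < 1:
        raise ValueError("n_movies and traces_per_movie must be >= 1")
    em = em or EmissionParams()
    ph = ph or PhotophysicsParams()
    q = build_rate_matrix(kp)
    n_bad = int(round(bad_fraction * traces_per_movie))
    traces = []
    for m in range(1, n_movies + 1):
        for i in range(traces_per_movie):
            ss = np.random.SeedSequence((seed, m, i))
            rng = np.random.default_rng(ss)
            path = simulate_state_path(q, duration, start_state=start_state, seed=rng)
            tr = render_trace(path, em, ph, frame_interval, seed=rng,
                              bad=bad_mode if i < n_bad else None)
            tr.trace_id = f"m{m:02d}_t{i:04d}"
            tr.movie_id = m
            traces.append(tr)
    cond = dict(condition or {})
    cond.setdefault("conc", kp.conc)
    return TraceSet(
        traces=traces,
        frame_interval=frame_interval,
        condition=cond,
        seed=seed,
        params={"kinetics": asdict(kp), "emission": asdict(em), "photophysics": asdict(ph),
                "n_movies": n_movies, "traces_per_movie": traces_per_movie,
                "duration": duration, "start_state": start_state,
                "bad_fraction": bad_fraction, "bad_mode": bad_mode},
    )


def write_traceset(ts: TraceSet, outdir: str | pathlib.Path) -> None:
    """One TSV per movie (trace_id, frame_index, donor, acceptor) + JSON sidecar."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for movie_id, traces in sorted(ts.by_movie().items()):
        frames = []
        for t in traces:
            frames.append(pd.DataFrame({
                "trace_id": t.trace_id,
                "frame_index": np.arange(t.n_frames),
                "donor": t.donor,
                "acceptor": t.acceptor,
            }))
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / f"movie_{movie_id:02d}.tsv", sep="\t", index=False, float_format="%.6f")
    meta = {"condition": ts.condition, "frame_interval": ts.frame_interval,
            "seed": ts.seed, "params": ts.params}
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_traceset(indir: str | pathlib.Path) -> TraceSet:
    indir = pathlib.Path(indir)
    meta = json.loads((indir / "metadata.json").read_text())
    traces = []
    for f in sorted(indir.glob("movie_*.tsv")):
        movie_id = int(f.stem.split("_")[1])
        df = pd.read_csv(f, sep="\t")
        for tid, grp in df.groupby("trace_id", sort=True):
            grp = grp.sort_values("frame_index")
            traces.append(PhotonTrace(
                donor=grp["donor"].to_numpy(float),
                acceptor=grp["acceptor"].to_numpy(float),
                frame_interval=float(meta["frame_interval"]),
                trace_id=str(tid), movie_id=movie_id))
    return TraceSet(traces=traces, frame_interval=float(meta["frame_interval"]),
                    condition=meta.get("condition", {}), seed=meta.get("seed"),
                    params=meta.get("params", {}))
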